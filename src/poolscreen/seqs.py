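"""Nucleotide sequence helpers shared by the simulator, matcher and QC stages.

Sequences are plain Python strings over {A,C,G,T} at the API surface and
uint8 code arrays (A=0, C=1, G=2, T=3) internally.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array (non-ACGT -> 255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(random_codes(rng, length))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-mer of a code array into int64 values.

    Positions whose window contains a non-ACGT code are returned as -1.
    Requires k <= 31.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing into int64")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    c = np.where(valid, codes, 0).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(c, k)
    values = windows @ weights
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.where(ok, values, -1)
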