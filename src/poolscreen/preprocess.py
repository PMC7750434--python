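"""Read QC and host/vector subtraction for the optional read-level path.

Quality trimming is a simple end-trim: leading and trailing bases below the
Phred threshold (default Q30) are removed and reads shorter than 30 bp are
discarded.  Host/vector subtraction replaces read mapping with exact k-mer
containment: a sequence is removed when at least a fraction ``tau`` of its
k-mers occur in the reference k-mer set (both strands indexed).  Both are
deterministic, dependency-free stand-ins with the same keep/remove contract
as the mapping-based originals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqs


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise PreprocessError(
                f"read {self.id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} quality scores"
            )


def quality_trim(read: Read, qmin: int = 30, minlen: int = 30) -> Read | None:
    """End-trim bases below ``qmin``; drop the read if < ``minlen`` bp remain."""
    if qmin < 0:
        raise PreprocessError("qmin must be >= 0")
    q = np.asarray(read.qualities)
    good = np.nonzero(q >= qmin)[0]
    if len(good) == 0:
        return None
    start, end = int(good[0]), int(good[-1]) + 1
    if end - start < minlen:
        return None
    if start == 0 and end == len(q):
        return read
    return Read(read.id, read.bases[start:end], read.qualities[start:end])


def reference_kmers(references: Mapping[str, str], k: int = 31) -> set[int]:
    """Packed k-mer set over both strands of the reference sequences."""
    if not references:
        raise PreprocessError("empty reference set")
    out: set[int] = set()
    for seq in references.values():
        for s in (seq, seqs.revcomp(seq)):
            km = seqs.kmer_codes(seqs.encode(s), k)
            out.update(int(v) for v in km[km >= 0])
    return out


def host_vector_filter(
    sequences: Sequence[tuple[str, str]],
    references: Mapping[str, str],
    k: int = 31,
    tau: float = 0.5,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Partition (id, sequence) pairs into (kept, removed) by k-mer containment.

    A sequence is removed iff the fraction of its k-mer positions found in
    the reference set is >= ``tau``.  Sequences shorter than k are kept
    (no evidence).
    """
    if not 0.0 < tau <= 1.0:
        raise PreprocessError("tau must be in (0, 1]")
    ref = reference_kmers(references, k)
    kept, removed = [], []
    for sid, seq in sequences:
        km = seqs.kmer_codes(seqs.encode(seq), k)
        km = km[km >= 0]
        if len(km) == 0:
            kept.append((sid, seq))
            continue
        frac = sum(1 for v in km if int(v) in ref) / len(km)
        (removed if frac >= tau else kept).append((sid, seq))
    return kept, removed


def filter_summary(
    n_input: int, n_kept: int, n_removed: int
) -> pd.DataFrame:
    """One-row QC summary table (counts and removed fraction)."""
    return pd.DataFrame(
        [
            {
                "input": n_input,
                "kept": n_kept,
                "removed": n_removed,
                "removed_fraction": n_removed / n_input if n_input else 0.0,
            }
        ]
    )
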