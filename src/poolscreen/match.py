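"""Cross-pool contig similarity: k-mer seeded, X-drop extended alignment.

Plate-pool contigs are compared against row- and column-pool contigs to find
near-identical sequences shared between pools (fragments of the same clone
insert).  The engine is a self-contained nucleotide matcher:

* exact k-mer seeds (default k=15) located through a sorted index over the
  subject contigs;
* ungapped two-way X-drop extension along the seed diagonal under +1/−2
  match/mismatch scoring (pooled copies of the same insert differ by
  substitutions only, so gapped refinement is unnecessary for the built-in
  simulator and is deliberately not applied);
* significance via the ungapped Karlin–Altschul e-value
  ``E = K·m·n·exp(−λS)``, with λ solved exactly from the scoring scheme and
  background base frequencies.

Hits are reported when identity, e-value and alignment length pass the
screening thresholds (defaults 95%, 1e-6, 100 bp); the best-scoring hit per
(query, subject) pair is retained.  Output is deterministic: queries are
processed in id order and ties break on lexicographic subject id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from . import seqs
from .design import PoolId


class MatchError(ValueError):
    pass


class SelfPoolError(MatchError):
    """Queries and subjects share a pool; comparisons must be cross-pool."""


@dataclass
class Contig:
    """A pool-assembled sequence; the id encodes pool of origin + serial."""

    id: str
    pool: PoolId
    sequence: str
    coverage: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)


def solve_lambda(
    match_score: float, mismatch_score: float, base_freqs: Sequence[float]
) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s(i,j)) = 1 (bisection-free).

    For match/mismatch scoring the sum collapses to
    ``q·e^(λ·match) + (1−q)·e^(λ·mismatch)`` with ``q = Σ p_i²``.
    """
    p = np.asarray(base_freqs, dtype=float)
    if p.shape != (4,) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
        raise MatchError("base_freqs must be 4 probabilities summing to 1")
    q = float((p**2).sum())
    if match_score <= 0 or mismatch_score >= 0:
        raise MatchError("need positive match and negative mismatch scores")

    def f(lam: float) -> float:
        return q * math.exp(lam * match_score) + (1 - q) * math.exp(
            lam * mismatch_score
        ) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=8.9e-16))


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch scores plus the derived Karlin–Altschul parameters.

    λ is solved exactly from the scores and background base frequencies.
    K defaults to 0.621, the standard ungapped nucleotide value for +1/−2
    scoring; it enters the e-value only as a multiplicative constant.
    """

    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    K: float = 0.621
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lam: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.lam == 0.0:
            object.__setattr__(
                self,
                "lam",
                solve_lambda(self.match_score, self.mismatch_score, self.base_freqs),
            )
        if self.lam <= 0 or self.K <= 0:
            raise MatchError("lambda and K must be positive")


def evalue(S: float, m: int, n: int, params: ScoringParams) -> float:
    """Ungapped Karlin–Altschul expect value ``K·m·n·exp(−λS)``."""
    if params.lam <= 0:
        raise MatchError("lambda not solved")
    if m <= 0 or n <= 0:
        raise MatchError("sequence lengths must be positive")
    x = params.lam * S
    if x > 700:  # exp underflow; the true value is < 1e-290
        return 0.0
    return params.K * m * n * math.exp(-x)


@dataclass(frozen=True)
class MatchHit:
    """One retained alignment between a query and a subject contig.

    Coordinates are 1-based inclusive on the forward strands of both
    sequences; ``strand`` is '-' when the query matches the subject's
    reverse complement.  Identity counts matches over alignment columns.
    """

    query_id: str
    subject_id: str
    subject_dimension: str
    identity: float
    aln_len: int
    mismatches: int
    gaps: int
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    score: int
    evalue: float


class SeedIndex:
    """Sorted exact k-mer index over the forward strand of subject contigs."""

    def __init__(self, contigs: Sequence[Contig], k: int = 15):
        if k < 8:
            raise MatchError("k must be >= 8")
        contigs = sorted(contigs, key=lambda c: c.id)
        if not contigs:
            raise MatchError("cannot index an empty contig set")
        self.k = k
        self.contigs = list(contigs)
        self.pools = {c.pool for c in contigs}
        self.codes = [seqs.encode(c.sequence) for c in contigs]
        self.total_length = int(sum(len(c) for c in self.codes))

        kmer_parts, idx_parts, pos_parts = [], [], []
        for i, codes in enumerate(self.codes):
            km = seqs.kmer_codes(codes, k)
            valid = km >= 0
            kmer_parts.append(km[valid])
            pos = np.nonzero(valid)[0].astype(np.int32)
            pos_parts.append(pos)
            idx_parts.append(np.full(len(pos), i, dtype=np.int32))
        kmers = np.concatenate(kmer_parts) if kmer_parts else np.empty(0, np.int64)
        order = np.argsort(kmers, kind="stable")
        self.kmers = kmers[order]
        self.contig_idx = np.concatenate(idx_parts)[order]
        self.positions = np.concatenate(pos_parts)[order]

    @property
    def n_positions(self) -> int:
        return len(self.kmers)


def build_index(contigs: Iterable[Contig], k: int = 15) -> SeedIndex:
    return SeedIndex(list(contigs), k=k)


def _xdrop_extend(
    scores: np.ndarray, seed_idx: int, x_drop: float
) -> tuple[int, int, float]:
    """Two-way ungapped X-drop extension over per-column scores.

    Returns (start, end) column indices (inclusive) and the segment score.
    The seed column is always included; extension in each direction stops at
    the first point where the running score drops more than ``x_drop`` below
    its maximum, and ends at that maximum.
    """
    right = scores[seed_idx:]
    cs = np.cumsum(right)
    run_max = np.maximum.accumulate(cs)
    bad = np.nonzero(run_max - cs > x_drop)[0]
    stop = bad[0] if len(bad) else len(cs)
    r_end = int(np.argmax(cs[:stop])) if stop > 0 else 0
    r_score = float(cs[r_end]) if stop > 0 else float(scores[seed_idx])

    left = scores[:seed_idx][::-1]
    if len(left):
        cs_l = np.cumsum(left)
        run_max_l = np.maximum.accumulate(cs_l)
        bad_l = np.nonzero(run_max_l - cs_l > x_drop)[0]
        stop_l = bad_l[0] if len(bad_l) else len(cs_l)
        if stop_l > 0 and cs_l[:stop_l].max() > 0:
            l_ext = int(np.argmax(cs_l[:stop_l])) + 1
            l_score = float(cs_l[l_ext - 1])
        else:
            l_ext, l_score = 0, 0.0
    else:
        l_ext, l_score = 0, 0.0
    return seed_idx - l_ext, seed_idx + r_end, r_score + l_score


def find_hits(
    queries: Iterable[Contig],
    index: SeedIndex,
    min_identity: float = 95.0,
    max_evalue: float = 1e-6,
    min_aln_len: int = 100,
    x_drop: float = 20.0,
    params: ScoringParams | None = None,
) -> list[MatchHit]:
    """Seed-and-extend every query against the index; filter and dedupe hits.

    The index must be built over other pools only — a query whose pool is
    also indexed raises :class:`SelfPoolError`.
    """
    queries = sorted(queries, key=lambda c: c.id)
    if params is None:
        params = ScoringParams()
    shared = {q.pool for q in queries} & index.pools
    if shared:
        raise SelfPoolError(f"query pools present in index: {sorted(p.tag() for p in shared)}")

    k = index.k
    hits: list[MatchHit] = []
    for query in queries:
        fwd = seqs.encode(query.sequence)
        if len(fwd) < k:
            continue
        best: dict[int, tuple] = {}  # subject idx -> (score, tiebreak, hit fields)
        for strand, qcodes in (("+", fwd), ("-", seqs.revcomp_codes(fwd))):
            qk = seqs.kmer_codes(qcodes, k)
            valid = np.nonzero(qk >= 0)[0]
            if not len(valid):
                continue
            left = np.searchsorted(index.kmers, qk[valid], side="left")
            right = np.searchsorted(index.kmers, qk[valid], side="right")
            counts = right - left
            tot = int(counts.sum())
            if tot == 0:
                continue
            ends = np.cumsum(counts)
            starts = ends - counts
            flat = np.repeat(left, counts) + (np.arange(tot) - np.repeat(starts, counts))
            qpos = np.repeat(valid, counts)
            sidx = index.contig_idx[flat]
            spos = index.positions[flat]
            diag = spos.astype(np.int64) - qpos.astype(np.int64)

            key = sidx.astype(np.int64) * (1 << 34) + (diag + (1 << 32))
            order = np.lexsort((qpos, key))
            key, qpos_s, sidx_s, diag_s = key[order], qpos[order], sidx[order], diag[order]
            group_starts = np.nonzero(np.concatenate(([True], key[1:] != key[:-1])))[0]
            group_ends = np.concatenate((group_starts[1:], [len(key)]))

            for g0, g1 in zip(group_starts, group_ends):
                si = int(sidx_s[g0])
                d = int(diag_s[g0])
                scodes = index.codes[si]
                lo = max(0, -d)
                hi = min(len(qcodes), len(scodes) - d)
                if hi - lo < min_aln_len:
                    continue
                matches = qcodes[lo:hi] == scodes[lo + d : hi + d]
                colscores = np.where(
                    matches, float(params.match_score), float(params.mismatch_score)
                )
                covered_to = -1
                for qp in qpos_s[g0:g1]:
                    rel = int(qp) - lo
                    if rel <= covered_to:
                        continue
                    a, b, score = _xdrop_extend(colscores, rel, x_drop)
                    covered_to = b
                    length = b - a + 1
                    if length < min_aln_len:
                        continue
                    n_match = int(matches[a : b + 1].sum())
                    ident = 100.0 * n_match / length
                    if ident < min_identity:
                        continue
                    E = evalue(score, len(qcodes), index.total_length, params)
                    if E > max_evalue:
                        continue
                    qs, qe = lo + a, lo + b  # 0-based on the oriented query
                    if strand == "+":
                        q1, q2 = qs + 1, qe + 1
                    else:  # map back to forward-query coordinates
                        q1, q2 = len(qcodes) - qe, len(qcodes) - qs
                    fields = (
                        ident,
                        length,
                        length - n_match,
                        q1,
                        q2,
                        qs + d + 1,
                        qe + d + 1,
                        strand,
                        int(score),
                        E,
                    )
                    rank = (int(score), -ord(strand))  # '+' preferred on ties
                    prev = best.get(si)
                    if prev is None or rank > prev[0]:
                        best[si] = (rank, fields)
        for si in sorted(best, key=lambda i: index.contigs[i].id):
            rank, f = best[si]
            subject = index.contigs[si]
            hits.append(
                MatchHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    subject_dimension=subject.pool.dimension,
                    identity=f[0],
                    aln_len=f[1],
                    mismatches=f[2],
                    gaps=0,
                    qstart=f[3],
                    qend=f[4],
                    sstart=f[5],
                    send=f[6],
                    strand=f[7],
                    score=f[8],
                    evalue=f[9],
                )
            )
    return hits
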