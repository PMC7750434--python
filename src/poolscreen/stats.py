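"""Rank-based descriptive statistics for pooled-library sequencing runs.

Covers the analysis battery applied to the per-contig table (name, length,
coverage, pool dimension, deconvolution status, set): Spearman correlation
between length and coverage, Tukey 1.5×IQR outlier fences, Kruskal–Wallis
across groups with Dunn post-hoc pairwise tests, and the coverage-vs-length
saturation profile with a knee estimate.

Conventions (the underlying study reports none): quartiles by linear
interpolation between order statistics; Dunn multiplicity adjustment is
Benjamini–Hochberg by default with Holm available; p-values are reported
exactly (no "<2.2e-16" truncation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .deconvolve import CloneAssignment
from .match import Contig


class StatsError(ValueError):
    pass


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    df: int | None = None
    pairwise: pd.DataFrame | None = None


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho (Pearson on average ranks) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("rho undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def tukey_filter(
    x: Sequence[float], factor: float = 1.5
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Single-pass Tukey fences: remove points outside Q1/Q3 ± factor·IQR.

    Quartiles use linear interpolation.  Re-running on the kept points may
    remove more (idempotence is not a property of the method).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise StatsError("need n >= 4 for quartile fences")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - factor * iqr, q3 + factor * iqr
    outside = (x < lower) | (x > upper)
    return x[~outside], x[outside], (float(lower), float(upper))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis H with the chi-square p approximation."""
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in arrays):
        raise StatsError("every group needs >= 1 observation")
    total_n = sum(len(g) for g in arrays)
    if total_n < 5:
        raise StatsError("need >= 5 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # identical values: no evidence of difference
        return RankTestResult(statistic=0.0, pvalue=1.0, df=len(groups) - 1)
    H, p = sps.kruskal(*arrays)
    return RankTestResult(statistic=float(H), pvalue=float(p), df=len(groups) - 1)


def dunn(
    groups: Sequence[Sequence[float]], adjust: str = "bh"
) -> RankTestResult:
    """Dunn's post-hoc pairwise z tests on pooled ranks, with tie correction.

    ``adjust`` is "bh" (Benjamini–Hochberg, default) or "holm".  The result's
    ``pairwise`` frame has one row per group pair with z, raw and adjusted p.
    """
    if adjust not in ("bh", "holm"):
        raise StatsError(f"unknown adjustment {adjust!r}")
    kw = kruskal_wallis(groups)  # validates the inputs
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for g in arrays:
        mean_ranks.append(ranks[offset : offset + len(g)].mean())
        sizes.append(len(g))
        offset += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_i": i, "group_j": j, "z": z, "pvalue": p})
    frame = pd.DataFrame(rows)
    method = "fdr_bh" if adjust == "bh" else "holm"
    frame["p_adjusted"] = multipletests(frame["pvalue"], method=method)[1]
    return RankTestResult(
        statistic=kw.statistic, pvalue=kw.pvalue, df=kw.df, pairwise=frame
    )


def contig_stats_table(
    contigs: Iterable[Contig],
    assignments: Iterable[CloneAssignment] | None = None,
) -> pd.DataFrame:
    """Assemble the per-contig analysis table.

    Columns: contig_id, length, coverage, dimension, set_index, status
    (empty for non-plate contigs or when assignments are not supplied).
    """
    status = {}
    if assignments is not None:
        status = {a.contig_id: a.status for a in assignments}
    rows = [
        {
            "contig_id": c.id,
            "length": c.length,
            "coverage": c.coverage,
            "dimension": c.pool.dimension,
            "set_index": c.pool.set_index,
            "status": status.get(c.id, ""),
        }
        for c in contigs
    ]
    return pd.DataFrame(
        rows,
        columns=["contig_id", "length", "coverage", "dimension", "set_index", "status"],
    )


@dataclass
class CoverageProfile:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    medians: np.ndarray
    counts: np.ndarray
    knee: float  # coverage at the knee bin center
    flag: str = ""  # "", "no-plateau", or "degenerate"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "median_length": self.medians,
                "n": self.counts,
            }
        )


def coverage_length_profile(
    stats: pd.DataFrame,
    bin_width: float = 5.0,
    epsilon: float = 0.05,
) -> CoverageProfile:
    """Per-coverage-bin median contig length and a knee (plateau) estimate.

    The plateau level is estimated as the median of the bin medians in the
    top quarter of the coverage range; the knee is the center of the first
    bin whose median reaches within ``epsilon`` (fractionally) of that
    level.  A profile still climbing in its final bins is flagged
    "no-plateau" with the knee at the last bin.  Descriptive output only;
    single-bin profiles are returned flagged rather than rejected.
    """
    if stats.empty:
        raise StatsError("empty stats table")
    cov = stats["coverage"].to_numpy(dtype=float)
    length = stats["length"].to_numpy(dtype=float)
    edges = np.arange(0.0, cov.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(cov, edges) - 1, 0, len(edges) - 2)
    centers, medians, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        medians.append(float(np.median(length[mask])))
        counts.append(int(mask.sum()))
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    counts = np.asarray(counts)
    if len(centers) == 1:
        return CoverageProfile(edges, centers, medians, counts, float(centers[0]), "degenerate")
    n_tail = max(2, len(medians) // 4)
    plateau = float(np.median(medians[-n_tail:]))
    level = (1.0 - epsilon) * plateau
    still_climbing = medians[-1] - medians[-2] >= epsilon * plateau
    if still_climbing:
        return CoverageProfile(
            edges, centers, medians, counts, float(centers[-1]), "no-plateau"
        )
    knee_idx = int(np.argmax(medians >= level))  # first crossing
    return CoverageProfile(edges, centers, medians, counts, float(centers[knee_idx]), "")
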