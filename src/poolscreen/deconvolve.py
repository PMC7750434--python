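"""Contig-to-clone deconvolution from cross-dimension pool hits.

A plate-pool contig is classified by where its significant similarity hits
fall: *complete* (hits in both a row pool and a column pool), *partial*
(hits in only one other dimension) or *singleton* (no hits).  For complete
contigs, every (row pool, column pool) pair present in the hits is combined
with the contig's own plate pool and resolved to a candidate well through
the pooling design; candidates are ranked by the summed best hit score per
dimension.  Only contigs with exactly one candidate well (``unique``) feed
per-clone records.

Deduplication collapses annotation instances of the same BGC class within
one well to a single record — "correcting" the count of contigs that belong
to the same clone — while annotations on contigs without a unique well
assignment remain counted individually.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import (
    COLUMN,
    PLATE,
    ROW,
    CrossSetError,
    NoSuchWellError,
    PoolAssignment,
    PoolId,
    WellAddress,
    coordinates_from_pools,
)
from .match import Contig, MatchHit
from .mining import ClusterAnnotation

COMPLETE = "complete"
PARTIAL = "partial"
SINGLETON = "singleton"
STATUSES = (COMPLETE, PARTIAL, SINGLETON)


class DeconvolutionError(ValueError):
    pass


@dataclass
class CloneAssignment:
    """Deconvolution outcome for one plate-pool contig."""

    contig_id: str
    status: str
    candidates: list[tuple[WellAddress, float]] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)  # inconsistent pool pairs
    #: top pool dominates its dimension (see assign_coordinates)
    dominant: bool = False

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def resolved(self) -> bool:
        """True when the top candidate is unambiguous.

        Either a single candidate, or per-dimension dominance: the
        best-scoring row pool and column pool each outscore every competitor
        in their dimension by the dominance ratio.  Multi-candidate contigs
        arise when short conserved elements (e.g. shared domain sequences)
        also match pools of unrelated clones; those spurious hits score far
        below the clone's own full-length overlaps.
        """
        return self.unique or self.dominant

    @property
    def top_well(self) -> WellAddress | None:
        return self.candidates[0][0] if self.candidates else None


@dataclass
class CloneRecord:
    """Deduplicated per-well record: member contigs and their BGC classes."""

    well: WellAddress
    contig_ids: list[str]
    class_counts: Counter  # raw annotation instances per class
    set_index: int
    strategy: str

    @property
    def classes(self) -> set[str]:
        return set(self.class_counts)


def _hits_by_dimension(hits: Iterable[MatchHit]) -> dict[str, list[MatchHit]]:
    grouped: dict[str, list[MatchHit]] = {}
    for h in hits:
        grouped.setdefault(h.subject_dimension, []).append(h)
    return grouped


def classify_contig(contig: Contig, hits: Sequence[MatchHit]) -> str:
    """Classify a plate-pool contig from its (pre-filtered) cross-pool hits."""
    if contig.pool.dimension != PLATE:
        raise DeconvolutionError(f"{contig.id} is not a plate-pool contig")
    for h in hits:
        subject_set = PoolId.from_tag(h.subject_id.split("|")[0]).set_index
        if subject_set != contig.pool.set_index:
            raise CrossSetError(
                f"hit {h.query_id}->{h.subject_id} crosses sets"
            )
    dims = {h.subject_dimension for h in hits} & {ROW, COLUMN}
    if len(dims) == 2:
        return COMPLETE
    if len(dims) == 1:
        return PARTIAL
    return SINGLETON


def assign_coordinates(
    contig: Contig,
    hits: Sequence[MatchHit],
    assignment: PoolAssignment,
    policy: str = "rank-all",
    dominance_ratio: float = 1.5,
) -> CloneAssignment:
    """Form ranked candidate wells for a contig from its row/column hits.

    For every (row pool, column pool) pair observed in the hits, the well at
    the intersection with the contig's own plate pool is a candidate; its
    combined score is the sum of the best hit score in each dimension.  Pool
    pairs with an empty intersection are flagged, not fatal.  The only
    implemented policy is "rank-all": report all candidates ordered by
    combined score (ties: canonical well id).

    The assignment is additionally marked ``dominant`` when the best row
    pool and the best column pool each outscore every competing pool of
    their dimension by ``dominance_ratio`` and their intersection is the
    top-ranked candidate.
    """
    if policy != "rank-all":
        raise DeconvolutionError(f"unknown conflict policy {policy!r}")
    status = classify_contig(contig, hits)
    out = CloneAssignment(contig_id=contig.id, status=status)
    if status != COMPLETE:
        return out
    best_by_pool: dict[str, dict[PoolId, float]] = {ROW: {}, COLUMN: {}}
    for h in hits:
        if h.subject_dimension not in (ROW, COLUMN):
            continue
        pool = PoolId.from_tag(h.subject_id.split("|")[0])
        d = best_by_pool[h.subject_dimension]
        d[pool] = max(d.get(pool, float("-inf")), float(h.score))
    candidates: dict[WellAddress, float] = {}
    for row_pool, rscore in best_by_pool[ROW].items():
        for col_pool, cscore in best_by_pool[COLUMN].items():
            try:
                well = coordinates_from_pools(
                    contig.pool, row_pool, col_pool, assignment
                )
            except NoSuchWellError:
                out.flagged.append(f"{row_pool.label}x{col_pool.label}")
                continue
            score = rscore + cscore
            if score > candidates.get(well, float("-inf")):
                candidates[well] = score
    out.candidates = sorted(
        candidates.items(), key=lambda wc: (-wc[1], wc[0].canonical())
    )
    if out.candidates:
        dominant_pools = []
        for dim in (ROW, COLUMN):
            ranked = sorted(best_by_pool[dim].items(), key=lambda ps: -ps[1])
            if len(ranked) == 1 or ranked[0][1] > dominance_ratio * ranked[1][1]:
                dominant_pools.append(ranked[0][0])
        if len(dominant_pools) == 2:
            try:
                top = coordinates_from_pools(
                    contig.pool, dominant_pools[0], dominant_pools[1], assignment
                )
                out.dominant = top == out.top_well
            except NoSuchWellError:
                out.dominant = False
    return out


@dataclass
class DeconvolutionResult:
    assignments: list[CloneAssignment]
    tally: dict[str, int]
    clone_coverage: float  # fraction of wells with >= 1 unique complete contig
    resolved_coverage: float  # same, counting dominant-top assignments too
    contig_rate: float  # fraction of plate contigs completely deconvoluted
    n_wells: int

    def assignments_by_contig(self) -> dict[str, CloneAssignment]:
        return {a.contig_id: a for a in self.assignments}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            rows.append(
                {
                    "contig_id": a.contig_id,
                    "status": a.status,
                    "unique": a.unique,
                    "resolved": a.resolved,
                    "top_well": a.top_well.canonical() if a.top_well else "",
                    "n_candidates": len(a.candidates),
                    "candidates": ";".join(
                        f"{w.canonical()}:{s:g}" for w, s in a.candidates
                    ),
                    "flagged": ";".join(a.flagged),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "contig_id",
                "status",
                "unique",
                "resolved",
                "top_well",
                "n_candidates",
                "candidates",
                "flagged",
            ],
        )


def deconvolute_library(
    plate_contigs: Iterable[Contig],
    hits: Iterable[MatchHit],
    assignment: PoolAssignment,
) -> DeconvolutionResult:
    """Deconvolute all plate-pool contigs of one set.

    Returns per-contig assignments, the status tally (which partitions the
    plate contigs), and the two summary rates: the fraction of plate contigs
    completely deconvoluted, and the per-clone coverage (fraction of wells
    recovered by at least one uniquely assigned complete contig).
    """
    by_query: dict[str, list[MatchHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    assignments = []
    tally = {s: 0 for s in STATUSES}
    wells_unique: set[WellAddress] = set()
    wells_resolved: set[WellAddress] = set()
    n = 0
    for contig in sorted(plate_contigs, key=lambda c: c.id):
        n += 1
        a = assign_coordinates(contig, by_query.get(contig.id, []), assignment)
        tally[a.status] += 1
        if a.status == COMPLETE:
            if a.unique:
                wells_unique.add(a.top_well)
            if a.resolved:
                wells_resolved.add(a.top_well)
        assignments.append(a)
    n_wells = len(assignment.inverse)
    return DeconvolutionResult(
        assignments=assignments,
        tally=tally,
        clone_coverage=len(wells_unique) / n_wells if n_wells else 0.0,
        resolved_coverage=len(wells_resolved) / n_wells if n_wells else 0.0,
        contig_rate=tally[COMPLETE] / n if n else 0.0,
        n_wells=n_wells,
    )


def deduplicate_by_clone(
    assignments: Iterable[CloneAssignment],
    annotations: Iterable[ClusterAnnotation],
    assignment: PoolAssignment | None = None,
) -> tuple[list[CloneRecord], pd.DataFrame]:
    """Collapse per-contig BGC annotations into per-clone records.

    Within a well, annotation instances of the same class collapse to one
    deduplicated entry.  A contig contributes to a well when its assignment
    is complete and resolved (single candidate, or a dominant top
    candidate); annotations on unresolved contigs remain counted
    individually (they cannot be corrected).  Returns the per-well records
    plus a per-class table with columns ``class_label``, ``ngs_count``
    (raw), ``dedup_count`` and ``assigned_count`` (deduplicated entries
    that carry a well coordinate).
    """
    amap = {a.contig_id: a for a in assignments}
    by_well: dict[WellAddress, dict] = {}
    raw = Counter()
    unassigned = Counter()
    for ann in annotations:
        a = amap.get(ann.contig_id)
        if a is None:
            warnings.warn(f"annotation references unknown contig {ann.contig_id}; skipped")
            continue
        raw[ann.class_label] += 1
        if a.status == COMPLETE and a.resolved:
            rec = by_well.setdefault(
                a.top_well, {"contigs": set(), "classes": Counter()}
            )
            rec["contigs"].add(ann.contig_id)
            rec["classes"][ann.class_label] += 1
        else:
            unassigned[ann.class_label] += 1

    set_index = assignment.set_index if assignment else -1
    strategy = assignment.strategy if assignment else ""
    records = [
        CloneRecord(
            well=w,
            contig_ids=sorted(d["contigs"]),
            class_counts=d["classes"],
            set_index=set_index,
            strategy=strategy,
        )
        for w, d in sorted(by_well.items())
    ]
    dedup_assigned = Counter()
    for rec in records:
        for cls in rec.classes:
            dedup_assigned[cls] += 1
    rows = []
    for cls in sorted(set(raw) | set(unassigned) | set(dedup_assigned)):
        rows.append(
            {
                "class_label": cls,
                "ngs_count": raw[cls],
                "dedup_count": dedup_assigned[cls] + unassigned[cls],
                "assigned_count": dedup_assigned[cls],
            }
        )
    table = pd.DataFrame(
        rows, columns=["class_label", "ngs_count", "dedup_count", "assigned_count"]
    )
    return records, table
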