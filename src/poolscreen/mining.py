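"""BGC mining rules: module parsing, viability, divergence, and summaries.

Polyketide synthases (PKS) and non-ribosomal peptide synthetases (NRPS) are
modular mega-enzymes.  A minimal PKS module carries a ketosynthase (KS), an
acyltransferase (AT) and an acyl carrier protein (ACP); a minimal NRPS module
carries a condensation (C), an adenylation (A) and a peptidyl-carrier protein
(PCP) domain.  Tailoring domains (KR, DH, ER, MT, TE, E) decorate modules but
never decide completeness.  A cluster is deemed *viable* when it contains at
least three complete adjacent modules.

This module also hosts the annotation-side filtering rules of the screening
pipeline: the >1 kb contig mining pre-filter, the 16S rRNA hit filters, the
per-class summary table with raw vs per-clone-deduplicated counts, and the
divergence metric (100 − % identity to the best database match).

``detect_toy_cassettes`` is a motif-scan detector for the synthetic library
only: planted cassettes encode each domain as a fixed marker subsequence, so
domain architecture can be recovered without gene prediction or an external
annotator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

#: Controlled vocabulary of domain tokens.
DOMAIN_TOKENS = ("KS", "AT", "ACP", "KR", "DH", "ER", "MT", "TE", "C", "A", "PCP", "E")

PKS_CORE = frozenset({"KS", "AT", "ACP"})
NRPS_CORE = frozenset({"C", "A", "PCP"})
PKS_TOKENS = frozenset({"KS", "AT", "ACP"})
NRPS_TOKENS = frozenset({"C", "A", "PCP"})
TAILORING_TOKENS = frozenset({"KR", "DH", "ER", "MT", "TE", "E"})
#: Carrier domains terminate a module.
CARRIER_TOKENS = frozenset({"ACP", "PCP"})

CLASS_PKS = "Type I PKS"
CLASS_NRPS = "NRPS"
CLASS_HYBRID = "Type I PKS-NRPS"

#: Class vocabulary, in report row order.
CLASS_VOCABULARY = (
    "Type I PKS",
    "Type I PKS-NRPS",
    "Type II PKS",
    "Type III PKS",
    "Transatpks",
    "Other KS",
    "NRPS",
    "Other",
    "Terpene",
    "Bacteriocin",
    "Aryl polyene",
    "Lassopeptide",
    "Lantipeptide",
    "Hserlactone",
    "Resorcinol",
    "Phosphonate",
    "Indole",
    "Ladderane",
    "Acyl Amino acids",
    "Butyrolactone",
    "Microviridin",
    "Siderophore",
    "Cyanobactin",
    "Thiopeptide",
    "Linaridin",
    "Phenazine",
    "Ectoine",
    "Hybrid Pathways",
)


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class Module:
    """One PKS or NRPS module: ordered domain tokens plus a completeness flag."""

    chemistry: str | None  # "PKS", "NRPS", or None when undecidable
    domains: tuple[str, ...]
    complete: bool


@dataclass(frozen=True)
class ClusterAnnotation:
    """A BGC interval on a contig with per-ORF ordered domain tokens.

    Interval coordinates are 1-based inclusive on the forward contig strand.
    """

    contig_id: str
    start: int
    end: int
    class_label: str
    orfs: tuple[tuple[str, ...], ...] = ()
    strand: str = "+"

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(t for orf in self.orfs for t in orf)


@dataclass(frozen=True)
class SixteenSHit:
    """A 16S rRNA database hit subject to the ribotype filtering rules."""

    query_id: str
    evalue: float
    initial_aln_len: int
    total_len: int
    identity: float
    phylum: str


def filter_min_length(contigs: Iterable, threshold: int = 1000) -> list:
    """Keep contigs strictly longer than ``threshold`` bp (mining pre-filter)."""
    if threshold < 0:
        raise MiningError("threshold must be >= 0")
    out = []
    for c in contigs:
        length = getattr(c, "length", None)
        if length is None:
            length = len(c.sequence if hasattr(c, "sequence") else c)
        if length > threshold:
            out.append(c)
    return out


def _module_chemistry(domains: Sequence[str]) -> str | None:
    toks = set(domains)
    if "ACP" in toks:
        return "PKS"
    if "PCP" in toks:
        return "NRPS"
    # trailing module without a carrier: decide from remaining core tokens
    if toks & {"KS", "AT"}:
        return "PKS"
    if toks & {"C", "A"}:
        return "NRPS"
    return None


def parse_modules(domains: Sequence[str]) -> list[Module]:
    """Segment an ordered domain-token list into modules.

    A module ends at each carrier domain (ACP or PCP); tokens after the last
    carrier form a final incomplete module.  Completeness requires the full
    core set for the module's chemistry (PKS: KS+AT+ACP; NRPS: C+A+PCP);
    tailoring domains never affect it.
    """
    for t in domains:
        if t not in DOMAIN_TOKENS:
            raise MiningError(f"unknown domain token {t!r}")
    modules: list[Module] = []
    current: list[str] = []
    for tok in domains:
        current.append(tok)
        if tok in CARRIER_TOKENS:
            modules.append(_finish_module(current))
            current = []
    if current:
        modules.append(_finish_module(current))
    return modules


def _finish_module(tokens: list[str]) -> Module:
    chem = _module_chemistry(tokens)
    toks = set(tokens)
    if chem == "PKS":
        complete = PKS_CORE <= toks
    elif chem == "NRPS":
        complete = NRPS_CORE <= toks
    else:
        complete = False
    return Module(chemistry=chem, domains=tuple(tokens), complete=complete)


def viability(modules: Sequence[Module]) -> bool:
    """True iff the cluster has a run of >= 3 consecutive complete modules."""
    run = 0
    for m in modules:
        run = run + 1 if m.complete else 0
        if run >= 3:
            return True
    return False


def classify_chemistry(modules: Sequence[Module]) -> str:
    """Assign the cluster class from the chemistry mix of its modules."""
    chems = {m.chemistry for m in modules if m.chemistry}
    if chems == {"PKS"}:
        return CLASS_PKS
    if chems == {"NRPS"}:
        return CLASS_NRPS
    if chems == {"PKS", "NRPS"}:
        return CLASS_HYBRID
    return "Other"


def divergence(identity: float) -> float:
    """Domain divergence: the complement of % identity (60% identity -> 40%)."""
    if not 0.0 <= identity <= 100.0:
        raise MiningError(f"identity {identity} outside [0, 100]")
    return 100.0 - identity


def clone_domain_summary(
    identities: Sequence[float], branch_lengths: Sequence[float]
) -> tuple[float, float, int]:
    """Per-clone means over its KS/A domains.

    Returns (mean domain divergence, mean branch length, number of domains).
    """
    if len(identities) == 0 or len(branch_lengths) == 0:
        raise MiningError("empty domain list has no summary")
    if len(identities) != len(branch_lengths):
        raise MiningError("one identity and one branch length per domain required")
    n = len(identities)
    mean_div = sum(divergence(x) for x in identities) / n
    mean_branch = sum(branch_lengths) / n
    return mean_div, mean_branch, n


def filter_16s_hits(
    hits: Iterable[SixteenSHit],
    max_e: float = 1e-5,
    min_init_aln: int = 45,
    min_len: int = 300,
    phylum_identity: float = 75.0,
    length_attr: str = "total_len",
) -> list[SixteenSHit]:
    """Apply the 16S ribotype hit filters.

    Keep a hit iff its e-value is strictly below ``max_e``, its initial
    alignment is at least ``min_init_aln`` bp and its length is at least
    ``min_len`` bp.  The phylum label survives only at >= ``phylum_identity``
    % identity; below that the hit is kept but relabelled "unclassified".
    ``length_attr`` selects which length the 300-bp rule reads
    ("total_len", the default interpretation, or "initial_aln_len").
    """
    kept = []
    for h in hits:
        if not (h.evalue < max_e and h.initial_aln_len >= min_init_aln):
            continue
        if getattr(h, length_attr) < min_len:
            continue
        if h.identity < phylum_identity:
            h = replace(h, phylum="unclassified")
        kept.append(h)
    return kept


def hit_rate(count: int, library_size: int, decimals: int = 1) -> float:
    """Screening hit rate as a percentage of the library, rounded."""
    if library_size <= 0:
        raise MiningError("library_size must be positive")
    return round(100.0 * count / library_size, decimals)


def summary_table(
    class_stats: pd.DataFrame,
    class_vocabulary: Sequence[str] = CLASS_VOCABULARY,
) -> pd.DataFrame:
    """Assemble the per-class screening summary with a totals row.

    ``class_stats`` must have columns ``class_label``, ``ngs_count`` (raw
    annotation instances), ``dedup_count`` (after per-clone deduplication)
    and ``assigned_count`` (deduplicated entries with a well coordinate).
    Unknown class labels are folded into "Other" with a warning.  The
    "Deconvoluted (%)" column is 100·assigned/deduplicated per class; the
    Total row reports the deduplicated-weighted percentage (the raw-weighted
    alternative is stored in ``df.attrs['pct_deconvoluted_raw_weighted']``).
    """
    stats = class_stats.copy()
    known = set(class_vocabulary)
    unknown = sorted(set(stats["class_label"]) - known)
    if unknown:
        warnings.warn(f"unknown BGC classes folded into 'Other': {unknown}")
        stats.loc[stats["class_label"].isin(unknown), "class_label"] = "Other"
    agg = (
        stats.groupby("class_label")[["ngs_count", "dedup_count", "assigned_count"]]
        .sum()
        .reindex([c for c in class_vocabulary], fill_value=0)
    )
    agg = agg[agg[["ngs_count", "dedup_count", "assigned_count"]].sum(axis=1) > 0]
    pct = 100.0 * agg["assigned_count"] / agg["dedup_count"].replace(0, pd.NA)
    table = agg.reset_index()
    table["pct_deconvoluted"] = pct.round(1).to_numpy()
    totals = {
        "class_label": "Total",
        "ngs_count": int(agg["ngs_count"].sum()),
        "dedup_count": int(agg["dedup_count"].sum()),
        "assigned_count": int(agg["assigned_count"].sum()),
        "pct_deconvoluted": (
            round(100.0 * agg["assigned_count"].sum() / agg["dedup_count"].sum(), 1)
            if agg["dedup_count"].sum()
            else float("nan")
        ),
    }
    table = pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
    raw_total = agg["ngs_count"].sum()
    table.attrs["pct_deconvoluted_raw_weighted"] = (
        round(100.0 * agg["assigned_count"].sum() / raw_total, 1) if raw_total else None
    )
    return table


def detect_toy_cassettes(
    contigs: Iterable,
    markers: dict[str, str] | None = None,
    max_gap: int = 600,
) -> list[ClusterAnnotation]:
    """Recover planted cassette architecture from synthetic contigs.

    Scans both strands for the fixed per-domain marker subsequences used by
    the synthetic library, groups marker occurrences separated by at most
    ``max_gap`` bp into one annotation, and reads tokens in cassette-plan
    order (reverse scan order on the minus strand).  This stands in for a
    gene-level annotator on simulated data only; markers are matched exactly,
    so substitution noise inside a marker hides that single domain.
    """
    from .simulate import marker_vocabulary, revcomp

    if markers is None:
        markers = marker_vocabulary()
    annotations: list[ClusterAnnotation] = []
    rc_markers = {tok: revcomp(seq) for tok, seq in markers.items()}
    for contig in contigs:
        seq = contig.sequence if hasattr(contig, "sequence") else contig[1]
        cid = contig.id if hasattr(contig, "id") else contig[0]
        for strand, vocab in (("+", markers), ("-", rc_markers)):
            occurrences: list[tuple[int, int, str]] = []  # (start0, end0, token)
            for tok, m in vocab.items():
                start = seq.find(m)
                while start != -1:
                    occurrences.append((start, start + len(m), tok))
                    start = seq.find(m, start + 1)
            if not occurrences:
                continue
            occurrences.sort()
            runs: list[list[tuple[int, int, str]]] = [[occurrences[0]]]
            for occ in occurrences[1:]:
                if occ[0] - runs[-1][-1][1] <= max_gap:
                    runs[-1].append(occ)
                else:
                    runs.append([occ])
            for run in runs:
                tokens = tuple(t for _, _, t in run)
                if strand == "-":
                    tokens = tokens[::-1]
                modules = parse_modules(tokens)
                annotations.append(
                    ClusterAnnotation(
                        contig_id=cid,
                        start=run[0][0] + 1,
                        end=run[-1][1],
                        class_label=classify_chemistry(modules),
                        orfs=(tokens,),
                        strand=strand,
                    )
                )
    annotations.sort(key=lambda a: (a.contig_id, a.start, a.strand))
    return annotations
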