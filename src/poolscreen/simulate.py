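"""Synthetic pooled-library generator with full ground truth.

Emulates the post-assembly state of a 3D-pooled clone library experiment:

1. :func:`simulate_clones` draws one random insert per well (log-normal
   length law truncated at configured bounds) and plants BGC-like cassettes
   in a configurable fraction of clones.  Each cassette encodes its ordered
   domain plan as fixed 120-bp marker subsequences separated by random
   linkers, so a motif scan (``mining.detect_toy_cassettes``) can recover
   the module architecture without gene prediction.
2. :func:`simulate_pool_contigs` pools the clones per a
   :class:`~poolscreen.design.PoolAssignment` and fragments each insert
   independently per pool (Poisson breakpoints whose expected fragment
   length saturates with coverage), applies i.i.d. substitution noise, drops
   short fragments, and optionally injects host/vector contaminant contigs.
   Assembly is not simulated mechanistically; fragmentation emulates its
   outcome.
3. :func:`simulate_reads` (optional stage) emits paired reads so the read-QC
   path can run end to end.

Everything is deterministic under the caller's seed, and every emitted
non-contaminant contig carries a ground-truth source record.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import seqs
from .design import LibraryLayout, PoolAssignment, PoolId, WellAddress
from .match import Contig
from .mining import CLASS_HYBRID, CLASS_NRPS, CLASS_PKS, DOMAIN_TOKENS

revcomp = seqs.revcomp

_MARKER_SEED = 0x5EED0B  # fixed: the marker vocabulary is part of the format


class SimulationError(ValueError):
    pass


@functools.lru_cache(maxsize=8)
def marker_vocabulary(marker_len: int = 120) -> dict[str, str]:
    """Fixed marker subsequence per domain token.

    Generated once from an internal constant seed so that simulator and
    detector agree across processes; pairwise distinct (including against
    reverse complements) by construction check.
    """
    rng = np.random.default_rng(_MARKER_SEED)
    vocab = {tok: seqs.random_seq(rng, marker_len) for tok in DOMAIN_TOKENS}
    all_seqs = list(vocab.values()) + [seqs.revcomp(s) for s in vocab.values()]
    if len(set(all_seqs)) != 2 * len(vocab):
        raise SimulationError("marker collision; increase marker_len")
    return vocab


@dataclass(frozen=True)
class CassetteSpec:
    """Plan for a planted BGC-like cassette."""

    chemistry: str  # "PKS" | "NRPS" | "hybrid"
    module_plan: tuple[tuple[str, ...], ...]
    class_label: str
    marker_len: int = 120
    linker_len: int = 40

    def tokens(self) -> tuple[str, ...]:
        return tuple(t for mod in self.module_plan for t in mod)

    def encoded_length(self) -> int:
        return len(self.tokens()) * (self.marker_len + self.linker_len)


def default_cassette_specs() -> tuple[CassetteSpec, ...]:
    """One PKS, one NRPS and one hybrid plan with complete modules."""
    pks = CassetteSpec(
        chemistry="PKS",
        module_plan=(("KS", "AT", "KR", "ACP"),) * 4,
        class_label=CLASS_PKS,
    )
    nrps = CassetteSpec(
        chemistry="NRPS",
        module_plan=(("C", "A", "PCP"),) * 4,
        class_label=CLASS_NRPS,
    )
    hybrid = CassetteSpec(
        chemistry="hybrid",
        module_plan=(("KS", "AT", "ACP"),) * 2 + (("C", "A", "PCP"),) * 2,
        class_label=CLASS_HYBRID,
    )
    return (pks, nrps, hybrid)


@dataclass(frozen=True)
class CassettePlacement:
    spec: CassetteSpec
    start: int  # 1-based inclusive on the insert
    end: int
    strand: str


@dataclass
class CloneInsert:
    well: WellAddress
    sequence: str
    cassettes: list[CassettePlacement] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GroundTruth:
    """Simulator-emitted truth: clone, cassette and contig source tables."""

    clones: list[dict] = field(default_factory=list)
    cassettes: list[dict] = field(default_factory=list)
    contigs: list[dict] = field(default_factory=list)

    def clone_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.clones)

    def cassette_table(self) -> pd.DataFrame:
        cols = ["well", "class_label", "chemistry", "start", "end", "strand"]
        return pd.DataFrame(self.cassettes, columns=cols)

    def contig_table(self) -> pd.DataFrame:
        cols = ["contig_id", "pool", "well", "start", "end", "is_contaminant"]
        return pd.DataFrame(self.contigs, columns=cols)

    def well_of_contig(self) -> dict[str, str]:
        return {
            r["contig_id"]: r["well"] for r in self.contigs if not r["is_contaminant"]
        }

    def cassette_wells(self) -> set[str]:
        return {r["well"] for r in self.cassettes}


@dataclass(frozen=True)
class FragmentationConfig:
    """Coverage-dependent fragmentation of pooled inserts into contigs.

    Expected fragment length rises linearly with coverage and plateaus at
    ``c_star`` (the empirical "no further gain beyond ~55X" behaviour):
    ``E(cov) = base_len + (plateau_len - base_len) * min(cov, c_star)/c_star``.
    ``plateau_len = inf`` disables breakage entirely.  Each clone's depth in
    each pool is drawn around ``coverage_per_pool`` (Gamma with shape
    ``coverage_shape``; ``inf`` for uniform depth) and drives both the
    fragmentation of that clone and the coverage metadata on its contigs,
    so contig length and coverage co-vary the way pooled assemblies do.
    Substitutions are i.i.d. per base at rate ``substitution_rate``;
    fragments shorter than ``min_fragment_len`` are dropped;
    ``contaminant_fraction`` adds that proportion of host/vector contigs
    per pool.
    """

    coverage_per_pool: float = 60.0
    coverage_shape: float = 6.0
    c_star: float = 55.0
    plateau_len: float = 8000.0
    base_len: float = 300.0
    substitution_rate: float = 0.0
    min_fragment_len: int = 300
    contaminant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate < 0.25:
            raise SimulationError("substitution_rate must be in [0, 0.25)")
        if self.min_fragment_len < 1:
            raise SimulationError("min_fragment_len must be >= 1")
        if self.c_star <= 0:
            raise SimulationError("c_star must be > 0")

    def expected_fragment_length(self, coverage: float) -> float:
        if math.isinf(self.plateau_len):
            return math.inf
        frac = min(coverage, self.c_star) / self.c_star
        return self.base_len + (self.plateau_len - self.base_len) * frac


def simulate_clones(
    layout: LibraryLayout,
    mean_length: float = 6000.0,
    dispersion: float = 0.35,
    cassette_rate: float = 0.1,
    seed: int = 17,
    specs: tuple[CassetteSpec, ...] | None = None,
    min_length: int | None = None,
    max_length: int | None = None,
) -> tuple[dict[WellAddress, CloneInsert], GroundTruth]:
    """Draw one insert per well of the layout; plant cassettes at ``cassette_rate``.

    Lengths follow a log-normal with the given arithmetic mean and log-scale
    dispersion, truncated to [min_length, max_length] (defaults: mean/3 and
    3x mean).  Cassettes overwrite a uniformly placed window of the insert
    (random strand) so insert length is preserved; inserts shorter than the
    encoded cassette are skipped for placement.
    """
    if mean_length < 1000:
        raise SimulationError("mean_length must be >= 1 kb")
    if dispersion <= 0:
        raise SimulationError("dispersion must be > 0")
    if not 0.0 <= cassette_rate <= 1.0:
        raise SimulationError("cassette_rate must be in [0, 1]")
    if specs is None:
        specs = default_cassette_specs()
    lo = int(min_length if min_length is not None else mean_length / 3)
    hi = int(max_length if max_length is not None else mean_length * 3)
    if not 1 <= lo <= hi:
        raise SimulationError("degenerate length bounds")

    rng = np.random.default_rng(seed)
    mu = math.log(mean_length) - dispersion**2 / 2.0
    vocab = {}
    for spec in specs:
        vocab.update(marker_vocabulary(spec.marker_len))

    clones: dict[WellAddress, CloneInsert] = {}
    truth = GroundTruth()
    for i, well in enumerate(layout.wells()):
        length = int(np.clip(rng.lognormal(mu, dispersion), lo, hi))
        codes = seqs.random_codes(rng, length)
        placements: list[CassettePlacement] = []
        if cassette_rate > 0 and rng.random() < cassette_rate:
            spec = specs[rng.integers(0, len(specs))]
            cassette = _build_cassette(spec, vocab, rng)
            if len(cassette) <= length:
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    cassette = seqs.revcomp_codes(cassette)
                offset = int(rng.integers(0, length - len(cassette) + 1))
                codes[offset : offset + len(cassette)] = cassette
                placements.append(
                    CassettePlacement(
                        spec=spec,
                        start=offset + 1,
                        end=offset + len(cassette),
                        strand=strand,
                    )
                )
        clone = CloneInsert(well=well, sequence=seqs.decode(codes), cassettes=placements)
        clones[well] = clone
        truth.clones.append(
            {"well": well.canonical(), "length": clone.length, "n_cassettes": len(placements)}
        )
        for p in placements:
            truth.cassettes.append(
                {
                    "well": well.canonical(),
                    "class_label": p.spec.class_label,
                    "chemistry": p.spec.chemistry,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                }
            )
    return clones, truth


def _build_cassette(
    spec: CassetteSpec, vocab: Mapping[str, str], rng: np.random.Generator
) -> np.ndarray:
    parts = []
    for tok in spec.tokens():
        parts.append(seqs.encode(vocab[tok]))
        parts.append(seqs.random_codes(rng, spec.linker_len))
    return np.concatenate(parts[:-1])  # no trailing linker


def simulate_pool_contigs(
    clones: Mapping[WellAddress, CloneInsert],
    assignment: PoolAssignment,
    frag: FragmentationConfig,
    seed: int = 17,
    truth: GroundTruth | None = None,
    references: Mapping[str, str] | None = None,
) -> tuple[dict[PoolId, list[Contig]], GroundTruth]:
    """Fragment every clone into per-pool contigs with noise and contaminants.

    Contig ids encode the pool of origin and a per-pool serial
    (``S1.plate.03|c000007``) and are parseable back to a
    :class:`~poolscreen.design.PoolId`.
    """
    missing = set(clones) - set(assignment.inverse)
    if missing:
        raise SimulationError(f"{len(missing)} clone wells not covered by assignment")
    if truth is None:
        truth = GroundTruth()
    if frag.contaminant_fraction > 0 and not references:
        references = synthetic_references(seed=0)

    rng = np.random.default_rng(seed)
    code_cache = {w: seqs.encode(c.sequence) for w, c in clones.items()}
    pool_contigs: dict[PoolId, list[Contig]] = {}

    for pool in assignment.pools():
        serial = 0
        out: list[Contig] = []
        members = sorted(assignment.membership[pool] & set(clones))
        for well in members:
            codes = code_cache[well]
            length = len(codes)
            if math.isinf(frag.coverage_shape):
                local_cov = frag.coverage_per_pool
            else:
                local_cov = float(
                    rng.gamma(frag.coverage_shape,
                              frag.coverage_per_pool / frag.coverage_shape)
                )
            expected = frag.expected_fragment_length(local_cov)
            if math.isinf(expected):
                n_breaks = 0
            else:
                n_breaks = int(rng.poisson(length / expected))
            if n_breaks:
                cuts = np.sort(rng.integers(1, length, size=n_breaks))
                bounds = np.concatenate(([0], np.unique(cuts), [length]))
            else:
                bounds = np.array([0, length])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a < frag.min_fragment_len:
                    continue
                frag_codes = codes[a:b].copy()
                if frag.substitution_rate > 0:
                    _mutate(frag_codes, frag.substitution_rate, rng)
                serial += 1
                cid = f"{pool.tag()}|c{serial:06d}"
                coverage = float(local_cov * rng.lognormal(0.0, 0.1))
                out.append(
                    Contig(
                        id=cid,
                        pool=pool,
                        sequence=seqs.decode(frag_codes),
                        coverage=coverage,
                    )
                )
                truth.contigs.append(
                    {
                        "contig_id": cid,
                        "pool": pool.tag(),
                        "well": well.canonical(),
                        "start": int(a) + 1,
                        "end": int(b),
                        "is_contaminant": False,
                    }
                )
        if frag.contaminant_fraction > 0 and out:
            n_cont = int(round(frag.contaminant_fraction * len(out)))
            ref_items = sorted(references.items())
            for _ in range(n_cont):
                name, ref = ref_items[rng.integers(0, len(ref_items))]
                flen = int(
                    np.clip(rng.normal(1500, 400), frag.min_fragment_len, len(ref))
                )
                start = int(rng.integers(0, len(ref) - flen + 1))
                serial += 1
                cid = f"{pool.tag()}|c{serial:06d}"
                out.append(
                    Contig(
                        id=cid,
                        pool=pool,
                        sequence=ref[start : start + flen],
                        coverage=float(frag.coverage_per_pool),
                    )
                )
                truth.contigs.append(
                    {
                        "contig_id": cid,
                        "pool": pool.tag(),
                        "well": "",
                        "start": start + 1,
                        "end": start + flen,
                        "is_contaminant": True,
                    }
                )
        pool_contigs[pool] = out
    return pool_contigs, truth


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    n = rng.binomial(len(codes), rate)
    if n == 0:
        return
    pos = rng.choice(len(codes), size=n, replace=False)
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    codes[pos] = (codes[pos] + shift) % 4


@functools.lru_cache(maxsize=2)
def synthetic_references(
    seed: int = 0, host_len: int = 40000, vector_len: int = 8000
) -> dict[str, str]:
    """Synthetic host-genome and vector surrogate sequences (fixed by seed)."""
    rng = np.random.default_rng(seed + 0xE0C011)
    return {
        "host_surrogate": seqs.random_seq(rng, host_len),
        "vector_surrogate": seqs.random_seq(rng, vector_len),
    }


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]


def simulate_reads(
    clones: Mapping[WellAddress, CloneInsert],
    assignment: PoolAssignment,
    depth: float = 10.0,
    read_len: int = 150,
    quality_mean: int = 38,
    quality_jitter: float = 0.0,
    insert_size: float = 400.0,
    insert_sd: float = 40.0,
    seed: int = 17,
) -> dict[PoolId, list[ReadPair]]:
    """Paired-end read simulation per pool (shape emulation only).

    Per clone and pool, the number of pairs is ``round(depth * L / (2 *
    read_len))`` so that total sequenced bases approximate ``depth * L``.
    Qualities are flat at ``quality_mean`` with optional integer jitter.
    """
    if depth <= 0:
        raise SimulationError("depth must be > 0")
    rng = np.random.default_rng(seed)
    out: dict[PoolId, list[ReadPair]] = {}
    for pool in assignment.pools():
        reads: list[ReadPair] = []
        members = sorted(assignment.membership[pool] & set(clones))
        for well in members:
            seq = clones[well].sequence
            L = len(seq)
            if read_len > L:
                raise SimulationError(
                    f"read_len {read_len} exceeds insert length {L} at {well}"
                )
            n_pairs = int(round(depth * L / (2.0 * read_len)))
            for i in range(n_pairs):
                fsize = int(np.clip(rng.normal(insert_size, insert_sd), read_len, L))
                start = int(rng.integers(0, L - fsize + 1))
                frag = seq[start : start + fsize]
                r1 = frag[:read_len]
                r2 = seqs.revcomp(frag[-read_len:])
                if quality_jitter > 0:
                    q1 = tuple(
                        int(q)
                        for q in np.clip(
                            rng.normal(quality_mean, quality_jitter, read_len), 2, 41
                        )
                    )
                    q2 = tuple(
                        int(q)
                        for q in np.clip(
                            rng.normal(quality_mean, quality_jitter, read_len), 2, 41
                        )
                    )
                else:
                    q1 = q2 = (quality_mean,) * read_len
                reads.append(
                    ReadPair(
                        id=f"{pool.tag()}|{well.canonical()}|r{i:06d}",
                        seq1=r1,
                        qual1=q1,
                        seq2=r2,
                        qual2=q2,
                    )
                )
        out[pool] = reads
    return out
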