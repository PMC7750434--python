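"""End-to-end pipeline driver: design -> simulate -> match -> deconvolute ->
screen -> stats, with per-stage artifacts and a deterministic run manifest.

Each stage writes its outputs (TSV/FASTA/JSON) under the run directory; the
manifest echoes the configuration, all derived seeds, per-stage counters and
input checksums.  Identical configuration and seed give byte-identical
manifests.  A stage failure raises :class:`StageError` naming the stage;
artifacts written before the failure are kept.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__, io
from .config import RunConfig
from .deconvolve import deconvolute_library, deduplicate_by_clone
from .design import build_layout, build_pooling_scheme, PLATE
from .match import ScoringParams, build_index, find_hits
from .mining import detect_toy_cassettes, filter_min_length, summary_table
from .simulate import (
    FragmentationConfig,
    simulate_clones,
    simulate_pool_contigs,
    simulate_reads,
)
from .stats import (
    contig_stats_table,
    coverage_length_profile,
    kruskal_wallis,
    dunn,
    spearman,
)

log = logging.getLogger("poolscreen")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _derive_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage substreams, all below 2**31."""
    ss = np.random.SeedSequence(seed)
    names = ("clones", "contigs", "reads")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline per the configuration; return the manifest."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    manifest: dict = {
        "tool": "poolscreen",
        "version": __version__,
        "config": config.to_dict(),
        "seeds": seeds,
        "stages": {},
        "checksums": {},
    }

    # --- design ---------------------------------------------------------
    stage = "design"
    try:
        lc = config.layout
        layout = build_layout(lc.n_plates, lc.plate_format, lc.set_size)
        assignments = [
            build_pooling_scheme(layout, s, lc.strategy)
            for s in range(1, layout.n_sets + 1)
        ]
        manifest_frames = [io.pool_manifest(a) for a in assignments]
        import pandas as pd

        io.write_tsv(pd.concat(manifest_frames, ignore_index=True), out / "pools.tsv")
        io.write_tsv(io.barcode_map(assignments), out / "barcodes.tsv")
        manifest["stages"][stage] = {
            "n_sets": layout.n_sets,
            "total_wells": layout.total_wells,
            "pool_counts": [a.pool_counts() for a in assignments],
        }
        log.info("design: %d sets, %d wells", layout.n_sets, layout.total_wells)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        sc = config.simulate
        clones, truth = simulate_clones(
            layout,
            mean_length=sc.mean_length,
            dispersion=sc.dispersion,
            cassette_rate=sc.cassette_rate,
            min_length=sc.min_length,
            max_length=sc.max_length,
            seed=seeds["clones"],
        )
        frag = FragmentationConfig(
            coverage_per_pool=sc.coverage_per_pool,
            coverage_shape=sc.coverage_shape,
            c_star=sc.c_star,
            plateau_len=sc.plateau_len,
            base_len=sc.base_len,
            substitution_rate=sc.substitution_rate,
            min_fragment_len=sc.min_fragment_len,
            contaminant_fraction=sc.contaminant_fraction,
        )
        pools_dir = out / "pools"
        pools_dir.mkdir(exist_ok=True)
        pool_contigs: dict = {}
        for a in assignments:
            pc, truth = simulate_pool_contigs(
                {w: clones[w] for w in a.wells},
                a,
                frag,
                seed=seeds["contigs"] + a.set_index,
                truth=truth,
            )
            pool_contigs[a.set_index] = pc
            for pid, contigs in pc.items():
                io.contigs_to_fasta(contigs, pools_dir / f"{pid.tag()}.fasta")
        io.write_tsv(truth.clone_table(), out / "clone_truth.tsv")
        io.write_tsv(truth.cassette_table(), out / "cassette_truth.tsv")
        io.write_tsv(truth.contig_table(), out / "contig_truth.tsv")
        n_contigs = sum(len(v) for pc in pool_contigs.values() for v in pc.values())
        manifest["stages"][stage] = {
            "n_clones": len(clones),
            "n_contigs": n_contigs,
            "n_cassettes": len(truth.cassettes),
        }
        log.info("simulate: %d clones -> %d contigs", len(clones), n_contigs)
        if sc.reads:
            reads_dir = out / "reads"
            reads_dir.mkdir(exist_ok=True)
            for a in assignments:
                per_pool = simulate_reads(
                    {w: clones[w] for w in a.wells},
                    a,
                    depth=sc.read_depth,
                    read_len=sc.read_len,
                    seed=seeds["reads"] + a.set_index,
                )
                for pid, pairs in per_pool.items():
                    io.write_fastq_pairs(
                        pairs,
                        reads_dir / f"{pid.tag()}_R1.fastq",
                        reads_dir / f"{pid.tag()}_R2.fastq",
                    )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- match ----------------------------------------------------------
    stage = "match"
    try:
        mc = config.match
        params = ScoringParams()
        all_hits = []
        plate_contigs_by_set = {}
        for a in assignments:
            pc = pool_contigs[a.set_index]
            queries = [c for pid, cs in pc.items() if pid.dimension == PLATE for c in cs]
            subjects = [c for pid, cs in pc.items() if pid.dimension != PLATE for c in cs]
            plate_contigs_by_set[a.set_index] = queries
            if not subjects or not queries:
                continue
            index = build_index(subjects, k=mc.k)
            all_hits.extend(
                find_hits(
                    queries,
                    index,
                    min_identity=mc.min_identity,
                    max_evalue=mc.max_evalue,
                    min_aln_len=mc.min_aln_len,
                    x_drop=mc.x_drop,
                    params=params,
                )
            )
        io.write_tsv(io.hits_to_frame(all_hits), out / "hits.tsv")
        manifest["stages"][stage] = {"n_hits": len(all_hits)}
        log.info("match: %d hits", len(all_hits))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- deconvolute ----------------------------------------------------
    stage = "deconvolute"
    try:
        import pandas as pd

        results = {}
        frames = []
        for a in assignments:
            hits = [h for h in all_hits if h.query_id.startswith(f"S{a.set_index}.")]
            res = deconvolute_library(plate_contigs_by_set[a.set_index], hits, a)
            results[a.set_index] = res
            frames.append(res.to_frame())
        io.write_tsv(pd.concat(frames, ignore_index=True), out / "assignments.tsv")
        manifest["stages"][stage] = {
            f"set_{s}": {
                "tally": r.tally,
                "clone_coverage": round(r.clone_coverage, 4),
                "contig_rate": round(r.contig_rate, 4),
            }
            for s, r in results.items()
        }
        for s, r in results.items():
            log.info(
                "deconvolute set %d: %s, clone coverage %.1f%%",
                s,
                r.tally,
                100 * r.clone_coverage,
            )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- screen ---------------------------------------------------------
    stage = "screen"
    try:
        import pandas as pd

        record_count = 0
        class_frames = []
        ann_frames = []
        for a in assignments:
            queries = plate_contigs_by_set[a.set_index]
            mined = filter_min_length(queries, config.screen.min_contig_len)
            annotations = detect_toy_cassettes(mined)
            ann_frames.append(io.annotations_to_frame(annotations))
            records, table = deduplicate_by_clone(
                results[a.set_index].assignments, annotations, a
            )
            record_count += len(records)
            class_frames.append(table)
        io.write_tsv(pd.concat(ann_frames, ignore_index=True), out / "annotations.tsv")
        merged = (
            pd.concat(class_frames, ignore_index=True)
            if class_frames
            else pd.DataFrame(
                columns=["class_label", "ngs_count", "dedup_count", "assigned_count"]
            )
        )
        table1 = summary_table(merged) if len(merged) else merged
        io.write_tsv(table1, out / "bgc_summary.tsv")
        manifest["stages"][stage] = {
            "n_clone_records": record_count,
            "n_annotations": int(merged["ngs_count"].sum()) if len(merged) else 0,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stats ----------------------------------------------------------
    stage = "stats"
    try:
        all_contigs = [
            c for pc in pool_contigs.values() for cs in pc.values() for c in cs
        ]
        all_assignments = [
            a for r in results.values() for a in r.assignments
        ]
        table = contig_stats_table(all_contigs, all_assignments)
        io.write_tsv(table, out / "contig_stats.tsv")
        stats_summary: dict = {}
        if len(table) >= 3:
            rho, p = spearman(table["length"], table["coverage"])
            stats_summary["spearman_length_coverage"] = {"rho": rho, "p": p}
        plate = table[table["status"] != ""]
        groups = [
            grp["length"].to_numpy()
            for _, grp in plate.groupby("status")
            if len(grp) > 0
        ]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 5:
            kw = dunn(groups)
            stats_summary["kruskal_wallis_length_by_status"] = {
                "H": kw.statistic,
                "p": kw.pvalue,
                "df": kw.df,
            }
        profile = coverage_length_profile(table)
        stats_summary["coverage_profile"] = {
            "knee": profile.knee,
            "flag": profile.flag,
        }
        io.write_json(stats_summary, out / "stats.json")
        manifest["stages"][stage] = {"n_contig_stats": len(table)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    for f in sorted(out.glob("*.tsv")):
        manifest["checksums"][f.name] = io.sha256_of(f)
    io.write_json(manifest, out / "manifest.json")
    return manifest
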