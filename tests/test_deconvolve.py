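"""Deconvolution: status classification, coordinates, dedup, recovery."""

import numpy as np
import pytest

from poolscreen.deconvolve import (
    COMPLETE,
    PARTIAL,
    SINGLETON,
    CloneAssignment,
    DeconvolutionError,
    assign_coordinates,
    classify_contig,
    deconvolute_library,
    deduplicate_by_clone,
)
from poolscreen.design import (
    COLUMN,
    PLATE,
    ROW,
    CrossSetError,
    PoolId,
    WellAddress,
    build_layout,
    build_pooling_scheme,
)
from poolscreen.match import Contig, MatchHit
from poolscreen.mining import ClusterAnnotation


def _hit(query_id, subject_pool: PoolId, score=500, identity=99.0):
    return MatchHit(
        query_id=query_id,
        subject_id=f"{subject_pool.tag()}|c000001",
        subject_dimension=subject_pool.dimension,
        identity=identity,
        aln_len=score,
        mismatches=0,
        gaps=0,
        qstart=1,
        qend=score,
        sstart=1,
        send=score,
        strand="+",
        score=score,
        evalue=1e-30,
    )


@pytest.fixture(scope="module")
def set3():
    layout = build_layout(50, 384, 10)
    return build_pooling_scheme(layout, 3, "direct384")  # plates 21-30


@pytest.fixture(scope="module")
def plate29_contig():
    return Contig(id="S3.plate.29|c000001", pool=PoolId(3, PLATE, "29"), sequence="A" * 200)


def test_classify_complete_partial_singleton(plate29_contig):
    row_hit = _hit(plate29_contig.id, PoolId(3, ROW, "F"))
    col_hit = _hit(plate29_contig.id, PoolId(3, COLUMN, "07"))
    assert classify_contig(plate29_contig, [row_hit, col_hit]) == COMPLETE
    assert classify_contig(plate29_contig, [col_hit]) == PARTIAL
    assert classify_contig(plate29_contig, []) == SINGLETON


def test_classify_rejects_non_plate_contig_and_cross_set_hits(plate29_contig):
    row_contig = Contig(id="S3.row.F|c1", pool=PoolId(3, ROW, "F"), sequence="A" * 50)
    with pytest.raises(DeconvolutionError):
        classify_contig(row_contig, [])
    with pytest.raises(CrossSetError):
        classify_contig(plate29_contig, [_hit(plate29_contig.id, PoolId(1, ROW, "A"))])


def test_assign_coordinates_unique_candidate(set3, plate29_contig):
    hits = [
        _hit(plate29_contig.id, PoolId(3, ROW, "O"), score=700),
        _hit(plate29_contig.id, PoolId(3, COLUMN, "18"), score=650),
    ]
    a = assign_coordinates(plate29_contig, hits, set3)
    assert a.status == COMPLETE and a.unique and a.resolved
    assert a.top_well.canonical() == "P29O18"
    assert a.candidates[0][1] == 1350.0


def test_assign_coordinates_ranks_multiple_candidates(set3, plate29_contig):
    hits = [
        _hit(plate29_contig.id, PoolId(3, ROW, "O"), score=700),
        _hit(plate29_contig.id, PoolId(3, ROW, "B"), score=120),
        _hit(plate29_contig.id, PoolId(3, COLUMN, "18"), score=650),
    ]
    a = assign_coordinates(plate29_contig, hits, set3)
    assert not a.unique and len(a.candidates) == 2
    assert [w.canonical() for w, _ in a.candidates] == ["P29O18", "P29B18"]
    assert a.resolved  # row O dominates row B by far more than the ratio


def test_dominance_fails_when_scores_are_close(set3, plate29_contig):
    hits = [
        _hit(plate29_contig.id, PoolId(3, ROW, "O"), score=700),
        _hit(plate29_contig.id, PoolId(3, ROW, "B"), score=690),
        _hit(plate29_contig.id, PoolId(3, COLUMN, "18"), score=650),
    ]
    a = assign_coordinates(plate29_contig, hits, set3)
    assert not a.unique and not a.resolved


def test_partial_contig_has_no_candidates(set3, plate29_contig):
    a = assign_coordinates(
        plate29_contig, [_hit(plate29_contig.id, PoolId(3, COLUMN, "07"))], set3
    )
    assert a.status == PARTIAL and a.candidates == [] and not a.resolved


def test_empty_hit_set_gives_all_singletons(set3):
    contigs = [
        Contig(id=f"S3.plate.21|c{i:06d}", pool=PoolId(3, PLATE, "21"), sequence="A" * 100)
        for i in range(5)
    ]
    res = deconvolute_library(contigs, [], set3)
    assert res.tally == {COMPLETE: 0, PARTIAL: 0, SINGLETON: 5}
    assert res.clone_coverage == 0.0


def test_status_tally_partitions_plate_contigs(clean_sim):
    res = clean_sim.result
    assert sum(res.tally.values()) == len(clean_sim.plate_contigs)


def test_noiseless_assignments_match_ground_truth(clean_sim):
    truth_well = clean_sim.truth.well_of_contig()
    for a in clean_sim.result.assignments:
        if a.status == COMPLETE:
            assert a.top_well.canonical() == truth_well[a.contig_id]


def test_noiseless_resolved_coverage_is_total(clean_sim):
    assert clean_sim.result.resolved_coverage == 1.0


def test_rearray_strategy_recovers_384_format_wells(rearray_sim):
    truth_well = rearray_sim.truth.well_of_contig()
    n_complete = 0
    for a in rearray_sim.result.assignments:
        if a.status == COMPLETE:
            n_complete += 1
            assert a.top_well.canonical() == truth_well[a.contig_id]
    assert n_complete > 300  # nearly all of the 384 clones
    assert rearray_sim.result.resolved_coverage > 0.95


def test_threshold_monotonicity_on_fixed_hit_panel(clean_sim):
    """Stricter identity or e-value cutoffs never add complete contigs."""
    base = clean_sim.result.tally[COMPLETE]
    for subset in (
        [h for h in clean_sim.hits if h.identity >= 99.99],
        [h for h in clean_sim.hits if h.evalue <= 1e-40],
    ):
        res = deconvolute_library(clean_sim.plate_contigs, subset, clean_sim.assignment)
        assert res.tally[COMPLETE] <= base
        assert sum(res.tally.values()) == len(clean_sim.plate_contigs)


def test_complete_contigs_are_longer_than_singletons(harsh_sim):
    """Length predicts deconvolution success on fragmented noisy data."""
    tally = harsh_sim.result.tally
    assert tally[SINGLETON] > 0 and tally[COMPLETE] > 0
    lengths = {c.id: c.length for c in harsh_sim.plate_contigs}
    by_status = {s: [] for s in (COMPLETE, SINGLETON)}
    for a in harsh_sim.result.assignments:
        if a.status in by_status:
            by_status[a.status].append(lengths[a.contig_id])
    assert np.median(by_status[COMPLETE]) >= np.median(by_status[SINGLETON])


# --- deduplication ---------------------------------------------------------


def _fake_assignment(contig_id, well, status=COMPLETE):
    a = CloneAssignment(contig_id=contig_id, status=status)
    if status == COMPLETE:
        a.candidates = [(well, 100.0)]
    return a


def test_same_class_same_well_collapses():
    well = WellAddress(5, "B", 3)
    assignments = [
        _fake_assignment("c1", well),
        _fake_assignment("c2", well),
    ]
    anns = [
        ClusterAnnotation("c1", 1, 500, "NRPS", (("C", "A", "PCP"),)),
        ClusterAnnotation("c2", 1, 400, "NRPS", (("C", "A", "PCP"),)),
    ]
    records, table = deduplicate_by_clone(assignments, anns)
    assert len(records) == 1 and records[0].well == well
    row = table[table.class_label == "NRPS"].iloc[0]
    assert row.ngs_count == 2 and row.dedup_count == 1 and row.assigned_count == 1


def test_same_class_different_wells_not_collapsed():
    assignments = [
        _fake_assignment("c1", WellAddress(5, "B", 3)),
        _fake_assignment("c2", WellAddress(6, "C", 4)),
    ]
    anns = [
        ClusterAnnotation("c1", 1, 500, "NRPS", (("C", "A", "PCP"),)),
        ClusterAnnotation("c2", 1, 400, "NRPS", (("C", "A", "PCP"),)),
    ]
    records, table = deduplicate_by_clone(assignments, anns)
    assert len(records) == 2
    assert table[table.class_label == "NRPS"].iloc[0].dedup_count == 2


def test_unresolved_annotations_count_individually():
    well = WellAddress(5, "B", 3)
    assignments = [
        _fake_assignment("c1", well),
        _fake_assignment("c2", well, status=SINGLETON),
    ]
    anns = [
        ClusterAnnotation("c1", 1, 500, "Terpene", ()),
        ClusterAnnotation("c2", 1, 400, "Terpene", ()),
    ]
    _, table = deduplicate_by_clone(assignments, anns)
    row = table.iloc[0]
    assert row.ngs_count == 2 and row.dedup_count == 2 and row.assigned_count == 1


def test_unknown_contig_annotation_warned_and_skipped():
    with pytest.warns(UserWarning, match="unknown contig"):
        records, table = deduplicate_by_clone(
            [], [ClusterAnnotation("ghost", 1, 10, "NRPS", ())]
        )
    assert records == [] and table.empty


def test_dedup_never_exceeds_raw_counts(clean_sim):
    from poolscreen.mining import detect_toy_cassettes, filter_min_length

    anns = detect_toy_cassettes(filter_min_length(clean_sim.plate_contigs, 1000))
    _, table = deduplicate_by_clone(clean_sim.result.assignments, anns, clean_sim.assignment)
    assert (table.dedup_count <= table.ngs_count).all()
    assert (table.assigned_count <= table.dedup_count).all()
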