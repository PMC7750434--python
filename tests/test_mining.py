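"""BGC mining rules: module parsing, viability, divergence, filters, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from poolscreen import seqs
from poolscreen.design import PLATE, PoolId
from poolscreen.match import Contig
from poolscreen.mining import (
    CARRIER_TOKENS,
    DOMAIN_TOKENS,
    MiningError,
    SixteenSHit,
    clone_domain_summary,
    detect_toy_cassettes,
    divergence,
    filter_16s_hits,
    filter_min_length,
    hit_rate,
    parse_modules,
    summary_table,
    viability,
    Module,
)
from poolscreen.simulate import marker_vocabulary

POOL = PoolId(1, PLATE, "01")


def _contig(cid, seq):
    return Contig(id=cid, pool=POOL, sequence=seq)


# --- length pre-filter -----------------------------------------------------


def test_min_length_filter_is_strict():
    contigs = [_contig(f"c{n}", "A" * n) for n in (999, 1000, 1001)]
    kept = filter_min_length(contigs, 1000)
    assert [c.length for c in kept] == [1001]
    assert filter_min_length([], 1000) == []
    assert filter_min_length(contigs, 0) == contigs


# --- module parsing --------------------------------------------------------


def test_parse_modules_nrps_three_complete():
    modules = parse_modules(["C", "A", "PCP"] * 3)
    assert len(modules) == 3
    assert all(m.complete and m.chemistry == "NRPS" for m in modules)


def test_parse_modules_incomplete_lacking_a_domain():
    modules = parse_modules(["C", "PCP", "C", "A", "PCP"])
    assert [m.complete for m in modules] == [False, True]
    assert modules[0].chemistry == "NRPS"


def test_parse_modules_pks_with_tailoring_domains():
    modules = parse_modules(["KS", "AT", "KR", "ACP"] * 4)
    assert len(modules) == 4
    assert all(m.complete and m.chemistry == "PKS" for m in modules)
    assert all("KR" in m.domains for m in modules)


def test_trailing_tokens_form_incomplete_module():
    modules = parse_modules(["C", "A", "PCP", "C", "A"])
    assert len(modules) == 2
    assert not modules[-1].complete and modules[-1].chemistry == "NRPS"


def test_parse_modules_empty_and_unknown_token():
    assert parse_modules([]) == []
    with pytest.raises(MiningError):
        parse_modules(["C", "A", "XYZ"])


@given(st.lists(st.sampled_from(DOMAIN_TOKENS), max_size=40))
def test_parse_modules_preserves_token_order(tokens):
    modules = parse_modules(tokens)
    flat = [t for m in modules for t in m.domains]
    assert flat == tokens
    for m in modules[:-1]:  # every non-final module ends at a carrier
        assert m.domains[-1] in CARRIER_TOKENS


# --- viability -------------------------------------------------------------


def _mods(flags):
    return [Module("NRPS", ("C", "A", "PCP"), f) for f in flags]


def test_viability_requires_three_adjacent_complete():
    assert viability(_mods([True, True, True]))
    assert not viability(_mods([True, False, True, True]))
    assert not viability(_mods([True, True]))


def test_viability_long_cluster_with_incomplete_modules():
    flags = [True] * 10 + [False] + [True] * 12 + [False] * 3
    assert sum(flags) == 22 and flags.count(False) == 4
    assert viability(_mods(flags))


@given(st.lists(st.booleans(), min_size=1, max_size=30))
def test_completing_a_module_never_destroys_viability(flags):
    before = viability(_mods(flags))
    for i, f in enumerate(flags):
        if not f:
            promoted = flags[:i] + [True] + flags[i + 1 :]
            if before:
                assert viability(_mods(promoted))


# --- divergence ------------------------------------------------------------


def test_divergence_worked_examples():
    assert divergence(60) == 40
    assert divergence(100) == 0
    assert divergence(23.8) == pytest.approx(76.2)


@given(st.floats(min_value=0, max_value=100, allow_nan=False))
def test_divergence_is_an_involution(x):
    assert divergence(divergence(x)) == pytest.approx(x, abs=1e-12)


def test_divergence_rejects_out_of_range():
    with pytest.raises(MiningError):
        divergence(-1)
    with pytest.raises(MiningError):
        divergence(101)


# --- per-clone domain summaries -------------------------------------------


def test_clone_domain_summary_examples():
    assert clone_domain_summary([60, 60], [2, 2]) == (40.0, 2.0, 2)
    assert clone_domain_summary([85.0], [3.1]) == (15.0, 3.1, 1)


def test_clone_domain_summary_against_direct_summation():
    rng = np.random.default_rng(31)
    idents = rng.uniform(20, 95, 1000)
    branches = rng.uniform(0.1, 4, 1000)
    mean_div, mean_br, n = clone_domain_summary(list(idents), list(branches))
    assert n == 1000
    assert abs(mean_div - (100 - math.fsum(idents) / 1000)) < 1e-12
    assert abs(mean_br - math.fsum(branches) / 1000) < 1e-12


def test_clone_domain_summary_empty_rejected():
    with pytest.raises(MiningError):
        clone_domain_summary([], [])


# --- 16S hit filters -------------------------------------------------------


def _s16(e=1e-6, init=50, length=400, ident=80.0, phylum="Acidobacteria"):
    return SixteenSHit("q", e, init, length, ident, phylum)


def test_16s_filters_keep_and_discard():
    kept = filter_16s_hits([_s16()])
    assert len(kept) == 1 and kept[0].phylum == "Acidobacteria"
    assert filter_16s_hits([_s16(length=250)]) == []
    assert filter_16s_hits([_s16(e=1e-4)]) == []
    assert filter_16s_hits([_s16(e=1e-5)]) == []  # strictly-below rule
    assert filter_16s_hits([_s16(init=44)]) == []


def test_16s_low_identity_becomes_unclassified():
    kept = filter_16s_hits([_s16(ident=70.0)])
    assert kept[0].phylum == "unclassified"


def test_16s_length_rule_toggle():
    hit = _s16(init=200, length=400)
    assert filter_16s_hits([hit], min_len=300, length_attr="initial_aln_len") == []
    assert len(filter_16s_hits([hit], min_len=300, length_attr="total_len")) == 1


# --- summary table and hit rates ------------------------------------------


def test_hit_rates_round_as_reported():
    assert hit_rate(50, 19200, 2) == 0.26
    assert hit_rate(223, 19200, 1) == 1.2
    with pytest.raises(MiningError):
        hit_rate(1, 0)


def test_summary_table_totals_row_conserves_columns():
    stats = pd.DataFrame(
        [
            {"class_label": "Type I PKS", "ngs_count": 75, "dedup_count": 39, "assigned_count": 29},
            {"class_label": "NRPS", "ngs_count": 509, "dedup_count": 160, "assigned_count": 110},
            {"class_label": "Terpene", "ngs_count": 371, "dedup_count": 201, "assigned_count": 163},
        ]
    )
    table = summary_table(stats)
    totals = table[table.class_label == "Total"].iloc[0]
    body = table[table.class_label != "Total"]
    assert totals.ngs_count == body.ngs_count.sum()
    assert totals.dedup_count == body.dedup_count.sum()
    assert totals.assigned_count == body.assigned_count.sum()
    assert table.attrs["pct_deconvoluted_raw_weighted"] is not None


def test_summary_table_folds_unknown_classes_into_other():
    stats = pd.DataFrame(
        [{"class_label": "Mystery", "ngs_count": 3, "dedup_count": 2, "assigned_count": 1}]
    )
    with pytest.warns(UserWarning, match="Other"):
        table = summary_table(stats)
    assert table.iloc[0].class_label == "Other"


# --- toy cassette detection ------------------------------------------------


def _cassette_seq(plan, rng, linker=40):
    vocab = marker_vocabulary()
    parts = []
    for tok in plan:
        parts.append(vocab[tok])
        parts.append(seqs.random_seq(rng, linker))
    return "".join(parts[:-1])


def test_detect_plus_strand_cassette():
    rng = np.random.default_rng(41)
    plan = ("KS", "AT", "ACP") * 4
    seq = seqs.random_seq(rng, 500) + _cassette_seq(plan, rng) + seqs.random_seq(rng, 500)
    anns = detect_toy_cassettes([_contig("c1", seq)])
    assert len(anns) == 1
    assert anns[0].domains == plan and anns[0].strand == "+"
    assert anns[0].class_label == "Type I PKS"
    assert anns[0].start == 501


def test_detect_reverse_strand_cassette_in_plan_order():
    rng = np.random.default_rng(42)
    plan = ("C", "A", "PCP") * 3
    cassette = _cassette_seq(plan, rng)
    seq = seqs.random_seq(rng, 300) + seqs.revcomp(cassette) + seqs.random_seq(rng, 300)
    anns = detect_toy_cassettes([_contig("c1", seq)])
    assert len(anns) == 1
    assert anns[0].domains == plan and anns[0].strand == "-"
    assert anns[0].class_label == "NRPS"


def test_cassette_split_across_fragments_concatenates_to_plan():
    rng = np.random.default_rng(43)
    plan = ("KS", "AT", "ACP", "KS", "AT", "ACP", "C", "A", "PCP")
    cassette = _cassette_seq(plan, rng)
    full = seqs.random_seq(rng, 400) + cassette + seqs.random_seq(rng, 400)
    cut = 400 + 6 * 160 - 20  # inside the linker after the sixth marker
    left, right = full[:cut], full[cut:]
    anns = detect_toy_cassettes([_contig("left", left), _contig("right", right)])
    assert len(anns) == 2
    combined = anns[0].domains + anns[1].domains
    assert combined == plan
    assert anns[0].class_label == "Type I PKS" and anns[1].class_label == "NRPS"


def test_hybrid_cassette_classified_as_pks_nrps():
    rng = np.random.default_rng(44)
    plan = ("KS", "AT", "ACP", "C", "A", "PCP")
    seq = _cassette_seq(plan, rng)
    anns = detect_toy_cassettes([_contig("c1", seq)])
    assert anns[0].class_label == "Type I PKS-NRPS"
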