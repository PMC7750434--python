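"""Shared fixtures: seeded end-to-end simulations reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

from poolscreen.deconvolve import DeconvolutionResult, deconvolute_library
from poolscreen.design import (
    PLATE,
    LibraryLayout,
    PoolAssignment,
    build_layout,
    build_pooling_scheme,
)
from poolscreen.match import MatchHit, build_index, find_hits
from poolscreen.simulate import (
    FragmentationConfig,
    GroundTruth,
    simulate_clones,
    simulate_pool_contigs,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@dataclass
class SimBundle:
    """One simulated library run: design through deconvolution."""

    layout: LibraryLayout
    assignment: PoolAssignment
    clones: dict
    truth: GroundTruth
    pool_contigs: dict
    plate_contigs: list
    subject_contigs: list
    hits: list[MatchHit]
    result: DeconvolutionResult


def run_simulation(
    n_plates: int = 4,
    plate_format: int = 96,
    strategy: str = "direct384",
    mean_length: float = 6000.0,
    min_length: int = 3000,
    max_length: int = 10000,
    cassette_rate: float = 0.2,
    substitution_rate: float = 0.0,
    plateau_len: float = 8000.0,
    min_fragment_len: int = 300,
    seed: int = 101,
) -> SimBundle:
    layout = build_layout(n_plates, plate_format, 10)
    assignment = build_pooling_scheme(layout, 1, strategy)
    clones, truth = simulate_clones(
        layout,
        mean_length=mean_length,
        cassette_rate=cassette_rate,
        min_length=min_length,
        max_length=max_length,
        seed=seed,
    )
    frag = FragmentationConfig(
        coverage_per_pool=60.0,
        substitution_rate=substitution_rate,
        plateau_len=plateau_len,
        min_fragment_len=min_fragment_len,
    )
    pool_contigs, truth = simulate_pool_contigs(
        clones, assignment, frag, seed=seed + 1, truth=truth
    )
    plate_contigs = [
        c for pid, cs in pool_contigs.items() if pid.dimension == PLATE for c in cs
    ]
    subjects = [
        c for pid, cs in pool_contigs.items() if pid.dimension != PLATE for c in cs
    ]
    hits = find_hits(plate_contigs, build_index(subjects))
    result = deconvolute_library(plate_contigs, hits, assignment)
    return SimBundle(
        layout=layout,
        assignment=assignment,
        clones=clones,
        truth=truth,
        pool_contigs=pool_contigs,
        plate_contigs=plate_contigs,
        subject_contigs=subjects,
        hits=hits,
        result=result,
    )


@pytest.fixture(scope="session")
def clean_sim() -> SimBundle:
    """Noiseless 4-plate x 96-well library (inserts 3-10 kb, cassette rate 0.2)."""
    return run_simulation(substitution_rate=0.0, seed=101)


@pytest.fixture(scope="session")
def noisy_sim() -> SimBundle:
    """Same library conditions with 1% substitution noise."""
    return run_simulation(substitution_rate=0.01, seed=101)


@pytest.fixture(scope="session")
def harsh_sim() -> SimBundle:
    """Heavily fragmented noisy library: produces partial/singleton contigs."""
    return run_simulation(
        n_plates=1,
        mean_length=3000.0,
        min_length=1000,
        max_length=8000,
        cassette_rate=0.0,
        substitution_rate=0.005,
        plateau_len=350.0,
        min_fragment_len=250,
        seed=11,
    )


@pytest.fixture(scope="session")
def rearray_sim() -> SimBundle:
    """One 384-well plate pooled through the 96-well quadrant re-array."""
    return run_simulation(
        n_plates=1,
        plate_format=384,
        strategy="rearray96",
        mean_length=2000.0,
        min_length=1200,
        max_length=5000,
        cassette_rate=0.1,
        substitution_rate=0.0,
        seed=7,
    )
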