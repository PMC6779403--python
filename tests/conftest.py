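"""Shared fixtures: a small synthetic reference and a small simulated cohort."""

import pytest

from trnavarseq.pipeline import run_cohort
from trnavarseq.synthetic_cohort import (
    SimParams,
    make_reference,
    plant_cohort,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Six loci including one gene-body-identical pair."""
    return SimParams(n_individuals=4, n_loci=6, identical_pair_fraction=1 / 3,
                     coverage_mean=40.0, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_params):
    return make_reference(small_params)


@pytest.fixture(scope="session")
def cohort_params() -> SimParams:
    """A compact cohort for pipeline-level tests."""
    return SimParams(n_individuals=6, n_loci=10, coverage_mean=40.0, seed=3)


@pytest.fixture(scope="session")
def cohort_truth(cohort_params):
    ref = make_reference(cohort_params)
    return plant_cohort(ref, cohort_params)


@pytest.fixture(scope="session")
def cohort_reads(cohort_truth, cohort_params):
    reads, provenance = simulate_reads(
        cohort_truth, cohort_params, with_provenance=True
    )
    return reads, provenance


@pytest.fixture(scope="session")
def cohort_result(cohort_truth, cohort_reads):
    reads, _ = cohort_reads
    return run_cohort(reads, cohort_truth.reference.loci)
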