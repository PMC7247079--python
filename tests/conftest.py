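import numpy as np
import pandas as pd
import pytest

import barseqfit as bf
from barseqfit.phenotype import PROLIFERATION, QUIESCENCE


@pytest.fixture(scope="session")
def small_truth():
    return bf.simulate_truth(
        n_strains=40, conditions=("C",), queries=("TOR1",), seed=3
    )


@pytest.fixture(scope="session")
def small_catalog(small_truth):
    return bf.make_catalog(
        n_strains=40, seed=7, n_indices=45, strain_ids=list(small_truth.strains)
    )


@pytest.fixture(scope="session")
def small_design():
    return bf.TimeCourseDesign(
        libraries=("HO", "TOR1"), conditions=("C",), n_replicates=2, depth=50_000
    )


@pytest.fixture(scope="session")
def small_counts(small_truth, small_design):
    return bf.simulate_counts(small_truth, small_design, seed=5)


@pytest.fixture(scope="session")
def tiny_counts(small_truth):
    """A few thousand reads' worth of counts, cheap to round-trip as FASTQ."""
    design = bf.TimeCourseDesign(
        libraries=("HO",), conditions=("C",), n_replicates=1, depth=3_000,
        times_h={PROLIFERATION: (0.0, 24.0)},
    )
    return bf.simulate_counts(small_truth, design, seed=5)


def make_samples(n_reps=3, times=(0, 9, 14, 18, 24), phase=PROLIFERATION,
                 library="HO", condition="C"):
    """Minimal single-library sample sheet for synthetic regression tests."""
    rows = []
    for rep in range(1, n_reps + 1):
        for t in times:
            rows.append(
                {
                    "sample_id": f"{library}_{condition}_r{rep}_t{t:g}",
                    "library": library,
                    "condition": condition,
                    "replicate": rep,
                    "time_h": float(t),
                    "phase": phase,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def two_phase_samples():
    pro = make_samples(times=(0, 9, 14, 18, 24), phase=PROLIFERATION)
    qui = make_samples(times=(32, 48, 96, 187, 368), phase=QUIESCENCE)
    return pd.concat([pro, qui])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
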