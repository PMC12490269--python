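import numpy as np
import pytest

from comboscreen import (
    CombinationDesign,
    DrugTruth,
    fit_median_effect,
    normalize_viability,
    simulate_single_agent_plate,
)


@pytest.fixture
def drug_truth():
    """A mid-potency reference drug: Dm = 1 µM, m = 1.5, C_max = 10 µM."""
    return DrugTruth("drugA", dm=1.0, m=1.5, cmax=10.0)


@pytest.fixture
def partner_truth():
    """A second drug with different potency and steeper slope."""
    return DrugTruth("drugB", dm=3.0, m=2.0, cmax=8.0)


@pytest.fixture
def noiseless_fit(drug_truth):
    """Median-effect fit recovered from a noiseless plate of the reference drug."""
    records = simulate_single_agent_plate(drug_truth, noise_sd=0.0, seed=0)
    (curve,) = normalize_viability(records)
    return fit_median_effect(curve)


@pytest.fixture
def pair_design(drug_truth, partner_truth):
    return CombinationDesign(
        drug_truth.drug, partner_truth.drug, drug_truth.cmax, partner_truth.cmax
    )


def random_fit_params(rng: np.random.Generator):
    """Draw a plausible (Dm, m) pair for property tests."""
    return float(10.0 ** rng.uniform(-1.5, 1.5)), float(rng.uniform(0.5, 3.0))
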