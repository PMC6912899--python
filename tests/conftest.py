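from __future__ import annotations

import numpy as np
import pytest

from mitosat.coalsim import (
    MarkerConfig,
    PriorSpec,
    ScenarioSpec,
    default_prior,
)
from mitosat.data import GenotypeTable, HaplotypeAlignment


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Two populations x three individuals x two loci, hand-built."""
    calls = np.array(
        [
            [[10, 10], [20, 22]],
            [[10, 12], [20, 20]],
            [[12, 12], [22, 22]],
            [[14, 14], [24, 24]],
            [[14, 16], [24, 26]],
            [[16, 16], [26, 26]],
        ]
    )
    return GenotypeTable(
        ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        ["A", "A", "A", "B", "B", "B"],
        ["L1", "L2"],
        calls,
    )


@pytest.fixture
def toy_alignment() -> HaplotypeAlignment:
    seqs = [
        "ACGTACGT",
        "ACGTACGA",
        "ACGTACGT",
        "TCGAACGA",
        "TCGAACGA",
        "TCGAACGT",
    ]
    return HaplotypeAlignment(
        [f"s{k}" for k in range(6)],
        ["A", "A", "A", "B", "B", "B"],
        seqs,
    )


def small_config(**kwargs) -> MarkerConfig:
    defaults = dict(n_diploid=(15, 12), n_haploid=(12, 10))
    defaults.update(kwargs)
    return MarkerConfig(**defaults)


def separable_prior() -> PriorSpec:
    """Narrow priors under which the four scenarios are well separated:
    deep divergence, strong migration where the scenario allows it, and a
    migration-window boundary away from both ends."""
    return default_prior().with_overrides(
        n1_sat=("loguniform", 1e3, 1e4),
        n2_sat=("loguniform", 1e3, 1e4),
        nanc_sat=("loguniform", 1e3, 1e4),
        n1_mt=("loguniform", 5e2, 5e3),
        n2_mt=("loguniform", 5e2, 5e3),
        nanc_mt=("loguniform", 5e2, 5e3),
        t2=("loguniform", 5e4, 2e5),
        t1=("uniform", 0.3, 0.7),
        m12_sat=("fixed", 1e-2, 1e-2),
        m21_sat=("fixed", 1e-2, 1e-2),
        m12_mt=("fixed", 1e-2, 1e-2),
        m21_mt=("fixed", 1e-2, 1e-2),
    )


# ---------------------------------------------------------------------------
# expensive shared references for the calibration experiments; session-scoped
# so the model-choice and recovery checks reuse a single simulation effort
# ---------------------------------------------------------------------------

SEPARABLE_ROWS_PER_SCENARIO = 5000
RECOVERY_ROWS = 10000
RECOVERY_PODS = 200


@pytest.fixture(scope="session")
def separable_reference():
    from mitosat.abcrf import build_reference

    rng = np.random.default_rng(20_001)
    return build_reference(
        separable_prior(),
        [1, 2, 3, 4],
        SEPARABLE_ROWS_PER_SCENARIO,
        small_config(),
        rng,
    )


@pytest.fixture(scope="session")
def recovery_setup():
    """Scenario-3 training table under the broad default priors plus PODs
    with known truth, for parameter-recovery validation."""
    from mitosat.abcrf import build_reference
    from mitosat.sumstats import summarize_pair
    from mitosat.synth import make_pods
    import pandas as pd

    rng = np.random.default_rng(20_002)
    config = small_config()
    prior = default_prior()
    reference = build_reference(prior, [3], RECOVERY_ROWS, config, rng)
    pods = make_pods(prior, ScenarioSpec(3), RECOVERY_PODS, config, rng)
    stats = np.stack([summarize_pair(t, a).values for t, a, _ in pods])
    truth = pd.DataFrame([tr.params for _, _, tr in pods])
    return reference, stats, truth
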