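import numpy as np
import pytest

from polymix import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_cohort():
    """Two-ancestry cohort with real trait signal, small enough for every test."""
    cfg = SimConfig(
        n_per_ancestry={"EUR": 1500, "AFR": 700},
        prevalence={"EUR": 0.10, "AFR": 0.07},
        trait_names=["AF", "HF", "BMI"],
        liability_loadings={"EUR": [0.6, 0.3, 0.1], "AFR": [0.3, 0.4, 0.1]},
        beta_age=0.25,
        beta_sex=0.2,
        n_pcs=5,
        pc_separation=3.0,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def brute_force_auroc(score, case):
    """Mann-Whitney pair counting: P(case score > control score), ties half."""
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=int)
    cases = score[case == 1]
    controls = score[case == 0]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))
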