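import numpy as np
import pandas as pd
import pytest

from ipwlearn.cohort import SyntheticConfig, generate_cohort
from ipwlearn.design import compute_ipw_weights, two_phase_sample
from ipwlearn.tables import PHASE2_COL, WEIGHT_COL


def small_config(seed: int = 0, **kw) -> SyntheticConfig:
    """A fast cohort: 1200 subjects, modest marker panel, clear signal."""
    defaults = dict(
        cohort_size=1200,
        case_rate=0.05,
        p_tcell=12,
        p_antibody=12,
        marker_block_size=6,
        n_signal_tcell=2,
        n_signal_antibody=2,
        linear_effect_size=0.8,
        interaction_effect_size=0.8,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(small_config(seed=7))


@pytest.fixture(scope="session")
def small_phase_two(small_cohort) -> pd.DataFrame:
    sampled = two_phase_sample(small_cohort, controls_per_case=5, seed=3)
    return compute_ipw_weights(sampled)


@pytest.fixture(scope="session")
def tiny_phase_two() -> pd.DataFrame:
    """~25 cases / 125 controls with weights, cheap enough for repeated CV."""
    cfg = small_config(seed=5, cohort_size=3000, case_rate=25 / 3000)
    cohort = generate_cohort(cfg)
    sampled = two_phase_sample(cohort, controls_per_case=5, seed=5)
    return compute_ipw_weights(sampled)


def brute_force_weighted_auc(p1, p0, w1, w0) -> float:
    """Independent pair-enumeration oracle for the weighted AUC."""
    num = den = 0.0
    for pi, wi in zip(p1, w1):
        for pj, wj in zip(p0, w0):
            ww = wi * wj
            den += ww
            if pi > pj:
                num += ww
            elif pi == pj:
                num += 0.5 * ww
    return num / den
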