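import numpy as np
import pandas as pd
import pytest

from methmr.ewas import MatchedPairSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def pairs_from_diffs(diffs, covariate_diffs=None):
    """Build a MatchedPairSet whose within-pair differences are `diffs`
    (controls at zero), optionally with named covariate differences."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    cov_case = pd.DataFrame(index=range(n))
    cov_ctrl = pd.DataFrame(index=range(n))
    if covariate_diffs:
        for name, vals in covariate_diffs.items():
            cov_case[name] = np.asarray(vals, dtype=float)
            cov_ctrl[name] = 0.0
    return MatchedPairSet(
        pair_id=np.arange(1, n + 1),
        case_methylation=pd.DataFrame({"cpg_1": diffs}),
        control_methylation=pd.DataFrame({"cpg_1": np.zeros(n)}),
        case_covariates=cov_case,
        control_covariates=cov_ctrl,
    )


@pytest.fixture
def small_cohort():
    from methmr.synthetic_data import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_individuals=2000, n_snps=3, maf=0.3, beta_gp=0.4,
        theta=0.0, gamma=-0.5, delta=0.7, base_logodds=-1.0,
        n_pairs=200, seed=11,
    )
    return simulate_cohort(cfg)
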