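"""Reference simulation scenarios for calibration experiments.

The confounded-null replicate is the scenario of central interest: no causal
methylation effect, but a smoking burden that lowers methylation and raises
disease risk.  Each replicate simulates two independent cohorts (exposure
and outcome samples of a two-sample design), exports summary statistics,
harmonizes, and computes the IVW causal estimate alongside the matched-pair
observational EWAS estimate from the outcome-side scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ewas import conditional_logistic
from .synthetic_data import (
    confounded_null_config,
    export_summary_stats,
    make_matched_pairs,
    simulate_cohort,
)
from .two_sample_mr import MRResult, harmonize, ivw_combine, wald_ratio

__all__ = ["ConfoundedNullReplicate", "run_confounded_null_replicate"]

#: seed offset separating the outcome-sample cohort from the exposure one
_OUTCOME_SEED_OFFSET = 500_000


@dataclass
class ConfoundedNullReplicate:
    """Per-replicate results of the confounded-null experiment."""

    seed: int
    ivw: MRResult
    ewas_log_or: float
    ewas_se: float


def run_confounded_null_replicate(
    seed: int,
    n_individuals: int = 20_000,
    n_pairs: int = 3000,
    theta: float = 0.0,
    run_ewas: bool = True,
    **config_kwargs,
) -> ConfoundedNullReplicate:
    """One replicate: two independent cohorts -> summary stats -> IVW.

    The exposure and outcome samples never share individuals (independent
    seeds), as the two-sample design requires.  The observational EWAS
    estimate is computed from matched pairs drawn from a third independent
    cohort so that it shares no data with either MR sample.
    """
    exp_cohort = simulate_cohort(
        confounded_null_config(seed, n_individuals=n_individuals, theta=theta,
                               n_pairs=0, **config_kwargs)
    )
    out_cohort = simulate_cohort(
        confounded_null_config(seed + _OUTCOME_SEED_OFFSET,
                               n_individuals=n_individuals, theta=theta,
                               n_pairs=0, **config_kwargs)
    )
    exposure = export_summary_stats(exp_cohort, "exposure")
    outcome = export_summary_stats(out_cohort, "outcome")
    harmonized, _ = harmonize(exposure, outcome)
    ivw = ivw_combine([wald_ratio(h) for h in harmonized])

    ewas_log_or = ewas_se = float("nan")
    if run_ewas:
        obs_cohort = simulate_cohort(
            confounded_null_config(seed + 2 * _OUTCOME_SEED_OFFSET,
                                   n_individuals=n_individuals, theta=theta,
                                   n_pairs=n_pairs, **config_kwargs)
        )
        pairs = make_matched_pairs(obs_cohort, (), n_pairs, seed=seed)
        res = conditional_logistic(pairs)
        ewas_log_or, ewas_se = res.log_or, res.se

    return ConfoundedNullReplicate(
        seed=seed, ivw=ivw, ewas_log_or=ewas_log_or, ewas_se=ewas_se
    )
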