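"""Fixed-effects meta-analysis and related summary machinery.

Implements inverse-variance-weighted pooling across studies, Cochran's Q /
I-squared heterogeneity, Benjamini-Hochberg FDR control, per-study direction
summaries, and Kruskal-Wallis + Dunn comparison of adjustment models.
Random-effects pooling is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, NumericalError

__all__ = [
    "MetaResult",
    "HeterogeneityResult",
    "ModelComparison",
    "fixed_effects_meta",
    "heterogeneity",
    "bh_fdr",
    "direction_consistency",
    "compare_models",
    "strata_heterogeneity",
]


class HeterogeneityResult(NamedTuple):
    q: float
    df: int
    i2: float
    pval: float


@dataclass
class MetaResult:
    """Pooled fixed-effects estimate across studies.

    ``i2`` is ``max(0, (Q - df) / Q)`` and lives in ``[0, 1)``; heterogeneity
    fields are ``None`` when fewer than two studies contribute.
    """

    estimate: float
    se: float
    pval: float
    weights: np.ndarray
    direction: str
    n_studies: int
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    i2: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)


def _validate(effects, ses) -> tuple[np.ndarray, np.ndarray]:
    effects = np.asarray(effects, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if effects.shape != ses.shape or effects.ndim != 1:
        raise InputError("effects and ses must be 1-D arrays of equal length")
    if effects.size == 0:
        raise InputError("at least one study is required")
    if not (np.isfinite(effects).all() and np.isfinite(ses).all()):
        raise InputError("non-finite effect or SE")
    if (ses <= 0).any():
        raise InputError("standard errors must be positive")
    return effects, ses


def fixed_effects_meta(
    effects: Sequence[float], ses: Sequence[float]
) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling.

    Weights are ``1/se_i**2``; the pooled estimate is the weighted mean and
    the pooled SE is ``(sum of weights)**-0.5``.  With a single study the
    input is returned unchanged (no heterogeneity fields).

    Examples
    --------
    >>> r = fixed_effects_meta([0.5, 0.3], [0.1, 0.2])
    >>> round(r.estimate, 2), round(r.se, 5)
    (0.46, 0.08944)
    """
    effects, ses = _validate(effects, ses)
    w = 1.0 / ses**2
    pooled = float(np.sum(w * effects) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled / pooled_se
    pval = float(2.0 * stats.norm.sf(abs(z)))
    direction, _ = direction_consistency(effects)
    result = MetaResult(
        estimate=pooled,
        se=pooled_se,
        pval=pval,
        weights=w,
        direction=direction,
        n_studies=effects.size,
    )
    if effects.size >= 2:
        het = heterogeneity(effects, ses)
        result.q, result.q_df, result.i2, result.q_pval = het
    return result


def heterogeneity(
    effects: Sequence[float], ses: Sequence[float]
) -> HeterogeneityResult:
    """Cochran's Q, its degrees of freedom, I-squared and chi-square p.

    ``Q = sum_i w_i (b_i - pooled)**2`` with ``w_i = 1/se_i**2``;
    ``I2 = max(0, (Q - df) / Q)``.
    """
    effects, ses = _validate(effects, ses)
    if effects.size < 2:
        raise InputError("heterogeneity requires at least two studies")
    w = 1.0 / ses**2
    pooled = np.sum(w * effects) / np.sum(w)
    q = float(np.sum(w * (effects - pooled) ** 2))
    df = effects.size - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 else 0.0
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, i2=i2, pval=pval)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if not np.isfinite(pvals).all() or (pvals < 0).any() or (pvals > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def direction_consistency(effects: Sequence[float]) -> tuple[str, bool]:
    """Per-study sign glyphs and an all-same-direction flag.

    Glyphs are ``+``, ``-`` and ``0``; exact zeros are sign-neutral and do
    not break consistency (documented convention).
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        raise InputError("at least one study is required")
    glyphs = "".join("+" if b > 0 else "-" if b < 0 else "0" for b in effects)
    signs = {g for g in glyphs if g != "0"}
    return glyphs, len(signs) <= 1


@dataclass
class ModelComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise post-hoc comparison."""

    h: float
    pval: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, pval, pval_adj
    group_names: list[str] = field(default_factory=list)


def compare_models(groups: Mapping[str, Sequence[float]]) -> ModelComparison:
    """Compare effect-size distributions across adjustment models.

    Kruskal-Wallis H (tie-corrected, via :func:`scipy.stats.kruskal`) plus
    Dunn's z on mean ranks with Bonferroni-adjusted pairwise p-values.

    Raises
    ------
    NumericalError
        If every value in every group is identical (H undefined under the
        tie correction).
    """
    names = list(groups)
    samples = [np.asarray(groups[name], dtype=float) for name in names]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise InputError("need >=2 groups with >=1 value each")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise NumericalError("all values identical: H undefined under tie correction")
    h, pval = stats.kruskal(*samples)

    # Dunn: mean ranks on the pooled sample, tie-corrected variance.
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    bounds = np.cumsum([0] + [s.size for s in samples])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(samples))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    n_pairs = len(list(combinations(range(len(samples)), 2)))
    for i, j in combinations(range(len(samples)), 2):
        var_ij = base_var * (1.0 / samples[i].size + 1.0 / samples[j].size)
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var_ij)
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "z": z,
                "pval": p_raw,
                "pval_adj": min(1.0, p_raw * n_pairs),
            }
        )
    return ModelComparison(
        h=float(h), pval=float(pval), pairwise=pd.DataFrame(rows), group_names=names
    )


def strata_heterogeneity(results: Sequence[MetaResult]) -> HeterogeneityResult:
    """Heterogeneity across stratum-level pooled estimates.

    Applies the same Q machinery used across studies to the pooled
    (estimate, se) of each stratum, e.g. never/former/current smokers.
    """
    if len(results) < 2:
        raise InputError("need >=2 strata")
    effects = [r.estimate for r in results]
    ses = [r.se for r in results]
    return heterogeneity(effects, ses)
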