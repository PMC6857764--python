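"""One-sample Mendelian randomization with individual-level data.

Allele-score instrument construction, score-exposure strength, confounder
balance checks, and two-stage Cox estimation of the hazard ratio per SD of
methylation, with smoking-stratified runs and across-strata heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .exceptions import ConvergenceError, InputError, NoInformationError
from .instruments import instrument_strength
from .meta_analysis import HeterogeneityResult, heterogeneity

__all__ = [
    "AlleleScore",
    "build_allele_score",
    "score_exposure",
    "confounder_balance",
    "two_stage_cox",
    "stratified_two_stage_cox",
]


@dataclass
class AlleleScore:
    """Weighted count of methylation-increasing alleles per individual."""

    values: np.ndarray
    snp_ids: list[str]
    weights: np.ndarray  # oriented (non-negative) weights actually applied
    flipped: np.ndarray  # bool per SNP: coded allele reflected (d -> 2 - d)
    kept: np.ndarray  # bool per individual: had complete dosages

    @property
    def n(self) -> int:
        return len(self.values)


def build_allele_score(
    genotypes: np.ndarray | pd.DataFrame,
    weights: Sequence[float],
    snp_ids: Sequence[str] | None = None,
    weighted: bool = True,
) -> AlleleScore:
    """Per-individual allele score oriented toward higher methylation.

    Each SNP whose weight (exposure effect) is negative has its dosage
    reflected (``2 - d``) and its weight negated, so every applied weight is
    non-negative and the score increases with predicted methylation.  In
    unweighted mode the applied weights are all 1 after orientation, so the
    score is a plain count in ``[0, 2 * n_snps]``.  Individuals with any
    missing dosage are dropped (``kept`` records who survived).
    """
    if isinstance(genotypes, pd.DataFrame):
        if snp_ids is None:
            snp_ids = list(genotypes.columns)
        g = genotypes.to_numpy(dtype=float)
    else:
        g = np.asarray(genotypes, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp_{i}" for i in range(g.shape[1])]
    w = np.asarray(weights, dtype=float)
    if g.ndim != 2 or g.shape[1] != w.size:
        raise InputError("dosage matrix and weights are misaligned")

    kept = ~np.isnan(g).any(axis=1)
    g = g[kept]
    flipped = w < 0
    g_oriented = np.where(flipped[None, :], 2.0 - g, g)
    applied = np.abs(w) if weighted else np.ones_like(w)
    values = g_oriented @ applied
    return AlleleScore(
        values=values,
        snp_ids=list(snp_ids),
        weights=applied,
        flipped=flipped,
        kept=kept,
    )


@dataclass
class ScoreExposureResult:
    """Score-methylation regression: effect per allele-score unit."""

    beta_pct: float  # percentage points of methylation per score unit
    se_pct: float
    beta_sd: float  # SD units per score unit
    se_sd: float
    pval: float
    r2: float
    f_stat: float
    n: int


def score_exposure(score: np.ndarray, methylation: np.ndarray) -> ScoreExposureResult:
    """Linear regression of methylation on the allele score.

    Reports the slope on percentage-point and SD scales, with r2 and F via
    the same t-statistic identities used for summary-level instruments.
    """
    score = np.asarray(score, dtype=float)
    meth = np.asarray(methylation, dtype=float)
    if score.size != meth.size or score.size < 3:
        raise InputError("need >=3 aligned individuals")
    if score.std() == 0:
        raise NoInformationError("constant allele score")
    fit_pct = stats.linregress(score, meth * 100.0)
    sd = meth.std(ddof=1)
    z = (meth - meth.mean()) / sd
    fit_sd = stats.linregress(score, z)
    r2, f_stat = instrument_strength(fit_sd.slope, fit_sd.stderr, score.size)
    return ScoreExposureResult(
        beta_pct=float(fit_pct.slope),
        se_pct=float(fit_pct.stderr),
        beta_sd=float(fit_sd.slope),
        se_sd=float(fit_sd.stderr),
        pval=float(fit_sd.pvalue),
        r2=r2,
        f_stat=f_stat,
        n=int(score.size),
    )


@dataclass
class BalanceReport:
    table: pd.DataFrame  # confounder, kind, effect, se, pval
    min_pval: float | None


def confounder_balance(
    score: np.ndarray, confounders: pd.DataFrame
) -> BalanceReport:
    """Association of each potential confounder with the allele score.

    Each confounder is regressed on the score: logistic regression for
    binary variables, ordinary least squares otherwise.  Categorical
    variables are factorised to integer codes first.  Reports per-confounder
    effect, SE and p, plus the minimum p across the table.
    """
    score = np.asarray(score, dtype=float)
    rows = []
    x = sm.add_constant(score)
    for name in confounders.columns:
        y = confounders[name]
        if not pd.api.types.is_numeric_dtype(y):
            y = pd.factorize(y, sort=True)[0]
        y = np.asarray(y, dtype=float)
        binary = len(np.unique(y)) == 2
        try:
            if binary:
                y01 = (y == y.max()).astype(float)
                fit = sm.Logit(y01, x).fit(disp=0)
            else:
                fit = sm.OLS(y, x).fit()
            rows.append(
                {"confounder": name, "kind": "logistic" if binary else "linear",
                 "effect": float(fit.params[1]), "se": float(fit.bse[1]),
                 "pval": float(fit.pvalues[1])}
            )
        except Exception as err:
            rows.append({"confounder": name, "kind": "failed", "effect": np.nan,
                         "se": np.nan, "pval": np.nan})
    table = pd.DataFrame(rows, columns=["confounder", "kind", "effect", "se", "pval"])
    min_p = float(table["pval"].min()) if len(table) and table["pval"].notna().any() else None
    return BalanceReport(table=table, min_pval=min_p)


@dataclass
class TwoStageCoxResult:
    """Hazard ratio per SD of methylation from two-stage Cox regression."""

    log_hr: float
    se_naive: float
    ci_naive: tuple[float, float]
    n: int
    n_events: int
    converged: bool
    se_boot: float | None = None
    ci_boot: tuple[float, float] | None = None
    n_boot: int = 0

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        """Preferred CI: bootstrap when available, else naive Wald."""
        return self.ci_boot if self.ci_boot is not None else self.ci_naive


def _two_stage_fit(
    data: pd.DataFrame, adjust: Sequence[str], meth_sd: float
) -> tuple[float, float, bool]:
    """One two-stage fit; returns (log HR per SD, naive SE, converged)."""
    covs = list(adjust)
    x1 = sm.add_constant(data[["score", *covs]].to_numpy(dtype=float))
    z = data["methylation"].to_numpy(dtype=float) / meth_sd
    coef, *_ = np.linalg.lstsq(x1, z, rcond=None)
    fitted = x1 @ coef

    cox_df = pd.DataFrame({"time": data["time"], "event": data["event"],
                           "fitted_meth": fitted})
    for c in covs:
        cox_df[c] = data[c].to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(cox_df, duration_col="time", event_col="event")
    except Exception as err:
        raise ConvergenceError(f"partial-likelihood fit failed: {err}") from err
    return (
        float(cph.params_["fitted_meth"]),
        float(cph.standard_errors_["fitted_meth"]),
        True,
    )


def two_stage_cox(
    data: pd.DataFrame,
    adjust: Sequence[str] = ("age", "sex"),
    n_boot: int = 500,
    seed: int = 0,
) -> TwoStageCoxResult:
    """Two-stage Cox MR: allele score -> fitted methylation -> hazard.

    Stage 1 regresses SD-unit methylation on the allele score plus
    adjustment covariates; stage 2 fits a proportional-hazards model of the
    outcome on the stage-1 fitted values plus the same covariates.  The
    naive model-based SE ignores stage-1 uncertainty (reported with that
    caveat); the preferred interval is a seeded nonparametric bootstrap over
    individuals (percentile CI), skipped when ``n_boot=0``.

    ``data`` needs columns time, event, score, methylation and the
    adjustment covariates; requires >= 10 events.
    """
    required = {"time", "event", "score", "methylation", *adjust}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"survival table missing columns: {sorted(missing)}")
    if (data["time"] <= 0).any():
        raise InputError("follow-up times must be positive")
    n_events = int(data["event"].sum())
    if n_events == 0:
        raise InputError("no events: hazard model undefined")
    if n_events < 10:
        raise InputError(f"too few events ({n_events} < 10)")

    meth_sd = float(data["methylation"].std(ddof=1))
    log_hr, se_naive, converged = _two_stage_fit(data, adjust, meth_sd)
    ci_naive = (log_hr - 1.96 * se_naive, log_hr + 1.96 * se_naive)

    se_boot = ci_boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(data)
        estimates = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sample = data.iloc[idx].reset_index(drop=True)
            if sample["event"].sum() < 2:
                continue
            try:
                b, _, _ = _two_stage_fit(sample, adjust, meth_sd)
            except ConvergenceError:
                continue
            estimates.append(b)
        if len(estimates) >= max(10, n_boot // 2):
            estimates = np.asarray(estimates)
            se_boot = float(estimates.std(ddof=1))
            ci_boot = tuple(np.quantile(estimates, [0.025, 0.975]))

    return TwoStageCoxResult(
        log_hr=log_hr,
        se_naive=se_naive,
        ci_naive=ci_naive,
        n=len(data),
        n_events=n_events,
        converged=converged,
        se_boot=se_boot,
        ci_boot=ci_boot,
        n_boot=n_boot,
    )


@dataclass
class StratifiedCoxResult:
    per_stratum: dict[str, TwoStageCoxResult | None]
    het: HeterogeneityResult | None


def stratified_two_stage_cox(
    data: pd.DataFrame,
    stratum: str = "smoking",
    adjust: Sequence[str] = ("age", "sex"),
    n_boot: int = 0,
    seed: int = 0,
) -> StratifiedCoxResult:
    """Independent two-stage Cox fits per stratum plus across-strata Q.

    Strata that fail the two-stage preconditions (too few events, constant
    score) are reported as ``None``; heterogeneity uses the naive SEs of the
    strata that fitted.
    """
    if stratum not in data.columns:
        raise InputError(f"unknown stratum variable {stratum!r}")
    out: dict[str, TwoStageCoxResult | None] = {}
    for level in sorted(data[stratum].unique(), key=str):
        subset = data[data[stratum] == level].reset_index(drop=True)
        try:
            out[str(level)] = two_stage_cox(subset, adjust=adjust,
                                            n_boot=n_boot, seed=seed)
        except (InputError, NoInformationError, ConvergenceError):
            out[str(level)] = None
    fitted = [r for r in out.values() if r is not None]
    het = None
    if len(fitted) >= 2:
        het = heterogeneity(
            [r.log_hr for r in fitted], [r.se_naive for r in fitted]
        )
    return StratifiedCoxResult(per_stratum=out, het=het)
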