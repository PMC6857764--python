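"""Matched-pair EWAS and tissue comparison.

Per-CpG methylation-disease associations from 1:1 matched case-control pairs
via conditional logistic regression, plus the covariate machinery used around
it: residual-PC surrogate variables, reference-based cell-proportion
estimation, smoking-stratified runs and the paired tumour/normal comparison.

Effect sizes are reported as odds ratios per SD increase in methylation on
the beta-value scale; tissue tests are run on M-values (logit2 of beta) for
variance stabilisation, with the beta-scale mean difference reported
alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .exceptions import ConvergenceError, InputError, NoInformationError
from .meta_analysis import bh_fdr

__all__ = [
    "MatchedPairSet",
    "EwasResult",
    "conditional_logistic",
    "ewas_scan",
    "surrogate_variables",
    "estimate_cell_proportions",
    "stratified_ewas",
    "paired_tissue_difference",
    "beta_to_m",
    "m_to_beta",
]

_BETA_EPS = 1e-6


def beta_to_m(beta: np.ndarray) -> np.ndarray:
    """logit2 transform; beta values clipped away from {0, 1}."""
    b = np.clip(np.asarray(beta, dtype=float), _BETA_EPS, 1.0 - _BETA_EPS)
    return np.log2(b / (1.0 - b))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse logit2: ``2**m / (2**m + 1)``."""
    return expit(np.asarray(m, dtype=float) * np.log(2.0))


@dataclass
class MatchedPairSet:
    """1:1 matched case-control pairs.

    Methylation is stored pairs x CpGs (beta values); covariates pairs x
    variables.  Exactly one case and one control per pair, no individual in
    two pairs — enforced upstream by the matcher.
    """

    pair_id: np.ndarray
    case_methylation: pd.DataFrame
    control_methylation: pd.DataFrame
    case_covariates: pd.DataFrame
    control_covariates: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.pair_id)
        for frame in (
            self.case_methylation,
            self.control_methylation,
            self.case_covariates,
            self.control_covariates,
        ):
            if len(frame) != n:
                raise InputError("pair tables must all have one row per pair")
        if list(self.case_methylation.columns) != list(self.control_methylation.columns):
            raise InputError("case and control methylation must share CpG columns")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_id)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.case_methylation.columns)

    def stratum_labels(self, name: str) -> pd.Series:
        """Pair-level stratum labels (taken from the case's covariate)."""
        if name not in self.case_covariates.columns:
            raise InputError(f"unknown stratum variable {name!r}")
        return self.case_covariates[name]

    def subset(self, mask: np.ndarray) -> "MatchedPairSet":
        mask = np.asarray(mask, dtype=bool)
        return MatchedPairSet(
            pair_id=self.pair_id[mask],
            case_methylation=self.case_methylation.loc[mask].reset_index(drop=True),
            control_methylation=self.control_methylation.loc[mask].reset_index(drop=True),
            case_covariates=self.case_covariates.loc[mask].reset_index(drop=True),
            control_covariates=self.control_covariates.loc[mask].reset_index(drop=True),
            n_dropped=self.n_dropped,
        )


@dataclass
class EwasResult:
    """Per-CpG conditional-logistic estimate, log-OR per SD of methylation."""

    cpg_id: str
    log_or: float
    se: float
    pval: float
    n_pairs: int
    n_informative: int
    model: str = "basic"
    stratum: str | None = None
    diverged: bool = False

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.log_or))


def _pair_design(
    pairs: MatchedPairSet,
    cpg: str | None,
    covariates: Sequence[str],
    standardize: bool,
) -> tuple[str, np.ndarray]:
    """Within-pair (case - control) difference matrix, exposure first."""
    cpgs = pairs.cpg_ids
    if cpg is None:
        if len(cpgs) != 1:
            raise InputError("cpg must be named when the pair set has several CpGs")
        cpg = cpgs[0]
    if cpg not in cpgs:
        raise InputError(f"unknown CpG {cpg!r}")
    case_x = pairs.case_methylation[cpg].to_numpy(dtype=float)
    ctrl_x = pairs.control_methylation[cpg].to_numpy(dtype=float)
    if standardize:
        pooled = np.concatenate([case_x, ctrl_x])
        sd = pooled.std(ddof=1)
        if sd > 0:
            case_x = case_x / sd
            ctrl_x = ctrl_x / sd
    cols = [case_x - ctrl_x]
    for cov in covariates:
        if cov not in pairs.case_covariates.columns:
            raise InputError(f"unknown covariate {cov!r}")
        cols.append(
            pairs.case_covariates[cov].to_numpy(dtype=float)
            - pairs.control_covariates[cov].to_numpy(dtype=float)
        )
    return cpg, np.column_stack(cols)


def _fit_pair_likelihood(d: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Newton maximisation of the 1:1 conditional likelihood.

    The log-likelihood is ``sum_i log sigma(d_i' beta)`` where ``d_i`` is the
    case-minus-control covariate difference of pair i — identical to
    intercept-free logistic regression on the differences with all outcomes 1.
    Returns (beta, covariance, diverged flag).
    """
    n, p = d.shape
    beta = np.zeros(p)
    diverged = False
    for _ in range(max_iter):
        eta = d @ beta
        mu = expit(eta)
        score = d.T @ (1.0 - mu)
        w = mu * (1.0 - mu)
        info = d.T @ (d * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise NoInformationError(f"singular information matrix: {err}") from err
        beta = beta + step
        if np.abs(beta).max() > 25.0:
            diverged = True  # separation: likelihood maximised at infinity
            break
        if np.abs(step).max() < tol:
            break
    else:
        diverged = True
    eta = d @ beta
    w = expit(eta) * expit(-eta)
    info = d.T @ (d * w[:, None])
    cov = np.linalg.inv(info)
    return beta, cov, diverged


def conditional_logistic(
    pairs: MatchedPairSet,
    covariates: Sequence[str] = (),
    cpg: str | None = None,
    standardize: bool = True,
    model: str = "basic",
    stratum: str | None = None,
) -> EwasResult:
    """Conditional logistic regression of case status on methylation.

    Maximises the 1:1 conditional likelihood
    ``prod exp(x_case b) / (exp(x_case b) + exp(x_ctrl b))`` by Newton
    iteration on within-pair differences.  The methylation exposure is scaled
    to SD units (pooled over cases and controls) before fitting unless
    ``standardize=False``, so the leading coefficient is a log-OR per SD.

    Raises
    ------
    NoInformationError
        If every within-pair difference is zero.
    """
    cpg, d = _pair_design(pairs, cpg, covariates, standardize)
    informative = np.any(d != 0, axis=1)
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise NoInformationError(
            f"{cpg}: all within-pair differences are zero; the conditional "
            "likelihood carries no information"
        )
    beta, cov, diverged = _fit_pair_likelihood(d[informative])
    se = float(np.sqrt(cov[0, 0]))
    z = beta[0] / se
    return EwasResult(
        cpg_id=cpg,
        log_or=float(beta[0]),
        se=se,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_pairs=pairs.n_pairs,
        n_informative=n_informative,
        model=model,
        stratum=stratum,
        diverged=diverged,
    )


def ewas_scan(
    pairs: MatchedPairSet,
    covariates: Sequence[str] = (),
    model: str = "basic",
) -> list[EwasResult]:
    """Run :func:`conditional_logistic` for every CpG column."""
    return [
        conditional_logistic(pairs, covariates=covariates, cpg=cpg, model=model)
        for cpg in pairs.cpg_ids
    ]


def surrogate_variables(
    methylation: np.ndarray | pd.DataFrame,
    protected: np.ndarray | None = None,
    k: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual principal components as surrogate variables.

    The methylation matrix (samples x probes) is residualised on the
    protected model (an intercept is always included), then the top ``k``
    left singular vectors of the residual are returned as orthonormal
    sample-level components, ordered by variance explained.

    This is a defined stand-in for iterative surrogate-variable estimation:
    it keeps the testable contract (capture structure not in the protected
    model) without the full algorithm.

    Returns
    -------
    components : ndarray, shape (samples, k)
    variance_explained : ndarray, shape (k,)
        Fraction of residual variance per component.
    """
    m = np.asarray(methylation, dtype=float)
    if m.ndim != 2:
        raise InputError("methylation must be a 2-D samples x probes matrix")
    n_samples, n_probes = m.shape
    if k <= 0:
        raise InputError("k must be positive")
    if k >= min(n_samples, n_probes):
        raise InputError("k must be < min(samples, probes)")
    design = np.ones((n_samples, 1))
    if protected is not None:
        protected = np.atleast_2d(np.asarray(protected, dtype=float))
        if protected.shape[0] != n_samples:
            protected = protected.T
        design = np.hstack([design, protected])
    coef, *_ = np.linalg.lstsq(design, m, rcond=None)
    resid = m - design @ coef
    total_var = float(np.sum(resid**2))
    if total_var < 1e-12:
        raise NoInformationError("no residual variance: surrogate variables undefined")
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    var_explained = s[:k] ** 2 / np.sum(s**2)
    return u[:, :k], var_explained


def estimate_cell_proportions(
    profile: np.ndarray,
    reference: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, dict]:
    """Reference-based cell-type deconvolution of one methylation profile.

    Solves ``min || R p - y ||^2`` subject to ``p >= 0`` and ``sum(p) = 1``
    (constrained least squares, SLSQP), where R is the CpGs x cell-types
    reference matrix and y the sample profile over the same CpGs.

    Returns the proportion vector and an info dict with the residual norm
    and a ``rank_deficient`` flag.
    """
    if isinstance(reference, pd.DataFrame):
        ref = reference.to_numpy(dtype=float)
        cell_types = list(reference.columns)
    else:
        ref = np.asarray(reference, dtype=float)
        cell_types = [f"cell_{i}" for i in range(ref.shape[1])]
    y = np.asarray(profile, dtype=float)
    if y.shape[0] != ref.shape[0]:
        raise InputError("reference must cover the sample's probes")
    n_types = ref.shape[1]
    rank_deficient = np.linalg.matrix_rank(ref) < n_types
    if rank_deficient:
        warnings.warn("rank-deficient reference matrix; proportions not unique")

    def objective(p):
        r = ref @ p - y
        return 0.5 * float(r @ r), ref.T @ r

    x0 = np.full(n_types, 1.0 / n_types)
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n_types,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise ConvergenceError(f"cell-proportion solver failed: {res.message}")
    props = np.clip(res.x, 0.0, None)
    props = props / props.sum()
    info = {
        "cell_types": cell_types,
        "residual_norm": float(np.linalg.norm(ref @ props - y)),
        "rank_deficient": bool(rank_deficient),
    }
    return props, info


def stratified_ewas(
    pairs: MatchedPairSet,
    stratum: str,
    covariates: Sequence[str] = (),
    cpg: str | None = None,
) -> dict[str, EwasResult | None]:
    """Independent conditional-logistic fits per stratum.

    Strata whose pairs carry no information (all differences zero, or the
    stratum is empty) are reported as ``None`` rather than dropped silently.
    """
    labels = pairs.stratum_labels(stratum)
    out: dict[str, EwasResult | None] = {}
    for level in sorted(pd.unique(labels), key=str):
        mask = (labels == level).to_numpy()
        subset = pairs.subset(mask)
        if subset.n_pairs == 0:
            out[str(level)] = None
            continue
        try:
            out[str(level)] = conditional_logistic(
                subset,
                covariates=covariates,
                cpg=cpg,
                stratum=str(level),
                model="stratified",
            )
        except NoInformationError:
            out[str(level)] = None
    return out


def paired_tissue_difference(
    tumour: pd.DataFrame,
    normal: pd.DataFrame,
) -> pd.DataFrame:
    """Paired tumour-minus-normal methylation comparison per CpG.

    Input matrices are CpGs x subjects (beta values) with identical subject
    sets.  The test is a paired t-test on M-values; the beta-scale mean
    difference is reported alongside, and BH-FDR is applied across CpGs.
    Positive differences mean higher methylation in tumour.
    """
    if sorted(tumour.columns) != sorted(normal.columns):
        raise InputError("tumour and normal matrices must share subject columns")
    if list(tumour.index) != list(normal.index):
        raise InputError("tumour and normal matrices must share CpG rows")
    normal = normal[tumour.columns]
    if tumour.shape[1] < 3:
        raise InputError("need at least 3 subject pairs")

    t_beta = tumour.to_numpy(dtype=float)
    n_beta = normal.to_numpy(dtype=float)
    t_m = beta_to_m(t_beta)
    n_m = beta_to_m(n_beta)
    diff_m = t_m - n_m

    rows = []
    for i, cpg in enumerate(tumour.index):
        d = diff_m[i]
        sd = d.std(ddof=1)
        if sd == 0.0:
            # degenerate: identical pairs (p=1) or an exactly constant shift
            stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
            p = 1.0 if d.mean() == 0 else 0.0
        else:
            stat, p = stats.ttest_rel(t_m[i], n_m[i])
        rows.append(
            {
                "cpg_id": cpg,
                "mean_diff_beta": float((t_beta[i] - n_beta[i]).mean()),
                "mean_diff_m": float(d.mean()),
                "t": float(stat),
                "pval": float(p),
                "n_pairs": tumour.shape[1],
            }
        )
    out = pd.DataFrame(rows).set_index("cpg_id")
    out["fdr"] = bh_fdr(out["pval"].to_numpy())
    return out
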