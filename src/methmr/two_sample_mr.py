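"""Two-sample Mendelian randomization.

Harmonization of exposure and outcome summary statistics onto a shared
effect allele, Wald ratios with delta-method standard errors, fixed-effects
inverse-variance-weighted combination with Cochran's Q across instruments,
MR-Egger regression, a correlated-instrument IVW variant, Z tests for
subgroup differences, and a-priori power for a binary outcome.

Estimates are log odds ratios of disease per SD-unit increase in
methylation; OR rendering happens at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import InputError, NumericalError
from .meta_analysis import fixed_effects_meta, heterogeneity
from .records import AssociationRecord

__all__ = [
    "HarmonizedInstrument",
    "MRResult",
    "harmonize",
    "wald_ratio",
    "ivw_combine",
    "mr_egger",
    "ivw_correlated",
    "z_difference",
    "mr_power",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindromic SNPs with effect-allele frequency in this open interval are
#: strand-ambiguous and dropped by default
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)


def _complement_allele(a: str) -> str | None:
    return _COMPLEMENT.get(a.upper())


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement_allele(a1) == a2.upper()


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects expressed for the same effect allele."""

    snp_id: str
    beta_gp: float  # exposure: SD methylation per effect allele
    se_gp: float
    beta_gd: float  # outcome: log-odds per effect allele
    se_gd: float
    effect_allele: str
    other_allele: str
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    palindromic: bool = False


@dataclass
class MRResult:
    """A causal estimate: log-OR of disease per SD increase in methylation."""

    method: str  # wald | ivw | egger | ivw_correlated
    estimate: float
    se: float
    pval: float
    n_instruments: int
    snp_id: str | None = None
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    ambiguous_eaf_window: tuple[float, float] = AMBIGUOUS_EAF_WINDOW,
    drop_palindromic: bool | None = None,
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Align outcome records to the exposure's effect allele.

    For each SNP present on both sides: if the outcome codes the other
    allele, the outcome effect sign is flipped (and its EAF reflected);
    strand flips are resolved through the allele complement.  Palindromic
    SNPs (A/T, C/G) cannot be resolved through allele letters; they are
    oriented by allele-frequency agreement, and dropped when either
    frequency falls in the ambiguous window (or is missing).  Irreconcilable
    allele pairs are dropped.  Every action is logged as ``(snp_id, action)``
    and the procedure is idempotent.
    """
    lo, hi = ambiguous_eaf_window
    exp_by_snp = {r.snp_id: r for r in exposure}
    out_by_snp = {r.snp_id: r for r in outcome}
    instruments: list[HarmonizedInstrument] = []
    log: list[tuple[str, str]] = []

    for snp_id, e in exp_by_snp.items():
        o = out_by_snp.get(snp_id)
        if o is None:
            log.append((snp_id, "dropped: absent from outcome"))
            continue
        if not (e.is_usable and o.is_usable):
            log.append((snp_id, "dropped: unusable record"))
            continue
        ea_e, oa_e = e.effect_allele, e.other_allele
        ea_o, oa_o = o.effect_allele, o.other_allele
        beta_gd, eaf_o = o.beta, o.eaf

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                log.append((snp_id, "dropped: incompatible alleles"))
                continue
            ambiguous = (
                e.eaf is None
                or eaf_o is None
                or lo < e.eaf < hi
                or lo < eaf_o < hi
            )
            if ambiguous:
                log.append((snp_id, "dropped: palindromic with ambiguous frequency"))
                continue
            # orient purely by frequency agreement
            flip = (e.eaf - 0.5) * (eaf_o - 0.5) < 0
            if ea_o != ea_e:
                # letters swapped; frequency refers to the swapped allele
                eaf_o = 1.0 - eaf_o
                beta_gd = -beta_gd
                flip = (e.eaf - 0.5) * (eaf_o - 0.5) < 0
            if flip:
                beta_gd = -beta_gd
                eaf_o = 1.0 - eaf_o
                log.append((snp_id, "flipped: palindromic oriented by frequency"))
            else:
                log.append((snp_id, "kept: palindromic oriented by frequency"))
            instruments.append(
                HarmonizedInstrument(
                    snp_id=snp_id, beta_gp=e.beta, se_gp=e.se,
                    beta_gd=beta_gd, se_gd=o.se,
                    effect_allele=ea_e, other_allele=oa_e,
                    eaf_exposure=e.eaf, eaf_outcome=eaf_o, palindromic=True,
                )
            )
            continue

        action = None
        if (ea_o, oa_o) == (ea_e, oa_e):
            action = "kept: alleles aligned"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_gd = -beta_gd
            eaf_o = None if eaf_o is None else 1.0 - eaf_o
            action = "flipped: effect alleles swapped"
        else:
            ca, cb = _complement_allele(ea_o), _complement_allele(oa_o)
            if ca is None or cb is None:
                action = None
            elif (ca, cb) == (ea_e, oa_e):
                action = "kept: strand flip resolved"
            elif (ca, cb) == (oa_e, ea_e):
                beta_gd = -beta_gd
                eaf_o = None if eaf_o is None else 1.0 - eaf_o
                action = "flipped: strand flip with swapped alleles"
        if action is None:
            log.append((snp_id, "dropped: incompatible alleles"))
            continue
        log.append((snp_id, action))
        instruments.append(
            HarmonizedInstrument(
                snp_id=snp_id, beta_gp=e.beta, se_gp=e.se,
                beta_gd=beta_gd, se_gd=o.se,
                effect_allele=ea_e, other_allele=oa_e,
                eaf_exposure=e.eaf, eaf_outcome=eaf_o, palindromic=False,
            )
        )
    return instruments, log


def _ratio_and_se(
    h: HarmonizedInstrument, second_order: bool, exposure_uncertainty: bool = True
) -> tuple[float, float]:
    if h.beta_gp == 0:
        raise NumericalError(f"{h.snp_id}: beta_GP is zero, Wald ratio undefined")
    est = h.beta_gd / h.beta_gp
    # first-order delta variance; written so the beta_GD -> 0 limit is
    # se_GD / |beta_GP| rather than 0 * inf
    var = h.se_gd**2 / h.beta_gp**2
    if exposure_uncertainty:
        var += h.beta_gd**2 * h.se_gp**2 / h.beta_gp**4
        if second_order:
            var += h.se_gd**2 * h.se_gp**2 / h.beta_gp**4
    return float(est), float(math.sqrt(var))


def wald_ratio(
    h: HarmonizedInstrument,
    second_order: bool = False,
    exposure_uncertainty: bool = True,
) -> MRResult:
    """Single-instrument causal estimate ``beta_GD / beta_GP``.

    The default SE is the first-order delta approximation
    ``|est| * sqrt(se_GD^2/beta_GD^2 + se_GP^2/beta_GP^2)``; the
    ``second_order`` flag adds the cross term
    ``se_GD^2 se_GP^2 / beta_GP^4`` to the variance.
    ``exposure_uncertainty=False`` gives the common simplification
    ``se_GD / |beta_GP|``.
    """
    est, se = _ratio_and_se(h, second_order, exposure_uncertainty)
    z = est / se
    return MRResult(
        method="wald",
        estimate=est,
        se=se,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=1,
        snp_id=h.snp_id,
    )


def ivw_combine(results: Sequence[MRResult]) -> MRResult:
    """Fixed-effects inverse-variance combination of Wald ratios.

    Reuses the meta-analysis pooling arithmetic and attaches Cochran's Q
    across ratios when two or more instruments contribute.  A single input
    is passed through unchanged.
    """
    if len(results) == 0:
        raise InputError("at least one ratio is required")
    if len(results) == 1:
        return replace(results[0])
    effects = [r.estimate for r in results]
    ses = [r.se for r in results]
    pooled = fixed_effects_meta(effects, ses)
    return MRResult(
        method="ivw",
        estimate=pooled.estimate,
        se=pooled.se,
        pval=pooled.pval,
        n_instruments=len(results),
        q=pooled.q,
        q_df=pooled.q_df,
        q_pval=pooled.q_pval,
    )


def mr_egger(harmonized: Sequence[HarmonizedInstrument]) -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure effects.

    Instruments are oriented so every exposure effect is positive
    (sign-flipping both effects of negative pairs), then ``beta_GD`` is
    regressed on ``beta_GP`` with a free intercept and weights
    ``1/se_GD^2``.  The intercept estimates average directional pleiotropy;
    the slope is the causal estimate.
    """
    if len(harmonized) < 3:
        raise InputError("MR-Egger needs at least 3 instruments")
    bx = np.array([h.beta_gp for h in harmonized], dtype=float)
    by = np.array([h.beta_gd for h in harmonized], dtype=float)
    se_y = np.array([h.se_gd for h in harmonized], dtype=float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    model = sm.WLS(by, sm.add_constant(bx), weights=1.0 / se_y**2).fit()
    slope, intercept = float(model.params[1]), float(model.params[0])
    se_slope, se_intercept = float(model.bse[1]), float(model.bse[0])
    return MRResult(
        method="egger",
        estimate=slope,
        se=se_slope,
        pval=float(model.pvalues[1]),
        n_instruments=len(harmonized),
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_pval=float(model.pvalues[0]),
    )


def ivw_correlated(
    harmonized: Sequence[HarmonizedInstrument],
    rho: pd.DataFrame | np.ndarray,
    second_order: bool = False,
    exposure_uncertainty: bool = True,
) -> MRResult:
    """IVW accounting for LD correlation between instruments.

    Generalised least squares of the Wald ratios on a constant with
    covariance ``Omega_ij = se_i * se_j * rho_ij`` built from the per-ratio
    delta SEs: ``est = 1' Omega^-1 r / 1' Omega^-1 1`` and
    ``se = (1' Omega^-1 1)^-1/2``.  With ``rho`` the identity this reduces
    exactly to :func:`ivw_combine`.

    Raises
    ------
    NumericalError
        If ``rho`` is not positive definite (eigenvalues reported).
    """
    if len(harmonized) == 0:
        raise InputError("at least one instrument is required")
    snp_ids = [h.snp_id for h in harmonized]
    if isinstance(rho, pd.DataFrame):
        rho_m = rho.loc[snp_ids, snp_ids].to_numpy(dtype=float)
    else:
        rho_m = np.asarray(rho, dtype=float)
    if rho_m.shape != (len(snp_ids), len(snp_ids)):
        raise InputError("rho must cover the instrument set")
    eig = np.linalg.eigvalsh(rho_m)
    if eig.min() <= 0:
        raise NumericalError(
            f"correlation matrix not positive definite; eigenvalues: {np.sort(eig)}"
        )
    ratios, ses = zip(
        *(_ratio_and_se(h, second_order, exposure_uncertainty) for h in harmonized)
    )
    r = np.asarray(ratios)
    s = np.asarray(ses)
    omega = np.outer(s, s) * rho_m
    omega_inv = np.linalg.inv(omega)
    ones = np.ones_like(r)
    denom = ones @ omega_inv @ ones
    est = float(ones @ omega_inv @ r / denom)
    se = float(denom**-0.5)
    z = est / se
    return MRResult(
        method="ivw_correlated",
        estimate=est,
        se=se,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(harmonized),
    )


def z_difference(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Z test for a difference between two independent estimates."""
    if se1 <= 0 or se2 <= 0:
        raise InputError("standard errors must be positive")
    z = (b1 - b2) / math.sqrt(se1**2 + se2**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def mr_power(
    n_cases: int,
    n_controls: int,
    r2: float,
    or_per_sd: float,
    alpha: float = 0.05,
) -> float:
    """A-priori power of two-sample MR with a binary outcome.

    Non-centrality approximation: ``ncp = N K (1-K) r2 (ln OR)^2`` with N
    the total sample size and K the case fraction; power is
    ``Phi(-z_{a/2} + sqrt(ncp)) + Phi(-z_{a/2} - sqrt(ncp))``.  This is an
    approximation — no exact design formula is claimed.
    """
    if not 0 <= r2 < 1:
        raise InputError("r2 must lie in [0, 1)")
    if n_cases <= 0 or n_controls <= 0 or or_per_sd <= 0 or not 0 < alpha < 1:
        raise InputError("invalid power inputs")
    n_total = n_cases + n_controls
    k = n_cases / n_total
    ncp = n_total * k * (1.0 - k) * r2 * math.log(or_per_sd) ** 2
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(-z_crit + root) + stats.norm.cdf(-z_crit - root))
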