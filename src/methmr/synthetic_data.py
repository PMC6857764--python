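"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces individual-level data for one CpG site under a
configurable causal diagram:

* cis-SNPs raise methylation additively on the M-value (logit2) scale;
* a standardised continuous "smoking burden" confounder shifts methylation
  (``gamma``) and disease risk (``delta``) simultaneously;
* an optional true causal effect ``theta`` of methylation (in SD units of
  the beta scale) on disease log-odds;
* optional exponential survival times driven by the same linear predictor.

The central scenario of interest is the confounded null: ``theta = 0`` with
``gamma < 0`` and ``delta > 0``, in which the observational methylation-
disease association departs from the null while genotype-disease effects
stay at zero.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .exceptions import InputError, MatchingError
from .ewas import MatchedPairSet
from .records import AssociationRecord

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "make_matched_pairs",
    "export_summary_stats",
    "beta_gp_for_r2",
    "confounded_null_config",
]

# allele pairs used to label simulated SNPs; none is palindromic so default
# harmonization never drops a simulated instrument
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]

_SMOKING_LEVELS = ["never", "former", "current"]


def _as_array(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise InputError(f"{name} must be a scalar or length-{n} sequence")
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Parameters
    ----------
    n_individuals, n_snps : int
    maf : float or sequence
        Per-SNP effect-allele frequency, each in (0, 1).
    beta_gp : float or sequence
        Per-allele SNP effect on the latent M-value.
    theta : float
        Causal effect of methylation on disease log-odds, per SD of the
        beta-value scale.
    gamma : float
        Confounder effect on methylation (M-value units).
    delta : float
        Confounder effect on disease log-odds.
    base_logodds : float
        Disease-model intercept.
    n_pairs : int
        Matched pairs to draw downstream; must satisfy
        ``n_individuals >= 2 * n_pairs``.
    seed : int
        Single source of randomness; identical seeds give bit-identical
        cohorts.
    survival : bool
        Also draw exponential survival times with log-hazard proportional
        to the same linear predictor.
    """

    n_individuals: int
    n_snps: int
    maf: float | Sequence[float] = 0.3
    beta_gp: float | Sequence[float] = 0.3
    theta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0
    base_logodds: float = -2.0
    n_pairs: int = 0
    seed: int = 0
    survival: bool = False
    log_base_hazard: float = -3.0
    follow_up: float = 15.0
    cpg_id: str = "cpg_1"
    cpg_chrom: str = "5"
    cpg_pos: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_snps < 1:
            raise InputError("need >=2 individuals and >=1 SNP")
        maf = self.maf_array
        if ((maf <= 0) | (maf >= 1)).any():
            raise InputError("maf must lie in (0, 1)")
        for name in ("theta", "gamma", "delta", "base_logodds", "log_base_hazard"):
            if not math.isfinite(getattr(self, name)):
                raise InputError(f"non-finite parameter {name}")
        if not np.isfinite(self.beta_gp_array).all():
            raise InputError("non-finite beta_gp")
        if self.n_individuals < 2 * self.n_pairs:
            raise InputError("n_individuals must be >= 2 * n_pairs")

    @property
    def maf_array(self) -> np.ndarray:
        return _as_array(self.maf, self.n_snps, "maf")

    @property
    def beta_gp_array(self) -> np.ndarray:
        return _as_array(self.beta_gp, self.n_snps, "beta_gp")


@dataclass
class Cohort:
    """One simulated individual-level cohort (single CpG)."""

    genotypes: np.ndarray  # (n, n_snps) dosages in {0, 1, 2}
    snp_info: pd.DataFrame  # snp_id, effect_allele, other_allele, maf, chrom, pos
    confounder: np.ndarray  # standardized smoking burden
    methylation: np.ndarray  # beta values in [0, 1]
    disease: np.ndarray  # 0/1
    covariates: pd.DataFrame  # confounder, smoking, age, sex
    cpg_id: str
    config: SimulationConfig
    time_to_event: np.ndarray | None = None
    event_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        if not (
            len(self.methylation) == len(self.disease) == len(self.confounder) == n
        ):
            raise InputError("cohort arrays have inconsistent lengths")
        if ((self.methylation < 0) | (self.methylation > 1)).any():
            raise InputError("methylation beta values must lie in [0, 1]")
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise InputError("dosages must be 0/1/2")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def methylation_sd(self) -> float:
        return float(self.methylation.std(ddof=1))

    @property
    def methylation_z(self) -> np.ndarray:
        m = self.methylation
        return (m - m.mean()) / m.std(ddof=1)


def beta_gp_for_r2(
    r2: float | Sequence[float],
    maf: float | Sequence[float],
    gamma: float = 0.0,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Per-allele M-value effects giving each SNP a target share of variance.

    With independent SNPs, confounder variance ``gamma**2`` and noise
    variance ``noise_sd**2``, the total M-value variance is
    ``(gamma**2 + noise_sd**2) / (1 - sum(r2))``, and each SNP's effect is
    ``sqrt(r2_i * var_M / (2 maf_i (1 - maf_i)))``.  Used as the analytic
    r2 -> beta oracle in tests.
    """
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if maf.size == 1:
        maf = np.full(r2.size, maf[0])
    total = r2.sum()
    if total >= 1:
        raise InputError("summed r2 must be < 1")
    var_m = (gamma**2 + noise_sd**2) / (1.0 - total)
    var_d = 2.0 * maf * (1.0 - maf)
    return np.sqrt(r2 * var_m / var_d)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort under the configured causal diagram.

    Genotypes are binomial(2, maf); the latent M-value is
    ``sum_j beta_gp_j * dosage_j + gamma * confounder + N(0, 1)``;
    methylation is the inverse-logit2 transform ``2**M / (2**M + 1)``;
    disease is Bernoulli with logit
    ``base_logodds + theta * z(methylation) + delta * confounder`` where z is
    the SD-unit beta-scale methylation.  Survival times, when requested, are
    exponential with the same linear predictor (minus intercept) on the
    log-hazard scale, censored administratively at ``follow_up``.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_individuals, config.n_snps
    maf = config.maf_array
    beta_gp = config.beta_gp_array

    genotypes = rng.binomial(2, maf, size=(n, s)).astype(np.int8)
    confounder = rng.standard_normal(n)
    m_value = genotypes @ beta_gp + config.gamma * confounder + rng.standard_normal(n)
    methylation = expit(m_value * np.log(2.0))

    z = (methylation - methylation.mean()) / methylation.std(ddof=1)
    linpred = config.theta * z + config.delta * confounder
    disease = rng.binomial(1, expit(config.base_logodds + linpred)).astype(np.int8)

    time_to_event = event_flag = None
    if config.survival:
        rate = np.exp(config.log_base_hazard + linpred)
        raw = rng.exponential(1.0 / rate)
        event_flag = (raw <= config.follow_up).astype(np.int8)
        time_to_event = np.minimum(raw, config.follow_up)

    # smoking strata derived by tertile cut of the continuous burden
    tertiles = np.quantile(confounder, [1 / 3, 2 / 3])
    smoking = np.asarray(_SMOKING_LEVELS)[np.searchsorted(tertiles, confounder)]

    covariates = pd.DataFrame(
        {
            "confounder": confounder,
            "smoking": smoking,
            "age": np.round(rng.normal(55.0, 8.0, size=n), 1),
            "sex": rng.binomial(1, 0.5, size=n).astype(np.int8),
        }
    )

    pair_idx = [
        _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(s)
    ]
    # deterministic cis positions so the same SNP has the same coordinates in
    # every cohort simulated from the same dimensions
    positions = config.cpg_pos + np.linspace(-750_000, 750_000, s).astype(int)
    snp_info = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:04d}" for i in range(s)],
            "effect_allele": [p[0] for p in pair_idx],
            "other_allele": [p[1] for p in pair_idx],
            "maf": maf,
            "chrom": config.cpg_chrom,
            "pos": np.maximum(positions, 1),
        }
    )

    return Cohort(
        genotypes=genotypes,
        snp_info=snp_info,
        confounder=confounder,
        methylation=methylation,
        disease=disease,
        covariates=covariates,
        cpg_id=config.cpg_id,
        config=config,
        time_to_event=time_to_event,
        event_flag=event_flag,
    )


def _discretize(values: pd.Series) -> pd.Series:
    """Tertile-bin continuous covariates; leave discrete ones alone."""
    if pd.api.types.is_float_dtype(values) and values.nunique() > 10:
        return pd.cut(values, bins=np.quantile(values, [0, 1 / 3, 2 / 3, 1.0]),
                      labels=False, include_lowest=True)
    return values


def make_matched_pairs(
    cohort: Cohort,
    matching_covariates: Sequence[str] = (),
    n_pairs: int | None = None,
    seed: int = 0,
) -> MatchedPairSet:
    """Greedy 1:1 exact matching on discretized covariates.

    Cases are visited in random order; each is paired without replacement to
    a random control with identical values on every (discretized) matching
    covariate.  Cases with no eligible control are dropped and counted in
    ``n_dropped``.

    Raises
    ------
    MatchingError
        If no pair at all can be formed.
    """
    rng = np.random.default_rng(seed)
    for name in matching_covariates:
        if name not in cohort.covariates.columns:
            raise InputError(f"unknown matching covariate {name!r}")

    keys = pd.DataFrame(index=np.arange(cohort.n_individuals))
    for name in matching_covariates:
        keys[name] = _discretize(cohort.covariates[name])
    key_tuples = [tuple(row) for row in keys.itertuples(index=False)] if matching_covariates else [()] * cohort.n_individuals

    case_idx = np.flatnonzero(cohort.disease == 1)
    ctrl_idx = np.flatnonzero(cohort.disease == 0)
    if n_pairs is None:
        n_pairs = min(len(case_idx), len(ctrl_idx))

    pool: dict[tuple, list[int]] = {}
    for i in ctrl_idx:
        pool.setdefault(key_tuples[i], []).append(int(i))
    for bucket in pool.values():
        rng.shuffle(bucket)

    case_order = rng.permutation(case_idx)
    matched_cases, matched_ctrls = [], []
    dropped = 0
    for i in case_order:
        if len(matched_cases) >= n_pairs:
            break
        bucket = pool.get(key_tuples[i])
        if bucket:
            matched_cases.append(int(i))
            matched_ctrls.append(bucket.pop())
        else:
            dropped += 1
    if not matched_cases:
        raise MatchingError("zero matchable case-control pairs")

    case_rows = np.asarray(matched_cases)
    ctrl_rows = np.asarray(matched_ctrls)
    meth = pd.DataFrame({cohort.cpg_id: cohort.methylation})
    return MatchedPairSet(
        pair_id=np.arange(1, len(case_rows) + 1),
        case_methylation=meth.iloc[case_rows].reset_index(drop=True),
        control_methylation=meth.iloc[ctrl_rows].reset_index(drop=True),
        case_covariates=cohort.covariates.iloc[case_rows].reset_index(drop=True),
        control_covariates=cohort.covariates.iloc[ctrl_rows].reset_index(drop=True),
        n_dropped=dropped,
    )


def export_summary_stats(cohort: Cohort, side: str) -> list[AssociationRecord]:
    """Per-SNP summary statistics for one side of a two-sample design.

    ``side="exposure"``: linear regression of SD-unit methylation on dosage.
    ``side="outcome"``: logistic regression of disease on dosage (log-odds
    per allele).  Monomorphic SNPs are flagged via ``note``, never dropped.
    """
    if side not in ("exposure", "outcome"):
        raise InputError("side must be 'exposure' or 'outcome'")
    records: list[AssociationRecord] = []
    n = cohort.n_individuals
    z = cohort.methylation_z
    disease = cohort.disease.astype(float)
    for j, info in cohort.snp_info.iterrows():
        d = cohort.genotypes[:, j].astype(float)
        eaf = float(d.mean() / 2.0)
        common = dict(
            snp_id=info["snp_id"],
            effect_allele=info["effect_allele"],
            other_allele=info["other_allele"],
            eaf=eaf,
            n=n,
            chrom=str(info["chrom"]),
            pos=int(info["pos"]),
            target=cohort.cpg_id if side == "exposure" else "disease",
        )
        if d.std() == 0.0:
            records.append(
                AssociationRecord(beta=np.nan, se=np.nan, pval=np.nan,
                                  note="monomorphic", **common)
            )
            continue
        if side == "exposure":
            fit = stats.linregress(d, z)
            records.append(
                AssociationRecord(
                    beta=float(fit.slope),
                    se=float(fit.stderr),
                    pval=float(fit.pvalue),
                    **common,
                )
            )
        else:
            try:
                model = sm.Logit(disease, sm.add_constant(d)).fit(disp=0)
                records.append(
                    AssociationRecord(
                        beta=float(model.params[1]),
                        se=float(model.bse[1]),
                        pval=float(model.pvalues[1]),
                        **common,
                    )
                )
            except Exception as err:  # separation etc.
                records.append(
                    AssociationRecord(beta=np.nan, se=np.nan, pval=np.nan,
                                      note=f"fit_failed: {err}", **common)
                )
    return records


def confounded_null_config(
    seed: int,
    n_individuals: int = 20_000,
    n_snps: int = 4,
    per_snp_r2: float = 0.02,
    maf: float = 0.3,
    gamma: float = -0.5,
    delta: float = 0.7,
    theta: float = 0.0,
    n_pairs: int = 3000,
    base_logodds: float = 0.0,
    **kwargs,
) -> SimulationConfig:
    """The canonical confounded-null scenario.

    Methylation and disease are linked only through the smoking burden
    (``gamma < 0`` lowers methylation, ``delta > 0`` raises risk), with no
    causal methylation effect.  Per-SNP effects are set analytically so each
    cis-SNP explains ``per_snp_r2`` of M-value variance.
    """
    beta_gp = beta_gp_for_r2([per_snp_r2] * n_snps, maf, gamma=gamma)
    return SimulationConfig(
        n_individuals=n_individuals,
        n_snps=n_snps,
        maf=maf,
        beta_gp=beta_gp,
        theta=theta,
        gamma=gamma,
        delta=delta,
        base_logodds=base_logodds,
        n_pairs=n_pairs,
        seed=seed,
        **kwargs,
    )
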