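import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from methmr.exceptions import InputError, NoInformationError
from methmr.ewas import (
    MatchedPairSet,
    beta_to_m,
    conditional_logistic,
    estimate_cell_proportions,
    m_to_beta,
    paired_tissue_difference,
    stratified_ewas,
    surrogate_variables,
)
from methmr.meta_analysis import fixed_effects_meta, heterogeneity
from methmr.synthetic_data import SimulationConfig, make_matched_pairs, simulate_cohort

from conftest import pairs_from_diffs


def oracle_difference_logistic(diffs):
    """Independent oracle: intercept-free logistic regression on the
    within-pair differences with all outcomes 1 (statsmodels GLM)."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    if diffs.shape[0] == 1:
        diffs = diffs.T
    model = sm.GLM(np.ones(diffs.shape[0]), diffs, family=sm.families.Binomial())
    return model.fit().params


class TestConditionalLogistic:
    def test_closed_form_ln3(self):
        # score equation: 3(1 - sigma(b)) = sigma(b) -> sigma(b) = 3/4
        r = conditional_logistic(pairs_from_diffs([1, 1, 1, -1]), standardize=False)
        assert r.log_or == pytest.approx(np.log(3), abs=1e-8)
        assert r.or_per_sd == pytest.approx(3.0, abs=1e-6)

    def test_closed_form_ln3_by_grid_search(self):
        # second independent route: maximize the likelihood on a dense grid
        grid = np.linspace(-3, 3, 120001)
        loglik = 3 * np.log(expit(grid)) + np.log(expit(-grid))
        assert grid[np.argmax(loglik)] == pytest.approx(np.log(3), abs=1e-4)

    def test_symmetry_zero(self):
        r = conditional_logistic(pairs_from_diffs([1, -1]), standardize=False)
        assert r.log_or == pytest.approx(0.0, abs=1e-10)

    def test_all_zero_differences_error(self):
        with pytest.raises(NoInformationError):
            conditional_logistic(pairs_from_diffs([0, 0, 0]))

    def test_matches_difference_logistic_oracle(self, rng):
        # 50 random small instances, tolerance 1e-6
        checked = 0
        while checked < 50:
            n = int(rng.integers(10, 30))
            diffs = rng.normal(0.2, 1.0, size=n)
            if (diffs > 0).all() or (diffs < 0).all():
                continue  # separated: MLE at infinity
            r = conditional_logistic(pairs_from_diffs(diffs), standardize=False)
            if r.diverged:
                continue
            expected = oracle_difference_logistic(diffs)[0]
            assert r.log_or == pytest.approx(expected, abs=1e-6)
            checked += 1

    def test_covariates_match_oracle(self, rng):
        n = 40
        diffs = rng.normal(0, 1, size=n)
        cov = rng.normal(0, 1, size=n)
        pairs = pairs_from_diffs(diffs, covariate_diffs={"x": cov})
        r = conditional_logistic(pairs, covariates=["x"], standardize=False)
        expected = oracle_difference_logistic(np.column_stack([diffs, cov]))
        assert r.log_or == pytest.approx(expected[0], abs=1e-6)

    def test_scale_invariance_of_or_per_sd(self, rng):
        diffs = rng.normal(0, 1, size=30)
        r1 = conditional_logistic(pairs_from_diffs(diffs))
        r2 = conditional_logistic(pairs_from_diffs(diffs * 7.3))
        assert r2.log_or == pytest.approx(r1.log_or, rel=1e-8)

    def test_separation_flagged(self):
        r = conditional_logistic(pairs_from_diffs([1.0, 2.0, 0.5]), standardize=False)
        assert r.diverged

    def test_confounder_adjustment_attenuates(self):
        # theta=0 but smoking confounds both; adjusting for the true
        # confounder must pull the estimate toward OR 1
        cfg = SimulationConfig(
            n_individuals=12000, n_snps=1, beta_gp=0.3, theta=0.0,
            gamma=-0.6, delta=0.8, base_logodds=-1.0, n_pairs=1500, seed=5,
        )
        cohort = simulate_cohort(cfg)
        pairs = make_matched_pairs(cohort, (), 1500, seed=5)
        unadj = conditional_logistic(pairs)
        adj = conditional_logistic(pairs, covariates=["confounder"])
        assert abs(adj.log_or) < abs(unadj.log_or)


class TestSurrogateVariables:
    def test_planted_batch_recovered(self, rng):
        n, p = 60, 300
        batch = np.repeat([0.0, 1.0], n // 2)
        m = rng.normal(0, 0.2, size=(n, p)) + np.outer(batch, rng.normal(1.0, 0.3, p))
        sv, var_exp = surrogate_variables(m, k=3)
        r = np.corrcoef(sv[:, 0], batch)[0, 1]
        assert abs(r) > 0.9
        assert var_exp[0] > var_exp[1]

    def test_orthonormal(self, rng):
        m = rng.normal(size=(40, 100))
        sv, _ = surrogate_variables(m, k=5)
        np.testing.assert_allclose(sv.T @ sv, np.eye(5), atol=1e-8)

    def test_zero_matrix_flagged(self):
        with pytest.raises(NoInformationError):
            surrogate_variables(np.zeros((20, 50)), k=2)

    def test_bad_k_rejected(self, rng):
        m = rng.normal(size=(10, 20))
        with pytest.raises(InputError):
            surrogate_variables(m, k=0)
        with pytest.raises(InputError):
            surrogate_variables(m, k=10)

    def test_protected_model_removed(self, rng):
        # structure fully explained by the protected variable leaves noise
        n, p = 50, 200
        protected = rng.normal(size=n)
        m = np.outer(protected, rng.normal(2.0, 0.1, p)) + rng.normal(0, 0.1, (n, p))
        sv, _ = surrogate_variables(m, protected=protected, k=2)
        assert abs(np.corrcoef(sv[:, 0], protected)[0, 1]) < 0.3


class TestCellProportions:
    @pytest.fixture
    def reference(self, rng):
        return pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(100, 2)), columns=["t_cell", "mono"]
        )

    def test_exact_mixture_recovered(self, reference):
        y = reference.to_numpy() @ np.array([0.3, 0.7])
        props, info = estimate_cell_proportions(y, reference)
        np.testing.assert_allclose(props, [0.3, 0.7], atol=1e-6)

    def test_vertex(self, reference):
        props, _ = estimate_cell_proportions(reference["t_cell"].to_numpy(), reference)
        np.testing.assert_allclose(props, [1.0, 0.0], atol=1e-6)

    def test_noisy_mixture(self, reference, rng):
        y = reference.to_numpy() @ np.array([0.4, 0.6]) + rng.normal(0, 0.01, 100)
        props, _ = estimate_cell_proportions(y, reference)
        np.testing.assert_allclose(props, [0.4, 0.6], atol=0.05)

    def test_constraints_hold(self, reference, rng):
        y = rng.uniform(0, 1, size=100)
        props, _ = estimate_cell_proportions(y, reference)
        assert (props >= 0).all()
        assert props.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_flagged(self, rng):
        col = rng.uniform(0.1, 0.9, 50)
        ref = np.column_stack([col, col])  # duplicated cell type
        with pytest.warns(UserWarning, match="rank-deficient"):
            _, info = estimate_cell_proportions(col, ref)
        assert info["rank_deficient"]

    def test_probe_mismatch_rejected(self, reference):
        with pytest.raises(InputError):
            estimate_cell_proportions(np.zeros(99), reference)


class TestStratifiedEwas:
    @pytest.fixture
    def cohort_pairs(self):
        cfg = SimulationConfig(
            n_individuals=9000, n_snps=1, beta_gp=0.3, theta=0.4,
            gamma=0.0, delta=0.0, base_logodds=-1.0, n_pairs=900, seed=3,
        )
        cohort = simulate_cohort(cfg)
        return make_matched_pairs(cohort, ("smoking",), 900, seed=3)

    def test_unknown_stratum_rejected(self, cohort_pairs):
        with pytest.raises(InputError):
            stratified_ewas(cohort_pairs, "not_a_column")

    def test_homogeneous_effect_consistent(self, cohort_pairs):
        results = stratified_ewas(cohort_pairs, "smoking")
        fitted = [r for r in results.values() if r is not None]
        assert len(fitted) == 3
        het = heterogeneity([r.log_or for r in fitted], [r.se for r in fitted])
        assert het.pval > 0.05  # no planted stratum difference

    def test_pooled_within_stratum_envelope(self, cohort_pairs):
        results = stratified_ewas(cohort_pairs, "smoking")
        fitted = [r for r in results.values() if r is not None]
        pooled = fixed_effects_meta([r.log_or for r in fitted], [r.se for r in fitted])
        ests = [r.log_or for r in fitted]
        assert min(ests) <= pooled.estimate <= max(ests)

    def test_degenerate_stratum_reported_missing(self):
        n = 12
        labels = np.array(["a"] * 6 + ["b"] * 6)
        meth = np.where(labels == "a", 0.5, np.linspace(0.2, 0.8, n))
        pairs = MatchedPairSet(
            pair_id=np.arange(n),
            case_methylation=pd.DataFrame({"cpg_1": meth}),
            control_methylation=pd.DataFrame({"cpg_1": np.where(labels == "a", 0.5, 0.4)}),
            case_covariates=pd.DataFrame({"grp": labels}),
            control_covariates=pd.DataFrame({"grp": labels}),
        )
        results = stratified_ewas(pairs, "grp")
        assert results["a"] is None  # all within-pair diffs zero there
        assert results["b"] is not None


class TestPairedTissue:
    def test_constant_beta_shift(self, rng):
        normal = pd.DataFrame(
            rng.uniform(0.3, 0.5, size=(4, 29)),
            index=[f"cpg_{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(29)],
        )
        tumour = normal + 0.1
        res = paired_tissue_difference(tumour, normal)
        np.testing.assert_allclose(res["mean_diff_beta"], 0.1, atol=1e-12)
        assert (res["pval"] < 1e-6).all()

    def test_identity(self, rng):
        mat = pd.DataFrame(rng.uniform(0.2, 0.8, size=(3, 10)),
                           index=list("abc"), columns=[f"s{i}" for i in range(10)])
        res = paired_tissue_difference(mat, mat.copy())
        np.testing.assert_allclose(res["mean_diff_beta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["pval"], 1.0)

    def test_sign_convention(self, rng):
        normal = pd.DataFrame(rng.uniform(0.4, 0.6, size=(1, 12)),
                              index=["cpg_1"], columns=[f"s{i}" for i in range(12)])
        tumour = normal - 0.2  # hypomethylated tumour
        res = paired_tissue_difference(tumour, normal)
        assert res["mean_diff_beta"].iloc[0] < 0
        assert res["mean_diff_m"].iloc[0] < 0

    def test_subject_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.uniform(size=(2, 5)), index=["x", "y"],
                         columns=list("abcde"))
        b = a.rename(columns={"a": "zz"})
        with pytest.raises(InputError):
            paired_tissue_difference(a, b)

    def test_m_transform_roundtrip(self, rng):
        beta = rng.uniform(0.01, 0.99, 100)
        np.testing.assert_allclose(m_to_beta(beta_to_m(beta)), beta, atol=1e-9)
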