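import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmr.exceptions import InputError, NumericalError
from methmr.records import AssociationRecord
from methmr.two_sample_mr import (
    HarmonizedInstrument,
    harmonize,
    ivw_combine,
    ivw_correlated,
    mr_egger,
    mr_power,
    wald_ratio,
    z_difference,
)


def exp_rec(snp="rs1", beta=0.5, se=0.05, ea="A", oa="G", eaf=0.3):
    return AssociationRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, eaf=eaf, pval=1e-8, n=1000)


def out_rec(snp="rs1", beta=-0.1, se=0.02, ea="A", oa="G", eaf=0.3):
    return AssociationRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, eaf=eaf, pval=0.01, n=50_000)


def hi(snp="rs1", bgp=0.5, segp=0.05, bgd=-0.02, segd=0.01):
    return HarmonizedInstrument(snp_id=snp, beta_gp=bgp, se_gp=segp,
                                beta_gd=bgd, se_gd=segd,
                                effect_allele="A", other_allele="G")


class TestHarmonize:
    def test_swapped_effect_allele_flips_sign(self):
        h, log = harmonize([exp_rec(ea="A", oa="G")],
                           [out_rec(ea="G", oa="A", beta=-0.1, eaf=0.7)])
        assert len(h) == 1
        assert h[0].beta_gd == pytest.approx(0.1)
        assert h[0].eaf_outcome == pytest.approx(0.3)

    def test_aligned_untouched(self):
        h, _ = harmonize([exp_rec()], [out_rec(beta=-0.1)])
        assert h[0].beta_gd == pytest.approx(-0.1)

    def test_strand_flip_resolved(self):
        # exposure A/G; outcome reported as T/C (complement strand)
        h, _ = harmonize([exp_rec(ea="A", oa="G")],
                         [out_rec(ea="T", oa="C", beta=-0.1)])
        assert len(h) == 1
        assert h[0].beta_gd == pytest.approx(-0.1)

    def test_strand_flip_with_swap(self):
        h, _ = harmonize([exp_rec(ea="A", oa="G")],
                         [out_rec(ea="C", oa="T", beta=-0.1, eaf=0.7)])
        assert h[0].beta_gd == pytest.approx(0.1)

    def test_palindromic_ambiguous_dropped(self):
        h, log = harmonize([exp_rec(ea="A", oa="T", eaf=0.50)],
                           [out_rec(ea="A", oa="T", eaf=0.50)])
        assert h == []
        assert any("palindromic" in action for _, action in log)

    def test_palindromic_clear_frequency_kept(self):
        h, _ = harmonize([exp_rec(ea="A", oa="T", eaf=0.10)],
                         [out_rec(ea="A", oa="T", eaf=0.12, beta=-0.1)])
        assert len(h) == 1
        assert h[0].beta_gd == pytest.approx(-0.1)

    def test_palindromic_discordant_frequency_flipped(self):
        h, _ = harmonize([exp_rec(ea="A", oa="T", eaf=0.10)],
                         [out_rec(ea="A", oa="T", eaf=0.90, beta=-0.1)])
        assert h[0].beta_gd == pytest.approx(0.1)

    def test_incompatible_alleles_dropped_with_reason(self):
        h, log = harmonize([exp_rec(ea="A", oa="G")],
                           [out_rec(ea="A", oa="C")])
        assert h == []
        assert log == [("rs1", "dropped: incompatible alleles")]

    def test_idempotent(self):
        exposure = [exp_rec(ea="A", oa="G"), exp_rec(snp="rs2", ea="C", oa="T", beta=-0.3)]
        outcome = [out_rec(ea="G", oa="A", beta=0.2, eaf=0.7),
                   out_rec(snp="rs2", ea="C", oa="T", beta=0.05)]
        h1, _ = harmonize(exposure, outcome)
        # rebuild outcome records from the harmonized result and re-run
        outcome2 = [
            AssociationRecord(snp_id=h.snp_id, effect_allele=h.effect_allele,
                              other_allele=h.other_allele, beta=h.beta_gd,
                              se=h.se_gd, eaf=h.eaf_outcome, pval=0.01, n=50_000)
            for h in h1
        ]
        h2, _ = harmonize(exposure, outcome2)
        for a, b in zip(h1, h2):
            assert a.beta_gd == pytest.approx(b.beta_gd)
            assert a.effect_allele == b.effect_allele


class TestWaldRatio:
    def test_hand_delta_arithmetic(self):
        r = wald_ratio(hi())
        assert r.estimate == pytest.approx(-0.04)
        expected_se = abs(-0.04) * np.sqrt(0.01**2 / 0.02**2 + 0.05**2 / 0.5**2)
        assert r.se == pytest.approx(expected_se, rel=1e-12)
        assert r.se == pytest.approx(0.0204, abs=1e-4)

    def test_identity_instrument(self):
        r = wald_ratio(hi(bgp=1.0, segp=0.0, bgd=-0.02, segd=0.01))
        assert r.estimate == pytest.approx(-0.02)
        assert r.se == pytest.approx(0.01)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(NumericalError):
            wald_ratio(hi(bgp=0.0))

    def test_null_outcome_limit_form(self):
        r = wald_ratio(hi(bgd=0.0, segd=0.01, bgp=0.5, segp=0.05))
        assert r.estimate == 0.0
        assert r.se == pytest.approx(0.01 / 0.5)

    def test_ci_definition(self):
        r = wald_ratio(hi())
        assert r.ci95 == (pytest.approx(r.estimate - 1.96 * r.se),
                          pytest.approx(r.estimate + 1.96 * r.se))

    def test_second_order_inflates_se(self):
        first = wald_ratio(hi())
        second = wald_ratio(hi(), second_order=True)
        assert second.se > first.se
        assert second.estimate == first.estimate


class TestIvwCombine:
    @staticmethod
    def _ratio(est, se):
        from methmr.two_sample_mr import MRResult
        return MRResult(method="wald", estimate=est, se=se, pval=0.5,
                        n_instruments=1)

    def test_same_arithmetic_as_meta(self):
        r = ivw_combine([self._ratio(0.5, 0.1), self._ratio(0.3, 0.2)])
        assert r.estimate == pytest.approx(0.46)
        assert r.se == pytest.approx(125**-0.5)
        assert r.q == pytest.approx(0.8)
        assert r.q_df == 1

    def test_single_ratio_bitwise_passthrough(self):
        w = wald_ratio(hi())
        r = ivw_combine([w])
        assert (r.estimate, r.se, r.pval, r.method) == (w.estimate, w.se, w.pval, w.method)
        assert r.q is None

    def test_identical_ratios_zero_q(self):
        r = ivw_combine([self._ratio(0.2, 0.1)] * 3)
        assert r.q == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ivw_combine([])


class TestMrEgger:
    def test_exact_line_through_origin(self):
        hs = [hi(snp=f"s{i}", bgp=x, segp=0.01, bgd=x / 2, segd=0.05)
              for i, x in enumerate((0.2, 0.4, 0.6))]
        r = mr_egger(hs)
        assert r.estimate == pytest.approx(0.5, abs=1e-10)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InputError):
            mr_egger([hi(), hi(snp="rs2")])

    def test_orientation_invariance(self):
        hs = [hi(snp=f"s{i}", bgp=x, bgd=0.3 * x + 0.05, segd=0.05)
              for i, x in enumerate((0.2, -0.4, 0.6, -0.8))]
        flipped = [HarmonizedInstrument(
            snp_id=h.snp_id, beta_gp=-h.beta_gp, se_gp=h.se_gp,
            beta_gd=-h.beta_gd, se_gd=h.se_gd,
            effect_allele=h.other_allele, other_allele=h.effect_allele)
            for h in hs]
        a, b = mr_egger(hs), mr_egger(flipped)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-9)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-9)

    def test_directional_pleiotropy_recovered(self, rng):
        # summary-level simulation: intercept ~ mu, slope ~ theta
        theta, mu = 0.3, 0.08
        n_instr, n_reps = 25, 200
        bgp = rng.uniform(0.1, 0.6, n_instr)
        se_gd = np.full(n_instr, 0.03)
        slopes, intercepts = [], []
        for _ in range(n_reps):
            pleio = rng.normal(mu, 0.02, n_instr)
            bgd = theta * bgp + pleio + rng.normal(0, se_gd)
            hs = [hi(snp=f"s{i}", bgp=bgp[i], segp=1e-6, bgd=bgd[i],
                     segd=se_gd[i]) for i in range(n_instr)]
            r = mr_egger(hs)
            slopes.append(r.estimate)
            intercepts.append(r.intercept)
        mc_se_slope = np.std(slopes, ddof=1) / np.sqrt(n_reps)
        mc_se_int = np.std(intercepts, ddof=1) / np.sqrt(n_reps)
        assert abs(np.mean(slopes) - theta) < 3 * mc_se_slope
        assert abs(np.mean(intercepts) - mu) < 3 * mc_se_int


class TestIvwCorrelated:
    def _instruments(self):
        return [hi(snp=f"s{i}", bgp=b, segp=0.02, bgd=g, segd=s)
                for i, (b, g, s) in enumerate(
                    [(0.4, 0.05, 0.02), (0.3, 0.02, 0.03), (0.5, 0.04, 0.025)])]

    def test_identity_reduces_to_ivw(self):
        hs = self._instruments()
        rho = pd.DataFrame(np.eye(3), index=[h.snp_id for h in hs],
                           columns=[h.snp_id for h in hs])
        a = ivw_correlated(hs, rho)
        b = ivw_combine([wald_ratio(h) for h in hs])
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)

    def test_duplicated_instrument_not_sqrt2_deflated(self):
        h = hi(bgp=0.4, segp=0.02, bgd=0.05, segd=0.02)
        h2 = hi(snp="rs2", bgp=0.4, segp=0.02, bgd=0.05, segd=0.02)
        single_se = wald_ratio(h).se
        rho = np.array([[1.0, 0.999], [0.999, 1.0]])
        r = ivw_correlated([h, h2], rho)
        assert r.se == pytest.approx(single_se, rel=0.05)
        assert r.se > single_se / np.sqrt(2) * 1.3

    def test_non_pd_rejected_with_eigenvalues(self):
        hs = self._instruments()[:2]
        rho = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(NumericalError, match="eigenvalues"):
            ivw_correlated(hs, rho)


class TestZDifference:
    def test_hand_arithmetic(self):
        z, p = z_difference(0.5, 0.1, 0.1, 0.1)
        assert z == pytest.approx(2.828, abs=1e-3)
        assert p == pytest.approx(0.0047, abs=2e-4)

    def test_equal_estimates(self):
        z, p = z_difference(0.3, 0.1, 0.3, 0.2)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = z_difference(0.5, 0.1, 0.1, 0.1)
        z2, p2 = z_difference(0.1, 0.1, 0.5, 0.1)
        assert z1 == -z2 and p1 == p2


class TestMrPower:
    def test_null_r2_gives_alpha(self):
        assert mr_power(1000, 1000, 0.0, 1.5) == pytest.approx(0.05, abs=1e-9)

    def test_null_or_gives_alpha(self):
        assert mr_power(1000, 1000, 0.01, 1.0) == pytest.approx(0.05, abs=1e-9)

    def test_invalid_r2(self):
        with pytest.raises(InputError):
            mr_power(1000, 1000, 1.2, 1.5)

    @given(
        st.integers(500, 50_000),
        st.floats(0.001, 0.1),
        st.floats(1.05, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_argument(self, n_cases, r2, odds):
        base = mr_power(n_cases, n_cases, r2, odds)
        assert mr_power(2 * n_cases, 2 * n_cases, r2, odds) >= base - 1e-12
        assert mr_power(n_cases, n_cases, min(r2 * 2, 0.99), odds) >= base - 1e-12
        assert mr_power(n_cases, n_cases, r2, odds * 1.2) >= base - 1e-12
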