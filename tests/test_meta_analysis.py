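"""Fisher-z meta-analysis: hand values, oracle equivalence, and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugrepo.meta_analysis import (
    EffectSize,
    fisher_combined_test,
    fisher_z,
    fixed_effect_combine,
    i_squared,
    inverse_fisher_z,
    meta_analyze_drug,
    q_statistic,
    random_effect_combine,
    select_model,
    tau_squared_dl,
    variance_of_z,
)

from conftest import meta_oracle


def eff(y=None, v=None, rho=None, n=None, label="d"):
    """Effect with either (rho, N) given or (Y, V) forced directly."""
    if rho is not None:
        return EffectSize(label=label, rho=rho, N=n or 50)
    e = EffectSize(label=label, rho=0.0, N=n or 50)
    e.Y, e.V = y, v
    e.rho = inverse_fisher_z(y)
    return e


class TestTransforms:
    def test_fixed_point_at_zero(self):
        assert fisher_z(0.0) == 0.0
        assert inverse_fisher_z(0.0) == 0.0

    def test_half_ln_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_odd_and_round_trip(self, rho):
        assert fisher_z(-rho) == pytest.approx(-fisher_z(rho), abs=1e-12)
        assert inverse_fisher_z(fisher_z(rho)) == pytest.approx(rho, abs=1e-12)

    def test_large_z_limits_to_one(self):
        rhos = [inverse_fisher_z(z) for z in (2.0, 5.0, 10.0)]
        assert all(a < b < 1 for a, b in zip(rhos, rhos[1:]))

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @pytest.mark.parametrize("n,expected", [(4, 1.0), (103, 0.01)])
    def test_variance_of_z(self, n, expected):
        assert variance_of_z(n) == pytest.approx(expected)

    def test_variance_undefined_below_four(self):
        with pytest.raises(ValueError):
            variance_of_z(3)


class TestFixedEffect:
    def test_single_study_identity(self):
        res = fixed_effect_combine([eff(rho=-0.5, n=20)])
        assert res.M == pytest.approx(fisher_z(-0.5))
        assert res.V_M == pytest.approx(variance_of_z(20))

    def test_equal_weights_average(self):
        res = fixed_effect_combine([eff(y=0.2, v=0.01), eff(y=0.4, v=0.01)])
        assert res.M == pytest.approx(0.3)
        assert res.V_M == pytest.approx(0.005)

    def test_hand_weighted_mean(self):
        res = fixed_effect_combine([eff(y=0.0, v=0.01), eff(y=0.6, v=0.04)])
        assert res.M == pytest.approx(0.12)

    def test_unweighted_equals_weighted_under_equal_variances(self):
        effects = [eff(y=0.1, v=0.02), eff(y=0.5, v=0.02), eff(y=-0.2, v=0.02)]
        assert fixed_effect_combine(effects, weighted=False).M == pytest.approx(
            fixed_effect_combine(effects, weighted=True).M
        )

    def test_m_within_study_range_and_variance_shrinks(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 8))
            effects = [
                eff(y=float(rng.normal()), v=float(rng.uniform(0.01, 0.5)))
                for _ in range(k)
            ]
            res = fixed_effect_combine(effects)
            ys = [e.Y for e in effects]
            assert min(ys) - 1e-12 <= res.M <= max(ys) + 1e-12
            assert res.V_M <= min(e.V for e in effects) + 1e-12

    def test_ci_multiplier_and_back_transform(self):
        res = fixed_effect_combine([eff(rho=-0.8, n=10)])
        assert res.LL_M == pytest.approx(res.M - 1.96 * res.SE_M)
        assert -1 < res.rho_LL < res.rho_combined < res.rho_UL < 1
        assert res.rho_combined == pytest.approx(-0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fixed_effect_combine([])


class TestHeterogeneity:
    def test_identical_studies_have_zero_q(self):
        q, df, p = q_statistic([eff(y=0.3, v=0.02), eff(y=0.3, v=0.05)])
        assert q == pytest.approx(0.0)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_q(self):
        q, df, _ = q_statistic([eff(y=0.0, v=0.01), eff(y=0.6, v=0.04)])
        assert q == pytest.approx(7.2)

    def test_q_permutation_invariant(self):
        effects = [eff(y=0.1, v=0.02), eff(y=-0.4, v=0.3), eff(y=0.5, v=0.07)]
        q1, *_ = q_statistic(effects)
        q2, *_ = q_statistic(effects[::-1])
        assert q1 == pytest.approx(q2)

    @pytest.mark.parametrize("q,df,expected", [
        (1.0, 1, 0.0), (4.0, 1, 75.0), (0.5, 2, 0.0),
    ])
    def test_i_squared(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)

    def test_tau_squared_hand_value(self):
        # W = (100, 25): C = 125 - (100^2 + 25^2)/125 = 40; tau2 = 6.2/40
        effects = [eff(y=0.0, v=0.01), eff(y=0.6, v=0.04)]
        q, df, _ = q_statistic(effects)
        assert tau_squared_dl(effects, q, df) == pytest.approx(0.155)

    def test_tau_squared_floored_at_zero(self):
        effects = [eff(y=0.3, v=0.02), eff(y=0.3, v=0.05)]
        assert tau_squared_dl(effects, 0.5, 1) == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            q_statistic([eff(y=0.1, v=0.1)])


class TestRandomEffects:
    def test_zero_tau2_degenerates_to_fixed(self):
        effects = [eff(y=0.3, v=0.02), eff(y=0.3, v=0.05)]
        fixed = fixed_effect_combine(effects)
        rand = random_effect_combine(effects)
        assert rand.tau2 == 0.0
        assert rand.M == pytest.approx(fixed.M)
        assert rand.SE_M == pytest.approx(fixed.SE_M)

    def test_positive_tau2_widens_se(self):
        effects = [eff(y=-0.8, v=0.02), eff(y=0.6, v=0.03), eff(y=0.1, v=0.05)]
        assert random_effect_combine(effects).SE_M >= fixed_effect_combine(effects).SE_M

    def test_ci_coverage_near_nominal(self):
        # k=4 batches, known true z = -0.6 and known tau2 = 0.1; with the
        # between-batch variance supplied the 95% CI must hit its nominal
        # coverage (estimating tau2 from only 4 batches undercovers, a
        # known small-k property of the DL estimator)
        rng = np.random.default_rng(2014)
        n, tau2, true_z = 50, 0.1, -0.6
        v = 1.0 / (n - 3)
        covered = 0
        n_sim = 2000
        for _ in range(n_sim):
            ys = rng.normal(true_z, np.sqrt(v + tau2), size=4)
            effects = [eff(y=float(y), v=v) for y in ys]
            res = random_effect_combine(effects, tau2=tau2)
            covered += res.LL_M <= true_z <= res.UL_M
        assert 0.93 <= covered / n_sim <= 0.97


class TestModelSelection:
    @pytest.mark.parametrize("p_het,expected", [
        (0.2, "fixed"), (0.05, "random"), (0.1, "fixed"), (0.0999, "random"),
    ])
    def test_threshold_rule(self, p_het, expected):
        assert select_model(p_het) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            select_model(1.5)


class TestFisherCombined:
    def test_all_ones(self):
        f, df, p = fisher_combined_test([1.0, 1.0, 1.0])
        assert f == pytest.approx(0.0)
        assert df == 6 and p == pytest.approx(1.0)

    def test_hand_value(self):
        f, df, _ = fisher_combined_test([0.05, 0.05])
        assert f == pytest.approx(11.983, abs=5e-4)
        assert df == 4

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            f, _, p = fisher_combined_test([0.0, 0.5])
        assert np.isfinite(f) and 0 < p < 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combined_test([])


class TestMetaAnalyzeDrug:
    def test_single_batch_flagged(self):
        res = meta_analyze_drug([eff(rho=-0.8, n=10)])
        assert res.single_study and res.k_studies == 1
        assert res.rho_combined == pytest.approx(-0.8)
        assert -1 < res.rho_LL < res.rho_UL < 1

    def test_identical_batches_select_fixed(self):
        res = meta_analyze_drug([eff(rho=-0.4, n=20), eff(rho=-0.4, n=20)])
        assert res.model == "fixed"
        assert res.Q == pytest.approx(0.0)
        assert res.M == pytest.approx(fisher_z(-0.4))

    def test_recovers_true_effect(self):
        rng = np.random.default_rng(7)
        n, true_rho = 50, -0.6
        v = 1.0 / (n - 3)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            zs = rng.normal(np.arctanh(true_rho), np.sqrt(v), size=4)
            effects = [
                EffectSize(label="d", rho=float(np.tanh(z)), N=n) for z in zs
            ]
            res = meta_analyze_drug(effects)
            hits += abs(res.rho_combined - true_rho) < 0.1
        assert hits / n_rep >= 0.95

    def test_matches_straight_formula_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 9))
            ys = rng.normal(0, 0.6, size=k)
            vs = rng.uniform(0.005, 0.3, size=k)
            effects = [eff(y=float(y), v=float(v)) for y, v in zip(ys, vs)]
            expected = meta_oracle(list(ys), list(vs))
            fix = fixed_effect_combine(effects)
            q, df, _ = q_statistic(effects)
            assert fix.M == pytest.approx(expected["M"], abs=1e-10)
            assert fix.V_M == pytest.approx(expected["V_M"], abs=1e-10)
            assert fix.Z == pytest.approx(expected["Z"], abs=1e-10)
            assert q == pytest.approx(expected["Q"], abs=1e-10)
            assert i_squared(q, df) == pytest.approx(expected["I2"], abs=1e-10)
            assert tau_squared_dl(effects, q, df) == pytest.approx(
                expected["tau2"], abs=1e-10
            )
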