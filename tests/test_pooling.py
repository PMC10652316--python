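"""Meta-analysis engine: pooling, heterogeneity, sensitivity, subgroups."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import escc_meta as em
from escc_meta.records import Z_95

# ---------------------------------------------------------------------------
# independent oracle: direct textbook formulas, fsum accumulation in reversed
# input order, no shared code with the implementation
# ---------------------------------------------------------------------------


def oracle_fixed(pairs):
    pairs = list(reversed(pairs))
    w = [1.0 / s**2 for _, s in pairs]
    sw = math.fsum(w)
    mu = math.fsum(wi * t for wi, (t, _) in zip(w, pairs)) / sw
    se = sw**-0.5
    q = math.fsum(wi * (t - mu) ** 2 for wi, (t, _) in zip(w, pairs))
    return mu, se, q


def oracle_dl(pairs):
    _, _, q = oracle_fixed(pairs)
    k = len(pairs)
    w = [1.0 / s**2 for _, s in reversed(pairs)]
    c = math.fsum(w) - math.fsum(wi**2 for wi in w) / math.fsum(w)
    tau2 = max(0.0, (q - (k - 1)) / c)
    ws = [1.0 / (s**2 + tau2) for _, s in reversed(pairs)]
    mu = math.fsum(wi * t for wi, (t, _) in zip(ws, reversed(pairs))) / math.fsum(ws)
    se = math.fsum(ws) ** -0.5
    return mu, se, tau2


estimate_lists = st.lists(
    st.tuples(st.floats(-2, 2), st.floats(0.05, 1.5)),
    min_size=2, max_size=5,
)


class TestPoolingOracle:
    @given(pairs=estimate_lists)
    @settings(max_examples=200, deadline=None)
    def test_fixed_matches_independent_formulas(self, pairs):
        est = [em.EffectEstimate(t, s) for t, s in pairs]
        res = em.pool_fixed(est)
        mu, se, q = oracle_fixed(pairs)
        assert res.mu_hat == pytest.approx(mu, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.q_stat == pytest.approx(q, abs=1e-10)

    @given(pairs=estimate_lists)
    @settings(max_examples=200, deadline=None)
    def test_random_effects_matches_independent_formulas(self, pairs):
        est = [em.EffectEstimate(t, s) for t, s in pairs]
        res = em.pool_random_dl(est)
        mu, se, tau2 = oracle_dl(pairs)
        assert res.mu_hat == pytest.approx(mu, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)

    @given(pairs=estimate_lists)
    @settings(max_examples=100, deadline=None)
    def test_pooled_estimate_is_convex_combination(self, pairs):
        est = [em.EffectEstimate(t, s) for t, s in pairs]
        thetas = [t for t, _ in pairs]
        for res in (em.pool_fixed(est), em.pool_random_dl(est)):
            assert min(thetas) - 1e-12 <= res.mu_hat <= max(thetas) + 1e-12

    @given(pairs=estimate_lists)
    @settings(max_examples=100, deadline=None)
    def test_random_se_not_below_fixed_se(self, pairs):
        est = [em.EffectEstimate(t, s) for t, s in pairs]
        assert em.pool_random_dl(est).se >= em.pool_fixed(est).se - 1e-12

    @given(pairs=estimate_lists)
    @settings(max_examples=100, deadline=None)
    def test_fixed_se_not_above_smallest_study_se(self, pairs):
        est = [em.EffectEstimate(t, s) for t, s in pairs]
        assert em.pool_fixed(est).se <= min(s for _, s in pairs) + 1e-12


class TestPublishedAnalyses:
    def test_protective_variant_pools_fixed_effect(self, analysis_effects):
        res = em.pool_fixed(analysis_effects["rs671/additive"])
        assert (round(res.or_point, 2), round(res.or_low, 2), round(res.or_high, 2)) == (
            0.60, 0.50, 0.73)

    def test_risk_variant_pools_random_effects(self, analysis_effects):
        res = em.pool_random_dl(analysis_effects["rs1229984/additive"])
        assert (round(res.or_point, 2), round(res.or_low, 2), round(res.or_high, 2)) == (
            2.50, 1.70, 3.69)

    def test_three_study_analysis_has_wide_random_ci(self, analysis_effects):
        res = em.pool_random_dl(analysis_effects["rs1042026/additive"])
        assert (round(res.or_point, 2), round(res.or_low, 2), round(res.or_high, 2)) == (
            2.15, 0.50, 9.28)


class TestPoolingEdgeCases:
    def test_single_estimate_passes_through(self):
        res = em.pool_fixed([em.EffectEstimate(0.3, 0.1)])
        assert res.k == 1 and res.q_stat == 0.0 and res.df == 0
        assert res.mu_hat == 0.3 and res.se == 0.1

    def test_equal_se_pools_to_arithmetic_mean(self):
        res = em.pool_fixed([em.EffectEstimate(0.2, 0.1), em.EffectEstimate(0.6, 0.1)])
        assert res.mu_hat == pytest.approx(0.4, abs=1e-12)

    def test_identical_estimates_have_zero_tau2_and_match_fixed(self):
        est = [em.EffectEstimate(0.5, 0.2)] * 5
        rand, fixed = em.pool_random_dl(est), em.pool_fixed(est)
        assert rand.tau2 == 0.0
        assert rand.mu_hat == pytest.approx(fixed.mu_hat, abs=1e-12)
        assert rand.se == pytest.approx(fixed.se, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(em.ValidationError):
            em.pool_fixed([])


class TestHeterogeneity:
    def test_homogeneous_published_set_has_zero_i2(self, analysis_effects):
        het = em.heterogeneity(analysis_effects["rs671/additive"])
        assert het.i2 == 0.0

    def test_heterogeneous_published_set(self, analysis_effects):
        het = em.heterogeneity(analysis_effects["rs674/additive"])
        assert round(het.i2, 1) == 69.9
        assert round(het.p_q, 3) == 0.003

    @given(pairs=estimate_lists)
    @settings(max_examples=100, deadline=None)
    def test_i2_clipped_to_zero_when_q_below_df(self, pairs):
        het = em.heterogeneity([em.EffectEstimate(t, s) for t, s in pairs])
        if het.q_stat <= het.df:
            assert het.i2 == 0.0
        assert 0.0 <= het.i2 < 100.0
        assert het.tau2 >= 0.0

    def test_requires_two_estimates(self):
        with pytest.raises(em.ValidationError):
            em.heterogeneity([em.EffectEstimate(0.0, 0.1)])


class TestModelSelection:
    @pytest.mark.parametrize("i2, expected", [(0.0, "fixed"), (49.9, "fixed"),
                                              (50.0, "fixed"), (50.1, "random"),
                                              (91.3, "random")])
    def test_i2_rule(self, i2, expected):
        assert em.select_model(i2) == expected

    @pytest.mark.parametrize("i2", [-1.0, 100.0, 150.0])
    def test_out_of_range_rejected(self, i2):
        with pytest.raises(em.ValidationError):
            em.select_model(i2)


class TestLeaveOneOut:
    def test_published_homogeneous_set_is_stable(self, analysis_effects):
        results = em.leave_one_out(analysis_effects["rs671/additive"])
        assert len(results) == 4
        assert all(0.50 <= r.or_point <= 0.80 for r in results)

    def test_identical_estimates_never_move_the_point(self):
        results = em.leave_one_out([em.EffectEstimate(0.5, 0.2)] * 3)
        assert all(r.mu_hat == pytest.approx(0.5, abs=1e-12) for r in results)

    def test_requires_three_estimates(self):
        with pytest.raises(em.ValidationError):
            em.leave_one_out([em.EffectEstimate(0.5, 0.2)] * 2)


def _sim_records(rng, k, theta, label):
    """Homogeneous synthetic records with a given subgroup label."""
    recs = []
    for i in range(k):
        se = rng.uniform(0.1, 0.3)
        log_or = rng.normal(theta, se)
        recs.append(em.StudyRecord(
            study_id=f"{label}{i}", year=2010, design="population_case_control",
            country=label, ethnicity="other", gene="ALDH2", variant="rs0",
            n_cases=100, n_controls=100, model="additive",
            or_point=math.exp(log_or),
            ci_low=math.exp(log_or - Z_95 * se),
            ci_high=math.exp(log_or + Z_95 * se),
        ))
    return recs


class TestSubgroups:
    def test_equal_group_estimates_give_p_one(self):
        rng = np.random.default_rng(11)
        recs = _sim_records(rng, 3, 0.2, "A")
        mirrored = [em.StudyRecord(**{**r.__dict__, "study_id": f"B{i}", "country": "B"})
                    for i, r in enumerate(recs)]
        res = em.subgroup_analysis(recs + mirrored, "country")
        assert res.p_interaction == pytest.approx(1.0)

    def test_constant_grouping_field_rejected(self):
        recs = _sim_records(np.random.default_rng(3), 4, 0.0, "only")
        with pytest.raises(em.ValidationError, match="2 groups"):
            em.subgroup_analysis(recs, "country")

    def test_singleton_groups_flagged(self):
        rng = np.random.default_rng(5)
        recs = _sim_records(rng, 3, 0.0, "A") + _sim_records(rng, 1, 0.0, "B")
        res = em.subgroup_analysis(recs, "country")
        assert res.singleton_groups == ("B",)

    def test_interaction_test_holds_type_i_error(self):
        """Identical true effects in both groups: ~5% false interactions."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            recs = _sim_records(rng, 5, 0.3, "A") + _sim_records(rng, 5, 0.3, "B")
            if em.subgroup_analysis(recs, "country").p_interaction < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_three_group_interaction_uses_q_between(self):
        rng = np.random.default_rng(7)
        recs = sum((_sim_records(rng, 3, t, lab)
                    for t, lab in [(0.0, "A"), (0.0, "B"), (2.0, "C")]), [])
        res = em.subgroup_analysis(recs, "country")
        assert len(res.per_group) == 3
        assert res.p_interaction < 0.001


class TestMetaRegression:
    def test_noiseless_linear_relation_recovers_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        theta = 0.1 + 0.5 * x
        est = [em.EffectEstimate(t, 0.05) for t in theta]
        res = em.meta_regression(est, x)
        assert res.slope == pytest.approx(0.5, abs=1e-8)
        assert res.intercept == pytest.approx(0.1, abs=1e-8)
        assert res.tau2_residual == 0.0

    def test_unrelated_covariate_on_homogeneous_data_is_null(self):
        rng = np.random.default_rng(42)
        se = rng.uniform(0.1, 0.3, 12)
        theta = rng.normal(0.2, se)
        est = [em.EffectEstimate(t, s) for t, s in zip(theta, se)]
        res = em.meta_regression(est, np.arange(12, dtype=float))
        assert abs(res.slope) < 0.1
        assert res.p_slope > 0.05

    def test_constant_covariate_rejected(self):
        est = [em.EffectEstimate(0.1, 0.1)] * 4
        with pytest.raises(em.ValidationError, match="constant"):
            em.meta_regression(est, [1.0] * 4)

    def test_requires_three_studies(self):
        est = [em.EffectEstimate(0.1, 0.1)] * 2
        with pytest.raises(em.ValidationError):
            em.meta_regression(est, [0.0, 1.0])


@pytest.mark.parametrize("variant_model", ["rs1229984/additive", "rs674/additive"])
def test_dl_pooling_agrees_with_metafor(analysis_effects, variant_model, tmp_path):
    """Cross-check the DL estimates against R metafor as an independent oracle."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    eff = analysis_effects[variant_model]
    yi = ",".join(repr(e.log_or) for e in eff)
    vi = ",".join(repr(e.se**2) for e in eff)
    script = tmp_path / "dl.R"
    script.write_text(
        "suppressMessages(library(metafor))\n"
        f"fit <- rma(yi=c({yi}), vi=c({vi}), method='DL')\n"
        "cat(sprintf('%.10f %.10f %.10f', fit$beta, fit$se, fit$tau2))\n"
    )
    out = subprocess.run(["Rscript", "--vanilla", str(script)],
                         capture_output=True, text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    mu_r, se_r, tau2_r = map(float, out.stdout.split())
    res = em.pool_random_dl(eff)
    assert res.mu_hat == pytest.approx(mu_r, abs=1e-8)
    assert res.se == pytest.approx(se_r, abs=1e-8)
    assert res.tau2 == pytest.approx(tau2_r, abs=1e-8)
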