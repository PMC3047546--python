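import numpy as np
import pytest

from richcomp.reml_varcomp import (
    NotConvergedError,
    OptimizerSettings,
    RemlFit,
    _neg_loglik_and_grad,
    blup_slopes,
    fixed_effect_anova,
    lrt_random_term,
    ml_deviance,
    reml_fit,
    reml_loglik_at,
    varcomp_table,
)
from richcomp.stratified_anova import per_site_regression
from richcomp.study_data import PlotRecord
from richcomp.synthetic_data import build_skeleton, simulate_responses
from tests.conftest import SMALL_DESIGN, SMALL_TRUTH, one_way_records

FAST = OptimizerSettings(n_starts=1)


class TestRemlFit:
    def test_balanced_one_way_matches_moment_oracle(self):
        # interior case: REML equals the ANOVA moment estimator
        rng = np.random.default_rng(3)
        n_groups, n_rep = 8, 6
        mus = 100 + rng.normal(0, 40, n_groups)
        records = []
        for g, mu in enumerate(mus):
            for k in range(n_rep):
                records.append(
                    PlotRecord(f"g{g}", "b1", f"g{g}-p{k}", 1, "mono",
                               float(mu + rng.normal(0, 15)), 1)
                )
        y = np.array([r.anpp for r in records]).reshape(n_groups, n_rep)
        msb = n_rep * np.var(y.mean(axis=1), ddof=1)
        msw = np.mean(np.var(y, axis=1, ddof=1) * n_rep / (n_rep - 1))
        msw = float(np.sum((y - y.mean(axis=1, keepdims=True)) ** 2) / (n_groups * (n_rep - 1)))
        oracle_between = (msb - msw) / n_rep
        assert oracle_between > 0  # interior

        fit = reml_fit(records, terms=("experiment",), settings=OptimizerSettings(n_starts=3))
        assert fit.converged
        assert fit.variances["experiment"] == pytest.approx(oracle_between, rel=1e-4)
        assert fit.variances["residual"] == pytest.approx(msw, rel=1e-4)

    def test_zero_between_group_variability(self):
        # identical group means: batch variance at the bound, residual = within
        records = one_way_records([50.0] * 6, 4, noise_sd=0.0)
        vals = [1.0, -1.0, 2.0, -2.0] * 6
        records = [
            PlotRecord(r.site_id, r.block_id, r.plot_id, r.richness,
                       r.composition_label, 50.0 + vals[i], r.composition_code)
            for i, r in enumerate(records)
        ]
        fit = reml_fit(records, terms=("experiment",), settings=FAST)
        y = np.array([r.anpp for r in records])
        assert fit.variances["experiment"] < 1e-4 * np.var(y)
        # with the batch at the bound the residual absorbs the sample variance
        assert fit.variances["residual"] == pytest.approx(float(np.var(y, ddof=1)), rel=0.05)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        skel = build_skeleton(SMALL_DESIGN[:3], sharing_fraction=0.3, seed=2)
        sim = simulate_responses(skel, SMALL_TRUTH, seed=2)
        from richcomp.reml_varcomp import _build

        frame, X, _, Gs = _build(sim.records, ("experiment", "block", "composition"))
        theta = np.log(rng.uniform(500, 5000, len(Gs) + 1))
        for reml in (True, False):
            nll, grad, *_ = _neg_loglik_and_grad(theta, frame.y, X, Gs, reml)
            for k in range(len(theta)):
                eps = 1e-6
                tp, tm = theta.copy(), theta.copy()
                tp[k] += eps
                tm[k] -= eps
                fp, *_ = _neg_loglik_and_grad(tp, frame.y, X, Gs, reml)
                fm, *_ = _neg_loglik_and_grad(tm, frame.y, X, Gs, reml)
                assert grad[k] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-6)

    def test_optimum_beats_truth(self, small_sim, small_reml_fit):
        truth_vars = [
            SMALL_TRUTH.sd_experiment**2,
            SMALL_TRUTH.sd_block**2,
            SMALL_TRUTH.sd_composition**2,
            SMALL_TRUTH.sd_richness_site**2,
            SMALL_TRUTH.sd_exp_composition**2,
            SMALL_TRUTH.sd_residual**2,
        ]
        ll_truth = reml_loglik_at(small_sim.records, small_reml_fit.terms, truth_vars)
        assert small_reml_fit.reml_loglik >= ll_truth - 1e-6

    def test_profile_unimodal_on_balanced_toy(self):
        rng = np.random.default_rng(12)
        records = one_way_records(100 + rng.normal(0, 30, 6), 5, noise_sd=10.0, seed=1)
        from richcomp.reml_varcomp import _build

        frame, X, _, Gs = _build(records, ("experiment",))
        resid_var = 100.0
        grid = np.linspace(50.0, 4000.0, 60)
        lls = [
            -_neg_loglik_and_grad(np.log([v, resid_var]), frame.y, X, Gs, True)[0]
            for v in grid
        ]
        diffs = np.sign(np.diff(lls))
        # at most one sign change: rises then falls
        changes = np.sum(np.abs(np.diff(diffs[diffs != 0])) > 0)
        assert changes <= 1

    def test_relabeling_invariance(self, small_sim):
        from dataclasses import replace

        mapping = {f"s{i:02d}": f"z{9 - i:02d}" for i in range(1, 7)}
        relabeled = [replace(r, site_id=mapping[r.site_id]) for r in small_sim.records]
        a = reml_fit(small_sim.records, settings=FAST)
        b = reml_fit(relabeled, settings=FAST)
        for term, var in a.variances.items():
            assert b.variances[term] == pytest.approx(var, rel=1e-3, abs=1e-6)

    def test_percent_shares_sum_to_100(self, small_reml_fit):
        assert sum(small_reml_fit.percent_shares.values()) == pytest.approx(100.0)
        table = varcomp_table(small_reml_fit)
        assert set(table["source"]) == set(small_reml_fit.terms) | {"residual"}

    def test_sd_is_sqrt_variance(self, small_reml_fit):
        for term, var in small_reml_fit.variances.items():
            assert small_reml_fit.sds[term] == pytest.approx(np.sqrt(var))

    def test_parameter_recovery_medians(self):
        # batches with many levels recover truth within 15% over replicates
        truth = SMALL_TRUTH
        skel = build_skeleton(SMALL_DESIGN, sharing_fraction=0.4, seed=7)
        estimates = {"composition": [], "experiment:composition": [], "residual": []}
        for rep in range(12):
            sim = simulate_responses(skel, truth, seed=100 + rep)
            fit = reml_fit(sim.records, settings=FAST)
            for term in estimates:
                estimates[term].append(fit.sds[term])
        truth_sd = {
            "composition": truth.sd_composition,
            "experiment:composition": truth.sd_exp_composition,
            "residual": truth.sd_residual,
        }
        for term, values in estimates.items():
            med = float(np.median(values))
            assert abs(med - truth_sd[term]) / truth_sd[term] < 0.15, term


@pytest.fixture(scope="module")
def small_reml_fit(small_sim):
    return reml_fit(small_sim.records, settings=FAST)


def _doctored_fit(slope, se) -> RemlFit:
    return RemlFit(
        terms=("experiment",),
        beta=np.array([0.0, slope]),
        beta_se=np.array([1.0, se]),
        variances={"experiment": 1.0, "residual": 2.0},
        sds={"experiment": 1.0, "residual": np.sqrt(2.0)},
        percent_shares={},
        blups={"experiment": np.zeros(2)},
        level_names={"experiment": ["a", "b"]},
        reml_loglik=0.0,
        converged=True,
        x_center=0.0,
        n=10,
    )


class TestFixedEffectAnova:
    def test_zero_slope_gives_zero_f(self):
        assert fixed_effect_anova(_doctored_fit(0.0, 3.0)).f == 0.0

    def test_slope_two_se_gives_f_four(self):
        res = fixed_effect_anova(_doctored_fit(6.0, 3.0))
        assert res.f == pytest.approx(4.0)
        assert res.df == 1
        assert res.ss == res.ms == pytest.approx(4.0 * 2.0)

    def test_refuses_non_converged(self):
        fit = _doctored_fit(1.0, 1.0)
        fit.converged = False
        with pytest.raises(NotConvergedError):
            fixed_effect_anova(fit)


class TestLrt:
    def test_dropping_zero_variance_batch_changes_little(self):
        rng = np.random.default_rng(4)
        records = one_way_records(100 + rng.normal(0, 30, 6), 4, noise_sd=8.0, seed=2)
        # block is constant within each site here, so its variance fits ~0
        res = lrt_random_term(records, ("experiment", "block"), "block", FAST)
        assert res.delta_deviance == pytest.approx(0.0, abs=0.2)
        assert res.p_halfmix == pytest.approx(1.0, abs=0.05)

    def test_unknown_term_rejected(self):
        records = one_way_records([10.0, 20.0], 3, noise_sd=1.0)
        with pytest.raises(KeyError):
            lrt_random_term(records, ("experiment",), "composition", FAST)

    def test_boundary_null_half_mass_at_zero(self):
        rng = np.random.default_rng(19)
        n_rep, zeros = 200, 0
        for _ in range(n_rep):
            records = one_way_records([100.0] * 8, 4, noise_sd=10.0, seed=int(rng.integers(1 << 30)))
            res = lrt_random_term(records, ("experiment",), "experiment", FAST)
            zeros += res.delta_deviance < 1e-4
        assert 0.35 < zeros / n_rep < 0.65

    def test_power_under_alternative(self):
        rng = np.random.default_rng(23)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            mus = 100 + rng.normal(0, 10, 8)  # batch SD = residual SD
            records = one_way_records(mus, 4, noise_sd=10.0, seed=int(rng.integers(1 << 30)))
            res = lrt_random_term(records, ("experiment",), "experiment", FAST)
            rejections += res.p_halfmix < 0.05
        assert rejections / n_rep > 0.4

    def test_deviance_nonnegative(self, small_sim):
        res = lrt_random_term(
            small_sim.records,
            ("experiment", "composition", "experiment:richness"),
            "composition",
            FAST,
        )
        assert res.delta_deviance >= 0.0
        assert 0.0 <= res.p_halfmix <= 1.0


class TestBlupSlopes:
    def test_zero_slope_variance_collapses_to_overall(self, small_skeleton):
        from dataclasses import replace as dc_replace

        truth = dc_replace(
            SMALL_TRUTH,
            sd_richness_site=0.0,
            sd_composition=0.0,
            sd_exp_composition=0.0,
            sd_block=0.0,
            sd_residual=5.0,
        )
        sim = simulate_responses(small_skeleton, truth, seed=6)
        fit = reml_fit(sim.records, settings=FAST)
        slopes = blup_slopes(fit)
        assert np.std(slopes.values) < 0.05 * abs(fit.beta[1])

    def test_requires_slope_batch(self, small_sim):
        fit = reml_fit(small_sim.records, terms=("experiment",), settings=FAST)
        with pytest.raises(KeyError):
            blup_slopes(fit)

    def test_shrinkage_reduces_spread(self, small_skeleton):
        tighter = 0
        n_rep = 15
        for rep in range(n_rep):
            sim = simulate_responses(small_skeleton, SMALL_TRUTH, seed=300 + rep)
            fit = reml_fit(sim.records, settings=FAST)
            blups = blup_slopes(fit)
            ols = per_site_regression(sim.records)
            ols_sd = float(np.std(ols["slope"].dropna().values, ddof=1))
            blup_sd = float(np.std(blups.values, ddof=1))
            tighter += blup_sd <= ols_sd + 1e-9
        assert tighter >= n_rep - 1

    def test_blup_no_further_from_mean_than_ols(self, reference_sim, reference_reml_fit):
        blups = blup_slopes(reference_reml_fit)
        ols = per_site_regression(reference_sim.records).set_index("site_id")["slope"]
        overall = float(reference_reml_fit.beta[1])
        ok = 0
        for site in blups.index:
            if np.isfinite(ols.get(site, np.nan)):
                ok += abs(blups[site] - overall) <= abs(ols[site] - overall) + 1e-6
        assert ok >= 0.8 * len(blups)


def test_ml_deviance_decreases_with_added_term(small_sim):
    dev_small = ml_deviance(small_sim.records, ("experiment",), FAST)
    dev_big = ml_deviance(small_sim.records, ("experiment", "composition"), FAST)
    assert dev_big <= dev_small + 1e-6
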