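"""Multimember REML: design construction, oracles, contrasts, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from routemem.errors import RankDeficiencyError
from routemem.mixedlm import (
    ModelSpec,
    _ProfiledREML,
    better_solo_comparison,
    build_design,
    contrast_from_fit,
    fit_model,
    fit_reml,
    planned_contrast,
    reml_loglik,
    residual_diagnostics,
    wald_tests,
)


def balanced_rows(n_pairs=2, response="y", rng=None):
    """Fully crossed toy: every pair observed in all condition/treatment/time
    cells at both sites; solo rows for each member bird."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in range(n_pairs):
        pair = f"p{p}"
        birds = (f"{pair}a", f"{pair}b")
        for cond, treat, tt, site in itertools.product(
            ("paired", "solo"), ("forgetting", "extra_training"),
            ("baseline", "memory_testing"), ("A", "B"),
        ):
            if cond == "paired":
                units = [(pair, birds[0], birds[1])]
            else:
                units = [(b, b, None) for b in birds]
            for unit, ba, bb in units:
                rows.append(
                    dict(
                        unit_id=unit, release_id=f"r{len(rows)}", pair_id=pair,
                        bird_a=ba, bird_b=bb, condition=cond, treatment=treat,
                        testing_time=tt, site=site, release_order=len(rows),
                        y=rng.normal(),
                    )
                )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_nine_columns_full_factorial_plus_site(self):
        df = balanced_rows()
        y, X, Z1, Z2, names, birds, pairs = build_design(df, ModelSpec(response="y"))
        assert X.shape[1] == 9
        assert names[0] == "(Intercept)"
        assert sum(":" in n for n in names) == 4  # three 2-way + one 3-way

    def test_multimember_weights(self):
        df = balanced_rows()
        y, X, Z1, Z2, names, birds, pairs = build_design(df, ModelSpec(response="y"))
        for i, (ba, bb) in enumerate(zip(df.bird_a, df.bird_b)):
            row = Z1[i]
            if isinstance(bb, str) and bb:
                assert sorted(row[row > 0]) == [0.5, 0.5]
            else:
                assert list(row[row > 0]) == [1.0]
            assert row.sum() == pytest.approx(1.0)
        assert np.all(Z2.sum(axis=1) == 1.0)

    def test_single_level_factor_raises_named_error(self):
        df = balanced_rows()
        df = df[df.site == "A"]
        with pytest.raises(RankDeficiencyError, match="site"):
            build_design(df, ModelSpec(response="y"))


class TestFitREML:
    def test_zero_variance_truth_matches_ols(self):
        # a draw whose REML optimum sits at the zero-variance boundary (with
        # finite iid data the estimated components are only *usually* zero)
        df = balanced_rows(n_pairs=3, rng=np.random.default_rng(3))
        y, X, Z1, Z2, names, *_ = build_design(df, ModelSpec(response="y"))
        fit = fit_reml(y, X, [Z1, Z2])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)
        assert fit.sigma2["individual"] == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma2["pair"] == pytest.approx(0.0, abs=1e-6)

    def test_balanced_oneway_matches_anova_closed_form(self, rng):
        # k groups x m replicates, single random intercept, X = intercept only
        k, m = 8, 6
        sig_b, sig_e = 1.5, 0.8
        u = rng.normal(0, sig_b, k)
        y = np.repeat(u, m) + rng.normal(0, sig_e, k * m) + 3.0
        X = np.ones((k * m, 1))
        Z = np.kron(np.eye(k), np.ones((m, 1)))
        fit = fit_reml(y, X, [Z], component_names=("group",))
        ybar_g = y.reshape(k, m).mean(axis=1)
        msb = m * np.sum((ybar_g - y.mean()) ** 2) / (k - 1)
        msw = np.sum((y.reshape(k, m) - ybar_g[:, None]) ** 2) / (k * (m - 1))
        np.testing.assert_allclose(fit.sigma2["resid"], msw, rtol=1e-5)
        np.testing.assert_allclose(fit.sigma2["group"], (msb - msw) / m, rtol=1e-5)

    def test_grid_search_oracle_small(self, rng):
        df = balanced_rows(n_pairs=2, rng=rng)
        y, X, Z1, Z2, *_ = build_design(df, ModelSpec(response="y"))
        # inject real structure so the optimum is interior
        y = y + Z1 @ rng.normal(0, 1.0, Z1.shape[1]) + Z2 @ rng.normal(0, 0.6, Z2.shape[1])
        fit = fit_reml(y, X, [Z1, Z2])
        grid = np.linspace(0.01, 4.0, 21)
        best = -np.inf
        for s0 in grid:
            for s1 in grid:
                for s2 in grid:
                    best = max(best, reml_loglik(y, X, [Z1, Z2], [s0, s1, s2]))
        assert fit.loglik_reml >= best - 1e-8

    def test_rescaling_equivariance(self, rng):
        df = balanced_rows(n_pairs=3, rng=rng)
        y, X, Z1, Z2, *_ = build_design(df, ModelSpec(response="y"))
        y = y + Z1 @ rng.normal(0, 0.8, Z1.shape[1])
        f1 = fit_reml(y, X, [Z1, Z2])
        c = 7.5
        f2 = fit_reml(c * y, X, [Z1, Z2])
        np.testing.assert_allclose(f2.beta, c * f1.beta, rtol=1e-4, atol=1e-7)
        np.testing.assert_allclose(
            f2.sigma2["resid"], c**2 * f1.sigma2["resid"], rtol=1e-4
        )
        np.testing.assert_allclose(
            f1.beta / f1.se, f2.beta / f2.se, rtol=1e-4, atol=1e-7
        )

    def test_duplicating_observations_preserves_beta(self, rng):
        df = balanced_rows(n_pairs=2, rng=rng)
        y, X, Z1, Z2, *_ = build_design(df, ModelSpec(response="y"))
        f1 = fit_reml(y, X, [Z1, Z2])
        f2 = fit_reml(
            np.concatenate([y, y]), np.vstack([X, X]),
            [np.vstack([Z1, Z1]), np.vstack([Z2, Z2])],
        )
        np.testing.assert_allclose(f2.beta, f1.beta, atol=1e-5)

    def test_profiled_criterion_equals_dense_loglik(self, rng):
        df = balanced_rows(n_pairs=2, rng=rng)
        y, X, Z1, Z2, *_ = build_design(df, ModelSpec(response="y"))
        prof = _ProfiledREML(y, X, [Z1, Z2])
        for g in ([0.7, 0.3], [2.5, 0.01], [0.0, 0.0]):
            ll, beta, s2, _ = prof(np.asarray(g))
            dense = reml_loglik(y, X, [Z1, Z2], [s2, g[0] * s2, g[1] * s2])
            assert ll == pytest.approx(dense, abs=1e-8)


class TestWaldAndContrasts:
    def test_wald_matches_vcov(self, rng):
        df = balanced_rows(n_pairs=3, rng=rng)
        fit = fit_model(df, ModelSpec(response="y"))
        for i, w in enumerate(wald_tests(fit)):
            assert w.estimate == fit.beta[i]
            assert w.se == pytest.approx(np.sqrt(fit.vcov[i, i]))
            assert w.t_value == pytest.approx(fit.beta[i] / fit.se[i])
            assert w.p_value == pytest.approx(
                2 * stats.norm.sf(abs(w.t_value)), rel=1e-12
            )
            assert np.sign(w.t_value) == np.sign(w.estimate) or w.estimate == 0

    def test_t_of_1_96_gives_p_of_0_05(self):
        from routemem.mixedlm import WaldResult

        w = WaldResult(term="x", estimate=1.959963984540054, se=1.0)
        assert w.p_value == pytest.approx(0.05, rel=1e-6)

    def test_releveling_preserves_loglik_and_matches_contrast_vector(self, rng):
        df = balanced_rows(n_pairs=3, rng=rng)
        df["y"] = df["y"] + (df.condition == "solo") * 0.8
        spec = ModelSpec(response="y")
        fit = fit_model(df, spec)
        res, refit = planned_contrast(
            df, spec,
            {"testing_time": "memory_testing", "treatment": "forgetting"},
            "condition[solo]",
        )
        assert refit.loglik_reml == pytest.approx(fit.loglik_reml, abs=1e-8)
        c = np.zeros(9)
        c[fit.term_names.index("condition[solo]")] = 1.0
        c[fit.term_names.index("condition[solo]:testing_time[memory_testing]")] = 1.0
        direct = contrast_from_fit(fit, c)
        assert res.estimate == pytest.approx(direct.estimate, rel=1e-6)
        assert res.se == pytest.approx(direct.se, rel=1e-4)


class TestResidualDiagnostics:
    def test_normal_residuals_rarely_rejected(self):
        n = 1000
        X = np.ones((n, 1))
        Z = np.zeros((n, 2))
        passes = 0
        n_seeds = 40
        for seed in range(n_seeds):
            y = np.random.default_rng(seed).normal(size=n)
            fit = fit_reml(y, X, [Z], component_names=("dummy",))
            fit.term_names = ["(Intercept)"]
            ks, p, qq = residual_diagnostics(fit, y, X, [Z])
            passes += p > 0.05
        assert passes / n_seeds >= 0.9

    def test_heavy_tails_usually_rejected(self):
        n = 1000
        X = np.ones((n, 1))
        Z = np.zeros((n, 2))
        rejected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            y = stats.t(df=2).rvs(n, random_state=seed)
            fit = fit_reml(y, X, [Z], component_names=("dummy",))
            ks, p, qq = residual_diagnostics(fit, y, X, [Z])
            rejected += p < 0.05
        assert rejected / n_seeds > 0.5

    def test_qq_points_sorted_monotone(self, rng):
        n = 200
        X = np.ones((n, 1))
        Z = np.zeros((n, 1))
        y = rng.normal(size=n)
        fit = fit_reml(y, X, [Z], component_names=("dummy",))
        _, _, qq = residual_diagnostics(fit, y, X, [Z])
        assert (qq.theoretical.diff().dropna() > 0).all()
        assert (qq.empirical.diff().dropna() >= 0).all()


class TestBetterSolo:
    def frame(self):
        rows = []
        for bird, nnd, so in [("pa", 120.0, 200.0), ("pb", 180.0, 150.0)]:
            rows.append(
                dict(
                    unit_id=bird, release_id=f"r_{bird}", pair_id="p0",
                    bird_a=bird, bird_b=None, condition="solo",
                    treatment="forgetting", testing_time="memory_testing",
                    site="A", release_order=1,
                    mean_nnd_m=nnd, second_order_mean_nnd_m=so,
                )
            )
        rows.append(
            dict(
                unit_id="p0", release_id="r_pair", pair_id="p0", bird_a="pa",
                bird_b="pb", condition="paired", treatment="forgetting",
                testing_time="memory_testing", site="A", release_order=2,
                mean_nnd_m=90.0, second_order_mean_nnd_m=95.0,
            )
        )
        # a pair with only one member tested solo -> excluded
        rows.append(
            dict(
                unit_id="qa", release_id="r_qa", pair_id="q0", bird_a="qa",
                bird_b=None, condition="solo", treatment="forgetting",
                testing_time="memory_testing", site="A", release_order=1,
                mean_nnd_m=140.0, second_order_mean_nnd_m=150.0,
            )
        )
        return pd.DataFrame(rows)

    def test_keeps_member_with_smaller_metric(self):
        out, logs = better_solo_comparison(self.frame(), "mean_nnd_m")
        solos = out[out.condition == "solo"]
        assert list(solos.bird_a) == ["pa"]  # 120 < 180

    def test_selection_is_metric_specific(self):
        out2, _ = better_solo_comparison(self.frame(), "second_order_mean_nnd_m")
        solos = out2[out2.condition == "solo"]
        assert list(solos.bird_a) == ["pb"]  # 150 < 200: the better bird differs

    def test_single_member_pairs_excluded_and_logged(self):
        out, logs = better_solo_comparison(self.frame(), "mean_nnd_m")
        assert not (out.bird_a == "qa").any()
        assert any("q0" in m for m in logs)
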