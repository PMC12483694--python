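"""GRM/GPCM response functions, model-implied margins, simulation, and
MML-EM estimation."""

import numpy as np
import pytest

from sisquoc import (
    GPCMItemParams,
    GRMItemParams,
    QuadratureGrid,
    fit_mml_em,
    gpcm_probs,
    grm_probs,
    model_implied_margins,
    simulate_pattern_frequencies,
)


def _expected_freqs(params, n, quad=None):
    """Model-implied expected pattern frequencies N * P(pattern)."""
    import itertools

    import pandas as pd

    quad = quad or QuadratureGrid.rectangular()
    cats = [p.n_categories for p in params]
    pats = np.array(list(itertools.product(*(range(k) for k in cats))))
    lik = np.ones((len(pats), quad.points.size))
    for j, p in enumerate(params):
        pj = grm_probs(p, quad.points) if isinstance(p, GRMItemParams) else gpcm_probs(p, quad.points)
        lik *= pj[:, pats[:, j]].T
    df = pd.DataFrame(pats, columns=[f"item{i}" for i in range(len(params))])
    df["freq"] = (lik @ quad.weights) * n
    return df


class TestResponseFunctions:
    def test_grm_symmetric_dichotomous(self):
        np.testing.assert_allclose(grm_probs(GRMItemParams(1.0, (0.0,)), 0.0), [0.5, 0.5])

    def test_grm_three_categories_at_zero(self):
        p = grm_probs(GRMItemParams(1.0, (-1.0, 1.0)), 0.0)
        np.testing.assert_allclose(p, [0.268941, 0.462117, 0.268941], atol=1e-6)

    def test_grm_limit_concentrates_on_last_category(self):
        p = grm_probs(GRMItemParams(2.0, (-1.0, 1.0)), 50.0)
        assert p[-1] == pytest.approx(1.0, abs=1e-12)

    def test_gpcm_three_categories_at_zero(self):
        p = gpcm_probs(GPCMItemParams(1.0, (-1.0, 1.0)), 0.0)
        np.testing.assert_allclose(p, [0.211942, 0.576117, 0.211942], atol=1e-6)

    def test_gpcm_zero_slope_is_uniform(self):
        for theta in (-3.0, 0.0, 2.5):
            np.testing.assert_allclose(
                gpcm_probs(GPCMItemParams(0.0, (1.0, -2.0, 0.3)), theta), 0.25
            )

    def test_dichotomous_models_coincide(self):
        theta = np.linspace(-6, 6, 101)
        for a, b in [(0.7, -1.2), (1.0, 0.0), (2.5, 1.7)]:
            np.testing.assert_allclose(
                grm_probs(GRMItemParams(a, (b,)), theta),
                gpcm_probs(GPCMItemParams(a, (b,)), theta),
                atol=1e-12,
            )

    def test_probabilities_sum_to_one_and_grm_cumulative_monotone(self, rng):
        theta = rng.normal(size=1000)
        for _ in range(20):
            k = rng.integers(2, 6)
            a = rng.uniform(0.2, 3)
            b = np.sort(rng.uniform(-3, 3, k - 1))
            b += np.arange(k - 1) * 1e-6  # guard strictness
            g = grm_probs(GRMItemParams(a, tuple(b)), theta)
            np.testing.assert_allclose(g.sum(axis=-1), 1.0, atol=1e-12)
            assert np.all(g >= 0)
            d = rng.uniform(-3, 3, k - 1)
            gp = gpcm_probs(GPCMItemParams(a, tuple(d)), theta)
            np.testing.assert_allclose(gp.sum(axis=-1), 1.0, atol=1e-12)
            assert np.all(gp >= 0)

    def test_unordered_grm_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GRMItemParams(1.0, (1.0, -1.0))


class TestModelImpliedMargins:
    def test_flat_item_gives_uniform_margin(self):
        m = model_implied_margins([GPCMItemParams(0.0, (0.0, 0.0)), GPCMItemParams(0.0, (0.0, 0.0))])
        np.testing.assert_allclose(m.univariate[0].probs, 1 / 3, atol=1e-12)

    def test_flat_items_are_independent(self):
        m = model_implied_margins([GPCMItemParams(0.0, (0.0,)), GPCMItemParams(0.0, (0.0,))])
        np.testing.assert_allclose(m.bivariate[(0, 1)].cells, 0.25, atol=1e-12)

    def test_shared_trait_induces_positive_dependence(self, rng):
        params = [GRMItemParams(2.0, (0.0,)), GRMItemParams(2.0, (0.0,))]
        quad = QuadratureGrid.rectangular(101)
        m = model_implied_margins(params, quad=quad)
        p11 = m.bivariate[(0, 1)].cells[1, 1]
        prod = m.univariate[0].probs[1] * m.univariate[1].probs[1]
        assert p11 > prod
        # Monte-Carlo oracle for the same quantity
        theta = rng.standard_normal(1_000_000)
        p1 = grm_probs(params[0], theta)[:, 1]
        p2 = grm_probs(params[1], theta)[:, 1]
        mc_p11 = float(np.mean(p1 * p2))
        assert p11 == pytest.approx(mc_p11, abs=0.002)


class TestSimulation:
    def test_flat_model_gives_uniform_margins(self, rng):
        params = [GPCMItemParams(0.0, (0.0, 0.0)) for _ in range(3)]
        df = simulate_pattern_frequencies(params, 100_000, rng)
        pj = df.groupby("item0")["freq"].sum() / 100_000
        np.testing.assert_allclose(pj, 1 / 3, atol=0.01)

    def test_fixed_seed_determinism(self):
        params = [GRMItemParams(1.0, (0.0,)), GRMItemParams(1.5, (0.5,))]
        a = simulate_pattern_frequencies(params, 1000, np.random.default_rng(5))
        b = simulate_pattern_frequencies(params, 1000, np.random.default_rng(5))
        assert (a["freq"] == b["freq"]).all()

    def test_empirical_margins_converge_to_implied(self, rng):
        params = [GRMItemParams(1.5, (-0.5, 0.7)), GRMItemParams(0.9, (0.0, 1.2))]
        df = simulate_pattern_frequencies(params, 100_000, rng)
        implied = model_implied_margins(params)
        emp0 = df.groupby("item0")["freq"].sum().to_numpy() / 100_000
        assert np.max(np.abs(emp0 - implied.univariate[0].probs)) < 0.01


class TestMmlEm:
    def test_noise_free_self_consistency_both_models(self):
        true_grm = [
            GRMItemParams(1.2, (-1.0, 0.2, 1.1)),
            GRMItemParams(1.8, (-0.4, 0.6, 1.5)),
            GRMItemParams(0.9, (-1.5, -0.2, 0.9)),
        ]
        true_gpcm = [
            GPCMItemParams(1.2, (-1.0, 0.2, 1.1)),
            GPCMItemParams(1.8, (0.6, -0.4, 1.5)),
            GPCMItemParams(0.9, (-1.5, 0.9, -0.2)),
        ]
        for model, true in (("grm", true_grm), ("gpcm", true_gpcm)):
            freqs = _expected_freqs(true, 5000)
            fit = fit_mml_em(freqs, model, tol=1e-5)
            for p, t in zip(fit.params, true):
                assert p.a == pytest.approx(t.a, abs=1e-3)
                loc_f = p.b if model == "grm" else p.d
                loc_t = t.b if model == "grm" else t.d
                np.testing.assert_allclose(loc_f, loc_t, atol=1e-3)

    def test_parameter_recovery_from_simulated_data(self):
        rng = np.random.default_rng(42)
        true = []
        for _ in range(3):
            a = rng.uniform(1, 2.5)
            b0 = rng.uniform(-1.5, -0.5)
            b = b0 + np.concatenate([[0], np.cumsum(rng.uniform(0.6, 1.2, 2))])
            true.append(GRMItemParams(a, tuple(b)))
        freqs = simulate_pattern_frequencies(true, 5000, rng)
        fit = fit_mml_em(freqs, "grm")
        fa = np.array([p.a for p in fit.params])
        ta = np.array([p.a for p in true])
        fb = np.array([p.b for p in fit.params])
        tb = np.array([p.b for p in true])
        assert np.sqrt(np.mean((fa - ta) ** 2)) < 0.15
        assert np.sqrt(np.mean((fb - tb) ** 2)) < 0.15

    def test_dichotomous_fits_attain_equal_likelihood(self, rng):
        true = [GRMItemParams(1.4, (-0.3,)), GRMItemParams(0.8, (0.6,)), GRMItemParams(1.9, (0.1,))]
        freqs = simulate_pattern_frequencies(true, 3000, rng)
        f_grm = fit_mml_em(freqs, "grm", tol=1e-5)
        f_gpcm = fit_mml_em(freqs, "gpcm", tol=1e-5)
        assert f_grm.log_likelihood == pytest.approx(f_gpcm.log_likelihood, abs=1e-4)

    def test_marginal_likelihood_ascends_every_cycle(self, rng):
        true = [GRMItemParams(1.1, (-0.5, 0.5)), GRMItemParams(1.7, (0.0, 1.0)), GRMItemParams(0.7, (-1.0, 0.3))]
        freqs = simulate_pattern_frequencies(true, 2000, rng)
        for model in ("grm", "gpcm"):
            fit = fit_mml_em(freqs, model)
            trace = np.asarray(fit.ll_trace)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_real_valued_frequencies_accepted(self):
        true = [GRMItemParams(1.0, (0.0,)), GRMItemParams(1.0, (0.5,))]
        freqs = _expected_freqs(true, 1000)  # non-integer frequencies
        assert not np.allclose(freqs["freq"], np.round(freqs["freq"]))
        fit = fit_mml_em(freqs, "grm")
        assert np.isfinite(fit.log_likelihood)

    def test_degenerate_category_warns_not_raises(self, rng):
        import pandas as pd

        # category 2 of item0 never observed
        df = pd.DataFrame(
            {"item0": [0, 0, 1, 1], "item1": [0, 1, 0, 1], "freq": [30, 20, 25, 25]}
        )
        df["item0"] = df["item0"].astype(int)
        with pytest.warns(UserWarning, match="zero observed mass"):
            # declare 3 categories by including a zero-frequency pattern
            df2 = pd.concat(
                [df, pd.DataFrame({"item0": [2], "item1": [0], "freq": [0]})],
                ignore_index=True,
            )
            fit = fit_mml_em(df2, "grm", max_cycles=200)
        assert fit.params[0].n_categories == 3
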