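"""SISQUOC sampler: margin laws, sequential fills, conservation, and
the simplex reference sampler."""

import numpy as np
import pytest
from scipy import stats

from sisquoc import (
    DirichletMixture,
    DirichletSpec,
    ItemSpec,
    MarginVector,
    frechet_bounds,
    sample_dataset,
    sample_simplex_reference,
    sample_univariate_margins,
    scale_to_counts,
    sis_fill_table,
    univariate_margin_spec,
)
from tests.conftest import CountingRng, random_margin


class TestMarginSpecs:
    def test_two_dichotomous_items_give_beta22(self):
        spec = univariate_margin_spec(0, ItemSpec.uniform(2, 2))
        assert isinstance(spec, DirichletSpec)
        np.testing.assert_allclose(spec.alphas, [2.0, 2.0])

    def test_equal_categories_aggregate_to_k(self):
        spec = univariate_margin_spec(3, ItemSpec.uniform(7, 4))
        np.testing.assert_allclose(spec.alphas, [4.0] * 4)

    def test_mixed_categories_give_equal_weight_mixture(self):
        # binary item with one 2-category and one 3-category partner
        spec = univariate_margin_spec(0, ItemSpec((2, 2, 3)))
        assert isinstance(spec, DirichletMixture)
        np.testing.assert_allclose(spec.weights, [0.5, 0.5])
        np.testing.assert_allclose(spec.components[0].alphas, [2.0, 2.0])
        np.testing.assert_allclose(spec.components[1].alphas, [3.0, 3.0])


class TestUnivariateMargins:
    def test_beta22_moments(self, rng):
        draws = np.array(
            [sample_univariate_margins(ItemSpec.uniform(2, 2), rng)[0].probs[0]
             for _ in range(10_000)]
        )
        assert draws.mean() == pytest.approx(0.5, abs=0.01)
        assert draws.var() == pytest.approx(0.05, abs=0.005)  # Beta(2,2) variance

    def test_four_category_symmetry(self, rng):
        draws = np.array(
            [sample_univariate_margins(ItemSpec.uniform(2, 4), rng)[0].probs
             for _ in range(4000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), 0.25, atol=0.01)

    def test_deterministic_under_fixed_seed(self):
        a = sample_univariate_margins(ItemSpec.uniform(3, 3), np.random.default_rng(9))
        b = sample_univariate_margins(ItemSpec.uniform(3, 3), np.random.default_rng(9))
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.probs, mb.probs)


class TestSisFill:
    def test_degenerate_margins_fully_determined(self, rng):
        t = sis_fill_table(MarginVector([1.0, 0.0]), MarginVector([0.3, 0.7]), rng)
        np.testing.assert_allclose(t.cells[0], [0.3, 0.7], atol=1e-12)
        np.testing.assert_allclose(t.cells[1], 0.0, atol=1e-12)

    def test_zero_draw_hits_lower_frechet_bound(self):
        class ZeroRng:
            def uniform(self, *a, **k):
                return 0.0

        t = sis_fill_table(MarginVector([0.6, 0.4]), MarginVector([0.7, 0.3]), ZeroRng())
        np.testing.assert_allclose(t.cells, [[0.3, 0.3], [0.4, 0.0]], atol=1e-12)

    def test_conservation_and_bounds_sweep(self, rng):
        # random shapes up to 5x5: margins reproduced, cells nonnegative,
        # every free cell inside its recursively updated Frechet interval
        for _ in range(500):
            m, n = rng.integers(2, 6, size=2)
            row = random_margin(rng, m)
            col = random_margin(rng, n)
            counter = CountingRng(rng)
            t = sis_fill_table(row, col, counter)
            assert counter.uniform_calls == (m - 1) * (n - 1)
            assert np.all(t.cells >= 0)
            np.testing.assert_allclose(t.cells.sum(axis=1), row.probs, atol=1e-10)
            np.testing.assert_allclose(t.cells.sum(axis=0), col.probs, atol=1e-10)
            partial = np.zeros_like(t.cells)
            for c in range(n - 1):
                for r_ in range(m - 1):
                    b = frechet_bounds(row, col, partial, r_, c)
                    assert b.contains(t.cells[r_, c], atol=1e-10)
                    partial[r_, c] = t.cells[r_, c]
                partial[m - 1, c] = t.cells[m - 1, c]


class TestSampleDataset:
    def test_element_counts_for_seven_four_category_items(self, rng):
        d = sample_dataset(ItemSpec.uniform(7, 4), rng)
        assert len(d.univariate) == 7
        assert sum(m.probs.size for m in d.univariate) == 28
        assert len(d.bivariate) == 21
        assert sum(t.cells.size for t in d.bivariate.values()) == 336

    def test_shared_margins_consistent_across_pairs(self, rng):
        d = sample_dataset(ItemSpec((2, 3, 4)), rng)
        for (i, j), t in d.bivariate.items():
            np.testing.assert_allclose(
                t.cells.sum(axis=1), d.univariate[i].probs, atol=1e-10
            )
            np.testing.assert_allclose(
                t.cells.sum(axis=0), d.univariate[j].probs, atol=1e-10
            )

    def test_bitwise_determinism(self):
        a = sample_dataset(ItemSpec.uniform(4, 3), np.random.default_rng(77))
        b = sample_dataset(ItemSpec.uniform(4, 3), np.random.default_rng(77))
        for ma, mb in zip(a.univariate, b.univariate):
            np.testing.assert_array_equal(ma.probs, mb.probs)
        for key in a.bivariate:
            np.testing.assert_array_equal(a.bivariate[key].cells, b.bivariate[key].cells)


class TestScaleToCounts:
    def test_simple_scaling(self, rng):
        d = sample_dataset(ItemSpec.uniform(3, 2), rng)
        c = scale_to_counts(d, 1000)
        assert c.sample_size == 1000
        key = (0, 1)
        np.testing.assert_allclose(
            c.bivariate[key].cells * 1000, d.bivariate[key].cells * 1000
        )

    def test_unit_scale_preserves_probabilities(self, rng):
        d = sample_dataset(ItemSpec.uniform(2, 2), rng)
        c = scale_to_counts(d, 1)
        np.testing.assert_array_equal(
            c.bivariate[(0, 1)].cells, d.bivariate[(0, 1)].cells
        )

    def test_integer_rounding_preserves_margin_consistency(self, rng):
        n = 997  # prime, so rounding is nontrivial
        for _ in range(20):
            d = sample_dataset(ItemSpec.uniform(3, 3), rng)
            c = scale_to_counts(d, n, integer_rounding=True)
            for (i, j), t in c.bivariate.items():
                counts = t.cells * n
                np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
                np.testing.assert_allclose(
                    counts.sum(axis=1), c.univariate[i].probs * n, atol=1e-9
                )
                np.testing.assert_allclose(
                    counts.sum(axis=0), c.univariate[j].probs * n, atol=1e-9
                )
                assert counts.sum() == pytest.approx(n)

    def test_nonpositive_sample_size_rejected(self, rng):
        d = sample_dataset(ItemSpec.uniform(2, 2), rng)
        with pytest.raises(ValueError):
            scale_to_counts(d, 0)


class TestSimplexReference:
    def test_rows_sum_to_one(self, rng):
        x = sample_simplex_reference(5, 1000, rng)
        np.testing.assert_allclose(x.sum(axis=1), 1.0, atol=1e-12)

    def test_two_cells_give_uniform_component(self, rng):
        x = sample_simplex_reference(2, 10_000, rng)
        assert stats.kstest(x[:, 0], "uniform").pvalue > 0.01

    def test_four_cells_give_beta13_marginals(self, rng):
        x = sample_simplex_reference(4, 10_000, rng)
        for k in range(4):
            assert stats.kstest(x[:, k], "beta", args=(1, 3)).pvalue > 0.01
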