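"""SISQUOC: sequential importance sampling of item-pair contingency
tables with Dirichlet-distributed margins.

The generator produces one *limited-information dataset* per draw: a
univariate category-probability vector for every item plus one bivariate
probability table for every unordered item pair, with every pair table
exactly reproducing the shared univariate margins.

The hierarchy has three steps:

1.  Univariate margins are drawn from the aggregation of the uniform
    Dirichlet over a pair table.  For a K x K table with all
    concentration parameters 1, summing across rows or columns gives a
    Dirichlet whose K parameters all equal K (Beta(2, 2) for K = 2).
    With mixed category counts the margin law is an equal-weight mixture
    of the aggregated Dirichlets contributed by each partner item.
2.  Each pair table is filled column by column; every free cell is drawn
    uniformly within its recursively updated Frechet bounds, and the
    determined cells are computed from the margin residuals.  An m x n
    table has exactly (m-1)(n-1) free cells.
3.  Steps 1-2 run over all J(J-1)/2 pairs with each item's margin drawn
    once and reused, keeping shared margins consistent.

No importance weights are applied: free cells are drawn uniformly and
the resulting tables are used directly, with distributional agreement
against the uniform-Dirichlet reference checked statistically by
:mod:`sisquoc.validation` rather than enforced by reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._exceptions import InconsistentMarginsError
from .core import ATOL_STRUCT, BivariateTable, MarginVector, frechet_bounds

__all__ = [
    "ItemSpec",
    "DirichletSpec",
    "DirichletMixture",
    "DatasetMargins",
    "univariate_margin_spec",
    "sample_univariate_margins",
    "sis_fill_table",
    "sample_dataset",
    "scale_to_counts",
    "sample_simplex_reference",
]

#: below this bound width the cell is set deterministically to the midpoint
BOUND_COLLAPSE_TOL = 1e-14


@dataclass(frozen=True)
class ItemSpec:
    """Test blueprint: the number of response categories per item."""

    categories: tuple[int, ...]

    def __post_init__(self) -> None:
        cats = tuple(int(k) for k in self.categories)
        object.__setattr__(self, "categories", cats)
        if len(cats) < 2:
            raise ValueError("need at least J = 2 items")
        if any(k < 2 for k in cats):
            raise ValueError("every item needs at least 2 categories")

    @classmethod
    def uniform(cls, n_items: int, n_categories: int) -> "ItemSpec":
        return cls((n_categories,) * n_items)

    @property
    def n_items(self) -> int:
        return len(self.categories)

    def pairs(self) -> list[tuple[int, int]]:
        return list(combinations(range(self.n_items), 2))


@dataclass(frozen=True)
class DirichletSpec:
    """Concentration parameters of a Dirichlet distribution."""

    alphas: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", a)
        if np.any(a <= 0):
            raise ValueError("Dirichlet concentration parameters must be positive")


@dataclass(frozen=True)
class DirichletMixture:
    """Finite mixture of Dirichlet components with matching dimension."""

    components: tuple[DirichletSpec, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(self.components) != w.size:
            raise ValueError("one weight per component required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > ATOL_STRUCT:
            raise ValueError("weights must be a probability vector")


@dataclass
class DatasetMargins:
    """One limited-information dataset.

    ``univariate[j]`` is item j's margin; ``bivariate[(i, j)]`` with
    i < j is the pair table whose row sums equal ``univariate[i]`` and
    column sums ``univariate[j]``.  Margins are always stored as
    probabilities; a count-scaled dataset carries ``sample_size`` and
    its count margins are ``probs * sample_size`` (see :func:`counts`).
    """

    univariate: list[MarginVector]
    bivariate: dict[tuple[int, int], BivariateTable]
    sample_size: int | None = None
    #: per-pair products of free-cell Frechet bound widths (diagnostic
    #: for potential importance reweighting; not used by the sampler)
    bound_width_products: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        j = len(self.univariate)
        expected = {(a, b) for a, b in combinations(range(j), 2)}
        if set(self.bivariate) != expected:
            raise InconsistentMarginsError(
                f"expected tables for all {len(expected)} unordered pairs"
            )
        for (a, b), tab in self.bivariate.items():
            if not tab.matches_margins(self.univariate[a], self.univariate[b]):
                raise InconsistentMarginsError(
                    f"pair ({a}, {b}) table margins disagree with shared "
                    f"univariate margins"
                )

    @property
    def n_items(self) -> int:
        return len(self.univariate)

    @property
    def item_spec(self) -> ItemSpec:
        return ItemSpec(tuple(len(m) for m in self.univariate))


def univariate_margin_spec(
    item: int, spec: ItemSpec
) -> DirichletSpec | DirichletMixture:
    """Margin distribution of one item under the uniform-Dirichlet target.

    With all items sharing K categories this is Dirichlet(K, ..., K)
    (K entries), from aggregating the all-ones concentration table over
    the partner item's K categories.  With mixed category counts it is
    an equal-weight mixture over the J - 1 partners, the component for
    partner k having all concentrations equal to K_k.
    """
    cats = spec.categories
    k_j = cats[item]
    partners = [k for i, k in enumerate(cats) if i != item]
    if len(set(partners)) == 1:
        return DirichletSpec(np.full(k_j, float(partners[0])))
    comps = tuple(DirichletSpec(np.full(k_j, float(kk))) for kk in partners)
    w = np.full(len(comps), 1.0 / len(comps))
    return DirichletMixture(comps, w)


def _draw_margin(
    law: DirichletSpec | DirichletMixture, rng: np.random.Generator
) -> MarginVector:
    if isinstance(law, DirichletSpec):
        return MarginVector(rng.dirichlet(law.alphas))
    idx = rng.choice(len(law.components), p=law.weights)
    return MarginVector(rng.dirichlet(law.components[idx].alphas))


def sample_univariate_margins(
    spec: ItemSpec, rng: np.random.Generator
) -> list[MarginVector]:
    """Draw each item's margin once, independently across items."""
    return [_draw_margin(univariate_margin_spec(j, spec), rng) for j in range(spec.n_items)]


def sis_fill_table(
    row_margins: MarginVector,
    col_margins: MarginVector,
    rng: np.random.Generator,
    row_item: int = 0,
    col_item: int = 1,
) -> BivariateTable:
    """Fill an m x n table by sequential importance sampling.

    Columns 0..n-2 are filled top to bottom: rows 0..m-2 are uniform
    draws within their Frechet bounds, row m-1 closes the column to its
    margin.  The last column is fully determined by the row residuals.
    Exactly (m-1)(n-1) uniform variates are consumed.

    Returns the table; the product of free-cell bound widths is exposed
    through :func:`sample_dataset` as a diagnostic.
    """
    tab, _ = _sis_fill(row_margins, col_margins, rng, row_item, col_item)
    return tab


def _sis_fill(
    row_margins: MarginVector,
    col_margins: MarginVector,
    rng: np.random.Generator,
    row_item: int,
    col_item: int,
) -> tuple[BivariateTable, float]:
    m, n = row_margins.k, col_margins.k
    cells = np.zeros((m, n))
    width_product = 1.0
    for c in range(n - 1):
        for r in range(m - 1):
            b = frechet_bounds(row_margins, col_margins, cells, r, c)
            if b.width < BOUND_COLLAPSE_TOL:
                # degenerate interval: deterministic midpoint, but still
                # consume the draw so the free-cell count is invariant
                rng.uniform()
                cells[r, c] = 0.5 * (b.lower + b.upper)
            else:
                cells[r, c] = b.lower + rng.uniform() * b.width
                width_product *= b.width
        cells[m - 1, c] = col_margins.probs[c] - cells[: m - 1, c].sum()
    cells[:, n - 1] = row_margins.probs - cells[:, : n - 1].sum(axis=1)
    return (
        BivariateTable(cells, row_item=row_item, col_item=col_item),
        width_product,
    )


def sample_dataset(spec: ItemSpec, rng: np.random.Generator) -> DatasetMargins:
    """Draw one limited-information dataset for the given item spec."""
    margins = sample_univariate_margins(spec, rng)
    tables: dict[tuple[int, int], BivariateTable] = {}
    widths: dict[tuple[int, int], float] = {}
    for i, j in spec.pairs():
        tables[(i, j)], widths[(i, j)] = _sis_fill(
            margins[i], margins[j], rng, i, j
        )
    return DatasetMargins(margins, tables, bound_width_products=widths)


def scale_to_counts(
    d: DatasetMargins, n: int, integer_rounding: bool = False
) -> DatasetMargins:
    """Scale probability margins by a sample size N.

    Counts are real-valued by default; with ``integer_rounding`` the
    bivariate cells are rounded by largest remainder so that every row
    and column total matches the (largest-remainder rounded) univariate
    counts and each table sums exactly to N.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if d.sample_size is not None:
        raise ValueError("dataset is already count-scaled")
    if not integer_rounding:
        return DatasetMargins(
            list(d.univariate),
            dict(d.bivariate),
            sample_size=n,
            bound_width_products=dict(d.bound_width_products),
        )
    uni = [_largest_remainder(m.probs * n, n) for m in d.univariate]
    biv = {}
    for (i, j), t in d.bivariate.items():
        biv[(i, j)] = _round_table(t.cells * n, uni[i], uni[j])
    return DatasetMargins(
        [MarginVector(u / n) for u in uni],
        {
            k: BivariateTable(c / n, row_item=k[0], col_item=k[1])
            for k, c in biv.items()
        },
        sample_size=n,
        bound_width_products=dict(d.bound_width_products),
    )


def counts(d: DatasetMargins) -> tuple[list[np.ndarray], dict[tuple[int, int], np.ndarray]]:
    """Count-valued margins of a count-scaled dataset."""
    if d.sample_size is None:
        raise ValueError("dataset is probability-valued; call scale_to_counts first")
    n = d.sample_size
    return [m.probs * n for m in d.univariate], {
        k: t.cells * n for k, t in d.bivariate.items()
    }


def _largest_remainder(x: np.ndarray, total: float) -> np.ndarray:
    """Round nonnegative reals to integers preserving their (integer) sum."""
    base = np.floor(x)
    deficit = int(round(total - base.sum()))
    if deficit > 0:
        order = np.argsort(-(x - base), kind="stable")
        base[order[:deficit]] += 1
    return base


def _round_table(cells: np.ndarray, row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Integer-round a count table so row/column sums hit given integer totals.

    Rows are rounded by largest remainder to their row totals; column
    discrepancies are then repaired by moving unit counts between rows
    within the columns, preserving row totals (a minimal transport fix).
    """
    m, n = cells.shape
    out = np.vstack([_largest_remainder(cells[r], row_tot[r]) for r in range(m)])
    col_err = out.sum(axis=0) - col_tot  # +1 means column has one too many
    # repeatedly move a unit from an over column to an under column within a row
    while np.any(col_err != 0):
        over = int(np.argmax(col_err))
        under = int(np.argmin(col_err))
        # pick the row where the move least distorts the real-valued target
        scores = (out[:, over] - cells[:, over]) - (out[:, under] - cells[:, under])
        candidates = np.where(out[:, over] > 0)[0]
        r = candidates[np.argmax(scores[candidates])]
        out[r, over] -= 1
        out[r, under] += 1
        col_err[over] -= 1
        col_err[under] += 1
    return out


def sample_simplex_reference(
    num_cells: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draws from the (num_cells - 1)-simplex.

    Normalized-exponential construction, equivalent to sorted uniform
    spacings; this is the full-information reference sampler used as the
    oracle in the validation battery.
    """
    if num_cells < 2:
        raise ValueError("need at least 2 cells")
    e = rng.exponential(size=(n_draws, num_cells))
    return e / e.sum(axis=1, keepdims=True)
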