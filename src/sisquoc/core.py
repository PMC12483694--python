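"""Probability tables with fixed margins: feasibility, Frechet bounds,
independence, association, and the cells/moments duality.

A bivariate contingency table of probabilities is constrained by its row
and column margins.  For any cell, the attainable range given the margins
(and any cells already fixed during a sequential fill) is a Frechet
interval; these intervals are the backbone of the sequential importance
sampler in :mod:`sisquoc.sampler`.

Conventions: categories are coded ``0..K-1``; for dichotomous items
category 1 is the "correct/endorse" category.  Cell ``(a, b)`` of a
bivariate table is ``P(row item = a, col item = b)``.  All indexing in
this package is 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._exceptions import (
    DimensionError,
    InfeasibleMomentsError,
    InfeasiblePartialTableError,
    InvalidMarginError,
)

#: structural tolerance for sums / margin reproduction
ATOL_STRUCT = 1e-10
#: roundoff tolerance: tiny negatives above this are clipped to zero
ATOL_CLIP = 1e-12

__all__ = [
    "MarginVector",
    "BivariateTable",
    "CellBounds",
    "MomentVector",
    "check_feasibility",
    "frechet_bounds",
    "independence_table",
    "odds_ratio_and_dependence",
    "cells_to_moments",
    "moments_to_cells",
]


@dataclass(frozen=True)
class MarginVector:
    """Univariate category-probability vector of one item.

    Parameters
    ----------
    probs : array-like of float, shape (K,)
        Category probabilities; nonnegative, summing to 1 within 1e-10,
        with K >= 2.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or p.size < 2:
            raise InvalidMarginError(
                f"margin vector must be 1-D with K >= 2 entries, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise InvalidMarginError(f"negative margin entry: {p.min()}")
        if abs(p.sum() - 1.0) > ATOL_STRUCT:
            raise InvalidMarginError(f"margin entries sum to {p.sum()!r}, not 1")

    @property
    def k(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size


@dataclass(frozen=True)
class BivariateTable:
    """An m x n table of cell probabilities for one item pair.

    Row sums reproduce the row item's univariate margin and column sums
    the column item's, each within 1e-10; the grand total is 1.
    """

    cells: np.ndarray
    row_item: int = 0
    col_item: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.cells, dtype=float)
        # one-time clipping of roundoff negatives (>= -1e-12) at finalization
        if np.any(c < 0):
            if np.any(c < -ATOL_CLIP):
                raise InvalidMarginError(f"negative cell probability: {c.min()}")
            c = np.clip(c, 0.0, None)
        object.__setattr__(self, "cells", c)
        if c.ndim != 2:
            raise DimensionError(f"bivariate table must be 2-D, got shape {c.shape}")
        if abs(c.sum() - 1.0) > ATOL_STRUCT:
            raise InvalidMarginError(f"cells sum to {c.sum()!r}, not 1")
        if not (0 <= self.row_item < self.col_item):
            raise ValueError("require 0 <= row_item < col_item")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def row_margin(self) -> MarginVector:
        return MarginVector(self.cells.sum(axis=1))

    @property
    def col_margin(self) -> MarginVector:
        return MarginVector(self.cells.sum(axis=0))

    def matches_margins(
        self, row: MarginVector, col: MarginVector, atol: float = ATOL_STRUCT
    ) -> bool:
        return bool(
            np.allclose(self.cells.sum(axis=1), row.probs, atol=atol, rtol=0)
            and np.allclose(self.cells.sum(axis=0), col.probs, atol=atol, rtol=0)
        )


@dataclass(frozen=True)
class CellBounds:
    """Closed interval [lower, upper] of feasible values for one cell."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise InfeasiblePartialTableError(
                f"invalid bounds [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float, atol: float = ATOL_CLIP) -> bool:
        return self.lower - atol <= x <= self.upper + atol


@dataclass(frozen=True)
class MomentVector:
    """Moments representation of a dichotomous item pair.

    ``mu_i`` and ``mu_j`` are the endorsement probabilities of the two
    items; ``mu_ij`` is the cross-product moment P(both = 1).  Feasibility
    requires ``max(0, mu_i + mu_j - 1) <= mu_ij <= min(mu_i, mu_j)``.
    """

    mu_i: float
    mu_j: float
    mu_ij: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_i <= 1.0 and 0.0 <= self.mu_j <= 1.0):
            raise InfeasibleMomentsError("first-order moments must lie in [0, 1]")
        lo = max(0.0, self.mu_i + self.mu_j - 1.0)
        hi = min(self.mu_i, self.mu_j)
        if not (lo - ATOL_CLIP <= self.mu_ij <= hi + ATOL_CLIP):
            raise InfeasibleMomentsError(
                f"cross moment {self.mu_ij} outside Frechet interval [{lo}, {hi}]"
            )


def check_feasibility(row_margins: MarginVector, col_margins: MarginVector) -> bool:
    """Existence condition for a probability table with the given margins.

    A nonnegative table with the prescribed row and column sums and grand
    total 1 exists iff both margin vectors individually sum to 1.  Margin
    well-formedness (nonnegativity) is enforced by :class:`MarginVector`
    itself, so for constructed inputs this reduces to the normalization
    check, stated here against raw sums for clarity.
    """
    return (
        abs(row_margins.probs.sum() - 1.0) <= ATOL_STRUCT
        and abs(col_margins.probs.sum() - 1.0) <= ATOL_STRUCT
    )


def frechet_bounds(
    row_margins: MarginVector,
    col_margins: MarginVector,
    partial_cells: np.ndarray | None,
    row: int,
    col: int,
) -> CellBounds:
    """Feasible interval for cell ``(row, col)`` in a sequential fill.

    The fill order is column-by-column: every column before ``col`` is
    complete, and within column ``col`` the rows before ``row`` are fixed.
    ``partial_cells`` holds the fixed cells (entries outside the fill
    prefix are ignored); ``None`` means an empty table.

    Writing ``r_a`` for row a's residual margin (margin minus its fixed
    cells) and ``c`` for column ``col``'s residual, the interval is::

        lower = max(0, c - sum of residuals of rows below ``row``)
        upper = min(r_row, c)

    which for an empty table reduces to the classical closed-form Frechet
    bounds ``[max(0, pi_r + pi_c - 1), min(pi_r, pi_c)]`` of a 2 x 2 cell.
    """
    m, n = row_margins.k, col_margins.k
    if partial_cells is None:
        partial_cells = np.zeros((m, n))
    partial = np.asarray(partial_cells, dtype=float)

    # residual row margins after subtracting fixed cells in earlier columns
    row_resid = row_margins.probs - partial[:, :col].sum(axis=1)
    # residual column margin after cells already fixed above in this column
    col_resid = col_margins.probs[col] - partial[:row, col].sum()

    lower = max(0.0, col_resid - row_resid[row + 1 :].sum())
    upper = min(row_resid[row], col_resid)
    if upper < lower:
        if lower - upper <= 1e-12:  # roundoff collapse
            mid = 0.5 * (lower + upper)
            lower = upper = mid
        else:
            raise InfeasiblePartialTableError(
                f"cell ({row}, {col}): bounds [{lower}, {upper}] are empty"
            )
    return CellBounds(max(0.0, lower), max(0.0, upper))


def independence_table(
    row_margins: MarginVector, col_margins: MarginVector, row_item: int = 0, col_item: int = 1
) -> BivariateTable:
    """Outer-product (independence) table for the given margins."""
    cells = np.outer(row_margins.probs, col_margins.probs)
    return BivariateTable(cells, row_item=row_item, col_item=col_item)


def odds_ratio_and_dependence(table: BivariateTable) -> tuple[float, str]:
    """Odds ratio and quadrant-dependence label of a 2 x 2 table.

    Returns ``(alpha, label)`` with ``alpha = p11 p22 / (p12 p21)`` and
    label ``"independent"`` when alpha is within 1e-10 of 1, ``"PQD"``
    (positively quadrant dependent) when alpha > 1 and ``"NQD"`` when
    alpha < 1.  A zero denominator with positive numerator yields +inf.
    """
    if table.shape != (2, 2):
        raise DimensionError(f"odds ratio requires a 2x2 table, got {table.shape}")
    # cell (a, b) = P(row=a, col=b); classical 2x2 layout indexes category 1 first
    p = table.cells
    num = p[1, 1] * p[0, 0]
    den = p[1, 0] * p[0, 1]
    if den == 0.0:
        alpha = math.inf if num > 0 else math.nan
    else:
        alpha = num / den
    if alpha != alpha:  # 0/0: degenerate table, treat as independent
        return 1.0, "independent"
    if abs(alpha - 1.0) <= ATOL_STRUCT:
        return alpha, "independent"
    return alpha, "PQD" if alpha > 1.0 else "NQD"


def cells_to_moments(table: BivariateTable) -> MomentVector:
    """Moments representation of a 2 x 2 table.

    ``mu_i = P(row item = 1)``, ``mu_j = P(col item = 1)``,
    ``mu_ij = P(both = 1)``.
    """
    if table.shape != (2, 2):
        raise DimensionError(f"moments require a 2x2 table, got {table.shape}")
    p = table.cells
    return MomentVector(
        mu_i=p[1, 0] + p[1, 1], mu_j=p[0, 1] + p[1, 1], mu_ij=p[1, 1]
    )


def moments_to_cells(m: MomentVector, row_item: int = 0, col_item: int = 1) -> BivariateTable:
    """Invert :func:`cells_to_moments`; exact to roundoff."""
    p11 = m.mu_ij
    p10 = m.mu_i - m.mu_ij
    p01 = m.mu_j - m.mu_ij
    p00 = 1.0 - m.mu_i - m.mu_j + m.mu_ij
    cells = np.array([[p00, p01], [p10, p11]])
    return BivariateTable(cells, row_item=row_item, col_item=col_item)
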