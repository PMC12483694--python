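"""Iterative proportional fitting: reconstruct a full multinomial joint
distribution over response patterns from univariate and bivariate margins.

Many joints share the same first- and second-order margins; IPFP starting
from the maximally uninformative all-ones array converges to one of them,
and for strictly positive targets the fitted joint is strictly positive,
so no response pattern is ruled out a priori.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import InconsistentMarginsError
from .core import BivariateTable, MarginVector
from .sampler import DatasetMargins

__all__ = ["JointTable", "ipfp_fit", "joint_to_margins", "joint_to_pattern_frequencies"]


@dataclass
class JointTable:
    """Joint probability array over all response patterns.

    ``probs`` has shape ``(K_1, ..., K_J)``; entry ``probs[x_1, ..., x_J]``
    is the probability of the response pattern ``(x_1, ..., x_J)``.
    """

    probs: np.ndarray
    iterations: int = 0
    max_change: float = np.nan
    converged: bool = True
    max_margin_residual: float = np.nan

    @property
    def n_items(self) -> int:
        return self.probs.ndim


def _pair_marginal(probs: np.ndarray, i: int, j: int) -> np.ndarray:
    axes = tuple(a for a in range(probs.ndim) if a not in (i, j))
    return probs.sum(axis=axes)


def ipfp_fit(
    margins: DatasetMargins, epsilon: float = 1e-8, max_iter: int = 10_000
) -> JointTable:
    """Fit a joint pattern distribution matching all bivariate tables.

    Starting from the all-ones array, each sweep visits the item pairs in
    lexicographic order and rescales the joint so its (i, j) collapse
    matches the target pair table (0/0 slices are left unchanged).  The
    array is renormalized after every sweep; iteration stops when the max
    absolute change in fitted pattern probabilities between consecutive
    sweeps drops below ``epsilon``.

    Univariate margins are implied by the bivariate tables and are not
    fitted separately; shared-margin consistency is validated up front
    (it is a construction invariant of :class:`~sisquoc.sampler.DatasetMargins`,
    revalidated here so hand-built inputs fail before iteration).
    """
    spec = margins.item_spec
    for (i, j), tab in margins.bivariate.items():
        if not tab.matches_margins(margins.univariate[i], margins.univariate[j]):
            raise InconsistentMarginsError(
                f"pair ({i}, {j}) disagrees with univariate margins"
            )

    shape = tuple(spec.categories)
    probs = np.ones(shape)
    probs /= probs.sum()
    pairs = sorted(margins.bivariate)
    targets = {p: margins.bivariate[p].cells for p in pairs}
    # zero target cells restrict the support; positivity is then relaxed
    strictly_positive = all(np.all(t > 0) for t in targets.values())

    it = 0
    max_change = np.inf
    for it in range(1, max_iter + 1):
        prev = probs.copy()
        for i, j in pairs:
            cur = _pair_marginal(probs, i, j)
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(cur > 0, targets[(i, j)] / np.where(cur > 0, cur, 1.0), 0.0)
                # 0/0: leave slice unchanged
                factor = np.where((cur == 0) & (targets[(i, j)] == 0), 1.0, factor)
            # broadcast factor over the remaining axes
            idx = [np.newaxis] * probs.ndim
            idx[i] = slice(None)
            idx[j] = slice(None)
            probs = probs * factor[tuple(idx)]
        probs /= probs.sum()
        max_change = float(np.max(np.abs(probs - prev)))
        if max_change < epsilon:
            break
    converged = max_change < epsilon
    if strictly_positive:
        # strictly positive targets imply a strictly positive limit, but
        # repeated rescaling can underflow a pattern to an exact zero;
        # restore representable positivity once, after iteration, so the
        # floor cannot feed back into the sweep dynamics
        np.clip(probs, 2.2250738585072014e-308, None, out=probs)
        probs /= probs.sum()

    resid = max(
        float(np.max(np.abs(_pair_marginal(probs, i, j) - targets[(i, j)])))
        for i, j in pairs
    )
    return JointTable(
        probs,
        iterations=it,
        max_change=max_change,
        converged=converged,
        max_margin_residual=resid,
    )


def joint_to_margins(joint: JointTable | np.ndarray) -> DatasetMargins:
    """Collapse a joint pattern array to its univariate and bivariate margins."""
    probs = joint.probs if isinstance(joint, JointTable) else np.asarray(joint, float)
    j = probs.ndim
    uni = [
        MarginVector(probs.sum(axis=tuple(a for a in range(j) if a != i)))
        for i in range(j)
    ]
    biv = {
        (a, b): BivariateTable(_pair_marginal(probs, a, b), row_item=a, col_item=b)
        for a, b in itertools.combinations(range(j), 2)
    }
    return DatasetMargins(uni, biv)


def joint_to_pattern_frequencies(joint: JointTable, n: int) -> pd.DataFrame:
    """Expected pattern frequencies N * P(pattern), lexicographic order.

    Returns a DataFrame with one column per item (category codes) and a
    ``freq`` column of real-valued expected frequencies.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    probs = joint.probs
    patterns = list(itertools.product(*(range(k) for k in probs.shape)))
    df = pd.DataFrame(patterns, columns=[f"item{i}" for i in range(probs.ndim)])
    df["freq"] = probs.reshape(-1) * n
    return df
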