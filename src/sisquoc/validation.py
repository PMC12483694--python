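"""Statistical validation battery for the SISQUOC sampler.

Compares sampled tables against the theoretical uniform Dirichlet over
the cell simplex (and against the full-information simplex reference
sampler): Kolmogorov-Smirnov tests per margin, a chi-square uniformity
check on binned cell coordinates, a histogram Kullback-Leibler
divergence estimate on the margin coordinate, and maximum-likelihood
recovery of the Dirichlet concentration parameters.

Binning is equal-probability under the reference distribution (robust
near the simplex boundary); the plug-in binned KL estimate carries the
well-known positive bias of about (n_bins - 1) / (2 n) even under the
null, which sets the scale of the reported values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from ._exceptions import SisquocError

__all__ = [
    "ValidationReport",
    "ks_univariate",
    "chi_square_uniformity",
    "kl_divergence_estimate",
    "dirichlet_alpha_mle",
    "validate_2x2_sampler",
]


@dataclass
class ValidationReport:
    """Summary of one run of the battery (2 x 2 dichotomous pair case)."""

    n_draws: int
    seed: int
    ks_margins: list[tuple[float, float]]  # (statistic, p) per univariate margin
    ks_two_sample_cells: list[tuple[float, float]]  # vs simplex reference, per cell
    chi_square: tuple[float, float]
    kl: float
    alpha_mle: np.ndarray

    def margins_pass(self, alpha: float = 0.05) -> bool:
        return all(p > alpha for _, p in self.ks_margins)


_REFERENCES = {
    "uniform": lambda: stats.uniform(0, 1),
}


def _reference_dist(reference: str | stats.rv_continuous | object):
    """Resolve a reference distribution: 'beta(a,b)', 'uniform', or frozen rv."""
    if hasattr(reference, "cdf"):
        return reference
    if not isinstance(reference, str):
        raise ValueError(f"unknown reference: {reference!r}")
    name = reference.strip().lower()
    if name in _REFERENCES:
        return _REFERENCES[name]()
    if name.startswith("beta(") and name.endswith(")"):
        a, b = (float(x) for x in name[5:-1].split(","))
        return stats.beta(a, b)
    raise ValueError(f"unknown reference distribution: {reference!r}")


def ks_univariate(samples: np.ndarray, reference) -> tuple[float, float]:
    """One-sample KS test of margin values against a named reference.

    ``reference`` may be ``"beta(a,b)"``, ``"uniform"`` or any frozen
    scipy distribution.  The Beta family covers every aggregated-
    Dirichlet margin law arising in this package.
    """
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dist = _reference_dist(reference)
    res = stats.kstest(x, dist.cdf)
    return float(res.statistic), float(res.pvalue)


def _equal_prob_edges(dist, n_bins: int) -> np.ndarray:
    return dist.ppf(np.linspace(0.0, 1.0, n_bins + 1))


def chi_square_uniformity(
    samples: np.ndarray, n_bins: int = 5, marginal=None
) -> tuple[float, float]:
    """Chi-square goodness of fit on binned cell coordinates.

    Each coordinate of the sampled probability vectors is binned into
    ``n_bins`` equal-probability bins under the theoretical Dirichlet
    cell marginal (Beta(1, C-1) for the uniform Dirichlet over C cells),
    bin occupancies are averaged across coordinates, and a one-sample
    chi-square against the uniform expectation is computed on the
    averaged counts.
    """
    x = np.atleast_2d(np.asarray(samples, float))
    n, c = x.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    dist = marginal if marginal is not None else stats.beta(1, c - 1)
    edges = _equal_prob_edges(dist, n_bins)
    counts = np.zeros(n_bins)
    for k in range(c):
        counts += np.histogram(x[:, k], edges)[0]
    counts /= c  # averaged occupancies across coordinates
    expected = n / n_bins
    if expected < 5:
        import warnings

        warnings.warn("expected bin count below 5; chi-square may be unreliable")
    stat = float(np.sum((counts - expected) ** 2 / expected))
    p = float(stats.chi2.sf(stat, n_bins - 1))
    return stat, p


def kl_divergence_estimate(
    samples: np.ndarray,
    reference_alphas: np.ndarray | list[float],
    n_bins: int = 5,
    margin_axis: tuple[int, ...] | None = None,
) -> float:
    """Histogram KL divergence of sampled tables from a Dirichlet reference.

    The comparison is made on the margin coordinate: each sampled
    probability vector is collapsed to the sum over ``margin_axis``
    (default: the first half of the cells, i.e. the row margin of a
    flattened two-way table), whose reference law is the aggregated Beta
    by the Dirichlet aggregation property.  That coordinate is binned
    into equal-probability bins under the reference, and the discrete
    plug-in KL  sum p-hat log(p-hat / p_ref)  is returned (0 log 0 = 0).
    """
    x = np.atleast_2d(np.asarray(samples, float))
    n, c = x.shape
    if n < 100:
        raise ValueError("need at least 100 draws for a stable estimate")
    alphas = np.asarray(reference_alphas, float)
    if alphas.size != c:
        raise ValueError("one concentration parameter per cell required")
    if margin_axis is None:
        margin_axis = tuple(range(c // 2))
    a1 = alphas[list(margin_axis)].sum()
    a2 = alphas.sum() - a1
    ref = stats.beta(a1, a2)
    coord = x[:, list(margin_axis)].sum(axis=1)
    edges = _equal_prob_edges(ref, n_bins)
    phat = np.histogram(coord, edges)[0] / n
    pref = 1.0 / n_bins
    mask = phat > 0
    return float(np.sum(phat[mask] * np.log(phat[mask] / pref)))


def dirichlet_alpha_mle(
    samples: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Maximum-likelihood Dirichlet concentration parameters.

    Fixed-point iteration on the digamma stationarity conditions
    (each update inverts the digamma by Newton), started from the
    method-of-moments estimate.  Zero components are clipped at 1e-12
    with a warning.
    """
    x = np.atleast_2d(np.asarray(samples, float))
    if x.shape[0] < 10:
        raise ValueError("need at least 10 draws")
    if np.any(x <= 0):
        import warnings

        warnings.warn("clipping nonpositive components at 1e-12")
        x = np.clip(x, 1e-12, None)
        x = x / x.sum(axis=1, keepdims=True)
    logp = np.log(x).mean(axis=0)
    m = x.mean(axis=0)
    v = x.var(axis=0)
    s = float(np.mean(m * (1 - m) / np.clip(v, 1e-300, None) - 1))
    a = np.clip(m * max(s, 1e-3), 1e-6, None)
    for _ in range(max_iter):
        target = digamma(a.sum()) + logp
        newa = _inv_digamma(target)
        if np.max(np.abs(newa - a)) < tol:
            return newa
        a = newa
    raise SisquocError(
        f"Dirichlet MLE did not converge in {max_iter} iterations "
        f"(last alphas {a}, max step {np.max(np.abs(newa - a))})"
    )


def _inv_digamma(y: np.ndarray, iters: int = 30) -> np.ndarray:
    # Minka's initialization, then Newton
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(iters):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def validate_2x2_sampler(
    n_draws: int = 10_000, seed: int = 1, n_bins: int = 5
) -> ValidationReport:
    """Run the full battery on SISQUOC 2 x 2 output.

    Draws ``n_draws`` tables from the two-dichotomous-item sampler and
    the same number of Dirichlet(1,1,1,1) reference points (via the
    simplex reference sampler, whose law is exactly that Dirichlet), and
    reports per-margin one-sample KS against Beta(2,2), per-cell
    two-sample KS, the chi-square uniformity check, the binned KL
    estimate, and the Dirichlet alpha MLE.
    """
    from .sampler import ItemSpec, sample_dataset, sample_simplex_reference

    rng = np.random.default_rng(seed)
    spec = ItemSpec.uniform(2, 2)
    cells = np.empty((n_draws, 4))
    margins = np.empty((n_draws, 2))
    for i in range(n_draws):
        d = sample_dataset(spec, rng)
        cells[i] = d.bivariate[(0, 1)].cells.reshape(-1)
        margins[i, 0] = d.univariate[0].probs[0]
        margins[i, 1] = d.univariate[1].probs[0]
    ref = sample_simplex_reference(4, n_draws, rng)

    ks_m = [ks_univariate(margins[:, j], "beta(2,2)") for j in range(2)]
    ks2 = []
    for k in range(4):
        r = stats.ks_2samp(cells[:, k], ref[:, k])
        ks2.append((float(r.statistic), float(r.pvalue)))
    chi = chi_square_uniformity(cells, n_bins=n_bins)
    kl = kl_divergence_estimate(cells, np.ones(4), n_bins=n_bins)
    alpha = dirichlet_alpha_mle(cells)
    return ValidationReport(
        n_draws=n_draws,
        seed=seed,
        ks_margins=ks_m,
        ks_two_sample_cells=ks2,
        chi_square=chi,
        kl=kl,
        alpha_mle=alpha,
    )
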