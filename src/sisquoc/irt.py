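"""Graded response model (GRM) and generalized partial credit model
(GPCM): category response functions, model-implied margins, simulation,
and marginal maximum likelihood estimation via Bock-Aitkin EM.

Both models are unidimensional with a standard-normal latent trait and
use the pure logistic metric (no 1.7 scaling constant).  The GRM builds
category probabilities from cumulative two-parameter logistic curves
with ordered thresholds ``b_1 < ... < b_{K-1}``::

    P(X >= k | theta) = 1 / (1 + exp(-a (theta - b_k)))
    P(X = k) = P(X >= k) - P(X >= k + 1)

The GPCM uses adjacent-category logits with unordered step parameters::

    P(X = k | theta)  propto  exp( sum_{h=1..k} a (theta - d_h) )

For K = 2 both reduce to the same 2PL and are numerically identical.

Estimation integrates the trait out over a fixed rectangular quadrature
grid (default 49 points on [-6, 6] with standard-normal weights).  The
E-step attributes each pattern's frequency to quadrature points by the
posterior of theta; the M-step maximizes each item's expected
complete-data log-likelihood by per-item Newton ascent with analytic
gradients and Hessians, step-halving, and a guaranteed-ascent scoring
fallback when the exact Hessian is indefinite.
Frequencies may be real-valued, as produced by IPFP reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .core import ATOL_STRUCT, BivariateTable, MarginVector
from .sampler import DatasetMargins

__all__ = [
    "GRMItemParams",
    "GPCMItemParams",
    "QuadratureGrid",
    "FitResult",
    "grm_probs",
    "gpcm_probs",
    "model_implied_margins",
    "simulate_pattern_frequencies",
    "fit_mml_em",
]

ModelName = Literal["grm", "gpcm"]

# stability bounds for the M-step
SLOPE_BOUNDS = (0.01, 50.0)
LOCATION_BOUNDS = (-20.0, 20.0)


@dataclass(frozen=True)
class GRMItemParams:
    """Slope and strictly increasing thresholds (trait units)."""

    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b)
        object.__setattr__(self, "b", b)
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError(f"GRM thresholds must be strictly increasing: {b}")

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class GPCMItemParams:
    """Slope and step parameters (no ordering constraint)."""

    a: float
    d: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", tuple(float(x) for x in self.d))

    @property
    def n_categories(self) -> int:
        return len(self.d) + 1


ItemParams = GRMItemParams | GPCMItemParams


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature points with standard-normal prior weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        w = np.asarray(self.weights, float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0) or abs(w.sum() - 1.0) > ATOL_STRUCT:
            raise ValueError("quadrature weights must be nonnegative and sum to 1")

    @classmethod
    def rectangular(cls, n_points: int = 49, lo: float = -6.0, hi: float = 6.0) -> "QuadratureGrid":
        """Equally spaced points with renormalized normal density weights."""
        pts = np.linspace(lo, hi, n_points)
        w = norm.pdf(pts)
        return cls(pts, w / w.sum())


@dataclass
class FitResult:
    """Outcome of one MML-EM fit."""

    params: list[ItemParams]
    log_likelihood: float
    cycles: int
    converged: bool
    max_change: float
    model: str = ""
    bounded: bool = False  # a parameter ended on a stability bound
    ll_trace: list[float] = field(default_factory=list)  # marginal LL per cycle


def grm_probs(p: GRMItemParams, theta: float | np.ndarray) -> np.ndarray:
    """GRM category probabilities; last axis indexes the K categories."""
    theta = np.asarray(theta, float)
    b = np.asarray(p.b)
    # cumulative P(X >= k), k = 1..K-1
    cum = expit(p.a * (theta[..., None] - b))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    star = np.concatenate([ones, cum, zeros], axis=-1)
    return star[..., :-1] - star[..., 1:]


def gpcm_probs(p: GPCMItemParams, theta: float | np.ndarray) -> np.ndarray:
    """GPCM category probabilities; last axis indexes the K categories."""
    theta = np.asarray(theta, float)
    d = np.asarray(p.d)
    steps = p.a * (theta[..., None] - d)  # (..., K-1)
    zeros = np.zeros(theta.shape + (1,))
    s = np.concatenate([zeros, np.cumsum(steps, axis=-1)], axis=-1)
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _item_probs(p: ItemParams, theta: np.ndarray) -> np.ndarray:
    return grm_probs(p, theta) if isinstance(p, GRMItemParams) else gpcm_probs(p, theta)


def model_implied_margins(
    params: Sequence[ItemParams],
    model: ModelName | None = None,
    quad: QuadratureGrid | None = None,
) -> DatasetMargins:
    """Univariate and bivariate margins implied by an item-parameter set.

    Under conditional independence given theta,
    ``pi_jk = sum_q w_q P_jk(theta_q)`` and
    ``pi_{jk,j'k'} = sum_q w_q P_jk(theta_q) P_j'k'(theta_q)``.
    ``model`` is accepted for symmetry with :func:`fit_mml_em` but the
    parameter objects themselves determine each item's response function.
    """
    quad = quad or QuadratureGrid.rectangular()
    w = quad.weights
    pj = [_item_probs(p, quad.points) for p in params]  # each (Q, K_j)
    uni = [MarginVector(w @ p) for p in pj]
    biv = {}
    for i in range(len(params)):
        for j in range(i + 1, len(params)):
            cells = np.einsum("q,qa,qb->ab", w, pj[i], pj[j])
            biv[(i, j)] = BivariateTable(cells, row_item=i, col_item=j)
    return DatasetMargins(uni, biv)


def simulate_pattern_frequencies(
    params: Sequence[ItemParams],
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate N respondents and return integer pattern counts.

    Each respondent draws theta ~ N(0, 1) and responds to every item
    independently given theta.  Patterns with zero count are included so
    the table always enumerates the full pattern space.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    theta = rng.standard_normal(n)
    cats = [p.n_categories for p in params]
    resp = np.empty((n, len(params)), dtype=int)
    for j, p in enumerate(params):
        probs = _item_probs(p, theta)  # (n, K_j)
        u = rng.uniform(size=n)
        resp[:, j] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    # tabulate over the full lexicographic pattern space
    mult = np.cumprod([1] + cats[::-1][:-1])[::-1]
    flat = resp @ mult
    counts = np.bincount(flat, minlength=int(np.prod(cats)))
    import itertools

    patterns = list(itertools.product(*(range(k) for k in cats)))
    df = pd.DataFrame(patterns, columns=[f"item{i}" for i in range(len(params))])
    df["freq"] = counts
    return df


# ---------------------------------------------------------------------------
# MML-EM estimation
# ---------------------------------------------------------------------------


def _start_values(
    freqs: np.ndarray, patterns: np.ndarray, cats: Sequence[int], model: ModelName
) -> list[ItemParams]:
    """Slopes 1.0; locations from observed univariate margins.

    GRM thresholds are set so the 2PL curves at theta = 0 match the
    observed upper-tail proportions; GPCM steps reuse the same values.
    """
    n = freqs.sum()
    out: list[ItemParams] = []
    for j, k in enumerate(cats):
        pj = np.bincount(patterns[:, j], weights=freqs, minlength=k) / n
        tail = 1.0 - np.cumsum(pj)[:-1]  # P(X >= k), k = 1..K-1
        tail = np.clip(tail, 1e-3, 1 - 1e-3)
        b = -np.log(tail / (1 - tail))
        # enforce strict increase for the GRM start
        for i in range(1, b.size):
            if b[i] <= b[i - 1]:
                b[i] = b[i - 1] + 1e-3
        if model == "grm":
            out.append(GRMItemParams(1.0, tuple(b)))
        else:
            out.append(GPCMItemParams(1.0, tuple(b)))
    return out


def _grm_ll_grad_hess(x: np.ndarray, r: np.ndarray, theta: np.ndarray, k: int):
    """Expected complete-data LL, gradient, Hessian for one GRM item.

    Parameters are in natural (a, b_1..b_{K-1}) coordinates; ordering is
    handled by the step-halving Newton driver, not by reparameterization.
    """
    a, b = x[0], x[1:]
    q = theta.size
    z = a * (theta[:, None] - b)  # (Q, K-1)
    c = expit(z)
    phi = c * (1 - c)
    star = np.concatenate([np.ones((q, 1)), c, np.zeros((q, 1))], axis=1)
    # floor keeps log finite and r/P^2 overflow-free far outside the bounds
    probs = np.clip(star[:, :-1] - star[:, 1:], 1e-120, None)  # (Q, K)
    ll = float(np.sum(r * np.log(probs)))
    gp = r / probs  # (Q, K)

    # dP_k/dt = dstar_k/dt - dstar_{k+1}/dt; star_m (m=1..K-1) = c_{m-1 col}
    # dLL/dstar_m = gp[:, m] - gp[:, m-1]  (enters P_{m-1} with -, P_m with +)
    coef = gp[:, 1:] - gp[:, :-1]  # (Q, K-1), column m-1 <-> star_m
    tb = theta[:, None] - b
    dll_da = float(np.sum(coef * phi * tb))
    dll_db = -a * np.sum(coef * phi, axis=0)  # (K-1,)
    grad = np.concatenate([[dll_da], dll_db])

    # Curvature: Gauss-Newton / empirical-information part
    # -sum_qk (r/P^2) dP dP', negative semidefinite by construction, so
    # the scoring direction is always an ascent direction (the remaining
    # second-order terms of the exact Hessian are dropped deliberately)
    n1 = k - 1
    t_mat = np.zeros((k, q, k))  # dP tensor: T[param, q, category]
    dca = phi * tb  # (Q, K-1) = dc_m/da
    dcb = -a * phi  # dc_m/db_m
    for m in range(n1):
        # star_{m+1} enters P_m with -1 and P_{m+1} with +1
        t_mat[0, :, m] -= dca[:, m]
        t_mat[0, :, m + 1] += dca[:, m]
        t_mat[1 + m, :, m] -= dcb[:, m]
        t_mat[1 + m, :, m + 1] += dcb[:, m]
    w2 = gp / probs
    h_nsd = -np.einsum("qk,tqk,uqk->tu", w2, t_mat, t_mat)
    # exact Hessian adds the (r/P) d2P remainder: d2c terms for (a,a),
    # (a,b_m) and (b_m,b_m) with the same +/- category pattern
    psi = phi * (1 - 2 * c)
    d2ca = psi * tb**2
    d2cab = psi * tb * (-a) - phi
    d2cb = a**2 * psi
    sel = coef  # (gp_{m+1} - gp_m) multiplies d2c_m
    h = h_nsd.copy()
    h[0, 0] += float(np.sum(sel * d2ca))
    hab = np.sum(sel * d2cab, axis=0)
    h[0, 1:] += hab
    h[1:, 0] += hab
    h[np.arange(1, k), np.arange(1, k)] += np.sum(sel * d2cb, axis=0)
    return ll, grad, h, h_nsd


def _grm_ll(x: np.ndarray, r: np.ndarray, theta: np.ndarray, k: int) -> float:
    a, b = x[0], x[1:]
    c = expit(a * (theta[:, None] - b))
    star = np.concatenate([np.ones((theta.size, 1)), c, np.zeros((theta.size, 1))], axis=1)
    probs = np.clip(star[:, :-1] - star[:, 1:], 1e-120, None)
    return float(np.sum(r * np.log(probs)))


def _gpcm_ll_grad_hess(x: np.ndarray, r: np.ndarray, theta: np.ndarray, k: int):
    """Expected complete-data LL, gradient, Hessian for one GPCM item."""
    a, d = x[0], x[1:]
    q = theta.size
    steps = a * (theta[:, None] - d)
    s = np.concatenate([np.zeros((q, 1)), np.cumsum(steps, axis=1)], axis=1)
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    probs = e / e.sum(axis=1, keepdims=True)
    ll = float(np.sum(r * np.log(np.clip(probs, 1e-300, None))))
    rq = r.sum(axis=1)

    # ds tensor: DS[t, q, cat]; s_k = a (k theta - D_k), D_k = sum_{h<=k} d_h
    kk = np.arange(k)
    dcum = np.concatenate([[0.0], np.cumsum(d)])
    ds = np.zeros((k, q, k))
    ds[0] = (kk * theta[:, None] - dcum)  # d s_k / d a
    for h in range(1, k):  # d s_k / d d_h = -a for cat >= h
        ds[h, :, h:] = -a
    ev = np.einsum("qk,tqk->tq", probs, ds)  # E_q[ds_t]
    grad = np.einsum("qk,tqk->t", r, ds) - ev @ rq
    # scoring curvature: -sum_q rq Cov_q(ds), negative semidefinite; the
    # bilinear a x d cross term of the exact Hessian is dropped so the
    # scoring direction always ascends
    m2 = np.einsum("qk,tqk,uqk->tuq", probs, ds, ds)
    cov = m2 - ev[:, None, :] * ev[None, :, :]
    h_nsd = -np.einsum("tuq,q->tu", cov, rq)
    # exact Hessian adds the bilinear a x d cross term d2s_k/da dd_h = -1[k>=h]
    tail_r = np.cumsum(r[:, ::-1], axis=1)[:, ::-1]
    tail_p = np.cumsum(probs[:, ::-1], axis=1)[:, ::-1]
    mixed = -tail_r[:, 1:].sum(axis=0) + (rq[:, None] * tail_p[:, 1:]).sum(axis=0)
    h = h_nsd.copy()
    h[0, 1:] += mixed
    h[1:, 0] += mixed
    return ll, grad, h, h_nsd


def _gpcm_ll(x: np.ndarray, r: np.ndarray, theta: np.ndarray, k: int) -> float:
    a, d = x[0], x[1:]
    steps = a * (theta[:, None] - d)
    s = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    probs = e / e.sum(axis=1, keepdims=True)
    return float(np.sum(r * np.log(np.clip(probs, 1e-300, None))))


def _grm_feasible(x: np.ndarray) -> bool:
    a, b = x[0], x[1:]
    return (
        SLOPE_BOUNDS[0] <= a <= SLOPE_BOUNDS[1]
        and np.all(np.diff(b) > 0)
        and LOCATION_BOUNDS[0] <= b[0]
        and b[-1] <= LOCATION_BOUNDS[1]
    )


def _gpcm_feasible(x: np.ndarray) -> bool:
    return (
        SLOPE_BOUNDS[0] <= x[0] <= SLOPE_BOUNDS[1]
        and np.all(np.abs(x[1:]) <= LOCATION_BOUNDS[1])
    )


def _newton_mstep(
    x0: np.ndarray,
    llgh,
    ll_only,
    feasible,
    r: np.ndarray,
    theta: np.ndarray,
    k: int,
    gtol: float = 1e-8,
    max_inner: int = 50,
) -> tuple[np.ndarray, bool]:
    """Per-item scoring ascent with step-halving inside feasibility bounds.

    The scoring direction solves the negative-semidefinite empirical-
    information system, so it always ascends; a step is halved (up to
    25 times) until it is feasible and improves the expected LL.
    Returns the final point and whether a stability bound was binding.
    """
    x = x0.copy()
    ll, g, h, h_nsd = llgh(x, r, theta, k)
    hit_bound = False
    eye = np.eye(x.size)
    for _ in range(max_inner):
        if np.max(np.abs(g)) < gtol:
            break
        step = None
        try:
            cand_step = np.linalg.solve(h, -g)
            if g @ cand_step > 0:  # Newton step ascends; use it
                step = cand_step
        except np.linalg.LinAlgError:
            pass
        if step is None:  # fall back to the always-ascending scoring step
            try:
                step = np.linalg.solve(h_nsd - 1e-10 * eye, -g)
            except np.linalg.LinAlgError:
                step = g / max(1.0, np.max(np.abs(g)))
        improved = False
        for _half in range(25):
            cand = x + step
            if feasible(cand) and ll_only(cand, r, theta, k) > ll:
                improved = True
                break
            step *= 0.5
        if not improved:
            hit_bound = hit_bound or not feasible(x + 2 * step)
            break
        x = cand
        ll, g, h, h_nsd = llgh(x, r, theta, k)
    return x, hit_bound


def _mstep_item(p: ItemParams, r: np.ndarray, theta: np.ndarray) -> tuple[ItemParams, bool]:
    k = p.n_categories
    if isinstance(p, GRMItemParams):
        x0 = np.concatenate([[p.a], p.b])
        x, hit = _newton_mstep(
            x0, _grm_ll_grad_hess, _grm_ll, _grm_feasible, r, theta, k
        )
        return GRMItemParams(float(x[0]), tuple(x[1:])), hit
    x0 = np.concatenate([[p.a], p.d])
    x, hit = _newton_mstep(
        x0, _gpcm_ll_grad_hess, _gpcm_ll, _gpcm_feasible, r, theta, k
    )
    return GPCMItemParams(float(x[0]), tuple(x[1:])), hit


def _param_array(p: ItemParams) -> np.ndarray:
    loc = p.b if isinstance(p, GRMItemParams) else p.d
    return np.concatenate([[p.a], loc])


def fit_mml_em(
    freqs: pd.DataFrame,
    model: ModelName,
    quad: QuadratureGrid | None = None,
    tol: float = 0.001,
    max_cycles: int = 20_000,
    start: Sequence[ItemParams] | None = None,
    freq_floor: float = 1e-9,
) -> FitResult:
    """Marginal maximum likelihood estimation by Bock-Aitkin EM.

    Parameters
    ----------
    freqs : DataFrame
        Pattern-frequency table: one column per item holding category
        codes 0..K-1, plus a ``freq`` column.  Frequencies may be
        real-valued (e.g. IPFP-reconstructed expected frequencies).
    model : {"grm", "gpcm"}
    tol : float
        EM stops when the max absolute parameter change in one cycle
        falls below this (default 0.001, a deliberately relaxed setting).
    max_cycles : int
        Cycle cap (default 20,000); exceeding it sets ``converged=False``.
    freq_floor : float
        Patterns with frequency at or below this are excluded from the
        likelihood (default 1e-9; their LL contribution is far below the
        parameter tolerance).

    Returns a :class:`FitResult`; non-convergence and bound-hitting are
    reported through flags, never exceptions.
    """
    quad = quad or QuadratureGrid.rectangular()
    item_cols = [c for c in freqs.columns if c != "freq"]
    patterns = freqs[item_cols].to_numpy(dtype=int)
    n_vec = freqs["freq"].to_numpy(dtype=float)
    if np.any(n_vec < 0) or n_vec.sum() <= 0:
        raise ValueError("frequencies must be nonnegative with positive total")
    cats = [int(patterns[:, j].max()) + 1 for j in range(patterns.shape[1])]

    # drop patterns with negligible frequency: a pattern carrying less
    # than ~1e-9 expected observations cannot move any parameter at the
    # EM tolerance, and reconstructed joints often concentrate mass on a
    # small pattern subset while keeping the rest barely positive
    keep = n_vec > freq_floor
    patterns, n_vec = patterns[keep], n_vec[keep]

    for j, k in enumerate(cats):
        mass = np.bincount(patterns[:, j], weights=n_vec, minlength=k)
        if np.any(mass == 0):
            warnings.warn(
                f"item {j}: category with zero observed mass; location "
                "estimates for that boundary may hit stability bounds",
                stacklevel=2,
            )

    params = list(start) if start is not None else _start_values(n_vec, patterns, cats, model)
    theta, w = quad.points, quad.weights
    q = theta.size
    # per-item category indicator matrices for fast expected-count updates
    indicators = [
        (patterns[:, j][:, None] == np.arange(k)[None, :]).astype(float)
        for j, k in enumerate(cats)
    ]

    ll = -np.inf
    ll_trace: list[float] = []
    cycles = 0
    max_change = np.inf
    bounded = False
    for cycles in range(1, max_cycles + 1):
        # E-step: pattern x node likelihoods
        lik = np.ones((patterns.shape[0], q))
        pj_list = []
        for j, p in enumerate(params):
            pj = _item_probs(p, theta)  # (Q, K_j)
            pj_list.append(pj)
            lik *= pj[:, patterns[:, j]].T
        marg = lik @ w  # (Npat,)
        ll_new = float(np.sum(n_vec * np.log(np.clip(marg, 1e-300, None))))
        ll_trace.append(ll_new)
        post = (lik * w) / np.clip(marg, 1e-300, None)[:, None]  # (Npat, Q)
        weighted_post = post * n_vec[:, None]

        # M-step
        bounded = False
        new_params: list[ItemParams] = []
        max_change = 0.0
        for j, p in enumerate(params):
            r = weighted_post.T @ indicators[j]  # (Q, K_j) expected counts
            new_p, hit = _mstep_item(p, r, theta)
            bounded = bounded or hit
            max_change = max(
                max_change,
                float(np.max(np.abs(_param_array(new_p) - _param_array(p)))),
            )
            new_params.append(new_p)
        params = new_params
        ll = ll_new
        if max_change < tol:
            break

    # final LL at the returned parameters
    lik = np.ones((patterns.shape[0], q))
    for j, p in enumerate(params):
        lik *= _item_probs(p, theta)[:, patterns[:, j]].T
    ll = float(np.sum(n_vec * np.log(np.clip(lik @ w, 1e-300, None))))

    return FitResult(
        params=params,
        log_likelihood=ll,
        cycles=cycles,
        converged=max_change < tol,
        max_change=max_change,
        model=model,
        bounded=bounded,
        ll_trace=ll_trace,
    )
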