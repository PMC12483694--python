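# Methods

This note documents the statistical machinery in `sisquoc`: what is
being sampled and estimated, the assumptions behind each step, the
numerical choices, and what the validation battery can and cannot show.

## The limited-information data space

A test of `J` polytomous items, item `j` having `K_j` ordered
categories, defines a multinomial over `prod_j K_j` response patterns.
Fitting-propensity analysis needs datasets drawn uniformly from the
complete space of possible data, and sampling full pattern-probability
vectors becomes infeasible as `J` and `K_j` grow (the pattern simplex
for 50 four-category items has ~1e30 coordinates).  The package instead
works in the limited-information space: each dataset consists of the
`J` univariate margin vectors and the `J(J-1)/2` bivariate pair tables.
For dichotomous items this is the first- and second-order moment
representation of the multivariate Bernoulli distribution, which is in
one-to-one correspondence with the cell representation
(`cells_to_moments` / `moments_to_cells`).

## Sampling: margins, then cells

Uniform coverage of a single `m x n` pair table with free margins is a
uniform (all-ones) Dirichlet over its `mn` cells.  The sampler exploits
two facts:

1. **Aggregation.** Summing blocks of a Dirichlet vector gives a
   Dirichlet over the block sums.  Under the all-ones Dirichlet on a
   `K x K` table, each margin vector is Dirichlet with all `K`
   parameters equal to `K` — Beta(2,2) componentwise for `K = 2`.
   With mixed category counts an item's margin faces different
   aggregated laws from different partners; its margin is drawn from an
   equal-weight mixture of the per-partner aggregated Dirichlets
   (weights configurable).
2. **Sequential fill under Frechet bounds.** Given fixed margins, a
   table is filled column by column; each free cell is drawn uniformly
   in its Frechet interval — the range consistent with nonnegativity
   and the residual row/column masses after subtracting already-fixed
   cells — and the last cell of each column, plus the whole last
   column, is determined by the margin residuals.  Exactly
   `(m-1)(n-1)` cells (the degrees of freedom) are random.

Each item's margin is drawn once per dataset and reused across all of
its pairs, so shared margins are exactly consistent; pair tables are
then filled independently.

**What this is not.** Independently drawn margins combined with
unweighted uniform cell draws do not reproduce the uniform-simplex
joint law exactly: under the true uniform law the margin density is
proportional to the Frechet interval length, not the aggregated Beta.
The discrepancy is small — the exact-law and sampler CDFs of a 2 x 2
cell differ by under 0.01 — and the package treats it as an empirical
question: the validation battery measures agreement rather than a
weight correction enforcing it.  No importance weights are applied; a
per-table product of bound widths is recorded as a diagnostic for
future reweighting work.

## Validation battery

For a dichotomous pair the theoretical reference is Dirichlet(1,1,1,1)
over the four cells, and the uniform-simplex sampler
(`sample_simplex_reference`, normalized exponentials) realizes it
exactly.  The battery runs:

- one-sample KS of each margin against Beta(2,2) (exact null — margins
  are drawn from that law);
- two-sample KS of each cell coordinate against simplex draws;
- a chi-square uniformity check on cell coordinates binned into
  equal-probability bins under the Beta(1,3) cell marginal, occupancies
  averaged across coordinates;
- a histogram KL divergence on the margin coordinate, with
  equal-probability bins under the reference (default 5 bins).  The
  plug-in estimate carries the standard positive bias of about
  `(bins - 1) / (2n)` even under the null — about 2e-4 at 5 bins and
  10,000 draws — which sets the scale of reported values;
- maximum-likelihood estimation of the Dirichlet concentration
  parameters (fixed-point iteration on the digamma stationarity
  conditions, Newton inversion of the digamma, tolerance 1e-10),
  expected near 1 per component.

Equal-probability (not equal-width) binning is used throughout because
cell distributions pile up near the simplex boundary.

## Joint reconstruction by IPFP

Full-information estimation needs pattern frequencies, so each
limited-information dataset is expanded into a joint pattern array by
iterative proportional fitting: start from the all-ones array, rescale
against each pair table in lexicographic pair order, renormalize after
each sweep, and stop when the maximum absolute change in fitted pattern
probabilities between sweeps falls below epsilon (module defaults
epsilon 1e-8, 10,000 sweeps).  Univariate constraints are implied by
the pair tables and are not fitted separately.  For strictly positive
targets the fitted joint is strictly positive, so no pattern is
excluded a priori; because repeated rescaling can drive a pattern's
value below double precision, values are floored at the smallest normal
double once after iteration finishes — never inside the sweeps, where a
floor could feed back into the dynamics (for targets containing zero
cells the support restriction is honored and no floor is applied).

A point that matters for interpretation: pair tables filled
independently are in general *not* mutually compatible with any joint
distribution (for three dichotomous items this is a linear-programming
feasibility question, and sampled margins routinely fail it).  IPFP
then converges to a strictly positive compromise whose pair collapses
approximate the targets; `JointTable.max_margin_residual` reports the
achieved deviation, typically on the order of 0.01-0.1 for sampled
margins and at the epsilon level for compatible ones (e.g. margins
collapsed from an existing joint, where the fixed-point property is
exact).  The fitting-propensity pipeline treats the compromise joint as
the dataset, which preserves the intent — a random, structureless
target for the candidate models — while guaranteeing a well-defined
multinomial.

## Item response models and estimation

Both models are unidimensional with a standard-normal latent trait
(fixing the scale) and the pure logistic metric (no 1.7 constant).

- **GRM**: `P(X >= k | theta) = logistic(a (theta - b_k))` with
  strictly increasing thresholds; category probabilities are adjacent
  differences of the cumulative curves.
- **GPCM**: `P(X = k | theta) ∝ exp(sum_{h<=k} a (theta - d_h))`;
  step parameters need not be ordered.

For `K = 2` both reduce to the same two-parameter logistic model.

Marginal maximum likelihood uses Bock-Aitkin EM with a fixed
rectangular quadrature grid (49 equally spaced points on [-6, 6],
standard-normal weights renormalized; configurable).  Pattern
frequencies may be real-valued, as produced by IPFP reconstruction.
The E-step computes each pattern's posterior over quadrature nodes; the
M-step maximizes each item's expected complete-data log-likelihood by
Newton ascent with step-halving (max 50 inner iterations, gradient
tolerance 1e-8) using analytic gradients and Hessians.  Because the
GPCM complete-data likelihood is bilinear in slope and steps (and the
GRM's not globally concave), the exact Newton direction can fail to
ascend; the solver then falls back to the scoring direction built from
the negative-semidefinite empirical-information part of the Hessian,
which always ascends.  Steps are rejected if they leave the feasible
region (slopes in [0.01, 50], locations in [-20, 20], GRM thresholds
strictly increasing); a fit that ends against a bound is flagged, not
failed.  EM stops when the maximum absolute parameter change in a cycle
falls below the tolerance (default 0.001 — a deliberately relaxed
setting suited to fitting many random datasets — with a 20,000-cycle
cap).  The marginal log-likelihood trace is recorded and is
non-decreasing by construction.

Starting values: slopes 1.0; GRM thresholds chosen so the cumulative
curves at theta = 0 match the observed upper-tail category proportions
(clipped away from 0/1, strictness enforced); GPCM steps reuse the same
values.

## The Y2/N fit statistic

Test-level fit is scored with the limited-information residual
statistic

    Y2/N = sum_j sum_{k>=1} (phat_jk - pi_jk)^2 / pi_jk
         + sum_{j<j'} sum_{k,k'>=1} (phat - pi)^2 / pi

over the linearly independent margins: category 0 is dropped for every
item, leaving `K-1` univariate terms per item and `(K-1)^2` bivariate
terms per pair.  `phat` are observed proportions (counts / N) and `pi`
model-implied probabilities from the fitted parameters, so the statistic
equals the frequency-based form divided by N.  The dropped category is
a fixed convention: with Pearson-type weighting the value depends on
which category is dropped (the denominators change), so the convention
is part of the statistic's definition here.  A zero expected
probability facing positive observed mass yields an infinite statistic,
flagged rather than masked.

## Fitting-propensity study

One replicate: sample a limited-information dataset, scale by N (default
5000), reconstruct the joint by IPFP, convert to expected pattern
frequencies, fit each candidate model by MML-EM, recompute model-implied
margins at the fitted parameters, and record Y2/N.  Replicates run on
deterministic substreams spawned from the master seed, so any replicate
is regenerable from (seed, dataset id); non-converged fits are flagged
and kept.  Summaries are ECDFs and deciles of Y2/N per model, and
Euler-style overlap counts (both / only-one / neither model under a
cutoff) on a cutoff grid spanning the observed range — by default the
pooled deciles, since overlap counts at cutoffs far outside the bulk of
the distribution are dominated by single datasets and uninformative.

Study-scale numerics: within `run_fp_study` the IPFP tolerance defaults
to 1e-6 with a 2,000-sweep cap; measured on 7-item, 4-category
datasets, the compromise joint's margin residual agrees to four decimals
with the 1e-8 setting while sweep counts differ by an order of
magnitude, and downstream fits are insensitive at the EM tolerance.
The packaged study runs 100 replicates of 7 four-category items — a
deliberate desk-scale design; with the two models' Y2/N values nearly
identical dataset by dataset, 100 replicates already pin the maximum
ECDF gap well below 0.1.

## What the synthetic data does and does not emulate

All inputs are generated internally; the generator emulates random,
structureless margin configurations covering the complete
limited-information data space — not realistic test data.  Passing
validation therefore says the *sampler* covers the space uniformly and
the *pipeline* treats both models symmetrically; it says nothing about
either model's fit to data with real psychometric structure
(unidimensionality, monotone item-total relations), which random
margins almost never possess.  Conclusions about fitting propensity are
statements about the models' flexibility over this space, not about
their adequacy for any empirical dataset.

## Known limitations

- The sampler's joint law over a pair table approximates, not equals,
  the uniform Dirichlet (see above); validation is statistical.
- Independently sampled pair tables are generally incompatible with any
  joint; IPFP yields a compromise and its residual is reported, not
  hidden.
- Y2/N values are comparable within a study but are not calibrated
  p-values; no reference distribution is attached.
- Mixture weights for mixed-category margins default to equal weights
  across partners; other weightings are accepted but not studied.
- Sampling restricted subregions (e.g. positively quadrant dependent
  tables only, or the independence surface) is out of scope; the
  association classifier (`odds_ratio_and_dependence`) only labels
  tables.
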