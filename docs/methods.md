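# Methods

## Model and conventions

The package assumes a linear time-invariant system observed at steady
state after each perturbation, so that the genes × experiments
fold-change matrix `Y`, the intended perturbation design `P`, the
interaction matrix `A` and the two error matrices satisfy
`−(P − F) = A (Y − E)`. The Moore–Penrose pseudo-inverse replaces the
matrix inverse everywhere because sparse interaction matrices can be
rank deficient.

Design entries are −1 per targeted gene. Knockdown efficiency is
generally unknown and varies between genes; since rescaling a design
column rescales the corresponding coefficients without changing which
are nonzero, the unit-magnitude convention does not affect inferred
topology, which is the quantity compared against null models.

A *link* is any entry of `A` with magnitude ≥ 1e−12 (entries below that
are treated as structural zeros after refits). Self-links (diagonal)
count as links. The sparsity summary divides the link count by the
number of *linked* genes (genes incident to at least one link), not by
the matrix dimension, so 125 links among 39 linked genes report 3.2
links/gene.

## Synthetic data generator

`random_grn` places −1 self-degradation on every diagonal and
`round(N·(links_per_gene − 1))` off-diagonal links uniformly at random,
magnitudes uniform in [0.5, 1.5], activating with probability 0.5 by
default. Stability (all eigenvalues with negative real part) is enforced
by shrinking all off-diagonal weights by a factor 0.9 per iteration —
shrinkage rather than rejection sampling, so generation always
terminates. `simulate_dataset` draws `F` and `E` i.i.d. Gaussian with
scales set by a single Frobenius-norm signal-to-noise ratio per matrix
(signal for `F` is `P`; signal for `E` is the noiseless response
`−A†P`). The default emulation profile is a single-knockdown screen with
3 replicates per target; a pairwise design (two genes per column, single
replicates) mirrors an independent validation screen.

What the generator does **not** emulate: off-target siRNA effects,
correlated or heavy-tailed noise, replicate batch structure, saturation
of strong knockdowns, and time-course dynamics. Passing tests on this
generator therefore demonstrate correctness and calibration of the
machinery under the stated linear-Gaussian conditions, not performance
on any particular real screen.

`shuffle_dataset` permutes each gene row of `Y` independently across
experiments. This destroys the gene↔perturbation correspondence while
preserving every gene's marginal distribution exactly; it is the null
used both inside the bootstrap FDR machinery and for the shuffled-data
wRSS null. The per-row permutation is our operationalization of
"shuffled data"; other schemes (global permutation, column permutation)
destroy either too little or too much structure.

## Inference

* **LSCO** — full estimate `Â = −P·pinv(Y)`, then entries with
  `|â| < ζ` removed (ties at the threshold kept). Raw magnitudes are
  thresholded without row normalization.
* **LASSO** — per target row, `min ‖(−P_i)ᵀ − Yᵀa‖² + λ‖a‖₁` with no
  intercept and no standardization (fold changes are already scaled
  around control). Solved by scikit-learn's coordinate descent;
  `λ = 0` falls back to ordinary least squares.
* **TLSCO** — classical multivariate total least squares via the SVD of
  the augmented matrix `[Yᵀ | −Pᵀ]` and the block formula
  `Aᵀ = −V₁₂V₂₂⁻¹`, then the same cutoff as LSCO. A warning is issued
  when there are fewer than 2N experiments.
* **CLS refit** — given a signed topology, each row solves a
  nonnegative least-squares problem after substituting
  `a_ij = s_ij·b_ij`; the zero pattern and signs are preserved exactly,
  and a coefficient whose unconstrained optimum violates its sign lands
  exactly at zero.

Inference deliberately ignores `E` and `F` (it fits `−P = AY`); the
errors-in-variables structure enters only in validation, where it is
estimated per network.

## Nested bootstrap and FDR

Inner bootstraps resample experiment columns with replacement,
stratified by perturbation target so every target keeps at least one
experiment and `(Y, P)` columns stay paired. Support is sign-aware: a
link's support is the fraction of bootstrap networks containing it with
its majority sign (ties broken toward +). Outer runs repeat the inner
bootstrap with independent seeds; the aggregate support is the mean
across runs. Shuffled-data support runs the identical procedure with a
fresh row-shuffle per outer run.

For LSCO/TLSCO the cutoff inside the bootstrap is **density-matched**:
each resample keeps a fixed fraction of entries (default native
sparsity 4.5 links/gene, inside the 3–5 links/gene range typical of
natural networks, with headroom for pruning). A fixed magnitude cutoff
would make the null incomparable — coefficients inferred from shuffled
data are systematically smaller, so a measured-scale cutoff leaves
shuffled networks much sparser and understates null support, which we
observed to produce anti-conservative FDR estimates.

`FDR(s)` = (mean number of links with shuffled support ≥ s across
shuffled runs) / (number of measured links with support ≥ s), clipped
to [0, 1], and 1 by convention when the measured count is zero. The
default grid is 0–1 in steps of 0.025. The selected cutoff is the
smallest grid value with FDR ≤ α. Because the measured selection uses
the aggregate over outer runs while the null counts are per-run, the
estimate is conservative; on desk-scale settings (8 × 25) a noisy
dataset may select nothing at α = 5%, which is reported explicitly
rather than papered over. An empty selection makes no false
discoveries (the `V/max(R,1)` convention).

## Balanced-error cross-validation

To score a network without a gold standard, all experiments targeting
one gene are left out in turn; on the remainder the two error sources
are balanced by the convex minimax program

```
minimize  max( ‖E‖²_F/‖Y′‖²_F , ‖F‖²_F/‖P′‖²_F )
subject to  F = P′ + A(Y′ − E)
```

with `F` eliminated, so only `E` is free. The program is solved exactly:
for a fixed weight `w`, the scalarized objective is a per-column ridge
system solved in the SVD basis of `A` (one SVD per network, reused over
folds); the minimax optimum is the weight at which the two relative
errors cross, located by bisection (their difference is monotone in
`w`). When even the minimum-norm minimizer of the process term leaves
the measurement term smaller, no crossing exists and that minimizer is
already optimal — then `E_rel < F_rel`; in all other cases the two
relative errors agree to solver tolerance (~1e−14 relative), which is
the balance property. Frobenius norms of `Y′` and `P′` are the
normalizers; degrees-of-freedom normalization differs only by constants
at fixed shapes.

Left-out experiments are predicted as `ŷ = −A†p` (response from
intended perturbation) and `p̂ = −Ay` (perturbation from observed
response), and the per-gene predictions are assembled into full
matrices (columns of a pairwise design are predicted once per target
and averaged). The wRSS weighs the squared response and perturbation
residuals by the inverse mean per-element balanced error variances
(floored at 1e−8 to guard the noiseless case).

**Weight scale in null comparisons.** Inverse-variance weights computed
from a network's *own* balanced errors shrink as the network worsens,
which would let a poor topology mask its misfit. When wRSS values are
compared — observed network versus shuffled-topology or shuffled-data
replicates — every fit therefore reuses the weights of the observed
(CLS-refit) network's fit, putting all fits on one common error scale.
With the shared scale the generating topology's wRSS falls far below
the null distribution, as it should.

**SVD truncation.** Before computing R² (always) and wRSS (by default),
singular values of `A` are dropped from the smallest up until every
entry of `−A†P` lies within the observed expression range widened by
10% of its span. Small singular values of an ill-conditioned refit blow
up the pseudo-inverse; truncation keeps predictions on the scale of the
data. The cutoff is chosen independently per network; if no rank
satisfies the bound, rank 1 is kept and flagged.

**Null models.** The shuffled-topology null redraws each row's
off-diagonal incoming links (self-links stay), sampling sources without
replacement with probability proportional to original out-degree + 1 —
one reading of "hub-preserving"; uniform sampling is available via
`hub_weighting=False`. Moved links keep their sign and weight, so
per-row in-degree and the global weight multiset are preserved. Each
null replicate is CLS-refit to the data before scoring — a stringent
null, since its weights are optimized to fit. The shuffled-data null
refits the inferred topology to each row-shuffled dataset. Defaults:
100 replicates; summaries are the median, IQR, the observed/median
ratio, and the add-one empirical p `(1 + #{null ≤ observed})/(n + 1)`,
which avoids zero p-values.

## Numerical choices

* Zero threshold after refits: 1e−12 absolute.
* LASSO coordinate-descent tolerance 1e−10, max 10⁵ iterations.
* Bisection in the balance solver: ≤ 200 iterations, relative
  convergence 1e−14 on the error gap.
* All randomness flows from `numpy.random.SeedSequence` spawns of a
  single seed, so every stage is reproducible; derived seeds are
  reduced below 2³¹.
* Problem sizes in the test suite and the acceptance script (15 genes,
  3 replicates, 8 nested × 25 inner bootstraps, 100 null replicates,
  5 replicate studies) were chosen as representative desk-scale
  conditions; all scale up by arguments.

## Known limitations

* The linear steady-state model cannot represent saturating or
  combinatorial regulation; inferred links are regulatory *influences*,
  possibly indirect through unmeasured genes.
* FDR estimation at desk scale is conservative: on hard datasets no
  support cutoff may reach the nominal level, and the procedure then
  returns no network rather than an uncontrolled one.
* The balance program assumes homogeneous error scales across genes; a
  gene-wise weighting would need per-gene variance estimates the data
  rarely support.
* The pairwise-design path predicts shared columns by averaging the two
  single-gene predictions, which slightly blurs attribution when both
  targets interact strongly.
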