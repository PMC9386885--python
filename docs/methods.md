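# Methods

## The problem

Given an N x J matrix of item responses assumed to follow a linear common-
factor model, how many factors should be retained?  `factorretain`
implements nine retention criteria and a Monte-Carlo harness that measures
each criterion's accuracy (probability of retaining exactly the true
number of factors) and bias (mean retained minus true) on synthetic
populations whose true structure is known, for continuous responses and
for responses dichotomized at an even (50-50) or skewed (75-25) split,
analyzed with Pearson or tetrachoric correlations.

## Population model

The generator produces a J x J population correlation matrix

    R = L Phi L' + W W' + diag(psi)

* `L` (J x M1): **major-factor loadings** with perfect simple structure —
  items are split into M1 contiguous, near-equal blocks (20 items on 3
  factors: 7/7/6) and each item loads sqrt(h²) on its block's factor, with
  the communality h² drawn uniformly from a discrete level set, by default
  {0.2, 0.3, 0.4} ("low") or {0.6, 0.7, 0.8} ("high").
* `Phi` (M1 x M1): interfactor correlations, a single value (0 or 0.5) on
  all off-diagonal entries.
* `W` (J x M2): **minor-factor loadings** representing model error — the
  many weak influences a researcher does not model.  Entries start as
  independent standard normals, column m is multiplied by 0.8^(m-1)
  (a decaying geometric series approximating infinitely many minor
  factors; M2 = 200), and each row is rescaled to a fixed share of the
  item's residual variance.
* `psi`: unique variances, whatever is left so each item has unit variance.

### The minor-variance share

How much residual variance the minor factors take is the single most
consequential generator choice; three rules are implemented
(`minor_share_rule`):

* `half_residual` (default): h²_minor = (1 − h²_major) / 2 — minor factors
  and unique factors split the unexplained variance evenly; the
  minor-loading row norm is the square root of half the residual variance.
  This rule is feasible at every communality level and reproduces the
  eigenvalue inflation characteristic of such populations: with it, the
  Kaiser criterion over-extracts by ~3 factors at low communalities and by
  ~1 factor at high communalities, and its accuracy at high communalities
  stays below 0.1 — the documented behavior of this class of
  minor-factor designs.  The two alternatives fail one of those checks:
* `half_sqrt_norm`: h²_minor = 0.25 (1 − h²_major).  Feasible everywhere
  but the contamination is so weak that the Kaiser criterion becomes
  almost exact at high communalities (accuracy ≈ 0.9-1.0), which no
  minor-factor study reports.
* `literal_half_sqrt`: h²_minor = 0.5 sqrt(1 − h²_major).  Produces
  negative unique variance for h²_major > 0.75, i.e. it cannot generate
  the high-communality conditions at all; construction raises an
  invalid-spec error rather than silently clipping.

One population is drawn per condition (communality range x interfactor
correlation) from a fixed seed and reused across all replications, so a
condition means "one fixed population", not "a new population per sample".
Cells summarize sampling variability only; an appreciable share of the
variance of mid-range accuracy values across studies comes from which
population happened to be drawn (re-running a low-communality EGA cell
with different population seeds moved its accuracy across 0.0-0.8 in our
profiling), which is why reproduction tolerances on mid-range cells are
necessarily loose.

## Sampling and dichotomization

Samples are drawn by the spectral (Kaiser-Dickman) route: Z = X F' with X
standard normal and F = U D^{1/2} from the eigendecomposition of R
(eigenvalues clipped at 0 to absorb -1e-15 round-off).  Dichotomization
maps value > delta to 1 (ties, a probability-zero event, to 0); delta = 0
gives the 50-50 split and delta = Phi^{-1}(0.75) ≈ 0.6745 the 75-25 split.

## Correlation estimation

Pearson matrices are ordinary product-moment correlations; a constant
column raises a degenerate-column error naming the column.  Tetrachoric
correlations are estimated pairwise by maximum likelihood with thresholds
fixed at the normal quantiles of the margins; the score equation then
reduces to matching the bivariate-normal quadrant probability to the
observed (1,1) cell proportion, which is solved by bracketing root search
on [-0.999, 0.999] (monotonicity makes this exact and fast).  Any empty
cell triggers a +0.5 continuity correction on all four cells, keeping
N = 100 estimates finite.  A pairwise-assembled matrix need not be
positive semidefinite; if its smallest eigenvalue falls below 1e-6 the
spectrum is clipped at 1e-6 and the matrix rescaled to unit diagonal
(iterating, since the rescale can undershoot the floor), and the estimate
is flagged `repaired`.

## Retention criteria

All eigenvalue-based criteria use principal-component eigenvalues of the
full correlation matrix.

* **EV (Kaiser)**: count of eigenvalues strictly greater than 1.
* **AF (acceleration factor)**: the scree elbow at the maximum second
  difference af_i = e_{i+1} − 2e_i + e_{i−1} (i = 2..J−1); retained count
  is the index before the first maximum, so AF ∈ [1, J−2].  **AFEV** caps
  AF by the Kaiser count (minimum of the two).
* **PAM / PA95 (parallel analysis)**: k = 100 standard-normal datasets of
  the same N x J are pushed through the *same* arm pipeline as the data —
  dichotomized at the arm's threshold and correlated with the arm's
  method — and the observed eigenvalues are compared sequentially against
  the per-index mean (PAM) or 95th percentile (PA95); retention stops at
  the first failure, with strict inequality.
* **RPA / RPAEV (revised parallel analysis)**: the reference for the
  (m+1)th eigenvalue comes from k datasets simulated under an m-component
  model fitted to the observed matrix.  The m-component null is built from
  the first m principal-component loadings L_m = U_m D_m^{1/2} as the
  correlation matrix of "components plus standard-normal errors",
  standardize(L_m L_m' + I).  This construction reduces exactly to the
  traditional PA null (pure standard normals) at m = 0 and keeps
  near-unit residual variance in the null, which is what makes the
  sequential test stop in data whose residual spectrum is non-trivial.
  The alternative sometimes described — L_m L_m' with the diagonal reset
  to 1 — is available as `construction="diag_reset"`, but its null carries
  so little residual variance that under minor-factor contamination the
  test never stops (every stage passes up to m = J); it is not the
  default for that reason.  RPAEV additionally requires each retained
  factor's observed eigenvalue to exceed 1, which with a descending
  spectrum equals min(RPA, EV).
* **MAP (minimum average partial)**: f_m is the mean squared off-diagonal
  partial correlation after partialing out the first m principal
  components (f_0 uses the raw correlations); retain argmin_{m≥1} f_m,
  or 0 when f_1 ≥ f_0.  A residual diagonal entry ≤ 1e-10 truncates the
  search at that m.
* **EGA (exploratory graph analysis)**: see below.

## EGA

1. A Gaussian graphical model is estimated by graphical lasso over 100
   log-spaced penalties from the largest absolute off-diagonal correlation
   down to one tenth of it, selecting the penalty minimizing
   EBIC = −2L + E log n + 4·γ·E log J (γ = 0.5, E = nonzero upper-triangle
   precision entries, L the Gaussian profile log-likelihood).  The 0.1
   grid floor is deliberate: with a deeper grid (e.g. the 0.01 floor used
   in generic EBIC-glasso practice, available via
   `ebic_glasso(lambda_min_ratio=0.01)`), EBIC keeps descending into the
   densest solution whenever the input matrix is ill-conditioned —
   pairwise tetrachoric matrices especially — and community structure
   drowns in spurious edges.
2. Walktrap community detection on absolute partial correlations: 4-step
   random-walk transition profiles, agglomerative merging of adjacent
   communities by the minimum Ward-form increase in within-community
   squared profile distance (ties broken toward the lowest community
   indices), zero-strength nodes remaining singletons and disconnected
   components never merging.  The merge level maximizing weighted
   modularity Q = Σ_j (e_jj − a_j²) is the solution; the full merge trace
   (pairs, Δσ, per-level assignments) is retained for inspection.
3. Unidimensionality binding: Walktrap's modularity objective penalizes
   single-community solutions, so a 4-variable unidimensional block
   (loadings 0.70) is simulated at the sample's N, transformed through
   the same arm pipeline, and column-bound to the data.  If the combined
   (J+4)-variable solution has ≤ 2 communities the data are declared
   unidimensional (1 factor); otherwise the pipeline reruns on the
   original J variables and reports that community count.  An empty
   selected network yields one community per node.

## Experiment and evaluation

The full design crosses N ∈ {100, 1000}, interfactor correlation
∈ {0, 0.5} and communality range ∈ {low, high} (8 cells), with 1,000
replications per cell by default (8,000 sample draws), each analyzed by 5
arms x 9 criteria (45 records per draw).  Randomness is hierarchical from
one master seed — population stream per condition, sampling stream per
(cell, replication), criterion substream per (cell, replication, arm,
criterion) — so parallel and serial runs coincide and any record can be
recomputed in isolation.  Criterion failures are recorded as
`status="missing"` rows, excluded from cell denominators.

Cell summaries (accuracy and mean bias per criterion per arm) are the
primary output.  A saturated logistic regression on the correctness dummy
and a saturated linear regression on the bias, with the full factorial
interaction of criterion, N, interfactor correlation, communality and arm,
are fitted as a verification harness: their fitted values must reproduce
the empirical cell means (exactly for the linear model; within 1e-6 for
non-separated logistic cells, with separated cells — empirical proportion
exactly 0 or 1 — reported and read off the empirical proportions).  The
regression framing therefore adds nothing beyond the cell summaries, and
the code verifies rather than assumes this.

## Numerical and scale choices

* Graphical-lasso solves use the coordinate-descent solver with a 1e-3
  dual-gap tolerance and warm starts along the penalty path; profiling
  showed identical selected graphs to a 1e-5 tolerance at ~100x less cost.
* Tetrachoric root searches use brentq at 1e-10; the zero-cell continuity
  correction bounds estimates strictly inside (−1, 1).
* Parallel-analysis comparison draws that produce a constant column (possible
  in small dichotomized samples) are regenerated, up to 50 attempts.
* Desk-scale reproduction (`scripts/acceptance.py`, `benchmark.measure_cell`)
  uses 100-200 replications per cell rather than 1,000; at those counts the
  Monte-Carlo standard error of an accuracy near 0.95 is about 0.015 and
  near 0.5 about 0.035, on top of the between-population variability noted
  above.

## What the generator does and does not emulate

It emulates: perfect-simple-structure major factors, geometric minor-factor
model error, exact multivariate normality, probit dichotomization at known
thresholds.  It does not emulate: cross-loadings on major factors,
non-normal continuous responses, polytomous (Likert) items, missing data,
or item-specific thresholds.  Passing cells here therefore speak to
criterion behavior under clean factor populations with diffuse model
error, not to robustness against structural misfit of other kinds.

## Known limitations

* RPA's m-component null is itself a modelling choice; the two available
  constructions bracket the published behavior of revised parallel
  analysis but the exact reference construction in the wider literature
  varies.
* Tetrachoric arms are ~5-10x slower than Pearson arms (190 pairwise ML
  fits per matrix; parallel-analysis variants multiply that by k).
* Isolated nodes count as communities in EGA (they inflate the count
  under heavy sparsification); with the 0.1 penalty floor this is rare at
  the study's sample sizes.
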