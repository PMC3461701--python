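# Methods

## Model and test

MDMR relates an N × N dissimilarity matrix D, computed over P outcome
variables, to M regressors X.  The chain is: A = −½ D∘D; G = C A C with
C = I − **11**′/N (Gower double-centering, so G's rows and columns sum to
zero and, for Euclidean D, G is the Gram matrix of the column-centered data
with tr(G) equal to the total sum of squares); H the orthogonal projector
onto span{**1**, X}; and the trace ratio F_raw = tr(HGH)/tr((I−H)G(I−H)).
tr(HGH) is computed as Σᵢⱼ HᵢⱼGᵢⱼ (valid because H is idempotent and both
matrices are symmetric), and the identity tr(HGH) + tr((I−H)G(I−H)) = tr(G)
holds to 1e-8 for every fit.

An intercept column is always prepended before forming H.  Because G is
doubly centered the constant direction contributes nothing to tr(HGH), so
the intercept is harmless — and it is required for F_raw to reduce to the
ANOVA SSR/SSE decomposition with 0/1 coding.

**Scaled statistic and reference distribution.**  The mean-square form
F = F_raw · (N − M − 1)/M is reported alongside F_raw.  For a single
regressor its null distribution is referred to F(P, P·N − 2): with P
independent unit-variance variables and Euclidean distance, the model and
residual traces are chi-squared with P·M and P·(N − M − 1) degrees of
freedom, so pooling over variables multiplies both df by P; the reference
pair (P, P·N − 2) matches this closely for moderate N and collapses to the
exact ANOVA pair (1, N − 2) at P = 1.  At very small N the reference
denominator df (P·N − 2) exceeds the true P·(N − 2), which makes the
analytic p-value mildly anticonservative — e.g. at N = 4, P = 10 the
statistic is exactly F(10, 20) under an iid normal null while the reference
is F(10, 38), giving a 7.7% closed-form rejection rate at nominal 5%.
This small-N behavior is a property of the approximation, reproduced (not
corrected) here; the permutation test is the primary inference.  For M > 1
the pair (P·M, P·N − M − 1) is an explicit extrapolation, flagged in the
result object; permutation inference is authoritative there.

**Permutation test.**  Rows of the regressor block are permuted jointly
while G and the intercept stay fixed (equivalently, samples are relabeled).
When the number of distinct row arrangements (multiset permutations) is at
most `n_perm`, the null set is enumerated exhaustively and
p = #{F ≥ F_obs}/#arrangements with the identity included; otherwise
`n_perm` sampled permutations give the add-one estimate
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1), which is strictly positive and
valid at level.  Ties within 1e-12 (relative) count as exceedances —
conservative, and necessary for exact small-sample answers such as the 2/6
of the worked example.  For a single regressor the statistic reduces to the
normalized quadratic form x̃′Gx̃/x̃′x̃ (x̃ the centered regressor), monotone
in F, so whole permutation batches are evaluated as one matrix product.

**Collinearity.**  H is built by column-pivoted QR; a column whose pivot
falls below 1e-10 × the leading pivot is dropped and reported by name.
df computations use the surviving rank.  If no regressor survives, the fit
errs out rather than silently testing an intercept-only model.

## Distances

Euclidean, Manhattan, and correlation (1 − Pearson r, range [0, 2]) are
provided.  With missing values, distances are pairwise-complete: Euclidean
sums of squares over the shared coordinates are rescaled by P/P_shared
(Manhattan sums by P/P_shared) so that expected magnitudes are comparable
across pairs with different missingness; each pair must share at least
⌈`min_shared_fraction` · P⌉ observed variables (default 0.5 — there is no
established critical missingness level, so the gate is deliberately
conservative and loud).  Input distance matrices are validated (symmetric
within 1e-8, zero diagonal, nonnegative) and symmetrized as (D + D′)/2
within tolerance.  The similarity transform s = 1 − d/d_max (empirical or
supplied maximum) is provided for display pipelines; rendering itself is
out of scope.

## Synthetic data

Generators draw from four families, each standardized to unit variance:
iid standard normal; an equal mixture of N(−1, 0.5²) and N(+1, 0.5²)
scaled by 1/√1.25 (a symmetric, strongly bimodal shape); exp(N(0, 1))
centered and scaled by its theoretical moments (heavy right tail); and
compound-symmetric multivariate normal with equicorrelation ρ (default
study value 0.06).  The bimodal and log-normal parameterizations are this
package's own choices of a representative bimodal/skewed shape; results for
them are qualitative, not tied to any external table.  A dichotomous design
assigns the first ⌊N/2⌋ samples to the control group and adds the mean
shift (in SD units) to the first ⌈fraction · P⌉ variables of the
experimental group.  A continuous design draws z ~ N(0,1) and replaces each
affected variable by r·z + √(1−r²)·noise, giving correlation r exactly for
the normal family and approximately for the others.

What the generators emulate: the null and shift/correlation alternatives of
the published level and power studies — independent variables, homoscedastic
groups, balanced designs.  What they do not: correlated variables beyond
exchangeable equicorrelation, unbalanced or confounded designs, outliers,
and measurement-level artifacts of real assays.  Passing tests therefore
certify the statistic's calibration and power under these idealized
conditions, not robustness on any particular real data set.

Default experiment sizes follow the published studies (1000 simulations;
nominal levels 1–75%; N ∈ {100, 50, 20, 10, 4} with P = 10 for level
studies; N = 30, P = 100 for power-vs-shift; 999 permutations for
production runs).  The shift grid for threshold finding uses step 0.02 over
[0, 1]: threshold precision is limited by Monte-Carlo error at any feasible
number of simulations, so a finer grid buys nothing.  The
`stop_after_threshold` option abandons a shift grid once 80% power is
reached, exploiting monotonicity of the power curve.

The Bonferroni comparator runs a two-sided two-sample t-test per variable
and rejects globally if any p ≤ α/P.  For independent variables its
familywise power has the closed form 1 − (1 − π₁)^P with π₁ the noncentral-t
power of a single test at level α/P, which the test suite uses as an
independent oracle for the simulated curve.

## Cluster-count selection

For k = 2..k_max the samples are clustered (UPGMA average-linkage cut of
the distance matrix via scipy, or k-means with 10 seeded restarts on the
raw data), memberships are canonically relabeled by first occurrence and
dummy-coded as k − 1 indicators, and a full MDMR fit is recorded per k.

Two decisions were genuinely open:

* **"Adding clusters does not add significantly."**  Operationalized as a
  restricted permutation test: fit the combined design [dummies_k,
  dummies_{k+1}], take the gain in tr(HGH) over dummies_k alone, and
  permute only the added block's rows.  selected_k is the smallest k whose
  increment p-value exceeds 0.05; if every increment is significant the
  argmax of the scaled F is reported (and the argmax is always recorded
  alongside for comparison).
* **"Is there structure at all?"**  Labels obtained by clustering the very
  distances under test always look significant when naively permuted — on
  pure Gaussian noise the fitted k=2 partition yields permutation p ≤ 0.025
  essentially always.  The any-structure gate therefore uses a
  selection-aware reference null: each variable is independently permuted
  across samples (destroying inter-sample structure, preserving marginals),
  the full pipeline (distance → clustering at k=2 → trace ratio) is re-run
  per reference draw, and the observed statistic is compared against that
  distribution.  On noise this reports "1 cluster" at the nominal error
  rate; without access to the raw data the naive gate is used and flagged
  in the selection trace as anti-conservative.

## Numerical choices and edge cases

Symmetry/idempotency tolerances are 1e-8; QR pivot threshold 1e-10
(relative); permutation tie tolerance 1e-12 (relative).  Exhaustive
enumeration counts distinct multiset arrangements, so heavily tied
regressors (e.g. 0/1 groups) enumerate C(N, N₁) cases, not N!.  A saturated
design (zero residual trace) and an all-zero distance matrix under the
empirical similarity transform are errors, not silent NaNs.  Seeds are
recorded in every result and report; identical seeds reproduce experiment
tables byte-for-byte.

## Known limitations

The analytic df rule is exact only at P = 1 (Euclidean, single 0/1
regressor) and approximate otherwise; no small-N correction is attempted.
Non-Euclidean distances can make G indefinite; F_raw then loses its
sum-of-squares reading (the permutation test remains valid).  The M > 1 df
rule is an extrapolation.  k-means selection requires raw data (clustering
on distances is deliberately not emulated).  The cluster-count procedure
inherits UPGMA's known difficulty separating weakly shifted groups, which
is precisely the regime where the MDMR scan is informative.
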