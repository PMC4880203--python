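# Methods

## Model and estimation

The trait model is the complete epistatic mixed model described in the
README: six independent polygenic random terms (a, d, aa, ad, da, dd), each
with covariance proportional to a marker-generated kinship matrix, plus iid
residual noise.  Fixed effects default to a single intercept; a user
covariate table is used as supplied, with an intercept column prepended
unless one is already present.

### Kinship matrices

Main-effect kinships are sums of marker-column outer products
(K_a = Σ_k Z_k Z_kᵀ, K_d likewise with W).  Interaction kinships sum the
outer products of Hadamard interaction columns over all unordered marker
pairs k < k′; the self-pair is excluded, and ad/da are distinct matrices
because the roles are ordered within each pair.  Two construction paths are
maintained: a definitional brute-force pair enumeration, and a fast path
using the Gram-matrix identities

    K_aa = ½[(ZZᵀ)∘(ZZᵀ) − (Z∘Z)(Z∘Z)ᵀ]       (K_dd analogously with W)
    K_ad = Σ_k (Z_k Z_kᵀ) ∘ Σ_{k'>k} W_k' W_k'ᵀ  (suffix sums; K_da with
                                                  roles swapped)

which reduces the interaction cost from O(m²n²) to O(mn²).  The two paths
are asserted equivalent (≤ 1e-9 relative Frobenius error) on random
instances in the test suite.

Each raw matrix is normalized to mean diagonal 1 and the divisor recorded,
so raw = normalized × constant exactly.  This convention puts the six
variance components on a common scale; LRTs are invariant to it up to
reparameterization.  No centering of Z or W is applied before forming
kinships — indicators enter exactly as coded.  A consequence worth knowing:
uncentered W has mean ≈ ½ in an F2, so the six matrices are strongly
correlated (e.g. corr(K_d, K_dd) ≈ 0.98 elementwise on simulated data),
which limits how sharply a single trait can separate the six components
(see *Identifiability*, below).

### REML

With H(λ) = Σ_i λ_i K_i + I, the residual variance is profiled analytically
and the criterion maximized over λ ∈ [0, ∞)⁶ is

    L(λ) = −½[(n−p)(ln σ̂² + 1) + ln|H| + ln|XᵀH⁻¹X|],
    σ̂² = (y − Xβ̂)ᵀH⁻¹(y − Xβ̂)/(n−p),   β̂ = GLS.

The model has seven variance parameters; profiling just removes one search
dimension, and a test verifies the profiled form equals the textbook
criterion (all three terms negative) evaluated on the full covariance at
θ = λσ̂².  Optimization uses L-BFGS-B with start 0.5 per ratio, box
[0, 10⁴], stopping when the objective changes by < 1e-8 or the projected
gradient norm falls below 1e-6, capped at 500 iterations.  The fit is
deterministic: identical inputs reproduce results bit for bit.  Boundary
estimates pile at exactly 0, as expected for variance ratios.

### Background spectrum and genome scans

The fitted aggregate G = Σ λ̂_i K_i is eigendecomposed once
(G = U diag(δ) Uᵀ; eigenvalues clipped at max(δ)·1e-12 from below and
sorted non-increasing), and the data rotated: y* = Uᵀy, X* = UᵀX.  In these
coordinates the null covariance is diag(δ + 1) and the polygenic null
log-likelihood L₀ is computed once.

Scans hold the background λ̂ structure fixed — only the candidate-effect
variance ratios are optimized per marker or pair.  This two-step scheme is
what makes the one-time eigendecomposition useful: each candidate is a
rank-q update (q = 2 columns for a marker, 4 for a pair), handled by the
Woodbury identity, so after the one-time O(n²) rotation of the candidate
columns each objective evaluation costs O(q²), independent of n.  The
candidate optimizer is the same bound-constrained quasi-Newton routine
(start 0.1, box [0, 10⁶], cap 200 iterations, ftol 1e-10).  The fast path
is asserted against a naive implementation that rebuilds the full n×n
covariance per candidate (agreement ≤ 1e-4 on the LRT).

LRT values are clipped to 0 when negative by at most 1e-8 (optimizer
round-off at the boundary); anything more negative raises an internal
consistency error.  A marker or pair whose candidate columns are all zero
returns LRT = 0 with a degeneracy flag rather than an exception; zero
columns within an otherwise informative candidate are pinned at zero
variance.  Nominal p-values use χ² with 2 or 4 df; because variances are
tested on the boundary of their space the true null is stochastically
smaller, so these p-values are conservative.  The null-calibration tests
confirm this empirically (e.g. a 2D null study's 0.95 LRT quantile ≈ 2.5
versus the nominal 9.49).  No multiple-testing correction is applied;
significance thresholds are the user's choice.

### Parallelism

Kinship work and the per-marker / per-pair scans are embarrassingly
parallel.  Work items are split into contiguous chunks whose sizes differ by
at most one and dispatched to worker processes; items are computed
independently and reassembled in submission order, so outputs are
byte-identical for every worker count (asserted in tests).  The
variance-component stage takes all six kinships as one joint optimization
and runs serially.

## Simulator

`simulate_genotypes` emulates an F2-type biparental population: each
individual carries two parental gametes, each gamete an independent Markov
chain along every chromosome with switch probability r (the adjacent-marker
recombination fraction, no interference), giving the stationary genotype
frequencies ¼ A : ½ H : ¼ B.  Defaults: 12 chromosomes (a rice-like
karyotype, capped at m) and r = 0.2 — bins are broad genomic segments, so
appreciable adjacent-bin recombination is realistic.  μ = 0 and σ² = 1
unless configured.

Traits come from three routes:

* **sparse** — explicit planted effects, the literal model sum plus
  N(0, σ²) noise; used for planted-signal studies.  The truth record stores
  the genetic sum and residuals so y − genetic = ε exactly.
* **polygenic** — every marker/pair effect drawn iid normal with each
  component's total variance split equally across its terms, with no
  kinship-based rescaling.  On the normalized-kinship scale this realizes
  λ_i = V_i·c_i/(#terms) (c_i the normalization constant), not V_i itself.
* **covariance draw** (`draw_polygenic_trait`) — y sampled directly from
  N(μ, (Σ λ_i K_i + I)σ²) using the actual normalized kinships; realizes a
  prescribed λ exactly and therefore drives the parameter-recovery studies.

What the simulator does *not* emulate: genotyping error, missing data,
segregation distortion, crossover interference, real LD block structure, or
non-Gaussian residuals.  Tests passing on simulated data show the machinery
is correct under the model's own assumptions; they do not certify behaviour
under those real-data complications.

## Identifiability of the variance ratios

The profiled likelihood is asymptotically flat along rays λ → cλ as
c → ∞ (σ̂² shrinks like 1/c while the genetic covariance λσ̂² stays fixed).
When a realization lets the rich six-matrix covariance fit the data almost
perfectly, the fitted residual variance collapses toward zero and the
*ratios* run off along this plateau, while the *component variances*
λ̂_i σ̂² remain finite and correctly attributed.  With the strongly
correlated uncentered kinships this happens in a noticeable fraction of
replicates at n = 300.  Consequently, per-component conclusions (and the
parameter-recovery assertions in the test suite) are drawn on the
component-variance / proportion scale, which stays identifiable; raw ratios
are reliable when few components are free (the single-component fits used
by the grid-search oracle) or when the residual variance is well separated
from zero.

## Degenerate inputs and numerical conventions

* Missing or invalid genotype symbols are an error naming row and column;
  no imputation.  Numeric Z/W tables are accepted verbatim (the coding
  pairing is not enforced in numeric mode).
* Constant phenotypes are readable but rejected by the variance fit with a
  zero-variance error.
* All matrix/table writers use `%.17g`, so write→read round-trips are exact;
  kinship gzip members are written with a fixed timestamp so repeated runs
  are byte-identical.
* Eigendecomposition uses the symmetric solver; an asymmetric aggregate
  (> 1e-8) signals a kinship invariant violation and raises.
* Ties in scan argmax resolution follow NumPy's first-maximum convention.

## Problem sizes in the test suite

Unit tests run on instances of n ≤ 120, m ≤ 40.  The statistical studies
use: six-component recovery at n = 300, m = 200 with 20 replicates per
component; null calibration with 200 pure-noise replicates (n = 200, m = 40
for the 1D rate; n = 100, m = 6 for the 2D quantile, one genotype draw per
study with fresh noise per replicate — the standard fixed-design null);
planted-signal recovery with 20 replicates at n = 200 (m = 50 for 1D,
m = 20 for 2D); fast-vs-dense scan equivalence on 20 instances with n ≤ 40,
m ≤ 8.  `scripts/acceptance.py` uses the same designs at reduced replicate
counts and reports the measured values.

## Known limitations

* The normalization convention (mean diagonal 1, no centering) is one of
  several in use; variance *proportions* from other conventions are not
  directly comparable, and reproducing published shares on external data
  may require matching the original convention.
* Ratio-scale estimates degenerate when σ̂² collapses (see above).
* Background ratios are not re-estimated per candidate during scans; a very
  large single-QTL effect is partly absorbed by the background, which makes
  the scans conservative rather than anticonservative.
* Single-machine parallelism only; no cluster scheduling.
* No SNP-to-bin construction: inputs are assumed pre-binned markers.
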