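# Methods

## Model

Multi-block data are K groups of continuous variables ("blocks")
measured on the same I observation units and concatenated column-wise
into one I × J matrix X (J = Σ_k J_k).  The model approximates the
(column-standardized, optionally block-scaled) data by a simultaneous
component decomposition written on the weight side,

    X ≈ X W Pᵀ,    T = X W,    PᵀP = I_Q,

with component weights W (J × Q) and loadings P (J × Q).  Because the
scores T are an explicit linear combination of the observed variables,
sparsity in W performs variable selection: a unit's score can be
computed from the selected variables alone.

Two kinds of structure are imposed on W:

* **Common/distinctive constraints.**  Each component is assigned a
  nonempty subset of blocks; weights outside those blocks are fixed to
  zero.  A component using every block is *common*, one using a proper
  subset is *distinctive* for those blocks.  The assignment expands
  into a binary J × Q constraint mask.  Loadings are never constrained,
  so a distinctive component may still account for variance in a
  foreign block.
* **Penalties.**  The estimation criterion is

      L(W, P) = ‖X − X W Pᵀ‖²_F + λ1 Σ|w_jq| + λ2 Σ w²_jq,   PᵀP = I,

  a lasso plus ridge on the free weights only.  The lasso sets weights
  exactly to zero; the ridge stabilizes the estimates and, when J > I,
  lifts the lasso-only limit of at most I selectable coefficients.
  With λ1 = λ2 = 0 and no mask the criterion is plain PCA of the
  concatenated blocks; with penalties but no mask it is sparse PCA.

The number of distinct common/distinctive structures for Q components
over K blocks is the number of multisets of size Q over the 2^K − 1
nonempty block subsets, C(2^K − 1 + Q − 1, Q): 10 for (K=2, Q=3), 15
for (K=2, Q=4), 924 for (K=3, Q=6).  Templates are canonicalized
(subsets sorted by size, then lexicographically) because component
order is not identified.

## Estimation

Alternating minimization with two exact conditional updates:

* **Loadings.**  For fixed W, the minimizing column-orthonormal P is
  the reduced-rank Procrustes solution P = U Vᵀ, where XᵀX W = U D Vᵀ
  is a thin SVD.  Rank-deficient cases inherit the deterministic
  tie-break of the LAPACK SVD.
* **Weights.**  For fixed orthonormal P, one full coordinate-descent
  sweep over the free entries (components outer, variables inner, fixed
  order for reproducibility).  Each coordinate is set to its exact
  univariate minimizer, the soft-threshold expression

      w_jq ← S(r_jq, λ1/2) / ((XᵀX)_jj + λ2),
      r_jq = (XᵀX P)_jq − Σ_{j'≠j} (XᵀX)_{jj'} w_{j'q},

  with S(a, t) = sign(a)·max(|a| − t, 0).  Masked coordinates are never
  touched, so constraint zeros are bitwise exact.  The update formula
  is validated in the test suite against an independent dense-grid 1-D
  oracle rather than trusted on derivation alone.

Both updates decrease L, so the recorded loss trace is non-increasing
and the iteration converges to a fixed point, usually a local minimum.
Convergence is declared when the relative loss decrease falls below
`tol` (default 1e−8) or after `max_iter` (default 500) iterations.

**Initialization.**  The default start is the leading-Q right singular
vectors of X, masked and column-renormalized — deterministic and close
to the unpenalized optimum.  Additional starts draw seeded
standard-normal values on the free positions; the start with the lowest
final loss wins.  Each component is finally sign-flipped so its
largest-magnitude weight is positive.

**Kernels.**  Two numerically identical inner loops are provided: one
on the precomputed J × J Gram matrix (O(J) per coordinate; used when
J ≤ I) and one streaming through X itself (O(I) per coordinate; used
when J > I, where it is both faster and lighter on memory).  They are
tested to agree to 1e−9.  The sweeps are JIT-compiled.

**Degenerate components.**  A component whose weights are entirely
thresholded away keeps its Procrustes loading column and is flagged
(`dead_components`), not treated as an error: under a strong lasso a
constrained component may lose all its planned variables.

**λ_max and cardinality matching.**  The smallest λ1 at which a sweep
from W = 0 stays at zero is 2·max over free (j,q) of |(XᵀX P⁰)_jq| with
P⁰ from the SVD start; it bounds penalty grids and bisection brackets.
`tune_lasso_to_cardinality` bisects λ1 (shared, against the total
nonzero count, or per component against per-component counts) until the
fitted count matches a target within 0.01%; because the count is a step
function of λ1, an exactly unreachable target returns the closest
bracket endpoint with `exact=False`.  The bisection uses continuation:
the first fit warm-starts from the λ1 = 0 solution — unique under the
ridge, so the path enters the correct basin rather than a rotated
local minimum — and subsequent fits from the previous accepted
weights, the standard homotopy practice for lasso paths.

## Model selection

**Eigenvector cross-validation.**  Rows are partitioned into seeded
folds (default 10, as in every analysis the package replicates).
Preprocessing (standardization, optional block scaling) is re-estimated
on the training rows of each fold and applied to the held-out rows.
For a held-out row x, the entry x_j is predicted without using x_j:
scores are computed from the remaining variables through the weights,
t̂ = Wᵀx_{−j}, and the default prediction solves the self-consistency
equation of model-based imputation,

    x̂_j = p_jᵀ Wᵀ x_{−j} / (1 − p_jᵀ w_j),

which is exact whenever the fitted model reconstructs the data exactly
and reduces to the classic eigenvector expression for plain PCA
(W = P).  Two variants are exposed: `deleted` (the uncorrected plug-in
p_jᵀWᵀx_{−j}) and `projection` (whole-row reconstruction x W Pᵀ, the
fast variant that trades a small optimistic bias for speed).  Because
the scores come from the weights, constraint masks and penalties
directly influence the MPRESS — a loadings-only projection would be
blind to them, since loadings are unconstrained in every candidate.

MPRESS is the mean squared prediction error over all held-out entries;
its standard error is the standard deviation of the per-fold mean
PRESS over folds divided by √(number of folds).

**One-standard-error rule.**  Among candidates whose MPRESS is within
one standard error of the minimum, the simplest is selected.
Complexity is oriented so that lower = simpler throughout: Q for
component-number tables, the free-weight count for structure tables
(most imposed zeros = simplest), and −λ for penalty grids (so the rule
returns the largest penalty within one SE).  Ties break toward lower
MPRESS, then label order.

**Sequential strategy.**  (1) choose Q by CV of unconstrained,
unpenalized models for Q = 1..Q_max; (2) choose the structure by CV of
every candidate template (λ1 = 0, fixed small ridge); (3) tune λ2 on a
log grid when J ≥ I (λ2 = 0 otherwise — with more units than variables
the solution is identified without it) and then λ1 on a linear grid
from 0 to λ_max.  The structure search warns above 10,000 candidates
and requires an explicit list beyond that.

## Synthetic data generator

The generator emulates a sparse SC model with controlled structure:

1. Draw P on the template pattern with standard-normal free entries,
   zero out floor(fraction × free entries) additional entries per
   component uniformly at random (keeping ≥ 1 nonzero per participating
   block), and orthonormalize columns within the pattern by alternating
   projections (polar orthonormalization / pattern masking, to 1e−12).
2. Draw T as orthonormalized standard-normal scores (QR with a
   deterministic sign fix).
3. Set X_signal = T Pᵀ and take W as the minimum-norm matrix with the
   same zero pattern solving X_signal W = T (per component, the
   least-squares minimum-norm solution of P_Sᵀ w_S = e_q on the support
   S).  The identity X_signal W = T holds to 1e−9 by construction.
4. Add homoscedastic Gaussian noise rescaled — including the
   signal-noise cross term — so the realized ‖E‖²/‖X‖² equals the
   requested noise fraction exactly (to 1e−6).

Ready-made crossed designs mirror the simulation conditions the package
replicates: {5%, 25%, 50% noise} × {high, low sparsity}, true structure
D1 D2 C, with high sparsity = 60% zeros in every component and low
sparsity = 2% zeros in the common and 52% in the distinctive
components; high-dimensional at I=100 with two blocks of 250 variables,
low-dimensional at I=195 with two blocks of 10; 20 replications per
cell.  Per-component zero fractions of *total* entries are converted to
fractions of *free* entries internally.

**What the generator does and does not emulate.**  It honors every
stated design factor (dimensions, structure, zero fractions, noise
fractions) but fixes internal details the design leaves open:
orthonormal scores, pattern-orthonormal loadings, minimum-norm weights,
homoscedastic noise.  Two consequences matter for interpreting results
on it.  First, the noiseless signal has all Q singular values equal, so
without penalties the weight matrix is identified only up to
block-respecting rotations and null-space components — parameter
recovery is meaningful only for the full procedure (mask + ridge +
cardinality-matched lasso), and the package's noiseless-recovery check
is stated for that procedure.  Second, each block carries an orthogonal
copy of the common component's scores, so overly sparse structures can
predict nearly as well as the generating one; structure selection on
this generator is therefore harder to separate by cross-validation
than the corresponding published results suggest, and the structure
study's selection rates should be read with that in mind.  Real
multi-block data, with dominant block-specific variation and unequal
component strengths, do not share these symmetries.

## Simulation studies

**Recovery study** (`run_recovery_study`): per condition × replication,
the generated data are analyzed as-is (the ground truth lives on the
generator's scale) twice — the constrained fit with the true mask and a
shared lasso bisected to the true total nonzero count, and concatenated
sparse PCA with per-component lasso values bisected to the true
per-component counts.  The constrained fit's ridge is CV-tuned once per
condition on replication 0 (one-SE rule on a log grid spanning 1e−4 to
10 times the mean diagonal of XᵀX) and reused within the condition; the
sparse PCA baseline uses a numerically negligible ridge (1e−6 of the
mean diagonal), mirroring the reference elastic-net implementation's
default.  The ridge matters decisively in the J > I regime: with a
negligible ridge the constrained fit's congruence drops from ≈0.999 to
≈0.77 at 5% noise.  Both aligned and unaligned vectorized Tucker
congruences and the zero/nonzero classification rate are recorded.

**Structure-selection study** (`run_structure_selection_study`): per
condition × replication, all 10 candidate structures (K=2, Q=3) are
cross-validated with λ1 = 0 and a per-condition CV-tuned ridge, using
one fold partition per replication so candidates are compared paired;
the study records whether the minimum-MPRESS and the one-SE candidates
equal the generating structure.

Replications draw from independent SeedSequence streams keyed by
(condition, replication), so results are bit-reproducible from the
stored config and independent of execution order.  The study runners
use a fit tolerance of 1e−7 inside cross-validation, which changes
selection outcomes by less than the fold-to-fold noise.

## Metrics

Tucker congruence is the cosine between the two vectorized weight
matrices; with alignment on (the default), the estimate's columns are
first permuted by optimal assignment on absolute column-wise congruence
and sign-flipped to nonnegative congruence — applied symmetrically to
both methods so the unconstrained baseline is not penalized for label
switching.  Values ≥ 0.85 are reported as fair similarity, ≥ 0.95 as
near equality.  The classification rate is the percentage of weights
whose zero/nonzero status agrees after alignment (truth zero iff
exactly 0; estimates zero below 1e−12 in magnitude — coordinate descent
produces exact zeros, so any tolerance below the smallest true
magnitude is equivalent).  %VAF is 100·(1 − ‖X − XWPᵀ‖²/‖X‖²) in total
and 100·‖X w_q p_qᵀ‖²/‖X‖² per component; per-component values sum to
the total only for orthogonal score columns.

## Numerical choices and limitations

* Standardization uses the sample variance (I − 1) by default, with a
  flag for the population convention; constant columns are an error,
  and missing values are rejected rather than imputed.
* The Gram/streaming kernel caches (XᵀXW, resp. XW) are refreshed every
  50 sweeps to cap floating-point drift.
* A curvature of zero at a coordinate (zero column with λ2 = 0) leaves
  the weight at zero rather than dividing by zero.
* Denominators |1 − p_jᵀw_j| < 1e−8 in the corrected CV prediction fall
  back to the uncorrected value and flag the result.
* The structure enumeration is exhaustive; designs beyond ~10,000
  candidates are the caller's responsibility.
* Fits are local minima; multiple random starts are supported but the
  studies use the deterministic SVD start for reproducibility.
* Study problem sizes: the recovery and high-dimensional selection
  studies run at I=100, J=500 with 20 and 5 replications per condition
  respectively, the low-dimensional study at I=195, J=20 with 20 — the
  design sizes of the conditions they replicate, with the
  high-dimensional selection study thinned to 5 replications as a
  deliberate compute/precision trade-off.
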