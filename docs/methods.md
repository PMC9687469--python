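# Methods

## Model

A sample with features `f ∈ R^n` is embedded in two steps.  The linear
front-end computes `(x1, x2) = W f` with a trainable `W ∈ R^{2×n}` and
no bias (a bias would change the `2n + 12` parameter total, and the
linear map is defined as a plain matrix product).  The circuit then
prepares

```
|x⟩ = Rx(x1)⊗Rx(x2) · Π_{l=4..1} [ Ry(θ_{3l-1})⊗Ry(θ_{3l}) · ZZ(θ_{3l-2}) · Rx(x1)⊗Rx(x2) ] |00⟩
```

with the conventions `Rx(φ) = exp(−iφX/2)`, `Ry(φ) = exp(−iφY/2)`,
`ZZ(θ) = exp(−iθ Z⊗Z/2)`, amplitudes ordered `(|00⟩,|01⟩,|10⟩,|11⟩)`.
Four ansatz layers of (encode, entangle, rotate) plus a closing
re-encoding give 13 gate layers and 14 circuit stages, and 12 trainable
angles.  The layer order and the closing encoder are the unique
arrangement consistent with a 14-stage trajectory and a 12-angle budget
under the (encode, ZZ, Ry-pair) ansatz; the `final_encoding` flag turns
the closing encoder off for the 13-stage variant.  Simulation is exact
statevector arithmetic on 4 amplitudes; there is no noise model, and no
generalization to wider registers beyond `n_layers`.

Training minimizes the Hilbert–Schmidt cost `C = 1 − ½ tr[(ρ−σ)²]`
between the two class density matrices.  The training loop evaluates the
algebraically identical pairwise-overlap expansion

```
tr[(ρ−σ)²] = mean_{aa'} |⟨a|a'⟩|² + mean_{bb'} |⟨b|b'⟩|² − 2 mean_{ab} |⟨a|b⟩|²
```

so the differentiated path never touches complex 4×4 matrix algebra; the
trace form remains the reported/reference route and the two are checked
against each other to 1e-10 in the tests.

## Gradients and optimization

Gradients of the batch cost with respect to all `2n + 12` parameters are
analytic.  Forward-mode tangent states `∂|x⟩/∂x1`, `∂|x⟩/∂x2` and
`∂|x⟩/∂θ_k` are propagated through the circuit gate by gate (each gate
contributes `U · tangent + (∂U) · state`), combined through the overlap
expansion (`∂|z|² = 2 Re(z* ∂z)`), and chained onto `W` via
`∂x_s/∂W[s,j] = f_j`.  The contract, enforced in the tests, is agreement
with central finite differences (`h = 1e−6`) to 1e−4 relative error.

The optimizer is RMSProp with the protocol defaults 1500 steps, batch
size 10, step size 0.01; the decay (0.9) and epsilon (1e−8) are the
standard values, recorded in run metadata.  "Batch size 10" is read as
10 samples drawn *per class* per step — the cost needs both ensembles
every step — with draws without replacement within a step unless a class
is smaller than the batch; a `pooled` batch mode (10 rows overall,
redrawn until both classes appear) exists for sensitivity analysis.
The trace records the mini-batch cost per step; reported training/test
costs are always recomputed on the full split ensembles.

Initialization (distribution unstated in the protocol, so fixed here and
named in run metadata): linear weights `N(0, 0.1²)`, angles uniform on
`[0, 2π)`.  With standardized features this starts `(x1, x2)` at scale
`≈ 0.1 √n` radians, inside the first period of the encoding.

## Classifier and scoring

`f(x) = ⟨x|ρ−σ|x⟩` is computed as the difference of mean fidelity
kernels against the cached embedded training ensembles (each training
and test sample is embedded exactly once).  Class A is the first label
in sorted order and carries the positive sign of `f`.  Ties (`f = 0`,
measure-zero but constructible) go to class B deterministically, and the
tie label is configurable.  Precision/recall/F1 are computed with
scikit-learn; the positive class defaults to the lexicographically
second label ("malignant" on the diagnostic table) and is configurable,
since which class the published scores treated as positive is unstated.
Zero-denominator cases warn and report 0.

## Preprocessing

Standardization uses per-column mean and population (1/N) standard
deviation, matching the usual standard-scaler semantics; constant
columns are flagged, warned about and passed through with sd 1 so
degenerate synthetic inputs survive.  PCA is an eigendecomposition of
the training sample covariance (1/(N−1)); loadings are orthonormal
eigenvector columns with explained variances sorted descending, and each
column is sign-fixed so its largest-magnitude entry is non-negative,
making results eigensolver-independent.  Both transforms are fitted on
the training split only and applied unchanged to held-out rows — the
leakage-safe default for an honest generalization estimate.  Whether the
original study pooled the data before fitting is unknowable from the
protocol as described, so a `fit_on_all` flag reproduces the pooled
alternative; the fine ordering of scores across adjacent PCA settings is
sensitive to this choice at the level of seed-to-seed scatter.

## Synthetic data

The generator emulates a clinical two-class table: class-conditional
Gaussians with shared covariance `(cov_scale²/cov_rank)·WWᵀ +
noise_sd²·I` (`W` standard normal, drawn once per seed) and means
`separation` apart along a random unit direction.  The low-rank
component gives PCA genuine structure to find; the `1/cov_rank` scaling
keeps per-feature variance at `cov_scale²` regardless of rank, and
`cov_rank = 0` yields pure isotropic noise (used to verify variance
recovery).  Labels are `{−1, +1}`, matching the sign classifier.
Splitting is stratified 3:2 by default (both classes guaranteed in small
test sets), with a flag for simple random splits.

Two named regimes fix the study conditions used by the tests:

* `overparameterized_spec`: 200 features, 100 rows (40 used for
  training), separation 1.0 under unit noise, rank 10 — classes whose
  distributions overlap almost completely, against 412 parameters;
* `well_conditioned_spec`: 10 features, 668 rows (400 training),
  separation 3.0, rank 3 — clearly but not trivially separable, against
  32 parameters.

The generator does **not** emulate heavy tails, missing values,
feature-scale heterogeneity beyond the shared component, or the
deep-network feature statistics of image embeddings; conclusions from
passing tests are about the geometry (separation vs noise vs parameter
count), not about any particular real dataset.

## Problem sizes and numerics

The test suite trains full 1500-step models only where the claim needs
them (5 seeds per synthetic regime; 5 split seeds × 6 sweep entries on
the 569-sample diagnostic table — about two minutes total); unit tests
use few-hundred-step toys.  State normalization is validated at 1e−9;
unitarity holds to 1e−12; Hermiticity/trace checks on density matrices
at 1e−8; orthonormality of loadings at 1e−8.  Seeds split by role
(generator, split, initialization, batch sampling) so each randomness
source is independently reproducible; identical configuration gives
byte-identical outputs.

## Known limitations

* Two qubits only; `n_layers` is the only circuit-shape dial.
* The pairwise-overlap cost is O(M²) in the batch/split size — fine at
  hundreds of samples, not tuned for much larger tables.
* The fidelity classifier weights all training points (no k-limited
  neighbourhood) and provides no probability calibration.
* Median score orderings across adjacent PCA settings (e.g. 8 vs 16 vs
  30 components) sit within seed-to-seed scatter on the diagnostic
  table; single-split orderings should not be over-read.
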