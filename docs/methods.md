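# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates.

## Shape model and pose normalization

A molecule is modelled as the union of its atoms' van der Waals spheres.
Pose normalization translates the unweighted centroid of the atom centres
to the origin and applies one uniform scale s = 1/max_i(|c_i| + r_i) to
both coordinates and radii, so the farthest sphere-surface point lies
exactly on the unit sphere. The centroid is unweighted (not mass-weighted)
and no rotational alignment is performed: the final descriptor is rotation
invariant, so aligning poses would add complexity without changing the
output. Hydrogens are kept when present in the input and never added;
occupancy and temperature factors are parsed from PDB records and carried
on the `Atom` but do not enter the default depth map (no established
weighting rule exists for them in a shape extent function; they are exposed
for extensions). Radii come from rdkit's periodic table, with a 1.5 Å
fallback for unrecognized elements (logged).

Degenerate geometry — all atoms coincident with effectively zero radius
(total extent below 1e−12) — raises rather than producing an unbounded
scale.

## Depth map

The spherical function f(θ, φ) is the *radial extent*: the largest
t ∈ [0, 1] such that t·u(θ, φ) lies inside some atom sphere, computed by
analytic ray–sphere intersection (the largest non-negative root of
t² − 2t(u·c) + |c|² − r² = 0 over atoms, 0 on a miss). The complementary
"depth from the sphere" 1 − f is available as `depth_variant="inverse"`;
both carry the same information (an affine map), extent being the
conventional star-shaped extent function of shape retrieval.

A voxel mode rasterizes atoms into an occupancy grid of side 2G + 1 voxels
over [−1, 1]³ (default G = 64) and reports, per direction, the along-ray
projection of the farthest occupied voxel the ray passes through (marched
at half-voxel steps). Its deviation from the analytic mode is bounded by
roughly the voxel half-diagonal plus the rasterization error, ≈ 2/G, and
it serves as a fidelity cross-check of the ray caster, not as the default.

Sampling grid: equiangular θ_j = π(2j+1)/(4B), φ_k = πk/B,
j, k = 0 … 2B−1. Default bandwidth B = 64.

## Harmonic analysis

Real spherical harmonics use the normalization
S_{l,m} = √((2l+1)(l−m)!/(4π(l+m)!)) and associated Legendre functions
without the Condon–Shortley phase. Two numerical choices matter:

- **Stable evaluation.** Unnormalized P_l^m overflow float64 near l ≈ 40,
  so the normalized functions P̄_{l,m} = S_{l,m}P_l^m are generated
  directly by the standard three-term recurrence (diagonal seeding then
  upward in l). S_{l,m} itself is computed in log space via `gammaln`.
  Values match `scipy.special.lpmv` (phase removed) wherever both are
  finite.
- **Quadrature.** Coefficients are computed with Driscoll–Healy weights
  for this offset equiangular grid,
  a_j = (2/B)·sinθ_j·Σ_{k<B} sin((2k+1)θ_j)/(2k+1), which integrate
  Legendre polynomials exactly up to degree 2B − 1. A plain midpoint
  sinθ·Δθ rule is only second-order accurate (Gram deviation ≈ 1e−4 at
  B = 64) and would dominate the coefficient error; with the exact weights
  the Gram matrix of the basis is the identity to machine precision and
  Parseval holds exactly for band-limited maps.

The per-degree norms ‖v_l‖ = √(Σ_m c_{l,m}²) form the descriptor; the sum
runs over all orders of a degree, which is what makes the vector invariant
under rotations (a rotation acts unitarily within each degree). The
residual rotation error observed in tests (~5e−3 relative at B = 32) is
sampling error of the depth map, not of the transform. Raw length is
l_max + 1 = 64 by default; the working dimension after selection defaults
to 60. `l_max ≤ B − 1` is enforced to avoid aliasing.

## mRMR selection

Mutual information uses the discrete plug-in estimator in nats on
contingency tables after equal-frequency discretization (default 10 bins;
vectors with ≤ 10 distinct values pass through as categories). The greedy
criterion at each step maximizes ψ = D − R over candidates, with D the
mean relevance I(x_j, y) of the candidate set and R the mean mutual
information over *distinct* pairs in the set. Diagonal terms are excluded
deliberately: I(x, x) is an entropy, not a redundancy, and including it
would (a) stop step 1 from reducing to max-relevance and (b) bias
selection against high-entropy features regardless of redundancy. Ties
break toward the lowest feature index, making runs reproducible.
Selection is always fitted on the training partition; the chosen index set
is frozen before any held-out data is touched.

## PCVM

The classifier is l(x) = ψ(Φ_θ(x)w + b) with a probit link and Gaussian
kernel exp(−‖x−x′‖²/θ²) on training points. Each weight has a truncated
Gaussian prior restricted to sign(w_i) = y_i; the bias has a zero-mean
Gaussian prior. Training is EM with the weights reparametrized as
w_i = y_i·ŵ_i, ŵ_i ≥ 0 (so the sign constraint holds after every
iteration by construction):

- E-step: truncated-normal mean of the probit latent variable,
  z̄ = η + y·N(η)/ψ(yη), and posterior means of the precision
  hyperparameters, ᾱ_i = 1/ŵ_i², β̄ = 1/b².
- M-step: ridge system ŵ = (ΦᵀΦ + diag ᾱ)⁻¹Φᵀ(z̄ − b), clipped at zero
  (the MAP under the truncated prior), then b = Σ(z̄ − Φŵ)/(n + β̄).
- Pruning: basis points with ᾱ_i > 1e6 (|ŵ_i| < 1e−3) are removed.

Defaults: max_iter 500, tol 1e−4 on the largest parameter change, seeded
normal initialization of ŵ and b (b must not start at exactly zero or its
precision pins it there). The kernel width is selected by stratified
k-fold cross-validation (10 folds by default) over multiples
{¼, ½, 1, 2, 4} of the median pairwise distance when not given.

Two behaviours are inherent to this scheme and documented rather than
hidden. First, the adaptive prior 1/w² is scale-free, so on cleanly
separable data the weights keep drifting slowly and the run may hit
max_iter without meeting tol; the model is still usable and the
`training_log` carries a converged flag. Second, the log-likelihood trace
can dip during the first iterations while pruning reshapes the basis; once
the retained set stabilizes the EM ascent is monotone, and the tests check
monotonicity after that transient. Prediction thresholds the probability
at 0.5, with ties assigned to the active class (arbitrary, documented).

## Evaluation

ACC, PRE, REC, MCC from the confusion counts in the standard forms;
Cohen's κ = (PA − PE)/(1 − PE) with PA = (TP+TN)/n and chance agreement
PE = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/n². Zero denominators yield NaN
plus an `undefined` flag instead of a silent zero. Implementations are
cross-checked against scikit-learn's `matthews_corrcoef` and
`cohen_kappa_score` in the tests.

## Synthetic data

The generators emulate the study conditions of a receptor–ligand activity
set without any downloads:

- **Labelling.** p-bioactivity = −log10 of the raw assay value; repeated
  measurements are averaged on the log scale (the raw-scale alternative is
  exposed). Actives are +1; inactives are sampled uniformly without
  replacement from a pool at 30% of the active count, reproducing the
  class imbalance typical of such data. An optional rule can additionally
  relabel actives with p-bioactivity below a threshold (−10 in the
  exploratory variant) as inactive; it is off by default because diluting
  the inactive class with weakly active compounds degrades the labels.
  Synthetic actives carry activities drawn uniformly over [−12, 4], the
  span such datasets exhibit.
- **Shapes.** Actives are compact Gaussian clusters of carbon atoms
  (σ = 1.5 Å); inactives are rods with 1.5 Å atom spacing; both get
  isotropic jitter (default 0.1 Å). The two classes are shape-separable by
  construction: they validate the pipeline's mechanics (invariance,
  fold-safety, calibration), not its chemistry. Passing tests on them
  shows the machinery is correct; it says nothing about accuracy on real
  ligand sets, where the activity signal in pure shape is far weaker.
- **Feature tables.** Small tables with known mutual-information structure
  (label-carrying, duplicated and noise columns) back the selection and
  classification oracle tests.

All generators are deterministic given a seed.

## Experiment protocol and problem sizes

One stratified 80/20 train/test split by seed; mRMR and all
hyperparameter tuning on the 80% only; 10-fold stratified CV for tuning
(folds reduced automatically when a class is too small); one final refit
and a single evaluation on the 20%. Baselines delegate to scikit-learn
(SVC with standardization, random forest with 200 trees, Gaussian naive
Bayes, k-nearest neighbours with standardization) at library defaults.

The shipped benchmark runs use 130 molecules (100 actives, ratio 0.3) at
the full descriptor setting B = 64, l_max = 63; unit tests use B = 16–32
grids and 20–30-molecule sets, sizes at which every property under test is
already sharp. Reports store the partition sizes, the selected feature
indices and a config hash so a run can be audited and reproduced.

## Known limitations

- Single conformer per molecule: the descriptor depends on the 3D pose
  given (or the one ETKDG generates from SMILES); conformer ensembles are
  out of scope.
- The depth map sees only the star-shaped silhouette from the centroid;
  deep concavities and interior voids are invisible to it.
- Binary classification only; no multiclass PCVM, no logit link.
- The mutual-information estimator is the binned plug-in; it is biased for
  small samples, which matters only for the selection ranking, not for
  classification itself.
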