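# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Signal model and deconvolution

Each voxel's diffusion-weighted attenuation is a non-negative mixture of
three Gaussian compartments evaluated on the acquisition's gradient
table (b in s/mm², unit direction g):

- stick (intra-axonal, axis u): exp(−b d_par (g·u)²)
- zeppelin (hindered extra-axonal, axis u):
  exp(−b (d_perp + (d_par_zep − d_perp)(g·u)²))
- ball (isotropic): exp(−b d_iso)

Diffusivities are fixed, not fitted: d_par = d_par_zep = 1.7×10⁻³,
d_perp = 0.61×10⁻³ mm²/s, and two ball compartments at 1.7×10⁻³
(hindered isotropic) and 3.0×10⁻³ mm²/s (CSF-like) — the endpoints of
the conventional isotropic range. The default acquisition is five
shells at b = 500/1200/2400/4000/6000 s/mm² with 30/30/60/60/60
directions plus 14 b=0 volumes (254 volumes), directions spread by
electrostatic repulsion.

The forward operator has one column per streamline (stick kernels along
its local segment directions, entries weighted by in-voxel length),
up to three zeppelin columns per active voxel (one per bundle passing
through, oriented along the bundle's mean in-voxel direction), and one
ball column per active voxel per isotropic diffusivity. Streamline
columns are normalized by total in-grid length so a unit coefficient
contributes unit b=0 signal spread along the path — the recovered
coefficient is therefore a signal fraction (IASF), assumed constant
along the streamline.

Geometric conventions: continuous mm coordinates; voxel (i,j,k) is the
half-open box [i·v,(i+1)·v)×…; every polyline segment is subdivided
into equal pieces no longer than v/10 and each piece is binned at its
midpoint. Phantom synthesis and operator assembly implement this rule
independently (the phantom never calls the operator), so recovery tests
compare two separate signal syntheses.

**Solver.** Non-negative least squares is solved by a deterministic
active-set method on the normal equations (fast-NNLS): the Gram matrix
is formed once from the sparse operator, coordinates enter the passive
set by largest gradient, and subproblems are solved exactly. When the
unconstrained minimizer is already feasible — always the case for
noiseless full-rank phantoms — a single Cholesky solve returns it
directly. No stochastic initialization anywhere; identical inputs give
identical weights. Streamlines with weight below 10⁻¹⁰ (numerical zero
for double-precision NNLS) are filtered as implausible.

## Phantoms

`make_crossing_phantom` builds up to three bundles along the grid axes
crossing at the centre. Streamlines sit on a deterministic golden-angle
spiral across a tube of radius 0.22× the grid extent and each carries
its own sine-bend amplitude. This layout is deliberate: recovery of
per-streamline weights is only meaningful when every streamline has a
distinct voxel footprint (full column rank); randomly jittered parallel
lines in a narrow tube collapse onto identical voxel rows and make the
inverse problem non-identifiable. Ground-truth weights are uniform on
[0.2, 0.7]; traversed voxels carry an isotropic fraction of 0.2.
Noise: additive Gaussian, or Rician (magnitude of complex Gaussian) at
σ = 0.02 for integration tests — the acquisition's true SNR is unknown
and the phantom defaults make no claim to match it.

## Connectomes

Endpoints take the ROI label of their containing voxel, else the
nearest labelled voxel within 2 mm (one voxel); streamlines with an
unassigned endpoint, filtered weights, or both endpoints in one ROI
contribute to no edge. Edge weight: a_ij = Σ x_k l_k / (Σ l_k / N_ij)
(IASF mode) or N_ij (NOS mode). Matrices are symmetric, zero-diagonal,
nodes ordered by (network, label).

The atlas-merge rule assigns each fine ROI, per subject, to the
canonical network with maximal voxel overlap; an ROI is retained only
if its modal assignment holds in ≥ 80 % of subjects and its homologous
ROI has the same modal assignment (a subject with zero overlap counts
as disagreeing). Note the homologue condition compares *modal*
assignments: an ROI can be retained even when its homologue itself
fails the agreement bar, as long as the two modal networks coincide.

## Network measures

Lengths for path-based measures are reciprocal weights (the reference
toolbox convention; the alternative log transform is not implemented).
Disconnected pairs contribute 0 (= 1/∞) to efficiency rather than being
excluded. Clustering is Onnela's geometric-mean triangle intensity with
weights normalized by the graph's own maximum — per graph and per
subnetwork, so values are comparable within a graph but the
normalization differs across subjects. Modularity is Newman's spectral
method on the generalized modularity matrix B = W − γ s sᵀ/v (γ = 1 by
default): recursive leading-eigenvector bisection, zero eigenvector
entries joining the positive block, each split refined by greedy
single-node moves and accepted only if it increases Q. The algorithm is
deterministic; the seed parameter exists only for interface symmetry.

## Synthetic cohorts

A cohort is n subjects (default 88, ages uniform on 8–19 years, 46
female) with connectomes over a synthetic parcellation of eight
canonical networks (default 8 ROIs each). Within-network edges follow

    w = baseline + slope·(age − age_min) + sex_offset·1[M]
        + age_sex_slope·(age − age_min)·1[M] + subject_offset + ε,

truncated at 0, with ε ~ N(0, sd) per edge and the subject offset
shared across a subject's edges. Age enters generation as
(age − age_min) so baselines stay interpretable; the statistics module
handles its own centering. Between-network edges take baseline 0.25
with the same noise and no covariate effects. ICV is log-normal with a
male offset tuned to a ≈ 0.3 correlation with sex — enough variance for
head-size adjustment to be testable, not a claim about real heads.
Defaults (baseline 0.5, edge noise SD 0.05, subject offset SD 0.02)
keep truncation at zero practically inactive, so edge weights are
Gaussian to numerical accuracy.

The null cohort (all age/sex effects zero, noise positive) sets the
subject offset to zero: the offset is shared across all of a subject's
networks and would correlate the eight per-network tests, while the
calibration experiment pools them under a binomial model that assumes
independence. Since networks own disjoint edge sets, edge noise alone
makes the tests independent, and the marginal null distribution of each
test is unchanged either way.

Effect flags per network include `age_effect_nodes`: when set, the age
slope applies only to edges incident to the flagged nodes, which is how
node-level local-efficiency effects are programmed for the
feature-importance experiments.

## Statistics

Mixed models: each measure is regressed on age, sex, network and
z-scored ICV (raw mm³ values ruin the optimizer's conditioning; slope
tests and AIC are invariant to the rescaling) with a subject random
intercept — subjects contribute one row per network, so independence
across rows is implausible. Four fixed-effect structures are fitted by
maximum likelihood (so AICs are comparable): main effects, +age:network,
+age:sex, and the full three-way. Model choice is lowest AIC, ties to
fewer parameters. Interaction p-values are likelihood-ratio chi-square
tests against the nested reduced model (statsmodels offers no
Satterthwaite approximation; the method is recorded in each fit's
metadata). Optimizers are tried in the order lbfgs, bfgs, powell;
a model that still fails is flagged non-converged and excluded from
selection.

Per-network inference is OLS of the measure on age + sex + ICV, judged
at α = 0.005 with adjusted R²; no further multiple-testing correction
is applied beyond that fixed threshold. The density replication re-runs
every per-network model with connection density added (zero-variance
covariates are dropped with a warning) and reports which significance
flags change.

Elastic net: age is predicted from a network's node-level local
efficiencies. The data are split 80:20 stratified by age tertile
(a plain random split of 18 validation subjects can otherwise miss an
age extreme; unstratified splitting is available by flag), features are
z-scaled with training statistics only, and the penalty is selected by
mean fivefold-CV R² over the L1-ratio grid
(0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1) × 50 log-spaced α values spanning
[10⁻⁴, 10] × max|Xᵀy|/n (the largest α that keeps any coefficient
alive). The final fit's stationarity (KKT) conditions are checkable to
10⁻⁶ independently of the solver, and the node ranking is by absolute
coefficient with cumulative |β| shares.

## Problem sizes of the validation experiments

Chosen as the package's standard demonstration sizes: phantom recovery
on a 10×10×10 grid (two 30-streamline bundles + decoy, 254 volumes,
≈ 320 active voxels); calibration over 1000 null cohorts of n = 88
(8000 pooled per-network tests); interaction power over 200 replicates
with a visual-network edge slope of 0.01 per year; feature recovery
over 20 seeds with 26 nodes (a visual-network-sized feature set), 3 of
them carrying signal.

## What the synthetic experiments do and do not show

They demonstrate correctness and statistical calibration of the
machinery: exact recovery when the model is identifiable and noiseless,
graceful degradation under Rician noise, exact type-I error, power for
programmed effects, and sparse-signal ranking. They do not emulate real
tractography error (no false-positive bundles with partial signal
support, no curvature families of real anatomy), real edge-weight
distributions, developmental non-linearity, or site/motion artifacts —
so passing tests validate the pipeline, not any empirical claim about
brain development. Reported effect sizes in real cohorts depend on data
this package does not ship.

## Known limitations

- Desk-scale deconvolution only (≤ ~10⁴ streamlines); the Gram-matrix
  NNLS is dense in the number of columns.
- Zeppelin orientations come from bundle mean directions, not spherical
  deconvolution peaks; tractography itself is out of scope.
- The exact column normalization of the reference COMMIT implementation
  is not published; the unit-b0-contribution contract used here is
  stated, not asserted as identical.
- Mixed-model p-values are asymptotic (LRT); small-sample df
  corrections are not implemented.
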