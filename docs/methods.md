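# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open.

## Compartment model and discretization

The forward model is the parallel multi-tissue compartment model: each
tissue pool j obeys dC_j/dt = Ktrans_j·C_p(t) − kep_j·C_j(t) with the
shared plasma input C_p, giving C_j = Ktrans_j·(C_p ⊛ e^{−kep_j t}).
Convolutions are discretized by left-rectangle quadrature on the uniform
frame grid, C(t_n) = Ktrans·Δt·Σ_{m≤n} C_p(t_m)·e^{−kep (t_n−t_m)},
which is causal and exact for impulse inputs; the same rule is used in the
Toeplitz matrix of the deconvolution step, so forward simulation and
fitting are mutually consistent to machine precision. Against direct
Runge–Kutta integration of the ODE the rule is first-order accurate: on a
0.005-min grid the relative error after the uptake phase is below 1%,
with the discrepancy concentrated at curve onset where the value itself is
near zero.

The measured pixel curve is x_i(t) = Σ_j K_{i,j}·(C_p ⊛ e^{−kep_j t}) +
v_{p,i}·C_p(t) with nonnegative local volume transfer constants K_{i,j}
and local plasma volume v_{p,i}. After dividing every pixel curve by its
temporal sum, the pixel cloud lies in the convex hull of the sum-normalized
compartment curves; the mixing proportions on that simplex are
K_{i,j}·s_j / Σ_k K_{i,k}·s_k where s_j is the temporal sum of compartment
curve j. Identifiability requires linearly independent compartment curves
and at least one pure-volume pixel per compartment.

Because of the normalization, recovered Ktrans values are relative
(defined up to one global scale per compartment); only kep is an absolute
rate in /min. Absolute Ktrans quantification would require an unnormalized,
calibrated plasma input and is out of scope.

## Plasma input model

The package does not assume any particular arterial input function for
real data (the plasma curve is identified from the data as the
earliest-peaking vertex). The synthetic generator needs one, and uses a
biexponential washout — amplitudes 3.99 and 4.78, decay rates 0.144 and
0.0111 /min, the classic two-exponential population clearance model for
Gd-DTPA — gated by a smooth onset ramp 1 − e^{−(t−t0)/τ} with τ = 0.12 min.
The default bolus arrival t0 = 1.75 min places the four 0.5-min
pre-contrast frames strictly before arrival while giving the first
retained frame real signal; frames before arrival are exactly zero, which
is what makes dropping them lossless for the convolution relation on the
cropped window.

## Synthetic study design

The generator emulates the validation design used for simplex-based
deconvolution methods: known compartment curves multiplied by customized
transfer-constant maps, plus i.i.d. Gaussian noise at a configurable SNR
(10·log10 of mean squared signal over noise variance, measured inside the
tumor mask), clipped at zero concentration.

The default phantom is a 24×24 grid holding a circular tumor (radius 11
px) with the canonical rim/core architecture: a plasma-rich vessel zone in
the center, the slow pool (kep = 0.15 /min) in the core annulus, the fast
pool (kep = 1.5 /min, ten times faster) on the peripheral rim. Each zone
is split into three angular sectors carrying slightly different mixing
prototypes (dominant fraction 0.62–0.82), and each compartment has one
square pure-pixel patch (side 2 by default). Mixing weights are the zone
prototypes scaled per column by (Ktrans_1, Ktrans_2, v_p): tissue columns
by Ktrans = (0.25, 0.12), the plasma column by v_p = 0.05 in tissue but
0.7 in the vessel zone and plasma patch — a vessel pixel is mostly blood,
which is also why vessel pixels show the strongest enhancement and why
arterial input functions are read from arteries. A smooth random gain
field (log-amplitude 0.2) multiplies whole weight rows; row scaling is
invisible after sum normalization, so it adds intensity realism without
moving any point on the scatter simplex. A noise-free study therefore
contains a small set of distinct normalized profiles (12 by default),
which is exactly the finite-vertex geometry the identifiability theorem
addresses, while noisy studies scatter around those profiles.

`default_parameter_grid()` ships twelve study conditions varying the kep
contrast (10× / 4×), the pure-patch size (2 / 3 px) and the SNR
(20/30/40 dB). The upstream description of the original twelve settings is
not available; this grid is a documented stand-in, not a reproduction.

What the generator does **not** emulate: MR signal-to-concentration
conversion, motion, spatially correlated noise, bolus-arrival-time
variation across pixels, and partial-volume geometry finer than the pixel
grid. Passing tests on this phantom therefore demonstrate the estimator's
correctness under the model's own assumptions, not robustness to those
real-data effects.

## Preprocessing

Fixed order: mask → drop the first k frames (default 4) → remove
uninformative pixels → sum-normalize. "Temporal dynamic variation" is
implemented as the temporal standard deviation; both 5% thresholds are
taken relative to the per-statistic maximum across the pixels of the
processed (masked) matrix, which makes them scale-free. Pixels failing
both rules are counted once, under the mean rule. An input in which every
pixel fails (no signal or no variation anywhere) is an error rather than
an empty result.

## Clustering

Affinity propagation is implemented exactly as the responsibility /
availability message-passing updates with damping λ (new = λ·old +
(1−λ)·new), terminating when the exemplar set is unchanged for 10
consecutive iterations. After convergence each exemplar is finalized as
the most central member of its cluster (maximal within-cluster similarity
sum), matching the reference algorithm's post-processing; cluster centers
are member means re-normalized to the simplex, serving the denoising
purpose of the step.

Two numerical measures keep the message passing well-behaved on simplex
data:

- **Tie-breaking jitter.** Near-duplicate pixel curves make the message
  dynamics degenerate — tied candidates oscillate indefinitely or freeze
  in transient states. `similarity_matrix` adds a symmetric deterministic
  perturbation of relative magnitude 1e−6 (far below any noise level;
  disable with `jitter=0`).
- **Duplicate collapse.** Exactly duplicated curves (noise-free or
  quantized data) are collapsed before message passing; when at most 32
  distinct profiles remain, each one simply becomes its own cluster.
  Identical pixels are the degenerate case of aggregation, and message
  passing on them is wasted work.

Damping defaults to 0.7. At 0.9 the dynamics settle into local optima
that merge small, distant clumps (e.g. the handful of plasma-dominant
pixels) into large clusters — the reference implementation behaves
identically on the same similarities, so this is a property of heavily
damped message passing, not of this implementation. The preference
(diagonal of the similarity matrix) defaults to the median off-diagonal
similarity and is exposed as a flag; on the default phantom it yields
M ≈ 6–18 clusters depending on SNR.

The EM refinement is a Gaussian-mixture EM with means initialized at the
affinity-propagation centers, weights proportional to cluster sizes, and a
single isotropic variance shared by all components (100 iterations
maximum, tolerance 1e−6 on the log-likelihood, ridge floor 1e−12 on the
variance). The shared-isotropic model was written in-package because the
common library implementations offer per-component spherical or shared
full covariances but not this combination, and because the per-iteration
log-likelihood trace is part of the contract (it is verified
non-decreasing). The exact combination rule of the original combined
APC+EM procedure is not publicly documented; APC-init → GMM-EM is this
package's interpretation.

## Margin of error and vertex search

The margin of a point to the hull of J vertex curves is the Euclidean
distance min_{α≥0, Σα=1} ‖x − Vα‖. It is solved by nonnegative least
squares with a penalty row enforcing the simplex constraint (penalty
weight 1e6 × the data scale), followed by an exact equality-constrained
KKT solve on the detected support; the result is accurate to ≤1e−9 and is
cross-checked against a brute-force simplex-grid oracle in the tests. The
vertex search evaluates all C(M, J) subsets of cluster centers
(feasible because M ≲ 20 and J ≤ 6), minimizing the summed margin of the
non-selected centers; ties break toward the lexicographically smallest
index tuple for reproducibility.

## Model selection

The description length of a candidate J is

    L(J) = −log p(data | model) + (P/2)·log(n)

where the likelihood models every normalized pixel curve as some convex
combination of the J vertex curves plus i.i.d. Gaussian noise (residual =
margin to the hull; variance = its MLE over all N·T values), and P counts
the J·T vertex-curve values, the noise variance, and **only the mixing
weights that are actually nonzero** in the per-pixel projections. The
active-weight count is the two-part-code view of a sparsity-constrained
fit: the nonnegative projection zeroes most weights exactly, and weights
that are not coded cost nothing. This matters in both directions. A flat
N·(J−1) count charges every pixel for a vertex that only a small region
uses (a plasma compartment occupying 5% of the tumor would be rejected),
while likelihoods evaluated on the M cluster centers alone under-penalize:
each extra vertex absorbs a full noise dimension of center-level residual
and center displacements due to normalization bias are statistically
significant, so such criteria drift toward the maximal J. A
cluster-center surrogate (size-weighted margins plus within-cluster
scatter) and a plain centers-only form remain available in `code_length`
for when the pixel data are not at hand.

Candidates default to J ∈ {2..6}; ties break toward smaller J. The
pipeline caps the candidate range at M−1 so at least one exterior center
constrains the fit — at J = M the hull-to-data objective is vacuously
zero and the Gaussian likelihood degenerates to its variance floor.

## Parameter estimation

The vertex peaking earliest is the plasma input (ties broken by the
steeper mean upslope from the first frame to the peak). Each tissue vertex
is fitted by minimizing ‖x − Toeplitz(C_p)·(Ktrans·e^{−kep t})‖ over
Ktrans, kep ≥ 0: a 200-point log-spaced grid on kep ∈ [1e−3, 20] /min
(bracketing physiologic DCE values) with the closed-form nonnegative
amplitude at each candidate, refined by a bounded golden-section search on
the bracketing interval to ≤1e−6. The fit is cross-checked in the tests
against a two-stage oracle (unconstrained nonnegative deconvolution, then
a log-linear fit of the exponential decay). A vertex nearly proportional
to the plasma input carries no washout information and is flagged
unreliable. Tissue-vertex fits carry no separate v_p term; plasma
contamination of a tissue vertex is treated as partial-volume residual,
and v_p appears only in the per-pixel maps.

Per-pixel maps solve min_{w≥0} ‖x_i − A·w‖ by NNLS against the vertex
basis; when the series carries its pre-normalization column sums the
weights are rescaled by them, making the maps proportional to the
concentration-scale local transfer constants (on noise-free data they
correlate perfectly with the generating maps, up to one global scale per
column). A pixel is pure when its largest weight is at least 0.8 of its
weight sum (threshold configurable); the partial-volume fraction is the
complement of the pure fraction. Longitudinal comparisons match
compartments across timepoints by descending kep — the fast pool tracks
the fast pool — which is invariant to column permutations of either basis.

## Known limitations

- **Partial-volume bias of the unsupervised vertex.** With few pure
  pixels and moderate noise, the cluster center chosen as the slow-pool
  vertex averages ~90–95%-pure pixels, biasing the slow kep upward (about
  +0.05 /min on the default phantom at 30–40 dB; the fast pool is
  recovered within ~2%). Noise-free vertices are exact to 1e−6. When
  pure-pixel locations are known (as in validation studies), estimating
  from designated pure-pixel curves removes the bias; increasing the
  pure-patch size or the pixel count sharpens the unsupervised estimate.
- The 10-iteration stability termination can declare convergence during a
  long transient on pathological similarity structures; the jitter makes
  this rare but the `converged` flag and warning should be heeded.
- Model selection behavior is validated on the synthetic design; on real
  data with motion or surrounding healthy tissue inside the mask, extra
  compartments may legitimately appear (healthy tissue is then modeled as
  its own compartment).
- Frames must be uniformly spaced (the Toeplitz deconvolution requires
  it); timestamps are otherwise taken at face value in minutes.
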