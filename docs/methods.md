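# Methods

`aquaopes` implements, at desk scale, the methodological stack used to
study ligand unbinding in water-gated protein pockets: on-the-fly
probability enhanced sampling (OPES) and its flooding variant for
residence times, machine-learned collective variables (LDA/Deep-LDA and
TICA/Deep-TICA), a four-step hydration-spot detector for trapped waters,
and the funnel-restraint standard-state correction for absolute binding
free energies.  All components are exercised on built-in analytic
potentials and seeded synthetic data rather than on all-atom MD; this
note records the models, the parameters that matter, and the design
choices made where the methods leave room.

## Model dynamics

The toy dynamics is overdamped Langevin (Euler–Maruyama),

    x <- x - (dt/friction) ∇U dt + sqrt(2 kT dt / friction) η,

in reduced units (kT = 1, dt = 1e-3 by default), so the free diffusion
constant is D = kT/friction.  Shipped potentials: a 1d double well
U = h(x²−1)², its 2d extension with a harmonic transverse mode, and a 2d
"binding funnel" in which an exit coordinate z is gated by a
solvation-like coordinate q (the saddle sits at q ≠ 0, so escape requires
both).  All potential parameters are artifact choices with no molecular
counterpart; they exist to exercise the sampling machinery at known
ground truth.  Trajectories are bitwise reproducible for a fixed spec and
seed (PCG64 noise consumed in fixed-order chunks); per-run child seeds
are derived from a master seed through `numpy.random.SeedSequence`.

Friction defaults to 1.  The FES-recovery validation uses friction 100 so
that the h = 5 kT well is kinetically trapped over the 1e7-step run
(unbiased transitions ≈ a few) while OPES produces dozens of round trips
— the regime the method is for.  Rate validations use friction 1, where
brute-force escape over a 7 kT barrier is affordable (mean first-passage
≈ 2×10⁵ steps).

## OPES

The CV density is estimated on the fly from weighted, normalized Gaussian
kernels deposited every `deposit_period` (default 500) steps,

    P_n(s) = Σ_k w_k G(s, s_k) / Σ_k w_k,      w_k = exp(β V_{k−1}(s_k)),

and converted into the well-tempered bias

    V_n(s) = (1 − 1/γ) (1/β) log(P_n(s)/Z_n + ε).

Conventions and choices:

* **V₀ ≡ 0** before the first deposit (the weight definition forces
  w₁ = 1).
* **Z_n** is the mean of P_n over the deposited centers, maintained
  incrementally in O(n) per deposit.  It tracks the explored
  configuration space; other normalizations differ by a constant bias
  offset, which does not affect forces.
* **ε** is set from the target cap ΔE as ε = exp(−βΔE/(1−1/γ)), so the
  far-field bias floor is exactly −ΔE and the total bias range that can
  be poured into a basin is ≈ ΔE.  Because P_n/Z_n can modestly exceed 1,
  the realized range can overshoot the cap by a fraction of kT; the
  validation suite checks the bias itself never exceeds +ΔE on a dense
  grid.
* **Kernel bandwidth**: fixed per dimension; when not given it is the CV
  standard deviation over a short (5000-step) unbiased probe segment,
  falling back to 2% of the grid range if the probe never moves.  No
  kernel merging or adaptive bandwidths — unnecessary at these kernel
  counts (~2×10⁴).
* **Engine**: between deposits the bias is static, so the integrator
  consumes a per-deposit refreshed 1D cache of bias value and force on a
  uniform grid (linear interpolation; constant extrapolation beyond the
  edges).  The inner loop is numba-compiled; a 1e7-step biased run takes
  a few seconds on one core.  Biasing acts on a single coordinate of the
  toy system, which covers every shipped study; `BiasState.evaluate`
  itself is dimension-agnostic.
* γ = 1 makes the prefactor vanish: bias and forces are identically
  zero and the trajectory is bit-identical to the unbiased one at the
  same seed.

Free-energy surfaces are recovered by reweighting frames with
exp(βV) (constant offsets cancel), histogramming the CV (bin count
configurable), F = −(1/β) log P min-zeroed, with node-wise errors from
the standard error over `n_blocks` contiguous blocks, each min-zeroed
before comparison.

## OPES flooding and residence times

For rates, two conditions make the hyperdynamics rescaling
t = ⟨e^{βV}⟩ t_MD valid: the bias must stay below the barrier and must
vanish in the transition region.  The flooding runner therefore

* refuses deposits whose center satisfies the excluded-region predicate
  (asserted post-run: the kernel table contains no such center), and
* **clamps the applied bias to zero on the excluded region**.  This
  matters: with ε as small as e^{−βΔE}, even a 10⁻³ kernel-tail density
  at the transition state converts into ~1 kT of shifted bias, which
  systematically inflates the acceleration factor.  Forces near the clamp
  boundary come from finite differences of the clamped curve.

The acceleration ⟨e^{βV}⟩ accumulates the floor-shifted bias
(V − V_floor ≥ 0, zero in unexplored and excluded regions) at every
integrator step up to the stop event.  A run whose cap is ≤ 0 disables
biasing entirely, making acceleration exactly 1; a constant static bias
V₀ gives exactly e^{βV₀}.  Unbinding is committed when the stop condition
has held for a dwell of 10 consecutive steps (recrossing suppression);
runs that exhaust their step budget are reported censored.

Accuracy: with the cap 2 kT below the barrier the rescaling carries an
intrinsic ~1.5–1.7× overestimate (present even with a frozen, converged
bias — a weak-separation effect, since only ~2 kT of barrier remains).
With the cap at ~60% of the barrier (4 kT under 7 kT) the systematic
shrinks to ~1.2 and the method sits comfortably inside its expected
factor-of-2 envelope; that margin is the package's recommended practice
and what the validation suite uses.  Cap-independence between 4 and 5 kT
is asserted within broad statistical error.

Residence-time samples are fit as exponentials: τ̂ is the maximum-
likelihood estimate (sample mean; censored runs add survival terms —
total observed time over completed events).  The fit quality is a
Kolmogorov–Smirnov statistic against 1 − e^{−t/τ̂}; because τ̂ comes from
the same sample, the p-value is calibrated by parametric bootstrap
(default 1000 resamples; the KS distance of an exponential sample against
its own fitted mean is scale-free, so the null is simulated at unit
rate).  A plain asymptotic mode exists for comparison and is
anti-conservative.  `split_and_fit` refits two user-labelled event groups
and reports the τ ratio; mechanism classification itself is out of scope.

## Hydration spots and water descriptors

The trapped-water detector: (1) select anchor atoms (α-carbons) that
enclose the region of interest; (2) build their convex hull
(`scipy.spatial.ConvexHull`); containment is closed — the boundary counts
as inside; (3) keep, per water and per contiguous interval, the positions
of waters staying inside longer than the lifetime threshold (default
100 ps).  A single-frame exit splits an interval; the pieces are tested
separately.  (4) K-means-cluster the pooled positions (10 restarts, fixed
seed).  With `k="auto"` the center count is swept upward and the largest
k whose minimum inter-center distance stays ≥ the lower spacing bound
(default 2 Å) is kept; the achieved minimum-pair and maximum
nearest-neighbour spacings are both reported, since "2–3 Å spacing" can
be read either way.  No periodic-boundary unwrapping is attempted — the
trajectories are assumed whole and hull-local.

Water coordination around a center uses the rational switching function
Σ_j (1−(r_j/r0)^n)/(1−(r_j/r0)^m) with defaults (n, m, r0) =
(6, 12, 3.5 Å) and the removable singularity at r = r0 taken at its limit
n/m.  The functional form and radii are exposed in the configuration:
they are a standard choice, not derivable from first principles.  The
descriptor vector is d = [G, H, V₁…V_k]: coordination at a ligand anchor
atom, at a binding-site anchor atom, and at each hydration spot (length
2 + k; 18 in the reference configuration with 16 spots).

## Machine-learned CVs

*LDA*: closed form, w ∝ (S_w + λI)⁻¹(μ_B − μ_U) with S_w the sum of the
class covariances; λ defaults to 0.05·trace(S_w)/dim when regularization
is requested.

*Deep-LDA*: a small MLP d → h (default hidden sizes 32-16-8, tanh) is
trained by alternating (i) the closed-form LDA projection w on the
current last-layer features h with (ii) Adam steps on the network that
maximize the projected Fisher ratio under fixed w.  The exported CV is
s = wᵀh rescaled so the class means sit at ±1 (bound state positive),
then passed through the sharpness-taming cubic map s → s + s³ by
default.  A stratified 20% validation split early-stops on the held-out
Fisher ratio (patience 20).  With linear activations the whole model is
linear and collapses onto the closed-form discriminant (cosine ≥ 0.99,
asserted).

*TICA*: weighted mean-free covariances C(0) (both pair endpoints) and
symmetrized C(τ); `scipy.linalg.eigh` on the regularized generalized
problem; implied timescales t_i = −τ/ln λ_i.  Frames from biased runs
carry weights e^{βV} approximating rescaled time; a pair (t, t+τ) enters
with the geometric mean of its endpoint weights.  Unit weights recover
the unbiased estimator exactly.

*Deep-TICA*: the same alternating scheme as Deep-LDA — generalized
eigensolve on the current network features, then Adam steps maximizing
the leading eigenvalue's Rayleigh quotient under the fixed eigenvector —
with a contiguous tail as the validation split (time series must not be
shuffled).  The exported CV is the leading eigenfunction scaled to unit
weighted variance; its sign is arbitrary.

The networks are plain numpy MLPs with manual backprop and Adam,
full-batch and single-threaded: at a few thousand parameters this trains
in seconds and keeps results exactly seed-reproducible.  Models
serialize to JSON at full float precision; a reload reproduces outputs
bit-for-bit.

## Funnel correction and thermodynamic decomposition

The funnel restraint (cone narrowing into a cylinder of radius R_cyl) is
a half-harmonic wall on the radial excess, continuous and once-
differentiable across the surface (the cone/cylinder seam has the usual
gradient kink along z exactly on the seam line).  The standard-state
binding free energy from a funnel-axis profile W(z) is

    ΔF = (1/β) log( C⁰ π R_cyl² ∫_B dz e^{−β(W(z) − W_U)} ),

with C⁰ = 1/1660 Å⁻³ and W_U the *mean* of W over an unbound plateau
interval (robust to noise; a single grid value is not).  The sign
convention is "unbinding cost": a stable binder gives ΔF > 0, matching
how binding stabilities are usually quoted; consequently ΔF grows
monotonically with R_cyl at fixed W (a wider cylinder grants the unbound
state more entropy).  The integral is a trapezoid on the FES grid
(second-order; exact on intervals where the integrand is linear), and ΔF
is invariant under constant shifts of W by construction.

ΔF(T) = ΔU − TΔS is fit by weighted least squares over ≥ 2 temperatures;
σ = 0 inputs fall back to an unweighted exact fit.  Uncertainties come
from the unscaled fit covariance, i.e. the supplied σ's are taken at
face value — their 1σ intervals cover the truth at the nominal 68% rate
(calibrated in the validation suite over 500 Monte Carlo repeats).

## Synthetic data

`synth_two_state_descriptors` draws two labelled Gaussian clouds
(default 18 components, unit shift on the first three, identity
covariances) standing in for unbiased bound/unbound training data.

`synth_water_scene` plants ground truth for the hydration pipeline: 40
anchor atoms on a 12 Å Fibonacci sphere (a convex protein-like
envelope), five interior spots ≥ 4.5 Å apart whose occupants jitter with
σ = 0.5 Å (clipped at 4σ so they can never exit), and 40 bulk waters
random-walking in the box with hull incursions force-capped at 40 ps.
Water exchange is an identity swap: after its 500 ps lifetime an
occupant trades coordinates with a bulk walker currently outside the
hull.  With the default 580 ps / 2 ps-frame trajectory, exactly the five
first occupants beat a 100 ps residence filter (their successors
accumulate only 82 ps) and no bulk walker can.  The scene reproduces the
bookkeeping structure of trapped-water analysis, not water physics: no
diffusion pathways, no hydrogen bonds, no density correlations — passing
on it validates hull/residence/clustering logic, not hydration-site
prediction on real trajectories.

## Validation problem sizes

The built-in validation suite (also exposed through
`scripts/acceptance.py`) uses: 1e7 integrator steps for FES recovery;
50 flooding + 50 brute-force escapes (and 10 × 50 flooding batches for
the exponentiality check); 100 Monte Carlo repeats of n = 200 for the
exponential-fit calibration; the default planted scene for hydration;
4000 + 4000 descriptor samples, a 4×10⁵-frame OU series and an
8×10⁴-frame planted-slow-mode series for CV learning; 10⁵-node grids for
the funnel closed forms; 500 repeats for thermo coverage.  These sizes
give each stochastic check a comfortable margin over its threshold while
keeping the whole suite in the minutes range on one core.

## Known limitations

* The integrator's fast path supports the shipped analytic potentials
  and single-coordinate biasing; arbitrary user potentials would need a
  new branch in the numba kernel.
* Single-walker only; `BiasState` serializes to a JSON-lines kernel
  table so shared-bias multi-walker variants can be layered on later.
* Flooding rate estimates inherit the hyperdynamics factor-≲2 envelope;
  they are order-of-magnitude tools, and the cap-margin guidance above
  is load-bearing.
* The hydration pipeline assumes persistent water identities and
  whole-molecule coordinates (no PBC imaging).
* Deep models are deliberately small; they are not meant for
  high-dimensional descriptor sets or GPU-scale training.
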