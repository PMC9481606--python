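# aquaopes

Enhanced-sampling methodology for ligand unbinding in water-gated
binding pockets, packaged as a desk-scale toolkit: **OPES** (on-the-fly
probability enhanced sampling) for free-energy surfaces, **OPES
flooding** for physical residence times, **machine-learned collective
variables** (LDA / Deep-LDA, TICA / Deep-TICA) for descriptor sets such
as water coordination numbers, a **hydration-spot detector** for
long-lived trapped waters, and the **funnel-restraint standard-state
correction** for absolute binding free energies with an enthalpy/entropy
decomposition.

It is written for method developers and students of enhanced sampling:
every component runs in seconds-to-minutes on one core against built-in
analytic potentials and seeded synthetic data with known ground truth,
so the whole pipeline — bias construction, reweighting, rate rescaling,
CV training, spot clustering — can be validated end to end without any
molecular dynamics engine.

## The methods in brief

**OPES.** The probability density of a collective variable s is
estimated on the fly from weighted Gaussian kernels,
P_n(s) = Σ w_k G(s, s_k)/Σ w_k with w_k = e^{βV_{k−1}(s_k)}, and turned
into the well-tempered bias

    V_n(s) = (1 − 1/γ) (1/β) log(P_n(s)/Z_n + ε),

which drives sampling toward P(s)^{1/γ}.  Setting
ε = e^{−βΔE/(1−1/γ)} caps the deposited bias at ΔE.

**OPES flooding.** Keep the cap below the barrier and deposit no bias in
the transition region; then the physical residence time follows from the
hyperdynamics rescaling t = ⟨e^{βV}⟩_V · t_MD.  Escape-time samples are
fit as exponentials (τ, k_off = 1/τ) with a parametric-bootstrap
Kolmogorov–Smirnov p-value; two-mechanism samples can be split and
refit per group.

**CVs.** Deep-LDA maximizes Fisher's ratio wᵀS_b w / wᵀS_w w on the last
hidden layer of a small network trained on bound/unbound descriptor
data (with the cubic output map s → s + s³); Deep-TICA extracts the
slowest-decorrelating mode of network features from (reweighted) biased
trajectories via the generalized eigenproblem C(τ)v = λC(0)v.

**Hydration spots.** Build a convex hull over anchor α-carbons, keep
waters resident inside for longer than a lifetime threshold (100 ps
default), K-means-cluster the pooled positions with the center count
chosen from a 2–3 Å spacing rule, and evaluate smooth water coordination
numbers around the resulting centers as CV descriptors.

**Binding thermodynamics.** ΔF = (1/β) log(C⁰ π R²_cyl ∫_B e^{−β(W−W_U)} dz)
with C⁰ = 1/1660 Å⁻³, plus a weighted fit of ΔF(T) = ΔU − TΔS.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import numpy as np
from aquaopes import (LangevinSpec, OPESConfig, StopSpec, ResidenceTimeSample,
                      brute_force_escape_times, count_well_transitions,
                      fit_exponential, make_potential, reweighted_fes,
                      run_flooding, run_opes)

# --- free-energy recovery on a 5 kT double well -----------------------
pot = make_potential("double_well_1d", {"h": 5.0})
spec = LangevinSpec(potential=pot, n_steps=2_000_000, friction=10.0,
                    seed=42, initial_position=(-1.0,))
config = OPESConfig(barrier=6.0, gamma=10.0, grid=(-2.5, 2.5, 501))
series, state = run_opes(spec, config)
print(f"kernels deposited: {state.n_kernels}")
print(f"interwell transitions: {count_well_transitions(series['cv'])}")

fes = reweighted_fes(series, np.linspace(-1.5, 1.5, 61), n_blocks=4)
mask = np.isfinite(fes.free_energy)
u = pot.energy(fes.grid[mask]); u -= u.min()
print(f"FES RMSE vs analytic: {np.sqrt(np.mean((fes.free_energy[mask]-u)**2)):.3f} kT")

# --- residence times by flooding on a 7 kT double well ----------------
pot7 = make_potential("double_well_1d", {"h": 7.0})
spec7 = LangevinSpec(potential=pot7, n_steps=10_000_000, seed=0,
                     initial_position=(-1.0,))
stop = StopSpec(threshold=0.8, op=">=", dwell=10)
flood_cfg = OPESConfig(barrier=4.0, gamma=10.0, sigma=0.12,
                       grid=(-2.0, 1.5, 401),
                       excluded_region=lambda s: s[0] > -0.3)
times = [run_flooding(spec7.with_(seed=100 + i, n_steps=3_000_000),
                      flood_cfg, stop).t_physical for i in range(50)]
report = fit_exponential(ResidenceTimeSample(np.array(times)), seed=1)
brute = brute_force_escape_times(spec7, stop, 50, seed=7)
print(f"flooding tau: {report.tau:.0f}  k_off: {report.k_off:.2e}  "
      f"KS p-value: {report.p_value:.2f}")
print(f"brute-force mean escape: {brute.mean():.0f}  "
      f"ratio: {report.tau / brute.mean():.2f}")
```

Output:

```
kernels deposited: 3999
interwell transitions: 102
FES RMSE vs analytic: 0.180 kT
flooding tau: 217  k_off: 4.60e-03  KS p-value: 0.92
brute-force mean escape: 201  ratio: 1.08
```

The biased walker crosses the 5 kT barrier 102 times in 2×10⁶ steps
(unbiased: essentially trapped) and the reweighted profile matches the
analytic potential to 0.18 kT.  On the 7 kT well, 50 flooded runs — each
orders of magnitude shorter than a real escape — rescale to a mean
residence time within 8% of 50 brute-force unbiased escapes, and the
sample is statistically exponential (KS p = 0.92), as a single-barrier
process should be.

The same functionality is scriptable through the `aqua-opes` CLI
(`synth`, `run`, `flood`, `fes`, `spots`, `train-cv`, `eval-cv`,
`thermo`, `rates`); try `aqua-opes --help`.

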