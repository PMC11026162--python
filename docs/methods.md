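# Methods

## Model

### Solution state and screening

A 1:1 electrolyte at concentration c₀ (mol/L), temperature T, relative
permittivity ε_r and viscosity η. The inverse Debye length is the full
expression κ² = 2e²N_A(1000c₀)/(ε_rε₀k_BT); in water at 298 K this reduces
to κ⁻¹ ≈ 0.304/√c₀ nm within 2%. Measured conductivities convert to c₀
through a single linear calibration slope (default Λ = 126.4 S·cm²/mol, the
limiting molar conductivity of NaCl); alcohol conductivities use the same
aqueous calibration with the inferred concentration multiplied by
η_solvent/η_water (η: water 0.89 cP, ethanol 1.1 cP, IPA 2.4 cP; a
Walden-style mobility correction). Registered solvents carry a default
interfacial solvation potential φ₀: −0.15 V (water), +0.10 V (ethanol),
+0.13 V (IPA). Only the *sign* of φ₀ is physically constrained (solvent
dipole orientation at an interface); the magnitude is an effective input
whose scale is absorbed by the interfacial-amplitude calibration, so these
defaults are conventions, not measurements.

### Charge regulation

Surfaces carry a single effective ionizable site species (acid or base) with
pK and areal density Γ. The ionization fraction follows the
Langmuir–Boltzmann isotherm

    acid: α = [1 + 10^(pK−pH) e^(−eψ_s/kT)]⁻¹,
    base: α = [1 + 10^(pH−pK) e^(+eψ_s/kT)]⁻¹,

and the diffuse layer obeys the Grahame relation
σ = 2ε_rε₀κ(kT/e)sinh(eψ_s/2kT). The self-consistent state solves
σ(ψ_s) = ±eΓα(ψ_s) by bracketed root finding on ψ_s ∈ [−0.5, 0.5] V
(tolerance 10⁻¹² V; the residual is monotone so the root is unique).
Molecular spheres (radius R, N sites) instead use the linearized-PB closure
ψ_s = q_p/(4πε_rε₀R(1+κR)) with q_p = ±eNα — adequate because κR ≲ 8 and
|ψ_s| ≲ 25 mV in the condensation regime. The regulation capacity
dα/dψ_s = ±(e/kT)α(1−α) is the model's predictor of solvation-driven
attraction; a normalized variant 4α(1−α) (unit maximum) is used for
comparisons and for the mixture-clustering OR rule (threshold 0.25 on the
normalized capacity; any species above threshold predicts mixed clusters;
oppositely charged mixtures are out of scope). Measured zeta potentials are
treated as a sign/magnitude proxy for ψ_s — no slip-plane model.

The single effective pK is a deliberate simplification: real silica exposes
silanol groups with pKs spanning 2–11, so the single-site silica preset
(pK 6) reproduces clustering near its own regulating window but not the full
breadth of the experimental pH response.

### Pair potential

U(x) = A e^(−κ₁x) + B e^(−κ₂x) + U_vdW with κ₁ = κ and κ₂/κ₁ = 0.95 by
default (configurable; the ratio is not sharply constrained physically).

- A = 64πR_eff ε_rε₀ (kT/e)² tanh²(eψ_s/4kT), the Derjaguin weak-overlap
  double-layer repulsion, R_eff = R₁R₂/(R₁+R₂). Note the tanh² ≤ 1 cap: for
  2.41 μm silica in water A ≤ ~2.7×10⁴ k_BT, which bounds how far out a well
  of given depth can sit (wells of 2–4 k_BT at x_min ≈ 5–6.5 κ⁻¹ at most).
- |B| = C_int · 2πR_eff κ₂⁻¹ |φ₀||σ| · 4α(1−α), with
  sign(B) = −sign(σφ₀). The κ₂⁻¹ factor closes the dimensions (making C_int
  dimensionless); C_int is one calibration constant per solvent (see
  Calibration). B vanishes with σ, φ₀ or the regulation capacity.
- U_vdW is the full non-retarded Hamaker sphere–sphere expression in the
  centre distance d = x+R₁+R₂ (close-approach limit −A_H R_eff/6x), default
  A_H = 2.4 zJ for silica in water, off by default in simulations (it
  matters only at x ≲ 0.2 μm, i.e. high-salt conditions). Retardation and
  electrolyte screening of the vdW term are neglected. At x = 0.2 μm the full
  expression gives −0.37 k_BT for 4.82 μm spheres — a "small contribution"
  consistent with the ~−0.5 k_BT scale quoted for that regime, which
  coincides with the slowly-converging close-approach asymptote (−0.59 k_BT);
  at x = 0.1 μm both agree on ≈ −1 k_BT within 20%.

The interior minimum has the closed form
x_min = ln(Aκ₁/(|B|κ₂))/(κ₁−κ₂) (existing iff Aκ₁ > |B|κ₂ with B < 0), and
the inverse map fixes (A, B) from a target (w, x_min):
A = −wκ₂/(κ₁−κ₂)·e^(κ₁x_min), B = wκ₁/(κ₁−κ₂)·e^(κ₂x_min), giving
U″(x_min) = −wκ₁κ₂ > 0. Curves are classified repulsive (B ≥ 0),
non-monotonic (interior minimum with w < 0), or attractive (monotone
negative, Aκ₁ ≤ |B|κ₂).

### Calibration and scenario presets

C_int is pinned per solvent by one anchor scenario, solved entirely in
closed form: the anchor's (w, x_min) give (A\*, B\*) via the inverse map;
inverting the Derjaguin amplitude gives ψ_s\*; the Grahame relation gives
σ\* and hence the effective site density Γ = |σ\*|/(eα\*); and
C_int = |B\*|/(2πR_eff κ₂⁻¹|φ₀|σ\*·4α\*(1−α\*)). Anchors:

| solvent | anchor scenario | w (k_BT) | x_min (κ⁻¹) | resulting C_int |
|---|---|---|---|---|
| water   | silica, c₀ = 5 μM, pH 5.6, pK 6 | −4.0 | 5.0 | ≈ 5.7 |
| ethanol | aminated silica, c₀ ≈ 0.4 μM    | −2.0 | 5.0 | ≈ 0.26 |
| IPA     | aminated silica, c₀ ≈ 0.4 μM    | −2.0 | 4.7 | ≈ 0.29 |

The silica–water anchor identifies the observed ~0.5 μm first-neighbour gap
with 5 screening lengths at 5 μM. The alcohol anchors use shallower wells;
the IPA anchor sits at 4.7 κ⁻¹ because IPA's lower permittivity caps the
electrostatic amplitude below what a 2 k_BT well at 5 κ⁻¹ would require.
Non-anchor attractive presets (silica pH series at 0.12 mM, carboxylated
melamine at 0.25 mM) reuse the solvent's C_int and solve instead for their
own (Γ, default pH) from a (w = −3 k_BT, x_min = 5 κ⁻¹) target; repulsive
presets (amine in water, carboxyl in ethanol) specify a plausible surface
potential (±40 mV) directly. Preset chemistry is thus *constructed* to
reproduce figure-level well geometry — the per-dataset surface parameters of
the original experiments are not published in machine-readable form — after
which every derived quantity (classification, response to charge flips, BD
structure, x_min/κ⁻¹ trends) is a genuine model output.

### Brownian dynamics

2D overdamped Euler–Maruyama in a periodic rectangular box:
r ← r + (D_i/kT)F dt + √(2D_i dt) ξ, with per-particle Stokes–Einstein
D_i = kT/(6πηR_i). Polydispersity (truncated Gaussian diameters, CV 3% for
silica/amine and 2% for the melamine particles) enters radii and D_i only;
the pair potential is size-independent. Forces come from the analytic
derivative of U(x) at x = r_ij − R_i − R_j under the minimum-image
convention, with force-shifted truncation at a centre-distance cutoff
(default 15κ⁻¹ + 2R_max — the residual energy tilt across the well is then
< 10⁻³ k_BT, which matters for the Boltzmann-closure validation). The
default timestep is the largest dt whose free-flight rms step for the
fastest particle is 0.1κ⁻¹. A steep inner wall (∝ (x_w/x)⁶, x_w = 5 nm,
10 k_BT scale) keeps contact configurations finite; its displacement per
step is clamped to 2x_w, and the unstable-timestep check (drift of the
smooth force exceeding κ⁻¹/2 in one step) deliberately excludes it, since
the wall's 5 nm length scale legitimately produces forces beyond the
κ-scale criterion. Initial placement is uniform with overlap rejection; a
configurable placement buffer (typically 3κ⁻¹ of extra surface clearance)
starts runs outside the steep force region. Runs are bit-reproducible given
the seed (the integrator consumes a seeded NumPy legacy RNG inside one
numba kernel).

Stationarity of the potential-energy-per-particle trace is detected
adaptively: the earliest window boundary from which the trailing linear
drift is within twice its own sampling noise *or* within 10% of the trailing
mean magnitude (attractive systems keep coarsening slowly, so a small
residual drift is accepted as stationary), with first/last window means
agreeing under the same tolerance.

### g(r) estimation and inference

g(r) is the pair-distance histogram normalized by N·ρ·2πr·dr per frame and
averaged, with 50 nm bins by default (matching the ~50 nm positional
uncertainty of tracked coordinates). Periodic data use minimum-image
distances; finite fields of view use a Ripley-style isotropic edge
correction (each pair weighted by the inverse fraction of the circle of
radius r around the reference particle lying inside the window, averaged
over both orderings; circle fractions are evaluated on a 512-point
discretization). Per-frame detected counts normalize the estimate, so
random missed detections leave g(r) unbiased.

The first coordination shell is the dominant local maximum beyond contact +
2 bins (height ≥ 1.25, prominence ≥ 0.25 by default); a secondary maximum
within ±2 bins of contact flags stuck dimers. The discrepancy between two
curves is w₁·Σ(Δg)² (window length counted in bins) + w₂·(Δr_peak/dr)² +
w₃·(Δg_peak)², default weights (1, 1, 4) — peak height is the quantity the
well-depth iteration is most sensitive to.

Inference (`PairPotentialInference.fit`) mirrors the experimental protocol:
κ₁ from the electrolyte, κ₂/κ₁ = 0.95, x_min from the target's first shell,
and only w iterated — bounded scalar minimization of the discrepancy over
w ∈ [−10, −0.1] k_BT (tolerance 0.3 k_BT, ≤ ~12 BD evaluations), with a
fixed BD seed inside the search so the objective is deterministic, and the
returned optimum re-simulated on three fresh seeds as a replicate-noise
diagnostic. Stricter peak thresholds (height 1.75, prominence 0.75) decide
whether the target has structure at all; featureless targets return a
purely repulsive potential with w = 0 by convention (B = 0, A defaulting to
500 k_BT — the depth of a generic strong repulsion; only the
classification and w are meaningful in that branch). Trial wells that
outrun the timestep are penalized rather than fatal; an optional outer
refinement of x_min over ±2 bins and a small κ₂/κ₁ grid can be enabled in
the config. Desk-scale inner simulations default to N ≈ 60 in a 60 μm box
for 150 s of simulated time — sizes chosen so a full three-depth recovery
study completes in minutes while still resolving the first shell; recovery
accuracy at this scale is ±1.5 k_BT in w and ±2 bins in x_min (validated in
the test suite).

### Condensation phase map

Proteins are spheres (R = 2.5 nm) carrying five acidic sites (pK 4.5),
titrated self-consistently as above; q_p = −5eα plateaus at −5e above
pH ≈ 6.5. The pair energy at a nominal contact separation x = 1 nm is

    u_DLVO = q_p²/(4πε_rε₀ r) · (e^(κR)/(1+κR))² e^(−κr) + u_vdW,  r = 2R+x,
    u_tot* = u_DLVO + u_int,

with the molecular Hamaker constant defaulting to zero (at x = 1 nm the vdW
term is negligible against the electrostatic and solvation terms for 2.5 nm
spheres; configurable). u_int reuses the solvation-amplitude form at
molecular R_eff. The condensed region is {u ≤ u_c} with u_c = −0.63 k_BT, an
input threshold; the boundary is extracted by marching squares with
log-interpolation on the salt axis.

At molecular scale the solvation term's amplitude constant *and* decay-length
ratio are calibrated jointly so the u_tot* = u_c contour passes through two
landmark points — (pH 6.5, c₀ = 10 mM) and (pH 5.5, c₀ = 0.5 M), i.e. the
boundary reaches ~0.5 M at its acidic end and pH ≈ 6.5 at its low-salt end.
Two conditions, two unknowns: the solution is C_mol ≈ 0.15 with
κ₂/κ₁ ≈ 0.08. The small ratio says that, within this parameterization, the
molecular-scale solvation term must decay far more slowly than the
electrostatics to keep condensation alive at 0.5 M; the colloid-scale value
0.95 cannot reproduce both landmarks with any amplitude. Everything else on
the map — the empty DLVO region under the same threshold, the monotone
shrinkage of the condensed region with pH and salt, its connectedness, and
the shrinkage when the solvation term is removed — is a prediction, not a
fit.

## Synthetic observations

`synthesize_observation` emulates the statistics of tracked video
microscopy, not images: a BD run to stationarity, subsampled at 5–30
frames/s for 150–500 frames, each coordinate perturbed by isotropic
Gaussian localization noise (σ = 20 nm default), detections dropped
independently (efficiency 0.98 default), and a configurable fraction of
particle pairs replaced by stuck dimers frozen at contact
(density-preserving). What it does *not* emulate: optical point-spread
artefacts, tracking misassignments between frames, frame-to-frame
correlated noise, drift of the field of view, and polydispersity-dependent
interactions. Tests passing on these observations therefore validate the
estimator chain against localization noise, missed detections and dimer
contamination — not against image-level systematics.

## Numerical choices and degenerate inputs

- Root finding: bisection/Brent everywhere with fixed brackets (±0.5 V for
  ψ_s; κ₂/κ₁ ∈ [0.01, 0.95] for the molecular calibration); tolerances
  10⁻¹² V and 10⁻¹⁰ respectively.
- κ₁ = κ₂ with both amplitudes nonzero is rejected as degenerate; w ≥ 0 or
  x_min ≤ 0 are rejected in the inverse map.
- Pair separations are floored at 0.5 nm inside the BD kernel when
  evaluating the potential (the wall dominates there anyway).
- The minimum search uses the closed form, refined by bounded scalar
  minimization (tolerance 10⁻¹² m) only when the vdW term is on.
- Energies are evaluated in SI joules; user-facing output divides by k_BT
  at the conditions' temperature.

## Problem sizes used in validation

The shipped validation suite runs at desk scale, chosen as the smallest
sizes at which each claim is statistically resolvable: cluster structure
with N ≈ 115 silica spheres in a 120 μm box for 1200 s of simulated time;
the Boltzmann closure with N = 40 small spheres at 0.49% area fraction for
900 s; inference recovery with N ≈ 60 in a 60 μm box per BD evaluation.
The experimental-scale configuration (200 × 200 μm, N = 320, ~30 min
simulated time) is directly expressible through `SimulationConfig` and runs
in roughly ten minutes of wall time per trajectory.

## Known limitations

- Hydrodynamic interactions, substrate effects and many-body (non-pairwise)
  couplings are omitted; the model is strictly pairwise additive.
- The interfacial amplitude is an effective parameterization calibrated per
  solvent, not a first-principles expression; φ₀ magnitudes are conventions.
- Single effective ionizable site per surface; silica's broad pK spectrum is
  not represented, so pH trends for silica are qualitative.
- The molecular condensation map inherits two calibrated constants; only its
  interior structure and the DLVO contrast are predictive.
- The linearized-PB sphere closure underestimates regulation for highly
  charged molecules at low salt.
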