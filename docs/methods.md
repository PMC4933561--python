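# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic-data generator
does and does not emulate. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Biphasic response template

A single-location response is modelled as a difference of causal
rise–decay lobes

    h(t; τr, τd) = (1 − e^(−t/τr)) · e^(−t/τd) / h(t*),   t* = τr ln(1 + τd/τr)

so each lobe's configured amplitude is exactly its maximum. The trace
is

    v(t) = A_d · h(t − t₀; 0.6, 2.0) − A_c · h(t − t₀ − 5.0; 2.5, 5.0) [+ secondary lobe]

with amplitudes in percent diameter change and t₀ the dilation onset.
This template is a modelling convenience — smooth, causal and
analytically tractable — not a fitted kinetic model. Defaults
(A_d = 10%, A_c = 2%, rise 0.6 s, decay 2 s, constriction delayed 5 s,
width 2.5 s) were chosen so the noiseless trace peaks ~1.8 s after
onset, crosses zero near 5–7 s and troughs inside the 3–13 s
constriction window, the shape seen in single-vessel imaging. Because
the dilation tail overlaps the constriction lobe, the measured trough
(~1.7% for A_c = 2%) is intentionally not equal to A_c; tests derive
expected values by densely evaluating the template (1 kHz), never by
assuming lobe orthogonality.

Pharmacological conditions are amplitude switches only: TTX zeroes both
phases, Y1-receptor blockade (BIBP 3226) zeroes the constriction lobe,
glutamatergic blockade (AP5+CNQX) delays it by 2 s. No
pharmacodynamics are simulated.

## Cohort structure and onset–depth law

A cohort draws locations uniformly in depth (default 50–560 µm, 10
subjects × 10 locations) and sets each location's ground-truth onset to

    onset(z) = max(0, surface_onset − z/v + ε),  ε ~ N(0, 0.05² s²)

i.e. a response conducted upstream along the diving arteriole at
velocity v (default 900 µm/s), linear in depth — the simplest law
consistent with fitting a straight line to onset-versus-depth scatter.
Amplitudes vary across locations as N(10, 2²)% clipped at 3%; additive
noise is i.i.d. Gaussian per sample (default SD 1%). White noise keeps
every oracle analytic; real traces have heartbeat/respiration bands
and slow drifts, so passing recovery tests here demonstrates estimator
correctness, not robustness to structured physiological noise.

## Metric estimators

All metrics run on percent-change traces smoothed with a Gaussian
kernel (FWHM 0.5 s, σ = FWHM/2.3548, reflection padding; constants map
to themselves). Choices where the procedure was genuinely open:

* **Baseline** D₀ is the mean over the whole pre-stimulus segment
  (≥ 1 s required); maximizes precision of D₀ and is configurable.
* **Peak search window** defaults to (0, 6] s post-stimulus; ties take
  the earliest time.
* **Onset fit** uses only the contiguous 20–80% run immediately
  preceding the peak (samples above 80% between the run and the peak
  are skipped), so a secondary dilation or early dip cannot contaminate
  the fit. Fewer than two usable samples, a non-positive peak or a
  non-positive fitted slope flag the onset as undefined (NaN) rather
  than raising. The line-through-a-curved-limb estimate carries a
  small constant early bias (≈ −0.09 s raw, ≈ −0.16 s smoothed for the
  default template); it is depth-independent and therefore cancels in
  the depth regression. The onset fit runs on the smoothed trace by
  default (`smooth_before_onset=False` to change).
* **Constriction**: minimum within 3–13 s, classifier threshold 1%,
  constriction onset = first downward zero crossing after the dilation
  peak, linearly interpolated, undefined if none occurs by 13 s.
* **Diameter (FWHM)**: background = 5th percentile of the line, 1-px
  profile smoothing before the peak search, crossings nearest the peak,
  sub-pixel linear interpolation; lines that never cross half maximum
  become NaN samples.

Depth summaries average within subject per 100-µm half-open bin before
taking mean ± SE across subjects; the regression is OLS over individual
measurements (the bin means are presentation only). Undefined metrics
are dropped row-wise, never imputed. Velocity is reported only for
negative slopes; positive slopes are annotated "downstream". The
co-expression count statistic uses a Wilson 95% interval.

## Photon Monte Carlo

Standard weighted-packet transport: exponential step lengths with
µt = µa + µs, per-interaction deposition of weight × µa/µt into a
cylindrical (r, z) grid (Δr = Δz = 10 µm, extent 1 mm, with overflow
bins so the budget closes exactly), Henyey–Greenstein polar angles,
Russian roulette below weight 1e-4 with survival 0.1, and a matched
(no-Fresnel) surface: any packet crossing z = 0 escapes fully. The
medium is homogeneous and semi-infinite; no vessels, layers or
wavelength dependence. A step cap (10⁶) with explicitly tracked
unterminated weight guards the µa = 0 limit, where roulette never
fires. The kernel is numba-compiled; 10⁶ packets of the cortical
medium take on the order of a minute on one CPU.

Validation is layered: Beer–Lambert in the pure-absorber limit; exact
transport theory (normal-incidence reflectance of an isotropically
scattering half-space from Chandrasekhar's H-function, R = 0.2853 at
albedo 0.8 — the simulation matches within Monte Carlo error); and an
independent analog (unweighted) simulation for an anisotropic case.

Two attenuation metrics are computed. The default, **plane-crossing
power**, is P(z) = 1 − (absorbed above z + escaped)/launched, i.e. the
launched weight still propagating below depth z; the loss by 200 µm is
100·(1 − P(200)/P(0)). The alternative is the **on-axis fluence**
profile (the photon-density map's depth profile). For the cortical
parameter set (µa = 0.2 mm⁻¹, µs = 68 mm⁻¹, g = 0.95) the reduced
scattering coefficient is µs′ = µs(1−g) = 3.4 mm⁻¹, giving an
effective diffusion attenuation length ~0.7 mm. Consequently *no*
weight- or fluence-based measure loses 90% by 200 µm under these
coefficients: the plane metric gives ≈20% (≈60% without the P(0)
normalization), on-axis fluence ≈37%, and even restricting to power
still confined to the beam footprint gives ≈77%. Widely quoted
"90% of blue light lost in the first 200 µm" figures come from fiber
measurements that fold in geometric spreading, or correspond to much
stronger effective attenuation than this parameter set implies. The
simulator reports what the stated optics actually yield; the
discrepancy is documented rather than papered over.

## Passive cable model

Morphologies are standard 7-column SWC with z as cortical depth
(files with the opposite convention are flipped and shifted so the
shallowest dendritic tip sits at 20 µm). The morphing chain is:
z-scale by 0.6 (rat → mouse cortical thickness); affine stretch of all
nodes between 100 µm (layer I/II border) and the soma so the soma
lands at 600 µm (layer V), nodes above 100 µm untouched, nodes below
the soma shifted rigidly; all neurite types passing through the middle
section are stretched alike.

Discretization: each parent–child segment becomes cylindrical
compartments ≤ 10 µm with linearly interpolated radii (membrane area
matches the frustum within 1%); a single-node soma becomes one
compartment with its sphere's surface area. Passive parameters are
textbook values — Rm = 30 kΩ·cm², Cm = 1 µF/cm², Ra = 150 Ω·cm,
rest −70 mV — fully exposed in `PassiveParams`, and the slab-clamp
analyses sweep Rm ∈ [20, 40], Ra ∈ [100, 200] to show sensitivity.
The clamp selects dendritic compartments by midpoint depth; soma and
axon are never clamped. Steady state is a sparse SPD solve; the
transient uses backward Euler at Δt = 0.1 ms and matches the direct
solve to <0.1 mV. The solver is verified against the sealed-end
finite-cable closed form V(x) = V₀·cosh((L−x)/λ)/cosh(L/λ) to <1%.

The bundled morphology is **synthetic**: a VIP-like bipolar plan (small
soma at 350 µm, one ascending trunk bifurcating into a four-tip layer-I
tuft, one descending dendrite, thin descending axon) with lengths and
radii in typical published ranges. With the defaults it yields a soma
steady state near −32 mV for a 100-µm slab clamp (−45 to −20 mV over
the parameter neighbourhood), developing within ~30 ms, and a deeper
slab always depolarizes the soma further. Published simulations on
real reconstructed VIP cells report −40 to −50 mV; the steady state
depends strongly on how many dendritic branches fall inside the
clamped slab, so the synthetic cell brackets the phenomenon
(strong passive dendrosomatic depolarization) rather than reproducing
any particular reconstruction's number. All membranes are passive —
no voltage-gated conductances, channel kinetics or synapses — so the
computed depolarization is a lower bound.

## Signal processing

The MUA filter is a single second-order Butterworth band-pass
(750–5000 Hz) applied forward and backward (`sosfiltfilt`): zero net
phase, effective magnitude the square of the section's, then
rectification. On a passband sinusoid the rectified mean is 2/π of the
amplitude (verified within 5%); a 10-Hz tone is attenuated below 1%
RMS. Requires ≥10 kHz sampling. Cell segmentation thresholds the
time-averaged line profile with Otsu's method and keeps runs ≥ 5 px;
stimulus artifacts are removed by linear interpolation over a 30-ms
window after each stimulus (the method behind "digital removal" was
open; interpolation is the simplest that preserves trace continuity),
followed by adjacent-pair averaging (100 Hz → 50 Hz, 20-ms
resolution).

## Problem sizes and determinism

Default analysis sizes — 100-location cohorts, 2×10⁵ packets in the
exploratory Monte Carlo driver and 10⁶ in `scripts/acceptance.py`,
≤10 µm compartments — were chosen as the smallest sizes at which the
recovered quantities are stable well inside their tolerances (velocity
recovery scatter ≈2–4% at n = 100; the P(z) profile changes <3% RMS
between 5×10⁴ and 2×10⁵ packets). Every stochastic operation takes an
explicit seed; identical configuration and seed give bit-identical
outputs, which the pipeline manifest (SHA-256 per output file) makes
checkable.

## Known limitations

* Gaussian white trace noise; no physiological noise structure, no
  motion artifacts, no vessel tracking.
* The depth–onset law is exactly linear; real conduction may decay or
  saturate with distance.
* Homogeneous tissue optics; no blood vessels (strong local
  absorbers) or layered refractive structure, and no Fresnel surface
  reflection by default (a mismatched-index option exists in the
  configuration).
* The cable model is passive and the bundled morphology synthetic;
  absolute somatic voltages should be read as order-of-magnitude,
  parameter-dependent quantities.
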