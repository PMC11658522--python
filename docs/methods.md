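# Methods

This note records the models behind `osteosense`, the conventions that had
to be chosen where the device's design documentation is silent, and what
the synthetic scenarios do and do not say about real tissue.

## Photon transport

The tissue is a homogeneous box (default 3 × 3 × 3 mm) with the probe on
its top face: source-fiber axis at x = −SDS/2, collector axis at +SDS/2,
SDS = 1.3 mm, both fibers 400 µm core, NA 0.22. Photons launch uniformly
over the source core disc with directions uniform in solid angle inside
the acceptance cone, carry unit weight, and random-walk with

* free paths s = −ln(1−u)/µ_t, µ_t = µ_a + µ_s, µ_s = µ_s′/(1−g);
* weight deposition at every interaction (w ← w·µ_s/µ_t), so absorption
  never terminates a path directly;
* Henyey–Greenstein deflection cosines from the closed-form inverse CDF,
  uniform azimuth;
* Russian roulette below weight 10⁻⁴ with survival factor 10 (the common
  transport convention; unbiased by construction);
* escape through any box face; photons crossing the top face are tested
  against the collector: inside the core disc *and* within the acceptance
  cone about the surface normal.

The estimate R_tissue is the mean per-photon collected weight; its
standard error is the sample standard deviation of that weight over
√n_photons. A weight ledger (collected + absorbed + escaped + net
roulette residual) closes to 1 within 10⁻⁶ on every run, and runs are
bit-reproducible per seed. The kernel is compiled with numba; 10⁷ photons
take one to two minutes per bone cell on one core.

### Conventions the design tables force

**Units.** The bone optical properties are bare numbers in the source
tables (e.g. µ_a = 0.216, µ_s′ = 28.6 for cancellous bone at 940 nm). We
read them as cm⁻¹, the tissue-optics convention; with mm⁻¹ the medium
would be an order of magnitude too turbid and the collected fractions
nowhere near the tabulated 0.1–0.15 ‰.

**Refractive index and acceptance cone.** Indices are not stated. The
package defaults to a matched boundary (no Fresnel reflection or
refraction) with n_tissue = n_external = 1, giving launch/acceptance
half-angles of asin(NA). This is the convention that reproduces all four
tabulated permille reflectances: an index-matched n = 1.4 medium
(half-angle asin(NA/1.4)) halves the collected solid angle and yields
almost exactly half the tabulated values in every cell. Both conventions
remain available through `ProbeGeometry`.

**Mesh-free volume.** The reference simulation voxelized the volume at
100 bins/mm; a homogeneous single layer needs no grid, so propagation
here is continuous inside the same box with escaping boundaries —
identical physics, faster. Pooled high-count runs agree with the
reference table to within ~2–3% in the worst cell (cortical bone at
1310 nm), which we attribute to residual cross-implementation differences
of this kind; it is well inside the Monte Carlo error of desk-scale runs.

**Problem size.** The default budget is 10⁷ photons (the reference used
10⁹). At R ≈ 1.3 × 10⁻⁴ this collects ~1500 photons per run, a relative
standard error of ~2.5%, which resolves the cancellous/cortical contrast
at 1310 nm while keeping a four-cell table to a few minutes. Runs
expecting fewer than ~100 collections warn.

## Signal chain

I_PD = P_LD · η_LD · R_tissue(λ) · η_PD · R_PD(λ) + I_dark, evaluated per
channel with the shipped registry defaults (P_LD = 51.1/10.3 mW at
940/1310 nm, both couplings 30%, R_PD = 0.62/0.91 A/W). Dark current
defaults to 0 (no datasheet figure in the design tables) and exists for
noise studies. Responsivity is a two-point lookup — the device uses
exactly two wavelengths, so no interpolation is offered; the photodiode's
1.05 A/W peak at 1550 nm is registry metadata only. The four-channel
table spans 80.6–433.4 nA; the design documents quote this envelope
rounded as 81–432 nA.

## Amplifier model

Two ideal single-pole stages around the measured component values:
G₁ = R_F1 (up to 5 MΩ), pole 1/(2πR_F1·C_F1); inverting G₂ = R_F2/R_4
= 10, pole 1/(2πR_F2·C_F2); AC coupling C₆ = 10 µF through R₄ = 47 kΩ
(τ = 0.47 s — the only component pairing that yields the documented time
constant); single 5 V supply with 2.7 V bias, all node voltages clipped
to the rails. Op-amp non-idealities (bias current, offset, finite GBP,
input-capacitance interaction with the photodiode's 60 pF junction) are
excluded: every documented figure is reproducible from the ideal model.

Two sign conventions coexist in the device's own arithmetic, and the
package keeps both explicitly rather than picking one:

* `steady_state_output` is DC-referenced: the second stage swings the
  full amplitude downward from bias ("towards ground"). This reproduces
  the bench validation (337 nA × 440 kV/A × 10 below a 2.8 V bias
  → 1.32 V) and the saturation-onset gain V_bias/(I·G₂) = 831 kV/A.
* The transient/AC path removes the duty-weighted mean through the
  coupling capacitor, so a two-level square wave splits symmetrically
  about the bias — 3.693 V / 1.707 V for the 432/101 nA pair at 6 MV/A.

The transient simulator uses exact zero-order-hold discretizations of
each first-order section (no generic ODE solver): one-pole IIR updates
for the stage poles, exact exponential charging for the coupling
capacitor. At power-on the capacitor starts discharged, reproducing the
initialization phase in which the output creeps from the rail to the
bias; "settling" is defined as the capacitor reaching within 2% of its
equilibrium, i.e. ~4τ ≈ 1.9 s. Steady-state peak-to-peak is measured as
the difference of the high- and low-phase plateau means over the final
quarter of the trace, skipping the leading 5% of each half-cycle so the
stage-pole edges do not bias the means; with the default 200 samples per
cycle this recovers ΔI·G₁·G₂ to better than 0.1%.

The small-signal frequency response multiplies the two stage poles with
the coupling high-pass. Note one deliberate distinction: the documented
per-stage bandwidths (4.68 kHz at 5 MΩ, 39 kHz at 600 kΩ, 50 kHz at
470 kΩ) are single-pole figures from `stage_bandwidth`. When one pole
dominates (G₁ = 5 MV/A) the numerically located −3 dB point of the full
response matches it within 1%; with the default components the 39 and
50 kHz poles are comparable and the combined corner sits near 28 kHz —
the model reports what the cascade actually does.

## Acquisition and the ratio classifier

Samples alternate strictly between channels at 55 S/s, each aligned with
its laser's PWM on-phase; every 200 ms window (11 samples, split 6/5)
produces one frame, so user feedback runs at exactly 5 Hz and no frame
mixes windows. The ADC mapping is a documented convention: single-ended,
6.144 V full scale across the positive 15-bit range of the 16-bit
converter (the hardware's observed dark code is not derivable from stated
information, so no attempt is made to reproduce it).

The ratio uses baseline-subtracted magnitudes, Q = |b − x̄_940| /
|b − x̄_1310| with b the code of the quiescent bias output: the inverting
second stage pulls codes *down* from the dark baseline, and only the
baseline-referred magnitude is proportional to photocurrent — which is
what the 4.75 threshold was designed against (cancellous ≈ 4.28 <
4.75 < cortical ≈ 5.27). The buzzer follows a strict "exceeds" rule:
Q = Q_t exactly leaves it off. Frames whose signal magnitude falls below
one LSB in either channel are flagged invalid and the buzzer holds its
previous state rather than classifying noise.

## Synthetic scenarios

`generate_trace` maps each sample's labelled tissue through reflectance →
photocurrent → steady-state amplifier output → ADC code. Noise enters at
the photocurrent, where the physics puts it: optional shot noise with
variance 2qIB (B = half the sample rate) and a multiplicative
relative-intensity term; quantization is the only ADC-stage noise. The
design documents contain no measured noise figures, so these defaults are
order-of-magnitude physical estimates — shot noise at 433 nA and 27.5 Hz
bandwidth is a ~10⁻⁵ relative perturbation, far below quantization. Per-
sample reflectances default to the registry constants (fast path,
decoupling classifier tests from transport runtime); fresh Monte Carlo
estimates can be substituted via `custom_reflectance`.

What the generator does *not* emulate: tissue heterogeneity and blood
films, probe pressure and angle, coupling drift between prototypes, the
AC-coupling dynamics *between* samples (each sample uses the steady-state
transfer; the 0.47 s coupling transient is modelled separately in
`circuits`), and ADC/I²C timing jitter. Passing classifier tests
therefore demonstrate the internal consistency of the published design —
the threshold separates the *modelled* tissues with margin — not clinical
performance on real bone.

A zero-noise breach is detected within two frames of the true transition
(≤ 400 ms: at most one mixed window plus one pure window), and
classification accuracy degrades monotonically as relative-intensity
noise grows, reaching chance when the noise swamps the 4.28/5.27
separation. Accuracies are reported with Wilson binomial intervals.

## Known limitations

* Single homogeneous layer only — no cancellous/cortical interface inside
  one volume, no fluence maps, no polarization or time resolution.
* The amplifier is ideal-op-amp; saturation recovery and slew limits are
  not modelled beyond rail clipping.
* The registry ships properties for the two selected wavelengths only;
  candidate-wavelength screening needs user-supplied properties.
* The ~2–3% transport offset against the reference table in the
  lowest-albedo cell (cortical, 1310 nm) is unresolved; it is invisible
  at desk-scale Monte Carlo error but shows up in pooled high-count runs.
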