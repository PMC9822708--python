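# Methods

This note documents the models, numerical choices and limitations behind
`tractacoustics`. It is the place to look when a default needs to be
questioned or a stage swapped out.

## Acoustic model

The vocal tract is treated as an air-filled cavity Ω whose closed boundary
is split into a glottal source patch ∂Ω_g, a tissue wall ∂Ω_w and a lip
opening ∂Ω_l. For each excitation frequency we solve the Helmholtz
equation

    ∇²p + κ²p = 0,   κ = ω/c,

for the complex pressure p, with

* **glottis** — Neumann velocity source, ∂p/∂n = −jωϱ₀V₀ with a constant
  particle velocity V₀ (1 m/s by default; all transfer functions are
  normalized by V₀, so its value cancels);
* **wall** — locally reacting impedance Z_w = ϱ₀c/μ as a Robin condition,
  with the dimensionless admittance coefficient μ = 0.005 (i.e.
  Z_w = 200·ϱ₀c), a standard soft-tissue value for vowel simulations;
* **lips** — spherical-wave radiation impedance
  Z_l(ω) = ϱ₀c·(jκr_l)/(1 + jκr_l) as a Robin condition, which absorbs
  outgoing spherical waves: mass-like at low κr_l, plane-wave-like at high.

Constants default to air at body temperature: c = 353 m/s,
ϱ₀ = 1.13 kg/m³.

Derived outputs per sweep: H_gl(ω) = p_l/V₀ and H_gg(ω) = p_g/V₀ with
pressures sampled at the node nearest each patch's area-weighted centroid
("central at the patch" is otherwise underdetermined), and the
volume-velocity transfer function

    V_gl(ω) = p_l·A_l / (Z_l·V₀·A_g),

which is dimensionless and tends to 0 dB at low frequency for any simply
connected cavity (volume-velocity continuity — a useful global sanity
check that the assembled system, areas and impedance are consistent).
Resonances f_Rn / antiresonances L_Rn are local extrema of the dB level
curve with ≥ 1 dB prominence, refined by a three-point parabola because the
frequency grid (10–25 Hz) limits raw precision.

### Discretization

Linear (P1) tetrahedra; element mass/stiffness matrices assembled exactly,
boundary terms with exact triangle mass matrices; one complex sparse LU
solve per frequency (SuperLU). The solver warns below 10 linear elements
per wavelength at the top of the sweep band. Two sweep presets exist:

* **desk** — 10 Hz–5 kHz in 25 Hz steps, 3–4 mm elements; used by the
  tests, the demo and the acceptance script so a full run stays in the
  minutes range on one CPU;
* **paper** — 10 Hz–10 kHz in 10 Hz steps, for production meshes
  (≤ 2.6 mm elements).

f = 0 is excluded from every grid: the source term vanishes and the
rigid-wall operator is singular there.

### Radiation model (a deliberate deviation)

The lip patch is a **flat disc** and r_l is the radius of the *equivalent
radiating sphere* in Z_l, defaulting to 0.6× the lip aperture radius. The
alternative — a geometric hemispherical "bubble" cap carrying the same
impedance with r_l equal to the aperture radius — adds a low-frequency end
correction of ≈ 1.17a (cap air column 2a/3 plus boundary mass a/2), well
above both the unflanged (0.61a) and flanged (0.82a) textbook values, and
systematically flattens resonance frequencies. Matching the equivalent
sphere to the unflanged radiation mass reproduces the classic open-end
correction a priori; the factor is an exposed parameter, so a bubble-cap
variant can be emulated by supplying a different r_l.

## Synthetic scenes

The generator produces the study conditions for every test:

* **Cavities.** Axisymmetric tubes/horns (structured extruded tet meshes;
  cross-sections are regular polygon disks, so analytic volumes/areas are
  matched to ≈ 1% at 3 mm elements) and a tube with a closed side branch
  (voxel/Kuhn tet mesh, since the junction is not extrudable). The default
  reference cylinder is L = 17.5 cm, r = 1.25 cm — vocal-tract scale.
  Megaphone (narrow pharynx → wide mouth) and inverted-megaphone profiles
  give OP/HP ratios above/below 1 by construction.
* **Side branch.** The branch "length" parameter l_b is defined as the
  branch's *acoustic quarter-wave length*: the drilled geometric depth is
  shortened by the flanged-opening end correction 8/(3π)·r_b, so the scene
  realizes a prescribed antiresonance at c/(4·l_b). This matches the
  generator's purpose (cavities with *known* resonances); with the default
  r_b = 4 mm and 1.35 mm voxels the FEM antiresonance lands within ≈ 4% of
  the nominal value, converging from above under refinement.
* **Glottal flow.** A sum of harmonics of f_o up to 10 kHz whose
  magnitudes fall at a prescribed slope (dB/octave), with seeded random
  phases. No physiological pulse shape is imposed: only periodicity and
  spectral slope matter downstream. Defaults: f_o = 208 Hz (the A♭3 task
  pitch; A♭4 = 415 Hz is the other), slope −12 dB/oct (a typical modal
  voice source), fs = 20 kHz, 1 s duration.
* **EGG.** Raised-cosine contacting rise, full-contact plateau,
  raised-cosine de-contacting fall, open plateau; amplitude 0–1 plus 0.3%
  seeded noise. The fraction of the cycle above the 50% level equals the
  prescribed contact quotient exactly (±1 sample), and the rise time
  shrinks as the contact quotient grows, mirroring the physiological
  covariation of firm closure with fast collision — this makes the
  surrogate index of contacting monotone across the family.
* **Microphone audio.** Discrete convolution of the flow with the fitted
  glottis-to-lips impulse response, so the back-filtering stage inverts
  exactly the forward model that produced its input.

What the generator does **not** emulate: nasal coupling, source–filter
interaction, room acoustics and measurement noise, f_o vibrato/jitter, and
MRI segmentation artifacts. Passing tests therefore demonstrate the
correctness of the numerical chain under its stated assumptions, not
robustness to real recording conditions.

## Morphometry

Seven sub-volumes (OPf, OPr, HPu, HPl, ET, SP, VV) are produced by an
ordered list of named cutting planes supplied as data
(`DissectionConfig`): the anatomical landmarks that define them (nasal
septum, uvula, epiglottis apex, aryepiglottic fold, ventricular folds) are
identified manually in practice, so an explicit plane file keeps study and
synthetic meshes on one code path. Tetrahedra are assigned by centroid —
no splitting — which makes the seven volumes sum to the bulk volume
exactly and costs well under 1% at study element sizes. OP = OPf + OPr,
HP = the rest, and OP/HP > 1 marks megaphone-like tracts.

Tract length L is the glottis-to-lips centerline: a shortest path on the
tet adjacency graph with edge weights penalized by inverse distance to the
wall (exponent 2), which holds the path on the duct's medial axis instead
of letting it cut corners; the centroid chain is then lightly smoothed
(20 Laplacian iterations, endpoints fixed) and resampled at two mean edge
lengths before measuring, removing the mesh-scale zigzag that would
otherwise inflate the length by several percent. Edge weights and endpoint
selection are quantized at 1e−9 of the mesh diameter so the result is
invariant under rigid motion to rounding precision. On a straight tube the
estimate is within 0.4% of the axis; on a right-angle bend within ≈ 4% of
the sum of segment axes (the residual is genuine corner rounding).

## Filter approximation and back-filtering

H_gl and H_gg are approximated at fs = 20 kHz (twice the 10 kHz analysis
band). The default fit is an equation-error least-squares design with a
length-256 numerator over a trivial denominator: on the full 10 Hz–10 kHz
grid this is an overdetermined linear problem, unconditionally stable, and
its grid RMS error is non-increasing in the filter length. When the sweep
stops short of Nyquist (desk preset) the complex-exponential basis is
nearly collinear, so the design target is extended with a zero
(band-limiting) response up to fs/2 at reduced weight and a mild ridge
(1e−4 of the RMS response) bounds the coefficients; small singular values
are truncated at 1e−6. An optional Sanathanan–Koerner pole-zero path
exists behind the same interface; unstable poles are reflected inside the
unit circle (1/z̄*, preserving the magnitude shape) and the numerator
refit. Every emitted filter asserts max pole magnitude < 1.

Audio preprocessing: 10th-order Butterworth high-pass at 0.8·f_o applied
zero-phase (forward–backward, so the magnitude acts twice: −6 dB at the
corner), then polyphase resampling to 20 kHz. Deconvolution is time-domain
polynomial long division — the exact inverse of discrete convolution for
finite sequences — with a regularized frequency-domain division
(ε = 1e−8 of the peak squared magnitude) as fallback when the leading
impulse-response sample is tiny or the recursion overflows
(non-minimum-phase responses); the method used is recorded in the result.
The analyzed segment is Hann-windowed before deconvolution. Glottal
pressure follows by direct-form filtering of v_g with the H_gg filter.

## EGG metrics

STAWS: Hann frames of 256 samples, hop 128, at 20 kHz, averaged in the
power domain and normalized to a 0 dB peak (gain-invariant). Spectral
slope: ordinary least squares of dB magnitude on log₂(f/f_o) over
[2f_o, 10f_o] — at the task pitches this spans ≈ 20 bins. Frame averaging
is plain Welch-style; the guideline's "bandwidth of 2·f_o" clause is read
as the analysis-band parameter already implied by the 78 Hz bin width.

The index of contacting I_c has no published closed form (the original is
implemented in a proprietary tool), so a surrogate with the documented
limiting behavior is used: per cycle, r = maximal rise of the
amplitude-normalized waveform over any window of T/8 (1 for a step-like
contacting phase), gated by s = A_pp/(A_pp + a_ref) with a_ref = 5% of the
recording's global peak-to-peak (driving soft, collision-free cycles
toward 0); I_c = median of r·s over cycles, bounded in [0, 1]. The
definition is isolated behind one function so a sourced original can
replace it without touching callers. Cycle boundaries sit at the steepest
positive slope within ±30% of the expected period (f_o is supplied per
task, as in the study protocol; no automatic f_o tracking).

## Intensity and loudness

Instantaneous glottal intensity I(t) = p_g(t)·v_g(t) in W/m²; moving
average over 100 fundamental periods; envelope = magnitude of the analytic
signal; effective intensity I_eff = RMS of the envelope with one smoothing
window trimmed at each end (edge transients of both operations); sound
power P_eff = I_eff·A_g. Intensity levels are reported re 1 W/m²,
pressure levels re 20 µPa.

Loudness normalization implements the broadcast integrated-loudness
measure (K-weighting as two biquads re-derived for the signal's sampling
rate from the standard's analog prototype — the 48 kHz table coefficients
are recovered exactly — 400 ms blocks, 75% overlap, −70 LUFS absolute and
−10 LU relative gates; a 997 Hz full-scale sine measures −3.01 LUFS). The
microphone signal is normalized to −23 LUFS *before* back-filtering; since
the whole chain is linear the normalized intensity equals the raw one
scaled by the squared gain, and the pipeline verifies this by actually
re-running the deconvolution on the scaled audio when the filters are at
hand.

## Problem sizes

Defaults were chosen so a complete run (suite or acceptance script) stays
in the minutes range on a single CPU: desk sweeps of 100–200 frequencies
on meshes of 5–20k nodes, 1–2 s signals at 20 kHz, and the side-branch
scene solved only in a 1 kHz band around its antiresonance. The full-paper
profile is a configuration preset, not a code change.

## Known limitations

* No thermoviscous losses; wall impedance is real, frequency-independent
  and spatially uniform.
* The radiation model is a first-order spherical-wave impedance; above
  ≈ 8 kHz (κr_l ≳ 1) its accuracy degrades gracefully but is untested
  against measurement.
* Voxel meshes have staircase boundaries; their patch areas and branch
  antiresonances carry O(h) geometric error.
* The deposited-study reproduction path (reading tagged MSH meshes of real
  vocal tracts and recorded audio) is implemented and exercised on
  synthetic data only; no real MRI-derived meshes ship with the package.
* The I_c surrogate matches the original's limits, not its exact values.
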