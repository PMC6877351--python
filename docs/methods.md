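# Methods

This note documents the models behind `neuronotch`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
evaluation does and does not demonstrate about real recordings.

## Stage models

All four stages are modelled at transfer-function level (zeros/poles/gain
in the continuous variable s). Component-value synthesis of the underlying
circuits (Bainter band-stop topology, Sallen-Key) is deliberately out of
scope: the topologies' hardware virtues — notch depth insensitive to
component matching, low sensitivity — have no transfer-function
consequence, so a behavioural model captures everything the downstream
measurements depend on.

**Pre-amplifier.** `H(s) = DG·s/(s + DG·K)`, `DG·K = 1/(R·C)`. Defaults
DG = 100 (40 dB), R = 1 MΩ, C = 270 nF, so the −3 dB corner is
`1/(2πRC)` ≈ 0.589 Hz. The time constant R·C = 0.27 s governs the
first-order transient formulas 2.2·R·C = 594 ms (10→90 % transition) and
4·R·C = 1.08 s (±2 % settling), and these are what the time-domain
measurements must reproduce; a nominal "0.5 Hz corner" quoted for such
hardware is treated as a rounded figure, not a design input.

**Notch.** The band edges satisfy `f1·f2 = f0²`, `f2 − f1 = BW` with
f0 = 140 Hz, BW = 30 Hz (edges ≈ 125.8 / 155.8 Hz). Geometric symmetry is
chosen over literal 125/155 Hz edges (which would centre the notch at
139.2 Hz) because the centre frequency is the design target: the magnitude
minimum must sit exactly on the stimulation frequency. The order-8
band-stop is the standard low-pass-prototype transformation of either a
0.5 dB Chebyshev (order 4) or a Bessel prototype (magnitude-normalized so
the prototype edge is the −3 dB point). The transformation does not
preserve the Bessel prototype's maximally flat delay; the design emits a
caveat warning to that effect. Peak passband gain is 0 dB; the even-order
Chebyshev therefore ripples in [−0.5, 0] dB with its DC gain at the ripple
minimum.

**Notch depth convention.** The ideal band-stop has true transmission
zeros at ±j·2π·f0, so point attenuation at f0 is unbounded. Depth is
reported as the *worst-case* attenuation over f0 ± 1 Hz relative to the
mid-band level — the way a finite notch depth is read off a measured Bode
plot. With defaults: Chebyshev ≈ 103 dB, Bessel ≈ 80 dB.

**Low-pass.** 2nd-order all-pole Bessel, magnitude-normalized so
|H(fc)| = −3 dB at fc = 500 Hz (the normalization matching a −3 dB knee on
a Bode plot; the alternative phase normalization would put the knee
elsewhere). Asymptotic slope −40 dB/decade.

**Gain stage.** Static 20/40 dB, ±2.5 V output rails. The optional
nonlinearity is a memoryless cubic `u + a3·u³` at the gain-stage input
followed by hard clipping at the rails. a3 = 0.1 V⁻² is sized once so the
full-scale THD of the 60 dB chain (2.3 mV peak input) is ≈ 0.12 %, inside
the 0.2 % envelope; the cubic reproduces the canonical two-tone behaviour
(fundamental 1 dB/dB, IMD3 3 dB/dB, input intercept `A² = 4/(3·a3)`),
which is what the distortion metrology is validated against.

## Discretization

Each dynamic stage is mapped by the bilinear transform with frequency
prewarping at its own critical frequency (pre-amp corner, notch centre,
low-pass cutoff) and emitted as second-order sections. Prewarping per
stage pins the notch minimum exactly at 140 Hz in the digital domain. At
the default 20 kHz rate the digital cascade tracks the analog magnitude
within 0.083 dB up to 1 kHz (worst at 1 kHz, from the warping of the
low-pass skirt). The rate must be at least 10× the low-pass cutoff.

## Synthetic signals

**Pulse trains** are monophasic rectangles rendered with exact-area
fractional edges: an edge falling between sample instants is split between
adjacent bins. Integer snapping would lock a 140 Hz train at 20 kHz to a
50 ms super-period (20000/140 = 1000/7) and spray spurious 20 Hz-multiple
lines at electrode-relevant levels through the recording band; area
rendering keeps the sampled train's line spectrum at multiples of the
stimulation frequency with sub-nV spurious content. Stimulator rise/fall
times and source impedance are not modelled (worst-case spectral
richness).

**LFP surrogates** are Gaussian processes synthesized in the frequency
domain: Gaussian spectral bumps (σ = bandwidth/2) at 20 Hz (beta band,
0.16 µV rms) and 80 Hz (0.10 µV rms) on a 1/f background carrying the
remaining variance, rescaled so the realized trace is exactly 0.32 µV rms.
The component split is a realism choice: it makes the beta peak the
tallest narrowband feature of the PSD while the 1/f background dominates
below a few Hz, as in subthalamic recordings.

**Input-referred noise** has one-sided PSD `S0·(1 + fc/f)` with
√S0 = 4 nV/√Hz and fc = 10 Hz, synthesized by Hermitian spectral shaping
(the f→0 singularity capped at the first non-zero FFT bin). The closed-form
band integral over 0.5–500 Hz is 95.4 nV rms. Note that a single
`S0·(1+fc/f)` model cannot simultaneously reproduce both a 26 nV (0.5–40 Hz)
and a 96 nV (0.5–500 Hz) figure (the model gives 25.1 nV for the narrow
band); the module reports the model value and leaves the discrepancy to the
noise source, not the integrator.

## Sensing model

The electrode pair splits the artefact into modes:

    v_cm   = κ_cm·artefact + (dc+ + dc−)/2
    v_diff = lfp + α·κ_cm·artefact + (dc+ − dc−) + drift
    input  = v_diff + v_cm·10^(−CMRR/20)

κ_cm = 3.3·10⁻³ puts a 3 V stimulus at ~10 mV of common-mode artefact at
the contacts — large enough to matter, small enough that the chain never
saturates, consistent with the hardware's no-saturation behaviour (the
actual in-bath coupling is not published; κ_cm is a free scenario
parameter). α encodes contact asymmetry: 0.02 for unipolar sensing
(symmetric about the stimulation contact), 0.2 for bipolar.

`drift` models stimulation-induced electrode polarization: monophasic
pulses deposit net charge, so a differential offset grows in proportion to
the time-integral of the differentially sensed artefact, scaled by the
DC-offset asymmetry (rate constant 15 V⁻¹s⁻¹, chosen once so the bipolar
scenario's drift residue sits in the tens-of-percent nrmse regime). It
vanishes with symmetric sensing, zero offsets, or stimulation off. After
the AC coupling settles, a polarization ramp leaves a small *constant*
residue (slope × R·C × gain) — the mechanism behind the error floor that
*shrinks* relative to the reference as the recording bandwidth grows,
producing the characteristic decrease of nrmse from 50 to 140 Hz
bandwidths when offsets are enabled, and a flat-to-increasing curve when
they are zeroed.

## Measurement conventions

* **Amplitude spectra** are single-sided RMS, dB re 1 V, scaled by the
  window's coherent gain so an on-bin sine of peak A reads
  `20·log10(A/√2)`. Flat-top is the default for (non-coherent) tone
  amplitude accuracy; Hann for noise densities. When the tones are exactly
  periodic in the analysis window (the IP3 sweep; the nV-tone checks) a
  rectangular window is used instead: coherent sampling needs no
  scalloping protection, and the flat-top's ~3.8-bin noise bandwidth would
  otherwise let 1/f noise or tone sidelobes corrupt products measured
  >120 dB below the carriers. Input-referred spectra divide the output
  spectrum by the channel's frequency response, as done on hardware.
* **Transients.** Rise time is the 10→90 % threshold interval; for an
  AC-coupled response returning to baseline the slowest transition is the
  recovery, measured between the last 90 % and last 10 % crossings (for
  the first-order front end this equals 2.2·R·C). Settling is the last
  excursion outside ±2 % of the response peak. Step overshoot is the
  excess of the maximum over the mid-band plateau; pulse responses report
  the first-undershoot ratio instead.
* **THD** uses harmonics 2–6 (five harmonics); **IP3** fits least-squares
  lines to the fundamental and 2f2−f1 sweeps in dBm into 50 Ω and
  intersects them. Slopes are impedance-invariant.
* **Bode slopes** are least-squares fits of magnitude vs log10 f over a
  stated decade, reported with the fit residual.
* **Frequency of the magnitude minimum** is located on a ≥10⁴-point
  logarithmic grid and refined by golden-section search to 0.01 Hz.
* Degenerate inputs (empty traces, non-finite samples, constant RMSE
  references, unresolvable tones) raise typed errors; nothing propagates
  NaNs silently.

## Bandwidth-sweep evaluation

The in-vitro style evaluation records a seeded LFP + noise realization
through each channel variant with and without stimulation (paired seeds:
the stim-on/off pair share the identical LFP and noise, so the error
isolates what stimulation adds), limits the bandwidth with a steep
linear-phase FIR (Kaiser-window design verified against its template:
stopband ≥ 80 dB beyond 1.1× cutoff; Parks–McClellan is unreliable at the
~20 000-tap template the 50 Hz cutoff needs at 20 kHz), and scores
normalized RMSE over the settled window (5–55 s of a 60 s record at
20 kHz — sizes chosen so the AC-coupling transient, FIR edges and drift
settling are excluded while spectral estimates stay tight). The FIR is
applied at the full simulation rate, playing the digitizer's anti-alias
role; aliasing itself is demonstrated separately by decimation without an
anti-alias filter, which folds stimulation harmonics to non-harmonic
frequencies (840 Hz → 160 Hz at 1 kS/s). An estimator floor — the nrmse
between two stim-off runs with independent noise — is reported alongside
every value.

## What the synthetic evaluation shows — and what it does not

The generator emulates the study conditions (pulse amplitude/rate/width,
LFP level and spectral peaks, noise density and corner, sensing asymmetry)
but not electrode impedance spectra, charge-transfer electrochemistry,
volume conduction, stimulator output stages, or amplifier macromodel
effects. Consequences to keep in mind:

* Both ideal notches carry exact transmission zeros at 140 Hz, so at the
  stimulation frequency itself the Chebyshev and Bessel channels suppress
  the artefact line equally — unlike real hardware, where finite notch
  depth separates them. The Chebyshev-vs-Bessel error ordering in the
  sweep therefore rests on second-order effects (DC-ripple scaling of the
  drift residue, 280 Hz harmonic shaping) with ~1–3 % margins: it holds
  deterministically on the default seeded scenarios, but across arbitrary
  seeds the margin at the widest bandwidth is within realization noise.
  The no-notch ordering, by contrast, is structural (the 140 Hz line
  enters the passband) with margins of ~60×.
* Normalized RMSE values are paired-seed quantities; an unpaired hardware
  measurement additionally carries the independent-noise floor reported
  alongside.
* The 142 Hz scenario's measured line suppression (~113 dB) reflects the
  differential path (α attenuation plus notch attenuation at 142 Hz); the
  common-mode path is CMRR + notch, far below it. Hardware figures
  combining both paths with unknown coupling cannot be compared number
  for number, only as bounds (the suppression exceeds the notch
  attenuation, with no rail saturation).
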