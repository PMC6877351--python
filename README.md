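# neuronotch

A desk-scale digital twin of a four-stage analog front end (AFE) for
recording local field potentials (LFPs) *during* deep brain stimulation
(DBS), together with the synthetic signals and the measurement battery
needed to characterize it.

## The problem

Therapeutic DBS delivers volts-scale pulse trains (3–6 V peak-to-peak,
140 Hz, 100 µs wide) centimetres away from electrodes trying to sense
µV-scale neural signals — an interferer up to six orders of magnitude
larger than the signal, sitting *inside* the recording band. The front end
modelled here suppresses the artefact in the analog domain before the
digitizer can saturate or alias:

1. **AC-coupled differential pre-amplifier** — gain `DG` with an active
   feedback integrator, `H(s) = DG·s/(s + DG·K)` with `DG·K = 1/(R·C)`
   (R = 1 MΩ, C = 270 nF → 0.59 Hz corner, 40 dB mid-band). The high CMRR
   of the differential input rejects the common-mode artefact; the AC
   coupling rejects tens-of-mV electrode polarization offsets, with the
   textbook transients `t_rise = 2.2·R·C` and `t_settle = 4·R·C`.
2. **8th-order band-stop ("notch") at 140 Hz** (stopband ≈ 126–156 Hz),
   as either a 0.5 dB-ripple Chebyshev or a Bessel approximation of the
   low-pass prototype — the steep-skirt vs. benign-transient trade-off.
   This removes the *differential*-mode artefact the CMRR cannot touch.
3. **2nd-order Sallen-Key low-pass** (Bessel poles, −3 dB at 500 Hz) to
   suppress stimulation harmonics and set the passband.
4. **Programmable output stage** (20/40 dB, ±2.5 V rails) for a total
   chain gain of 60 or 80 dB.

The package designs these stages as rational transfer functions, cascades
and discretizes them (bilinear transform, per-stage prewarping, second-order
sections), pushes synthetic electrode signals through them, and measures
everything an analog bench would: Bode magnitude and asymptotic slopes,
impulse/step/biphasic transients, calibrated RMS amplitude spectra
(a tone of peak A reads `20·log10(A/√2)` dB re 1 V), band-integrated
input noise for the `S(f) = S0·(1 + f_c/f)` model, THD, two-tone IMD with
third-order-intercept extraction, and normalized RMSE
(`100·rms(test − ref)/range(ref)`) for recording-quality scoring.

## Worked example

```python
import neuronotch as nn

model = nn.build_channel("chebyshev", 60)
print(f"mid-band gain at 25 Hz : {float(nn.freq_response(model,[25]).magnitude_db[0]):.2f} dB")
print(f"notch minimum          : {nn.find_magnitude_minimum(model):.2f} Hz")
print(f"notch depth (f0±1 Hz)  : {nn.notch_depth_db(model):.1f} dB")
print(f"integrated noise       : {nn.integrated_noise_rms(nn.NoiseModel(),0.5,500)*1e9:.1f} nV rms (0.5-500 Hz)")

rep = nn.run_invitro_sim(nn.ScenarioConfig(
    seed=1, variants=("chebyshev", "no_notch"),
    stim_modes=("bipolar",), bandwidths=(50.0, 140.0)))
print(rep.nrmse_table[["variant", "bandwidth_hz", "nrmse_percent"]].to_string(index=False))
```

prints

```
mid-band gain at 25 Hz : 59.50 dB
notch minimum          : 140.00 Hz
notch depth (f0±1 Hz)  : -102.6 dB
integrated noise       : 95.4 nV rms (0.5-500 Hz)
  variant  bandwidth_hz  nrmse_percent
chebyshev          50.0      34.636545
chebyshev         140.0      28.141091
 no_notch          50.0      34.699159
 no_notch         140.0    1904.255091
```

Reading it: the designed channel hits its 60 dB passband gain (the 0.5 dB
Chebyshev ripple accounts for the last half-dB), the notch minimum lands
exactly on the stimulation frequency with >100 dB of worst-case attenuation
within ±1 Hz, and the noise model integrates to 95.4 nV rms over the
recording band. In the simulated in-vitro evaluation, a synthetic 0.32 µV
rms LFP is recorded with and without bipolar stimulation: once the
available bandwidth reaches the stimulation frequency (140 Hz), the chain
without a notch filter is unusable (nrmse ≈ 1900 %) while the Chebyshev
notch channel's error *improves* with bandwidth, because its residual error
is dominated by a stimulation-induced DC drift residue that shrinks
relative to the growing recorded signal.

A CLI covers the common runs:

```sh
neuronotch design --variant chebyshev --export sos.csv --export-zpk zpk.csv
neuronotch characterize --out out/ --seed 1
neuronotch simulate --scenario bipolar_invitro --seed 7 --out out/
```

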