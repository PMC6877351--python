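"""Synthetic test and scenario signals.

Three generators cover everything the measurement bench needs:

* :func:`gen_pulse_train` — monophasic rectangular stimulation pulse trains
  (volts-scale, 140/142 Hz, 100 µs wide). Pulses are rendered with
  exact-area fractional edges: a pulse edge falling between two sample
  instants is split between the adjacent bins so the sampled train carries
  the continuous train's spectrum without edge-quantization tones. (Integer
  snapping of edges at 20 kHz would otherwise lock the 140 Hz train to a
  50 ms super-period and spray spurious 20 Hz-multiple lines through the
  recording band.)
* :func:`gen_lfp` — µV-scale local field potential surrogates: narrowband
  Gaussian components (a beta-band peak and an 80 Hz peak by default) on a
  1/f^β background, rescaled to an exact total RMS.
* :func:`gen_noise` — input-referred amplifier noise with one-sided PSD
  ``S(f) = S0·(1 + fc/f)`` (white density plus 1/f below the corner).

Stochastic signals are synthesized by frequency-domain shaping of white
Gaussian noise (Hermitian-symmetric spectrum, the f→0 singularity capped at
the first non-zero FFT bin) and are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidRateError, InvalidSpecificationError
from .trace import SignalTrace

__all__ = [
    "StimulusSpec",
    "LFPSpec",
    "NoiseModel",
    "gen_pulse_train",
    "gen_lfp",
    "gen_noise",
    "resample_no_antialias",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Monophasic rectangular stimulation pulse train.

    ``on_interval`` restricts pulse emission to a time window (seconds);
    ``None`` means the train runs for the whole record.
    """

    amplitude_pp: float = 3.0      # volt, peak-to-peak (baseline 0 -> peak)
    frequency: float = 140.0       # Hz
    pulse_width: float = 100e-6    # s
    shape: str = "monophasic_rectangular"
    on_interval: tuple[float, float] | None = None

    def __post_init__(self):
        if not (self.amplitude_pp > 0):
            raise InvalidSpecificationError("amplitude_pp must be positive")
        if not (self.frequency > 0):
            raise InvalidSpecificationError("frequency must be positive")
        if not (0 < self.pulse_width < 1 / self.frequency):
            raise InvalidSpecificationError(
                "pulse_width must be positive and shorter than one period"
            )
        if self.shape != "monophasic_rectangular":
            raise InvalidSpecificationError(
                f"unsupported pulse shape {self.shape!r}"
            )


@dataclass(frozen=True)
class LFPSpec:
    """Synthetic LFP: narrowband components on a 1/f^β background.

    ``components`` is a sequence of ``(center_hz, bandwidth_hz, rms_v)``
    triples; each contributes a Gaussian spectral bump (σ = bandwidth/2).
    The background takes up the remaining variance so the realized trace is
    rescaled to exactly ``total_rms``. Defaults emulate a parkinsonian
    subthalamic recording: a beta-band (20 Hz) peak, a smaller 80 Hz peak
    and a 1/f background, 0.32 µV RMS overall.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (20.0, 6.0, 0.16e-6),
        (80.0, 4.0, 0.10e-6),
    )
    background_exponent: float = 1.0
    total_rms: float = 0.32e-6     # volt
    seed: int | None = 0

    def __post_init__(self):
        if not (self.total_rms > 0):
            raise InvalidSpecificationError("total_rms must be positive")
        comp_var = 0.0
        for fc, bw, rms in self.components:
            if fc <= 0 or bw <= 0 or rms < 0:
                raise InvalidSpecificationError(
                    f"bad component (center={fc}, bw={bw}, rms={rms})"
                )
            comp_var += rms**2
        if comp_var >= self.total_rms**2:
            raise InvalidSpecificationError(
                "component variances exceed total_rms^2; no room for background"
            )

    @property
    def background_rms(self) -> float:
        comp_var = sum(rms**2 for _, _, rms in self.components)
        return float(np.sqrt(self.total_rms**2 - comp_var))


@dataclass(frozen=True)
class NoiseModel:
    """Input-referred noise: one-sided PSD ``S(f) = S0·(1 + fc_1f/f)``."""

    white_density: float = (4e-9) ** 2   # V^2/Hz (4 nV/sqrt(Hz))
    corner_hz: float = 10.0              # 1/f corner
    seed: int | None = 0

    def __post_init__(self):
        if self.white_density < 0:
            raise InvalidSpecificationError("white_density must be >= 0")
        if self.corner_hz < 0:
            raise InvalidSpecificationError("corner_hz must be >= 0")

    def psd(self, f: np.ndarray) -> np.ndarray:
        """One-sided PSD in V²/Hz at frequencies f (Hz, > 0)."""
        f = np.asarray(f, float)
        return self.white_density * (1.0 + self.corner_hz / f)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_pulse_train(
    spec: StimulusSpec,
    fs: float,
    duration: float,
    seed: int | None = None,
) -> SignalTrace:
    """Render the pulse train at rate ``fs`` for ``duration`` seconds.

    Pulses start at integer multiples of the period (within ``on_interval``)
    and are rendered with exact-area fractional edges. The generator is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    del seed  # deterministic signal
    if duration <= 0:
        raise InvalidSpecificationError("duration must be positive")
    if fs < 2 / spec.pulse_width:
        warnings.warn(
            f"fs = {fs:g} Hz resolves the {spec.pulse_width * 1e6:g} us pulse "
            "with fewer than 2 samples; recommend fs >= 2/pulse_width",
            stacklevel=2,
        )
    n = int(round(duration * fs))
    x = np.zeros(n)
    t_on, t_off = spec.on_interval or (0.0, duration)
    period = 1.0 / spec.frequency
    k0 = int(np.ceil(t_on / period - 1e-12))
    k = k0
    while True:
        t_a = k * period
        if t_a >= min(t_off, duration):
            break
        _add_rect(x, fs, t_a, min(t_a + spec.pulse_width, duration),
                  spec.amplitude_pp)
        k += 1
    return SignalTrace(x, fs)


def _add_rect(x: np.ndarray, fs: float, t_a: float, t_b: float, amp: float):
    """Add a rectangle [t_a, t_b) of height amp with area-exact edges."""
    a, b = t_a * fs, t_b * fs
    i0, i1 = int(np.floor(a)), int(np.floor(b))
    n = x.size
    if i0 == i1:
        if 0 <= i0 < n:
            x[i0] += amp * (b - a)
        return
    if 0 <= i0 < n:
        x[i0] += amp * (i0 + 1 - a)
    lo, hi = max(i0 + 1, 0), min(i1, n)
    if hi > lo:
        x[lo:hi] += amp
    if 0 <= i1 < n:
        x[i1] += amp * (b - i1)


def _synthesize_from_psd(psd, fs: float, n: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Gaussian realization of a one-sided PSD via Hermitian FFT shaping."""
    df = fs / n
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    nbins = freqs.size
    spec = np.zeros(nbins, complex)
    p = np.asarray(psd(freqs[1:]), float)
    amp = n * np.sqrt(p * df)
    g = rng.standard_normal((2, nbins - 1))
    spec[1:] = (g[0] + 1j * g[1]) / 2 * amp
    if n % 2 == 0:
        # Nyquist bin must be real; weight 1/N^2 in Parseval
        spec[-1] = g[0][-1] * amp[-1] / np.sqrt(2)
    return np.fft.irfft(spec, n=n)


def gen_lfp(spec: LFPSpec, fs: float, duration: float,
            seed: int | None = None) -> SignalTrace:
    """Generate a synthetic LFP trace, rescaled to exactly ``total_rms``."""
    for fc, _, _ in spec.components:
        if fc >= fs / 2:
            raise InvalidSpecificationError(
                f"component at {fc} Hz is not below Nyquist ({fs / 2} Hz)"
            )
    n = int(round(duration * fs))
    if n < 2:
        raise InvalidSpecificationError("duration too short for this rate")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    df = fs / n
    f1 = df  # first non-zero bin caps the 1/f^beta singularity

    def psd(f):
        f = np.asarray(f, float)
        total = np.zeros_like(f)
        for fc, bw, rms in spec.components:
            sigma = bw / 2.0
            g = np.exp(-0.5 * ((f - fc) / sigma) ** 2)
            total += rms**2 * g / (np.sqrt(2 * np.pi) * sigma)
        fb = np.maximum(f, f1)
        shape = fb ** (-spec.background_exponent)
        # normalize background to its variance budget over (0, fs/2]
        fgrid = np.arange(1, n // 2 + 1) * df
        norm = np.sum(np.maximum(fgrid, f1) ** (-spec.background_exponent)) * df
        total += spec.background_rms**2 * shape / norm
        return total

    x = _synthesize_from_psd(psd, fs, n, rng)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= spec.total_rms / rms
    return SignalTrace(x, fs)


def gen_noise(model: NoiseModel, fs: float, duration: float,
              seed: int | None = None) -> SignalTrace:
    """Generate input-referred noise with PSD ``S0·(1 + fc/f)``."""
    n = int(round(duration * fs))
    if n < 2:
        raise InvalidSpecificationError("duration*fs must be at least 2")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    if model.white_density == 0:
        return SignalTrace(np.zeros(n), fs)
    x = _synthesize_from_psd(model.psd, fs, n, rng)
    return SignalTrace(x, fs)


def resample_no_antialias(x: SignalTrace, target_fs: float) -> SignalTrace:
    """Plain decimation without an anti-alias filter.

    Deliberately reproduces the spectral folding a digitizer exhibits when
    its input is insufficiently band-limited: content above the new Nyquist
    rate folds to ``|f - k·target_fs|``, producing lines that are not
    harmonics of the original tone spacing.
    """
    ratio = x.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise InvalidRateError(
            f"target_fs must divide fs; got fs={x.fs}, target_fs={target_fs}"
        )
    r = int(round(ratio))
    return SignalTrace(x.samples[::r].copy(), target_fs, x.t0)
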