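"""Analog stage specifications and transfer-function design.

The front-end under study is a cascade of four analog stages:

1. an AC-coupled differential pre-amplifier (instrumentation amplifier with
   an active feedback integrator), ``H(s) = DG·s / (s + DG·K)`` with
   ``DG·K = 1/(R·C)`` — a first-order high-pass with mid-band gain ``DG``;
2. an 8th-order active band-stop ("notch") filter centred on the stimulation
   frequency (140 Hz), realized either as a 0.5 dB-ripple Chebyshev or a
   Bessel approximation of the low-pass prototype, transformed to a
   geometric-symmetric band-stop;
3. a 2nd-order Sallen-Key low-pass with Bessel pole placement, -3 dB at the
   cutoff (500 Hz by default);
4. a programmable output gain stage (20 or 40 dB) running off ±2.5 V rails.

Each design function returns an :class:`AnalogStage` — a zeros/poles/gain
triple in the continuous-frequency variable s (rad/s). Component-value
synthesis of the underlying circuits is out of scope; the stages are modelled
at transfer-function level, which captures everything the downstream
measurements depend on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DesignCaveatWarning, InvalidSpecificationError

__all__ = [
    "PreampSpec",
    "FILTER_FAMILIES",
    "NotchSpec",
    "LowpassSpec",
    "GainStageSpec",
    "AnalogStage",
    "design_preamp",
    "design_notch",
    "design_lowpass",
    "design_gain_stage",
]

#: Closed enumeration of notch approximation families.
FILTER_FAMILIES = ("chebyshev_0p5dB", "bessel")


@dataclass(frozen=True)
class AnalogStage:
    """One AFE stage as a rational transfer function in s.

    Attributes
    ----------
    zeros, poles : complex ndarray
        Zeros/poles in rad/s. Poles must lie in the open left half-plane;
        complex singularities occur in conjugate pairs (real coefficients).
    gain : float
        Transfer-function gain factor k of the zpk form.
    name : str
        Human-readable stage tag used in reports.
    critical_frequency : float or None
        The frequency (rad/s) preserved exactly under bilinear prewarping
        when the stage is discretized. ``None`` for static stages.
    """

    zeros: np.ndarray
    poles: np.ndarray
    gain: float
    name: str = "stage"
    critical_frequency: float | None = None

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.zeros, dtype=complex))
        p = np.atleast_1d(np.asarray(self.poles, dtype=complex))
        object.__setattr__(self, "zeros", z)
        object.__setattr__(self, "poles", p)
        if p.size and np.any(p.real >= 0):
            raise InvalidSpecificationError(
                f"stage {self.name!r} has poles outside the open left half-plane"
            )
        for arr, what in ((z, "zeros"), (p, "poles")):
            if arr.size and not _conjugate_paired(arr):
                raise InvalidSpecificationError(
                    f"stage {self.name!r}: complex {what} are not conjugate-paired"
                )

    @property
    def order(self) -> int:
        """Denominator degree (number of poles)."""
        return int(self.poles.size)

    def response(self, frequencies_hz) -> np.ndarray:
        """Complex response at the given frequencies (Hz)."""
        w = 2 * np.pi * np.atleast_1d(np.asarray(frequencies_hz, float))
        _, h = signal.freqs_zpk(self.zeros, self.poles, self.gain, worN=w)
        return h


def _conjugate_paired(values: np.ndarray, tol: float = 1e-8) -> bool:
    cplx = values[np.abs(values.imag) > tol * (1 + np.abs(values))]
    if cplx.size == 0:
        return True
    scale = np.max(np.abs(cplx))
    remaining = list(cplx)
    while remaining:
        v = remaining.pop()
        match = [i for i, u in enumerate(remaining)
                 if abs(u - np.conj(v)) <= 1e-8 * (1 + scale)]
        if not match:
            return False
        remaining.pop(match[0])
    return True


# ---------------------------------------------------------------------------
# Stage specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreampSpec:
    """AC-coupled pre-amplifier: differential gain plus feedback integrator.

    The feedback integrator (slope ``K``, in 1/s) forms a high-pass with the
    differential gain ``DG``: the product ``DG·K`` equals ``1/(R·C)`` of the
    integrator network, placing the -3 dB corner at ``1/(2πRC)`` ≈ 0.589 Hz
    with the default 1 MΩ / 270 nF values.
    """

    differential_gain: float = 100.0        # V/V (40 dB)
    feedback_resistance: float = 1e6        # ohm
    feedback_capacitance: float = 270e-9    # farad

    def __post_init__(self):
        for label, v in (
            ("differential_gain", self.differential_gain),
            ("feedback_resistance", self.feedback_resistance),
            ("feedback_capacitance", self.feedback_capacitance),
        ):
            if not (np.isfinite(v) and v > 0):
                raise InvalidSpecificationError(f"{label} must be positive, got {v}")

    @property
    def integrator_slope(self) -> float:
        """K in 1/s; DG·K = 1/(R·C)."""
        rc = self.feedback_resistance * self.feedback_capacitance
        return 1.0 / (self.differential_gain * rc)

    @property
    def corner_hz(self) -> float:
        """-3 dB high-pass corner DG·K/(2π) in Hz."""
        return self.differential_gain * self.integrator_slope / (2 * np.pi)

    @property
    def time_constant(self) -> float:
        """R·C in seconds; governs the transient formulas 2.2·RC and 4·RC."""
        return self.feedback_resistance * self.feedback_capacitance


@dataclass(frozen=True)
class NotchSpec:
    """Band-stop filter: centre frequency, stop bandwidth, order, family.

    The two band edges are geometric-symmetric about the centre:
    ``f1·f2 = f0²`` and ``f2 - f1 = BW``, so the magnitude minimum of the
    transformed filter falls exactly on ``f0``. With the defaults
    (f0 = 140 Hz, BW = 30 Hz) the edges are ≈125.8 and ≈155.8 Hz.
    """

    center_frequency: float = 140.0   # Hz
    stop_bandwidth: float = 30.0      # Hz
    order: int = 8                    # total pole count (even)
    family: str = "chebyshev_0p5dB"
    passband_ripple_db: float = 0.5   # Chebyshev family only

    def __post_init__(self):
        if not (self.center_frequency > 0):
            raise InvalidSpecificationError("center_frequency must be positive")
        if not (0 < self.stop_bandwidth < 2 * self.center_frequency):
            raise InvalidSpecificationError(
                "stop_bandwidth must lie in (0, 2·f0)"
            )
        if self.order < 2 or self.order % 2 != 0:
            raise InvalidSpecificationError(
                f"order must be even and >= 2, got {self.order}"
            )
        if self.family not in FILTER_FAMILIES:
            raise InvalidSpecificationError(
                f"family must be one of {FILTER_FAMILIES}, got {self.family!r}"
            )
        if not (self.passband_ripple_db > 0):
            raise InvalidSpecificationError("passband_ripple_db must be positive")

    @property
    def band_edges(self) -> tuple[float, float]:
        """(f1, f2) in Hz with f1·f2 = f0² and f2 - f1 = BW."""
        f0, bw = self.center_frequency, self.stop_bandwidth
        f1 = (-bw + np.sqrt(bw**2 + 4 * f0**2)) / 2
        return (f1, f1 + bw)


@dataclass(frozen=True)
class LowpassSpec:
    """Sallen-Key low-pass: Bessel pole placement, |H(fc)| = -3 dB."""

    cutoff: float = 500.0   # Hz
    order: int = 2
    family: str = "bessel"

    def __post_init__(self):
        if not (np.isfinite(self.cutoff) and self.cutoff > 0):
            raise InvalidSpecificationError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise InvalidSpecificationError("order must be >= 1")
        if self.family != "bessel":
            raise InvalidSpecificationError("only the bessel family is supported")


@dataclass(frozen=True)
class GainStageSpec:
    """Programmable output stage: 20 dB or 40 dB, ±rail supply."""

    gain_db: float = 20.0
    output_rail: float = 2.5  # volt

    ALLOWED_GAINS_DB = (20.0, 40.0)

    def __post_init__(self):
        if float(self.gain_db) not in self.ALLOWED_GAINS_DB:
            raise InvalidSpecificationError(
                f"gain_db restricted to {self.ALLOWED_GAINS_DB}, got {self.gain_db}"
            )
        if not (self.output_rail > 0):
            raise InvalidSpecificationError("output_rail must be positive")

    @property
    def gain_linear(self) -> float:
        return 10 ** (self.gain_db / 20)


# ---------------------------------------------------------------------------
# Design functions
# ---------------------------------------------------------------------------

def design_preamp(spec: PreampSpec = PreampSpec()) -> AnalogStage:
    """Design the AC-coupled pre-amplifier stage.

    Returns ``H(s) = DG·s/(s + DG·K)``: one zero at the origin (DC fully
    blocked) and one real pole at ``-1/(R·C)``. Mid-band gain is DG
    (40 dB for the default DG = 100).
    """
    wc = spec.differential_gain * spec.integrator_slope  # = 1/(R·C), rad/s
    return AnalogStage(
        zeros=np.array([0.0 + 0j]),
        poles=np.array([-wc + 0j]),
        gain=spec.differential_gain,
        name="preamp",
        critical_frequency=wc,
    )


def design_notch(spec: NotchSpec = NotchSpec()) -> AnalogStage:
    """Design the band-stop (notch) stage.

    The selected low-pass prototype family (order/2) is transformed to a
    band-stop with geometric-symmetric edges, placing a pair of transmission
    zeros at ±j·2π·f0: the magnitude minimum is exactly the centre frequency.
    Peak passband gain is 0 dB; the Chebyshev family ripples within its
    specified 0.5 dB below that.

    The "Bessel notch" is the band-stop transformation of a Bessel low-pass
    prototype; the transformation does not preserve the prototype's
    maximally-flat group delay, so a :class:`DesignCaveatWarning` is emitted.
    """
    f1, f2 = spec.band_edges
    wn = (2 * np.pi * f1, 2 * np.pi * f2)
    proto_order = spec.order // 2
    if spec.family == "chebyshev_0p5dB":
        z, p, k = signal.cheby1(
            proto_order, spec.passband_ripple_db, wn,
            btype="bandstop", analog=True, output="zpk",
        )
    else:
        warnings.warn(
            "Bessel band-stop: the low-pass-to-band-stop transformation does "
            "not preserve the Bessel prototype's phase linearity",
            DesignCaveatWarning,
            stacklevel=2,
        )
        z, p, k = signal.bessel(
            proto_order, wn, btype="bandstop", analog=True,
            output="zpk", norm="mag",
        )
    return AnalogStage(
        zeros=z, poles=p, gain=float(k),
        name=f"notch_{spec.family}",
        critical_frequency=2 * np.pi * spec.center_frequency,
    )


def design_lowpass(spec: LowpassSpec = LowpassSpec()) -> AnalogStage:
    """Design the low-pass stage: all-pole Bessel, DC gain 0 dB, -3 dB at fc."""
    z, p, k = signal.bessel(
        spec.order, 2 * np.pi * spec.cutoff, btype="low",
        analog=True, output="zpk", norm="mag",
    )
    return AnalogStage(
        zeros=z, poles=p, gain=float(k),
        name="lowpass",
        critical_frequency=2 * np.pi * spec.cutoff,
    )


def design_gain_stage(spec: GainStageSpec = GainStageSpec()) -> AnalogStage:
    """Design the static output gain stage (no dynamics)."""
    return AnalogStage(
        zeros=np.empty(0, complex),
        poles=np.empty(0, complex),
        gain=spec.gain_linear,
        name=f"gain_{spec.gain_db:g}dB",
        critical_frequency=None,
    )
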