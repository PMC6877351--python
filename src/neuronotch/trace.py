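"""Uniformly sampled voltage traces and their CSV interchange format.

A :class:`SignalTrace` is the package's in-memory container for a voltage
time series: a float64 sample array in volts, a sample rate in Hz and an
optional start time. Traces are immutable value objects; arithmetic helpers
return new traces.

The on-disk format is deliberately minimal and text-only: a comment header
line ``# fs=<Hz>`` followed by one voltage sample per row. Samples are
written with 17 significant digits, which round-trips IEEE-754 doubles
losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    IncompatibleTraceError,
    InvalidTraceError,
    TraceParseError,
)

__all__ = ["SignalTrace", "read_trace", "write_trace"]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled voltage series.

    Parameters
    ----------
    samples : array_like
        Voltage samples in volts. Must be non-empty and finite.
    fs : float
        Sample rate in Hz, strictly positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self._skip_validation:
            return
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidTraceError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise InvalidTraceError("trace contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise InvalidTraceError(f"sample rate must be positive, got {self.fs}")

    # -- basic views ---------------------------------------------------
    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def rms(self) -> float:
        """Root-mean-square value in volts."""
        return float(np.sqrt(np.mean(self.samples**2)))

    # -- arithmetic ----------------------------------------------------
    def _check_compatible(self, other: "SignalTrace") -> None:
        if self.fs != other.fs:
            raise IncompatibleTraceError(
                f"sample rates differ: {self.fs} Hz vs {other.fs} Hz"
            )
        if len(self) != len(other):
            raise IncompatibleTraceError(
                f"lengths differ: {len(self)} vs {len(other)}"
            )

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        return replace(self, samples=np.asarray(samples, float))

    def __add__(self, other):
        if isinstance(other, SignalTrace):
            self._check_compatible(other)
            return self.with_samples(self.samples + other.samples)
        return self.with_samples(self.samples + other)

    def __sub__(self, other):
        if isinstance(other, SignalTrace):
            self._check_compatible(other)
            return self.with_samples(self.samples - other.samples)
        return self.with_samples(self.samples - other)

    def __mul__(self, scalar: float):
        return self.with_samples(self.samples * float(scalar))

    __rmul__ = __mul__

    def crop(self, t_start: float, t_stop: float) -> "SignalTrace":
        """Return the sub-trace with times in [t_start, t_stop)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.fs)))
        i1 = min(len(self), int(np.floor((t_stop - self.t0) * self.fs)))
        if i1 <= i0:
            raise InvalidTraceError("crop window contains no samples")
        return SignalTrace(self.samples[i0:i1], self.fs, self.t0 + i0 / self.fs)


def write_trace(path: str | Path | io.TextIOBase, trace: SignalTrace) -> None:
    """Write a trace as ``# fs=<Hz>`` header plus one sample per row."""
    lines = [f"# fs={trace.fs!r}\n"]
    lines += [f"{v:.17g}\n" for v in trace.samples]
    if hasattr(path, "write"):
        path.write("".join(lines))
    else:
        Path(path).write_text("".join(lines))


def read_trace(path: str | Path | io.TextIOBase) -> SignalTrace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    TraceParseError
        On a missing ``# fs=`` header or a non-numeric sample row; the error
        carries the offending line number.
    InvalidTraceError
        If the data section is empty.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    lines = text.splitlines()
    fs = None
    samples: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("fs="):
                try:
                    fs = float(body[3:])
                except ValueError:
                    raise TraceParseError(
                        f"malformed sample-rate header {line!r}", lineno
                    ) from None
            continue
        if fs is None:
            raise TraceParseError(
                "data encountered before '# fs=<Hz>' header", lineno
            )
        try:
            samples.append(float(line))
        except ValueError:
            raise TraceParseError(
                f"non-numeric sample row {line!r}", lineno
            ) from None
    if fs is None:
        raise TraceParseError("missing '# fs=<Hz>' header")
    if not samples:
        raise InvalidTraceError("trace file contains no samples")
    return SignalTrace(np.asarray(samples), fs)
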