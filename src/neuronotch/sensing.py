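"""Electrode/tissue sensing geometry: common- vs differential-mode split.

During stimulation most of the artefact reaches the two recording contacts
identically (common mode) and is rejected by the front-end's CMRR; because
the contact surface areas differ, a fraction ``α`` of the artefact appears
differentially and can only be removed by the notch filter downstream.

:func:`sense` composes the electrode signals::

    v_cm   = κ_cm·artefact + (dc_pos + dc_neg)/2
    v_diff = lfp + α·κ_cm·artefact + (dc_pos − dc_neg) + drift
    input  = v_diff + v_cm·10^(−CMRR/20)

``drift`` models stimulation-induced electrode polarization: monophasic
pulses deposit net charge, so a differential offset accumulates in
proportion to the time-integral of the differentially sensed artefact,
scaled by the contacts' DC-offset asymmetry. It vanishes when stimulation
is off, when sensing is perfectly symmetric (α = 0) or when the DC offsets
are zero. This is the mechanism behind the bandwidth-dependent error floor
seen in stimulated recordings: a near-DC residue that passes the AC
coupling as a small constant once the integrator settles.

Presets: unipolar sensing (symmetric about the stimulation contact) has a
small differential fraction (α = 0.02); bipolar sensing is asymmetric
(α = 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import IncompatibleTraceError, InvalidSpecificationError
from .trace import SignalTrace

__all__ = ["SensingSpec", "ElectrodeSignals", "sense",
           "UNIPOLAR_SENSING", "BIPOLAR_SENSING"]


@dataclass(frozen=True)
class SensingSpec:
    """Electrode coupling model.

    Parameters
    ----------
    common_mode_coupling : float
        κ_cm, unitless attenuation from stimulator output to the electrode
        common mode (default 3.3e-3: a 3 V stimulus appears as ~10 mV of
        common-mode artefact at the contacts).
    asymmetry : float
        α ∈ [0, 1], fraction of the artefact appearing differentially.
    dc_offset_pos, dc_offset_neg : float
        Static electrode polarization voltages (volt, tens-of-mV scale).
    cmrr_db : float
        Common-mode rejection ratio of the front-end (dB); ``inf`` disables
        the leakage path entirely.
    polarization_rate : float
        Rate constant (1/(V·s)) of stimulation-induced differential
        polarization drift; the drift term is
        ``rate · (dc_pos − dc_neg) · ∫α·κ_cm·artefact dt``. Zero offsets,
        symmetric sensing (α = 0) or no stimulation give zero drift.
    """

    common_mode_coupling: float = 3.3e-3
    asymmetry: float = 0.02
    dc_offset_pos: float = 0.030
    dc_offset_neg: float = 0.025
    cmrr_db: float = 130.0
    polarization_rate: float = 15.0

    def __post_init__(self):
        if not (0 <= self.asymmetry <= 1):
            raise InvalidSpecificationError("asymmetry must lie in [0, 1]")
        if self.common_mode_coupling < 0:
            raise InvalidSpecificationError("common_mode_coupling must be >= 0")

    @property
    def cmrr_leak(self) -> float:
        """Linear common-mode-to-differential leakage factor."""
        if np.isinf(self.cmrr_db):
            return 0.0
        return 10 ** (-self.cmrr_db / 20)

    def without_offsets(self) -> "SensingSpec":
        """Copy with DC offsets (and hence polarization drift) zeroed."""
        return replace(self, dc_offset_pos=0.0, dc_offset_neg=0.0)


#: Symmetric sensing about the stimulation contact: mostly common-mode.
UNIPOLAR_SENSING = SensingSpec(asymmetry=0.02)
#: Asymmetric sensing next to a bipolar pair: more differential artefact.
BIPOLAR_SENSING = SensingSpec(asymmetry=0.2)


@dataclass(frozen=True)
class ElectrodeSignals:
    """Per-input electrode voltages and their mode decomposition."""

    v_pos: SignalTrace
    v_neg: SignalTrace
    v_diff: SignalTrace
    v_cm: SignalTrace

    def effective_input(self, cmrr_db: float) -> SignalTrace:
        """Differential voltage the front-end effectively amplifies."""
        leak = 0.0 if np.isinf(cmrr_db) else 10 ** (-cmrr_db / 20)
        return self.v_diff + leak * self.v_cm


def sense(lfp: SignalTrace, artefact: SignalTrace,
          spec: SensingSpec = SensingSpec()) -> ElectrodeSignals:
    """Couple an LFP and a stimulation artefact onto the electrode pair."""
    if lfp.fs != artefact.fs or len(lfp) != len(artefact):
        raise IncompatibleTraceError(
            "lfp and artefact traces must share sample rate and length"
        )
    kappa = spec.common_mode_coupling
    cm_art = kappa * artefact.samples
    drift = (
        spec.polarization_rate
        * (spec.dc_offset_pos - spec.dc_offset_neg)
        * spec.asymmetry
        * np.cumsum(cm_art) / lfp.fs
    )
    v_cm = cm_art + 0.5 * (spec.dc_offset_pos + spec.dc_offset_neg)
    v_diff = (
        lfp.samples
        + spec.asymmetry * cm_art
        + (spec.dc_offset_pos - spec.dc_offset_neg)
        + drift
    )
    v_pos = v_cm + v_diff / 2
    v_neg = v_cm - v_diff / 2
    mk = lambda s: SignalTrace(s, lfp.fs, lfp.t0)
    return ElectrodeSignals(
        v_pos=mk(v_pos), v_neg=mk(v_neg), v_diff=mk(v_diff), v_cm=mk(v_cm)
    )
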