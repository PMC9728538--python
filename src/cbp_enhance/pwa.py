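"""Pulse-wave-analysis derivations.

Pure functions implementing the hemodynamic indices reported alongside
brachial-cuff central blood pressure estimates:

* estimated SBP amplification — brachial cuff SBP minus the Type I
  calibrated central SBP (C1SBP), a proxy for peripheral pulse-pressure
  amplification;
* augmentation index (AIx@75) — the augmented share of aortic pulse
  pressure, ``100 * (PP - P1) / PP`` where ``P1`` is the incident
  (forward) pressure-wave height.  The heart-rate normalisation to
  75 bpm is applied inside the measuring device, upstream of this
  formula, so the function simply evaluates the printed expression on
  device-reported components while the name keeps the conventional
  "at 75 bpm" label;
* reflection magnitude — backward over forward wave-component ratio.
  Stored on the x100 (percent) scale throughout the package, matching
  the magnitude on which cohort summaries report it (e.g. 66.9 +/- 9.1).

No I/O, no state.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "WaveformComponents",
    "estimated_amplification",
    "aix75",
    "reflection_magnitude",
]


@dataclass(frozen=True)
class WaveformComponents:
    """Decomposition of an aortic pressure waveform (all mmHg).

    ``incident_wave_height`` (P1) is the pressure rise up to the arrival
    of the reflected wave; ``forward_component`` / ``backward_component``
    are the separated travelling-wave amplitudes.
    """

    pulse_pressure: float
    incident_wave_height: float
    forward_component: float
    backward_component: float

    def __post_init__(self) -> None:
        if self.pulse_pressure <= 0:
            raise ValueError(f"pulse_pressure must be > 0, got {self.pulse_pressure}")
        if self.forward_component <= 0:
            raise ValueError(
                f"forward_component must be > 0, got {self.forward_component}"
            )
        if not (0 <= self.incident_wave_height <= self.pulse_pressure):
            raise ValueError(
                "incident_wave_height must lie in [0, pulse_pressure], got "
                f"{self.incident_wave_height} with PP={self.pulse_pressure}"
            )


def estimated_amplification(brachial_sbp: float, c1sbp: float) -> float:
    """Estimated SBP amplification: brachial cuff SBP − C1SBP (mmHg).

    May be negative (central estimate above the cuff value); no clamping.

    Raises
    ------
    ValueError
        If either pressure is non-positive.
    """
    if brachial_sbp <= 0 or c1sbp <= 0:
        raise ValueError(
            f"pressures must be > 0, got brachial_sbp={brachial_sbp}, c1sbp={c1sbp}"
        )
    return brachial_sbp - c1sbp


def aix75(w: WaveformComponents) -> float:
    """Augmentation index at 75 bpm (%): ``100 * (PP - P1) / PP``.

    Values lie in (−∞, 100]; 0 means no augmentation (the incident wave
    accounts for the whole pulse pressure).
    """
    if w.pulse_pressure == 0:
        raise ValueError("pulse_pressure must be nonzero")
    return 100.0 * (w.pulse_pressure - w.incident_wave_height) / w.pulse_pressure


def reflection_magnitude(w: WaveformComponents) -> float:
    """Reflection magnitude on the x100 scale: ``100 * backward / forward``."""
    if w.forward_component == 0:
        raise ValueError("forward_component must be nonzero")
    return 100.0 * w.backward_component / w.forward_component
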