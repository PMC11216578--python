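"""Looming-stimulus geometry and schedules.

The standard threat stimulus is a dark disc on a grey background that expands
at 80 deg/s of visual angle for 500 ms (reaching 40 deg), holds for 250 ms,
and repeats 5 times back to back, giving a 3.75 s bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LoomSchedule", "loom_diameter", "loom_contrast"]


@dataclass(frozen=True)
class LoomSchedule:
    """Timing of a looming bout.

    Parameters are visual-angle expansion speed (deg/s), expansion duration
    (s), hold duration (s) and the number of consecutive looms in a bout.
    """

    expansion_speed: float = 80.0
    expansion_s: float = 0.5
    hold_s: float = 0.25
    n_looms: int = 5
    start_diameter: float = 0.0

    def __post_init__(self) -> None:
        if self.expansion_speed <= 0 or self.expansion_s <= 0 or self.hold_s < 0:
            raise ValueError("loom schedule parameters must be positive")
        if not 1 <= self.n_looms:
            raise ValueError("n_looms must be >= 1")

    @property
    def loom_s(self) -> float:
        """Duration of a single loom (expansion + hold)."""
        return self.expansion_s + self.hold_s

    @property
    def bout_s(self) -> float:
        """Duration of the whole bout."""
        return self.n_looms * self.loom_s

    @property
    def max_diameter(self) -> float:
        """Final disc diameter in degrees of visual angle."""
        return self.start_diameter + self.expansion_speed * self.expansion_s

    def loom_onsets(self, t0: float = 0.0) -> np.ndarray:
        """Onset time of each loom in the bout, relative to ``t0``."""
        return t0 + np.arange(self.n_looms) * self.loom_s


def loom_diameter(t, schedule: LoomSchedule | None = None) -> np.ndarray:
    """Disc diameter (deg) at time ``t`` (s) from bout onset.

    Outside the bout the diameter is 0 (no disc shown).
    """
    schedule = schedule or LoomSchedule()
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, schedule.loom_s)
    within = (t >= 0) & (t < schedule.bout_s)
    d = schedule.start_diameter + schedule.expansion_speed * np.minimum(
        phase, schedule.expansion_s
    )
    return np.where(within, d, 0.0)


def loom_contrast(background: float, disc: float) -> float:
    """Weber contrast of the disc against the background, in percent.

    Low-contrast stimuli are generated by raising the disc luminance towards
    the (fixed) background.
    """
    if background <= 0:
        raise ValueError("background luminance must be positive")
    return (background - disc) / background * 100.0
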