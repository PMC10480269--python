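"""Platform / chest-wall motion models.

The measurement target is a vertically oscillating surface (a mechanical
platform standing in for the chest wall).  Its displacement is modelled as

    b(t) = b_max * sin(2*pi*f*t + phase)

with ``b_max`` half the peak-to-peak travel.  A triangle waveform with the
same period and range is provided as well, because a constant-speed stepper
stage actually produces constant-velocity travel between its two stops.

The module also embeds the 35-condition benchmark grid of pre-set platform
frequencies (7 motor speeds x 5 displacements) used throughout the package
as ground truth, together with the 0.1-1 Hz normal-respiration band that
partitions it into 28 normal and 7 abnormal (pathological-rate) conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import sawtooth

__all__ = [
    "MotionSpec",
    "GridCondition",
    "NORMAL_RATE_BAND",
    "displacement_series",
    "platform_grid",
    "nominal_frequency",
    "write_grid",
    "read_grid",
]

#: Normal respiration band in Hz (6-60 breaths/min), inclusive at both ends.
NORMAL_RATE_BAND: tuple[float, float] = (0.1, 1.0)

_TWO_PI = 2.0 * math.pi


@dataclass
class MotionSpec:
    """One oscillation condition to be simulated and measured.

    Parameters
    ----------
    frequency : float
        Oscillation frequency in Hz.
    displacement : float
        Peak-to-peak vertical travel in cm; the sine amplitude is half this.
    waveform : {"sine", "triangle"}
        Shape of the displacement cycle.  Triangle is a constant-speed
        zig-zag with the same period and peak-to-peak range.
    phase : float
        Phase offset in radians, normalised into [0, 2*pi).
    duration : float
        Record length in seconds.
    label : str
        Free-text tag carried into provenance.
    """

    frequency: float
    displacement: float
    waveform: str = "sine"
    phase: float = 0.0
    duration: float = 60.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.displacement <= 0:
            raise ValueError(f"displacement must be > 0, got {self.displacement}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.waveform not in ("sine", "triangle"):
            raise ValueError(f"waveform must be 'sine' or 'triangle', got {self.waveform!r}")
        self.phase = float(self.phase) % _TWO_PI

    @property
    def amplitude(self) -> float:
        """Half the peak-to-peak travel (cm)."""
        return self.displacement / 2.0


@dataclass(frozen=True)
class GridCondition:
    """One cell of the benchmark grid: motor speed x displacement step."""

    rpm: int
    step: float  # displacement, cm
    frequency: float  # Hz, embedded ground-truth value
    is_abnormal: bool


def displacement_series(
    spec: MotionSpec, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the displacement waveform.

    Returns ``(time_axis, values)``: ``floor(duration * sample_rate)``
    uniformly spaced samples starting at t = 0, displacement in cm.

    Raises
    ------
    ValueError
        If ``sample_rate`` does not exceed twice the motion frequency
        (Nyquist violation).
    """
    if sample_rate <= 2.0 * spec.frequency:
        raise ValueError(
            f"sample rate {sample_rate} Hz violates the Nyquist criterion for "
            f"motion frequency {spec.frequency} Hz (need > {2.0 * spec.frequency} Hz)"
        )
    n = int(math.floor(spec.duration * sample_rate))
    t = np.arange(n) / sample_rate
    theta = _TWO_PI * spec.frequency * t + spec.phase
    if spec.waveform == "sine":
        values = spec.amplitude * np.sin(theta)
    else:
        # triangle matched to the sine phase convention: 0 at theta=0, rising
        values = spec.amplitude * sawtooth(theta + math.pi / 2.0, width=0.5)
    return t, values


# The 35 pre-set platform frequencies (Hz), keyed by (rpm, step_cm).  These
# are embedded measured/benchmark constants, not recomputed from kinematics.
_GRID_FREQUENCIES: dict[tuple[int, int], float] = {
    (10, 1): 0.333, (10, 2): 0.1655, (10, 3): 0.1101, (10, 4): 0.07683, (10, 5): 0.06993,
    (20, 1): 0.6666, (20, 2): 0.3291, (20, 3): 0.2196, (20, 4): 0.1703, (20, 5): 0.1396,
    (30, 1): 0.9876, (30, 2): 0.4828, (30, 3): 0.3381, (30, 4): 0.2491, (30, 5): 0.2115,
    (40, 1): 1.31, (40, 2): 0.6474, (40, 3): 0.4348, (40, 4): 0.3318, (40, 5): 0.279,
    (50, 1): 1.6, (50, 2): 0.8046, (50, 3): 0.5673, (50, 4): 0.4094, (50, 5): 0.3322,
    (60, 1): 1.861, (60, 2): 0.9584, (60, 3): 0.6931, (60, 4): 0.4971, (60, 5): 0.4094,
    (70, 1): 2.286, (70, 2): 1.111, (70, 3): 0.793, (70, 4): 0.5785, (70, 5): 0.4633,
}


def platform_grid() -> list[GridCondition]:
    """The full 35-condition benchmark grid (7 RPM values x 5 steps).

    A condition is flagged abnormal when its frequency falls outside the
    closed normal band ``NORMAL_RATE_BAND``; exactly 7 of the 35 are.
    """
    lo, hi = NORMAL_RATE_BAND
    return [
        GridCondition(rpm=rpm, step=float(step), frequency=f,
                      is_abnormal=not (lo <= f <= hi))
        for (rpm, step), f in sorted(_GRID_FREQUENCIES.items())
    ]


def nominal_frequency(rpm: float, step: float, lead: float = 4.0) -> float:
    """Idealised kinematic frequency of a screw-driven stage, in Hz.

    ``rpm * lead`` is the linear speed (cm/min); one oscillation covers the
    up-and-down travel ``2 * step``, so f = rpm * lead / (60 * 2 * step).
    This is a convenience approximation only -- the embedded grid values are
    the authoritative ground truth and deviate from this formula in some
    cells (the real stage's ramp profile is not a single lead constant).
    """
    if rpm <= 0 or step <= 0 or lead <= 0:
        raise ValueError(
            f"rpm, step and lead must all be > 0, got rpm={rpm}, step={step}, lead={lead}"
        )
    return rpm * lead / (60.0 * 2.0 * step)


def write_grid(path) -> None:
    """Export the benchmark grid as a tab-delimited table with header."""
    df = pd.DataFrame(
        [
            {"rpm": c.rpm, "step_cm": c.step, "frequency_hz": c.frequency,
             "is_abnormal": c.is_abnormal}
            for c in platform_grid()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_grid(path) -> list[GridCondition]:
    """Read a grid table written by :func:`write_grid`."""
    df = pd.read_csv(path, sep="\t")
    required = {"rpm", "step_cm", "frequency_hz", "is_abnormal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grid table missing columns: {sorted(missing)}")
    return [
        GridCondition(rpm=int(r.rpm), step=float(r.step_cm),
                      frequency=float(r.frequency_hz), is_abnormal=bool(r.is_abnormal))
        for r in df.itertuples()
    ]
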