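"""Scoring, classification and the benchmark grid experiment.

Accuracy is scored by the absolute percent uncertainty

    U(%) = 100 * |estimated - true| / true

and clinical relevance by classifying each recovered rate against the
0.1-1 Hz (6-60 bpm) normal-respiration band; rates outside that band are
the abnormal (alarmed, positive) class.  ``run_grid`` reproduces the full
benchmark experiment: every one of the 35 platform conditions simulated
and recovered ``repeats`` times under a noise model, scored, classified,
and aggregated per displacement and overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import NoiseModel, SpectrometerConfig, simulate_acquisition
from .card_optics import LaserSpot
from .motion import NORMAL_RATE_BAND, MotionSpec, platform_grid
from .pipeline import recover

__all__ = [
    "UncertaintyResult",
    "ConfusionMetrics",
    "GridReport",
    "absolute_uncertainty",
    "classify_rate",
    "confusion_metrics",
    "run_grid",
]

NORMAL = "normal"
ABNORMAL = "abnormal"


@dataclass(frozen=True)
class UncertaintyResult:
    estimated: float  # Hz
    true_value: float  # Hz
    absolute_uncertainty_percent: float


def absolute_uncertainty(estimated: float, true_value: float) -> float:
    """Absolute percent uncertainty: 100 * |estimated - true| / true."""
    if true_value <= 0:
        raise ValueError(f"true_value must be > 0, got {true_value}")
    return 100.0 * abs(estimated - true_value) / true_value


def classify_rate(
    frequency: float, normal_band: tuple[float, float] = NORMAL_RATE_BAND
) -> str:
    """'normal' iff the rate lies inside the closed normal band, else 'abnormal'."""
    lo, hi = normal_band
    if lo >= hi:
        raise ValueError(f"normal_band must satisfy low < high, got {normal_band}")
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    return NORMAL if lo <= frequency <= hi else ABNORMAL


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary diagnostic summary with abnormal as the positive class.

    Ratios with a zero denominator are reported as NaN, never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def positive_predictivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)


def confusion_metrics(predicted, truth) -> ConfusionMetrics:
    """Tally a binary confusion matrix from 'normal'/'abnormal' label lists."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"label lists differ in length: {len(predicted)} vs {len(truth)}"
        )
    valid = {NORMAL, ABNORMAL}
    if not set(predicted) <= valid or not set(truth) <= valid:
        raise ValueError(f"labels must be {sorted(valid)}")
    tp = sum(p == ABNORMAL and t == ABNORMAL for p, t in zip(predicted, truth))
    fp = sum(p == ABNORMAL and t == NORMAL for p, t in zip(predicted, truth))
    tn = sum(p == NORMAL and t == NORMAL for p, t in zip(predicted, truth))
    fn = sum(p == NORMAL and t == ABNORMAL for p, t in zip(predicted, truth))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class GridReport:
    """Results of the full grid experiment."""

    table: pd.DataFrame  # one row per condition x repeat
    per_displacement: pd.DataFrame  # mean/sd uncertainty per step
    overall_mean_uncertainty: float  # percent
    confusion: ConfusionMetrics
    seed: int
    repeats: int

    def summary_frame(self) -> pd.DataFrame:
        c = self.confusion
        rows = [
            {"metric": "overall_mean_uncertainty_pct", "value": self.overall_mean_uncertainty},
            {"metric": "n_recordings", "value": len(self.table)},
            {"metric": "sensitivity", "value": c.sensitivity},
            {"metric": "specificity", "value": c.specificity},
            {"metric": "positive_predictivity", "value": c.positive_predictivity},
            {"metric": "accuracy", "value": c.accuracy},
            {"metric": "tp", "value": c.tp},
            {"metric": "fp", "value": c.fp},
            {"metric": "tn", "value": c.tn},
            {"metric": "fn", "value": c.fn},
        ]
        return pd.DataFrame(rows)

    def write(self, directory) -> None:
        """Write grid_report.tsv (per-recording rows) and summary.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "grid_report.tsv", sep="\t", index=False)
        summary = pd.concat(
            [
                self.summary_frame(),
                self.per_displacement.rename(
                    columns={"step_cm": "metric"}
                ).assign(metric=lambda d: "mean_uncertainty_pct_step_" + d.metric.astype(str))[
                    ["metric", "mean_uncertainty_pct"]
                ].rename(columns={"mean_uncertainty_pct": "value"}),
            ],
            ignore_index=True,
        )
        summary.to_csv(directory / "summary.tsv", sep="\t", index=False)


def run_grid(
    repeats: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
    duration: float = 60.0,
    cfg: SpectrometerConfig | None = None,
    spot: LaserSpot | None = None,
    randomize_phase: bool = True,
) -> GridReport:
    """Simulate and recover every grid condition ``repeats`` times.

    ``noise=None`` uses the default calibrated noise preset; pass
    ``NoiseModel.zero()`` for a noiseless (deterministic) run.  All
    randomness -- per-recording noise seeds and, when ``randomize_phase``,
    the motion phase of each recording -- derives from ``seed``, so the
    whole report is reproducible.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    noise = noise if noise is not None else NoiseModel()
    master = np.random.default_rng(seed)
    rows = []
    for cond in platform_grid():
        for rep in range(repeats):
            run_seed = int(master.integers(2**31))
            phase = float(master.uniform(0.0, 2.0 * math.pi)) if randomize_phase else 0.0
            spec = MotionSpec(
                frequency=cond.frequency,
                displacement=cond.step,
                phase=phase,
                duration=duration,
                label=f"rpm{cond.rpm}_step{cond.step:g}",
            )
            run_noise = None if noise.is_zero else replace(noise, seed=run_seed)
            spectra = simulate_acquisition(spec, spot=spot, cfg=cfg, noise=run_noise)
            est = recover(spectra)
            rows.append(
                {
                    "rpm": cond.rpm,
                    "step_cm": cond.step,
                    "repeat": rep,
                    "true_hz": cond.frequency,
                    "estimated_hz": est.frequency,
                    "estimated_bpm": est.bpm,
                    "uncertainty_pct": absolute_uncertainty(est.frequency, cond.frequency),
                    "true_label": ABNORMAL if cond.is_abnormal else NORMAL,
                    "predicted_label": classify_rate(est.frequency),
                    "phase_rad": phase,
                    "noise_seed": run_seed,
                }
            )
    table = pd.DataFrame(rows)
    per_disp = (
        table.groupby("step_cm")["uncertainty_pct"]
        .agg(mean_uncertainty_pct="mean", sd_uncertainty_pct="std", n="count")
        .reset_index()
    )
    confusion = confusion_metrics(table.predicted_label, table.true_label)
    return GridReport(
        table=table,
        per_displacement=per_disp,
        overall_mean_uncertainty=float(table.uncertainty_pct.mean()),
        confusion=confusion,
        seed=seed,
        repeats=repeats,
    )
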