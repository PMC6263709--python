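"""MET referencing against a measured resting metabolic rate.

Energy expenditure is expressed in METs relative to each participant's own
resting metabolic rate (RMR), not the 3.5 mL O2/min/kg population standard:
RMR is the median calorimeter output during the second five minutes of supine
lying, and each task's MET is the median energy expenditure over the final two
minutes of the task divided by the RMR.  A minute is *inactive* (sedentary
when sitting) iff MET <= 1.5.

All internal computation is in kcal/min; a day-level report multiplies by
1440.  Windows are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CalorimeterTrace

#: The sedentary-behavior energy threshold in METs; the boundary itself
#: counts as inactive.
MET_THRESHOLD = 1.5

CATEGORY_INACTIVE = "inactive"
CATEGORY_ACTIVE = "active"


@dataclass(frozen=True)
class RMREstimate:
    """Resting metabolic rate in kcal/min with its source window (seconds)."""

    value: float
    window: tuple[float, float]

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError("RMR must be > 0")

    @property
    def kcal_per_day(self) -> float:
        return self.value * 1440.0


@dataclass(frozen=True)
class METLabel:
    met: float
    category: str

    def __post_init__(self):
        if self.met < 0:
            raise ValueError("MET must be >= 0")
        expected = met_category(self.met)
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with met={self.met} "
                f"(threshold {MET_THRESHOLD})"
            )


def met_category(met: float) -> str:
    """Binary activity category: inactive iff met <= 1.5."""
    return CATEGORY_INACTIVE if met <= MET_THRESHOLD else CATEGORY_ACTIVE


def compute_rmr(lying_trace: CalorimeterTrace) -> RMREstimate:
    """RMR = median energy expenditure during the second five minutes lying.

    The first five minutes are discarded as a settling period.  Requires a
    lying block of at least 10 minutes.
    """
    if lying_trace.duration < 600 - 1e-9:
        raise ValueError(
            f"lying trace must cover >= 10 min, got {lying_trace.duration:.0f} s"
        )
    rate = lying_trace.sample_rate
    i0 = int(round(300 * rate))
    i1 = int(round(600 * rate))
    window = lying_trace.values[i0:i1]
    return RMREstimate(value=float(np.median(window)), window=(300.0, 600.0))


def task_met(trace: CalorimeterTrace, task_window: tuple[float, float],
             rmr: RMREstimate | float) -> METLabel:
    """One MET value per task: median EE over the final two minutes / RMR.

    ``task_window`` is (start, end) in seconds on the trace's time axis; the
    window must span at least two minutes.
    """
    start, end = task_window
    if end - start < 120 - 1e-9:
        raise ValueError("task window must span >= 2 min")
    rmr_value = rmr.value if isinstance(rmr, RMREstimate) else float(rmr)
    if rmr_value <= 0:
        raise ValueError("RMR must be > 0")
    rate = trace.sample_rate
    i0 = int(round((end - 120 - trace.start_time) * rate))
    i1 = int(round((end - trace.start_time) * rate))
    if i0 < 0 or i1 > trace.n_samples:
        raise ValueError("final-two-minutes window outside the recorded trace")
    met = float(np.median(trace.values[i0:i1]) / rmr_value)
    return METLabel(met=met, category=met_category(met))


def standard_met_inflation(measured_vo2_rel: float, standard_vo2_rel: float = 3.5) -> int:
    """Percent by which MET referenced to the population-standard resting
    oxygen uptake would exceed MET referenced to the measured one.

    Both arguments are resting oxygen consumption in mL/min/kg; returns
    100 * (measured - standard) / standard rounded to the nearest integer
    percent.
    """
    if measured_vo2_rel <= 0 or standard_vo2_rel <= 0:
        raise ValueError("oxygen consumption values must be > 0")
    return round(100.0 * (measured_vo2_rel - standard_vo2_rel) / standard_vo2_rel)
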