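"""Growth labelling from longitudinal tumour volumes.

Vestibular schwannoma volume measurements carry a measurement error that is
relatively larger for small tumours, so a significant volume change is
defined against a patient-specific, volume-dependent threshold (the upper
limit of agreement with the mean, LOAM, of repeated volumetry), which spans
roughly 5%-30% relative change over the clinical volume range.  A tumour is
labelled *growing* (or *shrinking*) when its relative change versus the
volume at diagnosis exceeds +threshold (falls below -threshold) on at least
two consecutive follow-up scans, and *stable* otherwise.  The binary
prediction target is growth vs nongrowth (stable or shrinking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthThresholdModel", "CourseLabel", "loam_threshold",
           "classify_course"]

GROWING, STABLE, SHRINKING, UNDETERMINED = ("growing", "stable", "shrinking",
                                            "undetermined")


@dataclass(frozen=True)
class GrowthThresholdModel:
    """Volume-dependent relative-change threshold theta(V).

    ``theta(V) = clamp(a * V**-b, floor, ceiling)`` with V in cm3.  The
    exact published LOAM formula is intentionally not reproduced here; the
    model is injectable and the default power law is anchored so that the
    threshold reaches the ceiling (30%) near 0.2 cm3 and the floor (5%)
    near 2.3 cm3, the interquartile endpoints of the reference cohort.
    """

    coefficient: float
    exponent: float
    floor: float = 0.05
    ceiling: float = 0.30

    def __post_init__(self) -> None:
        if self.coefficient <= 0 or self.exponent < 0:
            raise ValueError("power-law parameters must be positive")
        if not 0 < self.floor <= self.ceiling < 1:
            raise ValueError("require 0 < floor <= ceiling < 1")

    @classmethod
    def from_anchor_points(cls, low=(0.2, 0.30), high=(2.3, 0.05),
                           floor=0.05, ceiling=0.30) -> "GrowthThresholdModel":
        """Fit (a, b) through two (volume, threshold) anchor points."""
        (v1, t1), (v2, t2) = low, high
        b = np.log(t1 / t2) / np.log(v2 / v1)
        a = t1 * v1**b
        return cls(coefficient=float(a), exponent=float(b),
                   floor=floor, ceiling=ceiling)

    def threshold(self, baseline_volume_cm3: float) -> float:
        return loam_threshold(baseline_volume_cm3, self)


DEFAULT_THRESHOLD_MODEL = GrowthThresholdModel.from_anchor_points()


def loam_threshold(baseline_volume_cm3, model: GrowthThresholdModel = None):
    """Patient-specific relative volumetric-change threshold (fraction).

    Monotonically non-increasing in baseline volume and clamped to
    [floor, ceiling].
    """
    if model is None:
        model = DEFAULT_THRESHOLD_MODEL
    v = np.asarray(baseline_volume_cm3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("baseline volume must be positive")
    theta = model.coefficient * v ** (-model.exponent)
    theta = np.clip(theta, model.floor, model.ceiling)
    return float(theta) if np.isscalar(baseline_volume_cm3) else theta


@dataclass(frozen=True)
class CourseLabel:
    """Three-way course label with its binary growth/nongrowth collapse."""

    value: str
    conflict: bool = False  # both growth and shrinkage patterns observed

    def __post_init__(self) -> None:
        if self.value not in (GROWING, STABLE, SHRINKING, UNDETERMINED):
            raise ValueError(f"unknown course label {self.value!r}")

    @property
    def binarized(self) -> str | None:
        if self.value == UNDETERMINED:
            return None
        return "growth" if self.value == GROWING else "nongrowth"

    @property
    def is_growth(self) -> bool:
        return self.value == GROWING


def classify_course(baseline_volume_cm3, followups,
                    model: GrowthThresholdModel = None) -> CourseLabel:
    """Label a volume trajectory as growing / stable / shrinking.

    ``followups`` is a sequence of (months, volume_cm3) pairs.  Relative
    change is always evaluated against the volume at diagnosis.  Growing
    requires exceedance of +theta on >= 2 consecutive scans (shrinking
    symmetrically below -theta); anything else is stable.  If both patterns
    occur, growth takes precedence and the label is flagged.  Fewer than
    two follow-ups yield the distinct ``undetermined`` label.
    """
    if baseline_volume_cm3 <= 0:
        raise ValueError("baseline volume must be positive")
    followups = sorted(followups, key=lambda mv: mv[0])
    if len(followups) < 2:
        return CourseLabel(UNDETERMINED)
    theta = loam_threshold(baseline_volume_cm3, model)
    rel = np.array([(v - baseline_volume_cm3) / baseline_volume_cm3
                    for _, v in followups])
    above = rel > theta
    below = rel < -theta
    grew = bool(np.any(above[:-1] & above[1:]))
    shrank = bool(np.any(below[:-1] & below[1:]))
    if grew:
        return CourseLabel(GROWING, conflict=shrank)
    if shrank:
        return CourseLabel(SHRINKING)
    return CourseLabel(STABLE)
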