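"""Linear detector calibration and external-standard quantification.

Peak area is modelled as an affine function of injected mass,
``A = k·m + b`` (ordinary least squares with a free intercept; published
curves for this assay all carry intercepts).  The reported ``r`` is the
Pearson correlation of (mass, area), the conventional linearity metric
for single-predictor calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from qams.errors import CurveError, DegenerateDesignError

__all__ = ["CalibrationCurve", "fit_calibration", "esm_mass", "check_linearity"]

#: Published linearity acceptance: every curve reached at least this r.
DEFAULT_R_THRESHOLD = 0.9996


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-component linear response ``area = slope·mass + intercept``.

    ``linear_range`` is the (min, max) injected mass in µg over which the
    curve was established; quantification outside it is flagged, not
    rejected.
    """

    component_code: str
    system_id: str
    slope: float
    intercept: float
    r: float
    linear_range: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError(f"calibration needs >= 3 points, got {self.n_points}")
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"linear range must satisfy min < max, got {self.linear_range}")

    def predict(self, mass: float) -> float:
        """Forward response: expected area for an injected mass (µg)."""
        return self.slope * mass + self.intercept

    def in_range(self, mass: float) -> bool:
        lo, hi = self.linear_range
        return lo <= mass <= hi

    def to_dict(self) -> dict:
        return {
            "component_code": self.component_code,
            "system_id": self.system_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "linear_range": list(self.linear_range),
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            component_code=d["component_code"],
            system_id=d["system_id"],
            slope=d["slope"],
            intercept=d["intercept"],
            r=d["r"],
            linear_range=tuple(d["linear_range"]),
            n_points=d["n_points"],
        )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    component_code: str = "",
    system_id: str = "",
) -> CalibrationCurve:
    """Fit ``area = k·mass + b`` by ordinary least squares.

    Parameters
    ----------
    points
        (injected mass µg, peak area) pairs; at least 3 points on at
        least 2 distinct masses.

    Raises
    ------
    DegenerateDesignError
        If all masses are identical (slope unidentifiable).
    """
    if len(points) < 3:
        raise DegenerateDesignError(f"need >= 3 calibration points, got {len(points)}")
    mass = np.asarray([p[0] for p in points], dtype=float)
    area = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(mass) == 0:
        raise DegenerateDesignError("all calibration masses identical; slope unidentifiable")
    res = stats.linregress(mass, area)
    return CalibrationCurve(
        component_code=component_code,
        system_id=system_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        linear_range=(float(mass.min()), float(mass.max())),
        n_points=len(points),
    )


def esm_mass(curve: CalibrationCurve, area: float) -> tuple[float, bool]:
    """Invert a calibration curve: injected mass (µg) for a peak area.

    Returns ``(mass, in_range)``.  Masses outside the curve's linear
    range — including negative masses when the area falls below the
    intercept — are returned as computed with ``in_range=False`` rather
    than rejected, so near-detection-limit results stay visible.
    """
    if not curve.slope > 0:
        raise CurveError(f"curve for {curve.component_code} has non-positive slope")
    mass = (area - curve.intercept) / curve.slope
    return mass, curve.in_range(mass)


def check_linearity(curve: CalibrationCurve, r_threshold: float = DEFAULT_R_THRESHOLD) -> bool:
    """Linearity gate: pass iff the curve's correlation reaches the threshold."""
    return curve.r >= r_threshold
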