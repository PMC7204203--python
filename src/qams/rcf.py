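"""Relative correction factors (RCFs) between analytes and the internal reference.

The RCF ``f_{s/i}`` relates the detector response per unit mass of
analyte *i* to that of the internal reference *s*.  Two estimators are
supported:

* **multipoint** — from paired standard injections at one level,
  ``f_{s/i} = (m_s·A_i)/(m_i·A_s)``, averaged over levels;
* **slope** — from the calibration slopes, ``f_{s/i} = k_i/k_s``,
  which discards the intercepts (treated as systematic error).

Under a purely proportional response (``A = k·m``) the two coincide at
every level; with non-zero intercepts the multipoint values drift with
level, which is exactly what their per-level dispersion reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from qams.errors import PanelError

__all__ = [
    "RCFSet",
    "multipoint_rcf",
    "aggregate_multipoint",
    "slope_rcf",
    "robustness_summary",
    "multipoint_rcf_from_series",
    "slope_rcf_set",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Report-display rounding: half-up (0.0005 -> 0.001), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RCFSet:
    """RCFs of every non-reference analyte under one condition.

    ``values`` maps analyte code → f_{s/i}; the internal reference is
    not listed (its factor is identically 1).  ``dispersion`` optionally
    carries per-analyte (mean, RSD %) when the factors were aggregated
    over several mass levels; ``condition`` labels the chromatographic
    condition (system / column / flow / temperature) the set belongs to.
    """

    internal_reference_code: str
    values: Mapping[str, float]
    method: str  # "multipoint" | "slope"
    condition: str = ""
    dispersion: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("multipoint", "slope"):
            raise ValueError(f"method must be 'multipoint' or 'slope', got {self.method!r}")
        if self.internal_reference_code in self.values:
            raise ValueError("internal reference must not appear among the analytes")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("relative correction factors must be positive")

    def factor(self, analyte_code: str) -> float:
        if analyte_code == self.internal_reference_code:
            return 1.0
        return self.values[analyte_code]


def multipoint_rcf(m_s: float, A_s: float, m_i: float, A_i: float) -> float:
    """RCF from one paired standard level: ``(m_s·A_i)/(m_i·A_s)``.

    ``m_s, A_s`` are the injected mass and peak area of the internal
    reference, ``m_i, A_i`` those of the analyte, from the same
    injection of the mixed working standard.
    """
    for name, v in (("m_s", m_s), ("A_s", A_s), ("m_i", m_i), ("A_i", A_i)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (m_s * A_i) / (m_i * A_s)


def aggregate_multipoint(f_values: Sequence[float]) -> tuple[float, float]:
    """Mean and RSD (%) of per-level multipoint RCFs.

    RSD uses the sample standard deviation (n−1 denominator), the
    analytical-chemistry convention.
    """
    if len(f_values) < 2:
        raise ValueError(f"need >= 2 per-level values to aggregate, got {len(f_values)}")
    arr = np.asarray(f_values, dtype=float)
    mean = float(arr.mean())
    return mean, float(100.0 * arr.std(ddof=1) / mean)


def slope_rcf(k_i: float, k_s: float) -> float:
    """RCF from calibration slopes: ``k_i / k_s``.

    ``k_s`` is the internal reference's slope, ``k_i`` the analyte's.
    """
    if not (k_i > 0 and k_s > 0):
        raise ValueError(f"slopes must be positive, got k_i={k_i}, k_s={k_s}")
    return k_i / k_s


def robustness_summary(rcf_sets: Sequence[RCFSet]) -> dict[str, float]:
    """Per-analyte RSD (%) of RCF values across conditions.

    The input sets must share the same analyte panel (one RCFSet per
    chromatographic condition); the result quantifies how durable each
    factor is when instrument, column, flow rate or temperature change.
    """
    if len(rcf_sets) < 2:
        raise ValueError(f"need >= 2 conditions, got {len(rcf_sets)}")
    panels = {tuple(sorted(s.values.keys())) for s in rcf_sets}
    if len(panels) != 1:
        raise PanelError(f"inconsistent analyte panels across conditions: {sorted(panels)}")
    refs = {s.internal_reference_code for s in rcf_sets}
    if len(refs) != 1:
        raise PanelError(f"inconsistent internal references across conditions: {sorted(refs)}")
    out = {}
    for code in sorted(panels.pop()):
        vals = np.asarray([s.values[code] for s in rcf_sets], dtype=float)
        out[code] = float(100.0 * vals.std(ddof=1) / vals.mean())
    return out


def multipoint_rcf_from_series(
    table,
    internal_reference_code: str,
    condition: str = "",
) -> RCFSet:
    """Per-level multipoint RCFs aggregated over a standard-series table.

    The table must hold standard records (``injected_mass`` set,
    ``component_code`` assigned) grouped by sample_id level, as produced
    by :func:`qams.synthetic.simulate_standard_series`.  Factors are
    computed level by level against the internal-reference record of the
    same level, then averaged.
    """
    levels: dict[str, dict[str, object]] = {}
    for rec in table:
        if rec.injected_mass is None or rec.component_code is None:
            raise ValueError("multipoint RCFs need assigned standard records with injected_mass set")
        levels.setdefault(rec.sample_id, {})[rec.component_code] = rec

    per_analyte: dict[str, list[float]] = {}
    for level_id, comps in sorted(levels.items()):
        if internal_reference_code not in comps:
            raise PanelError(f"level {level_id!r} lacks the internal reference {internal_reference_code}")
        ref = comps[internal_reference_code]
        for code, rec in comps.items():
            if code == internal_reference_code:
                continue
            per_analyte.setdefault(code, []).append(
                multipoint_rcf(ref.injected_mass, ref.area, rec.injected_mass, rec.area))

    dispersion = {code: aggregate_multipoint(vals) for code, vals in per_analyte.items()}
    return RCFSet(
        internal_reference_code=internal_reference_code,
        values={code: mean for code, (mean, _) in dispersion.items()},
        method="multipoint",
        condition=condition,
        dispersion=dispersion,
    )


def slope_rcf_set(
    curves: Mapping[str, "object"],
    internal_reference_code: str,
    condition: str = "",
) -> RCFSet:
    """Slope-method RCFSet from a mapping of component → CalibrationCurve."""
    k_s = curves[internal_reference_code].slope
    values = {
        code: slope_rcf(curve.slope, k_s)
        for code, curve in curves.items()
        if code != internal_reference_code
    }
    return RCFSet(
        internal_reference_code=internal_reference_code,
        values=values,
        method="slope",
        condition=condition,
    )
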