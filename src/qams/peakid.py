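"""Peak assignment by relative retention time (RRT).

With only the internal-reference standard on hand, analyte peaks are
located by their retention time *relative* to the reference peak:
``RRT_i = rt_i / rt_s``.  The ratio is invariant under uniform time
scaling (column length, flow), which is what makes it transferable
across chromatographic systems, unlike absolute retention or retention
differences.

The internal-reference peak itself is found either inside a caller-given
retention window (largest area wins) or, absent a hint, as the candidate
whose induced assignment minimises the total RRT deviation of all
matched components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from qams.chromdata import PeakRecord, PeakTable
from qams.errors import AmbiguityError, AssignmentError

__all__ = ["RRTReference", "relative_retention", "assign_peaks", "assignment_report"]

#: Fractional matching window around each expected RRT.  Wide enough for
#: observed cross-system RRT scatter (RSD ~1% for most analytes, ~5% for
#: the earliest-eluting one), narrow against inter-component gaps (>=9%).
DEFAULT_TOLERANCE = 0.02


@dataclass(frozen=True)
class RRTReference:
    """Expected relative retention per analyte, with a matching tolerance.

    ``expected`` maps analyte code → expected rt_i/rt_s; the internal
    reference is implicit at 1.0.  ``tolerance`` is fractional: a peak
    matches component *i* iff ``|rrt/expected_i − 1| <= tolerance``.
    """

    internal_reference_code: str
    expected: Mapping[str, float]
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self):
        if any(v <= 0 for v in self.expected.values()):
            raise ValueError("expected relative retentions must be positive")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be a fraction in (0, 1)")
        if self.internal_reference_code in self.expected:
            raise ValueError("internal reference must not appear among expected analytes")


def relative_retention(rt_i: float, rt_s: float) -> float:
    """Relative retention time ``rt_i / rt_s``."""
    if not (rt_i > 0 and rt_s > 0):
        raise ValueError(f"retention times must be positive, got {rt_i}, {rt_s}")
    return rt_i / rt_s


def _match(records: list[PeakRecord], ref_rec: PeakRecord, reference: RRTReference,
           strict: bool = True) -> dict[str, Optional[PeakRecord]]:
    """Match each expected component to peaks, given the reference peak."""
    matches: dict[str, Optional[PeakRecord]] = {}
    for code, expected in reference.expected.items():
        hits = [
            r for r in records
            if r is not ref_rec
            and abs(relative_retention(r.retention_time, ref_rec.retention_time) / expected - 1.0)
            <= reference.tolerance
        ]
        if len(hits) > 1:
            if strict:
                rts = ", ".join(f"{r.retention_time:.4g} min" for r in hits)
                raise AmbiguityError(
                    f"component {code}: {len(hits)} peaks within ±{reference.tolerance:.1%} "
                    f"of expected RRT {expected} ({rts})")
            matches[code] = None
        else:
            matches[code] = hits[0] if hits else None
    return matches


def _total_deviation(records: list[PeakRecord], ref_rec: PeakRecord, reference: RRTReference) -> float:
    """Assignment cost of taking ``ref_rec`` as the reference peak.

    Each expected component contributes its best within-tolerance
    fractional RRT deviation, or a unit penalty when no peak matches —
    so candidates are ranked first by how many components they explain,
    then by how tightly.
    """
    total = 0.0
    for code, expected in reference.expected.items():
        devs = [
            abs(relative_retention(r.retention_time, ref_rec.retention_time) / expected - 1.0)
            for r in records if r is not ref_rec
        ]
        total += min([d for d in devs if d <= reference.tolerance], default=1.0)
    return total


def assign_peaks(
    table: PeakTable,
    reference: RRTReference,
    internal_rt_hint: Optional[float] = None,
    hint_window: float = 0.10,
) -> PeakTable:
    """Assign component codes to peaks by relative retention time.

    Each sample's chromatogram is treated independently.  The
    internal-reference peak is the largest-area peak within
    ``±hint_window`` (fractional) of ``internal_rt_hint`` when a hint is
    given; otherwise the peak whose choice minimises the summed RRT
    deviation over all expected components.  Every expected component is
    then matched to the unique peak within tolerance of its expected
    RRT; components with no matching peak are left absent, extra peaks
    stay unassigned.

    Raises
    ------
    AssignmentError
        If no internal-reference candidate exists for a sample.
    AmbiguityError
        If two peaks fall within tolerance of one expected RRT.
    """
    codes: dict[tuple[str, str, float], Optional[str]] = {}
    for sample_id in sorted({r.sample_id for r in table}):
        records = [r for r in table if r.sample_id == sample_id]

        if internal_rt_hint is not None:
            candidates = [
                r for r in records
                if abs(r.retention_time / internal_rt_hint - 1.0) <= hint_window
            ]
            if not candidates:
                raise AssignmentError(
                    f"sample {sample_id!r}: no peak within ±{hint_window:.0%} of the "
                    f"internal-reference hint {internal_rt_hint} min")
            ref_rec = max(candidates, key=lambda r: r.area)
        else:
            if not records:
                raise AssignmentError(f"sample {sample_id!r}: empty chromatogram")
            ref_rec = min(records, key=lambda r: (_total_deviation(records, r, reference),
                                                  r.retention_time))

        matches = _match(records, ref_rec, reference)
        key = (ref_rec.sample_id, ref_rec.system_id, ref_rec.retention_time)
        codes[key] = reference.internal_reference_code
        for code, rec in matches.items():
            if rec is not None:
                codes[(rec.sample_id, rec.system_id, rec.retention_time)] = code
    return table.with_assignments(codes)


def assignment_report(table: PeakTable, reference: RRTReference) -> pd.DataFrame:
    """Tabular report of an assigned table: RRT, deviation and status per peak.

    Rows are peaks plus one ``absent`` row per expected component not
    found in a sample.  Assumes :func:`assign_peaks` has already run.
    """
    rows = []
    for sample_id in sorted({r.sample_id for r in table}):
        records = [r for r in table if r.sample_id == sample_id]
        ref_rec = next((r for r in records
                        if r.component_code == reference.internal_reference_code), None)
        present = {r.component_code for r in records if r.component_code}
        for r in records:
            rrt = (relative_retention(r.retention_time, ref_rec.retention_time)
                   if ref_rec else float("nan"))
            expected = (1.0 if r.component_code == reference.internal_reference_code
                        else reference.expected.get(r.component_code or "", float("nan")))
            rows.append({
                "sample_id": sample_id,
                "component_code": r.component_code or "",
                "retention_time_min": r.retention_time,
                "rrt": rrt,
                "expected_rrt": expected,
                "deviation_percent": 100.0 * (rrt / expected - 1.0) if expected == expected else float("nan"),
                "status": "assigned" if r.component_code else "unassigned",
            })
        for code in reference.expected:
            if code not in present:
                rows.append({
                    "sample_id": sample_id,
                    "component_code": code,
                    "retention_time_min": float("nan"),
                    "rrt": float("nan"),
                    "expected_rrt": reference.expected[code],
                    "deviation_percent": float("nan"),
                    "status": "absent",
                })
    return pd.DataFrame(rows)
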