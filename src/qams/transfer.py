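"""Geometric method transfer between chromatographic systems.

Standard pharmacopoeial scaling rules for moving a separation between
columns/instruments while keeping the separation comparable:

* flow scales with column cross-section, ``ν_t = ν_o·(d_t/d_o)²``
  (constant linear velocity);
* injection volume scales with column volume,
  ``V_inj,t = V_inj,o·(V_col,t/V_col,o)`` (constant relative load);
* gradient breakpoint times scale as
  ``t_t = t_o·(V_col,t/V_col,o)·(ν_o/ν_t)`` (constant gradient volume
  in column volumes); %A values are untouched.

Column volume is taken proportional to ``d²·L``; the proportionality
constant (π/4 and porosity) cancels in every ratio used here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from qams.chromdata import ChromSystem, GradientStep

__all__ = [
    "ColumnGeometry",
    "scale_flow",
    "scale_injection",
    "scale_gradient",
    "transfer_system",
]


@dataclass(frozen=True)
class ColumnGeometry:
    """Column inner diameter and length, mm."""

    inner_diameter: float
    length: float

    def __post_init__(self):
        if not (self.inner_diameter > 0 and self.length > 0):
            raise ValueError("column dimensions must be positive")

    @property
    def volume(self) -> float:
        """Geometric volume up to a constant factor (d²·L)."""
        return self.inner_diameter ** 2 * self.length


def scale_flow(flow_original: float, d_original: float, d_target: float) -> float:
    """Flow rate on the target column preserving linear velocity."""
    if not (flow_original > 0 and d_original > 0 and d_target > 0):
        raise ValueError("flow rate and diameters must be positive")
    return flow_original * (d_target / d_original) ** 2


def scale_injection(v_inj_original: float, v_col_original: float, v_col_target: float) -> float:
    """Injection volume on the target column preserving relative load."""
    if not (v_inj_original > 0 and v_col_original > 0 and v_col_target > 0):
        raise ValueError("volumes must be positive")
    return v_inj_original * (v_col_target / v_col_original)


def scale_gradient(
    gradient: Sequence[GradientStep],
    flow_original: float,
    flow_target: float,
    v_col_original: float,
    v_col_target: float,
) -> tuple[GradientStep, ...]:
    """Gradient on the target system preserving gradient volume.

    All breakpoint times are multiplied by the single factor
    ``(V_col,t/V_col,o)·(ν_o/ν_t)``; the %A profile is unchanged, so the
    segment count and composition shape are invariant.
    """
    if not all(v > 0 for v in (flow_original, flow_target, v_col_original, v_col_target)):
        raise ValueError("flows and column volumes must be positive")
    factor = (v_col_target / v_col_original) * (flow_original / flow_target)
    return tuple(
        GradientStep(
            t_start=step.t_start * factor,
            t_end=step.t_end * factor,
            percent_A_start=step.percent_A_start,
            percent_A_end=step.percent_A_end,
        )
        for step in gradient
    )


def transfer_system(system: ChromSystem, target: ChromSystem) -> ChromSystem:
    """Derive target-system conditions from an original method.

    Takes the target's hardware (column geometry, ids) and fills in
    flow, injection volume and gradient by geometric scaling from the
    original.  Transferring back onto the original hardware returns the
    original conditions (round-trip identity).
    """
    v_col_o = ColumnGeometry(system.column_inner_diameter, system.column_length).volume
    v_col_t = ColumnGeometry(target.column_inner_diameter, target.column_length).volume
    flow_t = scale_flow(system.flow_rate, system.column_inner_diameter, target.column_inner_diameter)
    return replace(
        target,
        flow_rate=flow_t,
        injection_volume=scale_injection(system.injection_volume, v_col_o, v_col_t),
        gradient=scale_gradient(system.gradient, system.flow_rate, flow_t, v_col_o, v_col_t),
    )
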