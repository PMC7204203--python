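"""Quantification of assigned peaks: ESM, QAMS1 and QAMS2.

Three routes from a peak area to an injected mass:

* **ESM** (external standard method): invert the analyte's own
  calibration curve, ``m_i = (A_i − b_i)/k_i``.
* **QAMS1** (multipoint correction): only the internal reference *s* is
  calibrated; its measured mass anchors the others through the
  multipoint RCF, ``m_i = (m_s·A_i)/(f_{s/i}·A_s)``.
* **QAMS2** (slope correction): ``m_i = A_i/(k_s·f_{s/i})`` with the
  slope-method RCF — since ``k_s·f_{s/i} = k_i`` this is the analyte's
  own slope with the intercept deliberately ignored.

Injected masses convert to contents (mg per g of dry powder) through
the extraction arithmetic; replicate injections of one sample are
averaged after conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from qams.calibration import CalibrationCurve, esm_mass
from qams.chromdata import PeakTable
from qams.rcf import RCFSet
from qams.synthetic import REPLICATE_SEPARATOR, ExtractionSpec

__all__ = [
    "QuantResult",
    "quantify_esm",
    "quantify_qams1",
    "quantify_qams2",
    "to_content",
    "quantify_table",
    "quant_report",
]

METHODS = ("ESM", "QAMS1", "QAMS2")


@dataclass(frozen=True)
class QuantResult:
    """Per-sample, per-component content under one quantification method."""

    sample_id: str
    component_code: str
    method: str
    injected_mass: float  # µg
    content: float  # mg per g dry powder
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.content < 0 and "below_zero" not in self.flags:
            raise ValueError("negative content must carry the 'below_zero' flag")


def quantify_esm(area_i: float, curve_i: CalibrationCurve,
                 component_code: Optional[str] = None) -> tuple[float, bool]:
    """External-standard mass (µg) from a peak area and the matching curve.

    Returns ``(mass, in_range)``.  If ``component_code`` is given it must
    equal the curve's component (guards against crossed curves).
    """
    if component_code is not None and component_code != curve_i.component_code:
        raise ValueError(
            f"curve is for {curve_i.component_code}, not {component_code}")
    return esm_mass(curve_i, area_i)


def quantify_qams1(area_i: float, area_s: float, mass_s: float, f_s_i: float) -> float:
    """QAMS1 mass (µg): ``(m_s·A_i)/(f_{s/i}·A_s)``.

    ``mass_s`` is the internal reference's mass in the same injection,
    itself obtained from the reference's calibration curve.
    """
    for name, v in (("area_i", area_i), ("area_s", area_s), ("mass_s", mass_s), ("f_s_i", f_s_i)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (mass_s * area_i) / (f_s_i * area_s)


def quantify_qams2(area_i: float, k_s: float, f_s_i: float) -> float:
    """QAMS2 mass (µg): ``A_i/(k_s·f_{s/i})``, the intercept-free inversion."""
    if not (k_s > 0 and f_s_i > 0):
        raise ValueError(f"k_s and f_s_i must be positive, got {k_s}, {f_s_i}")
    if area_i < 0:
        raise ValueError(f"area must be non-negative, got {area_i}")
    return area_i / (k_s * f_s_i)


def to_content(mass_inj: float, injection_volume: float, extraction: ExtractionSpec) -> float:
    """Content (mg/g) from an injected mass (µg).

    Inverse of the sampling arithmetic: mass/volume gives the extract
    concentration (µg/µL ≡ mg/mL); times the extract volume (mL) the
    analyte mass in the whole extract (mg); divided by the powder mass
    (g) the content.  Negative masses pass through (flagged upstream).
    """
    if not injection_volume > 0:
        raise ValueError(f"injection_volume must be positive, got {injection_volume}")
    return mass_inj * extraction.extract_volume / (injection_volume * extraction.sample_mass)


def _base_sample(sample_id: str) -> str:
    return sample_id.split(REPLICATE_SEPARATOR, 1)[0]


def quantify_table(
    table: PeakTable,
    curves: Mapping[str, CalibrationCurve],
    extraction: ExtractionSpec,
    multipoint: Optional[RCFSet] = None,
    slope: Optional[RCFSet] = None,
    methods: Sequence[str] = METHODS,
) -> list[QuantResult]:
    """Quantify an assigned peak table by the requested methods.

    ``curves`` needs every component for ESM but only the internal
    reference for the QAMS routes.  Replicate injections
    (``sample@rN``) are averaged into one result per base sample.
    QAMS methods require the internal-reference peak in every sample.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    needs_qams = any(m in methods for m in ("QAMS1", "QAMS2"))
    ref_code = None
    if needs_qams:
        rcf_set = multipoint if multipoint is not None else slope
        if rcf_set is None:
            raise ValueError("QAMS methods need an RCFSet")
        ref_code = rcf_set.internal_reference_code

    # per (base sample, component, method): list of (mass, content, flags)
    acc: dict[tuple[str, str, str], list[tuple[float, float, tuple[str, ...]]]] = {}

    for injection_id in sorted({r.sample_id for r in table}):
        records = {r.component_code: r for r in table
                   if r.sample_id == injection_id and r.component_code}
        ref_rec = records.get(ref_code) if needs_qams else None
        if needs_qams and ref_rec is None:
            raise ValueError(
                f"sample {injection_id!r} lacks the internal-reference peak {ref_code!r} "
                "required for QAMS quantification")
        mass_s = None
        if ref_rec is not None:
            mass_s, _ = esm_mass(curves[ref_code], ref_rec.area)

        for code, rec in records.items():
            for method in methods:
                if method == "ESM":
                    mass, in_range = esm_mass(curves[code], rec.area)
                    flags = () if in_range else ("out_of_range",)
                elif method == "QAMS1":
                    if code == ref_code:
                        mass, flags = mass_s, ()
                    else:
                        f = multipoint.factor(code)
                        mass = quantify_qams1(rec.area, ref_rec.area, mass_s, f)
                        flags = ()
                else:  # QAMS2
                    if code == ref_code:
                        mass = quantify_qams2(rec.area, curves[ref_code].slope, 1.0)
                        flags = ()
                    else:
                        f = slope.factor(code)
                        mass = quantify_qams2(rec.area, curves[ref_code].slope, f)
                        flags = ()
                content = to_content(mass, rec.injection_volume, extraction)
                if content < 0:
                    flags = flags + ("below_zero",)
                acc.setdefault((_base_sample(injection_id), code, method), []).append(
                    (mass, content, flags))

    results = []
    for (sample, code, method), vals in sorted(acc.items()):
        mean_mass = sum(v[0] for v in vals) / len(vals)
        mean_content = sum(v[1] for v in vals) / len(vals)
        flags = tuple(sorted({f for v in vals for f in v[2]}))
        if mean_content < 0 and "below_zero" not in flags:
            flags = flags + ("below_zero",)
        results.append(QuantResult(sample, code, method, mean_mass, mean_content, flags))
    return results


def quant_report(results: Sequence[QuantResult]) -> pd.DataFrame:
    """Quantification results as a tidy DataFrame (one row per result)."""
    return pd.DataFrame([
        {
            "sample_id": r.sample_id,
            "component_code": r.component_code,
            "method": r.method,
            "injected_mass_ug": r.injected_mass,
            "content_mg_per_g": r.content,
            "flags": ";".join(r.flags),
        }
        for r in results
    ])
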