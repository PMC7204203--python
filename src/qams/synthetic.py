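"""Seeded generator of standard-series and sample peak tables.

Emulates what the pipeline assumes about an LC instrument:

* linear detector response per component, ``A = k·m + b``;
* retention times with a fixed relative-retention structure around the
  internal-reference peak;
* multiplicative area noise at the relative-standard-deviation level a
  validated method exhibits (fractions of a percent to ~2%);
* per-region component contents converted to injected masses through the
  extraction arithmetic (sample mass → extract concentration → injected
  volume).

Everything is driven by ``numpy.random.default_rng`` seeds: identical
seed and parameters give bit-identical tables.  Rendered chromatograms
(sum of Gaussians over a drifting baseline) and a simple valley-bounded
trapezoidal integrator close the loop from peak list to signal and back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from qams import longan
from qams.calibration import esm_mass
from qams.chromdata import ChromSystem, PeakRecord, PeakTable

__all__ = [
    "ResponseModel",
    "NoiseModel",
    "RetentionModel",
    "ContentProfile",
    "ExtractionSpec",
    "simulate_standard_series",
    "simulate_sample_table",
    "simulate_recovery_experiment",
    "render_chromatogram",
    "integrate_chromatogram",
    "default_response_model",
    "default_noise_model",
    "default_retention_model",
    "default_content_profile",
    "standard_masses",
    "injected_mass_ug",
    "REPLICATE_SEPARATOR",
]

#: Replicate injections of one sample are suffixed "<sample_id>@r<k>".
REPLICATE_SEPARATOR = "@r"

# Internal-reference retention times (min) placing all five peaks inside
# each system's gradient window.  Absolute retention is a free parameter
# of the simulation; only the relative structure is method-defined.
_DEFAULT_REFERENCE_RT = {"UPLC": 12.0, "HPLC": 30.0}


@dataclass(frozen=True)
class ResponseModel:
    """Per-component linear detector response for one system.

    ``curves`` maps component code to (slope k in area/µg, intercept b).
    """

    system_id: str
    curves: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for code, (k, _) in self.curves.items():
            if not k > 0:
                raise ValueError(f"response slope for {code} must be positive, got {k}")

    def area(self, component_code: str, mass_ug: float) -> float:
        k, b = self.curves[component_code]
        return k * mass_ug + b

    def without_intercepts(self) -> "ResponseModel":
        """Idealised intercept-free copy (pure proportional response)."""
        return ResponseModel(self.system_id, {c: (k, 0.0) for c, (k, _) in self.curves.items()})


@dataclass(frozen=True)
class NoiseModel:
    """Area and retention-time noise.

    ``area_rsd`` is the multiplicative area noise in percent — a scalar
    applied to every component, or a per-component mapping; the noisy
    area is ``A·(1 + ε)``, ``ε ~ N(0, rsd/100)``, truncated at zero.

    Retention noise has two parts mirroring how LC retention actually
    varies: ``rt_drift_rsd`` (percent) is a *common-mode* multiplicative
    drift drawn once per injection and applied to every peak — flow and
    temperature fluctuations move the whole chromatogram together, and
    this component cancels exactly in relative retention times;
    ``rt_jitter_sd`` (min) is small independent per-peak jitter (apex
    determination).
    """

    area_rsd: float | Mapping[str, float] = 0.0
    rt_jitter_sd: float = 0.0
    rt_drift_rsd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rsds = self.area_rsd.values() if isinstance(self.area_rsd, Mapping) else [self.area_rsd]
        if any(r < 0 for r in rsds) or self.rt_jitter_sd < 0 or self.rt_drift_rsd < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def rsd_for(self, component_code: str) -> float:
        if isinstance(self.area_rsd, Mapping):
            return self.area_rsd[component_code]
        return self.area_rsd

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class RetentionModel:
    """Absolute internal-reference retention plus relative retentions.

    ``relative_retention`` maps each analyte code to rt_i / rt_ref; the
    internal reference itself has relative retention 1 by definition.
    """

    internal_reference_code: str
    internal_reference_rt: float
    relative_retention: Mapping[str, float]

    def __post_init__(self):
        if not self.internal_reference_rt > 0:
            raise ValueError("internal reference retention time must be positive")
        if any(v <= 0 for v in self.relative_retention.values()):
            raise ValueError("relative retentions must be positive")

    def rt(self, component_code: str) -> float:
        if component_code == self.internal_reference_code:
            return self.internal_reference_rt
        return self.internal_reference_rt * self.relative_retention[component_code]

    @property
    def codes(self) -> tuple[str, ...]:
        return (self.internal_reference_code, *self.relative_retention.keys())


@dataclass(frozen=True)
class ContentProfile:
    """Component contents (mg per g of dry powder) per sample/region."""

    contents: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        for sample, row in self.contents.items():
            for code, c in row.items():
                if c < 0:
                    raise ValueError(f"content of {code} in {sample} is negative")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.contents.keys())

    def content(self, sample_id: str, component_code: str) -> float:
        return self.contents[sample_id][component_code]


@dataclass(frozen=True)
class ExtractionSpec:
    """Extraction parameters: powder mass (g) taken into extract volume (mL)."""

    sample_mass: float = 4.0
    extract_volume: float = 20.0

    def __post_init__(self):
        if not (self.sample_mass > 0 and self.extract_volume > 0):
            raise ValueError("extraction parameters must be positive")


def injected_mass_ug(content_mg_per_g: float, extraction: ExtractionSpec, injection_volume_uL: float) -> float:
    """Injected mass (µg) of a component at a given content.

    content (mg/g) × sample mass (g) = mg in the extract; divided by the
    extract volume (mL) gives mg/mL ≡ µg/µL; times the injected volume
    (µL) gives µg on column.
    """
    return content_mg_per_g * extraction.sample_mass / extraction.extract_volume * injection_volume_uL


# ---------------------------------------------------------------------------
# Defaults wired to the published longan-leaf method constants
# ---------------------------------------------------------------------------

def default_response_model(system_id: str) -> ResponseModel:
    """Response model with the published calibration slopes/intercepts."""
    return ResponseModel(
        system_id,
        {
            code: (longan.calibration_curve(system_id, code).slope,
                   longan.calibration_curve(system_id, code).intercept)
            for code in longan.COMPONENT_CODES
        },
    )


def default_noise_model(system_id: str, seed: int = 0) -> NoiseModel:
    """Per-component area RSDs at the published instrument-precision level."""
    return NoiseModel(
        area_rsd=dict(longan.PRECISION_AREA_RSD_PERCENT[system_id]),
        rt_jitter_sd=0.02 if system_id == "UPLC" else 0.05,
        rt_drift_rsd=0.3,
        seed=seed,
    )


def default_retention_model(system_id: str) -> RetentionModel:
    """Cross-system mean relative retentions around the reference peak."""
    return RetentionModel(
        internal_reference_code=longan.INTERNAL_REFERENCE,
        internal_reference_rt=_DEFAULT_REFERENCE_RT[system_id],
        relative_retention=dict(longan.RRT_MEANS),
    )


def default_content_profile() -> ContentProfile:
    """The ten-region content panel (external-standard UPLC values)."""
    return ContentProfile({r: dict(row) for r, row in longan.REGION_CONTENTS_MG_PER_G["UPLC"].items()})


def standard_masses(system_id: str, volumes_uL: Optional[Sequence[float]] = None) -> dict[str, list[float]]:
    """Injected masses (µg) of the mixed working standard per volume level.

    The standard series injects one working solution at increasing
    volumes, so each component's mass ladder is its working concentration
    (µg/mL → µg/µL at /1000) times the volume series.
    """
    vols = volumes_uL if volumes_uL is not None else longan.STANDARD_INJECTION_VOLUMES_UL[system_id]
    return {
        code: [conc / 1000.0 * v for v in vols]
        for code, conc in longan.WORKING_SOLUTION_UG_PER_ML.items()
    }


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _noisy_area(area: float, rsd_percent: float, rng: np.random.Generator) -> float:
    # detector counts cannot go negative (zero-mass peak with b < 0)
    if rsd_percent == 0:
        return max(0.0, area)
    return max(0.0, area * (1.0 + rng.normal(0.0, rsd_percent / 100.0)))


def simulate_standard_series(
    response: ResponseModel,
    masses: Mapping[str, Sequence[float]],
    noise: NoiseModel,
    retention: Optional[RetentionModel] = None,
    injection_volumes: Optional[Sequence[float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> PeakTable:
    """Peak table of a standard dilution/volume series.

    One record per component per mass level, with ``injected_mass`` set
    (these are standards).  With zero noise, areas equal ``k·m + b``
    exactly.

    ``masses[code]`` is the mass ladder (µg) for one component; all
    ladders must have equal length.  ``injection_volumes`` optionally
    records the actual injected volumes per level (defaults to 1 µL).
    """
    if any(m < 0 for ladder in masses.values() for m in ladder):
        raise ValueError("injected masses must be non-negative")
    lengths = {len(v) for v in masses.values()}
    if len(lengths) != 1:
        raise ValueError("all components must have the same number of mass levels")
    n_levels = lengths.pop()
    if injection_volumes is not None and len(injection_volumes) != n_levels:
        raise ValueError("injection_volumes length must match the number of levels")
    retention = retention or default_retention_model(response.system_id)
    rng = rng if rng is not None else noise.rng()

    records = []
    for level in range(n_levels):
        vol = injection_volumes[level] if injection_volumes is not None else 1.0
        drift = 1.0 + rng.normal(0.0, noise.rt_drift_rsd / 100.0) if noise.rt_drift_rsd else 1.0
        for code in masses:
            m = masses[code][level]
            rt = retention.rt(code) * drift
            if noise.rt_jitter_sd:
                rt += rng.normal(0.0, noise.rt_jitter_sd)
            records.append(PeakRecord(
                sample_id=f"std_L{level + 1}",
                system_id=response.system_id,
                component_code=code,
                retention_time=max(1e-6, rt),
                area=_noisy_area(response.area(code, m), noise.rsd_for(code), rng),
                injection_volume=vol,
                injected_mass=m,
            ))
    return PeakTable(records=records, provenance=f"simulated standard series, seed={noise.seed}")


def simulate_sample_table(
    profile: ContentProfile,
    extraction: ExtractionSpec,
    system: ChromSystem,
    response: ResponseModel,
    retention: Optional[RetentionModel] = None,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> PeakTable:
    """Peak table of unknown samples generated from a content profile.

    Component identities are left blank (``component_code=None``) and
    ``injected_mass`` absent, as for real unknowns: peak assignment and
    quantification are downstream jobs.  Replicate injections are
    emitted as ``<sample_id>@r<k>``.
    """
    retention = retention or default_retention_model(response.system_id)
    rng = rng if rng is not None else noise.rng()
    missing = [c for c in retention.codes if c not in next(iter(profile.contents.values()))]
    if missing:
        raise ValueError(f"content profile lacks component(s): {missing}")

    records = []
    for sample_id in profile.sample_ids:
        for rep in range(1, replicates + 1):
            sid = sample_id if replicates == 1 else f"{sample_id}{REPLICATE_SEPARATOR}{rep}"
            drift = 1.0 + rng.normal(0.0, noise.rt_drift_rsd / 100.0) if noise.rt_drift_rsd else 1.0
            for code in retention.codes:
                m = injected_mass_ug(profile.content(sample_id, code), extraction, system.injection_volume)
                rt = retention.rt(code) * drift
                if noise.rt_jitter_sd:
                    rt = max(1e-6, rt + rng.normal(0.0, noise.rt_jitter_sd))
                records.append(PeakRecord(
                    sample_id=sid,
                    system_id=system.system_id,
                    component_code=None,
                    retention_time=rt,
                    area=_noisy_area(response.area(code, m), noise.rsd_for(code), rng),
                    injection_volume=system.injection_volume,
                    injected_mass=None,
                ))
    return PeakTable(records=records, provenance=f"simulated samples, seed={noise.seed}")


def simulate_recovery_experiment(
    contents: Mapping[str, float],
    system: ChromSystem,
    response: ResponseModel,
    noise: NoiseModel,
    curves: Mapping[str, "object"],
    n_portions: int = 9,
    spike_fraction: float = 1.0,
    extraction: ExtractionSpec = ExtractionSpec(sample_mass=2.0, extract_volume=20.0),
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[tuple[float, float, float]]]:
    """Simulated spike-recovery study.

    For each of ``n_portions`` powder portions and each component, a
    known standard mass (``spike_fraction`` × the native amount) is added
    before extraction; the unspiked and spiked extracts are measured by
    the external-standard method under instrument noise.

    Returns per component a list of ``(found_total, original, added)``
    injected masses (µg), ready for
    :func:`qams.validate.recovery_percent`.
    """
    rng = rng if rng is not None else noise.rng()
    out: dict[str, list[tuple[float, float, float]]] = {code: [] for code in contents}
    for _ in range(n_portions):
        for code, c in contents.items():
            m_native = injected_mass_ug(c, extraction, system.injection_volume)
            m_added = spike_fraction * m_native
            area_orig = _noisy_area(response.area(code, m_native), noise.rsd_for(code), rng)
            area_total = _noisy_area(response.area(code, m_native + m_added), noise.rsd_for(code), rng)
            original, _ = esm_mass(curves[code], area_orig)
            found_total, _ = esm_mass(curves[code], area_total)
            out[code].append((found_total, original, m_added))
    return out


# ---------------------------------------------------------------------------
# Rendered chromatograms and re-integration
# ---------------------------------------------------------------------------

def render_chromatogram(
    table: PeakTable,
    peak_width_sd: float = 0.05,
    sampling_rate: float = 10.0,
    baseline_level: float = 0.0,
    baseline_drift: float = 0.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    pad: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a peak table as a sampled signal (time min, intensity).

    Each peak becomes a Gaussian of standard deviation ``peak_width_sd``
    (min) whose integral equals the record's area.  ``sampling_rate`` is
    in Hz (points per second of elution); it must resolve the narrowest
    peak with at least 10 points per standard deviation.  The baseline is
    ``baseline_level + baseline_drift·t`` plus optional white noise.
    """
    if peak_width_sd <= 0:
        raise ValueError("peak_width_sd must be positive")
    points_per_sd = peak_width_sd * 60.0 * sampling_rate
    if points_per_sd < 10:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz gives {points_per_sd:.1f} points per peak sd; >= 10 required")
    t_end = (max((r.retention_time for r in table), default=0.0)) + pad
    n = max(2, int(np.ceil(t_end * 60.0 * sampling_rate)) + 1)
    t = np.linspace(0.0, t_end, n)
    y = baseline_level + baseline_drift * t
    for rec in table:
        y = y + rec.area / (peak_width_sd * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - rec.retention_time) / peak_width_sd) ** 2)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return t, y


def integrate_chromatogram(
    time_min: np.ndarray,
    intensity: np.ndarray,
    min_prominence: float = 1.0,
    system_id: str = "sim",
    sample_id: str = "sim",
    injection_volume: float = 1.0,
) -> PeakTable:
    """Detect and integrate peaks in a uniformly sampled signal.

    Apexes are local maxima above ``min_prominence``; each peak's
    boundaries are the signal minima towards the neighbouring apex (or
    signal edge), and its area is the trapezoidal integral above the
    straight line joining the boundary points (local linear baseline).
    A signal with no qualifying maxima yields an empty table.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and intensity must be 1-D arrays of equal length")
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("signal must be uniformly sampled")

    apexes, _ = find_peaks(y, prominence=min_prominence)
    records = []
    for j, apex in enumerate(apexes):
        lo_lim = apexes[j - 1] if j > 0 else 0
        hi_lim = apexes[j + 1] if j + 1 < len(apexes) else len(y) - 1
        left = lo_lim + int(np.argmin(y[lo_lim:apex + 1]))
        right = apex + int(np.argmin(y[apex:hi_lim + 1]))
        if right <= left:
            continue
        seg_t = t[left:right + 1]
        seg_y = y[left:right + 1]
        baseline = np.interp(seg_t, [t[left], t[right]], [y[left], y[right]])
        area = float(np.trapezoid(seg_y - baseline, seg_t))
        if area <= 0:
            continue
        records.append(PeakRecord(
            sample_id=sample_id,
            system_id=system_id,
            component_code=None,
            retention_time=float(t[apex]),
            area=area,
            injection_volume=injection_volume,
        ))
    return PeakTable(records=records, provenance="integrated from rendered signal")
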