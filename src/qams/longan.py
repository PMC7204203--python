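"""Published reference data for the *Dimocarpus longan* leaf flavonoid panel.

Five phenolic/flavonoid analytes are quantified in longan leaf extracts:
ethyl gallate (C1), astragalin (C2), quercetin (C3, the internal
reference), luteolin (C4) and kaempferol (C5).  This module collects the
published method constants for that assay — per-system linear calibration
curves (peak area vs injected mass, µg), per-injection-volume multipoint
relative correction factors, RCF robustness values over nine
chromatographic conditions, cross-system relative retention times, and
the measured contents (mg per g dry powder) of ten Guangxi growing
regions on both a UPLC and an HPLC system.

These constants are the defaults of the synthetic-data generator and the
inputs of the reproduction scripts; they are data, not code paths — every
statistic the package reports is recomputed from them at run time.
"""

from __future__ import annotations

from qams.calibration import CalibrationCurve
from qams.chromdata import ChromSystem, Component, GradientStep

__all__ = [
    "PANEL",
    "COMPONENT_CODES",
    "ANALYTE_CODES",
    "INTERNAL_REFERENCE",
    "UPLC_SYSTEM",
    "HPLC_SYSTEM",
    "CALIBRATION_CURVES",
    "calibration_curve",
    "WORKING_SOLUTION_UG_PER_ML",
    "STANDARD_INJECTION_VOLUMES_UL",
    "PRECISION_AREA_RSD_PERCENT",
    "MULTIPOINT_RCF_TABLE",
    "ROBUSTNESS_RCF_TABLE",
    "RRT_TABLE",
    "RRT_MEANS",
    "REGION_CONTENTS_MG_PER_G",
    "REGIONS",
]

PANEL = (
    Component("C1", "ethyl gallate"),
    Component("C2", "astragalin"),
    Component("C3", "quercetin", is_internal_reference=True),
    Component("C4", "luteolin"),
    Component("C5", "kaempferol"),
)

COMPONENT_CODES = tuple(c.code for c in PANEL)
INTERNAL_REFERENCE = "C3"
ANALYTE_CODES = tuple(c for c in COMPONENT_CODES if c != INTERNAL_REFERENCE)

# Gradient: methanol (A) / 0.2% phosphoric acid (B); detection 280 nm
# switching to 360 nm after the ethyl gallate peak.
UPLC_SYSTEM = ChromSystem(
    system_id="UPLC",
    instrument_class="UPLC",
    column_id="Waters ACQUITY UPLC HSS C18",
    column_inner_diameter=2.1,
    column_length=100.0,
    flow_rate=0.2,
    column_temperature=30.0,
    injection_volume=0.5,
    gradient=(
        GradientStep(0.0, 3.0, 20.0, 30.0),
        GradientStep(3.0, 5.0, 30.0, 38.0),
        GradientStep(5.0, 20.0, 38.0, 75.0),
    ),
    wavelength_program=((0.0, 280.0), (10.0, 360.0)),
)

HPLC_SYSTEM = ChromSystem(
    system_id="HPLC",
    instrument_class="HPLC",
    column_id="Thermo Syncronis C18",
    column_inner_diameter=4.6,
    column_length=212.0,
    flow_rate=1.0,
    column_temperature=30.0,
    injection_volume=5.0,
    gradient=(
        GradientStep(0.0, 7.0, 20.0, 30.0),
        GradientStep(7.0, 12.0, 30.0, 38.0),
        GradientStep(12.0, 48.0, 38.0, 75.0),
    ),
    wavelength_program=((0.0, 280.0), (22.0, 360.0)),
)

# Published linear calibration: area = k · mass(µg) + b, with Pearson r
# and the validated linear range in µg injected.
_CAL = {
    ("UPLC", "C1"): (7794.28, -16.64, 0.99988, (0.0490, 0.245)),
    ("UPLC", "C2"): (9618.87, -13.22, 0.99972, (0.0216, 0.108)),
    ("UPLC", "C3"): (19503.76, -50.67, 0.99992, (0.0832, 0.416)),
    ("UPLC", "C4"): (16010.58, -7.42, 0.99983, (0.00920, 0.0460)),
    ("UPLC", "C5"): (17806.81, -15.31, 0.99976, (0.0144, 0.0722)),
    ("HPLC", "C1"): (1354.52, 17.42, 0.99985, (0.490, 2.450)),
    ("HPLC", "C2"): (1713.83, 4.38, 0.99981, (0.216, 1.080)),
    ("HPLC", "C3"): (3574.23, 80.52, 0.99992, (0.832, 4.160)),
    ("HPLC", "C4"): (2903.01, -3.15, 0.99966, (0.0920, 0.460)),
    ("HPLC", "C5"): (3249.11, -16.06, 0.99964, (0.144, 0.722)),
}

CALIBRATION_CURVES: dict[tuple[str, str], CalibrationCurve] = {
    (system, code): CalibrationCurve(
        component_code=code,
        system_id=system,
        slope=k,
        intercept=b,
        r=r,
        linear_range=rng,
        n_points=6,
    )
    for (system, code), (k, b, r, rng) in _CAL.items()
}


def calibration_curve(system_id: str, component_code: str) -> CalibrationCurve:
    """The published calibration curve for one (system, component) pair."""
    return CALIBRATION_CURVES[(system_id, component_code)]


# Mixed working standard solution, µg of each analyte per mL; the standard
# series injects it at the volumes below, so injected mass = conc × volume.
WORKING_SOLUTION_UG_PER_ML = {
    "C1": 245.2,
    "C2": 108.0,
    "C3": 416.0,
    "C4": 46.0,
    "C5": 72.2,
}

STANDARD_INJECTION_VOLUMES_UL = {
    "UPLC": (0.2, 0.4, 0.5, 0.6, 0.8, 1.0),
    "HPLC": (2.0, 4.0, 5.0, 6.0, 8.0, 10.0),
}

# Six sequential injections of the working solution: per-component peak-area
# RSDs (%), the instruments' short-term precision.
PRECISION_AREA_RSD_PERCENT = {
    "UPLC": {"C1": 0.38, "C2": 0.17, "C3": 0.18, "C4": 0.34, "C5": 0.23},
    "HPLC": {"C1": 0.69, "C2": 0.65, "C3": 0.92, "C4": 1.98, "C5": 1.05},
}

# Multipoint relative correction factors f_{C3/i}, one row per standard
# injection volume (µL).  Columns are the four non-reference analytes.
MULTIPOINT_RCF_TABLE = {
    "UPLC": {
        0.2: {"C1": 0.395, "C2": 0.477, "C4": 0.805, "C5": 0.886},
        0.4: {"C1": 0.397, "C2": 0.485, "C4": 0.813, "C5": 0.900},
        0.5: {"C1": 0.398, "C2": 0.487, "C4": 0.815, "C5": 0.903},
        0.6: {"C1": 0.398, "C2": 0.490, "C4": 0.816, "C5": 0.907},
        0.8: {"C1": 0.398, "C2": 0.489, "C4": 0.814, "C5": 0.906},
        1.0: {"C1": 0.399, "C2": 0.490, "C4": 0.818, "C5": 0.908},
    },
    "HPLC": {
        2.0: {"C1": 0.379, "C2": 0.472, "C4": 0.781, "C5": 0.894},
        4.0: {"C1": 0.379, "C2": 0.476, "C4": 0.797, "C5": 0.882},
        5.0: {"C1": 0.379, "C2": 0.477, "C4": 0.800, "C5": 0.887},
        6.0: {"C1": 0.379, "C2": 0.477, "C4": 0.802, "C5": 0.891},
        8.0: {"C1": 0.379, "C2": 0.478, "C4": 0.804, "C5": 0.895},
        10.0: {"C1": 0.379, "C2": 0.478, "C4": 0.806, "C5": 0.898},
    },
}

# RCF robustness: nine chromatographic conditions (instrument, column,
# flow rate, column temperature) × four analytes.
ROBUSTNESS_RCF_TABLE = {
    "UPLC / column: Waters": {"C1": 0.397, "C2": 0.479, "C4": 0.817, "C5": 0.902},
    "UPLC / column: Thermo": {"C1": 0.398, "C2": 0.479, "C4": 0.824, "C5": 0.901},
    "UPLC / flow 0.2 mL/min": {"C1": 0.397, "C2": 0.481, "C4": 0.812, "C5": 0.897},
    "UPLC / flow 0.3 mL/min": {"C1": 0.391, "C2": 0.479, "C4": 0.803, "C5": 0.889},
    "UPLC / 25 C": {"C1": 0.393, "C2": 0.487, "C4": 0.808, "C5": 0.925},
    "UPLC / 30 C": {"C1": 0.396, "C2": 0.481, "C4": 0.809, "C5": 0.895},
    "UPLC / 35 C": {"C1": 0.399, "C2": 0.482, "C4": 0.818, "C5": 0.901},
    "HPLC / column: Phenomenex": {"C1": 0.376, "C2": 0.471, "C4": 0.785, "C5": 0.879},
    "HPLC / column: Agilent": {"C1": 0.377, "C2": 0.471, "C4": 0.775, "C5": 0.893},
}

# Relative retention time rt_i / rt_C3 on four system/column combinations.
RRT_TABLE = {
    ("UPLC", "Waters"): {"C1": 0.541, "C2": 0.828, "C4": 1.062, "C5": 1.179},
    ("UPLC", "Thermo"): {"C1": 0.542, "C2": 0.828, "C4": 1.062, "C5": 1.179},
    ("HPLC", "Phenomenex"): {"C1": 0.495, "C2": 0.844, "C4": 1.086, "C5": 1.180},
    ("HPLC", "Agilent"): {"C1": 0.493, "C2": 0.834, "C4": 1.070, "C5": 1.174},
}

RRT_MEANS = {
    code: sum(row[code] for row in RRT_TABLE.values()) / len(RRT_TABLE)
    for code in ANALYTE_CODES
}

REGIONS = (
    "Beihai", "Qinzhou", "Wuzhou", "Yulin", "Nanning",
    "Chongzuo", "Liuzhou", "Guigang", "Hezhou", "Fangchenggang",
)

# External-standard contents (mg per g dry leaf powder, mean of n = 3)
# of the ten growing regions on each instrument.
REGION_CONTENTS_MG_PER_G = {
    "UPLC": {
        "Beihai":        {"C1": 1.918, "C2": 0.356, "C3": 1.073, "C4": 0.144, "C5": 0.225},
        "Qinzhou":       {"C1": 2.679, "C2": 0.341, "C3": 2.438, "C4": 0.157, "C5": 0.561},
        "Wuzhou":        {"C1": 1.828, "C2": 0.237, "C3": 1.842, "C4": 0.148, "C5": 0.460},
        "Yulin":         {"C1": 1.631, "C2": 0.261, "C3": 1.799, "C4": 0.140, "C5": 0.425},
        "Nanning":       {"C1": 2.587, "C2": 0.289, "C3": 1.601, "C4": 0.172, "C5": 0.471},
        "Chongzuo":      {"C1": 1.850, "C2": 0.266, "C3": 0.426, "C4": 0.109, "C5": 0.213},
        "Liuzhou":       {"C1": 1.259, "C2": 0.303, "C3": 3.521, "C4": 0.145, "C5": 0.892},
        "Guigang":       {"C1": 1.880, "C2": 0.220, "C3": 2.589, "C4": 0.189, "C5": 0.751},
        "Hezhou":        {"C1": 2.915, "C2": 0.260, "C3": 1.936, "C4": 0.192, "C5": 0.522},
        "Fangchenggang": {"C1": 1.462, "C2": 0.286, "C3": 0.699, "C4": 0.129, "C5": 0.358},
    },
    "HPLC": {
        "Beihai":        {"C1": 1.940, "C2": 0.346, "C3": 0.955, "C4": 0.146, "C5": 0.229},
        "Qinzhou":       {"C1": 2.796, "C2": 0.363, "C3": 2.425, "C4": 0.161, "C5": 0.639},
        "Wuzhou":        {"C1": 1.824, "C2": 0.225, "C3": 1.835, "C4": 0.150, "C5": 0.469},
        "Yulin":         {"C1": 1.698, "C2": 0.264, "C3": 1.799, "C4": 0.148, "C5": 0.421},
        "Nanning":       {"C1": 2.617, "C2": 0.276, "C3": 1.613, "C4": 0.167, "C5": 0.469},
        "Chongzuo":      {"C1": 1.827, "C2": 0.243, "C3": 0.443, "C4": 0.115, "C5": 0.210},
        "Liuzhou":       {"C1": 1.234, "C2": 0.309, "C3": 3.372, "C4": 0.143, "C5": 0.931},
        "Guigang":       {"C1": 1.882, "C2": 0.216, "C3": 2.410, "C4": 0.194, "C5": 0.798},
        "Hezhou":        {"C1": 3.002, "C2": 0.262, "C3": 1.918, "C4": 0.184, "C5": 0.571},
        "Fangchenggang": {"C1": 1.490, "C2": 0.280, "C3": 0.685, "C4": 0.128, "C5": 0.392},
    },
}
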