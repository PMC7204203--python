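"""Method-validation statistics and method/instrument agreement.

Covers the classical validation battery for an LC assay — relative
standard deviation for precision/stability/repeatability, spike
recovery for accuracy — and the agreement analysis used to compare two
instruments or two quantification methods over the same samples:
per-component Pearson correlation with a two-tailed t-test, flagged at
α = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from qams.errors import PairingError
from qams.quantify import QuantResult

__all__ = [
    "rsd",
    "recovery_percent",
    "pearson_r",
    "AgreementReport",
    "agreement_report",
    "agreement_from_results",
    "plot_agreement",
]

ALPHA = 0.01


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: ``100·sd(n−1)/mean``."""
    if len(values) < 2:
        raise ValueError(f"RSD needs >= 2 values, got {len(values)}")
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def recovery_percent(found_total: float, original: float, added: float) -> float:
    """Spike recovery in percent: ``100·(found_total − original)/added``."""
    if not added > 0:
        raise ValueError(f"added amount must be positive, got {added}")
    return 100.0 * (found_total - original) / added


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-tailed p-value.

    The p-value comes from ``t = r·sqrt((n−2)/(1−r²))`` on n−2 degrees
    of freedom, the standard exact test under bivariate normality.
    """
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length sequences of >= 3 values")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("correlation undefined: zero variance in an argument")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AgreementReport:
    """Per-component agreement between two paired measurement series.

    ``pairs`` maps component code → (x values, y values) aligned by
    sample; ``r``, ``p`` and ``significant`` (at α = 0.01) are derived
    per component.
    """

    label_x: str
    label_y: str
    pairs: Mapping[str, tuple[tuple[float, ...], tuple[float, ...]]]
    r: Mapping[str, float]
    p: Mapping[str, float]
    significant: Mapping[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "component_code": code,
                "n": len(self.pairs[code][0]),
                "pearson_r": self.r[code],
                "p_two_tailed": self.p[code],
                f"significant_at_{ALPHA}": self.significant[code],
            }
            for code in self.pairs
        ])

    def summary(self) -> str:
        lines = [f"Agreement: {self.label_x} vs {self.label_y} (alpha = {ALPHA}, two-tailed)"]
        for code in self.pairs:
            star = "**" if self.significant[code] else "  "
            lines.append(
                f"  {code}: r = {self.r[code]:.3f} {star} (n = {len(self.pairs[code][0])}, "
                f"p = {self.p[code]:.2e})")
        return "\n".join(lines)


def agreement_report(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    label_x: str = "x",
    label_y: str = "y",
) -> AgreementReport:
    """Agreement analysis over per-component paired value lists.

    Each component's two lists must be aligned by sample and of equal
    length >= 3.
    """
    r, p, sig, frozen = {}, {}, {}, {}
    for code, (x, y) in pairs.items():
        if len(x) != len(y):
            raise PairingError(f"component {code}: paired lists differ in length ({len(x)} vs {len(y)})")
        if len(x) < 3:
            raise PairingError(f"component {code}: need >= 3 pairs, got {len(x)}")
        r[code], p[code] = pearson_r(x, y)
        sig[code] = p[code] < ALPHA
        frozen[code] = (tuple(float(v) for v in x), tuple(float(v) for v in y))
    return AgreementReport(label_x, label_y, frozen, r, p, sig)


def agreement_from_results(
    results_x: Sequence[QuantResult],
    results_y: Sequence[QuantResult],
    label_x: str = "x",
    label_y: str = "y",
) -> AgreementReport:
    """Pair two quantification result sets by (sample, component).

    Raises :class:`PairingError` listing any (sample, component) keys
    present on one side only.
    """
    def index(results):
        return {(r.sample_id, r.component_code): r.content for r in results}

    ix, iy = index(results_x), index(results_y)
    missing = sorted(set(ix) ^ set(iy))
    if missing:
        raise PairingError(f"unmatched (sample, component) keys: {missing}")
    pairs: dict[str, tuple[list[float], list[float]]] = {}
    for (sample, code) in sorted(ix):
        pairs.setdefault(code, ([], []))
        pairs[code][0].append(ix[(sample, code)])
        pairs[code][1].append(iy[(sample, code)])
    return agreement_report(pairs, label_x, label_y)


def plot_agreement(report: AgreementReport, path: str) -> None:
    """Scatter plots (one panel per component) of the paired series."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    codes = list(report.pairs)
    fig, axes = plt.subplots(1, len(codes), figsize=(3 * len(codes), 3), squeeze=False)
    for ax, code in zip(axes[0], codes):
        x, y = report.pairs[code]
        ax.scatter(x, y, s=18)
        lim = [min(min(x), min(y)), max(max(x), max(y))]
        ax.plot(lim, lim, lw=0.8, color="grey")
        ax.set_title(f"{code}: r = {report.r[code]:.3f}")
        ax.set_xlabel(report.label_x)
        ax.set_ylabel(report.label_y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
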