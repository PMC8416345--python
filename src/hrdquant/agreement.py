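"""Agreement statistics between two annotation sources.

Implements the method-comparison toolkit used to judge rater-vs-rater and
rater-vs-algorithm consistency: per-volume Dice overlap, intraclass
correlation ICC(2,1) (two-way random effects, absolute agreement, single
measures, with an F-based 95% CI), Pearson correlation with its t-test
p-value, and Bland–Altman mean difference with 95% limits of agreement
(mean ± 1.96 x SD of the paired differences, n−1 denominator).

The ICC is computed from the two-way ANOVA mean squares

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E) / n)

where MS_R, MS_C, MS_E are the row (subject), column (rater) and error
mean squares over an n x k table. The consistency form ICC(3,1) is
available via ``model="consistency"``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CLASSES, REGIONS, HRDSummary
from .volume_io import LabelMask


@dataclasses.dataclass
class PairedSeries:
    """Per-volume values of one parameter from two methods."""

    a: np.ndarray
    b: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired series must be equal-length 1D vectors")
        if len(self.a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("paired series must be finite")

    @property
    def n(self) -> int:
        return len(self.a)


def dice(mask_a: np.ndarray | LabelMask, mask_b: np.ndarray | LabelMask,
         class_label: int | None = None) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) for one class (None = any HRD).

    Defined as 1.0 when both selections are empty (vacuous agreement on a
    lesion-free scan).
    """
    a = mask_a.labels if isinstance(mask_a, LabelMask) else np.asarray(mask_a)
    b = mask_b.labels if isinstance(mask_b, LabelMask) else np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa = (a > 0) if class_label is None else (a == class_label)
    sb = (b > 0) if class_label is None else (b == class_label)
    denom = int(sa.sum()) + int(sb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(sa, sb).sum()) / denom


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Row, column and error mean squares of an n x k two-way table."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((table - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc(series: PairedSeries, model: str = "absolute", alpha: float = 0.05) -> dict:
    """Single-measures intraclass correlation with a 95% CI.

    ``model="absolute"`` gives ICC(2,1) (two-way random, absolute
    agreement); ``"consistency"`` gives ICC(3,1). The CI follows the
    F-distribution construction of McGraw & Wong. Zero total variance
    makes the ICC undefined and returns NaN estimates.
    """
    table = np.column_stack([series.a, series.b])
    n, k = table.shape
    if np.ptp(table) == 0:
        return {"icc": float("nan"), "ci95": (float("nan"), float("nan")),
                "model": model, "defined": False}
    msr, msc, mse = _two_way_mean_squares(table)
    if model == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse if mse > 0 else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
    elif model == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est = (msr - mse) / denom
        # F-based CI with Satterthwaite df on the column/error composite
        if est < 1 and mse > 0:
            a_ = (k * est) / (n * (1 - est))
            b_ = 1 + (k * est * (n - 1)) / (n * (1 - est))
            v = ((a_ * msc + b_ * mse) ** 2
                 / ((a_ * msc) ** 2 / (k - 1)
                    + (b_ * mse) ** 2 / ((n - 1) * (k - 1))))
            f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_lo * mse)
                  / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_hi * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
        else:
            lo, hi = float("nan"), float("nan")
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return {"icc": float(est), "ci95": (float(lo), float(hi)),
            "model": model, "defined": True}


def pearson(series: PairedSeries) -> dict:
    """Sample Pearson correlation with a two-sided t-test p (n−2 df)."""
    if series.n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(series.a) == 0 or np.ptp(series.b) == 0:
        return {"r": float("nan"), "p": float("nan"), "defined": False}
    r, p = stats.pearsonr(series.a, series.b)
    return {"r": float(r), "p": float(p), "defined": True}


def bland_altman(series: PairedSeries) -> dict:
    """Mean difference A−B, SD of differences (n−1), LOA mean ± 1.96 SD."""
    diff = series.a - series.b
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    return {"mean_diff": mean_diff, "sd_diff": sd_diff,
            "loa_lower": mean_diff - 1.96 * sd_diff,
            "loa_upper": mean_diff + 1.96 * sd_diff,
            "means": (series.a + series.b) / 2.0, "diffs": diff}


def dice_area_correlation(dice_values: Sequence[float], areas: Sequence[float]) -> dict:
    """Pearson correlation between per-volume Dice and total HRD area."""
    return pearson(PairedSeries(np.asarray(dice_values, float),
                                np.asarray(areas, float), name="dice_vs_area"))


@dataclasses.dataclass
class AgreementReport:
    """All agreement statistics between two annotation sources."""

    dice_mean_sd: dict[str, tuple[float, float]]
    per_parameter: dict[str, dict[str, dict]]  # roi -> parameter -> stats
    n_volumes: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for roi, params in self.per_parameter.items():
            for param, st in params.items():
                rows.append({
                    "roi": roi, "parameter": param,
                    "icc": st["icc"]["icc"],
                    "icc_ci_lo": st["icc"]["ci95"][0], "icc_ci_hi": st["icc"]["ci95"][1],
                    "pearson_r": st["pearson"]["r"], "pearson_p": st["pearson"]["p"],
                    "mean_diff": st["bland_altman"]["mean_diff"],
                    "loa_lower": st["bland_altman"]["loa_lower"],
                    "loa_upper": st["bland_altman"]["loa_upper"],
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {"n_volumes": self.n_volumes,
               "dice": {k: {"mean": v[0], "sd": v[1]} for k, v in self.dice_mean_sd.items()},
               "parameters": {}}
        for roi, params in self.per_parameter.items():
            out["parameters"][roi] = {}
            for param, st in params.items():
                ba = st["bland_altman"]
                out["parameters"][roi][param] = {
                    "icc": st["icc"]["icc"], "icc_ci95": list(st["icc"]["ci95"]),
                    "pearson_r": st["pearson"]["r"], "pearson_p": st["pearson"]["p"],
                    "mean_diff": ba["mean_diff"],
                    "loa": [ba["loa_lower"], ba["loa_upper"]],
                }
        return out


PARAMETERS = tuple(f"{c}_{m}" for c in CLASSES for m in ("area_mm2", "count"))


def build_report(mask_pairs: Sequence[tuple[LabelMask | np.ndarray, LabelMask | np.ndarray]],
                 summaries_a: Sequence[HRDSummary],
                 summaries_b: Sequence[HRDSummary],
                 icc_model: str = "absolute") -> AgreementReport:
    """Assemble Dice / ICC / Pearson / Bland–Altman statistics.

    Six parameters ({area, count} x {total, hard exudate, small HRD}) are
    evaluated in each region; Dice is reported as mean (SD) across volumes
    for the any-HRD mask and each class.
    """
    if not (len(mask_pairs) == len(summaries_a) == len(summaries_b)):
        raise ValueError("mask pairs and the two summary lists must align")
    n = len(summaries_a)
    dice_by_class = {"total_hrd": [], "hard_exudate": [], "small_hrd": []}
    for a, b in mask_pairs:
        dice_by_class["total_hrd"].append(dice(a, b, None))
        dice_by_class["hard_exudate"].append(dice(a, b, 1))
        dice_by_class["small_hrd"].append(dice(a, b, 2))
    dice_mean_sd = {k: (float(np.mean(v)), float(np.std(v, ddof=1)) if n > 1 else 0.0)
                    for k, v in dice_by_class.items()}

    per_parameter: dict[str, dict[str, dict]] = {}
    for roi in REGIONS:
        per_parameter[roi] = {}
        for cls in CLASSES:
            for metric in ("area_mm2", "count"):
                key = f"{roi}/{cls}/{metric}"
                series = PairedSeries(
                    np.array([s.series()[key] for s in summaries_a]),
                    np.array([s.series()[key] for s in summaries_b]),
                    name=f"{cls}_{metric}",
                    units="mm2" if metric == "area_mm2" else "count",
                )
                per_parameter[roi][f"{cls}_{metric}"] = {
                    "icc": icc(series, model=icc_model),
                    "pearson": pearson(series) if series.n >= 3 else
                        {"r": float("nan"), "p": float("nan"), "defined": False},
                    "bland_altman": bland_altman(series),
                }
    return AgreementReport(dice_mean_sd=dice_mean_sd, per_parameter=per_parameter,
                           n_volumes=n)
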