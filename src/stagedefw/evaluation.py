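"""Accuracy evaluation for birth weight prediction models.

Two complementary frameworks:

* percentage-error statistics — signed percentage error
  PE = (EFW - birth weight) / birth weight * 100; systematic error is
  the mean PE, random error the SD of PE, plus RMSE in grams, the
  proportions of predictions within 1/5/10% of birth weight and a
  one-sample t-test of the mean PE against zero;
* diagnostic accuracy — confusion matrices for detecting SGA, LGA and
  macrosomia from the EFW, summarised as sensitivity, specificity,
  PPV, NPV, likelihood ratios and overall accuracy.

A confusion-matrix reconstruction utility inverts rounded published
metric rows back to the unique integer matrix that produced them, which
lets printed table rows serve as exact fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biometry import (
    MACROSOMIA_THRESHOLD_G,
    CentileReference,
    Cohort,
)

__all__ = [
    "AccuracyReport",
    "ConfusionMatrix",
    "DiagnosticReport",
    "ModelComparison",
    "percentage_error",
    "accuracy_report",
    "diagnostic_report",
    "classify_predictions",
    "reconstruct_confusion",
    "compare_models",
    "round_half_away",
]

OUTCOMES = ("SGA", "LGA", "macrosomia")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def percentage_error(efw_g, birth_weight_g):
    """Signed percentage error (EFW - BW) / BW * 100. Vectorised."""
    bw = np.asarray(birth_weight_g, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("birth weight must be strictly positive")
    efw = np.asarray(efw_g, dtype=float)
    out = (efw - bw) / bw * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AccuracyReport:
    """Percentage-error accuracy summary for one model on one group."""

    n: int
    systematic_error_pct: float  # mean PE
    random_error_pct: float      # SD of PE (sample SD)
    rmse_g: float
    within_pct: Mapping[int, float]  # k -> proportion with |PE| <= k
    p_vs_zero: float             # two-sided one-sample t-test of PE vs 0

    def __post_init__(self):
        ks = sorted(self.within_pct)
        props = [self.within_pct[k] for k in ks]
        if any(b < a - 1e-12 for a, b in zip(props, props[1:])):
            raise ValueError("within-k proportions must be non-decreasing in k")

    def row(self) -> dict:
        """Flat dict with percent fields rounded table-style (2 dp)."""
        d = {
            "n": self.n,
            "systematic_error_pct": round_half_away(self.systematic_error_pct),
            "random_error_pct": round_half_away(self.random_error_pct),
            "rmse_g": round_half_away(self.rmse_g),
            "p_vs_zero": self.p_vs_zero,
        }
        for k, v in sorted(self.within_pct.items()):
            d[f"within_{k}pct"] = round_half_away(100.0 * v)
        return d


def accuracy_report(
    efw_g: Sequence[float],
    birth_weight_g: Sequence[float],
    within: Sequence[int] = (1, 5, 10),
) -> AccuracyReport:
    """Percentage-error statistics of a prediction series.

    Within-k% uses the inclusive convention |PE| <= k. The t-test
    p-value is NaN when the PE series is degenerate (zero variance).
    """
    efw = np.asarray(efw_g, dtype=float)
    bw = np.asarray(birth_weight_g, dtype=float)
    if efw.shape != bw.shape:
        raise ValueError(f"shape mismatch: {efw.shape} vs {bw.shape}")
    if efw.size < 2:
        raise ValueError("need at least two observations")
    pe = percentage_error(efw, bw)
    sd = float(np.std(pe, ddof=1))
    if sd > 0:
        p = float(stats.ttest_1samp(pe, 0.0).pvalue)
    else:
        p = float("nan")
    return AccuracyReport(
        n=int(efw.size),
        systematic_error_pct=float(np.mean(pe)),
        random_error_pct=sd,
        rmse_g=float(np.sqrt(np.mean((efw - bw) ** 2))),
        within_pct={int(k): float(np.mean(np.abs(pe) <= k)) for k in within},
        p_vs_zero=p,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion matrix cells must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must have at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticReport:
    """Diagnostic accuracy of EFW-based detection of one birth outcome.

    Proportions are stored on the 0-1 scale; undefined ratios (zero
    denominators) are NaN rather than silently zero.
    """

    outcome: str
    cm: ConfusionMatrix
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    overall_accuracy: float

    def row(self) -> dict:
        """Percent-scale row rounded to 2 decimals, printed-table style."""
        return {
            "outcome": self.outcome,
            "sensitivity_pct": round_half_away(100 * self.sensitivity),
            "specificity_pct": round_half_away(100 * self.specificity),
            "ppv_pct": round_half_away(100 * self.ppv),
            "npv_pct": round_half_away(100 * self.npv),
            "lr_pos": round_half_away(self.lr_pos),
            "lr_neg": round_half_away(self.lr_neg),
            "overall_accuracy_pct": round_half_away(100 * self.overall_accuracy),
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_report(cm: ConfusionMatrix, outcome: str = "") -> DiagnosticReport:
    """All seven diagnostic metrics from a confusion matrix.

    Overall accuracy is (TP + TN) / total. Likelihood ratios follow
    +LR = sens/(1-spec), -LR = (1-sens)/spec.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return DiagnosticReport(
        outcome=outcome,
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        lr_pos=_ratio(sens, 1.0 - spec),
        lr_neg=_ratio(1.0 - sens, spec),
        overall_accuracy=(cm.tp + cm.tn) / cm.total,
    )


def classify_predictions(
    efw_g: Sequence[float],
    records: Cohort | pd.DataFrame,
    ref: CentileReference,
) -> dict[str, ConfusionMatrix]:
    """Confusion matrices for SGA / LGA / macrosomia detection.

    Predicted labels threshold the EFW exactly as true labels threshold
    the birth weight: predicted SGA iff EFW < P10 at the completed
    week, predicted LGA iff EFW > P90, predicted macrosomia iff
    EFW >= 4000 g.
    """
    df = records.data if isinstance(records, Cohort) else records
    efw = np.asarray(efw_g, dtype=float)
    bw = df["birth_weight_g"].to_numpy(float)
    if efw.shape != bw.shape:
        raise ValueError("efw and records length mismatch")
    p10, p90 = ref.thresholds(df["ga_weeks"].to_numpy(float))

    pairs = {
        "SGA": (bw < p10, efw < p10),
        "LGA": (bw > p90, efw > p90),
        "macrosomia": (bw >= MACROSOMIA_THRESHOLD_G, efw >= MACROSOMIA_THRESHOLD_G),
    }
    out = {}
    for name, (truth, pred) in pairs.items():
        out[name] = ConfusionMatrix(
            tp=int(np.sum(truth & pred)),
            fp=int(np.sum(~truth & pred)),
            fn=int(np.sum(truth & ~pred)),
            tn=int(np.sum(~truth & ~pred)),
        )
    return out


def reconstruct_confusion(
    sensitivity_pct: float,
    specificity_pct: float,
    ppv_pct: float,
    npv_pct: float,
    total_n: int,
    ndigits: int = 2,
) -> list[ConfusionMatrix]:
    """Invert rounded percent metrics to integer confusion matrices.

    Exhaustively searches all integer (tp, fn, fp, tn) with
    tp + fn + fp + tn = total_n whose recomputed sensitivity,
    specificity, PPV and NPV round (half away from zero) to the given
    values. Published table rows typically admit a unique solution.
    """
    if total_n < 4:
        raise ValueError("total_n must be at least 4")
    for v in (sensitivity_pct, specificity_pct, ppv_pct, npv_pct):
        if not 0 <= v <= 100:
            raise ValueError("metrics must be percentages in [0, 100]")
    half = 0.5 / 10 ** ndigits + 1e-12

    def matches(values: np.ndarray, target: float) -> np.ndarray:
        scale = 10 ** ndigits
        rounded = np.floor(values * scale + 0.5) / scale
        return np.abs(rounded - target) < half

    solutions = []
    for pos in range(1, total_n):
        neg = total_n - pos
        tp = np.arange(pos + 1)
        tp = tp[matches(100.0 * tp / pos, sensitivity_pct)]
        if tp.size == 0:
            continue
        tn = np.arange(neg + 1)
        tn = tn[matches(100.0 * tn / neg, specificity_pct)]
        if tn.size == 0:
            continue
        TP, TN = np.meshgrid(tp, tn, indexing="ij")
        FN = pos - TP
        FP = neg - TN
        pred_pos = TP + FP
        pred_neg = TN + FN
        ok = (pred_pos > 0) & (pred_neg > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ok &= matches(100.0 * TP / np.maximum(pred_pos, 1), ppv_pct)
            ok &= matches(100.0 * TN / np.maximum(pred_neg, 1), npv_pct)
        for tp_i, fp_i, fn_i, tn_i in zip(TP[ok], FP[ok], FN[ok], TN[ok]):
            solutions.append(
                ConfusionMatrix(tp=int(tp_i), fp=int(fp_i), fn=int(fn_i), tn=int(tn_i))
            )
    return solutions


@dataclass(frozen=True)
class ModelComparison:
    """Relative comparison of accuracy reports against a reference model."""

    reference: str
    table: pd.DataFrame
    min_rel_decrease_abs_se_pct: float
    min_rel_decrease_rmse_pct: float


def compare_models(
    reports: Mapping[str, AccuracyReport],
    reference: str,
    alpha: float = 0.05,
) -> ModelComparison:
    """Compare named accuracy reports against a designated reference.

    The headline quantities are the minimum relative decrease achieved
    by the reference over every other model, for the absolute
    systematic error and for the RMSE:
    100 * (min_others(metric) - metric_ref) / metric_ref.
    Models whose systematic error differs from zero at ``alpha`` are
    flagged (the printed tables' asterisk).
    """
    if reference not in reports:
        raise KeyError(f"reference model {reference!r} not among reports")
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "model": name,
                "systematic_error_pct": rep.systematic_error_pct,
                "abs_systematic_error_pct": abs(rep.systematic_error_pct),
                "random_error_pct": rep.random_error_pct,
                "rmse_g": rep.rmse_g,
                "significant_vs_zero": bool(
                    np.isfinite(rep.p_vs_zero) and rep.p_vs_zero < alpha
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    others = table.drop(index=reference)
    ref_row = table.loc[reference]

    def rel_decrease(col: str) -> float:
        ref_val = ref_row[col]
        if ref_val == 0:
            return float("inf")
        return float(100.0 * (others[col].min() - ref_val) / ref_val)

    return ModelComparison(
        reference=reference,
        table=table,
        min_rel_decrease_abs_se_pct=rel_decrease("abs_systematic_error_pct"),
        min_rel_decrease_rmse_pct=rel_decrease("rmse_g"),
    )
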