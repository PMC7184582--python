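"""Diagnostic-performance battery: confusion tables against the full-mouth
reference, the standard indicator set, DOR with log-scale confidence
interval, hard-label binary and multiclass (pairwise one-vs-one) ROC AUC,
and the 2012-to-2018 staging reclassification cross-tab.

All rate-type indicators live on the [0, 1] proportion scale internally;
tables for reporting multiply by 100. A hard-label classifier has a single
operating point, so its ROC curve is the three-point polygon
{(0,0), (1-specificity, sensitivity), (1,1)} and its AUC is exactly
(sensitivity + specificity) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .case_definitions import CDC_AAP_2012, EFP_AAP_2018, Params2012, Params2018
from .chart_model import PeriodontalChart
from .prp import PRPProtocol, diagnose_under_protocol, make_protocol

__all__ = [
    "ConfusionCounts",
    "Estimate",
    "IndicatorSet",
    "DORResult",
    "confusion",
    "counts_from_rates",
    "indicators",
    "dor_ci",
    "binary_auc_from_labels",
    "multiclass_auc",
    "reclassification_table",
    "crosstab_to_edges",
    "evaluate_protocols",
    "tidy_indicator_table",
]

NA = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 contingency counts of a test against a reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a two-sided confidence interval."""

    value: float
    ci_low: float = NA
    ci_high: float = NA


@dataclass(frozen=True)
class IndicatorSet:
    sensitivity: Estimate
    specificity: Estimate
    accuracy: Estimate
    precision: Estimate
    youden: Estimate
    f1: Estimate
    mcc: Estimate
    auc: Estimate
    dor: Estimate
    log10_dor: float
    dor_corrected: bool

    def as_dict(self) -> dict[str, Estimate]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "youden": self.youden,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
            "dor": self.dor,
            "log10_dor": Estimate(self.log10_dor),
        }


def _as_binary(labels: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D label vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(int)


def confusion(reference: Sequence[int], test: Sequence[int]) -> ConfusionCounts:
    """2x2 counts of binary test labels against binary reference labels."""
    ref = _as_binary(reference, "reference")
    tst = _as_binary(test, "test")
    if ref.shape != tst.shape:
        raise ValueError("reference and test must have equal length")
    return ConfusionCounts(
        tp=int(((ref == 1) & (tst == 1)).sum()),
        fp=int(((ref == 0) & (tst == 1)).sum()),
        tn=int(((ref == 0) & (tst == 0)).sum()),
        fn=int(((ref == 1) & (tst == 0)).sum()),
    )


def counts_from_rates(
    sensitivity: float,
    specificity: float,
    n_positive: int = 1000,
    n_negative: int = 1000,
) -> ConfusionCounts:
    """Reconstruct a contingency table realizing given sensitivity and
    specificity at chosen margins (counts rounded to nearest integer).

    Useful for re-deriving rate-only published results: sensitivity,
    specificity and every prevalence-free statistic derived from them (Youden,
    DOR, hard-label AUC) are recovered up to the rounding of the margins.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    return ConfusionCounts(tp=tp, fn=n_positive - tp, tn=tn, fp=n_negative - tn)


def _wilson(x: int, n: int, ci_level: float) -> Estimate:
    """Wilson score interval for a binomial proportion; NA when n == 0."""
    if n == 0:
        return Estimate(NA, NA, NA)
    lo, hi = proportion_confint(x, n, alpha=1 - ci_level, method="wilson")
    return Estimate(x / n, float(lo), float(hi))


def dor_ci(c: ConfusionCounts, z: float = 1.96) -> "DORResult":
    """Diagnostic odds ratio (TP/FN)/(FP/TN) with a log-scale CI.

    The CI is log DOR +/- z * SE(log DOR) with
    SE = sqrt(1/TP + 1/TN + 1/FP + 1/FN), exponentiated back. When any cell
    is zero the Haldane-Anscombe correction adds 0.5 to all four cells and
    the result is flagged ``corrected``.
    """
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    corrected = 0 in (c.tp, c.fp, c.tn, c.fn)
    if corrected:
        tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
    dor = (tp / fn) / (fp / tn)
    se = math.sqrt(1 / tp + 1 / tn + 1 / fp + 1 / fn)
    log_dor = math.log(dor)
    lo = math.exp(log_dor - z * se)
    hi = math.exp(log_dor + z * se)
    return DORResult(dor=dor, ci_low=lo, ci_high=hi,
                     log10_dor=math.log10(dor), corrected=corrected)


@dataclass(frozen=True)
class DORResult:
    dor: float
    ci_low: float
    ci_high: float
    log10_dor: float
    corrected: bool


def binary_auc_from_labels(c: ConfusionCounts) -> float:
    """AUC of a hard-label classifier: trapezoidal area under the
    three-point ROC, identically (sensitivity + specificity) / 2.

    NA when the reference has no positives or no negatives.
    """
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        return NA
    sens = c.tp / pos
    spec = c.tn / neg
    return (sens + spec) / 2.0


def indicators(c: ConfusionCounts, ci_level: float = 0.95) -> IndicatorSet:
    """The full indicator battery from one confusion table.

    Proportion indicators (sensitivity, specificity, accuracy, precision,
    F1) get Wilson score intervals on their natural binomial denominators;
    Youden and AUC intervals are propagated from the sensitivity and
    specificity bounds; the DOR interval is on the log scale. Indicators with
    an empty denominator are reported as NA, as is the MCC interval (no
    closed-form CI is in common use).
    """
    sens = _wilson(c.tp, c.tp + c.fn, ci_level)
    spec = _wilson(c.tn, c.tn + c.fp, ci_level)
    acc = _wilson(c.tp + c.tn, c.total, ci_level)
    prec = _wilson(c.tp, c.tp + c.fp, ci_level)
    f1 = _wilson(2 * c.tp, 2 * c.tp + c.fp + c.fn, ci_level)

    if math.isnan(sens.value) or math.isnan(spec.value):
        youden = Estimate(NA, NA, NA)
        auc = Estimate(NA, NA, NA)
    else:
        youden = Estimate(
            sens.value + spec.value - 1.0,
            sens.ci_low + spec.ci_low - 1.0,
            sens.ci_high + spec.ci_high - 1.0,
        )
        auc = Estimate(
            (sens.value + spec.value) / 2.0,
            (sens.ci_low + spec.ci_low) / 2.0,
            (sens.ci_high + spec.ci_high) / 2.0,
        )

    num = c.tp * c.tn - c.fp * c.fn
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = Estimate(num / math.sqrt(den) if den > 0 else NA, NA, NA)

    d = dor_ci(c, z=abs(_z_for(ci_level)))
    return IndicatorSet(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        youden=youden,
        f1=f1,
        mcc=mcc,
        auc=auc,
        dor=Estimate(d.dor, d.ci_low, d.ci_high),
        log10_dor=d.log10_dor,
        dor_corrected=d.corrected,
    )


def _z_for(ci_level: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(0.5 + ci_level / 2.0))


def _as_stages(labels: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D stage vector")
    if not np.isin(arr, (0, 1, 2, 3)).all():
        raise ValueError(f"{name} must contain only stages 0-3")
    return arr.astype(int)


def multiclass_auc(reference: Sequence[int], test: Sequence[int]) -> float:
    """Hand-Till style multiclass AUC from hard stage labels.

    For every unordered pair of classes present in the reference, the sample
    is restricted to that pair; each class of the pair in turn plays
    "positive" with the one-hot indicator of the test label as the score,
    giving a hard-label binary AUC, and the two directions are averaged. The
    overall value is the unweighted mean over class pairs. With exactly two
    classes present this reduces to ``binary_auc_from_labels`` on the
    corresponding 2x2 table.
    """
    ref = _as_stages(reference, "reference")
    tst = _as_stages(test, "test")
    if ref.shape != tst.shape:
        raise ValueError("reference and test must have equal length")
    classes = np.unique(ref)
    if classes.size < 2:
        raise ValueError("reference must contain at least two classes")

    pair_aucs = []
    for i, j in combinations(classes.tolist(), 2):
        mask = (ref == i) | (ref == j)
        r, t = ref[mask], tst[mask]
        directions = []
        for pos in (i, j):
            c = confusion((r == pos).astype(int), (t == pos).astype(int))
            directions.append(binary_auc_from_labels(c))
        pair_aucs.append(float(np.mean(directions)))
    return float(np.mean(pair_aucs))


def reclassification_table(
    stages_from: Sequence[int], stages_to: Sequence[int]
) -> np.ndarray:
    """4x4 cross-tab of ordinal stages; rows = first (e.g. 2012) diagnosis,
    columns = second (e.g. 2018). Underlies the alluvial re-classification
    diagram."""
    a = _as_stages(stages_from, "stages_from")
    b = _as_stages(stages_to, "stages_to")
    if a.shape != b.shape:
        raise ValueError("stage vectors must have equal length")
    table = np.zeros((4, 4), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def crosstab_to_edges(table: np.ndarray) -> pd.DataFrame:
    """Long-format edge list (source_stage, target_stage, count) of a 4x4
    cross-tab, suitable for alluvial plotting tools."""
    table = np.asarray(table)
    if table.shape != (4, 4):
        raise ValueError("expected a 4x4 table")
    rows = [
        {"source_stage": i, "target_stage": j, "count": int(table[i, j])}
        for i in range(4)
        for j in range(4)
    ]
    return pd.DataFrame(rows)


def _estimate_columns(name: str, est: Estimate) -> dict[str, float]:
    return {name: est.value, f"{name}_lo": est.ci_low, f"{name}_hi": est.ci_high}


def evaluate_protocols(
    charts: Sequence[PeriodontalChart],
    definitions: Sequence[str] = (EFP_AAP_2018, CDC_AAP_2012),
    protocols: Sequence[PRPProtocol | str] = (),
    ci_level: float = 0.95,
    params_2012: Params2012 = Params2012(),
    params_2018: Params2018 = Params2018(),
) -> pd.DataFrame:
    """Evaluate each protocol against the same definition's full-mouth
    reference over a chart collection.

    Returns one row per (definition, protocol) with the presence-level
    indicator battery, the staging multiclass AUC and per-stage one-vs-rest
    precision (positive predictive value of each predicted stage).
    """
    if len(charts) == 0:
        raise ValueError("need at least one chart")
    protos = [
        p if isinstance(p, PRPProtocol) else make_protocol(p) for p in protocols
    ]
    if not protos:
        raise ValueError("need at least one protocol")
    full = make_protocol("FULL_MOUTH")

    rows = []
    for definition in definitions:
        ref_stages = np.array(
            [
                diagnose_under_protocol(c, full, definition, params_2012, params_2018).stage
                for c in charts
            ]
        )
        ref_case = (ref_stages >= 1).astype(int)
        for proto in protos:
            if proto.name == "FULL_MOUTH":
                test_stages = ref_stages
            else:
                test_stages = np.array(
                    [
                        diagnose_under_protocol(
                            c, proto, definition, params_2012, params_2018
                        ).stage
                        for c in charts
                    ]
                )
            test_case = (test_stages >= 1).astype(int)
            c2 = confusion(ref_case, test_case)
            ind = indicators(c2, ci_level=ci_level)
            row: dict[str, object] = {
                "definition": definition,
                "protocol": proto.name,
                "n": len(charts),
                "tp": c2.tp,
                "fp": c2.fp,
                "tn": c2.tn,
                "fn": c2.fn,
            }
            for name, est in ind.as_dict().items():
                row.update(_estimate_columns(name, est))
            row["dor_corrected"] = ind.dor_corrected
            try:
                row["staging_auc"] = multiclass_auc(ref_stages, test_stages)
            except ValueError:
                row["staging_auc"] = NA
            for stage in range(4):
                n_pred = int((test_stages == stage).sum())
                n_hit = int(((test_stages == stage) & (ref_stages == stage)).sum())
                est = _wilson(n_hit, n_pred, ci_level)
                row.update(_estimate_columns(f"precision_stage_{stage}", est))
            rows.append(row)
    return pd.DataFrame(rows)


def tidy_indicator_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide evaluation table into tidy form:
    definition, protocol, indicator, estimate, ci_lo, ci_hi."""
    base = [
        "sensitivity", "specificity", "accuracy", "precision", "youden",
        "f1", "mcc", "auc", "dor", "log10_dor", "staging_auc",
        "precision_stage_0", "precision_stage_1", "precision_stage_2",
        "precision_stage_3",
    ]
    records = []
    for _, row in wide.iterrows():
        for name in base:
            records.append(
                {
                    "definition": row["definition"],
                    "protocol": row["protocol"],
                    "indicator": name,
                    "estimate": row.get(name, NA),
                    "ci_lo": row.get(f"{name}_lo", NA),
                    "ci_hi": row.get(f"{name}_hi", NA),
                }
            )
    return pd.DataFrame(records)
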