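"""Patient-level evaluation statistics.

The surveillance system is evaluated like a diagnostic test: each patient in
the evaluated population is either detected (>= 1 event) or not, and either
HABSI-positive or not by the reference standard, giving a 2x2 confusion
matrix.  From it: sensitivity, specificity, PPV, NPV with exact
(Clopper-Pearson) 95% CIs, and Cohen's kappa with an asymptotic CI.

Also here: Pearson correlation of count series (agreement between two
surveillance sources by department or by time), incidence rates per 1000
patients / patient-days, and the confirmation-delay statistics (per-month
mean/SD of days from first positive specimen log-in to human confirmation;
the period mean is the unweighted mean of monthly means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .records import HabsiEvent

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "PerformanceMetrics",
    "patient_level_confusion",
    "compute_metrics",
    "cohen_kappa",
    "count_correlation",
    "delay_stats",
    "incidence",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """Relabel classes: positives become negatives and vice versa."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion (or kappa) with its 95% CI.

    ``value`` is None when the denominator is empty (undefined, never NaN).
    ``pct`` / ``rounded`` give the display form: percentages at 2 decimals,
    half-up.
    """

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def pct(self) -> float | None:
        return None if self.value is None else round_half_up(self.value * 100.0)

    @property
    def rounded(self) -> float | None:
        return None if self.value is None else round_half_up(self.value)


@dataclass(frozen=True)
class PerformanceMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    kappa: MetricEstimate

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: MetricEstimate = getattr(self, name)
            out[name] = {
                "value": m.value,
                "pct": m.pct,
                "ci95": [m.ci_low, m.ci_high],
            }
        out["kappa"] = {
            "value": self.kappa.value,
            "rounded": self.kappa.rounded,
            "ci95": [self.kappa.ci_low, self.kappa.ci_high],
        }
        return out


def patient_level_confusion(
    detected: set[str], reference: set[str], population: set[str] | list[str]
) -> ConfusionMatrix:
    """Tabulate the patient-level 2x2 table.

    Every evaluated patient counts exactly once; a patient is "detected"
    when at least one event was emitted for them.  A detected or reference
    patient outside the population is a fatal labelling error.
    """
    pop = set(population)
    stray = (detected | reference) - pop
    if stray:
        raise ValueError(f"labels for patients outside the population: {sorted(stray)[:5]}")
    tp = len(detected & reference)
    fp = len(detected - reference)
    fn = len(reference - detected)
    tn = len(pop) - tp - fp - fn
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _proportion(successes: int, total: int, alpha: float = 0.05) -> MetricEstimate:
    if total == 0:
        return MetricEstimate(None)
    p = successes / total
    # Clopper-Pearson exact interval via the beta distribution
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, total - successes + 1)
    hi = 1.0 if successes == total else stats.beta.ppf(1 - alpha / 2, successes + 1, total - successes)
    return MetricEstimate(p, float(lo), float(hi))


def cohen_kappa(cm: ConfusionMatrix, alpha: float = 0.05) -> MetricEstimate:
    """Cohen's kappa for the 2x2 table with an asymptotic 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp+tn)/N and chance agreement
    p_e = [(tp+fn)(tp+fp) + (tn+fp)(tn+fn)] / N^2.  The CI uses the
    large-sample standard error sqrt(p_o (1-p_o) / (N (1-p_e)^2)), clipped
    to [-1, 1].
    """
    n = cm.total
    if n == 0:
        return MetricEstimate(None)
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n**2
    if p_e == 1.0:
        return MetricEstimate(None)
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    z = stats.norm.ppf(1 - alpha / 2)
    return MetricEstimate(kappa, max(-1.0, kappa - z * se), min(1.0, kappa + z * se))


def compute_metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """Sensitivity, specificity, PPV, NPV (Clopper-Pearson 95% CIs) and
    Cohen's kappa from a confusion matrix.

    A metric whose denominator is zero comes back flagged undefined
    (``value is None``) rather than propagating NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return PerformanceMetrics(
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn),
        specificity=_proportion(cm.tn, cm.tn + cm.fp),
        ppv=_proportion(cm.tp, cm.tp + cm.fp),
        npv=_proportion(cm.tn, cm.tn + cm.fn),
        kappa=cohen_kappa(cm),
    )


def count_correlation(series_a, series_b) -> tuple[float, float]:
    """Pearson product-moment correlation between two count series.

    Returns (r, two-sided p).  Requires equal length >= 3 and nonzero
    variance in both series; a degenerate series raises rather than
    returning NaN.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-d series with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def delay_stats(events: list[HabsiEvent]) -> pd.DataFrame:
    """Confirmation-delay statistics by month of confirmation.

    Delay for an event is whole days from the date of the first positive
    specimen log-in (the onset) to the date of confirmation.  Events
    without a confirmation date are ignored.  Returns one row per month
    (mean, sd, n) plus a ``period`` row whose mean is the unweighted mean
    of the monthly means and whose sd is the dispersion of those monthly
    means.
    """
    rows = []
    for e in events:
        if e.confirmation_ts is None:
            continue
        delay = (e.confirmation_ts.date() - e.onset_ts.date()).days
        if delay < 0:
            raise ValueError(f"event {e.event_id}: confirmation precedes onset")
        rows.append({"month": e.confirmation_ts.strftime("%Y-%m"), "delay_days": delay})
    if not rows:
        return pd.DataFrame(columns=["month", "mean", "sd", "n"])
    df = pd.DataFrame(rows)
    monthly = (
        df.groupby("month")["delay_days"]
        .agg(mean="mean", sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    period = pd.DataFrame(
        [
            {
                "month": "period",
                "mean": monthly["mean"].mean(),
                "sd": float(np.std(monthly["mean"], ddof=1)) if len(monthly) > 1 else 0.0,
                "n": int(monthly["n"].sum()),
            }
        ]
    )
    return pd.concat([monthly, period], ignore_index=True)


def incidence(n_events: int, denominator: float) -> float:
    """Episodes per 1000 units of ``denominator`` (patients or patient-days)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 1000.0 * n_events / denominator


def incidence_by_stratum(counts: dict, denominators: dict) -> pd.DataFrame:
    """Per-stratum rates per 1000, with a pooled row and the min-max range.

    A stratum with zero denominator gets rate None (flagged undefined) and
    is excluded from the pooled rate and the range.
    """
    rows = []
    for stratum in sorted(set(counts) | set(denominators)):
        n = counts.get(stratum, 0)
        d = denominators.get(stratum, 0)
        rows.append(
            {
                "stratum": stratum,
                "events": n,
                "denominator": d,
                "rate_per_1000": incidence(n, d) if d > 0 else None,
            }
        )
    df = pd.DataFrame(rows, columns=["stratum", "events", "denominator", "rate_per_1000"])
    defined = df.dropna(subset=["rate_per_1000"])
    pooled_denom = defined["denominator"].sum()
    pooled = {
        "stratum": "pooled",
        "events": int(defined["events"].sum()),
        "denominator": pooled_denom,
        "rate_per_1000": incidence(int(defined["events"].sum()), pooled_denom)
        if pooled_denom > 0
        else None,
    }
    summary = pd.DataFrame([pooled])
    if len(defined):
        summary["rate_min"] = defined["rate_per_1000"].min()
        summary["rate_max"] = defined["rate_per_1000"].max()
    return pd.concat([df, summary], ignore_index=True)
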