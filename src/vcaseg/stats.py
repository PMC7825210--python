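"""Longitudinal treatment-monitoring summaries and the Welch two-sample test.

Per-day cross-subject means and standard deviations of vessel length and
width are summarized, the change between a reference day and a final day is
expressed as a percent change of the means, and the two days are compared
with an unpaired two-tailed Welch t-test. Welch's form (no pooled variance)
is used unconditionally so no data-dependent variance pre-test is involved;
"average" always means the arithmetic mean. A paired variant is available
behind a flag for repeated-measures designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as _student_t

from .errors import DegenerateDataError, MissingDayError, SampleSizeError, ValidationError
from .quantify import VesselMetrics, percent_change


@dataclass(frozen=True)
class TimeSeriesRecord:
    """One (subject, day) observation; day 0 is pre-treatment."""

    subject_id: str
    day: int
    metrics: VesselMetrics

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class TTestResult:
    """Welch unpaired two-tailed t-test summary."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Unpaired two-tailed t-test with Welch's correction.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b); degrees of freedom by
    Welch-Satterthwaite; p from the Student-t survival function. Sample
    standard deviations use the n-1 denominator.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError(f"each group needs >= 2 values, got {a.size} and {b.size}")
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            raise DegenerateDataError("both groups constant and equal: t undefined")
        # Constant groups with different means: infinitely significant.
        return TTestResult(math.copysign(math.inf, ma - mb), float(na + nb - 2), 0.0,
                           ma, mb, math.sqrt(va), math.sqrt(vb), na, nb)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(_student_t.sf(abs(t), df))
    return TTestResult(t, df, p, ma, mb, math.sqrt(va), math.sqrt(vb), na, nb)


def paired_ttest(before: Sequence[float], after: Sequence[float]) -> TTestResult:
    """Paired variant (test on within-subject differences)."""
    a = np.asarray(before, dtype=np.float64)
    b = np.asarray(after, dtype=np.float64)
    if a.size != b.size:
        raise ValidationError("paired test requires equally sized groups")
    if a.size < 2:
        raise SampleSizeError("paired test needs >= 2 pairs")
    d = b - a
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if d.mean() == 0.0:
            raise DegenerateDataError("all paired differences zero: t undefined")
        return TTestResult(math.copysign(math.inf, float(d.mean())), float(a.size - 1),
                           0.0, float(a.mean()), float(b.mean()),
                           float(a.std(ddof=1)), float(b.std(ddof=1)), a.size, b.size)
    t = float(d.mean()) / (sd / math.sqrt(d.size))
    df = float(d.size - 1)
    p = 2.0 * float(_student_t.sf(abs(t), df))
    return TTestResult(t, df, p, float(a.mean()), float(b.mean()),
                       float(a.std(ddof=1)), float(b.std(ddof=1)), a.size, b.size)


def significance_label(p: float) -> str:
    """Figure-legend label: '**' for p < 0.01, '*' for p < 0.05, else 'ns'."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class MonitorResult:
    """Study summary: per-day table, day-vs-day changes, and tests."""

    per_day: pd.DataFrame
    percent_changes: dict[str, float]
    tests: dict[str, TTestResult] | None
    labels: dict[str, str] | None
    note: str | None
    day_reference: int
    day_final: int


def _records_to_frame(table: Iterable[TimeSeriesRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        required = {"subject_id", "day", "length_px", "width_px"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"study table missing columns: {sorted(missing)}")
    else:
        rows = [
            {
                "subject_id": rec.subject_id,
                "day": rec.day,
                "length_px": rec.metrics.length_px,
                "width_px": rec.metrics.width_px,
            }
            for rec in table
        ]
        df = pd.DataFrame(rows, columns=["subject_id", "day", "length_px", "width_px"])
    if df.empty:
        raise ValidationError("study table is empty")
    if df.duplicated(subset=["subject_id", "day"]).any():
        dups = df[df.duplicated(subset=["subject_id", "day"], keep=False)]
        raise ValidationError(f"duplicate (subject_id, day) rows: {dups[['subject_id', 'day']].values.tolist()}")
    # Canonical ordering makes every downstream float reduction independent
    # of the input row order.
    return df.sort_values(["day", "subject_id"], kind="mergesort").reset_index(drop=True)


def monitor(
    table: Iterable[TimeSeriesRecord] | pd.DataFrame,
    day_reference: int = 1,
    day_final: int = 7,
    paired: bool = False,
) -> MonitorResult:
    """Summarize a longitudinal study of vessel length and width.

    Produces per-day cross-subject mean and standard deviation for both
    parameters, the percent change of the ``day_final`` mean relative to the
    ``day_reference`` mean, and an unpaired two-tailed Welch test between the
    two days per parameter with '**'/'*' significance labels. Output does
    not depend on the row order of the input. When either day has fewer than
    two observations the tests are skipped with an "insufficient groups"
    note instead of failing.
    """
    df = _records_to_frame(table)
    per_day = (
        df.groupby("day")[["length_px", "width_px"]]
        .agg(["mean", "std", "count"])
        .sort_index()
    )
    per_day.columns = ["_".join(col) for col in per_day.columns]

    for day in (day_reference, day_final):
        if day not in per_day.index:
            raise MissingDayError(f"day {day} absent for all subjects")

    percent_changes = {}
    for param in ("length_px", "width_px"):
        ref_mean = per_day.loc[day_reference, f"{param}_mean"]
        fin_mean = per_day.loc[day_final, f"{param}_mean"]
        percent_changes[param] = percent_change(ref_mean, fin_mean)

    ref_rows = df[df["day"] == day_reference]
    fin_rows = df[df["day"] == day_final]
    tests: dict[str, TTestResult] | None = {}
    labels: dict[str, str] | None = {}
    note = None
    if len(ref_rows) < 2 or len(fin_rows) < 2:
        tests, labels = None, None
        note = "insufficient groups: t-test skipped (need >= 2 subjects per compared day)"
    else:
        for param in ("length_px", "width_px"):
            if paired:
                merged = ref_rows.merge(fin_rows, on="subject_id", suffixes=("_ref", "_fin"))
                res = paired_ttest(merged[f"{param}_ref"], merged[f"{param}_fin"])
            else:
                res = welch_ttest(ref_rows[param].to_numpy(), fin_rows[param].to_numpy())
            tests[param] = res
            labels[param] = significance_label(res.p_value)
    return MonitorResult(per_day, percent_changes, tests, labels, note,
                         day_reference, day_final)


def plot_monitor(result: MonitorResult, length_path, width_path) -> None:
    """Line plots of per-day mean +/- SD for length and width."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for param, path, ylab in (
        ("length_px", length_path, "vessel length (px)"),
        ("width_px", width_path, "vessel width (px)"),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        days = result.per_day.index.to_numpy()
        mean = result.per_day[f"{param}_mean"].to_numpy()
        sd = result.per_day[f"{param}_std"].to_numpy()
        ax.errorbar(days, mean, yerr=sd, marker="o", capsize=3)
        ax.set_xlabel("treatment day")
        ax.set_ylabel(ylab)
        if result.labels is not None:
            ax.set_title(f"{param}: day {result.day_reference} vs {result.day_final} "
                         f"{result.labels[param]}")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
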