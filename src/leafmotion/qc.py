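"""Quality control and per-line aggregation of period estimates.

Two gates mirror standard practice for leaf-movement QTL phenotyping:
individual fits with periods outside the circadian band (below 18 h or
above 32 h) are discarded, and whole lines whose standard error of the
mean exceeds 0.50 h (30 min) are excluded — SEM is the precision gate on
the line-level phenotype handed to downstream mapping software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .period import PeriodEstimate

__all__ = [
    "PERIOD_LOWER_H",
    "PERIOD_UPPER_H",
    "SEM_CUTOFF_H",
    "LineSummary",
    "filter_periods",
    "summarize_line",
    "summarize_cohort",
]

PERIOD_LOWER_H = 18.0
PERIOD_UPPER_H = 32.0
SEM_CUTOFF_H = 0.50


def _period_of(est) -> float:
    return float(est.period) if hasattr(est, "period") else float(est)


@dataclass(frozen=True)
class LineSummary:
    """Aggregated period phenotype for one line/genotype.

    ``sem = sd / sqrt(n_retained)`` with sample sd (n-1 denominator).
    ``excluded`` is True when the line fails the SEM gate (or has fewer
    than 2 retained estimates, where SEM is undefined).
    """

    line_id: str
    n_retained: int
    mean_period: float
    sd: float
    sem: float
    n_removed_period_bounds: int
    excluded: bool
    exclusion_reason: str | None = None


def filter_periods(
    estimates: Sequence,
    lower: float = PERIOD_LOWER_H,
    upper: float = PERIOD_UPPER_H,
) -> tuple[list, list[tuple[object, str]]]:
    """Split estimates into (retained, removed-with-reason).

    Bounds are inclusive: estimates at exactly 18 h or 32 h are retained
    (only values strictly above/below the bounds are removed).  Accepts
    :class:`~leafmotion.period.PeriodEstimate` objects or bare floats.
    Every input appears exactly once across the two outputs.
    """
    retained: list = []
    removed: list[tuple[object, str]] = []
    for est in estimates:
        p = _period_of(est)
        if p < lower:
            removed.append((est, f"period {p:g} h below {lower:g} h"))
        elif p > upper:
            removed.append((est, f"period {p:g} h above {upper:g} h"))
        else:
            retained.append(est)
    return retained, removed


def summarize_line(
    line_id: str,
    retained: Sequence,
    sem_cutoff: float = SEM_CUTOFF_H,
) -> LineSummary:
    """Aggregate one line's retained estimates with the SEM gate.

    Lines with a single retained estimate are excluded outright: SEM is
    the precision certificate and is undefined at n = 1.
    """
    periods = np.array([_period_of(e) for e in retained], dtype=float)
    n = periods.size
    if n == 0:
        return LineSummary(
            line_id, 0, np.nan, np.nan, np.nan, 0,
            excluded=True, exclusion_reason="no retained estimates",
        )
    mean = float(np.mean(periods))
    if n == 1:
        return LineSummary(
            line_id, 1, mean, np.nan, np.nan, 0,
            excluded=True, exclusion_reason="single estimate; SEM undefined",
        )
    sd = float(np.std(periods, ddof=1))
    sem = sd / np.sqrt(n)
    excluded = sem > sem_cutoff
    reason = f"SEM {sem:.3f} h above cutoff {sem_cutoff:g} h" if excluded else None
    return LineSummary(line_id, n, mean, sd, float(sem), 0, excluded, reason)


def summarize_cohort(
    estimates: Iterable[PeriodEstimate],
    line_of: dict[str, str] | None = None,
    *,
    lower: float = PERIOD_LOWER_H,
    upper: float = PERIOD_UPPER_H,
    sem_cutoff: float = SEM_CUTOFF_H,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full QC pass over a cohort: bounds filter, then per-line SEM gate.

    ``line_of`` maps plant_id to line_id; by default each plant is its own
    line.  Returns (per-line summary table, removal log).  The summary
    table keeps only non-excluded lines; the removal log records both
    out-of-bounds plants and excluded lines.
    """
    estimates = list(estimates)
    retained, removed = filter_periods(estimates, lower, upper)
    removal_rows = [
        {"unit": "plant", "id": getattr(e, "plant_id", None) or "", "reason": reason}
        for e, reason in removed
    ]
    by_line: dict[str, list] = {}
    n_removed_by_line: dict[str, int] = {}
    for e, _ in removed:
        lid = _line_id(e, line_of)
        n_removed_by_line[lid] = n_removed_by_line.get(lid, 0) + 1
    for e in retained:
        by_line.setdefault(_line_id(e, line_of), []).append(e)

    rows = []
    for lid in sorted(by_line):
        summary = summarize_line(lid, by_line[lid], sem_cutoff)
        if summary.excluded:
            removal_rows.append(
                {"unit": "line", "id": lid, "reason": summary.exclusion_reason}
            )
            continue
        rows.append(
            {
                "line_id": lid,
                "n": summary.n_retained,
                "mean_period_h": summary.mean_period,
                "sem_h": summary.sem,
                "sd_h": summary.sd,
                "n_removed_period_bounds": n_removed_by_line.get(lid, 0),
            }
        )
    summary_df = pd.DataFrame(
        rows,
        columns=["line_id", "n", "mean_period_h", "sem_h", "sd_h",
                 "n_removed_period_bounds"],
    )
    removal_df = pd.DataFrame(removal_rows, columns=["unit", "id", "reason"])
    return summary_df, removal_df


def _line_id(est, line_of: dict[str, str] | None) -> str:
    pid = getattr(est, "plant_id", None) or "unknown"
    if line_of is None:
        return pid
    return line_of.get(pid, pid)
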