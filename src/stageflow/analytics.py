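"""Cohort-level summaries of generated trajectories.

Besides per-stage holding times and complication prevalences, this module
computes the retrospective "later-to-earlier" transition tables: among the
patients who have a complication (or a co-occurring complication pattern)
while in the last stage, the fraction who already had it while in each
earlier stage.  Because complication activity is irreversible, those
fractions are necessarily nonincreasing as the reference stage moves
earlier, and a subset pattern's fraction bounds its superset's from above.

"Has the complication at stage s" means the complication is active at some
time during the patient's occupancy of s (onsets are interval-valued and
slices yearly, so entry-instant membership would be ill-defined).  The
last-stage base group contains only patients who actually reach the last
stage; truncated patients are excluded from it but still count in the
cohort denominator of the last-stage percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX")


def roman(stage_index: int) -> str:
    """Roman label of a 0-based stage index."""
    return _ROMAN[stage_index]


def round_percent(numerator: float, denominator: float) -> float:
    """100 * num / den, rounded half-up to one decimal (printed precision)."""
    if denominator == 0:
        raise ZeroDivisionError("round_percent denominator is zero")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class StageSummary:
    """Per-stage cohort means.

    ``entry_year_mean[s]`` is the mean continuous entry year among patients
    reaching stage s (0.0 for stage I); ``holding_mean[s]`` the mean holding
    time among patients observed to leave s (NaN for the absorbing last
    stage); ``prevalence[s, w]`` the fraction of stage-s occupants with
    complication w active at some time while in s.
    """

    n_stages: int
    n_complications: int
    n_patients: int
    n_reaching: np.ndarray
    entry_year_mean: np.ndarray
    holding_mean: np.ndarray
    prevalence: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "stage": [roman(s) for s in range(self.n_stages)],
            "n_reaching": self.n_reaching,
            "entry_year_mean": self.entry_year_mean,
            "holding_mean": self.holding_mean,
        })
        for w in range(self.n_complications):
            df[f"prevalence_c{w + 1}"] = self.prevalence[:, w]
        return df


def stage_summary(cohort) -> StageSummary:
    """Holding times, entry years and prevalence by stage over a cohort."""
    if not cohort:
        raise ValueError("stage_summary requires a non-empty cohort")
    K = cohort[0].n_stages
    W = cohort[0].n_complications
    entry_sums = np.zeros(K)
    n_reach = np.zeros(K, dtype=int)
    hold_sums = np.zeros(K)
    n_hold = np.zeros(K, dtype=int)
    prev_counts = np.zeros((K, W))
    for p in cohort:
        entries = p.stage_entry_years
        for s, e in enumerate(entries):
            entry_sums[s] += e
            n_reach[s] += 1
            if s + 1 < len(entries):
                hold_sums[s] += entries[s + 1] - e
                n_hold[s] += 1
            for w in range(W):
                if p.active_during(w, s):
                    prev_counts[s, w] += 1
    with np.errstate(invalid="ignore"):
        entry_mean = np.where(n_reach > 0, entry_sums / np.maximum(n_reach, 1), np.nan)
        holding = np.where(n_hold > 0, hold_sums / np.maximum(n_hold, 1), np.nan)
        prevalence = np.where(n_reach[:, None] > 0,
                              prev_counts / np.maximum(n_reach, 1)[:, None], np.nan)
    return StageSummary(
        n_stages=K, n_complications=W, n_patients=len(cohort),
        n_reaching=n_reach, entry_year_mean=entry_mean,
        holding_mean=holding, prevalence=prevalence,
    )


def _has_pattern(patient, members, s: int) -> bool:
    return all(patient.active_during(w, s) for w in members)


def single_complication_table(cohort, complication_indices=None,
                              labels: dict | None = None) -> pd.DataFrame:
    """Per-complication last-stage counts and later-to-earlier percentages.

    Rows are complications; columns are the count and percentage positive
    while in the last stage, then one column per earlier stage with the
    percentage of that last-stage-positive group already positive there.
    Percentages use the printed one-decimal half-up rounding; undefined
    entries (empty base group) are NaN.
    """
    if not cohort:
        raise ValueError("table requires a non-empty cohort")
    K = cohort[0].n_stages
    W = cohort[0].n_complications
    last = K - 1
    if complication_indices is None:
        complication_indices = list(range(W))
    rows = []
    index = []
    for w in complication_indices:
        if not 0 <= w < W:
            raise ValueError(f"unknown complication index {w}")
        base = [p for p in cohort if p.reached_last_stage and p.active_during(w, last)]
        n_v = len(base)
        row = {"n_V": n_v, "pct_V": round_percent(n_v, len(cohort))}
        for s in range(last - 1, -1, -1):
            col = f"V->{roman(s)}"
            if n_v == 0:
                row[col] = np.nan
            else:
                n_s = sum(1 for p in base if p.active_during(w, s))
                row[col] = round_percent(n_s, n_v)
        rows.append(row)
        index.append((labels or {}).get(w, f"{w + 1}"))
    return pd.DataFrame(rows, index=pd.Index(index, name="complication"))


def pattern_table(cohort, patterns, labels: dict | None = None) -> dict:
    """Later-to-earlier statistics for co-occurring complication patterns.

    For each pattern (a list of complication indices) the base group is the
    set of patients with *all* members active while in the last stage.  The
    returned table has one column per non-empty subset of the pattern
    (ordered by size then lexicographically, as in published layouts) and
    one row per earlier stage, giving the percentage of the base group with
    the whole subset active while in that stage.  ``attrs["n_V"]`` and
    ``attrs["pct_V"]`` on each table carry the base-group size and its
    cohort percentage.
    """
    if not cohort:
        raise ValueError("table requires a non-empty cohort")
    K = cohort[0].n_stages
    W = cohort[0].n_complications
    last = K - 1
    out = {}
    for pattern in patterns:
        members = sorted(int(w) for w in pattern)
        if any(not 0 <= w < W for w in members):
            raise ValueError(f"pattern {pattern} has unknown complication index")
        if not members:
            raise ValueError("empty pattern")
        base = [p for p in cohort
                if p.reached_last_stage and _has_pattern(p, members, last)]
        n_v = len(base)
        subsets = [list(c) for r in range(1, len(members) + 1)
                   for c in combinations(members, r)]

        def _label(ws):
            return "[" + ", ".join((labels or {}).get(w, str(w + 1)) for w in ws) + "]"

        data = {}
        for sub in subsets:
            col = []
            for s in range(last - 1, -1, -1):
                if n_v == 0:
                    col.append(np.nan)
                else:
                    n_s = sum(1 for p in base if _has_pattern(p, sub, s))
                    col.append(round_percent(n_s, n_v))
            data[_label(sub)] = col
        df = pd.DataFrame(data, index=[f"V->{roman(s)}" for s in range(last - 1, -1, -1)])
        df.attrs["n_V"] = n_v
        df.attrs["pct_V"] = round_percent(n_v, len(cohort))
        out[_label(members)] = df
    return out


def plot_prevalence(summary: StageSummary, path, labels: dict | None = None) -> None:
    """Stacked per-stage complication prevalence bars (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = np.arange(summary.n_stages)
    width = 0.8 / summary.n_complications
    for w in range(summary.n_complications):
        label = (labels or {}).get(w, f"complication {w + 1}")
        ax.bar(x + w * width, summary.prevalence[:, w], width, label=label)
    ax.set_xticks(x + 0.4)
    ax.set_xticklabels([roman(s) for s in range(summary.n_stages)])
    ax.set_xlabel("stage")
    ax.set_ylabel("prevalence while in stage")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
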