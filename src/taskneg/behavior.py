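"""Questionnaire scoring/correlation and respiration-parameter analyses.

The post-scan inquiry form has 17 retained Likert items (1-5); four judges
grouped seven of them as "Thoughts" and three as "Sensations", and those
category means carry the statistics: paired condition comparisons
(Bonferroni corrected over the tested family) and across-subject Pearson
correlation matrices between Thoughts and Sensations items.  Respiration is
summarized per subject and condition by five measures extracted from the
airflow trace -- pace (breaths/min), inhale duration, inhale peak, inhale
mean and inhale integral -- compared between conditions with paired
t-tests, Bonferroni family 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from taskneg.distribution import paired_t
from taskneg.synth import ALL_ITEMS, SENSATION_ITEMS, THOUGHT_ITEMS

__all__ = [
    "CATEGORIES",
    "BREATH_MEASURES",
    "score_questionnaire",
    "compare_conditions",
    "category_correlation",
    "extract_breath_params",
    "compare_breath",
]

CATEGORIES: dict[str, tuple[str, ...]] = {
    "Thoughts": THOUGHT_ITEMS,  # 7 items
    "Sensations": SENSATION_ITEMS,  # 3 items
}

BREATH_MEASURES = ("pace", "inhale_duration", "inhale_peak", "inhale_mean",
                   "inhale_integral")


class BehaviorError(ValueError):
    pass


def _check_long_table(table: pd.DataFrame) -> None:
    need = {"subject", "condition", "item", "rating"}
    if not need.issubset(table.columns):
        raise BehaviorError(f"questionnaire table must have columns {sorted(need)}")
    r = table.rating
    if ((r < 1) | (r > 5)).any():
        raise BehaviorError("ratings must lie in 1..5")


def score_questionnaire(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted category means per subject and condition.

    Every category item must be present for every subject/condition; a
    missing item is an error naming it (a 6-item "Thoughts" mean would not
    be the published statistic).
    """
    _check_long_table(table)
    wide = table.pivot_table(index=["subject", "condition"], columns="item",
                             values="rating", aggfunc="first")
    out = {}
    for cat, items in CATEGORIES.items():
        missing = [q for q in items if q not in wide.columns or wide[q].isna().any()]
        if missing:
            raise BehaviorError(f"category {cat!r} missing item(s): {missing}")
        out[cat] = wide[list(items)].mean(axis=1)
    return pd.DataFrame(out).reset_index()


def compare_conditions(
    scores: pd.DataFrame,
    conditions: tuple[str, str] = ("Rest", "RS"),
    columns: list[str] | None = None,
    families: int | None = None,
) -> pd.DataFrame:
    """Paired condition comparison per score column, Bonferroni corrected.

    ``scores`` is subject x condition with value columns (category means
    from :func:`score_questionnaire`, or per-item scores).  The Bonferroni
    family defaults to the number of columns tested (2 for the categories,
    17 for the full form).
    """
    if columns is None:
        columns = [c for c in scores.columns if c not in ("subject", "condition")]
    if families is None:
        families = len(columns)
    a = scores[scores.condition == conditions[0]].set_index("subject")
    b = scores[scores.condition == conditions[1]].set_index("subject")
    common = a.index.intersection(b.index)
    if len(common) < 2 or len(common) < max(len(a), len(b)):
        raise BehaviorError("conditions are not fully paired by subject")
    rows = []
    for col in columns:
        t, p, df = paired_t(a.loc[common, col].to_numpy(),
                            b.loc[common, col].to_numpy())
        rows.append(dict(measure=col, t=t, p=p, df=df,
                         p_bonferroni=min(1.0, p * families) if np.isfinite(p) else p))
    return pd.DataFrame(rows)


def category_correlation(
    table: pd.DataFrame, condition: str
) -> tuple[pd.DataFrame, float, float]:
    """Across-subject Pearson correlations of each Thoughts item with each
    Sensations item in one condition.

    Returns (7x3 matrix, mean r, sd of r) over the defined item pairs;
    constant items are flagged NaN and excluded from the mean with a
    warning.
    """
    _check_long_table(table)
    sub = table[table.condition == condition]
    wide = sub.pivot_table(index="subject", columns="item", values="rating",
                           aggfunc="first")
    if len(wide) < 3:
        raise BehaviorError("need >= 3 subjects for correlations")
    mat = pd.DataFrame(index=list(THOUGHT_ITEMS), columns=list(SENSATION_ITEMS),
                       dtype=float)
    for qt in THOUGHT_ITEMS:
        for qs in SENSATION_ITEMS:
            x, y = wide[qt].to_numpy(float), wide[qs].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant item in pair ({qt}, {qs}); r undefined")
                mat.loc[qt, qs] = np.nan
            else:
                mat.loc[qt, qs] = float(stats.pearsonr(x, y).statistic)
    flat = mat.to_numpy(float).ravel()
    ok = flat[~np.isnan(flat)]
    return mat, float(ok.mean()), float(ok.std(ddof=1))


# ---------------------------------------------------------------------------
# Respiration


@dataclass(frozen=True)
class BreathSummary:
    pace: float  # breaths / min
    inhale_duration: float  # s
    inhale_peak: float  # flow units
    inhale_mean: float  # flow units
    inhale_integral: float  # flow units * s
    n_breaths: int

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in BREATH_MEASURES}


def extract_breath_params(
    time: np.ndarray,
    flow: np.ndarray,
    hysteresis_frac: float = 0.05,
) -> BreathSummary:
    """Extract the five respiration measures from an airflow trace.

    Inhales are contiguous positive-flow segments whose maximum exceeds a
    hysteresis threshold of ``hysteresis_frac`` times the trace SD (small
    zero-crossing wiggles are ignored); segments touching the trace
    boundaries are discarded as partial breaths.  Pace is 60 over the mean
    inhale-onset-to-onset interval; duration/peak/mean are per-inhale
    averages; the integral is the mean per-inhale trapezoidal area.
    """
    time = np.asarray(time, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if time.shape != flow.shape or time.ndim != 1:
        raise BehaviorError("time and flow must be equal-length 1D arrays")
    h = hysteresis_frac * flow.std()
    pos = flow > 0
    # maximal runs of positive flow
    edges = np.diff(pos.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if pos[0]:
        starts = [0] + starts
    if pos[-1]:
        ends = ends + [len(flow)]
    segs = [(a, b) for a, b in zip(starts, ends)
            if a > 0 and b < len(flow) and flow[a:b].max() > h]
    if len(segs) < 2:
        raise BehaviorError("fewer than two complete breaths detected")
    onsets = time[[a for a, _ in segs]]
    pace = 60.0 / float(np.mean(np.diff(onsets)))
    durations = [time[b - 1] - time[a] + (time[1] - time[0]) for a, b in segs]
    peaks = [float(flow[a:b].max()) for a, b in segs]
    means = [float(flow[a:b].mean()) for a, b in segs]
    integrals = [float(np.trapezoid(flow[a:b], time[a:b])) for a, b in segs]
    return BreathSummary(
        pace=pace,
        inhale_duration=float(np.mean(durations)),
        inhale_peak=float(np.mean(peaks)),
        inhale_mean=float(np.mean(means)),
        inhale_integral=float(np.mean(integrals)),
        n_breaths=len(segs),
    )


def compare_breath(
    summaries: pd.DataFrame, conditions: tuple[str, str] = ("Rest", "RS")
) -> pd.DataFrame:
    """Paired t-test per respiration measure between two conditions,
    Bonferroni corrected over the family of five measures.

    ``summaries`` has columns subject, condition, and the five measures.
    """
    return compare_conditions(summaries, conditions,
                              columns=list(BREATH_MEASURES),
                              families=len(BREATH_MEASURES))
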