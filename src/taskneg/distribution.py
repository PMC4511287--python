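"""Voxelwise t-distribution analysis and the antagonism index.

The core statistic of the pipeline.  For each participant's task-vs-rest
t-map we histogram all in-mask t-values (bins from -6 to 6 in steps of 1 by
default), count the voxels whose |t| exceeds a significance criterion
(shipped default 2.819, the two-tailed alpha = 0.01 Student-t quantile at
df 22 -- its provenance knobs df/alpha are both exposed), and form the
antagonism index

    A = (n_pos - n_neg) / (n_pos + n_neg)

A = -1 means purely negative ("gating": the task only switches regions
off), A = 0 a balanced push-pull ("antagonistic") profile.  Histograms are
averaged with within-subject (Cousineau-Morey) error bars, and positive vs
negative percentages / cross-task indices are compared with paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from taskneg.glm import StatMap

__all__ = [
    "DEFAULT_T_CRIT",
    "default_edges",
    "tvalue_histogram",
    "average_histograms",
    "count_significant",
    "antagonism_index",
    "critical_t",
    "paired_t",
    "summarize_cohort",
    "DistributionSummary",
]

#: Shipped significance criterion for counting activated/deactivated voxels:
#: the two-tailed alpha=0.01 Student-t quantile at df=22.
DEFAULT_T_CRIT = 2.819


class DistributionError(ValueError):
    pass


def default_edges(lo: float = -6.0, hi: float = 6.0, step: float = 1.0) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def tvalue_histogram(
    map_or_values: StatMap | np.ndarray,
    mask: np.ndarray | None = None,
    edges: np.ndarray | None = None,
    clip: bool = True,
) -> np.ndarray:
    """Per-bin voxel counts of in-mask t-values.

    With ``clip`` (default) out-of-range values are absorbed into the
    outermost bins, so the counts always sum to the mask size; otherwise
    they are dropped.
    """
    if isinstance(map_or_values, StatMap):
        vals = map_or_values.masked()
    else:
        vals = np.asarray(map_or_values, dtype=float)
        if mask is not None:
            vals = vals[np.asarray(mask).astype(bool)]
        else:
            vals = vals.ravel()
    if vals.size == 0:
        raise DistributionError("empty mask: no voxels to histogram")
    edges = default_edges() if edges is None else np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise DistributionError("edges must be strictly increasing with >= 2 entries")
    if clip:
        vals = np.clip(vals, edges[0], edges[-1] - 1e-12)
    counts, _ = np.histogram(vals, bins=edges)
    return counts


def average_histograms(hists: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean histogram across subjects with within-subject SEM per bin.

    ``hists`` has shape (subjects, conditions, bins).  Cousineau
    normalization subtracts each subject's mean over conditions and adds the
    grand mean, removing between-subject offsets; the SEM of the normalized
    values is then inflated by sqrt(C / (C - 1)) (Morey's bias correction)
    with C the number of conditions.  Returns (mean, sem), each
    (conditions, bins).
    """
    hists = np.asarray(hists, dtype=float)
    if hists.ndim != 3:
        raise DistributionError("expected (subjects, conditions, bins)")
    n_sub, n_cond, _ = hists.shape
    if n_sub < 2:
        raise DistributionError("need >= 2 subjects")
    if n_cond < 2:
        raise DistributionError("within-subject correction undefined for one condition")
    subj_mean = hists.mean(axis=1, keepdims=True)
    grand = hists.mean(axis=(0, 1), keepdims=True)
    norm = hists - subj_mean + grand
    sem = norm.std(axis=0, ddof=1) / np.sqrt(n_sub)
    sem *= np.sqrt(n_cond / (n_cond - 1))
    return hists.mean(axis=0), sem


def count_significant(
    map_or_values: StatMap | np.ndarray,
    t_crit: float = DEFAULT_T_CRIT,
    mask: np.ndarray | None = None,
) -> tuple[int, int, float, float]:
    """(n_pos, n_neg, pct_pos, pct_neg): voxels with t above +t_crit /
    below -t_crit, and their percentages of the mask size."""
    if t_crit <= 0:
        raise DistributionError("t_crit must be positive")
    if isinstance(map_or_values, StatMap):
        vals = map_or_values.masked()
    else:
        vals = np.asarray(map_or_values, dtype=float)
        if mask is not None:
            vals = vals[np.asarray(mask).astype(bool)]
        else:
            vals = vals.ravel()
    n = vals.size
    n_pos = int(np.sum(vals > t_crit))
    n_neg = int(np.sum(vals < -t_crit))
    return n_pos, n_neg, 100.0 * n_pos / n, 100.0 * n_neg / n


def antagonism_index(n_pos: int, n_neg: int) -> float:
    """(positive - negative) / (positive + negative) significant-voxel
    counts; NaN (with a warning) when a subject has none of either."""
    if n_pos < 0 or n_neg < 0:
        raise DistributionError("counts must be non-negative")
    if n_pos + n_neg == 0:
        warnings.warn("no significant voxels of either sign; antagonism index undefined")
        return float("nan")
    return (n_pos - n_neg) / (n_pos + n_neg)


def critical_t(df: int, alpha: float = 0.01, tails: int = 2) -> float:
    """Student-t criterion with total tail mass ``alpha`` (split across the
    two tails when two-tailed).  df=22, alpha=0.01, two-tailed -> 2.819."""
    if df < 1:
        raise DistributionError("df must be >= 1")
    if not 0 < alpha <= 1:
        raise DistributionError("alpha must be in (0, 1]")
    if tails not in (1, 2):
        raise DistributionError("tails must be 1 or 2")
    return float(stats.t.ppf(1.0 - alpha / tails, df))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Classic paired t-test on per-subject value pairs; two-tailed.

    Returns (t, p, df).  Zero-variance differences yield (nan, nan, df)
    unless the differences are exactly zero, which gives (0, 1, df).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DistributionError("paired samples must be equal-length 1D vectors")
    if a.size < 2:
        raise DistributionError("need at least 2 pairs")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise DistributionError("missing pairs are not allowed; drop them first")
    d = a - b
    df = d.size - 1
    if np.all(d == 0):
        return 0.0, 1.0, df
    if d.std(ddof=1) == 0:
        warnings.warn("zero-variance nonzero differences; paired t undefined")
        return float("nan"), float("nan"), df
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), df


@dataclass(frozen=True)
class DistributionSummary:
    """Per-subject counts/percentages/indices for each task, plus the paired
    tests: positive vs negative percentage within task, and the cross-task
    comparison of antagonism indices."""

    table: pd.DataFrame  # columns: subject, task, n_pos, n_neg, pct_pos, pct_neg, A
    t_crit: float
    within_task_tests: dict[str, tuple[float, float, int]]  # task -> (t, p, df)
    cross_task_test: tuple[float, float, int] | None  # on A, first vs second task
    dropped_subjects: tuple[str, ...] = ()


def summarize_cohort(
    subject_maps: dict[str, dict[str, StatMap | np.ndarray]],
    t_crit: float = DEFAULT_T_CRIT,
    masks: dict[str, np.ndarray] | None = None,
) -> DistributionSummary:
    """Full distribution analysis of a cohort.

    ``subject_maps[task][subject]`` is that subject's task-vs-rest t-map.
    Subjects with zero significant voxels of both signs in some task have an
    undefined index and are dropped pairwise from the cross-task test (with
    a warning).
    """
    rows = []
    tasks = list(subject_maps)
    for task in tasks:
        for subj, m in subject_maps[task].items():
            mask = masks.get(subj) if masks else None
            n_pos, n_neg, pct_pos, pct_neg = count_significant(m, t_crit, mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                A = antagonism_index(n_pos, n_neg)
            rows.append(
                dict(subject=subj, task=task, n_pos=n_pos, n_neg=n_neg,
                     pct_pos=pct_pos, pct_neg=pct_neg, A=A)
            )
    table = pd.DataFrame(rows)
    within = {}
    for task in tasks:
        sub = table[table.task == task].sort_values("subject")
        within[task] = paired_t(sub.pct_pos.to_numpy(), sub.pct_neg.to_numpy())
    cross, dropped = None, ()
    if len(tasks) >= 2:
        a = table[table.task == tasks[0]].set_index("subject").A
        b = table[table.task == tasks[1]].set_index("subject").A
        common = a.index.intersection(b.index)
        ok = common[~(a[common].isna() | b[common].isna())]
        dropped = tuple(sorted(set(common) - set(ok)))
        if dropped:
            warnings.warn(
                f"subjects dropped from cross-task test (undefined index): {dropped}"
            )
        cross = paired_t(a[ok].to_numpy(), b[ok].to_numpy())
    return DistributionSummary(
        table=table, t_crit=t_crit, within_task_tests=within,
        cross_task_test=cross, dropped_subjects=dropped,
    )
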