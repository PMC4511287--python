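"""Region-of-interest definition and block-locked time-course analysis.

ROIs are defined on an *independent* localizer contrast map: starting from
the peak suprathreshold voxel (default defining threshold p < 0.02,
two-tailed), contiguous suprathreshold voxels are added in order of
Euclidean distance from the peak until the next voxel would push the ROI
past a volume cap (default 1000 mm^3, i.e. at most 37 voxels of 3 mm).
Time courses are the ROI-mean signal expressed in percent signal change
against the mean of the rest volumes, cut into per-block windows spanning
the preceding rest through the following rest, and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from taskneg.distribution import critical_t
from taskneg.glm import StatMap
from taskneg.preprocess import BoldRun
from taskneg.protocol import REST, ExperimentTimeline

__all__ = ["RoiDefinition", "EventLockedCourse", "define_roi",
           "extract_roi_timecourse", "block_response_test"]


class RoiError(ValueError):
    pass


@dataclass(frozen=True)
class RoiDefinition:
    peak: tuple[int, int, int]
    voxels: np.ndarray  # (n, 3) int indices, peak first
    volume_mm3: float
    p_thresh: float
    volume_cap_mm3: float
    source: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def mask(self, grid: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass(frozen=True)
class EventLockedCourse:
    """Block-triggered average time course in percent signal change; time 0
    is block onset, the pre-onset rest window has mean 0 by construction."""

    time: np.ndarray  # s relative to block onset
    mean: np.ndarray  # % signal change
    sd: np.ndarray  # across blocks
    block_duration: float  # s (plateau marker)
    n_blocks: int
    plateau: float  # mean % change over the sustained window
    plateau_window: tuple[float, float]


def define_roi(
    stat_map: StatMap,
    p_thresh: float = 0.02,
    volume_cap_mm3: float = 1000.0,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
    sign: int = 0,
) -> RoiDefinition:
    """Grow an ROI around the localizer peak.

    Suprathreshold means |t| above the two-tailed ``p_thresh`` quantile at
    the map's df (``sign`` = +1/-1 restricts to one sign).  The peak is the
    max-|t| suprathreshold voxel; growth adds voxels of the peak's
    suprathreshold connected component (face adjacency) in order of
    Euclidean mm distance from the peak, ties broken lexicographically,
    while the accumulated volume stays within the cap.
    """
    from scipy import ndimage

    t_thr = critical_t(stat_map.df, p_thresh, tails=2)
    t = np.where(stat_map.mask, stat_map.values, 0.0)
    if sign > 0:
        supra = t > t_thr
    elif sign < 0:
        supra = t < -t_thr
    else:
        supra = np.abs(t) > t_thr
    if not supra.any():
        raise RoiError(f"no suprathreshold voxel at p < {p_thresh}")
    absmap = np.where(supra, np.abs(t), -np.inf)
    peak = np.unravel_index(np.argmax(absmap), t.shape)
    labels, _ = ndimage.label(supra, structure=ndimage.generate_binary_structure(3, 1))
    component = labels == labels[peak]
    coords = np.argwhere(component)
    vs = np.asarray(voxel_size)
    dist = np.linalg.norm((coords - np.asarray(peak)) * vs, axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], dist))
    vox_vol = float(np.prod(vs))
    n_max = int(np.floor(volume_cap_mm3 / vox_vol))
    chosen = coords[order][: max(1, n_max)]
    return RoiDefinition(
        peak=tuple(int(i) for i in peak),
        voxels=chosen,
        volume_mm3=len(chosen) * vox_vol,
        p_thresh=p_thresh,
        volume_cap_mm3=volume_cap_mm3,
    )


def extract_roi_timecourse(
    run: BoldRun,
    roi: RoiDefinition,
    timeline: ExperimentTimeline,
    condition: str,
    plateau_window: tuple[float, float] = (6.0, 21.0),
) -> EventLockedCourse:
    """Block-locked ROI-mean percent-signal-change course for one condition.

    The ROI mean series is converted to percent change against the mean of
    all rest volumes, windows run from one rest period before block onset to
    one rest period after offset, and are averaged across blocks.  The
    pre-onset window is re-zeroed (its mean defines the plotted baseline).
    The plateau is the mean over ``plateau_window`` seconds after onset
    (default 6-21 s: the sustained response, skipping the hemodynamic rise).
    """
    if roi.n_voxels == 0:
        raise RoiError("empty ROI")
    grid = run.grid
    if np.any(roi.voxels >= np.asarray(grid)) or np.any(roi.voxels < 0):
        raise RoiError("ROI voxels outside the run grid")
    series = run.data[tuple(roi.voxels.T)].mean(axis=0)  # (nt,)
    tr = run.tr
    rest_vols = np.zeros(run.n_volumes, dtype=bool)
    for ep in timeline.epochs_of(REST):
        rest_vols[int(round(ep.onset / tr)): int(round(ep.offset / tr))] = True
    if not rest_vols.any():
        raise RoiError("timeline has no rest volumes for the baseline")
    base = series[rest_vols].mean()
    if base == 0:
        pct = series * 0.0
    else:
        pct = 100.0 * (series - base) / base
    blocks = timeline.epochs_of(condition)
    if not blocks:
        raise RoiError(f"condition {condition!r} has no blocks")
    block_s = blocks[0].duration
    rest_s = timeline.epochs_of(REST)[0].duration
    pre = int(round(rest_s / tr))
    ln = int(round((block_s + rest_s) / tr)) + pre
    windows = []
    for ep in blocks:
        i0 = int(round(ep.onset / tr)) - pre
        w = np.full(ln, np.nan)
        for j in range(ln):
            if 0 <= i0 + j < run.n_volumes:
                w[j] = pct[i0 + j]
        windows.append(w)
    W = np.asarray(windows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(W, axis=0)
        sd = np.nanstd(W, axis=0, ddof=1)
    time = (np.arange(ln) - pre) * tr
    base_win = time < 0
    mean = mean - np.nanmean(mean[base_win])
    lo, hi = plateau_window
    plat = float(np.nanmean(mean[(time >= lo) & (time < hi)]))
    return EventLockedCourse(
        time=time, mean=mean, sd=sd, block_duration=block_s,
        n_blocks=len(blocks), plateau=plat, plateau_window=plateau_window,
    )


def block_response_test(
    plateaus: np.ndarray, families: int = 4
) -> tuple[float, float, float]:
    """One-sample t of per-subject sustained (plateau) responses against 0,
    with Bonferroni correction over ``families`` tests (default 4: two ROIs
    by two conditions).  Returns (t, p, p_bonferroni)."""
    from scipy import stats

    plateaus = np.asarray(plateaus, dtype=float)
    if plateaus.size < 2:
        raise RoiError("need at least 2 subjects")
    if families < 1:
        raise RoiError("families must be >= 1")
    if plateaus.std(ddof=1) == 0:
        if np.all(plateaus == 0):
            return 0.0, 1.0, 1.0
        warnings.warn("zero-variance plateaus; t undefined")
        return float("nan"), float("nan"), float("nan")
    res = stats.ttest_1samp(plateaus, 0.0)
    p = float(res.pvalue)
    return float(res.statistic), p, min(1.0, p * families)
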