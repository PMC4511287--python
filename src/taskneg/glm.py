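"""Mass-univariate GLM fitting, contrasts, and random-effects group maps.

Each voxel's time series is regressed on the design (task regressors, six
motion nuisance columns, intercept) by ordinary least squares.  Rest is not
a regressor: the intercept absorbs the pooled average of all rest periods,
so the t-statistic on a task column tests that task against the mean rest
baseline.  Serial correlation is not modeled (plain OLS).  Volumes falling
in movement-artifact segments (translation step > 1 mm by default) are
excluded from the fit.  Group inference is a random-effects one-sample t of
per-subject contrast values against zero (df = n_subjects - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from taskneg.preprocess import BoldRun
from taskneg.protocol import DesignMatrix

__all__ = [
    "StatMap",
    "SubjectFit",
    "fit_subject_glm",
    "contrast_t",
    "group_random_effects",
    "motion_exclusions",
]


class GlmError(ValueError):
    pass


@dataclass(frozen=True)
class StatMap:
    """Per-voxel statistic on the run grid."""

    values: np.ndarray  # (nx, ny, nz)
    kind: str  # "beta" | "t"
    df: int
    contrast: np.ndarray | None
    mask: np.ndarray  # bool, values defined only inside

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "t"):
            raise GlmError(f"unknown stat kind {self.kind!r}")
        if self.kind == "t" and self.df <= 0:
            raise GlmError("t map requires df > 0")

    def masked(self) -> np.ndarray:
        """Flat vector of in-mask values."""
        return self.values[self.mask]


@dataclass(frozen=True)
class SubjectFit:
    """OLS fit of one subject's run: betas, residual variance, and the
    pieces needed for contrast t-statistics."""

    betas: np.ndarray  # (n_regressors, nx, ny, nz)
    resid_var: np.ndarray  # (nx, ny, nz), RSS / df
    design: DesignMatrix
    df: int
    used: np.ndarray  # bool per volume (False = excluded)
    mask: np.ndarray
    xtx_inv: np.ndarray  # (X'X)^-1 on the used rows


def motion_exclusions(motion: np.ndarray, threshold_mm: float = 1.0) -> list[tuple[int, int]]:
    """Volume ranges whose translational motion step exceeds ``threshold_mm``.

    The rule looks at frame-to-frame displacement of the three translational
    columns; each offending transition excludes both adjacent volumes.
    """
    motion = np.asarray(motion, dtype=float)
    d = np.linalg.norm(np.diff(motion[:, :3], axis=0), axis=1)
    bad = np.flatnonzero(d > threshold_mm)
    return [(int(i), int(i + 2)) for i in bad]


def _used_mask(n: int, exclusions: list[tuple[int, int]] | None) -> np.ndarray:
    used = np.ones(n, dtype=bool)
    for a, b in exclusions or []:
        if not (0 <= a < b <= n):
            raise GlmError(f"exclusion range ({a}, {b}) outside 0..{n}")
        used[a:b] = False
    return used


def fit_subject_glm(
    run: BoldRun,
    design: DesignMatrix,
    exclusions: list[tuple[int, int]] | None = None,
) -> SubjectFit:
    """Voxelwise OLS on the non-excluded volumes.

    df = n_used - rank(design).  Constant (zero-variance) voxels get betas
    but NaN residual variance, flagging their t as undefined downstream.
    """
    if design.n_volumes != run.n_volumes:
        raise GlmError(
            f"design has {design.n_volumes} rows but run has {run.n_volumes} volumes"
        )
    used = _used_mask(run.n_volumes, exclusions)
    X = design.values[used]
    rank = np.linalg.matrix_rank(X)
    df = int(used.sum()) - rank
    if df <= 0:
        raise GlmError(f"non-positive degrees of freedom ({df}) after exclusions")
    mask = run.get_mask()
    Y = run.data[..., used].reshape(-1, int(used.sum())).T  # (n_used, nvox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    with np.errstate(invalid="ignore"):
        rvar = rss / df
    flat_const = Y.std(axis=0) == 0
    rvar[flat_const] = np.nan
    shape3 = run.grid
    return SubjectFit(
        betas=beta.reshape(-1, *shape3),
        resid_var=rvar.reshape(shape3),
        design=design,
        df=df,
        used=used,
        mask=mask,
        xtx_inv=np.linalg.inv(X.T @ X),
    )


def contrast_t(fit: SubjectFit, contrast: np.ndarray | str) -> StatMap:
    """t = c'b / sqrt(s^2 c'(X'X)^-1 c) per voxel.

    A task-vs-rest contrast is the unit vector on that task's column (rest
    being the unmodeled pooled baseline).  A string is resolved to that unit
    contrast by column label.
    """
    if isinstance(contrast, str):
        contrast = fit.design.contrast_vector(contrast)
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.design.labels),):
        raise GlmError(f"contrast length {c.size} != {len(fit.design.labels)} columns")
    if not np.any(c):
        raise GlmError("all-zero contrast")
    eff = np.tensordot(c, fit.betas, axes=1)
    var_scale = float(c @ fit.xtx_inv @ c)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = eff / np.sqrt(fit.resid_var * var_scale)
    return StatMap(values=t, kind="t", df=fit.df, contrast=c, mask=fit.mask)


def contrast_beta(fit: SubjectFit, contrast: np.ndarray | str) -> StatMap:
    """c'b per voxel (effect size on the regressor's scale)."""
    if isinstance(contrast, str):
        contrast = fit.design.contrast_vector(contrast)
    c = np.asarray(contrast, dtype=float)
    eff = np.tensordot(c, fit.betas, axes=1)
    return StatMap(values=eff, kind="beta", df=fit.df, contrast=c, mask=fit.mask)


def group_random_effects(subject_maps: list[StatMap] | list[np.ndarray]) -> StatMap:
    """Random-effects group map: per voxel, a one-sample t of subject
    contrast values (betas or t's) against zero; df = n_subjects - 1.

    Voxels with zero between-subject variance but a nonzero mean get an
    infinite-t sentinel with a warning.
    """
    arrays, mask = [], None
    for m in subject_maps:
        if isinstance(m, StatMap):
            arrays.append(m.values)
            mask = m.mask if mask is None else (mask & m.mask)
        else:
            arrays.append(np.asarray(m, dtype=float))
    n = len(arrays)
    if n < 2:
        raise GlmError("group analysis requires at least 2 subjects")
    g0 = arrays[0].shape
    if any(a.shape != g0 for a in arrays):
        raise GlmError("subject maps are not on a common grid")
    if mask is None:
        mask = np.ones(g0, dtype=bool)
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = (sd == 0) & (mean != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    if np.any(degenerate & mask):
        warnings.warn("zero between-subject variance with nonzero mean; t set to +/-inf")
        t[degenerate] = np.sign(mean[degenerate]) * np.inf
    return StatMap(values=t, kind="t", df=n - 1, contrast=None, mask=mask)


def select_lag(
    run: BoldRun,
    timeline,
    conditions,
    motion: np.ndarray | None,
    lags: tuple[float, ...] = (3.0, 4.5, 6.0),
):
    """Per-subject hemodynamic-lag choice: fit the GLM at each candidate lag
    and keep the one maximizing the mean absolute task t inside the mask."""
    from dataclasses import replace as _rep

    from taskneg.protocol import HrfParams, build_design_matrix

    best, best_score, best_lag = None, -np.inf, None
    for lag in lags:
        design = build_design_matrix(timeline, conditions, motion, HrfParams(lag_s=lag))
        fit = fit_subject_glm(run, design)
        score = np.nanmean(
            [np.nanmean(np.abs(contrast_t(fit, c).masked())) for c in conditions]
        )
        if score > best_score:
            best, best_score, best_lag = fit, score, lag
    return best, best_lag
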