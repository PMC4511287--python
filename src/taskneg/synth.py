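"""Forward simulation of block-design BOLD cohorts with known ground truth.

Two voxel-activation regimes are distinguished:

* ``antagonistic`` -- the task both activates and deactivates cortex
  (balanced positive and negative responders; ideal antagonism index 0);
* ``gating`` -- the task only switches regions off (negative responders
  only; ideal antagonism index -1).

A subject's signal at a responding voxel is

    baseline * (1 + amplitude/100 * regressor(t)) + drift + noise + motion

with ``amplitude`` in percent signal change, the regressor the
HRF-convolved task boxcar, a slow cosine drift, AR(1)-filtered Gaussian
noise whose stationary sd is expressed in percent of baseline (so
SNR = amplitude / white_sd), and a motion-coupled nuisance component.  The
module also generates Likert questionnaire cohorts with a controlled
Thoughts x Sensations correlation and quasi-periodic respiration traces.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from taskneg.preprocess import BoldRun, smooth_gaussian
from taskneg.protocol import ExperimentTimeline, HrfParams, make_regressor

__all__ = [
    "GroundTruth",
    "NoiseParams",
    "make_ground_truth",
    "generate_subject_bold",
    "generate_cohort",
    "generate_questionnaire",
    "generate_respiration",
    "THOUGHT_ITEMS",
    "SENSATION_ITEMS",
    "OTHER_ITEMS",
]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel regime labels (+1 task-positive, -1 task-negative, 0 null)
    and signed response amplitudes in percent signal change."""

    labels: np.ndarray  # (nx, ny, nz) int8
    amplitude: np.ndarray  # (nx, ny, nz) float, % signal change
    voxel_size: tuple[float, float, float]
    regime: str
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.amplitude[self.labels == 1] <= 0):
            raise SynthError("task_positive voxels require amplitude > 0")
        if np.any(self.amplitude[self.labels == -1] >= 0):
            raise SynthError("task_negative voxels require amplitude < 0")
        if np.any(self.amplitude[self.labels == 0] != 0):
            raise SynthError("null voxels require amplitude 0")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ideal_antagonism_index(self) -> float:
        n_pos = int(np.sum(self.labels == 1))
        n_neg = int(np.sum(self.labels == -1))
        if n_pos + n_neg == 0:
            return float("nan")
        return (n_pos - n_neg) / (n_pos + n_neg)


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise mixed into the simulated BOLD signal.  Amplitudes are
    in percent of the baseline intensity."""

    white_sd: float = 1.0  # stationary sd of the AR(1) noise, % of baseline
    ar1: float = 0.3  # lag-1 autoregressive coefficient
    drift_amplitude: float = 1.0  # slow cosine drift, % of baseline
    drift_cycles: float = 1.0  # cycles per run (inside the high-pass band)
    motion_amplitude: float = 0.2  # motion-coupled component, % of baseline
    spatial_fwhm_mm: float = 0.0  # smoothness of the noise field
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.white_sd, self.drift_amplitude, self.motion_amplitude,
               self.spatial_fwhm_mm) < 0:
            raise SynthError("noise amplitudes must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise SynthError("AR(1) coefficient must be in [0, 1)")


def _clustered_placement(
    rng: np.random.Generator, free: np.ndarray, count: int, n_blobs: int, grid
) -> np.ndarray:
    """Pick ``count`` voxels from the free set as ~n_blobs round regions
    (nearest free voxels to random centers).  Returns flat indices."""
    coords = np.argwhere(free.reshape(grid))
    order = []
    per = [count // n_blobs + (1 if i < count % n_blobs else 0) for i in range(n_blobs)]
    taken = np.zeros(len(coords), dtype=bool)
    for k in per:
        if k == 0:
            continue
        avail = np.flatnonzero(~taken)
        center = coords[rng.choice(avail)]
        d = np.linalg.norm(coords - center, axis=1)
        d[taken] = np.inf
        pick = np.argsort(d, kind="stable")[:k]
        taken[pick] = True
        order.extend(pick)
    chosen = coords[order]
    return np.ravel_multi_index(chosen.T, grid)


def make_ground_truth(
    regime: str,
    grid: tuple[int, int, int] = (20, 20, 20),
    fractions: tuple[float, float] = (0.1, 0.1),
    amplitudes: tuple[float, float] = (1.0, -1.0),
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
    placement: str = "clustered",
    n_blobs: int = 4,
) -> GroundTruth:
    """Draw voxel labels for the requested regime.

    ``fractions`` are the (positive, negative) responder fractions; counts
    are deterministic (round(fraction * n_voxels)), placement random by
    seed, either fully scattered (``placement="random"``) or grouped into
    round regions (``"clustered"``, the default -- cortical responses are
    spatially coherent).  The gating regime forces the positive fraction
    to 0.
    """
    if regime not in ("antagonistic", "gating"):
        raise SynthError(f"unknown regime {regime!r}")
    f_pos, f_neg = fractions
    if f_pos < 0 or f_neg < 0 or f_pos + f_neg > 1:
        raise SynthError("fractions must be >= 0 and sum to <= 1")
    if regime == "gating":
        f_pos = 0.0
    a_pos, a_neg = amplitudes
    if f_pos > 0 and a_pos <= 0:
        raise SynthError("positive amplitude must be > 0")
    if f_neg > 0 and a_neg >= 0:
        raise SynthError("negative amplitude must be < 0")
    n_vox = int(np.prod(grid))
    n_pos = int(round(f_pos * n_vox))
    n_neg = int(round(f_neg * n_vox))
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_vox, dtype=np.int8)
    if placement == "random":
        chosen = rng.choice(n_vox, size=n_pos + n_neg, replace=False)
        pos_idx, neg_idx = chosen[:n_pos], chosen[n_pos:]
    elif placement == "clustered":
        free = np.ones(n_vox, dtype=bool)
        pos_idx = _clustered_placement(rng, free, n_pos, n_blobs, grid) if n_pos else np.array([], int)
        free[pos_idx] = False
        neg_idx = _clustered_placement(rng, free, n_neg, n_blobs, grid) if n_neg else np.array([], int)
    else:
        raise SynthError(f"unknown placement {placement!r}")
    labels[pos_idx] = 1
    labels[neg_idx] = -1
    labels = labels.reshape(grid)
    amp = np.zeros(grid)
    amp[labels == 1] = a_pos
    amp[labels == -1] = a_neg
    regions = {
        "language-like": labels == 1,  # task-positive (e.g. Broca-like)
        "DMN-like": labels == -1,  # task-negative (default-mode-like)
    }
    return GroundTruth(
        labels=labels, amplitude=amp, voxel_size=voxel_size, regime=regime,
        regions=regions,
    )


def _simulate_motion(rng: np.random.Generator, nt: int, step_mm: float = 0.02) -> np.ndarray:
    """Slow random-walk head motion: 3 translations (mm), 3 rotations (deg)."""
    steps = rng.normal(0.0, step_mm, size=(nt, 6))
    steps[:, 3:] *= 0.5  # rotations drift less
    return np.cumsum(steps, axis=0)


def generate_subject_bold(
    truth: GroundTruth,
    timeline: ExperimentTimeline,
    noise: NoiseParams = NoiseParams(),
    subject: str = "sub-01",
    task_condition: str | None = None,
    hrf: HrfParams = HrfParams(),
    baseline: float = 1000.0,
) -> tuple[BoldRun, np.ndarray]:
    """Simulate one subject's run and its motion trace.

    Responding voxels follow the HRF-convolved regressor of
    ``task_condition`` (default: the timeline's first condition) at their
    ground-truth amplitude; other timeline conditions evoke no response.
    Fully reproducible from (parameters, seed): the per-subject stream is
    ``seed`` jointly hashed with the subject id.
    """
    nt = timeline.n_volumes
    grid = truth.grid
    n_vox = int(np.prod(grid))
    if task_condition is None:
        task_condition = timeline.conditions[0]
    reg = make_regressor(timeline, task_condition, hrf)
    subj_key = zlib.crc32(subject.encode()) % (2**31)
    rng = np.random.default_rng([noise.seed, subj_key])

    amp = truth.amplitude.reshape(n_vox, 1) / 100.0
    clean = baseline * (1.0 + amp * reg[None, :])  # (n_vox, nt)

    data = clean
    motion = _simulate_motion(rng, nt)
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(n_vox, 1))
        t = np.arange(nt)[None, :]
        drift = (baseline * noise.drift_amplitude / 100.0) * np.cos(
            2 * np.pi * noise.drift_cycles * t / nt + phase
        )
        data = data + drift
    if noise.white_sd > 0:
        innov = rng.standard_normal((n_vox, nt))
        if noise.ar1 > 0:
            # scale innovations so the stationary sd equals white_sd
            innov *= np.sqrt(1.0 - noise.ar1**2)
            colored = sp_signal.lfilter([1.0], [1.0, -noise.ar1], innov, axis=1)
        else:
            colored = innov
        if noise.spatial_fwhm_mm > 0:
            vol = colored.reshape(*grid, nt)
            vol = smooth_gaussian(vol, noise.spatial_fwhm_mm, truth.voxel_size)
            colored = vol.reshape(n_vox, nt)
            colored /= colored.std(axis=1, keepdims=True).mean()
        data = data + (baseline * noise.white_sd / 100.0) * colored
    if noise.motion_amplitude > 0:
        weights = rng.normal(0.0, 1.0, size=(n_vox, 3))
        coupled = weights @ motion[:, :3].T  # (n_vox, nt)
        scale = coupled.std() or 1.0
        data = data + (baseline * noise.motion_amplitude / 100.0) * coupled / scale
    run = BoldRun(
        data=np.ascontiguousarray(data.reshape(*grid, nt)),
        voxel_size=truth.voxel_size,
        tr=timeline.tr,
        subject=subject,
        run=task_condition,
    )
    return run, motion


def generate_cohort(
    truth: GroundTruth,
    timeline: ExperimentTimeline,
    n_subjects: int = 23,
    noise: NoiseParams = NoiseParams(),
    task_condition: str | None = None,
    hrf: HrfParams = HrfParams(),
):
    """Yield (subject id, BoldRun, motion) for a cohort; each subject gets an
    independent substream of the base seed keyed by their id."""
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        yield sid, *generate_subject_bold(
            truth, timeline, noise, subject=sid, task_condition=task_condition, hrf=hrf
        )


# ---------------------------------------------------------------------------
# Questionnaire cohort

THOUGHT_ITEMS = tuple(f"q{i:02d}" for i in range(1, 8))  # 7 items
SENSATION_ITEMS = tuple(f"q{i:02d}" for i in range(8, 11))  # 3 items
OTHER_ITEMS = tuple(f"q{i:02d}" for i in range(11, 18))  # 7 items
ALL_ITEMS = THOUGHT_ITEMS + SENSATION_ITEMS + OTHER_ITEMS

_CUTPOINTS = np.array([-1.5, -0.5, 0.5, 1.5])


def _ordinal_attenuation() -> float:
    """Analytic attenuation of a latent-normal correlation under the fixed
    cut-point discretization to a 1-5 scale (linear approximation)."""
    lam = stats.norm.pdf(_CUTPOINTS).sum()
    p = np.diff(np.concatenate([[0.0], stats.norm.cdf(_CUTPOINTS), [1.0]]))
    var_d = np.sum(p * (np.arange(1, 6) - np.sum(p * np.arange(1, 6))) ** 2)
    return float(lam**2 / var_d)


def _latent_correlation_matrix(cross_r: float, within_r: float) -> np.ndarray:
    k = len(ALL_ITEMS)
    R = np.eye(k)
    ti = [ALL_ITEMS.index(q) for q in THOUGHT_ITEMS]
    si = [ALL_ITEMS.index(q) for q in SENSATION_ITEMS]
    for block in (ti, si):
        for a in block:
            for b in block:
                if a != b:
                    R[a, b] = within_r
    for a in ti:
        for b in si:
            R[a, b] = R[b, a] = cross_r
    return R


def generate_questionnaire(
    n_subjects: int = 30,
    condition_effects: dict[str, dict[str, float]] | None = None,
    target_r: dict[str, float] | None = None,
    within_r: float = 0.3,
    seed: int = 0,
    conditions: tuple[str, ...] = ("Rest", "RS"),
) -> pd.DataFrame:
    """Simulate a Likert questionnaire cohort (long table: subject,
    condition, item, rating; ratings 1-5).

    A latent multivariate normal per condition carries the category
    structure: Thoughts (7 items) and Sensations (3 items) correlate within
    category at ``within_r`` and across categories at the condition's
    ``target_r`` (defaults: Rest -0.24, task -0.04 -- the anti-correlation
    collapse under repetitive speech); remaining items are independent.
    The latent cross correlation is pre-boosted by the analytic ordinal
    attenuation factor so the *observed* discretized correlation matches
    the target.  ``condition_effects`` shift category means in latent-SD
    units (defaults: Thoughts -1.0, Sensations -0.7 under the task).
    """
    if target_r is None:
        target_r = {"Rest": -0.24, "RS": -0.04}
    if condition_effects is None:
        condition_effects = {"RS": {"Thoughts": -1.0, "Sensations": -0.7}}
    if n_subjects == 0:
        return pd.DataFrame(columns=["subject", "condition", "item", "rating"])
    atten = _ordinal_attenuation()
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        r_obs = target_r.get(cond, 0.0)
        r_lat = r_obs / atten
        if abs(r_obs) >= 1 or abs(r_lat) >= 1:
            raise SynthError(f"target correlation {r_obs} infeasible after boosting")
        R = _latent_correlation_matrix(r_lat, within_r)
        ev = np.linalg.eigvalsh(R)
        if ev.min() <= 1e-10:
            raise SynthError("latent correlation matrix is not positive definite")
        L = np.linalg.cholesky(R)
        shift = np.zeros(len(ALL_ITEMS))
        for cat, items in (("Thoughts", THOUGHT_ITEMS), ("Sensations", SENSATION_ITEMS),
                           ("other", OTHER_ITEMS)):
            e = condition_effects.get(cond, {}).get(cat, 0.0)
            for q in items:
                shift[ALL_ITEMS.index(q)] = e
        latent = rng.standard_normal((n_subjects, len(ALL_ITEMS))) @ L.T + shift
        ratings = 1 + np.searchsorted(_CUTPOINTS, latent).reshape(n_subjects, -1)
        for s in range(n_subjects):
            for j, item in enumerate(ALL_ITEMS):
                rows.append(
                    dict(subject=f"sub-{s + 1:02d}", condition=cond, item=item,
                         rating=int(ratings[s, j]))
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Respiration traces


def generate_respiration(
    pace: float = 15.0,
    depth: float = 1.0,
    duration_s: float = 150.0,
    fs: float = 25.0,
    noise_sd: float = 0.0,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Quasi-periodic airflow trace (columns: time s, flow).

    Each breath is one sine cycle (positive lobe = inhale) whose period is
    the nominal 60/pace seconds multiplied by a lognormal jitter factor,
    plus optional white measurement noise.
    """
    if pace <= 0:
        raise SynthError("pace must be positive")
    if fs < 10:
        raise SynthError("sampling rate must be >= 10 Hz")
    rng = np.random.default_rng(seed)
    T0 = 60.0 / pace
    bounds = [0.0]
    while bounds[-1] < duration_s:
        T = T0 * float(np.exp(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else T0
        bounds.append(bounds[-1] + T)
    bounds = np.asarray(bounds)
    t = np.arange(0.0, duration_s, 1.0 / fs)
    idx = np.searchsorted(bounds, t, side="right") - 1
    phase = (t - bounds[idx]) / np.diff(bounds)[idx]
    flow = depth * np.sin(2 * np.pi * phase)
    if noise_sd > 0:
        flow = flow + rng.normal(0.0, noise_sd, size=flow.shape)
    return pd.DataFrame({"time": t, "flow": flow})
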