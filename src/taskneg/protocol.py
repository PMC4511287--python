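"""Experiment timelines and GLM design matrices for block-design fMRI.

A run alternates task blocks (one of several covert-task conditions, e.g.
repetitive speech or verbal fluency) with quiet-rest periods.  The timeline
is the digital form of that protocol: an ordered list of condition epochs
with onsets and durations in seconds.  Regressors are unit boxcars over a
condition's epochs convolved with a hemodynamic response function (HRF) and
sampled on the volume grid; rest is never modeled -- the intercept absorbs
the pooled average of all rest periods, so a task-vs-rest contrast is simply
the unit vector on that task's column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExperimentTimeline",
    "DesignMatrix",
    "HrfParams",
    "double_gamma_hrf",
    "build_timeline",
    "make_regressor",
    "build_design_matrix",
    "rs_spec",
    "vf_spec",
]

REST = "Rest"


class ProtocolError(ValueError):
    """Invalid experiment specification or design."""


@dataclass(frozen=True)
class Epoch:
    condition: str
    onset: float  # s
    duration: float  # s

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class ExperimentTimeline:
    """Ordered, non-overlapping condition epochs on a fixed volume grid."""

    epochs: tuple[Epoch, ...]
    tr: float  # s
    n_volumes: int
    cue_duration: float | None = None  # s, auditory cue at each epoch onset

    def __post_init__(self) -> None:
        last = 0.0
        for ep in self.epochs:
            if ep.duration <= 0:
                raise ProtocolError(f"non-positive epoch duration: {ep}")
            if ep.onset < last - 1e-9:
                raise ProtocolError("epochs overlap or are unsorted")
            last = ep.offset
        total = self.n_volumes * self.tr
        if self.epochs and self.epochs[-1].offset > total + 1e-6:
            raise ProtocolError(
                f"epochs span {self.epochs[-1].offset} s but grid holds only {total} s"
            )

    @property
    def duration(self) -> float:
        """Total run duration in seconds (= n_volumes * tr)."""
        return self.n_volumes * self.tr

    @property
    def conditions(self) -> tuple[str, ...]:
        """Distinct non-rest condition labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for ep in self.epochs:
            if ep.condition != REST:
                seen.setdefault(ep.condition, None)
        return tuple(seen)

    def n_rest_epochs(self) -> int:
        return sum(1 for ep in self.epochs if ep.condition == REST)

    def epochs_of(self, condition: str) -> tuple[Epoch, ...]:
        return tuple(ep for ep in self.epochs if ep.condition == condition)


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF: peak at ``peak_s``, undershoot at
    ``undershoot_s``, peak:undershoot amplitude ratio ``ratio``, plus a pure
    onset lag (the assumed hemodynamic delay, 3-6 s per participant)."""

    peak_s: float = 5.0
    undershoot_s: float = 15.0
    ratio: float = 6.0
    lag_s: float = 4.5
    dt: float = 0.1  # internal sampling step, s


def double_gamma_hrf(t: np.ndarray, params: HrfParams = HrfParams()) -> np.ndarray:
    """Evaluate the double-gamma HRF (without the onset lag) at times ``t`` (s).

    Gamma densities with unit scale peak at shape-1, so shapes are
    ``peak_s + 1`` and ``undershoot_s + 1``; the undershoot is subtracted at
    1/ratio amplitude.  Negative times map to 0.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, params.peak_s + 1.0) - gamma.pdf(t, params.undershoot_s + 1.0) / params.ratio
    return np.where(t >= 0, h, 0.0)


@dataclass(frozen=True)
class DesignMatrix:
    """Design matrix: one column per modeled condition, optional six motion
    nuisance columns, and a trailing intercept."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n_volumes, n_regressors)
    hrf: HrfParams

    def __post_init__(self) -> None:
        if len(self.labels) != self.values.shape[1]:
            raise ProtocolError("label count does not match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ProtocolError("duplicated column labels")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> int:
        return self.labels.index(label)

    def contrast_vector(self, label: str) -> np.ndarray:
        """Unit contrast on one task column -- task vs the pooled rest
        baseline, which lives in the intercept."""
        c = np.zeros(len(self.labels))
        c[self.column(label)] = 1.0
        return c


def build_timeline(
    conditions: list[str] | tuple[str, ...],
    n_blocks: int = 5,
    block_s: float = 21.0,
    rest_s: float = 12.0,
    tr: float = 3.0,
    *,
    order: list[str] | None = None,
    seed: int | None = None,
    lead_in_rest: bool = False,
    cue_duration: float | None = None,
) -> ExperimentTimeline:
    """Construct a block-design timeline: every task block is followed by a
    rest period.

    The block order is pseudorandom (per ``seed``) over the interleaved
    conditions unless an explicit ``order`` of length
    ``len(conditions) * n_blocks`` is given.  With three conditions, five
    21-s blocks each and 12-s rests at TR 3 s the run lasts
    3*5*(21+12) = 495 s = 8.25 min and has 15 rest epochs.
    """
    conditions = list(conditions)
    if not conditions:
        return ExperimentTimeline(epochs=(), tr=tr, n_volumes=0, cue_duration=cue_duration)
    if n_blocks < 1:
        raise ProtocolError("n_blocks must be >= 1")
    if block_s <= 0 or rest_s <= 0 or tr <= 0:
        raise ProtocolError("durations and tr must be positive")
    if len(set(conditions)) != len(conditions):
        raise ProtocolError("duplicated condition labels")

    if order is not None:
        expected = sorted(conditions * n_blocks)
        if sorted(order) != expected:
            raise ProtocolError("explicit order must contain each condition n_blocks times")
        sequence = list(order)
    else:
        rng = np.random.default_rng(seed)
        sequence = conditions * n_blocks
        rng.shuffle(sequence)

    # snap block boundaries to the volume grid by rounding onset/TR
    epochs: list[Epoch] = []
    t = 0.0
    for cond in sequence:
        on = round(t / tr) * tr
        t += block_s
        off = round(t / tr) * tr
        epochs.append(Epoch(cond, on, off - on))
        t += rest_s
        rest_off = round(t / tr) * tr
        epochs.append(Epoch(REST, off, rest_off - off))
    if lead_in_rest:
        shift = rest_s
        epochs = [Epoch(REST, 0.0, shift)] + [
            replace(ep, onset=ep.onset + shift) for ep in epochs
        ]
        t += shift
    n_volumes = int(round(t / tr))
    return ExperimentTimeline(
        epochs=tuple(epochs), tr=tr, n_volumes=n_volumes, cue_duration=cue_duration
    )


def rs_spec(seed: int | None = 0, **kw) -> ExperimentTimeline:
    """The repetitive-speech run: RS + two control conditions, five 21-s
    blocks each, 12-s rests, TR 3 s (495 s, 165 volumes, 15 rests)."""
    return build_timeline(["RS", "Motor", "ThoughtControl"], seed=seed, **kw)


def vf_spec(seed: int | None = 0, **kw) -> ExperimentTimeline:
    """The verbal-fluency run: VF + three control conditions (660 s,
    220 volumes, 20 rests)."""
    return build_timeline(
        ["VF", "AbstractThought", "Imagery", "SentenceConjugation"], seed=seed, **kw
    )


def make_regressor(
    timeline: ExperimentTimeline,
    condition: str,
    hrf: HrfParams = HrfParams(),
    *,
    normalize: bool = True,
    strict: bool = True,
    _kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Boxcar over a condition's epochs, shifted by the hemodynamic lag,
    convolved with the HRF, sampled at TR, peak-normalized to 1.

    With ``strict`` (default) a label absent from every epoch raises; with
    ``strict=False`` it yields an all-zero column.  ``_kernel`` overrides the
    HRF samples on the ``hrf.dt`` grid (a unit impulse yields the TR-sampled
    boxcar itself).
    """
    known = any(ep.condition == condition for ep in timeline.epochs)
    if strict and not known and timeline.n_volumes:
        raise ProtocolError(f"unknown condition label: {condition!r}")
    dt = hrf.dt
    n_fine = int(round(timeline.duration / dt)) + 1
    box = np.zeros(n_fine)
    for ep in timeline.epochs_of(condition):
        i0 = int(round((ep.onset + hrf.lag_s) / dt))
        i1 = int(round((ep.offset + hrf.lag_s) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    if _kernel is None:
        t_k = np.arange(0, 32.0 + dt, dt)
        kernel = double_gamma_hrf(t_k, hrf) * dt
    else:
        kernel = np.asarray(_kernel, dtype=float)
    fine = np.convolve(box, kernel)[:n_fine]
    idx = np.round(np.arange(timeline.n_volumes) * timeline.tr / dt).astype(int)
    col = fine[idx]
    if normalize:
        peak = np.max(np.abs(col))
        if peak > 0:
            col = col / peak
    return col


def build_design_matrix(
    timeline: ExperimentTimeline,
    conditions: list[str] | tuple[str, ...] | None = None,
    motion: np.ndarray | None = None,
    hrf: HrfParams = HrfParams(),
    *,
    include_cues: bool = False,
) -> DesignMatrix:
    """Assemble the subject-level design: task regressors (rest is the
    implicit baseline), optional cue regressor, six motion nuisance columns
    when a motion trace is supplied, and an intercept.

    Raises on rank deficiency, naming the collinear columns.
    """
    if conditions is None:
        conditions = timeline.conditions
    conditions = list(conditions)
    if len(set(conditions)) != len(conditions):
        raise ProtocolError("duplicated condition labels")
    cols = [make_regressor(timeline, c, hrf) for c in conditions]
    labels = list(conditions)
    if include_cues:
        cue = timeline.cue_duration or 1.0
        cue_tl = ExperimentTimeline(
            epochs=tuple(
                Epoch("cue", ep.onset, min(cue, ep.duration)) for ep in timeline.epochs
            ),
            tr=timeline.tr,
            n_volumes=timeline.n_volumes,
        )
        cols.append(make_regressor(cue_tl, "cue", hrf))
        labels.append("cue")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (timeline.n_volumes, 6):
            raise ProtocolError(
                f"motion trace must be ({timeline.n_volumes}, 6), got {motion.shape}"
            )
        for i in range(6):
            cols.append(motion[:, i])
        labels += [f"motion{i}" for i in range(1, 7)]
    cols.append(np.ones(timeline.n_volumes))
    labels.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_labels(X, labels)
        raise ProtocolError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(labels=tuple(labels), values=X, hrf=hrf)


def _collinear_labels(X: np.ndarray, labels: list[str]) -> list[str]:
    # greedy: a column is flagged if it lies in the span of the previous ones
    bad = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            bad.append(labels[j])
    return bad or labels
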