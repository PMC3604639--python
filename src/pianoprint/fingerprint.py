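"""Per-note timing deviations, pianistic fingerprints, and unevenness.

The core quantity is the *deviation trace*: fit an ordinary least-squares
straight line to (temporal index, onset time) over the 15 notes of a run and
keep the residuals, in ms, positive meaning late.  The line's slope is free
per run, so local tempo drift and the overall starting time are absorbed and
only the note-by-note microstructure remains.  Traces from many runs of the
same hand x direction are averaged element-wise; the four averaged traces of
one recording session form the 2 (hands) x 2 (directions) x 15 (notes)
fingerprint of that pianist-session.

*Unevenness* (SD-IKI) summarizes a run by the sample standard deviation of
its 14 inter-keystroke intervals, and a session by the median over runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ingest import DIRECTIONS, HANDS, DomainError, ScaleRun

#: canonical cell order of a fingerprint: (hand, body-centered direction)
CELLS: tuple[tuple[str, str], ...] = (
    ("left", "inward"),
    ("left", "outward"),
    ("right", "inward"),
    ("right", "outward"),
)

N_NOTES = 15


@dataclass(frozen=True)
class DeviationTrace:
    """15 per-note lateness residuals (ms) for one hand x direction."""

    values: tuple[float, ...]
    hand: str
    direction: str
    session: str = ""
    n_runs: int = 1

    def __post_init__(self) -> None:
        if len(self.values) != N_NOTES:
            raise DomainError(f"a deviation trace has {N_NOTES} values, got {len(self.values)}")
        if self.hand not in HANDS or self.direction not in DIRECTIONS:
            raise DomainError(f"unknown condition ({self.hand}, {self.direction})")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class Fingerprint:
    """2 x 2 x 15 matrix of mean deviation traces for one pianist-session."""

    traces: dict[tuple[str, str], DeviationTrace] = field(default_factory=dict)
    pianist: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        if set(self.traces) != set(CELLS):
            missing = set(CELLS) - set(self.traces)
            extra = set(self.traces) - set(CELLS)
            raise DomainError(f"fingerprint cells wrong: missing {missing or '{}'}, extra {extra or '{}'}")

    def cell(self, hand: str, direction: str) -> DeviationTrace:
        return self.traces[(hand, direction)]

    def as_array(self) -> np.ndarray:
        """(2 hands, 2 directions, 15 notes) array in canonical cell order."""
        out = np.empty((2, 2, N_NOTES))
        for i, hand in enumerate(HANDS):
            for j, direction in enumerate(DIRECTIONS):
                out[i, j] = self.traces[(hand, direction)].as_array()
        return out


@dataclass(frozen=True)
class UnevennessScore:
    """Median over runs of the per-run SD of inter-keystroke intervals."""

    value: float
    hand: str
    direction: str
    session: str = ""
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DomainError("unevenness is a standard deviation and cannot be negative")


def detrend_onsets(onsets: np.ndarray) -> np.ndarray:
    """OLS residuals of onset times regressed on temporal index.

    Accepts a (n_notes,) vector or an (n_runs, n_notes) matrix; the fit is
    per row.  Used by both the single-run path and the vectorized synthetic
    pipeline so the two cannot disagree.
    """
    y = np.atleast_2d(np.asarray(onsets, dtype=float))
    n = y.shape[1]
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    slope = (y @ xc) / (xc @ xc)
    fitted = y.mean(axis=1, keepdims=True) + slope[:, None] * xc
    resid = y - fitted
    return resid[0] if np.asarray(onsets).ndim == 1 else resid


def fit_deviation_trace(run: ScaleRun) -> DeviationTrace:
    """Deviation trace of one run: observed minus straight-line-fit onsets."""
    onsets = np.asarray(run.onsets, dtype=float)
    if np.allclose(onsets, onsets[0]):
        raise DomainError("degenerate run: all onsets equal")
    resid = detrend_onsets(onsets)
    return DeviationTrace(
        values=tuple(resid),
        hand=run.hand,
        direction=run.direction,
        session=run.session,
        n_runs=1,
    )


def aggregate_traces(traces: list[DeviationTrace]) -> DeviationTrace:
    """Element-wise mean of traces from one condition (hand, direction, session)."""
    if not traces:
        raise DomainError("cannot aggregate an empty list of traces")
    first = traces[0]
    for t in traces[1:]:
        if (t.hand, t.direction, t.session) != (first.hand, first.direction, first.session):
            raise DomainError("cannot aggregate traces from mixed conditions")
    mean = np.mean([t.as_array() for t in traces], axis=0)
    return replace(first, values=tuple(mean), n_runs=len(traces))


def build_fingerprint(
    traces: list[DeviationTrace], pianist: str = "", session: str = ""
) -> Fingerprint:
    """Assemble four aggregated traces (one per cell) into a fingerprint."""
    cells: dict[tuple[str, str], DeviationTrace] = {}
    for t in traces:
        key = (t.hand, t.direction)
        if key in cells:
            raise DomainError(f"duplicate condition {key}")
        cells[key] = t
    if set(cells) != set(CELLS):
        raise DomainError(f"missing condition(s): {set(CELLS) - set(cells)}")
    session = session or traces[0].session
    return Fingerprint(traces=cells, pianist=pianist, session=session)


def run_ikis(run: ScaleRun) -> np.ndarray:
    """The 14 inter-keystroke intervals (ms) of a run."""
    return np.diff(np.asarray(run.onsets, dtype=float))


def run_unevenness(runs: list[ScaleRun]) -> UnevennessScore:
    """Unevenness: median over runs of the sample SD of each run's 14 IKIs."""
    if not runs:
        raise DomainError("cannot score an empty list of runs")
    sds = [float(np.std(run_ikis(r), ddof=1)) for r in runs]
    first = runs[0]
    return UnevennessScore(
        value=float(np.median(sds)),
        hand=first.hand,
        direction=first.direction,
        session=first.session,
        n_runs=len(runs),
    )
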