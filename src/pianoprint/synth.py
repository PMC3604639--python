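"""Synthetic pianist populations and simulated observers.

The generator emulates the statistical structure the analysis assumes: each
pianist owns a latent 2 (hands) x 2 (directions) x 15 (notes) deviation
matrix; a recording session adds a per-cell session-level perturbation; each
scale run adds independent per-keystroke motor noise on the nominal 125 ms
onset grid.

Latent structure per note j of cell (hand h, direction d):

    latent[h, d, j] = s * (sqrt(ec) P_j + sqrt(mc) M_{d,j} + sqrt(1-ec-mc) U_{h,d,j})

with P shared by all four cells (effector coupling ec), M_d shared by the two
cells of the same body-centered movement direction (movement coupling mc),
and U unique - all standard normal, s = ``between_sd``.  Every cell's
marginal per-note SD is s regardless of the couplings.

Calibration of the defaults (moment-matched, then checked by simulation in
the test suite): measured traces are OLS residuals, which shrinks iid per-
note noise by sqrt(13/15).  With between_sd 4.85, session_sd 2.5,
keystroke_sd 2.5 and 12 runs per session the model predicts a between-
pianist trace distance near 7.2 ms, a within-pianist cross-session distance
near 3.4 ms, and a median run unevenness between 8 and 9 ms - the regime of
professional scale playing at 8 notes/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fingerprint import (
    CELLS,
    DeviationTrace,
    Fingerprint,
    N_NOTES,
    detrend_onsets,
)
from .ingest import DomainError, NoteEvent, ScaleRun, ScaleSpec, expected_pitch_sequence
from .mlp import PsychometricCurve, psychometric_p
from .smf import RawNote, write_smf

# calibrated generator defaults (ms); see module docstring
BETWEEN_SD = 4.85
SESSION_SD = 2.5
KEYSTROKE_SD = 2.5
MOVEMENT_COUPLING = 0.25
EFFECTOR_COUPLING = 0.10
N_RUNS = 12
BASE_IOI = 125.0


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SyntheticPianist:
    """Ground-truth latent deviation profile of one simulated pianist."""

    label: str
    latent: np.ndarray  # (2 hands, 2 directions, 15 notes), ms
    movement_coupling: float
    effector_coupling: float

    def latent_trace(self, hand: str, direction: str) -> np.ndarray:
        i = ("left", "right").index(hand)
        j = ("inward", "outward").index(direction)
        return self.latent[i, j]


def gen_population(
    n_pianists: int = 8,
    between_sd: float = BETWEEN_SD,
    movement_coupling: float = MOVEMENT_COUPLING,
    effector_coupling: float = EFFECTOR_COUPLING,
    seed: int | np.random.Generator = 0,
    magnitude_matched: bool = False,
) -> list[SyntheticPianist]:
    """Draw a population of latent fingerprints.

    With ``magnitude_matched`` every cell's latent vector is rescaled to the
    same RMS (``between_sd``), so pianists differ in trace *shape* only - the
    regime in which overall unevenness carries no identity information.
    """
    if n_pianists < 2:
        raise DomainError("need at least two pianists")
    if between_sd <= 0:
        raise DomainError("between_sd must be positive")
    for c in (movement_coupling, effector_coupling):
        if not 0 <= c <= 1:
            raise DomainError("couplings must lie in [0, 1]")
    if movement_coupling + effector_coupling > 1:
        raise DomainError("movement_coupling + effector_coupling must not exceed 1")
    rng = _rng(seed)
    unique_w = np.sqrt(1 - movement_coupling - effector_coupling)
    pop = []
    for p in range(n_pianists):
        shared = rng.standard_normal(N_NOTES)  # across all four cells
        per_direction = rng.standard_normal((2, N_NOTES))  # per movement direction
        unique = rng.standard_normal((2, 2, N_NOTES))
        latent = between_sd * (
            np.sqrt(effector_coupling) * shared[None, None, :]
            + np.sqrt(movement_coupling) * per_direction[None, :, :]
            + unique_w * unique
        )
        if magnitude_matched:
            rms = np.sqrt(np.mean(latent**2, axis=2, keepdims=True))
            latent = latent * (between_sd / rms)
        pop.append(
            SyntheticPianist(
                label=f"P{p + 1:02d}",
                latent=latent,
                movement_coupling=movement_coupling,
                effector_coupling=effector_coupling,
            )
        )
    return pop


def gen_session_runs(
    pianist: SyntheticPianist,
    session: str = "first",
    n_runs: int = N_RUNS,
    session_sd: float = SESSION_SD,
    keystroke_sd: float = KEYSTROKE_SD,
    base_ioi: float = BASE_IOI,
    seed: int | np.random.Generator = 0,
    drift_sd: float = 0.0,
    left_hand_noise_multiplier: float = 1.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Simulate one recording session: onset matrices per fingerprint cell.

    Returns {(hand, direction): (n_runs, 15) onsets in ms}.  Each cell draws
    one per-note session shift (SD ``session_sd``) plus, optionally, a
    between-session drift of the latent profile (SD ``drift_sd``, for long
    retest intervals); each run adds iid per-keystroke noise.  The optional
    left-hand multiplier scales the left hand's keystroke noise (off at 1.0).
    """
    if n_runs < 1:
        raise DomainError("need at least one run")
    if session_sd < 0 or keystroke_sd < 0 or drift_sd < 0:
        raise DomainError("noise SDs must be non-negative")
    rng = _rng(seed)
    grid = np.arange(N_NOTES) * base_ioi
    out: dict[tuple[str, str], np.ndarray] = {}
    for hand, direction in CELLS:
        latent = pianist.latent_trace(hand, direction)
        shift = rng.normal(0.0, session_sd, N_NOTES) if session_sd else np.zeros(N_NOTES)
        drift = rng.normal(0.0, drift_sd, N_NOTES) if drift_sd else 0.0
        k_sd = keystroke_sd * (left_hand_noise_multiplier if hand == "left" else 1.0)
        noise = rng.normal(0.0, k_sd, (n_runs, N_NOTES)) if k_sd else np.zeros((n_runs, N_NOTES))
        out[(hand, direction)] = grid[None, :] + latent[None, :] + shift[None, :] + drift + noise
    return out


def session_fingerprint(
    runs: dict[tuple[str, str], np.ndarray],
    pianist: str = "",
    session: str = "",
) -> Fingerprint:
    """Detrend every run, average per cell, and assemble the fingerprint.

    Uses the same OLS detrending as the single-run pipeline
    (``fingerprint.detrend_onsets``), vectorized over runs.
    """
    traces = {}
    for (hand, direction), onsets in runs.items():
        resid = detrend_onsets(onsets)
        traces[(hand, direction)] = DeviationTrace(
            values=tuple(resid.mean(axis=0)),
            hand=hand,
            direction=direction,
            session=session,
            n_runs=onsets.shape[0],
        )
    return Fingerprint(traces=traces, pianist=pianist, session=session)


def session_unevenness(runs: dict[tuple[str, str], np.ndarray]) -> dict[tuple[str, str], float]:
    """Median over runs of the per-run sample SD of the 14 IKIs, per cell."""
    return {
        cell: float(np.median(np.std(np.diff(onsets, axis=1), axis=1, ddof=1)))
        for cell, onsets in runs.items()
    }


def runs_to_scale_runs(
    onsets: np.ndarray,
    hand: str,
    direction: str,
    session: str = "",
    spec: ScaleSpec | None = None,
    note_duration: float = 137.5,
) -> list[ScaleRun]:
    """Materialize simulated onset rows as validated ScaleRun objects."""
    spec = spec or ScaleSpec()
    pitches = expected_pitch_sequence(spec, hand, direction)
    runs = []
    for row in np.atleast_2d(onsets):
        notes = tuple(
            NoteEvent(pitch=p, onset=float(t), offset=float(t) + note_duration)
            for p, t in zip(pitches, row)
        )
        runs.append(ScaleRun(notes=notes, hand=hand, direction=direction, session=session, spec=spec))
    return runs


def session_to_smf(
    runs: dict[tuple[str, str], np.ndarray],
    spec: ScaleSpec | None = None,
    gap_ms: float = 1000.0,
    note_duration: float = 137.5,
) -> dict[tuple[str, str], bytes]:
    """Serialize a session to one SMF per cell, runs concatenated with a gap."""
    spec = spec or ScaleSpec()
    out = {}
    for (hand, direction), cell_onsets in runs.items():
        pitches = expected_pitch_sequence(spec, hand, direction)
        notes = []
        t0 = 0.0
        for row in np.atleast_2d(cell_onsets):
            start = t0 - row[0]
            for p, t in zip(pitches, row):
                notes.append(
                    RawNote(pitch=p, onset_ms=start + float(t),
                            offset_ms=start + float(t) + note_duration, velocity=64)
                )
            t0 = start + row[-1] + gap_ms
        out[(hand, direction)] = write_smf(notes)
    return out


# ---------------------------------------------------------------------------
# simulated observers


@dataclass
class ObserverModel:
    """Stochastic regular/irregular responder with a known psychometric curve.

    ``kind`` selects the decision variable: ``factor_threshold`` responds to
    the magnification factor itself; ``unevenness_threshold`` responds to the
    rendered scale's unevenness in ms (its curve midpoint and slope live on
    the ms scale), which makes the ms threshold a property of the observer
    rather than of the probe trace.
    """

    kind: str
    curve: PsychometricCurve
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        if self.kind not in ("factor_threshold", "unevenness_threshold"):
            raise DomainError(f"unknown observer kind {self.kind!r}")

    def p_irregular(self, factor: float, unevenness_ms: float | None = None) -> float:
        x = factor if self.kind == "factor_threshold" else unevenness_ms
        if x is None or np.isnan(x):
            raise DomainError("unevenness-threshold observer needs the stimulus unevenness")
        return float(psychometric_p(self.curve, x))

    def respond(
        self,
        factor: float,
        unevenness_ms: float | None = None,
        rng: np.random.Generator | None = None,
    ) -> bool:
        rng = rng or self.rng
        return bool(rng.random() < self.p_irregular(factor, unevenness_ms))


def gen_observer(kind: str, params: dict, seed: int | np.random.Generator = 0) -> ObserverModel:
    """Build a seeded observer; ``params`` hold the true curve (a, m, k)."""
    curve = PsychometricCurve(
        a=float(params.get("a", 0.0)),
        m=float(params["m"]),
        k=float(params.get("k", 4.0)),
    )
    return ObserverModel(kind=kind, curve=curve, rng=_rng(seed))


@dataclass
class RecognitionObserver:
    """Same/different judge for scale pairs, deaf to sub-threshold deviations.

    A scale's deviations register only if its unevenness exceeds
    ``threshold_ms`` (the irregularity detection threshold); otherwise the
    scale is heard as isochronous.  The judge responds "different pianists"
    when the distance between the two perceived traces, plus internal noise,
    exceeds ``criterion_ms``; on a lapse (probability ``lapse_rate``) it
    guesses.
    """

    threshold_ms: float = 10.22
    criterion_ms: float = 25.0
    internal_noise_ms: float = 3.0
    lapse_rate: float = 0.1

    def respond_different(
        self,
        trace_a: DeviationTrace,
        trace_b: DeviationTrace,
        factor: float,
        rng: np.random.Generator,
        base_ioi: float = BASE_IOI,
    ) -> bool:
        from .stimulus import factor_to_unevenness  # local import avoids a cycle

        if rng.random() < self.lapse_rate:
            return bool(rng.random() < 0.5)
        va = factor * trace_a.as_array()
        vb = factor * trace_b.as_array()
        if factor_to_unevenness(factor, trace_a, base_ioi) <= self.threshold_ms:
            va = np.zeros_like(va)
        if factor_to_unevenness(factor, trace_b, base_ioi) <= self.threshold_ms:
            vb = np.zeros_like(vb)
        d = float(np.sqrt(np.mean((va - vb) ** 2))) + rng.normal(0.0, self.internal_noise_ms)
        return d > self.criterion_ms
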