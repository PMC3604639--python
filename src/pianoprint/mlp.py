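"""Maximum-likelihood adaptive procedure for irregularity thresholds.

The procedure maintains a grid of hypothetical psychometric curves

    p(yes) = a + (1 - a) / (1 + exp(-k (x - m)))

with 500 midpoints m linearly spaced over the magnification-factor range
[0, 5], crossed with false-alarm rates a in {0, .10, .20, .30, .40} and a
fixed slope k = 4 - 2500 curves in all.  After every response the likelihood
of the full response history is evaluated under each curve; the next stimulus
is placed at the 64%-response point of the maximum-likelihood curve.  The
block threshold is the midpoint of the final maximum-likelihood curve.

Six catch trials (factor 0) per 36-trial block - two within the first 12
trials, four over the remaining 24 - estimate the observer's false-alarm
behaviour; a block whose catch "irregular" ratio exceeds 30% is flagged
invalid.  Catch trials never enter the likelihood history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .fingerprint import DeviationTrace
from .ingest import DomainError
from .stimulus import factor_to_unevenness

log = logging.getLogger(__name__)

FALSE_ALARM_RATES = (0.0, 0.10, 0.20, 0.30, 0.40)
N_MIDPOINTS = 500
FACTOR_RANGE = (0.0, 5.0)
SLOPE = 4.0
TARGET_P = 0.64
_P_FLOOR = 1e-9  # keeps a=0 hypotheses comparable when they predict p=0


@dataclass(frozen=True)
class PsychometricCurve:
    """One hypothetical yes-probability curve: false-alarm a, midpoint m, slope k."""

    a: float
    m: float
    k: float = SLOPE

    def __post_init__(self) -> None:
        if not 0 <= self.a < 1:
            raise DomainError(f"false-alarm rate must be in [0, 1), got {self.a}")
        if self.k <= 0:
            raise DomainError("slope must be positive")


def psychometric_p(curve: PsychometricCurve, x: float | np.ndarray) -> float | np.ndarray:
    """p(responding 'irregular') at stimulus level x under the curve."""
    p = curve.a + (1 - curve.a) / (1 + np.exp(-curve.k * (np.asarray(x, dtype=float) - curve.m)))
    return float(p) if np.isscalar(x) else p


@dataclass
class MLPState:
    """Grid of candidate curves plus the adaptive response history.

    Likelihoods are recomputed from the full history on demand; tie-breaks
    (including the empty history, where all curves are equally likely) go to
    the lowest grid index, i.e. smallest false-alarm rate, then smallest
    midpoint.
    """

    midpoints: np.ndarray = field(
        default_factory=lambda: np.tile(np.linspace(*FACTOR_RANGE, N_MIDPOINTS), len(FALSE_ALARM_RATES))
    )
    false_alarms: np.ndarray = field(
        default_factory=lambda: np.repeat(FALSE_ALARM_RATES, N_MIDPOINTS)
    )
    slope: float = SLOPE
    history: list[tuple[float, bool]] = field(default_factory=list)
    _ll: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_curves(self) -> int:
        return len(self.midpoints)

    def _trial_log_p(self, x: float, response: bool) -> np.ndarray:
        p = self.false_alarms + (1 - self.false_alarms) / (
            1 + np.exp(-self.slope * (x - self.midpoints))
        )
        p = np.clip(p, _P_FLOOR, 1 - _P_FLOOR)
        return np.log(p if response else 1 - p)

    def record(self, x: float, response: bool) -> None:
        """Append one adaptive trial (stimulus level, yes/no) to the history."""
        self.history.append((float(x), bool(response)))
        if self._ll is None:
            self._ll = np.zeros(self.n_curves)
        self._ll = self._ll + self._trial_log_p(float(x), bool(response))

    def log_likelihoods(self) -> np.ndarray:
        """Log-likelihood of the full history under every grid curve.

        Kept incrementally (one term added per recorded trial); identical to
        ``recompute_log_likelihoods`` up to floating-point summation order.
        """
        return np.zeros(self.n_curves) if self._ll is None else self._ll

    def recompute_log_likelihoods(self) -> np.ndarray:
        """Naive from-scratch recomputation over the stored history."""
        ll = np.zeros(self.n_curves)
        for x, response in self.history:
            ll += self._trial_log_p(x, response)
        return ll

    def ml_curve(self) -> PsychometricCurve:
        """The maximum-likelihood curve (lowest index on ties)."""
        i = int(np.argmax(self.log_likelihoods()))
        return PsychometricCurve(a=float(self.false_alarms[i]), m=float(self.midpoints[i]), k=self.slope)


def mlp_next_level(state: MLPState) -> float:
    """Stimulus level for the next trial: the 64%-response point of the ML curve.

    Inverts a + (1-a) L(x) = 0.64 analytically; if the curve's false-alarm
    rate already exceeds 64% the target is unattainable and the grid maximum
    is returned with a warning.  The level is clipped to the factor range.
    """
    curve = state.ml_curve()
    if curve.a >= TARGET_P:
        log.warning("64%% point unattainable for a=%.2f; presenting grid maximum", curve.a)
        return FACTOR_RANGE[1]
    L = (TARGET_P - curve.a) / (1 - curve.a)
    x = curve.m + np.log(L / (1 - L)) / curve.k
    return float(np.clip(x, *FACTOR_RANGE))


@dataclass(frozen=True)
class TrialRecord:
    index: int
    x: float
    is_catch: bool
    response: bool


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of one thresholding block."""

    threshold_factor: float
    threshold_unevenness: float  # nan when no base trace was supplied
    valid: bool
    catch_false_alarm_rate: float
    trials: tuple[TrialRecord, ...]


def catch_positions(rng: np.random.Generator, n_trials: int = 36) -> np.ndarray:
    """Six catch-trial positions: two in trials 1-12, four in the remainder."""
    first = rng.choice(12, size=2, replace=False)
    rest = rng.choice(np.arange(12, n_trials), size=4, replace=False)
    return np.sort(np.concatenate([first, rest]))


def mlp_run_block(
    observer,
    n_trials: int = 36,
    seed: int | np.random.Generator = 0,
    base_trace: DeviationTrace | None = None,
    catch_included_in_total: bool = True,
    max_catch_rate: float = 0.30,
) -> ThresholdResult:
    """Run one adaptive thresholding block against a simulated observer.

    ``observer`` must expose ``respond(factor, unevenness_ms, rng) -> bool``.
    Catch trials present factor 0 and are excluded from the likelihood
    history.  With ``catch_included_in_total`` (default) the six catches
    count toward ``n_trials``, leaving 30 adaptive trials; otherwise six
    catches are appended on top.  The threshold is the midpoint of the final
    maximum-likelihood curve; ``threshold_unevenness`` converts it to ms via
    ``base_trace`` when one is given.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = n_trials if catch_included_in_total else n_trials + 6
    catches = set(int(i) for i in catch_positions(rng, total))
    state = MLPState()
    records: list[TrialRecord] = []
    for t in range(total):
        is_catch = t in catches
        x = 0.0 if is_catch else mlp_next_level(state)
        unevenness = factor_to_unevenness(x, base_trace) if base_trace is not None else float("nan")
        response = bool(observer.respond(x, unevenness, rng))
        records.append(TrialRecord(index=t, x=x, is_catch=is_catch, response=response))
        if not is_catch:
            state.record(x, response)
    catch_rate = float(np.mean([r.response for r in records if r.is_catch]))
    threshold = state.ml_curve().m
    threshold_ms = (
        factor_to_unevenness(threshold, base_trace) if base_trace is not None else float("nan")
    )
    return ThresholdResult(
        threshold_factor=threshold,
        threshold_unevenness=threshold_ms,
        valid=catch_rate <= max_catch_rate,
        catch_false_alarm_rate=catch_rate,
        trials=tuple(records),
    )


def dprime(
    hit_rate: float,
    false_alarm_rate: float,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> float:
    """Signal-detection sensitivity: z(hit rate) - z(false-alarm rate).

    Rates of exactly 0 or 1 give infinite quantiles; when the per-class trial
    count is supplied they are pulled in to 1/(2n) and 1 - 1/(2n).
    """
    if not (0 <= hit_rate <= 1 and 0 <= false_alarm_rate <= 1):
        raise DomainError("rates must lie in [0, 1]")

    def adjust(rate: float, n: int | None) -> float:
        if rate in (0.0, 1.0):
            if n is None:
                raise DomainError("extreme rate needs the trial count for the 1/(2n) adjustment")
            return 1 / (2 * n) if rate == 0.0 else 1 - 1 / (2 * n)
        return rate

    h = adjust(hit_rate, n_signal)
    f = adjust(false_alarm_rate, n_noise)
    return float(norm.ppf(h) - norm.ppf(f))
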