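import numpy as np
import pytest

from pianoprint import DeviationTrace, ScaleSpec
from pianoprint.synth import gen_population, gen_session_runs, session_fingerprint


@pytest.fixture(scope="session")
def spec() -> ScaleSpec:
    return ScaleSpec()


def make_trace(values, hand="right", direction="outward", session="", n_runs=1) -> DeviationTrace:
    values = np.asarray(values, dtype=float)
    if values.size != 15:
        raise ValueError("test traces must have 15 values")
    return DeviationTrace(values=tuple(values), hand=hand, direction=direction,
                          session=session, n_runs=n_runs)


def cohort_fingerprints(n_pianists=8, seed=0, session_seed=1000, **gen_kw):
    """Population -> per-(pianist, session) fingerprints, the fast numeric path."""
    pop = gen_population(n_pianists, seed=seed, **{k: v for k, v in gen_kw.items()
                                                   if k in ("between_sd", "movement_coupling",
                                                            "effector_coupling", "magnitude_matched")})
    run_kw = {k: v for k, v in gen_kw.items()
              if k in ("n_runs", "session_sd", "keystroke_sd", "drift_sd")}
    rng = np.random.default_rng(session_seed)
    fps = {}
    for p in pop:
        for s in ("first", "followup"):
            runs = gen_session_runs(p, session=s, seed=rng, **run_kw)
            fps[(p.label, s)] = session_fingerprint(runs, p.label, s)
    return pop, fps


@pytest.fixture(scope="session")
def small_cohort():
    """Eight pianists, two sessions, default calibration."""
    return cohort_fingerprints(8, seed=42, session_seed=4242)
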