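"""The synthetic generator: calibration, structure, and observers."""

import numpy as np
import pytest

from conftest import cohort_fingerprints
from pianoprint.fingerprint import CELLS
from pianoprint.ingest import DomainError, extract_valid_runs, read_midi_notes, ScaleSpec
from pianoprint.similarity import grouped_contrasts, nn_identify, trace_distance
from pianoprint.synth import (
    ObserverModel,
    gen_observer,
    gen_population,
    gen_session_runs,
    runs_to_scale_runs,
    session_fingerprint,
    session_to_smf,
    session_unevenness,
)


class TestGenPopulation:
    def test_reproducible_and_marginal_sd(self):
        a = gen_population(8, seed=5)
        b = gen_population(8, seed=5)
        assert all(np.array_equal(x.latent, y.latent) for x, y in zip(a, b))
        latents = np.concatenate([p.latent.ravel() for p in gen_population(50, seed=0)])
        assert np.std(latents) == pytest.approx(4.85, rel=0.05)

    def test_zero_spread_population_is_at_chance(self):
        with pytest.raises(DomainError):
            gen_population(8, between_sd=0.0)

    def test_independent_cells_distance_is_sqrt2_sigma(self):
        # E|X-Y|^2 = 2 sigma^2 for independent zero-mean latents; the mean
        # distance sits slightly below sqrt(2)*sigma (Jensen: E chi_15/sqrt(15)
        # ~ 0.983), so compare the mean *squared* distance exactly and the
        # mean distance with the chi correction
        pop = gen_population(60, between_sd=5.0, movement_coupling=0.0,
                             effector_coupling=0.0, seed=1)
        dists = np.array([
            trace_distance(pop[i].latent_trace("right", "outward"),
                           pop[j].latent_trace("right", "outward"))
            for i in range(len(pop)) for j in range(i + 1, len(pop))
        ])
        assert np.mean(dists**2) == pytest.approx(2 * 5.0**2, rel=0.05)
        from scipy.special import gamma

        chi_corr = np.sqrt(2 / 15) * gamma(8) / gamma(7.5)
        assert np.mean(dists) == pytest.approx(np.sqrt(2) * 5.0 * chi_corr, rel=0.03)

    def test_invalid_couplings_rejected(self):
        with pytest.raises(DomainError):
            gen_population(8, movement_coupling=0.7, effector_coupling=0.5)

    def test_magnitude_matched_cells_have_equal_rms(self):
        pop = gen_population(8, magnitude_matched=True, seed=2)
        for p in pop:
            rms = np.sqrt(np.mean(p.latent**2, axis=2))
            assert np.allclose(rms, 4.85)


class TestGenSessionRuns:
    def test_noiseless_session_recovers_latent_exactly(self):
        pop = gen_population(4, seed=3)
        runs = gen_session_runs(pop[0], n_runs=3, session_sd=0.0, keystroke_sd=0.0, seed=0)
        fp = session_fingerprint(runs, pop[0].label, "first")
        for hand, direction in CELLS:
            latent = pop[0].latent_trace(hand, direction)
            from pianoprint.fingerprint import detrend_onsets

            assert np.allclose(fp.cell(hand, direction).as_array(), detrend_onsets(latent), atol=1e-9)

    def test_calibration_between_within_and_unevenness(self):
        """Defaults reproduce the study regime: ~7.2 ms between-pianist trace
        distance, ~3.4 ms within-pianist across sessions, 8-9 ms unevenness."""
        between, within, unev = [], [], []
        for seed in range(25):
            _, fps = cohort_fingerprints(8, seed=seed, session_seed=900 + seed)
            pianists = sorted({p for p, _ in fps})
            for a in pianists:
                for b in pianists:
                    for cell in CELLS:
                        d = trace_distance(fps[(a, "first")].cell(*cell),
                                           fps[(b, "followup")].cell(*cell))
                        (within if a == b else between).append(d)
        for seed in range(10):
            pop = gen_population(8, seed=seed)
            for p in pop:
                unev.extend(session_unevenness(gen_session_runs(p, seed=seed)).values())
        assert np.mean(within) == pytest.approx(3.42, abs=0.5)
        assert np.mean(between) == pytest.approx(7.24, abs=0.5)
        assert 8.0 <= np.mean(unev) <= 9.0

    def test_self_distance_shrinks_with_run_count(self):
        pop = gen_population(2, seed=7)
        p = pop[0]

        def self_dist(n_runs, seed):
            f1 = session_fingerprint(gen_session_runs(p, n_runs=n_runs, session_sd=0.0, seed=seed))
            f2 = session_fingerprint(gen_session_runs(p, n_runs=n_runs, session_sd=0.0, seed=seed + 1))
            return np.mean([trace_distance(f1.cell(*c), f2.cell(*c)) for c in CELLS])

        few = np.mean([self_dist(2, 10 + i) for i in range(20)])
        many = np.mean([self_dist(32, 200 + i) for i in range(20)])
        assert many < few
        assert many == pytest.approx(few / 4, rel=0.35)  # noise ~ 1/sqrt(n_runs)

    def test_movement_coupling_orders_contrasts(self):
        wins_movement, wins_crosshand = 0, 0
        n_seeds = 30
        for seed in range(n_seeds):
            _, fps = cohort_fingerprints(6, seed=seed, session_seed=5000 + seed)
            table = grouped_contrasts(list(fps.values())).set_index(["contrast", "group"])["mean"]
            wins_movement += table[("movement_sound", "same_movement")] < table[("movement_sound", "same_sound")]
            wins_crosshand += table[("cross_hand", "same_pianist")] < table[("cross_hand", "different_pianist")]
        assert wins_movement >= n_seeds - 2
        assert wins_crosshand >= n_seeds - 2

    def test_through_midi_pipeline_matches_numeric_path(self):
        pop = gen_population(2, seed=11)
        runs = gen_session_runs(pop[0], n_runs=3, seed=4)
        numeric_fp = session_fingerprint(runs, pop[0].label, "first")
        spec = ScaleSpec()
        for (hand, direction), data in session_to_smf(runs).items():
            events = read_midi_notes(data)
            scale_runs = extract_valid_runs(events, spec, hand, direction)
            assert len(scale_runs) == 3
            from pianoprint.fingerprint import aggregate_traces, fit_deviation_trace

            agg = aggregate_traces([fit_deviation_trace(r) for r in scale_runs])
            assert np.max(np.abs(agg.as_array() - numeric_fp.cell(hand, direction).as_array())) < 1.0


class TestObservers:
    def test_far_above_midpoint_always_irregular(self):
        obs = gen_observer("factor_threshold", {"m": 1.0, "a": 0.0}, seed=0)
        assert obs.p_irregular(50.0) == pytest.approx(1.0)

    def test_false_alarm_rate_at_zero_stimulus(self):
        obs = gen_observer("factor_threshold", {"m": 2.5, "a": 0.2}, seed=1)
        rng = np.random.default_rng(2)
        responses = [obs.respond(0.0, rng=rng) for _ in range(10_000)]
        assert np.mean(responses) == pytest.approx(0.2, abs=0.02)

    def test_unevenness_observer_needs_unevenness(self):
        obs = gen_observer("unevenness_threshold", {"m": 10.22, "a": 0.0, "k": 0.8}, seed=0)
        with pytest.raises(DomainError):
            obs.p_irregular(2.0, None)
        assert obs.p_irregular(2.0, 10.22) == pytest.approx(0.5)

    def test_ms_threshold_invariant_to_base_trace(self):
        """An observer whose decision variable is unevenness in ms yields the
        same ms threshold from probe traces of different base unevenness,
        while the factor thresholds differ (more uneven trace -> lower factor
        threshold)."""
        from conftest import make_trace
        from pianoprint.mlp import mlp_run_block
        from pianoprint.stimulus import trace_unevenness

        rng = np.random.default_rng(3)
        v = rng.normal(0, 3, 15)
        unit = v / np.std(np.diff(v), ddof=1)  # base unevenness exactly 1 ms
        quiet = make_trace(unit * 3.0)   # factor threshold ~ 10.22/3.0 ~ 3.4
        loud = make_trace(unit * 7.5)    # factor threshold ~ 10.22/7.5 ~ 1.4

        def thresholds(base, n=20):
            f, ms = [], []
            for s in range(n):
                obs = gen_observer("unevenness_threshold", {"m": 10.22, "a": 0.0, "k": 2.0}, seed=s)
                res = mlp_run_block(obs, seed=700 + s, base_trace=base)
                f.append(res.threshold_factor)
                ms.append(res.threshold_unevenness)
            return np.mean(f), np.mean(ms)

        f_quiet, ms_quiet = thresholds(quiet)
        f_loud, ms_loud = thresholds(loud)
        assert f_loud < f_quiet
        assert ms_quiet == pytest.approx(10.22, abs=2.0)
        assert ms_loud == pytest.approx(10.22, abs=2.0)

    def test_unknown_observer_kind_rejected(self):
        from pianoprint.mlp import PsychometricCurve

        with pytest.raises(DomainError):
            ObserverModel(kind="nope", curve=PsychometricCurve(a=0.0, m=1.0))
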