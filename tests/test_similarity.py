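"""Distances, correlations, nearest-match identification, and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trace
from pianoprint.fingerprint import CELLS, Fingerprint
from pianoprint.ingest import DomainError
from pianoprint.similarity import (
    bootstrap_recognition,
    fingerprint_distance,
    grouped_contrast_distances,
    grouped_contrasts,
    nn_identify,
    recognition_stats,
    trace_correlation,
    trace_distance,
)

vec15 = st.lists(st.floats(-20, 20), min_size=15, max_size=15)


def fp_from_array(arr, pianist="", session=""):
    traces = {
        (h, d): make_trace(arr[i, j], hand=h, direction=d, session=session)
        for i, h in enumerate(("left", "right"))
        for j, d in enumerate(("inward", "outward"))
    }
    return Fingerprint(traces=traces, pianist=pianist, session=session)


class TestTraceDistance:
    def test_identity_and_constant_offset(self):
        a = make_trace(np.sin(np.arange(15)))
        assert trace_distance(a, a) == 0.0
        b = make_trace(np.sin(np.arange(15)) + 2.0)
        assert trace_distance(a, b) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=30)
    @given(a=vec15, b=vec15)
    def test_matches_rms_oracle_and_metric_axioms(self, a, b):
        ta, tb = make_trace(a), make_trace(b)
        d = trace_distance(ta, tb)
        oracle = float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 15))
        assert d == pytest.approx(oracle)
        assert d >= 0
        assert trace_distance(tb, ta) == pytest.approx(d)

    @settings(derandomize=True, max_examples=30)
    @given(a=vec15, b=vec15, c=vec15)
    def test_triangle_inequality(self, a, b, c):
        ta, tb, tc = (make_trace(v) for v in (a, b, c))
        assert trace_distance(ta, tc) <= trace_distance(ta, tb) + trace_distance(tb, tc) + 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            trace_distance(np.zeros(15), np.zeros(14))


class TestTraceCorrelation:
    def test_self_correlation_capped(self, caplog):
        a = make_trace(np.sin(np.arange(15)))
        with caplog.at_level("WARNING"):
            r, z = trace_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert np.isfinite(z) and z > 10

    def test_sign_flip_and_affine_invariance(self):
        v = np.sin(np.arange(15))
        v = v - v.mean()
        r_neg, _ = trace_correlation(make_trace(v), make_trace(-v))
        assert r_neg == pytest.approx(-1.0)
        r_affine, _ = trace_correlation(make_trace(v), make_trace(2 * v + 7))
        assert r_affine == pytest.approx(1.0)

    def test_constant_trace_rejected(self):
        with pytest.raises(DomainError, match="constant"):
            trace_correlation(make_trace(np.zeros(15)), make_trace(np.arange(15.0)))


class TestFingerprintDistance:
    def test_equal_fingerprints_distance_zero(self):
        rng = np.random.default_rng(0)
        fp = fp_from_array(rng.normal(0, 5, (2, 2, 15)))
        assert fingerprint_distance(fp, fp) == 0.0

    def test_single_cell_reduces_to_trace_distance(self):
        rng = np.random.default_rng(1)
        a, b = (fp_from_array(rng.normal(0, 5, (2, 2, 15))) for _ in range(2))
        cell = ("right", "outward")
        assert fingerprint_distance(a, b, cells=[cell]) == pytest.approx(
            trace_distance(a.cell(*cell), b.cell(*cell))
        )

    def test_space_alignment_reverses_mirrored_cross_hand_traces(self):
        # left-inward sounds ascending, right-inward descending: build a
        # pianist whose two inward traces are mirror images in time
        rng = np.random.default_rng(2)
        arr = rng.normal(0, 5, (2, 2, 15))
        arr[1, 0] = arr[0, 0][::-1]  # right-inward = reversed left-inward
        fp = fp_from_array(arr)
        pair = [(("left", "inward"), ("right", "inward"))]
        d_space = fingerprint_distance(fp, fp, cells=pair, alignment="space")
        d_time = fingerprint_distance(fp, fp, cells=pair, alignment="time")
        assert d_space == pytest.approx(0.0)
        assert d_time > 0

    def test_empty_cell_set_rejected(self):
        rng = np.random.default_rng(3)
        fp = fp_from_array(rng.normal(0, 5, (2, 2, 15)))
        with pytest.raises(DomainError):
            fingerprint_distance(fp, fp, cells=[])


class TestNNIdentify:
    def make_population(self, n=8, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        db, queries = [], []
        for i in range(n):
            arr = rng.normal(0, 5, (2, 2, 15))
            db.append(fp_from_array(arr, pianist=f"P{i:02d}", session="first"))
            queries.append(
                fp_from_array(arr + rng.normal(0, noise, arr.shape),
                              pianist=f"P{i:02d}", session="followup")
            )
        return queries, db

    def test_identical_database_gives_perfect_rate(self):
        queries, db = self.make_population(noise=0.0)
        res = nn_identify(queries, db)
        assert res.rate == 1.0
        assert res.chance == pytest.approx(0.125)

    def test_distance_and_correlation_agree_on_offset_free_population(self):
        queries, db = self.make_population(noise=1.0, seed=5)
        r1 = nn_identify(queries, db, metric="distance")
        r2 = nn_identify(queries, db, metric="correlation")
        assert r1.assignments == r2.assignments

    def test_relabeling_invariance(self):
        queries, db = self.make_population(noise=1.0, seed=6)
        res = nn_identify(queries, db)
        perm = np.random.default_rng(0).permutation(len(db))
        res_shuffled = nn_identify(queries, [db[i] for i in perm])
        assert res.assignments == res_shuffled.assignments

    def test_empty_database_rejected(self):
        queries, db = self.make_population()
        with pytest.raises(DomainError):
            nn_identify(queries, [])

    def test_duplicate_labels_rejected(self):
        queries, db = self.make_population()
        with pytest.raises(DomainError):
            nn_identify(queries, db + [db[0]])


class TestRecognitionStats:
    @pytest.mark.parametrize(
        "k,n,printed",
        [
            (6, 8, (0.35, 0.97)),
            (8, 8, (0.63, 1.0)),
            (15, 18, (0.59, 0.96)),
            (18, 18, (0.81, 1.0)),
            (7, 20, (0.15, 0.59)),
        ],
    )
    def test_clopper_pearson_intervals_round_to_printed_values(self, k, n, printed):
        _, (lo, hi) = recognition_stats(k, n, 0.125)
        assert (round(lo, 2), round(hi, 2)) == printed

    def test_zero_successes_lower_bound_is_zero(self):
        _, (lo, hi) = recognition_stats(0, 10, 0.125)
        assert lo == 0.0

    def test_binomial_p_matches_exact_tail_oracle(self):
        from math import comb

        k, n, chance = 6, 8, 0.125
        p, _ = recognition_stats(k, n, chance)
        oracle = sum(comb(n, j) * chance**j * (1 - chance) ** (n - j) for j in range(k, n + 1))
        assert p == pytest.approx(oracle)
        assert p < 0.001

    def test_coverage_at_half(self):
        # Clopper-Pearson is conservative: coverage >= 95% at n=8, p=0.5
        from scipy.stats import binom

        n, p_true = 8, 0.5
        cover = 0.0
        for k in range(n + 1):
            _, (lo, hi) = recognition_stats(k, n, 0.5)
            if lo <= p_true <= hi:
                cover += float(binom.pmf(k, n, p_true))
        assert cover >= 0.95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            recognition_stats(9, 8, 0.125)
        with pytest.raises(DomainError):
            recognition_stats(4, 8, 0.0)


class TestBootstrap:
    def _pool(self, n=18, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        pool = []
        for i in range(n):
            arr = rng.normal(0, 5, (2, 2, 15))
            pool.append(
                (
                    fp_from_array(arr, pianist=f"P{i:02d}", session="a"),
                    fp_from_array(arr + rng.normal(0, noise, arr.shape),
                                  pianist=f"P{i:02d}", session="b"),
                )
            )
        return pool

    def test_perfectly_identifiable_pool_degenerate(self):
        mean, sd, ci = bootstrap_recognition(self._pool(noise=0.0), reps=200, seed=1)
        assert mean == 1.0 and sd == 0.0 and ci == (1.0, 1.0)

    def test_same_seed_reproducible(self):
        pool = self._pool(noise=6.0, seed=3)
        a = bootstrap_recognition(pool, reps=300, seed=7)
        b = bootstrap_recognition(pool, reps=300, seed=7)
        assert a == b

    def test_matches_independent_loop_reimplementation(self):
        pool = self._pool(n=12, noise=6.0, seed=4)
        mean, sd, ci = bootstrap_recognition(pool, subsample_size=8, reps=500, seed=11)

        # naive double implementation: same rng stream, explicit nn loop
        rng = np.random.default_rng(11)
        order = np.argsort([db.pianist for db, _ in pool])
        spool = [pool[i] for i in order]
        rates = []
        for _ in range(500):
            idx = np.sort(rng.choice(len(spool), size=8, replace=False))
            sub = [spool[i] for i in idx]
            hits = 0
            for db_fp, q_fp in sub:
                dists = [fingerprint_distance(q_fp, other_db) for other_db, _ in sub]
                hits += sub[int(np.argmin(dists))][0].pianist == db_fp.pianist
            rates.append(hits / 8)
        assert mean == pytest.approx(np.mean(rates), abs=1e-3)
        assert sd == pytest.approx(np.std(rates, ddof=1), abs=1e-3)

    def test_pool_too_small_rejected(self):
        with pytest.raises(DomainError):
            bootstrap_recognition(self._pool(n=5), subsample_size=8)


class TestGroupedContrasts:
    def test_identical_sessions_have_zero_self_distance(self):
        rng = np.random.default_rng(9)
        fps = []
        for i in range(3):
            arr = rng.normal(0, 5, (2, 2, 15))
            fps.append(fp_from_array(arr, pianist=f"P{i}", session="first"))
            fps.append(fp_from_array(arr, pianist=f"P{i}", session="followup"))
        table = grouped_contrasts(fps).set_index(["contrast", "group"])
        assert table.loc[("self_other", "self"), "mean"] == 0.0
        assert table.loc[("self_other", "other"), "mean"] > 0

    def test_two_pianist_pair_counts_match_hand_count(self):
        rng = np.random.default_rng(10)
        fps = []
        for i in range(2):
            for s in ("first", "followup"):
                fps.append(fp_from_array(rng.normal(0, 5, (2, 2, 15)),
                                         pianist=f"P{i}", session=s))
        raw = grouped_contrast_distances(fps)
        counts = raw.groupby(["contrast", "group"]).size()
        # self_other: 2 pianists x 4 cells self; 2 ordered other pairs x 4 cells
        assert counts[("self_other", "self")] == 8
        assert counts[("self_other", "other")] == 8
        # movement_sound: per pianist, 2 pairings x 2 session-orders per group
        assert counts[("movement_sound", "same_movement")] == 8
        assert counts[("movement_sound", "same_sound")] == 8
        # cross_hand: 2 directions x 2 cell-orders, same 2 / different 2 ordered pairs
        assert counts[("cross_hand", "same_pianist")] == 8
        assert counts[("cross_hand", "different_pianist")] == 8

    def test_incomplete_pianist_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(11)
        fps = []
        for i in range(3):
            arr = rng.normal(0, 5, (2, 2, 15))
            fps.append(fp_from_array(arr, pianist=f"P{i}", session="first"))
            if i < 2:
                fps.append(fp_from_array(arr, pianist=f"P{i}", session="followup"))
        with caplog.at_level("WARNING"):
            raw = grouped_contrast_distances(fps)
        assert "P2" in caplog.text
        assert set(raw.pianist_a) == {"P0", "P1"}
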