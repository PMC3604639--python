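"""Fingerprint similarity, nearest-match identification, and evaluation.

The *temporal distance* between two deviation traces is the RMS of their
element-wise differences, sqrt(sum((a_i - b_i)^2) / n), an ms-scaled
Euclidean distance.  The alternative similarity is the Pearson correlation,
compared on the Fisher-z scale.  Identification is independent nearest
neighbour: each query fingerprint is matched to the database entry with
minimal distance (or maximal correlation), and the hit count is evaluated
with an exact one-sided binomial test against chance plus a Clopper-Pearson
95% interval.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprint import CELLS, DeviationTrace, Fingerprint
from .ingest import DomainError, keyboard_direction

log = logging.getLogger(__name__)

#: cross-hand cell pairings generated by the same movement (both inward or
#: both outward) versus those producing the same sound (both ascending or
#: both descending on the keyboard).
SAME_MOVEMENT_PAIRS = (
    (("left", "inward"), ("right", "inward")),
    (("left", "outward"), ("right", "outward")),
)
SAME_SOUND_PAIRS = (
    (("left", "inward"), ("right", "outward")),
    (("left", "outward"), ("right", "inward")),
)

_Z_CAP = float(np.arctanh(1 - 1e-15))


def trace_distance(a: DeviationTrace | np.ndarray, b: DeviationTrace | np.ndarray) -> float:
    """RMS temporal distance in ms between two equal-length traces."""
    va = a.as_array() if isinstance(a, DeviationTrace) else np.asarray(a, dtype=float)
    vb = b.as_array() if isinstance(b, DeviationTrace) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise DomainError(f"trace length mismatch: {va.shape} vs {vb.shape}")
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def trace_correlation(a: DeviationTrace | np.ndarray, b: DeviationTrace | np.ndarray) -> tuple[float, float]:
    """Pearson r between two traces and its Fisher z = atanh(r).

    z is capped just below infinity for |r| = 1 so self-comparisons stay
    finite and ordered above every other correlation.
    """
    va = a.as_array() if isinstance(a, DeviationTrace) else np.asarray(a, dtype=float)
    vb = b.as_array() if isinstance(b, DeviationTrace) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise DomainError(f"trace length mismatch: {va.shape} vs {vb.shape}")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DomainError("undefined correlation: constant trace")
    r = float(np.corrcoef(va, vb)[0, 1])
    if abs(r) >= 1 - 1e-15:
        log.warning("|r| = 1; Fisher z capped at %.2f", _Z_CAP)
        z = _Z_CAP if r > 0 else -_Z_CAP
    else:
        z = float(np.arctanh(r))
    return r, z


CellKey = tuple[str, str]
CellPair = tuple[CellKey, CellKey]


def _normalize_pairs(cells: list[CellKey | CellPair] | None) -> list[CellPair]:
    if cells is None:
        return [(c, c) for c in CELLS]
    pairs: list[CellPair] = []
    for c in cells:
        if len(c) == 2 and isinstance(c[0], str):
            pairs.append((c, c))  # type: ignore[arg-type]
        else:
            pairs.append(c)  # type: ignore[arg-type]
    if not pairs:
        raise DomainError("empty cell set")
    return pairs


def _cell_vector(fp: Fingerprint, cell: CellKey, alignment: str) -> np.ndarray:
    v = fp.cell(*cell).as_array()
    if alignment == "space" and keyboard_direction(*cell) == "descending":
        return v[::-1]  # keyboard (ascending-pitch) order
    return v


def concatenated_vector(
    fp: Fingerprint,
    cells: list[CellKey | CellPair] | None = None,
    alignment: str = "time",
    side: int = 0,
) -> np.ndarray:
    """Concatenate the requested cells of a fingerprint into one vector.

    ``side`` selects which member of each cell pair applies to this
    fingerprint (0 for query-side, 1 for database-side cells).
    """
    if alignment not in ("time", "space"):
        raise DomainError(f"unknown alignment {alignment!r}")
    pairs = _normalize_pairs(cells)
    return np.concatenate([_cell_vector(fp, pair[side], alignment) for pair in pairs])


def fingerprint_distance(
    a: Fingerprint,
    b: Fingerprint,
    cells: list[CellKey | CellPair] | None = None,
    alignment: str = "time",
) -> float:
    """RMS distance over all notes of the requested cells.

    ``cells`` may list cell keys (compared like-for-like) or explicit
    (cell-of-a, cell-of-b) pairs for cross-hand comparisons.  With
    ``alignment='space'`` traces are put in keyboard (ascending-pitch) order
    before comparison, so a descending-sounding trace is reversed; with the
    default time alignment traces are compared in playing order.
    """
    va = concatenated_vector(a, cells, alignment, side=0)
    vb = concatenated_vector(b, cells, alignment, side=1)
    return trace_distance(va, vb)


def fingerprint_correlation(
    a: Fingerprint,
    b: Fingerprint,
    cells: list[CellKey | CellPair] | None = None,
    alignment: str = "time",
) -> tuple[float, float]:
    """Pearson r (and Fisher z) over the concatenated requested cells."""
    va = concatenated_vector(a, cells, alignment, side=0)
    vb = concatenated_vector(b, cells, alignment, side=1)
    return trace_correlation(va, vb)


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of nearest-match identification of a set of queries."""

    assignments: dict[str, str]
    n_correct: int
    n_total: int
    chance: float
    p_binomial: float
    ci95: tuple[float, float]

    @property
    def rate(self) -> float:
        return self.n_correct / self.n_total


def recognition_stats(n_correct: int, n_total: int, chance: float) -> tuple[float, tuple[float, float]]:
    """Exact binomial tail p and two-sided Clopper-Pearson 95% CI.

    p is the one-sided probability of at least ``n_correct`` hits under the
    chance rate; the CI is for the true success proportion.
    """
    if not 0 <= n_correct <= n_total or n_total <= 0:
        raise DomainError(f"invalid counts {n_correct}/{n_total}")
    if not 0 < chance < 1:
        raise DomainError(f"chance must be in (0, 1), got {chance}")
    p = float(stats.binom.sf(n_correct - 1, n_total, chance))
    lo = 0.0 if n_correct == 0 else float(stats.beta.ppf(0.025, n_correct, n_total - n_correct + 1))
    hi = 1.0 if n_correct == n_total else float(stats.beta.ppf(0.975, n_correct + 1, n_total - n_correct))
    return p, (lo, hi)


def _score_matrix(
    queries: list[Fingerprint],
    database: list[Fingerprint],
    metric: str,
    cells: list[CellKey | CellPair] | None,
    alignment: str,
) -> np.ndarray:
    """Query x database matrix; lower is always a better match."""
    q = np.stack([concatenated_vector(f, cells, alignment, side=0) for f in queries])
    d = np.stack([concatenated_vector(f, cells, alignment, side=1) for f in database])
    if metric == "distance":
        diff = q[:, None, :] - d[None, :, :]
        return np.sqrt(np.mean(diff**2, axis=2))
    if metric == "correlation":
        qz = (q - q.mean(axis=1, keepdims=True)) / q.std(axis=1, keepdims=True)
        dz = (d - d.mean(axis=1, keepdims=True)) / d.std(axis=1, keepdims=True)
        r = qz @ dz.T / q.shape[1]
        return -r  # maximal correlation = minimal score
    raise DomainError(f"unknown metric {metric!r}")


def nn_identify(
    queries: list[Fingerprint],
    database: list[Fingerprint],
    metric: str = "distance",
    cells: list[CellKey | CellPair] | None = None,
    alignment: str = "time",
) -> IdentificationResult:
    """Assign each query to its nearest database fingerprint, independently.

    Assignments are not forced one-to-one; several queries may claim the same
    database pianist.  Exact score ties resolve to the lexicographically
    smallest database label (with a warning).  Chance is 1/|database|.
    """
    if not database:
        raise DomainError("empty database")
    labels_db = [f.pianist for f in database]
    if len(set(labels_db)) != len(labels_db):
        raise DomainError("database pianist labels must be unique")
    order = np.argsort(labels_db)
    database = [database[i] for i in order]
    labels_db = [labels_db[i] for i in order]

    scores = _score_matrix(queries, database, metric, cells, alignment)
    best = scores.argmin(axis=1)
    for i, j in enumerate(best):
        tied = np.flatnonzero(scores[i] == scores[i, j])
        if len(tied) > 1:
            log.warning(
                "query %s: %d tied matches; choosing smallest label %s",
                queries[i].pianist, len(tied), labels_db[j],
            )
    assignments = {q.pianist: labels_db[j] for q, j in zip(queries, best)}
    n_correct = sum(q.pianist == labels_db[j] for q, j in zip(queries, best))
    chance = 1.0 / len(database)
    p, ci = recognition_stats(n_correct, len(queries), chance)
    return IdentificationResult(
        assignments=assignments,
        n_correct=n_correct,
        n_total=len(queries),
        chance=chance,
        p_binomial=p,
        ci95=ci,
    )


def bootstrap_recognition(
    pool: list[tuple[Fingerprint, Fingerprint]],
    subsample_size: int = 8,
    reps: int = 10_000,
    metric: str = "distance",
    seed: int | np.random.Generator = 0,
    cells: list[CellKey | CellPair] | None = None,
) -> tuple[float, float, tuple[float, float]]:
    """Bootstrap the recognition rate over subsamples of distinct pianists.

    ``pool`` holds (database-session, query-session) fingerprint pairs, one
    per pianist.  Each rep draws ``subsample_size`` distinct pianists without
    replacement, runs nearest-match identification within the subsample, and
    records the rate.  Returns (mean, SD, 2.5/97.5 percentile interval); SD
    uses the n-1 denominator.
    """
    if len(pool) < subsample_size:
        raise DomainError(f"pool of {len(pool)} smaller than subsample size {subsample_size}")
    labels = [db.pianist for db, _ in pool]
    order = np.argsort(labels)
    pool = [pool[i] for i in order]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # all pairwise scores once; each rep is an argmin over a submatrix
    db_fps = [db for db, _ in pool]
    q_fps = [q for _, q in pool]
    scores = _score_matrix(q_fps, db_fps, metric, cells, alignment="time")

    n = len(pool)
    rates = np.empty(reps)
    for rep in range(reps):
        idx = np.sort(rng.choice(n, size=subsample_size, replace=False))
        sub = scores[np.ix_(idx, idx)]
        rates[rep] = np.mean(sub.argmin(axis=1) == np.arange(subsample_size))
    ci = (float(np.percentile(rates, 2.5)), float(np.percentile(rates, 97.5)))
    return float(rates.mean()), float(rates.std(ddof=1)), ci


def grouped_contrast_distances(
    fingerprints: list[Fingerprint],
    alignment: str = "time",
) -> pd.DataFrame:
    """Raw pairwise distances for the three grouped contrasts.

    Returns one row per compared pair with columns (contrast, group,
    pianist_a, pianist_b, cell_a, cell_b, value):

    - ``self_other``: same cell, across the two sessions, self vs other.
    - ``movement_sound``: within pianist, cross-hand cell pairs across
      sessions, grouped by same-movement vs same-sound pairing.
    - ``cross_hand``: same-direction cross-hand pairs across sessions,
      grouped by same vs different pianist.

    Pianists lacking exactly two sessions are excluded with a warning.
    """
    by_pianist: dict[str, dict[str, Fingerprint]] = {}
    for fp in fingerprints:
        by_pianist.setdefault(fp.pianist, {})[fp.session] = fp
    complete = {p: s for p, s in by_pianist.items() if len(s) == 2}
    for p in sorted(set(by_pianist) - set(complete)):
        log.warning("pianist %s lacks two complete sessions; excluded from contrasts", p)
    if len(complete) < 2:
        raise DomainError("need at least two pianists with two sessions each")

    rows: list[dict] = []
    pianists = sorted(complete)
    firsts = {p: complete[p][sorted(complete[p])[0]] for p in pianists}
    followups = {p: complete[p][sorted(complete[p])[1]] for p in pianists}

    def cell_dist(fa: Fingerprint, ca: CellKey, fb: Fingerprint, cb: CellKey) -> float:
        return fingerprint_distance(fa, fb, cells=[(ca, cb)], alignment=alignment)

    # self vs other: like-for-like cells across sessions
    for pa, pb in itertools.product(pianists, pianists):
        for cell in CELLS:
            rows.append(
                dict(
                    contrast="self_other",
                    group="self" if pa == pb else "other",
                    pianist_a=pa, pianist_b=pb,
                    cell_a="/".join(cell), cell_b="/".join(cell),
                    value=cell_dist(firsts[pa], cell, followups[pb], cell),
                )
            )

    # same movement vs same sound: within pianist, cross-hand, across sessions
    for p in pianists:
        for group, pairs in (("same_movement", SAME_MOVEMENT_PAIRS), ("same_sound", SAME_SOUND_PAIRS)):
            for ca, cb in pairs:
                for fa, cell_a, fb, cell_b in (
                    (firsts[p], ca, followups[p], cb),
                    (firsts[p], cb, followups[p], ca),
                ):
                    rows.append(
                        dict(
                            contrast="movement_sound", group=group,
                            pianist_a=p, pianist_b=p,
                            cell_a="/".join(cell_a), cell_b="/".join(cell_b),
                            value=cell_dist(fa, cell_a, fb, cell_b),
                        )
                    )

    # cross-hand, same direction: same vs different pianist
    for pa, pb in itertools.product(pianists, pianists):
        for direction in ("inward", "outward"):
            ca, cb = ("left", direction), ("right", direction)
            for cell_a, cell_b in ((ca, cb), (cb, ca)):
                rows.append(
                    dict(
                        contrast="cross_hand",
                        group="same_pianist" if pa == pb else "different_pianist",
                        pianist_a=pa, pianist_b=pb,
                        cell_a="/".join(cell_a), cell_b="/".join(cell_b),
                        value=cell_dist(firsts[pa], cell_a, followups[pb], cell_b),
                    )
                )
    return pd.DataFrame(rows)


def grouped_contrasts(fingerprints: list[Fingerprint], alignment: str = "time") -> pd.DataFrame:
    """Mean +/- SD distance per contrast group (see grouped_contrast_distances)."""
    raw = grouped_contrast_distances(fingerprints, alignment=alignment)
    out = (
        raw.groupby(["contrast", "group"])["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out
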