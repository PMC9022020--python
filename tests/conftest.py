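import numpy as np
import pytest

from pks.core import PKSProfile, StandardPathwayList
from pks.pathways import PathwayDB
from pks.wss import SNVProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_list():
    return StandardPathwayList(
        species_id="sp", depth=1000,
        map_ids=("map00001", "map00002", "map00003"),
    )


def make_profile(calls, genome_length=3000, species="sp"):
    return SNVProfile(species, genome_length, frozenset(calls))


def make_pks(vector, plist, sample_id="s", day=0):
    return PKSProfile(sample_id=sample_id, day=day, vector=tuple(vector),
                      pathway_list=plist)


def random_db(rng, n_pathways, n_ecs):
    """Random pathway DB over full EC strings (no wildcards)."""
    pool = [f"1.2.{i // 50 + 1}.{i % 50 + 1}" for i in range(n_ecs)]
    entries = {}
    for i in range(n_pathways):
        size = int(rng.integers(1, max(2, n_ecs // 2)))
        ecs = rng.choice(pool, size=min(size, n_ecs), replace=False)
        entries[f"map{i + 1:05d}"] = frozenset(str(e) for e in ecs)
    return PathwayDB(entries)


def brute_force_min_cover(observed, db):
    """Oracle: enumerate all subsets, return the optimum under the tie rule.

    Returns (pathways, orphans); independent of the branch-and-bound path.
    """
    from itertools import combinations

    from pks.pathways import ec_matches

    ids = sorted(db.entries)
    coverage = {
        m: frozenset(o for o in observed
                     if any(ec_matches(o, d) for d in db.entries[m]))
        for m in ids
    }
    coverable = frozenset().union(*coverage.values()) if coverage else frozenset()
    orphans = frozenset(observed) - coverable
    if not coverable:
        return frozenset(), orphans
    best = None
    for k in range(len(ids) + 1):
        candidates = []
        for combo in combinations(ids, k):
            covered = frozenset().union(*(coverage[m] for m in combo)) if combo else frozenset()
            if covered == coverable:
                weight = sum(len(coverage[m]) for m in combo)
                candidates.append((-weight, tuple(sorted(combo))))
        if candidates:
            best = min(candidates)[1]
            break
    return frozenset(best), orphans


def brute_force_wss(a, b, window):
    """Oracle: direct per-window Jaccard mean, scanning windows explicitly."""
    n_windows = -(-a.genome_length // window)
    scores = []
    for k in range(n_windows):
        lo, hi = k * window + 1, (k + 1) * window
        wa = {c for c in a.calls if lo <= c[0] <= hi}
        wb = {c for c in b.calls if lo <= c[0] <= hi}
        if wa or wb:
            scores.append(len(wa & wb) / len(wa | wb))
    if not scores:
        raise ValueError("no informative windows")
    return 100.0 * sum(scores) / len(scores), len(scores)
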