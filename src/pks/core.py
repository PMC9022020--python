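"""Binary pathway-pattern profiles and their longitudinal dynamics.

A *standard pathway list* is the sorted union of pathway calls across
samples that only ever appear in WSS-related pairs at a fixed read depth.
Each sample then becomes a binary presence/absence vector over that list;
pairs are compared by Hamming distance, cohorts summarized by the share of
zero-difference pairs, and one individual's time series is scanned for
clusters of time points with bitwise-identical vectors, including
extinction/reappearance events and whether the series resolves to a
pattern seen only once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import logging

from .pathways import PathwayCallSet

logger = logging.getLogger(__name__)

__all__ = [
    "StandardPathwayList",
    "PKSProfile",
    "PairDifference",
    "PairSummary",
    "Cluster",
    "ClusterReport",
    "build_standard_list",
    "make_pks_profile",
    "pks_difference",
    "summarize_related_pairs",
    "find_clusters",
    "round_pct",
]


def round_pct(value: float | Decimal, ndigits: int = 1) -> float:
    """Round half away from zero (``ROUND_HALF_UP`` on the magnitude)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StandardPathwayList:
    """Comparison axis: unique, lexicographically sorted pathway map IDs."""

    species_id: str
    depth: int
    map_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.map_ids)) != len(self.map_ids):
            raise ValueError("map_ids must be unique")
        if list(self.map_ids) != sorted(self.map_ids):
            raise ValueError("map_ids must be sorted lexicographically")

    def __len__(self) -> int:
        return len(self.map_ids)


@dataclass(frozen=True)
class PKSProfile:
    """Presence/absence vector for one sample over a standard pathway list."""

    sample_id: str
    day: int
    vector: tuple[int, ...]
    pathway_list: StandardPathwayList

    def __post_init__(self) -> None:
        if len(self.vector) != len(self.pathway_list):
            raise ValueError(
                f"vector length {len(self.vector)} != list length "
                f"{len(self.pathway_list)}"
            )
        if any(v not in (0, 1) for v in self.vector):
            raise ValueError("vector entries must be 0 or 1")


@dataclass(frozen=True)
class PairDifference:
    """Signed per-pathway changes between two profiles; +1 gain, -1 loss."""

    pair_id: str
    n_diff: int
    delta: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_diff != sum(1 for d in self.delta if d != 0):
            raise ValueError("n_diff must equal the number of nonzero delta entries")


@dataclass(frozen=True)
class PairSummary:
    n_pairs: int
    n_zero: int
    pct_zero: float
    n_nonzero: int
    pct_nonzero: float
    shared_pattern_groups: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class Cluster:
    """Time points of one individual sharing a bitwise-identical vector."""

    pattern: tuple[int, ...]
    member_days: tuple[int, ...]
    reappearances: int


@dataclass(frozen=True)
class ClusterReport:
    clusters: tuple[Cluster, ...]
    cluster_membership_count: int
    reappearance_events: tuple[int, ...]
    classification: str  # "shared" | "unique"
    resolved: bool

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "pattern": list(c.pattern),
                    "member_days": list(c.member_days),
                    "reappearances": c.reappearances,
                }
                for c in self.clusters
            ],
            "cluster_membership_count": self.cluster_membership_count,
            "reappearance_events": list(self.reappearance_events),
            "classification": self.classification,
            "resolved": self.resolved,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ClusterReport":
        clusters = tuple(
            Cluster(tuple(c["pattern"]), tuple(c["member_days"]), c["reappearances"])
            for c in data["clusters"]
        )
        return cls(
            clusters=clusters,
            cluster_membership_count=data["cluster_membership_count"],
            reappearance_events=tuple(data["reappearance_events"]),
            classification=data["classification"],
            resolved=data["resolved"],
        )


def build_standard_list(
    callsets: Mapping[str, PathwayCallSet],
    pair_relatedness: Mapping[tuple[str, str], str | bool],
    species_id: str,
    depth: int,
) -> StandardPathwayList:
    """Union of pathway calls over samples participating only in related pairs.

    ``pair_relatedness`` maps ``(sample_a, sample_b)`` to ``"related"`` /
    ``"unrelated"`` (booleans accepted).  Every sample must appear in at
    least one labelled pair; samples with any unrelated pair are excluded.
    """

    def is_related(label: str | bool) -> bool:
        return label is True or label == "related"

    labels: dict[str, list[bool]] = {}
    for (a, b), label in pair_relatedness.items():
        rel = is_related(label)
        labels.setdefault(a, []).append(rel)
        labels.setdefault(b, []).append(rel)

    unlabelled = set(callsets) - set(labels)
    if unlabelled:
        raise ValueError(
            f"samples with no relatedness-labelled pair: {sorted(unlabelled)}"
        )
    if not any(is_related(v) for v in pair_relatedness.values()):
        raise ValueError("no related pairs; cannot build a standard pathway list")

    keep = [s for s in callsets if all(labels[s])]
    excluded = sorted(set(callsets) - set(keep))
    if excluded:
        logger.info("build_standard_list: excluded %d sample(s) in unrelated pairs: %s",
                    len(excluded), ", ".join(excluded))
    union: set[str] = set()
    for sample in keep:
        union |= callsets[sample].pathways
    return StandardPathwayList(
        species_id=species_id, depth=depth, map_ids=tuple(sorted(union))
    )


def make_pks_profile(
    callset: PathwayCallSet,
    pathway_list: StandardPathwayList,
    day: int = 0,
) -> PKSProfile:
    """Project a pathway call set onto the standard list as a 0/1 vector.

    Called pathways outside the list are ignored (count logged).
    """
    listed = set(pathway_list.map_ids)
    outside = len(callset.pathways - listed)
    if outside:
        logger.info(
            "make_pks_profile(%s): %d called pathway(s) outside the standard list",
            callset.sample_id, outside,
        )
    vector = tuple(int(m in callset.pathways) for m in pathway_list.map_ids)
    return PKSProfile(
        sample_id=callset.sample_id, day=day, vector=vector,
        pathway_list=pathway_list,
    )


def pks_difference(a: PKSProfile, b: PKSProfile, pair_id: str | None = None) -> PairDifference:
    """Hamming comparison of two profiles on the same standard list.

    ``delta[i]`` is ``b.vector[i] - a.vector[i]``: +1 for a gain relative
    to ``a``, -1 for a loss.
    """
    if a.pathway_list != b.pathway_list:
        raise ValueError("profiles use different standard pathway lists")
    delta = tuple(y - x for x, y in zip(a.vector, b.vector))
    n_diff = sum(1 for d in delta if d != 0)
    if pair_id is None:
        pair_id = f"{a.sample_id}|{b.sample_id}"
    return PairDifference(pair_id=pair_id, n_diff=n_diff, delta=delta)


def summarize_related_pairs(diffs: Sequence[PairDifference]) -> PairSummary:
    """Cohort summary over related-pair differences.

    Percentages are 100·count/n rounded half-away-from-zero to one decimal.
    ``shared_pattern_groups`` collects groups (size ≥ 2) of pairs whose
    *nonzero* delta patterns are identical; zero-difference pairs never
    form a group.
    """
    if not diffs:
        raise ValueError("need at least one pair difference")
    n = len(diffs)
    n_zero = sum(1 for d in diffs if d.n_diff == 0)
    n_nonzero = n - n_zero
    by_pattern: dict[tuple[int, ...], list[str]] = {}
    for d in diffs:
        if d.n_diff > 0:
            by_pattern.setdefault(d.delta, []).append(d.pair_id)
    groups = tuple(
        tuple(sorted(members))
        for _, members in sorted(by_pattern.items())
        if len(members) >= 2
    )
    return PairSummary(
        n_pairs=n,
        n_zero=n_zero,
        pct_zero=round_pct(Decimal(100 * n_zero) / Decimal(n)),
        n_nonzero=n_nonzero,
        pct_nonzero=round_pct(Decimal(100 * n_nonzero) / Decimal(n)),
        shared_pattern_groups=groups,
    )


def find_clusters(series: Sequence[PKSProfile]) -> ClusterReport:
    """Detect identical-pattern clusters in one individual's time series.

    Clusters are maximal groups of ≥2 time points with bitwise-identical
    vectors, ordered by first appearance.  Per cluster, a *reappearance*
    is a maximal run of intervening sampled time points carrying a
    different pattern between consecutive members.  The series is
    *resolved* when the last time point's pattern occurs exactly once.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    days = [p.day for p in series]
    if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    ref_list = series[0].pathway_list
    if any(p.pathway_list != ref_list for p in series):
        raise ValueError("all profiles must share one standard pathway list")

    by_vector: dict[tuple[int, ...], list[int]] = {}
    for idx, p in enumerate(series):
        by_vector.setdefault(p.vector, []).append(idx)

    clusters: list[Cluster] = []
    for vector, indices in sorted(by_vector.items(), key=lambda kv: kv[1][0]):
        if len(indices) < 2:
            continue
        gaps = sum(1 for i, j in zip(indices, indices[1:]) if j - i > 1)
        clusters.append(
            Cluster(
                pattern=vector,
                member_days=tuple(days[i] for i in indices),
                reappearances=gaps,
            )
        )

    last_vector = series[-1].vector
    resolved = len(by_vector[last_vector]) == 1
    return ClusterReport(
        clusters=tuple(clusters),
        cluster_membership_count=sum(len(c.member_days) for c in clusters),
        reappearance_events=tuple(c.reappearances for c in clusters),
        classification="shared" if clusters else "unique",
        resolved=resolved,
    )
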