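"""Pathway inference: EC numbers from GFF3 annotations, parsimony pathway calls.

The pathway call for a sample is the *minimum-cardinality* set of pathway
map IDs whose EC sets together cover every observed EC that belongs to at
least one pathway (a minimum set cover, solved exactly).  Observed ECs
matching no pathway are reported as orphans.  Among multiple minimum
covers the tie-break is: maximum total observed-EC coverage summed over
the selected pathways, then the lexicographically smallest map-ID tuple,
so repeated calls are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from gffutils import feature as _gff_feature

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDB",
    "PathwayCallSet",
    "GffParseError",
    "extract_ec_from_gff",
    "ec_matches",
    "minimal_pathway_set",
]


class GffParseError(ValueError):
    """Raised for a malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"GFF line {line_no}: {message}")


@dataclass(frozen=True)
class PathwayDB:
    """Map from pathway map ID (e.g. ``map00010``) to its non-empty EC set."""

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for map_id, ecs in self.entries.items():
            if not ecs:
                raise ValueError(f"pathway {map_id!r} has an empty EC set")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayDB":
        """Load a two-column TSV (``map_id``, ``ec_number``), one pair per line."""
        df = pd.read_csv(path, sep="\t", header=None, names=["map_id", "ec_number"],
                         dtype=str, comment="#")
        entries: dict[str, set[str]] = {}
        for row in df.itertuples():
            entries.setdefault(row.map_id, set()).add(row.ec_number)
        return cls({k: frozenset(v) for k, v in entries.items()})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for map_id in sorted(self.entries):
                for ec in sorted(self.entries[map_id]):
                    fh.write(f"{map_id}\t{ec}\n")


@dataclass(frozen=True)
class PathwayCallSet:
    """Pathways inferred present in one sample, plus EC bookkeeping."""

    sample_id: str
    pathways: frozenset[str]
    covered_ecs: frozenset[str]
    orphan_ecs: frozenset[str]


def extract_ec_from_gff(gff: str | Path | IO[str]) -> set[str]:
    """Collect the distinct ``eC_number`` attribute values from a GFF3 stream.

    Duplicates collapse to presence.  Lines after a ``##FASTA`` directive are
    ignored; malformed feature lines raise :class:`GffParseError`.
    """
    if isinstance(gff, (str, Path)):
        with open(gff) as handle:
            return extract_ec_from_gff(handle)

    ecs: set[str] = set()
    in_fasta = False
    for line_no, raw in enumerate(gff, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##FASTA"):
            in_fasta = True
        if in_fasta or line.startswith("#") or line.startswith(">"):
            continue
        if len(line.split("\t")) != 9:
            raise GffParseError(
                line_no, f"expected 9 tab-separated columns, got "
                f"{len(line.split(chr(9)))}"
            )
        try:
            feature = _gff_feature.feature_from_line(line)
        except Exception as exc:
            raise GffParseError(line_no, str(exc)) from exc
        ecs.update(feature.attributes.get("eC_number", []))
    return ecs


def ec_matches(observed: str, db_ec: str) -> bool:
    """Whether two EC numbers match, treating ``-`` components as wildcards.

    Partial EC numbers like ``2.7.1.-`` (on either side) match full numbers
    component-wise.
    """
    a_parts = observed.split(".")
    b_parts = db_ec.split(".")
    if len(a_parts) != len(b_parts):
        return False
    return all(x == y or x == "-" or y == "-" for x, y in zip(a_parts, b_parts))


def minimal_pathway_set(
    observed: Iterable[str], db: PathwayDB, sample_id: str = "sample"
) -> PathwayCallSet:
    """Exact minimum set cover of the observed ECs by pathway EC sets.

    Branch and bound on the uncovered EC with the fewest candidate
    pathways; pruning uses a simple covering lower bound.  Deterministic
    under the documented tie rule.
    """
    observed_set = set(observed)
    map_ids = sorted(db.entries)

    # candidate pathways per observed EC (wildcard-aware)
    covers: dict[str, frozenset[str]] = {}  # map_id -> coverable observed ECs
    for map_id in map_ids:
        ecs = db.entries[map_id]
        hit = frozenset(
            obs for obs in observed_set if any(ec_matches(obs, d) for d in ecs)
        )
        if hit:
            covers[map_id] = hit
    coverable = frozenset().union(*covers.values()) if covers else frozenset()
    orphans = frozenset(observed_set - coverable)

    if not coverable:
        return PathwayCallSet(sample_id, frozenset(), frozenset(), orphans)

    # bitmask encoding of the coverable universe
    universe = sorted(coverable)
    bit = {ec: 1 << i for i, ec in enumerate(universe)}
    full = (1 << len(universe)) - 1
    candidate_ids = sorted(covers)
    masks = {m: sum(bit[ec] for ec in covers[m]) for m in candidate_ids}
    weights = {m: len(covers[m]) for m in candidate_ids}  # observed-EC coverage
    max_cover = max(bin(v).count("1") for v in masks.values())
    by_ec = {
        ec: sorted(m for m in candidate_ids if masks[m] & bit[ec])
        for ec in universe
    }

    best: list[tuple[int, int, tuple[str, ...]]] = [(len(candidate_ids) + 1, 0, ())]

    def search(covered: int, chosen: list[str], weight: int) -> None:
        if covered == full:
            key = (len(chosen), -weight, tuple(sorted(chosen)))
            if key < best[0]:
                best[0] = key
            return
        uncovered = [ec for ec in universe if not covered & bit[ec]]
        lower = -(-len(uncovered) // max_cover)  # ceil
        if len(chosen) + lower > best[0][0]:
            return
        # branch on the most constrained uncovered EC
        target = min(uncovered, key=lambda ec: (len(by_ec[ec]), ec))
        for m in by_ec[target]:
            if m in chosen:
                continue
            chosen.append(m)
            search(covered | masks[m], chosen, weight + weights[m])
            chosen.pop()

    search(0, [], 0)
    chosen_ids = frozenset(best[0][2])
    logger.debug(
        "minimal_pathway_set(%s): %d/%d ECs coverable, %d pathways chosen",
        sample_id, len(coverable), len(observed_set), len(chosen_ids),
    )
    return PathwayCallSet(
        sample_id=sample_id,
        pathways=chosen_ids,
        covered_ecs=coverable,
        orphan_ecs=orphans,
    )
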