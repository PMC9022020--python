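"""Windowed SNV similarity (WSS) scoring and relatedness classification.

Two samples' SNV call sets against one species reference are compared by
tiling the genome into consecutive fixed-width windows, computing the
Jaccard similarity of ``(position, alt)`` call sets inside every window
where at least one sample has a call, and averaging over those informative
windows.  The score is reported on a 0–100 scale.  A pair is called
*related* when its score is strictly above a per-species cutoff; cutoffs
are calibrated from labelled score lists by maximizing Youden's J over
midpoint candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Literal

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SNVProfile",
    "WSSResult",
    "CutoffModel",
    "VcfParseError",
    "load_snv_profile",
    "compute_wss",
    "calibrate_cutoff",
    "classify_pair",
    "load_cutoff_table",
    "save_cutoff_table",
]

_NUCS = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised for malformed VCF input; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"VCF line {line_no}: {message}")


@dataclass(frozen=True)
class SNVProfile:
    """Per-sample SNV calls against a single species reference genome.

    ``calls`` holds ``(position, alt)`` pairs with 1-based positions; at
    most one alternate allele per position.
    """

    species_id: str
    genome_length: int
    calls: frozenset[tuple[int, str]]

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        seen: dict[int, str] = {}
        for pos, alt in self.calls:
            if not 1 <= pos <= self.genome_length:
                raise ValueError(
                    f"call position {pos} outside genome [1, {self.genome_length}]"
                )
            if alt not in _NUCS:
                raise ValueError(f"invalid alternate allele {alt!r} at {pos}")
            if pos in seen and seen[pos] != alt:
                raise ValueError(f"conflicting alternate alleles at position {pos}")
            seen[pos] = alt


@dataclass(frozen=True)
class WSSResult:
    """Similarity score in [0, 100]; ``related`` is None until classified."""

    score: float
    n_windows_used: int
    related: bool | None = None
    species_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"score {self.score} outside [0, 100]")


@dataclass(frozen=True)
class CutoffModel:
    species_id: str
    cutoff: float
    calibration_n: tuple[int, int]  # (n_related, n_unrelated)


def load_snv_profile(
    vcf: str | Path | IO[str],
    species_id: str,
    genome_length: int | None = None,
) -> SNVProfile:
    """Read single-nucleotide PASS (or unfiltered) calls from a VCF stream.

    Multi-allelic records, indels and filtered records are skipped (counts
    are logged).  ``genome_length`` may be omitted when the header carries a
    ``##contig`` line with a ``length`` field.  Duplicate positions with
    conflicting alternate alleles are an error.

    Parsing is deliberately line-based rather than delegated to an indexed
    VCF reader so that text streams are accepted and malformed lines are
    reported with their line number.
    """
    if isinstance(vcf, (str, Path)):
        with open(vcf) as handle:
            return load_snv_profile(handle, species_id, genome_length)

    calls: dict[int, str] = {}
    skipped = {"indel": 0, "multiallelic": 0, "filtered": 0}
    contig_length = None
    for line_no, raw in enumerate(vcf, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##contig=") and "length=" in line:
                token = line.split("length=", 1)[1]
                token = token.split(",")[0].rstrip(">")
                try:
                    contig_length = int(token)
                except ValueError as exc:
                    raise VcfParseError(line_no, f"bad contig length {token!r}") from exc
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise VcfParseError(line_no, f"expected ≥8 columns, got {len(fields)}")
        _chrom, pos_s, _id, ref, alt, _qual, filt = fields[:7]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise VcfParseError(line_no, f"non-integer POS {pos_s!r}") from exc
        if filt not in ("PASS", ".", ""):
            skipped["filtered"] += 1
            continue
        if "," in alt:
            skipped["multiallelic"] += 1
            continue
        if len(ref) != 1 or len(alt) != 1 or alt not in _NUCS:
            skipped["indel"] += 1
            continue
        if pos in calls and calls[pos] != alt:
            raise VcfParseError(
                line_no, f"conflicting alternate alleles at position {pos}"
            )
        calls[pos] = alt

    total_skipped = sum(skipped.values())
    if total_skipped:
        logger.info(
            "load_snv_profile(%s): skipped %d records (%s)",
            species_id,
            total_skipped,
            ", ".join(f"{k}={v}" for k, v in skipped.items() if v),
        )
    length = genome_length if genome_length is not None else contig_length
    if length is None:
        raise ValueError(
            "genome_length not given and no ##contig length found in header"
        )
    return SNVProfile(
        species_id=species_id,
        genome_length=length,
        calls=frozenset(calls.items()),
    )


def compute_wss(a: SNVProfile, b: SNVProfile, window: int = 1000) -> WSSResult:
    """Score two SNV profiles on the same reference.

    The genome is tiled into consecutive windows of ``window`` bases
    (1-based inclusive coordinates; the final partial window counts).  Each
    window where either profile has at least one call contributes the
    Jaccard similarity of the two windows' ``(position, alt)`` sets; the
    score is 100 times the mean over those windows.
    """
    if a.species_id != b.species_id:
        raise ValueError(f"species mismatch: {a.species_id!r} vs {b.species_id!r}")
    if a.genome_length != b.genome_length:
        raise ValueError("genome_length mismatch")
    if window <= 0:
        raise ValueError("window must be positive")

    by_window: dict[int, tuple[set, set]] = {}
    for source, calls in ((0, a.calls), (1, b.calls)):
        for pos, alt in calls:
            widx = (pos - 1) // window
            pair = by_window.setdefault(widx, (set(), set()))
            pair[source].add((pos, alt))
    if not by_window:
        raise ValueError("no informative windows")

    total = 0.0
    for wa, wb in by_window.values():
        total += len(wa & wb) / len(wa | wb)
    n_used = len(by_window)
    return WSSResult(
        score=100.0 * total / n_used,
        n_windows_used=n_used,
        species_id=a.species_id,
    )


def calibrate_cutoff(
    related_scores: Iterable[float],
    unrelated_scores: Iterable[float],
    species_id: str,
) -> CutoffModel:
    """Pick the score cutoff maximizing Youden's J.

    Candidates are midpoints between consecutive sorted unique pooled
    scores.  Sensitivity counts related scores strictly above the
    candidate; specificity counts unrelated scores at or below it.  Ties
    resolve to the largest candidate.
    """
    related = list(related_scores)
    unrelated = list(unrelated_scores)
    if not related or not unrelated:
        raise ValueError("both related and unrelated score lists must be non-empty")
    pooled = sorted(set(related) | set(unrelated))
    if len(pooled) < 2:
        raise ValueError("cannot calibrate: all pooled scores identical")
    candidates = [(lo + hi) / 2.0 for lo, hi in zip(pooled, pooled[1:])]

    best_j = -float("inf")
    best_c = candidates[0]
    for c in candidates:
        sens = sum(s > c for s in related) / len(related)
        spec = sum(s <= c for s in unrelated) / len(unrelated)
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and c > best_c):
            best_j, best_c = j, c
    return CutoffModel(
        species_id=species_id,
        cutoff=best_c,
        calibration_n=(len(related), len(unrelated)),
    )


def classify_pair(
    result: WSSResult, model: CutoffModel
) -> Literal["related", "unrelated"]:
    """Call a pair related iff its score is strictly above the cutoff."""
    if result.species_id is not None and result.species_id != model.species_id:
        raise ValueError(
            f"species mismatch: result {result.species_id!r} vs model "
            f"{model.species_id!r}"
        )
    return "related" if result.score > model.cutoff else "unrelated"


_CUTOFF_COLS = ["species_id", "cutoff", "n_related", "n_unrelated"]


def save_cutoff_table(models: Iterable[CutoffModel], path: str | Path) -> None:
    rows = [
        {
            "species_id": m.species_id,
            "cutoff": m.cutoff,
            "n_related": m.calibration_n[0],
            "n_unrelated": m.calibration_n[1],
        }
        for m in models
    ]
    pd.DataFrame(rows, columns=_CUTOFF_COLS).to_csv(path, sep="\t", index=False)


def load_cutoff_table(path: str | Path) -> dict[str, CutoffModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CUTOFF_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"cutoff table {path}: missing columns {sorted(missing)}")
    return {
        row.species_id: CutoffModel(
            species_id=row.species_id,
            cutoff=float(row.cutoff),
            calibration_n=(int(row.n_related), int(row.n_unrelated)),
        )
        for row in df.itertuples()
    }
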