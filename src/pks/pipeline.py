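"""Cohort orchestration: QC → WSS → pathway calls → pattern profiles → clusters.

A run is described by a YAML config listing per-sample inputs (VCF, GFF,
optional FASTQ) with individual IDs and collection days.  Outputs are
written to a directory: ``wss.tsv`` (pair scores and relatedness calls),
``pks_grid.tsv`` (binary pathway grid), ``clusters.json`` (per-individual
cluster reports), ``summary.tsv`` (zero-difference accounting) and
``run.log``.  Runs are deterministic under a fixed seed; log lines carry
no timestamps so re-runs are byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import (
    ClusterReport,
    PKSProfile,
    StandardPathwayList,
    build_standard_list,
    find_clusters,
    make_pks_profile,
    pks_difference,
    summarize_related_pairs,
)
from .pathways import PathwayDB, extract_ec_from_gff, minimal_pathway_set
from .reads import QCParams, qc_filter_reads, read_fastq, subsample_reads
from .wss import classify_pair, compute_wss, load_cutoff_table, load_snv_profile

logger = logging.getLogger(__name__)

__all__ = [
    "SampleEntry",
    "RunConfig",
    "run_longitudinal_analysis",
    "render_grid",
    "read_grid",
]


@dataclass(frozen=True)
class SampleEntry:
    individual: str
    day: int
    vcf: Path
    gff: Path
    fastq: Path | None = None

    @property
    def sample_id(self) -> str:
        return f"{self.individual}_d{self.day}"


@dataclass(frozen=True)
class RunConfig:
    species_id: str
    pathway_db: Path
    cutoff_table: Path
    samples: tuple[SampleEntry, ...]
    depth: int = 5_000_000
    seed: int = 1000
    reference: str | Mapping[str, str] = "last"
    window: int = 1000
    qc: QCParams = field(default_factory=QCParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        base = path.parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = []
        for entry in raw.get("samples", []):
            fastq = entry.get("fastq")
            samples.append(
                SampleEntry(
                    individual=str(entry["individual"]),
                    day=int(entry["day"]),
                    vcf=base / entry["vcf"],
                    gff=base / entry["gff"],
                    fastq=base / fastq if fastq else None,
                )
            )
        qc_raw = raw.get("qc", {})
        cfg = cls(
            species_id=str(raw["species_id"]),
            pathway_db=base / raw["pathway_db"],
            cutoff_table=base / raw["cutoff_table"],
            samples=tuple(samples),
            depth=int(raw.get("depth", 5_000_000)),
            seed=int(raw.get("seed", 1000)),
            reference=raw.get("reference", "last"),
            window=int(raw.get("window", 1000)),
            qc=QCParams(
                min_length=int(qc_raw.get("min_length", 50)),
                window_len=int(qc_raw.get("window_len", 50)),
                min_mean_q=float(qc_raw.get("min_mean_q", 20.0)),
            ),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        for s in self.samples:
            for p in (s.vcf, s.gff, s.fastq):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"sample {s.sample_id}: missing {p}")
        for p in (self.pathway_db, self.cutoff_table):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input file {p}")
        by_ind: dict[str, set[int]] = {}
        for s in self.samples:
            if s.day in by_ind.setdefault(s.individual, set()):
                raise ValueError(f"duplicate day {s.day} for {s.individual}")
            by_ind[s.individual].add(s.day)
        for ind, days in by_ind.items():
            if len(days) < 2:
                raise ValueError(f"individual {ind} needs at least two samples")


def _reference_sample(
    policy: str | Mapping[str, str], individual: str, ordered: Sequence[SampleEntry]
) -> SampleEntry:
    if isinstance(policy, str):
        if policy == "last":
            return ordered[-1]
        if policy == "first":
            return ordered[0]
        raise ValueError(f"unknown reference policy {policy!r}")
    sid = policy[individual]
    for s in ordered:
        if s.sample_id == sid:
            return s
    raise ValueError(f"explicit reference {sid!r} not among {individual}'s samples")


def render_grid(profiles: Sequence[PKSProfile], output: str | Path) -> None:
    """Write profiles as a TSV grid: rows = map IDs, columns = samples by day.

    Columns are labelled ``sample_id|day`` and ordered by (individual
    prefix, day).  A leading comment line preserves the list's species and
    depth so the grid round-trips losslessly to profiles.
    """
    if not profiles:
        raise ValueError("no profiles to render")
    plist = profiles[0].pathway_list
    if any(p.pathway_list != plist for p in profiles):
        raise ValueError("profiles use different standard pathway lists")
    ordered = sorted(profiles, key=lambda p: (p.sample_id.split("_d")[0], p.day))
    with open(output, "w", newline="") as fh:
        fh.write(f"# species_id={plist.species_id}\tdepth={plist.depth}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["map_id"] + [f"{p.sample_id}|{p.day}" for p in ordered])
        for i, map_id in enumerate(plist.map_ids):
            writer.writerow([map_id] + [p.vector[i] for p in ordered])


def read_grid(path: str | Path) -> list[PKSProfile]:
    """Inverse of :func:`render_grid`."""
    with open(path) as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("# species_id="):
            raise ValueError(f"{path}: missing grid metadata line")
        meta = dict(
            part.split("=", 1) for part in meta_line[2:].split("\t")
        )
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        rows = list(reader)
    map_ids = tuple(r[0] for r in rows)
    plist = StandardPathwayList(
        species_id=meta["species_id"], depth=int(meta["depth"]), map_ids=map_ids
    )
    profiles = []
    for col, label in enumerate(header[1:], start=1):
        sample_id, day = label.rsplit("|", 1)
        vector = tuple(int(r[col]) for r in rows)
        profiles.append(
            PKSProfile(sample_id=sample_id, day=int(day), vector=vector,
                       pathway_list=plist)
        )
    return profiles


def run_longitudinal_analysis(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full per-cohort analysis; returns the result bundle.

    Unrelated pairs are flagged in ``wss.tsv`` and excluded from the
    standard pathway list, the difference summaries and the cluster
    series.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate()

    pkg_logger = logging.getLogger("pks")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(handler)
    old_level = pkg_logger.level
    pkg_logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(old_level)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    logger.info("run: species=%s depth=%d seed=%d reference=%s",
                config.species_id, config.depth, config.seed, config.reference)

    models = load_cutoff_table(config.cutoff_table)
    if config.species_id not in models:
        raise ValueError(
            f"no WSS cutoff for species {config.species_id!r} in "
            f"{config.cutoff_table}; calibrate one first with `pks calibrate`"
        )
    model = models[config.species_id]
    db = PathwayDB.from_tsv(config.pathway_db)

    # optional read accounting: QC + seeded subsampling of provided FASTQs
    for s in config.samples:
        if s.fastq is None:
            continue
        reads = list(read_fastq(s.fastq))
        passed = list(qc_filter_reads(reads, config.qc))
        kept = subsample_reads(passed, config.depth, config.seed)
        logger.info("reads %s: %d total, %d post-QC, %d after subsampling to %d",
                    s.sample_id, len(reads), len(passed), len(kept), config.depth)

    callsets = {}
    snvs = {}
    for s in config.samples:
        snvs[s.sample_id] = load_snv_profile(s.vcf, config.species_id)
        ecs = extract_ec_from_gff(s.gff)
        callsets[s.sample_id] = minimal_pathway_set(ecs, db, sample_id=s.sample_id)

    by_ind: dict[str, list[SampleEntry]] = {}
    for s in config.samples:
        by_ind.setdefault(s.individual, []).append(s)
    for entries in by_ind.values():
        entries.sort(key=lambda s: s.day)

    wss_rows = []
    pair_labels: dict[tuple[str, str], str] = {}
    references: dict[str, SampleEntry] = {}
    for ind in sorted(by_ind):
        ordered = by_ind[ind]
        ref = _reference_sample(config.reference, ind, ordered)
        references[ind] = ref
        for s in ordered:
            if s.sample_id == ref.sample_id:
                continue
            result = compute_wss(snvs[s.sample_id], snvs[ref.sample_id],
                                 window=config.window)
            label = classify_pair(result, model)
            pair_labels[(s.sample_id, ref.sample_id)] = label
            if label == "unrelated":
                logger.info("pair %s|%s unrelated (score %.2f <= cutoff %.2f); "
                            "excluded from PKS summaries",
                            s.sample_id, ref.sample_id, result.score, model.cutoff)
            wss_rows.append({
                "individual": ind,
                "sample": s.sample_id,
                "day": s.day,
                "reference": ref.sample_id,
                "reference_day": ref.day,
                "score": round(result.score, 4),
                "n_windows": result.n_windows_used,
                "classification": label,
            })
    pd.DataFrame(wss_rows).to_csv(out / "wss.tsv", sep="\t", index=False)

    plist = build_standard_list(callsets, pair_labels, config.species_id, config.depth)
    logger.info("standard pathway list: %d pathways", len(plist))

    # pattern analysis keeps the reference plus its related partners; the
    # non-reference side of an unrelated pair is dropped, and a whole
    # individual drops out when no pair is related
    bad: set[str] = set()
    for ind in sorted(by_ind):
        ref_id = references[ind].sample_id
        partners = [s.sample_id for s in by_ind[ind] if s.sample_id != ref_id]
        if all(pair_labels[(p, ref_id)] == "unrelated" for p in partners):
            bad.update(partners)
            bad.add(ref_id)
        else:
            bad.update(p for p in partners
                       if pair_labels[(p, ref_id)] == "unrelated")

    profiles: dict[str, PKSProfile] = {}
    for s in config.samples:
        if s.sample_id in bad:
            continue
        profiles[s.sample_id] = make_pks_profile(
            callsets[s.sample_id], plist, day=s.day
        )

    diffs = []
    for ind in sorted(by_ind):
        ref = references[ind]
        for s in by_ind[ind]:
            if s.sample_id == ref.sample_id:
                continue
            if pair_labels[(s.sample_id, ref.sample_id)] != "related":
                continue
            diffs.append(
                pks_difference(profiles[s.sample_id], profiles[ref.sample_id])
            )

    reports: dict[str, ClusterReport] = {}
    for ind in sorted(by_ind):
        series = [profiles[s.sample_id] for s in by_ind[ind]
                  if s.sample_id in profiles]
        if len(series) < 2:
            logger.info("individual %s: <2 related samples, skipping clusters", ind)
            continue
        reports[ind] = find_clusters(series)

    render_grid(sorted(profiles.values(), key=lambda p: p.sample_id),
                out / "pks_grid.tsv")
    with open(out / "clusters.json", "w") as fh:
        json.dump({ind: rep.to_dict() for ind, rep in sorted(reports.items())},
                  fh, indent=2, sort_keys=True)

    summary_rows = []
    if diffs:
        cohort = summarize_related_pairs(diffs)
        summary_rows.append({
            "scope": "cohort",
            "n_pairs": cohort.n_pairs,
            "n_zero": cohort.n_zero,
            "pct_zero": cohort.pct_zero,
            "n_nonzero": cohort.n_nonzero,
            "pct_nonzero": cohort.pct_nonzero,
            "n_shared_groups": len(cohort.shared_pattern_groups),
        })
    for ind in sorted(by_ind):
        ind_diffs = [d for d in diffs
                     if d.pair_id.split("|")[0].startswith(f"{ind}_d")]
        if not ind_diffs:
            continue
        s = summarize_related_pairs(ind_diffs)
        summary_rows.append({
            "scope": ind, "n_pairs": s.n_pairs, "n_zero": s.n_zero,
            "pct_zero": s.pct_zero, "n_nonzero": s.n_nonzero,
            "pct_nonzero": s.pct_nonzero,
            "n_shared_groups": len(s.shared_pattern_groups),
        })
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)

    return {
        "wss": wss_rows,
        "pathway_list": plist,
        "profiles": profiles,
        "diffs": diffs,
        "clusters": reports,
        "summary": summary_rows,
    }
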