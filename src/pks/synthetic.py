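"""Synthetic fixtures: every pipeline input, generated with known ground truth.

All generators take explicit seeds (no global random state) and can emit
real on-disk formats (FASTQ/VCF/GFF3/TSV/JSON) so the I/O paths are
exercised, not just in-memory objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import PairDifference, StandardPathwayList, PKSProfile
from .pathways import PathwayDB
from .reads import ReadRecord, write_fastq
from .wss import SNVProfile, calibrate_cutoff, compute_wss, save_cutoff_table

__all__ = [
    "PlantedTruth",
    "generate_pathway_db",
    "generate_strain_pair",
    "generate_strain_series",
    "generate_longitudinal_series",
    "generate_reads",
    "ecs_for_pathways",
    "write_vcf",
    "write_gff",
    "generate_cohort",
    "generate_rarefaction_inputs",
    "make_threshold_downstream",
]

_NUCS = "ACGT"


@dataclass
class PlantedTruth:
    """Ground truth for a generated fixture, consistent by construction."""

    pair_labels: dict[str, str] = field(default_factory=dict)
    expected_wss_band: dict[str, tuple[float, float]] = field(default_factory=dict)
    planted_clusters: dict[str, list[int]] = field(default_factory=dict)
    planted_reappearances: dict[str, int] = field(default_factory=dict)
    classification: str = "unique"
    resolved: bool = True

    def to_dict(self) -> dict:
        return {
            "pair_labels": dict(self.pair_labels),
            "expected_wss_band": {k: list(v) for k, v in self.expected_wss_band.items()},
            "planted_clusters": {k: list(v) for k, v in self.planted_clusters.items()},
            "planted_reappearances": dict(self.planted_reappearances),
            "classification": self.classification,
            "resolved": self.resolved,
        }


def generate_pathway_db(
    n_pathways: int, ec_pool_size: int, overlap_frac: float, seed: int
) -> PathwayDB:
    """Random pathway database over a pool of distinct EC numbers.

    Each pathway owns a private slice of the pool plus, for
    ``overlap_frac > 0``, draws from other pathways' slices, so expected
    pairwise overlap scales with ``overlap_frac``; at 0 the EC sets are
    pairwise disjoint.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in [0, 1]")
    size = ec_pool_size // n_pathways
    if size < 1:
        raise ValueError("ec_pool_size must be >= n_pathways")
    rng = np.random.default_rng(seed)
    # distinct by construction: the last component enumerates the pool
    pool = [
        f"{rng.integers(1, 7)}.{rng.integers(1, 7)}.{rng.integers(1, 3)}.{i + 1}"
        for i in range(ec_pool_size)
    ]
    entries: dict[str, frozenset[str]] = {}
    for i in range(n_pathways):
        own = pool[i * size : (i + 1) * size]
        n_borrow = int(round(size * overlap_frac))
        keep = own[: size - n_borrow] if n_borrow else own
        others = [ec for ec in pool[: n_pathways * size] if ec not in own]
        borrowed = (
            list(rng.choice(others, size=min(n_borrow, len(others)), replace=False))
            if n_borrow and others
            else []
        )
        entries[f"map{i + 1:05d}"] = frozenset(keep) | frozenset(borrowed)
    return PathwayDB(entries)


def generate_strain_pair(
    genome_length: int, n_snv: int, shared_frac: float, seed: int
) -> tuple[SNVProfile, SNVProfile]:
    """Two SNV profiles sharing ``floor(shared_frac * n_snv)`` calls.

    Private calls occupy positions distinct from every other call, so at
    ``shared_frac == 0`` the profiles share no ``(position, alt)`` pair and
    the windowed similarity is exactly 0.
    """
    if not 0.0 <= shared_frac <= 1.0:
        raise ValueError("shared_frac must be in [0, 1]")
    n_shared = int(shared_frac * n_snv)
    n_private = n_snv - n_shared
    needed = n_shared + 2 * n_private
    if needed > genome_length:
        raise ValueError(f"genome_length {genome_length} too small for {needed} calls")
    rng = np.random.default_rng(seed)
    positions = rng.choice(genome_length, size=needed, replace=False) + 1
    alts = rng.choice(list(_NUCS), size=needed)
    calls = [(int(p), str(a)) for p, a in zip(positions, alts)]
    shared = calls[:n_shared]
    a_calls = frozenset(shared + calls[n_shared : n_shared + n_private])
    b_calls = frozenset(shared + calls[n_shared + n_private :])
    make = lambda c: SNVProfile("species", genome_length, c)
    return make(a_calls), make(b_calls)


def generate_strain_series(
    genome_length: int,
    n_snv: int,
    shared_fracs: Sequence[float],
    seed: int,
    species_id: str = "species",
) -> tuple[SNVProfile, list[SNVProfile]]:
    """A reference profile plus one profile per entry of ``shared_fracs``.

    Each derived profile keeps ``floor(frac * n_snv)`` of the reference
    calls and replaces the rest with private calls off the reference
    positions.
    """
    rng = np.random.default_rng(seed)
    ref_pos = rng.choice(genome_length // 2, size=n_snv, replace=False) + 1
    ref_alts = rng.choice(list(_NUCS), size=n_snv)
    ref_calls = [(int(p), str(a)) for p, a in zip(ref_pos, ref_alts)]
    ref = SNVProfile(species_id, genome_length, frozenset(ref_calls))

    others = []
    offset = genome_length // 2  # private calls live in the other genome half
    for frac in shared_fracs:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("shared fractions must be in [0, 1]")
        n_keep = int(frac * n_snv)
        keep_idx = rng.choice(n_snv, size=n_keep, replace=False)
        kept = [ref_calls[i] for i in sorted(keep_idx)]
        n_priv = n_snv - n_keep
        priv_pos = rng.choice(genome_length - offset, size=n_priv, replace=False) + offset + 1
        priv_alts = rng.choice(list(_NUCS), size=n_priv)
        private = [(int(p), str(a)) for p, a in zip(priv_pos, priv_alts)]
        others.append(SNVProfile(species_id, genome_length, frozenset(kept + private)))
    return ref, others


def _distinct_vectors(n: int, length: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    if length < 1 or n > 2**length:
        raise ValueError(
            f"list_length {length} too small for {n} distinct patterns"
        )
    if length <= 62:
        seen: set[int] = set()
        while len(seen) < n:
            seen.add(int(rng.integers(0, 2**length)))
        codes = sorted(seen)
        rng.shuffle(codes)
        return [tuple((c >> i) & 1 for i in range(length)) for c in codes]
    out: set[tuple[int, ...]] = set()
    while len(out) < n:
        out.add(tuple(int(b) for b in rng.integers(0, 2, size=length)))
    return list(out)


def generate_longitudinal_series(
    n_timepoints: int,
    list_length: int,
    cluster_spec: Mapping[str, Sequence[int]],
    seed: int,
    days: Sequence[int] | None = None,
    species_id: str = "species",
    depth: int = 5_000_000,
    sample_prefix: str = "s",
) -> tuple[list[PKSProfile], PlantedTruth]:
    """Profiles whose identical-pattern structure equals ``cluster_spec`` exactly.

    ``cluster_spec`` maps pattern IDs to their member days (each cluster
    needs ≥2 members; clusters must be disjoint).  Time points outside any
    cluster receive globally unique vectors.
    """
    if days is None:
        days = list(range(n_timepoints))
    days = list(days)
    if len(days) != n_timepoints or sorted(set(days)) != days:
        raise ValueError("days must be strictly increasing, one per time point")

    day_set = set(days)
    assigned: dict[int, str] = {}
    for pid, members in cluster_spec.items():
        members = list(members)
        if len(members) < 2:
            raise ValueError(f"cluster {pid!r} needs at least two member days")
        if not set(members) <= day_set:
            raise ValueError(f"cluster {pid!r} has days outside the series")
        for d in members:
            if d in assigned:
                raise ValueError(f"day {d} assigned to two clusters")
            assigned[d] = pid

    unique_days = [d for d in days if d not in assigned]
    n_patterns = len(cluster_spec) + len(unique_days)
    rng = np.random.default_rng(seed)
    vectors = _distinct_vectors(n_patterns, list_length, rng)

    pattern_of: dict[str, tuple[int, ...]] = {}
    for i, pid in enumerate(sorted(cluster_spec)):
        pattern_of[pid] = vectors[i]
    unique_iter = iter(vectors[len(cluster_spec):])

    plist = StandardPathwayList(
        species_id=species_id,
        depth=depth,
        map_ids=tuple(f"map{i + 1:05d}" for i in range(list_length)),
    )
    profiles = []
    for day in days:
        vec = pattern_of[assigned[day]] if day in assigned else next(unique_iter)
        profiles.append(
            PKSProfile(
                sample_id=f"{sample_prefix}_d{day}", day=day, vector=vec,
                pathway_list=plist,
            )
        )

    reapp: dict[str, int] = {}
    for pid, members in cluster_spec.items():
        idx = sorted(days.index(d) for d in members)
        reapp[pid] = sum(1 for i, j in zip(idx, idx[1:]) if j - i > 1)
    truth = PlantedTruth(
        planted_clusters={pid: sorted(m) for pid, m in cluster_spec.items()},
        planted_reappearances=reapp,
        classification="shared" if cluster_spec else "unique",
        resolved=days[-1] not in assigned,
    )
    return profiles, truth


def generate_reads(
    n_reads: int, read_len: int, seed: int, mean_q: int = 30
) -> list[ReadRecord]:
    """Uniform-random reads with flat quality ``mean_q``."""
    rng = np.random.default_rng(seed)
    seqs = rng.choice(list(_NUCS), size=(n_reads, read_len))
    return [
        ReadRecord(f"read{i + 1}", "".join(row), (mean_q,) * read_len)
        for i, row in enumerate(seqs)
    ]


def ecs_for_pathways(db: PathwayDB, map_ids: Sequence[str]) -> set[str]:
    """Union of the EC sets of the given pathways."""
    out: set[str] = set()
    for m in map_ids:
        out |= db.entries[m]
    return out


def write_vcf(profile: SNVProfile, path: str | Path) -> None:
    """Emit a minimal VCF 4.2 with one PASS SNV record per call."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={profile.species_id},length={profile.genome_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, alt in sorted(profile.calls):
            ref = "A" if alt != "A" else "C"
            fh.write(f"{profile.species_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_gff(ecs: Sequence[str] | set[str], path: str | Path) -> None:
    """Emit a minimal GFF3 with one CDS per EC, carrying ``eC_number``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ec in enumerate(sorted(ecs)):
            start = 1 + i * 300
            fh.write(
                f"contig1\tpks_sim\tCDS\t{start}\t{start + 299}\t.\t+\t0\t"
                f"ID=cds_{i + 1};product=synthetic;eC_number={ec}\n"
            )


def generate_cohort(
    out_dir: str | Path,
    seed: int,
    n_individuals: int = 2,
    days: Sequence[int] = (0, 3, 7, 14, 21),
    list_length: int = 8,
    cluster_specs: Mapping[str, Mapping[str, Sequence[int]]] | None = None,
    species_id: str = "species1",
    genome_length: int = 60_000,
    n_snv: int = 300,
    depth: int = 1000,
    include_fastq: bool = False,
    n_reads: int = 200,
    plant_unrelated: bool = False,
) -> dict:
    """Write a complete, self-consistent run directory for the pipeline.

    Emits per-sample VCF (+GFF, optionally FASTQ), a disjoint pathway
    database, a calibrated cutoff table, a ``config.yaml`` and a
    ``truth.json``.  Returns the truth as a dict.  With
    ``plant_unrelated`` the first individual's first sample gets a
    divergent strain, so its pair classifies unrelated and is excluded
    downstream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    days = list(days)
    individuals = [f"I{i + 1}" for i in range(n_individuals)]
    if cluster_specs is None:
        # default: first individual carries one planted cluster, rest unique;
        # avoid the first day when it is planted as an unrelated strain
        anchor = days[1] if plant_unrelated else days[0]
        cluster_specs = {
            individuals[0]: {"A": [anchor, days[-2]]} if len(days) >= 4 else {}
        }

    db = generate_pathway_db(
        n_pathways=list_length, ec_pool_size=list_length * 3,
        overlap_frac=0.0, seed=int(rng.integers(0, 2**31)),
    )
    db_path = out / "pathway_db.tsv"
    db.to_tsv(db_path)
    map_ids = sorted(db.entries)

    # cutoff calibrated from throwaway well-separated pairs
    cal_seed = int(rng.integers(0, 2**31))
    rel_scores, unrel_scores = [], []
    for k in range(8):
        a, b = generate_strain_pair(genome_length, n_snv, 0.9, cal_seed + 2 * k)
        rel_scores.append(compute_wss(a, b).score)
        a, b = generate_strain_pair(genome_length, n_snv, 0.1, cal_seed + 2 * k + 1)
        unrel_scores.append(compute_wss(a, b).score)
    model = calibrate_cutoff(rel_scores, unrel_scores, species_id)
    cutoff_path = out / "cutoffs.tsv"
    save_cutoff_table([model], cutoff_path)

    truth: dict = {"individuals": {}, "pair_labels": {}, "cutoff": model.cutoff}
    samples_cfg = []
    for ind in individuals:
        spec = {k: list(v) for k, v in (cluster_specs.get(ind) or {}).items()}
        profiles, planted = generate_longitudinal_series(
            n_timepoints=len(days), list_length=list_length, cluster_spec=spec,
            seed=int(rng.integers(0, 2**31)), days=days, species_id=species_id,
            depth=depth, sample_prefix=ind,
        )
        fracs = [0.9] * (len(days) - 1)
        if plant_unrelated and ind == individuals[0]:
            fracs[0] = 0.1
        ref, others = generate_strain_series(
            genome_length, n_snv, fracs, int(rng.integers(0, 2**31)), species_id
        )
        snv_of = {days[i]: others[i] for i in range(len(days) - 1)}
        snv_of[days[-1]] = ref

        for i, day in enumerate(days):
            sid = f"{ind}_d{day}"
            vcf_path = out / f"{sid}.vcf"
            write_vcf(snv_of[day], vcf_path)
            presence = [map_ids[j] for j, v in enumerate(profiles[i].vector) if v]
            gff_path = out / f"{sid}.gff"
            write_gff(ecs_for_pathways(db, presence), gff_path)
            entry = {
                "individual": ind, "day": int(day),
                "vcf": vcf_path.name, "gff": gff_path.name,
            }
            if include_fastq:
                fq_path = out / f"{sid}.fastq"
                write_fastq(
                    generate_reads(n_reads, 100, int(rng.integers(0, 2**31))),
                    fq_path,
                )
                entry["fastq"] = fq_path.name
            samples_cfg.append(entry)
            if day != days[-1]:
                pair_id = f"{sid}|{ind}_d{days[-1]}"
                frac = fracs[days.index(day)]
                truth["pair_labels"][pair_id] = (
                    "related" if frac >= 0.5 else "unrelated"
                )
        truth["individuals"][ind] = planted.to_dict()

    config = {
        "species_id": species_id,
        "pathway_db": db_path.name,
        "cutoff_table": cutoff_path.name,
        "depth": int(depth),
        "seed": int(seed),
        "reference": "last",
        "window": 1000,
        "samples": samples_cfg,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def generate_rarefaction_inputs(
    out_dir: str | Path,
    n_pairs: int,
    n_reads: int,
    read_len: int,
    pathway_ids: Sequence[str],
    detect_depth: int,
    frac_divergent: float,
    seed: int,
) -> dict:
    """FASTQ pairs plus per-sample pathway detection thresholds.

    Divergent pairs carry one pathway that the second mate only detects at
    ``detect_depth`` reads or more, so the zero-difference percentage rises
    with depth and flattens once every threshold is exceeded.  Writes
    ``thresholds.json`` describing pairs and thresholds; returns it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_div = int(round(frac_divergent * n_pairs))
    pairs, thresholds = [], {}
    for i in range(n_pairs):
        sa, sb = f"p{i + 1}a", f"p{i + 1}b"
        pairs.append([sa, sb])
        thresholds[sa] = {p: 0 for p in pathway_ids}
        thresholds[sb] = {p: 0 for p in pathway_ids}
        if i < n_div:
            marker = pathway_ids[i % len(pathway_ids)]
            thresholds[sb][marker] = int(detect_depth)
        for sid in (sa, sb):
            write_fastq(
                generate_reads(n_reads, read_len, int(rng.integers(0, 2**31))),
                out / f"{sid}.fastq",
            )
    meta = {"pairs": pairs, "thresholds": thresholds}
    with open(out / "thresholds.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return meta


def make_threshold_downstream(
    thresholds: Mapping[str, Mapping[str, int]],
    pairs: Sequence[Sequence[str]],
):
    """Downstream pipeline stub: pathway detected iff read count ≥ threshold."""
    pathway_ids = sorted({p for t in thresholds.values() for p in t})

    def downstream(subsampled: Mapping[str, list[ReadRecord]]):
        diffs = []
        for sa, sb in pairs:
            na, nb = len(subsampled[sa]), len(subsampled[sb])
            va = tuple(int(na >= thresholds[sa].get(p, 0)) for p in pathway_ids)
            vb = tuple(int(nb >= thresholds[sb].get(p, 0)) for p in pathway_ids)
            delta = tuple(y - x for x, y in zip(va, vb))
            diffs.append(
                PairDifference(
                    pair_id=f"{sa}|{sb}",
                    n_diff=sum(1 for d in delta if d),
                    delta=delta,
                )
            )
        return diffs, None

    return downstream
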