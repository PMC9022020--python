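"""Read-level I/O: FASTQ parsing, quality filtering and seeded subsampling.

Quality control follows sliding-window trimming then a minimum-length
filter (Trimmomatic ``SLIDINGWINDOW`` / ``MINLEN`` semantics): a read is
truncated at the start of the first window whose mean Phred quality falls
below the threshold, and the survivor is kept only if it is still at least
``min_length`` bases long.

Subsampling is uniform without replacement, deterministic under a fixed
seed, and preserves input order, so paired files subsampled with the same
seed stay mate-consistent.  It is intentionally *not* bit-compatible with
``seqtk sample``; the contract is seed-determinism only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "QCParams",
    "qc_filter_read",
    "qc_filter_reads",
    "subsample_reads",
    "read_fastq",
    "write_fastq",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with per-base Phred quality scores.

    Attributes
    ----------
    read_id:
        Read identifier (FASTQ header without the leading ``@``).
    sequence:
        Nucleotide string over the alphabet ``ACGTN``.
    qualities:
        Per-base Phred scores, same length as ``sequence``.
    """

    read_id: str
    sequence: str
    qualities: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid bases {sorted(bad)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds.

    Defaults: discard reads shorter than 50 bases and truncate at the first
    50-base sliding window with mean quality below Phred 20.
    """

    min_length: int = 50
    window_len: int = 50
    min_mean_q: float = 20.0

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.window_len <= 0 or self.min_mean_q <= 0:
            raise ValueError("QC parameters must be strictly positive")


def qc_filter_read(read: ReadRecord, params: QCParams = QCParams()) -> ReadRecord | None:
    """Apply sliding-window quality trimming and the length filter.

    The read is scanned 5'→3' with a window of ``params.window_len`` bases
    advancing one base at a time; it is truncated at the start of the first
    window whose mean quality is below ``params.min_mean_q``.  Reads shorter
    than one window are judged on their whole-read mean quality.  Returns the
    (possibly truncated) read, or ``None`` if the survivor is shorter than
    ``params.min_length``.
    """
    n = len(read)
    if n == 0:
        return None
    quals = np.asarray(read.qualities, dtype=np.float64)
    w = params.window_len
    if n < w:
        kept = n if quals.mean() >= params.min_mean_q else 0
    else:
        kept = n
        # prefix sums -> mean of every length-w window in O(n)
        csum = np.concatenate(([0.0], np.cumsum(quals)))
        means = (csum[w:] - csum[:-w]) / w
        failing = np.nonzero(means < params.min_mean_q)[0]
        if failing.size:
            kept = int(failing[0])
    if kept < params.min_length:
        return None
    if kept == n:
        return read
    return ReadRecord(read.read_id, read.sequence[:kept], read.qualities[:kept])


def qc_filter_reads(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> Iterator[ReadRecord]:
    """Yield the surviving reads of :func:`qc_filter_read` over a stream."""
    for read in reads:
        kept = qc_filter_read(read, params)
        if kept is not None:
            yield kept


def subsample_reads(
    reads: Sequence[ReadRecord] | Iterable[ReadRecord], n: int, seed: int
) -> list[ReadRecord]:
    """Sample ``min(n, len(reads))`` reads uniformly without replacement.

    Output preserves the original input order.  The selected *index set*
    depends only on ``(seed, total, n)``, so two files with aligned records
    subsampled with one seed select the same positions.
    """
    if n < 0:
        raise ValueError(f"subsample size must be non-negative, got {n}")
    pool = list(reads)
    if n >= len(pool):
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in np.sort(idx)]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate :class:`ReadRecord` objects from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ (gzipped if the path ends in ``.gz``).

    Returns the number of records written.
    """
    count = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write(rec, handle, "fastq")
            count += 1
    return count
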