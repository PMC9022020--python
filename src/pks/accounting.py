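"""Cohort read accounting: totals over per-dataset read counts."""

from __future__ import annotations

from typing import Mapping

__all__ = ["total_read_count", "STUDY_DATASET_READ_COUNTS"]

# Published per-dataset metagenomic read counts of the four public cohorts
# the method was developed on (NCBI PRJNA388263, ENA PRJEB8094, the HMP
# portal, NCBI PRJNA624223).
STUDY_DATASET_READ_COUNTS: dict[str, int] = {
    "fukuyama": 359_276_476,
    "raymond": 1_500_234_831,
    "hmp": 4_124_040_250,
    "zuo": 407_435_415,
}


def total_read_count(per_dataset: Mapping[str, int]) -> int:
    """Sum per-dataset read counts; rejects negative entries."""
    total = 0
    for name, count in per_dataset.items():
        if count < 0:
            raise ValueError(f"dataset {name!r}: negative read count {count}")
        total += int(count)
    return total
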