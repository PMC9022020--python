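"""Depth sweeps: track the zero-difference percentage and pick a working depth.

At each requested depth every sample's reads are subsampled (seed =
``base_seed + repeat``), a caller-supplied downstream pipeline turns the
subsampled cohort into related-pair differences, and the per-depth value
is the mean zero-difference percentage over repeats.  The working depth is
the smallest one whose value is within ``tol`` percentage points of the
deepest depth's value (the plateau criterion); an explicit override
reproduces a fixed choice such as 5 million reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .core import PairDifference, summarize_related_pairs
from .reads import ReadRecord, subsample_reads

__all__ = ["DepthPoint", "DepthCurve", "zero_diff_curve", "select_depth"]

# downstream: subsampled cohort -> (related-pair differences, mean WSS or None)
Downstream = Callable[
    [Mapping[str, list[ReadRecord]]],
    tuple[Sequence[PairDifference], float | None],
]


@dataclass(frozen=True)
class DepthPoint:
    depth: int
    pct_zero: float  # mean over repeats
    repeats: tuple[float, ...]
    mean_wss: float | None
    full: bool  # at least one sample had fewer reads than `depth`


@dataclass(frozen=True)
class DepthCurve:
    points: tuple[DepthPoint, ...]

    def __post_init__(self) -> None:
        depths = [p.depth for p in self.points]
        if len(depths) < 2:
            raise ValueError("a depth curve needs at least two depths")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depths must be strictly increasing")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "depth": p.depth,
                "pct_zero": p.pct_zero,
                "repeats": ",".join(f"{r:g}" for r in p.repeats),
                "mean_wss": "" if p.mean_wss is None else p.mean_wss,
                "full": int(p.full),
            }
            for p in self.points
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthCurve":
        df = pd.read_csv(path, sep="\t")
        points = tuple(
            DepthPoint(
                depth=int(row.depth),
                pct_zero=float(row.pct_zero),
                repeats=tuple(float(x) for x in str(row.repeats).split(",")),
                mean_wss=None if pd.isna(row.mean_wss) else float(row.mean_wss),
                full=bool(row.full),
            )
            for row in df.itertuples()
        )
        return cls(points=points)


def zero_diff_curve(
    samples: Mapping[str, Sequence[ReadRecord]],
    depths: Sequence[int],
    repeats_per_depth: int,
    base_seed: int,
    downstream: Downstream,
) -> DepthCurve:
    """Sweep depths, re-running subsampling + downstream per repeat."""
    if repeats_per_depth < 1:
        raise ValueError("repeats_per_depth must be >= 1")
    if list(depths) != sorted(set(depths)):
        raise ValueError("depths must be sorted and unique")

    points = []
    for depth in depths:
        full = any(depth > len(reads) for reads in samples.values())
        repeat_pcts: list[float] = []
        wss_values: list[float] = []
        for r in range(repeats_per_depth):
            seed = base_seed + r
            subsampled = {
                sid: subsample_reads(reads, depth, seed)
                for sid, reads in sorted(samples.items())
            }
            diffs, mean_wss = downstream(subsampled)
            repeat_pcts.append(summarize_related_pairs(list(diffs)).pct_zero)
            if mean_wss is not None:
                wss_values.append(mean_wss)
        points.append(
            DepthPoint(
                depth=depth,
                pct_zero=sum(repeat_pcts) / len(repeat_pcts),
                repeats=tuple(repeat_pcts),
                mean_wss=sum(wss_values) / len(wss_values) if wss_values else None,
                full=full,
            )
        )
    return DepthCurve(points=tuple(points))


def select_depth(
    curve: DepthCurve, tol: float, override: int | None = None
) -> int:
    """Smallest depth within ``tol`` points of the deepest depth's value.

    ``override`` short-circuits the rule (it must be a depth on the curve).
    """
    depths = [p.depth for p in curve.points]
    if override is not None:
        if override not in depths:
            raise ValueError(f"override depth {override} not on the curve")
        return override
    target = curve.points[-1].pct_zero
    for p in curve.points:
        if abs(p.pct_zero - target) <= tol:
            return p.depth
    return depths[-1]  # unreachable: the deepest point always qualifies
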