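"""Sliding-window scaffolding shared by the heterozygosity and diversity scans.

Windows are 1-based inclusive ``[start, start + size - 1]``, anchored at each
contig's first base and advanced by ``step``; windows extending past the
contig end are dropped rather than truncated so per-window denominators stay
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 100 kb windows stepping by 10 kb by default.

    ``min_snps`` flags near-empty windows; flagged windows are reported but
    excluded from genome-wide means/SDs and outlier scanning.
    """

    size: int = 100_000
    step: int = 10_000
    min_snps: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")

    def starts(self, contig_length: int) -> np.ndarray:
        """1-based start coordinates of all windows fully inside the contig."""
        last_start = contig_length - self.size + 1
        if last_start < 1:
            return np.empty(0, dtype=np.int64)
        return np.arange(1, last_start + 1, self.step, dtype=np.int64)


def window_table(contig_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """All windows over the given contigs as a (contig, start, end) frame."""
    frames = []
    for contig, length in contig_lengths.items():
        starts = spec.starts(int(length))
        frames.append(pd.DataFrame({
            "contig": contig,
            "start": starts,
            "end": starts + spec.size - 1,
        }))
    if not frames:
        return pd.DataFrame(columns=["contig", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def aggregate_in_windows(pos: np.ndarray, values: np.ndarray,
                         starts: np.ndarray, size: int) -> np.ndarray:
    """Sum ``values`` (per sorted position) inside each window via prefix sums.

    Returns an array of shape ``(n_windows,) + values.shape[1:]``.
    """
    csum = np.concatenate([np.zeros((1,) + values.shape[1:]),
                           np.cumsum(values, axis=0)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + size - 1, side="right")
    return csum[hi] - csum[lo]


class GenomeMask:
    """Callable-site mask from merged BED intervals (0-based half-open input)."""

    def __init__(self, intervals: dict[str, np.ndarray]):
        # each value: (k, 2) array of merged 1-based inclusive [start, end]
        self.intervals = intervals

    @classmethod
    def from_bed(cls, path) -> "GenomeMask":
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                contig, s, e = line.split("\t")[:3]
                raw.setdefault(contig, []).append((int(s) + 1, int(e)))
        merged = {}
        for contig, ivs in raw.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1] + 1:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[contig] = np.array(out, dtype=np.int64)
        return cls(merged)

    def window_bp(self, contig: str, start: int, end: int) -> int:
        """Masked (callable) base count inside a 1-based inclusive window."""
        ivs = self.intervals.get(contig)
        if ivs is None:
            return 0
        lo = np.maximum(ivs[:, 0], start)
        hi = np.minimum(ivs[:, 1], end)
        return int(np.maximum(hi - lo + 1, 0).sum())
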