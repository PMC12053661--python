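"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open throughout (BED convention).  The
fragment midpoint convention is ``floor((start + end) / 2)`` everywhere;
for even-length fragments this picks the left of the two central bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end"]

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "orf_start", "orf_end", "rpkm"]


def fragment_midpoints(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Midpoint of a half-open interval: floor((start+end)/2)."""
    return (np.asarray(start) + np.asarray(end)) // 2


@dataclass
class FragmentSet:
    """A sample's MNase-protected fragments.

    ``frame`` has columns chrom (str), start, end (int, 0-based half-open).
    """

    sample_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return fragment_midpoints(
            self.frame["start"].to_numpy(), self.frame["end"].to_numpy()
        )

    def size_histogram(self) -> pd.Series:
        """Counts per fragment length, indexed by length."""
        return pd.Series(self.lengths).value_counts().sort_index()

    def validate(self, max_length: int = 1000) -> None:
        lengths = self.lengths
        if len(self.frame) and ((lengths < 1).any() or (lengths > max_length).any()):
            bad = int(((lengths < 1) | (lengths > max_length)).sum())
            raise ValueError(
                f"{self.sample_id}: {bad} fragments with length outside [1, {max_length}]"
            )

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.sample_id, self.frame.loc[np.asarray(mask)].copy())


@dataclass
class Signal1D:
    """Anchor-relative per-bp signal over window [-w_up, +w_down].

    ``values[i]`` corresponds to relative position ``i - w_up``; length is
    ``w_up + w_down + 1``.  Orientation is 5'->3' of the anchoring feature.
    """

    values: np.ndarray
    w_up: int
    w_down: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Signal1D values must be one-dimensional")
        if len(self.values) != self.w_up + self.w_down + 1:
            raise ValueError(
                f"Signal1D length {len(self.values)} != w_up+w_down+1 "
                f"({self.w_up}+{self.w_down}+1)"
            )

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.w_up, self.w_down + 1)

    def value_at(self, rel: int) -> float:
        return float(self.values[rel + self.w_up])

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class CoverageTrack:
    """Sparse per-bp coverage (bedGraph semantics: gaps read as zero).

    ``intervals`` maps chrom -> (starts, ends, values) as sorted,
    non-overlapping numpy arrays.
    """

    intervals: dict = field(default_factory=dict)

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if (starts < 0).any():
            raise ValueError(f"{chrom}: negative coordinates in coverage intervals")
        if (ends <= starts).any():
            raise ValueError(f"{chrom}: empty or inverted coverage intervals")
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{chrom}: overlapping coverage intervals")
        if not np.isfinite(values).all():
            raise ValueError(f"{chrom}: non-finite coverage values")
        self.intervals[chrom] = (starts, ends, values)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp values over [start, end); positions with no interval are 0."""
        if end <= start:
            raise ValueError("query interval must be non-empty")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self.intervals:
            return out
        starts, ends, vals = self.intervals[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
            a = max(int(s), start)
            b = min(int(e), end)
            if b > a:
                out[a - start : b - start] = v
        return out


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table; returns it unchanged on success."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    dup = genes["gene_id"][genes["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id: {dup.iloc[0]!r}")
    bad_strand = set(genes["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValueError(
            f"invalid strand value(s) {sorted(bad_strand)}; allowed: '+', '-'"
        )
    if (genes["orf_start"] >= genes["orf_end"]).any():
        raise ValueError("gene table has orf_start >= orf_end")
    if (genes[["tss", "orf_start"]].to_numpy() < 0).any():
        raise ValueError("gene table has negative coordinates")
    if (genes["rpkm"] < 0).any():
        raise ValueError("gene table has negative rpkm")
    return genes
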