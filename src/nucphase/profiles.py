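"""Anchor-relative midpoint signals, TSS heatmaps, aggregate profiles, and
2D midpoint-by-length ("typhoon") occupancy profiles.

The fragment midpoint is used as a proxy for nucleosome dyad density.
All TSS-oriented outputs read 5'->3' of the gene: for a minus-strand
anchor the relative position is ``anchor - midpoint``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FragmentSet, Signal1D, validate_gene_table


def _chrom_midpoints(fs: FragmentSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted midpoints, lengths) for fast window queries."""
    mids = fs.midpoints
    lengths = fs.lengths
    chroms = fs.frame["chrom"].to_numpy()
    out = {}
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        m = mids[mask]
        l = lengths[mask]
        order = np.argsort(m, kind="stable")
        out[chrom] = (m[order], l[order])
    return out


def _window_counts(
    sorted_mids: np.ndarray, anchor: int, strand: str, w_up: int, w_down: int
) -> np.ndarray:
    """Counts of midpoints per anchor-relative bp, oriented 5'->3'."""
    if strand == "+":
        lo, hi = anchor - w_up, anchor + w_down
    else:
        lo, hi = anchor - w_down, anchor + w_up
    i0 = np.searchsorted(sorted_mids, lo, side="left")
    i1 = np.searchsorted(sorted_mids, hi, side="right")
    mids = sorted_mids[i0:i1]
    rel = (mids - anchor) if strand == "+" else (anchor - mids)
    return np.bincount(rel + w_up, minlength=w_up + w_down + 1).astype(float)


def midpoint_signal(
    fs: FragmentSet,
    chrom: str,
    anchor: int,
    strand: str,
    w_up: int,
    w_down: int,
) -> Signal1D:
    """Per-bp fragment-midpoint counts around one oriented anchor."""
    if w_up < 0 or w_down < 0:
        raise ValueError("window sizes must be >= 0")
    if strand not in {"+", "-"}:
        raise ValueError(f"invalid strand {strand!r}")
    index = _chrom_midpoints(fs)
    if chrom not in index:
        return Signal1D(np.zeros(w_up + w_down + 1), w_up, w_down)
    counts = _window_counts(index[chrom][0], anchor, strand, w_up, w_down)
    return Signal1D(counts, w_up, w_down)


@dataclass
class TssHeatmap:
    """Per-gene TSS-anchored midpoint matrix, rows in decreasing activity."""

    gene_ids: list[str]
    rpkm: np.ndarray
    matrix: np.ndarray  # genes x (w_up + w_down + 1)
    w_up: int
    w_down: int
    n_skipped: int = 0


def _ordered_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Decreasing rpkm; ties broken lexicographically by gene_id."""
    return genes.sort_values(
        ["rpkm", "gene_id"], ascending=[False, True], kind="stable"
    )


def tss_heatmap(
    fs: FragmentSet, genes: pd.DataFrame, w_up: int = 200, w_down: int = 1000
) -> TssHeatmap:
    """One row per gene (midpoint signal at its TSS), ordered by activity.

    Genes on chromosomes absent from the fragment set are skipped; their
    number is reported on the result and in a warning.
    """
    genes = _ordered_genes(validate_gene_table(genes))
    index = _chrom_midpoints(fs)
    width = w_up + w_down + 1
    rows, ids, rpkms = [], [], []
    skipped = 0
    for rec in genes.itertuples():
        if rec.chrom not in index:
            skipped += 1
            continue
        rows.append(
            _window_counts(index[rec.chrom][0], rec.tss, rec.strand, w_up, w_down)
        )
        ids.append(rec.gene_id)
        rpkms.append(rec.rpkm)
    if skipped:
        warnings.warn(f"tss_heatmap: skipped {skipped} gene(s) on unknown chromosomes")
    matrix = np.vstack(rows) if rows else np.zeros((0, width))
    return TssHeatmap(ids, np.asarray(rpkms, dtype=float), matrix, w_up, w_down, skipped)


def aggregate_profile(
    fs: FragmentSet,
    genes: pd.DataFrame,
    w_up: int,
    w_down: int,
    normalize: str = "per-gene-mean",
) -> Signal1D:
    """Element-wise mean (or sum) of TSS-oriented per-gene midpoint signals."""
    if len(genes) == 0:
        raise ValueError("aggregate_profile requires a non-empty gene subset")
    if normalize not in {"per-gene-mean", "raw"}:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    hm = tss_heatmap(fs, genes, w_up, w_down)
    if hm.matrix.shape[0] == 0:
        raise ValueError("no usable genes for aggregate_profile")
    agg = hm.matrix.mean(axis=0) if normalize == "per-gene-mean" else hm.matrix.sum(axis=0)
    return Signal1D(agg, w_up, w_down)


@dataclass
class TyphoonProfile:
    """Fragment midpoints vs lengths around an anchor, with 2D KDE shading."""

    positions: np.ndarray  # anchor-relative midpoint positions
    lengths: np.ndarray
    density: np.ndarray
    w_up: int
    w_down: int
    len_range: tuple[int, int]
    bandwidths: tuple[float, float]


def typhoon_profile(
    fs: FragmentSet,
    chrom: str,
    anchor: int,
    strand: str,
    w_up: int,
    w_down: int,
    len_range: tuple[int, int] = (20, 250),
    bandwidths: tuple[float, float] = (20.0, 5.0),
) -> TyphoonProfile:
    """Chromatin occupancy profile: midpoint vs length scatter with a
    Gaussian-kernel 2D density evaluated at every retained point.

    ``bandwidths`` are the kernel SDs along (position, length) in bp.
    """
    lo, hi = len_range
    if lo < 20 or hi > 250 or lo > hi:
        raise ValueError("len_range must lie within [20, 250]")
    index = _chrom_midpoints(fs)
    if chrom not in index:
        raise ValueError(f"no fragments on chromosome {chrom!r}")
    mids, lens = index[chrom]
    if strand == "+":
        rel = mids - anchor
    else:
        rel = anchor - mids
    keep = (rel >= -w_up) & (rel <= w_down) & (lens >= lo) & (lens <= hi)
    x = rel[keep].astype(float)
    y = lens[keep].astype(float)
    if len(x) < 2:
        raise ValueError("typhoon_profile needs at least 2 in-window points")
    bx, by = bandwidths
    density = np.empty(len(x))
    norm = 1.0 / (2.0 * np.pi * bx * by * len(x))
    chunk = 2000
    for i in range(0, len(x), chunk):
        dx = (x[i : i + chunk, None] - x[None, :]) / bx
        dy = (y[i : i + chunk, None] - y[None, :]) / by
        density[i : i + chunk] = norm * np.exp(-0.5 * (dx**2 + dy**2)).sum(axis=1)
    return TyphoonProfile(x, y, density, w_up, w_down, len_range, bandwidths)
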