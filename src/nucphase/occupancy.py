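"""Gene-body metagene profiles, occupancy center of mass, and the
correlation between nucleosome 5'-shift and RNAPII change.

Each gene's ORF is rescaled to a common 0..1 axis (5'->3'), split into
``n_bins`` equal-width bins, and summarized either from fragment midpoints
or from a per-bp coverage track.  Per-gene rows are densities (per bp), so
the group mean is not dominated by long or deep genes.  The center of mass
(CoM) of a gene's profile summarizes where along the body its occupancy
sits; a 5'-ward redistribution lowers the CoM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import CoverageTrack, FragmentSet, validate_gene_table


@dataclass
class MetageneProfile:
    group: str
    values: np.ndarray  # mean per-bin signal across genes
    n_bins: int
    n_genes: int


def genebody_profile(
    source: FragmentSet | CoverageTrack,
    genes: pd.DataFrame,
    n_bins: int = 50,
    min_gene_len: int = 500,
    group: str = "all",
) -> tuple[MetageneProfile, pd.DataFrame]:
    """Metagene profile over ORFs plus the per-gene binned matrix.

    Fragment sources bin midpoint counts; coverage sources average per-bp
    values.  Rows are oriented 5'->3' and expressed per bp of bin width.
    Genes shorter than ``max(min_gene_len, n_bins)`` bp are excluded with
    a warning.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    genes = validate_gene_table(genes)

    if isinstance(source, FragmentSet):
        from .profiles import _chrom_midpoints

        index = _chrom_midpoints(source)

    rows, ids = [], []
    skipped = 0
    for rec in genes.itertuples():
        length = rec.orf_end - rec.orf_start
        if length < max(min_gene_len, n_bins):
            skipped += 1
            continue
        edges = np.linspace(rec.orf_start, rec.orf_end, n_bins + 1)
        widths = np.diff(edges)
        if isinstance(source, FragmentSet):
            if rec.chrom not in index:
                row = np.zeros(n_bins)
            else:
                mids = index[rec.chrom][0]
                i0 = np.searchsorted(mids, rec.orf_start, side="left")
                i1 = np.searchsorted(mids, rec.orf_end, side="left")
                counts, _ = np.histogram(mids[i0:i1], bins=edges)
                row = counts / widths
        else:
            perbp = source.values(rec.chrom, int(rec.orf_start), int(rec.orf_end))
            idx = np.minimum(
                ((np.arange(length) / length) * n_bins).astype(int), n_bins - 1
            )
            sums = np.bincount(idx, weights=perbp, minlength=n_bins)
            row = sums / np.bincount(idx, minlength=n_bins)
        if rec.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(rec.gene_id)
    if skipped:
        warnings.warn(f"genebody_profile: excluded {skipped} gene(s) shorter "
                      f"than {max(min_gene_len, n_bins)} bp")
    if not rows:
        raise ValueError("genebody_profile: no usable genes")
    matrix = pd.DataFrame(np.vstack(rows), index=ids)
    return MetageneProfile(group, matrix.to_numpy().mean(axis=0), n_bins, len(ids)), matrix


def center_of_mass(profile: np.ndarray | pd.Series) -> float:
    """CoM of a binned gene-body profile on the relative axis [0, 1].

    Bin i contributes at its center (i + 0.5) / n_bins.  An all-zero
    profile has no defined CoM and returns NaN.
    """
    v = np.asarray(profile, dtype=float)
    total = v.sum()
    if total <= 0:
        return float("nan")
    centers = (np.arange(len(v)) + 0.5) / len(v)
    return float((centers * v).sum() / total)


def per_gene_com(matrix: pd.DataFrame) -> pd.Series:
    """Center of mass for every row of a per-gene binned matrix."""
    return matrix.apply(center_of_mass, axis=1)


def polII_5prime_mean(
    track: CoverageTrack, genes: pd.DataFrame
) -> pd.Series:
    """Mean coverage over the 5' half of each ORF (transcription-oriented)."""
    genes = validate_gene_table(genes)
    out = {}
    for rec in genes.itertuples():
        mid = (rec.orf_start + rec.orf_end) // 2
        if rec.strand == "+":
            vals = track.values(rec.chrom, int(rec.orf_start), int(mid))
        else:
            vals = track.values(rec.chrom, int(mid), int(rec.orf_end))
        out[rec.gene_id] = float(vals.mean()) if len(vals) else float("nan")
    return pd.Series(out, name="polII_5prime_mean")


def per_gene_change(
    reference: pd.Series, condition: pd.Series, relative: bool = True
) -> pd.Series:
    """Per-gene signal change, condition vs reference.

    With ``relative=True`` (default) the change is (cond - ref) / ref,
    which makes genes comparable regardless of their expression level;
    genes with non-positive reference signal are dropped.
    """
    paired = pd.concat({"ref": reference, "cond": condition}, axis=1, join="inner")
    delta = paired["cond"] - paired["ref"]
    if relative:
        ok = paired["ref"] > 0
        return (delta[ok] / paired.loc[ok, "ref"]).rename("change")
    return delta.rename("change")


def shift_polII_correlation(
    delta_com: pd.Series, delta_polII: pd.Series
) -> dict:
    """Spearman correlation of per-gene nucleosome CoM change against
    per-gene RNAPII change (paired on gene id, two-sided p)."""
    paired = pd.concat(
        {"com": delta_com, "pol": delta_polII}, axis=1, join="inner"
    ).dropna()
    if len(paired) < 10:
        raise ValueError("shift_polII_correlation needs >= 10 paired genes")
    if paired["com"].nunique() == 1 or paired["pol"].nunique() == 1:
        raise ValueError("shift_polII_correlation: constant input vector")
    rho, p = spearmanr(paired["com"], paired["pol"])
    return {"rho": float(rho), "p": float(p), "n": int(len(paired))}
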