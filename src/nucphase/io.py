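"""Reading and writing fragment / annotation formats, the nucleosome-size
filter, and per-fragment-size matched subsampling across samples.

All coordinates are 0-based half-open (BED).  BEDPE mate pairs are
collapsed to the outer span of the two mates.
"""

from __future__ import annotations

import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CoverageTrack, FragmentSet, validate_gene_table


class FragmentParseError(ValueError):
    """Raised when a fragment file contains malformed records."""


def _sample_id_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".bed", ".bedpe", ".gz", ".tsv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_fragments(
    path: str | Path, fmt: str = "bed3", sample_id: str | None = None
) -> FragmentSet:
    """Read fragments from BED3 or BEDPE.

    Malformed lines (too few fields, non-integer or inverted coordinates)
    raise :class:`FragmentParseError` listing 1-based line numbers.  BEDPE
    mates on different chromosomes are dropped with a warning giving their
    count.
    """
    path = Path(path)
    if fmt not in {"bed3", "bedpe"}:
        raise ValueError(f"unknown fragment format {fmt!r}; expected bed3 or bedpe")
    if not path.exists():
        raise FileNotFoundError(path)
    n_fields = 3 if fmt == "bed3" else 6
    records = []
    bad_lines: list[int] = []
    cross_chrom = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields:
                bad_lines.append(lineno)
                continue
            try:
                if fmt == "bed3":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                    c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
                    if c1 != c2:
                        cross_chrom += 1
                        continue
                    chrom, start, end = c1, min(s1, s2), max(e1, e2)
            except ValueError:
                bad_lines.append(lineno)
                continue
            if start < 0 or start >= end:
                bad_lines.append(lineno)
                continue
            records.append((chrom, start, end))
    if bad_lines:
        shown = ", ".join(map(str, bad_lines[:20]))
        more = "" if len(bad_lines) <= 20 else f" (+{len(bad_lines) - 20} more)"
        raise FragmentParseError(
            f"{path}: {len(bad_lines)} malformed line(s): {shown}{more}"
        )
    if cross_chrom:
        warnings.warn(
            f"{path}: dropped {cross_chrom} mate pair(s) on different chromosomes",
            stacklevel=2,
        )
    frame = pd.DataFrame(records, columns=["chrom", "start", "end"])
    fs = FragmentSet(sample_id or _sample_id_from_path(path), frame)
    fs.validate()
    return fs


def write_fragments(fs: FragmentSet, path: str | Path, fmt: str = "bed3") -> None:
    """Write fragments as BED3, or as BEDPE with two 50 bp synthetic mates."""
    path = Path(path)
    if fmt == "bed3":
        fs.frame[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )
    elif fmt == "bedpe":
        df = fs.frame
        mate = np.minimum(50, (df["end"] - df["start"]).to_numpy())
        out = pd.DataFrame(
            {
                "chrom1": df["chrom"],
                "start1": df["start"],
                "end1": df["start"] + mate,
                "chrom2": df["chrom"],
                "start2": df["end"] - mate,
                "end2": df["end"],
                "name": [f"frag{i}" for i in range(len(df))],
                "score": ".",
                "strand1": "+",
                "strand2": "-",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown fragment format {fmt!r}")


def filter_fragment_length(fs: FragmentSet, lo: int, hi: int) -> FragmentSet:
    """Keep fragments with lo <= length <= hi (both bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    lengths = fs.lengths
    return fs.subset((lengths >= lo) & (lengths <= hi))


def subsample_matched(
    samples: list[FragmentSet], size_lo: int, size_hi: int, seed: int
) -> list[FragmentSet]:
    """Equalize per-fragment-size depth across samples.

    For every fragment length L in [size_lo, size_hi], the smallest count of
    L-length fragments across samples is found and every sample is
    subsampled (uniform, without replacement) to exactly that depth at L.
    Lengths outside the range are dropped.  The RNG stream for each
    (sample, length) pair is derived from the master seed and the sample id,
    so results do not depend on sample order.
    """
    if len(samples) < 2:
        raise ValueError("subsample_matched requires at least two samples")
    if size_lo > size_hi:
        raise ValueError("size_lo must be <= size_hi")
    for fs in samples:
        if len(fs) == 0:
            raise ValueError(f"sample {fs.sample_id!r} has no fragments")

    lengths = [fs.lengths for fs in samples]
    target: dict[int, int] = {}
    for L in range(size_lo, size_hi + 1):
        target[L] = min(int((lens == L).sum()) for lens in lengths)

    out = []
    for fs, lens in zip(samples, lengths):
        keep_idx: list[np.ndarray] = []
        for L, m in target.items():
            if m == 0:
                continue
            idx = np.flatnonzero(lens == L)
            if len(idx) > m:
                sub_seed = np.random.SeedSequence(
                    [int(seed), zlib.crc32(fs.sample_id.encode()), L]
                )
                rng = np.random.default_rng(sub_seed)
                idx = np.sort(rng.choice(idx, size=m, replace=False))
            keep_idx.append(idx)
        if keep_idx:
            keep = np.sort(np.concatenate(keep_idx))
        else:
            keep = np.empty(0, dtype=np.int64)
        out.append(FragmentSet(fs.sample_id, fs.frame.iloc[keep].copy()))
    return out


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV gene annotation table."""
    path = Path(path)
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    try:
        return validate_gene_table(genes)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    validate_gene_table(genes).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph into a sparse coverage track (gaps read as zero)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    track = CoverageTrack()
    for chrom, sub in df.groupby("chrom", sort=True):
        try:
            track.add_chrom(
                chrom,
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return track


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )
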