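"""Per-gene RPKM and the transcribed / non-transcribed classification.

A gene is called transcribed when log2(RPKM + 1) >= threshold (default
0.5, boundary inclusive).
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

TRANSCRIBED_THRESHOLD = 0.5


def compute_rpkm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library_size: int | None = None,
) -> dict[str, float]:
    """RPKM = count / (length/1000) / (library_size/1e6).

    ``library_size`` defaults to the sum of the supplied counts.
    """
    missing = [g for g in counts if g not in lengths]
    if missing:
        raise KeyError(f"gene {missing[0]!r} present in counts but not in lengths")
    if library_size is None:
        library_size = int(sum(counts.values()))
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    out = {}
    for gene, c in counts.items():
        L = lengths[gene]
        if L <= 0:
            raise ValueError(f"gene {gene!r} has non-positive length {L}")
        out[gene] = c / (L / 1000.0) / (library_size / 1e6)
    return out


def classify_transcribed(
    rpkm: Mapping[str, float], threshold: float = TRANSCRIBED_THRESHOLD
) -> dict[str, bool]:
    """Flag genes with log2(rpkm + 1) >= threshold (inclusive boundary)."""
    out = {}
    for gene, r in rpkm.items():
        if r < 0:
            raise ValueError(f"gene {gene!r} has negative rpkm {r}")
        out[gene] = bool(np.log2(r + 1.0) >= threshold)
    return out


def expression_table(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library_size: int | None = None,
    threshold: float = TRANSCRIBED_THRESHOLD,
) -> pd.DataFrame:
    """Combined per-gene table: count, length, rpkm, log2(rpkm+1), flag."""
    rpkm = compute_rpkm(counts, lengths, library_size)
    flags = classify_transcribed(rpkm, threshold)
    return pd.DataFrame(
        {
            "gene_id": list(counts),
            "count": [counts[g] for g in counts],
            "length_bp": [lengths[g] for g in counts],
            "rpkm": [rpkm[g] for g in counts],
            "log2_rpkm_p1": [float(np.log2(rpkm[g] + 1.0)) for g in counts],
            "transcribed": [flags[g] for g in counts],
        }
    )
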