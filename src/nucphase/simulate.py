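"""Synthetic MNase fragment generator with known ground truth.

The generator emulates the chromatin organization of budding-yeast genes:
a nucleosome-depleted region (NDR) at the promoter, a well-positioned +1
nucleosome ~60 bp downstream of the TSS, and a phased array of nucleosomes
with a characteristic dyad-to-dyad spacing (172 bp in the wild-type-like
condition).  Each nucleosome additionally occupies one of several
rotational settings offset by one DNA helical turn (a 10 bp lattice), so
its dyad is ``grid + lattice * r`` with ``r`` drawn from
``rotational_probs`` over steps {-1, 0, +1}.

Condition presets model disruption of the Spt6-Spn1 histone-chaperone
interaction: spacing increases by up to 10 bp, rotational occupancy moves
one lattice step downstream, nucleosome occupancy tilts toward the 5' end
of gene bodies, and RNAPII coverage drops at the 5' end.  All condition
effects apply to transcribed genes only; non-transcribed genes always
follow the baseline parameters.

Protected fragments are built from a 147 bp core plus independently drawn
edge extensions, so that the fragment-length distribution is
Normal(frag_len_mean_bp, frag_len_sd_bp) while midpoints scatter around
the dyad along the slope-2 diagonals seen in midpoint-vs-length plots.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GENE_COLUMNS, FragmentSet

NUCLEOSOME_CORE_BP = 147
# edge margin a dyad must keep from the ORF end for its nucleosome to fit
_DYAD_MARGIN_BP = 73
# RNAPII metaprofile anchor values (5' and 3' ends of a transcribed ORF)
_POL2_F5 = 1.25
_POL2_F3 = 0.75

_PRESET_OVERRIDABLE = {
    "spacing_bp",
    "rotational_probs",
    "occupancy_5prime_weight",
    "polII_5prime_scale",
    "digestion_asymmetry_bp",
    "frag_len_mean_bp",
    "frag_len_sd_bp",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic genome and fragment model."""

    n_genes: int = 250
    chrom_name: str = "chrSim"
    chrom_length_bp: int | None = None  # None: sized to fit the layout
    gene_len_log_mean: float = float(np.log(1400.0))
    gene_len_log_sd: float = 0.35
    gene_len_min_bp: int = 700
    gene_len_max_bp: int = 4000
    intergenic_gap_bp: int = 300
    ndr_width_bp: int = 140
    tss_to_orf_bp: int = 30
    plus_one_offset_bp: int = 60
    spacing_bp: int = 172
    rotational_lattice_bp: int = 10
    rotational_probs: tuple[float, float, float] = (0.15, 0.70, 0.15)
    frag_len_mean_bp: float = 157.0
    frag_len_sd_bp: float = 8.0
    digestion_asymmetry_bp: float = 0.0
    fragments_per_nucleosome: float = 50.0
    transcribed_fraction: float = 0.8
    expr_log_sd: float = 1.0
    occupancy_5prime_weight: float = 0.10
    polII_5prime_scale: float = 1.0
    severity_range: tuple[float, float] = (0.3, 1.0)
    library_size: int = 5_000_000
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in (
            "gene_len_min_bp",
            "gene_len_max_bp",
            "intergenic_gap_bp",
            "ndr_width_bp",
            "spacing_bp",
            "rotational_lattice_bp",
            "fragments_per_nucleosome",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.rotational_probs) - 1.0) > 1e-9:
            raise ValueError("rotational_probs must sum to 1")
        if min(self.rotational_probs) < 0:
            raise ValueError("rotational_probs must be non-negative")
        if not 0.0 <= self.transcribed_fraction <= 1.0:
            raise ValueError("transcribed_fraction must be in [0, 1]")
        if self.spacing_bp <= self.rotational_lattice_bp:
            raise ValueError("spacing_bp must exceed rotational_lattice_bp")
        return self


@dataclass(frozen=True)
class ConditionPreset:
    """A named condition as a partial override of the baseline config."""

    name: str
    overrides: dict = field(default_factory=dict)

    def apply(self, config: SimulationConfig) -> SimulationConfig:
        unknown = set(self.overrides) - _PRESET_OVERRIDABLE
        if unknown:
            raise ValueError(
                f"preset {self.name!r} overrides undeclared fields: {sorted(unknown)}"
            )
        return dataclasses.replace(config, **self.overrides).validate()


#: Severity ordering of the Spt6-Spn1 disruption conditions:
#: spt6-F249K > spn1-F267E > spn1-R263D (deltas interpolated at 1, 2/3, 1/3).
PRESETS: dict[str, ConditionPreset] = {
    "WT": ConditionPreset("WT", {}),
    "spt6-F249K-like": ConditionPreset(
        "spt6-F249K-like",
        {
            "spacing_bp": 182,
            "rotational_probs": (0.05, 0.25, 0.70),
            "occupancy_5prime_weight": 0.35,
            "polII_5prime_scale": 0.55,
        },
    ),
    "spn1-F267E-like": ConditionPreset(
        "spn1-F267E-like",
        {
            "spacing_bp": 179,
            "rotational_probs": (0.08, 0.40, 0.52),
            "occupancy_5prime_weight": 0.27,
            "polII_5prime_scale": 0.70,
        },
    ),
    "spn1-R263D-like": ConditionPreset(
        "spn1-R263D-like",
        {
            "spacing_bp": 175,
            "rotational_probs": (0.12, 0.55, 0.33),
            "occupancy_5prime_weight": 0.18,
            "polII_5prime_scale": 0.85,
        },
    ),
}


@dataclass
class GeneModel:
    """One simulated gene with its ground-truth dyad array."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    orf_start: int
    orf_end: int
    rpkm: float
    count: int
    transcribed: bool
    severity: float
    dyads: np.ndarray  # genomic positions, ordered along transcription

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1


def _gene_params(gene: GeneModel, base: SimulationConfig, condition: SimulationConfig):
    """Parameters governing a gene: condition values if transcribed, else baseline."""
    return condition if gene.transcribed else base


def simulate_genes(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    condition: SimulationConfig | None = None,
    rng_dyads: np.random.Generator | None = None,
) -> list[GeneModel]:
    """Lay out non-overlapping genes on both strands and assign dyad arrays.

    ``rng`` drives the gene layout and expression draws; ``rng_dyads``
    (defaults to ``rng``) drives the rotational-offset draws, so that two
    conditions simulated from the same seed share an identical gene layout.
    ``condition`` supplies the spacing/rotational parameters used for
    transcribed genes; non-transcribed genes always use ``config``.
    """
    config = config.validate()
    condition = (condition or config).validate()
    rng_dyads = rng_dyads if rng_dyads is not None else rng

    n = config.n_genes
    lengths = np.exp(
        rng.normal(config.gene_len_log_mean, config.gene_len_log_sd, size=n)
    )
    lengths = np.clip(np.round(lengths), config.gene_len_min_bp, config.gene_len_max_bp)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    n_transcribed = int(round(config.transcribed_fraction * n))
    transcribed = np.zeros(n, dtype=bool)
    transcribed[rng.permutation(n)[:n_transcribed]] = True
    severity = rng.uniform(*config.severity_range, size=n)

    # RNA-seq counts: transcribed genes share the library according to
    # lognormal weights; non-transcribed genes get 0-1 stray reads.
    counts = np.zeros(n, dtype=np.int64)
    weights = np.exp(rng.normal(0.0, config.expr_log_sd, size=n))
    stray = rng.integers(0, 2, size=n)
    if n_transcribed:
        w = np.where(transcribed, weights, 0.0)
        counts = np.round(w / w.sum() * config.library_size).astype(np.int64)
        counts = np.maximum(counts, np.where(transcribed, 1000, 0))
    counts = np.where(transcribed, counts, stray)
    rpkm = counts / (lengths / 1000.0) / (config.library_size / 1e6)

    genes: list[GeneModel] = []
    cursor = 1000
    pad = max(config.frag_len_mean_bp, 200)
    for i in range(n):
        L = int(lengths[i])
        strand = str(strands[i])
        if strand == "+":
            tss = cursor + config.ndr_width_bp
            orf_start = tss + config.tss_to_orf_bp
            orf_end = orf_start + L
            block_end = orf_end
        else:
            orf_start = cursor
            orf_end = orf_start + L
            tss = orf_end - 1 + config.tss_to_orf_bp
            block_end = tss + config.ndr_width_bp + 1
        gene = GeneModel(
            gene_id=f"gene{i:04d}",
            chrom=config.chrom_name,
            strand=strand,
            tss=tss,
            orf_start=orf_start,
            orf_end=orf_end,
            rpkm=float(rpkm[i]),
            count=int(counts[i]),
            transcribed=bool(transcribed[i]),
            severity=float(severity[i]),
            dyads=np.empty(0, dtype=np.int64),
        )
        params = _gene_params(gene, config, condition)
        gene.dyads = _draw_dyads(gene, params, rng_dyads)
        genes.append(gene)
        cursor = block_end + config.intergenic_gap_bp

    needed = cursor + int(pad)
    if config.chrom_length_bp is not None and needed > config.chrom_length_bp:
        raise ValueError(
            f"impossible layout: {n} genes need {needed} bp but "
            f"chrom_length_bp={config.chrom_length_bp}"
        )
    return genes


def _draw_dyads(
    gene: GeneModel, params: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dyad positions: grid at tss+offset+k*spacing plus a rotational offset."""
    if gene.strand == "+":
        span = gene.orf_end - gene.tss
    else:
        span = gene.tss - gene.orf_start + 1
    reach = span - _DYAD_MARGIN_BP - params.plus_one_offset_bp
    n_dyads = int(reach // params.spacing_bp) + 1 if reach >= 0 else 0
    if n_dyads <= 0:
        return np.empty(0, dtype=np.int64)
    steps = rng.choice(
        np.array([-1, 0, 1]), size=n_dyads, p=np.asarray(params.rotational_probs)
    )
    local = (
        params.plus_one_offset_bp
        + np.arange(n_dyads) * params.spacing_bp
        + steps * params.rotational_lattice_bp
    )
    local = local[local <= span - _DYAD_MARGIN_BP]
    return (gene.tss + gene.direction * local).astype(np.int64)


def _occupancy_weights(n_dyads: int, gamma: float) -> np.ndarray:
    """Per-nucleosome occupancy, exponential 5' tilt, normalized to mean 1."""
    w = np.exp(-gamma * np.arange(n_dyads))
    return w * n_dyads / w.sum()


def simulate_fragments(
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    condition: SimulationConfig | None = None,
    sample_id: str = "sim",
) -> FragmentSet:
    """Draw MNase-like protected fragments around each ground-truth dyad.

    Per dyad, Poisson(fragments_per_nucleosome x occupancy weight) fragments
    are drawn.  Each fragment is a 147 bp core plus independent upstream and
    downstream edge extensions, giving lengths ~ Normal(frag_len_mean_bp,
    frag_len_sd_bp) clamped to [100, 250].  A positive
    digestion_asymmetry_bp further trims the downstream (transcription
    direction) edge by a Poisson-distributed amount.
    """
    if not genes:
        raise ValueError("simulate_fragments requires a non-empty gene list")
    config = config.validate()
    condition = (condition or config).validate()

    starts_all: list[np.ndarray] = []
    ends_all: list[np.ndarray] = []
    for gene in genes:
        params = _gene_params(gene, config, condition)
        gamma = _effective_occupancy(gene, config, condition)
        n_dyads = len(gene.dyads)
        if n_dyads == 0:
            continue
        counts = rng.poisson(
            config.fragments_per_nucleosome * _occupancy_weights(n_dyads, gamma)
        )
        total = int(counts.sum())
        if total == 0:
            continue
        dyads = np.repeat(gene.dyads, counts)
        ext_mean = (params.frag_len_mean_bp - NUCLEOSOME_CORE_BP) / 2.0
        ext_sd = params.frag_len_sd_bp / np.sqrt(2.0)
        half = NUCLEOSOME_CORE_BP / 2.0
        up = np.round(half + rng.normal(ext_mean, ext_sd, size=total))
        down = np.round(half + rng.normal(ext_mean, ext_sd, size=total))
        asym = params.digestion_asymmetry_bp
        if asym != 0.0:
            trim = rng.poisson(abs(asym), size=total) * np.sign(asym)
            down = down - trim
        up = np.clip(up, 50, 125).astype(np.int64)
        down = np.clip(down, 40, 125).astype(np.int64)
        if gene.strand == "+":
            starts, ends = dyads - up, dyads + down
        else:
            starts, ends = dyads - down, dyads + up
        starts_all.append(starts)
        ends_all.append(ends)

    if starts_all:
        starts = np.concatenate(starts_all)
        ends = np.concatenate(ends_all)
    else:
        starts = np.empty(0, dtype=np.int64)
        ends = np.empty(0, dtype=np.int64)
    frame = pd.DataFrame(
        {"chrom": config.chrom_name, "start": starts, "end": ends}
    ).sort_values(["start", "end"], kind="stable")
    fs = FragmentSet(sample_id, frame)
    fs.validate()
    return fs


def _effective_occupancy(
    gene: GeneModel, base: SimulationConfig, condition: SimulationConfig
) -> float:
    """Occupancy tilt for one gene; the condition delta is scaled by the
    gene's severity factor so effect sizes vary across genes."""
    if not gene.transcribed:
        return base.occupancy_5prime_weight
    delta = condition.occupancy_5prime_weight - base.occupancy_5prime_weight
    return base.occupancy_5prime_weight + gene.severity * delta


def effective_polII_scale(
    gene: GeneModel, base: SimulationConfig, condition: SimulationConfig
) -> float:
    if not gene.transcribed:
        return base.polII_5prime_scale
    delta = condition.polII_5prime_scale - base.polII_5prime_scale
    return base.polII_5prime_scale + gene.severity * delta


@dataclass
class SimulatedCondition:
    """One condition's full synthetic bundle."""

    name: str
    base_config: SimulationConfig
    config: SimulationConfig
    genes: list[GeneModel]
    fragments: FragmentSet


def simulate_condition(
    config: SimulationConfig,
    preset: str | ConditionPreset,
    seed: int,
) -> SimulatedCondition:
    """Simulate one condition; gene layout depends only on (config, seed).

    Independent RNG streams are spawned for layout, dyad offsets, and
    fragments, so all presets simulated at the same seed share an identical
    gene universe (ids, coordinates, strands, expression).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    cond_cfg = preset.apply(config)
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_layout = np.random.default_rng(streams[0])
    rng_dyads = np.random.default_rng(streams[1])
    rng_frags = np.random.default_rng(streams[2])
    genes = simulate_genes(
        config, rng_layout, condition=cond_cfg, rng_dyads=rng_dyads
    )
    fragments = simulate_fragments(
        genes, config, rng_frags, condition=cond_cfg, sample_id=preset.name
    )
    return SimulatedCondition(preset.name, config, cond_cfg, genes, fragments)


def genes_to_table(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "orf_start": g.orf_start,
                "orf_end": g.orf_end,
                "rpkm": g.rpkm,
            }
            for g in genes
        ],
        columns=GENE_COLUMNS,
    )


def dyad_table(
    genes: list[GeneModel],
    *,
    max_nuc_index: int | None = None,
    within_gene_bp: int | None = None,
    transcribed_only: bool = False,
) -> pd.DataFrame:
    """Ground-truth dyads as (chrom, position, strand, gene_id, nuc_index).

    ``max_nuc_index=0`` selects +1-nucleosome dyads only (the best-positioned
    class, standing in for a chemically mapped high-confidence dyad set);
    ``within_gene_bp`` keeps dyads within the first N bp of the gene body.
    """
    rows = []
    for g in genes:
        if transcribed_only and not g.transcribed:
            continue
        for k, pos in enumerate(g.dyads):
            if max_nuc_index is not None and k > max_nuc_index:
                break
            if within_gene_bp is not None:
                local = (pos - g.tss) * g.direction
                if local > within_gene_bp:
                    continue
            rows.append(
                {
                    "chrom": g.chrom,
                    "position": int(pos),
                    "strand": g.strand,
                    "gene_id": g.gene_id,
                    "nuc_index": k,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "position", "strand", "gene_id", "nuc_index"]
    )


def polII_bedgraph(
    genes: list[GeneModel],
    base: SimulationConfig,
    condition: SimulationConfig | None = None,
    bins_per_gene: int = 20,
) -> pd.DataFrame:
    """RNAPII coverage: per-gene piecewise-linear profile from 5' to 3'.

    WT coverage runs from 1.25x to 0.75x of the gene's expression level
    across the ORF; the condition's polII_5prime_scale (severity-scaled per
    gene) multiplies the 5' anchor, flattening / lowering the 5' end.
    """
    condition = condition or base
    rows = []
    for g in genes:
        level = g.rpkm
        if level <= 0:
            continue
        scale5 = effective_polII_scale(g, base, condition)
        f5, f3 = _POL2_F5 * scale5, _POL2_F3
        edges = np.linspace(g.orf_start, g.orf_end, bins_per_gene + 1).astype(int)
        centers = (edges[:-1] + edges[1:]) / 2.0
        frac = (centers - g.orf_start) / (g.orf_end - g.orf_start)
        if g.strand == "-":
            frac = 1.0 - frac
        vals = level * (f5 + (f3 - f5) * frac)
        for s, e, v in zip(edges[:-1], edges[1:], vals):
            if e > s:
                rows.append((g.chrom, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def simulate_dataset(
    config: SimulationConfig,
    presets: list[str | ConditionPreset],
    out_dir: str | Path,
    seed: int,
) -> dict[str, dict[str, Path]]:
    """Write one file bundle per condition preset; returns written paths.

    Per condition: fragments (BED3 and BEDPE), gene table TSV, per-gene
    counts TSV, RNAPII bedGraph, ground-truth dyads TSV, and a ground-truth
    JSON with all parameters.  Identical (config, seed) runs are
    byte-identical.
    """
    from . import io as fio

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: dict[str, dict[str, Path]] = {}
    for preset in presets:
        sim = simulate_condition(config, preset, seed)
        name = sim.name
        paths = {
            "bed": out_dir / f"{name}.fragments.bed",
            "bedpe": out_dir / f"{name}.fragments.bedpe",
            "genes": out_dir / f"{name}.genes.tsv",
            "counts": out_dir / f"{name}.counts.tsv",
            "polII": out_dir / f"{name}.polII.bedgraph",
            "dyads": out_dir / f"{name}.dyads.tsv",
            "truth": out_dir / f"{name}.truth.json",
        }
        try:
            fio.write_fragments(sim.fragments, paths["bed"], fmt="bed3")
            fio.write_fragments(sim.fragments, paths["bedpe"], fmt="bedpe")
            genes_to_table(sim.genes).to_csv(
                paths["genes"], sep="\t", index=False, float_format="%.6g"
            )
            pd.DataFrame(
                {
                    "gene_id": [g.gene_id for g in sim.genes],
                    "count": [g.count for g in sim.genes],
                }
            ).to_csv(paths["counts"], sep="\t", index=False)
            fio.write_bedgraph(
                polII_bedgraph(sim.genes, config, sim.config), paths["polII"]
            )
            dyad_table(sim.genes).to_csv(paths["dyads"], sep="\t", index=False)
            truth = {
                "preset": name,
                "seed": seed,
                "base_config": _config_json(config),
                "condition_config": _config_json(sim.config),
                "n_fragments": len(sim.fragments),
                "genes": {
                    g.gene_id: {
                        "transcribed": g.transcribed,
                        "severity": g.severity,
                        "dyads": [int(d) for d in g.dyads],
                    }
                    for g in sim.genes
                },
            }
            paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
        except OSError as exc:
            raise OSError(f"failed writing {name} bundle under {out_dir}: {exc}") from exc
        written[name] = paths
    return written


def _config_json(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def stable_seed(master_seed: int, *tokens) -> int:
    """Deterministic sub-seed derived from a master seed and string/int tokens."""
    h = zlib.crc32(repr(tokens).encode())
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)
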