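"""End-to-end WT-vs-mutant contrast: normalize, classify, profile, phase,
transform, and summarize into a machine-readable report."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, io, occupancy, phasing, pileup

logger = logging.getLogger("nucphase")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Configuration of a two-condition contrast run."""

    genes: Path
    dyads: Path
    conditions: dict  # name -> {fragments, counts, polii}
    reference: str  # condition treated as baseline (e.g. WT)
    out_dir: Path
    seed: int = 1
    min_len: int = 140
    max_len: int = 180
    subsample_range: tuple[int, int] = (20, 250)
    lag_range: tuple[int, int] = (100, 250)
    composite_window: int = 100
    rotation_angle: float = 27.0
    transform: str = "rotation"
    max_shift: int = 30
    n_bins: int = 50
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["genes"] = Path(raw["genes"])
        raw["dyads"] = Path(raw["dyads"])
        raw["out_dir"] = Path(raw["out_dir"])
        for key in ("subsample_range", "lag_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            logger.info("stage %s", name)
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    return wrap


def run_contrast(config: RunConfig) -> dict:
    """Run the full contrast between the reference condition and each other
    condition; writes intermediate TSVs and a JSON report, returns the
    report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(config.conditions)
    if config.reference not in names:
        raise StageError("setup", f"reference {config.reference!r} not in conditions")

    # --- load & normalize -------------------------------------------------
    def load():
        sets = {}
        for name, paths in config.conditions.items():
            p = Path(paths["fragments"])
            if not p.exists():
                raise FileNotFoundError(f"fragments file {p} for condition {name}")
            fmt = "bedpe" if p.suffix == ".bedpe" else "bed3"
            sets[name] = io.read_fragments(p, fmt=fmt, sample_id=name)
        return sets

    frag_sets = _stage("load_fragments")(load)

    def normalize():
        matched = io.subsample_matched(
            list(frag_sets.values()), *config.subsample_range, seed=config.seed
        )
        return {fs.sample_id: fs for fs in matched}

    frag_sets = _stage("normalize")(normalize)
    nuc_sets = {
        name: io.filter_fragment_length(fs, config.min_len, config.max_len)
        for name, fs in frag_sets.items()
    }

    genes = _stage("read_genes")(io.read_gene_table, config.genes)

    # --- classify ---------------------------------------------------------
    def classify():
        counts_path = Path(config.conditions[config.reference]["counts"])
        counts_df = pd.read_csv(counts_path, sep="\t")
        counts = dict(zip(counts_df["gene_id"], counts_df["count"]))
        lengths = dict(zip(genes["gene_id"], genes["orf_end"] - genes["orf_start"]))
        table = expression.expression_table(counts, lengths)
        table.to_csv(out / "expression.tsv", sep="\t", index=False)
        flags = dict(zip(table["gene_id"], table["transcribed"]))
        return genes.assign(transcribed=[flags.get(g, False) for g in genes["gene_id"]])

    genes = _stage("classify")(classify)
    transcribed = genes[genes["transcribed"]]
    nontranscribed = genes[~genes["transcribed"]]

    report: dict = {
        "reference": config.reference,
        "conditions": names,
        "seed": config.seed,
        "n_genes": int(len(genes)),
        "n_transcribed": int(len(transcribed)),
    }

    # --- per-gene phasing -------------------------------------------------
    def phase_all():
        tables = {}
        for name, fs in nuc_sets.items():
            tab = phasing.per_gene_phasing(
                fs, transcribed, lag_lo=config.lag_range[0], lag_hi=config.lag_range[1]
            )
            tab.to_csv(out / f"phasing.{name}.tsv", sep="\t", index=False)
            tables[name] = tab
        return tables

    phasing_tables = _stage("phasing")(phase_all)
    report["phasing"] = {}
    for name in names:
        if name == config.reference:
            continue
        report["phasing"][name] = phasing.phasing_contrast(
            phasing_tables[config.reference], phasing_tables[name]
        )

    # --- pileup / rotation / shift ----------------------------------------
    def pileup_stage():
        dyad_path = Path(config.dyads)
        if not dyad_path.exists():
            raise FileNotFoundError(f"dyad file {dyad_path}")
        dyads = pileup.read_dyads(dyad_path)
        densities = {}
        edges = {}
        for name, fs in nuc_sets.items():
            comp = pileup.dyad_composite(
                fs, dyads, w=config.composite_window,
                len_range=(config.min_len, config.max_len),
            )
            t = pileup.rotate_pileup(
                comp, angle_deg=config.rotation_angle, transform=config.transform
            )
            dens = pileup.horizontal_density(t)
            pd.DataFrame(
                {"position": dens.positions, "density": dens.values}
            ).to_csv(out / f"density.{name}.tsv", sep="\t", index=False)
            densities[name] = dens
            edges[name] = pileup.edge_profiles(
                fs, dyads, w=config.composite_window,
                len_range=(config.min_len, config.max_len),
            )
        return densities, edges

    densities, edges = _stage("pileup")(pileup_stage)
    report["density_shift"] = {}
    report["edge_shift"] = {}
    ref_edges = edges[config.reference]
    for name in names:
        if name == config.reference:
            continue
        report["density_shift"][name] = pileup.density_shift(
            densities[config.reference], densities[name], max_shift=config.max_shift
        )
        report["edge_shift"][name] = pileup.edge_shifts(ref_edges, edges[name])

    # --- metagene / CoM / correlation --------------------------------------
    def metagene_stage():
        coms = {}
        pol5 = {}
        for name, fs in nuc_sets.items():
            prof, matrix = occupancy.genebody_profile(
                fs, transcribed, n_bins=config.n_bins, group=f"{name}:transcribed"
            )
            pd.DataFrame({"bin": np.arange(config.n_bins), "mean": prof.values}).to_csv(
                out / f"metagene.{name}.tsv", sep="\t", index=False
            )
            coms[name] = occupancy.per_gene_com(matrix)
            polii_path = config.conditions[name].get("polii")
            if polii_path:
                track = io.read_bedgraph(polii_path)
                pol5[name] = occupancy.polII_5prime_mean(track, transcribed)
        return coms, pol5

    coms, pol5 = _stage("metagene")(metagene_stage)
    report["com"] = {}
    report["shift_polII_correlation"] = {}
    ref = config.reference
    for name in names:
        if name == ref:
            continue
        delta_com = coms[name] - coms[ref]
        report["com"][name] = {
            "median_reference": float(coms[ref].median()),
            "median_condition": float(coms[name].median()),
            "delta_median": float(delta_com.median()),
        }
        if name in pol5 and ref in pol5:
            delta_pol = occupancy.per_gene_change(pol5[ref], pol5[name])
            report["shift_polII_correlation"][name] = occupancy.shift_polII_correlation(
                delta_com, delta_pol
            )

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report


def setup_logging(log_path: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_path is not None:
        handlers.append(logging.FileHandler(log_path))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
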