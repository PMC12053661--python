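import dataclasses

import numpy as np
import pandas as pd
import pytest

from nucphase.simulate import (
    PRESETS,
    ConditionPreset,
    GeneModel,
    SimulationConfig,
    _draw_dyads,
    genes_to_table,
    simulate_condition,
    simulate_dataset,
    simulate_fragments,
    simulate_genes,
)
from nucphase.types import fragment_midpoints


def _single_gene(cfg, strand="+", length=2000):
    return GeneModel(
        gene_id="g0", chrom=cfg.chrom_name, strand=strand,
        tss=10000 if strand == "+" else 12000,
        orf_start=10030 if strand == "+" else 10000,
        orf_end=10030 + length if strand == "+" else 12000 - 29,
        rpkm=50.0, count=1000, transcribed=True, severity=1.0,
        dyads=np.empty(0, dtype=np.int64),
    )


class TestDyadLayout:
    def test_zero_lattice_draws_follow_the_spacing_grid(self):
        cfg = dataclasses.replace(
            SimulationConfig(), rotational_probs=(0.0, 1.0, 0.0)
        )
        gene = _single_gene(cfg)
        dyads = _draw_dyads(gene, cfg, np.random.default_rng(0))
        assert list(dyads[:3]) == [
            gene.tss + 60, gene.tss + 60 + 172, gene.tss + 60 + 344
        ]

    def test_minus_strand_dyads_run_upstream_in_coordinates(self):
        cfg = dataclasses.replace(
            SimulationConfig(), rotational_probs=(0.0, 1.0, 0.0)
        )
        gene = _single_gene(cfg, strand="-")
        dyads = _draw_dyads(gene, cfg, np.random.default_rng(0))
        assert list(dyads[:2]) == [gene.tss - 60, gene.tss - 60 - 172]

    def test_lattice_step_fraction_matches_rotational_probs(self):
        cfg = dataclasses.replace(SimulationConfig(), n_genes=200)
        genes = simulate_genes(cfg, np.random.default_rng(1))
        residues = []
        for g in genes:
            local = np.abs(g.dyads - g.tss) - cfg.plus_one_offset_bp
            k = np.round(local / cfg.spacing_bp).astype(int)
            residues.extend(local - k * cfg.spacing_bp)
        residues = np.array(residues)
        n = len(residues)
        p_plus = (residues == 10).mean()
        se = np.sqrt(0.15 * 0.85 / n)
        assert abs(p_plus - 0.15) < 3 * se

    def test_genes_do_not_overlap_and_fit_chromosome(self):
        cfg = dataclasses.replace(SimulationConfig(), n_genes=80)
        genes = simulate_genes(cfg, np.random.default_rng(2))
        spans = sorted((g.orf_start, g.orf_end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_impossible_layout_raises_sizing_error(self):
        cfg = dataclasses.replace(
            SimulationConfig(), n_genes=100, chrom_length_bp=10000
        )
        with pytest.raises(ValueError, match="impossible layout"):
            simulate_genes(cfg, np.random.default_rng(0))

    def test_transcribed_fraction_zero_means_no_transcribed_genes(self):
        cfg = dataclasses.replace(
            SimulationConfig(), n_genes=30, transcribed_fraction=0.0
        )
        genes = simulate_genes(cfg, np.random.default_rng(3))
        assert not any(g.transcribed for g in genes)
        assert all(np.log2(g.rpkm + 1) < 0.5 for g in genes)

    def test_transcribed_flags_respect_rpkm_rule(self):
        genes = simulate_genes(SimulationConfig(), np.random.default_rng(4))
        for g in genes:
            assert g.transcribed == (np.log2(g.rpkm + 1) >= 0.5)


class TestFragments:
    def test_noise_free_fragments_have_midpoint_at_dyad(self):
        cfg = dataclasses.replace(
            SimulationConfig(),
            frag_len_mean_bp=150.0, frag_len_sd_bp=0.0,
            rotational_probs=(0.0, 1.0, 0.0),
        )
        gene = _single_gene(cfg)
        gene.dyads = _draw_dyads(gene, cfg, np.random.default_rng(0))
        fs = simulate_fragments([gene], cfg, np.random.default_rng(0))
        mids = fragment_midpoints(fs.frame["start"], fs.frame["end"])
        assert set(np.unique(mids)) <= set(gene.dyads)
        assert (fs.lengths == 150).all()

    def test_total_count_is_poisson_around_expectation(self):
        cfg = dataclasses.replace(
            SimulationConfig(), fragments_per_nucleosome=20.0,
            occupancy_5prime_weight=0.0,
        )
        rng = np.random.default_rng(2)
        genes = simulate_genes(cfg, np.random.default_rng(5))
        n_dyads = sum(len(g.dyads) for g in genes)
        fs = simulate_fragments(genes, cfg, rng)
        expect = 20.0 * n_dyads
        assert abs(len(fs) - expect) < 3 * np.sqrt(expect)

    def test_digestion_asymmetry_trims_downstream_edge_only(self):
        base = dataclasses.replace(SimulationConfig(), fragments_per_nucleosome=200.0)
        asym = dataclasses.replace(base, digestion_asymmetry_bp=4.0)
        gene = _single_gene(base)
        gene.dyads = _draw_dyads(gene, base, np.random.default_rng(0))
        fs0 = simulate_fragments([gene], base, np.random.default_rng(1))
        fs1 = simulate_fragments([gene], asym, np.random.default_rng(1))
        # + strand: upstream edge = start, downstream edge = end
        def edge_means(fs):
            mids = fragment_midpoints(
                fs.frame["start"].to_numpy(), fs.frame["end"].to_numpy()
            )
            nearest = np.argmin(np.abs(gene.dyads[:, None] - mids[None, :]), axis=0)
            dyad = gene.dyads[nearest]
            return (
                (fs.frame["start"].to_numpy() - dyad).mean(),
                (fs.frame["end"].to_numpy() - dyad).mean(),
            )
        up0, down0 = edge_means(fs0)
        up1, down1 = edge_means(fs1)
        assert abs((down0 - down1) - 4.0) < 0.5
        assert abs(up0 - up1) < 0.5

    def test_fragments_stay_within_bounds_and_lengths_clamped(self, wt_small):
        fs = wt_small.fragments
        assert (fs.frame["start"] >= 0).all()
        assert (fs.lengths >= 100).all() and (fs.lengths <= 250).all()


class TestConditions:
    def test_shared_seed_gives_identical_gene_layout(self, wt_small, mut_small):
        assert genes_to_table(wt_small.genes).equals(genes_to_table(mut_small.genes))

    def test_presets_only_touch_declared_fields(self):
        base = SimulationConfig()
        for preset in PRESETS.values():
            cond = preset.apply(base)
            for field in dataclasses.fields(SimulationConfig):
                if field.name not in preset.overrides:
                    assert getattr(cond, field.name) == getattr(base, field.name)

    def test_wt_preset_is_empty_and_severity_ordering_holds(self):
        assert PRESETS["WT"].overrides == {}
        spacings = [
            PRESETS[n].apply(SimulationConfig()).spacing_bp
            for n in ("spn1-R263D-like", "spn1-F267E-like", "spt6-F249K-like")
        ]
        assert spacings == sorted(spacings) and spacings[-1] == 182

    def test_undeclared_override_rejected(self):
        bad = ConditionPreset("x", {"n_genes": 5})
        with pytest.raises(ValueError, match="undeclared"):
            bad.apply(SimulationConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            dataclasses.replace(
                SimulationConfig(), rotational_probs=(0.5, 0.4, 0.2)
            ).validate()
        with pytest.raises(ValueError, match="transcribed_fraction"):
            dataclasses.replace(SimulationConfig(), transcribed_fraction=1.2).validate()


class TestDatasetFiles:
    def test_bundle_written_and_record_counts_conserved(self, tmp_path, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_genes=50)
        written = simulate_dataset(cfg, ["WT"], tmp_path, seed=3)
        paths = written["WT"]
        assert all(p.exists() for p in paths.values())
        sim = simulate_condition(cfg, "WT", 3)
        n_lines = sum(1 for _ in open(paths["bed"]))
        assert n_lines == len(sim.fragments)

    def test_same_config_and_seed_is_byte_identical(self, tmp_path, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_genes=20)
        a = simulate_dataset(cfg, ["WT"], tmp_path / "a", seed=5)
        b = simulate_dataset(cfg, ["WT"], tmp_path / "b", seed=5)
        for key in a["WT"]:
            assert a["WT"][key].read_bytes() == b["WT"][key].read_bytes()

    def test_mutant_bundle_shares_gene_table_but_not_fragments(
        self, tmp_path, small_cfg
    ):
        cfg = dataclasses.replace(small_cfg, n_genes=20)
        w = simulate_dataset(cfg, ["WT", "spt6-F249K-like"], tmp_path, seed=5)
        assert (
            w["WT"]["genes"].read_bytes()
            == w["spt6-F249K-like"]["genes"].read_bytes()
        )
        assert (
            w["WT"]["bed"].read_bytes() != w["spt6-F249K-like"]["bed"].read_bytes()
        )
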