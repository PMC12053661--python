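# nucphase

Nucleosome-positioning analysis of paired-end MNase-seq data, built for
studying how transcription-coupled histone chaperones (the Spt6–Spn1
heterodimer in budding yeast) maintain chromatin organization over genes.

When chromatin is digested with micrococcal nuclease, the ~150 bp
fragments protected by nucleosomes report each nucleosome's position; the
fragment *midpoint* is a proxy for the dyad, the particle's symmetry
axis.  `nucphase` quantifies three things from such fragments:

- **Phasing** — the characteristic dyad-to-dyad distance along a gene,
  defined as the lag k maximizing the autocorrelation
  r(k) = Σ(s_t − s̄)(s_{t+k} − s̄) / Σ(s_t − s̄)² of the TSS-oriented
  midpoint signal s (search range 100–250 bp).  A 172 bp repeat is
  maximally self-correlated at lag 172 and anti-correlated at 86 bp.
- **Rotational positioning** — which ~10 bp helical setting a nucleosome
  occupies.  In a dyad-anchored midpoint × fragment-length composite,
  shared-edge fragments form slope ±2 diagonals spaced one helical turn
  apart; rotating each half of the plot by 27° (= round of arctan ½)
  turns these diagonals into columns, so the horizontal density reads out
  the dyad-setting distribution, and condition contrasts yield the
  lattice-step displacement.  Fragment-edge distributions discriminate a
  true rotational shift (both edges move together) from one-sided MNase
  over-digestion (one edge moves).
- **Gene-body redistribution** — metagene occupancy over the 0–1 ORF
  axis, each gene summarized by its occupancy center of mass, and the
  Spearman correlation of per-gene CoM changes against relative RNAPII
  coverage changes.

Standard upstream steps are included: BED3/BEDPE/bedGraph/TSV IO, the
inclusive 140–180 bp nucleosome-size filter, per-fragment-size matched
subsampling across samples (20–250 bp), and RPKM-based classification of
transcribed genes (log2(RPKM+1) ≥ 0.5).  A synthetic fragment generator
with wild-type and chaperone-disruption presets provides ground truth
for every estimator; see `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate matched wild-type-like and mutant-like conditions (identical
gene layouts, 200 transcribed genes) and run the headline analyses:

```python
from nucphase import (SimulationConfig, simulate_condition,
                      aggregate_profile, estimate_phasing, per_gene_phasing,
                      phasing_contrast, dyad_composite, rotate_pileup,
                      horizontal_density, density_shift, filter_fragment_length)
from nucphase.simulate import genes_to_table, dyad_table

cfg = SimulationConfig()                      # 250 genes, 200 transcribed
wt  = simulate_condition(cfg, "WT", seed=1)
mut = simulate_condition(cfg, "spt6-F249K-like", seed=1)
genes = genes_to_table(wt.genes)
transcribed = genes[[g.transcribed for g in wt.genes]]

agg = aggregate_profile(wt.fragments, transcribed, 0, 1499)
est = estimate_phasing(agg, 100, 250)
print(f"WT aggregate phasing: {est.phasing_bp} bp (ACF {est.acf_at_max:.2f})")

contrast = phasing_contrast(per_gene_phasing(wt.fragments, transcribed),
                            per_gene_phasing(mut.fragments, transcribed))
print(f"median phasing WT {contrast['median_a']:.0f} bp -> "
      f"mutant {contrast['median_b']:.0f} bp "
      f"(delta {contrast['delta_median']:+.0f} bp, p={contrast['rank_sum_p']:.1e})")

anchors = dyad_table(wt.genes, max_nuc_index=0, transcribed_only=True)
dens = {}
for sim in (wt, mut):
    nuc = filter_fragment_length(sim.fragments, 140, 180)
    comp = dyad_composite(nuc, anchors, w=100, len_range=(140, 180))
    dens[sim.name] = horizontal_density(rotate_pileup(comp, angle_deg=27.0))
print(f"rotational dyad shift: {density_shift(dens['WT'], dens['spt6-F249K-like']):+d} bp")
```

Output:

```
WT aggregate phasing: 172 bp (ACF 0.85)
median phasing WT 172 bp -> mutant 182 bp (delta +10 bp, p=2.3e-62)
rotational dyad shift: +9 bp
```

The wild-type condition recovers its configured 172 bp repeat; the
mutant condition lengthens phasing by 10 bp on the same genes, and its
dyad-setting distribution sits one helical turn downstream of the
wild-type reference dyads (the cross-correlation reads 9 bp because a
quarter of the mutant's rotational mass remains at the central setting;
the lattice-step decomposition of the edge profiles, `edge_shifts`,
reports the modal 10 bp step for both fragment edges).

The same contrast runs end-to-end from the shell:

```sh
nucphase simulate --preset WT --preset spt6-F249K-like --out sim/ --seed 1
nucphase run --config run.yaml        # normalize -> classify -> phase ->
                                      # pileup/shift -> metagene/correlation
```

writing per-stage TSVs and a `report.json` with the phasing contrast,
density shift, edge shifts, CoM deltas, and the CoM-vs-RNAPII Spearman
correlation.

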