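# Methods

`nucphase` analyzes paired-end MNase-seq protected fragments to quantify
three aspects of nucleosome organization over genes: *phasing* (the
characteristic dyad-to-dyad distance), *rotational positioning* (which
~10 bp helical setting a nucleosome occupies), and the *gene-body
distribution* of occupancy, together with its relation to RNAPII
coverage.  A synthetic fragment generator with full ground truth makes
every stage testable without sequencing data.

## Fragment handling and normalization

Fragments are 0-based half-open intervals (BED); BEDPE mate pairs are
collapsed to their outer span.  The fragment midpoint, used throughout as
a proxy for dyad density, is `floor((start + end) / 2)` — for even-length
fragments the true center falls between two bases and the left one is
taken.  This single convention is shared by the simulator and all
analysis modules; its one visible consequence is that exact strand-mirror
symmetry holds only for odd-length fragments (even lengths carry a
half-bp ambiguity), which is how the symmetry property is tested.

Nucleosome-sized fragments are selected with an inclusive length filter,
140 ≤ L ≤ 180 bp.  To compare libraries of different depth and digestion
extent, samples are subsampled to matched per-fragment-size depth: for
every length in 20–250 bp the smallest count across samples becomes the
common depth, drawn uniformly without replacement.  The RNG stream for
each (sample, length) pair is derived from the master seed and the sample
id, so results are independent of sample order.

Genes are called transcribed when log2(RPKM + 1) ≥ 0.5 (boundary
inclusive), with RPKM = count / (length/1000) / (library/10^6) and the
library size defaulting to the sum of supplied counts.

## Phasing by ACF maximization

The per-gene (or aggregate) midpoint signal is a per-bp count vector read
5'→3' from the TSS.  Its normalized autocorrelation uses the biased
estimator with the full-series mean:

    r(k) = Σ_t (s_t − s̄)(s_{t+k} − s̄) / Σ_t (s_t − s̄)²

A signal with dyads every 172 bp is maximally self-correlated at lag
172 and anti-correlated at 86 bp.  Phasing is the ACF-maximizing lag over
a search range of 100–250 bp (brackets the yeast repeat length and ±
plausible changes; ties resolve to the smallest lag).  Per gene, the
signal runs from the TSS to TSS + 1500 bp truncated at the gene end
(at least 600 bp, i.e. ≥3 nucleosomes, is required), and is smoothed
with a Gaussian of σ = 10 bp before the ACF because per-bp midpoint
counts are sparse at realistic depth; aggregate estimates are insensitive
to this smoothing.  Genes with fewer than 50 in-region fragments or a
flat signal are flagged `qc_pass = False` rather than estimated.
Condition contrasts report medians over qc-passing genes and a two-sided
Wilcoxon rank-sum p-value.

## The rotated dyad pile-up

In a dyad-anchored plot of midpoint position (x) versus fragment length
(y), fragments sharing one protected edge fall on diagonals of slope
±2 (extending the free edge by 1 bp moves the midpoint by 1/2 bp).
Alternative rotational dyad settings produce parallel diagonals one
helical turn apart.  `rotate_pileup` rotates points with x < 0 clockwise
and points with x ≥ 0 counterclockwise by 27° — the integer-degree
rounding of arctan(1/2) = 26.57°, the angle that exactly verticalizes
slope-2 diagonals — about (position 0, reference length 160 bp, the
center of the 140–180 band).  Points are re-binned at the nearest
integer, so counts stay integral and total signal is conserved exactly.
Two conventions deserve note:

- assignment to a rotation half follows the *original* sign of x, so
  every count is transformed exactly once;
- by default the transformed horizontal coordinate is divided by
  cos 27°, so one column step corresponds to one bp of dyad
  displacement (otherwise a 10 bp lattice step would read as ~8.9 bp).
  A shear transform (`transform="shear"`, x' = x ∓ y/2), which
  verticalizes the diagonals without rescaling, is also provided.

Column sums of the transformed matrix, normalized to unit area, give the
horizontal density; the displacement between two conditions' densities is
the integer argmax of their mean-centered cross-correlation (ties toward
the smallest magnitude, then positive).

## Edge analysis and lattice-step displacement

A downstream shift of the dyad distribution could alternatively be
produced by asymmetric MNase sensitivity at one nucleosome edge.  The
two hypotheses separate in the edge distributions: a rotational shift
moves *both* the upstream and downstream fragment-edge distributions by
the same amount, whereas one-sided over-digestion moves only one.  Edge
positions are recorded at the first and last protected base (end − 1 for
the downstream edge, honoring half-open coordinates), oriented by
transcription.

Because per-edge digestion noise (sd ≈ 5–6 bp) is comparable to the
10 bp lattice, neighboring rotational settings overlap strongly in the
edge histograms; a plain cross-correlation argmax is then biased below
the modal displacement, and the raw histogram mode is unstable.
`lattice_step_shift` instead exploits the fact that rotational
displacement is quantized: the condition's edge distribution is
decomposed by non-negative least squares onto copies of the reference
distribution shifted by whole lattice steps, and the displacement of the
dominant component is reported.  The cross-correlation estimator remains
available (`method="xcorr"`).

## Gene-body occupancy and RNAPII

Each ORF is rescaled to a common 0–1 axis (5'→3'), split into 50 bins,
and summarized per gene as a density per bp (length normalization keeps
long genes from dominating); group profiles are means of per-gene rows.
Genes shorter than 500 bp are excluded.  The per-gene center of mass
(CoM) on [0, 1] summarizes where occupancy sits; a 5'-ward
redistribution lowers it.  RNAPII coverage is summarized per gene as the
mean over the 5' half of the ORF, and condition changes are expressed as
*relative* changes ((cond − ref)/ref) so that the per-gene comparison is
not dominated by absolute expression level.  The association between
nucleosome 5'-shifting and RNAPII change is the Spearman rank correlation
of per-gene ΔCoM against per-gene relative ΔRNAPII (two-sided).

## The synthetic data generator

The generator emulates budding-yeast gene chromatin: non-overlapping
genes on both strands (lengths lognormal, median ~1.4 kb, clamped to
0.7–4 kb; 300 bp intergenic gaps; 140 bp promoter NDR), a +1 nucleosome
dyad 60 bp downstream of the TSS, and a phased dyad array

    dyad_k = tss + 60 + k·spacing + lattice·r_k        (oriented)

with spacing 172 bp in the wild-type-like condition, a 10 bp rotational
lattice, and per-nucleosome setting r_k drawn i.i.d. from
`rotational_probs` over {−1, 0, +1} (WT: 0.15 / 0.70 / 0.15).  Modeling
rotational settings as displacements from the spacing grid (rather than
as increments accumulated along the array) keeps the composite
displacement of each nucleosome bounded at one lattice step — the
behavior the dyad-anchored composites show — while a spacing change
still moves the ACF periodicity.

Fragments are a 147 bp core plus independent upstream/downstream edge
extensions, so lengths are Normal(157, 8) clamped to [100, 250] while
midpoints scatter around the dyad along the slope-±2 diagonals that the
pile-up transform is designed for.  Per dyad, Poisson(50 × w_k)
fragments are drawn, with occupancy weights w_k ∝ exp(−γ·k) normalized
to mean 1 per gene (γ = 0.10 in WT: a mild, realistic 5' enrichment).
Optional asymmetric digestion trims the downstream edge by a
Poisson-distributed amount.  80% of genes are transcribed; RNA-seq
counts share a 5×10^6-read library by lognormal weights (non-transcribed
genes get 0–1 stray reads, keeping them strictly below the
classification threshold), and RNAPII coverage is a per-gene
piecewise-linear profile running from 1.25× to 0.75× of the expression
level across the ORF.

Condition presets model Spt6–Spn1 disruption with the severity ordering
spt6-F249K > spn1-F267E > spn1-R263D: the strongest preset sets spacing
to 182 bp, moves rotational mass to the +1 setting (0.05 / 0.25 / 0.70),
raises the occupancy tilt to γ = 0.35 and scales the RNAPII 5' anchor by
0.55; the weaker alleles interpolate these deltas at 2/3 and 1/3.  All
condition effects apply to transcribed genes only — non-transcribed
genes always follow baseline parameters — and the occupancy/RNAPII
deltas are additionally scaled by a per-gene severity factor
(uniform 0.3–1) so that per-gene effect sizes vary and the
CoM-vs-RNAPII correlation is non-degenerate.  The phasing and rotational
deltas are uniform across genes.  Conditions simulated from the same
seed share an identical gene universe (independent RNG streams for
layout, dyad settings, and fragments), so contrasts are matched by
construction.

A "high-confidence" dyad set, standing in for a chemically mapped
reference, is taken as the +1-nucleosome ground-truth dyads of the
wild-type condition — the best-positioned nucleosome class, and the set
on which each nucleosome's displacement is bounded at one lattice step.

What the generator does *not* model: DNA sequence (A/T dinucleotide
content, promoter motifs), MNase sequence bias, replication-dependent
deposition, inter-nucleosome steric coupling, linker histones, and real
gene-expression structure.  Passing tests therefore demonstrate that the
estimators recover known parameters under a faithful statistical
caricature of the assay, not that they are robust to every bias of real
chromatin data.

## Problem sizes and numerical choices

The default simulation uses 250 genes (200 transcribed) at 50 fragments
per nucleosome (~10^5 fragments per condition), which the test suite
uses throughout; the acceptance script simulates 2500 genes so that the
composite anchor set contains 2000 high-confidence dyads, the scale of
the chemically mapped reference set.  Degenerate inputs are errors, not
silent results: zero-variance signals for the ACF and shift detectors,
all-zero profiles for the CoM (NaN, flagged), empty dyad sets, fewer
than two points for the kernel density.  Ties everywhere resolve
deterministically (smallest lag, smallest |shift| then positive,
lexicographic gene order).  All randomness flows from explicit seeds via
independent spawned streams; identical (config, seed) runs are
byte-identical on disk.

## Known limitations

- The cross-correlation displacement of the transformed pile-up
  densities under the strongest preset measures 9 bp for a 10 bp modal
  lattice shift: the rotational mass remaining at the central setting
  pulls the continuous cross-correlation peak about one bp below the
  lattice step.  The lattice-step decomposition does not have this bias
  and is used for edge displacements.
- Replicate handling is out of scope: inputs are assumed to be merged
  libraries, and spike-in scaling of ChIP coverage is assumed applied
  upstream.
- Per-gene phasing at realistic depth depends on the σ = 10 bp
  pre-smoothing; gene-level estimates for sparse genes should be read
  through their `qc_pass`/`acf_at_max` columns.
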