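# leachresp

Marine bacteria can grow on — and degrade — the chemical leachates that
plastic debris releases into seawater. Identifying *which* taxa respond
takes two measurement chains: single-cell activity from micrographs
(BONCAT click-labelling of newly synthesised protein, combined with
CARD-FISH probes for taxonomic groups, counterstained with DAPI), and
16S rRNA gene amplicon sequencing of the incubated communities.
`leachresp` implements both chains as a tested pipeline for a
six-treatment incubation design — three plastic conditions (no-plastic
control, virgin LDPE leachate, aged beach-plastic leachate) crossed
with two leaching light regimes (solar-irradiated vs dark), in
triplicate, seeded 9:1 with coastal seawater — plus a synthetic-data
generator that emulates the design so every stage is testable without
any external download.

## What it computes

**Single-cell activity** (`leachresp.image_quant`). Cells are segmented
on the DAPI channel (Otsu threshold, 8-connected components, minimum
area); a cell's mean grey value is MGV = Σ pixel grey values / pixel
count. A cell is BONCAT+ only if it is DAPI+ and its BONCAT MGV exceeds
a background-statistics threshold (background mean + k·SD, k = 3). Per
sample, total activity = Σ BONCAT MGV of BONCAT+ cells / number of
fields of view, and a probe-targeted group's contribution to activity
is Σ MGV(BONCAT) over probe+ ∧ BONCAT+ cells / Σ MGV(BONCAT) over all
BONCAT+ cells. Nested probes (Alteromonadales ⊂ Gammaproteobacteria,
*Roseobacter* ⊂ Alphaproteobacteria) are resolved by subtraction into
exclusive displayed categories that sum to 1.

**Amplicon post-processing** (`leachresp.amplicon`). ASV read counts
are divided by the mean 16S rRNA gene copy number of the lowest
available taxonomic rank among genus/family/order (class-or-above
resolution stays uncorrected) and re-closed to relative abundances.
Alpha diversity uses repeated rarefaction to the minimum depth (100
draws, cell-wise means rounded to integers): richness nASV, Shannon
H = −Σ pᵢ ln pᵢ, Pielou J = H / ln(nASV).

**Responder clustering** (`leachresp.clustering`). ASVs above 1 %
relative abundance in ≥ 1 sample are centred-log-ratio transformed
(clrᵢ = ln((xᵢ+δ)/g(x+δ))) and hierarchically clustered by Euclidean
distance between their across-sample profiles; the tree is cut at
k = 7 response patterns. Cluster proportions × flow-cytometry totals
give absolute cells mL⁻¹.

**Statistics** (`leachresp.stats_core`). Self-implemented and
oracle-tested: Kruskal–Wallis (mid-ranks, tie correction) with Dunn
post hoc pairs (Holm-adjusted), permutation Spearman, Bray–Curtis, and
a sequential (Type I) two-factor PERMANOVA with interaction
(Gower-centred distance matrix, hat-matrix traces, free label
permutation; verified against vegan's `adonis2`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate_experiment.py`, then 02…06). Outputs
land in `results/`; micrographs and the bulky per-cell table in
`scratch/`. A complete run prints, among other lines:

```
experiment: 175 ASVs x 19 samples -> data/experiment
BONCAT+ cells per FOV: aged 82 vs control 21 (4.0x)
Alteromonadales at t4: mean activity-abundance deviation -0.23
richness ~ protein-like DOM proportion: Spearman rho=0.90 p=0.0001
PERMANOVA plastic: R2=52% p=0.000999
PERMANOVA light: R2=19% p=0.000999
52 abundant ASVs in 7 clusters; silhouette peaks at k=6
adjusted Rand index vs planted patterns: 0.98
total cells (1e6/mL) by treatment: ... aged:irradiated 12.3 ... control:irradiated 3.1
```

Reading: the aged-plastic leachate carries ~4× the control's active
(BONCAT+) cell density; the Alteromonadales-like early responders are
abundant but inactivated by day 4 (they plot below the 1:1
abundance-vs-activity line); plastic type explains the largest share
of community variance; and the CLR/Euclidean tree recovers the planted
responder patterns almost exactly (adjusted Rand index 0.98 against
the generator's manifest).

The same pipeline is scriptable end-to-end from a YAML config:

```
leachresp simulate-asv --seed 2 --out data/exp2
leachresp run-all --config config.yaml
```

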