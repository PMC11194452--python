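# Methods

This note records the models, parameter choices and numerical
conventions behind `leachresp`, and what the synthetic-data tests do
and do not establish about real data.

## Single-cell activity model

A field of view (FOV) is imaged three times on the same filter
section: DAPI (all cells), BONCAT (fluorescence from click-labelled
newly synthesised protein; intensity taken proportional to
translational activity), and one CARD-FISH probe. Because each probe is
hybridised on its own filter section, probes observe independent FOV
sets of the same community; group categories that overlap (a nested
probe inside a broader one) are resolved by subtraction afterwards,
never within one image.

Segmentation is deliberately simple: global Otsu threshold on DAPI,
8-connected components, minimum area 5 px (default). Touching-cell
splitting is out of scope; on crowded filters the pipeline will
under-count cells and slightly over-estimate per-cell areas — a known
limitation, acceptable at the cell densities the incubation design
produces (tens of cells per field).

Positivity gating uses background statistics because no absolute
threshold generalises across exposure settings: a cell is BONCAT+
(probe+) if its mean grey value in that channel exceeds the mean + k·SD
of the non-cell pixels, k = 3 by default. The BONCAT mean grey value is
not background-subtracted by default (a flag exists); activity ratios
between groups are therefore ratios of absolute in-cell grey values.

Derived categories (e.g. "other Gammaproteobacteria" = broad-probe
fraction − nested-probe fraction) can come out slightly negative from
section-to-section sampling noise; they are clipped to zero, logged,
and the category set is re-closed so displayed contributions sum to
exactly 1.

## Amplicon processing

Copy-number correction divides each ASV's reads by the mean 16S rRNA
gene copy number looked up at the lowest available rank on the ladder
species → genus → family → order (species entries are resolved through
their genus). ASVs classified only to class or above are left
uncorrected: coarse-rank copy-number predictions are unreliable enough
that correcting with them would add bias rather than remove it. A miss
at every eligible rank falls back to no correction, with a log line per
ASV. Columns are re-closed to sum 1 after weighting.

Rarefaction subsamples without replacement (multivariate
hypergeometric) to the minimum sample depth, repeats 100 times, and
averages cell-wise, rounding half-away-from-zero to integers. After
rounding, a column may miss the exact depth by the rounding residue;
this is tolerated and documented rather than re-balanced. Alpha
diversity (richness, Shannon H with natural log, Pielou J = H/ln nASV)
is computed on the raw rarefied counts, *not* on copy-number-corrected
values; composition figures, the 1 % abundance screen and the
clustering all use corrected relative abundances. Evenness is undefined
(flagged NaN, never 0) for samples with fewer than two taxa.

## Responder clustering

ASVs above 1 % relative abundance in at least one sample (strict
inequality) are CLR-transformed with pseudocount δ = half the smallest
nonzero relative abundance, then clustered by agglomerative
hierarchical clustering (complete linkage by default; ward and average
selectable) on Euclidean distances between ASV rows, cutting at k = 7.
k is a config parameter; since the original cut was chosen by visual
inspection of a heatmap, the pipeline also reports the mean silhouette
across k = 2–12 as a quantitative proxy. Rows are sorted by ASV id
before linkage so the output is order-deterministic. Cluster labels are
arbitrary; all scoring is label-permutation-invariant (adjusted Rand
index).

Absolute scaling multiplies each cluster's summed proportion (including
an "other (rare)" pool for screened-out ASVs) by the sample's
flow-cytometry total, conserving the total exactly per sample before
replicate averaging.

## Statistics

All test statistics are implemented from their defining formulas
(mid-ranks and tie corrections throughout); scipy supplies only
distribution functions and rank assignment. Permutation p-values use
the add-one estimator (1 + #{≥ observed})/(1 + n_perm), so p ∈
[1/(n_perm+1), 1] and a fixed seed reproduces the value exactly.

PERMANOVA partitions the Gower-centred matrix of squared Bray–Curtis
dissimilarities sequentially (Type I) over plastic, light,
plastic:light, using hat-matrix trace increments; pseudo-F uses the
full-model residual mean square; significance comes from unrestricted
permutation of sample labels (1000 by default). The projector is built
by SVD, which keeps the partition exact for rank-deficient dummy
designs. The dissimilarity, the transformation state of the input, and
the permutation scheme are genuinely open choices (the source analysis
does not state them); the defaults — Bray–Curtis on
copy-number-corrected relative abundances, free permutations — follow
the dominant convention in community ecology and are configurable.
Dunn post hoc p-values default to Holm adjustment, with raw p also
reported; Spearman's p is computed by permutation rather than the
t-approximation because the design yields only 6–18 paired values.

## Synthetic data: what it emulates and what it does not

The micrograph generator renders cells as hard disks (radius 2–4 px)
over a uniform background (level 20 of 255) with i.i.d. Gaussian noise
(SD 2 by default), no point-spread blur (optional flag) and no
illumination gradients. DAPI marks every cell; BONCAT sets the in-cell
grey value to the cell's activity level; the FISH channel lights the
cells whose group a probe targets, with a configurable per-probe
hybridisation sensitivity to mimic probes that miss part of their
target group. Group counts per FOV use largest-remainder rounding of
the planted fractions by default, so planted proportions are exact per
field. Treatment-calibrated scenarios scale cells-per-FOV with the
measured end-point flow-cytometry totals (aged ≈ 4.4× control) and, at
day 4, mark the Alteromonadales-like early responders as largely
inactivated (active fraction 0.2 vs 0.9 at day 1).

The sequencing generator plants eight response archetypes — generalists
(12 ASVs), non-irradiated-preferring (8), irradiated-aged responders
(8), an irradiated-aged-specific *Pseudoalteromonas*-like group (7),
irradiated-LDPE responders (4), non-irradiated-aged responders (8),
inoculum-only oligotrophs (8) that collapse after the 9:1 dilution, and
a flat 120-ASV rare tail kept below the 1 % screen. Within a responder
cluster, weight falls on a geometric ladder (ratio 0.9, lognormal
jitter σ = 0.12), echoing the dominance of a few lead responders while
keeping within-cluster CLR level offsets smaller than between-pattern
contrasts. Non-preferred treatments carry effectively zero expectation
(expected count ≪ 1 read) rather than trace amounts: partial presence
near one expected read would put member ASVs on the pseudocount
boundary of the CLR, where the zero/one-read flicker adds more row
noise than the biological signal — the white blocks of a responder
heatmap correspond to genuine absence, and the generator follows that.

Replicate noise is a compound multinomial: each taxon's expected share
is perturbed by an independent gamma factor with mean 1 and CV 20 %
(default), re-closed, then read counts are drawn multinomially at a
per-sample depth uniform on [4436, 8000]. A shared-concentration
Dirichlet-multinomial was rejected because it ties dispersion to
abundance — at a concentration giving 20 % CV for abundant responders
it gives rare taxa ~90 % CV, which both misstates replicate behaviour
of a planted rare tail and randomly pushes rare ASVs over the abundance
screen. Flow totals and DOC/FDOM covariates are fixed at the measured
treatment values (mean ± SD for totals), e.g. aged-irradiated
13.4×10⁶ cells mL⁻¹ vs control-irradiated 3.06×10⁶.

Passing tests on these synthetics establishes that the *computational
chain* is correct (exact arithmetic, conservation, calibration,
recovery of planted structure). They do not establish robustness to
features the generator omits: cell crowding and irregular morphology,
uneven illumination, autofluorescence, chimeric or contaminant ASVs,
compositional covariance between taxa, or depth-dependent taxon
dropout.

## Problem sizes and numerical conventions

Default analysis sizes — 175 ASVs × 19 samples, 2 FOVs per probe per
treatment at 256×256 px, 100 rarefaction draws, 1000 permutations —
keep a full run in the tens of seconds while leaving every estimate's
Monte-Carlo error well inside the tolerances asserted in the tests
(e.g. null rejection rates are checked within three binomial standard
errors at 500 simulations). Ties use mid-ranks everywhere;
equal-statistic permutation comparisons use a 1e-12 slack so exact ties
count as extreme; all generators and tests derive their randomness from
explicit seeds.
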