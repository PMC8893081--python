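# Methods

`nilgenetics` implements the quantitative-genetics analysis chain of a
three-locus near-isogenic-line (NIL) study in rapeseed: multi-environment
BLUE estimation, an exact additive–dominance–epistasis decomposition of
genotype means, mid-parent heterosis, LSD multiple comparisons, a
sliding-window recurrent-parent genome-recovery analysis, and a
bulked-segregant marker screen with a single-marker QTL scan. A synthetic
data module generates every input with known ground truth so the whole
chain is exercisable and testable without any external download.

## The three-locus genotype space

Each line carries one of three states at each of the loci *BnFLC.A2*,
*BnFLC.C2*, *BnFLC.A3b*: `0` (homozygous early-flowering/mutated allele),
`1` (homozygous late-flowering/wild-type allele), or `2` (heterozygous).
Genotype IDs end in the three digits in this fixed locus order
(`ID01-000` … `ID08-111` for the 8 homozygotes, `ID09-020` … `ID27-121`
for the 19 hybrids). The digit semantics are functional, not
parental-origin based: `1` always denotes the late-flowering allele,
even though the wild-type *BnFLC.A3b* allele descends from the donor
parent while the wild-type *A2*/*C2* alleles descend from the recurrent
parent. `cross()` derives F1 genotypes from inbred parents only; the F1 of
a heterozygous parent is not a single genotype and is rejected.

## Effect decomposition (F∞ metric)

Per locus the model uses the homozygote-midpoint (F∞) coding
`x_a = −1/+1/0` and `x_d = 0/0/1` for states `0/1/2`, so the additive
effect `a` is half the difference between homozygotes and the dominance
effect `d` is the heterozygote's deviation from the homozygote midpoint —
the parameterisation that matches the mid-parent framing of heterosis.
The saturated three-locus design has 27 columns: `m`, three `a`, three
`d`, and all products (`aa`×3, `ad`×6, `dd`×3, `aaa`, `aad`×3, `add`×3,
`ddd`). With all 27 genotypes the design matrix is square with
|det| = 2²⁷, so effects are obtained by one exact linear solve — the
system is exactly identified and least squares would add nothing. The
8-genotype homozygous subsystem is a ±1 Hadamard-type matrix
(HᵀH = 8 I), solved the same way; its solution equals `Hᵀy/8`.

An orthogonal-contrast (F2-metric) coding (`x_d = −½/−½/+½`) is available
through the `metric` switch, because published effect tables do not
always state which metric they used and interaction terms differ by known
scale factors between the two. The default is F∞.

A subtlety worth recording: zero dominance does **not** imply zero
mid-parent heterosis when additive×additive epistasis is present. A
double heterozygote's F1 loses the `aa` term its two parents share, so
F1 − MP = −aa under this coding. The tests assert the correct
statements (dominance components vanish under dominance-free truth; MPH
vanishes under purely additive truth).

## Multi-environment BLUEs

The trial model treats genotypes as fixed and environment, plot within
environment, and plant within plot (residual) as random:

    y = X·g + Z_env·u_env + Z_plot·u_plot + e .

Flowering time is a plot-level trait (scored when half the plants of a
plot have flowered), so its model omits the plant term and its residual
*is* the plot-to-plot variance; the package reports it as `sigma2_plot`
with `sigma2_resid = 0` for such traits. All other traits are
plant-level.

Variance components are estimated by REML. The restricted likelihood is
profiled over the residual variance and evaluated through Henderson's
mixed-model equations — one Cholesky factorisation of the (p+q)
coefficient matrix per evaluation — and the variance ratios
γ_k = σ²_k/σ²_e are maximised on the log scale with Nelder–Mead, which
keeps every component non-negative by construction. This direct
maximisation was chosen over EM iteration because EM needs the full MME
inverse per step and converges slowly near the zero boundary, while the
profiled criterion handles a 4,000-observation trial fit in well under a
second. γ is capped at e¹⁴ (≈10⁶): the cap bounds the condition number of
the mixed-model equations so GLS estimates stay accurate to ~1e-9 even on
noiseless degenerate data, while real designs sit orders of magnitude
below it. The engine is cross-checked against `statsmodels` `MixedLM` in
the test suite (agreement to ~0.1% on variance components, ~1e-5 on fixed
effects, limited by the comparator's own convergence tolerance).

For perfectly balanced data the GLS genotype estimates coincide exactly
with two-stage means (mean of environment means); the suite asserts this
identity to 1e-8.

Broad-sense heritability uses the entry-mean basis

    H² = σ²_g / (σ²_g + σ²_plot/n_env + σ²_resid/(n_env·n_reps)),

clipped to [0,1], with σ²_g from a companion fit in which genotype is
random (intercept fixed). The environment main effect does not enter: it
shifts all genotypes equally and cancels from genotype contrasts.

## LSD letters and correlations

Fisher's LSD for two means is `t(1−α/2, df)·√(2·MSE/n)` (α = 0.05
default). Letters are assigned by covering the ascending-sorted means
with maximal runs of mutual non-significance; the smallest mean carries
"a", matching field-trial table convention, and ties break by genotype
ID. For one-dimensional means this construction makes "share a letter"
exactly equivalent to "differ by less than the LSD", which the suite
verifies against a brute-force pairwise oracle. Pearson correlations
between traits are computed across genotype BLUEs; zero-variance traits
yield NaN entries plus a warning, never a silent 0.

## Genome recovery

Effective SNPs are sites where both parents are homozygous for different
alleles. The offspring is scored 0 (matches recurrent parent), 1
(heterozygous) or 2 (matches donor); missing calls are dropped before
windowing, so windows run over consecutive *retained* SNPs. Windows of 15
SNPs advancing 1 SNP at a time are recovered when their score sum is
strictly below 8; an all-heterozygous window (sum 15) is therefore not
recovered — heterozygous genome is not recurrent-parent genome. The
threshold, window and step are configurable.

Recovered windows' SNP spans merge into recovery regions. Region extent
is the outermost SNP positions of the contributing windows — no
extrapolation past flanking SNPs and no between-SNP midpoint breakpoints —
a conservative, reproducible choice. Runs of recovered windows separated
by a non-recovered window still merge when their spans overlap
positionally, which keeps regions non-overlapping while the total
recovered length equals a per-base oracle (every base covered by ≥1
recovered window); the suite checks this equality exhaustively on random
score vectors. Chromosomes with fewer than 15 effective SNPs are
unassessed and contribute zero recovered length. The recovery rate is
total recovered length over the reference genome length; note that with
this definition even a fully recurrent line scores below 1 by the
uncovered chromosome ends beyond the outermost SNPs. Coordinates are
1-based inclusive internally; BED output is 0-based half-open.

## BSA and single-marker scan

Bulks are the k most extreme individuals per phenotypic tail (k = 12
default, ties by ID). A marker co-segregates when at most `max_mismatch`
typed alleles deviate from "all A in one bulk, all B in the other" in
either orientation; missing calls never count as mismatches. Under a null
of marker–bulk independence the per-marker pass probability at k = 12 is
2·2⁻²⁴ ≈ 1.2×10⁻⁷, so 10⁵ null markers are expected to yield zero hits.

The QTL scan is deliberately a single-marker one-way analysis — not
interval mapping: per marker, PVE = 100·SS_between/SS_total (equal to the
squared point-biserial correlation ×100) and
LOD = −(n/2)·log₁₀(1 − SS_between/SS_total), with the usual F test.
Heterozygous calls in doubled haploids are genotyping errors and are
dropped with a warning; markers monomorphic or with an allele class
smaller than 3 are skipped.

## Synthetic data

* **Trials**: genotype-class means are `design_row(g)·truth`; each
  environment draws one common effect, each plot one effect, each plant
  one residual, all Gaussian. Defaults are three environments
  (two winter, one spring), five plots of ten plants, and variance
  components σ²_env = 4, σ²_plot = 1, σ²_resid = 4 (trait units² —
  realistic for a gram-scale yield trait). The packaged reference truth
  for plant yield is a = (1.446, 1.365, 1.361) g,
  d = (3.504, 2.991, 3.284) g, ddd = 4.393 g around m = 20 g.
* **Backcross genomes**: donor segments (homozygous or heterozygous) are
  planted directly on a recurrent background rather than simulating
  generations of meiosis — the recovery algorithm only ever sees the
  mosaic, so this is sufficient and exactly controllable, and the exact
  planted recurrent fraction is returned. Parents are fixed for opposite
  alleles at every SNP; an optional error rate flips child calls.
* **DH populations**: each individual is one recombinant gamete doubled,
  with recombination between adjacent loci at the Haldane probability
  r = (1 − e^(−2d/100))/2. QTL are inserted into the recombination walk at
  their map positions and hidden from the marker frame; with ±1 coding a
  QTL of effect β explains β²/(β²+σ²) of the variance, which
  `qtl_effect_for_pve` inverts.

All generators are deterministic given parameters and seed; seeds are
explicit arguments, never global state.

What the generators do *not* emulate: genotype×environment interaction,
non-Gaussian or heteroscedastic trait noise, field spatial trends,
segregation distortion, linkage between the three NIL loci, and selection
during backcrossing. Passing tests therefore demonstrate correctness of
the algorithms under the stated models, not robustness to those
real-data complications.

## Validation sizes and numerical choices

The validation suite and `scripts/acceptance.py` use: 1,000 random effect
vectors for the solver round trip (max error ~1e-13); 100 replicate
trials of 4,050 plant observations each for pipeline parameter recovery
(every component within 3 Monte-Carlo SEs of truth); 500 random score
vectors against the per-base recovery oracle plus planted fractions
0.90–0.98 on three 2-Mb chromosomes at 0.005 SNPs/bp (rate within 0.01 of
truth); 10,000 sampled 15-score compositions at sums 7/8 for the strict
threshold boundary; 10⁵ null markers for the bulk screen; and a
352-individual DH population with 2,000 loosely linked markers for scan
calibration (type-I error 0.05 ± 0.01) plus 20 replicates of a planted
7.6%-PVE QTL. These sizes were chosen to make Monte-Carlo error small
relative to each tolerance while keeping a desk-scale run.

Degenerate inputs are handled explicitly: noiseless trials (variance
ratios hit the γ cap, estimates stay exact), all-equal phenotypes in bulk
selection (deterministic ID split, flagged degenerate), zero-variance
traits in correlations (NaN + warning), monomorphic markers (skipped),
chromosomes shorter than one window (unassessed).

## Known limitations

* The mixed model fits environment as a random main effect without G×E
  interaction terms; with only three environments σ²_env is weakly
  estimated (this does not affect genotype contrasts, which are free of
  the environment main effect).
* The published heritability and effect values were computed from
  per-genotype BLUE tables released only as journal supplementary
  material; without them the package validates against planted synthetic
  truth rather than the original data, and the original study's exact
  mixed-model specification (software defaults included) is not known.
* Recovery-region extent is defined by outermost SNP positions; analyses
  that extrapolate regions to chromosome ends or between-SNP midpoints
  will report slightly higher rates on the same calls.
* The scan is single-marker; closely linked markers are not conditioned
  on one another and PVE at non-causal linked markers is attenuated, not
  decomposed.
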