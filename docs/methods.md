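# Methods

This note documents the models and procedures `cnvhic` implements, the
generative model behind the synthetic cohort, the defaults and why they
were chosen, and the numerical decisions made where the design was open.

## Coordinate model

All in-memory coordinates are 0-based half-open; the `.pairs` and VCF-like
dialects are 1-based on disk, BED/bedGraph 0-based, following each format's
convention. Heterozygous deletions are modeled as haplotype-level intervals
on the reference frame (`GenomeModel`); boundary inference from data is out
of scope. A deleted haplotype's geometry lives in its *haplotype frame*:
positions left of the deletion are unchanged, positions right of it shift
left by the deleted length, positions inside have no image. Restriction
fragments are generated at a fixed cut spacing (default 5 kbp, a six-cutter
scale); a position exactly on a cut belongs to the right-hand fragment —
the convention is arbitrary but fixed and tested.

## Synthetic diploid cohort

The generator emits, per sample and haplotype, Poisson contact counts with

  λ_ij = C · s^(−α) · comp(i, j) · tad(i, j)

where `s` is the separation in bins **in the haplotype frame** (clamped at
1), `comp` multiplies by κ for same-compartment bin pairs and 1/κ
otherwise (alternating A/B blocks, default 2.5 Mbp, κ = 2), and `tad`
multiplies by τ for same-domain pairs (repeating sizes 0.8/1.2/1.0 Mbp,
τ = 3). Compartment and TAD identity stay on the reference frame — the
deleted homolog keeps the intact structure; only its distances change — so
the gain of contacts between deletion-flanking regions is an *emergent*
prediction of distance decay, not an injected effect. Bins inside the
deletion emit nothing on the deleted haplotype. Trans contacts are
constant-rate per 500-kbp cell, halved where one endpoint lies in the
deletion on the deleted haplotype; configurable hotspots multiply rates in
deletion samples (these are synthetic rewiring events, injected so the
differential-contact statistics have something to find).

Counts are materialized as read pairs at positions anchored just downstream
of a restriction cut (offset uniform in [0, 300) bp), which is what makes
restriction-distance filters meaningful; ~6% of simulated pairs fail the
standard sum-of-distances filter, as intended. The default cohort is 5
deletion / 6 control samples over a 50-Mbp chromosome emulating 22q (3-Mbp
deletion at 18.5–21.5 Mbp — the published flanking windows constrain the
geometry but exact breakpoints are not claimed) plus two 20-Mbp decoy
chromosomes; α = 1.0 (the conventional fractal-globule-range decay; only
relative contrasts matter downstream) and C = 20 per 50-kbp bin keep a full
run near one million pairs per sample.

Phased heterozygous SNVs are uniform at 6×10⁻⁴/bp (the scale of phased
het-SNV density in human genomes). SNVs inside the deletion stay in the
table — in a trio they are phasable by inheritance — but reads from the
deleted haplotype never cover them because that DNA emits no reads. Each
read end covering SNVs carries its true haplotype's alleles (error-free
sequencing; sequencing error and cross-homolog ligation are not modeled, so
assignment accuracy on synthetic data is exactly 100% and conflict counts
are a machinery check, not an error-rate estimate).

Three preset configurations define the study conditions:

- `CohortConfig()` — the 5-vs-6 whole-genome cohort above; used for
  group-level fold-change and integration analyses.
- `capture_config()` — one deletion and one control sample on the 50-Mbp
  chromosome at deep coverage (C = 40, SNV density 1×10⁻³), emulating a
  capture Hi-C library targeted at the deletion chromosome; used for
  haplotype-resolved maps and architecture calling, which need per-homolog
  depth.
- `trans_config()` — per-cell trans rate 120 with multi-cell ×3 hotspot
  blocks. A fixed p < 1e-4 Welch test on 5-vs-6 samples only has power when
  per-cell counts are large (the Welch degrees of freedom are ~6, so the
  critical t is ~11); the published significant trans-contacts sat among
  the strongest 5% of contacts, i.e. exactly in that regime, and this
  preset reproduces it.

ChIP tables are log2-normal per site (σ = 0.25); deletion sites lose one
log2 unit in deletion samples (heterozygous halving), a configured set of
flank sites shifts −δ for H3K27ac and +δ for H3K27me3 (reciprocal, δ = 1),
and TSS-linked histone sites share a per-gene-per-sample latent factor with
expression (correlation √0.5 ≈ 0.71, positive for H3K27ac, negative for
H3K27me3) so the coupling statistics have signal. Expression is log2-normal
FPKM, halved inside the deletion, with 30 genome-wide DE genes (±1 log2)
and 20 low-expression genes (mean FPKM 0.1) to exercise the FPKM < 0.5
filter; gene placement is 3:1 biased toward A-compartment bins, which also
provides the eigenvector orientation track. FISH distances are
normalized-scale truths (grand mean 1.0, deletion effect −0.2, gender
effect 0.05, subject intercept σ = 0.08, residual σ = 0.25, 16–33 cells
per line) multiplied back by r_short·r_long so the analysis side must
normalize; the σ values are typical relative variability for normalized
inter-probe distances and give the 5-vs-6 design ~85% power at the default
effect. Allele counts for ASE are balanced binomial (p = 0.5) outside the
deletion and monoallelic for the intact haplotype inside it.

What the generator does **not** emulate: sequence-level reads, ligation
chemistry, capture efficiency profiles, fragment-length biases, SNV calling
or phasing error, duplication CNVs, non-uniform SNV density. Passing tests
therefore demonstrate that the machinery is correct under the stated
statistical structure, not that it is robust to every artifact of real
libraries.

## Contact matrices and fold changes

Depth scaling multiplies each raw matrix by `target_total / total` (default
10 million), the stated pre-combination normalization; fragment-level bias
models are deliberately not re-implemented — group contrasts on synthetic
data do not need them, and on real data normalization models interact
badly with CNVs unless deletion bins are masked first. Group combination is
the element-wise mean of depth-scaled matrices with missing cells as 0.

The fold-change contrast is provided in two modes because "fold change of
log2-transformed mean contacts computed as (deletion−control)/control" can
be read two ways: `relative_log2` evaluates the sentence literally,
(log2(d+ε) − log2(c+ε))/log2(c+ε), and is the default; `log2_ratio` is the
conventional symmetric contrast that a −2…2 color scale suggests. Cells
whose relative_log2 denominator is ≤ 0 are NaN and counted; ε = 1 on
depth-scaled values bounds fold changes for empty cells. Biology-facing
tests state their mode; the halving properties are asserted on log2_ratio,
where one lost copy is −1 by construction.

## Haplotype-resolved maps

Pair haplotype resolution: concordant or one-sided evidence resolves;
double-unknown, cross-haplotype and conflicting pairs are discarded with
counted reasons (cross-haplotype counts feed the switch detector).

Density equalization of the deletion region samples `round(region length ×
density)` distinct single-bp positions uniformly without replacement, where
density is the chromosome's phased-SNV count outside the region divided by
the length outside; 10 seeded replicates. A contact "involves" a sampled
position through its restriction fragment — contacts are fragment-level
events — so the filter retains a region-endpoint pair only if that
endpoint's fragment contains a sampled position, applied to both homologs
symmetrically. At the default densities nearly every region fragment
contains a sampled position, so on synthetic data (uniform SNV density) the
filter is almost neutral and the replicate-stability check (Spearman of
region-involving contact profiles across the 10 samplings) passes near 1;
on real data with uneven informativeness the same mechanism would thin
unevenly, which is the point of the replicate check. Reported matrices
default to the mean over replicates, with per-replicate output available.

The difference map scales both homolog matrices to equal assigned-pair
totals before subtracting. For *sign tests* on difference blocks, the raw
(unscaled) per-homolog counts are used: under equal rates, the sign of a
cell's count difference is a fair coin, whereas after multiplicative
rescaling every tied nonzero cell inherits the sign of the larger scale
factor, which mis-calibrates a sign test on null data.

The phasing-switch detector counts, for every candidate breakpoint on a
window grid, the both-ends-informative cis pairs straddling it; candidates
where cross-haplotype straddlers outnumber concordant ones are flagged.
This is report-only — no automatic haplotype correction is attempted.

## Compartments and domains

O/E divides each cis cell by the mean at its separation over unmasked
cells; all-zero rows and configured deletion bins are masked (NaN, not
zero-filled — zero-filling would make the deletion masquerade as a
compartment flip). PC1 is the leading eigenvector of the Pearson
correlation matrix of O/E columns, sign-oriented so bins with higher gene
density are A (the orientation convention must come from outside the
matrix; gene density is the standard anchor).

DI uses the published signed chi-square form with a 2-Mbp window (the
window size of the method this follows; exposed as configuration).
Chromosome-edge bins use truncated windows and are flagged. Domain calling
replaces the original mixture-HMM with a penalized three-state dynamic
program: per-bin scores ±DI/mean|DI| (clipped at ±3 so single extreme bins
cannot absorb their neighbours' transition budget, minus a 0.2 margin so
zero-DI stretches prefer the neutral state), penalty 1.0 per state change;
a domain opens at the start of a downstream-biased run and closes at the
end of the following upstream-biased run; domains under `min_size`
(default 120 kbp, three 40-kbp bins) are dropped. The contract is
boundary-level accuracy against generative truth (≥90% within ±1 bin at
the default depth), not model identity. Ties in the DP resolve toward the
lower state index, making the caller deterministic.

## Differential contacts

The unequal-variance (Welch) form is used because the referenced `t.test`
default is Welch; an equal-variance option exists. Inclusion requires ≥1
raw pair in every sample; the threshold p < 1e-4 is fixed with no
multiple-testing correction (a BH option exists for reuse). "Strongest"
contacts are ranked by the mean depth-scaled value across all samples
(control-only ranking available). Cells where both groups have zero
variance are excluded with a reason. Label swaps permute deletion/control
status ten times; within-group controls split one group into two
pseudo-groups three times; both are seeded.

## Integration statistics

Z-scores standardize per-site log2 fold changes within one mark; the
region-side significance cutoff is |Z| > 2 while the TSS-side partition
uses |Z| > 1 for H3K27ac and |Z| > 2 for H3K27me3 — the inconsistency is
preserved as configuration rather than resolved. Binned enrichment tests
each 500-kbp bin's flagged/total counts against the genome-wide remainder
by two-sided Fisher, BH across tested bins, NA for empty bins.
Permutation tests are two-sided on the difference of group means with the
add-one estimator p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1); when the number
of distinct regroupings is ≤ 20,000 the test switches to exhaustive
enumeration and the p value is exact. Two-sidedness and the add-one rule
are validity choices where the source procedure is unstated.

The expression–chromatin correlation permutes each gene's FPKM across
samples ten times for the background and compares observed vs pooled
background r by two-sided Wilcoxon rank-sum. ASE uses an exact two-sided
binomial test against the per-sample mean alternative-allele fraction over
SNVs with coverage strictly greater than 10.

The FISH model is `Distance ~ Deletion + Gender + Deletion/Subject` with
Subject random within Deletion. The Deletion contrast is tested against the
between-subject mean square — implemented as a one-way ANOVA on subject
means (expected-mean-squares logic, deterministic and oracle-checkable)
rather than an iterative mixed-model fit; Gender is tested against the
cell-level residual from the sequential fit. Distance normalization
"by the multiple of the shortest and longest radius" is implemented as the
product r_short·r_long by default with a geometric-mean option, since
"multiple" is ambiguous. Degenerate inputs (all-equal distances) return
F = 0, p = 1. Null calibration of the Deletion test is ~4.7% at nominal 5%
over 2,000 simulated cohorts.

## Problem sizes

The test suite and the acceptance script run the cohort analyses at the
default sizes above: the 5-vs-6 cohort (~1.1 M pairs/sample), one capture
pair of samples (~2 M pairs each), 3 null + 20 power replicates of the
count-level trans simulation, 500–800 null and 200–400 power FISH cohorts,
and the CLI pipeline twice on the scaled-down configuration. These sizes
were chosen so the full validation is a desk-scale computation while every
statistic still operates in its intended regime.

## Known limitations

- The simulator's error-free allele tags make haplotype-assignment accuracy
  a correctness check only; real-data accuracy is bounded by sequencing and
  phasing error, which are not modeled.
- Per-fragment bias normalization is not implemented; contrasts assume
  biases cancel between groups.
- The domain caller is a simplification of the published HMM and is
  validated at the boundary level on block-TAD truth; sub-TAD structure and
  nested domains are out of scope.
- The windowed cis ranking and hotspot magnitudes are synthetic constructs;
  on real data the ranking's values depend on normalization choices that
  this package intentionally keeps minimal.
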