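# Methods

## Scope and model

The package implements a promoter-level analysis of CAGE data. The unit of
observation is the CTSS — a 1-based genomic position on a strand carrying a
raw tag count per sample. All downstream structure (clusters, shapes,
motifs, differential calls) is derived from CTSS tables plus a genome FASTA,
a gene-annotation table and position frequency matrices.

## Power-law normalization

CAGE tag-count distributions are approximately power-law. For each sample
the reverse cumulative revcum(x) = #{CTSS : count >= x} is computed at every
distinct observed count and fitted by ordinary least squares in
log10–log10 space over counts in `fit_range` (default [5, 1000]; at least
ten distinct values required). Counts are then mapped onto a reference law
revcum_ref(y) = β y^(−α) at equal reverse-cumulative rank:

    tpm(x) = (10^b · x^s / β)^(−1/α)

with α = 1.05 (common CAGE practice; the underlying report does not print a
value) and β determined by the constraint that the continuous reference law
carries 10⁶ tags in total: ∫₁^∞ y·d(−revcum) = β·α/(α−1), hence
β = 10⁶(α−1)/α ≈ 47,619. The mapping is strictly increasing, so count ranks
are preserved exactly and tied counts share one tpm.

Biological replicates are merged by summing raw counts per CTSS before one
joint normalization; the replicate-level raw counts are kept for the
differential test. Note the mapping is a power transform with exponent
−s/α; when a library's fitted slope is shallower than −α (as for the
synthetic world, ≈ −0.92) the transform is mildly concave, which compresses
dominant-TSS fractions — the synthetic promoter architectures were chosen
to be robust to this (below).

## Clustering

Per sample, same-strand CTSSs are chained while neighbouring positions are
<= 20 bp apart (inclusive; "maximum allowed distance" is read as including
the maximum). Each tag cluster is trimmed to robust boundaries: q_low
(q_high) is the smallest position whose cumulative expression, scanning in
genomic order, reaches 10% (90%) of the cluster total; members outside
[q_low, q_high] are dropped and the interquantile width is
IQW = q_high − q_low + 1 (inclusive bases). Trimming is defined as a
one-shot operation — a trimmed cluster carries a flag and re-trimming is a
no-op — because re-deriving quantiles from the trimmed mass is not a
fixpoint at exact quantile boundaries. Clusters with total tpm <= 5
(strict, per the stated "higher than 5 tpm") are discarded.

Tag clusters from all samples are merged transitively into consensus
clusters when the end-to-start gap between spans is <= 100 bp. Per-sample
CC expression is the sum of that sample's CTSS tpm within the CC span (zero
when absent); the dominant TSS is the position of maximal tpm with ties
broken toward the 5' end of the transcribed strand (a deterministic rule;
the source method is silent). Each CC also records which samples
contributed a called tag cluster; a CC is *shared* when every sample did.

Annotation assigns each CC to the nearest annotated TSS on its strand, with
feature precedence Promoter(<=1kb) > 5'UTR > Exon > Intron > 3'UTR >
Promoter(1–3kb) > Downstream(<3kb) > Distal intergenic. CCs in
Promoter(<=1kb) or 5'UTR form the promoter-proximal set used downstream.
When several CCs map to one gene, the one with the highest summed tpm
represents the gene.

## Promoter shape

sharp: IQW < 10; peaked broad: IQW >= 10 with the dominant TSS carrying
> 60% of CC expression; broad: the rest. Width exactly 10 is not sharp and
fraction exactly 0.6 is not peaked. The operative definition classifies
sharp on width alone; a `strict_sharp` flag additionally requires the >60%
dominant fraction (a variant stated in one figure legend of the source
study). Shape transitions are tabulated on CCs with >= 10 tpm in both
conditions.

## Motif analysis

Promoter windows run from 120 bp upstream to 50 bp downstream of the
dominant TSS, strand-oriented (offset 0 = dominant TSS); only the sense
strand is scanned, as the motifs are orientation-specific. PWM columns are
count matrices regularized with pseudocount 0.8 spread by the uniform
background and column-normalized. Scores are log2 odds against uniform
0.25; the match percent is min–max scaled between the PWM's attainable
extremes, so a hit threshold of 90% is scale-free. A promoter is a hit for
a motif if any offset with the full motif inside the window reaches the
threshold (presence/absence, matching Fisher tests on promoter counts).
Group enrichment uses two-sided Fisher exact tests of hit counts in a group
vs the unchanged background, log2 odds ratios with Haldane 0.5 correction
on empty cells, and the stated raw p < 0.01 significance rule (a BH column
is provided for convenience). TATA match distributions restrict motif
start offsets to [−40, −20] inclusive; poly-W pentamers are the 32 words
over {A,T}⁵ with start offsets in the same region, each occurrence flagged
when it overlaps a >= 90% TATA hit (separating TATA-embedded pentamers
from W-box-like words).

## Differential expression

The source analysis used an external NB framework; this package ships a
self-contained equivalent. Size factors are DESeq-style median-of-ratios.
Per-CC dispersions are estimated by method of moments from within-condition
residuals of normalized counts and pooled into a trend
α(μ) = a₀ + a₁/μ fitted through binned means (weighted least squares,
coefficients clipped non-negative). The test uses the trended dispersion
directly (shrinkage weight 1.0): with three replicates the gene-wise
moment estimate has ~4 degrees of freedom and blending it into the variance
makes the Wald test anti-conservative; the trend-only choice is calibrated
(type-I error ≈ 0.05 in the null simulation) and is the default. The Wald
statistic is ln(m_B/m_A) over a delta-method standard error with NB
variance μ/s + αμ² per replicate; condition means of zero get a 0.5
pseudo-mean; all-zero CCs return p = 1. Calls use BH-adjusted p < 0.05.
Only shared, promoter-proximal, per-gene representative CCs are tested —
testing unshared CCs (a cluster called in one condition only) produces
spurious fold changes from span coverage alone.

## Gene-set statistics

Tau = Σ(1 − xᵢ/x_max)/(n−1) and Shannon entropy in bits of the normalized
expression vector; both are scale-invariant. Permutation enrichment draws
`n_perm` (default 10,000) query-sized sets from the universe without
replacement; p = (1 + #{perm >= observed})/(n_perm + 1), never zero.
Set-intersection chi-square is Pearson's statistic on the 2×2 membership
table without continuity correction (matching the large-sample usage).
Ortholog translation is a user-supplied two-column table; no live lookups.

## Alternative promoters and temporal trends

Pairs pass selection when TPM > 5 (strict) in either region, in each
condition. Candidates show a >= 2-fold change (inclusive) of relative
expression rel = alt/cano between conditions; Δ values are signed relative
changes vs condition A, with "unchanged" = |Δ| < 0.25 (strict) and
"moved" = |Δ| >= 0.5 directional per group name — the only reading
consistent with the four group names in the compressed source notation.
Patterns outside the four groups are discarded. A 0.5 pseudo-TPM guards
rel when the canonical promoter is silent (flagged in output). Temporal
trends require max tpm > 5 across the three stages and per-step ratios
strictly > 1.5 in one direction; zeros get a 0.5 pseudo-TPM.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the stated world of the validation: 5,000
genes on 3-kb slots across 10 chromosomes (GC 0.37, zebrafish-like),
2 conditions × 3 replicates, planted |log2FC| = 2 in 250 + 250 genes with
baseline mean tags from a Pareto law (exponent 1.05 matching the
normalization reference; floored at 100 tags so differential genes sit at
the mean-100 regime, capped at 30,000), negative-binomial replicate noise
with dispersion 0.05 (the regime of well-correlated biological CAGE
replicates, per-promoter log-tpm r > 0.9), and per-library background
noise CTSSs in gene bodies (30 per gene slot, counts <= 40) that shape the
low end of the reverse-cumulative fit without ever passing the tag-cluster
threshold.

Shape classes: sharp = discretized Gaussian σ = 1; broad = σ = 15;
peaked broad = a dominant TSS carrying 0.7 of expression plus six minor
TSSs (three per side, offsets 6–25 bp) carrying 0.05 each. The satellite
architecture (rather than a thin Gaussian tail) is deliberate: at realistic
depth a 0.5-tpm support filter deletes single-tag tail positions, which
would collapse a Gaussian-tailed peaked promoter into an apparent sharp
one; discrete minor TSSs survive filtering and are a documented feature of
real wide promoters. 5% of genes transition shape class between conditions.
Motifs are planted as consensus sequences of synthetic PFMs (emitted in
JASPAR text; no database matrices are redistributed): TATA at −32..−28 in
60% of slow-cycling-up genes vs 10% elsewhere, CCAAT at −100..−60 with the
mirrored bias, plus baseline Sp1/INR/YY1 and one-mismatch "TATA-like"
variants (87% match, inside the 75–90% band).

Alternative-promoter pairs and temporal triples are emitted directly as
TPM tables sampled inside each class's defining region by rejection
sampling, with the published class counts as defaults (1,612 pairs of which
231 expressed and 79 candidates: 12/22/10/26 classified + 9 discarded;
434 gained / 93 lost / 4,473 unchanged temporal profiles). Because those
classifiers are deterministic rules, planted classes are recoverable
exactly; a green test there establishes the rule logic, not robustness to
count noise. Catalogues are planted with cell-cycle membership odds
0.45 vs 0.05 favouring the fast-cycling-up group and tissue-restricted
expression odds 0.5 vs 0.1 favouring the slow-cycling-up group.

What the generator does not emulate: mappability and alignment artefacts,
the CAGE extra-G bias, promoter-proximal antisense signal, empirically
shaped (non-Gaussian) TSS distributions, and genuinely continuous
low-expression genes below the 100-tag floor. Weakly expressed *broad*
promoters near the floor can lose every position to the 0.5-tpm support
filter and drop out entirely (~5% of genes in the default world) — the
same behaviour a real pipeline shows on shallow libraries — so planted
recovery is evaluated on the well-expressed (>= 10 tpm in both conditions)
set the shape analysis is defined on.

## Numerical and reproducibility choices

All randomness flows through one `numpy` Generator seeded from the config;
dataset emission and every pipeline TSV are byte-identical across reruns
(fixed float formatting, no timestamps in outputs). Quantile bounds use
`searchsorted` with >= semantics (ties go to the 5'-most position).
Fisher p-values come from `scipy.stats.fisher_exact`; BH adjustment from
`statsmodels`; both are cross-checked in the tests against enumeration and
step-up oracles. The pipeline runs stages in dependency order — the motif
stage runs after differential expression because enrichment groups are the
DE calls — and any stage can be re-run from cached TSV intermediates.

## Known limitations

- The NB test is a simplified stand-in (no Cook's-distance outlier
  handling, no independent filtering, no covariates); users can substitute
  external results through the CC count TSV interface.
- The trend-only dispersion underfits datasets with genuinely heterogeneous
  gene-wise dispersion; the `shrinkage` parameter exposes the blend.
- Promoter windows clipped at chromosome ends shorten silently (recorded in
  window metadata); positional profiles near contig edges are therefore
  based on fewer observations.
- The annotation model is single-transcript per gene; genes with multiple
  annotated isoform TSSs must be encoded as separate rows.
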