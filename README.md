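# promoterome

Analysis of promoter architecture from CAGE data: how transcription start
site (TSS) usage, core-promoter motifs and promoter "shape" differ between
cell populations — e.g. between slowly cycling (G1-enriched) and rapidly
cycling (S/G2/M-enriched) cells of a developing embryo, where slow-cycling
cells favour sharp, TATA-driven promoters and fast-cycling cells favour
broad, CCAAT-driven ones.

CAGE (cap analysis of gene expression) sequences capped mRNA 5' ends,
giving a count of tags at every single-base TSS position (a *CTSS*). This
package turns per-sample CTSS count tables into:

1. **Power-law normalized expression (tpm).** CTSS count distributions are
   near power laws; each library's reverse cumulative
   revcum(x) = #\{CTSS with count >= x\} is fitted by OLS in log-log space
   and counts are mapped onto a reference law revcum(y) = β·y^(−α) with
   α = 1.05 and β fixed so the implied library size is 10⁶ tags:
   tpm(x) = (10^b·x^s / β)^(−1/α).
2. **Tag clusters and consensus clusters.** CTSSs supported by >= 0.5 tpm
   are chained (gap <= 20 bp, same strand), trimmed to the 10th–90th
   expression percentile positions, kept above 5 tpm, and aggregated across
   samples into consensus clusters (CCs, within 100 bp), annotated to the
   nearest gene TSS.
3. **Promoter shape.** Interquantile width IQW = q₉₀ − q₁₀ + 1;
   *sharp* (IQW < 10 bp), *peaked broad* (wide, one TSS > 60% of
   expression), *broad* (the rest); shape-transition matrices between
   conditions on CCs >= 10 tpm in both.
4. **Core-promoter motifs.** PWM scans of −120..+50 windows around each
   dominant TSS (hit = 90% min–max-scaled log-odds match), Fisher exact
   enrichment per gene group vs the unchanged background, TATA match-percent
   distributions in −40..−20, WW-dinucleotide profiles and poly-W pentamer
   (W-box) usage with canonical-TATA overlap flags.
5. **Differential expression.** Median-of-ratios size factors, trended
   method-of-moments NB dispersion, Wald test on log fold change,
   Benjamini–Hochberg adjusted p < 0.05.
6. **Gene-set statistics.** Tissue-specificity Tau
   (Στ(1 − xᵢ/x_max)/(n−1)) and Shannon entropy; permutation tests for
   catalogue overlap; chi-square set intersections.
7. **Alternative promoters and temporal trends.** Twinned
   canonical/alternative promoter pairs classified by >= 2-fold change in
   relative usage; three-stage expression classified as gained/lost when
   each sequential step changes > 1.5-fold in the same direction.

A first-class synthetic-data generator (`promoterome.synthetic_data`) emits
a genome with planted motifs, shape classes, fold changes,
alternative-promoter and temporal classes plus all the truth labels, so
every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate.py --seed 1          # ground-truthed dataset
python analysis/02_normalize_and_cluster.py
python analysis/03_promoter_shape.py
python analysis/04_differential_expression.py
python analysis/05_core_promoter_motifs.py
python analysis/06_gene_set_statistics.py
python analysis/07_alternative_promoters.py
python analysis/08_temporal_trends.py
```

Output from this exact run (seed 1, 5,000 genes, 2 conditions × 3
replicates of ~4M tags):

```
G1: fitted reverse-cumulative slope -0.921 (reference -1.05)
4709 consensus clusters; 4607 shared between conditions
shape transitions: 182/3696 (4.9%) of well-expressed CCs
planted shape recovery G1: 99.8% (n=3696)
calls: {'unchanged': 4068, 'up_SG2M': 270, 'up_G1': 269}
empirical FDR at BH 0.05: 0.078
   up_G1   TATA: log2 OR +3.28  p=3.97e-62 *
 up_SG2M  CCAAT: log2 OR +3.64  p=4.18e-77 *
 up_SG2M: overlap 103 (expected 19.4), p=9.999e-05
   up_G1: tau 0.673, entropy 1.76 bits (n=269)
1612 twinned pairs, 231 expressed in both conditions, 79 with a 2-fold relative change
planted trend recovery: 100.0%
```

Reading it: the merged libraries fit a power law close to the α = 1.05
reference; nearly every planted promoter becomes a consensus cluster shared
between the conditions; shape classes are recovered at 99.8% on
well-expressed promoters; the differential test calls all planted 4-fold
changes with empirical FDR 0.078 at the nominal BH 0.05 level; the TATA-box
is strongly enriched in genes up in the slow-cycling population and the
CCAAT-box in genes up in the fast-cycling one (log2 odds ratios +3.3/+3.6);
cell-cycle catalogue genes concentrate in the fast-cycling up group
(103 observed vs 19 expected, permutation p ≈ 1/10001) while the
slow-cycling up group is more tissue-specific (higher Tau, lower entropy);
and the deterministic alternative-promoter and temporal classifications
recover their planted classes exactly (231 expressed pairs, 79 candidates).

The same stages are available as a CLI
(`promoterome simulate|run-all|normalize|cluster|...`) driven by a YAML
config, and as library functions.

## Acceptance script

`scripts/acceptance.py` re-runs the complete computation from scratch —
generates the default synthetic dataset from the given seed and executes
every pipeline stage — and writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
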