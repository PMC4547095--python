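# chromcode

Genome-wide analysis of what an induced transcriptional repressor does to
chromatin — and whether chromatin alone predicts repression.

Long-range repressors of the Hairy/Enhancer-of-Split family silence genes
by recruiting corepressors (Groucho, CtBP) and deacetylases that modify
chromatin in broad blocks. But genome-wide, much of that biochemical
activity lands on genes whose expression never moves ("errant targeting").
`chromcode` implements the full analytical pipeline for this problem, with
a synthetic-data generator that plants known ground truth so every stage
is testable without sequencing data:

1. **simulate** — replicate NB-distributed binned ChIP-seq coverage for 6
   histone marks + Pol II (+ H3/input controls) in two conditions, with
   differential blocks, repressor peaks and expression changes planted on
   a 583-gene cohort (241 repressed / 146 activated / 196 unaffected);
2. **diffblocks** — sliding-window (1 kb / 500 bp) negative-binomial Wald
   test; windows with p < 0.05 and |log2FC| > 0.4 merge into
   direction-consistent blocks with bin-level boundary refinement;
3. **annotate** — nearest-TSS gene assignment, promoter/exon/intron/
   intergenic context, repressor-binding linkage, Pol II promoter-vs-body
   change classes;
4. **overlap** — ≥1 bp co-occurrence with signed natural-log
   hypergeometric tails (negative = enrichment, positive = divergence);
5. **profiles** — composite profiles (4 kb / 10 bp, per bp per region),
   heatmap matrices (5 kb / 25 bp), scatter correlations, KS block-width
   comparisons;
6. **features + ml** — a 41-feature table per gene (4 block features × 7
   differential datasets, 4 peak features × 3 binding factors, wild-type
   expression) feeding an ensemble protocol: 4 feature selectors
   (information gain, symmetrical uncertainty, χ², ReliefF) × 4
   classifiers (random forest, naive Bayes, KNN, SVM), top-20 features,
   stratified 10-fold CV, 50 iterations, >50% majority vote per gene.

The window statistic, for window means m₁ (wt) and m₂ (induced) over
replicates:

    z = [ln(m₂+c) − ln(m₁+c)] / sqrt(Σᵢ vᵢ/(mᵢ+c)²),   vᵢ = (mᵢ + φ̂ᵢ mᵢ²)/nᵢ

with a pooled method-of-moments overdispersion φ̂ per condition and
pseudocount c = 1; two-sided normal p. The co-occurrence statistic is the
hypergeometric tail ln P(X ≥ k) for k of K regions hitting any of n
partners among N genome slots.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on the seed-1
benchmark cohort and write tables under `results/` (bulky per-gene/region
matrices go to `scratch/`):

```
python analysis/01_simulate.py
python analysis/02_call_blocks.py
python analysis/03_annotate_link.py
python analysis/04_cooccurrence.py
python analysis/05_profiles.py
python analysis/06_features_classify.py
```

`02_call_blocks.py` prints, among the per-mark counts:

```
    mark direction  n_blocks  mean_width_bp  mean_abs_log2fc
    H4Ac  decrease       242         2431.7             1.12
 H3K27Ac  decrease       231         1885.5             1.06
 H3K9me3  increase        68         1536.8             1.09
      H3  decrease         1          300.0             0.48

H4Ac decrease blocks: n=242, mean 2.43 kb, median 2.20 kb, >1 kb: 92%
```

Deacetylation dominates (H4Ac blocks average ~2.4 kb, mostly >1 kb), the
repressive mark H3K9me3 moves in the opposite direction, and the H3
density control stays silent — the detector reports changes in marks, not
in nucleosome occupancy.

`04_cooccurrence.py` shows the strong decrease×decrease corner of the
co-occurrence matrix (e.g. H4Ac↓ vs H3K27Ac↓: ln p ≈ −358) and the
gene-set test:

```
repressed (241) vs Hairy-bound (300) genes: 187 shared (78%),
hypergeometric ln p = -61.0
activated (146) vs Hairy-bound (300) genes: 53 shared (36%),
hypergeometric ln p = 11.0
```

— repressed genes are overwhelmingly physical repressor targets
(negative = enriched), activated genes are not (positive = divergence).

`06_features_classify.py` builds the 583 × 41 table and runs the full
selector × classifier grid (this prints after a few minutes):

```
Aggregate accuracy (%) per selector x classifier:
classifier                knn  naive_bayes  random_forest   svm
chi_square               85.2         82.8           85.6  85.1
info_gain                85.2         82.8           85.6  85.1
relief                   85.2         83.2           84.4  85.6
symmetrical_uncertainty  85.6         82.7           85.9  84.9

Majority-class baseline: 58%

Nonrepressed genes called 'repressed' by >=12/16 methods: 28
Of these, 28 are errantly targeted in the ground truth
```

Every method clears the 58% baseline by a wide margin, and the genes that
nearly all 16 method combinations miscall as "repressed" are exactly the
planted errant-targeting cases — loci whose chromatin carries the full
repression signature while transcription never moved. The accuracy
ceiling is set by the generator itself: ~10% of repressed genes respond
transcriptionally without a chromatin footprint, and 30% of nonrepressed
genes carry misleading chromatin.

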