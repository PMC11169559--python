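# sgenrich

Analysis of stress-granule (SG) transcriptomes from IP-vs-input RNA-seq.

Stress granules are cytoplasmic ribonucleoprotein condensates that form
under stress and can be isolated by immunoprecipitation (e.g. of
GFP-tagged G3BP1). Comparing the immunoprecipitated (IP) fraction against
total lysate (input) identifies which RNAs the granules recruit, and
comparing that contrast across conditions — wild-type vs an
ALS-associated FUS mutant, with or without knockdown of the m6A writer
METTL3 — identifies which RNAs *change* their granule association.
`sgenrich` implements that analysis end-to-end for count-level data,
together with a synthetic data generator that plants ground truth so
every stage can be validated.

## What it computes

**Enrichment calling.** For each condition, a gene-wise negative-binomial
log-link GLM of IP vs input counts with log-effective-library-size
offsets (median-of-ratios size factors; in IP designs the pseudo-reference
is built from input samples so granule composition does not bias the
baseline). The Wald test on the fraction coefficient gives a p-value;
genes with log2FC > 1 and Benjamini–Hochberg FDR < 0.05 are *enriched*,
log2FC < −1 and FDR < 0.05 *depleted*, the rest *invariant*. NB
dispersion (var = μ + φμ²) is a method-of-moments estimate shrunk toward
a mean-abundance trend; an exact conditional binomial test covers the
1-vs-1, φ→0 case and doubles as an oracle for the Wald path.

**Differential enrichment.** A condition × fraction factorial GLM whose
interaction coefficient is the contrast (IP1−INP1)−(IP2−INP2).
Differentially enriched genes must also exceed 1 FPKM in at least one of
the four sample types and be called enriched in at least one condition.
Comparing knockdown against control partitions genes into *commonly
enriched*, *KD-enriched* (gained), *KD-depleted* (lost), and *invariant*;
intersecting the gained set with the wild-type enriched set yields the
*relocated* RNAs.

**Robustness.** Top-N enrichment-ranked set overlaps across conditions
over a grid of N (5000 … 500), and library-size resampling: counts are
thinned to target totals by multivariate hypergeometric draws
(without-replacement fragment sampling at the gene level) and the
classification is re-run.

**Composition and overlays.** 4-mer frequency profiles of enriched vs
invariant transcripts, their log2 fold-change matrix and k-means
clustering (3 clusters, seed-stable); per-group methylated fractions with
Fisher exact tests, transcript-length comparisons (Mann–Whitney),
five-level expression stratification, knockdown-vs-control abundance
fold-change comparisons per fraction, and a length-matched resampling
control for methylation differences.

## Worked example

```python
from sgenrich import SimConfig, simulate_experiment, evaluate_recovery
from sgenrich.differential import run_group_analysis

cfg = SimConfig(seed=1)   # 2,000 genes, 4 conditions, 3 IP + 3 input reps each
counts, design, annotation, truth = simulate_experiment(cfg)
res = run_group_analysis(counts, design, annotation)

groups = res["groups"]
print("group sizes:", {k: len(v) for k, v in groups.sets().items()})
print(f"relocated overlap: {res['relocated_overlap_fraction']:.1%}")
print(evaluate_recovery(groups, truth)[["precision", "recall", "f1"]].round(3))
```

prints

```
group sizes: {'commonly_enriched': 279, 'delta_enriched': 280, 'delta_depleted': 275, 'invariant': 1166, 'relocated': 210}
relocated overlap: 75.0%
                   precision  recall     f1
group
commonly_enriched      1.000   0.930  0.964
delta_enriched         0.986   0.920  0.952
delta_depleted         0.989   0.907  0.946
invariant              0.943   0.999  0.970
relocated              0.986   0.920  0.952
```

The generator planted 300 genes per non-invariant group with ±2 log2
effects; the analysis recovers each group with F1 ≥ 0.9, and 75% of the
genes gained upon knockdown in the mutant overlap the wild-type granule
transcriptome — the relocated set. (The relocated row compares the
assigned relocated set against the planted one.)

The same stages are available from the shell:

```bash
sgenrich simulate --seed 1 --out sim/
sgenrich enrich  --counts sim/counts.tsv --design sim/design.tsv --condition P525L_KD
sgenrich groups  --counts sim/counts.tsv --design sim/design.tsv \
                 --annotation sim/annotation.tsv \
                 --kd P525L_KD --ctrl P525L --reference WT
sgenrich run --seed 1 --out run/        # full pipeline, one manifest
```

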