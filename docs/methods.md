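# Methods

## The statistical model

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean μ<sub>gj</sub> and variance μ<sub>gj</sub> + φ<sub>g</sub>μ<sub>gj</sub>²
(φ is the gene-wise dispersion, dimensionless; φ = 0 recovers Poisson).
All models are log-link GLMs with an offset log e<sub>j</sub>, the
sample's effective library size, fitted by iteratively reweighted least
squares batched across genes (shared design matrix, per-gene weights;
convergence at 1e−10 on the coefficients, at most 100 iterations, linear
predictor clamped to ±30).

*Enrichment* within a condition uses the design [1, IP]; the IP
coefficient divided by ln 2 is the reported log2 fold change, and a Wald
test on it gives the p-value. *Differential enrichment* between two
conditions uses the factorial design [1, c, f, c·f] with centred ±½
codes for condition and fraction; the interaction coefficient is exactly
(IP1−INP1)−(IP2−INP2) on the log scale, and the centred coding makes
swapping the conditions an exact sign flip of the estimate, even for
degenerate fits.

Wald statistics are referred to a t distribution with the dispersion
estimator's pooled residual degrees of freedom (16 in the standard
four-condition, three-replicate design) rather than the normal: the
dispersion is a plug-in estimate, and with few replicates the
normal-reference Wald test is measurably liberal. Under the null
simulation the raw p < 0.05 rate then sits at the nominal level.

### Normalization

Size factors are median-of-ratios: the median over all-nonzero genes of
the ratio between the sample's count and a per-gene geometric-mean
pseudo-reference. Two deliberate choices:

1. **Effective size = geometric-mean library size × centred factor.**
   Median-of-ratios factors already carry each sample's relative depth
   (doubling a column doubles its factor), so they scale one
   representative library size; multiplying each sample's own total
   would count depth twice.
2. **Input-referenced pseudo-reference.** When a sample design is
   available, the pseudo-reference is built from input-fraction samples
   only. In an IP experiment the enriched minority can occupy a large
   share of the IP library (with 900 of 2,000 genes enriched four-fold,
   unenriched genes are compositionally depressed by ≈0.9 log2); a
   reference that mixes IP columns under-corrects this and biases every
   unenriched gene toward apparent depletion. Measuring against the
   transcriptome (input) removes the bias. Without a design the plain
   all-sample reference is used.

FPKM is count / (length<sub>kb</sub> × effective size in millions),
using the representative transcript length (longest isoform matching the
gene biotype; longest overall for non-coding genes).

### Dispersion

Per-gene φ is a pooled method-of-moments estimate: within each
(condition, fraction) group on the normalized scale, the residual
variance decomposes into a Poisson part and φ·μ²; pooling across groups
and solving gives raw φ (floored at 0). Raw values are shrunk with
weight 0.3 toward a binned-median trend over log mean abundance (20
quantile bins, linear interpolation). The shrinkage weight trades
gene-wise specificity against stability at 2–4 replicates; planted-truth
recovery and null calibration are the arbiters, and both are exercised
in the test suite. All-zero genes receive the median dispersion and are
flagged.

### Edge cases

- Genes with all-zero counts in a tested subset: p = 1, log2FC = 0,
  flagged.
- One fraction all zero (complete separation): the GLM coefficient
  diverges, so the reported log2FC is the pseudo-count-stabilized ratio
  of normalized group totals (+0.5 to each total); for the factorial
  contrast the analogous four-cell stabilized estimate is used, which is
  antisymmetric under condition swap by construction.
- Exact conditional test (one sample per group, φ→0): conditional on
  the total, the IP count is binomial with success probability
  s_IP/(s_IP+s_input); the two-sided p-value sums all outcomes no more
  likely than the observed one. Agreement with rational-arithmetic
  enumeration is tested to 1e−12 for all totals ≤ 30.
- Benjamini–Hochberg is computed within the tested universe (genes with
  ≥ 1 fragment in the analysed samples); NaN p-values are excluded from
  the test count and propagated.

## Group assignment

With knockdown (KD) and control calls plus the contrast:

- *commonly enriched* — enriched in both, not differentially enriched;
- *KD-enriched (gained)* — differentially enriched (FDR < 0.05, max
  sample-type FPKM > 1, enriched somewhere) and enriched in KD only;
- *KD-depleted (lost)* — the mirror image;
- *invariant* — the remainder (including genes failing the FPKM filter,
  keeping the partition exhaustive).

A differentially enriched gene called enriched in both conditions is
assigned by the sign of its contrast and flagged. The *relocated* set is
the intersection of the gained set with the reference (wild-type)
enriched set; its overlap fraction is reported alongside.

## Robustness analyses

**Convergence.** Genes are ranked by log2FC (descending; ties by
ascending p then gene id, so top-N sets are nested in N), and top-N sets
are intersected pairwise and all-way for N in {5000 … 500}. N values
above the universe are truncated. Both raw intersections and
intersection/N are reported, as no single overlap metric is canonical.

**Thinning.** Sampling fragments without replacement down to a target
total is, at the gene level, exactly a multivariate hypergeometric draw
with the sample's counts as the urn — column sums hit targets exactly
and per-gene expectations are count × target/total. The resampling
stability report thins every non-reference condition to the reference's
per-fraction mean library size, re-estimates dispersion, re-runs the
enrichment calls, and reports per-gene status agreement and per-status
Jaccard indices over a configurable number of repetitions (default 10;
the repetition count is an open choice, made configurable).

## K-mer composition

Per-transcript k-mer frequencies use overlapping windows with the number
of valid windows (L − k + 1 for clean sequences) as denominator — the
standard normalization, which makes each vector sum to one; windows
containing non-ACGT characters drop from numerator and denominator.
Set-level profiles are unweighted means over transcripts (each
transcript counts once regardless of length; "average transcript
frequency" is per-transcript, not per-nucleotide). The
enriched-vs-invariant log2 fold change uses a pseudo-frequency of half
the smallest positive observed frequency. K-means on the 4^k ×
conditions matrix uses k-means++ with 25 restarts and a fixed seed;
labels are renumbered by descending cluster mean so output is stable.
Heatmap rendering is presentation, not analysis, and is left to the
caller.

## Annotation overlays

Methylated fractions are plain percentages per group; the attached
Fisher exact tests against the invariant background are an addition of
this implementation (the underlying comparison is descriptive). Length
comparisons use Mann–Whitney, exact by full enumeration of label
assignments when both groups have ≤ 8 members (tie-safe via midranks),
otherwise the normal approximation with tie correction. Expression
strata are five equal-count quantile bins of mean input-fraction FPKM
over expressed genes. The length-matched control resamples the reference
group to match the focal group's composition across length deciles (200
seeded resamples, deciles of the pooled distribution, nearest non-empty
bin as fallback); if the focal group's methylated percentage falls
inside the central 95% of the matched distribution, its excess is
attributable to length.

## The synthetic-data generator

The generator emulates a four-condition SG-IP study: wild-type and
mutant genotypes, each with and without m6A-writer knockdown, IP and
input fractions, unequal library sizes. Defaults define the standard
validation scenario used throughout:

| parameter | default | rationale |
| --- | --- | --- |
| genes | 2,000 | desk-scale transcriptome |
| replicates | 3 per fraction per condition | small-n regime typical of IP studies |
| library sizes | 150–250 k fragments | a deep (~20 M) design scaled down 100× |
| baseline expression | log-normal(0, 1) relative abundances | long-tailed expression |
| dispersion | φ ~ 0.05·lognormal(0, 0.3) | typical biological overdispersion |
| planted effects | +2 log2, 300 genes per non-invariant group | clearly enriched but not trivial at these depths |
| relocated share | 75% of the gained group also enriched in wild type | mirrors the observed overlap regime |
| lengths | log-normal(7.2, 0.6) nt; commonly enriched shifted +0.5 | plants the length confounder |
| methylation | base rate 11% at median length, +1.1 logit per log2 length, +1.55 logit for relocated | reproduces the ≈11% / ≈22% / ≈37% invariant/common/relocated regime |
| sequence bias | enriched groups G/C-shifted (A,C,G,T = .22,.26,.30,.22 vs .27,.23,.23,.27) | detectable 4-mer signal with analytic expectations |

IP counts multiply the baseline by 2^effect and renormalize, so the
compositional distortion of real IP libraries is present in the
simulation and the normalization has to earn its keep. IP and input
replicates are independent (no pairing), matching the unpaired factorial
model downstream. Sequences are i.i.d. draws from per-group nucleotide
compositions, so every k-mer's expected fold change is a product of base
ratios — the planted truth for ranking checks. A `noise_seed` redraws
counts while keeping the planted truth fixed, which is how replicate
experiments of one truth are produced for the convergence analysis.

What the generator does **not** emulate: positional coverage and
read-level artefacts, isoform structure, paired IP/input samples,
IP-efficiency variation (no spike-in or efficiency normalization is
modelled), Markov-order sequence structure beyond composition, and
peak-level methylation (flags are gene-level Bernoulli). Passing tests
therefore show that the statistics recover what was planted under NB
noise and compositional distortion — not that every artefact of real
libraries is handled.

## Determinism

Every stochastic stage takes an explicit seed recorded in the JSON run
manifest; the pipeline derives stage seeds from one master seed, writes
no timestamps, and reruns of an unchanged configuration are served from
cache (keyed by a config checksum) or reproduce byte-identical outputs
when forced.

## Scale choices

The bundled scenarios (2,000 genes; 6,000 for the convergence study;
10⁴ draws for thinning moments) keep the full suite and the acceptance
script in the tens of seconds on one CPU while leaving Monte-Carlo
bands tight enough for the calibration and recovery checks.

## Known limitations

- The NB engine uses Wald tests with moment/trend dispersion, not
  quasi-likelihood F-tests or Cox–Reid-adjusted likelihoods; it is
  validated against exact oracles and planted truth, not against any
  external package's output.
- Genes present in counts but absent from the annotation stay in the
  tested universe but cannot pass FPKM-dependent filters.
- The expressed-gene universe for overlays defaults to expressed-only
  stratification; group assignment itself partitions the full tested
  universe.
- The exact Mann–Whitney enumeration is limited to n ≤ 8 per group
  (C(16,8) assignments); larger groups use the asymptotic test.
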