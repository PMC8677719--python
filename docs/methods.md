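# Methods

This note records the models, conventions and numerical choices behind each
stage of the package, what the synthetic generators do and do not emulate,
and the design decisions taken where the procedure left room.

## PBM binding profiles

A protein-binding microarray reports a fluorescence value per probe; the
pipeline starts downstream of spatial averaging/correction, from per-probe
intensities.  Processing order is fixed: quantile normalization across
replicate arrays → median over the (eight) replicate probes of each unique
sequence → z-transformation.

**Quantile normalization.**  The value at rank r in each array is replaced
by the mean over arrays of the rank-r values.  Tied values within one array
receive the mean of their tied ranks' row means.  On tie-free data (the
almost-sure case for continuous fluorescence) the procedure leaves all
arrays with one common sorted multiset and is idempotent; exact ties break
both properties by a bounded amount because the tie rule averages within a
single array.  The implementation requires ≥ 2 arrays over identical probe
sets.

**z-scores.**  z = (ln F − μ)/σ with μ, σ the mean and *population*
(divide-by-n) standard deviation of ln F over the random-background probe
set only.  Natural log is used; since μ and σ are computed on the same
scale, the base cancels and the choice is purely a reproducibility
convention.  Whether the original procedure used population or sample sd is
not documented anywhere we know of; the population form is fixed here and
the difference is O(1/n) with n ≈ 1100 background sequences.  Background
z-scores therefore have mean 0 and sd 1 exactly (tested to 1e-9).

**Profile comparison.**  OLS of z₂ on z₁ over shared sequences, with R² the
squared Pearson correlation on the retained pairs.  The published exclusion
rule ("excluding z-scores lower than 2") does not say which axis it applies
to; the default retains a pair if *either* profile reaches z ≥ 2, which
keeps every point that is bound in at least one experiment.  `both` and
`first` are available.  Fewer than 3 retained pairs is an error, not a
degenerate fit.

## Motif construction

The array's binding sites are fixed-width and pre-aligned by design, so the
motif is built by straight column counting over the k = 25 highest-z
non-background sequences — no EM or Gibbs discovery step.  Ties in z are
broken by ascending lexicographic sequence order for determinism.
Frequencies use a background-apportioned pseudocount,

    f[b][j] = (count(b, j) + c·bg[b]) / (n + c),   c = 0.1 by default,

small enough not to blunt a 25-site matrix, large enough to keep log-odds
finite.  The PWM is log2(f/bg) (bits); information content per column is
Σ_b f log2(f/bg), which reduces to 2 − entropy for a uniform background.
Motifs are written and read in MEME minimal text format (version 4);
sequence logos are not rendered, only the underlying IC vector is computed.

## Upstream window extraction and scanning

Coordinates are 0-based half-open internally; GFF3 is converted from
1-based closed on input, BED is native.  The TSS is the strand-aware 5'
end of the `gene` feature.  For a + strand gene the window is genomic
[tss−w, tss); for a − strand gene it is (tss, tss+w] reverse-complemented,
so every window reads 5'→3' toward the TSS and offset w−1 abuts the TSS.
Windows truncated at contig edges are kept and logged; empty windows are
skipped with a warning.

**Exact p-values.**  The null model is an i.i.d. background sequence.  PWM
entries are rounded onto an integer grid of 1000 steps spanning the
achievable score range, and the exact distribution of the integer total is
built by dynamic programming over motif positions (cost 4·w·bins).  Query
scores are quantized with the same per-entry rounding, which makes hit
calls and p-values mutually consistent by construction; the residual
discretization error on any total score is below width × step.  P(S ≥ s) is
monotone non-increasing in s by construction.

**Scanning.**  Both strands are scored at every offset; the minus-strand
statistic scores the forward sequence with the reverse-complemented matrix,
whose null distribution is computed separately (it differs from the forward
one when the background composition is asymmetric).  A position is a hit at
p ≤ 10⁻⁴ per strand per position — the conventional FIMO default, declared
rather than inferred.  When both strands pass at one offset the site is
counted once (better-scoring strand reported); for a palindromic κB-type
motif this prevents systematic double counting.  Ambiguity codes (N) score
−∞ and can never be hits.

## Stage concordance filter

Mean FPKM per stage (arithmetic mean over replicates), then two
deterministic rules in order: discard genes with zero mean in *any* stage
("not expressed in a given life stage"; the laxer all-stages-zero reading
is available as an option), then keep genes whose means increase strictly
along the declared stage order.  Ties fail the strict ordering
("lowest/medium/highest" implies strict ranks); a non-strict option exists.
Zeros are tested on stage means, not individual replicates, matching
per-stage summarized tables; this too is configurable.  The filter is
order-invariant in genes and replicates and commutes with any strictly
increasing value transform fixing 0 — both properties are tested, along
with equality to a brute-force per-gene reimplementation on 10⁴-gene
random tables.

## Overrepresentation

One-sided upper-tail hypergeometric test per category:
p = P(X ≥ k), X ~ Hypergeom(N, K, n), computed via `scipy.stats.hypergeom`
and verified against full tail enumeration for N ≤ 30.  Fold enrichment is
(k/n)/(K/N), so fold > 1 ⇔ overrepresentation exactly.  BH adjustment is
delegated to statsmodels.  The universe is a caller decision (all genes vs
annotated-only); category members outside the declared universe are
ignored, selected genes outside it are an error.  No ontology structure
(DAG propagation, term collapsing) is modeled.

## Reporter arithmetic

Luciferase: within each independent experiment, triplicate readings are
averaged and divided by that experiment's control mean; the per-experiment
folds are then averaged and reported with SE = s/√n, where s is the sample
(n−1) standard deviation over experiments.  The normalize-then-average
order is fixed; it makes the statistic invariant to any common rescaling
within an experiment.  Sample sd is a convention choice (the source
equation says only "sample standard deviation" of unstated ddof context);
ddof = 1 is conventional for experiment-level SE and documented here.
β-galactosidase: Units = 1000·OD415/(V·t·OD595) with V in ml and t in
minutes; linear in OD415 and inversely linear in each denominator term.

## Synthetic data

One root seed; each generator draws from an independent child stream keyed
by stage name, so regenerating one input never perturbs another and equal
seeds give bit-identical outputs.

* **Truth motif**: the 10-bp κB palindrome GGGAATTCCC with probability 0.85
  on the consensus base per column (rest spread evenly).  The palindrome is
  the canonical κB probe sequence and deliberately exercises the scanner's
  same-offset strand deduplication.
* **PBM**: 36-bp probes with the site centered, mirroring a fixed-design
  binding-site array.  Bound probes embed a site *sampled* from the truth
  PFM; log-fluorescence is baseline + affinity_scale · max(0, best
  log-odds over the probe) + N(0, noise_sd), background probes get baseline
  + noise.  Defaults: 2592 bound / 1159 background unique sequences, 8
  replicate probes, 2 arrays, affinity_scale 0.5, noise sd 0.2 (log units).
  The figure-scale background count 1159 is a parameter, not a constant
  (published counts for the same array differ between 1159 and 1195).
* **Expression**: 8674 genes, three stages, triplicate.  Per-gene scale is
  lognormal (median 10 FPKM, sd 1 log unit).  Concordant genes
  (default fraction 0.155) take strictly increasing stage means with
  stepwise factors U(1.3, 3); the driver gene sits at exact ratios
  (1, 2.3, 5.0); all other genes get a random non-increasing permutation of
  such a triple.  Replicates multiply the stage mean by lognormal noise.
  Zero inflation (default 5% of gene×stage cells) zeroes *all* replicates
  of a cell, matching the zero-discard semantics of the filter; the driver
  is exempt, and zero-inflated concordant genes are removed from the truth
  concordant set since the filter cannot recover them by construction.
* **Promoters**: one contig per gene (uniform base composition), random
  strand, with 0–4 non-overlapping consensus implants inside the 500-bp
  window; GFF3/BED models are written so that window extraction returns
  exactly the generated promoter.  Implant offsets are recorded in window
  coordinates.
* **Categories**: n random categories (default 20, sizes 40–80) plus one
  whose members are sampled with selection odds multiplied by
  enriched_category_effect (default 5) for truth-concordant genes; effect 1
  makes it exchangeable with the null categories.

What the generators do **not** emulate: microarray spatial artifacts,
probe-sequence composition bias, read-level RNA-seq (only FPKM tables),
correlated replicate noise, real promoter base composition or chromatin
context, and ontology-structured category overlap.  Passing recovery tests
therefore demonstrates correctness of the computations under the stated
statistical model, not robustness to the artifacts a real dataset adds
upstream of this pipeline.

## Numerical and testing notes

* Score-grid bins: 1000, capping discretization error while keeping the DP
  a few-millisecond operation at width 10.
* The null-uniformity check of the hypergeometric test runs 200 replicate
  simulations with a 3000-gene universe and category sizes 300–600: the
  p-value of a hypergeometric test is discrete, and these sizes keep its
  support dense enough that a continuous-uniform KS reference at α = 0.01
  is a fair comparison.  The sizes were fixed from this support-density
  argument, not tuned.
* Test problem sizes (10⁴ sites for motif recovery, 10⁴-gene oracle
  tables, 50-gene promoter bundles, 100 scanner-oracle windows) keep the
  default suite under a minute while leaving estimation error well inside
  the asserted tolerances.
* `scripts/acceptance.py` runs the full chain at study scale (8674 genes,
  3751 unique probe sequences) in a few seconds; all randomness derives
  from the `--seed` argument.

## Known limitations

* Profile round-trip through TSV preserves z-scores but not the raw μ/σ of
  the background (z is already standardized); re-derived profiles report
  standardized moments.
* The scanner's p-values condition on the declared background composition;
  it does not estimate the composition from the scanned sequences.
* The concordance filter is deterministic by design — no dispersion
  modeling or differential-expression inference.
* Quantile normalization's multiset/idempotence identities hold exactly
  only for tie-free data (see above).
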