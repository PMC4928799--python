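# Methods

## The question the pipeline answers

Given lists of genes differentially expressed between two conditions in a
reference organism (here, honey-bee brain gene sets tied to social
behavioural phenotypes), are those lists enriched or depleted in *widely
conserved* genes? Conservation is defined operationally: a gene's
conservation is the number of panel species in which it has at least one
ortholog. The pipeline takes orthology calls as input (InParanoid- or
OrthoMCL-style cluster exports); it never infers orthology itself.

## Statistics

### Subset-resampling null

For a mapped gene set of size n drawn from a population of N genes, the
observed statistic is either the set's mean ortholog count or, per
species, the number of set genes with an ortholog in that species. The
null is simple random sampling: R sets of size n drawn uniformly without
replacement from the N genes, the statistic recomputed for each. The
enrichment p-value is the fraction of resamples whose statistic is
**greater than or equal to** the observed one (closed inequality); the
depletion p-value uses ≤. Consequences:

* p-values are integer multiples of 1/R, and p_enrich + p_deplete ≥ 1;
* a zero tail count is reported as p = 0 with a `below_resolution` flag,
  printed "< 1/R", and floored at 1/R before any log-based combination;
* mean comparisons are done on integer sums at fixed n, so ties are exact.

When C(N, n) ≤ an exactness threshold (default 20 000) the sampler is
replaced by exhaustive enumeration of every subset; sampled and exact
p-values must agree within the binomial Monte-Carlo error, which the test
suite checks. One resampling pass scores **all** species (the same random
sets are reused across the 54 per-species tests); per-species draws are
therefore shared, not independent, which changes nothing about each
marginal p-value.

The default R is 10^6, the resolution used when this statistic is run at
publication scale. The test suite and the acceptance script use R between
500 and 10^5 with correspondingly widened Monte-Carlo tolerances; the
problem sizes actually used are stated in each test.

Sampling is implemented as a chunked partial-sort of uniform random keys
(argpartition over an R_chunk × N key matrix), which draws exact uniform
without-replacement samples in O(N) per resample.

### Benjamini–Hochberg

Step-up FDR adjustment (`bh_adjust`, backed by statsmodels) is applied in
two families: across species within each set's per-species vector, and
across sets for the set-level p-values. Both raw and adjusted values are
always emitted, because a set can be called enriched on either scale and
the choice is left to the reader of the output tables.

### Two-sample Kolmogorov–Smirnov

D is the maximum absolute gap between the two right-continuous empirical
CDFs evaluated at every distinct pooled value. This tie-handling
convention makes D = 1 exactly when the two samples' ranges are disjoint
and D = 0 for identical multisets. The tail probability is the classical
asymptotic series with finite-sample correction

    Ne = n1·n2/(n1+n2)
    λ  = (√Ne + 0.12 + 0.11/√Ne)·D
    Q(λ) = 2·Σ_{j≥1} (−1)^{j−1} e^{−2j²λ²}

truncated when a term falls below 1e-8 of the partial sum (or below 0.001
of the previous term), clamped to [0, 1], with Q(0) = 1 and Q = 1 returned
when the series has not converged by j = 100 (which only happens where the
true tail is 1 to within the truncation error). The asymptotic formula is
used even at clade sizes of 10 vs 17 because that is the published
convention for this analysis; `ks_permutation_p` provides an exact or
Monte-Carlo permutation tail for cross-checking, but it is not the
default. The suite verifies Q against a 2000-replicate null simulation at
n1 = n2 = 50 (±0.02 at the 10% and 5% points) and D against brute-force
ECDF scans.

### Fisher's combined probability

k independent p-values combine via X² = −2·Σ ln p ~ χ²(2k); the combined
p is the chi-square survival at X². Inputs must lie in (0, 1] — resampling
zeros are floored at 1/R by the caller. For the three colony-vs-worker
genotype KS p-values printed for this analysis (0.026, 0.122, 0.612) the
combined value is 0.0519, which the suite pins against the independently
evaluated even-df closed form e^{−x/2}·Σ_{i<k}(x/2)^i/i! to 1e-10.

### Term over-representation

Hypergeometric upper tail by default; the EASE variant (remove one study
hit before taking the tail; p = 1 when k ≤ 1) is available because the
published analysis used a tool built on it. EASE ≥ hypergeometric for
every margin. The background defaults to population genes carrying at
least one term; `background="all"` uses the whole population. Up,
down, and combined study sets are three independent BH families.
Agreement with any external annotation tool's printed p-values is *not* a
goal: those depend on that tool's background universe and annotation
snapshot. Correctness is instead established against exhaustive
enumeration of all draws on small margins.

### Clade-conserved subsets

"Conserved in a clade" means present in **every** clade species
(intersection). A quorum parameter (default 1.0) can relax this to a
fraction of the clade, since the intersection reading, while the natural
one, is not the only defensible choice. Direction labels survive the
subset and the subsequent up/down partition.

## Synthetic data generator

The generator emulates the study population so the full pipeline runs
and is testable without any downloads:

* **Panel**: 54 counting species — arthropoda (17), eutheria (10), other
  metazoa (26), yeast (1) — plus a non-counting reference organism. The
  arthropod count is configurable because the real panel's exact clade
  membership is panel-file data, not a constant.
* **Matrix**: each of 7462 genes is independently assigned a conservation
  class with probabilities (0.05, 0.35, 0.60) — lineage-unique,
  clade-conserved, ubiquitous — and presence per species is an independent
  Bernoulli: clade-conserved genes are present with probability 0.95
  inside the focal (arthropod) clade and 0.02 outside; ubiquitous genes
  with 0.93 everywhere; unique genes nowhere. The yeast outgroup caps the
  ubiquitous presence probability at 0.5, reflecting its role as a
  deep-split control. These defaults put the count-histogram modes at 0,
  ≈17 and ≈50 of 54, the trimodal shape characteristic of such scans.
* **Gene sets** are drawn without replacement with weight
  exp(β·count): β = 0 is an exact uniform null (used for type-I
  calibration), β > 0 plants conservation enrichment. The sampler uses
  Gumbel keys, which realises Plackett–Luce successive sampling exactly;
  the test oracle enumerates that model on a 10-gene population.
* **Annotation**: random term→gene maps plus optionally planted terms
  with exact memberships, and a random-tree parent table (acyclic by
  construction).

One global seed feeds named substreams (classes, matrix, sets,
annotation) so artifacts can be regenerated independently.

What the generator does **not** emulate: phylogenetically correlated
presence (no gene birth–death process along a tree), in-paralog
multiplicity, expression values, or realistic GO topology. Passing tests
therefore demonstrate statistical correctness of the machinery and
recoverability of planted signal, not biological realism of any
particular dataset.

## Numerical and design choices

* Presence, not ortholog multiplicity, is stored: per-gene counts max out
  at the species count, matching the published histogram's x-axis range.
* ID mapping is many-to-one; ambiguous platform IDs (one source, two
  targets) are rejected at parse with a logged count, and two sources
  hitting one target collapse to a single matrix row so set statistics
  never double-count a gene.
* Set summary SD uses the population divisor n (`ddof=0`), configurable;
  the divisor convention of the printed tables is not documented, so it
  is exposed rather than hidden.
* Result files are byte-deterministic: fixed column orders, floats at six
  significant digits, no timestamps in the manifest; a pipeline run is
  assembled in a temporary directory and moved into place atomically, so
  a failed stage leaves no partial bundle.
* The set-level output table carries both raw and BH-adjusted resampling
  p-values because the published analysis cites both without stating
  which backed each significance call.

## Known limitations

* The per-species resampling reuses one draw pool across species; p-value
  *vectors* across species are therefore correlated in a way independent
  draws would not be (each marginal p-value is unaffected).
* The asymptotic KS tail is anti-conservative for very small samples;
  use `ks_permutation_p` when that matters.
* The resampling p-value has resolution 1/R; downstream Fisher
  combinations of floored zeros are upper bounds.
* The independent-Bernoulli generator cannot produce correlated presence
  patterns (e.g. whole-clade losses), so tests on synthetic data say
  nothing about robustness to phylogenetic correlation in real orthology
  tables.
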