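# Methods

## Counting model

Each gene is analyzed from a codon alignment of n ingroup strains
(default expectation 15, matching a typical *D. melanogaster* population
sample) and two outgroups filling the *D. simulans* and *D. yakuba*
roles.  Every column is classified independently:

* **Polymorphism** — two or more bases segregate among the ingroup
  strains.  Each derived allele relative to the ancestral base
  contributes one polymorphism (so a tri-allelic column can contribute
  two), preserving count additivity.
* **Fixed difference** — the ingroup is monomorphic and its base differs
  from the base carried by *both* outgroups.  Requiring outgroup
  agreement polarizes the change onto the ingroup lineage; columns where
  the outgroups disagree are excluded from divergence counting (they
  remain eligible as polymorphisms).  An `unpolarized` mode counts
  pairwise differences against the first outgroup alone, for comparison
  with unpolarized MK analyses.
* **Synonymous vs nonsynonymous** — decided by translating the ancestral
  codon with only the focal base swapped (standard genetic code).  Codons
  with several changed positions are therefore classified site by site in
  ancestral context, which is deterministic and avoids enumerating
  mutational pathways.  At context positions where the outgroups disagree
  or are missing, the ancestral base falls back to the ingroup majority
  (ties broken alphabetically); this choice only affects the rare columns
  that are already partially unpolarizable.
* **Exclusions** — any N or gap in any ingroup strain excludes the whole
  codon (keeping the polymorphism sample size constant at n strains); an
  N/gap in an outgroup excludes only divergence classification at that
  codon; columns whose ancestral or derived codon is a stop are excluded.
  `n_codons` counts codons with at least one non-excluded position.

Coordinates are 0-based internally; the alignment frame is assumed to
start at the first position (no frame search).

## Per-gene statistics

**DoS** = D_N/(D_N+D_S) − P_N/(P_N+P_S), undefined (stored as NaN) when
either denominator is zero; undefined genes stay in the tables and are
skipped by every mean/bootstrap consumer.

**MK test** — the inclusive upper hypergeometric tail P(X ≥ D_N) of the
2×2 table with margins fixed, computed through `scipy.stats.hypergeom.sf`
(log-space-safe, no underflow for large tables).  This one-tailed
orientation asks specifically for an excess of nonsynonymous divergence,
the signature of recurrent positive selection.  An all-zero table returns
p = 1.

**Power filter** — the default reads "marginal counts" as the four
margins of the 2×2 table (row sums D_N+D_S, P_N+P_S and column sums
D_N+P_N, D_S+P_S), requiring each ≥ 6.  A `cells` variant applies the
same threshold to the four cells instead; the two rules genuinely
disagree (e.g. a table with D_N=5, D_S=26, P_N=0, P_S=62 passes neither
margin rule nor appears powered under cells), and both are exposed
because contingency-table usage supports either reading.

**π0 and FDR** — the default π0 estimator targets *conservative* tests,
whose null p-values are stochastically larger than uniform (the exact
test's discreteness guarantees this): π0 = min(1, 2·mean(p > 0.5)),
reasoning that half of a uniform null's mass lies above 0.5 while
alternatives contribute almost nothing there.  A Storey λ-grid estimator
(π0(λ) = #{p>λ}/(m(1−λ)) smoothed with a cubic polynomial and read off at
λ = 0.95) is available as `method="storey"`.  The FDR at threshold α is
min(1, π0·m·α / #{p ≤ α}), undefined when nothing is rejected.

## Gene-set bootstrap

For a phenotype's N significant genes, the observed mean DoS (over
members with defined DoS) is compared with the means of R random N-gene
samples drawn **without replacement** from the genes with defined DoS —
without replacement because a real phenotype set cannot contain a gene
twice, and defined-only because the observed statistic is computed on
defined values.  Default R = 10,000.  The decision is two-tailed against
the central 95% interval [2.5%, 97.5%] of the null; an `asymmetric`
literal reading (reject only above the 97.5% quantile) is available via
`two_sided=False`.  The empirical p-value is 2·min(Pr(null ≤ obs),
Pr(null ≥ obs)) with inclusive ties (conservative), capped at 1.
Sampling is vectorized: each replicate ranks independent uniform keys and
takes the N smallest, an exact without-replacement draw, chunked to bound
memory.

## Pleiotropy

A gene's pleiotropy is the number of *distinct* functional categories
(CR, SR, IS, GR, TE, IM, HY) among the phenotypes it significantly
affects; several phenotypes in one category count once.  "Adaptive"
defaults to MK p < 0.01 among powered genes.  The enrichment test pools
genes with ≥ 2 categories against single-category genes in a one-tailed
(upper) Fisher's exact test on the adaptive-by-multi 2×2 table.
Mann–Whitney U comparisons of DoS across pleiotropy classes are
two-sided; with both groups ≤ 8 the p-value is exact (full enumeration of
splits, ties mid-counted in U, p = min(1, 2·min tail)); larger samples
use the tie-corrected normal approximation.  A least-squares regression
of category count on codon count (r², slope p) screens for the
longer-genes-have-more-power artifact.  Per-(gene, phenotype) effect
directions (sign of Z) are exported as a long-format table for tile
plots; no statistics are computed on them.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes,
not population-genetic realism (no coalescent genealogies, recombination,
linked selection or demography):

* **Count tables** — D_N, D_S, P_N, P_S are Poisson with
  gene-length-proportional means, split 3:1 nonsynonymous:synonymous
  (an approximate codon-table opportunity average; only relative rates
  matter for DoS).  Defaults: `theta_poly = 0.04` and `lambda_div = 0.04`
  per codon with gene lengths uniform on 100–1500 codons, matching the
  per-codon polymorphism and divergence densities visible in published
  per-gene *D. melanogaster* count tables (tens of segregating and fixed
  sites for a ~1,000-codon gene).  Because the nonsynonymous proportion
  is identical for divergence and polymorphism in neutral genes, their
  expected DoS is exactly zero (binomial conditioning on the totals);
  adaptive genes multiply the nonsynonymous divergence rate by
  `adaptive_boost` (default 5).
* **Alignments** — an ancestral sequence of uniform sense codons carries
  planted events: fixed events put the derived base in all ingroup
  strains, polymorphic events in a uniform-size nonempty proper subset;
  both outgroups keep the ancestral state, so polarization always
  succeeds and the planted event list is an exact oracle for the counter.
  Events at distinct sites are classified in ancestral context exactly as
  the counter classifies them, hence recovery is exact by construction —
  this is what makes the planted-truth tests sharp.
* **Screens** — Z ~ Normal(0, 1) noise, Normal(effect, 1) for planted
  effect genes.

What passing tests on these data do *not* show: robustness to alignment
error, to unequal mutation rates across sites, to non-equilibrium
demography (which skews the site-frequency spectrum and hence P_N/P_S),
or to biased gene conversion — all of which affect real MK analyses.

## Pipeline determinism and sizes

One master seed fixes every stage seed via
`sha256("{seed}:{stage}") mod 2^31`, so reruns are byte-identical and
stage results are independent of execution order; parallel counting
(`--threads`) cannot change results because outputs are collected in
sorted file order.  The manifest records parameters, seed and per-stage
row counts, with no timestamps.

Test and acceptance problem sizes are chosen to make the checks sharp at
interactive runtimes: 2,000-gene genomes for calibration (Monte-Carlo
standard error ~0.005 on a rejection rate of 0.05), 400 random sets ×
1,000 bootstrap replicates for the type-I check (the 99% binomial band
at 400 trials comfortably exceeds the O(1/R) quantile noise), and 1,000
random alignments for exact planted-truth recovery.

## Known limitations

* Polarization by two-outgroup agreement ignores homoplasy and
  back-mutation on outgroup lineages; deeply diverged outgroups inflate
  the excluded-column fraction.
* The per-site ancestral-context classification undercounts multi-hit
  codons relative to pathway-enumeration methods; both are approximations
  and the difference is negligible at *melanogaster*-scale divergence.
* The conservative π0 estimator is intentionally upward-biased for
  non-conservative tests; use `storey` when p-values are approximately
  uniform under the null.
* The exact Mann–Whitney path enumerates C(n1+n2, n1) splits and is
  limited to groups of ≤ 8 by default.
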