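# Methods

## Setting and assumptions

The package targets small tumor-sequencing cohorts (order 10 samples, one per
patient) with somatic variants called by two independent pipelines and
copy-number calls reported at cytoband resolution. Three modeling assumptions
run through everything:

1. **Presence/absence suffices for the phylogeny.** Variants are clonal within
   a tumor; allele fractions are used only to decide presence (VAF ≥ threshold),
   not to deconvolve subclones. There is no cellular-prevalence or CCF model.
2. **Consensus defines reliability.** A variant is reliable when both callers
   report it (positional identity `(chrom, pos, ref, alt)` where available,
   raw identifier otherwise). Read counts in a consensus record come from the
   declared primary caller; counts are never merged, since the two callers'
   depths are not commensurable.
3. **Cytobands are labels, not intervals.** CNV sharing is exact label
   equality by default ("20p" and "20p13" are different regions); an optional
   arm-containment query mode exists but is off, because containment semantics
   are not derivable from cytoband strings alone.

## The tree criterion

For a presence matrix over samples `S`, the aggregated variant count of a
rooted binary leaf-labeled tree `T` is the number of variants whose carrier
set equals some clade of `T`. This realizes the iterative trunk-then-split
narrative of shared-variant tree building: the variants shared by all samples
form the base (carrier set = `S` = root clade), each split creates two clades
that collect the variants carried by exactly that subset, and elimination is
automatic because a variant's carrier set equals at most one clade. An
alternative reading — counting variants carried by *at least* all members of
a clade — was considered and rejected: it counts a shared variant once per
compatible clade, rewarding spurious extra splits, and makes the perfect
phylogeny non-uniquely optimal.

Properties the tests verify:

* `score(T) ≤ #variants`, with equality iff the carrier sets are laminar;
* private and trunk variants are assigned under every topology, so only
  variants with 2..n−1 carriers discriminate between trees;
* summed over all non-empty sample subsets, clade weights partition the
  variant total (every carrier set is some subset).

## Exact search

`best(C) = w(C) + max over bipartitions of C` is evaluated over all subsets
by bitmask DP; submask enumeration makes the total work O(3^n) (n = 10 →
~59k bipartition evaluations). The tree is reconstructed by backtracking.
For n ≤ 6 an explicit generator of all (2n−3)!! topologies (15 at n = 4, 105
at n = 5) provides the independent optimum to compare against; the DP and the
enumeration are separate code paths sharing only the weight function.

**Tie-breaking.** Among co-optimal bipartitions the half containing the
lexicographically smallest sample is the first child, and the candidate with
the lexicographically smallest first-child sample tuple wins; children are
ordered by smallest leaf at serialization. Identical matrices therefore give
byte-identical Newick output regardless of input row/column order. A
`report_all` mode returns every argmax topology instead.

**Degenerate inputs.** Samples with no variants after filtering stay in the
tree (a warning is emitted; canonical order decides where they attach, since
no placement changes the score). More samples than `max_exhaustive_n`
(default 12) is an error advising a higher VAF threshold, not a silent
approximation.

## Presence thresholding

A call is present when its VAF is ≥ `af_threshold` (default 0.05, inclusive
at the boundary; configurable). Records without read counts are treated as
present — a caller that reports no depths still reported the variant. Raising
the threshold can only remove presence calls (a property test).

## Mutation summaries

Substitutions are folded onto the pyrimidine reference frame (G>A → C>T,
etc.), giving the conventional six classes of which C>T and T>C are
transitions. Kataegis is operationalized as a maximal run of ≥ 6 consecutive
SNVs on one chromosome with mean inter-mutation distance ≤ 1000 bp — the
standard rainfall-plot criterion; the term needs an operational definition to
make "no kataegis found" a computable statement. Demographic SDs use the
sample (n−1) estimator, which reproduces the published 16.5-year age SD
(population SD would give 15.7). The diameter SD computes to 13.05 mm,
printed upstream as "± 13"; at one decimal this package reports 13.1.

## Fisher and t tests

The two-sided Fisher p sums hypergeometric point probabilities ≤ the observed
table's (relative tie tolerance 1e−7) over the full margin-fixed support —
the point-probability convention of the common statistics packages. The t
test defaults to pooled-variance Student (Welch by flag). No multiplicity
correction is applied; every result carries an `uncorrected` tag. Degenerate
margins (e.g. a gene carried by all samples) are flagged untestable rather
than dropped.

## Synthetic cohort generator

The generator emulates the data-generating process end to end: a uniform
random rooted binary topology by recursive random bipartition; a fixed trunk
variant count (default 10) with Poisson counts per internal edge (mean 4) and
per leaf (mean 3); substitutions drawn with transition fraction 2/3
(transition-dominant, as exome spectra typically are) and variant classes
from a missense-heavy weight table; per-site depth Poisson with mean 100 (the
targeted coverage in this setting) and carrier mutant reads
Binomial(depth, 0.4) — a clonal heterozygous variant at moderate purity.
Non-carriers draw Binomial(depth, 0.001) background; a non-carrier record is
emitted only when ≥ 1 mutant read occurred, since a caller needs evidence.
Each of the two simulated callers independently drops true calls with
probability `fn_rate` (default 0.05) and adds Poisson(`fp_rate`=2) false
positives at VAF uniform in [0.01, 0.04] — below the default presence
threshold by construction, so thresholding (not bookkeeping) removes them.
Clinical covariates are drawn around the published cohort's age/diameter
distributions, with optional planted gene→feature effects for power checks.
The CNV matrix plants 44 gain and 72 loss cytoband columns (the counts
reported for this tumor family), one gain shared by every sample.

`min_edge_variants` floors the per-edge variant count; recovery checks use
`min_edge_variants=2` because topology identifiability requires every edge to
be marked — an edge with no variants is legitimately unrecoverable and any
resolution of it is score-equivalent.

What the generator does **not** model: subclonal structure, read-level errors
beyond the binomial, mutational-signature context, CNV–SNV interaction,
caller-specific biases. Passing tests therefore demonstrate correctness of
the algorithms under clonal, well-calibrated noise — not robustness to every
artifact of real FFPE exomes.

## Problem sizes used in the acceptance run

The acceptance script compares the DP against the enumeration oracle on 200
random matrices (n ∈ {3,4,5}, up to 15 variants), checks noise-free recovery
over 50 simulated 6-sample cohorts, calibrates the Fisher test on 500 random
tables (totals ≤ 30) and 2000 simulated null cohorts of 10 samples, and runs
the kataegis scan on planted clusters and a 10-sample simulated cohort.
These sizes give tight Monte-Carlo error on every rate while keeping the run
in the seconds range.

## Known limitations

* The tree search is exponential by design (exact); cohorts beyond ~12
  samples need pre-filtering rather than this search.
* The aggregated-variant-count criterion ignores how *many* reads support a
  variant once it passes the threshold; borderline VAFs near the threshold
  flip presence calls discretely.
* Association tests on 10 samples have very low power; the screen is
  exploratory and intentionally uncorrected.
* Published association p-values for this cohort depend on feature
  definitions (e.g. "tumor mass", "recurrence") that are not derivable from
  the printed clinical table; the package does not claim to reproduce them.
* The group-level CNV fixture stores both 17q12 and 17q22 for the silent
  adenomas because the source lists both labels for the same shared pattern;
  queries treat them as distinct regions.
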