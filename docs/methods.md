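# Methods

## The generative model

Each locus is an independent realization of a two-population isolation
model. Time is measured in expected substitutions per site, so that the
mutation rate never appears separately: a population with mutation-scaled
size θ = 4Nμ gives a pair of lineages an exponential coalescence time with
mean θ/2, i.e. pairwise rate 2/θ. Going backward from the present, the
2n lineages sampled in each population (two per diploid) coalesce within
their population at rate k(k−1)/θᵢ until the divergence time τ; all
surviving lineages then enter a single ancestral population with rate
k(k−1)/θ_A and coalesce to the root. Consequences used throughout as test
oracles:

- with τ = 0 and equal θ the model is one panmictic population and a
  pair's expected TMRCA is θ/2;
- a between-population pair has branch separation b = 2τ + 2T with
  T ~ Exp(mean θ_A/2), so E[b] = 2τ + θ_A;
- no between-population pair can coalesce before τ.

Mutation is finite-sites Jukes–Cantor: each branch of length b receives
Poisson(bL) events, each substituting a uniformly chosen different base at
a uniformly chosen site. Multiple hits are therefore possible and raw
distances saturate toward 3/4, matching the JC-corrected distances used
downstream; the infinite-sites model was rejected for exactly this
consistency reason. For a fixed separation b the per-site difference
probability is q(b) = (3/4)(1 − e^(−4b/3)), which the simulator tests
verify by Monte Carlo.

A locus is paralogous with probability `paralog_fraction`. The duplicate
copy's ancestral sequence is the original root sequence mutated by
Poisson(`paralog_divergence` × L) events, after which the copy evolves on
its own, independently simulated genealogy — so under-splitting inflates
within-locus diversity realistically rather than adding a frozen offset.
Both copies emit reads for every individual.

Reads are emitted forward-orientation, full-length (RAD loci are anchored
at the restriction site), Poisson(`depth_mean`) per haplotype copy, with
independent per-base substitution errors at `error_rate` and a constant
placeholder quality string. Randomness flows from a single seed through
per-locus `SeedSequence(seed, spawn_key=(locus,))` substreams, so
enlarging `n_loci` extends a dataset without reshuffling earlier loci and
identical parameters give byte-identical output.

What the generator does **not** emulate: PCR duplicates, allele dropout
from restriction-site polymorphism, indels, quality-score structure, more
than two populations, or gene flow after τ. Passing tests therefore show
that the *assembly-induced* biases are reproduced and measured correctly
under idealized sequencing; they do not certify behaviour under
library-prep artifacts.

## Assembly

The mismatch budget is M = ⌊L(100−s)/100⌋, which reproduces the standard
anchors at L = 100 (s = 93 → 7 mismatches, s = 99 → 1). The pipeline per
individual: dereplicate reads into stacks → drop stacks with depth < m
(no secondary-read rescue) → cluster stacks whose consensi are within M
mismatches → call up to `max_alleles` alleles ranked by (depth desc,
sequence asc), recording the pre-truncation count so the excess-allele
paralogy filter still fires. Across individuals, loci merge when the
minimum Hamming distance between their allele sets is ≤ M (the
within-individual and across-individual budgets are exposed separately but
default to the same value).

Clustering is **connected components** of the ≤M-mismatch graph, not the
depth-ordered greedy matching of the original stack assemblers. This is
deterministic, independent of input order, exactly checkable against a
brute-force all-pairs oracle, and makes stringent partitions provable
refinements of liberal ones. Components are found with exact pigeonhole
banding: the read is cut into M+1 contiguous blocks, any pair within M
mismatches must match exactly in some block, so hash buckets per block
yield every candidate pair without the O(n²) scan; candidates are verified
by direct mismatch count. All ties (allele ranking, consensus choice,
component ordering) break lexicographically so assemblies are
byte-reproducible. No gapped comparison exists anywhere in the package:
reads are fixed-length and anchored.

Default parameters: m = 10 and `max_alleles` = 3 (one above ploidy, so
paralog-contaminated loci are identifiable), per the workflow being
emulated. The sweep-style analyses in this repository run at m = 3: with
the scaled-down per-allele depth of ~10× and a 0.5% error rate, the
expected error-free depth per allele is ~6, so m = 10 would discard most
true alleles, while m = 3 still removes essentially all error stacks
(a specific erroneous read must recur three times to survive).

## Split diagnostics

Under-splitting proxy: loci where any individual carries more than two
distinct alleles; such loci are presumed paralog-contaminated and removed
before all downstream statistics. Over-splitting proxy: each stringent
assembly's consensi are best-hit mapped onto the most liberal (93%)
assembly by ungapped Hamming identity ≥ 93%; if k stringent loci share a
best hit, they contribute k−1 (default; counting all k is available). The
number of 93% loci that map onto *other* 93% loci is subtracted once from
every threshold's raw count (floored at zero), so a perfect 1:1 mapping
scores exactly 0. The exact arithmetic of the subtraction and the
best-hit (rather than all-hits) convention are documented interpretations
of a procedure whose source description is ambiguous. On simulated data
the truth-based rates are also computed: the fraction of true loci whose
retained reads occupy ≥2 catalog loci (over-splitting) and the fraction of
catalog loci containing reads from ≥2 true loci (under-splitting), with
paralog copies counted as distinct true loci.

## Population statistics

Distances between individuals at a locus average the metric over the 2×2
allele-copy pairs (homozygotes count their allele twice); per-pair means
use only loci genotyped in both individuals, and JC-saturated loci
(p ≥ 3/4) are excluded from means and counted rather than clamped.

Hudson's F_ST = 1 − H_w/H_b per locus, with H_w the mean number of
pairwise differences over all distinct pairs of allele copies within
populations (pooled across the two populations by default; per-population
averaging available) and H_b the mean over between-population pairs.
Monomorphic loci and loci with H_b = 0 are excluded; the sweep reports the
mean of per-locus ratios (ratio-of-sums available). Two documented
variants: `distinct_sequences_only` drops identical-sequence pairs from
H_w, and `with_replacement` uses the frequency-weighted mean including
self-pairs — the latter is the variant under which "identical allele
compositions ⇒ F_ST = 0" and duplication-invariance hold exactly; the
default distinct-pair estimator carries the usual small-sample offset.

## The isolation-moment estimator

For each locus, one allele copy is drawn uniformly per population (random
individual, then random copy, from a seeded generator) and K = their
difference count. A single draw per population keeps the loci i.i.d.;
multiple copies from one locus share a genealogy and would correlate,
invalidating the variance identity. In the infinite-sites limit
K | b ~ Poisson(Lb), so E[K] = L(2τ+θ_A) and
Var[K] = L(2τ+θ_A) + L²θ_A², inverted by θ̂_A = √(Var−Mean)/L,
τ̂ = (Mean/L − θ̂_A)/2.

Because mutation here is finite-sites, the default estimator inverts the
exact moments instead: K | b ~ Binomial(L, q(b)) with
q(b) = (3/4)(1−e^(−4b/3)), and with a = e^(−8τ/3), x = 4θ_A/3,

    E[e^(−4b/3)] = a/(1+x)        E[e^(−8b/3)] = a²/(1+2x)

from the Laplace transform of the exponential ancestral time. The mean
fixes E[e^(−4b/3)], the variance fixes the second moment, and their ratio
r = (1+x)²/(1+2x) gives the closed-form solution
x = (r−1) + √(r(r−1)), after which τ comes from a. Negative solutions
floor at zero and are flagged; fewer than 50 informative loci flags the
estimate low-confidence. The infinite-sites closed form remains available
(`method="infinite_sites"`); the two agree as divergence → 0, and the
finite-sites inversion removes a ≈7% downward bias in θ̂_A already visible
at θ_A = τ = 0.005. Contemporary θ̂ᵢ is within-population π.

A structural limitation worth stating: the estimator can only see the
divergence the assembly retained. When mean between-population divergence
approaches the mismatch budget (e.g. 2τ+θ_A = 0.05 against M/L = 0.07),
the upper tail of per-locus divergence — precisely the variance excess
that identifies θ_A — is split away at *every* threshold in the 93–99%
range and θ̂_A floors at zero throughout; the composite signal then loads
onto τ̂. At moderate divergence (2τ+θ_A ≈ 0.025) the expected gradient
appears: θ̂_A near truth at 93% and collapsing toward zero at 99%.

## Gene-tree depth

Per locus, distinct alleles (deduplicated, lexicographically ordered for
determinism) get a pairwise JC distance matrix and a neighbor-joining tree
(scikit-bio, negative branch lengths clamped to zero); depth is the height
of the midpoint-rooted tree, computed as half the maximum tip-to-tip path.
Monomorphic loci contribute depth 0; saturated loci are flagged and
skipped. The sweep reports the mean over a seeded subsample of up to 1,000
loci. NJ+JC replaces per-locus Bayesian inference with model selection:
deterministic and adequate for ≤16 alleles of 100 bp, but absolute depths
are not comparable with posterior-mean depths — only the across-threshold
*pattern* is the object of interest.

## Sweep orchestration and sizes

`run_sweep` assembles the same reads at every threshold (93–99 by
default), removes under-split-flagged loci, computes all statistics on the
filtered assemblies, and writes a fixed-format TSV (stable float
formatting; identical config+seed ⇒ identical bytes). The over-split
reference threshold must be present in the sweep when the proxy is
enabled. `compare_lineages` aligns several reports on their shared
thresholds and emits per-statistic ratios to a baseline lineage plus the
across-lineage variance. Plots are an optional convenience; the TSV is the
contract.

Problem sizes used in the shipped analyses: 8 diploids (4 per population),
L = 100, ~10× per-allele depth; 2,000 loci for the sweep experiments,
5,000 error-free loci for moment-estimator recovery, 120–1,200 loci for
unit-level fixtures. A full 7-threshold sweep at 2,000 loci runs in about
a minute on one core.

## Known limitations

- Connected-component clustering can chain clouds that greedy assemblers
  would keep apart; this is the price of determinism and oracle
  equivalence, and is documented rather than hidden.
- The excess-allele filter has false negatives (paralogs that never show
  three alleles in any individual) and, with error-heavy data and liberal
  budgets, occasional false positives; the truth-based rates quantify both
  on simulated data.
- The moment estimator ignores within-locus information beyond one allele
  pair and assumes free recombination between loci and none within.
- Depth values from NJ trees, and all absolute statistics, are
  simulation-calibrated; only relative, across-threshold behaviour should
  be read onto empirical datasets.
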