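# radsweep

Similarity-threshold sensitivity analysis for de novo RAD-Seq locus
assembly, on synthetic data with known truth.

## The problem

De novo assembly of short, fixed-length reads (RAD-Seq/GBS) clusters reads
into loci by sequence similarity. The threshold *s* is a knob with no free
lunch: stringent thresholds (98–99%) split divergent alleles of one true
locus into several assembled loci (**over-splitting**), deflating allele
counts, genetic distances, gene-tree depths and ancestral population-size
estimates; liberal thresholds risk merging paralogous loci into one
(**under-splitting**), detectable as diploid individuals carrying more than
two alleles. Because species differ in diversity, the same threshold biases
different datasets differently, which undermines comparative
phylogeography. For non-model organisms without reference genomes these
failure modes cannot be observed directly — so `radsweep` builds the
experiment where they can be: a coalescent simulation in which every read
carries a tag back to its true locus, assembled under a sweep of
thresholds, with both the observable proxies and the true splitting rates
reported side by side.

## What it implements

- **simgen** — a two-population isolation-model coalescent simulator:
  populations 1 and 2 diverge from an ancestor at time τ (expected
  substitutions/site), with mutation-scaled sizes θᵢ = 4Nᵢμ per site
  (pairwise coalescence rate 2/θᵢ in mutation time). Mutations are
  finite-sites Jukes–Cantor; an optional fraction of loci carries an
  independently coalescing paralogous copy. Reads are 100 bp, Poisson
  depth, independent per-base errors, written as FASTQ plus a truth table.
- **stackasm** — the stack assembler: identical reads pile into stacks,
  stacks below the depth floor *m* are dropped, stacks within
  M = ⌊L(100−s)/100⌋ mismatches cluster into per-individual loci
  (connected components of the mismatch graph), up to `max_alleles` of the
  deepest distinct consensi are called as alleles, and individual loci
  merge across individuals into catalog loci under the same budget.
- **splitdiag** — the under-split proxy (loci where an individual shows >2
  alleles; removed before downstream statistics), the over-split proxy
  (stringent-threshold loci best-hit-mapped onto the 93% assembly by
  ungapped Hamming identity ≥93%, counting Σ max(0, k−1) collisions minus
  the 93%-vs-93% self-map baseline), and the truth-based split rates only
  simulation can provide.
- **popstats** — p-distances and Jukes–Cantor distances
  d = −(3/4)·ln(1−4p/3) between individuals; Hudson's
  F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub> from mean pairwise
  differences within vs between populations; segregating sites, Watterson's
  θ̂ and π; and a moment estimator of ancestral θ_A and τ from the
  per-locus count K of differences between one allele drawn per population
  (E[K] = L(2τ+θ_A), Var[K] = L(2τ+θ_A) + L²θ_A² in the infinite-sites
  limit; the default inverts the exact finite-sites Jukes–Cantor moments).
- **treedepth** — per-locus gene trees by neighbor joining on JC distances;
  depth = height of the midpoint-rooted tree (half the tree diameter) in
  expected substitutions per site.
- **sweep** — the orchestrator: simulate or load reads, assemble at every
  threshold (93–99% by default), remove flagged loci, compute everything,
  and emit one tidy TSV row per threshold, plus a cross-lineage comparison
  of ratios and variances.

A deliberate difference from the Stacks family: clustering is connected
components over the ≤M-mismatch graph rather than depth-ordered greedy
matching — deterministic, order-independent, and exactly checkable against
a brute-force oracle (which the test suite does).

## Worked example

```python
import radsweep as rs

params = rs.SimParams(n_loci=500, tau=0.01, theta1=0.005, theta2=0.005,
                      theta_a=0.005, depth_mean=10, error_rate=0.005, seed=42)
config = rs.SweepConfig(sim=params, thresholds=[93, 95, 97, 99],
                        min_depth_m=3, seed=42, tree_sample=500)
report = rs.run_sweep(config)
cols = ["threshold", "n_loci", "mean_alleles_per_locus", "oversplit_prop",
        "true_oversplit_rate", "mean_jc_distance", "mean_fst",
        "mean_tree_depth", "theta_a", "tau"]
print(report.table[cols].round(4).to_string(index=False))
```

prints

```
 threshold  n_loci  mean_alleles_per_locus  oversplit_prop  true_oversplit_rate  mean_jc_distance  mean_fst  mean_tree_depth  theta_a    tau
        93     501                  3.8024             NaN                0.002            0.0166    0.7236           0.0179   0.0053 0.0100
        95     509                  3.7426          0.0118                0.018            0.0162    0.7212           0.0171   0.0000 0.0124
        97     566                  3.3657          0.1113                0.116            0.0144    0.7084           0.0139   0.0000 0.0107
        99     973                  1.9579          0.4810                0.650            0.0081    0.6094           0.0043   0.0000 0.0059
```

Reading it: the generating truth is 500 loci, τ = 0.01, θ_A = 0.005. At
the liberal 93% threshold the assembly recovers roughly one catalog locus
per true locus and the estimates sit on the truth (τ̂ = 0.0100,
θ̂_A = 0.0053, with no over-split reference column since 93% *is* the
reference). As the threshold tightens, true loci fracture
(`true_oversplit_rate` 0.2% → 65%), inflating the locus count (501 → 973)
while deflating alleles per locus, genetic distance, tree depth and the
ancestral θ — exactly the threshold-dependent bias the package exists to
quantify. F<sub>ST</sub>, a ratio of within- to between-population
divergence in which both terms shrink together, moves far less. The
over-split proxy (`oversplit_prop`, computable without any truth) tracks
the true rate closely, which is what licenses its use on real data.

The same sweep is available from the shell:

```sh
radsweep sweep --config sweep.cfg --out outdir --seed 42
radsweep simulate --config sim.cfg --out data/
radsweep assemble --similarity 95 --min-depth 10 --max-alleles 3 \
    --reads data/ --popmap data/popmap.tsv --out asm95/
```

where config files are flat `key = value` text mirroring the `SimParams` /
`SweepConfig` field names.

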