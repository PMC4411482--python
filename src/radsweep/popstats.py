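"""Population-genetic summaries per assembly.

Distances (p and Jukes-Cantor), Hudson's Fst from the ratio of mean
within- to mean between-population pairwise differences, standard diversity
estimators (segregating sites, Watterson's theta, nucleotide diversity pi),
and a moment estimator of the ancestral theta and the divergence time tau
under the two-population isolation model.

The moment estimator works on the per-locus count ``K`` of differing sites
between one allele drawn from each population. The between-population
branch separation is ``b = 2*tau + 2*T`` with ``T`` exponential of mean
``theta_A/2`` (tau and theta_A per site). In the infinite-sites limit
``K | b ~ Poisson(L*b)``, so

    E[K]   = L * (2*tau + theta_A)
    Var[K] = L * (2*tau + theta_A) + L**2 * theta_A**2

giving the closed forms ``theta_A = sqrt(Var[K] - E[K]) / L`` and
``tau = (E[K]/L - theta_A) / 2``. Because mutations here are finite-sites
Jukes-Cantor, the default estimator instead inverts the exact finite-sites
moments: a site differs with probability ``q(b) = (3/4)(1 - exp(-4b/3))``
and ``K | b ~ Binomial(L, q(b))``, whose first two moments follow from the
Laplace transform ``E[exp(-s*T)] = 1 / (1 + s*theta_A/2)``; the resulting
two-equation system reduces to a quadratic in theta_A (see
``isolation_moments``). Both estimators agree as divergence -> 0. Sampling
a single allele per population per locus keeps the variance identity exact
— multiple copies from one locus share a genealogy and would correlate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import hamming, pairwise_hamming_matrix, seqs_to_matrix
from .stackasm import Assembly, CatalogLocus

__all__ = [
    "DistanceResult",
    "FstResult",
    "ThetaEstimates",
    "p_distance",
    "jc_distance",
    "individual_pair_distance",
    "pairwise_distances",
    "mean_distance",
    "hudson_fst",
    "mean_fst",
    "segregating_sites",
    "watterson_theta",
    "nucleotide_diversity",
    "population_copies",
    "isolation_moments",
    "isolation_moments_from_loci",
]

SATURATION = 0.75  # p at or beyond which the JC correction is undefined


def p_distance(seq_a: str, seq_b: str) -> float:
    """Raw proportion of differing sites between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if not seq_a:
        raise ValueError("empty sequences")
    return hamming(seq_a, seq_b) / len(seq_a)


def jc_distance(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN for saturated inputs (p >= 3/4), which callers exclude
    from means rather than clamp.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= SATURATION:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DistanceResult:
    individual_i: str
    individual_j: str
    mean_p: float
    mean_jc: float
    n_loci: int
    n_saturated: int


def individual_pair_distance(locus: CatalogLocus, ind_i: str, ind_j: str,
                             metric: str = "p") -> float | None:
    """Mean distance over the 2x2 allele-copy pairs of two diploids at one
    locus; homozygotes contribute their allele twice. None when either
    individual is missing (or paralog-contaminated) at the locus; NaN when
    the JC metric saturates."""
    copies_i = locus.allele_copies(ind_i)
    copies_j = locus.allele_copies(ind_j)
    if copies_i is None or copies_j is None:
        return None
    ps = [p_distance(a, b) for a in copies_i for b in copies_j]
    if metric == "p":
        return float(np.mean(ps))
    if metric == "jc":
        ds = [jc_distance(p) for p in ps]
        return float(np.mean(ds))  # NaN propagates if any pair saturates
    raise ValueError("metric must be 'p' or 'jc'")


def pairwise_distances(assembly: Assembly) -> list[DistanceResult]:
    """Per-individual-pair mean p and JC distances across shared loci.

    Loci are used for a pair only when both individuals are genotyped
    there; JC-saturated loci are excluded from the JC mean and counted.
    """
    individuals = sorted({ind for loc in assembly.loci for ind in loc.genotypes})
    results = []
    for ind_i, ind_j in combinations(individuals, 2):
        ps, jcs, n_sat = [], [], 0
        for loc in assembly.loci:
            p = individual_pair_distance(loc, ind_i, ind_j, "p")
            if p is None:
                continue
            ps.append(p)
            jc = individual_pair_distance(loc, ind_i, ind_j, "jc")
            if math.isnan(jc):
                n_sat += 1
            else:
                jcs.append(jc)
        results.append(DistanceResult(
            ind_i, ind_j,
            mean_p=float(np.mean(ps)) if ps else math.nan,
            mean_jc=float(np.mean(jcs)) if jcs else math.nan,
            n_loci=len(ps), n_saturated=n_sat))
    return results


def mean_distance(assembly: Assembly, metric: str = "jc") -> float:
    """Grand mean over individual pairs of their per-pair mean distance."""
    res = pairwise_distances(assembly)
    vals = [r.mean_jc if metric == "jc" else r.mean_p
            for r in res if r.n_loci > 0]
    return float(np.mean(vals)) if vals else math.nan


def population_copies(locus: CatalogLocus, popmap: dict[str, str],
                      ) -> dict[str, list[str]]:
    """Diploid allele copies per population at one locus (2 per genotyped
    individual; missing/paralog-contaminated individuals are skipped)."""
    out: dict[str, list[str]] = {}
    for ind, pop in popmap.items():
        copies = locus.allele_copies(ind)
        if copies is not None:
            out.setdefault(pop, []).extend(copies)
    return out


@dataclass
class FstResult:
    catalog_id: int
    hw: float
    hb: float
    fst: float | None


def hudson_fst(locus: CatalogLocus, popmap: dict[str, str],
               pooled: bool = True,
               distinct_sequences_only: bool = False,
               with_replacement: bool = False) -> FstResult | None:
    """Hudson's Fst = 1 - Hw/Hb at one locus.

    Hw is the mean number of pairwise differences among allele copies
    within populations (pooled over both populations by default, or the
    average of the two per-population means), Hb the mean over
    between-population pairs. Monomorphic loci and loci with fewer than two
    copies in either population return None; Hb = 0 leaves fst None so the
    locus is excluded from means. ``distinct_sequences_only`` restricts
    within-population pairs to pairs of non-identical sequences (the
    alternative reading of "different sequences"); the default treats any
    two sampled copies as different draws. ``with_replacement`` switches Hw
    to the frequency-weighted mean over ordered copy pairs including
    self-pairs, which is exactly invariant to duplicating every copy and
    yields Fst = 0 for populations with identical allele compositions; the
    default distinct-pair estimator has the usual small-sample offset.
    """
    by_pop = population_copies(locus, popmap)
    pops = sorted(by_pop)
    if len(pops) != 2:
        return None
    c1, c2 = by_pop[pops[0]], by_pop[pops[1]]
    if len(c1) < 2 or len(c2) < 2:
        return None
    if len(set(c1) | set(c2)) == 1:
        return None  # monomorphic
    within_counts: list[float] = []
    for copies in (c1, c2):
        if with_replacement:
            pop_counts = [hamming(a, b) for a in copies for b in copies]
        else:
            pop_counts = [hamming(a, b) for a, b in combinations(copies, 2)]
        if distinct_sequences_only:
            pop_counts = [d for d in pop_counts if d > 0]
        if pooled:
            within_counts.extend(pop_counts)
        else:
            within_counts.append(float(np.mean(pop_counts))
                                 if pop_counts else 0.0)
    hw = float(np.mean(within_counts)) if within_counts else 0.0
    hb = float(np.mean([hamming(a, b) for a in c1 for b in c2]))
    fst = (1.0 - hw / hb) if hb > 0 else None
    return FstResult(locus.catalog_id, hw, hb, fst)


def mean_fst(assembly: Assembly, popmap: dict[str, str],
             method: str = "mean_of_ratios", pooled: bool = True,
             distinct_sequences_only: bool = False) -> float:
    """Mean Fst over polymorphic loci with Hb > 0.

    ``mean_of_ratios`` averages per-locus Fst values; ``ratio_of_sums``
    computes 1 - sum(Hw)/sum(Hb) over the same loci.
    """
    rows = [r for r in (hudson_fst(loc, popmap, pooled,
                                   distinct_sequences_only)
                        for loc in assembly.loci)
            if r is not None and r.fst is not None]
    if not rows:
        return math.nan
    if method == "mean_of_ratios":
        return float(np.mean([r.fst for r in rows]))
    if method == "ratio_of_sums":
        return 1.0 - sum(r.hw for r in rows) / sum(r.hb for r in rows)
    raise ValueError("method must be 'mean_of_ratios' or 'ratio_of_sums'")


def segregating_sites(copies: list[str]) -> int:
    """Number of columns with more than one base among the allele copies."""
    if not copies:
        return 0
    mat = seqs_to_matrix(list(copies))
    return int((mat != mat[0]).any(axis=0).sum())


def watterson_theta(loci: list[list[str]], n_copies: int) -> float:
    """Watterson's per-site estimator pooled over loci:
    theta_W = S_total / (a_n * L * n_loci), a_n = sum_{k=1}^{n-1} 1/k."""
    if n_copies < 2:
        raise ValueError("need at least 2 copies")
    if not loci:
        return math.nan
    L = len(loci[0][0])
    a_n = sum(1.0 / k for k in range(1, n_copies))
    s_total = sum(segregating_sites(copies) for copies in loci)
    return s_total / (a_n * L * len(loci))


def nucleotide_diversity(loci: list[list[str]]) -> float:
    """Mean pairwise p-distance per site, averaged over loci (pi)."""
    vals = []
    for copies in loci:
        if len(copies) < 2:
            continue
        mat = seqs_to_matrix(list(copies))
        dm = pairwise_hamming_matrix(mat)
        n = len(copies)
        iu = np.triu_indices(n, k=1)
        vals.append(dm[iu].mean() / mat.shape[1])
    return float(np.mean(vals)) if vals else math.nan


@dataclass
class ThetaEstimates:
    """Isolation-model moment estimates (all per site)."""

    theta1: float
    theta2: float
    theta_a: float
    tau: float
    mean_k: float
    var_k: float
    n_loci: int
    locus_length: int
    floored: bool = False          # a negative moment solution was set to 0
    low_confidence: bool = False   # fewer than 50 informative loci


def _invert_infinite_sites(mean_k: float, var_k: float, L: int,
                           ) -> tuple[float, float, bool]:
    excess = var_k - mean_k
    floored = excess < 0
    theta_a = math.sqrt(max(0.0, excess)) / L
    tau_raw = (mean_k / L - theta_a) / 2.0
    return theta_a, max(0.0, tau_raw), floored or tau_raw < 0


def _invert_finite_sites(mean_k: float, var_k: float, L: int,
                         ) -> tuple[float, float, bool]:
    """Solve the exact binomial/JC moment equations for (theta_A, tau).

    With q(b) = (3/4)(1 - exp(-4b/3)), b = 2*tau + 2*T, T ~ Exp(mean
    theta_A/2): writing a = exp(-8*tau/3), u = 1/(1 + 4*theta_A/3),
    w = 1/(1 + 8*theta_A/3),

        E1 := E[exp(-4b/3)] = a*u          E[q]  = (3/4)(1 - E1)
        E2 := E[exp(-8b/3)] = a^2*w        E[q2] = (9/16)(1 - 2*E1 + E2)
        E[K] = L*E[q],   Var[K] = L*(E[q] - E[q2]) + L^2*(E[q2] - E[q]^2)

    E1 comes from the mean, E[q2] from the variance, and the ratio
    r = E2/E1^2 = (1 + x)^2 / (1 + 2x) with x = 4*theta_A/3 gives the
    quadratic x = (r-1) + sqrt(r*(r-1)). Negative solutions floor at 0.
    """
    floored = False
    eq = mean_k / L
    e1 = 1.0 - 4.0 * eq / 3.0
    if e1 <= 0:  # saturated mean divergence: estimator undefined
        return math.nan, math.nan, True
    if L > 1:
        eq2 = (var_k - L * eq + (L * eq) ** 2) / (L * (L - 1))
    else:
        eq2 = eq ** 2
    e2 = 2.0 * e1 - 1.0 + 16.0 * eq2 / 9.0
    r = e2 / e1 ** 2
    if r <= 1.0:
        floored = r < 1.0
        x = 0.0
    else:
        x = (r - 1.0) + math.sqrt(r * (r - 1.0))
    theta_a = 0.75 * x
    a = e1 * (1.0 + x)
    if a >= 1.0:
        floored = floored or a > 1.0
        tau = 0.0
    else:
        tau = -0.375 * math.log(a)
    return theta_a, tau, floored


def _moments_from_counts(k_counts: np.ndarray, L: int,
                         theta1: float, theta2: float,
                         method: str = "finite_sites") -> ThetaEstimates:
    mean_k = float(np.mean(k_counts))
    var_k = float(np.var(k_counts, ddof=1)) if len(k_counts) > 1 else 0.0
    if method == "finite_sites":
        theta_a, tau, floored = _invert_finite_sites(mean_k, var_k, L)
    elif method == "infinite_sites":
        theta_a, tau, floored = _invert_infinite_sites(mean_k, var_k, L)
    else:
        raise ValueError("method must be 'finite_sites' or 'infinite_sites'")
    return ThetaEstimates(
        theta1=theta1, theta2=theta2, theta_a=theta_a, tau=tau,
        mean_k=mean_k, var_k=var_k, n_loci=len(k_counts), locus_length=L,
        floored=floored, low_confidence=len(k_counts) < 50)


def isolation_moments_from_loci(loci: list[tuple[list[str], list[str]]],
                                L: int, rng: np.random.Generator,
                                method: str = "finite_sites",
                                ) -> ThetaEstimates:
    """Moment estimates from per-locus (pop1 copies, pop2 copies) lists.

    One copy is drawn uniformly per population per locus (seeded), K is
    their difference count, and the moment identities are inverted —
    exactly under the finite-sites JC model by default, or with the
    infinite-sites closed form (``method='infinite_sites'``). Contemporary
    thetas are the within-population pi over all copies.
    """
    ks = []
    pop1_loci, pop2_loci = [], []
    for c1, c2 in loci:
        if not c1 or not c2:
            continue
        a = c1[int(rng.integers(len(c1)))]
        b = c2[int(rng.integers(len(c2)))]
        ks.append(hamming(a, b))
        pop1_loci.append(c1)
        pop2_loci.append(c2)
    if not ks:
        raise ValueError("no locus with copies in both populations")
    theta1 = nucleotide_diversity(pop1_loci)
    theta2 = nucleotide_diversity(pop2_loci)
    return _moments_from_counts(np.asarray(ks), L, theta1, theta2, method)


def isolation_moments(assembly: Assembly, popmap: dict[str, str],
                      rng: np.random.Generator,
                      method: str = "finite_sites") -> ThetaEstimates:
    """Moment estimates from an assembly (run after paralog filtering)."""
    pops = sorted(set(popmap.values()))
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    loci = []
    for loc in assembly.loci:
        by_pop = population_copies(loc, popmap)
        loci.append((by_pop.get(pops[0], []), by_pop.get(pops[1], [])))
    return isolation_moments_from_loci(
        loci, assembly.params.locus_length, rng, method)


def summary_table(results: list[DistanceResult]) -> pd.DataFrame:
    """Tabulate per-pair distance results for TSV export."""
    return pd.DataFrame(
        [{"individual_i": r.individual_i, "individual_j": r.individual_j,
          "mean_p": r.mean_p, "mean_jc": r.mean_jc,
          "n_loci": r.n_loci, "n_saturated": r.n_saturated}
         for r in results])
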