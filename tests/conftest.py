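"""Shared fixtures: small truth-known datasets and one moderate-divergence
threshold sweep reused across modules (session-scoped — simulation and
assembly dominate suite runtime)."""

from __future__ import annotations

import numpy as np
import pytest

import radsweep as rs


def locus_copies_by_pop(locus: rs.TrueLocus, n_per_pop: int,
                        ) -> tuple[list[str], list[str]]:
    """Split a true locus's primary-copy haplotypes into the two
    population samples (individuals are named p1_*/p2_*)."""
    inds = sorted(locus.haplotypes)
    c1 = [h for ind in inds if ind.startswith("p1")
          for h in locus.haplotypes[ind]]
    c2 = [h for ind in inds if ind.startswith("p2")
          for h in locus.haplotypes[ind]]
    assert len(c1) == len(c2) == 2 * n_per_pop
    return c1, c2


@pytest.fixture(scope="session")
def shallow_dataset() -> rs.SimulatedDataset:
    """Error-free, paralog-free, shallow-divergence reads: every allele is
    an exact read pile, so assembly should recover the truth exactly."""
    params = rs.SimParams(n_loci=120, tau=0.005, theta1=0.005, theta2=0.005,
                          theta_a=0.005, depth_mean=10, error_rate=0.0,
                          seed=7)
    return rs.simulate_dataset(params)


@pytest.fixture(scope="session")
def moderate_sweep() -> rs.SweepReport:
    """Full 93-99% sweep on a moderate-divergence simulation (tau=0.01,
    theta=0.005, 10x depth, 0.5% error). Deep enough that stringent
    thresholds over-split, shallow enough that the 93% assembly retains
    the divergence tail the ancestral-theta estimator needs."""
    params = rs.SimParams(n_loci=1200, tau=0.01, theta1=0.005, theta2=0.005,
                          theta_a=0.005, depth_mean=10, error_rate=0.005,
                          seed=21)
    config = rs.SweepConfig(sim=params, min_depth_m=3, seed=21,
                            tree_sample=600)
    return rs.run_sweep(config)


def make_reads(seq_counts: dict[str, int], individual: str = "ind1",
               ) -> list[rs.ReadRecord]:
    """Reads with given multiplicities for one individual."""
    reads = []
    for seq, n in seq_counts.items():
        for k in range(n):
            reads.append(rs.ReadRecord(f"{individual}_{seq[:6]}_{k}", seq,
                                       individual, (0, 0, 0)))
    return reads


def random_cluster_instance(rng: np.random.Generator, n_max: int = 20,
                            L: int = 30, n_centers: int = 3,
                            mut_rate: float = 0.08) -> list[str]:
    """Random stack consensi drawn around a few center sequences so that
    mismatch graphs have non-trivial structure at small budgets."""
    bases = "ACGT"
    centers = ["".join(rng.choice(list(bases), L)) for _ in range(n_centers)]
    n = int(rng.integers(2, n_max + 1))
    seqs = []
    for _ in range(n):
        s = list(centers[int(rng.integers(n_centers))])
        for pos in np.nonzero(rng.random(L) < mut_rate)[0]:
            s[pos] = bases[int(rng.integers(4))]
        seqs.append("".join(s))
    return seqs


def oracle_components(seqs: list[str], M: int) -> set[frozenset[int]]:
    """Independent connected-components oracle: scipy Hamming distances +
    breadth-first search."""
    from scipy.spatial.distance import pdist, squareform

    n = len(seqs)
    if n == 1:
        return {frozenset([0])}
    arr = np.array([[ord(c) for c in s] for s in seqs])
    dm = squareform(pdist(arr, metric="hamming")) * arr.shape[1]
    adj = dm <= M + 0.5
    seen: set[int] = set()
    comps: set[frozenset[int]] = set()
    for start in range(n):
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            node = queue.pop()
            for nb in np.nonzero(adj[node])[0]:
                if int(nb) not in comp:
                    comp.add(int(nb))
                    queue.append(int(nb))
        seen |= comp
        comps.add(frozenset(comp))
    return comps
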