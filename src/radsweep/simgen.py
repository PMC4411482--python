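"""Synthetic RAD-Seq reads with known truth under a two-population isolation model.

The generator realises the same demographic model the downstream moment
estimator inverts: two contemporary populations that split from a single
ancestral population at divergence time ``tau``, with mutation-scaled
population sizes ``theta = 4*Ne*mu`` per site for each daughter population
and for the ancestor. All times and branch lengths are measured in expected
substitutions per site, so a coalescent pair within a population of size
``theta`` has expected time-to-ancestor ``theta/2``.

Mutations follow a finite-sites Jukes-Cantor process (multiple hits allowed),
matching the JC-corrected distances used downstream. An optional fraction of
loci carries a diverged paralogous copy that emits reads for every
individual, the mechanism behind under-splitting in real assemblies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import codes_to_seqs

__all__ = [
    "SimParams",
    "Genealogy",
    "TrueLocus",
    "ReadRecord",
    "SimulatedDataset",
    "simulate_genealogy",
    "drop_mutations",
    "add_paralog",
    "generate_reads",
    "simulate_true_loci",
    "simulate_dataset",
    "write_dataset",
    "load_reads",
    "load_popmap",
    "load_truth",
]

_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i

#: constant placeholder quality (Phred 40) — quality-aware processing is
#: upstream of assembly and out of scope here.
QUALITY_CHAR = "I"


def _seq_to_codes(seq: str) -> np.ndarray:
    codes = _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return codes


@dataclass(frozen=True)
class SimParams:
    """Simulation settings; defaults mirror the two-population study design
    (2 populations x 4 diploid individuals, 100-bp single-end reads at ~10x
    per allele). theta/tau defaults are mid-range 'shallow' values; sweep
    them upward (tau ~ 0.02, theta ~ 0.01) for deep-divergence scenarios.
    """

    n_loci: int
    locus_length: int = 100
    n_individuals_per_pop: int = 4
    theta1: float = 0.005
    theta2: float = 0.005
    theta_a: float = 0.005
    tau: float = 0.005
    paralog_fraction: float = 0.0
    paralog_divergence: float = 0.05
    depth_mean: float = 10.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.n_individuals_per_pop < 1:
            raise ValueError("n_individuals_per_pop must be >= 1")
        for name in ("theta1", "theta2", "theta_a", "tau",
                     "paralog_divergence", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")

    @property
    def individuals(self) -> list[str]:
        n = self.n_individuals_per_pop
        return [f"p{p}_i{i}" for p in (1, 2) for i in range(1, n + 1)]

    @property
    def populations(self) -> dict[str, str]:
        n = self.n_individuals_per_pop
        return {ind: ("pop1" if k < n else "pop2")
                for k, ind in enumerate(self.individuals)}


@dataclass
class Genealogy:
    """Binary coalescent tree over haploid lineages (2 per diploid).

    ``parent[i]`` is the parent node of node ``i`` (-1 at the root) and
    ``times[i]`` its age in expected substitutions per site; tips are nodes
    ``0..n_tips-1`` at time 0.
    """

    parent: np.ndarray
    times: np.ndarray
    n_tips: int
    pop_assignments: np.ndarray

    def tmrca(self, i: int, j: int) -> float:
        anc_i = set()
        k = i
        while k != -1:
            anc_i.add(k)
            k = int(self.parent[k])
        k = j
        while k not in anc_i:
            k = int(self.parent[k])
        return float(self.times[k])

    def separation(self, i: int, j: int) -> float:
        """Total branch length between two tips (2 * TMRCA for tips)."""
        return 2.0 * self.tmrca(i, j) - float(self.times[i] + self.times[j])


def _coalesce_epoch(active: list[int], theta: float, t_start: float,
                    t_end: float | None, times: np.ndarray,
                    parent: np.ndarray, next_node: int,
                    rng: np.random.Generator) -> tuple[float, int]:
    """Pairwise-rate-2/theta coalescent on ``active`` from t_start to t_end."""
    t = t_start
    while len(active) >= 2:
        k = len(active)
        if theta <= 0:
            if t_end is None:
                raise ValueError(
                    "non-positive theta for a population that must coalesce")
            break  # theta == 0 before tau: no within-population coalescence
        rate = k * (k - 1) / theta  # C(k,2) pairs at pairwise rate 2/theta
        t += rng.exponential(1.0 / rate)
        if t_end is not None and t > t_end:
            t = t_end
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        times[next_node] = t
        parent[a] = next_node
        parent[b] = next_node
        active[:] = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return t, next_node


def simulate_genealogy(params: SimParams, pop_assignments: Iterable[int],
                       rng: np.random.Generator) -> Genealogy:
    """Simulate one locus genealogy under the isolation model.

    Lineages coalesce within their population back to time ``tau``
    (pairwise rate 2/theta_i), after which all remaining lineages join a
    single ancestral population with pairwise rate 2/theta_a. Raises if the
    ancestral population, which must absorb all remaining lineages, has
    non-positive theta.
    """
    pops = np.asarray(list(pop_assignments), dtype=np.intp)
    n_tips = len(pops)
    if n_tips < 2:
        raise ValueError("need at least 2 lineages")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.intp)
    times = np.zeros(n_nodes, dtype=float)
    next_node = n_tips
    survivors: list[int] = []
    for pop, theta in ((0, params.theta1), (1, params.theta2)):
        active = [int(i) for i in np.nonzero(pops == pop)[0]]
        _, next_node = _coalesce_epoch(
            active, theta, 0.0, params.tau, times, parent, next_node, rng)
        survivors.extend(active)
    _, next_node = _coalesce_epoch(
        survivors, params.theta_a, params.tau, None, times, parent,
        next_node, rng)
    return Genealogy(parent=parent[:next_node], times=times[:next_node],
                     n_tips=n_tips, pop_assignments=pops)


def drop_mutations(genealogy: Genealogy, L: int, rng: np.random.Generator,
                   root_sequence: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Evolve sequences down the genealogy under finite-sites Jukes-Cantor.

    Each branch receives Poisson(branch_length * L) substitution events; an
    event replaces the base at a uniform site with a uniform *different*
    base, so multiple hits are possible. Returns ``(tip_matrix, root)`` as
    base-index (0..3) uint8 arrays; ``root_sequence`` seeds the ancestral
    state (drawn uniformly when omitted).
    """
    root = int(np.nonzero(genealogy.parent == -1)[0][0])
    if root_sequence is None:
        root_sequence = rng.integers(0, 4, size=L, dtype=np.uint8)
    seqs: dict[int, np.ndarray] = {root: np.array(root_sequence, dtype=np.uint8)}
    children: dict[int, list[int]] = {}
    for i, p in enumerate(genealogy.parent):
        if p != -1:
            children.setdefault(int(p), []).append(i)
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, []):
            blen = float(genealogy.times[node] - genealogy.times[child])
            seq = seqs[node].copy()
            n_mut = rng.poisson(blen * L)
            for _ in range(n_mut):
                site = int(rng.integers(L))
                seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
            seqs[child] = seq
            stack.append(child)
    tips = np.vstack([seqs[i] for i in range(genealogy.n_tips)])
    return tips, seqs[root]


@dataclass
class TrueLocus:
    """Ground truth for one locus: two haplotypes per individual per copy."""

    locus_id: int
    haplotypes: dict[str, tuple[str, str]]
    paralog_copy: dict[str, tuple[str, str]] | None = None
    genealogy_times: np.ndarray | None = None
    ancestral_sequence: str = ""

    @property
    def length(self) -> int:
        return len(next(iter(self.haplotypes.values()))[0])

    @property
    def n_copies(self) -> int:
        return 2 if self.paralog_copy is not None else 1


@dataclass(frozen=True)
class ReadRecord:
    """One simulated read plus its provenance tag (locus, copy, haplotype)."""

    read_id: str
    sequence: str
    individual_id: str
    truth_tag: tuple[int, int, int]


def _tips_to_haplotypes(tips: np.ndarray, individuals: list[str],
                        ) -> dict[str, tuple[str, str]]:
    seqs = codes_to_seqs(tips)
    return {ind: (seqs[2 * k], seqs[2 * k + 1])
            for k, ind in enumerate(individuals)}


def add_paralog(true_locus: TrueLocus, paralog_divergence: float,
                params: SimParams, rng: np.random.Generator) -> TrueLocus:
    """Attach an independently-coalescing duplicate copy to a locus.

    The duplicate's ancestral sequence is the original locus's ancestral
    sequence mutated by Poisson(paralog_divergence * L) JC events, after
    which the copy evolves on its own isolation-model genealogy; every
    individual then emits reads from both copies.
    """
    if paralog_divergence < 0:
        raise ValueError("paralog_divergence must be >= 0")
    L = true_locus.length
    individuals = sorted(true_locus.haplotypes)
    root = _seq_to_codes(true_locus.ancestral_sequence).copy()
    for _ in range(rng.poisson(paralog_divergence * L)):
        site = int(rng.integers(L))
        root[site] = (root[site] + 1 + rng.integers(3)) % 4
    pops = np.repeat([0, 1], 2 * params.n_individuals_per_pop)
    gen = simulate_genealogy(params, pops, rng)
    tips, _ = drop_mutations(gen, L, rng, root_sequence=root)
    true_locus.paralog_copy = _tips_to_haplotypes(tips, individuals)
    return true_locus


def generate_reads(true_locus: TrueLocus, depth_mean: float, error_rate: float,
                   rng: np.random.Generator) -> list[ReadRecord]:
    """Emit Poisson(depth_mean) error-prone reads per haplotype per copy."""
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    L = true_locus.length
    out: list[ReadRecord] = []
    copies = [(0, true_locus.haplotypes)]
    if true_locus.paralog_copy is not None:
        copies.append((1, true_locus.paralog_copy))
    for copy_idx, haps in copies:
        for ind in sorted(haps):
            for hap_idx, hap in enumerate(haps[ind]):
                n = int(rng.poisson(depth_mean))
                if n == 0:
                    continue
                codes = np.repeat(_seq_to_codes(hap)[None, :], n, axis=0)
                if error_rate > 0:
                    mask = rng.random((n, L)) < error_rate
                    n_err = int(mask.sum())
                    if n_err:
                        codes[mask] = (codes[mask]
                                       + rng.integers(1, 4, size=n_err,
                                                      dtype=np.uint8)) % 4
                for k, seq in enumerate(codes_to_seqs(codes)):
                    rid = (f"L{true_locus.locus_id}_c{copy_idx}_{ind}"
                           f"_h{hap_idx}_n{k}")
                    out.append(ReadRecord(rid, seq, ind,
                                          (true_locus.locus_id, copy_idx,
                                           hap_idx)))
    return out


@dataclass
class SimulatedDataset:
    """A full truth-known dataset: loci, reads per individual, populations."""

    params: SimParams
    loci: list[TrueLocus]
    reads_by_individual: dict[str, list[ReadRecord]]
    populations: dict[str, str]

    @property
    def truth(self) -> dict[str, tuple[int, int, int]]:
        """read_id -> (locus_id, copy, haplotype_index)."""
        return {r.read_id: r.truth_tag
                for reads in self.reads_by_individual.values() for r in reads}

    @property
    def true_locus_keys(self) -> list[tuple[int, int]]:
        """(locus_id, copy) keys; paralog copies count as distinct loci."""
        keys = []
        for loc in self.loci:
            keys.append((loc.locus_id, 0))
            if loc.paralog_copy is not None:
                keys.append((loc.locus_id, 1))
        return keys


def _simulate_locus(params: SimParams, locus_id: int,
                    pops: np.ndarray) -> tuple[TrueLocus, np.random.Generator]:
    # per-locus substream: growing n_loci never reshuffles earlier loci
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(locus_id,)))
    is_paralog = rng.random() < params.paralog_fraction
    gen = simulate_genealogy(params, pops, rng)
    tips, root = drop_mutations(gen, params.locus_length, rng)
    locus = TrueLocus(
        locus_id=locus_id,
        haplotypes=_tips_to_haplotypes(tips, params.individuals),
        genealogy_times=gen.times[gen.n_tips:].copy(),
        ancestral_sequence=codes_to_seqs(root[None, :])[0],
    )
    if is_paralog:
        add_paralog(locus, params.paralog_divergence, params, rng)
    return locus, rng


def simulate_true_loci(params: SimParams) -> list[TrueLocus]:
    """Simulate ground-truth haplotypes only (no reads): the error-free
    view of the study design used for calibration and parameter-recovery
    checks. Locus ``l`` is identical to locus ``l`` of
    :func:`simulate_dataset` under the same parameters."""
    pops = np.repeat([0, 1], 2 * params.n_individuals_per_pop)
    return [_simulate_locus(params, l, pops)[0] for l in range(params.n_loci)]


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Simulate the whole study design with per-locus substreams.

    Each locus draws from ``SeedSequence(seed, spawn_key=(locus,))`` so
    growing ``n_loci`` extends the dataset without reshuffling earlier loci.
    """
    individuals = params.individuals
    pops = np.repeat([0, 1], 2 * params.n_individuals_per_pop)
    loci: list[TrueLocus] = []
    reads_by_individual: dict[str, list[ReadRecord]] = {
        ind: [] for ind in individuals}
    for l in range(params.n_loci):
        locus, rng = _simulate_locus(params, l, pops)
        loci.append(locus)
        for rec in generate_reads(locus, params.depth_mean, params.error_rate,
                                  rng):
            reads_by_individual[rec.individual_id].append(rec)
    return SimulatedDataset(params=params, loci=loci,
                            reads_by_individual=reads_by_individual,
                            populations=params.populations)


# --------------------------------------------------------------------------
# on-disk round trip: FASTQ per individual + popmap + truth table


def write_dataset(dataset: SimulatedDataset, out_dir: str) -> dict[str, str]:
    """Write one FASTQ per individual plus popmap.tsv and truth.tsv.

    Returns the mapping of logical name -> path. Quality strings are a
    constant placeholder; the truth table round-trips provenance losslessly.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for ind in sorted(dataset.reads_by_individual):
        path = os.path.join(out_dir, f"{ind}.fastq")
        records = []
        for r in dataset.reads_by_individual[ind]:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
            records.append(rec)
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
        paths[ind] = path
    popmap = os.path.join(out_dir, "popmap.tsv")
    with open(popmap, "w") as fh:
        for ind in sorted(dataset.populations):
            fh.write(f"{ind}\t{dataset.populations[ind]}\n")
    paths["popmap"] = popmap
    truth = os.path.join(out_dir, "truth.tsv")
    with open(truth, "w") as fh:
        fh.write("read_id\tindividual\tpopulation\tlocus\tcopy\thaplotype\n")
        for ind in sorted(dataset.reads_by_individual):
            pop = dataset.populations[ind]
            for r in dataset.reads_by_individual[ind]:
                loc, copy, hap = r.truth_tag
                fh.write(f"{r.read_id}\t{ind}\t{pop}\t{loc}\t{copy}\t{hap}\n")
    paths["truth"] = truth
    return paths


def load_popmap(path: str) -> dict[str, str]:
    populations: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                ind, pop = line.split()[:2]
                populations[ind] = pop
    return populations


def load_truth(path: str) -> dict[str, tuple[int, int, int]]:
    truth: dict[str, tuple[int, int, int]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            parts = line.split()
            truth[parts[idx["read_id"]]] = (
                int(parts[idx["locus"]]), int(parts[idx["copy"]]),
                int(parts[idx["haplotype"]]))
    return truth


def load_reads(fastq_dir: str, populations: dict[str, str],
               truth: dict[str, tuple[int, int, int]] | None = None,
               ) -> dict[str, list[ReadRecord]]:
    """Read per-individual FASTQ files named ``<individual>.fastq``."""
    reads: dict[str, list[ReadRecord]] = {}
    for ind in sorted(populations):
        path = os.path.join(fastq_dir, f"{ind}.fastq")
        recs: list[ReadRecord] = []
        for rec in SeqIO.parse(path, "fastq"):
            tag = truth.get(rec.id, (-1, -1, -1)) if truth else (-1, -1, -1)
            recs.append(ReadRecord(rec.id, str(rec.seq), ind, tag))
        reads[ind] = recs
    return reads
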