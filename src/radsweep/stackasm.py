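"""De novo assembly of fixed-length reads into alleles and catalog loci.

Re-implements the similarity-threshold workflow used by stack-based RAD-Seq
assemblers: identical reads are piled into stacks, shallow stacks are
discarded (secondary-read rescue disabled), stacks within a mismatch budget
are clustered into per-individual loci, each individual's deepest distinct
consensi are called as alleles, and individual loci are merged across
individuals into catalog loci under the same budget.

One deliberate difference from the greedy, depth-ordered matching of the
original tools: clustering here is connected components over the
"<= M mismatches" graph, which is deterministic, input-order independent,
and checkable against an exhaustive all-pairs oracle. A consequence is that
partitions at a stringent threshold are exact refinements of partitions at
any more liberal threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from ._util import (DisjointSet, neighbor_pairs, seqs_to_matrix)
from .simgen import ReadRecord

__all__ = [
    "AssemblyParams",
    "Stack",
    "IndividualLocus",
    "CatalogLocus",
    "Assembly",
    "mismatch_budget",
    "dereplicate",
    "filter_depth",
    "cluster_stacks",
    "call_alleles",
    "build_catalog",
    "assemble",
]


def mismatch_budget(similarity_s: int, L: int) -> int:
    """Convert a percent-similarity threshold into a mismatch allowance.

    M = floor(L * (100 - s) / 100); two fixed-length sequences may share a
    locus only if their Hamming distance is at most M. At L=100 this gives
    the usual anchors: 93% -> 7 mismatches, 99% -> 1 mismatch.
    """
    if not 0 < similarity_s <= 100:
        raise ValueError("similarity_s must be in (0, 100]")
    if L < 1:
        raise ValueError("L must be >= 1")
    return (L * (100 - similarity_s)) // 100


@dataclass(frozen=True)
class AssemblyParams:
    """Assembly settings (similarity %, min stack depth, allele cap).

    ``catalog_mismatch_n`` is the across-individual budget (the `-n` of
    stack assemblers); it defaults to the within-individual budget derived
    from ``similarity_s``, as in a symmetric threshold sweep.
    """

    similarity_s: int
    locus_length: int = 100
    min_depth_m: int = 10
    max_alleles: int = 3
    catalog_mismatch_n: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.similarity_s <= 100:
            raise ValueError("similarity_s must be in (0, 100]")
        if self.min_depth_m < 1:
            raise ValueError("min_depth_m must be >= 1")
        if self.max_alleles < 2:
            raise ValueError("max_alleles must be >= ploidy (2)")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")

    @property
    def within_budget(self) -> int:
        return mismatch_budget(self.similarity_s, self.locus_length)

    @property
    def across_budget(self) -> int:
        if self.catalog_mismatch_n is not None:
            return self.catalog_mismatch_n
        return self.within_budget


@dataclass
class Stack:
    """All identical reads of one sequence from one individual."""

    consensus: str
    depth: int
    individual_id: str
    read_ids: list[str] = field(default_factory=list)


@dataclass
class IndividualLocus:
    """One individual's called alleles at one clustered locus."""

    individual_id: str
    alleles: list[Stack]
    raw_allele_count: int


@dataclass
class CatalogLocus:
    """An across-individual locus: per-individual genotypes + consensus."""

    catalog_id: int
    genotypes: dict[str, IndividualLocus]
    consensus: str

    @property
    def paralog_flag(self) -> bool:
        """True when any individual shows more distinct alleles than a
        diploid can carry (the standard excess-allele paralogy filter)."""
        return any(g.raw_allele_count > 2 for g in self.genotypes.values())

    @property
    def distinct_alleles(self) -> list[str]:
        return sorted({s.consensus for g in self.genotypes.values()
                       for s in g.alleles})

    def allele_copies(self, individual_id: str) -> list[str] | None:
        """Diploid allele copies: homozygotes contribute their allele twice;
        individuals with >2 alleles yield None (paralog-contaminated)."""
        g = self.genotypes.get(individual_id)
        if g is None:
            return None
        seqs = [s.consensus for s in g.alleles]
        if len(seqs) == 1:
            return [seqs[0], seqs[0]]
        if len(seqs) == 2:
            return seqs
        return None

    @property
    def read_ids(self) -> list[str]:
        return [rid for g in self.genotypes.values()
                for s in g.alleles for rid in s.read_ids]


@dataclass
class Assembly:
    """All catalog loci built from one read set at one threshold."""

    params: AssemblyParams
    loci: list[CatalogLocus]
    provenance: dict = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def drop(self, catalog_ids: set[int]) -> "Assembly":
        """A new Assembly without the given loci (e.g. paralog-flagged)."""
        kept = [loc for loc in self.loci if loc.catalog_id not in catalog_ids]
        return Assembly(params=self.params, loci=kept,
                        provenance=dict(self.provenance,
                                        dropped=sorted(catalog_ids)))


def dereplicate(reads: list[ReadRecord]) -> list[Stack]:
    """Pile identical reads into stacks, sorted by (depth desc, seq asc)."""
    if not reads:
        return []
    L = len(reads[0].sequence)
    groups: dict[str, list[str]] = {}
    individual = reads[0].individual_id
    for r in reads:
        if len(r.sequence) != L:
            raise ValueError("mixed read lengths in one individual")
        groups.setdefault(r.sequence, []).append(r.read_id)
    stacks = [Stack(seq, len(ids), individual, ids)
              for seq, ids in groups.items()]
    stacks.sort(key=lambda s: (-s.depth, s.consensus))
    return stacks


def filter_depth(stacks: list[Stack], min_depth_m: int) -> list[Stack]:
    """Drop stacks below the depth floor; no secondary-read rescue."""
    return [s for s in stacks if s.depth >= min_depth_m]


def cluster_stacks(stacks: list[Stack], M: int) -> list[list[Stack]]:
    """Partition one individual's stacks into loci: connected components of
    the graph joining stacks at Hamming distance <= M. Components are
    ordered by their lexicographically smallest consensus."""
    if not stacks:
        return []
    mat = seqs_to_matrix([s.consensus for s in stacks])
    comps = _components(len(stacks), neighbor_pairs(mat, M))
    clusters = [[stacks[i] for i in comp] for comp in comps]
    clusters.sort(key=lambda c: min(s.consensus for s in c))
    return clusters


def _components(n: int, edges) -> list[list[int]]:
    dsu = DisjointSet(n)
    for i, j in edges:
        dsu.union(i, j)
    return dsu.components()


def call_alleles(cluster: list[Stack], max_alleles: int) -> IndividualLocus:
    """Rank a cluster's distinct consensi by (depth desc, seq asc) and keep
    the top ``max_alleles``; the pre-truncation count is retained so the
    excess-allele paralogy filter can fire even after truncation."""
    if not cluster:
        raise ValueError("empty cluster")
    merged: dict[str, Stack] = {}
    for s in cluster:
        if s.consensus in merged:
            m = merged[s.consensus]
            m.depth += s.depth
            m.read_ids = m.read_ids + s.read_ids
        else:
            merged[s.consensus] = Stack(s.consensus, s.depth, s.individual_id,
                                        list(s.read_ids))
    ranked = sorted(merged.values(), key=lambda s: (-s.depth, s.consensus))
    return IndividualLocus(individual_id=cluster[0].individual_id,
                           alleles=ranked[:max_alleles],
                           raw_allele_count=len(ranked))


def build_catalog(individual_loci: list[IndividualLocus], M: int,
                  params: AssemblyParams,
                  provenance: dict | None = None) -> Assembly:
    """Merge individual loci across individuals into catalog loci.

    Two individual loci join when the minimum Hamming distance between
    their allele sets is <= M; catalog loci are the connected components.
    The consensus is the modally most frequent allele (ties break to the
    lexicographically smallest) so assemblies are byte-reproducible.
    """
    if not individual_loci:
        return Assembly(params=params, loci=[],
                        provenance=provenance or {})
    allele_seqs: list[str] = []
    allele_locus: list[int] = []
    for idx, il in enumerate(individual_loci):
        for s in il.alleles:
            allele_seqs.append(s.consensus)
            allele_locus.append(idx)
    L = len(allele_seqs[0])
    if any(len(s) != L for s in allele_seqs):
        raise ValueError("individual loci must share the locus length")
    mat = seqs_to_matrix(allele_seqs)
    dsu = DisjointSet(len(individual_loci))
    # linking any close allele pair links their loci, which reproduces the
    # min-distance-over-allele-sets edge relation exactly
    for i, j in neighbor_pairs(mat, M):
        dsu.union(allele_locus[i], allele_locus[j])
    comps = dsu.components()
    # deterministic catalog order: by smallest allele sequence in component
    keyed = []
    for comp in comps:
        smallest = min(min(s.consensus for s in individual_loci[i].alleles)
                       for i in comp)
        keyed.append((smallest, comp))
    keyed.sort()
    loci: list[CatalogLocus] = []
    for cid, (_, comp) in enumerate(keyed):
        genotypes: dict[str, IndividualLocus] = {}
        for idx in comp:
            il = individual_loci[idx]
            if il.individual_id in genotypes:
                pooled = genotypes[il.individual_id].alleles + il.alleles
                raw = (genotypes[il.individual_id].raw_allele_count
                       + il.raw_allele_count)
                merged = call_alleles(pooled, params.max_alleles)
                merged.raw_allele_count = max(raw, merged.raw_allele_count)
                genotypes[il.individual_id] = merged
            else:
                genotypes[il.individual_id] = il
        counts: dict[str, int] = {}
        for g in genotypes.values():
            for s in g.alleles:
                counts[s.consensus] = counts.get(s.consensus, 0) + 1
        consensus = min(counts, key=lambda seq: (-counts[seq], seq))
        loci.append(CatalogLocus(catalog_id=cid, genotypes=genotypes,
                                 consensus=consensus))
    return Assembly(params=params, loci=loci, provenance=provenance or {})


def assemble(reads_by_individual: dict[str, list[ReadRecord]],
             params: AssemblyParams) -> Assembly:
    """Full pipeline: dereplicate -> depth filter -> cluster -> call ->
    catalog, for one similarity threshold."""
    M = params.within_budget
    individual_loci: list[IndividualLocus] = []
    hasher = hashlib.sha1()
    for ind in sorted(reads_by_individual):
        reads = reads_by_individual[ind]
        for r in reads:
            hasher.update(r.sequence.encode())
        stacks = filter_depth(dereplicate(reads), params.min_depth_m)
        for cluster in cluster_stacks(stacks, M):
            individual_loci.append(call_alleles(cluster, params.max_alleles))
    provenance = {
        "input_sha1": hasher.hexdigest(),
        "n_individuals": len(reads_by_individual),
        "similarity_s": params.similarity_s,
        "min_depth_m": params.min_depth_m,
    }
    return build_catalog(individual_loci, params.across_budget, params,
                         provenance)
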