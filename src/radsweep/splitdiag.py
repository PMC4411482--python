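"""Diagnostics for over- and under-splitting of assembled loci.

Two observable proxies plus, for simulated data, the true rates:

* under-splitting — loci where some individual carries more distinct
  alleles than its ploidy allows; such loci are presumed to contain
  paralogous reads and are removed before downstream statistics.
* over-splitting — loci assembled at a stringent threshold that map (by
  ungapped fixed-length comparison at >= 93% identity) onto the same locus
  of the most liberal (93%) assembly, minus a self-map baseline counting
  93% loci that map onto other 93% loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import pairwise_hamming_matrix, seqs_to_matrix
from .stackasm import Assembly, mismatch_budget

__all__ = [
    "SplitReport",
    "flag_undersplit",
    "map_loci",
    "oversplit_index",
    "selfmap_baseline",
    "true_split_rates",
]


@dataclass
class SplitReport:
    threshold: int
    n_loci: int
    undersplit_count: int = 0
    undersplit_proportion: float = 0.0
    oversplit_count: int | None = None
    oversplit_proportion: float | None = None
    baseline_selfmap_count: int | None = None
    true_oversplit_rate: float | None = None
    true_undersplit_rate: float | None = None


def flag_undersplit(assembly: Assembly) -> tuple[list[int], float]:
    """Catalog ids where any individual shows >2 distinct alleles, and the
    flagged proportion of all loci."""
    flagged = [loc.catalog_id for loc in assembly.loci if loc.paralog_flag]
    prop = len(flagged) / assembly.n_loci if assembly.n_loci else 0.0
    return flagged, prop


def map_loci(query_assembly: Assembly, reference_assembly: Assembly,
             min_identity: int = 93) -> dict[int, int]:
    """Best-hit map from query consensi to reference consensi.

    A reference is a candidate when its ungapped Hamming identity with the
    query is at least ``min_identity`` percent (distance within the usual
    floor budget); the best hit minimises distance, ties breaking to the
    lexicographically smallest reference consensus. When query and
    reference are the same assembly, self-hits are excluded. Returns
    ``{query_catalog_id: reference_catalog_id}`` for mapped queries only.
    """
    if not query_assembly.loci or not reference_assembly.loci:
        return {}
    q_seqs = [loc.consensus for loc in query_assembly.loci]
    r_seqs = [loc.consensus for loc in reference_assembly.loci]
    L = len(q_seqs[0])
    if any(len(s) != L for s in r_seqs):
        raise ValueError("query and reference assemblies differ in length")
    budget = mismatch_budget(min_identity, L)
    dm = pairwise_hamming_matrix(seqs_to_matrix(q_seqs),
                                 seqs_to_matrix(r_seqs))
    same = query_assembly is reference_assembly
    mapping: dict[int, int] = {}
    for qi, q_loc in enumerate(query_assembly.loci):
        dists = dm[qi]
        best_ri = -1
        best = (budget + 1, "")
        for ri in np.nonzero(dists <= budget)[0]:
            ri = int(ri)
            if same and reference_assembly.loci[ri].catalog_id == q_loc.catalog_id:
                continue
            key = (int(dists[ri]), r_seqs[ri])
            if best_ri == -1 or key < best:
                best, best_ri = key, ri
        if best_ri != -1:
            mapping[q_loc.catalog_id] = reference_assembly.loci[best_ri].catalog_id
    return mapping


def selfmap_baseline(liberal_assembly: Assembly, min_identity: int = 93) -> int:
    """Number of liberal-threshold loci that map onto *other* loci of the
    same assembly — the background rate subtracted from each raw count."""
    return len(map_loci(liberal_assembly, liberal_assembly, min_identity))


def oversplit_index(stringent_assembly: Assembly, liberal_assembly: Assembly,
                    min_identity: int = 93,
                    baseline: int | None = None,
                    count_mode: str = "extra") -> SplitReport:
    """Over-splitting proxy: multiple stringent loci collapsing onto one
    liberal locus.

    ``count_mode='extra'`` counts k-1 events per liberal target hit by k
    stringent loci (the default reading); ``'involved'`` counts all k. The
    self-map ``baseline`` (computed from the liberal assembly when not
    supplied) is subtracted and the result floored at zero.
    """
    t = stringent_assembly.params.similarity_s
    ref_s = liberal_assembly.params.similarity_s
    if t <= ref_s:
        raise ValueError(
            "stringent threshold must exceed the liberal reference threshold")
    if count_mode not in ("extra", "involved"):
        raise ValueError("count_mode must be 'extra' or 'involved'")
    mapping = map_loci(stringent_assembly, liberal_assembly, min_identity)
    hits: dict[int, int] = {}
    for ref_id in mapping.values():
        hits[ref_id] = hits.get(ref_id, 0) + 1
    if count_mode == "extra":
        raw = sum(max(0, k - 1) for k in hits.values())
    else:
        raw = sum(k for k in hits.values() if k > 1)
    if baseline is None:
        baseline = selfmap_baseline(liberal_assembly, min_identity)
    count = max(0, raw - baseline)
    n = stringent_assembly.n_loci
    return SplitReport(
        threshold=t, n_loci=n,
        oversplit_count=count,
        oversplit_proportion=(count / n if n else 0.0),
        baseline_selfmap_count=baseline,
    )


def true_split_rates(assembly: Assembly,
                     truth: dict[str, tuple[int, int, int]],
                     true_locus_keys: list[tuple[int, int]] | None = None,
                     ) -> tuple[float, float]:
    """Truth-based rates available only in simulation.

    true over-split rate: fraction of true loci (paralog copies counted
    separately) whose retained reads land in >= 2 catalog loci.
    true under-split rate: fraction of catalog loci containing retained
    reads from >= 2 true loci.
    """
    catalogs_of_true: dict[tuple[int, int], set[int]] = {}
    trues_of_catalog: dict[int, set[tuple[int, int]]] = {}
    for loc in assembly.loci:
        for rid in loc.read_ids:
            tag = truth.get(rid)
            if tag is None:
                raise ValueError(f"read {rid!r} has no truth tag")
            key = (tag[0], tag[1])
            catalogs_of_true.setdefault(key, set()).add(loc.catalog_id)
            trues_of_catalog.setdefault(loc.catalog_id, set()).add(key)
    if true_locus_keys is None:
        true_locus_keys = sorted({(t[0], t[1]) for t in truth.values()})
    n_true = len(true_locus_keys)
    n_over = sum(1 for key in true_locus_keys
                 if len(catalogs_of_true.get(key, ())) >= 2)
    n_cat = assembly.n_loci
    n_under = sum(1 for keys in trues_of_catalog.values() if len(keys) >= 2)
    return (n_over / n_true if n_true else 0.0,
            n_under / n_cat if n_cat else 0.0)
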