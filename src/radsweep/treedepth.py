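"""Per-locus gene-tree depth in expected substitutions per site.

Each locus's distinct alleles get a Jukes-Cantor distance matrix and a
neighbor-joining tree (negative branch lengths clamped to zero); the depth
reported is the height of the midpoint-rooted tree, i.e. half the tree
diameter (the longest tip-to-tip path). NJ on JC distances replaces
per-locus Bayesian tree inference: it is deterministic and adequate for
the handful of 100-bp alleles a locus carries, though absolute depths are
not comparable with posterior-mean depths from a Bayesian analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .popstats import SATURATION, jc_distance, p_distance
from .stackasm import Assembly, CatalogLocus

__all__ = ["GeneTreeSummary", "locus_tree", "mean_depth"]


@dataclass
class GeneTreeSummary:
    locus_id: int
    n_alleles: int
    depth: float
    newick: str | None = None
    saturated: bool = False


def _depth_from_alleles(alleles: list[str], want_newick: bool,
                        ) -> tuple[float, str | None, bool]:
    n = len(alleles)
    if n == 1:
        return 0.0, ("(a0:0.0);" if want_newick else None), False
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(alleles[i], alleles[j])
            if p >= SATURATION:
                return math.nan, None, True
            dm[i, j] = dm[j, i] = jc_distance(p)
    if n == 2:
        d = dm[0, 1]
        newick = f"(a0:{d / 2:.6g},a1:{d / 2:.6g});" if want_newick else None
        return d / 2.0, newick, False
    ids = [f"a{i}" for i in range(n)]
    tree = nj(DistanceMatrix(dm, ids), neg_as_zero=True)
    tip_dists = tree.tip_tip_distances()
    diameter = float(np.max(tip_dists.data))
    newick = str(tree).strip() if want_newick else None
    return diameter / 2.0, newick, False


def locus_tree(locus: CatalogLocus, want_newick: bool = False,
               ) -> GeneTreeSummary:
    """Depth summary for one catalog locus.

    Distinct alleles are deduplicated and ordered lexicographically before
    tree building, so the result is invariant to input order and to
    duplicated copies. Loci with a saturated pair (p >= 3/4) are flagged
    and carry a NaN depth.
    """
    alleles = locus.distinct_alleles
    if not alleles:
        raise ValueError("locus has no alleles")
    depth, newick, saturated = _depth_from_alleles(alleles, want_newick)
    return GeneTreeSummary(locus_id=locus.catalog_id, n_alleles=len(alleles),
                           depth=depth, newick=newick, saturated=saturated)


def mean_depth(assembly: Assembly, n_sample: int = 1000,
               seed: int | np.random.Generator = 0) -> float:
    """Mean gene-tree depth over a seeded random subsample of loci.

    All loci are used when the assembly holds fewer than ``n_sample``;
    monomorphic loci contribute depth 0; saturated loci are excluded.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    loci = assembly.loci
    if not loci:
        return math.nan
    if len(loci) > n_sample:
        idx = rng.choice(len(loci), size=n_sample, replace=False)
        loci = [loci[int(i)] for i in sorted(idx)]
    depths = [s.depth for s in (locus_tree(loc) for loc in loci)
              if not s.saturated]
    return float(np.mean(depths)) if depths else math.nan
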