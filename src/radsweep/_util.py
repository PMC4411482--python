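"""Shared low-level helpers: sequence packing, Hamming neighbours, union-find.

Sequences cross module boundaries as plain ``str`` over {A,C,G,T}; anything
quadratic (all-pairs mismatch counting) runs on uint8 matrices instead.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def seqs_to_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Pack equal-length ACGT strings into an (n, L) uint8 matrix of ASCII codes."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have the same length")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), L
    )


def codes_to_seqs(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`seqs_to_matrix` for base-index (0..3) matrices."""
    ascii_mat = _BASES[mat]
    return [row.tobytes().decode("ascii") for row in ascii_mat]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def pairwise_hamming_matrix(mat_a: np.ndarray, mat_b: np.ndarray | None = None,
                            chunk: int = 512) -> np.ndarray:
    """Dense (n_a, n_b) mismatch-count matrix, row-chunked to bound memory."""
    if mat_b is None:
        mat_b = mat_a
    n_a = mat_a.shape[0]
    out = np.empty((n_a, mat_b.shape[0]), dtype=np.int32)
    for lo in range(0, n_a, chunk):
        hi = min(lo + chunk, n_a)
        out[lo:hi] = (mat_a[lo:hi, None, :] != mat_b[None, :, :]).sum(axis=2)
    return out


def neighbor_pairs(mat: np.ndarray, max_mismatches: int) -> list[tuple[int, int]]:
    """All index pairs (i < j) with Hamming distance <= max_mismatches.

    Exact pigeonhole banding: the read length is split into M+1 contiguous
    blocks, so any pair within M mismatches matches exactly in at least one
    block; candidates are verified by a direct mismatch count. Falls back to
    the dense scan for small inputs.
    """
    n, L = mat.shape
    if n < 2:
        return []
    if max_mismatches >= L:
        return list(combinations(range(n), 2))
    if n <= 256 or max_mismatches + 1 > L:
        dm = pairwise_hamming_matrix(mat)
        ii, jj = np.nonzero(np.triu(dm <= max_mismatches, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    candidates: set[tuple[int, int]] = set()
    bounds = np.linspace(0, L, max_mismatches + 2).astype(int)
    for b in range(max_mismatches + 1):
        sub = np.ascontiguousarray(mat[:, bounds[b]:bounds[b + 1]])
        buckets: dict[bytes, list[int]] = {}
        for i in range(n):
            buckets.setdefault(sub[i].tobytes(), []).append(i)
        for members in buckets.values():
            if len(members) > 1:
                candidates.update(combinations(members, 2))
    if not candidates:
        return []
    pairs = np.array(sorted(candidates), dtype=np.intp)
    dist = (mat[pairs[:, 0]] != mat[pairs[:, 1]]).sum(axis=1)
    keep = pairs[dist <= max_mismatches]
    return [tuple(p) for p in keep.tolist()]


class DisjointSet:
    """Union-find with path compression; components come out in stable order."""

    def __init__(self, n: int):
        self._parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[i] != root:
            self._parent[i], i = root, self._parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self._parent[max(ri, rj)] = min(ri, rj)

    def components(self) -> list[list[int]]:
        groups: dict[int, list[int]] = {}
        for i in range(len(self._parent)):
            groups.setdefault(self.find(i), []).append(i)
        return [groups[k] for k in sorted(groups)]


def connected_components(n: int, edges: Iterable[tuple[int, int]]) -> list[list[int]]:
    dsu = DisjointSet(n)
    for i, j in edges:
        dsu.union(i, j)
    return dsu.components()
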