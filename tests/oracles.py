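"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is a deliberately naive implementation, kept separate from
the package code paths it checks.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Sequence, Tuple

import numpy as np

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def sort_median(values: Sequence[float]) -> float:
    """Median via explicit sorting and the midpoint convention."""
    ordered = sorted(values)
    n = len(ordered)
    if n % 2:
        return float(ordered[n // 2])
    return (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0


def brute_terminal_overlap(seq: str, max_frac: float = 0.5) -> int:
    """Longest exact prefix/suffix overlap by quadratic scanning."""
    best = 0
    for k in range(1, int(max_frac * len(seq)) + 1):
        prefix, suffix = seq[:k], seq[-k:]
        if "N" in prefix or "N" in suffix:
            continue
        if prefix == suffix:
            best = k
    return best


def brute_codon_counts(cds_list: Sequence[str], codons: Sequence[str]) -> np.ndarray:
    """Tally codons by dict counting over explicit triplet slices."""
    tally: Dict[str, int] = {c: 0 for c in codons}
    for cds in cds_list:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in tally:
                tally[codon] += 1
    return np.array([tally[c] for c in codons])


def brute_tetra_profile(seq: str) -> np.ndarray:
    """Sliding-window 4-mer frequencies over both strands."""
    kmers = ["".join(p) for p in product("ACGT", repeat=4)]
    index = {k: i for i, k in enumerate(kmers)}
    counts = np.zeros(256)
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - 3):
            window = s[i:i + 4]
            if window in index:
                counts[index[window]] += 1
    return counts / counts.sum()


def gotoh_score(a: str, b: str, matrix, gap_open: float = -11.0,
                gap_extend: float = -1.0) -> float:
    """Affine-gap global alignment score by explicit three-state DP.

    The first residue of a gap scores ``gap_open``; each further
    residue ``gap_extend`` (matching Biopython's convention).
    """
    n, m = len(a), len(b)
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a aligned to -)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


# ---------------------------------------------------------------------------
# Exhaustive 5-taxon topology search


def _all_topologies(taxa: Sequence[str]) -> List[List[Tuple[str, str]]]:
    """All unrooted binary topologies as edge lists over labeled nodes.

    Internal nodes are named i0, i1, ...; built by inserting taxa one at
    a time into every existing edge.
    """
    taxa = list(taxa)
    assert len(taxa) >= 3
    base = [(taxa[0], "i0"), (taxa[1], "i0"), (taxa[2], "i0")]
    trees = [(base, 1)]  # (edges, next internal index)
    for leaf in taxa[3:]:
        grown = []
        for edges, nxt in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                new_node = f"i{nxt}"
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, new_node), (v, new_node), (leaf, new_node)]
                grown.append((new_edges, nxt + 1))
        trees = grown
    return [edges for edges, _ in trees]


def _paths(edges: List[Tuple[str, str]], taxa: Sequence[str]) -> Dict[Tuple[str, str], List[int]]:
    """Leaf-pair -> indicator row over edges (which edges lie on the path)."""
    adj: Dict[str, List[Tuple[str, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(src: str, dst: str) -> List[int]:
        stack = [(src, None, [])]
        seen = set()
        while stack:
            node, _, used = stack.pop()
            if node == dst:
                return used
            seen.add(node)
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    stack.append((nxt, node, used + [eidx]))
        raise RuntimeError("disconnected topology")

    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            row = [0] * len(edges)
            for eidx in path(a, b):
                row[eidx] = 1
            out[(a, b)] = row
    return out


def _topology_bipartitions(edges: List[Tuple[str, str]], taxa: Sequence[str]) -> set:
    """Non-trivial bipartitions induced by internal edges."""
    taxa_set = frozenset(taxa)
    ref = min(taxa_set)
    adj: Dict[str, List[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    parts = set()
    for u, v in edges:
        if u in taxa_set or v in taxa_set:
            continue
        # leaves on the v side of edge (u, v)
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in taxa_set:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        clade = frozenset(side)
        if ref in clade:
            clade = taxa_set - clade
        if 2 <= len(clade) <= len(taxa_set) - 2:
            parts.add(clade)
    return parts


def best_topology_bipartitions(taxa: Sequence[str], dmat: np.ndarray) -> set:
    """Exhaustive search: least-squares-fit every unrooted topology and
    return the bipartitions of the best-fitting one."""
    index = {t: i for i, t in enumerate(taxa)}
    best = None
    for edges in _all_topologies(taxa):
        rows, dvec = [], []
        for (a, b), row in _paths(edges, taxa).items():
            rows.append(row)
            dvec.append(dmat[index[a], index[b]])
        A = np.array(rows, dtype=float)
        d = np.array(dvec)
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        residual = float(np.sum((A @ x - d) ** 2))
        if best is None or residual < best[0]:
            best = (residual, edges)
    return _topology_bipartitions(best[1], taxa)
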