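"""Distance trees of replicase homologs.

Builds neighbor-joining trees of labeled protein sets in three steps:

1. **Multiple alignment** by a deterministic center-star progressive
   scheme: the sequence with the highest summed pairwise similarity is
   the center, every other sequence is globally aligned to it, and the
   pairwise alignments are merged ("once a gap, always a gap"). A
   pre-computed alignment (aligned FASTA) can be supplied instead.
2. **Distances** from complete-gap-free columns only (columns containing
   a gap or missing data in any sequence are eliminated), using the
   Kimura-style correction for multiple substitutions,
   d = -ln(1 - p - 0.2 p^2), capped for saturated pairs.
3. **Neighbor joining** on the distance matrix, with branch support
   from bootstrap resampling of alignment columns (default 100
   replicates), reported as percentages on internal nodes of the newick
   output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .replicase import aligned_pair, make_aligner

#: Distance assigned to saturated pairs (p too large for the correction).
MAX_DISTANCE = 10.0

#: Symbols treated as missing data in alignment columns.
MISSING = {"-", ".", "X", "*"}


@dataclass
class ProteinTree:
    """NJ tree with bootstrap support, plus the column count used."""

    newick: str
    n_columns: int
    leaf_ids: Tuple[str, ...]
    tree: TreeNode


# ---------------------------------------------------------------------------
# Center-star progressive multiple alignment


def _merge_center_star(center_id: str, center_seq: str,
                       pairs: Dict[str, Tuple[str, str]]) -> Dict[str, str]:
    """Merge pairwise alignments to the center into one MSA."""
    L = len(center_seq)
    # insertions[i] = columns inserted before center residue i (i == L: after last)
    master_ins = [0] * (L + 1)
    parsed: Dict[str, List[List[str]]] = {}
    for sid, (cg, og) in pairs.items():
        blocks: List[List[str]] = [[] for _ in range(L + 1)]
        aligned: List[str] = [""] * L
        i = 0
        for c_char, o_char in zip(cg, og):
            if c_char == "-":
                blocks[i].append(o_char)
            else:
                aligned[i] = o_char
                i += 1
        parsed[sid] = [blocks, aligned]  # type: ignore[list-item]
        for i in range(L + 1):
            master_ins[i] = max(master_ins[i], len(blocks[i]))

    def expand(aligned: Sequence[str], blocks: Sequence[Sequence[str]]) -> str:
        out = []
        for i in range(L):
            ins = "".join(blocks[i])
            out.append(ins + "-" * (master_ins[i] - len(ins)))
            out.append(aligned[i])
        ins = "".join(blocks[L])
        out.append(ins + "-" * (master_ins[L] - len(ins)))
        return "".join(out)

    msa = {
        center_id: expand(list(center_seq), [[] for _ in range(L + 1)])
    }
    for sid, (blocks, aligned) in parsed.items():
        msa[sid] = expand(aligned, blocks)
    return msa


def align_multiple(sequences: Dict[str, str]) -> Dict[str, str]:
    """Center-star progressive multiple alignment of proteins."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to align")
    aligner = make_aligner()
    ids = sorted(sequences)
    if len(ids) == 2:
        a, b = ids
        ga, gb = aligned_pair(sequences[a], sequences[b], aligner)
        return {a: ga, b: gb}
    # choose the center: maximal summed alignment score, ties by id
    scores = {sid: 0.0 for sid in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = aligner.score(sequences[a].upper(), sequences[b].upper())
            scores[a] += s
            scores[b] += s
    center = max(ids, key=lambda sid: (scores[sid], sid))
    center_seq = sequences[center].upper()
    pairs = {
        sid: aligned_pair(center_seq, sequences[sid], aligner)
        for sid in ids
        if sid != center
    }
    return _merge_center_star(center, center_seq, pairs)


# ---------------------------------------------------------------------------
# Distances


def gap_free_columns(msa: Dict[str, str]) -> Tuple[List[str], np.ndarray]:
    """(ids, residue matrix) of columns with no gaps/missing data."""
    ids = sorted(msa)
    rows = [msa[sid].upper() for sid in ids]
    length = {len(r) for r in rows}
    if len(length) != 1:
        raise ValueError("aligned sequences have unequal lengths")
    arr = np.array([list(r) for r in rows])
    keep = ~np.isin(arr, sorted(MISSING)).any(axis=0)
    return ids, arr[:, keep]


def kimura_protein_distance(p: float) -> float:
    """Kimura-style corrected protein distance from a p-distance."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return MAX_DISTANCE
    return min(-float(np.log(arg)), MAX_DISTANCE)


def distance_matrix(ids: Sequence[str], columns: np.ndarray) -> np.ndarray:
    """Pairwise corrected distances from a residue-column matrix."""
    n, m = columns.shape
    if m == 0:
        raise ValueError("alignment has no complete (gap-free) columns")
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(columns[i] != columns[j]))
            dmat[i, j] = dmat[j, i] = kimura_protein_distance(p)
    return dmat


# ---------------------------------------------------------------------------
# Neighbor joining and bootstrap


def nj_tree(ids: Sequence[str], dmat: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a distance matrix."""
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(DistanceMatrix(dmat, list(ids)))
    # negative branch lengths from NJ are clamped to zero, as usual
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions as canonical frozensets of leaf names."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if ref in clade:
            clade = leaves - clade
        if 2 <= len(clade) <= len(leaves) - 2:
            parts.add(clade)
    return parts


def build_tree(sequences: Dict[str, str],
               alignment: Optional[Dict[str, str]] = None,
               n_bootstrap: int = 100,
               seed: int = 0) -> ProteinTree:
    """NJ tree of labeled proteins with column-resampling bootstrap.

    ``alignment`` (gapped FASTA contents as a dict) bypasses the
    built-in center-star aligner. Bootstrap supports are attached as
    integer percentages on internal node names of the newick output.
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    msa = alignment if alignment is not None else align_multiple(sequences)
    ids, columns = gap_free_columns(msa)
    n_columns = columns.shape[1]
    tree = nj_tree(ids, distance_matrix(ids, columns))

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: Dict[frozenset, int] = {}
        for _ in range(n_bootstrap):
            resampled = columns[:, rng.integers(0, n_columns, size=n_columns)]
            rep_tree = nj_tree(ids, distance_matrix(ids, resampled))
            for part in bipartitions(rep_tree):
                counts[part] = counts.get(part, 0) + 1
        leaves = frozenset(t.name for t in tree.tips())
        ref = min(leaves)
        for node in tree.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if ref in clade:
                clade = leaves - clade
            if 2 <= len(clade) <= len(leaves) - 2:
                support = 100.0 * counts.get(clade, 0) / n_bootstrap
                node.name = str(int(round(support)))

    newick = str(tree).strip()
    return ProteinTree(
        newick=newick,
        n_columns=n_columns,
        leaf_ids=tuple(ids),
        tree=tree,
    )
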