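import random

import numpy as np
import pytest

from repliconkit import align_multiple, build_tree
from repliconkit.tree import (
    bipartitions,
    distance_matrix,
    gap_free_columns,
    kimura_protein_distance,
    nj_tree,
)
from oracles import best_topology_bipartitions

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length):
    return "".join(rng.choice(AAS) for _ in range(length))


class TestAlignment:
    def test_center_star_preserves_residues(self):
        rng = random.Random(30)
        base = _random_protein(rng, 80)
        seqs = {
            "a": base,
            "b": base[:40] + base[50:],           # internal deletion
            "c": base[:60] + "WWWWW" + base[60:],  # insertion
            "d": base,
        }
        msa = align_multiple(seqs)
        lengths = {len(s) for s in msa.values()}
        assert len(lengths) == 1
        for sid, seq in seqs.items():
            assert msa[sid].replace("-", "") == seq

    def test_gap_free_columns_drop_gapped_sites(self):
        msa = {"a": "AC-DE", "b": "ACWDE", "c": "ACWD-"}
        ids, cols = gap_free_columns(msa)
        assert ids == ["a", "b", "c"]
        assert cols.shape == (3, 3)  # columns 1,2,4 survive

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError, match="no complete"):
            distance_matrix(["a", "b"], np.empty((2, 0)))


class TestDistances:
    def test_zero_p_distance_is_zero(self):
        assert kimura_protein_distance(0.0) == 0.0

    def test_correction_exceeds_p(self):
        for p in (0.1, 0.3, 0.5):
            assert kimura_protein_distance(p) > p

    def test_saturated_pairs_capped(self):
        assert kimura_protein_distance(0.95) == pytest.approx(10.0)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths_solve_three_point_formulas(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        dmat = np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        tree = nj_tree(["a", "b", "c"], dmat)
        tips = {t.name: t for t in tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(d_ab)
        assert tips["a"].distance(tips["c"]) == pytest.approx(d_ac)
        assert tips["b"].distance(tips["c"]) == pytest.approx(d_bc)

    def test_additive_five_taxon_matrix_recovers_generating_topology(self):
        # additive matrix from tree ((a,b),(c,d),e) with known branch lengths
        rng = np.random.default_rng(77)
        for _ in range(5):
            bl = rng.uniform(0.05, 0.5, size=7)
            # edges: a,b -> u; c,d -> v; e -> w; u-w, v-w
            pos = {
                "a": ("u", bl[0]), "b": ("u", bl[1]),
                "c": ("v", bl[2]), "d": ("v", bl[3]), "e": ("w", bl[4]),
            }
            internal = {("u", "w"): bl[5], ("v", "w"): bl[6]}

            def dist(x, y):
                px, dx = pos[x]
                py, dy = pos[y]
                if px == py:
                    return dx + dy
                extra = 0.0
                for (m, n), v in internal.items():
                    if m in (px, py):
                        extra += v
                if px == "w" or py == "w":
                    # leaf hanging off the central node: only one internal edge
                    extra = internal[("u", "w")] if "u" in (px, py) else internal[("v", "w")]
                return dx + dy + extra

            taxa = ["a", "b", "c", "d", "e"]
            dmat = np.zeros((5, 5))
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    if i < j:
                        dmat[i, j] = dmat[j, i] = dist(x, y)
            tree = nj_tree(taxa, dmat)
            # canonical form: the side not containing the reference leaf "a"
            expected = {frozenset({"c", "d", "e"}), frozenset({"c", "d"})}
            observed = bipartitions(tree)
            assert observed == expected
            # exhaustive least-squares search agrees
            assert best_topology_bipartitions(taxa, dmat) == expected
            # path metric reproduced on the additive input
            tips = {t.name: t for t in tree.tips()}
            for i, x in enumerate(taxa):
                for y in taxa[i + 1:]:
                    assert tips[x].distance(tips[y]) == pytest.approx(
                        dist(x, y), abs=1e-9
                    )

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(["a", "b"], np.zeros((2, 2)))


class TestBuildTree:
    def test_leaf_set_and_supports(self, panel):
        seqs = {e.id: e.sequence for e in panel.entries[:6]}
        result = build_tree(seqs, n_bootstrap=25, seed=3)
        assert set(result.leaf_ids) == set(seqs)
        assert result.n_columns > 0
        tree = result.tree
        assert {t.name for t in tree.tips()} == set(seqs)
        for node in tree.non_tips(include_self=False):
            if node.name is not None:
                assert 0 <= int(node.name) <= 100

    def test_duplicate_sequences_form_zero_length_pair(self, panel):
        orig = panel.entries[0].id
        seqs = {e.id: e.sequence for e in panel.entries[:4]}
        seqs["dup"] = seqs[orig]
        msa = align_multiple(seqs)
        ids, cols = gap_free_columns(msa)
        dmat = distance_matrix(ids, cols)
        i, j = ids.index("dup"), ids.index(orig)
        assert dmat[i, j] == 0.0
        result = build_tree(seqs, n_bootstrap=0)
        tips = {t.name: t for t in result.tree.tips()}
        # the identical pair sits as a cherry with zero-length terminals
        cherry = {t.name for t in tips["dup"].parent.tips()}
        assert {orig, "dup"} <= cherry
        assert tips["dup"].length == pytest.approx(0.0, abs=1e-9)

    def test_precomputed_alignment_bypasses_aligner(self):
        msa = {
            "a": "MKTA-YIAK",
            "b": "MKTAWYIAK",
            "c": "MKSAWYLAK",
            "d": "MKSA-YLAR",
        }
        result = build_tree(msa, alignment=msa, n_bootstrap=10, seed=0)
        assert result.n_columns == 8
        assert set(result.leaf_ids) == set(msa)

    def test_deterministic_given_seed(self, panel):
        seqs = {e.id: e.sequence for e in panel.entries[:5]}
        t1 = build_tree(seqs, n_bootstrap=15, seed=9)
        t2 = build_tree(seqs, n_bootstrap=15, seed=9)
        assert t1.newick == t2.newick

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_tree({"a": "MKT", "b": "MKT"})
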