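import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from repliconkit import (
    AnnotationRecord,
    GenomeSet,
    Replicon,
    Role,
    imprint_decision,
    imprint_distance,
    profile_dendrogram,
    rscu_profile,
    tetra_profile,
)
from repliconkit.imprint import (
    CODON_FAMILIES,
    RSCU_CODONS,
    TETRAMERS,
    codon_counts,
    impute_rscu,
    rscu_from_counts,
)
from oracles import brute_codon_counts, brute_tetra_profile, revcomp


def _genome_from_cds(cds_list, genome_id="g"):
    """One-chromosome genome whose sequence is the concatenated CDS."""
    seq = "".join(cds_list)
    anns = []
    pos = 1
    for cds in cds_list:
        anns.append(
            AnnotationRecord("chr", pos, pos + len(cds) - 1, "+", "CDS")
        )
        pos += len(cds)
    genome = GenomeSet(genome_id, [Replicon("chr", seq, Role.CHROMOSOME)])
    genome.add_annotations(anns)
    return genome


def _random_cds(rng, n_codons):
    sense = [c for _aa, fam in CODON_FAMILIES for c in fam]
    return "ATG" + "".join(rng.choice(sense) for _ in range(n_codons)) + "TAA"


class TestRSCU:
    def test_two_member_family_all_mass_on_one_codon(self):
        genome = _genome_from_cds(["ATG" + "TTT" * 3 + "TAA"])
        rscu = rscu_profile(genome, "chr")
        idx = {c: i for i, c in enumerate(RSCU_CODONS)}
        assert rscu[idx["TTT"]] == pytest.approx(2.0)
        assert rscu[idx["TTC"]] == pytest.approx(0.0)

    def test_uniform_usage_gives_all_ones(self):
        cds = "ATG" + "".join(RSCU_CODONS) + "TGG" + "TAA"
        rscu = rscu_profile(_genome_from_cds([cds]), "chr")
        assert np.allclose(rscu, 1.0)

    def test_matches_brute_force_tally_on_random_cds(self):
        rng = random.Random(314)
        cds_list = [_random_cds(rng, rng.randint(20, 120)) for _ in range(50)]
        counts = codon_counts(cds_list)
        assert np.array_equal(counts, brute_codon_counts(cds_list, RSCU_CODONS))
        rscu = rscu_from_counts(counts)
        pos = 0
        for _aa, fam in CODON_FAMILIES:
            k = len(fam)
            total = counts[pos: pos + k].sum()
            for j in range(k):
                assert rscu[pos + j] == pytest.approx(
                    k * counts[pos + j] / total
                )
            pos += k

    def test_family_sums_equal_family_size(self):
        rng = random.Random(7)
        cds_list = [_random_cds(rng, 200) for _ in range(5)]
        rscu = rscu_from_counts(codon_counts(cds_list))
        pos = 0
        for _aa, fam in CODON_FAMILIES:
            k = len(fam)
            block = rscu[pos: pos + k]
            if not np.isnan(block).any():
                assert block.sum() == pytest.approx(k, abs=1e-9)
            pos += k

    def test_cds_order_does_not_change_profile(self):
        rng = random.Random(8)
        cds_list = [_random_cds(rng, 50) for _ in range(10)]
        a = rscu_from_counts(codon_counts(cds_list))
        b = rscu_from_counts(codon_counts(list(reversed(cds_list))))
        assert np.allclose(a, b, equal_nan=True)

    def test_no_cds_gives_unavailable_profile(self):
        genome = GenomeSet(
            "g", [Replicon("chr", "ACGT" * 100, Role.CHROMOSOME)]
        )
        assert rscu_profile(genome, "chr") is None

    def test_minus_strand_cds_counted_in_coding_orientation(self):
        cds = "ATG" + "TTT" * 5 + "TAA"
        genome = GenomeSet(
            "g", [Replicon("chr", revcomp(cds), Role.CHROMOSOME)]
        )
        genome.add_annotations(
            [AnnotationRecord("chr", 1, len(cds), "-", "CDS")]
        )
        rscu = rscu_profile(genome, "chr")
        idx = {c: i for i, c in enumerate(RSCU_CODONS)}
        assert rscu[idx["TTT"]] == pytest.approx(2.0)


class TestTetra:
    def test_homopolymer_strand_symmetric(self):
        freq = tetra_profile("AAAAAAA")
        idx = {k: i for i, k in enumerate(TETRAMERS)}
        assert freq[idx["AAAA"]] == pytest.approx(0.5)
        assert freq[idx["TTTT"]] == pytest.approx(0.5)
        assert freq.sum() == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=200))
    def test_profile_invariant_under_reverse_complement(self, seq):
        assert np.allclose(tetra_profile(seq), tetra_profile(revcomp(seq)))

    def test_matches_sliding_window_oracle_on_random_sequence(self):
        rng = random.Random(55)
        seq = "".join(rng.choice("ACGT") for _ in range(10_000))
        assert np.allclose(tetra_profile(seq), brute_tetra_profile(seq))

    def test_windows_with_ambiguous_bases_skipped(self):
        seq = "ACGTNACGT"
        freq = tetra_profile(seq)
        assert np.allclose(freq, brute_tetra_profile(seq))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            tetra_profile("ACG")


class TestImprintDistance:
    def test_identical_vectors_distance_zero(self):
        v = np.arange(10.0)
        assert imprint_distance(v, v) == pytest.approx(0.0)

    def test_anticorrelated_vectors_distance_two(self):
        v = np.arange(10.0)
        assert imprint_distance(v, -v) == pytest.approx(2.0)

    def test_matches_pearson_formula_on_random_vectors(self):
        rng = np.random.default_rng(256)
        a, b = rng.random(256), rng.random(256)
        assert imprint_distance(a, b) == pytest.approx(1 - pearsonr(a, b)[0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            imprint_distance(np.ones(5), np.arange(5.0))


class TestImprintDecision:
    def test_host_biased_ecrs_pass_and_foreign_fail(self, end_to_end_runs):
        """Generative ground truth: ECRs drawn from the host composition
        model must look chromosome-like; ECRs drawn from the reference
        model must not (>= 95% over the fixed-seed replicates)."""
        host_ok = foreign_ok = total = 0
        for _truth, _results, decisions in end_to_end_runs:
            by_id = {d.replicon_id: d for d in decisions}
            total += 1
            host_ok += by_id["p_chromid"].imprint_pass
            foreign_ok += not by_id["p_foreign"].imprint_pass
        assert host_ok / total >= 0.95
        assert foreign_ok / total >= 0.95

    def test_source_assignment_separation(self, end_to_end_runs):
        """Both signatures assign host- and reference-drawn 20 kb+ ECRs
        to their source in >= 95% of trials (host GC 60%, reference 66%)."""
        correct = trials = 0
        for _truth, _results, decisions in end_to_end_runs:
            for d in decisions:
                if d.replicon_id == "p_chromid":
                    correct += d.cu_chromosome_like and d.tetra_chromosome_like
                    trials += 1
                elif d.replicon_id == "p_foreign":
                    correct += (not d.cu_chromosome_like
                                and not d.tetra_chromosome_like)
                    trials += 1
        assert trials == 40
        assert correct / trials >= 0.95

    def test_chromosome_subsequence_is_chromosome_like(self, sim_pair):
        genome, _truth, reference = sim_pair
        chrom = genome.chromosome
        sub_len = 20_000
        sub_anns = [
            AnnotationRecord("sub", a.start, a.end, a.strand, "CDS", a.labels)
            for a in genome.annotations_for(chrom.id)
            if a.end <= sub_len
        ]
        host = GenomeSet(
            "g2",
            [
                Replicon(chrom.id, chrom.sequence, Role.CHROMOSOME),
                Replicon("sub", chrom.sequence[:sub_len], Role.ECR),
            ],
        )
        host.add_annotations(
            [AnnotationRecord(chrom.id, a.start, a.end, a.strand, "CDS", a.labels)
             for a in genome.annotations_for(chrom.id)]
            + sub_anns
        )
        decisions = imprint_decision(host, reference)
        assert decisions[0].imprint_pass

    def test_ecr_without_cds_fails_cu_with_reason(self, sim_pair):
        genome, _truth, reference = sim_pair
        chrom = genome.chromosome
        host = GenomeSet(
            "g3",
            [
                Replicon(chrom.id, chrom.sequence, Role.CHROMOSOME),
                Replicon("bare", chrom.sequence[:5000], Role.ECR),
            ],
        )
        host.add_annotations(
            [AnnotationRecord(chrom.id, a.start, a.end, a.strand, "CDS", a.labels)
             for a in genome.annotations_for(chrom.id)]
        )
        (decision,) = imprint_decision(host, reference)
        assert not decision.cu_chromosome_like
        assert not decision.imprint_pass
        assert "CDS" in decision.reason


class TestDendrogram:
    def test_newick_contains_all_replicons(self, sim_pair):
        genome, _truth, reference = sim_pair
        newick = profile_dendrogram([genome, reference], "tetra")
        for rep in genome.replicons:
            assert f"{genome.genome_id}:{rep.id}" in newick
        assert newick.endswith(";")


def test_imputation_replaces_only_missing_families():
    rscu = np.array([2.0, 0.0, np.nan, np.nan])
    imputed = impute_rscu(rscu)
    assert imputed.tolist() == [2.0, 0.0, 1.0, 1.0]
    assert np.isnan(rscu).sum() == 2  # original untouched
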