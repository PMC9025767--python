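"""Genomic-imprint profiles: codon usage and tetranucleotide signatures.

Replicons that have co-evolved with their host chromosome converge on
its compositional signature, while recently acquired plasmids retain the
imprint of a former host. Two complementary signatures are profiled per
replicon:

* **RSCU** (relative synonymous codon usage): for codon c in a
  synonymous family F, RSCU(c) = |F| * count(c) / sum of counts over F.
  Methionine, tryptophan and stop codons carry no synonymous choice and
  are excluded, leaving a 59-dimensional vector. Codon counts are pooled
  over all CDS of the replicon (concatenation, not per-gene averaging).
* **Tetranucleotide frequency**: frequencies of the 256 overlapping
  4-mers accumulated from the sequence *and* its reverse complement so
  the signature is strand-convention-free; windows containing N are
  skipped.

Profiles are compared with the correlation distance 1 - r (Pearson),
which is scale-free and standard for compositional signatures. An ECR
is called *chromosome-like* under a signature when it lies closer to its
host chromosome than to every replicon of an internal reference genome
(an unrelated, well-characterized genome acting as outgroup). The
chromid imprint criterion requires agreement of both signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .model import GenomeSet, Role, reverse_complement

# --------------------------------------------------------------------------
# Codon machinery (standard genetic code; bacterial CDS use the same
# codon->amino-acid mapping for internal codons)

_TABLE = CodonTable.unambiguous_dna_by_id[1]

_EXCLUDED_AA = {"M", "W"}


def _build_families() -> List[Tuple[str, Tuple[str, ...]]]:
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in _TABLE.forward_table.items():
        if aa in _EXCLUDED_AA:
            continue
        by_aa.setdefault(aa, []).append(codon)
    return [(aa, tuple(sorted(c))) for aa, c in sorted(by_aa.items())]


#: Synonymous families as (amino acid, codons), alphabetical; 59 codons total.
CODON_FAMILIES: List[Tuple[str, Tuple[str, ...]]] = _build_families()

#: Canonical ordering of the 59 RSCU codons.
RSCU_CODONS: List[str] = [c for _aa, fam in CODON_FAMILIES for c in fam]

_RSCU_INDEX = {c: i for i, c in enumerate(RSCU_CODONS)}

#: Canonical ordering of the 256 tetranucleotides.
TETRAMERS: List[str] = ["".join(p) for p in product("ACGT", repeat=4)]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ImprintProfile:
    """Compositional signature of one replicon."""

    replicon_id: str
    rscu: Optional[np.ndarray]  # 59-vector, NaN for unobserved families
    tetra: np.ndarray           # 256-vector of frequencies summing to 1
    n_codons: int
    n_tetramers: int

    @property
    def cu_available(self) -> bool:
        return self.rscu is not None


@dataclass(frozen=True)
class ImprintDecision:
    """Chromosome-likeness verdict for one ECR under both signatures."""

    replicon_id: str
    cu_chromosome_like: bool
    tetra_chromosome_like: bool
    imprint_pass: bool
    reason: str = ""


# --------------------------------------------------------------------------
# RSCU


def _cds_sequences(genome: GenomeSet, replicon_id: str) -> List[str]:
    seq = genome.replicon(replicon_id).sequence
    out = []
    for rec in genome.annotations_for(replicon_id):
        if rec.feature_type != "CDS":
            continue
        sub = seq[rec.start - 1: rec.end]
        if rec.strand == "-":
            sub = reverse_complement(sub)
        out.append(sub)
    return out


def codon_counts(cds_sequences: Sequence[str]) -> np.ndarray:
    """Pooled counts of the 59 synonymous codons over a set of CDS.

    Incomplete trailing codons are trimmed; codons containing N are
    skipped; stop/ATG/TGG codons are ignored.
    """
    counts = np.zeros(len(RSCU_CODONS), dtype=np.int64)
    for cds in cds_sequences:
        usable = len(cds) - len(cds) % 3
        for i in range(0, usable, 3):
            idx = _RSCU_INDEX.get(cds[i:i + 3])
            if idx is not None:
                counts[idx] += 1
    return counts


def rscu_from_counts(counts: np.ndarray) -> np.ndarray:
    """RSCU values from codon counts; NaN for families with zero total."""
    rscu = np.full(len(RSCU_CODONS), np.nan)
    pos = 0
    for _aa, fam in CODON_FAMILIES:
        k = len(fam)
        total = counts[pos:pos + k].sum()
        if total > 0:
            rscu[pos:pos + k] = k * counts[pos:pos + k] / total
        pos += k
    return rscu


def rscu_profile(genome: GenomeSet, replicon_id: str) -> Optional[np.ndarray]:
    """RSCU vector for a replicon, or None when it has no usable CDS."""
    cds = _cds_sequences(genome, replicon_id)
    if not cds:
        return None
    counts = codon_counts(cds)
    if counts.sum() == 0:
        return None
    return rscu_from_counts(counts)


def impute_rscu(rscu: np.ndarray) -> np.ndarray:
    """Replace unobserved-family NaNs with the neutral value 1.0."""
    out = rscu.copy()
    out[np.isnan(out)] = 1.0
    return out


# --------------------------------------------------------------------------
# Tetranucleotide signature


def _tetra_counts_one_strand(sequence: str) -> np.ndarray:
    code = np.full(len(sequence), -1, dtype=np.int64)
    for base, value in _BASE_CODE.items():
        code[np.frombuffer(sequence.encode(), dtype=np.uint8)
             == ord(base)] = value
    if len(code) < 4:
        return np.zeros(256, dtype=np.int64)
    windows = (
        code[:-3] * 64 + code[1:-2] * 16 + code[2:-1] * 4 + code[3:]
    )
    valid = (
        (code[:-3] >= 0) & (code[1:-2] >= 0)
        & (code[2:-1] >= 0) & (code[3:] >= 0)
    )
    return np.bincount(windows[valid], minlength=256)


def tetra_profile(sequence: str) -> np.ndarray:
    """Strand-symmetric tetranucleotide frequency vector (sums to 1)."""
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4 nt has no tetranucleotides")
    sequence = sequence.upper()
    counts = (
        _tetra_counts_one_strand(sequence)
        + _tetra_counts_one_strand(reverse_complement(sequence))
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("no tetranucleotide window free of ambiguous bases")
    return counts / total


def tetra_count(sequence: str) -> int:
    """Number of valid 4-mer windows counted over both strands."""
    sequence = sequence.upper()
    return int(
        _tetra_counts_one_strand(sequence).sum()
        + _tetra_counts_one_strand(reverse_complement(sequence)).sum()
    )


# --------------------------------------------------------------------------
# Distances and decisions


def imprint_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation distance 1 - Pearson r, in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant vector has no correlation distance")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def profile(genome: GenomeSet, replicon_id: str) -> ImprintProfile:
    """Both signatures for one replicon."""
    rep = genome.replicon(replicon_id)
    cds = _cds_sequences(genome, replicon_id)
    rscu = None
    n_codons = 0
    if cds:
        counts = codon_counts(cds)
        n_codons = int(counts.sum())
        if n_codons > 0:
            rscu = rscu_from_counts(counts)
    return ImprintProfile(
        replicon_id=replicon_id,
        rscu=rscu,
        tetra=tetra_profile(rep.sequence),
        n_codons=n_codons,
        n_tetramers=tetra_count(rep.sequence),
    )


def _nearest_is_chromosome(ecr_vec: np.ndarray, chrom_vec: np.ndarray,
                           ref_vecs: Sequence[np.ndarray]) -> bool:
    d_chrom = imprint_distance(ecr_vec, chrom_vec)
    d_ref = min(imprint_distance(ecr_vec, v) for v in ref_vecs)
    return d_chrom < d_ref


def imprint_decision(genome: GenomeSet, reference: GenomeSet) -> List[ImprintDecision]:
    """Chromosome-likeness of every ECR, judged against a reference genome.

    For each signature the ECR is chromosome-like when its distance to
    the host chromosome is smaller than its distance to every replicon
    of the reference genome. The chromid imprint criterion passes only
    when both signatures agree. ECRs without usable CDS fail the codon
    criterion with an explicit reason.
    """
    host_chrom = profile(genome, genome.chromosome.id)
    ref_profiles = [profile(reference, r.id) for r in reference.replicons]
    ref_tetra = [p.tetra for p in ref_profiles]
    ref_rscu = [impute_rscu(p.rscu) for p in ref_profiles if p.cu_available]
    decisions = []
    for ecr in genome.ecrs:
        prof = profile(genome, ecr.id)
        tetra_like = _nearest_is_chromosome(prof.tetra, host_chrom.tetra, ref_tetra)
        reason = ""
        if not prof.cu_available or not host_chrom.cu_available or not ref_rscu:
            cu_like = False
            reason = "no usable CDS for codon-usage profile"
        else:
            cu_like = _nearest_is_chromosome(
                impute_rscu(prof.rscu), impute_rscu(host_chrom.rscu), ref_rscu
            )
        decisions.append(
            ImprintDecision(
                replicon_id=ecr.id,
                cu_chromosome_like=cu_like,
                tetra_chromosome_like=tetra_like,
                imprint_pass=cu_like and tetra_like,
                reason=reason,
            )
        )
    return decisions


# --------------------------------------------------------------------------
# Dendrogram (for figure-style inspection output)


def profile_dendrogram(genomes: Sequence[GenomeSet], signature: str = "tetra") -> str:
    """Average-linkage dendrogram over replicon profiles, as newick.

    ``signature`` selects "tetra" or "cu". Replicons without a usable
    profile under the chosen signature are skipped. Labels are
    ``genome_id:replicon_id``.
    """
    from skbio.tree import TreeNode

    labels: List[str] = []
    vectors: List[np.ndarray] = []
    for genome in genomes:
        for rep in genome.replicons:
            prof = profile(genome, rep.id)
            if signature == "tetra":
                vec = prof.tetra
            elif signature == "cu":
                if not prof.cu_available:
                    continue
                vec = impute_rscu(prof.rscu)
            else:
                raise ValueError(f"unknown signature {signature!r}")
            labels.append(f"{genome.genome_id}:{rep.id}")
            vectors.append(vec)
    if len(vectors) < 2:
        raise ValueError("need at least two profiles for a dendrogram")
    n = len(vectors)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = imprint_distance(vectors[i], vectors[j])
    linkage = average(squareform(dmat, checks=False))
    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()
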