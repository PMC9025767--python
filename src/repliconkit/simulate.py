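"""Synthetic multipartite genomes with known ground truth.

Generates closed bacterial genome sets — one chromosome plus
extrachromosomal replicons — whose every property relevant to the
pipeline is controlled:

* **Composition**: each replicon is drawn from a 3rd-order Markov
  background model plus a codon-usage model inside simulated CDS, both
  derived deterministically from a seed and a GC target. Every Markov
  context emits G+C with exactly the target probability, so realized GC
  concentrates tightly on the target, while the C/G and A/T splits vary
  by context and give each composition profile a distinctive
  tetranucleotide and codon-usage signature. An ECR can inherit the
  *host* profile (chromid-like imprint), the *reference* profile
  (foreign imprint) or a custom one.
* **Marker genes**: parA/parB partitioning, T4SS core components,
  MOB-family relaxases and a replicase gene (a diverged copy of a panel
  exemplar, back-translated with the host codon model) are written as
  labeled CDS into the GFF-ready annotations.
* **Coverage**: per-base depths are independent Poisson draws with mean
  copy_number x chromosome median depth.
* **Circularity**: a circular replicon is emitted as a linear contig
  whose first ``overlap`` bases are duplicated at its end.

The module also ships the transcribed replicon-characteristics table of
the five closed (Pseudo)Sulfitobacter genomes used for report-level
tests (sizes, GC, copy numbers, classes, partitioning, mobility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .imprint import CODON_FAMILIES
from .model import (
    AnnotationRecord,
    CoverageTrack,
    GenomeSet,
    Replicon,
    Role,
    tokenize_labels,
)
from .replicase import ReplicasePanel, load_panel

_BASES = "ACGT"

#: Sense codons of the standard code (61), canonical order.
SENSE_CODONS: List[str] = sorted(
    [c for _aa, fam in CODON_FAMILIES for c in fam] + ["ATG", "TGG"]
)

_CODON_GC = np.array([sum(b in "GC" for b in c) / 3.0 for c in SENSE_CODONS])

_AA_TO_CODONS: Dict[str, List[str]] = {}
for _aa, _fam in CODON_FAMILIES:
    _AA_TO_CODONS[_aa] = list(_fam)
_AA_TO_CODONS["M"] = ["ATG"]
_AA_TO_CODONS["W"] = ["TGG"]

_STOP = "TAA"

MARKER_PRODUCTS = {
    "parA": "ParA family partition protein",
    "parB": "ParB family partition protein",
    "virB4": "type IV secretion system ATPase VirB4",
    "virD4": "type IV secretion system coupling protein VirD4",
    "virB6": "type IV secretion system protein VirB6",
    "mobP": "MobP family relaxase",
    "mobQ": "MobQ family relaxase",
    "mobV": "MobV family relaxase",
    "mobF": "MobF family relaxase",
}

_REPLICASE_GENE_NAME = {"DnaA-like": "DnaA", "RepC_soli": "RepC"}


class CompositionProfile:
    """Seeded composition model: Markov background + codon usage.

    ``transition`` is a (64, 4) matrix of P(next base | previous 3);
    every row emits G+C with probability exactly ``gc``. ``codon_p`` is
    a distribution over the 61 sense codons whose expected GC equals
    ``gc`` (achieved by exponential tilting of seeded Dirichlet
    weights).
    """

    def __init__(self, seed_seq: Sequence[int], gc: float):
        if not (0.0 < gc < 1.0):
            raise ValueError(f"GC target must be in (0,1), got {gc}")
        self.gc = gc
        rng = np.random.default_rng(list(seed_seq))
        # Markov rows: fixed G+C mass, context-specific splits
        beta_gc = rng.beta(4.0, 4.0, size=64)   # C vs G split
        beta_at = rng.beta(4.0, 4.0, size=64)   # A vs T split
        self.transition = np.stack(
            [
                (1 - gc) * beta_at,        # A
                gc * beta_gc,              # C
                gc * (1 - beta_gc),        # G
                (1 - gc) * (1 - beta_at),  # T
            ],
            axis=1,
        )
        self._cumulative = np.cumsum(self.transition, axis=1)
        # codon distribution: Dirichlet noise tilted to the GC target.
        # The tilt target is nudged up to offset the fixed ATG start and
        # TAA stop (7 A/T bases, 1 G/C per ~200-codon gene).
        weights = rng.dirichlet(np.full(len(SENSE_CODONS), 0.8))
        weights = np.maximum(weights, 1e-6)
        gc_codon = min(max(gc + (6.0 * gc - 1.0) / 600.0, 0.01), 0.99)

        def mean_gc(lam: float) -> float:
            w = weights * np.exp(lam * _CODON_GC)
            return float(np.dot(w, _CODON_GC) / w.sum()) - gc_codon

        lam = brentq(mean_gc, -80.0, 80.0)
        w = weights * np.exp(lam * _CODON_GC)
        self.codon_p = w / w.sum()
        # family-conditional codon preferences (for back-translation)
        self._codon_index = {c: i for i, c in enumerate(SENSE_CODONS)}

    def sample_background(self, length: int, rng: np.random.Generator) -> str:
        """Draw ``length`` bases from the 3rd-order Markov background."""
        base_p = self.transition.mean(axis=0)
        base_p = base_p / base_p.sum()
        start = rng.choice(4, size=3, p=base_p)
        ctx = int(start[0]) * 16 + int(start[1]) * 4 + int(start[2])
        out = [_BASES[b] for b in start]
        if length <= 3:
            return "".join(out)[:length]
        uniforms = rng.random(length - 3)
        cum = self._cumulative
        for u in uniforms:
            b = int(np.searchsorted(cum[ctx], u, side="right"))
            b = min(b, 3)
            out.append(_BASES[b])
            ctx = (ctx * 4 + b) % 64
        return "".join(out)

    def sample_cds(self, n_codons: int, rng: np.random.Generator) -> str:
        """A CDS of ``n_codons`` internal codons plus start and stop."""
        idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=self.codon_p)
        return "ATG" + "".join(SENSE_CODONS[i] for i in idx) + _STOP

    def back_translate(self, protein: str, rng: np.random.Generator) -> str:
        """Encode a protein using the profile's codon preferences."""
        parts = []
        for aa in protein.upper():
            codons = _AA_TO_CODONS.get(aa)
            if not codons:  # unknown residue: encode as alanine
                codons = _AA_TO_CODONS["A"]
            idx = [self._codon_index[c] for c in codons]
            p = self.codon_p[idx]
            total = p.sum()
            p = p / total if total > 0 else np.full(len(idx), 1 / len(idx))
            parts.append(codons[int(rng.choice(len(codons), p=p))])
        return "".join(parts) + _STOP


@dataclass
class EcrSpec:
    """Specification of one simulated extrachromosomal replicon."""

    id: str
    length: int
    copy_number: float
    bias: str = "host"          # host | reference | custom
    gc: Optional[float] = None  # required for bias == "custom"
    circular_overlap: int = 0
    markers: Tuple[str, ...] = ()
    replicase_type: Optional[str] = None
    replicase_divergence: float = 0.1

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError(f"ECR {self.id!r}: length must be >= 1 kb")
        if self.copy_number <= 0:
            raise ValueError(f"ECR {self.id!r}: copy number must be > 0")
        if self.circular_overlap < 0:
            raise ValueError(f"ECR {self.id!r}: overlap must be >= 0")
        if self.circular_overlap >= self.length / 2:
            raise ValueError(
                f"ECR {self.id!r}: overlap {self.circular_overlap} must be "
                f"< half the length {self.length}"
            )
        if self.bias == "custom" and self.gc is None:
            raise ValueError(f"ECR {self.id!r}: custom bias requires a GC target")


@dataclass
class SimSpec:
    """Specification of one simulated genome set plus its reference."""

    seed: int
    genome_id: str = "sim"
    chromosome_length: int = 100_000
    chromosome_gc: float = 0.60
    reference_gc: float = 0.66
    reference_length: int = 80_000
    reference_n_ecrs: int = 2
    reference_ecr_length: int = 30_000
    chromosome_depth: float = 100.0
    noise: str = "poisson"
    gene_density: float = 0.7
    ecrs: List[EcrSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chromosome_length < 1000:
            raise ValueError("chromosome length must be >= 1 kb")
        if not (0.0 < self.chromosome_gc < 1.0 and 0.0 < self.reference_gc < 1.0):
            raise ValueError("GC targets must be in (0,1)")
        if self.noise != "poisson":
            raise ValueError(f"unsupported coverage noise model {self.noise!r}")

    def host_profile(self) -> CompositionProfile:
        return CompositionProfile([self.seed, 17], self.chromosome_gc)

    def reference_profile(self) -> CompositionProfile:
        return CompositionProfile([self.seed, 23], self.reference_gc)


def _make_replicon_sequence(
    rep_id: str,
    length: int,
    profile: CompositionProfile,
    rng: np.random.Generator,
    gene_density: float,
    markers: Sequence[str],
    replicase_type: Optional[str],
    replicase_divergence: float,
    panel: Optional[ReplicasePanel],
) -> Tuple[str, List[AnnotationRecord], Dict[int, str]]:
    """Core (non-duplicated) sequence with CDS annotations and products."""
    special: List[Tuple[str, str]] = []  # (cds sequence, product)
    marker_rng = rng
    if replicase_type is not None:
        if panel is None:
            panel = load_panel()
        exemplars = [e for e in panel.entries if e.type_label == replicase_type]
        if not exemplars:
            raise ValueError(f"no panel exemplar for type {replicase_type!r}")
        protein = _mutate_protein(
            exemplars[0].sequence, replicase_divergence, marker_rng
        )
        gene = _REPLICASE_GENE_NAME.get(replicase_type, replicase_type)
        special.append(
            (profile.back_translate(protein, marker_rng),
             f"replication initiation protein {gene}")
        )
    for marker in markers:
        product = MARKER_PRODUCTS.get(marker)
        if product is None:
            raise ValueError(f"unknown marker gene {marker!r}")
        n_codons = int(marker_rng.integers(150, 350))
        special.append((profile.sample_cds(n_codons, marker_rng), product))

    chunks: List[str] = []
    annotations: List[AnnotationRecord] = []
    products: Dict[int, str] = {}
    pos = 0

    def add_cds(seq: str, product: str) -> None:
        nonlocal pos
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from .model import reverse_complement

            seq = reverse_complement(seq)
        start = pos + 1
        end = pos + len(seq)
        annotations.append(
            AnnotationRecord(
                replicon_id=rep_id,
                start=start,
                end=end,
                strand=strand,
                feature_type="CDS",
                labels=tokenize_labels(product),
            )
        )
        products[len(annotations) - 1] = product
        chunks.append(seq)
        pos = end

    # leading intergenic spacer
    lead = int(rng.integers(50, 150))
    chunks.append(profile.sample_background(lead, rng))
    pos += lead
    for seq, product in special:
        add_cds(seq, product)
        gap = int(rng.integers(50, 150))
        chunks.append(profile.sample_background(gap, rng))
        pos += gap
    # filler genes up to the target density, then background tail
    while pos < length * max(min(gene_density, 0.95), 0.05):
        remaining = length - pos
        if remaining < 400:
            break
        n_codons = int(rng.integers(100, min(300, (remaining - 60) // 3)))
        add_cds(profile.sample_cds(n_codons, rng),
                "hypothetical protein")
        gap = int(rng.integers(50, 150))
        chunks.append(profile.sample_background(gap, rng))
        pos += gap
    if pos < length:
        chunks.append(profile.sample_background(length - pos, rng))
    sequence = "".join(chunks)[:length]
    annotations = [a for a in annotations if a.end <= len(sequence)]
    return sequence, annotations, products


def _mutate_protein(protein: str, rate: float,
                    rng: np.random.Generator) -> str:
    """Substitute a fraction ``rate`` of residues uniformly at random."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    n_mut = int(round(rate * len(out)))
    sites = rng.choice(len(out), size=min(n_mut, len(out)), replace=False)
    for site in sites:
        choices = [a for a in aas if a != out[site]]
        out[site] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def simulate_genome(spec: SimSpec,
                    panel: Optional[ReplicasePanel] = None
                    ) -> Tuple[GenomeSet, pd.DataFrame]:
    """Generate the genome set described by ``spec`` plus its truth table.

    Returns (genome, truth). The genome carries sequences, annotations
    and Poisson coverage tracks; the truth table records per replicon
    the intended role (chromosome/chromid/plasmid), bias source, true
    copy number, circular-overlap length and marker content. The
    intended role follows the four-criterion rule applied to the
    generating parameters: host imprint, partitioning markers, copy
    number below 2 and GC within 2.5 points of the chromosome.
    """
    rng = np.random.default_rng([spec.seed, 1])
    cov_rng = np.random.default_rng([spec.seed, 2])
    host = spec.host_profile()
    reference = spec.reference_profile()
    if panel is None and any(e.replicase_type for e in spec.ecrs):
        panel = load_panel()

    replicons: List[Replicon] = []
    annotations: List[AnnotationRecord] = []
    products: Dict[int, str] = {}
    truth_rows = []

    def register(rep: Replicon, anns: List[AnnotationRecord],
                 prods: Dict[int, str]) -> None:
        offset = len(annotations)
        replicons.append(rep)
        annotations.extend(anns)
        for i, product in prods.items():
            products[offset + i] = product

    chrom_id = f"c{spec.genome_id}"
    seq, anns, prods = _make_replicon_sequence(
        chrom_id, spec.chromosome_length, host, rng, spec.gene_density,
        markers=("parA", "parB"), replicase_type=None,
        replicase_divergence=0.0, panel=panel,
    )
    register(Replicon(id=chrom_id, sequence=seq, role_hint=Role.CHROMOSOME),
             anns, prods)
    truth_rows.append(
        {
            "replicon_id": chrom_id,
            "true_class": "chromosome",
            "bias": "host",
            "gc_target": spec.chromosome_gc,
            "true_copy_number": 1.0,
            "circular_overlap": 0,
            "markers": "parA,parB",
            "replicase_type": "",
        }
    )

    for ecr in spec.ecrs:
        if ecr.bias == "host":
            profile = host
            gc_target = spec.chromosome_gc
        elif ecr.bias == "reference":
            profile = reference
            gc_target = spec.reference_gc
        elif ecr.bias == "custom":
            profile = CompositionProfile([spec.seed, 31, len(replicons)], ecr.gc)
            gc_target = ecr.gc
        else:
            raise ValueError(f"unknown bias source {ecr.bias!r}")
        core_length = ecr.length - ecr.circular_overlap
        seq, anns, prods = _make_replicon_sequence(
            ecr.id, core_length, profile, rng, spec.gene_density,
            markers=ecr.markers, replicase_type=ecr.replicase_type,
            replicase_divergence=ecr.replicase_divergence, panel=panel,
        )
        if ecr.circular_overlap:
            seq = seq + seq[: ecr.circular_overlap]
        register(Replicon(id=ecr.id, sequence=seq, role_hint=Role.ECR),
                 anns, prods)
        has_parab = "parA" in ecr.markers and "parB" in ecr.markers
        chromidlike = (
            ecr.bias == "host"
            and has_parab
            and ecr.copy_number < 2.0
            and abs(gc_target - spec.chromosome_gc) * 100 < 2.5
        )
        truth_rows.append(
            {
                "replicon_id": ecr.id,
                "true_class": "chromid" if chromidlike else "plasmid",
                "bias": ecr.bias,
                "gc_target": gc_target,
                "true_copy_number": ecr.copy_number,
                "circular_overlap": ecr.circular_overlap,
                "markers": ",".join(ecr.markers),
                "replicase_type": ecr.replicase_type or "",
            }
        )

    genome = GenomeSet(
        genome_id=spec.genome_id,
        replicons=replicons,
        annotations=annotations,
    )
    truth = pd.DataFrame(truth_rows)
    for rep, row in zip(genome.replicons, truth_rows):
        mean = row["true_copy_number"] * spec.chromosome_depth
        depths = cov_rng.poisson(mean, size=rep.length_bp)
        genome.add_coverage(CoverageTrack(replicon_id=rep.id, depths=depths))
    genome.annotation_products = products  # for GFF export
    return genome, truth


def simulate_reference(spec: SimSpec) -> GenomeSet:
    """The internal-reference genome: chromosome plus a few ECRs, all
    drawn from the reference composition profile."""
    rng = np.random.default_rng([spec.seed, 3])
    profile = spec.reference_profile()
    replicons = []
    annotations: List[AnnotationRecord] = []
    chrom_id = "cREF"
    seq, anns, _ = _make_replicon_sequence(
        chrom_id, spec.reference_length, profile, rng, spec.gene_density,
        markers=("parA", "parB"), replicase_type=None,
        replicase_divergence=0.0, panel=None,
    )
    replicons.append(Replicon(id=chrom_id, sequence=seq, role_hint=Role.CHROMOSOME))
    annotations.extend(anns)
    for i in range(spec.reference_n_ecrs):
        rid = f"pREF_{chr(ord('a') + i)}"
        seq, anns, _ = _make_replicon_sequence(
            rid, spec.reference_ecr_length, profile, rng, spec.gene_density,
            markers=(), replicase_type=None, replicase_divergence=0.0,
            panel=None,
        )
        replicons.append(Replicon(id=rid, sequence=seq, role_hint=Role.ECR))
        annotations.extend(anns)
    return GenomeSet(genome_id="REF", replicons=replicons,
                     annotations=annotations)


def default_simulation(seed: int) -> SimSpec:
    """The canonical study-condition simulation used by the test suite.

    A 100 kb chromosome at GC 60% with a 66% GC internal reference, and
    three ECRs: a 25 kb host-imprinted chromid (parAB, 0.9 copies,
    circular with a 60 nt terminal overlap), a 25 kb foreign-imprinted
    conjugative plasmid (reference composition, parAB, T4SS), and a
    6,732 bp high-copy mobilizable plasmid (20 copies, MOBQ relaxase,
    RepY-type replicase).
    """
    return SimSpec(
        seed=seed,
        genome_id=f"sim{seed}",
        ecrs=[
            EcrSpec(
                id="p_chromid",
                length=25_000,
                copy_number=0.9,
                bias="host",
                circular_overlap=60,
                markers=("parA", "parB"),
                replicase_type="RepABC",
            ),
            EcrSpec(
                id="p_foreign",
                length=25_000,
                copy_number=0.8,
                bias="reference",
                markers=("parA", "parB", "virB4", "virD4", "virB6"),
                replicase_type="RepABC",
            ),
            EcrSpec(
                id="p_highcopy",
                length=6_732,
                copy_number=20.0,
                bias="host",
                markers=("mobQ",),
                replicase_type="RepY",
            ),
        ],
    )


# ---------------------------------------------------------------------------
# Packaged replicon-characteristics table (five closed genomes)


def load_replicon_table() -> pd.DataFrame:
    """Replicon characteristics of the five closed (Pseudo)Sulfitobacter
    genomes: sizes, GC, copy numbers, classes, replication modules,
    partitioning and mobility, as published for the deposited assemblies."""
    ref = resources.files("repliconkit") / "data" / "sulfitobacter_replicons.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def table_annotations(table: pd.DataFrame) -> Dict[str, List[AnnotationRecord]]:
    """Re-encode the table's partitioning/mobility/replicase columns as
    synthetic annotation records, one list per replicon, so the feature
    screen can be exercised against the published gene complements."""
    out: Dict[str, List[AnnotationRecord]] = {}
    for _, row in table.iterrows():
        rid = str(row["replicon_id"])
        prods: List[str] = []
        if row["partitioning"] == "yes":
            prods += [MARKER_PRODUCTS["parA"], MARKER_PRODUCTS["parB"]]
        mobility = str(row["mobility"])
        if mobility == "T4SS":
            prods += [MARKER_PRODUCTS["virB4"], MARKER_PRODUCTS["virD4"],
                      MARKER_PRODUCTS["virB6"]]
        elif mobility.startswith("MOB"):
            fam = mobility[3].upper()
            prods.append(f"Mob{fam} family relaxase")
        module = str(row["replication_module"])
        base = module.split("-")[0].split("_")[0]
        prods.append(f"replication initiation protein {base}")
        records = []
        pos = 1
        for product in prods:
            records.append(
                AnnotationRecord(
                    replicon_id=rid,
                    start=pos,
                    end=pos + 899,
                    strand="+",
                    feature_type="CDS",
                    labels=tokenize_labels(product),
                )
            )
            pos += 1000
        out[rid] = records
    return out


def summarize_replicon_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genome summary counts from the packaged table: ECRs, chromids,
    plasmids, conjugative (T4SS) plasmids and mobilizable (MOB) plasmids."""
    rows = []
    for genome_id, sub in table.groupby("genome_id", sort=False):
        ecrs = sub[sub["replicon_class"] != "chromosome"]
        plasmids = ecrs[ecrs["replicon_class"] == "plasmid"]
        rows.append(
            {
                "genome_id": genome_id,
                "n_replicons": len(sub),
                "n_ecrs": len(ecrs),
                "n_chromids": int((ecrs["replicon_class"] == "chromid").sum()),
                "n_plasmids": len(plasmids),
                "n_t4ss_plasmids": int((plasmids["mobility"] == "T4SS").sum()),
                "n_mob_plasmids": int(
                    plasmids["mobility"].str.startswith("MOB").sum()
                ),
                "n_mobile_plasmids": int(
                    (plasmids["mobility"] != "no").sum()
                ),
            }
        )
    return pd.DataFrame(rows)
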