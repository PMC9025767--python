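"""Plasmid-biology gene complements from annotation labels.

Screens each replicon's annotations for the gene sets that matter for
the chromid/plasmid decision and for mobility classification:

* **parAB partitioning system** — a ParA motor ATPase plus a ParB
  DNA-binding protein; hallmark of low-copy replicons under active
  segregation.
* **Conjugative T4SS** — called when the two universally conserved core
  components co-occur: a VirB4-like ATPase and a VirD4-like coupling
  protein. Such a replicon is self-transmissible.
* **MOB relaxase** — the oriT-nicking protein required for mobilization;
  its family (MOBP/Q/V/F/H/C) is taken from the annotation token. A
  replicon with a relaxase but no T4SS is mobilizable, not
  self-transmissible.
* **Replicase hits** — CDS carrying replication-initiator tokens, with
  their translated protein sequences, feeding the replicase typing
  stage.

Matching is token-based on gene=/product= strings against a JSON
vocabulary (domain-scan outputs can be substituted via the override
hook). Unknown tokens are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio.Seq import Seq

from .model import AnnotationRecord, GenomeSet, reverse_complement

MOB_NONE = "none"


def load_vocabulary(path: Optional[Union[str, Path]] = None) -> dict:
    """Load the token vocabulary (bundled default when path is None)."""
    if path is None:
        ref = resources.files("repliconkit") / "data" / "feature_vocabulary.json"
        return json.loads(ref.read_text())
    with open(path) as handle:
        return json.load(handle)


@dataclass
class FeatureComplement:
    """Detected plasmid-biology gene complement of one replicon."""

    replicon_id: str
    has_parAB: bool
    t4ss: bool
    mob_family: str  # MOBP/MOBQ/MOBV/MOBF/MOBH/MOBC or "none"
    replicase_hits: List[Tuple[AnnotationRecord, str]] = field(default_factory=list)


def _categories(rec: AnnotationRecord, vocab: dict) -> List[dict]:
    tokens = vocab["tokens"]
    return [tokens[t] for t in sorted(rec.labels) if t in tokens]


def detect_partitioning(annotations: Sequence[AnnotationRecord],
                        vocab: Optional[dict] = None,
                        max_distance: Optional[int] = None) -> bool:
    """True iff the replicon carries both a parA- and a parB-labeled CDS.

    With ``max_distance`` set, some parA/parB pair must additionally lie
    within that many bases (start-to-start), approximating an operon
    arrangement; by default co-presence anywhere on the replicon counts.
    """
    vocab = vocab or load_vocabulary()
    par_a = [a for a in annotations
             if any(c["category"] == "partitioning_a" for c in _categories(a, vocab))]
    par_b = [a for a in annotations
             if any(c["category"] == "partitioning_b" for c in _categories(a, vocab))]
    if not par_a or not par_b:
        return False
    if max_distance is None:
        return True
    return any(
        abs(a.start - b.start) <= max_distance for a in par_a for b in par_b
    )


def detect_mobility(annotations: Sequence[AnnotationRecord],
                    vocab: Optional[dict] = None) -> Tuple[bool, str]:
    """(t4ss, mob_family) for one replicon's annotations.

    T4SS requires co-presence of the VirB4-like ATPase and VirD4-like
    coupling-protein markers. The MOB family is that of the
    highest-priority relaxase token present (priority order from the
    vocabulary), or "none".
    """
    vocab = vocab or load_vocabulary()
    has_atpase = False
    has_coupling = False
    families = set()
    for rec in annotations:
        for entry in _categories(rec, vocab):
            cat = entry["category"]
            if cat == "t4ss_atpase":
                has_atpase = True
            elif cat == "t4ss_coupling":
                has_coupling = True
            elif cat == "relaxase":
                families.add(entry["family"])
    mob_family = MOB_NONE
    for fam in vocab.get("mob_priority", []):
        if fam in families:
            mob_family = fam
            break
    return has_atpase and has_coupling, mob_family


def _translate_cds(genome: GenomeSet, rec: AnnotationRecord) -> str:
    seq = genome.replicon(rec.replicon_id).sequence[rec.start - 1: rec.end]
    if rec.strand == "-":
        seq = reverse_complement(seq)
    usable = len(seq) - len(seq) % 3
    protein = str(Seq(seq[:usable]).translate(table=11))
    return protein.rstrip("*")


def replicase_hits(genome: GenomeSet, replicon_id: str,
                   vocab: Optional[dict] = None) -> List[Tuple[AnnotationRecord, str]]:
    """CDS with replicase tokens, paired with translated proteins."""
    vocab = vocab or load_vocabulary()
    hits = []
    for rec in genome.annotations_for(replicon_id):
        if rec.feature_type != "CDS":
            continue
        if any(c["category"] == "replicase" for c in _categories(rec, vocab)):
            hits.append((rec, _translate_cds(genome, rec)))
    return hits


def feature_complement(genome: GenomeSet, replicon_id: str,
                       vocab: Optional[dict] = None,
                       max_distance: Optional[int] = None) -> FeatureComplement:
    """Full gene-complement screen for one replicon."""
    vocab = vocab or load_vocabulary()
    annotations = genome.annotations_for(replicon_id)
    t4ss, mob_family = detect_mobility(annotations, vocab)
    return FeatureComplement(
        replicon_id=replicon_id,
        has_parAB=detect_partitioning(annotations, vocab, max_distance),
        t4ss=t4ss,
        mob_family=mob_family,
        replicase_hits=replicase_hits(genome, replicon_id, vocab),
    )


def feature_complements(genome: GenomeSet,
                        vocab: Optional[dict] = None,
                        max_distance: Optional[int] = None) -> Dict[str, FeatureComplement]:
    """Gene complements for every replicon of the genome."""
    vocab = vocab or load_vocabulary()
    return {
        rep.id: feature_complement(genome, rep.id, vocab, max_distance)
        for rep in genome.replicons
    }


def apply_mob_override(complements: Dict[str, FeatureComplement],
                       tsv_path: Union[str, Path]) -> Dict[str, FeatureComplement]:
    """Override token-derived MOB families with a precomputed relaxase scan.

    The TSV must have columns ``replicon_id`` and ``mob_family``
    (e.g. exported from an HMM-based relaxase screen). Replicons not
    listed keep their token-derived family.
    """
    table = pd.read_csv(tsv_path, sep="\t")
    for _, row in table.iterrows():
        rid = str(row["replicon_id"])
        if rid in complements:
            complements[rid].mob_family = str(row["mob_family"])
    return complements
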