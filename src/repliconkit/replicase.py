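"""Plasmid replicase typing by protein comparison against an exemplar panel.

The replication-initiation protein (replicase) defines a plasmid's type
and, within a type, its compatibility group. Nine type families are
recognized here: RepA, RepB, RepABC, DnaA-like, RepL, RepC_soli, RepQ,
RepY and RepW. A query replicase is assigned the type of its
highest-identity panel exemplar when the global-alignment identity
reaches a threshold (default 0.30, the conventional homology floor for
replication proteins); otherwise it is "unclassified".

The bundled panel (``data/replicase_panel_synthetic.faa``) consists of
synthetic exemplar proteins, generated once with a fixed seed, two per
type family; a user panel of curated proteins can be supplied in the
same FASTA format with ``|type=`` header tags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

#: The closed vocabulary of replicase type families.
REPLICASE_TYPES = (
    "RepA", "RepB", "RepABC", "DnaA-like", "RepL",
    "RepC_soli", "RepQ", "RepY", "RepW",
)

UNCLASSIFIED = "unclassified"

IDENTITY_THRESHOLD = 0.30

_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_TYPE_TAG = re.compile(r"type=([A-Za-z0-9_\-]+)")
_SUBTYPE_TAG = re.compile(r"subtype=([A-Za-z0-9_\-]+)")


@dataclass(frozen=True)
class PanelEntry:
    id: str
    sequence: str
    type_label: str
    subtype: str = ""
    source: str = ""


@dataclass
class ReplicasePanel:
    """Labeled exemplar proteins, one or more per type family."""

    entries: List[PanelEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("replicase panel is empty")
        for e in self.entries:
            if not e.type_label:
                raise ValueError(f"panel entry {e.id!r} has no type label")
            _check_protein(e.sequence, e.id)

    @property
    def types(self) -> List[str]:
        seen = []
        for e in self.entries:
            if e.type_label not in seen:
                seen.append(e.type_label)
        return seen


@dataclass(frozen=True)
class TypingResult:
    replicon_id: str
    best_type: str
    best_identity: float
    best_exemplar: str


def _check_protein(sequence: str, name: str = "") -> None:
    if not sequence:
        raise ValueError(f"protein {name!r}: empty sequence")
    bad = set(sequence.upper()) - _AA
    if bad:
        raise ValueError(f"protein {name!r}: non-amino-acid symbols {sorted(bad)!r}")


def load_panel(path: Optional[Union[str, Path]] = None) -> ReplicasePanel:
    """Load a panel FASTA; headers carry ``|type=`` (and optional
    ``|subtype=``) tags. None loads the bundled synthetic panel."""
    if path is None:
        handle = (resources.files("repliconkit") / "data"
                  / "replicase_panel_synthetic.faa")
        records = list(SeqIO.parse(str(handle), "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    entries = []
    for rec in records:
        header = rec.description
        m = _TYPE_TAG.search(header)
        if not m:
            raise ValueError(f"panel record {rec.id!r}: missing type= tag")
        sub = _SUBTYPE_TAG.search(header)
        entries.append(
            PanelEntry(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                type_label=m.group(1),
                subtype=sub.group(1) if sub else "",
                source="synthetic" if path is None else str(path),
            )
        )
    return ReplicasePanel(entries=entries)


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = -11.0,
                 gap_extend: float = -1.0) -> PairwiseAligner:
    """Global affine-gap protein aligner (Needleman-Wunsch/Gotoh)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(a: str, b: str,
                 aligner: Optional[PairwiseAligner] = None) -> Tuple[float, float]:
    """Optimal global alignment of two proteins.

    Returns (score, identity) where identity is the fraction of aligned
    columns (no dual-gap columns arise in pairwise global alignment)
    whose residues are identical.
    """
    a, b = a.upper(), b.upper()
    _check_protein(a, "query")
    _check_protein(b, "subject")
    aligner = aligner or make_aligner()
    alignment = next(iter(aligner.align(a, b)))
    col_a, col_b = alignment[0], alignment[1]
    columns = len(col_a)
    matches = sum(x == y and x != "-" for x, y in zip(col_a, col_b))
    return float(alignment.score), matches / columns if columns else 0.0


def aligned_pair(a: str, b: str,
                 aligner: Optional[PairwiseAligner] = None) -> Tuple[str, str]:
    """Gapped strings of the optimal global alignment of a and b."""
    aligner = aligner or make_aligner()
    alignment = next(iter(aligner.align(a.upper(), b.upper())))
    return str(alignment[0]), str(alignment[1])


def type_replicase(query: str, panel: ReplicasePanel,
                   replicon_id: str = "",
                   threshold: float = IDENTITY_THRESHOLD,
                   aligner: Optional[PairwiseAligner] = None) -> TypingResult:
    """Assign the type of the highest-identity panel exemplar.

    Ties on identity are broken by the higher alignment score, then by
    lexicographic exemplar id, so the result is independent of panel
    order.
    """
    aligner = aligner or make_aligner()
    best = None  # (identity, score, -lex rank) comparisons done explicitly
    for entry in sorted(panel.entries, key=lambda e: e.id):
        score, identity = global_align(query, entry.sequence, aligner)
        key = (identity, score)
        if best is None or key > best[0]:
            best = (key, entry)
    (identity, _score), entry = best
    if identity >= threshold:
        return TypingResult(replicon_id, entry.type_label, identity, entry.id)
    return TypingResult(replicon_id, UNCLASSIFIED, identity, entry.id)
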