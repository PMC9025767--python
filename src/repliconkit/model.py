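"""Core data model for multipartite bacterial genomes.

A *genome set* holds the replicons of one closed genome: exactly one
chromosome plus any number of extrachromosomal replicons (ECRs, i.e.
plasmids and chromids), together with gene annotations and optional
per-base read-depth tracks.

Coordinates are 1-based and inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

_VALID_BASES = set("ACGTN")

_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+")


class Role(str, Enum):
    """Declared role of a replicon within its genome."""

    CHROMOSOME = "chromosome"
    ECR = "ecr"
    UNKNOWN = "unknown"


def gc_percent(sequence: str) -> float:
    """GC content in percent, computed over determined (non-N) bases.

    Returns 0.0 for a sequence with no determined bases.
    """
    g = sequence.count("G")
    c = sequence.count("C")
    denom = g + c + sequence.count("A") + sequence.count("T")
    if denom == 0:
        return 0.0
    return 100.0 * (g + c) / denom


@dataclass
class Replicon:
    """One replicon: a chromosome, chromid or plasmid sequence."""

    id: str
    sequence: str
    role_hint: Role = Role.UNKNOWN

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        extra = set(self.sequence) - _VALID_BASES
        if extra:
            raise ValueError(
                f"replicon {self.id!r}: invalid characters {sorted(extra)!r}"
            )
        self.role_hint = Role(self.role_hint)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.sequence)


@dataclass
class AnnotationRecord:
    """A gene/CDS feature with normalized label tokens.

    ``labels`` holds lower-cased alphanumeric tokens extracted from the
    gene= and product= attributes, e.g. {"para", "family", "protein"}.
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature on {self.replicon_id!r}: bad interval "
                f"[{self.start}, {self.end}] (1-based inclusive, end >= start)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.labels = frozenset(t.lower() for t in self.labels)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def tokenize_labels(*texts: Optional[str]) -> frozenset:
    """Split free-text gene/product strings into lower-cased tokens."""
    out = set()
    for text in texts:
        if text:
            out.update(t.lower() for t in _TOKEN_RE.findall(text))
    return frozenset(out)


@dataclass
class CoverageTrack:
    """Per-base read depth for one replicon (dense, position 1..L)."""

    replicon_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError(
                f"coverage for {self.replicon_id!r}: depths must be a "
                "non-empty 1-D array"
            )
        if np.any(self.depths < 0):
            raise ValueError(f"coverage for {self.replicon_id!r}: negative depth")

    def __len__(self) -> int:
        return int(self.depths.size)


@dataclass
class GenomeSet:
    """All replicons of one closed genome plus annotations and coverage."""

    genome_id: str
    replicons: List[Replicon]
    annotations: List[AnnotationRecord] = field(default_factory=list)
    coverage: Dict[str, CoverageTrack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_chrom = sum(r.role_hint is Role.CHROMOSOME for r in self.replicons)
        if n_chrom != 1:
            raise ValueError(
                f"genome {self.genome_id!r}: expected exactly one chromosome, "
                f"found {n_chrom}"
            )
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.genome_id!r}: duplicate replicon ids")
        self.validate_annotations(self.annotations)
        for rid, track in self.coverage.items():
            self._check_track(rid, track)

    # -- lookups ---------------------------------------------------------

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(f"no replicon {replicon_id!r} in genome {self.genome_id!r}")

    @property
    def chromosome(self) -> Replicon:
        for r in self.replicons:
            if r.role_hint is Role.CHROMOSOME:
                return r
        raise ValueError(f"genome {self.genome_id!r} has no chromosome")

    @property
    def ecrs(self) -> List[Replicon]:
        return [r for r in self.replicons if r.role_hint is not Role.CHROMOSOME]

    def annotations_for(self, replicon_id: str) -> List[AnnotationRecord]:
        return [a for a in self.annotations if a.replicon_id == replicon_id]

    # -- mutation with validation ---------------------------------------

    def validate_annotations(self, records: Iterable[AnnotationRecord]) -> None:
        known = {r.id: r.length_bp for r in self.replicons}
        bad = []
        for rec in records:
            if rec.replicon_id not in known:
                bad.append(f"{rec.replicon_id}: unknown replicon")
            elif rec.end > known[rec.replicon_id]:
                bad.append(
                    f"{rec.replicon_id}:{rec.start}-{rec.end} exceeds length "
                    f"{known[rec.replicon_id]}"
                )
        if bad:
            raise ValueError(
                "annotations reference invalid coordinates: " + "; ".join(bad)
            )

    def add_annotations(self, records: Sequence[AnnotationRecord]) -> None:
        self.validate_annotations(records)
        self.annotations.extend(records)

    def _check_track(self, replicon_id: str, track: CoverageTrack) -> None:
        length = self.replicon(replicon_id).length_bp
        if len(track) != length:
            raise ValueError(
                f"coverage for {replicon_id!r} has {len(track)} positions, "
                f"replicon length is {length}"
            )

    def add_coverage(self, track: CoverageTrack) -> None:
        self._check_track(track.replicon_id, track)
        self.coverage[track.replicon_id] = track


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
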