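"""Readers and writers for the external formats the pipeline consumes.

Formats: FASTA (replicon sequences, via Biopython), GFF3 (CDS/gene
annotations), a headerless three-column per-base depth TSV
(replicon_id <TAB> 1-based position <TAB> depth), and a JSON
configuration naming the chromosome and the label vocabulary.
"""

from __future__ import annotations

import json
import urllib.parse
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationRecord,
    CoverageTrack,
    GenomeSet,
    Replicon,
    Role,
    tokenize_labels,
)

PathLike = Union[str, Path]


def read_replicons(path: PathLike, chromosome_id: str, genome_id: Optional[str] = None) -> GenomeSet:
    """Load replicon sequences from a FASTA file into a :class:`GenomeSet`.

    ``chromosome_id`` must name one of the FASTA records; every other
    record becomes an ECR. Sequences are uppercased.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [rec.id for rec in records]
    if chromosome_id not in ids:
        raise ValueError(
            f"chromosome id {chromosome_id!r} not among FASTA records {ids!r}"
        )
    replicons = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        role = Role.CHROMOSOME if rec.id == chromosome_id else Role.ECR
        replicons.append(Replicon(id=rec.id, sequence=seq, role_hint=role))
    return GenomeSet(genome_id=genome_id or Path(path).stem, replicons=replicons)


def write_replicons(genome: GenomeSet, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in genome.replicons
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLUMNS = 9


def _parse_attributes(field: str) -> Dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff(path: PathLike, feature_types: Iterable[str] = ("CDS", "gene")) -> List[AnnotationRecord]:
    """Read CDS/gene features from a GFF3 file.

    Label tokens are extracted from the ``gene=`` and ``product=``
    attributes (lower-cased alphanumeric tokens). Features whose type is
    not in ``feature_types`` are skipped. Coordinate sanity against
    replicon lengths is enforced later by :meth:`GenomeSet.add_annotations`.
    """
    wanted = set(feature_types)
    out: List[AnnotationRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_GFF_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = fields
            if ftype not in wanted:
                continue
            attrs = _parse_attributes(attr)
            try:
                rec = AnnotationRecord(
                    replicon_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    feature_type=ftype,
                    labels=tokenize_labels(attrs.get("gene"), attrs.get("product")),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_gff(records: Iterable[AnnotationRecord], path: PathLike,
              products: Optional[Dict[int, str]] = None) -> None:
    """Write annotation records as GFF3. ``products`` optionally maps the
    record index to a product string; otherwise labels are joined."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, rec in enumerate(records):
            product = (products or {}).get(i) or " ".join(sorted(rec.labels))
            attrs = f"ID=feat{i};product={urllib.parse.quote(product)}"
            handle.write(
                "\t".join(
                    [
                        rec.replicon_id,
                        "repliconkit",
                        rec.feature_type,
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Depth TSV


def read_depth(path: PathLike, lengths: Optional[Dict[str, int]] = None) -> Dict[str, CoverageTrack]:
    """Read a headerless 3-column depth TSV into dense coverage tracks.

    Rows are (replicon_id, 1-based position, depth). Positions absent
    from the file are filled with 0. If ``lengths`` is given, each track
    is padded to the replicon length and positions beyond it are an
    error; otherwise the track length is the maximum observed position.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["replicon_id", "pos", "depth"],
        dtype={"replicon_id": str, "pos": np.int64, "depth": np.int64},
    )
    if (table["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    if (table["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth values")
    dupes = table.duplicated(subset=["replicon_id", "pos"])
    if dupes.any():
        first = table[dupes].iloc[0]
        raise ValueError(
            f"{path}: duplicate position {first['pos']} on {first['replicon_id']!r}"
        )
    tracks: Dict[str, CoverageTrack] = {}
    for rid, group in table.groupby("replicon_id", sort=False):
        max_pos = int(group["pos"].max())
        if lengths is not None:
            if rid not in lengths:
                raise ValueError(f"{path}: unknown replicon {rid!r}")
            if max_pos > lengths[rid]:
                raise ValueError(
                    f"{path}: position {max_pos} exceeds length "
                    f"{lengths[rid]} of {rid!r}"
                )
            size = lengths[rid]
        else:
            size = max_pos
        depths = np.zeros(size, dtype=np.int64)
        depths[group["pos"].to_numpy() - 1] = group["depth"].to_numpy()
        tracks[str(rid)] = CoverageTrack(replicon_id=str(rid), depths=depths)
    return tracks


def write_depth(tracks: Iterable[CoverageTrack], path: PathLike) -> None:
    with open(path, "w") as handle:
        for track in tracks:
            rid = track.replicon_id
            for pos, depth in enumerate(track.depths, start=1):
                handle.write(f"{rid}\t{pos}\t{int(depth)}\n")


# ---------------------------------------------------------------------------
# JSON config


def load_config(path: PathLike) -> dict:
    with open(path) as handle:
        return json.load(handle)
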