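"""Chromid/plasmid classification and the replicon report.

An extrachromosomal replicon (ECR) is classified as a **chromid** —
a replicon that has stably co-evolved with the chromosome — only when
all four criteria hold:

  i.   a parAB partitioning system is present;
  ii.  the copy number is low, strictly below 2;
  iii. the GC content deviates strictly less than 2.5 percentage points
       from the chromosome;
  iv.  the genomic imprint (codon usage AND tetranucleotide signature)
       is chromosome-like.

Any failure makes it a plasmid. Thresholds are applied to
full-precision values and are configurable; values are rounded only for
display. When imprint evidence is missing the criterion fails closed
(the replicon is reported as a plasmid) with an explicit
"insufficient evidence" flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .copy_number import CopyNumberResult
from .features import MOB_NONE, FeatureComplement
from .imprint import ImprintDecision
from .model import GenomeSet

COPY_NUMBER_THRESHOLD = 2.0
DELTA_GC_THRESHOLD = 2.5

CHROMOSOME = "chromosome"
CHROMID = "chromid"
PLASMID = "plasmid"


def delta_gc(replicon_gc: float, chromosome_gc: float) -> float:
    """Absolute GC difference in percentage points."""
    return abs(replicon_gc - chromosome_gc)


def classify_criteria(partitioning: bool, copy_low: bool,
                      gc_close: bool, imprint_pass: bool) -> str:
    """Pure decision rule: chromid iff all four criteria hold."""
    return CHROMID if (partitioning and copy_low and gc_close and imprint_pass) else PLASMID


@dataclass
class ClassificationResult:
    """One replicon's classification, mirroring a replicon-report row."""

    replicon_id: str
    replicon_class: str  # chromosome / chromid / plasmid
    criteria: Dict[str, bool]
    copy_number: float
    gc_percent: float
    delta_gc: float
    has_parAB: bool = False
    t4ss: bool = False
    mob_family: str = MOB_NONE
    replicase_type: str = ""
    flags: List[str] = field(default_factory=list)

    @property
    def mobility(self) -> str:
        if self.t4ss:
            return "T4SS"
        if self.mob_family != MOB_NONE:
            return self.mob_family
        return "no"


def classify(genome: GenomeSet,
             copy_results: Sequence[CopyNumberResult],
             imprint_decisions: Optional[Sequence[ImprintDecision]] = None,
             complements: Optional[Mapping[str, FeatureComplement]] = None,
             replicase_types: Optional[Mapping[str, str]] = None,
             copy_threshold: float = COPY_NUMBER_THRESHOLD,
             gc_threshold: float = DELTA_GC_THRESHOLD) -> List[ClassificationResult]:
    """Apply the four-criterion rule to every replicon of a genome.

    ``copy_results`` must cover every replicon. Missing imprint
    decisions or feature complements fail their criteria closed, with a
    flag recording the missing evidence.
    """
    copy_by_id = {c.replicon_id: c for c in copy_results}
    missing = [r.id for r in genome.replicons if r.id not in copy_by_id]
    if missing:
        raise ValueError(f"no copy-number result for replicons: {missing!r}")
    imprint_by_id = {d.replicon_id: d for d in (imprint_decisions or [])}
    complements = complements or {}
    replicase_types = replicase_types or {}
    chrom = genome.chromosome
    chrom_gc = chrom.gc_percent

    results = []
    for rep in genome.replicons:
        comp = complements.get(rep.id)
        dec = imprint_by_id.get(rep.id)
        dgc = delta_gc(rep.gc_percent, chrom_gc)
        flags: List[str] = []
        criteria = {
            "partitioning": bool(comp and comp.has_parAB),
            "copy_low": copy_by_id[rep.id].copy_number < copy_threshold,
            "gc_close": dgc < gc_threshold,
            "imprint_pass": bool(dec and dec.imprint_pass),
        }
        if rep.id == chrom.id:
            cls = CHROMOSOME
        else:
            if comp is None:
                flags.append("insufficient evidence: no feature screen")
            if dec is None:
                flags.append("insufficient evidence: no imprint decision")
            elif dec.reason:
                flags.append(f"imprint: {dec.reason}")
            cls = classify_criteria(**{
                "partitioning": criteria["partitioning"],
                "copy_low": criteria["copy_low"],
                "gc_close": criteria["gc_close"],
                "imprint_pass": criteria["imprint_pass"],
            })
        results.append(
            ClassificationResult(
                replicon_id=rep.id,
                replicon_class=cls,
                criteria=criteria,
                copy_number=copy_by_id[rep.id].copy_number,
                gc_percent=rep.gc_percent,
                delta_gc=dgc,
                has_parAB=bool(comp and comp.has_parAB),
                t4ss=bool(comp and comp.t4ss),
                mob_family=comp.mob_family if comp else MOB_NONE,
                replicase_type=replicase_types.get(rep.id, ""),
                flags=flags,
            )
        )
    return results


def report(results: Sequence[ClassificationResult],
           genome: Optional[GenomeSet] = None) -> pd.DataFrame:
    """Replicon report table (GC and copy number rounded to 1 d.p.)."""
    lengths = {r.id: r.length_bp for r in genome.replicons} if genome else {}
    rows = []
    for res in results:
        rows.append(
            {
                "replicon_id": res.replicon_id,
                "size_bp": lengths.get(res.replicon_id),
                "replicon_class": res.replicon_class,
                "gc": round(res.gc_percent, 1),
                "copy_number": round(res.copy_number, 1),
                "delta_gc": round(res.delta_gc, 1),
                "replication_module": res.replicase_type,
                "partitioning": "yes" if res.has_parAB else "no",
                "mobility": res.mobility,
                "flags": "; ".join(res.flags),
            }
        )
    return pd.DataFrame(rows)


def summarize(results: Sequence[ClassificationResult]) -> Dict[str, int]:
    """Per-genome summary counts of ECR classes and mobility.

    ``n_mob_plasmids`` counts plasmids carrying a MOB relaxase but no
    T4SS (mobilizable); ``n_t4ss_plasmids`` counts conjugative plasmids;
    ``n_mobile_plasmids`` is their union (any transfer capability).
    """
    ecrs = [r for r in results if r.replicon_class != CHROMOSOME]
    plasmids = [r for r in ecrs if r.replicon_class == PLASMID]
    return {
        "n_ecrs": len(ecrs),
        "n_chromids": sum(r.replicon_class == CHROMID for r in ecrs),
        "n_plasmids": len(plasmids),
        "n_t4ss_plasmids": sum(r.t4ss for r in plasmids),
        "n_mob_plasmids": sum(
            (r.mob_family != MOB_NONE) and not r.t4ss for r in plasmids
        ),
        "n_mobile_plasmids": sum(
            r.t4ss or r.mob_family != MOB_NONE for r in plasmids
        ),
    }
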