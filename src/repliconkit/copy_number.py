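"""Replicon copy-number estimation from read depth.

The copy number of an extrachromosomal replicon is the ratio of its
median per-base coverage to the median per-base coverage of the
chromosome, so the chromosome is 1.0 by definition. The median is robust
to coverage spikes at repeats and to dips at replication termini, which
is why it is preferred over the mean for this ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .model import CoverageTrack, GenomeSet


@dataclass(frozen=True)
class CopyNumberResult:
    replicon_id: str
    median_depth: float
    copy_number: float


def median_depth(track: CoverageTrack) -> float:
    """Median of the per-base depths (even-length ties are averaged).

    Zero-depth positions count: they are genuine observations of the
    replicon's coverage, not missing data.
    """
    if len(track) == 0:
        raise ValueError(f"coverage track {track.replicon_id!r} is empty")
    return float(np.median(track.depths))


def copy_numbers(genome: GenomeSet) -> List[CopyNumberResult]:
    """Per-replicon copy numbers relative to the chromosome's median depth.

    Every replicon of the genome must carry a coverage track. Raises if
    the chromosome's median depth is zero (the ratio is undefined).
    """
    chrom = genome.chromosome
    missing = [r.id for r in genome.replicons if r.id not in genome.coverage]
    if missing:
        raise ValueError(f"no coverage track for replicons: {missing!r}")
    chrom_median = median_depth(genome.coverage[chrom.id])
    if chrom_median == 0:
        raise ValueError(
            f"chromosome {chrom.id!r} has zero median depth; "
            "copy-number ratios are undefined"
        )
    results = []
    for rep in genome.replicons:
        med = median_depth(genome.coverage[rep.id])
        results.append(
            CopyNumberResult(
                replicon_id=rep.id,
                median_depth=med,
                copy_number=med / chrom_median,
            )
        )
    return results


def copy_number_table(genome: GenomeSet) -> "pd.DataFrame":
    """Copy numbers as a report table (lengths, medians, ratios)."""
    import pandas as pd

    rows = []
    by_id: Dict[str, int] = {r.id: r.length_bp for r in genome.replicons}
    for res in copy_numbers(genome):
        rows.append(
            {
                "replicon_id": res.replicon_id,
                "length": by_id[res.replicon_id],
                "median_depth": res.median_depth,
                "copy_number": res.copy_number,
            }
        )
    return pd.DataFrame(rows)
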