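"""Segment copy-number status calling and the HER2-vs-centromere relation.

Status thresholds on the baseline-2 intensity scale: below 1.8 is a
deletion, above 2.2 an amplification, and the closed interval [1.8, 2.2] is
normal (the printed boundary row at 1.80 is normal, which fixes the
inclusivity). Amplifications split further into high (>= 4-fold) and
moderate (< 4-fold) strata.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .probe_io import normalize_chrom
from .segmentation import Segment

DELETION_THRESHOLD = 1.8
AMPLIFICATION_THRESHOLD = 2.2
HIGH_FOLD_THRESHOLD = 4.0
#: tolerance for calling the HER2 and centromere values "in balance"
RELATION_TOLERANCE = 0.2

#: HER2 locus interval, Hg19, 1-based inclusive.
HER2_INTERVAL: tuple[str, int, int] = ("17", 37_642_255, 37_970_066)
#: Chromosome-17 centromere-proximal window (flanks of the Hg19 centromeric
#: gap). The FISH reference-probe footprint is not published; this default
#: is configurable wherever it is used.
CENTROMERE_INTERVAL: tuple[str, int, int] = ("17", 22_200_000, 25_800_000)


class CnStatus(str, enum.Enum):
    deletion = "del"
    normal = "normal"
    amplification = "amp"


class Relation(str, enum.Enum):
    balance = "balance"
    her2plus = "HER2plus"
    centplus = "centplus"


class FoldClass(str, enum.Enum):
    high = "high"
    moderate = "moderate"
    none = "none"


def classify_cn(mean_intensity: float) -> CnStatus:
    """Threshold a segment mean into deletion / normal / amplification."""
    if not np.isfinite(mean_intensity) or mean_intensity < 0:
        raise ValueError(f"mean intensity must be finite and >= 0, got {mean_intensity}")
    if mean_intensity < DELETION_THRESHOLD:
        return CnStatus.deletion
    if mean_intensity > AMPLIFICATION_THRESHOLD:
        return CnStatus.amplification
    return CnStatus.normal


def fold_class(mean_intensity: float) -> FoldClass:
    if classify_cn(mean_intensity) is not CnStatus.amplification:
        return FoldClass.none
    return FoldClass.high if mean_intensity >= HIGH_FOLD_THRESHOLD else FoldClass.moderate


@dataclass(frozen=True)
class Her2Call:
    her2_cn: float
    cent_cn: float
    relation: Relation
    status: CnStatus
    fold: FoldClass

    def to_dict(self) -> dict:
        return {
            "her2_cn": self.her2_cn,
            "cent_cn": self.cent_cn,
            "relation": self.relation.value,
            "status": self.status.value,
            "fold_class": self.fold.value,
        }


def parse_interval(text: str) -> tuple[str, int, int]:
    """Parse ``chr17:37642255-37970066`` (1-based inclusive) into a tuple."""
    m = re.fullmatch(r"(chr)?([0-9XY]+):([0-9,]+)-([0-9,]+)", text.strip())
    if not m:
        raise ValueError(f"cannot parse genomic interval {text!r}")
    chrom = normalize_chrom(m.group(2))
    start = int(m.group(3).replace(",", ""))
    end = int(m.group(4).replace(",", ""))
    if start > end:
        raise ValueError(f"interval start after end in {text!r}")
    return chrom, start, end


def relation_label(her2_cn: float, cent_cn: float, tolerance: float = RELATION_TOLERANCE) -> Relation:
    diff = her2_cn - cent_cn
    if abs(diff) <= tolerance + 1e-12:  # guard the boundary against fp noise
        return Relation.balance
    return Relation.her2plus if diff > 0 else Relation.centplus


def _interval_weighted_mean(segments: Sequence[Segment], interval: tuple[str, int, int]) -> float:
    chrom, start, end = normalize_chrom(interval[0]), interval[1], interval[2]
    weights = []
    means = []
    for seg in segments:
        if seg.chrom != chrom:
            continue
        overlap = min(seg.end_pos, end) - max(seg.start_pos, start) + 1
        if overlap <= 0:
            continue
        # approximate probes-in-interval: segment probe count scaled by the
        # overlapped fraction of the segment span
        frac = overlap / seg.length_bp()
        weights.append(seg.n_probes * frac)
        means.append(seg.mean_intensity)
    if not weights:
        raise ValueError(f"no segment overlaps interval {chrom}:{start}-{end}")
    return float(np.average(means, weights=weights))


def her2_call(
    segments: Sequence[Segment],
    her2_interval: tuple[str, int, int] = HER2_INTERVAL,
    cent_interval: tuple[str, int, int] = CENTROMERE_INTERVAL,
    relation_tolerance: float = RELATION_TOLERANCE,
) -> Her2Call:
    """HER2-locus and centromere-window values plus the relation label.

    Values are probe-count-weighted means of the segment means overlapping
    each interval, so a breakpoint inside an interval does not bias the call
    toward either flank.
    """
    her2_cn = _interval_weighted_mean(segments, her2_interval)
    cent_cn = _interval_weighted_mean(segments, cent_interval)
    return Her2Call(
        her2_cn=her2_cn,
        cent_cn=cent_cn,
        relation=relation_label(her2_cn, cent_cn, relation_tolerance),
        status=classify_cn(her2_cn),
        fold=fold_class(her2_cn),
    )


def cohort_status_summary(cn_values: Sequence[float]) -> dict[str, int]:
    """Status and fold-class counts over a cohort of segment copy numbers."""
    if len(cn_values) == 0:
        raise ValueError("cohort_status_summary requires a non-empty list")
    counts = {"amplification": 0, "deletion": 0, "normal": 0, "high_fold": 0, "moderate_fold": 0}
    for value in cn_values:
        status = classify_cn(value)
        if status is CnStatus.amplification:
            counts["amplification"] += 1
            if value >= HIGH_FOLD_THRESHOLD:
                counts["high_fold"] += 1
            else:
                counts["moderate_fold"] += 1
        elif status is CnStatus.deletion:
            counts["deletion"] += 1
        else:
            counts["normal"] += 1
    return counts


def minimal_amplicon_span(start: int, end: int) -> int:
    """Interval length in kb, rounded half-up to the nearest integer."""
    if end <= start:
        raise ValueError(f"interval end must exceed start, got {start}..{end}")
    return int(math.floor((end - start) / 1000 + 0.5))
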