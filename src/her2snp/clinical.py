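"""IHC/FISH classification, the virtual FISH ratio, and concordance analysis.

IHC 3+ is positive outright; IHC 2+ is equivocal and resolved by the
FISH HER2/CEP17 ratio at an inclusive cut-off of 2; IHC 0/1+ is negative
without FISH. The SNP-side call is positive when the HER2 segment status is
amplification; concordance cross-tabulates the two per sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .cn_calls import CnStatus, classify_cn
from .probe_io import ClinicalRecord

FISH_CUTOFF = 2.0


class Basis(str, enum.Enum):
    ihc3 = "ihc3"
    ihc2_fish_amplified = "ihc2_fish_amplified"
    ihc2_fish_not_amplified = "ihc2_fish_not_amplified"
    ihc_low = "ihc_low"


@dataclass(frozen=True)
class IhcFishCall:
    positive: bool
    basis: Basis

    def __post_init__(self) -> None:
        expected = self.basis in (Basis.ihc3, Basis.ihc2_fish_amplified)
        if self.positive != expected:
            raise ValueError("positivity inconsistent with basis")


def ihc_fish_classify(ihc: int, fish_ratio: Optional[float] = None) -> IhcFishCall:
    """Combined IHC/FISH positivity call."""
    if ihc not in (0, 1, 2, 3):
        raise ValueError(f"IHC score must be 0, 1, 2 or 3, got {ihc!r}")
    if ihc == 3:
        return IhcFishCall(True, Basis.ihc3)
    if ihc == 2:
        if fish_ratio is None:
            raise ValueError("IHC 2+ is equivocal and requires a FISH ratio")
        if fish_ratio >= FISH_CUTOFF:
            return IhcFishCall(True, Basis.ihc2_fish_amplified)
        return IhcFishCall(False, Basis.ihc2_fish_not_amplified)
    return IhcFishCall(False, Basis.ihc_low)


def virtual_fish(her2_copies: float, cep17_copies: float) -> tuple[float, bool]:
    """HER2/CEP17 signal ratio with the inclusive cut-off at 2.

    Being a ratio it is scale-invariant, which is exactly why
    co-amplification of the centromere region (and whole-genome polyploidy)
    can mask a real HER2 amplification.
    """
    if cep17_copies <= 0:
        raise ValueError("CEP17 copies must be > 0")
    if her2_copies < 0:
        raise ValueError("HER2 copies must be >= 0")
    ratio = her2_copies / cep17_copies
    return ratio, ratio >= FISH_CUTOFF


@dataclass
class ConcordanceReport:
    n_records: int
    n_concordant: int
    n_discrepant: int
    n_ihc_fish_positive: int
    discrepant_negative: int  # discrepant samples whose IHC/FISH call was negative
    discrepant_positive: int
    discrepant_by_ihc: dict[int, tuple[int, int]]  # ihc score -> (discrepant, total)
    concordant_ids: list[int]
    discrepant_ids: list[int]
    discrepant_negative_ids: list[int]
    discrepant_positive_ids: list[int]
    excluded_ids: list[int]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_concordant": self.n_concordant,
            "n_discrepant": self.n_discrepant,
            "n_ihc_fish_positive": self.n_ihc_fish_positive,
            "discrepant_negative": self.discrepant_negative,
            "discrepant_positive": self.discrepant_positive,
            "discrepant_by_ihc": {str(k): list(v) for k, v in self.discrepant_by_ihc.items()},
            "concordant_ids": self.concordant_ids,
            "discrepant_ids": self.discrepant_ids,
            "discrepant_negative_ids": self.discrepant_negative_ids,
            "discrepant_positive_ids": self.discrepant_positive_ids,
            "excluded_ids": self.excluded_ids,
        }


def concordance(records: Sequence[ClinicalRecord], use_revised: bool = False) -> ConcordanceReport:
    """Cross-tabulate the SNP amplification call against the IHC/FISH call.

    SNP-positive means segment status = amplification under the threshold
    classifier applied to the record's segment copy number. Records whose
    IHC/FISH inputs cannot be classified (equivocal IHC without a ratio) are
    excluded and listed.
    """
    concordant_ids: list[int] = []
    discrepant_ids: list[int] = []
    discrepant_negative_ids: list[int] = []
    discrepant_positive_ids: list[int] = []
    excluded_ids: list[int] = []
    n_positive = 0
    by_ihc_total: dict[int, int] = {0: 0, 1: 0, 2: 0, 3: 0}
    by_ihc_discrepant: dict[int, int] = {0: 0, 1: 0, 2: 0, 3: 0}

    for record in records:
        ihc, fish = record.effective(use_revised)
        try:
            call = ihc_fish_classify(ihc, fish)
        except ValueError:
            excluded_ids.append(record.sample_id)
            continue
        by_ihc_total[ihc] += 1
        if call.positive:
            n_positive += 1
        snp_positive = classify_cn(record.snp_segment_cn) is CnStatus.amplification
        if snp_positive == call.positive:
            concordant_ids.append(record.sample_id)
        else:
            discrepant_ids.append(record.sample_id)
            by_ihc_discrepant[ihc] += 1
            if call.positive:
                discrepant_positive_ids.append(record.sample_id)
            else:
                discrepant_negative_ids.append(record.sample_id)

    return ConcordanceReport(
        n_records=len(records),
        n_concordant=len(concordant_ids),
        n_discrepant=len(discrepant_ids),
        n_ihc_fish_positive=n_positive,
        discrepant_negative=len(discrepant_negative_ids),
        discrepant_positive=len(discrepant_positive_ids),
        discrepant_by_ihc={s: (by_ihc_discrepant[s], by_ihc_total[s]) for s in (0, 1, 2, 3)},
        concordant_ids=concordant_ids,
        discrepant_ids=discrepant_ids,
        discrepant_negative_ids=discrepant_negative_ids,
        discrepant_positive_ids=discrepant_positive_ids,
        excluded_ids=excluded_ids,
    )
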