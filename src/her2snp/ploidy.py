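"""Ploidy inference from segment intensities plus allelic-balance patterns.

Genome-mean normalization maps every uniform genome onto the same intensity
baseline, so intensity alone cannot distinguish a diploid from a tetraploid.
Heterozygous allele ratios break the tie: a segment with ``c`` total copies
of which ``a`` carry the A allele clusters at ``a / c`` (diluted toward 0.5
by normal-cell contamination). For each candidate genome baseline ``P`` we
quantize every segment's intensity into implied integer copies, predict the
admissible heterozygous band set, and score the fraction of evidentiary
segments whose observed bands are explainable; the smallest ``P`` reaching
the score floor is reported, flagged as a lower bound when ``P + 1``
explains the data equally well. A sample is polyploid when the median
implied copy number across chromosomes is at least 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .segmentation import Segment

logger = logging.getLogger(__name__)

#: probes with an allele ratio within this distance of 0 or 1 are treated as
#: germline-homozygous and excluded from band clustering
HOMOZYGOUS_MARGIN = 0.08
#: a single surviving mode within this distance of 0.5 means "balanced"
BALANCE_TOLERANCE = 0.05
#: observed-vs-predicted band matching tolerance in the consistency score
BAND_MATCH_TOLERANCE = 0.04
#: fraction of evidentiary segments that must be explainable
SCORE_FLOOR = 0.95
MIN_SNP_PROBES = 30
DEFAULT_P_RANGE = range(2, 13)


@dataclass(frozen=True)
class AllelicState:
    """Clustered heterozygous allele-ratio bands of one segment."""

    het_band_centers: tuple[float, ...]  # mirror-closed, sorted
    balanced: bool
    loh: bool
    determined: bool = True
    n_het_probes: int = 0

    def __post_init__(self) -> None:
        centers = tuple(sorted(self.het_band_centers))
        object.__setattr__(self, "het_band_centers", centers)
        if self.balanced and self.loh:
            raise ValueError("a segment cannot be both balanced and LOH")
        for c in centers:
            if not any(math.isclose(c, 1.0 - other, abs_tol=1e-6) for other in centers):
                raise ValueError("band centers must be mirror-closed")

    @classmethod
    def undetermined(cls) -> "AllelicState":
        return cls(het_band_centers=(), balanced=False, loh=False, determined=False)


def _kde_modes(values: np.ndarray, grid_step: float = 0.002, rel_height: float = 0.25) -> list[float]:
    """Modes of a mirror-augmented 1-D KDE over [0, 1]."""
    augmented = np.concatenate([values, 1.0 - values])
    spread = float(np.std(augmented))
    if spread < 1e-6:
        return sorted({float(np.round(values[0], 6)), float(np.round(1 - values[0], 6))})
    kde = gaussian_kde(augmented, bw_method=max(0.025, min(0.06, spread * 0.5)) / spread)
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    density = kde(grid)
    peak = density.max()
    modes: list[float] = []
    for i in range(1, len(grid) - 1):
        if density[i] >= density[i - 1] and density[i] > density[i + 1] and density[i] >= rel_height * peak:
            modes.append(float(grid[i]))
    # merge near-duplicate peaks from plateau sampling
    merged: list[float] = []
    for m in modes:
        if merged and m - merged[-1] < 0.03:
            merged[-1] = (merged[-1] + m) / 2
        else:
            merged.append(m)
    # enforce exact mirror closure on the merged peak list
    closed = set()
    for m in merged:
        lo, hi = min(m, 1 - m), max(m, 1 - m)
        if abs(hi - lo) < 0.02:
            closed.add(0.5)
        else:
            closed.add(round(lo, 6))
            closed.add(round(hi, 6))
    return sorted(closed)


def detect_allelic_state(allele_ratios: Sequence[float]) -> AllelicState:
    """Cluster one segment's allele ratios into mirror-symmetric het bands.

    Ratios within :data:`HOMOZYGOUS_MARGIN` of 0 or 1 are discarded as
    germline-homozygous; LOH is declared when essentially nothing survives.
    Fewer than :data:`MIN_SNP_PROBES` input ratios yields an undetermined
    state that downstream scoring ignores.
    """
    ratios = np.asarray([r for r in allele_ratios if r is not None and np.isfinite(r)], dtype=np.float64)
    if ratios.size < MIN_SNP_PROBES:
        return AllelicState.undetermined()
    het = ratios[(ratios > HOMOZYGOUS_MARGIN) & (ratios < 1.0 - HOMOZYGOUS_MARGIN)]
    if het.size < max(5, 0.05 * ratios.size):
        return AllelicState(het_band_centers=(), balanced=False, loh=True, n_het_probes=int(het.size))
    modes = _kde_modes(het)
    folded = sorted({min(m, 1.0 - m) for m in modes})
    balanced = len(folded) == 1 and abs(folded[0] - 0.5) <= BALANCE_TOLERANCE
    if balanced:
        modes = [0.5]
    return AllelicState(
        het_band_centers=tuple(modes),
        balanced=balanced,
        loh=False,
        n_het_probes=int(het.size),
    )


def implied_copies(mean_intensity: float, baseline_ploidy: int) -> int:
    """Quantize a baseline-2 intensity onto integer copies for baseline ``P``."""
    if baseline_ploidy < 1:
        raise ValueError("baseline ploidy must be >= 1")
    if mean_intensity < 0:
        raise ValueError("mean intensity must be >= 0")
    return int(math.floor(mean_intensity * baseline_ploidy / 2.0 + 0.5))  # round half-up


def implied_copies_with_purity(mean_intensity: float, baseline_ploidy: int, purity: float) -> int:
    """Purity-aware inverse of the intensity model.

    On a genome at baseline ``P`` with tumor-cell fraction ``p``, a segment
    with ``c`` copies shows intensity ~ 2 (p c + 2(1-p)) / (p P + 2(1-p));
    inverting that affine map before rounding keeps quantization honest at
    low purity. Reduces to :func:`implied_copies` at purity 1."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    if purity == 0.0:
        return 2  # contamination only: every segment reads as the normal genome
    baseline_mix = purity * baseline_ploidy + 2.0 * (1.0 - purity)
    c = (mean_intensity * baseline_mix / 2.0 - 2.0 * (1.0 - purity)) / purity
    return max(0, int(math.floor(c + 0.5)))


def predicted_het_bands(total_copies: int, purity: float) -> list[float]:
    """Admissible heterozygous band centers for ``c`` total copies at a purity."""
    if total_copies <= 1:
        return []
    den = purity * total_copies + (1.0 - purity) * 2.0
    return [(purity * a + (1.0 - purity)) / den for a in range(1, total_copies)]


def _segment_consistent(
    segment: Segment, state: AllelicState, baseline: int, purity: float, band_tol: float
) -> bool:
    c = implied_copies_with_purity(segment.mean_intensity, baseline, purity)
    if state.loh:
        # copy-neutral or amplified LOH: an (a, 0) split exists for any c >= 1
        return True
    if state.balanced and c % 2 != 0:
        return False
    predicted = predicted_het_bands(c, purity)
    if not predicted:
        return False  # het bands observed but none are possible
    return all(any(abs(b - q) <= band_tol for q in predicted) for b in state.het_band_centers)


def consistency_score(
    segments: Sequence[Segment],
    states: Sequence[AllelicState],
    baseline: int,
    purity: float = 1.0,
    band_tol: float = BAND_MATCH_TOLERANCE,
) -> float:
    """Fraction of evidentiary segments explainable under baseline ``P``.

    NaN when no segment has a determined allelic state (unevaluable sample).
    """
    if len(segments) != len(states):
        raise ValueError("segments and states must be parallel")
    n_evidence = 0
    n_consistent = 0
    for segment, state in zip(segments, states):
        if not state.determined:
            continue
        n_evidence += 1
        if _segment_consistent(segment, state, baseline, purity, band_tol):
            n_consistent += 1
    if n_evidence == 0:
        return float("nan")
    return n_consistent / n_evidence


@dataclass(frozen=True)
class PloidyCall:
    min_ploidy: Optional[int]
    is_lower_bound: bool
    polyploid: Optional[bool]
    per_chromosome_copies: dict[str, float]
    upd_flags: tuple[tuple[str, int, int], ...]
    resolved: bool
    best_p: Optional[int] = None
    best_score: Optional[float] = None
    reason: Optional[str] = None

    def render_ploidy(self) -> str:
        if not self.resolved:
            return "unresolved"
        return f"{self.min_ploidy}+" if self.is_lower_bound else str(self.min_ploidy)

    def to_dict(self) -> dict:
        return {
            "min_ploidy": self.min_ploidy,
            "is_lower_bound": self.is_lower_bound,
            "polyploid": self.polyploid,
            "per_chromosome_copies": self.per_chromosome_copies,
            "upd_flags": [list(f) for f in self.upd_flags],
            "resolved": self.resolved,
            "best_p": self.best_p,
            "best_score": self.best_score,
            "reason": self.reason,
            "rendered": self.render_ploidy(),
        }


def _weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    order = np.argsort(values)
    v = np.asarray(values, dtype=np.float64)[order]
    w = np.asarray(weights, dtype=np.float64)[order]
    cum = np.cumsum(w)
    cutoff = cum[-1] / 2.0
    return float(v[np.searchsorted(cum, cutoff)])


def infer_ploidy(
    segments: Sequence[Segment],
    states: Sequence[AllelicState],
    purity: float = 1.0,
    p_range: range = DEFAULT_P_RANGE,
    score_floor: float = SCORE_FLOOR,
    band_tol: float = BAND_MATCH_TOLERANCE,
) -> PloidyCall:
    """Minimal genome baseline consistent with intensities and allele bands."""
    scores: dict[int, float] = {}
    min_ploidy: Optional[int] = None
    for candidate in p_range:
        score = consistency_score(segments, states, candidate, purity, band_tol)
        if math.isnan(score):
            return PloidyCall(
                min_ploidy=None,
                is_lower_bound=False,
                polyploid=None,
                per_chromosome_copies={},
                upd_flags=(),
                resolved=False,
                reason="no evidentiary segments (all allelic states undetermined)",
            )
        scores[candidate] = score
        if score >= score_floor:
            min_ploidy = candidate
            break
    if min_ploidy is None:
        best_p = max(scores, key=lambda p: scores[p])
        return PloidyCall(
            min_ploidy=None,
            is_lower_bound=False,
            polyploid=None,
            per_chromosome_copies={},
            upd_flags=(),
            resolved=False,
            best_p=best_p,
            best_score=scores[best_p],
            reason=f"no baseline in {p_range.start}..{p_range.stop - 1} reaches score floor {score_floor}",
        )

    next_p = min_ploidy + 1
    is_lower_bound = (
        next_p in p_range
        and consistency_score(segments, states, next_p, purity, band_tol) >= score_floor
    )

    per_chrom: dict[str, float] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(
            (implied_copies_with_purity(seg.mean_intensity, min_ploidy, purity), seg.n_probes)
        )
    for chrom, pairs in by_chrom.items():
        per_chrom[chrom] = _weighted_median([c for c, _ in pairs], [w for _, w in pairs])

    upd_flags = tuple(
        (seg.chrom, seg.start_pos, seg.end_pos)
        for seg, state in zip(segments, states)
        if state.determined and state.loh
        and implied_copies_with_purity(seg.mean_intensity, min_ploidy, purity) == 2
    )
    polyploid = float(np.median(list(per_chrom.values()))) >= 3.0
    return PloidyCall(
        min_ploidy=min_ploidy,
        is_lower_bound=is_lower_bound,
        polyploid=polyploid,
        per_chromosome_copies=per_chrom,
        upd_flags=upd_flags,
        resolved=True,
        best_p=min_ploidy,
        best_score=scores[min_ploidy],
    )


def her2_absolute_copies(her2_cn: float, ploidy_call: PloidyCall) -> Optional[tuple[int, bool]]:
    """(integer copies, lower-bound flag) at the HER2 locus; None if unresolved."""
    if not ploidy_call.resolved or ploidy_call.min_ploidy is None:
        return None
    return implied_copies(her2_cn, ploidy_call.min_ploidy), ploidy_call.is_lower_bound


def states_for_segments(probeset, segments: Sequence[Segment]) -> list[AllelicState]:
    """Assign each segment the allelic state of the probes it spans."""
    states = []
    for seg in segments:
        ratios = probeset.allele_ratios(seg.chrom)
        positions = probeset.positions(seg.chrom)
        mask = (positions >= seg.start_pos) & (positions <= seg.end_pos)
        vals = ratios[mask]
        states.append(detect_allelic_state(vals[np.isfinite(vals)]))
    return states
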