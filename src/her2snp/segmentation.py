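"""Breakpoint detection by recursive bisection on probe intensities.

A split between two neighboring runs of probes is accepted when all of the
following hold:

1. the two sides have statistically different mean intensities
   (Welch two-sample t-test, p below ``alpha``, default 0.001);
2. among admissible positions the one with the smallest p-value is chosen
   (ties broken leftmost);
3. both sides retain at least ``min_points`` probes (100 for SNP500K
   arrays, 200 for SNP6);
4. the two side means differ by at least ``min_magnitude_factor`` times a
   robust per-chromosome noise estimate (default factor 0.3).

Accepted halves are re-bisected until no admissible split passes; the
resulting segments tile every probe of the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .probe_io import PLATFORM_MIN_POINTS, ProbeSet

logger = logging.getLogger(__name__)

NOISE_ESTIMATORS = ("mad_diff",)


@dataclass(frozen=True)
class Segment:
    """A contiguous run of probes with homogeneous mean intensity."""

    chrom: str
    start_pos: int
    end_pos: int
    start_idx: Optional[int]  # 0-based, half-open, within the chromosome's probes
    end_idx: Optional[int]
    n_probes: int
    mean_intensity: float
    boundary_p: Optional[float] = None  # p of the test at the left breakpoint
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("segment start_pos must be <= end_pos")
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")

    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.001
    min_points: Optional[int] = None  # None -> platform default
    min_magnitude_factor: float = 0.3
    noise_estimator: str = "mad_diff"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_points is not None and self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if self.min_magnitude_factor < 0:
            raise ValueError("min_magnitude_factor must be >= 0")
        if self.noise_estimator not in NOISE_ESTIMATORS:
            raise ValueError(f"unknown noise estimator {self.noise_estimator!r}")

    def resolve_min_points(self, platform: str) -> int:
        if self.min_points is not None:
            return self.min_points
        return PLATFORM_MIN_POINTS[platform]


def estimate_noise(intensities: Sequence[float]) -> float:
    """Robust probe-level noise sd: MAD of lag-1 differences x 1.4826 / sqrt(2).

    Differencing removes segment-level mean structure, so a handful of true
    steps does not inflate the estimate; the constants calibrate the MAD to
    the sd of Gaussian noise.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size < 3:
        raise ValueError("noise estimation requires at least 3 probes")
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def _log_t_sf(t_abs: np.ndarray, df: np.ndarray) -> np.ndarray:
    """log of the Student-t upper tail, stable far into the tail.

    scipy's ``t.logsf`` underflows to -inf around |t| ~ 1e2 at moderate df;
    beyond that we substitute the leading term of the regularized
    incomplete-beta expansion, sf(t) ~ 0.5 * z^(df/2) / ((df/2) B(df/2, 1/2))
    with z = df / (df + t^2)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logsf = stats.t.logsf(t_abs, df)
        deep = np.isneginf(logsf) & np.isfinite(t_abs) & np.isfinite(df)
        if np.any(deep):
            z = df / (df + t_abs**2)
            asym = (
                np.log(0.5)
                + (df / 2.0) * np.log(z)
                - np.log(df / 2.0)
                - special.betaln(df / 2.0, 0.5)
            )
            logsf = np.where(deep, asym, logsf)
    return logsf


def _welch_logp_vectorized(
    n1: np.ndarray, m1: np.ndarray, v1: np.ndarray, n2: np.ndarray, m2: np.ndarray, v2: np.ndarray
) -> np.ndarray:
    """Log of the two-sided Welch t-test p-value.

    Working in log space keeps split selection well resolved where the raw
    p-value would underflow to 0. Zero pooled variance degenerates to
    log(1) = 0 for equal means and -inf otherwise."""
    se2 = v1 / n1 + v2 / n2
    dm = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dm / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        logp = np.log(2.0) + _log_t_sf(np.abs(t), df)
    degenerate = se2 <= 0
    if np.any(degenerate):
        logp = np.where(degenerate, np.where(dm == 0, 0.0, -np.inf), logp)
    logp = np.where(np.isnan(logp), 0.0, logp)
    return logp


def best_split(
    intensities: Sequence[float], lo: int, hi: int, min_points: int
) -> Optional[tuple[int, float]]:
    """Most significant admissible split of ``intensities[lo:hi]``.

    Returns ``(k, p)`` where ``k`` is the absolute index starting the right
    half, scanning every split leaving >= ``min_points`` probes on each side
    and minimizing the Welch t-test p-value (leftmost on ties). ``None`` when
    the window is too short to admit any split.
    """
    x = np.asarray(intensities, dtype=np.float64)
    n = hi - lo
    if n < 2 * min_points:
        return None
    seg = x[lo:hi]
    seg = seg - seg.mean()  # centering improves prefix-sum conditioning
    cs = np.cumsum(seg)
    cs2 = np.cumsum(seg * seg)
    k = np.arange(min_points, n - min_points + 1)  # size of the left side
    n1 = k.astype(np.float64)
    n2 = (n - k).astype(np.float64)
    left_sum = cs[k - 1]
    left_sq = cs2[k - 1]
    m1 = left_sum / n1
    m2 = (cs[-1] - left_sum) / n2
    v1 = np.maximum(left_sq - left_sum**2 / n1, 0.0) / (n1 - 1)
    v2 = np.maximum((cs2[-1] - left_sq) - (cs[-1] - left_sum) ** 2 / n2, 0.0) / (n2 - 1)
    logp = _welch_logp_vectorized(n1, m1, v1, n2, m2, v2)
    best = int(np.argmin(logp))  # argmin returns the first (leftmost) minimum
    return lo + int(k[best]), float(np.exp(logp[best]))


def segment_chromosome(
    intensities: Sequence[float],
    positions: Sequence[int],
    params: SegmentationParams = SegmentationParams(),
    chrom: str = "1",
    min_points: Optional[int] = None,
    sample_id: Optional[str] = None,
) -> list[Segment]:
    """Recursively bisect one chromosome's probes into segments.

    A chromosome with fewer than ``min_points`` probes is returned as a
    single (flagged-by-log) segment. The per-chromosome noise estimate is
    fixed once before recursion and used for the magnitude criterion at
    every accepted split.
    """
    x = np.asarray(intensities, dtype=np.float64)
    pos = np.asarray(positions, dtype=np.int64)
    if x.size != pos.size:
        raise ValueError("intensities and positions must have equal length")
    if x.size == 0:
        raise ValueError("cannot segment an empty chromosome")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    mp = min_points if min_points is not None else (params.min_points or 100)

    def make_segment(lo: int, hi: int, boundary_p: Optional[float]) -> Segment:
        return Segment(
            chrom=chrom,
            start_pos=int(pos[lo]),
            end_pos=int(pos[hi - 1]),
            start_idx=lo,
            end_idx=hi,
            n_probes=hi - lo,
            mean_intensity=float(np.mean(x[lo:hi])),
            boundary_p=boundary_p,
            sample_id=sample_id,
        )

    if x.size < mp:
        logger.warning(
            "chromosome %s has %d probes (< min_points=%d); emitting a single unsplit segment",
            chrom, x.size, mp,
        )
        return [make_segment(0, x.size, None)]

    noise = estimate_noise(x) if x.size >= 3 else 0.0
    magnitude_floor = params.min_magnitude_factor * noise

    def accepted(lo: int, hi: int) -> Optional[tuple[int, float]]:
        found = best_split(x, lo, hi, mp)
        if found is None:
            return None
        k, p = found
        mean_diff = abs(float(np.mean(x[lo:k])) - float(np.mean(x[k:hi])))
        if p < params.alpha and mean_diff >= magnitude_floor:
            return k, p
        return None

    breakpoints: list[tuple[int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        found = accepted(lo, hi)
        if found is not None:
            k, p = found
            recurse(lo, k)
            breakpoints.append((k, p))
            recurse(k, hi)

    recurse(0, x.size)
    breakpoints.sort()

    # local refinement: greedy bisection can place a split between two true
    # change points; re-locate (or prune) each breakpoint within the window
    # bounded by its neighbors, using the same acceptance tests
    for _ in range(10):
        changed = False
        bounds = [0] + [k for k, _ in breakpoints] + [x.size]
        for i in range(len(breakpoints)):
            found = accepted(bounds[i], bounds[i + 2])
            if found is None:
                del breakpoints[i]
                changed = True
                break
            if found[0] != breakpoints[i][0]:
                breakpoints[i] = found
                changed = True
                break
        if not changed:
            break

    segments = []
    edges = [0] + [k for k, _ in breakpoints] + [x.size]
    pvals = [None] + [p for _, p in breakpoints]
    for lo, hi, p in zip(edges, edges[1:], pvals):
        segments.append(make_segment(lo, hi, p))
    return segments


def segment_sample(
    probeset: ProbeSet, params: SegmentationParams = SegmentationParams()
) -> list[Segment]:
    """Segment every chromosome of a (normalized) ProbeSet."""
    if len(probeset) == 0:
        raise ValueError("empty ProbeSet")
    mp = params.resolve_min_points(probeset.platform)
    segments: list[Segment] = []
    for chrom in probeset.chromosomes():
        chrom_segments = segment_chromosome(
            probeset.intensities(chrom),
            probeset.positions(chrom),
            params,
            chrom=chrom,
            min_points=mp,
            sample_id=probeset.sample_id,
        )
        logger.info(
            "sample %s chromosome %s: %d probes -> %d segment(s)",
            probeset.sample_id, chrom, len(probeset.positions(chrom)), len(chrom_segments),
        )
        segments.extend(chrom_segments)
    return segments
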