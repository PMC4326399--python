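"""Synthetic probe-level data for tumor genomes with known karyotypes.

The signal model: a probe in a region with tumor total copies ``c`` (germline
2) has pre-normalization expected intensity ``purity*c + (1-purity)*2`` plus
Gaussian noise; a germline-heterozygous SNP probe carrying ``a`` copies of
its A allele has expected allele ratio
``(purity*a + (1-purity)*1) / (purity*c + (1-purity)*2)`` plus noise, clipped
to [0, 1]; germline-homozygous probes sit near 0 or 1. Output intensities
are always passed through :func:`~her2snp.probe_io.normalize_baseline2`, so
whole-genome ploidy is deliberately invisible at the intensity level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .probe_io import ProbeSet, load_genome_table, normalize_baseline2, normalize_chrom


@dataclass(frozen=True)
class RegionState:
    """A genomic interval with fixed parental copy counts (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    copies_a: int
    copies_b: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.copies_a < 0 or self.copies_b < 0:
            raise ValueError("copy counts must be non-negative")

    @property
    def total(self) -> int:
        return self.copies_a + self.copies_b


@dataclass(frozen=True)
class KaryotypeSpec:
    """Everything needed to simulate one tumor sample."""

    background_a: int = 1
    background_b: int = 1
    regions: tuple[RegionState, ...] = ()
    purity: float = 1.0
    noise_sd: float = 0.1
    baf_sd: float = 0.03
    probes_per_mb: float = 4.0
    het_fraction: float = 0.6
    seed: int = 0
    #: optional intensity response exponent (< 1 compresses high copies)
    compression: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        if self.background_a < 0 or self.background_b < 0 or self.background_ploidy < 1:
            raise ValueError("background ploidy must be >= 1 with non-negative parental counts")
        if self.noise_sd < 0 or self.baf_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.probes_per_mb <= 0:
            raise ValueError("probes_per_mb must be > 0")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0, 1]")
        if self.compression is not None and not 0 < self.compression <= 1:
            raise ValueError("compression exponent must lie in (0, 1]")
        by_chrom: dict[str, list[RegionState]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regs in by_chrom.items():
            regs.sort(key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping regions on chromosome {chrom}")

    @property
    def background_ploidy(self) -> int:
        return self.background_a + self.background_b

    def validate_against_genome(self, genome: dict[str, int]) -> None:
        for r in self.regions:
            if r.chrom not in genome:
                raise ValueError(f"region chromosome {r.chrom} absent from genome table")
            if r.end > genome[r.chrom]:
                raise ValueError(f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome length")

    def state_at(self, chrom: str, pos: int) -> tuple[int, int]:
        for r in self.regions:
            if r.chrom == chrom and r.start <= pos <= r.end:
                return r.copies_a, r.copies_b
        return self.background_a, self.background_b


def expected_intensity(total_copies: int, purity: float, compression: Optional[float] = None) -> float:
    """Pre-normalization expected intensity of the purity mixture."""
    raw = purity * total_copies + (1.0 - purity) * 2.0
    if compression is not None:
        raw = 2.0 * (raw / 2.0) ** compression
    return raw


def expected_allele_ratio(copies_a: int, total_copies: int, purity: float) -> float:
    """Expected A-allele fraction for a germline-heterozygous probe."""
    den = purity * total_copies + (1.0 - purity) * 2.0
    if den == 0:
        return 0.5  # zero DNA: ratio undefined, report the symmetric value
    return (purity * copies_a + (1.0 - purity) * 1.0) / den


def simulate_probeset(
    spec: KaryotypeSpec,
    genome: Optional[dict[str, int]] = None,
    sample_id: str = "sim",
    platform: str = "SNP500K",
) -> ProbeSet:
    """Draw a normalized ProbeSet for one karyotype. Same spec => same output."""
    if genome is None:
        genome = load_genome_table()
    genome = {normalize_chrom(c): int(l) for c, l in genome.items()}
    spec.validate_against_genome(genome)
    rng = np.random.default_rng(spec.seed)

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    from .probe_io import chrom_sort_key

    for chrom in sorted(genome, key=chrom_sort_key):
        length = genome[chrom]
        n = max(1, int(round(length / 1e6 * spec.probes_per_mb)))
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + 1
        chroms.append(chrom)
        positions.append(pos)

    all_chrom: list[str] = []
    all_pos: list[np.ndarray] = []
    all_intensity: list[np.ndarray] = []
    all_ratio: list[np.ndarray] = []
    for chrom, pos in zip(chroms, positions):
        n = pos.size
        copies_a = np.full(n, spec.background_a, dtype=np.int64)
        copies_b = np.full(n, spec.background_b, dtype=np.int64)
        for region in spec.regions:
            if region.chrom != chrom:
                continue
            in_region = (pos >= region.start) & (pos <= region.end)
            copies_a[in_region] = region.copies_a
            copies_b[in_region] = region.copies_b
        total = copies_a + copies_b

        mu = spec.purity * total + (1.0 - spec.purity) * 2.0
        if spec.compression is not None:
            mu = 2.0 * (mu / 2.0) ** spec.compression
        intensity = mu + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else mu.astype(float)
        intensity = np.maximum(intensity, 0.0)

        is_het = rng.random(n) < spec.het_fraction
        coin = rng.random(n) < 0.5
        # het germline: the A allele rides one parental haplotype; hom
        # germline: every tumor and normal copy carries the same allele
        a_copies = np.where(coin, copies_a, copies_b)
        den = spec.purity * total + (1.0 - spec.purity) * 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            het_mu = (spec.purity * a_copies + (1.0 - spec.purity)) / den
        het_mu = np.where(den == 0, 0.5, het_mu)
        mu_r = np.where(is_het, het_mu, np.where(coin, 1.0, 0.0))
        ratios = mu_r + rng.normal(0.0, spec.baf_sd, size=n) if spec.baf_sd > 0 else mu_r
        ratios = np.clip(ratios, 0.0, 1.0)

        all_chrom.extend([chrom] * n)
        all_pos.append(pos)
        all_intensity.append(np.asarray(intensity, dtype=np.float64))
        all_ratio.append(np.asarray(ratios, dtype=np.float64))

    probeset = ProbeSet.from_arrays(
        all_chrom,
        np.concatenate(all_pos),
        np.concatenate(all_intensity),
        np.concatenate(all_ratio),
        sample_id=sample_id,
        platform=platform,
    )
    return normalize_baseline2(probeset)


# ---------------------------------------------------------------------------
# Cohort scenarios
# ---------------------------------------------------------------------------

CHR17_LEN = 81_195_210
# 17p + pericentromeric block vs 17q arm; both comfortably exceed the
# SNP500K min_points at the default probe density.
_CHR17_P_ARM = (1, 26_000_000)
_CHR17_Q_ARM = (26_500_001, CHR17_LEN)

SCENARIOS = (
    "diploid",
    "her2_amp",
    "coamp",
    "polyploid",
    "polyploid_her2_amp",
    "cnloh",
)


def _chr17_arms(genome: dict[str, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    if "17" not in genome:
        raise ValueError("HER2 scenarios require chromosome 17 in the genome table")
    length = genome["17"]
    split = min(_CHR17_P_ARM[1], length // 2)
    return (1, split), (split + 500_001, length)


def _other_chroms(genome: dict[str, int], n: int) -> list[str]:
    from .probe_io import chrom_sort_key

    candidates = [c for c in sorted(genome, key=chrom_sort_key) if c != "17"]
    if len(candidates) < n:
        raise ValueError(f"scenario needs at least {n} non-chr17 chromosomes")
    # spread picks across the genome rather than taking the first few
    step = max(1, len(candidates) // n)
    return candidates[::step][:n]


def _scenario_spec(
    scenario: str, seed: int, purity: float, rng: np.random.Generator, genome: dict[str, int]
) -> KaryotypeSpec:
    base = dict(purity=purity, seed=seed)
    if scenario == "diploid":
        return KaryotypeSpec(background_a=1, background_b=1, **base)
    if scenario == "her2_amp":
        p_arm, q_arm = _chr17_arms(genome)
        amp = int(rng.integers(3, 7))  # total copies of the 17q arm
        return KaryotypeSpec(
            background_a=1,
            background_b=1,
            regions=(RegionState("17", *q_arm, copies_a=amp - 1, copies_b=1),),
            **base,
        )
    if scenario == "coamp":
        p_arm, q_arm = _chr17_arms(genome)
        amp = int(rng.integers(4, 7))
        return KaryotypeSpec(
            background_a=1,
            background_b=1,
            regions=(
                RegionState("17", *p_arm, copies_a=amp - 1, copies_b=1),
                RegionState("17", *q_arm, copies_a=amp - 1, copies_b=1),
            ),
            **base,
        )
    if scenario in ("polyploid", "polyploid_her2_amp"):
        ploidy = int(rng.integers(3, 9))
        bg_a = (ploidy + 1) // 2
        bg_b = ploidy // 2
        regions: list[RegionState] = []
        if ploidy % 2 == 0:
            # balanced background: seed a few imbalanced whole chromosomes so
            # the ploidy is identifiable from allele ratios
            for chrom in _other_chroms(genome, 4):
                regions.append(
                    RegionState(chrom, 1, genome[chrom], copies_a=bg_a + 1, copies_b=bg_b - 1)
                )
        if scenario == "polyploid_her2_amp":
            _, q_arm = _chr17_arms(genome)
            regions.append(
                RegionState("17", *q_arm, copies_a=bg_a + max(2, ploidy // 2), copies_b=bg_b)
            )
        return KaryotypeSpec(background_a=bg_a, background_b=bg_b, regions=tuple(regions), **base)
    if scenario == "cnloh":
        regions = tuple(
            RegionState(chrom, 1, genome[chrom], copies_a=2, copies_b=0)
            for chrom in _other_chroms(genome, 2)
        )
        return KaryotypeSpec(background_a=1, background_b=1, regions=regions, **base)
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def make_paper_like_cohort(
    n_samples: int,
    scenario_mix: dict[str, float],
    seed: int = 0,
    genome: Optional[dict[str, int]] = None,
    purity_range: tuple[float, float] = (0.7, 1.0),
) -> list[tuple[ProbeSet, KaryotypeSpec]]:
    """A reproducible labeled cohort drawn from the named scenario mix.

    Scenario counts are apportioned deterministically (floor + largest
    remainder) and then shuffled; each sample gets its own child seed, so a
    fixed (n, mix, seed) triple yields a byte-identical cohort.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for name in scenario_mix:
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    total = sum(scenario_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"scenario mix proportions must sum to 1, got {total}")

    quotas = {name: frac * n_samples for name, frac in scenario_mix.items()}
    counts = {name: int(math.floor(q)) for name, q in quotas.items()}
    leftover = n_samples - sum(counts.values())
    for name in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:leftover]:
        counts[name] += 1

    if genome is None:
        genome_table = load_genome_table()
    else:
        genome_table = {normalize_chrom(c): int(l) for c, l in genome.items()}

    rng = np.random.default_rng(seed)
    assignments = [name for name in sorted(counts) for _ in range(counts[name])]
    rng.shuffle(assignments)

    cohort: list[tuple[ProbeSet, KaryotypeSpec]] = []
    for i, scenario in enumerate(assignments):
        child_seed = int(rng.integers(0, 2**31 - 1))
        purity = float(rng.uniform(*purity_range))
        spec = _scenario_spec(scenario, child_seed, purity, rng, genome_table)
        probeset = simulate_probeset(spec, genome=genome_table, sample_id=f"sim{i + 1:03d}_{scenario}")
        cohort.append((probeset, spec))
    return cohort
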