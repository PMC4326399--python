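"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from her2snp.probe_io import load_table1_fixture, load_table2_fixture
from her2snp.sim_genome import KaryotypeSpec, RegionState


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


def toy_genome(n_chroms: int = 20, mb: int = 40, special: dict[str, int] | None = None) -> dict[str, int]:
    """A small genome of equally sized chromosomes labeled '1'..'n'."""
    genome = {str(i): mb * 1_000_000 for i in range(1, n_chroms + 1)}
    if special:
        genome.update({c: m * 1_000_000 for c, m in special.items()})
    return genome


def _whole_chrom(genome: dict[str, int], chrom: str, a: int, b: int) -> RegionState:
    return RegionState(chrom, 1, genome[chrom], copies_a=a, copies_b=b)


#: per-ploidy whole-chromosome allele splits that make the baseline
#: identifiable from heterozygous band positions (see karyotype builder)
_PLOIDY_DESIGNS: dict[int, tuple[tuple[int, int], dict[str, tuple[int, int]]]] = {
    2: ((1, 1), {"3": (2, 1), "7": (2, 1), "9": (2, 0)}),
    3: ((2, 1), {"5": (3, 1)}),
    4: ((2, 2), {"3": (3, 1), "7": (3, 1), "11": (3, 1), "15": (2, 1), "18": (2, 1)}),
    6: ((3, 3), {"3": (4, 2), "7": (4, 2), "11": (4, 2), "15": (4, 1), "18": (4, 1)}),
    8: ((4, 4), {"3": (5, 3), "7": (5, 3), "11": (5, 2), "15": (5, 2), "18": (7, 1)}),
}


def ploidy_karyotype(
    ploidy: int,
    seed: int,
    purity: float = 0.85,
    noise_sd: float = 0.1,
    baf_sd: float = 0.03,
) -> tuple[KaryotypeSpec, dict[str, int]]:
    """A 20-chromosome karyotype at the given genome baseline.

    Backgrounds are the near-even parental split; a handful of chromosomes
    carry imbalanced or aneuploid states chosen so that no smaller baseline
    can explain the heterozygous band positions.
    """
    if ploidy not in _PLOIDY_DESIGNS:
        raise ValueError(f"no recovery design for ploidy {ploidy}")
    genome = toy_genome()
    (bg_a, bg_b), overrides = _PLOIDY_DESIGNS[ploidy]
    regions = tuple(_whole_chrom(genome, c, a, b) for c, (a, b) in overrides.items())
    spec = KaryotypeSpec(
        background_a=bg_a,
        background_b=bg_b,
        regions=regions,
        purity=purity,
        noise_sd=noise_sd,
        baf_sd=baf_sd,
        probes_per_mb=4.0,
        het_fraction=0.6,
        seed=seed,
    )
    return spec, genome


def figure3_karyotype(seed: int, purity: float = 0.9) -> tuple[KaryotypeSpec, dict[str, int]]:
    """Genome-wide balance at intensity ~2 with one weakly imbalanced
    chromosome that also carries a small deletion and a small amplification:
    only a tetraploid (or larger) baseline explains the band pattern."""
    genome = toy_genome(special={"14": 150})
    regions = (
        RegionState("14", 1, 75_000_000, copies_a=3, copies_b=1),
        RegionState("14", 75_000_001, 110_000_000, copies_a=2, copies_b=1),
        RegionState("14", 110_000_001, 150_000_000, copies_a=3, copies_b=2),
    )
    spec = KaryotypeSpec(
        background_a=2,
        background_b=2,
        regions=regions,
        purity=purity,
        noise_sd=0.1,
        baf_sd=0.03,
        probes_per_mb=4.0,
        het_fraction=0.6,
        seed=seed,
    )
    return spec, genome


def staircase(rng: np.random.Generator, levels, sizes, noise_sd: float = 0.1):
    """Piecewise-constant intensities + Gaussian noise, with 1-based positions."""
    x = np.concatenate([lvl + rng.normal(0.0, noise_sd, size) for lvl, size in zip(levels, sizes)])
    pos = np.arange(1, x.size + 1) * 1000
    return x, pos
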