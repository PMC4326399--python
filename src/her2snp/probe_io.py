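"""Probe-level data model, baseline-2 normalization, and file I/O.

Probe files are headered TSV with columns ``chrom``, ``pos``, ``intensity``
and optionally ``sample`` and ``allele_ratio``. Positions are 1-based.
Intensities live on the copy-number scale where the genome-wide mean is
defined to be 2. Segments are exchanged in the standard SEG table layout.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical chromosome ordering (autosomes then X).
CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

PLATFORMS = ("SNP500K", "SNP6")

#: Default minimum number of probes per segment, by platform.
PLATFORM_MIN_POINTS = {"SNP500K": 100, "SNP6": 200}

_TABLE1_SHA256 = "9f951b93f80f443abcbdec5bbef5897997fc1f788c993c539cf340cb2151228d"
_TABLE2_SHA256 = "7e75fce8c343b3ad099fcc601feaa5c928ae1ab9b6f260783f25930dcfd504a0"


class ProbeParseError(ValueError):
    """Raised when a probe file line cannot be parsed."""


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate to process (e.g. all zeros)."""


def normalize_chrom(label: str) -> str:
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_RANK[normalize_chrom(chrom)]


@dataclass(frozen=True)
class ProbeRecord:
    """One probe: position plus copy-number intensity and optional allele ratio."""

    chrom: str
    pos: int
    intensity: float
    allele_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"probe position must be >= 1, got {self.pos}")
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"probe intensity must be finite and >= 0, got {self.intensity}")
        if self.allele_ratio is not None:
            if not (0.0 <= self.allele_ratio <= 1.0):
                raise ValueError(f"allele ratio must lie in [0, 1], got {self.allele_ratio}")


class ProbeSet:
    """An ordered, per-sample collection of probes.

    Probes are stored as parallel numpy arrays grouped by chromosome; the
    sequence interface (`len`, iteration, indexing) yields
    :class:`ProbeRecord` views. Construction sorts by (chrom, pos) — with a
    logged notice if the input was out of order — and validates invariants.
    """

    def __init__(
        self,
        probes: Iterable[ProbeRecord],
        sample_id: str = "sample",
        platform: str = "SNP500K",
    ) -> None:
        if platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {platform!r}")
        self.sample_id = str(sample_id)
        self.platform = platform
        probes = list(probes)
        if not probes:
            raise ValueError("ProbeSet requires at least one probe")
        order = sorted(range(len(probes)), key=lambda i: (chrom_sort_key(probes[i].chrom), probes[i].pos))
        if order != list(range(len(probes))):
            logger.info("probe input for sample %s was unsorted; sorted by (chrom, pos)", sample_id)
            probes = [probes[i] for i in order]
        self._chrom = np.array([p.chrom for p in probes], dtype=object)
        self._pos = np.array([p.pos for p in probes], dtype=np.int64)
        self._intensity = np.array([p.intensity for p in probes], dtype=np.float64)
        self._ratio = np.array(
            [np.nan if p.allele_ratio is None else p.allele_ratio for p in probes], dtype=np.float64
        )
        for chrom in self.chromosomes():
            pos = self.positions(chrom)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"duplicate probe positions on chromosome {chrom}")

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        pos: Sequence[int],
        intensity: Sequence[float],
        allele_ratio: Optional[Sequence[float]] = None,
        sample_id: str = "sample",
        platform: str = "SNP500K",
    ) -> "ProbeSet":
        n = len(pos)
        if allele_ratio is None:
            allele_ratio = [None] * n
        records = [
            ProbeRecord(
                chrom[i],
                int(pos[i]),
                float(intensity[i]),
                None
                if allele_ratio[i] is None or (isinstance(allele_ratio[i], float) and math.isnan(allele_ratio[i]))
                else float(allele_ratio[i]),
            )
            for i in range(n)
        ]
        return cls(records, sample_id=sample_id, platform=platform)

    # -- sequence interface -------------------------------------------------
    def __len__(self) -> int:
        return len(self._pos)

    def __iter__(self) -> Iterator[ProbeRecord]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> ProbeRecord:
        r = self._ratio[i]
        return ProbeRecord(
            self._chrom[i], int(self._pos[i]), float(self._intensity[i]), None if np.isnan(r) else float(r)
        )

    @property
    def probes(self) -> list[ProbeRecord]:
        return list(self)

    # -- array accessors ----------------------------------------------------
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self._chrom:
            seen.setdefault(c)
        return sorted(seen, key=chrom_sort_key)

    def _mask(self, chrom: Optional[str]) -> np.ndarray:
        if chrom is None:
            return np.ones(len(self), dtype=bool)
        return self._chrom == normalize_chrom(chrom)

    def positions(self, chrom: Optional[str] = None) -> np.ndarray:
        return self._pos[self._mask(chrom)]

    def intensities(self, chrom: Optional[str] = None) -> np.ndarray:
        return self._intensity[self._mask(chrom)]

    def allele_ratios(self, chrom: Optional[str] = None) -> np.ndarray:
        """Allele ratios (NaN where absent)."""
        return self._ratio[self._mask(chrom)]

    def min_points(self) -> int:
        return PLATFORM_MIN_POINTS[self.platform]

    def with_intensities(self, intensity: np.ndarray) -> "ProbeSet":
        out = object.__new__(ProbeSet)
        out.sample_id = self.sample_id
        out.platform = self.platform
        out._chrom = self._chrom
        out._pos = self._pos
        out._intensity = np.asarray(intensity, dtype=np.float64).copy()
        out._ratio = self._ratio
        return out

    def with_allele_ratios(self, allele_ratio: np.ndarray) -> "ProbeSet":
        out = object.__new__(ProbeSet)
        out.sample_id = self.sample_id
        out.platform = self.platform
        out._chrom = self._chrom
        out._pos = self._pos
        out._intensity = self._intensity
        out._ratio = np.asarray(allele_ratio, dtype=np.float64).copy()
        return out


def normalize_baseline2(probeset: ProbeSet) -> ProbeSet:
    """Rescale intensities by a single global factor so the genome-wide mean is 2.

    Idempotent and scale-invariant: only probe-to-probe ratios carry
    information afterwards, which is exactly why whole-genome polyploidy is
    invisible at the intensity level.
    """
    x = probeset.intensities()
    mean = float(np.mean(x))
    if mean <= 0:
        raise DegenerateInputError("cannot normalize: genome-wide mean intensity is zero")
    return probeset.with_intensities(x * (2.0 / mean))


# ---------------------------------------------------------------------------
# Probe TSV I/O
# ---------------------------------------------------------------------------

def read_probes(path: str | Path, format: str = "tsv", platform: str = "SNP500K") -> ProbeSet:
    """Read a probe TSV into a validated :class:`ProbeSet`.

    Rows whose intensity is ``NA``/empty are dropped (count logged). A
    malformed field raises :class:`ProbeParseError` naming the line.
    """
    if format != "tsv":
        raise ValueError(f"unsupported probe file format: {format!r}")
    path = Path(path)
    records: list[ProbeRecord] = []
    sample_id = path.stem
    n_dropped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ProbeParseError(f"{path}: empty file") from None
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        for required in ("chrom", "pos", "intensity"):
            if required not in cols:
                raise ProbeParseError(f"{path}: missing required column {required!r}")
        has_ratio = "allele_ratio" in cols
        has_sample = "sample" in cols
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                raw_intensity = row[cols["intensity"]].strip()
                if raw_intensity in ("", "NA", "NaN", "nan"):
                    n_dropped += 1
                    continue
                ratio: Optional[float] = None
                if has_ratio:
                    raw_ratio = row[cols["allele_ratio"]].strip()
                    if raw_ratio not in ("", "NA", "NaN", "nan"):
                        ratio = float(raw_ratio)
                if has_sample and row[cols["sample"]].strip():
                    sample_id = row[cols["sample"]].strip()
                records.append(
                    ProbeRecord(
                        chrom=row[cols["chrom"]],
                        pos=int(row[cols["pos"]]),
                        intensity=float(raw_intensity),
                        allele_ratio=ratio,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ProbeParseError(f"{path}:{lineno}: malformed probe line: {exc}") from exc
    if n_dropped:
        logger.info("%s: dropped %d probe(s) with missing intensity", path, n_dropped)
    return ProbeSet(records, sample_id=sample_id, platform=platform)


def write_probes(probeset: ProbeSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "chrom", "pos", "intensity", "allele_ratio"])
        for p in probeset:
            writer.writerow(
                [
                    probeset.sample_id,
                    p.chrom,
                    p.pos,
                    f"{p.intensity:.6g}",
                    "" if p.allele_ratio is None else f"{p.allele_ratio:.6g}",
                ]
            )


# ---------------------------------------------------------------------------
# SEG I/O
# ---------------------------------------------------------------------------

SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_segments_seg(segments, path: str | Path, sample_id: Optional[str] = None) -> None:
    """Write segments as a SEG-format table; rejects per-chromosome overlaps."""
    by_chrom: dict[str, list] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start_pos)
        for a, b in zip(segs, segs[1:]):
            if b.start_pos <= a.end_pos:
                raise ValueError(
                    f"overlapping segments on chromosome {chrom}: "
                    f"{a.start_pos}-{a.end_pos} and {b.start_pos}-{b.end_pos}"
                )
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SEG_HEADER)
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            for seg in by_chrom[chrom]:
                sid = sample_id if sample_id is not None else getattr(seg, "sample_id", None) or "sample"
                writer.writerow([sid, seg.chrom, seg.start_pos, seg.end_pos, seg.n_probes, f"{seg.mean_intensity:.4f}"])


def read_segments_seg(path: str | Path):
    """Read a SEG table back into :class:`~her2snp.segmentation.Segment` objects.

    Probe-index fields are not representable in SEG and come back as None.
    """
    from .segmentation import Segment  # local import to avoid a cycle

    path = Path(path)
    segments = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if [h.strip() for h in header] != SEG_HEADER:
            raise ProbeParseError(f"{path}: unexpected SEG header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                segments.append(
                    Segment(
                        chrom=normalize_chrom(row[1]),
                        start_pos=int(row[2]),
                        end_pos=int(row[3]),
                        start_idx=None,
                        end_idx=None,
                        n_probes=int(row[4]),
                        mean_intensity=float(row[5]),
                        boundary_p=None,
                        sample_id=row[0],
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ProbeParseError(f"{path}:{lineno}: malformed SEG line: {exc}") from exc
    return segments


# ---------------------------------------------------------------------------
# Packaged clinical-table fixtures
# ---------------------------------------------------------------------------

RELATION_LABELS = ("balance", "HER2plus", "centplus")
STATUS_LABELS = ("amp", "normal", "del")


@dataclass(frozen=True)
class ClinicalRecord:
    """One row of the packaged 65-sample clinical comparison table."""

    sample_id: int
    ihc_original: int
    fish_original: Optional[float]
    snp_segment_cn: float
    relation_label_published: str
    status_published: str
    ihc_revised: Optional[int] = None
    fish_revised: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.sample_id <= 65:
            raise ValueError(f"sample_id must be 1..65, got {self.sample_id}")
        if self.ihc_original not in (0, 1, 2, 3):
            raise ValueError(f"IHC score must be 0..3, got {self.ihc_original}")
        if self.relation_label_published not in RELATION_LABELS:
            raise ValueError(f"bad relation label {self.relation_label_published!r}")
        if self.status_published not in STATUS_LABELS:
            raise ValueError(f"bad status label {self.status_published!r}")
        if self.snp_segment_cn < 0:
            raise ValueError("segment copy number must be non-negative")

    @property
    def ihc(self) -> int:
        return self.ihc_original

    def effective(self, use_revised: bool = False) -> tuple[int, Optional[float]]:
        """(ihc, fish) pair, optionally substituting the re-analysis values."""
        if use_revised:
            ihc = self.ihc_revised if self.ihc_revised is not None else self.ihc_original
            fish = self.fish_revised if self.fish_revised is not None else self.fish_original
            return ihc, fish
        return self.ihc_original, self.fish_original


@dataclass(frozen=True)
class PloidyRecord:
    """One row of the packaged per-sample ploidy summary table."""

    sample_id: int
    polyploid: bool
    her2_estimate: str
    fish3d: Optional[str] = None


def _fixture_bytes(name: str, expected_sha256: str) -> bytes:
    data = resources.files("her2snp.fixtures").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha256:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    return data


def load_table1_fixture() -> list[ClinicalRecord]:
    """The packaged 65-sample IHC/FISH/SNP comparison table."""
    data = _fixture_bytes("table1.tsv", _TABLE1_SHA256)
    rows = list(csv.DictReader(data.decode().splitlines(), delimiter="\t"))
    records = []
    for row in rows:
        records.append(
            ClinicalRecord(
                sample_id=int(row["sample"]),
                ihc_original=int(row["ihc"]),
                ihc_revised=int(row["ihc_revised"]) if row["ihc_revised"] else None,
                fish_original=float(row["fish"]) if row["fish"] else None,
                fish_revised=float(row["fish_revised"]) if row["fish_revised"] else None,
                snp_segment_cn=float(row["seg_cn"]),
                relation_label_published=row["relation"],
                status_published=row["status"],
            )
        )
    if len(records) != 65:
        raise RuntimeError(f"clinical table fixture must hold 65 records, got {len(records)}")
    return records


def load_table2_fixture() -> list[PloidyRecord]:
    """The packaged per-sample polyploidy summary (flag, estimate, 3D-FISH count)."""
    data = _fixture_bytes("table2.tsv", _TABLE2_SHA256)
    rows = list(csv.DictReader(data.decode().splitlines(), delimiter="\t"))
    records = []
    for row in rows:
        records.append(
            PloidyRecord(
                sample_id=int(row["sample"]),
                polyploid=row["polyploid"] == "Yes",
                her2_estimate=row["her2_estimate"],
                fish3d=row["fish3d"] or None,
            )
        )
    if len(records) != 65:
        raise RuntimeError(f"ploidy table fixture must hold 65 records, got {len(records)}")
    return records


def load_genome_table() -> dict[str, int]:
    """Hg19 chromosome lengths (1..22, X) as a {chrom: length} map."""
    data = resources.files("her2snp.fixtures").joinpath("hg19_chrom_lengths.tsv").read_text()
    out: dict[str, int] = {}
    for row in csv.DictReader(data.splitlines(), delimiter="\t"):
        out[normalize_chrom(row["chrom"])] = int(row["length"])
    return out
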