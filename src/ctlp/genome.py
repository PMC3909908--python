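"""Genome coordinate model: assemblies, arms, telomere geometry.

All internal coordinates are 0-based, half-open; SEG I/O converts from the
1-based inclusive convention of segmentation tables. Chromosome names are
stored without the ``chr`` prefix (``"1"`` ... ``"22"``, ``"X"``, ``"Y"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import pandas as pd

MB = 1_000_000

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

# UCSC build hg18: chromosome lengths and centromere gap intervals (bp).
_HG18_LENGTHS: dict[str, int] = {
    "1": 247_249_719, "2": 242_951_149, "3": 199_501_827, "4": 191_273_063,
    "5": 180_857_866, "6": 170_899_992, "7": 158_821_424, "8": 146_274_826,
    "9": 140_273_252, "10": 135_374_737, "11": 134_452_384, "12": 132_349_534,
    "13": 114_142_980, "14": 106_368_585, "15": 100_338_915, "16": 88_827_254,
    "17": 78_774_742, "18": 76_117_153, "19": 63_811_651, "20": 62_435_964,
    "21": 46_944_323, "22": 49_691_432, "X": 154_913_754, "Y": 57_772_954,
}

_HG18_CENTROMERES: dict[str, tuple[int, int]] = {
    "1": (121_236_957, 123_476_957), "2": (91_689_898, 94_689_898),
    "3": (90_587_544, 93_487_544), "4": (49_354_874, 52_354_874),
    "5": (46_441_398, 49_441_398), "6": (58_938_125, 61_938_125),
    "7": (58_058_273, 61_058_273), "8": (43_958_052, 46_958_052),
    "9": (47_107_499, 50_107_499), "10": (39_244_941, 41_624_941),
    "11": (51_450_781, 54_450_781), "12": (34_747_961, 36_142_961),
    "13": (16_000_000, 17_868_000), "14": (15_070_000, 18_070_000),
    "15": (15_260_000, 18_260_000), "16": (35_143_302, 36_943_302),
    "17": (22_187_133, 22_287_133), "18": (15_400_898, 16_764_896),
    "19": (26_923_622, 29_923_622), "20": (26_267_569, 28_033_230),
    "21": (10_260_000, 13_260_000), "22": (11_330_000, 14_330_000),
    "X": (58_598_737, 61_598_737), "Y": (11_253_954, 12_308_578),
}


def normalize_chromosome(name: object) -> str:
    """Map SEG-dialect chromosome labels onto canonical names.

    Accepts ``chr1``/``1``, ``23``/``X``, ``24``/``Y`` and case variants.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        s = "X"
    elif s == "24":
        s = "Y"
    elif s.lower() in ("x", "y"):
        s = s.upper()
    return s


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open interval ``[start, end)`` on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid region {self.chromosome}:[{self.start},{self.end}): "
                "require 0 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        """True iff the two regions share at least one base."""
        return (
            self.chromosome == other.chromosome
            and max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome lengths, centromere intervals and telomere geometry.

    ``included_chromosomes`` is the subset over which genome-wide quantities
    (the total length *G* and the status-change count) are computed; ``None``
    means every chromosome in the assembly.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]]
    telomere_window_bp: int = 5 * MB
    included_chromosomes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names in assembly")
        if not lengths:
            raise ValueError("assembly has no chromosomes")
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            cen = self.centromeres.get(chrom)
            if cen is None:
                raise ValueError(f"chromosome {chrom} has no centromere interval")
            if not (0 <= cen[0] <= cen[1] <= length):
                raise ValueError(f"centromere of {chrom} outside chromosome")
        if self.telomere_window_bp < 0:
            raise ValueError("telomere_window_bp must be >= 0")
        shortest = min(lengths.values())
        if self.telomere_window_bp > shortest / 2:
            raise ValueError(
                "telomere_window_bp exceeds half of the shortest chromosome"
            )
        if self.included_chromosomes is not None:
            unknown = set(self.included_chromosomes) - set(lengths)
            if unknown:
                raise KeyError(f"included chromosomes not in assembly: {sorted(unknown)}")

    @cached_property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def included(self) -> tuple[str, ...]:
        if self.included_chromosomes is None:
            return tuple(name for name, _ in self.chromosomes)
        return self.included_chromosomes

    @cached_property
    def G(self) -> int:
        """Total genome length over the included chromosomes."""
        return sum(self.lengths[c] for c in self.included)

    def length_of(self, chromosome: str) -> int:
        try:
            return self.lengths[chromosome]
        except KeyError:
            raise KeyError(f"unknown chromosome {chromosome!r} in assembly {self.name}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def hg18(cls, include_sex: bool = False) -> "GenomeAssembly":
        """The UCSC hg18 assembly; autosomes 1-22 included by default."""
        included = AUTOSOMES + (("X", "Y") if include_sex else ())
        return cls(
            name="hg18",
            chromosomes=tuple(_HG18_LENGTHS.items()),
            centromeres=dict(_HG18_CENTROMERES),
            included_chromosomes=included,
        )

    @classmethod
    def from_file(cls, path, name: str | None = None,
                  telomere_window_bp: int = 5 * MB,
                  included_chromosomes: Iterable[str] | None = None) -> "GenomeAssembly":
        """Load an assembly from a tab-separated table.

        Required header columns: ``chromosome``, ``length``, ``cen_start``,
        ``cen_end``.
        """
        df = pd.read_csv(path, sep="\t")
        required = ["chromosome", "length", "cen_start", "cen_end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"assembly file missing column(s): {missing}")
        chroms = tuple(
            (normalize_chromosome(r.chromosome), int(r.length))
            for r in df.itertuples()
        )
        cens = {
            normalize_chromosome(r.chromosome): (int(r.cen_start), int(r.cen_end))
            for r in df.itertuples()
        }
        return cls(
            name=name or str(path),
            chromosomes=chroms,
            centromeres=cens,
            telomere_window_bp=telomere_window_bp,
            included_chromosomes=tuple(included_chromosomes)
            if included_chromosomes is not None else None,
        )

    def to_file(self, path) -> None:
        rows = [
            {"chromosome": c, "length": l,
             "cen_start": self.centromeres[c][0], "cen_end": self.centromeres[c][1]}
            for c, l in self.chromosomes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def arm_of(position: int, chromosome: str, assembly: GenomeAssembly
           ) -> tuple[str, tuple[int, int]]:
    """Arm label and span for a position: ``p``, ``q`` or ``centromeric``.

    The p arm is ``[0, cen_start)``, the q arm ``[cen_end, length)``; the two
    spans plus the centromere interval partition the chromosome.
    """
    length = assembly.length_of(chromosome)
    if not (0 <= position < length):
        raise ValueError(
            f"position {position} outside chromosome {chromosome} (length {length})"
        )
    cen_start, cen_end = assembly.centromeres[chromosome]
    if position < cen_start:
        return "p", (0, cen_start)
    if position >= cen_end:
        return "q", (cen_end, length)
    return "centromeric", (cen_start, cen_end)


def telomere_windows(chromosome: str, assembly: GenomeAssembly
                     ) -> tuple[GenomicRegion, GenomicRegion]:
    """The two terminal telomere windows ``[0, w)`` and ``[L-w, L)``.

    For chromosomes shorter than twice the window the two windows are
    truncated to a non-overlapping partition of the chromosome.
    """
    length = assembly.length_of(chromosome)
    w = assembly.telomere_window_bp
    w_q = min(w, length // 2)
    w_p = min(w, length - w_q)
    return (
        GenomicRegion(chromosome, 0, w_p),
        GenomicRegion(chromosome, length - w_q, length),
    )


def validate_region(region: GenomicRegion, assembly: GenomeAssembly) -> GenomicRegion:
    """Return the region unchanged iff it is a valid non-empty interval."""
    length = assembly.length_of(region.chromosome)
    if region.start >= region.end:
        raise ValueError(
            f"empty or reversed region {region.chromosome}:"
            f"[{region.start},{region.end}): require start < end"
        )
    if region.start < 0 or region.end > length:
        raise ValueError(
            f"region {region.chromosome}:[{region.start},{region.end}) outside "
            f"chromosome bounds [0,{length})"
        )
    return region
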