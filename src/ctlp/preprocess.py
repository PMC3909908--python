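"""Copy-number status calling and profile preprocessing.

Segmented log2-ratio profiles are reduced to ordered runs of copy-number
status (gain / neutral / loss) with the breakpoints between them. Three
filtering rules are applied before status runs are formed:

(i)   array-specific log2 thresholds call each segment gain, neutral or loss;
(ii)  a status change between adjacent segments is suppressed when their
      log2 means differ by less than a merge distance (default: the sum of
      the absolute calling thresholds), damping segmentation "striation"
      artifacts;
(iii) segments shorter than a minimum size (default 10 kb, roughly the
      practical resolution of the densest SNP platforms) are removed, the
      gap being annexed by the left neighbour.

The breakpoints of the resulting profile are the events counted by the scan
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeAssembly, GenomicRegion

GAIN = "gain"
NEUTRAL = "neutral"
LOSS = "loss"
STATUSES = (GAIN, NEUTRAL, LOSS)


@dataclass(frozen=True)
class Segment:
    """One segment of a piecewise-constant copy-number profile."""

    chromosome: str
    start: int
    end: int
    mean_log2: float
    n_markers: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chromosome}:[{self.start},{self.end}) is empty"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CallingThresholds:
    """Array-specific log2 thresholds and filtering parameters.

    ``merge_distance`` defaults to ``gain_log2 + |loss_log2|``.
    """

    gain_log2: float = 0.15
    loss_log2: float = -0.15
    min_segment_bp: int = 10_000
    merge_distance: float | None = None

    def __post_init__(self) -> None:
        if not (self.gain_log2 > 0 > self.loss_log2):
            raise ValueError("require gain_log2 > 0 > loss_log2")
        if self.min_segment_bp < 0:
            raise ValueError("min_segment_bp must be >= 0")
        if self.merge_distance is None:
            object.__setattr__(
                self, "merge_distance", self.gain_log2 + abs(self.loss_log2)
            )
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")


@dataclass(frozen=True)
class Run:
    """Maximal stretch of constant copy-number status."""

    region: GenomicRegion
    status: str
    mean_log2: float


@dataclass(frozen=True)
class Breakpoint:
    position: int
    from_status: str
    to_status: str


@dataclass
class StatusProfile:
    """Per-sample status runs and breakpoints, per chromosome.

    ``n_G`` is the total number of status changes over the chromosomes
    included in the assembly's genome-wide set.
    """

    sample_id: str
    runs: dict[str, list[Run]]
    breakpoints: dict[str, list[Breakpoint]]
    included: tuple[str, ...]

    @property
    def n_G(self) -> int:
        return sum(len(self.breakpoints.get(c, [])) for c in self.included)

    def breakpoint_positions(self, chromosome: str) -> np.ndarray:
        return np.array(
            [b.position for b in self.breakpoints.get(chromosome, [])], dtype=np.int64
        )


def call_status(mean_log2: float, thresholds: CallingThresholds) -> str:
    """Call a segment's copy-number status from its mean log2 ratio.

    Boundaries are inclusive: gain iff mean >= gain_log2, loss iff
    mean <= loss_log2.
    """
    if not math.isfinite(mean_log2):
        raise ValueError(f"non-finite mean_log2: {mean_log2}")
    if mean_log2 >= thresholds.gain_log2:
        return GAIN
    if mean_log2 <= thresholds.loss_log2:
        return LOSS
    return NEUTRAL


def _check_sorted_non_overlapping(chrom: str, segs: Sequence[Segment]) -> None:
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping segments on {chrom}: [{a.start},{a.end}) and "
                f"[{b.start},{b.end})"
            )


def preprocess_profile(
    segments: Iterable[Segment],
    thresholds: CallingThresholds,
    assembly: GenomeAssembly,
    sample_id: str = "sample",
) -> StatusProfile:
    """Reduce a segmented profile to status runs and breakpoints.

    Pipeline order: (1) remove segments shorter than ``min_segment_bp``;
    (2) close the resulting gaps by extending the left neighbour (a leading
    gap goes to the right neighbour); (3) call each segment's status;
    (4) suppress transitions whose adjacent-segment log2 distance is below
    ``merge_distance``, propagating left to right; (5) coalesce equal-status
    neighbours into runs; (6) emit breakpoints at run boundaries.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        assembly.length_of(seg.chromosome)  # raises on unknown chromosome
        if not math.isfinite(seg.mean_log2):
            raise ValueError(
                f"non-finite mean_log2 in segment {seg.chromosome}:"
                f"[{seg.start},{seg.end})"
            )
        by_chrom.setdefault(seg.chromosome, []).append(seg)

    runs: dict[str, list[Run]] = {}
    breakpoints: dict[str, list[Breakpoint]] = {}
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        _check_sorted_non_overlapping(chrom, segs)
        span = (segs[0].start, segs[-1].end)

        # (1) size filter
        kept = [s for s in segs if s.length >= thresholds.min_segment_bp]
        if not kept:
            runs[chrom] = []
            breakpoints[chrom] = []
            continue

        # (2) gap closure: internal gaps to the left neighbour, terminal gaps
        # restore the original covered span.
        starts = [span[0]] + [s.start for s in kept[1:]]
        ends = [n.start for n in kept[1:]] + [span[1]]
        means = [s.mean_log2 for s in kept]

        # (3) status calling
        called = [call_status(m, thresholds) for m in means]

        # (4) transition suppression, left to right
        status = list(called)
        for i in range(1, len(status)):
            if abs(means[i] - means[i - 1]) < thresholds.merge_distance:
                status[i] = status[i - 1]

        # (5) coalesce into runs; the run mean is the length-weighted mean of
        # member segments whose *called* status matches the run status, which
        # keeps re-calling the emitted runs stable.
        chrom_runs: list[Run] = []
        i = 0
        while i < len(status):
            j = i
            while j + 1 < len(status) and status[j + 1] == status[i]:
                j += 1
            members = [
                k for k in range(i, j + 1) if called[k] == status[i]
            ] or list(range(i, j + 1))
            wsum = sum(ends[k] - starts[k] for k in members)
            mean = sum(means[k] * (ends[k] - starts[k]) for k in members) / wsum
            chrom_runs.append(
                Run(GenomicRegion(chrom, starts[i], ends[j]), status[i], mean)
            )
            i = j + 1

        # (6) breakpoints at run boundaries
        chrom_bps = [
            Breakpoint(b.region.start, a.status, b.status)
            for a, b in zip(chrom_runs, chrom_runs[1:])
        ]
        runs[chrom] = chrom_runs
        breakpoints[chrom] = chrom_bps

    return StatusProfile(
        sample_id=sample_id,
        runs=runs,
        breakpoints=breakpoints,
        included=assembly.included,
    )


def count_changes(profile: StatusProfile, interval: GenomicRegion) -> int:
    """Number of status-change breakpoints with position in ``[start, end)``."""
    pos = profile.breakpoint_positions(interval.chromosome)
    lo = np.searchsorted(pos, interval.start, side="left")
    hi = np.searchsorted(pos, interval.end, side="left")
    return int(hi - lo)


def runs_as_segments(profile: StatusProfile) -> list[Segment]:
    """Re-express a profile's runs as segments (for round-trip use)."""
    out: list[Segment] = []
    for chrom_runs in profile.runs.values():
        for run in chrom_runs:
            out.append(
                Segment(
                    run.region.chromosome, run.region.start, run.region.end,
                    run.mean_log2,
                )
            )
    return out
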