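"""Scan-statistic detection of chromothripsis-like patterns (CTLP).

A fixed-size window W slides along each chromosome in 5 Mb steps, over a
series of window sizes, defining a collection of candidate zones. With n_W
the observed status changes inside a window, n_G the genome-wide total and
mu_W = (W/G) * n_G the expectation under a homogeneous Poisson model, the
log10 likelihood-ratio score of a window is

    log10 lambda = n_W*log10(n_W/mu_W) + (n_G-n_W)*log10((n_G-n_W)/(n_G-mu_W))

when the window is in excess (n_W/mu_W > (n_G-n_W)/(n_G-mu_W)), and 0
otherwise. Per chromosome, the window maximizing the score is the CTLP
candidate; a chromosome is called CTLP when the best window has at least
``min_switches`` status changes (default 20) and a score of at least
``min_log10_lr`` (default 8), the operating point calibrated on published
chromothripsis cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    MB,
    GenomeAssembly,
    GenomicRegion,
    arm_of,
    telomere_windows,
)
from .preprocess import NEUTRAL, StatusProfile

LOCALIZED = "localized"
ARM_LEVEL = "arm-level"
CHROMOSOME_LEVEL = "chromosome-level"


@dataclass(frozen=True)
class ScanWindow:
    """One evaluated zone: location, size, counts and score."""

    region: GenomicRegion
    W: int
    n_W: int
    mu_W: float
    log10_lambda: float


@dataclass(frozen=True)
class ScanConfig:
    """Window series, step length and calling thresholds."""

    window_sizes: tuple[int, ...] | None = None
    step: int = 5 * MB
    min_switches: int = 20
    min_log10_lr: float = 8.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.min_switches < 0 or self.min_log10_lr < 0:
            raise ValueError("calling thresholds must be >= 0")
        if self.window_sizes is not None:
            object.__setattr__(
                self, "window_sizes", tuple(sorted(set(int(w) for w in self.window_sizes)))
            )
            if any(w <= 0 for w in self.window_sizes):
                raise ValueError("window sizes must be > 0")

    def sizes_for(self, assembly: GenomeAssembly) -> tuple[int, ...]:
        if self.window_sizes is not None:
            return self.window_sizes
        return tuple(default_window_series(assembly))


@dataclass(frozen=True)
class CTLPCall:
    """Per-chromosome CTLP verdict."""

    sample_id: str
    chromosome: str
    best_window: ScanWindow
    refined_region: GenomicRegion
    switch_count: int
    extent: str
    telomere_p: bool
    telomere_q: bool
    ctlp_fraction_of_genome: float = 0.0

    @property
    def log10_lambda(self) -> float:
        return self.best_window.log10_lambda


def default_window_series(assembly: GenomeAssembly, min_size_mb: int = 30) -> list[int]:
    """Window-size series derived from chromosome sizes.

    Deduplicated, sorted, Mb-rounded lengths of the assembly's chromosomes,
    clipped to at least ``min_size_mb`` (30 Mb by default; for hg18 the
    series tops out at 247 Mb, the rounded length of chromosome 1).
    """
    sizes = sorted(
        {round(length / MB) * MB for _, length in assembly.chromosomes}
    )
    sizes = [s for s in sizes if s >= min_size_mb * MB]
    if not sizes:
        warnings.warn(
            "all chromosomes shorter than the minimum window size; "
            "empty window series",
            stacklevel=2,
        )
    return sizes


def generate_windows(
    assembly: GenomeAssembly,
    sizes: tuple[int, ...] | list[int],
    step: int = 5 * MB,
) -> dict[str, list[GenomicRegion]]:
    """All candidate zones, grouped by chromosome.

    For each chromosome of length L and each window size W <= L, starts run
    0, step, 2*step, ... with start + W <= L; windows never span chromosomes.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    zones: dict[str, list[GenomicRegion]] = {}
    for chrom in assembly.included:
        length = assembly.length_of(chrom)
        regions: list[GenomicRegion] = []
        for w in sizes:
            if w > length:
                continue
            for start in range(0, length - w + 1, step):
                regions.append(GenomicRegion(chrom, start, start + w))
        zones[chrom] = regions
    return zones


def log10_likelihood_ratio(n_W: int, mu_W: float, n_G: int) -> float:
    """Scan-statistic log10 likelihood ratio for one window.

    Returns 0 when the excess condition ``n_W/mu_W > (n_G-n_W)/(n_G-mu_W)``
    fails; uses the convention ``0*log(0) = 0`` when ``n_W = n_G``.
    """
    if not (0 < mu_W < n_G):
        raise ValueError(f"require 0 < mu_W < n_G, got mu_W={mu_W}, n_G={n_G}")
    if not (0 <= n_W <= n_G):
        raise ValueError(f"require 0 <= n_W <= n_G, got n_W={n_W}")
    rem = n_G - n_W
    if n_W * (n_G - mu_W) <= rem * mu_W:  # excess condition fails
        return 0.0
    term1 = n_W * np.log10(n_W / mu_W) if n_W > 0 else 0.0
    term2 = rem * np.log10(rem / (n_G - mu_W)) if rem > 0 else 0.0
    return float(term1 + term2)


def _log10_lr_vector(n_W: np.ndarray, mu_W: float, n_G: int) -> np.ndarray:
    """Vectorized score over windows of one size (0 where not in excess)."""
    out = np.zeros(len(n_W), dtype=float)
    if not (0 < mu_W < n_G):
        return out
    nw = n_W.astype(float)
    rem = n_G - nw
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(nw > 0, nw * np.log10(np.maximum(nw, 1e-300) / mu_W), 0.0)
        t2 = np.where(rem > 0, rem * np.log10(np.maximum(rem, 1e-300) / (n_G - mu_W)), 0.0)
    excess = nw * (n_G - mu_W) > rem * mu_W
    out[excess] = (t1 + t2)[excess]
    return out


def scan_genome(
    profile: StatusProfile,
    assembly: GenomeAssembly,
    config: ScanConfig | None = None,
) -> dict[str, ScanWindow]:
    """Best-scoring window per included chromosome.

    Ties are broken toward the smaller window size, then the leftmost start.
    Chromosomes shorter than every window size are absent from the result.
    """
    config = config or ScanConfig()
    sizes = config.sizes_for(assembly)
    n_G = profile.n_G
    G = assembly.G
    best: dict[str, ScanWindow] = {}
    for chrom in assembly.included:
        length = assembly.length_of(chrom)
        positions = profile.breakpoint_positions(chrom)
        best_win: ScanWindow | None = None
        for w in sizes:
            if w > length:
                continue
            starts = np.arange(0, length - w + 1, config.step, dtype=np.int64)
            lo = np.searchsorted(positions, starts, side="left")
            hi = np.searchsorted(positions, starts + w, side="left")
            counts = hi - lo
            mu = w / G * n_G
            scores = _log10_lr_vector(counts, mu, n_G)
            i = int(np.argmax(scores))
            if best_win is None or scores[i] > best_win.log10_lambda:
                start = int(starts[i])
                best_win = ScanWindow(
                    region=GenomicRegion(chrom, start, start + w),
                    W=w,
                    n_W=int(counts[i]),
                    mu_W=mu,
                    log10_lambda=float(scores[i]),
                )
        if best_win is not None:
            best[chrom] = best_win
    return best


def refine_region(window: ScanWindow, profile: StatusProfile) -> GenomicRegion | None:
    """Trim the best window to its outermost internal breakpoints."""
    pos = profile.breakpoint_positions(window.region.chromosome)
    inside = pos[(pos >= window.region.start) & (pos < window.region.end)]
    if len(inside) < 2:
        return None
    return GenomicRegion(window.region.chromosome, int(inside[0]), int(inside[-1]))


def classify_extent(region: GenomicRegion, assembly: GenomeAssembly) -> str:
    """Extent class of a CTLP region.

    Chromosome-level iff the region spans >= 80% of the chromosome; else
    arm-level iff it lies within one arm and covers >= 90% of that arm;
    otherwise localized.
    """
    length = assembly.length_of(region.chromosome)
    if region.length >= 0.8 * length:
        return CHROMOSOME_LEVEL
    start_label, span = arm_of(region.start, region.chromosome, assembly)
    end_label, _ = arm_of(region.end - 1, region.chromosome, assembly)
    if start_label == end_label and start_label in ("p", "q"):
        arm_len = span[1] - span[0]
        if (
            region.start >= span[0]
            and region.end <= span[1]
            and arm_len > 0
            and region.length >= 0.9 * arm_len
        ):
            return ARM_LEVEL
    return LOCALIZED


def telomere_involvement(
    region: GenomicRegion, assembly: GenomeAssembly
) -> tuple[bool, bool]:
    """Whether a region overlaps the p-terminal / q-terminal 5 Mb windows."""
    p_win, q_win = telomere_windows(region.chromosome, assembly)
    return region.overlaps(p_win), region.overlaps(q_win)


def call_ctlp(
    best_windows: dict[str, ScanWindow],
    profile: StatusProfile,
    config: ScanConfig | None = None,
    assembly: GenomeAssembly | None = None,
) -> list[CTLPCall]:
    """Apply the combined thresholds and build per-chromosome CTLP calls.

    A chromosome is flagged iff its best window has ``n_W >= min_switches``
    and ``log10_lambda >= min_log10_lr``; at most one call per chromosome.
    """
    config = config or ScanConfig()
    calls: list[CTLPCall] = []
    pending: list[tuple[str, ScanWindow, GenomicRegion]] = []
    for chrom, win in best_windows.items():
        if win.n_W >= config.min_switches and win.log10_lambda >= config.min_log10_lr:
            region = refine_region(win, profile)
            if region is None:
                continue
            pending.append((chrom, win, region))
    total_refined = sum(r.length for _, _, r in pending)
    for chrom, win, region in pending:
        if assembly is not None:
            extent = classify_extent(region, assembly)
            tel_p, tel_q = telomere_involvement(region, assembly)
            frac = total_refined / assembly.G
        else:
            extent, tel_p, tel_q, frac = LOCALIZED, False, False, 0.0
        calls.append(
            CTLPCall(
                sample_id=profile.sample_id,
                chromosome=chrom,
                best_window=win,
                refined_region=region,
                switch_count=win.n_W,
                extent=extent,
                telomere_p=tel_p,
                telomere_q=tel_q,
                ctlp_fraction_of_genome=frac,
            )
        )
    return calls


def genome_fractions(
    calls: list[CTLPCall],
    profile: StatusProfile,
    assembly: GenomeAssembly,
) -> tuple[float, float]:
    """Per-sample genome fractions ``(ctlp_fraction, cna_fraction)``.

    ``ctlp_fraction`` is the total refined CTLP region length over G;
    ``cna_fraction`` is the total gain+loss run length over G. Both are
    computed over the assembly's included chromosomes.
    """
    ctlp_len = sum(
        c.refined_region.length
        for c in calls
        if c.refined_region.chromosome in assembly.included
    )
    cna_len = sum(
        run.region.length
        for chrom in assembly.included
        for run in profile.runs.get(chrom, [])
        if run.status != NEUTRAL
    )
    return ctlp_len / assembly.G, cna_len / assembly.G


def detect(
    segments,
    assembly: GenomeAssembly,
    thresholds=None,
    config: ScanConfig | None = None,
    sample_id: str = "sample",
):
    """Convenience pipeline: preprocess -> scan -> call.

    Returns ``(profile, best_windows, calls)``.
    """
    from .preprocess import CallingThresholds, preprocess_profile

    thresholds = thresholds or CallingThresholds()
    profile = preprocess_profile(segments, thresholds, assembly, sample_id)
    best = scan_genome(profile, assembly, config)
    calls = call_ctlp(best, profile, config, assembly)
    return profile, best, calls
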