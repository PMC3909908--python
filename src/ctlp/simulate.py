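"""Monte-Carlo procedures: telomere-enrichment test and platform resolution.

Two simulation studies accompany the detector. The telomere test asks
whether CTLP regions overlap chromosome-terminal 5 Mb windows more often
than chance: each chromosome is treated as a circle, the terminal junction
is rotated to a uniform random position while CTLP regions stay fixed, and
the number of CTLP chromosomes touching a (rotated) terminal window forms
the permutation null. The platform study subsamples probe-level data to a
target probe count, re-segments, and re-runs the detector, estimating
detection sensitivity as a function of platform resolution.

Segmentation for the platform pathway is a greedy binary segmentation
minimizing residual sum of squares, with a BIC-style per-changepoint
penalty (penalized least-squares change-point fitting).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, telomere_windows
from .preprocess import CallingThresholds, Segment, preprocess_profile
from .scan import CTLPCall, ScanConfig, call_ctlp, scan_genome


@dataclass
class TelomereTestResult:
    observed_overlap: int
    null_distribution: np.ndarray
    p_value: float
    n_sims: int
    seed: int | None

    def __post_init__(self) -> None:
        assert 0 < self.p_value <= 1


@dataclass
class SensitivityCurve:
    probe_counts: list[int]
    detected_fraction: list[float]
    reps: int
    seed: int | None


def _terminal_half_widths(assembly: GenomeAssembly, chrom: str) -> tuple[int, int]:
    p_win, q_win = telomere_windows(chrom, assembly)
    return p_win.length, q_win.length


def _circular_overlap(r: np.ndarray, a: int, b: int, w_p: int, w_q: int, L: int
                      ) -> np.ndarray:
    """Overlap of arc ``[r - w_q, r + w_p)`` with ``[a, b)`` on a circle of L."""
    ov = np.zeros(len(r), dtype=bool)
    for shift in (-L, 0, L):
        lo = np.maximum(r - w_q, a + shift)
        hi = np.minimum(r + w_p, b + shift)
        ov |= lo < hi
    return ov


def shuffle_telomere_test(
    calls: list[CTLPCall],
    assembly: GenomeAssembly,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> TelomereTestResult:
    """Permutation test for telomere enrichment of CTLP regions.

    Per iteration and per CTLP chromosome, the terminal junction of the
    circularized chromosome is rotated by a uniform offset; the statistic is
    the number of CTLP chromosomes whose (fixed) region overlaps a rotated
    terminal window. The p-value uses the add-one permutation estimator
    ``(1 + #{null >= observed}) / (1 + n_sims)`` and therefore never
    reaches 0 (floor ``1/(n_sims+1)``).
    """
    if not calls:
        raise ValueError("nothing to test: no CTLP calls")
    rng = np.random.default_rng(seed)

    per_chrom: dict[tuple[str, str], list[CTLPCall]] = {}
    for call in calls:
        per_chrom.setdefault((call.sample_id, call.chromosome), []).append(call)

    observed = 0
    null_counts = np.zeros(n_sims, dtype=np.int64)
    for (_, chrom), chrom_calls in per_chrom.items():
        L = assembly.length_of(chrom)
        w_p, w_q = _terminal_half_widths(assembly, chrom)
        regions = [c.refined_region for c in chrom_calls]
        # observed: junction at position 0 (the actual terminals)
        r0 = np.zeros(1, dtype=np.int64)
        obs_hit = any(
            bool(_circular_overlap(r0, reg.start, reg.end, w_p, w_q, L)[0])
            for reg in regions
        )
        observed += int(obs_hit)
        r = rng.integers(0, L, size=n_sims)
        hit = np.zeros(n_sims, dtype=bool)
        for reg in regions:
            hit |= _circular_overlap(r, reg.start, reg.end, w_p, w_q, L)
        null_counts += hit

    p = (1 + int(np.sum(null_counts >= observed))) / (1 + n_sims)
    return TelomereTestResult(
        observed_overlap=observed,
        null_distribution=null_counts,
        p_value=p,
        n_sims=n_sims,
        seed=seed,
    )


def subsample_probes(probes: pd.DataFrame, k: int, seed=None) -> pd.DataFrame:
    """Uniform sample of ``k`` probes without replacement, position-sorted."""
    n = len(probes)
    if not (0 < k <= n):
        raise ValueError(f"k must be in (0, {n}], got {k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    out = probes.iloc[np.sort(idx)]
    return out.sort_values(["chromosome", "position"], kind="mergesort").reset_index(
        drop=True
    )


# -- penalized least-squares change-point segmentation ----------------------

def _best_split(y: np.ndarray, csum: np.ndarray, csum2: np.ndarray,
                lo: int, hi: int) -> tuple[float, int]:
    """Best single split of ``y[lo:hi]`` by residual-SS reduction."""
    n = hi - lo
    if n < 2:
        return 0.0, -1
    total = csum[hi] - csum[lo]
    k = np.arange(lo + 1, hi)
    ls = csum[k] - csum[lo]
    rs = total - ls
    gain = ls**2 / (k - lo) + rs**2 / (hi - k) - total**2 / n
    i = int(np.argmax(gain))
    return float(gain[i]), int(k[i])


def segment_series(y: np.ndarray, penalty: float) -> list[int]:
    """Greedy binary segmentation of a 1-D series.

    Repeatedly accepts the split with the largest residual-sum-of-squares
    reduction, as long as the reduction exceeds ``penalty``; returns sorted
    internal changepoint indices (a changepoint at ``i`` splits between
    ``y[i-1]`` and ``y[i]``).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        return []
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y**2)])
    heap: list[tuple[float, int, int, int]] = []

    def push(lo: int, hi: int) -> None:
        gain, split = _best_split(y, csum, csum2, lo, hi)
        if split >= 0 and gain > penalty:
            heapq.heappush(heap, (-gain, lo, hi, split))

    push(0, n)
    cps: list[int] = []
    while heap:
        _, lo, hi, split = heapq.heappop(heap)
        cps.append(split)
        push(lo, split)
        push(split, hi)
    return sorted(cps)


def default_penalty(y: np.ndarray) -> float:
    """BIC-style penalty ``2 * sigma^2 * ln(n)`` with a robust noise estimate.

    The noise SD is estimated from the median absolute first difference
    (insensitive to the piecewise-constant signal itself).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        return 1e-10
    sigma = np.median(np.abs(np.diff(y))) / (0.6745 * np.sqrt(2.0))
    return max(2.0 * sigma**2 * np.log(n), 1e-10)


def resegment(probes: pd.DataFrame, penalty: float | None = None) -> list[Segment]:
    """Piecewise-constant fit of a probe table into segments.

    Per chromosome, changepoints are found by penalized least squares;
    segment boundaries are placed at probe midpoints, segment means are the
    means of member probes, and ``n_markers`` records the member count.
    Chromosomes with fewer than two probes yield a single segment.
    """
    segments: list[Segment] = []
    for chrom, grp in probes.groupby("chromosome", sort=False, observed=True):
        grp = grp.sort_values("position", kind="mergesort")
        pos = grp["position"].to_numpy(dtype=np.int64)
        y = grp["log2"].to_numpy(dtype=float)
        n = len(y)
        if n == 0:
            continue
        if n == 1:
            segments.append(Segment(str(chrom), int(pos[0]), int(pos[0]) + 1, float(y[0]), 1))
            continue
        pen = default_penalty(y) if penalty is None else penalty
        cps = segment_series(y, pen)
        bounds = (
            [int(pos[0])]
            + [int((pos[i - 1] + pos[i]) // 2) for i in cps]
            + [int(pos[-1]) + 1]
        )
        edges = [0] + cps + [n]
        for i in range(len(edges) - 1):
            lo, hi = edges[i], edges[i + 1]
            segments.append(
                Segment(
                    str(chrom), bounds[i], bounds[i + 1],
                    float(np.mean(y[lo:hi])), hi - lo,
                )
            )
    return segments


def detect_from_probes(
    probes: pd.DataFrame,
    assembly: GenomeAssembly,
    thresholds: CallingThresholds | None = None,
    config: ScanConfig | None = None,
    penalty: float | None = None,
    sample_id: str = "sample",
) -> list[CTLPCall]:
    """Full probe-level pipeline: resegment -> preprocess -> scan -> call."""
    thresholds = thresholds or CallingThresholds()
    segments = resegment(probes, penalty=penalty)
    profile = preprocess_profile(segments, thresholds, assembly, sample_id)
    best = scan_genome(profile, assembly, config)
    return call_ctlp(best, profile, config, assembly)


def platform_sensitivity(
    truth_cases: list[tuple[pd.DataFrame, str]],
    probe_counts: list[int],
    reps: int,
    seed: int | None,
    assembly: GenomeAssembly,
    thresholds: CallingThresholds | None = None,
    config: ScanConfig | None = None,
    penalty: float | None = None,
) -> SensitivityCurve:
    """Detection sensitivity across simulated platform resolutions.

    ``truth_cases`` pairs a full-resolution probe table with the chromosome
    carrying a known CTLP event (detectable at full resolution). For each
    probe count the pipeline subsample -> resegment -> preprocess -> scan ->
    call is repeated ``reps`` times per case; the detected fraction is the
    share of runs in which the truth chromosome is called CTLP.
    """
    ss = np.random.SeedSequence(seed)
    fractions: list[float] = []
    for count in probe_counts:
        detected = 0
        total = 0
        for probes, truth_chrom in truth_cases:
            k = min(count, len(probes))
            for _ in range(reps):
                child = np.random.default_rng(ss.spawn(1)[0])
                sub = subsample_probes(probes, k, seed=child)
                calls = detect_from_probes(
                    sub, assembly, thresholds, config, penalty=penalty
                )
                detected += int(any(c.chromosome == truth_chrom for c in calls))
                total += 1
        fractions.append(detected / total if total else 0.0)
    return SensitivityCurve(
        probe_counts=list(probe_counts),
        detected_fraction=fractions,
        reps=reps,
        seed=seed,
    )
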