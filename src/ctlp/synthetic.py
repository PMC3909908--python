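"""Synthetic segmented profiles and probe tables with known CTLP truth.

The generator emulates the statistical structure the detector assumes: a
piecewise-constant log2-ratio genome with scattered background copy-number
aberrations, optionally one or more injected chromothripsis-like events (a
region shattered into many >= 10 kb fragments with alternating copy states),
and a probe-level rendering at a chosen marker density with Gaussian
intensity noise. Default state means are +0.4 (gain) and -0.5 (loss) on the
log2 scale, comfortably separated relative to the default calling thresholds
of +/-0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MB, GenomeAssembly, GenomicRegion, validate_region
from .preprocess import GAIN, LOSS, NEUTRAL, Segment

STATE_MEANS = {GAIN: 0.4, NEUTRAL: 0.0, LOSS: -0.5}

#: probes per Mb of an Affymetrix SNP6-class platform (~1.8 M markers,
#: ~1.7 kb mean inter-marker distance).
SNP6_DENSITY_PER_MB = 588.0


@dataclass(frozen=True)
class CTLPEvent:
    chromosome: str
    region: GenomicRegion
    n_fragments: int
    states: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Ground-truth record of a generated sample."""

    sample_id: str
    events: list[CTLPEvent] = field(default_factory=list)
    background_cna: int = 0
    probe_density_per_mb: float | None = None
    noise_sd: float | None = None
    seed: int | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_background(
    assembly: GenomeAssembly,
    n_cna: int,
    size_range: tuple[int, int] = (1 * MB, 20 * MB),
    states: tuple[str, ...] = (GAIN, LOSS),
    seed=None,
    state_means: dict[str, float] | None = None,
    min_gap: int = 50_000,
    max_tries: int = 1000,
) -> list[Segment]:
    """Neutral genome with ``n_cna`` scattered non-overlapping CNA segments.

    CNAs are placed uniformly (chromosome chosen proportional to length),
    separated from each other and from chromosome ends by ``min_gap`` so
    each contributes exactly two status changes after preprocessing. The
    remainder of every chromosome is filled with neutral segments.
    """
    rng = _rng(seed)
    means = dict(STATE_MEANS)
    means.update(state_means or {})
    chroms = list(assembly.included)
    lengths = np.array([assembly.length_of(c) for c in chroms], dtype=float)
    if size_range[0] > min(lengths) or size_range[1] > min(lengths):
        raise ValueError("CNA sizes must not exceed the shortest chromosome")
    weights = lengths / lengths.sum()

    placed: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    tries = 0
    count = 0
    while count < n_cna:
        if tries >= max_tries * max(1, n_cna):
            raise RuntimeError(
                f"could not place {n_cna} non-overlapping CNAs after {tries} tries"
            )
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = assembly.length_of(chrom)
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if size + 2 * min_gap > L:
            continue
        start = int(rng.integers(min_gap, L - size - min_gap + 1))
        end = start + size
        ok = all(
            end + min_gap <= s or e + min_gap <= start
            for s, e, _ in placed[chrom]
        )
        if not ok:
            continue
        state = states[rng.integers(len(states))]
        placed[chrom].append((start, end, state))
        count += 1

    segments: list[Segment] = []
    for chrom in chroms:
        L = assembly.length_of(chrom)
        cnas = sorted(placed[chrom])
        cursor = 0
        for start, end, state in cnas:
            if start > cursor:
                segments.append(Segment(chrom, cursor, start, means[NEUTRAL]))
            segments.append(Segment(chrom, start, end, means[state]))
            cursor = end
        if cursor < L:
            segments.append(Segment(chrom, cursor, L, means[NEUTRAL]))
    return segments


def inject_ctlp(
    segments: list[Segment],
    assembly: GenomeAssembly,
    chromosome: str,
    region: GenomicRegion,
    n_fragments: int,
    states: tuple[str, ...] = (GAIN, NEUTRAL),
    seed=None,
    mode: str = "random",
    state_means: dict[str, float] | None = None,
    min_fragment_bp: int = 10_000,
) -> tuple[list[Segment], CTLPEvent]:
    """Shatter ``region`` into ``n_fragments`` intervals of alternating state.

    Fragment lengths follow uniform stick-breaking above a 10 kb floor (so
    every fragment survives the preprocessing size filter); consecutive
    fragments never share a state, so the event contributes
    ``n_fragments - 1`` internal status changes.
    """
    if n_fragments < 2:
        raise ValueError("n_fragments must be >= 2")
    if len(states) < 2:
        raise ValueError("need at least two states to alternate")
    validate_region(region, assembly)
    if region.chromosome != chromosome:
        raise ValueError("region chromosome does not match")
    if region.length < n_fragments * min_fragment_bp:
        raise ValueError(
            f"region of {region.length} bp too small for {n_fragments} "
            f"fragments of >= {min_fragment_bp} bp"
        )
    rng = _rng(seed)
    means = dict(STATE_MEANS)
    means.update(state_means or {})

    slack = region.length - n_fragments * min_fragment_bp
    extra = rng.dirichlet(np.ones(n_fragments)) * slack
    lengths = (min_fragment_bp + extra).astype(np.int64)
    lengths[-1] += region.length - int(lengths.sum())
    bounds = region.start + np.concatenate([[0], np.cumsum(lengths)])

    frag_states: list[str] = []
    for i in range(n_fragments):
        if mode == "cycle":
            frag_states.append(states[i % len(states)])
        else:
            options = [s for s in states if not frag_states or s != frag_states[-1]]
            frag_states.append(options[rng.integers(len(options))])

    new_segments: list[Segment] = []
    for seg in segments:
        if seg.chromosome != chromosome or seg.end <= region.start or seg.start >= region.end:
            new_segments.append(seg)
            continue
        if seg.start < region.start:
            new_segments.append(
                Segment(chromosome, seg.start, region.start, seg.mean_log2, seg.n_markers)
            )
        if seg.end > region.end:
            new_segments.append(
                Segment(chromosome, region.end, seg.end, seg.mean_log2, seg.n_markers)
            )
    for i in range(n_fragments):
        new_segments.append(
            Segment(chromosome, int(bounds[i]), int(bounds[i + 1]), means[frag_states[i]])
        )
    new_segments.sort(key=lambda s: (s.chromosome, s.start))
    event = CTLPEvent(chromosome, region, n_fragments, tuple(states))
    return new_segments, event


def render_probes(
    segments: list[Segment],
    density_per_mb: float = SNP6_DENSITY_PER_MB,
    noise_sd: float = 0.15,
    seed=None,
) -> pd.DataFrame:
    """Probe table (probe_id, chromosome, position, log2) over a profile.

    Probe counts are Poisson with expectation ``density * length`` per
    chromosome, positions uniform over the covered span, and each probe's
    log2 value is its segment mean plus Gaussian noise.
    """
    if density_per_mb <= 0:
        raise ValueError("density must be > 0")
    rng = _rng(seed)
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    frames = []
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        span = (segs[0].start, segs[-1].end)
        n = int(rng.poisson(density_per_mb * (span[1] - span[0]) / MB))
        if n == 0:
            continue
        pos = np.sort(rng.integers(span[0], span[1], size=n))
        starts = np.array([s.start for s in segs])
        means = np.array([s.mean_log2 for s in segs])
        idx = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(segs) - 1)
        log2 = means[idx]
        if noise_sd > 0:
            log2 = log2 + rng.normal(0.0, noise_sd, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"p_{chrom}_{i}" for i in range(n)],
                    "chromosome": chrom,
                    "position": pos,
                    "log2": log2,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["probe_id", "chromosome", "position", "log2"])
    return pd.concat(frames, ignore_index=True)


def simulate_sample(
    assembly: GenomeAssembly,
    seed=None,
    sample_id: str = "synthetic",
    n_background_cna: int = 20,
    ctlp_chromosome: str | None = None,
    ctlp_region: GenomicRegion | None = None,
    n_fragments: int = 30,
    ctlp_states: tuple[str, ...] = (GAIN, NEUTRAL),
) -> tuple[list[Segment], SyntheticTruth]:
    """Background genome plus (optionally) one injected CTLP event."""
    rng = _rng(seed)
    segments = simulate_background(assembly, n_background_cna, seed=rng)
    truth = SyntheticTruth(
        sample_id=sample_id,
        background_cna=n_background_cna,
        seed=seed if isinstance(seed, int) else None,
    )
    if ctlp_chromosome is not None:
        if ctlp_region is None:
            L = assembly.length_of(ctlp_chromosome)
            size = min(30 * MB, int(L * 0.3))
            start = int(rng.integers(0, L - size + 1))
            ctlp_region = GenomicRegion(ctlp_chromosome, start, start + size)
        segments, event = inject_ctlp(
            segments, assembly, ctlp_chromosome, ctlp_region, n_fragments,
            states=ctlp_states, seed=rng,
        )
        truth.events.append(event)
    return segments, truth
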