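import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctlp.genome import MB, GenomeAssembly, GenomicRegion
from ctlp.preprocess import Breakpoint, GAIN, NEUTRAL, StatusProfile
from ctlp.scan import (
    ARM_LEVEL,
    CHROMOSOME_LEVEL,
    LOCALIZED,
    ScanConfig,
    ScanWindow,
    call_ctlp,
    classify_extent,
    default_window_series,
    generate_windows,
    genome_fractions,
    log10_likelihood_ratio,
    refine_region,
    scan_genome,
    telomere_involvement,
)


def profile_from_positions(positions, chrom="A", included=("A",)):
    """StatusProfile carrying only breakpoints (runs not needed for scanning)."""
    bps = {chrom: [Breakpoint(int(p), NEUTRAL, GAIN) for p in sorted(positions)]}
    return StatusProfile("t", runs={}, breakpoints=bps, included=included)


def brute_force_best(positions, length, G, n_G, sizes, step):
    """Exhaustive evaluation of the printed likelihood-ratio formula.

    Independent of the scan implementation: enumerates every window of
    every size and evaluates lambda directly in log space.
    """
    import math

    positions = sorted(positions)
    best = None
    for w in sorted(sizes):
        if w > length:
            continue
        for start in range(0, length - w + 1, step):
            n_w = sum(start <= p < start + w for p in positions)
            mu = w / G * n_G
            rem = n_G - n_w
            if not (0 < mu < n_G) or n_w * (n_G - mu) <= rem * mu:
                lam = 0.0
            else:
                lam = 0.0
                if n_w > 0:
                    lam += n_w * math.log10(n_w / mu)
                if rem > 0:
                    lam += rem * math.log10(rem / (n_G - mu))
            if best is None or lam > best[0]:
                best = (lam, w, start, n_w)
    return best


class TestDefaultWindowSeries:
    def test_hg18_tops_at_247_mb(self, hg18):
        series = default_window_series(hg18)
        assert max(series) == 247 * MB
        assert min(series) >= 30 * MB
        assert series == sorted(set(series))

    def test_dedupe_and_sort(self):
        asm = GenomeAssembly(
            "t",
            (("A", 50 * MB), ("B", 50 * MB), ("C", 80 * MB)),
            {c: (20 * MB, 25 * MB) for c in "ABC"},
        )
        assert default_window_series(asm) == [50 * MB, 80 * MB]

    def test_all_short_chromosomes_warn(self):
        asm = GenomeAssembly(
            "t", (("A", 20 * MB),), {"A": (8 * MB, 9 * MB)}
        )
        with pytest.warns(UserWarning):
            assert default_window_series(asm) == []


class TestGenerateWindows:
    def test_enumeration(self, toy_assembly):
        asm = GenomeAssembly("t", (("A", 50 * MB),), {"A": (20 * MB, 25 * MB)})
        zones = generate_windows(asm, [30 * MB], step=5 * MB)
        starts = [r.start for r in zones["A"]]
        assert starts == [0, 5 * MB, 10 * MB, 15 * MB, 20 * MB]

    def test_oversized_window_skipped(self):
        asm = GenomeAssembly("t", (("A", 50 * MB),), {"A": (20 * MB, 25 * MB)})
        assert generate_windows(asm, [60 * MB])["A"] == []

    def test_window_equal_to_chromosome(self):
        asm = GenomeAssembly("t", (("A", 50 * MB),), {"A": (20 * MB, 25 * MB)})
        zones = generate_windows(asm, [50 * MB])
        assert len(zones["A"]) == 1
        assert zones["A"][0] == GenomicRegion("A", 0, 50 * MB)


class TestLikelihoodRatio:
    def test_zero_at_expectation(self):
        assert log10_likelihood_ratio(4, 4.0, 40) == 0.0

    def test_zero_at_no_events(self):
        assert log10_likelihood_ratio(0, 2.0, 40) == 0.0

    def test_spot_value_against_log_space_oracle(self):
        # independent evaluation: 25*log10(12.5) + 15*log10(15/38)
        expected = 25 * np.log10(25 / 2.0) + 15 * np.log10(15 / 38.0)
        got = log10_likelihood_ratio(25, 2.0, 40)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(21.367, abs=1e-3)

    def test_all_events_in_window(self):
        # n_W = n_G exercises the 0*log(0) = 0 convention
        got = log10_likelihood_ratio(40, 2.0, 40)
        assert got == pytest.approx(40 * np.log10(20.0))

    @pytest.mark.parametrize("mu", [0.0, -1.0, 40.0, 41.0])
    def test_invalid_mu_rejected(self, mu):
        with pytest.raises(ValueError):
            log10_likelihood_ratio(5, mu, 40)

    def test_monotone_in_n_w_where_excess_holds(self):
        n_G, mu = 50, 3.0
        scores = [log10_likelihood_ratio(n, mu, n_G) for n in range(4, 51)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    @given(
        n_G=st.integers(1, 200),
        frac=st.floats(0.01, 0.99),
        n_W=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_negative(self, n_G, frac, n_W):
        n_W = min(n_W, n_G)
        mu = frac * n_G
        assert log10_likelihood_ratio(n_W, mu, n_G) >= 0.0


class TestScanGenome:
    def test_cluster_recovered_with_expected_score(self, toy_assembly):
        rng = np.random.default_rng(42)
        cluster = rng.integers(40 * MB, 50 * MB, size=30)
        rest = rng.choice(
            np.concatenate([np.arange(0, 40 * MB, MB), np.arange(50 * MB, 100 * MB, MB)]),
            size=5, replace=False,
        )
        positions = np.concatenate([cluster, rest])
        prof = profile_from_positions(positions)
        cfg = ScanConfig(window_sizes=(30 * MB,))
        best = scan_genome(prof, toy_assembly, cfg)["A"]
        oracle = brute_force_best(
            positions, 100 * MB, toy_assembly.G, 35, [30 * MB], 5 * MB
        )
        assert best.log10_lambda == pytest.approx(oracle[0])
        assert best.region.start <= 40 * MB and best.region.end >= 50 * MB
        assert best.n_W >= 30

    def test_no_breakpoints_scores_zero(self, toy_assembly):
        prof = profile_from_positions([])
        best = scan_genome(prof, toy_assembly, ScanConfig(window_sizes=(30 * MB,)))
        assert best["A"].log10_lambda == 0.0

    def test_uniform_density_scores_zero(self, toy_assembly):
        # windows at exactly the genome-wide density fail the excess condition
        positions = np.arange(0, 100 * MB, 10 * MB)  # 10 breakpoints, uniform
        prof = profile_from_positions(positions)
        cfg = ScanConfig(window_sizes=(50 * MB,), step=10 * MB)
        best = scan_genome(prof, toy_assembly, cfg)["A"]
        assert best.log10_lambda == 0.0

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        """Scan equals brute-force enumeration on random small genomes."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(40, 200)) * MB
        asm = GenomeAssembly(
            "t", (("A", length),), {"A": (length // 3, length // 2)}
        )
        n_bp = int(rng.integers(0, 50))
        if rng.random() < 0.7 and n_bp > 0:
            center = int(rng.integers(0, length))
            spread = int(rng.integers(1, 20)) * MB
            positions = np.clip(
                rng.integers(center - spread, center + spread + 1, size=n_bp),
                0, length - 1,
            )
        else:
            positions = rng.integers(0, length, size=n_bp)
        sizes = [30 * MB, 50 * MB, min(100 * MB, length)]
        prof = profile_from_positions(positions)
        cfg = ScanConfig(window_sizes=tuple(sizes))
        best = scan_genome(prof, asm, cfg)["A"]
        oracle = brute_force_best(positions, length, asm.G, n_bp, sizes, 5 * MB)
        assert best.log10_lambda == pytest.approx(oracle[0], abs=1e-9)
        if oracle[0] > 0:
            assert (best.W, best.region.start) == (oracle[1], oracle[2])

    def test_positional_invariance(self, toy_assembly):
        positions = np.array([40, 41, 42, 43, 60], dtype=np.int64) * MB
        cfg = ScanConfig(window_sizes=(30 * MB,))
        best0 = scan_genome(profile_from_positions(positions), toy_assembly, cfg)["A"]
        shift = 5 * MB  # multiple of the step keeps the window grid aligned
        best1 = scan_genome(
            profile_from_positions(positions + shift), toy_assembly, cfg
        )["A"]
        assert best1.log10_lambda == pytest.approx(best0.log10_lambda)
        assert best1.region.start == best0.region.start + shift


class TestCallCtlp:
    def _windows(self, n_w, lam, chrom="A"):
        win = ScanWindow(
            GenomicRegion(chrom, 30 * MB, 60 * MB), 30 * MB, n_w, 2.0, lam
        )
        return {chrom: win}

    def _profile(self, chrom="A"):
        positions = np.linspace(35 * MB, 55 * MB, 30).astype(int)
        return profile_from_positions(positions, chrom)

    def test_both_thresholds_met(self, toy_assembly):
        calls = call_ctlp(
            self._windows(30, 10.2), self._profile(), ScanConfig(), toy_assembly
        )
        assert len(calls) == 1
        assert calls[0].switch_count == 30

    def test_too_few_switches(self, toy_assembly):
        assert call_ctlp(
            self._windows(19, 12.0), self._profile(), ScanConfig(), toy_assembly
        ) == []

    def test_score_below_threshold(self, toy_assembly):
        assert call_ctlp(
            self._windows(25, 7.9), self._profile(), ScanConfig(), toy_assembly
        ) == []

    def test_refined_region_trimmed_to_breakpoints(self, toy_assembly):
        calls = call_ctlp(
            self._windows(30, 10.2), self._profile(), ScanConfig(), toy_assembly
        )
        region = calls[0].refined_region
        win = calls[0].best_window.region
        assert win.start <= region.start < region.end <= win.end
        assert region.start == 35 * MB
        assert region.end == 55 * MB


class TestRefineRegion:
    def test_requires_two_internal_breakpoints(self):
        prof = profile_from_positions([40 * MB])
        win = ScanWindow(GenomicRegion("A", 30 * MB, 60 * MB), 30 * MB, 1, 0.5, 9.0)
        assert refine_region(win, prof) is None


class TestClassifyExtent:
    def test_chromosome_level(self, toy_assembly):
        region = GenomicRegion("A", 5 * MB, 90 * MB)  # 85% of the chromosome
        assert classify_extent(region, toy_assembly) == CHROMOSOME_LEVEL

    def test_arm_level(self, toy_assembly):
        # 92% of the 45 Mb p arm, fully inside it
        region = GenomicRegion("A", 0, int(0.92 * 45 * MB))
        assert classify_extent(region, toy_assembly) == ARM_LEVEL

    def test_localized(self, toy_assembly):
        # 50% of the q arm
        region = GenomicRegion("A", 55 * MB, int(55 * MB + 0.5 * 45 * MB))
        assert classify_extent(region, toy_assembly) == LOCALIZED

    def test_every_region_gets_exactly_one_label(self, toy_assembly, rng):
        for _ in range(200):
            a, b = np.sort(rng.integers(0, 100 * MB, size=2))
            if a == b:
                continue
            label = classify_extent(GenomicRegion("A", int(a), int(b)), toy_assembly)
            assert label in (LOCALIZED, ARM_LEVEL, CHROMOSOME_LEVEL)


class TestTelomereInvolvement:
    @pytest.mark.parametrize(
        "start_mb, end_mb, p_flag, q_flag",
        [
            (2, 40, True, False),
            (10, 20, False, False),
            (0, 100, True, True),
            (96, 100, False, True),
        ],
    )
    def test_flags(self, toy_assembly, start_mb, end_mb, p_flag, q_flag):
        region = GenomicRegion("A", start_mb * MB, end_mb * MB)
        assert telomere_involvement(region, toy_assembly) == (p_flag, q_flag)


class TestGenomeFractions:
    def test_ctlp_fraction(self, toy_assembly):
        prof = profile_from_positions([])
        win = ScanWindow(GenomicRegion("A", 0, 30 * MB), 30 * MB, 30, 2.0, 12.0)
        call_region = GenomicRegion("A", 10 * MB, 24 * MB)  # 14 Mb of 100 Mb
        from ctlp.scan import CTLPCall

        call = CTLPCall("t", "A", win, call_region, 30, LOCALIZED, False, False)
        ctlp_frac, cna_frac = genome_fractions([call], prof, toy_assembly)
        assert ctlp_frac == pytest.approx(0.14)
        assert cna_frac == 0.0

    def test_fully_aberrant_genome(self, toy_assembly):
        from ctlp.preprocess import CallingThresholds, Segment, preprocess_profile

        segs = [Segment("A", 0, 100 * MB, 0.8)]
        prof = preprocess_profile(segs, CallingThresholds(), toy_assembly)
        _, cna_frac = genome_fractions([], prof, toy_assembly)
        assert cna_frac == pytest.approx(1.0)
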