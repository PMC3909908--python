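"""Readers and writers: SEG tables, probe tables, BED and run reports.

SEG input is 1-based inclusive and converted to the package's 0-based
half-open coordinates on read; BED output is 0-based half-open per the BED
standard. Chromosome labels with or without the ``chr`` prefix (and
``23``/``24`` for X/Y) are accepted and unified.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import normalize_chromosome
from .preprocess import Segment
from .scan import CTLPCall

SEG_COLUMNS = {
    "id": "sample",
    "sample": "sample",
    "chrom": "chromosome",
    "chromosome": "chromosome",
    "loc.start": "start",
    "start": "start",
    "loc.end": "end",
    "end": "end",
    "num.mark": "n_markers",
    "num_mark": "n_markers",
    "seg.mean": "mean_log2",
    "seg_mean": "mean_log2",
}

REQUIRED = ("sample", "chromosome", "start", "end", "mean_log2")


def _read_table(path) -> pd.DataFrame:
    # tolerate tab and multi-space delimited dialects
    return pd.read_csv(path, sep=r"\s+", comment="#")


def read_seg(path) -> dict[str, list[Segment]]:
    """Parse a SEG file into per-sample lists of sorted segments."""
    df = _read_table(path)
    df.columns = [SEG_COLUMNS.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file {path} missing column(s): {missing}")

    for col in ("start", "end", "mean_log2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 2  # header is line 1
            raise ValueError(f"malformed value in column {col!r} at line {line} of {path}")
        df[col] = vals
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)

    out: dict[str, list[Segment]] = {}
    for sample, grp in df.groupby("sample", sort=False):
        grp = grp.sort_values(["chromosome", "start"], kind="mergesort")
        segs: list[Segment] = []
        for row in grp.itertuples():
            n_mark = None
            if "n_markers" in grp.columns and not pd.isna(getattr(row, "n_markers", None)):
                n_mark = int(row.n_markers)
            segs.append(
                Segment(
                    chromosome=row.chromosome,
                    start=int(row.start) - 1,  # 1-based inclusive -> half-open
                    end=int(row.end),
                    mean_log2=float(row.mean_log2),
                    n_markers=n_mark,
                )
            )
        for a, b in zip(segs, segs[1:]):
            if a.chromosome == b.chromosome and b.start < a.end:
                raise ValueError(
                    f"overlapping segments for sample {sample} on chromosome "
                    f"{a.chromosome} in {path}"
                )
        out[str(sample)] = segs
    return out


def write_seg(profiles: Mapping[str, Iterable[Segment]], path) -> None:
    """Write per-sample segments as a SEG table (1-based inclusive)."""
    rows = []
    for sample, segs in profiles.items():
        for s in segs:
            rows.append(
                {
                    "ID": sample,
                    "chrom": s.chromosome,
                    "loc.start": s.start + 1,
                    "loc.end": s.end,
                    # 0 = marker count unknown (keeps whitespace dialects parseable)
                    "num.mark": s.n_markers if s.n_markers is not None else 0,
                    "seg.mean": f"{s.mean_log2:.6f}",
                }
            )
    pd.DataFrame(
        rows, columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    """Read a probe table (probe_id, chromosome, position, log2)."""
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("probe_id", "chromosome", "position", "log2") if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} missing column(s): {missing}")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df["position"] = pd.to_numeric(df["position"]).astype(np.int64)
    df["log2"] = pd.to_numeric(df["log2"])
    return df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)


BED_HEADER = "#chrom\tstart\tend\tname\tscore\tswitch_count\textent"


def write_bed(calls: Iterable[CTLPCall], path) -> None:
    """Write refined CTLP regions as BED3+ (score = min(1000, 100*log10 LR))."""
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for call in calls:
            r = call.refined_region
            score = min(1000, round(100 * call.log10_lambda))
            fh.write(
                f"chr{r.chromosome}\t{r.start}\t{r.end}\t{call.sample_id}\t"
                f"{score}\t{call.switch_count}\t{call.extent}\n"
            )


def calls_to_frame(calls: Iterable[CTLPCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample_id,
                "chromosome": c.chromosome,
                "window_start": c.best_window.region.start,
                "window_end": c.best_window.region.end,
                "window_size": c.best_window.W,
                "n_W": c.best_window.n_W,
                "mu_W": c.best_window.mu_W,
                "log10_lambda": c.best_window.log10_lambda,
                "region_start": c.refined_region.start,
                "region_end": c.refined_region.end,
                "switch_count": c.switch_count,
                "extent": c.extent,
                "telomere_p": c.telomere_p,
                "telomere_q": c.telomere_q,
                "ctlp_fraction_of_genome": c.ctlp_fraction_of_genome,
            }
        )
    cols = [
        "sample", "chromosome", "window_start", "window_end", "window_size",
        "n_W", "mu_W", "log10_lambda", "region_start", "region_end",
        "switch_count", "extent", "telomere_p", "telomere_q",
        "ctlp_fraction_of_genome",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_report(
    calls_by_sample: Mapping[str, list[CTLPCall]],
    fractions_by_sample: Mapping[str, tuple[float, float]],
    config_echo: dict,
    tsv_path,
    json_path,
) -> dict:
    """Write the per-call TSV and a JSON cohort summary; returns the summary."""
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    calls_to_frame(all_calls).to_csv(tsv_path, sep="\t", index=False)

    n_samples = len(calls_by_sample)
    positives = [s for s, calls in calls_by_sample.items() if calls]
    chrom_counts: dict[str, int] = {}
    for c in all_calls:
        chrom_counts[c.chromosome] = chrom_counts.get(c.chromosome, 0) + 1
    total_calls = len(all_calls)
    summary = {
        "n_samples": n_samples,
        "n_ctlp_positive": len(positives),
        "prevalence": len(positives) / n_samples if n_samples else 0.0,
        "n_ctlp_chromosomes": total_calls,
        "per_chromosome_frequency": {
            chrom: count / total_calls for chrom, count in sorted(chrom_counts.items())
        },
        "fractions": {
            s: {"ctlp_fraction": f[0], "cna_fraction": f[1]}
            for s, f in fractions_by_sample.items()
        },
        "config": config_echo,
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
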