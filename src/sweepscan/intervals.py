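"""Threshold-based candidate-interval extraction, combination and reporting.

Candidate intervals are maximal runs of consecutive SNPs whose statistic
passes a threshold; an interval spans from the first to the last passing
SNP's position (quoting SNP coordinates as the bounds).  Evidence from
several statistics is combined by interval union or intersection, and
refined regions are reported in bp and truncated kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenomicInterval

XPEHH_THRESHOLD = 4.34  # conventional |XP-EHH| candidate threshold


@dataclass(frozen=True)
class ThresholdSpec:
    """A pass rule for one statistic.

    ``direction`` is ``ge`` (value >= threshold... strictly ``>`` per the
    scanning convention), ``le`` or ``abs_ge``; ``provenance`` records how
    the threshold was obtained ("fixed" or a percentile description with
    the q and n used).
    """

    statistic: str
    threshold: float
    direction: str = "ge"
    provenance: str = "fixed"
    percentile_q: float | None = None
    percentile_n: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "le", "abs_ge"):
            raise ValueError("direction must be ge, le or abs_ge")

    def passes(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            if self.direction == "ge":
                ok = v > self.threshold
            elif self.direction == "le":
                ok = v < self.threshold
            else:
                ok = np.abs(v) > self.threshold
        ok[np.isnan(v)] = False
        return ok


def extract_intervals(
    scan: pd.DataFrame, spec: ThresholdSpec, bridge_na: bool = False
) -> list[GenomicInterval]:
    """Maximal runs of consecutive passing SNPs as genomic intervals.

    ``scan`` needs columns ``chrom``, ``pos_bp`` and the statistic named in
    ``spec``.  Single-SNP runs yield zero-length intervals.  With
    ``bridge_na`` NA SNPs neither pass nor break a run when flanked by
    passing SNPs; by default an NA breaks the run.
    """
    if spec.statistic not in scan.columns:
        raise ValueError(f"unknown statistic {spec.statistic!r}")
    out: list[GenomicInterval] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        v = sub[spec.statistic].to_numpy(dtype=float)
        pos = sub["pos_bp"].to_numpy()
        ok = spec.passes(v)
        na = np.isnan(v)
        start = None
        last_pass = None
        for k in range(len(v) + 1):
            at_end = k == len(v)
            if not at_end and ok[k]:
                if start is None:
                    start = k
                last_pass = k
            elif at_end or not (bridge_na and na[k] and start is not None):
                if start is not None:
                    out.append(
                        GenomicInterval(str(chrom), int(pos[start]), int(pos[last_pass]))
                    )
                    start = last_pass = None
    return out


def _merge_sorted(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals; input need not be sorted."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda i: (i.chrom, i.start_bp, i.end_bp)):
        if out and out[-1].chrom == iv.chrom and iv.start_bp <= out[-1].end_bp + 1:
            if iv.end_bp > out[-1].end_bp:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start_bp, iv.end_bp)
        else:
            out.append(iv)
    return out


def combine_intervals(
    a: list[GenomicInterval], b: list[GenomicInterval], mode: str = "intersection"
) -> list[GenomicInterval]:
    """Interval union or intersection, merged and sorted."""
    if mode == "union":
        return _merge_sorted(list(a) + list(b))
    if mode != "intersection":
        raise ValueError("mode must be 'union' or 'intersection'")
    a = _merge_sorted(list(a))
    b = _merge_sorted(list(b))
    out = []
    for ia in a:
        for ib in b:
            if ia.chrom != ib.chrom:
                continue
            lo = max(ia.start_bp, ib.start_bp)
            hi = min(ia.end_bp, ib.end_bp)
            if lo <= hi:
                out.append(GenomicInterval(ia.chrom, lo, hi))
    return _merge_sorted(out)


def report_refined(intervals: list[GenomicInterval]) -> pd.DataFrame:
    """Per-interval report (chrom, start, end, length_bp, length_kb) plus
    per-chromosome summed lengths for multi-interval regions."""
    rows = [
        {
            "chrom": iv.chrom,
            "start_bp": iv.start_bp,
            "end_bp": iv.end_bp,
            "length_bp": iv.length_bp,
            "length_kb": iv.length_kb,
        }
        for iv in intervals
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "length_bp", "length_kb"]
    )
    if len(df):
        sums = (
            df.groupby("chrom", sort=False)["length_bp"]
            .sum()
            .rename("total_length_bp")
            .reset_index()
        )
        sums["total_length_kb"] = sums["total_length_bp"] // 1000
        df = df.merge(sums, on="chrom", how="left")
    return df
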