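"""Genotype quality control.

The cascade applied by the pipeline: sample missingness filter (default
max 30%), then locus missingness filter (default max 15%), then per-SNP
filters — pooled minor allele frequency >= 10% and a per-breed exact
Hardy-Weinberg test at alpha 0.0002.  X-chromosome analyses use females
only (male and female effective population sizes differ on X, and
hemizygous males would distort homozygosity-based statistics).

Missingness cutoffs can be motivated by a missingness curve (entities
excluded vs. percent-missing threshold) whose inflection point marks where
the exclusion count starts changing linearly; :func:`suggest_inflection_cutoff`
formalizes that as the discrete second-difference argmax, but is advisory —
the filters always take explicit thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISSING_SAMPLE = 0.30
DEFAULT_MAX_MISSING_LOCUS = 0.15
DEFAULT_MAF_MIN = 0.10
DEFAULT_HWE_ALPHA = 0.0002
DEFAULT_CUTOFF = {"samples": 30.0, "loci": 15.0}


@dataclass
class MissingnessCurve:
    """Entities excluded as a function of a percent-missing cutoff."""

    axis: str  # "samples" or "loci"
    thresholds: np.ndarray  # percent, 1%-step grid 0..100
    n_excluded: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_excluded) > 0):
            raise ValueError("n_excluded must be non-increasing in the threshold")


@dataclass
class SNPQCReport:
    """Per-SNP QC decisions: missing rate, MAF, per-breed HWE p, verdict."""

    df: pd.DataFrame  # snp_id, missing_rate, maf, hwe_p_<breed>..., pass, fail_reason

    def n_passed(self) -> int:
        return int(self.df["pass"].sum())


def _missing_rates(g: GenotypeMatrix, axis: str) -> np.ndarray:
    miss = g.missing_mask()
    if axis == "samples":
        return miss.mean(axis=1)
    if axis == "loci":
        return miss.mean(axis=0)
    raise ValueError("axis must be 'samples' or 'loci'")


def missingness_profile(g: GenotypeMatrix, axis: str) -> MissingnessCurve:
    """Count entities whose missing rate exceeds each cutoff on a 1% grid."""
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    rates = _missing_rates(g, axis) * 100.0
    thresholds = np.arange(0, 101, dtype=float)
    n_excluded = np.array([(rates > t).sum() for t in thresholds])
    return MissingnessCurve(axis, thresholds, n_excluded)


def suggest_inflection_cutoff(curve: MissingnessCurve, default: float | None = None) -> float:
    """Grid point maximizing the discrete second difference of n_excluded.

    Advisory only.  On a flat or strictly linear curve (no knee) the
    configured default is returned with a logged note; ties break toward
    the smaller (more stringent) threshold.
    """
    if default is None:
        default = DEFAULT_CUTOFF[curve.axis]
    y = curve.n_excluded.astype(float)
    if len(y) < 3:
        return default
    d2 = y[:-2] - 2 * y[1:-1] + y[2:]  # second difference at interior points
    if np.all(d2 == 0):
        logger.info("missingness curve has no knee; using default %.0f%%", default)
        return default
    k = int(np.argmax(d2))  # argmax returns the first (smallest) maximizer
    return float(curve.thresholds[k + 1])


def filter_by_missingness(g: GenotypeMatrix, axis: str, max_missing: float) -> GenotypeMatrix:
    """Drop entities with missing rate strictly greater than ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    rates = _missing_rates(g, axis)
    keep = np.flatnonzero(rates <= max_missing)
    if len(keep) == 0:
        raise ValueError(f"all {axis} removed at max_missing={max_missing}")
    return g.subset_samples(keep) if axis == "samples" else g.subset_snps(keep)


def minor_allele_frequency(g: GenotypeMatrix, snp: int | None = None) -> np.ndarray | float:
    """Pooled-sample minor allele frequency, NaN where all calls are missing."""
    p = g.allele_b_freq()
    maf = np.minimum(p, 1.0 - p)
    return maf if snp is None else float(maf[snp])


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts, given the observed
    allele counts, that are no more probable than the observed count
    (Wigginton-style enumeration).  Returns 1.0 for monomorphic samples.
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("no genotypes")
    n_b = n_ab + 2 * n_bb  # minor-ness does not matter; test is symmetric
    n_rare = min(n_b, 2 * n - n_b)
    if n_rare == 0:
        return 1.0
    # enumerate P(het = h | allele counts) via the standard recurrence
    het_probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    h = mid
    while h > 1:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        het_probs[h - 2] = het_probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h <= n_rare - 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        het_probs[h + 2] = het_probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    het_probs /= het_probs.sum()
    obs_het = n_ab
    p = het_probs[het_probs <= het_probs[obs_het] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def _genotype_counts(codes_col: np.ndarray) -> tuple[int, int, int]:
    return (
        int((codes_col == 0).sum()),
        int((codes_col == 1).sum()),
        int((codes_col == 2).sum()),
    )


def apply_snp_filters(
    g: GenotypeMatrix,
    samples: SampleTable | None = None,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[GenotypeMatrix, SNPQCReport]:
    """Exclude SNPs with pooled MAF < maf_min or HWE p < hwe_alpha in a breed.

    Both criteria are evaluated for every SNP (the report is
    order-independent); the recorded fail_reason prefers ``maf`` when both
    fail.  SNPs with no non-missing calls fail with reason ``maf``.
    """
    samples = samples or g.samples
    breed_a, breed_b = samples.require_two_breeds()
    rows_a = g.breed_rows(breed_a)
    rows_b = g.breed_rows(breed_b)

    maf = minor_allele_frequency(g)
    missing_rate = g.missing_mask().mean(axis=0)
    recs = []
    for j in range(g.n_snps):
        hwe_p = {}
        for breed, rows in ((breed_a, rows_a), (breed_b, rows_b)):
            col = g.codes[rows, j]
            col = col[col != MISSING]
            hwe_p[breed] = hwe_exact_test(*_genotype_counts(col)) if len(col) else np.nan
        maf_fail = np.isnan(maf[j]) or maf[j] < maf_min
        hwe_fail = any(
            not np.isnan(p) and p < hwe_alpha for p in hwe_p.values()
        )
        reason = "maf" if maf_fail else ("hwe" if hwe_fail else "none")
        recs.append(
            {
                "snp_id": g.snp_map.df["snp_id"].iloc[j],
                "missing_rate": missing_rate[j],
                "maf": maf[j],
                f"hwe_p_{breed_a}": hwe_p[breed_a],
                f"hwe_p_{breed_b}": hwe_p[breed_b],
                "pass": not (maf_fail or hwe_fail),
                "fail_reason": reason,
            }
        )
    report = SNPQCReport(pd.DataFrame(recs))
    keep = np.flatnonzero(report.df["pass"].to_numpy())
    return g.subset_snps(keep), report


def subset_for_chrX(g: GenotypeMatrix, samples: SampleTable | None = None):
    """Retain females only, for X-chromosome analyses.

    Samples of unknown sex are dropped with a warning; a breed left with
    zero females is an error (the X scan is then impossible).
    """
    samples = samples or g.samples
    sex = samples.df["sex"].to_numpy()
    n_unknown = int((sex == "U").sum())
    if n_unknown:
        logger.warning("dropping %d samples of unknown sex for chrX", n_unknown)
    keep = np.flatnonzero(sex == "F")
    kept = samples.df.iloc[keep]
    for breed in samples.df["breed"].unique():
        if (kept["breed"] == breed).sum() == 0:
            raise ValueError(f"no females in breed {breed}: X scan impossible")
    sub = g.subset_samples(keep)
    return sub, sub.samples
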