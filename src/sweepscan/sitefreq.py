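"""Allele-frequency-spectrum statistics.

Three per-SNP FST estimators for a two-population comparison:

* ``wright`` — the basic fixation index ``(H_T - H_S) / H_T`` with ``H_S``
  the unweighted mean of the two breeds' expected heterozygosities
  ``2 p_i (1 - p_i)`` and ``H_T = 2 p̄ (1 - p̄)`` at the unweighted mean
  frequency; bounded in [0, 1].
* ``weir_cockerham`` — the two-population theta estimator with sample-size
  correction; can go (slightly) negative at undifferentiated SNPs and is
  reported as-is.
* ``hudson`` — ``1 - H_w / H_b`` with unbiased within-population
  heterozygosity (``2 p q n/(n-1)`` on allele counts) and between-population
  heterozygosity ``p1(1-p2) + p2(1-p1)``.

Windowed FST is the sliding mean over five adjacent SNPs, centered, never
spanning chromosomes.  The per-SNP run-of-homozygosity statistic counts, in
one animal, the consecutive homozygous SNPs in the maximal run containing
the index SNP (zero if the index SNP is heterozygous; missing calls break
runs), and the scan reports the per-breed median over animals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MISSING, GenomicInterval, GenotypeMatrix, SampleTable

ESTIMATORS = ("wright", "weir_cockerham", "hudson")


def _breed_freqs_and_sizes(g: GenotypeMatrix, samples: SampleTable):
    breed_a, breed_b = samples.require_two_breeds()
    out = []
    for breed in (breed_a, breed_b):
        rows = np.flatnonzero(samples.breeds == breed)
        codes = g.codes[rows]
        obs = codes != MISSING
        n_ind = obs.sum(axis=0).astype(float)  # diploids with calls
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, codes, 0).sum(axis=0) / (2 * n_ind)
        p = np.where(n_ind > 0, p, np.nan)
        het_obs = np.where(obs, codes == 1, False).sum(axis=0) / np.where(
            n_ind > 0, n_ind, np.nan
        )
        out.append((p, n_ind, het_obs))
    return out[0], out[1]


def fst_wright(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """(H_T - H_S)/H_T with unweighted means; NaN where monomorphic overall."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (ht - hs) / ht
    return np.where(ht > 0, fst, np.nan)


def fst_hudson(p1, p2, n1_alleles, n2_alleles) -> np.ndarray:
    """Hudson's estimator 1 - H_w/H_b with unbiased within heterozygosity."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1_alleles, dtype=float)
    n2 = np.asarray(n2_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hw1 = 2 * p1 * (1 - p1) * n1 / (n1 - 1)
        hw2 = 2 * p2 * (1 - p2) * n2 / (n2 - 1)
        hw = (hw1 + hw2) / 2.0
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        fst = 1.0 - hw / hb
    return np.where(hb > 0, fst, np.nan)


def fst_weir_cockerham(p1, p2, n1, n2, h1, h2) -> np.ndarray:
    """Weir-Cockerham theta for two populations.

    ``n1, n2`` are diploid sample sizes, ``h1, h2`` observed heterozygote
    frequencies.  Returns the per-SNP ratio a / (a + b + c); negative values
    are retained.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom
    poly = (pbar > 0) & (pbar < 1) | (s2 > 0)
    return np.where(poly & (denom != 0), theta, np.nan)


def fst_per_snp(
    g: GenotypeMatrix, samples: SampleTable | None = None, estimator: str = "wright"
) -> np.ndarray:
    """Per-SNP two-breed FST under the named estimator.

    SNPs monomorphic overall, or with one breed entirely missing, yield NaN.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    samples = samples or g.samples
    (p1, n1, h1), (p2, n2, h2) = _breed_freqs_and_sizes(g, samples)
    if estimator == "wright":
        return fst_wright(p1, p2)
    if estimator == "hudson":
        return fst_hudson(p1, p2, 2 * n1, 2 * n2)
    return fst_weir_cockerham(p1, p2, n1, n2, h1, h2)


def windowed_mean(values: np.ndarray, chroms: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean of ``window`` SNPs, never spanning chromosomes.

    NaN members are dropped from each mean; SNPs within ``window // 2`` of a
    chromosome end get NaN (incomplete windows are not reported).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), np.nan)
    half = window // 2
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        v = values[idx]
        for k in range(half, len(idx) - half):
            w = v[k - half : k + half + 1]
            w = w[~np.isnan(w)]
            if len(w):
                out[idx[k]] = w.mean()
    return out


def windowed_fst(values: np.ndarray, chroms: np.ndarray | None = None, window: int = 5) -> np.ndarray:
    """5-SNP (by default) centered sliding mean of per-SNP FST values."""
    if chroms is None:
        chroms = np.zeros(len(values), dtype=int)
    return windowed_mean(values, np.asarray(chroms), window)


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


def homozygosity_run_lengths(codes_row: np.ndarray) -> np.ndarray:
    """Per-SNP run length containing each SNP, for one animal's genotypes.

    The run length at a SNP is the number of consecutive homozygous SNPs in
    the maximal homozygous run containing it; 0 at heterozygous SNPs and NaN
    at missing calls.  Missing calls terminate runs.
    """
    codes_row = np.asarray(codes_row)
    n = len(codes_row)
    out = np.zeros(n, dtype=float)
    hom = (codes_row == 0) | (codes_row == 2)
    miss = codes_row == MISSING
    j = 0
    while j < n:
        if hom[j]:
            k = j
            while k < n and hom[k]:
                k += 1
            out[j:k] = k - j
            j = k
        else:
            out[j] = np.nan if miss[j] else 0.0
            j += 1
    return out


def homozygosity_run_length(g: GenotypeMatrix, sample: int, snp: int) -> float:
    """Run length for one animal at one SNP (NaN if the call is missing)."""
    return float(homozygosity_run_lengths(g.codes[sample])[snp])


def median_homozygosity_scan(
    g: GenotypeMatrix,
    samples: SampleTable | None = None,
    region: slice | None = None,
    flank_snps: int = 25,
) -> pd.DataFrame:
    """Per-SNP, per-breed median run-of-homozygosity lengths.

    ``region`` is a SNP-index slice for the candidate region; the scan is
    evaluated over the region extended by ``flank_snps`` on each side (runs
    are computed on the extended window only, so they truncate at its
    boundaries).  Animals missing at a SNP are excluded from that SNP's
    median; a breed with no evaluable animal gets NaN.
    """
    samples = samples or g.samples
    n = g.n_snps
    if region is None:
        lo, hi = 0, n
    else:
        lo, hi = region.indices(n)[:2]
    wlo, whi = max(0, lo - flank_snps), min(n, hi + flank_snps)
    breeds = samples.breed_labels()
    cols = {"snp_index": np.arange(wlo, whi), "pos_bp": g.snp_map.pos_bp[wlo:whi]}
    for breed in breeds:
        rows = np.flatnonzero(samples.breeds == breed)
        runs = np.stack([homozygosity_run_lengths(g.codes[i, wlo:whi]) for i in rows])
        med = np.full(whi - wlo, np.nan)
        for k in range(whi - wlo):
            col = runs[:, k]
            col = col[~np.isnan(col)]
            if len(col):
                med[k] = np.median(col)
        cols[f"med_hom_{breed}"] = med
    return pd.DataFrame(cols)


def empirical_percentile_threshold(values, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    v = np.asarray(values, dtype=float)
    v = np.sort(v[np.isfinite(v)])
    if len(v) == 0:
        raise ValueError("no finite values")
    # round-to-9-decimals guards against float artifacts (0.999*1000 != 999)
    k = int(np.ceil(round(q / 100.0 * len(v), 9)))
    return float(v[max(k, 1) - 1])
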