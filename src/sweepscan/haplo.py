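"""Haplotype-based selection statistics: EHH, iHH, iHS, XP-EHH, pairwise r2.

Extended haplotype homozygosity (EHH) at distance d from a core SNP is the
probability that two randomly chosen haplotypes carrying a specified core
allele are identical over the closed interval from the core out to d:

    EHH(d) = sum_h C(n_h, 2) / C(n_c, 2)

over the distinct extended haplotypes h among the n_c carriers.  The
integrated EHH (iHH) is the trapezoidal area of the EHH decay against
physical distance (bp), summed over both directions, truncated where EHH
first drops below a cutoff (default 0.05; the crossing is linearly
interpolated).  Distances are physical: no genetic map is assumed, so iHH
carries bp*EHH units.

uiHS = ln(iHH_A / iHH_D) contrasts the ancestral and derived core alleles;
it is standardized to mean 0 / variance 1 within derived-allele-frequency
bins (18 equal-width bins over [0.05, 0.95] by default; equal-count binning
is available), with X-flagged SNPs standardized in a separate pass.

XP-EHH contrasts two populations at the same SNP: EHH is computed over all
haplotypes in each population, both integrals truncated at the point where
the pooled two-population EHH first drops below the cutoff, and
raw = ln(I_A / I_B) is z-scored over the scan.  Positive standardized
values indicate unusually long haplotypes (a sweep) in population A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import HaplotypeSet

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
IHS_BINS = 18
IHS_WINDOW = 10


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------


@dataclass
class EHHProfile:
    """EHH decay outward from a core SNP, per direction.

    ``idx_right``/``idx_left`` list SNP indices outward from the core
    (both start with the core itself); ``ehh_right``/``ehh_left`` are the
    corresponding EHH values.  For an allele-specific core the value at the
    core is 1; for ``core_allele="all"`` it is the single-site
    homozygosity at the core.
    """

    core: int
    core_allele: str
    n_carriers: int
    positions_bp: np.ndarray
    idx_right: np.ndarray
    ehh_right: np.ndarray
    idx_left: np.ndarray
    ehh_left: np.ndarray

    def __post_init__(self) -> None:
        for e in (self.ehh_right, self.ehh_left):
            if np.any(np.diff(e) > 1e-12):
                raise AssertionError("EHH must be non-increasing outward")


def _ehh_decay(
    haps: np.ndarray, cols: np.ndarray, min_ehh: float | None = None
) -> np.ndarray:
    """EHH along successive columns for the given haplotype rows.

    ``cols`` runs outward from (and includes) the core column.  Identity
    classes only ever split as columns accumulate, so EHH is non-increasing.
    With ``min_ehh`` the decay stops right after the first value below it
    (the returned array is truncated there), which keeps long scans linear
    in the decay length rather than the region length.
    """
    n = haps.shape[0]
    denom = n * (n - 1) / 2.0
    group = np.zeros(n, dtype=np.int64)
    out = np.empty(len(cols))
    for k, j in enumerate(cols):
        # refine identity classes by the allele at column j
        pair = group * 2 + haps[:, j]
        _, group = np.unique(pair, return_inverse=True)
        counts = np.bincount(group)
        out[k] = (counts * (counts - 1) / 2.0).sum() / denom
        if min_ehh is not None and out[k] < min_ehh:
            return out[: k + 1]
    return out


def ehh_profile(
    haps: HaplotypeSet | np.ndarray,
    core: int,
    core_allele: str,
    ancestral_is_b: float | None = None,
    min_ehh: float | None = None,
    max_snps: int | None = None,
) -> EHHProfile:
    """EHH decay profile for one core SNP.

    Parameters
    ----------
    haps
        HaplotypeSet or a raw binary haplotype matrix.
    core_allele
        ``"ancestral"``/``"derived"`` (requires the SNP's ancestral state,
        taken from the map or given via ``ancestral_is_b``), ``"0"``/``"1"``
        for an explicit allele, or ``"all"`` for the whole sample
        (cross-population use).

    Raises
    ------
    ValueError
        If fewer than 2 haplotypes carry the core allele.
    """
    if isinstance(haps, HaplotypeSet):
        H = haps.haps
        pos = haps.snp_map.pos_bp
        if ancestral_is_b is None and core_allele in ("ancestral", "derived"):
            ancestral_is_b = haps.snp_map.ancestral_is_b()[core]
    else:
        H = np.asarray(haps)
        pos = np.arange(H.shape[1])

    if core_allele == "all":
        rows = np.arange(H.shape[0])
    else:
        if core_allele in ("ancestral", "derived"):
            if ancestral_is_b is None or np.isnan(ancestral_is_b):
                raise ValueError(f"ancestral state unknown at SNP {core}")
            anc = int(ancestral_is_b)
            target = anc if core_allele == "ancestral" else 1 - anc
        else:
            target = int(core_allele)
        rows = np.flatnonzero(H[:, core] == target)
    if len(rows) < 2:
        raise ValueError(
            f"fewer than 2 haplotypes carry core allele {core_allele!r} at SNP {core}"
        )
    sub = H[rows]
    stop_r = H.shape[1] if max_snps is None else min(H.shape[1], core + max_snps + 1)
    stop_l = -1 if max_snps is None else max(-1, core - max_snps - 1)
    idx_right = np.arange(core, stop_r)
    idx_left = np.arange(core, stop_l, -1)
    ehh_right = _ehh_decay(sub, idx_right, min_ehh)
    # the left decay re-refines from the core, prefixed by the core column
    ehh_left = _ehh_decay(sub, idx_left, min_ehh)
    idx_right = idx_right[: len(ehh_right)]
    idx_left = idx_left[: len(ehh_left)]
    return EHHProfile(
        core=core,
        core_allele=core_allele,
        n_carriers=len(rows),
        positions_bp=np.asarray(pos),
        idx_right=idx_right,
        ehh_right=ehh_right,
        idx_left=idx_left,
        ehh_left=ehh_left,
    )


def _direction_area(
    pos: np.ndarray, ehh: np.ndarray, cutoff: float, stop_bp: float | None = None
) -> tuple[float, bool]:
    """Trapezoidal area of one direction's decay.

    ``pos`` are bp positions outward from the core (first entry = core),
    monotone in either direction.  Integration stops at the interpolated
    EHH = cutoff crossing, at ``stop_bp`` if given, or at the edge
    (returning truncated=True).
    """
    if len(pos) < 2:
        return 0.0, True
    x = np.abs(pos.astype(float) - float(pos[0]))  # distance from core
    stop_x = None if stop_bp is None else abs(float(stop_bp) - float(pos[0]))
    area = 0.0
    for k in range(1, len(x)):
        x0, x1 = x[k - 1], x[k]
        y0, y1 = ehh[k - 1], ehh[k]
        if stop_x is not None and x1 >= stop_x:
            # linear interpolation of EHH at the stop boundary
            y_stop = y0 + (y1 - y0) * (stop_x - x0) / (x1 - x0) if x1 > x0 else y1
            area += (y0 + y_stop) / 2.0 * (stop_x - x0)
            return area, False
        if y1 < cutoff:
            # interpolate the cutoff crossing
            x_c = x0 + (x1 - x0) * (y0 - cutoff) / (y0 - y1) if y0 > y1 else x0
            area += (y0 + cutoff) / 2.0 * (x_c - x0)
            return area, False
        area += (y0 + y1) / 2.0 * (x1 - x0)
    return area, True


@dataclass
class IHHResult:
    area: float
    edge_truncated: bool


def integrate_ehh(profile: EHHProfile, cutoff: float = EHH_CUTOFF) -> IHHResult:
    """Integrated EHH (bp*EHH), summed over both directions.

    Each direction integrates outward until the first EHH < cutoff crossing
    (linearly interpolated); a direction that reaches the region edge above
    the cutoff truncates there and flags the record edge-truncated.
    """
    pos = profile.positions_bp
    a_r, t_r = _direction_area(pos[profile.idx_right], profile.ehh_right, cutoff)
    a_l, t_l = _direction_area(pos[profile.idx_left], profile.ehh_left, cutoff)
    return IHHResult(a_r + a_l, t_r or t_l)


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------


def unstandardized_ihs(ihh_a: float, ihh_d: float) -> float:
    """uiHS = ln(iHH_A / iHH_D); NaN if either area is non-positive."""
    if not (ihh_a > 0 and ihh_d > 0):
        return float("nan")
    return float(np.log(ihh_a / ihh_d))


def ihs_scan(
    haps: HaplotypeSet,
    maf_min: float = 0.10,
    cutoff: float = EHH_CUTOFF,
    drop_edge_truncated: bool = False,
) -> pd.DataFrame:
    """Per-SNP iHH_A, iHH_D, uiHS and derived allele frequency (one population).

    Scored SNPs are those with a known ancestral state, within-sample
    MAF >= ``maf_min``, and at least two carriers of each core allele.
    Edge-truncated integrals are flagged and retained unless
    ``drop_edge_truncated``.
    """
    anc_b = haps.snp_map.ancestral_is_b()
    p_b = haps.haps.mean(axis=0)
    n_snps = haps.n_snps
    out = {
        "snp_index": np.arange(n_snps),
        "pos_bp": haps.snp_map.pos_bp,
        "daf": np.full(n_snps, np.nan),
        "ihh_a": np.full(n_snps, np.nan),
        "ihh_d": np.full(n_snps, np.nan),
        "uihs": np.full(n_snps, np.nan),
        "edge_truncated": np.zeros(n_snps, dtype=bool),
    }
    for j in range(n_snps):
        if np.isnan(anc_b[j]):
            continue
        maf = min(p_b[j], 1 - p_b[j])
        if maf < maf_min:
            continue
        daf = 1 - p_b[j] if anc_b[j] == 1 else p_b[j]
        try:
            prof_a = ehh_profile(haps, j, "ancestral", min_ehh=cutoff)
            prof_d = ehh_profile(haps, j, "derived", min_ehh=cutoff)
        except ValueError:
            logger.debug("SNP %d skipped: <2 carriers of a core allele", j)
            continue
        ra = integrate_ehh(prof_a, cutoff)
        rd = integrate_ehh(prof_d, cutoff)
        truncated = ra.edge_truncated or rd.edge_truncated
        if truncated and drop_edge_truncated:
            continue
        out["daf"][j] = daf
        out["ihh_a"][j] = ra.area
        out["ihh_d"][j] = rd.area
        out["uihs"][j] = unstandardized_ihs(ra.area, rd.area)
        out["edge_truncated"][j] = truncated
    return pd.DataFrame(out)


@dataclass
class BinStats:
    """Per-frequency-bin moments used for iHS standardization."""

    df: pd.DataFrame  # bin_id, daf_lo, daf_hi, count, mean_uihs, sd_uihs


def standardize_ihs(
    records: pd.DataFrame,
    n_bins: int = IHS_BINS,
    x_flag: np.ndarray | None = None,
    daf_range: tuple[float, float] = (0.05, 0.95),
    binning: str = "equal_width",
) -> tuple[np.ndarray, BinStats]:
    """Standardize uiHS within derived-allele-frequency bins.

    ``records`` needs columns ``uihs`` and ``daf``.  Autosomal and
    X-flagged SNPs (boolean ``x_flag``) are binned and standardized in
    separate passes (the X has its own demographic history).  Bins with
    fewer than 2 scored SNPs or zero spread yield NaN for their members.

    Returns the per-SNP standardized iHS and the per-bin moments.
    """
    if binning not in ("equal_width", "equal_count"):
        raise ValueError("binning must be 'equal_width' or 'equal_count'")
    uihs = records["uihs"].to_numpy(dtype=float)
    daf = records["daf"].to_numpy(dtype=float)
    n = len(uihs)
    if x_flag is None:
        x_flag = np.zeros(n, dtype=bool)
    x_flag = np.asarray(x_flag, dtype=bool)
    ihs = np.full(n, np.nan)
    bin_rows = []
    lo, hi = daf_range
    for is_x in (False, True):
        sel = np.flatnonzero((x_flag == is_x) & ~np.isnan(uihs) & ~np.isnan(daf))
        if len(sel) == 0:
            continue
        d = np.clip(daf[sel], lo, hi)
        if binning == "equal_width":
            edges = np.linspace(lo, hi, n_bins + 1)
        else:
            edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
            edges[0], edges[-1] = lo, hi
        bin_id = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            members = sel[bin_id == b]
            if len(members) == 0:
                continue
            vals = uihs[members]
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
            if len(vals) < 2 or not sd > 0:
                logger.debug("bin %d (%s): %d SNPs, undefined SD", b, "X" if is_x else "A", len(vals))
                mean_out, sd_out = mean, np.nan
            else:
                ihs[members] = (vals - mean) / sd
                mean_out, sd_out = mean, sd
            bin_rows.append(
                {
                    "x": is_x,
                    "bin_id": b,
                    "daf_lo": edges[b],
                    "daf_hi": edges[b + 1],
                    "count": len(vals),
                    "mean_uihs": mean_out,
                    "sd_uihs": sd_out,
                }
            )
    return ihs, BinStats(pd.DataFrame(bin_rows))


def windowed_abs_ihs(
    ihs: np.ndarray, chroms: np.ndarray | None = None, window: int = IHS_WINDOW
) -> np.ndarray:
    """Sliding mean of |iHS| over ``window`` consecutive SNPs.

    The value is assigned to the window's center-right SNP (index
    ``start + window // 2``); NaN members are dropped from each mean and
    windows never span chromosomes.  A chromosome shorter than the window
    gets all NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.abs(np.asarray(ihs, dtype=float))
    n = len(v)
    if chroms is None:
        chroms = np.zeros(n, dtype=int)
    chroms = np.asarray(chroms)
    out = np.full(n, np.nan)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < window:
            continue
        vv = v[idx]
        for start in range(len(idx) - window + 1):
            w = vv[start : start + window]
            w = w[~np.isnan(w)]
            if len(w):
                out[idx[start + window // 2]] = w.mean()
    return out


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------


@dataclass
class XPEHHRecord:
    i_a: float
    i_b: float
    raw: float  # ln(I_A / I_B)
    edge_truncated: bool = False


def xpehh_raw(
    haps_a: HaplotypeSet | np.ndarray,
    haps_b: HaplotypeSet | np.ndarray,
    core: int,
    cutoff: float = EHH_CUTOFF,
) -> XPEHHRecord:
    """Raw XP-EHH at one SNP: ln of the ratio of integrated whole-sample EHH.

    Both populations' EHH (over all haplotypes) are integrated to the same
    boundary per direction — the interpolated point where the *pooled*
    two-population EHH first drops below the cutoff (or the region edge,
    flagged).  Returns NaN raw if either integral is zero.
    """
    Ha = haps_a.haps if isinstance(haps_a, HaplotypeSet) else np.asarray(haps_a)
    Hb = haps_b.haps if isinstance(haps_b, HaplotypeSet) else np.asarray(haps_b)
    if isinstance(haps_a, HaplotypeSet):
        pos = haps_a.snp_map.pos_bp
    else:
        pos = np.arange(Ha.shape[1])
    pooled = np.concatenate([Ha, Hb], axis=0)
    pos = np.asarray(pos)
    prof_p = ehh_profile(pooled, core, "all", min_ehh=cutoff)
    # follow each population's decay at least as far as the pooled stop
    extent = max(len(prof_p.idx_right), len(prof_p.idx_left))
    prof_a = ehh_profile(Ha, core, "all", max_snps=extent)
    prof_b = ehh_profile(Hb, core, "all", max_snps=extent)

    area_a = area_b = 0.0
    truncated = False
    for side in ("right", "left"):
        idx = getattr(prof_p, f"idx_{side}")
        p = pos[idx].astype(float)
        e_p = getattr(prof_p, f"ehh_{side}")
        # pooled stop point (bp) for this direction
        stop_bp = None
        cross = np.flatnonzero(e_p < cutoff)
        if len(cross):
            k = cross[0]
            if k == 0:
                stop_bp = p[0]
            else:
                x0, x1 = p[k - 1], p[k]
                y0, y1 = e_p[k - 1], e_p[k]
                frac = (y0 - cutoff) / (y0 - y1) if y0 > y1 else 0.0
                stop_bp = x0 + (x1 - x0) * frac
        else:
            truncated = True
        for prof, which in ((prof_a, "a"), (prof_b, "b")):
            pidx = getattr(prof, f"idx_{side}")
            area, _ = _direction_area(
                pos[pidx].astype(float), getattr(prof, f"ehh_{side}"), -np.inf, stop_bp
            )
            if which == "a":
                area_a += area
            else:
                area_b += area
    raw = (
        float(np.log(area_a / area_b))
        if area_a > 0 and area_b > 0
        else float("nan")
    )
    return XPEHHRecord(area_a, area_b, raw, truncated)


def xpehh_scan(
    haps_a: HaplotypeSet, haps_b: HaplotypeSet, cutoff: float = EHH_CUTOFF
) -> pd.DataFrame:
    """Raw XP-EHH at every SNP (population A vs population B)."""
    n = haps_a.n_snps
    rows = {
        "snp_index": np.arange(n),
        "pos_bp": haps_a.snp_map.pos_bp,
        "i_a": np.full(n, np.nan),
        "i_b": np.full(n, np.nan),
        "xpehh_raw": np.full(n, np.nan),
        "edge_truncated": np.zeros(n, dtype=bool),
    }
    for j in range(n):
        rec = xpehh_raw(haps_a, haps_b, j, cutoff)
        rows["i_a"][j] = rec.i_a
        rows["i_b"][j] = rec.i_b
        rows["xpehh_raw"][j] = rec.raw
        rows["edge_truncated"][j] = rec.edge_truncated
    return pd.DataFrame(rows)


def standardize_xpehh(raw: np.ndarray) -> np.ndarray:
    """z-score the raw XP-EHH values over all scored SNPs in the scan."""
    raw = np.asarray(raw, dtype=float)
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValueError("need >= 2 defined raw XP-EHH scores")
    sd = raw[ok].std(ddof=1)
    out = np.full(len(raw), np.nan)
    if not sd > 0:
        logger.warning("constant raw XP-EHH series; standardized scores undefined")
        return out
    out[ok] = (raw[ok] - raw[ok].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Pairwise r2
# ---------------------------------------------------------------------------


def pairwise_r2(haps: HaplotypeSet | np.ndarray, snp_i: int, snp_j: int) -> float:
    """LD r2 between two SNPs from phased haplotype counts (NaN if monomorphic)."""
    H = haps.haps if isinstance(haps, HaplotypeSet) else np.asarray(haps)
    a = H[:, snp_i].astype(float)
    b = H[:, snp_j].astype(float)
    p_i, p_j = a.mean(), b.mean()
    denom = p_i * (1 - p_i) * p_j * (1 - p_j)
    if denom == 0:
        return float("nan")
    d = (a * b).mean() - p_i * p_j
    return float(d * d / denom)


def r2_matrix(haps: HaplotypeSet, indices: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise r2 over the given SNP indices (all SNPs by default)."""
    H = haps.haps
    if indices is None:
        indices = np.arange(H.shape[1])
    indices = np.asarray(indices)
    ids = haps.snp_map.df["snp_id"].iloc[indices].to_numpy()
    m = np.full((len(indices), len(indices)), np.nan)
    for x, i in enumerate(indices):
        m[x, x] = 1.0 if len(np.unique(H[:, i])) > 1 else np.nan
        for y in range(x + 1, len(indices)):
            m[x, y] = m[y, x] = pairwise_r2(H, i, indices[y])
    return pd.DataFrame(m, index=ids, columns=ids)
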