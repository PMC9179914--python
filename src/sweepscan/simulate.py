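"""Synthetic two-breed SNP panels with truth labels.

The generator emulates the study design the scan statistics assume: two
breeds of diploid samples (default 45 each, 37 females / 8 males), SNPs at
roughly chip-like spacing, background allele-frequency differentiation at a
target FST produced by the Balding-Nichols drift model, ancestral-allele
truth labels, an optional implanted selective-sweep haplotype at high
frequency in one breed, and an X-chromosome mode that emits females only.

Background SNPs are in linkage equilibrium: haplotype alleles are drawn
independently per SNP from the breed frequencies.  Only the implanted sweep
creates linkage disequilibrium, which isolates the haplotype statistics'
signal and keeps the generator verifiable.  An exact fixture builder
(:func:`fixture_from_haplotype_table`) realizes a published-style
core-haplotype frequency table as a concrete haplotype population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, HaplotypeSet, SampleTable, SNPMap


@dataclass
class SweepSpec:
    """An implanted sweep: one fixed all-derived haplotype over a SNP span.

    ``carrier_freq`` is the fraction of the sweep breed's haplotypes
    replaced by the sweep haplotype; ``core_index`` marks the focal SNP and
    must lie within ``span`` (half-open SNP index range).
    """

    breed: str
    core_index: int
    span: tuple[int, int]
    carrier_freq: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq must be in [0, 1]")
        if not self.span[0] <= self.core_index < self.span[1]:
            raise ValueError("core_index must lie within span")


@dataclass
class SimulationConfig:
    """Two-breed simulation parameters.

    Defaults mirror the study design: 45 diploids per breed (37 F / 8 M),
    ~25 kb SNP spacing, background FST 0.024.
    """

    n_snps: int = 100
    n_per_breed: int = 45
    n_females: int = 37
    spacing_bp: int = 25_000
    spacing_jitter: float = 0.3  # uniform +/- fraction of spacing_bp
    background_fst: float = 0.024
    sweep: SweepSpec | None = None
    chrom_mode: str = "autosome"  # or "X"
    chrom: str | None = None
    breed_labels: tuple[str, str] = ("fat_tail", "thin_tail")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fst < 1.0:
            raise ValueError("background_fst must be in [0, 1)")
        if self.chrom_mode not in ("autosome", "X"):
            raise ValueError("chrom_mode must be 'autosome' or 'X'")
        if self.n_females > self.n_per_breed:
            raise ValueError("n_females cannot exceed n_per_breed")
        if self.sweep is not None and self.sweep.breed not in self.breed_labels:
            raise ValueError("sweep breed must be one of breed_labels")


@dataclass
class TruthLabels:
    """Generator ground truth: ancestral alleles and sweep carriers."""

    ancestral_is_b: np.ndarray  # bool per SNP: ancestral allele is allele_b
    sweep_carrier: np.ndarray  # bool per haplotype row
    sweep: SweepSpec | None = None

    def to_frame(self, snp_map: SNPMap) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": snp_map.df["snp_id"],
                "ancestral": snp_map.df["ancestral"],
                "in_sweep_span": [
                    self.sweep is not None and self.sweep.span[0] <= j < self.sweep.span[1]
                    for j in range(len(snp_map))
                ],
            }
        )


def drift_parameter_for_target_fst(target_fst: float) -> float:
    """Balding-Nichols drift parameter realizing a target measured FST.

    With only two populations the basic Wright index estimates total
    heterozygosity from the two populations' mean frequency, which
    underestimates the ancestral value, so its expectation over neutral SNPs
    is approximately ``F/2 / (1 - F/2)`` for drift parameter ``F``.  The
    generator therefore draws with ``F = 2 t / (1 + t)`` so that the mean
    per-SNP Wright FST across simulated neutral SNPs recovers the target
    ``t`` the user asked for (the scale on which scans quote background
    differentiation).
    """
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must be in [0, 1)")
    return 2.0 * target_fst / (1.0 + target_fst)


def sample_breed_frequencies(p_ancestral: float, fst: float, rng: np.random.Generator):
    """Draw two breed allele frequencies under the Balding-Nichols model.

    Each breed frequency is an independent draw from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``;
    ``fst = 0`` returns ``(p, p)`` exactly and boundary ``p`` returns the
    fixed frequencies unchanged.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if p_ancestral <= 0.0 or p_ancestral >= 1.0:
        return p_ancestral, p_ancestral
    if fst == 0.0:
        return p_ancestral, p_ancestral
    a = p_ancestral * (1.0 - fst) / fst
    b = (1.0 - p_ancestral) * (1.0 - fst) / fst
    return float(rng.beta(a, b)), float(rng.beta(a, b))


def _build_samples(cfg: SimulationConfig) -> SampleTable:
    rows = []
    for breed in cfg.breed_labels:
        for i in range(cfg.n_per_breed):
            sex = "F" if i < cfg.n_females else "M"
            rows.append({"id": f"{breed}_{i:03d}", "breed": breed, "sex": sex})
    return SampleTable(pd.DataFrame(rows))


def _build_map(cfg: SimulationConfig, rng: np.random.Generator, ancestral_is_b: np.ndarray) -> SNPMap:
    chrom = cfg.chrom or ("X" if cfg.chrom_mode == "X" else "1")
    jitter = rng.integers(
        -int(cfg.spacing_bp * cfg.spacing_jitter),
        int(cfg.spacing_bp * cfg.spacing_jitter) + 1,
        size=cfg.n_snps,
    )
    pos = cfg.spacing_bp * np.arange(1, cfg.n_snps + 1, dtype=np.int64) + jitter
    # enforce strictly increasing positive positions
    pos = np.maximum.accumulate(pos) + np.arange(cfg.n_snps)
    pos += max(0, 1 - int(pos[0]))
    alleles = np.array(list("ACGT"))
    ia = rng.integers(0, 4, size=cfg.n_snps)
    ib = (ia + rng.integers(1, 4, size=cfg.n_snps)) % 4
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(cfg.n_snps)],
            "chrom": chrom,
            "pos_bp": pos,
            "allele_a": alleles[ia],
            "allele_b": alleles[ib],
        }
    )
    df["ancestral"] = np.where(ancestral_is_b, df["allele_b"], df["allele_a"])
    return SNPMap(df)


def simulate_two_breed_dataset(cfg: SimulationConfig):
    """Simulate a phased two-breed dataset.

    Ancestral frequencies are drawn uniformly on (0.1, 0.9); breed
    frequencies drift from them under Balding-Nichols at
    ``cfg.background_fst``; haplotype alleles are independent across SNPs.
    The ancestral allele of each SNP is the major allele of its ancestral
    frequency draw, so derived alleles start rare.  In X mode only females
    are emitted.

    Returns
    -------
    (HaplotypeSet, GenotypeMatrix, SNPMap, SampleTable, TruthLabels)
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _build_samples(cfg)
    if cfg.chrom_mode == "X":
        keep = np.flatnonzero(samples.df["sex"].to_numpy() == "F")
        samples = samples.subset(keep)

    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    f_drift = drift_parameter_for_target_fst(cfg.background_fst)
    p_breed = np.empty((2, cfg.n_snps))
    for j in range(cfg.n_snps):
        p_breed[0, j], p_breed[1, j] = sample_breed_frequencies(
            p_anc[j], f_drift, rng
        )
    # ancestral allele = major allele of the ancestral draw; p_anc is the
    # frequency of allele_b, so ancestral is allele_b iff p_anc > 0.5
    ancestral_is_b = p_anc > 0.5

    snp_map = _build_map(cfg, rng, ancestral_is_b)
    n_hap = 2 * len(samples)
    haps = np.empty((n_hap, cfg.n_snps), dtype=np.int8)
    breed_of_sample = samples.breeds
    for b, breed in enumerate(cfg.breed_labels):
        srows = np.flatnonzero(breed_of_sample == breed)
        hrows = np.sort(np.concatenate([2 * srows, 2 * srows + 1]))
        u = rng.random((len(hrows), cfg.n_snps))
        haps[hrows] = (u < p_breed[b]).astype(np.int8)

    labels = TruthLabels(ancestral_is_b, np.zeros(n_hap, dtype=bool), None)
    hap_set = HaplotypeSet(haps, snp_map, samples)
    if cfg.sweep is not None:
        hap_set, labels = implant_sweep(hap_set, labels, cfg.sweep, rng)
    return hap_set, hap_set.to_genotypes(), snp_map, samples, labels


def implant_sweep(
    haps: HaplotypeSet, labels: TruthLabels, sweep: SweepSpec, rng: np.random.Generator
):
    """Replace a fraction of one breed's haplotypes by a fixed sweep haplotype.

    Over ``sweep.span`` the chosen carriers all receive the same haplotype,
    composed of the derived allele at every span SNP; non-carriers and the
    other breed are untouched.  The carrier count is ``round(carrier_freq *
    n_haplotypes)`` (half-up); a count of zero is an error.
    """
    lo, hi = sweep.span
    if lo < 0 or hi > haps.n_snps:
        raise ValueError("sweep span outside SNP range")
    hrows = haps.breed_hap_rows(sweep.breed)
    n_carriers = int(np.floor(sweep.carrier_freq * len(hrows) + 0.5))
    if n_carriers == 0:
        raise ValueError("carrier_freq rounds to zero carriers; no sweep implanted")
    carriers = rng.choice(hrows, size=n_carriers, replace=False)
    derived_is_b = ~labels.ancestral_is_b[lo:hi]
    sweep_hap = derived_is_b.astype(np.int8)
    new = haps.haps.copy()
    new[np.ix_(carriers, np.arange(lo, hi))] = sweep_hap
    carrier_mask = labels.sweep_carrier.copy()
    carrier_mask[carriers] = True
    return (
        HaplotypeSet(new, haps.snp_map, haps.samples),
        TruthLabels(labels.ancestral_is_b, carrier_mask, sweep),
    )


def _largest_remainder_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    """Integer counts ~ round(freq*n), corrected to sum exactly to n."""
    raw = freqs * n
    counts = np.floor(raw + 0.5).astype(int)
    diff = n - counts.sum()
    if diff != 0:
        # adjust the entries whose rounding moved them furthest in the
        # direction that compensates the deficit/excess
        resid = raw - counts
        order = np.argsort(-resid) if diff > 0 else np.argsort(resid)
        for k in range(abs(diff)):
            counts[order[k % len(counts)]] += 1 if diff > 0 else -1
    if (counts < 0).any():
        raise ValueError("frequency column produced a negative count")
    return counts


def expand_dash_haplotypes(hap_strings: list[list[str]]) -> list[list[str]]:
    """Expand dash-coded haplotype rows against the first haplotype.

    In published core-haplotype tables a dash means "same nucleotide as
    haplotype 1 at this position".
    """
    if not hap_strings:
        return []
    ref = hap_strings[0]
    if any(a == "-" for a in ref):
        raise ValueError("haplotype 1 may not contain dashes")
    return [[r if a == "-" else a for a, r in zip(row, ref)] for row in hap_strings]


def fixture_from_haplotype_table(
    core_alleles: list[tuple[str, str]],
    positions_bp: list[int],
    ancestral_row: list[str],
    hap_strings: list[list[str]],
    freq_columns: dict[str, list[float]],
    n_haplotypes_per_breed: dict[str, int],
    chrom: str = "1",
    freq_tol: float = 0.02,
) -> HaplotypeSet:
    """Build an exact haplotype population realizing a frequency table.

    Parameters
    ----------
    core_alleles
        Per-SNP ``(allele_a, allele_b)`` pairs.
    positions_bp, ancestral_row
        SNP positions and the ancestral allele per SNP ("?" for unknown).
    hap_strings
        Haplotype rows as allele characters; dashes are expanded against
        haplotype 1.
    freq_columns
        Per-breed frequency per haplotype row (column sums must be within
        ``freq_tol`` of 1; published columns round to 2 decimals).
    n_haplotypes_per_breed
        Haplotypes (not diploids) to emit per breed; counts are
        ``round(freq * n)`` with a largest-remainder correction so each
        breed totals exactly ``n``.  Odd totals get one pad haplotype
        duplicated so rows pair into diploids.
    """
    hap_strings = expand_dash_haplotypes(hap_strings)
    n_snps = len(core_alleles)
    for row in hap_strings:
        if len(row) != n_snps:
            raise ValueError("haplotype row length mismatch")
    map_df = pd.DataFrame(
        {
            "snp_id": [f"core{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos_bp": positions_bp,
            "allele_a": [a for a, _ in core_alleles],
            "allele_b": [b for _, b in core_alleles],
            "ancestral": [a if a != "?" else None for a in ancestral_row],
        }
    )
    snp_map = SNPMap(map_df)

    def encode(row: list[str]) -> np.ndarray:
        out = np.empty(n_snps, dtype=np.int8)
        for j, a in enumerate(row):
            pa, pb = core_alleles[j]
            if a == pa:
                out[j] = 0
            elif a == pb:
                out[j] = 1
            else:
                raise ValueError(f"allele {a!r} not among {pa}/{pb} at SNP {j}")
        return out

    encoded = [encode(row) for row in hap_strings]
    all_rows = []
    sample_rows = []
    for breed, freqs in freq_columns.items():
        freqs = np.asarray([0.0 if f is None else f for f in freqs], dtype=float)
        if len(freqs) != len(encoded):
            raise ValueError("frequency column length mismatch")
        total = freqs.sum()
        if abs(total - 1.0) > freq_tol + 1e-9:
            raise ValueError(
                f"frequency column for {breed} sums to {total:.3f}, outside tolerance"
            )
        n = n_haplotypes_per_breed[breed]
        # counts from the raw printed frequencies (rounding columns already
        # sum close to 1); largest-remainder correction reconciles to n
        counts = _largest_remainder_counts(freqs, n)
        breed_rows = []
        for hap, c in zip(encoded, counts):
            breed_rows.extend([hap] * int(c))
        if len(breed_rows) % 2:  # pad to an even row count for diploid pairing
            breed_rows.append(breed_rows[-1].copy())
        all_rows.extend(breed_rows)
        for i in range(len(breed_rows) // 2):
            sample_rows.append(
                {"id": f"{breed}_fix{i:03d}", "breed": breed, "sex": "F"}
            )
    haps = np.stack(all_rows)
    return HaplotypeSet(haps, snp_map, SampleTable(pd.DataFrame(sample_rows)))
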