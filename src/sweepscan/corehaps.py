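"""Core-region haplotype analysis and ancestral-allele inference.

A core region is a short set of contiguous SNPs at a selection peak.  Over
it, each breed carries a set of distinct allele strings (core haplotypes)
whose frequencies, together with per-position ancestral/derived status,
summarize whether selection in a breed acted on old standing variation or
on new (derived) mutations.

Ancestral states for SNPs without database annotation are inferred from a
user-supplied cross-species allele table: if exactly one of the SNP's two
alleles is observed across the outgroup species it is taken as ancestral;
otherwise a rank-weighted majority vote is taken in which species closer to
the focal lineage outvote more distant ones (an exact tie yields unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenomicInterval, HaplotypeSet, SampleTable, SNPMap

logger = logging.getLogger(__name__)


@dataclass
class CoreRegion:
    """Contiguous core SNPs on one chromosome plus their genomic span."""

    chrom: str
    snp_indices: np.ndarray
    span: GenomicInterval

    def __len__(self) -> int:
        return len(self.snp_indices)


def define_core_region(snp_indices, snp_map: SNPMap) -> CoreRegion:
    """Build a core region from member SNP indices (>=2, one chromosome)."""
    idx = np.sort(np.asarray(snp_indices))
    if len(idx) < 2:
        raise ValueError("a core region needs >= 2 SNPs")
    chroms = set(snp_map.chrom[idx])
    if len(chroms) != 1:
        raise ValueError(f"core SNPs span multiple chromosomes: {sorted(chroms)}")
    pos = snp_map.pos_bp[idx]
    chrom = chroms.pop()
    return CoreRegion(chrom, idx, GenomicInterval(chrom, int(pos.min()), int(pos.max())))


@dataclass
class CoreHaplotypeTable:
    """Distinct core haplotypes with per-breed counts/frequencies.

    ``df`` rows are sorted by descending pooled frequency (ties by allele
    string); the per-position derived flags compare against the ancestral
    row (None where the ancestral state is unknown).
    """

    df: pd.DataFrame  # haplotype, count_<breed>, freq_<breed>..., n_derived, n_ancestral, n_unknown
    ancestral_row: list[str | None]
    breed_totals: dict[str, int]

    def display(self, dash_compress: bool = False, freq_decimals: int = 2) -> pd.DataFrame:
        """Rounded, optionally dash-compressed view (dash = same as row 1)."""
        out = self.df.copy()
        for c in out.columns:
            if c.startswith("freq_"):
                out[c] = out[c].round(freq_decimals)
        if dash_compress and len(out):
            ref = out["haplotype"].iloc[0]
            out["haplotype"] = [
                "".join("-" if (i > 0 and a == r) else a for a, r in zip(h, ref))
                for i, h in enumerate(out["haplotype"])
            ]
        return out


def enumerate_core_haplotypes(
    haps: HaplotypeSet,
    samples: SampleTable | None = None,
    core: CoreRegion | None = None,
) -> CoreHaplotypeTable:
    """Count distinct haplotype allele strings over the core SNPs per breed.

    Frequencies are counts over 2 x (breed diploids); rows sort by
    descending pooled frequency, ties lexicographically.
    """
    samples = samples or haps.samples
    idx = core.snp_indices if core is not None else np.arange(haps.n_snps)
    sub = haps.haps[:, idx]
    map_sub = haps.snp_map.df.iloc[idx]
    allele_chars = np.stack(
        [map_sub["allele_a"].to_numpy(), map_sub["allele_b"].to_numpy()]
    )
    strings = [
        "".join(allele_chars[sub[r, k], k] for k in range(sub.shape[1]))
        for r in range(sub.shape[0])
    ]
    breed_of_hap = np.repeat(samples.breeds, 2)
    breeds = samples.breed_labels()
    counts: dict[str, dict[str, int]] = {}
    for s, b in zip(strings, breed_of_hap):
        counts.setdefault(s, {br: 0 for br in breeds})[b] += 1
    totals = {b: int((breed_of_hap == b).sum()) for b in breeds}

    anc_row = [a if pd.notna(a) else None for a in map_sub["ancestral"]]
    rows = []
    for s, per_breed in counts.items():
        rec = {"haplotype": s}
        for b in breeds:
            rec[f"count_{b}"] = per_breed[b]
            rec[f"freq_{b}"] = per_breed[b] / totals[b] if totals[b] else np.nan
        nd, na, nu = classify_alleles(s, anc_row)
        rec.update(n_derived=nd, n_ancestral=na, n_unknown=nu)
        rec["_pooled"] = sum(per_breed.values()) / sum(totals.values())
        rows.append(rec)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["_pooled", "haplotype"], ascending=[False, True], kind="stable"
    ).drop(columns="_pooled").reset_index(drop=True)
    return CoreHaplotypeTable(df, anc_row, totals)


def classify_alleles(haplotype: str, ancestral_row) -> tuple[int, int, int]:
    """Per-position comparison to the ancestral row.

    Returns (n_derived, n_ancestral, n_unknown); positions whose ancestral
    state is unknown (None/"?") count as unknown.
    """
    if len(haplotype) != len(ancestral_row):
        raise ValueError("haplotype and ancestral row lengths differ")
    nd = na = nu = 0
    for a, anc in zip(haplotype, ancestral_row):
        if anc is None or anc == "?":
            nu += 1
        elif a == anc:
            na += 1
        else:
            nd += 1
    return nd, na, nu


@dataclass
class SpeciesAlleleTable:
    """Outgroup alleles per SNP plus a species divergence ranking.

    ``ranks`` lists species from closest to most distant from the focal
    lineage; ``observations`` maps snp_id -> {species: allele}.
    """

    ranks: list[str]
    observations: dict[str, dict[str, str]]

    def rank_weight(self, species: str) -> float:
        # closer species get larger weight (inverse rank)
        return 1.0 / (self.ranks.index(species) + 1)


def infer_ancestral_allele(
    snp_id: str, allele_a: str, allele_b: str, table: SpeciesAlleleTable
) -> str | None:
    """Infer the ancestral allele of one SNP from outgroup observations.

    Rule 1: if exactly one of the SNP's alleles appears across the
    outgroups, that allele is ancestral.  Rule 2: otherwise a majority vote
    weighted by inverse divergence rank decides (closer species outvote
    more distant ones).  An exact tie, or no usable observation, returns
    None (unknown).  Observations matching neither SNP allele are ignored
    with a log message.
    """
    obs = table.observations.get(snp_id, {})
    votes: dict[str, float] = {allele_a: 0.0, allele_b: 0.0}
    seen: set[str] = set()
    for species, allele in obs.items():
        if allele is None:
            continue
        if allele not in (allele_a, allele_b):
            logger.warning(
                "SNP %s: outgroup %s allele %r matches neither %s nor %s; ignored",
                snp_id, species, allele, allele_a, allele_b,
            )
            continue
        seen.add(allele)
        votes[allele] += table.rank_weight(species)
    if not seen:
        return None
    if len(seen) == 1:
        return next(iter(seen))
    if votes[allele_a] == votes[allele_b]:
        return None
    return allele_a if votes[allele_a] > votes[allele_b] else allele_b


def annotate_ancestral(snp_map: SNPMap, table: SpeciesAlleleTable) -> SNPMap:
    """Fill unknown ancestral states in a SNP map from a species table."""
    df = snp_map.df.copy()
    for j in range(len(df)):
        if pd.isna(df.at[j, "ancestral"]) or not df.at[j, "ancestral"]:
            df.at[j, "ancestral"] = infer_ancestral_allele(
                df.at[j, "snp_id"], df.at[j, "allele_a"], df.at[j, "allele_b"], table
            )
    return SNPMap(df)


def pool_rare_haplotypes(table: CoreHaplotypeTable, breed: str, floor: float = 0.02):
    """Display helper: split a breed's rows into frequent rows and a pooled
    remainder (haplotypes below ``floor`` frequency), as published tables do.

    Returns (frequent_df, n_pooled, pooled_freq).
    """
    df = table.df
    freq = df[f"freq_{breed}"]
    keep = df[freq >= floor]
    rest = df[(freq > 0) & (freq < floor)]
    return keep.reset_index(drop=True), len(rest), float(rest[f"freq_{breed}"].sum())
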