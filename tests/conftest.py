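"""Shared fixtures: published core-haplotype table data for a two-breed
fat-tail vs thin-tail sheep panel, and small simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.data import SampleTable, SNPMap, GenotypeMatrix
from sweepscan.simulate import (
    SimulationConfig,
    SweepSpec,
    simulate_two_breed_dataset,
)

FAT, THIN = "fat_tail", "thin_tail"

# Core-haplotype frequency tables from the fine-mapped sheep candidate
# regions (chromosomes 5, 7 and X).  Dash = same allele as haplotype 1;
# None = haplotype absent in that breed.  Frequencies are the published
# 2-decimal values.
CORE_TABLES = {
    "chr5": {
        "chrom": "5",
        "alleles": [("C", "T"), ("A", "G"), ("T", "C"), ("A", "G"), ("A", "C")],
        "positions": [47_149_354, 47_149_400, 47_165_900, 47_171_110, 47_175_489],
        "ancestral": ["T", "G", "T", "G", "C"],
        "haplotypes": [
            list("CACAA"),
            ["-", "G", "-", "-", "-"],
            ["-", "G", "T", "-", "-"],
            ["-", "G", "-", "G", "C"],
            ["T", "G", "-", "-", "-"],
            ["T", "-", "T", "-", "-"],
            ["T", "G", "T", "-", "-"],
            ["T", "G", "T", "G", "C"],
        ],
        "freq": {
            FAT: [0.90, 0.01, 0.01, None, None, 0.01, 0.04, 0.02],
            THIN: [0.15, 0.06, None, 0.12, 0.13, None, 0.11, 0.31],
        },
    },
    "chr7": {
        "chrom": "7",
        "alleles": [("C", "T"), ("A", "C"), ("T", "C"), ("A", "C")],
        "positions": [46_604_500, 46_604_644, 46_604_722, 46_642_359],
        "ancestral": ["C", "C", "C", "A"],
        "haplotypes": [
            list("CCCC"),
            ["-", "-", "-", "A"],
            ["T", "A", "-", "-"],
            ["T", "A", "-", "A"],
            ["T", "A", "T", "-"],
            ["T", "A", "T", "A"],
        ],
        "freq": {
            FAT: [0.06, 0.20, 0.02, 0.14, 0.31, 0.27],
            THIN: [0.80, 0.14, 0.03, None, 0.02, None],
        },
    },
    "chrX": {
        "chrom": "X",
        "alleles": [("A", "G"), ("C", "T"), ("T", "C"), ("T", "A"), ("G", "C"), ("G", "A")],
        "positions": [59_742_181, 59_750_338, 59_912_586, 59_971_891, 59_971_909, 59_984_949],
        "ancestral": ["A", "T", "T", "T", "C", "A"],
        "haplotypes": [
            list("GCTTGG"),
            ["-", "-", "C", "-", "C", "A"],
            ["-", "-", "C", "A", "C", "A"],
            ["A", "T", "-", "A", "C", "A"],
            ["A", "T", "C", "-", "-", "-"],
            ["A", "T", "C", "-", "C", "A"],
            ["A", "T", "C", "A", "C", "A"],
        ],
        "freq": {
            FAT: [0.89, None, None, None, 0.11, None, None],
            THIN: [0.12, 0.01, 0.18, 0.04, 0.08, 0.01, 0.54],
        },
    },
}

# fine-mapped candidate regions (chrom, start_bp, end_bp, printed length)
FINE_MAP_REGIONS = [
    ("5", 46_971_979, 47_919_440, 947_461),
    ("7", 46_392_398, 46_852_870, 460_472),
    ("X", 58_424_602, 61_409_447, 2_984_845),
]

# refined candidate intervals quoted by their bounding SNP coordinates
REFINED_CHRX = ("X", 59_257_971, 60_264_325, 1006)
BROAD_CHRX = ("X", 58_621_412, 61_452_816, 2831)


@pytest.fixture(scope="session")
def core_tables():
    return CORE_TABLES


def make_snp_map(n=5, chrom="1", spacing=1000, start=1000):
    pos = start + spacing * np.arange(n)
    df = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n)],
            "chrom": chrom,
            "pos_bp": pos,
            "allele_a": "A",
            "allele_b": "G",
            "ancestral": "A",
        }
    )
    return SNPMap(df)


def make_samples(n, breed="b1", sex="F", prefix="s"):
    return SampleTable(
        pd.DataFrame(
            {"id": [f"{prefix}{i}" for i in range(n)], "breed": breed, "sex": sex}
        )
    )


def make_two_breed_samples(n_per_breed, breeds=(FAT, THIN)):
    frames = [make_samples(n_per_breed, b, prefix=f"{b}_").df for b in breeds]
    return SampleTable(pd.concat(frames, ignore_index=True))


def genotypes_from_codes(codes, samples=None, snp_map=None, **mapkw):
    codes = np.asarray(codes)
    snp_map = snp_map or make_snp_map(codes.shape[1], **mapkw)
    samples = samples or make_samples(codes.shape[0])
    return GenotypeMatrix(codes, snp_map, samples)


@pytest.fixture(scope="session")
def sweep_dataset():
    """60-SNP two-breed dataset with a 0.9-frequency sweep in the fat-tail
    breed over SNPs 25..35 (core 30)."""
    cfg = SimulationConfig(
        n_snps=60, seed=11, sweep=SweepSpec(FAT, 30, (25, 36), 0.9)
    )
    haps, g, snp_map, samples, labels = simulate_two_breed_dataset(cfg)
    return {"cfg": cfg, "haps": haps, "g": g, "map": snp_map,
            "samples": samples, "labels": labels}


@pytest.fixture(scope="session")
def neutral_dataset():
    cfg = SimulationConfig(n_snps=120, seed=5)
    haps, g, snp_map, samples, labels = simulate_two_breed_dataset(cfg)
    return {"cfg": cfg, "haps": haps, "g": g, "map": snp_map,
            "samples": samples, "labels": labels}
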