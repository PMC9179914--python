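"""Domain containers and readers/writers for standard genotype formats.

Conventions
-----------
* Coordinates are 1-based inclusive internally; BED output converts to
  0-based half-open.  Interval length is ``end_bp - start_bp`` and kb
  lengths are truncated (floor), matching the convention of quoting SNP
  coordinates as interval bounds.
* Genotype codes count copies of ``allele_b`` (the ALT allele in VCF, the
  second-listed allele in PED/MAP); missing is coded ``-1``.
* Haplotype values are binary: 0 = ``allele_a``, 1 = ``allele_b``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SEX_CODES = ("F", "M", "U")


class FormatError(ValueError):
    """A file does not parse under the named standard."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SNPMap:
    """Per-SNP map: chromosome, 1-based position, alleles, ancestral state.

    ``ancestral`` holds the ancestral allele character where known and
    ``None`` where unknown.
    """

    df: pd.DataFrame  # columns: snp_id, chrom, pos_bp, allele_a, allele_b, ancestral

    REQUIRED = ("snp_id", "chrom", "pos_bp", "allele_a", "allele_b", "ancestral")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"SNPMap missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if (df["allele_a"] == df["allele_b"]).any():
            raise ValueError("allele_a == allele_b at some SNP")
        bad = df["ancestral"].notna() & ~(
            (df["ancestral"] == df["allele_a"]) | (df["ancestral"] == df["allele_b"])
        )
        if bad.any():
            raise ValueError("ancestral allele not among the SNP's alleles")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    def subset(self, idx) -> "SNPMap":
        return SNPMap(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    def ancestral_is_b(self) -> np.ndarray:
        """Per SNP: True if ancestral == allele_b, False if allele_a, NaN unknown."""
        out = np.full(len(self), np.nan)
        known = self.df["ancestral"].notna().to_numpy()
        out[known] = (
            self.df.loc[known, "ancestral"] == self.df.loc[known, "allele_b"]
        ).to_numpy()
        return out


@dataclass
class SampleTable:
    """Sample metadata: unique id, breed label, sex (F/M/U)."""

    df: pd.DataFrame  # columns: id, breed, sex

    def __post_init__(self) -> None:
        for c in ("id", "breed", "sex"):
            if c not in self.df.columns:
                raise ValueError(f"SampleTable missing column {c}")
        self.df = self.df.reset_index(drop=True)
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup}")
        bad_sex = ~self.df["sex"].isin(SEX_CODES)
        if bad_sex.any():
            raise ValueError("sex must be one of F, M, U")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    @property
    def breeds(self) -> np.ndarray:
        return self.df["breed"].to_numpy()

    def breed_labels(self) -> list[str]:
        return sorted(self.df["breed"].unique().tolist())

    def subset(self, idx) -> "SampleTable":
        return SampleTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    def require_two_breeds(self) -> tuple[str, str]:
        labels = self.breed_labels()
        if len(labels) != 2:
            raise ValueError(f"expected exactly two breeds, found {labels}")
        return labels[0], labels[1]


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes, n_samples x n_snps, counting allele_b copies.

    Codes are in {0, 1, 2, MISSING}.
    """

    codes: np.ndarray
    snp_map: SNPMap
    samples: SampleTable

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n_s, n_m = self.codes.shape
        if n_s != len(self.samples) or n_m != len(self.snp_map):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_map)} SNPs"
            )
        ok = np.isin(self.codes, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.codes[idx], self.snp_map, self.samples.subset(idx))

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.codes[:, idx], self.snp_map.subset(idx), self.samples)

    def breed_rows(self, breed: str) -> np.ndarray:
        return np.flatnonzero(self.samples.breeds == breed)

    def allele_b_freq(self, rows=None) -> np.ndarray:
        """Per-SNP allele_b frequency over non-missing calls (NaN if none)."""
        codes = self.codes if rows is None else self.codes[np.asarray(rows)]
        obs = codes != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(obs, codes, 0).sum(axis=0) / n_alleles
        return np.where(n_alleles > 0, freq, np.nan)


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes: rows 2k and 2k+1 belong to sample k."""

    haps: np.ndarray  # (2*n_samples, n_snps) of {0,1}
    snp_map: SNPMap
    samples: SampleTable

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.ndim != 2 or self.haps.shape[0] % 2:
            raise ValueError("haplotype array must be 2D with an even row count")
        if self.haps.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype rows must be 2 x n_samples")
        if self.haps.shape[1] != len(self.snp_map):
            raise ValueError("haplotype columns must match SNP map")
        if not np.isin(self.haps, (0, 1)).all():
            raise ValueError("haplotypes must be binary with no missing values")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        codes = self.haps[0::2] + self.haps[1::2]
        return GenotypeMatrix(codes, self.snp_map, self.samples)

    def breed_hap_rows(self, breed: str) -> np.ndarray:
        srows = np.flatnonzero(self.samples.breeds == breed)
        return np.sort(np.concatenate([2 * srows, 2 * srows + 1]))

    def subset_breed(self, breed: str) -> "HaplotypeSet":
        srows = np.flatnonzero(self.samples.breeds == breed)
        hrows = np.empty(2 * len(srows), dtype=int)
        hrows[0::2] = 2 * srows
        hrows[1::2] = 2 * srows + 1
        return HaplotypeSet(self.haps[hrows], self.snp_map, self.samples.subset(srows))

    def subset_samples(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        hrows = np.empty(2 * len(idx), dtype=int)
        hrows[0::2] = 2 * idx
        hrows[1::2] = 2 * idx + 1
        return HaplotypeSet(self.haps[hrows], self.snp_map, self.samples.subset(idx))

    def subset_snps(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(self.haps[:, idx], self.snp_map.subset(idx), self.samples)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval.

    Length is defined as ``end_bp - start_bp`` (the arithmetic used when an
    interval is quoted by its bounding SNP coordinates) and ``length_kb``
    truncates to whole kb.
    """

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.start_bp < 1:
            raise ValueError("coordinates are 1-based")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_kb(self) -> int:
        return math.floor(self.length_bp / 1000)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and (
            self.start_bp <= other.end_bp and other.start_bp <= self.end_bp
        )


@dataclass
class ConcordanceReport:
    """Allelic concordance between two genotype sources on shared calls."""

    n_overlapping_snps: int
    per_snp: pd.DataFrame  # columns: snp_id, chrom, pos_bp, n_pairs, concordance
    mean_concordance: float

    def __post_init__(self) -> None:
        conc = self.per_snp["concordance"].dropna()
        if len(conc) and ((conc < 0).any() or (conc > 1).any()):
            raise ValueError("concordance fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_sample_sidecar(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"id", "breed", "sex"}
    if not need.issubset(df.columns):
        raise FormatError(f"sample sidecar must have columns {sorted(need)}")
    df["sex"] = df["sex"].fillna("U")
    return df[["id", "breed", "sex"]]


def _attach_metadata(ids: list[str], samples_tsv) -> SampleTable:
    if samples_tsv is None:
        df = pd.DataFrame({"id": ids, "breed": "unknown", "sex": "U"})
    else:
        meta = _read_sample_sidecar(samples_tsv).set_index("id")
        missing = [i for i in ids if i not in meta.index]
        if missing:
            raise ValueError(f"samples absent from sidecar: {missing[:5]}")
        meta = meta.loc[ids].reset_index()
        df = meta[["id", "breed", "sex"]]
    return SampleTable(df)


def _parse_vcf(path, multiallelic: str, phased_required: bool):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows = []
    codes_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    phased_ok = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if multiallelic == "drop":
                logger.warning(
                    "dropping non-biallelic-SNP record %s:%s", var.CHROM, var.POS
                )
                continue
            raise FormatError(
                f"non-biallelic or non-SNP record at {var.CHROM}:{var.POS}"
            )
        gts = var.genotypes  # list of [a0, a1, phased]
        col = np.empty(len(ids), dtype=np.int8)
        hap = np.zeros((2, len(ids)), dtype=np.int8)
        for k, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                col[k] = MISSING
                phased_ok = False
            else:
                col[k] = a0 + a1
                hap[0, k], hap[1, k] = a0, a1
                if not g[2]:
                    phased_ok = phased_ok and (a0 == a1)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos_bp": int(var.POS),
                "allele_a": var.REF,
                "allele_b": var.ALT[0],
                "ancestral": _ancestral_from_info(var),
            }
        )
        codes_cols.append(col)
        hap_cols.append(hap)
    if not rows:
        raise FormatError(f"no usable records in {path}")
    if phased_required and not phased_ok:
        raise FormatError("VCF is not fully phased / has missing genotypes")
    return ids, rows, codes_cols, hap_cols


def _ancestral_from_info(var):
    aa = var.INFO.get("AA")
    if aa is None:
        return None
    aa = str(aa).upper()
    return aa if aa in (var.REF, var.ALT[0]) else None


def read_genotypes(path, format: str = "vcf", samples_tsv=None, multiallelic: str = "error"):
    """Read diploid genotypes from VCF or PLINK PED/MAP.

    Parameters
    ----------
    path
        VCF file path, or the PED path (its ``.map`` sidecar is inferred by
        extension) for ``format="ped_map"``.
    samples_tsv
        Optional TSV with columns id, breed, sex; required when the format
        carries no breed labels (both supported formats).
    multiallelic
        ``"error"`` (default) rejects non-biallelic/non-SNP records;
        ``"drop"`` drops them with a logged warning.

    Returns
    -------
    (GenotypeMatrix, SNPMap, SampleTable)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        ids, rows, codes_cols, _ = _parse_vcf(path, multiallelic, phased_required=False)
        snp_map, order = _sorted_map(rows)
        codes = np.stack([codes_cols[i] for i in order], axis=1)
        samples = _attach_metadata(ids, samples_tsv)
        return GenotypeMatrix(codes, snp_map, samples), snp_map, samples
    if format == "ped_map":
        return _read_ped_map(path, samples_tsv)
    raise ValueError(f"unknown format {format!r}")


def read_phased_vcf(path, samples_tsv=None, multiallelic: str = "error"):
    """Read a fully phased VCF into a :class:`HaplotypeSet` (plus genotypes)."""
    ids, rows, codes_cols, hap_cols = _parse_vcf(
        Path(path), multiallelic, phased_required=True
    )
    snp_map, order = _sorted_map(rows)
    codes = np.stack([codes_cols[i] for i in order], axis=1)
    samples = _attach_metadata(ids, samples_tsv)
    n = len(ids)
    haps = np.empty((2 * n, len(order)), dtype=np.int8)
    for j, i in enumerate(order):
        haps[0::2, j] = hap_cols[i][0]
        haps[1::2, j] = hap_cols[i][1]
    hap_set = HaplotypeSet(haps, snp_map, samples)
    return hap_set, GenotypeMatrix(codes, snp_map, samples), snp_map, samples


def _sorted_map(rows: list[dict]):
    df = pd.DataFrame(rows)
    order = np.lexsort((df["pos_bp"].to_numpy(), df["chrom"].to_numpy()))
    return SNPMap(df.iloc[order].reset_index(drop=True)), list(order)


def _read_ped_map(ped_path: Path, samples_tsv):
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(map_path)
    map_rows = []
    for ln, line in enumerate(map_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{map_path}:{ln}: expected 4 MAP fields")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)

    ids, sexes, geno_rows = [], [], []
    for ln, line in enumerate(ped_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise FormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
            )
        ids.append(parts[1])
        sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
        geno_rows.append(parts[6:])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample id in PED")

    # allele_a = first non-missing allele observed at the SNP, allele_b the
    # second distinct one (PED text carries no REF/ALT designation)
    alleles_ab: list[list[str]] = [[] for _ in range(n_snps)]
    for row in geno_rows:
        for j in range(n_snps):
            for a in (row[2 * j], row[2 * j + 1]):
                if a == "0":
                    continue
                known = alleles_ab[j]
                if a not in known:
                    if len(known) >= 2:
                        raise FormatError(
                            f"SNP {map_rows[j][1]} has >2 alleles in PED"
                        )
                    known.append(a)
    for j, known in enumerate(alleles_ab):
        while len(known) < 2:  # monomorphic or all-missing columns
            known.append("N" if "N" not in known else "X")

    codes = np.empty((len(ids), n_snps), dtype=np.int8)
    for i, row in enumerate(geno_rows):
        for j in range(n_snps):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                codes[i, j] = MISSING
            else:
                b = alleles_ab[j][1]
                codes[i, j] = (a1 == b) + (a2 == b)

    rows = [
        {
            "snp_id": sid,
            "chrom": chrom,
            "pos_bp": pos,
            "allele_a": alleles_ab[j][0],
            "allele_b": alleles_ab[j][1],
            "ancestral": None,
        }
        for j, (chrom, sid, pos) in enumerate(map_rows)
    ]
    snp_map, order = _sorted_map(rows)
    codes = codes[:, order]
    if samples_tsv is not None:
        samples = _attach_metadata(ids, samples_tsv)
    else:
        samples = SampleTable(pd.DataFrame({"id": ids, "breed": "unknown", "sex": sexes}))
    return GenotypeMatrix(codes, snp_map, samples), snp_map, samples


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_vcf(path, genotypes: GenotypeMatrix | None = None, haplotypes: HaplotypeSet | None = None) -> None:
    """Write a VCF 4.2 file; phased ("|") when a HaplotypeSet is supplied."""
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("supply exactly one of genotypes or haplotypes")
    src = haplotypes if haplotypes is not None else genotypes
    snp_map, samples = src.snp_map, src.samples
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples.ids),
    ]
    anc = snp_map.df["ancestral"]
    for j in range(len(snp_map)):
        rec = snp_map.df.iloc[j]
        info = f"AA={anc.iloc[j]}" if pd.notna(anc.iloc[j]) and anc.iloc[j] else "."
        if haplotypes is not None:
            gts = [
                f"{haplotypes.haps[2 * k, j]}|{haplotypes.haps[2 * k + 1, j]}"
                for k in range(len(samples))
            ]
        else:
            conv = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            gts = [conv[int(c)] for c in genotypes.codes[:, j]]
        lines.append(
            f"{rec.chrom}\t{rec.pos_bp}\t{rec.snp_id}\t{rec.allele_a}\t"
            f"{rec.allele_b}\t.\t.\t{info}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_tsv(path, samples: SampleTable) -> None:
    samples.df[["id", "breed", "sex"]].to_csv(path, sep="\t", index=False)


def write_ped_map(prefix, genotypes: GenotypeMatrix) -> None:
    """Write PLINK text PED/MAP (``<prefix>.ped`` / ``<prefix>.map``)."""
    prefix = Path(prefix)
    snp_map, samples = genotypes.snp_map, genotypes.samples
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, rec in snp_map.df.iterrows():
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.pos_bp}\n")
    sex_code = {"M": "1", "F": "2", "U": "0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(len(samples)):
            rec = samples.df.iloc[i]
            fields = [rec.breed, rec.id, "0", "0", sex_code[rec.sex], "-9"]
            for j in range(len(snp_map)):
                c = genotypes.codes[i, j]
                a, b = snp_map.df.iloc[j][["allele_a", "allele_b"]]
                pair = {0: (a, a), 1: (a, b), 2: (b, b), MISSING: ("0", "0")}[int(c)]
                fields.extend(pair)
            fh.write(" ".join(map(str, fields)) + "\n")


def write_scan_table(result_df: pd.DataFrame, path) -> None:
    """Write a per-SNP scan table as TSV, missing values as "NA"."""
    result_df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_scan_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})


def write_intervals_bed(intervals, path) -> None:
    """Write intervals as BED (0-based half-open) in input order."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out


# ---------------------------------------------------------------------------
# Merging two genotype sources
# ---------------------------------------------------------------------------


def merge_genotype_sources(primary: GenotypeMatrix, secondary: GenotypeMatrix):
    """Merge two genotype sources; the primary platform wins at conflicts.

    SNPs are matched by (chrom, pos_bp) with allele harmonization (a
    secondary SNP whose alleles are swapped relative to the primary has its
    codes flipped ``c -> 2 - c``); samples are matched by id.  Returns the
    union-of-SNPs matrix restricted to the primary's samples plus a
    :class:`ConcordanceReport` over overlapping non-missing genotype pairs.
    SNPs with irreconcilable allele coding are excluded and logged.
    """
    pmap, smap = primary.snp_map.df, secondary.snp_map.df
    pkey = list(zip(pmap["chrom"], pmap["pos_bp"]))
    skey = list(zip(smap["chrom"], smap["pos_bp"]))
    skey_idx = {k: j for j, k in enumerate(skey)}

    sec_ids = {sid: i for i, sid in enumerate(secondary.samples.ids)}
    shared_samples = [
        (i, sec_ids[sid]) for i, sid in enumerate(primary.samples.ids) if sid in sec_ids
    ]

    conc_rows = []
    merged_cols = []
    merged_map_rows = []
    used_secondary = set()

    for i_p, key in enumerate(pkey):
        col = primary.codes[:, i_p].copy()
        prec = pmap.iloc[i_p]
        j_s = skey_idx.get(key)
        if j_s is not None:
            used_secondary.add(j_s)
            srec = smap.iloc[j_s]
            if (srec.allele_a, srec.allele_b) == (prec.allele_a, prec.allele_b):
                flip = False
            elif (srec.allele_b, srec.allele_a) == (prec.allele_a, prec.allele_b):
                flip = True
            else:
                logger.warning(
                    "excluding SNP %s:%s: irreconcilable alleles %s/%s vs %s/%s",
                    key[0], key[1], prec.allele_a, prec.allele_b,
                    srec.allele_a, srec.allele_b,
                )
                continue
            scol_full = secondary.codes[:, j_s]
            n_pairs = n_match = 0
            for i_pr, i_se in shared_samples:
                s_code = scol_full[i_se]
                if s_code != MISSING and flip:
                    s_code = 2 - s_code
                p_code = col[i_pr]
                if p_code != MISSING and s_code != MISSING:
                    n_pairs += 1
                    n_match += p_code == s_code
                elif p_code == MISSING and s_code != MISSING:
                    col[i_pr] = s_code  # fill missing primary calls
            conc_rows.append(
                {
                    "snp_id": prec.snp_id,
                    "chrom": key[0],
                    "pos_bp": key[1],
                    "n_pairs": n_pairs,
                    "concordance": n_match / n_pairs if n_pairs else np.nan,
                }
            )
        merged_cols.append(col)
        merged_map_rows.append(prec)

    # secondary-only SNPs, restricted to primary's samples
    prim_ids = {sid: i for i, sid in enumerate(primary.samples.ids)}
    pkey_set = set(pkey)
    for j_s in range(len(smap)):
        if skey[j_s] in pkey_set:
            continue
        col = np.full(primary.n_samples, MISSING, dtype=np.int8)
        for sid, i_se in sec_ids.items():
            if sid in prim_ids:
                col[prim_ids[sid]] = secondary.codes[i_se, j_s]
        merged_cols.append(col)
        merged_map_rows.append(smap.iloc[j_s])

    mdf = pd.DataFrame(merged_map_rows).reset_index(drop=True)
    order = np.lexsort((mdf["pos_bp"].to_numpy(), mdf["chrom"].to_numpy()))
    mdf = mdf.iloc[order].reset_index(drop=True)
    codes = np.stack(merged_cols, axis=1)[:, order]
    merged = GenotypeMatrix(codes, SNPMap(mdf), primary.samples)

    conc_df = pd.DataFrame(
        conc_rows, columns=["snp_id", "chrom", "pos_bp", "n_pairs", "concordance"]
    )
    mean_c = float(conc_df["concordance"].dropna().mean()) if len(conc_df) else np.nan
    report = ConcordanceReport(len(conc_rows), conc_df, mean_c)
    return merged, report
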