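"""Model/results surface tying the scan together.

:class:`SelectionScan` is the model object: built from a phased two-breed
dataset (haplotypes, SNP map, sample metadata) and a :class:`ScanConfig`,
its :meth:`~SelectionScan.fit` computes every per-SNP statistic — three FST
estimators, windowed FST, per-breed median runs of homozygosity, per-breed
iHS (binned standardization, X separate), and XP-EHH — and returns a
:class:`ScanResults` carrying the per-SNP table, the standardization bin
moments, empirical thresholds, candidate-interval extraction and a
``summary()``.

Chromosomes named in ``ScanConfig.x_chroms`` are treated as X: females
only, and iHS standardized in a separate pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import haplo, qc, sitefreq
from .data import (
    GenomicInterval,
    GenotypeMatrix,
    HaplotypeSet,
    SampleTable,
    read_phased_vcf,
    write_intervals_bed,
    write_scan_table,
)
from .intervals import (
    XPEHH_THRESHOLD,
    ThresholdSpec,
    combine_intervals,
    extract_intervals,
    report_refined,
)

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tunable scan parameters (defaults follow the standard workflow)."""

    fst_window: int = 5
    flank_snps: int = 25
    ehh_cutoff: float = 0.05
    ihs_bins: int = 18
    ihs_window: int = 10
    ihs_maf_min: float = 0.10
    fst_percentile_autosome: float = 99.9
    fst_percentile_x: float = 99.0
    xpehh_threshold: float = XPEHH_THRESHOLD
    x_chroms: tuple[str, ...] = ("X",)
    pop_a: str | None = None  # XP-EHH numerator breed; positive => sweep in A


class SelectionScan:
    """Two-breed selection-signature scan model.

    Parameters
    ----------
    haplotypes
        Phased haplotypes for both breeds (carries map and samples).
    config
        :class:`ScanConfig`; ``config.pop_a`` names the breed whose sweep
        shows as positive XP-EHH (defaults to the first sorted breed label).
    """

    def __init__(self, haplotypes: HaplotypeSet, config: ScanConfig | None = None):
        self.haplotypes = haplotypes
        self.config = config or ScanConfig()
        self.samples = haplotypes.samples
        self.snp_map = haplotypes.snp_map
        self.breed_a, self.breed_b = self.samples.require_two_breeds()
        if self.config.pop_a is not None:
            if self.config.pop_a not in (self.breed_a, self.breed_b):
                raise ValueError(f"pop_a {self.config.pop_a!r} is not a breed label")
            if self.config.pop_a == self.breed_b:
                self.breed_a, self.breed_b = self.breed_b, self.breed_a

    @classmethod
    def from_vcf(cls, vcf_path, samples_tsv, config: ScanConfig | None = None):
        """Build from a fully phased VCF plus an id/breed/sex sidecar TSV."""
        hap_set, _, _, _ = read_phased_vcf(vcf_path, samples_tsv)
        return cls(hap_set, config)

    # -- helpers -----------------------------------------------------------

    def _is_x(self, chrom: str) -> bool:
        return str(chrom) in self.config.x_chroms

    def _chrom_subset(self, chrom: str) -> HaplotypeSet:
        idx = np.flatnonzero(self.snp_map.chrom == chrom)
        sub = self.haplotypes.subset_snps(idx)
        if self._is_x(chrom):
            keep = np.flatnonzero(sub.samples.df["sex"].to_numpy() == "F")
            if len(keep) == 0:
                raise ValueError("no females available for X-chromosome scan")
            sub = sub.subset_samples(keep)
        return sub

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "ScanResults":
        cfg = self.config
        chroms = pd.unique(self.snp_map.chrom)
        tables = []
        ihs_parts: dict[str, list[pd.DataFrame]] = {self.breed_a: [], self.breed_b: []}
        x_flags: dict[str, list[np.ndarray]] = {self.breed_a: [], self.breed_b: []}

        for chrom in chroms:
            sub = self._chrom_subset(chrom)
            g = sub.to_genotypes()
            t = pd.DataFrame(
                {
                    "snp_id": sub.snp_map.df["snp_id"],
                    "chrom": str(chrom),
                    "pos_bp": sub.snp_map.pos_bp,
                }
            )
            for est, col in (
                ("wright", "fst_wright"),
                ("weir_cockerham", "fst_wc"),
                ("hudson", "fst_hudson"),
            ):
                t[col] = sitefreq.fst_per_snp(g, estimator=est)
            t["windowed_fst"] = sitefreq.windowed_fst(
                t["fst_wright"].to_numpy(), window=cfg.fst_window
            )
            med = sitefreq.median_homozygosity_scan(g)
            for breed in (self.breed_a, self.breed_b):
                t[f"med_hom_{breed}"] = med[f"med_hom_{breed}"].to_numpy()

            for breed in (self.breed_a, self.breed_b):
                bh = sub.subset_breed(breed)
                rec = haplo.ihs_scan(bh, maf_min=cfg.ihs_maf_min, cutoff=cfg.ehh_cutoff)
                ihs_parts[breed].append(rec)
                x_flags[breed].append(
                    np.full(len(rec), self._is_x(chrom), dtype=bool)
                )
                t[f"ihh_a_{breed}"] = rec["ihh_a"].to_numpy()
                t[f"ihh_d_{breed}"] = rec["ihh_d"].to_numpy()
                t[f"uihs_{breed}"] = rec["uihs"].to_numpy()

            xp = haplo.xpehh_scan(
                sub.subset_breed(self.breed_a),
                sub.subset_breed(self.breed_b),
                cutoff=cfg.ehh_cutoff,
            )
            t["xpehh_raw"] = xp["xpehh_raw"].to_numpy()
            tables.append(t)

        table = pd.concat(tables, ignore_index=True)

        # iHS standardization across the whole scan, per breed, X separate
        bin_stats = {}
        for breed in (self.breed_a, self.breed_b):
            rec = pd.concat(ihs_parts[breed], ignore_index=True)
            flags = np.concatenate(x_flags[breed])
            ihs, bins = haplo.standardize_ihs(
                rec, n_bins=cfg.ihs_bins, x_flag=flags
            )
            table[f"ihs_{breed}"] = ihs
            table[f"abs_ihs_win_{breed}"] = haplo.windowed_abs_ihs(
                ihs, table["chrom"].to_numpy(), window=cfg.ihs_window
            )
            bin_stats[breed] = bins

        try:
            table["xpehh"] = haplo.standardize_xpehh(table["xpehh_raw"].to_numpy())
        except ValueError:
            logger.warning("too few scored SNPs to standardize XP-EHH")
            table["xpehh"] = np.nan

        thresholds = self._thresholds(table)
        return ScanResults(self, table, bin_stats, thresholds)

    def _thresholds(self, table: pd.DataFrame) -> dict[str, ThresholdSpec]:
        cfg = self.config
        out: dict[str, ThresholdSpec] = {}
        is_x = table["chrom"].map(self._is_x).to_numpy()
        wf = table["windowed_fst"].to_numpy(dtype=float)
        for label, mask, q in (
            ("windowed_fst_autosome", ~is_x, cfg.fst_percentile_autosome),
            ("windowed_fst_x", is_x, cfg.fst_percentile_x),
        ):
            vals = wf[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                thr = sitefreq.empirical_percentile_threshold(vals, q)
                out[label] = ThresholdSpec(
                    "windowed_fst", thr, "ge",
                    provenance=f"percentile q={q} of n={len(vals)} windowed FST values",
                    percentile_q=q, percentile_n=len(vals),
                )
        out["xpehh"] = ThresholdSpec(
            "xpehh", cfg.xpehh_threshold, "abs_ge", provenance="fixed convention"
        )
        return out


class ScanResults:
    """Fitted scan: per-SNP statistics, bin moments, thresholds, intervals."""

    def __init__(self, model: SelectionScan, table: pd.DataFrame, bin_stats, thresholds):
        self.model = model
        self.table = table
        self.bin_stats = bin_stats
        self.thresholds = thresholds

    # -- intervals ---------------------------------------------------------

    def intervals(self, spec: ThresholdSpec | str, bridge_na: bool = False):
        """Candidate intervals for a named threshold or an explicit spec."""
        if isinstance(spec, str):
            spec = self.thresholds[spec]
        return extract_intervals(self.table, spec, bridge_na=bridge_na)

    def refine(self, mode: str = "intersection") -> pd.DataFrame:
        """Combine windowed-FST and |XP-EHH| intervals into refined regions."""
        fst_ivs: list[GenomicInterval] = []
        for key in ("windowed_fst_autosome", "windowed_fst_x"):
            if key in self.thresholds:
                spec = self.thresholds[key]
                sub = self.table[
                    self.table["chrom"].map(self.model._is_x)
                    == key.endswith("_x")
                ]
                fst_ivs.extend(extract_intervals(sub, spec))
        xp_ivs = self.intervals("xpehh")
        return report_refined(combine_intervals(fst_ivs, xp_ivs, mode=mode))

    # -- output ------------------------------------------------------------

    COLUMN_ORDER_PREFIX = ["snp_id", "chrom", "pos_bp", "fst_wright", "fst_wc",
                           "fst_hudson", "windowed_fst"]

    def to_tsv(self, path) -> None:
        write_scan_table(self.table, path)

    def summary(self) -> str:
        m = self.model
        t = self.table
        lines = [
            "Two-breed selection-signature scan",
            "=" * 50,
            f"breeds:            {m.breed_a} (A) vs {m.breed_b} (B)",
            f"samples:           {len(m.samples)} diploids",
            f"SNPs:              {len(t)} on chromosomes "
            + ", ".join(map(str, pd.unique(t['chrom']))),
            "",
            "mean per-SNP FST   wright {:.4f}   weir-cockerham {:.4f}   hudson {:.4f}".format(
                np.nanmean(t["fst_wright"]),
                np.nanmean(t["fst_wc"]),
                np.nanmean(t["fst_hudson"]),
            ),
        ]
        for name, spec in self.thresholds.items():
            lines.append(
                f"threshold {name:<24s} {spec.direction:>6s} {spec.threshold:.4f}"
                f"  [{spec.provenance}]"
            )
        refined = self.refine()
        lines.append("")
        lines.append(f"refined candidate intervals (FST ∩ |XP-EHH|): {len(refined)}")
        for _, r in refined.iterrows():
            lines.append(
                f"  {r.chrom}:{r.start_bp:,}-{r.end_bp:,}  "
                f"{r.length_bp:,} bp ({r.length_kb} kb)"
            )
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot(self, statistic: str = "windowed_fst", ax=None):
        """Plot a per-SNP statistic against genomic position (one panel per
        chromosome stacked vertically when several are present)."""
        import matplotlib.pyplot as plt

        chroms = pd.unique(self.table["chrom"])
        if ax is None:
            fig, axes = plt.subplots(len(chroms), 1, squeeze=False, figsize=(8, 2.5 * len(chroms)))
            axes = axes[:, 0]
        else:
            axes = [ax]
            fig = ax.figure
        for a, chrom in zip(axes, chroms):
            sub = self.table[self.table["chrom"] == chrom]
            a.plot(sub["pos_bp"], sub[statistic], ".-", ms=3)
            a.set_xlabel(f"position (bp), chr {chrom}")
            a.set_ylabel(statistic)
        fig.tight_layout()
        return fig


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_scan_pipeline(config: dict, outdir) -> dict:
    """Deterministic end-to-end run: input/QC -> scan -> intervals.

    ``config`` keys:

    * ``input``: {"vcf": path, "samples": path} for phased input, or
      ``simulate``: kwargs for :class:`~sweepscan.simulate.SimulationConfig`
      (including ``sweep`` kwargs for :class:`~sweepscan.simulate.SweepSpec`).
    * ``qc``: optional {"max_missing_sample", "max_missing_locus",
      "maf_min", "hwe_alpha"} — applied to genotype-level input.
    * ``scan``: optional kwargs for :class:`ScanConfig`.
    * ``refine``: optional {"mode": "intersection"|"union"}.

    Writes scan.tsv, qc_report.tsv, intervals.tsv/.bed and run_config.json
    into ``outdir`` and returns {"results": ScanResults, "paths": {...}}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    if "simulate" in config:
        from .simulate import SimulationConfig, SweepSpec, simulate_two_breed_dataset

        sim_kwargs = dict(config["simulate"])
        if sim_kwargs.get("sweep") is not None and not isinstance(
            sim_kwargs["sweep"], SweepSpec
        ):
            sw = dict(sim_kwargs["sweep"])
            sw["span"] = tuple(sw["span"])
            sim_kwargs["sweep"] = SweepSpec(**sw)
        if "breed_labels" in sim_kwargs:
            sim_kwargs["breed_labels"] = tuple(sim_kwargs["breed_labels"])
        sim_cfg = SimulationConfig(**sim_kwargs)
        hap_set, genotypes, snp_map, samples, labels = simulate_two_breed_dataset(sim_cfg)
        labels.to_frame(snp_map).to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
        paths["truth_labels"] = str(outdir / "truth_labels.tsv")
    elif "input" in config:
        hap_set, genotypes, snp_map, samples = read_phased_vcf(
            config["input"]["vcf"], config["input"].get("samples")
        )
    else:
        raise ValueError("config must name 'input' or 'simulate'")

    # QC on the genotype matrix; haplotype columns follow the locus filter
    qc_cfg = config.get("qc", {})
    g = genotypes
    g = qc.filter_by_missingness(
        g, "samples", qc_cfg.get("max_missing_sample", qc.DEFAULT_MAX_MISSING_SAMPLE)
    )
    g = qc.filter_by_missingness(
        g, "loci", qc_cfg.get("max_missing_locus", qc.DEFAULT_MAX_MISSING_LOCUS)
    )
    g, report = qc.apply_snp_filters(
        g,
        maf_min=qc_cfg.get("maf_min", qc.DEFAULT_MAF_MIN),
        hwe_alpha=qc_cfg.get("hwe_alpha", qc.DEFAULT_HWE_ALPHA),
    )
    report.df.to_csv(outdir / "qc_report.tsv", sep="\t", index=False, na_rep="NA")
    paths["qc_report"] = str(outdir / "qc_report.tsv")
    logger.info(
        "QC: %d/%d samples, %d/%d SNPs retained",
        g.n_samples, genotypes.n_samples, g.n_snps, genotypes.n_snps,
    )

    keep_snps = np.flatnonzero(
        snp_map.df["snp_id"].isin(g.snp_map.df["snp_id"]).to_numpy()
    )
    keep_samples = np.flatnonzero(
        samples.df["id"].isin(g.samples.df["id"]).to_numpy()
    )
    hap_set = hap_set.subset_samples(keep_samples).subset_snps(keep_snps)

    scan_cfg = ScanConfig(**config.get("scan", {}))
    results = SelectionScan(hap_set, scan_cfg).fit()
    results.to_tsv(outdir / "scan.tsv")
    paths["scan"] = str(outdir / "scan.tsv")

    mode = config.get("refine", {}).get("mode", "intersection")
    refined = results.refine(mode=mode)
    refined.to_csv(outdir / "intervals.tsv", sep="\t", index=False, na_rep="NA")
    write_intervals_bed(
        [
            GenomicInterval(str(r.chrom), int(r.start_bp), int(r.end_bp))
            for _, r in refined.iterrows()
        ],
        outdir / "intervals.bed",
    )
    paths["intervals"] = str(outdir / "intervals.tsv")
    paths["intervals_bed"] = str(outdir / "intervals.bed")

    def _jsonable(obj):
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if hasattr(obj, "__dataclass_fields__"):
            return _jsonable(asdict(obj))
        return obj

    (outdir / "run_config.json").write_text(json.dumps(_jsonable(config), indent=2, default=str))
    paths["run_config"] = str(outdir / "run_config.json")
    return {"results": results, "paths": paths}
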