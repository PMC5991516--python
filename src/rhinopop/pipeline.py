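"""End-to-end orchestration: filter -> diversity -> ROH -> selection scan.

A :class:`PipelineConfig` (YAML on disk) names the inputs and carries every
stage parameter; :func:`run_pipeline` executes the stages in order, writes
each stage's tables, and assembles a summary report.  All randomness in the
simulation entry point flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diversity, roh, selection, variants
from .simulate import SimConfig, simulate_split_genotypes, write_gene_fixture

logger = logging.getLogger("rhinopop")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_command"]


@dataclass
class PipelineConfig:
    vcf: str = ""
    panel: str = ""
    genes: str | None = None
    scaffold_lengths: str | None = None  # TSV scaffold<TAB>length; else VCF header
    outdir: str = "rhinopop_out"
    # filtering
    filter: variants.FilterConfig = field(default_factory=variants.FilterConfig)
    # diversity
    denominator_bp: int | None = None  # callable genome length; None = scaffold total
    ld_window_snps: int = 50
    ld_step_snps: int = 10
    ld_r2_max: float = 0.1
    # ROH
    roh_window: int = roh.DEFAULT_WINDOW
    roh_step: int = roh.DEFAULT_STEP
    roh_threshold: float = roh.DEFAULT_THRESHOLD
    roh_refine: bool = True
    # selection scan
    scan_window: int = selection.DEFAULT_SCAN_WINDOW
    scan_quantile: float = selection.DEFAULT_QUANTILE
    scan_population: str | None = None  # default: first panel population
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.scan_quantile < 0.5):
            raise ValueError("scan_quantile must be in (0, 0.5)")
        if not (self.roh_window >= self.roh_step > 0):
            raise ValueError("require roh_window >= roh_step > 0")
        if self.roh_threshold <= 0:
            raise ValueError("roh_threshold must be > 0")
        if not (self.ld_window_snps > self.ld_step_snps > 0):
            raise ValueError("require ld_window_snps > ld_step_snps > 0")
        for name in ("vcf", "panel"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} file missing: {p!r}")
        for name in ("genes", "scaffold_lengths"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file missing: {p!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        fcfg = variants.FilterConfig(**raw.pop("filter", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(filter=fcfg, **raw)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "pipeline.log"),
    ):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)


def _read_lengths(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["scaffold", "length"])
    return dict(zip(df["scaffold"].astype(str), df["length"].astype(int)))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages; returns a report dict mirroring the written files."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("parameters: %s", dataclasses.asdict(config))

    stage = "read"
    try:
        lengths = _read_lengths(config.scaffold_lengths) if config.scaffold_lengths else None
        table = variants.read_variants(
            config.vcf,
            scaffold_lengths=lengths,
            ranksum_key=config.filter.ranksum_key,
            alt_support_key=config.filter.alt_support_key,
        )
        panel = diversity.PopulationPanel.from_tsv(config.panel)
        logger.info("read %d records, %d samples", table.n_records, table.n_samples)

        stage = "filter"
        filtered, report = variants.apply_filters(table, config.filter)
        report.to_tsv(str(outdir / "filter_report.tsv"))
        variants.write_variants(
            filtered, str(outdir / "filtered.vcf"),
            ranksum_key=config.filter.ranksum_key,
            alt_support_key=config.filter.alt_support_key,
        )
        logger.info("filter: %d -> %d (%s)", report.n_input, report.n_passed,
                    report.removed_by_rule)

        stage = "diversity"
        het = diversity.individual_heterozygosity(
            filtered, config.denominator_bp, panel
        )
        het.to_tsv(str(outdir / "heterozygosity.tsv"), panel)
        div = diversity.pairwise_divergence(filtered, panel, config.denominator_bp)
        part = diversity.partition_snps(filtered, panel)
        part.to_tsv(str(outdir / "snp_partition.tsv"))
        sfs = diversity.joint_sfs(filtered, panel)
        sfs.to_dadi(str(outdir / "joint_sfs.txt"))
        logger.info("diversity: dxy=%.6g, partition=%s", div.dxy,
                    dataclasses.asdict(part))

        stage = "roh"
        genome_bp = sum(filtered.scaffold_lengths.values())
        summaries: dict[str, roh.ROHSummary] = {}
        with open(outdir / "roh.bed", "w") as bed:
            for sample in filtered.samples:
                windows = roh.windowed_heterozygosity(
                    filtered, sample, config.roh_window, config.roh_step
                )
                mask = roh.call_roh_windows(windows, config.roh_threshold)
                runs = roh.merge_roh_runs(windows, mask, config.roh_window,
                                          config.roh_step)
                if config.roh_refine:
                    runs = roh.refine_roh_boundaries(runs, filtered, sample)
                summaries[sample] = roh.roh_summary(runs, genome_bp)
                for r in runs:
                    bed.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.sample}"
                              f"\t{r.span_bp}\n")
        with open(outdir / "roh_summary.tsv", "w") as fh:
            fh.write("sample\tfroh\tmedian_span_bp\tmax_span_bp\tn_runs\n")
            for sample, s in summaries.items():
                fh.write(s.to_tsv_row(sample) + "\n")
        with open(outdir / "roh_histogram.tsv", "w") as fh:
            bins = next(iter(summaries.values())).histogram if summaries else {}
            fh.write("bin\t" + "\t".join(summaries) + "\n")
            for label in bins:
                row = "\t".join(str(summaries[s].histogram[label]) for s in summaries)
                fh.write(f"{label}\t{row}\n")
        logger.info("roh: froh=%s",
                    {s: round(v.froh, 5) for s, v in summaries.items()})

        stage = "scan"
        scan_pop = config.scan_population or panel.populations[0]
        scan_samples = panel.members(scan_pop)
        stats = selection.window_stats(filtered, scan_samples, config.scan_window)
        pd.DataFrame(
            [(w.scaffold, w.start, w.end, w.S, w.theta_w, w.theta_pi,
              w.tajima_d if w.tajima_d is not None else float("nan"))
             for w in stats],
            columns=["scaffold", "start", "end", "S", "theta_w", "theta_pi",
                     "tajima_d"],
        ).to_csv(outdir / "window_stats.tsv", sep="\t", index=False)
        outliers = selection.outlier_windows(stats, config.scan_quantile)
        with open(outdir / "outliers.bed", "w") as fh:
            for r in outliers:
                fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.tail}"
                         f"\t{r.tajima_d:.4f}\n")
        coding: list[selection.CodingSNPRecord] = []
        if config.genes:
            genes = selection.read_gene_intervals(config.genes)
            coding = selection.coding_snps_in_outliers(outliers, genes,
                                                       filtered, panel)
            with open(outdir / "coding_snps.tsv", "w") as fh:
                fh.write("scaffold\tpos\tgene\tfixation_class\n")
                for c in coding:
                    fh.write(f"{c.scaffold}\t{c.pos}\t{c.gene_id}"
                             f"\t{c.fixation_class}\n")
        logger.info("scan: %d outlier regions, %d coding SNPs",
                    len(outliers), len(coding))

        stage = "report"
        gene_counts: dict[str, dict[str, int]] = {}
        for c in coding:
            d = gene_counts.setdefault(c.gene_id, {})
            d[c.fixation_class] = d.get(c.fixation_class, 0) + 1
        report_payload = {
            "seed": config.seed,
            "filter": {"input": report.n_input, "passed": report.n_passed,
                       "removed_by_rule": report.removed_by_rule},
            "heterozygosity": het.per_sample,
            "heterozygosity_population_means": het.population_means,
            "dxy": div.dxy,
            "snp_partition": {
                "shared_polymorphic": part.shared_polymorphic,
                "fixed_both": part.fixed_both,
                **{f"unique_{k}": v for k, v in part.unique.items()},
                "fixed_one_polymorphic_other": part.fixed_one_polymorphic_other,
                "invariant": part.invariant_total,
            },
            "froh": {s: v.froh for s, v in summaries.items()},
            "outlier_regions": len(outliers),
            "outlier_genes": gene_counts,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report_payload, fh, indent=1, sort_keys=True)
        logger.info("pipeline complete: %s", outdir)
        return report_payload
    except Exception:
        logger.exception("pipeline failed at stage %r; outputs may be partial", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from sys.exc_info()[1]


def simulate_command(
    config: SimConfig, outdir: str, n_genes: int | None = None
) -> dict[str, str]:
    """Write a complete synthetic fixture bundle (VCF, panel, lengths, genes,
    truth) and return the file paths."""
    if n_genes is None:  # roughly one gene per 100 kbp, capped
        n_genes = max(1, min(50, sum(l for _, l in config.scaffolds) // 100_000))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_split_genotypes(config)
    paths = {
        "vcf": str(out / "synthetic.vcf"),
        "panel": str(out / "panel.tsv"),
        "scaffold_lengths": str(out / "scaffold_lengths.tsv"),
        "genes": str(out / "genes.bed"),
        "truth": str(out / "truth.json"),
    }
    variants.write_variants(table, paths["vcf"])
    with open(paths["panel"], "w") as fh:
        for s in table.samples:
            pop = config.pop1 if s.startswith(config.pop1) else config.pop2
            fh.write(f"{s}\t{pop}\n")
    with open(paths["scaffold_lengths"], "w") as fh:
        for scaffold, length in config.scaffolds:
            fh.write(f"{scaffold}\t{length}\n")
    write_gene_fixture(config.scaffolds, n_genes, seed=config.seed + 1,
                       path=paths["genes"])
    truth.to_json(paths["truth"])
    return paths
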