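"""Umbrella workflow: simulate / detect / quantify stages and the
cross-modality concordance report.

The concordance report mirrors multi-sampling comparisons of the mosaic
fraction measured by different modalities (bulk BAF, methylation, stained
area, single-nucleus) on the same patient, reporting the per-sample
min-max spread across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import bulk, io, methylation, promoters, sc, simulate

__all__ = ["RunConfig", "ConcordanceReport", "build_concordance", "parse_config", "run_pipeline"]

STAGES = ("simulate", "bulk_detect", "methyl", "sc_call", "promoters", "report")


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    Thresholds default to the published rules where they exist (8 informative
    reads, per-cell BAF 0.85 / 0.60, 2-probe epimutation rules) and to the
    documented package defaults otherwise.
    """

    out_dir: str = "."
    stages: tuple = STAGES
    seed: int = 0
    # inputs (each optional; the simulate stage fills the gaps)
    snp_tsv: str = ""
    vcf: str = ""
    mlpa_tsv: str = ""
    phased_tsv: str = ""
    cell_counts_tsv: str = ""
    celltype_tsv: str = ""
    junction_tsv: str = ""
    # locus and thresholds
    locus_chrom: str = "chr11"
    locus_start: int = 1
    locus_end: int = 2_800_000
    alteration: str = "cn_LOH"
    alpha: float = 0.05
    het_low: float = 0.2
    het_high: float = 0.8
    min_depth: int = 8
    min_reads: int = 8
    loh_baf: float = 0.85
    ref_baf: float = 0.60
    k_sd: float = 3.0
    rho: float = 0.30

    @property
    def locus(self) -> bulk.LocusSpec:
        return bulk.LocusSpec(
            self.locus_chrom, self.locus_start, self.locus_end, self.alteration
        )


def parse_config(path) -> RunConfig:
    """Flat ``key=value`` config file; '#' starts a comment."""
    values: dict = {}
    types = {f.name: f.type for f in fields(RunConfig)}
    casts = {"int": int, "float": float, "str": str}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "stages":
                values[key] = tuple(s.strip() for s in value.split(","))
            elif key in types:
                values[key] = casts.get(types[key], str)(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return RunConfig(**values)


@dataclass
class ConcordanceReport:
    """Per-(sample, modality) fractions plus the per-sample min-max spread."""

    rows: pd.DataFrame
    spread: pd.DataFrame


def build_concordance(estimates: list[bulk.MosaicEstimate]) -> ConcordanceReport:
    """Tabulate mosaic-fraction estimates across detection modalities.

    One row per (sample, method) with the fraction and p-value; the spread
    table carries min, max and range of the fraction per sample.
    """
    if not estimates:
        raise ValueError("at least one estimate required")
    rows = pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "method": e.method,
                "fraction_pct": e.fraction_pct,
                "p_value": e.p_value,
                "detected": e.detected,
            }
            for e in estimates
        ]
    )
    spread = (
        rows.groupby("sample_id")["fraction_pct"]
        .agg(["min", "max"])
        .rename(columns={"min": "fraction_min", "max": "fraction_max"})
    )
    spread["spread"] = spread["fraction_max"] - spread["fraction_min"]
    return ConcordanceReport(rows, spread.reset_index())


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages, writing one TSV per stage plus a log.

    Returns a mapping from stage name to output path.  Input paths are
    validated before any stage runs; a failing stage raises with its name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in cfg.stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
    for attr in ("snp_tsv", "vcf", "mlpa_tsv", "phased_tsv", "cell_counts_tsv",
                 "celltype_tsv", "junction_tsv"):
        path = getattr(cfg, attr)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"config input {attr}={path} does not exist")
    log = io.RunLog(out_dir / "run.log")
    log.write(event="start", seed=cfg.seed, stages=",".join(cfg.stages))
    outputs: dict = {}
    estimates: list[bulk.MosaicEstimate] = []
    scfg = simulate.ScenarioConfig(
        seed=cfg.seed, rho=cfg.rho, alteration=cfg.alteration, locus=cfg.locus
    )

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("simulate"):
            sites, truth = simulate.simulate_bulk_snps(scfg)
            outputs["simulate"] = str(io.write_tsv(sites, out_dir / "sim_snps.tsv"))
            io.write_tsv(
                pd.DataFrame({"key": ["rho", "alteration"],
                              "value": [truth["rho"], truth["alteration"]]}),
                out_dir / "sim_snps_truth.tsv",
            )
            probes, probe_truth = simulate.simulate_methylation(scfg)
            io.write_tsv(probes, out_dir / "sim_mlpa.tsv")
            io.write_tsv(probe_truth, out_dir / "sim_mlpa_truth.tsv")
            counts, phased, cell_truth = simulate.simulate_cells(scfg)
            io.write_tsv(counts, out_dir / "sim_cell_counts.tsv")
            io.write_tsv(phased, out_dir / "sim_phased.tsv")
            io.write_tsv(cell_truth[["cell_id", "cell_type"]], out_dir / "sim_celltypes.tsv")
            io.write_tsv(cell_truth, out_dir / "sim_cells_truth.tsv")
            jcs, jc_truth = simulate.simulate_junctions(scfg)
            jrows = [
                {"sample_id": jc.sample_id, "category": c, "max_depth": d,
                 "universal_depth": jc.universal_depth}
                for jc in jcs
                for c, d in jc.category_depths.items()
            ]
            io.write_tsv(pd.DataFrame(jrows), out_dir / "sim_junctions.tsv")
            log.write(event="stage", name="simulate", n_snps=len(sites))

        if _stage("bulk_detect"):
            if cfg.vcf:
                model = bulk.BulkMosaicModel.from_vcf(cfg.vcf, locus=cfg.locus,
                                                     het_low=cfg.het_low,
                                                     het_high=cfg.het_high,
                                                     min_depth=cfg.min_depth)
            else:
                snp_path = cfg.snp_tsv or outputs.get("simulate")
                if not snp_path:
                    raise ValueError("bulk_detect needs snp_tsv, vcf, or the simulate stage")
                model = bulk.BulkMosaicModel(
                    io.read_snp_tsv(snp_path), locus=cfg.locus, het_low=cfg.het_low,
                    het_high=cfg.het_high, min_depth=cfg.min_depth,
                )
            res = model.fit(alpha=cfg.alpha)
            outputs["bulk_detect"] = str(io.write_tsv(res.to_frame(), out_dir / "bulk_report.tsv"))
            res.estimate.sample_id = "sample"
            estimates.append(res.estimate)
            log.write(event="stage", name="bulk_detect",
                      fraction_pct=res.fraction_pct, p_value=res.p_value)

        if _stage("methyl"):
            mlpa_path = cfg.mlpa_tsv or (out_dir / "sim_mlpa.tsv" if _stage("simulate") else "")
            if not mlpa_path:
                raise ValueError("methyl needs mlpa_tsv or the simulate stage")
            mres = methylation.MethylationModel.from_tsv(mlpa_path, k_sd=cfg.k_sd).fit()
            outputs["methyl"] = str(io.write_tsv(mres.to_frame(), out_dir / "methyl_report.tsv"))
            first = mres.samples.iloc[0]
            estimates.append(
                bulk.MosaicEstimate(fraction_pct=float(first["fraction_pct"]),
                                    method="methylation", sample_id="sample")
            )
            log.write(event="stage", name="methyl", n_samples=len(mres.samples))

        if _stage("sc_call"):
            counts_path = cfg.cell_counts_tsv or (
                out_dir / "sim_cell_counts.tsv" if _stage("simulate") else ""
            )
            phased_path = cfg.phased_tsv or (
                out_dir / "sim_phased.tsv" if _stage("simulate") else ""
            )
            if not counts_path or not phased_path:
                raise ValueError("sc_call needs cell_counts_tsv and phased_tsv, or simulate")
            ctypes_path = cfg.celltype_tsv or (
                out_dir / "sim_celltypes.tsv" if _stage("simulate") else ""
            )
            ctypes = io.read_celltype_tsv(ctypes_path) if ctypes_path else None
            scres = sc.SingleCellLohModel(
                io.read_cell_counts_tsv(counts_path),
                io.read_phased_tsv(phased_path),
                cell_types=ctypes,
                min_reads=cfg.min_reads, loh_baf=cfg.loh_baf, ref_baf=cfg.ref_baf,
            ).fit()
            outputs["sc_call"] = str(io.write_tsv(scres.cells, out_dir / "sc_cells.tsv"))
            if scres.by_type is not None:
                io.write_tsv(scres.by_type, out_dir / "sc_by_celltype.tsv")
            determinate = scres.cells["call"].isin(["cn_LOH", "no_cnLOH"])
            frac = 100.0 * (scres.cells["call"] == "cn_LOH").sum() / max(determinate.sum(), 1)
            estimates.append(
                bulk.MosaicEstimate(fraction_pct=float(frac), method="sc", sample_id="sample")
            )
            log.write(event="stage", name="sc_call", n_cells=len(scres.cells))

        if _stage("promoters"):
            j_path = cfg.junction_tsv or (
                out_dir / "sim_junctions.tsv" if _stage("simulate") else ""
            )
            if not j_path:
                raise ValueError("promoters needs junction_tsv or the simulate stage")
            jdf = pd.read_csv(j_path, sep="\t")
            if {"category", "max_depth", "universal_depth"}.issubset(jdf.columns):
                pmodel = promoters.PromoterUsageModel.from_summary_frame(jdf)
            else:
                raise ValueError(
                    "promoters stage expects a summarized junction table "
                    "(sample_id, category, max_depth, universal_depth)"
                )
            pres = pmodel.fit()
            outputs["promoters"] = str(io.write_tsv(pres.to_frame(), out_dir / "promoter_usage.tsv"))
            log.write(event="stage", name="promoters", n_samples=len(pres.usages))

        if _stage("report"):
            if not estimates:
                raise ValueError("report stage needs at least one upstream estimate")
            report = build_concordance(estimates)
            outputs["report"] = str(io.write_tsv(report.rows, out_dir / "concordance_rows.tsv"))
            io.write_tsv(report.spread, out_dir / "concordance_spread.tsv")
            log.write(event="stage", name="report", n_estimates=len(estimates))
    except Exception as exc:  # noqa: BLE001 - annotate failing stage, then re-raise
        log.write(event="error", message=type(exc).__name__)
        raise
    log.write(event="done", n_outputs=len(outputs))
    return outputs
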