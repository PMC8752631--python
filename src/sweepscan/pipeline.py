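"""End-to-end orchestration: VCF -> filters -> windows -> XP-CLR -> sweep blocks.

Every run writes its resolved configuration beside the outputs, logs per-stage
counts to standard error, and is deterministic given the config and seed.
Stage outputs are plain TSV/BED/JSON so each stage can be re-run or inspected
independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import roh as roh_mod
from . import sweep_caller, window_stats, xpclr
from .simulate import CULT_POP, WILD_POP, SimConfig
from .variant_io import (FilterRules, GenotypeMatrix, apply_site_filters,
                         read_gff, read_population_map, read_vcf, write_bed,
                         write_window_table)

logger = logging.getLogger("sweepscan")


@dataclass
class PipelineConfig:
    """Single-file configuration for an end-to-end run."""

    vcf: str = ""
    gff: str = ""
    population_map: str = ""
    out_dir: str = "sweepscan_out"
    pop_wild: str = WILD_POP
    pop_cult: str = CULT_POP
    filters: FilterRules = field(default_factory=FilterRules)
    window_size: int = window_stats.DEFAULT_WINDOW_SIZE
    window_step: int = window_stats.DEFAULT_WINDOW_STEP
    min_snps: int = window_stats.DEFAULT_MIN_SNPS
    q_xpclr: float = 0.95
    q_fst: float = 0.95
    xpclr_model: xpclr.XpclrModel = field(default_factory=xpclr.XpclrModel)
    estimate_omega: bool = True
    roh: roh_mod.RohParams = field(default_factory=roh_mod.RohParams)
    ld_max_dist: int = 200_000
    ld_bins: int = 20
    seed: int = 0
    sim: SimConfig | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "filters" in kwargs and isinstance(kwargs["filters"], dict):
            kwargs["filters"] = FilterRules(**kwargs["filters"])
        if "xpclr_model" in kwargs and isinstance(kwargs["xpclr_model"], dict):
            kwargs["xpclr_model"] = xpclr.XpclrModel(**{
                k: (tuple(v) if k == "s_grid" else v)
                for k, v in kwargs["xpclr_model"].items()})
        if "roh" in kwargs and isinstance(kwargs["roh"], dict):
            kwargs["roh"] = roh_mod.RohParams(**kwargs["roh"])
        if kwargs.get("sim") and isinstance(kwargs["sim"], dict):
            sim = dict(kwargs["sim"])
            if "sweep_loci" in sim:
                sim["sweep_loci"] = tuple(tuple(x) for x in sim["sweep_loci"])
            kwargs["sim"] = SimConfig(**sim)
        return cls(**kwargs)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _infer_chrom_lengths(gm: GenotypeMatrix) -> dict[str, int]:
    out = {}
    for chrom in pd.unique(gm.chrom):
        idx = gm.chrom_sites(chrom)
        out[str(chrom)] = int(gm.pos[idx].max()) + 1
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run filter -> window stats -> XP-CLR -> calling -> annotation -> ROH/SFS/LD.

    Returns the output directory.  Any stage failure propagates with the
    stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifest: dict = {"stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    name = stage("read")
    try:
        popmap = read_population_map(config.population_map)
        gm = read_vcf(config.vcf, popmap)
        genes = read_gff(config.gff) if config.gff else None
        manifest["stages"][name] = {"n_sites": gm.n_sites,
                                    "n_samples": gm.n_samples}

        name = stage("filter")
        gm_f, counts = apply_site_filters(gm, config.filters)
        manifest["stages"][name] = {"removed": counts, "kept": gm_f.n_sites}
        logger.info("filter: kept %d of %d sites", gm_f.n_sites, gm.n_sites)

        name = stage("windows")
        lengths = config.chrom_lengths or _infer_chrom_lengths(gm_f)
        windows = window_stats.make_windows(lengths, config.window_size,
                                            config.window_step)
        table = window_stats.build_window_table(
            gm_f, windows, config.pop_wild, config.pop_cult,
            min_snps=config.min_snps)
        manifest["stages"][name] = {
            "n_windows": len(table),
            "n_defined": int(table["defined"].sum()),
        }

        name = stage("xpclr")
        model = config.xpclr_model
        if config.estimate_omega:
            omega = xpclr.estimate_omega(gm_f, config.pop_wild, config.pop_cult)
            model = dataclasses.replace(model, omega=omega)
        table = xpclr.xpclr_scan(gm_f, table, config.pop_wild, config.pop_cult,
                                 model, min_snps=config.min_snps)
        write_window_table(table, out / "window_table.tsv")
        manifest["stages"][name] = {"omega": model.omega}

        name = stage("call")
        selected, diag = sweep_caller.call_sweeps(table, config.q_xpclr,
                                                  config.q_fst)
        blocks = sweep_caller.merge_blocks(selected)
        manifest["stages"][name] = _as_plain(asdict(diag))

        name = stage("annotate")
        if genes is not None:
            blocks, flat_genes, gene_summary = sweep_caller.annotate_blocks(
                blocks, genes)
            flat_genes.to_csv(out / "genes_selected.tsv", sep="\t", index=False)
        else:
            flat_genes, gene_summary = pd.DataFrame(), {}
        bdf = sweep_caller.blocks_to_frame(blocks)
        bdf.to_csv(out / "blocks.tsv", sep="\t", index=False)
        write_bed(bdf, out / "blocks.bed",
                  extra_cols=["max_xpclr"] if len(bdf) else None)
        manifest["stages"][name] = {"n_blocks": len(blocks), **gene_summary}

        name = stage("roh")
        if genes is not None:
            cult_samples = [gm_f.samples[i]
                            for i in gm_f.pop_sample_indices(config.pop_cult)]
            runs, extents = roh_mod.roh_scan(gm_f, genes, config.roh,
                                             samples=cult_samples)
            per, summary = roh_mod.terminal_homozygosity(runs, extents,
                                                         config.roh)
            runs.to_csv(out / "roh_runs.tsv", sep="\t", index=False)
            per.to_csv(out / "roh_terminal.tsv", sep="\t", index=False)
            summary.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
            manifest["stages"][name] = {
                "n_runs": len(runs),
                "n_samples_flagged": int(summary["genome_flag"].sum()),
            }

        name = stage("sfs")
        for pop, fname in [(config.pop_wild, "sfs_wild.tsv"),
                           (config.pop_cult, "sfs_cult.tsv")]:
            sfs = window_stats.folded_sfs(gm_f, pop)
            pd.DataFrame({"minor_count": np.arange(1, len(sfs) + 1),
                          "n_sites": sfs}).to_csv(out / fname, sep="\t",
                                                  index=False)
        manifest["stages"][name] = "done"

        name = stage("ld")
        for pop, fname in [(config.pop_wild, "ld_wild.tsv"),
                           (config.pop_cult, "ld_cult.tsv")]:
            ld = window_stats.ld_decay(gm_f, pop, config.ld_max_dist,
                                       config.ld_bins)
            ld.to_csv(out / fname, sep="\t", index=False)
        manifest["stages"][name] = "done"
    except Exception as err:
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(_as_plain(manifest), fh, indent=2)
    report(out)
    return out


def report(out_dir) -> dict:
    """Collect headline numbers from a finished run into report.json + text.

    Missing stage outputs leave explicit null gaps rather than failing.
    """
    out = Path(out_dir)
    rep: dict = {}
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        stages = manifest.get("stages", {})
        rep["n_sites_input"] = stages.get("read", {}).get("n_sites")
        rep["n_sites_filtered"] = stages.get("filter", {}).get("kept")
        rep["filter_removed"] = stages.get("filter", {}).get("removed")
        rep["n_windows"] = stages.get("windows", {}).get("n_windows")
        rep["n_windows_defined"] = stages.get("windows", {}).get("n_defined")
        call = stages.get("call", {})
        rep["xpclr_threshold"] = call.get("xpclr_threshold")
        rep["fst_threshold"] = call.get("fst_threshold")
        rep["n_windows_overlap"] = call.get("n_overlap")
        rep["n_windows_selected"] = call.get("n_final")
        ann = stages.get("annotate", {})
        rep["n_blocks"] = ann.get("n_blocks")
        rep["n_genes_selected"] = ann.get("n_genes_selected")
        rep["n_genes_total"] = ann.get("n_genes_total")
        pct = ann.get("percent_genes_selected")
        rep["percent_genes_selected"] = (f"{pct:.2f}" if pct is not None
                                         else None)
        roh_stage = stages.get("roh", {})
        rep["n_roh_runs"] = roh_stage.get("n_runs")
        rep["n_roh_samples_flagged"] = roh_stage.get("n_samples_flagged")
    else:
        rep["note"] = "manifest.json missing; partial report"

    with open(out / "report.json", "w") as fh:
        json.dump(_as_plain(rep), fh, indent=2)
    lines = [f"{k}: {v}" for k, v in rep.items()]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return rep
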