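"""Configuration-driven end-to-end runner.

Ties the stages together: simulate (optional) → preprocess → differential
expression with permutation eFDR → co-expression network → over-
representation analysis (optional, needs a GMT) → phenotype statistics.
Every intermediate is serialized under the output directory and a JSON run
report collects the headline numbers. Identical config + seed reproduce the
report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import TagSeqDE, DEResults
from .enrichment import ora, read_gmt
from .network import CoexpressionNetwork
from .phenotype import spearman_holm, top_degs, welch_test_raw
from .preprocess import (
    CountMatrix,
    filter_prevalence,
    normalize_median_of_ratios,
    pca_samples,
    read_counts,
    validate_markers,
    write_counts,
)
from .simulate import SimulationParams, simulate_experiment, simulate_phenotypes

log = logging.getLogger("stresshypo")

__all__ = ["PipelineConfig", "run_pipeline", "make_volcano_table"]


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters.

    Stage toggles default to on; a stage with missing inputs (e.g. no GMT
    for enrichment) is skipped with a log message rather than an error.
    """

    outdir: str = "stresshypo_out"
    counts_path: str | None = None  # TSV; None -> simulate
    sample_sheet_path: str | None = None
    gmt_path: str | None = None
    seed: int = 0

    run_simulate: bool = True
    run_preprocess: bool = True
    run_de: bool = True
    run_wgcna: bool = True
    run_ora: bool = True
    run_phenotype: bool = True

    simulate_params: dict = field(default_factory=dict)
    markers: list[str] = field(default_factory=lambda: ["hcrt", "npvf", "npy"])
    min_count: int = 10
    filter_mode: str = "any"
    n_perm: int = 5000
    lfc_threshold: float = 0.2
    efdr_threshold: float = 0.05
    wgcna_min_count: int = 15
    wgcna_max_low_fraction: float = 0.75
    power: int | str = 6
    power_rule: str = "paper"
    min_module_size: int = 30
    cut_height: float = 0.995
    cut_method: str = "static"
    k_each_top_degs: int = 5
    holm_family_size: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_volcano_table(de_table: pd.DataFrame, efdr_cap: float = 1e-4) -> pd.DataFrame:
    """Plotting table: log2FC, −log10 eFDR (zeros capped at ``efdr_cap``), call.

    Threshold guides (0.2 / 0.75 / 1.5 on |log2FC|) travel in ``attrs``.
    """
    out = pd.DataFrame(
        {
            "log2FC": de_table["log2FC"],
            "neg_log10_efdr": -np.log10(np.maximum(de_table["eFDR"], efdr_cap)),
            "call": de_table["call"],
        },
        index=de_table.index,
    )
    out.attrs["lfc_guides"] = [0.2, 0.75, 1.5]
    out.attrs["efdr_cap"] = efdr_cap
    return out


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("timings_s", {})[name] = round(dt, 3)
            if exc is None:
                log.info("stage %s: done in %.1fs", name, dt)
            else:
                log.error("stage %s: failed (%s)", name, exc)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns and persists the run report."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
    }

    counts = sheet = truth = None
    if config.counts_path:
        counts = read_counts(config.counts_path)
        if config.sample_sheet_path:
            sheet = pd.read_csv(config.sample_sheet_path, index_col=0)
    elif config.run_simulate:
        with _stage(report, "simulate"):
            params = SimulationParams(**{"seed": config.seed, **config.simulate_params})
            counts, sheet, truth = simulate_experiment(params)
            write_counts(counts, outdir / "counts.tsv")
            sheet.to_csv(outdir / "sample_sheet.csv")
            truth.save(outdir / "truth.json")
            report["simulate"] = {"n_genes": counts.n_genes, "n_samples": counts.n_samples}

    if counts is None or sheet is None:
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        return report
    group = (sheet.loc[counts.sample_ids, "group"] == "Stressed").astype(int).to_numpy()

    if config.run_preprocess:
        with _stage(report, "preprocess"):
            pca = pca_samples(normalize_median_of_ratios(
                filter_prevalence(counts, config.wgcna_min_count, config.wgcna_max_low_fraction)
            ))
            pca.to_csv(outdir / "pca_samples.csv")
            markers = validate_markers(counts, config.markers)
            markers.to_csv(outdir / "markers.csv")
            report["preprocess"] = {
                "n_outliers": int(pca["outlier"].sum()),
                "markers_found": int(markers["found"].sum()),
            }

    de_res: DEResults | None = None
    if config.run_de:
        with _stage(report, "de"):
            model = TagSeqDE.from_counts(
                counts, sheet, min_count=config.min_count, filter_mode=config.filter_mode
            )
            de_res = model.fit(
                n_perm=config.n_perm,
                seed=config.seed,
                lfc_threshold=config.lfc_threshold,
                efdr_threshold=config.efdr_threshold,
            )
            de_res.save(outdir / "de_results.tsv")
            make_volcano_table(de_res.table).to_csv(outdir / "volcano.tsv", sep="\t")
            (outdir / "de_null_meta.json").write_text(
                json.dumps({"n_perm": de_res.null.n_perm, "seed": de_res.null.seed})
            )
            report["de"] = {
                "n_tested": de_res.n_tested,
                "n_up": de_res.n_up,
                "n_down": de_res.n_down,
            }

    net_res = None
    if config.run_wgcna:
        with _stage(report, "wgcna"):
            net_counts = filter_prevalence(
                counts, config.wgcna_min_count, config.wgcna_max_low_fraction
            )
            expr = normalize_median_of_ratios(net_counts)
            net = CoexpressionNetwork(
                expr, group=group, power=config.power, power_rule=config.power_rule
            )
            net_res = net.fit(
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
                method=config.cut_method,
            )
            net_res.save(outdir / "wgcna")
            reg = net_res.group_regression
            report["wgcna"] = {
                "power": net_res.power,
                "n_modules": net_res.n_modules,
                "n_group_associated": (
                    int((reg["p"] < 0.05).sum()) if reg is not None else 0
                ),
            }

    if config.run_ora and config.gmt_path and de_res is not None:
        with _stage(report, "ora"):
            sets = read_gmt(config.gmt_path)
            degs = list(de_res.table.index[de_res.table["call"] != "ns"])
            universe = list(de_res.table.index)
            table = ora(degs, universe, sets)
            table.to_csv(outdir / "ora.tsv", sep="\t")
            report["ora"] = {
                "n_sets_tested": len(table),
                "n_sets_q05": int((table["q"] < 0.05).sum()) if len(table) else 0,
            }

    if config.run_phenotype:
        with _stage(report, "phenotype"):
            pheno = simulate_phenotypes(seed=config.seed)
            pheno.to_csv(outdir / "phenotypes.csv")
            ctrl = pheno[pheno["group"] == "Control"]
            stre = pheno[pheno["group"] == "Stressed"]
            tests = {}
            for measure in ("body_weight_p42", "weight_gain_pct", "fat_mass", "food_efficiency"):
                res = welch_test_raw(ctrl[measure], stre[measure])
                tests[measure] = {"t": res.t, "df": res.df, "p": res.p, "d": res.d}
            report["phenotype"] = tests
            if de_res is not None:
                genes, _ = top_degs(de_res.table, k_each=config.k_each_top_degs)
                behaviors = pheno.loc[stre.index, ["attacks_received", "tail_ups", "scent_marks"]]
                expr = pd.DataFrame(
                    de_res.model.norm.logcpm,
                    index=de_res.model.norm.gene_ids,
                    columns=de_res.model.norm.sample_ids,
                ).loc[genes]
                cors = spearman_holm(expr, behaviors, family_size=config.holm_family_size)
                cors.to_csv(outdir / "behavior_correlations.csv", index=False)
                report["behavior_correlations"] = {
                    "n_tests": int(cors["p_raw"].notna().sum()),
                    "n_holm_sig": int((cors["p_holm"] < 0.05).sum()),
                }

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
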