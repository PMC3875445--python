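"""End-to-end orchestration: simulate -> quantify -> differential ->
overlap -> select -> cluster -> qpcr, with a YAML-configurable, seeded,
fully reproducible run that writes every stage table plus a JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, differential, qpcr, selection, synthetic
from .cluster import cluster_profiles
from .quantify import CountMatrix, compute_rpkm, summarize_composition

log = logging.getLogger("mirshift")

ALL_STAGES = ("simulate", "quantify", "diff", "select", "cluster", "qpcr")


@dataclass
class PipelineConfig:
    """Resolved run parameters. Unknown YAML keys are rejected."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    counts_path: str | None = None     # use an existing count matrix instead of simulating
    alpha: float = 0.05
    min_fold: float = 1.5
    test_method: str = "exact"
    pseudocount: float = 0.5
    top_n: int = 100
    ts_tf_max: float = 20.0
    min_tf: float = 4.0
    top_pool: str = "L1"
    annotations_path: str | None = None
    cluster_top_features: int = 50
    qpcr_n_replicates: int = 6
    qpcr_ct_sd: float = 0.2
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw = {**raw, "stages": tuple(raw["stages"])}
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        sim_known = {f.name for f in dataclasses.fields(synthetic.SimulationConfig)}
        sim_unknown = set(cfg.simulation) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation key(s): {sorted(sim_unknown)}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def simulation_config(self) -> synthetic.SimulationConfig:
        return synthetic.SimulationConfig(seed=self.seed, **self.simulation)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages; returns (and writes) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    (outdir / "config.resolved.yaml").write_text(cfg_yaml, encoding="utf-8")
    report: dict = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stages_run": [],
    }
    log.info("run start: seed=%s config_sha=%s", config.seed, report["config_sha256"][:12])

    counts: CountMatrix | None = None
    experiment = None
    stage = "simulate"
    try:
        if "simulate" in config.stages:
            experiment = synthetic.simulate_experiment(config.simulation_config())
            experiment.write(outdir / "synthetic")
            counts = experiment.counts
            report["stages_run"].append(stage)
            report["simulate"] = {
                "n_features": len(experiment.catalog.entries),
                "tumour_detectable": experiment.catalog.n_tumour_detectable,
                "serum_detectable": experiment.catalog.n_serum_detectable,
            }
        elif config.counts_path:
            counts = CountMatrix.from_tsv(config.counts_path)

        stage = "quantify"
        rpkm = None
        if "quantify" in config.stages and counts is not None:
            rpkm = compute_rpkm(counts)
            rpkm.to_csv(outdir / "rpkm.tsv", sep="\t")
            comp_src = (
                experiment.compositions
                if experiment is not None
                else datasets.LIBRARY_CLASS_COUNTS
            )
            comp = summarize_composition(comp_src)
            comp.to_tsv(outdir / "composition.tsv")
            report["stages_run"].append(stage)
            report["quantify"] = {
                "composition_percent": {
                    lib: comp.percentages.loc[lib].to_dict()
                    for lib in comp.percentages.index
                }
            }

        stage = "diff"
        diff_t = diff_s = None
        if "diff" in config.stages and counts is not None:
            diff_t = differential.differential_table(
                counts, "L1", "L2", "tumour",
                config.alpha, config.min_fold, config.test_method, config.pseudocount,
            )
            diff_s = differential.differential_table(
                counts, "L3", "L4", "serum",
                config.alpha, config.min_fold, config.test_method, config.pseudocount,
            )
            pd.concat([diff_t, diff_s]).to_csv(outdir / "differential.tsv", sep="\t")
            t_aff = diff_t.index[diff_t["affected"]]
            s_aff = diff_s.index[diff_s["affected"]]
            part = differential.overlap_partition(t_aff, s_aff)
            report["stages_run"].append(stage)
            report["diff"] = {
                "tumour_affected": {
                    "up": int((diff_t["affected"] & (diff_t["direction"] == "up")).sum()),
                    "down": int((diff_t["affected"] & (diff_t["direction"] == "down")).sum()),
                },
                "serum_affected": {
                    "up": int((diff_s["affected"] & (diff_s["direction"] == "up")).sum()),
                    "down": int((diff_s["affected"] & (diff_s["direction"] == "down")).sum()),
                },
                "overlap": part.counts,
            }

        stage = "select"
        if "select" in config.stages and rpkm is not None:
            ann = (
                selection.load_annotations(config.annotations_path)
                if config.annotations_path
                else None
            )
            cand = selection.prioritize(
                rpkm, ann, config.top_n, config.ts_tf_max, config.min_tf, config.top_pool
            )
            cand.to_csv(outdir / "candidates.tsv", sep="\t")
            report["stages_run"].append(stage)
            report["select"] = {
                "n_candidates": int(len(cand)),
                "n_selected": int(cand["selected"].sum()),
                "annotated_selected": list(selection.annotated_selection(cand).index),
            }

        stage = "cluster"
        if "cluster" in config.stages and rpkm is not None:
            # cluster the most abundant affected-ish features for a readable map
            keep = (
                rpkm.loc[(rpkm > 0).all(axis=1)]
                .assign(_s=lambda d: d.sum(axis=1))
                .sort_values("_s", ascending=False)
                .drop(columns="_s")
                .head(config.cluster_top_features)
            )
            z, genes, samples = cluster_profiles(keep)
            z.to_csv(outdir / "zscores.tsv", sep="\t")
            (outdir / "genes.nwk").write_text(genes.to_newick(), encoding="utf-8")
            (outdir / "samples.nwk").write_text(samples.to_newick(), encoding="utf-8")
            report["stages_run"].append(stage)
            report["cluster"] = {
                "n_features": int(len(keep)),
                "sample_leaf_order": [samples.labels[i] for i in samples.leaf_order],
            }

        stage = "qpcr"
        if "qpcr" in config.stages and experiment is not None:
            nine_like = experiment.catalog.affected("tumour")[:9]
            truth = experiment.catalog.entries.loc[nine_like, "tumour_effect"]
            plate = synthetic.simulate_qpcr(
                truth,
                synthetic.QpcrSimConfig(
                    seed=config.seed,
                    n_replicates=config.qpcr_n_replicates,
                    ct_sd=config.qpcr_ct_sd,
                ),
            )
            plate.to_csv(outdir / "qpcr_plate.csv", index=False)
            summary = qpcr.analyse_plate(
                plate, list(truth.index), list(datasets.REFERENCE_GENE_CANDIDATES)
            )
            report["stages_run"].append(stage)
            report["qpcr"] = summary
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8",
    )
    log.info("run complete: %s", ", ".join(report["stages_run"]) or "no stages")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
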