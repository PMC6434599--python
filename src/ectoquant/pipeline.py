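"""Run orchestration: simulate -> quantify/summarize/prep -> compare.

A run is a directory of stage outputs plus a manifest tying every number in
the final report back to a stage file: inputs, outputs, SHA-256 checksums,
the configuration echo, library versions and the seed.  Stages execute in
dependency order in a single process; any stage failure aborts the run with
the stage name, leaving partial outputs behind next to a ``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simgen import (
    CohortSimParams,
    TissueSimParams,
    write_simulation,
    GROUP_CASE,
)
from .imquant import (
    QuantConfig,
    ThresholdSpec,
    read_image_bundle,
    read_regions,
    quantify_image,
    records_to_frame,
)
from .flowsum import FlowEvents, GateTree, default_gate_tree, summarize_sample, cmc_inclusion
from .tabprep import prepare_analytes
from .stats import adjusted_comparison, detectability_comparison, fisher_exact

log = logging.getLogger("ectoquant")

__all__ = ["RunConfig", "run", "ALL_STAGES"]

ALL_STAGES = ("simulate", "quantify-images", "summarize-flow", "prep-analytes", "compare")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML/JSON loadable)."""

    seed: int = 0
    out_dir: str = "ectoquant-run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    n_case: int = 15
    n_control: int = 20
    image_size_px: int = 256
    n_flow_events: int = 20000
    tophat_radius_px: int = 10
    threshold_a_fixed: float = 500.0
    threshold_b_scale_k: float = 2.0
    gate_tree_path: str | None = None
    limits_path: str | None = None
    covariates: list[str] = field(default_factory=lambda: ["duration_sex_work", "douching"])
    min_cd3: int = 100

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls(**doc)

    def validate_paths(self) -> None:
        for attr in ("gate_tree_path", "limits_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: no such file: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _quant_config(cfg: RunConfig) -> QuantConfig:
    return QuantConfig(
        threshold_a=ThresholdSpec(mode="fixed", fixed_value=cfg.threshold_a_fixed),
        threshold_b=ThresholdSpec(mode="quartile_scaled", scale_k=cfg.threshold_b_scale_k),
        tophat_radius_px=cfg.tophat_radius_px,
    )


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config),
        "versions": {
            "ectoquant": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "stages": {},
    }
    stage = None
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s", stage)
            outputs = _STAGE_FNS[stage](config, out, data_dir)
            manifest["stages"][stage] = {
                "outputs": {
                    str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
                }
            }
    except Exception as exc:
        failed_marker.write_text(f"stage {stage!r} failed: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, data_dir: Path) -> list[Path]:
    cohort = CohortSimParams(
        n_case=cfg.n_case,
        n_control=cfg.n_control,
        effects={"MIP-1a": 1.0, "MIP-3a": 0.9},
        censor_rates={
            "case": {"IL-1b": 0.0, "MIP-1a": 0.07},
            "control": {"IL-1b": 0.63, "MIP-1a": 0.67},
        },
        seed=cfg.seed,
    )
    tissue = TissueSimParams(
        height_px=cfg.image_size_px, width_px=cfg.image_size_px, seed=cfg.seed
    )
    sim_manifest = write_simulation(
        data_dir, cohort, tissue=tissue, n_flow_events=cfg.n_flow_events
    )
    return [data_dir / f for f in sim_manifest["files"]] + [data_dir / "manifest.json"]


def _stage_quantify(cfg: RunConfig, out: Path, data_dir: Path) -> list[Path]:
    images = pd.read_csv(data_dir / "images.tsv", sep="\t")
    qc = _quant_config(cfg)
    records = []
    for _, row in images.iterrows():
        bundle = read_image_bundle(data_dir / row["image"])
        regions = read_regions(data_dir / row["regions"])
        records.append(quantify_image(bundle, regions, qc))
    frame = records_to_frame(records)
    frame.insert(1, "group", images["group"].to_numpy())
    path = out / "image_quant.tsv"
    frame.to_csv(path, sep="\t", index=False)
    audit = out / "image_quant_audit.json"
    audit.write_text(json.dumps(qc.audit(), indent=1))
    return [path, audit]


def _stage_flow(cfg: RunConfig, out: Path, data_dir: Path) -> list[Path]:
    subjects = pd.read_csv(data_dir / "subjects.tsv", sep="\t")
    tree = (
        GateTree.from_json(Path(cfg.gate_tree_path))
        if cfg.gate_tree_path
        else default_gate_tree()
    )
    rows = []
    for _, subj in subjects.iterrows():
        df = pd.read_csv(data_dir / f"flow_{subj['subject_id']}.tsv", sep="\t")
        events = FlowEvents(data=df, sample_id=subj["subject_id"], compartment="blood")
        included = (
            cmc_inclusion(events, tree, min_cd3=cfg.min_cd3)
            if events.compartment == "cervical"
            else True
        )
        row = summarize_sample(events, tree)
        row["group"] = subj["group"]
        row["included"] = included
        rows.append(row)
    path = out / "flow_summary.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    tree_path = out / "gate_tree.json"
    tree.to_json(tree_path)
    return [path, tree_path]


def _stage_prep(cfg: RunConfig, out: Path, data_dir: Path) -> list[Path]:
    cyto = pd.read_csv(data_dir / "cytokines.tsv", sep="\t")
    limits = pd.read_csv(
        Path(cfg.limits_path) if cfg.limits_path else data_dir / "limits.tsv", sep="\t"
    )
    prepared = prepare_analytes(cyto, limits)
    path = out / "analytes_prepared.tsv"
    prepared.to_csv(path, sep="\t", index=False)
    return [path]


def _stage_compare(cfg: RunConfig, out: Path, data_dir: Path) -> list[Path]:
    subjects = pd.read_csv(data_dir / "subjects.tsv", sep="\t")
    subjects["group_code"] = (subjects["group"] == GROUP_CASE).astype(int)
    covars = subjects[["subject_id", "group", "group_code", *cfg.covariates]]

    endpoints: list[tuple[str, pd.DataFrame]] = []
    quant_path = out / "image_quant.tsv"
    if quant_path.exists():
        q = pd.read_csv(quant_path, sep="\t")
        q = q.rename(columns={"image_id": "subject_id"})
        endpoints += [
            (c, q[["subject_id", c]])
            for c in ("pct_a_total", "pct_b_total", "pct_ab_total", "pct_ab_of_a")
        ]
    flow_path = out / "flow_summary.tsv"
    if flow_path.exists():
        fl = pd.read_csv(flow_path, sep="\t")
        fl = fl.rename(columns={"sample_id": "subject_id"})
        fl = fl[fl["included"]]
        cols = [c for c in fl.columns if c.startswith(("pct_", "mfi_"))]
        endpoints += [(c, fl[["subject_id", c]]) for c in cols]
    prep_path = out / "analytes_prepared.tsv"
    detect_rows = []
    if prep_path.exists():
        prep = pd.read_csv(prep_path, sep="\t")
        for analyte, sub in prep.groupby("analyte"):
            wide = sub.rename(columns={"sample_id": "subject_id"})
            endpoints.append(
                (f"log10_{analyte}", wide[["subject_id", "log10_value"]].rename(
                    columns={"log10_value": f"log10_{analyte}"}))
            )
            merged = wide[["subject_id", "detectable"]].merge(covars, on="subject_id")
            table, p = detectability_comparison(
                merged["detectable"].to_numpy(), merged["group"].to_numpy()
            )
            detect_rows.append(
                {"analyte": analyte, "table": table.tolist(), "fisher_p": p}
            )

    results = []
    run_log: dict = {"endpoints": {}, "detectability": detect_rows}
    for name, frame in endpoints:
        merged = covars.merge(frame, on="subject_id")
        try:
            res = adjusted_comparison(merged, name, covariates=cfg.covariates)
        except ValueError as exc:
            run_log["endpoints"][name] = {"error": str(exc)}
            continue
        results.append(
            {
                "endpoint": name,
                "n_case": res.n_per_group[0],
                "n_control": res.n_per_group[1],
                "median_case": res.medians[0],
                "median_control": res.medians[1],
                "iqr_case": f"{res.iqrs[0][0]:.3g}-{res.iqrs[0][1]:.3g}",
                "iqr_control": f"{res.iqrs[1][0]:.3g}-{res.iqrs[1][1]:.3g}",
                "univariate_test": res.univariate_test,
                "univariate_p": res.univariate_p,
                "group_coef": res.group_coef,
                "adjusted_p": res.adjusted_p,
                "covariates": "+".join(res.covariates),
            }
        )
        run_log["endpoints"][name] = {
            "shapiro_p": list(res.shapiro_p),
            "n_dropped_missing": res.n_dropped_missing,
            "degenerate": res.degenerate,
        }

    # group-difference table for the confounders themselves
    douche_table = pd.crosstab(subjects["douching"], subjects["group"])
    try:
        run_log["douching_fisher_p"] = fisher_exact(douche_table.to_numpy()[::-1])
    except ValueError as exc:  # degenerate table in a tiny cohort
        run_log["douching_fisher_p"] = None
        run_log["douching_fisher_error"] = str(exc)

    res_path = out / "comparisons.tsv"
    pd.DataFrame(results).to_csv(res_path, sep="\t", index=False)
    log_path = out / "compare_log.json"
    log_path.write_text(json.dumps(run_log, indent=1, default=str))
    report = out / "report.txt"
    with report.open("w") as fh:
        fh.write("Two-group comparison report (case = DMPA, control = no HC)\n")
        fh.write(f"n = {cfg.n_case} cases / {cfg.n_control} controls\n\n")
        for r in results:
            fh.write(
                f"{r['endpoint']}: median {r['median_case']:.3g} vs "
                f"{r['median_control']:.3g}; univariate p={r['univariate_p']:.3g}; "
                f"adjusted p={r['adjusted_p']:.3g} "
                f"(coef {r['group_coef']:.3g}, adj. {r['covariates']})\n"
            )
    return [res_path, log_path, report]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "quantify-images": _stage_quantify,
    "summarize-flow": _stage_flow,
    "prep-analytes": _stage_prep,
    "compare": _stage_compare,
}
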