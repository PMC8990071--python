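"""End-to-end orchestration: margin filter -> batch correction -> cell
typing -> molar calibration -> apoptosis simulations -> heterogeneity
summaries.

Batch correction needs a reference immune population before the final
classifier has run, so the pipeline first annotates all cells through the
gating hierarchy with slide-dependent thresholds, corrects batches against
the gate-called regulatory/helper T cells, then trains the random forest
on a gate-labeled subset using corrected intensities as features — the
two-pass structure the assay requires.

All randomness flows from one root seed through named substreams, so a
rerun with the same config reproduces every output table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import batch as batch_mod
from . import calibration as calib_mod
from . import celltyping as typing_mod
from . import heterogeneity as het_mod
from .caspase import CaspaseParameters, quadrant_classify, simulate_caspase
from .cohort import CohortTable, filter_margins, write_cohort
from .momp import MompParameters, required_stress_dose, simulate_momp
from .panel import APOPTOSIS_MARKERS
from .synthetic import GeneratorConfig, generate_cohort


@dataclass
class PipelineConfig:
    """One config for the whole run; every stage reads from here."""

    outdir: str = "results"
    seed: int = 0
    mode: str = "per_cell"  # per_cell | per_core | both
    # stage toggles
    do_margin_filter: bool = True
    do_batch_correction: bool = True
    do_required_dose: bool = False  # bisection per cell is costly; opt in
    # stage parameters
    x_margin: float = 15.0
    y_margin: float = 10.0
    min_population: int = 100
    training_frac: float = 0.006
    n_trees: int = 2000
    min_train: int = 20
    min_ref: int = 50  # reference cells per slide for the rankit fit
    momp: MompParameters = field(default_factory=MompParameters)
    caspase: CaspaseParameters = field(default_factory=CaspaseParameters)
    standards: calib_mod.ReferenceStandards = field(
        default_factory=calib_mod.example_standards
    )
    generator: GeneratorConfig | None = None  # used when no input table given

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        kwargs = dict(data)
        if "momp" in kwargs:
            kwargs["momp"] = MompParameters(**kwargs["momp"])
        if "caspase" in kwargs:
            kwargs["caspase"] = CaspaseParameters(**kwargs["caspase"])
        if "standards" in kwargs:
            s = kwargs["standards"]
            kwargs["standards"] = calib_mod.ReferenceStandards(
                hela_mean_intensity=s["hela_mean_intensity"],
                hela_concentration_um=s["hela_concentration_um"],
                cohort_reference_um={m: tuple(v) for m, v in s["cohort_reference_um"].items()},
                apaf1_um=s.get("apaf1_um", calib_mod.APAF1_DEFAULT_UM),
            )
        if "generator" in kwargs and kwargs["generator"] is not None:
            g = dict(kwargs["generator"])
            for key in ("cores_per_patient", "qc_beta"):
                if key in g:
                    g[key] = tuple(g[key])
            kwargs["generator"] = GeneratorConfig(**g)
        return cls(**kwargs)


def _substreams(seed: int) -> dict[str, int]:
    """Named integer sub-seeds derived from the root seed (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    names = ("generate", "annotate", "train", "bootstrap")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


class _RunLog:
    """JSON-lines log reconciling cell counts in/out per stage."""

    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict] = []

    def stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        entry = {"stage": name, "cells_in": n_in, "cells_out": n_out,
                 "cells_excluded": n_in - n_out, **extra}
        self.entries.append(entry)

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")


def _simulate_cells(profiles: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Run both ODE models for every profile row; returns readout table."""
    rows = []
    for pid, prof in profiles.iterrows():
        p = prof.to_dict()
        sim_m = simulate_momp(p, cfg.momp.reference_stress_dose_nM, cfg.momp)
        sim_c = simulate_caspase(p, cfg.caspase)
        momp_low = sim_m.max_pore_pct < cfg.momp.pore_threshold_pct
        row = {
            "id": pid,
            "max_pore_pct": sim_m.max_pore_pct,
            "momp_low": momp_low,
            "sc_pct": sim_c.substrate_cleavage_pct,
            "caspase_high": sim_c.high_activity,
            "quadrant": quadrant_classify(not momp_low, sim_c.high_activity),
        }
        if cfg.do_required_dose:
            row["required_stress_nM"] = required_stress_dose(p, cfg.momp)
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def run_pipeline(
    config: PipelineConfig,
    table: CohortTable | None = None,
) -> dict[str, pd.DataFrame | CohortTable]:
    """Execute the full analysis; returns result tables and writes them
    (plus a JSON-lines stage log) under ``config.outdir``."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _substreams(cfg.seed)
    log = _RunLog(outdir / "pipeline_log.jsonl")

    if table is None:
        gen = cfg.generator or GeneratorConfig()
        gen = dataclasses.replace(gen, seed=seeds["generate"])
        table, truth = generate_cohort(gen)
        truth.cells.to_csv(outdir / "ground_truth_cells.csv", index=False)
        log.stage("generate", len(table), len(table), seed=seeds["generate"])

    n0 = len(table)
    if cfg.do_margin_filter:
        table = filter_margins(table, cfg.x_margin, cfg.y_margin)
        log.stage("margin_filter", n0, len(table))

    # preliminary gate annotation of ALL cells with slide-dependent
    # thresholds: defines the batch-correction reference population
    all_annot = typing_mod.annotate_per_slide(table, sample_frac=1.0,
                                              seed=seeds["annotate"])
    prelim = table.copy()
    prelim.cells.loc[all_annot.index, "cell_type"] = all_annot["gate_label"]

    if cfg.do_batch_correction:
        corrected, batch_model = batch_mod.correct_batch(prelim, min_ref=cfg.min_ref)
        batch_model.to_yaml(outdir / "batch_model.yaml")
        log.stage("batch_correction", len(prelim), len(corrected))
    else:
        corrected, batch_model = prelim, None
        log.stage("batch_correction", len(prelim), len(prelim), skipped=True)

    # final typing: the gate annotations (slide-wise, pre-correction) are
    # the training labels; corrected intensities are the features
    rng = np.random.default_rng(seeds["annotate"])
    n_train = max(1, int(round(cfg.training_frac * len(corrected))))
    train_idx = rng.choice(corrected.cells.index, size=min(n_train, len(corrected)),
                           replace=False)
    # top up classes the random sample under-represents (annotator analogue:
    # rare populations are annotated deliberately, not by lottery)
    chosen = set(train_idx)
    labels_all = all_annot["gate_label"]
    for cls, n_have in labels_all.loc[train_idx].value_counts().reindex(
            labels_all.unique(), fill_value=0).items():
        if n_have < cfg.min_train:
            pool = labels_all.index[(labels_all == cls) & ~labels_all.index.isin(chosen)]
            extra = rng.choice(pool, size=min(cfg.min_train - n_have, len(pool)),
                               replace=False)
            chosen.update(extra)
    train_idx = np.array(sorted(chosen))
    labeled = corrected.cells.loc[train_idx].copy()
    labeled["gate_label"] = labels_all.loc[train_idx]
    model = typing_mod.train_classifier(
        labeled, n_trees=cfg.n_trees, seed=seeds["train"], min_train=cfg.min_train)
    typed = typing_mod.classify(corrected, model)
    log.stage("cell_typing", len(corrected), len(typed),
              oob_type2_error=model.oob_type2_error)

    fractions = typing_mod.type_fractions(typed)
    fractions.to_csv(outdir / "type_fractions.csv")

    results: dict[str, pd.DataFrame | CohortTable] = {
        "table": typed,
        "type_fractions": fractions,
    }

    modes = ("per_cell", "per_core") if cfg.mode == "both" else (cfg.mode,)
    for mode in modes:
        per = "cell" if mode == "per_cell" else "core"
        profiles = calib_mod.calibrate_profiles(typed, cfg.standards, per=per)
        readouts = _simulate_cells(profiles, cfg)
        profiles.to_csv(outdir / f"profiles_{mode}.csv")
        readouts.to_csv(outdir / f"model_readouts_{mode}.csv")
        results[f"profiles_{mode}"] = profiles
        results[f"readouts_{mode}"] = readouts
        log.stage(f"simulate_{mode}", len(profiles), len(readouts))

    if "per_cell" in modes:
        merged = typed.cells.merge(
            results["readouts_per_cell"], left_on="cell_id", right_index=True)
        summary = het_mod.core_summary(
            merged, markers=APOPTOSIS_MARKERS, min_n=cfg.min_population)
        summary.to_csv(outdir / "core_summary.csv", index=False)
        results["core_summary"] = summary
        results["cells_with_readouts"] = merged
        log.stage("heterogeneity", len(merged), len(merged))

    write_cohort(typed, outdir / "cohort_typed.csv")
    log.flush()
    return results


def report_summary(results: Mapping[str, pd.DataFrame | CohortTable]) -> str:
    """Human-readable run report (plain text tables)."""
    lines: list[str] = []
    if not results or "table" not in results:
        return "WARNING: empty results; nothing to report\n"
    table: CohortTable = results["table"]  # type: ignore[assignment]
    lines.append(f"cells analyzed: {len(table)}")
    fr = results.get("type_fractions")
    if fr is not None and len(fr):
        lines.append("\ncell-type fractions per core:")
        lines.append(fr.round(3).to_string())
        lines.append("\ncohort mean fractions:")
        lines.append(fr.mean(axis=0).round(3).to_string())
    cells = table.cells
    if "cell_type" in cells.columns:
        from .panel import BROAD_STRATA
        lines.append("\nmedian marker intensity by stratum (apoptosis panel):")
        rows = {}
        for stratum, types in BROAD_STRATA.items():
            sub = cells[cells["cell_type"].isin(types)]
            if len(sub):
                rows[stratum] = sub[list(APOPTOSIS_MARKERS)].median()
        if rows:
            lines.append(pd.DataFrame(rows).round(2).to_string())
    summary = results.get("core_summary")
    if summary is not None and len(summary):
        qcols = [c for c in summary.columns if c.startswith("frac_") and
                 any(q in c for q in ("both", "only"))]
        cancer = summary[summary["stratum"] == "cancer"]
        if len(cancer) and qcols:
            lines.append("\npathway-quadrant fractions (cancer cells, per core):")
            lines.append(
                cancer.set_index("core_id")[qcols].round(3).to_string())
    lines.append("\n(group comparisons, when requested, use routine statistics"
                 " — ANOVA/Tukey — via statsmodels/scipy)")
    return "\n".join(lines) + "\n"
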