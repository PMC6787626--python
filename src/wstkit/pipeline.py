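"""End-to-end orchestration: synthesise/ingest -> score -> impute -> test ->
model -> ROC -> reference intervals, with seeded reproducibility.

A single global seed fans out to per-stage seeds via stable hashing of the
stage name, so any stage can be rerun in isolation and reproduce its part
of a full run.  Every stage logs its input/output row counts so exclusion
arithmetic stays auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wstkit import defaults
from wstkit.forest import RFParams, TreeParams, fit_rf, fit_decision_tree
from wstkit.intervals import class_reference_intervals, intervals_frame, overlap_matrix
from wstkit.preprocessing import impute_markers, summarise_markers
from wstkit.roc import pairwise_class_roc
from wstkit.scoring import score_table
from wstkit.synthetic import CohortConfig, default_cohort_config, generate_cohort
from wstkit.trend_tests import run_marker_tests

log = logging.getLogger("wstkit")

REQUIRED_COLUMNS = (
    "participant_id",
    "diagnosis",
    "standing_time",
    "difficulty",
    "hr_supine",
    "hr_standing_max",
)

CLASS_PAIRS = ((0, 1), (0, 2), (1, 2))


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class PipelineConfig:
    input_path: str | None = None
    synthetic: CohortConfig | None = None
    feature_panel: tuple[str, ...] = defaults.DEFAULT_FEATURE_PANEL
    impute_markers: tuple[str, ...] = defaults.URINE_MARKERS
    impute_on: str = "class4"          # impute before merging classes by default
    alpha: float = 0.05
    rf: RFParams = field(default_factory=RFParams)
    tree: TreeParams = field(default_factory=TreeParams)
    correct_only_intervals: bool = True
    output_dir: str = "wstkit_out"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be set")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV/TSV.

    Empty cells become missing values; any non-numeric cell in a numeric
    column raises with its row and column.  Unknown columns are preserved.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required column(s): {missing}")
    numeric_cols = [c for c in table.columns if c not in ("participant_id", "diagnosis")]
    for col in numeric_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {col!r}, row(s) {bad.tolist()[:5]}"
            )
        table[col] = coerced
    n_missing = int(table[numeric_cols].isna().sum().sum())
    log.info("read %d rows from %s (%d missing numeric cells)", len(table), path, n_missing)
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write a report bundle.

    Returns a manifest dict mapping stage names to their artefact paths.
    Identical config and seed produce a byte-identical bundle.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"seed": config.seed, "stages": {}}

    def emit(stage: str, name: str, writer) -> Path:
        p = out / name
        writer(p)
        manifest["stages"].setdefault(stage, []).append(name)
        return p

    try:
        # -- cohort -------------------------------------------------------
        if config.synthetic is not None:
            cfg = config.synthetic
            cohort = generate_cohort(cfg)
        else:
            cohort = read_cohort(config.input_path)
        log.info("cohort: %d rows", len(cohort))
        emit("cohort", "cohort.csv", lambda p: cohort.to_csv(p, index=False))

        # -- scoring ------------------------------------------------------
        scored = score_table(cohort)
        emit("score", "scored.csv", lambda p: scored.to_csv(p, index=False))

        # -- imputation ---------------------------------------------------
        present = [m for m in config.impute_markers if m in scored.columns]
        imputed = impute_markers(scored, present, config.impute_on)
        emit("impute", "imputed.csv", lambda p: imputed.to_csv(p, index=False))

        # -- descriptives and tests --------------------------------------
        markers = [m for m in defaults.MARKER_NAMES if m in imputed.columns]
        summary = summarise_markers(imputed, markers, "class3")
        emit("describe", "summaries.tsv",
             lambda p: summary.to_csv(p, sep="\t", index=False))
        tests = run_marker_tests(imputed, markers, "class3", alpha=config.alpha)
        emit("test", "tests.tsv", lambda p: tests.to_csv(p, sep="\t", index=False))

        # -- severity model ----------------------------------------------
        panel = [m for m in config.feature_panel if m in imputed.columns]
        rf_params = RFParams(
            mtry=config.rf.mtry, ntree=config.rf.ntree, replace=config.rf.replace,
            permutation_importance=config.rf.permutation_importance,
            seed=stage_seed(config.seed, "model"),
        )
        model = fit_rf(imputed[panel], imputed["class3"].to_numpy(), rf_params)
        emit("model", "rf_model.json", lambda p: p.write_text(model.to_json()))
        tree_params = TreeParams(
            minsplit=config.tree.minsplit, cp=config.tree.cp,
            seed=stage_seed(config.seed, "tree"),
        )
        tree = fit_decision_tree(imputed[panel], imputed["class3"].to_numpy(), tree_params)
        emit("model", "tree_rules.json", lambda p: p.write_text(json.dumps(
            [{"path": r.path, "class": int(r.predicted_class), "n": r.n,
              "accuracy": round(r.accuracy, 4)} for r in tree.rules], indent=2)))

        # -- ROC ----------------------------------------------------------
        aucs: dict[str, float] = {}
        for pair in CLASS_PAIRS:
            for correct_only in (False, True):
                key = f"{pair[0]}v{pair[1]}" + ("_correct" if correct_only else "")
                try:
                    roc = pairwise_class_roc(model, imputed, pair, correct_only)
                except ValueError as exc:
                    log.warning("roc %s skipped: %s", key, exc)
                    continue
                aucs[key] = round(roc.auc, 6)
                emit("roc", f"roc_{key}.tsv",
                     lambda p, r=roc: r.to_frame().to_csv(p, sep="\t", index=False))
        emit("roc", "aucs.json", lambda p: p.write_text(json.dumps(aucs, indent=2)))

        # -- reference intervals -----------------------------------------
        ivs = class_reference_intervals(imputed, panel, "class3")
        frames = [intervals_frame(ivs)]
        if config.correct_only_intervals:
            try:
                ivs_c = class_reference_intervals(
                    imputed, panel, "class3", correct_mask=model.correct_mask
                )
                frames.append(intervals_frame(ivs_c))
            except ValueError as exc:
                log.warning("correct-only intervals skipped: %s", exc)
        ri = pd.concat(frames, ignore_index=True)
        emit("ri", "reference_intervals.tsv",
             lambda p: ri.to_csv(p, sep="\t", index=False))
        for marker in panel:
            emit("ri", f"overlap_{marker}.tsv",
                 lambda p, m=marker: overlap_matrix(ivs, m).to_csv(p, sep="\t"))

        # -- summary report ----------------------------------------------
        report = _render_report(config, cohort, scored, summary, tests, model, aucs, ri)
        emit("report", "report.md", lambda p: p.write_text(report))
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _render_report(config, cohort, scored, summary, tests, model, aucs, ri) -> str:
    counts4 = scored["class4"].value_counts().sort_index()
    counts3 = scored["class3"].value_counts().sort_index()
    lines = [
        "# Severity analysis report",
        "",
        f"- seed: {config.seed}",
        f"- rows: {len(cohort)}",
        f"- 4-class sizes: {counts4.to_dict()}",
        f"- merged 3-class sizes: {counts3.to_dict()}",
        f"- POTS positive: {int(scored['pots'].sum())}",
        "",
        "## Forest (out-of-bag)",
        "",
        f"- overall OOB error: {model.oob_error_overall:.4f}",
        f"- per-class OOB error: {np.round(model.oob_error_per_class, 4).tolist()}",
        f"- confusion (rows=true): {model.oob_confusion.tolist()}",
        f"- permutation ranking: {model.ranking('permutation')}",
        f"- Gini ranking: {model.ranking('gini')}",
        "",
        "## Pairwise AUC",
        "",
    ]
    for k, v in aucs.items():
        lines.append(f"- {k}: {v}")
    lines += ["", "## Marker summaries (merged classes)", "",
              summary.round(4).to_csv(sep="|", index=False).strip()]
    lines += ["", "## Tests", "", tests.round(6).to_csv(sep="|", index=False).strip()]
    lines += ["", "## Reference intervals (median, 25th-75th IQR)", "",
              ri.round(4).to_csv(sep="|", index=False).strip(), ""]
    return "\n".join(lines)


def default_pipeline_config(seed: int = 0, output_dir: str = "wstkit_out",
                            ntree: int = 500) -> PipelineConfig:
    """Synthetic-cohort pipeline config with a desk-scale forest."""
    return PipelineConfig(
        synthetic=default_cohort_config(seed=stage_seed(seed, "synth")),
        rf=RFParams(ntree=ntree, seed=seed),
        output_dir=output_dir,
        seed=seed,
    )
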