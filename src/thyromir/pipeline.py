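"""End-to-end orchestration and tabular IO.

`run_pipeline` takes a raw-Cq or panel table through normalization, QC
exclusions, molecular regrouping, the fixed classifiers, a re-trained tree
and the accuracy report, writing a reproducible bundle of TSV/JSON/text
artifacts.  All tables are UTF-8 TSV with a header; missing values are empty
fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import markers as mk
from . import normalize as norm
from .metrics import kfold_cv, per_class_metrics, total_error, ConfusionMatrix, discordance_report
from .model import DEFAULT_FEATURES
from .reclassify import (ReclassThresholds, binary_labels, composition_report,
                         histology_binary, molecular_grouping)
from .tree import (C45Params, UnclassifiableError, c45_train,
                   fixed_malignancy_tree, fixed_typing_tree, render_tree)

log = logging.getLogger("thyromir")


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str | None = None
    output_dir: str = "thyromir_out"
    thresholds: ReclassThresholds = field(default_factory=ReclassThresholds)
    c45: C45Params = field(default_factory=C45Params)
    cv_k: int = 5
    seed: int = 0
    group_by: str = "sample"          # or "patient"
    rna_threshold: float = norm.LOW_RNA_THRESHOLD
    features: tuple[str, ...] = DEFAULT_FEATURES
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = ReclassThresholds(**raw["thresholds"])
        if "c45" in raw:
            raw["c45"] = C45Params(**raw["c45"])
        if "features" in raw:
            raw["features"] = tuple(raw["features"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# tabular IO

def read_marker_table(path) -> pd.DataFrame:
    """Read a cohort table (raw-Cq or panel mode) from TSV.

    Missing values are empty fields; malformed numeric cells are reported
    with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in ("sample_id", "histotype") if c not in df.columns]
    if required:
        raise ValueError(f"{path}: missing mandatory columns {required}")
    numeric = [c for c in df.columns
               if c.startswith(("cq_", "level_", "mut_", "fus_"))
               or c in ("rna_ng_ul", "mtdna_ratio")]
    for col in numeric:
        raw = df[col].replace("", None)
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: malformed value {raw[bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = parsed
    for col in mk.MUTATION_COLUMNS:
        if col in df:
            df[col] = df[col].astype("Int64")
    return df


def write_marker_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, table: pd.DataFrame | None = None) -> dict:
    """Run the full analysis; returns the artifact dictionary and writes the
    report bundle under ``config.output_dir``.

    Stages: (1) normalization if the input is a raw-Cq table; (2) QC
    exclusions (anaplastic specimens, low RNA, BRAF-discordant histology);
    (3) molecular regrouping; (4) fixed-tree classification with leaf traces;
    (5) C4.5 re-training on the molecular binary label with k-fold CV;
    (6) accuracy tables and the histology-vs-molecular discordance summary.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = read_marker_table(config.input_path)

    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 1. normalization
    if any(c.startswith("cq_") for c in table.columns):
        log.info("normalizing %d raw-Cq records", len(table))
        panels = norm.normalize_table(table)
    else:
        panels = table.copy()

    # 2. exclusions
    exclusions = []
    panels, ana = norm.anaplastic_filter(panels)
    exclusions += [(sid, "anaplastic specimen") for sid in ana["sample_id"]]
    panels, low = norm.qc_low_rna(panels, config.rna_threshold)
    exclusions += [(sid, f"total RNA below {config.rna_threshold} ng/ul")
                   for sid in low["sample_id"]]
    panels, braf = norm.braf_discordance_filter(panels)
    exclusions += [(sid, "BRAF V600E in non-papillary histotype")
                   for sid in braf["sample_id"]]
    panels = panels.reset_index(drop=True)
    log.info("%d samples reach analysis (%d excluded)", len(panels), len(exclusions))

    # 3. molecular regrouping (samples with missing key markers are reported
    # and set aside rather than aborting the run)
    grouping, problems = molecular_grouping(panels, config.thresholds,
                                            errors="report")
    if problems:
        exclusions += [(sid, f"unclassifiable: {reason}") for sid, reason in problems]
        panels = panels.loc[panels["sample_id"].isin(grouping.index)].reset_index(drop=True)
        log.warning("%d samples unclassifiable in molecular regrouping", len(problems))
    binary = binary_labels(grouping)
    composition = composition_report(
        grouping, panels.set_index("sample_id")["histotype"]
    )
    panels_cls = panels.assign(
        molecular_class=grouping.reindex(panels["sample_id"]).values,
        molecular_binary=binary.reindex(panels["sample_id"]).values,
    )

    # 4. fixed trees
    mal_tree, typ_tree = fixed_malignancy_tree(), fixed_typing_tree()
    fixed_rows = []
    for _, row in panels_cls.iterrows():
        try:
            mal, mal_trace = mal_tree.classify(row)
        except UnclassifiableError as e:
            mal, mal_trace = "", [str(e)]
        try:
            typ, typ_trace = typ_tree.classify(row)
        except UnclassifiableError as e:
            typ, typ_trace = "", [str(e)]
        fixed_rows.append({
            "sample_id": row["sample_id"],
            "malignancy_call": mal, "malignancy_trace": " | ".join(mal_trace),
            "typing_call": typ, "typing_trace": " | ".join(typ_trace),
        })
    fixed_calls = pd.DataFrame(fixed_rows)

    # 5. trained tree + CV on the molecular binary label
    trained = c45_train(panels_cls, "molecular_binary", config.features, config.c45)
    cv = kfold_cv(panels_cls, "molecular_binary", config.features, config.c45,
                  k=config.cv_k, seed=config.seed, group_by=config.group_by)

    # 6. metrics and discordance
    hist_binary = histology_binary(panels_cls["histotype"])
    classified = fixed_calls["malignancy_call"] != ""
    cm_fixed = ConfusionMatrix.from_labels(
        panels_cls.loc[classified.values, "molecular_binary"],
        fixed_calls.loc[classified, "malignancy_call"].str.lower(),
        ("benign", "malignant"),
    )
    metrics_tbl = per_class_metrics(cv.training_confusion).join(
        per_class_metrics(cv.cv_confusion), lsuffix="_train", rsuffix="_cv"
    )
    discord = discordance_report(binary.reindex(panels_cls["sample_id"]).values,
                                 hist_binary.values)

    artifacts = {
        "panels": panels_cls,
        "exclusions": pd.DataFrame(exclusions, columns=["sample_id", "reason"]),
        "molecular_classes": grouping,
        "composition": composition,
        "fixed_tree_calls": fixed_calls,
        "fixed_vs_molecular_confusion": cm_fixed,
        "trained_tree": trained,
        "trained_tree_text": render_tree(trained),
        "cv": cv,
        "metrics": metrics_tbl,
        "total_error": cv.total_error,
        "cv_total_error": cv.cv_total_error,
        "discordance": discord,
    }

    # write the bundle
    write_marker_table(panels_cls, outdir / "panels.tsv")
    artifacts["exclusions"].to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    grouping.rename_axis("sample_id").reset_index().to_csv(
        outdir / "molecular_classes.tsv", sep="\t", index=False)
    composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    fixed_calls.to_csv(outdir / "fixed_tree_calls.tsv", sep="\t", index=False)
    (outdir / "trained_tree.txt").write_text(artifacts["trained_tree_text"] + "\n",
                                             encoding="utf-8")
    trained.to_json(outdir / "trained_tree.json")
    metrics_tbl.rename_axis("class").reset_index().to_csv(
        outdir / "metrics.tsv", sep="\t", index=False)
    with open(outdir / "discordance.json", "w", encoding="utf-8") as fh:
        json.dump(discord, fh, indent=2)
    return artifacts
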