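"""End-to-end orchestration: simulate/ingest → stats → classify → permute.

``run_full_pipeline`` executes the whole workflow from one config and
writes a deterministic report bundle (JSON results, CSV metric tables,
confusion-matrix heatmaps, volume box plots). Rerunning with an identical
config produces byte-identical JSON files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .feature_table import FeatureTable, VOLUME_FEATURES, read_table, write_table
from .metrics import ClassificationReport, ConfusionMatrix
from .nested_cv import CVConfig, fixed_pc_run
from .permutation import run_permutation_test
from .synthetic import SyntheticConfig, generate_cohort
from .volumetrics import region_analysis

logger = logging.getLogger("cryosperm")


@dataclass(frozen=True)
class PipelineConfig:
    """One serialised source of truth for a full run (manifest paths are
    relative to ``out_dir`` so reruns compare byte-identically)."""

    input_path: Optional[str] = None  # None -> simulate a cohort
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    label_columns: Sequence[str] = ("donor_id", "treatment")
    cv: CVConfig = field(default_factory=CVConfig)
    n_pcs: int = 5
    permutations: int = 1000
    volume_features: Sequence[str] = VOLUME_FEATURES
    out_dir: str = "cryosperm_out"

    def validate(self) -> None:
        if not self.label_columns:
            raise ValueError("at least one label target is required")


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def render_confusion_heatmap(
    report: ClassificationReport, path, title: str = ""
) -> None:
    """Confusion-matrix heatmap: blue diagonal, red off-diagonal shades,
    darker = higher; the per-class metrics table is drawn alongside."""
    cm = report.confusion
    counts = cm.counts.astype(float)
    c = len(cm.class_labels)
    diag = np.where(np.eye(c, dtype=bool), counts, np.nan)
    off = np.where(~np.eye(c, dtype=bool), counts, np.nan)
    fig, (ax, ax_tab) = plt.subplots(
        1, 2, figsize=(3 + 0.6 * c + 4, 2.5 + 0.45 * c), width_ratios=[1.3, 1]
    )
    vmax = max(counts.max(), 1.0)
    ax.imshow(off, cmap="Reds", vmin=0, vmax=vmax)
    ax.imshow(diag, cmap="Blues", vmin=0, vmax=vmax)
    for i in range(c):
        for j in range(c):
            if counts[i, j] > 0:
                ax.text(j, i, f"{int(counts[i, j])}", ha="center", va="center", fontsize=8)
    ax.set_xticks(range(c), [str(l) for l in cm.class_labels], rotation=45, ha="right")
    ax.set_yticks(range(c), [str(l) for l in cm.class_labels])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    ax_tab.axis("off")
    frame = report.to_frame().round(3).fillna("—")
    tab = ax_tab.table(
        cellText=frame.to_numpy(), colLabels=list(frame.columns), loc="center"
    )
    tab.auto_set_font_size(False)
    tab.set_fontsize(7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_volume_boxplot(table: FeatureTable, feature: str, grouping: str, path) -> None:
    labels = table.labels(grouping)
    order = list(dict.fromkeys(labels))
    values = [table.column(feature)[labels == g] for g in order]
    fig, ax = plt.subplots(figsize=(1.2 * len(order) + 2, 4))
    ax.boxplot(values, tick_labels=[str(g) for g in order])
    ax.set_ylabel(f"{feature} (µm³)")
    ax.set_xlabel(grouping)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return a manifest of the written artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": []}

    # stage 1 — cohort
    if config.input_path is None:
        logger.info("simulating cohort (seed %d)", config.synthetic.seed)
        table = generate_cohort(config.synthetic)
        cohort_path = out / "cohort.csv"
        write_table(table, cohort_path)
        manifest["outputs"].append(cohort_path.name)
    else:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"pipeline input not found: {path}")
        table = read_table(path)
    manifest["n_rows"] = len(table)

    # stage 2 — volumetric statistics
    volumetrics = {}
    for feature in config.volume_features:
        for grouping in ("treatment", "donor_id"):
            bundle = region_analysis(table, feature, grouping)
            volumetrics[f"{feature}__{grouping}"] = bundle.to_dict()
            plot_path = out / f"volumes_{feature}_{grouping}.png"
            render_volume_boxplot(table, feature, grouping, plot_path)
            manifest["outputs"].append(plot_path.name)
    vol_path = out / "volumetrics.json"
    _dump_json(volumetrics, vol_path)
    manifest["outputs"].append(vol_path.name)

    # stage 3 — fixed-PC classification + permutation per label target
    for label in config.label_columns:
        logger.info("classifying by %s (fixed %d PCs, seed %d)", label, config.n_pcs, config.cv.seed)
        result, report = fixed_pc_run(table, label, n_pcs=config.n_pcs, config=config.cv)
        cls_path = out / f"classification_{label}.json"
        _dump_json({"result": result.to_dict(), "report": report.to_dict()}, cls_path)
        csv_path = out / f"metrics_{label}.csv"
        report.to_frame().to_csv(csv_path, index=False)
        png_path = out / f"confusion_{label}.png"
        render_confusion_heatmap(report, png_path, title=f"classification by {label}")
        manifest["outputs"] += [cls_path.name, csv_path.name, png_path.name]

        perm = run_permutation_test(
            table,
            label,
            config=replace(config.cv, fixed_pcs=config.n_pcs),
            b=config.permutations,
            seed=config.cv.seed,
        )
        logger.info("%s permutation p = %.4f (B = %d)", label, perm.p_value, perm.b)
        perm_path = out / f"permutation_{label}.json"
        _dump_json(perm.to_dict(), perm_path)
        manifest["outputs"].append(perm_path.name)

    manifest_path = out / "manifest.json"
    _dump_json(manifest, manifest_path)
    return manifest
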