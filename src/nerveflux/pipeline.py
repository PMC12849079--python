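"""End-to-end orchestration: QC -> baseline adjustment -> normalization
-> mitostress metrics -> reference lines -> toxicity metrics -> animal
aggregation -> group comparison.

The stage order is fixed: QC runs on raw traces (so adjustment cannot
induce exclusions), baseline adjustment precedes normalization, and the
mitotoxicity reference lines are built from the adjusted, normalized
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mef_normalization import NormalizationFactors, normalize_run
from .mitostress import metrics_table
from .mitotox import build_reference_line, reference_table, toxicity_table
from .plate_model import PlateRun
from .preprocess import QCRules, apply_qc, baseline_adjust, qc_report
from .stats_report import aggregate_by_animal, build_report, compare_groups

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the analysis pipeline."""

    qc_rules: QCRules = QCRules()
    baseline_mode: str = "group_offset"
    norm_mode: str = "relative_mef"
    positive_group: str | None = None
    reference_mean: str = "geometric"
    basal_mode: str = "last"
    welch: bool = False


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline execution."""

    run: PlateRun
    qc: pd.DataFrame
    metrics: pd.DataFrame
    toxicity: pd.DataFrame | None
    references: pd.DataFrame | None
    animal_summaries: pd.DataFrame
    comparisons: pd.DataFrame | None
    pos_ref: object = None
    neg_ref: object = None

    def write_report(self, outdir: str | Path, extra_provenance: dict | None = None):
        paths = build_report(
            outdir,
            self.run,
            self.animal_summaries,
            self.comparisons,
            extra_provenance=extra_provenance,
        )
        qc_path = Path(outdir) / "qc_report.csv"
        self.qc.to_csv(qc_path, index=False, float_format="%.10g")
        paths["qc_report"] = qc_path
        metrics_path = Path(outdir) / "well_metrics.csv"
        self.metrics.to_csv(metrics_path, index=False, float_format="%.10g")
        paths["well_metrics"] = metrics_path
        if self.toxicity is not None:
            tox_path = Path(outdir) / "well_toxicity.csv"
            self.toxicity.to_csv(tox_path, index=False, float_format="%.10g")
            paths["well_toxicity"] = tox_path
        if self.references is not None:
            ref_path = Path(outdir) / "reference_lines.csv"
            self.references.to_csv(ref_path, index=False, float_format="%.10g")
            paths["reference_lines"] = ref_path
        return paths


def run_pipeline(
    run: PlateRun,
    factors: NormalizationFactors | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Execute the full analysis on a raw plate run.

    Mitotoxicity metrics are computed when ``config.positive_group`` is
    set and the run contains negative-control wells; otherwise the
    toxicity stage is skipped (tables are None).  Group comparisons are
    computed when exactly two groups are present.
    """
    qc = qc_report(run, config.qc_rules)
    staged = apply_qc(run, config.qc_rules)
    staged = baseline_adjust(staged, mode=config.baseline_mode)
    if config.norm_mode != "none":
        if factors is None:
            raise ValueError(
                f"norm_mode {config.norm_mode!r} needs normalization factors"
            )
        staged = normalize_run(
            staged, factors, mode=config.norm_mode, reference=config.reference_mean
        )

    metrics = metrics_table(staged, basal_mode=config.basal_mode)

    toxicity = references = None
    pos = neg = None
    has_neg = any(
        meta.is_negative_control for _, meta, _ in staged.included()
    )
    if config.positive_group is not None and has_neg:
        pos = build_reference_line(staged, group=config.positive_group)
        neg = build_reference_line(staged, negative=True)
        toxicity = toxicity_table(staged, pos, neg)
        references = reference_table([pos, neg])

    per_well = metrics
    if toxicity is not None and not toxicity.empty:
        per_well = metrics.merge(
            toxicity.drop(columns=["animal_id", "group", "side"]),
            on="well_id",
            how="left",
        )
    summaries = aggregate_by_animal(per_well)

    comparisons = None
    if summaries["group"].nunique() == 2:
        comparisons = compare_groups(summaries, welch=config.welch)

    return PipelineResult(
        run=staged,
        qc=qc,
        metrics=metrics,
        toxicity=toxicity,
        references=references,
        animal_summaries=summaries,
        comparisons=comparisons,
        pos_ref=pos,
        neg_ref=neg,
    )
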