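"""Animal-level aggregation, group statistics, phenotype classification
and report output.

The animal, not the well, is the statistical unit: technical replicate
wells (left and right nerve fragments pooled) are averaged per animal
before any test, preventing pseudo-replication.  Two-group comparisons
use the unpaired two-tailed Student's (pooled-variance) t-test, Welch
behind a flag; two-factor designs (e.g. genotype x week for glucose and
body weight) use two-way ANOVA with Šídák-adjusted pairwise comparisons
based on the residual mean square.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .plate_model import PlateRun, phase_windows

__all__ = [
    "HYPERGLYCEMIA_THRESHOLD_MM",
    "GLUCOMETER_CEILING_MM",
    "classify_hyperglycemia",
    "is_censored_glucose",
    "hyperglycemia_table",
    "significance_tier",
    "aggregate_by_animal",
    "compare_groups",
    "compare_two_factor",
    "energy_map_table",
    "trace_summary_table",
    "build_report",
]

#: Renal threshold for glucose reabsorption in mice, mM.
HYPERGLYCEMIA_THRESHOLD_MM = 16.7
#: Glucometer detection ceiling, mM; readings at the ceiling are censored.
GLUCOMETER_CEILING_MM = 33.3


def classify_hyperglycemia(glucose_mM: float) -> bool:
    """True iff random-fed blood glucose strictly exceeds 16.7 mM."""
    if glucose_mM < 0:
        raise ValueError("glucose concentration must be >= 0")
    return glucose_mM > HYPERGLYCEMIA_THRESHOLD_MM


def is_censored_glucose(glucose_mM: float) -> bool:
    """True iff the reading sits at the meter ceiling (>= 33.3 mM)."""
    return glucose_mM >= GLUCOMETER_CEILING_MM


def hyperglycemia_table(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Phenotype table with hyperglycemic and censored flags added."""
    out = phenotype.copy()
    out["hyperglycemic"] = out["blood_glucose_mM"] > HYPERGLYCEMIA_THRESHOLD_MM
    out["glucose_censored"] = out["blood_glucose_mM"] >= GLUCOMETER_CEILING_MM
    return out


def significance_tier(p: float) -> str:
    """'***' p<0.001, '**' p<0.01, '*' p<0.05, else 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate_by_animal(
    per_well: pd.DataFrame,
    value_cols: list[str] | None = None,
    by_side: bool = False,
) -> pd.DataFrame:
    """Mean of each metric over an animal's included standard wells.

    ``per_well`` is a metrics and/or toxicity table (one row per well,
    with animal_id and group columns).  ``by_side=True`` stratifies by
    nerve side instead of pooling, for the left-vs-right check.
    Animals contribute only wells present in the table (QC-failing
    wells never reach these tables).
    """
    if per_well.empty:
        raise ValueError("per-well table is empty; nothing to aggregate")
    keys = ["animal_id", "group"] + (["side"] if by_side else [])
    if value_cols is None:
        skip = {"well_id", "animal_id", "group", "side", "notes"}
        value_cols = [
            c
            for c in per_well.columns
            if c not in skip and pd.api.types.is_numeric_dtype(per_well[c])
        ]
    g = per_well.groupby(keys, sort=True)
    out = g[value_cols].mean()
    out["n_wells_included"] = g.size()
    return out.reset_index()


def compare_groups(
    summaries: pd.DataFrame,
    metric_cols: list[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group comparison of animal-level means, metric by metric.

    Unpaired two-tailed Student's t-test (pooled variance) by default;
    ``welch=True`` drops the equal-variance assumption.  Reports group
    means +/- SD across animals, the t statistic, p-value and
    significance tier.
    """
    groups = sorted(summaries["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"two-group comparison needs exactly 2 groups, got {groups}")
    g1, g2 = groups
    for g in groups:
        if (summaries["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")
    if metric_cols is None:
        skip = {"animal_id", "group", "side", "n_wells_included"}
        metric_cols = [
            c
            for c in summaries.columns
            if c not in skip and pd.api.types.is_numeric_dtype(summaries[c])
        ]

    rows = []
    for metric in metric_cols:
        x1 = summaries.loc[summaries["group"] == g1, metric].dropna().to_numpy()
        x2 = summaries.loc[summaries["group"] == g2, metric].dropna().to_numpy()
        t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
        rows.append(
            {
                "metric": metric,
                "group_1": g1,
                "group_2": g2,
                "mean_1": x1.mean(),
                "sd_1": x1.std(ddof=1),
                "n_1": len(x1),
                "mean_2": x2.mean(),
                "sd_2": x2.std(ddof=1),
                "n_2": len(x2),
                "test": "welch_t" if welch else "student_t",
                "statistic": float(t),
                "p_value": float(p),
                "significance": significance_tier(float(p)),
            }
        )
    return pd.DataFrame(rows)


def compare_two_factor(
    data: pd.DataFrame,
    value: str,
    factor_a: str = "group",
    factor_b: str = "week",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA with Šídák-adjusted pairwise comparisons.

    Fits ``value ~ A * B``; the pairwise family contains every
    within-level pair of the other factor (for a 2x2 design: factor A
    within each level of B and factor B within each level of A, four
    comparisons).  Pairwise t statistics use the ANOVA residual mean
    square; Šídák adjustment is ``1 - (1 - p)^m`` over the family.

    Returns ``(anova_table, pairwise_table)``.
    """
    df = data[[value, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "A", "B"]
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2).reset_index(names="term")

    mse = model.mse_resid
    dof = model.df_resid
    cells = df.groupby(["A", "B"])["y"].agg(["mean", "count"])

    comparisons = []
    for b in sorted(df["B"].unique()):
        lv = sorted(df.loc[df["B"] == b, "A"].unique())
        comparisons += [((a1, b), (a2, b)) for i, a1 in enumerate(lv) for a2 in lv[i + 1 :]]
    for a in sorted(df["A"].unique()):
        lv = sorted(df.loc[df["A"] == a, "B"].unique())
        comparisons += [((a, b1), (a, b2)) for i, b1 in enumerate(lv) for b2 in lv[i + 1 :]]
    m = len(comparisons)

    rows = []
    for c1, c2 in comparisons:
        m1, n1 = cells.loc[c1, "mean"], cells.loc[c1, "count"]
        m2, n2 = cells.loc[c2, "mean"], cells.loc[c2, "count"]
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(abs(t), dof)
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        rows.append(
            {
                "comparison": f"{factor_a}={c1[0]},{factor_b}={c1[1]} vs "
                f"{factor_a}={c2[0]},{factor_b}={c2[1]}",
                "mean_diff": m1 - m2,
                "t": float(t),
                "p_value": float(p),
                "p_sidak": float(p_adj),
                "significance": significance_tier(float(p_adj)),
            }
        )
    return anova, pd.DataFrame(rows)


def energy_map_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD of the animal-level energy-map coordinates."""
    need = {"last_basal", "basal_ecar"}
    if not need <= set(summaries.columns):
        raise ValueError("summaries lack energy-map columns last_basal/basal_ecar")
    g = summaries.groupby("group")
    out = g.agg(
        basal_ocr_mean=("last_basal", "mean"),
        basal_ocr_sd=("last_basal", lambda s: s.std(ddof=1)),
        basal_ecar_mean=("basal_ecar", "mean"),
        basal_ecar_sd=("basal_ecar", lambda s: s.std(ddof=1)),
        n_animals=("last_basal", "size"),
    )
    return out.reset_index()


def trace_summary_table(run: PlateRun) -> pd.DataFrame:
    """Per-group, per-reading mean +/- SD trace with injection markers.

    Uses included standard wells; the ``injection`` column carries the
    compound injected immediately before each phase's first reading.
    """
    sched = run.schedule
    windows = phase_windows(sched)
    first_reading = {rng[0]: lab for lab, rng in windows.items() if lab != "basal"}
    rows = []
    by_group: dict[str, list[np.ndarray]] = {}
    by_group_ecar: dict[str, list[np.ndarray]] = {}
    for _, meta, trace in run.standard_wells():
        by_group.setdefault(meta.group, []).append(trace.ocr)
        by_group_ecar.setdefault(meta.group, []).append(trace.ecar)
    for group in sorted(by_group):
        ocr = np.vstack(by_group[group])
        ecar = np.vstack(by_group_ecar[group])
        for i in range(1, sched.n_total + 1):
            rows.append(
                {
                    "group": group,
                    "measurement_index": i,
                    "time_min": sched.time_min(i),
                    "phase": sched.phase_of(i),
                    "injection": first_reading.get(i, ""),
                    "ocr_mean": float(np.nanmean(ocr[:, i - 1])),
                    "ocr_sd": float(np.nanstd(ocr[:, i - 1], ddof=1))
                    if ocr.shape[0] > 1
                    else float("nan"),
                    "ecar_mean": float(np.nanmean(ecar[:, i - 1])),
                    "ecar_sd": float(np.nanstd(ecar[:, i - 1], ddof=1))
                    if ecar.shape[0] > 1
                    else float("nan"),
                    "n_wells": ocr.shape[0],
                }
            )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def build_report(
    outdir: str | Path,
    run: PlateRun,
    animal_summaries: pd.DataFrame,
    comparisons: pd.DataFrame | None = None,
    extra_provenance: dict | None = None,
) -> dict[str, Path]:
    """Write the report bundle; deterministic for identical inputs.

    Emits animal-level summaries, group comparisons (skipped with a note
    when fewer than two groups are present), energy-map data, the
    per-group trace summary and a provenance JSON echoing the run's
    processing log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["animal_summaries"] = outdir / "animal_summaries.csv"
    _write_csv(animal_summaries.sort_values(["group", "animal_id"]), paths["animal_summaries"])

    paths["group_comparisons"] = outdir / "group_comparisons.csv"
    if comparisons is None:
        n_groups = animal_summaries["group"].nunique()
        if n_groups == 2:
            comparisons = compare_groups(animal_summaries)
        else:
            warnings.warn(
                f"{n_groups} group(s) present; group comparisons skipped",
                stacklevel=2,
            )
            comparisons = pd.DataFrame(
                {"note": [f"comparisons skipped: {n_groups} group(s) present"]}
            )
    _write_csv(comparisons, paths["group_comparisons"])

    paths["energy_map"] = outdir / "energy_map.csv"
    _write_csv(energy_map_table(animal_summaries), paths["energy_map"])

    paths["trace_summary"] = outdir / "trace_summary.csv"
    _write_csv(trace_summary_table(run), paths["trace_summary"])

    paths["provenance"] = outdir / "provenance.json"
    prov = {"pipeline": run.provenance, **(extra_provenance or {})}
    paths["provenance"].write_text(json.dumps(prov, indent=1, sort_keys=True, default=str))
    return paths
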