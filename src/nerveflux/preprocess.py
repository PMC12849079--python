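"""Per-well QC for inhibitor response and group baseline adjustment.

The original screening of traces for "appropriate inhibitor response"
was visual; this module quantifies it with three ratio rules plus an
absolute basal floor, all evaluated on raw (pre-adjustment) OCR so that
adjustment can never induce an exclusion:

* oligomycin response: min post-Omy OCR / last basal OCR must fall
  below ``omy_max_ratio`` (the ATP-synthase inhibitor must lower OCR),
* FCCP response: max post-FCCP OCR / min post-Omy OCR must exceed
  ``fccp_min_ratio`` (the uncoupler must raise OCR),
* Rot/AA response: min post-Rot/AA OCR / max post-FCCP OCR must fall
  below ``rotaa_max_ratio``,
* signal floor: last basal OCR must be at least ``min_basal_ocr``.

Rot/AA-pretreated negative-control wells cannot respond to inhibitors
by design and are exempt from the checks.  Failing wells are retained
but flagged; they never reach metric extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import PlateRun, QC_STATUSES, Trace, WellMeta

__all__ = [
    "QCRules",
    "QCResult",
    "qc_classify_well",
    "apply_qc",
    "qc_report",
    "baseline_adjust",
    "BASELINE_MODES",
]

BASELINE_MODES = ("none", "group_offset", "percent")


@dataclass(frozen=True)
class QCRules:
    """Quantitative thresholds for the inhibitor-response screen."""

    omy_max_ratio: float = 0.9
    fccp_min_ratio: float = 1.2
    rotaa_max_ratio: float = 0.9
    min_basal_ocr: float = 5.0

    def __post_init__(self) -> None:
        for name in ("omy_max_ratio", "fccp_min_ratio", "rotaa_max_ratio"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite positive ratio")
        if not math.isfinite(self.min_basal_ocr):
            raise ValueError("min_basal_ocr must be finite")


@dataclass(frozen=True)
class QCResult:
    """Outcome of the screen for one well.

    ``status`` is pass|fail|exempt|excluded; ``passed`` is true for pass
    and exempt.  ``values`` holds the three ratios and the last basal
    OCR (NaN where a window was incomplete).
    """

    well_id: str
    passed: bool
    status: str
    failed_checks: tuple[str, ...]
    values: dict[str, float]


def _ratio(num: float, den: float) -> float:
    if math.isnan(num) or math.isnan(den) or den == 0:
        return float("nan")
    return num / den


def qc_classify_well(trace: Trace, meta: WellMeta, rules: QCRules) -> QCResult:
    """Screen one well for an appropriate inhibitor response.

    Negative-control wells pass with checks recorded as exempt.  Missing
    readings in a required window give status ``excluded`` (the well
    cannot be judged), never pass/fail.
    """
    labels = trace.schedule.labels
    if len(labels) < 3:
        raise ValueError("QC rules require the 3-injection mito stress schedule")
    omy, fccp, rotaa = labels[:3]

    last_basal = trace.last_basal("ocr")
    omy_win = trace.window(omy)
    fccp_win = trace.window(fccp)
    rotaa_win = trace.window(rotaa)
    min_omy = float("nan") if np.isnan(omy_win).any() else float(omy_win.min())
    max_fccp = float("nan") if np.isnan(fccp_win).any() else float(fccp_win.max())
    min_rotaa = float("nan") if np.isnan(rotaa_win).any() else float(rotaa_win.min())

    values = {
        "omy_ratio": _ratio(min_omy, last_basal),
        "fccp_ratio": _ratio(max_fccp, min_omy),
        "rotaa_ratio": _ratio(min_rotaa, max_fccp),
        "last_basal_ocr": last_basal,
    }

    if meta.is_negative_control:
        return QCResult(meta.well_id, True, "exempt", ("exempt",), values)

    needed = (last_basal, min_omy, max_fccp, min_rotaa)
    if any(math.isnan(v) for v in needed):
        return QCResult(
            meta.well_id, False, "excluded", ("incomplete_window",), values
        )

    failed = []
    if not values["omy_ratio"] <= rules.omy_max_ratio:
        failed.append("omy_response")
    if not values["fccp_ratio"] >= rules.fccp_min_ratio:
        failed.append("fccp_response")
    if not values["rotaa_ratio"] <= rules.rotaa_max_ratio:
        failed.append("rotaa_response")
    if not last_basal >= rules.min_basal_ocr:
        failed.append("basal_floor")

    passed = not failed
    return QCResult(
        meta.well_id, passed, "pass" if passed else "fail", tuple(failed), values
    )


def apply_qc(run: PlateRun, rules: QCRules = QCRules()) -> PlateRun:
    """Screen every well; return a copy with ``qc_status`` set.

    Failing wells stay in the run but are flagged; per-group pass/fail
    counts are logged into provenance.
    """
    out = run.copy()
    counts: dict[str, dict[str, int]] = {}
    for wid, well in out.wells.items():
        res = qc_classify_well(well.trace, well.meta, rules)
        well.meta.qc_status = res.status
        well.meta.qc_reason = ";".join(res.failed_checks) if not res.passed else (
            "exempt" if res.status == "exempt" else ""
        )
        g = counts.setdefault(well.meta.group, {s: 0 for s in QC_STATUSES})
        g[res.status] += 1
    out.log(
        "apply_qc",
        rules=vars(rules) | {},
        counts={g: {k: v for k, v in c.items() if v} for g, c in counts.items()},
    )
    return out


def qc_report(run: PlateRun, rules: QCRules = QCRules()) -> pd.DataFrame:
    """Per-well QC report table (does not modify the run)."""
    rows = []
    for wid, meta, trace in run.iter_wells():
        res = qc_classify_well(trace, meta, rules)
        rows.append(
            {
                "well_id": wid,
                "animal_id": meta.animal_id,
                "group": meta.group,
                "passed": res.passed,
                "status": res.status,
                "failed_checks": ";".join(res.failed_checks),
                "omy_ratio": res.values["omy_ratio"],
                "fccp_ratio": res.values["fccp_ratio"],
                "rotaa_ratio": res.values["rotaa_ratio"],
                "last_basal_ocr": res.values["last_basal_ocr"],
            }
        )
    return pd.DataFrame(rows)


def baseline_adjust(run: PlateRun, mode: str = "group_offset") -> PlateRun:
    """Baseline-adjust each experimental group's traces.

    Modes
    -----
    ``none``
        Identity.
    ``group_offset`` (default)
        For each group, shift every included well's whole OCR trace
        additively so its basal-window mean equals the group mean of
        basal-window means; ECAR likewise with its own group mean.
        Preserves the group's pointwise mean trace and every
        within-well difference, hence all difference-based metrics;
        units stay pmol O2/min.  Aligning on the basal-window mean
        rather than the single last basal reading keeps the across-well
        dispersion of basal OCR finite, which the reference-based
        z-scores standardize against.
    ``percent``
        Divide each included well's readings by its own basal-window
        mean and multiply by 100; units become % of baseline.

    QC must have run first (no well may be ``pending``); a group with
    zero included wells raises, naming the group.
    """
    if mode not in BASELINE_MODES:
        raise ValueError(f"mode must be one of {BASELINE_MODES}")
    out = run.copy()
    if mode == "none":
        out.log("baseline_adjust", mode="none")
        return out
    pending = [wid for wid, m, _ in out.iter_wells(statuses=("pending",))]
    if pending:
        raise ValueError(
            f"baseline adjustment requires QC first; pending wells: {pending[:5]}"
        )

    included = list(out.included())
    by_group: dict[str, list] = {}
    for wid, meta, trace in included:
        by_group.setdefault(meta.group, []).append((wid, meta, trace))
    for g in out.groups:
        if g not in by_group:
            raise ValueError(f"group {g!r} has zero included wells")

    def basal_mean(trace: Trace, signal: str) -> float:
        win = trace.window("basal", signal)
        if np.isnan(win).all():
            raise ValueError("well has no basal readings; cannot baseline-adjust")
        return float(np.nanmean(win))

    summary: dict[str, dict[str, float]] = {}
    if mode == "group_offset":
        for g, members in by_group.items():
            m_ocr = float(np.mean([basal_mean(t, "ocr") for _, _, t in members]))
            m_ecar = float(np.mean([basal_mean(t, "ecar") for _, _, t in members]))
            for wid, meta, trace in members:
                trace.ocr += m_ocr - basal_mean(trace, "ocr")
                trace.ecar += m_ecar - basal_mean(trace, "ecar")
            summary[g] = {"mean_basal_ocr": m_ocr, "mean_basal_ecar": m_ecar}
    else:  # percent
        for g, members in by_group.items():
            for wid, meta, trace in members:
                b_ocr = basal_mean(trace, "ocr")
                b_ecar = basal_mean(trace, "ecar")
                if not b_ocr > 0 or not b_ecar > 0:
                    raise ValueError(
                        f"well {wid}: nonpositive basal mean, "
                        "percent adjustment undefined"
                    )
                trace.ocr *= 100.0 / b_ocr
                trace.ecar *= 100.0 / b_ecar
            summary[g] = {"unit": "% baseline"}

    out.log("baseline_adjust", mode=mode, groups=summary)
    return out
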