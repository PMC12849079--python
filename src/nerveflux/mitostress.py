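"""Classical mito stress test metrics and energy-map coordinates.

The sequential Omy -> FCCP -> Rot/AA injection protocol partitions OCR
into respiration components computed from five window values of the
trace:

* non-mitochondrial respiration (NMR) = minimal OCR after Rot/AA
* basal respiration   = last pre-Omy OCR - NMR
* ATP production      = last pre-Omy OCR - minimal OCR after Omy
* proton leak         = minimal OCR after Omy - NMR
* maximal respiration = maximal OCR after FCCP - NMR
* spare capacity (%)  = 100 * maximal / basal
* coupling eff. (%)   = 100 * ATP / basal

ATP + leak = basal is an exact algebraic identity of these definitions.
All window values are elements of the trace (no interpolation); a NaN
reading inside a needed window makes the dependent metrics NaN, with the
reason recorded in ``notes``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import PlateRun, Trace

__all__ = [
    "WindowValues",
    "MitoStressMetrics",
    "compute_mitostress",
    "energy_map_point",
    "metrics_table",
    "METRIC_COLUMNS",
]

#: Metric columns of the per-well metrics table, in output order.
METRIC_COLUMNS = ["nmr", "basal", "atp", "leak", "maximal", "spare_pct", "coupling_pct"]


@dataclass(frozen=True)
class WindowValues:
    """The five audit values a trace's metrics derive from."""

    last_basal: float
    min_omy: float
    max_fccp: float
    min_rotaa: float
    max_last6_omy: float  # used by the uncoupling toxicity index


@dataclass(frozen=True)
class MitoStressMetrics:
    """The seven respiration parameters of one trace.

    Units are pmol O2/min (or % of baseline if the trace was
    percent-adjusted); spare_pct and coupling_pct are percentages.
    Undefined metrics are NaN with the reason in ``notes``.
    """

    nmr: float
    basal: float
    atp: float
    leak: float
    maximal: float
    spare_pct: float
    coupling_pct: float
    window_values: WindowValues
    notes: tuple[str, ...] = ()


def _injection_labels(trace: Trace) -> tuple[str, str, str]:
    labels = trace.schedule.labels
    if len(labels) < 3:
        raise ValueError(
            "mito stress metrics need three injections "
            "(ATP-synthase inhibitor, uncoupler, ETC inhibitors); "
            f"schedule has {len(labels)}"
        )
    return labels[0], labels[1], labels[2]


def _window_stat(values: np.ndarray, fn) -> float:
    """min/max over a window; NaN if any reading is missing."""
    if np.isnan(values).any():
        return float("nan")
    return float(fn(values))


def compute_mitostress(trace: Trace, basal_mode: str = "last") -> MitoStressMetrics:
    """Compute the seven mito stress parameters of one trace.

    Parameters
    ----------
    trace
        A QC-passed trace (the function itself does not re-check QC).
    basal_mode
        ``"last"`` (default) takes the pre-injection reference as the
        last basal reading, the literal reading of the metric
        definitions; ``"mean"`` uses the mean of the basal window.
    """
    if basal_mode not in ("last", "mean"):
        raise ValueError("basal_mode must be 'last' or 'mean'")
    omy, fccp, rotaa = _injection_labels(trace)

    basal_win = trace.window("basal")
    if basal_mode == "last":
        last_basal = float(basal_win[-1])
    else:
        last_basal = _window_stat(basal_win, np.mean)
    omy_win = trace.window(omy)
    min_omy = _window_stat(omy_win, np.min)
    max_last6_omy = _window_stat(omy_win[-6:], np.max)
    max_fccp = _window_stat(trace.window(fccp), np.max)
    min_rotaa = _window_stat(trace.window(rotaa), np.min)

    notes: list[str] = []
    for name, v in (
        ("last_basal", last_basal),
        (f"min_{omy}", min_omy),
        (f"max_{fccp}", max_fccp),
        (f"min_{rotaa}", min_rotaa),
    ):
        if math.isnan(v):
            notes.append(f"missing readings: {name} undefined")

    nmr = min_rotaa
    basal = last_basal - nmr
    atp = last_basal - min_omy
    leak = min_omy - nmr
    maximal = max_fccp - nmr

    if math.isnan(basal) or basal <= 0:
        spare = float("nan")
        coupling = float("nan")
        if not math.isnan(basal):
            notes.append("nonpositive basal respiration: spare/coupling undefined")
    else:
        spare = 100.0 * maximal / basal
        coupling = 100.0 * atp / basal

    return MitoStressMetrics(
        nmr=nmr,
        basal=basal,
        atp=atp,
        leak=leak,
        maximal=maximal,
        spare_pct=spare,
        coupling_pct=coupling,
        window_values=WindowValues(
            last_basal=last_basal,
            min_omy=min_omy,
            max_fccp=max_fccp,
            min_rotaa=min_rotaa,
            max_last6_omy=max_last6_omy,
        ),
        notes=tuple(notes),
    )


def energy_map_point(trace: Trace) -> tuple[float, float]:
    """(basal OCR, basal ECAR) of a trace: the energy-map coordinates.

    Uses the last basal reading of each signal, consistent with the
    basal-respiration definition.  NaN coordinates signal missing basal
    readings.
    """
    return trace.last_basal("ocr"), trace.last_basal("ecar")


def metrics_table(run: PlateRun, basal_mode: str = "last") -> pd.DataFrame:
    """Per-well metrics for the included standard wells of a run.

    Columns: identity (well_id, animal_id, group, side), the seven
    metrics, the five audit window values, and basal_ecar for the
    energy map.
    """
    rows = []
    for wid, meta, trace in run.standard_wells():
        m = compute_mitostress(trace, basal_mode=basal_mode)
        w = m.window_values
        rows.append(
            {
                "well_id": wid,
                "animal_id": meta.animal_id,
                "group": meta.group,
                "side": meta.side,
                "nmr": m.nmr,
                "basal": m.basal,
                "atp": m.atp,
                "leak": m.leak,
                "maximal": m.maximal,
                "spare_pct": m.spare_pct,
                "coupling_pct": m.coupling_pct,
                "last_basal": w.last_basal,
                "min_omy": w.min_omy,
                "max_fccp": w.max_fccp,
                "min_rotaa": w.min_rotaa,
                "max_last6_omy": w.max_last6_omy,
                "basal_ecar": trace.last_basal("ecar"),
                "notes": ";".join(m.notes),
            }
        )
    return pd.DataFrame(rows)
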