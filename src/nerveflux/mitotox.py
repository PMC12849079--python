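"""Reference-line mitotoxicity metrics.

A reference line is the per-reading average of baseline-adjusted,
normalized traces from a control set: the *positive* reference from the
designated control group's standard wells (maximal activity) and the
*negative* reference from Rot/AA-pretreated wells of all animals
(complete inhibition).  Against these, four dimensionless scores are
computed per test trace:

* ``MTI_F``: (test FCCP max - positive FCCP max) / (positive FCCP max -
  negative FCCP-window min).  0 at the positive maximum, -1 at the
  negative floor.
* ``MTI_U``: (test max of last 6 post-Omy readings - positive Omy min) /
  (positive FCCP max - positive Omy min).  0 fully coupled at the
  positive Omy floor, 1 fully uncoupled at the positive FCCP maximum.
* ``z_basal`` / ``z_fccp``: test last-basal (resp. FCCP-window max)
  standardized against the across-member mean and SD of the positive
  reference wells' own last-basal (resp. FCCP max) values.

Window extrema entering MTI numerator/denominator references are taken
on the averaged mean trace; the z-score mean/SD are across member
wells, the only level at which the averaged line has a dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mitostress import compute_mitostress
from .plate_model import PlateRun, ScheduleMismatchError, Trace, phase_slice

__all__ = [
    "DegenerateReferenceError",
    "ReferenceSummary",
    "ReferenceLine",
    "build_reference_line",
    "compute_mti_f",
    "compute_mti_u",
    "compute_zscores",
    "toxicity_table",
    "reference_table",
]


class DegenerateReferenceError(ValueError):
    """Reference line cannot support the requested score."""


@dataclass(frozen=True)
class ReferenceSummary:
    """Scalar statistics derived from a reference line.

    ``min_omy``, ``max_fccp`` and ``min_fccp_window`` are window extrema
    of the mean trace; ``last_basal_*`` and ``max_fccp_mean``/``sd`` are
    across-member statistics of the per-well values.
    """

    last_basal_mean: float
    last_basal_sd: float
    min_omy: float
    max_fccp: float
    min_fccp_window: float
    max_fccp_mean: float
    max_fccp_sd: float


@dataclass(eq=False)
class ReferenceLine:
    """Averaged trace with per-reading dispersion over member wells."""

    mean_ocr: np.ndarray
    sd_ocr: np.ndarray
    n_wells: int
    member_wells: tuple[str, ...]
    kind: str  # positive | negative
    schedule: object
    summary: ReferenceSummary


def _member_stats(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return mean, sd


def build_reference_line(
    run: PlateRun, *, group: str | None = None, negative: bool = False
) -> ReferenceLine:
    """Average included traces into a positive or negative reference.

    ``negative=True`` selects Rot/AA-pretreated (negative-control) wells
    of all animals; otherwise ``group`` selects the designated control
    group's included standard wells.  Member traces must be complete
    (no missing readings).
    """
    if negative:
        members = [
            (wid, meta, trace)
            for wid, meta, trace in run.included()
            if meta.is_negative_control
        ]
        kind = "negative"
    else:
        if group is None:
            raise ValueError("a positive reference needs a group label")
        members = [
            (wid, meta, trace)
            for wid, meta, trace in run.standard_wells()
            if meta.group == group
        ]
        kind = "positive"
    if not members:
        raise DegenerateReferenceError(
            f"no included wells match the {kind} reference selector"
            + (f" (group={group!r})" if not negative else "")
        )
    complete = [
        (wid, meta, trace)
        for wid, meta, trace in members
        if not np.isnan(trace.ocr).any()
    ]
    dropped = len(members) - len(complete)
    if not complete:
        raise DegenerateReferenceError(
            f"all {kind} reference member traces have missing readings"
        )
    sched = complete[0][2].schedule
    if any(t.schedule != sched for _, _, t in complete):
        raise ScheduleMismatchError("reference members on different schedules")

    stack = np.vstack([t.ocr for _, _, t in complete])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(complete) > 1 else np.zeros_like(mean)

    labels = sched.labels
    omy_sl = phase_slice(sched, labels[0])
    fccp_sl = phase_slice(sched, labels[1])
    n_basal = sched.n_basal
    lb_mean, lb_sd = _member_stats([t.ocr[n_basal - 1] for _, _, t in complete])
    fm_mean, fm_sd = _member_stats([t.ocr[fccp_sl].max() for _, _, t in complete])

    summary = ReferenceSummary(
        last_basal_mean=lb_mean,
        last_basal_sd=lb_sd,
        min_omy=float(mean[omy_sl].min()),
        max_fccp=float(mean[fccp_sl].max()),
        min_fccp_window=float(mean[fccp_sl].min()),
        max_fccp_mean=fm_mean,
        max_fccp_sd=fm_sd,
    )
    line = ReferenceLine(
        mean_ocr=mean,
        sd_ocr=sd,
        n_wells=len(complete),
        member_wells=tuple(wid for wid, _, _ in complete),
        kind=kind,
        schedule=sched,
        summary=summary,
    )
    if dropped:
        run.log("reference_line_dropped_members", kind=kind, dropped=dropped)
    return line


def _test_window_values(trace: Trace) -> tuple[float, float, float]:
    """(last_basal, max_fccp, max_last6_omy) of a test trace."""
    w = compute_mitostress(trace).window_values
    return w.last_basal, w.max_fccp, w.max_last6_omy


def compute_mti_f(trace: Trace, pos: ReferenceLine, neg: ReferenceLine) -> float:
    """Mitotoxicity index for the FCCP response.

    0 when the test FCCP maximum matches the positive reference, -1 when
    it sits at the negative reference's FCCP-window floor.
    """
    den = pos.summary.max_fccp - neg.summary.min_fccp_window
    if not den > 0:
        raise DegenerateReferenceError(
            "positive FCCP maximum does not exceed negative FCCP-window "
            f"minimum (denominator {den})"
        )
    _, test_max_fccp, _ = _test_window_values(trace)
    return (test_max_fccp - pos.summary.max_fccp) / den


def compute_mti_u(trace: Trace, pos: ReferenceLine) -> float:
    """Mitotoxicity index for uncoupling.

    Scores the test trace's late post-Omy maximum on the positive
    reference's Omy-floor-to-FCCP-maximum span: 0 fully coupled, 1
    fully uncoupled.
    """
    den = pos.summary.max_fccp - pos.summary.min_omy
    if not den > 0:
        raise DegenerateReferenceError(
            "positive FCCP maximum does not exceed its Omy minimum "
            f"(denominator {den})"
        )
    _, _, test_last6 = _test_window_values(trace)
    return (test_last6 - pos.summary.min_omy) / den


def compute_zscores(trace: Trace, pos: ReferenceLine) -> tuple[float, float]:
    """(z_basal, z_fccp) of a test trace against the positive members.

    Standardizes the test last-basal OCR and FCCP-window maximum against
    the across-member mean and SD of the positive reference wells.
    Requires at least two positive members with variation.
    """
    s = pos.summary
    for name, sd, mean in (
        ("last_basal", s.last_basal_sd, s.last_basal_mean),
        ("max_fccp", s.max_fccp_sd, s.max_fccp_mean),
    ):
        if not (sd > 1e-9 * max(abs(mean), 1.0)):
            raise DegenerateReferenceError(
                f"positive reference {name} SD is zero or degenerate "
                "(need >= 2 positive wells with variation)"
            )
    lb, max_fccp, _ = _test_window_values(trace)
    return (lb - s.last_basal_mean) / s.last_basal_sd, (
        max_fccp - s.max_fccp_mean
    ) / s.max_fccp_sd


def toxicity_table(
    run: PlateRun, pos: ReferenceLine, neg: ReferenceLine
) -> pd.DataFrame:
    """Per-well toxicity metrics for the included standard wells."""
    rows = []
    for wid, meta, trace in run.standard_wells():
        z_basal, z_fccp = compute_zscores(trace, pos)
        rows.append(
            {
                "well_id": wid,
                "animal_id": meta.animal_id,
                "group": meta.group,
                "side": meta.side,
                "mti_f": compute_mti_f(trace, pos, neg),
                "mti_u": compute_mti_u(trace, pos),
                "z_basal": z_basal,
                "z_fccp": z_fccp,
            }
        )
    return pd.DataFrame(rows)


def reference_table(lines: list[ReferenceLine]) -> pd.DataFrame:
    """Long-format reference-line table (kind, reading index, mean, sd, n)."""
    rows = []
    for line in lines:
        for i, (m, s) in enumerate(zip(line.mean_ocr, line.sd_ocr), start=1):
            rows.append(
                {
                    "kind": line.kind,
                    "measurement_index": i,
                    "mean_ocr": float(m),
                    "sd_ocr": float(s),
                    "n_wells": line.n_wells,
                }
            )
    return pd.DataFrame(rows)
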