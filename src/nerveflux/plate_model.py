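"""Data model and I/O for plate-based respirometry runs.

A run is a set of wells on one injection schedule.  Each well carries an
OCR trace (pmol O2/min) and an ECAR trace (mpH/min) sampled at fixed
intervals: ``n_basal`` readings before the first injection, then
``n_post`` readings after each injection.  The classical mito stress
test uses three injections — an ATP-synthase inhibitor (oligomycin A),
an uncoupler (FCCP) and complex I/III inhibitors (rotenone + antimycin
A) — giving 5 + 8 x 3 = 29 readings at 6-minute intervals.

Reading indices are 1-based everywhere in the public API and in the long
CSV format; missing readings are explicit (empty CSV field, NaN in
memory) and are never imputed.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateFormatError",
    "ScheduleMismatchError",
    "InjectionSchedule",
    "WellMeta",
    "Trace",
    "Well",
    "PlateRun",
    "phase_windows",
    "phase_slice",
    "read_plate_long",
    "write_plate_long",
    "read_phenotype",
    "write_phenotype",
    "validate_animals",
    "PLATE_COLUMNS",
    "PHENOTYPE_COLUMNS",
]

#: Fixed column order of the long plate CSV dialect.
PLATE_COLUMNS = [
    "well_id",
    "animal_id",
    "group",
    "side",
    "fragment_index",
    "fragment_length_mm",
    "is_negative_control",
    "measurement_index",
    "phase",
    "time_min",
    "ocr_pmol_min",
    "ecar_mpH_min",
]

PHENOTYPE_COLUMNS = ["animal_id", "group", "week", "blood_glucose_mM", "body_weight_g"]

QC_STATUSES = ("pending", "pass", "fail", "excluded", "exempt")
SIDES = ("left", "right", "NA")


class PlateFormatError(ValueError):
    """The file does not conform to the documented long CSV dialect."""


class ScheduleMismatchError(ValueError):
    """Well reading counts or indices disagree with the injection schedule."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Timing layout of a run: basal readings, then readings per injection.

    Parameters
    ----------
    n_basal
        Number of readings recorded before the first injection.
    n_post
        Number of readings recorded after each injection.
    interval_min
        Minutes between consecutive readings.
    injections
        Ordered ``(label, concentration_uM)`` pairs.  The default is the
        mito stress test: 5 uM oligomycin A, 2.5 uM FCCP, 5 uM Rot/AA.
    """

    n_basal: int = 5
    n_post: int = 8
    interval_min: float = 6.0
    injections: tuple[tuple[str, float], ...] = (
        ("Omy", 5.0),
        ("FCCP", 2.5),
        ("RotAA", 5.0),
    )

    def __post_init__(self) -> None:
        if self.n_basal < 1:
            raise ValueError("n_basal must be >= 1")
        if self.n_post < 1:
            raise ValueError("n_post must be >= 1")
        if not self.interval_min > 0:
            raise ValueError("interval_min must be > 0")
        if len(self.injections) < 1:
            raise ValueError("at least one injection is required")
        inj = tuple((str(lab), float(conc)) for lab, conc in self.injections)
        labels = [lab for lab, _ in inj]
        if len(set(labels)) != len(labels):
            raise ValueError("injection labels must be unique")
        if "basal" in labels:
            raise ValueError("'basal' is reserved for the pre-injection phase")
        object.__setattr__(self, "injections", inj)

    @property
    def labels(self) -> tuple[str, ...]:
        """Injection labels in order."""
        return tuple(lab for lab, _ in self.injections)

    @property
    def n_total(self) -> int:
        """Total number of readings per trace."""
        return self.n_basal + self.n_post * len(self.injections)

    def time_min(self, index: int) -> float:
        """Nominal time of a 1-based reading index, in minutes."""
        return (index - 1) * self.interval_min

    def phase_of(self, index: int) -> str:
        """Phase label containing a 1-based reading index."""
        if not 1 <= index <= self.n_total:
            raise ValueError(f"reading index {index} outside [1, {self.n_total}]")
        if index <= self.n_basal:
            return "basal"
        k = (index - self.n_basal - 1) // self.n_post
        return self.labels[k]


def phase_windows(schedule: InjectionSchedule) -> dict[str, tuple[int, int]]:
    """Inclusive 1-based reading-index range of each phase.

    The basal window is ``[1, n_basal]``; the k-th injection window is
    ``[n_basal + (k-1)*n_post + 1, n_basal + k*n_post]``.  The windows
    are contiguous, disjoint and cover ``[1, n_total]``.
    """
    out = {"basal": (1, schedule.n_basal)}
    start = schedule.n_basal + 1
    for label in schedule.labels:
        out[label] = (start, start + schedule.n_post - 1)
        start += schedule.n_post
    return out


def phase_slice(schedule: InjectionSchedule, phase: str) -> slice:
    """0-based ``slice`` of a phase window, for indexing trace arrays."""
    lo, hi = phase_windows(schedule)[phase]
    return slice(lo - 1, hi)


@dataclass
class WellMeta:
    """Identity and status of one well."""

    well_id: str
    animal_id: str
    group: str
    side: str = "NA"
    fragment_index: int = 1
    fragment_length_mm: float = 1.5
    is_negative_control: bool = False
    qc_status: str = "pending"
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.qc_status not in QC_STATUSES:
            raise ValueError(
                f"qc_status must be one of {QC_STATUSES}, got {self.qc_status!r}"
            )
        if self.fragment_index < 1:
            raise ValueError("fragment_index must be >= 1")
        if not self.fragment_length_mm > 0:
            raise ValueError("fragment_length_mm must be > 0")


@dataclass(eq=False)
class Trace:
    """Paired OCR/ECAR time series on one schedule.

    Missing readings are NaN; they are carried through explicitly and
    make dependent metrics undefined rather than being imputed.
    """

    ocr: np.ndarray
    ecar: np.ndarray
    schedule: InjectionSchedule

    def __post_init__(self) -> None:
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        n = self.schedule.n_total
        if self.ocr.shape != (n,) or self.ecar.shape != (n,):
            raise ScheduleMismatchError(
                f"trace length must equal schedule total {n}; "
                f"got ocr {self.ocr.shape}, ecar {self.ecar.shape}"
            )

    def window(self, phase: str, signal: str = "ocr") -> np.ndarray:
        """Readings of one phase window (view into the trace array)."""
        arr = getattr(self, signal)
        return arr[phase_slice(self.schedule, phase)]

    def last_basal(self, signal: str = "ocr") -> float:
        """The reading immediately before the first injection."""
        return float(getattr(self, signal)[self.schedule.n_basal - 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.schedule == other.schedule
            and np.array_equal(self.ocr, other.ocr, equal_nan=True)
            and np.array_equal(self.ecar, other.ecar, equal_nan=True)
        )


@dataclass(eq=False)
class Well:
    """One well: metadata plus its trace."""

    meta: WellMeta
    trace: Trace

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Well):
            return NotImplemented
        return self.meta == other.meta and self.trace == other.trace


@dataclass(eq=False)
class PlateRun:
    """A full assay dataset: wells sharing one injection schedule.

    ``provenance`` is an append-only log of processing steps (QC rules,
    adjustment/normalization modes, seeds); it is not serialized in the
    long CSV and is ignored by equality.
    """

    schedule: InjectionSchedule
    wells: dict[str, Well] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for well_id, well in self.wells.items():
            if well.meta.well_id != well_id:
                raise ValueError(
                    f"well key {well_id!r} != meta.well_id {well.meta.well_id!r}"
                )
            if well.trace.schedule != self.schedule:
                raise ScheduleMismatchError(
                    f"well {well_id} trace is on a different schedule"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateRun):
            return NotImplemented
        return self.schedule == other.schedule and self.wells == other.wells

    def copy(self) -> "PlateRun":
        """Deep copy; transforms operate on copies, never in place."""
        return PlateRun(
            schedule=self.schedule,
            wells={
                wid: Well(copy.deepcopy(w.meta), Trace(w.trace.ocr.copy(), w.trace.ecar.copy(), self.schedule))
                for wid, w in self.wells.items()
            },
            provenance=copy.deepcopy(self.provenance),
        )

    def log(self, step: str, **details) -> None:
        self.provenance.append({"step": step, **details})

    # -- selection helpers -------------------------------------------------

    def iter_wells(self, statuses: tuple[str, ...] | None = None):
        """Yield ``(well_id, meta, trace)``, optionally filtered by qc_status."""
        for wid, well in self.wells.items():
            if statuses is None or well.meta.qc_status in statuses:
                yield wid, well.meta, well.trace

    def included(self):
        """Wells that downstream analysis consumes (QC pass or exempt)."""
        return self.iter_wells(statuses=("pass", "exempt"))

    def standard_wells(self):
        """Included wells that are not negative controls."""
        for wid, meta, trace in self.iter_wells(statuses=("pass",)):
            if not meta.is_negative_control:
                yield wid, meta, trace

    @property
    def animal_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, meta, _ in self.iter_wells():
            seen.setdefault(meta.animal_id, None)
        return tuple(seen)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, meta, _ in self.iter_wells():
            seen.setdefault(meta.group, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# long CSV I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Serialize a float: shortest round-trip representation, '' for NaN."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str, row: int) -> bool:
    low = s.strip().lower()
    if low in ("true", "1"):
        return True
    if low in ("false", "0"):
        return False
    raise PlateFormatError(f"row {row}: invalid boolean {s!r} in is_negative_control")


def write_plate_long(run: PlateRun, path: str | Path) -> None:
    """Write a run to the long CSV dialect.

    One row per (well, reading); fixed column order; floats with full
    round-trip precision; missing readings as empty fields.  Writing the
    same run twice produces byte-identical files.
    """
    sched = run.schedule
    lines = [",".join(PLATE_COLUMNS)]
    for wid, well in run.wells.items():
        m = well.meta
        for i in range(1, sched.n_total + 1):
            lines.append(
                ",".join(
                    [
                        wid,
                        m.animal_id,
                        m.group,
                        m.side,
                        str(m.fragment_index),
                        _fmt(m.fragment_length_mm),
                        _fmt_bool(m.is_negative_control),
                        str(i),
                        sched.phase_of(i),
                        _fmt(sched.time_min(i)),
                        _fmt(well.trace.ocr[i - 1]),
                        _fmt(well.trace.ecar[i - 1]),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _numeric_column(df: pd.DataFrame, col: str, *, allow_missing: bool = False) -> pd.Series:
    # float() rather than pd.to_numeric: the latter's string parser is not
    # correctly rounded, which would break exact round-tripping
    raw = df[col].astype(str).str.strip()

    def convert(item: tuple[int, str]) -> float:
        idx, s = item
        if s == "":
            return math.nan
        try:
            return float(s)
        except ValueError:
            raise PlateFormatError(
                f"row {idx + 2}: non-numeric value {s!r} in column {col}"
            ) from None

    out = pd.Series(
        [convert(item) for item in raw.items()], index=raw.index, dtype=float
    )
    if not allow_missing and out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise PlateFormatError(f"row {row}: missing value in required column {col}")
    return out


def read_plate_long(path: str | Path, schedule: InjectionSchedule) -> PlateRun:
    """Read the long CSV dialect into a :class:`PlateRun`.

    Raises
    ------
    PlateFormatError
        Missing required column, non-numeric OCR/ECAR, duplicate
        (well, measurement_index) rows, unknown phase label.
    ScheduleMismatchError
        Any well whose reading indices are not exactly 1..n_total.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return PlateRun(schedule=schedule, wells={})

    midx = _numeric_column(df, "measurement_index").astype(int)
    frag_idx = _numeric_column(df, "fragment_index").astype(int)
    frag_len = _numeric_column(df, "fragment_length_mm")
    time_min = _numeric_column(df, "time_min", allow_missing=True)
    ocr = _numeric_column(df, "ocr_pmol_min", allow_missing=True)
    ecar = _numeric_column(df, "ecar_mpH_min", allow_missing=True)

    allowed_phases = {"basal", *schedule.labels}
    bad_phase = ~df["phase"].isin(allowed_phases)
    if bad_phase.any():
        row = int(bad_phase.idxmax()) + 2
        raise PlateFormatError(
            f"row {row}: unknown phase {df['phase'][bad_phase.idxmax()]!r}; "
            f"expected one of {sorted(allowed_phases)}"
        )

    dup = df.duplicated(subset=["well_id", "measurement_index"])
    if dup.any():
        wid = df["well_id"][dup.idxmax()]
        raise PlateFormatError(
            f"duplicate (well, measurement_index) rows: well {wid!r}, "
            f"index {midx[dup.idxmax()]}"
        )

    n = schedule.n_total
    bad_wells = []
    for wid, sub in df.groupby("well_id", sort=False):
        idx = sorted(midx[sub.index])
        if idx != list(range(1, n + 1)):
            bad_wells.append(str(wid))
    if bad_wells:
        raise ScheduleMismatchError(
            f"wells with reading indices != 1..{n}: {', '.join(bad_wells)}"
        )

    # optional time column cross-check (warn, not fatal)
    expected_time = (midx - 1) * schedule.interval_min
    have_time = time_min.notna()
    if have_time.any():
        off = (time_min[have_time] - expected_time[have_time]).abs()
        if (off > 0.5).any():
            warnings.warn(
                "time_min column deviates from (index-1)*interval_min by more "
                "than 0.5 min for some rows; derived times are used",
                stacklevel=2,
            )

    wells: dict[str, Well] = {}
    for wid, sub in df.groupby("well_id", sort=False):
        first = sub.index[0]
        meta = WellMeta(
            well_id=str(wid),
            animal_id=str(df["animal_id"][first]),
            group=str(df["group"][first]),
            side=str(df["side"][first]),
            fragment_index=int(frag_idx[first]),
            fragment_length_mm=float(frag_len[first]),
            is_negative_control=_parse_bool(
                df["is_negative_control"][first], int(first) + 2
            ),
        )
        order = np.argsort(midx[sub.index].to_numpy())
        rows = sub.index.to_numpy()[order]
        trace = Trace(
            ocr=ocr[rows].to_numpy(dtype=float),
            ecar=ecar[rows].to_numpy(dtype=float),
            schedule=schedule,
        )
        wells[str(wid)] = Well(meta, trace)

    run = PlateRun(schedule=schedule, wells=wells)
    run.log("read_plate_long", path=str(path), n_wells=len(wells))
    return run


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read the phenotype CSV (animal, group, week, glucose, weight)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing required column(s): {', '.join(missing)}")
    out = df[PHENOTYPE_COLUMNS].copy()
    out["week"] = _numeric_column(df, "week").astype(int)
    out["blood_glucose_mM"] = _numeric_column(df, "blood_glucose_mM")
    out["body_weight_g"] = _numeric_column(df, "body_weight_g")
    return out


def write_phenotype(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS)


def validate_animals(run: PlateRun, phenotype: pd.DataFrame) -> None:
    """Check every animal referenced by a well exists in the phenotype table."""
    known = set(phenotype["animal_id"].astype(str))
    missing = [a for a in run.animal_ids if a not in known]
    if missing:
        raise ValueError(
            f"animals referenced by wells but absent from phenotype table: "
            f"{', '.join(missing)}"
        )
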