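"""Synthetic respirometry plates and proteomics tables with known truth.

The generator emulates the ex vivo peripheral-nerve assay design: ten
1.5 mm nerve fragments per animal (five per sciatic nerve side) on a
5 basal + 8x3 post-injection schedule at 6-minute intervals, one
Rot/AA-pretreated negative-control well per animal, two genotype groups,
plus occasional non-responder wells for QC exercising.

Each well follows piecewise exponential-approach kinetics between four
plateaus: basal B, post-oligomycin O, post-FCCP F and the Rot/AA floor
R.  Within a phase with target plateau P, the noise-free level at the
t-th reading is ``P + (L0 - P) * exp(-tau * t)`` where L0 is the level
at the end of the previous phase.  Observed readings carry multiplicative
Gaussian noise ``level * (1 + eps)``, ``eps ~ N(0, noise_cv)`` —
respirometry variability scales with signal.  Negative-control wells sit
at R in every phase (the pretreatment abolishes all responses);
non-responders stay flat at B.

A genotype deficit scales the mitochondrial component of each plateau
above the Rot/AA floor (``B' = R + f*(B-R)`` etc.), which lowers basal,
ATP-linked, leak and maximal respiration by exactly the factor f while
leaving spare capacity, coupling efficiency and non-mitochondrial
respiration unchanged — the bioenergetic signature of the diabetic
nerve phenotype the generator emulates.  Between-animal variability uses
the same component scaling with a lognormal-free truncated-normal factor
per animal.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mitostress import MitoStressMetrics, WindowValues
from .plate_model import (
    InjectionSchedule,
    PlateRun,
    Trace,
    Well,
    WellMeta,
    write_plate_long,
    write_phenotype,
)

__all__ = [
    "WellKinetics",
    "GroupSpec",
    "SimConfig",
    "GroundTruth",
    "default_config",
    "apply_deficit",
    "analytic_metrics",
    "noise_free_trace",
    "simulate_plate",
    "simulate_proteomics",
    "simulate_phenotype",
    "write_bundle",
    "PLATEAU_ATTAINMENT",
]

#: tau * n_post at or above which plateaus are attained to ~1e-11 of the
#: plateau gap, making window extrema equal the plateau parameters.
PLATEAU_ATTAINMENT = 25.0

# Distinct fixed subsidiary streams so that plate, proteomics and
# phenotype draws are independent but jointly reproducible from one seed,
# and so the MEF draws are shared between simulate_plate and
# simulate_proteomics.
_STREAM_PLATE = 2
_STREAM_MEF = 7919
_STREAM_PROTEOMICS = 104729
_STREAM_PHENOTYPE = 1299709


@dataclass(frozen=True)
class WellKinetics:
    """Plateau parameters of one well's injection response.

    B, O, F, R are the basal, post-oligomycin, post-FCCP and Rot/AA-floor
    OCR plateaus (pmol O2/min); ``tau`` is the per-reading exponential
    approach rate; ``ecar_basal`` the basal ECAR plateau (mpH/min).
    """

    B: float
    O: float
    F: float
    R: float
    tau: float = 1.0
    ecar_basal: float = 30.0

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.ecar_basal < 0:
            raise ValueError("ecar_basal must be >= 0")

    @property
    def is_responder_shape(self) -> bool:
        """True if the plateaus show the expected inhibitor responses."""
        return self.O < self.B and self.F > self.O and self.R <= self.O

    @property
    def plateaus(self) -> tuple[float, float, float, float]:
        return (self.B, self.O, self.F, self.R)


def apply_deficit(k: WellKinetics, factor: float) -> WellKinetics:
    """Scale the mitochondrial plateau components above the Rot/AA floor.

    ``B' = R + factor*(B-R)`` and likewise for O and F; R is untouched.
    This multiplies basal, ATP, leak and maximal respiration by exactly
    ``factor`` while leaving spare capacity, coupling efficiency and NMR
    unchanged.  ECAR is scaled by the same factor.
    """
    if not factor > 0:
        raise ValueError("deficit factor must be > 0")
    return dataclasses.replace(
        k,
        B=k.R + factor * (k.B - k.R),
        O=k.R + factor * (k.O - k.R),
        F=k.R + factor * (k.F - k.R),
        ecar_basal=factor * k.ecar_basal,
    )


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generator settings.

    ``between_animal_cv`` is the coefficient of variation of a per-animal
    factor applied to the mitochondrial plateau components (and ECAR), so
    animals differ in respiration level but not in the dimensionless
    metrics.  ``glucose_mM`` / ``body_weight_g`` are
    ``(week, mean, sd)`` triples for the phenotype table.
    """

    kinetics: WellKinetics
    between_animal_cv: float = 0.10
    glucose_mM: tuple[tuple[int, float, float], ...] = (
        (6, 7.5, 0.8),
        (15, 7.5, 1.1),
    )
    body_weight_g: tuple[tuple[int, float, float], ...] = (
        (6, 21.1, 1.0),
        (15, 25.0, 1.2),
    )

    def __post_init__(self) -> None:
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full study-design configuration for the generator."""

    groups: dict[str, GroupSpec]
    schedule: InjectionSchedule = InjectionSchedule()
    n_animals_per_group: int = 12
    fragments_per_side: int = 5
    sides: int = 2
    negative_controls_per_animal: int = 1
    nonresponder_prob: float = 0.05
    noise_cv: float = 0.05
    seed: int = 0
    mef_mean: float = 0.15
    mef_sd: float = 0.02
    n_proteins: int = 400
    mito_fraction_of_proteins: float = 0.25
    fragment_length_mm: float = 1.5

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be >= 1")
        if self.fragments_per_side < 1:
            raise ValueError("fragments_per_side must be >= 1")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")
        if self.negative_controls_per_animal < 0:
            raise ValueError("negative_controls_per_animal must be >= 0")
        for name, p in (
            ("nonresponder_prob", self.nonresponder_prob),
            ("mito_fraction_of_proteins", self.mito_fraction_of_proteins),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_cv < 0 or self.mef_sd < 0:
            raise ValueError("noise_cv and mef_sd must be >= 0")
        if not 0.0 < self.mef_mean < 1.0:
            raise ValueError("mef_mean must be in (0, 1)")
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        n_mito = round(self.n_proteins * self.mito_fraction_of_proteins)
        if n_mito == 0:
            raise ValueError(
                "no mitochondrial proteins in the table but mef_mean > 0"
            )
        if n_mito == self.n_proteins:
            raise ValueError(
                "all proteins mitochondrial but mef_mean < 1"
            )

    @property
    def wells_per_animal(self) -> int:
        return self.fragments_per_side * self.sides + self.negative_controls_per_animal

    @property
    def animal_ids(self) -> tuple[str, ...]:
        return tuple(
            f"{g}-{i:02d}"
            for g in self.groups
            for i in range(1, self.n_animals_per_group + 1)
        )


def default_config(
    seed: int = 0,
    deficit: float = 0.85,
    control_group: str = "BKS",
    deficit_group: str = "dbdb",
    **overrides,
) -> SimConfig:
    """Two-genotype study configuration.

    The control group follows the reference kinetics (B=30, O=14, F=70,
    R=10 pmol O2/min; basal ECAR 30 mpH/min); the second group carries a
    multiplicative mitochondrial deficit (default 0.85) on the plateau
    components above the Rot/AA floor, plus a hyperglycemic/obese
    phenotype.  Pass ``deficit=1.0`` for a null design (no group effect).
    """
    base = WellKinetics(B=30.0, O=14.0, F=70.0, R=10.0, tau=1.0, ecar_basal=30.0)
    groups = {
        control_group: GroupSpec(kinetics=base),
        deficit_group: GroupSpec(
            kinetics=apply_deficit(base, deficit),
            glucose_mM=((6, 20.1, 6.6), (15, 30.5, 4.7)),
            body_weight_g=((6, 36.8, 1.4), (15, 45.0, 3.0)),
        ),
    }
    return SimConfig(groups=groups, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# analytic (ground-truth) metrics
# ---------------------------------------------------------------------------


def analytic_metrics(k: WellKinetics) -> MitoStressMetrics:
    """Mito stress metrics implied by plateau parameters alone.

    Valid when plateaus are attained within each window, i.e.
    ``tau * n_post >= PLATEAU_ATTAINMENT``; then window extrema equal the
    plateaus and NMR=R, basal=B-R, ATP=B-O, leak=O-R, maximal=F-R,
    spare=100*(F-R)/(B-R), coupling=100*(B-O)/(B-R).

    Raises
    ------
    ZeroDivisionError
        If B == R (basal respiration zero: spare/coupling undefined).
    """
    if k.B == k.R:
        raise ZeroDivisionError(
            "B == R: basal respiration is zero, spare/coupling undefined"
        )
    basal = k.B - k.R
    atp = k.B - k.O
    leak = k.O - k.R
    maximal = k.F - k.R
    return MitoStressMetrics(
        nmr=k.R,
        basal=basal,
        atp=atp,
        leak=leak,
        maximal=maximal,
        spare_pct=100.0 * maximal / basal,
        coupling_pct=100.0 * atp / basal,
        window_values=WindowValues(
            last_basal=k.B,
            min_omy=k.O,
            max_fccp=k.F,
            min_rotaa=k.R,
            max_last6_omy=k.O,
        ),
    )


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


def noise_free_trace(
    plateaus: tuple[float, ...], tau: float, schedule: InjectionSchedule
) -> np.ndarray:
    """Exponential-approach level at every reading, without noise.

    ``plateaus`` has one target level per phase (basal + one per
    injection).  The level starts at the basal plateau and relaxes
    toward each phase's target at rate ``tau`` per reading.
    """
    if len(plateaus) != 1 + len(schedule.injections):
        raise ValueError("need one plateau per phase (basal + each injection)")
    counts = [schedule.n_basal] + [schedule.n_post] * len(schedule.injections)
    out = np.empty(schedule.n_total)
    level = float(plateaus[0])
    pos = 0
    for target, n in zip(plateaus, counts):
        t = np.arange(1, n + 1)
        seg = target + (level - target) * np.exp(-tau * t)
        out[pos : pos + n] = seg
        level = float(seg[-1])
        pos += n
    return out


def _draw_mefs(config: SimConfig) -> dict[str, float]:
    """Per-animal MEF draws on a dedicated stream shared by both simulators."""
    rng = np.random.default_rng([config.seed, _STREAM_MEF])
    draws = rng.normal(config.mef_mean, config.mef_sd, len(config.animal_ids))
    draws = np.clip(draws, 0.005, 0.995)
    return dict(zip(config.animal_ids, draws.tolist()))


def _well_id(i: int) -> str:
    """Plate coordinate for the i-th well (0-based), 96 wells per plate."""
    plate, pos = divmod(i, 96)
    row, col = divmod(pos, 12)
    return f"{plate + 1}-{chr(ord('A') + row)}{col + 1:02d}"


@dataclass
class GroundTruth:
    """Everything the generator drew, for downstream validation."""

    kinetics: dict[str, WellKinetics]
    responder: dict[str, bool]
    mef: dict[str, float]
    analytic: dict[str, MitoStressMetrics]

    def to_dict(self) -> dict:
        return {
            "kinetics": {w: dataclasses.asdict(k) for w, k in self.kinetics.items()},
            "responder": self.responder,
            "mef": self.mef,
            "analytic": {
                w: {
                    "nmr": m.nmr,
                    "basal": m.basal,
                    "atp": m.atp,
                    "leak": m.leak,
                    "maximal": m.maximal,
                    "spare_pct": m.spare_pct,
                    "coupling_pct": m.coupling_pct,
                }
                for w, m in self.analytic.items()
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def simulate_plate(config: SimConfig) -> tuple[PlateRun, GroundTruth]:
    """Generate a plate run plus its ground truth.

    Deterministic for a fixed config (bit-identical traces); different
    seeds give different draws.  Negative-control wells sit at the
    Rot/AA floor in every phase; non-responders stay flat at the basal
    plateau.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PLATE])
    mefs = _draw_mefs(config)
    sched = config.schedule
    if len(sched.injections) != 3:
        raise ValueError("the plate simulator models the 3-injection mito stress test")

    wells: dict[str, Well] = {}
    kinetics: dict[str, WellKinetics] = {}
    responder: dict[str, bool] = {}
    analytic: dict[str, MitoStressMetrics] = {}
    clean_rows: list[np.ndarray] = []
    ecar_levels: list[float] = []

    i_well = 0
    for group, spec in config.groups.items():
        k_g = spec.kinetics
        for a in range(1, config.n_animals_per_group + 1):
            animal = f"{group}-{a:02d}"
            # per-animal factor on the mitochondrial plateau components
            s = float(rng.normal(1.0, spec.between_animal_cv))
            s = max(s, 0.2)
            k_a = apply_deficit(k_g, s)

            sides = ("left", "right")[: config.sides]
            for side in sides:
                for frag in range(1, config.fragments_per_side + 1):
                    wid = _well_id(i_well)
                    is_resp = bool(rng.random() >= config.nonresponder_prob)
                    if is_resp:
                        plateaus = (k_a.B, k_a.O, k_a.F, k_a.R)
                        kin = k_a
                    else:
                        plateaus = (k_a.B,) * 4
                        kin = dataclasses.replace(k_a, O=k_a.B, F=k_a.B, R=k_a.B)
                    meta = WellMeta(
                        well_id=wid,
                        animal_id=animal,
                        group=group,
                        side=side,
                        fragment_index=frag,
                        fragment_length_mm=config.fragment_length_mm,
                        is_negative_control=False,
                    )
                    clean_rows.append(noise_free_trace(plateaus, k_a.tau, sched))
                    ecar_levels.append(k_a.ecar_basal)
                    wells[wid] = Well(meta, None)  # trace filled in below
                    kinetics[wid] = kin
                    responder[wid] = is_resp
                    if is_resp:
                        analytic[wid] = analytic_metrics(k_a)
                    i_well += 1
            for j in range(config.negative_controls_per_animal):
                wid = _well_id(i_well)
                meta = WellMeta(
                    well_id=wid,
                    animal_id=animal,
                    group=group,
                    side=sides[j % len(sides)],
                    fragment_index=config.fragments_per_side + 1 + j // len(sides),
                    fragment_length_mm=config.fragment_length_mm,
                    is_negative_control=True,
                )
                plateaus = (k_a.R,) * 4
                clean_rows.append(noise_free_trace(plateaus, k_a.tau, sched))
                ecar_levels.append(k_a.ecar_basal)
                wells[wid] = Well(meta, None)
                kinetics[wid] = dataclasses.replace(k_a, B=k_a.R, O=k_a.R, F=k_a.R)
                responder[wid] = False
                i_well += 1

    clean = np.vstack(clean_rows)
    n_wells, n_total = clean.shape
    ocr_obs = clean * (1.0 + rng.normal(0.0, config.noise_cv, clean.shape))
    ecar_clean = np.tile(np.asarray(ecar_levels)[:, None], (1, n_total))
    ecar_obs = ecar_clean * (1.0 + rng.normal(0.0, config.noise_cv, ecar_clean.shape))

    for row, wid in enumerate(wells):
        wells[wid] = Well(
            wells[wid].meta, Trace(ocr_obs[row], ecar_obs[row], sched)
        )

    run = PlateRun(schedule=sched, wells=wells)
    run.log(
        "simulate_plate",
        seed=config.seed,
        groups=list(config.groups),
        n_animals_per_group=config.n_animals_per_group,
        wells_per_animal=config.wells_per_animal,
        nonresponder_prob=config.nonresponder_prob,
        noise_cv=config.noise_cv,
    )
    truth = GroundTruth(
        kinetics=kinetics, responder=responder, mef=mefs, analytic=analytic
    )
    return run, truth


# ---------------------------------------------------------------------------
# proteomics simulation
# ---------------------------------------------------------------------------


def simulate_proteomics(config: SimConfig) -> tuple[pd.DataFrame, frozenset[str]]:
    """Protein-abundance table (triplicate per animal) plus annotation set.

    Abundances are lognormal draws rescaled within each sample so the
    summed share of annotated mitochondrial proteins equals that
    animal's drawn MEF exactly — MEF recovery from the table is exact by
    construction.  Shares the MEF draws with :func:`simulate_plate`.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PROTEOMICS])
    mefs = _draw_mefs(config)
    n_mito = round(config.n_proteins * config.mito_fraction_of_proteins)
    mito_ids = [f"MT{i:04d}" for i in range(1, n_mito + 1)]
    other_ids = [f"NP{i:04d}" for i in range(1, config.n_proteins - n_mito + 1)]
    proteins = mito_ids + other_ids

    rows = []
    for animal in config.animal_ids:
        mef = mefs[animal]
        for rep in (1, 2, 3):
            raw = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_proteins)
            m = raw[:n_mito].sum()
            o = raw[n_mito:].sum()
            total = m + o
            scaled = np.concatenate(
                [raw[:n_mito] * (mef * total / m), raw[n_mito:] * ((1 - mef) * total / o)]
            )
            sample = f"{animal}-r{rep}"
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "animal_id": animal,
                        "protein_id": proteins,
                        "abundance": scaled,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    return table, frozenset(mito_ids)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def simulate_phenotype(config: SimConfig) -> pd.DataFrame:
    """Per-animal, per-week blood glucose and body weight draws.

    Glucose is censored at the glucometer ceiling of 33.3 mM.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PHENOTYPE])
    rows = []
    for group, spec in config.groups.items():
        glucose = {w: (m, s) for w, m, s in spec.glucose_mM}
        weight = {w: (m, s) for w, m, s in spec.body_weight_g}
        for a in range(1, config.n_animals_per_group + 1):
            animal = f"{group}-{a:02d}"
            for week in sorted(set(glucose) | set(weight)):
                gm, gs = glucose[week]
                wm, ws = weight[week]
                g = min(max(float(rng.normal(gm, gs)), 0.0), 33.3)
                w = max(float(rng.normal(wm, ws)), 1.0)
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "week": week,
                        "blood_glucose_mM": g,
                        "body_weight_g": w,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle output
# ---------------------------------------------------------------------------


def write_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate everything and write the plain-text data bundle.

    Emits the plate long CSV, phenotype CSV, proteomics TSV, the
    mitochondrial annotation list and a ground-truth JSON; returns the
    paths by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run, truth = simulate_plate(config)
    table, annot = simulate_proteomics(config)
    pheno = simulate_phenotype(config)

    paths = {
        "plate": outdir / "plate_long.csv",
        "phenotype": outdir / "phenotype.csv",
        "proteomics": outdir / "proteomics.tsv",
        "annotation": outdir / "mito_annotation.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_plate_long(run, paths["plate"])
    write_phenotype(pheno, paths["phenotype"])
    table.to_csv(paths["proteomics"], sep="\t", index=False)
    paths["annotation"].write_text("\n".join(sorted(annot)) + "\n")
    truth.write_json(paths["ground_truth"])
    return paths
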