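"""Mitochondrial enrichment factor (MEF) normalization of flux data.

The MEF of a sample is the summed abundance of proteins annotated
mitochondrial (a MitoCarta-style membership list) divided by the summed
abundance of all proteins — a dimensionless fraction in [0, 1] that
tracks mitochondrial protein content.  Flux traces are normalized per
animal (the proteomics derives from a separate nerve fragment, so no
per-well factor exists), by default relative to the cohort geometric
mean so the cohort scale and units are preserved.  Total protein and
citrate synthase activity are supported as alternative divisors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .plate_model import PlateFormatError, PlateRun

__all__ = [
    "PROTEOMICS_COLUMNS",
    "NormalizationError",
    "NormalizationFactors",
    "read_proteomics",
    "read_annotation",
    "compute_mef",
    "normalize_run",
    "NORMALIZATION_MODES",
]

PROTEOMICS_COLUMNS = ["sample_id", "animal_id", "protein_id", "abundance"]
NORMALIZATION_MODES = (
    "relative_mef",
    "absolute_mef",
    "total_protein",
    "cs_activity",
    "none",
)


class NormalizationError(ValueError):
    """Missing or invalid normalization factor."""


def read_proteomics(path: str | Path) -> pd.DataFrame:
    """Read the proteomics TSV (sample_id, animal_id, protein_id, abundance)."""
    df = pd.read_csv(path, sep="\t", dtype={"abundance": float})
    missing = [c for c in PROTEOMICS_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing required column(s): {', '.join(missing)}")
    return df[PROTEOMICS_COLUMNS]


def read_annotation(path: str | Path) -> frozenset[str]:
    """Read the mitochondrial annotation list (one protein ID per line)."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return frozenset(i for i in ids if i)


def compute_mef(
    table: pd.DataFrame, annotation: frozenset[str] | set[str]
) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-animal mitochondrial enrichment factors.

    ``MEF_sample = sum(abundance over annotated proteins) /
    sum(abundance over all proteins)``; the per-animal MEF is the mean
    over that animal's replicate samples.  Invariant under global
    rescaling of a sample's abundances.

    Returns ``(sample_mef, animal_mef)`` as Series indexed by sample_id
    and animal_id.
    """
    if not annotation:
        raise ValueError("annotation set is empty")
    missing = [c for c in PROTEOMICS_COLUMNS if c not in table.columns]
    if missing:
        raise PlateFormatError(f"missing required column(s): {', '.join(missing)}")
    if (table["abundance"] < 0).any():
        raise ValueError("negative abundances in proteomics table")
    if table.duplicated(subset=["sample_id", "protein_id"]).any():
        raise ValueError("duplicate (sample_id, protein_id) rows")

    total = table.groupby("sample_id")["abundance"].sum()
    zero = total[total <= 0]
    if len(zero):
        raise ValueError(f"zero total abundance in sample(s): {list(zero.index)}")

    is_mito = table["protein_id"].isin(annotation)
    if not is_mito.any():
        warnings.warn(
            "annotation set shares no protein IDs with the table; MEF is 0",
            stacklevel=2,
        )
    mito = table[is_mito].groupby("sample_id")["abundance"].sum()
    sample_mef = (mito.reindex(total.index, fill_value=0.0) / total).rename("mef")

    animal_of = table.drop_duplicates("sample_id").set_index("sample_id")["animal_id"]
    animal_mef = sample_mef.groupby(animal_of).mean().rename("mef")
    return sample_mef, animal_mef


@dataclass
class NormalizationFactors:
    """Per-animal normalization factors by mode."""

    mef: dict[str, float] = field(default_factory=dict)
    total_protein: dict[str, float] = field(default_factory=dict)
    cs_activity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, v in self.mef.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"MEF for animal {a} outside [0, 1]: {v}")

    @classmethod
    def from_mef(cls, animal_mef: pd.Series) -> "NormalizationFactors":
        return cls(mef={str(a): float(v) for a, v in animal_mef.items()})

    @classmethod
    def read_csv(cls, path: str | Path) -> "NormalizationFactors":
        df = pd.read_csv(path)
        if "animal_id" not in df.columns:
            raise PlateFormatError("missing required column(s): animal_id")
        kw = {}
        for col in ("mef", "total_protein", "cs_activity"):
            if col in df.columns:
                sub = df[df[col].notna()]
                kw[col] = dict(zip(sub["animal_id"].astype(str), sub[col].astype(float)))
        return cls(**kw)

    def write_csv(self, path: str | Path) -> None:
        animals = sorted(set(self.mef) | set(self.total_protein) | set(self.cs_activity))
        df = pd.DataFrame(
            {
                "animal_id": animals,
                "mef": [self.mef.get(a, float("nan")) for a in animals],
                "total_protein": [self.total_protein.get(a, float("nan")) for a in animals],
                "cs_activity": [self.cs_activity.get(a, float("nan")) for a in animals],
            }
        )
        df.to_csv(path, index=False)

    def for_mode(self, mode: str) -> dict[str, float]:
        if mode in ("relative_mef", "absolute_mef"):
            return self.mef
        if mode == "total_protein":
            return self.total_protein
        if mode == "cs_activity":
            return self.cs_activity
        raise ValueError(f"no factors for mode {mode!r}")


def normalize_run(
    run: PlateRun,
    factors: NormalizationFactors,
    mode: str = "relative_mef",
    reference: str = "geometric",
) -> PlateRun:
    """Scale each animal's traces by its normalization factor.

    ``relative_mef`` (default) divides by ``MEF_animal / reference-mean
    MEF`` over the animals with included wells, preserving the cohort
    scale and units (the reference mean is geometric by default,
    arithmetic with ``reference="arithmetic"``).  ``absolute_mef``
    divides by the MEF itself; ``total_protein`` / ``cs_activity``
    divide by the respective factor; ``none`` is the identity.

    Per-well scalar division leaves every dimensionless metric (spare,
    coupling, and the reference-based toxicity scores when references
    are rebuilt) unchanged.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}")
    out = run.copy()
    if mode == "none":
        out.log("normalize_run", mode="none")
        return out
    if reference not in ("geometric", "arithmetic"):
        raise ValueError("reference must be 'geometric' or 'arithmetic'")

    table = factors.for_mode(mode)
    animals = sorted({meta.animal_id for _, meta, _ in out.included()})
    missing = [a for a in animals if a not in table]
    if missing:
        raise NormalizationError(
            f"no {mode} factor for animal(s): {', '.join(missing)}"
        )
    bad = [a for a in animals if not table[a] > 0]
    if bad:
        raise NormalizationError(
            f"nonpositive {mode} factor for animal(s): {', '.join(bad)}"
        )

    if mode == "relative_mef":
        vals = np.array([table[a] for a in animals])
        ref = float(gmean(vals)) if reference == "geometric" else float(vals.mean())
        divisor = {a: table[a] / ref for a in animals}
    else:
        divisor = {a: table[a] for a in animals}

    for wid, well in out.wells.items():
        d = divisor.get(well.meta.animal_id)
        if d is not None:
            well.trace.ocr /= d
            well.trace.ecar /= d
    out.log(
        "normalize_run",
        mode=mode,
        reference=reference if mode == "relative_mef" else None,
        divisors={a: float(d) for a, d in divisor.items()},
    )
    return out
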