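"""Domain types, instrument configuration and table I/O.

Calibrant and feature tables are plain CSV with a header row; fitted
parameters and configuration are serialized as JSON.  Arrival times are
milliseconds everywhere, m/z in thomson, CCS in squared angstroms.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import RowParseError, SchemaError, UnknownClassError

#: Mass of molecular nitrogen, the usual TWIM drift gas, in Da.
NITROGEN_MASS = 28.0134


class BiomolecularClass(str, enum.Enum):
    """Singly-charged biomolecular classes with their own calibration."""

    LIPID = "lipid"
    SMALL_MOLECULE = "small_molecule"
    PEPTIDE = "peptide"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Accepted spellings for class labels, compared after lowercasing and
# stripping spaces/hyphens/underscores.  User tables vary wildly here.
_CLASS_SYNONYMS = {
    "lipid": BiomolecularClass.LIPID,
    "lipids": BiomolecularClass.LIPID,
    "smallmolecule": BiomolecularClass.SMALL_MOLECULE,
    "smallmolecules": BiomolecularClass.SMALL_MOLECULE,
    "smallmol": BiomolecularClass.SMALL_MOLECULE,
    "metabolite": BiomolecularClass.SMALL_MOLECULE,
    "metabolites": BiomolecularClass.SMALL_MOLECULE,
    "peptide": BiomolecularClass.PEPTIDE,
    "peptides": BiomolecularClass.PEPTIDE,
}


def normalize_class_label(label: str) -> BiomolecularClass:
    """Map a free-form class label onto the class enum.

    Matching is case-insensitive and ignores spaces, hyphens and
    underscores, so ``"Small Molecule"``, ``"small_molecule"`` and
    ``"metabolite"`` all resolve to :attr:`BiomolecularClass.SMALL_MOLECULE`.
    """
    key = str(label).strip().lower().replace(" ", "").replace("-", "").replace("_", "")
    try:
        return _CLASS_SYNONYMS[key]
    except KeyError:
        accepted = sorted({s for s in _CLASS_SYNONYMS})
        raise UnknownClassError(
            f"unknown biomolecular class {label!r}; accepted labels (any casing): {accepted}"
        ) from None


@dataclass(frozen=True)
class InstrumentConfig:
    """Instrument constants and decision thresholds.

    Parameters
    ----------
    edc_coefficient
        Dimensionless EDC delay coefficient scaling the mass-dependent
        post-mobility flight-time correction; unique to each instrument.
    drift_gas_mass
        Mass of the drift gas in Da (default nitrogen).
    mz_constraint_small_molecule_max
        Features at or above this m/z cannot be assigned as small molecules.
    mz_constraint_lipid_min
        Features at or below this m/z cannot be assigned as lipids.
    score_thresholds
        Strictly increasing percent breakpoints separating calibration-effect
        scores 1|2, 2|3 and 3|4.
    """

    edc_coefficient: float = 1.57
    drift_gas_mass: float = NITROGEN_MASS
    mz_constraint_small_molecule_max: float = 550.0
    mz_constraint_lipid_min: float = 300.0
    score_thresholds: tuple = (1.0, 3.0, 6.0)

    def __post_init__(self):
        if self.edc_coefficient < 0:
            raise ValueError("edc_coefficient must be >= 0")
        if self.drift_gas_mass <= 0:
            raise ValueError("drift_gas_mass must be > 0")
        t = tuple(float(x) for x in self.score_thresholds)
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ValueError("score_thresholds must be three strictly increasing values")
        object.__setattr__(self, "score_thresholds", t)

    def to_dict(self) -> dict:
        return {
            "edc_coefficient": self.edc_coefficient,
            "drift_gas_mass": self.drift_gas_mass,
            "mz_constraint_small_molecule_max": self.mz_constraint_small_molecule_max,
            "mz_constraint_lipid_min": self.mz_constraint_lipid_min,
            "score_thresholds": list(self.score_thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(
            edc_coefficient=d["edc_coefficient"],
            drift_gas_mass=d.get("drift_gas_mass", NITROGEN_MASS),
            mz_constraint_small_molecule_max=d.get("mz_constraint_small_molecule_max", 550.0),
            mz_constraint_lipid_min=d.get("mz_constraint_lipid_min", 300.0),
            score_thresholds=tuple(d.get("score_thresholds", (1.0, 3.0, 6.0))),
        )


@dataclass
class Calibrant:
    """A reference species with a known drift-tube CCS.

    ``arrival_time`` may be absent until extracted from raw mobility data.
    Lipid and small-molecule calibrants are singly charged; peptide
    calibrants may carry z = 1-3.
    """

    name: str
    mz: float
    z: int
    ccs_ref: float
    biomolecular_class: BiomolecularClass
    arrival_time: Optional[float] = None

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"calibrant {self.name!r}: mz must be > 0")
        if not self.ccs_ref > 0:
            raise ValueError(f"calibrant {self.name!r}: ccs_ref must be > 0")
        if self.z < 1:
            raise ValueError(f"calibrant {self.name!r}: z must be >= 1")
        cls = self.biomolecular_class
        if cls is BiomolecularClass.PEPTIDE:
            if self.z not in (1, 2, 3):
                raise ValueError(f"calibrant {self.name!r}: peptide z must be 1-3")
        elif self.z != 1:
            raise ValueError(f"calibrant {self.name!r}: {cls.value} calibrants must have z = 1")
        if self.arrival_time is not None and not self.arrival_time > 0:
            raise ValueError(f"calibrant {self.name!r}: arrival_time must be > 0")


@dataclass
class Feature:
    """An unknown ion to be calibrated and classified."""

    feature_id: str
    mz: float
    z: int
    arrival_time: float
    retention_time: Optional[float] = None

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id!r}: mz must be > 0")
        if not self.arrival_time > 0:
            raise ValueError(f"feature {self.feature_id!r}: arrival_time must be > 0")
        if self.z < 1:
            raise ValueError(f"feature {self.feature_id!r}: z must be >= 1")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _row_float(row_idx: int, value, column: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise RowParseError(row_idx, f"non-numeric {column} value {value!r}") from None
    if math.isnan(out):
        raise RowParseError(row_idx, f"missing {column} value")
    return out


def read_calibrant_table(path) -> list[Calibrant]:
    """Read a calibrant CSV (columns name, mz, ccs_ref, class, z[, arrival_time]).

    Rows are returned in input order; class labels are normalized
    case-insensitively (see :func:`normalize_class_label`).
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, ["name", "mz", "ccs_ref", "class", "z"], f"calibrant table {path}")
    has_at = "arrival_time" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        mz = _row_float(i, rec["mz"], "mz")
        ccs = _row_float(i, rec["ccs_ref"], "ccs_ref")
        try:
            z = int(float(rec["z"]))
        except (TypeError, ValueError):
            raise RowParseError(i, f"non-numeric z value {rec['z']!r}") from None
        at = None
        if has_at and rec.get("arrival_time") not in (None, "") and not (
            isinstance(rec.get("arrival_time"), float) and math.isnan(rec["arrival_time"])
        ):
            at = _row_float(i, rec["arrival_time"], "arrival_time")
        try:
            cal = Calibrant(
                name=str(rec["name"]),
                mz=mz,
                z=z,
                ccs_ref=ccs,
                biomolecular_class=normalize_class_label(rec["class"]),
                arrival_time=at,
            )
        except ValueError as e:
            raise RowParseError(i, str(e)) from None
        out.append(cal)
    return out


def read_feature_table(path) -> list[Feature]:
    """Read a feature CSV (columns feature_id, mz, z, arrival_time[, retention_time]).

    Duplicate feature ids trigger a warning but both rows are kept.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, ["feature_id", "mz", "z", "arrival_time"], f"feature table {path}")
    dups = df["feature_id"][df["feature_id"].duplicated()].unique()
    if len(dups):
        warnings.warn(
            f"duplicate feature_id values kept as-is: {', '.join(map(str, dups[:5]))}",
            stacklevel=2,
        )
    has_rt = "retention_time" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        mz = _row_float(i, rec["mz"], "mz")
        at = _row_float(i, rec["arrival_time"], "arrival_time")
        try:
            z = int(float(rec["z"]))
        except (TypeError, ValueError):
            raise RowParseError(i, f"non-numeric z value {rec['z']!r}") from None
        rt = None
        if has_rt and rec.get("retention_time") not in (None, ""):
            try:
                rt = float(rec["retention_time"])
                if math.isnan(rt):
                    rt = None
            except ValueError:
                raise RowParseError(i, f"non-numeric retention_time {rec['retention_time']!r}") from None
        try:
            feat = Feature(
                feature_id=str(rec["feature_id"]), mz=mz, z=z, arrival_time=at,
                retention_time=rt,
            )
        except ValueError as e:
            raise RowParseError(i, str(e)) from None
        out.append(feat)
    return out


# Column layout of the results CSV.  Per-class CCS/delta columns cover the
# three singly charged classes; multiply charged features leave the lipid and
# small-molecule columns empty and report the charge-matched peptide value in
# the peptide column.
RESULT_COLUMNS = [
    "feature_id", "mz", "z", "retention_time", "arrival_time",
    "ccs_lipid", "ccs_small_molecule", "ccs_peptide",
    "delta_lipid", "delta_small_molecule", "delta_peptide",
    "assigned_class", "final_ccs", "score", "constraint_fallback",
]


def write_results(assignments, path) -> None:
    """Write assignments to a results CSV (one row per feature).

    Numeric CCS values are written with four decimal places.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments to write")
    rows = []
    for a in assignments:
        row = {c: "" for c in RESULT_COLUMNS}
        f = a.feature
        row.update(
            feature_id=f.feature_id, mz=f.mz, z=f.z,
            retention_time="" if f.retention_time is None else f.retention_time,
            arrival_time=f.arrival_time,
            assigned_class=a.assigned_class,
            final_ccs=f"{a.final_ccs:.4f}",
            score="" if a.score is None else a.score,
            constraint_fallback=int(a.constraint_fallback),
        )
        for key, ccs in a.per_class_ccs.items():
            col = "ccs_peptide" if key.startswith("peptide") else f"ccs_{key}"
            row[col] = f"{ccs:.4f}"
        for key, delta in a.per_class_delta.items():
            col = "delta_peptide" if key.startswith("peptide") else f"delta_{key}"
            row[col] = f"{delta:.4f}"
        rows.append(row)
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
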