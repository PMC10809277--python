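"""The class-assignment decision core.

Every singly charged feature is calibrated with each available z=1
curve (lipid, small molecule, peptide).  Each calibrated value is
compared against its own class's CCS-vs-m/z trendline, and the class
whose calibrated value lands closest to its trendline (smallest
delta-CCS) wins -- subject to m/z plausibility constraints (small
molecules below m/z 550, lipids above m/z 300).  When the closest class
is rejected by the constraints, the next closest eligible class is
taken and the assignment is flagged.

Features with two or more charges are treated as peptides and
calibrated only with the charge-matched peptide curve; no trendline
arbitration is performed for them.

Each singly charged assignment carries a calibration-effect score, 1-4,
quantifying how different the assigned-class CCS is from the value the
next closest class would have produced: 4 means >= 6% apart (the choice
of calibration mattered a lot), 1 means < 1% (any calibration would
have given nearly the same value).  Multiply charged assignments score
0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config_io import BiomolecularClass, Feature, InstrumentConfig
from .errors import MissingCurveError, UnassignableFeatureError, UnsupportedChargeError
from .powerlaw_calibration import CalibrationCurve, apply_calibration
from .trendlines import TrendlineModel, delta_ccs, predict_trendline_ccs

# Deterministic tie-break order for exactly equal delta-CCS values.
_CLASS_PRIORITY = {
    BiomolecularClass.LIPID: 0,
    BiomolecularClass.SMALL_MOLECULE: 1,
    BiomolecularClass.PEPTIDE: 2,
}


@dataclass
class Assignment:
    """Outcome of calibrating and classifying one feature."""

    feature: Feature
    per_class_ccs: dict = field(default_factory=dict)
    per_class_delta: dict = field(default_factory=dict)
    assigned_class: str = ""
    final_ccs: float = 0.0
    score: Optional[int] = None
    constraint_fallback: bool = False


def class_eligible(
    biomolecular_class: BiomolecularClass, mz: float, config: InstrumentConfig
) -> bool:
    """m/z plausibility of a class for a singly charged feature.

    Small molecules must lie strictly below the small-molecule m/z cap,
    lipids strictly above the lipid m/z floor; peptides are unconstrained.
    """
    if mz <= 0:
        raise ValueError("mz must be > 0")
    cls = BiomolecularClass(biomolecular_class)
    if cls is BiomolecularClass.SMALL_MOLECULE:
        return mz < config.mz_constraint_small_molecule_max
    if cls is BiomolecularClass.LIPID:
        return mz > config.mz_constraint_lipid_min
    return True


def score_assignment(
    assigned_ccs: float,
    next_best_ccs: Optional[float],
    z: int,
    thresholds: Sequence[float] = (1.0, 3.0, 6.0),
) -> Optional[int]:
    """Calibration-effect score.

    With ``d = 100 * |assigned - next_best| / assigned``: d >= 6 -> 4,
    3 <= d < 6 -> 3, 1 <= d < 3 -> 2, d < 1 -> 1 (boundaries belong to
    the higher score).  Multiply charged features score 0; with no
    second attempted class the score is undefined (None).
    """
    if z >= 2:
        return 0
    if next_best_ccs is None:
        return None
    if assigned_ccs <= 0 or next_best_ccs <= 0:
        raise ValueError("CCS values must be positive for scoring")
    t1, t2, t3 = thresholds
    d = 100.0 * abs(assigned_ccs - next_best_ccs) / assigned_ccs
    if d >= t3:
        return 4
    if d >= t2:
        return 3
    if d >= t1:
        return 2
    return 1


def assign_feature(
    feature: Feature,
    curves: dict[str, CalibrationCurve],
    trendlines: dict[str, TrendlineModel],
    config: InstrumentConfig,
) -> Assignment:
    """Calibrate one feature with all applicable curves and pick its class.

    ``curves`` is keyed by curve key ("lipid", "small_molecule",
    "peptide", "peptide_z2", "peptide_z3"); ``trendlines`` by the z=1
    class names.  Raises :class:`UnsupportedChargeError` for z >= 4 and
    :class:`UnassignableFeatureError` when no class passes the m/z
    constraints.
    """
    z = feature.z
    if z >= 4:
        raise UnsupportedChargeError(
            f"feature {feature.feature_id!r}: charge {z} outside the calibrated range (1-3)"
        )
    if z >= 2:
        key = f"peptide_z{z}"
        if key not in curves:
            raise MissingCurveError(
                f"feature {feature.feature_id!r}: no {key} calibration curve available"
            )
        ccs = apply_calibration(
            feature.arrival_time, feature.mz, z, curves[key], config,
            label=feature.feature_id,
        )
        return Assignment(
            feature=feature,
            per_class_ccs={key: ccs},
            per_class_delta={},
            assigned_class=key,
            final_ccs=ccs,
            score=0,
        )

    # z = 1: arbitrate among every class with both a curve and a trendline
    per_ccs: dict[str, float] = {}
    per_delta: dict[str, float] = {}
    attempted: list[BiomolecularClass] = []
    for cls in _CLASS_PRIORITY:
        key = cls.value
        if key not in curves or key not in trendlines:
            continue
        ccs = apply_calibration(
            feature.arrival_time, feature.mz, 1, curves[key], config,
            label=feature.feature_id,
        )
        predicted = predict_trendline_ccs(
            trendlines[key], feature.mz, warn_extrapolation=False
        )
        per_ccs[key] = ccs
        per_delta[key] = delta_ccs(ccs, predicted)
        attempted.append(cls)
    if not attempted:
        raise MissingCurveError(
            f"feature {feature.feature_id!r}: no z=1 curve with a matching trendline"
        )

    ranked = sorted(attempted, key=lambda c: (per_delta[c.value], _CLASS_PRIORITY[c]))
    eligible = [c for c in ranked if class_eligible(c, feature.mz, config)]
    if not eligible:
        raise UnassignableFeatureError(feature.feature_id, per_delta)
    chosen = eligible[0]
    fallback = chosen is not ranked[0]

    next_best = next((c for c in ranked if c is not chosen), None)
    score = score_assignment(
        per_ccs[chosen.value],
        per_ccs[next_best.value] if next_best is not None else None,
        z,
        config.score_thresholds,
    )
    return Assignment(
        feature=feature,
        per_class_ccs=per_ccs,
        per_class_delta=per_delta,
        assigned_class=chosen.value,
        final_ccs=per_ccs[chosen.value],
        score=score,
        constraint_fallback=fallback,
    )


def assign_features(
    features: Sequence[Feature],
    curves: dict[str, CalibrationCurve],
    trendlines: dict[str, TrendlineModel],
    config: InstrumentConfig,
) -> tuple[list[Assignment], list[UnassignableFeatureError]]:
    """Assign a batch, collecting unassignable features instead of raising."""
    assignments, failures = [], []
    for f in features:
        try:
            assignments.append(assign_feature(f, curves, trendlines, config))
        except UnassignableFeatureError as e:
            failures.append(e)
    return assignments, failures
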