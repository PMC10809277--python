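"""Power-law CCS calibration for traveling-wave ion mobility.

TWIM arrival times have no closed-form relation to collision cross
section, so CCS is obtained by calibration against species with known
drift-tube values.  The protocol implemented here is the standard
corrected-time / corrected-CCS power law:

1. the measured arrival time is stripped of the mass-dependent
   post-mobility flight time, ``t' = t_a - EDC * sqrt(m/z) / 1000``
   (times in ms);
2. the reference CCS is normalized by charge and by the square root of
   the ion-gas reduced mass, ``omega' = ccs * sqrt(mu) / z`` with
   ``mu = m_ion * m_gas / (m_ion + m_gas)``;
3. a class-specific power law ``omega' = A * t'**B`` is fitted by
   nonlinear least squares (seeded from a log-log linear regression);
4. for unknowns the corrections are inverted:
   ``ccs = A * t'**B * z / sqrt(mu)``.

Because each biomolecular class expands differently in size with mass,
one curve is fitted per class (and per charge state for peptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .config_io import BiomolecularClass, Calibrant, InstrumentConfig
from .errors import (
    FitConvergenceError,
    InsufficientCalibrantsError,
    InvalidCorrectionError,
)


@dataclass(frozen=True)
class CorrectedPoint:
    """One calibrant in calibration space: (t', omega')."""

    t_prime: float
    omega_prime: float

    def __post_init__(self):
        if not self.t_prime > 0:
            raise ValueError("t_prime must be > 0")
        if not self.omega_prime > 0:
            raise ValueError("omega_prime must be > 0")


@dataclass
class CalibrationCurve:
    """Fitted power-law parameters for one class/charge group."""

    biomolecular_class: BiomolecularClass
    z_group: int
    A: float
    B: float
    n_calibrants: int = 0
    rmse_ccs: float = 0.0
    mean_abs_pct_error: float = 0.0
    per_calibrant_errors: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.A > 0 and self.B > 0):
            raise ValueError("power-law parameters A and B must be positive")

    @property
    def key(self) -> str:
        return curve_key(self.biomolecular_class, self.z_group)

    def to_dict(self) -> dict:
        return {
            "class": self.biomolecular_class.value,
            "z_group": self.z_group,
            "A": self.A,
            "B": self.B,
            "n_calibrants": self.n_calibrants,
            "rmse_ccs": self.rmse_ccs,
            "mean_abs_pct_error": self.mean_abs_pct_error,
            "per_calibrant_errors": list(self.per_calibrant_errors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            biomolecular_class=BiomolecularClass(d["class"]),
            z_group=int(d["z_group"]),
            A=float(d["A"]),
            B=float(d["B"]),
            n_calibrants=int(d.get("n_calibrants", 0)),
            rmse_ccs=float(d.get("rmse_ccs", 0.0)),
            mean_abs_pct_error=float(d.get("mean_abs_pct_error", 0.0)),
            per_calibrant_errors=list(d.get("per_calibrant_errors", [])),
        )


def curve_key(biomolecular_class: BiomolecularClass, z: int) -> str:
    """Dictionary key for a curve: class name, with charge for peptides z>=2."""
    cls = BiomolecularClass(biomolecular_class)
    if cls is BiomolecularClass.PEPTIDE and z >= 2:
        return f"peptide_z{z}"
    return cls.value


def correct_arrival_time(t_a, mz, edc: float, *, label: str = "ion"):
    """EDC flight-time correction: ``t' = t_a - edc * sqrt(mz) / 1000`` (ms).

    Raises :class:`InvalidCorrectionError` when the correction exceeds the
    arrival time, which indicates inconsistent inputs (wrong units or EDC).
    Accepts scalars or arrays.
    """
    t_a = np.asarray(t_a, dtype=float)
    mz = np.asarray(mz, dtype=float)
    t_prime = t_a - edc * np.sqrt(mz) / 1000.0
    if np.any(t_prime <= 0):
        raise InvalidCorrectionError(
            f"{label}: corrected arrival time <= 0 (t_a={t_a}, mz={mz}, edc={edc})"
        )
    return t_prime if t_prime.ndim else float(t_prime)


def reduced_mass(m_ion, m_gas: float):
    """Reduced mass of the ion-gas pair, ``mu = m_ion*m_gas/(m_ion+m_gas)`` (Da)."""
    m_ion = np.asarray(m_ion, dtype=float)
    if np.any(m_ion <= 0) or m_gas <= 0:
        raise ValueError("masses must be positive")
    mu = m_ion * m_gas / (m_ion + m_gas)
    return mu if mu.ndim else float(mu)


def correct_ccs(ccs_ref, z, mu):
    """Charge/reduced-mass normalized CCS: ``omega' = ccs * sqrt(mu) / z``."""
    ccs_ref = np.asarray(ccs_ref, dtype=float)
    out = ccs_ref * np.sqrt(mu) / z
    return out if out.ndim else float(out)


def _loglog_seed(t: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(np.log(t), np.log(w))
    return float(np.exp(res.intercept)), float(res.slope)


def fit_power_law(
    points: Sequence[CorrectedPoint], *, method: str = "nonlinear"
) -> tuple[float, float, dict]:
    """Fit ``omega' = A * t'**B`` to corrected calibrant points.

    ``method='nonlinear'`` (default) runs unweighted nonlinear least
    squares in linear space, seeded from a log-log regression;
    ``method='loglog'`` returns the log-log regression itself.  The
    diagnostics dict carries both parameterizations plus residuals.
    """
    if len(points) < 3:
        raise InsufficientCalibrantsError(
            f"power-law fit needs >= 3 calibrants, got {len(points)}"
        )
    t = np.array([p.t_prime for p in points], dtype=float)
    w = np.array([p.omega_prime for p in points], dtype=float)
    a0, b0 = _loglog_seed(t, w)
    if method == "loglog":
        A, B = a0, b0
    elif method == "nonlinear":
        try:
            popt, _ = optimize.curve_fit(
                lambda x, A, B: A * x ** B, t, w, p0=(a0, b0), maxfev=10000
            )
        except RuntimeError as e:
            raise FitConvergenceError(
                f"power-law fit did not converge: {e}", seed_params=(a0, b0)
            ) from None
        A, B = float(popt[0]), float(popt[1])
    else:
        raise ValueError(f"unknown fit method {method!r}")
    residuals = w - A * t ** B
    diagnostics = {
        "loglog_A": a0,
        "loglog_B": b0,
        "residuals_omega": residuals.tolist(),
        "rss_omega": float(np.sum(residuals**2)),
    }
    return A, B, diagnostics


def apply_calibration(
    t_a, mz, z: int, curve: CalibrationCurve, config: InstrumentConfig, *, label: str = "ion"
):
    """Calibrated CCS of an unknown: ``A * t'**B * z / sqrt(mu)`` (A^2).

    Inverts the charge/reduced-mass normalization used when fitting the
    curve.  Accepts scalar or array ``t_a``/``mz``.
    """
    t_prime = correct_arrival_time(t_a, mz, config.edc_coefficient, label=label)
    mu = reduced_mass(np.asarray(mz, dtype=float) * z, config.drift_gas_mass)
    out = curve.A * np.asarray(t_prime) ** curve.B * z / np.sqrt(mu)
    return out if np.ndim(out) else float(out)


def calibration_metrics(
    curve: CalibrationCurve, calibrants: Sequence[Calibrant], config: InstrumentConfig
) -> tuple[float, float, list[float]]:
    """Self-consistency of a fitted curve on its own calibrants.

    Returns ``(rmse_ccs, mean_abs_pct_error, per_calibrant_errors)`` where
    per-calibrant error is ``100 * (calibrated - ccs_ref) / ccs_ref`` and
    RMSE is computed on CCS in A^2.
    """
    calibrants = list(calibrants)
    if not calibrants:
        raise ValueError("empty calibrant set")
    for c in calibrants:
        if curve_key(c.biomolecular_class, c.z) != curve.key:
            raise ValueError(
                f"calibrant {c.name!r} ({curve_key(c.biomolecular_class, c.z)}) "
                f"does not belong to curve {curve.key}"
            )
    calibrated = np.array(
        [apply_calibration(c.arrival_time, c.mz, c.z, curve, config, label=c.name)
         for c in calibrants]
    )
    ref = np.array([c.ccs_ref for c in calibrants])
    pct = 100.0 * (calibrated - ref) / ref
    rmse = float(np.sqrt(np.mean((calibrated - ref) ** 2)))
    return rmse, float(np.mean(np.abs(pct))), pct.tolist()


def fit_calibration_curve(
    calibrants: Iterable[Calibrant],
    config: InstrumentConfig,
    *,
    biomolecular_class: Optional[BiomolecularClass] = None,
    z: Optional[int] = None,
    method: str = "nonlinear",
) -> CalibrationCurve:
    """Fit one class/charge calibration curve from calibrants with arrival times.

    When ``biomolecular_class``/``z`` are omitted they are inferred from the
    calibrants, which must then be homogeneous.
    """
    cals = [c for c in calibrants]
    if biomolecular_class is not None:
        cals = [c for c in cals if c.biomolecular_class is biomolecular_class]
    if z is not None:
        cals = [c for c in cals if c.z == z]
    if len(cals) < 3:
        raise InsufficientCalibrantsError(
            f"need >= 3 calibrants for class={biomolecular_class}, z={z}; got {len(cals)}"
        )
    keys = {curve_key(c.biomolecular_class, c.z) for c in cals}
    if len(keys) > 1:
        raise ValueError(f"calibrants span multiple class/charge groups: {sorted(keys)}")
    missing = [c.name for c in cals if c.arrival_time is None]
    if missing:
        raise ValueError(f"calibrants lack arrival times: {', '.join(missing)}")
    cls = cals[0].biomolecular_class
    zg = cals[0].z
    points = [
        CorrectedPoint(
            t_prime=correct_arrival_time(c.arrival_time, c.mz, config.edc_coefficient, label=c.name),
            omega_prime=correct_ccs(
                c.ccs_ref, c.z, reduced_mass(c.mz * c.z, config.drift_gas_mass)
            ),
        )
        for c in cals
    ]
    A, B, diagnostics = fit_power_law(points, method=method)
    curve = CalibrationCurve(
        biomolecular_class=cls, z_group=zg, A=A, B=B,
        n_calibrants=len(cals), diagnostics=diagnostics,
    )
    rmse, mape, per_err = calibration_metrics(curve, cals, config)
    curve.rmse_ccs = rmse
    curve.mean_abs_pct_error = mape
    curve.per_calibrant_errors = per_err
    return curve


def fit_all_curves(
    calibrants: Iterable[Calibrant], config: InstrumentConfig, *, method: str = "nonlinear"
) -> dict[str, CalibrationCurve]:
    """Fit every class/charge group present among the calibrants.

    Groups with fewer than three calibrants raise; peptides are split by
    charge state (z = 1, 2, 3 each get their own curve).
    """
    groups: dict[str, list[Calibrant]] = {}
    for c in calibrants:
        groups.setdefault(curve_key(c.biomolecular_class, c.z), []).append(c)
    return {
        key: fit_calibration_curve(
            group, config, biomolecular_class=group[0].biomolecular_class,
            z=group[0].z, method=method,
        )
        for key, group in groups.items()
    }


def save_curves(curves: dict[str, CalibrationCurve], config: InstrumentConfig, path) -> None:
    from .config_io import save_json

    save_json(
        {"config": config.to_dict(), "curves": {k: c.to_dict() for k, c in curves.items()}},
        path,
    )


def load_curves(path) -> tuple[dict[str, CalibrationCurve], InstrumentConfig]:
    from .config_io import load_json

    d = load_json(path)
    config = InstrumentConfig.from_dict(d["config"])
    curves = {k: CalibrationCurve.from_dict(v) for k, v in d["curves"].items()}
    return curves, config
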