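"""Synthetic calibrants/features with known ground truth, and the
calibration-error robustness experiment.

The generators emulate the geometry of positive-mode ion-mobility
conformational space: three class trendlines (peptides lowest, small
molecules below peptides at low mass, lipids highest over m/z
300-1000), and class-specific power-law calibration curves that agree
with one another to within a few percent -- the regime in which the
choice of calibration genuinely matters.

The robustness experiment mirrors a paired perturbation design: one
fixed set of reference features (true CCS drawn from its class
trendline with multiplicative scatter) has its CCS values shifted by a
signed percentage, the shifted values are converted back to arrival
times through the class's own calibration curve, and the full
assignment machinery is run.  The tabulated per-class accuracy shows
how calibration error erodes classification: lipids (uppermost
trendline) lose accuracy under negative errors, peptides (lowest
trendline) under positive errors, while small molecules, well separated
from both at low m/z, are largely insensitive.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .class_assignment import assign_feature
from .config_io import BiomolecularClass, Calibrant, Feature, InstrumentConfig
from .errors import GenerationError
from .powerlaw_calibration import (
    CalibrationCurve,
    correct_ccs,
    curve_key,
    reduced_mass,
)
from .trendlines import TrendlineModel, predict_trendline_ccs

# ---------------------------------------------------------------------------
# Default synthetic reference geometry
# ---------------------------------------------------------------------------

#: Power-law trendline coefficients (a, b) for CCS = a * mz**b, chosen to
#: mimic the ordering and spacing of conformational space: lipids sit
#: 20-40 A^2 above peptides over m/z 400-1000, peptides 25-40 A^2 above small
#: molecules below m/z 550.
DEFAULT_TRENDLINE_COEFFS = {
    BiomolecularClass.LIPID: (7.7, 0.55),
    BiomolecularClass.SMALL_MOLECULE: (6.0, 0.54),
    BiomolecularClass.PEPTIDE: (9.5, 0.50),
}

#: m/z ranges over which each class's synthetic features/calibrants live.
DEFAULT_MZ_RANGES = {
    BiomolecularClass.LIPID: (400.0, 1000.0),
    BiomolecularClass.SMALL_MOLECULE: (120.0, 540.0),
    BiomolecularClass.PEPTIDE: (300.0, 1000.0),
}

#: Power-law calibration parameters (A, B) per curve key.  The z=1 curves
#: agree to ~1-3% over the working drift-time range, so cross-class
#: calibrated values differ by realistic amounts.
DEFAULT_CURVE_PARAMS = {
    "lipid": (420.0, 0.52),
    "small_molecule": (430.0, 0.515),
    "peptide": (412.0, 0.524),
    "peptide_z2": (450.0, 0.49),
    "peptide_z3": (465.0, 0.46),
}


def default_trendlines() -> dict[str, TrendlineModel]:
    """Synthetic per-class trendlines over the default m/z ranges."""
    models = {}
    for cls, (a, b) in DEFAULT_TRENDLINE_COEFFS.items():
        lo, hi = DEFAULT_MZ_RANGES[cls]
        models[cls.value] = TrendlineModel(
            biomolecular_class=cls, form="power", coefficients=(a, b),
            mz_domain=(lo, hi), n_refs=0,
        )
    return models


def default_curves() -> dict[str, CalibrationCurve]:
    """Synthetic calibration curves for all five class/charge groups."""
    out = {}
    for key, (A, B) in DEFAULT_CURVE_PARAMS.items():
        if key.startswith("peptide_z"):
            cls, z = BiomolecularClass.PEPTIDE, int(key[-1])
        else:
            cls, z = BiomolecularClass(key), 1
        out[key] = CalibrationCurve(biomolecular_class=cls, z_group=z, A=A, B=B)
    return out


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions under which synthetic features are generated."""

    class_proportions: dict = field(
        default_factory=lambda: {
            BiomolecularClass.LIPID: 1 / 3,
            BiomolecularClass.SMALL_MOLECULE: 1 / 3,
            BiomolecularClass.PEPTIDE: 1 / 3,
        }
    )
    mz_ranges: dict = field(default_factory=lambda: dict(DEFAULT_MZ_RANGES))
    trendline_scatter_pct: float = 1.0
    calibration_error_pct: float = 0.0
    n_features: int = 600
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass
class RobustnessTable:
    """Per-class assignment accuracy (%) across signed CCS perturbations."""

    classes: list
    perturbations_pct: list
    accuracy: np.ndarray  # shape (classes, perturbations), percent

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.accuracy,
            index=[c.value for c in self.classes],
            columns=[f"{p:+g}%" if p else "0%" for p in self.perturbations_pct],
        )


def invert_calibration(
    ccs: float, mz: float, z: int, curve: CalibrationCurve, config: InstrumentConfig
) -> float:
    """Arrival time (ms) that calibrates to ``ccs`` under the given curve.

    Exact inverse of the calibration chain: normalize the CCS, solve the
    power law for t', add back the EDC flight-time term.
    """
    mu = reduced_mass(mz * z, config.drift_gas_mass)
    omega_prime = correct_ccs(ccs, z, mu)
    t_prime = (omega_prime / curve.A) ** (1.0 / curve.B)
    t_a = t_prime + config.edc_coefficient * np.sqrt(mz) / 1000.0
    if not t_prime > 0 or not np.isfinite(t_a):
        raise GenerationError(
            f"back-solved arrival time invalid for ccs={ccs}, mz={mz}, z={z}"
        )
    return float(t_a)


def generate_synthetic_calibrants(
    biomolecular_class: BiomolecularClass,
    z: int,
    A: float,
    B: float,
    n: int,
    noise_pct: float,
    seed: int,
    config: InstrumentConfig,
    mz_range: Optional[tuple[float, float]] = None,
) -> list[Calibrant]:
    """Calibrants lying on the power-law curve (A, B), optionally noisy.

    m/z values span the class range; the true CCS follows the class
    trendline (scaled to the total ion mass for multiply charged
    peptides); arrival times are back-solved exactly through the target
    curve; multiplicative Gaussian noise at ``noise_pct`` %CV is applied
    to the recorded reference CCS only, emulating reference-value error.
    """
    if n < 3:
        raise ValueError("need n >= 3 calibrants")
    cls = BiomolecularClass(biomolecular_class)
    rng = np.random.default_rng(seed)
    lo, hi = mz_range if mz_range is not None else DEFAULT_MZ_RANGES[cls]
    mzs = np.linspace(lo, hi, n)
    a, b = DEFAULT_TRENDLINE_COEFFS[cls]
    curve = CalibrationCurve(biomolecular_class=cls, z_group=z, A=A, B=B)
    out = []
    for i, mz in enumerate(mzs):
        # reference CCS from the class trendline, evaluated at total ion mass
        # so multiply charged peptides get realistic (larger) cross sections
        ccs_true = a * (mz * z) ** b
        t_a = invert_calibration(ccs_true, float(mz), z, curve, config)
        ccs_ref = ccs_true * (1.0 + noise_pct / 100.0 * rng.standard_normal())
        if ccs_ref <= 0:
            raise GenerationError("noise drove a reference CCS non-positive")
        out.append(
            Calibrant(
                name=f"{curve_key(cls, z)}_cal_{i:02d}",
                mz=float(mz), z=z, ccs_ref=float(ccs_ref),
                biomolecular_class=cls, arrival_time=t_a,
            )
        )
    return out


def generate_synthetic_features(
    spec: SyntheticSpec,
    trendlines: dict[str, TrendlineModel],
    curves: dict[str, CalibrationCurve],
    config: InstrumentConfig,
) -> list[tuple[Feature, BiomolecularClass]]:
    """Singly charged features on class trendlines with controlled errors.

    Each feature's true CCS is its class trendline value times
    ``(1 + scatter)`` with scatter ~ N(0, trendline_scatter_pct); the
    calibration error shifts that CCS by a fixed signed percentage
    before the arrival time is back-solved through the class's own
    calibration curve.  Ground-truth labels are returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    out = []
    idx = 0
    for cls, n_cls in counts.items():
        key = cls.value
        if key not in curves or key not in trendlines:
            raise ValueError(f"curves/trendlines missing class {key}")
        lo, hi = spec.mz_ranges[cls]
        mzs = rng.uniform(lo, hi, size=n_cls)
        scatter = rng.standard_normal(n_cls) * spec.trendline_scatter_pct / 100.0
        base = predict_trendline_ccs(trendlines[key], mzs, warn_extrapolation=False)
        true_ccs = base * (1.0 + scatter)
        observed = true_ccs * (1.0 + spec.calibration_error_pct / 100.0)
        for mz, ccs in zip(mzs, observed):
            if ccs <= 0:
                raise GenerationError("perturbation drove a CCS non-positive")
            t_a = invert_calibration(float(ccs), float(mz), 1, curves[key], config)
            out.append(
                (
                    Feature(feature_id=f"synth_{idx:05d}", mz=float(mz), z=1, arrival_time=t_a),
                    cls,
                )
            )
            idx += 1
    return out


def _class_counts(spec: SyntheticSpec) -> dict[BiomolecularClass, int]:
    classes = list(spec.class_proportions)
    counts = {c: int(round(spec.class_proportions[c] * spec.n_features)) for c in classes}
    # rounding drift absorbed by the first class
    counts[classes[0]] += spec.n_features - sum(counts.values())
    return counts


def perturbation_experiment(
    perturbations_pct: Sequence[float],
    base_spec: SyntheticSpec,
    trendlines: dict[str, TrendlineModel],
    curves: dict[str, CalibrationCurve],
    config: InstrumentConfig,
) -> RobustnessTable:
    """Classification accuracy vs signed calibration error.

    The same base feature set (identical m/z and scatter draws, via the
    spec's seed) is perturbed at each level -- a paired design, so
    accuracy differences across columns reflect the perturbation alone.
    """
    perturbations = list(perturbations_pct)
    if not perturbations:
        raise ValueError("perturbation list must be non-empty")
    classes = list(base_spec.class_proportions)
    acc = np.zeros((len(classes), len(perturbations)))
    for j, p in enumerate(perturbations):
        spec_p = replace(base_spec, calibration_error_pct=float(p))
        labelled = generate_synthetic_features(spec_p, trendlines, curves, config)
        correct = {c: 0 for c in classes}
        total = {c: 0 for c in classes}
        for feature, true_class in labelled:
            total[true_class] += 1
            assignment = assign_feature(feature, curves, trendlines, config)
            if assignment.assigned_class == true_class.value:
                correct[true_class] += 1
        for i, c in enumerate(classes):
            acc[i, j] = 100.0 * correct[c] / total[c] if total[c] else np.nan
    return RobustnessTable(classes=classes, perturbations_pct=perturbations, accuracy=acc)


# ---------------------------------------------------------------------------
# Synthetic raw mobility data (mzML)
# ---------------------------------------------------------------------------

_MZML_SPECTRUM = """\
  <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    <scanList count="1">
      <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
      <scan>
        <cvParam cvRef="MS" accession="MS:1002476" name="ion mobility drift time" value="{drift_time}" unitCvRef="UO" unitAccession="UO:0000028" unitName="millisecond"/>
      </scan>
    </scanList>
    <binaryDataArrayList count="2">
      <binaryDataArray encodedLength="{mz_len}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
        <binary>{mz_b64}</binary>
      </binaryDataArray>
      <binaryDataArray encodedLength="{int_len}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
        <binary>{int_b64}</binary>
      </binaryDataArray>
    </binaryDataArrayList>
  </spectrum>
"""

_MZML_DOC = """\
<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://unit-ontology.googlecode.com/svn/trunk/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="synthetic_mobility_run">
    <spectrumList count="{count}">
{spectra}    </spectrumList>
  </run>
</mzML>
"""


def _b64(values) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


@dataclass(frozen=True)
class SyntheticMobilitySpecies:
    """One species placed into a synthetic mobility run (synthetic stand-in
    for a real instrument acquisition)."""

    mz: float
    arrival_time: float  # ms, Gaussian ATD center
    atd_sigma: float = 0.3  # ms
    intensity: float = 1000.0


def write_synthetic_mzml(
    path,
    species: Sequence[SyntheticMobilitySpecies],
    drift_time_grid=None,
    noise_level: float = 0.0,
    seed: int = 0,
) -> Path:
    """Write a small synthetic mobility-resolved mzML run.

    One spectrum per drift-time bin; each species contributes a Gaussian
    ATD at its m/z.  Optional additive uniform noise (fraction of the
    species intensity) exercises fitting robustness.  The file is plain
    uncompressed XML for testability.
    """
    if drift_time_grid is None:
        drift_time_grid = np.arange(1.0, 14.0, 0.05)
    drift_time_grid = np.asarray(drift_time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    blocks = []
    for i, dt in enumerate(drift_time_grid):
        mzs, intensities = [], []
        for sp in species:
            value = sp.intensity * np.exp(-0.5 * ((dt - sp.arrival_time) / sp.atd_sigma) ** 2)
            if noise_level > 0:
                value += noise_level * sp.intensity * rng.random()
            if value > 1e-6:
                mzs.append(sp.mz)
                intensities.append(value)
        mz_b64, int_b64 = _b64(mzs), _b64(intensities)
        blocks.append(
            _MZML_SPECTRUM.format(
                index=i, scan=i + 1, n=len(mzs), drift_time=f"{dt:.6f}",
                mz_len=len(mz_b64), int_len=len(int_b64),
                mz_b64=mz_b64, int_b64=int_b64,
            )
        )
    path = Path(path)
    path.write_text(_MZML_DOC.format(count=len(blocks), spectra="".join(blocks)))
    return path
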