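"""Per-class CCS-vs-m/z trendlines.

Each biomolecular class occupies its own band of ion-mobility
conformational space: at a given m/z, peptides are the most compact
(lowest CCS), lipids the most extended, with small molecules below both
at low mass.  A regression of reference drift-tube CCS on m/z per class
("trendline") captures that band and serves as the yardstick for judging
which class-specific calibration produced the most plausible CCS for an
unknown feature.

The default functional form is a power law, CCS = a * (m/z)**b, the
canonical scaling of biomolecular cross sections with mass; linear and
quadratic forms are selectable so externally fitted coefficients can be
loaded verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .config_io import BiomolecularClass


class ExtrapolationWarning(UserWarning):
    """A trendline was evaluated outside the m/z range of its references."""


_FORMS = ("power", "linear", "quadratic")


@dataclass
class TrendlineModel:
    """Fitted CCS-vs-m/z regression for one class."""

    biomolecular_class: BiomolecularClass
    form: str
    coefficients: tuple
    mz_domain: tuple
    n_refs: int

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"form must be one of {_FORMS}")
        self.coefficients = tuple(float(c) for c in self.coefficients)
        self.mz_domain = (float(self.mz_domain[0]), float(self.mz_domain[1]))

    def in_domain(self, mz: float) -> bool:
        return self.mz_domain[0] <= mz <= self.mz_domain[1]

    def to_dict(self) -> dict:
        return {
            "class": self.biomolecular_class.value,
            "form": self.form,
            "coefficients": list(self.coefficients),
            "mz_domain": list(self.mz_domain),
            "n_refs": self.n_refs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrendlineModel":
        return cls(
            biomolecular_class=BiomolecularClass(d["class"]),
            form=d["form"],
            coefficients=tuple(d["coefficients"]),
            mz_domain=tuple(d["mz_domain"]),
            n_refs=int(d.get("n_refs", 0)),
        )


def fit_trendline(
    refs: Sequence[tuple[float, float]],
    biomolecular_class: BiomolecularClass,
    form: str = "power",
) -> TrendlineModel:
    """Least-squares fit of reference (m/z, CCS) pairs with the chosen form."""
    if form not in _FORMS:
        raise ValueError(f"form must be one of {_FORMS}")
    refs = list(refs)
    if len(refs) < 5:
        raise ValueError(f"trendline fit needs >= 5 reference pairs, got {len(refs)}")
    mz = np.array([r[0] for r in refs], dtype=float)
    ccs = np.array([r[1] for r in refs], dtype=float)
    if np.any(mz <= 0) or np.any(ccs <= 0):
        raise ValueError("reference m/z and CCS values must be positive")
    if form == "power":
        lr = stats.linregress(np.log(mz), np.log(ccs))
        p0 = (float(np.exp(lr.intercept)), float(lr.slope))
        popt, _ = optimize.curve_fit(lambda x, a, b: a * x ** b, mz, ccs, p0=p0, maxfev=10000)
        coeffs = (float(popt[0]), float(popt[1]))
    elif form == "linear":
        coeffs = tuple(float(c) for c in np.polyfit(mz, ccs, 1)[::-1])
    else:  # quadratic
        coeffs = tuple(float(c) for c in np.polyfit(mz, ccs, 2)[::-1])
    model = TrendlineModel(
        biomolecular_class=BiomolecularClass(biomolecular_class),
        form=form,
        coefficients=coeffs,
        mz_domain=(float(mz.min()), float(mz.max())),
        n_refs=len(refs),
    )
    # predictions must stay positive over the supported range
    grid = np.linspace(*model.mz_domain, 50)
    if np.any(_evaluate(model, grid) <= 0):
        raise ValueError("fitted trendline predicts non-positive CCS inside its domain")
    return model


def _evaluate(model: TrendlineModel, mz):
    mz = np.asarray(mz, dtype=float)
    c = model.coefficients
    if model.form == "power":
        out = c[0] * mz ** c[1]
    elif model.form == "linear":
        out = c[0] + c[1] * mz
    else:
        out = c[0] + c[1] * mz + c[2] * mz ** 2
    return out


def predict_trendline_ccs(model: TrendlineModel, mz, *, warn_extrapolation: bool = True):
    """Evaluate the trendline at ``mz`` (A^2).

    Extrapolation beyond the reference m/z range is permitted but flagged
    with an :class:`ExtrapolationWarning`.
    """
    arr = np.asarray(mz, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("mz must be > 0")
    if warn_extrapolation and np.any((arr < model.mz_domain[0]) | (arr > model.mz_domain[1])):
        warnings.warn(
            f"{model.biomolecular_class.value} trendline evaluated outside its "
            f"reference m/z range {model.mz_domain}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = _evaluate(model, arr)
    return out if out.ndim else float(out)


def delta_ccs(calibrated: float, predicted: float) -> float:
    """Absolute distance |calibrated - predicted| in A^2."""
    if calibrated <= 0 or predicted <= 0:
        raise ValueError("CCS values must be positive")
    return abs(calibrated - predicted)


def signed_delta_ccs(calibrated: float, predicted: float) -> float:
    """Signed distance calibrated - predicted (positive = above the trendline)."""
    return calibrated - predicted


def save_trendlines(models: dict[str, TrendlineModel], path) -> None:
    from .config_io import save_json

    save_json({k: m.to_dict() for k, m in models.items()}, path)


def load_trendlines(path) -> dict[str, TrendlineModel]:
    from .config_io import load_json

    return {k: TrendlineModel.from_dict(v) for k, v in load_json(path).items()}
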