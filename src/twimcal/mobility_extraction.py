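"""Arrival-time extraction from raw mobility data.

A calibrant's arrival time is obtained by summing intensity inside an
m/z window across all mobility-resolved spectra of an mzML run, which
yields an arrival-time distribution (ATD), and fitting a single
Gaussian to the most intense peak of that distribution; the fitted mean
(apex) is the arrival time.

The mzML reader here is intentionally minimal: it streams ``<spectrum>``
elements with lxml, decodes the m/z and intensity binary arrays (32- or
64-bit floats, zlib or uncompressed) and reads the per-spectrum
ion-mobility drift time cvParam (MS:1002476, ms).  Files without a
mobility dimension are rejected.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree
from scipy import optimize

from .errors import NoSignalError, UnsupportedDataError

_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions understood by the binary-array decoder
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_DRIFT_TIME = "MS:1002476"


@dataclass
class ArrivalTimeDistribution:
    """Summed intensity vs arrival time for one m/z window."""

    arrival_times: np.ndarray  # ms, strictly increasing
    intensities: np.ndarray  # counts, >= 0

    def __post_init__(self):
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.arrival_times.shape != self.intensities.shape:
            raise ValueError("arrival_times and intensities must have equal length")
        if np.any(np.diff(self.arrival_times) <= 0):
            raise ValueError("arrival_times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class GaussianFit:
    """Result of fitting one Gaussian to an ATD."""

    apex: float  # ms
    amplitude: float
    sigma: float  # ms
    fit_rss: float
    fallback_to_argmax: bool = False

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def _decode_binary_array(elem) -> tuple[np.ndarray, str]:
    """Decode one <binaryDataArray>; returns (values, array-type accession)."""
    dtype = "<f8"
    decompress = False
    kind = ""
    for cv in elem.iter(_NS + "cvParam"):
        acc = cv.get("accession", "")
        if acc == _ACC_FLOAT32:
            dtype = "<f4"
        elif acc == _ACC_FLOAT64:
            dtype = "<f8"
        elif acc == _ACC_ZLIB:
            decompress = True
        elif acc in (_ACC_MZ_ARRAY, _ACC_INTENSITY_ARRAY):
            kind = acc
    binary = elem.find(_NS + "binary")
    raw = base64.b64decode(binary.text or "")
    if decompress:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float), kind


def iter_mobility_spectra(path):
    """Yield ``(drift_time_ms, mz_array, intensity_array)`` per spectrum.

    Raises :class:`UnsupportedDataError` if any spectrum lacks the
    ion-mobility drift-time cvParam.
    """
    path = Path(path)
    context = etree.iterparse(str(path), events=("end",), tag=_NS + "spectrum")
    any_spectrum = False
    for _, spectrum in context:
        any_spectrum = True
        drift_time = None
        for cv in spectrum.iter(_NS + "cvParam"):
            if cv.get("accession") == _ACC_DRIFT_TIME:
                drift_time = float(cv.get("value"))
                break
        if drift_time is None:
            raise UnsupportedDataError(
                f"{path.name}: spectrum {spectrum.get('id')!r} has no ion-mobility "
                "drift time (MS:1002476); file lacks a mobility dimension"
            )
        mz = intensity = None
        for arr in spectrum.iter(_NS + "binaryDataArray"):
            values, kind = _decode_binary_array(arr)
            if kind == _ACC_MZ_ARRAY:
                mz = values
            elif kind == _ACC_INTENSITY_ARRAY:
                intensity = values
        if mz is None or intensity is None:
            raise UnsupportedDataError(
                f"{path.name}: spectrum {spectrum.get('id')!r} lacks m/z or intensity arrays"
            )
        yield drift_time, mz, intensity
        spectrum.clear()
    if not any_spectrum:
        raise UnsupportedDataError(f"{path.name}: no spectra found")


def extract_atd(raw_run, target_mz: float, mz_tolerance: float = 0.05) -> ArrivalTimeDistribution:
    """Extract the ATD of an m/z window from an mzML run.

    Intensities are summed over ``[target_mz - mz_tolerance,
    target_mz + mz_tolerance]`` in every spectrum and binned by the
    spectrum's drift time (spectra sharing a drift time are summed).  An
    empty window yields an all-zero ATD on the run's drift-time grid.
    """
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be > 0")
    lo, hi = target_mz - mz_tolerance, target_mz + mz_tolerance
    bins: dict[float, float] = {}
    for drift_time, mz, intensity in iter_mobility_spectra(raw_run):
        mask = (mz >= lo) & (mz <= hi)
        bins[drift_time] = bins.get(drift_time, 0.0) + float(intensity[mask].sum())
    times = np.array(sorted(bins), dtype=float)
    values = np.array([bins[t] for t in times], dtype=float)
    return ArrivalTimeDistribution(times, values)


def _gauss(t, amplitude, mean, sigma):
    return amplitude * np.exp(-0.5 * ((t - mean) / sigma) ** 2)


def _main_peak_slice(intensities: np.ndarray) -> slice:
    """Bounds of the connected nonzero run containing the global maximum."""
    peak = int(np.argmax(intensities))
    left = peak
    while left > 0 and intensities[left - 1] > 0:
        left -= 1
    right = peak
    n = len(intensities)
    while right < n - 1 and intensities[right + 1] > 0:
        right += 1
    return slice(left, right + 1)


def fit_gaussian_apex(atd: ArrivalTimeDistribution) -> GaussianFit:
    """Least-squares Gaussian fit of an ATD; the fitted mean is the apex.

    Only the most intense connected peak is fitted when the window holds
    several mobility peaks.  If the optimizer fails, the apex falls back
    to the grid point of maximum intensity (flagged on the result).
    """
    if not np.any(atd.intensities > 0):
        raise NoSignalError("arrival-time distribution is all zero")
    sel = _main_peak_slice(atd.intensities)
    t = atd.arrival_times[sel]
    y = atd.intensities[sel]
    if np.count_nonzero(y) < 5:
        raise NoSignalError(
            f"main ATD peak has only {np.count_nonzero(y)} nonzero points; >= 5 required"
        )
    # seed: amplitude = max, mean = argmax bin, sigma from FWHM
    peak = int(np.argmax(y))
    amp0 = float(y[peak])
    mean0 = float(t[peak])
    above = t[y >= amp0 / 2.0]
    fwhm = float(above.max() - above.min()) if len(above) > 1 else float(t[1] - t[0])
    sigma0 = max(fwhm / 2.355, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, t, y, p0=(amp0, mean0, sigma0), maxfev=5000
        )
        amplitude, mean, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        if not (atd.arrival_times[0] <= mean <= atd.arrival_times[-1]):
            raise RuntimeError("fitted apex outside the time grid")
        rss = float(np.sum((y - _gauss(t, *popt)) ** 2))
        return GaussianFit(apex=mean, amplitude=amplitude, sigma=sigma, fit_rss=rss)
    except RuntimeError:
        return GaussianFit(
            apex=mean0, amplitude=amp0, sigma=sigma0,
            fit_rss=float(np.sum((y - _gauss(t, amp0, mean0, sigma0)) ** 2)),
            fallback_to_argmax=True,
        )


def extract_arrival_time(
    raw_run, target_mz: float, mz_tolerance: float = 0.05
) -> GaussianFit:
    """Convenience: window extraction followed by Gaussian apex fitting."""
    return fit_gaussian_apex(extract_atd(raw_run, target_mz, mz_tolerance))
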