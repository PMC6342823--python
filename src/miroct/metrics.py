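"""Characterization operators: axial resolution, sensitivity roll-off,
spectral-resolution inversion, sampling resolutions, thickness from OPD.

All depth quantities are one-way OPD in air (µm); spectral quantities are on
the mid-IR wavelength scale (nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .reconstruction import AScan

__all__ = [
    "MetricsError",
    "RollOffCurve",
    "ThicknessResult",
    "axial_resolution",
    "peak_fwhm",
    "rolloff_curve",
    "spectral_resolution_from_rolloff",
    "thickness_from_opd",
    "sampling_resolutions",
]


class MetricsError(RuntimeError):
    """Raised when a measurement cannot be made reliably (no peak, bad fit)."""


@dataclass(frozen=True)
class RollOffCurve:
    """Peak sensitivity (dB, relative to the shallowest probe) versus OPD."""

    opd_um: np.ndarray
    sensitivity_db: np.ndarray
    z6db_um: float
    lower_bound: bool = False  # True when the 6 dB point was not bracketed


@dataclass(frozen=True)
class ThicknessResult:
    """Physical thickness from an OPD measurement: ``d = OPD / n`` with
    uncertainty twice the digital sampling resolution divided by ``n``."""

    thickness_um: float
    uncertainty_um: float
    inputs: dict = field(default_factory=dict)


def _find_peak(ascan: AScan, hint_um: float | None, window_um: float = 150.0):
    mag = ascan.magnitude
    depth = ascan.depth_um
    if hint_um is None:
        sel = slice(1, len(mag))  # skip the DC bin
    else:
        idx = np.flatnonzero(np.abs(depth - hint_um) <= window_um)
        if idx.size == 0:
            raise MetricsError("peak hint outside the depth axis")
        sel = slice(int(idx[0]), int(idx[-1]) + 1)
    i = int(np.argmax(mag[sel])) + sel.start
    return i


def peak_fwhm(ascan: AScan, peak_opd_hint: float | None = None) -> float:
    """Model-free FWHM (µm) of a peak via interpolated half-max crossings."""
    i = _find_peak(ascan, peak_opd_hint)
    mag = ascan.magnitude
    half = mag[i] / 2.0
    lo = i
    while lo > 0 and mag[lo] > half:
        lo -= 1
    hi = i
    while hi < len(mag) - 1 and mag[hi] > half:
        hi += 1
    if mag[lo] > half or mag[hi] > half:
        raise MetricsError("peak does not fall to half maximum within the axis")
    d = ascan.depth_um
    z_lo = np.interp(half, [mag[lo], mag[lo + 1]], [d[lo], d[lo + 1]])
    z_hi = np.interp(half, [mag[hi], mag[hi - 1]], [d[hi], d[hi - 1]])
    return float(z_hi - z_lo)


def axial_resolution(ascan: AScan, peak_opd_hint: float | None = None, *,
                     min_prominence_db: float = 10.0,
                     max_residual: float = 0.15) -> float:
    """Axial resolution (µm FWHM) by least-squares Gaussian fit of a peak.

    The fit spans +/- 3 nominal widths around the peak (nominal width from
    the half-max crossings), restricted to samples above a quarter of the
    peak height so sidelobes of non-Gaussian responses do not bias the width.
    The peak must stand at least ``min_prominence_db`` above the local floor;
    multiple local maxima above half height inside the window, or a poor fit
    (relative RMS residual above ``max_residual``), raise ``MetricsError``
    rather than returning a silently wrong number.
    """
    i = _find_peak(ascan, peak_opd_hint)
    mag = ascan.magnitude
    depth = ascan.depth_um
    floor = np.median(mag)
    if 20.0 * np.log10(mag[i] / max(floor, np.finfo(float).tiny)) < min_prominence_db:
        raise MetricsError("no peak at least 10 dB above the local floor")
    w_est = peak_fwhm(ascan, peak_opd_hint)
    window = np.abs(depth - depth[i]) <= 3.0 * w_est
    # multiple distinct maxima above half height -> not a single peak
    wi = np.flatnonzero(window)
    wm = mag[wi]
    local_max = (wm[1:-1] > wm[:-2]) & (wm[1:-1] >= wm[2:]) & (
        wm[1:-1] > floor + 0.5 * (mag[i] - floor))
    if np.count_nonzero(local_max) > 1:
        raise MetricsError("multiple peaks inside the fit window")
    sel = window & (mag > floor + 0.25 * (mag[i] - floor))
    z = depth[sel]
    y = mag[sel]

    def gauss(zz, amp, z0, sigma):
        return amp * np.exp(-((zz - z0) ** 2) / (2.0 * sigma**2))

    sigma0 = w_est / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    p0 = [mag[i] - floor, depth[i], sigma0]
    try:
        popt, _ = curve_fit(gauss, z, y - floor, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - fit divergence
        raise MetricsError(f"Gaussian fit failed: {exc}") from exc
    resid = np.sqrt(np.mean((gauss(z, *popt) - (y - floor)) ** 2)) / popt[0]
    if resid > max_residual:
        raise MetricsError(
            f"Gaussian fit residual {resid:.2f} too large (asymmetric or "
            "multiple peaks?)")
    return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * abs(popt[2]))


def rolloff_curve(ascans, probe_opds_um=None) -> RollOffCurve:
    """Peak sensitivity versus OPD and the interpolated 6 dB depth.

    Sensitivity at each probe is ``20 log10`` of the peak magnitude relative
    to the shallowest probe.  The 6 dB depth is linearly interpolated in dB
    between the bracketing probes; if the curve never drops 6 dB the deepest
    probe is reported as a lower bound.
    """
    ascans = list(ascans)
    if len(ascans) < 5:
        raise ValueError("need at least 5 probe depths for a roll-off curve")
    if probe_opds_um is None:
        probe_opds_um = [None] * len(ascans)
    peaks = []
    opds = []
    for a, hint in zip(ascans, probe_opds_um):
        i = _find_peak(a, hint)
        peaks.append(a.magnitude[i])
        opds.append(a.depth_um[i] if hint is None else hint)
    order = np.argsort(opds)
    opds = np.asarray(opds, dtype=float)[order]
    peaks = np.asarray(peaks, dtype=float)[order]
    sens = 20.0 * np.log10(peaks / peaks[0])
    below = np.flatnonzero(sens <= -6.0)
    if below.size == 0:
        return RollOffCurve(opd_um=opds, sensitivity_db=sens,
                            z6db_um=float(opds[-1]), lower_bound=True)
    j = int(below[0])
    if j == 0:
        raise MetricsError("shallowest probe already beyond the 6 dB point")
    z6 = np.interp(-6.0, [sens[j - 1], sens[j]][::-1],
                   [opds[j - 1], opds[j]][::-1])
    return RollOffCurve(opd_um=opds, sensitivity_db=sens, z6db_um=float(z6))


def spectral_resolution_from_rolloff(z6db_um: float, lambda0_nm: float) -> float:
    """Invert the Gaussian roll-off model: ``dlambda = ln2 lambda0^2/(pi z6)``.

    ``z6db_um`` is the one-way OPD of the 6 dB sensitivity drop; the result is
    the spectral resolution FWHM in nm on the same wavelength scale as
    ``lambda0_nm``.
    """
    if z6db_um <= 0 or lambda0_nm <= 0:
        raise ValueError("inputs must be positive")
    return float(np.log(2.0) * lambda0_nm**2 / (np.pi * z6db_um * 1e3))


def thickness_from_opd(opd_thickness_um: float, n: float,
                       sampling_um: float) -> ThicknessResult:
    """Physical layer thickness from its OPD extent and refractive index."""
    if opd_thickness_um <= 0 or n <= 0 or sampling_um <= 0:
        raise ValueError("inputs must be positive")
    return ThicknessResult(
        thickness_um=opd_thickness_um / n,
        uncertainty_um=2.0 * sampling_um / n,
        inputs={"opd_um": opd_thickness_um, "n": n, "sampling_um": sampling_um})


def sampling_resolutions(band_nm, n_detected_pixels: int,
                         speed_mm_s: float, integration_ms: float):
    """(average spectral sampling nm/pixel, lateral sampling µm/line)."""
    lo, hi = band_nm
    if hi < lo or n_detected_pixels <= 0 or speed_mm_s < 0 or integration_ms < 0:
        raise ValueError("invalid inputs")
    spectral = (hi - lo) / n_detected_pixels
    lateral = speed_mm_s * integration_ms  # mm/s * ms = µm
    return float(spectral), float(lateral)
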