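"""Raw frames to A-scans: the spectral-domain OCT processing chain.

Order of operations (fixed): dark subtraction and reference normalization,
two-interferogram pixel-to-wavenumber calibration, resampling to a uniform
wavenumber grid, numerical dispersion compensation, Hanning apodization over
the occupied spectral support, zero-padded FFT, magnitude.

The calibration follows the standard two-reference-interferogram scheme: the
analytic-signal phase of two noiseless mirror fringes at known OPDs z_a, z_b
gives ``k(p) = (phi_a(p) - phi_b(p)) / (2 (z_a - z_b))`` up to a constant that
is anchored to the spectrometer's nominal band edge, and the residual
``phi_a(p) - 2 k(p) z_a`` is the interferometer dispersion mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .forward_model import RawFrame

__all__ = [
    "CalibrationError",
    "Fringe",
    "CalibrationMap",
    "AScan",
    "BScan",
    "VolumeScan",
    "preprocess",
    "build_calibration",
    "reconstruct_ascan",
    "assemble_scan",
    "assemble_volume",
]


class CalibrationError(RuntimeError):
    """Raised when calibration input is degenerate or phase unwrap fails."""


@dataclass(frozen=True)
class Fringe:
    """Zero-mean normalized fringe signal per pixel, with a validity mask."""

    values: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CalibrationMap:
    """Pixel-to-wavenumber map plus dispersion compensation phase.

    ``k_of_pixel`` holds the recovered mid-IR wavenumber per pixel (NaN
    outside the usable support); ``k_uniform`` is the ascending uniform
    wavenumber grid used for resampling, ``resample_positions`` the matching
    fractional pixel indices, and ``dispersion_phase`` the mean-removed
    interferometer mismatch phase per uniform-k sample.
    """

    k_of_pixel: np.ndarray
    support: tuple[int, int]
    k_uniform: np.ndarray
    resample_positions: np.ndarray
    dispersion_phase: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dk(self) -> float:
        return float(self.k_uniform[1] - self.k_uniform[0])

    @property
    def k_span(self) -> float:
        return float(self.k_uniform[-1] - self.k_uniform[0])


@dataclass(frozen=True)
class AScan:
    """Depth-resolved reflectivity magnitude versus one-way OPD in air."""

    depth_um: np.ndarray
    magnitude: np.ndarray
    db: np.ndarray
    zero_pad_factor: int
    complex_profile: np.ndarray | None = None

    @property
    def depth_bin_um(self) -> float:
        return float(self.depth_um[1] - self.depth_um[0])


@dataclass(frozen=True)
class BScan:
    """Adjacent A-scans with lateral stage metadata (image axes depth x lateral)."""

    image: np.ndarray
    db: np.ndarray
    depth_um: np.ndarray
    lateral_um: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VolumeScan:
    bscans: tuple[BScan, ...]
    step_um: float


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess(sample: RawFrame, dark: RawFrame, reference: RawFrame, *,
               eps_counts: float = 1.0) -> Fringe:
    """Dark-subtract and reference-normalize a raw frame.

    Returns ``(sample - dark)/(reference - dark) - 1``, the zero-mean fringe
    term.  Pixels where the reference signal is at or below ``eps_counts``
    above dark, and saturated pixels in either frame, are masked (value 0,
    ``valid`` False) so later fits can exclude them.
    """
    if not (len(sample.counts) == len(dark.counts) == len(reference.counts)):
        raise ValueError("frames must have identical pixel counts")
    if not (sample.bit_depth == dark.bit_depth == reference.bit_depth):
        raise ValueError("frames must share bit depth")
    s = sample.counts.astype(float)
    d = dark.counts.astype(float)
    r = reference.counts.astype(float)
    denom = r - d
    valid = denom > eps_counts
    if not np.any(valid):
        raise CalibrationError("reference frame carries no signal above dark")
    valid &= ~sample.saturated & ~reference.saturated
    values = np.zeros_like(s)
    values[valid] = (s[valid] - d[valid]) / denom[valid] - 1.0
    return Fringe(values=values, valid=valid)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def _as_values(fringe) -> np.ndarray:
    if isinstance(fringe, Fringe):
        out = fringe.values.copy()
        out[~fringe.valid] = 0.0
        return out
    return np.asarray(fringe, dtype=float)


def _as_valid(fringe, n: int) -> np.ndarray:
    if isinstance(fringe, Fringe):
        return fringe.valid
    return np.ones(n, dtype=bool)


def _analytic_carrier(values: np.ndarray) -> np.ndarray:
    """One-sided band-pass around the fringe carrier -> analytic signal.

    Keeping only positive frequencies in a band around the dominant fringe
    frequency rejects both the DC/autocorrelation terms and the negative-
    frequency copy, so the phase of the result is the (signed) fringe phase.
    """
    n = len(values)
    spectrum = np.fft.fft(values)
    half = n // 2
    mag = np.abs(spectrum[:half])
    lo_guard = max(3, n // 512)  # skip DC and the slow envelope terms
    carrier = int(np.argmax(mag[lo_guard:half])) + lo_guard
    lo = max(2, int(0.45 * carrier))
    hi = min(half, int(1.8 * carrier) + 1)
    kept = np.zeros_like(spectrum)
    kept[lo:hi] = 2.0 * spectrum[lo:hi]
    return np.fft.ifft(kept)


def _support(envelope: np.ndarray, valid: np.ndarray, threshold: float,
             trim: float = 0.03):
    """Longest contiguous index range where the fringe envelope is occupied."""
    masked = np.where(valid, envelope, 0.0)
    above = masked > threshold * masked.max()
    if not np.any(above):
        raise CalibrationError("no fringe support above the threshold")
    # longest contiguous run
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    lengths = [e - s for s, e in zip(starts, ends)]
    best = int(np.argmax(lengths))
    p0, p1 = starts[best], ends[best]
    if p1 - p0 < 16:
        raise CalibrationError("fringe support too small for calibration")
    pad = max(4, int(trim * (p1 - p0)))
    return p0 + pad, p1 - pad


def _unwrapped_phase(analytic: np.ndarray, p0: int, p1: int) -> np.ndarray:
    wrapped = np.angle(analytic[p0:p1])
    # detect tears on the wrapped adjacent differences, where a jump beyond
    # pi from the local trend makes the unwrap branch ambiguous
    dphi = np.angle(np.exp(1j * np.diff(wrapped)))
    resid = dphi - np.median(dphi)
    bad = np.flatnonzero(np.abs(resid) > np.pi)
    if bad.size:
        raise CalibrationError(
            f"phase unwrap failure at pixel {p0 + int(bad[0])}: fringe phase "
            "tear (fringes must stay resolvable across the support)")
    return np.unwrap(wrapped)


def build_calibration(frame_a, frame_b, opd_a_um: float, opd_b_um: float,
                      spec, *, support_threshold: float = 0.05,
                      n_out: int | None = None,
                      dispersion_fit_order: int | None = 8) -> CalibrationMap:
    """Recover the pixel-to-wavenumber map from two mirror interferograms.

    Parameters
    ----------
    frame_a, frame_b : Fringe or array
        Preprocessed fringe signals of a single mirror at the two OPDs.
    opd_a_um, opd_b_um : float
        The (distinct) one-way OPDs of the two interferograms.
    spec : SpectrometerModel
        Supplies the nominal pixel map used to anchor the constant wavenumber
        offset; the two-frame phase difference determines ``k(p)`` only up to
        a multiple of ``pi / |z_a - z_b|``.
    dispersion_fit_order : int or None
        The raw mismatch phase carries quantization ripple from the finite
        bit depth; since physical dispersion is smooth in k it is stored as a
        polynomial fit of this order (None keeps the raw samples).
    """
    if opd_a_um == opd_b_um:
        raise CalibrationError("degenerate calibration: OPDs must differ")
    a = _as_values(frame_a)
    b = _as_values(frame_b)
    if a.shape != b.shape:
        raise ValueError("calibration frames must have equal length")

    analytic_a = _analytic_carrier(a)
    analytic_b = _analytic_carrier(b)
    env = np.minimum(np.abs(analytic_a), np.abs(analytic_b))
    valid = _as_valid(frame_a, len(a)) & _as_valid(frame_b, len(b))
    p0, p1 = _support(env, valid, support_threshold)
    phi_a = _unwrapped_phase(analytic_a, p0, p1)
    phi_b = _unwrapped_phase(analytic_b, p0, p1)

    dz = opd_a_um - opd_b_um
    k_raw = (phi_a - phi_b) / (2.0 * dz)
    # orient k(p) like the nominal map (the analytic-signal phase always
    # increases with pixel, so the raw difference may come out mirrored)
    k_nom = spec.pixel_k_midir()[p0:p1]
    sign = 1.0 if (k_raw[-1] - k_raw[0]) * (k_nom[-1] - k_nom[0]) > 0 else -1.0
    k_raw = sign * k_raw
    # anchor the constant offset (quantized in pi/|dz|) to the nominal map
    quantum = np.pi / abs(dz)
    m = np.round(np.median(k_nom - k_raw) / quantum)
    k = k_raw + m * quantum
    dkdp = np.diff(k)
    if not (np.all(dkdp > 0) or np.all(dkdp < 0)):
        raise CalibrationError("recovered k(p) is not monotone")

    psi = sign * phi_a - 2.0 * k * opd_a_um  # interferometer mismatch phase

    n_pixels = len(a)
    k_of_pixel = np.full(n_pixels, np.nan)
    k_of_pixel[p0:p1] = k
    if n_out is None:
        n_out = n_pixels // 2
    k_uniform = np.linspace(k.min(), k.max(), n_out)
    pix = np.arange(p0, p1, dtype=float)
    order = np.argsort(k)
    resample_positions = np.interp(k_uniform, k[order], pix[order])
    if dispersion_fit_order is not None:
        fit = np.polynomial.Polynomial.fit(k, psi, int(dispersion_fit_order))
        disp = fit(k_uniform)
    else:
        disp = np.interp(k_uniform, k[order], psi[order])
    disp = disp - disp.mean()
    return CalibrationMap(
        k_of_pixel=k_of_pixel, support=(p0, p1), k_uniform=k_uniform,
        resample_positions=resample_positions, dispersion_phase=disp,
        meta={"opd_pair_um": (opd_a_um, opd_b_um)})


# --------------------------------------------------------------------------
# A-scan reconstruction
# --------------------------------------------------------------------------

def reconstruct_ascan(fringe, cal: CalibrationMap, *, window: str = "hanning",
                      zero_pad_factor: int = 4,
                      interpolator: str = "cubic",
                      keep_complex: bool = False,
                      compensate_dispersion: bool = True) -> AScan:
    """Resample, dispersion-compensate, window, zero-pad, Fourier transform.

    The depth axis is one-way OPD in air with bin width
    ``pi / (K * zero_pad_factor)`` where ``K`` is the uniform wavenumber span.
    ``window`` is applied across the resampled (occupied) spectral support.
    """
    if window not in ("hanning", "none"):
        raise ValueError(f"unknown window {window!r}")
    if zero_pad_factor < 1 or int(zero_pad_factor) != zero_pad_factor:
        raise ValueError("zero_pad_factor must be a positive integer")
    values = _as_values(fringe)
    x = np.arange(len(values), dtype=float)
    if interpolator == "cubic":
        resampled = CubicSpline(x, values)(cal.resample_positions)
    elif interpolator == "linear":
        resampled = np.interp(cal.resample_positions, x, values)
    else:
        raise ValueError(f"unknown interpolator {interpolator!r}")

    sig = resampled.astype(complex)
    if compensate_dispersion:
        sig = sig * np.exp(-1j * cal.dispersion_phase)
    n = len(sig)
    if window == "hanning":
        sig = sig * np.hanning(n)
    n_pad = n * int(zero_pad_factor)
    spectrum = np.fft.fft(sig, n_pad)
    half = n_pad // 2
    magnitude = np.abs(spectrum[:half])
    depth = np.pi * np.arange(half) / (cal.dk * n_pad)
    floor = np.median(magnitude)
    floor = floor if floor > 0 else np.finfo(float).tiny
    db = 20.0 * np.log10(np.maximum(magnitude, np.finfo(float).tiny) / floor)
    return AScan(depth_um=depth, magnitude=magnitude, db=db,
                 zero_pad_factor=int(zero_pad_factor),
                 complex_profile=spectrum if keep_complex else None)


# --------------------------------------------------------------------------
# scan assembly
# --------------------------------------------------------------------------

def assemble_scan(ascans, mode: str, *, speed_mm_s: float | None = None,
                  integration_ms: float | None = None,
                  step_um: float | None = None, meta: dict | None = None) -> BScan:
    """Assemble A-scans into a B-scan with lateral stage metadata.

    ``continuous_x`` derives the lateral spacing from stage speed x line
    integration time (3 mm/s x 3 ms -> 9 µm) and records the total
    acquisition time; ``stepped_y`` uses the stage step size directly.
    """
    ascans = list(ascans)
    if len(ascans) < 2:
        raise ValueError("a B-scan needs at least 2 A-scans")
    depth = ascans[0].depth_um
    for a in ascans[1:]:
        if len(a.depth_um) != len(depth) or not np.allclose(a.depth_um, depth):
            raise ValueError("A-scans have inconsistent depth axes")
    if mode == "continuous_x":
        if speed_mm_s is None or integration_ms is None:
            raise ValueError("continuous_x needs speed_mm_s and integration_ms")
        spacing = speed_mm_s * integration_ms  # mm/s * ms = µm
        total_time_s = len(ascans) * integration_ms * 1e-3
    elif mode == "stepped_y":
        if step_um is None:
            raise ValueError("stepped_y needs step_um")
        spacing = step_um
        total_time_s = None
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    if spacing <= 0:
        raise ValueError("lateral spacing must be positive")
    image = np.stack([a.magnitude for a in ascans], axis=1)
    db = np.stack([a.db for a in ascans], axis=1)
    lateral = np.arange(len(ascans)) * spacing
    info = {"mode": mode, "lateral_spacing_um": float(spacing),
            "speed_mm_s": speed_mm_s, "integration_ms": integration_ms,
            "step_um": step_um, "total_time_s": total_time_s}
    if meta:
        info.update(meta)
    return BScan(image=image, db=db, depth_um=depth, lateral_um=lateral,
                 meta=info)


def assemble_volume(bscans, step_um: float) -> VolumeScan:
    bscans = tuple(bscans)
    if len(bscans) < 2:
        raise ValueError("a volume needs at least 2 B-scans")
    if step_um <= 0:
        raise ValueError("step must be positive")
    return VolumeScan(bscans=bscans, step_um=float(step_um))
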