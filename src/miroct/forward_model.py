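"""Raw spectral-domain OCT frame synthesis.

The forward model produces the per-pixel count arrays a line-scan spectrometer
would record for a given stack of reflecting interfaces: the spectral fringe
pattern ``S(k)[rho_ref + sum r_j^2 + sum 2*sqrt(rho_ref)*r_j*cos(2 k z_j +
phi_j(k))]`` smoothed by the finite spectral resolution (which produces the
sensitivity roll-off with depth), sampled through a nonlinear pixel-to-
wavenumber map, scaled by integration time, optionally shot/dark noised, and
quantized to the detector bit depth.

Conventions
-----------
* ``z`` is the ONE-WAY optical path difference (OPD) in air, µm; the fringe
  phase is ``2 k z``.
* Wavenumbers ``k = 2*pi/lambda`` are on the mid-IR scale in rad/µm.  The
  spectrometer physically samples the upconverted near-IR spectrum; its pixel
  grid maps back to mid-IR wavenumber through the sum-frequency relation,
  which is the dominant (and intentional) pixel-map nonlinearity.
* The spectral-resolution kernel is Gaussian with FWHM given in nm on the
  mid-IR scale; the resulting amplitude roll-off is
  ``A(z) = exp(-z^2 dk^2 / (4 ln 2))`` with ``dk = 2 pi dlambda / lambda0^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import C_UM_PER_FS
from .upconversion import downconvert_wavelength

__all__ = [
    "SourceSpectrum",
    "SpectrometerModel",
    "Interface",
    "ReflectorStack",
    "RawFrame",
    "FrameTriple",
    "CalibrationFrames",
    "make_source_spectrum",
    "dispersion_phase",
    "rolloff_attenuation",
    "synth_interferogram",
    "generate_calibration_frames",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSpectrum:
    """Spectral power envelope on a dense uniform wavenumber grid.

    ``k_grid`` is strictly increasing in rad/µm (mid-IR scale); ``envelope``
    is non-negative relative power, zero outside ``band`` (nm pair).
    """

    k_grid: np.ndarray
    envelope: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        if self.k_grid.ndim != 1 or self.k_grid.shape != self.envelope.shape:
            raise ValueError("k_grid and envelope must be matching 1-D arrays")
        if np.any(np.diff(self.k_grid) <= 0):
            raise ValueError("k_grid must be strictly increasing")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")

    @property
    def center_wavelength_nm(self) -> float:
        """Geometric mean of the band edges (nm)."""
        lo, hi = self.band
        return float(np.sqrt(lo * hi))


@dataclass(frozen=True)
class SpectrometerModel:
    """Line-scan spectrometer plus the upconversion map to mid-IR wavenumber.

    Defaults follow a 4096-pixel silicon spectrometer covering 796–879 nm at
    10 bit and 45 kHz, fed by a 1064 nm-pumped upconversion module.  The
    spectral resolution is quoted as a Gaussian FWHM on the mid-IR wavelength
    scale (default 2.7 nm).  ``nonlinearity = (a2, a3)`` adds a quadratic /
    cubic distortion to the otherwise linear pixel->wavelength map, with the
    endpoints pinned.
    """

    n_pixels: int = 4096
    lambda_range_nm: tuple[float, float] = (796.0, 879.0)
    pump_nm: float = 1064.0
    nonlinearity: tuple[float, float] = (0.0, 0.0)
    resolution_fwhm_nm: float = 2.7
    bit_depth: int = 10
    line_rate_hz: float = 45_000.0
    full_well_fraction: float = 0.8
    nominal_integration_ms: float = 3.0
    dark_mean: float = 8.0
    dark_std: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        if self.resolution_fwhm_nm <= 0:
            raise ValueError("resolution_fwhm_nm must be positive")
        lo, hi = self.lambda_range_nm
        if not lo < hi:
            raise ValueError("lambda_range_nm must be increasing")
        if np.any(np.diff(self.pixel_lambda_nm()) <= 0):
            raise ValueError("pixel map must be strictly monotone")

    @property
    def full_well(self) -> int:
        return 2 ** self.bit_depth - 1

    def pixel_lambda_nm(self) -> np.ndarray:
        """Near-IR wavelength at each pixel (nm), endpoints pinned."""
        lo, hi = self.lambda_range_nm
        u = np.linspace(0.0, 1.0, self.n_pixels)
        a2, a3 = self.nonlinearity
        warped = u + a2 * (u**2 - u) + a3 * (u**3 - u)
        return lo + (hi - lo) * warped

    def pixel_k_midir(self) -> np.ndarray:
        """Mid-IR wavenumber at each pixel (rad/µm); decreasing with pixel."""
        lam_ir_nm = downconvert_wavelength(self.pixel_lambda_nm(), self.pump_nm)
        return 2.0 * np.pi / (lam_ir_nm * 1e-3)

    def nyquist_depth_um(self, band: tuple[float, float] | None = None) -> float:
        """Largest unambiguous one-way OPD for the in-band pixel spacing."""
        k = self.pixel_k_midir()
        if band is not None:
            lam = downconvert_wavelength(self.pixel_lambda_nm(), self.pump_nm)
            sel = (lam >= band[0]) & (lam <= band[1])
            if sel.sum() >= 2:
                k = k[sel]
        dk = np.median(np.abs(np.diff(k)))
        return float(np.pi / (2.0 * dk))


@dataclass(frozen=True)
class Interface:
    """One reflecting interface of a sample.

    ``z_um``: one-way OPD in air to the interface; ``r``: amplitude
    reflectivity; ``gdd_fs2``: accumulated double-pass group-delay dispersion
    of the material traversed to reach it; ``phase_poly``: optional extra
    polynomial phase coefficients in ``(k - k0)`` (ascending order, rad).
    """

    z_um: float
    r: float
    gdd_fs2: float = 0.0
    phase_poly: tuple[float, ...] | None = None


@dataclass(frozen=True)
class ReflectorStack:
    interfaces: tuple[Interface, ...]

    def __post_init__(self) -> None:
        zs = [i.z_um for i in self.interfaces]
        if any(z < 0 for z in zs):
            raise ValueError("interface OPDs must be non-negative")
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("interface OPDs must be strictly increasing")
        if any(not 0.0 <= i.r <= 1.0 for i in self.interfaces):
            raise ValueError("amplitude reflectivities must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.interfaces)

    @classmethod
    def single_mirror(cls, z_um: float, r: float = 0.2,
                      gdd_fs2: float = 0.0) -> "ReflectorStack":
        return cls((Interface(z_um, r, gdd_fs2),))


@dataclass(frozen=True)
class RawFrame:
    """One spectrometer readout: integer counts per pixel."""

    counts: np.ndarray
    kind: str  # sample | reference | dark
    integration_ms: float
    bit_depth: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D array")
        if self.kind not in ("sample", "reference", "dark"):
            raise ValueError(f"unknown frame kind {self.kind!r}")

    @property
    def saturated(self) -> np.ndarray:
        return self.counts >= 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class FrameTriple:
    sample: RawFrame
    reference: RawFrame
    dark: RawFrame


@dataclass(frozen=True)
class CalibrationFrames:
    """Two noiseless single-mirror frames plus their companions."""

    frame_a: RawFrame
    frame_b: RawFrame
    reference: RawFrame
    dark: RawFrame
    opd_a_um: float
    opd_b_um: float


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def make_source_spectrum(band_nm, shape="flat", *, n_points=32768,
                         fwhm_nm=None, table=None,
                         margin=0.05) -> SourceSpectrum:
    """Build a normalized source envelope on a dense uniform k-grid.

    Parameters
    ----------
    band_nm : (float, float)
        Emission band (lambda_min, lambda_max) in nm; the envelope is zero
        outside it.
    shape : {"flat", "gaussian", "tabulated"}
        ``gaussian`` needs ``fwhm_nm`` (defaults to the band width) and is
        centered on the band-center wavenumber; ``tabulated`` linearly
        interpolates ``table = (lambda_nm, power)``.
    n_points : int
        Grid density; default 8x a 4096-pixel spectrometer.
    margin : float
        Fractional spectral margin kept around the band (envelope zero there)
        so that resolution convolution and pixel sampling see the band edges.
    """
    lo, hi = float(band_nm[0]), float(band_nm[1])
    if not lo < hi:
        raise ValueError("band must satisfy lambda_min < lambda_max")
    k_lo = 2.0 * np.pi / (hi * 1e-3)
    k_hi = 2.0 * np.pi / (lo * 1e-3)
    span = k_hi - k_lo
    k = np.linspace(k_lo - margin * span, k_hi + margin * span, int(n_points))
    in_band = (k >= k_lo) & (k <= k_hi)

    if shape == "flat":
        env = in_band.astype(float)
    elif shape == "gaussian":
        width_nm = (hi - lo) if fwhm_nm is None else float(fwhm_nm)
        lam0 = 0.5 * (lo + hi)
        dk_fwhm = 2.0 * np.pi * (width_nm * 1e-3) / (lam0 * 1e-3) ** 2
        k0 = 0.5 * (k_lo + k_hi)
        env = np.exp(-4.0 * np.log(2.0) * ((k - k0) / dk_fwhm) ** 2)
        env = np.where(in_band, env, 0.0)
    elif shape == "tabulated":
        if table is None:
            raise ValueError("shape='tabulated' requires a (lambda_nm, power) table")
        lam_tab = np.asarray(table[0], dtype=float)
        pow_tab = np.asarray(table[1], dtype=float)
        order = np.argsort(lam_tab)
        lam_nm = 2.0 * np.pi / k * 1e3
        env = np.interp(lam_nm, lam_tab[order], pow_tab[order], left=0.0, right=0.0)
        env = np.where(in_band, env, 0.0)
    else:
        raise ValueError(f"unknown source shape {shape!r}")

    total = np.trapezoid(env, k)
    if total <= 0:
        raise ValueError("source envelope integrates to zero")
    return SourceSpectrum(k_grid=k, envelope=env / total, band=(lo, hi))


def dispersion_phase(gvd_fs2_per_mm, physical_length_mm, k_grid, *,
                     k0=None, double_pass=True) -> np.ndarray:
    """Quadratic spectral phase of a dispersive element.

    ``phi(k) = 0.5 * GDD * (omega(k) - omega0)^2`` with ``GDD = gvd * length``
    (doubled for double-pass geometry), ``omega = c k`` in rad/fs and
    ``omega0`` at the grid (or supplied) band-center wavenumber.
    """
    if physical_length_mm < 0:
        raise ValueError("physical length must be non-negative")
    k = np.asarray(k_grid, dtype=float)
    gdd = gvd_fs2_per_mm * physical_length_mm * (2.0 if double_pass else 1.0)
    if k0 is None:
        k0 = 0.5 * (k.min() + k.max())
    omega = C_UM_PER_FS * k
    omega0 = C_UM_PER_FS * k0
    return 0.5 * gdd * (omega - omega0) ** 2


def resolution_dk(resolution_fwhm_nm, center_wavelength_nm) -> float:
    """Gaussian spectral-resolution FWHM converted to wavenumber (rad/µm)."""
    if resolution_fwhm_nm <= 0:
        raise ValueError("spectral resolution must be positive")
    lam0_um = center_wavelength_nm * 1e-3
    return 2.0 * np.pi * (resolution_fwhm_nm * 1e-3) / lam0_um**2


def rolloff_attenuation(z_um, resolution_fwhm_nm, center_wavelength_nm):
    """Amplitude sensitivity roll-off ``A(z)`` of the Gaussian-resolution model.

    ``A(z) = exp(-z^2 dk^2 / (4 ln 2))`` with ``dk = 2 pi dlambda/lambda0^2``;
    the 6 dB sensitivity (power) point sits at
    ``z = ln 2 * lambda0^2 / (pi * dlambda)``.
    """
    z = np.asarray(z_um, dtype=float)
    if np.any(z < 0):
        raise ValueError("OPD must be non-negative")
    dk = resolution_dk(resolution_fwhm_nm, center_wavelength_nm)
    out = np.exp(-(z**2) * dk**2 / (4.0 * np.log(2.0)))
    return float(out) if out.ndim == 0 else out


def _interference_intensity(stack, source, rho_ref, mismatch_phase,
                            include_sample=True):
    """Dense-grid spectral intensity before resolution smoothing."""
    k = source.k_grid
    base = np.full_like(k, rho_ref)
    if include_sample and len(stack):
        k0 = 2.0 * np.pi / (source.center_wavelength_nm * 1e-3)
        phi_mis = np.zeros_like(k)
        if mismatch_phase is not None:
            phi_mis = mismatch_phase(k) if callable(mismatch_phase) \
                else np.asarray(mismatch_phase, dtype=float)
        for iface in stack.interfaces:
            base = base + iface.r**2
            phi = dispersion_phase(1.0, iface.gdd_fs2, k, k0=k0,
                                   double_pass=False) if iface.gdd_fs2 else 0.0
            if iface.phase_poly is not None:
                phi = phi + np.polynomial.polynomial.polyval(
                    k - k0, iface.phase_poly)
            base = base + 2.0 * np.sqrt(rho_ref) * iface.r * np.cos(
                2.0 * k * iface.z_um + phi + phi_mis)
    return source.envelope * base


def _smooth_resolution(intensity, source, spec):
    dk_fwhm = resolution_dk(spec.resolution_fwhm_nm, source.center_wavelength_nm)
    dk_grid = source.k_grid[1] - source.k_grid[0]
    sigma = dk_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / dk_grid
    return gaussian_filter1d(intensity, sigma, mode="constant", cval=0.0,
                             truncate=6.0)


def _sample_pixels(intensity, source, spec):
    kp = spec.pixel_k_midir()
    return np.interp(kp, source.k_grid, intensity, left=0.0, right=0.0)


def synth_interferogram(stack: ReflectorStack, source: SourceSpectrum,
                        spec: SpectrometerModel, *, noise=False, seed=None,
                        integration_ms=None, rho_ref=0.5,
                        mismatch_phase=None) -> FrameTriple:
    """Synthesize matched sample / reference / dark frames.

    The sample frame carries the reference intensity, the autocorrelation
    terms ``r_j^2`` and the cross fringes ``2 sqrt(rho_ref) r_j cos(2 k z_j +
    phi_j(k))``; the reference frame only the reference-arm envelope; the dark
    frame only dark counts.  All three share the detector gain, which is fixed
    so the reference maximum reaches ``full_well_fraction`` of full well at
    the nominal integration time.

    ``phi_j`` combines the per-interface accumulated GDD, any higher-order
    phase polynomial, and the global interferometer ``mismatch_phase``
    (callable of k or array on the source grid).  A stack OPD beyond the
    unambiguous pixel-sampling range triggers an aliasing warning but is
    still synthesized.
    """
    if integration_ms is None:
        integration_ms = spec.nominal_integration_ms
    if len(stack):
        z_nyq = spec.nyquist_depth_um(source.band)
        worst = max(i.z_um for i in stack.interfaces)
        if worst > z_nyq:
            warnings.warn(
                f"interface OPD {worst:.0f} µm exceeds the unambiguous depth "
                f"range {z_nyq:.0f} µm; the fringe will alias", stacklevel=2)

    frames = {}
    intensities = {
        "sample": _interference_intensity(stack, source, rho_ref, mismatch_phase),
        "reference": _interference_intensity(stack, source, rho_ref,
                                             mismatch_phase, include_sample=False),
        "dark": np.zeros_like(source.k_grid),
    }
    ref_px = _sample_pixels(
        _smooth_resolution(intensities["reference"], source, spec), source, spec)
    peak_ref = ref_px.max()
    if peak_ref <= 0:
        raise ValueError("reference intensity is zero on all pixels")
    gain = spec.full_well_fraction * spec.full_well / (
        peak_ref * spec.nominal_integration_ms)

    rng = np.random.default_rng(seed) if noise else None
    for kind, dense in intensities.items():
        px = _sample_pixels(_smooth_resolution(dense, source, spec), source, spec)
        counts = gain * px * integration_ms + spec.dark_mean
        if noise:
            counts = rng.poisson(np.clip(counts, 0.0, None)).astype(float)
            counts = counts + rng.normal(0.0, spec.dark_std, counts.shape)
        counts = np.clip(np.rint(counts), 0, spec.full_well).astype(np.int64)
        frames[kind] = RawFrame(counts=counts, kind=kind,
                                integration_ms=float(integration_ms),
                                bit_depth=spec.bit_depth,
                                seed=seed if noise else None)
    return FrameTriple(**frames)


def generate_calibration_frames(spec: SpectrometerModel, source: SourceSpectrum,
                                opd_pair_um, *, mismatch_phase=None,
                                r=0.05) -> CalibrationFrames:
    """Noiseless single-mirror frames at two OPDs for wavenumber calibration.

    The frames embed whatever pixel-map nonlinearity and interferometer
    dispersion mismatch the models carry; feeding them to
    ``reconstruction.build_calibration`` recovers both.
    """
    za, zb = float(opd_pair_um[0]), float(opd_pair_um[1])
    if za <= 0 or zb <= 0:
        raise ValueError("calibration OPDs must be positive")
    if za == zb:
        raise ValueError("calibration OPDs must be distinct (degenerate pair)")
    ta = synth_interferogram(ReflectorStack.single_mirror(za, r), source, spec,
                             noise=False, mismatch_phase=mismatch_phase)
    tb = synth_interferogram(ReflectorStack.single_mirror(zb, r), source, spec,
                             noise=False, mismatch_phase=mismatch_phase)
    return CalibrationFrames(frame_a=ta.sample, frame_b=tb.sample,
                             reference=ta.reference, dark=ta.dark,
                             opd_a_um=za, opd_b_um=zb)
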