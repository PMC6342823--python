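"""Sum-frequency upconversion band mapping.

Mid-infrared OCT signals (here a 3576–4625 nm supercontinuum band) are mixed
with a strong 1064 nm pump in a periodically poled nonlinear crystal.  Energy
conservation, ``1/lambda_P + 1/lambda_IR = 1/lambda_UP``, shifts the whole band
to the near infrared (820–865 nm) where silicon spectrometers are fast and
low-noise, without losing the spectral interference modulation.  This module
implements that wavelength map, the derived band/bandwidth bookkeeping, photon
conserving spectral remapping, and a scalar collinear quasi-phase-matching
mismatch calculator.

Units: wavelengths in nm unless noted; poling period in µm; the mismatch is
returned in rad/µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UpconversionConfig",
    "BandMapResult",
    "upconvert_wavelength",
    "downconvert_wavelength",
    "map_band",
    "remap_spectrum",
    "qpm_mismatch",
]


@dataclass(frozen=True)
class UpconversionConfig:
    """Parameters of the upconversion module.

    Attributes
    ----------
    pump_wavelength : float
        Mixing (pump) laser wavelength in nm.  Default 1064 (Nd:YVO4).
    midir_band : tuple of float
        (lambda_min, lambda_max) of the accepted mid-IR band, nm.
    quantum_efficiency : float
        Flat scalar conversion efficiency over the band (fraction).  The
        wavelength dependence of the real module is not modeled; a per-sample
        efficiency table may be passed directly to :func:`remap_spectrum`.
    poling_period : float
        Quasi-phase-matching poling period Lambda in µm.
    """

    pump_wavelength: float = 1064.0
    midir_band: tuple[float, float] = (3576.0, 4625.0)
    quantum_efficiency: float = 0.01
    poling_period: float = 23.0

    def __post_init__(self) -> None:
        if self.pump_wavelength <= 0:
            raise ValueError("pump_wavelength must be positive")
        lo, hi = self.midir_band
        # a degenerate band (lo == hi) is allowed: it maps to a single line
        if not (0 < lo <= hi):
            raise ValueError("midir_band must satisfy 0 < lambda_min <= lambda_max")
        if not (0 < self.quantum_efficiency <= 1):
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if self.poling_period <= 0:
            raise ValueError("poling_period must be positive")


@dataclass(frozen=True)
class BandMapResult:
    """Detected-band summary produced by :func:`map_band` (all nm)."""

    nearir_band: tuple[float, float]
    nearir_bandwidth: float
    midir_bandwidth: float


def upconvert_wavelength(lambda_ir, lambda_p):
    """Map a mid-IR wavelength to its sum-frequency (upconverted) wavelength.

    Energy conservation of the three-photon process gives
    ``1/lambda_UP = 1/lambda_P + 1/lambda_IR``; the result is always shorter
    than either input.  Accepts scalars or arrays (nm in, nm out).
    """
    lam_ir = np.asarray(lambda_ir, dtype=float)
    lam_p = np.asarray(lambda_p, dtype=float)
    if np.any(~np.isfinite(lam_ir)) or np.any(~np.isfinite(lam_p)):
        raise ValueError("wavelengths must be finite")
    if np.any(lam_ir <= 0) or np.any(lam_p <= 0):
        raise ValueError("wavelengths must be positive")
    out = 1.0 / (1.0 / lam_p + 1.0 / lam_ir)
    return float(out) if out.ndim == 0 else out


def downconvert_wavelength(lambda_up, lambda_p):
    """Inverse map: recover the mid-IR wavelength from the upconverted one.

    Requires ``lambda_up < lambda_p`` (otherwise the sum-frequency relation
    has no positive solution).
    """
    lam_up = np.asarray(lambda_up, dtype=float)
    lam_p = np.asarray(lambda_p, dtype=float)
    if np.any(lam_up <= 0) or np.any(lam_p <= 0):
        raise ValueError("wavelengths must be positive")
    inv = 1.0 / lam_up - 1.0 / lam_p
    if np.any(inv <= 0):
        raise ValueError("lambda_up must be shorter than the pump wavelength")
    out = 1.0 / inv
    return float(out) if out.ndim == 0 else out


def map_band(cfg: UpconversionConfig) -> BandMapResult:
    """Apply the upconversion map to both band edges and report bandwidths."""
    lo, hi = cfg.midir_band
    up_lo = upconvert_wavelength(lo, cfg.pump_wavelength)
    up_hi = upconvert_wavelength(hi, cfg.pump_wavelength)
    return BandMapResult(
        nearir_band=(up_lo, up_hi),
        nearir_bandwidth=up_hi - up_lo,
        midir_bandwidth=hi - lo,
    )


def remap_spectrum(lambda_ir, density_ir, cfg: UpconversionConfig, qe=None):
    """Remap a photon-count spectral density from the mid-IR to the near-IR.

    Parameters
    ----------
    lambda_ir : array
        Strictly monotonic mid-IR wavelength grid (nm) inside
        ``cfg.midir_band``.
    density_ir : array
        Non-negative photon-count density per nm on that grid.
    cfg : UpconversionConfig
    qe : array or None
        Optional per-sample quantum efficiency overriding the flat
        ``cfg.quantum_efficiency``.

    Returns
    -------
    (lambda_up, density_up) : arrays
        Near-IR grid (nm, same monotonic ordering) and photon-count density
        per nm.  Photon count is conserved up to the efficiency factor:
        ``integral(density_up) = QE * integral(density_ir)`` because the
        Jacobian ``|dlambda_UP/dlambda_IR| = (lambda_UP/lambda_IR)**2`` is
        applied exactly.
    """
    lam = np.asarray(lambda_ir, dtype=float)
    dens = np.asarray(density_ir, dtype=float)
    if lam.ndim != 1 or lam.shape != dens.shape:
        raise ValueError("grid and density must be matching 1-D arrays")
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavelength grid must be strictly monotonic")
    if np.any(dens < 0):
        raise ValueError("spectral density must be non-negative")
    lo, hi = cfg.midir_band
    if lam.min() < lo - 1e-9 or lam.max() > hi + 1e-9:
        raise ValueError("wavelength grid lies outside the configured mid-IR band")
    eff = cfg.quantum_efficiency if qe is None else np.asarray(qe, dtype=float)
    lam_up = upconvert_wavelength(lam, cfg.pump_wavelength)
    jac = (lam_up / lam) ** 2  # dlambda_UP / dlambda_IR
    dens_up = eff * dens / jac
    return lam_up, dens_up


def qpm_mismatch(lambda_ir, lambda_p, n_ir, n_p, n_up, poling_period):
    """Collinear first-order quasi-phase-matching mismatch, rad/µm.

    Sign convention: ``dk = 2*pi*(n_UP/lam_UP - n_P/lam_P - n_IR/lam_IR
    - 1/Lambda)`` with wavelengths converted to µm, i.e. the upconverted wave
    vector minus pump, signal, and one grating vector.  Zero means perfect
    first-order phase matching.
    """
    if poling_period <= 0:
        raise ValueError("poling_period must be positive")
    for name, n in (("n_ir", n_ir), ("n_p", n_p), ("n_up", n_up)):
        if np.any(np.asarray(n) <= 0):
            raise ValueError(f"{name} must be positive")
    lam_up = upconvert_wavelength(lambda_ir, lambda_p)
    lam_ir_um = np.asarray(lambda_ir, dtype=float) * 1e-3
    lam_p_um = np.asarray(lambda_p, dtype=float) * 1e-3
    lam_up_um = np.asarray(lam_up, dtype=float) * 1e-3
    dk = 2.0 * np.pi * (
        n_up / lam_up_um - n_p / lam_p_um - n_ir / lam_ir_um - 1.0 / poling_period
    )
    return float(dk) if np.ndim(dk) == 0 else dk
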