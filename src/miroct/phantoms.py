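"""Sample generators: the NDT phantoms as reflector stacks and voxel domains.

Three reference samples drive the virtual bench:

* a three-layer ceramic stack — 375 µm zirconia (C1, n = 2.138) on a 475 µm
  alumina plate (C2, n = 1.675) with up to 60 µm deep laser-milled valleys in
  its top surface, on a 300 µm alumina backing plate (C3);
* a 255 µm silicon wafer probed at 1.3 µm (GVD 1576 fs²/mm) and 4 µm
  (385 fs²/mm);
* an alumina green tape of varying thickness on a ~62 µm cellulose acetate
  foil (n 1.68 / 1.48).

Scattering/absorption coefficients for the ceramics and the tape are NOT
published alongside the geometry; the defaults below are PLACEHOLDERS chosen
only to reproduce the qualitative contrast ordering (much weaker, more
isotropic scattering at 4 µm than at 1.3 µm).  Supply measured values through
``MaterialProperties`` for quantitative work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import Interface, ReflectorStack
from .mc_transport import VoxelDomain

__all__ = [
    "MaterialProperties",
    "CeramicStackSpec",
    "WaferSpec",
    "ceramic_stack_domain",
    "ceramic_stack_reflectors",
    "wafer_reflectors",
    "tape_on_foil_domain",
    "fresnel_amplitude",
]

WAVELENGTH_TAGS = ("1.3", "4.0")


@dataclass(frozen=True)
class MaterialProperties:
    """(mua mm^-1, mus mm^-1, g) per wavelength tag, plus refractive index."""

    n: float
    by_tag: dict = field(default_factory=dict)

    def optical(self, tag: str):
        if tag not in self.by_tag:
            raise KeyError(f"no optical properties for wavelength tag {tag!r}")
        return self.by_tag[tag]


def _placeholder(n, mus13, g13, mus4, g4, mua=0.02) -> MaterialProperties:
    # placeholder coefficients (not published values); see module docstring
    return MaterialProperties(n=n, by_tag={
        "1.3": (mua, mus13, g13),
        "4.0": (mua, mus4, g4),
    })


ZIRCONIA = _placeholder(n=2.138, mus13=6.0, g13=0.85, mus4=1.5, g4=0.5)
ALUMINA = _placeholder(n=1.675, mus13=20.0, g13=0.80, mus4=2.0, g4=0.30)
ALUMINA_TAPE = _placeholder(n=1.68, mus13=60.0, g13=0.80, mus4=4.0, g4=0.30)
ACETATE_FOIL = _placeholder(n=1.48, mus13=1.0, g13=0.70, mus4=0.5, g4=0.30)
AIR = MaterialProperties(n=1.0, by_tag={t: (0.0, 0.0, 0.0)
                                        for t in WAVELENGTH_TAGS})


@dataclass(frozen=True)
class CeramicStackSpec:
    """Geometry and materials of the three-plate ceramic sample.

    Valleys are milled into C2's top surface; by default their widths follow
    the simulation layout (5..180 µm in steps of 5), the physically milled
    sample spans 5–300 µm.
    """

    c1_thickness_um: float = 375.0
    c2_thickness_um: float = 475.0
    c3_thickness_um: float = 300.0
    #: thin air layer between the stacked (not bonded) C2 and C3 plates; it
    #: is what makes the otherwise index-matched alumina/alumina boundary
    #: visible as an echo
    interplate_gap_um: float = 5.0
    valley_depth_um: float = 60.0
    valley_widths_um: tuple[float, ...] = tuple(
        float(w) for w in range(5, 181, 5))
    c1: MaterialProperties = ZIRCONIA
    c2: MaterialProperties = ALUMINA
    c3: MaterialProperties = ALUMINA

    def __post_init__(self) -> None:
        if min(self.c1_thickness_um, self.c2_thickness_um,
               self.c3_thickness_um) <= 0:
            raise ValueError("layer thicknesses must be positive")
        if self.valley_depth_um > self.c2_thickness_um:
            raise ValueError("valley depth exceeds the C2 plate thickness")


@dataclass(frozen=True)
class WaferSpec:
    """Silicon wafer: thickness and GVD per probe wavelength tag."""

    thickness_um: float = 255.0
    gvd_fs2_per_mm: dict = field(
        default_factory=lambda: {"1.3": 1576.0, "4.0": 385.0})

    def __post_init__(self) -> None:
        if self.thickness_um < 0:
            raise ValueError("thickness must be non-negative")


def fresnel_amplitude(n1: float, n2: float) -> float:
    """Normal-incidence amplitude reflectivity |n1 - n2| / (n1 + n2)."""
    return abs(n1 - n2) / (n1 + n2)


# --------------------------------------------------------------------------
# ceramic stack
# --------------------------------------------------------------------------

def ceramic_stack_domain(spec: CeramicStackSpec, wavelength_tag: str,
                         *, dims=(1400, 9, 230),
                         voxel_size_um: float = 5.0) -> VoxelDomain:
    """Voxelize the ceramic stack for the MC engine.

    Default grid: 1400 x 9 x 230 voxels of 5 µm (7000 x 45 x 1150 µm^3),
    uniform along Y.  Valleys are air-filled recesses in C2's top surface,
    laid out left to right with uniform gaps between them.
    """
    if wavelength_tag not in WAVELENGTH_TAGS:
        raise ValueError(f"wavelength_tag must be one of {WAVELENGTH_TAGS}")
    nx, ny, nz = dims
    h = voxel_size_um
    depth_um = nz * h
    total = (spec.c1_thickness_um + spec.c2_thickness_um
             + spec.c3_thickness_um)
    if total > depth_um + 1e-9:
        raise ValueError("stack geometry exceeds the domain depth")

    dom = VoxelDomain.uniform(dims, voxel_size_um=h)

    def fill(z0_um, z1_um, mat, x_sel=slice(None)):
        k0 = int(round(z0_um / h))
        k1 = int(round(z1_um / h))
        mua, mus, g = mat.optical(wavelength_tag)
        dom.mua[x_sel, :, k0:k1] = mua
        dom.mus[x_sel, :, k0:k1] = mus
        dom.g[x_sel, :, k0:k1] = g
        dom.n[x_sel, :, k0:k1] = mat.n

    z1 = spec.c1_thickness_um
    z2 = z1 + spec.c2_thickness_um
    z3 = z2 + spec.c3_thickness_um
    fill(0.0, z1, spec.c1)
    fill(z1, z2, spec.c2)
    fill(z2, z3, spec.c3)
    if spec.interplate_gap_um > 0:
        # the stacked C2/C3 plates are separated by a thin air film, carved
        # out of C3's allocation so the total depth stays the plate sum
        fill(z2, z2 + spec.interplate_gap_um, AIR)

    if spec.valley_widths_um:
        widths = np.asarray(spec.valley_widths_um, dtype=float)
        extent = nx * h
        gap = (extent - widths.sum()) / (len(widths) + 1)
        if gap < 0:
            raise ValueError("valleys do not fit the domain width")
        x = gap
        for wdt in widths:
            i0 = int(round(x / h))
            i1 = max(i0 + 1, int(round((x + wdt) / h)))
            fill(z1, z1 + spec.valley_depth_um, AIR, x_sel=slice(i0, i1))
            x += wdt + gap
    return dom


def ceramic_stack_reflectors(spec: CeramicStackSpec, *,
                             through_valley: bool = False,
                             z_offset_um: float = 0.0) -> ReflectorStack:
    """Interface list of the ceramic stack for the spectral forward model.

    Interfaces sit at cumulative one-way OPDs ``sum n_i d_i`` with
    normal-incidence Fresnel amplitude reflectivities; interfaces between
    index-matched layers (C2/C3) are dropped.  ``through_valley`` routes the
    beam through an air-filled valley (C1/air and air/C2 interfaces, and all
    deeper OPDs reduced by ``depth * (n_C2 - 1)``).
    """
    n1, n2, n3 = spec.c1.n, spec.c2.n, spec.c3.n
    ifaces = []
    z = z_offset_um
    ifaces.append((z, fresnel_amplitude(1.0, n1)))          # air / C1
    z += spec.c1_thickness_um * n1
    if through_valley:
        ifaces.append((z, fresnel_amplitude(n1, 1.0)))      # C1 / air (valley)
        z += spec.valley_depth_um * 1.0
        ifaces.append((z, fresnel_amplitude(1.0, n2)))      # air / C2
        z += (spec.c2_thickness_um - spec.valley_depth_um) * n2
    else:
        ifaces.append((z, fresnel_amplitude(n1, n2)))       # C1 / C2
        z += spec.c2_thickness_um * n2
    gap = spec.interplate_gap_um
    if gap > 0:                                             # C2 / air / C3
        ifaces.append((z, fresnel_amplitude(n2, 1.0)))
        z += gap
        ifaces.append((z, fresnel_amplitude(1.0, n3)))
    else:
        r23 = fresnel_amplitude(n2, n3)
        if r23 > 0:                                         # C2 / C3
            ifaces.append((z, r23))
    z += (spec.c3_thickness_um - gap) * n3
    ifaces.append((z, fresnel_amplitude(n3, 1.0)))          # C3 / air
    return ReflectorStack(tuple(Interface(z_um=zz, r=rr) for zz, rr in ifaces))


# --------------------------------------------------------------------------
# silicon wafer
# --------------------------------------------------------------------------

def wafer_reflectors(spec: WaferSpec, probe: str, n_group: float,
                     *, z_offset_um: float = 100.0) -> ReflectorStack:
    """Two-interface silicon wafer with double-pass GDD on the back face.

    ``n_group`` (the group index used for the OPD mapping) is a required
    input — it is not part of the sample description here; ~3.6 is a typical
    literature value for silicon in this range.
    """
    if probe not in spec.gvd_fs2_per_mm:
        raise ValueError(f"no GVD tabulated for probe {probe!r}")
    if n_group is None or n_group <= 1:
        raise ValueError("a group index > 1 must be supplied")
    r = fresnel_amplitude(1.0, n_group)
    front = Interface(z_um=z_offset_um, r=r)
    if spec.thickness_um == 0:
        return ReflectorStack((front,))
    gdd = 2.0 * (spec.thickness_um * 1e-3) * spec.gvd_fs2_per_mm[probe]
    back = Interface(z_um=z_offset_um + spec.thickness_um * n_group,
                     r=r, gdd_fs2=gdd)
    return ReflectorStack((front, back))


# --------------------------------------------------------------------------
# alumina tape on acetate foil
# --------------------------------------------------------------------------

def tape_on_foil_domain(tape_thickness_um: float, wavelength_tag: str,
                        *, foil_thickness_um: float = 62.0,
                        dims=(200, 9, 80), voxel_size_um: float = 2.0,
                        tape: MaterialProperties = ALUMINA_TAPE,
                        foil: MaterialProperties = ACETATE_FOIL) -> VoxelDomain:
    """Two-layer domain: strongly scattering tape over weakly scattering foil.

    ``tape_thickness_um = 0`` reproduces the bare-foil reference section.
    """
    if tape_thickness_um < 0 or foil_thickness_um < 0:
        raise ValueError("thicknesses must be non-negative")
    if wavelength_tag not in WAVELENGTH_TAGS:
        raise ValueError(f"wavelength_tag must be one of {WAVELENGTH_TAGS}")
    nx, ny, nz = dims
    h = voxel_size_um
    if tape_thickness_um + foil_thickness_um > nz * h + 1e-9:
        raise ValueError("layers exceed the domain depth")
    dom = VoxelDomain.uniform(dims, voxel_size_um=h)
    k_tape = int(round(tape_thickness_um / h))
    k_foil = k_tape + int(round(foil_thickness_um / h))
    for (k0, k1), mat in (((0, k_tape), tape), ((k_tape, k_foil), foil)):
        if k1 <= k0:
            continue
        mua, mus, g = mat.optical(wavelength_tag)
        dom.mua[:, :, k0:k1] = mua
        dom.mus[:, :, k0:k1] = mus
        dom.g[:, :, k0:k1] = g
        dom.n[:, :, k0:k1] = mat.n
    return dom
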