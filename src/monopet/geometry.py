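"""Cylindrical scanner built from flat monolithic detector modules.

The scanner is a polygonal ring of flat LYSO slabs tangent to the bore
cylinder.  Two presets are shipped: ``design_a`` (7 rings, 36.2 cm axial
field of view) and ``design_b`` (14 rings, 72.6 cm), both with 40 modules
of 50 x 50 x 16 mm^3 per ring on a 70 cm bore.

Coordinate frame: right-handed, ``z`` along the scanner axis, origin at the
axial and transverse centre.  Lengths in mm, times in ns, energies in keV.
Module ``k`` of a ring sits at azimuth ``2*pi*k/modules_per_ring`` with
``k = 0`` on the +x axis; rings are centred on ``z = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .constants import MU_LYSO


@dataclass(frozen=True)
class ScannerConfig:
    """Scanner design parameters (defaults shared by designs A and B)."""

    bore_diameter: float = 700.0  # mm
    modules_per_ring: int = 40
    n_rings: int = 7
    crystal_width_transaxial: float = 50.0  # mm
    crystal_width_axial: float = 50.0  # mm
    crystal_thickness: float = 16.0  # mm
    ring_gap: float = 2.0  # mm
    ctr_fwhm: float = 200.0  # ps, coincidence time resolution
    coincidence_window: float = 3.0  # ns, |t1 - t2| <= window
    energy_resolution_frac: float = 0.115  # FWHM/E at 511 keV
    energy_window: Tuple[float, float] = (440.0, 650.0)  # keV
    dead_time: float = 300.0  # ns
    dead_time_model: str = "paralysable"
    name: str = "custom"

    def __post_init__(self) -> None:
        positive = {
            "bore_diameter": self.bore_diameter,
            "modules_per_ring": self.modules_per_ring,
            "n_rings": self.n_rings,
            "crystal_width_transaxial": self.crystal_width_transaxial,
            "crystal_width_axial": self.crystal_width_axial,
            "crystal_thickness": self.crystal_thickness,
            "ctr_fwhm": self.ctr_fwhm,
            "coincidence_window": self.coincidence_window,
            "energy_resolution_frac": self.energy_resolution_frac,
            "dead_time": self.dead_time,
        }
        for key, value in positive.items():
            if value <= 0:
                raise ValueError(f"{key} must be strictly positive")
        if self.ring_gap < 0:
            raise ValueError("ring_gap must be non-negative")
        lo, hi = self.energy_window
        if not lo < hi:
            raise ValueError("energy_window low must be below high")
        if self.dead_time_model != "paralysable":
            raise ValueError("only the paralysable dead-time model is supported")
        circumference = math.pi * self.bore_diameter
        if self.modules_per_ring * self.crystal_width_transaxial > circumference:
            raise ValueError("modules do not fit on the ring circumference")
        # Flat tangent slabs overlap when the half width exceeds the
        # tangent distance to the neighbouring slab plane.
        half_width = self.crystal_width_transaxial / 2.0
        if half_width > (self.bore_diameter / 2.0) * math.tan(
            math.pi / self.modules_per_ring
        ):
            raise ValueError("flat modules overlap azimuthally")

    @property
    def afov(self) -> float:
        """Axial field of view in mm."""
        return (
            self.n_rings * self.crystal_width_axial
            + (self.n_rings - 1) * self.ring_gap
        )

    @property
    def ring_pitch(self) -> float:
        return self.crystal_width_axial + self.ring_gap


def design_a(**overrides) -> ScannerConfig:
    """7-ring design, 36.2 cm axial FOV."""
    return ScannerConfig(n_rings=7, name="design_a", **overrides)


def design_b(**overrides) -> ScannerConfig:
    """14-ring design, 72.6 cm axial FOV (two stacked design-A scanners)."""
    return ScannerConfig(n_rings=14, name="design_b", **overrides)


PRESETS = {"design_a": design_a, "design_b": design_b, "a": design_a, "b": design_b}


def save_config(config: ScannerConfig, path: str | Path) -> None:
    data = asdict(config)
    data["energy_window"] = list(config.energy_window)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> ScannerConfig:
    data = yaml.safe_load(Path(path).read_text())
    data["energy_window"] = tuple(data["energy_window"])
    return ScannerConfig(**data)


@dataclass
class ScannerGeometry:
    """Placed module layout derived from a :class:`ScannerConfig`."""

    config: ScannerConfig
    module_centers: np.ndarray  # (n_modules, 3) crystal centres
    module_normals: np.ndarray  # (n_modules, 3) inward face normals point outward (+radial)
    module_index: np.ndarray  # (n_modules, 2) (ring, azimuth)
    afov: float

    @property
    def n_modules(self) -> int:
        return len(self.module_centers)

    @property
    def inner_radius(self) -> float:
        return self.config.bore_diameter / 2.0

    @property
    def ring_z_min(self) -> np.ndarray:
        """Lower z edge of every ring slab."""
        pitch = self.config.ring_pitch
        r = np.arange(self.config.n_rings)
        return -self.afov / 2.0 + r * pitch

    def module_id(self, ring: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
        return ring * self.config.modules_per_ring + azimuth


@dataclass(frozen=True)
class GeometryReport:
    """Headline geometric figures of a design.

    ``detector_surface`` is the total inner crystal area in 1e6 mm^2 and
    ``scintillator_volume`` the crystal volume in 1e6 mm^3; the opening
    angle is ``arctan(aFOV / bore diameter)``.
    """

    afov_cm: float
    opening_angle_deg: float  # exact value
    opening_angle_rounded: int  # nearest degree, as usually quoted
    detector_surface: float  # 1e6 mm^2
    scintillator_volume: float  # 1e6 mm^3


def build_scanner(config: ScannerConfig) -> ScannerGeometry:
    """Place all modules of the design at equal azimuthal spacing."""
    n_az = config.modules_per_ring
    n_r = config.n_rings
    azimuths = 2.0 * math.pi * np.arange(n_az) / n_az
    normals_1r = np.stack(
        [np.cos(azimuths), np.sin(azimuths), np.zeros(n_az)], axis=1
    )
    afov = config.afov
    pitch = config.ring_pitch
    ring_z = -afov / 2.0 + config.crystal_width_axial / 2.0 + pitch * np.arange(n_r)

    centre_radius = config.bore_diameter / 2.0 + config.crystal_thickness / 2.0
    centers = np.zeros((n_r * n_az, 3))
    normals = np.zeros((n_r * n_az, 3))
    index = np.zeros((n_r * n_az, 2), dtype=np.int64)
    for r in range(n_r):
        sl = slice(r * n_az, (r + 1) * n_az)
        normals[sl] = normals_1r
        centers[sl, :2] = centre_radius * normals_1r[:, :2]
        centers[sl, 2] = ring_z[r]
        index[sl, 0] = r
        index[sl, 1] = np.arange(n_az)
    return ScannerGeometry(config, centers, normals, index, afov)


def derived_metrics(geom: ScannerGeometry) -> GeometryReport:
    """Axial length, opening angle, detector surface and crystal volume."""
    cfg = geom.config
    surface_mm2 = (
        geom.n_modules * cfg.crystal_width_transaxial * cfg.crystal_width_axial
    )
    volume_mm3 = surface_mm2 * cfg.crystal_thickness
    angle = math.degrees(math.atan2(geom.afov, cfg.bore_diameter))
    return GeometryReport(
        afov_cm=geom.afov / 10.0,
        opening_angle_deg=angle,
        opening_angle_rounded=int(round(angle)),
        detector_surface=surface_mm2 / 1e6,
        scintillator_volume=volume_mm3 / 1e6,
    )


def intersect_rays(
    geom: ScannerGeometry,
    origins: np.ndarray,
    directions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ray / module-slab intersection.

    Parameters
    ----------
    origins, directions : (N, 3) arrays; directions must be unit vectors and
        origins must lie inside the bore cylinder.

    Returns
    -------
    module : (N,) int64, module id or -1 when the ray escapes axially or
        passes between modules.
    entry : (N, 3) entry point on the inner face (undefined where miss).
    chord : (N,) chord length through the 16 mm slab, clipped by the module
        side faces (0 where miss).

    Rays enter crystals only through the inner face; the sliver of rays
    that would clip a neighbouring slab through its side wall is treated
    as a miss.
    """
    from ._kernels import hit_scanner

    O = np.ascontiguousarray(origins, dtype=np.float64)
    D = np.ascontiguousarray(directions, dtype=np.float64)
    if O.ndim != 2:
        O = O[None, :]
        D = D[None, :]
    cfg = geom.config
    return hit_scanner(
        O,
        D,
        geom.inner_radius,
        cfg.crystal_thickness,
        cfg.crystal_width_transaxial / 2.0,
        cfg.modules_per_ring,
        -geom.afov / 2.0,
        cfg.ring_pitch,
        cfg.crystal_width_axial,
        cfg.n_rings,
    )


def intersect_ray(
    geom: ScannerGeometry, origin, direction
) -> Optional[tuple[int, np.ndarray, float]]:
    """Scalar convenience wrapper around :func:`intersect_rays`."""
    m, e, c = intersect_rays(
        geom, np.asarray(origin)[None, :], np.asarray(direction)[None, :]
    )
    if m[0] < 0:
        return None
    return int(m[0]), e[0], float(c[0])


def geometry_tables(geom: ScannerGeometry) -> tuple:
    """Scalar constants consumed by the numba kernels.

    Returns ``(R, thickness, half_width, n_az, z0, pitch, axial_width,
    n_rings, mu_lyso)``.
    """
    cfg = geom.config
    return (
        geom.inner_radius,
        cfg.crystal_thickness,
        cfg.crystal_width_transaxial / 2.0,
        cfg.modules_per_ring,
        -geom.afov / 2.0,
        cfg.ring_pitch,
        cfg.crystal_width_axial,
        cfg.n_rings,
        MU_LYSO,
    )


def module_frame(geom: ScannerGeometry, module: np.ndarray):
    """Unit vectors (normal, tangential) and ring z-range per module id."""
    cfg = geom.config
    n_az = cfg.modules_per_ring
    az = module % n_az
    ring = module // n_az
    ang = 2.0 * math.pi * az / n_az
    normal = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=-1)
    tangent = np.stack([-np.sin(ang), np.cos(ang), np.zeros_like(ang)], axis=-1)
    zlo = -geom.afov / 2.0 + ring * cfg.ring_pitch
    return normal, tangent, zlo, zlo + cfg.crystal_width_axial
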