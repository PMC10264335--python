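"""NEMA spatial-resolution and image-quality analyses.

Spatial resolution: the point-spread function of a reconstructed point
source is profiled through its maximum along the radial, tangential and
axial directions; the peak value comes from a parabolic fit through the
peak bin and its neighbours and the FWHM from linear interpolation of the
half-maximum crossings (the NEMA one-dimensional profile method).

Image quality: circular regions of interest, one per hot sphere on the
sphere-centre slice and sixty background ROIs per sphere size (twelve on
each of five slices), feed the contrast recovery coefficient
CRC = (C_H/C_B - 1)/(A_H/A_B - 1) and the background variability
N_j = SD_j / C_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coincidence import TRUE, CoincidenceList, process_singles
from .geometry import ScannerGeometry, build_scanner, design_a, PRESETS
from .grids import ImageVolume, VoxelGrid, voxelise_mu_map
from .mc import PhysicsModel, Scenario, run_simulation
from .phantoms import (
    IQ_SPHERE_DIAMETERS,
    IQ_SPHERE_RING_DIAMETER,
    make_iq_phantom,
    make_point_source,
    nema_point_positions,
)
from .recon import (
    ENDPOINT_BLUR_FWHM_MM,
    blur_lor_endpoints,
    compute_sensitivity_map,
    reconstruct_mlem,
)

# ---------------------------------------------------------------------------
# PSF measurement


def _parabolic_peak(y0: float, y1: float, y2: float) -> float:
    """Peak value of the parabola through three equidistant samples."""
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a local maximum; fall back to the centre sample
        return y1
    delta = 0.5 * (y0 - y2) / denom
    return y1 - 0.25 * (y0 - y2) * delta


def fwhm_from_profile(profile: np.ndarray, bin_width: float) -> float:
    """FWHM of a single-peaked 1-D profile, NEMA style."""
    profile = np.asarray(profile, dtype=np.float64)
    k = int(np.argmax(profile))
    if k == 0 or k == len(profile) - 1:
        raise ValueError("profile peak lies on the border")
    peak = _parabolic_peak(profile[k - 1], profile[k], profile[k + 1])
    half = peak / 2.0
    # walk outwards to the half-maximum crossings
    left = None
    for i in range(k, 0, -1):
        if profile[i - 1] <= half <= profile[i]:
            frac = (profile[i] - half) / max(profile[i] - profile[i - 1], 1e-300)
            left = i - frac
            break
    right = None
    for i in range(k, len(profile) - 1):
        if profile[i + 1] <= half <= profile[i]:
            frac = (profile[i] - half) / max(profile[i] - profile[i + 1], 1e-300)
            right = i + frac
            break
    if left is None or right is None:
        # degenerate single-bin peak: report one bin width
        return bin_width
    return (right - left) * bin_width


def measure_fwhm(image: ImageVolume, axis: int) -> float:
    """FWHM (mm) of the PSF along a grid axis, profiled through the maximum."""
    vals = image.values
    peak_idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
    index: List = list(peak_idx)
    index[axis] = slice(None)
    profile = vals[tuple(index)]
    return fwhm_from_profile(profile, image.grid.voxel_size[axis])


@dataclass(frozen=True)
class PSFMeasurement:
    radius_mm: float
    axial_station_mm: float
    fwhm_radial: float
    fwhm_tangential: float
    fwhm_axial: float


def resolution_study(
    design: str = "a",
    seed: int = 0,
    coincidences_per_position: int = 100_000,
    n_iterations: int = 10,
    voxel_mm: float = 0.5,
    grid_shape: Tuple[int, int, int] = (64, 64, 64),
    blur_fwhm_mm: float = ENDPOINT_BLUR_FWHM_MM,
    physics: Optional[PhysicsModel] = None,
    bare_source: bool = False,
    positions: Optional[Sequence[Tuple[float, float]]] = None,
) -> List[PSFMeasurement]:
    """PSF FWHM at the six NEMA point-source positions.

    Sources sit on the +x axis, so the grid axes coincide with the NEMA
    radial (x), tangential (y) and axial (z) directions.  Each position is
    simulated until the target number of true coincidences is collected,
    endpoints are blurred with the intrinsic detector resolution, and the
    source is reconstructed with non-TOF MLEM on a local 0.5 mm grid.
    """
    geom = build_scanner(PRESETS[design]())
    rng = np.random.default_rng(seed)
    physics = physics or PhysicsModel()
    results: List[PSFMeasurement] = []
    if positions is None:
        positions = nema_point_positions(geom.afov)
    for radius, z_station in positions:
        position = np.array([radius, 0.0, z_station])
        phantom, source = make_point_source(position, bare=bare_source)
        scenario = Scenario(geom, source, phantom, physics)
        trues: List[CoincidenceList] = []
        collected = 0
        budget = 30
        while collected < coincidences_per_position and budget > 0:
            need = coincidences_per_position - collected
            # rough pair efficiency of a few percent; simulate in slabs
            n_decays = max(int(need * 25), 200_000)
            duration = n_decays / source.total_activity
            singles = run_simulation(scenario, duration, rng)
            coinc = process_singles(singles, geom.config)
            coinc = coinc.select(coinc.label == TRUE)
            trues.append(coinc)
            collected += len(coinc)
            budget -= 1
        coinc = CoincidenceList.concatenate(trues)
        coinc = blur_lor_endpoints(coinc, geom, blur_fwhm_mm, rng)
        grid = VoxelGrid.centred(position, voxel_mm, grid_shape)
        sens = compute_sensitivity_map(geom, grid, n_directions=96, rng=rng)
        res = reconstruct_mlem(
            coinc, grid, n_iterations=n_iterations, sensitivity=sens
        )
        results.append(
            PSFMeasurement(
                radius_mm=radius,
                axial_station_mm=z_station,
                fwhm_radial=measure_fwhm(res.image, 0),
                fwhm_tangential=measure_fwhm(res.image, 1),
                fwhm_axial=measure_fwhm(res.image, 2),
            )
        )
    return results


def resolution_table(measurements: Sequence[PSFMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "radius_cm": [m.radius_mm / 10.0 for m in measurements],
            "axial_station_mm": [m.axial_station_mm for m in measurements],
            "radial_mm": [m.fwhm_radial for m in measurements],
            "tangential_mm": [m.fwhm_tangential for m in measurements],
            "axial_mm": [m.fwhm_axial for m in measurements],
        }
    )


# ---------------------------------------------------------------------------
# image-quality ROI protocol


@dataclass
class CircularROI:
    center_xy: Tuple[float, float]
    radius: float
    slice_z: float


@dataclass
class IQROISet:
    """One hot ROI per sphere plus sixty background ROIs per sphere size."""

    hot: Dict[float, CircularROI]  # keyed by sphere diameter
    background: Dict[float, List[CircularROI]]


#: Background ROI template: twelve fixed centres (mm) that keep even the
#: largest (37 mm) ROI clear of every sphere, the lung insert and the
#: phantom wall on all five analysis slices.
_BG_TEMPLATE_XY = (
    (115.0, 0.0),
    (-115.0, 0.0),
    (105.0, 35.0),
    (105.0, -35.0),
    (-105.0, 35.0),
    (-105.0, -35.0),
    (75.0, 50.0),
    (75.0, -50.0),
    (-75.0, 50.0),
    (-75.0, -50.0),
    (0.0, 80.0),
    (0.0, -80.0),
)
_BG_SLICE_OFFSETS_MM = (-20.0, -10.0, 0.0, 10.0, 20.0)


def place_iq_rois(
    grid: VoxelGrid,
    sphere_centers: Optional[np.ndarray] = None,
    sphere_diameters: Sequence[float] = IQ_SPHERE_DIAMETERS,
) -> IQROISet:
    """NEMA ROI layout on the reconstructed IQ image.

    Hot ROIs (diameter equal to the sphere inner diameter) sit on the
    sphere-centre slice; background ROIs of every size share twelve fixed
    template centres on each of the five analysis slices.
    """
    if sphere_centers is None:
        ring_r = IQ_SPHERE_RING_DIAMETER / 2.0
        sphere_centers = np.array(
            [
                [ring_r * math.cos(math.radians(60 * i)),
                 ring_r * math.sin(math.radians(60 * i)), 0.0]
                for i in range(len(sphere_diameters))
            ]
        )
    hot = {}
    for (cx, cy, cz), diam in zip(sphere_centers, sphere_diameters):
        hot[diam] = CircularROI((cx, cy), diam / 2.0, cz)
    bg_centers = list(_BG_TEMPLATE_XY)
    # template sanity: no background ROI may overlap a sphere or the lung
    max_roi_r = max(sphere_diameters) / 2.0
    for cx, cy in bg_centers:
        if math.hypot(cx, cy) < 25.0 + max_roi_r:
            raise ValueError("background ROI overlaps the lung insert")
        for (sx, sy, _), diam in zip(sphere_centers, sphere_diameters):
            if math.hypot(cx - sx, cy - sy) < diam / 2.0 + max_roi_r:
                raise ValueError("background ROI overlaps a sphere")
    background: Dict[float, List[CircularROI]] = {d: [] for d in sphere_diameters}
    for diam in sphere_diameters:
        for dz in _BG_SLICE_OFFSETS_MM:
            for cx, cy in bg_centers:
                background[diam].append(CircularROI((cx, cy), diam / 2.0, dz))
    return IQROISet(hot, background)


def roi_mean(image: ImageVolume, roi: CircularROI) -> float:
    """Mean image value over voxels whose centres fall inside the ROI disc
    on the slice nearest the ROI plane."""
    g = image.grid
    cz = np.asarray(g.voxel_centers()[2])
    iz = int(np.argmin(np.abs(cz - roi.slice_z)))
    cx, cy = np.asarray(g.voxel_centers()[0]), np.asarray(g.voxel_centers()[1])
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    mask = (X - roi.center_xy[0]) ** 2 + (Y - roi.center_xy[1]) ** 2 <= roi.radius**2
    if not mask.any():
        raise ValueError("ROI covers no voxel centre")
    return float(image.values[:, :, iz][mask].mean())


@dataclass
class IQSphereResult:
    diameter_mm: float
    c_hot: float
    c_background: float
    crc: float
    sd_background: float
    background_variability: float


@dataclass
class IQReport:
    iteration: int
    spheres: List[IQSphereResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "diameter_mm": [s.diameter_mm for s in self.spheres],
                "C_H": [s.c_hot for s in self.spheres],
                "C_B": [s.c_background for s in self.spheres],
                "CRC": [s.crc for s in self.spheres],
                "SD": [s.sd_background for s in self.spheres],
                "N": [s.background_variability for s in self.spheres],
            }
        )


def crc_and_bv(
    image: ImageVolume,
    rois: IQROISet,
    a_hot: float,
    a_background: float,
    iteration: int = 0,
) -> IQReport:
    """Contrast recovery and background variability for one image.

    CRC = (C_H/C_B - 1) / (A_H/A_B - 1); N_j = SD_j / C_B with SD_j the
    standard deviation of the sixty background ROI means of size j.
    """
    if a_hot == a_background:
        raise ValueError("hot and background activities must differ")
    spheres = []
    for diam, hot_roi in rois.hot.items():
        c_h = roi_mean(image, hot_roi)
        means = np.array([roi_mean(image, r) for r in rois.background[diam]])
        c_b = float(means.mean())
        sd = float(means.std(ddof=1))
        crc = (c_h / c_b - 1.0) / (a_hot / a_background - 1.0)
        spheres.append(
            IQSphereResult(diam, c_h, c_b, crc, sd, sd / c_b if c_b > 0 else 0.0)
        )
    return IQReport(iteration, spheres)


def iq_study(
    design: str = "a",
    sbr: float = 4.0,
    seed: int = 0,
    duration_s: float = 400.0,
    scale: float = 0.005,
    n_iterations: int = 20,
    voxel_mm: float = 2.0,
    blur_fwhm_mm: float = ENDPOINT_BLUR_FWHM_MM,
    sens_directions: int = 64,
) -> List[IQReport]:
    """Full image-quality chain at ``scale`` times the nominal 400 s scan.

    Simulates the IQ phantom (trues only, as only trues are reconstructed),
    blurs the LOR endpoints, reconstructs with TOF-MLEM (2 mm voxels,
    attenuation correction) and evaluates CRC and background variability
    after every iteration.
    """
    geom = build_scanner(PRESETS[design]())
    rng = np.random.default_rng(seed)
    phantom, source = make_iq_phantom(sbr)
    scenario = Scenario(geom, source, phantom)
    singles = run_simulation(
        scenario,
        duration_s * scale,
        rng,
        trues_only=True,
        max_decays=5e9,
    )
    coinc = process_singles(singles, geom.config)
    coinc = coinc.select(coinc.label == TRUE)
    coinc = blur_lor_endpoints(coinc, geom, blur_fwhm_mm, rng)
    grid = VoxelGrid.centred((0.0, 0.0, 0.0), voxel_mm, (160, 124, 100))
    mu_map = voxelise_mu_map(phantom, grid)
    sens = compute_sensitivity_map(
        geom, grid, mu_map, n_directions=sens_directions, rng=rng, coarsen=2
    )
    result = reconstruct_mlem(
        coinc,
        grid,
        n_iterations=n_iterations,
        sensitivity=sens,
        tof_ctr_ps=geom.config.ctr_fwhm,
        keep_snapshots=True,
    )
    rois = place_iq_rois(grid)
    reports = []
    for it, snap in enumerate(result.snapshots, start=1):
        image = ImageVolume(grid, snap)
        reports.append(crc_and_bv(image, rois, float(sbr), 1.0, iteration=it))
    return reports
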