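"""Lightweight Monte Carlo engine for annihilation-photon transport.

This is the synthetic-data generator of the package: it samples decays as a
homogeneous Poisson process, emits annihilation photon pairs, transports
them through the phantom with photoelectric absorption and Klein-Nishina
Compton scattering, and records crystal interactions as time-stamped
singles that keep full ground-truth lineage (decay id, phantom scatter
count, true interaction point).  Energy windowing, dead time and
coincidence pairing are applied downstream.

The crystal response is deliberately simple: an interaction depth is drawn
from the exponential attenuation profile along the chord through the 16 mm
slab, and with probability ``p_full`` the entire photon energy is deposited
(photoelectric capture or Compton plus reabsorption, which large monolithic
crystals recover for most multi-interaction events); otherwise a single
Klein-Nishina Compton deposit is recorded and the scattered photon escapes.
``p_full`` is the one free parameter of the detector model; it was fixed
once against the design-A centre-line sensitivity and is frozen for every
other study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .constants import (
    C_MM_PER_NS,
    ELECTRON_REST_KEV,
    ENERGY_CUTOFF_KEV,
    FWHM_TO_SIGMA,
    MU_LYSO,
)
from .geometry import ScannerGeometry, intersect_rays
from .phantoms import EMPTY_PHANTOM, PhantomModel, SourceModel

#: Full-energy deposit probability of the 16 mm monolithic LYSO slab at
#: 511 keV.  Single calibrated constant of the detector model (see module
#: docstring); frozen.
P_FULL_DEFAULT = 0.72


@dataclass(frozen=True)
class PhysicsModel:
    """Knobs of the stand-in physics; defaults are the study conditions."""

    p_full: float = P_FULL_DEFAULT
    acolinearity_fwhm_deg: float = 0.5  # per-axis FWHM of the 180 deg deviation
    positron_range: bool = True  # F-18 range displacement in f18 mode
    #: two-exponential approximation of the F-18 annihilation-distance
    #: distribution in water: weights and scales (mm), mean 0.6 mm
    positron_range_weights: Tuple[float, float] = (0.6, 0.4)
    positron_range_scales_mm: Tuple[float, float] = (0.2, 1.2)
    energy_cutoff_kev: float = ENERGY_CUTOFF_KEV
    mu_lyso: float = MU_LYSO


@dataclass
class SinglesList:
    """Columnar list of crystal interactions (time-ordered unless noted)."""

    decay_id: np.ndarray  # int64
    module: np.ndarray  # int32
    position: np.ndarray  # (N, 3) float32, true interaction point (has DOI)
    energy_true: np.ndarray  # float32, deposited energy keV
    energy: np.ndarray  # float32, measured (blurred) energy keV
    time: np.ndarray  # float64 ns
    n_scatters: np.ndarray  # int16, phantom Compton scatters of the photon

    def __len__(self) -> int:
        return len(self.decay_id)

    def select(self, mask: np.ndarray) -> "SinglesList":
        return SinglesList(
            self.decay_id[mask],
            self.module[mask],
            self.position[mask],
            self.energy_true[mask],
            self.energy[mask],
            self.time[mask],
            self.n_scatters[mask],
        )

    def sort_by_time(self) -> "SinglesList":
        order = np.argsort(self.time, kind="stable")
        return self.select(order)

    @staticmethod
    def concatenate(parts: list["SinglesList"]) -> "SinglesList":
        if not parts:
            return empty_singles()
        return SinglesList(
            *(
                np.concatenate([getattr(p, f) for p in parts])
                for f in (
                    "decay_id",
                    "module",
                    "position",
                    "energy_true",
                    "energy",
                    "time",
                    "n_scatters",
                )
            )
        )


def empty_singles() -> SinglesList:
    return SinglesList(
        np.empty(0, np.int64),
        np.empty(0, np.int32),
        np.empty((0, 3)),
        np.empty(0, np.float32),
        np.empty(0, np.float32),
        np.empty(0, np.float64),
        np.empty(0, np.int16),
    )


# ---------------------------------------------------------------------------
# decay and emission sampling


def sample_decays(
    source: SourceModel,
    duration_s: float,
    rng: np.random.Generator,
    start_time_ns: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson decay stream.

    Returns ``(times_ns, positions)`` with times sorted ascending over
    ``[start, start + duration)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    mean = source.total_activity * duration_s
    n = int(rng.poisson(mean))
    if n == 0:
        return np.empty(0), np.empty((0, 3))
    times = start_time_ns + np.sort(rng.uniform(0.0, duration_s * 1e9, size=n))
    positions = source.sample_positions(n, rng)
    return times, positions


def positron_displacement(
    n: int, physics: PhysicsModel, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic annihilation-point displacement for the F-18 mode."""
    w = np.asarray(physics.positron_range_weights, dtype=np.float64)
    scales = np.asarray(physics.positron_range_scales_mm)
    comp = rng.uniform(size=n) >= w[0] / w.sum()
    r = rng.exponential(scale=1.0, size=n) * scales[comp.astype(int)]
    return r[:, None] * isotropic_directions(n, rng)


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1
    )


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors perpendicular to each row of d."""
    helper = np.zeros_like(d)
    smallest = np.argmin(np.abs(d), axis=1)
    helper[np.arange(len(d)), smallest] = 1.0
    e1 = _cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = _cross(d, e1)
    return e1, e2


def emit_pair(
    positions: np.ndarray,
    mode: str,
    physics: PhysicsModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Photon-pair emission.

    Returns ``(annihilation_points, d1, d2)``.  In ``back_to_back`` mode the
    second photon is the exact antipode of the first and no positron range
    is applied; in ``f18`` mode the annihilation point is displaced by the
    positron range and the pair deviates from 180 degrees by a Gaussian
    acolinearity (0.5 degree FWHM per transverse axis by default).
    """
    n = len(positions)
    annih = np.asarray(positions, dtype=np.float64)
    d1 = isotropic_directions(n, rng)
    if mode == "back_to_back":
        return annih, d1, -d1
    if mode != "f18":
        raise ValueError(f"unknown emission mode {mode!r}")
    if physics.positron_range:
        annih = annih + positron_displacement(n, physics, rng)
    sigma = math.radians(physics.acolinearity_fwhm_deg) * FWHM_TO_SIGMA
    if sigma > 0:
        e1, e2 = _orthonormal_basis(d1)
        a = rng.normal(0.0, sigma, size=n)[:, None]
        b = rng.normal(0.0, sigma, size=n)[:, None]
        d2 = -(d1 + a * e1 + b * e2)
        d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
    else:
        d2 = -d1
    return annih, d1, d2


# ---------------------------------------------------------------------------
# photon transport


def compton_energy(energy_kev: np.ndarray, cos_theta: np.ndarray) -> np.ndarray:
    """Scattered-photon energy E' = E / (1 + (E/511)(1 - cos theta))."""
    return energy_kev / (1.0 + (energy_kev / ELECTRON_REST_KEV) * (1.0 - cos_theta))


def sample_klein_nishina(
    energy_kev: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample the Compton scattering angle cosine from Klein-Nishina.

    Plain rejection sampling against a uniform cos-theta proposal with the
    forward-peak value as envelope; exact for any photon energy.
    """
    n = len(energy_kev)
    out = np.empty(n)
    todo = np.arange(n)
    alpha = energy_kev / ELECTRON_REST_KEV
    while len(todo):
        a = alpha[todo]
        cos_t = rng.uniform(-1.0, 1.0, size=len(todo))
        ratio = 1.0 / (1.0 + a * (1.0 - cos_t))  # E'/E
        f = ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_t**2))
        accept = rng.uniform(0.0, 2.0, size=len(todo)) < f
        out[todo[accept]] = cos_t[accept]
        todo = todo[~accept]
    return out


def rotate_directions(
    d: np.ndarray, cos_theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rotate each direction by theta with a uniform azimuth."""
    e1, e2 = _orthonormal_basis(d)
    sin_theta = np.sqrt(np.maximum(1.0 - cos_theta**2, 0.0))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=len(d))
    return (
        d * cos_theta[:, None]
        + (np.cos(phi) * sin_theta)[:, None] * e1
        + (np.sin(phi) * sin_theta)[:, None] * e2
    )


@dataclass
class PhotonBatch:
    """State of a photon population during transport (structure of arrays)."""

    position: np.ndarray  # (N, 3)
    direction: np.ndarray  # (N, 3) unit
    energy: np.ndarray  # keV
    n_scatters: np.ndarray  # phantom Compton count
    path: np.ndarray  # accumulated path length from annihilation, mm
    alive: np.ndarray  # bool: not absorbed / terminated


def _segment_table(phantom: PhantomModel, O: np.ndarray, D: np.ndarray):
    """Sorted forward boundary parameters and per-segment region indices."""
    pieces = [np.zeros((len(O), 1))]
    for prim in phantom.primitives:
        for iv in prim.intervals(O, D):
            pieces.append(np.maximum(iv, 0.0))
    ts = np.concatenate(pieces, axis=1)
    ts[~np.isfinite(ts)] = 0.0
    ts.sort(axis=1)
    mids = 0.5 * (ts[:, :-1] + ts[:, 1:])
    # region lookup at each segment midpoint
    n, m = mids.shape
    flat = O[:, None, :] + mids[:, :, None] * D[:, None, :]
    region = phantom.region_index(flat.reshape(-1, 3)).reshape(n, m)
    return ts, region


def transport_photons(
    batch: PhotonBatch,
    phantom: PhantomModel,
    rng: np.random.Generator,
    max_interactions: int = 25,
) -> PhotonBatch:
    """Transport photons until they escape the phantom or are absorbed.

    Free paths are sampled from the exponential attenuation law through the
    piecewise-constant material layout; at an interaction the photon is
    either photoelectrically absorbed or Compton-scattered with a
    Klein-Nishina angle.  Photons falling below the energy cutoff are
    terminated in place.
    """
    if phantom.is_empty:
        return batch
    mus = np.array([0.0] + [p.material.mu_511 for p in phantom.primitives])
    cfs = np.array([0.0] + [p.material.compton_fraction for p in phantom.primitives])
    active = batch.alive.copy()
    for _ in range(max_interactions):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        O = batch.position[idx]
        D = batch.direction[idx]
        # cheap analytic escape test first; only the interacting minority
        # pays for the full segment walk
        total = phantom.line_integral_mu(O, D)
        tau = rng.exponential(size=len(idx))
        inter = tau < total
        gi = idx[inter]
        active[idx[~inter]] = False  # escaped
        if len(gi) == 0:
            break
        O, D, tau = O[inter], D[inter], tau[inter]
        ts, region = _segment_table(phantom, O, D)
        seg_mu = mus[region + 1]
        seg_len = np.diff(ts, axis=1)
        seg_tau = seg_mu * seg_len
        cum = np.cumsum(seg_tau, axis=1)
        seg = np.argmax(cum >= tau[:, None], axis=1)
        rows = np.arange(len(gi))
        prev = np.where(seg > 0, cum[rows, np.maximum(seg - 1, 0)], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                seg_tau[rows, seg] > 0,
                (tau - prev) / seg_tau[rows, seg],
                0.0,
            )
        t_i = ts[rows, seg] + frac * seg_len[rows, seg]
        batch.position[gi] = O + t_i[:, None] * D
        batch.path[gi] += t_i
        inter_region = region[rows, seg]
        # photoelectric vs Compton by the local material
        cf = cfs[inter_region + 1]
        compton = rng.uniform(size=len(gi)) < cf
        pe = gi[~compton]
        batch.alive[pe] = False
        active[pe] = False
        ci = gi[compton]
        if len(ci):
            cos_t = sample_klein_nishina(batch.energy[ci], rng)
            new_e = compton_energy(batch.energy[ci], cos_t)
            batch.direction[ci] = rotate_directions(
                batch.direction[ci], cos_t, rng
            )
            batch.energy[ci] = new_e
            batch.n_scatters[ci] += 1
            low = new_e < ENERGY_CUTOFF_KEV
            dead = ci[low]
            batch.alive[dead] = False
            active[dead] = False
    return batch


def _convex_tables(phantom: PhantomModel):
    """Primitive parameter arrays for the numba transport kernel, or None
    when the phantom contains non-convex primitives."""
    from .phantoms import Box, CylinderZ, Sphere
    from . import _kernels

    n = len(phantom.primitives)
    ptype = np.empty(n, dtype=np.int64)
    centers = np.empty((n, 3))
    radius = np.empty(n)
    extra = np.zeros(n)
    half = np.empty(n)
    for i, prim in enumerate(phantom.primitives):
        if isinstance(prim, CylinderZ):
            ptype[i] = _kernels.PRIM_CYLZ
            radius[i] = prim.radius
            half[i] = prim.half_length
        elif isinstance(prim, Sphere):
            ptype[i] = _kernels.PRIM_SPHERE
            radius[i] = prim.radius
            half[i] = 0.0
        elif isinstance(prim, Box):
            ptype[i] = _kernels.PRIM_BOX
            radius[i] = prim.half_sizes[0]
            extra[i] = prim.half_sizes[1]
            half[i] = prim.half_sizes[2]
        else:
            return None
        centers[i] = prim.center
    mu = np.array([p.material.mu_511 for p in phantom.primitives])
    cf = np.array([p.material.compton_fraction for p in phantom.primitives])
    parent = np.asarray(phantom.parents, dtype=np.int64)
    return ptype, centers, radius, extra, half, mu, cf, parent


def transport_fast(
    batch: PhotonBatch,
    phantom: PhantomModel,
    rng: np.random.Generator,
    max_interactions: int = 25,
) -> Optional[PhotonBatch]:
    """Numba transport for convex-primitive phantoms; None if unsupported."""
    if phantom.is_empty:
        return batch
    tables = _convex_tables(phantom)
    if tables is None:
        return None
    from ._kernels import transport_convex

    ptype, centers, radius, extra, half, mu, cf, parent = tables
    energy = batch.energy.astype(np.float64)
    transport_convex(
        batch.position,
        batch.direction,
        energy,
        batch.n_scatters,
        batch.path,
        batch.alive,
        ptype,
        centers,
        radius,
        extra,
        half,
        mu,
        cf,
        parent,
        int(rng.integers(2**31 - 1)),
        ENERGY_CUTOFF_KEV,
        max_interactions,
    )
    batch.energy = energy
    return batch


def survival_filter(
    annih: np.ndarray,
    d: np.ndarray,
    phantom: PhantomModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli unscattered-escape mask using the analytic optical depth.

    Exact importance shortcut for studies that use only unscattered (true)
    events: a photon escapes the phantom without interacting with
    probability ``exp(-integral mu dl)``; all other histories are dropped.
    """
    if phantom.is_empty:
        return np.ones(len(d), dtype=bool)
    depth = _escape_depth(annih, d, phantom)
    return rng.uniform(size=len(d)) < np.exp(-depth)


def _escape_depth(
    annih: np.ndarray, d: np.ndarray, phantom: PhantomModel
) -> np.ndarray:
    """Optical depth to escape; numba fast path for two-level trees."""
    from .phantoms import Box, CylinderZ, Sphere, TorsoPrism
    from . import _kernels

    def _params(prim):
        if isinstance(prim, CylinderZ):
            return _kernels.PRIM_CYLZ, prim.center, prim.radius, 0.0, prim.half_length
        if isinstance(prim, Sphere):
            return _kernels.PRIM_SPHERE, prim.center, prim.radius, 0.0, 0.0
        if isinstance(prim, Box):
            return (
                _kernels.PRIM_BOX,
                prim.center,
                prim.half_sizes[0],
                prim.half_sizes[1],
                prim.half_sizes[2],
            )
        return None

    two_level = all(
        (p == -1 if i == 0 else p == 0) for i, p in enumerate(phantom.parents)
    ) and all(
        isinstance(prim, (CylinderZ, Sphere, Box))
        for prim in phantom.primitives[1:]
    )
    root = phantom.primitives[0] if phantom.primitives else None
    if two_level and isinstance(root, (TorsoPrism, CylinderZ, Sphere, Box)):
        parts = root._parts() if isinstance(root, TorsoPrism) else [root]
        rows = [_params(p) for p in parts]
        crows = [_params(p) for p in phantom.primitives[1:]]
        if all(r is not None for r in rows + crows):
            children = phantom.primitives[1:]
            return _kernels.survival_depth(
                np.ascontiguousarray(annih),
                np.ascontiguousarray(d),
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
                np.array([r[3] for r in rows]),
                np.array([r[4] for r in rows]),
                root.material.mu_511,
                np.array([r[0] for r in crows], dtype=np.int64),
                np.array([r[1] for r in crows]).reshape(len(crows), 3),
                np.array([r[2] for r in crows]),
                np.array([r[3] for r in crows]),
                np.array([r[4] for r in crows]),
                np.array([c.material.mu_511 for c in children]),
            )
    return phantom.line_integral_mu(annih, d)


# ---------------------------------------------------------------------------
# crystal detection


def detect_in_crystal(
    geom: ScannerGeometry,
    decay_id: np.ndarray,
    decay_time_ns: np.ndarray,
    batch: PhotonBatch,
    physics: PhysicsModel,
    rng: np.random.Generator,
) -> SinglesList:
    """Project escaped photons onto the scanner and sample interactions.

    Returns the unsorted singles list of photons that interact in a crystal.
    """
    live = batch.alive
    module, entry, chord = intersect_rays(
        geom, batch.position[live], batch.direction[live]
    )
    hit = module >= 0
    depth = rng.exponential(scale=1.0 / physics.mu_lyso, size=len(module))
    interact = hit & (depth < chord)
    sel_live = np.flatnonzero(live)[interact]
    d = batch.direction[sel_live]
    point = entry[interact] + depth[interact][:, None] * d
    energy = batch.energy[sel_live]
    n = len(sel_live)
    # deposit: full energy with probability p_full, else a single Compton
    # electron deposit (the scattered photon escapes the crystal)
    full = rng.uniform(size=n) < physics.p_full
    deposit = energy.copy()
    if (~full).any():
        cos_t = sample_klein_nishina(energy[~full], rng)
        deposit[~full] = energy[~full] - compton_energy(energy[~full], cos_t)
    # energy resolution: FWHM fraction scales as sqrt(511/E)
    fwhm = geom.config.energy_resolution_frac * np.sqrt(
        ELECTRON_REST_KEV * np.maximum(deposit, 1e-3)
    )
    measured = np.maximum(
        deposit + rng.normal(0.0, 1.0, size=n) * fwhm * FWHM_TO_SIGMA, 1e-3
    )
    flight = (
        batch.path[sel_live]
        + np.linalg.norm(entry[interact] - batch.position[sel_live], axis=1)
        + depth[interact]
    )
    # single-detector jitter sigma = CTR / (2.355 * sqrt(2))
    sigma_t = geom.config.ctr_fwhm * 1e-3 * FWHM_TO_SIGMA / math.sqrt(2.0)
    time = (
        decay_time_ns[sel_live]
        + flight / C_MM_PER_NS
        + rng.normal(0.0, sigma_t, size=n)
    )
    return SinglesList(
        decay_id[sel_live].astype(np.int64),
        module[interact].astype(np.int32),
        point.astype(np.float32),
        deposit.astype(np.float32),
        measured.astype(np.float32),
        time,
        batch.n_scatters[sel_live].astype(np.int16),
    )


# ---------------------------------------------------------------------------
# end-to-end simulation


@dataclass
class Scenario:
    """Bundle of geometry, phantom, source and physics for one acquisition."""

    geometry: ScannerGeometry
    source: SourceModel
    phantom: PhantomModel = field(default_factory=lambda: EMPTY_PHANTOM)
    physics: PhysicsModel = field(default_factory=PhysicsModel)
    name: str = "scenario"


def run_simulation(
    scenario: Scenario,
    duration_s: float,
    rng: np.random.Generator | int,
    trues_only: bool = False,
    chunk_decays: int = 2_000_000,
    max_decays: float = 2e9,
    counters: Optional[Dict[str, int]] = None,
) -> SinglesList:
    """Simulate an acquisition and return the time-ordered singles stream.

    ``trues_only`` activates the unscattered-escape shortcut: scattered and
    absorbed histories are dropped analytically, which reproduces the true
    coincidences exactly and is used where the analysis discards everything
    else.  ``counters`` (optional dict) collects photon bookkeeping tallies.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    expected = scenario.source.total_activity * duration_s
    if expected > max_decays:
        raise ValueError(
            f"{expected:.3g} expected decays exceed the event budget "
            f"({max_decays:.3g}); lower the duration or raise max_decays"
        )
    n_total = int(rng.poisson(scenario.source.total_activity * duration_s))
    parts = []
    tally = {
        "decays": n_total,
        "photons": 2 * n_total,
        "absorbed_phantom": 0,
        "escaped": 0,
        "detected": 0,
        "missed": 0,
    }
    for lo in range(0, n_total, chunk_decays):
        hi = min(lo + chunk_decays, n_total)
        # decay times need not be ordered within a chunk; the final singles
        # stream is sorted globally
        t = rng.uniform(0.0, duration_s * 1e9, size=hi - lo)
        positions = scenario.source.sample_positions(hi - lo, rng)
        ids = np.arange(lo, hi, dtype=np.int64)
        annih, d1, d2 = emit_pair(
            positions, scenario.source.emission_mode, scenario.physics, rng
        )
        pos2 = np.concatenate([annih, annih])
        dirs = np.concatenate([d1, d2])
        ids2 = np.concatenate([ids, ids])
        t2 = np.concatenate([t, t])
        if trues_only:
            keep = survival_filter(pos2, dirs, scenario.phantom, rng)
            batch = PhotonBatch(
                pos2[keep].copy(),
                dirs[keep],
                np.full(keep.sum(), ELECTRON_REST_KEV),
                np.zeros(keep.sum(), dtype=np.int16),
                np.zeros(keep.sum()),
                np.ones(keep.sum(), dtype=bool),
            )
            ids2, t2 = ids2[keep], t2[keep]
            tally["absorbed_phantom"] += int((~keep).sum())
        else:
            batch = PhotonBatch(
                pos2.copy(),
                dirs.copy(),
                np.full(len(ids2), ELECTRON_REST_KEV),
                np.zeros(len(ids2), dtype=np.int16),
                np.zeros(len(ids2)),
                np.ones(len(ids2), dtype=bool),
            )
            fast = transport_fast(batch, scenario.phantom, rng)
            batch = (
                fast
                if fast is not None
                else transport_photons(batch, scenario.phantom, rng)
            )
            tally["absorbed_phantom"] += int((~batch.alive).sum())
        singles = detect_in_crystal(
            geom=scenario.geometry,
            decay_id=ids2,
            decay_time_ns=t2,
            batch=batch,
            physics=scenario.physics,
            rng=rng,
        )
        tally["detected"] += len(singles)
        tally["escaped"] += int(batch.alive.sum())
        if trues_only and len(singles):
            # drop singles whose partner photon was not detected: they can
            # never form a true coincidence (both photons of a decay live in
            # the same chunk), which keeps the stream memory-bounded
            order = np.argsort(singles.decay_id, kind="stable")
            sorted_ids = singles.decay_id[order]
            ids, counts = np.unique(sorted_ids, return_counts=True)
            paired = np.isin(singles.decay_id, ids[counts >= 2])
            singles = singles.select(paired)
        parts.append(singles)
    tally["missed"] = tally["escaped"] - tally["detected"]
    if counters is not None:
        counters.update(tally)
    return SinglesList.concatenate(parts).sort_by_time()
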