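"""Emission sources and attenuating phantoms for the four NEMA set-ups.

Phantoms are ordered lists of geometric primitives (z-axis cylinders,
spheres, axis-aligned boxes and the NEMA torso prism), each carrying a
material and optionally an activity concentration.  Later primitives
override earlier ones in overlaps; in all shipped phantoms the overlap
structure is a containment tree (every primitive lies entirely inside its
``parent``), which makes attenuation line integrals and effective volumes
exact and cheap.

Activity concentrations are given in kBq/mL, which conveniently equals
Bq/mm^3; activities are in Bq, lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import (
    AIR,
    GLASS,
    LUNG,
    Material,
    POLYETHYLENE,
    VACUUM,
    WATER,
)

# ---------------------------------------------------------------------------
# primitives


@dataclass
class Primitive:
    material: Material
    activity_kbq_ml: float = 0.0

    def contains(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def intervals(self, O: np.ndarray, D: np.ndarray) -> List[np.ndarray]:
        """Ray-parameter intervals inside the primitive.

        Returns a list of (N, 2) arrays ``[t_in, t_out]``; empty
        intersections are encoded as ``t_in >= t_out``.
        """
        raise NotImplementedError  # pragma: no cover

    def volume(self) -> float:  # pragma: no cover
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the primitive (rejection from the box)."""
        lo, hi = self.bounding_box()
        out = np.empty((0, 3))
        while len(out) < n:
            m = max(int(1.5 * (n - len(out)) / max(self._fill_fraction(), 1e-3)), 16)
            cand = rng.uniform(lo, hi, size=(m, 3))
            out = np.concatenate([out, cand[self.contains(cand)]])
        return out[:n]

    def bounding_box(self) -> Tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def _fill_fraction(self) -> float:
        lo, hi = self.bounding_box()
        box = float(np.prod(hi - lo))
        return self.volume() / box if box > 0 else 1.0


@dataclass
class CylinderZ(Primitive):
    """Right circular cylinder with axis parallel to z."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 1.0
    half_length: float = 1.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        return (d[:, 0] ** 2 + d[:, 1] ** 2 <= self.radius**2) & (
            np.abs(d[:, 2]) <= self.half_length
        )

    def intervals(self, O, D):
        ox = O[:, 0] - self.center[0]
        oy = O[:, 1] - self.center[1]
        oz = O[:, 2] - self.center[2]
        a = D[:, 0] ** 2 + D[:, 1] ** 2
        b = ox * D[:, 0] + oy * D[:, 1]
        c = ox**2 + oy**2 - self.radius**2
        t0, t1 = _quadratic_interval(a, b, c, inside_for_parallel=c <= 0)
        # clip by the end caps
        tz0, tz1 = _slab_interval(oz, D[:, 2], self.half_length)
        lo = np.maximum(t0, tz0)
        hi = np.minimum(t1, tz1)
        return [np.stack([lo, hi], axis=1)]

    def volume(self) -> float:
        return math.pi * self.radius**2 * 2.0 * self.half_length

    def bounding_box(self):
        r = np.array([self.radius, self.radius, self.half_length])
        return self.center - r, self.center + r


@dataclass
class Sphere(Primitive):
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 1.0

    def contains(self, pts):
        d = pts - self.center
        return np.einsum("ij,ij->i", d, d) <= self.radius**2

    def intervals(self, O, D):
        o = O - self.center
        b = np.einsum("ij,ij->i", o, D)
        c = np.einsum("ij,ij->i", o, o) - self.radius**2
        t0, t1 = _quadratic_interval(np.ones(len(O)), b, c, inside_for_parallel=None)
        return [np.stack([t0, t1], axis=1)]

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    def bounding_box(self):
        r = np.full(3, self.radius)
        return self.center - r, self.center + r


@dataclass
class Box(Primitive):
    """Axis-aligned box."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    half_sizes: np.ndarray = field(default_factory=lambda: np.ones(3))

    def contains(self, pts):
        d = np.abs(pts - self.center)
        return np.all(d <= self.half_sizes, axis=1)

    def intervals(self, O, D):
        lo = np.full(len(O), -np.inf)
        hi = np.full(len(O), np.inf)
        for ax in range(3):
            t0, t1 = _slab_interval(
                O[:, ax] - self.center[ax], D[:, ax], self.half_sizes[ax]
            )
            lo = np.maximum(lo, t0)
            hi = np.minimum(hi, t1)
        return [np.stack([lo, hi], axis=1)]

    def volume(self) -> float:
        return float(8.0 * np.prod(self.half_sizes))

    def bounding_box(self):
        return self.center - self.half_sizes, self.center + self.half_sizes

    def sample(self, n, rng):
        lo, hi = self.bounding_box()
        return rng.uniform(lo, hi, size=(n, 3))


@dataclass
class TorsoPrism(Primitive):
    """NEMA body-phantom cross-section extruded along z.

    The transverse outline is the union of two discs of radius ``ry``
    centred at ``(+-dx, 0)`` and the rectangle ``|x| <= dx, |y| <= ry``
    (two half-circles joined by straight walls; 300 x 230 mm envelope with
    the default ``dx = 35``, ``ry = 115``).
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dx: float = 35.0
    ry: float = 115.0
    half_length: float = 90.0

    def contains(self, pts):
        x = pts[:, 0] - self.center[0]
        y = pts[:, 1] - self.center[1]
        z = pts[:, 2] - self.center[2]
        in_z = np.abs(z) <= self.half_length
        in_rect = (np.abs(x) <= self.dx) & (np.abs(y) <= self.ry)
        in_c1 = (x - self.dx) ** 2 + y**2 <= self.ry**2
        in_c2 = (x + self.dx) ** 2 + y**2 <= self.ry**2
        return in_z & (in_rect | in_c1 | in_c2)

    def _parts(self):
        c1 = np.array([self.center[0] + self.dx, self.center[1], self.center[2]])
        c2 = np.array([self.center[0] - self.dx, self.center[1], self.center[2]])
        return [
            CylinderZ(self.material, 0.0, c1, self.ry, self.half_length),
            CylinderZ(self.material, 0.0, c2, self.ry, self.half_length),
            Box(
                self.material,
                0.0,
                self.center.copy(),
                np.array([self.dx, self.ry, self.half_length]),
            ),
        ]

    def intervals(self, O, D):
        # The three convex parts overlap; consumers must union them
        # (``chord_lengths`` does, and the transport segment walk resolves
        # materials by point lookup).
        parts: List[np.ndarray] = []
        for part in self._parts():
            parts.extend(part.intervals(O, D))
        return parts

    def volume(self) -> float:
        area = math.pi * self.ry**2 + 4.0 * self.dx * self.ry
        return area * 2.0 * self.half_length

    def bounding_box(self):
        h = np.array([self.dx + self.ry, self.ry, self.half_length])
        return self.center - h, self.center + h


def _quadratic_interval(a, b, c, inside_for_parallel):
    """Roots of a t^2 + 2 b t + c = 0 as an [t0, t1] interval.

    Where ``a ~ 0`` (ray parallel to the cylinder axis) the ray is either
    entirely inside (interval = full line) or outside (empty).
    """
    a = np.asarray(a, dtype=np.float64)
    eps = 1e-14
    ok = a > eps
    disc = b * b - a * c
    hit = ok & (disc >= 0.0)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t0 = np.where(hit, (-b - sq) / np.where(ok, a, 1.0), np.inf)
    t1 = np.where(hit, (-b + sq) / np.where(ok, a, 1.0), -np.inf)
    if inside_for_parallel is not None:
        par_in = (~ok) & inside_for_parallel
        t0 = np.where(par_in, -np.inf, t0)
        t1 = np.where(par_in, np.inf, t1)
    return t0, t1


def _slab_interval(o, d, half):
    """Interval where |o + t d| <= half."""
    with np.errstate(divide="ignore", invalid="ignore"):
        moving = np.abs(d) > 1e-14
        ta = np.where(moving, (-half - o) / np.where(moving, d, 1.0), -np.inf)
        tb = np.where(moving, (half - o) / np.where(moving, d, 1.0), np.inf)
    lo = np.minimum(ta, tb)
    hi = np.maximum(ta, tb)
    inside = np.abs(o) <= half
    lo = np.where(moving, lo, np.where(inside, -np.inf, np.inf))
    hi = np.where(moving, hi, np.where(inside, np.inf, -np.inf))
    return lo, hi


def union_length(
    intervals: List[np.ndarray], lo_clip: float = 0.0, hi_clip: float = np.inf
) -> np.ndarray:
    """Length of the union of [lo, hi] interval sets clipped to a range."""
    k = len(intervals)
    stack = np.stack(intervals, axis=1)  # (N, k, 2)
    lo = np.clip(stack[:, :, 0], lo_clip, hi_clip)
    hi = np.clip(stack[:, :, 1], lo_clip, hi_clip)
    order = np.argsort(lo, axis=1)
    lo = np.take_along_axis(lo, order, axis=1)
    hi = np.take_along_axis(hi, order, axis=1)
    total = np.maximum(hi[:, 0] - lo[:, 0], 0.0)
    running = np.maximum(hi[:, 0], lo[:, 0])
    for j in range(1, k):
        start = np.maximum(lo[:, j], running)
        total += np.maximum(hi[:, j] - start, 0.0)
        running = np.maximum(running, hi[:, j])
    return total


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomModel:
    """Priority-ordered primitives with a containment-tree overlap structure.

    ``parents[i]`` is the index of the primitive that entirely contains
    primitive ``i`` (or -1 for a root).  Later primitives override earlier
    ones wherever they overlap.
    """

    primitives: List[Primitive] = field(default_factory=list)
    parents: List[int] = field(default_factory=list)
    name: str = "phantom"

    def __post_init__(self) -> None:
        if self.parents and len(self.parents) != len(self.primitives):
            raise ValueError("parents must match primitives")
        if not self.parents:
            self.parents = [-1] + [0] * (len(self.primitives) - 1)

    @property
    def is_empty(self) -> bool:
        return len(self.primitives) == 0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        inside = np.zeros(len(pts), dtype=bool)
        for prim in self.primitives:
            inside |= prim.contains(pts)
        return inside

    def region_index(self, pts: np.ndarray) -> np.ndarray:
        """Index of the highest-priority primitive containing each point (-1 outside)."""
        idx = np.full(len(pts), -1, dtype=np.int64)
        for i, prim in enumerate(self.primitives):
            idx[prim.contains(pts)] = i
        return idx

    def mu_at(self, pts: np.ndarray) -> np.ndarray:
        idx = self.region_index(pts)
        mus = np.array([0.0] + [p.material.mu_511 for p in self.primitives])
        return mus[idx + 1]

    def compton_fraction_at(self, pts: np.ndarray) -> np.ndarray:
        idx = self.region_index(pts)
        cf = np.array([0.0] + [p.material.compton_fraction for p in self.primitives])
        return cf[idx + 1]

    def chord_lengths(self, O: np.ndarray, D: np.ndarray, t_stop=None) -> np.ndarray:
        """Per-primitive chord length of each forward ray, (N, n_prim)."""
        n = len(O)
        out = np.zeros((n, len(self.primitives)))
        hi_clip = np.inf if t_stop is None else t_stop
        for i, prim in enumerate(self.primitives):
            ivs = prim.intervals(O, D)
            out[:, i] = union_length(ivs, 0.0, hi_clip)
        return out

    def line_integral_mu(self, O: np.ndarray, D: np.ndarray, t_stop=None) -> np.ndarray:
        """Exact optical depth along forward rays using the containment tree."""
        if self.is_empty:
            return np.zeros(len(O))
        chords = self.chord_lengths(O, D, t_stop)
        depth = np.zeros(len(O))
        for i, prim in enumerate(self.primitives):
            mu_parent = (
                0.0
                if self.parents[i] < 0
                else self.primitives[self.parents[i]].material.mu_511
            )
            depth += (prim.material.mu_511 - mu_parent) * chords[:, i]
        return depth

    def effective_volumes(self) -> np.ndarray:
        """Volume of each primitive minus the volume of its children."""
        vols = np.array([p.volume() for p in self.primitives])
        eff = vols.copy()
        for i, parent in enumerate(self.parents):
            if parent >= 0:
                eff[parent] -= vols[i]
        return eff

    def total_activity(self) -> float:
        eff = self.effective_volumes() if self.primitives else np.zeros(0)
        return float(
            sum(
                p.activity_kbq_ml * v
                for p, v in zip(self.primitives, eff)
            )
        )

    def sample_emission(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform-by-activity emission positions over the active regions."""
        eff = self.effective_volumes()
        weights = np.array(
            [p.activity_kbq_ml * v for p, v in zip(self.primitives, eff)]
        )
        if weights.sum() <= 0:
            raise ValueError("phantom has no active region")
        counts = rng.multinomial(n, weights / weights.sum())
        pts = np.empty((n, 3))
        pos = 0
        children = {
            i: [j for j, par in enumerate(self.parents) if par == i]
            for i in range(len(self.primitives))
        }
        for i, cnt in enumerate(counts):
            if cnt == 0:
                continue
            need = cnt
            fill = pos
            while need > 0:
                cand = self.primitives[i].sample(need, rng)
                keep = np.ones(len(cand), dtype=bool)
                for j in children[i]:
                    keep &= ~self.primitives[j].contains(cand)
                cand = cand[keep]
                pts[fill : fill + len(cand)] = cand
                fill += len(cand)
                need -= len(cand)
            pos += cnt
        return pts

    def bounding_box(self):
        if self.is_empty:
            return np.zeros(3), np.zeros(3)
        los, his = zip(*(p.bounding_box() for p in self.primitives))
        return np.min(los, axis=0), np.max(his, axis=0)


EMPTY_PHANTOM = PhantomModel([], [], name="vacuum")


# ---------------------------------------------------------------------------
# sources


@dataclass
class SourceModel:
    """Emitter of annihilation-photon pairs.

    ``back_to_back`` emits exactly antiparallel 511 keV photons from the
    stated geometry; ``f18`` adds the positron-range displacement and the
    acolinearity deviation of a real fluorine-18 source.
    """

    kind: str  # line | point | volume
    emission_mode: str = "back_to_back"
    total_activity: float = 0.0  # Bq
    line_start: Optional[np.ndarray] = None
    line_end: Optional[np.ndarray] = None
    point: Optional[np.ndarray] = None
    phantom: Optional[PhantomModel] = None  # for volume sources
    name: str = "source"

    def __post_init__(self) -> None:
        if self.total_activity < 0:
            raise ValueError("activity must be non-negative")
        if self.kind not in ("line", "point", "volume"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.emission_mode not in ("back_to_back", "f18"):
            raise ValueError(f"unknown emission mode {self.emission_mode!r}")

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "line":
            u = rng.uniform(size=n)[:, None]
            return self.line_start + u * (self.line_end - self.line_start)
        if self.kind == "point":
            return np.broadcast_to(self.point, (n, 3)).copy()
        return self.phantom.sample_emission(n, rng)


# ---------------------------------------------------------------------------
# NEMA set-ups

#: NEMA NU-2 scatter phantom dimensions (mm).
SCATTER_PHANTOM_RADIUS = 101.5
SCATTER_PHANTOM_HALF_LENGTH = 350.0
SCATTER_CHANNEL_RADIUS = 3.2
SCATTER_LINE_OFFSET = 45.0

#: IQ phantom: sphere inner diameters (mm) and their placement circle.
IQ_SPHERE_DIAMETERS = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
IQ_SPHERE_RING_DIAMETER = 114.4
IQ_BACKGROUND_KBQ_ML = 5.3
IQ_INTERIOR_HALF_LENGTH = 90.0
IQ_LUNG_RADIUS = 25.0


def make_sensitivity_source(
    radial_offset: float = 0.0, activity: float = 5e6, length: float = 700.0
) -> SourceModel:
    """70 cm back-to-back line source of the NEMA sensitivity measurement."""
    half = length / 2.0
    return SourceModel(
        kind="line",
        emission_mode="back_to_back",
        total_activity=activity,
        line_start=np.array([radial_offset, 0.0, -half]),
        line_end=np.array([radial_offset, 0.0, half]),
        name=f"sensitivity_line_r{radial_offset:g}",
    )


def make_scatter_phantom(
    activity_concentration: float,
) -> Tuple[PhantomModel, SourceModel]:
    """NEMA NU-2 scatter phantom: 203 mm polyethylene cylinder, 700 mm long,
    with the F-18 line source in a 6.4 mm channel at 45 mm radial offset.

    ``activity_concentration`` is the NEMA figure in kBq/mL: total line
    activity divided by the phantom cylinder volume.
    """
    if activity_concentration < 0:
        raise ValueError("concentration must be non-negative")
    body = CylinderZ(
        POLYETHYLENE,
        0.0,
        np.zeros(3),
        SCATTER_PHANTOM_RADIUS,
        SCATTER_PHANTOM_HALF_LENGTH,
    )
    channel = CylinderZ(
        AIR,
        0.0,
        np.array([SCATTER_LINE_OFFSET, 0.0, 0.0]),
        SCATTER_CHANNEL_RADIUS,
        SCATTER_PHANTOM_HALF_LENGTH,
    )
    phantom = PhantomModel([body, channel], [-1, 0], name="nema_scatter")
    activity = activity_concentration * body.volume()  # kBq/mL == Bq/mm^3
    source = SourceModel(
        kind="line",
        emission_mode="f18",
        total_activity=activity,
        line_start=np.array([SCATTER_LINE_OFFSET, 0.0, -SCATTER_PHANTOM_HALF_LENGTH]),
        line_end=np.array([SCATTER_LINE_OFFSET, 0.0, SCATTER_PHANTOM_HALF_LENGTH]),
        name="scatter_line",
    )
    return phantom, source


def make_point_source(
    position: Sequence[float],
    activity: float = 3.7e6,
    bare: bool = False,
    bore_radius: float = 350.0,
    capillary_outer_diameter: float = 1.8,
    capillary_inner_diameter: float = 0.52,
    capillary_height: float = 0.9,
) -> Tuple[PhantomModel, SourceModel]:
    """F-18 point source in a water droplet inside a glass capillary.

    With ``bare=True`` no surrounding material is modelled (unit-test
    variant).  The capillary dimensions default to the stated glass
    capillary (0.52 mm inner / 1.8 mm outer diameter, 0.9 mm height).
    """
    position = np.asarray(position, dtype=np.float64)
    if np.hypot(position[0], position[1]) >= bore_radius:
        raise ValueError("point source outside the bore")
    source = SourceModel(
        kind="point",
        emission_mode="f18",
        total_activity=activity,
        point=position,
        name="point_source",
    )
    if bare:
        return EMPTY_PHANTOM, source
    glass = CylinderZ(
        GLASS, 0.0, position.copy(), capillary_outer_diameter / 2.0,
        capillary_height / 2.0,
    )
    bore = CylinderZ(
        WATER, 0.0, position.copy(), capillary_inner_diameter / 2.0,
        capillary_height / 2.0,
    )
    droplet = Sphere(WATER, 0.0, position.copy(), 0.25)
    phantom = PhantomModel([glass, bore, droplet], [-1, 0, 1], name="capillary")
    return phantom, source


def nema_point_positions(afov: float) -> List[Tuple[float, float]]:
    """The six NEMA resolution positions (radius, z): radii 10/100/200 mm at
    the axial centre and at three-eighths of the axial FOV."""
    stations = (0.0, 3.0 / 8.0 * afov)
    return [(r, z) for z in stations for r in (10.0, 100.0, 200.0)]


def make_iq_phantom(
    sbr: float,
    background_concentration: float = IQ_BACKGROUND_KBQ_ML,
    torso_shape: str = "nema",
) -> Tuple[PhantomModel, SourceModel]:
    """NEMA image-quality phantom: torso background, cold lung insert and
    six hot spheres at ``sbr`` times the background concentration.

    ``torso_shape`` may be ``"nema"`` (two half-circles joined by straight
    walls) or ``"ellipse"`` (a plain elliptical cylinder of the same
    envelope).
    """
    import warnings

    if sbr not in (4.0, 8.0, 4, 8):
        warnings.warn(f"non-standard sphere-to-background ratio {sbr}")
    if torso_shape == "nema":
        torso: Primitive = TorsoPrism(
            WATER,
            background_concentration,
            np.zeros(3),
            dx=35.0,
            ry=115.0,
            half_length=IQ_INTERIOR_HALF_LENGTH,
        )
    elif torso_shape == "ellipse":
        torso = _EllipticalCylinder(
            WATER,
            background_concentration,
            np.zeros(3),
            150.0,
            115.0,
            IQ_INTERIOR_HALF_LENGTH,
        )
    else:
        raise ValueError(f"unknown torso shape {torso_shape!r}")
    lung = CylinderZ(
        LUNG, 0.0, np.zeros(3), IQ_LUNG_RADIUS, IQ_INTERIOR_HALF_LENGTH
    )
    prims: List[Primitive] = [torso, lung]
    parents = [-1, 0]
    ring_r = IQ_SPHERE_RING_DIAMETER / 2.0
    for i, diam in enumerate(IQ_SPHERE_DIAMETERS):
        ang = math.radians(60.0 * i)
        center = np.array([ring_r * math.cos(ang), ring_r * math.sin(ang), 0.0])
        prims.append(
            Sphere(WATER, sbr * background_concentration, center, diam / 2.0)
        )
        parents.append(0)
    phantom = PhantomModel(prims, parents, name=f"nema_iq_sbr{sbr:g}")
    source = SourceModel(
        kind="volume",
        emission_mode="f18",
        total_activity=phantom.total_activity(),
        phantom=phantom,
        name="iq_volume",
    )
    return phantom, source


@dataclass
class _EllipticalCylinder(Primitive):
    """Elliptical cylinder along z (torso simplification)."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rx: float = 1.0
    ry: float = 1.0
    half_length: float = 1.0

    def contains(self, pts):
        x = (pts[:, 0] - self.center[0]) / self.rx
        y = (pts[:, 1] - self.center[1]) / self.ry
        return (x**2 + y**2 <= 1.0) & (
            np.abs(pts[:, 2] - self.center[2]) <= self.half_length
        )

    def intervals(self, O, D):
        ox = (O[:, 0] - self.center[0]) / self.rx
        oy = (O[:, 1] - self.center[1]) / self.ry
        dxs = D[:, 0] / self.rx
        dys = D[:, 1] / self.ry
        a = dxs**2 + dys**2
        b = ox * dxs + oy * dys
        c = ox**2 + oy**2 - 1.0
        t0, t1 = _quadratic_interval(a, b, c, inside_for_parallel=c <= 0)
        tz0, tz1 = _slab_interval(
            O[:, 2] - self.center[2], D[:, 2], self.half_length
        )
        return [np.stack([np.maximum(t0, tz0), np.minimum(t1, tz1)], axis=1)]

    def volume(self) -> float:
        return math.pi * self.rx * self.ry * 2.0 * self.half_length

    def bounding_box(self):
        h = np.array([self.rx, self.ry, self.half_length])
        return self.center - h, self.center + h
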