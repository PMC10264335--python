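"""Numba inner loops: ray/module intersection and photon transport.

These kernels carry the per-photon arithmetic of the engine.  The module
intersection kernel is the single implementation of the slab geometry (the
vectorised wrapper in :mod:`monopet.geometry` calls it); the transport
kernel handles phantoms whose primitives are convex (z-cylinders, spheres,
axis-aligned boxes) in a containment tree, which covers every shipped
phantom that is transported in full; the trues-only survival kernel
additionally handles a multi-part union root (the torso prism).  Anything
else falls back to the generic numpy path.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# primitive type codes for the transport kernel
PRIM_CYLZ = 0
PRIM_SPHERE = 1
PRIM_BOX = 2  # axis-aligned; half sizes (radius, extra, half) = (hx, hy, hz)


@njit(cache=True, inline="always")
def hit_one(ox, oy, oz, dx, dy, dz, R, thick, half_w, n_az, z0, pitch, ax_w, n_rings):
    """Scalar first-module intersection; returns (module, t_in, chord)."""
    a = dx * dx + dy * dy
    if a < 1e-16:
        return -1, 0.0, 0.0
    b = ox * dx + oy * dy
    c = ox * ox + oy * oy - R * R
    disc = b * b - a * c
    if disc < 0.0:
        return -1, 0.0, 0.0
    t_cyl = (-b + math.sqrt(disc)) / a
    dphi = 2.0 * math.pi / n_az
    phi = math.atan2(oy + t_cyl * dy, ox + t_cyl * dx)
    k0 = int(round(phi / dphi))
    best = np.inf
    mod = -1
    chord = 0.0
    for dk in range(-1, 2):
        k = (k0 + dk) % n_az
        ang = k * dphi
        nx = math.cos(ang)
        ny = math.sin(ang)
        denom = dx * nx + dy * ny
        if denom <= 1e-12:
            continue
        on = ox * nx + oy * ny
        t_in = (R - on) / denom
        if t_in < 0.0 or t_in >= best:
            continue
        px = ox + t_in * dx
        py = oy + t_in * dy
        pz = oz + t_in * dz
        ux = -ny
        uy = nx
        u = px * ux + py * uy
        if abs(u) > half_w:
            continue
        w = pz - z0
        ring = int(math.floor(w / pitch))
        if ring < 0 or ring >= n_rings:
            continue
        if w - ring * pitch > ax_w:
            continue
        t_out = (R + thick - on) / denom
        du = dx * ux + dy * uy
        ou = ox * ux + oy * uy
        if abs(du) > 1e-12:
            t_u = ((half_w if du > 0.0 else -half_w) - ou) / du
        else:
            t_u = np.inf
        zlo = z0 + ring * pitch
        zhi = zlo + ax_w
        if abs(dz) > 1e-12:
            t_z = ((zhi if dz > 0.0 else zlo) - oz) / dz
        else:
            t_z = np.inf
        t_exit = min(t_out, min(t_u, t_z))
        best = t_in
        mod = ring * n_az + k
        chord = max(t_exit - t_in, 0.0)
    return mod, best, chord


@njit(cache=True)
def hit_scanner(O, D, R, thick, half_w, n_az, z0, pitch, ax_w, n_rings):
    """First-module intersection for rays from inside the bore.

    Returns ``(module, entry, chord)``; module -1 where the ray escapes
    axially or passes between modules.  Entry is on the inner face; the
    chord is clipped by the outer face, the side walls and the ring ends.
    """
    n = len(O)
    module = np.full(n, -1, dtype=np.int64)
    entry = np.zeros((n, 3))
    chord = np.zeros(n)
    for i in range(n):
        mod, t_in, ch = hit_one(
            O[i, 0],
            O[i, 1],
            O[i, 2],
            D[i, 0],
            D[i, 1],
            D[i, 2],
            R,
            thick,
            half_w,
            n_az,
            z0,
            pitch,
            ax_w,
            n_rings,
        )
        module[i] = mod
        if mod >= 0:
            entry[i, 0] = O[i, 0] + t_in * D[i, 0]
            entry[i, 1] = O[i, 1] + t_in * D[i, 1]
            entry[i, 2] = O[i, 2] + t_in * D[i, 2]
            chord[i] = ch
    return module, entry, chord


@njit(cache=True, inline="always")
def _axis_slab(o, d, half):
    """[t0, t1] where |o + t d| <= half (single axis)."""
    if abs(d) > 1e-14:
        ta = (-half - o) / d
        tb = (half - o) / d
        if ta > tb:
            ta, tb = tb, ta
        return ta, tb
    if abs(o) <= half:
        return -np.inf, np.inf
    return np.inf, -np.inf


@njit(cache=True, inline="always")
def _prim_interval(ptype, cx, cy, cz, radius, extra, half, ox, oy, oz, dx, dy, dz):
    """Forward [t0, t1] of the ray inside one convex primitive (0,0 if none)."""
    if ptype == PRIM_BOX:
        t0, t1 = _axis_slab(ox - cx, dx, radius)
        ta, tb = _axis_slab(oy - cy, dy, extra)
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        ta, tb = _axis_slab(oz - cz, dz, half)
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        t0 = max(t0, 0.0)
        if t1 <= t0:
            return 0.0, 0.0
        return t0, t1
    if ptype == PRIM_CYLZ:
        rx = ox - cx
        ry = oy - cy
        a = dx * dx + dy * dy
        if a < 1e-14:
            if rx * rx + ry * ry > radius * radius:
                return 0.0, 0.0
            t0 = -np.inf
            t1 = np.inf
        else:
            b = rx * dx + ry * dy
            c = rx * rx + ry * ry - radius * radius
            disc = b * b - a * c
            if disc < 0.0:
                return 0.0, 0.0
            sq = math.sqrt(disc)
            t0 = (-b - sq) / a
            t1 = (-b + sq) / a
        # z caps
        rz = oz - cz
        if abs(dz) > 1e-14:
            ta = (-half - rz) / dz
            tb = (half - rz) / dz
            zlo = min(ta, tb)
            zhi = max(ta, tb)
        elif abs(rz) <= half:
            zlo = -np.inf
            zhi = np.inf
        else:
            return 0.0, 0.0
        t0 = max(t0, zlo)
        t1 = min(t1, zhi)
    else:  # sphere
        rx = ox - cx
        ry = oy - cy
        rz = oz - cz
        b = rx * dx + ry * dy + rz * dz
        c = rx * rx + ry * ry + rz * rz - radius * radius
        disc = b * b - c
        if disc < 0.0:
            return 0.0, 0.0
        sq = math.sqrt(disc)
        t0 = -b - sq
        t1 = -b + sq
    t0 = max(t0, 0.0)
    if t1 <= t0:
        return 0.0, 0.0
    return t0, t1


@njit(cache=True, inline="always")
def _prim_contains(ptype, cx, cy, cz, radius, extra, half, x, y, z):
    if ptype == PRIM_BOX:
        return (
            abs(x - cx) <= radius and abs(y - cy) <= extra and abs(z - cz) <= half
        )
    if ptype == PRIM_CYLZ:
        return (
            (x - cx) ** 2 + (y - cy) ** 2 <= radius * radius
            and abs(z - cz) <= half
        )
    dx = x - cx
    dy = y - cy
    dz = z - cz
    return dx * dx + dy * dy + dz * dz <= radius * radius


@njit(cache=True)
def transport_convex(
    pos,
    dirs,
    energy,
    nscat,
    path,
    alive,
    ptype,
    pcenter,
    pradius,
    pextra,
    phalf,
    pmu,
    pcf,
    parent,
    seed,
    cutoff,
    max_interactions,
):
    """Photon transport through a containment tree of convex primitives.

    Photoelectric absorption vs Klein-Nishina Compton scattering at each
    interaction; terminates below ``cutoff``.  Arrays are modified in
    place; ``alive`` remains True for escaped photons.
    """
    np.random.seed(seed)
    n = len(pos)
    P = len(ptype)
    t0s = np.empty(P)
    t1s = np.empty(P)
    bounds = np.empty(2 * P + 1)
    for i in range(n):
        if not alive[i]:
            continue
        for _ in range(max_interactions):
            ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
            dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
            total_tau = 0.0
            for p in range(P):
                t0, t1 = _prim_interval(
                    ptype[p],
                    pcenter[p, 0],
                    pcenter[p, 1],
                    pcenter[p, 2],
                    pradius[p],
                    pextra[p],
                    phalf[p],
                    ox,
                    oy,
                    oz,
                    dx,
                    dy,
                    dz,
                )
                t0s[p] = t0
                t1s[p] = t1
                mu_eff = pmu[p]
                if parent[p] >= 0:
                    mu_eff -= pmu[parent[p]]
                total_tau += mu_eff * (t1 - t0)
            tau = -math.log(np.random.random())
            if tau >= total_tau:
                break  # escapes the phantom
            # walk the sorted boundaries to locate the interaction
            nb = 1
            bounds[0] = 0.0
            for p in range(P):
                if t1s[p] > t0s[p]:
                    bounds[nb] = t0s[p]
                    bounds[nb + 1] = t1s[p]
                    nb += 2
            bounds[:nb].sort()
            cum = 0.0
            t_int = 0.0
            region = -1
            for j in range(nb - 1):
                lo = bounds[j]
                hi = bounds[j + 1]
                if hi <= lo:
                    continue
                mx = ox + 0.5 * (lo + hi) * dx
                my = oy + 0.5 * (lo + hi) * dy
                mz = oz + 0.5 * (lo + hi) * dz
                reg = -1
                for p in range(P):
                    if _prim_contains(
                        ptype[p],
                        pcenter[p, 0],
                        pcenter[p, 1],
                        pcenter[p, 2],
                        pradius[p],
                        pextra[p],
                        phalf[p],
                        mx,
                        my,
                        mz,
                    ):
                        reg = p
                mu = pmu[reg] if reg >= 0 else 0.0
                seg_tau = mu * (hi - lo)
                if cum + seg_tau >= tau and seg_tau > 0.0:
                    t_int = lo + (tau - cum) / mu
                    region = reg
                    break
                cum += seg_tau
            else:
                break  # numerical corner: treat as escape
            pos[i, 0] = ox + t_int * dx
            pos[i, 1] = oy + t_int * dy
            pos[i, 2] = oz + t_int * dz
            path[i] += t_int
            if np.random.random() >= pcf[region]:
                alive[i] = False  # photoelectric absorption
                break
            # Klein-Nishina angle by rejection
            a = energy[i] / 511.0
            ct = 0.0
            while True:
                ct = 2.0 * np.random.random() - 1.0
                ratio = 1.0 / (1.0 + a * (1.0 - ct))
                f = ratio * ratio * (ratio + 1.0 / ratio - (1.0 - ct * ct))
                if 2.0 * np.random.random() < f:
                    break
            new_e = energy[i] / (1.0 + a * (1.0 - ct))
            # rotate the direction by acos(ct) with uniform azimuth
            st = math.sqrt(max(1.0 - ct * ct, 0.0))
            phi = 2.0 * math.pi * np.random.random()
            # orthonormal basis perpendicular to d
            if abs(dx) <= abs(dy) and abs(dx) <= abs(dz):
                hx, hy, hz = 1.0, 0.0, 0.0
            elif abs(dy) <= abs(dz):
                hx, hy, hz = 0.0, 1.0, 0.0
            else:
                hx, hy, hz = 0.0, 0.0, 1.0
            e1x = dy * hz - dz * hy
            e1y = dz * hx - dx * hz
            e1z = dx * hy - dy * hx
            norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= norm
            e1y /= norm
            e1z /= norm
            e2x = dy * e1z - dz * e1y
            e2y = dz * e1x - dx * e1z
            e2z = dx * e1y - dy * e1x
            ca = math.cos(phi) * st
            sa = math.sin(phi) * st
            dirs[i, 0] = dx * ct + ca * e1x + sa * e2x
            dirs[i, 1] = dy * ct + ca * e1y + sa * e2y
            dirs[i, 2] = dz * ct + ca * e1z + sa * e2z
            energy[i] = new_e
            nscat[i] += 1
            if new_e < cutoff:
                alive[i] = False
                break
    return pos


# ---------------------------------------------------------------------------
# voxel-grid ray traversal and list-mode MLEM


@njit(cache=True, inline="always")
def trace_ray(
    x1, y1, z1, x2, y2, z2, ox, oy, oz, vx, vy, vz, nx, ny, nz,
    idx_buf, w_buf, mid_buf,
):
    """Exact radiological path of the segment p1 -> p2 through the grid.

    Fills ``idx_buf`` (flat C-order voxel index), ``w_buf`` (intersection
    length, mm) and ``mid_buf`` (distance of the segment midpoint from p1,
    mm); returns the number of voxels crossed.
    """
    dx = x2 - x1
    dy = y2 - y1
    dz = z2 - z1
    L = math.sqrt(dx * dx + dy * dy + dz * dz)
    if L <= 0.0:
        return 0
    tmin = 0.0
    tmax = 1.0
    # clip against the grid box
    for ax in range(3):
        if ax == 0:
            p, d, o, v, n = x1, dx, ox, vx, nx
        elif ax == 1:
            p, d, o, v, n = y1, dy, oy, vy, ny
        else:
            p, d, o, v, n = z1, dz, oz, vz, nz
        lo = o
        hi = o + n * v
        if abs(d) > 1e-12:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
        elif p <= lo or p >= hi:
            return 0
    if tmax <= tmin:
        return 0
    t = tmin
    eps = 1e-9
    px = x1 + (t + eps) * dx
    py = y1 + (t + eps) * dy
    pz = z1 + (t + eps) * dz
    ix = int(math.floor((px - ox) / vx))
    iy = int(math.floor((py - oy) / vy))
    iz = int(math.floor((pz - oz) / vz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    step_z = 1 if dz > 0 else -1
    if abs(dx) > 1e-12:
        t_delta_x = vx / abs(dx)
        nxt = ox + (ix + (1 if dx > 0 else 0)) * vx
        t_max_x = (nxt - x1) / dx
    else:
        t_delta_x = np.inf
        t_max_x = np.inf
    if abs(dy) > 1e-12:
        t_delta_y = vy / abs(dy)
        nxt = oy + (iy + (1 if dy > 0 else 0)) * vy
        t_max_y = (nxt - y1) / dy
    else:
        t_delta_y = np.inf
        t_max_y = np.inf
    if abs(dz) > 1e-12:
        t_delta_z = vz / abs(dz)
        nxt = oz + (iz + (1 if dz > 0 else 0)) * vz
        t_max_z = (nxt - z1) / dz
    else:
        t_delta_z = np.inf
        t_max_z = np.inf
    m = 0
    while t < tmax - 1e-12:
        t_next = t_max_x
        if t_max_y < t_next:
            t_next = t_max_y
        if t_max_z < t_next:
            t_next = t_max_z
        if t_next > tmax:
            t_next = tmax
        w = (t_next - t) * L
        if w > 0.0 and 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            idx_buf[m] = (ix * ny + iy) * nz + iz
            w_buf[m] = w
            mid_buf[m] = 0.5 * (t + t_next) * L
            m += 1
        if t_max_x <= t_max_y and t_max_x <= t_max_z:
            ix += step_x
            t_max_x += t_delta_x
        elif t_max_y <= t_max_z:
            iy += step_y
            t_max_y += t_delta_y
        else:
            iz += step_z
            t_max_z += t_delta_z
        t = t_next
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            break
    return m


@njit(cache=True)
def forward_project(P1, P2, ox, oy, oz, vx, vy, vz, nx, ny, nz, x):
    """Line-integral forward projection of image x along each LOR."""
    n = len(P1)
    out = np.zeros(n)
    cap = nx + ny + nz + 4
    idx_buf = np.empty(cap, dtype=np.int64)
    w_buf = np.empty(cap)
    mid_buf = np.empty(cap)
    for i in range(n):
        m = trace_ray(
            P1[i, 0], P1[i, 1], P1[i, 2], P2[i, 0], P2[i, 1], P2[i, 2],
            ox, oy, oz, vx, vy, vz, nx, ny, nz, idx_buf, w_buf, mid_buf,
        )
        acc = 0.0
        for j in range(m):
            acc += w_buf[j] * x[idx_buf[j]]
        out[i] = acc
    return out


@njit(cache=True)
def back_project(P1, P2, ox, oy, oz, vx, vy, vz, nx, ny, nz, y):
    """Adjoint of forward_project."""
    out = np.zeros(nx * ny * nz)
    cap = nx + ny + nz + 4
    idx_buf = np.empty(cap, dtype=np.int64)
    w_buf = np.empty(cap)
    mid_buf = np.empty(cap)
    for i in range(len(P1)):
        m = trace_ray(
            P1[i, 0], P1[i, 1], P1[i, 2], P2[i, 0], P2[i, 1], P2[i, 2],
            ox, oy, oz, vx, vy, vz, nx, ny, nz, idx_buf, w_buf, mid_buf,
        )
        for j in range(m):
            out[idx_buf[j]] += w_buf[j] * y[i]
    return out


@njit(cache=True)
def mlem_iteration(
    P1, P2, tof_center, use_tof, tof_sigma_mm,
    ox, oy, oz, vx, vy, vz, nx, ny, nz, x,
):
    """One list-mode MLEM backprojection pass: returns sum_i w_ij / qbar_i."""
    acc = np.zeros(x.shape)
    cap = nx + ny + nz + 4
    idx_buf = np.empty(cap, dtype=np.int64)
    w_buf = np.empty(cap)
    mid_buf = np.empty(cap)
    inv_two_sigma2 = 0.0
    if use_tof:
        inv_two_sigma2 = 1.0 / (2.0 * tof_sigma_mm * tof_sigma_mm)
    for i in range(len(P1)):
        x1, y1, z1 = P1[i, 0], P1[i, 1], P1[i, 2]
        x2, y2, z2 = P2[i, 0], P2[i, 1], P2[i, 2]
        offset = 0.0
        if use_tof:
            # restrict the traversal to +-3.5 sigma around the TOF estimate
            L = math.sqrt(
                (x2 - x1) ** 2 + (y2 - y1) ** 2 + (z2 - z1) ** 2
            )
            if L <= 0.0:
                continue
            s0 = (tof_center[i] - 3.5 * tof_sigma_mm) / L
            s1 = (tof_center[i] + 3.5 * tof_sigma_mm) / L
            if s0 < 0.0:
                s0 = 0.0
            if s1 > 1.0:
                s1 = 1.0
            if s1 <= s0:
                continue
            offset = s0 * L
            x2 = x1 + s1 * (P2[i, 0] - x1)
            y2 = y1 + s1 * (P2[i, 1] - y1)
            z2 = z1 + s1 * (P2[i, 2] - z1)
            x1 = P1[i, 0] + s0 * (P2[i, 0] - P1[i, 0])
            y1 = P1[i, 1] + s0 * (P2[i, 1] - P1[i, 1])
            z1 = P1[i, 2] + s0 * (P2[i, 2] - P1[i, 2])
        m = trace_ray(
            x1, y1, z1, x2, y2, z2,
            ox, oy, oz, vx, vy, vz, nx, ny, nz, idx_buf, w_buf, mid_buf,
        )
        if m == 0:
            continue
        if use_tof:
            for j in range(m):
                d = mid_buf[j] + offset - tof_center[i]
                w_buf[j] *= math.exp(-d * d * inv_two_sigma2)
        denom = 0.0
        for j in range(m):
            denom += w_buf[j] * x[idx_buf[j]]
        if denom <= 0.0:
            continue
        inv = 1.0 / denom
        for j in range(m):
            acc[idx_buf[j]] += w_buf[j] * inv
    return acc


@njit(cache=True)
def ray_integrals(P1, P2, ox, oy, oz, vx, vy, vz, nx, ny, nz, mu):
    """Radiological path integral of mu between the endpoint pairs."""
    return forward_project(P1, P2, ox, oy, oz, vx, vy, vz, nx, ny, nz, mu)


@njit(cache=True)
def sensitivity_map_kernel(
    gox, goy, goz, gvx, gvy, gvz, gnx, gny, gnz,
    dirs,
    R, thick, half_w, n_az, z0, pitch, ax_w, n_rings, mu_lyso,
    use_att, aox, aoy, aoz, avx, avy, avz, anx, any_, anz, amu,
):
    """Pair-detection probability per voxel, averaged over directions.

    For each voxel centre and each sampled direction, both photons must
    intersect a crystal; the contribution is the product of the
    interaction probabilities along the two chords, attenuated by the
    optional mu-map line integral along the full LOR.
    """
    out = np.zeros(gnx * gny * gnz)
    K = len(dirs)
    cap = anx + any_ + anz + 4
    idx_buf = np.empty(cap, dtype=np.int64)
    w_buf = np.empty(cap)
    mid_buf = np.empty(cap)
    far = 2.0 * (R + thick)
    for ix in range(gnx):
        px = gox + (ix + 0.5) * gvx
        for iy in range(gny):
            py = goy + (iy + 0.5) * gvy
            for iz in range(gnz):
                pz = goz + (iz + 0.5) * gvz
                s = 0.0
                for k in range(K):
                    dx = dirs[k, 0]
                    dy = dirs[k, 1]
                    dz = dirs[k, 2]
                    m1, t1, c1 = hit_one(
                        px, py, pz, dx, dy, dz,
                        R, thick, half_w, n_az, z0, pitch, ax_w, n_rings,
                    )
                    if m1 < 0:
                        continue
                    m2, t2, c2 = hit_one(
                        px, py, pz, -dx, -dy, -dz,
                        R, thick, half_w, n_az, z0, pitch, ax_w, n_rings,
                    )
                    if m2 < 0:
                        continue
                    p = (1.0 - math.exp(-mu_lyso * c1)) * (
                        1.0 - math.exp(-mu_lyso * c2)
                    )
                    if use_att:
                        depth = 0.0
                        m = trace_ray(
                            px - far * dx, py - far * dy, pz - far * dz,
                            px + far * dx, py + far * dy, pz + far * dz,
                            aox, aoy, aoz, avx, avy, avz, anx, any_, anz,
                            idx_buf, w_buf, mid_buf,
                        )
                        for j in range(m):
                            depth += w_buf[j] * amu[idx_buf[j]]
                        p *= math.exp(-depth)
                    s += p
                out[(ix * gny + iy) * gnz + iz] = s / K
    return out


@njit(cache=True)
def survival_depth(
    pos,
    dirs,
    root_ptype,
    root_center,
    root_radius,
    root_extra,
    root_half,
    mu_root,
    ch_ptype,
    ch_center,
    ch_radius,
    ch_extra,
    ch_half,
    ch_mu,
):
    """Optical depth to escape for a two-level phantom tree.

    The root region may be a union of up to a few convex parts (the torso
    prism); children are disjoint convex primitives fully inside the root.
    depth = mu_root * |union(root parts)| + sum_j (mu_j - mu_root) * |child_j|.
    """
    n = len(pos)
    R = len(root_ptype)
    C = len(ch_ptype)
    out = np.empty(n)
    t0s = np.empty(R)
    t1s = np.empty(R)
    for i in range(n):
        ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        for p in range(R):
            t0, t1 = _prim_interval(
                root_ptype[p],
                root_center[p, 0],
                root_center[p, 1],
                root_center[p, 2],
                root_radius[p],
                root_extra[p],
                root_half[p],
                ox,
                oy,
                oz,
                dx,
                dy,
                dz,
            )
            t0s[p] = t0
            t1s[p] = t1
        # union length of the root part intervals (tiny insertion sort)
        for a in range(1, R):
            ka0 = t0s[a]
            ka1 = t1s[a]
            b = a - 1
            while b >= 0 and t0s[b] > ka0:
                t0s[b + 1] = t0s[b]
                t1s[b + 1] = t1s[b]
                b -= 1
            t0s[b + 1] = ka0
            t1s[b + 1] = ka1
        union = 0.0
        running = -1.0
        for p in range(R):
            lo = t0s[p]
            hi = t1s[p]
            if hi <= lo:
                continue
            if lo > running:
                union += hi - lo
                running = hi
            elif hi > running:
                union += hi - running
                running = hi
        depth = mu_root * union
        for c in range(C):
            t0, t1 = _prim_interval(
                ch_ptype[c],
                ch_center[c, 0],
                ch_center[c, 1],
                ch_center[c, 2],
                ch_radius[c],
                ch_extra[c],
                ch_half[c],
                ox,
                oy,
                oz,
                dx,
                dy,
                dz,
            )
            depth += (ch_mu[c] - mu_root) * (t1 - t0)
        out[i] = depth
    return out
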