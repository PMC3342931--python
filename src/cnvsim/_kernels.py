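"""Numba kernels for the lattice Monte Carlo engine.

All kernels operate on flat numpy arrays owned by
:class:`cnvsim.core.SimulationState`.  Conventions:

* the lattice is ``site[x, y, z]`` (int32 cell IDs, 0 = Medium);
* x and y are periodic, z has fixed walls (choroidal base below, outer
  limiting membrane above) — copies and contacts never cross a wall;
* contact energy is summed over the 26-neighborhood with unit weights,
  copy proposals are drawn from the 6-neighborhood;
* center-of-mass bookkeeping keeps *unwrapped* coordinate sums so that
  cells straddling a periodic face have a well-defined COM; spring
  lengths use the minimum-image distance between COMs, in micrometres.

Randomness comes from an explicit xorshift128+ stream (two uint64 words)
so trajectories are bit-reproducible for a given seed regardless of
numpy's global state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# neighborhoods

def _build_offsets():
    off26 = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                off26.append((dx, dy, dz))
    off6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    return (np.array(off26, dtype=np.int64), np.array(off6, dtype=np.int64))


OFF26, OFF6 = _build_offsets()

# ---------------------------------------------------------------------------
# xorshift128+ RNG


@njit(cache=True, inline="always")
def _xs_next(rng):
    s1 = rng[0]
    s0 = rng[1]
    rng[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    rng[1] = s1
    return rng[0] + rng[1]


@njit(cache=True, inline="always")
def _rand_u(rng):
    # 53-bit uniform in [0, 1)
    return (_xs_next(rng) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _randint(rng, n):
    # multiply-shift: unbiased enough for lattice sampling, no division
    return int(((_xs_next(rng) >> np.uint64(32)) * np.uint64(n)) >> np.uint64(32))


def seed_rng(seed):
    """Expand an integer seed into an xorshift128+ state via splitmix64."""
    mask = (1 << 64) - 1
    state = np.empty(2, dtype=np.uint64)
    x = (int(seed) + 0x9E3779B97F4A7C15) & mask
    for i in range(2):
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
        state[i] = np.uint64(z)
        x = (x + 0x9E3779B97F4A7C15) & mask
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def metropolis_accept(d_h, temperature, rng):
    """Boltzmann acceptance: always if ``d_h <= 0``, else exp(-d_h/T)."""
    if d_h <= 0.0:
        return True
    return _rand_u(rng) < np.exp(-d_h / temperature)


# ---------------------------------------------------------------------------
# geometry helpers


@njit(cache=True, inline="always", fastmath=True)
def _ring_min(d, n):
    # minimum-image displacement on a ring of size n
    return d - n * np.floor(d / n + 0.5)


@njit(cache=True, inline="always", fastmath=True)
def _unwrap(coord, ref, n):
    """Image of ``coord`` (voxel units) nearest to ``ref`` on a ring of size n."""
    return ref + _ring_min(coord - ref, n)


@njit(cache=True, inline="always", fastmath=True)
def _com_dist(ax, ay, az, bx, by, bz, nx, ny, voxel_size):
    dx = _ring_min(ax - bx, nx)
    dy = _ring_min(ay - by, ny)
    dz = az - bz
    return np.sqrt(dx * dx + dy * dy + dz * dz) * voxel_size


@njit(cache=True, fastmath=True)
def _spring_energy_links(la, lb, llam, lrest, lact, vol, sx, sy, sz,
                         nx, ny, voxel_size):
    """Total energy of all active springs; links with an empty endpoint count 0."""
    e = 0.0
    for l in range(la.shape[0]):
        if lact[l] == 0:
            continue
        a = la[l]
        b = lb[l]
        if vol[a] == 0 or vol[b] == 0:
            continue
        ax = sx[a] / vol[a]
        ay = sy[a] / vol[a]
        az = sz[a] / vol[a]
        bx = sx[b] / vol[b]
        by = sy[b] / vol[b]
        bz = sz[b] / vol[b]
        d = _com_dist(ax, ay, az, bx, by, bz, nx, ny, voxel_size)
        e += 0.5 * llam[l] * (d - lrest[l]) ** 2
    return e


@njit(cache=True, fastmath=True)
def total_energy_kernel(site, ctype, vol, tvol, frozen, sx, sy, sz,
                        J, lam_vol, surf, tsurf, lsur,
                        la, lb, llam, lrest, lact, voxel_size):
    """Brute-force effective energy: contact + volume + surface + springs.

    The surface term ``lam_surf (S - S_t)^2`` is an interface stabilizer
    (zero stiffness reduces to the plain contact+volume+spring energy).
    """
    nx, ny, nz = site.shape
    e = 0.0
    # contact: each unordered 26-neighbor pair once (13 positive half-offsets)
    for i in range(OFF26.shape[0]):
        dx = OFF26[i, 0]
        dy = OFF26[i, 1]
        dz = OFF26[i, 2]
        if dz < 0 or (dz == 0 and (dy < 0 or (dy == 0 and dx < 0))):
            continue
        for x in range(nx):
            x2 = (x + dx) % nx
            for y in range(ny):
                y2 = (y + dy) % ny
                for z in range(nz):
                    z2 = z + dz
                    if z2 >= nz:
                        continue
                    a = site[x, y, z]
                    b = site[x2, y2, z2]
                    if a != b:
                        e += J[ctype[a], ctype[b]]
    # volume and surface constraints (Medium and frozen material carry none)
    for c in range(1, vol.shape[0]):
        if frozen[c] == 0 and vol[c] > 0:
            dv = vol[c] - tvol[c]
            e += lam_vol * dv * dv
            if lsur[c] > 0.0:
                ds = surf[c] - tsurf[c]
                e += lsur[c] * ds * ds
    e += _spring_energy_links(la, lb, llam, lrest, lact, vol, sx, sy, sz,
                              nx, ny, voxel_size)
    return e


# ---------------------------------------------------------------------------
# delta energy of one index copy

# status codes for a proposed copy
OK = 0
FROZEN_TARGET = 1
FROZEN_SOURCE = 2
SAME_CELL = 3
OUT_OF_DOMAIN = 4


@njit(cache=True, fastmath=True, inline="always")
def _surface_shift(site, s_id, o_id, tx, ty, tz):
    """Face-count changes of the gaining and losing cells when t flips o→s."""
    nx, ny, nz = site.shape
    ds_s = 0
    ds_o = 0
    for k in range(6):
        z2 = tz + OFF6[k, 2]
        if z2 < 0 or z2 >= nz:
            continue
        x2 = tx + OFF6[k, 0]
        if x2 < 0:
            x2 += nx
        elif x2 >= nx:
            x2 -= nx
        y2 = ty + OFF6[k, 1]
        if y2 < 0:
            y2 += ny
        elif y2 >= ny:
            y2 -= ny
        nid = site[x2, y2, z2]
        ds_s += -1 if nid == s_id else 1
        ds_o += 1 if nid == o_id else -1
    return ds_s, ds_o


@njit(cache=True, fastmath=True, inline="always")
def _spring_delta(s_id, o_id, px, py, pz,
                  vol, sx, sy, sz,
                  la, lb, llam, lrest, lact, adj_ptr, adj_idx,
                  nx, ny, voxel_size):
    """Spring-energy change when cell ``s_id`` gains voxel p and ``o_id`` loses it."""
    d_e = 0.0
    # new COM of the gaining cell
    have_s = s_id > 0
    if have_s:
        vs = vol[s_id]
        csx = sx[s_id] / vs
        csy = sy[s_id] / vs
        csz = sz[s_id] / vs
        uxs = _unwrap(px, csx, nx)
        uys = _unwrap(py, csy, ny)
        nsx = (sx[s_id] + uxs) / (vs + 1)
        nsy = (sy[s_id] + uys) / (vs + 1)
        nsz = (sz[s_id] + pz) / (vs + 1)
    else:
        csx = csy = csz = nsx = nsy = nsz = 0.0
    have_o = o_id > 0
    o_dies = False
    if have_o:
        vo = vol[o_id]
        cox = sx[o_id] / vo
        coy = sy[o_id] / vo
        coz = sz[o_id] / vo
        if vo == 1:
            o_dies = True
            nox = cox
            noy = coy
            noz = coz
        else:
            uxo = _unwrap(px, cox, nx)
            uyo = _unwrap(py, coy, ny)
            nox = (sx[o_id] - uxo) / (vo - 1)
            noy = (sy[o_id] - uyo) / (vo - 1)
            noz = (sz[o_id] - pz) / (vo - 1)
    else:
        cox = coy = coz = nox = noy = noz = 0.0

    if have_s:
        for k in range(adj_ptr[s_id], adj_ptr[s_id + 1]):
            l = adj_idx[k]
            if lact[l] == 0:
                continue
            other = lb[l] if la[l] == s_id else la[l]
            if vol[other] == 0:
                continue
            if other == o_id:
                # both endpoints move (or the link dies with o)
                d0 = _com_dist(csx, csy, csz, cox, coy, coz, nx, ny, voxel_size)
                e0 = 0.5 * llam[l] * (d0 - lrest[l]) ** 2
                if o_dies:
                    d_e -= e0
                else:
                    d1 = _com_dist(nsx, nsy, nsz, nox, noy, noz, nx, ny, voxel_size)
                    d_e += 0.5 * llam[l] * (d1 - lrest[l]) ** 2 - e0
                continue
            bx = sx[other] / vol[other]
            by = sy[other] / vol[other]
            bz = sz[other] / vol[other]
            d0 = _com_dist(csx, csy, csz, bx, by, bz, nx, ny, voxel_size)
            d1 = _com_dist(nsx, nsy, nsz, bx, by, bz, nx, ny, voxel_size)
            d_e += 0.5 * llam[l] * ((d1 - lrest[l]) ** 2 - (d0 - lrest[l]) ** 2)
    if have_o:
        for k in range(adj_ptr[o_id], adj_ptr[o_id + 1]):
            l = adj_idx[k]
            if lact[l] == 0:
                continue
            other = lb[l] if la[l] == o_id else la[l]
            if other == s_id:
                continue  # handled above
            if vol[other] == 0:
                continue
            bx = sx[other] / vol[other]
            by = sy[other] / vol[other]
            bz = sz[other] / vol[other]
            d0 = _com_dist(cox, coy, coz, bx, by, bz, nx, ny, voxel_size)
            e0 = 0.5 * llam[l] * (d0 - lrest[l]) ** 2
            if o_dies:
                d_e -= e0
            else:
                d1 = _com_dist(nox, noy, noz, bx, by, bz, nx, ny, voxel_size)
                d_e += 0.5 * llam[l] * (d1 - lrest[l]) ** 2 - e0
    return d_e


@njit(cache=True, fastmath=True)
def delta_energy_kernel(site, ctype, vol, tvol, frozen, sx, sy, sz,
                        J, lam_vol, surf, tsurf, lsur,
                        chem, chem_sat, ec_mask, f0, f1,
                        la, lb, llam, lrest, lact, adj_ptr, adj_idx,
                        voxel_size,
                        svx, svy, svz, tx, ty, tz):
    """ΔH of copying the cell ID at source voxel onto the target voxel.

    Returns ``(d_h, status)``; ``d_h`` is meaningful only when status == OK.
    """
    nx, ny, nz = site.shape
    o_id = site[tx, ty, tz]
    s_id = site[svx, svy, svz]
    if frozen[o_id] == 1:
        return 0.0, FROZEN_TARGET
    if s_id == o_id:
        return 0.0, SAME_CELL
    if frozen[s_id] == 1:
        return 0.0, FROZEN_SOURCE

    d_h = 0.0
    # contact term over the 26-neighborhood of the target voxel
    cto = ctype[o_id]
    cts = ctype[s_id]
    for i in range(OFF26.shape[0]):
        z2 = tz + OFF26[i, 2]
        if z2 < 0 or z2 >= nz:
            continue
        x2 = tx + OFF26[i, 0]
        if x2 < 0:
            x2 += nx
        elif x2 >= nx:
            x2 -= nx
        y2 = ty + OFF26[i, 1]
        if y2 < 0:
            y2 += ny
        elif y2 >= ny:
            y2 -= ny
        nid = site[x2, y2, z2]
        if nid != o_id:
            d_h -= J[cto, ctype[nid]]
        if nid != s_id:
            d_h += J[cts, ctype[nid]]

    # volume constraint
    if s_id > 0:
        dv = vol[s_id] - tvol[s_id]
        d_h += lam_vol * ((dv + 1.0) ** 2 - dv * dv)
    if o_id > 0:
        dv = vol[o_id] - tvol[o_id]
        d_h += lam_vol * ((dv - 1.0) ** 2 - dv * dv)

    # surface-area constraint (6-neighbor faces; walls carry no face)
    if s_id > 0 or o_id > 0:
        ls = lsur[s_id] if s_id > 0 else 0.0
        lo_ = lsur[o_id] if o_id > 0 else 0.0
        if ls > 0.0 or lo_ > 0.0:
            ds_s, ds_o = _surface_shift(site, s_id, o_id, tx, ty, tz)
            if ls > 0.0:
                d0 = surf[s_id] - tsurf[s_id]
                d_h += ls * ((d0 + ds_s) ** 2 - d0 * d0)
            if lo_ > 0.0:
                d0 = surf[o_id] - tsurf[o_id]
                d_h += lo_ * ((d0 + ds_o) ** 2 - d0 * d0)

    # breakable springs via COM shift
    if s_id > 0 or o_id > 0:
        d_h += _spring_delta(s_id, o_id, float(tx), float(ty), float(tz),
                             vol, sx, sy, sz,
                             la, lb, llam, lrest, lact, adj_ptr, adj_idx,
                             nx, ny, voxel_size)

    # contact-inhibited chemotaxis: only the advancing cell responds, and
    # only when the displaced cell is not an endothelial cell
    if s_id > 0 and ec_mask[cto] == 0:
        sat = chem_sat[cts]
        lam0 = chem[cts, 0]
        if lam0 != 0.0:
            dc = f0[tx, ty, tz] - f0[svx, svy, svz]
            # saturable receptor response: the per-step drive is capped
            if dc > sat:
                dc = sat
            elif dc < -sat:
                dc = -sat
            d_h -= lam0 * dc
        lam1 = chem[cts, 1]
        if lam1 != 0.0:
            dc = f1[tx, ty, tz] - f1[svx, svy, svz]
            if dc > sat:
                dc = sat
            elif dc < -sat:
                dc = -sat
            d_h -= lam1 * dc
    return d_h, OK


@njit(cache=True, fastmath=True, inline="always")
def _apply_copy(site, vol, sx, sy, sz, alive, surf, s_id, tx, ty, tz):
    """Commit an accepted copy: site map, volume/COM/surface ledgers."""
    nx, ny, nz = site.shape
    o_id = site[tx, ty, tz]
    ds_s, ds_o = _surface_shift(site, s_id, o_id, tx, ty, tz)
    if s_id > 0:
        surf[s_id] += ds_s
    if o_id > 0:
        surf[o_id] += ds_o
    if s_id > 0:
        cx = sx[s_id] / vol[s_id]
        cy = sy[s_id] / vol[s_id]
        sx[s_id] += _unwrap(float(tx), cx, nx)
        sy[s_id] += _unwrap(float(ty), cy, ny)
        sz[s_id] += float(tz)
        vol[s_id] += 1
    if o_id > 0:
        cx = sx[o_id] / vol[o_id]
        cy = sy[o_id] / vol[o_id]
        sx[o_id] -= _unwrap(float(tx), cx, nx)
        sy[o_id] -= _unwrap(float(ty), cy, ny)
        sz[o_id] -= float(tz)
        vol[o_id] -= 1
        if vol[o_id] == 0:
            alive[o_id] = 0
            sx[o_id] = 0.0
            sy[o_id] = 0.0
            sz[o_id] = 0.0
    site[tx, ty, tz] = s_id


@njit(cache=True, fastmath=True)
def run_mcs_kernel(site, ctype, vol, tvol, frozen, alive, sx, sy, sz,
                   J, lam_vol, surf, tsurf, lsur,
                   temperature, chem, chem_sat, ec_mask, f0, f1,
                   la, lb, llam, lrest, lact, adj_ptr, adj_idx,
                   voxel_size, rng, n_mcs, attempts_per_mcs):
    """Run ``n_mcs`` Monte Carlo steps of Metropolis index-copy dynamics.

    One MCS makes ``attempts_per_mcs`` proposals: a random lattice voxel is
    the copy target and a random 6-neighbor supplies the cell ID.  Returns
    per-MCS acceptance counts.
    """
    nx, ny, nz = site.shape
    nvox = nx * ny * nz
    accepted = np.zeros(n_mcs, dtype=np.int64)
    for m in range(n_mcs):
        for _ in range(attempts_per_mcs):
            r = _randint(rng, nvox)
            tz = r % nz
            r //= nz
            ty = r % ny
            tx = r // ny
            o_id = site[tx, ty, tz]
            if frozen[o_id] == 1:
                continue
            k = _randint(rng, 6)
            svz = tz + OFF6[k, 2]
            if svz < 0 or svz >= nz:
                continue
            svx = tx + OFF6[k, 0]
            if svx < 0:
                svx += nx
            elif svx >= nx:
                svx -= nx
            svy = ty + OFF6[k, 1]
            if svy < 0:
                svy += ny
            elif svy >= ny:
                svy -= ny
            s_id = site[svx, svy, svz]
            if s_id == o_id or frozen[s_id] == 1:
                continue
            d_h, status = delta_energy_kernel(
                site, ctype, vol, tvol, frozen, sx, sy, sz,
                J, lam_vol, surf, tsurf, lsur, chem, chem_sat, ec_mask,
                f0, f1,
                la, lb, llam, lrest, lact, adj_ptr, adj_idx,
                voxel_size, svx, svy, svz, tx, ty, tz)
            if status != OK:
                continue
            if metropolis_accept(d_h, temperature, rng):
                _apply_copy(site, vol, sx, sy, sz, alive, surf,
                            s_id, tx, ty, tz)
                accepted[m] += 1
    return accepted
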