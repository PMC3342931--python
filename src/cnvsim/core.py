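"""Generic lattice Monte Carlo engine (Glazier–Graner–Hogeweg / cellular Potts).

The engine evolves a 3D voxel lattice of generalized cells by Metropolis
index-copy dynamics under an effective energy

``H = Σ_contacts J(τ_a, τ_b)  +  Σ_cells λ_vol (V - V_t)²
    + Σ_active links (λ_link / 2)(ℓ - ℓ_rest)²``

plus a non-conservative contact-inhibited chemotaxis term applied per copy
attempt.  Contact energies follow the convention that *more negative J means
stronger adhesion*; the spring term models cytoskeletally coupled junctions
as breakable linear springs anchored at cell centers of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import OFF6, seed_rng
from .types import EC_MASK, N_TYPES, STALK, TYPE_NAMES


class IntegrityError(RuntimeError):
    """Raised when incremental ledgers disagree with the lattice."""


@dataclass
class EngineParameters:
    """Kinetic and bookkeeping parameters of the Monte Carlo engine.

    Parameters
    ----------
    temperature : float
        Metropolis temperature in contact-energy units; sets the amplitude
        of membrane fluctuations.
    lambda_vol : float
        Volume-constraint stiffness (energy per voxel²).
    lambda_surface : float
        Surface-area constraint stiffness (energy per face²); optional
        per-cell shape regularization (zero by default).
    contact_tension : float
        Baseline interfacial tension γ added to every boundary (2γ per
        cell–cell bond, γ per cell–medium bond).  The adhesion tables are
        offsets from this baseline; γ = 0 reduces the contact term to the
        raw table.
    chemotaxis_saturation : float
        Saturable receptor response: the per-copy concentration difference
        entering the chemotaxis term is clipped to ±this value (infinite =
        linear response).
    mcs_per_hour : float
        Monte Carlo steps per simulated hour; fixes the time calibration.
    link_formation_area : int
        Contact area (voxel faces) at which a junctional pair first forms
        a plastic link.
    link_break_extension_um : float
        A link ruptures when stretched more than this beyond its rest
        length; while the pair stays in contact the link re-forms at the
        new separation, so junctions yield plastically under sustained load
        but resist transient fluctuations in proportion to their stiffness.
    link_persistence_hours : float
        A link whose pair has had zero contact for this long is removed.
    """

    temperature: float = 20.0
    lambda_vol: float = 5.0
    lambda_surface: float = 0.0
    contact_tension: float = 0.0
    chemotaxis_saturation: object = np.inf  # scalar or per-type array
    mcs_per_hour: float = 8.0
    link_formation_area: int = 4
    link_break_extension_um: float = 1.5
    link_persistence_hours: float = 6.0
    copy_neighborhood: int = 6
    contact_neighborhood: int = 26


def _grow(arr, n, fill=0):
    out = np.full(n, fill, dtype=arr.dtype)
    out[: arr.shape[0]] = arr
    return out


class SimulationState:
    """Cell lattice plus all per-cell, per-link and per-field bookkeeping.

    Attributes
    ----------
    site : ndarray of int32, shape (nx, ny, nz)
        Voxel → generalized-cell ID map (0 = Medium).
    ctype, volume, target_volume, frozen, alive, birth_time : ndarray
        Per-cell arrays indexed by cell ID (slot 0 is Medium and unused).
    J : ndarray, shape (8, 8)
        Symmetric contact-energy table by cell type.
    link_lambda_table : ndarray, shape (8, 8)
        Plastic-coupling stiffness per junctional type pair (0 = no link).
    fields : dict of str → ndarray
        Chemical fields aligned with the lattice.
    clock : float
        Simulated time in hours.
    """

    def __init__(self, dims, voxel_size=2.0, params=None, max_cells=64):
        nx, ny, nz = dims
        self.dims = (int(nx), int(ny), int(nz))
        self.voxel_size = float(voxel_size)
        self.params = params or EngineParameters()
        self.site = np.zeros(self.dims, dtype=np.int32)
        n = max_cells + 1
        self.ctype = np.zeros(n, dtype=np.uint8)
        self.volume = np.zeros(n, dtype=np.int64)
        self.target_volume = np.zeros(n, dtype=np.float64)
        self.frozen = np.zeros(n, dtype=np.uint8)
        self.alive = np.zeros(n, dtype=np.uint8)
        self.surface = np.zeros(n, dtype=np.int64)
        self.target_surface = np.zeros(n, dtype=np.float64)
        self.lambda_surface_cell = np.full(
            n, self.params.lambda_surface, dtype=np.float64)
        self.birth_time = np.zeros(n, dtype=np.float64)
        self._sx = np.zeros(n, dtype=np.float64)
        self._sy = np.zeros(n, dtype=np.float64)
        self._sz = np.zeros(n, dtype=np.float64)
        self.n_cells = 0
        self.J = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)
        self.link_lambda_table = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)
        self.chemotaxis = np.zeros((N_TYPES, 2), dtype=np.float64)
        # links
        self.link_a = np.zeros(0, dtype=np.int32)
        self.link_b = np.zeros(0, dtype=np.int32)
        self.link_lambda = np.zeros(0, dtype=np.float64)
        self.link_rest = np.zeros(0, dtype=np.float64)
        self.link_active = np.zeros(0, dtype=np.uint8)
        self.link_last_contact = np.zeros(0, dtype=np.float64)
        self._pair_to_link = {}
        self._adj_ptr = np.zeros(n + 1, dtype=np.int64)
        self._adj_idx = np.zeros(0, dtype=np.int64)
        self.fields = {}
        self.clock = 0.0
        self.events = []
        self.rng = seed_rng(0)
        # per-cell physiology counters used by the retina rules
        self.vegf_low_hours = np.zeros(n, dtype=np.float64)
        self.isolated_hours = np.zeros(n, dtype=np.float64)
        self.death_start = np.full(n, -1.0, dtype=np.float64)
        self.death_target0 = np.zeros(n, dtype=np.float64)

    # -- cell management ----------------------------------------------------

    def new_cell(self, ctype, target_volume=0.0, frozen=False):
        """Allocate a cell slot and return its ID (voxels are added separately)."""
        self.n_cells += 1
        cid = self.n_cells
        if cid >= self.ctype.shape[0]:
            n = max(2 * self.ctype.shape[0], cid + 1)
            for name in ("ctype", "volume", "target_volume", "frozen", "alive",
                         "surface", "target_surface",
                         "birth_time", "_sx", "_sy", "_sz", "vegf_low_hours",
                         "isolated_hours", "death_target0"):
                setattr(self, name, _grow(getattr(self, name), n))
            self.lambda_surface_cell = _grow(
                self.lambda_surface_cell, n,
                fill=self.params.lambda_surface)
            self.death_start = _grow(self.death_start, n, fill=-1.0)
            self._adj_ptr = np.zeros(n + 1, dtype=np.int64)
            self.rebuild_adjacency()
        self.ctype[cid] = ctype
        self.target_volume[cid] = target_volume
        self.lambda_surface_cell[cid] = self.params.lambda_surface
        self.frozen[cid] = 1 if frozen else 0
        self.alive[cid] = 1
        self.birth_time[cid] = self.clock
        return cid

    def paint(self, cid, xs, ys, zs):
        """Claim voxels for a cell, updating volume and COM ledgers."""
        xs = np.asarray(xs, dtype=np.int64)
        ys = np.asarray(ys, dtype=np.int64)
        zs = np.asarray(zs, dtype=np.int64)
        self.site[xs, ys, zs] = cid
        if cid > 0:
            self.volume[cid] += xs.size
            # construction never straddles the periodic seam mid-cell, so raw
            # sums are valid; dynamic updates use unwrapped increments
            self._sx[cid] += xs.sum()
            self._sy[cid] += ys.sum()
            self._sz[cid] += zs.sum()

    def com(self, cid):
        """Center of mass in voxel units (may lie outside [0, n) when wrapped)."""
        v = self.volume[cid]
        if v == 0:
            raise ValueError(f"cell {cid} has no voxels")
        return np.array([self._sx[cid], self._sy[cid], self._sz[cid]]) / v

    def com_um(self, cid):
        return self.com(cid) * self.voxel_size

    def cells_of_type(self, *ctypes):
        ids = np.arange(1, self.n_cells + 1)
        mask = (self.alive[ids] == 1) & np.isin(self.ctype[ids], ctypes)
        return ids[mask]

    # -- audits -------------------------------------------------------------

    def recount_volumes(self):
        return np.bincount(self.site.ravel(), minlength=self.ctype.shape[0])

    def check_integrity(self):
        counts = self.recount_volumes()
        if not np.array_equal(counts[1:self.n_cells + 1],
                              self.volume[1:self.n_cells + 1]):
            raise IntegrityError("volume ledgers disagree with the lattice")

    def recount_surfaces(self):
        """Per-cell surface area in 6-neighbor faces (walls carry no face)."""
        s = self.site
        n = self.ctype.shape[0]
        surf = np.zeros(n, dtype=np.int64)
        for axis in (0, 1):
            rolled = np.roll(s, -1, axis=axis)
            m = s != rolled
            surf += np.bincount(s[m], minlength=n)
            surf += np.bincount(rolled[m], minlength=n)
        m = s[:, :, :-1] != s[:, :, 1:]
        surf += np.bincount(s[:, :, :-1][m], minlength=n)
        surf += np.bincount(s[:, :, 1:][m], minlength=n)
        surf[0] = 0
        return surf

    def init_surfaces(self, set_targets=True):
        """Initialize surface ledgers (and targets) from the lattice."""
        self.surface = self.recount_surfaces()
        if set_targets:
            self.target_surface = self.surface.astype(np.float64).copy()

    def recount_com(self, cid):
        """Brute-force COM respecting periodic wrap (unwraps toward the ledger COM)."""
        xs, ys, zs = np.nonzero(self.site == cid)
        ref = self.com(cid)
        nx, ny, _ = self.dims
        ux = xs - nx * np.round((xs - ref[0]) / nx)
        uy = ys - ny * np.round((ys - ref[1]) / ny)
        return np.array([ux.mean(), uy.mean(), zs.mean()])

    # -- contact ledger -----------------------------------------------------

    def contact_pairs(self):
        """Pairwise contact areas in voxel faces (6-neighborhood).

        Returns a dict mapping ``(a, b)`` with ``a < b`` to the shared face
        count; recomputed from the lattice so it is exact by construction.
        """
        s = self.site
        a_list = []
        b_list = []
        for axis in (0, 1):
            rolled = np.roll(s, -1, axis=axis)
            m = s != rolled
            a_list.append(s[m])
            b_list.append(rolled[m])
        m = s[:, :, :-1] != s[:, :, 1:]
        a_list.append(s[:, :, :-1][m])
        b_list.append(s[:, :, 1:][m])
        a = np.concatenate(a_list).astype(np.int64)
        b = np.concatenate(b_list).astype(np.int64)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        key = lo * (self.n_cells + 1) + hi
        uniq, counts = np.unique(key, return_counts=True)
        n1 = self.n_cells + 1
        return {(int(k // n1), int(k % n1)): int(c)
                for k, c in zip(uniq, counts)}

    def contact_area(self, a, b, pairs=None):
        if pairs is None:
            pairs = self.contact_pairs()
        return pairs.get((min(a, b), max(a, b)), 0)

    def type_contact_matrix(self, pairs=None):
        """Total contact area between every pair of cell types (voxel faces)."""
        if pairs is None:
            pairs = self.contact_pairs()
        m = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)
        for (a, b), area in pairs.items():
            ta, tb = self.ctype[a], self.ctype[b]
            m[ta, tb] += area
            if ta != tb:
                m[tb, ta] += area
        return m

    # -- links --------------------------------------------------------------

    def rebuild_adjacency(self):
        n = self.ctype.shape[0]
        act = np.nonzero(self.link_active)[0]
        ends = np.concatenate([self.link_a[act], self.link_b[act]]).astype(np.int64)
        link_ids = np.concatenate([act, act])
        order = np.argsort(ends, kind="stable")
        counts = np.bincount(ends, minlength=n) if ends.size else \
            np.zeros(n, dtype=np.int64)
        ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        self._adj_ptr = ptr
        self._adj_idx = link_ids[order]

    def add_link(self, a, b, lam, rest):
        key = (min(a, b), max(a, b))
        if key in self._pair_to_link and self.link_active[self._pair_to_link[key]]:
            raise ValueError(f"link {key} already exists")
        self.link_a = np.append(self.link_a, np.int32(a))
        self.link_b = np.append(self.link_b, np.int32(b))
        self.link_lambda = np.append(self.link_lambda, float(lam))
        self.link_rest = np.append(self.link_rest, float(rest))
        self.link_active = np.append(self.link_active, np.uint8(1))
        self.link_last_contact = np.append(self.link_last_contact, self.clock)
        self._pair_to_link[key] = self.link_active.shape[0] - 1

    def link_length(self, l):
        nx, ny, _ = self.dims
        a, b = self.link_a[l], self.link_b[l]
        ca, cb = self.com(a), self.com(b)
        d = ca - cb
        d[0] -= nx * np.round(d[0] / nx)
        d[1] -= ny * np.round(d[1] / ny)
        return float(np.linalg.norm(d) * self.voxel_size)

    def active_links(self):
        return np.nonzero(self.link_active)[0]

    # -- energies -----------------------------------------------------------

    def effective_J(self):
        """Contact table including the baseline interfacial tension."""
        g = self.params.contact_tension
        if g == 0.0:
            return self.J
        Jeff = self.J + 2.0 * g
        Jeff[0, :] -= g
        Jeff[:, 0] -= g
        Jeff[0, 0] = self.J[0, 0]
        return Jeff

    def total_energy(self, check=True):
        """Full effective energy (contact + volume + springs); the ΔH oracle."""
        if check:
            self.check_integrity()
        return float(_kernels.total_energy_kernel(
            self.site, self.ctype, self.volume, self.target_volume,
            self.frozen, self._sx, self._sy, self._sz,
            self.effective_J(), self.params.lambda_vol,
            self.surface, self.target_surface, self.lambda_surface_cell,
            self.link_a, self.link_b, self.link_lambda, self.link_rest,
            self.link_active, self.voxel_size))

    def delta_energy(self, source_voxel, target_voxel):
        """ΔH of copying the cell at ``source_voxel`` onto ``target_voxel``.

        The two voxels must be 6-neighbors.  Raises ``ValueError`` for a
        non-neighbor pair and ``FrozenTargetError`` when the target voxel
        belongs to frozen material.
        """
        sv = np.asarray(source_voxel, dtype=np.int64)
        tv = np.asarray(target_voxel, dtype=np.int64)
        nx, ny, nz = self.dims
        d = sv - tv
        d[0] = (d[0] + nx // 2) % nx - nx // 2
        d[1] = (d[1] + ny // 2) % ny - ny // 2
        if not any(np.array_equal(d, o) for o in OFF6):
            raise ValueError("source and target voxels are not copy neighbors")
        f0, f1 = self._chemo_fields()
        d_h, status = _kernels.delta_energy_kernel(
            self.site, self.ctype, self.volume, self.target_volume,
            self.frozen, self._sx, self._sy, self._sz,
            self.effective_J(), self.params.lambda_vol,
            self.surface, self.target_surface, self.lambda_surface_cell,
            self.chemotaxis, self._chem_sat_vector(),
            EC_MASK, f0, f1,
            self.link_a, self.link_b, self.link_lambda, self.link_rest,
            self.link_active, self._adj_ptr, self._adj_idx,
            self.voxel_size,
            sv[0], sv[1], sv[2], tv[0], tv[1], tv[2])
        if status == _kernels.FROZEN_TARGET:
            raise FrozenTargetError("target voxel belongs to frozen material")
        if status == _kernels.SAME_CELL:
            return 0.0
        if status == _kernels.FROZEN_SOURCE:
            raise FrozenTargetError("source cell is frozen")
        return float(d_h)

    def _chem_sat_vector(self):
        sat = self.params.chemotaxis_saturation
        if np.isscalar(sat):
            return np.full(N_TYPES, float(sat))
        return np.asarray(sat, dtype=np.float64)

    def _chemo_fields(self):
        zero = None
        f0 = self.fields.get("RPE_VEGF")
        f1 = self.fields.get("Short_VEGF")
        if f0 is None or f1 is None:
            zero = np.zeros(self.dims, dtype=np.float64)
        return (f0 if f0 is not None else zero,
                f1 if f1 is not None else zero)

    # -- dynamics -----------------------------------------------------------

    def attempts_per_mcs(self):
        """One attempt per non-frozen voxel per MCS."""
        n = self.n_cells + 1
        frozen_vox = int(self.volume[:n][self.frozen[:n] == 1].sum())
        return int(np.prod(self.dims)) - frozen_vox

    def run_mcs(self, n_mcs):
        """Advance ``n_mcs`` Monte Carlo steps; returns per-MCS acceptance counts.

        Simulated time advances by ``n_mcs / mcs_per_hour`` hours.
        """
        if n_mcs < 0:
            raise ValueError("n_mcs must be non-negative")
        if n_mcs == 0:
            return np.zeros(0, dtype=np.int64)
        f0, f1 = self._chemo_fields()
        accepted = _kernels.run_mcs_kernel(
            self.site, self.ctype, self.volume, self.target_volume,
            self.frozen, self.alive, self._sx, self._sy, self._sz,
            self.effective_J(), self.params.lambda_vol,
            self.surface, self.target_surface, self.lambda_surface_cell,
            self.params.temperature,
            self.chemotaxis, self._chem_sat_vector(),
            EC_MASK, f0, f1,
            self.link_a, self.link_b, self.link_lambda, self.link_rest,
            self.link_active, self._adj_ptr, self._adj_idx,
            self.voxel_size, self.rng, int(n_mcs), self.attempts_per_mcs())
        self.clock += n_mcs / self.params.mcs_per_hour
        return accepted

    def attempt_index_copy(self):
        """Make a single random copy attempt; returns True when accepted."""
        before = self.run_mcs_single_attempt()
        return before

    def run_mcs_single_attempt(self):
        f0, f1 = self._chemo_fields()
        accepted = _kernels.run_mcs_kernel(
            self.site, self.ctype, self.volume, self.target_volume,
            self.frozen, self.alive, self._sx, self._sy, self._sz,
            self.effective_J(), self.params.lambda_vol,
            self.surface, self.target_surface, self.lambda_surface_cell,
            self.params.temperature,
            self.chemotaxis, self._chem_sat_vector(),
            EC_MASK, f0, f1,
            self.link_a, self.link_b, self.link_lambda, self.link_rest,
            self.link_active, self._adj_ptr, self._adj_idx,
            self.voxel_size, self.rng, 1, 1)
        return bool(accepted[0])

    # -- link maintenance ---------------------------------------------------

    def _com_table(self):
        """COMs of all cell slots in voxel units (zero-volume cells → 0)."""
        v = np.maximum(self.volume, 1).astype(np.float64)
        return np.stack([self._sx / v, self._sy / v, self._sz / v], axis=1)

    def _pair_lengths(self, a_ids, b_ids, coms):
        nx, ny, _ = self.dims
        d = coms[a_ids] - coms[b_ids]
        d[:, 0] -= nx * np.round(d[:, 0] / nx)
        d[:, 1] -= ny * np.round(d[:, 1] / ny)
        return np.linalg.norm(d, axis=1) * self.voxel_size

    def maintain_links(self, pairs=None):
        """Create, stretch-test and expire plastic links.

        A link forms between a junctional type pair (nonzero entry of
        ``link_lambda_table``) once their contact area reaches the formation
        threshold, with rest length equal to the current COM separation.
        A link is removed when stretched past its rupture extension or when
        its pair has had no contact for the persistence window.
        """
        if pairs is None:
            pairs = self.contact_pairs()
        p = self.params
        coms = self._com_table()
        act = self.active_links()
        if act.size:
            a = self.link_a[act].astype(np.int64)
            b = self.link_b[act].astype(np.int64)
            dead = (self.volume[a] == 0) | (self.volume[b] == 0)
            touching = np.array(
                [self.contact_area(int(x), int(y), pairs) > 0
                 for x, y in zip(a, b)])
            self.link_last_contact[act[touching]] = self.clock
            expired = (~touching) & (
                self.clock - self.link_last_contact[act]
                >= p.link_persistence_hours)
            lengths = self._pair_lengths(a, b, coms)
            broken = lengths > self.link_rest[act] + p.link_break_extension_um
            self.link_active[act[dead | expired | broken]] = 0
        # formation over contacting junctional pairs
        new_a, new_b, new_lam, new_rest = [], [], [], []
        for (a, b), area in pairs.items():
            if a == 0 or area < p.link_formation_area:
                continue
            lam = self.link_lambda_table[self.ctype[a], self.ctype[b]]
            if lam <= 0:
                continue
            l = self._pair_to_link.get((a, b))
            if l is not None and self.link_active[l]:
                continue
            if self.alive[a] == 0 or self.alive[b] == 0:
                continue
            rest = self._pair_distance(a, b)
            if l is not None:
                # reuse the slot for a re-formed link
                self.link_lambda[l] = lam
                self.link_rest[l] = rest
                self.link_active[l] = 1
                self.link_last_contact[l] = self.clock
            else:
                new_a.append(a)
                new_b.append(b)
                new_lam.append(lam)
                new_rest.append(rest)
        if new_a:
            base = self.link_active.shape[0]
            self.link_a = np.concatenate(
                [self.link_a, np.array(new_a, dtype=np.int32)])
            self.link_b = np.concatenate(
                [self.link_b, np.array(new_b, dtype=np.int32)])
            self.link_lambda = np.concatenate([self.link_lambda, new_lam])
            self.link_rest = np.concatenate([self.link_rest, new_rest])
            self.link_active = np.concatenate(
                [self.link_active, np.ones(len(new_a), dtype=np.uint8)])
            self.link_last_contact = np.concatenate(
                [self.link_last_contact,
                 np.full(len(new_a), self.clock)])
            for i, (a, b) in enumerate(zip(new_a, new_b)):
                self._pair_to_link[(a, b)] = base + i
        self.rebuild_adjacency()

    def _pair_distance(self, a, b):
        nx, ny, _ = self.dims
        d = self.com(a) - self.com(b)
        d[0] -= nx * np.round(d[0] / nx)
        d[1] -= ny * np.round(d[1] / ny)
        return float(np.linalg.norm(d) * self.voxel_size)

    # -- mitosis ------------------------------------------------------------

    def split_cell(self, cell_id, rng):
        """Divide a stalk cell by a random plane through its COM.

        Returns ``(cell_id, new_cell_id)``.  The daughter keeps type Stalk
        and each half receives half the parent's target volume.
        """
        if self.frozen[cell_id]:
            raise ValueError("cannot split a frozen cell")
        if self.ctype[cell_id] != STALK:
            raise ValueError("only stalk cells divide")
        xs, ys, zs = np.nonzero(self.site == cell_id)
        nx, ny, _ = self.dims
        ref = self.com(cell_id)
        ux = xs - nx * np.round((xs - ref[0]) / nx)
        uy = ys - ny * np.round((ys - ref[1]) / ny)
        uz = zs.astype(np.float64)
        rel = np.stack([ux - ux.mean(), uy - uy.mean(), uz - uz.mean()], axis=1)
        for _ in range(64):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            side = rel @ n > 0
            if 0 < side.sum() < side.size:
                break
        else:
            raise RuntimeError("could not find a dividing plane")
        half_target = self.target_volume[cell_id] / 2.0
        new_id = self.new_cell(STALK, target_volume=half_target)
        # move the positive side to the daughter
        self.site[xs[side], ys[side], zs[side]] = new_id
        self.volume[new_id] = int(side.sum())
        self._sx[new_id] = ux[side].sum()
        self._sy[new_id] = uy[side].sum()
        self._sz[new_id] = uz[side].sum()
        self.volume[cell_id] -= int(side.sum())
        self._sx[cell_id] -= ux[side].sum()
        self._sy[cell_id] -= uy[side].sum()
        self._sz[cell_id] -= uz[side].sum()
        self.target_volume[cell_id] = half_target
        # surface ledgers: recount locally; targets scale as V^(2/3)
        surf = self.recount_surfaces()
        self.surface[cell_id] = surf[cell_id]
        self.surface[new_id] = surf[new_id]
        factor = 0.5 ** (2.0 / 3.0)
        self.target_surface[new_id] = self.target_surface[cell_id] * factor
        self.target_surface[cell_id] *= factor
        self.lambda_surface_cell[new_id] = self.lambda_surface_cell[cell_id]
        self.rebuild_adjacency()
        return cell_id, new_id

    # -- misc ---------------------------------------------------------------

    def log_event(self, kind, **info):
        self.events.append({"time": self.clock, "kind": kind, **info})

    def summary(self):
        ids = np.arange(1, self.n_cells + 1)
        live = ids[self.alive[ids] == 1]
        counts = {TYPE_NAMES[t]: int((self.ctype[live] == t).sum())
                  for t in range(1, N_TYPES)}
        return {"clock": self.clock, "cells": counts,
                "links": int(self.link_active.sum())}


class FrozenTargetError(RuntimeError):
    """A copy proposal targeted (or sourced from) frozen material."""
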