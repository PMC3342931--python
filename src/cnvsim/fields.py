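"""Reaction–diffusion fields: oxygen, two VEGF-A pools and MMP.

Four scalar fields live on the cell lattice:

* **Oxygen** (mmHg): delivered by choriocapillaris endothelium, consumed by
  photoreceptor inner segments, held at a fixed tension at the outer
  limiting membrane.  RPE oxygen uptake is zero by construction.
* **RPE_VEGF** (molecules/voxel): the long-diffusing survival and
  chemotactic factor secreted by the RPE and taken up by endothelial cells.
* **Short_VEGF**: the short-diffusing autocrine factor secreted by all
  endothelial cells; its diffusion length is one fifth that of RPE-derived
  VEGF at equal decay rate, i.e. a 25-fold smaller diffusion constant.
* **MMP**: a near-immobile protease secreted by the tip cell that degrades
  Bruch's-membrane blocks.

Two solvers are provided: an explicit Euler step (``step_field``) with the
usual 3D stability bound dt ≤ h²/6D, and a quasi-static steady-state solve
used by the simulation loop, where field relaxation (minutes) is fast
relative to cell rearrangement (hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .types import BRM, MEDIUM, RPE, STALK, TIP, VASCULAR


@dataclass
class ScalarField:
    """One diffusing, decaying chemical aligned with the cell lattice.

    Parameters
    ----------
    name : str
        One of Oxygen, RPE_VEGF, Short_VEGF, MMP.
    grid : ndarray
        Concentration per voxel (mmHg for oxygen, molecules/voxel otherwise).
    D : float
        Diffusion constant, µm²/h.
    k_decay : float
        First-order decay rate, 1/h.
    secretion : dict
        Cell type → secretion rate (amount/voxel/h).
    uptake : dict
        Cell type → first-order uptake rate (1/h) applied in that type's voxels.
    boundary : tuple
        Per-axis condition: "periodic", "noflux" or ("dirichlet", lo, hi);
        x and y are periodic, z carries the retina's wall conditions.
    """

    name: str
    grid: np.ndarray
    D: float
    k_decay: float
    voxel_size: float = 2.0
    secretion: dict = field(default_factory=dict)
    uptake: dict = field(default_factory=dict)
    boundary: tuple = ("periodic", "periodic", "noflux")

    def stability_dt(self):
        if self.D == 0:
            return np.inf
        return self.voxel_size ** 2 / (6.0 * self.D)


def _ends(bc):
    """Normalize a per-axis boundary spec to (lo_end, hi_end).

    Each end is "noflux" or ("dirichlet", value); the whole axis may also be
    "periodic".  Accepted axis forms: "periodic", "noflux",
    ("dirichlet", vlo, vhi) and ("mixed", lo_spec, hi_spec).
    """
    if bc == "periodic":
        return None
    if bc == "noflux":
        return ("noflux", "noflux")
    if bc[0] == "dirichlet":
        return (("dirichlet", bc[1]), ("dirichlet", bc[2]))
    if bc[0] == "mixed":
        return (bc[1], bc[2])
    raise ValueError(f"unknown boundary spec {bc!r}")


def _laplacian(grid, boundary, h):
    """7-point Laplacian / h² honoring the per-axis boundary conditions."""
    lap = np.zeros_like(grid)
    for axis in range(3):
        bc = boundary[axis]
        if bc == "periodic":
            lap += np.roll(grid, 1, axis) + np.roll(grid, -1, axis) - 2 * grid
        else:
            lo_end, hi_end = _ends(bc)
            up = np.roll(grid, -1, axis)
            dn = np.roll(grid, 1, axis)
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = 0
            hi[axis] = -1
            if lo_end == "noflux":
                dn[tuple(lo)] = grid[tuple(lo)]
            else:
                # Dirichlet value on the wall face: ghost = 2 v - c_edge
                dn[tuple(lo)] = 2 * lo_end[1] - grid[tuple(lo)]
            if hi_end == "noflux":
                up[tuple(hi)] = grid[tuple(hi)]
            else:
                up[tuple(hi)] = 2 * hi_end[1] - grid[tuple(hi)]
            lap += up + dn - 2 * grid
    return lap / h ** 2


def source_maps(fld, site, ctype):
    """Secretion (amount/voxel/h) and uptake (1/h) maps for the current lattice."""
    type_map = ctype[site]
    sec = np.zeros(site.shape, dtype=np.float64)
    upt = np.zeros(site.shape, dtype=np.float64)
    for t, rate in fld.secretion.items():
        sec[type_map == t] = rate
    for t, rate in fld.uptake.items():
        upt[type_map == t] = rate
    return sec, upt


def step_field(fld, site, ctype, dt):
    """Advance one explicit Euler step of secretion–uptake–diffusion–decay.

    Refuses an unstable time step, reporting the admissible bound.  Dirichlet
    faces are re-clamped to their wall value after the step; concentrations
    stay non-negative.
    """
    bound = fld.stability_dt()
    if dt > bound:
        raise ValueError(
            f"dt={dt} violates the explicit stability bound dt <= h²/(6D) "
            f"= {bound:.6g} for field {fld.name}")
    sec, upt = source_maps(fld, site, ctype)
    c = fld.grid
    dc = sec - (fld.k_decay + upt) * c
    if fld.D > 0:
        dc = dc + fld.D * _laplacian(c, fld.boundary, fld.voxel_size)
    c = c + dt * dc
    np.maximum(c, 0.0, out=c)
    # Dirichlet walls are clamped at the cell *face* by the ghost convention:
    # (c_edge + c_ghost)/2 equals the wall value identically.
    fld.grid = c
    return fld


class SteadyStateSolver:
    """Quasi-static solver for ``(k + u(x)) c − D ∇²c = s(x)`` on the lattice.

    The constant part of the operator is assembled once; voxel-wise uptake
    enters the diagonal at solve time.  Solves use conjugate gradients warm
    started from the previous solution.
    """

    def __init__(self, dims, voxel_size, D, k_decay, boundary):
        self.dims = tuple(dims)
        self.h = voxel_size
        self.D = D
        self.k = k_decay
        self.boundary = boundary
        n = int(np.prod(dims))
        lap = self._assemble_laplacian()
        self.base = (sp.identity(n, format="csr") * k_decay - D * lap).tocsr()
        self.bc_rhs = self._dirichlet_rhs()
        self._x0 = None

    def _ops_1d(self, n, bc):
        main = np.full(n, -2.0)
        off = np.ones(n - 1)
        L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
        if bc == "periodic":
            L[0, n - 1] = 1.0
            L[n - 1, 0] = 1.0
        else:
            lo_end, hi_end = _ends(bc)
            # noflux: mirror ghost; dirichlet: ghost = 2 v − c_edge (rhs part)
            L[0, 0] = -1.0 if lo_end == "noflux" else -3.0
            L[n - 1, n - 1] = -1.0 if hi_end == "noflux" else -3.0
        return sp.csr_matrix(L)

    def _assemble_laplacian(self):
        nx, ny, nz = self.dims
        Lx = self._ops_1d(nx, self.boundary[0])
        Ly = self._ops_1d(ny, self.boundary[1])
        Lz = self._ops_1d(nz, self.boundary[2])
        Ix, Iy, Iz = (sp.identity(n, format="csr") for n in (nx, ny, nz))
        lap = (sp.kron(sp.kron(Lx, Iy), Iz)
               + sp.kron(sp.kron(Ix, Ly), Iz)
               + sp.kron(sp.kron(Ix, Iy), Lz))
        return (lap / self.h ** 2).tocsr()

    def _dirichlet_rhs(self):
        rhs = np.zeros(self.dims)
        for axis, bc in enumerate(self.boundary):
            if bc == "periodic":
                continue
            lo_end, hi_end = _ends(bc)
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = 0
            hi[axis] = -1
            if lo_end != "noflux":
                rhs[tuple(lo)] += 2 * self.D * lo_end[1] / self.h ** 2
            if hi_end != "noflux":
                rhs[tuple(hi)] += 2 * self.D * hi_end[1] / self.h ** 2
        return rhs.ravel()

    def solve(self, secretion, uptake=None):
        """Steady concentration for the given secretion/uptake maps."""
        b = secretion.ravel() + self.bc_rhs
        A = self.base
        if uptake is not None and np.any(uptake):
            A = A + sp.diags(uptake.ravel())
        x, info = spla.cg(A, b, x0=self._x0, rtol=1e-6, atol=1e-12,
                          maxiter=5000)
        if info != 0:
            x = spla.spsolve(A.tocsc(), b)
        np.maximum(x, 0.0, out=x)
        self._x0 = x
        return x.reshape(self.dims)


# ---------------------------------------------------------------------------
# analytic 1D oxygen profile


@dataclass
class OxygenGeometry1D:
    """Layered 1D geometry for the steady transretinal oxygen profile.

    Depth ``x`` runs from the choriocapillaris face of Bruch's membrane to
    the outer limiting membrane (OLM).  Only the photoreceptor inner
    segments consume oxygen (uniform volumetric rate); BrM, RPE and the
    outer segments are purely conductive, and RPE uptake is zero.
    """

    L_BrM: float = 6.0
    L_RPE: float = 12.0
    L_OS: float = 30.0
    L_IS: float = 24.0
    L_OLM: float = 67.0  # from the RPE side of BrM
    P_cc: float = 80.0
    P_olm: float = 20.0
    Q_pis: float = 0.0  # consumption / diffusivity, mmHg/µm²

    def __post_init__(self):
        for name in ("L_BrM", "L_RPE", "L_OS", "L_IS", "L_OLM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        stack = self.L_RPE + self.L_OS + self.L_IS
        if abs(stack - self.L_OLM) > 0.1 * self.L_OLM:
            raise ValueError("layer stack does not fit the OLM location")

    @property
    def span(self):
        return self.L_BrM + self.L_OLM

    @property
    def x_rpe(self):
        """Depth of the RPE–POS interface (reported as 'PO₂ at the RPE')."""
        return self.L_BrM + self.L_RPE

    @property
    def pis_interval(self):
        a = self.L_BrM + self.L_RPE + self.L_OS
        return a, a + self.L_IS


class OxygenProfile:
    """Closed-form steady profile; callable at any depth in [0, span] µm."""

    def __init__(self, geom):
        if geom.P_cc < 0 or geom.P_olm < 0 or geom.Q_pis < 0:
            raise ValueError("pressures and consumption must be non-negative")
        self.geom = geom
        a, b = geom.pis_interval
        S = geom.span
        self._a, self._b, self._S = a, b, S
        self._GS = self._G(S)
        self.slope = (geom.P_olm - geom.P_cc - geom.Q_pis * self._GS) / S
        self.physical = self(np.linspace(0.0, S, 256)).min() >= 0.0

    def _G(self, x):
        a, b = self._a, self._b
        x = np.asarray(x, dtype=np.float64)
        inner = np.clip(x, a, b) - a
        return inner ** 2 / 2.0 + (b - a) * np.clip(x - b, 0.0, None)

    def __call__(self, x):
        g = self.geom
        return g.P_cc + self.slope * np.asarray(x, dtype=np.float64) \
            + g.Q_pis * self._G(x)

    @property
    def p_rpe(self):
        return float(self(self.geom.x_rpe))


def oxygen_profile_1d(geom):
    """Steady-state piecewise oxygen profile with Dirichlet ends.

    Linear in BrM/RPE/POS, quadratic across the uniformly consuming inner
    segments, flux-continuous at every interface.  The returned profile is
    flagged non-physical when any pressure drops below zero.
    """
    return OxygenProfile(geom)


class InfeasibleTarget(ValueError):
    """Requested oxygen tension not reachable with non-negative consumption."""


def calibrate_pis_uptake(geom, target_p_rpe):
    """Inner-segment consumption for which PO₂ at the RPE equals the target.

    Inverts the closed-form profile; a target above the zero-consumption
    (linear) value would need a negative rate and raises
    :class:`InfeasibleTarget`.
    """
    zero = OxygenGeometry1D(**{**geom.__dict__, "Q_pis": 0.0})
    x_r = geom.x_rpe
    S = geom.span
    linear_val = geom.P_cc + (geom.P_olm - geom.P_cc) * x_r / S
    prof0 = OxygenProfile(zero)
    GS = prof0._G(S)
    # P_rpe(q) = linear_val − q·GS·x_r/S  (G(x_r) = 0: the sink lies deeper)
    q = (linear_val - target_p_rpe) * S / (x_r * GS)
    if q < -1e-12:
        raise InfeasibleTarget(
            f"target {target_p_rpe} mmHg exceeds the zero-consumption value "
            f"{linear_val:.3f} mmHg")
    return float(max(q, 0.0))


# ---------------------------------------------------------------------------
# MMP-driven degradation of Bruch's membrane


def degrade_brm(mmp_grid, state, rate, dt, rng):
    """Convert BrM voxels to Medium with probability ``rate·c_MMP·dt`` each.

    Frozen-block volume ledgers are updated; this is the only process that
    removes Bruch's-membrane material.  Returns the number of voxels removed.
    """
    if rate < 0:
        raise ValueError("degradation rate must be non-negative")
    brm_mask = state.ctype[state.site] == BRM
    if not brm_mask.any():
        return 0
    p = np.clip(rate * mmp_grid * dt, 0.0, 1.0)
    hit = brm_mask & (rng.random(state.site.shape) < p)
    n = int(hit.sum())
    if n == 0:
        return 0
    ids = np.unique(state.site[hit])
    state.site[hit] = MEDIUM
    # ledger update: recompute sums for affected blocks (cheap, few blocks)
    for cid in ids:
        vox = np.nonzero(state.site == cid)
        state.volume[cid] = vox[0].size
        if vox[0].size == 0:
            state.alive[cid] = 0
            state._sx[cid] = state._sy[cid] = state._sz[cid] = 0.0
        else:
            state._sx[cid] = vox[0].sum()
            state._sy[cid] = vox[1].sum()
            state._sz[cid] = vox[2].sum()
    # degradation reshapes the frozen blocks; refresh their surface ledgers
    surf = state.recount_surfaces()
    state.surface[ids] = surf[ids]
    return n


def default_field_params(voxel_size=2.0):
    """Default kinetic parameters for the four fields.

    Diffusion lengths: RPE-derived VEGF 50 µm, short-diffusing VEGF 10 µm
    (5× ratio, hence 25× in D at the shared decay rate), MMP under one
    voxel.  Secretion rates are normalized so the intact-retina steady
    RPE-derived VEGF concentration is ≈1 at the RPE apical face.
    """
    k = 0.5  # 1/h shared decay
    return {
        "RPE_VEGF": {"D": 2500.0 * k, "k_decay": k,
                     "secretion": {RPE: 1.0},
                     "uptake": {VASCULAR: 3.0, STALK: 3.0, TIP: 3.0},
                     "boundary": ("periodic", "periodic", "noflux")},
        "Short_VEGF": {"D": 100.0 * k, "k_decay": k,
                       "secretion": {VASCULAR: 1.0, STALK: 1.0, TIP: 1.0},
                       "uptake": {},
                       "boundary": ("periodic", "periodic", "noflux")},
        "MMP": {"D": 0.5 * k * voxel_size ** 2, "k_decay": k,
                "secretion": {TIP: 1.0},
                "uptake": {},
                "boundary": ("periodic", "periodic", "noflux")},
        "Oxygen": {"D": 7200.0, "k_decay": 0.0,
                   "secretion": {}, "uptake": {},
                   "boundary": ("periodic", "periodic", "noflux")},
    }
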