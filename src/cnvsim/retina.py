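"""Scene construction and cell-fate rules for the outer-retina model.

The simulated tissue is a stack (bottom to top along z):

1. a choroidal margin of Medium hosting a sheet-like choriocapillaris (CC)
   network of Vascular cells adhered to the choroidal face of Bruch's
   membrane, with lumen gaps;
2. a 6 µm Bruch's membrane (BrM) slab of small frozen blocks;
3. a confluent monolayer of ~12 µm cuboidal RPE cells, junctionally linked
   to each other and to BrM;
4. columnar photoreceptors: paired outer-segment (30 µm) and inner-segment
   (24 µm) compartments joined by junctional links, four columns per RPE
   cell.

The outer limiting membrane (OLM) is the fixed upper wall; x and y are
periodic.  Cell-fate rules: a seeded endothelial tip cell secretes MMP for
24 h and then differentiates into a stalk cell; stalk cells grow with local
RPE-derived VEGF unless contact-inhibited by other endothelial cells and
divide at a doubling volume; endothelial cells die below a survival
threshold of RPE-derived VEGF; RPE cells die only when they have lost both
their lateral RPE contact and their BrM contact for a sustained period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EngineParameters, SimulationState

#: default interface-stabilizing surface-constraint stiffness of the tissue
RETINA_LAMBDA_SURFACE = 0.0
RETINA_CONTACT_TENSION = 25.0
RETINA_TEMPERATURE = 10.0
RETINA_CHEM_SATURATION = 0.005  # stalk receptor cap; the tip is uncapped
from .fields import ScalarField, SteadyStateSolver, default_field_params, source_maps
from .scenarios import scenario_by_id, scenario_parameters
from .types import (BRM, MEDIUM, PIS, POS, RPE, STALK, TIP, VASCULAR,
                    EC_TYPES, N_TYPES)


@dataclass
class RetinalGeometry:
    """Layer thicknesses (µm) and lattice discretization."""

    lateral_um: float = 48.0
    voxel_size: float = 2.0
    L_BrM: float = 6.0
    L_RPE: float = 12.0
    L_OS: float = 30.0
    L_IS: float = 24.0
    L_OLM: float = 67.0
    choroid_um: float = 12.0
    rpe_cell_um: float = 12.0
    photoreceptor_um: float = 6.0  # column footprint edge
    cc_tile_um: float = 8.0
    brm_block_um: float = 8.0
    P_cc: float = 80.0
    P_olm: float = 20.0

    def __post_init__(self):
        stack = self.L_RPE + self.L_OS + self.L_IS
        if abs(stack - self.L_OLM) > 0.1 * self.L_OLM:
            raise ValueError("stacked layers do not fit the OLM location")
        if self.lateral_um < 4 * self.rpe_cell_um:
            raise ValueError("lateral extent cannot host a confluent monolayer")

    def vox(self, um):
        n = um / self.voxel_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"{um} µm is not a whole number of voxels")
        return int(round(n))

    @property
    def dims(self):
        n_lat = self.vox(self.lateral_um)
        nz = (self.vox(self.choroid_um) + self.vox(self.L_BrM)
              + self.vox(self.L_RPE) + self.vox(self.L_OS) + self.vox(self.L_IS))
        return (n_lat, n_lat, nz)

    @property
    def z_layers(self):
        """z voxel ranges per layer: dict name → (z0, z1) half-open."""
        z = 0
        out = {}
        for name, um in (("choroid", self.choroid_um), ("BrM", self.L_BrM),
                         ("RPE", self.L_RPE), ("POS", self.L_OS),
                         ("PIS", self.L_IS)):
            n = self.vox(um)
            out[name] = (z, z + n)
            z += n
        return out


@dataclass
class CellTypeCatalog:
    """Per-type behavioral parameters of the generalized cells.

    Chemotaxis strengths are per (type, field) with fields ordered
    (RPE-derived VEGF, short-diffusing VEGF); endothelial cells respond to
    both, the choriocapillaris only to the short-diffusing pool.
    """

    chemotaxis_stalk_rpe_vegf: float = 45000.0
    chemotaxis_tip_rpe_vegf: float = 50000.0
    chemotaxis_ec_short_vegf: float = 100.0
    stalk_target_volume: int = 64          # voxels (≈8 µm cell at 2 µm voxel)
    stalk_growth_rate: float = 18.0         # voxels/h per unit VEGF
    growth_pressure_margin: float = 4.0     # max target-volume lead (voxels)
    growth_inhibition_threshold: float = 0.75  # EC-contact surface fraction
    ec_survival_fraction: float = 0.1      # of the intact apical VEGF level
    ec_grace_hours: float = 6.0
    rpe_grace_hours: float = 12.0
    death_ramp_hours: float = 6.0
    tip_lifetime_hours: float = 24.0
    mmp_degradation_rate: float = 1.0      # 1/(concentration·h)
    cc_coverage_gap_mod: int = 3           # every third CC tile is a lumen gap
    # surface elasticity: epithelium and photoreceptors hold their shapes
    # tightly; endothelial cells are loose and deformable (mesenchymal)
    ec_surface_lambda: float = 0.05
    ec_surface_slack: float = 2.0
    epithelial_surface_slack: float = 1.05

    def chemotaxis_table(self):
        chem = np.zeros((N_TYPES, 2), dtype=np.float64)
        chem[STALK] = (self.chemotaxis_stalk_rpe_vegf,
                       self.chemotaxis_ec_short_vegf)
        chem[TIP] = (self.chemotaxis_tip_rpe_vegf,
                     self.chemotaxis_ec_short_vegf)
        chem[VASCULAR] = (0.0, self.chemotaxis_ec_short_vegf)
        return chem

    @property
    def stalk_doubling_volume(self):
        return 2 * self.stalk_target_volume


class ConstructionError(RuntimeError):
    pass


def _tile_range(n, size):
    if n % size:
        raise ConstructionError(f"lateral extent {n} not a multiple of {size}")
    return range(0, n, size)


def build_retina(geometry, catalog, scenario, rng, params=None):
    """Construct the intact retina for one adhesion scenario.

    Returns a ready :class:`SimulationState` with cells, junctional links
    and fields initialized to their intact-tissue steady states.
    """
    if isinstance(scenario, int):
        scenario = scenario_by_id(scenario)
    geom = geometry
    nx, ny, nz = geom.dims
    layers = geom.z_layers
    if params is None:
        params = EngineParameters(
            temperature=RETINA_TEMPERATURE,
            lambda_surface=RETINA_LAMBDA_SURFACE,
            contact_tension=RETINA_CONTACT_TENSION,
            chemotaxis_saturation=RETINA_CHEM_SATURATION)
    if np.isscalar(params.chemotaxis_saturation):
        # the tip is the specialized invasive phenotype: unsaturated response
        sat = np.full(N_TYPES, float(params.chemotaxis_saturation))
        sat[TIP] = np.inf
        params.chemotaxis_saturation = sat
    state = SimulationState((nx, ny, nz), voxel_size=geom.voxel_size,
                            params=params, max_cells=4096)
    J, lam = scenario_parameters(scenario)
    state.J = J
    state.link_lambda_table = lam
    state.chemotaxis = catalog.chemotaxis_table()
    state.scenario = scenario
    state.geometry = geom
    state.catalog = catalog
    h = geom.voxel_size

    # --- choriocapillaris: sheet of Vascular tiles with lumen gaps ----------
    cz0, cz1 = layers["choroid"]
    cc_size = geom.vox(geom.cc_tile_um)
    cc_z0 = cz1 - geom.vox(8.0)  # 8 µm tall CC lumen wall under BrM
    gap_mod = catalog.cc_coverage_gap_mod
    offset = int(rng.integers(gap_mod))
    for i, x0 in enumerate(_tile_range(nx, cc_size)):
        for j, y0 in enumerate(_tile_range(ny, cc_size)):
            if (2 * i + j + offset) % gap_mod == 0:
                continue  # lumen gap (Medium)
            cid = state.new_cell(VASCULAR)
            xs, ys, zs = np.meshgrid(np.arange(x0, x0 + cc_size),
                                     np.arange(y0, y0 + cc_size),
                                     np.arange(cc_z0, cz1), indexing="ij")
            state.paint(cid, xs.ravel(), ys.ravel(), zs.ravel())
            state.target_volume[cid] = state.volume[cid]

    # --- Bruch's membrane: frozen blocks ------------------------------------
    bz0, bz1 = layers["BrM"]
    bs = geom.vox(geom.brm_block_um)
    for x0 in _tile_range(nx, bs):
        for y0 in _tile_range(ny, bs):
            cid = state.new_cell(BRM, frozen=True)
            xs, ys, zs = np.meshgrid(np.arange(x0, x0 + bs),
                                     np.arange(y0, y0 + bs),
                                     np.arange(bz0, bz1), indexing="ij")
            state.paint(cid, xs.ravel(), ys.ravel(), zs.ravel())
            state.target_volume[cid] = state.volume[cid]

    # --- RPE monolayer -------------------------------------------------------
    rz0, rz1 = layers["RPE"]
    rpe_size = geom.vox(geom.rpe_cell_um)
    for x0 in _tile_range(nx, rpe_size):
        for y0 in _tile_range(ny, rpe_size):
            cid = state.new_cell(RPE)
            xs, ys, zs = np.meshgrid(np.arange(x0, x0 + rpe_size),
                                     np.arange(y0, y0 + rpe_size),
                                     np.arange(rz0, rz1), indexing="ij")
            state.paint(cid, xs.ravel(), ys.ravel(), zs.ravel())
            state.target_volume[cid] = state.volume[cid]

    # --- photoreceptor columns: POS below PIS --------------------------------
    pr = geom.vox(geom.photoreceptor_um)
    for lname, ctype_ in (("POS", POS), ("PIS", PIS)):
        z0, z1 = layers[lname]
        for x0 in _tile_range(nx, pr):
            for y0 in _tile_range(ny, pr):
                cid = state.new_cell(ctype_)
                xs, ys, zs = np.meshgrid(np.arange(x0, x0 + pr),
                                         np.arange(y0, y0 + pr),
                                         np.arange(z0, z1), indexing="ij")
                state.paint(cid, xs.ravel(), ys.ravel(), zs.ravel())
                state.target_volume[cid] = state.volume[cid]

    # audit: the RPE monolayer must be confluent over BrM
    state.check_integrity()

    # --- junctional links from initial contacts ------------------------------
    state.maintain_links()
    state.init_surfaces()  # surface targets = intact shapes
    ids = np.arange(1, state.n_cells + 1)
    # quiescent tissue (including the CC endothelium) holds its shape;
    # only activated ECs (tip/stalk) are made mesenchymal when they appear
    state.target_surface[ids] = state.surface[ids] * \
        catalog.epithelial_surface_slack

    # --- fields ---------------------------------------------------------------
    _init_fields(state, geom)
    catalog.ec_survival_threshold = (
        catalog.ec_survival_fraction * rpe_apical_vegf(state))
    state.tip_seeded = False
    return state


def _init_fields(state, geom):
    """Create the four fields and solve their intact steady states."""
    fp = default_field_params(geom.voxel_size)
    dims = state.dims
    state.field_defs = {}
    state.solvers = {}
    for name, p in fp.items():
        boundary = p["boundary"]
        if name == "Oxygen":
            boundary = ("periodic", "periodic",
                        ("mixed", "noflux", ("dirichlet", geom.P_olm)))
        fobj = ScalarField(name=name, grid=np.zeros(dims), D=p["D"],
                           k_decay=p["k_decay"], voxel_size=geom.voxel_size,
                           secretion=dict(p["secretion"]),
                           uptake=dict(p["uptake"]), boundary=boundary)
        state.field_defs[name] = fobj
        state.solvers[name] = SteadyStateSolver(dims, geom.voxel_size,
                                                p["D"], p["k_decay"], boundary)
    update_fields(state)


#: oxygen exchange rate clamping vascular voxels toward the CC tension (1/h)
OXYGEN_EXCHANGE = 50.0
#: uniform oxygen consumption by inner segments (mmHg/h), calibrated so the
#: intact profile passes ~65 mmHg at the RPE when the CC is at 80 mmHg
PIS_OXYGEN_UPTAKE = 6.0


def update_fields(state):
    """Quasi-static update: solve each field to steady state on the lattice."""
    for name, fobj in state.field_defs.items():
        sec, upt = source_maps(fobj, state.site, state.ctype)
        if name == "Oxygen":
            vasc = np.isin(state.ctype[state.site], EC_TYPES)
            upt = upt + OXYGEN_EXCHANGE * vasc
            sec = sec + OXYGEN_EXCHANGE * state.geometry.P_cc * vasc
            sec = sec - PIS_OXYGEN_UPTAKE * (state.ctype[state.site] == PIS)
        grid = state.solvers[name].solve(sec, upt)
        fobj.grid = grid
        state.fields[name] = grid


def rpe_apical_vegf(state):
    """Mean RPE-derived VEGF in the voxel plane just above the RPE layer."""
    z0, z1 = state.geometry.z_layers["RPE"]
    return float(state.fields["RPE_VEGF"][:, :, z1].mean())


# ---------------------------------------------------------------------------
# cell-fate operations


class PlacementError(RuntimeError):
    pass


def seed_tip_cell(state, location=None):
    """Convert one CC vascular cell into the (single) MMP-secreting tip cell.

    ``location`` is a lattice coordinate inside the CC layer; by default the
    vascular cell nearest the lateral domain center is used.  Seeding twice,
    or at a site with no CC cell, is an error.
    """
    if getattr(state, "tip_seeded", False):
        raise PlacementError("single-tip protocol: a tip cell was already seeded")
    vasc = state.cells_of_type(VASCULAR)
    if location is None:
        nx, ny, _ = state.dims
        center = np.array([nx / 2.0, ny / 2.0])
        coms = np.array([state.com(c)[:2] for c in vasc])
        d = coms - center
        d -= np.round(d / np.array([nx, ny])) * np.array([nx, ny])
        cid = int(vasc[np.argmin((d ** 2).sum(axis=1))])
    else:
        cid = int(state.site[tuple(location)])
        if cid == 0 or state.ctype[cid] != VASCULAR:
            raise PlacementError("no CC cell at the requested location")
    state.ctype[cid] = TIP
    state.birth_time[cid] = state.clock
    # activated phenotype: loose, deformable surface
    cat = state.catalog
    state.lambda_surface_cell[cid] = cat.ec_surface_lambda
    state.target_surface[cid] = cat.ec_surface_slack * 6.0 * \
        float(state.volume[cid]) ** (2.0 / 3.0)
    state.tip_seeded = True
    state.log_event("tip_seeded", cell=cid)
    return state


def differentiate_tips(state):
    """Tip cells older than their 24 h lifetime become stalk cells.

    Differentiation ends MMP secretion (only tip cells secrete MMP)."""
    life = state.catalog.tip_lifetime_hours
    for cid in state.cells_of_type(TIP):
        if state.clock - state.birth_time[cid] >= life:
            state.ctype[cid] = STALK
            state.log_event("tip_differentiated", cell=cid)
    return state


def _mean_field_per_cell(state, name):
    grid = state.fields[name]
    flat = state.site.ravel()
    sums = np.bincount(flat, weights=grid.ravel(),
                       minlength=state.ctype.shape[0])
    vols = np.maximum(state.volume, 1)
    return sums[: state.ctype.shape[0]] / vols


def _start_death(state, cid, cause):
    state.death_start[cid] = state.clock
    state.death_target0[cid] = state.target_volume[cid]
    if not hasattr(state, "death_cause"):
        state.death_cause = {}
    state.death_cause[int(cid)] = cause
    state.log_event("death_started", cell=int(cid), cause=cause)


def update_survival(state, dt=1.0, pairs=None):
    """Apply the death rules and advance target-volume death ramps.

    * endothelial cells (CC, stalk, tip) die after the grace period when
      their mean RPE-derived VEGF stays below the survival threshold;
    * RPE cells die only when they have had neither lateral RPE contact nor
      BrM contact for the grace period;
    * dying cells ramp their target volume to zero over the ramp window and
      are removed when their last voxel disappears.
    """
    if pairs is None:
        pairs = state.contact_pairs()
    cat = state.catalog
    mean_vegf = _mean_field_per_cell(state, "RPE_VEGF")
    # contact presence per cell and type
    has_rpe_contact = set()
    has_brm_contact = set()
    for (a, b), _area in pairs.items():
        ta, tb = state.ctype[a], state.ctype[b]
        if ta == RPE and tb == RPE:
            has_rpe_contact.add(a)
            has_rpe_contact.add(b)
        if ta == RPE and tb == BRM:
            has_brm_contact.add(a)
        if tb == RPE and ta == BRM:
            has_brm_contact.add(b)
    for cid in np.arange(1, state.n_cells + 1):
        if state.alive[cid] == 0 or state.frozen[cid]:
            continue
        t = state.ctype[cid]
        dying = state.death_start[cid] >= 0
        if not dying:
            if t in EC_TYPES:
                if mean_vegf[cid] < cat.ec_survival_threshold:
                    state.vegf_low_hours[cid] += dt
                else:
                    state.vegf_low_hours[cid] = 0.0
                if state.vegf_low_hours[cid] >= cat.ec_grace_hours:
                    _start_death(state, cid, "vegf_starvation")
                    dying = True
            elif t == RPE:
                if cid not in has_rpe_contact and cid not in has_brm_contact:
                    state.isolated_hours[cid] += dt
                else:
                    state.isolated_hours[cid] = 0.0
                if state.isolated_hours[cid] >= cat.rpe_grace_hours:
                    _start_death(state, cid, "adhesion_loss")
                    dying = True
        if dying:
            frac = (state.clock - state.death_start[cid]) / cat.death_ramp_hours
            shrink = max(0.0, 1.0 - frac)
            state.target_volume[cid] = state.death_target0[cid] * shrink
            if not hasattr(state, "death_tsurf0"):
                state.death_tsurf0 = {}
            ts0 = state.death_tsurf0.setdefault(
                int(cid), float(state.target_surface[cid]))
            state.target_surface[cid] = ts0 * shrink ** (2.0 / 3.0)
    # removal bookkeeping: every vanished cell gets exactly one logged cause
    if not hasattr(state, "removed_logged"):
        state.removed_logged = set()
    if not hasattr(state, "death_cause"):
        state.death_cause = {}
    for cid in np.arange(1, state.n_cells + 1):
        cid = int(cid)
        if state.volume[cid] == 0 and state.frozen[cid] == 0 and \
                cid not in state.removed_logged:
            state.alive[cid] = 0
            cause = state.death_cause.get(cid, "squeezed")
            state.log_event("cell_removed", cell=cid,
                            type=int(state.ctype[cid]), cause=cause)
            state.removed_logged.add(cid)
    return state


def grow_stalk_cells(state, dt=1.0, rng=None, pairs=None):
    """VEGF-dependent, contact-inhibited stalk growth and mitosis.

    Each stalk cell's target volume rises by ``rate·⟨c⟩·dt`` unless the
    fraction of its surface in contact with other endothelial cells exceeds
    the inhibition threshold; cells at the doubling volume divide.
    """
    cat = state.catalog
    if pairs is None:
        pairs = state.contact_pairs()
    mean_vegf = _mean_field_per_cell(state, "RPE_VEGF")
    total_area = {}
    ec_area = {}
    for (a, b), area in pairs.items():
        for sid, other in ((a, b), (b, a)):
            if sid == 0 or state.ctype[sid] != STALK:
                continue
            total_area[sid] = total_area.get(sid, 0) + area
            if other != 0 and state.ctype[other] in EC_TYPES:
                ec_area[sid] = ec_area.get(sid, 0) + area
    to_split = []
    for cid in state.cells_of_type(STALK):
        if state.death_start[cid] >= 0:
            continue
        tot = total_area.get(cid, 0)
        frac = ec_area.get(cid, 0) / tot if tot else 0.0
        if frac <= cat.growth_inhibition_threshold:
            # growth exerts a bounded pressure: the target volume leads the
            # realized volume by at most the pressure margin, so expansion
            # stalls where the surrounding adhesion resists it and proceeds
            # where the tissue yields
            new_target = min(
                state.target_volume[cid] + cat.stalk_growth_rate
                * mean_vegf[cid] * dt,
                state.volume[cid] + cat.growth_pressure_margin)
            state.target_volume[cid] = max(state.target_volume[cid],
                                           new_target)
            # compact-shape surface target (cube scaling, EC slack)
            state.target_surface[cid] = cat.ec_surface_slack * 6.0 * \
                state.target_volume[cid] ** (2.0 / 3.0)
        if state.volume[cid] >= cat.stalk_doubling_volume:
            to_split.append(cid)
    if rng is None:
        rng = np.random.default_rng(0)
    for cid in to_split:
        a, b = state.split_cell(cid, rng)
        state.log_event("division", parent=int(a), daughter=int(b))
    return state


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind, rng=None):
    """Small deterministic states for unit tests.

    Kinds: ``two_cell_toy`` (two cells + Medium on a small lattice),
    ``mini_retina`` (48 µm build, scenario 1), ``uniform_slab`` (empty
    lattice for field tests).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if kind == "two_cell_toy":
        state = SimulationState((8, 8, 8), voxel_size=2.0, max_cells=8)
        from .scenarios import baseline_contact_energy, baseline_link_lambda
        state.J = baseline_contact_energy()
        state.link_lambda_table = baseline_link_lambda()
        a = state.new_cell(RPE, target_volume=8)
        state.paint(a, *np.meshgrid(np.arange(2, 4), np.arange(3, 5),
                                    np.arange(3, 5), indexing="ij"))
        b = state.new_cell(RPE, target_volume=8)
        state.paint(b, *np.meshgrid(np.arange(4, 6), np.arange(3, 5),
                                    np.arange(3, 5), indexing="ij"))
        return state
    if kind == "mini_retina":
        geom = RetinalGeometry(lateral_um=48.0)
        return build_retina(geom, CellTypeCatalog(), 1, rng)
    if kind == "uniform_slab":
        state = SimulationState((8, 8, 16), voxel_size=2.0, max_cells=8)
        state.fields["RPE_VEGF"] = np.zeros(state.dims)
        state.fields["Short_VEGF"] = np.zeros(state.dims)
        return state
    raise ValueError(f"unknown fixture kind {kind!r}")
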