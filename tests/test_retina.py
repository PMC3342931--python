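"""Scene construction and cell-fate rules of the retina model."""

import numpy as np
import pytest

from cnvsim.retina import (CellTypeCatalog, PlacementError, RetinalGeometry,
                           build_retina, differentiate_tips, make_fixture,
                           rpe_apical_vegf, seed_tip_cell, update_survival)
from cnvsim.types import (BRM, MEDIUM, PIS, POS, RPE, STALK, TIP, TYPE_NAMES,
                          VASCULAR)


def test_geometry_layer_stack_and_dims():
    geom = RetinalGeometry(lateral_um=48.0)
    nx, ny, nz = geom.dims
    assert nx == ny == 24
    layers = geom.z_layers
    order = ["choroid", "BrM", "RPE", "POS", "PIS"]
    assert list(layers) == order
    assert layers["PIS"][1] == nz  # OLM is the top wall
    # OLM location ≈ stacked layer thickness within 10%
    assert abs((geom.L_RPE + geom.L_OS + geom.L_IS) - geom.L_OLM) \
        <= 0.1 * geom.L_OLM


def test_geometry_rejects_too_narrow_domain():
    with pytest.raises(ValueError):
        RetinalGeometry(lateral_um=24.0)


def test_reference_domain_rpe_count():
    """A 120×120 µm domain hosts ~100 RPE cells of 12 µm footprint."""
    geom = RetinalGeometry(lateral_um=120.0)
    n = (geom.lateral_um / geom.rpe_cell_um) ** 2
    assert n == 100


def test_mini_retina_construction(mini_retina):
    """All seven generalized-cell types are present in the correct vertical
    order, the lattice and ledgers agree, and no CNV exists at t = 0."""
    st = mini_retina
    st.check_integrity()
    tm = st.ctype[st.site]
    present = set(np.unique(tm))
    assert {MEDIUM, VASCULAR, RPE, POS, PIS, BRM} <= present
    # layer order bottom to top by mean z of each type
    means = {t: np.nonzero(tm == t)[2].mean()
             for t in (VASCULAR, BRM, RPE, POS, PIS)}
    assert means[VASCULAR] < means[BRM] < means[RPE] < means[POS] < means[PIS]
    # no CNV at t=0
    from cnvsim.morphometry import compute_mw, measure
    rec = measure(st)
    assert rec.n_stalk == 0
    assert compute_mw(rec) is None
    # 16 RPE cells forming a confluent monolayer
    assert len(st.cells_of_type(RPE)) == 16


def test_rpe_brm_coverage_at_construction(mini_retina):
    """The RPE covers >95% of the BrM apical face at t = 0."""
    st = mini_retina
    z_top_brm = st.geometry.z_layers["BrM"][1] - 1
    tm = st.ctype[st.site]
    apical = tm[:, :, z_top_brm + 1]
    brm_face = tm[:, :, z_top_brm] == BRM
    coverage = (apical[brm_face] == RPE).mean()
    assert coverage > 0.95


def test_polarized_contacts_emerge_from_geometry(mini_retina):
    """Each RPE cell touches BrM below, RPE laterally and POS above without
    any imposed polarity."""
    st = mini_retina
    pairs = st.contact_pairs()
    for cid in st.cells_of_type(RPE):
        partners = {st.ctype[a if b == cid else b]
                    for (a, b) in pairs if cid in (a, b)}
        assert {BRM, RPE, POS} <= partners


def test_fields_initialized_to_positive_steady_state(mini_retina):
    for name in ("Oxygen", "RPE_VEGF", "Short_VEGF"):
        grid = mini_retina.fields[name]
        assert grid.shape == mini_retina.dims
        assert grid.min() >= 0
        assert grid.max() > 0
    assert rpe_apical_vegf(mini_retina) > 0


def test_fixture_kinds_and_determinism():
    toy = make_fixture("two_cell_toy")
    live = toy.cells_of_type(*range(1, 8))
    assert len(live) == 2
    a = make_fixture("mini_retina", np.random.default_rng(5))
    b = make_fixture("mini_retina", np.random.default_rng(5))
    assert np.array_equal(a.site, b.site)
    assert np.array_equal(a.ctype, b.ctype)
    with pytest.raises(ValueError):
        make_fixture("unknown")


def test_seed_tip_cell_protocol():
    st = make_fixture("mini_retina", np.random.default_rng(3))
    n_vasc = len(st.cells_of_type(VASCULAR))
    seed_tip_cell(st)
    tips = st.cells_of_type(TIP)
    assert len(tips) == 1
    assert len(st.cells_of_type(VASCULAR)) == n_vasc - 1
    # single-tip protocol: a second seeding is an error
    with pytest.raises(PlacementError):
        seed_tip_cell(st)


def test_seed_tip_cell_requires_cc_location():
    st = make_fixture("mini_retina", np.random.default_rng(3))
    rz = st.geometry.z_layers["RPE"][0]
    with pytest.raises(PlacementError):
        seed_tip_cell(st, location=(0, 0, rz + 2))


def test_tip_differentiates_at_24_hours():
    st = make_fixture("mini_retina", np.random.default_rng(4))
    seed_tip_cell(st)
    tip = st.cells_of_type(TIP)[0]
    st.clock = 23.9
    differentiate_tips(st)
    assert st.ctype[tip] == TIP  # still a tip just before the boundary
    st.clock = 24.0
    differentiate_tips(st)
    assert st.ctype[tip] == STALK
    # MMP secretion ceases with the type switch (only tips secrete MMP)
    from cnvsim.fields import source_maps
    sec, _ = source_maps(st.field_defs["MMP"], st.site, st.ctype)
    assert sec.max() == 0.0
    differentiate_tips(st)  # no tips left: no-op
    assert st.ctype[tip] == STALK


def test_rpe_survival_rule():
    """An RPE cell keeping either lateral RPE contact or BrM contact
    survives; a fully isolated one dies after the grace period."""
    st = make_fixture("mini_retina", np.random.default_rng(6))
    cat = st.catalog
    rpe = st.cells_of_type(RPE)
    victim = int(rpe[0])
    # teleport the victim into the choroidal Medium, away from RPE and BrM
    st.site[st.site == victim] = MEDIUM
    st.volume[victim] = 0
    st._sx[victim] = st._sy[victim] = st._sz[victim] = 0.0
    st.paint(victim, *np.meshgrid(range(2, 5), range(2, 5), range(0, 3),
                                  indexing="ij"))
    st.init_surfaces(set_targets=False)
    hours = 0.0
    while hours <= cat.rpe_grace_hours:
        update_survival(st, dt=3.0)
        st.clock += 3.0
        hours += 3.0
    assert st.death_start[victim] >= 0
    causes = [e for e in st.events if e["kind"] == "death_started"
              and e["cell"] == victim]
    assert len(causes) == 1 and causes[0]["cause"] == "adhesion_loss"
    # a neighboring RPE cell that kept its contacts is untouched
    keeper = int(rpe[1])
    assert st.death_start[keeper] < 0


def test_ec_starvation_rule():
    """An endothelial cell below the VEGF survival threshold for the grace
    period is marked for death with the starvation cause."""
    st = make_fixture("mini_retina", np.random.default_rng(8))
    cat = st.catalog
    vasc = int(st.cells_of_type(VASCULAR)[0])
    st.fields["RPE_VEGF"] = np.zeros(st.dims)  # starve everyone
    for _ in range(4):
        update_survival(st, dt=3.0)
        st.clock += 3.0
    assert st.death_start[vasc] >= 0
    cause = [e for e in st.events if e["kind"] == "death_started"
             and e["cell"] == vasc][0]["cause"]
    assert cause == "vegf_starvation"
    # the target volume ramps toward zero
    t0 = st.death_target0[vasc]
    update_survival(st, dt=3.0)
    assert st.target_volume[vasc] < t0


def test_death_bookkeeping_single_cause():
    """Every removed cell carries exactly one logged removal cause."""
    st = make_fixture("mini_retina", np.random.default_rng(9))
    vasc = int(st.cells_of_type(VASCULAR)[0])
    st.site[st.site == vasc] = MEDIUM
    st.volume[vasc] = 0
    st._sx[vasc] = st._sy[vasc] = st._sz[vasc] = 0.0
    st.init_surfaces(set_targets=False)
    update_survival(st, dt=3.0)
    update_survival(st, dt=3.0)  # repeated calls must not double-log
    removals = [e for e in st.events if e["kind"] == "cell_removed"
                and e["cell"] == vasc]
    assert len(removals) == 1
    assert "cause" in removals[0]
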