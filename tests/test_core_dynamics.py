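"""Metropolis dynamics, Monte Carlo stepping, mitosis and link maintenance."""

import numpy as np
import pytest

from cnvsim._kernels import metropolis_accept, seed_rng
from cnvsim.core import EngineParameters, SimulationState
from cnvsim.types import BRM, POS, RPE, STALK, VASCULAR
from conftest import random_cell_state


def test_metropolis_zero_delta_always_accepted():
    rng = seed_rng(5)
    assert all(metropolis_accept(0.0, 20.0, rng) for _ in range(100))


def test_metropolis_acceptance_rate_matches_boltzmann():
    """For ΔH = T·ln 2 the acceptance rate is 1/2; empirical frequency over
    10⁴ trials must sit within 3σ of the binomial expectation."""
    temperature = 20.0
    n = 10_000
    for p_expect in (0.5, np.exp(-1.0)):
        d_h = -temperature * np.log(p_expect)
        rng = seed_rng(123)
        hits = sum(metropolis_accept(d_h, temperature, rng) for _ in range(n))
        sigma = np.sqrt(n * p_expect * (1 - p_expect))
        assert abs(hits - n * p_expect) < 3 * sigma


def test_run_mcs_zero_steps_is_identity():
    rng = np.random.default_rng(0)
    st = random_cell_state(rng)
    before = st.site.copy()
    clock = st.clock
    out = st.run_mcs(0)
    assert out.size == 0
    assert np.array_equal(st.site, before)
    assert st.clock == clock
    with pytest.raises(ValueError):
        st.run_mcs(-1)


def test_run_mcs_advances_clock():
    rng = np.random.default_rng(1)
    st = random_cell_state(rng)
    st.params.mcs_per_hour = 6.0
    st.run_mcs(12)
    assert st.clock == pytest.approx(2.0)


def test_cold_limit_relaxes_volumes_to_target():
    """As T → 0 with only the volume term active, every cell's volume
    converges to its target within 50 MCS."""
    rng = np.random.default_rng(7)
    st = random_cell_state(rng, temperature=1e-3, with_links=False)
    st.J[:] = 0.0
    st.lambda_surface_cell[:] = 0.0
    # perturb targets away from current volumes
    for c in range(1, st.n_cells + 1):
        if st.volume[c] > 0:
            st.target_volume[c] = st.volume[c] + (3 if c % 2 else -3)
    st.run_mcs(50)
    for c in range(1, st.n_cells + 1):
        if st.alive[c]:
            assert st.volume[c] == int(st.target_volume[c])


def test_ledger_audit_after_dynamics():
    """After 100 MCS, the incremental volume, COM and surface ledgers equal
    brute-force recounts, and the total voxel count is conserved."""
    rng = np.random.default_rng(11)
    st = random_cell_state(rng, lambda_surface=1.0)
    nvox = int(np.prod(st.dims))
    st.run_mcs(100)
    st.check_integrity()
    assert st.recount_volumes().sum() == nvox
    assert np.array_equal(st.recount_surfaces(), st.surface)
    for cid in range(1, st.n_cells + 1):
        if st.volume[cid] > 0:
            assert np.allclose(st.com(cid), st.recount_com(cid), atol=1e-8)


def test_frozen_material_never_moves():
    """Proposals into (or out of) frozen material are rejected: the frozen
    block's voxels are bit-identical after dynamics."""
    st = SimulationState((8, 8, 8), params=EngineParameters(temperature=50.0),
                         max_cells=8)
    b = st.new_cell(BRM, frozen=True)
    st.paint(b, *np.meshgrid(range(2, 6), range(2, 6), [3], indexing="ij"))
    c = st.new_cell(RPE, target_volume=16)
    st.paint(c, *np.meshgrid(range(2, 6), range(2, 6), [4], indexing="ij"))
    st.init_surfaces()
    st.J[RPE, BRM] = st.J[BRM, RPE] = -38.0
    before = (st.site == b).copy()
    st.run_mcs(30)
    assert np.array_equal(st.site == b, before)
    assert st.volume[b] == 16


def test_seed_determinism_bit_identical():
    """Identical seed and configuration give bit-identical trajectories."""
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(5)
        st = random_cell_state(rng)
        st.rng = seed_rng(99)
        st.run_mcs(20)
        outs.append(st.site.copy())
    assert np.array_equal(outs[0], outs[1])


# ---------------------------------------------------------------------------
# mitosis


def _cube_stalk(side=2, target=8):
    st = SimulationState((8, 8, 8), max_cells=8)
    c = st.new_cell(STALK, target_volume=target)
    st.paint(c, *np.meshgrid(range(3, 3 + side), range(3, 3 + side),
                             range(3, 3 + side), indexing="ij"))
    st.init_surfaces()
    return st, c


def test_split_symmetric_cube():
    st, c = _cube_stalk()
    a, b = st.split_cell(c, np.random.default_rng(0))
    assert st.volume[a] == st.volume[b] == 4
    assert st.ctype[a] == st.ctype[b] == STALK
    assert st.target_volume[a] == st.target_volume[b] == 4.0


def test_split_conserves_volume_on_random_shapes():
    rng = np.random.default_rng(21)
    for trial in range(30):
        st = SimulationState((10, 10, 10), max_cells=8)
        c = st.new_cell(STALK, target_volume=30)
        # random connected-ish blob
        xs = rng.integers(2, 8, size=30)
        ys = rng.integers(2, 8, size=30)
        zs = rng.integers(2, 8, size=30)
        st.site[xs, ys, zs] = c
        st.volume[c] = int((st.site == c).sum())
        vox = np.nonzero(st.site == c)
        st._sx[c], st._sy[c], st._sz[c] = (v.sum() for v in vox)
        st.init_surfaces()
        v0 = st.volume[c]
        a, b = st.split_cell(c, rng)
        assert st.volume[a] + st.volume[b] == v0
        assert st.volume[a] > 0 and st.volume[b] > 0
        st.check_integrity()


def test_split_rejects_non_stalk_and_frozen():
    st = SimulationState((8, 8, 8), max_cells=8)
    r = st.new_cell(RPE, target_volume=8)
    st.paint(r, *np.meshgrid(range(2, 4), range(2, 4), range(2, 4),
                             indexing="ij"))
    st.init_surfaces()
    with pytest.raises(ValueError):
        st.split_cell(r, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# plastic links


def _linked_pair(lam=300.0, sep=3):
    st = SimulationState((12, 12, 12), max_cells=8)
    a = st.new_cell(RPE, target_volume=8)
    st.paint(a, *np.meshgrid(range(2, 4), range(4, 6), range(4, 6),
                             indexing="ij"))
    b = st.new_cell(RPE, target_volume=8)
    st.paint(b, *np.meshgrid(range(4, 6), range(4, 6), range(4, 6),
                             indexing="ij"))
    st.init_surfaces()
    st.link_lambda_table[RPE, RPE] = lam
    return st, a, b


def test_link_forms_at_contact_with_scenario_stiffness():
    """Two RPE cells in face contact under a junctional scenario form exactly
    one RPE–RPE link with the scenario's stiffness, anchored at the COMs."""
    st, a, b = _linked_pair(lam=300.0)
    st.maintain_links()
    act = st.active_links()
    assert act.size == 1
    l = act[0]
    assert {int(st.link_a[l]), int(st.link_b[l])} == {a, b}
    assert st.link_lambda[l] == 300.0
    assert st.link_rest[l] == pytest.approx(st._pair_distance(a, b))
    # maintaining again must not duplicate the link
    st.maintain_links()
    assert st.active_links().size == 1


def test_link_breaks_beyond_rupture_extension():
    """Forcing the pair apart beyond the rupture extension deactivates the
    link and removes its spring energy."""
    st, a, b = _linked_pair(lam=60.0)
    st.maintain_links()
    # teleport cell b far away (bookkeeping-level displacement)
    st.site[st.site == b] = 0
    st.volume[b] = 0
    st._sx[b] = st._sy[b] = st._sz[b] = 0.0
    bnew_x = np.arange(9, 11)
    st.paint(b, *np.meshgrid(bnew_x, range(4, 6), range(4, 6), indexing="ij"))
    st.init_surfaces()
    st.maintain_links()
    assert st.active_links().size == 0
    # spring energy contribution is zero once inactive
    from cnvsim._kernels import _spring_energy_links
    e = _spring_energy_links(st.link_a, st.link_b, st.link_lambda,
                             st.link_rest, st.link_active, st.volume,
                             st._sx, st._sy, st._sz,
                             st.dims[0], st.dims[1], st.voxel_size)
    assert e == 0.0


def test_pos_pos_link_stiffness():
    st = SimulationState((12, 12, 12), max_cells=8)
    a = st.new_cell(POS, target_volume=8)
    st.paint(a, *np.meshgrid(range(2, 4), range(4, 6), range(4, 6),
                             indexing="ij"))
    b = st.new_cell(POS, target_volume=8)
    st.paint(b, *np.meshgrid(range(4, 6), range(4, 6), range(4, 6),
                             indexing="ij"))
    st.init_surfaces()
    from cnvsim.scenarios import baseline_link_lambda
    st.link_lambda_table = baseline_link_lambda()
    st.maintain_links()
    act = st.active_links()
    assert act.size == 1
    assert st.link_lambda[act[0]] == 30.0


def test_link_expires_after_persistence_window():
    st, a, b = _linked_pair(lam=300.0)
    st.maintain_links()
    # separate cells slightly so contact is lost but length stays short
    st.site[st.site == b] = 0
    st.volume[b] = 0
    st._sx[b] = st._sy[b] = st._sz[b] = 0.0
    st.paint(b, *np.meshgrid(range(5, 7), range(4, 6), range(4, 6),
                             indexing="ij"))
    st.init_surfaces()
    st.clock += st.params.link_persistence_hours + 0.1
    st.maintain_links()
    assert st.active_links().size == 0
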