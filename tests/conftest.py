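import numpy as np
import pytest

from cnvsim.core import EngineParameters, SimulationState
from cnvsim.retina import make_fixture
from cnvsim.scenarios import baseline_contact_energy, baseline_link_lambda
from cnvsim.types import MEDIUM, RPE, STALK


@pytest.fixture(scope="session")
def mini_retina():
    """One shared intact 48 µm retina (scenario 1); treat as read-only."""
    return make_fixture("mini_retina", np.random.default_rng(7))


@pytest.fixture
def two_cell_toy():
    return make_fixture("two_cell_toy")


def random_cell_state(rng, dims=(20, 20, 20), n_cells=8, temperature=20.0,
                      lambda_surface=0.0, with_links=True, with_chem=False):
    """A random multi-cell lattice with full ledgers, for ΔH-oracle tests."""
    params = EngineParameters(temperature=temperature,
                              lambda_surface=lambda_surface)
    state = SimulationState(dims, voxel_size=2.0, params=params,
                            max_cells=n_cells + 4)
    state.J = baseline_contact_energy()
    state.link_lambda_table = baseline_link_lambda()
    nx, ny, nz = dims
    # seed cells as random blobs, then scramble with a short hot run
    side = 4
    for i in range(n_cells):
        ctype = [RPE, STALK][i % 2]
        cid = state.new_cell(ctype, target_volume=side ** 3)
        x0 = rng.integers(0, nx - side)
        y0 = rng.integers(0, ny - side)
        z0 = rng.integers(0, nz - side)
        xs, ys, zs = np.meshgrid(np.arange(x0, x0 + side),
                                 np.arange(y0, y0 + side),
                                 np.arange(z0, z0 + side), indexing="ij")
        # overwrite any previous owner and fix its ledgers afterwards
        state.site[xs, ys, zs] = 0
        state.paint(cid, xs.ravel(), ys.ravel(), zs.ravel())
    # rebuild ledgers from the lattice (paint overlaps corrupt earlier cells)
    counts = state.recount_volumes()
    for c in range(1, state.n_cells + 1):
        state.volume[c] = counts[c] if c < counts.size else 0
        if state.volume[c] == 0:
            state.alive[c] = 0
            state._sx[c] = state._sy[c] = state._sz[c] = 0.0
        else:
            xs, ys, zs = np.nonzero(state.site == c)
            state._sx[c] = xs.sum()
            state._sy[c] = ys.sum()
            state._sz[c] = zs.sum()
    state.init_surfaces()
    if with_chem:
        state.chemotaxis[STALK] = (10.0, 0.0)
        state.fields["RPE_VEGF"] = rng.random(dims)
        state.fields["Short_VEGF"] = np.zeros(dims)
    if with_links:
        state.maintain_links()
    else:
        state.rebuild_adjacency()
    state.rng[:] = np.uint64(rng.integers(1, 2 ** 62, size=2))
    return state
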