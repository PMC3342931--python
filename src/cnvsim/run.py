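"""One-replica simulation driver.

The hourly loop interleaves Monte Carlo lattice dynamics with the slower
biology: link maintenance, quasi-static field updates, Bruch's-membrane
degradation by MMP, tip-cell differentiation, survival bookkeeping and
stalk growth/mitosis.  Morphometric records are taken every storage cadence
(default 6 simulated hours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import seed_rng
from .config import RunConfig
from .core import EngineParameters
from .fields import degrade_brm
from .morphometry import classify_run, detect_initiation, measure
from .retina import (CellTypeCatalog, RetinalGeometry, build_retina,
                     differentiate_tips, grow_stalk_cells, seed_tip_cell,
                     update_fields, update_survival)
from .scenarios import scenario_by_id, scenario_by_levels, condition_preset


@dataclass
class RunResult:
    """Outcome of one replica: the record stream plus its classification."""

    records: list
    classification: dict
    seed: int
    scenario_id: int
    config: RunConfig
    state: object = None

    @property
    def onset(self):
        return self.classification["onset"]


def resolve_scenario(selector):
    """Scenario from an ID, an explicit level 5-tuple, or a condition name."""
    if isinstance(selector, int):
        return scenario_by_id(selector)
    if isinstance(selector, (tuple, list)) and len(selector) == 5:
        return scenario_by_levels(*selector)
    if isinstance(selector, str):
        preset = condition_preset(selector)
        # the most severe admissible level per axis characterizes the condition
        levels = tuple(min(preset[k]) for k in ("RRl", "RRp", "RBl", "RBp", "ROl"))
        return scenario_by_levels(*levels)
    raise ValueError(f"cannot interpret scenario selector {selector!r}")


def build_state(config, rng=None):
    cfg = config.resolved()
    scenario = resolve_scenario(cfg.scenario)
    geom = RetinalGeometry(lateral_um=cfg.lateral_um, voxel_size=cfg.voxel_size)
    params = EngineParameters(temperature=cfg.temperature,
                              lambda_vol=cfg.lambda_vol,
                              lambda_surface=cfg.lambda_surface,
                              contact_tension=cfg.contact_tension,
                              chemotaxis_saturation=cfg.chemotaxis_saturation,
                              mcs_per_hour=cfg.mcs_per_hour)
    catalog = CellTypeCatalog()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = build_retina(geom, catalog, scenario, rng, params=params)
    state.rng = seed_rng(cfg.seed)
    return state


def run_simulation(config, keep_state=False, progress=None):
    """Run one replica and classify it.

    Parameters
    ----------
    config : RunConfig
    keep_state : bool
        Attach the final state to the result (for snapshots/inspection).
    progress : callable or None
        Called as ``progress(hour, total_hours)`` once per simulated hour.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    state = build_state(cfg, rng=rng)
    scenario = state.scenario
    if not cfg.no_tip:
        seed_tip_cell(state)
        update_fields(state)  # tip now secretes MMP
    records = [measure(state)]
    total_hours = int(round(cfg.duration_hours))
    tick = int(round(cfg.tick_hours))
    cat = state.catalog
    mcs_per_tick = int(round(cfg.mcs_per_hour * tick))
    stop_after = getattr(cfg, "stop_after_hours", None)
    hard_stop = getattr(cfg, "hard_stop_hours", None)
    for hour in range(tick, total_hours + 1, tick):
        state.run_mcs(mcs_per_tick)
        # BrM proteolysis by the MMP field
        degrade_brm(state.fields["MMP"], state, cat.mmp_degradation_rate,
                    float(tick), rng)
        differentiate_tips(state)
        pairs = state.contact_pairs()
        state.maintain_links(pairs)
        _update_fast_fields(state)  # oxygen stays at its intact steady state
        update_survival(state, dt=float(tick), pairs=pairs)
        grow_stalk_cells(state, dt=float(tick), rng=rng, pairs=pairs)
        if hour % cfg.cadence_hours == 0:
            records.append(measure(state))
            initiated = detect_initiation(records) is not None
            past_floor = stop_after is None or hour >= stop_after
            if cfg.stop_on_initiation and initiated and past_floor:
                break
            if stop_after is not None and not cfg.stop_on_initiation \
                    and hour >= stop_after:
                break
            if hard_stop is not None and hour >= hard_stop:
                break
        if progress is not None:
            progress(hour, total_hours)
    classification = classify_run(records, duration_hours=cfg.duration_hours)
    return RunResult(records=records, classification=classification,
                     seed=cfg.seed, scenario_id=scenario.id, config=cfg,
                     state=state if keep_state else None)


def _update_fast_fields(state):
    """Hourly quasi-static update of the fields that drive cell behavior."""
    from .fields import source_maps

    for name in ("RPE_VEGF", "Short_VEGF", "MMP"):
        fobj = state.field_defs[name]
        sec, upt = source_maps(fobj, state.site, state.ctype)
        grid = state.solvers[name].solve(sec, upt)
        fobj.grid = grid
        state.fields[name] = grid
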