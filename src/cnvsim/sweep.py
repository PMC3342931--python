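"""Replica management over adhesion scenarios and regression analysis.

The factorial sweep runs replicas per scenario, aggregates initiation
probability, mean morphometric weight and dynamics-class frequencies, and
fits ordinary least squares of each response on the five graded adhesion
levels (coded numerically 1–3) plus all pairwise products.  The fitted
surfaces are tabulated on the symmetric reduction RRp = RRl, RBp = RBl for
reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import RunConfig, replica_seed
from .morphometry import DYNAMICS_TABLE
from .run import run_simulation
from .scenarios import enumerate_scenarios

MAIN_EFFECTS = ("RRl", "RRp", "RBl", "RBp", "ROl")


@dataclass
class ScenarioOutcome:
    """Per-replica classifications and aggregates for one scenario."""

    scenario_id: int
    replicas: list = field(default_factory=list)  # dicts per replica
    failed: list = field(default_factory=list)

    @property
    def n(self):
        return len(self.replicas)

    @property
    def p_init(self):
        if not self.replicas:
            return float("nan")
        return sum(1 for r in self.replicas if r["initiated"]) / self.n

    @property
    def mean_mw(self):
        vals = [r["mean_mw"] for r in self.replicas if r["mean_mw"] is not None]
        return float(np.mean(vals)) if vals else None

    def dynamics_frequencies(self):
        freq = {cls: 0.0 for cls in DYNAMICS_TABLE.values()}
        for r in self.replicas:
            if r["dynamics"] in freq:
                freq[r["dynamics"]] += 1.0 / self.n
        return freq

    def to_row(self):
        row = {"scenario_id": self.scenario_id, "n": self.n,
               "p_init": self.p_init, "mean_mw": self.mean_mw}
        row.update({f"p_{k}": v for k, v in self.dynamics_frequencies().items()})
        return row


def run_replicas(scenario_id, n, seeds=None, config=None, no_tip_controls=0):
    """Run ``n`` independent replicas of one scenario (plus optional controls).

    Seeds must be distinct; by default they derive from the config's base
    seed, the scenario ID and the replica index.
    """
    if n < 1:
        raise ValueError("need at least one replica")
    config = config or RunConfig()
    if seeds is None:
        seeds = [replica_seed(config.seed, scenario_id, i) for i in range(n)]
    if len(set(seeds)) != len(seeds):
        raise ValueError("replica seeds must be distinct")
    outcome = ScenarioOutcome(scenario_id=scenario_id)
    for i, s in enumerate(seeds):
        cfg = replace(config, scenario=scenario_id, seed=int(s))
        try:
            res = run_simulation(cfg)
        except Exception as exc:  # a failed replica is recorded, not fatal
            import warnings

            warnings.warn(f"replica {i} of scenario {scenario_id} failed: {exc}")
            outcome.failed.append({"replica": i, "seed": int(s),
                                   "error": str(exc)})
            continue
        rec = dict(res.classification)
        rec.update({"replica": i, "seed": int(s)})
        outcome.replicas.append(rec)
    for i in range(no_tip_controls):
        s = replica_seed(config.seed, scenario_id, 10_000 + i)
        cfg = replace(config, scenario=scenario_id, seed=int(s), no_tip=True)
        res = run_simulation(cfg)
        rec = dict(res.classification)
        rec.update({"replica": f"control-{i}", "seed": int(s), "control": True})
        # no-tip controls are kept apart from the tip-cell aggregates
        outcome.controls = getattr(outcome, "controls", [])
        outcome.controls.append(rec)
    return outcome


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    """OLS fit of a response on the 5 adhesion levels and pairwise products."""

    params: pd.Series
    r_squared: float
    adj_r_squared: float
    include_interactions: bool
    bse: pd.Series = None

    def predict(self, levels):
        """Evaluate the fitted surface at a level dict {RRl: .., ...}."""
        x = {"const": 1.0}
        for k in MAIN_EFFECTS:
            x[k] = float(levels[k])
        if self.include_interactions:
            for a, b in itertools.combinations(MAIN_EFFECTS, 2):
                x[f"{a}:{b}"] = float(levels[a]) * float(levels[b])
        return float(sum(self.params.get(k, 0.0) * v for k, v in x.items()))


def design_matrix(design, include_interactions=True):
    X = pd.DataFrame({k: design[k].astype(float) for k in MAIN_EFFECTS})
    if include_interactions:
        for a, b in itertools.combinations(MAIN_EFFECTS, 2):
            X[f"{a}:{b}"] = X[a] * X[b]
    return sm.add_constant(X, has_constant="add")


def fit_regression(design, response, include_interactions=True):
    """OLS of one response value per scenario on the coded adhesion levels.

    ``design`` is a DataFrame with columns RRl, RRp, RBl, RBp, ROl (numeric
    levels 1–3); ``response`` is aligned with its rows.  A rank-deficient
    design raises with an explicit diagnostic.
    """
    X = design_matrix(design, include_interactions)
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("response length does not match design rows")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            "columns); the level combinations do not identify all terms")
    model = sm.OLS(y, X).fit()
    if np.var(y) <= 1e-14 * (1.0 + np.mean(y) ** 2):
        # a constant response carries no explainable variance
        r2 = adj = 0.0
    else:
        r2, adj = float(model.rsquared), float(model.rsquared_adj)
    return RegressionResult(params=model.params,
                            r_squared=r2,
                            adj_r_squared=min(adj, r2),
                            include_interactions=include_interactions,
                            bse=model.bse)


def project_symmetric(result, grid=None):
    """Tabulate the fitted surface on the symmetric (RR, RB, RO) reduction.

    The five-parameter surface is evaluated with RRp = RRl = RR and
    RBp = RBl = RB on a 3D grid; returns a DataFrame (RR, RB, RO, value)
    suitable for isosurface-style reporting.
    """
    if grid is None:
        grid = np.linspace(1.0, 3.0, 9)
    rows = []
    ro_levels = grid
    for rr in grid:
        for rb in grid:
            for ro in ro_levels:
                v = result.predict({"RRl": rr, "RRp": rr,
                                    "RBl": rb, "RBp": rb, "ROl": ro})
                rows.append((rr, rb, ro, v))
    return pd.DataFrame(rows, columns=["RR", "RB", "RO", "value"])


def sweep_design_frame(scenario_ids=None):
    """Design matrix rows (one per scenario) for the regression."""
    scen = enumerate_scenarios()
    if scenario_ids is not None:
        wanted = set(scenario_ids)
        scen = [s for s in scen if s.id in wanted]
    return pd.DataFrame(
        [{"scenario_id": s.id, "RRl": s.RRl, "RRp": s.RRp, "RBl": s.RBl,
          "RBp": s.RBp, "ROl": s.ROl} for s in scen])


def run_sweep(scenario_ids, replicas, config=None):
    """Run the factorial sweep; returns (outcomes, aggregate DataFrame)."""
    outcomes = []
    for sid in scenario_ids:
        outcomes.append(run_replicas(sid, replicas, config=config))
    agg = pd.DataFrame([o.to_row() for o in outcomes])
    return outcomes, agg
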