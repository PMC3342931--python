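"""The 108-scenario adhesion factorial and its parameter mapping.

Five adhesion strengths of the BrM–RPE–POS complex are each graded as
normal (3), moderately impaired (2) or severely impaired (1):

* ``RRl`` — RPE–RPE labile adhesion (contact energy), levels {1, 3}
* ``RRp`` — RPE–RPE plastic coupling (spring stiffness), levels {1, 2, 3}
* ``RBl`` — RPE–BrM labile adhesion, levels {1, 2, 3}
* ``RBp`` — RPE–BrM plastic coupling, levels {1, 2, 3}
* ``ROl`` — RPE–POS labile adhesion, levels {1, 3}

The full factorial has 2·3·3·3·2 = 108 scenarios.  Scenario IDs follow the
enumeration that reproduces every published ID↔tuple anchor: lexicographic
with all levels descending, ordered by (RBl, ROl, RRl, RRp, RBp), so that
ID 1 is all-normal and ID 108 all-severe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BRM, MEDIUM, PIS, POS, RPE, STALK, TIP, VASCULAR, N_TYPES

RRL_LEVELS = {3: -40.0, 1: -18.0}
RBL_LEVELS = {3: -38.0, 2: -28.0, 1: -18.0}
ROL_LEVELS = {3: -16.0, 1: -1.0}
RRP_LEVELS = {3: 300.0, 2: 60.0, 1: 30.0}
RBP_LEVELS = {3: 300.0, 2: 60.0, 1: 30.0}

#: enumeration order (field, admissible levels in descending order)
_ORDER = (
    ("RBl", (3, 2, 1)),
    ("ROl", (3, 1)),
    ("RRl", (3, 1)),
    ("RRp", (3, 2, 1)),
    ("RBp", (3, 2, 1)),
)


@dataclass(frozen=True)
class AdhesionScenario:
    """One point of the adhesion factorial; ``id`` runs 1–108."""

    id: int
    RRl: int
    RRp: int
    RBl: int
    RBp: int
    ROl: int

    @property
    def levels(self):
        return (self.RRl, self.RRp, self.RBl, self.RBp, self.ROl)


def _validate_levels(RRl, RRp, RBl, RBp, ROl):
    checks = (
        ("RRl", RRl, RRL_LEVELS),
        ("RRp", RRp, RRP_LEVELS),
        ("RBl", RBl, RBL_LEVELS),
        ("RBp", RBp, RBP_LEVELS),
        ("ROl", ROl, ROL_LEVELS),
    )
    for name, lvl, table in checks:
        if lvl not in table:
            raise ValueError(
                f"{name}={lvl} is not an admissible level "
                f"(allowed: {sorted(table)})")


def enumerate_scenarios():
    """All 108 scenarios in canonical ID order (1 = all-normal, 108 = all-severe)."""
    out = []
    i = 1
    for RBl in _ORDER[0][1]:
        for ROl in _ORDER[1][1]:
            for RRl in _ORDER[2][1]:
                for RRp in _ORDER[3][1]:
                    for RBp in _ORDER[4][1]:
                        out.append(AdhesionScenario(i, RRl, RRp, RBl, RBp, ROl))
                        i += 1
    return out


_BY_ID = None
_BY_TUPLE = None


def _tables():
    global _BY_ID, _BY_TUPLE
    if _BY_ID is None:
        scen = enumerate_scenarios()
        _BY_ID = {s.id: s for s in scen}
        _BY_TUPLE = {s.levels: s for s in scen}
    return _BY_ID, _BY_TUPLE


def scenario_by_id(scenario_id):
    by_id, _ = _tables()
    if scenario_id not in by_id:
        raise ValueError(f"scenario id {scenario_id} outside 1..108")
    return by_id[scenario_id]


def scenario_by_levels(RRl, RRp, RBl, RBp, ROl):
    _validate_levels(RRl, RRp, RBl, RBp, ROl)
    _, by_tuple = _tables()
    return by_tuple[(RRl, RRp, RBl, RBp, ROl)]


# ---------------------------------------------------------------------------
# level → parameter mapping


def baseline_contact_energy():
    """Contact-energy table J at normal adhesion (more negative = stickier)."""
    J = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)

    def put(a, b, v):
        J[a, b] = v
        J[b, a] = v

    ec = (VASCULAR, STALK, TIP)
    for i, a in enumerate(ec):
        for b in ec[i:]:
            put(a, b, -20.0)
    for a in ec:
        put(a, BRM, -10.0)
        put(a, RPE, -10.0)
        put(a, POS, -10.0)
        put(a, PIS, -10.0)
        put(a, MEDIUM, 3.0)
    put(BRM, BRM, -12.0)
    put(BRM, RPE, RBL_LEVELS[3])
    put(BRM, POS, 0.0)
    put(BRM, PIS, 0.0)
    put(BRM, MEDIUM, -1.0)
    put(RPE, RPE, RRL_LEVELS[3])
    put(RPE, POS, ROL_LEVELS[3])
    put(RPE, PIS, ROL_LEVELS[3])
    put(RPE, MEDIUM, 3.0)
    put(POS, POS, -16.0)
    put(POS, PIS, -16.0)
    put(POS, MEDIUM, 3.0)
    put(PIS, PIS, -16.0)
    put(PIS, MEDIUM, 3.0)
    J[MEDIUM, MEDIUM] = 0.0
    return J


def baseline_link_lambda():
    """Plastic-coupling stiffness per junctional type pair (energy/µm²)."""
    lam = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)

    def put(a, b, v):
        lam[a, b] = v
        lam[b, a] = v

    put(RPE, RPE, RRP_LEVELS[3])
    put(RPE, BRM, RBP_LEVELS[3])
    put(POS, POS, 30.0)
    put(PIS, PIS, 30.0)
    put(PIS, POS, 30.0)
    put(VASCULAR, VASCULAR, 200.0)
    put(STALK, VASCULAR, 150.0)
    put(TIP, VASCULAR, 50.0)
    put(STALK, STALK, 50.0)
    put(STALK, TIP, 50.0)
    put(VASCULAR, BRM, 200.0)
    put(STALK, BRM, 25.0)
    put(TIP, BRM, 25.0)
    return lam


def scenario_parameters(scenario):
    """Contact-energy and spring tables for one scenario.

    Returns ``(J, link_lambda)`` — full (8, 8) tables with the scenario's
    graded entries substituted into the normal-adhesion baseline.
    """
    _validate_levels(scenario.RRl, scenario.RRp, scenario.RBl,
                     scenario.RBp, scenario.ROl)
    J = baseline_contact_energy()
    lam = baseline_link_lambda()
    J[RPE, RPE] = RRL_LEVELS[scenario.RRl]
    J[RPE, BRM] = J[BRM, RPE] = RBL_LEVELS[scenario.RBl]
    J[RPE, POS] = J[POS, RPE] = ROL_LEVELS[scenario.ROl]
    J[RPE, PIS] = J[PIS, RPE] = ROL_LEVELS[scenario.ROl]
    lam[RPE, RPE] = RRP_LEVELS[scenario.RRp]
    lam[RPE, BRM] = lam[BRM, RPE] = RBP_LEVELS[scenario.RBp]
    return J, lam


# ---------------------------------------------------------------------------
# clinical-condition presets


def condition_presets():
    """Pathological conditions mapped to adhesion-level constraints.

    Each entry gives the admissible level set per adhesion axis ("+" = normal,
    moderate or severe impairment per the clinical evidence) and the CNV
    dynamics classes the corresponding scenarios produce in simulation.
    """
    A = {  # shorthand: level sets
        "normal": (3,),
        "moderate": (2,),
        "severe": (1,),
        "impaired": (1, 2),
        "any": (1, 2, 3),
    }
    presets = {
        "Normal Aging (No Drusen)": {
            "RRl": (3,), "RRp": (3,), "RBl": (3,), "RBp": (3,), "ROl": (3,),
            "expected": ("no initiation",),
        },
        "Soft Drusen": {
            "RRl": (3,), "RRp": (3,), "RBl": A["impaired"],
            "RBp": A["impaired"], "ROl": (3,),
            "expected": ("S11", "T12", "P13"),
        },
        "Sub-Retinal Drusenoid": {
            "RRl": (1,), "RRp": A["impaired"], "RBl": A["impaired"],
            "RBp": A["impaired"], "ROl": (1,),
            "expected": ("T12", "S22", "P23"),
        },
        "Active Inflammation": {
            "RRl": (1,), "RRp": A["impaired"], "RBl": (3,), "RBp": (3,),
            "ROl": A["any"],
            "expected": ("S22",),
        },
        "Retinal Detachment": {
            "RRl": (1,), "RRp": A["impaired"], "RBl": (3,), "RBp": (3,),
            "ROl": (1,),
            "expected": ("S22",),
        },
        "High Fat Diet": {
            "RRl": (3,), "RRp": A["any"], "RBl": A["impaired"],
            "RBp": A["impaired"], "ROl": (3,),
            "expected": ("ET1",),
        },
        "Chemotoxicity": {
            "RRl": (1,), "RRp": A["impaired"], "RBl": A["impaired"],
            "RBp": A["impaired"], "ROl": (1,),
            "expected": ("P23",),
        },
        "Sub-Retinal Injection": {
            "RRl": (1,), "RRp": A["impaired"], "RBl": (2, 3), "RBp": A["any"],
            "ROl": (1,),
            "expected": ("S22", "P23"),
        },
        "Sub-Retinal Injection + VEGF Overexpression": {
            "RRl": (1,), "RRp": A["impaired"], "RBl": (2, 3), "RBp": A["any"],
            "ROl": (1,),
            "expected": ("S22", "P23"),
        },
    }
    return presets


def condition_preset(name):
    presets = condition_presets()
    if name not in presets:
        raise KeyError(f"unknown condition {name!r}; "
                       f"known: {sorted(presets)}")
    return presets[name]


def scenarios_to_frame():
    """The scenario table as a pandas DataFrame (id, RRl, RRp, RBl, RBp, ROl)."""
    import pandas as pd

    rows = [(s.id, s.RRl, s.RRp, s.RBl, s.RBp, s.ROl)
            for s in enumerate_scenarios()]
    return pd.DataFrame(rows, columns=["id", "RRl", "RRp", "RBl", "RBp", "ROl"])
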