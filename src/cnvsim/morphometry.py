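"""Morphometric quantification and classification of simulated CNV.

The central statistic is the *morphometric weight*

    MW = area(stalk, BrM) / (area(stalk, BrM) + area(stalk, POS))

which locates the stalk-cell population between Bruch's membrane (MW → 1,
sub-RPE, Type 1) and the photoreceptor outer segments (MW → 0, sub-retinal,
Type 2).  MW is undefined while stalk cells touch neither structure.
CNV *type* is assigned per three-month window from the stalk-count-weighted
mean MW; the ordered (early, late) pair gives one of nine dynamics classes
(stable / translocation / progression).  *Initiation* is the first time the
stalk-cell count exceeds three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import BRM, POS, RPE, STALK

TYPE1 = "Type1"
TYPE2 = "Type2"
TYPE3 = "Type3"
NO_CNV = "no CNV locus"

#: (early, late) → dynamics class
DYNAMICS_TABLE = {
    (TYPE1, TYPE1): "S11",
    (TYPE1, TYPE2): "T12",
    (TYPE1, TYPE3): "P13",
    (TYPE2, TYPE1): "T21",
    (TYPE2, TYPE2): "S22",
    (TYPE2, TYPE3): "P23",
    (TYPE3, TYPE1): "T31",
    (TYPE3, TYPE2): "T32",
    (TYPE3, TYPE3): "S33",
}

NOT_CLASSIFIABLE = "not classifiable (no CNV)"


@dataclass
class MorphometricRecord:
    """Per-time-point contact areas and counts of the CNV quantification."""

    time: float  # simulated hours
    n_stalk: int = 0
    ca_stalk_brm: float = 0.0
    ca_stalk_pos: float = 0.0
    ca_rpe_brm: float = 0.0
    ca_pos_brm: float = 0.0
    n_rpe: int = 0
    n_stalk_subrpe: int = 0
    n_stalk_subretinal: int = 0
    flagged_intra_rpe: int = 0

    def __post_init__(self):
        for name in ("n_stalk", "ca_stalk_brm", "ca_stalk_pos", "ca_rpe_brm",
                     "ca_pos_brm", "n_rpe", "n_stalk_subrpe",
                     "n_stalk_subretinal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def measure(state):
    """Build a :class:`MorphometricRecord` from the current lattice."""
    pairs = state.contact_pairs()
    ct = state.ctype
    ca_sb = ca_sp = ca_rb = ca_pb = 0.0
    stalk_brm = {}
    stalk_pos = {}
    stalk_rpe = {}
    stalk_total = {}
    for (a, b), area in pairs.items():
        ta, tb = ct[a], ct[b]
        for sid, other in ((a, tb), (b, ta)) if ta == STALK or tb == STALK else ():
            if ct[sid] != STALK:
                continue
            stalk_total[sid] = stalk_total.get(sid, 0) + area
            if other == BRM:
                stalk_brm[sid] = stalk_brm.get(sid, 0) + area
            elif other == POS:
                stalk_pos[sid] = stalk_pos.get(sid, 0) + area
            elif other == RPE:
                stalk_rpe[sid] = stalk_rpe.get(sid, 0) + area
        key = (min(ta, tb), max(ta, tb))
        if key == (min(STALK, BRM), max(STALK, BRM)):
            ca_sb += area
        elif key == (min(STALK, POS), max(STALK, POS)):
            ca_sp += area
        elif key == (min(RPE, BRM), max(RPE, BRM)):
            ca_rb += area
        elif key == (min(POS, BRM), max(POS, BRM)):
            ca_pb += area
    stalks = state.cells_of_type(STALK)
    # exceptional Type-3 configuration: stalk cells wedged between RPE cells
    flagged = sum(
        1 for s in stalks
        if stalk_rpe.get(s, 0) > max(stalk_brm.get(s, 0), stalk_pos.get(s, 0),
                                     0.5 * stalk_total.get(s, 1))
    )
    return MorphometricRecord(
        time=state.clock,
        n_stalk=len(stalks),
        ca_stalk_brm=ca_sb,
        ca_stalk_pos=ca_sp,
        ca_rpe_brm=ca_rb,
        ca_pos_brm=ca_pb,
        n_rpe=len(state.cells_of_type(RPE)),
        n_stalk_subrpe=sum(1 for s in stalks if stalk_brm.get(s, 0) > 0),
        n_stalk_subretinal=sum(1 for s in stalks if stalk_pos.get(s, 0) > 0),
        flagged_intra_rpe=flagged,
    )


def compute_mw(record):
    """Morphometric weight in [0, 1], or None when undefined (no contact)."""
    denom = record.ca_stalk_brm + record.ca_stalk_pos
    if denom == 0:
        return None
    return record.ca_stalk_brm / denom


def classify_type(mw):
    """CNV type from a morphometric weight.

    Type 1 (sub-RPE) for MW ≥ 0.75, Type 2 (sub-retinal) for MW ≤ 0.25,
    Type 3 (combined) in between; an undefined MW means no CNV locus.
    """
    if mw is None:
        return NO_CNV
    if not 0.0 <= mw <= 1.0:
        raise ValueError("MW must lie in [0, 1]")
    if mw >= 0.75:
        return TYPE1
    if mw <= 0.25:
        return TYPE2
    return TYPE3


def window_mean_mw(records, window):
    """Stalk-count-weighted mean MW over a time window.

    Parameters
    ----------
    records : sequence of MorphometricRecord
    window : (t0, t1) in simulated hours, inclusive.

    Returns None when no record in the window has a defined MW.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive extent")
    num = 0.0
    den = 0.0
    seen = False
    for r in records:
        if not (t0 <= r.time <= t1):
            continue
        seen = True
        mw = compute_mw(r)
        if mw is None or r.n_stalk == 0:
            continue
        num += r.n_stalk * mw
        den += r.n_stalk
    if not seen:
        raise ValueError("no records fall inside the window")
    if den == 0:
        return None
    return num / den


def classify_dynamics(early_type, late_type):
    """Dynamics class (S11 … S33) from the early/late CNV types."""
    if early_type in (None, NO_CNV) or late_type in (None, NO_CNV):
        return NOT_CLASSIFIABLE
    return DYNAMICS_TABLE[(early_type, late_type)]


def detect_initiation(records):
    """Onset time: first record where the stalk count exceeds three, else None."""
    times = [r.time for r in records]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("records must be time-ordered")
    for r in records:
        if r.n_stalk > 3:
            return r.time
    return None


def classify_run(records, duration_hours=None):
    """Full per-replica classification from a record stream.

    The early and late windows are the first and last quarters of the run
    (for the reference full-year run these are the first and last three
    months).  Returns a dict with onset, window MWs, types and the dynamics
    class.
    """
    if not records:
        raise ValueError("no records")
    t_end = duration_hours if duration_hours is not None else records[-1].time
    quarter = t_end / 4.0
    early = window_mean_mw(records, (0.0, quarter))
    try:
        late = window_mean_mw(records, (t_end - quarter, t_end))
    except ValueError:
        late = None  # run stopped before the late window (early-stop mode)
    early_type = classify_type(early)
    late_type = classify_type(late)
    onset = detect_initiation(records)
    mws = [compute_mw(r) for r in records]
    defined = [(m, r.n_stalk) for m, r in zip(mws, records) if m is not None]
    mean_mw = (sum(m * n for m, n in defined) / sum(n for _, n in defined)
               if defined and sum(n for _, n in defined) > 0 else None)
    return {
        "onset": onset,
        "initiated": onset is not None,
        "early_mw": early,
        "late_mw": late,
        "early_type": early_type,
        "late_type": late_type,
        "dynamics": classify_dynamics(early_type, late_type),
        "mean_mw": mean_mw,
    }


def records_to_frame(records):
    return pd.DataFrame([r.__dict__ for r in records])


def records_from_frame(df):
    return [MorphometricRecord(**{k: row[k] for k in
                                  MorphometricRecord.__dataclass_fields__
                                  if k in df.columns})
            for _, row in df.iterrows()]
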