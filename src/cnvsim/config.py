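"""Run configuration: presets, YAML round trip and seed management."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

#: scale presets — lateral extent (µm) and default duration (simulated months)
SCALE_PRESETS = {
    "full": {"lateral_um": 120.0, "months": 12.0},
    "mini": {"lateral_um": 48.0, "months": 1.0},
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation replica.

    ``scenario`` selects the adhesion scenario by ID (1–108), by an explicit
    5-tuple of levels (RRl, RRp, RBl, RBp, ROl), or by a clinical-condition
    preset name.  ``scale`` picks the domain preset; a simulated month is 30
    days.  All randomness derives from ``seed``.
    """

    scenario: object = 1
    scale: str = "mini"
    months: float | None = None
    seed: int = 0
    no_tip: bool = False
    cadence_hours: float = 6.0
    stop_on_initiation: bool = False
    stop_after_hours: float | None = None
    hard_stop_hours: float | None = None
    # engine
    temperature: float = 10.0
    lambda_vol: float = 5.0
    lambda_surface: float = 0.0
    contact_tension: float = 25.0
    chemotaxis_saturation: float = 0.005
    mcs_per_hour: float = 8.0
    tick_hours: float = 2.0
    # geometry overrides (None = preset value)
    lateral_um: float | None = None
    voxel_size: float = 2.0
    # output
    out_dir: str | None = None

    def resolved(self):
        """Fill preset-dependent defaults; returns a new config."""
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}")
        p = SCALE_PRESETS[self.scale]
        return replace(
            self,
            months=self.months if self.months is not None else p["months"],
            lateral_um=self.lateral_um if self.lateral_um is not None
            else p["lateral_um"],
        )

    @property
    def duration_hours(self):
        cfg = self.resolved()
        return cfg.months * 30.0 * 24.0

    # -- serialization -------------------------------------------------------

    def to_dict(self):
        d = asdict(self)
        if isinstance(d["scenario"], tuple):
            d["scenario"] = list(d["scenario"])
        return d

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("scenario"), list):
            d["scenario"] = tuple(d["scenario"])
        return cls(**d)

    def to_yaml(self):
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text):
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self):
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def replica_seed(base_seed, scenario_id, replica_index):
    """Deterministic per-replica seed from (base, scenario, replica), < 2³¹."""
    h = hashlib.sha256(
        f"{base_seed}:{scenario_id}:{replica_index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31 - 1)
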