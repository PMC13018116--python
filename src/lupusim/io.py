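"""Scenario configuration files, run manifests and shipped presets.

A scenario file is a YAML document with up to three sections::

    parameters:    # optional overrides of the calibrated defaults
      q1: 0.2
    schedule:
      genotype: nzbw
      polyic_window: [19, 23]
      depletion_targets: [tILC]
      depletion_strength: 0.8
      depletion_window: [19, 25]
      feedback_knockouts: []
    telegraph:     # optional; presence marks a hybrid scenario
      k_off: 0.029
      k_on: 0.57
      n_on: 4
      xi: 0.55

Unknown keys anywhere are rejected with the offending locations listed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field

import yaml

from .params import ModelParameters, default_parameters
from .schedule import InterventionSchedule
from .telegraph import TelegraphConfig

__all__ = ["load_scenario", "scenario_from_dict", "PRESETS", "RunManifest"]


#: Shipped scenario presets (schedule section plus optional telegraph).
PRESETS = {
    # stimulated lupus-prone mice: poly(I:C) weeks 19-23, no depletion
    "nzbw_polyic": {
        "schedule": {"genotype": "nzbw", "polyic_window": [19, 23]},
    },
    # stimulated wild-type contrast
    "wt_polyic": {
        "schedule": {"genotype": "wt", "polyic_window": [19, 23]},
    },
    # untreated lupus-prone mice (deterministic)
    "nzbw_untreated": {
        "schedule": {"genotype": "nzbw", "polyic_window": None},
    },
    # anti-asialoGM1 tissue-ILC depletion during weeks 19-25
    "aagm1": {
        "schedule": {"genotype": "nzbw", "polyic_window": [19, 23],
                     "depletion_targets": ["tILC"],
                     "depletion_strength": 0.8,
                     "depletion_window": [19, 25]},
    },
    # vessel NK-cell depletion
    "vnk_depletion": {
        "schedule": {"genotype": "nzbw", "polyic_window": [19, 23],
                     "depletion_targets": ["vNK"],
                     "depletion_strength": 0.8,
                     "depletion_window": [19, 25]},
    },
    # combined depletion
    "combined_depletion": {
        "schedule": {"genotype": "nzbw", "polyic_window": [19, 23],
                     "depletion_targets": ["tILC", "vNK"],
                     "depletion_strength": 0.8,
                     "depletion_window": [19, 25]},
    },
    # untreated lupus-prone mice with acute inflammatory events
    "nzbw_hybrid": {
        "schedule": {"genotype": "nzbw", "polyic_window": None},
        "telegraph": "default",
    },
}


def scenario_from_dict(data: dict, source: str = "<dict>"):
    """Validate a scenario mapping into typed objects.

    Returns ``(ModelParameters, InterventionSchedule, TelegraphConfig or
    None)``.
    """
    known = {"parameters", "schedule", "telegraph", "preset_variant"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{source}: unknown top-level keys {unknown}")
    params = default_parameters(
        genotype=data.get("schedule", {}).get("genotype", "nzbw"),
        preset=data.get("preset_variant", "default"))
    overrides = data.get("parameters") or {}
    if overrides:
        try:
            params = params.replace(**overrides)
        except TypeError as exc:
            bad = sorted(set(overrides)
                         - {f.name for f in dataclasses.fields(params)})
            raise ValueError(
                f"{source}: unknown parameter keys {bad}") from exc
    try:
        schedule = InterventionSchedule.from_dict(data.get("schedule") or {})
    except ValueError as exc:
        raise ValueError(f"{source}: invalid schedule: {exc}") from exc
    telegraph = None
    tcfg = data.get("telegraph")
    if tcfg == "default":
        from .analysis import default_telegraph

        telegraph = default_telegraph()
    elif tcfg is not None:
        try:
            telegraph = TelegraphConfig.from_dict(tcfg)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{source}: invalid telegraph: {exc}") from exc
    return params, schedule, telegraph


def load_scenario(path_or_preset):
    """Load a scenario from a YAML file path or a shipped preset name."""
    name = str(path_or_preset)
    if name in PRESETS:
        return scenario_from_dict(PRESETS[name], source=f"preset {name!r}")
    with open(name) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{name}: scenario file must be a mapping")
    return scenario_from_dict(data, source=name)


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a command bit-compatibly."""

    scenario: str
    command: str
    params: dict
    preset_hash: str
    schedule: dict
    seed: int | None = None
    telegraph: dict | None = None
    options: dict = field(default_factory=dict)
    tool_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    @classmethod
    def create(cls, scenario, command, params: ModelParameters,
               schedule: InterventionSchedule,
               telegraph: TelegraphConfig | None = None,
               seed=None, **options):
        return cls(scenario=str(scenario), command=command,
                   params=params.to_dict(), preset_hash=params.preset_hash,
                   schedule=schedule.to_dict(),
                   telegraph=telegraph.to_dict() if telegraph else None,
                   seed=seed, options=options)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))

    def reconstruct(self):
        """Typed objects for re-running the recorded command."""
        params = ModelParameters.from_dict(self.params)
        schedule = InterventionSchedule.from_dict(self.schedule)
        telegraph = (TelegraphConfig.from_dict(self.telegraph)
                     if self.telegraph else None)
        return params, schedule, telegraph
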