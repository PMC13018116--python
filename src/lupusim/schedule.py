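"""Intervention schedules: genotype, poly(I:C) stimulation, cell depletion
and feedback-loop knockouts.

Times are weeks of mouse age.  The standard experimental design stimulates
type-I interferon with poly(I:C) during weeks 19--23; depletion therapy
(anti-asialoGM1 for tissue ILC, or the analogous vessel NK-cell depletion)
runs for six weeks from the start of stimulation, weeks 19--25, at strength
``kappa = 0.8``: during the window the tILC carrying capacity and/or the
vNK infiltration rate are multiplied by ``1 - kappa``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .params import FEEDBACK_LOOPS

__all__ = ["InterventionSchedule", "DEPLETION_TARGETS"]

DEPLETION_TARGETS = ("tILC", "vNK")


@dataclass(frozen=True)
class InterventionSchedule:
    """Time-windowed external controls applied to a simulation.

    Attributes
    ----------
    genotype : {"nzbw", "wt"}
        Genetic background; "wt" disables immune-complex production.
    polyic_window : (float, float) or None
        Poly(I:C) stimulation window in weeks of age; ``None`` disables the
        stimulus (untreated scenario).
    depletion_targets : frozenset of {"tILC", "vNK"}
        Compartments depleted during the depletion window.
    depletion_strength : float
        Depletion strength ``kappa`` in [0, 1]; the affected capacity/rate
        is multiplied by ``1 - kappa`` inside the window.
    depletion_window : (float, float)
        Depletion window in weeks of age.
    feedback_knockouts : frozenset of {"F1".."F5"}
        Feedback loops eliminated for the whole run.
    """

    genotype: str = "nzbw"
    polyic_window: tuple | None = (19.0, 23.0)
    depletion_targets: frozenset = field(default_factory=frozenset)
    depletion_strength: float = 0.8
    depletion_window: tuple = (19.0, 25.0)
    feedback_knockouts: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.genotype.lower() not in ("nzbw", "wt"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        object.__setattr__(self, "genotype", self.genotype.lower())
        for name in ("polyic_window", "depletion_window"):
            win = getattr(self, name)
            if win is None:
                continue
            lo, hi = float(win[0]), float(win[1])
            if not lo < hi:
                raise ValueError(f"{name} {win} is not well-ordered")
            object.__setattr__(self, name, (lo, hi))
        if not 0.0 <= self.depletion_strength <= 1.0:
            raise ValueError("depletion_strength must lie in [0, 1]")
        targets = frozenset(self.depletion_targets)
        if not targets <= set(DEPLETION_TARGETS):
            raise ValueError(
                f"unknown depletion targets: "
                f"{sorted(targets - set(DEPLETION_TARGETS))}"
            )
        object.__setattr__(self, "depletion_targets", targets)
        kos = frozenset(self.feedback_knockouts)
        if not kos <= set(FEEDBACK_LOOPS):
            raise ValueError(
                f"unknown feedback loops: {sorted(kos - set(FEEDBACK_LOOPS))}"
            )
        object.__setattr__(self, "feedback_knockouts", kos)

    def replace(self, **changes) -> "InterventionSchedule":
        return dataclasses.replace(self, **changes)

    # -- queries ---------------------------------------------------------
    def polyic_active(self, t_weeks: float) -> bool:
        win = self.polyic_window
        return win is not None and win[0] <= t_weeks <= win[1]

    def depletion_active(self, t_weeks: float) -> bool:
        lo, hi = self.depletion_window
        return bool(self.depletion_targets) and lo <= t_weeks <= hi

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "polyic_window": list(self.polyic_window)
            if self.polyic_window else None,
            "depletion_targets": sorted(self.depletion_targets),
            "depletion_strength": self.depletion_strength,
            "depletion_window": list(self.depletion_window),
            "feedback_knockouts": sorted(self.feedback_knockouts),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InterventionSchedule":
        known = {"genotype", "polyic_window", "depletion_targets",
                 "depletion_strength", "depletion_window",
                 "feedback_knockouts"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
        data = dict(data)
        if data.get("polyic_window") is not None:
            data["polyic_window"] = tuple(data["polyic_window"])
        if data.get("depletion_window") is not None:
            data["depletion_window"] = tuple(data["depletion_window"])
        if "depletion_targets" in data:
            data["depletion_targets"] = frozenset(data["depletion_targets"])
        if "feedback_knockouts" in data:
            data["feedback_knockouts"] = frozenset(data["feedback_knockouts"])
        return cls(**data)
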