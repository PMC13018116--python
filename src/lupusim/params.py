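"""Model parameters for the lupus-nephritis cell-interaction model.

The model's kinetic core uses seven literature-anchored rates (per day):
maximal proliferation ``gamma``, removal ``delta``, maximal infiltration
``beta``, activation ``alpha``, maximal cytokine endocytosis ``lam``,
maximal secretion ``q`` and cytokine degradation ``eta``.  These are fixed
defaults and should not normally be edited.

The remaining parameters -- Hill half-saturations ``K1..K3``, feedback
weights ``zeta1..zeta5``, the IFN-to-monocyte drive ``theta``, the damage
and immune-complex kinetics ``mu1, nu1, mu2, nu2, n_ic`` and the IFN-I
concentration levels ``q0, q1, q2`` -- are fixed by the calibration
procedure in :mod:`lupusim.analysis` (see :func:`calibrate_defaults`), which
pins qualitative disease behaviour (two-peak interferon response, wild-type
recovery, late spontaneous onset, depletion responses) rather than fitting
time-series data.  The shipped numbers are the versioned output of that
procedure.

Two named presets exist:

``default``
    The down-scaled variant used for depletion and cohort analyses:
    immune-complex feedback on macrophage and monocyte recruitment is
    weakened to ``zeta3 = zeta5 = 0.2`` to emphasise the ILC-mediated
    amplification route.
``uniform_feedback``
    The topology-focused variant in which the three immune-complex-gated
    feedback pathways carry equal weight (``zeta3 = zeta5 = zeta4``); here
    direct feedback on the myeloid compartments dominates the dynamics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

__all__ = [
    "ModelParameters",
    "default_parameters",
    "apply_feedback_knockout",
    "TABLE_RATES",
    "FEEDBACK_LOOPS",
    "PERTURBABLE",
]

#: Literature-anchored kinetic rates (1/day): the immutable defaults.
TABLE_RATES = {
    "gamma": 2.4,   # maximal cell proliferation (~10 h doubling)
    "delta": 0.24,  # cell removal (~4 d lifetime)
    "beta": 2.4,    # maximal cell infiltration
    "alpha": 4.8,   # cell activation (~5 h transcriptional response)
    "lam": 14.4,    # maximal cytokine endocytosis (~10 min uptake)
    "q": 1.44,      # maximal cytokine secretion
    "eta": 0.24,    # cytokine degradation (~4 d)
}

#: Mapping of positive-feedback-loop labels to the weight they control.
#: F1: damage-induced IFN-I release (zeta1)
#: F2: damage-induced tILC activation (zeta2)
#: F3: immune-complex-driven MOMA recruitment (zeta3)
#: F4: immune-complex-induced IFN-I release (zeta4)
#: F5: immune-complex-driven monocyte recruitment (zeta5)
FEEDBACK_LOOPS = {"F1": "zeta1", "F2": "zeta2", "F3": "zeta3",
                  "F4": "zeta4", "F5": "zeta5"}


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter record of the lupus model.

    All rates are per day; abundances, concentrations and Hill constants are
    in dimensionless intrinsic units.  Instances are immutable; use
    :meth:`replace` to derive variants.
    """

    # core kinetic rates (fixed defaults)
    gamma: float = TABLE_RATES["gamma"]
    delta: float = TABLE_RATES["delta"]
    beta: float = TABLE_RATES["beta"]
    alpha: float = TABLE_RATES["alpha"]
    lam: float = TABLE_RATES["lam"]
    q: float = TABLE_RATES["q"]
    eta: float = TABLE_RATES["eta"]
    # calibrated structural parameters (versioned calibration output)
    omega: float = 0.280205          # carrying capacity of tILC/iPEC/cEC pools
    K1: float = 0.217919             # Hill constant of IFN-I gates
    K2: float = 0.304075             # shared Hill constant (cells/damage/IC/cytokines)
    K3: float = 1.801679              # Hill constant of the MO -> vNK gate
    zeta1: float = 0.215183          # F1 weight: damage -> IFN-I
    zeta2: float = 0.009746        # F2 weight: damage -> tILC activation
    zeta3: float = 0.2           # F3 weight: IC -> MOMA recruitment
    zeta4: float = 3.000000           # F4 weight: IC -> IFN-I
    zeta5: float = 0.2           # F5 weight: IC -> MO recruitment
    theta: float = 0.468742          # IFN-I -> monocyte recruitment weight
    mu1: float = 1.0 / 42.0      # damage acquisition rate (6-week scale)
    nu1: float = 1.422415            # damage normalisation (fast) rate
    mu2: float = 0.067310           # immune-complex chain rate (NZB/W only)
    nu2: float = 0.012513          # immune-complex degradation rate
    n_ic: int = 3                # Erlang shape of the damage -> IC chain
    q0: float = 0.057531            # baseline IFN-I level
    q1: float = 0.077080              # poly(I:C)-induced IFN-I level
    q2: float = 2.772330              # feedback-induced IFN-I level scale

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "n_ic":
                if int(v) != v or v < 1:
                    raise ValueError("n_ic must be a positive integer")
                object.__setattr__(self, "n_ic", int(v))
            elif v < 0:
                raise ValueError(f"parameter {f.name} must be non-negative")
        for level in ("q0", "q1", "q2"):
            # concentration levels live on the saturating IFN scale
            if getattr(self, level) < 0:
                raise ValueError(f"{level} must be non-negative")

    # -- construction helpers -------------------------------------------
    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def scaled(self, factors: dict) -> "ModelParameters":
        """Return a copy with fields multiplied by ``factors[name]``."""
        return self.replace(**{k: getattr(self, k) * f
                               for k, f in factors.items()})

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def preset_hash(self) -> str:
        """Short content hash identifying this exact parameter record."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


#: Names of parameters perturbed in virtual-cohort robustness analyses:
#: every positive rate, weight and level except structural integers.
PERTURBABLE = [
    "gamma", "delta", "beta", "alpha", "lam", "q", "eta",
    "omega", "K1", "K2", "K3",
    "zeta1", "zeta2", "zeta3", "zeta4", "zeta5", "theta",
    "mu1", "nu1", "mu2", "nu2", "q0", "q1", "q2",
]


def default_parameters(genotype: str = "nzbw",
                       preset: str = "default") -> ModelParameters:
    """Calibrated default parameters for a genotype.

    Parameters
    ----------
    genotype : {"nzbw", "wt"}
        The lupus-prone NZB/W genotype produces immune complexes from tissue
        damage (``mu2 > 0``); the wild-type contrast lacks the
        autoantibody-mediated pathway (``mu2 = 0``).
    preset : {"default", "uniform_feedback"}
        See module docstring.
    """
    genotype = genotype.lower()
    if genotype not in ("nzbw", "wt"):
        raise ValueError(f"unknown genotype {genotype!r}")
    p = ModelParameters()
    if preset == "uniform_feedback":
        p = p.replace(zeta3=p.zeta4, zeta5=p.zeta4)
    elif preset != "default":
        raise ValueError(f"unknown preset {preset!r}")
    if genotype == "wt":
        p = p.replace(mu2=0.0)
    return p


def apply_feedback_knockout(params: ModelParameters,
                            knockouts) -> ModelParameters:
    """Zero the feedback weights of the given loops (subset of F1..F5)."""
    knockouts = set(knockouts)
    unknown = knockouts - set(FEEDBACK_LOOPS)
    if unknown:
        raise ValueError(f"unknown feedback loops: {sorted(unknown)}")
    return params.replace(**{FEEDBACK_LOOPS[k]: 0.0 for k in knockouts})
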