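"""Generic building blocks for coupled cell--cytokine interaction models.

The modeling framework describes populations of immune-cell states ``x_i``
and tissue cytokines ``c_j`` interacting through four elementary processes,
each gated by cubic Hill functions of cell or cytokine levels:

* infiltration into the compartment, optionally delayed through an
  Erlang-distributed response time (a linear chain of first-order stages),
* activation / state-conversion fluxes between cell states,
* logistic proliferation up to a carrying capacity,
* first-order removal.

Cytokines are secreted by cells, removed by receptor-mediated endocytosis
(saturating in the cytokine level) and by first-order degradation.

All quantities are dimensionless "intrinsic units"; rates are per day.

The module provides the primitives (:func:`hill`, :func:`saturating_sum`,
:class:`DelayChain`) and a declarative :class:`NetworkSpec` from which a
right-hand-side function for :func:`scipy.integrate.solve_ivp` is assembled
with :func:`assemble_rhs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "hill",
    "saturating_sum",
    "DelayChain",
    "HillTerm",
    "Drive",
    "CellSpec",
    "CytokineSpec",
    "NetworkSpec",
    "assemble_rhs",
]

#: Hill exponent used throughout; every gating function in the model family
#: is cubic.
HILL_EXPONENT = 3


def hill(x, K):
    """Cubic Hill function ``x**3 / (K**3 + x**3)``.

    Parameters
    ----------
    x : float or ndarray
        Non-negative input level (cell abundance or cytokine concentration,
        intrinsic units).
    K : float
        Half-saturation constant, ``K > 0``.

    Returns
    -------
    float or ndarray
        Value in ``[0, 1)``; ``hill(K, K) == 0.5``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill() input must be non-negative")
    if K <= 0:
        raise ValueError("hill() half-saturation constant must be positive")
    x3 = x**HILL_EXPONENT
    out = x3 / (K**HILL_EXPONENT + x3)
    return float(out) if out.ndim == 0 else out


def saturating_sum(terms):
    """Sum of non-negative drive terms, capped at one.

    The cap is applied once to the summed drive (``min{Σ terms, 1}``), not
    term-wise, matching how composite activation and infiltration drives are
    bounded by the maximal per-capita rate.
    """
    terms = np.asarray(list(terms), dtype=float)
    if terms.size and np.any(terms < 0):
        raise ValueError("saturating_sum() terms must be non-negative")
    return float(min(terms.sum(), 1.0))


@dataclass
class DelayChain:
    """Erlang-distributed response time as a linear chain of ``n`` stages.

    The chain ``R[k, n]`` converts an input signal ``u(t)`` into a delayed
    output ``y_n(t)`` through

    .. math::

        \\dot y_1 = k (u - y_1), \\qquad
        \\dot y_i = k (y_{i-1} - y_i), \\quad i = 2 \\dots n .

    The impulse response of the chain is the Erlang density with rate ``k``
    and shape ``n`` (mean ``n/k``, standard deviation ``sqrt(n)/k``), and a
    constant input is reproduced exactly in steady state.  For ``n = 1`` the
    chain is a plain first-order lag.

    Attributes
    ----------
    rate : float
        Stage rate ``k`` in 1/day; must be positive.
    shape : int
        Number of sequential stages ``n >= 1``.
    """

    rate: float
    shape: int = 1

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("DelayChain rate must be positive")
        if int(self.shape) != self.shape or self.shape < 1:
            raise ValueError("DelayChain shape must be a positive integer")
        self.shape = int(self.shape)

    @property
    def mean_delay(self):
        """Mean response time ``n / k`` (days)."""
        return self.shape / self.rate

    @property
    def sd_delay(self):
        """Standard deviation of the response time, ``sqrt(n) / k`` (days)."""
        return np.sqrt(self.shape) / self.rate

    def rhs(self, y, u):
        """Chain state derivatives for state ``y`` (length ``n``), input ``u``."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.shape,):
            raise ValueError(
                f"chain state has length {y.size}, expected {self.shape}"
            )
        dy = np.empty_like(y)
        dy[0] = self.rate * (u - y[0])
        if self.shape > 1:
            dy[1:] = self.rate * (y[:-1] - y[1:])
        return dy

    def output(self, y):
        """Delayed signal: the last chain stage ``y_n``."""
        return np.asarray(y, dtype=float)[-1]

    def impulse_response(self, t):
        """Closed-form Erlang density ``k^n t^{n-1} e^{-kt} / (n-1)!``."""
        from scipy.stats import gamma as gamma_dist

        return gamma_dist.pdf(np.asarray(t, dtype=float), a=self.shape,
                              scale=1.0 / self.rate)


@dataclass
class HillTerm:
    """One weighted Hill gate ``weight * h[species, K]`` inside a drive."""

    species: str
    K: float
    weight: float = 1.0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError(f"Hill constant for {self.species!r} must be > 0")
        if self.weight < 0:
            raise ValueError(f"weight for {self.species!r} must be >= 0")


@dataclass
class Drive:
    """Composite gating drive: capped sum of weighted Hill gates.

    ``value = min{Σ_k w_k h[s_k, K_k], 1}`` if ``capped`` else the raw sum.
    An empty drive evaluates to zero.
    """

    terms: list = field(default_factory=list)
    capped: bool = True

    def __call__(self, levels):
        total = 0.0
        for term in self.terms:
            total += term.weight * hill(levels[term.species], term.K)
        return min(total, 1.0) if self.capped else total


@dataclass
class CellSpec:
    """One cell state in the network.

    Parameters
    ----------
    name : str
    infiltration : Drive or None
        Gating drive of the infiltration flux; flux is
        ``beta * (delayed drive)`` where the delay is the Erlang chain
        ``R[beta, chain_shape]`` (``chain_shape=0`` means undelayed).
    beta : float
        Maximal infiltration rate (1/day).
    chain_shape : int
        Erlang shape of the infiltration delay; 0 disables the chain.
    activation : list of (source, alpha, Drive or None)
        Conversion couplings ``alpha * drive * (x_source - x_self)``.
    gamma, proliferation : float, Drive or None
        Logistic proliferation ``gamma * drive * (1 - x/omega) * x``.
    omega : float
        Carrying capacity (ignored when gamma is 0).
    delta : float
        Removal rate (1/day).
    """

    name: str
    infiltration: Drive | None = None
    beta: float = 0.0
    chain_shape: int = 0
    activation: list = field(default_factory=list)
    gamma: float = 0.0
    proliferation: Drive | None = None
    omega: float = 1.0
    delta: float = 0.0


@dataclass
class CytokineSpec:
    """One cytokine: secreted by cells, endocytosed (saturating) and degraded.

    ``dc/dt = Σ_n q_n x_n - Σ_n lambda_n h[c, K] x_n - eta c``
    """

    name: str
    K: float = 1.0
    eta: float = 0.0
    secretion: dict = field(default_factory=dict)    # cell name -> q
    endocytosis: dict = field(default_factory=dict)  # cell name -> lambda


@dataclass
class NetworkSpec:
    """Declarative description of a coupled cell--cytokine network."""

    cells: list = field(default_factory=list)
    cytokines: list = field(default_factory=list)

    # -- validation -------------------------------------------------------
    def validate(self):
        names = [c.name for c in self.cells] + [c.name for c in self.cytokines]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names in NetworkSpec")
        known = set(names)
        for cell in self.cells:
            for rate in (cell.beta, cell.gamma, cell.delta):
                if rate < 0:
                    raise ValueError(f"negative rate in cell {cell.name!r}")
            if cell.omega <= 0:
                raise ValueError(f"non-positive capacity in cell {cell.name!r}")
            for drv in (cell.infiltration, cell.proliferation):
                if drv is not None:
                    for term in drv.terms:
                        if term.species not in known:
                            raise ValueError(
                                f"unknown species {term.species!r} "
                                f"referenced by cell {cell.name!r}"
                            )
            for src, alpha, drv in cell.activation:
                if src not in {c.name for c in self.cells}:
                    raise ValueError(
                        f"unknown activation source {src!r} in {cell.name!r}"
                    )
                if alpha < 0:
                    raise ValueError(f"negative activation rate in {cell.name!r}")
                if drv is not None:
                    for term in drv.terms:
                        if term.species not in known:
                            raise ValueError(
                                f"unknown species {term.species!r} in "
                                f"activation drive of {cell.name!r}"
                            )
        cellnames = {c.name for c in self.cells}
        for cyt in self.cytokines:
            if cyt.K <= 0:
                raise ValueError(f"non-positive Hill constant for {cyt.name!r}")
            if cyt.eta < 0:
                raise ValueError(f"negative degradation for {cyt.name!r}")
            for d in (cyt.secretion, cyt.endocytosis):
                for cn, rate in d.items():
                    if cn not in cellnames:
                        raise ValueError(
                            f"unknown cell {cn!r} coupled to cytokine {cyt.name!r}"
                        )
                    if rate < 0:
                        raise ValueError(f"negative rate on cytokine {cyt.name!r}")
            if cyt.eta == 0 and not cyt.endocytosis:
                raise ValueError(
                    f"cytokine {cyt.name!r} is neither degraded nor consumed"
                )
        return self

    # -- state layout -----------------------------------------------------
    # [cells...] ++ [chain stages, cell order] ++ [cytokines...]
    def state_names(self):
        names = [c.name for c in self.cells]
        for cell in self.cells:
            for i in range(cell.chain_shape):
                names.append(f"{cell.name}.y{i + 1}")
        names += [c.name for c in self.cytokines]
        return names

    def initial_state(self, values=None):
        """Zero state vector, optionally pre-filling named species."""
        names = self.state_names()
        s = np.zeros(len(names))
        if values:
            idx = {n: i for i, n in enumerate(names)}
            for k, v in values.items():
                s[idx[k]] = v
        return s

    # -- serialization ----------------------------------------------------
    def to_dict(self):
        def drive(d):
            if d is None:
                return None
            return {
                "capped": d.capped,
                "terms": [
                    {"species": t.species, "K": t.K, "weight": t.weight}
                    for t in d.terms
                ],
            }

        return {
            "cells": [
                {
                    "name": c.name,
                    "infiltration": drive(c.infiltration),
                    "beta": c.beta,
                    "chain_shape": c.chain_shape,
                    "activation": [
                        {"source": s, "alpha": a, "drive": drive(d)}
                        for s, a, d in c.activation
                    ],
                    "gamma": c.gamma,
                    "proliferation": drive(c.proliferation),
                    "omega": c.omega,
                    "delta": c.delta,
                }
                for c in self.cells
            ],
            "cytokines": [
                {
                    "name": c.name,
                    "K": c.K,
                    "eta": c.eta,
                    "secretion": dict(c.secretion),
                    "endocytosis": dict(c.endocytosis),
                }
                for c in self.cytokines
            ],
        }

    @classmethod
    def from_dict(cls, data):
        def drive(d):
            if d is None:
                return None
            return Drive(
                terms=[HillTerm(t["species"], t["K"], t["weight"])
                       for t in d["terms"]],
                capped=d["capped"],
            )

        cells = [
            CellSpec(
                name=c["name"],
                infiltration=drive(c["infiltration"]),
                beta=c["beta"],
                chain_shape=c["chain_shape"],
                activation=[(a["source"], a["alpha"], drive(a["drive"]))
                            for a in c["activation"]],
                gamma=c["gamma"],
                proliferation=drive(c["proliferation"]),
                omega=c["omega"],
                delta=c["delta"],
            )
            for c in data["cells"]
        ]
        cytokines = [
            CytokineSpec(
                name=c["name"], K=c["K"], eta=c["eta"],
                secretion=dict(c["secretion"]),
                endocytosis=dict(c["endocytosis"]),
            )
            for c in data["cytokines"]
        ]
        return cls(cells=cells, cytokines=cytokines).validate()

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def assemble_rhs(spec: NetworkSpec):
    """Build the derivative function ``f(t, state)`` for a validated spec.

    The state vector stacks cell levels, then all infiltration-chain stages
    (grouped per cell, in cell order), then cytokine levels; see
    :meth:`NetworkSpec.state_names` for the exact layout, which is part of
    the public contract.

    Cell dynamics::

        dx_i/dt = beta_i * y_out,i            (delayed infiltration, optional)
                + Σ_n alpha_in * drive * (x_n - x_i)
                + [gamma_i * drive * (1 - x_i/omega_i) - delta_i] * x_i

    Cytokine dynamics::

        dc_j/dt = Σ_n q_nj x_n - Σ_n lambda_nj h[c_j, K_j] x_n - eta_j c_j
    """
    spec.validate()
    names = spec.state_names()
    index = {n: i for i, n in enumerate(names)}
    n_state = len(names)
    cell_idx = {c.name: index[c.name] for c in spec.cells}

    def rhs(t, state):
        state = np.asarray(state, dtype=float)
        if state.shape != (n_state,):
            raise ValueError(
                f"state vector has length {state.size}, expected {n_state}"
            )
        levels = {n: max(state[i], 0.0) for n, i in index.items()}
        ds = np.zeros(n_state)
        for cell in spec.cells:
            i = cell_idx[cell.name]
            x = state[i]
            dx = 0.0
            if cell.infiltration is not None and cell.beta > 0:
                u = cell.infiltration(levels)
                if cell.chain_shape:
                    chain = DelayChain(cell.beta, cell.chain_shape)
                    j0 = index[f"{cell.name}.y1"]
                    y = state[j0:j0 + cell.chain_shape]
                    ds[j0:j0 + cell.chain_shape] = chain.rhs(y, u)
                    dx += cell.beta * y[-1]
                else:
                    dx += cell.beta * u
            for src, alpha, drv in cell.activation:
                gate = drv(levels) if drv is not None else 1.0
                dx += alpha * gate * (state[cell_idx[src]] - x)
            if cell.gamma > 0:
                gate = (cell.proliferation(levels)
                        if cell.proliferation is not None else 1.0)
                dx += cell.gamma * gate * (1.0 - x / cell.omega) * x
            dx -= cell.delta * x
            ds[i] += dx
        for cyt in spec.cytokines:
            j = index[cyt.name]
            c = state[j]
            dc = -cyt.eta * c
            gate = hill(max(c, 0.0), cyt.K)
            for cn, qn in cyt.secretion.items():
                dc += qn * state[cell_idx[cn]]
            for cn, ln in cyt.endocytosis.items():
                dc -= ln * gate * state[cell_idx[cn]]
            ds[j] += dc
        return ds

    return rhs
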