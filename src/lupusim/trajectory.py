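"""Trajectory container: a simulated time course with its provenance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time course of the full model state on a uniform weekly sub-grid.

    Attributes
    ----------
    t_weeks : ndarray
        Output times in weeks of age (monotone increasing).
    states : ndarray, shape (n_state, n_time)
        State matrix; rows ordered as ``names``.
    names : list of str
        State component names (``x1..x9``, chain stages, ``c1..c4``).
    params, schedule
        The exact parameter record and intervention schedule of the run.
    stopped_at : float or None
        Week at which integration was halted by the damage-threshold event,
        if it was.
    """

    t_weeks: np.ndarray
    states: np.ndarray
    names: list
    params: object = None
    schedule: object = None
    stopped_at: float | None = None

    def __post_init__(self):
        self.t_weeks = np.asarray(self.t_weeks, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.names), self.t_weeks.size):
            raise ValueError("states shape does not match names/times")

    def __getitem__(self, name):
        return self.states[self.names.index(name)]

    @property
    def damage(self):
        return self["x8"]

    @property
    def ifn(self):
        """Algebraic IFN-I trace along the trajectory."""
        from .model import ifn_level

        return ifn_level(self.t_weeks, self["x8"], self["x9"],
                         self.params, self.schedule)

    def at(self, t_week, name="x8"):
        """Linearly interpolated value of a component at a time point."""
        t = float(t_week)
        if not (self.t_weeks[0] <= t <= self.t_weeks[-1]):
            raise ValueError(
                f"t={t} outside trajectory range "
                f"[{self.t_weeks[0]}, {self.t_weeks[-1]}]"
            )
        return float(np.interp(t, self.t_weeks, self[name]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_weeks, every state column, and IFN-I ``c``."""
        data = {"time_weeks": self.t_weeks}
        for i, n in enumerate(self.names):
            data[n] = self.states[i]
        data["c"] = self.ifn
        return pd.DataFrame(data)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params=None, schedule=None):
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("time_weeks", "c")]
        return cls(t_weeks=df["time_weeks"].to_numpy(),
                   states=df[names].to_numpy().T, names=names,
                   params=params, schedule=schedule)
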