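"""Telegraph (dichotomous) process of acute inflammatory events.

Spontaneous acute inflammatory episodes are modelled as a two-state
process switching between an off-state and an on-state.  The off->on
reaction fires as a Poisson process with rate ``k_off`` (the rate of
*leaving* the off-state -- the naming follows the reaction it terminates,
and is kept here for consistency with the model's published description);
the on->off recovery is a multi-step response-time reaction ``R[k_on,
n_on]``, so on-durations are Erlang distributed with mean ``tau_on = n_on /
k_on`` and coefficient of variation ``1 / sqrt(n_on)``.

Paths are sampled exactly with the stochastic simulation (Gillespie)
algorithm, starting in the off-state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DAYS_PER_WEEK

__all__ = ["TelegraphConfig", "TelegraphPath", "sample_telegraph"]


@dataclass(frozen=True)
class TelegraphConfig:
    """Rates of the acute-event telegraph process (per day).

    Attributes
    ----------
    k_off : float
        Rate of the off->on transition (expected off-duration
        ``tau_off = 1/k_off``).
    k_on : float
        Stage rate of the on->off recovery chain.
    n_on : int
        Number of recovery stages; on-durations are Erlang(k_on, n_on).
    xi : float
        Immune-complex production scale of an active event, in (0, 1); the
        immune-complex equation gains a source ``mu2 * xi`` while an event
        is on.
    """

    k_off: float
    k_on: float
    n_on: int = 1
    xi: float = 0.5

    def __post_init__(self):
        if self.k_off < 0:
            raise ValueError("k_off must be non-negative")
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")
        if int(self.n_on) != self.n_on or self.n_on < 1:
            raise ValueError("n_on must be a positive integer")
        object.__setattr__(self, "n_on", int(self.n_on))
        if not 0.0 <= self.xi < 1.0:
            raise ValueError("xi must lie in [0, 1)")

    # Derived event-duration statistics (days)
    @property
    def tau_on(self):
        """Mean on-duration ``n_on / k_on``."""
        return self.n_on / self.k_on

    @property
    def sigma_on(self):
        """Standard deviation of the on-duration, ``sqrt(n_on) / k_on``."""
        return np.sqrt(self.n_on) / self.k_on

    @property
    def cv_on(self):
        """Coefficient of variation of on-durations, ``1/sqrt(n_on)``."""
        return 1.0 / np.sqrt(self.n_on)

    @property
    def tau_off(self):
        """Mean off-duration ``1 / k_off``."""
        if self.k_off == 0:
            return np.inf
        return 1.0 / self.k_off

    @property
    def on_fraction(self):
        """Long-run expected fraction of time spent in the on-state."""
        return self.tau_on / (self.tau_on + self.tau_off)

    @classmethod
    def from_durations(cls, tau_on_weeks, tau_off_weeks, cv=1.0, xi=0.5):
        """Build a config from mean durations in weeks and an on-duration CV.

        The CV is realised through the Erlang shape ``n_on =
        round(1/cv**2)`` (so only values ``1/sqrt(integer)`` are exactly
        representable; the nearest integer shape is used).
        """
        n_on = max(1, round(1.0 / cv**2))
        tau_on = tau_on_weeks * DAYS_PER_WEEK
        tau_off = tau_off_weeks * DAYS_PER_WEEK
        return cls(k_off=1.0 / tau_off, k_on=n_on / tau_on, n_on=n_on, xi=xi)

    def to_dict(self):
        return {"k_off": self.k_off, "k_on": self.k_on,
                "n_on": self.n_on, "xi": self.xi}

    @classmethod
    def from_dict(cls, data):
        unknown = set(data) - {"k_off", "k_on", "n_on", "xi"}
        if unknown:
            raise ValueError(f"unknown telegraph keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class TelegraphPath:
    """Realisation of the event process: switching times in weeks.

    ``switch_times`` are the strictly increasing times at which the state
    flips, starting from the off-state at the path start; even-indexed
    switches are off->on.
    """

    switch_times: np.ndarray
    start_week: float
    horizon_week: float

    def __post_init__(self):
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        if self.switch_times.size and np.any(np.diff(self.switch_times) <= 0):
            raise ValueError("switching times must be strictly increasing")

    def state_at(self, t_weeks):
        """Event state (0/1) at the given week(s)."""
        t = np.asarray(t_weeks, dtype=float)
        n_before = np.searchsorted(self.switch_times, t, side="right")
        out = (n_before % 2).astype(float)
        return float(out) if out.ndim == 0 else out

    def on_time(self):
        """Total on-time in weeks over the path horizon."""
        times = np.concatenate(
            [[self.start_week], self.switch_times, [self.horizon_week]]
        )
        spans = np.diff(times)
        return float(spans[1::2].sum())

    def on_durations(self):
        """Completed on-episode durations (weeks)."""
        st = self.switch_times
        n = (st.size // 2) * 2
        return st[1:n:2] - st[0:n:2]

    def to_frame(self) -> pd.DataFrame:
        """Two-column step function (time_weeks, state) for serialization."""
        times = [self.start_week, *self.switch_times, self.horizon_week]
        states = [self.state_at(self.start_week),
                  *((i + 1) % 2 for i in range(self.switch_times.size)),
                  self.state_at(self.horizon_week)]
        return pd.DataFrame({"time_weeks": times, "state": states})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def sample_telegraph(config: TelegraphConfig, horizon: float,
                     rng, start: float = 12.0) -> TelegraphPath:
    """Draw one exact SSA realisation of the event process.

    Off-durations are exponential with rate ``k_off``; on-durations are the
    sum of ``n_on`` exponential stages with rate ``k_on`` (Erlang), which is
    the exact stochastic counterpart of the multi-step recovery reaction.

    Parameters
    ----------
    horizon : float
        Path end, weeks of age.
    rng : numpy.random.Generator or int
        Random generator (or a seed).
    start : float
        Path start, weeks of age; the process starts in the off-state.
    """
    if horizon <= start:
        raise ValueError("horizon must exceed start")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = start
    switches = []
    while True:
        if config.k_off == 0:
            break
        t += rng.exponential(1.0 / config.k_off) / DAYS_PER_WEEK
        if t >= horizon:
            break
        switches.append(t)  # off -> on
        t += rng.gamma(config.n_on, 1.0 / config.k_on) / DAYS_PER_WEEK
        if t >= horizon:
            break
        switches.append(t)  # on -> off
    return TelegraphPath(np.asarray(switches), start, horizon)
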