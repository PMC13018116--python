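"""Hybrid deterministic--stochastic model: acute events driving immune
complexes.

Between event switches the deterministic model is integrated unchanged
except for the immune-complex equation, which gains an event source:

``dx9/dt = mu2 * (xi * X_on + y_out) - nu2 * x9``

where ``X_on`` is the telegraph state and ``y_out`` the damage-driven chain
output.  The solver is restarted at every switch so the discontinuous
forcing is never smoothed across, and the state is continuous there.
Events start (in the off-state) at the reporting start week; the burn-in is
deterministic.
"""

from __future__ import annotations

import numpy as np

from . import model
from .model import START_WEEK, simulate
from .params import ModelParameters
from .schedule import InterventionSchedule
from .telegraph import TelegraphConfig, TelegraphPath, sample_telegraph
from .trajectory import Trajectory

__all__ = ["simulate_hybrid", "t_stoch"]


def simulate_hybrid(params: ModelParameters, schedule: InterventionSchedule,
                    config: TelegraphConfig, seed, horizon: float = 60.0,
                    grid: float = 0.1, path: TelegraphPath | None = None,
                    stop_at_damage: float | None = None,
                    rtol: float = 1e-8, atol: float = 1e-11):
    """Run one hybrid realisation; returns ``(Trajectory, TelegraphPath)``.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`; with a
    fixed seed the switching times and the trajectory are reproducible
    bit-for-bit.  A pre-sampled ``path`` may be supplied instead (``seed``
    is then ignored).
    """
    if path is None:
        path = sample_telegraph(config, horizon, seed, start=START_WEEK)
    y0 = model.initial_state(params, schedule)
    bounds = [START_WEEK, *path.switch_times[
        (path.switch_times > START_WEEK) & (path.switch_times < horizon)],
        horizon]
    ts, ys = [], []
    s = y0
    stopped = None
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        xon = config.xi * path.state_at(0.5 * (lo + hi))
        seg = simulate(params, schedule, horizon=hi, grid=grid, y0=s,
                       start=lo, xon_term=xon, rtol=rtol, atol=atol,
                       stop_at_damage=stop_at_damage)
        ts.append(seg.t_weeks)
        ys.append(seg.states)
        s = seg.states[:, -1]
        if seg.stopped_at is not None:
            stopped = seg.stopped_at
            break
    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    traj = Trajectory(t_weeks=t[keep], states=y[:, keep],
                      names=model.state_names(params.n_ic),
                      params=params, schedule=schedule, stopped_at=stopped)
    return traj, path


def t_stoch(hybrid_esrd_week, reference_esrd_week):
    """Stochastic onset-delay output: hybrid minus reference time-to-ESRD.

    Either argument may be ``None`` (ESRD not reached within the horizon);
    the result is then ``None`` (a censored observation), never a number.
    """
    if reference_esrd_week is None:
        raise ValueError("reference time-to-ESRD is undefined")
    if hybrid_esrd_week is None:
        return None
    return float(hybrid_esrd_week) - float(reference_esrd_week)
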