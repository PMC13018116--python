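"""The lupus-nephritis cell-interaction model: equations and simulator.

State variables (dimensionless intrinsic units):

========  =======================================================
``x1``    resting tissue helper ILC ("tILC low")
``x2``    activated tissue helper ILC (tILC)
``x3``    monocyte-derived macrophages in tissue (MOMA)
``x4``    lupus-associated intermediate parietal epithelial cells
``x5``    vessel-associated NK cells (vNK)
``x6``    monocytes in vessels (MO)
``x7``    lupus-associated capillary endothelial cells (cEC)
``x8``    tissue damage
``x9``    immune-complex deposits (IC; absent in wild type)
``y1..``  stages of the damage-driven IC production chain
``c1..4`` tissue cytokines coupling MOMA<->iPEC and MO<->cEC
========  =======================================================

Type-I interferon ``c`` is a bounded algebraic (quasi-steady-state)
concentration combining a baseline level, the poly(I:C) stimulus and
damage/immune-complex-induced release.

Internally time is measured in days (all rates are per day); the public
interface uses weeks of age with a fixed conversion factor of 7.  Reported
trajectories start at week 12 (the age of unstimulated control animals)
after an eight-week burn-in from a small tILC seed, so that the genotypes
may already drift apart before stimulation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParameters
from .schedule import InterventionSchedule
from .trajectory import Trajectory

__all__ = [
    "DAYS_PER_WEEK",
    "START_WEEK",
    "BURNIN_WEEKS",
    "state_names",
    "ifn_level",
    "lupus_rhs",
    "initial_state",
    "simulate",
]

DAYS_PER_WEEK = 7.0
#: Week of age at which reported trajectories start.
START_WEEK = 12.0
#: Length of the pre-report burn-in from the tILC seed.
BURNIN_WEEKS = 8.0

_CELLS = ["x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9"]
_CYTOKINES = ["c1", "c2", "c3", "c4"]


def state_names(n_ic: int):
    """Ordered state-vector component names (chain stages after ``x9``)."""
    return (_CELLS + [f"y{i + 1}" for i in range(n_ic)] + _CYTOKINES)


# -- packed-parameter right-hand side ----------------------------------------
# P layout (see _pack); control scalars are resolved per integration segment
# so the discontinuous indicator functions never cross a solver step.

_PKEYS = ["gamma", "delta", "beta", "alpha", "lam", "q", "eta", "omega",
          "K1", "K2", "K3", "zeta1", "zeta2", "zeta3", "zeta4", "zeta5",
          "theta", "mu1", "nu1", "mu2", "nu2", "q0", "q1", "q2"]


def _pack(params: ModelParameters, schedule: InterventionSchedule):
    p = params
    if schedule.genotype == "wt":
        p = p.replace(mu2=0.0)
    if schedule.feedback_knockouts:
        from .params import apply_feedback_knockout

        p = apply_feedback_knockout(p, schedule.feedback_knockouts)
    return np.array([getattr(p, k) for k in _PKEYS], dtype=float), p.n_ic


def _rhs_core(t, s, P, n_ic, ind, om_fac, b5_fac, xon_term):
    (gamma, delta, beta, alpha, lam, q, eta, omega,
     K1, K2, K3, z1, z2, z3, z4, z5,
     theta, mu1, nu1, mu2, nu2, q0, q1, q2) = P

    K13, K23, K33 = K1**3, K2**3, K3**3

    x1 = s[0] if s[0] > 0.0 else 0.0
    x2 = s[1] if s[1] > 0.0 else 0.0
    x3 = s[2] if s[2] > 0.0 else 0.0
    x4 = s[3] if s[3] > 0.0 else 0.0
    x5 = s[4] if s[4] > 0.0 else 0.0
    x6 = s[5] if s[5] > 0.0 else 0.0
    x7 = s[6] if s[6] > 0.0 else 0.0
    x8 = s[7] if s[7] > 0.0 else 0.0
    x9 = s[8] if s[8] > 0.0 else 0.0

    h_x2 = x2**3 / (K23 + x2**3)
    h_x8 = x8**3 / (K23 + x8**3)
    h_x9 = x9**3 / (K23 + x9**3)
    h_x6 = x6**3 / (K33 + x6**3)

    # algebraic IFN-I
    c = q0 + q1 * ind + q2 * (z4 * h_x9 + z1 * h_x8)
    if c > 1.0:
        c = 1.0
    h_c_K1 = c**3 / (K13 + c**3)

    nc = 9 + n_ic
    c1 = s[nc] if s[nc] > 0.0 else 0.0
    c2 = s[nc + 1] if s[nc + 1] > 0.0 else 0.0
    c3 = s[nc + 2] if s[nc + 2] > 0.0 else 0.0
    c4 = s[nc + 3] if s[nc + 3] > 0.0 else 0.0
    h_c1 = c1**3 / (K23 + c1**3)
    h_c2 = c2**3 / (K23 + c2**3)
    h_c3 = c3**3 / (K23 + c3**3)
    h_c4 = c4**3 / (K23 + c4**3)

    ds = np.empty_like(s)

    # tILC activation drive (capped at the maximal per-capita rate)
    act = h_c_K1 + z2 * h_x8
    if act > 1.0:
        act = 1.0
    T = s[0] + s[1]
    # logistic pool growth; when the pool exceeds the (possibly depleted)
    # capacity the contraction acts per-capita on the resting pool so that
    # x1 cannot be driven negative
    cap = 1.0 - T / (omega * om_fac)
    grow = gamma * cap * (T if cap >= 0.0 else x1)
    ds[0] = grow - alpha * act * s[0] - delta * s[0]
    ds[1] = alpha * act * s[0] - delta * s[1]

    # MOMA: gated infiltration plus cytokine-gated proliferation
    d3 = h_x2 + z3 * h_x9
    if d3 > 1.0:
        d3 = 1.0
    ds[2] = beta * d3 + gamma * h_c2 * s[2] - delta * s[2]

    # iPEC: basal influx and c1-gated growth up to capacity
    ds[3] = (beta + gamma * h_c1 * s[3]) * (1.0 - s[3] / omega) - delta * s[3]

    # vNK: monocyte-gated infiltration (depletable)
    ds[4] = beta * h_x6 * b5_fac - delta * s[4]

    # MO: IC- and IFN-gated infiltration plus c4-gated proliferation
    d6 = z5 * h_x9 + theta * h_c_K1
    if d6 > 1.0:
        d6 = 1.0
    ds[5] = beta * d6 + gamma * h_c4 * s[5] - delta * s[5]

    # cEC: basal influx and c3-gated growth up to capacity
    ds[6] = (beta + gamma * h_c3 * s[6]) * (1.0 - s[6] / omega) - delta * s[6]

    # tissue damage from effector burden
    ds[7] = mu1 * (x3 + x5 + x6) - nu1 * s[7]

    # immune complexes: delayed damage-driven production (+ acute events)
    ds[8] = mu2 * (xon_term + s[9 + n_ic - 1]) - nu2 * s[8]
    ds[9] = mu2 * (x8 - s[9])
    for i in range(1, n_ic):
        ds[9 + i] = mu2 * (s[8 + i] - s[9 + i])

    # tissue cytokines: secretion, saturating endocytosis, degradation
    ds[nc] = q * x3 - lam * h_c1 * x4 - eta * s[nc]
    ds[nc + 1] = q * x4 - lam * h_c2 * x3 - eta * s[nc + 1]
    ds[nc + 2] = q * x6 - lam * h_c3 * x7 - eta * s[nc + 2]
    ds[nc + 3] = q * x7 - lam * h_c4 * x6 - eta * s[nc + 3]
    return ds


try:  # pragma: no cover - exercised implicitly
    import numba

    _rhs_fast = numba.njit(cache=False)(_rhs_core)
    _rhs_fast(0.0, np.zeros(16), np.ones(24), 3, 0.0, 1.0, 1.0, 0.0)
except Exception:  # pragma: no cover
    _rhs_fast = _rhs_core


def ifn_level(t_weeks, x8, x9, params: ModelParameters,
              schedule: InterventionSchedule):
    """Quasi-steady-state type-I interferon concentration in [0, 1].

    ``c = min{q0 + q1*1(t in stimulus window)
              + q2*(zeta4 h[x9,K2] + zeta1 h[x8,K2]), 1}``

    Feedback knockouts recorded on the schedule zero the corresponding
    weight.
    """
    from .framework import hill

    p = params
    if schedule.feedback_knockouts:
        from .params import apply_feedback_knockout

        p = apply_feedback_knockout(p, schedule.feedback_knockouts)
    t_weeks = np.asarray(t_weeks, dtype=float)
    if p.q1 and schedule.polyic_window is not None:
        lo, hi = schedule.polyic_window
        ind = ((t_weeks >= lo) & (t_weeks <= hi)).astype(float)
    else:
        ind = np.zeros_like(t_weeks)
    x8 = np.maximum(np.asarray(x8, dtype=float), 0.0)
    x9 = np.maximum(np.asarray(x9, dtype=float), 0.0)
    c = (p.q0 + p.q1 * ind
         + p.q2 * (p.zeta4 * hill(x9, p.K2) + p.zeta1 * hill(x8, p.K2)))
    out = np.minimum(c, 1.0)
    return float(out) if out.ndim == 0 else out


def lupus_rhs(t_weeks, state, params: ModelParameters,
              schedule: InterventionSchedule, xon_term: float = 0.0):
    """Full model derivatives at a time point (per-day rates).

    This is the reference entry point for a single evaluation; the
    simulator resolves the piecewise-constant controls per segment instead
    of per call.  ``xon_term`` is the acute-inflammation forcing
    ``xi * X_on`` of the hybrid model (zero in the deterministic model).
    """
    P, n_ic = _pack(params, schedule)
    state = np.asarray(state, dtype=float)
    if state.shape != (13 + n_ic,):
        raise ValueError(
            f"state vector has length {state.size}, expected {13 + n_ic}"
        )
    if np.any(state < -1e-6):
        raise ValueError("state has negative components beyond tolerance")
    ind = 1.0 if schedule.polyic_active(t_weeks) else 0.0
    om_fac = b5_fac = 1.0
    if schedule.depletion_active(t_weeks):
        if "tILC" in schedule.depletion_targets:
            om_fac = 1.0 - schedule.depletion_strength
        if "vNK" in schedule.depletion_targets:
            b5_fac = 1.0 - schedule.depletion_strength
    return _rhs_core(t_weeks * DAYS_PER_WEEK, state, P, n_ic, ind,
                     om_fac, b5_fac, xon_term)


def _segments(schedule: InterventionSchedule, t0: float, t1: float,
              extra=()):
    """Breakpoints of the piecewise-constant controls inside [t0, t1]."""
    pts = {t0, t1}
    if schedule.polyic_window:
        pts.update(schedule.polyic_window)
    if schedule.depletion_targets:
        pts.update(schedule.depletion_window)
    pts.update(extra)
    return sorted(p for p in pts if t0 <= p <= t1)


def _controls(schedule: InterventionSchedule, t_mid: float):
    ind = 1.0 if schedule.polyic_active(t_mid) else 0.0
    om_fac = b5_fac = 1.0
    if schedule.depletion_active(t_mid):
        if "tILC" in schedule.depletion_targets:
            om_fac = 1.0 - schedule.depletion_strength
        if "vNK" in schedule.depletion_targets:
            b5_fac = 1.0 - schedule.depletion_strength
    return ind, om_fac, b5_fac


def initial_state(params: ModelParameters, schedule: InterventionSchedule,
                  seed_fraction: float = 0.01, rtol: float = 1e-8,
                  atol: float = 1e-11):
    """State at the reporting start (week 12) after the burn-in.

    All effector populations start at zero; the resting tILC pool is seeded
    at ``seed_fraction * omega`` (an exactly-zero pool would be a degenerate
    fixed point of the logistic growth) and the system is integrated for
    eight weeks under baseline conditions, which relaxes the tILC pool to
    its carrying-capacity steady state.  Under the NZB/W genotype the
    immune-complex ratchet already accumulates slowly during the burn-in,
    so the two genotypes differ (slightly) at week 12.
    """
    if not 0 < seed_fraction < 1:
        raise ValueError("seed_fraction must lie in (0, 1)")
    P, n_ic = _pack(params, schedule)
    s = np.zeros(13 + n_ic)
    s[0] = seed_fraction * params.omega
    t0 = (START_WEEK - BURNIN_WEEKS) * DAYS_PER_WEEK
    t1 = START_WEEK * DAYS_PER_WEEK
    # baseline controls: the burn-in precedes every intervention window
    sol = solve_ivp(_rhs_fast, (t0, t1), s, method="LSODA",
                    args=(P, n_ic, 0.0, 1.0, 1.0, 0.0),
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"burn-in integration failed: {sol.message}")
    return sol.y[:, -1]


def simulate(params: ModelParameters, schedule: InterventionSchedule,
             horizon: float = 60.0, grid: float = 0.1,
             rtol: float = 1e-8, atol: float = 1e-11,
             stop_at_damage: float | None = None,
             xon_term: float = 0.0, y0=None,
             start: float = START_WEEK) -> Trajectory:
    """Integrate the model and return a :class:`Trajectory`.

    Parameters
    ----------
    horizon : float
        Final week of age.
    grid : float
        Output grid step in weeks (uniform).
    stop_at_damage : float, optional
        If given, integration halts (by event detection) when the damage
        variable first reaches this value -- used to stop runs at the
        end-stage renal disease reference level.
    xon_term : float
        Constant acute-event forcing ``xi * X_on`` (hybrid model).
    y0 : ndarray, optional
        Initial state at ``start``; default is :func:`initial_state`.
    """
    if horizon <= start:
        raise ValueError("horizon must exceed the start week")
    P, n_ic = _pack(params, schedule)
    if y0 is None:
        y0 = initial_state(params, schedule)
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (13 + n_ic,):
        raise ValueError("initial state has wrong length")

    event = None
    if stop_at_damage is not None:
        def event(t, s, *a):
            return s[7] - stop_at_damage
        event.terminal = True
        event.direction = 1.0

    ts, ys = [], []
    s = y0
    stopped = None
    segs = _segments(schedule, start, horizon)
    for lo, hi in zip(segs[:-1], segs[1:]):
        ind, om_fac, b5_fac = _controls(schedule, 0.5 * (lo + hi))
        t_eval = np.arange(lo, hi, grid)
        sol = solve_ivp(
            _rhs_fast, (lo * DAYS_PER_WEEK, hi * DAYS_PER_WEEK), s,
            method="LSODA", t_eval=t_eval * DAYS_PER_WEEK,
            args=(P, n_ic, ind, om_fac, b5_fac, xon_term),
            rtol=rtol, atol=atol, events=event, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{lo}, {hi}] weeks: {sol.message}; "
                f"last state: {s}"
            )
        ts.append(sol.t / DAYS_PER_WEEK)
        ys.append(sol.y)
        if event is not None and sol.t_events[0].size:
            stopped = sol.t_events[0][0] / DAYS_PER_WEEK
            ts.append([stopped])
            ys.append(sol.y_events[0].T)
            break
        # segment endpoint (t_eval excludes hi to avoid duplicates)
        end = solve_ivp(
            _rhs_fast, (sol.t[-1], hi * DAYS_PER_WEEK), sol.y[:, -1],
            method="LSODA",
            args=(P, n_ic, ind, om_fac, b5_fac, xon_term),
            rtol=rtol, atol=atol,
        )
        s = end.y[:, -1]
    else:
        ts.append([segs[-1]])
        ys.append(s[:, None])

    t = np.concatenate([np.asarray(x, dtype=float) for x in ts])
    y = np.concatenate(ys, axis=1)
    return Trajectory(
        t_weeks=t, states=y, names=state_names(n_ic),
        params=params, schedule=schedule, stopped_at=stopped,
    )
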