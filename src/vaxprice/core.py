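"""Vaccinated-SIRD epidemic dynamics coupled to Lucas-tree asset pricing.

The model world: a unit population moves between Susceptible, Infected,
Recovered and Deceased compartments in discrete time.  Susceptibles are
infected at rate ``delta * I_t`` and vaccinated (moved straight to Recovered)
at rate ``tau_t``; infecteds recover with probability ``gamma`` and die with
probability ``rho``.  Each individual's health state follows the induced
time-inhomogeneous Markov chain.  On the economic side every individual owns
``k`` identical Lucas trees paying dividend ``d_t``, receives a
state-contingent labour endowment ``w(theta)`` (infected individuals earn
less) and possibly a uniform unstorable cash handout ``b_t``.  With
non-storable income, equilibrium consumption is ``c_t(theta) = b_t + d_t*k +
w(theta)`` for the living and zero for the deceased.  When nearly everyone is
still susceptible, the equilibrium tree price seen by a susceptible individual
is approximately ``p_t = m / u'(c_t(S))`` where ``m`` discounts future
dividends weighted by the expected marginal utility of consumption along the
individual's health-state chain.

Because infection cuts labour income, susceptibles carry a precautionary
saving motive that props up the asset price; vaccination removes infection
risk and therefore lowers the price.  This module computes the price, its
finite-difference sensitivity to the vaccination rate, and the comparative
statics in the income gap and in cash handouts, together with the per-horizon
decomposition of dm/dtau whose leading term vanishes because susceptible and
recovered endowments coincide.

Layout (in the order the method runs):

1. constants, logging, errors
2. epidemic core   -- compartment recursion and per-period transition kernel
3. economy pricing -- consumption, utility, the pricing series m, the price,
                      the dm/dtau decomposition, Euler residual, Monte-Carlo
                      path oracle
4. comparative statics -- finite-difference dp/dtau (partial and full modes),
                      income-gap and handout sweeps, proposition report
5. interface / IO  -- config schema, presets, output serialization
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "STATES",
    "S_IDX",
    "I_IDX",
    "R_IDX",
    "D_IDX",
    "DEFAULT_SEED",
    "DEFAULT_TOL",
    "DEFAULT_MAX_HORIZON",
    "DEFAULT_STEP",
    "InfeasibleParameterError",
    "ConvergenceError",
    "ConfigError",
    "EpidemicParams",
    "EpidemicState",
    "Trajectory",
    "TransitionMatrix",
    "validate_params",
    "step",
    "simulate",
    "transition_matrix",
    "UtilitySpec",
    "EconomyParams",
    "PriceResult",
    "DeltaDecomposition",
    "MonteCarloResult",
    "consumption",
    "marginal_utility",
    "propagate",
    "m_partial_sum",
    "m_series",
    "price",
    "delta_decomposition",
    "euler_residual",
    "monte_carlo_m",
    "Scenario",
    "SweepResult",
    "dprice_dtau",
    "gap_sweep",
    "handout_sweep",
    "proposition_report",
    "RunConfig",
    "load_config",
    "loads_config",
    "preset",
    "preset_names",
    "scenario_from_config",
    "write_outputs",
]

__version__ = "0.1.0"

# ---------------------------------------------------------------------------
# 1. constants, logging, errors
# ---------------------------------------------------------------------------

#: Fixed health-state ordering used by every array in this module.
STATES: tuple[str, str, str, str] = ("S", "I", "R", "D")
S_IDX, I_IDX, R_IDX, D_IDX = 0, 1, 2, 3
_ALIVE = (S_IDX, I_IDX, R_IDX)

DEFAULT_SEED = 20220421
DEFAULT_TOL = 1e-10
DEFAULT_MAX_HORIZON = 2000
DEFAULT_STEP = 1e-4  # finite-difference step h

logger = logging.getLogger("vaxprice")


class InfeasibleParameterError(ValueError):
    """A parameter combination would make some transition probability leave [0, 1]."""


class ConvergenceError(RuntimeError):
    """The pricing series could not be truncated below tolerance within max_horizon."""

    def __init__(self, message: str, achieved_bound: float, horizon: int):
        super().__init__(message)
        self.achieved_bound = achieved_bound
        self.horizon = horizon


class ConfigError(ValueError):
    """Configuration file failed schema validation."""


def _as_schedule(value: Union[float, Sequence[float]]) -> tuple[float, ...]:
    if isinstance(value, (int, float)):
        return (float(value),)
    out = tuple(float(v) for v in value)
    if not out:
        raise ValueError("schedule must be non-empty")
    return out


def _schedule_at(schedule: tuple[float, ...], t: int) -> float:
    # schedules shorter than the horizon repeat their last value
    return schedule[t] if t < len(schedule) else schedule[-1]


# ---------------------------------------------------------------------------
# 2. epidemic core
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpidemicParams:
    """Per-period epidemic rates.

    Parameters
    ----------
    delta : float
        Transmission coefficient; a susceptible meets infection risk
        ``delta * I_t`` per period.
    gamma : float
        Per-period recovery probability of an infected individual.
    rho : float
        Per-period death probability of an infected individual.
    tau_schedule : float or sequence of float
        Per-period vaccination rates tau_t applied to susceptibles.  A scalar
        means a constant schedule; a schedule shorter than the simulated
        horizon is extended by repeating its last value.
    """

    delta: float
    gamma: float
    rho: float
    tau_schedule: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_schedule", _as_schedule(self.tau_schedule))
        if self.delta < 0:
            raise InfeasibleParameterError(f"delta must be >= 0, got {self.delta}")
        if not 0 < self.gamma <= 1:
            raise InfeasibleParameterError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.rho < 0:
            raise InfeasibleParameterError(f"rho must be >= 0, got {self.rho}")
        if self.gamma + self.rho > 1:
            raise InfeasibleParameterError(
                f"gamma+rho exceeds 1: gamma={self.gamma}, rho={self.rho}"
            )
        for k, tau in enumerate(self.tau_schedule):
            if tau < 0:
                raise InfeasibleParameterError(f"tau_schedule[{k}] must be >= 0, got {tau}")

    def tau_at(self, t: int) -> float:
        """Vaccination rate in period ``t`` (schedule repeats its last value)."""
        return _schedule_at(self.tau_schedule, t)


@dataclass(frozen=True)
class EpidemicState:
    """Compartment shares (population normalised to 1) at one period."""

    s: float
    i: float
    r: float
    d: float = 0.0
    t: int = 0

    def __post_init__(self) -> None:
        for name in ("s", "i", "r", "d"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"compartment share {name} is negative: {getattr(self, name)}")
        total = self.s + self.i + self.r + self.d
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment shares must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.i, self.r, self.d], dtype=float)


def validate_params(params: EpidemicParams, trajectory_or_state=None) -> EpidemicParams:
    """Check feasibility: gamma+rho <= 1 and tau_t + delta*I_t <= 1 for the states used.

    The transition probabilities are affine in tau and I, so these two
    inequalities are exactly what keeps every kernel entry inside [0, 1].
    Raises :class:`InfeasibleParameterError` naming the violated constraint
    and period.
    """
    # gamma+rho and sign constraints are enforced by the dataclass already;
    # re-check here so externally mutated inputs fail loudly too.
    if params.gamma + params.rho > 1:
        raise InfeasibleParameterError(
            f"gamma+rho exceeds 1: gamma={params.gamma}, rho={params.rho}"
        )
    states: Sequence[EpidemicState]
    if trajectory_or_state is None:
        states = ()
    elif isinstance(trajectory_or_state, EpidemicState):
        states = (trajectory_or_state,)
    elif isinstance(trajectory_or_state, Trajectory):
        states = tuple(trajectory_or_state.states)
    else:
        states = tuple(trajectory_or_state)
    for st in states:
        tau = params.tau_at(st.t)
        if tau + params.delta * st.i > 1 + 1e-12:
            raise InfeasibleParameterError(
                f"tau + delta*I exceeds 1 at period {st.t}: "
                f"tau={tau}, delta={params.delta}, I={st.i}"
            )
    return params


def step(
    state: EpidemicState, params: EpidemicParams, tau: Optional[float] = None
) -> EpidemicState:
    """One period of the vaccinated-SIRD recursion.

    S' = (1 - tau - delta*I) S,  I' = (1 + delta*S - gamma - rho) I,
    R' = R + gamma*I + tau*S,    D' = D + rho*I.
    Vaccination and infection are simultaneous competing outflows from S.
    """
    if tau is None:
        tau = params.tau_at(state.t)
    if tau < 0:
        raise InfeasibleParameterError(f"tau must be >= 0, got {tau} at period {state.t}")
    if tau + params.delta * state.i > 1 + 1e-12:
        raise InfeasibleParameterError(
            f"tau + delta*I exceeds 1 at period {state.t}: "
            f"tau={tau}, delta={params.delta}, I={state.i}"
        )
    s, i, r, d = state.s, state.i, state.r, state.d
    # at the feasibility boundary the complement can underflow to -eps
    s_next = max(1.0 - tau - params.delta * i, 0.0) * s
    i_next = (1.0 + params.delta * s - params.gamma - params.rho) * i
    r_next = r + params.gamma * i + tau * s
    d_next = d + params.rho * i
    return EpidemicState(s=s_next, i=i_next, r=r_next, d=d_next, t=state.t + 1)


@dataclass
class Trajectory:
    """Ordered compartment states for t = 0..T, extendable on demand.

    ``state_at(t)`` lazily extends the path with the stored parameters, so
    pricing routines may look arbitrarily far ahead without the caller
    pre-committing to a horizon.
    """

    states: list[EpidemicState]
    params: EpidemicParams
    _extension_logged: bool = field(default=False, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, idx: int) -> EpidemicState:
        return self.states[idx]

    def __iter__(self):
        return iter(self.states)

    def state_at(self, t: int) -> EpidemicState:
        if t < 0:
            raise IndexError("period index must be >= 0")
        n_sched = len(self.params.tau_schedule)
        while len(self.states) <= t:
            if n_sched > 1 and len(self.states) > n_sched and not self._extension_logged:
                logger.info(
                    "tau schedule (length %d) shorter than requested horizon; "
                    "repeating its last value", n_sched,
                )
                self._extension_logged = True
            self.states.append(step(self.states[-1], self.params))
        return self.states[t]

    def tau_at(self, t: int) -> float:
        return self.params.tau_at(t)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as columns ``t,S,I,R,D,tau`` (fixed S,I,R,D ordering)."""
        rows = [
            (st.t, st.s, st.i, st.r, st.d, self.params.tau_at(st.t)) for st in self.states
        ]
        return pd.DataFrame(rows, columns=["t", "S", "I", "R", "D", "tau"])


def simulate(initial: EpidemicState, params: EpidemicParams, T: int) -> Trajectory:
    """Iterate the recursion for ``T`` steps; returns a trajectory of length T+1.

    With ``tau_t = 0`` for all t this coincides with the plain SIRD model.
    Raises :class:`InfeasibleParameterError` at the first offending period.
    """
    if T < 0:
        raise ValueError("horizon T must be >= 0")
    validate_params(params, initial)
    states = [initial]
    for _ in range(T):
        states.append(step(states[-1], params))
    return Trajectory(states=states, params=params)


@dataclass(frozen=True)
class TransitionMatrix:
    """One-period individual health-state kernel, rows/cols ordered (S, I, R, D)."""

    P: np.ndarray
    t: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (4, 4):
            raise ValueError(f"kernel must be 4x4, got {P.shape}")
        object.__setattr__(self, "P", P)


def transition_matrix(
    state: EpidemicState, params: EpidemicParams, tau: Optional[float] = None
) -> TransitionMatrix:
    """Per-period kernel implied by the aggregate recursion.

    Row S: (1 - tau - delta*I, delta*I, tau, 0); row I: (0, 1-gamma-rho,
    gamma, rho); rows R and D are absorbing unit vectors.
    """
    if tau is None:
        tau = params.tau_at(state.t)
    di = params.delta * state.i
    if tau < 0 or tau + di > 1 + 1e-12:
        raise InfeasibleParameterError(
            f"tau + delta*I exceeds 1 at period {state.t}: "
            f"tau={tau}, delta={params.delta}, I={state.i}"
        )
    P = np.array(
        [
            [max(1.0 - tau - di, 0.0), di, tau, 0.0],
            [0.0, max(1.0 - params.gamma - params.rho, 0.0), params.gamma, params.rho],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(P=P, t=state.t)


# ---------------------------------------------------------------------------
# 3. economy pricing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtilitySpec:
    """Instant utility with u(0) = 0, u' > 0, u'' < 0.

    ``power``: u(c) = c^(1-sigma)/(1-sigma) with sigma in (0, 1), so u(0)=0
    holds (log utility would not qualify).  u'(c) = c^(-sigma) diverges at 0.

    ``bounded_exponential``: u(c) = 1 - exp(-alpha*c) with alpha > 0; u'(0) =
    alpha is finite, which is what makes the include-deceased pricing
    convention usable.
    """

    kind: Literal["power", "bounded_exponential"] = "power"
    param: float = 0.5

    def __post_init__(self) -> None:
        if self.kind == "power":
            if not 0 < self.param < 1:
                raise ValueError(f"power utility exponent must be in (0, 1), got {self.param}")
        elif self.kind == "bounded_exponential":
            if self.param <= 0:
                raise ValueError(f"bounded_exponential alpha must be > 0, got {self.param}")
        else:
            raise ValueError(f"unknown utility kind {self.kind!r}")

    def u(self, c: float) -> float:
        if c < 0:
            raise ValueError(f"consumption must be >= 0, got {c}")
        if self.kind == "power":
            return c ** (1.0 - self.param) / (1.0 - self.param)
        return 1.0 - math.exp(-self.param * c)

    def u_prime(self, c: float) -> float:
        if c < 0:
            raise ValueError(f"consumption must be >= 0, got {c}")
        if self.kind == "power":
            if c == 0:
                raise ValueError("power utility has unbounded marginal utility at c=0")
            return c ** (-self.param)
        return self.param * math.exp(-self.param * c)


def marginal_utility(utility: UtilitySpec, c: float) -> float:
    """u'(c); strictly positive and decreasing, domain error at c=0 for power utility."""
    return utility.u_prime(c)


@dataclass(frozen=True)
class EconomyParams:
    """Endowments, dividends, discounting and pricing conventions.

    Consumption of a living individual in state theta is ``b_t + d_t*k +
    w(theta)`` (recovered earn the susceptible endowment ``w_S``); the
    deceased consume 0.  ``kernel_convention`` chooses how the deceased enter
    the pricing series: ``exclude_deceased`` gives them weight zero (the
    series sums over the living only, assets destroyed at death);
    ``include_deceased`` weighs them by the finite u'(0), hence requires the
    bounded-exponential utility.  ``infected_excluded`` models infected
    individuals shut out of economic activity: their consumption is pinned at
    ``c_floor`` and does not respond to handouts.
    """

    w_S: float = 1.0
    w_I: float = 0.2
    dividend: tuple[float, ...] = (0.1,)
    beta: float = 0.95
    handout: tuple[float, ...] = (0.0,)
    holdings: float = 1.0
    utility: UtilitySpec = field(default_factory=UtilitySpec)
    kernel_convention: Literal["exclude_deceased", "include_deceased"] = "exclude_deceased"
    infected_excluded: bool = False
    c_floor: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dividend", _as_schedule(self.dividend))
        object.__setattr__(self, "handout", _as_schedule(self.handout))
        if self.c_floor is None:
            object.__setattr__(self, "c_floor", 1e-3 * self.w_S)
        if not self.w_S >= self.w_I >= 0:
            raise ValueError(f"need w_S >= w_I >= 0, got w_S={self.w_S}, w_I={self.w_I}")
        if any(d <= 0 for d in self.dividend):
            raise ValueError("every dividend d_t must be > 0")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if any(b < 0 for b in self.handout):
            raise ValueError("handouts b_t must be >= 0")
        if self.holdings <= 0:
            raise ValueError(f"holdings k must be > 0, got {self.holdings}")
        if self.kernel_convention not in ("exclude_deceased", "include_deceased"):
            raise ValueError(f"unknown kernel_convention {self.kernel_convention!r}")
        if self.kernel_convention == "include_deceased" and self.utility.kind == "power":
            raise ValueError(
                "include_deceased needs finite u'(0); use bounded_exponential utility"
            )
        if self.infected_excluded and not self.c_floor > 0:
            raise ValueError(f"c_floor must be > 0, got {self.c_floor}")

    def dividend_at(self, t: int) -> float:
        return _schedule_at(self.dividend, t)

    def handout_at(self, t: int) -> float:
        return _schedule_at(self.handout, t)


def consumption(econ: EconomyParams, theta: Union[str, int], t: int) -> float:
    """Equilibrium consumption c_t(theta) under no-trade symmetric holdings.

    Living states consume ``b_t + d_t*k + w(theta)`` with w(R) = w(S); the
    deceased consume 0.  Under ``infected_excluded`` the infected consume the
    fixed floor regardless of the handout.
    """
    idx = STATES.index(theta) if isinstance(theta, str) else int(theta)
    if idx == D_IDX:
        return 0.0
    if idx == I_IDX and econ.infected_excluded:
        return float(econ.c_floor)
    w = econ.w_I if idx == I_IDX else econ.w_S
    return econ.handout_at(t) + econ.dividend_at(t) * econ.holdings + w


def _weighted_uprime(econ: EconomyParams, t: int) -> np.ndarray:
    """Per-state pricing weight * u'(c_t(state)); 0 for D under exclude_deceased."""
    out = np.empty(4)
    for idx in _ALIVE:
        out[idx] = econ.utility.u_prime(consumption(econ, idx, t))
    if econ.kernel_convention == "include_deceased":
        out[D_IDX] = econ.utility.u_prime(0.0)
    else:
        out[D_IDX] = 0.0
    return out


def propagate(dist: np.ndarray, kernel: Union[TransitionMatrix, np.ndarray]) -> np.ndarray:
    """Chapman-Kolmogorov one-step push-forward of a health-state distribution."""
    v = np.asarray(dist, dtype=float)
    if v.shape != (4,):
        raise ValueError(f"distribution must have shape (4,), got {v.shape}")
    if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("distribution entries must be >= 0 and sum to 1")
    P = kernel.P if isinstance(kernel, TransitionMatrix) else np.asarray(kernel, dtype=float)
    if P.shape != (4, 4):
        raise ValueError(f"kernel must be 4x4, got {P.shape}")
    return v @ P


def _uprime_sup(econ: EconomyParams) -> float:
    """Upper bound on the pricing weight over all states and periods (tail bound)."""
    b_min = min(econ.handout)
    d_min = min(econ.dividend)
    cs = [b_min + d_min * econ.holdings + econ.w_S]
    if econ.infected_excluded:
        cs.append(float(econ.c_floor))
    else:
        cs.append(b_min + d_min * econ.holdings + econ.w_I)
    sup = max(econ.utility.u_prime(c) for c in cs)
    if econ.kernel_convention == "include_deceased":
        sup = max(sup, econ.utility.u_prime(0.0))
    return sup


def _kernel_for(traj: Trajectory, t: int, tau0: Optional[float], t_eval: int) -> np.ndarray:
    """Kernel for the transition t -> t+1; tau at t_eval may be overridden (partial mode)."""
    st = traj.state_at(t)
    tau = traj.tau_at(t)
    if tau0 is not None and t == t_eval:
        tau = tau0
    return transition_matrix(st, traj.params, tau=tau).P


def m_partial_sum(
    traj: Trajectory,
    econ: EconomyParams,
    t: int,
    horizon: int,
    tau0_override: Optional[float] = None,
) -> float:
    """Pricing series m truncated after exactly ``horizon`` terms.

    m = sum_{w=1..horizon} beta^w d_{t+w} * E[weight * u'(c_{t+w}(theta_{t+w}))
    | theta_t = S], the expectation running over the individual's
    health-state chain started susceptible at t.  Used by the exhaustive
    path-enumeration cross-checks; :func:`m_series` adds the certified tail
    truncation.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    dist = np.zeros(4)
    dist[S_IDX] = 1.0
    total = 0.0
    disc = 1.0
    for omega in range(1, horizon + 1):
        dist = dist @ _kernel_for(traj, t + omega - 1, tau0_override, t)
        disc *= econ.beta
        total += disc * econ.dividend_at(t + omega) * float(dist @ _weighted_uprime(econ, t + omega))
    return total


def _m_truncated(
    traj: Trajectory,
    econ: EconomyParams,
    t: int,
    tol: float,
    max_horizon: int,
    tau0_override: Optional[float] = None,
) -> tuple[float, int, float]:
    """m with certified geometric tail truncation; returns (m, horizon, tail_bound)."""
    d_sup = max(econ.dividend)
    up_sup = _uprime_sup(econ)
    beta = econ.beta
    dist = np.zeros(4)
    dist[S_IDX] = 1.0
    total = 0.0
    disc = 1.0
    for omega in range(1, max_horizon + 1):
        dist = dist @ _kernel_for(traj, t + omega - 1, tau0_override, t)
        disc *= beta
        total += disc * econ.dividend_at(t + omega) * float(dist @ _weighted_uprime(econ, t + omega))
        # every omitted term is <= beta^w d_sup up_sup, summed geometrically
        tail = disc * beta / (1.0 - beta) * d_sup * up_sup
        if tail < tol:
            return total, omega, tail
    raise ConvergenceError(
        f"pricing series not below tol={tol} within max_horizon={max_horizon} "
        f"(achieved bound {tail})",
        achieved_bound=tail,
        horizon=max_horizon,
    )


@dataclass(frozen=True)
class PriceResult:
    """The pricing series value m, the price p_tilde = m / u'(c_t(S)), and truncation info."""

    m: float
    p_tilde: float
    horizon_used: int
    tail_bound: float
    t: int


def m_series(
    traj: Trajectory,
    econ: EconomyParams,
    t: int = 0,
    tol: float = DEFAULT_TOL,
    max_horizon: int = DEFAULT_MAX_HORIZON,
    tau0_override: Optional[float] = None,
) -> PriceResult:
    """Compute m for an individual susceptible at ``t`` and the implied price.

    The series is truncated at the first horizon whose geometric tail bound
    ``beta^(W+1)/(1-beta) * sup d * sup u'`` drops below ``tol``; the bound is
    recorded on the result.  ``tau0_override`` replaces the vaccination rate
    inside the period-``t`` kernel only (the aggregate trajectory is left
    untouched) — that is the object differentiated in partial mode.
    """
    m, horizon, tail = _m_truncated(traj, econ, t, tol, max_horizon, tau0_override)
    up_S = econ.utility.u_prime(consumption(econ, S_IDX, t))
    return PriceResult(m=m, p_tilde=m / up_S, horizon_used=horizon, tail_bound=tail, t=t)


def price(
    traj: Trajectory,
    econ: EconomyParams,
    t: int = 0,
    tol: float = DEFAULT_TOL,
    max_horizon: int = DEFAULT_MAX_HORIZON,
) -> PriceResult:
    """Equilibrium asset price p_tilde_t = m / u'(c_t(S)) for a susceptible individual."""
    return m_series(traj, econ, t=t, tol=tol, max_horizon=max_horizon)


@dataclass(frozen=True)
class DeltaDecomposition:
    """Per-horizon terms Delta_{t+w} of dm/dtau_t.

    Delta_{t+w} = beta^w d_{t+w} (E[weight*u' at t+w | enter R at t+1] -
    E[weight*u' at t+w | stay S at t+1]).  The first term is exactly zero
    because c_{t+1}(S) = c_{t+1}(R); with a positive income gap every later
    term is negative, which signs dp/dtau.
    """

    t: int
    deltas: np.ndarray  # deltas[w-1] is Delta_{t+w}, w = 1..horizon

    @property
    def omegas(self) -> np.ndarray:
        return np.arange(1, len(self.deltas) + 1)

    def total(self) -> float:
        return float(self.deltas.sum())


def delta_decomposition(
    traj: Trajectory, econ: EconomyParams, t: int, horizon: int
) -> DeltaDecomposition:
    """Decompose dm/dtau_t horizon by horizon, following the first-step kernel only."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    dist_R = np.zeros(4)
    dist_R[R_IDX] = 1.0
    dist_S = np.zeros(4)
    dist_S[S_IDX] = 1.0
    deltas = np.empty(horizon)
    disc = 1.0
    for omega in range(1, horizon + 1):
        if omega > 1:
            P = _kernel_for(traj, t + omega - 1, None, t)
            dist_R = dist_R @ P
            dist_S = dist_S @ P
        disc *= econ.beta
        wu = _weighted_uprime(econ, t + omega)
        deltas[omega - 1] = (
            disc * econ.dividend_at(t + omega) * float((dist_R - dist_S) @ wu)
        )
    return DeltaDecomposition(t=t, deltas=deltas)


def euler_residual(
    traj: Trajectory,
    econ: EconomyParams,
    t: int = 0,
    tol: float = DEFAULT_TOL,
    max_horizon: int = DEFAULT_MAX_HORIZON,
) -> float:
    """Diagnostic Euler-equation residual at the approximate price.

    |u'(c_t(S)) - beta * E_t[weight*u'(c_{t+1})(p_{t+1}+d_{t+1})] / p_t|.
    Exactly zero in the disease-free limit (up to truncation); away from it
    the residual quantifies the S_t ~ N approximation and is reported, not
    asserted.
    """
    p_t = price(traj, econ, t=t, tol=tol, max_horizon=max_horizon)
    p_t1 = price(traj, econ, t=t + 1, tol=tol, max_horizon=max_horizon)
    q = transition_matrix(traj.state_at(t), traj.params).P[S_IDX]
    wu = _weighted_uprime(econ, t + 1)
    d1 = econ.dividend_at(t + 1)
    expectation = float(q @ wu) * (p_t1.p_tilde + d1)
    up_S = econ.utility.u_prime(consumption(econ, S_IDX, t))
    return abs(up_S - econ.beta * expectation / p_t.p_tilde)


@dataclass(frozen=True)
class MonteCarloResult:
    """Seeded Monte-Carlo estimate of m with its standard error."""

    mean: float
    stderr: float
    n_paths: int
    horizon: int


def monte_carlo_m(
    traj: Trajectory,
    econ: EconomyParams,
    t: int = 0,
    horizon: int = 50,
    n_paths: int = 100_000,
    seed: int = DEFAULT_SEED,
) -> MonteCarloResult:
    """Estimate m by sampling individual health-state paths from the kernels.

    Independent of the deterministic distribution recursion: paths are drawn
    state by state with inverse-CDF sampling and each path accumulates its own
    discounted weighted-u' dividend stream.  Serves as the stochastic oracle
    for :func:`m_series`.
    """
    rng = np.random.default_rng(seed)
    states = np.zeros(n_paths, dtype=np.int64)  # all susceptible at t
    acc = np.zeros(n_paths)
    disc = 1.0
    for omega in range(1, horizon + 1):
        P = _kernel_for(traj, t + omega - 1, None, t)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_paths)
        states = (u[:, None] > cum[states, :]).sum(axis=1)
        disc *= econ.beta
        wu = _weighted_uprime(econ, t + omega)
        acc += disc * econ.dividend_at(t + omega) * wu[states]
    return MonteCarloResult(
        mean=float(acc.mean()),
        stderr=float(acc.std(ddof=1) / math.sqrt(n_paths)),
        n_paths=n_paths,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# 4. comparative statics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Everything needed to price and differentiate: epidemic, economy, settings.

    ``mode`` selects what a tau-derivative means: ``partial`` perturbs only
    the period-``t_eval`` transition kernel (the aggregate trajectory is held
    fixed, matching the analytic differentiation of the first-step
    probabilities); ``full`` re-simulates the whole trajectory with the
    perturbed vaccination rate, letting the perturbation feed back into
    future infection risk.
    """

    epidemic: EpidemicParams
    initial: EpidemicState
    economy: EconomyParams
    t_eval: int = 0
    tol: float = DEFAULT_TOL
    max_horizon: int = DEFAULT_MAX_HORIZON
    mode: Literal["partial", "full"] = "partial"
    h: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        validate_params(self.epidemic, self.initial)
        if self.t_eval < 0:
            raise ValueError("t_eval must be >= 0")
        if self.mode not in ("partial", "full"):
            raise ValueError(f"mode must be 'partial' or 'full', got {self.mode!r}")
        if self.h <= 0:
            raise ValueError(f"step h must be > 0, got {self.h}")

    def trajectory(self) -> Trajectory:
        return simulate(self.initial, self.epidemic, 0)

    def price(self, economy: Optional[EconomyParams] = None) -> PriceResult:
        econ = economy if economy is not None else self.economy
        return price(self.trajectory(), econ, t=self.t_eval, tol=self.tol,
                     max_horizon=self.max_horizon)


def _perturbed_epidemic(params: EpidemicParams, t_eval: int, tau_new: float) -> EpidemicParams:
    """Schedule with tau_{t_eval} replaced and later periods kept at their old values."""
    n = max(len(params.tau_schedule), t_eval + 2)
    sched = [params.tau_at(k) for k in range(n)]
    sched[t_eval] = tau_new
    return replace(params, tau_schedule=tuple(sched))


def dprice_dtau(
    scenario: Scenario,
    h: Optional[float] = None,
    mode: Optional[str] = None,
    economy: Optional[EconomyParams] = None,
) -> float:
    """Finite-difference derivative of the price w.r.t. the vaccination rate tau_{t_eval}.

    Central difference (p(tau+h) - p(tau-h)) / 2h, falling back to a one-sided
    difference (with a logged notice) when tau-h < 0 or tau+h+delta*I > 1.
    """
    h = scenario.h if h is None else h
    mode = scenario.mode if mode is None else mode
    econ = economy if economy is not None else scenario.economy
    t = scenario.t_eval
    traj = scenario.trajectory()
    tau0 = scenario.epidemic.tau_at(t)
    i_t = traj.state_at(t).i
    up_ok = tau0 + h + scenario.epidemic.delta * i_t <= 1.0
    down_ok = tau0 - h >= 0.0
    if not up_ok and not down_ok:
        raise InfeasibleParameterError(
            f"neither tau+h nor tau-h is feasible at period {t} (tau={tau0}, h={h})"
        )

    if mode == "partial":
        def p_of(tau: float) -> float:
            return m_series(
                traj, econ, t=t, tol=scenario.tol, max_horizon=scenario.max_horizon,
                tau0_override=tau,
            ).p_tilde
    else:
        def p_of(tau: float) -> float:
            params = _perturbed_epidemic(scenario.epidemic, t, tau)
            new_traj = simulate(scenario.initial, params, 0)
            return m_series(
                new_traj, econ, t=t, tol=scenario.tol, max_horizon=scenario.max_horizon
            ).p_tilde

    if up_ok and down_ok:
        return (p_of(tau0 + h) - p_of(tau0 - h)) / (2.0 * h)
    if up_ok:
        logger.info("tau-h infeasible at period %d; using one-sided forward difference", t)
        return (p_of(tau0 + h) - p_of(tau0)) / h
    logger.info("tau+h infeasible at period %d; using one-sided backward difference", t)
    return (p_of(tau0) - p_of(tau0 - h)) / h


@dataclass(frozen=True)
class SweepResult:
    """Price and tau-sensitivity along a one-parameter grid."""

    param_name: str
    grid: np.ndarray
    p_tilde: np.ndarray
    dprice: np.ndarray
    mode: str
    h: float
    tol: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": self.grid,
                "p_tilde": self.p_tilde,
                "dprice_dtau": self.dprice,
                "abs_dprice_dtau": np.abs(self.dprice),
            }
        )


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(list(grid), dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("grid must be a non-empty 1-d sequence")
    if g.size > 1:
        diffs = np.diff(g)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("grid not strictly monotone")
    return g


def _sweep(scenario: Scenario, name: str, grid: np.ndarray, econ_of) -> SweepResult:
    p_vals = np.empty(grid.size)
    d_vals = np.empty(grid.size)
    for j, x in enumerate(grid):
        econ = econ_of(float(x))
        p_vals[j] = scenario.price(economy=econ).p_tilde
        d_vals[j] = dprice_dtau(scenario, economy=econ)
    return SweepResult(
        param_name=name, grid=grid, p_tilde=p_vals, dprice=d_vals,
        mode=scenario.mode, h=scenario.h, tol=scenario.tol,
    )


def gap_sweep(scenario: Scenario, w_I_grid: Sequence[float]) -> SweepResult:
    """Sweep the infected endowment w_I toward w_S: the income gap shrinks.

    With no mortality the sensitivity |dp/dtau| falls monotonically to the
    knife-edge zero at w_I = w_S.
    """
    grid = _check_grid(w_I_grid)
    w_S = scenario.economy.w_S
    if np.any(grid > w_S) or np.any(grid < 0):
        raise ValueError(f"every w_I must satisfy 0 <= w_I <= w_S={w_S}")
    return _sweep(scenario, "w_I", grid, lambda x: replace(scenario.economy, w_I=x))


def handout_sweep(scenario: Scenario, b_grid: Sequence[float]) -> SweepResult:
    """Sweep the uniform unstorable cash handout b.

    In the default model handouts compress the marginal-utility gap between
    the infected and the rest, shrinking |dp/dtau|; when the infected are
    excluded from consumption (fixed floor) handouts act only on the living
    non-infected states and the effect reverses.
    """
    grid = _check_grid(b_grid)
    if np.any(grid < 0):
        raise ValueError("handouts must be >= 0")
    return _sweep(scenario, "handout", grid, lambda x: replace(scenario.economy, handout=(x,)))


def _report_for(scenario: Scenario) -> dict:
    """All proposition/corollary checks for one scenario (numbers + pass flags)."""
    d_partial = dprice_dtau(scenario, mode="partial")
    d_full = dprice_dtau(scenario, mode="full")
    gap = scenario.economy.w_S - scenario.economy.w_I

    dec = delta_decomposition(
        scenario.trajectory(), scenario.economy, scenario.t_eval, horizon=50
    )
    delta1_zero = bool(dec.deltas[0] == 0.0)
    later_negative = bool(np.all(dec.deltas[1:] < 0)) if gap > 0 else None

    # Corollary 1 on the zero-gap, no-mortality variant of this scenario
    knife_epi = replace(scenario.epidemic, rho=0.0)
    knife_econ = replace(scenario.economy, w_I=scenario.economy.w_S, infected_excluded=False)
    knife = replace(scenario, epidemic=knife_epi, economy=knife_econ)
    d_knife = dprice_dtau(knife)
    gap_grid = [frac * scenario.economy.w_S for frac in (0.2, 0.5, 0.8, 1.0)]
    sweep = gap_sweep(replace(knife, economy=replace(knife_econ, w_I=0.0)), gap_grid)
    abs_d = np.abs(sweep.dprice)
    gap_monotone = bool(np.all(np.diff(abs_d) < 1e-12))

    # Corollary 2 both directions
    def abs_d_at(b: float, excluded: bool) -> float:
        econ = replace(scenario.economy, handout=(b,), infected_excluded=excluded)
        return abs(dprice_dtau(scenario, economy=econ))

    cor2_default = abs_d_at(0.2, False) - abs_d_at(0.0, False)
    cor2_excluded = abs_d_at(0.2, True) - abs_d_at(0.0, True)

    return {
        "settings": {
            "mode": scenario.mode,
            "h": scenario.h,
            "tol": scenario.tol,
            "t_eval": scenario.t_eval,
        },
        "proposition_1": {
            "dprice_dtau_partial": d_partial,
            "dprice_dtau_full": d_full,
            "passed": bool(d_partial < 0 and d_full < 0),
        },
        "delta_decomposition": {
            "delta_1": float(dec.deltas[0]),
            "min_later_delta": float(dec.deltas[1:].min()),
            "max_later_delta": float(dec.deltas[1:].max()),
            "delta_1_zero": delta1_zero,
            "later_all_negative": later_negative,
            "passed": bool(delta1_zero and (later_negative is not False)),
        },
        "corollary_1": {
            "knife_edge_dprice_dtau": d_knife,
            "knife_edge_passed": bool(abs(d_knife) <= 1e-8),
            "gap_grid": list(map(float, sweep.grid)),
            "abs_dprice_dtau": list(map(float, abs_d)),
            "monotone_passed": gap_monotone,
            "passed": bool(abs(d_knife) <= 1e-8 and gap_monotone),
        },
        "corollary_2": {
            "abs_diff_default": cor2_default,
            "abs_diff_infected_excluded": cor2_excluded,
            "passed": bool(cor2_default < 0 < cor2_excluded),
        },
    }


def proposition_report(scenarios: Optional[Mapping[str, Scenario]] = None) -> dict:
    """Machine-readable pass/fail report for the model's comparative-statics claims.

    For each named scenario: the sign of dp/dtau in both modes, the
    per-horizon decomposition signs, the zero-gap/no-mortality knife edge and
    gap monotonicity, and the handout effect in both model variants.  An
    empty mapping yields an empty report.  Deterministic: re-running with the
    same scenarios reproduces the same JSON byte for byte.
    """
    if scenarios is None:
        scenarios = {"baseline": scenario_from_config(preset("baseline"))}
    report: dict = {"version": __version__, "scenarios": {}}
    for name in sorted(scenarios):
        report["scenarios"][name] = _report_for(scenarios[name])
    report["all_passed"] = all(
        block["passed"]
        for sc in report["scenarios"].values()
        for key, block in sc.items()
        if isinstance(block, dict) and "passed" in block
    )
    return report


# ---------------------------------------------------------------------------
# 5. interface / IO
# ---------------------------------------------------------------------------


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class UtilityConfig(_Block):
    kind: Literal["power", "bounded_exponential"] = "power"
    param: float = 0.5


class EpidemicConfig(_Block):
    delta: float = Field(default=0.3, ge=0)
    gamma: float = Field(default=0.2, gt=0, le=1)
    rho: float = Field(default=0.05, ge=0)
    tau: Union[float, list[float]] = 0.05


class InitialConfig(_Block):
    s: float = Field(default=0.97, ge=0, le=1)
    i: float = Field(default=0.02, ge=0, le=1)
    r: float = Field(default=0.01, ge=0, le=1)
    d: float = Field(default=0.0, ge=0, le=1)


class EconomyConfig(_Block):
    w_S: float = Field(default=1.0, ge=0)
    w_I: float = Field(default=0.2, ge=0)
    dividend: Union[float, list[float]] = 0.1
    beta: float = Field(default=0.95, gt=0, lt=1)
    handout: Union[float, list[float]] = 0.0
    holdings: float = Field(default=1.0, gt=0)
    utility: UtilityConfig = UtilityConfig()
    kernel_convention: Literal["exclude_deceased", "include_deceased"] = "exclude_deceased"
    infected_excluded: bool = False
    c_floor: Optional[float] = None


class StaticsConfig(_Block):
    mode: Literal["partial", "full"] = "partial"
    h: float = Field(default=DEFAULT_STEP, gt=0)
    gap_grid: list[float] = [0.2, 0.5, 0.8, 1.0]
    handout_grid: list[float] = [0.0, 0.1, 0.2]


class RunBlock(_Block):
    T: int = Field(default=100, ge=0)
    t_eval: int = Field(default=0, ge=0)
    tol: float = Field(default=DEFAULT_TOL, gt=0)
    max_horizon: int = Field(default=DEFAULT_MAX_HORIZON, ge=1)
    seed: int = DEFAULT_SEED
    out_dir: str = "out"


class RunConfig(_Block):
    """Validated scenario configuration; unknown keys are rejected."""

    epidemic: EpidemicConfig = EpidemicConfig()
    initial: InitialConfig = InitialConfig()
    economy: EconomyConfig = EconomyConfig()
    statics: StaticsConfig = StaticsConfig()
    run: RunBlock = RunBlock()


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        parts.append(f"{loc}: {err['msg']} (got {err.get('input')!r})")
    return "; ".join(parts)


def loads_config(text: str) -> RunConfig:
    """Parse and validate a YAML (or JSON) configuration string."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc
    # feasibility beyond per-field bounds: delegate to the epidemic validator
    scenario_from_config(cfg)
    return cfg


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load, validate and feasibility-check a scenario configuration file."""
    return loads_config(Path(path).read_text(encoding="utf-8"))


def scenario_from_config(cfg: RunConfig) -> Scenario:
    """Materialise the domain objects from a validated configuration."""
    epi = EpidemicParams(
        delta=cfg.epidemic.delta,
        gamma=cfg.epidemic.gamma,
        rho=cfg.epidemic.rho,
        tau_schedule=_as_schedule(cfg.epidemic.tau),
    )
    init = EpidemicState(s=cfg.initial.s, i=cfg.initial.i, r=cfg.initial.r, d=cfg.initial.d)
    econ = EconomyParams(
        w_S=cfg.economy.w_S,
        w_I=cfg.economy.w_I,
        dividend=_as_schedule(cfg.economy.dividend),
        beta=cfg.economy.beta,
        handout=_as_schedule(cfg.economy.handout),
        holdings=cfg.economy.holdings,
        utility=UtilitySpec(kind=cfg.economy.utility.kind, param=cfg.economy.utility.param),
        kernel_convention=cfg.economy.kernel_convention,
        infected_excluded=cfg.economy.infected_excluded,
        c_floor=cfg.economy.c_floor,
    )
    return Scenario(
        epidemic=epi,
        initial=init,
        economy=econ,
        t_eval=cfg.run.t_eval,
        tol=cfg.run.tol,
        max_horizon=cfg.run.max_horizon,
        mode=cfg.statics.mode,
        h=cfg.statics.h,
    )


# Pinned scenario presets (immutable within a release).  "baseline" is the
# versioned reference calibration every comparative-statics check runs on.
_PRESETS: dict[str, dict] = {
    "baseline": {},
    "zero-gap-no-mortality": {
        "epidemic": {"rho": 0.0},
        "economy": {"w_I": 1.0},
    },
    "infected-excluded": {
        "economy": {"infected_excluded": True, "c_floor": 1e-3},
    },
    "disease-free": {
        "epidemic": {"tau": 0.0},
        "initial": {"s": 1.0, "i": 0.0, "r": 0.0, "d": 0.0},
    },
}


def preset_names() -> tuple[str, ...]:
    return tuple(sorted(_PRESETS))


def preset(name: str) -> RunConfig:
    """One of the pinned scenario presets.

    ``baseline``: the reference calibration (delta=0.3, gamma=0.2, rho=0.05,
    tau=0.05, S0=0.97, I0=0.02, R0=0.01; w_S=1, w_I=0.2, d=0.1, beta=0.95,
    power utility sigma=0.5, no handout, exclude-deceased kernel).
    ``zero-gap-no-mortality``: w_I = w_S and rho = 0 (the knife edge).
    ``infected-excluded``: consumption of the infected pinned at the floor.
    ``disease-free``: I0 = 0, tau = 0; the price equals the constant-dividend
    closed form beta*d/(1-beta).
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
        )
    return RunConfig.model_validate(_PRESETS[name])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # '.' decimal, no thousands separators, UTF-8, LF endings, full precision
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_outputs(
    results: Mapping[str, object],
    config: RunConfig,
    out_dir: Union[str, Path],
    seed: int = DEFAULT_SEED,
) -> dict:
    """Serialize results and a reproducibility manifest into ``out_dir``.

    ``results`` may contain ``trajectory`` (Trajectory), ``price``
    (PriceResult or list thereof), ``sweeps`` (mapping name -> SweepResult)
    and ``report`` (dict).  Returns the manifest: resolved config, version,
    seed, timestamp and a sha256 inventory of every data file.  Re-running
    with the same config and seed reproduces identical data-file checksums.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    files: dict[str, str] = {}

    traj = results.get("trajectory")
    if traj is not None:
        path = out / "trajectory.csv"
        _write_csv(traj.to_frame(), path)
        files["trajectory.csv"] = _sha256(path)

    pr = results.get("price")
    if pr is not None:
        prices = pr if isinstance(pr, (list, tuple)) else [pr]
        df = pd.DataFrame(
            [(p.t, p.m, p.p_tilde, p.horizon_used, p.tail_bound) for p in prices],
            columns=["t", "m", "p_tilde", "horizon_used", "tail_bound"],
        )
        path = out / "price.csv"
        _write_csv(df, path)
        files["price.csv"] = _sha256(path)

    sweeps = results.get("sweeps") or {}
    for name, sweep in sweeps.items():
        path = out / f"sweep_{name}.csv"
        _write_csv(sweep.to_frame(), path)
        files[path.name] = _sha256(path)

    report = results.get("report")
    if report is not None:
        path = out / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        files["report.json"] = _sha256(path)

    manifest = {
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.model_dump(),
        "files": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
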