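"""Grey-box dynamic model of fed-batch *Pichia pastoris* fermentation.

Six-state balance model: cell concentration X, substrate (methanol)
concentration S, enzyme (inulinase) concentration E, dissolved oxygen C_L,
hydrogen-ion concentration [H+] and broth volume V, driven by four feed
streams (methanol, ammonia water, phosphate, antifoam) and pluggable
specific-rate laws mu, nu, rho, eta, gamma.

Internal time unit is hours; feed rates are stored in L/h (convert from
L/min at ingestion with :func:`lpm_to_lph`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StateVector",
    "FeedVector",
    "EnvironmentVector",
    "ModelConfig",
    "KineticParams",
    "RateLaws",
    "Trajectory",
    "lpm_to_lph",
    "volume_rhs",
    "state_rhs",
    "simulate",
    "default_rate_laws",
]

# state layout: x1..x6 = (X, S, E, C_L, [H+], V)
STATE_NAMES = ("X", "S", "E", "C_L", "H", "V")
FEED_NAMES = ("fC", "fN", "fM", "fA")


def lpm_to_lph(rate_l_per_min: float) -> float:
    """Convert a feed rate from L/min (instrument convention) to L/h."""
    return 60.0 * rate_l_per_min


@dataclass(frozen=True)
class StateVector:
    """Process state. Units: X g/L, S g/L, E U/mL, C_L % saturation (or
    mg/L, declared in config), H mol/L, V L."""

    X: float
    S: float
    E: float
    C_L: float
    H: float
    V: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"broth volume must be positive, got V={self.V}")
        if self.H <= 0 or not math.isfinite(math.log10(self.H)):
            raise ValueError(f"hydrogen-ion concentration must give finite pH, got H={self.H}")

    @property
    def pH(self) -> float:
        return -math.log10(self.H)

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.S, self.E, self.C_L, self.H, self.V], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "StateVector":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class FeedVector:
    """Feed rates in L/h: methanol fC, ammonia fN, phosphate fM, antifoam fA."""

    fC: float
    fN: float
    fM: float
    fA: float

    def __post_init__(self) -> None:
        for name in FEED_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"feed rate {name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.fC, self.fN, self.fM, self.fA], dtype=float)

    @property
    def total(self) -> float:
        return self.fC + self.fN + self.fM + self.fA


@dataclass(frozen=True)
class EnvironmentVector:
    """Measured environment: temperature Tw (degC), agitation Sa (rpm), airflow Fa (L/min)."""

    Tw: float
    Sa: float
    Fa: float

    def __post_init__(self) -> None:
        if self.Sa < 0 or self.Fa < 0:
            raise ValueError("agitation speed and airflow must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.Tw, self.Sa, self.Fa], dtype=float)


@dataclass
class ModelConfig:
    """Plant/transport parameters of the balance model.

    ``substrate_inflow`` selects the substrate feed term: ``"balanced"`` is
    the mass-consistent +S_C*u1/V; ``"literal_over_V"`` and ``"literal_times_V"``
    reproduce the two printed (dimensionally inconsistent) variants for
    comparison. ``inhibition_inflow`` analogously selects the enzyme-equation
    phosphate/antifoam term: ``"dilute"`` uses (K_M*u3 + K_A*u4)/V,
    ``"literal"`` uses (K_M*u3 + K_A*u4)*V. K_M and K_A are signed; the
    default sign is the printed '+', set them negative for true inhibition.
    """

    S_C: float = 780.0          # feed methanol concentration, g/L
    K_P: float = 0.01           # enzyme degradation constant, 1/h
    K_M: float = 0.0            # phosphate coefficient in enzyme eq. (signed)
    K_A: float = 0.0            # antifoam coefficient in enzyme eq. (signed)
    K_La: float = 20.0          # O2 volumetric mass-transfer coefficient, 1/h
    C_L_star: float = 100.0     # O2 saturation level, same units as C_L
    S_f: float = 1e-6           # acid equivalent of methanol feed, mol/L
    S_m: float = 1e-6           # acid equivalent of phosphate feed, mol/L
    S_n: float = 0.5            # base equivalent of ammonia feed, mol/L
    S_a: float = 1e-6           # acid equivalent of antifoam feed, mol/L
    A: np.ndarray = field(default_factory=lambda: np.ones((6, 4)))
    nonneg_clip: bool = True
    substrate_inflow: str = "balanced"
    inhibition_inflow: str = "dilute"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (6, 4):
            raise ValueError(f"dilution coefficient matrix A must be 6x4, got {self.A.shape}")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("dilution coefficient matrix A must be finite")
        if self.K_La < 0:
            raise ValueError("K_La must be >= 0")
        if self.C_L_star <= 0:
            raise ValueError("C_L_star must be > 0")
        if self.substrate_inflow not in ("balanced", "literal_over_V", "literal_times_V"):
            raise ValueError(f"unknown substrate_inflow mode {self.substrate_inflow!r}")
        if self.inhibition_inflow not in ("dilute", "literal"):
            raise ValueError(f"unknown inhibition_inflow mode {self.inhibition_inflow!r}")


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the default specific-rate law bundle (fixture values,
    not estimates of any particular plant)."""

    mu_max: float = 0.015   # maximum specific growth rate, 1/h
    K_S: float = 15.0       # substrate half-saturation, g/L
    K_i: float = 40.0       # substrate-inhibition constant, g/L
    K_O: float = 5.0        # oxygen half-saturation, C_L units
    X_max: float = 65.0     # logistic crowding capacity, g/L
    K_E: float = 50.0       # product-inhibition constant, U/mL
    Y_XS: float = 0.40      # biomass yield on substrate, g/g
    m_S: float = 0.01       # substrate maintenance, g/(g h)
    alpha: float = 3.0      # growth-associated enzyme production, U/(mL) per g/L biomass growth
    beta: float = 0.005     # constitutive enzyme production, U/(mL g h)
    Y_XO: float = 5e-4      # biomass yield on oxygen, g per (C_L unit * L)
    m_O: float = 5.0        # oxygen maintenance, C_L units * L/(g h)
    c_H: float = 1e-7       # proton release per biomass growth, mol/g

    def __post_init__(self) -> None:
        for name in ("Y_XS", "Y_XO"):
            if getattr(self, name) <= 0:
                raise ValueError(f"yield {name} must be positive")
        for name in ("K_S", "K_i", "K_O", "X_max", "K_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"saturation/inhibition constant {name} must be positive")


RateFn = Callable[[np.ndarray], float]


@dataclass
class RateLaws:
    """Bundle of specific rates as functions of the state array x1..x6.

    mu 1/h (growth), nu g substrate/(g cell h), rho enzyme/(g cell h),
    eta oxygen/(g cell h), gamma mol H+/(g cell h). ``partials(name, x)``
    returns the gradient of a rate w.r.t. the six states; the default is a
    central finite difference, overridable with analytic gradients.
    """

    mu: RateFn
    nu: RateFn
    rho: RateFn
    eta: RateFn
    gamma: RateFn
    analytic_partials: dict | None = None
    fd_step: float = 1e-6

    _NAMES = ("mu", "nu", "rho", "eta", "gamma")

    def rate(self, name: str, x: np.ndarray) -> float:
        if name not in self._NAMES:
            raise KeyError(name)
        val = float(getattr(self, name)(np.asarray(x, dtype=float)))
        if not math.isfinite(val):
            raise FloatingPointError(f"rate law {name!r} returned non-finite value at x={x}")
        return val

    def all_rates(self, x: np.ndarray) -> dict:
        return {name: self.rate(name, x) for name in self._NAMES}

    def partials(self, name: str, x: np.ndarray) -> np.ndarray:
        """Gradient of one rate w.r.t. (x1..x6)."""
        if self.analytic_partials is not None and name in self.analytic_partials:
            return np.asarray(self.analytic_partials[name](np.asarray(x, dtype=float)), dtype=float)
        fn = getattr(self, name)
        x = np.asarray(x, dtype=float)
        grad = np.zeros(6)
        for i in range(6):
            h = self.fd_step * max(abs(x[i]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (fn(xp) - fn(xm)) / (2.0 * h)
        return grad

    @classmethod
    def constant(cls, mu=0.0, nu=0.0, rho=0.0, eta=0.0, gamma=0.0) -> "RateLaws":
        """State-independent rates (degenerate; useful as a negative control)."""
        vals = dict(mu=mu, nu=nu, rho=rho, eta=eta, gamma=gamma)
        laws = cls(**{k: (lambda x, v=v: v) for k, v in vals.items()})
        laws.analytic_partials = {k: (lambda x: np.zeros(6)) for k in vals}
        return laws


def default_rate_laws(params: KineticParams | None = None) -> RateLaws:
    """Default kinetic bundle with analytic state gradients.

    mu = mu_max * S/(K_S + S + S^2/K_i) * C_L/(K_O + C_L)
         * (1 - X/X_max) * K_E/(K_E + E)

    i.e. Monod uptake with substrate inhibition, oxygen limitation, logistic
    crowding, and product inhibition by the accumulating enzyme. The product
    term closes the feedback loop from enzyme concentration to the measurable
    outputs, which the invertibility analysis relies on. The companions are
    linear couplings: nu = mu/Y_XS + m_S, rho = alpha*mu + beta
    (Luedeking-Piret), eta = mu/Y_XO + m_O, gamma = c_H * mu.
    """
    p = params or KineticParams()

    def _mu_factors(x):
        X, S, E, C_L = x[0], x[1], x[2], x[3]
        den_s = p.K_S + S + S * S / p.K_i
        f_s = S / den_s if den_s > 0 else 0.0
        f_o = C_L / (p.K_O + C_L)
        f_x = 1.0 - X / p.X_max
        f_e = p.K_E / (p.K_E + E)
        return f_s, f_o, f_x, f_e, den_s

    def mu(x):
        f_s, f_o, f_x, f_e, _ = _mu_factors(x)
        return max(p.mu_max * f_s * f_o * f_x * f_e, 0.0)

    def grad_mu(x):
        X, S, E, C_L = x[0], x[1], x[2], x[3]
        f_s, f_o, f_x, f_e, den_s = _mu_factors(x)
        g = np.zeros(6)
        base = p.mu_max * f_s * f_o * f_x * f_e
        if base <= 0.0:
            return g
        # d f_s/dS = (K_S - S^2/K_i) / den_s^2
        g[0] = -p.mu_max * f_s * f_o * f_e / p.X_max
        g[1] = p.mu_max * f_o * f_x * f_e * (p.K_S - S * S / p.K_i) / (den_s * den_s)
        g[2] = -base / (p.K_E + E)
        g[3] = p.mu_max * f_s * f_x * f_e * p.K_O / ((p.K_O + C_L) ** 2)
        return g

    laws = RateLaws(
        mu=mu,
        nu=lambda x: mu(x) / p.Y_XS + p.m_S,
        rho=lambda x: p.alpha * mu(x) + p.beta,
        eta=lambda x: mu(x) / p.Y_XO + p.m_O,
        gamma=lambda x: p.c_H * mu(x),
    )
    laws.analytic_partials = {
        "mu": grad_mu,
        "nu": lambda x: grad_mu(x) / p.Y_XS,
        "rho": lambda x: p.alpha * grad_mu(x),
        "eta": lambda x: grad_mu(x) / p.Y_XO,
        "gamma": lambda x: p.c_H * grad_mu(x),
    }
    return laws


def volume_rhs(feeds: FeedVector | np.ndarray) -> float:
    """dV/dt = fC + fN + fM + fA (L/h); no broth removal in fed-batch."""
    u = feeds.as_array() if isinstance(feeds, FeedVector) else np.asarray(feeds, dtype=float)
    if np.any(u < 0):
        raise ValueError(f"feed rates must be >= 0, got {u}")
    return float(u.sum())


def state_rhs(
    state: StateVector | np.ndarray,
    feeds: FeedVector | np.ndarray,
    rates: RateLaws,
    config: ModelConfig,
) -> np.ndarray:
    """Right-hand side of the six balance equations, units/h.

    Growth, consumption and production terms scale with biomass x1; every
    state except volume carries a dilution term -(x_j/x6) * sum_i a_ji u_i.
    """
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    u = feeds.as_array() if isinstance(feeds, FeedVector) else np.asarray(feeds, dtype=float)
    if x[5] <= 0:
        raise ValueError(f"broth volume must be positive, got V={x[5]}")
    if np.any(u < 0):
        raise ValueError(f"feed rates must be >= 0, got {u}")

    r = rates.all_rates(x)
    V = x[5]
    dil = (config.A @ u) / V  # per-state sum_i a_ji u_i / V

    if config.substrate_inflow == "balanced":
        s_in = config.S_C * u[0] / V
    elif config.substrate_inflow == "literal_over_V":
        s_in = config.S_C / V
    else:  # literal_times_V
        s_in = config.S_C * V

    if config.inhibition_inflow == "dilute":
        e_in = (config.K_M * u[2] + config.K_A * u[3]) / V
    else:
        e_in = (config.K_M * u[2] + config.K_A * u[3]) * V

    dx = np.empty(6)
    dx[0] = r["mu"] * x[0] - x[0] * dil[0]
    dx[1] = -r["nu"] * x[0] + s_in - x[1] * dil[1]
    dx[2] = r["rho"] * x[0] - config.K_P * x[2] + e_in - x[2] * dil[2]
    dx[3] = -r["eta"] * x[0] + config.K_La * (config.C_L_star - x[3]) - x[3] * dil[3]
    dx[4] = (
        r["gamma"] * x[0]
        - x[4] * dil[4]
        + (config.S_f * u[0] - config.S_m * u[2] - config.S_n * u[1] - config.S_a * u[3]) / V
    )
    dx[5] = u.sum()
    if not np.all(np.isfinite(dx)):
        bad = [STATE_NAMES[i] for i in range(6) if not math.isfinite(dx[i])]
        raise FloatingPointError(f"non-finite derivative for state(s) {bad} at x={x}")
    return dx


@dataclass
class Trajectory:
    """Dense time-indexed record of states, feeds and environment."""

    t: np.ndarray            # (n,), hours, strictly increasing
    states: np.ndarray       # (n, 6)
    feeds: np.ndarray        # (n, 4), L/h
    env: np.ndarray          # (n, 3)
    clip_count: int = 0      # negative-state clips applied during integration

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.feeds = np.asarray(self.feeds, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        n = self.t.shape[0]
        if not (self.states.shape == (n, 6) and self.feeds.shape == (n, 4) and self.env.shape == (n, 3)):
            raise ValueError("trajectory channels must share the time grid length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.t.shape[0]

    def state_at(self, i: int) -> StateVector:
        return StateVector.from_array(self.states[i])


def _as_profile(profile, width: int) -> Callable[[float], np.ndarray]:
    """Accept a constant vector, a FeedVector/EnvironmentVector, or a callable t->vector."""
    if callable(profile):
        def fn(t: float) -> np.ndarray:
            v = profile(t)
            if isinstance(v, (FeedVector, EnvironmentVector)):
                v = v.as_array()
            return np.asarray(v, dtype=float)
        return fn
    if isinstance(profile, (FeedVector, EnvironmentVector)):
        const = profile.as_array()
    else:
        const = np.asarray(profile, dtype=float)
    if const.shape != (width,):
        raise ValueError(f"constant profile must have shape ({width},), got {const.shape}")
    return lambda t: const


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


def simulate(
    x0: StateVector,
    feed_profile,
    env_profile,
    t_end: float,
    dt: float = 0.01,
    rates: RateLaws | None = None,
    config: ModelConfig | None = None,
    t_start: float = 0.0,
    method: str = "rk4",
) -> Trajectory:
    """Integrate the balance model on a fixed grid.

    Fixed-step classical RK4 (default, deterministic) or scipy's adaptive
    RK45 sampled on the same grid. With ``config.nonneg_clip`` the five
    concentration states are floored at zero after each step and the number
    of clips recorded on the returned trajectory.
    """
    if dt <= 0 or t_end <= t_start:
        raise ValueError("need dt > 0 and t_end > t_start")
    rates = rates if rates is not None else default_rate_laws()
    config = config if config is not None else ModelConfig()
    feed_fn = _as_profile(feed_profile, 4)
    env_fn = _as_profile(env_profile, 3)

    n_steps = int(round((t_end - t_start) / dt))
    t_grid = t_start + dt * np.arange(n_steps + 1)
    t_grid[-1] = t_end

    if method == "rk45":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, x: state_rhs(x, feed_fn(t), rates, config),
            (t_start, t_end),
            x0.as_array(),
            method="RK45",
            t_eval=t_grid,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise IntegrationError(f"RK45 failed: {sol.message}", float(sol.t[-1]) if len(sol.t) else t_start)
        states = sol.y.T.copy()
        clip_count = 0
        if config.nonneg_clip:
            neg = states[:, :5] < 0
            clip_count = int(neg.sum())
            states[:, :5] = np.maximum(states[:, :5], 0.0)
    elif method == "rk4":
        states = np.empty((n_steps + 1, 6))
        states[0] = x0.as_array()
        clip_count = 0
        x = states[0].copy()
        for k in range(n_steps):
            t = t_grid[k]
            h = t_grid[k + 1] - t
            try:
                k1 = state_rhs(x, feed_fn(t), rates, config)
                k2 = state_rhs(x + 0.5 * h * k1, feed_fn(t + 0.5 * h), rates, config)
                k3 = state_rhs(x + 0.5 * h * k2, feed_fn(t + 0.5 * h), rates, config)
                k4 = state_rhs(x + h * k3, feed_fn(t + h), rates, config)
            except (ValueError, FloatingPointError) as exc:
                raise IntegrationError(f"integration failed at t={t:.6g} h: {exc}", t) from exc
            x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if config.nonneg_clip:
                neg = x[:5] < 0
                if neg.any():
                    clip_count += int(neg.sum())
                    x[:5] = np.maximum(x[:5], 0.0)
            states[k + 1] = x
    else:
        raise ValueError(f"unknown integrator {method!r}")

    feeds = np.stack([feed_fn(t) for t in t_grid])
    env = np.stack([env_fn(t) for t in t_grid])
    return Trajectory(t=t_grid, states=states, feeds=feeds, env=env, clip_count=clip_count)
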