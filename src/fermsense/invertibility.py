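"""Local invertibility diagnostics for the measurable-output subsystem.

The soft sensor reconstructs the unmeasured states (X, S, E) = (x1, x2, x3)
from the measurable ones (C_L, [H+], V) = (x4, x5, x6) and their time
derivatives. That reconstruction exists locally only where the map from
(x1, x2, x3) to the derivative vector (d2x4/dt2, dx4/dt, dx5/dt) has a
full-rank 3x3 Jacobian. This module estimates that Jacobian by central
finite differences along the simulated flow and reports its numerical rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelConfig, RateLaws, StateVector, Trajectory, state_rhs

__all__ = [
    "OutputDerivatives",
    "JacobianReport",
    "output_derivatives",
    "jacobian_J",
    "invertibility_scan",
]


@dataclass
class OutputDerivatives:
    """Measured outputs z = (x4, x5, x6) and their derivative information."""

    z: np.ndarray
    z1_dot: float    # dx4/dt
    z1_ddot: float   # d2x4/dt2 (finite-differenced along the flow)
    z2_dot: float    # dx5/dt

    def __post_init__(self) -> None:
        vals = np.array([self.z1_dot, self.z1_ddot, self.z2_dot])
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(vals))):
            raise FloatingPointError("non-finite output derivative; reduce the FD step")


def _rk4_step(x: np.ndarray, u: np.ndarray, rates: RateLaws, config: ModelConfig, h: float) -> np.ndarray:
    k1 = state_rhs(x, u, rates, config)
    k2 = state_rhs(x + 0.5 * h * k1, u, rates, config)
    k3 = state_rhs(x + 0.5 * h * k2, u, rates, config)
    k4 = state_rhs(x + h * k3, u, rates, config)
    return x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def output_derivatives(
    state,
    feeds,
    rates: RateLaws,
    config: ModelConfig,
    h: float = 1e-3,
) -> OutputDerivatives:
    """First derivatives of x4, x5 directly from the balance equations;
    the second derivative of x4 by a central difference of dx4/dt over a
    short simulated arc (feeds held constant, arc half-length ``h`` hours)."""
    if h <= 0:
        raise ValueError("FD step h must be > 0")
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    u = feeds.as_array() if hasattr(feeds, "as_array") else np.asarray(feeds, dtype=float)
    dx = state_rhs(x, u, rates, config)
    x_plus = _rk4_step(x, u, rates, config, h)
    x_minus = _rk4_step(x, u, rates, config, -h)
    d_plus = state_rhs(x_plus, u, rates, config)
    d_minus = state_rhs(x_minus, u, rates, config)
    z1_ddot = (d_plus[3] - d_minus[3]) / (2.0 * h)
    return OutputDerivatives(z=x[3:6].copy(), z1_dot=float(dx[3]), z1_ddot=float(z1_ddot), z2_dot=float(dx[4]))


@dataclass
class JacobianReport:
    """Numerical invertibility report at one operating point."""

    J: np.ndarray                 # raw 3x3 Jacobian d(z1_ddot, z1_dot, z2_dot)/d(x1, x2, x3)
    singular_values: np.ndarray   # of the row-equilibrated Jacobian
    rank: int
    tol: float
    invertible: bool
    det_diagnostic: float         # product-form proxy; ~0 whenever rank < 3 or d(eta)/d(x1) = 0
    g_terms: dict                 # numerically evaluated auxiliary quantities

    def __post_init__(self) -> None:
        if not (0 <= self.rank <= 3):
            raise ValueError("rank must lie in [0, 3]")


def jacobian_J(
    state,
    feeds,
    rates: RateLaws,
    config: ModelConfig,
    h: float = 1e-4,
    h_time: float = 1e-3,
    rank_rtol: float = 1e-8,
    equilibrate: bool = True,
) -> JacobianReport:
    """Estimate the 3x3 Jacobian of (d2x4/dt2, dx4/dt, dx5/dt) w.r.t. the
    unmeasured states (x1, x2, x3) and decide its numerical rank.

    Each column is a central finite difference with step ``h`` scaled by the
    state magnitude. The rank is decided by singular-value thresholding at
    ``rank_rtol`` times the largest singular value; with ``equilibrate`` the
    SVD is taken on a row-equilibrated copy (each row divided by its
    inf-norm), since the three output rows carry different physical units
    and raw magnitudes would mask a mathematically full-rank matrix. Row
    scaling leaves the rank itself invariant.
    """
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    u = feeds.as_array() if hasattr(feeds, "as_array") else np.asarray(feeds, dtype=float)

    def outputs(xi: np.ndarray) -> np.ndarray:
        od = output_derivatives(xi, u, rates, config, h=h_time)
        return np.array([od.z1_ddot, od.z1_dot, od.z2_dot])

    J = np.empty((3, 3))
    for i in range(3):
        hi = h * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        J[:, i] = (outputs(xp) - outputs(xm)) / (2.0 * hi)

    J_eq = J.copy()
    if equilibrate:
        row_norm = np.max(np.abs(J_eq), axis=1)
        row_norm[row_norm == 0] = 1.0
        J_eq = J_eq / row_norm[:, None]
    try:
        sv = np.linalg.svd(J_eq, compute_uv=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"singular-value computation failed: {exc}") from exc
    tol = sv.max() * rank_rtol if sv.max() > 0 else 0.0
    rank = int(np.sum(sv > tol))

    # auxiliary diagnostics standing in for the printed symbolic chain
    grad_eta = rates.partials("eta", x)
    grad_gamma = rates.partials("gamma", x)
    eta_123 = grad_eta[:3]
    norm_eta = np.linalg.norm(eta_123)
    factor = eta_123[0] / norm_eta if norm_eta > 0 else 0.0
    det_diag = float(np.linalg.det(J_eq) * factor)
    g_terms = {
        "eta": rates.rate("eta", x),
        "gamma": rates.rate("gamma", x),
        "d_eta_dx1": float(grad_eta[0]),
        "d_eta_dx2": float(grad_eta[1]),
        "d_eta_dx3": float(grad_eta[2]),
        "d_gamma_dx1": float(grad_gamma[0]),
        "d_gamma_dx2": float(grad_gamma[1]),
        "d_gamma_dx3": float(grad_gamma[2]),
        "det_J_raw": float(np.linalg.det(J)),
    }
    return JacobianReport(
        J=J,
        singular_values=sv,
        rank=rank,
        tol=tol,
        invertible=(rank == 3),
        det_diagnostic=det_diag,
        g_terms=g_terms,
    )


def invertibility_scan(
    trajectory: Trajectory,
    rates: RateLaws,
    config: ModelConfig,
    stride: int = 10,
    **jac_kwargs,
) -> tuple[list, float]:
    """Jacobian reports at every ``stride``-th trajectory point and the
    fraction of sampled points with full rank. A stride longer than the
    trajectory yields a single report at t0."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = range(0, len(trajectory), stride)
    reports = [
        jacobian_J(trajectory.states[i], trajectory.feeds[i], rates, config, **jac_kwargs)
        for i in idx
    ]
    fraction = sum(r.invertible for r in reports) / len(reports)
    return reports, fraction
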