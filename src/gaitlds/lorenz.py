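"""Lorenz-system fixture with an independent tangent-space Lyapunov oracle.

Used to validate the Rosenstein divergence estimator against a ground truth
that never touches the neighbour-tracking code path: the largest exponent of
the Lorenz flow (sigma=10, rho=28, beta=8/3 gives ~0.906 nats per time unit)
computed by Benettin-style tangent-vector renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class LorenzError(ValueError):
    pass


def _deriv(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def _jacobian(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([
        [-sigma, sigma, 0.0],
        [rho - z, -1.0, -x],
        [y, x, -beta],
    ])


def _rk4_step(state, dt, sigma, rho, beta):
    k1 = _deriv(state, sigma, rho, beta)
    k2 = _deriv(state + 0.5 * dt * k1, sigma, rho, beta)
    k3 = _deriv(state + 0.5 * dt * k2, sigma, rho, beta)
    k4 = _deriv(state + dt * k3, sigma, rho, beta)
    return state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


@dataclass
class LorenzFixture:
    x: np.ndarray  # x-component series after transient discard
    dt: float
    oracle_le: float  # largest exponent, nats per time unit (Benettin)
    params: tuple[float, float, float]


def benettin_lyapunov(
    dt: float = 0.01,
    n: int = 20000,
    seed_state=(1.0, 1.0, 1.0),
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    transient: int = 2000,
) -> float:
    """Largest Lyapunov exponent by tangent-vector renormalization.

    The tangent vector is advanced with the RK4-discretized variational
    equation alongside the trajectory and renormalized every step; the mean
    log stretching rate over the post-transient steps is the exponent.
    """
    state = np.asarray(seed_state, dtype=float)
    v = np.array([1.0, 0.0, 0.0])
    log_sum = 0.0
    count = 0
    for i in range(n + transient):
        # variational RK4 uses the Jacobian along the RK4 stage points
        k1 = _deriv(state, sigma, rho, beta)
        j1 = _jacobian(state, sigma, rho, beta) @ v
        s2 = state + 0.5 * dt * k1
        k2 = _deriv(s2, sigma, rho, beta)
        j2 = _jacobian(s2, sigma, rho, beta) @ (v + 0.5 * dt * j1)
        s3 = state + 0.5 * dt * k2
        k3 = _deriv(s3, sigma, rho, beta)
        j3 = _jacobian(s3, sigma, rho, beta) @ (v + 0.5 * dt * j2)
        s4 = state + dt * k3
        k4 = _deriv(s4, sigma, rho, beta)
        j4 = _jacobian(s4, sigma, rho, beta) @ (v + dt * j3)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        v = v + dt / 6.0 * (j1 + 2 * j2 + 2 * j3 + j4)
        norm = np.linalg.norm(v)
        if not np.isfinite(norm) or norm == 0.0:
            raise LorenzError("tangent vector diverged or vanished")
        v /= norm
        if i >= transient:
            log_sum += np.log(norm)
            count += 1
        if np.abs(state).max() > 1e6:
            raise LorenzError("divergent integration detected")
    return float(log_sum / (count * dt))


def lorenz_fixture(
    dt: float = 0.01,
    n: int = 15000,
    seed_state=(1.0, 1.0, 1.0),
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    transient: int = 3000,
    oracle_n: int = 20000,
) -> LorenzFixture:
    """Fixed-step RK4 x-component series plus the Benettin oracle exponent."""
    if dt > 0.02:
        raise LorenzError(f"dt={dt} too coarse (need <= 0.02)")
    if n < 1000:
        raise LorenzError(f"n={n} too short for a usable fixture")
    state = np.asarray(seed_state, dtype=float)
    xs = np.empty(n)
    for i in range(transient):
        state = _rk4_step(state, dt, sigma, rho, beta)
    for i in range(n):
        state = _rk4_step(state, dt, sigma, rho, beta)
        if np.abs(state).max() > 1e6:
            raise LorenzError("divergent integration detected")
        xs[i] = state[0]
    oracle = benettin_lyapunov(dt=dt, n=oracle_n, seed_state=seed_state,
                               sigma=sigma, rho=rho, beta=beta)
    return LorenzFixture(x=xs, dt=dt, oracle_le=oracle, params=(sigma, rho, beta))
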