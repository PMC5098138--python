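"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation paths they check:

* ``mc_sphere_remaining`` — Brownian random walk of many particles inside an
  absorbing sphere (with a Brownian-bridge correction for wall crossings
  between discrete steps), checking the eigenfunction series.
* ``graetz_penetration`` — Crank–Nicolson solution of the convection
  -diffusion (Graetz) problem in a tube with parabolic flow and absorbing
  wall, checking the Gormley–Kennedy expressions.
* ``grid_search_exponential`` — brute-force SSE minimization over a parameter
  grid, checking nonlinear least-squares fits.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def mc_sphere_remaining(
    fourier: float, n_walkers: int = 100_000, n_steps: int = 600, seed: int = 0
) -> tuple[float, float]:
    """Surviving fraction after dimensionless time Dt/r^2 = ``fourier``.

    Unit sphere, unit diffusivity.  Walkers start uniformly in the sphere;
    each step is an isotropic Gaussian displacement.  Between sampling
    points a walker may touch the wall and return: the Brownian-bridge
    first-passage probability exp(-d1*d2/(D*dt)) against the locally flat
    wall removes that discretization bias.  Returns (fraction, standard
    error).
    """
    rng = np.random.default_rng(seed)
    dt = fourier / n_steps
    sigma = np.sqrt(2.0 * dt)

    # uniform start: radius ~ U^(1/3), isotropic direction
    u = rng.random(n_walkers) ** (1.0 / 3.0)
    direction = rng.standard_normal((n_walkers, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    pos = u[:, None] * direction

    alive = np.ones(n_walkers, dtype=bool)
    for _ in range(n_steps):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        old = pos[idx]
        new = old + sigma * rng.standard_normal((idx.size, 3))
        r_old = np.linalg.norm(old, axis=1)
        r_new = np.linalg.norm(new, axis=1)
        crossed = r_new >= 1.0
        # bridge correction for walkers that stayed inside at both ends
        d1 = 1.0 - r_old
        d2 = 1.0 - r_new
        p_touch = np.exp(-d1 * d2 / dt)
        touched = (~crossed) & (rng.random(idx.size) < p_touch)
        dead = crossed | touched
        alive[idx[dead]] = False
        pos[idx[~dead]] = new[~dead]
    frac = alive.mean()
    se = np.sqrt(frac * (1.0 - frac) / n_walkers)
    return float(frac), float(se)


def graetz_penetration(mu: float, n_r: int = 400, n_z: int = 4000) -> float:
    """Penetration of the Graetz problem at mu = pi*D*L/Q.

    Cell-centered finite differences in radius (wall Dirichlet via ghost
    cell, natural symmetry at the axis), Crank–Nicolson in the axial
    coordinate with Rannacher start-up (damped implicit-Euler substeps) to
    suppress oscillations from the inlet discontinuity.  The flow-averaged
    outlet concentration is the penetration.
    """
    if mu <= 0:
        return 1.0
    h = 1.0 / n_r
    rho = (np.arange(n_r) + 0.5) * h
    faces = np.arange(n_r + 1) * h  # rho_{i-1/2}
    B = 2.0 * (1.0 - rho**2)  # convective weight

    # operator L c = (1/rho_i h^2) [rho_{i+1/2}(c_{i+1}-c_i) - rho_{i-1/2}(c_i-c_{i-1})]
    lower = faces[1:-1] / (rho[1:] * h**2)  # coefficient of c_{i-1}
    upper = faces[1:-1] / (rho[:-1] * h**2)  # coefficient of c_{i+1}
    diag = -(faces[:-1] + faces[1:]) / (rho * h**2)
    # wall ghost: c_ghost = -c_{N-1}  ->  fold into the last diagonal entry
    diag[-1] -= faces[-1] / (rho[-1] * h**2)

    def step(c: np.ndarray, dz: float, theta: float) -> np.ndarray:
        # (B/dz - theta L) c_new = (B/dz + (1-theta) L) c_old
        rhs = B / dz * c
        if theta < 1.0:
            w = 1.0 - theta
            Lc = np.empty_like(c)
            Lc[0] = diag[0] * c[0] + upper[0] * c[1]
            Lc[1:-1] = lower[:-1] * c[:-2] + diag[1:-1] * c[1:-1] + upper[1:] * c[2:]
            Lc[-1] = lower[-1] * c[-2] + diag[-1] * c[-1]
            rhs = rhs + w * Lc
        ab = np.zeros((3, n_r))
        ab[0, 1:] = -theta * upper
        ab[1, :] = B / dz - theta * diag
        ab[2, :-1] = -theta * lower
        return solve_banded((1, 1), ab, rhs)

    c = np.ones(n_r)
    n_start = 40
    dz_start = mu / n_z / 4.0
    for _ in range(n_start):
        c = step(c, dz_start, 1.0)
    remaining = mu - n_start * dz_start
    dz = remaining / n_z
    for _ in range(n_z):
        c = step(c, dz, 0.5)
    return float(np.sum(4.0 * rho * (1.0 - rho**2) * c) * h)


def grid_search_exponential(
    x: np.ndarray,
    y: np.ndarray,
    a_grid: np.ndarray,
    b_grid: np.ndarray,
) -> tuple[float, float]:
    """argmin over (a, b) of sum (y - a*exp(-b*x))^2 on a dense grid."""
    best = (np.inf, np.nan, np.nan)
    for a in a_grid:
        pred = a * np.exp(-np.outer(b_grid, x))
        sse = np.sum((y[None, :] - pred) ** 2, axis=1)
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), float(a), float(b_grid[j]))
    return best[1], best[2]
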