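"""Independent reference implementations used to cross-check the package.

These deliberately use brute force (grid search, pairwise enumeration,
direct partial-likelihood evaluation) and share no code with the library
paths they validate.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def grid_search_amplitude_scaling(
    e: np.ndarray,
    volumes: np.ndarray,
    ed_index: int,
    lvp_systole: float,
    edp: float,
    v0: float,
    a_range: tuple[float, float] = (1e-4, 3.0),
    b_range: tuple[float, float] = (-0.5, 0.5),
    n_grid: int = 61,
    n_passes: int = 5,
    shrink: float = 0.15,
) -> tuple[float, float]:
    """Dense 2-D grid search for the affine elastance scaling (a, b).

    Minimizes the worst relative violation of the two pressure constraints
    over a coarse-to-fine grid; entirely independent of the fixed-point
    solver.
    """
    w = volumes - v0
    a_lo, a_hi = a_range
    b_lo, b_hi = b_range
    best = (np.nan, np.nan)
    for _ in range(n_passes):
        a_vals = np.linspace(a_lo, a_hi, n_grid)
        b_vals = np.linspace(b_lo, b_hi, n_grid)
        A, B = np.meshgrid(a_vals, b_vals, indexing="ij")
        # P has shape (n_grid, n_grid, n_frames)
        P = (A[..., None] * e + B[..., None]) * w
        err_peak = np.abs(P.max(axis=-1) - lvp_systole) / lvp_systole
        err_edp = np.abs(P[..., ed_index] - edp) / edp
        err = np.maximum(err_peak, err_edp)
        i, j = np.unravel_index(np.argmin(err), err.shape)
        best = (float(a_vals[i]), float(b_vals[j]))
        a_half = (a_hi - a_lo) * shrink / 2
        b_half = (b_hi - b_lo) * shrink / 2
        a_lo, a_hi = best[0] - a_half, best[0] + a_half
        b_lo, b_hi = best[1] - b_half, best[1] + b_half
    return best


def trapezoid_loop_area(volumes: np.ndarray, pressures: np.ndarray) -> float:
    """|∮ P dV| of the implicitly closed loop by trapezoidal integration."""
    v = np.append(volumes, volumes[0])
    p = np.append(pressures, pressures[0])
    return abs(float(np.trapezoid(p, v)))


def cox_log_partial_likelihood(
    beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Log partial likelihood of a single-covariate Cox model (no ties)."""
    ll = 0.0
    for i in np.nonzero(events)[0]:
        risk_set = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk_set])))
    return ll


def cox_brute_force_mle(
    x: np.ndarray, times: np.ndarray, events: np.ndarray,
    bounds: tuple[float, float] = (-8.0, 8.0),
) -> float:
    """Maximize the single-covariate partial likelihood by bounded search."""
    res = optimize.minimize_scalar(
        lambda b: -cox_log_partial_likelihood(b, x, times, events),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def harrell_c_pairwise(
    risk: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's C by explicit enumeration of comparable pairs."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # pair comparable if i fails first (strictly) and i is an event
            if events[i] and times[i] < times[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def longhand_km(times: np.ndarray, events: np.ndarray) -> dict[float, float]:
    """Product-limit estimate computed longhand, event time by event time."""
    order = np.argsort(times)
    t_sorted, e_sorted = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    out: dict[float, float] = {}
    for t in np.unique(t_sorted[e_sorted.astype(bool)]):
        at_risk = np.sum(t_sorted >= t)
        d = np.sum((t_sorted == t) & e_sorted.astype(bool))
        s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out
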