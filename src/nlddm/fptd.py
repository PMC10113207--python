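"""Forward Fokker–Planck solver producing first-passage-time densities.

The probability density of the decision variable evolves under

    dp/dt = -d/dx [ mu(x) p ] + (sigma²/2) d²p/dx²

on the domain ``[-a, a]`` (nl-DDM) or ``[-B, B]`` (DDM) with absorbing ends.
Space is discretized in conservative flux form with Scharfetter–Gummel
(exponentially fitted) face fluxes, which stay stable and positive even when
the drift dominates diffusion on a cell; time stepping is Crank–Nicolson
(implicit, second order).  The probability flux absorbed at each end per
step, divided by the step, gives the defective correct/error RT densities;
whatever density remains at ``t_max`` is reported as undecided mass, never
renormalized away.  The non-decision time is a pure translation of the time
grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._kernels import cn_evolve
from .models import DdmParams, ModelParams, NlddmParams, nlddm_drift, params_to_dict

__all__ = [
    "FPTDSolution",
    "SolutionSummary",
    "ZeroMassError",
    "solve_fptd",
    "apply_nondecision_shift",
    "solution_summaries",
    "export_solution",
]

DEFAULT_DT = 0.002  # s
DEFAULT_T_MAX = 5.0  # s
DEFAULT_NX = 200  # cells across the domain -> dx = domain / 200


class ZeroMassError(ValueError):
    """Conditional RT mean requested for a boundary that received no mass."""


@dataclass
class FPTDSolution:
    """Discretized defective first-passage densities for both boundaries.

    ``t`` holds time-step midpoints (plus any applied non-decision shift);
    ``f_correct``/``f_error`` are probability densities per second whose
    integrals are the choice probabilities.
    """

    t: np.ndarray
    f_correct: np.ndarray
    f_error: np.ndarray
    undecided_mass: float
    dt: float
    dx: float
    domain: tuple
    t_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def p_correct(self) -> float:
        return float(np.sum(self.f_correct) * self.dt)

    @property
    def p_error(self) -> float:
        return float(np.sum(self.f_error) * self.dt)

    @property
    def total_mass(self) -> float:
        return self.p_correct + self.p_error + self.undecided_mass

    def density_at(self, t, boundary: str = "correct") -> np.ndarray:
        """Linear interpolation of a defective density; zero outside the grid."""
        f = self.f_correct if boundary == "correct" else self.f_error
        return np.interp(np.asarray(t, dtype=float), self.t, f, left=0.0, right=0.0)

    def cdf(self, t, boundary: str = "correct") -> np.ndarray:
        f = self.f_correct if boundary == "correct" else self.f_error
        cum = np.concatenate([[0.0], np.cumsum(f) * self.dt])
        edges = np.concatenate([[self.t[0] - 0.5 * self.dt], self.t + 0.5 * self.dt])
        return np.interp(np.asarray(t, dtype=float), edges, cum, left=0.0, right=cum[-1])


@dataclass
class SolutionSummary:
    p_correct: float
    p_error: float
    undecided_mass: float
    mean_rt_correct: float
    mean_rt_error: float


def _bernoulli(w: np.ndarray) -> np.ndarray:
    """B(w) = w / (e^w - 1), the exponential-fitting weight; B(0) = 1.

    Computed from the positive branch ``B(|w|) = |w| e^{-|w|} / (1 - e^{-|w|})``
    and the identity ``B(-w) = w + B(w)``, which stays finite for any drift.
    """
    w = np.asarray(w, dtype=float)
    wa = np.abs(w)
    out = np.empty_like(w)
    small = wa < 1e-10
    out[small] = 1.0 - 0.5 * w[small]
    ws = wa[~small]
    b_pos = ws * np.exp(-ws) / (-np.expm1(-ws))
    out[~small] = np.where(w[~small] > 0, b_pos, ws + b_pos)
    return out


def _drift_on(params: ModelParams, x: np.ndarray) -> np.ndarray:
    if isinstance(params, NlddmParams):
        return nlddm_drift(x, params)
    if isinstance(params, DdmParams):
        return np.full_like(x, params.nu)
    raise TypeError(f"unsupported model parameters: {type(params)!r}")


def _initial_density(params: ModelParams, nodes: np.ndarray, h: float) -> np.ndarray:
    """Deposit the uniform starting distribution by cell-proportional weights.

    Interior node ``i`` owns the cell ``[x_i - h/2, x_i + h/2]``; partial
    cells at the support edges receive fractional mass.  A point start is
    split linearly between its two neighboring nodes.
    """
    lo, hi = params.x0 - params.sz, params.x0 + params.sz
    cell_lo, cell_hi = nodes - 0.5 * h, nodes + 0.5 * h
    if lo < cell_lo[0] or hi > cell_hi[-1]:
        raise ValueError(
            f"starting support [{lo}, {hi}] touches the absorbing boundary "
            f"region at this resolution (interior cells span "
            f"[{cell_lo[0]:.6g}, {cell_hi[-1]:.6g}]); refine dx or shrink the support"
        )
    if params.sz <= 0:
        q = np.zeros_like(nodes)
        j = int(np.clip(np.searchsorted(nodes, params.x0) - 1, 0, len(nodes) - 2))
        wr = (params.x0 - nodes[j]) / h
        q[j] = (1.0 - wr) / h
        q[j + 1] = wr / h
        return q
    overlap = np.clip(np.minimum(cell_hi, hi) - np.maximum(cell_lo, lo), 0.0, None)
    q = overlap / (hi - lo) / h
    return q / (np.sum(q) * h)


def solve_fptd(
    params: ModelParams,
    dx: Optional[float] = None,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
) -> FPTDSolution:
    """Solve the forward Fokker–Planck equation for the model's FPT densities.

    The solution is on the decision-time axis; ``params.t_nd`` is applied
    afterwards via :func:`apply_nondecision_shift`, so the returned grid
    already includes the non-decision shift when ``t_nd > 0``.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be > 0")
    L = params.boundary
    if dx is None:
        nx = DEFAULT_NX
    else:
        if dx <= 0:
            raise ValueError(f"dx must be > 0, got {dx}")
        nx = max(int(round(2.0 * L / dx)), 8)
    h = 2.0 * L / nx
    nodes = -L + h * np.arange(1, nx)  # interior nodes
    faces = -L + h * (np.arange(nx) + 0.5)
    D = 0.5 * params.sigma**2
    w = _drift_on(params, faces) * h / D
    Bp = _bernoulli(w)    # B(w)
    Bm = _bernoulli(-w)   # B(-w)

    r = D / h**2
    lower = np.zeros(nx - 1)
    upper = np.zeros(nx - 1)
    lower[1:] = r * Bm[1:-1]
    upper[:-1] = r * Bp[1:-1]
    diag = -r * (Bp[:-1] + Bm[1:])

    q0 = _initial_density(params, nodes, h)
    n_steps = int(np.ceil(t_max / dt))
    f_error, f_correct, q_final = cn_evolve(
        lower, diag, upper, q0, dt, n_steps, r * h * Bp[0], r * h * Bm[-1]
    )
    t_mid = dt * (np.arange(n_steps) + 0.5)
    undecided = float(np.sum(q_final) * h)
    sol = FPTDSolution(
        t=t_mid,
        f_correct=np.maximum(f_correct, 0.0),
        f_error=np.maximum(f_error, 0.0),
        undecided_mass=undecided,
        dt=dt,
        dx=h,
        domain=(-L, L),
        meta={"params": params_to_dict(params)},
    )
    if params.t_nd > 0:
        sol = apply_nondecision_shift(sol, params.t_nd)
    return sol


def apply_nondecision_shift(sol: FPTDSolution, t_nd: float) -> FPTDSolution:
    """Translate the densities by ``t_nd`` seconds; mass is preserved exactly."""
    if t_nd < 0:
        raise ValueError(f"t_nd must be >= 0, got {t_nd}")
    if t_nd == 0:
        return sol
    return replace(sol, t=sol.t + t_nd, t_offset=sol.t_offset + t_nd)


def solution_summaries(sol: FPTDSolution, strict: bool = False) -> SolutionSummary:
    """Choice probabilities and conditional RT means by quadrature on the grid.

    A conditional mean is NaN when its boundary received (numerically) no
    mass; with ``strict=True`` that case raises :class:`ZeroMassError`.
    """

    def _mean(f: np.ndarray, mass: float, name: str) -> float:
        if mass < 1e-12:
            if strict:
                raise ZeroMassError(
                    f"no probability mass reached the {name} boundary; "
                    "its conditional mean RT is undefined"
                )
            return float("nan")
        return float(np.sum(sol.t * f) * sol.dt / mass)

    pc, pe = sol.p_correct, sol.p_error
    return SolutionSummary(
        p_correct=pc,
        p_error=pe,
        undecided_mass=sol.undecided_mass,
        mean_rt_correct=_mean(sol.f_correct, pc, "correct"),
        mean_rt_error=_mean(sol.f_error, pe, "error"),
    )


def export_solution(sol: FPTDSolution, path) -> None:
    """Write (time, correct_density, error_density) as CSV."""
    import pandas as pd

    pd.DataFrame(
        {"time": sol.t, "correct_density": sol.f_correct, "error_density": sol.f_error}
    ).to_csv(path, index=False)
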