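"""Seeded stochastic and noise-free trajectory simulation, and synthetic
response-time dataset generation from either model.

The stochastic integrator is first-order Euler–Maruyama with boundary
crossing detected by sign change at grid points (no Brownian-bridge
correction); the discretization bias shrinks with the step and is covered by
the step-refinement checks in the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .models import DdmParams, ModelParams, NlddmParams, nlddm_drift, params_to_dict

__all__ = [
    "Trajectory",
    "RTDataset",
    "StationaryStartError",
    "simulate_path",
    "noiseless_trajectory",
    "simulate_dataset",
    "DEFAULT_DT",
    "DEFAULT_T_MAX",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 5e-4  # s; 0.5 ms Euler step
DEFAULT_T_MAX = 5.0  # s; response windows in typical tasks are 2-3 s


class StationaryStartError(ValueError):
    """Noise-free trajectory started exactly on the unstable fixed point."""


@dataclass
class Trajectory:
    """A single decision-variable path.

    ``rt`` is the first boundary-crossing time plus the non-decision time and
    is present iff ``outcome`` is not ``"undecided"``.
    """

    times: np.ndarray
    states: np.ndarray
    outcome: str  # "correct" | "error" | "undecided"
    rt: Optional[float]
    params: ModelParams

    def __post_init__(self):
        if (self.rt is None) != (self.outcome == "undecided"):
            raise ValueError("rt must be present iff the trajectory was absorbed")


@dataclass
class RTDataset:
    """Trial-level table of response times, correctness and condition labels.

    ``trials`` has columns ``participant``, ``rt`` (seconds, > 0), ``correct``
    (bool) plus optional condition-factor columns.  Undecided trials are not
    rows; their count is kept in ``n_undecided``.
    """

    trials: pd.DataFrame
    n_undecided: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def rt(self) -> np.ndarray:
        return self.trials["rt"].to_numpy(dtype=float)

    @property
    def correct(self) -> np.ndarray:
        return self.trials["correct"].to_numpy(dtype=bool)

    def validate(self) -> "RTDataset":
        required = {"participant", "rt", "correct"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"RTDataset is missing columns {sorted(missing)}")
        if len(self.trials) and not (self.trials["rt"] > 0).all():
            raise ValueError("all response times must be > 0")
        return self


def _model_code(params: ModelParams):
    if isinstance(params, NlddmParams):
        return _kernels.NLDDM_CODE, params.k, params.a, params.z
    if isinstance(params, DdmParams):
        return _kernels.DDM_CODE, params.nu, 0.0, 0.0
    raise TypeError(f"unsupported model parameters: {type(params)!r}")


def simulate_path(
    params: ModelParams,
    start: float,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    seed: int = 0,
) -> Trajectory:
    """Euler–Maruyama integration of a single trial from ``start``.

    Absorption is declared at the first grid point at or beyond ``±a``
    (nl-DDM) or ``±B`` (DDM); the reported ``rt`` includes ``t_nd``.
    Identical seeds give identical trajectories.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    bound = params.boundary
    if not (-bound < start < bound):
        raise ValueError(f"start {start} outside the open domain (±{bound})")
    code, c1, c2, c3 = _model_code(params)
    n_steps = int(np.ceil(t_max / dt))
    noise = np.random.default_rng(seed).standard_normal(n_steps)
    states, n_kept, raw = _kernels.sim_path(
        code, c1, c2, c3, params.sigma, bound, float(start), dt, noise
    )
    states = states[:n_kept]
    times = dt * np.arange(n_kept)
    if raw == 0:
        return Trajectory(times, states, "undecided", None, params)
    outcome = "correct" if raw == 1 else "error"
    rt = times[-1] + params.t_nd
    return Trajectory(times, states, outcome, float(rt), params)


def noiseless_trajectory(
    params: NlddmParams, start: float, t_grid: np.ndarray
) -> Trajectory:
    """Deterministic ODE solution of ``dx/dt = -k (x+a)(x-z)(x-a)``.

    The path approaches the attractor on ``start``'s side of ``z``
    asymptotically and never reaches it, so the outcome is always
    ``"undecided"``.  Starting exactly at ``z`` is rejected: without noise
    there is no motion there.
    """
    if not isinstance(params, NlddmParams):
        raise TypeError("noiseless trajectories are defined for the nl-DDM")
    if not (-params.a < start < params.a):
        raise ValueError(f"start {start} outside (±{params.a})")
    if start == params.z:
        raise StationaryStartError(
            f"start == z == {start}: the unstable fixed point is stationary "
            "in the absence of noise"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda t, x: nlddm_drift(x, params),
        (t_grid[0], t_grid[-1]),
        [float(start)],
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        method="RK45",
    )
    return Trajectory(sol.t, sol.y[0], "undecided", None, params)


def simulate_dataset(
    params: ModelParams,
    n_trials: int,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    seed: int = 0,
    participant: str = "sim",
    conditions: Optional[dict] = None,
) -> RTDataset:
    """Simulate ``n_trials`` independent decisions into an :class:`RTDataset`.

    Per-trial starting points are drawn uniformly from ``[x0 - sz, x0 + sz]``;
    the seed controls both the starting points and the within-trial noise.
    Decided trials become rows (``rt`` includes ``t_nd``); undecided trials
    are counted in ``n_undecided``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be > 0")
    ss = np.random.SeedSequence(seed)
    start_seed, noise_seed = ss.spawn(2)
    starts = np.random.default_rng(start_seed).uniform(
        params.x0 - params.sz, params.x0 + params.sz, size=n_trials
    )
    code, c1, c2, c3 = _model_code(params)
    n_steps = int(np.ceil(t_max / dt))
    kernel_seed = int(noise_seed.generate_state(1)[0] & 0x7FFFFFFF)
    dts, outcomes = _kernels.sim_trials(
        code, c1, c2, c3, params.sigma, params.boundary, starts, dt, n_steps, kernel_seed
    )
    decided = outcomes != 0
    df = pd.DataFrame(
        {
            "participant": participant,
            "rt": dts[decided] + params.t_nd,
            "correct": outcomes[decided] == 1,
        }
    )
    for name, value in (conditions or {}).items():
        df[name] = value
    n_undecided = int((~decided).sum())
    if n_undecided:
        logger.debug("%d of %d trials undecided at t_max=%.3g s", n_undecided, n_trials, t_max)
    meta = {
        "params": params_to_dict(params),
        "seed": int(seed),
        "dt": dt,
        "t_max": t_max,
        "n_trials": int(n_trials),
        "n_undecided": n_undecided,
    }
    return RTDataset(trials=df, n_undecided=n_undecided, meta=meta).validate()
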