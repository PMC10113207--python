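"""Negative-log-likelihood evaluation, BIC, condition-dependent model
configurations, and global parameter fitting.

A :class:`ModelConfig` declares which model parameter varies by which
condition factor (e.g. one drift per stimulus, one boundary per
instruction × phase) and which parameters are fixed (typically the noise
scale, ``sigma = 0.3``, since only two of drift/boundary/noise are
identifiable).  Fitting maximizes the likelihood of the observed RTs under
the model's first-passage densities, solved per condition cell by the
Fokker–Planck solver, using a seeded differential-evolution global search
followed by a Nelder–Mead polish.  Likelihoods are over decided trials only;
undecided/timeout mass does not enter.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .fptd import FPTDSolution, solve_fptd
from .models import DdmParams, NlddmParams
from .simulate import RTDataset

__all__ = [
    "ModelConfig",
    "FitOptions",
    "FitResult",
    "build_config",
    "multisensory_config",
    "lexical_config",
    "negative_log_likelihood",
    "bic",
    "fit_model",
    "DENSITY_FLOOR",
]

DENSITY_FLOOR = 1e-10

_BASE_PARAMS = {
    "nlddm": ("k", "a", "z", "x0", "sz", "t_nd", "sigma"),
    "ddm": ("nu", "B", "x0", "sz", "t_nd", "sigma"),
}

# Search bounds.  z, x0 and sz are searched as fractions of the domain
# geometry (z and x0 of the smallest boundary in play, sz of the gap left
# between |x0| and that boundary) so that box bounds alone keep the joint
# constraints [x0-sz, x0+sz] subset (-a, a) and z in (-a, a) feasible.
DEFAULT_BOUNDS = {
    "nlddm": {
        "k": (0.05, 40.0),
        "a": (0.3, 3.0),
        "z": (-0.9, 0.9),
        "x0": (-0.8, 0.8),
        "sz": (0.0, 0.9),
        "t_nd": (0.0, 0.6),
        "sigma": (0.05, 1.0),
    },
    "ddm": {
        "nu": (-12.0, 12.0),
        "B": (0.2, 6.0),
        "z": (-0.9, 0.9),
        "x0": (-0.8, 0.8),
        "sz": (0.0, 0.9),
        "t_nd": (0.0, 0.6),
        "sigma": (0.05, 1.0),
    },
}

_FRACTIONAL = {"z", "x0", "sz"}


@dataclass(frozen=True)
class ModelConfig:
    """Which parameters are free, how they split by condition, their bounds."""

    kind: str
    factor_map: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    levels: Dict[str, Tuple] = field(default_factory=dict)
    fixed: Dict[str, float] = field(default_factory=lambda: {"sigma": 0.3})
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _BASE_PARAMS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        base = _BASE_PARAMS[self.kind]
        for p, factors in self.factor_map.items():
            if p not in base:
                raise ValueError(f"{p!r} is not a parameter of the {self.kind}")
            for f in factors:
                if f not in self.levels:
                    raise ValueError(f"factor {f!r} has no declared levels")
        for p in self.fixed:
            if p not in base:
                raise ValueError(f"{p!r} is not a parameter of the {self.kind}")
        merged = dict(DEFAULT_BOUNDS[self.kind])
        merged.update(self.bounds)
        object.__setattr__(self, "bounds", merged)
        for p in base:
            lo, hi = self.bounds[p]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {p!r} must be finite with lo < hi")

    @property
    def base_params(self) -> Tuple[str, ...]:
        return _BASE_PARAMS[self.kind]

    def used_factors(self) -> Tuple[str, ...]:
        seen = []
        for p in self.base_params:
            for f in self.factor_map.get(p, ()):
                if f not in seen:
                    seen.append(f)
        return tuple(seen)

    def free_parameters(self) -> list:
        """Ordered list of (parameter, level-tuple); shared params get ()."""
        out = []
        for p in self.base_params:
            if p in self.fixed:
                continue
            factors = self.factor_map.get(p, ())
            if not factors:
                out.append((p, ()))
            else:
                for combo in itertools.product(*(self.levels[f] for f in factors)):
                    out.append((p, combo))
        return out

    @property
    def n_free(self) -> int:
        return len(self.free_parameters())


def build_config(
    kind: str,
    factor_map: Optional[Dict[str, Sequence[str]]] = None,
    levels: Optional[Dict[str, Sequence]] = None,
    fixed: Optional[Dict[str, float]] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
) -> ModelConfig:
    """Assemble a :class:`ModelConfig`; ``sigma`` defaults to fixed at 0.3."""
    return ModelConfig(
        kind=kind,
        factor_map={p: tuple(f) for p, f in (factor_map or {}).items()},
        levels={f: tuple(ls) for f, ls in (levels or {}).items()},
        fixed=dict(fixed) if fixed is not None else {"sigma": 0.3},
        bounds=dict(bounds or {}),
    )


def multisensory_config(kind: str, stimuli: Sequence = ("face", "number_sound")) -> ModelConfig:
    """Two-stimulus classification configuration.

    DDM: one boundary, one drift per stimulus, shared start distribution and
    non-decision time (6 free parameters).  nl-DDM: shared ``k`` and ``a``,
    one ``z`` per stimulus, shared start distribution and non-decision time
    (7 free parameters).  ``sigma`` fixed at 0.3 in both.
    """
    varying = "nu" if kind == "ddm" else "z"
    return build_config(kind, {varying: ("stimulus",)}, {"stimulus": stimuli})


def lexical_config(
    kind: str,
    words: Sequence = ("frequent", "rare", "very_rare", "non_word"),
    instructions: Sequence = ("speed", "accuracy"),
    phases: Sequence = ("early", "late"),
) -> ModelConfig:
    """Word-classification configuration with speed/accuracy instruction and
    early/late experiment phase.

    DDM: one drift per word type (4) and one boundary per
    instruction × phase (4); nl-DDM: one ``z`` per word type (4), one ``a``
    per instruction (2), one ``k`` per phase (2).  Both share start
    distribution and non-decision time, 11 free parameters each.
    """
    levels = {"word": words, "instruction": instructions, "phase": phases}
    if kind == "ddm":
        fm = {"nu": ("word",), "B": ("instruction", "phase")}
    else:
        fm = {"z": ("word",), "a": ("instruction",), "k": ("phase",)}
    return build_config(kind, fm, levels)


def bic(nll: float, n_params: int, n_samples: int) -> float:
    """Bayesian Information Criterion, ``ln(n) * n_params + 2 * nll``."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if n_params < 0:
        raise ValueError(f"n_params must be >= 0, got {n_params}")
    return math.log(n_samples) * n_params + 2.0 * nll


def _nll_arrays(rts: np.ndarray, sol: FPTDSolution, correct: np.ndarray) -> float:
    end = sol.t[-1] + 0.5 * sol.dt
    if np.any(rts > end + 1e-12):
        raise ValueError(
            f"trial RT {rts.max():.4g} s beyond the solved horizon {end:.4g} s"
        )
    f_c = sol.density_at(rts[correct], "correct")
    f_e = sol.density_at(rts[~correct], "error")
    dens = np.concatenate([f_c, f_e])
    return float(-np.sum(np.log(np.maximum(dens, DENSITY_FLOOR))))


def negative_log_likelihood(
    data: RTDataset,
    solutions: Dict[tuple, FPTDSolution],
    by: Sequence[str] = (),
) -> float:
    """NLL of the observed RTs under per-condition first-passage densities.

    ``solutions`` maps a tuple of the ``by`` factor values to the (already
    non-decision-shifted) solution for that condition; trials in a condition
    without a solution, or beyond a solution's time horizon, raise.
    Densities are floored at ``DENSITY_FLOOR`` before the log, so RTs that
    fall where the model puts no mass (e.g. below ``t_nd``) contribute
    ``-ln(floor)`` rather than infinity.
    """
    df = data.trials
    if not len(df):
        raise ValueError("dataset is empty")
    total = 0.0
    if not by:
        groups = [((), df)]
    else:
        groups = [
            (key if isinstance(key, tuple) else (key,), sub)
            for key, sub in df.groupby(list(by), sort=False, observed=True)
        ]
    for key, sub in groups:
        if key not in solutions:
            raise KeyError(f"no solved FPTD for condition {key!r}")
        total += _nll_arrays(
            sub["rt"].to_numpy(dtype=float),
            solutions[key],
            sub["correct"].to_numpy(dtype=bool),
        )
    return total


@dataclass
class FitOptions:
    """Numerical settings for :func:`fit_model`.

    The solver grid used during fitting is deliberately coarser than the
    stand-alone solver default; the refinement checks in the test suite
    bound the discretization error this introduces.
    """

    nx: int = 120
    dt: float = 0.004
    de_maxiter: int = 25
    popsize: int = 15  # scipy semantics: population = popsize * n_free
    tol: float = 1e-6
    polish: bool = True
    polish_maxfev: int = 1500


@dataclass
class FitResult:
    """Fitted parameters (absolute scale), NLL, BIC and optimizer metadata."""

    params: pd.DataFrame  # columns: parameter, level, value
    nll: float
    bic: float
    n_samples: int
    n_params: int
    converged: bool
    seed: int
    n_evaluations: int
    config: ModelConfig
    x: np.ndarray  # internal (fraction-parameterized) optimum

    def value(self, parameter: str, level: tuple = ()) -> float:
        tab = self.params
        row = tab[(tab["parameter"] == parameter) & (tab["level"] == "/".join(map(str, level)))]
        if not len(row):
            raise KeyError(f"no fitted value for {parameter!r} at level {level!r}")
        return float(row["value"].iloc[0])

    def export(self, path) -> None:
        """One row per parameter plus a summary row, as CSV."""
        tab = self.params.copy()
        summary = pd.DataFrame(
            [
                {"parameter": "_nll", "level": "", "value": self.nll},
                {"parameter": "_bic", "level": "", "value": self.bic},
                {"parameter": "_n_samples", "level": "", "value": self.n_samples},
                {"parameter": "_n_params", "level": "", "value": self.n_params},
                {"parameter": "_seed", "level": "", "value": self.seed},
                {"parameter": "_converged", "level": "", "value": float(self.converged)},
            ]
        )
        pd.concat([tab, summary], ignore_index=True).to_csv(path, index=False)


class _Problem:
    """Flattened view of one fit: free vector <-> per-cell model parameters."""

    def __init__(self, data: RTDataset, config: ModelConfig, options: FitOptions):
        data.validate()
        if not len(data):
            raise ValueError("cannot fit an empty dataset")
        self.config = config
        self.options = options
        self.free = config.free_parameters()
        self.bounds = [config.bounds[p] for p, _ in self.free]
        self.factors = config.used_factors()
        df = data.trials
        for f in self.factors:
            if f not in df.columns:
                raise ValueError(f"dataset has no condition column {f!r}")
        if self.factors:
            grouped = df.groupby(list(self.factors), sort=False, observed=True)
            self.cells = []
            for key, sub in grouped:
                key = key if isinstance(key, tuple) else (key,)
                if not len(sub):
                    continue
                self.cells.append(
                    (
                        dict(zip(self.factors, key)),
                        sub["rt"].to_numpy(dtype=float),
                        sub["correct"].to_numpy(dtype=bool),
                    )
                )
        else:
            self.cells = [({}, df["rt"].to_numpy(dtype=float), df["correct"].to_numpy(dtype=bool))]
        self.max_rt = float(df["rt"].max())
        self.t_max = self.max_rt + options.dt
        self.n_eval = 0

    # -- vector packing -----------------------------------------------------

    def _values(self, x: np.ndarray) -> Dict[str, Dict[tuple, float]]:
        out: Dict[str, Dict[tuple, float]] = {}
        for (p, lev), v in zip(self.free, x):
            out.setdefault(p, {})[lev] = float(v)
        for p, v in self.config.fixed.items():
            out.setdefault(p, {})[()] = float(v)
        return out

    def _lookup(self, values, p: str, cell: dict) -> float:
        factors = self.config.factor_map.get(p, ())
        key = tuple(cell[f] for f in factors) if factors else ()
        return values[p][key]

    def _domain_floor(self, values) -> float:
        bp = "a" if self.config.kind == "nlddm" else "B"
        return min(values[bp].values())

    def absolute(self, x: np.ndarray) -> Dict[str, Dict[tuple, float]]:
        """De-fractionalize z, x0, sz against the smallest fitted boundary."""
        values = self._values(x)
        amin = self._domain_floor(values)
        fixed = self.config.fixed  # fixed values are already absolute
        if "z" in values and "z" not in fixed:
            values["z"] = {k: v * amin for k, v in values["z"].items()}
        if "x0" not in fixed:
            values["x0"] = {k: v * amin for k, v in values["x0"].items()}
        x0_ref = max(abs(v) for v in values["x0"].values())
        if "sz" not in fixed:
            values["sz"] = {k: v * (amin - x0_ref) for k, v in values["sz"].items()}
        return values

    def cell_params(self, values, cell: dict):
        g = lambda p: self._lookup(values, p, cell)
        if self.config.kind == "nlddm":
            return NlddmParams(
                k=g("k"), a=g("a"), z=g("z"), x0=g("x0"), sz=g("sz"),
                t_nd=g("t_nd"), sigma=g("sigma"),
            )
        return DdmParams(
            nu=g("nu"), B=g("B"), x0=g("x0"), sz=g("sz"), t_nd=g("t_nd"), sigma=g("sigma")
        )

    # -- objective ----------------------------------------------------------

    def nll(self, x: np.ndarray) -> float:
        self.n_eval += 1
        values = self.absolute(x)
        opt = self.options
        total = 0.0
        solved: Dict[tuple, FPTDSolution] = {}
        try:
            for cell, rts, correct in self.cells:
                params = self.cell_params(values, cell)
                key = tuple(sorted(cell.items()))
                if key not in solved:
                    decision = params.with_(t_nd=0.0)
                    solved[key] = solve_fptd(
                        decision,
                        dx=2.0 * params.boundary / opt.nx,
                        dt=opt.dt,
                        t_max=self.t_max,
                    )
                sol = solved[key]
                dec_t = rts - params.t_nd
                f_c = np.interp(dec_t[correct], sol.t, sol.f_correct, left=0.0, right=0.0)
                f_e = np.interp(dec_t[~correct], sol.t, sol.f_error, left=0.0, right=0.0)
                dens = np.concatenate([f_c, f_e])
                total += float(-np.sum(np.log(np.maximum(dens, DENSITY_FLOOR))))
        except (ValueError, FloatingPointError):
            return 1e12
        return total if np.isfinite(total) else 1e12


def fit_model(
    data: RTDataset,
    config: ModelConfig,
    seed: int = 0,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Global maximum-likelihood fit of ``config`` to ``data``.

    Differential evolution (seeded, population ``popsize * n_free``) explores
    the bounded fraction-parameterized space, then a Nelder–Mead polish
    refines the best point.  Non-convergence is reported in the
    ``converged`` flag, never silently.
    """
    options = options or FitOptions()
    prob = _Problem(data, config, options)
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)
    de = optimize.differential_evolution(
        prob.nll,
        bounds=prob.bounds,
        seed=rng_seed,
        maxiter=options.de_maxiter,
        popsize=options.popsize,
        tol=options.tol,
        init="sobol",
        polish=False,
        updating="immediate",
    )
    x_best, f_best = de.x, de.fun
    polished_ok = False
    if options.polish:
        local = optimize.minimize(
            prob.nll,
            x_best,
            method="Nelder-Mead",
            options={"maxfev": options.polish_maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        if np.isfinite(local.fun) and local.fun <= f_best:
            # clip back into bounds; Nelder-Mead is unconstrained
            xc = np.clip(local.x, [b[0] for b in prob.bounds], [b[1] for b in prob.bounds])
            fc = prob.nll(xc)
            if fc <= f_best:
                x_best, f_best = xc, fc
        polished_ok = bool(local.success)
    converged = bool((de.success or polished_ok) and np.isfinite(f_best) and f_best < 1e11)

    values = prob.absolute(x_best)
    rows = []
    for p, lev in prob.free:
        factors = config.factor_map.get(p, ())
        rows.append(
            {
                "parameter": p,
                "level": "/".join(str(v) for v in lev) if factors else "",
                "value": values[p][lev],
            }
        )
    n = len(data)
    k = config.n_free
    return FitResult(
        params=pd.DataFrame(rows),
        nll=float(f_best),
        bic=bic(float(f_best), k, n),
        n_samples=n,
        n_params=k,
        converged=converged,
        seed=int(seed),
        n_evaluations=prob.n_eval,
        config=config,
        x=np.asarray(x_best, dtype=float),
    )
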