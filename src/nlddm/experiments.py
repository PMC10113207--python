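"""Computational studies built on the toolkit.

Two study designs are provided:

* a one-at-a-time DDM parameter sweep — vary ``B``, ``nu``, ``x0`` and
  ``sz`` over their stated ranges around fixed defaults, simulate a dataset
  per grid point, refit the nl-DDM to each, and correlate generating DDM
  parameters with fitted nl-DDM parameters (Pearson);
* pairwise model comparison on BIC values — a normality check on the paired
  differences selects a one-sided paired t-test or a one-sided Wilcoxon
  signed-rank test — plus Bonferroni-corrected paired t-tests of fitted
  parameters across condition levels.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import FitOptions, build_config, fit_model
from .models import DdmParams
from .simulate import simulate_dataset

__all__ = [
    "SweepSpec",
    "CorrelationMatrix",
    "ModelComparison",
    "run_parameter_sweep",
    "correlation_matrix",
    "compare_models",
    "compare_parameters_across_conditions",
    "bonferroni_alpha",
]

logger = logging.getLogger(__name__)

SWEEP_DEFAULTS = dict(nu=0.2, B=1.0, x0=0.0, sz=0.0, t_nd=0.3, sigma=0.3)
SWEEP_RANGES = {
    "B": (0.2, 5.0),
    "nu": (0.0, 10.0),
    "x0": (-1.0, 1.0),
    "sz": (0.0, 1.0),
}
_SUPPORT_MARGIN = 0.98  # fraction of B the start support may reach


@dataclass
class SweepSpec:
    """One-at-a-time DDM sweep: grids, defaults, trial count, master seed."""

    defaults: DdmParams = field(default_factory=lambda: DdmParams(**SWEEP_DEFAULTS))
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=lambda: dict(SWEEP_RANGES))
    n_grid: int = 100
    n_trials: int = 500
    seed: int = 0
    dt: float = 5e-4
    t_max: float = 5.0

    def __post_init__(self):
        if self.n_grid < 1 or self.n_trials < 1:
            raise ValueError("n_grid and n_trials must be >= 1")
        for p in self.ranges:
            if p not in ("B", "nu", "x0", "sz"):
                raise ValueError(f"cannot sweep unknown DDM parameter {p!r}")

    @property
    def n_datasets(self) -> int:
        """Total generated datasets: one per grid point per swept parameter."""
        return self.n_grid * len(self.ranges)

    def grid(self):
        """Yield (parameter, requested value, feasible DdmParams) rows.

        Grids are uniform (inclusive) over each stated range.  Values that
        would place the start support on or past the absorbing boundary are
        recorded as requested but simulated with the support clipped to
        ``±0.98 B``, since absorbing dynamics require an interior start.
        """
        for p, (lo, hi) in self.ranges.items():
            for v in np.linspace(lo, hi, self.n_grid):
                raw = {
                    f: float(getattr(self.defaults, f))
                    for f in ("nu", "B", "x0", "sz", "t_nd", "sigma")
                }
                raw[p] = float(v)
                yield p, float(v), _feasible(raw)


def _feasible(raw: dict) -> DdmParams:
    half = _SUPPORT_MARGIN * raw["B"]
    lo = float(np.clip(raw["x0"] - raw["sz"], -half, half))
    hi = float(np.clip(raw["x0"] + raw["sz"], -half, half))
    return DdmParams(
        nu=raw["nu"], B=raw["B"], x0=(lo + hi) / 2, sz=(hi - lo) / 2,
        t_nd=raw["t_nd"], sigma=raw["sigma"],
    )


def run_parameter_sweep(
    spec: SweepSpec,
    options: Optional[FitOptions] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate each grid point's dataset and refit the nl-DDM to it.

    Following the generating conditions, ``sigma`` and ``t_nd`` are fixed at
    0.3 in the fitted nl-DDM; ``k, a, z, x0, sz`` are free.  Fit failures
    are recorded per dataset (NaN parameters, ``converged=False``), never
    fatal.  A fixed master seed reproduces the sweep row for row.
    """
    options = options or FitOptions()
    config = build_config("nlddm", fixed={"sigma": 0.3, "t_nd": 0.3})
    entries = list(spec.grid())
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * len(entries))
    rows = []
    for i, (p_name, requested, gen) in enumerate(entries):
        sim_seed = int(seeds[2 * i] & 0x7FFFFFFF)
        fit_seed = int(seeds[2 * i + 1] & 0x7FFFFFFF)
        row = {
            "param_varied": p_name,
            "B": spec.defaults.B,
            "nu": spec.defaults.nu,
            "x0": spec.defaults.x0,
            "sz": spec.defaults.sz,
            p_name: requested,
        }
        try:
            data = simulate_dataset(
                gen, spec.n_trials, dt=spec.dt, t_max=spec.t_max, seed=sim_seed
            )
            row["n_decided"] = len(data)
            fit = fit_model(data, config, seed=fit_seed, options=options)
            row.update(
                k=fit.value("k"),
                a=fit.value("a"),
                z=fit.value("z"),
                x0_nl=fit.value("x0"),
                sz_nl=fit.value("sz"),
                nll=fit.nll,
                bic=fit.bic,
                converged=fit.converged,
            )
        except Exception as exc:  # noqa: BLE001 - per-dataset failures are data
            logger.warning("sweep point %s=%.4g failed: %s", p_name, requested, exc)
            row.update(
                n_decided=row.get("n_decided", 0),
                k=np.nan, a=np.nan, z=np.nan, x0_nl=np.nan, sz_nl=np.nan,
                nll=np.nan, bic=np.nan, converged=False,
            )
        rows.append(row)
        if progress:
            logger.info("sweep %d/%d done (%s=%.4g)", i + 1, len(entries), p_name, requested)
    return pd.DataFrame(rows)


DDM_SWEEP_COLUMNS = ("B", "nu", "x0", "sz")
NLDDM_SWEEP_COLUMNS = ("k", "a", "z", "x0_nl", "sz_nl")


@dataclass
class CorrelationMatrix:
    """Pearson correlations between DDM and nl-DDM parameter columns.

    Within-DDM pairs are masked (their variation was imposed by the sweep
    design, so their correlations are artifacts); masked and undefined cells
    are listed explicitly.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    masked: list
    missing: list
    n: int

    def stars(self) -> pd.DataFrame:
        """Significance markers: * p<0.05, ** p<0.01, *** p<0.001."""

        def mark(pv):
            if not np.isfinite(pv):
                return ""
            return "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""

        return self.p.map(mark)

    def to_csv(self, path) -> None:
        """Tidy export: one row per cell with masked cells listed explicitly."""
        rows = []
        stars = self.stars()
        for x in self.rho.index:
            for y in self.rho.columns:
                rows.append(
                    {
                        "param_x": x,
                        "param_y": y,
                        "rho": self.rho.loc[x, y],
                        "p": self.p.loc[x, y],
                        "stars": stars.loc[x, y],
                        "masked": (x, y) in self.masked or (y, x) in self.masked,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def correlation_matrix(
    sweep: pd.DataFrame,
    ddm_columns: Sequence[str] = DDM_SWEEP_COLUMNS,
    nlddm_columns: Sequence[str] = NLDDM_SWEEP_COLUMNS,
) -> CorrelationMatrix:
    """Pearson rho and two-sided p per parameter pair over complete rows.

    p-values use the exact t reference with n - 2 degrees of freedom.
    Constant columns make rho undefined; such pairs are reported missing.
    """
    cols = list(ddm_columns) + list(nlddm_columns)
    complete = sweep[cols].dropna()
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 complete sweep rows, got {n}")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(pmat.values, np.nan)
    masked, missing = [], []
    for x, y in itertools.combinations(cols, 2):
        if x in ddm_columns and y in ddm_columns:
            rho.loc[x, y] = rho.loc[y, x] = np.nan
            pmat.loc[x, y] = pmat.loc[y, x] = np.nan
            masked.append((x, y))
            continue
        xv, yv = complete[x].to_numpy(), complete[y].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            rho.loc[x, y] = rho.loc[y, x] = np.nan
            pmat.loc[x, y] = pmat.loc[y, x] = np.nan
            missing.append((x, y))
            continue
        r, pv = stats.pearsonr(xv, yv)
        rho.loc[x, y] = rho.loc[y, x] = r
        pmat.loc[x, y] = pmat.loc[y, x] = pv
    return CorrelationMatrix(rho=rho, p=pmat, masked=masked, missing=missing, n=n)


@dataclass
class ModelComparison:
    """One-sided paired comparison of two BIC (or loss) sequences."""

    n: int
    mean_diff: float
    shapiro_statistic: float
    shapiro_p: float
    branch: str  # "t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    effect_size: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_models(
    bic_model: Sequence[float], bic_reference: Sequence[float], alpha: float = 0.05
) -> ModelComparison:
    """Test whether ``bic_model`` is systematically below ``bic_reference``.

    Differences are checked for normality (Shapiro–Wilk at ``alpha``); if
    normality is not rejected a one-sided paired t-test runs, otherwise a
    one-sided Wilcoxon signed-rank test.  Effect size is Cohen's d for the
    t branch and the matched-pairs rank-biserial correlation for the
    signed-rank branch.
    """
    a = np.asarray(bic_model, dtype=float)
    b = np.asarray(bic_reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired BIC lists must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    d = a - b
    if np.all(d == 0):
        return ModelComparison(n, 0.0, np.nan, np.nan, "degenerate", 0.0, 1.0, 0.0, alpha)
    if np.std(d) == 0:
        # constant nonzero shift: normality is undefined, the exact
        # signed-rank null still applies
        sw_stat, sw_p = np.nan, np.nan
        branch = "wilcoxon"
    else:
        sw_stat, sw_p = stats.shapiro(d)
        branch = "t" if sw_p >= alpha else "wilcoxon"
    if branch == "t":
        res = stats.ttest_rel(a, b, alternative="less")
        effect = float(np.mean(d) / np.std(d, ddof=1))
        return ModelComparison(
            n, float(np.mean(d)), float(sw_stat), float(sw_p), "t",
            float(res.statistic), float(res.pvalue), effect, alpha,
        )
    res = stats.wilcoxon(d, alternative="less")
    nz = d[d != 0]
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    effect = (w_pos - w_neg) / (w_pos + w_neg)
    return ModelComparison(
        n, float(np.mean(d)), float(sw_stat), float(sw_p), "wilcoxon",
        float(res.statistic), float(res.pvalue), float(effect), alpha,
    )


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Family alpha divided by the number of comparisons."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons


def compare_parameters_across_conditions(
    values: pd.DataFrame,
    alpha: float = 0.05,
    levels: Optional[Sequence] = None,
) -> Tuple[pd.DataFrame, float]:
    """All pairwise paired t-tests of a fitted parameter across levels.

    ``values`` has columns ``participant``, ``level``, ``value`` (one fitted
    value per participant and level).  Participants missing any level are
    excluded with a logged warning.  Returns the comparison table and the
    Bonferroni-corrected alpha (family ``alpha`` / number of pairs).
    """
    required = {"participant", "level", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values table needs columns {sorted(required)}")
    wide = values.pivot_table(index="participant", columns="level", values="value")
    if levels is None:
        levels = list(wide.columns)
    else:
        missing_levels = [l for l in levels if l not in wide.columns]
        if missing_levels:
            raise ValueError(f"levels {missing_levels} absent from the data")
    incomplete = wide.index[wide[list(levels)].isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "excluding %d participant(s) with missing levels: %s",
            len(incomplete), list(incomplete),
        )
        wide = wide.drop(index=incomplete)
    pairs = list(itertools.combinations(levels, 2))
    corrected = bonferroni_alpha(alpha, len(pairs))
    rows = []
    for la, lb in pairs:
        x, y = wide[la].to_numpy(), wide[lb].to_numpy()
        diff = x - y
        if np.all(diff == 0):
            t_stat, pv = 0.0, 1.0
        else:
            res = stats.ttest_rel(x, y)
            t_stat, pv = float(res.statistic), float(res.pvalue)
        sd = np.std(diff, ddof=1)
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "t": t_stat,
                "df": len(x) - 1,
                "p": pv,
                "cohen_d": float(np.mean(diff) / sd) if sd > 0 else 0.0,
                "significant": pv < corrected,
            }
        )
    return pd.DataFrame(rows), corrected
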