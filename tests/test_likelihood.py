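"""Likelihood evaluation, BIC, configuration counts and fitting behavior."""
import math

import numpy as np
import pandas as pd
import pytest

from nlddm import (
    DdmParams,
    FPTDSolution,
    NlddmParams,
    RTDataset,
    apply_nondecision_shift,
    bic,
    build_config,
    fit_model,
    lexical_config,
    multisensory_config,
    negative_log_likelihood,
    simulate_dataset,
    solve_fptd,
)
from nlddm.likelihood import DENSITY_FLOOR, FitOptions


def _flat_solution(height=1.0, dt=0.01, t_end=1.0):
    """A synthetic defective density that is constant on [0, t_end]."""
    n = int(t_end / dt)
    t = dt * (np.arange(n) + 0.5)
    return FPTDSolution(
        t=t,
        f_correct=np.full(n, height),
        f_error=np.zeros(n),
        undecided_mass=0.0,
        dt=dt,
        dx=0.01,
        domain=(-1, 1),
    )


def _one_trial(rt, correct=True):
    return RTDataset(
        trials=pd.DataFrame({"participant": ["p"], "rt": [rt], "correct": [correct]})
    )


def test_nll_is_zero_where_density_is_one():
    assert negative_log_likelihood(_one_trial(0.5), {(): _flat_solution()}) == pytest.approx(0.0)


def test_nll_floors_rts_before_nondecision_time():
    sol = apply_nondecision_shift(_flat_solution(), 0.4)
    nll = negative_log_likelihood(_one_trial(0.2), {(): sol})
    assert nll == pytest.approx(-math.log(DENSITY_FLOOR))


def test_nll_rejects_rt_beyond_horizon():
    with pytest.raises(ValueError, match="beyond"):
        negative_log_likelihood(_one_trial(2.0), {(): _flat_solution()})


def test_nll_requires_solution_per_condition():
    data = RTDataset(
        trials=pd.DataFrame(
            {"participant": ["p", "p"], "rt": [0.4, 0.5],
             "correct": [True, True], "stimulus": ["face", "number"]}
        )
    )
    with pytest.raises(KeyError):
        negative_log_likelihood(data, {("face",): _flat_solution()}, by=("stimulus",))


def test_nll_prefers_generating_parameters_over_flipped_drift():
    true = DdmParams(nu=0.8, B=1.0, t_nd=0.3, sigma=0.3)
    data = simulate_dataset(true, 2000, seed=8)
    sols = {
        name: {(): solve_fptd(p.with_(t_nd=0.0), t_max=float(data.rt.max()))}
        for name, p in {"true": true, "flipped": true.with_(nu=-0.8)}.items()
    }
    shift = lambda d: {k: apply_nondecision_shift(s, 0.3) for k, s in d.items()}
    nll_true = negative_log_likelihood(data, shift(sols["true"]))
    nll_flip = negative_log_likelihood(data, shift(sols["flipped"]))
    assert nll_true < nll_flip


@pytest.mark.parametrize(
    "nll, k, n, expected",
    [
        (0.0, 0, 10, 0.0),
        (500.0, 7, 100, 7 * math.log(100) + 1000.0),
        (500.0, 6, 100, 6 * math.log(100) + 1000.0),
    ],
)
def test_bic_formula(nll, k, n, expected):
    assert bic(nll, k, n) == pytest.approx(expected)


def test_bic_penalty_is_monotone_in_parameter_count():
    assert bic(500.0, 7, 100) > bic(500.0, 6, 100)


def test_bic_rejects_empty_sample():
    with pytest.raises(ValueError):
        bic(10.0, 2, 0)


def test_configuration_free_parameter_counts():
    assert multisensory_config("ddm").n_free == 6
    assert multisensory_config("nlddm").n_free == 7
    assert lexical_config("ddm").n_free == 11
    assert lexical_config("nlddm").n_free == 11


def test_configuration_declares_levels_and_bounds():
    cfg = lexical_config("nlddm")
    names = [p for p, _ in cfg.free_parameters()]
    assert names.count("z") == 4 and names.count("a") == 2 and names.count("k") == 2
    for p, _ in cfg.free_parameters():
        lo, hi = cfg.bounds[p]
        assert np.isfinite(lo) and np.isfinite(hi) and lo < hi


def test_configuration_rejects_unknown_factor_or_parameter():
    with pytest.raises(ValueError):
        build_config("nlddm", factor_map={"z": ("stimulus",)})  # undeclared levels
    with pytest.raises(ValueError):
        build_config("ddm", factor_map={"k": ("stimulus",)}, levels={"stimulus": ("a", "b")})
    with pytest.raises(ValueError):
        build_config("wiener-cascade")


def test_fit_rejects_empty_dataset(fast_fit_options):
    empty = RTDataset(trials=pd.DataFrame(columns=["participant", "rt", "correct"]))
    with pytest.raises(ValueError):
        fit_model(empty, build_config("nlddm"), options=fast_fit_options)


def test_fit_recovers_bias_direction_and_bic_invariant(fast_fit_options):
    """Smoke-scale fit: the sign of z and the BIC identity must hold."""
    true = NlddmParams(k=2.0, a=1.0, z=-0.3, t_nd=0.3, sigma=0.3)
    data = simulate_dataset(true, 600, seed=14)
    cfg = build_config("nlddm", fixed={"sigma": 0.3, "t_nd": 0.3})
    fit = fit_model(data, cfg, seed=3, options=fast_fit_options)
    assert fit.value("z") < 0
    assert fit.bic == bic(fit.nll, fit.n_params, fit.n_samples)  # exact
    assert fit.n_params == cfg.n_free == 5
    assert fit.n_samples == len(data)


def test_fit_respects_fixed_parameters(fast_fit_options):
    data = simulate_dataset(DdmParams(nu=0.8, B=1.0, t_nd=0.3, sigma=0.3), 400, seed=2)
    cfg = build_config("ddm", fixed={"sigma": 0.3, "t_nd": 0.3, "x0": 0.0, "sz": 0.0})
    fit = fit_model(data, cfg, seed=5, options=fast_fit_options)
    assert set(fit.params["parameter"]) == {"nu", "B"}
    assert fit.n_params == 2


def test_fit_result_export(tmp_path, fast_fit_options):
    data = simulate_dataset(DdmParams(nu=0.8, B=1.0, t_nd=0.3, sigma=0.3), 300, seed=2)
    cfg = build_config("ddm", fixed={"sigma": 0.3, "t_nd": 0.3, "x0": 0.0, "sz": 0.0})
    fit = fit_model(data, cfg, seed=5, options=fast_fit_options)
    out = tmp_path / "fit.csv"
    fit.export(out)
    back = pd.read_csv(out, keep_default_na=False)
    assert float(back.loc[back["parameter"] == "_bic", "value"].iloc[0]) == pytest.approx(fit.bic)
    assert len(back[~back["parameter"].str.startswith("_")]) == fit.n_params


def test_condition_dependent_fit_uses_per_condition_densities(fast_fit_options):
    """Two stimuli with opposite bias: fitted z values must separate in sign."""
    face = NlddmParams(k=2.5, a=1.0, z=-0.35, t_nd=0.3, sigma=0.3)
    number = NlddmParams(k=2.5, a=1.0, z=0.35, t_nd=0.3, sigma=0.3)
    parts = [
        simulate_dataset(face, 400, seed=21, conditions={"stimulus": "face"}).trials,
        simulate_dataset(number, 400, seed=22, conditions={"stimulus": "number_sound"}).trials,
    ]
    data = RTDataset(trials=pd.concat(parts, ignore_index=True))
    cfg = build_config(
        "nlddm", factor_map={"z": ("stimulus",)},
        levels={"stimulus": ("face", "number_sound")},
        fixed={"sigma": 0.3, "t_nd": 0.3},
    )
    fit = fit_model(data, cfg, seed=9, options=fast_fit_options)
    assert fit.value("z", ("face",)) < 0 < fit.value("z", ("number_sound",))
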