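"""Sweep machinery, correlation matrices and paired model/parameter tests."""
import numpy as np
import pandas as pd
import pytest

from nlddm import (
    SweepSpec,
    bonferroni_alpha,
    compare_models,
    compare_parameters_across_conditions,
    correlation_matrix,
    run_parameter_sweep,
)
from nlddm.likelihood import FitOptions


def test_sweep_spec_dataset_count():
    assert SweepSpec(n_grid=100).n_datasets == 400
    assert SweepSpec(n_grid=3).n_datasets == 12


def test_sweep_grids_are_uniform_and_one_at_a_time():
    spec = SweepSpec(n_grid=5)
    rows = list(spec.grid())
    assert len(rows) == 20
    b_values = [v for p, v, _ in rows if p == "B"]
    np.testing.assert_allclose(b_values, np.linspace(0.2, 5.0, 5))
    for p, v, params in rows:
        for other in ("B", "nu"):
            if other != p:
                assert getattr(params, other) == getattr(spec.defaults, other)


def test_sweep_clips_infeasible_start_support():
    spec = SweepSpec(n_grid=3)
    by_param = {(p, round(v, 3)): params for p, v, params in spec.grid()}
    edge = by_param[("x0", 1.0)]
    assert edge.x0 == pytest.approx(0.98)  # requested 1.0, clipped inside B=1
    wide = by_param[("sz", 1.0)]
    assert wide.x0 + wide.sz <= 0.98


def test_small_sweep_runs_and_is_reproducible(fast_fit_options):
    spec = SweepSpec(n_grid=2, n_trials=150, seed=77, t_max=3.0)
    a = run_parameter_sweep(spec, options=fast_fit_options)
    b = run_parameter_sweep(spec, options=fast_fit_options)
    assert len(a) == 8
    assert {"param_varied", "k", "a", "z", "x0_nl", "sz_nl"} <= set(a.columns)
    pd.testing.assert_frame_equal(a, b)


def _synthetic_sweep_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    b = rng.uniform(0.2, 5.0, n)
    nu = rng.uniform(0.0, 10.0, n)
    x0 = rng.uniform(-1.0, 1.0, n)
    sz = rng.uniform(0.0, 1.0, n)
    return pd.DataFrame(
        {
            "B": b, "nu": nu, "x0": x0, "sz": sz,
            "k": 2 * b + rng.normal(0, 0.1, n),
            "a": -nu + rng.normal(0, 0.1, n),
            "z": 0.5 * nu + rng.normal(0, 0.1, n),
            "x0_nl": x0 + rng.normal(0, 0.05, n),
            "sz_nl": np.full(n, 0.3),  # constant -> undefined correlations
        }
    )


def test_correlation_matrix_structure():
    cm = correlation_matrix(_synthetic_sweep_table())
    # symmetry and unit diagonal
    pd.testing.assert_frame_equal(cm.rho, cm.rho.T)
    np.testing.assert_allclose(np.diag(cm.rho), 1.0)
    assert ((cm.rho.abs() <= 1.0) | cm.rho.isna()).all().all()
    # within-DDM pairs masked
    assert np.isnan(cm.rho.loc["B", "nu"])
    assert ("B", "nu") in cm.masked
    # planted relations recovered with sign
    assert cm.rho.loc["B", "k"] > 0.9
    assert cm.rho.loc["nu", "a"] < -0.9
    assert cm.p.loc["B", "k"] < 0.001
    # constant column reported missing, not crashed
    assert np.isnan(cm.rho.loc["B", "sz_nl"])
    assert any("sz_nl" in pair for pair in cm.missing)


def test_correlation_matrix_stars_and_export(tmp_path):
    cm = correlation_matrix(_synthetic_sweep_table())
    assert cm.stars().loc["B", "k"] == "***"
    out = tmp_path / "corr.csv"
    cm.to_csv(out)
    tidy = pd.read_csv(out)
    assert tidy["masked"].any()
    row = tidy[(tidy.param_x == "B") & (tidy.param_y == "nu")].iloc[0]
    assert bool(row["masked"])


def test_correlation_matrix_requires_enough_rows():
    with pytest.raises(ValueError):
        correlation_matrix(_synthetic_sweep_table(n=2))


def test_compare_models_identical_lists_not_significant():
    rep = compare_models([10.0, 11.0, 12.0, 13.0], [10.0, 11.0, 12.0, 13.0])
    assert rep.branch == "degenerate"
    assert rep.p_value == 1.0 and not rep.significant


def test_compare_models_constant_shift_is_significant():
    rng = np.random.default_rng(1)
    a = rng.normal(1000.0, 50.0, 25)
    rep = compare_models(a - 10.0, a)
    # constant differences: normality undefined, exact signed-rank null applies
    assert rep.branch == "wilcoxon"
    assert rep.p_value < 0.05 and rep.significant
    assert rep.effect_size == pytest.approx(-1.0)


def test_compare_models_branch_selection():
    rng = np.random.default_rng(7)
    base = rng.normal(1000.0, 30.0, 40)
    gaussian = compare_models(base + rng.normal(-5.0, 2.0, 40), base)
    assert gaussian.branch == "t"
    heavy = compare_models(base + rng.standard_cauchy(40) * 20.0 - 5.0, base)
    assert heavy.branch == "wilcoxon"


def test_compare_models_input_validation():
    with pytest.raises(ValueError):
        compare_models([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        compare_models([1.0, 2.0], [1.0, 2.0])


def test_bonferroni_alpha_matches_six_comparison_family():
    assert bonferroni_alpha(0.05, 6) == pytest.approx(0.05 / 6)
    assert round(bonferroni_alpha(0.05, 6), 3) == 0.008
    assert bonferroni_alpha(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


def _values_table(n_participants=12, levels=("l1", "l2", "l3", "l4"), shift=0.0, seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        base = rng.normal(1.0, 0.1)
        for j, level in enumerate(levels):
            rows.append(
                {"participant": f"p{i}", "level": level, "value": base + shift * j + rng.normal(0, 0.02)}
            )
    return pd.DataFrame(rows)


def test_pairwise_parameter_comparisons_four_levels():
    table, alpha = compare_parameters_across_conditions(_values_table(shift=0.3))
    assert len(table) == 6
    assert alpha == pytest.approx(0.05 / 6)
    assert table["significant"].all()


def test_pairwise_parameter_comparisons_two_levels():
    table, alpha = compare_parameters_across_conditions(_values_table(levels=("early", "late")))
    assert len(table) == 1
    assert alpha == 0.05


def test_pairwise_comparisons_identical_values_give_zero_t():
    df = _values_table(levels=("a", "b"))
    df["value"] = 1.0
    table, _ = compare_parameters_across_conditions(df)
    assert (table["t"] == 0.0).all() and (table["p"] == 1.0).all()


def test_pairwise_comparisons_exclude_incomplete_participants(caplog):
    df = _values_table(shift=0.3)
    df = df[~((df.participant == "p0") & (df.level == "l4"))]
    with caplog.at_level("WARNING"):
        table, _ = compare_parameters_across_conditions(df)
    assert "p0" in caplog.text
    assert (table["df"] == 10).all()  # 12 participants minus excluded, minus 1
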