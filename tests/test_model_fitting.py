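"""Perturbation sweeps, best-fit selection, classification, attribution."""

import numpy as np
import pytest

from slimsig import (
    FlowSample,
    MutantEffect,
    SyntheticSpec,
    attribute_parameter,
    best_fit_and_classify,
    default_fraction_grid,
    gen_effect_mutant,
    gen_model_truth_experiment,
    sweep_parameter,
    wt_model_divergences,
)
from slimsig.model_fitting import SweepResult


def test_default_grid_is_20_points_plus_baseline():
    grid = default_fraction_grid()
    assert grid.size == 21
    assert grid[0] == 0.0
    assert grid[-2] == pytest.approx(0.95)
    assert grid[-1] == 1.0
    assert np.allclose(np.diff(grid[:-1]), 0.05)
    half = default_fraction_grid(max_fraction=0.5, include_baseline=False)
    assert half.size == 11
    assert half[-1] == pytest.approx(0.5)


def test_sweep_validation(default_params):
    with pytest.raises(ValueError, match="parameter_group"):
        sweep_parameter(default_params, "translation", [0.5], [], [], None)
    with pytest.raises(ValueError, match="empty fraction grid"):
        sweep_parameter(default_params, "activity", [], [], [], None)


@pytest.fixture(scope="module")
def truth_ctx(default_params):
    return gen_model_truth_experiment(
        default_params, "activity", 0.5, n_replicates=4, n_cells=4_000, seed=7
    )


def test_missing_uninduced_control_raises(default_params, truth_ctx):
    with pytest.raises(ValueError, match="uninduced control"):
        sweep_parameter(
            default_params,
            "activity",
            [1.0],
            truth_ctx["induced"],
            truth_ctx["uninduced"][:1],
            truth_ctx["wt_reference"],
            n_cells=2_000,
            seed=1,
        )


def test_fraction_one_column_anchors_to_wt_model_divergence(default_params, truth_ctx):
    cache = {}
    sweep = sweep_parameter(
        default_params,
        "activity",
        np.array([0.5, 1.0]),
        truth_ctx["induced"],
        truth_ctx["uninduced"],
        truth_ctx["wt_reference"],
        n_cells=3_000,
        seed=5,
        sim_cache=cache,
    )
    wt_divs = wt_model_divergences(
        default_params,
        truth_ctx["induced"],
        truth_ctx["uninduced"],
        truth_ctx["wt_reference"],
        n_cells=3_000,
        seed=5,
        sim_cache=cache,
    )
    assert np.allclose(sweep.per_replicate_kl[:, -1], wt_divs)


def test_sweep_result_consistency(default_params, truth_ctx):
    sweep = sweep_parameter(
        default_params,
        "remodeling",
        np.array([0.25, 0.75, 1.0]),
        truth_ctx["induced"],
        truth_ctx["uninduced"],
        truth_ctx["wt_reference"],
        n_cells=2_000,
        seed=2,
    )
    assert sweep.per_replicate_kl.shape == (4, 3)
    n = sweep.per_replicate_kl.shape[0]
    assert np.allclose(
        sweep.se_kl, sweep.per_replicate_kl.std(axis=0, ddof=1) / np.sqrt(n)
    )
    with pytest.raises(ValueError, match="strictly increasing"):
        SweepResult(
            strain="s",
            parameter_group="activity",
            fractions=np.array([0.5, 0.5]),
            per_replicate_kl=np.zeros((2, 2)),
            replicates=("r1", "r2"),
            n_cells_per_point=100,
            seed=0,
        )


def _toy_sweep(group, fractions, kl_matrix, strain="toy"):
    kl_matrix = np.asarray(kl_matrix, dtype=float)
    return SweepResult(
        strain=strain,
        parameter_group=group,
        fractions=np.asarray(fractions, dtype=float),
        per_replicate_kl=kl_matrix,
        replicates=tuple(f"r{i}" for i in range(kl_matrix.shape[0])),
        n_cells_per_point=1000,
        seed=0,
    )


def test_argmin_ties_break_toward_baseline():
    kl = np.array([[0.2, 0.1, 0.1], [0.2, 0.1, 0.1], [0.3, 0.1, 0.1]])
    sweep = _toy_sweep("activity", [0.0, 0.5, 1.0], kl)
    fit = best_fit_and_classify([sweep], np.array([0.1, 0.1, 0.12]))
    assert fit.best_fraction == 1.0


def test_saturated_columns_are_excluded_from_argmin():
    kl = np.array([[np.inf, 0.3, 0.2], [np.inf, 0.25, 0.22]])
    sweep = _toy_sweep("activity", [0.0, 0.5, 1.0], kl)
    fit = best_fit_and_classify([sweep], np.array([0.2, 0.21, 0.19]))
    assert np.isfinite(fit.best_mean_kl)
    assert fit.best_fraction == 1.0


def test_attribution_identical_sets_not_identifiable():
    a = np.array([0.01, 0.02, 0.03, 0.04])
    identifiable, p = attribute_parameter(a, a.copy())
    assert not identifiable
    assert p == 1.0


def test_attribution_separated_sets_identifiable():
    identifiable, p = attribute_parameter(
        [0.01, 0.02, 0.02, 0.03], [0.50, 0.60, 0.70, 0.80]
    )
    assert identifiable
    assert p == pytest.approx(2 / 70)


def test_attribution_requires_matched_sizes():
    with pytest.raises(ValueError, match="same replicates"):
        attribute_parameter([0.1, 0.2], [0.1, 0.2, 0.3])


def test_wt_self_fit_is_explained_at_baseline(default_params):
    ctx = gen_model_truth_experiment(
        default_params, "activity", 1.0, n_replicates=4, n_cells=4_000, seed=19
    )
    cache = {}
    grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    sweeps = [
        sweep_parameter(
            default_params,
            g,
            grid,
            ctx["induced"],
            ctx["uninduced"],
            ctx["wt_reference"],
            n_cells=6_000,
            seed=23,
            sim_cache=cache,
        )
        for g in ("activity", "remodeling")
    ]
    wt_divs = wt_model_divergences(
        default_params,
        ctx["induced"],
        ctx["uninduced"],
        ctx["wt_reference"],
        n_cells=6_000,
        seed=23,
        sim_cache=cache,
    )
    fit = best_fit_and_classify(sweeps, wt_divs)
    # the KL surface is flat near the unperturbed model (weak identifiability
    # close to baseline), so the self-fit may settle one grid step away
    assert fit.best_fraction >= 0.75
    assert fit.explained


def test_mutant_beyond_model_reach_is_not_explained(default_params):
    # a bimodal mutant whose two modes are far wider apart than any
    # single-fraction perturbation of the model can produce
    spec = SyntheticSpec(
        n_days=1,
        reps_per_day=4,
        n_events=4_000,
        uninduced_law=(2.0, 0.3),
        induced_law=(9.0, 0.3),
        seed=31,
    )
    mut = gen_effect_mutant(spec, MutantEffect("bimodal", 0.5, 0.0), strain="wide")
    induced = [s for s in mut if s.condition == "induced"]
    uninduced = [s for s in mut if s.condition == "uninduced"]
    ctx = gen_model_truth_experiment(
        default_params, "activity", 1.0, n_replicates=6, n_cells=4_000, seed=37
    )
    cache = {}
    grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    sweeps = [
        sweep_parameter(
            default_params,
            g,
            grid,
            induced,
            uninduced,
            ctx["wt_reference"],
            n_cells=4_000,
            seed=41,
            sim_cache=cache,
        )
        for g in ("activity", "remodeling")
    ]
    wt_divs = wt_model_divergences(
        default_params,
        ctx["induced"],
        ctx["uninduced"],
        ctx["wt_reference"],
        n_cells=4_000,
        seed=41,
        sim_cache=cache,
    )
    fit = best_fit_and_classify(sweeps, wt_divs)
    assert not fit.explained
    assert fit.best_mean_kl > 5 * np.mean(wt_divs)


def test_flexibility_best_fit_no_worse_than_baseline(default_params, truth_ctx):
    cache = {}
    grid = np.array([0.25, 0.5, 0.75, 1.0])
    sweep = sweep_parameter(
        default_params,
        "activity",
        grid,
        truth_ctx["induced"],
        truth_ctx["uninduced"],
        truth_ctx["wt_reference"],
        n_cells=3_000,
        seed=47,
        sim_cache=cache,
    )
    assert sweep.mean_kl.min() <= sweep.mean_kl[-1]
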