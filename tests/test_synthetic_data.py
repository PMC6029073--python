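"""Synthetic experiment generator: structure, determinism, effect laws."""

import numpy as np
import pytest

from slimsig import (
    HogModelParams,
    MutantEffect,
    SyntheticSpec,
    compute_divergences,
    gen_effect_mutant,
    gen_model_truth_mutant,
    gen_wt_experiment,
    pool_wt,
    simulate_population,
)
from slimsig.reporter_calibration import add_basal

from conftest import kde_mode_count


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(n_events=0)
    with pytest.raises(ValueError):
        SyntheticSpec(reps_per_day=0)
    with pytest.raises(ValueError):
        SyntheticSpec(uninduced_law=(4.0, 0.0))
    with pytest.raises(ValueError):
        MutantEffect(magnitude=1.5)
    with pytest.raises(ValueError):
        MutantEffect(kind="sharp")


def test_determinism_bit_identical(small_spec):
    a = gen_wt_experiment(small_spec)
    b = gen_wt_experiment(small_spec)
    assert len(a) == len(b)
    for x, y in zip(a, b):
        assert x.key == y.key
        assert np.array_equal(x.intensities, y.intensities)


def test_replicate_day_structure(small_spec):
    samples = gen_wt_experiment(small_spec)
    days = {s.experiment_day for s in samples}
    assert days == {"day1", "day2"}
    for day in days:
        induced = [s for s in samples if s.experiment_day == day and s.condition == "induced"]
        uninduced = [s for s in samples if s.experiment_day == day and s.condition == "uninduced"]
        assert len(induced) == len(uninduced) == 3


def test_default_reps_per_day_drawn_from_3_4():
    spec = SyntheticSpec(n_days=6, reps_per_day=None, n_events=200, seed=5)
    samples = gen_wt_experiment(spec)
    for d in range(1, 7):
        n = sum(
            1
            for s in samples
            if s.experiment_day == f"day{d}" and s.condition == "induced"
        )
        assert n in (3, 4)


def test_wt_replicate_to_pool_divergence_band():
    # the generator's noise defaults are calibrated so that replicate-to-pool
    # divergence sits at the replicate-noise scale of the real assay
    spec = SyntheticSpec(n_days=2, reps_per_day=4, n_events=50_000, seed=42)
    wt = gen_wt_experiment(spec)
    pools = {d: pool_wt(wt, d) for d in ("day1", "day2")}
    records = compute_divergences(wt, pools)
    med = np.median([r.kl_nats for r in records])
    assert 0.005 <= med <= 0.05


def test_graded_magnitude_zero_identical_to_wt(small_spec):
    wt = gen_wt_experiment(small_spec)
    mut = gen_effect_mutant(small_spec, MutantEffect("graded", 0.0), strain="m0")
    for x, y in zip(wt, mut):
        assert np.array_equal(x.intensities, y.intensities)


def test_graded_half_magnitude_hits_midpoint():
    spec = SyntheticSpec(n_days=1, reps_per_day=4, n_events=50_000, seed=9)
    mut = gen_effect_mutant(spec, MutantEffect("graded", 0.5), strain="m50")
    mu_u, _ = spec.uninduced_law
    mu_i, _ = spec.induced_law
    midpoint = (mu_u + mu_i) / 2
    logs = np.concatenate(
        [s.intensities for s in mut if s.condition == "induced"]
    )
    logs = np.log(logs)
    # replicate/day jitter contributes to the spread around the midpoint
    spread = np.sqrt(spec.induced_law[1] ** 2 / logs.size + spec.day_batch_sd**2 + spec.rep_sd**2 / 4)
    assert abs(logs.mean() - midpoint) <= 3 * spread


def test_graded_monotonicity_in_magnitude(small_spec):
    means = []
    for mag in (0.0, 0.25, 0.5, 0.75, 1.0):
        mut = gen_effect_mutant(small_spec, MutantEffect("graded", mag), strain="m")
        means.append(
            np.mean(
                np.concatenate(
                    [s.intensities for s in mut if s.condition == "induced"]
                )
            )
        )
    assert all(a > b for a, b in zip(means, means[1:]))


def test_uninduced_law_unaffected_by_effect(small_spec):
    wt = gen_wt_experiment(small_spec)
    mut = gen_effect_mutant(small_spec, MutantEffect("bimodal", 0.6, 0.5), strain="mb")
    for x, y in zip(wt, mut):
        if x.condition == "uninduced":
            assert np.array_equal(x.intensities, y.intensities)


def test_bimodal_mutant_is_bimodal_wt_is_not():
    spec = SyntheticSpec(n_days=1, reps_per_day=3, n_events=50_000, seed=30)
    mut = gen_effect_mutant(
        spec, MutantEffect("bimodal", 0.5, weak_mode_attenuation=0.5), strain="hot1"
    )
    sample = next(s for s in mut if s.condition == "induced")
    # flow histograms are examined on log scale
    assert kde_mode_count(np.log(sample.intensities)) >= 2
    wt = gen_wt_experiment(spec)
    wt_sample = next(s for s in wt if s.condition == "induced")
    assert kde_mode_count(np.log(wt_sample.intensities)) == 1


def test_model_truth_fraction_one_is_unperturbed(default_params):
    a = gen_model_truth_mutant(default_params, "activity", 1.0, n_cells=500, seed=3)
    sim = simulate_population(default_params, n_cells=500, seed=3)
    expected = 3.0 * add_basal(sim.protein_counts, seed=3 + 1_000_003) + 100.0
    assert np.array_equal(a.intensities, expected)


def test_model_truth_activity_reduction_lowers_mean(default_params):
    lo = gen_model_truth_mutant(default_params, "activity", 0.25, n_cells=5_000, seed=8)
    hi = gen_model_truth_mutant(default_params, "activity", 1.0, n_cells=5_000, seed=8)
    se = np.sqrt(
        lo.intensities.var(ddof=1) / lo.n_events
        + hi.intensities.var(ddof=1) / hi.n_events
    )
    assert lo.intensities.mean() < hi.intensities.mean() - 3 * se


def test_model_truth_validation(default_params):
    with pytest.raises(ValueError):
        gen_model_truth_mutant(default_params, "activity", 1.5, n_cells=100, seed=0)
    with pytest.raises(ValueError):
        gen_model_truth_mutant(default_params, "speed", 0.5, n_cells=100, seed=0)


def test_wt_self_divergence_below_graded_mutant_divergence():
    # rank-based separation between WT self-noise and a magnitude-0.2 mutant
    from slimsig import wilcoxon_rank_sum

    ok = 0
    n_seeds = 6
    for seed in range(n_seeds):
        spec = SyntheticSpec(n_days=2, reps_per_day=4, n_events=5_000, seed=100 + seed)
        wt = gen_wt_experiment(spec)
        pools = {d: pool_wt(wt, d) for d in ("day1", "day2")}
        wt_kl = [r.kl_nats for r in compute_divergences(wt, pools)]
        mut = gen_effect_mutant(spec, MutantEffect("graded", 0.2), strain="m20")
        mut_kl = [r.kl_nats for r in compute_divergences(mut, pools)]
        if wilcoxon_rank_sum(mut_kl, wt_kl, "greater") < 0.05:
            ok += 1
    assert ok >= 0.9 * n_seeds
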