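"""Synthetic flow-cytometry experiments with realistic replicate structure.

No public single-cell dataset accompanies the reporter assay this package
analyzes, so the pipeline is validated on synthetic experiments that
emulate its statistical structure:

* wild-type replicates organized by experiment day (3-4 replicates per
  day, ~50,000 events each), with a day-level batch shift shared by all
  replicates of a day and a smaller replicate-level jitter, producing
  replicate-to-day-pool KL divergences of order 0.01 — the empirically
  reported scale of replicate noise in such assays;
* graded-effect mutants whose induced distribution slides from the
  wild-type induced law toward the uninduced law;
* bimodal mutants: a mixture of non-responding cells (identical in law to
  the uninduced state) and weakly responding cells;
* ground-truth "model mutants" simulated from the stochastic HOG model
  with a known perturbed parameter fraction, for parameter-recovery tests.

Fluorescence is lognormal (positive, right-skewed, as flow data are); the
parametric form is a modeling choice of this package, not a measured fact.
All sampling is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .flow_io import FlowSample
from .hog_model import HogModelParams, simulate_population
from .reporter_calibration import add_basal

__all__ = [
    "SyntheticSpec",
    "MutantEffect",
    "gen_wt_experiment",
    "gen_effect_mutant",
    "gen_model_truth_mutant",
    "gen_model_truth_experiment",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise structure of a synthetic flow experiment.

    ``uninduced_law`` / ``induced_law`` are (log-mean, log-sd) of the
    lognormal event distributions.  ``day_batch_sd`` jitters the log-mean
    per experiment day (shared by that day's replicates, so day-matched
    pooling absorbs it); ``rep_sd`` adds smaller replicate-level log-mean
    jitter, which sets the scale of wild-type replicate-to-pool divergence.
    """

    n_days: int = 2
    reps_per_day: int | None = None  # None: drawn from {3, 4} per day
    n_events: int = 50_000
    uninduced_law: tuple = (4.0, 0.3)
    induced_law: tuple = (6.0, 0.3)
    day_batch_sd: float = 0.05
    rep_sd: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.reps_per_day is not None and self.reps_per_day < 1:
            raise ValueError("reps_per_day must be >= 1")
        if self.n_events < 100:
            raise ValueError("n_events must be >= 100")
        for name in ("uninduced_law", "induced_law"):
            mu, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name} log-sd must be positive")
        if self.day_batch_sd < 0 or self.rep_sd < 0:
            raise ValueError("batch/replicate sds must be non-negative")


@dataclass(frozen=True)
class MutantEffect:
    """Perturbation applied to the induced distribution of a mutant.

    ``graded``: the induced log-mean loses ``magnitude`` times the
    wild-type induced/uninduced log-mean gap.  ``bimodal``: a fraction
    ``magnitude`` of cells are non-responders drawn from the uninduced law,
    the rest respond with the log-mean gap shrunk by
    ``weak_mode_attenuation``.
    """

    kind: str = "graded"
    magnitude: float = 0.5
    weak_mode_attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("graded", "bimodal"):
            raise ValueError(f"effect kind must be graded|bimodal, got {self.kind!r}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError(f"magnitude must lie in [0, 1], got {self.magnitude}")
        if not 0.0 <= self.weak_mode_attenuation <= 1.0:
            raise ValueError("weak_mode_attenuation must lie in [0, 1]")


def _day_layout(spec: SyntheticSpec, rng: np.random.Generator) -> list:
    if spec.reps_per_day is not None:
        return [spec.reps_per_day] * spec.n_days
    return [int(rng.integers(3, 5)) for _ in range(spec.n_days)]


def _experiment(spec: SyntheticSpec, strain: str, induced_mu_fn, strain_seed: int = 0) -> list:
    """Common generator: one uninduced + one induced sample per replicate.

    ``induced_mu_fn(rng, day_shift, rep_shift)`` returns the induced event
    vector for one replicate, so graded and bimodal variants share the
    replicate/day noise structure.  Day batch shifts depend only on
    ``spec.seed`` and the day index: strains generated with the same spec
    seed but different ``strain_seed`` emulate strains measured side by
    side in the same experiment (shared day effects, independent cells).
    """
    root = np.random.SeedSequence(spec.seed)
    rng_layout = np.random.default_rng(root.spawn(1)[0])
    layout = _day_layout(spec, rng_layout)
    mu_u, sd_u = spec.uninduced_law
    samples = []
    for d, n_reps in enumerate(layout):
        day = f"day{d + 1}"
        day_ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, d))
        rng_day = np.random.default_rng(day_ss)
        day_shift = rng_day.normal(0.0, spec.day_batch_sd)
        for r in range(n_reps):
            rep_ss = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(2, d, r, strain_seed)
            )
            rng = np.random.default_rng(rep_ss)
            rep_shift = rng.normal(0.0, spec.rep_sd)
            unind = rng.lognormal(mu_u + day_shift + rep_shift, sd_u, spec.n_events)
            ind = induced_mu_fn(rng, day_shift, rep_shift)
            rep = f"r{r + 1}"
            samples.append(
                FlowSample(strain, rep, day, "uninduced", unind)
            )
            samples.append(FlowSample(strain, rep, day, "induced", ind))
    return samples


def gen_wt_experiment(spec: SyntheticSpec) -> list:
    """Generate a wild-type experiment (uninduced + induced per replicate)."""
    mu_i, sd_i = spec.induced_law

    def induced(rng, day_shift, rep_shift):
        return rng.lognormal(mu_i + day_shift + rep_shift, sd_i, spec.n_events)

    return _experiment(spec, "WT", induced)


def gen_effect_mutant(
    spec: SyntheticSpec,
    effect: MutantEffect,
    strain: str = "mutant",
    strain_seed: int = 0,
) -> list:
    """Generate a mutant experiment with a graded or bimodal induced effect.

    Uninduced samples are identical in law to wild-type uninduced; a
    graded mutant with magnitude 0 reproduces the wild-type experiment
    exactly at the same seed (and default ``strain_seed``).  Passing a
    nonzero ``strain_seed`` keeps the experiment-level day batch shifts of
    the wild-type run with the same spec seed while drawing independent
    cells — strains measured within the same experiment.
    """
    mu_u, sd_u = spec.uninduced_law
    mu_i, sd_i = spec.induced_law
    gap = mu_i - mu_u

    def induced(rng, day_shift, rep_shift):
        if effect.kind == "graded":
            mu = mu_u + (1.0 - effect.magnitude) * gap + day_shift + rep_shift
            return rng.lognormal(mu, sd_i, spec.n_events)
        # bimodal: non-responders share the uninduced law exactly
        n_off = rng.binomial(spec.n_events, effect.magnitude)
        off = rng.lognormal(mu_u + day_shift + rep_shift, sd_u, n_off)
        mu_weak = (
            mu_u
            + (1.0 - effect.weak_mode_attenuation) * gap
            + day_shift
            + rep_shift
        )
        on = rng.lognormal(mu_weak, sd_i, spec.n_events - n_off)
        vals = np.concatenate((off, on))
        rng.shuffle(vals)
        return vals

    return _experiment(spec, strain, induced, strain_seed)


def gen_model_truth_mutant(
    params: HogModelParams,
    which: str,
    fraction: float,
    n_cells: int = 10_000,
    calibration: tuple = (3.0, 100.0),
    seed: int = 0,
    *,
    strain: str | None = None,
    replicate: str = "r1",
    day: str = "day1",
    basal_mu: float = 2.5,
    basal_sigma: float = 0.6,
) -> FlowSample:
    """Simulate an induced replicate from the model with a known true
    perturbation fraction (ground truth for parameter-recovery tests).

    ``which`` selects the perturbed group ("activity" scales the
    stress-activation coefficient, "remodeling" the remodeler on-rate);
    the chosen scale is set to ``fraction`` and the stochastic model is
    simulated, basal expression added, and a fixed affine map
    ``calibration = (a, b)`` applied to move counts onto an arbitrary
    fluorescence scale.  The true generating fraction is recorded in the
    strain name unless ``strain`` is given.
    """
    if which not in ("activity", "remodeling"):
        raise ValueError(f"which must be activity|remodeling, got {which!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if which == "activity":
        p = params.with_scales(activity=fraction)
    else:
        p = params.with_scales(remodeling=fraction)
    sim = simulate_population(p, n_cells=n_cells, seed=seed)
    fluor = add_basal(
        sim.protein_counts, basal_mu, basal_sigma, seed=seed + 1_000_003
    )
    a, b = calibration
    name = strain if strain is not None else f"truth_{which}_{fraction:.2f}"
    return FlowSample(name, replicate, day, "induced", a * fluor + b)


def gen_model_truth_experiment(
    params: HogModelParams,
    which: str,
    fraction: float,
    n_replicates: int = 4,
    n_cells: int = 10_000,
    calibration: tuple = (3.0, 100.0),
    seed: int = 0,
    **kw,
) -> dict:
    """Truth mutant plus the context the fitting pipeline needs.

    Returns a dict with ``induced`` (list of replicates with the true
    generating fraction), ``uninduced`` (matching unstressed controls) and
    ``wt_reference`` (an unperturbed induced wild-type model replicate used
    for maximum alignment during calibration).  All on the same arbitrary
    fluorescence scale defined by ``calibration``.
    """
    induced = [
        gen_model_truth_mutant(
            params,
            which,
            fraction,
            n_cells,
            calibration,
            seed=seed + 17 * r,
            replicate=f"r{r + 1}",
            **kw,
        )
        for r in range(n_replicates)
    ]
    a, b = calibration
    uninduced = []
    for r in range(n_replicates):
        sim = simulate_population(
            params.uninduced(), n_cells=n_cells, seed=seed + 17 * r + 7
        )
        fluor = add_basal(sim.protein_counts, seed=seed + 17 * r + 11)
        uninduced.append(
            FlowSample(
                induced[0].strain,
                f"r{r + 1}",
                induced[0].experiment_day,
                "uninduced",
                a * fluor + b,
            )
        )
    wt_sim = simulate_population(params, n_cells=n_cells, seed=seed + 991)
    wt_fluor = add_basal(wt_sim.protein_counts, seed=seed + 997)
    wt_reference = FlowSample(
        "WT", "ref", induced[0].experiment_day, "induced", a * wt_fluor + b
    )
    return {"induced": induced, "uninduced": uninduced, "wt_reference": wt_reference}
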