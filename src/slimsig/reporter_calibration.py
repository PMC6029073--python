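"""Convert simulated reporter molecule counts to fluorescence scale.

Simulations produce protein counts in molecules; flow cytometry measures
arbitrary fluorescence units.  Three steps bridge the two:

1. ``add_basal`` — every cell receives a small lognormally distributed
   basal-expression constant (defaults mu = 2.5, sigma = 0.6 on the log
   scale), so unstimulated simulated cells have a realistic positive
   fluorescence floor instead of exact zeros.
2. ``fit_calibration`` — a linear transform v = a*x + b is solved from two
   constraints: the maximum of the induced simulation maps onto the maximum
   of a designated wild-type reference replicate (which is then excluded
   from divergence comparisons), and the mean of the unstimulated
   simulation maps onto the mean of the unstimulated experimental control
   for the replicate under comparison.
3. ``calibrate_simulation`` — applies the transform and appends the
   experimental replicate's minimum and maximum intensities as support
   anchors ("linear extension"), so the empirical CDF of the calibrated
   sample covers the full experimental range and divergence estimates stay
   finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationParams",
    "add_basal",
    "fit_calibration",
    "calibrate_simulation",
]


@dataclass(frozen=True)
class CalibrationParams:
    """Fitted linear transform and its provenance.

    ``basal_mu`` / ``basal_sigma`` parameterize the lognormal basal
    constant as the mean/sd of the underlying normal of the logarithm.
    ``reference_replicate`` names the wild-type replicate whose maximum was
    used for alignment; it must be excluded from subsequent KL comparisons.
    """

    a: float
    b: float
    basal_mu: float = 2.5
    basal_sigma: float = 0.6
    reference_replicate: str | None = None
    ext_min: float | None = None
    ext_max: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.a}")
        if self.basal_sigma <= 0:
            raise ValueError("basal_sigma must be positive")


def add_basal(
    protein_counts,
    basal_mu: float = 2.5,
    basal_sigma: float = 0.6,
    seed: int = 0,
) -> np.ndarray:
    """Add an independent lognormal basal-expression constant per cell.

    Returns ``count_i + L_i`` with ``log L_i ~ Normal(basal_mu,
    basal_sigma^2)``; outputs are strictly positive.
    """
    counts = np.asarray(protein_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty protein_counts")
    if np.any(counts < 0):
        raise ValueError("protein counts must be non-negative")
    if basal_sigma <= 0:
        raise ValueError("basal_sigma must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return counts + rng.lognormal(mean=basal_mu, sigma=basal_sigma, size=counts.size)


def fit_calibration(
    sim_induced,
    sim_uninduced,
    wt_reference_induced,
    experimental_uninduced_control,
    *,
    basal_mu: float = 2.5,
    basal_sigma: float = 0.6,
    reference_replicate: str | None = None,
    max_quantile: float = 1.0,
) -> CalibrationParams:
    """Solve the two-constraint linear transform a*x + b.

    Constraints: ``a * max(sim_induced) + b = max(wt_reference_induced)``
    and ``a * mean(sim_uninduced) + b = mean(experimental_uninduced_control)``.
    ``max_quantile`` < 1 substitutes a robust upper quantile for the strict
    maximum (a strict sample maximum is outlier-sensitive); the default
    keeps the strict maximum.
    """
    si = np.asarray(sim_induced, dtype=float)
    su = np.asarray(sim_uninduced, dtype=float)
    wr = np.asarray(wt_reference_induced, dtype=float)
    ec = np.asarray(experimental_uninduced_control, dtype=float)
    for name, arr in (
        ("sim_induced", si),
        ("sim_uninduced", su),
        ("wt_reference_induced", wr),
        ("experimental_uninduced_control", ec),
    ):
        if arr.size == 0:
            raise ValueError(f"{name} is empty")
    if not 0.0 < max_quantile <= 1.0:
        raise ValueError("max_quantile must lie in (0, 1]")

    sim_hi = float(np.max(si)) if max_quantile == 1.0 else float(np.quantile(si, max_quantile))
    ref_hi = float(np.max(wr)) if max_quantile == 1.0 else float(np.quantile(wr, max_quantile))
    sim_lo = float(np.mean(su))
    ctrl_lo = float(np.mean(ec))

    denom = sim_hi - sim_lo
    if denom == 0.0:
        raise ValueError(
            "degenerate calibration constraints: max(sim_induced) equals "
            "mean(sim_uninduced)"
        )
    a = (ref_hi - ctrl_lo) / denom
    if a <= 0:
        raise ValueError(f"calibration produced non-positive slope a={a:.4g}")
    b = ctrl_lo - a * sim_lo
    return CalibrationParams(
        a=a,
        b=b,
        basal_mu=basal_mu,
        basal_sigma=basal_sigma,
        reference_replicate=reference_replicate,
        ext_min=None,
        ext_max=None,
    )


def calibrate_simulation(
    sim_values, calib: CalibrationParams, experimental_replicate
) -> np.ndarray:
    """Apply the fitted transform and extend support to the experimental range.

    Returns ``a * sim + b`` with the experimental replicate's minimum and
    maximum appended as two extra support anchors, so the calibrated
    sample's range covers the experimental replicate's range.
    """
    sim = np.asarray(sim_values, dtype=float)
    exp = np.asarray(experimental_replicate, dtype=float)
    if sim.size == 0 or exp.size == 0:
        raise ValueError("empty input to calibrate_simulation")
    mapped = calib.a * sim + calib.b
    return np.concatenate((mapped, [float(np.min(exp)), float(np.max(exp))]))
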