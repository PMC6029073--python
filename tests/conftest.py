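import numpy as np
import pytest

from slimsig import HogModelParams, SyntheticSpec


@pytest.fixture(scope="session")
def default_params() -> HogModelParams:
    return HogModelParams()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced-size synthetic experiment for fast unit tests."""
    return SyntheticSpec(n_days=2, reps_per_day=3, n_events=2000, seed=11)


def kde_mode_count(values, bw_method=0.2, rel_prominence=1.2, n_grid=512):
    """Count well-separated modes of a sample via a Gaussian KDE.

    A mode is a local maximum of the density whose peak exceeds
    ``rel_prominence`` times the deepest valley separating it from a higher
    mode.  Used as an independent multimodality oracle.
    """
    from scipy.stats import gaussian_kde

    vals = np.asarray(values, dtype=float)
    kde = gaussian_kde(vals, bw_method=bw_method)
    grid = np.linspace(vals.min(), vals.max(), n_grid)
    d = kde(grid)
    peaks = [
        i
        for i in range(1, n_grid - 1)
        if d[i] >= d[i - 1] and d[i] > d[i + 1]
    ]
    if not peaks:
        return 1
    # merge peaks not separated by a sufficiently deep valley
    peaks.sort(key=lambda i: -d[i])
    kept = []
    for i in peaks:
        separated = True
        for j in kept:
            lo, hi = sorted((i, j))
            valley = d[lo : hi + 1].min()
            if min(d[i], d[j]) < rel_prominence * valley:
                separated = False
                break
        if separated:
            kept.append(i)
    return len(kept)
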