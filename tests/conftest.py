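import numpy as np
import pytest

from lovedyn import CTParams, ObservationSeries, is_stationary


def random_stationary_params(rng, meas_lo=0.5, meas_hi=5.0) -> CTParams:
    """Random stationary CTParams spanning slow and fast regimes."""
    while True:
        a = rng.normal(scale=1.0, size=(2, 2))
        a[0, 0] = -abs(a[0, 0]) - 0.05
        a[1, 1] = -abs(a[1, 1]) - 0.05
        if is_stationary(a):
            break
    low = np.tril(rng.normal(size=(2, 2)))
    low[0, 0] = abs(low[0, 0]) + 0.2
    low[1, 1] = abs(low[1, 1]) + 0.2
    return CTParams(
        drift=a,
        diffusion=low,
        manifest_intercept=rng.normal(50.0, 10.0, 2),
        meas_sd=rng.uniform(meas_lo, meas_hi, 2),
    )


def random_series(rng, params, t_max=15, missing_prob=0.0) -> ObservationSeries:
    """Random irregular series (values synthetic, not model-generated)."""
    t = rng.integers(1, t_max)
    times = np.cumsum(rng.uniform(0.1, 8.0, t))
    times -= times[0]
    values = np.clip(rng.normal(60.0, 10.0, (t, 2)), 0.0, 100.0)
    if missing_prob > 0:
        mask = rng.random((t, 2)) < missing_prob
        # keep at least one observed value overall
        if mask.all():
            mask[0, 0] = False
        values = np.where(mask, np.nan, values)
    return ObservationSeries(person_id="x", times=times, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
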