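import math

import numpy as np
import pytest

import bmgrowth as bg


def make_noiseless_series(
    beta: float,
    rng: np.random.Generator,
    times=(0.0, 3.04, 5.46),
    v0: float | None = None,
    ratio: float | None = None,
    lesion_id: str = "lesion",
) -> tuple[bg.VBParameters, bg.LesionSeries]:
    """Exact three-point series on a Von Bertalanffy trajectory.

    The rate coefficient is derived from a total growth ratio V2/V0 (drawn
    log-uniformly from [1.2, 10] unless given), which keeps every exponent
    short of blow-up over the sampled interval.
    """
    if v0 is None:
        v0 = float(math.exp(rng.normal(math.log(0.5), 0.8)))
    if ratio is None:
        ratio = float(math.exp(rng.uniform(math.log(1.2), math.log(10.0))))
    t2 = times[2] - times[0]
    u = 1.0 - beta
    if abs(u) < bg.BETA_ONE_BAND:
        alpha = math.log(ratio) / t2
    else:
        alpha = v0**u * math.expm1(u * math.log(ratio)) / (u * t2)
    params = bg.VBParameters(v0=v0, alpha=alpha, beta=beta, t0=times[0])
    volumes = bg.vb_trajectory(params, times)
    series = bg.LesionSeries(
        lesion_id=lesion_id,
        patient_id="patient",
        times=tuple(times),
        volumes=tuple(float(v) for v in volumes),
    )
    return params, series


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration synthetic cohort (60 PD + 41 RN), seed 0."""
    return bg.generate_cohort(bg.CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def default_cohort_fits(default_cohort):
    return [
        (lesion.series, bg.fit_vb_exponent(lesion.series))
        for lesion in default_cohort
    ]
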