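"""Synthetic labelled cohorts with the structure the analysis assumes.

The study's clinical dataset (101 brain metastases growing over three
consecutive MRI follow-ups after focal radiotherapy: 60 progressive-disease
and 41 radiation-necrosis events) is not publicly deposited, so this module
generates cohorts with the same observable structure: per lesion, three
strictly increasing volumes on an exact Von Bertalanffy trajectory whose
growth exponent is drawn from a group-specific normal (PD centred on 0.52,
RN on 2.10), scan intervals jittered around 3.04 and 2.42 months, baseline
volume lognormal (median 0.5 cm^3), and multiplicative Uniform(+-5%)
measurement noise.  The rate coefficient alpha is derived from a drawn total
growth ratio V2/V0 rather than sampled directly, which guarantees a
realistic, non-exploding three-point series for every exponent.

The ground truth (parameters and noiseless rates) is recorded alongside each
lesion, so estimator behaviour can be checked exactly.  Sampling is
deterministic for a fixed seed, with per-lesion substreams derived from
(seed, lesion index) so that cohorts are stable under size changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import GrowthRates, LesionSeries, growth_rate
from .growth import BETA_ONE_BAND, VBParameters, blowup_time, vb_trajectory

__all__ = [
    "CohortConfig",
    "SyntheticLesion",
    "sample_group_beta",
    "generate_trajectory",
    "generate_cohort",
]

_REJECTION_CAP = 1000


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings.

    Group sizes, exponent means, inter-scan intervals and the noise bound
    follow the printed cohort summaries; the exponent spreads, baseline
    volume distribution and growth-ratio range are calibration choices the
    printed summaries do not constrain (see the methods note).
    """

    n_pd: int = 60
    n_rn: int = 41
    beta_pd_mean: float = 0.52
    beta_rn_mean: float = 2.10
    beta_sd_pd: float = 0.9
    beta_sd_rn: float = 1.3
    v0_log_mean: float = math.log(0.5)  # lognormal median 0.5 cm^3
    v0_log_sd: float = 0.85
    interval1_mean: float = 3.04  # months, first scan pair
    interval2_mean: float = 2.42  # months, second scan pair
    interval_jitter_sd: float = 0.5  # months, truncated at half the mean
    target_ratio_range: tuple = (1.2, 10.0)  # admissible noiseless V2/V0
    noise_bound: float = 0.05
    p_srs: float = 62 / 101
    p_fsrt: float = 39 / 101
    p_wbrt: float = 20 / 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_rn < 0:
            raise ValueError("group sizes must be non-negative")
        if self.interval1_mean <= 0 or self.interval2_mean <= 0:
            raise ValueError("scan intervals must be positive")
        if not 0.0 <= self.noise_bound < 1.0:
            raise ValueError("noise_bound must lie in [0, 1)")
        lo, hi = self.target_ratio_range
        if not 1.0 < lo < hi:
            raise ValueError("target_ratio_range must satisfy 1 < low < high")
        if not math.isclose(self.p_srs + self.p_fsrt, 1.0, abs_tol=1e-9):
            raise ValueError("SRS and FSRT probabilities must sum to 1")
        if not 0.0 <= self.p_wbrt <= 1.0:
            raise ValueError("p_wbrt must be a probability")


@dataclass(frozen=True)
class SyntheticLesion:
    """Observed series plus the generating ground truth."""

    series: LesionSeries
    true_params: VBParameters
    true_lambda: GrowthRates  # computed on the noiseless volumes


def sample_group_beta(group: str, config: CohortConfig, rng: np.random.Generator) -> float:
    """Draw a growth exponent from the group's normal distribution."""
    if group == "PD":
        return float(rng.normal(config.beta_pd_mean, config.beta_sd_pd))
    if group == "RN":
        return float(rng.normal(config.beta_rn_mean, config.beta_sd_rn))
    raise ValueError(f"group must be 'PD' or 'RN', got {group!r}")


def _sample_interval(mean: float, sd: float, rng: np.random.Generator) -> float:
    # Jitter truncated (by redraw) at half the mean, keeping intervals
    # positive and centred on the configured mean.
    while True:
        jitter = rng.normal(0.0, sd)
        if abs(jitter) <= 0.5 * mean:
            return mean + jitter


def _alpha_for_ratio(v0: float, beta: float, ratio: float, t2: float) -> float:
    """alpha making the noiseless trajectory reach V2 = ratio * V0 at t2."""
    if abs(beta - 1.0) < BETA_ONE_BAND:
        return math.log(ratio) / t2
    u = 1.0 - beta
    return v0**u * math.expm1(u * math.log(ratio)) / (u * t2)


def generate_trajectory(
    beta: float,
    config: CohortConfig,
    rng: np.random.Generator,
    lesion_id: str = "lesion",
    patient_id: str = "patient",
    label: str = "unknown",
    subgroup: str | None = None,
    upfront_wbrt: bool | None = None,
) -> SyntheticLesion:
    """One synthetic lesion with exponent ``beta``.

    Samples baseline volume, jittered scan times (0, d1, d1+d2) and a total
    growth ratio; derives alpha from the ratio; applies multiplicative
    measurement noise; redraws everything until the observed volumes are
    strictly increasing (cap 1000 attempts).
    """
    for _ in range(_REJECTION_CAP):
        v0 = float(math.exp(rng.normal(config.v0_log_mean, config.v0_log_sd)))
        d1 = _sample_interval(config.interval1_mean, config.interval_jitter_sd, rng)
        d2 = _sample_interval(config.interval2_mean, config.interval_jitter_sd, rng)
        times = (0.0, d1, d1 + d2)
        lo, hi = config.target_ratio_range
        ratio = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        alpha = _alpha_for_ratio(v0, beta, ratio, times[2])
        params = VBParameters(v0=v0, alpha=alpha, beta=beta, t0=0.0)
        if blowup_time(params) <= times[2]:
            continue  # cannot happen with ratio-derived alpha, but be safe
        noiseless = vb_trajectory(params, times)
        noise = 1.0 + rng.uniform(-config.noise_bound, config.noise_bound, size=3)
        observed = noiseless * noise
        if not (observed[0] < observed[1] < observed[2]):
            continue
        series = LesionSeries(
            lesion_id=lesion_id,
            patient_id=patient_id,
            times=times,
            volumes=tuple(float(v) for v in observed),
            label=label,
            subgroup=subgroup,
            upfront_wbrt=upfront_wbrt,
        )
        true_lambda = GrowthRates(
            lambda1=growth_rate(noiseless[0], noiseless[1], times[0], times[1]),
            lambda2=growth_rate(noiseless[1], noiseless[2], times[1], times[2]),
        )
        return SyntheticLesion(series=series, true_params=params, true_lambda=true_lambda)
    raise RuntimeError(
        f"could not generate an increasing series for beta={beta:.3g} after "
        f"{_REJECTION_CAP} attempts; widen target_ratio_range or lower noise_bound"
    )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> list:
    """Full labelled cohort: n_pd PD lesions followed by n_rn RN lesions.

    Each lesion draws from its own substream derived from (seed, index), so
    the same seed reproduces the cohort bit for bit and enlarging the cohort
    leaves existing lesions unchanged.
    """
    config = config if config is not None else CohortConfig()
    base_seed = config.seed if seed is None else seed
    lesions: list[SyntheticLesion] = []
    for i in range(config.n_pd + config.n_rn):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(i,))
        )
        group = "PD" if i < config.n_pd else "RN"
        beta = sample_group_beta(group, config, rng)
        subgroup = "SRS" if rng.random() < config.p_srs else "FSRT"
        upfront_wbrt = bool(rng.random() < config.p_wbrt)
        lesions.append(
            generate_trajectory(
                beta,
                config,
                rng,
                lesion_id=f"L{i:04d}",
                patient_id=f"P{i:04d}",
                label=group,
                subgroup=subgroup,
                upfront_wbrt=upfront_wbrt,
            )
        )
    return lesions
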