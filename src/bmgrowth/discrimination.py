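"""Cohort-level statistics: group comparison and ROC classification.

The growth exponent beta is used as a score to separate radiation necrosis
(RN, the positive class — inflammatory lesions show transiently accelerated,
super-exponential dynamics and hence large exponents) from progressive
disease (PD).  The module provides:

* ``rank_auc`` — empirical ROC over all distinct score thresholds with
  trapezoidal AUC (equal, with ties counting one half, to the normalised
  Mann–Whitney U statistic);
* ``kruskal_wallis`` — nonparametric group comparison (tie-corrected H,
  chi-squared p-value);
* ``optimal_operating_point`` — Youden's J maximiser on an ROC;
* ``normality_check`` — one-sample Kolmogorov–Smirnov p-value against a
  normal with the sample's mean/SD, used to justify the nonparametric path;
* ``run_discrimination`` — the full per-stratum analysis producing a
  :class:`CohortResult`, with strata mirroring the treatment subgroups
  (upfront WBRT, single-session SRS, fractionated SRT) and an optional
  restriction to robust lesions.

Raw p-values are always reported; ``p_adjusted`` carries a Bonferroni
correction across however many strata were analysed in the same run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .fitting import FitResult, GrowthRates, LesionSeries, growth_rates
from .robustness import RobustnessResult

__all__ = [
    "CohortResult",
    "StratumError",
    "rank_auc",
    "kruskal_wallis",
    "optimal_operating_point",
    "normality_check",
    "run_discrimination",
    "run_discrimination_suite",
    "STRATA",
]

#: Analysis strata: the whole cohort plus the three treatment subgroups.
STRATA = ("all", "WBRT", "SRS", "FSRT")


class StratumError(ValueError):
    """Stratum is empty or single-class after filtering."""


def rank_auc(
    scores_positive: Sequence[float], scores_negative: Sequence[float]
) -> tuple[float, list]:
    """Empirical ROC and trapezoidal AUC, positives scored high.

    Returns ``(auc, roc)`` with ``roc`` an ordered list of
    ``(threshold, true_positive_rate, false_positive_rate)`` tuples over all
    distinct-score thresholds (leading sentinel threshold +inf included so
    the curve starts at (0, 0)).  Tied scores contribute one half, making
    the trapezoidal AUC identical to Mann–Whitney pair counting.
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    roc = [(float(t), float(tp), float(fp)) for t, tp, fp in zip(thresholds, tpr, fpr)]
    return auc, roc


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    For two groups the verdict coincides with the two-sided Mann–Whitney
    test (asymptotic, no continuity correction).  All-identical data yield
    (0, 1) rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*arrays)
    return float(stat), float(p)


def optimal_operating_point(roc: Sequence[tuple]) -> tuple[float, float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold.  Returns ``(threshold, sensitivity, specificity)``.
    """
    if not roc:
        raise ValueError("empty ROC")
    best_key = None
    best = None
    for threshold, tpr, fpr in roc:
        j = tpr - fpr
        key = (j, tpr, -threshold)
        if best_key is None or key > best_key:
            best_key = key
            best = (float(threshold), float(tpr), float(1.0 - fpr))
    return best


def normality_check(values: Sequence[float]) -> float:
    """One-sample Kolmogorov–Smirnov p against N(sample mean, sample SD).

    Used only to justify the nonparametric analysis path.  Because the
    reference normal is fitted to the same sample, the p-value is
    conservative (biased high) for genuinely normal data.  Zero-variance
    input degenerates to p = 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least five values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn("zero-variance input: normality rejected degenerately")
        return 0.0
    return float(stats.kstest(x, "norm", args=(float(np.mean(x)), sd)).pvalue)


def _summary(values: np.ndarray) -> dict:
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "iqr": (float(q1), float(q3)),
    }


@dataclass(frozen=True)
class CohortResult:
    """Per-stratum discrimination outcome.

    ``lambda_summary`` exposes the mean two-point growth rates per group so
    that the rate-ordering between groups (which can flip between the first
    and second scan pair) is directly inspectable.
    """

    subgroup_tag: str
    n_pd: int
    n_rn: int
    beta_summary_pd: dict
    beta_summary_rn: dict
    kw_statistic: float
    p_value: float
    p_adjusted: float
    roc: list
    auc: float
    operating_point: tuple
    lambda_summary: dict = field(default_factory=dict)
    normality_p_beta: float = math.nan

    def to_dict(self) -> dict:
        return {
            "subgroup_tag": self.subgroup_tag,
            "n_pd": self.n_pd,
            "n_rn": self.n_rn,
            "beta_summary_pd": self.beta_summary_pd,
            "beta_summary_rn": self.beta_summary_rn,
            "kw_statistic": self.kw_statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "auc": self.auc,
            "operating_point": {
                "threshold": self.operating_point[0],
                "sensitivity": self.operating_point[1],
                "specificity": self.operating_point[2],
            },
            "lambda_summary": self.lambda_summary,
            "normality_p_beta": self.normality_p_beta,
            "roc": [
                {"threshold": t, "tpr": tp, "fpr": fp} for t, tp, fp in self.roc
            ],
        }


def _in_stratum(series: LesionSeries, stratum: str) -> bool:
    if stratum == "all":
        return True
    if stratum == "WBRT":
        return series.upfront_wbrt is True
    if stratum in ("SRS", "FSRT"):
        return series.subgroup == stratum
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def run_discrimination(
    fits: Sequence[tuple[LesionSeries, FitResult]],
    stratum: str = "all",
    robust_only: bool = False,
    robustness: Mapping[str, RobustnessResult] | None = None,
    robust_key: str = "mean",
    n_comparisons: int = 1,
) -> CohortResult:
    """RN-vs-PD discrimination by growth exponent within one stratum.

    Parameters
    ----------
    fits:
        Pairs of labelled series and their converged fit results; every
        series must be labelled PD or RN.
    stratum:
        "all", "WBRT" (upfront whole-brain radiotherapy), "SRS"
        (single-session) or "FSRT" (fractionated).
    robust_only:
        Restrict to lesions whose robustness verdict (``robust_key`` "mean"
        or "median") is positive; requires ``robustness`` keyed by lesion id.
    n_comparisons:
        Bonferroni divisor applied to produce ``p_adjusted``.
    """
    if robust_key not in ("mean", "median"):
        raise ValueError("robust_key must be 'mean' or 'median'")
    if robust_only and robustness is None:
        raise ValueError("robust_only requires robustness results")
    selected: list[tuple[LesionSeries, FitResult]] = []
    for series, fit in fits:
        if series.label not in ("PD", "RN"):
            raise ValueError(
                f"lesion {series.lesion_id}: discrimination requires a PD/RN label"
            )
        if not fit.converged:
            continue
        if not _in_stratum(series, stratum):
            continue
        if robust_only:
            rob = robustness.get(series.lesion_id)
            if rob is None:
                continue
            verdict = rob.robust_by_mean if robust_key == "mean" else rob.robust_by_median
            if not verdict:
                continue
        selected.append((series, fit))
    beta_pd = np.array(
        [f.params.beta for s, f in selected if s.label == "PD"], dtype=float
    )
    beta_rn = np.array(
        [f.params.beta for s, f in selected if s.label == "RN"], dtype=float
    )
    if beta_pd.size == 0 or beta_rn.size == 0:
        raise StratumError(
            f"stratum {stratum!r} is empty or single-class after filtering "
            f"(PD={beta_pd.size}, RN={beta_rn.size})"
        )
    kw_stat, p = kruskal_wallis([beta_pd, beta_rn])
    auc, roc = rank_auc(beta_rn, beta_pd)
    operating = optimal_operating_point(roc)

    lam = {"PD": ([], []), "RN": ([], [])}
    for series, _fit in selected:
        rates = growth_rates(series)
        lam[series.label][0].append(rates.lambda1)
        lam[series.label][1].append(rates.lambda2)
    lambda_summary = {
        grp: {
            "lambda1_mean": float(np.mean(l1)),
            "lambda2_mean": float(np.mean(l2)),
        }
        for grp, (l1, l2) in lam.items()
    }
    pooled = np.concatenate([beta_pd, beta_rn])
    norm_p = normality_check(pooled) if pooled.size >= 5 else math.nan
    return CohortResult(
        subgroup_tag=stratum,
        n_pd=int(beta_pd.size),
        n_rn=int(beta_rn.size),
        beta_summary_pd=_summary(beta_pd),
        beta_summary_rn=_summary(beta_rn),
        kw_statistic=kw_stat,
        p_value=p,
        p_adjusted=float(min(1.0, p * n_comparisons)),
        roc=roc,
        auc=auc,
        operating_point=operating,
        lambda_summary=lambda_summary,
        normality_p_beta=norm_p,
    )


def run_discrimination_suite(
    fits: Sequence[tuple[LesionSeries, FitResult]],
    strata: Sequence[str] = STRATA,
    robust_only: bool = False,
    robustness: Mapping[str, RobustnessResult] | None = None,
    robust_key: str = "mean",
) -> dict:
    """Run several strata in one invocation with Bonferroni adjustment.

    Returns ``{stratum: CohortResult | StratumError}``; the Bonferroni
    divisor is the number of strata attempted.
    """
    n = len(strata)
    out: dict = {}
    for stratum in strata:
        try:
            out[stratum] = run_discrimination(
                fits,
                stratum=stratum,
                robust_only=robust_only,
                robustness=robustness,
                robust_key=robust_key,
                n_comparisons=n,
            )
        except StratumError as exc:
            out[stratum] = exc
    return out
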