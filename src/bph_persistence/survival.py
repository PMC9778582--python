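"""Drug-survival statistics: product-limit estimation and the log-rank test.

The Kaplan–Meier estimator, its Greenwood variance, pointwise confidence
intervals (complementary log-log by default), median survival with
confidence bounds by inversion of the pointwise interval, and the k-group
log-rank test are implemented here from first principles; independent
reference implementations serve as cross-checks in the test suite only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm


def _as_arrays(observations, events=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept SurvivalObservation sequences, (time, event) pairs, or two arrays."""
    if events is not None:
        t = np.asarray(observations, dtype=float)
        e = np.asarray(events, dtype=int)
    else:
        obs = list(observations)
        if obs and hasattr(obs[0], "time_days"):
            t = np.array([o.time_days for o in obs], dtype=float)
            e = np.array([o.event for o in obs], dtype=int)
        else:
            t = np.array([p[0] for p in obs], dtype=float)
            e = np.array([p[1] for p in obs], dtype=int)
    if t.size == 0:
        raise ValueError("at least one observation required")
    if (t < 0).any():
        raise ValueError("negative times")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct event times.

    At tied times, events precede censorings (the universal convention):
    subjects censored at t are still at risk for the events at t.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_total: int
    n_events: int
    t_max: float  # largest observed time, event or censoring


@dataclass(frozen=True)
class MedianEstimate:
    """Median survival with confidence bounds; None where never reached."""

    median_days: float | None
    ci_lower: float | None
    ci_upper: float | None


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]


def km_estimate(
    observations, events=None, *, ci_method: str = "loglog", alpha: float = 0.05
) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Pointwise 1-alpha confidence intervals use the complementary log-log
    transform by default (bounds stay inside [0, 1]); ``ci_method="linear"``
    gives plain Greenwood intervals clipped to [0, 1].
    """
    t, e = _as_arrays(observations, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    uniq = np.unique(t[e == 1])
    at_risk = np.empty(uniq.size)
    deaths = np.empty(uniq.size)
    for i, ti in enumerate(uniq):
        at_risk[i] = np.sum(t >= ti)
        deaths[i] = np.sum((t == ti) & (e == 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - deaths / at_risk
        surv = np.cumprod(factors)
        # Greenwood: Var S = S^2 * cumsum(d / (n (n - d)))
        gterm = np.where(at_risk > deaths, deaths / (at_risk * (at_risk - deaths)), np.inf)
        gcum = np.cumsum(gterm)
        var = surv**2 * gcum

    z = norm.ppf(1 - alpha / 2.0)
    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    for i, s in enumerate(surv):
        if s <= 0.0 or s >= 1.0 or not np.isfinite(gcum[i]):
            lo[i] = hi[i] = s
        elif ci_method == "loglog":
            se_theta = math.sqrt(gcum[i]) / abs(math.log(s))
            lo[i] = s ** math.exp(z * se_theta)
            hi[i] = s ** math.exp(-z * se_theta)
        elif ci_method == "linear":
            half = z * math.sqrt(var[i])
            lo[i] = max(0.0, s - half)
            hi[i] = min(1.0, s + half)
        else:
            raise ValueError("ci_method must be 'loglog' or 'linear'")

    return KMCurve(
        event_times=uniq,
        at_risk=at_risk,
        deaths=deaths,
        survival=surv,
        greenwood_var=np.where(np.isfinite(var), var, 0.0),
        ci_lower=lo,
        ci_upper=hi,
        n_total=n,
        n_events=int(e.sum()),
        t_max=float(t.max()),
    )


def survival_at(curve: KMCurve, t: float) -> dict:
    """Right-continuous step-function value of S at t, with its CI.

    ``pct`` fields report percentages rounded to one decimal.  ``beyond_data``
    flags evaluation past the largest observed time (the last value is
    carried forward).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = int(np.searchsorted(curve.event_times, t, side="right"))
    if idx == 0:
        s, lo, hi = 1.0, 1.0, 1.0
    else:
        s = float(curve.survival[idx - 1])
        lo = float(curve.ci_lower[idx - 1])
        hi = float(curve.ci_upper[idx - 1])
    return {
        "estimate": s,
        "ci_lower": lo,
        "ci_upper": hi,
        "pct": round(100.0 * s, 1),
        "pct_ci": (round(100.0 * lo, 1), round(100.0 * hi, 1)),
        "beyond_data": t > curve.t_max,
    }


def km_median(curve: KMCurve) -> MedianEstimate:
    """Smallest t with S(t) <= 0.5; CI bounds by inversion of the pointwise
    confidence band at 0.5 (Brookmeyer–Crowley style).  None = not reached."""
    eps = 1e-12

    def _first_leq(values: np.ndarray) -> float | None:
        hit = np.nonzero(values <= 0.5 + eps)[0]
        return float(curve.event_times[hit[0]]) if hit.size else None

    return MedianEstimate(
        median_days=_first_leq(curve.survival),
        ci_lower=_first_leq(curve.ci_lower),
        ci_upper=_first_leq(curve.ci_upper),
    )


def logrank_test(group_observations: Mapping[str, object]) -> LogRankResult:
    """k-group log-rank test.

    At each distinct pooled event time the expected events in group g are
    d * n_g / n; the chi-square statistic is the quadratic form of the
    observed-minus-expected vector (first k-1 groups) with the hypergeometric
    covariance, referred to a chi-square distribution with k-1 df.
    """
    labels = sorted(group_observations)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    arrays = {}
    for g in labels:
        arrays[g] = _as_arrays(group_observations[g])

    all_t = np.concatenate([arrays[g][0] for g in labels])
    all_e = np.concatenate([arrays[g][1] for g in labels])
    event_times = np.unique(all_t[all_e == 1])

    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in event_times:
        n_g = np.array([np.sum(arrays[g][0] >= ti) for g in labels], dtype=float)
        d_g = np.array(
            [np.sum((arrays[g][0] == ti) & (arrays[g][1] == 1)) for g in labels],
            dtype=float,
        )
        n = n_g.sum()
        d = d_g.sum()
        if n <= 0 or d <= 0:
            continue
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            scale = d * (n - d) / (n - 1.0)
            cov += scale * (np.diag(n_g) / n - np.outer(n_g, n_g) / n**2)

    x = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    try:
        chi2 = float(x @ np.linalg.solve(v, x))
    except np.linalg.LinAlgError:
        chi2 = float(x @ np.linalg.pinv(v) @ x)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(chi2_dist.sf(chi2, df))
    return LogRankResult(
        chi_square=chi2,
        df=df,
        p_value=p,
        observed={g: float(o) for g, o in zip(labels, observed)},
        expected={g: float(ex) for g, ex in zip(labels, expected)},
    )


def format_p(p: float) -> str:
    """Report p to 3 decimals with a floored display below 0.001."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
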