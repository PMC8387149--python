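"""Estimation statistics for two-group comparisons and cross-assay regression.

This module implements the estimation-statistics workflow used for seizure
and locomotion assays: report the effect size (unpaired mean difference with
a bootstrap 95% CI, plus Cohen's d) instead of a null-hypothesis test.  No
p-values are produced anywhere, by design.

The bootstrap resamples each group with replacement at its own size
(default 5000 resamples).  The default confidence interval is
bias-corrected and accelerated (BCa), falling back to the percentile
interval — with a logged downgrade — when the bias correction or the
jackknife acceleration is undefined (degenerate bootstrap distributions,
zero jackknife spread).

Cohen's d uses the pooled-SD denominator

    d = (mean(b) - mean(a)) / s_p,
    s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)

with sample variances.  Cross-assay agreement between per-genotype effect
sizes is summarised by an ordinary least-squares line and R^2 (squared
Pearson correlation), via ``scipy.stats.linregress``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateDesignError, ValidationError

__all__ = [
    "EffectSize",
    "RegressionResult",
    "BootstrapEffectSize",
    "EffectSizeRegression",
    "bootstrap_mean_difference",
    "cohens_d",
    "fit_effect_size_regression",
    "percent_change",
    "cumulative_seizing_fraction",
    "child_seed",
]

log = logging.getLogger(__name__)

DEFAULT_N_BOOT = 5000
MIN_N_BOOT = 1000


@dataclass(frozen=True)
class EffectSize:
    """Bootstrap mean difference (b − a) with 95% CI and Cohen's d."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_difference: float
    ci_low: float
    ci_high: float
    cohens_d: float
    n_boot: int
    seed: int
    ci_method: str


@dataclass(frozen=True)
class RegressionResult:
    """OLS line through per-genotype effect sizes."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    r2_ci_low: Optional[float] = None
    r2_ci_high: Optional[float] = None


def child_seed(root_seed: int, *labels: str) -> np.random.SeedSequence:
    """Deterministic per-comparison seed from a root seed and string labels.

    Adding or reordering other comparisons never perturbs an existing one,
    because each comparison's stream depends only on its own labels.
    """
    digest = zlib.crc32("|".join(labels).encode("utf-8"))
    return np.random.SeedSequence([int(root_seed), digest])


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValidationError(f"group {name!r} needs n >= 2, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"group {name!r} contains non-finite values")
    return arr


def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference, d = (mean(b) − mean(a)) / s_p."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        raise ValidationError("both groups have zero variance: Cohen's d undefined")
    return float((np.mean(b) - np.mean(a)) / np.sqrt(pooled_var))


def _bca_interval(
    boot: np.ndarray, theta: float, jackknife: np.ndarray, alpha: float
) -> Optional[Tuple[float, float]]:
    """BCa interval; None when bias or acceleration is undefined."""
    prop = float(np.mean(boot < theta))
    if prop <= 0.0 or prop >= 1.0:
        return None
    z0 = special.ndtri(prop)
    resid = jackknife.mean() - jackknife
    denom = float(np.sum(resid**2)) ** 1.5
    if denom == 0.0:
        return None
    accel = float(np.sum(resid**3)) / (6.0 * denom)
    z_lo = special.ndtri(alpha / 2.0)
    z_hi = special.ndtri(1.0 - alpha / 2.0)
    a_lo = special.ndtr(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    a_hi = special.ndtr(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    if not (0.0 < a_lo < 1.0 and 0.0 < a_hi < 1.0):
        return None
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return float(lo), float(hi)


def bootstrap_mean_difference(
    a,
    b,
    n_boot: int = DEFAULT_N_BOOT,
    seed: Union[int, np.random.SeedSequence, None] = None,
    ci_method: str = "bca",
    alpha: float = 0.05,
    group_a: str = "a",
    group_b: str = "b",
) -> EffectSize:
    """Unpaired mean difference mean(b) − mean(a) with a bootstrap CI.

    Each group is resampled with replacement at its own size, ``n_boot``
    times; the CI is BCa by default with a logged percentile fallback.
    Deterministic given ``seed``.

    Returns
    -------
    EffectSize
        ``ci_method`` on the result records the method actually used.
    """
    a = _check_sample(a, group_a)
    b = _check_sample(b, group_b)
    if n_boot < MIN_N_BOOT:
        raise ValidationError(f"n_boot must be >= {MIN_N_BOOT}, got {n_boot}")
    if ci_method not in ("bca", "percentile"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)
    na, nb = a.size, b.size
    theta = float(np.mean(b) - np.mean(a))

    idx_a = rng.integers(0, na, size=(n_boot, na))
    idx_b = rng.integers(0, nb, size=(n_boot, nb))
    boot = b[idx_b].mean(axis=1) - a[idx_a].mean(axis=1)

    method_used = ci_method
    interval: Optional[Tuple[float, float]] = None
    if boot.max() == boot.min():
        # degenerate distribution (e.g. both groups constant)
        interval = (float(boot[0]), float(boot[0]))
        if ci_method == "bca":
            method_used = "percentile"
            log.info("bootstrap CI: degenerate distribution, reporting point interval")
    elif ci_method == "bca":
        # leave-one-out over both groups for the acceleration constant
        jack_a = np.mean(b) - (a.sum() - a) / (na - 1)
        jack_b = (b.sum() - b) / (nb - 1) - np.mean(a)
        interval = _bca_interval(boot, theta, np.concatenate([jack_a, jack_b]), alpha)
        if interval is None:
            method_used = "percentile"
            log.info(
                "bootstrap CI for (%s, %s): BCa undefined, falling back to percentile",
                group_a,
                group_b,
            )
    if interval is None:
        interval = tuple(np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0]))

    try:
        d = cohens_d(a, b)
    except ValidationError:
        d = float("nan")
        log.info("Cohen's d undefined for (%s, %s): zero pooled SD", group_a, group_b)
    ci_low, ci_high = float(interval[0]), float(interval[1])
    if not (ci_low <= theta <= ci_high):
        log.warning(
            "CI [%g, %g] does not bracket the point estimate %g (BCa edge case)",
            ci_low,
            ci_high,
            theta,
        )
    return EffectSize(
        group_a=group_a,
        group_b=group_b,
        n_a=na,
        n_b=nb,
        mean_difference=theta,
        ci_low=ci_low,
        ci_high=ci_high,
        cohens_d=d,
        n_boot=n_boot,
        seed=int(seed_seq.entropy if np.isscalar(seed_seq.entropy) else seed_seq.entropy[0]),
        ci_method=method_used,
    )


class BootstrapEffectSize(BaseEstimator):
    """Estimator form of :func:`bootstrap_mean_difference`.

    ``fit(a, b)`` computes the effect of group ``b`` relative to group
    ``a`` and exposes ``mean_difference_``, ``ci_low_``, ``ci_high_``,
    ``cohens_d_`` and ``effect_`` (the full :class:`EffectSize`).
    """

    def __init__(
        self,
        n_boot: int = DEFAULT_N_BOOT,
        ci_method: str = "bca",
        alpha: float = 0.05,
        random_state: Optional[int] = None,
    ):
        self.n_boot = n_boot
        self.ci_method = ci_method
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, a, b) -> "BootstrapEffectSize":
        eff = bootstrap_mean_difference(
            a,
            b,
            n_boot=self.n_boot,
            seed=self.random_state,
            ci_method=self.ci_method,
            alpha=self.alpha,
        )
        self.effect_ = eff
        self.mean_difference_ = eff.mean_difference
        self.ci_low_ = eff.ci_low
        self.ci_high_ = eff.ci_high
        self.cohens_d_ = eff.cohens_d
        self.ci_method_used_ = eff.ci_method
        return self


def fit_effect_size_regression(
    x,
    y,
    n_boot: Optional[int] = None,
    seed: Union[int, np.random.SeedSequence, None] = None,
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS line through (x, y) effect-size points; R² = squared Pearson r.

    With ``n_boot`` set, a CI for R² is bootstrapped by resampling the
    points (genotypes) with replacement.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    if x.size < 2:
        raise ValidationError(f"regression needs >= 2 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all x equal: regression design is degenerate")
    fit = stats.linregress(x, y)
    r2_lo = r2_hi = None
    if n_boot:
        rng = np.random.default_rng(seed)
        r2s = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, x.size, size=x.size)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                r2s[i] = np.nan
            else:
                r2s[i] = stats.linregress(xb, yb).rvalue ** 2
        valid = r2s[np.isfinite(r2s)]
        if valid.size:
            r2_lo, r2_hi = (
                float(np.quantile(valid, alpha / 2.0)),
                float(np.quantile(valid, 1.0 - alpha / 2.0)),
            )
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
        r2_ci_low=r2_lo,
        r2_ci_high=r2_hi,
    )


class EffectSizeRegression(BaseEstimator):
    """sklearn-style wrapper for the cross-assay effect-size regression."""

    def __init__(
        self,
        n_boot: Optional[int] = None,
        alpha: float = 0.05,
        random_state: Optional[int] = None,
    ):
        self.n_boot = n_boot
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y) -> "EffectSizeRegression":
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        res = fit_effect_size_regression(
            X, y, n_boot=self.n_boot, seed=self.random_state, alpha=self.alpha
        )
        self.result_ = res
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.r_squared_ = res.r_squared
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=float).ravel()
        return self.intercept_ + self.slope_ * X


def percent_change(treated, control) -> float:
    """100 × (mean(treated) − mean(control)) / mean(control)."""
    treated = np.asarray(treated, dtype=float).ravel()
    control = np.asarray(control, dtype=float).ravel()
    if treated.size == 0 or control.size == 0:
        raise ValidationError("percent_change needs non-empty samples")
    mc = float(np.mean(control))
    if mc <= 0:
        raise ValidationError(f"control mean must be > 0, got {mc}")
    return float(100.0 * (np.mean(treated) - mc) / mc)


def cumulative_seizing_fraction(
    onsets: Sequence[Optional[float]],
    checkpoints,
    t_max: Optional[float] = None,
) -> np.ndarray:
    """Cumulative fraction of animals seized by each checkpoint.

    ``onsets`` contains one entry per animal: the seizure onset time in
    seconds, or ``None``/NaN for animals that never seized in the window
    (right-censored).  With ``t_max`` set, onsets beyond it also count as
    censored.  Censored animals stay in the denominator and are never
    counted as seized, so the curve is a non-decreasing fraction of the
    whole cohort.
    """
    checkpoints = np.asarray(checkpoints, dtype=float)
    if checkpoints.size == 0 or np.any(np.diff(checkpoints) <= 0):
        raise ValidationError("checkpoints must be non-empty and strictly increasing")
    vals = np.array(
        [np.nan if o is None else float(o) for o in onsets], dtype=float
    )
    if vals.size == 0:
        raise ValidationError("empty cohort: cumulative fraction undefined")
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ValidationError("onset times must be >= 0")
    if t_max is not None:
        vals = np.where(vals > t_max, np.nan, vals)
    observed = vals[np.isfinite(vals)]
    return (observed[None, :] <= checkpoints[:, None]).sum(axis=1) / vals.size
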