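"""Rolling Poisson-regression trend and anomaly detection for daily counts.

Each analysis day, the trailing window of daily counts (default 30 days) is
modeled as independent Poisson variables whose log-mean is a linear
combination of four factors:

* ``bias`` — the baseline log-rate (always retained);
* ``linear`` — a ramp scaled to [0, 1] over the window, so its coefficient is
  the log fold-change across the whole window (long-term drift);
* ``abrupt`` — an indicator of the most recent ``A`` days (default 5),
  capturing recent step changes;
* ``intermediate`` — an indicator of the ``I`` days (default 10) immediately
  before the abrupt span, absorbing a past step change without inflating the
  baseline.

Backward elimination keeps only factors whose Wald p-value is below ``alpha``
(default 0.05).  The last day's observed count is then checked against the
central ``level`` (default 95%) probability region of its fitted Poisson
distribution; counts outside it are labeled *unexplained*.  Retained abrupt
or linear factors raise an *alert*, reported as a multiplicative percent
change relative to baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .events import DailyCounts

logger = logging.getLogger(__name__)

FACTORS: tuple[str, ...] = ("bias", "linear", "intermediate", "abrupt")


@dataclass(frozen=True)
class DesignSpec:
    """Window geometry and inference levels of the rolling model."""

    window: int = 30
    abrupt: int = 5
    intermediate: int = 10
    alpha: float = 0.05
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.abrupt < 1 or self.intermediate < 0:
            raise ValueError("abrupt >= 1 and intermediate >= 0 required")
        if self.abrupt + self.intermediate >= self.window:
            raise ValueError("abrupt + intermediate must be < window")
        if not (0.0 < self.alpha <= 1.0):
            # alpha = 1 is the degenerate keep-everything boundary
            raise ValueError("alpha must lie in (0, 1]")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")


@dataclass
class GLMFit:
    """A fitted (possibly reduced) Poisson GLM on one window.

    ``mu`` holds the fitted mean for every design row (including rows dropped
    from the likelihood because their count was missing).  ``excluded`` lists
    factors removed as non-estimable (e.g. an indicator whose span contains
    only zero counts, driving its MLE to -inf).
    """

    factor_names: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    mu: np.ndarray
    converged: bool
    deviance: float
    excluded: tuple[str, ...] = ()

    @property
    def retained_factors(self) -> tuple[str, ...]:
        return self.factor_names


def build_design(spec: DesignSpec) -> np.ndarray:
    """Window-length design matrix with columns (bias, linear, intermediate, abrupt).

    Day index d runs 1..W with d = W the most recent day: bias = 1,
    linear = (d-1)/(W-1), abrupt = 1[d > W-A],
    intermediate = 1[W-A-I < d <= W-A].
    """
    w, a, i = spec.window, spec.abrupt, spec.intermediate
    d = np.arange(1, w + 1, dtype=float)
    design = np.column_stack([
        np.ones(w),
        (d - 1) / (w - 1),
        ((w - a - i < d) & (d <= w - a)).astype(float),
        (d > w - a).astype(float),
    ])
    return design


def _is_indicator(col: np.ndarray) -> bool:
    return bool(np.isin(col, (0.0, 1.0)).all())


def fit_poisson_glm(
    counts: Sequence[float] | np.ndarray,
    design: np.ndarray,
    factor_names: Sequence[str] = FACTORS,
) -> GLMFit:
    """Maximum-likelihood log-link Poisson fit via IRLS (statsmodels).

    Missing counts (NaN) are dropped pairwise from the likelihood; the
    corresponding design rows still receive fitted means.  Non-estimable
    factors — indicator columns never active in the window, or active only on
    zero-count days — are excluded up front and reported in ``excluded``.
    """
    y = np.asarray(counts, dtype=float)
    design = np.asarray(design, dtype=float)
    factor_names = tuple(factor_names)
    if y.shape[0] != design.shape[0]:
        raise ValueError("counts length must equal number of design rows")
    if design.shape[1] != len(factor_names):
        raise ValueError("one factor name per design column required")
    if np.nanmin(y) < 0:
        raise ValueError("counts must be non-negative")

    mask = ~np.isnan(y)
    yv, X = y[mask], design[mask]
    if yv.size == 0:
        raise ValueError("no usable (non-missing) counts in window")

    excluded: list[str] = []
    keep: list[int] = []
    for j, name in enumerate(factor_names):
        col = X[:, j]
        if name != "bias" and _is_indicator(col):
            support = col == 1.0
            if not support.any() or yv[support].sum() == 0:
                excluded.append(name)
                logger.info("factor %r non-estimable in window, excluded", name)
                continue
        keep.append(j)
    # guard against residual rank deficiency (drop trailing non-bias columns)
    while len(keep) > 1 and np.linalg.matrix_rank(X[:, keep]) < len(keep):
        j = keep.pop()
        excluded.append(factor_names[j])
        logger.info("factor %r collinear in window, excluded", factor_names[j])

    names = tuple(factor_names[j] for j in keep)

    if yv.sum() == 0:
        # all-zero counts: only the degenerate bias-at--inf model exists
        beta = {"bias": -np.inf} if "bias" in names else {}
        return GLMFit(
            factor_names=tuple(beta), beta=beta,
            se={k: np.inf for k in beta}, p_values={},
            mu=np.zeros(design.shape[0]), converged=True, deviance=0.0,
            excluded=tuple(n for n in factor_names if n not in beta),
        )

    model = sm.GLM(yv, X[:, keep], family=sm.families.Poisson())
    with warnings.catch_warnings():
        # exact-fit windows (e.g. constant counts) trip statsmodels'
        # separation heuristic although the MLE is perfectly identified;
        # genuinely non-identifiable indicators are excluded above
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(maxiter=200, tol=1e-10)
    beta = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    p_values = {n: float(p) for n, p in zip(names, res.pvalues) if n != "bias"}
    mu = np.exp(design[:, keep] @ res.params)
    return GLMFit(
        factor_names=names,
        beta=beta,
        se={k: float(v) for k, v in se.items()},
        p_values=p_values,
        mu=mu,
        converged=bool(getattr(res, "converged", True)),
        deviance=float(res.deviance),
        excluded=tuple(excluded),
    )


def select_factors(
    counts: Sequence[float] | np.ndarray,
    design: np.ndarray,
    spec: DesignSpec,
    factor_names: Sequence[str] = FACTORS,
    method: str = "screen",
) -> GLMFit:
    """Retain only statistically significant trend factors, then refit.

    ``method="screen"`` (default) fits the full model once, drops every
    non-bias factor whose Wald p-value is >= alpha, and refits with the
    retained set; the reported ``p_values`` are the screening ones that made
    the decision.  Under a constant-rate null this retains each factor at
    rate ~alpha, i.e. the selection is calibrated.

    ``method="backward"`` is classical backward elimination (repeatedly drop
    the single worst non-significant factor and refit until all retained
    factors are significant); it is slightly anti-conservative — per-factor
    false retention runs above alpha because factors are retested after
    collinear companions leave.

    The bias term is never removed.
    """
    if method not in ("screen", "backward"):
        raise ValueError("method must be 'screen' or 'backward'")
    design = np.asarray(design, dtype=float)
    names = list(factor_names)
    cols = {n: design[:, j] for j, n in enumerate(names)}

    def fit_for(names_: list[str]) -> GLMFit:
        X = np.column_stack([cols[n] for n in names_])
        return fit_poisson_glm(counts, X, names_)

    while True:
        fit = fit_for(names)
        if fit.excluded:
            names = [n for n in names if n in fit.factor_names]
            continue
        droppable = {n: p for n, p in fit.p_values.items() if p >= spec.alpha}
        if not droppable:
            return fit
        if method == "backward":
            worst = max(droppable, key=lambda n: (droppable[n], n))
            names.remove(worst)
            continue
        # screen: drop all non-significant factors at once and refit
        kept = [n for n in names if n not in droppable]
        final = fit_for(kept)
        # decision p-values come from the screening (full) model
        final.p_values = {n: p for n, p in fit.p_values.items()
                          if n in final.factor_names}
        return final


def backward_select(
    counts: Sequence[float] | np.ndarray,
    design: np.ndarray,
    spec: DesignSpec,
    factor_names: Sequence[str] = FACTORS,
) -> GLMFit:
    """Iterative backward elimination (see :func:`select_factors`)."""
    return select_factors(counts, design, spec, factor_names, method="backward")


def poisson_central_interval(mu: float, level: float = 0.95) -> tuple[int, int]:
    """Equal-tailed integer bounds containing at least ``level`` Poisson mass.

    lo is the smallest k with CDF(k) >= (1-level)/2 and hi the smallest k
    with CDF(k) >= 1-(1-level)/2, so the pmf mass on [lo, hi] is >= level.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    tail = (1.0 - level) / 2.0
    lo = int(stats.poisson.ppf(tail, mu))
    hi = int(stats.poisson.ppf(1.0 - tail, mu))
    return max(lo, 0), hi


def factor_effects(fit: GLMFit) -> dict[str, tuple[float, float]]:
    """Multiplicative effect of each retained factor: (multiplier, % change)."""
    if not fit.converged:
        raise ValueError("factor effects require a converged fit")
    return {
        name: (float(np.exp(b)), float(100.0 * (np.exp(b) - 1.0)))
        for name, b in fit.beta.items()
    }


@dataclass
class RollingResult:
    """Per-analysis-date outcome of the rolling regression."""

    date: date
    skipped: bool = False
    fit: GLMFit | None = None
    interval: tuple[int, int] | None = None
    observed: float | None = None
    unexplained: bool | None = None
    alert: bool | None = None
    abrupt_effect_pct: float | None = None
    linear_effect_pct: float | None = None

    def to_record(self) -> dict:
        rec: dict = {"date": self.date.isoformat(), "skipped": self.skipped}
        if self.skipped or self.fit is None:
            return rec
        rec.update({
            "retained_factors": list(self.fit.retained_factors),
            "coefficients": {k: round(v, 6) for k, v in self.fit.beta.items()},
            "interval": list(self.interval) if self.interval else None,
            "observed": self.observed,
            "unexplained": self.unexplained,
            "alert": self.alert,
            "abrupt_effect_pct": self.abrupt_effect_pct,
            "linear_effect_pct": self.linear_effect_pct,
        })
        return rec


def rolling_analysis(
    counts: DailyCounts | pd.Series,
    spec: DesignSpec = DesignSpec(),
    *,
    holdout_last: bool = False,
    min_usable: int | None = None,
    selection: str = "screen",
) -> list[RollingResult]:
    """Run the windowed model for every date with a full trailing window.

    The last day of each window is included in the fit and its observed count
    is scored against the central ``level`` region of its fitted Poisson mean
    (``holdout_last=True`` instead excludes it from the likelihood and scores
    it out-of-sample).  Windows with fewer than ``min_usable`` non-missing
    days (default: all of them) are reported as skipped, never fabricated.
    Advancing one day re-fits the model, so an absorbed anomaly adjusts
    subsequent predictions instead of re-triggering.
    """
    series = counts.counts if isinstance(counts, DailyCounts) else counts
    series = series.sort_index()
    w = spec.window
    if len(series) < w:
        raise ValueError(f"need at least window={w} days, got {len(series)}")
    if min_usable is None:
        min_usable = w
    design = build_design(spec)
    values = series.to_numpy(dtype=float)
    dates = [ts.date() for ts in series.index]

    results: list[RollingResult] = []
    for i in range(w - 1, len(series)):
        window = values[i - w + 1: i + 1].copy()
        observed = window[-1]
        usable = int(np.sum(~np.isnan(window)))
        if usable < min_usable or np.isnan(observed):
            results.append(RollingResult(date=dates[i], skipped=True))
            continue
        if holdout_last:
            window_fit = window.copy()
            window_fit[-1] = np.nan
        else:
            window_fit = window
        fit = select_factors(window_fit, design, spec, method=selection)
        mu_last = float(fit.mu[-1])
        if mu_last <= 0:
            results.append(RollingResult(date=dates[i], skipped=True))
            continue
        lo, hi = poisson_central_interval(mu_last, spec.level)
        effects = factor_effects(fit)
        alert = ("abrupt" in fit.retained_factors) or ("linear" in fit.retained_factors)
        results.append(RollingResult(
            date=dates[i],
            fit=fit,
            interval=(lo, hi),
            observed=float(observed),
            unexplained=not (lo <= observed <= hi),
            alert=alert,
            abrupt_effect_pct=effects.get("abrupt", (None, None))[1],
            linear_effect_pct=effects.get("linear", (None, None))[1],
        ))
    return results


def series_cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine similarity of two non-negative series, in [0, 1].

    Zero-vector convention: two all-zero series agree maximally (1.0); an
    all-zero series compared with a non-zero one scores 0.0.  This convention
    is needed because the cosine is undefined at zero norm.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 and ny == 0.0:
        return 1.0
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))
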