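"""Sensor Profiles: per-bin Bernoulli habit models over many days.

A Sensor Profile (SP) breaks the day into fixed-width time bins (default 30
minutes) and models each bin as an independent Bernoulli variable: the
probability of the sensor (e.g. bed occupancy) being sufficiently active in
that bin.  On top of the per-bin MLE ``p_hat = n_pos / N`` with confidence
intervals, the module provides:

* profile comparison — per-bin two-proportion tests with Holm-Bonferroni
  family-wise error control;
* multi-modal routine discovery — agglomerative clustering of day traces
  under cosine distance, with the cluster count selected by mean silhouette
  over clusters of sufficient size;
* novelty detection — the negative log-likelihood of a day trace under a
  reference profile (Novelty Score), thresholded by a Tukey-style IQR rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .events import DayTrace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Profile estimation
# ---------------------------------------------------------------------------


@dataclass
class SensorProfile:
    """Per-bin Bernoulli estimates with confidence intervals."""

    bin_labels: tuple[str, ...]
    bin_width: int
    p_hat: np.ndarray
    n_pos: np.ndarray
    n_total: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float = 0.95

    @property
    def n_bins(self) -> int:
        return int(self.p_hat.size)

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "level": self.level,
            "bins": [
                {
                    "label": lbl,
                    "p_hat": round(float(p), 6),
                    "n_pos": int(np_), "n_total": int(nt),
                    "ci_low": round(float(lo), 6), "ci_high": round(float(hi), 6),
                }
                for lbl, p, np_, nt, lo, hi in zip(
                    self.bin_labels, self.p_hat, self.n_pos, self.n_total,
                    self.ci_low, self.ci_high)
            ],
        }


def _bin_labels(n_bins: int, bin_width: int) -> tuple[str, ...]:
    return tuple(f"{(j * bin_width) // 60:02d}:{(j * bin_width) % 60:02d}"
                 for j in range(n_bins))


def _trace_matrix(traces: Sequence[DayTrace]) -> np.ndarray:
    if not traces:
        raise ValueError("at least one day trace is required")
    n_bins = traces[0].n_bins
    width = traces[0].bin_width
    for tr in traces:
        if tr.n_bins != n_bins or tr.bin_width != width:
            raise ValueError(
                f"trace for {tr.date} has {tr.n_bins} bins of {tr.bin_width} min; "
                f"expected {n_bins} bins of {width} min")
    return np.vstack([tr.bins for tr in traces]).astype(float)


def estimate_profile(
    traces: Sequence[DayTrace],
    ci: str = "wilson",
    level: float = 0.95,
) -> SensorProfile:
    """MLE profile over a set of day traces: per bin, p_hat = n_pos / N.

    Wilson score intervals are attached by default; they remain well-behaved
    when p_hat sits at 0 or 1 with few days, giving the visibly asymmetric
    bands expected for rarely- or always-occupied bins.  ``ci="beta"``
    selects Clopper-Pearson instead.
    """
    if ci not in ("wilson", "beta"):
        raise ValueError("ci must be 'wilson' or 'beta'")
    X = _trace_matrix(traces)
    n_total = np.full(X.shape[1], X.shape[0], dtype=int)
    n_pos = X.sum(axis=0).astype(int)
    p_hat = n_pos / n_total
    lo, hi = proportion_confint(n_pos, n_total, alpha=1.0 - level, method=ci)
    lo = np.minimum(np.nan_to_num(np.asarray(lo, dtype=float), nan=0.0), p_hat)
    hi = np.maximum(np.nan_to_num(np.asarray(hi, dtype=float), nan=1.0), p_hat)
    return SensorProfile(
        bin_labels=_bin_labels(X.shape[1], traces[0].bin_width),
        bin_width=traces[0].bin_width,
        p_hat=p_hat, n_pos=n_pos, n_total=n_total,
        ci_low=np.clip(lo, 0.0, 1.0), ci_high=np.clip(hi, 0.0, 1.0),
        level=level,
    )


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, order-preserving.

    The i-th smallest p-value is multiplied by (m - i + 1), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class ComparisonResult:
    """Per-bin two-proportion comparison of two profiles."""

    bin_labels: tuple[str, ...]
    p_hat_a: np.ndarray
    p_hat_b: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    significant: np.ndarray
    alpha: float

    @property
    def significant_bins(self) -> list[str]:
        return [lbl for lbl, sig in zip(self.bin_labels, self.significant) if sig]


def _two_proportion_p(pos_a: int, n_a: int, pos_b: int, n_b: int) -> float:
    """Two-sided p-value for a 2x2 activation table.

    Pearson chi-square without continuity correction when all expected cells
    are >= 5; Fisher's exact test for sparse tables (it also handles
    degenerate tables with an empty margin, returning p = 1).
    """
    table = np.array([[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 5).any():
        return float(stats.fisher_exact(table.astype(int))[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def compare_profiles(
    traces_a: Sequence[DayTrace],
    traces_b: Sequence[DayTrace],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Test, bin by bin, whether two day-trace sets share activation rates.

    Each bin contributes a 2x2 table (active/inactive days in A vs. B); raw
    two-proportion p-values are Holm-adjusted across all bins so the
    family-wise error rate over the day stays at ``alpha``.
    """
    A = _trace_matrix(traces_a)
    B = _trace_matrix(traces_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("trace sets must share the bin structure")
    n_a, n_b = A.shape[0], B.shape[0]
    pos_a = A.sum(axis=0).astype(int)
    pos_b = B.sum(axis=0).astype(int)
    raw = np.array([
        _two_proportion_p(pa, n_a, pb, n_b) for pa, pb in zip(pos_a, pos_b)
    ])
    adjusted = holm_bonferroni(raw)
    return ComparisonResult(
        bin_labels=_bin_labels(A.shape[1], traces_a[0].bin_width),
        p_hat_a=pos_a / n_a,
        p_hat_b=pos_b / n_b,
        raw_p=raw,
        adjusted_p=adjusted,
        significant=adjusted < alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Clustering of day traces
# ---------------------------------------------------------------------------

SMALL_CLUSTER = -1


@dataclass
class ClusterResult:
    """Outcome of multi-modal routine discovery.

    ``labels`` assigns each day a valid-cluster id (0 = largest) or
    ``SMALL_CLUSTER`` (-1) for days in clusters below the minimum size.
    ``silhouette`` is None for the degenerate single-cluster outcome.
    """

    labels: np.ndarray
    n_clus: int
    prototypes: list[SensorProfile]
    silhouette: float | None
    dates: tuple[date, ...]


def cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - cosine similarity with the zero-vector convention.

    Two all-zero traces are identical (distance 0); an all-zero trace is
    maximally distant (1) from any non-zero trace.
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = (X @ X.T) / np.outer(safe, safe)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim[np.ix_(zero, zero)] = 1.0
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def cluster_day_traces(
    traces: Sequence[DayTrace],
    n_sam: int = 5,
    k_max: int = 8,
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering under cosine distance with silhouette selection.

    For each candidate number of clusters k in 2..k_max, clusters with fewer
    than ``n_sam`` member days are marked invalid; the k maximizing the mean
    silhouette score over valid-cluster members is selected (ties break
    toward fewer clusters).  If no k yields at least two valid clusters the
    result degenerates to a single cluster covering all days.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    X = _trace_matrix(traces)
    n_days = X.shape[0]
    if n_days < 2 * n_sam:
        raise ValueError(f"need at least 2*n_sam = {2 * n_sam} traces, got {n_days}")
    dates = tuple(tr.date for tr in traces)
    D = cosine_distance_matrix(X)

    def degenerate() -> ClusterResult:
        return ClusterResult(
            labels=np.zeros(n_days, dtype=int),
            n_clus=1,
            prototypes=[estimate_profile(traces)],
            silhouette=None,
            dates=dates,
        )

    if D.max() < 1e-12:  # all traces identical
        return degenerate()

    best: tuple[float, int, np.ndarray] | None = None
    for k in range(2, min(k_max, n_days - 1) + 1):
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                        linkage=linkage)
        labels = model.fit_predict(D)
        sizes = np.bincount(labels, minlength=k)
        valid = np.flatnonzero(sizes >= n_sam)
        if valid.size < 2:
            continue
        # silhouette of the full partition, averaged over the members of
        # valid clusters: undersized clusters do not count toward the score
        # but still act as neighbors, so peeling single noisy days off a
        # routine is not rewarded
        member = np.isin(labels, valid)
        samples = silhouette_samples(D, labels, metric="precomputed")
        score = float(samples[member].mean())
        if best is None or score > best[0]:
            best = (score, k, labels)

    if best is None:
        return degenerate()

    score, _, labels = best
    sizes = np.bincount(labels)
    valid = [int(c) for c in np.flatnonzero(sizes >= n_sam)]
    valid.sort(key=lambda c: (-sizes[c], c))  # largest valid cluster gets id 0
    remap = {c: i for i, c in enumerate(valid)}
    out_labels = np.array([remap.get(int(l), SMALL_CLUSTER) for l in labels])
    prototypes = [
        estimate_profile([tr for tr, l in zip(traces, out_labels) if l == i])
        for i in range(len(valid))
    ]
    return ClusterResult(
        labels=out_labels,
        n_clus=len(valid),
        prototypes=prototypes,
        silhouette=score,
        dates=dates,
    )


# ---------------------------------------------------------------------------
# Novelty scoring
# ---------------------------------------------------------------------------


@dataclass
class NoveltyResult:
    """Novelty scores, IQR threshold and inlier/outlier labels per day."""

    scores: np.ndarray
    threshold: float
    outlier: np.ndarray
    dates: tuple[date, ...] = ()


def default_epsilon(prototype: SensorProfile) -> float:
    """Clip bound for profile probabilities: max(1/(2N), 0.005).

    The Bernoulli log-likelihood is infinite when an estimated probability of
    exactly 0 or 1 disagrees with a realization; clipping by half the
    resolution of the estimate (one pseudo-observation in 2N) regularizes it,
    with a 0.005 floor for very long reference periods.
    """
    n = int(prototype.n_total.max())
    return max(1.0 / (2.0 * n), 0.005)


def novelty_score(
    trace: DayTrace,
    prototype: SensorProfile,
    epsilon: float | None = None,
) -> float:
    """Negative log-likelihood of a day trace under a reference profile.

    Bins are treated as conditionally independent:
    ``NS = -sum_j [x_j log t_j + (1-x_j) log(1-t_j)]`` with the prototype
    probabilities clipped into ``[epsilon, 1-epsilon]``.  Low scores mean the
    day matches the reference routine; high scores flag deviant days.
    """
    if trace.n_bins != prototype.n_bins:
        raise ValueError("trace and prototype must share the bin structure")
    if epsilon is None:
        epsilon = default_epsilon(prototype)
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 0.5)")
    theta = np.clip(prototype.p_hat, epsilon, 1.0 - epsilon)
    x = trace.bins.astype(float)
    return float(-np.sum(x * np.log(theta) + (1.0 - x) * np.log1p(-theta)))


def novelty_scores(
    traces: Sequence[DayTrace],
    prototype: SensorProfile,
    epsilon: float | None = None,
) -> np.ndarray:
    return np.array([novelty_score(tr, prototype, epsilon) for tr in traces])


def iqr_outlier_threshold(
    scores: Sequence[float],
    dates: Sequence[date] = (),
    require_positive_iqr: bool = False,
) -> NoveltyResult:
    """Tukey-style outlier rule on novelty scores: Q75 + 1.5 * IQR.

    Percentiles use linear interpolation.  A day is an inlier iff its score
    is strictly below the threshold.  Edge case: when all scores are equal
    the IQR is 0, the threshold equals the common score and the strict
    inequality labels every day an outlier; ``require_positive_iqr=True``
    suppresses flagging in that degenerate case.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValueError("at least 4 scores are required for the IQR rule")
    q25, q75 = np.percentile(s, [25.0, 75.0])
    iqr = q75 - q25
    threshold = float(q75 + 1.5 * iqr)
    if require_positive_iqr and iqr <= 0.0:
        outlier = np.zeros(s.size, dtype=bool)
    else:
        outlier = s >= threshold
    return NoveltyResult(scores=s, threshold=threshold, outlier=outlier,
                         dates=tuple(dates))


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_profile(profile: SensorProfile, ax=None, label: str | None = None,
                 color=None):
    """Plot a profile's p_hat over the day with a shaded confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    hours = np.arange(profile.n_bins) * profile.bin_width / 60.0
    line, = ax.plot(hours, profile.p_hat, label=label, color=color)
    ax.fill_between(hours, profile.ci_low, profile.ci_high,
                    alpha=0.25, color=line.get_color())
    ax.set_xlabel("local time [h]")
    ax.set_ylabel("P(active)")
    ax.set_xlim(0, 24)
    ax.set_ylim(-0.02, 1.02)
    if label:
        ax.legend(loc="upper center")
    return ax
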