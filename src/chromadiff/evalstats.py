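"""Benchmark analysis: histogram statistics, PCA, correlations, regressions.

The perturbation benchmark produces one error matrix per (base image,
perturbed channel, fraction, metric). Each matrix is summarized by five
histogram statistics — mean, variance, skewness, excess kurtosis, and
Shannon entropy (bits, 256-bin histogram) — computed by default on the
quantized 8-bit error image, matching what the grayscale output actually
shows. The record table then feeds three analyses:

* a PCA biplot of the z-scored statistics, to see how tightly each metric's
  records cluster (a reliable metric responds consistently to a controlled
  single-channel perturbation);
* per-metric Pearson correlation heatmaps between the statistics and the
  perturbation fraction;
* per-metric, per-channel ordinary least squares of a statistic (mean or
  variance) on the fraction in percent, pooling the base images: slope,
  intercept, R^2, two-sided Wald p on the slope, and 95 % t-based
  confidence margins. A linear metric should give high R^2 with an
  intercept confidence interval covering zero (no perturbation, no error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .diffmap import quantize
from .errors import ParameterError
from .metrics import METRIC_NAMES, MetricParams, compute_metric
from .perturb import CHANNELS, DEFAULT_FRACTIONS, generate_set

__all__ = [
    "STAT_NAMES",
    "HistogramStats",
    "histogram_stats",
    "run_benchmark",
    "PCAResult",
    "pca_biplot",
    "correlation_heatmap",
    "RegressionResult",
    "linearity_regression",
    "run_regressions",
    "summarize_table1",
]

STAT_NAMES = ("mean", "variance", "skewness", "kurtosis", "entropy")


@dataclass(frozen=True)
class HistogramStats:
    mean: float
    variance: float
    skewness: float
    kurtosis: float  # excess (Fisher)
    entropy: float  # bits

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def histogram_stats(values: np.ndarray, domain: str = "quantized") -> HistogramStats:
    """Five summary statistics of an error matrix.

    domain="quantized" (default) rounds/clamps to the 8-bit grayscale image
    first and uses the exact 256-bin histogram for entropy. domain="float"
    keeps the raw float values for the moments and bins entropy over the
    observed [min, max] range in 256 equal bins.

    Moments are population moments; a constant matrix has variance 0 and,
    by convention, skewness = kurtosis = entropy = 0.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ParameterError("cannot compute statistics of an empty matrix")
    if domain not in ("quantized", "float"):
        raise ParameterError(f"unknown stats domain {domain!r}")

    if domain == "quantized":
        q = quantize(arr)
        x = q.astype(np.float64).ravel()
        counts = np.bincount(q.ravel(), minlength=256)
    else:
        x = arr.ravel()
        lo, hi = x.min(), x.max()
        if hi > lo:
            counts, _ = np.histogram(x, bins=256, range=(lo, hi))
        else:
            counts = np.array([x.size])

    m = x.mean()
    var = np.mean((x - m) ** 2)
    if var > 0:
        z3 = np.mean((x - m) ** 3) / var**1.5
        z4 = np.mean((x - m) ** 4) / var**2 - 3.0
    else:
        z3 = z4 = 0.0
    p = counts[counts > 0] / x.size
    ent = float(-(p * np.log2(p)).sum())
    return HistogramStats(float(m), float(var), float(z3), float(z4), ent)


def run_benchmark(
    bases: list[np.ndarray],
    metrics: tuple[str, ...] = METRIC_NAMES,
    params: MetricParams = MetricParams(),
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    channels: tuple[str, ...] = CHANNELS,
    stats_domain: str = "quantized",
    dataset_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Perturb every base image, diff against it, summarize each error matrix.

    Returns one row per (dataset, metric, channel, fraction):
    len(bases) * len(channels) * len(fractions) * len(metrics) records.
    """
    if not bases:
        raise ParameterError("at least one base image is required")
    if dataset_ids is None:
        dataset_ids = [chr(ord("A") + i) for i in range(len(bases))]
    rows = []
    for ds, base in zip(dataset_ids, bases):
        perturbed = generate_set(base, fractions=fractions, channels=channels)
        for spec, altered in perturbed:
            for metric in metrics:
                error = compute_metric(metric, base, altered, params)
                st = histogram_stats(error, domain=stats_domain)
                rows.append(
                    {
                        "dataset_id": ds,
                        "metric": metric,
                        "channel": spec.channel,
                        "fraction": spec.fraction,
                        **st.as_dict(),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAResult:
    """Two-component PCA of the z-scored record statistics."""

    scores: np.ndarray  # (n_records, 2)
    loadings: np.ndarray  # (n_features, 2), orthonormal columns
    explained_variance_ratio: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray  # metric label per record
    dispersion: pd.Series  # per-metric mean pairwise score distance


def pca_biplot(records: pd.DataFrame, feature_cols: tuple[str, ...] = STAT_NAMES) -> PCAResult:
    """PCA of the benchmark statistics, z-scored column-wise.

    Zero-variance features are dropped with a warning. Each component's sign
    is fixed so its largest-magnitude loading is positive. The per-metric
    dispersion (mean pairwise distance between that metric's scores) reports
    how open each metric's cluster is in the biplot plane.
    """
    if len(records) < 3:
        raise ParameterError("PCA needs at least 3 records")
    X = records.loc[:, list(feature_cols)].to_numpy(dtype=np.float64)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_cols, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    names = tuple(f for f, k in zip(feature_cols, keep) if k)
    if len(names) < 2:
        raise ParameterError("fewer than 2 non-constant features; PCA is undefined")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # (n_features, 2)
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    labels = records["metric"].to_numpy() if "metric" in records else np.array([""] * len(records))
    disp = {}
    for m in pd.unique(labels):
        pts = scores[labels == m]
        if len(pts) < 2:
            disp[m] = 0.0
        else:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            disp[m] = float(d[np.triu_indices(len(pts), 1)].mean())
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=names,
        labels=labels,
        dispersion=pd.Series(disp, name="mean_pairwise_distance"),
    )


def correlation_heatmap(records: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Pearson correlation grid over the five statistics plus the fraction.

    With `metric` given, only that metric's records enter. Correlations
    involving a constant column are set to 0 with a warning (they are
    undefined; 0 marks "no linear association measurable").
    """
    sub = records if metric is None else records[records["metric"] == metric]
    cols = list(STAT_NAMES) + ["fraction"]
    X = sub.loc[:, cols].to_numpy(dtype=np.float64)
    if len(X) < 2:
        raise ParameterError("need at least 2 records for correlations")
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant columns set to zero correlation: {[c for c, k in zip(cols, const) if k]}",
            stacklevel=2,
        )
    corr = np.zeros((len(cols), len(cols)))
    ok = ~const
    if ok.any():
        corr[np.ix_(ok, ok)] = np.corrcoef(X[:, ok], rowvar=False)
    return pd.DataFrame(corr, index=cols, columns=cols)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a histogram statistic on the perturbation fraction (in %)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided Wald t test on the slope
    n_points: int
    slope_margin: float  # 95 % confidence half-width
    intercept_margin: float


def linearity_regression(
    records: pd.DataFrame,
    response: str = "mean",
    channel: str = "R",
    metric: str | None = None,
) -> RegressionResult:
    """Regress `response` on the perturbation fraction for one channel.

    Base images are pooled (the default grouping is one regression per
    metric x channel). The fraction is expressed in percent, so a slope of
    2 means "+2 metric units of mean error per extra percent reduction".
    """
    if response not in STAT_NAMES:
        raise ParameterError(f"response must be one of {STAT_NAMES}")
    sub = records[records["channel"] == channel]
    if metric is not None:
        sub = sub[sub["metric"] == metric]
    x = sub["fraction"].to_numpy(dtype=np.float64) * 100.0
    y = sub[response].to_numpy(dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ParameterError(f"need at least 3 points for a regression, got {n}")
    if np.ptp(y) == 0.0:
        # Constant response: slope 0, R^2 0 by convention (scipy yields NaN r).
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, n, 0.0, 0.0)
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=n,
        slope_margin=float(tcrit * res.stderr),
        intercept_margin=float(tcrit * res.intercept_stderr),
    )


def run_regressions(
    records: pd.DataFrame,
    responses: tuple[str, ...] = ("mean", "variance"),
    channels: tuple[str, ...] = CHANNELS,
) -> pd.DataFrame:
    """All metric x channel x response regressions as one tidy table."""
    rows = []
    for metric in pd.unique(records["metric"]):
        for ch in channels:
            for resp in responses:
                r = linearity_regression(records, response=resp, channel=ch, metric=metric)
                rows.append(
                    {
                        "metric": metric,
                        "channel": ch,
                        "response": resp,
                        "slope": r.slope,
                        "intercept": r.intercept,
                        "r_squared": r.r_squared,
                        "p_value": r.p_value,
                        "n_points": r.n_points,
                        "slope_margin": r.slope_margin,
                        "intercept_margin": r.intercept_margin,
                    }
                )
    return pd.DataFrame(rows)


def summarize_table1(regressions: pd.DataFrame) -> pd.DataFrame:
    """Per-metric summary of the linearity analysis.

    Averages over channels: R^2 of the mean-regressions, R^2 of the
    variance-regressions, and slope/intercept of the mean-regressions with
    their average 95 % margins. Missing cells stay NaN.
    """
    rows = []
    for metric in pd.unique(regressions["metric"]):
        sub = regressions[regressions["metric"] == metric]
        means = sub[sub["response"] == "mean"]
        varis = sub[sub["response"] == "variance"]
        rows.append(
            {
                "metric": metric,
                "avg_r2_means": means["r_squared"].mean(),
                "avg_r2_variances": varis["r_squared"].mean(),
                "avg_slope_means": means["slope"].mean(),
                "avg_slope_margin": means["slope_margin"].mean(),
                "avg_intercept_means": means["intercept"].mean(),
                "avg_intercept_margin": means["intercept_margin"].mean(),
            }
        )
    return pd.DataFrame(rows)


def format_table1(summary: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`summarize_table1`."""
    lines = [
        f"{'METRIC':<10} {'avg R2(mean)':>12} {'avg R2(var)':>12} "
        f"{'avg slope(mean)':>20} {'avg intercept(mean)':>22}"
    ]
    for _, r in summary.iterrows():
        lines.append(
            f"{r['metric']:<10} {r['avg_r2_means']:>12.3f} {r['avg_r2_variances']:>12.3f} "
            f"{r['avg_slope_means']:>12.3f} ±{r['avg_slope_margin']:.3f} "
            f"{r['avg_intercept_means']:>13.3f} ±{r['avg_intercept_margin']:.3f}"
        )
    return "\n".join(lines)
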