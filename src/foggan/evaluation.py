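"""Real-vs-synthetic similarity diagnostics.

Given a real and a synthetic feature matrix (same columns, original
units), this module computes the comparison suite used to judge whether
generated accelerometer rows are statistically faithful:

* Pearson correlation matrices for both, their elementwise absolute
  difference, and a categorical strength reading of each coefficient;
* per-feature cumulative-sum curves;
* per-feature (log10 |mean|, log10 SD) summary points;
* PCA fitted on the (standardized) real matrix with both clouds projected
  into that frame, plus explained-variance ratios;
* per-feature two-sample Kolmogorov-Smirnov statistics and Jensen-Shannon
  divergences (natural log, 50 shared equal-width bins);

aggregated into a :class:`SimilarityReport` with two scalar summaries:
the maximum absolute correlation difference and the mean per-feature KS
statistic — both bounded and monotone in dissimilarity.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import rel_entr
from sklearn.decomposition import PCA

__all__ = [
    "CorrelationReport",
    "PcaComparison",
    "SimilarityReport",
    "pearson_correlation_matrix",
    "classify_correlation_strength",
    "correlation_report",
    "cumulative_sum_curves",
    "log_mean_std_points",
    "pca_compare",
    "feature_distribution_metrics",
    "similarity_report",
    "render_figures",
]

LOG_EPS = 1e-12
JS_BINS = 50

# Correlation-magnitude bands; the half-open edges close the gaps between
# the published interior points (0.01-0.1 moderate, 0.1-0.15 high,
# 0.16-0.3 highly significant).
_BANDS = (
    (0.01, "negligible"),
    (0.10, "moderate"),
    (0.16, "high"),
    (np.inf, "highly significant"),
)


def _as_matrix(X, name: str = "matrix") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {X.shape}")
    return X


def pearson_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlations of the columns; symmetric with unit diagonal.

    A constant column has no defined correlation: its off-diagonal entries
    are set to 0 by convention (see ``constant_columns`` for the flag).
    """
    X = _as_matrix(X)
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for a correlation matrix")
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0.0
    sd_safe = np.where(const, 1.0, sd)
    C = (Xc.T @ Xc) / (n * np.outer(sd_safe, sd_safe))
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def constant_columns(X: np.ndarray) -> np.ndarray:
    """Boolean flag per column: True where the column is constant."""
    return _as_matrix(X).std(axis=0) == 0.0


def classify_correlation_strength(r: float) -> str:
    """Categorical strength of a correlation coefficient's magnitude."""
    mag = abs(float(r))
    if mag > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for upper, label in _BANDS:
        if mag < upper:
            return label
    return _BANDS[-1][1]  # pragma: no cover


@dataclass
class CorrelationReport:
    """Correlation matrices of both datasets, their gap, and band labels."""

    real_matrix: np.ndarray
    synthetic_matrix: np.ndarray
    abs_difference: np.ndarray
    band_labels: list[list[str]]          # on the real matrix's entries
    real_constant: np.ndarray
    synthetic_constant: np.ndarray

    @property
    def max_abs_difference(self) -> float:
        return float(self.abs_difference.max())


def correlation_report(real: np.ndarray, synthetic: np.ndarray) -> CorrelationReport:
    real = _as_matrix(real, "real")
    synthetic = _as_matrix(synthetic, "synthetic")
    if real.shape[1] != synthetic.shape[1]:
        raise ValueError(
            f"column mismatch: real has {real.shape[1]}, synthetic {synthetic.shape[1]}"
        )
    cr = pearson_correlation_matrix(real)
    cs = pearson_correlation_matrix(synthetic)
    bands = [[classify_correlation_strength(v) for v in row] for row in cr]
    return CorrelationReport(
        real_matrix=cr,
        synthetic_matrix=cs,
        abs_difference=np.abs(cr - cs),
        band_labels=bands,
        real_constant=constant_columns(real),
        synthetic_constant=constant_columns(synthetic),
    )


def cumulative_sum_curves(
    real: np.ndarray, synthetic: np.ndarray, feature_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Running totals of one feature column in row order, for both matrices."""
    real = _as_matrix(real, "real")
    synthetic = _as_matrix(synthetic, "synthetic")
    k = real.shape[1]
    if not 0 <= feature_index < k or feature_index >= synthetic.shape[1]:
        raise IndexError(f"feature_index {feature_index} out of range")
    return np.cumsum(real[:, feature_index]), np.cumsum(synthetic[:, feature_index])


def log_mean_std_points(
    real: np.ndarray, synthetic: np.ndarray, eps: float = LOG_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (log10(|mean|+eps), log10(SD+eps)) pairs for both matrices."""

    def points(X: np.ndarray) -> np.ndarray:
        X = _as_matrix(X)
        return np.column_stack(
            [
                np.log10(np.abs(X.mean(axis=0)) + eps),
                np.log10(X.std(axis=0) + eps),
            ]
        )

    return points(real), points(synthetic)


@dataclass
class PcaComparison:
    """PCA frame fitted on the real data with both clouds projected into it."""

    loadings: np.ndarray                 # (k_components, n_features)
    real_projection: np.ndarray
    synthetic_projection: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_compare(real: np.ndarray, synthetic: np.ndarray, k: int = 2) -> PcaComparison:
    """Fit PCA on the standardized real matrix; project both matrices.

    The real distribution is the reference frame: the synthetic cloud is
    standardized with the real means/SDs and projected with the real
    loadings, so displacement and shape differences stay visible.
    """
    real = _as_matrix(real, "real")
    synthetic = _as_matrix(synthetic, "synthetic")
    if k > real.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {real.shape[1]}")
    if real.shape[1] != synthetic.shape[1]:
        raise ValueError("real and synthetic must share the feature count")
    mean = real.mean(axis=0)
    sd = real.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    pca = PCA(n_components=k, svd_solver="full")
    real_proj = pca.fit_transform((real - mean) / sd)
    synth_proj = pca.transform((synthetic - mean) / sd)
    return PcaComparison(
        loadings=pca.components_,
        real_projection=real_proj,
        synthetic_projection=synth_proj,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def feature_distribution_metrics(
    real: np.ndarray, synthetic: np.ndarray, bins: int = JS_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature KS statistics and Jensen-Shannon divergences.

    KS is the two-sample empirical-CDF supremum; JS uses natural log over
    ``bins`` equal-width bins spanning the pooled range of each feature,
    so it is bounded by ln 2 (attained on disjoint supports).
    """
    real = _as_matrix(real, "real")
    synthetic = _as_matrix(synthetic, "synthetic")
    if real.shape[1] != synthetic.shape[1]:
        raise ValueError("real and synthetic must share the feature count")
    if len(real) == 0 or len(synthetic) == 0:
        raise ValueError("cannot compare empty samples")
    k = real.shape[1]
    ks = np.empty(k)
    js = np.empty(k)
    for j in range(k):
        a, b = real[:, j], synthetic[:, j]
        ks[j] = stats.ks_2samp(a, b).statistic
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        if lo == hi:  # both columns a single shared value
            js[j] = 0.0
            continue
        edges = np.linspace(lo, hi, bins + 1)
        p = np.histogram(a, bins=edges)[0] / len(a)
        q = np.histogram(b, bins=edges)[0] / len(b)
        m = 0.5 * (p + q)
        js[j] = float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())
    return ks, js


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------


def _downsample(curve: np.ndarray, n_points: int) -> np.ndarray:
    if len(curve) <= n_points:
        return curve
    idx = np.unique(np.linspace(0, len(curve) - 1, n_points).round().astype(int))
    return curve[idx]


@dataclass
class SimilarityReport:
    """Every diagnostic for one (real, synthetic) pair plus scalar summaries."""

    correlation: CorrelationReport
    cumsum_real: np.ndarray               # (k, <=curve_points) downsampled curves
    cumsum_synthetic: np.ndarray
    n_real: int
    n_synthetic: int
    log_points_real: np.ndarray
    log_points_synthetic: np.ndarray
    pca: PcaComparison
    ks: np.ndarray
    js: np.ndarray
    max_abs_correlation_difference: float
    mean_ks: float

    def to_dict(self) -> dict:
        c = self.correlation
        return {
            "correlation": {
                "real_matrix": c.real_matrix.tolist(),
                "synthetic_matrix": c.synthetic_matrix.tolist(),
                "abs_difference": c.abs_difference.tolist(),
                "band_labels": c.band_labels,
                "real_constant": c.real_constant.tolist(),
                "synthetic_constant": c.synthetic_constant.tolist(),
            },
            "cumsum_real": self.cumsum_real.tolist(),
            "cumsum_synthetic": self.cumsum_synthetic.tolist(),
            "n_real": self.n_real,
            "n_synthetic": self.n_synthetic,
            "log_points_real": self.log_points_real.tolist(),
            "log_points_synthetic": self.log_points_synthetic.tolist(),
            "pca": {
                "loadings": self.pca.loadings.tolist(),
                "real_projection": self.pca.real_projection.tolist(),
                "synthetic_projection": self.pca.synthetic_projection.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            },
            "ks": self.ks.tolist(),
            "js": self.js.tolist(),
            "max_abs_correlation_difference": self.max_abs_correlation_difference,
            "mean_ks": self.mean_ks,
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityReport":
        c = d["correlation"]
        corr = CorrelationReport(
            real_matrix=np.asarray(c["real_matrix"]),
            synthetic_matrix=np.asarray(c["synthetic_matrix"]),
            abs_difference=np.asarray(c["abs_difference"]),
            band_labels=c["band_labels"],
            real_constant=np.asarray(c["real_constant"], dtype=bool),
            synthetic_constant=np.asarray(c["synthetic_constant"], dtype=bool),
        )
        p = d["pca"]
        pca = PcaComparison(
            loadings=np.asarray(p["loadings"]),
            real_projection=np.asarray(p["real_projection"]),
            synthetic_projection=np.asarray(p["synthetic_projection"]),
            explained_variance_ratio=np.asarray(p["explained_variance_ratio"]),
        )
        return cls(
            correlation=corr,
            cumsum_real=np.asarray(d["cumsum_real"]),
            cumsum_synthetic=np.asarray(d["cumsum_synthetic"]),
            n_real=int(d["n_real"]),
            n_synthetic=int(d["n_synthetic"]),
            log_points_real=np.asarray(d["log_points_real"]),
            log_points_synthetic=np.asarray(d["log_points_synthetic"]),
            pca=pca,
            ks=np.asarray(d["ks"]),
            js=np.asarray(d["js"]),
            max_abs_correlation_difference=float(d["max_abs_correlation_difference"]),
            mean_ks=float(d["mean_ks"]),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SimilarityReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def similarity_report(
    real: np.ndarray,
    synthetic: np.ndarray,
    n_components: int = 2,
    curve_points: int = 512,
    max_projection_points: int = 2000,
) -> SimilarityReport:
    """Assemble the full diagnostic suite for one (real, synthetic) pair.

    Cumulative-sum curves and PCA projections are stored downsampled
    (``curve_points`` / ``max_projection_points`` rows) to keep the report
    file small; scalar summaries are computed on the full data.
    """
    real = _as_matrix(real, "real")
    synthetic = _as_matrix(synthetic, "synthetic")
    corr = correlation_report(real, synthetic)
    k = real.shape[1]
    cr = np.stack(
        [_downsample(np.cumsum(real[:, j]), curve_points) for j in range(k)]
    )
    cs = np.stack(
        [_downsample(np.cumsum(synthetic[:, j]), curve_points) for j in range(k)]
    )
    lr, ls = log_mean_std_points(real, synthetic)
    pca = pca_compare(real, synthetic, k=n_components)
    pca = PcaComparison(
        loadings=pca.loadings,
        real_projection=_downsample(pca.real_projection, max_projection_points),
        synthetic_projection=_downsample(pca.synthetic_projection, max_projection_points),
        explained_variance_ratio=pca.explained_variance_ratio,
    )
    ks, js = feature_distribution_metrics(real, synthetic)
    return SimilarityReport(
        correlation=corr,
        cumsum_real=cr,
        cumsum_synthetic=cs,
        n_real=len(real),
        n_synthetic=len(synthetic),
        log_points_real=lr,
        log_points_synthetic=ls,
        pca=pca,
        ks=ks,
        js=js,
        max_abs_correlation_difference=corr.max_abs_difference,
        mean_ks=float(ks.mean()),
    )


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def render_figures(
    real: np.ndarray,
    synthetic: np.ndarray,
    report: SimilarityReport,
    outdir: str | os.PathLike,
) -> list[str]:
    """Render the five diagnostic figure families as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    paths = []
    k = report.ks.shape[0]

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (M, title) in zip(
        axes,
        [
            (report.correlation.real_matrix, "real"),
            (report.correlation.synthetic_matrix, "synthetic"),
            (report.correlation.abs_difference, "|difference|"),
        ],
    ):
        im = ax.imshow(M, vmin=-1 if title != "|difference|" else 0, vmax=1, cmap="RdBu_r")
        ax.set_title(f"correlation: {title}")
        fig.colorbar(im, ax=ax, fraction=0.046)
    paths.append(_save(fig, outdir, "correlation.png"))

    ncols = 3
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(12, 3 * nrows), squeeze=False)
    for j in range(k):
        ax = axes[j // ncols][j % ncols]
        ax.plot(report.cumsum_real[j], label="real")
        ax.plot(report.cumsum_synthetic[j], label="synthetic")
        ax.set_title(f"cumsum f{j + 1}")
    axes[0][0].legend()
    paths.append(_save(fig, outdir, "cumsum.png"))

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(*report.log_points_real.T, label="real")
    ax.scatter(*report.log_points_synthetic.T, marker="x", label="synthetic")
    ax.set_xlabel("log10 |mean|")
    ax.set_ylabel("log10 SD")
    ax.legend()
    paths.append(_save(fig, outdir, "log_mean_std.png"))

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(*report.pca.real_projection[:, :2].T, s=4, alpha=0.4, label="real")
    ax.scatter(*report.pca.synthetic_projection[:, :2].T, s=4, alpha=0.4, label="synthetic")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    paths.append(_save(fig, outdir, "pca.png"))

    fig, axes = plt.subplots(nrows, ncols, figsize=(12, 3 * nrows), squeeze=False)
    for j in range(k):
        ax = axes[j // ncols][j % ncols]
        lo = min(real[:, j].min(), synthetic[:, j].min())
        hi = max(real[:, j].max(), synthetic[:, j].max())
        bins = np.linspace(lo, hi, JS_BINS + 1) if lo < hi else JS_BINS
        ax.hist(real[:, j], bins=bins, density=True, alpha=0.5, label="real")
        ax.hist(synthetic[:, j], bins=bins, density=True, alpha=0.5, label="synthetic")
        ax.set_title(f"f{j + 1}  KS={report.ks[j]:.3f}")
    axes[0][0].legend()
    paths.append(_save(fig, outdir, "distributions.png"))
    return paths


def _save(fig, outdir, name: str) -> str:
    path = os.path.join(os.fspath(outdir), name)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path
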