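"""Hand-crafted time-series features of force segments.

Each force-ON segment is summarized by 29 named scalar features covering
moments and extrema of the force distribution, distributional shape,
spectral structure, tiled-window stability indices from the time-series
feature canon (stability, lumpiness, spikiness, ARCH heterogeneity,
first autocorrelation zero, flat spots, ...), and two inter-prong
descriptors. Single-channel features are computed on the mean of the two
prong channels; Prong Correlation and Prong Asymmetry describe the
relation between the channels themselves.

The canonical order of ``FEATURE_NAMES`` is frozen: feature tables,
augmentation channels and rankings all use it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.inspection import permutation_importance
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

from .core import ForceSegment

FEATURE_NAMES = (
    "Duration Force",            # s
    "Mean Force",                # N
    "Median Force",              # N
    "Max Force",                 # N
    "Min Force",                 # N
    "Range Force",               # N
    "SD Force",                  # N
    "IQR Force",                 # N
    "RMS Force",                 # N
    "Skewness",
    "Kurtosis",
    "Coefficient of Variance",
    "Entropy",                   # spectral, in [0, 1]
    "Stability",
    "Lumpiness",
    "Heterogeneity",
    "Spikiness",
    "Trend Strength",
    "Linearity",
    "Curvature",
    "ACF1",
    "First Autocorrelation Zero",
    "Flat Spots",
    "Crossing Points",
    "Peak Count",
    "Dominant Frequency",        # Hz
    "Spectral Centroid",         # Hz
    "Prong Correlation",
    "Prong Asymmetry",           # mean |L - R|, N
)

#: The four dashboard performance indices ("subset 1").
SUBSET1 = ("Duration Force", "Range Force", "Entropy", "Heterogeneity")

_TILE = 20            # samples per tile for stability/lumpiness (1 s at 20 Hz)


def subset1() -> tuple[str, str, str, str]:
    """The canonical 4-feature dashboard subset, in fixed order."""
    return SUBSET1


# ---------------------------------------------------------------------------
# individual feature helpers (operating on the mean-prong channel x)

def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    xd = x - x.mean()
    denom = float(np.dot(xd, xd))
    if denom == 0:
        return np.zeros(max_lag)
    return np.array([np.dot(xd[:-k], xd[k:]) / denom
                     for k in range(1, max_lag + 1)])


def _spectral(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(entropy in [0,1], dominant frequency Hz, spectral centroid Hz)."""
    xd = x - x.mean()
    freqs, power = signal.periodogram(xd, fs=fs, detrend=False)
    freqs, power = freqs[1:], power[1:]          # drop the DC bin
    total = power.sum()
    if total <= 0 or len(power) < 2:
        return 0.0, 0.0, 0.0
    p = power / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
    dominant = float(freqs[np.argmax(power)])
    centroid = float((freqs * p).sum())
    return entropy, dominant, centroid


def _tiled(x: np.ndarray, width: int) -> np.ndarray:
    n_tiles = len(x) // width
    return x[:n_tiles * width].reshape(n_tiles, width)


def _trend_terms(x: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Quadratic orthonormal-polynomial regression on time.

    Returns (trend strength, linearity, curvature, residuals): linearity
    and curvature are the coefficients on the orthonormalized linear and
    quadratic time regressors; trend strength is the fraction of variance
    they explain.
    """
    n = len(x)
    t = np.arange(n, dtype=float)
    basis = np.polynomial.polynomial.polyvander(t, 2)
    q, _ = np.linalg.qr(basis)
    coefs = q.T @ x
    fitted = q @ coefs
    resid = x - fitted
    var_x = x.var()
    strength = 0.0 if var_x == 0 else max(0.0, 1.0 - resid.var() / var_x)
    return strength, float(coefs[1]), float(coefs[2]), resid


def _spikiness(resid: np.ndarray) -> float:
    """Variance of leave-one-out variances of the detrended series."""
    n = len(resid)
    if n < 3:
        return 0.0
    total = resid.sum()
    total_sq = (resid ** 2).sum()
    loo_means = (total - resid) / (n - 1)
    loo_vars = (total_sq - resid ** 2) / (n - 1) - loo_means ** 2
    return float(loo_vars.var())


def _heterogeneity(x: np.ndarray, n_lags: int = 12) -> float:
    """ARCH-effect statistic: R^2 of an autoregression of squared
    demeaned values on their lags, in [0, 1]."""
    xd = x - x.mean()
    z = xd ** 2
    lags = min(n_lags, len(z) // 2 - 1)
    if lags < 1:
        return 0.0
    y = z[lags:]
    X = np.column_stack([z[lags - k - 1:len(z) - k - 1] for k in range(lags)])
    X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_res = ((y - fitted) ** 2).sum()
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def _first_acf_zero(x: np.ndarray) -> float:
    max_lag = max(1, len(x) - 2)
    acf = _acf(x, max_lag)
    below = np.nonzero(acf <= 0)[0]
    return float(below[0] + 1) if len(below) else float(len(x))


def _flat_spots(x: np.ndarray, n_bins: int = 10) -> float:
    """Longest run of consecutive samples falling in one of ``n_bins``
    equal-width amplitude bins."""
    if x.max() == x.min():
        return float(len(x))
    bins = np.minimum((n_bins * (x - x.min()) / (x.max() - x.min())).astype(int),
                      n_bins - 1)
    best = run = 1
    for a, b in zip(bins[:-1], bins[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return float(best)


def _crossing_points(x: np.ndarray) -> float:
    above = x > x.mean()
    return float(np.count_nonzero(above[1:] != above[:-1]))


def extract_features(segment: ForceSegment, fs: float | None = None) -> dict:
    """Compute the 29 canonical features of one segment.

    Returns an ordered mapping ``{name: value}`` following
    ``FEATURE_NAMES``. Raises for segments shorter than 20 samples.
    """
    if len(segment) < 20:
        raise ValueError("segment too short for feature extraction "
                         "(need >= 20 samples)")
    fs = segment.fs if fs is None else fs
    x = segment.mean_force()
    n = len(x)
    sd = float(x.std())
    mean = float(x.mean())
    q75, q25 = np.percentile(x, [75, 25])
    entropy, dominant, centroid = _spectral(x, fs)
    tiles = _tiled(x, _TILE)
    stability = float(tiles.mean(axis=1).var()) if len(tiles) > 1 else 0.0
    lumpiness = float(tiles.var(axis=1).var()) if len(tiles) > 1 else 0.0
    strength, linearity, curvature, resid = _trend_terms(x)
    acf1 = float(_acf(x, 1)[0])
    peaks, _ = signal.find_peaks(x)
    corr = 0.0
    if segment.left.std() > 0 and segment.right.std() > 0:
        corr = float(np.corrcoef(segment.left, segment.right)[0, 1])
    values = {
        "Duration Force": n / fs,
        "Mean Force": mean,
        "Median Force": float(np.median(x)),
        "Max Force": float(x.max()),
        "Min Force": float(x.min()),
        "Range Force": float(x.max() - x.min()),
        "SD Force": sd,
        "IQR Force": float(q75 - q25),
        "RMS Force": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": float(stats.skew(x)) if sd > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x)) if sd > 0 else 0.0,
        "Coefficient of Variance": sd / mean if mean != 0 else 0.0,
        "Entropy": entropy,
        "Stability": stability,
        "Lumpiness": lumpiness,
        "Heterogeneity": _heterogeneity(x),
        "Spikiness": _spikiness(resid),
        "Trend Strength": strength,
        "Linearity": linearity,
        "Curvature": curvature,
        "ACF1": acf1,
        "First Autocorrelation Zero": _first_acf_zero(x),
        "Flat Spots": _flat_spots(x),
        "Crossing Points": _crossing_points(x),
        "Peak Count": float(len(peaks)),
        "Dominant Frequency": dominant,
        "Spectral Centroid": centroid,
        "Prong Correlation": corr,
        "Prong Asymmetry": float(np.abs(segment.left - segment.right).mean()),
    }
    out = {name: float(values[name]) for name in FEATURE_NAMES}
    for name, v in out.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite feature {name!r}")
    return out


def feature_matrix(segments: list[ForceSegment]) -> pd.DataFrame:
    """(n x 29) feature table, row order = segment order."""
    rows = []
    for seg in segments:
        try:
            rows.append(extract_features(seg))
        except ValueError as err:
            raise ValueError(f"segment {seg.segment_id}: {err}") from err
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def remove_outliers_z(table: pd.DataFrame, z: float = 3.0) -> pd.DataFrame:
    """Drop rows with any |z-score| >= z in a numeric column.

    Scores are computed once on the input table (not iteratively);
    zero-variance columns are skipped.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for outlier screening")
    num = table.select_dtypes(include=[np.number])
    keep = np.ones(len(table), dtype=bool)
    for col in num.columns:
        vals = num[col].to_numpy(dtype=float)
        sd = vals.std()
        if sd == 0:
            continue
        keep &= np.abs((vals - vals.mean()) / sd) < z
    return table.loc[keep].reset_index(drop=True)


def rank_features(X: pd.DataFrame, y, seed: int = 0) -> pd.DataFrame:
    """Rank features by KNN permutation importance and boosted-tree gain.

    Returns a table with both scores, both ranks and their rank-sum
    consensus rank (1 = most important), sorted by consensus.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking requires at least 2 classes")
    codes = pd.factorize(y)[0]
    Xs = (X - X.mean()) / X.std().replace(0, 1.0)
    knn = KNeighborsClassifier(n_neighbors=5).fit(Xs, codes)
    perm = permutation_importance(knn, Xs, codes, scoring="accuracy",
                                  n_repeats=10, random_state=seed)
    xgb = XGBClassifier(n_estimators=100, max_depth=3, random_state=seed,
                        verbosity=0, importance_type="gain")
    xgb.fit(X.to_numpy(), codes)
    gain = xgb.feature_importances_
    out = pd.DataFrame({
        "feature": X.columns,
        "knn_importance": perm.importances_mean,
        "xgb_gain": gain,
    })
    out["knn_rank"] = out["knn_importance"].rank(ascending=False, method="min")
    out["xgb_rank"] = out["xgb_gain"].rank(ascending=False, method="min")
    out["consensus_rank"] = (out["knn_rank"] + out["xgb_rank"]
                             ).rank(method="min")
    return out.sort_values("consensus_rank").reset_index(drop=True)
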