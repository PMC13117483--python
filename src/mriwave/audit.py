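"""Train/validation partition auditing.

Per-slice feature vectors (intensity, spatial-frequency and GLCM texture
descriptors computed inside an automatic tissue mask), pooled whitening, and
three multivariate two-sample statistics — energy distance, unbiased RBF-MMD
with the median-heuristic bandwidth, and order-1 sliced-Wasserstein — with
stratified permutation p-values.  A healthy subject-level split shows small
statistics and unremarkable p-values: the training and validation slices are
then exchangeable with respect to intensity, texture and frequency content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import cdist, pdist

from mriwave.bands import band_energies, dwt2_bands

log = logging.getLogger(__name__)

_EPS = 1e-10

PERCENTILES = (1, 5, 25, 50, 75, 95, 99)
HIST_BINS = 64
GLCM_LEVELS = 32
# unit-distance offsets for 0/45/90/135 degrees, (row, col)
GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))

GLCM_FEATURE_NAMES = ("contrast", "homogeneity", "energy", "correlation", "dissimilarity")


def tissue_mask(slice2d: np.ndarray, low_percentile: float = 25.0) -> np.ndarray:
    """Boolean tissue mask: above-percentile intensities, largest component.

    Returns an all-False mask (caller should skip the slice) when no pixel
    clears the threshold — e.g. a constant slice.
    """
    x = np.asarray(slice2d, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite slice")
    thr = np.percentile(x, low_percentile)
    raw = x > thr
    if not raw.any():
        log.info("empty tissue mask (constant slice?) — slice skipped")
        return np.zeros_like(raw)
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    return raw


def intensity_features(slice2d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Moments, selected percentiles and a 64-bin z-score histogram (sums to 1)."""
    vals = np.asarray(slice2d, dtype=float)[mask]
    mu, sd = vals.mean(), vals.std()
    skew = stats.skew(vals) if sd > 0 else 0.0
    kurt = stats.kurtosis(vals) if sd > 0 else 0.0
    pcts = np.percentile(vals, PERCENTILES)
    z = (vals - mu) / (sd + _EPS)
    hist, _ = np.histogram(z, bins=HIST_BINS, range=(-4.0, 4.0))
    hist = hist / max(hist.sum(), 1)
    return np.concatenate([[mu, sd, skew, kurt], pcts, hist])


def frequency_features(slice2d: np.ndarray) -> np.ndarray:
    """db2 band energies, detail/approximation ratio and Fourier high/low ratio.

    The low-frequency Fourier region is a centered disk of half the Nyquist
    radius; high is its complement.  Energies are mean squared magnitudes.
    """
    x = np.asarray(slice2d, dtype=float)
    if min(x.shape) < 4:
        raise ValueError("slice too small for a db2 decomposition")
    e_aa, e_ad, e_da, e_dd = band_energies(dwt2_bands(x, "db2"))
    ratio1 = (e_ad + e_da + e_dd) / (e_aa + _EPS)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(x))) ** 2
    n0, n1 = x.shape
    u = np.arange(n0) - n0 // 2
    v = np.arange(n1) - n1 // 2
    rr = np.hypot(*np.meshgrid(u, v, indexing="ij"))
    low = rr <= min(n0, n1) / 4.0  # half the Nyquist radius
    e_low = spec[low].mean()
    e_high = spec[~low].mean()
    ratio2 = e_high / (e_low + _EPS)
    return np.array([e_aa, e_ad, e_da, e_dd, ratio1, ratio2])


def _quantize(slice2d: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = slice2d[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return np.zeros_like(slice2d, dtype=np.intp)
    q = np.floor((slice2d - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_features(slice2d: np.ndarray, mask: np.ndarray | None = None,
                  levels: int = GLCM_LEVELS) -> np.ndarray:
    """Texture descriptors from a symmetrized, orientation-averaged GLCM.

    Pixel pairs at unit distance along 0/45/90/135 degrees, both endpoints
    inside the mask; intensities min-max quantized to ``levels`` gray levels
    over the masked region.  Features: contrast, homogeneity, energy,
    correlation (epsilon-guarded), dissimilarity.
    """
    x = np.asarray(slice2d, dtype=float)
    if mask is None:
        mask = np.ones(x.shape, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    q = _quantize(x, mask, levels)
    n0, n1 = x.shape
    mats = []
    for dr, dc in GLCM_OFFSETS:
        r0, r1 = max(0, -dr), min(n0, n0 - dr)
        c0, c1 = max(0, -dc), min(n1, n1 - dc)
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        valid = mask[src] & mask[dst]
        i, j = q[src][valid], q[dst][valid]
        M = np.zeros((levels, levels))
        np.add.at(M, (i, j), 1.0)
        np.add.at(M, (j, i), 1.0)  # symmetrize
        if M.sum() > 0:
            mats.append(M / M.sum())
    if not mats:
        raise ValueError("no valid pixel pairs inside the mask")
    P = np.mean(mats, axis=0)  # orientation-averaged, normalized GLCM
    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float(((ii - jj) ** 2 * P).sum())
    homogeneity = float((P / (1.0 + np.abs(ii - jj))).sum())
    energy = float((P**2).sum())
    dissimilarity = float((np.abs(ii - jj) * P).sum())
    px, py = P.sum(axis=1), P.sum(axis=0)
    mx, my = (np.arange(levels) * px).sum(), (np.arange(levels) * py).sum()
    sx = np.sqrt(((np.arange(levels) - mx) ** 2 * px).sum())
    sy = np.sqrt(((np.arange(levels) - my) ** 2 * py).sum())
    correlation = float((((ii - mx) * (jj - my) * P).sum()) / (sx * sy + _EPS))
    return np.array([contrast, homogeneity, energy, correlation, dissimilarity])


def extract_features(slice2d: np.ndarray, low_percentile: float = 25.0) -> np.ndarray | None:
    """Full per-slice feature vector, or None when the tissue mask is empty."""
    mask = tissue_mask(slice2d, low_percentile)
    if not mask.any():
        return None
    return np.concatenate([
        intensity_features(slice2d, mask),
        frequency_features(np.where(mask, slice2d, 0.0)),
        glcm_features(slice2d, mask),
    ])


def feature_names() -> list[str]:
    names = ["mean", "sd", "skewness", "kurtosis"]
    names += [f"p{p}" for p in PERCENTILES]
    names += [f"hist_{i}" for i in range(HIST_BINS)]
    names += ["E_AA", "E_AD", "E_DA", "E_DD", "detail_approx_ratio", "fourier_high_low_ratio"]
    names += list(GLCM_FEATURE_NAMES)
    return names


# ---------------------------------------------------------------------------
# pooled whitening


def pooled_whiten(train_feats: np.ndarray, val_feats: np.ndarray, ridge: float = 0.0):
    """Pooled z-score then covariance whitening; one transform, both partitions.

    The output pool has mean 0 and covariance ~ identity (exact at ridge 0
    for full-rank input).  Zero-variance features or a rank-deficient pooled
    covariance at ridge 0 are rejected with a suggestion to set ``ridge``.
    """
    X = np.asarray(train_feats, dtype=float)
    Y = np.asarray(val_feats, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("expected 2-D feature matrices with equal dimensionality")
    pool = np.vstack([X, Y])
    mu = pool.mean(axis=0)
    sd = pool.std(axis=0)
    if ridge == 0 and np.any(sd == 0):
        dead = np.where(sd == 0)[0]
        raise ValueError(
            f"zero-variance features at indices {dead.tolist()}; set ridge > 0 or drop them")
    sd = np.where(sd == 0, 1.0, sd)
    pool_z = (pool - mu) / sd
    cov = np.cov(pool_z, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    if ridge == 0 and evals.min() <= 1e-12:
        raise ValueError(
            f"pooled covariance is rank deficient (min eigenvalue {evals.min():.3g}); "
            "set ridge > 0")
    W = evecs @ np.diag(1.0 / np.sqrt(evals + ridge)) @ evecs.T
    transform = lambda A: ((A - mu) / sd) @ W
    return transform(X), transform(Y)


# ---------------------------------------------------------------------------
# two-sample statistics


def energy_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """E-statistic: 2/(nm) sum||x-y|| - 1/n^2 sum||x-x'|| - 1/m^2 sum||y-y'||."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("empty sample")
    dxy = cdist(X, Y).mean()
    dxx = cdist(X, X).mean()
    dyy = cdist(Y, Y).mean()
    return float(2.0 * dxy - dxx - dyy)


def median_heuristic_bandwidth(pool: np.ndarray) -> float:
    """Median pairwise Euclidean distance over distinct unordered pairs."""
    d = pdist(np.atleast_2d(pool))
    return float(np.median(d))


def mmd_rbf(X: np.ndarray, Y: np.ndarray, sigma: float | None = None) -> float:
    """Unbiased squared MMD with a Gaussian kernel exp(-||x-y||^2 / (2 sigma^2)).

    Bandwidth defaults to the median heuristic over the pooled sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, m = X.shape[0], Y.shape[0]
    if n < 2 or m < 2:
        raise ValueError("unbiased MMD needs at least 2 points per sample")
    if sigma is None:
        sigma = median_heuristic_bandwidth(np.vstack([X, Y]))
    if sigma == 0:
        raise ValueError("median-heuristic bandwidth is zero (all pooled points identical)")
    k = lambda A, B: np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma**2))
    kxx, kyy, kxy = k(X, X), k(Y, Y), k(X, Y)
    term_x = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    term_y = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    if n == m:
        # equal-size unbiased form: index-paired cross diagonal excluded, so
        # identical multisets give exactly zero
        cross = (kxy.sum() - np.trace(kxy)) / (n * (n - 1))
    else:
        cross = kxy.mean()
    return float(term_x + term_y - 2.0 * cross)


def sliced_wasserstein(X: np.ndarray, Y: np.ndarray, n_directions: int = 100,
                       seed: int = 0) -> float:
    """Order-1 sliced Wasserstein over random unit directions.

    With unequal sample sizes the larger sample is subsampled (without
    replacement, seeded, per direction) to K = min(n, m) before sorting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, m = X.shape[0], Y.shape[0]
    if n == 0 or m == 0 or n_directions < 1:
        raise ValueError("need non-empty samples and at least one direction")
    d = X.shape[1]
    K = min(n, m)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51D]))
    dirs = rng.normal(size=(int(n_directions), d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    total = 0.0
    for th in dirs:
        px, py = X @ th, Y @ th
        if n > K:
            px = px[rng.choice(n, size=K, replace=False)]
        if m > K:
            py = py[rng.choice(m, size=K, replace=False)]
        total += np.mean(np.abs(np.sort(px) - np.sort(py)))
    return float(total / len(dirs))


@dataclass(frozen=True)
class TwoSampleResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int


def permutation_pvalue(stat_fn, X: np.ndarray, Y: np.ndarray, strata_x, strata_y,
                       n_perm: int = 1000, seed: int = 0) -> TwoSampleResult:
    """Stratified permutation test: labels shuffled within strata.

    Partition sizes are preserved exactly per stratum; the p-value uses the
    add-one correction ``(1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    sx = np.asarray(strata_x)
    sy = np.asarray(strata_y)
    if len(sx) != X.shape[0] or len(sy) != Y.shape[0]:
        raise ValueError("one stratum label per observation required")
    only = set(sx.tolist()) ^ set(sy.tolist())
    if only:
        raise ValueError(f"strata present in only one partition: {sorted(only, key=str)}")
    obs = float(stat_fn(X, Y))
    pool = np.vstack([X, Y])
    labels = np.concatenate([sx, sy])
    is_x = np.concatenate([np.ones(X.shape[0], bool), np.zeros(Y.shape[0], bool)])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E12]))
    strata_idx = {s: np.where(labels == s)[0] for s in np.unique(labels)}
    count = 0
    assign = is_x.copy()
    for _ in range(int(n_perm)):
        for idx in strata_idx.values():
            assign[idx] = is_x[idx][rng.permutation(len(idx))]
        stat = stat_fn(pool[assign], pool[~assign])
        if stat >= obs:
            count += 1
    p = (1.0 + count) / (1.0 + int(n_perm))
    return TwoSampleResult(statistic=obs, p_value=float(p), n_perm=int(n_perm), seed=int(seed))
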