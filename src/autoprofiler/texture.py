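"""Texture and shape-moment descriptors for masked objects.

Haralick statistics are computed from gray-level co-occurrence matrices
(GLCMs) at distance 1 in the four 2-D directions (0, 45, 90, 135 degrees),
with the object's intensity range quantised to a fixed number of gray levels.
Each of the 14 classical statistics is summarised by its mean and range over
the directions, giving 28 values per object.

Zernike moments are magnitudes of projections of the binary object mask onto
the orthogonal Zernike polynomials over a disk about the object centroid.
With radial degree n <= 8 (m >= 0, n - m even) there are exactly 25 moments;
magnitudes are invariant to rotation of the mask.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.feature import graycomatrix

from .catalogue import HARALICK_NAMES

__all__ = ["haralick_features", "zernike_moments", "ZERNIKE_PAIRS"]

_EPS = np.finfo(np.float64).tiny

#: (n, m) index pairs for Zernike moments up to radial degree 8, in order.
ZERNIKE_PAIRS: list[tuple[int, int]] = [
    (n, m) for n in range(9) for m in range(n + 1) if (n - m) % 2 == 0
]
assert len(ZERNIKE_PAIRS) == 25


def _quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Quantise object pixels to 1..levels over their min-max; background = 0."""
    vals = image[mask].astype(np.float64)
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=np.uint16)
    if hi > lo:
        scaled = (image.astype(np.float64) - lo) / (hi - lo)
        q[mask] = np.minimum((scaled[mask] * levels).astype(np.uint16), levels - 1) + 1
    else:
        q[mask] = 1
    return q


def _haralick_14(p: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of one normalised symmetric GLCM."""
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = math.sqrt(max(((i - mu_x) ** 2 * px).sum(), 0.0))
    sd_y = math.sqrt(max(((i - mu_y) ** 2 * py).sum(), 0.0))

    out = np.empty(14)
    # f1 angular second moment
    out[0] = (p**2).sum()
    # f2 contrast
    out[1] = (((ii - jj) ** 2) * p).sum()
    # f3 correlation
    if sd_x > 0 and sd_y > 0:
        out[2] = ((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        out[2] = np.nan
    # f4 sum of squares: variance
    out[3] = (((ii - mu_x) ** 2) * p).sum()
    # f5 inverse difference moment
    out[4] = (p / (1.0 + (ii - jj) ** 2)).sum()
    # sum and difference distributions
    k_sum = np.arange(2 * n - 1, dtype=np.float64)  # i+j in 0..2n-2
    p_sum = np.zeros(2 * n - 1)
    k_diff = np.arange(n, dtype=np.float64)  # |i-j| in 0..n-1
    p_diff = np.zeros(n)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    # f6 sum average, f7 sum variance, f8 sum entropy
    out[5] = (k_sum * p_sum).sum()
    out[6] = (((k_sum - out[5]) ** 2) * p_sum).sum()
    out[7] = -(p_sum * np.log(p_sum + _EPS))[p_sum > 0].sum()
    # f9 entropy
    hxy = -(p * np.log(p + _EPS))[p > 0].sum()
    out[8] = hxy
    # f10 difference variance, f11 difference entropy
    mu_d = (k_diff * p_diff).sum()
    out[9] = (((k_diff - mu_d) ** 2) * p_diff).sum()
    out[10] = -(p_diff * np.log(p_diff + _EPS))[p_diff > 0].sum()
    # f12/f13 information measures of correlation
    pxy = np.outer(px, py)
    valid = pxy > 0
    hxy1 = -(p[valid] * np.log(pxy[valid])).sum()
    hxy2 = -(pxy[valid] * np.log(pxy[valid])).sum()
    hx = -(px * np.log(px + _EPS))[px > 0].sum()
    hy = -(py * np.log(py + _EPS))[py > 0].sum()
    denom = max(hx, hy)
    out[11] = (hxy - hxy1) / denom if denom > 0 else np.nan
    arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
    out[12] = math.sqrt(max(arg, 0.0))
    # f14 maximal correlation coefficient
    out[13] = _max_correlation_coefficient(p, px, py)
    return out


def _max_correlation_coefficient(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return np.nan
    pk = p[np.ix_(keep, keep)]
    pxk = px[keep]
    pyk = py[keep]
    q = (pk / pxk[:, None]) @ (pk / pyk[None, :]).T
    try:
        ev = np.linalg.eigvals(q)
    except np.linalg.LinAlgError:
        return np.nan
    ev = np.sort(np.real(ev))
    second = ev[-2]
    if not np.isfinite(second):
        return np.nan
    return math.sqrt(max(second, 0.0))


def haralick_features(
    image: np.ndarray, mask: np.ndarray, levels: int = 64
) -> np.ndarray:
    """28 texture values (14 Haralick statistics x mean/range over directions).

    Parameters
    ----------
    image, mask
        Intensity image and boolean object mask (same shape).
    levels
        Number of gray levels the object's intensity range is quantised to.

    Returns
    -------
    Array of length 28 ordered as in ``catalogue.TEXTURE_BASE``
    (feature-major: ASM_mean, ASM_range, contrast_mean, ...). All-NaN for
    objects with no co-occurring pixel pairs (e.g. a single pixel).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        return np.full(28, np.nan)
    q = _quantize(image, mask, levels)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )[1:, 1:, 0, :]
    per_dir = []
    for a in range(glcm.shape[-1]):
        m = glcm[:, :, a].astype(np.float64)
        total = m.sum()
        if total == 0:  # no valid pair in this direction (thin objects)
            continue
        per_dir.append(_haralick_14(m / total))
    if not per_dir:
        return np.full(28, np.nan)
    stats = np.vstack(per_dir)  # (directions, 14)
    mean = stats.mean(axis=0)
    rng = stats.max(axis=0) - stats.min(axis=0)
    out = np.empty(28)
    out[0::2] = mean
    out[1::2] = rng
    return out


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    r = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        r += c * rho ** (n - 2 * s)
    return r


def zernike_moments(mask: np.ndarray, radius: float) -> np.ndarray:
    """Magnitudes of the 25 Zernike moments (degree <= 8) of a binary mask.

    The mask is sampled on the disk of the given radius (in pixels) about its
    own centroid; pixel weights are normalised so the moments are independent
    of object area.
    """
    if radius <= 0:
        raise ValueError("Zernike radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return np.full(25, np.nan)
    cy, cx = ys.mean(), xs.mean()
    dy = (ys - cy) / radius
    dx = (xs - cx) / radius
    rho = np.hypot(dx, dy)
    inside = rho <= 1.0
    if not inside.any():
        return np.full(25, np.nan)
    rho = rho[inside]
    theta = np.arctan2(dy[inside], dx[inside])
    w = 1.0 / inside.sum()
    out = np.empty(25)
    for k, (n, m) in enumerate(ZERNIKE_PAIRS):
        r = _radial_poly(n, m, rho)
        a = (n + 1) / np.pi * w * np.sum(r * np.exp(-1j * m * theta))
        out[k] = abs(a)
    return out
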