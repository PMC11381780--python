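"""Handcrafted texture features over a masked region of interest.

Thirty-three features in five classical families, in fixed order:

* grey-histogram (6): mean, variance, skewness, excess kurtosis, energy,
  entropy of the foreground intensity distribution;
* grey-level co-occurrence matrix, GLCM (6): contrast, correlation, energy
  (angular second moment), homogeneity, entropy, dissimilarity, averaged
  over the four standard offsets at distance 1;
* Gabor (3): mean magnitude of the zero-mean complex Gabor response at
  orientations 0/60/120 degrees, single scale;
* Gauss–Markov random field, GMRF (12): least-squares interaction
  parameters of a fifth-order symmetric autoregression;
* Tamura (6): coarseness, contrast, directionality, line-likeness,
  regularity, roughness.

All families respect the binary mask: GLCM pairs require both pixels in
the foreground; the windowed families operate on the foreground bounding
box.  Degenerate inputs (constant patches, empty co-occurrence) follow the
fixed conventions documented per function so results are exactly testable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

__all__ = [
    "FEATURE_NAMES",
    "GMRF_OFFSETS",
    "FeatureVector33",
    "quantize_levels",
    "grey_histogram_features",
    "glcm_accumulate",
    "glcm_statistics",
    "gabor_features",
    "gmrf_fit",
    "synthesize_gmrf",
    "tamura_features",
    "extract_features",
]

GLCM_LEVELS = 32
GLCM_DISTANCE = 1
GLCM_ANGLES = (0, 45, 90, 135)

GABOR_WAVELENGTH = 8.0
GABOR_SIGMA = 4.0
GABOR_ANGLES_DEG = (0.0, 60.0, 120.0)

#: half-plane offsets (dr, dc) of the fifth-order symmetric GMRF
GMRF_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 0), (1, 1), (1, -1),
    (0, 2), (2, 0), (1, 2), (2, 1),
    (2, -1), (1, -2), (2, 2), (2, -2),
)

GMRF_MIN_SITES = 30

TAMURA_SIZES = tuple(2**k for k in range(6))  # averaging windows 1..32
TAMURA_DIR_BINS = 16
TAMURA_DIR_THRESHOLD = 12.0 / 255.0
TAMURA_LINE_DISTANCE = 4
TAMURA_REGULARITY_R = 0.25

FEATURE_NAMES: tuple[str, ...] = (
    "gh_mean", "gh_variance", "gh_skewness", "gh_kurtosis", "gh_energy", "gh_entropy",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "glcm_entropy", "glcm_dissimilarity",
    "gabor_000", "gabor_060", "gabor_120",
    *(f"gmrf_{dr}_{dc}".replace("-", "m") for dr, dc in GMRF_OFFSETS),
    "tamura_coarseness", "tamura_contrast", "tamura_directionality",
    "tamura_linelikeness", "tamura_regularity", "tamura_roughness",
)
assert len(FEATURE_NAMES) == 33


class FeatureVector33:
    """Ordered 33-element texture descriptor: 6 GH | 6 GLCM | 3 Gabor | 12 GMRF | 6 Tamura."""

    names = FEATURE_NAMES

    def __init__(self, values: np.ndarray, sample_id: str = ""):
        values = np.asarray(values, dtype=float)
        if values.shape != (33,):
            raise ValueError(f"expected 33 values, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains non-finite values")
        self.values = values
        self.sample_id = sample_id

    def __len__(self) -> int:
        return 33

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _validate_patch(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError(f"pixels {pixels.shape} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise ValueError("empty foreground")
    return mask


def quantize_levels(pixels: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Linearly bin foreground pixels into {0..levels-1} using the foreground min/max.

    Background positions are set to -1.  A constant foreground maps to all
    zeros.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = _validate_patch(pixels, mask)
    pixels = np.asarray(pixels, dtype=float)
    fg = pixels[mask]
    lo, hi = fg.min(), fg.max()
    out = np.full(pixels.shape, -1, dtype=np.int64)
    if hi == lo:
        out[mask] = 0
        return out
    binned = np.floor((pixels - lo) / (hi - lo) * levels).astype(np.int64)
    out[mask] = np.clip(binned[mask], 0, levels - 1)
    return out


def grey_histogram_features(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean, variance, skewness, excess kurtosis, energy, entropy of the ROI.

    Moments are population moments over foreground pixels; energy and
    entropy (bits) come from a 256-bin histogram over [0, 1].  A
    zero-variance foreground fixes skewness and kurtosis to 0.
    """
    mask = _validate_patch(pixels, mask)
    vals = np.asarray(pixels, dtype=float)[mask]
    if np.ptp(vals) == 0.0:  # constant foreground: exact convention values
        return np.array([vals[0], 0.0, 0.0, 0.0, 1.0, 0.0])
    mean = vals.mean()
    var = vals.var()
    if var > 0:
        z = (vals - mean) / np.sqrt(var)
        skew = np.mean(z**3)
        kurt = np.mean(z**4) - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    hist, _ = np.histogram(vals, bins=256, range=(0.0, 1.0))
    p = hist / hist.sum()
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return np.array([mean, var, skew, kurt, energy, entropy])


_GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_accumulate(
    quantized: np.ndarray,
    mask: np.ndarray,
    distance: int = GLCM_DISTANCE,
    angle: int = 0,
    levels: int = GLCM_LEVELS,
) -> tuple[np.ndarray, bool]:
    """Symmetric normalized co-occurrence matrix at one offset.

    Counts level pairs (p, p+offset) where both pixels are foreground,
    adds the transpose and normalizes to sum 1.  Returns ``(matrix,
    degenerate)``; a degenerate result (no valid pair) is the zero matrix
    with the flag set.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _GLCM_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_GLCM_OFFSETS)}, got {angle}")
    quantized = np.asarray(quantized)
    mask = np.asarray(mask, dtype=bool)
    dr, dc = (distance * o for o in _GLCM_OFFSETS[angle])
    h, w = quantized.shape

    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = quantized[r0s:r0e, c0s:c0e]
    b = quantized[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]

    cm = np.zeros((levels, levels), dtype=float)
    if not valid.any():
        return cm, True
    np.add.at(cm, (a[valid], b[valid]), 1.0)
    cm = cm + cm.T
    return cm / cm.sum(), False


def glcm_statistics(matrices: list[tuple[np.ndarray, bool]]) -> np.ndarray:
    """Contrast, correlation, energy, homogeneity, entropy, dissimilarity.

    Each statistic is averaged over the supplied per-angle matrices.
    Conventions: correlation of a zero-variance matrix is 1; a degenerate
    (flagged) matrix contributes the constant-patch values
    (0, 1, 1, 1, 0, 0).  Energy is the angular second moment.
    """
    stats = []
    n_degenerate = 0
    for cm, degenerate in matrices:
        if degenerate:
            stats.append(np.array([0.0, 1.0, 1.0, 1.0, 0.0, 0.0]))
            n_degenerate += 1
            continue
        levels = cm.shape[0]
        i = np.arange(levels)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        diff = ii - jj
        contrast = float(np.sum(cm * diff**2))
        dissim = float(np.sum(cm * np.abs(diff)))
        homog = float(np.sum(cm / (1.0 + diff**2)))
        asm = float(np.sum(cm**2))
        nz = cm[cm > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
        pi = cm.sum(axis=1)
        mu = float(np.sum(i * pi))
        var = float(np.sum((i - mu) ** 2 * pi))
        if var > 0:
            corr = float(np.sum((ii - mu) * (jj - mu) * cm) / var)
        else:
            corr = 1.0
        stats.append(np.array([contrast, corr, asm, homog, entropy, dissim]))
    if n_degenerate == len(matrices):
        warnings.warn("all co-occurrence matrices degenerate; returning convention values")
    return np.mean(stats, axis=0)


def _zero_mean_gabor(theta_deg: float) -> np.ndarray:
    k = gabor_kernel(
        frequency=1.0 / GABOR_WAVELENGTH,
        theta=np.deg2rad(theta_deg),
        sigma_x=GABOR_SIGMA,
        sigma_y=GABOR_SIGMA,
    )
    # remove the DC component so constant patches give zero response
    return k - k.mean()


def gabor_features(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean complex Gabor response magnitude over the foreground.

    One scale (wavelength 8 px, sigma 4 px) at orientations 0, 60 and 120
    degrees; the kernel is made zero-mean so a constant patch responds 0.
    """
    mask = _validate_patch(pixels, mask)
    pixels = np.asarray(pixels, dtype=float)
    if min(pixels.shape) < 16:
        raise ValueError(f"patch must be at least 16x16 for Gabor filtering, got {pixels.shape}")
    out = np.empty(3)
    for idx, theta in enumerate(GABOR_ANGLES_DEG):
        k = _zero_mean_gabor(theta)
        if k.shape[0] > pixels.shape[0] or k.shape[1] > pixels.shape[1]:
            raise ValueError("patch smaller than Gabor kernel support")
        resp_r = ndimage.convolve(pixels, np.real(k), mode="reflect")
        resp_i = ndimage.convolve(pixels, np.imag(k), mode="reflect")
        mag = np.hypot(resp_r, resp_i)
        out[idx] = mag[mask].mean()
    return out


def _bbox(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def gmrf_fit(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Least-squares interaction parameters of a fifth-order symmetric GMRF.

    The mean-subtracted foreground is modeled as a conditional
    autoregression y(s) = sum_r theta_r (y(s+r) + y(s-r)) + e(s) over the 12
    half-plane offsets; theta is estimated by ordinary least squares using
    only sites whose full 5x5-order neighborhood lies inside the
    foreground.  Fewer than 30 usable sites, or singular normal equations,
    yield zeros with a warning; a constant patch yields zeros.
    """
    mask = _validate_patch(pixels, mask)
    rs, cs = _bbox(mask)
    if (rs.stop - rs.start) < 9 or (cs.stop - cs.start) < 9:
        raise ValueError("foreground bounding box must be at least 9x9 for GMRF fitting")
    patch = np.asarray(pixels, dtype=float)[rs, cs]
    m = mask[rs, cs]
    y = patch - patch[m].mean()
    h, w = y.shape

    # usable sites: in-mask, with every +/- offset position also in-mask
    pad = 2
    usable = np.zeros_like(m)
    usable[pad:h - pad, pad:w - pad] = True
    usable &= m
    for dr, dc in GMRF_OFFSETS:
        for sr, sc in ((dr, dc), (-dr, -dc)):
            shifted = np.zeros_like(m)
            shifted[max(0, -sr):h + min(0, -sr), max(0, -sc):w + min(0, -sc)] = (
                m[max(0, sr):h + min(0, sr), max(0, sc):w + min(0, sc)]
            )
            usable &= shifted

    rows_idx, cols_idx = np.nonzero(usable)
    if rows_idx.size < GMRF_MIN_SITES:
        warnings.warn(f"only {rows_idx.size} usable GMRF sites; returning zeros")
        return np.zeros(12)
    target = y[rows_idx, cols_idx]
    design = np.empty((rows_idx.size, 12))
    for j, (dr, dc) in enumerate(GMRF_OFFSETS):
        design[:, j] = y[rows_idx + dr, cols_idx + dc] + y[rows_idx - dr, cols_idx - dc]
    if np.allclose(design, 0.0) or np.allclose(target, 0.0):
        return np.zeros(12)
    theta, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < 12:
        warnings.warn("degenerate GMRF normal equations; returning zeros")
        return np.zeros(12)
    return theta


def synthesize_gmrf(
    shape: tuple[int, int],
    thetas: dict[tuple[int, int], float],
    seed: int,
    sigma: float = 1.0,
) -> np.ndarray:
    """Draw a stationary GMRF sample with the given symmetric interactions.

    Spectral synthesis: the conditional autoregression with parameters
    ``thetas`` has power spectrum sigma^2 / (1 - 2 sum_r theta_r cos(2 pi
    f.r)); white Fourier noise is shaped accordingly.  Used for
    parameter-recovery checks of :func:`gmrf_fit`.
    """
    h, w = shape
    fr = np.fft.fftfreq(h)[:, None]
    fc = np.fft.fftfreq(w)[None, :]
    denom = np.ones((h, w))
    for (dr, dc), theta in thetas.items():
        denom = denom - 2.0 * theta * np.cos(2.0 * np.pi * (fr * dr + fc * dc))
    if np.any(denom <= 0):
        raise ValueError("interaction parameters violate the stationarity condition")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w))
    spectrum = np.fft.fft2(noise) * (sigma / np.sqrt(denom))
    return np.real(np.fft.ifft2(spectrum))


def _tamura_coarseness(patch: np.ndarray) -> tuple[float, np.ndarray]:
    h, w = patch.shape
    best_diff = np.zeros((h, w))
    # tie rule: smallest size wins (strict inequality when updating)
    best_size = np.ones((h, w))
    for size in TAMURA_SIZES:
        avg = ndimage.uniform_filter(patch, size=size, mode="reflect")
        half = max(size // 2, 1)
        dh = np.abs(np.roll(avg, -half, axis=1) - np.roll(avg, half, axis=1))
        dv = np.abs(np.roll(avg, -half, axis=0) - np.roll(avg, half, axis=0))
        d = np.maximum(dh, dv)
        improved = d > best_diff
        best_diff[improved] = d[improved]
        best_size[improved] = size
    return float(best_size.mean()), best_size


def _tamura_contrast(patch: np.ndarray) -> float:
    var = patch.var()
    if var == 0:
        return 0.0
    mu = patch.mean()
    m4 = np.mean((patch - mu) ** 4)
    alpha4 = m4 / var**2
    return float(np.sqrt(var) / alpha4**0.25)


def _gradient_orientation_histogram(patch: np.ndarray) -> np.ndarray:
    gh = ndimage.prewitt(patch, axis=1, mode="reflect")
    gv = ndimage.prewitt(patch, axis=0, mode="reflect")
    mag = (np.abs(gh) + np.abs(gv)) / 2.0
    theta = np.mod(np.arctan2(gv, gh), np.pi)
    keep = mag > TAMURA_DIR_THRESHOLD
    if not keep.any():
        return np.zeros(TAMURA_DIR_BINS)
    bins = np.minimum(
        (theta[keep] / np.pi * TAMURA_DIR_BINS).astype(int), TAMURA_DIR_BINS - 1
    )
    hist = np.bincount(bins, minlength=TAMURA_DIR_BINS).astype(float)
    return hist / hist.sum()


def _tamura_directionality(patch: np.ndarray) -> float:
    # histogram sharpness: sum of squared bin masses, 1 for a single
    # dominant orientation, 1/n_bins for isotropic texture, 0 if no edges
    hist = _gradient_orientation_histogram(patch)
    return float(np.sum(hist**2))


def _tamura_linelikeness(patch: np.ndarray) -> float:
    gh = ndimage.prewitt(patch, axis=1, mode="reflect")
    gv = ndimage.prewitt(patch, axis=0, mode="reflect")
    mag = (np.abs(gh) + np.abs(gv)) / 2.0
    theta = np.mod(np.arctan2(gv, gh), np.pi)
    keep = mag > TAMURA_DIR_THRESHOLD
    if not keep.any():
        return 0.0
    n = TAMURA_DIR_BINS
    bins = np.minimum((theta / np.pi * n).astype(int), n - 1)
    d = TAMURA_LINE_DISTANCE
    h, w = patch.shape
    # co-occurrence of edge directions along each pixel's own direction
    centers = (np.arange(n) + 0.5) * np.pi / n
    rr, cc = np.nonzero(keep)
    ang = centers[bins[rr, cc]]
    r2 = np.clip(np.round(rr + d * np.sin(ang)).astype(int), 0, h - 1)
    c2 = np.clip(np.round(cc + d * np.cos(ang)).astype(int), 0, w - 1)
    partner_ok = keep[r2, c2]
    if not partner_ok.any():
        return 0.0
    b1 = bins[rr, cc][partner_ok]
    b2 = bins[r2, c2][partner_ok]
    num = float(np.sum(np.cos((b1 - b2) * 2.0 * np.pi / n)))
    den = float(partner_ok.sum())
    return num / den


def _tamura_regularity(patch: np.ndarray) -> float:
    h, w = patch.shape
    halves_r, halves_c = h // 2, w // 2
    subs = [
        patch[:halves_r, :halves_c], patch[:halves_r, halves_c:],
        patch[halves_r:, :halves_c], patch[halves_r:, halves_c:],
    ]
    subs = [s for s in subs if s.size >= 16]
    if len(subs) < 2:
        return 1.0
    crs = [_tamura_coarseness(s)[0] for s in subs]
    cons = [_tamura_contrast(s) for s in subs]
    dirs = [_tamura_directionality(s) for s in subs]
    lins = [_tamura_linelikeness(s) for s in subs]
    spread = sum(float(np.std(v)) for v in (crs, cons, dirs, lins))
    return 1.0 - TAMURA_REGULARITY_R * spread


def tamura_features(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The six Tamura perceptual descriptors on the foreground bounding box.

    Coarseness uses best-size averaging over window sizes 1..32 (ties go to
    the smallest size, so a constant patch scores 1); contrast is
    sigma/alpha4^0.25; directionality is the sharpness (sum of squares) of
    the thresholded gradient-orientation histogram; line-likeness is the
    mean direction-co-occurrence cosine at distance 4; regularity is
    1 - r * (sum of subwindow standard deviations of the first four);
    roughness is coarseness + contrast.
    """
    mask = _validate_patch(pixels, mask)
    rs, cs = _bbox(mask)
    if (rs.stop - rs.start) < 32 or (cs.stop - cs.start) < 32:
        raise ValueError("foreground bounding box must be at least 32x32 for Tamura features")
    patch = np.asarray(pixels, dtype=float)[rs, cs]
    coarseness, _ = _tamura_coarseness(patch)
    contrast = _tamura_contrast(patch)
    directionality = _tamura_directionality(patch)
    linelikeness = _tamura_linelikeness(patch)
    regularity = _tamura_regularity(patch)
    roughness = coarseness + contrast
    return np.array([coarseness, contrast, directionality, linelikeness, regularity, roughness])


def extract_features(
    image,
    glcm_levels: int = GLCM_LEVELS,
    glcm_distance: int = GLCM_DISTANCE,
) -> FeatureVector33:
    """Concatenate the five families (GH|GLCM|Gabor|GMRF|Tamura) for one image.

    ``image`` is any object with ``pixels``, ``mask`` and ``sample_id``
    attributes (a :class:`~fewtex.phantom.LabeledImage` fits).  Output
    order and length are fixed; the computation is deterministic.
    """
    pixels, mask = image.pixels, image.mask
    gh = grey_histogram_features(pixels, mask)
    q = quantize_levels(pixels, mask, glcm_levels)
    mats = [
        glcm_accumulate(q, mask, glcm_distance, angle, glcm_levels) for angle in GLCM_ANGLES
    ]
    glcm = glcm_statistics(mats)
    gabor = gabor_features(pixels, mask)
    gmrf = gmrf_fit(pixels, mask)
    tamura = tamura_features(pixels, mask)
    values = np.concatenate([gh, glcm, gabor, gmrf, tamura])
    return FeatureVector33(values, sample_id=getattr(image, "sample_id", ""))
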