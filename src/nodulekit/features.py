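"""Region descriptors: statistical moments, LTP, LOOP and backbone features.

Texture is described by two local patterns computed over 3x3 neighbourhoods:

* LTP (local ternary pattern) compares each of the 8 neighbours to the
  center with a dead zone of half-width ``tau``: a neighbour scores +1 when
  it exceeds the center by at least tau, -1 when it falls below by at least
  tau, 0 inside the dead zone.  The ternary digits are split into the
  conventional *upper* (+1 digits) and *lower* (-1 digits) binary codes;
  the literal signed base-3 sum is also exposed.

* LOOP (local optimal oriented pattern) is a binary code whose bit weights
  are not fixed by position: the exponent of neighbour N is the rank of the
  magnitude of the Kirsch directional response oriented toward N (0 =
  smallest ... 7 = largest, ties broken by neighbour index).  Because the
  Kirsch kernels have zero sum, the code is invariant to adding a constant
  to the window.

The 8-neighbour ordering convention is pinned: n = 0 at the east neighbour,
proceeding counterclockwise (E, NE, N, NW, W, SW, S, SE).

Statistical features are population moments of a region's pixel values,
ordered [mean, kurtosis, skewness, standard deviation, variance]; kurtosis
is non-excess (Gaussian -> 3) and a zero-variance region reports skewness
and kurtosis of 0.

All descriptor computations are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "NEIGHBOR_OFFSETS",
    "KIRSCH_KERNELS",
    "TextureConfig",
    "FeatureVector",
    "statistical_features",
    "ltp_code",
    "loop_code",
    "texture_histogram",
    "FilterBankDescriptor",
    "backbone_features",
    "concat_features",
]

# (row, col) offsets, n = 0 at east, counterclockwise.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def _kirsch_kernels() -> np.ndarray:
    """Eight 3x3 Kirsch compass kernels, kernel n oriented toward neighbour n."""
    east = np.array([[-3, -3, 5],
                     [-3,  0, 5],
                     [-3, -3, 5]], dtype=float)
    # ring order counterclockwise starting east; rotating the ring by one
    # step re-orients the kernel toward the next counterclockwise neighbour
    ring = [(0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0), (0, 1)]
    # map ring positions to neighbour offsets: position (r, c) corresponds
    # to offset (r - 1, c - 1)
    kernels = []
    vals = np.array([east[r, c] for r, c in ring])
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        # rotate the ring values so the '5' column faces neighbour n
        target = ring.index((dr + 1, dc + 1))
        anchor = ring.index((0 + 1, 1 + 1))  # east position
        rolled = np.roll(vals, target - anchor)
        k = np.zeros((3, 3))
        for (r, c), v in zip(ring, rolled):
            k[r, c] = v
        kernels.append(k)
    return np.stack(kernels)


KIRSCH_KERNELS: np.ndarray = _kirsch_kernels()


@dataclass(frozen=True)
class TextureConfig:
    """LTP dead-zone half-width, neighbourhood convention and binning."""

    ltp_threshold: float = 5.0 / 255.0
    histogram_bins: int = 32

    def __post_init__(self) -> None:
        if self.ltp_threshold < 0:
            raise ValueError("ltp_threshold must be >= 0")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")


class LTPCode(NamedTuple):
    digits: np.ndarray   # 8 values in {-1, 0, 1}
    upper: int           # sum over +1 digits of 2^n
    lower: int           # sum over -1 digits of 2^n
    ternary: int         # literal signed sum of digit * 3^n


def statistical_features(region_pixels: np.ndarray) -> np.ndarray:
    """Five population moments of a region, ordered [M, K, S, sigma, nu].

    mean M, kurtosis K = m4/m2^2 (non-excess), skewness S = m3/m2^1.5,
    standard deviation sigma = sqrt(m2), variance nu = m2.  A constant
    region reports K = S = 0 by convention.
    """
    v = np.asarray(region_pixels, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("region too small: need at least 2 pixels")
    mean = v.mean()
    d = v - mean
    m2 = np.mean(d ** 2)
    if m2 == 0.0:
        return np.array([mean, 0.0, 0.0, 0.0, 0.0])
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    return np.array([mean, m4 / m2 ** 2, m3 / m2 ** 1.5, np.sqrt(m2), m2])


def ltp_code(window: np.ndarray, tau: float) -> LTPCode:
    """LTP of a 3x3 window.

    The indicator of the neighbour-center difference A is +1 for A >= tau,
    0 for -tau < A < tau and -1 for A <= -tau (the boundary A = -tau is
    assigned -1 so the three cases partition the line).
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (3, 3):
        raise ValueError("window must be 3x3")
    center = window[1, 1]
    diffs = np.array([window[1 + dr, 1 + dc] - center for dr, dc in NEIGHBOR_OFFSETS])
    digits = np.where(diffs >= tau, 1, np.where(diffs <= -tau, -1, 0))
    powers2 = 1 << np.arange(8)
    powers3 = 3 ** np.arange(8)
    return LTPCode(
        digits=digits,
        upper=int(powers2[digits == 1].sum()),
        lower=int(powers2[digits == -1].sum()),
        ternary=int((digits * powers3).sum()),
    )


def loop_code(window: np.ndarray) -> int:
    """LOOP code of a 3x3 window (0..255).

    Bit for neighbour N is set when its value is >= the center; its weight
    is 2^rank where rank orders the magnitudes of the 8 Kirsch directional
    responses of the window (0 = smallest), ties broken by neighbour index.
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (3, 3):
        raise ValueError("window must be 3x3")
    center = window[1, 1]
    mags = np.abs(np.tensordot(KIRSCH_KERNELS, window, axes=([1, 2], [0, 1])))
    ranks = np.argsort(np.argsort(mags, kind="stable"), kind="stable")
    code = 0
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if window[1 + dr, 1 + dc] - center >= 0:
            code += 1 << int(ranks[n])
    return code


def _shifted(image: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """View of `image` shifted so element (r, c) holds image[r+dr, c+dc]."""
    h, w = image.shape
    out = np.empty((h - 2, w - 2))
    out[:] = image[1 + dr: h - 1 + dr, 1 + dc: w - 1 + dc]
    return out


def _code_images(image: np.ndarray, tau: float) -> dict[str, np.ndarray]:
    """Vectorised LTP-upper/lower and LOOP code images over interior pixels."""
    center = image[1:-1, 1:-1]
    powers = 1 << np.arange(8)
    ltp_upper = np.zeros_like(center, dtype=np.int64)
    ltp_lower = np.zeros_like(center, dtype=np.int64)
    nonneg = np.empty((8,) + center.shape, dtype=bool)
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        diff = _shifted(image, dr, dc) - center
        ltp_upper += powers[n] * (diff >= tau)
        ltp_lower += powers[n] * (diff <= -tau)
        nonneg[n] = diff >= 0
    resp = np.stack([
        ndimage.correlate(image, k, mode="nearest")[1:-1, 1:-1]
        for k in KIRSCH_KERNELS
    ])
    ranks = np.argsort(np.argsort(np.abs(resp), axis=0, kind="stable"),
                       axis=0, kind="stable")
    loop = (nonneg * (1 << ranks.astype(np.int64))).sum(axis=0)
    return {"ltp_upper": ltp_upper, "ltp_lower": ltp_lower, "loop": loop}


def texture_histogram(
    image: np.ndarray,
    mask: np.ndarray,
    kind: str,
    config: TextureConfig | None = None,
) -> np.ndarray:
    """Normalised histogram of texture codes over the in-mask pixels.

    Codes are computed at every masked pixel with a full 3x3 neighbourhood
    inside the image; the 0..255 code range is rebinned to
    ``config.histogram_bins`` equal-width bins and normalised to sum 1.
    A region with no valid pixels yields the all-zero histogram (warning
    logged).
    """
    config = config or TextureConfig()
    if kind not in ("ltp_upper", "ltp_lower", "loop"):
        raise ValueError("kind must be one of ltp_upper, ltp_lower, loop")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) != 0
    if image.shape != mask.shape:
        raise ValueError("incompatible mask: shape differs from image")
    interior = mask[1:-1, 1:-1]
    if not interior.any():
        logger.warning("texture_histogram: no valid in-mask interior pixels")
        return np.zeros(config.histogram_bins)
    codes = _code_images(image, config.ltp_threshold)[kind][interior]
    hist, _ = np.histogram(codes, bins=config.histogram_bins, range=(0, 256))
    return hist / hist.sum()


class FilterBankDescriptor:
    """Handcrafted backbone: multi-scale filter-bank statistics.

    The global descriptor of an image is, for each of four maps (Gaussian
    smooths and gradient magnitudes at two scales), the pair (mean, std),
    followed by a log-area term — 9 numbers.  Per-pixel maps (for the
    FCM fusion) are the same four maps.  Fully deterministic.
    """

    def __init__(self, sigmas: tuple[float, float] = (1.0, 2.0)):
        self.sigmas = tuple(sigmas)

    @property
    def n_features(self) -> int:
        return 4 * len(self.sigmas) + 1

    def pixel_maps(self, image: np.ndarray) -> list[np.ndarray]:
        image = np.asarray(image, dtype=float)
        maps = []
        for s in self.sigmas:
            maps.append(ndimage.gaussian_filter(image, s))
            maps.append(ndimage.gaussian_gradient_magnitude(image, s))
        return maps

    def __call__(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        out = []
        for m in self.pixel_maps(image):
            out.extend([m.mean(), m.std()])
        out.append(np.log1p(image.size) / 10.0)
        return np.array(out)


def backbone_features(image: np.ndarray, extractor=None,
                      expected_length: int | None = None) -> np.ndarray:
    """Fixed-length global descriptor of an image via a pluggable extractor."""
    extractor = extractor if extractor is not None else FilterBankDescriptor()
    vec = np.asarray(extractor(image), dtype=float).ravel()
    expected = expected_length
    if expected is None:
        expected = getattr(extractor, "n_features", None)
    if expected is not None and vec.size != expected:
        raise ValueError(
            f"backbone contract violation: got length {vec.size}, expected {expected}"
        )
    return vec


@dataclass(frozen=True)
class FeatureVector:
    """Concatenation E = [backbone f_R, stats st_R, texture T_R]."""

    backbone: np.ndarray
    stats: np.ndarray
    texture: np.ndarray
    concatenated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concatenated",
            np.concatenate([self.backbone, self.stats, self.texture]),
        )

    def parts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Slice the concatenation back into (backbone, stats, texture)."""
        nb, ns = self.backbone.size, self.stats.size
        E = self.concatenated
        return E[:nb], E[nb:nb + ns], E[nb + ns:]

    def __len__(self) -> int:
        return self.concatenated.size


def concat_features(f_R, st_R, T_R, *, backbone_length: int | None = None,
                    stats_length: int = 5) -> FeatureVector:
    """Assemble the classifier input E = backbone || stats || texture."""
    f_R = np.asarray(f_R, dtype=float).ravel()
    st_R = np.asarray(st_R, dtype=float).ravel()
    T_R = np.asarray(T_R, dtype=float).ravel()
    if backbone_length is not None and f_R.size != backbone_length:
        raise ValueError("length mismatch: backbone part")
    if st_R.size != stats_length:
        raise ValueError("length mismatch: stats part")
    return FeatureVector(backbone=f_R, stats=st_R, texture=T_R)
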