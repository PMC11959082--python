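"""Synthetic CT-phantom generator with ground truth.

Each phantom emulates a single axial chest-CT slice as the detection
pipeline sees it: a bright body/background field, two dark elliptical lung
fields that do not touch the image border, thin bright vessel-like curves
inside the lungs, and quasi-circular bright nodules of known position,
size and label.  Benign nodules are smooth discs below a radius threshold;
malignant nodules are larger with a sinusoidal boundary irregularity —
size plus margin irregularity is the malignancy proxy, so labels are
learnable from the implemented descriptor set.  Ground-truth masks are
recorded before additive Gaussian noise.

Intensities are kept on a [0, 1]-ish scale with the ordering
background > nodule > lung field, which is what the Otsu binarisation and
the brightest-cluster selection downstream rely on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import bezier_curve

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom",
           "generate_samples", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic slices.

    Geometry fields are fractions of the image size; intensities are means
    of the rendered tissue classes before noise.
    """

    image_size: int = 256
    # lung ellipse semi-axes as fractions of image size (vertical, horizontal)
    lung_semi_axis_v: tuple[float, float] = (0.28, 0.33)
    lung_semi_axis_h: tuple[float, float] = (0.13, 0.17)
    lung_center_jitter: float = 0.02
    background_mean: float = 0.85
    lung_mean: float = 0.25
    nodule_mean: float = 0.65
    vessel_mean: float = 0.40
    intensity_jitter: float = 0.02
    noise_sigma: float = 0.03
    nodules_per_image: tuple[int, int] = (1, 1)
    vessels_per_image: tuple[int, int] = (2, 4)
    benign_radius: tuple[float, float] = (3.0, 6.0)
    malignant_radius: tuple[float, float] = (8.0, 12.0)
    radius_threshold: float = 7.0
    irregularity_amplitude: float = 2.0
    irregularity_lobes: tuple[int, int] = (4, 9)
    malignant_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.background_mean > self.nodule_mean > self.lung_mean):
            raise ValueError(
                "intensity ordering background > nodule > lung is required"
            )
        if min(self.benign_radius[0], self.malignant_radius[0]) < 2:
            raise ValueError("nodule radius must be >= 2 px")

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PhantomSample:
    image: np.ndarray
    lung_mask: np.ndarray
    nodule_masks: list[np.ndarray]
    labels: list[str]                      # 'benign' | 'malignant'
    radii: list[float]
    seed: int
    config_digest: str = ""


def _lung_ellipses(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Two elliptical lung fields away from the border."""
    s = config.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    mask = np.zeros((s, s), dtype=bool)
    for cx_frac in (0.30, 0.70):
        cy = s * (0.5 + rng.uniform(-1, 1) * config.lung_center_jitter)
        cx = s * (cx_frac + rng.uniform(-1, 1) * config.lung_center_jitter)
        av = s * rng.uniform(*config.lung_semi_axis_v)
        ah = s * rng.uniform(*config.lung_semi_axis_h)
        mask |= ((yy - cy) / av) ** 2 + ((xx - cx) / ah) ** 2 <= 1.0
    return mask


def _draw_vessels(image: np.ndarray, lung_mask: np.ndarray,
                  config: PhantomConfig, rng: np.random.Generator) -> None:
    """Thin bright curves clipped to the lung fields (in-place)."""
    n = int(rng.integers(config.vessels_per_image[0],
                         config.vessels_per_image[1] + 1))
    coords = np.argwhere(lung_mask)
    if coords.size == 0:
        return
    s = config.image_size
    for _ in range(n):
        p0, p1 = coords[rng.integers(len(coords), size=2)]
        mid = (p0 + p1) / 2 + rng.normal(0, s * 0.05, size=2)
        mid = np.clip(mid, 0, s - 1)
        rr, cc = bezier_curve(int(p0[0]), int(p0[1]), int(mid[0]), int(mid[1]),
                              int(p1[0]), int(p1[1]), weight=1.0,
                              shape=image.shape)
        keep = lung_mask[rr, cc]
        image[rr[keep], cc[keep]] = (
            config.vessel_mean + rng.uniform(-1, 1) * config.intensity_jitter
        )


def _place_nodule(lung_mask: np.ndarray, taken: np.ndarray, radius: float,
                  amplitude: float, rng: np.random.Generator):
    """Center with clearance from the lung boundary and other nodules."""
    clearance = radius + amplitude + 2.0
    edt = ndimage.distance_transform_edt(lung_mask & ~taken)
    candidates = np.argwhere(edt >= clearance)
    if len(candidates) == 0:
        return None
    cy, cx = candidates[rng.integers(len(candidates))]
    return int(cy), int(cx)


def generate_phantom(config: PhantomConfig, seed: int | None = None) -> PhantomSample:
    """Render one slice with ground truth; bit-reproducible from its seed."""
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    n_nod = int(rng.integers(config.nodules_per_image[0],
                             config.nodules_per_image[1] + 1))
    flags = rng.uniform(size=n_nod) < config.malignant_fraction
    return _generate_with_labels(config, seed, flags)


def generate_samples(n: int, config: PhantomConfig,
                     seed: int | None = None) -> list[PhantomSample]:
    """n phantoms with balanced per-nodule labels.

    Labels are assigned from a shuffled, exactly balanced pool (per
    ``malignant_fraction``) rather than independent coin flips, which keeps
    the class share of any dataset of >= 50 nodules within a rounding error
    of the configured ratio.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(base)
    counts = rng.integers(config.nodules_per_image[0],
                          config.nodules_per_image[1] + 1, size=n)
    total = int(counts.sum())
    n_mal = int(round(total * config.malignant_fraction))
    pool = np.array([True] * n_mal + [False] * (total - n_mal))
    rng.shuffle(pool)

    samples = []
    k = 0
    for i in range(n):
        sample_labels = pool[k:k + counts[i]]
        k += counts[i]
        samples.append(
            _generate_with_labels(config, int(base + 1 + i), sample_labels)
        )
    return samples


def _generate_with_labels(config: PhantomConfig, seed: int,
                          malignant_flags: np.ndarray) -> PhantomSample:
    """generate_phantom with the nodule count and labels imposed."""
    rng = np.random.default_rng(seed)
    s = config.image_size
    lung_mask = _lung_ellipses(config, rng)
    image = np.full((s, s), config.background_mean)
    image[lung_mask] = config.lung_mean
    _draw_vessels(image, lung_mask, config, rng)

    yy, xx = np.mgrid[0:s, 0:s]
    nodule_masks, labels, radii = [], [], []
    taken = np.zeros_like(lung_mask)
    for malignant in malignant_flags:
        malignant = bool(malignant)
        lo, hi = (config.malignant_radius if malignant else config.benign_radius)
        radius = float(rng.uniform(lo, hi))
        amp = config.irregularity_amplitude if malignant else 0.0
        center = _place_nodule(lung_mask, taken, radius, amp, rng)
        if center is None:
            raise RuntimeError("infeasible geometry: nodule cannot fit in lung field")
        cy, cx = center
        dist = np.hypot(yy - cy, xx - cx)
        if malignant:
            k = int(rng.integers(config.irregularity_lobes[0],
                                 config.irregularity_lobes[1] + 1))
            phase = rng.uniform(0, 2 * np.pi)
            theta = np.arctan2(yy - cy, xx - cx)
            boundary = radius + amp * np.sin(k * theta + phase)
        else:
            boundary = radius
        nod = (dist <= boundary) & lung_mask
        nodule_masks.append(nod.astype(np.uint8))
        labels.append("malignant" if malignant else "benign")
        radii.append(radius)
        image[nod] = config.nodule_mean + rng.uniform(-1, 1) * config.intensity_jitter
        taken |= ndimage.binary_dilation(nod, iterations=3)

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    return PhantomSample(image=image, lung_mask=lung_mask.astype(np.uint8),
                         nodule_masks=nodule_masks, labels=labels, radii=radii,
                         seed=seed, config_digest=config.digest())


def generate_dataset(n: int, config: PhantomConfig, seed: int,
                     out_dir) -> "pandas.DataFrame":
    """Write n phantoms (PNG images/masks) and a per-nodule manifest.csv."""
    import pandas as pd

    from .io import write_image, write_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, config, seed)
    rows = []
    for i, sample in enumerate(samples):
        img_path = out_dir / f"phantom_{i:04d}.png"
        lung_path = out_dir / f"phantom_{i:04d}_lung.png"
        write_image(img_path, sample.image, vmax=1.2)
        write_mask(lung_path, sample.lung_mask)
        for j, (nod, label, radius) in enumerate(
            zip(sample.nodule_masks, sample.labels, sample.radii)
        ):
            nod_path = out_dir / f"phantom_{i:04d}_nodule_{j}.png"
            write_mask(nod_path, nod)
            rows.append({
                "image": img_path.name,
                "lung_mask": lung_path.name,
                "nodule_mask": nod_path.name,
                "label": label,
                "radius": round(radius, 3),
                "seed": sample.seed,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
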