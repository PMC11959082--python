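"""Reading and writing grayscale slices and binary masks (PNG and NIfTI)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_image(path) -> np.ndarray:
    """Read a 2-D grayscale image as float64.

    PNG (8- or 16-bit, rescaled to [0, 1]) and NIfTI (``.nii``/``.nii.gz``,
    first axis taken as the slice axis; single-slice volumes are squeezed)
    are supported.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if data.ndim == 3:
            data = data[0] if data.shape[0] == 1 else data[0]
        if data.ndim != 2:
            raise ValueError(f"expected a 2-D slice, got shape {data.shape}")
        return data
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr


def write_image(path, image: np.ndarray, *, vmax: float | None = None) -> None:
    """Write a 2-D float image as 16-bit grayscale PNG or as NIfTI."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if str(path).endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(image[None].astype(np.float32), np.eye(4)), str(path))
        return
    import imageio.v3 as iio

    scale = vmax if vmax is not None else max(float(image.max()), 1e-12)
    arr = np.clip(image / scale, 0.0, 1.0)
    iio.imwrite(path, (arr * 65535).round().astype(np.uint16))


def read_mask(path) -> np.ndarray:
    """Read a binary mask; any nonzero pixel counts as foreground."""
    return (read_image(path) > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 0/255 8-bit PNG (or NIfTI)."""
    path = Path(path)
    mask = np.asarray(mask).astype(bool)
    if str(path).endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask[None].astype(np.uint8), np.eye(4)), str(path))
        return
    import imageio.v3 as iio

    iio.imwrite(path, (mask * np.uint8(255)))
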