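"""Geometric standardization and multi-scale intensity harmonization.

Volumes from different scanners are brought onto a common grid (resampling
to a uniform physical spacing, cropping to the tight in-plane bounding box
of nonzero intensity, zero-padding to a fixed frame) and onto a common
intensity scale: the image is smoothed with a bank of Gaussian kernels
(sigma = 0 keeps the original), each smoothed version is z-scored and
rescaled to the matching moments of a smoothed reference scan,

    I_tilde(k) = (I(k) - mu(k)) / sd(k) * sd_ref(k) + mu_ref(k),

and the harmonized image is the sum over scales.  Matching moments at
several smoothing scales aligns both the global intensity scale and the
slowly varying shading between scanners.

Axis convention throughout the package: arrays are indexed (x, y, z) with
0-based indices; spacing is mm per voxel along (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import nibabel as nib
from scipy import ndimage

__all__ = [
    "Volume",
    "HarmonizationSpec",
    "GeometrySpec",
    "DegenerateInputError",
    "SizeExceededError",
    "gaussian_smooth",
    "harmonization_spec",
    "harmonize",
    "resample",
    "crop_and_pad",
    "load_volume",
    "save_volume",
    "DEFAULT_SIGMAS",
    "DEFAULT_SPACING",
]

DEFAULT_SIGMAS = (0.0, 2.0, 4.0, 6.0)       # voxel units, on the resampled grid
DEFAULT_SPACING = (0.47, 0.47, 6.5)          # mm


class DegenerateInputError(ValueError):
    """A constant image cannot be matched to a reference with spread."""


class SizeExceededError(ValueError):
    """Content bounding box larger than the requested padded frame."""


@dataclass
class Volume:
    """A 3-D intensity grid with physical voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin_note: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise ValueError(f"volume grid must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class HarmonizationSpec:
    """Gaussian scales and per-scale reference moments."""

    sigmas: tuple[float, ...]
    reference_stats: tuple[tuple[float, float], ...]

    def __post_init__(self):
        self.sigmas = tuple(float(s) for s in self.sigmas)
        self.reference_stats = tuple(
            (float(m), float(s)) for m, s in self.reference_stats
        )
        if not self.sigmas or self.sigmas[0] != 0.0:
            raise ValueError("sigmas must start with 0 (the non-smoothed image)")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("sigmas must be non-negative")
        if len(self.reference_stats) != len(self.sigmas):
            raise ValueError("need one (mean, sd) pair per sigma")
        if any(sd < 0 for _, sd in self.reference_stats):
            raise ValueError("reference standard deviations must be >= 0")


@dataclass
class GeometrySpec:
    """Target spacing and padded frame for geometric standardization."""

    target_spacing: tuple[float, float, float] = DEFAULT_SPACING
    pad_shape: tuple[int, int, int] = (320, 320, 1)
    pad_value: float = 0.0

    def __post_init__(self):
        self.target_spacing = tuple(float(s) for s in self.target_spacing)
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target spacing must be strictly positive")
        self.pad_shape = tuple(int(s) for s in self.pad_shape)
        if any(s < 1 for s in self.pad_shape):
            raise ValueError("pad_shape components must be >= 1")


# ---------------------------------------------------------------------------
# Operations


def gaussian_smooth(vol: Volume, sigma: float) -> Volume:
    """Separable Gaussian smoothing; sigma in voxels, reflect boundaries."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return Volume(vol.data.astype(float).copy(), vol.spacing, vol.origin_note)
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma, mode="reflect")
    return Volume(out, vol.spacing, vol.origin_note)


def harmonization_spec(
    reference: Volume, sigmas=DEFAULT_SIGMAS
) -> HarmonizationSpec:
    """Build a spec from a reference scan: per-scale whole-grid moments."""
    stats = []
    for s in sigmas:
        sm = gaussian_smooth(reference, s).data
        stats.append((float(sm.mean()), float(sm.std())))
    return HarmonizationSpec(tuple(sigmas), tuple(stats))


def harmonize(vol: Volume, spec: HarmonizationSpec) -> Volume:
    """Sum of per-scale moment-matched smoothed images."""
    out = np.zeros(vol.shape, dtype=float)
    for sigma, (mu_ref, sd_ref) in zip(spec.sigmas, spec.reference_stats):
        sm = gaussian_smooth(vol, sigma).data
        mu, sd = sm.mean(), sm.std()
        if sd <= 0:
            if sd_ref > 0:
                raise DegenerateInputError(
                    f"zero intensity variance at scale sigma={sigma}"
                )
            out += mu_ref
            continue
        out += (sm - mu) / sd * sd_ref + mu_ref
    return Volume(out, vol.spacing, vol.origin_note)


def resample(vol: Volume, geo: GeometrySpec, is_label: bool = False) -> Volume:
    """Resample to uniform physical spacing.

    Trilinear interpolation for intensities, nearest-neighbor for labels;
    output shape is ``round(shape * spacing / target)`` with a floor of 1.
    """
    target = geo.target_spacing
    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vol.shape, vol.spacing, target)
    )
    if new_shape == vol.shape and target == vol.spacing:
        return Volume(vol.data.copy(), target, vol.origin_note)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.data.transpose(2, 1, 0).astype(float))
    )
    img.SetSpacing(vol.spacing)
    interp = sitk.sitkNearestNeighbor if is_label else sitk.sitkLinear
    res = sitk.Resample(
        img,
        tuple(int(n) for n in new_shape),
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        target,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    out = sitk.GetArrayFromImage(res).transpose(2, 1, 0)
    if is_label:
        out = np.rint(out).astype(vol.data.dtype)
    return Volume(out, target, vol.origin_note)


def crop_and_pad(vol: Volume, geo: GeometrySpec) -> Volume:
    """Crop in-plane to the nonzero bounding box, then pad to the frame.

    Padding is symmetric with the odd voxel on the high-index side; an
    all-zero volume keeps its full extent (no content to crop to).
    """
    data = vol.data
    nz = np.nonzero(data)
    if nz[0].size == 0:
        cropped = data
    else:
        x0, x1 = nz[0].min(), nz[0].max() + 1
        y0, y1 = nz[1].min(), nz[1].max() + 1
        cropped = data[x0:x1, y0:y1, :]
    pads = []
    for axis, target in enumerate(geo.pad_shape):
        cur = cropped.shape[axis]
        if cur > target:
            raise SizeExceededError(
                f"content extent {cur} exceeds pad_shape[{axis}] = {target}"
            )
        total = target - cur
        pads.append((total // 2, total - total // 2))
    out = np.pad(cropped, pads, constant_values=geo.pad_value)
    return Volume(out, vol.spacing, vol.origin_note)


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; spacing from the header, axes (x, y, z)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(float)
    if data.ndim > 3:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, origin_note=Path(path).name)


def save_volume(vol: Volume, path: str | Path, labels: bool = False) -> None:
    """Write NIfTI-1; labels as unsigned 8-bit, intensities as float32."""
    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data.astype(np.uint8 if labels else np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))
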