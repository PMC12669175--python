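"""Reproducible 3-D lesion phantoms emulating the target imaging regime.

Each phantom is an anisotropic single-channel volume (default spacing
0.47 x 0.47 x 6.5 mm, thick slices) holding an ellipsoidal "brain" support
with a smooth random-field texture, a small number of bright compact
lesions placed near the support boundary (the leptomeningeal location),
additive Gaussian noise, and a per-"scanner" affine intensity perturbation
(gain/offset) applied last.  The exact lesion voxels form the ground-truth
mask, so foreground occupies well under 5% of the grid — the class
imbalance the segmentation objective has to cope with.

An optional bright stripe along the support boundary reproduces the
characteristic false-positive distractor of real contrast-enhanced scans
(non-lesion tissue interfaces that look lesion-bright).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess_harmonize import Volume, save_volume

__all__ = [
    "PhantomSpec",
    "ScannerProfile",
    "PlacementError",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_PROFILES",
]


class PlacementError(RuntimeError):
    """Could not place a lesion inside the support after bounded retries."""


@dataclass
class ScannerProfile:
    """Per-scanner affine intensity perturbation."""

    name: str = "ref"
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 4.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (0.47, 0.47, 6.5)
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)   # mm
    lesion_contrast: float = 1.8
    background_texture: float = 0.12      # relative amplitude of the field
    base_intensity: float = 100.0
    boundary_stripe: bool = False         # bright non-lesion distractor
    scanner: ScannerProfile = field(default_factory=ScannerProfile)
    seed: int = 0

    def __post_init__(self):
        if self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must exceed 1")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


# four profiles emulating a heterogeneous multi-scanner cohort
DEFAULT_PROFILES = [
    ScannerProfile("scanner-A", 1.00, 0.0, 4.0),
    ScannerProfile("scanner-B", 1.35, 18.0, 6.0),
    ScannerProfile("scanner-C", 0.72, -12.0, 3.0),
    ScannerProfile("scanner-D", 1.15, 30.0, 5.0),
]


def _ellipsoid_mask(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox)
    )
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """One (intensity volume, binary label volume) pair, fully seeded."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing)

    # ellipsoidal brain support with a smooth multiplicative texture
    center = np.array([(s - 1) / 2 for s in shape])
    support_radii = np.array([0.42 * s for s in shape])
    support = _ellipsoid_mask(shape, center, support_radii)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), (6, 6, 1))
    texture /= max(np.abs(texture).max(), 1e-12)
    background = spec.base_intensity * (1.0 + spec.background_texture * texture)
    clean = np.where(support, background, 0.0)

    if spec.boundary_stripe:
        inner = _ellipsoid_mask(shape, center, support_radii * 0.92)
        stripe = support & ~inner
        clean[stripe] *= spec.lesion_contrast

    # lesions: bright ellipsoids near the support boundary
    mask = np.zeros(shape, dtype=np.uint8)
    placed = 0
    attempts = 0
    while placed < spec.n_lesions:
        attempts += 1
        if attempts > 200 * max(spec.n_lesions, 1):
            raise PlacementError(
                f"placed {placed}/{spec.n_lesions} lesions after {attempts} tries"
            )
        r_mm = rng.uniform(*spec.lesion_radius_range)
        radii_vox = np.maximum(r_mm / spacing, 0.51)
        # radial placement at 60-85% of the support radius, random direction
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        frac = rng.uniform(0.60, 0.85)
        pos = center + direction * frac * support_radii
        pos[2] = np.clip(np.round(pos[2]), 1, shape[2] - 2)  # slice-centred in z
        lesion = _ellipsoid_mask(shape, pos, radii_vox)
        if not lesion.any():
            continue
        if not support[tuple(np.clip(np.round(pos).astype(int), 0,
                                     np.array(shape) - 1))]:
            continue
        lesion &= support
        if not lesion.any() or (mask[lesion] > 0).any():
            continue
        clean[lesion] *= spec.lesion_contrast
        mask[lesion] = 1
        placed += 1

    noisy = clean + rng.normal(0.0, spec.scanner.noise_sd, shape) * support
    data = spec.scanner.gain * noisy + spec.scanner.offset * support
    note = f"phantom(seed={spec.seed},scanner={spec.scanner.name})"
    return (
        Volume(data, spec.spacing, note),
        Volume(mask, spec.spacing, note + ":labels"),
    )


def generate_cohort(
    n: int,
    template: PhantomSpec,
    profiles: list[ScannerProfile] | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> list[tuple[Volume, Volume, ScannerProfile]]:
    """Generate ``n`` phantoms with round-robin scanner assignment.

    With ``out_dir`` set, each subject is written as
    ``sub-XX.nii.gz`` / ``sub-XX_mask.nii.gz`` plus a JSON sidecar holding
    the seed and scanner profile.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    profiles = profiles or DEFAULT_PROFILES
    base_seed = template.seed if seed is None else seed
    out = []
    for i in range(n):
        prof = profiles[i % len(profiles)]
        spec = PhantomSpec(
            **{
                **asdict(template),
                "scanner": prof,
                "seed": int(base_seed + i),
            }
        )
        vol, mask = generate_phantom(spec)
        out.append((vol, mask, prof))
        if out_dir is not None:
            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            try:
                save_volume(vol, d / f"sub-{i:02d}.nii.gz")
                save_volume(mask, d / f"sub-{i:02d}_mask.nii.gz", labels=True)
                (d / f"sub-{i:02d}.json").write_text(
                    json.dumps(
                        {"seed": spec.seed, "scanner": asdict(prof)}, indent=2
                    )
                )
            except OSError as e:
                raise OSError(f"failed writing subject {i} under {d}: {e}") from e
    return out
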