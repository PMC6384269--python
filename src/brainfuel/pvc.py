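"""MR-based partial-volume correction (Müller-Gärtner).

PET resolution (point-spread FWHM of several mm) mixes signal between
grey matter, white matter and CSF.  The Müller-Gärtner correction uses
the MR tissue segmentation to undo this at grey-matter voxels:

    corrected(v) = (pet(v) - WMref * smooth(wm)(v)) / smooth(gm)(v)

where ``smooth`` is convolution with the scanner point-spread function,
``WMref`` is the (assumed homogeneous) white-matter activity, and CSF is
assumed activity-free.  Voxels with grey-matter probability below a
threshold are marked missing (NaN) rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PointSpreadModel",
    "TissueMaps",
    "apply_psf",
    "mg_correct",
    "estimate_wm_reference",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class PointSpreadModel:
    """Isotropic Gaussian scanner point-spread function.

    fwhm = 0 means the identity (no blurring).  The default 6 mm is
    typical for whole-body TOF PET systems of this class.
    """

    fwhm: float = 6.0

    def __post_init__(self) -> None:
        if self.fwhm < 0:
            raise ValueError("fwhm must be non-negative")

    def sigma_voxels(self, voxel_size: float) -> float:
        if voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        return self.fwhm * _FWHM_TO_SIGMA / voxel_size


@dataclass
class TissueMaps:
    """Grey/white-matter probability maps plus the MG parameters."""

    gm_map: np.ndarray
    wm_map: np.ndarray
    wm_reference_value: float | None = None
    gm_threshold: float = 0.3

    def __post_init__(self) -> None:
        self.gm_map = np.asarray(self.gm_map, dtype=float)
        self.wm_map = np.asarray(self.wm_map, dtype=float)
        if self.gm_map.shape != self.wm_map.shape:
            raise ValueError("gm and wm maps must share a grid")
        for m in (self.gm_map, self.wm_map):
            if np.any((m < 0) | (m > 1)):
                raise ValueError("tissue probabilities must lie in [0, 1]")
        if not 0.0 < self.gm_threshold < 1.0:
            raise ValueError("gm_threshold must lie in (0, 1)")


def apply_psf(image: np.ndarray, psf: PointSpreadModel, voxel_size: float) -> np.ndarray:
    """Gaussian blur with kernel SD = fwhm/2.3548 per axis.

    Edge-value ('nearest') padding keeps total counts conserved for
    structures away from the grid boundary.
    """
    image = np.asarray(image, dtype=float)
    if psf.fwhm == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=psf.sigma_voxels(voxel_size), mode="nearest")


def mg_correct(
    pet: np.ndarray,
    maps: TissueMaps,
    psf: PointSpreadModel,
    voxel_size: float,
) -> np.ndarray:
    """Müller-Gärtner-corrected grey-matter activity image.

    Returns an image that equals the corrected GM activity at voxels
    with gm probability >= ``maps.gm_threshold`` and NaN elsewhere
    (including retained voxels where the smoothed GM map vanishes,
    which are flagged missing rather than divided by zero).
    """
    pet = np.asarray(pet, dtype=float)
    if pet.shape != maps.gm_map.shape:
        raise ValueError("PET grid does not match tissue maps")
    wm_ref = maps.wm_reference_value
    if wm_ref is None:
        wm_ref = estimate_wm_reference(pet, maps, psf, voxel_size)
    gm_s = apply_psf(maps.gm_map, psf, voxel_size)
    wm_s = apply_psf(maps.wm_map, psf, voxel_size)
    out = np.full_like(pet, np.nan)
    keep = maps.gm_map >= maps.gm_threshold
    ok = keep & (gm_s > 1e-6)
    out[ok] = (pet[ok] - wm_ref * wm_s[ok]) / gm_s[ok]
    return out


def estimate_wm_reference(
    pet: np.ndarray,
    maps: TissueMaps,
    psf: PointSpreadModel | None = None,
    voxel_size: float = 1.0,
) -> float:
    """White-matter reference activity: mean PET value over deep WM.

    Deep WM is the wm-probability >= 0.95 region after one erosion with
    a ball whose radius matches the PSF width (two kernel SDs, at least
    one voxel), so the retained voxels sit beyond the grey-matter
    spill-in range.  If that erosion empties the mask the radius is
    shrunk until voxels remain; with no qualifying voxels at all a
    ValueError is raised.
    """
    pet = np.asarray(pet, dtype=float)
    base = maps.wm_map >= 0.95
    if not base.any():
        raise ValueError("no deep white-matter voxels (wm >= 0.95)")
    radius = 1
    if psf is not None and psf.fwhm > 0:
        radius = max(1, int(np.ceil(2.0 * psf.sigma_voxels(voxel_size))))
    for r in range(radius, 0, -1):
        grid = np.indices((2 * r + 1,) * base.ndim) - r
        structure = (grid**2).sum(axis=0) <= r**2
        core = ndimage.binary_erosion(base, structure=structure)
        if core.any():
            return float(pet[core].mean())
    raise ValueError("white-matter mask vanishes under erosion; too thin for the PSF")
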