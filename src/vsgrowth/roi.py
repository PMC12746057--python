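"""Image normalisation and tumour-ROI conditioning.

The region of interest used for parameter-map radiomics is the structural
tumour annotation with cystic components removed (cysts lack cellularity
and microvascularity) and a morphological erosion applied to guard against
partial-volume contamination at the tumour rim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["RoiMask", "zscore_normalize", "remove_cysts", "erode_cross",
           "project_mask"]

# 3x3 in-plane 4-connected cross structuring element
_CROSS_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class RoiMask:
    """Binary ROI with voxel spacing (mm) and a provenance tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = "raw"

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if not np.isin(d, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "data", d.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def zscore_normalize(image, reference_region=None):
    """Z-score normalise an image over a reference region.

    The reference defaults to the nonzero support of the image.  The output
    has mean 0 and SD 1 over the reference; an affine intensity change of
    the input leaves the output unchanged.
    """
    img = np.asarray(image, dtype=float)
    if reference_region is None:
        ref = img != 0
    else:
        ref = np.asarray(reference_region, dtype=bool)
        if ref.shape != img.shape:
            raise ValueError("reference region shape must match image")
    vals = img[ref]
    if vals.size < 2:
        raise ValueError("reference region must contain > 1 voxel")
    sd = vals.std()
    if sd == 0:
        raise ValueError("reference region has zero variance")
    return (img - vals.mean()) / sd


def remove_cysts(roi: RoiMask, cysts: RoiMask) -> RoiMask:
    """Set difference roi \\ cysts; degenerate (empty) results are allowed
    but tagged so callers can exclude the patient."""
    if roi.data.shape != cysts.data.shape or roi.spacing != cysts.spacing:
        raise ValueError("ROI and cyst masks must share the same grid")
    out = roi.data & ~cysts.data
    provenance = "cyst_removed" if out.any() else "cyst_removed_degenerate"
    return replace(roi, data=out, provenance=provenance)


def erode_cross(roi: RoiMask, mode: str = "2d") -> RoiMask:
    """Erode the mask with a 3x3 cross-shaped structuring element.

    ``mode='2d'`` (default) erodes slice-wise in-plane along the last axis,
    matching the anisotropic partial-volume geometry of dynamic imaging;
    ``mode='3d'`` uses the 6-connected 3D cross.
    """
    if mode == "2d":
        out = np.zeros_like(roi.data)
        for k in range(roi.data.shape[2]):
            out[:, :, k] = ndimage.binary_erosion(roi.data[:, :, k], _CROSS_2D)
    elif mode == "3d":
        out = ndimage.binary_erosion(roi.data,
                                     ndimage.generate_binary_structure(3, 1))
    else:
        raise ValueError(f"unknown erosion mode {mode!r}")
    return replace(roi, data=out, provenance="eroded")


def project_mask(roi: RoiMask, target_shape, target_spacing,
                 source_origin=(0.0, 0.0, 0.0),
                 target_origin=(0.0, 0.0, 0.0)) -> RoiMask:
    """Nearest-neighbour resampling of a mask onto an axis-aligned target grid.

    Both grids are described by shape, spacing (mm) and world origin of the
    voxel-centre at index 0; orientation is assumed axis-aligned (rotation
    is out of scope — the transform is consumed, not estimated).  Identity
    when the grids match.
    """
    target_shape = tuple(int(s) for s in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if (roi.data.shape == target_shape and roi.spacing == target_spacing
            and tuple(source_origin) == tuple(target_origin)):
        return roi
    out = np.zeros(target_shape, dtype=bool)
    idx = [np.arange(n) for n in target_shape]
    # world coordinate of each target voxel centre, per axis
    src_idx = []
    for ax in range(3):
        world = target_origin[ax] + idx[ax] * target_spacing[ax]
        j = np.rint((world - source_origin[ax]) / roi.spacing[ax]).astype(int)
        src_idx.append(j)
    ii, jj, kk = np.meshgrid(*src_idx, indexing="ij")
    valid = np.ones(target_shape, dtype=bool)
    for arr, n in zip((ii, jj, kk), roi.data.shape):
        valid &= (arr >= 0) & (arr < n)
    out[valid] = roi.data[ii[valid], jj[valid], kk[valid]]
    return RoiMask(out, spacing=target_spacing, provenance=roi.provenance)
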