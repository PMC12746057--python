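"""Radiomic feature extraction over a tumour ROI.

Implements fixed-bin-width gray-level discretization and the 101-feature
bank used throughout the pipeline: 18 first-order, 8 shape, 24 GLCM,
16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM features, following the Image
Biomarker Standardisation Initiative definitions (GLDM, which IBSI does
not standardise, follows the common reference-implementation convention).
Applied to the four channels (T2, K^trans, v_e, v_p) this yields a
404-element named vector per patient.

Conventions that matter for comparability:

* Discretization is min-anchored: ``level = floor((x - min_ROI)/width) + 1``
  with no clipping of extremes, so all features are invariant to intensity
  shifts.
* Texture matrices use the 13 unique 3D directions at distance 1; GLCM and
  GLRLM features are computed per direction and averaged.
* The gray-level axis spans 1..max occupied level (empty levels carry zero
  mass); normalised inverse-difference features use that axis length.
* Dependence size in the GLDM is the count of 26-neighbours equal to the
  centre (tolerance ``alpha``); emphasis weights use ``j = size + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscretizationRule", "fit_bin_widths", "discretize",
    "first_order_features", "shape_features", "glcm_features",
    "glrlm_features", "glszm_features", "ngtdm_features", "gldm_features",
    "extract_vector", "feature_names", "CHANNELS", "FAMILY_COUNTS",
]

_EPS = np.finfo(float).tiny

CHANNELS = ("t2", "ktrans", "ve", "vp")

FIRST_ORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
SHAPE_NAMES = (
    "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "Maximum3DDiameter", "MajorAxisLength", "Elongation", "Flatness",
)
GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
    "JointEntropy", "MaximumProbability", "MCC", "SumAverage",
    "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast",
               "Strength")
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

FAMILIES = (
    ("firstorder", FIRST_ORDER_NAMES),
    ("shape", SHAPE_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
    ("gldm", GLDM_NAMES),
)
FAMILY_COUNTS = {fam: len(names) for fam, names in FAMILIES}

# 13 unique 3D directions at Chebyshev distance 1 (first nonzero positive)
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0),
    (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
)
_OFFSETS_26 = tuple(
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)


def feature_names(channels=CHANNELS) -> list[str]:
    """The frozen 404-name manifest, ordered channel-major then family."""
    return [f"{ch}_{fam}_{name}"
            for ch in channels for fam, names in FAMILIES for name in names]


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationRule:
    """Per-channel fixed bin widths derived from a training set.

    ``width = (mean over training patients of ROI intensity range) / n_bins``
    so the effective number of levels is about ``n_bins`` for a typical
    patient while extreme patients keep their full range (no clipping).
    """

    n_bins: int
    widths: dict[str, float]
    mean_ranges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if any(w <= 0 for w in self.widths.values()):
            raise ValueError("bin widths must be positive")


def fit_bin_widths(roi_values_by_channel, n_bins: int) -> DiscretizationRule:
    """Fit per-channel bin widths on training-set ROI intensities.

    Parameters
    ----------
    roi_values_by_channel : mapping channel -> sequence of 1D arrays, one
        array of in-ROI voxel values per training patient.
    n_bins : the bin-count scaling hyper-parameter.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    widths, mean_ranges = {}, {}
    for channel, value_lists in roi_values_by_channel.items():
        ranges = []
        for vals in value_lists:
            vals = np.asarray(vals, dtype=float)
            if vals.size == 0:
                warnings.warn(f"empty ROI skipped while fitting widths "
                              f"({channel})")
                continue
            ranges.append(float(vals.max() - vals.min()))
        if not ranges:
            raise ValueError(f"no usable training ROIs for channel {channel}")
        mean_range = float(np.mean(ranges))
        if mean_range <= 0:
            raise ValueError(f"nonpositive mean intensity range for channel "
                             f"{channel}")
        mean_ranges[channel] = mean_range
        widths[channel] = mean_range / n_bins
    return DiscretizationRule(n_bins=n_bins, widths=widths,
                              mean_ranges=mean_ranges)


def discretize(image, mask, width: float) -> np.ndarray:
    """Min-anchored fixed-bin-width discretization of the ROI.

    Returns an integer volume with levels >= 1 inside the mask and 0
    outside.  Extremes are never clipped.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(img.shape, dtype=np.int64)
    vals = img[mask]
    if vals.size == 0:
        return out
    levels = np.floor((vals - vals.min()) / width).astype(np.int64) + 1
    out[mask] = levels
    return out


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def first_order_features(values, discretized_values, voxel_volume=1.0) -> dict:
    """The 18 first-order statistics of the in-ROI intensities.

    ``discretized_values`` (integer levels of the same voxels) feed the
    histogram-based Entropy and Uniformity; everything else uses the raw
    values.  Variance and moments are population (biased) statistics and
    Kurtosis is not excess-corrected.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first-order features require >= 1 voxel")
    d = np.asarray(discretized_values).ravel()
    counts = np.bincount(d)[1:]
    p = counts[counts > 0] / x.size

    mean = x.mean()
    m2 = np.mean((x - mean) ** 2)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation":
            float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(np.mean((x - mean) ** 3) / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(np.mean((x - mean) ** 4) / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
    return out


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

#: Gaussian pre-smoothing (voxels) of the binary indicator before meshing;
#: suppresses marching-cubes staircase inflation of the surface area.
_MESH_SMOOTHING_SIGMA = 0.7


def _mesh(mask, spacing):
    from skimage import measure

    padded = np.pad(mask.astype(float), 2)
    if _MESH_SMOOTHING_SIGMA > 0:
        smoothed = ndimage.gaussian_filter(padded, _MESH_SMOOTHING_SIGMA)
        # tiny masks can smooth entirely below the iso-level
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    volume = float(abs(np.sum(np.einsum("ij,ij->i", tri[:, 0],
                                        np.cross(tri[:, 1], tri[:, 2])))) / 6.0)
    return verts, area, volume


def shape_features(mask, spacing=(1.0, 1.0, 1.0)) -> dict:
    """Eight 3D shape descriptors of the binary ROI.

    Volume is the voxel-count volume; surface area, mesh volume (used
    inside sphericity) come from a marching-cubes mesh of the mask;
    axis lengths from the principal components of voxel-centre
    coordinates.  Shape is intensity-free and therefore identical across
    channels of the same patient.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("shape features require a nonempty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))
    volume = n * voxel_volume

    verts, area, mesh_volume = _mesh(mask, spacing)
    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area

    # maximum 3D diameter over convex-hull vertices of the surface mesh
    from scipy.spatial import ConvexHull

    if len(verts) > 3:
        try:
            hull_pts = verts[ConvexHull(verts).vertices]
        except Exception:  # degenerate (flat) geometry
            hull_pts = verts
    else:
        hull_pts = verts
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_diam = float(np.sqrt((diffs**2).sum(-1)).max())

    coords = np.argwhere(mask) * np.asarray(spacing)
    if n > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major = 4.0 * np.sqrt(eig[0])
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max_diam,
        "MajorAxisLength": float(major),
        "Elongation": elongation,
        "Flatness": flatness,
    }


# ---------------------------------------------------------------------------
# Texture-matrix helpers
# ---------------------------------------------------------------------------

def _offset_slices(shape, d):
    """Slices (a, b) such that arr[a] and arr[b] are offset by d."""
    a, b = [], []
    for ax in range(3):
        if d[ax] > 0:
            a.append(slice(0, shape[ax] - d[ax]))
            b.append(slice(d[ax], shape[ax]))
        elif d[ax] < 0:
            a.append(slice(-d[ax], shape[ax]))
            b.append(slice(0, shape[ax] + d[ax]))
        else:
            a.append(slice(None))
            b.append(slice(None))
    return tuple(a), tuple(b)


def _shift(arr, d, fill=0):
    """Value of arr at v - d (i.e. arr shifted by +d), ``fill`` off-grid."""
    out = np.full_like(arr, fill)
    a, b = _offset_slices(arr.shape, d)
    out[b] = arr[a]
    return out


def _safe_log2(p):
    return np.log2(np.where(p > 0, p, 1.0))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_single(levels, ng, d):
    """Symmetric normalised co-occurrence matrix for one direction, or None
    if the direction produces no valid pair."""
    a, b = _offset_slices(levels.shape, d)
    la, lb = levels[a], levels[b]
    valid = (la > 0) & (lb > 0)
    if not valid.any():
        return None
    pairs = np.bincount((la[valid] - 1) * ng + (lb[valid] - 1),
                        minlength=ng * ng).reshape(ng, ng).astype(float)
    pairs = pairs + pairs.T
    return pairs / pairs.sum()


def glcm_features(discretized, mask) -> dict:
    """Direction-averaged 3D GLCM features (13 directions, distance 1).

    Features are computed per direction on the symmetric normalised matrix
    and averaged; directions yielding no valid pair are skipped."""
    levels = np.asarray(discretized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("GLCM requires >= 2 voxels")
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    mats = [m for d in DIRECTIONS_13
            if (m := _glcm_single(levels, ng, d)) is not None]
    if not mats:
        raise ValueError("no voxel pairs in any direction")
    P = np.stack(mats)  # (nd, ng, ng)
    nd = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    absdiff = np.abs(ii - jj)
    offdiag = absdiff > 0

    px = P.sum(axis=2)  # (nd, ng); equals py by symmetry
    ux = (i * px).sum(axis=1)  # (nd,)
    sigx2 = (((i[None, :] - ux[:, None]) ** 2) * px).sum(axis=1)

    idx_sum = (ii + jj).astype(int).ravel() - 2
    idx_diff = absdiff.astype(int).ravel()
    rows = np.repeat(np.arange(nd), ng * ng)
    psum = np.zeros((nd, 2 * ng - 1))
    pdiff = np.zeros((nd, ng))
    np.add.at(psum, (rows, np.tile(idx_sum, nd)), P.reshape(nd, -1).ravel())
    np.add.at(pdiff, (rows, np.tile(idx_diff, nd)), P.reshape(nd, -1).ravel())
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    kdiff = np.arange(0, ng, dtype=float)

    autoc = (ii * jj * P).sum(axis=(1, 2))
    correlation = np.where(sigx2 > 0,
                           (autoc - ux * ux) / np.where(sigx2 > 0, sigx2, 1.0),
                           1.0)  # single-level convention
    da = (kdiff * pdiff).sum(axis=1)
    joint_entropy = -(P * _safe_log2(P)).sum(axis=(1, 2))
    hx = -(px * _safe_log2(px)).sum(axis=1)
    pxy = px[:, :, None] * px[:, None, :]
    hxy1 = -(P * _safe_log2(pxy)).sum(axis=(1, 2))
    hxy2 = -(pxy * _safe_log2(pxy)).sum(axis=(1, 2))
    imc1 = np.where(hx > 0, (joint_entropy - hxy1) / np.where(hx > 0, hx, 1.0),
                    0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)),
                           0.0, None))

    mcc = np.empty(nd)
    for a in range(nd):
        occ = px[a] > 0
        if occ.sum() > 1:
            psub = P[a][np.ix_(occ, occ)]
            pxs = px[a][occ]
            q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
            eigs = np.sort(np.abs(np.linalg.eigvals(q)))
            mcc[a] = np.sqrt(max(0.0, min(eigs[-2], 1.0)))
        else:
            mcc[a] = 1.0

    cplus = ii + jj
    dev = cplus[None, :, :] - 2.0 * ux[:, None, None]
    inv_var = (P * np.where(offdiag, 1.0 / np.where(offdiag, absdiff, 1.0) ** 2,
                            0.0)).sum(axis=(1, 2))
    vals = {
        "Autocorrelation": autoc,
        "ClusterProminence": (dev**4 * P).sum(axis=(1, 2)),
        "ClusterShade": (dev**3 * P).sum(axis=(1, 2)),
        "ClusterTendency": (dev**2 * P).sum(axis=(1, 2)),
        "Contrast": ((ii - jj) ** 2 * P).sum(axis=(1, 2)),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": -(pdiff * _safe_log2(pdiff)).sum(axis=1),
        "DifferenceVariance": ((kdiff[None, :] - da[:, None]) ** 2
                               * pdiff).sum(axis=1),
        "Id": (P / (1.0 + absdiff)).sum(axis=(1, 2)),
        "Idm": (P / (1.0 + absdiff**2)).sum(axis=(1, 2)),
        "Idmn": (P / (1.0 + (absdiff / ng) ** 2)).sum(axis=(1, 2)),
        "Idn": (P / (1.0 + absdiff / ng)).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": joint_entropy,
        "MaximumProbability": P.max(axis=(1, 2)),
        "MCC": mcc,
        "SumAverage": (ksum * psum).sum(axis=1),
        "SumEntropy": -(psum * _safe_log2(psum)).sum(axis=1),
        "SumSquares": sigx2,
    }
    return {k: float(np.mean(vals[k])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _run_length_matrix(levels, ng, d):
    """Run-length count matrix (ng x max_len) along direction d."""
    prev = _shift(levels, d, fill=0)
    starts = (levels > 0) & (prev != levels)
    coords = np.argwhere(starts)
    if coords.size == 0:
        return np.zeros((ng, 1))
    vals = levels[starts]
    lengths = np.ones(len(coords), dtype=np.int64)
    cur = coords.copy()
    active = np.arange(len(coords))
    dd = np.asarray(d)
    shape = np.asarray(levels.shape)
    while active.size:
        nxt = cur[active] + dd
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(active.size, dtype=bool)
        if inb.any():
            sub = nxt[inb]
            cont[inb] = levels[sub[:, 0], sub[:, 1], sub[:, 2]] == vals[active[inb]]
        lengths[active[cont]] += 1
        cur[active[cont]] = nxt[cont]
        active = active[cont]
    max_len = int(lengths.max())
    mat = np.zeros((ng, max_len))
    np.add.at(mat, (vals - 1, lengths - 1), 1.0)
    return mat


def _rlm_features_single(mat, n_voxels):
    ng, nl = mat.shape
    nr = mat.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_NAMES}
    g = np.arange(1, ng + 1, dtype=float)
    l = np.arange(1, nl + 1, dtype=float)
    pg = mat.sum(axis=1)
    pl = mat.sum(axis=0)
    p = mat / nr
    mu_g = float(np.sum(g[:, None] * p))
    mu_l = float(np.sum(l[None, :] * p))
    gg, ll = np.meshgrid(g, l, indexing="ij")
    return {
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "GrayLevelVariance": float(np.sum((gg - mu_g) ** 2 * p)),
        "HighGrayLevelRunEmphasis": float(np.sum(mat * gg**2) / nr),
        "LongRunEmphasis": float(np.sum(mat * ll**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(mat * gg**2 * ll**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(mat * ll**2 / gg**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(mat / gg**2) / nr),
        "RunEntropy": float(-np.sum(p * _safe_log2(p))),
        "RunLengthNonUniformity": float(np.sum(pl**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pl**2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float(np.sum((ll - mu_l) ** 2 * p)),
        "ShortRunEmphasis": float(np.sum(mat / ll**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(mat * gg**2 / ll**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(mat / (gg**2 * ll**2)) / nr),
    }


def glrlm_features(discretized, mask) -> dict:
    """Direction-averaged gray-level run-length features (13 directions)."""
    levels = np.asarray(discretized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    n_voxels = int(mask.sum())
    if n_voxels < 1:
        raise ValueError("GLRLM requires a nonempty mask")
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    mats = [_run_length_matrix(levels, ng, d) for d in DIRECTIONS_13]
    nl = max(m.shape[1] for m in mats)
    P = np.stack([np.pad(m, ((0, 0), (0, nl - m.shape[1]))) for m in mats])
    nr = P.sum(axis=(1, 2))  # (nd,)
    g = np.arange(1, ng + 1, dtype=float)
    l = np.arange(1, nl + 1, dtype=float)
    gg, ll = np.meshgrid(g, l, indexing="ij")
    pg = P.sum(axis=2)
    pl = P.sum(axis=1)
    p = P / nr[:, None, None]
    mu_g = (g[None, :] * pg).sum(axis=1) / nr
    mu_l = (l[None, :] * pl).sum(axis=1) / nr
    vals = {
        "GrayLevelNonUniformity": (pg**2).sum(axis=1) / nr,
        "GrayLevelNonUniformityNormalized": (pg**2).sum(axis=1) / nr**2,
        "GrayLevelVariance": ((gg[None] - mu_g[:, None, None]) ** 2
                              * p).sum(axis=(1, 2)),
        "HighGrayLevelRunEmphasis": (P * gg**2).sum(axis=(1, 2)) / nr,
        "LongRunEmphasis": (P * ll**2).sum(axis=(1, 2)) / nr,
        "LongRunHighGrayLevelEmphasis": (P * gg**2 * ll**2).sum(axis=(1, 2))
                                        / nr,
        "LongRunLowGrayLevelEmphasis": (P * ll**2 / gg**2).sum(axis=(1, 2))
                                       / nr,
        "LowGrayLevelRunEmphasis": (P / gg**2).sum(axis=(1, 2)) / nr,
        "RunEntropy": -(p * _safe_log2(p)).sum(axis=(1, 2)),
        "RunLengthNonUniformity": (pl**2).sum(axis=1) / nr,
        "RunLengthNonUniformityNormalized": (pl**2).sum(axis=1) / nr**2,
        "RunPercentage": nr / n_voxels,
        "RunVariance": ((ll[None] - mu_l[:, None, None]) ** 2
                        * p).sum(axis=(1, 2)),
        "ShortRunEmphasis": (P / ll**2).sum(axis=(1, 2)) / nr,
        "ShortRunHighGrayLevelEmphasis": (P * gg**2 / ll**2).sum(axis=(1, 2))
                                         / nr,
        "ShortRunLowGrayLevelEmphasis": (P / (gg**2 * ll**2)).sum(axis=(1, 2))
                                        / nr,
    }
    return {k: float(np.mean(vals[k])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _size_zone_matrix(levels, ng):
    zones = []  # (gray level, size)
    for g in range(1, ng + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, nlab = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    if not zones:
        return np.zeros((ng, 1))
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(discretized, mask) -> dict:
    """Gray-level size-zone features (zones are 26-connected components)."""
    levels = np.asarray(discretized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    n_voxels = int(mask.sum())
    if n_voxels < 1:
        raise ValueError("GLSZM requires a nonempty mask")
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    mat = _size_zone_matrix(levels, ng)
    nz = mat.sum()
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    s = np.arange(1, mat.shape[1] + 1, dtype=float)
    pg = mat.sum(axis=1)
    ps = mat.sum(axis=0)
    p = mat / nz
    mu_g = float(np.sum(g[:, None] * p))
    mu_s = float(np.sum(s[None, :] * p))
    gg, ss = np.meshgrid(g, s, indexing="ij")
    return {
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nz**2),
        "GrayLevelVariance": float(np.sum((gg - mu_g) ** 2 * p)),
        "HighGrayLevelZoneEmphasis": float(np.sum(mat * gg**2) / nz),
        "LargeAreaEmphasis": float(np.sum(mat * ss**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(mat * gg**2 * ss**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(mat * ss**2 / gg**2) / nz),
        "LowGrayLevelZoneEmphasis": float(np.sum(mat / gg**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(mat / ss**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(mat * gg**2 / ss**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(mat / (gg**2 * ss**2)) / nz),
        "ZoneEntropy": float(-np.sum(p * _safe_log2(p))),
        "ZonePercentage": float(nz / n_voxels),
        "ZoneVariance": float(np.sum((ss - mu_s) ** 2 * p)),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.ones((3, 3, 3))
_NEIGHBOR_KERNEL[1, 1, 1] = 0

#: Cap applied to coarseness when the denominator vanishes (flat region)
COARSENESS_CAP = 1e6


def ngtdm_features(discretized, mask) -> dict:
    """Neighbouring gray-tone difference features (26-neighbourhood means)."""
    levels = np.asarray(discretized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("NGTDM requires a nonempty mask")
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())

    nb_sum = ndimage.correlate(levels.astype(float), _NEIGHBOR_KERNEL,
                               mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(mask.astype(float), _NEIGHBOR_KERNEL,
                               mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    nvp = int(valid.sum())
    if nvp == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    A = nb_sum[valid] / nb_cnt[valid]
    lv = levels[valid].astype(float)

    n_i = np.bincount(levels[valid], minlength=ng + 1)[1:].astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, levels[valid] - 1, np.abs(lv - A))
    p_i = n_i / nvp

    i = np.arange(1, ng + 1, dtype=float)
    occ = p_i > 0
    ngp = int(occ.sum())
    io, po, so = i[occ], p_i[occ], s_i[occ]

    sum_ps = float(np.sum(po * so))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp > 1:
        dif2 = (io[:, None] - io[None, :]) ** 2
        contrast = (float(np.sum(po[:, None] * po[None, :] * dif2))
                    / (ngp * (ngp - 1))) * (float(s_i.sum()) / nvp)
        denom = float(np.sum(np.abs(io[:, None] * po[:, None]
                                    - io[None, :] * po[None, :])))
        busyness = sum_ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0

    absdif = np.abs(io[:, None] - io[None, :])
    pair_w = (po[:, None] * so[:, None] + po[None, :] * so[None, :]) \
        / (po[:, None] + po[None, :])
    complexity = float(np.sum(absdif * pair_w)) / nvp
    ssum = float(s_i.sum())
    strength = (float(np.sum((po[:, None] + po[None, :])
                             * (io[:, None] - io[None, :]) ** 2)) / ssum
                if ssum > 0 else 0.0)
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": complexity,
        "Contrast": float(contrast),
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_features(discretized, mask, alpha: int = 0) -> dict:
    """Gray-level dependence features.

    A neighbour is *dependent* when its level differs from the centre by at
    most ``alpha``; the dependence size of a voxel is the number of its
    dependent 26-neighbours inside the ROI, and emphasis weights use
    ``j = size + 1``.
    """
    levels = np.asarray(discretized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("GLDM requires a nonempty mask")
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())

    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        nb = _shift(levels, d, fill=0)
        dep += ((nb > 0) & (np.abs(nb - levels) <= alpha)) & mask
    dvals = dep[mask]
    gvals = levels[mask]
    nd = int(dvals.max()) + 1
    mat = np.zeros((ng, nd))
    np.add.at(mat, (gvals - 1, dvals), 1.0)

    nz = mat.sum()
    g = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)  # dependence size + 1
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    p = mat / nz
    mu_g = float(np.sum(g[:, None] * p))
    mu_j = float(np.sum(j[None, :] * p))
    gg, jjm = np.meshgrid(g, j, indexing="ij")
    return {
        "DependenceEntropy": float(-np.sum(p * _safe_log2(p))),
        "DependenceNonUniformity": float(np.sum(pd**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nz**2),
        "DependenceVariance": float(np.sum((jjm - mu_j) ** 2 * p)),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GrayLevelVariance": float(np.sum((gg - mu_g) ** 2 * p)),
        "HighGrayLevelEmphasis": float(np.sum(mat * gg**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(mat * jjm**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis":
            float(np.sum(mat * gg**2 * jjm**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis":
            float(np.sum(mat * jjm**2 / gg**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(mat / gg**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(mat / jjm**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis":
            float(np.sum(mat * gg**2 / jjm**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis":
            float(np.sum(mat / (gg**2 * jjm**2)) / nz),
    }


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

_TEXTURE_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


def extract_vector(channel_images: dict, mask, rule: DiscretizationRule,
                   spacing=(1.0, 1.0, 1.0)):
    """Extract the full 404-element named feature vector of one patient.

    Parameters
    ----------
    channel_images : mapping of channel name (t2, ktrans, ve, vp) to a 3D
        image on the common ROI grid.
    mask : common binary ROI.
    rule : fitted discretization rule carrying per-channel bin widths.
    spacing : voxel spacing in mm.

    Returns
    -------
    dict of ``"{channel}_{family}_{feature}"`` -> value, in the frozen
    manifest order; shape features are computed once on the mask and
    replicated per channel (keeping the 101-per-channel accounting).
    """
    missing = [c for c in CHANNELS if c not in channel_images]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    mask = np.asarray(mask, dtype=bool)
    shape = shape_features(mask, spacing)
    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    for ch in CHANNELS:
        img = np.asarray(channel_images[ch], dtype=float)
        disc = discretize(img, mask, rule.widths[ch])
        fo = first_order_features(img[mask], disc[mask], voxel_volume)
        for fam, names in FAMILIES:
            if fam == "firstorder":
                vals = fo
            elif fam == "shape":
                vals = shape
            else:
                vals = _TEXTURE_FUNCS[fam](disc, mask)
            for name in names:
                out[f"{ch}_{fam}_{name}"] = float(vals[name])
    return out
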