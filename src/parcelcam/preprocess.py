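"""Volume preprocessing (crop, variance scaling, resize) and graph validation.

The volume path mirrors the final preprocessing applied to MNI-registered
T1-weighted scans before classification: a center crop of the field of view
to 148 x 180 x 144 voxels, intensity standardization ("variance scaling",
interpreted as z-scoring over brain voxels), and a resample to
115 x 144 x 118.  Label volumes travel through the identical geometry with
nearest-neighbour interpolation so the voxel-to-parcel correspondence
survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .atlas import AtlasParcellation, ConnectivityGraph, VolumeScan

__all__ = [
    "PreprocessConfig",
    "GraphReport",
    "variance_scale",
    "crop_and_resize",
    "crop_and_resize_labels",
    "preprocess_volume",
    "validate_graph",
]

DEFAULT_CROP = (148, 180, 144)
DEFAULT_OUT = (115, 144, 118)


@dataclass(frozen=True)
class PreprocessConfig:
    crop_shape: tuple[int, int, int] = DEFAULT_CROP
    out_shape: tuple[int, int, int] = DEFAULT_OUT
    normalization: str = "variance_scaling"  # or "divide_only"


def variance_scale(v: VolumeScan, mask: np.ndarray | None = None,
                   divide_only: bool = False) -> VolumeScan:
    """Standardize intensities over a scaling region, applied to all voxels.

    The region defaults to the nonzero voxels (brain tissue in a
    skull-stripped scan).  ``divide_only`` skips the mean subtraction.
    """
    x = v.voxels
    if mask is None:
        mask = x != 0
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("scaling region has fewer than 2 voxels")
    region = x[mask]
    sd = region.std()
    if sd == 0:
        raise ValueError("zero variance over the scaling region")
    mean = 0.0 if divide_only else region.mean()
    out = (x - mean) / sd
    return VolumeScan(voxels=out, affine=v.affine, subject_id=v.subject_id,
                      session_id=v.session_id, label=v.label)


def _center_crop(x: np.ndarray, crop_shape: tuple[int, int, int]) -> np.ndarray:
    if any(int(i) < int(c) for i, c in zip(x.shape, crop_shape)):
        raise ValueError(
            f"input shape {x.shape} smaller than crop shape {tuple(crop_shape)}"
        )
    sl = []
    for i, c in zip(x.shape, crop_shape):
        start = (int(i) - int(c)) // 2
        sl.append(slice(start, start + int(c)))
    return x[tuple(sl)]


def _resize(x: np.ndarray, out_shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Resample to an exact output shape (pixel-center aligned)."""
    in_shape = x.shape
    if tuple(in_shape) == tuple(out_shape):
        return x.copy()
    axes = [
        (np.arange(o) + 0.5) * (i / o) - 0.5 for i, o in zip(in_shape, out_shape)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(x, coords, order=order, mode="nearest")
    return out.reshape(out_shape)


def crop_and_resize(v: VolumeScan, cfg: PreprocessConfig = PreprocessConfig()) -> VolumeScan:
    """Center crop to ``crop_shape`` then trilinear resample to ``out_shape``."""
    cropped = _center_crop(v.voxels, cfg.crop_shape)
    out = _resize(cropped, cfg.out_shape, order=1)
    return VolumeScan(voxels=out, affine=v.affine, subject_id=v.subject_id,
                      session_id=v.session_id, label=v.label)


def crop_and_resize_labels(
    atlas: AtlasParcellation, cfg: PreprocessConfig = PreprocessConfig()
) -> AtlasParcellation:
    """Apply the scan geometry to a label volume with nearest-neighbour
    resampling; warns if a previously non-empty parcel becomes empty."""
    cropped = _center_crop(atlas.label_volume, cfg.crop_shape)
    out = _resize(cropped.astype(float), cfg.out_shape, order=0)
    out = np.round(out).astype(np.int32)
    before = set(np.unique(atlas.label_volume)) - {0}
    after = set(np.unique(out)) - {0}
    lost = sorted(before - after)
    if lost:
        warnings.warn(
            f"parcels emptied by crop/resize: {lost}", RuntimeWarning, stacklevel=2
        )
    return AtlasParcellation(label_volume=out, parcel_table=atlas.parcel_table,
                             affine=atlas.affine)


def preprocess_volume(v: VolumeScan, cfg: PreprocessConfig = PreprocessConfig()) -> VolumeScan:
    """Crop -> variance scale -> resize, the full volume pipeline."""
    cropped = VolumeScan(voxels=_center_crop(v.voxels, cfg.crop_shape),
                         affine=v.affine, subject_id=v.subject_id,
                         session_id=v.session_id, label=v.label)
    scaled = variance_scale(cropped, divide_only=(cfg.normalization == "divide_only"))
    return crop_and_resize(scaled, PreprocessConfig(cfg.crop_shape, cfg.out_shape,
                                                    cfg.normalization))


@dataclass
class GraphReport:
    symmetry_residual: float
    n_negative: int
    diagonal_mass: float
    passed: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.passed.values())


def validate_graph(g: ConnectivityGraph | np.ndarray,
                   tol: float = 1e-8) -> GraphReport:
    """Pure report of the connectivity invariants (readers enforce them)."""
    m = g.matrix if isinstance(g, ConnectivityGraph) else np.asarray(g, dtype=float)
    resid = float(np.abs(m - m.T).max()) if m.size else 0.0
    n_neg = int((m < 0).sum())
    diag = float(np.abs(np.diag(m)).sum()) if m.size else 0.0
    return GraphReport(
        symmetry_residual=resid,
        n_negative=n_neg,
        diagonal_mass=diag,
        passed={
            "symmetric": resid <= tol,
            "nonnegative": n_neg == 0,
            "zero_diagonal": diag == 0.0,
        },
    )
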