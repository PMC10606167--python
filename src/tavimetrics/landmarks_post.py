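"""Landmark mask post-processing.

A landmark-detection network emits one soft mask channel per anatomical
landmark.  This module turns those channels into world-coordinate points
deterministically: binarize at 0.5, keep the largest connected component,
take its voxel centroid, and map through the voxel→world affine into LPS
millimetres.  It is independent of any network — any 5-channel volume in
[0, 1] with an affine works.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import SchemaError, ValidationError
from .io import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "LandmarkMaskVolume",
    "mask_to_landmark",
    "masks_to_landmark_set",
    "landmark_mae",
    "read_mask_volume",
    "DEFAULT_CHANNEL_MAP",
]

# channel order convention when none is configured
DEFAULT_CHANNEL_MAP: dict[str, int] = {name: i
                                       for i, name in enumerate(LANDMARK_NAMES)}


@dataclass
class LandmarkMaskVolume:
    """A 5-channel scalar volume in [0, 1] plus a voxel-index→world(LPS)
    affine (4×4, mm)."""

    values: np.ndarray          # (5, nx, ny, nz)
    affine: np.ndarray          # 4x4

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if values.ndim != 4 or values.shape[0] != 5:
            raise ValidationError(
                f"expected a (5, nx, ny, nz) volume, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("mask volume contains non-finite values")
        if values.min() < 0 or values.max() > 1:
            raise ValidationError("mask values must lie in [0, 1]")
        if affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        self.values = values
        self.affine = affine


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValidationError("connectivity must be 6, 18 or 26")


def mask_to_landmark(channel: np.ndarray, affine: np.ndarray,
                     threshold: float = 0.5,
                     connectivity: int = 26) -> np.ndarray | None:
    """One soft mask channel → one world-coordinate landmark (or None).

    Binarize at ``threshold``, label with the given 3D connectivity
    (default 26, the standard for blob masks), keep the largest component
    by voxel count (ties go to the component containing the
    lexicographically smallest voxel index), and map the unweighted voxel
    centroid through the affine.  Returns None — not an error — when no
    voxel exceeds the threshold: an absent landmark is a prediction
    failure, and the caller decides whether that is fatal.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 3:
        raise ValidationError("channel must be a 3D volume")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine must be an invertible 4x4 matrix")

    binary = channel > threshold
    if not binary.any():
        return None
    labels, n = ndimage.label(binary, structure=_connectivity_structure(connectivity))
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = np.flatnonzero(counts == counts.max()) + 1
    if len(best) > 1:
        # tie-break: component owning the lexicographically smallest index
        firsts = []
        for lab in best:
            idx = np.argwhere(labels == lab)
            firsts.append(tuple(idx[np.lexsort(idx.T[::-1])][0]))
        best = [best[int(np.argmin(np.array(firsts, dtype=object)))]]
    centroid_idx = np.argwhere(labels == best[0]).mean(axis=0)
    world = affine @ np.append(centroid_idx, 1.0)
    return world[:3]


def masks_to_landmark_set(vol: LandmarkMaskVolume,
                          channel_map: dict[str, int] | None = None,
                          threshold: float = 0.5,
                          connectivity: int = 26) -> LandmarkSet:
    """Apply :func:`mask_to_landmark` per channel and assemble the set.

    ``channel_map`` binds the five landmark names to channel indices
    bijectively; a channel with no supra-threshold voxels raises a
    missing-landmark error naming the landmark.
    """
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    if set(channel_map) != set(LANDMARK_NAMES):
        raise SchemaError(
            f"channel_map must name exactly {sorted(LANDMARK_NAMES)}")
    if sorted(channel_map.values()) != list(range(5)):
        raise SchemaError("channel_map must be a bijection onto channels 0-4")
    points = {}
    for name, ch in channel_map.items():
        p = mask_to_landmark(vol.values[ch], vol.affine, threshold,
                             connectivity)
        if p is None:
            raise ValidationError(
                f"landmark {name!r} absent: no voxel above {threshold} in "
                f"channel {ch}")
        points[name] = p
    return LandmarkSet(**points)


def landmark_mae(predicted: LandmarkSet, truth: LandmarkSet) -> float:
    """Mean Euclidean distance (mm) between the five paired landmarks."""
    dists = [float(np.linalg.norm(getattr(predicted, n) - getattr(truth, n)))
             for n in LANDMARK_NAMES]
    return float(np.mean(dists))


def read_mask_volume(path) -> LandmarkMaskVolume:
    """Read a 4D landmark mask volume (NIfTI via nibabel, NRRD via
    SimpleITK).

    The stored affine is taken verbatim as voxel→LPS — no frame flip is
    applied (ITK images are natively LPS; NIfTI affines must be written in
    LPS by the producer, per this package's declared convention).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise SchemaError(f"{path}: expected a 4D volume")
        values = np.moveaxis(data, -1, 0)  # (nx,ny,nz,5) → (5,nx,ny,nz)
        return LandmarkMaskVolume(values=values, affine=np.asarray(img.affine))
    if suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (nz,ny,nx[,c]) or (c,nz,ny,nx)
        if arr.ndim != 4:
            raise SchemaError(f"{path}: expected a 4D volume")
        if arr.shape[-1] == 5 and arr.shape[0] != 5:
            arr = np.moveaxis(arr, -1, 0)
        values = np.transpose(arr, (0, 3, 2, 1))  # channels, x, y, z
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin())
        affine = np.eye(4)
        affine[:3, :3] = direction * spacing
        affine[:3, 3] = origin
        return LandmarkMaskVolume(values=values, affine=affine)
    raise SchemaError(f"{path}: unsupported mask format (use NIfTI or NRRD)")
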