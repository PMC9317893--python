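"""Core image containers and NIfTI-1 I/O.

A :class:`Volume` is a 3-D scalar intensity grid with voxel spacing (mm) and a
voxel-to-world affine (RAS mm convention); a :class:`LabelMap` is an integer
map on the same geometry.  Volumes are held as 64-bit floats regardless of
on-disk dtype; label maps as 32-bit integers.  Only single-file NIfTI-1
(``.nii`` / ``.nii.gz``) is supported; NIfTI-2 and ANALYZE are rejected.

Label-map metadata (level, label dictionary) travels in a JSON NIfTI header
extension so that a label map round-trips through a single file.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import (
    ContractError,
    DimensionalityError,
    GeometryError,
    ValidationError,
)

logger = logging.getLogger("pallidex")

#: header-extension code used for the label-map JSON sidecar ("comment")
_EXT_CODE = 6

#: number of intensity bits kept by :func:`canonical_intensities`
CANONICAL_BITS = 12

FINE = "fine"
COARSE = "coarse"

# Default fine-label dictionary of the stylized phantom protocol.  The real
# protocol uses a configurable dictionary with >100 entries; only the globus
# pallidus ids are structurally required by the index pipeline.
DEFAULT_FINE_LABELS: dict[int, str] = {
    0: "background",
    1: "csf_shell",
    2: "cortical_gm",
    3: "white_matter",
    4: "ventricles",
    5: "thalamus_left",
    6: "thalamus_right",
    7: "gp_left",
    8: "gp_right",
    9: "putamen_left",
    10: "putamen_right",
    11: "caudate_left",
    12: "caudate_right",
    13: "brainstem",
}

GP_LEFT = "gp_left"
GP_RIGHT = "gp_right"


def _check_geometry(data: np.ndarray, spacing, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D grid, got {data.ndim}-D with shape {data.shape}"
        )
    if min(data.shape) < 1:
        raise ValidationError(f"degenerate shape {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive values, got {spacing}")
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")


@dataclass
class Volume:
    """3-D scalar image with geometry.

    Parameters
    ----------
    data:
        Finite intensities, converted to float64.
    spacing:
        Voxel size (sx, sy, sz) in mm, all positive.
    affine:
        4x4 voxel-to-world map (RAS mm).
    meta:
        Free-form acquisition metadata; carried along, never interpreted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_geometry(self.data, self.spacing, self.affine)
        bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if bad:
            raise ValidationError(f"volume contains {bad} non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.affine, dict(self.meta))

    def same_grid(self, other: "Volume | LabelMap") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class LabelMap:
    """Integer-labeled grid companion to a :class:`Volume`.

    ``level`` distinguishes the fine protocol (individual structures, GP
    included) from the coarse partition into large regions.  0 is reserved
    for background.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    level: str = FINE
    label_dictionary: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValidationError("label map contains non-integer values")
        self.labels = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_geometry(self.labels, self.spacing, self.affine)
        if self.labels.min() < 0:
            raise ValidationError("label map contains negative ids")
        if self.level not in (FINE, COARSE):
            raise ValidationError(f"unknown label level {self.level!r}")
        if not self.label_dictionary:
            self.label_dictionary = {
                int(i): f"label_{int(i)}" for i in np.unique(self.labels)
            }

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def id_of(self, name: str) -> int:
        for i, n in self.label_dictionary.items():
            if n == name:
                return int(i)
        raise KeyError(f"label name {name!r} not in dictionary")

    def mask(self, *names: str) -> np.ndarray:
        ids = [self.id_of(n) for n in names]
        return np.isin(self.labels, ids)

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return LabelMap(labels, self.spacing, self.affine, self.level,
                        dict(self.label_dictionary))


def _load_nifti1(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    # exact type check: Nifti2Image subclasses Nifti1Image in nibabel
    if type(img) is not nib.Nifti1Image:
        raise ValidationError(
            f"{path}: only single-file NIfTI-1 is supported "
            f"(got {type(img).__name__})"
        )
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D image, got shape {img.shape}"
        )
    return img


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI-1 file into a float64 :class:`Volume`."""
    img = _load_nifti1(path)
    data = np.asarray(img.dataobj).astype(np.float64)
    bad = int(np.size(data) - np.isfinite(data).sum())
    if bad:
        raise ValidationError(f"{path}: volume contains {bad} non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, np.asarray(img.affine, dtype=np.float64))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as float64 NIfTI-1."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    """Read an integer NIfTI-1 label map (metadata from the JSON extension)."""
    img = _load_nifti1(path)
    arr = np.asarray(img.dataobj)
    if not np.all(arr == np.round(arr)):
        raise ValidationError(f"{path}: label map has non-integer voxels")
    arr = arr.astype(np.int32)
    if arr.min() < 0:
        raise ValidationError(f"{path}: label map contains negative ids")
    level, ldict = FINE, {}
    for ext in img.header.extensions:
        if ext.get_code() == _EXT_CODE:
            try:
                payload = json.loads(bytes(ext.get_content()).decode("utf-8"))
            except (ValueError, UnicodeDecodeError):
                continue
            if isinstance(payload, dict) and "pallidex_level" in payload:
                level = payload["pallidex_level"]
                ldict = {int(k): v for k, v in payload.get("labels", {}).items()}
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(arr, spacing, np.asarray(img.affine, dtype=np.float64),
                    level, ldict)


def write_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Write a label map as int32 NIfTI-1 with a JSON metadata extension."""
    if labelmap.labels.max(initial=0) == 0:
        logger.warning("writing empty label map (all background): %s", path)
    img = nib.Nifti1Image(labelmap.labels.astype(np.int32), labelmap.affine)
    img.header.set_zooms(labelmap.spacing)
    payload = json.dumps({
        "pallidex_level": labelmap.level,
        "labels": {str(k): v for k, v in labelmap.label_dictionary.items()},
    })
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension(_EXT_CODE, payload.encode("utf-8")))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# gain-invariant canonical intensities
# ---------------------------------------------------------------------------

def canonical_scale(data: np.ndarray) -> float:
    """Mean absolute intensity: the gain-equivariant reference scale.

    Raw T1 intensities carry an arbitrary scanner gain.  All *decisions* in
    the pipeline (registration forces, similarity ranking, fusion votes,
    clustering) are taken on intensities divided by this scale: rescaling
    the input by k rescales the reference by the same k up to ~1e-15
    relative rounding, so the scale-free intensities — and after
    quantization, every downstream decision — are unchanged.
    """
    m = float(np.mean(np.abs(data)))
    if m <= 0 or not math.isfinite(m):
        raise ContractError("cannot canonicalize a non-positive/empty image")
    return m


def quantize(values: np.ndarray, bits: int = CANONICAL_BITS) -> np.ndarray:
    """Snap scale-free intensities to a 2**-bits grid.

    After quantization the array is bitwise reproducible across runs whose
    inputs differ only by a global gain, so every downstream decision is too.
    """
    step = 2.0 ** bits
    return np.round(values * step) / step


def canonical_intensities(volume: Volume, bits: int = CANONICAL_BITS) -> Volume:
    """Gain-canonical, quantized copy of ``volume`` (decision pathway input)."""
    s = canonical_scale(volume.data)
    return volume.with_data(quantize(volume.data / s, bits))


def require_same_grid(a, b, what: str = "inputs") -> None:
    if a.shape != b.shape or not np.allclose(a.affine, b.affine):
        raise ContractError(f"{what} are not on the same grid")
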