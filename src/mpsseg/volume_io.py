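"""Multi-modal volume data model, NIfTI I/O, cropping and region merging.

Volumes follow the BraTS conventions: four co-registered MR sequences
(T1, T1C, T2, FLAIR) per case, integer labels {0: background, 1: NCR/NET,
2: ED, 4: ET}, and the nested evaluation regions

    WT (whole tumor)      = {1, 2, 4}
    TC (tumor core)       = {1, 4}
    ET (enhancing tumor)  = {4}

All shapes are quoted slice-first: the on-disk first axis is the axial
slice axis (a BraTS volume is 155 x 240 x 240).  Raw labels {0,1,2,4} are
kept on disk and in :class:`LabelVolume`; contiguous class indices
{0,1,2,3} = {background, NCR/NET, ED, ET} are used for softmax channels
and obtained via :meth:`LabelVolume.to_class_indices`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical channel order used throughout the package.
CHANNELS = ("t1", "t1ce", "t2", "flair")

#: Valid raw label values (BraTS dialect).
RAW_LABELS = (0, 1, 2, 4)

#: raw label -> contiguous class index; class index -> raw label.
_RAW_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
_CLASS_TO_RAW = np.array([0, 1, 2, 4], dtype=np.int16)

REGIONS = ("WT", "TC", "ET")
_REGION_LABELS = {"WT": (1, 2, 4), "TC": (1, 4), "ET": (4,)}


class IncompleteModalitySet(ValueError):
    """A case is missing one or more of the four MR sequences."""


class UnalignedVolumes(ValueError):
    """Channels (or labels) of one case do not share a single shape."""


@dataclass
class MultiModalVolume:
    """Four aligned 3D intensity channels plus voxel geometry.

    ``data`` is stacked channel-first, shape ``(4, S0, S1, S2)`` in the
    order of :data:`CHANNELS`.  ``spacing`` is the per-axis voxel size in
    mm.  ``orientation`` records which plane's slicing axis currently
    leads (``"axial"`` for the on-disk layout).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "axial"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(CHANNELS):
            raise UnalignedVolumes(
                f"unaligned volumes: expected (4, S0, S1, S2), got {self.data.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing entries must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNELS.index(name)]

    @property
    def flair(self) -> np.ndarray:
        return self.channel("flair")

    def copy(self) -> "MultiModalVolume":
        return MultiModalVolume(
            self.data.copy(), tuple(self.spacing), self.orientation,
            None if self.affine is None else self.affine.copy(),
        )


@dataclass
class LabelVolume:
    """Per-voxel tumor sub-region labels in the raw BraTS dialect."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "axial"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("labels must be integral")
            self.labels = self.labels.astype(np.int16)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        bad = np.setdiff1d(np.unique(self.labels), RAW_LABELS)
        if bad.size:
            raise ValueError(f"invalid label values {bad.tolist()}; expected {RAW_LABELS}")
        self.labels = self.labels.astype(np.int16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def to_class_indices(self) -> np.ndarray:
        """Map raw labels {0,1,2,4} to contiguous classes {0,1,2,3}."""
        out = self.labels.copy()
        out[out == 4] = 3
        return out.astype(np.int16)

    @classmethod
    def from_class_indices(
        cls, classes: np.ndarray, spacing=(1.0, 1.0, 1.0), orientation="axial", affine=None
    ) -> "LabelVolume":
        classes = np.asarray(classes, dtype=np.int64)
        if classes.min() < 0 or classes.max() > 3:
            raise ValueError("class indices must lie in {0,1,2,3}")
        return cls(_CLASS_TO_RAW[classes], spacing, orientation, affine)

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.labels.copy(), tuple(self.spacing), self.orientation,
            None if self.affine is None else self.affine.copy(),
        )


@dataclass
class RegionMask:
    """Boolean mask for one nested evaluation region (WT, TC or ET)."""

    region: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        self.mask = np.asarray(self.mask, dtype=bool)


# ---------------------------------------------------------------------------
# NIfTI I/O

def _load_nifti(path: str | os.PathLike):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine, img.header.get_zooms()[:3]


def read_volume(channel_paths: dict[str, str | os.PathLike]) -> MultiModalVolume:
    """Load the four MR sequences of one case from NIfTI files.

    Parameters
    ----------
    channel_paths
        Mapping of sequence name (``t1``, ``t1ce``, ``t2``, ``flair``)
        to a readable NIfTI file.

    Raises
    ------
    IncompleteModalitySet
        If any of the four sequences is missing from the mapping.
    UnalignedVolumes
        If the channel arrays do not all share one shape.
    """
    missing = [c for c in CHANNELS if c not in channel_paths]
    if missing:
        raise IncompleteModalitySet(f"incomplete modality set: missing {missing}")
    arrays, affine, spacing = [], None, None
    for name in CHANNELS:
        arr, aff, zooms = _load_nifti(channel_paths[name])
        if affine is None:
            affine, spacing = aff, tuple(float(z) for z in zooms)
        arrays.append(np.asarray(arr, dtype=np.float32))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise UnalignedVolumes(f"unaligned volumes: shapes {sorted(shapes)}")
    return MultiModalVolume(np.stack(arrays), spacing, "axial", affine)


def read_case(case_dir: str | os.PathLike) -> tuple[MultiModalVolume, LabelVolume | None]:
    """Read a BraTS-layout case directory ``<case>/<case>_{t1,...,seg}.nii.gz``."""
    case_dir = str(case_dir)
    case = os.path.basename(os.path.normpath(case_dir))
    paths = {}
    for name in CHANNELS:
        for ext in (".nii.gz", ".nii"):
            p = os.path.join(case_dir, f"{case}_{name}{ext}")
            if os.path.exists(p):
                paths[name] = p
                break
    vol = read_volume(paths)
    seg = None
    for ext in (".nii.gz", ".nii"):
        p = os.path.join(case_dir, f"{case}_seg{ext}")
        if os.path.exists(p):
            seg = read_labels(p)
            break
    if seg is not None and seg.shape != vol.shape:
        raise UnalignedVolumes("unaligned volumes: labels do not match channels")
    return vol, seg


def read_labels(path: str | os.PathLike) -> LabelVolume:
    arr, affine, spacing = _load_nifti(path)
    return LabelVolume(np.rint(arr).astype(np.int16), tuple(float(z) for z in spacing),
                       "axial", affine)


def write_volume(v: MultiModalVolume, directory: str | os.PathLike, case: str) -> dict[str, str]:
    """Write the four channels as ``<case>_<seq>.nii.gz`` files; returns paths."""
    os.makedirs(directory, exist_ok=True)
    affine = v.affine if v.affine is not None else np.diag(list(v.spacing) + [1.0])
    out = {}
    for i, name in enumerate(CHANNELS):
        p = os.path.join(str(directory), f"{case}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(v.data[i].astype(np.float32), affine), p)
        out[name] = p
    return out


def write_labels(l: LabelVolume, path: str | os.PathLike,
                 reference: MultiModalVolume | LabelVolume | None = None) -> str:
    """Write a label volume as NIfTI using the reference volume's geometry.

    Labels are validated against the raw dialect {0,1,2,4} by the
    :class:`LabelVolume` constructor, so a read-back equals the input
    voxel-for-voxel.
    """
    ref = reference if reference is not None else l
    affine = ref.affine if ref.affine is not None else np.diag(list(ref.spacing) + [1.0])
    nib.save(nib.Nifti1Image(l.labels.astype(np.int16), affine), str(path))
    return str(path)


# ---------------------------------------------------------------------------
# Cropping

def _bounding_box(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    if idx.size == 0:
        center = np.array(mask.shape) // 2
        return center, center
    return idx.min(axis=0), idx.max(axis=0)


def crop_volume(
    v: MultiModalVolume,
    l: LabelVolume | None,
    target_shape: tuple[int, int, int],
) -> tuple[MultiModalVolume, LabelVolume | None, tuple[int, int, int]]:
    """Crop a case to ``target_shape``, centered on the brain.

    The crop window is centered on the bounding box of nonzero FLAIR
    intensity (the brain) and clamped to the volume bounds, discarding
    surrounding black background.  Returns the cropped volume, cropped
    labels (if given) and the crop offsets needed to re-embed predictions
    into the original frame (see :func:`embed_labels`).
    """
    src = np.array(v.shape)
    tgt = np.array(target_shape, dtype=int)
    if np.any(tgt > src):
        raise ValueError(f"crop exceeds volume: target {tuple(tgt)} > source {tuple(src)}")
    lo, hi = _bounding_box(v.flair != 0)
    center = (lo + hi) / 2.0
    start = np.rint(center - (tgt - 1) / 2.0).astype(int)
    start = np.clip(start, 0, src - tgt)
    sl = tuple(slice(s, s + t) for s, t in zip(start, tgt))
    cv = MultiModalVolume(v.data[(slice(None),) + sl], v.spacing, v.orientation, v.affine)
    cl = None
    if l is not None:
        cl = LabelVolume(l.labels[sl], l.spacing, l.orientation, l.affine)
    return cv, cl, tuple(int(s) for s in start)


def embed_labels(l: LabelVolume, original_shape: tuple[int, int, int],
                 crop_offsets: tuple[int, int, int]) -> LabelVolume:
    """Re-embed a cropped prediction into the original frame, zeros outside."""
    out = np.zeros(original_shape, dtype=np.int16)
    sl = tuple(slice(o, o + s) for o, s in zip(crop_offsets, l.shape))
    out[sl] = l.labels
    return LabelVolume(out, l.spacing, l.orientation, l.affine)


# ---------------------------------------------------------------------------
# Region merging

def merge_regions(l: LabelVolume) -> dict[str, RegionMask]:
    """Merge raw labels into the nested WT / TC / ET evaluation regions.

    WT = {1,2,4}, TC = {1,4}, ET = {4}; hence ET <= TC <= WT as sets for
    any label volume.
    """
    return {
        r: RegionMask(r, np.isin(l.labels, _REGION_LABELS[r])) for r in REGIONS
    }
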