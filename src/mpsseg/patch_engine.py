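"""Plane reorientation, intensity standardization, patch sampling, augmentation.

MR scans are stored axially; the same volume can be resliced along the
coronal or sagittal plane by permuting axes so the requested plane's
slicing axis leads.  Training patches are sampled per plane under the
brain constraint: the center pixel of a patch must not sit at the
volume-wide FLAIR minimum (which is the black background), so patches
concentrate on brain tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, MultiModalVolume


@dataclass(frozen=True)
class PlaneSpec:
    """An anatomical slicing plane as an axis permutation.

    ``permutation`` maps on-disk (slice, row, col) axes so the named
    plane's slicing axis becomes the leading axis.
    """

    name: str
    permutation: tuple[int, int, int]

    @property
    def inverse(self) -> tuple[int, int, int]:
        inv = [0, 0, 0]
        for i, p in enumerate(self.permutation):
            inv[p] = i
        return tuple(inv)


PLANES: dict[str, PlaneSpec] = {
    "axial": PlaneSpec("axial", (0, 1, 2)),
    "coronal": PlaneSpec("coronal", (1, 0, 2)),
    "sagittal": PlaneSpec("sagittal", (2, 0, 1)),
}


@dataclass
class Patch2D:
    """A four-channel 2D training example with its per-pixel class labels."""

    image: np.ndarray  # (4, H, W) float32
    label: np.ndarray  # (H, W) int, class indices {0,1,2,3}
    plane: str
    source: tuple  # (case id, slice index, row offset, col offset)
    center: tuple | None = None  # (slice, row, col) of the drawn center pixel

    def __post_init__(self) -> None:
        if self.image.shape[1:] != self.label.shape:
            raise ValueError("image and label must share H x W")


def _get_plane(plane: str | PlaneSpec) -> PlaneSpec:
    if isinstance(plane, PlaneSpec):
        return plane
    try:
        return PLANES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}") from None


def reorient_array(a: np.ndarray, plane: str | PlaneSpec, inverse: bool = False) -> np.ndarray:
    """Permute the spatial axes of a 3D (or channel-first 4D) array."""
    p = _get_plane(plane)
    perm = p.inverse if inverse else p.permutation
    if a.ndim == 3:
        return np.transpose(a, perm)
    if a.ndim == 4:  # leading channel axis
        return np.transpose(a, (0,) + tuple(x + 1 for x in perm))
    raise ValueError("expected a 3D or channel-first 4D array")


def reorient(v, plane: str | PlaneSpec):
    """Reslice a volume so the requested plane's slicing axis leads.

    Accepts :class:`MultiModalVolume`, :class:`LabelVolume` or a plain
    probability array shaped ``(C, S0, S1, S2)``.  Round trip through
    :func:`restore_axial` is the identity.
    """
    p = _get_plane(plane)
    if isinstance(v, MultiModalVolume):
        if v.orientation != "axial":
            v = restore_axial(v)
        spacing = tuple(v.spacing[i] for i in p.permutation)
        return MultiModalVolume(reorient_array(v.data, p), spacing, p.name, v.affine)
    if isinstance(v, LabelVolume):
        if v.orientation != "axial":
            v = restore_axial(v)
        spacing = tuple(v.spacing[i] for i in p.permutation)
        return LabelVolume(reorient_array(v.labels, p), spacing, p.name, v.affine)
    return reorient_array(np.asarray(v), p)


def restore_axial(v):
    """Undo :func:`reorient`, returning the axial (on-disk) orientation."""
    if isinstance(v, (MultiModalVolume, LabelVolume)):
        p = _get_plane(v.orientation)
        inv = p.inverse
        spacing = tuple(v.spacing[i] for i in inv)
        if isinstance(v, MultiModalVolume):
            return MultiModalVolume(reorient_array(v.data, p, inverse=True),
                                    spacing, "axial", v.affine)
        return LabelVolume(reorient_array(v.labels, p, inverse=True),
                           spacing, "axial", v.affine)
    raise ValueError("restore_axial needs a volume object carrying an orientation tag")


def standardize(v: MultiModalVolume) -> MultiModalVolume:
    """Per-channel z-score over nonzero (brain) voxels; zeros stay zero.

    The black background carries no signal, so the statistics are taken
    over nonzero voxels only.  A channel whose nonzero voxels are
    constant maps to all-zeros; a channel with fewer than two nonzero
    voxels is degenerate and rejected.
    """
    out = v.data.copy()
    for c in range(out.shape[0]):
        ch = out[c]
        mask = ch != 0
        n = int(mask.sum())
        if n < 2:
            raise ValueError("degenerate channel: fewer than 2 nonzero voxels")
        mu = ch[mask].mean()
        sd = ch[mask].std()
        if sd == 0:
            ch[mask] = 0.0
        else:
            ch[mask] = (ch[mask] - mu) / sd
    return MultiModalVolume(out, v.spacing, v.orientation, v.affine)


def valid_center_mask(flair_slice: np.ndarray, flair_min: float,
                      patch_size: int) -> np.ndarray:
    """Centers whose FLAIR strictly exceeds the volume minimum.

    The geometric border is not excluded here; sampling shifts the patch
    window inward so patches never need padding.
    """
    return flair_slice > flair_min


def sample_patches(
    vol: MultiModalVolume,
    lab: LabelVolume,
    plane: str | PlaneSpec,
    n: int,
    patch_size: int = 128,
    rng_seed: int | np.random.Generator = 0,
    case_id: str = "case",
) -> list[Patch2D]:
    """Randomly sample ``n`` patches along one plane.

    Each patch center is drawn uniformly from pixels whose FLAIR
    intensity strictly exceeds the volume-wide FLAIR minimum (so centers
    fall on brain, not on the black surround).  The patch window is then
    shifted inward as needed so it lies fully inside the slice.
    Deterministic under a fixed seed.
    """
    p = _get_plane(plane)
    v = reorient(vol, p)
    l = reorient(lab, p)
    classes = l.to_class_indices()
    flair = v.flair
    fmin = float(flair.min())
    n_slices, H, W = flair.shape
    if patch_size > H or patch_size > W:
        raise ValueError("patch_size exceeds in-plane dimensions after reorientation")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    valid = flair > fmin  # (n_slices, H, W)
    flat = np.flatnonzero(valid)
    if flat.size == 0:
        raise ValueError("no brain tissue in plane: no valid patch centers")
    picks = rng.choice(flat, size=n, replace=True)
    half = patch_size // 2
    patches = []
    for f in picks:
        s, r, c = np.unravel_index(f, valid.shape)
        r0 = int(np.clip(r - half, 0, H - patch_size))
        c0 = int(np.clip(c - half, 0, W - patch_size))
        img = v.data[:, s, r0:r0 + patch_size, c0:c0 + patch_size]
        seg = classes[s, r0:r0 + patch_size, c0:c0 + patch_size]
        patches.append(Patch2D(np.ascontiguousarray(img), np.ascontiguousarray(seg),
                               p.name, (case_id, int(s), r0, c0),
                               center=(int(s), int(r), int(c))))
    return patches


def augment(
    patch: Patch2D,
    rng: np.random.Generator,
    max_rotation_deg: float = 10.0,
    max_shift_fraction: float = 0.1,
    flip_prob: float = 0.5,
) -> Patch2D:
    """Apply one random geometric augmentation to image and label jointly.

    Rotation angle is uniform in [0, ``max_rotation_deg``] degrees,
    shifts uniform within ``max_shift_fraction`` of the patch size per
    axis, each flip applied with probability ``flip_prob``.  The label
    receives the identical transform with nearest-neighbor interpolation,
    so the label set {0,1,2,3} is preserved.
    """
    angle = float(rng.uniform(0.0, max_rotation_deg))
    h, w = patch.label.shape
    shift = rng.uniform(-max_shift_fraction, max_shift_fraction, size=2) * (h, w)
    flip_h = bool(rng.random() < flip_prob)
    flip_v = bool(rng.random() < flip_prob)

    img = patch.image.astype(np.float32)
    seg = patch.label
    if angle != 0.0:
        img = np.stack([
            ndimage.rotate(ch, angle, reshape=False, order=1, mode="nearest")
            for ch in img
        ])
        seg = ndimage.rotate(seg, angle, reshape=False, order=0, mode="nearest")
    if np.any(shift != 0):
        img = np.stack([ndimage.shift(ch, shift, order=1, mode="nearest") for ch in img])
        seg = ndimage.shift(seg, shift, order=0, mode="nearest")
    if flip_h:
        img = img[:, :, ::-1]
        seg = seg[:, ::-1]
    if flip_v:
        img = img[:, ::-1, :]
        seg = seg[::-1, :]
    return Patch2D(np.ascontiguousarray(img), np.ascontiguousarray(seg),
                   patch.plane, patch.source)
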