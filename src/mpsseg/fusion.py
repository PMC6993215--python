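"""Multi-planar consensus fusion of probability maps.

Three networks segment the same volume along the axial, coronal and
sagittal planes; their per-voxel class probabilities (already restored
to the axial frame) are averaged,

    p = (p_axial + p_coronal + p_sagittal) / 3,

which stays on the probability simplex.  The fused map is the input to
CRF refinement; a plain argmax converts any map to discrete labels.
"""

from __future__ import annotations

import numpy as np

from .volume_io import LabelVolume


def _check_map(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p)
    if p.ndim != 4:
        raise ValueError("probability map must be (C, S0, S1, S2)")
    return p


def fuse_planes(p_axial, p_coronal, p_sagittal) -> np.ndarray:
    """Voxel-wise arithmetic mean of three normalized maps in the axial frame."""
    maps = [_check_map(p) for p in (p_axial, p_coronal, p_sagittal)]
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch between plane maps: {sorted(shapes)}")
    return (maps[0] + maps[1] + maps[2]) / 3.0


def argmax_labels(p: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Per-voxel argmax class, mapped back to raw BraTS labels {0,1,2,4}.

    Ties resolve toward the lower class index (``argmax`` first-maximum
    semantics), i.e. toward background.
    """
    p = _check_map(p)
    classes = p.argmax(axis=0)
    return LabelVolume.from_class_indices(classes, spacing=spacing)
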