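"""Region-level segmentation metrics over the nested WT / TC / ET regions.

Dice, sensitivity and specificity are voxel-count ratios; the Hausdorff
distance is computed between the region surfaces (mask voxels with at
least one face-adjacent non-mask neighbor, volume border counting as
outside), with Euclidean distances in millimetres via the voxel spacing.
Both the classic maximum and the robust 95th-percentile variant
("Hausdorff95", the maximum of the two directed 95th percentiles) are
reported.

Empty-mask conventions (the common BraTS choices): both masks empty ->
Dice/sensitivity 1; exactly one empty -> Dice 0 and the distance is the
:data:`UNDEFINED_DISTANCE` sentinel (NaN), reported distinctly, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import LabelVolume, RegionMask, REGIONS, merge_regions

#: Sentinel for a surface distance that does not exist (an empty mask).
UNDEFINED_DISTANCE = float("nan")


def _as_mask(m) -> np.ndarray:
    if isinstance(m, RegionMask):
        return m.mask
    return np.asarray(m, dtype=bool)


def dice(P1, G1) -> float:
    """``2|P1 & G1| / (|P1| + |G1|)``; 1 if both masks are empty."""
    P1, G1 = _as_mask(P1), _as_mask(G1)
    if P1.shape != G1.shape:
        raise ValueError("shape mismatch")
    denom = int(P1.sum()) + int(G1.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((P1 & G1).sum()) / denom


def sensitivity(P1, G1) -> float:
    """True-positive rate ``|P1 & G1| / |G1|``; 1 if G1 is empty."""
    P1, G1 = _as_mask(P1), _as_mask(G1)
    if P1.shape != G1.shape:
        raise ValueError("shape mismatch")
    g = int(G1.sum())
    if g == 0:
        return 1.0
    return int((P1 & G1).sum()) / g


def specificity(P0, G0) -> float:
    """True-negative rate ``|P0 & G0| / |G0|``; 1 if G0 is empty."""
    P0, G0 = _as_mask(P0), _as_mask(G0)
    if P0.shape != G0.shape:
        raise ValueError("shape mismatch")
    g = int(G0.sum())
    if g == 0:
        return 1.0
    return int((P0 & G0).sum()) / g


_FACE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity cross


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask voxels with a face-adjacent non-mask neighbor.

    The volume border counts as outside, so a mask touching the border
    is surface there.
    """
    mask = _as_mask(mask)
    eroded = ndimage.binary_erosion(mask, structure=_FACE, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(P1, G1, spacing=(1.0, 1.0, 1.0), percentile: float = 100.0) -> float:
    """Surface Hausdorff distance in mm.

    ``percentile=100`` gives the classic maximum of the two directed
    suprema; ``percentile=95`` the robust Hausdorff95 (maximum of the two
    directed 95th percentiles).  Either mask empty -> NaN sentinel.
    """
    P1, G1 = _as_mask(P1), _as_mask(G1)
    if P1.shape != G1.shape:
        raise ValueError("shape mismatch")
    if not P1.any() or not G1.any():
        return UNDEFINED_DISTANCE
    sp = np.asarray(spacing, dtype=float)
    sp_pts = surface_voxels(P1) * sp
    sg_pts = surface_voxels(G1) * sp
    d_pg = cKDTree(sg_pts).query(sp_pts)[0]
    d_gp = cKDTree(sp_pts).query(sg_pts)[0]
    if percentile >= 100.0:
        return float(max(d_pg.max(), d_gp.max()))
    return float(max(np.percentile(d_pg, percentile), np.percentile(d_gp, percentile)))


@dataclass
class MetricsReport:
    """Per-region metric table for one case."""

    rows: dict[str, dict[str, float]]

    def as_row(self, case: str = "") -> dict[str, float | str]:
        """Flatten to one machine-readable record (for CSV export)."""
        out: dict[str, float | str] = {"case": case}
        for region, vals in self.rows.items():
            for k, v in vals.items():
                out[f"{region}_{k}"] = v
        return out


def evaluate_case(pred: LabelVolume, truth: LabelVolume,
                  spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    """All metrics for one case over the merged WT / TC / ET regions."""
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between prediction and ground truth")
    pm = merge_regions(pred)
    gm = merge_regions(truth)
    rows = {}
    for r in REGIONS:
        P1, G1 = pm[r].mask, gm[r].mask
        rows[r] = {
            "dice": dice(P1, G1),
            "sensitivity": sensitivity(P1, G1),
            "specificity": specificity(~P1, ~G1),
            "hausdorff": hausdorff(P1, G1, spacing, 100.0),
            "hausdorff95": hausdorff(P1, G1, spacing, 95.0),
        }
    return MetricsReport(rows)
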