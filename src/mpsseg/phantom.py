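"""Synthetic multi-modal brain-tumor phantoms with known ground truth.

A phantom is a zero-intensity background containing a brain ellipsoid
with a nested tumor: a necrotic core (label 1) inside an enhancing shell
(label 4) inside an edema shell (label 2) inside healthy brain (label 0
with nonzero intensity).  Each compartment has a modality-specific mean
intensity chosen so each region is conspicuous in the sequence where it
is conspicuous in real scans: edema is brightest in FLAIR, enhancing
tumor is brightest in T1C, and the necrotic center is dark in T1C.
Additive Gaussian noise (and an optional low-frequency multiplicative
bias field) are the only corruption modes.

The compartment geometry is ellipsoidal with per-axis semi-axes; the
nesting invariant NCR < TC < ED per axis is enforced at construction.
Class volumes are realistically imbalanced: on the default configuration
well over 90% of voxels are background or healthy brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import CHANNELS, LabelVolume, MultiModalVolume, write_labels, write_volume

#: Mean intensity per (compartment, sequence), arbitrary MR-like units.
#: Rows: background, healthy brain, ED, ET, NCR.
DEFAULT_INTENSITIES: dict[str, dict[str, float]] = {
    "background": {"t1": 0.0, "t1ce": 0.0, "t2": 0.0, "flair": 0.0},
    "healthy": {"t1": 100.0, "t1ce": 100.0, "t2": 80.0, "flair": 70.0},
    "ed": {"t1": 80.0, "t1ce": 80.0, "t2": 120.0, "flair": 140.0},
    "et": {"t1": 90.0, "t1ce": 160.0, "t2": 100.0, "flair": 100.0},
    "ncr": {"t1": 60.0, "t1ce": 40.0, "t2": 130.0, "flair": 90.0},
}


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of one synthetic case.

    ``radii`` maps compartment name (``ed``, ``tc``, ``ncr``) to ellipsoid
    semi-axes in voxels; nesting requires ``ncr < tc < ed`` per axis (the
    ET shell is the TC ellipsoid minus the NCR core).  ``noise_sd`` is the
    standard deviation of the additive Gaussian intensity noise; the
    default compartment separations are at least three times the default
    noise so a small network can learn the task quickly.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    brain_radius_fraction: float = 0.42
    tumor_center: tuple[float, float, float] | str = "random"
    radii: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ed": (14.0, 16.0, 12.0),
            "tc": (9.0, 10.0, 7.5),
            "ncr": (4.5, 5.0, 3.5),
        }
    )
    intensity_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITIES.items()}
    )
    noise_sd: float = 6.0
    bias_field: bool = False
    bias_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        ed, tc, ncr = (np.asarray(self.radii[k], float) for k in ("ed", "tc", "ncr"))
        if not (np.all(ncr < tc) and np.all(tc < ed)):
            raise ValueError("invalid compartment radii: nesting requires ncr < tc < ed per axis")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _bias(shape, rng, amplitude) -> np.ndarray:
    # one low-frequency cosine mode per axis, random phase
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    f = np.ones(shape, dtype=np.float64)
    for g, s in zip(grids, shape):
        f = f * (1.0 + amplitude * np.cos(np.pi * g / s + rng.uniform(0, 2 * np.pi)))
    return f


def generate_phantom(cfg: PhantomConfig) -> tuple[MultiModalVolume, LabelVolume]:
    """Generate one phantom case; identical config and seed give identical output."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(s) for s in cfg.shape)
    brain_center = np.array(shape, float) / 2.0 - 0.5
    brain_radii = np.array(shape, float) * cfg.brain_radius_fraction

    if isinstance(cfg.tumor_center, str):
        if cfg.tumor_center != "random":
            raise ValueError("tumor_center must be 3 floats or 'random'")
        # keep the ED ellipsoid inside the brain ellipsoid
        ed = np.asarray(cfg.radii["ed"], float)
        slack = np.maximum(brain_radii - ed, 0.0) * 0.55
        center = brain_center + rng.uniform(-1, 1, size=3) * slack
    else:
        center = np.asarray(cfg.tumor_center, float)

    ed_r = np.asarray(cfg.radii["ed"], float)
    if np.sum(((center - brain_center) / np.maximum(brain_radii - ed_r, 1e-9)) ** 2) > 1.0:
        raise ValueError("invalid compartment radii: tumor does not fit inside the brain")

    brain = _ellipsoid(shape, brain_center, brain_radii)
    ed_m = _ellipsoid(shape, center, cfg.radii["ed"]) & brain
    tc_m = _ellipsoid(shape, center, cfg.radii["tc"]) & brain
    ncr_m = _ellipsoid(shape, center, cfg.radii["ncr"]) & brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[ed_m] = 2
    labels[tc_m] = 4   # enhancing shell
    labels[ncr_m] = 1  # necrotic core

    compartment = np.full(shape, "background", dtype=object)
    compartment[brain] = "healthy"
    compartment[ed_m] = "ed"
    compartment[tc_m] = "et"
    compartment[ncr_m] = "ncr"

    data = np.zeros((len(CHANNELS),) + shape, dtype=np.float32)
    for ci, ch in enumerate(CHANNELS):
        for comp, table in cfg.intensity_table.items():
            data[ci][compartment == comp] = table[ch]
    if cfg.bias_field:
        data *= _bias(shape, rng, cfg.bias_amplitude)[None]
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
    # background stays exactly zero so the FLAIR-minimum patch constraint is meaningful
    data[:, ~brain] = 0.0

    vol = MultiModalVolume(data.astype(np.float32))
    return vol, LabelVolume(labels)


def generate_cohort(
    n: int,
    base_cfg: PhantomConfig | None = None,
    radius_jitter: float = 0.2,
    intensity_jitter: float = 0.05,
    max_retries: int = 20,
) -> list[tuple[MultiModalVolume, LabelVolume, PhantomConfig]]:
    """Generate ``n`` cases with jittered tumor geometry and contrast.

    Per-case seeds derive deterministically from ``base_cfg.seed``.
    Radii are scaled by independent uniform factors in ``1 +- radius_jitter``
    and intensities by ``1 +- intensity_jitter``; a draw that violates the
    nesting invariant is resampled, with a bounded number of retries.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_cfg if base_cfg is not None else PhantomConfig()
    master = np.random.default_rng(base.seed)
    cases = []
    for i in range(n):
        for attempt in range(max_retries):
            seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(seed)
            radii = {
                k: tuple(np.asarray(v, float) * rng.uniform(1 - radius_jitter, 1 + radius_jitter, 3))
                for k, v in base.radii.items()
            }
            table = {
                comp: {ch: m * rng.uniform(1 - intensity_jitter, 1 + intensity_jitter)
                       for ch, m in seqs.items()}
                for comp, seqs in base.intensity_table.items()
            }
            try:
                cfg = replace(base, radii=radii, intensity_table=table,
                              tumor_center="random", seed=seed)
                vol, lab = generate_phantom(cfg)
            except ValueError:
                continue
            cases.append((vol, lab, cfg))
            break
        else:
            raise RuntimeError(f"could not generate a valid case after {max_retries} retries")
    return cases


def write_case(vol: MultiModalVolume, lab: LabelVolume, directory, case: str) -> None:
    """Persist one case in the BraTS directory layout volume_io reads."""
    import os

    case_dir = os.path.join(str(directory), case)
    write_volume(vol, case_dir, case)
    write_labels(lab, os.path.join(case_dir, f"{case}_seg.nii.gz"), vol)
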