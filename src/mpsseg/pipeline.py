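"""End-to-end orchestration: phantoms -> patches -> training -> fusion -> CRF -> metrics.

A run is fully determined by a :class:`RunConfig`: every stochastic
stage draws its seed from the master seed via a spawned seed sequence,
so re-running a config reproduces its artifacts.  The ablation profiles
of the model-comparison experiment are encoded as named configuration
switches:

===========  ==============================================================
profile      meaning
===========  ==============================================================
mps_cnn      full model: spatial pooling indices, all three planes, CRF
model_A      plain max-pool + nearest upsampling instead of index unpooling
model_B/C/D  single plane only (axial / sagittal / coronal), no fusion/CRF
model_E      full model without the CRF refinement stage
model_F..J   loss ablations: unweighted/weighted Dice, unweighted/weighted
             log loss, multiclass focal loss
===========  ==============================================================
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dense_crf3d import CRFParams, mean_field_refine
from .fusion import argmax_labels, fuse_planes
from .losses import LossConfig
from .metrics import evaluate_case
from .patch_engine import sample_patches, standardize
from .phantom import PhantomConfig, generate_cohort
from .spatial_net import NetworkConfig, TrainConfig, predict_volume, train_network
from .volume_io import REGIONS

ALL_PLANES = ("axial", "coronal", "sagittal")

#: Training-patch share per plane, proportional to the reference extraction
#: counts (axial : coronal : sagittal = 111,690 : 142,160 : 118,400).
PLANE_PATCH_WEIGHTS = {"axial": 111690, "coronal": 142160, "sagittal": 118400}


@dataclass
class ProfileSpec:
    planes: tuple[str, ...] = ALL_PLANES
    use_indices: bool = True
    use_crf: bool = True
    loss_variant: str = "aggregated"


PROFILES: dict[str, ProfileSpec] = {
    "mps_cnn": ProfileSpec(),
    "model_A": ProfileSpec(use_indices=False),
    "model_B": ProfileSpec(planes=("axial",), use_crf=False),
    "model_C": ProfileSpec(planes=("sagittal",), use_crf=False),
    "model_D": ProfileSpec(planes=("coronal",), use_crf=False),
    "model_E": ProfileSpec(use_crf=False),
    "model_F": ProfileSpec(loss_variant="dice_unweighted"),
    "model_G": ProfileSpec(loss_variant="dice_weighted"),
    "model_H": ProfileSpec(loss_variant="log_unweighted"),
    "model_I": ProfileSpec(loss_variant="log_weighted"),
    "model_J": ProfileSpec(loss_variant="focal"),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    profile: str = "mps_cnn"
    n_train_cases: int = 10
    n_test_cases: int = 3
    val_fraction: float = 0.2  # case-level validation split
    patches_per_plane: int = 200
    patch_size: int = 32
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig(depth=2, base_filters=8))
    training: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=15, batch_size=16, learning_rate=3e-3))
    loss: LossConfig = field(default_factory=LossConfig)
    #: None -> CRFParams.scaled_to(phantom.shape): spatial kernel widths
    #: shrink with the volume, keeping the CRF's reach proportional to the
    #: anatomy it was tuned on.
    crf: CRFParams | None = None
    seed: int = 0
    out_dir: str | None = None

    @property
    def crf_params(self) -> CRFParams:
        if self.crf is not None:
            return self.crf
        return CRFParams.scaled_to(tuple(self.phantom.shape))

    def stage_seed(self, stage: str) -> int:
        h = abs(hash((self.seed, stage))) % (2**31 - 1)
        return h


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _plane_budget(total: int, plane: str) -> int:
    w = PLANE_PATCH_WEIGHTS[plane] / np.mean(list(PLANE_PATCH_WEIGHTS.values()))
    return max(1, int(round(total * w)))


def make_cohorts(cfg: RunConfig):
    """Generate train and held-out test phantom cohorts from the master seed."""
    s_train, s_test = _stage_seeds(cfg.seed, 2)
    train = generate_cohort(cfg.n_train_cases, replace(cfg.phantom, seed=s_train))
    test = generate_cohort(cfg.n_test_cases, replace(cfg.phantom, seed=s_test))
    return train, test


def run_pipeline(cfg: RunConfig, cohorts=None, trained=None) -> dict:
    """Execute all stages of the configured profile; returns a results dict.

    ``cohorts=(train, test)`` and ``trained={plane: net}`` allow re-using
    phantom cohorts and trained networks across ablation profiles that
    share them (the comparison experiment evaluates all profiles on one
    common test cohort).  When ``cfg.out_dir`` is set, models, label
    maps, metrics and logs are persisted there.
    """
    profile = PROFILES[cfg.profile]
    net_cfg = replace(cfg.network, use_indices=profile.use_indices)
    loss_cfg = replace(cfg.loss, variant=profile.loss_variant)

    train_cases, test_cases = cohorts if cohorts is not None else make_cohorts(cfg)
    n_val = max(1, int(round(cfg.val_fraction * len(train_cases)))) \
        if len(train_cases) > 1 else 0
    fit_cases, val_cases = train_cases[:len(train_cases) - n_val], \
        train_cases[len(train_cases) - n_val:]

    seeds = _stage_seeds(cfg.seed, 3 + 2 * len(profile.planes))
    nets, histories = {}, {}
    for pi, plane in enumerate(profile.planes):
        if trained is not None and plane in trained:
            nets[plane] = trained[plane]
            histories[plane] = []
            continue
        budget = _plane_budget(cfg.patches_per_plane, plane)
        rng = np.random.default_rng(seeds[3 + 2 * pi])
        patches, val_patches = [], []
        for ci, (vol, lab, _) in enumerate(fit_cases):
            sv = standardize(vol)
            per_case = max(1, budget // len(fit_cases))
            patches += sample_patches(sv, lab, plane, per_case, cfg.patch_size,
                                      rng, case_id=f"train{ci}")
        for ci, (vol, lab, _) in enumerate(val_cases):
            sv = standardize(vol)
            val_patches += sample_patches(sv, lab, plane, max(1, budget // 10),
                                          cfg.patch_size, rng, case_id=f"val{ci}")
        tc = replace(cfg.training, seed=seeds[3 + 2 * pi + 1])
        nets[plane], histories[plane] = train_network(
            patches, net_cfg, loss_cfg, tc, val_patches or None)

    reports, per_case_rows = [], []
    for ci, (vol, lab, _) in enumerate(test_cases):
        sv = standardize(vol)
        plane_maps = {pl: predict_volume(sv, pl, nets[pl]) for pl in profile.planes}
        if len(profile.planes) == 3:
            fused = fuse_planes(plane_maps["axial"], plane_maps["coronal"],
                                plane_maps["sagittal"])
        else:
            fused = plane_maps[profile.planes[0]]
        if profile.use_crf:
            _, pred = mean_field_refine(fused, sv, cfg.crf_params, mode="filtered")
        else:
            pred = argmax_labels(fused)
        report = evaluate_case(pred, lab, spacing=(1.0, 1.0, 1.0))
        reports.append((report, pred, fused, plane_maps))
        per_case_rows.append(report.as_row(f"test{ci}"))

    df = pd.DataFrame(per_case_rows)
    summary = {
        f"{r}_{m}_mean": float(df[f"{r}_{m}"].mean())
        for r in REGIONS for m in ("dice", "sensitivity", "specificity", "hausdorff95")
    }
    result = {
        "profile": cfg.profile,
        "nets": nets,
        "histories": histories,
        "per_case": df,
        "summary": summary,
        "details": reports,
        "test_truths": [lab for (_, lab, _) in test_cases],
        "config": cfg,
    }
    if cfg.out_dir:
        _persist(cfg, result, test_cases)
    return result


def _persist(cfg: RunConfig, result: dict, test_cases) -> None:
    from .volume_io import write_labels

    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    for plane, net in result["nets"].items():
        net.save(os.path.join(out, f"net_{plane}.npz"))
        if result["histories"][plane]:
            pd.DataFrame(result["histories"][plane]).to_csv(
                os.path.join(out, f"history_{plane}.csv"), index=False)
    result["per_case"].to_csv(os.path.join(out, "metrics.csv"), index=False)
    for ci, (report, pred, fused, _) in enumerate(result["details"]):
        write_labels(pred, os.path.join(out, f"test{ci}_pred.nii.gz"))
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump({"profile": cfg.profile, "seed": cfg.seed, **result["summary"]}, fh, indent=2)


def run_comparison(cfg: RunConfig) -> dict:
    """Train once, then score single-plane, fused, and fused+CRF variants.

    The three per-plane networks are trained exactly as in the full
    profile; every test case is then evaluated under five decision
    rules — each single plane alone, the fused average, and the fused
    average after CRF refinement — so the contribution of fusion and of
    the CRF stage can be compared on one common cohort without
    retraining.  Also reports the connected-component size spectrum of
    the predicted whole-tumor mask before and after the CRF (face
    connectivity), since removing small isolated components is the
    refinement's qualitative job.
    """
    from scipy import ndimage as _ndi

    base = run_pipeline(replace(cfg, profile="mps_cnn", out_dir=None))
    variants: dict[str, list] = {pl: [] for pl in ALL_PLANES}
    variants["fused"] = []
    variants["fused_crf"] = []
    comp_sizes = {"pre_crf": [], "post_crf": []}
    for ci, (report, pred, fused, plane_maps) in enumerate(base["details"]):
        truth = base["test_truths"][ci]
        for pl in ALL_PLANES:
            lab = argmax_labels(plane_maps[pl])
            variants[pl].append(evaluate_case(lab, truth).as_row(f"test{ci}"))
        pre = argmax_labels(fused)
        variants["fused"].append(evaluate_case(pre, truth).as_row(f"test{ci}"))
        variants["fused_crf"].append(report.as_row(f"test{ci}"))
        for key, labvol in (("pre_crf", pre), ("post_crf", pred)):
            wt = labvol.labels > 0
            marked, n = _ndi.label(wt)
            sizes = _ndi.sum_labels(wt, marked, index=range(1, n + 1))
            comp_sizes[key].append(np.asarray(sizes, dtype=int))
    return {
        "nets": base["nets"],
        "per_variant": {k: pd.DataFrame(v) for k, v in variants.items()},
        "component_sizes": comp_sizes,
        "base": base,
    }


def ablation_report(results: list[dict]) -> pd.DataFrame:
    """Summary table (min, quartiles, median, mean) per model and region.

    All runs must have been evaluated on a common test cohort (same
    number of cases); inconsistent runs are rejected.
    """
    sizes = {len(r["per_case"]) for r in results}
    if len(sizes) != 1:
        raise ValueError("inconsistent cohorts: runs evaluated on different case counts")
    rows = []
    for res in results:
        df = res["per_case"]
        if df.empty:
            raise ValueError(f"run {res['profile']} has no metrics")
        for r in REGIONS:
            for metric in ("dice", "hausdorff95"):
                s = df[f"{r}_{metric}"]
                rows.append({
                    "model": res["profile"], "region": r, "metric": metric,
                    "min": s.min(), "q1": s.quantile(0.25), "median": s.median(),
                    "q3": s.quantile(0.75), "max": s.max(), "mean": s.mean(),
                })
    return pd.DataFrame(rows)
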