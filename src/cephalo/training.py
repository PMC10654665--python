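"""Alternating two-stage training schedule.

One *cycle* = one backbone epoch (heatmap L2 loss) followed by a block of
refiner epochs (default 100) trained on freshly decoded stage-1 predictions
of the current backbone.  Refiner parameters are initialized once and persist
across cycles.  The backbone learning rate follows a milestone schedule
(full scale: 1e-4, dropping to 1e-5 at cycle 30 and 1e-6 at cycle 50 of 60).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .backbone import Adam, DataError, HeatmapModel, make_optimizer, train_backbone_epoch
from .core import ContractError, LandmarkSet
from .heatmaps import DEFAULT_SIGMA, HeatmapStack, decode
from .metrics import MetricsReport, radial_errors, summarize
from .refiner import RefinerModel, train_refiner
from .synthetic import SyntheticDataset


class TrainingError(RuntimeError):
    pass


@dataclass
class CycleSchedule:
    cycles: int = 60
    backbone_epochs_per_cycle: int = 1
    refiner_epochs_per_cycle: int = 100
    backbone_lr: float = 1e-4
    lr_milestones: Dict[int, float] = field(default_factory=lambda: {30: 1e-5, 50: 1e-6})
    batch_size: int = 16
    sigma: float = DEFAULT_SIGMA
    normalized_heatmaps: bool = False  # peak-1 targets train better at desk scale
    decode_offset: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ContractError("cycles must be >= 0")

    def lr_at(self, cycle: int) -> float:
        lr = self.backbone_lr
        for milestone in sorted(self.lr_milestones):
            if cycle >= milestone:
                lr = self.lr_milestones[milestone]
        return lr


def decode_dataset(
    model: HeatmapModel,
    ds: SyntheticDataset,
    sigma: float = DEFAULT_SIGMA,
    offset: bool = True,
    batch_size: int = 16,
) -> List[LandmarkSet]:
    """Forward + decode every image of a dataset to stage-1 landmark sets
    expressed in the original (template) space."""
    scheme = ds.gt[0].scheme
    space = ds.gt[0].space
    out: List[LandmarkSet] = []
    for start in range(0, ds.n, batch_size):
        maps = model.forward(ds.images[start : start + batch_size], train=False)
        for m in maps:
            hs = HeatmapStack(maps=m, sigma=sigma, reduction=4, crop=ds.crop)
            out.append(decode(hs, scheme, space, offset=offset))
    return out


def evaluate_predictions(
    stage1_sets: Sequence[LandmarkSet],
    gt_sets: Sequence[LandmarkSet],
    refiner: Optional[RefinerModel] = None,
) -> Tuple[MetricsReport, Optional[MetricsReport]]:
    """Metrics with and without refinement from shared stage-1 predictions."""
    report_stage1 = summarize(radial_errors(list(stage1_sets), list(gt_sets)))
    report_refined = None
    if refiner is not None:
        refined = [refiner.refine(s) for s in stage1_sets]
        report_refined = summarize(radial_errors(refined, list(gt_sets)))
    return report_stage1, report_refined


def evaluate_checkpoint(
    model: HeatmapModel,
    refiner: Optional[RefinerModel],
    ds: SyntheticDataset,
    sigma: float = DEFAULT_SIGMA,
    offset: bool = True,
) -> Tuple[MetricsReport, Optional[MetricsReport]]:
    """Ablation pair (stage-1 report, refined report) on one dataset.

    Both reports are computed from the *same* decoded stage-1 predictions.
    """
    stage1 = decode_dataset(model, ds, sigma=sigma, offset=offset)
    return evaluate_predictions(stage1, ds.gt, refiner)


def run_cycles(
    schedule: CycleSchedule,
    model: HeatmapModel,
    refiner: RefinerModel,
    train_ds: SyntheticDataset,
    eval_ds: SyntheticDataset,
    optimizer: Optional[Adam] = None,
) -> Tuple[HeatmapModel, RefinerModel, pd.DataFrame]:
    """Run the alternating schedule and return models plus a per-cycle trace.

    The trace has one row per cycle with columns ``cycle``, ``backbone_loss``,
    ``refiner_loss``, ``train_mre_mm`` and ``eval_mre_mm`` (refined MRE).
    """
    if train_ds.n == 0 or eval_ds.n == 0:
        raise DataError("empty dataset")
    optimizer = optimizer or make_optimizer(model, lr=schedule.backbone_lr)
    rng = np.random.default_rng(schedule.seed)
    targets = train_ds.target_maps(
        sigma=schedule.sigma, normalized=schedule.normalized_heatmaps
    )
    rows: List[dict] = []
    for cycle in range(schedule.cycles):
        optimizer.lr = schedule.lr_at(cycle)
        backbone_loss = float("nan")
        for _ in range(schedule.backbone_epochs_per_cycle):
            backbone_loss = train_backbone_epoch(
                model, train_ds.images, targets, optimizer,
                batch_size=schedule.batch_size, rng=rng,
            )
        stage1_train = decode_dataset(
            model, train_ds, sigma=schedule.sigma, offset=schedule.decode_offset
        )
        _, refiner_trace = train_refiner(
            refiner, stage1_train, train_ds.gt, epochs=schedule.refiner_epochs_per_cycle
        )
        refiner_loss = refiner_trace[-1] if refiner_trace else float("nan")

        _, train_report = evaluate_predictions(stage1_train, train_ds.gt, refiner)
        _, eval_report = evaluate_checkpoint(
            model, refiner, eval_ds, sigma=schedule.sigma, offset=schedule.decode_offset
        )
        row = {
            "cycle": cycle,
            "backbone_loss": backbone_loss,
            "refiner_loss": refiner_loss,
            "train_mre_mm": train_report.mre,
            "eval_mre_mm": eval_report.mre,
        }
        for key in ("backbone_loss", "refiner_loss", "train_mre_mm", "eval_mre_mm"):
            if not np.isfinite(row[key]):
                raise TrainingError(f"non-finite {key} at cycle {cycle}")
        rows.append(row)
    columns = ["cycle", "backbone_loss", "refiner_loss", "train_mre_mm", "eval_mre_mm"]
    trace = pd.DataFrame(rows, columns=columns)
    return model, refiner, trace
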