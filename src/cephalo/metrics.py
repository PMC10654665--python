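"""Radial-error evaluation: MRE, SD, per-axis errors, and SDR at mm thresholds.

All quantities default to millimetres; pass ``unit='px'`` to stay in pixels.
The standard deviation uses the sample (n-1) denominator.  "Within t mm" is
interpreted inclusively (R <= t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import N_LANDMARKS, ContractError, LandmarkSet, check_compatible

DEFAULT_THRESHOLDS_MM: Tuple[float, ...] = (2.0, 2.5, 3.0, 4.0)


class DataError(ValueError):
    """Not enough data for the requested summary."""


@dataclass
class RadialErrors:
    """Per-image, per-landmark radial and axis errors.

    Arrays have shape ``(n_images, 23)``.  ``dx``/``dy`` are absolute axis
    differences and satisfy ``r == sqrt(dx**2 + dy**2)`` to 1e-9.
    """

    dx: np.ndarray
    dy: np.ndarray
    r: np.ndarray
    unit: str = "mm"

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "r"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.shape[1] != N_LANDMARKS:
                raise ContractError(f"{name} must have {N_LANDMARKS} columns")
            setattr(self, name, arr)
        if not (self.dx.shape == self.dy.shape == self.r.shape):
            raise ContractError("dx, dy, r must share a shape")

    @property
    def n_images(self) -> int:
        return self.r.shape[0]


def radial_errors(
    pred: "LandmarkSet | Sequence[LandmarkSet]",
    gt: "LandmarkSet | Sequence[LandmarkSet]",
    unit: str = "mm",
) -> RadialErrors:
    """Absolute per-axis differences and radial errors between predictions and truth."""
    preds = [pred] if isinstance(pred, LandmarkSet) else list(pred)
    gts = [gt] if isinstance(gt, LandmarkSet) else list(gt)
    if len(preds) != len(gts):
        raise ContractError("prediction and ground-truth lists differ in length")
    if not preds:
        raise DataError("at least one image is required")
    dx_rows, dy_rows = [], []
    for p, g in zip(preds, gts):
        check_compatible(p, g)
        delta = np.abs(p.coords - g.coords)
        if unit == "mm":
            delta = delta * g.space.require_spacing()
        elif unit != "px":
            raise ValueError(f"unknown unit {unit!r}")
        dx_rows.append(delta[:, 0])
        dy_rows.append(delta[:, 1])
    dx = np.vstack(dx_rows)
    dy = np.vstack(dy_rows)
    return RadialErrors(dx=dx, dy=dy, r=np.hypot(dx, dy), unit=unit)


def _mean_sd(values: np.ndarray) -> Tuple[float, float]:
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n >= 2 else float("nan")
    return mean, sd


def _sdr(values: np.ndarray, thresholds: Sequence[float]) -> Dict[float, float]:
    n = values.size
    return {float(t): 100.0 * float(np.count_nonzero(values <= t)) / n for t in thresholds}


@dataclass
class MetricsReport:
    """Aggregate + per-landmark MRE/SD/axis-error/SDR summary."""

    mre: float
    sd: float
    dx_mean: float
    dx_sd: float
    dy_mean: float
    dy_sd: float
    sdr: Dict[float, float]
    n: int
    per_landmark: pd.DataFrame
    unit: str = "mm"

    def to_frame(self) -> pd.DataFrame:
        """Per-landmark table with an 'Average' row, mirroring the per-landmark report."""
        avg = {
            "landmark": "Average",
            "mre": self.mre,
            "sd": self.sd,
            "dx": self.dx_mean,
            "dx_sd": self.dx_sd,
            "dy": self.dy_mean,
            "dy_sd": self.dy_sd,
        }
        for t, v in self.sdr.items():
            avg[f"sdr_{t}"] = v
        return pd.concat(
            [self.per_landmark, pd.DataFrame([avg])], ignore_index=True
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "n": self.n,
            "mre": self.mre,
            "sd": self.sd,
            "dx_mean": self.dx_mean,
            "dx_sd": self.dx_sd,
            "dy_mean": self.dy_mean,
            "dy_sd": self.dy_sd,
            "sdr": {str(t): v for t, v in self.sdr.items()},
        }


def summarize(
    errors: RadialErrors,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_MM,
    scheme_names: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Summarize radial errors into MRE, SD, axis means and SDR.

    MRE is the mean of all pooled radial errors; SD is their sample standard
    deviation (n-1 denominator, NaN when only one value is available).  SDR
    at threshold t is the percentage of radial errors with ``R <= t``.
    """
    r = errors.r.ravel()
    if r.size == 0:
        raise DataError("cannot summarize an empty error set")
    mre, sd = _mean_sd(r)
    dx_mean, dx_sd = _mean_sd(errors.dx.ravel())
    dy_mean, dy_sd = _mean_sd(errors.dy.ravel())
    sdr = _sdr(r, thresholds)

    names = list(scheme_names) if scheme_names is not None else [
        f"L{i}" for i in range(1, N_LANDMARKS + 1)
    ]
    rows = []
    for j in range(N_LANDMARKS):
        rj = errors.r[:, j]
        m, s = _mean_sd(rj)
        dxm, dxs = _mean_sd(errors.dx[:, j])
        dym, dys = _mean_sd(errors.dy[:, j])
        row = {
            "landmark": names[j],
            "mre": m,
            "sd": s,
            "dx": dxm,
            "dx_sd": dxs,
            "dy": dym,
            "dy_sd": dys,
        }
        for t, v in _sdr(rj, thresholds).items():
            row[f"sdr_{t}"] = v
        rows.append(row)

    return MetricsReport(
        mre=mre,
        sd=sd,
        dx_mean=dx_mean,
        dx_sd=dx_sd,
        dy_mean=dy_mean,
        dy_sd=dy_sd,
        sdr=sdr,
        n=int(r.size),
        per_landmark=pd.DataFrame(rows),
        unit=errors.unit,
    )


def mre_of(pred_sets, gt_sets, unit: str = "mm") -> float:
    """Convenience: pooled mean radial error of a prediction/truth pairing."""
    return summarize(radial_errors(pred_sets, gt_sets, unit=unit)).mre
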