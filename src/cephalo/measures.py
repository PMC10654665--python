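"""Eight clinical measures, three-way face-type classification, and SCR.

Measure recipes are expressed over 1-based landmark indices.  Angular sums
(ODI, APDI) use *signed* line-to-line angles; see
:func:`cephalo.core.angle_between_lines` for the sign convention.

Two of the published classification bands are internally inconsistent and are
corrected here (the corrections are configurable via custom
:class:`MeasureDefinition` instances):

* the mandibular-position bands list "retrognathic > 74.6" / "prognathic
  < 78.7", which would overlap the normal band on both sides; this package
  uses retrognathic < 74.6 and prognathic > 78.7 (the conventional reading);
* the overbite-depth "open tendency < 68.4" band would leave (68.4, 78.4)
  unclassified; values below the normal band's lower edge (78.4) are
  classified as open tendency;
* the incisal-distance band for "edge to edge" is taken as values below the
  normal band (< 2 mm); values above 4.5 mm are "large overjet".

Normal-range boundaries are inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd

from .core import (
    ContractError,
    LandmarkSet,
    angle_at_vertex,
    angle_between_lines,
    distance,
)

TYPE1, TYPE2, TYPE3 = "type1", "type2", "type3"


class MeasureError(ValueError):
    """Degenerate geometry encountered while computing a clinical measure."""


@dataclass(frozen=True)
class MeasureDefinition:
    """A named clinical measure: geometric recipe plus classification bands."""

    name: str
    unit: str  # "deg", "ratio" or "mm"
    recipe: Callable[[LandmarkSet], float]
    lo: float
    hi: float
    above_class: str  # label for value > hi
    below_class: str  # label for value < lo
    description: str = ""

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ContractError(f"{self.name}: band must satisfy lo <= hi")
        if {self.above_class, self.below_class} - {TYPE2, TYPE3}:
            raise ContractError(f"{self.name}: off-normal classes must be type2/type3")
        if self.above_class == self.below_class:
            raise ContractError(f"{self.name}: above/below classes must differ")


def _L(ls: LandmarkSet, i: int) -> np.ndarray:
    return ls.point(i)


def _anb(ls: LandmarkSet) -> float:
    return angle_at_vertex(_L(ls, 5), _L(ls, 2), _L(ls, 6))


def _snb(ls: LandmarkSet) -> float:
    return angle_at_vertex(_L(ls, 1), _L(ls, 2), _L(ls, 6))


def _sna(ls: LandmarkSet) -> float:
    return angle_at_vertex(_L(ls, 1), _L(ls, 2), _L(ls, 5))


def _odi(ls: LandmarkSet) -> float:
    a = angle_between_lines(_L(ls, 5), _L(ls, 6), _L(ls, 8), _L(ls, 10), signed=True)
    b = angle_between_lines(_L(ls, 3), _L(ls, 4), _L(ls, 17), _L(ls, 18), signed=True)
    return a + b


def _apdi(ls: LandmarkSet) -> float:
    a = angle_between_lines(_L(ls, 3), _L(ls, 4), _L(ls, 2), _L(ls, 7), signed=True)
    b = angle_between_lines(_L(ls, 2), _L(ls, 7), _L(ls, 5), _L(ls, 6), signed=True)
    c = angle_between_lines(_L(ls, 3), _L(ls, 4), _L(ls, 17), _L(ls, 18), signed=True)
    return a + b + c


def _fhi(ls: LandmarkSet) -> float:
    pfh = distance(_L(ls, 1), _L(ls, 10))
    afh = distance(_L(ls, 2), _L(ls, 8))
    if afh == 0.0:
        raise MeasureError("FHI: anterior face height is zero")
    return pfh / afh


def _fma(ls: LandmarkSet) -> float:
    return angle_between_lines(_L(ls, 1), _L(ls, 2), _L(ls, 10), _L(ls, 9), signed=False)


def _mw(ls: LandmarkSet) -> float:
    return distance(_L(ls, 12), _L(ls, 11), space=ls.space, unit="mm")


def default_measures() -> Dict[str, MeasureDefinition]:
    """The eight measures with their (corrected) classification bands."""
    return {
        "ANB": MeasureDefinition(
            "ANB", "deg", _anb, 3.2, 5.7, above_class=TYPE2, below_class=TYPE3,
            description="angle at L2 between L5 and L6",
        ),
        "SNB": MeasureDefinition(
            "SNB", "deg", _snb, 74.6, 78.7, above_class=TYPE3, below_class=TYPE2,
            description="angle at L2 between L1 and L6; retrognathic below, prognathic above",
        ),
        "SNA": MeasureDefinition(
            "SNA", "deg", _sna, 79.4, 83.2, above_class=TYPE2, below_class=TYPE3,
            description="angle at L2 between L1 and L5",
        ),
        "ODI": MeasureDefinition(
            "ODI", "deg", _odi, 78.4, 80.5, above_class=TYPE2, below_class=TYPE3,
            description="signed angle(L5-L6, L8-L10) + signed angle(L3-L4, L17-L18)",
        ),
        "APDI": MeasureDefinition(
            "APDI", "deg", _apdi, 77.6, 85.2, above_class=TYPE3, below_class=TYPE2,
            description="sum of three signed line angles over L3-L4, L2-L7, L5-L6, L17-L18",
        ),
        "FHI": MeasureDefinition(
            "FHI", "ratio", _fhi, 0.65, 0.75, above_class=TYPE2, below_class=TYPE3,
            description="dist(L1, L10) / dist(L2, L8)",
        ),
        "FMA": MeasureDefinition(
            "FMA", "deg", _fma, 26.8, 31.4, above_class=TYPE2, below_class=TYPE3,
            description="unsigned angle between lines L1-L2 and L10-L9",
        ),
        "MW": MeasureDefinition(
            "MW", "mm", _mw, 2.0, 4.5, above_class=TYPE3, below_class=TYPE2,
            description="distance between L12 and L11 in mm",
        ),
    }


MEASURE_NAMES = ("ANB", "SNB", "SNA", "ODI", "APDI", "FHI", "FMA", "MW")


def compute_measure(definition: MeasureDefinition, ls: LandmarkSet) -> float:
    """Evaluate a measure's geometric recipe on a landmark set."""
    try:
        value = definition.recipe(ls)
    except (MeasureError, ValueError) as exc:
        raise MeasureError(f"{definition.name}: {exc}") from exc
    if not np.isfinite(value):
        raise MeasureError(f"{definition.name}: non-finite value {value}")
    return float(value)


def classify(definition: MeasureDefinition, value: float) -> str:
    """Map a measure value to type1/type2/type3 (normal band inclusive)."""
    if not np.isfinite(value):
        raise ValueError(f"{definition.name}: cannot classify non-finite value")
    if definition.lo <= value <= definition.hi:
        return TYPE1
    return definition.above_class if value > definition.hi else definition.below_class


def compute_all(ls: LandmarkSet, measures: Dict[str, MeasureDefinition] | None = None) -> Dict[str, float]:
    measures = measures or default_measures()
    return {name: compute_measure(d, ls) for name, d in measures.items()}


@dataclass
class MeasureReport:
    """Per-image measure values/classes and per-measure SCR over an image set."""

    table: pd.DataFrame  # one row per image: value_* and class_* columns, gt & pred
    scr: Dict[str, float]  # measure name -> % of images with matching class

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {"scr": dict(self.scr), "n_images": int(len(self.table))}


def scr(
    gt_sets: Sequence[LandmarkSet],
    pred_sets: Sequence[LandmarkSet],
    measures: Dict[str, MeasureDefinition] | None = None,
    image_ids: Sequence[str] | None = None,
) -> MeasureReport:
    """Successful classification rate per measure across paired image sets."""
    gt_sets = list(gt_sets)
    pred_sets = list(pred_sets)
    if len(gt_sets) != len(pred_sets):
        raise ContractError("ground-truth and prediction sets differ in length")
    if not gt_sets:
        raise ContractError("at least one image is required")
    measures = measures or default_measures()
    ids = list(image_ids) if image_ids is not None else [
        f"img{i:04d}" for i in range(len(gt_sets))
    ]

    rows: List[dict] = []
    matches = {name: 0 for name in measures}
    for image_id, g, p in zip(ids, gt_sets, pred_sets):
        row: dict = {"image_id": image_id}
        for name, d in measures.items():
            vg = compute_measure(d, g)
            vp = compute_measure(d, p)
            cg = classify(d, vg)
            cp = classify(d, vp)
            row[f"{name}_gt"] = vg
            row[f"{name}_pred"] = vp
            row[f"{name}_class_gt"] = cg
            row[f"{name}_class_pred"] = cp
            if cg == cp:
                matches[name] += 1
        rows.append(row)

    n = len(gt_sets)
    rates = {name: 100.0 * m / n for name, m in matches.items()}
    return MeasureReport(table=pd.DataFrame(rows), scr=rates)
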