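"""Tumor-response labeling and the IHC expression score.

RECIST here is the abridged single-lesion variant: the percentage change
between the initial largest tumor diameter and the diameter after two
treatment cycles decides the category (CR on complete resolution, PR at
>= 30% decrease, PD on new lesions or >= 20% increase, SD otherwise), and
responders are CR + PR. The IHC score multiplies a 0-3 staining intensity
by a 0-3 staining-area score with a high/low cutoff at 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORY_ORDER = {"PD": 0, "SD": 1, "PR": 2, "CR": 3}
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


class LabelingError(ValueError):
    pass


@dataclass(frozen=True)
class TumorMeasurement:
    patient_id: str
    initial_diameter: float  # cm, largest diameter before treatment
    post_cycle2_diameter: float  # cm, after two cycles
    new_lesions: bool = False

    def __post_init__(self) -> None:
        if not self.initial_diameter > 0:
            raise LabelingError("initial diameter must be > 0")
        if self.post_cycle2_diameter < 0:
            raise LabelingError("post-treatment diameter must be >= 0")


@dataclass(frozen=True)
class RecistLabel:
    category: str  # CR / PR / SD / PD
    reduction_pct: float  # 100 * (initial - post) / initial; negative = growth

    @property
    def responder(self) -> bool:
        return self.category in RESPONDER_CATEGORIES


def recist_classify(m: TumorMeasurement) -> RecistLabel:
    """Single-lesion RECIST category from initial vs post-cycle-2 diameter.

    New lesions dominate (PD); complete resolution without new lesions is
    CR; a decrease >= 30% is PR; an increase >= 20% is PD; else SD.
    """
    reduction = 100.0 * (m.initial_diameter - m.post_cycle2_diameter) / m.initial_diameter
    # round off float noise so exact 30%/20% boundary measurements classify
    # per the stated closed thresholds
    reduction = round(reduction, 9)
    if m.new_lesions:
        category = "PD"
    elif m.post_cycle2_diameter == 0:
        category = "CR"
    elif reduction <= -20.0:
        category = "PD"
    elif reduction >= 30.0:
        category = "PR"
    else:
        category = "SD"
    return RecistLabel(category=category, reduction_pct=reduction)


def label_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """RECIST-label every row of a clinical table.

    Requires columns patient_id, initial_diameter_cm, post_cycle2_diameter_cm
    and optionally new_lesions (0/1). Returns patient_id, category,
    responder, reduction_pct.
    """
    rows = []
    for _, row in clinical.iterrows():
        m = TumorMeasurement(
            patient_id=str(row["patient_id"]),
            initial_diameter=float(row["initial_diameter_cm"]),
            post_cycle2_diameter=float(row["post_cycle2_diameter_cm"]),
            new_lesions=bool(row.get("new_lesions", False)),
        )
        label = recist_classify(m)
        rows.append((m.patient_id, label.category, label.responder, label.reduction_pct))
    return pd.DataFrame(
        rows, columns=["patient_id", "category", "responder", "reduction_pct"]
    )


# ---------------------------------------------------------------------------
# IHC scoring
# ---------------------------------------------------------------------------

IHC_CUTOFF = 3


@dataclass(frozen=True)
class IhcScore:
    intensity: int  # 0-3
    area: int  # 0-3
    cutoff: int = IHC_CUTOFF

    @property
    def score(self) -> int:
        return self.intensity * self.area

    @property
    def expression_class(self) -> str:
        return "high" if self.score >= self.cutoff else "low"


def area_score(area_fraction: float) -> int:
    """Staining-area score: 0 for no staining, 1 for (0, 30%], 2 for
    (30%, 70%], 3 above 70%."""
    if not 0.0 <= area_fraction <= 1.0:
        raise LabelingError(f"area fraction must be in [0, 1], got {area_fraction}")
    if area_fraction == 0:
        return 0
    if area_fraction <= 0.30:
        return 1
    if area_fraction <= 0.70:
        return 2
    return 3


def ihc_score(intensity: int, area_fraction: float, cutoff: int = IHC_CUTOFF) -> IhcScore:
    """Intensity (0-3) x area score, classed high iff score >= cutoff."""
    if intensity not in (0, 1, 2, 3):
        raise LabelingError(f"intensity must be an integer in 0..3, got {intensity}")
    return IhcScore(intensity=intensity, area=area_score(area_fraction), cutoff=cutoff)
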