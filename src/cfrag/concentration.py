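"""Longitudinal cfDNA concentration analytics.

The cfDNA ratio divides the concentration at T2 (day 1 after the first
chemotherapy cycle) by the pretreatment concentration at T1. Paired
time-point comparisons use the Wilcoxon signed-rank test; the SCC-Ag panel
derives the ratio/difference parameters used for comparison with the cfDNA
ratio; correlations are Spearman by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluation import WilcoxonResult, wilcoxon_signed_rank

TIME_POINTS = tuple(f"T{i}" for i in range(1, 15))
CONFOUNDER_FLAGS = frozenset({"infection", "bone_marrow_depression", "other_confounder"})


class ConcentrationError(ValueError):
    pass


class MissingTimePointError(ConcentrationError):
    pass


class UndefinedRatioError(ConcentrationError):
    pass


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-patient cfDNA ng/mL values keyed by treatment time point."""

    patient_id: str
    values: dict[str, float]
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        for tp, value in self.values.items():
            if tp not in TIME_POINTS:
                raise ConcentrationError(
                    f"unknown time point {tp!r}; expected one of T1..T14"
                )
            if not value > 0:
                raise ConcentrationError(
                    f"{self.patient_id} {tp}: concentration must be > 0, got {value}"
                )
        unknown = set(self.flags) - CONFOUNDER_FLAGS
        if unknown:
            raise ConcentrationError(f"unknown confounder flags: {sorted(unknown)}")

    @property
    def confounded(self) -> bool:
        return bool(self.flags)


def cfdna_ratio(series: ConcentrationSeries) -> float:
    """T2 concentration divided by T1 concentration."""
    missing = [tp for tp in ("T1", "T2") if tp not in series.values]
    if missing:
        raise MissingTimePointError(
            f"{series.patient_id}: missing time point(s) {missing}"
        )
    return series.values["T2"] / series.values["T1"]


def ratio_group(ratio: float, threshold: float = 2.0) -> str:
    """Threshold grouping of the cfDNA ratio (boundary goes to '<=')."""
    return f"<={threshold:g}" if ratio <= threshold else f">{threshold:g}"


def exclude_confounded(
    cohort: Iterable[ConcentrationSeries],
) -> tuple[list[ConcentrationSeries], list[ConcentrationSeries]]:
    """Cohort-level split into (kept, excluded-for-confounders)."""
    kept, excluded = [], []
    for series in cohort:
        (excluded if series.confounded else kept).append(series)
    return kept, excluded


@dataclass(frozen=True)
class PairedTimepointResult:
    time_point_a: str
    time_point_b: str
    n_pairs: int
    n_dropped_missing: int
    statistic: float
    p_value: float
    method: str


def paired_timepoint_test(
    cohort: Sequence[ConcentrationSeries], tp_a: str, tp_b: str
) -> PairedTimepointResult:
    """Two-sided Wilcoxon signed-rank on paired concentrations at two time
    points; patients missing either time point are dropped and counted."""
    pairs = [
        (s.values[tp_a], s.values[tp_b])
        for s in cohort
        if tp_a in s.values and tp_b in s.values
    ]
    dropped = len(list(cohort)) - len(pairs)
    if len(pairs) < 2:
        raise ConcentrationError(
            f"need >= 2 complete pairs for {tp_a} vs {tp_b}, got {len(pairs)}"
        )
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    res: WilcoxonResult = wilcoxon_signed_rank(b, a)
    return PairedTimepointResult(
        time_point_a=tp_a,
        time_point_b=tp_b,
        n_pairs=len(pairs),
        n_dropped_missing=dropped,
        statistic=res.statistic,
        p_value=res.p_value,
        method=res.method,
    )


@dataclass(frozen=True)
class SccAgPanel:
    """Three SCC-Ag levels and derived comparison parameters.

    Derived parameters are recomputed from the stored levels on access and
    are None when an operand is missing: ratio1 = scc2/scc1, ratio2 =
    scc3/scc1, diff1 = scc2 - scc1, diff2 = scc3 - scc1.
    """

    scc1: float | None
    scc2: float | None
    scc3: float | None

    def _ratio(self, other: float | None) -> float | None:
        if other is None or self.scc1 is None:
            return None
        if self.scc1 == 0:
            raise UndefinedRatioError("SCC-Ag ratio undefined: pretreatment level is 0")
        return other / self.scc1

    def _diff(self, other: float | None) -> float | None:
        if other is None or self.scc1 is None:
            return None
        return other - self.scc1

    @property
    def ratio1(self) -> float | None:
        return self._ratio(self.scc2)

    @property
    def ratio2(self) -> float | None:
        return self._ratio(self.scc3)

    @property
    def diff1(self) -> float | None:
        return self._diff(self.scc2)

    @property
    def diff2(self) -> float | None:
        return self._diff(self.scc3)

    def as_dict(self) -> dict:
        return {
            "scc1": self.scc1,
            "scc2": self.scc2,
            "scc3": self.scc3,
            "ratio1": self.ratio1,
            "ratio2": self.ratio2,
            "diff1": self.diff1,
            "diff2": self.diff2,
        }


def scc_ag_panel(
    scc1: float | None, scc2: float | None = None, scc3: float | None = None
) -> SccAgPanel:
    def _clean(x):
        return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)

    return SccAgPanel(_clean(scc1), _clean(scc2), _clean(scc3))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


class ConstantInputError(ConcentrationError):
    pass


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> CorrelationResult:
    """Correlation with two-sided p; Spearman (tie-corrected ranks) by
    default, Pearson available."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConcentrationError("vectors must have equal length")
    if x.size < 3:
        raise ConcentrationError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ConcentrationError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(rho), float(p), int(x.size), method)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def read_concentration_table(path) -> list[ConcentrationSeries]:
    """Long-format table: patient_id, time_point, ng_per_ml, flags
    (semicolon-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "time_point": str})
    series = []
    for pid, sub in df.groupby("patient_id", sort=True):
        flags: set[str] = set()
        if "flags" in sub.columns:
            for raw in sub["flags"].fillna(""):
                flags.update(f for f in str(raw).split(";") if f)
        values = dict(zip(sub["time_point"], sub["ng_per_ml"].astype(float)))
        series.append(ConcentrationSeries(pid, values, frozenset(flags)))
    return series


def write_concentration_table(cohort: Iterable[ConcentrationSeries], path) -> None:
    rows = []
    for s in cohort:
        flag_str = ";".join(sorted(s.flags))
        for tp in TIME_POINTS:
            if tp in s.values:
                rows.append((s.patient_id, tp, s.values[tp], flag_str))
    pd.DataFrame(
        rows, columns=["patient_id", "time_point", "ng_per_ml", "flags"]
    ).to_csv(path, sep="\t", index=False)
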