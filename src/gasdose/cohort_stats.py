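"""Cohort-level GPR-vs-AGV analysis.

Aggregates per-patient gamma passing rates (one per plan comparison) and the
active gas volume into summary statistics, Pearson correlations, and a
linear trend from which the AGV threshold where the fitted GPR crosses 90%
(the TG-218 action level for IMRT plan QA) is interpolated.  A 21-patient
reference cohort ships with the package as a CSV fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COMPARISONS",
    "AGVRecord",
    "TrendFit",
    "GprAgvTrend",
    "load_table1_fixture",
    "records_to_frame",
    "frame_to_records",
    "read_records_csv",
    "write_records_csv",
    "cohort_summary",
    "pearson_r",
    "fit_trend",
]

COMPARISONS = ("WPLANvsAPLAN", "WPLANvsGPLAN", "GPLANvsAPLAN")
_CSV_COLUMNS = {"WPLANvsAPLAN": "gprWA", "WPLANvsGPLAN": "gprWG",
                "GPLANvsAPLAN": "gprGA"}


@dataclass
class AGVRecord:
    """One patient's mean GPR (%) per plan comparison and AGV (cc)."""

    patient: str
    gpr: dict[str, float]
    agv_cc: float

    def __post_init__(self) -> None:
        unknown = set(self.gpr) - set(COMPARISONS)
        if unknown:
            raise ValueError(f"unknown comparisons: {sorted(unknown)}")
        for comp, value in self.gpr.items():
            if not (0.0 <= value <= 100.0):
                raise ValueError(f"GPR for {comp} out of [0, 100]: {value}")
        if self.agv_cc < 0:
            raise ValueError("AGV must be >= 0")


@dataclass
class TrendFit:
    """Linear GPR-vs-AGV trend for one plan comparison.

    slope/intercept/r_squared describe the OLS line of GPR (%) on AGV (cc),
    as plotted.  ``agv_at_90`` is the AGV at which the trend crosses a GPR of
    90%, interpolated from the inverse (calibration) regression of AGV on
    GPR evaluated at 90% — the estimator appropriate for predicting the AGV
    working point from a GPR level; ``agv_at_90_from_gpr_fit`` is the
    closed-form crossing (90 - intercept)/slope of the forward line.  Both
    are None when the trend is non-decreasing (flagged, no threshold).
    """

    comparison: str
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    agv_at_90: float | None
    agv_at_90_from_gpr_fit: float | None
    n: int

    def summary(self) -> str:
        lines = [
            f"GPR vs AGV linear trend -- {self.comparison} (n = {self.n})",
            f"  slope      {self.slope:10.4f}  %/cc",
            f"  intercept  {self.intercept:10.2f}  %",
            f"  R^2        {self.r_squared:10.3f}",
            f"  Pearson r  {self.pearson_r:10.2f}",
        ]
        if self.agv_at_90 is None:
            lines.append("  AGV @ GPR=90%: undefined (non-negative slope)")
        else:
            lines.append(f"  AGV @ GPR=90%  {self.agv_at_90:7.0f}  cc"
                         f"  (forward-fit crossing {self.agv_at_90_from_gpr_fit:.0f} cc)")
        return "\n".join(lines)


def load_table1_fixture() -> list[AGVRecord]:
    """The packaged 21-patient reference cohort (integer GPRs, AGV in cc)."""
    with resources.files("gasdose.data").joinpath("table1.csv").open() as fh:
        frame = pd.read_csv(fh)
    return frame_to_records(frame)


def records_to_frame(records: list[AGVRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient": r.patient, "agv_cc": r.agv_cc}
        for comp, col in _CSV_COLUMNS.items():
            row[col] = r.gpr.get(comp, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient", "gprWA", "gprWG", "gprGA", "agv_cc"])


def frame_to_records(frame: pd.DataFrame) -> list[AGVRecord]:
    records = []
    for _, row in frame.iterrows():
        gpr = {comp: float(row[col]) for comp, col in _CSV_COLUMNS.items()
               if col in frame.columns and np.isfinite(row[col])}
        records.append(AGVRecord(patient=str(row["patient"]), gpr=gpr,
                                 agv_cc=float(row["agv_cc"])))
    return records


def read_records_csv(path: str | Path) -> list[AGVRecord]:
    return frame_to_records(pd.read_csv(path))


def write_records_csv(records: list[AGVRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def _gpr_column(records: list[AGVRecord], comparison: str) -> np.ndarray:
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; "
                         f"expected one of {COMPARISONS}")
    return np.array([r.gpr[comparison] for r in records], dtype=float)


def cohort_summary(records: list[AGVRecord], comparison: str) -> tuple[int, float, float]:
    """(mean rounded to integer %, min, max) of one comparison's GPR column."""
    if not records:
        raise ValueError("no records")
    col = _gpr_column(records, comparison)
    return int(round(col.mean())), float(col.min()), float(col.max())


def pearson_r(x, y) -> float:
    """Product-moment correlation (full precision; round to 2 decimals for
    reporting)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


class GprAgvTrend:
    """Model object for the linear GPR-vs-AGV trend of one comparison."""

    def __init__(self, records: list[AGVRecord], comparison: str) -> None:
        if len(records) < 3:
            raise ValueError("need at least 3 records")
        self.records = list(records)
        self.comparison = comparison
        self.agv = np.array([r.agv_cc for r in records], dtype=float)
        self.gpr = _gpr_column(records, comparison)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, comparison: str) -> "GprAgvTrend":
        return cls(frame_to_records(frame), comparison)

    def fit(self) -> TrendFit:
        slope, intercept = np.polyfit(self.agv, self.gpr, 1)
        r = pearson_r(self.agv, self.gpr)
        if slope >= 0:
            agv90 = agv90_fwd = None
        else:
            # calibration (inverse) regression: AGV on GPR, read off at 90%
            s_inv, i_inv = np.polyfit(self.gpr, self.agv, 1)
            agv90 = float(s_inv * 90.0 + i_inv)
            agv90_fwd = float((90.0 - intercept) / slope)
        return TrendFit(comparison=self.comparison, slope=float(slope),
                        intercept=float(intercept), r_squared=r * r,
                        pearson_r=r, agv_at_90=agv90,
                        agv_at_90_from_gpr_fit=agv90_fwd, n=len(self.records))


def fit_trend(records: list[AGVRecord], comparison: str) -> TrendFit:
    """Fit the GPR-vs-AGV trend for one comparison (see :class:`TrendFit`)."""
    return GprAgvTrend(records, comparison).fit()
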