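"""Gas-pocket HU statistics, HU-to-RED calibration, and RED overrides.

In abdominal CT, gas pockets image far above the density of air: their mean
attenuation sits around -620 HU rather than -1000 HU, because the pocket is
a mixture of gas, fluid film and partial-volume wall.  Converting the pooled
mean HU of the contoured gas (GAS) through the scanner's calibration curve
gives the gastrointestinal gas relative electron density (GIGED), the value
this package uses as a physically motivated override instead of the
conventional air override (RED 0.0012).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids_structures import BinaryMask, ScalarVolume

__all__ = [
    "CalibrationCurve",
    "GasHUReport",
    "AIR_RED",
    "WATER_RED",
    "default_calibration",
    "structure_hu_stats",
    "ks_normality",
    "mann_whitney_unpaired",
    "fit_calibration_segment",
    "hu_to_red",
    "override_red",
    "gas_hu_report",
]

AIR_RED = 0.0012
WATER_RED = 1.000


@dataclass(frozen=True)
class CalibrationCurve:
    """A linear HU-to-RED conversion fitted over the [-1000, 0] HU segment.

    slope is in RED per HU; intercept is the RED at 0 HU.  Evaluation outside
    the fit domain extrapolates with a warning.
    """

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    fit_domain: tuple[float, float] = (-1000.0, 0.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        for bound in self.fit_domain:
            red = self.slope * bound + self.intercept
            if not (-1e-9 <= red <= 1.2 + 1e-9):
                raise ValueError(
                    f"calibration evaluates to RED {red:.3f} at {bound} HU, "
                    "outside the physical range [0, 1.2]"
                )

    def red(self, hu: float | np.ndarray) -> float | np.ndarray:
        hu_arr = np.asarray(hu, dtype=float)
        lo, hi = self.fit_domain
        if np.any(hu_arr < lo) or np.any(hu_arr > hi):
            warnings.warn(
                f"HU outside calibration fit domain [{lo}, {hi}]; extrapolating",
                stacklevel=2,
            )
        out = self.slope * hu_arr + self.intercept
        return float(out) if np.isscalar(hu) else out


def default_calibration() -> CalibrationCurve:
    """The package's default two-point calibration: (-1000 HU, 0) to (0 HU, 1).

    This line reproduces GIGED = 0.38 at -620 HU; site-specific scanner
    tables can be substituted via :func:`fit_calibration_segment`.
    """
    return fit_calibration_segment([(-1000.0, 0.0), (0.0, 1.0)])


def structure_hu_stats(ct: ScalarVolume, mask: BinaryMask) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count of member-voxel HU."""
    if ct.unit != "HU":
        raise ValueError("structure_hu_stats expects an HU volume")
    if ct.grid != mask.grid:
        raise ValueError("CT and mask are on different grids")
    values = ct.values[mask.member]
    if values.size == 0:
        raise ValueError("empty mask")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd, int(values.size)


def ks_normality(values) -> float:
    """Two-sided Kolmogorov-Smirnov p-value against a normal with the sample's
    own mean and SD (decision threshold alpha = 0.05)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for a normality test")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input: normality test undefined")
    return float(stats.kstest(values, "norm", args=(values.mean(), sd)).pvalue)


def mann_whitney_unpaired(a, b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value for two unpaired samples.

    Exact enumeration of the U distribution when the smaller sample has
    n <= 8 and there are no ties; otherwise the normal approximation with
    tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def fit_calibration_segment(points, fit_domain=(-1000.0, 0.0)) -> CalibrationCurve:
    """Ordinary least squares line through the (HU, RED) points inside the fit
    domain; out-of-domain points are ignored."""
    pts = [(float(h), float(r)) for h, r in points]
    lo, hi = fit_domain
    inside = [(h, r) for h, r in pts if lo <= h <= hi]
    if len(inside) < 2:
        raise ValueError(
            f"need at least 2 calibration points within [{lo}, {hi}] HU, "
            f"got {len(inside)}"
        )
    hu = np.array([p[0] for p in inside])
    red = np.array([p[1] for p in inside])
    slope, intercept = np.polyfit(hu, red, 1)
    return CalibrationCurve(points=tuple(pts), slope=float(slope),
                            intercept=float(intercept), fit_domain=tuple(fit_domain))


def hu_to_red(curve: CalibrationCurve, hu: float) -> float:
    """Convert one HU value through the calibration line."""
    return float(curve.red(hu))


def override_red(red: ScalarVolume, mask: BinaryMask, value: float) -> ScalarVolume:
    """Return a copy of *red* with member voxels set to *value* (input is not
    mutated)."""
    if red.unit != "RED":
        raise ValueError("override_red expects a RED volume")
    if red.grid != mask.grid:
        raise ValueError("RED volume and mask are on different grids")
    if value < 0:
        raise ValueError("override value must be >= 0")
    out = red.values.copy()
    out[mask.member] = value
    return ScalarVolume(red.grid, out, "RED")


@dataclass
class GasHUReport:
    """Cohort-level gas HU statistics and the pooled GIGED.

    per_structure maps GAS/STG/SBG/LBG to (mean HU, SD HU, n); for the
    per-patient aggregation the entries are (mean of per-patient means, SD of
    per-patient means, number of patients).  normality_p holds the KS p-value
    per structure, pairwise_p the Mann-Whitney p per organ pair, and giged the
    pooled-GAS RED (rounded to 2 decimals).
    """

    per_structure: dict[str, tuple[float, float, int]]
    normality_p: dict[str, float] = field(default_factory=dict)
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    pooled_gas_mean_hu: float = float("nan")
    giged: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "per_structure": {k: {"mean_hu": v[0], "sd_hu": v[1], "n": v[2]}
                              for k, v in self.per_structure.items()},
            "normality_p": dict(self.normality_p),
            "pairwise_p": {f"{a}_vs_{b}": p for (a, b), p in self.pairwise_p.items()},
            "pooled_gas_mean_hu": self.pooled_gas_mean_hu,
            "giged": self.giged,
        }


_ORGAN_GAS = ("STG", "SBG", "LBG")


def gas_hu_report(per_patient_stats: dict[str, list[tuple[float, float, int]]],
                  calibration: CalibrationCurve | None = None) -> GasHUReport:
    """Aggregate per-patient gas HU statistics into a cohort report.

    *per_patient_stats* maps structure name (at least "GAS"; typically also
    STG/SBG/LBG) to one (mean, SD, n_voxels) tuple per patient, as returned by
    :func:`structure_hu_stats`.  The pooled GAS mean is the voxel-count-
    weighted mean of the per-patient means (i.e. the mean over all GAS voxels
    of the cohort), and GIGED is that value through the calibration curve,
    rounded to 2 decimals.  KS normality is tested on the per-patient means of
    each structure; Mann-Whitney compares the organ pairs.
    """
    if "GAS" not in per_patient_stats:
        raise ValueError("per_patient_stats must contain 'GAS'")
    calibration = calibration or default_calibration()
    per_structure: dict[str, tuple[float, float, int]] = {}
    normality: dict[str, float] = {}
    means_by_structure: dict[str, np.ndarray] = {}
    for name, entries in per_patient_stats.items():
        means = np.array([e[0] for e in entries], dtype=float)
        means_by_structure[name] = means
        sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
        per_structure[name] = (float(means.mean()), sd, int(means.size))
        if means.size >= 3 and means.std(ddof=1) > 0:
            normality[name] = ks_normality(means)
    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(_ORGAN_GAS):
        for b in _ORGAN_GAS[i + 1:]:
            if a in means_by_structure and b in means_by_structure:
                pairwise[(a, b)] = mann_whitney_unpaired(
                    means_by_structure[a], means_by_structure[b])
    gas = per_patient_stats["GAS"]
    counts = np.array([e[2] for e in gas], dtype=float)
    means = np.array([e[0] for e in gas], dtype=float)
    pooled = float(np.average(means, weights=counts))
    giged = round(hu_to_red(calibration, pooled), 2)
    return GasHUReport(per_structure=per_structure, normality_p=normality,
                       pairwise_p=pairwise, pooled_gas_mean_hu=pooled, giged=giged)
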