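"""2-D gamma-index comparison of planar dose distributions.

The gamma index combines dose difference (as % of a normalization dose) and
distance-to-agreement (mm): a reference pixel passes when some nearby point
of the evaluated distribution agrees within both tolerances combined in
quadrature (gamma <= 1).  The protocol here is the tight plan-recalculation
setting: 1%/1 mm with a 10% low-dose threshold, normalization to the global
maximum of the reference plane, and the gamma passing rate (GPR) averaged
over the three orthogonal planes through the GTV centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids_structures import BinaryMask, ScalarVolume, mask_centroid, rasterize_structure
from .rtdicom_io import PatientCase

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "extract_orthogonal_planes",
    "gamma_2d",
    "compare_plans",
]

PLANE_NAMES = ("axial", "sagittal", "coronal")


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-analysis tolerances; percentages are of the normalization dose
    (global maximum of the reference plane)."""

    dose_tol_pct: float = 1.0
    dta_mm: float = 1.0
    low_dose_threshold_pct: float = 10.0
    search_radius_factor: float = 3.0   # search out to this multiple of dta
    step_factor: float = 0.1            # evaluated-dose interpolation step, in dta units

    def __post_init__(self) -> None:
        for name in ("dose_tol_pct", "dta_mm", "low_dose_threshold_pct",
                     "search_radius_factor", "step_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GammaResult:
    """Per-plane gamma maps and passing rates plus their arithmetic mean."""

    gamma_maps: dict[str, np.ndarray]
    gpr: dict[str, float]
    mean_gpr: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_gpr = float(np.mean(list(self.gpr.values())))


def extract_orthogonal_planes(dose: ScalarVolume, point) -> dict[str, tuple[np.ndarray, tuple[float, float]]]:
    """The axial, sagittal and coronal dose slices through the grid planes
    nearest to *point* (mm); no interpolation.

    Returns a mapping plane-name -> (2-D array, in-plane spacing mm).
    """
    grid = dose.grid
    if not grid.contains_point(point):
        raise ValueError(f"point {tuple(point)} lies outside the dose grid")
    i, j, k = grid.nearest_index(point)
    dx, dy, dz = grid.spacing
    return {
        "axial": (dose.values[:, :, k].copy(), (dx, dy)),
        "sagittal": (dose.values[i, :, :].copy(), (dy, dz)),
        "coronal": (dose.values[:, j, :].copy(), (dx, dz)),
    }


def gamma_2d(reference: np.ndarray, evaluated: np.ndarray,
             spacing: tuple[float, float],
             criteria: GammaCriteria = GammaCriteria()) -> tuple[np.ndarray, float]:
    """Gamma map and passing rate of *evaluated* against *reference*.

    Reference pixels below the low-dose threshold are excluded (NaN in the
    map).  For the rest, the evaluated dose is probed bilinearly on a polar
    disc of offsets (step ``step_factor*dta``, radius
    ``search_radius_factor*dta``); offsets are visited in order of increasing
    distance so the search stops as soon as the distance term alone exceeds
    the worst current gamma.  The per-pixel result may therefore only
    *overestimate* the ideal continuum gamma, by at most the discretization
    of the search.
    """
    reference = np.asarray(reference, dtype=float)
    evaluated = np.asarray(evaluated, dtype=float)
    if reference.shape != evaluated.shape:
        raise ValueError("reference and evaluated planes differ in shape")
    if len(spacing) != 2 or any(s <= 0 for s in spacing):
        raise ValueError("spacing must be two positive values (mm)")
    norm = reference.max()
    if norm <= 0:
        raise ValueError("reference maximum dose must be > 0")
    delta = criteria.dose_tol_pct / 100.0 * norm
    threshold = criteria.low_dose_threshold_pct / 100.0 * norm
    include = reference >= threshold
    if not include.any():
        raise ValueError("no pixels above dose threshold")

    dta = criteria.dta_mm
    step = criteria.step_factor * dta
    radius = criteria.search_radius_factor * dta
    n_steps = int(np.floor(radius / step))
    offs = step * np.arange(-n_steps, n_steps + 1)
    ox, oy = np.meshgrid(offs, offs, indexing="ij")
    r2 = ox**2 + oy**2
    keep = r2 <= radius**2 + 1e-12
    offsets = np.column_stack([ox[keep], oy[keep], r2[keep]])
    offsets = offsets[np.argsort(offsets[:, 2], kind="stable")]

    ii, jj = np.nonzero(include)
    ref_vals = reference[include]
    base = np.vstack([ii.astype(float), jj.astype(float)])
    gamma2 = np.full(ref_vals.shape, np.inf)
    dta2 = dta * dta
    for dx_mm, dy_mm, rr2 in offsets:
        dist_term = rr2 / dta2
        worst = gamma2.max()
        if dist_term >= worst:
            break  # no remaining offset can improve any pixel
        coords = base + np.array([[dx_mm / spacing[0]], [dy_mm / spacing[1]]])
        ev = ndimage.map_coordinates(evaluated, coords, order=1,
                                     mode="constant", cval=np.nan, prefilter=False)
        g2 = (ev - ref_vals) ** 2 / (delta * delta) + dist_term
        gamma2 = np.fmin(gamma2, g2)  # NaN samples (outside grid) are ignored
    gamma_map = np.full(reference.shape, np.nan)
    gamma_map[include] = np.sqrt(gamma2)
    gpr = 100.0 * float(np.mean(gamma2 <= 1.0 + 1e-9))
    return gamma_map, gpr


def compare_plans(case: PatientCase, plan_a: str, plan_b: str,
                  criteria: GammaCriteria = GammaCriteria()) -> GammaResult:
    """Run the three-plane gamma protocol between two of a case's plans.

    *plan_a* is the reference.  The three orthogonal planes pass through the
    GTV centroid (GTV rasterized onto the dose grid); the result carries one
    GPR per plane and their arithmetic mean.
    """
    for name in (plan_a, plan_b):
        if name not in case.doses:
            raise ValueError(f"plan {name!r} not present in case")
    if "GTV" not in case.structures:
        raise ValueError("case has no GTV structure")
    ref_dose = case.doses[plan_a]
    gtv = rasterize_structure(case.structures["GTV"], ref_dose.grid)
    centroid = mask_centroid(gtv)
    ref_planes = extract_orthogonal_planes(ref_dose, centroid)
    eval_planes = extract_orthogonal_planes(case.doses[plan_b], centroid)
    maps: dict[str, np.ndarray] = {}
    gpr: dict[str, float] = {}
    for plane in PLANE_NAMES:
        ref_arr, spacing = ref_planes[plane]
        eval_arr, _ = eval_planes[plane]
        maps[plane], gpr[plane] = gamma_2d(ref_arr, eval_arr, spacing, criteria)
    return GammaResult(gamma_maps=maps, gpr=gpr)
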