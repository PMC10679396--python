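"""Synthetic abdominal phantoms, a declared toy dose engine, plan triplets,
the variable-density slab experiment, and cohort simulation.

The generator emulates the study conditions end to end with no external
data: an ellipsoidal body at ~0 HU with Gaussian texture, ellipsoidal gas
pockets whose voxel HU are drawn from Normal(-620, 90), three
gastrointestinal organ regions so the per-organ gas partitions (STG/SBG/LBG)
are non-trivial, a GTV with a 3 mm isotropic PTV margin, and a 24-beam
arrangement with two blocked ~20 deg sectors near 120 and 240 deg.

The dose engine is an explicitly declared stand-in for a clinical Monte
Carlo engine: per beam, primary dose attenuates exponentially with
radiological path length (the line integral of relative electron density),
shaped laterally by a Gaussian-penumbra aperture fitted to the PTV, plus an
interface-perturbation term that mimics the electron return effect (ERE):
dose is boosted on the solid side of a high-to-low density interface and
suppressed inside the cavity, with an amplitude that fades to zero as the
cavity density approaches 0.5 (by which point measured depth-dose curves are
water-like).  Only ordering and shape properties of its output are
meaningful; absolute passing rates are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .density_mapping import (AIR_RED, WATER_RED, CalibrationCurve,
                              default_calibration, override_red)
from .dvh_agv import compute_agv
from .gamma_compare import GammaCriteria, compare_plans, gamma_2d
from .grids_structures import (BinaryMask, ScalarVolume, Structure,
                               StructureSet, VoxelGrid, rasterize_structure)
from .rtdicom_io import PatientCase
from .cohort_stats import COMPARISONS, AGVRecord

__all__ = [
    "PhantomSpec",
    "BeamSet",
    "EngineParams",
    "generate_patient",
    "toy_dose_engine",
    "build_plan_triplet",
    "slab_experiment",
    "simulate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one synthetic abdominal phantom."""

    seed: int
    body_semiaxes: tuple[float, float, float] = (140.0, 100.0, 80.0)  # mm
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)             # mm
    gtv_radius: float = 12.0                                          # mm
    ptv_margin: float = 3.0                                           # mm, isotropic
    n_pockets: int = 6
    pocket_semiaxes: tuple[float, float] = (8.0, 24.0)                # mm range
    pocket_hu_mean: float = -620.0
    pocket_hu_sd: float = 90.0
    body_hu_sd: float = 15.0
    grid_margin: float = 12.0                                         # mm air border

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_pockets < 0:
            raise ValueError("n_pockets must be >= 0")
        if self.pocket_semiaxes[0] <= 0 or self.pocket_semiaxes[1] < self.pocket_semiaxes[0]:
            raise ValueError("pocket_semiaxes must be an increasing positive range")


@dataclass(frozen=True)
class BeamSet:
    """Equispaced coplanar beams with two blocked ~20 deg couch sectors."""

    n_beams: int = 24
    blocked_centers_deg: tuple[float, float] = (120.0, 240.0)
    blocked_width_deg: float = 20.0
    prescription: float = 40.0      # Gy, prescribed at the 80% isodose
    prescription_isodose: float = 0.80

    def angles_deg(self) -> np.ndarray:
        """Beam gantry angles: n_beams spread evenly over the unblocked arc."""
        blocked = sorted(self.blocked_centers_deg)
        width = self.blocked_width_deg
        allowed = 360.0 - width * len(blocked)
        s = (np.arange(self.n_beams) + 0.5) * allowed / self.n_beams
        # map arc-length position to circle angle by skipping blocked sectors
        out = []
        for v in s:
            shift = 0.0
            for centre in blocked:
                if v + shift >= centre - width / 2.0:
                    shift += width
            out.append(v + shift)
        return np.asarray(out)


@dataclass(frozen=True)
class EngineParams:
    """Tunables of the toy dose engine (see module docstring)."""

    mu_eff_cm: float = 0.06          # effective attenuation per cm radiological length
    penumbra_sigma_mm: float = 4.0   # lateral Gaussian penumbra
    aperture_margin_mm: float = 5.0  # aperture expansion beyond target projection
    ere_gain: float = 0.6            # dimensionless interface-perturbation gain
    ere_range_mm: float = 10.0       # exponential range of the perturbation
    ere_red_scale: float = 0.5       # cavity RED at which the perturbation vanishes
    ere_min_drop: float = 0.1        # minimum RED drop that counts as an interface

    def __post_init__(self) -> None:
        for name in ("mu_eff_cm", "penumbra_sigma_mm", "aperture_margin_mm",
                     "ere_gain", "ere_range_mm", "ere_red_scale", "ere_min_drop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# phantom generation


def _ellipsoid_contours(center, semiaxes, z_coords, n_vertices: int = 32):
    """Per-slice elliptical cross-section polygons of an axis-aligned ellipsoid."""
    cx, cy, cz = center
    a, b, c = semiaxes
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    contours = []
    for z in z_coords:
        u = (z - cz) / c
        if abs(u) >= 1.0:
            continue
        scale = np.sqrt(1.0 - u * u)
        verts = np.column_stack([cx + a * scale * np.cos(theta),
                                 cy + b * scale * np.sin(theta)])
        contours.append((float(z), verts))
    return contours


def _ellipsoid_voxels(grid: VoxelGrid, center, semiaxes) -> np.ndarray:
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    return (((xs - center[0]) / semiaxes[0]) ** 2
            + ((ys - center[1]) / semiaxes[1]) ** 2
            + ((zs - center[2]) / semiaxes[2]) ** 2) <= 1.0


_ORGAN_LAYOUT = {
    # relative centre and relative semi-axes, in units of the body semi-axes
    "ST": ((-0.45, -0.35, 0.25), (0.25, 0.28, 0.35)),
    "SB": ((0.00, 0.38, -0.20), (0.38, 0.30, 0.40)),
    "LB": ((0.45, -0.22, 0.00), (0.27, 0.32, 0.48)),
}
_ORGAN_OF_POCKET = ("ST", "SB", "LB")  # round-robin assignment


def generate_patient(spec: PhantomSpec) -> PatientCase:
    """Generate one synthetic patient: HU volume plus contoured structures
    (GTV, PTV, ST, SB, LB, GAS); no doses.  Bit-reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    ax, ay, az = spec.body_semiaxes
    extent = (2 * (ax + spec.grid_margin), 2 * (ay + spec.grid_margin),
              2 * (az + spec.grid_margin))
    shape = tuple(int(np.ceil(e / s)) | 1 for e, s in zip(extent, spec.spacing))
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spec.spacing))
    grid = VoxelGrid(origin=origin, spacing=spec.spacing, shape=shape)
    z_coords = grid.axis_coords(2)

    body = _ellipsoid_voxels(grid, (0, 0, 0), spec.body_semiaxes)
    hu = np.full(grid.shape, -1000.0)
    hu[body] = rng.normal(0.0, spec.body_hu_sd, size=int(body.sum()))

    structures = StructureSet()
    gtv_center = (0.0, -0.1 * ay, 0.0)
    r = spec.gtv_radius
    structures.add(Structure("GTV", _ellipsoid_contours(gtv_center, (r, r, r), z_coords)))
    rp = r + spec.ptv_margin
    structures.add(Structure("PTV", _ellipsoid_contours(gtv_center, (rp, rp, rp), z_coords)))

    organ_geom = {}
    for name, (rel_c, rel_s) in _ORGAN_LAYOUT.items():
        center = tuple(rc * s for rc, s in zip(rel_c, spec.body_semiaxes))
        semi = tuple(rs * s for rs, s in zip(rel_s, spec.body_semiaxes))
        organ_geom[name] = (center, semi)
        structures.add(Structure(name, _ellipsoid_contours(center, semi, z_coords)))

    # place pockets inside their assigned organ, without mutual overlap
    placed: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = []
    gas_contours: list[tuple[float, np.ndarray]] = []
    ptv_clear = rp + 2.0
    for p in range(spec.n_pockets):
        organ = _ORGAN_OF_POCKET[p % len(_ORGAN_OF_POCKET)]
        oc, os_ = organ_geom[organ]
        lo, hi = spec.pocket_semiaxes
        for _attempt in range(1000):
            semi = rng.uniform(lo, hi, 3)
            semi = np.minimum(semi, 0.85 * np.asarray(os_))
            center = np.asarray(oc) + rng.uniform(-1.0, 1.0, 3) * (np.asarray(os_) - semi)
            # crowded organs accept progressively smaller pockets
            hi = max(lo, 0.995 * hi)
            if np.any(np.abs(center - np.asarray(oc)) + semi > np.asarray(os_)):
                continue
            if np.linalg.norm(center - np.asarray(gtv_center)) < semi.max() + ptv_clear:
                continue
            ok = True
            for pc, ps in placed:
                gap = np.abs(center - np.asarray(pc)) - (semi + np.asarray(ps))
                if np.all(gap < 1.0):  # bounding boxes closer than 1 mm everywhere
                    ok = False
                    break
            if ok:
                placed.append((tuple(center), tuple(semi)))
                gas_contours.extend(_ellipsoid_contours(center, semi, z_coords))
                break
        else:
            raise RuntimeError(
                f"could not place pocket {p + 1} without overlap after 1000 attempts"
            )
    if gas_contours or spec.n_pockets == 0:
        structures.add(Structure("GAS", gas_contours) if gas_contours
                       else Structure("GAS", []))

    if gas_contours:
        gas_mask = rasterize_structure(structures["GAS"], grid)
        n_gas = gas_mask.n_voxels
        hu[gas_mask.member] = np.clip(
            rng.normal(spec.pocket_hu_mean, spec.pocket_hu_sd, size=n_gas),
            -1000.0, None)

    ct = ScalarVolume(grid, hu, "HU")
    return PatientCase(ct=ct, structures=structures, doses={}, prescription_dose=0.0)


# ---------------------------------------------------------------------------
# toy dose engine


def _ere_modulation(red_rot: np.ndarray, dy_mm: float, params: EngineParams) -> np.ndarray:
    """Multiplicative ERE-like perturbation along the beam axis (axis 1).

    At each high-to-low density step exceeding ``ere_min_drop``, a source term
    proportional to the drop and to ``max(0, 1 - RED_gap/ere_red_scale)`` is
    deposited; it boosts dose on the upstream (solid) side and suppresses it
    downstream (inside the cavity), both decaying exponentially with range
    ``ere_range_mm``.
    """
    if params.ere_gain == 0.0:
        return np.ones_like(red_rot)
    drop = red_rot[:, :-1, :] - red_rot[:, 1:, :]
    gap_red = red_rot[:, 1:, :]
    amp = params.ere_gain * np.clip(1.0 - gap_red / params.ere_red_scale, 0.0, 1.0)
    src = np.where(drop > params.ere_min_drop, drop * amp, 0.0)
    source = np.concatenate([np.zeros_like(red_rot[:, :1, :]), src], axis=1)
    decay = float(np.exp(-dy_mm / params.ere_range_mm))
    ny = red_rot.shape[1]
    cavity = np.zeros_like(red_rot)
    cavity[:, 0, :] = source[:, 0, :]
    for j in range(1, ny):
        cavity[:, j, :] = cavity[:, j - 1, :] * decay + source[:, j, :]
    boost = np.zeros_like(red_rot)
    for j in range(ny - 2, -1, -1):
        boost[:, j, :] = (boost[:, j + 1, :] + source[:, j + 1, :]) * decay
    return np.clip(1.0 + boost - cavity, 0.0, None)


def _beam_dose_along_y(red_values: np.ndarray, fluence: np.ndarray,
                       spacing, params: EngineParams) -> np.ndarray:
    """Dose of one beam travelling along +y (axis 1) through *red_values*."""
    dy_mm = spacing[1]
    rad_cm = (np.cumsum(red_values, axis=1) - 0.5 * red_values) * dy_mm / 10.0
    primary = np.exp(-params.mu_eff_cm * rad_cm)
    dose = fluence[:, None, :] * primary
    return dose * _ere_modulation(red_values, dy_mm, params)


def _aperture(target_proj: np.ndarray, spacing_xz, params: EngineParams) -> np.ndarray:
    """Gaussian-penumbra fluence map from a boolean beam's-eye-view projection."""
    if target_proj.any():
        dist = ndimage.distance_transform_edt(~target_proj, sampling=spacing_xz)
        opened = dist <= params.aperture_margin_mm
    else:
        opened = target_proj
    sigma = (params.penumbra_sigma_mm / spacing_xz[0],
             params.penumbra_sigma_mm / spacing_xz[1])
    return ndimage.gaussian_filter(opened.astype(float), sigma=sigma)


def toy_dose_engine(red: ScalarVolume, beams: BeamSet, params: EngineParams,
                    target: BinaryMask | None = None,
                    normalize: bool = True) -> ScalarVolume:
    """Deterministic multi-beam dose on a RED volume.

    Each beam rotates the RED map (and the target mask, for its aperture)
    about the grid's z axis, attenuates exponentially with radiological
    depth, applies the Gaussian-penumbra aperture and the ERE-like interface
    term, and is rotated back and summed.  With ``normalize`` the total dose
    is scaled so the prescription sits at the ``prescription_isodose``
    level of the global maximum (default: Rx at the 80% isodose).
    """
    if red.unit != "RED":
        raise ValueError("toy_dose_engine expects a RED volume")
    if not np.any(red.values > 0):
        raise ValueError("RED volume is zero everywhere")
    if target is not None and target.grid != red.grid:
        raise ValueError("target mask and RED volume are on different grids")
    grid = red.grid
    dx, dy, dz = grid.spacing
    if target is not None:
        target_arr = target.member
    else:  # default square field about the grid centre
        target_arr = np.zeros(grid.shape, dtype=bool)
        half = [max(1, int(15.0 / s)) for s in grid.spacing]
        cx, cy, cz = (n // 2 for n in grid.shape)
        target_arr[cx - half[0]:cx + half[0] + 1,
                   cy - half[1]:cy + half[1] + 1,
                   cz - half[2]:cz + half[2] + 1] = True

    total = np.zeros(grid.shape)
    for angle in beams.angles_deg():
        red_rot = ndimage.rotate(red.values, angle, axes=(0, 1), reshape=False,
                                 order=1, mode="constant", cval=0.0, prefilter=False)
        red_rot = np.clip(red_rot, 0.0, None)
        tgt_rot = ndimage.rotate(target_arr.astype(float), angle, axes=(0, 1),
                                 reshape=False, order=1, mode="constant",
                                 cval=0.0, prefilter=False) > 0.5
        fluence = _aperture(tgt_rot.any(axis=1), (dx, dz), params)
        dose_rot = _beam_dose_along_y(red_rot, fluence, grid.spacing, params)
        total += np.clip(
            ndimage.rotate(dose_rot, -angle, axes=(0, 1), reshape=False,
                           order=1, mode="constant", cval=0.0, prefilter=False),
            0.0, None)
    if normalize:
        total *= beams.prescription / (beams.prescription_isodose * total.max())
    return ScalarVolume(grid, total, "Gy")


# ---------------------------------------------------------------------------
# plan triplets


def build_plan_triplet(case: PatientCase, calibration: CalibrationCurve | None = None,
                       engine: EngineParams = EngineParams(),
                       beams: BeamSet = BeamSet(),
                       giged: float | None = None) -> PatientCase:
    """Recompute the case's dose three times with the GAS density overridden
    to air (APLAN), water (WPLAN) and GIGED (GPLAN).

    The beam weights and global normalization are fixed on the unmodified
    calibrated density map (no re-optimization): the scale factor that puts
    the prescription at the 80% isodose of the baseline calculation is
    applied unchanged to all three plans.
    """
    if "GAS" not in case.structures:
        raise ValueError("case has no GAS structure")
    if "PTV" not in case.structures:
        raise ValueError("case has no PTV structure")
    calibration = calibration or default_calibration()
    if giged is None:
        giged = round(calibration.red(-620.0), 2)
    grid = case.ct.grid
    red_base = ScalarVolume(
        grid, np.clip(calibration.red(np.clip(case.ct.values, -1000.0, 0.0)), 0.0, None),
        "RED")
    gas_mask = rasterize_structure(case.structures["GAS"], grid)
    ptv_mask = rasterize_structure(case.structures["PTV"], grid)

    raw_base = toy_dose_engine(red_base, beams, engine, target=ptv_mask,
                               normalize=False)
    scale = beams.prescription / (beams.prescription_isodose * raw_base.values.max())

    doses = {}
    for plan, value in (("APLAN", AIR_RED), ("WPLAN", WATER_RED), ("GPLAN", giged)):
        red_plan = override_red(red_base, gas_mask, value)
        raw = toy_dose_engine(red_plan, beams, engine, target=ptv_mask,
                              normalize=False)
        doses[plan] = ScalarVolume(grid, raw.values * scale, "Gy")
    return PatientCase(ct=case.ct, structures=case.structures, doses=doses,
                       prescription_dose=beams.prescription)


# ---------------------------------------------------------------------------
# slab-phantom experiment


def slab_experiment(gap_red_values, engine: EngineParams = EngineParams(),
                    spacing_mm: float = 3.0, side_mm: float = 300.0,
                    field_mm: float = 100.0, gap_depth_mm: float = 75.0,
                    gap_thickness_mm: float = 30.0, iso_depth_mm: float = 150.0,
                    dose_at_iso: float = 10.0,
                    criteria: GammaCriteria = GammaCriteria()):
    """Single fixed beam onto a solid-water cube containing a variable-density
    gap slab; each gap-RED dose is gamma-compared (on the axial plane through
    the beam axis) against the air-gap dose.

    Returns ``(table, pdds)`` where *table* is a list of ``(red, gpr)`` pairs
    (the first entry compares air against itself, GPR 100 by construction)
    and *pdds* maps each RED to its central-axis percentage depth-dose curve
    ``(depth_mm, pdd_percent)``.
    """
    gap_red_values = [float(v) for v in gap_red_values]
    if not gap_red_values:
        raise ValueError("gap_red_values must be non-empty")
    n = int(round(side_mm / spacing_mm)) | 1
    spacing = (spacing_mm, spacing_mm, spacing_mm)
    xs = (np.arange(n) - (n - 1) / 2.0) * spacing_mm   # in-plane, centred
    depth = np.arange(n) * spacing_mm + spacing_mm / 2.0  # along the beam

    half = field_mm / 2.0
    proj = (np.abs(xs)[:, None] <= half) & (np.abs(xs)[None, :] <= half)
    fluence = _aperture(proj, (spacing_mm, spacing_mm), params=engine)
    gap = (depth >= gap_depth_mm) & (depth < gap_depth_mm + gap_thickness_mm)
    ic = n // 2
    k_iso = int(np.argmin(np.abs(depth - iso_depth_mm)))

    def dose_for(red_gap: float) -> np.ndarray:
        red = np.ones((n, n, n))
        red[:, gap, :] = red_gap
        d = _beam_dose_along_y(red, fluence, spacing, engine)
        return d * (dose_at_iso / d[ic, k_iso, ic])

    ref = dose_for(AIR_RED)
    ref_plane = ref[:, :, ic]
    table = []
    pdds = {}
    for red_gap in gap_red_values:
        d = dose_for(red_gap)
        _, gpr = gamma_2d(ref_plane, d[:, :, ic], (spacing_mm, spacing_mm), criteria)
        table.append((red_gap, gpr))
        cax = d[ic, :, ic]
        pdds[red_gap] = (depth.copy(), 100.0 * cax / cax.max())
    return table, pdds


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(n_patients: int, seed: int,
                    base_spec: PhantomSpec | None = None,
                    vary_pockets: bool = True,
                    beams: BeamSet = BeamSet(),
                    engine: EngineParams = EngineParams(),
                    criteria: GammaCriteria = GammaCriteria(),
                    calibration: CalibrationCurve | None = None) -> list[AGVRecord]:
    """Run the full pipeline on *n_patients* synthetic patients with varied
    gas load and return their AGV records (GPR per comparison + AGV).

    With ``vary_pockets`` (default), pocket number and size are drawn per
    patient from the master seed so the cohort spans small to large active
    gas volumes; otherwise the base spec's pocket settings are kept for every
    patient (only the seed changes).  The AGV is evaluated on the APLAN dose
    by convention.
    """
    if n_patients < 5:
        raise ValueError("need at least 5 patients for a cohort")
    master = np.random.default_rng(seed)
    records = []
    for i in range(n_patients):
        child_seed = int(master.integers(0, 2**31 - 1))
        spec = base_spec or PhantomSpec(seed=0)
        spec = replace(spec, seed=child_seed)
        if vary_pockets:
            n_pockets = int(master.integers(1, 9))
            size_hi = float(master.uniform(10.0, 30.0))
            spec = replace(spec, n_pockets=n_pockets,
                           pocket_semiaxes=(6.0, size_hi))
        case = generate_patient(spec)
        case = build_plan_triplet(case, calibration=calibration, engine=engine,
                                  beams=beams)
        gas_mask = rasterize_structure(case.structures["GAS"], case.ct.grid)
        agv = compute_agv(gas_mask, case.doses["APLAN"], case.prescription_dose)
        gpr = {}
        for comp in COMPARISONS:
            ref, ev = comp.split("vs")
            gpr[comp] = compare_plans(case, ref, ev, criteria).mean_gpr
        records.append(AGVRecord(patient=f"SYN {i + 1}", gpr=gpr, agv_cc=agv))
    return records
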