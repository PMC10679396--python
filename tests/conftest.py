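"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import gasdose as g


@pytest.fixture(scope="session")
def triplet_case() -> g.PatientCase:
    """One default synthetic patient with its APLAN/WPLAN/GPLAN doses."""
    case = g.generate_patient(g.PhantomSpec(seed=7))
    return g.build_plan_triplet(case)


@pytest.fixture(scope="session")
def table1() -> list[g.AGVRecord]:
    return g.load_table1_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def point_in_polygon_slow(x: float, y: float, verts: np.ndarray) -> bool:
    """Scalar even-odd crossing test with the half-open edge convention;
    deliberately written as a plain loop, independent of the package."""
    inside = False
    n = len(verts)
    for a in range(n):
        x1, y1 = verts[a]
        x2, y2 = verts[(a + 1) % n]
        if (y1 > y) != (y2 > y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_at:
                inside = not inside
    return inside


def smooth_dose_pair(rng: np.random.Generator, shape=(20, 20)):
    """A smooth reference field (10-18 Gy) and a slightly perturbed copy."""
    base = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 2.5)
    ref = 10.0 + 8.0 * (base - base.min()) / np.ptp(base)
    ev = (ref * (1.0 + rng.normal(0.0, 0.01))
          + ndimage.gaussian_filter(rng.normal(0.0, 0.15, shape), 2.0))
    return ref, ev


def brute_force_gamma(ref: np.ndarray, ev: np.ndarray, spacing,
                      criteria: g.GammaCriteria):
    """Exhaustive gamma oracle: per reference pixel, minimize over the
    bilinearly interpolated evaluated dose on a dense 0.01*dta offset grid
    out to a 5*dta radius (per-pixel early cutoff where the distance term
    alone already exceeds the local-dose-difference gamma)."""
    norm = ref.max()
    delta = criteria.dose_tol_pct / 100.0 * norm
    thr = criteria.low_dose_threshold_pct / 100.0 * norm
    dta = criteria.dta_mm
    step, radius = 0.01 * dta, 5.0 * dta
    ns = int(round(radius / step))
    offs = step * np.arange(-ns, ns + 1)
    ox, oy = np.meshgrid(offs, offs, indexing="ij")
    r2 = ox**2 + oy**2
    keep = r2 <= radius**2 + 1e-12
    dxs, dys, rr2 = ox[keep], oy[keep], r2[keep]
    gamma = np.full(ref.shape, np.nan)
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            if ref[i, j] < thr:
                continue
            g0 = abs(ev[i, j] - ref[i, j]) / delta
            sel = rr2 <= min(radius, g0 * dta) ** 2 + 1e-12
            coords = np.vstack([i + dxs[sel] / spacing[0],
                                j + dys[sel] / spacing[1]])
            vals = ndimage.map_coordinates(ev, coords, order=1,
                                           mode="constant", cval=np.nan,
                                           prefilter=False)
            g2 = (vals - ref[i, j]) ** 2 / delta**2 + rr2[sel] / dta**2
            best = np.nanmin(g2) if np.any(~np.isnan(g2)) else np.inf
            gamma[i, j] = np.sqrt(min(best, g0 * g0))
    include = ref >= thr
    gpr = 100.0 * float(np.mean(gamma[include] <= 1.0 + 1e-9))
    return gamma, gpr


@pytest.fixture(scope="session")
def gamma_oracle():
    return brute_force_gamma


@pytest.fixture(scope="session")
def dose_pair_factory():
    return smooth_dose_pair
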