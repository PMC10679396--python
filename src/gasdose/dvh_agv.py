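"""Cumulative DVH metrics and the active gas volume (AGV) statistic.

The AGV is the volume (cc) of the contoured gas that actually lies in the
beam path, operationalized as the intersection of the GAS mask with the
region receiving at least 5% of the prescription dose.  It is the package's
predictor for how strongly a gas-density override will perturb the plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_structures import BinaryMask, ScalarVolume, mask_volume_cc

__all__ = [
    "CumulativeDVH",
    "DvhMetrics",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dvh_metrics",
    "dvh_delta",
    "compute_agv",
]


@dataclass
class CumulativeDVH:
    """Cumulative dose-volume histogram of one structure.

    ``fraction[i]`` is the fraction of the structure's volume receiving at
    least ``bin_edges[i]`` Gy; the curve is non-increasing, starts at 1.0 and
    reaches 0.0 above the maximum voxel dose.
    """

    structure: str
    bin_edges: np.ndarray
    fraction: np.ndarray
    total_cc: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.bin_edges.shape != self.fraction.shape:
            raise ValueError("bin_edges and fraction must have equal length")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


@dataclass
class DvhMetrics:
    """Point metrics from a structure's DVH (doses in Gy, V95 in %)."""

    structure: str
    d98: float
    d50: float
    d2: float
    dmin: float
    dmean: float
    dmax: float
    v95: float | None = None  # only meaningful for the PTV

    def __post_init__(self) -> None:
        if not (self.d98 <= self.d50 + 1e-9 and self.d50 <= self.d2 + 1e-9):
            raise ValueError("DVH metrics must satisfy D98 <= D50 <= D2")
        if not (self.dmin <= self.dmean + 1e-9 and self.dmean <= self.dmax + 1e-9):
            raise ValueError("dose metrics must satisfy min <= mean <= max")


def cumulative_dvh(dose: ScalarVolume, mask: BinaryMask,
                   bin_width: float = 0.01, structure: str = "") -> CumulativeDVH:
    """Exact voxel-counting cumulative DVH with the given bin width (Gy)."""
    if dose.unit != "Gy":
        raise ValueError("cumulative_dvh expects a Gy volume")
    if dose.grid != mask.grid:
        raise ValueError("dose and mask are on different grids")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = dose.values[mask.member]
    if values.size == 0:
        raise ValueError("empty mask")
    n_bins = int(np.ceil((values.max() + bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=np.append(edges, np.inf))
    # fraction of voxels with dose >= edge[i]
    fraction = 1.0 - np.concatenate([[0.0], np.cumsum(counts[:-1])]) / values.size
    return CumulativeDVH(structure=structure, bin_edges=edges, fraction=fraction,
                         total_cc=mask_volume_cc(mask))


def dose_at_volume(dvh: CumulativeDVH, q: float) -> float:
    """Dq: the highest dose covering at least q% of the structure volume,
    linearly interpolated between DVH bins."""
    if not (0.0 < q <= 100.0):
        raise ValueError("q must be in (0, 100]")
    target = q / 100.0
    frac = dvh.fraction
    edges = dvh.bin_edges
    idx = np.nonzero(frac >= target - 1e-12)[0]
    if idx.size == 0:
        return 0.0
    i = idx[-1]
    if i == len(edges) - 1 or frac[i] - frac[i + 1] < 1e-15:
        return float(edges[i])
    t = (frac[i] - target) / (frac[i] - frac[i + 1])
    return float(edges[i] + t * (edges[i + 1] - edges[i]))


def volume_at_dose(dvh: CumulativeDVH, d: float) -> float:
    """Vd: the percentage of structure volume receiving at least d Gy."""
    if d < 0:
        raise ValueError("dose must be >= 0")
    frac = np.interp(d, dvh.bin_edges, dvh.fraction)
    return float(100.0 * frac)


def dvh_metrics(dose: ScalarVolume, mask: BinaryMask, structure: str = "",
                prescription: float | None = None,
                bin_width: float = 0.01) -> DvhMetrics:
    """D98/D50/D2, exact min/mean/max, and (if a prescription is given) the
    V95 coverage at 95% of the prescription dose."""
    dvh = cumulative_dvh(dose, mask, bin_width=bin_width, structure=structure)
    values = dose.values[mask.member]
    v95 = None
    if prescription is not None:
        if prescription <= 0:
            raise ValueError("prescription must be > 0")
        v95 = volume_at_dose(dvh, 0.95 * prescription)
    return DvhMetrics(
        structure=structure,
        d98=dose_at_volume(dvh, 98.0),
        d50=dose_at_volume(dvh, 50.0),
        d2=dose_at_volume(dvh, 2.0),
        dmin=float(values.min()),
        dmean=float(values.mean()),
        dmax=float(values.max()),
        v95=v95,
    )


def dvh_delta(metrics_a: DvhMetrics, metrics_b: DvhMetrics) -> dict[str, float]:
    """Field-wise differences a - b (first-named plan minus second) for two
    metric sets of the same structure."""
    if metrics_a.structure != metrics_b.structure:
        raise ValueError(
            f"structure mismatch: {metrics_a.structure!r} vs {metrics_b.structure!r}"
        )
    out = {
        "d98": metrics_a.d98 - metrics_b.d98,
        "d50": metrics_a.d50 - metrics_b.d50,
        "d2": metrics_a.d2 - metrics_b.d2,
        "dmin": metrics_a.dmin - metrics_b.dmin,
        "dmean": metrics_a.dmean - metrics_b.dmean,
        "dmax": metrics_a.dmax - metrics_b.dmax,
    }
    if metrics_a.v95 is not None and metrics_b.v95 is not None:
        out["v95"] = metrics_a.v95 - metrics_b.v95
    return out


def compute_agv(gas: BinaryMask, dose: ScalarVolume, prescription: float,
                isodose_fraction: float = 0.05) -> float:
    """Active gas volume: cc of GAS voxels receiving at least
    ``isodose_fraction`` (default 5%) of the prescription dose (inclusive)."""
    if dose.unit != "Gy":
        raise ValueError("compute_agv expects a Gy volume")
    if dose.grid != gas.grid:
        raise ValueError("dose and GAS mask are on different grids")
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    threshold = isodose_fraction * prescription
    active = gas.member & (dose.values >= threshold)
    return float(active.sum() * gas.grid.voxel_volume_mm3 / 1000.0)
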