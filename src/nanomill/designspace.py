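"""(E_M, N) design space for a mean-particle-size acceptance window.

The design space is the region of the two critical process parameters --
cumulative mass-specific energy E_M (kJ/kg, horizontal axis) and turnover
cycles N (vertical axis) -- demonstrated to yield acceptable mean particle
size.  Its E_M extent comes from inverting the fitted size-energy law at
the window edges (large sizes need little energy, small sizes much); its N
extent from the operationally demonstrated span of turnover cycles.  Two
corners are beveled where the experimental coverage thins (low-E_M/high-N
and high-E_M/low-N): no batch has ever been run there, so the claim of
demonstrated quality does not extend into those corners.  The result is a
six-sided polygon by default; an explicit vertex list may override the
automatic construction when the registered geometry must be reproduced
verbatim.

Membership is boundary-inclusive (a batch on the edge of the demonstrated
region is inside it).  The size surface over the design space is a
piecewise-linear interpolation on a triangulation of the supporting batches:
exact at every support point and free of overshoot.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError
from shapely.geometry import Point, Polygon

from .correlation import SizeEnergyCorrelation, inverse_energy
from .errors import DesignSpaceError, ExtrapolationWarning
from .io import BatchRecord


@dataclass
class DesignSpace:
    """Polygon in (E_M, N) with its size acceptance window.

    ``vertices`` is an ordered (k, 2) array of (E_M kJ/kg, N) pairs forming
    a simple polygon with positive area.  ``construction`` records whether
    the polygon was built automatically from a correlation plus coverage or
    supplied explicitly.
    """

    vertices: np.ndarray
    x_window_nm: tuple
    construction: str = "auto"
    correlation: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DesignSpaceError("polygon needs at least 3 (E_M, N) vertices")
        self.vertices = v
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise DesignSpaceError("polygon must be simple with positive area")
        lo, hi = self.x_window_nm
        if not lo < hi:
            raise DesignSpaceError("size window must satisfy x_lo < x_hi")
        self.x_window_nm = (float(lo), float(hi))

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def to_dict(self) -> dict:
        return {
            "vertices": self.vertices.tolist(),
            "x_window_nm": list(self.x_window_nm),
            "construction": self.construction,
            "correlation": self.correlation,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpace":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            x_window_nm=tuple(d["x_window_nm"]),
            construction=d.get("construction", "explicit"),
            correlation=d.get("correlation"),
            metadata=d.get("metadata", {}),
        )


def construct_design_space(
    corr: SizeEnergyCorrelation,
    x_window_nm: tuple = (120.0, 180.0),
    N_bounds: tuple = (35.0, 232.0),
    E_M_margin: float = 0.0,
    coverage: Optional[np.ndarray] = None,
    vertices: Optional[Sequence] = None,
) -> DesignSpace:
    """Construct the design space for a size acceptance window.

    The E_M edges sit at ``inverse_energy(x_hi)`` (left) and
    ``inverse_energy(x_lo)`` (right), optionally widened by the relative
    ``E_M_margin``; the N edges at ``N_bounds``.  ``coverage`` -- the
    (E_M, N) points of batches whose size fell inside the window -- drives
    the two bevel cuts: each cut is the tightest 45-degree supporting line
    (in edge-normalized coordinates) of the coverage cloud at the
    low-E_M/high-N and high-E_M/low-N corners, so every covering batch stays
    inside by construction.  Without coverage the polygon is the plain
    rectangle.  ``vertices`` overrides the construction verbatim.
    """
    x_lo, x_hi = float(x_window_nm[0]), float(x_window_nm[1])
    if not x_lo < x_hi:
        raise DesignSpaceError("degenerate size window: x_lo must be < x_hi")
    if vertices is not None:
        return DesignSpace(
            vertices=np.asarray(vertices, dtype=float),
            x_window_nm=(x_lo, x_hi),
            construction="explicit",
            correlation=corr.to_dict() if corr is not None else None,
        )
    n_lo, n_hi = float(N_bounds[0]), float(N_bounds[1])
    if not (0 < n_lo < n_hi):
        raise DesignSpaceError("N bounds must be positive and increasing")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            e_left = inverse_energy(corr, x_hi)
            e_right = inverse_energy(corr, x_lo)
    except ValueError as exc:
        raise DesignSpaceError(f"size window outside fitted range: {exc}") from exc
    e_left *= 1.0 - E_M_margin
    e_right *= 1.0 + E_M_margin
    if not e_left < e_right:
        raise DesignSpaceError("inverted E_M extent; check correlation exponent sign")

    # bevel cuts in edge-normalized coordinates u = (E - e_left)/span_E,
    # v = (N - n_lo)/span_N; cut fractions c in (0, 1], 1 = no cut.
    c_nw = c_se = 1.0
    if coverage is not None and len(coverage):
        pts = np.asarray(coverage, dtype=float)
        u = (pts[:, 0] - e_left) / (e_right - e_left)
        v = (pts[:, 1] - n_lo) / (n_hi - n_lo)
        c_nw = float(min(1.0, np.min(u + 1.0 - v)))  # low-E_M / high-N corner
        c_se = float(min(1.0, np.min(1.0 - u + v)))  # high-E_M / low-N corner
        if c_nw <= 0 or c_se <= 0:
            raise DesignSpaceError("coverage point outside the rectangular extent")

    def denorm(u, v):
        return (e_left + u * (e_right - e_left), n_lo + v * (n_hi - n_lo))

    corners = [denorm(0.0, 0.0)]
    if c_se < 1.0:
        corners += [denorm(1.0 - c_se, 0.0), denorm(1.0, c_se)]
    else:
        corners += [denorm(1.0, 0.0)]
    corners += [denorm(1.0, 1.0)]
    if c_nw < 1.0:
        corners += [denorm(c_nw, 1.0), denorm(0.0, 1.0 - c_nw)]
    else:
        corners += [denorm(0.0, 1.0)]

    return DesignSpace(
        vertices=np.asarray(corners, dtype=float),
        x_window_nm=(x_lo, x_hi),
        construction="auto",
        correlation=corr.to_dict(),
        metadata={
            "N_bounds": [n_lo, n_hi],
            "E_M_extent": [e_left, e_right],
            "bevel_fractions": {"low_E_high_N": c_nw, "high_E_low_N": c_se},
        },
    )


def contains(space: DesignSpace, E_M_kJ_kg: float, N: float) -> bool:
    """Boundary-inclusive point-in-polygon test in (E_M, N)."""
    if not (np.isfinite(E_M_kJ_kg) and np.isfinite(N)):
        return False
    poly = space.polygon
    p = Point(float(E_M_kJ_kg), float(N))
    if poly.covers(p):
        return True
    # tolerate floating-point fuzz for points lying exactly on an edge
    scale = max(np.ptp(space.vertices[:, 0]), np.ptp(space.vertices[:, 1]))
    return poly.exterior.distance(p) <= 1e-9 * scale


def classify_batches(
    space: DesignSpace, records: Sequence[BatchRecord]
) -> pd.DataFrame:
    """Per-batch design-space membership and size-window verdict.

    Returns one row per record with ``in_window`` (measured x_PCS inside the
    acceptance window; False when unmeasured) and ``in_space`` (the batch's
    (E_M, N) inside the polygon).
    """
    lo, hi = space.x_window_nm
    rows = []
    for r in records:
        in_window = r.x_PCS_nm is not None and lo <= r.x_PCS_nm <= hi
        rows.append(
            {
                "experiment": r.experiment,
                "E_M_kJ_kg": r.E_M_kJ_kg,
                "N": r.N,
                "x_PCS_nm": r.x_PCS_nm,
                "in_window": bool(in_window),
                "in_space": contains(space, r.E_M_kJ_kg, r.N),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SizeSurface:
    """Interpolated mean-particle-size surface over (E_M, N).

    Piecewise-linear on the Delaunay triangulation of the support batches:
    exact at supports, NaN outside their convex hull, never exceeding the
    support range (convex combinations only).
    """

    support: np.ndarray  # (n, 3): E_M, N, x_PCS
    grid_E_M: np.ndarray
    grid_N: np.ndarray
    values_nm: np.ndarray  # shape (len(grid_N), len(grid_E_M))
    method: str = "linear"

    def to_frame(self) -> pd.DataFrame:
        ee, nn = np.meshgrid(self.grid_E_M, self.grid_N)
        return pd.DataFrame(
            {
                "E_M_kJ_kg": ee.ravel(),
                "N": nn.ravel(),
                "x_hat_nm": self.values_nm.ravel(),
            }
        )


def build_size_surface(
    records: Sequence[BatchRecord],
    grid_shape: tuple = (60, 60),
    grid_E_M: Optional[np.ndarray] = None,
    grid_N: Optional[np.ndarray] = None,
) -> SizeSurface:
    """Triangulate the measured batches and interpolate x_PCS on a grid."""
    pts = np.asarray(
        [
            (r.E_M_kJ_kg, r.N, r.x_PCS_nm)
            for r in records
            if r.x_PCS_nm is not None
        ],
        dtype=float,
    )
    if pts.shape[0] < 3:
        raise DesignSpaceError("surface needs at least 3 measured batches")
    try:
        interp = LinearNDInterpolator(pts[:, :2], pts[:, 2])
    except QhullError as exc:
        raise DesignSpaceError(f"support points are collinear: {exc}") from exc
    if grid_E_M is None:
        grid_E_M = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_shape[0])
    if grid_N is None:
        grid_N = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_shape[1])
    ee, nn = np.meshgrid(grid_E_M, grid_N)
    values = interp(ee, nn)
    return SizeSurface(
        support=pts,
        grid_E_M=np.asarray(grid_E_M, dtype=float),
        grid_N=np.asarray(grid_N, dtype=float),
        values_nm=values,
    )


def surface_value(surface: SizeSurface, E_M_kJ_kg: float, N: float) -> float:
    """Interpolated size at one point (NaN outside the support hull)."""
    interp = LinearNDInterpolator(surface.support[:, :2], surface.support[:, 2])
    return float(interp(E_M_kJ_kg, N))


def default_design_space(
    records: Optional[Sequence[BatchRecord]] = None,
    x_window_nm: tuple = (120.0, 180.0),
    N_bounds: Optional[tuple] = None,
    E_M_margin: float = 0.0,
) -> DesignSpace:
    """Design space from a batch table: fit the size-energy law, take the
    in-window batches as coverage, and construct the beveled polygon.

    Defaults to the packaged 22-experiment reference table and the 120-180 nm
    acceptance window; ``N_bounds`` defaults to the table's N span.
    """
    from .correlation import fit_size_energy
    from .io import load_reference_table

    if records is None:
        records = load_reference_table()
    corr = fit_size_energy(records)
    lo, hi = x_window_nm
    coverage = np.asarray(
        [
            (r.E_M_kJ_kg, r.N)
            for r in records
            if r.x_PCS_nm is not None and lo <= r.x_PCS_nm <= hi
        ],
        dtype=float,
    )
    if N_bounds is None:
        all_N = [r.N for r in records]
        N_bounds = (float(min(all_N)), float(max(all_N)))
    return construct_design_space(
        corr,
        x_window_nm=x_window_nm,
        N_bounds=N_bounds,
        E_M_margin=E_M_margin,
        coverage=coverage,
    )
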