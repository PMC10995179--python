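"""Curve functionals of a cyclic voltammogram.

Three quantities drive the QC workflow:

* **ABC** — the area between the anodic (rising-potential) and cathodic
  (falling-potential) branches of one CV loop, in µA·V.  A proxy for surface
  charge density.  Computed with the left-rectangle rule on the anodic
  potential grid.
* **peak current** — the grid-search maximum-magnitude current on a branch
  (anodic by default, marking the oxidation peak), in µA.  A proxy for charge
  transfer.
* **D** — the area of the symmetric set difference between the planar regions
  enclosed by two CV loops, in µA·V.  The workflow's curve-similarity
  distance: zero iff the regions coincide, symmetric, and a pseudometric.

Real CV traces can self-intersect near the vertex potentials, so a raw loop
is first *repaired* into a planar region set with even-odd fill semantics:
the trace is noded at its self-crossings, the resulting faces are classified
by ray-crossing parity against the original closed trace, and odd-parity
faces form the region.  All boolean operations run on coordinates jointly
rescaled to the unit box (potential spans volts while currents span hundreds
of µA; anisotropy would otherwise degrade geometric predicates) and areas are
rescaled back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.ops import polygonize, unary_union

from .io_formats import Voltammogram

#: Geometric tolerance in normalized (unit-box) coordinates.
EPS = 1e-9


class DegenerateGeometryError(ValueError):
    """The loop encloses no usable area (collinear points or area < EPS)."""


class BranchSplitError(ValueError):
    """The potential trace has no turning point to separate the branches."""


@dataclass
class LoopPolygon:
    """A CV loop repaired into a valid planar region set (even-odd fill)."""

    vertices: np.ndarray          # (n, 2) raw closed trace, original units
    region: Polygon | MultiPolygon  # repaired region, original units

    @property
    def area(self) -> float:
        return float(self.region.area)


@dataclass
class AreaValue:
    """A nonnegative area in µA·V."""

    value: float

    def __post_init__(self) -> None:
        # clamp away float negatives from boolean-op round-off
        if self.value < 0:
            if self.value < -1e-6:
                raise ValueError(f"negative area {self.value}")
            self.value = 0.0

    def __float__(self) -> float:
        return self.value


@dataclass
class PeakResult:
    peak_current: float   # µA, signed value at the max-magnitude grid point
    peak_potential: float  # V
    branch: str           # "anodic" | "cathodic"


# ---------------------------------------------------------------------------
# Even-odd region construction
# ---------------------------------------------------------------------------

def _crossing_parity(px: np.ndarray, py: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Ray-crossing parity of query points against a closed polyline.

    Casts a horizontal ray to +x; odd crossing count means inside under the
    even-odd fill rule.  Vectorized over points and edges.
    """
    x1, y1 = coords[:-1, 0], coords[:-1, 1]
    x2, y2 = coords[1:, 0], coords[1:, 1]
    px = np.atleast_1d(px)[:, None]
    py = np.atleast_1d(py)[:, None]
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = np.sum(straddles & (px < xint), axis=1)
    return crossings % 2


def _evenodd_region(coords: np.ndarray) -> Polygon | MultiPolygon:
    """Region enclosed by a closed trace under the even-odd fill rule.

    ``coords`` is (n, 2) with an explicit closing vertex.  Simple rings take
    the fast path; self-intersecting ones are noded and their faces kept when
    the face's representative point has odd crossing parity.
    """
    ring = LineString(coords)
    if ring.is_simple:
        poly = Polygon(coords)
        if poly.is_valid:
            return poly
    noded = unary_union(ring)
    faces = list(polygonize(noded))
    keep = []
    for face in faces:
        rp = face.representative_point()
        if _crossing_parity(np.array([rp.x]), np.array([rp.y]), coords)[0] == 1:
            keep.append(face)
    if not keep:
        raise DegenerateGeometryError("trace encloses no area under even-odd fill")
    region = unary_union(keep)
    if isinstance(region, Polygon):
        return region
    return MultiPolygon([g for g in region.geoms if isinstance(g, Polygon)])


def _bounds(*vgrams: Voltammogram) -> tuple[float, float, float, float]:
    """Joint (vmin, vrange, imin, irange) over one or more loops."""
    v = np.concatenate([g.potential for g in vgrams])
    i = np.concatenate([g.current for g in vgrams])
    vr = float(v.max() - v.min()) or 1.0
    ir = float(i.max() - i.min()) or 1.0
    return float(v.min()), vr, float(i.min()), ir


def _closed_coords(v: Voltammogram, vmin: float, vr: float,
                   imin: float, ir: float) -> np.ndarray:
    x = (v.potential - vmin) / vr
    y = (v.current - imin) / ir
    coords = np.column_stack([x, y])
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[0]])
    return coords


def _region_normalized(v: Voltammogram, vmin: float, vr: float,
                       imin: float, ir: float) -> Polygon | MultiPolygon:
    coords = _closed_coords(v, vmin, vr, imin, ir)
    try:
        region = _evenodd_region(coords)
    except DegenerateGeometryError:
        raise DegenerateGeometryError(
            f"degenerate loop: electrode {v.electrode_id!r} sweep {v.sweep_index}"
        ) from None
    if region.area < EPS:
        raise DegenerateGeometryError(
            f"degenerate loop (area < {EPS} normalized): "
            f"electrode {v.electrode_id!r} sweep {v.sweep_index}"
        )
    return region


def as_loop(v: Voltammogram) -> LoopPolygon:
    """Repair a voltammogram trace into a :class:`LoopPolygon` (original units)."""
    vmin, vr, imin, ir = _bounds(v)
    region = _region_normalized(v, vmin, vr, imin, ir)
    # map the normalized region back to volts / µA
    region = shapely.affinity.affine_transform(region, [vr, 0, 0, ir, vmin, imin])
    raw = np.column_stack([v.potential, v.current])
    return LoopPolygon(vertices=raw, region=region)


# ---------------------------------------------------------------------------
# Branch handling and ABC
# ---------------------------------------------------------------------------

def split_branches(v: Voltammogram) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split a loop into anodic / cathodic passes.

    The trace is rotated so it starts at the potential minimum; the anodic
    branch runs up to the first global potential maximum, the cathodic branch
    is the remainder.  Returns (V_anodic, I_anodic, V_cathodic, I_cathodic).
    """
    start = int(np.argmin(v.potential))
    pv = np.roll(v.potential, -start)
    ci = np.roll(v.current, -start)
    imax = int(np.argmax(pv))
    if imax == 0 or imax >= pv.size - 1:
        raise BranchSplitError(
            f"electrode {v.electrode_id!r} sweep {v.sweep_index}: no potential turning point"
        )
    va, ia = pv[: imax + 1], ci[: imax + 1]
    vc, ic = pv[imax:], ci[imax:]
    if va.size < 2 or vc.size < 2:
        raise BranchSplitError(
            f"electrode {v.electrode_id!r} sweep {v.sweep_index}: branch too short"
        )
    return va, ia, vc, ic


def abc(v: Voltammogram) -> AreaValue:
    """Area between the anodic and cathodic branches (left-rectangle rule).

    The cathodic branch is linearly interpolated onto the anodic potential
    grid; the left Riemann sum of |I_anodic − I_cathodic| over that grid gives
    the area.  For a simple loop this agrees with the even-odd polygon area
    up to one-grid-cell discretization error.
    """
    va, ia, vc, ic = split_branches(v)
    order = np.argsort(vc, kind="stable")
    i_low = np.interp(va, vc[order], ic[order])
    dv = np.diff(va)
    value = float(np.sum(np.abs(ia[:-1] - i_low[:-1]) * dv))
    return AreaValue(value)


def peak_current(v: Voltammogram, branch: str = "anodic") -> PeakResult:
    """Maximum-magnitude current on a branch, found by grid search.

    No interpolation beyond the sampled grid: the peak is a data point.  The
    anodic branch (oxidation peak) is the default.
    """
    va, ia, vc, ic = split_branches(v)
    if branch == "anodic":
        bv, bi = va, ia
    elif branch == "cathodic":
        bv, bi = vc, ic
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if bv.size == 0:
        raise BranchSplitError(f"empty {branch} branch")
    idx = int(np.argmax(np.abs(bi)))
    return PeakResult(peak_current=float(bi[idx]), peak_potential=float(bv[idx]),
                      branch=branch)


# ---------------------------------------------------------------------------
# Symmetric-difference distance
# ---------------------------------------------------------------------------

def symmetric_difference_area(v1: Voltammogram, v2: Voltammogram) -> AreaValue:
    """Non-overlapping area D between two CV loops, in µA·V.

    D = area(A) + area(B) − 2·area(A ∩ B) on the repaired even-odd regions.
    Symmetric, nonnegative, zero iff the regions coincide; as a symmetric-
    difference measure it satisfies the triangle inequality (pseudometric).
    """
    vmin, vr, imin, ir = _bounds(v1, v2)
    a = _region_normalized(v1, vmin, vr, imin, ir)
    b = _region_normalized(v2, vmin, vr, imin, ir)
    d_norm = a.area + b.area - 2.0 * a.intersection(b).area
    if d_norm < EPS:  # coincident regions up to tolerance
        d_norm = 0.0
    return AreaValue(d_norm * vr * ir)
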