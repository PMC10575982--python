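"""AFM height-map analysis: backbone tracing, curvature, and chirality.

Coordinate convention: image origin at the top-left pixel centre, x
rightward (columns), y downward (rows); positions are in nm (pixel index ×
pixel size) and heights in nm.

The chirality statistic follows the crossing-point construction: section
profiles are taken along two lines through a bundle crossing (roles "AB"
and "CD", chosen so that the AB bundle lies underneath when the structure
is right-handed), uphill slopes are regressed on the ascending flank of
each profile, and the sign of slope_AB - slope_CD calls the handedness
(positive = right).  Only uphill flanks are used because downhill regions
are unreliable in high-speed AFM (tip parachuting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, DomainError

__all__ = [
    "AFMImage",
    "BackboneTrace",
    "SectionLine",
    "ChiralityResult",
    "CurvatureResult",
    "trace_backbone",
    "curvature_radius",
    "turns_from_trace",
    "section_profile",
    "uphill_slope",
    "chirality_from_slopes",
    "find_crossing",
    "fit_circle",
]

#: slopes closer than this (nm/nm) are called indeterminate
DEFAULT_SLOPE_TOLERANCE = 1e-3


@dataclass
class AFMImage:
    """Height map (nm) on a square-pixel grid."""

    heights: np.ndarray
    pixel_size_nm: float
    scan_direction: str = "left-to-right"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise DomainError("heights must be a nonempty 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise DomainError("heights must be finite")
        if self.pixel_size_nm <= 0:
            raise DomainError("pixel_size_nm must be positive")
        if self.scan_direction not in ("left-to-right", "right-to-left"):
            raise DomainError("scan_direction must be 'left-to-right' or 'right-to-left'")

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the scan in nm."""
        ny, nx = self.heights.shape
        return ((nx - 1) * self.pixel_size_nm, (ny - 1) * self.pixel_size_nm)

    def mirrored(self) -> "AFMImage":
        """Left-right mirror image (flips chirality of any rendered structure)."""
        return AFMImage(self.heights[:, ::-1].copy(), self.pixel_size_nm, self.scan_direction)


@dataclass
class BackboneTrace:
    """Ordered centreline polyline (nm) of a traced ridge."""

    points_nm: np.ndarray

    def __post_init__(self) -> None:
        self.points_nm = np.asarray(self.points_nm, dtype=float)
        if self.points_nm.ndim != 2 or self.points_nm.shape[1] != 2:
            raise DomainError("points must be an (n, 2) array")
        if len(self.points_nm) < 3:
            raise DomainError("backbone trace needs at least 3 points")
        if np.any(np.all(np.diff(self.points_nm, axis=0) == 0, axis=1)):
            raise DomainError("consecutive trace points must be distinct")

    def arclength(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points_nm, axis=0), axis=1)))

    def __len__(self) -> int:
        return len(self.points_nm)


@dataclass(frozen=True)
class SectionLine:
    """A section line through the image: two endpoints (nm) and a role."""

    p0_nm: tuple
    p1_nm: tuple
    role: str = "AB"
    n_samples: int = 100

    def __post_init__(self) -> None:
        if np.allclose(self.p0_nm, self.p1_nm):
            raise DomainError("section-line endpoints must be distinct")
        if self.role not in ("AB", "CD"):
            raise DomainError("role must be 'AB' or 'CD'")
        if self.n_samples < 10:
            raise DomainError("need at least 10 samples along the line")


@dataclass(frozen=True)
class ChiralityResult:
    """Crossing-slope chirality call: right iff slope_AB - slope_CD > tolerance."""

    slope_AB: float
    slope_CD: float
    delta: float
    call: str

    def __post_init__(self) -> None:
        if self.call not in ("right", "left", "indeterminate"):
            raise DomainError(f"invalid call {self.call!r}")


@dataclass(frozen=True)
class CurvatureResult:
    """Least-squares circle fit of a backbone trace."""

    radius_nm: float
    center_nm: tuple
    rms_nm: float
    turns: float | None = None

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise DomainError("radius must be positive")
        if self.turns is not None and self.turns < 0:
            raise DomainError("turns must be >= 0")


# ------------------------------------------------------------ ridge tracing

def trace_backbone(img: AFMImage, height_threshold: float) -> BackboneTrace:
    """Trace the centreline of the largest above-threshold ridge.

    The thresholded mask is skeletonised; the longest geodesic path through
    the skeleton of the largest connected component is returned as an
    ordered polyline in nm.  Branched skeletons take the longest path and
    emit a warning.
    """
    import networkx as nx
    from skimage.morphology import skeletonize

    mask = img.heights > height_threshold
    if not mask.any():
        raise DomainError(f"no pixels above threshold {height_threshold} nm")
    labels, n_lab = ndimage.label(mask)
    if n_lab > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_lab + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    skel = skeletonize(mask)
    rows, cols = np.nonzero(skel)
    if len(rows) < 3:
        raise DomainError("skeleton too short to trace")

    G = nx.Graph()
    pixset = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pixset:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                nb = (r + dr, c + dc)
                if nb in pixset:
                    G.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    if any(d > 2 for _, d in G.degree()):
        warnings.warn("branched skeleton: taking the longest path", stacklevel=2)

    # double-sweep: farthest node from an arbitrary start, then farthest from that
    start = next(iter(G.nodes))
    dist = nx.single_source_dijkstra_path_length(G, start)
    a = max(dist, key=dist.get)
    dist_a, paths_a = nx.single_source_dijkstra(G, a)
    b = max(dist_a, key=dist_a.get)
    path = paths_a[b]
    pts = np.array([(c * img.pixel_size_nm, r * img.pixel_size_nm) for r, c in path])
    return BackboneTrace(points_nm=pts)


# ------------------------------------------------------------- circle fitting

def fit_circle(points: np.ndarray, cond_threshold: float = 1e8) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through 2-D ``points``: Taubin algebraic fit
    refined geometrically; returns (center, radius, rms).

    Raises DegenerateGeometryError for (near-)collinear input, detected via
    the conditioning of the algebraic system.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DomainError("need an (n>=3, 2) point array")
    xm, ym = pts.mean(axis=0)
    u = pts[:, 0] - xm
    v = pts[:, 1] - ym
    z = u * u + v * v
    # collinearity check on the centred coordinates
    _, sv, _ = np.linalg.svd(np.column_stack([u, v]), full_matrices=False)
    if sv[0] == 0 or sv[0] / max(sv[-1], np.finfo(float).tiny) > cond_threshold:
        raise DegenerateGeometryError("points are collinear: circle radius is unbounded")

    # algebraic circle fit in centred coordinates, then geometric refinement
    A = np.column_stack([u, v, np.ones(len(pts))])
    b = z
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx = 0.5 * sol[0]
    cy = 0.5 * sol[1]
    r0 = float(np.sqrt(sol[2] + cx * cx + cy * cy))

    def resid(theta):
        tx, ty, tr = theta
        return np.hypot(u - tx, v - ty) - tr

    res = least_squares(resid, x0=[cx, cy, r0], method="lm")
    cx, cy, r = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    if r <= 0 or not np.isfinite(r):
        raise DegenerateGeometryError("circle fit did not produce a positive radius")
    return np.array([cx + xm, cy + ym]), float(r), rms


def curvature_radius(traced: BackboneTrace) -> CurvatureResult:
    """Curvature radius (nm) of a traced backbone by least-squares circle fit."""
    center, radius, rms = fit_circle(traced.points_nm)
    return CurvatureResult(radius_nm=radius, center_nm=tuple(center), rms_nm=rms)


def turns_from_trace(traced: BackboneTrace, radius_nm: float) -> float:
    """Number of helical turns: polyline arclength / (2π · radius)."""
    if radius_nm <= 0:
        raise DomainError("radius must be positive")
    s = traced.arclength()
    if s == 0:
        raise DomainError("zero-length polyline")
    return s / (2.0 * np.pi * radius_nm)


# ---------------------------------------------------------- section profiles

def section_profile(img: AFMImage, line: SectionLine) -> tuple[np.ndarray, np.ndarray]:
    """Sample heights by bilinear interpolation along a section line.

    Returns (distance nm, height nm) at ``line.n_samples`` uniform stations.
    """
    p0 = np.asarray(line.p0_nm, dtype=float)
    p1 = np.asarray(line.p1_nm, dtype=float)
    w, h = img.extent_nm
    for p in (p0, p1):
        if not (0 <= p[0] <= w and 0 <= p[1] <= h):
            raise DomainError(f"section-line endpoint {tuple(p)} outside image bounds {(w, h)} nm")
    t = np.linspace(0.0, 1.0, line.n_samples)
    xy = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    cols = xy[:, 0] / img.pixel_size_nm
    rows = xy[:, 1] / img.pixel_size_nm
    heights = ndimage.map_coordinates(img.heights, [rows, cols], order=1, mode="nearest")
    dist = t * float(np.linalg.norm(p1 - p0))
    return dist, heights


def uphill_slope(
    distance_nm: np.ndarray,
    height_nm: np.ndarray,
    flank_window: tuple = (0.2, 0.8),
) -> float:
    """Least-squares slope (nm/nm) of the ascending flank of a profile.

    The flank runs from the start of the profile to its maximum; samples
    whose height lies between 20% and 80% of the rise above the flank's
    base enter the regression.  Raises for profiles with no ascent.
    """
    d = np.asarray(distance_nm, dtype=float)
    z = np.asarray(height_nm, dtype=float)
    if len(d) != len(z) or len(d) < 3:
        raise DomainError("profile arrays must match and have >= 3 samples")
    ipk = int(np.argmax(z))
    if ipk == 0:
        raise DomainError("profile maximum at its first sample: no uphill flank")
    flank_d = d[: ipk + 1]
    flank_z = z[: ipk + 1]
    base = float(flank_z.min())
    rise = float(flank_z[-1] - base)
    if rise <= 0:
        raise DomainError("profile has no ascending flank")
    lo, hi = flank_window
    sel = (flank_z >= base + lo * rise) & (flank_z <= base + hi * rise)
    if sel.sum() < 2:
        # very steep flank: fall back to the two bracketing samples
        sel = np.zeros_like(sel)
        sel[max(ipk - 1, 0): ipk + 1] = True
    slope = float(np.polyfit(flank_d[sel], flank_z[sel], 1)[0])
    return slope


def chirality_from_slopes(
    slope_AB: float,
    slope_CD: float,
    tolerance: float = DEFAULT_SLOPE_TOLERANCE,
) -> ChiralityResult:
    """Handedness from the uphill-slope difference slope_AB - slope_CD.

    Positive difference beyond ``tolerance`` calls right-handed; negative
    beyond tolerance calls left-handed; otherwise indeterminate.
    """
    if not (np.isfinite(slope_AB) and np.isfinite(slope_CD)):
        raise DomainError("slopes must be finite")
    delta = float(slope_AB - slope_CD)
    if delta > tolerance:
        call = "right"
    elif delta < -tolerance:
        call = "left"
    else:
        call = "indeterminate"
    return ChiralityResult(slope_AB=float(slope_AB), slope_CD=float(slope_CD), delta=delta, call=call)


def find_crossing(img: AFMImage, smooth_nm: float = 2.0) -> tuple[float, float]:
    """Locate the crossing point as the global maximum of the smoothed map.

    Returns (x, y) in nm; a helper for choosing section lines.
    """
    sigma = smooth_nm / img.pixel_size_nm
    sm = ndimage.gaussian_filter(img.heights, sigma) if sigma > 0 else img.heights
    r, c = np.unravel_index(int(np.argmax(sm)), sm.shape)
    return (c * img.pixel_size_nm, r * img.pixel_size_nm)
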