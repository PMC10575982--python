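"""Coarse-grained trajectory analysis: oxDNA I/O, RMSD/RMSF, helix fitting.

The oxDNA configuration format stores, per frame, three header lines
(``t = ...``, ``b = ...``, ``E = ...``) followed by one row per nucleotide
with 15 whitespace-separated floats (position, backbone-base versor, normal
versor, velocity, angular velocity) in reduced units.  Lengths convert at
0.8518 nm per oxDNA unit and times at 3.03 ps per oxDNA unit.

RMSD here is deliberately computed without superposition: it is the root
mean (over entities) squared displacement from the frame-0 position, so a
rigid 5 nm translation reads as exactly 5 nm.  RMSF is the per-entity root
mean squared excursion about the window-averaged position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, DomainError, ParseError

__all__ = [
    "OXDNA_LENGTH_NM",
    "OXDNA_TIME_PS",
    "Trajectory",
    "HelixFit",
    "RadiusComparison",
    "read_oxdna",
    "write_oxdna",
    "rmsd_trace",
    "rmsf",
    "select_time_window",
    "average_guide_points",
    "fit_helix",
    "compare_backbone_pier",
]

OXDNA_LENGTH_NM = 0.8518  # nm per oxDNA length unit
OXDNA_TIME_PS = 3.03      # ps per oxDNA time unit


@dataclass
class Trajectory:
    """Frames × entities × 3 positions (nm) with per-frame times (ps)."""

    times_ps: np.ndarray
    positions_nm: np.ndarray

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        if self.positions_nm.ndim != 3 or self.positions_nm.shape[2] != 3:
            raise DomainError("positions must have shape (frames, entities, 3)")
        if len(self.times_ps) != len(self.positions_nm):
            raise DomainError("times and positions must have the same frame count")
        if len(self.times_ps) < 1:
            raise DomainError("need at least one frame")
        if np.any(np.diff(self.times_ps) < 0):
            raise DomainError("times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)

    @property
    def n_entities(self) -> int:
        return self.positions_nm.shape[1]


@dataclass
class HelixFit:
    """Fitted helix: axis, radius (nm), pitch (nm/turn), turns, handedness."""

    axis_point_nm: np.ndarray
    axis_direction: np.ndarray
    radius_nm: float
    pitch_nm: float
    turns: float
    handedness: str          # "right" | "left" | "indeterminate"
    rms_nm: float

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise DomainError("radius must be positive")
        if self.pitch_nm < 0:
            raise DomainError("pitch must be >= 0")
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-6:
            raise DomainError("axis_direction must be a unit vector")
        if self.handedness not in ("right", "left", "indeterminate"):
            raise DomainError(f"invalid handedness {self.handedness!r}")


@dataclass(frozen=True)
class RadiusComparison:
    """Backbone vs pier helix radii; positive difference = backbone inside."""

    r_backbone_nm: float
    r_pier_nm: float
    difference_nm: float
    call: str  # "backbone-inside" | "backbone-outside" | "indeterminate"


# ------------------------------------------------------------------ oxDNA I/O

def read_topology(path) -> int:
    """Return the nucleotide count from an oxDNA topology file."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ParseError(f"{path}:1: malformed topology header")
        try:
            n_nt = int(header[0])
        except ValueError as exc:
            raise ParseError(f"{path}:1: malformed topology header") from exc
        n_rows = sum(1 for line in fh if line.strip())
    if n_rows != n_nt:
        raise ParseError(f"{path}: topology declares {n_nt} nucleotides but has {n_rows} rows")
    return n_nt


def read_oxdna(
    topology_path,
    configuration_path,
    length_unit_nm: float = OXDNA_LENGTH_NM,
    time_unit_ps: float = OXDNA_TIME_PS,
) -> Trajectory:
    """Parse an oxDNA topology + configuration/trajectory file pair.

    Keeps positions only; converts lengths and times to nm / ps.  Raises
    ParseError with a line number for malformed headers, wrong column
    counts, or a truncated final frame.
    """
    n_nt = read_topology(topology_path)
    times = []
    frames = []
    with open(configuration_path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        header = lines[i].split("=")
        if len(header) != 2 or header[0].strip() != "t":
            raise ParseError(f"{configuration_path}:{i + 1}: expected 't = ...' header")
        try:
            t = float(header[1])
        except ValueError as exc:
            raise ParseError(f"{configuration_path}:{i + 1}: bad time value") from exc
        if i + 2 >= n_lines or not lines[i + 1].lstrip().startswith("b") \
                or not lines[i + 2].lstrip().startswith("E"):
            raise ParseError(f"{configuration_path}:{i + 1}: frame {frame_no} missing 'b'/'E' header lines")
        i += 3
        pos = np.empty((n_nt, 3))
        for row in range(n_nt):
            if i >= n_lines or not lines[i].strip():
                raise ParseError(
                    f"{configuration_path}:{i + 1}: frame {frame_no} truncated "
                    f"({row}/{n_nt} nucleotide rows)"
                )
            fields = lines[i].split()
            if len(fields) != 15:
                raise ParseError(
                    f"{configuration_path}:{i + 1}: expected 15 columns, got {len(fields)}"
                )
            pos[row] = [float(fields[0]), float(fields[1]), float(fields[2])]
            i += 1
        times.append(t * time_unit_ps)
        frames.append(pos * length_unit_nm)
    if not frames:
        raise ParseError(f"{configuration_path}: no frames found")
    return Trajectory(times_ps=np.array(times), positions_nm=np.array(frames))


def write_oxdna(
    topology_path,
    configuration_path,
    traj: Trajectory,
    length_unit_nm: float = OXDNA_LENGTH_NM,
    time_unit_ps: float = OXDNA_TIME_PS,
    box_units: float = 100.0,
) -> None:
    """Write a Trajectory in the oxDNA layout (one poly-T strand topology).

    Versors are placeholders and velocities zero; only positions carry
    information.  Intended for reader round-trip tests and interchange.
    """
    n = traj.n_entities
    with open(topology_path, "w") as fh:
        fh.write(f"{n} 1\n")
        for k in range(n):
            prev = k - 1 if k > 0 else -1
            nxt = k + 1 if k < n - 1 else -1
            fh.write(f"1 T {prev} {nxt}\n")
    with open(configuration_path, "w") as fh:
        for t, frame in zip(traj.times_ps, traj.positions_nm):
            fh.write(f"t = {t / time_unit_ps:.10g}\n")
            fh.write(f"b = {box_units:g} {box_units:g} {box_units:g}\n")
            fh.write("E = 0 0 0\n")
            for p in frame / length_unit_nm:
                fh.write(
                    f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} "
                    "1 0 0 0 1 0 0 0 0 0 0 0\n"
                )


# --------------------------------------------------------------- RMSD / RMSF

def rmsd_trace(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """RMSD(t) = sqrt(mean over entities |r_i(t) - r_i(0)|^2), no superposition."""
    if traj.n_frames < 2:
        raise DomainError("need at least 2 frames")
    disp = traj.positions_nm - traj.positions_nm[0]
    rmsd = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=1))
    return traj.times_ps, rmsd


def select_time_window(traj: Trajectory, t_lo_ns: float, t_hi_ns: float) -> np.ndarray:
    """Frame indices with time in the half-open window (t_lo, t_hi] ns.

    Half-open so a request of 2000–3000 ns on a 10 ns-spaced trajectory
    selects exactly 100 frames.
    """
    t_ns = traj.times_ps / 1e3
    return np.nonzero((t_ns > t_lo_ns) & (t_ns <= t_hi_ns))[0]


def rmsf(traj: Trajectory, frame_indices=None) -> np.ndarray:
    """Per-entity RMSF (nm) about the window-averaged reference position.

    ``frame_indices`` selects the averaging window (default: all frames);
    use :func:`select_time_window` for a time-based window.
    """
    if frame_indices is None:
        frame_indices = np.arange(traj.n_frames)
    frame_indices = np.asarray(frame_indices, dtype=int)
    if len(frame_indices) < 2:
        raise DomainError("RMSF window must select at least 2 frames")
    sub = traj.positions_nm[frame_indices]
    ref = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - ref) ** 2, axis=2), axis=0))


# ------------------------------------------------------------- guide points

def average_guide_points(positions_nm: np.ndarray, index_pairs) -> np.ndarray:
    """Midpoints of entity index pairs, order preserved (26 entities → 13 points)."""
    pos = np.asarray(positions_nm, dtype=float)
    n = len(pos)
    pts = []
    for i, j in index_pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise DomainError(f"guide-point index pair ({i}, {j}) out of range for {n} entities")
        pts.append(0.5 * (pos[i] + pos[j]))
    return np.asarray(pts)


# ------------------------------------------------------------- helix fitting

def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _helix_residuals(points: np.ndarray, axis: np.ndarray):
    """Radial and axial residuals of points about the best circle+pitch for
    a given axis direction; returns (residuals, derived-quantities dict)."""
    u, v = _orthonormal_basis(axis)
    xi = points @ u
    eta = points @ v
    zeta = points @ axis
    # algebraic circle fit in the axis-normal plane
    xm, ym = xi.mean(), eta.mean()
    a = np.column_stack([xi - xm, eta - ym, np.ones(len(points))])
    b = (xi - xm) ** 2 + (eta - ym) ** 2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx = 0.5 * sol[0] + xm
    cy = 0.5 * sol[1] + ym
    r = np.sqrt(max(sol[2] + (cx - xm) ** 2 + (cy - ym) ** 2, 1e-30))
    rho = np.hypot(xi - cx, eta - cy)
    phi = np.unwrap(np.arctan2(eta - cy, xi - cx))
    coef = np.polyfit(phi, zeta, 1)
    axial = zeta - np.polyval(coef, phi)
    radial = rho - r
    derived = {
        "radius": float(r), "phase": phi, "dz_dphi": float(coef[0]),
        "center_plane": (float(cx), float(cy)), "zeta_mean": float(zeta.mean()),
        "basis": (u, v),
    }
    return np.concatenate([radial, axial]), derived


def fit_helix(points, axis_tol: float = 1e-10) -> HelixFit:
    """Least-squares helix through ordered 3-D points.

    The axis direction is optimised (two spherical angles) so that the
    combined radial and axial residuals of a circle fit in the axis-normal
    plane plus a linear fit of axial position versus unwrapped phase are
    minimised.  Handedness is the sign of the mean triple product
    (t_k × t_{k+1}) · axis over consecutive tangents, with the axis oriented
    along the point ordering; it is reported indeterminate when the fit RMS
    reaches the radius.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DomainError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise DomainError("helix fit needs at least 4 points")
    centred = pts - pts.mean(axis=0)
    _, sv, _ = np.linalg.svd(centred, full_matrices=False)
    if sv[0] == 0 or sv[1] / sv[0] < 1e-8:
        raise DegenerateGeometryError("points are collinear: helix is degenerate")

    d = np.diff(pts, axis=0)
    cr = np.cross(d[:-1], d[1:])
    a0 = cr.sum(axis=0)
    if np.linalg.norm(a0) < 1e-12:
        # fall back: smallest principal direction of the tangents
        _, _, vt = np.linalg.svd(d - d.mean(axis=0), full_matrices=False)
        a0 = vt[-1]
    a0 = a0 / np.linalg.norm(a0)

    theta0 = np.arccos(np.clip(a0[2], -1.0, 1.0))
    phi0 = np.arctan2(a0[1], a0[0])

    def axis_of(angles):
        th, ph = angles
        return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

    def cost(angles):
        res, _ = _helix_residuals(pts, axis_of(angles))
        return res

    opt = least_squares(cost, x0=[theta0, phi0], xtol=axis_tol, ftol=axis_tol, gtol=axis_tol)
    axis = axis_of(opt.x)
    res, derived = _helix_residuals(pts, axis)
    rms = float(np.sqrt(np.mean(res**2)))
    radius = derived["radius"]
    phi = derived["phase"]
    turns = float(abs(phi[-1] - phi[0]) / (2.0 * np.pi))
    pitch = float(2.0 * np.pi * abs(derived["dz_dphi"]))

    # orient the axis along the point ordering
    if (pts[-1] - pts[0]) @ axis < 0:
        axis = -axis

    tangents = d / np.linalg.norm(d, axis=1, keepdims=True)
    triple = np.einsum("ij,j->i", np.cross(tangents[:-1], tangents[1:]), axis)
    s = float(np.mean(triple))
    if rms >= radius or s == 0.0:
        handedness = "indeterminate"
    else:
        handedness = "right" if s > 0 else "left"

    u, v = derived["basis"]
    cx, cy = derived["center_plane"]
    axis_point = cx * u + cy * v + derived["zeta_mean"] * axis_of(opt.x)
    return HelixFit(
        axis_point_nm=axis_point, axis_direction=axis, radius_nm=radius,
        pitch_nm=pitch, turns=turns, handedness=handedness, rms_nm=rms,
    )


def compare_backbone_pier(
    fit_b: HelixFit,
    fit_p: HelixFit,
    max_axis_angle_deg: float = 30.0,
    tol_nm: float = 0.0,
) -> RadiusComparison:
    """Radius difference r_pier - r_backbone with an inside/outside call.

    Positive difference → backbone-inside; negative → backbone-outside.
    Requires the two helix axes to agree within ``max_axis_angle_deg``
    (axis sign ignored).
    """
    cosang = abs(float(fit_b.axis_direction @ fit_p.axis_direction))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if angle > max_axis_angle_deg:
        raise DomainError(f"helix axes differ by {angle:.1f} deg (> {max_axis_angle_deg} deg)")
    diff = float(fit_p.radius_nm - fit_b.radius_nm)
    if diff > tol_nm:
        call = "backbone-inside"
    elif diff < -tol_nm:
        call = "backbone-outside"
    else:
        call = "indeterminate"
    return RadiusComparison(
        r_backbone_nm=fit_b.radius_nm, r_pier_nm=fit_p.radius_nm,
        difference_nm=diff, call=call,
    )
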