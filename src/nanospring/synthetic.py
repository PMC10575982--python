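"""Seeded generators for every input class the analysis pipeline consumes.

Instrument and simulation data for nanospring experiments are not publicly
deposited, so these generators emulate the statistical structure of each
input: WLC+Hooke force-extension curves with optional unfolding hysteresis,
exponential-relaxation force-jump traces obeying a bilinear spring law,
rendered crossing-bundle AFM height maps of chosen handedness, helical
point clouds, and fluctuating pseudo-trajectories.  Every generator is a
pure function of its arguments: the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afm import AFMImage, SectionLine
from .exceptions import DomainError
from .jump import ForceJumpTrace
from .models import ConstructModel, WLCParams, construct_extension, wlc_extension_at_force
from .ramp import ForceExtensionTrace
from .trajectory import Trajectory

__all__ = [
    "BilinearSpring",
    "gen_force_extension",
    "gen_force_jump_trace",
    "gen_afm_crossing_image",
    "gen_helix_points",
    "gen_trajectory",
]


@dataclass(frozen=True)
class BilinearSpring:
    """Piecewise-linear spring law with an entropic/enthalpic breakpoint.

    Extension at force F (continuous at the breakpoint):
        x(F) = x0 + F/k_low                          for F <= breakpoint
        x(F) = x0 + Fb/k_low + (F - Fb)/k_high       for F >  breakpoint
    """

    k_low: float
    k_high: float
    breakpoint: float = 2.0
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_low <= 0 or self.k_high <= 0 or self.breakpoint <= 0:
            raise DomainError("bilinear spring law requires positive k_low, k_high, breakpoint")

    def extension(self, F) -> np.ndarray:
        F = np.asarray(F, dtype=float)
        low = self.x0 + F / self.k_low
        high = self.x0 + self.breakpoint / self.k_low + (F - self.breakpoint) / self.k_high
        out = np.where(F <= self.breakpoint, low, high)
        return float(out) if out.ndim == 0 else out


# --------------------------------------------------------- force-extension

def gen_force_extension(
    model: ConstructModel,
    forces_pN: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    rips: list[tuple[float, float]] | None = None,
    refold_fraction: float = 0.0,
    loading_rate_pN_s: float = 5.5,
) -> tuple[ForceExtensionTrace, ForceExtensionTrace]:
    """Generate a (stretch, relax) ForceExtensionTrace pair from a model.

    ``rips`` is a list of (rip force pN, extension gain nm): on the stretch
    curve each gain is added only above its rip force (unfolding); on the
    relax curve a fraction ``1 - refold_fraction`` of each gain persists at
    all forces (slow refolding → large hysteresis; ``refold_fraction=1``
    reproduces the stretch curve).  Gaussian extension noise is seeded.
    """
    forces = np.sort(np.asarray(forces_pN, dtype=float))
    if np.any(forces < model.F0):
        raise DomainError("force grid extends below the calibration offset F0")
    rng = np.random.default_rng(seed)
    base = construct_extension(forces, model)

    stretch_off = np.zeros_like(forces)
    relax_off = np.zeros_like(forces)
    for f_rip, dl in rips or []:
        stretch_off += np.where(forces >= f_rip, dl, 0.0)
        relax_off += np.where(forces >= f_rip, dl, dl * (1.0 - refold_fraction))

    x_stretch = base + stretch_off + rng.normal(0.0, noise_sigma, forces.shape)
    x_relax = base + relax_off + rng.normal(0.0, noise_sigma, forces.shape)
    t_stretch = (forces - forces[0]) / loading_rate_pN_s
    t_total = t_stretch[-1]
    t_relax = t_total + (forces[-1] - forces[::-1]) / loading_rate_pN_s
    stretch = ForceExtensionTrace(
        force_pN=forces, extension_nm=x_stretch, direction="stretch", time_s=t_stretch,
    )
    relax = ForceExtensionTrace(
        force_pN=forces[::-1], extension_nm=x_relax[::-1], direction="relax", time_s=t_relax,
    )
    return stretch, relax


# -------------------------------------------------------------- force jumps

def gen_force_jump_trace(
    spring: BilinearSpring,
    schedule: list[tuple[float, float]],
    handles: WLCParams | None = None,
    tau_s: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    dt_s: float = 0.001,
) -> ForceJumpTrace:
    """Force-jump temporal trace: exponential relaxation between equilibria.

    ``schedule`` is a list of (setpoint pN, duration s).  At each setpoint
    change the extension relaxes exponentially (time constant ``tau_s``)
    from its current value to the new equilibrium implied by the bilinear
    spring law plus (optionally) the handle WLC extension.
    """
    if not schedule:
        raise DomainError("schedule must be nonempty")
    if tau_s <= 0:
        raise DomainError("tau must be positive")
    rng = np.random.default_rng(seed)

    def equilibrium(F: float) -> float:
        x = float(spring.extension(F))
        if handles is not None:
            x += float(wlc_extension_at_force(F, handles))
        return x

    t_chunks, f_chunks, x_chunks = [], [], []
    t_now = 0.0
    x_now = equilibrium(schedule[0][0])
    for setpoint, duration in schedule:
        n = max(int(round(duration / dt_s)), 2)
        t = t_now + dt_s * np.arange(n)
        x_eq = equilibrium(setpoint)
        x = x_eq + (x_now - x_eq) * np.exp(-(t - t_now) / tau_s)
        t_chunks.append(t)
        f_chunks.append(np.full(n, setpoint))
        x_chunks.append(x)
        t_now = t[-1] + dt_s
        x_now = float(x[-1])
    time = np.concatenate(t_chunks)
    force = np.concatenate(f_chunks)
    ext = np.concatenate(x_chunks) + rng.normal(0.0, noise_sigma, len(time))
    return ForceJumpTrace(time_s=time, force_pN=force, extension_nm=ext)


# ---------------------------------------------------------------- AFM images

def gen_afm_crossing_image(
    helix_radius_nm: float = 40.0,
    handedness: str = "right",
    bundle_height_nm: float = 6.0,
    bundle_width_nm: float = 6.0,
    pixel_size_nm: float = 1.0,
    tip_broadening_nm: float = 0.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    crossing_angle_deg: float = 90.0,
    rotation_deg: float = 0.0,
    drape_factor: float = 2.5,
) -> tuple[AFMImage, SectionLine, SectionLine]:
    """Render two crossing bundles and the AB/CD section lines.

    Two Gaussian-profile ridges cross at the canvas centre.  Handedness
    decides which ridge passes underneath; the over-passing ridge is
    elevated near the crossing by the under-ridge height over a broadened
    (draped) envelope, so the section profile along the under ridge climbs
    more steeply than the one along the over ridge.  Section lines follow
    the convention that the AB-line bundle lies underneath when the
    structure is right-handed, so the rendered handedness is recoverable
    from the uphill-slope difference.
    """
    from scipy import ndimage

    if handedness not in ("right", "left"):
        raise DomainError("handedness must be 'right' or 'left'")
    if helix_radius_nm <= bundle_width_nm:
        raise DomainError("helix radius must exceed the bundle width")

    side_nm = max(4.0 * helix_radius_nm, 16.0 * bundle_width_nm)
    n_px = int(round(side_nm / pixel_size_nm)) + 1
    coords = np.arange(n_px) * pixel_size_nm
    X, Y = np.meshgrid(coords, coords)
    center = np.array([coords[-1] / 2.0, coords[-1] / 2.0])

    alpha = np.radians(rotation_deg + 45.0)
    beta = np.radians(rotation_deg + 45.0 - crossing_angle_deg)
    dir_ab = np.array([np.cos(alpha), np.sin(alpha)])
    dir_cd = np.array([np.cos(beta), np.sin(beta)])
    if abs(dir_ab[0] * dir_cd[1] - dir_ab[1] * dir_cd[0]) < 0.1:
        raise DomainError("bundles do not cross within the canvas (near-parallel)")

    def ridge_coords(direction):
        dx = X - center[0]
        dy = Y - center[1]
        along = dx * direction[0] + dy * direction[1]
        perp = -dx * direction[1] + dy * direction[0]
        return along, perp

    along_ab, perp_ab = ridge_coords(dir_ab)
    along_cd, perp_cd = ridge_coords(dir_cd)
    w = bundle_width_nm / 2.0
    h = bundle_height_nm

    def profile(perp):
        g = np.exp(-0.5 * (perp / w) ** 2)
        return np.where(np.abs(perp) <= 3.0 * w, g, 0.0)

    # right-handed → the AB ridge is the one lying underneath
    if handedness == "right":
        perp_under, perp_over = perp_ab, perp_cd
        along_over = along_cd
    else:
        perp_under, perp_over = perp_cd, perp_ab
        along_over = along_ab

    under = h * profile(perp_under)
    drape = h * np.exp(-0.5 * (along_over / (drape_factor * w)) ** 2)
    drape = np.where(np.abs(along_over) <= 3.0 * drape_factor * w, drape, 0.0)
    over = (h + drape) * profile(perp_over)
    heights = np.maximum(under, over)

    if tip_broadening_nm > 0:
        heights = ndimage.gaussian_filter(heights, tip_broadening_nm / pixel_size_nm)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, noise_sigma, heights.shape)

    half = min(0.35 * side_nm, 10.0 * drape_factor * w)
    line_ab = SectionLine(
        p0_nm=tuple(center - half * dir_ab), p1_nm=tuple(center + half * dir_ab),
        role="AB", n_samples=200,
    )
    line_cd = SectionLine(
        p0_nm=tuple(center - half * dir_cd), p1_nm=tuple(center + half * dir_cd),
        role="CD", n_samples=200,
    )
    return AFMImage(heights=heights, pixel_size_nm=pixel_size_nm), line_ab, line_cd


# ------------------------------------------------------------- helix points

def gen_helix_points(
    radius_nm: float,
    pitch_nm: float,
    turns: float,
    n_points: int,
    handedness: str = "right",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Ordered points on an ideal helix plus isotropic Gaussian noise."""
    if n_points < 4:
        raise DomainError("need at least 4 points")
    if turns <= 0:
        raise DomainError("turns must be positive")
    if handedness not in ("right", "left"):
        raise DomainError("handedness must be 'right' or 'left'")
    sign = 1.0 if handedness == "right" else -1.0
    t = np.linspace(0.0, 2.0 * np.pi * turns, n_points)
    pts = np.column_stack([
        radius_nm * np.cos(t),
        sign * radius_nm * np.sin(t),
        pitch_nm * t / (2.0 * np.pi),
    ])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    return pts


# -------------------------------------------------------------- trajectories

def gen_trajectory(
    base_positions_nm: np.ndarray,
    fluct_sigma_nm: float,
    n_frames: int,
    frame_spacing_ns: float = 10.0,
    seed: int = 0,
    drift_nm_per_frame: np.ndarray | None = None,
) -> Trajectory:
    """Pseudo-trajectory: base conformation + iid Gaussian displacement.

    Optionally adds a linear drift (3-vector per frame).  Times are
    ``frame_spacing_ns`` apart starting at 0.
    """
    if n_frames < 2:
        raise DomainError("need at least 2 frames")
    base = np.asarray(base_positions_nm, dtype=float)
    if base.ndim != 2 or base.shape[1] != 3:
        raise DomainError("base positions must be (entities, 3)")
    rng = np.random.default_rng(seed)
    frames = base[None, :, :] + rng.normal(0.0, fluct_sigma_nm, (n_frames, *base.shape))
    if drift_nm_per_frame is not None:
        drift = np.asarray(drift_nm_per_frame, dtype=float)
        frames = frames + np.arange(n_frames)[:, None, None] * drift[None, None, :]
    times_ps = np.arange(n_frames) * frame_spacing_ns * 1e3
    return Trajectory(times_ps=times_ps, positions_nm=frames)
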