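"""Two-stage WLC+Hooke fitting of force-extension traces and hysteresis.

Stage 1 holds the dsDNA-handle WLC parameters and the nanospring parameters
at supplied (theory) values and fits only the force-calibration offset F0 on
the sub-2 pN part of the trace.  Stage 2 then refits all five elastic
parameters (Lp, L0, K0, k, x0) freely, with F0 held at the stage-1 value,
by nonlinear least squares on the extension residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DomainError
from .models import ConstructModel, SpringParams, WLCParams, spring_extension, wlc_extension_at_force

__all__ = [
    "ForceExtensionTrace",
    "FitResult",
    "HysteresisResult",
    "calibrate_force_offset",
    "fit_construct",
    "hysteresis_area",
]

#: Stage-1 calibration uses only data below this force (pN).
CALIBRATION_FMAX = 2.0

#: Default stage-2 fit window (pN).
DEFAULT_FIT_RANGE = (0.1, 8.2)


@dataclass
class ForceExtensionTrace:
    """A force-extension record from one pulling or relaxing ramp.

    ``direction`` is ``"stretch"`` (force non-decreasing in record order) or
    ``"relax"``.  Forces must lie in [0, 60] pN and there must be at least
    10 points.
    """

    force_pN: np.ndarray
    extension_nm: np.ndarray
    direction: str = "stretch"
    time_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        if self.force_pN.shape != self.extension_nm.shape or self.force_pN.ndim != 1:
            raise DomainError("force and extension must be 1-D arrays of equal length")
        if len(self.force_pN) < 10:
            raise DomainError("trace needs at least 10 points")
        if self.direction not in ("stretch", "relax"):
            raise DomainError(f"direction must be 'stretch' or 'relax', got {self.direction!r}")
        if np.any(self.force_pN < -1e-9) or np.any(self.force_pN > 60.0):
            raise DomainError("forces must lie within [0, 60] pN")
        if self.direction == "stretch" and np.any(np.diff(self.force_pN) < -1e-9):
            raise DomainError("stretch trace must have non-decreasing force order")
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)

    def __len__(self) -> int:
        return len(self.force_pN)


@dataclass
class FitResult:
    """Outcome of a construct fit: fitted model, errors, and diagnostics."""

    model: ConstructModel
    stderr: dict = field(default_factory=dict)
    residual_rms_nm: float = np.nan
    force_range_pN: tuple = DEFAULT_FIT_RANGE
    converged: bool = False
    n_points: int = 0
    at_bounds: tuple = ()

    def report(self) -> str:
        h, s = self.model.handles, self.model.spring
        lines = [
            "construct fit",
            f"  converged        : {self.converged}",
            f"  n points         : {self.n_points}",
            f"  force range (pN) : {self.force_range_pN[0]:g} .. {self.force_range_pN[1]:g}",
            f"  residual RMS (nm): {self.residual_rms_nm:.3g}",
            f"  Lp (nm) : {h.Lp:.4g} +/- {self.stderr.get('Lp', float('nan')):.2g}",
            f"  L0 (nm) : {h.L0:.6g} +/- {self.stderr.get('L0', float('nan')):.2g}",
            f"  K0 (pN) : {h.K0:.6g} +/- {self.stderr.get('K0', float('nan')):.2g}",
            f"  k (pN/nm): {s.k:.4g} +/- {self.stderr.get('k', float('nan')):.2g}",
            f"  x0 (nm) : {s.x0:.6g} +/- {self.stderr.get('x0', float('nan')):.2g}",
            f"  F0 (pN) : {self.model.F0:.4g}",
        ]
        if self.at_bounds:
            lines.append(f"  at bounds: {', '.join(self.at_bounds)} (non-identifiable)")
        return "\n".join(lines)


@dataclass(frozen=True)
class HysteresisResult:
    """Area (pN·nm) enclosed between stretch and relax curves over a force window."""

    area_pN_nm: float
    force_window_pN: tuple

    def __post_init__(self) -> None:
        lo, hi = self.force_window_pN
        if not lo < hi:
            raise DomainError("force window must satisfy lo < hi")
        if not np.isfinite(self.area_pN_nm):
            raise DomainError("area must be finite")


def _model_extension(F, Lp, L0, K0, k, x0, F0):
    """Construct extension with candidate F0; forces below F0 clip to zero
    effective force so that stage-1 scans over F0 stay defined."""
    Fe = np.maximum(np.asarray(F, dtype=float) - F0, 0.0)
    p = WLCParams(Lp=Lp, L0=L0, K0=K0)
    return wlc_extension_at_force(Fe, p) + x0 + Fe / k


def calibrate_force_offset(
    trace: ForceExtensionTrace,
    theory: ConstructModel,
    f_max: float = CALIBRATION_FMAX,
    bounds: tuple = (-2.0, 2.0),
) -> float:
    """Stage-1 calibration: fit only F0 on the sub-``f_max`` data with all
    elastic parameters held at the supplied theory values."""
    mask = trace.force_pN < f_max
    if not np.any(mask):
        raise DomainError(f"no data below {f_max} pN for force calibration")
    F = trace.force_pN[mask]
    x = trace.extension_nm[mask]
    h, s = theory.handles, theory.spring

    def resid(theta):
        return _model_extension(F, h.Lp, h.L0, h.K0, s.k, s.x0, theta[0]) - x

    res = least_squares(resid, x0=[theory.F0], bounds=([bounds[0]], [bounds[1]]), method="trf")
    if not res.success:
        raise DomainError("force-offset calibration did not converge")
    return float(res.x[0])


def fit_construct(
    trace: ForceExtensionTrace,
    init: ConstructModel,
    force_range: tuple = DEFAULT_FIT_RANGE,
    calibrate: bool = True,
    free_F0: bool = True,
    hold: tuple = ("Lp",),
) -> FitResult:
    """Two-stage fit of the combined WLC+Hooke model to one trace.

    Stage 1 (optional) calibrates F0 from sub-2 pN data with parameters held
    at ``init``; stage 2 frees the elastic parameters — and, by default, F0
    starting from its stage-1 value — inside ``force_range``.

    ``hold`` names parameters pinned at their ``init`` values during stage 2.
    By default the handle persistence length is held: dsDNA Lp is a known
    constant (≈50 nm) and leaving it free inflates the x0 uncertainty by an
    order of magnitude through the Lp–L0–x0 correlation.  Pass ``hold=()``
    for a fully free fit; note that K0 and k are then determined only in the
    combination L0/K0 + 1/k (their linear-in-force terms are exactly
    collinear), so their split is reported at whatever the optimiser leaves.

    Returns a FitResult whose ``converged`` flag reflects optimiser status
    and whose ``at_bounds`` names parameters pinned at a bound
    (non-identifiable directions, e.g. ``k`` for a handles-only trace).
    """
    lo, hi = force_range
    mask = (trace.force_pN >= lo) & (trace.force_pN <= hi)
    if mask.sum() < 6:
        raise DomainError("need at least 6 points inside the force range (5 free parameters)")
    F = trace.force_pN[mask]
    x = trace.extension_nm[mask]

    F0 = calibrate_force_offset(trace, init) if calibrate else init.F0

    h, s = init.handles, init.spring
    all_names = ["Lp", "L0", "K0", "k", "x0", "F0"]
    full0 = np.array([h.Lp, h.L0, h.K0, s.k, s.x0, F0])
    full_lower = np.array([10.0, 0.5 * h.L0, 200.0, 1e-6, 0.0, -2.0])
    full_upper = np.array([100.0, 2.0 * h.L0, 5000.0, 1e3, 10.0 * max(s.x0, 10.0), 2.0])
    unknown = set(hold) - set(all_names[:5])
    if unknown:
        raise DomainError(f"cannot hold unknown parameters: {sorted(unknown)}")
    free = [i for i, nm in enumerate(all_names)
            if nm not in hold and (nm != "F0" or free_F0)]
    names = [all_names[i] for i in free]
    theta0 = np.clip(full0, full_lower, full_upper)[free]
    lower, upper = full_lower[free], full_upper[free]

    def resid(theta):
        full = full0.copy()
        full[free] = theta
        return _model_extension(F, *full) - x

    res = least_squares(
        resid, x0=theta0, bounds=(lower, upper), method="trf",
        x_scale=np.maximum(np.abs(theta0), 1e-3), xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    full = full0.copy()
    full[free] = res.x
    Lp, L0, K0, k, x0, F0 = full
    n, p = len(F), len(free)
    rms = float(np.sqrt(np.mean(res.fun**2)))

    stderr: dict = {}
    try:
        _, sv, VT = np.linalg.svd(res.jac, full_matrices=False)
        keep = sv > max(sv) * 1e-10
        cov = (VT[keep].T / sv[keep] ** 2) @ VT[keep]
        sigma2 = np.sum(res.fun**2) / max(n - p, 1)
        perr = np.sqrt(np.clip(np.diag(cov) * sigma2, 0, np.inf))
        stderr = dict(zip(names, map(float, perr)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    rel_pos = (res.x - lower) / (upper - lower)
    at_bounds = tuple(nm for nm, r in zip(names, rel_pos) if r < 1e-6 or r > 1 - 1e-6)

    model = ConstructModel(
        handles=WLCParams(Lp=Lp, L0=L0, K0=K0, kBT=h.kBT),
        spring=SpringParams(k=k, x0=x0),
        F0=F0,
    )
    return FitResult(
        model=model, stderr=stderr, residual_rms_nm=rms,
        force_range_pN=(lo, hi), converged=bool(res.success), n_points=n,
        at_bounds=at_bounds,
    )


def _resample(trace: ForceExtensionTrace, grid: np.ndarray) -> np.ndarray:
    order = np.argsort(trace.force_pN, kind="stable")
    return np.interp(grid, trace.force_pN[order], trace.extension_nm[order])


def hysteresis_area(
    stretch: ForceExtensionTrace,
    relax: ForceExtensionTrace,
    window: tuple = (10.0, 20.0),
    n_grid: int = 200,
) -> HysteresisResult:
    """Signed area (pN·nm) between stretch and relax extension-vs-force
    curves over ``window``, positive when stretch lies at larger extension.

    Both traces are monotonically resampled onto a uniform ``n_grid``-point
    force grid by linear interpolation and the difference is integrated with
    the trapezoidal rule.  Antisymmetric under argument swap.
    """
    lo, hi = window
    if not lo < hi:
        raise DomainError("window must satisfy lo < hi")
    for tr, name in ((stretch, "stretch"), (relax, "relax")):
        if tr.force_pN.min() > lo + 1e-9 or tr.force_pN.max() < hi - 1e-9:
            raise DomainError(f"{name} trace does not cover the window [{lo}, {hi}] pN")
    grid = np.linspace(lo, hi, n_grid)
    diff = _resample(stretch, grid) - _resample(relax, grid)
    area = float(np.trapezoid(diff, grid))
    return HysteresisResult(area_pN_nm=area, force_window_pN=(lo, hi))
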