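"""Force-jump trace segmentation, per-event kinetics, and spring constants.

A force-jump experiment steps the force setpoint abruptly (recoil: high to
low; uncoil: low to high) and records the extension as it relaxes to the new
equilibrium.  Each setpoint change yields one event with an equilibrium
extension change ΔL, a time-to-equilibrium t_eq, and a mean relaxation rate
ΔL/t_eq.  Spring constants follow from Hooke's law as the regression slope
of final force versus ΔL, separately below and above a breakpoint force
(default 2 pN) separating the entropic and enthalpic coiling regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = [
    "ForceJumpTrace",
    "JumpEvent",
    "SpringConstantResult",
    "detect_jump_events",
    "measure_event",
    "spring_constants_from_events",
]

DEFAULT_MIN_STEP = 0.4   # pN
DEFAULT_SETTLE = 0.010   # s, the jump completion time
DEFAULT_BREAKPOINT = 2.0  # pN


@dataclass
class ForceJumpTrace:
    """Equal-length time (s) / force (pN) / extension (nm) records."""

    time_s: np.ndarray
    force_pN: np.ndarray
    extension_nm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        if not (self.time_s.shape == self.force_pN.shape == self.extension_nm.shape):
            raise DomainError("time, force and extension must have equal shapes")
        if self.time_s.ndim != 1 or len(self.time_s) < 2:
            raise DomainError("trace needs at least 2 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise DomainError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class JumpEvent:
    """One recoiling or uncoiling event between two force setpoints."""

    F_start_pN: float
    F_end_pN: float
    direction: str            # "recoil" (force drop) or "uncoil" (force rise)
    delta_L_nm: float
    t_eq_s: float
    rate_nm_per_s: float
    i_start: int
    i_end: int

    def __post_init__(self) -> None:
        if self.delta_L_nm < 0:
            raise DomainError("delta_L must be >= 0")
        if self.t_eq_s <= 0:
            raise DomainError("t_eq must be > 0")
        expected = "recoil" if self.F_end_pN < self.F_start_pN else "uncoil"
        if self.direction != expected:
            raise DomainError(
                f"direction {self.direction!r} inconsistent with force change "
                f"{self.F_start_pN} -> {self.F_end_pN}"
            )


@dataclass
class SpringConstantResult:
    """Hooke spring constants from the two force regimes around a breakpoint."""

    k_low_pN_nm: float
    k_high_pN_nm: float
    breakpoint_pN: float
    stderr_low: float
    stderr_high: float
    n_low: int
    n_high: int

    def __post_init__(self) -> None:
        if self.k_low_pN_nm <= 0 or self.k_high_pN_nm <= 0:
            raise DomainError("spring constants must be positive")
        if self.breakpoint_pN <= 0:
            raise DomainError("breakpoint must be positive")

    def report(self) -> str:
        return (
            "spring constants (Hooke, F/dL)\n"
            f"  k (< {self.breakpoint_pN:g} pN) : {self.k_low_pN_nm:.4g} +/- "
            f"{self.stderr_low:.2g} pN/nm  (n={self.n_low})\n"
            f"  k (> {self.breakpoint_pN:g} pN) : {self.k_high_pN_nm:.4g} +/- "
            f"{self.stderr_high:.2g} pN/nm  (n={self.n_high})"
        )


def _estimate_noise(x: np.ndarray) -> float:
    """Robust noise scale from first differences (white-noise MAD estimator)."""
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def measure_event(
    time_s: np.ndarray,
    extension_nm: np.ndarray,
    noise_sigma: float | None = None,
    rate_mode: str = "mean",
    x_start: float | None = None,
) -> tuple[float, float, float]:
    """Measure (delta_L, t_eq, rate) on one post-jump segment.

    delta_L is |median extension of the final 10% of the segment minus the
    extension at segment start|; ``x_start`` overrides the (noisy) first
    sample as the start extension — the event detector passes the previous
    segment's equilibrium plateau, which estimates the same quantity without
    single-sample noise or settle-interval relaxation loss.  t_eq is the
    first time from which the extension stays within 2·noise_sigma of the
    final median for the rest of the segment.  ``rate_mode="mean"`` returns
    delta_L/t_eq; ``"initial"`` returns the slope of the first 5% of the
    segment.
    """
    t = np.asarray(time_s, dtype=float)
    x = np.asarray(extension_nm, dtype=float)
    if len(t) < 10:
        raise DomainError("segment too short to estimate a plateau")
    n_tail = max(int(round(0.1 * len(x))), 3)
    plateau = float(np.median(x[-n_tail:]))
    delta_L = abs(plateau - (x[0] if x_start is None else x_start))

    if noise_sigma is None:
        noise_sigma = _estimate_noise(x[-n_tail:])
    band = max(2.0 * noise_sigma, 5e-3 * max(delta_L, 1e-12))
    # apply the band to a lightly smoothed signal so that individual noise
    # excursions do not push the plateau-entry time to the segment end
    n_win = min(max(len(x) // 50, 1), 51)
    if n_win > 1:
        from scipy.ndimage import uniform_filter1d

        smooth = uniform_filter1d(x, n_win, mode="nearest")
    else:
        smooth = x
    inside = np.abs(smooth - plateau) <= band
    # first index from which every later sample is inside the band
    outside_idx = np.nonzero(~inside)[0]
    j = 0 if outside_idx.size == 0 else int(outside_idx[-1]) + 1
    j = min(j, len(t) - 1)
    dt = t[1] - t[0]
    t_eq = max(float(t[j] - t[0]), float(dt))

    if rate_mode == "mean":
        rate = delta_L / t_eq
    elif rate_mode == "initial":
        n_head = max(int(round(0.05 * len(x))), 3)
        slope = np.polyfit(t[:n_head], x[:n_head], 1)[0]
        rate = abs(float(slope))
    else:
        raise DomainError(f"unknown rate_mode {rate_mode!r}")
    return delta_L, t_eq, rate


def detect_jump_events(
    trace: ForceJumpTrace,
    min_step: float = DEFAULT_MIN_STEP,
    settle: float = DEFAULT_SETTLE,
    noise_sigma: float | None = None,
    rate_mode: str = "mean",
) -> list[JumpEvent]:
    """Segment a trace at force-setpoint changes of magnitude >= ``min_step``.

    Each event's measurement segment starts after the ``settle`` interval
    following the jump.  Returns an empty list for a constant-force trace.
    """
    if len(trace) == 0:
        return []
    F = trace.force_pN
    steps = np.nonzero(np.abs(np.diff(F)) >= min_step)[0] + 1
    if steps.size == 0:
        return []
    # merge change indices closer together than the settle interval (one jump)
    change_points = [int(steps[0])]
    for s in steps[1:]:
        if trace.time_s[s] - trace.time_s[change_points[-1]] > settle:
            change_points.append(int(s))

    events: list[JumpEvent] = []
    boundaries = [0] + change_points + [len(trace)]
    for prev, cp, nxt in zip(boundaries[:-2], change_points, boundaries[2:]):
        F_start = float(np.median(F[max(cp - 5, 0):cp]))
        F_end = float(np.median(F[cp:nxt]))
        direction = "recoil" if F_end < F_start else "uncoil"
        i0 = int(np.searchsorted(trace.time_s, trace.time_s[cp] + settle))
        i0 = min(max(i0, cp), nxt - 1)
        seg_t = trace.time_s[i0:nxt]
        seg_x = trace.extension_nm[i0:nxt]
        if len(seg_t) < 10:
            raise DomainError(
                f"segment at t={trace.time_s[cp]:.4g}s shorter than the settle interval"
            )
        # start extension = previous segment's plateau (median of its tail)
        n_prev = cp - prev
        n_tail = max(int(round(0.1 * n_prev)), 1)
        x_start = float(np.median(trace.extension_nm[cp - n_tail:cp]))
        delta_L, t_eq, rate = measure_event(seg_t, seg_x, noise_sigma, rate_mode, x_start=x_start)
        events.append(JumpEvent(
            F_start_pN=F_start, F_end_pN=F_end, direction=direction,
            delta_L_nm=delta_L, t_eq_s=t_eq, rate_nm_per_s=rate,
            i_start=i0, i_end=nxt,
        ))
    return events


def _ols_slope(xvals: np.ndarray, yvals: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope of y on x with its standard error."""
    x = np.asarray(xvals, dtype=float)
    y = np.asarray(yvals, dtype=float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise DomainError("degenerate regression: zero variance in delta_L")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    if n > 2:
        resid = y - (ym + slope * (x - xm))
        se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    else:
        se = float("nan")
    return slope, se


def spring_constants_from_events(
    events: list[JumpEvent],
    breakpoint: float = DEFAULT_BREAKPOINT,
) -> SpringConstantResult:
    """Spring constants from Hooke's law (F/ΔL) in two force regimes.

    Ordinary least squares of final force on ΔL, restricted to events whose
    final force lies at/below (``k_low``) or above (``k_high``) the
    breakpoint; the magnitude of each slope is the spring constant.
    """
    low = [e for e in events if e.F_end_pN <= breakpoint]
    high = [e for e in events if e.F_end_pN > breakpoint]
    if len(low) < 2:
        raise DomainError(f"need >= 2 events at or below the {breakpoint} pN breakpoint, got {len(low)}")
    if len(high) < 2:
        raise DomainError(f"need >= 2 events above the {breakpoint} pN breakpoint, got {len(high)}")
    s_lo, se_lo = _ols_slope([e.delta_L_nm for e in low], [e.F_end_pN for e in low])
    s_hi, se_hi = _ols_slope([e.delta_L_nm for e in high], [e.F_end_pN for e in high])
    return SpringConstantResult(
        k_low_pN_nm=abs(s_lo), k_high_pN_nm=abs(s_hi), breakpoint_pN=breakpoint,
        stderr_low=se_lo, stderr_high=se_hi, n_low=len(low), n_high=len(high),
    )
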