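"""Closed-form and numerically inverted mechanical models.

Units throughout the package: forces in pN, lengths in nm, energies in
pN·nm.  The extensible worm-like chain (WLC) is used for the double-stranded
DNA handles, a Hooke spring for the nanospring itself, and the two are
combined additively into the extension of the full tethered construct:

    x(F) = x_WLC(F - F0) + (F - F0)/k + x0

where ``F0`` is a small force-calibration offset removing instrumental bias
near zero force.

The extensible WLC interpolation used here is

    F = (kBT/Lp) * [ 1/(4 (1 - x/L0 + F/K0)^2) - 1/4 + x/L0 - F/K0 ]

which is implicit in ``F``; both directions (force at extension, extension
at force) are solved numerically to high accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError

#: Thermal energy at 298.15 K in pN·nm.
KBT_ROOM = 4.114

__all__ = [
    "KBT_ROOM",
    "WLCParams",
    "SpringParams",
    "ConstructModel",
    "JunctionGeometry",
    "wlc_force_at_extension",
    "wlc_extension_at_force",
    "spring_extension",
    "construct_extension",
    "duplex_push_force",
    "gq_bend_force",
    "linker_end_to_end",
]


@dataclass(frozen=True)
class WLCParams:
    """Extensible worm-like-chain parameters for a dsDNA segment.

    Parameters
    ----------
    Lp : float
        Persistence length (nm).
    L0 : float
        Contour length (nm).
    K0 : float
        Stretch (elastic) modulus (pN).
    kBT : float
        Thermal energy (pN·nm); defaults to 298.15 K.
    """

    Lp: float
    L0: float
    K0: float
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        for name in ("Lp", "L0", "K0", "kBT"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"WLCParams.{name} must be positive and finite, got {v!r}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SpringParams:
    """Hookean nanospring: spring constant ``k`` (pN/nm) and zero-force length ``x0`` (nm)."""

    k: float
    x0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and self.k > 0):
            raise DomainError(f"SpringParams.k must be positive, got {self.k!r}")
        if not (np.isfinite(self.x0) and self.x0 >= 0):
            raise DomainError(f"SpringParams.x0 must be >= 0, got {self.x0!r}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ConstructModel:
    """Full tethered construct: WLC handles in series with a Hooke nanospring.

    ``F0`` is the force-calibration offset (pN) subtracted from the measured
    force before evaluating both elastic terms.
    """

    handles: WLCParams
    spring: SpringParams
    F0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.F0):
            raise DomainError(f"ConstructModel.F0 must be finite, got {self.F0!r}")

    def as_dict(self) -> dict:
        d = {f"handles.{k}": v for k, v in self.handles.as_dict().items()}
        d.update({f"spring.{k}": v for k, v in self.spring.as_dict().items()})
        d["F0"] = self.F0
        return d


@dataclass(frozen=True)
class JunctionGeometry:
    """Geometry and mechanics of one inter-module junction.

    Defaults: 0.68 nm between neighbouring ssDNA bases, a 2–3 nm
    G-quadruplex end-to-end span, 20 pN mechanical stability per GQ, and two
    GQs / two bridge duplexes per junction.
    """

    nt_spacing: float = 0.68
    gq_span_lo: float = 2.0
    gq_span_hi: float = 3.0
    gq_rupture_force: float = 20.0
    n_gq_per_junction: int = 2
    n_duplex_per_junction: int = 2

    def __post_init__(self) -> None:
        for name in ("nt_spacing", "gq_span_lo", "gq_span_hi"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"JunctionGeometry.{name} must be positive, got {v!r}")
        if self.gq_rupture_force < 0:
            raise DomainError("gq_rupture_force must be >= 0")
        if self.gq_span_lo > self.gq_span_hi:
            raise DomainError("gq_span_lo must not exceed gq_span_hi")
        if self.n_gq_per_junction < 0 or self.n_duplex_per_junction < 0:
            raise DomainError("junction counts must be >= 0")


def _wlc_rhs(F: float, x: float, p: WLCParams) -> float:
    """Right-hand side of the extensible WLC relation, as a function of F."""
    u = 1.0 - x / p.L0 + F / p.K0
    return (p.kBT / p.Lp) * (0.25 / (u * u) - 0.25 + x / p.L0 - F / p.K0)


def wlc_force_at_extension(x: float, p: WLCParams, rtol: float = 1e-9) -> float:
    """Force (pN) of an extensible WLC held at extension ``x`` (nm).

    The relation is implicit in ``F``; the unique non-negative root is
    bracketed and solved with Brent's method.  Extensions at or beyond the
    contour length are admissible because of the enthalpic F/K0 term.
    """
    if not np.isfinite(x) or x < 0:
        raise DomainError(f"extension must be >= 0, got {x!r}")
    if x == 0.0:
        return 0.0

    # The physical branch requires 1 - x/L0 + F/K0 > 0.
    lo = max(0.0, p.K0 * (x / p.L0 - 1.0)) + 1e-12
    h = lambda F: F - _wlc_rhs(F, x, p)
    if h(lo) > 0.0:  # pragma: no cover - lo is always below the root
        raise DomainError(f"no admissible WLC force bracket at x={x}")
    hi = max(1.0, 2.0 * lo)
    for _ in range(200):
        if h(hi) > 0.0:
            break
        hi *= 2.0
    else:
        raise DomainError(f"WLC force bracket did not close at x={x} (extension out of range)")
    return brentq(h, lo, hi, rtol=rtol, xtol=1e-15)


def wlc_extension_at_force(F, p: WLCParams):
    """Extension (nm) of an extensible WLC at force ``F`` (pN); vectorised.

    Substituting u = 1 - x/L0 + F/K0 turns the implicit relation into the
    cubic 4u^3 + 4(c - 3/4)u^2 - 1 = 0 with c = F·Lp/kBT, whose unique
    root in (0, 1] is found by vectorised bisection; then
    x = L0 (1 + F/K0 - u).
    """
    F = np.asarray(F, dtype=float)
    if np.any(~np.isfinite(F)) or np.any(F < 0):
        raise DomainError("force must be finite and >= 0")
    scalar = F.ndim == 0
    Fv = np.atleast_1d(F)

    c = Fv * p.Lp / p.kBT
    a2 = 4.0 * (c - 0.75)

    def poly(u):
        return 4.0 * u**3 + a2 * u * u - 1.0

    lo = np.full_like(Fv, 1e-12)
    hi = np.ones_like(Fv)
    # poly(1) = 4c >= 0; equality only at F=0 where the root is exactly u=1.
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        neg = poly(mid) < 0.0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    u = 0.5 * (lo + hi)
    x = p.L0 * (1.0 + Fv / p.K0 - u)
    x = np.where(Fv == 0.0, 0.0, x)
    return float(x[0]) if scalar else x


def spring_extension(F, s: SpringParams):
    """Hookean nanospring extension x_s(F) = x0 + F/k (nm); vectorised."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise DomainError("force must be >= 0")
    out = s.x0 + F / s.k
    return float(out) if out.ndim == 0 else out


def construct_extension(F, m: ConstructModel):
    """Extension (nm) of the full construct at measured force ``F`` (pN).

    Sum of the handle WLC extension and the nanospring Hooke extension,
    both evaluated at the calibrated force F - F0.  Raises for F < F0.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < m.F0 - 1e-12):
        raise DomainError(f"force below calibration offset F0={m.F0}")
    Fe = np.maximum(F - m.F0, 0.0)
    out = wlc_extension_at_force(Fe, m.handles) + spring_extension(Fe, m.spring)
    return float(out) if np.ndim(out) == 0 else out


def duplex_push_force(p: WLCParams, n_strands: int = 1) -> float:
    """Force (pN) exerted by ``n_strands`` bridge duplexes held at contour length.

    Each duplex is assumed stretched to end-to-end distance equal to its
    contour length; the tension follows from the extensible WLC.
    """
    if n_strands < 0:
        raise DomainError("n_strands must be >= 0")
    if n_strands == 0:
        return 0.0
    return n_strands * wlc_force_at_extension(p.L0, p)


def gq_bend_force(g: JunctionGeometry = JunctionGeometry()) -> float:
    """Total bending force (pN) per junction on the G-quadruplex side."""
    return g.n_gq_per_junction * g.gq_rupture_force


def linker_end_to_end(n_nt: int, g: JunctionGeometry = JunctionGeometry()) -> tuple[float, bool]:
    """End-to-end length (nm) of an ``n_nt`` ssDNA linker, and whether it
    falls within the G-quadruplex span range [gq_span_lo, gq_span_hi]."""
    if n_nt < 0:
        raise DomainError("n_nt must be >= 0")
    length = n_nt * g.nt_spacing
    within = g.gq_span_lo <= length <= g.gq_span_hi
    return length, within
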