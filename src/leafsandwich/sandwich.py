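"""Closed-form sandwich-plate model of a leaf lamina.

A flat lamina is idealised as a symmetric three-layer sandwich: two stiff
epidermis faces (cuticle + epidermal tissue, Young's modulus ``E_f``)
enclosing a compliant mesophyll core (``E_c``).  With ``alpha`` the core
thickness as a fraction of total lamina thickness, linear-elastic
superposition gives the whole-lamina moduli measured in tension and in
three-point bending::

    E_T = (1 - alpha)   * E_f + alpha   * E_c        (tension: area-weighted)
    E_B = (1 - alpha^3) * E_f + alpha^3 * E_c        (bending: I-weighted)

Because bending weights the faces by ``1 - alpha^3`` rather than
``1 - alpha``, the ratio ``E_B/E_T`` exceeds 1 for any genuine sandwich
(``beta = E_c/E_f < 1``) and is bounded above by ``1 + alpha + alpha^2``,
which approaches 3 as ``alpha -> 1``.  The pair (E_T, E_B) can therefore be
inverted analytically for the two layer moduli given ``alpha`` — the central
trick of this package: layer stiffnesses are obtained from two whole-lamina
tests plus one anatomical ratio, without peeling the epidermis.

Units are fixed as N, mm, MPa (1 MPa = 1 N/mm^2) throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "SandwichGeometry",
    "CompositeModuli",
    "LayerModuli",
    "RatioDiagnostic",
    "SecondMomentPartition",
    "composite_tensile_modulus",
    "composite_bending_modulus",
    "modulus_ratio",
    "ratio_upper_bound",
    "invert_layer_moduli",
    "optimal_alpha",
    "partition_second_moment",
    "classify_sandwich",
]


class NonPhysicalModulusWarning(UserWarning):
    """Inversion produced a layer modulus outside the physical range."""


@dataclass(frozen=True)
class SandwichGeometry:
    """Cross-section geometry of a sandwich strip.

    alpha : mesophyll (core) thickness fraction, dimensionless, in (0, 1)
    thickness_d : total lamina thickness, mm
    width_w : strip width, mm
    """

    alpha: float
    thickness_d: float
    width_w: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.thickness_d <= 0 or self.width_w <= 0:
            raise ValueError("thickness_d and width_w must be positive")


@dataclass(frozen=True)
class CompositeModuli:
    """Whole-lamina Young's moduli (MPa) from tension (E_T) and bending (E_B)."""

    E_T: float
    E_B: float

    def __post_init__(self) -> None:
        if self.E_T <= 0 or self.E_B <= 0:
            raise ValueError("composite moduli must be positive")

    @property
    def ratio(self) -> float:
        return self.E_B / self.E_T


@dataclass(frozen=True)
class LayerModuli:
    """Epidermis-face (E_f) and mesophyll-core (E_c) Young's moduli, MPa.

    ``physical`` is False when the inversion returns E_c < 0 or E_f <= 0,
    which happens whenever the measured E_B/E_T exceeds the sandwich bound
    1 + alpha + alpha^2 — a known artefact of real data, reported as-is and
    never clamped.
    """

    E_f: float
    E_c: float

    @property
    def physical(self) -> bool:
        return self.E_f > 0 and self.E_c >= 0

    @property
    def beta(self) -> float:
        """Core-to-face stiffness ratio E_c/E_f."""
        return self.E_c / self.E_f


@dataclass(frozen=True)
class RatioDiagnostic:
    """E_B/E_T diagnostic against the sandwich bound for a given alpha."""

    ratio: float
    upper_bound: float
    beta: float
    exceeds_bound: bool


@dataclass(frozen=True)
class SecondMomentPartition:
    """Partition of a strip's second moment of area between core and faces.

    For a core of fractional thickness ``alpha`` centred on the neutral
    axis, I_core = alpha^3 * I_total and the faces carry the remainder.
    """

    I_total: float
    I_face: float
    I_core: float


def _check_alpha(alpha: float, *, open_interval: bool = False) -> None:
    lo_ok = alpha > 0 if open_interval else alpha >= 0
    hi_ok = alpha < 1 if open_interval else alpha <= 1
    if not (lo_ok and hi_ok and math.isfinite(alpha)):
        kind = "(0, 1)" if open_interval else "[0, 1]"
        raise ValueError(f"alpha must be in {kind}, got {alpha}")


def composite_tensile_modulus(E_f: float, E_c: float, alpha: float) -> float:
    """Whole-lamina tensile modulus of a sandwich, MPa.

    Area-weighted mixture: ``(1 - alpha) * E_f + alpha * E_c``.
    """
    _check_alpha(alpha)
    if not (math.isfinite(E_f) and math.isfinite(E_c)):
        raise ValueError("layer moduli must be finite")
    return (1.0 - alpha) * E_f + alpha * E_c


def composite_bending_modulus(E_f: float, E_c: float, alpha: float) -> float:
    """Whole-lamina bending modulus of a sandwich, MPa.

    Second-moment-weighted mixture: ``(1 - alpha^3) * E_f + alpha^3 * E_c``.
    """
    _check_alpha(alpha)
    if not (math.isfinite(E_f) and math.isfinite(E_c)):
        raise ValueError("layer moduli must be finite")
    a3 = alpha**3
    return (1.0 - a3) * E_f + a3 * E_c


def modulus_ratio(alpha: float, beta: float) -> float:
    """Theoretical E_B/E_T of a sandwich with core fraction ``alpha`` and
    core-to-face stiffness ratio ``beta = E_c/E_f``.

    Equals ``(1 - alpha^3 (1 - beta)) / (1 - alpha (1 - beta))``; 1 for a
    homogeneous material (beta = 1) and at most ``1 + alpha + alpha^2``.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if beta < 1:
        _check_alpha(alpha)
        if alpha == 1.0 and beta == 0.0:
            raise ValueError("ratio is singular at alpha=1, beta=0 (limit is 3)")
    denom = 1.0 - alpha * (1.0 - beta)
    if denom <= 0:
        raise ValueError(f"degenerate sandwich: denominator {denom} <= 0")
    return (1.0 - alpha**3 * (1.0 - beta)) / denom


def ratio_upper_bound(alpha: float) -> float:
    """Upper bound of E_B/E_T at core fraction ``alpha``: 1 + alpha + alpha^2.

    This is the beta -> 0 limit of :func:`modulus_ratio`; it reaches 3 at
    alpha = 1, the ceiling for an ideal sandwich with vanishingly thin faces.
    """
    _check_alpha(alpha)
    return 1.0 + alpha + alpha**2


def invert_layer_moduli(E_T: float, E_B: float, alpha: float) -> LayerModuli:
    """Solve the two mixture equations for the layer moduli.

    E_f = (E_B - alpha^2 E_T) / (1 - alpha^2)
    E_c = ((1 + alpha + alpha^2) E_T - E_B) / (alpha (1 + alpha))

    Round-trips exactly with the forward mixtures.  E_c comes out negative
    precisely when E_B/E_T exceeds the sandwich bound; such results keep
    their sign (``physical`` is False) and trigger a warning.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(
            f"alpha must be strictly inside (0, 1) for inversion, got {alpha}"
        )
    if E_T <= 0 or E_B <= 0:
        raise ValueError("measured moduli must be positive")
    a2 = alpha * alpha
    E_f = (E_B - a2 * E_T) / (1.0 - a2)
    E_c = ((1.0 + alpha + a2) * E_T - E_B) / (alpha * (1.0 + alpha))
    result = LayerModuli(E_f=E_f, E_c=E_c)
    if not result.physical:
        warnings.warn(
            f"non-physical inversion result (E_f={E_f:.4g}, E_c={E_c:.4g} MPa): "
            f"E_B/E_T={E_B / E_T:.3f} vs bound {ratio_upper_bound(alpha):.3f}",
            NonPhysicalModulusWarning,
            stacklevel=2,
        )
    return result


def optimal_alpha(beta: float) -> float:
    """Core fraction maximising E_B/E_T at fixed ``beta``, for ``beta`` in [0, 1).

    The stationarity condition of :func:`modulus_ratio` in alpha reduces to
    the cubic ``2 (1 - beta) alpha^3 - 3 alpha^2 + 1 = 0``, which has exactly
    one root in (0, 1] for beta in [0, 1); at beta = 0 the root is the
    boundary supremum alpha = 1.  Solved by bracketed root finding to 1e-12.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError(
            f"beta must be in [0, 1) — at beta >= 1 the ratio is constant or "
            f"decreasing in alpha and has no interior optimum (got {beta})"
        )
    if beta == 0.0:
        return 1.0
    gamma = 1.0 - beta

    def dnum(a: float) -> float:
        # numerator of d(ratio)/d(alpha); positive left of the optimum
        return 2.0 * gamma * a**3 - 3.0 * a**2 + 1.0

    # dnum(0) = 1 > 0, dnum(1) = 2(gamma - 1) < 0 for beta > 0
    return float(brentq(dnum, 1e-12, 1.0, xtol=1e-12, rtol=8.9e-16))


def partition_second_moment(I_total: float, alpha: float) -> SecondMomentPartition:
    """Split a strip's second moment of area into core and face shares."""
    if I_total <= 0:
        raise ValueError("I_total must be positive")
    _check_alpha(alpha)
    I_core = alpha**3 * I_total
    return SecondMomentPartition(
        I_total=I_total, I_face=I_total - I_core, I_core=I_core
    )


def classify_sandwich(E_T: float, E_B: float, alpha: float) -> RatioDiagnostic:
    """Diagnose measured moduli against the sandwich bound.

    Computes the measured ratio, the bound 1 + alpha + alpha^2, and the
    implied beta; ``exceeds_bound`` is equivalent to the inversion giving a
    negative core modulus.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonPhysicalModulusWarning)
        layers = invert_layer_moduli(E_T, E_B, alpha)
    ratio = E_B / E_T
    bound = ratio_upper_bound(alpha)
    return RatioDiagnostic(
        ratio=ratio,
        upper_bound=bound,
        beta=layers.beta,
        exceeds_bound=ratio > bound,
    )
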