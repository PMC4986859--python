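"""Force–displacement curve analysis for tensile and three-point bending tests.

A universal testing machine records force F (N) against crosshead
displacement delta (mm) at constant speed.  In the linear-elastic regime

    tension:  F = E_T * A * delta / l0          =>  E_T = k * l0 / A
    bending:  F = 48 * E_B * I * delta / L^3    =>  E_B = k * L^3 / (48 I)

where k is the initial slope of the curve, A = w*d the strip cross-section,
I = w*d^3/12 its second moment of area, l0 the free length and L the span.
The "initial slope" is estimated from the part of the curve below half the
peak force after trimming the toe region (clamp/contact slack), by picking
the contiguous window with the best linear fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .sandwich import (
    CompositeModuli,
    LayerModuli,
    RatioDiagnostic,
    classify_sandwich,
    invert_layer_moduli,
)

__all__ = [
    "ForceDisplacementCurve",
    "TensileSpecimen",
    "BendingSpecimen",
    "TestResult",
    "SlopePolicy",
    "Side",
    "rectangular_second_moment",
    "initial_slope",
    "tensile_modulus",
    "bending_modulus",
    "combine_sides",
    "leaf_pipeline",
]

#: slender-beam floor: warn when span/thickness drops below this
DEFAULT_SHEAR_THRESHOLD = 20.0


class Side(str, Enum):
    ADAXIAL = "adaxial"
    ABAXIAL = "abaxial"


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """Ordered (displacement mm, force N) samples from one mechanical test."""

    displacement: np.ndarray
    force: np.ndarray
    sampling_note: Optional[str] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D")
        if len(d) < 10:
            raise ValueError(f"need >= 10 samples for slope estimation, got {len(d)}")
        if np.any(np.diff(d) < 0):
            raise ValueError("displacement must be non-decreasing")
        if d[0] < 0:
            raise ValueError("first displacement must be >= 0")

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass(frozen=True)
class TensileSpecimen:
    """Tensile strip geometry (mm)."""

    width_w: float
    thickness_d: float
    free_length_l0: float

    def __post_init__(self) -> None:
        if min(self.width_w, self.thickness_d, self.free_length_l0) <= 0:
            raise ValueError("all tensile specimen dimensions must be positive")

    @property
    def area(self) -> float:
        """Cross-section area, mm^2."""
        return self.width_w * self.thickness_d


@dataclass(frozen=True)
class BendingSpecimen:
    """Three-point bending strip geometry (mm) and tested side."""

    width_w: float
    thickness_d: float
    span_L: float
    side: Side

    def __post_init__(self) -> None:
        if min(self.width_w, self.thickness_d, self.span_L) <= 0:
            raise ValueError("all bending specimen dimensions must be positive")
        object.__setattr__(self, "side", Side(self.side))

    @property
    def span_thickness_ratio(self) -> float:
        return self.span_L / self.thickness_d


@dataclass
class TestResult:
    """Outcome of one curve analysis."""

    modulus: float  # MPa
    slope: float  # N/mm
    fit_window: tuple[int, int]  # [start, stop) indices into the curve
    r_squared: float
    strength: Optional[float] = None  # MPa, tensile only
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SlopePolicy:
    """How the initial slope is extracted from a curve.

    method:
        "best_window"    — best-r^2 contiguous window of >= ``min_window_frac``
                           of the eligible samples (default);
        "first_fraction" — least squares over the first ``window_frac`` of the
                           eligible samples;
        "max_secant"     — steepest secant from the trimmed origin.
    toe_frac : forces below this fraction of peak force are toe region and
        trimmed from the front of the curve.
    force_cap_frac : only samples with force below this fraction of peak are
        eligible (stay clear of pre-failure softening).
    min_points : absolute floor on window size.
    auto_zero : subtract the displacement at which force first crosses the
        toe threshold (affects reported windows only, never the slope).
    """

    method: str = "best_window"
    toe_frac: float = 0.02
    force_cap_frac: float = 0.5
    min_window_frac: float = 0.15
    window_frac: float = 0.25
    min_points: int = 10
    auto_zero: bool = False
    max_grid: int = 40  # candidate window starts/stops per axis

    def __post_init__(self) -> None:
        if self.method not in ("best_window", "first_fraction", "max_secant"):
            raise ValueError(f"unknown slope method {self.method!r}")
        if not 0 <= self.toe_frac < 1 or not 0 < self.force_cap_frac <= 1:
            raise ValueError("toe_frac in [0,1) and force_cap_frac in (0,1] required")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")


DEFAULT_POLICY = SlopePolicy()


def rectangular_second_moment(width_w: float, thickness_d: float) -> float:
    """Second moment of area of a rectangular cross-section: w d^3 / 12, mm^4."""
    if width_w <= 0 or thickness_d <= 0:
        raise ValueError("width and thickness must be positive")
    return width_w * thickness_d**3 / 12.0


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and r^2; exact on collinear input."""
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    if sxx == 0.0:
        raise ValueError("zero displacement range in fit window")
    sxy = float(xm @ ym)
    syy = float(ym @ ym)
    slope = sxy / sxx
    r2 = 1.0 if syy == 0.0 else min(1.0, sxy * sxy / (sxx * syy))
    return slope, r2


def _windowed_fit(
    d: np.ndarray, f: np.ndarray, min_len: int, max_grid: int
) -> tuple[float, tuple[int, int], float]:
    """Best-r^2 contiguous window via prefix sums on a decimated index grid."""
    n = len(d)
    s1 = np.concatenate(([0.0], np.cumsum(np.ones(n))))
    sx = np.concatenate(([0.0], np.cumsum(d)))
    sy = np.concatenate(([0.0], np.cumsum(f)))
    sxx = np.concatenate(([0.0], np.cumsum(d * d)))
    sxy = np.concatenate(([0.0], np.cumsum(d * f)))
    syy = np.concatenate(([0.0], np.cumsum(f * f)))

    starts = np.unique(np.linspace(0, n - min_len, num=min(max_grid, n), dtype=int))
    stops = np.unique(np.linspace(min_len, n, num=min(max_grid, n), dtype=int))
    i, j = np.meshgrid(starts, stops, indexing="ij")
    valid = (j - i) >= min_len
    i, j = i[valid], j[valid]

    cn = s1[j] - s1[i]
    cxx = (sxx[j] - sxx[i]) - (sx[j] - sx[i]) ** 2 / cn
    cxy = (sxy[j] - sxy[i]) - (sx[j] - sx[i]) * (sy[j] - sy[i]) / cn
    cyy = (syy[j] - syy[i]) - (sy[j] - sy[i]) ** 2 / cn

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(cyy > 0, cxy**2 / (cxx * cyy), 1.0)
    r2 = np.where(cxx > 0, r2, -np.inf)  # flat displacement: unusable
    r2 = np.clip(r2, -np.inf, 1.0)
    # prefer larger windows among numerically tied r^2 (within 1e-12)
    best_r2 = r2.max()
    if not np.isfinite(best_r2):
        raise ValueError("no usable fit window (displacement constant?)")
    tied = r2 >= best_r2 - 1e-12
    k = np.flatnonzero(tied)[np.argmax(cn[tied])]
    win = (int(i[k]), int(j[k]))
    slope, r2_exact = _ols_slope(d[win[0] : win[1]], f[win[0] : win[1]])
    return slope, win, r2_exact


def initial_slope(
    curve: ForceDisplacementCurve, policy: SlopePolicy = DEFAULT_POLICY
) -> tuple[float, tuple[int, int], float]:
    """Initial stiffness of a force–displacement curve.

    Returns ``(slope N/mm, fit_window, r_squared)``.  The window indices
    refer to the original curve.  Exactly linear curves return the analytic
    slope with r^2 = 1 under every policy.
    """
    d = curve.displacement
    f = curve.force
    peak = float(f.max())
    if peak <= 0:
        raise ValueError("curve has no positive force")

    toe_end = int(np.argmax(f > policy.toe_frac * peak))
    eligible = np.flatnonzero(f <= policy.force_cap_frac * peak)
    eligible = eligible[eligible >= toe_end]
    if len(eligible) == 0:  # degenerate: keep everything past the toe
        eligible = np.arange(toe_end, len(f))
    stop = int(eligible.max()) + 1
    dd, ff = d[toe_end:stop], f[toe_end:stop]
    if policy.auto_zero:
        dd = dd - dd[0]

    n = len(dd)
    min_len = max(policy.min_points, int(math.ceil(policy.min_window_frac * n)))
    if n < policy.min_points:
        raise ValueError(
            f"only {n} samples in the eligible region, need >= {policy.min_points}"
        )
    min_len = min(min_len, n)

    if policy.method == "best_window":
        slope, (a, b), r2 = _windowed_fit(dd, ff, min_len, policy.max_grid)
        return slope, (toe_end + a, toe_end + b), r2
    if policy.method == "first_fraction":
        k = max(min_len, int(math.ceil(policy.window_frac * n)))
        slope, r2 = _ols_slope(dd[:k], ff[:k])
        return slope, (toe_end, toe_end + k), r2
    # max_secant
    with np.errstate(divide="ignore", invalid="ignore"):
        sec = (ff[1:] - ff[0]) / (dd[1:] - dd[0])
    sec = np.where(np.isfinite(sec), sec, -np.inf)
    k = int(np.argmax(sec)) + 1
    return float(sec[k - 1]), (toe_end, toe_end + k + 1), 1.0


def tensile_modulus(
    curve: ForceDisplacementCurve,
    specimen: TensileSpecimen,
    policy: SlopePolicy = DEFAULT_POLICY,
) -> TestResult:
    """Young's modulus from a tensile test: E_T = k l0 / A, plus strength."""
    slope, window, r2 = initial_slope(curve, policy)
    E_T = slope * specimen.free_length_l0 / specimen.area
    strength = float(curve.force.max()) / specimen.area
    warn: list[str] = []
    if slope <= 0:
        warn.append(f"non-positive fitted slope {slope:.4g} N/mm")
    return TestResult(
        modulus=E_T,
        slope=slope,
        fit_window=window,
        r_squared=r2,
        strength=strength,
        warnings=warn,
    )


def bending_modulus(
    curve: ForceDisplacementCurve,
    specimen: BendingSpecimen,
    policy: SlopePolicy = DEFAULT_POLICY,
    shear_threshold: float = DEFAULT_SHEAR_THRESHOLD,
) -> TestResult:
    """Young's modulus from a three-point bending test: E_B = k L^3 / (48 I).

    A warning is recorded when span/thickness falls below ``shear_threshold``
    (shear deformation no longer negligible; the modulus is then biased low).
    """
    slope, window, r2 = initial_slope(curve, policy)
    I = rectangular_second_moment(specimen.width_w, specimen.thickness_d)
    E_B = slope * specimen.span_L**3 / (48.0 * I)
    warn: list[str] = []
    ratio = specimen.span_thickness_ratio
    if ratio < shear_threshold:
        warn.append(
            f"span:thickness {ratio:.1f} < {shear_threshold:g}; "
            "shear deformation may bias E_B low"
        )
    if slope <= 0:
        warn.append(f"non-positive fitted slope {slope:.4g} N/mm")
    return TestResult(
        modulus=E_B, slope=slope, fit_window=window, r_squared=r2, warnings=warn
    )


def combine_sides(
    E_B_adaxial: Optional[float], E_B_abaxial: Optional[float]
) -> tuple[float, list[str]]:
    """Average adaxial and abaxial bending moduli for one leaf.

    Missing one side degrades to the available value with a warning instead
    of failing the leaf.
    """
    warn: list[str] = []
    if E_B_adaxial is None and E_B_abaxial is None:
        raise ValueError("both bending sides missing")
    if E_B_adaxial is None:
        warn.append("adaxial bending test missing; using abaxial only")
        return float(E_B_abaxial), warn
    if E_B_abaxial is None:
        warn.append("abaxial bending test missing; using adaxial only")
        return float(E_B_adaxial), warn
    if E_B_adaxial <= 0 or E_B_abaxial <= 0:
        raise ValueError("bending moduli must be positive")
    return 0.5 * (E_B_adaxial + E_B_abaxial), warn


def leaf_pipeline(
    tensile_curve: ForceDisplacementCurve,
    bending_curves: Sequence[Optional[ForceDisplacementCurve]],
    tensile_specimen: TensileSpecimen,
    bending_specimens: Sequence[Optional[BendingSpecimen]],
    alpha: float,
    policy: SlopePolicy = DEFAULT_POLICY,
) -> tuple[CompositeModuli, LayerModuli, RatioDiagnostic]:
    """Full per-leaf analysis: curves -> (E_T, E_B) -> (E_f, E_c) -> diagnostic.

    ``bending_curves``/``bending_specimens`` hold the adaxial and abaxial
    tests in any order (``None`` for a missing side).  Identical to running
    the individual steps by hand.
    """
    try:
        tens = tensile_modulus(tensile_curve, tensile_specimen, policy)
    except ValueError as exc:
        raise ValueError(f"tensile step failed: {exc}") from exc

    by_side: dict[Side, float] = {}
    for crv, spec in zip(bending_curves, bending_specimens):
        if crv is None or spec is None:
            continue
        try:
            res = bending_modulus(crv, spec, policy)
        except ValueError as exc:
            raise ValueError(f"bending step ({spec.side.value}) failed: {exc}") from exc
        by_side[spec.side] = res.modulus
    E_B, _ = combine_sides(by_side.get(Side.ADAXIAL), by_side.get(Side.ABAXIAL))

    composite = CompositeModuli(E_T=tens.modulus, E_B=E_B)
    try:
        layers = invert_layer_moduli(composite.E_T, composite.E_B, alpha)
        diagnostic = classify_sandwich(composite.E_T, composite.E_B, alpha)
    except ValueError as exc:
        raise ValueError(f"inversion step failed: {exc}") from exc
    return composite, layers, diagnostic
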