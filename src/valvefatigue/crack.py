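"""Tear (crack) propagation at the maximum-stress site of a leaflet.

The initial tear is modelled as an elliptical crack with semi-major axis
``a`` and semi-minor axis ``b`` (mm).  Per cardiac cycle, each counted
sub-cycle drives growth as follows:

1. the stress concentration factor of the current geometry amplifies the
   applied (far-field) stress,
2. the elastic-plastic stress at the crack is recovered from the Glinka
   strain-energy-density criterion

       sigma^2/E + (2 sigma/(e+1)) (sigma/K)^(1/e) = (Kt S)^2 / E,

3. the stress intensity factor range ``dK = (sigma_max - sigma_min)
   sqrt(pi * length)`` uses the *other* axis as the length parameter
   (growth along the major axis uses b, growth along the minor axis uses a),
4. the Paris law ``d(alpha)/dN = C dK^m`` gives the per-cycle length
   increment, superposed over sub-cycles and cardiac cycles.

Geometry (and hence Kt and dK) is refreshed after every block of
``block_size`` cardiac cycles; block_size = 1 refreshes every cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fatigue import MaterialFatigueProperties
from .load_spectrum import SubCycle

__all__ = [
    "EllipticalCrack",
    "CrackGrowthTrajectory",
    "stress_concentration_factor",
    "glinka_notch_stress",
    "stress_intensity_range",
    "paris_increment",
    "propagate_crack",
]

#: Relative residual bound the Glinka root must satisfy.
GLINKA_RESIDUAL_RTOL = 1e-10


@dataclass(frozen=True)
class EllipticalCrack:
    """Semi-axes of the hypothesised initial tear, in mm (a >= b > 0)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("semi-minor axis b must be positive")
        if self.a < self.b:
            raise ValueError("semi-major axis a must be >= b")


def stress_concentration_factor(
    a: float, b: float, convention: Literal["paper", "classical"] = "paper"
) -> float:
    """Stress concentration factor of an elliptical crack.

    The default convention is ``Kt = 1 + 2 b / a`` (in (1, 3] for a >= b);
    ``convention="classical"`` selects the textbook elliptical-hole factor
    ``Kt = 1 + 2 a / b`` for sensitivity studies.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if convention == "paper":
        return 1.0 + 2.0 * b / a
    if convention == "classical":
        return 1.0 + 2.0 * a / b
    raise ValueError(f"unknown kt convention: {convention!r}")


def glinka_notch_stress(
    s: float, kt: float, material: MaterialFatigueProperties
) -> float:
    """Elastic-plastic stress at the crack from the Glinka energy criterion.

    Solves ``sigma^2/E + (2 sigma/(e+1)) (sigma/K)^(1/e) = (Kt s)^2/E`` for
    the unique root in (0, Kt*s] (the left side is strictly increasing).
    Negative applied stress is solved on the magnitude and the sign
    restored; s = 0 returns 0.  The returned root's residual is verified to
    be below ``1e-10`` of the right-hand side.
    """
    if kt < 1:
        raise ValueError("Kt must be >= 1")
    if s == 0.0:
        return 0.0
    mag = abs(s)
    e_mod = material.e_modulus
    e_exp = material.hardening_exp
    k_coeff = material.strength_coeff
    rhs = (kt * mag) ** 2 / e_mod

    def f(sigma: float) -> float:
        plastic = (2.0 * sigma / (e_exp + 1.0)) * (sigma / k_coeff) ** (1.0 / e_exp)
        return sigma * sigma / e_mod + plastic - rhs

    hi = kt * mag
    # f(0) = -rhs < 0 and f(hi) = plastic(hi) >= 0, so the bracket is valid
    root = brentq(f, 0.0, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(f(root)) > GLINKA_RESIDUAL_RTOL * rhs:
        raise RuntimeError(
            f"Glinka solve did not converge: residual {f(root):.3e} "
            f"for S={s}, Kt={kt}"
        )
    return math.copysign(root, s)


def stress_intensity_range(
    sigma_max: float, sigma_min: float, axis_length: float
) -> float:
    """dK = (sigma_max - sigma_min) sqrt(pi * length), in MPa*sqrt(mm)."""
    if sigma_max < sigma_min:
        raise ValueError("sigma_max must be >= sigma_min")
    if axis_length <= 0:
        raise ValueError("axis_length must be positive")
    return (sigma_max - sigma_min) * math.sqrt(math.pi * axis_length)


def paris_increment(delta_k: float, material: MaterialFatigueProperties) -> float:
    """Per-cycle growth length d(alpha) = C dK^m, in mm (0 for dK = 0)."""
    if delta_k < 0:
        raise ValueError("delta_k must be non-negative")
    if delta_k == 0.0:
        return 0.0
    return material.paris_c * delta_k**material.paris_m


@dataclass
class CrackGrowthTrajectory:
    """Crack geometry history recorded at block boundaries.

    ``status`` is "completed" if all requested cardiac cycles ran, or
    "tear-through" if an axis exceeded ``max_axis_length`` first.  The dK
    columns report the dominant (largest-range) sub-cycle of the block.
    """

    cycles: np.ndarray
    a: np.ndarray
    b: np.ndarray
    kt: np.ndarray
    dk_major: np.ndarray
    dk_minor: np.ndarray
    status: str = "completed"
    initial: EllipticalCrack | None = None

    @property
    def final_a(self) -> float:
        return float(self.a[-1])

    @property
    def final_b(self) -> float:
        return float(self.b[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "a_mm": self.a,
                "b_mm": self.b,
                "kt": self.kt,
                "dK_major": self.dk_major,
                "dK_minor": self.dk_minor,
            }
        )

    def summary(self) -> dict:
        return {
            "status": self.status,
            "cycles_run": int(self.cycles[-1]),
            "initial_a_mm": self.initial.a if self.initial else float(self.a[0]),
            "initial_b_mm": self.initial.b if self.initial else float(self.b[0]),
            "final_a_mm": self.final_a,
            "final_b_mm": self.final_b,
            "growth_a_mm": self.final_a - float(self.a[0]),
            "growth_b_mm": self.final_b - float(self.b[0]),
        }


def propagate_crack(
    crack0: EllipticalCrack,
    subcycles: Sequence[SubCycle],
    material: MaterialFatigueProperties,
    n_cardiac_cycles: int,
    block_size: int = 1,
    kt_convention: Literal["paper", "classical"] = "paper",
    max_axis_length: float | None = None,
    half_cycle_weight: bool = True,
) -> CrackGrowthTrajectory:
    """Propagate an elliptical crack under a per-cardiac-cycle spectrum.

    For each block of ``block_size`` cardiac cycles the current geometry
    fixes Kt and the per-axis dK of every sub-cycle; increments are weighted
    by sub-cycle counts (half-cycles weigh 0.5 unless ``half_cycle_weight``
    is False, in which case fractional counts are floored to whole cycles)
    and applied at the block end.  Stops early with status "tear-through"
    when an axis exceeds ``max_axis_length``.

    The axis-swap rule applies: growth of the major axis uses b as the
    length parameter in dK, growth of the minor axis uses a.  Because the
    minor-axis driving length is the larger one, b may outgrow a; the
    geometry is left unsorted and Kt applied to the values as they evolve.
    """
    if n_cardiac_cycles < 1:
        raise ValueError("n_cardiac_cycles must be >= 1")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    def weight(c: float) -> float:
        return c if half_cycle_weight else float(math.floor(c))

    active = [
        (sc, weight(sc.count))
        for sc in subcycles
        if sc.s_max > sc.s_min and weight(sc.count) > 0
    ]

    a, b = crack0.a, crack0.b
    rec_cycles = [0]
    rec_a, rec_b = [a], [b]
    rec_kt = [stress_concentration_factor(a, b, kt_convention)]
    rec_dkM: list[float] = [0.0]
    rec_dkm: list[float] = [0.0]
    status = "completed"

    done = 0
    while done < n_cardiac_cycles:
        nb = min(block_size, n_cardiac_cycles - done)
        kt = stress_concentration_factor(a, b, kt_convention)
        da = db = 0.0
        dk_major_dom = dk_minor_dom = 0.0
        dom_range = -1.0
        for sc, w in active:
            sig_max = glinka_notch_stress(sc.s_max, kt, material)
            sig_min = glinka_notch_stress(sc.s_min, kt, material)
            dk_major = stress_intensity_range(sig_max, sig_min, b)
            dk_minor = stress_intensity_range(sig_max, sig_min, a)
            da += w * paris_increment(dk_major, material)
            db += w * paris_increment(dk_minor, material)
            if sig_max - sig_min > dom_range:
                dom_range = sig_max - sig_min
                dk_major_dom, dk_minor_dom = dk_major, dk_minor
        a += nb * da
        b += nb * db
        done += nb
        rec_cycles.append(done)
        rec_a.append(a)
        rec_b.append(b)
        rec_kt.append(kt)
        rec_dkM.append(dk_major_dom)
        rec_dkm.append(dk_minor_dom)
        if max_axis_length is not None and max(a, b) > max_axis_length:
            status = "tear-through"
            break
        if da == 0.0 and db == 0.0:
            # no growth possible; remaining blocks are identical
            rec_cycles[-1] = n_cardiac_cycles
            break

    return CrackGrowthTrajectory(
        cycles=np.asarray(rec_cycles),
        a=np.asarray(rec_a),
        b=np.asarray(rec_b),
        kt=np.asarray(rec_kt),
        dk_major=np.asarray(rec_dkM),
        dk_minor=np.asarray(rec_dkm),
        status=status,
        initial=crack0,
    )
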