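"""Fatigue life from a counted sub-cycle spectrum.

Each counted sub-cycle (amplitude ``s_a``, mean ``s_m``) is converted to an
equivalent fully pulsatile stress with the parabolic Gerber mean-stress
correction,

    SNf = s_a / (1 - (s_m / Su)^2),

the cycles-to-failure follow from the Basquin high-cycle S-N relation
``SNf = sigma_f (2 Nf)^beta``, and damage accumulates linearly (Miner's
rule): the expected life is the number of cardiac cycles at which the summed
per-spectrum damage reaches 1.

The Basquin parameters supplied must be calibrated on pulsatile (R = 0)
tests, since the Gerber step maps every cycle onto that reference curve.
No endurance limit is assumed by default: damage accrues at all stress
levels.  Sub-cycles whose mean stress magnitude reaches the ultimate
strength, or whose equivalent stress reaches the single-cycle strength, are
clamped to immediate failure (Nf = 0.5, i.e. failure within one half-cycle)
and reported as warnings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .load_spectrum import (
    DEFAULT_REL_TOLERANCE,
    StressHistory,
    SubCycle,
    count_spectrum,
)

__all__ = [
    "MaterialFatigueProperties",
    "FatigueLifeResult",
    "SubCycleDamage",
    "gerber_equivalent_stress",
    "basquin_life",
    "spectrum_damage",
    "total_life",
    "cycles_to_duration",
    "fatigue_life_pipeline",
]

logger = logging.getLogger(__name__)

#: Minimum countable life: failure within one half-cycle.
MIN_LIFE_CYCLES = 0.5


class MaterialFatigueProperties(BaseModel):
    """Fatigue and fracture constants of the leaflet material.

    Units: stresses in MPa, lengths in mm; ``paris_c`` must be supplied in
    units consistent with mm and MPa*sqrt(mm) (it is not converted).
    """

    su: float = Field(gt=0, description="nominal ultimate tensile strength, MPa")
    sigma_f: float = Field(
        gt=0, description="single-cycle fatigue strength limit, MPa"
    )
    beta: float = Field(
        lt=0, description="fatigue life exponent (slope of the S-N curve)"
    )
    e_modulus: float = Field(gt=0, description="elastic modulus, MPa")
    hardening_exp: float = Field(
        gt=0, le=1, description="work hardening exponent (dimensionless)"
    )
    strength_coeff: float = Field(
        gt=0, description="cyclic strength coefficient, MPa"
    )
    paris_c: float = Field(
        gt=0, description="crack growth rate coefficient, mm/(cycle*(MPa*sqrt(mm))^m)"
    )
    paris_m: float = Field(gt=0, description="crack growth exponent (dimensionless)")

    @field_validator("beta")
    @classmethod
    def _beta_negative(cls, v: float) -> float:
        if v >= 0:
            raise ValueError("beta must be negative (life decreases with stress)")
        return v


def gerber_equivalent_stress(s_a: float, s_m: float, su: float) -> float:
    """Fully pulsatile equivalent stress via the parabolic Gerber correction.

    Returns ``s_a / (1 - (s_m/su)^2)``.  The squared mean-stress term is
    sign-symmetric, so compressive and tensile means are penalised equally.
    ``|s_m| >= su`` returns ``inf`` as an immediate-failure signal.
    """
    if s_a < 0:
        raise ValueError("s_a must be non-negative")
    if su <= 0:
        raise ValueError("su must be positive")
    if abs(s_m) >= su:
        logger.warning(
            "mean stress |%.4g| MPa reaches ultimate strength %.4g MPa: "
            "immediate failure",
            s_m,
            su,
        )
        return math.inf
    return s_a / (1.0 - (s_m / su) ** 2)


def basquin_life(snf: float, material: MaterialFatigueProperties) -> float:
    """Cycles to failure from the Basquin relation SNf = sigma_f (2 Nf)^beta.

    Inverts to ``Nf = 0.5 (SNf/sigma_f)^(1/beta)``; monotonically decreasing
    in SNf.  Equivalent stresses at or above ``sigma_f`` clamp to the minimum
    countable life of 0.5 cycles.
    """
    if not snf > 0:
        raise ValueError("SNf must be positive")
    if snf >= material.sigma_f:
        logger.warning(
            "equivalent stress %.4g MPa >= single-cycle strength %.4g MPa: "
            "life clamped to %.1f cycles",
            snf,
            material.sigma_f,
            MIN_LIFE_CYCLES,
        )
        return MIN_LIFE_CYCLES
    return 0.5 * (snf / material.sigma_f) ** (1.0 / material.beta)


@dataclass(frozen=True)
class SubCycleDamage:
    """Per-sub-cycle breakdown row: equivalent stress, life, damage share."""

    subcycle: SubCycle
    snf: float
    nf: float
    damage: float
    clamped: bool = False


@dataclass
class FatigueLifeResult:
    """Output of the fatigue pipeline for one load spectrum."""

    damage_per_spectrum: float
    total_life_cycles: float  # math.inf when no damage accrues
    duration_days: float
    duration_years: float
    bpm: float
    breakdown: list[SubCycleDamage] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def infinite_life(self) -> bool:
        return math.isinf(self.total_life_cycles)

    def breakdown_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_max_MPa": [r.subcycle.s_max for r in self.breakdown],
                "s_min_MPa": [r.subcycle.s_min for r in self.breakdown],
                "s_a_MPa": [r.subcycle.s_a for r in self.breakdown],
                "s_m_MPa": [r.subcycle.s_m for r in self.breakdown],
                "count": [r.subcycle.count for r in self.breakdown],
                "SNf_MPa": [r.snf for r in self.breakdown],
                "Nf_cycles": [r.nf for r in self.breakdown],
                "damage": [r.damage for r in self.breakdown],
                "clamped": [r.clamped for r in self.breakdown],
            }
        )

    def to_dict(self) -> dict:
        """JSON-safe summary (infinite life encoded as null + flag)."""
        return {
            "damage_per_spectrum": self.damage_per_spectrum,
            "total_life_cycles": (
                None if self.infinite_life else self.total_life_cycles
            ),
            "infinite_life": self.infinite_life,
            "duration_days": None if self.infinite_life else self.duration_days,
            "duration_years": None if self.infinite_life else self.duration_years,
            "bpm": self.bpm,
            "warnings": list(self.warnings),
            "breakdown": self.breakdown_frame().to_dict(orient="records"),
        }


def _subcycle_damage(
    sc: SubCycle,
    material: MaterialFatigueProperties,
    endurance_limit: float | None,
    clamp_negative_mean: bool,
    warnings_out: list[str] | None = None,
) -> SubCycleDamage | None:
    """Damage contribution of one sub-cycle, or None if it contributes none."""
    if sc.s_a == 0:
        return None
    if endurance_limit is not None and sc.s_a <= endurance_limit:
        return None
    s_m = sc.s_m
    if clamp_negative_mean and s_m < 0:
        s_m = 0.0
    snf = gerber_equivalent_stress(sc.s_a, s_m, material.su)
    clamped = False
    if math.isinf(snf):
        nf = MIN_LIFE_CYCLES
        clamped = True
        if warnings_out is not None:
            warnings_out.append(
                f"sub-cycle ({sc.s_max:.4g}, {sc.s_min:.4g}) MPa: mean stress "
                f"reaches ultimate strength; immediate failure assumed"
            )
    else:
        nf = basquin_life(snf, material)
        if nf == MIN_LIFE_CYCLES and snf >= material.sigma_f:
            clamped = True
            if warnings_out is not None:
                warnings_out.append(
                    f"sub-cycle ({sc.s_max:.4g}, {sc.s_min:.4g}) MPa: equivalent "
                    f"stress {snf:.4g} MPa >= sigma_f; life clamped to 0.5"
                )
    return SubCycleDamage(sc, snf, nf, sc.count / nf, clamped)


def spectrum_damage(
    subcycles: Sequence[SubCycle],
    material: MaterialFatigueProperties,
    endurance_limit: float | None = None,
    clamp_negative_mean: bool = False,
) -> float:
    """Miner damage of one cardiac-cycle spectrum: sum of count / Nf."""
    total = 0.0
    for sc in subcycles:
        row = _subcycle_damage(sc, material, endurance_limit, clamp_negative_mean)
        if row is not None:
            total += row.damage
    return total


def total_life(damage_per_spectrum: float) -> float:
    """Expected life in cardiac cycles: L = 1 / damage (inf for zero damage)."""
    if damage_per_spectrum < 0:
        raise ValueError("damage must be non-negative")
    if damage_per_spectrum == 0:
        return math.inf
    return 1.0 / damage_per_spectrum

def cycles_to_duration(life_cycles: float, bpm: float = 70.0) -> tuple[float, float]:
    """Convert a life in cardiac cycles to (years, days) at a heart rate.

    One cardiac cycle is one beat; years use the 365-day convention.
    """
    if life_cycles < 0:
        raise ValueError("life_cycles must be non-negative")
    if bpm <= 0:
        raise ValueError("bpm must be positive")
    days = life_cycles / (bpm * 60.0 * 24.0)
    return days / 365.0, days


def fatigue_life_pipeline(
    history: StressHistory,
    material: MaterialFatigueProperties,
    bpm: float = 70.0,
    rel_tolerance: float = DEFAULT_REL_TOLERANCE,
    n_cycles: int | None = None,
    endurance_limit: float | None = None,
    clamp_negative_mean: bool = False,
) -> FatigueLifeResult:
    """End-to-end fatigue life evaluation of a stress history.

    Composes turning-point extraction, peak simplification, rainflow
    counting (normalised to one cardiac cycle), Gerber correction, Basquin
    life, and Miner accumulation; deterministic for fixed input and options.
    """
    subcycles = count_spectrum(history, rel_tolerance, n_cycles)
    warnings: list[str] = []
    breakdown: list[SubCycleDamage] = []
    for sc in subcycles:
        row = _subcycle_damage(
            sc, material, endurance_limit, clamp_negative_mean, warnings
        )
        if row is not None:
            breakdown.append(row)
    damage = sum(r.damage for r in breakdown)
    life = total_life(damage)
    years, days = cycles_to_duration(life, bpm) if math.isfinite(life) else (
        math.inf,
        math.inf,
    )
    return FatigueLifeResult(
        damage_per_spectrum=damage,
        total_life_cycles=life,
        duration_days=days,
        duration_years=years,
        bpm=bpm,
        breakdown=breakdown,
        warnings=warnings,
    )
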