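"""Synthetic cardiac-cycle stress spectra.

Leaflet stress histories from patient-specific fluid-structure simulations
are not redistributable, so this module generates seeded, cardiac-cycle-
shaped stand-ins: one dominant systolic stress extremum per cycle, a
secondary diastolic feature, a sign profile distinguishing the
compression-dominant outer surface from the tension-dominant inner surface,
and exact repetition across cycles when noise is off (the stationary-
spectrum assumption of the fatigue model).

Three packaged templates emulate the three virtual patients of the study
conditions: systolic peak magnitudes 0.659 MPa (A, outer surface,
compression-dominant with a diastolic tensile reversal), 0.632 MPa (B,
outer surface, compression-dominant with a larger diastolic excursion) and
1.676 MPa (C, inner surface, persistent tension through both phases), all
at 70 beats per minute.  The waveform shapes are qualitative emulations of
the published spectra, not reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .load_spectrum import StressHistory

__all__ = [
    "SpectrumTemplate",
    "generate_cardiac_spectrum",
    "constant_amplitude_spectrum",
    "patient_template",
    "PATIENT_TEMPLATES",
]


@dataclass(frozen=True)
class SpectrumTemplate:
    """Parameters of one synthetic cardiac load spectrum.

    peak_stress and diastolic_stress are magnitudes in MPa; the sign profile
    places the systolic peak in compression (outer surface) or tension
    (inner surface).  ``n_harmonics`` sharpens the systolic bump (the bump
    is sin^(2n)); ``noise_sd`` adds seeded Gaussian noise in MPa.
    """

    peak_stress: float
    diastolic_stress: float = 0.0
    sign_profile: Literal["tension", "compression"] = "tension"
    systole_fraction: float = 0.35
    bpm: float = 70.0
    n_harmonics: int = 2
    noise_sd: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.peak_stress <= 0:
            raise ValueError("peak_stress must be positive")
        if self.diastolic_stress < 0:
            raise ValueError("diastolic_stress must be non-negative")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bpm <= 0:
            raise ValueError("bpm must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


#: Packaged per-patient templates (peak magnitudes from the study conditions;
#: diastolic counter-stresses are qualitative defaults).
PATIENT_TEMPLATES: dict[str, SpectrumTemplate] = {
    "A": SpectrumTemplate(
        peak_stress=0.659,
        diastolic_stress=0.10,
        sign_profile="compression",
        label="patient-A outer surface",
    ),
    "B": SpectrumTemplate(
        peak_stress=0.632,
        diastolic_stress=0.30,
        sign_profile="compression",
        label="patient-B outer surface",
    ),
    "C": SpectrumTemplate(
        peak_stress=1.676,
        diastolic_stress=0.80,
        sign_profile="tension",
        label="patient-C inner surface",
    ),
}


def patient_template(name: str, **overrides) -> SpectrumTemplate:
    """Packaged template for virtual patient "A", "B" or "C"."""
    try:
        base = PATIENT_TEMPLATES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown patient template {name!r}; use A, B or C")
    if overrides:
        from dataclasses import replace

        return replace(base, **overrides)
    return base


def _bump(phase: np.ndarray, exponent: int) -> np.ndarray:
    """Smooth 0->1->0 bump over phase in [0, 1], normalised to sampled max 1."""
    y = np.sin(np.pi * phase) ** (2 * exponent)
    peak = y.max()
    return y / peak if peak > 0 else y


def generate_cardiac_spectrum(
    template: SpectrumTemplate,
    n_cycles: int = 1,
    samples_per_cycle: int = 200,
) -> StressHistory:
    """Generate a stress history of ``n_cycles`` identical cardiac cycles.

    Each cycle holds a systolic bump of magnitude ``peak_stress`` over the
    systolic window and a diastolic bump of magnitude ``diastolic_stress``
    over the remainder.  The bumps are renormalised on the sample grid so
    the noise-free sampled extreme equals the template peak exactly.
    Deterministic for a fixed seed.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if samples_per_cycle < 16:
        raise ValueError("samples_per_cycle must be >= 16")
    period = 60.0 / template.bpm
    phase = np.arange(samples_per_cycle) / samples_per_cycle
    fs = template.systole_fraction
    cycle = np.zeros(samples_per_cycle)
    sys_mask = phase < fs
    cycle[sys_mask] = template.peak_stress * _bump(
        phase[sys_mask] / fs, template.n_harmonics
    )
    if template.sign_profile == "compression":
        cycle[sys_mask] *= -1.0
    dia_mask = ~sys_mask
    if template.diastolic_stress > 0 and dia_mask.any():
        cycle[dia_mask] = template.diastolic_stress * _bump(
            (phase[dia_mask] - fs) / (1.0 - fs), template.n_harmonics
        )
    stress = np.concatenate([np.tile(cycle, n_cycles), cycle[:1]])
    time = np.arange(stress.size) * (period / samples_per_cycle)
    if template.noise_sd > 0:
        rng = np.random.default_rng(template.seed)
        stress = stress + rng.normal(0.0, template.noise_sd, stress.size)
    return StressHistory(
        time=time,
        stress=stress,
        label=template.label or "synthetic cardiac spectrum",
        period=period,
    )


def constant_amplitude_spectrum(
    s_max: float,
    s_min: float,
    n_cycles: int = 1,
    samples_per_cycle: int = 64,
    bpm: float = 70.0,
) -> StressHistory:
    """Triangular wave between s_min and s_max, one full cycle per period.

    The wave starts and ends each period at s_min and reaches s_max exactly
    at mid-period on the sample grid, so rainflow counting of k periods
    yields exactly k cycles (s_max, s_min).
    """
    if not s_max > s_min:
        raise ValueError("s_max must exceed s_min")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if samples_per_cycle < 16:
        raise ValueError("samples_per_cycle must be >= 16")
    period = 60.0 / bpm
    half = samples_per_cycle // 2
    up = np.linspace(s_min, s_max, half + 1)
    down = np.linspace(s_max, s_min, samples_per_cycle - half + 1)[1:-1]
    cycle = np.concatenate([up, down])
    stress = np.concatenate([np.tile(cycle, n_cycles), [s_min]])
    time = np.arange(stress.size) * (period / samples_per_cycle)
    return StressHistory(
        time=time,
        stress=stress,
        label=f"constant amplitude ({s_max}, {s_min}) MPa",
        period=period,
    )
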