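"""Packaged reference values from the published study conditions.

``REPORTED_FATIGUE_LIVES`` holds the reported fatigue lives (in cardiac
cycles) of the three virtual patients at the top (inner-surface) and bottom
(outer-surface) maximum-stress integration points, used as inputs for
duration conversions and regression checks.  ``REPORTED_PEAK_STRESS_MPA``
holds the printed per-patient systolic peak stress magnitudes.
"""

from __future__ import annotations

#: Reported fatigue lives, cycles, keyed by (patient, integration point).
REPORTED_FATIGUE_LIVES: dict[tuple[str, str], float] = {
    ("A", "top"): 5.65e9,
    ("A", "bottom"): 4.58e9,
    ("B", "top"): 4.58e8,
    ("B", "bottom"): 2.02e9,
    ("C", "top"): 9.30e5,
    ("C", "bottom"): 4.40e5,
}

#: Printed systolic peak stress magnitudes, MPa.
REPORTED_PEAK_STRESS_MPA: dict[str, float] = {
    "A": 0.659,
    "B": 0.632,
    "C": 1.676,
}

#: Regulatory durability requirement for the valve platform, cycles.
CYCLE_REQUIREMENT = 4.0e8

#: Heart rate of the pulse-duplicator protocol, beats per minute.
REFERENCE_BPM = 70.0
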