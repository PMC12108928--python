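"""Hyperelastic material helpers for the leaflet material card.

The leaflet tissue (glutaraldehyde-treated bovine pericardium) is described
by a one-term reduced-polynomial (neo-Hookean) strain-energy function

    U = C10 (I1 - 3) + (1/D1) (Jel - 1)^2

with C10 and D1 derived from the initial shear modulus mu0 and Poisson's
ratio nu.  These helpers document the material card; the fatigue pipeline
itself operates on stress histories produced upstream and does not consume
them.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

__all__ = ["HyperelasticParams", "neo_hookean_params", "neo_hookean_energy"]


def neo_hookean_params(mu0: float, nu: float) -> tuple[float, float]:
    """Convert (initial shear modulus, Poisson ratio) to (C10, D1).

    C10 = mu0 / 2 and D1 = 3 (1 - 2 nu) / (mu0 (nu + 1)); D1 = 0 in the
    incompressible limit nu = 0.5.
    """
    if mu0 <= 0:
        raise ValueError("mu0 must be positive")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("nu must lie in [0, 0.5]")
    c10 = mu0 / 2.0
    d1 = 3.0 * (1.0 - 2.0 * nu) / (mu0 * (nu + 1.0))
    return c10, d1


def neo_hookean_energy(c10: float, d1: float, i1: float, j_el: float) -> float:
    """Strain energy per unit reference volume, in MPa.

    ``i1`` is the first deviatoric strain invariant (>= 3 for admissible
    states) and ``j_el`` the elastic volume ratio.  With d1 = 0 the material
    is incompressible and only j_el = 1 is admissible.
    """
    if j_el <= 0:
        raise ValueError("j_el must be positive")
    iso = c10 * (i1 - 3.0)
    if d1 == 0.0:
        if j_el != 1.0:
            raise ValueError("incompressible material (d1 = 0) requires j_el = 1")
        return iso
    return iso + (1.0 / d1) * (j_el - 1.0) ** 2


class HyperelasticParams(BaseModel):
    """Neo-Hookean parameter set; C10/D1 follow from mu0 and nu."""

    mu0: float = Field(gt=0, description="initial shear modulus, MPa")
    nu: float = Field(ge=0, le=0.5, description="Poisson's ratio")

    @property
    def c10(self) -> float:
        return neo_hookean_params(self.mu0, self.nu)[0]

    @property
    def d1(self) -> float:
        return neo_hookean_params(self.mu0, self.nu)[1]

    @model_validator(mode="after")
    def _check(self) -> "HyperelasticParams":
        neo_hookean_params(self.mu0, self.nu)  # raises on invalid
        return self

    def energy(self, i1: float, j_el: float) -> float:
        return neo_hookean_energy(self.c10, self.d1, i1, j_el)
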