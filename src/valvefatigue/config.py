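"""Material configuration files (JSON or YAML), schema-validated.

A material config has a required ``fatigue`` section matching
:class:`~valvefatigue.fatigue.MaterialFatigueProperties` field names
(stresses in MPa, lengths in mm; ``paris_c`` in units consistent with mm
and MPa*sqrt(mm)) and an optional ``hyperelastic`` section (``mu0`` MPa,
``nu``).  The fatigue (Basquin) parameters must be calibrated on fully
pulsatile (R = 0) tests: the Gerber step maps every counted cycle onto that
reference S-N curve.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ValidationError

from .fatigue import MaterialFatigueProperties
from .materials import HyperelasticParams

__all__ = [
    "MaterialConfig",
    "load_material_config",
    "demo_material_config",
    "demo_material",
]


class MaterialConfig(BaseModel):
    fatigue: MaterialFatigueProperties
    hyperelastic: HyperelasticParams | None = None


def load_material_config(path: str | Path) -> MaterialConfig:
    """Load and validate a material config from a .yaml/.yml/.json file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: material config must be a mapping")
    try:
        return MaterialConfig.model_validate(data)
    except ValidationError as err:
        raise ValueError(f"{path}: invalid material config:\n{err}") from err


def demo_material_config() -> MaterialConfig:
    """The packaged demo material card (placeholder constants; see file)."""
    ref = resources.files("valvefatigue") / "data" / "demo_material.yaml"
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return MaterialConfig.model_validate(data)


def demo_material() -> MaterialFatigueProperties:
    """Fatigue section of the packaged demo material card."""
    return demo_material_config().fatigue
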