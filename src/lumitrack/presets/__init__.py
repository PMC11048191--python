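"""Named simulation scenarios.

Each preset is a small YAML file bundling a cell line / treatment label with
the population parameters that plant that condition's ground truth: the
responder mixture (what fraction of cells suppress the reporter, and how
deeply) and the between-session mobility (how many cells are lost or
displaced, encoding the 2D vs Matrigel-overlay contrast).  Users can point
``load_preset`` at their own YAML files with the same schema.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from ..config import MixtureConfig, MobilityConfig, OpticsConfig, PopulationConfig

__all__ = ["list_presets", "load_preset", "override_population", "Preset"]

_PKG = "lumitrack.presets"


@dataclasses.dataclass(frozen=True)
class Preset:
    name: str
    label: str
    cell_line: str
    treatment: str
    population: PopulationConfig
    optics: OpticsConfig


def list_presets() -> List[str]:
    """Names of the bundled scenario files."""
    names = []
    for entry in resources.files(_PKG).iterdir():
        if entry.name.endswith(".yaml"):
            names.append(entry.name[: -len(".yaml")])
    return sorted(names)


def _population_from_dict(d: dict, seed: int, n_cells: Optional[int]) -> PopulationConfig:
    d = dict(d)
    mix = MixtureConfig(**d.pop("mixture", {}))
    mob = MobilityConfig(**d.pop("mobility", {}))
    if "field_size" in d:
        d["field_size"] = tuple(d["field_size"])
    for key in ("intensity_lognormal", "gfp_lognormal"):
        if key in d:
            d[key] = tuple(d[key])
    if n_cells is not None:
        d["n_cells"] = n_cells
    return PopulationConfig(mixture=mix, mobility=mob, seed=seed, **d)


def override_population(pop: PopulationConfig, overrides: dict) -> PopulationConfig:
    """Return a copy of ``pop`` with nested overrides applied."""
    d = dict(overrides or {})
    mix = dataclasses.replace(pop.mixture, **d.pop("mixture", {}))
    mob = dataclasses.replace(pop.mobility, **d.pop("mobility", {}))
    if "field_size" in d:
        d["field_size"] = tuple(d["field_size"])
    for key in ("intensity_lognormal", "gfp_lognormal"):
        if key in d:
            d[key] = tuple(d[key])
    out = dataclasses.replace(pop, mixture=mix, mobility=mob, **d)
    out.validate()
    return out


def load_preset(
    name: str,
    seed: int = 0,
    n_cells: Optional[int] = None,
    path: Optional[Path] = None,
) -> Preset:
    """Load a bundled preset by name, or any YAML scenario file via ``path``.

    ``n_cells`` overrides the preset's population size; ``seed`` seeds every
    random stage downstream.
    """
    if path is not None:
        text = Path(path).read_text()
    else:
        ref = resources.files(_PKG) / f"{name}.yaml"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise KeyError(
                f"unknown preset {name!r}; available: {', '.join(list_presets())}"
            ) from None
    raw = yaml.safe_load(text)
    pop = _population_from_dict(raw.get("population", {}), seed=seed, n_cells=n_cells)
    optics = OpticsConfig(**raw.get("optics", {}))
    pop.validate()
    optics.validate()
    return Preset(
        name=name,
        label=raw.get("label", name),
        cell_line=raw.get("cell_line", ""),
        treatment=raw.get("treatment", ""),
        population=pop,
        optics=optics,
    )
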