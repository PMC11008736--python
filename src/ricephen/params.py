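"""Thermal-response parameters for the piecewise-linear development model.

Each life stage of a planthopper species is described by four constants:

``t_min``
    lower developmental threshold (deg C) — no development below it;
``t_upper``
    upper threshold above which the development rate stops increasing
    (the rate plateaus);
``t_stop``
    critical thermal maximum at which development ceases entirely;
``k``
    thermal constant (degree-days) — the accumulated effective
    temperature required to complete the stage.

The packaged default registry (``data/species_params.yaml``) carries the
laboratory-derived constants for *Nilaparvata lugens*, *Sogatella
furcifera* and *Laodelphax striatellus* at the egg, nymph and
preoviposition stages.  Users may supply their own YAML registry with the
same ``species -> stage -> {t_min, t_upper, t_stop, k}`` layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

STAGE_NAMES = ("egg", "nymph", "preoviposition")
SPECIES_NAMES = ("N_lugens", "S_furcifera", "L_striatellus")

#: Order in which stages are chained when predicting one generation.
#: A generation interval runs adult arrival/peak -> next adult peak, so it
#: opens with the preoviposition period of the arriving adults, then the
#: egg and nymphal development of their offspring.
GENERATION_STAGE_ORDER = ("preoviposition", "egg", "nymph")


@dataclass(frozen=True)
class StageParams:
    """Piecewise-linear thermal response of one life stage."""

    stage_name: str
    t_min: float
    t_upper: float
    t_stop: float
    k: float

    def __post_init__(self) -> None:
        if self.stage_name not in STAGE_NAMES:
            raise ValueError(
                f"unknown stage {self.stage_name!r}; expected one of {STAGE_NAMES}"
            )
        if not (self.t_min < self.t_upper <= self.t_stop):
            raise ValueError(
                "thresholds must satisfy t_min < t_upper <= t_stop, got "
                f"{self.t_min}, {self.t_upper}, {self.t_stop}"
            )
        if not self.k > 0:
            raise ValueError(f"thermal constant k must be positive, got {self.k}")


@dataclass(frozen=True)
class SpeciesModel:
    """Ordered set of stage parameters defining one generation of a species."""

    species_name: str
    stages: tuple[StageParams, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.species_name not in SPECIES_NAMES:
            raise ValueError(
                f"unknown species {self.species_name!r}; expected one of {SPECIES_NAMES}"
            )
        names = [s.stage_name for s in self.stages]
        if sorted(names) != sorted(STAGE_NAMES):
            raise ValueError(
                f"species model needs exactly one of each stage {STAGE_NAMES}, got {names}"
            )

    def stage(self, name: str) -> StageParams:
        for s in self.stages:
            if s.stage_name == name:
                return s
        raise KeyError(name)

    def generation_stages(
        self, order: tuple[str, ...] = GENERATION_STAGE_ORDER
    ) -> tuple[StageParams, ...]:
        """Stages in the order they are chained over one generation."""
        return tuple(self.stage(name) for name in order)


def _model_from_mapping(species: str, mapping: dict) -> SpeciesModel:
    stages = tuple(
        StageParams(stage_name=stage, **{k: float(v) for k, v in vals.items()})
        for stage, vals in mapping.items()
    )
    return SpeciesModel(species_name=species, stages=stages)


def load_species_registry(path: str | Path | None = None) -> dict[str, SpeciesModel]:
    """Load a species -> :class:`SpeciesModel` registry from YAML.

    With ``path=None`` the packaged default parameter set is returned.
    """
    if path is None:
        text = resources.files("ricephen.data").joinpath("species_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise ValueError("species registry must be a non-empty mapping")
    return {sp: _model_from_mapping(sp, stages) for sp, stages in raw.items()}


def get_species_model(species: str, path: str | Path | None = None) -> SpeciesModel:
    """Convenience lookup of one species in a registry (default registry if no path)."""
    registry = load_species_registry(path)
    try:
        return registry[species]
    except KeyError:
        raise KeyError(
            f"species {species!r} not in registry; available: {sorted(registry)}"
        ) from None
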