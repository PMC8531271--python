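"""Serializable model specification: structural + stochastic components.

A :class:`ModelSpec` bundles everything needed to simulate or fit one drug:
the typical-value structural parameters, the random-effects SDs, the
residual-error model and the nominal dosing.  Two specifications matching
the final paediatric lamivudine and abacavir models ship with the package
(``load_model("lamivudine")`` / ``load_model("abacavir")``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import yaml

from .random_effects import ErrorModel, RandomEffectsSpec
from .structural import StructuralParams

__all__ = ["DosingSpec", "ModelSpec", "load_model", "save_model"]


@dataclass(frozen=True)
class DosingSpec:
    mg_per_kg: float = 4.0
    interval: float = 12.0  # h


@dataclass(frozen=True)
class ModelSpec:
    drug: str
    structural: StructuralParams
    random_effects: RandomEffectsSpec = field(default_factory=RandomEffectsSpec)
    error: ErrorModel = field(default_factory=ErrorModel)
    dosing: DosingSpec = field(default_factory=DosingSpec)

    def with_mdr_effect(self, target: str, theta: float) -> "ModelSpec":
        """Copy of the spec with a proportional MDR-TB effect on ``target``."""
        return replace(self, structural=replace(
            self.structural, mdr_target=target, theta_mdr=theta))

    def without_mdr_effect(self) -> "ModelSpec":
        return replace(self, structural=replace(
            self.structural, mdr_target=None, theta_mdr=0.0))

    def to_dict(self) -> dict:
        d = {
            "drug": self.drug,
            "structural": {k: v for k, v in asdict(self.structural).items()
                           if k != "mdr_target" or v is not None},
            "random_effects": {k: float(v) for k, v in
                               asdict(self.random_effects).items()
                               if k != "correlations"},
            "error": asdict(self.error),
            "dosing": {"mg_per_kg": self.dosing.mg_per_kg,
                       "interval": self.dosing.interval},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        dosing = d.get("dosing", {})
        return cls(
            drug=d["drug"],
            structural=StructuralParams(**d["structural"]),
            random_effects=RandomEffectsSpec(**d.get("random_effects", {})),
            error=ErrorModel(**d.get("error", {})),
            dosing=DosingSpec(
                mg_per_kg=float(dosing.get("mg_per_kg", 4.0)),
                interval=float(dosing.get("interval", 12.0))),
        )


def load_model(name_or_path: str | Path) -> ModelSpec:
    """Load a model spec from a bundled name or a YAML file path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        ref = resources.files("pedpk.models") / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(
                f"no bundled model {name_or_path!r} and no such file")
        text = ref.read_text()
    return ModelSpec.from_dict(yaml.safe_load(text))


def save_model(spec: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
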