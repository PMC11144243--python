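"""Media: named metabolite-availability tables.

A medium grants each listed metabolite a maximal import rate
(mmol·gDW⁻¹·h⁻¹); anything not listed cannot be imported.  Mineral ions and
water/protons are treated as always available at the default cap unless a
medium overrides them — carbon and nitrogen sources must always be granted
explicitly, mirroring minimal-mineral-medium practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Set

import yaml

from .model import DEFAULT_BOUND, base_id

#: Mineral/base-id set granted at the default cap unless a medium overrides.
DEFAULT_MINERALS: frozenset = frozenset(
    {"h", "h2o", "o2", "pi", "so4", "k", "mg2", "fe2", "na1", "cl"}
)


@dataclass
class Medium:
    name: str
    imports: Dict[str, float] = field(default_factory=dict)
    unconstrained_minerals: Set[str] = field(default_factory=lambda: set(DEFAULT_MINERALS))

    def __post_init__(self) -> None:
        normalized = {}
        for met, rate in self.imports.items():
            rate = float(rate)
            if rate < 0:
                raise ValueError(f"medium {self.name!r}: negative rate for {met!r}")
            normalized[base_id(met)] = rate
        self.imports = normalized
        self.unconstrained_minerals = {base_id(m) for m in self.unconstrained_minerals}

    def uptake_allowance(self, met_base: str) -> float:
        if met_base in self.imports:
            return self.imports[met_base]
        if met_base in self.unconstrained_minerals:
            return DEFAULT_BOUND
        return 0.0

    def with_import(self, met: str, rate: float) -> "Medium":
        new_imports = dict(self.imports)
        new_imports[base_id(met)] = float(rate)
        return replace(self, imports=new_imports,
                       unconstrained_minerals=set(self.unconstrained_minerals))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "imports": dict(sorted(self.imports.items())),
            "unconstrained_minerals": sorted(self.unconstrained_minerals),
        }


def _medium_from_dict(doc: dict) -> Medium:
    kwargs = {"name": doc["name"], "imports": dict(doc.get("imports", {}))}
    if "unconstrained_minerals" in doc:
        kwargs["unconstrained_minerals"] = set(doc["unconstrained_minerals"])
    return Medium(**kwargs)


def load_media(path) -> List[Medium]:
    """Load one medium or a panel of media from a JSON/YAML file."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
    if isinstance(doc, dict) and "media" in doc:
        doc = doc["media"]
    if isinstance(doc, dict):
        doc = [doc]
    return [_medium_from_dict(d) for d in doc]


def load_medium(path, name: str | None = None) -> Medium:
    media = load_media(path)
    if name is None:
        if len(media) != 1:
            raise ValueError(
                f"{path} holds {len(media)} media; specify one of "
                f"{[m.name for m in media]}"
            )
        return media[0]
    for m in media:
        if m.name == name:
            return m
    raise KeyError(f"medium {name!r} not found in {path}")


def save_media(media: List[Medium], path) -> None:
    docs = [m.to_dict() for m in media]
    payload = docs[0] if len(docs) == 1 else docs
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
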