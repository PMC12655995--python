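"""Trait catalog for cacao germplasm descriptors.

The default catalog covers the standard agromorphological descriptor set used
to characterize cacao (*Theobroma cacao* L.) collections: 33 quantitative
descriptors (leaf, flower, fruit and seed biometrics) and 18 qualitative
descriptors with fixed categorical levels (shapes, colors, anthocyanin
presence).  Descriptors are keyed by their conventional acronyms (FM = fruit
mass, SI = seed index, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

STRUCTURES = ("leaf", "flower", "fruit", "seed")
KINDS = ("quantitative", "qualitative")


@dataclass(frozen=True)
class TraitDef:
    """Definition of a single descriptor.

    Parameters
    ----------
    acronym : str
        Short unique key, e.g. ``"FM"``.
    structure : str
        Plant structure the descriptor is measured on: leaf, flower, fruit
        or seed.
    kind : str
        ``"quantitative"`` (real-valued) or ``"qualitative"`` (categorical).
    units : str
        Measurement units for quantitative descriptors (``"unit"`` for
        counts); empty for qualitative ones.
    levels : tuple of str
        Ordered categorical levels; only for qualitative descriptors.
    name : str
        Human-readable descriptor name.
    """

    acronym: str
    structure: str
    kind: str
    units: str = ""
    levels: tuple[str, ...] = field(default_factory=tuple)
    name: str = ""

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "qualitative" and len(self.levels) < 2:
            raise ValueError(
                f"qualitative descriptor {self.acronym!r} needs >=2 levels"
            )


class TraitCatalog:
    """Immutable collection of :class:`TraitDef` keyed by acronym."""

    def __init__(self, traits: Iterable[TraitDef]):
        traits = list(traits)
        acronyms = [t.acronym for t in traits]
        if len(set(acronyms)) != len(acronyms):
            dupes = sorted({a for a in acronyms if acronyms.count(a) > 1})
            raise ValueError(f"duplicate acronyms in catalog: {dupes}")
        self._traits: dict[str, TraitDef] = {t.acronym: t for t in traits}

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._traits

    def __getitem__(self, acronym: str) -> TraitDef:
        try:
            return self._traits[acronym]
        except KeyError:
            raise KeyError(f"descriptor {acronym!r} not in catalog") from None

    def __iter__(self):
        return iter(self._traits.values())

    def __len__(self) -> int:
        return len(self._traits)

    @property
    def acronyms(self) -> list[str]:
        return list(self._traits)

    def quantitative(self) -> list[TraitDef]:
        return [t for t in self if t.kind == "quantitative"]

    def qualitative(self) -> list[TraitDef]:
        return [t for t in self if t.kind == "qualitative"]

    def is_quantitative(self, acronym: str) -> bool:
        return self[acronym].kind == "quantitative"

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = [
            {
                "acronym": t.acronym,
                "structure": t.structure,
                "kind": t.kind,
                "units": t.units,
                "levels": list(t.levels),
                "name": t.name,
            }
            for t in self
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TraitCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            TraitDef(
                acronym=d["acronym"],
                structure=d["structure"],
                kind=d["kind"],
                units=d.get("units", ""),
                levels=tuple(d.get("levels", ())),
                name=d.get("name", ""),
            )
            for d in payload
        )


def _q(acronym, structure, units, name):
    return TraitDef(acronym, structure, "quantitative", units=units, name=name)


def _c(acronym, structure, levels, name):
    return TraitDef(
        acronym, structure, "qualitative", levels=tuple(levels), name=name
    )


_QUANTITATIVE = [
    _q("LL", "leaf", "cm", "Leaf length"),
    _q("LW", "leaf", "cm", "Leaf width"),
    _q("PtL", "leaf", "cm", "Petiole length"),
    _q("PdL", "flower", "cm", "Pedicel length"),
    _q("SpL", "flower", "mm", "Sepal length"),
    _q("SW", "flower", "mm", "Sepal width"),
    _q("PL", "flower", "mm", "Petal length"),
    _q("PW", "flower", "mm", "Petal width"),
    _q("LgW", "flower", "mm", "Ligule width"),
    _q("FL", "flower", "mm", "Filament length"),
    _q("StL", "flower", "mm", "Staminode length"),
    _q("SL", "flower", "mm", "Style length"),
    _q("OL", "flower", "mm", "Ovary length"),
    _q("OW", "flower", "mm", "Ovary width"),
    _q("SH", "fruit", "MPa", "Shell hardness"),
    _q("FM", "fruit", "g", "Fruit mass"),
    _q("FrL", "fruit", "cm", "Fruit length"),
    _q("FW", "fruit", "cm", "Fruit width"),
    _q("PrT", "fruit", "cm", "Pericarp thickness"),
    _q("GD", "fruit", "cm", "Groove depth"),
    _q("PM", "fruit", "g", "Pericarp mass"),
    _q("NL", "fruit", "unit", "Number of locules"),
    _q("TSS", "fruit", "°Brix", "Total soluble solids"),
    _q("NSL", "seed", "unit", "Number of seeds per locule"),
    _q("FSMF", "seed", "g", "Fresh seed mass per fruit"),
    _q("NSF", "seed", "unit", "Number of seeds per fruit"),
    _q("SI", "seed", "g", "Seed index"),
    _q("PI", "seed", "unit", "Pod index"),
    _q("NIS", "seed", "unit", "Number of intact seeds"),
    _q("NES", "seed", "unit", "Number of empty seeds"),
    _q("SeL", "seed", "mm", "Seed length"),
    _q("SD", "seed", "mm", "Seed diameter"),
    _q("ST", "seed", "mm", "Seed thickness"),
]

_QUALITATIVE = [
    _c("LBS", "leaf", ["Acute", "Obtuse", "Rounded", "Codiform"], "Leaf base shape"),
    _c("LAS", "leaf", ["Apiculate", "Acuminate", "Caudate"], "Leaf apex shape"),
    _c("YLC", "leaf", ["Green", "Brown", "Red"], "Young leaf color"),
    _c("PC", "flower", ["Green", "Reddish green", "Reddish"], "Pedicel color"),
    _c("ASe", "flower", ["Absent", "Present"], "Anthocyanin in sepals"),
    _c("ASt", "flower", ["Absent", "Present"], "Anthocyanin in staminodes"),
    _c("AF", "flower", ["Absent", "Present"], "Anthocyanin in filament"),
    _c("AO", "flower", ["Absent", "Present"], "Anthocyanin in ovary"),
    _c("AL", "flower", ["Absent", "Present"], "Anthocyanin in ligule"),
    _c("IFC", "fruit", ["Green", "Pigmented green", "Red"], "Immature fruit color"),
    _c("MFC", "fruit", ["Yellow", "Orange", "Green", "Red"], "Mature fruit color"),
    _c(
        "FS",
        "fruit",
        ["Oblong", "Elliptical", "Obovate", "Rounded", "Ovate"],
        "Fruit shape",
    ),
    _c(
        "FAS",
        "fruit",
        ["Attenuate", "Acute", "Obtuse", "Rounded", "Apezonate", "Dentate"],
        "Fruit apex shape",
    ),
    _c(
        "FBC",
        "fruit",
        ["Absent", "Slight", "Intermediate", "Strong"],
        "Fruit basal constriction",
    ),
    _c("FR", "fruit", ["Absent", "Mild", "Intermediate", "Rough"], "Fruit roughness"),
    _c(
        "STS",
        "seed",
        ["Flattened", "Intermediate", "Rounded"],
        "Seed transversal shape",
    ),
    _c(
        "SLS",
        "seed",
        ["Oblong", "Elliptical", "Ovate", "Irregular"],
        "Seed longitudinal shape",
    ),
    _c("SC", "seed", ["White", "Pink", "Violet", "Purple"], "Seed color"),
]


def default_catalog() -> TraitCatalog:
    """The standard cacao descriptor catalog (33 quantitative, 18 qualitative)."""
    return TraitCatalog(_QUANTITATIVE + _QUALITATIVE)
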