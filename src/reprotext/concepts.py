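"""Concept inventory: the 15 data elements extracted from reproductive notes.

Each concept is described by a :class:`ConceptSpec` — its hook keywords, the
extraction rule family it follows (quantity / categorical / date), whether it
is followed over time as a ``(date, value)`` series, its recognised units and
a plausibility window used by postprocessing.  The default table ships as an
editable YAML file (``data/concepts.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

# rule families
QUANTITY = "quantity"
CATEGORICAL = "categorical"
DATE = "date"

# canonical concept names
MENARCHE_AGE = "menarche_age"
MENSTRUAL_CYCLE = "menstrual_cycle"
MENSTRUATION_AMOUNT = "menstruation_amount"
EXAM_DATE = "exam_date"
FSH = "fsh"
LH = "lh"
E2 = "e2"
P = "p"
PRL = "prl"
T = "t"
AMH = "amh"
ENDOMETRIUM = "endometrial_thickness"
UTERINE_POSITION = "uterine_position"
AFC_LEFT = "afc_left"
AFC_RIGHT = "afc_right"

HORMONES = (FSH, LH, E2, P, PRL, T, AMH)
ULTRASOUND = (ENDOMETRIUM, UTERINE_POSITION, AFC_LEFT, AFC_RIGHT)


class UnknownConceptError(KeyError):
    """Raised when a concept name is not in the active inventory."""


@dataclass(frozen=True)
class ConceptSpec:
    """Static description of one extractable concept."""

    name: str
    field: str
    keywords: tuple[str, ...]
    rule: str
    timed: bool
    gap: str = "tight"
    units: tuple[str, ...] = ()
    categories: tuple[str, ...] = ()
    plausible_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"{self.name}: keywords must be non-empty")
        if self.rule not in (QUANTITY, CATEGORICAL, DATE):
            raise ValueError(f"{self.name}: unknown rule tag {self.rule!r}")
        if self.plausible_range is not None:
            lo, hi = self.plausible_range
            if not lo < hi:
                raise ValueError(f"{self.name}: plausible_range min must be < max")


def _spec_from_mapping(m: dict) -> ConceptSpec:
    rng = m.get("plausible_range")
    return ConceptSpec(
        name=m["name"],
        field=m["field"],
        keywords=tuple(m["keywords"]),
        rule=m["rule"],
        timed=bool(m["timed"]),
        gap=m.get("gap", "tight"),
        units=tuple(m.get("units") or ()),
        categories=tuple(m.get("categories") or ()),
        plausible_range=tuple(rng) if rng else None,
    )


def load_concept_specs(path: Optional[str] = None) -> dict[str, ConceptSpec]:
    """Load the concept table from *path*, or the packaged default."""
    if path is None:
        text = resources.files("reprotext.data").joinpath("concepts.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = {}
    for m in raw["concepts"]:
        spec = _spec_from_mapping(m)
        specs[spec.name] = spec
    return specs


_DEFAULT: Optional[dict[str, ConceptSpec]] = None


def default_specs() -> dict[str, ConceptSpec]:
    """The packaged concept inventory (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_concept_specs()
    return _DEFAULT


def get_spec(name: str, specs: Optional[dict[str, ConceptSpec]] = None) -> ConceptSpec:
    table = specs if specs is not None else default_specs()
    try:
        return table[name]
    except KeyError:
        raise UnknownConceptError(name) from None
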