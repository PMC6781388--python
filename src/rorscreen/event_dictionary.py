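"""Grouping of MedDRA Preferred Terms into named events of interest.

Adverse events in spontaneous-report databases are coded at the MedDRA
Preferred Term (PT) level; screening usually targets broader clinically
meaningful classes (e.g. "Pneumonia" as a family of pneumonia PTs).  An
:class:`EventDictionary` maps PT strings to class names by exact-string
matching after whitespace trimming and case-folding — no MedDRA codes or
hierarchy traversal, so no licensed ontology is required.  The packaged
default dictionary covers five infection-related classes relevant to
anti-TNF biologic surveillance: infection, interstitial lung disease,
pneumonia, sepsis, and tuberculosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "EventDefinition",
    "EventDictionary",
    "load_default_dictionary",
    "load_dictionary",
    "classify_pt",
    "normalize_pt",
]


def normalize_pt(pt: str) -> str:
    """Normalise a Preferred Term for matching: collapse whitespace, casefold."""
    return " ".join(pt.split()).casefold()


@dataclass(frozen=True)
class EventDefinition:
    """A named event class defined by a set of MedDRA Preferred Terms."""

    class_name: str
    preferred_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.class_name:
            raise ValueError("class_name must be non-empty")
        if not self.preferred_terms:
            raise ValueError(f"class {self.class_name!r} has no preferred terms")
        object.__setattr__(self, "preferred_terms", frozenset(self.preferred_terms))


class EventDictionary:
    """A disjoint collection of event classes with PT lookup.

    No Preferred Term may belong to two classes (classification must be
    unambiguous); violating dictionaries are rejected at construction,
    naming the offending term.
    """

    def __init__(self, definitions: Iterable[EventDefinition]) -> None:
        self._definitions: tuple[EventDefinition, ...] = tuple(definitions)
        lookup: dict[str, str] = {}
        for definition in self._definitions:
            for pt in sorted(definition.preferred_terms):
                key = normalize_pt(pt)
                if key in lookup and lookup[key] != definition.class_name:
                    raise ValueError(
                        f"preferred term {pt!r} belongs to both "
                        f"{lookup[key]!r} and {definition.class_name!r}"
                    )
                lookup[key] = definition.class_name
        self._lookup = lookup

    @property
    def definitions(self) -> tuple[EventDefinition, ...]:
        return self._definitions

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(d.class_name for d in self._definitions)

    def __len__(self) -> int:
        return len(self._definitions)

    def __iter__(self) -> Iterator[EventDefinition]:
        return iter(self._definitions)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self._lookup

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventDictionary):
            return NotImplemented
        return set(self._definitions) == set(other._definitions)

    def __getitem__(self, class_name: str) -> EventDefinition:
        for definition in self._definitions:
            if definition.class_name == class_name:
                return definition
        raise KeyError(class_name)

    def classify(self, pt: str) -> str | None:
        """Return the unique class containing ``pt``, or ``None``."""
        return self._lookup.get(normalize_pt(pt))

    def lookup_table(self) -> Mapping[str, str]:
        """Normalised-PT → class-name mapping (for vectorised joins)."""
        return dict(self._lookup)


def _from_mapping(mapping: Mapping[str, Iterable[str]]) -> EventDictionary:
    definitions = [
        EventDefinition(
            class_name=str(name).strip(),
            preferred_terms=frozenset(" ".join(str(pt).split()) for pt in pts),
        )
        for name, pts in mapping.items()
    ]
    return EventDictionary(definitions)


def load_dictionary(config: str | Path | Mapping[str, Iterable[str]]) -> EventDictionary:
    """Load an event dictionary from a YAML file or an in-memory mapping.

    The config is a mapping from class name to a list of Preferred Terms.
    An empty mapping yields an empty (valid) dictionary; a PT appearing in
    two classes is a validation error.
    """
    if isinstance(config, Mapping):
        return _from_mapping(config)
    with open(config, encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"dictionary config {config} must map class -> PT list")
    return _from_mapping(data)


def load_default_dictionary() -> EventDictionary:
    """The packaged five-class infection-of-interest dictionary."""
    source = resources.files("rorscreen.data").joinpath("infection_events.yaml")
    data = yaml.safe_load(source.read_text(encoding="utf-8"))
    return _from_mapping(data)


def classify_pt(pt: str, dictionary: EventDictionary) -> str | None:
    """Map a Preferred Term to its event class, or ``None`` if unlisted."""
    return dictionary.classify(pt)
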