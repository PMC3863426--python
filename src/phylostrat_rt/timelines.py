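"""Phylostratum timelines: ordered age classes along a focal species' lineage.

A timeline is the ordered list of ancestral taxa (oldest first) used to bin
gene-duplication events into discrete evolutionary age classes
("phylostrata").  Index 1 is the oldest class and the youngest class is the
focal species itself.  Taxa that reconciliation software reports at levels
deliberately excluded from the timeline (e.g. Euarchontoglires, collapsed
onto Eutheria) are handled through ``collapse_aliases``.

Two timelines ship with the package: ``human`` (14 classes, Bilateria ->
Homo sapiens) and ``mouse`` (13 classes, Bilateria -> Mus musculus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

from .errors import ConfigurationError

__all__ = [
    "PhylostratumTimeline",
    "load_timeline",
    "get_timeline",
    "BUILTIN_TIMELINES",
]

BUILTIN_TIMELINES = {
    "human": "human_v1.yaml",
    "human_v1": "human_v1.yaml",
    "mouse": "mouse_v1.yaml",
    "mouse_v1": "mouse_v1.yaml",
}


@dataclass(frozen=True)
class PhylostratumTimeline:
    """An ordered set of age classes for one focal species.

    Parameters
    ----------
    name:
        Identifier for the timeline (e.g. ``human_v1``).
    classes:
        Taxon labels ordered oldest -> youngest.  The 1-based position of a
        label is its phylostratum index; the last label must be the focal
        species.
    collapse_aliases:
        Mapping from out-of-timeline taxon labels to the class they are
        collapsed onto before lookup.
    focal_species:
        Taxon label of the species whose genes are dated.
    """

    name: str
    classes: tuple[str, ...]
    collapse_aliases: Mapping[str, str] = field(default_factory=dict)
    focal_species: str = ""

    def __post_init__(self):
        if not self.classes:
            raise ConfigurationError("timeline has no classes")
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError("timeline class labels must be unique")
        object.__setattr__(self, "classes", tuple(self.classes))
        focal = self.focal_species or self.classes[-1]
        object.__setattr__(self, "focal_species", focal)
        if focal != self.classes[-1]:
            raise ConfigurationError(
                f"focal species {focal!r} must equal the youngest class "
                f"{self.classes[-1]!r}"
            )
        for alias, target in self.collapse_aliases.items():
            if target not in self.classes:
                raise ConfigurationError(
                    f"collapse alias {alias!r} -> {target!r} does not map to a "
                    "timeline class"
                )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index_of(self, label: str) -> int:
        """1-based phylostratum index of a class label (1 = oldest)."""
        return self.classes.index(label) + 1

    def label_of(self, index: int) -> str:
        if not 1 <= index <= len(self.classes):
            raise ConfigurationError(f"phylostratum index {index} out of range")
        return self.classes[index - 1]


def load_timeline(path: Union[str, Path]) -> PhylostratumTimeline:
    """Load a timeline from a YAML file (keys: name, classes, focal_species,
    collapse_aliases)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _timeline_from_doc(doc)


def get_timeline(name: str) -> PhylostratumTimeline:
    """Return a built-in timeline (``human`` or ``mouse``), or load from a
    path if *name* is not a built-in."""
    if name in BUILTIN_TIMELINES:
        ref = resources.files("phylostrat_rt.data") / BUILTIN_TIMELINES[name]
        doc = yaml.safe_load(ref.read_text())
        return _timeline_from_doc(doc)
    if Path(name).exists():
        return load_timeline(name)
    raise ConfigurationError(
        f"unknown timeline {name!r}; built-ins: {sorted(set(BUILTIN_TIMELINES))}"
    )


def _timeline_from_doc(doc: dict) -> PhylostratumTimeline:
    try:
        classes: Sequence[str] = doc["classes"]
    except (KeyError, TypeError):
        raise ConfigurationError("timeline document must define 'classes'")
    return PhylostratumTimeline(
        name=doc.get("name", "unnamed"),
        classes=tuple(classes),
        collapse_aliases=dict(doc.get("collapse_aliases") or {}),
        focal_species=doc.get("focal_species", ""),
    )
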