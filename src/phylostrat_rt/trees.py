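"""Gene-family trees and duplication-age assignment (phylostratification).

Trees arrive as Newick text with NHX comments carrying three tags:

* ``D=Y|N`` — whether the internal node is a duplication (Y) or speciation (N);
* ``S=<taxon>`` — the taxon label the reconciliation assigned to the node
  (or, on a leaf, the species the gene belongs to);
* ``DCS=<float>`` — the duplication-consistency score in [0, 1], required on
  every duplication node.

A focal-species gene is dated by walking from its leaf toward the root and
inspecting duplication nodes in order:

* score strictly above the threshold (default 0.3): accept — the gene is a
  protein-coding duplicated gene (PDG) with the age class of that node's
  taxon;
* score exactly 0: the duplication is treated as a reconstruction artifact —
  skip it and keep walking toward the root;
* score in (0, threshold]: the call is unclear — the gene is UNASSIGNED;
* no acceptable duplication on the whole root path: the gene is a SINGLETON.

An accepted node whose taxon predates the oldest timeline class (e.g. a
pre-metazoan duplication) also yields SINGLETON: the gene has no duplication
origin *within the analyzed era*.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Union

import dendropy
import pandas as pd

from .errors import DataError, GeneTreeParseError
from .timelines import PhylostratumTimeline

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "AgeStatus",
    "AgeAssignment",
    "OUT_OF_TIMELINE",
    "parse_gene_tree",
    "write_gene_tree",
    "map_taxon_to_class",
    "assign_duplication_age",
    "assignments_to_frame",
]

_KNOWN_TAGS = {"D", "S", "DCS"}


class _OutOfTimeline:
    """Sentinel for taxa that cannot be placed on the timeline."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "OUT_OF_TIMELINE"


OUT_OF_TIMELINE = _OutOfTimeline()


@dataclass
class GeneTreeNode:
    """One node of a gene-family tree.

    Internal nodes carry an event type (``duplication``/``speciation``), a
    taxon label and, for duplications, a consistency score.  Leaves carry a
    gene id and optionally a species label (from an ``S`` tag).
    """

    node_id: str
    event: Optional[str] = None  # 'duplication' | 'speciation' | None (leaf)
    taxon: Optional[str] = None
    score: Optional[float] = None
    gene_id: Optional[str] = None
    species: Optional[str] = None
    children: list["GeneTreeNode"] = field(default_factory=list)
    parent: Optional["GeneTreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "GeneTreeNode") -> "GeneTreeNode":
        child.parent = self
        self.children.append(child)
        return child


@dataclass
class GeneTree:
    """A rooted, annotated gene-family tree."""

    root: GeneTreeNode
    family_id: Optional[str] = None

    def __iter__(self) -> Iterator[GeneTreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[GeneTreeNode]:
        return [n for n in self if n.is_leaf]

    def focal_leaves(self, focal_species: Optional[str] = None) -> list[GeneTreeNode]:
        """Leaves belonging to the focal species.

        Leaves without a species annotation are treated as focal, which lets
        bare Newick trees (no leaf S tags) be dated directly.
        """
        out = []
        for leaf in self.leaves():
            if leaf.species is None or focal_species is None or leaf.species == focal_species:
                out.append(leaf)
        return out


class AgeStatus(str, Enum):
    PDG = "PDG"
    SINGLETON = "SINGLETON"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class AgeAssignment:
    """Duplication-age call for one focal-species gene."""

    gene_id: str
    status: AgeStatus
    age_class: Optional[int] = None  # 1-based phylostratum index (1 = oldest)
    age_label: Optional[str] = None
    evidence_node: Optional[str] = None


def _parse_nhx_comment(comment: str, node_id: str) -> dict:
    body = comment.strip()
    if body.startswith("&&NHX"):
        body = body[len("&&NHX"):]
    tags = {}
    for part in body.split(":"):
        if not part:
            continue
        if "=" not in part:
            raise GeneTreeParseError(
                f"node {node_id}: malformed NHX tag {part!r} in comment {comment!r}"
            )
        key, value = part.split("=", 1)
        if key not in _KNOWN_TAGS:
            logger.warning("node %s: ignoring unknown NHX tag %s=%s", node_id, key, value)
            continue
        tags[key] = value
    return tags


def parse_gene_tree(nhx_text: str, family_id: Optional[str] = None) -> GeneTree:
    """Parse one NHX gene-family tree from text.

    Raises :class:`GeneTreeParseError` for unbalanced parentheses, an NHX
    comment lacking the ``S`` tag on an internal node, or a ``DCS`` outside
    [0, 1].  Internal nodes with no NHX comment at all are accepted as
    unannotated speciation nodes (a bare Newick tree is a valid, if
    uninformative, gene tree).
    """
    try:
        dtree = dendropy.Tree.get(
            data=nhx_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise GeneTreeParseError(f"invalid Newick/NHX text: {exc}") from exc

    counter = [0]

    def convert(dnode) -> GeneTreeNode:
        counter[0] += 1
        is_leaf = len(dnode.child_nodes()) == 0
        if is_leaf and dnode.taxon is not None:
            node_id = dnode.taxon.label
        else:
            node_id = f"n{counter[0]}"
        node = GeneTreeNode(node_id=node_id)
        comments = [c for c in dnode.comments if c.strip().startswith("&&NHX")]
        tags = _parse_nhx_comment(comments[0], node_id) if comments else {}
        if is_leaf:
            if dnode.taxon is None:
                raise GeneTreeParseError(f"node {node_id}: leaf without a name")
            node.gene_id = dnode.taxon.label
            node.species = tags.get("S")
        else:
            if tags and "S" not in tags:
                raise GeneTreeParseError(
                    f"node {node_id}: internal node NHX comment missing S tag"
                )
            node.taxon = tags.get("S")
            node.event = "duplication" if tags.get("D") == "Y" else "speciation"
            if "DCS" in tags:
                try:
                    score = float(tags["DCS"])
                except ValueError:
                    raise GeneTreeParseError(
                        f"node {node_id}: DCS {tags['DCS']!r} is not a number"
                    )
                if not 0.0 <= score <= 1.0:
                    raise GeneTreeParseError(
                        f"node {node_id}: DCS {score} outside [0, 1]"
                    )
                node.score = score
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    return GeneTree(root=root, family_id=family_id)


def write_gene_tree(tree: GeneTree) -> str:
    """Serialize a gene tree back to one-line NHX text."""

    def fmt(node: GeneTreeNode) -> str:
        if node.is_leaf:
            out = node.gene_id or node.node_id
            if node.species is not None:
                out += f"[&&NHX:S={node.species}]"
            return out + ":1"
        inner = ",".join(fmt(c) for c in node.children)
        tags = []
        if node.taxon is not None:
            tags.append(f"D={'Y' if node.event == 'duplication' else 'N'}")
            tags.append(f"S={node.taxon}")
            if node.score is not None:
                tags.append(f"DCS={node.score!r}")
        comment = f"[&&NHX:{':'.join(tags)}]" if tags else ""
        return f"({inner}){comment}:1"

    body = fmt(tree.root)
    # the root carries no branch length
    if body.endswith(":1"):
        body = body[:-2]
    return body + ";"


def map_taxon_to_class(
    taxon: str, timeline: PhylostratumTimeline
) -> Union[int, _OutOfTimeline]:
    """Resolve a taxon label to its 1-based phylostratum index.

    Collapse aliases are applied first; any label absent from the timeline
    (including taxa older than its oldest class) maps to
    :data:`OUT_OF_TIMELINE`.  Total function: never raises.
    """
    label = timeline.collapse_aliases.get(taxon, taxon)
    try:
        return timeline.index_of(label)
    except ValueError:
        return OUT_OF_TIMELINE


def _root_path_duplications(leaf: GeneTreeNode) -> Iterator[GeneTreeNode]:
    node = leaf.parent
    while node is not None:
        if node.event == "duplication":
            yield node
        node = node.parent


def assign_duplication_age(
    tree: GeneTree,
    timeline: PhylostratumTimeline,
    score_threshold: float = 0.3,
) -> list[AgeAssignment]:
    """Date every focal-species leaf of *tree* (see module docstring for the
    rules).  Returns one :class:`AgeAssignment` per focal leaf."""
    assignments = []
    for leaf in tree.focal_leaves(timeline.focal_species):
        status = AgeStatus.SINGLETON
        age_class = age_label = evidence = None
        for dup in _root_path_duplications(leaf):
            if dup.score is None:
                raise DataError(
                    f"duplication node {dup.node_id} has no consistency score"
                )
            if dup.score == 0.0:
                continue  # artifact: age comes from the previous node on the path
            if dup.score > score_threshold:
                idx = map_taxon_to_class(dup.taxon, timeline)
                if idx is OUT_OF_TIMELINE:
                    status = AgeStatus.SINGLETON  # duplicated before the analyzed era
                else:
                    status = AgeStatus.PDG
                    age_class = idx
                    age_label = timeline.label_of(idx)
                    evidence = dup.node_id
            else:
                status = AgeStatus.UNASSIGNED
            break
        assignments.append(
            AgeAssignment(
                gene_id=leaf.gene_id,
                status=status,
                age_class=age_class,
                age_label=age_label,
                evidence_node=evidence,
            )
        )
    return assignments


def assignments_to_frame(assignments: list[AgeAssignment]) -> pd.DataFrame:
    """Tabulate assignments as a DataFrame (one row per gene)."""
    frame = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "status": [a.status.value for a in assignments],
            "age_class_label": [a.age_label for a in assignments],
            "age_class_index": pd.array(
                [a.age_class for a in assignments], dtype="Int64"
            ),
            "evidence_node": [a.evidence_node for a in assignments],
        }
    )
    dup = frame["gene_id"].duplicated()
    if dup.any():
        raise DataError(
            f"gene(s) present in multiple trees: {sorted(frame.loc[dup, 'gene_id'])[:5]}"
        )
    return frame


def read_tree_file(path) -> GeneTree:
    with io.open(path) as fh:
        return parse_gene_tree(fh.read(), family_id=str(path))
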