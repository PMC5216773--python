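"""MeSH descriptor parsing and disease DAG construction.

MeSH (Medical Subject Headings) ships an ASCII descriptor format made of
``*NEWRECORD`` blocks of ``KEY = value`` lines.  The fields used here are

* ``MH`` -- the descriptor heading (the disease name),
* ``UI`` -- the unique descriptor identifier,
* ``MN`` -- one tree number per line, a dotted code such as ``C04.557.337``
  that encodes the descriptor's position in the hierarchy.

Category C of MeSH covers diseases.  A disease's DAG is its own descriptor
plus every descriptor owning a proper dotted prefix of any of its tree
numbers, with edges from the more general term (parent) to the more
specific term (child).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Grammar of a MeSH tree number: a letter, then dot-separated digit groups.
TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")


@dataclass(frozen=True)
class MeshDescriptor:
    """A single MeSH descriptor restricted to one category."""

    heading: str
    unique_id: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tree_numbers:
            raise ValueError(f"descriptor {self.heading!r} has no tree numbers")
        for tn in self.tree_numbers:
            if not TREE_NUMBER_RE.match(tn):
                raise ValueError(f"malformed tree number {tn!r} on {self.heading!r}")


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease's MeSH term set: the descriptor plus all its ancestors.

    ``edges`` are (parent heading, child heading) pairs pointing from the
    more general to the more specific term.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]


@dataclass
class DiseaseNameMap:
    """Outcome of reconciling free-text disease names with MeSH headings."""

    mapping: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).lower()


def parse_mesh_ascii(path, category_prefix: str = "C") -> list[MeshDescriptor]:
    """Parse a MeSH ASCII descriptor file, keeping one category.

    Only descriptors with at least one tree number starting with
    ``category_prefix`` are returned, and tree numbers outside the category
    are dropped from those that are.  A record whose MN line violates the
    dotted-segment grammar is skipped with a warning rather than aborting
    the whole parse.
    """
    descriptors: list[MeshDescriptor] = []
    record: dict | None = None

    def flush(rec: dict | None) -> None:
        if not rec or "MH" not in rec:
            return
        if rec.get("_malformed"):
            logger.warning("skipping record %r: malformed MN line", rec.get("MH"))
            return
        kept = tuple(tn for tn in rec.get("MN", []) if tn.startswith(category_prefix))
        if not kept:
            return
        descriptors.append(
            MeshDescriptor(
                heading=rec["MH"],
                unique_id=rec.get("UI", rec["MH"]),
                tree_numbers=kept,
            )
        )

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.strip() == "*NEWRECORD":
                flush(record)
                record = {"MN": []}
                continue
            if record is None or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "MH":
                record["MH"] = value
            elif key == "UI":
                record["UI"] = value
            elif key == "MN":
                if TREE_NUMBER_RE.match(value):
                    record["MN"].append(value)
                else:
                    record["_malformed"] = True
        flush(record)

    seen: dict[str, str] = {}
    for d in descriptors:
        if d.unique_id in seen:
            raise ValueError(f"duplicate unique id {d.unique_id!r} in {path}")
        seen[d.unique_id] = d.heading
    return descriptors


def _tree_number_index(descriptors) -> dict[str, str]:
    """Map every tree number to the heading that owns it."""
    index: dict[str, str] = {}
    for d in descriptors:
        for tn in d.tree_numbers:
            index[tn] = d.heading
    return index


def _proper_prefixes(tree_number: str) -> list[str]:
    """Dotted prefixes of a tree number, shortest first, excluding itself."""
    parts = tree_number.split(".")
    return [".".join(parts[:i]) for i in range(1, len(parts))]


def build_disease_dag(
    descriptor: MeshDescriptor,
    all_descriptors,
    _index: dict[str, str] | None = None,
) -> DiseaseDAG:
    """Build the ancestor DAG of one descriptor.

    Nodes are the descriptor's heading plus the headings owning any proper
    dotted prefix of any of its tree numbers.  Each edge connects a prefix's
    owner to the owner of its one-segment extension; when an intermediate
    prefix has no descriptor record the level is skipped and the child is
    connected to the nearest resolvable ancestor.
    """
    index = _index if _index is not None else _tree_number_index(all_descriptors)
    for tn in descriptor.tree_numbers:
        if index.get(tn) != descriptor.heading:
            raise ValueError(
                f"descriptor {descriptor.heading!r} not present in the descriptor set"
            )

    nodes: set[str] = {descriptor.heading}
    edges: set[tuple[str, str]] = set()
    for tn in descriptor.tree_numbers:
        chain = _proper_prefixes(tn) + [tn]
        last_resolved: str | None = None
        for prefix in chain:
            owner = index.get(prefix)
            if owner is None:
                logger.warning(
                    "no descriptor owns tree number %s (ancestor of %s); skipping level",
                    prefix,
                    descriptor.heading,
                )
                continue
            nodes.add(owner)
            if last_resolved is not None and last_resolved != owner:
                edges.add((last_resolved, owner))
            last_resolved = owner
    return DiseaseDAG(
        disease_id=descriptor.heading,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
    )


def build_all_dags(descriptors) -> dict[str, DiseaseDAG]:
    """Build the DAG of every descriptor, keyed by heading."""
    index = _tree_number_index(descriptors)
    return {
        d.heading: build_disease_dag(d, descriptors, _index=index)
        for d in descriptors
    }


def map_disease_names(raw_names, descriptors) -> DiseaseNameMap:
    """Match free-text disease names against MeSH headings.

    Matching is exact after trimming, collapsing internal whitespace and
    lower-casing; no fuzzy matching is attempted, so near-synonyms (e.g.
    "lung cancer" vs the heading "Lung Neoplasms") land in ``unmapped`` for
    the caller to surface rather than being silently guessed.
    """
    by_norm = {_normalize_name(d.heading): d.heading for d in descriptors}
    out = DiseaseNameMap()
    for raw in raw_names:
        if not raw or not raw.strip():
            raise ValueError("empty disease name")
        hit = by_norm.get(_normalize_name(raw))
        if hit is None:
            out.unmapped.append(raw)
        else:
            out.mapping[raw] = hit
    return out
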