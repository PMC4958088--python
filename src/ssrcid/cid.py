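"""The cultivar identification diagram (CID).

A CID is a decision tree over an ordered panel of SSR markers.  The root
splits all cultivars into groups by their genotype at the first marker; a
cultivar alone in its group is identified and becomes a resolved leaf; every
group still holding several cultivars is split again by the next marker in
the fixed global order.  Groups whose members share the genotype at *every*
panel marker end as flagged unresolved leaves — the signal that the panel
needs another marker, not an error.

Reading the diagram answers, for any cultivar, exactly which markers must be
assayed to tell it apart from the rest of the panel — usually far fewer than
the whole panel.  The marker order convention is descending per-locus PID,
so identification starts from the coarsest split and refines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

from .genotypes import (
    CultivarRecord,
    GenotypeCall,
    GenotypeTable,
    format_genotype_string,
    parse_genotype_string,
)

__all__ = [
    "CIDNode",
    "CID",
    "IdentificationResult",
    "MarkerNeededError",
    "build_cid",
    "identify",
    "add_cultivar",
    "cid_report",
    "render_cid",
    "cid_from_json",
]


class MarkerNeededError(KeyError):
    """Identification halted: the sample lacks a genotype the path requires."""

    def __init__(self, marker: str):
        super().__init__(marker)
        self.marker = marker

    def __str__(self) -> str:
        return f"need marker {self.marker} to continue identification"


@dataclass
class CIDNode:
    """One node of the diagram.

    Internal nodes carry ``marker`` and ``branches`` (genotype -> child);
    leaves carry ``cultivars``.  A leaf is *resolved* when it holds exactly
    one cultivar.
    """

    marker: str | None = None
    branches: dict[GenotypeCall, "CIDNode"] = field(default_factory=dict)
    cultivars: tuple[int, ...] = ()

    @property
    def kind(self) -> str:
        return "internal" if self.marker is not None else "leaf"

    @property
    def is_leaf(self) -> bool:
        return self.marker is None

    @property
    def resolved(self) -> bool:
        return self.is_leaf and len(self.cultivars) == 1

    def leaf_iter(self) -> Iterator["CIDNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.branches.values():
                yield from child.leaf_iter()

    def member_codes(self) -> tuple[int, ...]:
        """All cultivar codes below this node."""
        if self.is_leaf:
            return self.cultivars
        out: list[int] = []
        for child in self.branches.values():
            out.extend(child.member_codes())
        return tuple(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CIDNode):
            return NotImplemented
        return (
            self.marker == other.marker
            and self.branches == other.branches
            and tuple(sorted(self.cultivars)) == tuple(sorted(other.cultivars))
        )


@dataclass
class CID:
    """A built diagram: the root node plus the global marker order it follows."""

    root: CIDNode
    marker_order: tuple[str, ...]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CID):
            return NotImplemented
        return self.marker_order == other.marker_order and self.root == other.root


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of traversing the diagram with a sample's genotypes.

    ``outcome`` is ``"unique"`` (one cultivar), ``"ambiguous"`` (an unresolved
    leaf was reached) or ``"no_match"`` (the sample's genotype matched no
    branch at some node).  ``path`` lists the (marker, genotype) pairs
    consumed, in order.
    """

    outcome: str
    cultivar: int | None
    candidates: tuple[int, ...]
    path: tuple[tuple[str, GenotypeCall], ...]


def _build_node(
    codes: Sequence[int],
    order: Sequence[str],
    depth: int,
    lookup: Callable[[int, str], GenotypeCall],
) -> CIDNode:
    if len(codes) == 1:
        return CIDNode(cultivars=tuple(codes))
    if depth == len(order):
        return CIDNode(cultivars=tuple(codes))  # unresolved: panel exhausted
    marker = order[depth]
    groups: dict[GenotypeCall, list[int]] = {}
    for code in codes:
        groups.setdefault(lookup(code, marker), []).append(code)
    branches = {
        g: _build_node(members, order, depth + 1, lookup)
        for g, members in sorted(groups.items(), key=lambda kv: format_genotype_string(kv[0]))
    }
    return CIDNode(marker=marker, branches=branches)


def build_cid(table: GenotypeTable, marker_order: Sequence[str] | None = None) -> CID:
    """Build the diagram for ``table`` under a fixed global marker order.

    ``marker_order`` defaults to the table's marker order.  Branches are kept
    in genotype-string ascending order so serialisation is deterministic.
    """
    order = tuple(marker_order) if marker_order is not None else tuple(table.markers)
    if not order:
        raise ValueError("marker_order must be non-empty")
    for m in order:
        if m not in table.markers:
            raise KeyError(f"marker {m!r} absent from table")
    root = _build_node(table.codes, order, 0, lambda c, m: table.calls[(c, m)])
    return CID(root=root, marker_order=order)


def identify(
    cid: CID, sample: Mapping[str, GenotypeCall | str]
) -> IdentificationResult:
    """Traverse the diagram with a sample's (possibly partial) genotypes.

    Only the markers actually on the traversed path are required; supplying
    fewer markers than the panel is the normal, economical case.  A missing
    required marker raises :class:`MarkerNeededError` naming it.
    """
    genotypes = {
        m: (g if isinstance(g, GenotypeCall) else parse_genotype_string(g))
        for m, g in sample.items()
    }
    node = cid.root
    path: list[tuple[str, GenotypeCall]] = []
    while not node.is_leaf:
        marker = node.marker
        if marker not in genotypes:
            raise MarkerNeededError(marker)
        g = genotypes[marker]
        path.append((marker, g))
        child = node.branches.get(g)
        if child is None:
            return IdentificationResult("no_match", None, (), tuple(path))
        node = child
    if node.resolved:
        return IdentificationResult("unique", node.cultivars[0], node.cultivars, tuple(path))
    return IdentificationResult("ambiguous", None, node.cultivars, tuple(path))


def add_cultivar(
    cid: CID,
    table: GenotypeTable,
    record: CultivarRecord,
    genotypes: Mapping[str, GenotypeCall | str],
) -> tuple[CID, GenotypeTable]:
    """Insert a newly released cultivar into an existing diagram.

    The cultivar is routed down by its genotypes; a resolved leaf it collides
    with is re-split by the next unused markers, and if the panel is exhausted
    without separation the leaf becomes a flagged unresolved group.  Returns
    the updated diagram together with the extended genotype table; the result
    is identical to rebuilding from scratch on that table.
    """
    extended = table.with_cultivar(record, genotypes)

    def lookup(code: int, marker: str) -> GenotypeCall:
        return extended.calls[(code, marker)]

    def insert(node: CIDNode, depth: int) -> CIDNode:
        if node.is_leaf:
            members = tuple(node.cultivars) + (record.code,)
            return _build_node(members, cid.marker_order, depth, lookup)
        marker = node.marker
        g = lookup(record.code, marker)
        branches = dict(node.branches)
        child = branches.get(g)
        if child is None:
            branches[g] = CIDNode(cultivars=(record.code,))
        else:
            branches[g] = insert(child, depth + 1)
        ordered = dict(
            sorted(branches.items(), key=lambda kv: format_genotype_string(kv[0]))
        )
        return CIDNode(marker=marker, branches=ordered)

    new_root = insert(cid.root, 0)
    return CID(root=new_root, marker_order=cid.marker_order), extended


def _paths(node: CIDNode, prefix: tuple[str, ...]) -> Iterator[tuple[CIDNode, tuple[str, ...]]]:
    if node.is_leaf:
        yield node, prefix
    else:
        for child in node.branches.values():
            yield from _paths(child, prefix + (node.marker,))


def cid_report(cid: CID) -> dict:
    """Summary of the diagram: per-cultivar paths, level widths, unresolved sets.

    ``markers_needed[code]`` lists the markers that must be assayed to reach
    the cultivar's leaf; its length is the identification depth.
    """
    markers_needed: dict[int, list[str]] = {}
    unresolved: list[tuple[int, ...]] = []
    n_resolved = 0
    for leaf, prefix in _paths(cid.root, ()):
        if leaf.resolved:
            n_resolved += 1
        else:
            unresolved.append(tuple(sorted(leaf.cultivars)))
        for code in leaf.cultivars:
            markers_needed[code] = list(prefix)
    groups_per_level: dict[int, int] = {}

    def count(node: CIDNode, depth: int) -> None:
        if node.is_leaf:
            return
        groups_per_level[depth] = groups_per_level.get(depth, 0) + len(node.branches)
        for child in node.branches.values():
            count(child, depth + 1)

    count(cid.root, 0)
    return {
        "n_cultivars": len(markers_needed),
        "n_resolved": n_resolved,
        "n_unresolved_groups": len(unresolved),
        "unresolved": unresolved,
        "markers_needed": markers_needed,
        "path_length": {c: len(p) for c, p in markers_needed.items()},
        "groups_per_level": groups_per_level,
    }


def _node_to_jsonable(node: CIDNode) -> dict:
    if node.is_leaf:
        return {"kind": "leaf", "cultivars": list(node.cultivars), "resolved": node.resolved}
    return {
        "kind": "internal",
        "marker": node.marker,
        "branches": {
            format_genotype_string(g): _node_to_jsonable(child)
            for g, child in sorted(
                node.branches.items(), key=lambda kv: format_genotype_string(kv[0])
            )
        },
    }


def _node_from_jsonable(obj: dict) -> CIDNode:
    if obj["kind"] == "leaf":
        return CIDNode(cultivars=tuple(obj["cultivars"]))
    return CIDNode(
        marker=obj["marker"],
        branches={
            parse_genotype_string(g): _node_from_jsonable(child)
            for g, child in obj["branches"].items()
        },
    )


def render_cid(cid: CID, format: str = "text") -> str:
    """Serialise the diagram as nested text, Graphviz DOT, or round-trippable JSON."""
    if format == "json":
        return json.dumps(
            {"marker_order": list(cid.marker_order), "root": _node_to_jsonable(cid.root)},
            indent=2,
        )
    if format == "dot":
        lines = ["digraph CID {", "  node [shape=box];"]
        counter = [0]

        def emit(node: CIDNode) -> str:
            name = f"n{counter[0]}"
            counter[0] += 1
            if node.is_leaf:
                label = ",".join(str(c) for c in node.cultivars)
                flag = "" if node.resolved else " (unresolved)"
                lines.append(f'  {name} [label="{label}{flag}", shape=ellipse];')
            else:
                lines.append(f'  {name} [label="{node.marker}"];')
                for g, child in sorted(
                    node.branches.items(), key=lambda kv: format_genotype_string(kv[0])
                ):
                    cname = emit(child)
                    lines.append(f'  {name} -> {cname} [label="{format_genotype_string(g)}"];')
            return name

        emit(cid.root)
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "text":
        lines = []

        def walk(node: CIDNode, indent: int, edge: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                label = ", ".join(str(c) for c in node.cultivars)
                flag = "" if node.resolved else "  [unresolved]"
                lines.append(f"{pad}{edge}-> {label}{flag}")
            else:
                lines.append(f"{pad}{edge}{node.marker}:")
                for g, child in sorted(
                    node.branches.items(), key=lambda kv: format_genotype_string(kv[0])
                ):
                    walk(child, indent + 1, f"{format_genotype_string(g)} ")

        walk(cid.root, 0, "")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}; use 'text', 'dot' or 'json'")


def cid_from_json(text: str) -> CID:
    """Inverse of ``render_cid(..., format='json')``."""
    obj = json.loads(text)
    return CID(root=_node_from_jsonable(obj["root"]), marker_order=tuple(obj["marker_order"]))
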