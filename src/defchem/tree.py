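"""Rooted time-calibrated phylogenies and per-node annotation tables.

The tree model is deliberately small: a rooted tree with branch lengths in
millions of years (Ma), unique tip labels, and stable integer node ids
assigned by post-order traversal so that annotation tables written in one
run can be joined against trees re-read in another.  Multifurcations are
retained as-is; likelihood code downstream handles them natively.

Parsing of Newick and NEXUS files is delegated to :mod:`dendropy`; the
parsed tree is converted into the package's own structure and validated
(mandatory branch lengths, non-negative lengths, unique non-empty tip
labels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import dendropy
import pandas as pd

from defchem.errors import TreeFormatError, ValidationError

__all__ = [
    "Node",
    "Phylogeny",
    "read_tree",
    "tree_from_string",
    "write_tree",
    "is_ultrametric",
    "write_annotated_tree",
    "read_annotated_tree",
    "write_node_table",
    "read_node_table",
]


@dataclass(eq=False)
class Node:
    """A node in a rooted phylogeny.

    ``length`` is the branch length to the parent in Ma; it is ``None`` only
    for the root.  ``id`` is assigned by the owning :class:`Phylogeny` in
    post-order and is stable for a fixed topology and child order.
    """

    label: Optional[str] = None
    length: Optional[float] = None
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)
    id: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {self.id} {kind} label={self.label!r} length={self.length}>"


class Phylogeny:
    """A validated rooted tree with post-order node ids.

    Construct from a root :class:`Node` whose descendants are fully linked;
    the constructor assigns ids 0..n-1 in post-order (children visited in
    their stored order) and enforces the structural invariants.
    """

    def __init__(self, root: Node, *, default_branch_length: Optional[float] = None):
        self.root = root
        self._nodes: list[Node] = []
        self._validate_and_index(default_branch_length)

    # -- construction -----------------------------------------------------

    def _validate_and_index(self, default_branch_length: Optional[float]) -> None:
        seen: set[int] = set()
        order: list[Node] = []
        # iterative post-order; also detects cycles/reuse
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                raise ValidationError("node appears more than once; tree is not acyclic")
            seen.add(id(node))
            stack.append((node, True))
            for child in reversed(node.children):
                if child.parent is not node:
                    raise ValidationError("child/parent links inconsistent")
                stack.append((child, False))
        if self.root.parent is not None:
            raise ValidationError("root must not have a parent")

        labels: dict[str, Node] = {}
        for i, node in enumerate(order):
            node.id = i
            if node is not self.root:
                if node.length is None:
                    if default_branch_length is None:
                        raise ValidationError(
                            f"missing branch length on node {node.label or '<internal>'} "
                            "(supply default_branch_length to accept)"
                        )
                    node.length = default_branch_length
                if node.length < 0:
                    raise ValidationError(
                        f"negative branch length {node.length} on node "
                        f"{node.label or '<internal>'}"
                    )
            if node.is_tip:
                if not node.label:
                    raise ValidationError("tip with empty label")
                if node.label in labels:
                    raise ValidationError(f"duplicate tip label {node.label!r}")
                labels[node.label] = node
        self._nodes = order
        self._tip_index = labels

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def nodes(self) -> list[Node]:
        """All nodes in post-order (ids equal list positions)."""
        return self._nodes

    @property
    def tips(self) -> list[Node]:
        return [n for n in self._nodes if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self._nodes if not n.is_tip]

    def tip(self, label: str) -> Node:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"no tip labelled {label!r}") from None

    def postorder(self) -> Iterator[Node]:
        return iter(self._nodes)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def depths(self) -> dict[int, float]:
        """Distance from the root to every node, keyed by node id."""
        out = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node.id] = out[node.parent.id] + node.length
        return out

    def max_depth(self) -> float:
        d = self.depths()
        return max(d[t.id] for t in self.tips)

    # -- mutation-free transforms -----------------------------------------

    def rescaled(self, factor: float) -> "Phylogeny":
        """A copy with every branch length multiplied by ``factor``."""
        if factor < 0:
            raise ValidationError("rescale factor must be nonnegative")
        clone = tree_from_string(self.to_newick())
        for node in clone.nodes:
            if node.length is not None:
                node.length *= factor
        return clone

    def rescaled_to_depth(self, target: float) -> "Phylogeny":
        """A copy rescaled so the maximum root-to-tip distance equals ``target``."""
        depth = self.max_depth()
        if depth <= 0:
            raise ValidationError("tree has zero depth; cannot rescale")
        return self.rescaled(target / depth)

    # -- serialization -----------------------------------------------------

    def to_newick(self, *, annotations: Optional[Mapping[int, str]] = None) -> str:
        """Newick string; ``annotations`` maps node id -> comment body text."""

        def fmt(node: Node) -> str:
            if node.is_tip:
                s = _quote_label(node.label)
            else:
                inner = ",".join(fmt(c) for c in node.children)
                s = f"({inner})" + (_quote_label(node.label) if node.label else "")
            if annotations and node.id in annotations:
                s += f"[&{annotations[node.id]}]"
            if node.length is not None:
                s += f":{node.length!r}"
            return s

        return fmt(self.root) + ";"


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|/+-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# reading


def _from_dendropy(dtree: dendropy.Tree, default_branch_length: Optional[float]) -> Phylogeny:
    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge length, if any, is not part of the model
    return Phylogeny(root, default_branch_length=default_branch_length)


def _get_dendropy(src: str, schema: str, from_path: bool, **kwargs) -> dendropy.Tree:
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {schema!r}")
    try:
        if from_path:
            return dendropy.Tree.get(
                path=src,
                schema=schema,
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                **kwargs,
            )
        return dendropy.Tree.get(
            data=src,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **kwargs,
        )
    except (dendropy.utility.error.DataParseError, dendropy.dataio.tokenizer.Tokenizer.UnexpectedEndOfStreamError) as exc:
        msg = str(exc)
        if "Multiple occurrences" in msg:  # duplicate taxon labels
            raise ValidationError(f"duplicate tip labels: {msg}") from exc
        raise TreeFormatError(f"could not parse {schema} input: {msg}") from exc


def read_tree(
    path: str,
    format: str = "newick",
    *,
    default_branch_length: Optional[float] = None,
) -> Phylogeny:
    """Read and validate a rooted tree from ``path``.

    Parameters
    ----------
    path:
        File containing one tree.
    format:
        ``"newick"`` or ``"nexus"``.
    default_branch_length:
        If given, edges without a stated length receive this value instead
        of triggering a validation error.
    """
    dtree = _get_dendropy(path, format, from_path=True)
    return _from_dendropy(dtree, default_branch_length)


def tree_from_string(
    data: str,
    format: str = "newick",
    *,
    default_branch_length: Optional[float] = None,
) -> Phylogeny:
    """Parse a tree from an in-memory string (same contract as :func:`read_tree`)."""
    dtree = _get_dendropy(data, format, from_path=False)
    return _from_dendropy(dtree, default_branch_length)


def write_tree(tree: Phylogeny, path: str, format: str = "newick") -> None:
    """Write ``tree`` to ``path`` as Newick or a minimal NEXUS TREES block."""
    newick = tree.to_newick()
    if format == "newick":
        text = newick + "\n"
    elif format == "nexus":
        text = _nexus_wrap(newick)
    else:
        raise ValueError(f"unsupported tree format {format!r}")
    with open(path, "w") as fh:
        fh.write(text)


def _nexus_wrap(newick: str) -> str:
    return "#NEXUS\nBEGIN TREES;\n    TREE tree1 = [&R] " + newick + "\nEND;\n"


# ---------------------------------------------------------------------------
# ultrametricity


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths agree within ``rel_tol`` of the maximum."""
    if tree.n_tips < 2:
        raise ValidationError("ultrametricity requires at least 2 tips")
    depths = tree.depths()
    tip_depths = [depths[t.id] for t in tree.tips]
    dmax = max(tip_depths)
    if dmax == 0:
        return True
    return all(abs(d - dmax) <= rel_tol * dmax for d in tip_depths)


# ---------------------------------------------------------------------------
# annotated NEXUS round-trip


def _format_annotation_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_annotated_tree(tree: Phylogeny, table: pd.DataFrame, path: str) -> None:
    """Write a NEXUS tree whose nodes carry ``[&key=value,...]`` comment blocks.

    ``table`` is indexed by node id; every column becomes an annotation key.
    NaN cells are omitted.  The output parses back with :func:`read_tree`
    (comments ignored) or :func:`read_annotated_tree` (comments recovered).
    """
    valid = {n.id for n in tree.nodes}
    unknown = [k for k in table.index if k not in valid]
    if unknown:
        raise ValidationError(f"annotation keys are not node ids of this tree: {unknown}")
    annotations: dict[int, str] = {}
    for node_id, row in table.iterrows():
        items = [
            f"{col}={_format_annotation_value(val)}"
            for col, val in row.items()
            if not pd.isna(val)
        ]
        if items:
            annotations[int(node_id)] = ",".join(items)
    with open(path, "w") as fh:
        fh.write(_nexus_wrap(tree.to_newick(annotations=annotations)))


def read_annotated_tree(path: str) -> tuple[Phylogeny, pd.DataFrame]:
    """Read a NEXUS file written by :func:`write_annotated_tree`.

    Returns the tree plus a node table holding the recovered annotations
    (numeric strings coerced to floats).  Node ids match what a plain
    :func:`read_tree` of the same file produces.
    """
    dtree = _get_dendropy(
        open(path).read(), "nexus", from_path=False, extract_comment_metadata=True
    )
    tree = _from_dendropy(dtree, None)
    # Walk both trees in parallel: conversion preserves child order, so the
    # post-order ranks line up.
    dpost = [n for n in dtree.seed_node.postorder_iter()]
    records: dict[int, dict[str, object]] = {}
    for rank, dnode in enumerate(dpost):
        items = {}
        for ann in dnode.annotations:
            items[ann.name] = _coerce(ann.value)
        for ann in dnode.edge.annotations:
            items.setdefault(ann.name, _coerce(ann.value))
        if items:
            records[rank] = items
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "node_id"
    return tree, table.sort_index()


def _coerce(value):
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value


# ---------------------------------------------------------------------------
# node tables as TSV


def write_node_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="node_id")


def read_node_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node_id")
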