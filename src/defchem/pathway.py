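"""Biosynthetic pathway graphs for defense-compound scoring.

A :class:`PathwayDAG` is a directed acyclic graph over defense compounds in
which an edge ``u -> v`` states that compound ``u`` is a hypothetical
biosynthetic precursor of compound ``v``.  The packaged default transcribes
the hypothesized benzoquinone pathway of juliform millipedes (23 legend
compounds): phenol at the head, hydroquinones derived by ring substitution,
and each benzoquinone produced by oxidation of its corresponding
hydroquinone.  The arrow topology of a figure is inherently a reading, so
the default ships as an editable pair of TSV files (compound table + edge
list) and every scoring operation takes the DAG as an explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from defchem.errors import ValidationError

__all__ = ["Compound", "PathwayDAG", "load_pathway", "load_default_pathway"]

COMPOUND_CLASSES = ("phenol", "hydroquinone", "benzoquinone", "other")


@dataclass(frozen=True)
class Compound:
    id: int
    name: str
    klass: str  # one of COMPOUND_CLASSES

    def __post_init__(self):
        if self.klass not in COMPOUND_CLASSES:
            raise ValidationError(
                f"compound {self.id} ({self.name}): unknown class {self.klass!r}"
            )


class PathwayDAG:
    """Acyclic precursor->product graph over defense compounds."""

    def __init__(self, compounds: Iterable[Compound], edges: Iterable[tuple[int, int]]):
        self.compounds = {c.id: c for c in compounds}
        if len(self.compounds) != len(list(self.compounds)):
            raise ValidationError("duplicate compound ids")
        g = nx.DiGraph()
        g.add_nodes_from(self.compounds)
        for u, v in edges:
            for end in (u, v):
                if end not in self.compounds:
                    raise ValidationError(f"edge endpoint {end} is not a declared compound")
            g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"pathway graph contains a cycle: {cycle}")
        self.graph = g
        # case-insensitive name -> id lookup, with a small synonym table
        self._name_index: dict[str, int] = {}
        for c in self.compounds.values():
            self._name_index[c.name.casefold()] = c.id
        self._name_index.update(
            {syn.casefold(): cid for syn, cid in _SYNONYMS.items() if cid in self.compounds}
        )

    # -- lookups ----------------------------------------------------------

    def __contains__(self, compound_id: int) -> bool:
        return compound_id in self.compounds

    def __len__(self) -> int:
        return len(self.compounds)

    def id_of(self, name: str) -> int:
        """Resolve a compound name (case-insensitive, synonyms allowed) to its id."""
        try:
            return self._name_index[name.casefold()]
        except KeyError:
            raise KeyError(f"unknown compound name {name!r}") from None

    def klass(self, compound_id: int) -> str:
        return self.compounds[compound_id].klass

    def ids_of_class(self, klass: str) -> set[int]:
        return {c.id for c in self.compounds.values() if c.klass == klass}

    def ancestors(self, compound_id: int) -> set[int]:
        """All (transitive) precursors of a compound."""
        if compound_id not in self.compounds:
            raise ValidationError(f"unknown compound id {compound_id}")
        return set(nx.ancestors(self.graph, compound_id))

    def frontier(self) -> set[int]:
        """Compounds with no products (the outer edge of the pathway)."""
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def connected_ids(self) -> set[int]:
        """Compounds attached to at least one pathway edge."""
        return {n for n in self.graph.nodes if self.graph.degree(n) > 0}


# A few spellings that recur in the defensive-chemistry literature.
_SYNONYMS = {
    "p-benzoquinone": 3,
    "para-benzoquinone": 3,
    "benzoquinone": 3,
    "toluquinone": 10,
    "2-methylbenzoquinone": 10,
    "benzoyl cyanide": 21,
    "1,4-naphthoquinone": 20,
}


def load_pathway(compounds_path: str, edges_path: str) -> PathwayDAG:
    """Load a pathway from a compound table and an edge list (both TSV).

    The compound table needs columns ``id``, ``name``, ``class``; the edge
    list needs ``precursor_id``, ``product_id``.
    """
    ctab = pd.read_csv(compounds_path, sep="\t")
    etab = pd.read_csv(edges_path, sep="\t")
    compounds = [
        Compound(int(r["id"]), str(r["name"]), str(r["class"])) for _, r in ctab.iterrows()
    ]
    edges = [(int(r.precursor_id), int(r.product_id)) for _, r in etab.iterrows()]
    return PathwayDAG(compounds, edges)


def load_default_pathway() -> PathwayDAG:
    """The packaged benzoquinone-pathway transcription (23 compounds)."""
    data = resources.files("defchem") / "data"
    return load_pathway(str(data / "pathway_compounds.tsv"), str(data / "pathway_edges.tsv"))
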