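"""Coding chemical occurrence records into phylogenetic characters.

Three characters are produced from family-level occurrence records:

* a 7-state chemical-class character (no chemical, quinazolinone alkaloids,
  heterocyclic nitrogen-containing compounds, terpenes,
  benzoquinones-hydroquinones, phenol, cyanogenics);
* an ordered 3-state production-stage character (none, phenol,
  benzoquinone), reflecting the hypothesis that phenol production precedes
  benzoquinone production;
* a continuous complexity count: the number of benzoquinone-pathway
  compounds a lineage produces, counted after *precursor closure* — if a
  compound on the outer edge of the pathway is recorded, its hypothetical
  precursors are counted as present even when unreported.

Hydroquinones are treated as precursors inside the benzoquinone pathway,
not as phenol production: a taxon recorded only with hydroquinones codes as
stage ``none`` by default (the compounds still count toward complexity);
set ``hydroquinone_is_benzoquinone=True`` to fold them into the
benzoquinone stage instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from defchem.errors import ValidationError
from defchem.pathway import PathwayDAG, load_default_pathway

__all__ = [
    "CLASS_STATES",
    "CLASS_TAGS",
    "STAGE_STATES",
    "ChemOccurrence",
    "precursor_closure",
    "complexity_score",
    "code_stage_character",
    "code_class_character",
    "aggregate_to_family",
    "read_occurrences",
    "write_discrete_character",
    "write_continuous_character",
    "read_discrete_character",
    "read_continuous_character",
]

#: 7-state chemical-class character, in its canonical order (state 1 first).
CLASS_STATES = (
    "no chemical",
    "quinazolinone alkaloids",
    "heterocyclic N compounds",
    "terpenes",
    "benzoquinones-hydroquinones",
    "phenol",
    "cyanogenics",
)

#: Class tags that may appear in occurrence records (states 2..7).
CLASS_TAGS = CLASS_STATES[1:]

#: Ordered 3-state production-stage character.
STAGE_STATES = ("none", "phenol", "benzoquinone")

_TAG_INDEX = {t.casefold(): i + 2 for i, t in enumerate(CLASS_TAGS)}
# common spelling variants
_TAG_INDEX.update(
    {
        "heterocyclic nitrogen-containing compounds": 3,
        "benzoquinones and hydroquinones": 5,
        "benzoquinones": 5,
        "cyanogenic": 7,
    }
)


@dataclass(frozen=True)
class ChemOccurrence:
    """Chemical record for one taxon (typically a family-level terminal)."""

    taxon: str
    compounds: frozenset = field(default_factory=frozenset)  # compound ids
    class_tags: frozenset = field(default_factory=frozenset)  # canonical tag strings

    @staticmethod
    def make(taxon: str, compounds: Iterable[int] = (), class_tags: Iterable[str] = ()):
        canonical = []
        for tag in class_tags:
            key = tag.casefold()
            if key not in _TAG_INDEX:
                raise ValidationError(f"unknown chemical class tag {tag!r}")
            canonical.append(CLASS_TAGS[_TAG_INDEX[key] - 2])
        return ChemOccurrence(taxon, frozenset(int(c) for c in compounds), frozenset(canonical))


# ---------------------------------------------------------------------------
# pathway scoring


def precursor_closure(observed: Iterable[int], dag: PathwayDAG) -> set[int]:
    """Augment a compound set with all its pathway precursors.

    Idempotent and a superset of the input.  Unknown compound ids are an
    error (use :func:`complexity_score` if you want them silently ignored).
    """
    observed = set(observed)
    unknown = sorted(c for c in observed if c not in dag)
    if unknown:
        raise ValidationError(f"compound ids not in pathway: {unknown}")
    closed = set(observed)
    for c in observed:
        closed |= dag.ancestors(c)
    return closed


def complexity_score(record: ChemOccurrence, dag: PathwayDAG) -> int:
    """Number of pathway compounds produced, with precursors counted as present.

    Compounds outside the pathway are ignored for this score.
    """
    on_pathway = {c for c in record.compounds if c in dag}
    return len(precursor_closure(on_pathway, dag))


# ---------------------------------------------------------------------------
# discrete characters


def code_stage_character(
    record: ChemOccurrence,
    dag: Optional[PathwayDAG] = None,
    *,
    hydroquinone_is_benzoquinone: bool = False,
) -> str:
    """Code the ordered production-stage character for one taxon.

    Returns ``"benzoquinone"`` if the record contains any benzoquinone-class
    compound (or the benzoquinones-hydroquinones class tag); otherwise
    ``"phenol"`` if phenol is present; otherwise ``"none"``.
    """
    if dag is None:
        dag = load_default_pathway()
    classes = {dag.klass(c) for c in record.compounds if c in dag}
    bq = "benzoquinone" in classes or "benzoquinones-hydroquinones" in record.class_tags
    if hydroquinone_is_benzoquinone and "hydroquinone" in classes:
        bq = True
    if bq:
        return "benzoquinone"
    if "phenol" in classes or "phenol" in record.class_tags:
        return "phenol"
    return "none"


def code_class_character(
    record: ChemOccurrence, policy: str = "polymorphic"
) -> Union[int, frozenset]:
    """Code the 7-state chemical-class character (states numbered 1..7).

    Under the default ``polymorphic`` policy a taxon producing several
    classes yields an ambiguity set over the member states (its likelihood
    is spread over those states downstream).  Under ``priority`` a single
    state is returned, picking the highest-numbered (most derived) class
    present.  An empty record is state 1, "no chemical".
    """
    states = {_TAG_INDEX[t.casefold()] for t in record.class_tags}
    if not states:
        return 1
    if policy == "priority":
        return max(states)
    if policy == "polymorphic":
        return frozenset(states) if len(states) > 1 else next(iter(states))
    raise ValueError(f"unknown policy {policy!r}")


def aggregate_to_family(
    records: Iterable[ChemOccurrence], family_map: Mapping[str, str]
) -> dict[str, ChemOccurrence]:
    """Union species-level records into family-level records.

    Every species must appear in ``family_map``; the family record is the
    set union of its members' compounds and class tags (order-independent
    and idempotent under re-aggregation).
    """
    grouped: dict[str, list[ChemOccurrence]] = {}
    for rec in records:
        if rec.taxon not in family_map:
            raise ValidationError(f"species {rec.taxon!r} has no family assignment")
        grouped.setdefault(family_map[rec.taxon], []).append(rec)
    out = {}
    for family, members in grouped.items():
        compounds = frozenset().union(*(m.compounds for m in members))
        tags = frozenset().union(*(m.class_tags for m in members))
        out[family] = ChemOccurrence(family, compounds, tags)
    return out


# ---------------------------------------------------------------------------
# file formats


def read_occurrences(path: str, dag: Optional[PathwayDAG] = None) -> dict[str, ChemOccurrence]:
    """Read a TSV occurrence table into per-taxon records.

    Expected columns: ``taxon``, ``observation`` (a compound id, compound
    name, or class tag), optional ``source``.  Compound names resolve
    case-insensitively against the pathway's compound table and synonym
    list; anything that matches a class tag is stored as a tag.
    """
    if dag is None:
        dag = load_default_pathway()
    tab = pd.read_csv(path, sep="\t", comment="#")
    if not {"taxon", "observation"} <= set(tab.columns):
        raise ValidationError("occurrence table needs columns: taxon, observation")
    compounds: dict[str, set[int]] = {}
    tags: dict[str, set[str]] = {}
    for _, row in tab.iterrows():
        taxon = str(row["taxon"])
        obs = str(row["observation"]).strip()
        compounds.setdefault(taxon, set())
        tags.setdefault(taxon, set())
        if obs in ("-", "none"):  # explicit "no chemicals recorded" marker
            continue
        # compound resolution wins over class tags ("phenol" is both)
        try:
            cid = int(obs)
        except ValueError:
            try:
                cid = dag.id_of(obs)
            except KeyError:
                if obs.casefold() in _TAG_INDEX:
                    tags[taxon].add(CLASS_TAGS[_TAG_INDEX[obs.casefold()] - 2])
                    continue
                raise ValidationError(
                    f"observation {obs!r} for taxon {taxon!r} is neither a class tag, "
                    "a compound id, nor a known compound name"
                ) from None
        if cid not in dag:
            raise ValidationError(f"compound id {cid} (taxon {taxon!r}) not in pathway")
        compounds[taxon].add(cid)
    return {
        t: ChemOccurrence(t, frozenset(compounds[t]), frozenset(tags[t])) for t in compounds
    }


def write_discrete_character(states: Mapping[str, object], path: str) -> None:
    """Write a tip -> state table (ambiguity sets joined with ``/``)."""
    with open(path, "w") as fh:
        fh.write("tip\tstate\n")
        for tip in sorted(states):
            val = states[tip]
            if isinstance(val, (set, frozenset)):
                val = "/".join(str(s) for s in sorted(val))
            fh.write(f"{tip}\t{val}\n")


def read_discrete_character(path: str) -> dict[str, object]:
    out: dict[str, object] = {}
    tab = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in tab.iterrows():
        val = str(row["state"])
        if "/" in val:
            out[str(row["tip"])] = frozenset(v for v in val.split("/"))
        else:
            out[str(row["tip"])] = val
    return out


def write_continuous_character(values: Mapping[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tvalue\n")
        for tip in sorted(values):
            fh.write(f"{tip}\t{values[tip]!r}\n")


def read_continuous_character(path: str) -> dict[str, float]:
    tab = pd.read_csv(path, sep="\t")
    return {str(r["tip"]): float(r["value"]) for _, r in tab.iterrows()}
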