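"""Chemical character coding: closure, complexity, stage/class coding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from defchem.coding import (
    CLASS_STATES,
    STAGE_STATES,
    ChemOccurrence,
    aggregate_to_family,
    code_class_character,
    code_stage_character,
    complexity_score,
    precursor_closure,
    read_occurrences,
)
from defchem.errors import ValidationError
from defchem.pathway import Compound, PathwayDAG, load_default_pathway


def toy_chain():
    """A -> B -> C as ids 1 -> 2 -> 3."""
    return PathwayDAG(
        [Compound(1, "A", "phenol"), Compound(2, "B", "hydroquinone"),
         Compound(3, "C", "benzoquinone")],
        [(1, 2), (2, 3)],
    )


def random_dag(rng: np.random.Generator, n: int = 30) -> PathwayDAG:
    """Random DAG on n nodes: edges only from lower to higher id (acyclic)."""
    compounds = [Compound(i, f"c{i}", "other") for i in range(n)]
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.12
    ]
    return PathwayDAG(compounds, edges)


def closure_oracle(observed, dag: PathwayDAG) -> set[int]:
    """Reachability inversion by repeated edge relaxation (no nx.ancestors)."""
    closed = set(observed)
    changed = True
    while changed:
        changed = False
        for u, v in dag.graph.edges:
            if v in closed and u not in closed:
                closed.add(u)
                changed = True
    return closed


class TestClosure:
    def test_empty(self):
        assert precursor_closure(set(), toy_chain()) == set()

    def test_chain(self):
        assert precursor_closure({3}, toy_chain()) == {1, 2, 3}

    def test_unknown_compound_listed(self):
        with pytest.raises(ValidationError, match=r"\[7, 9\]"):
            precursor_closure({1, 7, 9}, toy_chain())

    def test_random_dags_match_relaxation_oracle(self, rng):
        for _ in range(100):
            dag = random_dag(rng)
            obs = {int(i) for i in rng.choice(30, size=rng.integers(0, 8), replace=False)}
            closed = precursor_closure(obs, dag)
            assert closed == closure_oracle(obs, dag)
            assert precursor_closure(closed, dag) == closed  # idempotent
            assert obs <= closed

    def test_monotone(self, rng):
        dag = random_dag(rng)
        small = {1, 5}
        large = {1, 5, 20}
        assert precursor_closure(small, dag) <= precursor_closure(large, dag)


class TestComplexity:
    def test_no_pathway_compounds(self):
        rec = ChemOccurrence.make("x", class_tags=["terpenes"])
        assert complexity_score(rec, toy_chain()) == 0

    def test_chain_prefix(self):
        rec = ChemOccurrence.make("x", compounds=[2])
        assert complexity_score(rec, toy_chain()) == 2

    def test_matches_oracle_counts(self, rng):
        for _ in range(50):
            dag = random_dag(rng)
            obs = {int(i) for i in rng.choice(30, size=5, replace=False)}
            rec = ChemOccurrence("x", frozenset(obs), frozenset())
            assert complexity_score(rec, dag) == len(closure_oracle(obs, dag))

    def test_monotone_under_added_compounds(self):
        dag = load_default_pathway()
        r1 = ChemOccurrence.make("x", compounds=[10])
        r2 = ChemOccurrence.make("x", compounds=[10, 18])
        assert complexity_score(r2, dag) >= complexity_score(r1, dag)


class TestStageCharacter:
    def test_empty_is_none(self):
        assert code_stage_character(ChemOccurrence.make("x")) == "none"

    def test_phenol(self):
        rec = ChemOccurrence.make("x", compounds=[1])
        assert code_stage_character(rec) == "phenol"

    def test_benzoquinone_precedence(self):
        rec = ChemOccurrence.make("x", compounds=[1, 10])
        assert code_stage_character(rec) == "benzoquinone"

    def test_hydroquinone_only_is_not_phenol(self):
        rec = ChemOccurrence.make("x", compounds=[2])
        assert code_stage_character(rec) == "none"
        assert code_stage_character(rec, hydroquinone_is_benzoquinone=True) == "benzoquinone"

    def test_monotone_along_pathway(self):
        """Adding compounds can never demote the coded stage."""
        dag = load_default_pathway()
        order = {s: i for i, s in enumerate(STAGE_STATES)}
        base = ChemOccurrence.make("x", compounds=[1])
        richer = ChemOccurrence.make("x", compounds=[1, 2, 10])
        assert order[code_stage_character(richer, dag)] >= order[code_stage_character(base, dag)]


class TestClassCharacter:
    def test_empty_is_state_one(self):
        assert code_class_character(ChemOccurrence.make("x")) == 1

    def test_cyanogenics_is_state_seven(self):
        assert code_class_character(ChemOccurrence.make("x", class_tags=["cyanogenics"])) == 7

    def test_polymorphic_ambiguity_set(self):
        rec = ChemOccurrence.make(
            "x", class_tags=["phenol", "benzoquinones-hydroquinones"]
        )
        assert code_class_character(rec, "polymorphic") == frozenset({5, 6})

    def test_priority_picks_single_state(self):
        rec = ChemOccurrence.make(
            "x", class_tags=["phenol", "benzoquinones-hydroquinones"]
        )
        assert code_class_character(rec, "priority") == 6

    def test_seven_states_declared(self):
        assert len(CLASS_STATES) == 7
        assert CLASS_STATES[0] == "no chemical"
        assert len(STAGE_STATES) == 3


class TestAggregation:
    def test_single_species_identity(self):
        rec = ChemOccurrence.make("sp1", compounds=[1, 2], class_tags=["phenol"])
        fam = aggregate_to_family([rec], {"sp1": "F"})
        assert fam["F"].compounds == rec.compounds
        assert fam["F"].class_tags == rec.class_tags

    def test_union(self):
        r1 = ChemOccurrence.make("sp1", compounds=[1, 2])
        r2 = ChemOccurrence.make("sp2", compounds=[9, 10])
        fam = aggregate_to_family([r1, r2], {"sp1": "F", "sp2": "F"})
        assert fam["F"].compounds == frozenset({1, 2, 9, 10})

    def test_missing_family_rejected(self):
        with pytest.raises(ValidationError, match="family"):
            aggregate_to_family([ChemOccurrence.make("sp1")], {})

    @settings(derandomize=True, max_examples=30)
    @given(
        sets=st.lists(
            st.frozensets(st.integers(1, 23), max_size=6), min_size=1, max_size=5
        )
    )
    def test_order_independent_and_idempotent(self, sets):
        recs = [ChemOccurrence(f"s{i}", s, frozenset()) for i, s in enumerate(sets)]
        fmap = {f"s{i}": "F" for i in range(len(sets))}
        fam = aggregate_to_family(recs, fmap)["F"]
        fam_rev = aggregate_to_family(recs[::-1], fmap)["F"]
        assert fam.compounds == fam_rev.compounds
        again = aggregate_to_family([fam], {"F": "F"})["F"]
        assert again.compounds == fam.compounds


class TestPackagedPathway:
    def test_has_23_compounds(self):
        assert len(load_default_pathway()) == 23

    def test_benzoquinones_have_hydroquinone_precursors(self):
        """Each backbone benzoquinone is preceded by a hydroquinone."""
        dag = load_default_pathway()
        hydro = dag.ids_of_class("hydroquinone")
        for bq in dag.ids_of_class("benzoquinone") & dag.connected_ids():
            assert dag.ancestors(bq) & hydro, f"benzoquinone {bq} lacks a hydroquinone"

    def test_name_lookup_case_insensitive(self):
        dag = load_default_pathway()
        assert dag.id_of("PHENOL") == 1
        assert dag.id_of("toluquinone") == 10  # synonym


class TestOccurrenceIO:
    def test_read_occurrences(self, tmp_path):
        p = tmp_path / "occ.tsv"
        p.write_text(
            "taxon\tobservation\tsource\n"
            "Fam1\tphenol\tlit\n"
            "Fam1\t10\tgcms\n"
            "Fam2\tcyanogenics\tlit\n"
        )
        recs = read_occurrences(str(p))
        assert recs["Fam1"].compounds == frozenset({1, 10})
        assert recs["Fam2"].class_tags == frozenset({"cyanogenics"})

    def test_unknown_observation_rejected(self, tmp_path):
        p = tmp_path / "occ.tsv"
        p.write_text("taxon\tobservation\nFam1\tnot-a-compound\n")
        with pytest.raises(ValidationError, match="not-a-compound"):
            read_occurrences(str(p))
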