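"""Synthetic data generation for every stage of the analysis.

Provides seeded, reproducible stand-ins for the empirical inputs: birth-
death chronograms (conditioned on tip count, optionally rescaled to a
target crown age such as the ~467 Ma depth of the millipede chronogram),
discrete characters evolved under arbitrary rate models, continuous
characters under Brownian motion, and chemical occurrence tables whose
compound sets are consistent with each tip's simulated production stage.

Discrete simulation samples states at branch endpoints from the exact
transition matrix P(t) — exact for likelihood testing and much faster than
event-by-event simulation; a Gillespie mode is available where realized
transition counts are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from defchem.coding import ChemOccurrence
from defchem.errors import ValidationError
from defchem.mk import RateModel, _branch_matrices
from defchem.pathway import PathwayDAG, load_default_pathway
from defchem.tree import Node, Phylogeny

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_pure_birth_fixed_duration",
    "simulate_discrete",
    "simulate_discrete_gillespie",
    "simulate_continuous",
    "simulate_chem_records",
]


@dataclass
class SimConfig:
    """Parameters of a full synthetic dataset.

    Defaults emulate the empirical study conditions: a family-level
    chronogram a few hundred Ma deep with a moderate extinction fraction,
    and stage-character rates slow enough that a handful of gains and
    losses occur across the tree.
    """

    seed: int = 0
    n_tips: int = 49
    birth: float = 0.03  # per Ma
    death: float = 0.01  # per Ma
    crown_age: Optional[float] = 467.0  # Ma; None = leave simulated depth
    sigma2: float = 0.05  # BM rate for the complexity character, per Ma
    root_value: float = 0.0
    stage_rates: tuple[float, float, float] = (0.004, 0.004, 0.001)
    # gain none->phenol, gain phenol->benzoquinone, shared loss; per Ma, so
    # a 467 Ma-deep tree sees ~1.9 expected gains per root-to-tip path
    p_terminal: float = 0.5  # inclusion probability per terminal compound
    p_drop: float = 0.5  # probability a precursor goes unrecorded

    def __post_init__(self):
        if not self.birth > self.death >= 0:
            raise ValidationError("need birth > death >= 0")
        if self.n_tips < 3:
            raise ValidationError("need at least 3 tips")
        for p in (self.p_terminal, self.p_drop):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_tips: int,
    birth: float,
    death: float = 0.0,
    *,
    rng: Union[int, np.random.Generator] = 0,
    crown_age: Optional[float] = None,
    max_retries: int = 100,
) -> Phylogeny:
    """Complete-sampling birth-death tree conditioned on the extant tip count.

    Simulates forward from two crown lineages; when the extant count first
    exceeds ``n_tips``, a cut time is drawn uniformly from the periods
    during which exactly ``n_tips`` lineages were extant (a general-
    sampling-style draw), extinct subtrees are pruned, and the result is an
    ultrametric tree with tips ``t1..tn``.  Total extinction or loss of one
    crown lineage triggers a bounded retry.  With ``crown_age`` set, branch
    lengths are rescaled so the root-to-tip depth equals it.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not birth > 0 or death < 0:
        raise ValidationError("need birth > 0 and death >= 0")
    for _ in range(max_retries):
        tree = _try_birth_death(n_tips, birth, death, rng)
        if tree is not None:
            if crown_age is not None:
                tree = tree.rescaled_to_depth(crown_age)
            return tree
    raise ValidationError(
        f"birth-death simulation failed {max_retries} times (total extinction)"
    )


def _try_birth_death(n_tips, birth, death, rng) -> Optional[Phylogeny]:
    root = Node()
    left, right = Node(), Node()
    root.add_child(left)
    root.add_child(right)
    active = [(left, 0.0), (right, 0.0)]  # (node, birth time)
    ended: list[tuple[Node, float, float]] = []  # (node, start, end) for split/dead
    t = 0.0
    intervals: list[tuple[float, float]] = []  # periods with exactly n_tips extant
    max_events = 200 * n_tips
    for _ in range(max_events):
        n_active = len(active)
        if n_active == 0:
            return None
        rate = n_active * (birth + death)
        dt = rng.exponential(1.0 / rate)
        if n_active == n_tips:
            intervals.append((t, t + dt))
        t += dt
        i = int(rng.integers(n_active))
        node, born = active[i]
        is_birth = rng.random() < birth / (birth + death)
        if is_birth:
            if n_active == n_tips:
                # count is about to exceed the target: sample the cut time
                break
            c1, c2 = Node(), Node()
            node.add_child(c1)
            node.add_child(c2)
            node.length = t - born
            ended.append((node, born, t))
            active.pop(i)
            active.append((c1, t))
            active.append((c2, t))
        else:
            node.length = t - born
            ended.append((node, born, t))
            active.pop(i)
    else:
        return None
    if not intervals:
        return None
    # uniform time over the accumulated n_tips intervals
    lengths = np.array([b - a for a, b in intervals])
    pick = rng.choice(len(intervals), p=lengths / lengths.sum())
    a, b = intervals[pick]
    tau = rng.uniform(a, b)
    # lineages extant at tau become the tips (children born after tau are cut)
    survivors = []
    for node, born in active:
        if born <= tau:
            node.length = tau - born
            node.children = []
            survivors.append(node)
    for node, start, end in ended:
        if start <= tau < end:
            node.length = tau - start
            node.children = []
            survivors.append(node)
    if len(survivors) != n_tips:
        return None
    # prune: keep only ancestors of survivors, drop post-tau or extinct parts
    keep = set()
    for node in survivors:
        cur = node
        while cur is not None and id(cur) not in keep:
            keep.add(id(cur))
            cur = cur.parent
    survivor_ids = {id(n) for n in survivors}

    def prune(node: Node) -> Optional[Node]:
        if id(node) in survivor_ids:
            node.children = []
            return node
        kids = [prune(c) for c in node.children if id(c) in keep]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress unifurcation
            child = kids[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            child.parent = node.parent
            return child
        node.children = []
        for k in kids:
            node.add_child(k)
        return node

    new_root = prune(root)
    if new_root is None or len(new_root.children) < 2:
        return None  # one crown lineage died out
    new_root.length = None
    new_root.parent = None
    # deterministic tip labels in traversal order
    counter = [0]

    def label_tips(node: Node):
        if not node.children:
            counter[0] += 1
            node.label = f"t{counter[0]}"
        for c in node.children:
            label_tips(c)

    label_tips(new_root)
    return Phylogeny(new_root)


def simulate_pure_birth_fixed_duration(
    birth: float, duration: float, *, rng: Union[int, np.random.Generator] = 0
) -> int:
    """Number of lineages after ``duration`` of a pure-birth (Yule) process
    started from a single lineage; E[N] = exp(birth * duration)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, t = 1, 0.0
    while True:
        t += rng.exponential(1.0 / (n * birth))
        if t > duration:
            return n
        n += 1


# ---------------------------------------------------------------------------
# characters


def _root_state(root_distribution, model: RateModel, rng) -> int:
    if isinstance(root_distribution, str):
        if root_distribution == "flat":
            pi = np.full(model.k, 1.0 / model.k)
        elif root_distribution == "stationary":
            pi = model.stationary_distribution()
        else:
            raise ValidationError(f"unknown root distribution {root_distribution!r}")
    else:
        pi = np.asarray(root_distribution, dtype=float)
        pi = pi / pi.sum()
    return int(rng.choice(model.k, p=pi))


def simulate_discrete(
    tree: Phylogeny,
    model: RateModel,
    root_distribution="flat",
    *,
    rng: Union[int, np.random.Generator] = 0,
) -> tuple[dict[str, str], dict[int, str]]:
    """Evolve a discrete character down the tree by endpoint sampling.

    The root state is drawn from ``root_distribution``; each branch's end
    state is sampled from the exact transition matrix row for its length.
    Returns (tip data keyed by label, true states for every node id).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = model.states.labels
    nonroot = [n for n in tree.nodes if n is not tree.root]
    P = _branch_matrices(model.Q, np.array([n.length for n in nonroot]))
    Pmap = {n.id: P[i] for i, n in enumerate(nonroot)}
    states: dict[int, int] = {tree.root.id: _root_state(root_distribution, model, rng)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        row = Pmap[node.id][states[node.parent.id]]
        row = np.clip(row, 0, None)
        row = row / row.sum()
        states[node.id] = int(rng.choice(model.k, p=row))
    tip_data = {n.label: labels[states[n.id]] for n in tree.tips}
    true_states = {nid: labels[s] for nid, s in states.items()}
    return tip_data, true_states


def simulate_discrete_gillespie(
    tree: Phylogeny,
    model: RateModel,
    root_distribution="flat",
    *,
    rng: Union[int, np.random.Generator] = 0,
) -> tuple[dict[str, str], dict[int, str], int]:
    """Event-by-event simulation; additionally returns the realized number
    of transitions (useful when true change counts matter)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Q = model.Q
    labels = model.states.labels
    states: dict[int, int] = {tree.root.id: _root_state(root_distribution, model, rng)}
    n_events = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = states[node.parent.id]
        t = 0.0
        while True:
            out = -Q[s, s]
            if out <= 0:
                break
            t += rng.exponential(1.0 / out)
            if t > node.length:
                break
            probs = np.clip(Q[s].copy(), 0, None)
            probs[s] = 0
            probs /= probs.sum()
            s = int(rng.choice(model.k, p=probs))
            n_events += 1
        states[node.id] = s
    tip_data = {n.label: labels[states[n.id]] for n in tree.tips}
    return tip_data, {nid: labels[s] for nid, s in states.items()}, n_events


def simulate_continuous(
    tree: Phylogeny,
    sigma2: float,
    root_value: float = 0.0,
    *,
    rng: Union[int, np.random.Generator] = 0,
) -> tuple[dict[str, float], dict[int, float]]:
    """Brownian motion on the tree: increments ~ Normal(0, sigma2 * length)."""
    if sigma2 < 0:
        raise ValidationError("sigma2 must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values: dict[int, float] = {tree.root.id: float(root_value)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        sd = np.sqrt(sigma2 * node.length)
        values[node.id] = values[node.parent.id] + float(rng.normal(0.0, sd))
    return {n.label: values[n.id] for n in tree.tips}, values


# ---------------------------------------------------------------------------
# chemical records


def simulate_chem_records(
    tree: Phylogeny,
    stage_model: RateModel,
    dag: Optional[PathwayDAG] = None,
    *,
    rng: Union[int, np.random.Generator] = 0,
    root_distribution=(1.0, 0.0, 0.0),
    p_terminal: float = 0.5,
    p_drop: float = 0.5,
) -> tuple[dict[str, ChemOccurrence], dict[int, str]]:
    """Occurrence records consistent with a simulated production stage.

    The 3-state stage character evolves under ``stage_model``.  Tips in
    stage ``phenol`` receive phenol; tips in stage ``benzoquinone`` receive
    a random set of terminal benzoquinone-pathway compounds (each terminal
    kept with probability ``p_terminal``, at least one guaranteed) whose
    upstream precursors are then *omitted from the record* independently
    with probability ``p_drop`` — so precursor closure has real work to do.
    Class tags are assigned consistently with the compounds present.
    Returns (records keyed by tip label, true stage per node id).
    """
    if dag is None:
        dag = load_default_pathway()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if tuple(stage_model.states.labels) != ("none", "phenol", "benzoquinone"):
        raise ValidationError("stage_model must be over (none, phenol, benzoquinone)")
    tip_stage, true_states = simulate_discrete(
        tree, stage_model, root_distribution, rng=rng
    )
    phenol_id = dag.id_of("phenol")
    bq_terminals = sorted(
        (dag.frontier() & dag.ids_of_class("benzoquinone")) & dag.connected_ids()
    )
    records: dict[str, ChemOccurrence] = {}
    for tip in tree.tips:
        stage = tip_stage[tip.label]
        compounds: set[int] = set()
        tags: set[str] = set()
        if stage == "phenol":
            compounds.add(phenol_id)
            tags.add("phenol")
        elif stage == "benzoquinone":
            chosen = [c for c in bq_terminals if rng.random() < p_terminal]
            if not chosen:
                chosen = [bq_terminals[int(rng.integers(len(bq_terminals)))]]
            compounds.update(chosen)
            closure = set(chosen)
            for c in chosen:
                closure |= dag.ancestors(c)
            for precursor in sorted(closure - set(chosen)):
                if rng.random() >= p_drop:
                    compounds.add(precursor)
            tags.add("benzoquinones-hydroquinones")
            if phenol_id in compounds:
                tags.add("phenol")
        records[tip.label] = ChemOccurrence(
            tip.label, frozenset(compounds), frozenset(tags)
        )
    return records, true_states
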