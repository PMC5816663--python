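"""Shared fixtures and independent oracles.

The enumeration oracles here deliberately avoid the package's pruning code
path: likelihoods and marginals are computed by summing over every
assignment of states to interior nodes, with per-branch transition
matrices from scipy's expm directly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from defchem.tree import Phylogeny, tree_from_string


def random_tree_newick(rng: np.random.Generator, n_tips: int, max_len: float = 2.0) -> str:
    """A random rooted binary tree with uniform branch lengths (not ultrametric)."""
    parts = [f"t{i}:{rng.uniform(0.05, max_len):.6f}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        a, b = parts[i], parts[j]
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(f"({a},{b}):{rng.uniform(0.05, max_len):.6f}")
    body = parts[0]
    body = body[: body.rfind(":")]  # root carries no branch length
    return body + ";"


def random_tree(rng: np.random.Generator, n_tips: int, max_len: float = 2.0) -> Phylogeny:
    return tree_from_string(random_tree_newick(rng, n_tips, max_len))


def random_generator(rng: np.random.Generator, k: int) -> np.ndarray:
    """A random generator matrix with off-diagonal rates in (0.1, 1.5)."""
    Q = rng.uniform(0.1, 1.5, size=(k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def enumerate_root_partials(tree: Phylogeny, data: dict, Q: np.ndarray, labels) -> np.ndarray:
    """L_r = P(tip data | root state r) by brute-force summation."""
    k = Q.shape[0]
    internals = [n for n in tree.nodes if not n.is_tip]
    P = {n.id: expm(Q * n.length) for n in tree.nodes if n.parent is not None}
    tip_states = {}
    for t in tree.tips:
        v = data[t.label]
        if isinstance(v, (set, frozenset)):
            tip_states[t.id] = [labels.index(str(s)) for s in v]
        elif v is None or v == "?":
            tip_states[t.id] = list(range(k))
        else:
            tip_states[t.id] = [labels.index(str(v))]
    out = np.zeros(k)
    nonroot_internals = [n for n in internals if n.parent is not None]
    for r in range(k):
        total = 0.0
        for assign in itertools.product(range(k), repeat=len(nonroot_internals)):
            amap = {n.id: s for n, s in zip(nonroot_internals, assign)}
            amap[tree.root.id] = r
            for tip_combo in itertools.product(*(tip_states[t.id] for t in tree.tips)):
                p = 1.0
                for t, s in zip(tree.tips, tip_combo):
                    p *= P[t.id][amap[t.parent.id], s]
                for n in nonroot_internals:
                    p *= P[n.id][amap[n.parent.id], amap[n.id]]
                total += p
        out[r] = total
    return out


def enumerate_log_likelihood(tree, data, Q, labels, pi) -> float:
    L = enumerate_root_partials(tree, data, Q, labels)
    return float(np.log(pi @ L))


def enumerate_marginals(tree, data, Q, labels, pi) -> np.ndarray:
    """P(node = s | data) for every node, by enumeration over assignments."""
    k = Q.shape[0]
    internals = [n for n in tree.nodes if not n.is_tip]
    P = {n.id: expm(Q * n.length) for n in tree.nodes if n.parent is not None}
    tip_states = {}
    for t in tree.tips:
        v = data[t.label]
        if isinstance(v, (set, frozenset)):
            tip_states[t.id] = [labels.index(str(s)) for s in v]
        elif v is None or v == "?":
            tip_states[t.id] = list(range(k))
        else:
            tip_states[t.id] = [labels.index(str(v))]
    post = np.zeros((len(tree), k))
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {n.id: s for n, s in zip(internals, assign)}
        for tip_combo in itertools.product(*(tip_states[t.id] for t in tree.tips)):
            full = dict(amap)
            for t, s in zip(tree.tips, tip_combo):
                full[t.id] = s
            p = pi[full[tree.root.id]]
            for n in tree.nodes:
                if n.parent is not None:
                    p *= P[n.id][full[n.parent.id], full[n.id]]
            for nid, s in full.items():
                post[nid, s] += p
    return post / post.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def three_tip_tree():
    return tree_from_string("((A:1,B:1):1,C:2);")
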