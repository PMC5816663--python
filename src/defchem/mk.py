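"""Constrained Mk models: likelihood, fitting, model selection, ancestral states.

A discrete character with k states evolves on the tree as a continuous-time
Markov chain with generator Q.  Rate matrices are expressed through an
integer *index matrix* M: off-diagonal entries sharing the same positive
integer share one rate parameter, zero entries are structurally forbidden
transitions, and the diagonal is determined by the row-sum-zero constraint.
The classical ER / SYM / ARD families and arbitrary custom matrices (such
as the ordered none -> phenol -> benzoquinone stage model) are all index
matrices.

Likelihoods use Felsenstein's pruning algorithm with per-node rescaling and
handle multifurcations and ambiguous/missing tips natively (an ambiguous
tip contributes a partial-likelihood vector of ones over its allowed
states).  The root can be treated as flat, stationary, a fixed vector, or
by the FitzJohn et al. weighting in which each root state is weighted by
its probability of giving rise to the observed tip data; the last is the
default throughout.

Marginal ancestral reconstructions are computed by an up-down pass and are
exact conditionals P(node = s | tip data) under the fitted model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from defchem.errors import FitError, ValidationError
from defchem.tree import Phylogeny

__all__ = [
    "StateSpace",
    "RateModel",
    "FitResult",
    "FitzJohnRoot",
    "LRTResult",
    "MarginalReconstruction",
    "transition_probabilities",
    "log_likelihood",
    "fitzjohn_root",
    "fit_mk",
    "nested_warm_start",
    "likelihood_ratio_test",
    "marginal_ancestral_states",
    "build_stage_model",
    "read_index_matrix",
    "write_index_matrix",
]

ROOT_TREATMENTS = ("flat", "stationary", "fitzjohn")


@dataclass(frozen=True)
class StateSpace:
    """Ordered list of unique state labels."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValidationError("a state space needs at least 2 states")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("state labels must be unique")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state {label!r}") from None


class RateModel:
    """A state space plus an index matrix and (optionally) rate parameters."""

    def __init__(
        self,
        states: StateSpace,
        index_matrix: np.ndarray,
        theta: Optional[Sequence[float]] = None,
    ):
        M = np.asarray(index_matrix, dtype=int).copy()
        k = states.k
        if M.shape != (k, k):
            raise ValidationError(f"index matrix must be {k}x{k}")
        if (M < 0).any():
            raise ValidationError("index matrix entries must be nonnegative")
        np.fill_diagonal(M, 0)
        self.states = states
        self.index_matrix = M
        off = M[~np.eye(k, dtype=bool)]
        self._param_ids = tuple(sorted(set(off[off > 0])))
        self.theta: Optional[np.ndarray] = None
        if theta is not None:
            theta = np.asarray(theta, dtype=float)
            if theta.shape != (self.n_params,):
                raise ValidationError(
                    f"theta must have {self.n_params} entries, got {theta.shape}"
                )
            if (theta <= 0).any():
                raise ValidationError("rates must be positive")
            self.theta = theta

    @property
    def k(self) -> int:
        return self.states.k

    @property
    def n_params(self) -> int:
        """Number of free rate parameters (distinct positive indices)."""
        return len(self._param_ids)

    def with_theta(self, theta: Sequence[float]) -> "RateModel":
        return RateModel(self.states, self.index_matrix, theta)

    @property
    def Q(self) -> np.ndarray:
        """Realized generator matrix; requires theta."""
        if self.theta is None:
            raise FitError("rate parameters are unset; call with_theta or fit_mk first")
        k = self.k
        Q = np.zeros((k, k))
        lookup = {pid: self.theta[i] for i, pid in enumerate(self._param_ids)}
        for i in range(k):
            for j in range(k):
                if i != j and self.index_matrix[i, j] > 0:
                    Q[i, j] = lookup[self.index_matrix[i, j]]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi with pi Q = 0 (left null space, normalized)."""
        from scipy.linalg import null_space

        ns = null_space(self.Q.T)
        if ns.shape[1] == 0:
            raise FitError("no stationary distribution found")
        v = np.abs(ns[:, 0])
        if v.sum() == 0:
            raise FitError("degenerate stationary distribution")
        return v / v.sum()

    # -- constructors ------------------------------------------------------

    @staticmethod
    def er(states: StateSpace, rate: Optional[float] = None) -> "RateModel":
        """Equal-rates model: one shared rate for every transition."""
        M = np.ones((states.k, states.k), dtype=int)
        return RateModel(states, M, None if rate is None else [rate])

    @staticmethod
    def sym(states: StateSpace) -> "RateModel":
        """Symmetric model: one rate per unordered state pair."""
        k = states.k
        M = np.zeros((k, k), dtype=int)
        nxt = 1
        for i in range(k):
            for j in range(i + 1, k):
                M[i, j] = M[j, i] = nxt
                nxt += 1
        return RateModel(states, M)

    @staticmethod
    def ard(states: StateSpace) -> "RateModel":
        """All-rates-different model: one rate per ordered state pair."""
        k = states.k
        M = np.zeros((k, k), dtype=int)
        nxt = 1
        for i in range(k):
            for j in range(k):
                if i != j:
                    M[i, j] = nxt
                    nxt += 1
        return RateModel(states, M)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RateModel k={self.k} params={self.n_params} "
            f"theta={None if self.theta is None else np.round(self.theta, 6)}>"
        )


def build_stage_model(*, allow_total_loss: bool = True) -> RateModel:
    """The ordered production-stage model over (none, phenol, benzoquinone).

    Phenol production is assumed ancestral to benzoquinone production: the
    only permitted gains are none -> phenol (rate 1) and phenol ->
    benzoquinone (rate 2); the direct gain none -> benzoquinone is
    structurally forbidden.  All losses share a single rate (rate 3):
    phenol -> none, benzoquinone -> phenol and, when ``allow_total_loss``
    (the default), the total loss benzoquinone -> none.  Three free
    parameters either way.
    """
    states = StateSpace(("none", "phenol", "benzoquinone"))
    M = np.array(
        [
            [0, 1, 0],
            [3, 0, 2],
            [3 if allow_total_loss else 0, 3, 0],
        ]
    )
    return RateModel(states, M)


# ---------------------------------------------------------------------------
# transition probabilities


def transition_probabilities(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt): row-stochastic transition probability matrix."""
    if t < 0:
        raise ValidationError("time must be nonnegative")
    P = expm(model.Q * t)
    return np.clip(P, 0.0, 1.0)


def _branch_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q * t) for a whole vector of branch lengths at once.

    Uses a single eigendecomposition when Q is diagonalizable and
    well-conditioned, falling back to per-branch scaling-and-squaring
    otherwise.  Returns an array of shape (len(lengths), k, k).
    """
    k = Q.shape[0]
    try:
        lam, V = np.linalg.eig(Q)
        condV = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        condV = np.inf
    if np.isfinite(condV) and condV < 1e8:
        Vinv = np.linalg.inv(V)
        E = np.exp(np.outer(lengths, lam))  # (n, k)
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
        P = np.real(P)
    else:
        P = np.stack([expm(Q * t) for t in lengths])
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# tip data handling

TipValue = Union[int, str, frozenset, set, None]


def _tip_partial(value: TipValue, states: StateSpace) -> np.ndarray:
    k = states.k
    vec = np.zeros(k)
    if value is None or (isinstance(value, str) and value in ("?", "-")):
        return np.ones(k)
    if isinstance(value, (set, frozenset)):
        for v in value:
            vec[_state_index(v, states)] = 1.0
        if vec.sum() == 0:
            raise ValidationError("empty ambiguity set")
        return vec
    vec[_state_index(value, states)] = 1.0
    return vec


def _state_index(value: Union[int, str], states: StateSpace) -> int:
    if isinstance(value, (int, np.integer)):
        if not 0 <= value < states.k:
            raise ValidationError(f"state index {value} out of range for k={states.k}")
        return int(value)
    if isinstance(value, str) and value.isdigit() and value not in states.labels:
        return _state_index(int(value), states)
    return states.index(value)


def _tip_partials(tree: Phylogeny, data: Mapping[str, TipValue], states: StateSpace):
    partials = {}
    for tip in tree.tips:
        if tip.label not in data:
            raise ValidationError(
                f"tip {tip.label!r} has no character data (use None or '?' for missing)"
            )
        partials[tip.id] = _tip_partial(data[tip.label], states)
    return partials


def _data_fingerprint(tree: Phylogeny, data: Mapping[str, TipValue]) -> str:
    h = hashlib.sha256()
    h.update(tree.to_newick().encode())
    for label in sorted(data):
        val = data[label]
        if isinstance(val, (set, frozenset)):
            val = "/".join(sorted(str(v) for v in val))
        h.update(f"{label}={val};".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# pruning likelihood


def _postorder_partials(
    tree: Phylogeny, tip_partials, P: dict[int, np.ndarray], k: int
) -> tuple[dict[int, np.ndarray], float]:
    """Scaled conditional likelihoods D_v(s) for every node; returns (partials, log scale)."""
    D: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            D[node.id] = tip_partials[node.id]
            continue
        vec = np.ones(k)
        for child in node.children:
            vec = vec * (P[child.id] @ D[child.id])
        m = vec.max()
        if m <= 0 or not np.isfinite(m):
            raise FitError(
                f"partial likelihoods vanished at node {node.id}; "
                "data may be impossible under structural zeros of Q"
            )
        D[node.id] = vec / m
        log_scale += np.log(m)
    return D, log_scale


def _root_prior(
    root: Union[str, np.ndarray, Sequence[float]],
    model: RateModel,
    root_partials: np.ndarray,
) -> np.ndarray:
    if isinstance(root, str):
        if root == "flat":
            return np.full(model.k, 1.0 / model.k)
        if root == "stationary":
            return model.stationary_distribution()
        if root == "fitzjohn":
            return fitzjohn_root(root_partials).weights
        raise ValueError(f"unknown root treatment {root!r}")
    pi = np.asarray(root, dtype=float)
    if pi.shape != (model.k,) or (pi < 0).any() or pi.sum() <= 0:
        raise ValidationError("fixed root vector must be nonnegative and nonzero")
    return pi / pi.sum()


@dataclass(frozen=True)
class FitzJohnRoot:
    """Root weighting where state i gets weight L_i / sum_j L_j."""

    weights: np.ndarray
    total_likelihood: float
    root_marginal: np.ndarray


def fitzjohn_root(root_partials: Sequence[float]) -> FitzJohnRoot:
    """Weight each root state by its probability of giving rise to the data.

    Given per-state root conditional likelihoods L, the weights are
    w_i = L_i / sum(L), the reported total likelihood is sum_i w_i L_i, and
    the root marginal is proportional to w_i L_i.
    """
    L = np.asarray(root_partials, dtype=float)
    if (L < 0).any():
        raise ValidationError("root partial likelihoods must be nonnegative")
    total = L.sum()
    if total <= 0:
        raise ValidationError("all root partial likelihoods are zero")
    w = L / total
    wl = w * L
    return FitzJohnRoot(w, float(wl.sum()), wl / wl.sum())


def log_likelihood(
    tree: Phylogeny,
    data: Mapping[str, TipValue],
    model: RateModel,
    root: Union[str, Sequence[float]] = "fitzjohn",
) -> float:
    """Pruning-algorithm log-likelihood of the tip data under ``model``.

    ``root`` is ``"flat"``, ``"stationary"``, ``"fitzjohn"`` or an explicit
    probability vector.  Multifurcations are handled natively; ambiguous or
    missing tips spread their likelihood over the allowed states.
    """
    k = model.k
    Q = model.Q
    nonroot = [n for n in tree.nodes if n is not tree.root]
    lengths = np.array([n.length for n in nonroot])
    Pstack = _branch_matrices(Q, lengths)
    P = {n.id: Pstack[i] for i, n in enumerate(nonroot)}
    tip_partials = _tip_partials(tree, data, model.states)
    D, log_scale = _postorder_partials(tree, tip_partials, P, k)
    Lroot = D[tree.root.id]
    if isinstance(root, str) and root == "fitzjohn":
        total = fitzjohn_root(Lroot).total_likelihood
    else:
        pi = _root_prior(root, model, Lroot)
        total = float(pi @ Lroot)
    if total <= 0 or not np.isfinite(total):
        raise FitError("non-finite likelihood; check data compatibility with the model")
    return float(np.log(total) + log_scale)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """A maximum-likelihood fit of a rate model."""

    model: RateModel
    log_likelihood: float
    n_params: int
    converged: bool
    n_restarts: int
    root: str
    data_fingerprint: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.log_likelihood

    def summary(self) -> str:
        lines = [
            f"states: {', '.join(self.model.states.labels)}",
            f"free parameters: {self.n_params}",
            f"log-likelihood: {self.log_likelihood:.6f}",
            f"AIC: {self.aic:.6f}",
            f"root treatment: {self.root}",
            f"converged: {self.converged} (restarts: {self.n_restarts})",
            "rates: " + ", ".join(f"{x:.6g}" for x in self.model.theta),
        ]
        return "\n".join(lines)


def nested_warm_start(nested: "FitResult", general: RateModel) -> np.ndarray:
    """Map a fitted nested model's rates into a general model's parameters.

    For each of the general model's rate classes, takes the nested fit's
    rate on any transition the class covers; transitions the nested model
    forbids start at a negligible rate.  Used to warm-start ARD (or any
    refinement) from an ER/SYM/custom solution so that nested
    log-likelihood orderings survive optimization noise.
    """
    Qn = nested.model.Q
    Mn = nested.model.index_matrix
    Mg = general.index_matrix
    if ((Mn > 0) & (Mg == 0)).any():
        raise ValidationError("models are not nested (general forbids an allowed transition)")
    theta = np.full(general.n_params, 1e-9)
    for slot, pid in enumerate(general._param_ids):
        hits = np.argwhere((Mg == pid) & (Mn > 0))
        if len(hits):
            i, j = hits[0]
            theta[slot] = max(Qn[i, j], 1e-9)
    return theta


def fit_mk(
    tree: Phylogeny,
    data: Mapping[str, TipValue],
    model: RateModel,
    root: Union[str, Sequence[float]] = "fitzjohn",
    *,
    n_restarts: int = 10,
    rate_bounds: tuple[float, float] = (1e-9, 1e3),
    seed: int = 0,
    maxiter: int = 500,
    extra_starts: Optional[Sequence[Sequence[float]]] = None,
) -> FitResult:
    """Maximum-likelihood fit of ``model``'s rates by bounded quasi-Newton.

    Optimization is in log-rate space with ``n_restarts`` dispersed starting
    points centred on 1 / (mean root-to-tip depth), the natural scale at
    which roughly one event is expected per lineage.  ``extra_starts``
    (rate-space vectors, e.g. from :func:`nested_warm_start`) are appended
    to the restart list.  The returned log-likelihood is the best across
    restarts; a fit that never converged is flagged, not hidden.
    """
    lo, hi = rate_bounds
    if not (0 < lo < hi):
        raise ValidationError("rate bounds must satisfy 0 < lo < hi")
    depths = tree.depths()
    mean_depth = float(np.mean([depths[t.id] for t in tree.tips]))
    base_rate = 1.0 / mean_depth if mean_depth > 0 else 1.0
    rng = np.random.default_rng(seed)
    npar = model.n_params
    fingerprint = _data_fingerprint(tree, data)

    def neg_ll(log_theta: np.ndarray) -> float:
        try:
            ll = log_likelihood(tree, data, model.with_theta(np.exp(log_theta)), root)
        except FitError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    log_lo, log_hi = np.log(lo), np.log(hi)
    starts = [np.full(npar, np.log(base_rate))]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.clip(np.log(base_rate) + rng.uniform(-4, 4, size=npar), log_lo, log_hi)
        )
    for extra in extra_starts or ():
        extra = np.asarray(extra, dtype=float)
        if extra.shape != (npar,) or (extra <= 0).any():
            raise ValidationError("extra_starts must be positive rate vectors")
        starts.append(np.clip(np.log(extra), log_lo, log_hi))
    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            neg_ll,
            np.clip(x0, log_lo, log_hi),
            method="L-BFGS-B",
            bounds=[(log_lo, log_hi)] * npar,
            options={"maxiter": maxiter},
        )
        # guard the contract: never return worse than the start point
        if res.fun > neg_ll(x0):
            res.x, res.fun, res.success = x0, neg_ll(x0), False
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    fitted = model.with_theta(theta)
    root_name = root if isinstance(root, str) else "fixed"
    return FitResult(
        model=fitted,
        log_likelihood=float(-best.fun),
        n_params=npar,
        converged=any_converged,
        n_restarts=len(starts),
        root=root_name,
        data_fingerprint=fingerprint,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(nested: FitResult, general: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested model against a more general one.

    The statistic 2(logL_general - logL_nested) is clipped at zero and
    referred to a chi-square with df = difference in free parameter counts.
    When a structural zero places a parameter on its boundary this plain
    chi-square reference is conservative; it is what is reported.
    """
    if nested.n_params >= general.n_params:
        raise ValidationError("nested model must have fewer free parameters")
    if (
        nested.data_fingerprint
        and general.data_fingerprint
        and nested.data_fingerprint != general.data_fingerprint
    ):
        raise ValidationError("fits are not on the same tree and data")
    stat = max(0.0, 2.0 * (general.log_likelihood - nested.log_likelihood))
    df = general.n_params - nested.n_params
    return LRTResult(stat, df, float(chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# marginal ancestral states


@dataclass
class MarginalReconstruction:
    """Per-node marginal state probabilities under a fitted model."""

    states: StateSpace
    probabilities: np.ndarray  # (n_nodes, k), row per node id
    threshold: float
    root_treatment: str

    def top_state(self, node_id: int) -> str:
        """The highest-probability state, or ``"unresolved"`` below threshold."""
        p = self.probabilities[node_id]
        i = int(np.argmax(p))
        return self.states.labels[i] if p[i] > self.threshold else "unresolved"

    def to_table(self, tree: Phylogeny) -> pd.DataFrame:
        rows = {}
        for node in tree.internal_nodes:
            row = {
                f"p_{label}": self.probabilities[node.id, j]
                for j, label in enumerate(self.states.labels)
            }
            row["top_state"] = self.top_state(node.id)
            rows[node.id] = row
        tab = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        tab.index.name = "node_id"
        return tab


def marginal_ancestral_states(
    tree: Phylogeny,
    data: Mapping[str, TipValue],
    model: RateModel,
    root: Union[str, Sequence[float]] = "fitzjohn",
    *,
    threshold: float = 0.75,
) -> MarginalReconstruction:
    """Marginal probability of each state at every node, given all tip data.

    Computed by the standard up-down algorithm: an upward (pruning) pass
    collects the likelihood of the data below each node, a downward pass
    propagates the contribution of everything outside the node's subtree,
    and the product, normalized, is P(node = s | data).  The reporting rule
    flags a single state only when its probability exceeds ``threshold``
    (default 0.75).
    """
    k = model.k
    Q = model.Q
    nonroot = [n for n in tree.nodes if n is not tree.root]
    lengths = np.array([n.length for n in nonroot])
    Pstack = _branch_matrices(Q, lengths)
    P = {n.id: Pstack[i] for i, n in enumerate(nonroot)}
    tip_partials = _tip_partials(tree, data, model.states)
    D, _ = _postorder_partials(tree, tip_partials, P, k)

    pi = _root_prior(root, model, D[tree.root.id])
    U: dict[int, np.ndarray] = {tree.root.id: pi}
    marginals = np.zeros((len(tree), k))
    for node in tree.preorder():
        m = U[node.id] * D[node.id]
        s = m.sum()
        if s <= 0:
            raise FitError(f"zero marginal at node {node.id}")
        marginals[node.id] = m / s
        if node.is_tip:
            continue
        down = [P[c.id] @ D[c.id] for c in node.children]
        for idx, child in enumerate(node.children):
            out = U[node.id].copy()
            for jdx, vec in enumerate(down):
                if jdx != idx:
                    out = out * vec
            om = out.max()
            if om > 0:
                out = out / om
            U[child.id] = out @ P[child.id]
    root_name = root if isinstance(root, str) else "fixed"
    return MarginalReconstruction(model.states, marginals, threshold, root_name)


# ---------------------------------------------------------------------------
# index matrix files


def write_index_matrix(model: RateModel, path: str) -> None:
    """Write the k x k integer index matrix, with state labels as a header."""
    with open(path, "w") as fh:
        fh.write("# states: " + "\t".join(model.states.labels) + "\n")
        for row in model.index_matrix:
            fh.write("\t".join(str(int(x)) for x in row) + "\n")


def read_index_matrix(path: str, states: Optional[StateSpace] = None) -> RateModel:
    """Read an index matrix file written by :func:`write_index_matrix`."""
    labels = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "states:" in line:
                    labels = tuple(line.split("states:", 1)[1].split())
                continue
            rows.append([int(x) for x in line.split()])
    M = np.array(rows, dtype=int)
    if states is None:
        if labels is None:
            labels = tuple(f"s{i}" for i in range(len(rows)))
        states = StateSpace(labels)
    return RateModel(states, M)
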