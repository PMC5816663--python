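"""Brownian-motion ancestral estimation for continuous characters.

The complexity count (number of benzoquinone-pathway compounds produced) is
modelled as an unbounded real evolving by Brownian motion, the same choice
made by contMap-style visualizations of count characters.  Ancestral values
are the maximum-likelihood (joint/GLS) estimates: with tip values x and
shared-path-length covariance C, the root estimate is the GLS mean
a0 = (1' C^-1 x) / (1' C^-1 1), the rate estimate is
sigma^2 = (x - a0 1)' C^-1 (x - a0 1) / n, and every internal node's
estimate is the conditional Gaussian mean given the tips.  Joint ML and
marginal GLS estimates coincide under a Gaussian model, so the estimates
also solve the branch-length-weighted tree Laplacian system.

Negative ancestral estimates are possible for count data near zero; they
are flagged, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from defchem.errors import ValidationError
from defchem.tree import Phylogeny

__all__ = ["BMFit", "BranchPainting", "bm_ancestral_states", "paint_branches"]


@dataclass
class BMFit:
    """Brownian-motion fit: rate, root state, and per-node estimates."""

    sigma2: float
    root_estimate: float
    log_likelihood: float
    estimates: dict[int, float]  # node id -> ancestral (or observed tip) value
    variances: dict[int, float]  # node id -> estimation variance (tips: 0)
    degenerate: bool  # True when all tips are equal (sigma2 = 0)
    has_negative_estimates: bool

    def to_table(self, tree: Phylogeny) -> pd.DataFrame:
        rows = {
            n.id: {
                "estimate": self.estimates[n.id],
                "variance": self.variances[n.id],
                "is_tip": n.is_tip,
            }
            for n in tree.nodes
        }
        tab = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        tab.index.name = "node_id"
        return tab


def _vcv(tree: Phylogeny) -> tuple[np.ndarray, list[int]]:
    """Shared-path-length covariance among tips, plus tip node ids (row order)."""
    tips = tree.tips
    n = len(tips)
    depths = tree.depths()
    # ancestor sets per tip
    anc: dict[int, list[int]] = {}
    for tip in tips:
        path = []
        node = tip
        while node is not None:
            path.append(node.id)
            node = node.parent
        anc[tip.id] = path
    C = np.zeros((n, n))
    ancsets = {tid: set(p) for tid, p in anc.items()}
    for i, ti in enumerate(tips):
        C[i, i] = depths[ti.id]
        for j in range(i + 1, n):
            tj = tips[j]
            shared = ancsets[ti.id] & ancsets[tj.id]
            mrca_depth = max(depths[a] for a in shared)
            C[i, j] = C[j, i] = mrca_depth
    return C, [t.id for t in tips]


def bm_ancestral_states(tree: Phylogeny, data: Mapping[str, float]) -> BMFit:
    """ML ancestral estimates at every internal node under Brownian motion.

    All tips need finite values.  A singular covariance (duplicate
    zero-length terminal paths) is reported as an error naming the
    offending branches; a star tree with equal positive branch lengths is
    fine (root estimate = tip mean).
    """
    tips = tree.tips
    x = np.array([float(data[t.label]) for t in tips])
    if not np.all(np.isfinite(x)):
        raise ValidationError("all tips need finite values")
    n = len(tips)
    if tree.max_depth() <= 0:
        raise ValidationError("tree has zero depth")
    C, tip_ids = _vcv(tree)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        zero = [t.label for t in tips if t.length == 0]
        raise ValidationError(
            "singular tip covariance; zero-length terminal branches: " f"{zero}"
        ) from None
    one = np.ones(n)
    denom = one @ Cinv @ one
    a0 = float((one @ Cinv @ x) / denom)
    resid = x - a0
    sigma2 = float(resid @ Cinv @ resid / n)
    degenerate = bool(np.allclose(x, x[0]))

    # Gaussian log-likelihood at the ML estimates
    if sigma2 > 0:
        sign, logdet = np.linalg.slogdet(C)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    else:
        ll = np.inf  # point mass; flagged via `degenerate`

    depths = tree.depths()
    estimates: dict[int, float] = {}
    variances: dict[int, float] = {}
    for tid, val in zip(tip_ids, x):
        estimates[tid] = float(val)
        variances[tid] = 0.0

    # covariance between an internal node and each tip = depth of their MRCA,
    # which for an ancestor-descendant pair is the depth of the internal node
    # along the tip's path, else the depth of the shared ancestor.
    tip_paths = {}
    for tip in tips:
        path = set()
        node = tip
        while node is not None:
            path.add(node.id)
            node = node.parent
        tip_paths[tip.id] = path
    node_paths = {}
    for node in tree.nodes:
        path = set()
        cur = node
        while cur is not None:
            path.add(cur.id)
            cur = cur.parent
        node_paths[node.id] = path

    for node in tree.internal_nodes:
        cu = np.zeros(n)
        for j, tip in enumerate(tips):
            shared = node_paths[node.id] & tip_paths[tip.id]
            cu[j] = max(depths[a] for a in shared)
        w = Cinv @ cu
        est = a0 + float(w @ resid)
        estimates[node.id] = est
        tu = depths[node.id]
        slack = 1.0 - float(one @ w)
        var = sigma2 * (tu - float(cu @ w) + slack * slack / denom)
        variances[node.id] = max(0.0, float(var))

    has_neg = any(v < 0 for v in estimates.values())
    return BMFit(
        sigma2=sigma2,
        root_estimate=estimates[tree.root.id],
        log_likelihood=float(ll),
        estimates=estimates,
        variances=variances,
        degenerate=degenerate,
        has_negative_estimates=has_neg,
    )


@dataclass
class BranchPainting:
    """Per-edge interpolated values for contMap-style branch painting."""

    segments: dict[int, list[tuple[float, float]]]  # child node id -> [(pos, value)]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for edge_id, pts in self.segments.items():
            for pos, val in pts:
                rows.append({"edge": edge_id, "position": pos, "value": val})
        return pd.DataFrame(rows)


def paint_branches(tree: Phylogeny, fit: BMFit, steps_per_edge: int = 10) -> BranchPainting:
    """Linear interpolation of ancestral estimates along every edge.

    Each edge (identified by its child node id) receives
    ``steps_per_edge + 1`` points from the parent's estimate (position 0)
    to the child's (position 1); ``steps_per_edge=1`` gives endpoints only.
    The interpolant is the Brownian-bridge mean between the two endpoint
    estimates.
    """
    if steps_per_edge < 1:
        raise ValidationError("steps_per_edge must be >= 1")
    segments = {}
    for node in tree.nodes:
        if node.parent is None:
            continue
        a = fit.estimates[node.parent.id]
        b = fit.estimates[node.id]
        pts = [
            (s / steps_per_edge, a + (b - a) * s / steps_per_edge)
            for s in range(steps_per_edge + 1)
        ]
        segments[node.id] = pts
    return BranchPainting(segments)
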