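"""Chronogram estimation by nonparametric rate smoothing (NPRS) plus
offset-exponential fossil-calibration utilities.

NPRS dates the nodes of a phylogram (branch lengths in substitutions/site) by
minimizing the sum of squared differences between the local substitution
rates of ancestor and descendant branches, subject to age constraints; at the
root the variance of the root children's rates is penalized.  The soft
maximum of an offset-exponential calibration prior is its upper quantile
(0.95 by default): offset + mean * (-ln(1 - q)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats, special

logger = logging.getLogger(__name__)

RATE_EPS = 1e-9  # duration floor for zero-length branches


@dataclass
class CalibrationPrior:
    """Offset-exponential node-age prior: hard minimum ``offset`` (Myr) and
    exponential ``mean`` (Myr) above it."""

    offset: float
    mean: float
    taxa: tuple = ()

    def __post_init__(self):
        if self.offset <= 0 or self.mean <= 0:
            raise ValueError("offset and mean must be > 0")

    @property
    def dist(self):
        return stats.expon(loc=self.offset, scale=self.mean)

    def pdf(self, age):
        return self.dist.pdf(age)

    def cdf(self, age):
        return self.dist.cdf(age)


def calibration_soft_bound(prior: CalibrationPrior, quantile: float = 0.95) -> float:
    """Age holding ``quantile`` of the prior mass: the conventional soft
    maximum is the 0.95 quantile, offset - mean * ln(0.05)."""
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    return float(prior.offset - prior.mean * np.log1p(-quantile))


@dataclass
class AgeConstraint:
    """Min and/or max age (Myr) for the MRCA of a set of tip labels (or the
    root when ``taxa`` is empty)."""

    taxa: tuple = ()
    min_age: float | None = None
    max_age: float | None = None

    def __post_init__(self):
        if self.min_age is not None and self.max_age is not None:
            if self.min_age > self.max_age:
                raise ValueError("min_age must be <= max_age")


def _constrained_nodes(tree, constraints):
    out = []
    for c in constraints:
        if c.taxa:
            node = tree.mrca(taxon_labels=list(c.taxa))
            if node is None:
                raise ValueError(f"no MRCA for {c.taxa}")
        else:
            node = tree.seed_node
        out.append((node, c))
    return out


def nprs_smooth(
    tree: dendropy.Tree,
    constraints,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict]:
    """Date a phylogram by nonparametric rate smoothing.

    The root age must be bounded (a constraint on the root, or with both
    min and max on some node propagating a finite root bracket — in practice
    supply a root constraint).  Node ages are parameterized as fractions of
    the feasible interval below their parent, so parent > child holds
    structurally; the objective is minimized with L-BFGS-B from ``restarts``
    jittered starting points.

    Returns (chronogram, diagnostics).  Branch lengths of the returned tree
    are in Myr.
    """
    rng = np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    cons = _constrained_nodes(tree, constraints)
    node_min = {n: 0.0 for n in tree.preorder_node_iter()}
    node_max = {n: np.inf for n in tree.preorder_node_iter()}
    for node, c in cons:
        if node.is_leaf():
            raise ValueError("constraints on tips are not supported")
        if c.min_age is not None:
            node_min[node] = max(node_min[node], c.min_age)
        if c.max_age is not None:
            node_max[node] = min(node_max[node], c.max_age)
    # propagate minima upward (a parent is older than any descendant minimum)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        for ch in node.child_nodes():
            node_min[node] = max(node_min[node], node_min.get(ch, 0.0))
    # propagate maxima downward
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node_max[node] = min(node_max[node], node_max[node.parent_node])
    root = tree.seed_node
    if not np.isfinite(node_max[root]):
        raise ValueError("root age must be bounded from above by a constraint")
    if node_min[root] > node_max[root]:
        raise ValueError("infeasible constraints at the root")
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    blen = {
        n: max(n.edge.length or 0.0, 0.0)
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    }

    def ages_from(x):
        ages = {}
        for leaf in tree.leaf_node_iter():
            ages[leaf] = 0.0
        for i, node in enumerate(internal):
            frac = special.expit(x[i])
            if node is root:
                lo, hi = node_min[root], node_max[root]
            else:
                hi = min(ages[node.parent_node], node_max[node])
                lo = node_min[node]
            ages[node] = lo + frac * max(hi - lo, 0.0)
        return ages

    def rates(ages):
        out = {}
        for node, length in blen.items():
            dur = max(ages[node.parent_node] - ages[node], RATE_EPS)
            out[node] = length / dur
        return out

    def objective(x):
        ages = ages_from(x)
        r = rates(ages)
        w = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                pass
            if node.parent_node is not None and node.parent_node is not root:
                w += (r[node] - r[node.parent_node]) ** 2
        kids = root.child_nodes()
        rbar = np.mean([r[c] for c in kids])
        w += sum((r[c] - rbar) ** 2 for c in kids)
        return w

    best = None
    for i in range(restarts):
        x0 = rng.normal(0, 1.0, len(internal)) if i else np.zeros(len(internal))
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    ages = ages_from(best.x)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = max(ages[node.parent_node] - ages[node], 0.0)
    tree.length_unit = "myr"
    diagnostics = {
        "objective": float(best.fun),
        "restarts": restarts,
        "converged": bool(best.success),
        "root_age": float(ages[root]),
    }
    logger.info("NPRS objective %.6g, root age %.3f", best.fun, ages[root])
    return tree, diagnostics
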