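"""Ancestral-state reconstruction and the trait-correlation test battery:
Mk and Brownian ASR, Pagel's correlated-evolution test for binary characters,
phylogenetic ANOVA with a Brownian simulation null, PGLS regression, the
Mann-Whitney depth comparison, and 500-m depth discretization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import clone_tree, node_ages
from .simulate import (
    ContinuousTraitSpec,
    DiscreteTraitSpec,
    simulate_discrete_trait,
    _as_rng,
)

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """Generic hypothesis-test record."""

    name: str
    statistic: dict
    df: dict
    p_value: float | None
    p_phylo: float | None = None
    n_species: int = 0

    def __post_init__(self):
        for p in (self.p_value, self.p_phylo):
            if p is not None:
                assert 0 <= p <= 1


# ---------------------------------------------------------------------------
# depth discretization


@dataclass(frozen=True)
class DepthStateSet:
    """1-based indices of the 500-m depth bins a species' range occupies."""

    bins: frozenset
    bin_width: float = 500.0

    def __post_init__(self):
        b = sorted(self.bins)
        assert b, "a depth range occupies at least one bin"
        assert b == list(range(b[0], b[-1] + 1)), "bins must be contiguous"


def discretize_depth(
    depth_min: float, depth_max: float, bin_width: float = 500.0
) -> DepthStateSet:
    """Bins [0, 500), [500, 1000), ... intersected by [depth_min, depth_max];
    a maximum falling exactly on a bin boundary closes the bin below it."""
    if depth_min < 0 or depth_max < depth_min:
        raise ValueError("need 0 <= depth_min <= depth_max")
    lo = int(depth_min // bin_width)
    if depth_max > 0 and depth_max % bin_width == 0:
        hi = int(depth_max // bin_width) - 1
    else:
        hi = int(depth_max // bin_width)
    hi = max(hi, lo)
    return DepthStateSet(bins=frozenset(range(lo + 1, hi + 2)), bin_width=bin_width)


def depth_state_table(traits: pd.DataFrame, bin_width: float = 500.0):
    """Per-species depth bin sets plus the global bin count."""
    sub = traits.dropna(subset=["depth_min_m", "depth_max_m"])
    sets = {
        row["species"]: discretize_depth(
            row["depth_min_m"], row["depth_max_m"], bin_width
        )
        for _, row in sub.iterrows()
    }
    nbins = max((max(s.bins) for s in sets.values()), default=0)
    return sets, nbins


# ---------------------------------------------------------------------------
# Mk machinery


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for every branch length, via one eigendecomposition
    (falls back to expm when Q is defective)."""
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(lengths, w)), Vinv)
        P = np.real(P)
        if not np.all(np.isfinite(P)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * t) for t in lengths])
    return np.clip(P, 0.0, None)


def _mk_pruning(tree, tip_partials, Q, root_prior):
    """Felsenstein pruning; returns (lnL, per-node up/msg caches for the
    marginal pass)."""
    nodes = list(tree.postorder_node_iter())
    lengths = np.array(
        [n.edge.length or 0.0 for n in nodes if n.parent_node is not None]
    )
    Pmap = {}
    P_all = _transition_matrices(Q, lengths)
    idx = 0
    for n in nodes:
        if n.parent_node is not None:
            Pmap[n] = P_all[idx]
            idx += 1
    up, msg = {}, {}
    logscale = 0.0
    for n in nodes:
        if n.is_leaf():
            up[n] = tip_partials[n.taxon.label].astype(float)
        else:
            u = np.ones(Q.shape[0])
            for c in n.child_nodes():
                msg[c] = Pmap[c] @ up[c]
                u = u * msg[c]
            s = u.sum()
            if s <= 0:
                return -np.inf, None
            logscale += np.log(s)
            up[n] = u / s
    lnl = logscale + np.log(np.dot(root_prior, up[tree.seed_node]))
    return float(lnl), (up, msg, Pmap)


def _mk_marginals(tree, caches, root_prior):
    up, msg, Pmap = caches
    outside = {tree.seed_node: np.asarray(root_prior, float)}
    probs = {}
    for n in tree.preorder_node_iter():
        if n.is_leaf():
            continue
        pre = outside[n]
        m = up[n] * pre
        probs[n] = m / m.sum()
        for c in n.child_nodes():
            sib = pre.copy()
            for s in n.child_nodes():
                if s is not c:
                    sib = sib * msg[s]
            outside[c] = sib @ Pmap[c]
    return probs


@dataclass
class AsrResult:
    node_probs: pd.DataFrame
    lnl: float
    Q: np.ndarray | None = None
    states: list | None = None
    sigma2: float | None = None
    root_value: float | None = None


def _label_nodes(tree):
    labels = {}
    for i, n in enumerate(tree.preorder_node_iter()):
        if not n.is_leaf():
            labels[n] = f"node{i}"
    return labels


def mk_asr(
    tree,
    states: dict,
    model: str = "ER",
    root_prior: str = "flat",
) -> AsrResult:
    """ML Mk ancestral-state reconstruction with marginal node probabilities.

    ``states`` maps tip label -> state (hashable) or an iterable of states
    for multistate/ambiguous tips (partial likelihood 1 on each occupied
    state).  ``model`` is ``"ER"`` (single symmetric rate, default) or
    ``"ARD"`` (all rates different).
    """
    cats = sorted({s for v in states.values() for s in _as_state_set(v)})
    k = len(cats)
    if k < 2:
        raise ValueError("need >= 2 observed states for reconstruction")
    index = {c: i for i, c in enumerate(cats)}
    tip_partials = {}
    for label, v in states.items():
        vec = np.zeros(k)
        for s in _as_state_set(v):
            vec[index[s]] = 1.0
        tip_partials[label] = vec
    prior = np.full(k, 1.0 / k)

    def build_q(rates):
        Q = np.zeros((k, k))
        if model == "ER":
            Q[:] = rates[0]
        else:
            it = iter(rates)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = next(it)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    nrates = 1 if model == "ER" else k * (k - 1)
    depth = max(node_ages(tree).values())

    def neg(logr):
        lnl, _ = _mk_pruning(tree, tip_partials, build_q(np.exp(logr)), prior)
        return -lnl

    x0 = np.log(np.full(nrates, 1.0 / depth))
    if nrates == 1:
        res = optimize.minimize_scalar(
            lambda x: neg([x]), bounds=(np.log(1e-6 / depth), np.log(1e3 / depth)),
            method="bounded",
        )
        rates = np.exp([res.x])
    else:
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"maxiter": 5000, "fatol": 1e-9})
        rates = np.exp(res.x)
    Q = build_q(rates)
    lnl, caches = _mk_pruning(tree, tip_partials, Q, prior)
    probs = _mk_marginals(tree, caches, prior)
    labels = _label_nodes(tree)
    ages = node_ages(tree)
    rows = [
        {"node": labels[n], "age": ages[n],
         **{f"p_{c}": probs[n][index[c]] for c in cats}}
        for n in probs
    ]
    return AsrResult(
        node_probs=pd.DataFrame(rows), lnl=lnl, Q=Q, states=cats
    )


def _as_state_set(v):
    if isinstance(v, (set, frozenset, list, tuple)):
        return set(v)
    return {v}


def mk_loglik(tree, states: dict, Q: np.ndarray, root_prior=None) -> float:
    """Mk log-likelihood at a fixed rate matrix (flat root prior default)."""
    cats = sorted({s for v in states.values() for s in _as_state_set(v)})
    k = Q.shape[0]
    if len(cats) > k:
        raise ValueError("more observed states than matrix dimension")
    index = {c: i for i, c in enumerate(cats)}
    tips = {}
    for label, v in states.items():
        vec = np.zeros(k)
        for s in _as_state_set(v):
            vec[index[s]] = 1.0
        tips[label] = vec
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    lnl, _ = _mk_pruning(tree, tips, Q, prior)
    return lnl


# ---------------------------------------------------------------------------
# Brownian motion: covariance, ASR, likelihood


def _tip_order(tree):
    return [l.taxon.label for l in tree.leaf_node_iter()]


def bm_covariance(tree) -> tuple[np.ndarray, list]:
    """Brownian covariance of tip values: shared root-to-MRCA path lengths
    (in time units) per unit rate."""
    tips = _tip_order(tree)
    pos = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    ages = node_ages(tree)
    root_age = ages[tree.seed_node]
    C = np.zeros((n, n))
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [pos[node.taxon.label]]
            C[below[node][0], below[node][0]] = root_age
            continue
        kids = node.child_nodes()
        depth = root_age - ages[node]
        merged = []
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in below[kids[a]]:
                    for j in below[kids[b]]:
                        C[i, j] = C[j, i] = depth
            merged.extend(below[kids[a]])
        merged.extend(below[kids[-1]])
        below[node] = merged
    return C, tips


def bm_fit(tree, values: dict[str, float]):
    """ML Brownian fit: root value (GLS mean), rate sigma2, log-likelihood."""
    C, tips = bm_covariance(tree)
    y = np.array([values[t] for t in tips], float)
    n = y.size
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    mu = (one @ Cinv @ y) / (one @ Cinv @ one)
    resid = y - mu
    sigma2 = (resid @ Cinv @ resid) / n
    sign, logdet = np.linalg.slogdet(C)
    lnl = -0.5 * (
        n * np.log(2 * np.pi * sigma2) + logdet + n
    )
    return float(mu), float(sigma2), float(lnl), C, tips


def bm_asr(tree, values: dict[str, float], log_input: bool = False) -> AsrResult:
    """Brownian ancestral means and variances by GLS.

    With ``log_input=True`` the values are natural-logged first (e.g. shell
    lengths in mm) and must be positive.
    """
    vals = dict(values)
    if log_input:
        if any(v <= 0 for v in vals.values()):
            raise ValueError("values must be positive before log transform")
        vals = {k: float(np.log(v)) for k, v in vals.items()}
    if len(vals) < 3:
        raise ValueError("need >= 3 tip values")
    mu, sigma2, lnl, C, tips = bm_fit(tree, vals)
    y = np.array([vals[t] for t in tips])
    Cinv = np.linalg.inv(C)
    ages = node_ages(tree)
    root_age = ages[tree.seed_node]
    pos = {t: i for i, t in enumerate(tips)}
    labels = _label_nodes(tree)
    # cross-covariance of an internal node with each tip: shared path length
    below_cache = {}
    rows = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below_cache[node] = {pos[node.taxon.label]}
        else:
            s = set()
            for c in node.child_nodes():
                s |= below_cache[c]
            below_cache[node] = s
    tip_mrca_depth = np.zeros(len(tips))
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        depth_v = root_age - ages[node]
        cvec = np.empty(len(tips))
        for t, i in pos.items():
            # shared path = depth of MRCA(node, tip i); walk up from node
            anc = node
            while i not in below_cache[anc]:
                anc = anc.parent_node
            cvec[i] = root_age - ages[anc]
        w = Cinv @ cvec
        mean_v = mu + w @ (y - mu)
        var_v = sigma2 * (depth_v - cvec @ w)
        rows.append(
            {"node": labels[node], "age": ages[node],
             "mean": float(mean_v), "variance": float(max(var_v, 0.0))}
        )
    return AsrResult(
        node_probs=pd.DataFrame(rows), lnl=lnl, sigma2=sigma2, root_value=mu
    )


# ---------------------------------------------------------------------------
# Pagel's correlated-evolution test


def _binary_P(a: float, b: float, lengths: np.ndarray) -> np.ndarray:
    """Closed-form 2-state transition matrices for rates 0->1 = a, 1->0 = b."""
    s = a + b
    out = np.empty((lengths.size, 2, 2))
    if s == 0:
        out[:] = np.eye(2)
        return out
    e = np.exp(-s * lengths)
    out[:, 0, 0] = (b + a * e) / s
    out[:, 0, 1] = (a - a * e) / s
    out[:, 1, 0] = (b - b * e) / s
    out[:, 1, 1] = (a + b * e) / s
    return out


def _prune_scaled_py(parents, P, up):
    """Scaled postorder pruning over flattened arrays; returns the summed log
    scaling factors (partials are renormalized after every child)."""
    logscale = 0.0
    for i in range(up.shape[0]):
        p = parents[i]
        if p < 0:
            continue
        msg = P[i] @ up[i]
        up[p] = up[p] * msg
        s = up[p].sum()
        if s <= 0 or not np.isfinite(s):
            return -np.inf
        up[p] /= s
        logscale += np.log(s)
    return logscale


try:  # hot loops of the Monte-Carlo tests; fall back to pure Python
    from numba import njit

    _prune_scaled = njit(cache=False)(_prune_scaled_py)

    @njit(cache=False)
    def _joint_neg_core(rates, parents, lengths, tip_rows, joint_states, root):
        # dependent-model generator on joint states (x,y) = 00,01,10,11
        Q = np.zeros((4, 4))
        Q[0, 2], Q[1, 3] = rates[0], rates[1]
        Q[2, 0], Q[3, 1] = rates[2], rates[3]
        Q[0, 1], Q[2, 3] = rates[4], rates[5]
        Q[1, 0], Q[3, 2] = rates[6], rates[7]
        for i in range(4):
            Q[i, i] = 0.0
            Q[i, i] = -Q[i].sum()
        nnodes = parents.shape[0]
        up = np.ones((nnodes, 4))
        for t in range(tip_rows.shape[0]):
            row = tip_rows[t]
            for j in range(4):
                up[row, j] = 0.0
            up[row, joint_states[t]] = 1.0
        logscale = 0.0
        eye = np.eye(4)
        for i in range(nnodes):
            p = parents[i]
            if p < 0:
                continue
            # expm(Q * t) by scaling-and-squaring a 6th-order Taylor series
            A = Q * lengths[i]
            nrm = np.abs(A).sum() / 4.0
            s = 0
            while nrm > 0.25:
                nrm *= 0.5
                s += 1
            A = A / (2.0 ** s)
            P = eye.copy()
            term = eye.copy()
            for k in range(1, 7):
                term = (term @ A) / k
                P = P + term
            for _ in range(s):
                P = P @ P
            msg = P @ up[i]
            up[p] = up[p] * msg
            tot = up[p].sum()
            if tot <= 0 or not np.isfinite(tot):
                return np.inf
            up[p] /= tot
            logscale += np.log(tot)
        return -(logscale + np.log(0.25 * up[root].sum()))

except ImportError:  # pragma: no cover
    _prune_scaled = _prune_scaled_py
    _joint_neg_core = None


def _binary_loglik(tree_cache, tip_states: np.ndarray, a: float, b: float) -> float:
    """Pruning likelihood for one binary trait; tree_cache from _tree_cache."""
    parents, lengths, tip_rows, nnodes, root = tree_cache
    P = _binary_P(a, b, lengths)
    up = np.ones((nnodes, 2))
    for row, st in zip(tip_rows, tip_states):
        if st >= 0:
            up[row] = 0.0
            up[row, st] = 1.0
    logscale = _prune_scaled(parents, P, up)
    if not np.isfinite(logscale):
        return -np.inf
    return float(logscale + np.log(0.5 * up[root].sum()))


def _tree_cache(tree):
    """Flatten a tree for fast repeated pruning: postorder arrays of parent
    indices and branch lengths, children contiguous."""
    order = []
    index = {}

    def visit(node):
        for c in node.child_nodes():
            visit(c)
        index[node] = len(order)
        order.append(node)

    visit(tree.seed_node)
    # re-emit with children-of-same-parent contiguous (postorder already is)
    parents = np.array(
        [index[n.parent_node] if n.parent_node else -1 for n in order]
    )
    lengths = np.array([n.edge.length or 0.0 for n in order])
    tip_rows = [index[n] for n in order if n.is_leaf()]
    tip_labels = [n.taxon.label for n in order if n.is_leaf()]
    return (parents, lengths, np.array(tip_rows), len(order), index[tree.seed_node]), tip_labels


def _fit_binary(tree_cache, tip_states, restarts, rng, depth):
    def neg(x):
        return -_binary_loglik(tree_cache, tip_states, *np.exp(x))

    x0 = np.log([1.0 / depth, 1.0 / depth])
    best = None
    for i in range(restarts):
        start = x0 if i == 0 else x0 + rng.normal(0, 1.2, 2)
        res = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -best.fun


def _dependent_Q(rates) -> np.ndarray:
    """8-parameter joint generator on states (x,y) = 00, 01, 10, 11; no
    simultaneous double transitions."""
    (ax_y0, ax_y1, bx_y0, bx_y1, ay_x0, ay_x1, by_x0, by_x1) = rates
    Q = np.zeros((4, 4))
    Q[0, 2], Q[1, 3] = ax_y0, ax_y1  # x: 0->1 given y
    Q[2, 0], Q[3, 1] = bx_y0, bx_y1  # x: 1->0
    Q[0, 1], Q[2, 3] = ay_x0, ay_x1  # y: 0->1 given x
    Q[1, 0], Q[3, 2] = by_x0, by_x1  # y: 1->0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _joint_loglik(tree_cache, joint_states, Q) -> float:
    parents, lengths, tip_rows, nnodes, root = tree_cache
    P = _transition_matrices(Q, lengths)
    up = np.ones((nnodes, 4))
    for row, st in zip(tip_rows, joint_states):
        up[row] = 0.0
        up[row, st] = 1.0
    logscale = _prune_scaled(parents, P, up)
    if not np.isfinite(logscale):
        return -np.inf
    return float(logscale + np.log(0.25 * up[root].sum()))


def pagel_correlation_test(
    tree,
    x: dict[str, int],
    y: dict[str, int],
    restarts: int = 10,
    sims: int = 1000,
    seed=None,
) -> TestResult:
    """Pagel's test of correlated evolution of two binary characters: the
    4-rate independent model (each trait evolves on its own 2-state chain)
    against the 8-rate dependent model (each trait's rates depend on the
    other's state).  The statistic is Delta logL; the Monte-Carlo p-value
    refits both models to data simulated under the fitted independent model.
    """
    rng = _as_rng(seed)
    tips = sorted(set(x) & set(y))
    xs = np.array([int(x[t]) for t in tips])
    ys = np.array([int(y[t]) for t in tips])
    for arr, nm in ((xs, "x"), (ys, "y")):
        if len(np.unique(arr)) < 2:
            raise ValueError(f"trait {nm} is constant after pruning")
    sub = clone_tree(tree)
    sub.retain_taxa_with_labels(tips)
    sub.purge_taxon_namespace()
    cache, tip_labels = _tree_cache(sub)
    order = [tips.index(l) for l in tip_labels]
    xs, ys = xs[order], ys[order]
    depth = max(node_ages(sub).values())

    def delta_stat(xv, yv):
        (a1, b1), l1 = _fit_binary(cache, xv, restarts, rng, depth)
        (a2, b2), l2 = _fit_binary(cache, yv, restarts, rng, depth)
        lnl_ind = l1 + l2

        joint = 2 * xv + yv
        lo, hi = np.log(1e-8 / depth), np.log(200.0 / depth)
        parents, lengths, tip_rows, _, root = cache

        def neg_dep(logr):
            if np.any(logr < lo) or np.any(logr > hi):
                return np.inf
            with np.errstate(all="ignore"):
                if _joint_neg_core is not None:
                    return _joint_neg_core(
                        np.exp(logr), parents, lengths, tip_rows,
                        joint, root,
                    )
                return -_joint_loglik(cache, joint, _dependent_Q(np.exp(logr)))

        x0 = np.clip(np.log([a1, a1, b1, b1, a2, a2, b2, b2]), lo + 1, hi - 1)
        best = None
        for i in range(restarts):
            start = x0 if i == 0 else x0 + rng.normal(0, 1.0, 8)
            res = optimize.minimize(neg_dep, start, method="Nelder-Mead",
                                    options={"maxiter": 500, "xatol": 1e-4,
                                             "fatol": 1e-6})
            if best is None or res.fun < best.fun:
                best = res
        lnl_dep = max(-best.fun, lnl_ind)  # nested
        return lnl_dep - lnl_ind, (a1, b1, a2, b2)

    delta_obs, indep_rates = delta_stat(xs, ys)
    a1, b1, a2, b2 = indep_rates
    spec1 = DiscreteTraitSpec(
        Q=np.array([[-a1, a1], [b1, -b1]]), root_probs=np.array([0.5, 0.5])
    )
    spec2 = DiscreteTraitSpec(
        Q=np.array([[-a2, a2], [b2, -b2]]), root_probs=np.array([0.5, 0.5])
    )
    count = 0
    for _ in range(sims):
        while True:
            sx = simulate_discrete_trait(sub, spec1, rng)
            sy = simulate_discrete_trait(sub, spec2, rng)
            xv = np.array([sx[l] for l in tip_labels])
            yv = np.array([sy[l] for l in tip_labels])
            if len(np.unique(xv)) > 1 and len(np.unique(yv)) > 1:
                break
        d, _ = delta_stat(xv, yv)
        if d >= delta_obs:
            count += 1
    p = (1.0 + count) / (1.0 + sims)
    return TestResult(
        name="pagel",
        statistic={"delta_logL": float(delta_obs)},
        df={"extra_rates": 4},
        p_value=None,
        p_phylo=float(p),
        n_species=len(tips),
    )


# ---------------------------------------------------------------------------
# phylogenetic ANOVA


def _anova_F(y: np.ndarray, groups: np.ndarray):
    """One-way ANOVA F; vectorized over columns of y when 2-D."""
    y = np.atleast_2d(y.T).T  # (n, m)
    n = y.shape[0]
    labels = np.unique(groups)
    k = labels.size
    grand = y.mean(axis=0)
    ssb = np.zeros(y.shape[1])
    ssw = np.zeros(y.shape[1])
    for g in labels:
        mask = groups == g
        gm = y[mask].mean(axis=0)
        ssb += mask.sum() * (gm - grand) ** 2
        ssw += ((y[mask] - gm) ** 2).sum(axis=0)
    F = (ssb / (k - 1)) / (ssw / (n - k))
    return F, k - 1, n - k


def phylo_anova(
    tree,
    y: dict[str, float],
    groups: dict[str, str],
    sims: int = 5000,
    seed=None,
) -> TestResult:
    """Phylogenetic ANOVA: the ordinary F statistic referred to a null
    distribution of F values computed from Brownian-motion data simulated on
    the tree (rate estimated from the data), alongside the parametric p."""
    rng = _as_rng(seed)
    tips = [t for t in _tip_order(tree) if t in y and t in groups]
    if set(tips) != set(_tip_order(tree)):
        tree = clone_tree(tree)
        tree.retain_taxa_with_labels(tips)
        tree.purge_taxon_namespace()
    order = _tip_order(tree)
    yv = np.array([float(y[t]) for t in order])
    gv = np.array([groups[t] for t in order])
    labs, cnt = np.unique(gv, return_counts=True)
    if labs.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(cnt < 2):
        raise ValueError(f"singleton groups: {labs[cnt < 2].tolist()}")
    F_obs, df1, df2 = _anova_F(yv, gv)
    F_obs = float(F_obs[0])
    p_param = float(stats.f.sf(F_obs, df1, df2))
    _, sigma2, _, C, _ = bm_fit(tree, dict(zip(order, yv)))
    L = np.linalg.cholesky(C * max(sigma2, 1e-12))
    z = L @ rng.standard_normal((len(order), sims))
    F_sim, _, _ = _anova_F(z, gv)
    p_phylo = float((1.0 + np.sum(F_sim >= F_obs)) / (1.0 + sims))
    return TestResult(
        name="phylo_anova",
        statistic={"F": F_obs},
        df={"between": df1, "within": df2},
        p_value=p_param,
        p_phylo=p_phylo,
        n_species=len(order),
    )


# ---------------------------------------------------------------------------
# PGLS


def pgls_fit(tree, y: dict[str, float], x: dict[str, float]) -> TestResult:
    """Phylogenetic generalized least squares of y on x with Brownian error
    covariance (shared path lengths); reports intercept/slope t statistics,
    the overall F and residual degrees of freedom."""
    import statsmodels.api as sm

    tips = [t for t in _tip_order(tree) if t in y and t in x]
    if len(tips) < 4:
        raise ValueError("need >= 4 complete cases")
    if set(tips) != set(_tip_order(tree)):
        tree = clone_tree(tree)
        tree.retain_taxa_with_labels(tips)
        tree.purge_taxon_namespace()
    order = _tip_order(tree)
    C, _ = bm_covariance(tree)
    yv = np.array([float(y[t]) for t in order])
    xv = np.array([float(x[t]) for t in order])
    X = np.column_stack([np.ones_like(xv), xv])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design (constant predictor?)")
    res = sm.GLS(yv, X, sigma=C).fit()
    return TestResult(
        name="pgls",
        statistic={
            "intercept": float(res.params[0]),
            "slope": float(res.params[1]),
            "t_intercept": float(res.tvalues[0]),
            "t_slope": float(res.tvalues[1]),
            "F": float(res.fvalue),
        },
        df={"model": int(res.df_model), "resid": int(res.df_resid)},
        p_value=float(res.f_pvalue),
        n_species=len(order),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney depth comparison


def mann_whitney_depth(
    depths_a, depths_b, exact_limit: int = 12
) -> TestResult:
    """Two-sided Mann-Whitney U comparison of species depths between habitat
    groups; exact p for small samples, normal approximation (tie-corrected)
    otherwise."""
    a = np.asarray(list(depths_a), float)
    b = np.asarray(list(depths_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= exact_limit and b.size <= exact_limit
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        name="mann_whitney",
        statistic={"U": float(res.statistic)},
        df={},
        p_value=float(min(res.pvalue, 1.0)),
        n_species=a.size + b.size,
    )


def pooled_habitat(habitat: pd.Series) -> pd.Series:
    """Pool vent and seep into one chemosynthetic-habitat category (organic
    falls kept separate)."""
    return habitat.map(
        lambda h: "vent+seep" if h in ("vent", "seep") else h
    )
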