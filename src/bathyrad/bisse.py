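"""Binary-state speciation and extinction (BiSSE) likelihood and the
Yule-constrained character-dependent test.

The likelihood integrates the coupled extinction/data (E/D) equations
backward along branches,

    dE_i/dt = mu_i - (lambda_i + mu_i + q_ij) E_i + q_ij E_j + lambda_i E_i^2
    dD_i/dt = -(lambda_i + mu_i + q_ij) D_i + q_ij D_j + 2 lambda_i E_i D_i,

multiplies the D vectors elementwise by the state's lambda at every internal
node (including the root), and combines the two root-state likelihoods either
with equal weights or with weights proportional to the D values themselves
(FitzJohn-style; the default).  State-specific sampling fractions enter the
tip initial conditions: D_i = rho_i for an observed (or ambiguous) state i,
E_i(0) = 1 - rho_i.

Because E(t) depends on age only — not on the branch — the D system is a
linear time-varying ODE shared across branches; its fundamental matrix is
integrated once per parameter vector and branch propagation reduces to 2x2
solves.  When all mu = 0 and sampling is complete E vanishes identically and
propagation is a constant-matrix exponential, diagonalized once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.integrate import solve_ivp

from .phylo import node_ages

logger = logging.getLogger(__name__)


@dataclass
class BisseParams:
    lam0: float
    lam1: float
    mu0: float = 0.0
    mu1: float = 0.0
    q01: float = 0.0
    q10: float = 0.0
    rho0: float = 1.0
    rho1: float = 1.0

    def __post_init__(self):
        vals = [self.lam0, self.lam1, self.mu0, self.mu1, self.q01, self.q10]
        if any(v < 0 for v in vals):
            raise ValueError("all rates must be >= 0")
        if not (0 < self.rho0 <= 1 and 0 < self.rho1 <= 1):
            raise ValueError("sampling fractions must be in (0, 1]")

    @property
    def no_extinction(self) -> bool:
        return (
            self.mu0 == 0 and self.mu1 == 0
            and self.rho0 == 1 and self.rho1 == 1
        )


def _tip_vector(state, params: BisseParams) -> np.ndarray:
    """Initial D for a tip: an observed state, ``None``/NaN for ambiguity,
    or a pair of state probabilities (e.g. a posterior summary of an
    inferred tip pattern)."""
    rho = np.array([params.rho0, params.rho1])
    if state is None or (isinstance(state, float) and np.isnan(state)):
        return rho.copy()
    if isinstance(state, (tuple, list, np.ndarray)):
        probs = np.asarray(state, float)
        if probs.shape != (2,) or np.any(probs < 0) or probs.sum() <= 0:
            raise ValueError("tip state probabilities must be two non-negatives")
        return rho * probs / probs.sum()
    state = int(state)
    if state not in (0, 1):
        raise ValueError(f"tip states must be binary, got {state!r}")
    d = np.zeros(2)
    d[state] = rho[state]
    return d


class _Propagator:
    """Propagates D vectors from a younger to an older age."""

    def __init__(self, params: BisseParams, max_age: float):
        self.params = params
        lam = np.array([params.lam0, params.lam1])
        mu = np.array([params.mu0, params.mu1])
        q = np.array([params.q01, params.q10])
        self.lam, self.mu, self.q = lam, mu, q
        if params.no_extinction:
            A = np.array(
                [[-(lam[0] + q[0]), q[0]], [q[1], -(lam[1] + q[1])]]
            )
            w, V = np.linalg.eig(A)
            self.w, self.V, self.Vinv = w.real, V.real, np.linalg.inv(V).real
            self.E_sol = None
            self.Phi = None
        else:
            def dE(t, E):
                return (
                    mu
                    - (lam + mu + q) * E
                    + q * E[::-1]
                    + lam * E ** 2
                )

            self.E_sol = solve_ivp(
                dE, (0.0, max_age), 1.0 - np.array([params.rho0, params.rho1]),
                dense_output=True, rtol=1e-9, atol=1e-12, method="LSODA",
            )
            if not self.E_sol.success:
                raise RuntimeError("E integration failed")

            def dPhi(t, phi):
                E = self.E_sol.sol(t)
                A = np.array(
                    [
                        [-(lam[0] + mu[0] + q[0]) + 2 * lam[0] * E[0], q[0]],
                        [q[1], -(lam[1] + mu[1] + q[1]) + 2 * lam[1] * E[1]],
                    ]
                )
                return (A @ phi.reshape(2, 2)).ravel()

            sol = solve_ivp(
                dPhi, (0.0, max_age), np.eye(2).ravel(),
                dense_output=True, rtol=1e-10, atol=1e-14, method="LSODA",
            )
            if not sol.success:
                raise RuntimeError("D fundamental-matrix integration failed")
            self.Phi = sol.sol

    def E_at(self, t: float) -> np.ndarray:
        if self.E_sol is None:
            return np.zeros(2)
        return self.E_sol.sol(t)

    def up(self, d: np.ndarray, t_young: float, t_old: float) -> np.ndarray:
        dt = t_old - t_young
        if dt < 0:
            raise ValueError("negative branch duration")
        if self.Phi is None:
            P = (self.V * np.exp(self.w * dt)) @ self.Vinv
            return P @ d
        phi_old = self.Phi(t_old).reshape(2, 2)
        phi_young = self.Phi(t_young).reshape(2, 2)
        return phi_old @ np.linalg.solve(phi_young, d)


class BisseTreeCache:
    """Flattened postorder arrays of an ultrametric binary tree plus tip
    state vectors, for fast repeated likelihood evaluation."""

    def __init__(self, tree, states):
        ages = node_ages(tree)
        order = list(tree.postorder_node_iter())
        index = {n: i for i, n in enumerate(order)}
        for n in order:
            if not n.is_leaf() and len(n.child_nodes()) != 2:
                raise ValueError(
                    "BiSSE requires a binary tree; resolve polytomies first"
                )
        self.n_nodes = len(order)
        self.parents = np.array(
            [index[n.parent_node] if n.parent_node else -1 for n in order]
        )
        self.age_young = np.array([ages[n] for n in order])
        self.age_old = np.array(
            [ages[n.parent_node] if n.parent_node else ages[n] for n in order]
        )
        self.is_tip = np.array([n.is_leaf() for n in order])
        self.root = index[tree.seed_node]
        self.root_age = ages[tree.seed_node]
        self.tip_states = {}
        for n in order:
            if n.is_leaf():
                label = n.taxon.label
                if label not in states:
                    raise ValueError(f"no state for tip {label!r}")
                self.tip_states[index[n]] = states[label]


def _bisse_loglik_cached(
    cache: BisseTreeCache,
    params: BisseParams,
    root: str = "fitzjohn",
    condition_on_survival: bool = False,
) -> float:
    prop = _Propagator(params, max_age=cache.root_age * (1 + 1e-9))
    D = np.zeros((cache.n_nodes, 2))
    for i, st in cache.tip_states.items():
        D[i] = _tip_vector(st, params)
    nkids = np.zeros(cache.n_nodes, dtype=int)
    dt = cache.age_old - cache.age_young
    if prop.Phi is None:
        # constant propagator: all branch matrices in one vectorized einsum
        P = np.einsum(
            "ij,tj,jk->tik", prop.V, np.exp(np.outer(dt, prop.w)), prop.Vinv
        )
    else:
        P = None
    logscale = 0.0
    for i in range(cache.n_nodes):
        p = cache.parents[i]
        if p < 0:
            continue
        if not cache.is_tip[i]:
            D[i] = D[i] * prop.lam
            s = D[i].sum()
            if not np.isfinite(s) or s <= 0:
                raise RuntimeError(
                    f"D underflow at node of age {cache.age_young[i]:.3f}"
                )
            logscale += np.log(s)
            D[i] /= s
        up = (
            P[i] @ D[i]
            if P is not None
            else prop.up(D[i], cache.age_young[i], cache.age_old[i])
        )
        if not np.all(np.isfinite(up)) or up.sum() <= 0 or np.any(up < -1e-9):
            raise RuntimeError(
                f"D integration failed on the branch spanning ages "
                f"{cache.age_young[i]:.3f}-{cache.age_old[i]:.3f}"
            )
        if nkids[p] == 0:
            D[p] = np.maximum(up, 0.0)
        else:
            D[p] = D[p] * np.maximum(up, 0.0)
        nkids[p] += 1
    d_root = D[cache.root] * prop.lam
    s = d_root.sum()
    logscale += np.log(s)
    d_root = d_root / s
    if root == "fitzjohn":
        w = d_root / d_root.sum()
    elif root == "equal":
        w = np.array([0.5, 0.5])
    else:
        raise ValueError(f"unknown root treatment {root!r}")
    if condition_on_survival:
        e_root = prop.E_at(cache.root_age)
        denom = np.sum(w * prop.lam * (1 - e_root) ** 2)
        return float(logscale + np.log(np.sum(w * d_root)) - np.log(denom))
    return float(logscale + np.log(np.sum(w * d_root)))


def bisse_loglik(
    tree,
    states: dict[str, int | None],
    params: BisseParams,
    root: str = "fitzjohn",
    condition_on_survival: bool = False,
) -> float:
    """BiSSE log-likelihood of a binary-state character on an ultrametric
    binary tree.  ``states`` maps tip labels to 0/1 (``None``/NaN = missing,
    treated as ambiguous).  ``root`` is ``"fitzjohn"`` (weights proportional
    to the root D values, the default) or ``"equal"``."""
    cache = BisseTreeCache(tree, states)
    return _bisse_loglik_cached(cache, params, root, condition_on_survival)


def yule_tree_loglik(tree, lam: float) -> float:
    """Joint density of a labelled Yule tree: one speciation factor per
    internal node (root included) and exponential survivorship along every
    branch; the factorization partner of state-independent BiSSE."""
    nint = sum(1 for _ in tree.preorder_internal_node_iter())
    tbl = sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    )
    return float(nint * np.log(lam) - lam * tbl)


@dataclass
class SseTestResult:
    lnl_h1: float
    lnl_h0: float
    lam0: float
    lam1: float
    lam_yule: float
    q01: float
    q10: float
    lr: float
    p_value: float

    def __post_init__(self):
        assert self.lr >= -1e-6
        assert 0 <= self.p_value <= 1


def fit_sse_models(
    tree,
    states: dict[str, int | None],
    sampling: tuple[float, float] = (1.0, 1.0),
    root: str = "fitzjohn",
    restarts: int = 3,
) -> SseTestResult:
    """Fit the character-dependent (H1: free lambda0, lambda1) and
    state-independent (H0: lambda0 = lambda1 = lambda_Yule) Yule-constrained
    BiSSE models and report the 1-d.f. likelihood-ratio test.

    ``sampling`` gives the fraction of extant species in each state included
    in the tree.  Extinction is fixed at zero in both hypotheses (a full-BiSSE
    mode is available through :func:`bisse_loglik` directly).
    """
    observed = [s for s in states.values() if s is not None]
    if len(observed) < 10:
        raise ValueError("need >= 10 tips with observed states")
    rho0, rho1 = sampling
    ntips = sum(1 for _ in tree.leaf_node_iter())
    tbl = sum(
        n.edge.length or 0.0
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    )
    lam_init = max(ntips - 1, 1) / tbl
    q_init = 10.0 / tbl

    def make_params(lams, qs):
        return BisseParams(
            lam0=lams[0], lam1=lams[1], q01=qs[0], q10=qs[1],
            rho0=rho0, rho1=rho1,
        )

    cache = BisseTreeCache(tree, states)

    def neg_h0(x):
        lam, q01, q10 = np.exp(x)
        try:
            return -_bisse_loglik_cached(
                cache, make_params((lam, lam), (q01, q10)), root
            )
        except (RuntimeError, FloatingPointError, ValueError):
            return np.inf

    def neg_h1(x):
        lam0, lam1, q01, q10 = np.exp(x)
        try:
            return -_bisse_loglik_cached(
                cache, make_params((lam0, lam1), (q01, q10)), root
            )
        except (RuntimeError, FloatingPointError, ValueError):
            return np.inf

    def multistart(neg, x0, jitter_scale=0.7):
        best = None
        rng = np.random.default_rng(0)
        for i in range(restarts):
            start = np.asarray(x0, float)
            if i > 0:
                start = start + rng.normal(0, jitter_scale, size=len(x0))
            res = optimize.minimize(
                neg, start, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    r0 = multistart(neg_h0, np.log([lam_init, q_init, q_init]))
    # seed H1 from the H0 optimum
    x1 = np.concatenate([[r0.x[0], r0.x[0]], r0.x[1:]])
    r1 = multistart(neg_h1, x1)
    lnl0, lnl1 = -r0.fun, -r1.fun
    if lnl1 < lnl0:  # nested models: H1 can always match H0
        lnl1 = lnl0
        r1.x = x1
    lam0, lam1, q01, q10 = np.exp(r1.x)
    lr = max(2.0 * (lnl1 - lnl0), 0.0)
    return SseTestResult(
        lnl_h1=float(lnl1),
        lnl_h0=float(lnl0),
        lam0=float(lam0),
        lam1=float(lam1),
        lam_yule=float(np.exp(r0.x[0])),
        q01=float(q01),
        q10=float(q10),
        lr=float(lr),
        p_value=float(stats.chi2.sf(lr, df=1)),
    )
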