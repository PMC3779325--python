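"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed forms: diversification
likelihoods are recomputed by adaptive quadrature of the event intensity,
extinction probabilities by direct ODE integration, BiSSE by a monolithic
high-resolution ODE solve, and Mk/joint-chain likelihoods and marginals by
exhaustive enumeration over internal-state assignments with matrix
exponentials.
"""

import itertools

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.linalg import expm


def quadrature_pure_birth_family(bt, rate_of_age_and_N, breakpoints=()):
    """Reconstructed pure-birth log-likelihood via quadrature: lambda may
    depend on age and on the lineage count N(t).  Ages where the rate is
    discontinuous go in ``breakpoints``."""
    t = np.concatenate([bt.ages, [0.0]])
    lnl = 0.0
    for j in range(1, bt.n - 1):
        lnl += np.log((j + 1) * rate_of_age_and_N(t[j], j + 1))
    for k in range(bt.n - 1):
        N = k + 2
        pts = [b for b in breakpoints if t[k + 1] < b < t[k]]
        val, _ = quad(lambda s: rate_of_age_and_N(s, N), t[k + 1], t[k],
                      limit=200, points=pts or None)
        lnl -= N * val
    return lnl


def ode_extinction_prob(t, lam, mu, events=()):
    """E(t) by piecewise ODE integration with survival jumps at events."""
    e, lo = 0.0, 0.0
    for age, rho in sorted(events):
        if age >= t:
            break
        sol = solve_ivp(
            lambda s, E: mu - (lam + mu) * E + lam * E ** 2, (lo, age), [e],
            rtol=1e-11, atol=1e-13,
        )
        e = 1 - rho * (1 - sol.y[0, -1])
        lo = age
    if t > lo:
        sol = solve_ivp(
            lambda s, E: mu - (lam + mu) * E + lam * E ** 2, (lo, t), [e],
            rtol=1e-11, atol=1e-13,
        )
        e = sol.y[0, -1]
    return float(e)


def quadrature_birth_death(bt, lam, mu, events=()):
    """Birth-death (optionally with mass extinctions) log-likelihood via the
    intensity integral N(t) lambda (1 - E(t)) evaluated by quadrature."""
    t = np.concatenate([bt.ages, [0.0]])
    lnl = 0.0
    for j in range(1, bt.n - 1):
        lnl += np.log(
            (j + 1) * lam * (1 - ode_extinction_prob(t[j], lam, mu, events))
        )
    ev_ages = [a for a, _ in events]
    for k in range(bt.n - 1):
        N = k + 2
        val, _ = quad(
            lambda s: lam * (1 - ode_extinction_prob(s, lam, mu, events)),
            t[k + 1], t[k], limit=200,
            points=[a for a in ev_ages if t[k + 1] < a < t[k]],
        )
        lnl -= N * val
    return lnl


def ode_bisse_two_tip(t1, s_left, s_right, prm, root="fitzjohn"):
    """BiSSE likelihood of a two-tip tree by one monolithic ODE solve."""
    lam = np.array([prm.lam0, prm.lam1])
    mu = np.array([prm.mu0, prm.mu1])
    q = np.array([prm.q01, prm.q10])
    rho = np.array([prm.rho0, prm.rho1])

    def ode(t, yv):
        E, DL, DR = yv[:2], yv[2:4], yv[4:6]
        dE = mu - (lam + mu + q) * E + q * E[::-1] + lam * E ** 2
        dDL = -(lam + mu + q) * DL + q * DL[::-1] + 2 * lam * E * DL
        dDR = -(lam + mu + q) * DR + q * DR[::-1] + 2 * lam * E * DR
        return np.concatenate([dE, dDL, dDR])

    DL0, DR0 = np.zeros(2), np.zeros(2)
    DL0[s_left] = rho[s_left]
    DR0[s_right] = rho[s_right]
    sol = solve_ivp(ode, (0, t1), np.concatenate([1 - rho, DL0, DR0]),
                    rtol=1e-12, atol=1e-14, method="Radau")
    DL, DR = sol.y[2:4, -1], sol.y[4:6, -1]
    D = lam * DL * DR
    w = D / D.sum() if root == "fitzjohn" else np.array([0.5, 0.5])
    return float(np.log(np.sum(w * D)))


def enumeration_mk(tree, tip_states, Q, root_prior=None):
    """Mk likelihood and marginal node probabilities by brute-force
    enumeration over all internal-state assignments."""
    k = Q.shape[0]
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    post = list(tree.postorder_node_iter())
    Z = 0.0
    probs = {n: np.zeros(k) for n in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        pr = root_prior[amap[tree.seed_node]]
        for n in post:
            if n.parent_node is None:
                continue
            ps = amap[n.parent_node]
            if n.is_leaf():
                cs_set = tip_states[n.taxon.label]
                cs_set = cs_set if isinstance(cs_set, (set, frozenset, list, tuple)) else {cs_set}
                pr *= sum(expm(Q * n.edge.length)[ps, c] for c in cs_set)
            else:
                pr *= expm(Q * n.edge.length)[ps, amap[n]]
        Z += pr
        for n in internals:
            probs[n][amap[n]] += pr
    return float(np.log(Z)), {n: p / Z for n, p in probs.items()}
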