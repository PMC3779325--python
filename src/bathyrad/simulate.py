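"""Synthetic chronograms and traits with the structure the analyses assume.

The generator stands in for the empirical mussel tree: a ~60-tip chronogram
with root age ~85 Myr, an episodic speciation burst in the 41-33.8 Ma window
(rates 0.01 / 0.17 / 0.05 events/Myr), binary symbiont characters whose
derived state elevates speciation, a Brownian ln-shell-length trait and
500-m-binned depth ranges.

Two tree samplers are provided:

* an exact sampler for pure-birth (Yule-family) processes with any
  time-varying rate, conditioned jointly on crown age ``T`` and tip count
  ``n`` — conditional on (T, n) the n-2 post-crown branching times are iid
  with density proportional to lambda(u) * exp(Lambda(u)) in forward time u,
  which for piecewise-constant rates inverts analytically per segment;
* a forward Gillespie simulator for birth-death processes with extinction
  and instantaneous mass-extinction events (independent Bernoulli survival
  with probability rho per lineage), pruned to the reconstructed tree, with
  rejection used for conditioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .phylo import BranchingTimes, clone_tree, parse_newick

logger = logging.getLogger(__name__)


@dataclass
class RateInterval:
    """Constant (lambda, mu) on the age interval [old_age, young_age)."""

    old_age: float
    young_age: float
    lam: float
    mu: float = 0.0


@dataclass
class SimConfig:
    """Conditions for one tree simulation.

    ``schedule`` partitions [0, crown_age]; ages in Myr, rates in events/Myr.
    ``mass_extinctions`` is a list of (age, survival fraction rho) pairs.
    Conditioning: crown age is always fixed (both crown lineages must leave
    sampled descendants); ``n_tips`` additionally conditions on the
    reconstructed tip count by rejection.
    """

    crown_age: float
    schedule: list[RateInterval]
    n_tips: int | None = None
    mass_extinctions: list[tuple[float, float]] = field(default_factory=list)
    sampling_fraction: float = 1.0
    rejection_budget: int = 100_000

    def __post_init__(self):
        for iv in self.schedule:
            if iv.lam < 0 or iv.mu < 0:
                raise ValueError("rates must be non-negative")
        for age, rho in self.mass_extinctions:
            if not (0 < rho <= 1):
                raise ValueError("survival fraction must be in (0, 1]")
            if not (0 < age < self.crown_age):
                raise ValueError("mass-extinction age must lie inside the tree span")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling fraction must be in (0, 1]")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("cannot condition on fewer than 2 tips")

    @property
    def is_pure_birth(self) -> bool:
        return (
            all(iv.mu == 0 for iv in self.schedule)
            and not self.mass_extinctions
            and self.sampling_fraction == 1.0
        )


def constant_rate_config(
    crown_age: float,
    lam: float,
    mu: float = 0.0,
    n_tips: int | None = None,
    mass_extinctions=(),
) -> SimConfig:
    return SimConfig(
        crown_age=crown_age,
        schedule=[RateInterval(crown_age, 0.0, lam, mu)],
        n_tips=n_tips,
        mass_extinctions=list(mass_extinctions),
    )


def mussel_preset(n_tips: int | None = 62) -> SimConfig:
    """Episodic Yule preset emulating the mussel radiation: crown 85 Ma,
    speciation 0.01/Myr before 41.2 Ma, 0.17/Myr in the burst window
    41.2-33.8 Ma, 0.05/Myr since, 62 extant species."""
    return SimConfig(
        crown_age=85.0,
        schedule=[
            RateInterval(85.0, 41.2, 0.01),
            RateInterval(41.2, 33.8, 0.17),
            RateInterval(33.8, 0.0, 0.05),
        ],
        n_tips=n_tips,
    )


# ---------------------------------------------------------------------------
# Exact conditioned sampler for time-varying pure birth


def _schedule_arrays(schedule):
    # segments in forward time from the crown: u in [a_i, b_i), rate lam_i
    old = np.array([iv.old_age for iv in schedule], float)
    young = np.array([iv.young_age for iv in schedule], float)
    lam = np.array([iv.lam for iv in schedule], float)
    order = np.argsort(-old)
    return old[order], young[order], lam[order]


def yule_conditioned_branching_times(
    config: SimConfig, rng: np.random.Generator
) -> BranchingTimes:
    """Draw branching times of a pure-birth tree conditioned on crown age and
    tip count, using the iid representation (no rejection).

    Branching ages t are drawn with density proportional to
    lambda(t) * exp(-Lambda(0, t)) where Lambda is the cumulative rate from
    the present, truncated to (0, T): piecewise-exponential inverse-CDF
    sampling for piecewise-constant schedules.
    """
    if not config.is_pure_birth:
        raise ValueError("exact conditioned sampler requires a pure-birth config")
    if config.n_tips is None:
        raise ValueError("conditioned sampler needs a target tip count")
    n = config.n_tips
    T = config.crown_age
    old, young, lam = _schedule_arrays(config.schedule)
    # cumulative rate from the present (age 0) to the young edge of each segment
    seg_len = old - young
    cum_young = np.concatenate([np.cumsum((seg_len * lam)[::-1])[::-1][1:], [0.0]])
    # weight of each segment under density lam * exp(-Lambda(0,t)) dt, t = age
    with np.errstate(over="ignore"):
        w = np.where(
            lam > 0,
            np.exp(-cum_young) - np.exp(-(cum_young + lam * seg_len)),
            0.0,
        )
    if w.sum() <= 0:
        raise ValueError("schedule has zero total speciation rate")
    probs = w / w.sum()
    seg = rng.choice(len(lam), size=n - 2, p=probs)
    u = rng.random(n - 2)
    # inverse CDF within segment: t = young + (-1/lam) * log(1 - u*(1-e^{-lam*len}))
    with np.errstate(divide="ignore"):
        span = -np.log1p(-u * (1 - np.exp(-lam[seg] * seg_len[seg]))) / lam[seg]
    ages = young[seg] + span
    ages = np.concatenate([[T], ages])
    return BranchingTimes.from_ages(ages)


# ---------------------------------------------------------------------------
# Forward Gillespie birth-death simulation with mass extinctions


class _Lineage:
    __slots__ = ("parent", "birth", "death", "alive", "state")

    def __init__(self, parent, birth, state=0):
        self.parent = parent
        self.birth = birth  # forward time
        self.death = None
        self.alive = True
        self.state = state


def _forward_once(config: SimConfig, rng: np.random.Generator):
    """One unconditioned forward pass; returns the lineage list or None if the
    whole clade died."""
    T = config.crown_age
    old, young, lam = _schedule_arrays(config.schedule)
    mu = np.array([iv.mu for iv in sorted(config.schedule, key=lambda i: -i.old_age)])
    # forward-time boundaries of rate segments and ME events
    seg_start = T - old  # forward time at which each segment begins
    seg_end = T - young
    events = sorted(((T - age, rho) for age, rho in config.mass_extinctions))
    lineages = [_Lineage(None, 0.0), _Lineage(None, 0.0)]
    alive = [0, 1]
    t = 0.0
    ev_idx = 0
    si = 0
    while t < T and alive:
        while si < len(lam) - 1 and t >= seg_end[si]:
            si += 1
        total = len(alive) * (lam[si] + mu[si])
        t_next_seg = seg_end[si] if si < len(lam) - 1 else T
        t_next_ev = events[ev_idx][0] if ev_idx < len(events) else np.inf
        horizon = min(t_next_seg, t_next_ev, T)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + wait >= horizon:
            t = horizon
            if ev_idx < len(events) and horizon == t_next_ev:
                rho = events[ev_idx][1]
                survivors = []
                for i in alive:
                    if rng.random() < rho:
                        survivors.append(i)
                    else:
                        lineages[i].alive = False
                        lineages[i].death = t
                alive = survivors
                ev_idx += 1
            continue
        t += wait
        i = alive[rng.integers(len(alive))]
        if rng.random() < lam[si] / (lam[si] + mu[si]):
            for _ in range(2):
                lineages.append(_Lineage(i, t))
                alive.append(len(lineages) - 1)
            lineages[i].alive = False
            lineages[i].death = t
            alive.remove(i)
        else:
            lineages[i].alive = False
            lineages[i].death = t
            alive.remove(i)
    if not alive:
        return None
    return lineages


def _sampled_flags(lineages, sampled: set[int] | None):
    """Whether each lineage has at least one sampled surviving descendant.
    Children always carry higher indices than their parent, so one reverse
    pass suffices."""
    nlin = len(lineages)
    children: list[list[int]] = [[] for _ in range(nlin)]
    for i, l in enumerate(lineages):
        if l.parent is not None:
            children[l.parent].append(i)
    has = [False] * nlin
    for i in range(nlin - 1, -1, -1):
        if children[i]:
            has[i] = any(has[c] for c in children[i])
        else:
            has[i] = lineages[i].alive and (sampled is None or i in sampled)
    return has, children


def reconstructed_branching_ages(lineages, T, sampled: set[int] | None = None):
    """Branching ages (crown first) of the reconstructed tree implied by a
    forward simulation, or None if either crown lineage left no sampled
    descendant.  Avoids building the tree."""
    has, children = _sampled_flags(lineages, sampled)
    if not (has[0] and has[1]):
        return None
    ages = [T]
    for i, l in enumerate(lineages):
        if len(children[i]) == 2 and has[children[i][0]] and has[children[i][1]]:
            ages.append(T - l.death)
    return ages


def _reconstructed_newick(lineages, T, sampled: set[int] | None, labels=None):
    """Prune extinct/unsampled lineages and emit the reconstructed tree as a
    Newick string with branch lengths in Myr (tips at the present)."""
    nlin = len(lineages)
    if sampled is None:
        sampled = {i for i, l in enumerate(lineages) if l.alive}
    children: dict[int, list[int]] = {i: [] for i in range(nlin)}
    roots = []
    for i, l in enumerate(lineages):
        if l.parent is None:
            roots.append(i)
        else:
            children[l.parent].append(i)

    # bottom-up assembly of Newick fragments with lengths; each memo entry is
    # (fragment ending in ":length", start time of the fragment's stem) or None
    memo: dict[int, tuple[str, float] | None] = {}

    def build2(i):
        if i in memo:
            return memo[i]
        l = lineages[i]
        kids = [build2(c) for c in children[i]]
        kids = [k for k in kids if k is not None]
        if not kids:
            if l.alive and i in sampled:
                name = labels[i] if labels else f"t{i}"
                memo[i] = (f"{name}:{T - l.birth:.10g}", l.birth)
            else:
                memo[i] = None
            return memo[i]
        if len(kids) == 1:
            frag, split = kids[0]
            # extend: the fragment's pendant length must grow by (split - birth)
            # fragments store length from their own split; splice by rebuilding
            name_part, length_part = frag.rsplit(":", 1)
            new_len = float(length_part) + (split - l.birth)
            memo[i] = (f"{name_part}:{new_len:.10g}", l.birth)
            return memo[i]
        split = l.death  # the birth time of the children
        inner = ",".join(f[0] for f in kids)
        memo[i] = (f"({inner}):{split - l.birth:.10g}", l.birth)
        return memo[i]

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * nlin + 100))
    try:
        frags = [build2(r) for r in roots]
    finally:
        sys.setrecursionlimit(old_limit)
    frags = [f for f in frags if f is not None]
    if len(frags) < 2:
        return None  # crown condition violated: one side died entirely
    inner = ",".join(f[0] for f in frags)
    return f"({inner});"


def simulate_tree(config: SimConfig, seed_or_rng) -> dendropy.Tree:
    """Simulate a reconstructed ultrametric tree under the configured
    (possibly episodic, possibly mass-extinction) birth-death process,
    conditioned on the crown age (both crown lineages leave sampled
    descendants) and, when requested, on the reconstructed tip count.

    A degenerate schedule with zero speciation rate yields the 2-tip tree
    immediately.  Rejection is used for conditioning; exceeding the budget
    raises a RuntimeError with diagnostics.
    """
    rng = _as_rng(seed_or_rng)
    T = config.crown_age
    if all(iv.lam == 0 for iv in config.schedule) and not config.mass_extinctions \
            and all(iv.mu == 0 for iv in config.schedule):
        if config.n_tips not in (None, 2):
            raise RuntimeError("zero speciation cannot reach the target tip count")
        return parse_newick(f"(t0:{T},t1:{T});")
    # fast exact path: pure birth conditioned on n
    if config.is_pure_birth and config.n_tips is not None:
        bt = yule_conditioned_branching_times(config, rng)
        return tree_from_branching_times(bt, rng)
    attempts = 0
    while attempts < config.rejection_budget:
        attempts += 1
        lineages = _forward_once(config, rng)
        if lineages is None:
            continue
        sampled = None
        survivors = [i for i, l in enumerate(lineages) if l.alive]
        if config.sampling_fraction < 1.0:
            k = int(round(len(survivors) * config.sampling_fraction))
            if k < 2:
                continue
            sampled = set(rng.choice(survivors, size=k, replace=False).tolist())
            ntips = k
        else:
            ntips = len(survivors)
        if config.n_tips is not None and ntips != config.n_tips:
            continue
        newick = _reconstructed_newick(lineages, T, sampled)
        if newick is None:  # one crown side unsampled
            continue
        logger.debug("simulate_tree accepted after %d attempts", attempts)
        return parse_newick(newick)
    raise RuntimeError(
        f"rejection budget exceeded ({config.rejection_budget} attempts) for "
        f"conditioning on n={config.n_tips}, T={config.crown_age}"
    )


def simulate_branching_times(config: SimConfig, seed_or_rng) -> BranchingTimes:
    """Branching times of a simulated reconstructed tree, without building
    the tree (fast path: exact conditioned sampling for pure-birth configs)."""
    rng = _as_rng(seed_or_rng)
    if config.is_pure_birth and config.n_tips is not None:
        return yule_conditioned_branching_times(config, rng)
    T = config.crown_age
    attempts = 0
    while attempts < config.rejection_budget:
        attempts += 1
        lineages = _forward_once(config, rng)
        if lineages is None:
            continue
        sampled = None
        survivors = [i for i, l in enumerate(lineages) if l.alive]
        if config.sampling_fraction < 1.0:
            k = int(round(len(survivors) * config.sampling_fraction))
            if k < 2:
                continue
            sampled = set(rng.choice(survivors, size=k, replace=False).tolist())
            ntips = k
        else:
            ntips = len(survivors)
        if config.n_tips is not None and ntips != config.n_tips:
            continue
        ages = reconstructed_branching_ages(lineages, T, sampled)
        if ages is None:
            continue
        return BranchingTimes.from_ages(ages)
    raise RuntimeError(
        f"rejection budget exceeded ({config.rejection_budget} attempts) for "
        f"conditioning on n={config.n_tips}, T={config.crown_age}"
    )


def tree_from_branching_times(
    bt: BranchingTimes, seed_or_rng, labels=None
) -> dendropy.Tree:
    """Build a random-topology ultrametric tree realizing the given branching
    times (coalescent-style: join two uniformly chosen lineages at each age,
    youngest first — the exchangeable topology of a pure-birth process)."""
    rng = _as_rng(seed_or_rng)
    n = bt.n
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    nodes = [(lbl, 0.0) for lbl in labels]  # (fragment, age)
    for age in np.sort(bt.ages):  # youngest first
        i, j = rng.choice(len(nodes), size=2, replace=False)
        (fi, ai), (fj, aj) = nodes[i], nodes[j]
        frag = f"({fi}:{age - ai:.10g},{fj}:{age - aj:.10g})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((frag, age))
    assert len(nodes) == 1
    return parse_newick(nodes[0][0] + ";")


# ---------------------------------------------------------------------------
# Tip subsampling


def subsample_tips(
    tree: dendropy.Tree, fraction_missing: float, seed_or_rng
) -> dendropy.Tree:
    """Retain a uniformly random subset of round(n * (1 - f)) tips, emulating
    incomplete species sampling; the tree is re-pruned and stays ultrametric."""
    rng = _as_rng(seed_or_rng)
    if not (0 <= fraction_missing < 1):
        raise ValueError("fraction_missing must be in [0, 1)")
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    k = int(round(len(labels) * (1 - fraction_missing)))
    if k < 3:
        raise ValueError(f"subsampling would leave {k} tips (< 3)")
    if k == len(labels):
        return clone_tree(tree)
    keep = rng.choice(labels, size=k, replace=False).tolist()
    out = clone_tree(tree)
    out.retain_taxa_with_labels(keep)
    out.purge_taxon_namespace()
    return out


# ---------------------------------------------------------------------------
# Trait simulation


@dataclass
class DiscreteTraitSpec:
    """CTMC spec: instantaneous rate matrix Q (rows sum to 0, off-diagonals
    >= 0) and root state distribution."""

    Q: np.ndarray
    root_probs: np.ndarray

    def __post_init__(self):
        self.Q = np.asarray(self.Q, float)
        self.root_probs = np.asarray(self.root_probs, float)
        if self.Q.shape[0] != self.Q.shape[1]:
            raise ValueError("Q must be square")
        if np.any(self.Q - np.diag(np.diag(self.Q)) < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-9:
            raise ValueError("Q rows must sum to 0")
        if abs(self.root_probs.sum() - 1) > 1e-9:
            raise ValueError("root probabilities must sum to 1")


def symmetric_binary_spec(rate: float, root_probs=(0.5, 0.5)) -> DiscreteTraitSpec:
    Q = np.array([[-rate, rate], [rate, -rate]], float)
    return DiscreteTraitSpec(Q=Q, root_probs=np.asarray(root_probs, float))


def simulate_discrete_trait(
    tree: dendropy.Tree, spec: DiscreteTraitSpec, seed_or_rng
) -> dict[str, int]:
    """Simulate a discrete character along the tree by Gillespie simulation of
    the CTMC on each branch from a root draw; returns tip label -> state."""
    rng = _as_rng(seed_or_rng)
    k = spec.Q.shape[0]
    states: dict[dendropy.Node, int] = {}
    out: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = int(rng.choice(k, p=spec.root_probs))
        else:
            s = states[node.parent_node]
            t = node.edge.length or 0.0
            while t > 0:
                rate = -spec.Q[s, s]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= t:
                    break
                t -= wait
                probs = spec.Q[s].copy()
                probs[s] = 0.0
                probs /= probs.sum()
                s = int(rng.choice(k, p=probs))
            states[node] = s
        if node.is_leaf():
            out[node.taxon.label] = states[node]
    return out


@dataclass
class ContinuousTraitSpec:
    """Brownian-motion spec: diffusion rate sigma2 per Myr and root value."""

    sigma2: float
    root_value: float = 0.0

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


def simulate_continuous_trait(
    tree: dendropy.Tree, spec: ContinuousTraitSpec, seed_or_rng
) -> dict[str, float]:
    """Brownian motion along branches: increments ~ Normal(0, sigma2 * length)
    summed root to tip; returns tip label -> value."""
    rng = _as_rng(seed_or_rng)
    values: dict[dendropy.Node, float] = {}
    out: dict[str, float] = {}
    sd_unit = np.sqrt(spec.sigma2)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = spec.root_value
        else:
            t = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, sd_unit * np.sqrt(t)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


# ---------------------------------------------------------------------------
# State-dependent (BiSSE) forward simulation


def simulate_bisse_tree(
    params,
    crown_age: float,
    seed_or_rng,
    n_tips: int | None = None,
    max_lineages: int = 100_000,
    rejection_budget: int = 10_000,
):
    """Jointly simulate a tree and binary tip states under state-dependent
    branching (BiSSE forward process), pruned of extinct lineages and
    conditioned on the crown age (and optionally the tip count).

    ``params`` is a :class:`bathyrad.bisse.BisseParams`.  Returns
    ``(tree, {tip label: state})``.
    """
    rng = _as_rng(seed_or_rng)
    lam = np.array([params.lam0, params.lam1])
    mu = np.array([params.mu0, params.mu1])
    q = np.array([params.q01, params.q10])
    T = crown_age
    for attempt in range(rejection_budget):
        # both crown lineages inherit the root state, drawn 50/50
        s0 = int(rng.random() < 0.5)
        lineages = [_Lineage(None, 0.0, s0), _Lineage(None, 0.0, s0)]
        alive = [0, 1]
        t = 0.0
        ok = True
        while t < T and alive:
            if len(lineages) > max_lineages:
                ok = False
                break
            st = np.array([lineages[i].state for i in alive])
            rates = lam[st] + mu[st] + q[st]
            total = rates.sum()
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if t + wait >= T:
                break
            t += wait
            pick = rng.choice(len(alive), p=rates / total)
            i = alive[pick]
            s = lineages[i].state
            r = rng.random() * (lam[s] + mu[s] + q[s])
            if r < lam[s]:
                for _ in range(2):
                    lineages.append(_Lineage(i, t, s))
                    alive.append(len(lineages) - 1)
                lineages[i].alive = False
                lineages[i].death = t
                alive.remove(i)
            elif r < lam[s] + mu[s]:
                lineages[i].alive = False
                lineages[i].death = t
                alive.remove(i)
            else:
                lineages[i].state = 1 - s
        if not ok or not alive:
            continue
        newick = _reconstructed_newick(lineages, T, None)
        if newick is None:
            continue
        tree = parse_newick(newick)
        ntips = sum(1 for _ in tree.leaf_node_iter())
        if n_tips is not None and ntips != n_tips:
            continue
        states = {
            f"t{i}": lineages[i].state
            for i, l in enumerate(lineages)
            if l.alive
        }
        states = {
            leaf.taxon.label: states[leaf.taxon.label]
            for leaf in tree.leaf_node_iter()
        }
        return tree, states
    raise RuntimeError(
        f"BiSSE simulation rejection budget exceeded ({rejection_budget})"
    )


def mussel_trait_table(tree: dendropy.Tree, seed_or_rng, missing_rate: float = 0.15):
    """Generate a mussel-like trait table for a chronogram's tips: habitat
    (organic-fall/vent/seep, 3-state Markov), presence/absence of
    sulfur-oxidizing and methanotrophic symbionts, symbiont location,
    ln-shell-length evolving by Brownian motion with a habitat-linked shift
    (vent/seep species trend larger), and 500-m-scale depth ranges with
    vent/seep species deeper on average.  A fraction of entries is blanked to
    emulate incomplete data (``missing_rate`` per optional cell)."""
    import pandas as pd

    rng = _as_rng(seed_or_rng)
    q = 0.02
    habitat_spec = DiscreteTraitSpec(
        Q=np.array(
            [[-2 * q, q, q], [q / 4, -q / 2, q / 4], [q / 4, q / 4, -q / 2]]
        ),
        root_probs=np.array([1.0, 0.0, 0.0]),  # ancestrally on organic falls
    )
    habitat_states = simulate_discrete_trait(tree, habitat_spec, rng)
    habitat_names = {0: "organic-fall", 1: "vent", 2: "seep"}
    methano = simulate_discrete_trait(
        tree,
        DiscreteTraitSpec(
            Q=np.array([[-0.01, 0.01], [0.002, -0.002]]),
            root_probs=np.array([1.0, 0.0]),
        ),
        rng,
    )
    location = simulate_discrete_trait(
        tree,
        DiscreteTraitSpec(
            Q=np.array([[-0.012, 0.012], [0.002, -0.002]]),
            root_probs=np.array([1.0, 0.0]),
        ),
        rng,
    )
    ln_shell = simulate_continuous_trait(
        tree, ContinuousTraitSpec(sigma2=0.02, root_value=np.log(30.0)), rng
    )
    rows = []
    for leaf in tree.leaf_node_iter():
        sp = leaf.taxon.label
        hab = habitat_names[habitat_states[sp]]
        vent_seep = hab in ("vent", "seep")
        shell = float(np.exp(ln_shell[sp] + (0.8 if vent_seep else 0.0)))
        depth_mid = rng.normal(2200 if vent_seep else 1200, 500)
        depth_mid = float(np.clip(depth_mid, 80, 6000))
        spread = float(rng.uniform(50, 800))
        row = {
            "species": sp,
            "habitat": hab,
            "sulfur_symbiont": 1,
            "methanotroph": methano[sp],
            "symbiont_location": "intracellular" if location[sp] else "extracellular",
            "shell_length_mm": round(shell, 1),
            "depth_min_m": round(max(depth_mid - spread, 0.0), 0),
            "depth_max_m": round(depth_mid + spread, 0),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("methanotroph", "symbiont_location", "shell_length_mm"):
        mask = rng.random(len(df)) < missing_rate
        df.loc[mask, col] = np.nan
    return df


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
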