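"""Tree and trait I/O plus the elementary quantities downstream stages consume.

Trees are held as :class:`dendropy.Tree` objects.  Ages are measured backward
from the present in Myr (tips of an ultrametric chronogram sit at age 0);
phylograms carry branch lengths in substitutions/site.  Branching times and
lineages-through-time curves are the sufficient statistics for every
diversification likelihood in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative (to root age) tolerance under which a tree counts as ultrametric
ULTRAMETRIC_RTOL = 1e-6

TRAIT_COLUMNS = [
    "species",
    "habitat",
    "sulfur_symbiont",
    "methanotroph",
    "symbiont_location",
    "shell_length_mm",
    "depth_min_m",
    "depth_max_m",
]

HABITATS = {"organic-fall", "vent", "seep"}
SYMBIONT_LOCATIONS = {"intracellular", "extracellular"}


class TreeError(ValueError):
    """Raised for malformed or invalid trees."""


class UltrametricityError(TreeError):
    """Raised when a chronogram is required but tip depths disagree."""


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, length_unit: str = "myr") -> dendropy.Tree:
    """Parse a rooted Newick string into a validated tree.

    Numeric internal-node labels are interpreted as support values (stored on
    ``node.support``); bracketed comments are ignored.  ``length_unit`` is
    recorded on the tree (``"myr"`` or ``"subst"``) but not interpreted here.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
        if node.parent_node is not None and node.edge.length < 0:
            raise TreeError(f"negative branch length on edge to {node}")
        # numeric internal labels -> support
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    tree.length_unit = length_unit
    logger.info("parsed tree with %d tips", len(labels))
    return tree


def read_newick(path: str, length_unit: str = "myr") -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), length_unit=length_unit)


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize a tree; returns the Newick string (and writes it if asked)."""
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and getattr(node, "support", None) is not None:
            node.label = repr(node.support)
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Ages, branching times, LTT


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Ages (Myr before present) of all nodes, forcing tips to age 0.

    Raises :class:`UltrametricityError` if tip depths deviate from the maximum
    root-to-tip depth by more than ``ULTRAMETRIC_RTOL`` relative to the root
    age; smaller deviations are absorbed (round-off in Newick files).
    """
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    tip_depths = [depths[l] for l in tree.leaf_node_iter()]
    tmax = max(tip_depths)
    if tmax <= 0:
        raise TreeError("tree has zero depth")
    dev = max(tmax - d for d in tip_depths)
    if dev > ULTRAMETRIC_RTOL * tmax:
        raise UltrametricityError(
            f"tree not ultrametric: max tip-age deviation {dev:.6g} "
            f"(root age {tmax:.6g})"
        )
    return {node: max(tmax - d, 0.0) if node.is_leaf() is False else 0.0
            for node, d in depths.items()}


def crown_age(tree: dendropy.Tree) -> float:
    ages = node_ages(tree)
    return ages[tree.seed_node]


@dataclass
class BranchingTimes:
    """Ages of internal branching events, sorted descending; crown age first.

    ``ages`` has length ``n - 1`` for an ``n``-tip chronogram.  ``ties`` flags
    the presence of simultaneous branching events (these matter because
    multi-rate fits place candidate shifts at branching times).
    """

    ages: np.ndarray
    n: int
    ties: bool = False

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.size != self.n - 1:
            raise ValueError("need n - 1 branching times for n tips")
        if np.any(self.ages <= 0):
            raise ValueError("branching times must be strictly positive")
        if np.any(np.diff(self.ages) > 0):
            raise ValueError("branching times must be sorted descending")
        self.ties = bool(np.any(np.diff(self.ages) == 0))

    @property
    def crown(self) -> float:
        return float(self.ages[0])

    @classmethod
    def from_ages(cls, ages) -> "BranchingTimes":
        ages = np.sort(np.asarray(ages, dtype=float))[::-1]
        return cls(ages=ages, n=ages.size + 1)


def branching_times(tree: dendropy.Tree) -> BranchingTimes:
    """Extract branching times from an ultrametric tree.

    Polytomies contribute repeated (tied) ages so that the result always has
    ``n - 1`` entries, stable-ordered by preorder node position on ties.
    """
    ages = node_ages(tree)
    events = []
    for node in tree.preorder_internal_node_iter():
        nchild = len(node.child_nodes())
        # a polytomy of c children stands for c - 1 coincident binary events
        events.extend([ages[node]] * (nchild - 1))
    return BranchingTimes.from_ages(events)


@dataclass
class LTTCurve:
    """Lineages-through-time step function: count of reconstructed lineages
    at each age, stepping up (backward in age order: down) at every branching
    event."""

    ages: np.ndarray  # descending, starts at crown age, ends at 0
    counts: np.ndarray  # lineage count on [ages[i+1], ages[i])

    def count_at(self, age: float) -> int:
        idx = np.searchsorted(-self.ages, -age, side="right") - 1
        idx = min(max(idx, 0), self.counts.size - 1)
        return int(self.counts[idx])


def ltt_curve(tree: dendropy.Tree) -> LTTCurve:
    """LTT curve of an ultrametric tree (>= 2 tips): starts at 2 lineages at
    the crown age and ends at the tip count at age 0."""
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise TreeError("LTT curve requires >= 2 tips")
    bt = branching_times(tree)
    ages = np.concatenate([bt.ages, [0.0]])
    counts = np.arange(2, bt.n + 1)
    return LTTCurve(ages=ages, counts=counts)


def ltt_from_branching_times(bt: BranchingTimes) -> LTTCurve:
    ages = np.concatenate([bt.ages, [0.0]])
    return LTTCurve(ages=ages, counts=np.arange(2, bt.n + 1))


# ---------------------------------------------------------------------------
# Trait tables


def read_traits(path_or_buffer) -> pd.DataFrame:
    """Read a species-by-trait TSV (empty cell = missing) and validate it."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"species": str})
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in trait table")
    df = df.set_index("species", drop=False)
    if "habitat" in df.columns:
        bad = set(df["habitat"].dropna()) - HABITATS
        if bad:
            raise ValueError(f"unknown habitat values: {sorted(bad)}")
    if "symbiont_location" in df.columns:
        bad = set(df["symbiont_location"].dropna()) - SYMBIONT_LOCATIONS
        if bad:
            raise ValueError(f"unknown symbiont_location values: {sorted(bad)}")
    if "shell_length_mm" in df.columns:
        if (df["shell_length_mm"].dropna() <= 0).any():
            raise ValueError("shell lengths must be positive (mm)")
    if {"depth_min_m", "depth_max_m"} <= set(df.columns):
        sub = df.dropna(subset=["depth_min_m", "depth_max_m"])
        if (sub["depth_min_m"] > sub["depth_max_m"]).any():
            raise ValueError("depth_min_m must be <= depth_max_m")
        if (sub["depth_min_m"] < 0).any():
            raise ValueError("depths must be non-negative")
    logger.info("trait table with %d species", len(df))
    return df


def write_traits(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep-copy a tree with its own taxon namespace, so pruning the copy can
    never disturb the original (or later copies)."""
    out = tree.clone(depth=1)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return out


# ---------------------------------------------------------------------------
# Preparation: collapse unsupported nodes, prune missing data


def collapse_unsupported(tree: dendropy.Tree, support_threshold: float) -> int:
    """Collapse internal edges whose child node support falls below the
    threshold, producing polytomies.  Returns the number of collapsed edges.
    The collapsed branch length is added to the children so total depth is
    preserved."""
    ncollapsed = 0
    for node in list(tree.preorder_internal_node_iter()):
        if node.parent_node is None:
            continue
        sup = getattr(node, "support", None)
        if sup is not None and sup < support_threshold:
            for child in node.child_nodes():
                child.edge.length = (child.edge.length or 0.0) + (
                    node.edge.length or 0.0
                )
            node.edge.collapse()
            ncollapsed += 1
    return ncollapsed


def resolve_polytomies(tree: dendropy.Tree, rng=None) -> int:
    """Arbitrarily resolve polytomies with zero-length branches (for methods
    that require binary trees).  Returns the number of inserted nodes."""
    before = sum(1 for _ in tree.preorder_internal_node_iter())
    tree.resolve_polytomies(limit=2, rng=rng)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    after = sum(1 for _ in tree.preorder_internal_node_iter())
    return after - before


def prepare_tree(
    tree: dendropy.Tree,
    traits: pd.DataFrame | None = None,
    support_threshold: float = 0.0,
    character: str | None = None,
    resolve: bool = False,
    rng=None,
) -> tuple[dendropy.Tree, pd.DataFrame | None, dict]:
    """Collapse unsupported nodes and prune species with missing data for the
    named character, mirroring the pre-analysis cleaning of comparative tests.

    Returns ``(tree, traits, provenance)`` where provenance records the
    collapse/prune/resolution bookkeeping.  Raises if fewer than 3 tips remain.
    """
    tree = clone_tree(tree)
    prov: dict = {"collapsed": 0, "pruned": [], "resolved": 0}
    if support_threshold > 0:
        prov["collapsed"] = collapse_unsupported(tree, support_threshold)
    if traits is not None and character is not None:
        keep = traits.dropna(subset=[character])["species"].tolist()
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        keep = [s for s in keep if s in tips]
        prov["pruned"] = sorted(tips - set(keep))
        if len(keep) < 3:
            raise TreeError(
                f"pruning on '{character}' leaves {len(keep)} tips (< 3)"
            )
        if prov["pruned"]:
            tree.retain_taxa_with_labels(keep)
            tree.purge_taxon_namespace()
        traits = traits.loc[traits["species"].isin(keep)].copy()
    if resolve:
        prov["resolved"] = resolve_polytomies(tree, rng=rng)
    ntips = sum(1 for _ in tree.leaf_node_iter())
    if ntips < 3:
        raise TreeError(f"prepared tree has {ntips} tips (< 3)")
    prov["n_tips"] = ntips
    logger.info(
        "prepared tree: %d tips, %d collapsed, %d pruned",
        ntips, prov["collapsed"], len(prov["pruned"]),
    )
    return tree, traits, prov
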