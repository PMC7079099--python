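"""Synthetic tree quintet: a purpose-built chronogram and degraded variants.

The experimental unit is a set of five trees on a common tip set:

* ``tree_purpose`` — a fully bifurcating ultrametric Kingman-coalescent tree,
  rescaled to a target root age, standing in for a chronogram inferred from
  sequence data;
* three "synthesis-style" variants (``apg``-like, ``zanne``-like,
  ``otl``-like) built by collapsing internal nodes into polytomies, dropping a
  fraction of tips, and re-dating the topology by even node-age interpolation
  (the bladj algorithm) from a retained subset of the original node ages;
* ``tree_random`` — an unrelated coalescent tree on the same tips, rescaled to
  the mean root age of the degraded variants, as a negative control.

The three variant parameterisations are ordered in severity (apg > zanne >
otl), emulating a coarsely dated classification backbone, a calibrated
megatree, and a supertree re-dated from an external age database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tree import Phylogeny, prune_to_tips

__all__ = [
    "VariantSpec",
    "DegradationConfig",
    "TreeSet",
    "simulate_coalescent_tree",
    "rescale_to_root_age",
    "collapse_nodes",
    "bladj_date",
    "make_tree_set",
]


def simulate_coalescent_tree(n_tips, seed, labels=None) -> Phylogeny:
    """Random Kingman-coalescent tree, ultrametric and bifurcating.

    With ``k`` extant lineages the waiting time to the next coalescence is
    Exponential with rate ``k (k - 1) / 2`` (coalescent time units) and the
    coalescing pair is chosen uniformly.  Deterministic given ``seed``.

    Parameters
    ----------
    labels
        Optional explicit tip labels (length ``n_tips``); default
        ``t1 .. t{n}``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    # grow upward: each record is (node_payload); parents created on merge
    children: list = [None] * n_tips  # tips
    ages = [0.0] * n_tips
    labs: list = list(labels)
    lineages = list(range(n_tips))
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        children.append([a, b])
        ages.append(t)
        labs.append(None)
        new = len(children) - 1
        lineages = [x for x in lineages if x not in (a, b)] + [new]

    root = lineages[0]
    # assemble preorder arrays
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        if children[u]:
            stack.extend(reversed(children[u]))
    newid = {u: k for k, u in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.full(n, np.nan)
    out_labels: list = [None] * n
    for u in order:
        out_labels[newid[u]] = labs[u]
        if children[u]:
            for c in children[u]:
                parent[newid[c]] = newid[u]
                blen[newid[c]] = ages[u] - ages[c]
    tree = Phylogeny(parent, blen, out_labels)
    return _ensure_internal_labels(tree)


def _ensure_internal_labels(tree: Phylogeny) -> Phylogeny:
    """Give every internal node a stable label (``nd{i}``) if it lacks one."""
    labels = list(tree.labels)
    for i in range(tree.n_nodes):
        if tree.children[i] and not labels[i]:
            labels[i] = f"nd{i}"
    return Phylogeny(tree.parent.copy(), tree.blen.copy(), labels)


def rescale_to_root_age(tree: Phylogeny, target: float) -> Phylogeny:
    """Multiply every branch length so the root age becomes exactly ``target``."""
    if target <= 0:
        raise ValueError("target root age must be positive")
    current = tree.root_age()
    if current == 0:
        raise ValueError("tree has zero root age; cannot rescale")
    out = tree.copy()
    out.blen = out.blen * (target / current)
    return out


def collapse_nodes(tree: Phylogeny, fraction: float, rule: str = "random", seed=None):
    """Delete a fraction of internal non-root nodes, creating polytomies.

    ``ceil(fraction * n_internal_nonroot)`` nodes are removed and their
    children attached to their parents.  ``rule`` is ``"youngest-first"``
    (delete shallowest splits first) or ``"random"``.  The root is never
    collapsed.

    Returns
    -------
    (topology, ages)
        The collapsed tree (still dated: branch lengths are recomputed from
        the surviving nodes' original depths) and a dict mapping each
        surviving internal node label (root included) to its original age.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    tree = _ensure_internal_labels(tree)
    internal = [i for i in range(1, tree.n_nodes) if tree.children[i]]
    m = math.ceil(fraction * len(internal))
    if m == 0:
        ages_arr = tree.node_ages()
        ages = {tree.labels[i]: float(ages_arr[i]) for i in [0] + internal}
        return tree.copy(), ages
    ages_arr = tree.node_ages()
    if rule == "youngest-first":
        victims = sorted(internal, key=lambda i: (ages_arr[i], i))[:m]
    elif rule == "random":
        rng = np.random.default_rng(seed)
        victims = rng.choice(np.array(internal), size=m, replace=False).tolist()
    else:
        raise ValueError(f"unknown rule: {rule!r}")
    dead = np.zeros(tree.n_nodes, dtype=bool)
    dead[victims] = True

    depth = tree.node_depths()
    survivors = [i for i in range(tree.n_nodes) if not dead[i]]
    newid = {u: k for k, u in enumerate(survivors)}
    parent = np.full(len(survivors), -1, dtype=np.int64)
    blen = np.full(len(survivors), np.nan)
    labels = [tree.labels[u] for u in survivors]
    for k, u in enumerate(survivors):
        if u == 0:
            continue
        p = tree.parent[u]
        while dead[p]:
            p = tree.parent[p]
        parent[k] = newid[p]
        blen[k] = depth[u] - depth[p]
    out = Phylogeny(parent, blen, labels)
    ages = {
        out.labels[i]: float(ages_arr[survivors[i]])
        for i in range(out.n_nodes)
        if out.children[i]
    }
    return out, ages


def bladj_date(topology: Phylogeny, fixed_ages: dict) -> Phylogeny:
    """Assign ages to undated internal nodes by even interpolation (bladj).

    ``fixed_ages`` maps internal node labels to ages and must include the
    root; tips implicitly have age 0.  Nodes are processed breadth-first from
    the root; an undated node on the path between its (already dated) parent
    and its nearest fixed-or-tip descendant receives the evenly interpolated
    age, first assignment winning.  Ties between equally near dated
    descendants are broken toward the oldest.  Ages are clamped to the parent
    age, so branch lengths are always >= 0 and the output is ultrametric.
    """
    n = topology.n_nodes
    label_to_node = {}
    for i in range(n):
        if topology.children[i] and topology.labels[i] is not None:
            label_to_node[topology.labels[i]] = i

    age = np.full(n, np.nan)
    anchored = np.zeros(n, dtype=bool)
    for i in topology.tip_ids:
        age[i] = 0.0
        anchored[i] = True
    for lab, a in fixed_ages.items():
        if lab not in label_to_node:
            raise KeyError(f"fixed age given for unknown internal node label {lab!r}")
        i = label_to_node[lab]
        age[i] = float(a)
        anchored[i] = True
    if np.isnan(age[0]):
        raise ValueError("the root must have a fixed age")

    # consistency: every fixed descendant must be younger than every fixed ancestor
    for i in range(1, n):
        if not anchored[i] or not topology.children[i]:
            continue
        p = topology.parent[i]
        while p != -1:
            if anchored[p] and age[p] < age[i]:
                raise ValueError(
                    f"inconsistent fixed ages: node {topology.labels[i]!r} "
                    f"(age {age[i]}) is a descendant of {topology.labels[p]!r} "
                    f"(age {age[p]})"
                )
            p = topology.parent[p]

    # breadth-first order by edge depth
    edepth = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        edepth[i] = edepth[topology.parent[i]] + 1
    bfs = sorted(range(n), key=lambda i: (edepth[i], i))

    out_age = age.copy()
    for u in bfs:
        if not np.isnan(out_age[u]):
            continue
        a = out_age[topology.parent[u]]  # parent already assigned (BFS order)
        # nearest anchored descendant; ties -> oldest
        best_dist, best_age = None, None
        frontier = [u]
        dist = 0
        while best_dist is None:
            dist += 1
            nxt = []
            for v in frontier:
                for c in topology.children[v]:
                    if anchored[c]:
                        if best_dist is None or age[c] > best_age:
                            best_dist, best_age = dist, age[c]
                    else:
                        nxt.append(c)
            frontier = nxt
        # path dated-parent -> u -> descendant has best_dist + 1 edges
        step = (a - best_age) / (best_dist + 1)
        out_age[u] = min(a - step, a)

    blen = np.full(n, np.nan)
    for i in range(1, n):
        blen[i] = out_age[topology.parent[i]] - out_age[i]
    return Phylogeny(topology.parent.copy(), blen, list(topology.labels))


# --------------------------------------------------------------------- quintet
@dataclass
class VariantSpec:
    """Degradation recipe for one synthesis-style variant."""

    collapse_fraction: float
    collapse_rule: str = "random"
    dated_node_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.collapse_fraction < 1:
            raise ValueError("collapse_fraction must be in [0, 1)")
        if not 0 < self.dated_node_fraction <= 1:
            raise ValueError("dated_node_fraction must be in (0, 1]")
        if self.collapse_rule not in ("random", "youngest-first"):
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")


@dataclass
class DegradationConfig:
    """Parameters of the three synthesis-style variants.

    Defaults are ordered in severity: the apg-like variant collapses 40% of
    internal nodes youngest-first and keeps only 30% of node ages for
    re-dating (a family/genus backbone dated at few calibration points); the
    zanne-like variant collapses 25% at random but keeps all surviving ages (a
    calibrated megatree); the otl-like variant collapses 15% at random with
    half the ages kept (a supertree re-dated from an age database).
    """

    apg: VariantSpec = field(
        default_factory=lambda: VariantSpec(0.40, "youngest-first", 0.3)
    )
    zanne: VariantSpec = field(default_factory=lambda: VariantSpec(0.25, "random", 1.0))
    otl: VariantSpec = field(default_factory=lambda: VariantSpec(0.15, "random", 0.5))
    tip_drop_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.tip_drop_fraction < 1:
            raise ValueError("tip_drop_fraction must be in [0, 1)")

    @property
    def variants(self) -> dict:
        return {"apg": self.apg, "zanne": self.zanne, "otl": self.otl}

    @classmethod
    def zero(cls) -> "DegradationConfig":
        """No degradation at all: the identity limit used in sanity checks."""
        return cls(
            apg=VariantSpec(0.0, "youngest-first", 1.0),
            zanne=VariantSpec(0.0, "random", 1.0),
            otl=VariantSpec(0.0, "random", 1.0),
            tip_drop_fraction=0.0,
        )


@dataclass
class TreeSet:
    """The five-tree experimental unit, harmonised to a common tip set."""

    tree_purpose: Phylogeny
    tree_apg: Phylogeny
    tree_zanne: Phylogeny
    tree_otl: Phylogeny
    tree_random: Phylogeny
    config: DegradationConfig
    common_tips: tuple

    @property
    def trees(self) -> dict:
        return {
            "purpose": self.tree_purpose,
            "apg": self.tree_apg,
            "zanne": self.tree_zanne,
            "otl": self.tree_otl,
            "random": self.tree_random,
        }

    @property
    def degraded(self) -> dict:
        return {"apg": self.tree_apg, "zanne": self.tree_zanne, "otl": self.tree_otl}


def _degrade(tree: Phylogeny, spec: VariantSpec, common, rng) -> Phylogeny:
    topo, ages = collapse_nodes(
        tree,
        spec.collapse_fraction,
        spec.collapse_rule,
        seed=rng.integers(2**31),
    )
    pruned = prune_to_tips(topo, common) if set(common) != set(topo.tip_labels) else topo
    surviving = [
        pruned.labels[i]
        for i in range(1, pruned.n_nodes)
        if pruned.children[i] and pruned.labels[i] in ages
    ]
    # calibration ages concentrate at deep, well-known divergences: retain the
    # oldest dated_node_fraction of surviving node ages for re-dating
    k = int(round(spec.dated_node_fraction * len(surviving)))
    chosen = sorted(surviving, key=lambda lab: -ages[lab])[:k]
    root_lab = pruned.labels[0]
    fixed = {lab: ages[lab] for lab in chosen}
    fixed[root_lab] = ages[root_lab]
    return bladj_date(pruned, fixed)


def make_tree_set(
    n_tips: int,
    root_age: float,
    config: DegradationConfig | None = None,
    seed=0,
) -> TreeSet:
    """Build the five-tree quintet.

    A single shared set of dropped tips is used for all three degraded
    variants, so the common tip set has size ``ceil(n_tips * (1 -
    tip_drop_fraction))`` — the same ~95% overlap observed between empirical
    purpose-built trees and their synthesis-based counterparts.
    """
    if n_tips < 10:
        raise ValueError("need at least 10 tips")
    if config is None:
        config = DegradationConfig()
    ss = np.random.SeedSequence(seed)
    rng_purpose, rng_drop, rng_apg, rng_zanne, rng_otl, rng_rand = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    purpose_full = rescale_to_root_age(
        simulate_coalescent_tree(n_tips, rng_purpose), root_age
    )
    n_common = math.ceil(n_tips * (1.0 - config.tip_drop_fraction))
    all_tips = purpose_full.tip_labels
    common = sorted(
        rng_drop.choice(np.array(all_tips, dtype=object), size=n_common, replace=False)
    )

    variant_rngs = {"apg": rng_apg, "zanne": rng_zanne, "otl": rng_otl}
    degraded = {
        name: _degrade(purpose_full, spec, common, variant_rngs[name])
        for name, spec in config.variants.items()
    }
    mean_root = float(np.mean([t.root_age() for t in degraded.values()]))
    tree_random = rescale_to_root_age(
        simulate_coalescent_tree(n_common, rng_rand, labels=list(common)), mean_root
    )
    tree_purpose = (
        prune_to_tips(purpose_full, common)
        if n_common < n_tips
        else purpose_full
    )
    return TreeSet(
        tree_purpose=tree_purpose,
        tree_apg=degraded["apg"],
        tree_zanne=degraded["zanne"],
        tree_otl=degraded["otl"],
        tree_random=tree_random,
        config=replace(config),
        common_tips=tuple(common),
    )
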