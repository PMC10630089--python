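"""Ancestral presence/absence reconstruction on rooted species trees.

Two reconstruction modes are provided for a binary character with possible
``"?"`` (unknown) leaf states:

* :func:`sankoff_reconstruct` — exact minimum-cost (Sankoff) dynamic
  programming over states {0, 1} with arbitrary non-negative gain and loss
  costs, polytomies handled natively.  Unknown leaves are zero-cost
  wildcards.  The reported labeling follows a canonical tie-break that keeps
  a child in its parent's state (and prefers 0 at the root), which delays
  gains toward the tips; a second dynamic program enumerates the
  (gain, loss) count pairs achievable by co-optimal labelings and flags the
  result ambiguous when the gain count is not unique.

* :func:`dollo_reconstruct` — Dollo parsimony: the character arises exactly
  once and can only be lost thereafter.  The single gain is placed on the
  edge above the last common ancestor of the definitely-present leaves
  (the *latest* possible origin); unknown leaves are resolved to minimize
  losses, and the *earliest* defensible origin (the highest ancestor whose
  subtree contains no definitely-absent leaf) is reported alongside.

The root prior distinguishes characters that were absent before their origin
(``"forced-0"``: a presence at the root is itself counted as a gain, on the
implicit stem edge) from ubiquitous characters (``"free"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import pandas as pd

from .trees import Tree, TreeNode, tree_to_newick, parse_newick

__all__ = [
    "CostModel",
    "Event",
    "ReconstructionResult",
    "sankoff_reconstruct",
    "dollo_reconstruct",
    "annotate_tree",
    "parse_annotated_newick",
]

STEM = None  # parent marker for the implicit edge above the root


@dataclass
class CostModel:
    cost_gain: float = 1.0
    cost_loss: float = 1.0
    root_prior: Literal["free", "forced-0"] = "forced-0"

    def __post_init__(self) -> None:
        if self.cost_gain < 0 or self.cost_loss < 0:
            raise ValueError("transition costs must be non-negative")
        if self.cost_gain == 0 and self.cost_loss == 0:
            raise ValueError("at least one transition cost must be positive")

    def transition(self, parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return self.cost_gain if child_state == 1 else self.cost_loss


@dataclass(frozen=True)
class Event:
    parent: Optional[str]  # None for the implicit stem edge above the root
    child: str
    kind: Literal["gain", "loss"]


@dataclass
class ReconstructionResult:
    node_states: dict[str, int]
    events: list[Event]
    total_cost: float
    n_gains: int
    n_losses: int
    ambiguous_counts: bool = False
    gain_node_latest: Optional[str] = None
    gain_node_earliest: Optional[str] = None

    def event_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"parent": e.parent if e.parent is not None else "<stem>",
                 "child": e.child, "event": e.kind}
                for e in self.events
            ],
            columns=["parent", "child", "event"],
        )


def _validate_leaf_states(tree: Tree, leaf_states: Mapping[str, object]) -> dict[str, str]:
    leaves = set(tree.leaf_names())
    states = {str(k): str(v) for k, v in leaf_states.items()}
    missing = leaves - states.keys()
    if missing:
        raise ValueError(f"leaves missing from state map: {sorted(missing)}")
    extra = states.keys() - leaves
    if extra:
        raise ValueError(f"state map names not in tree: {sorted(extra)}")
    bad = {k: v for k, v in states.items() if v not in {"0", "1", "?"}}
    if bad:
        raise ValueError(f"leaf states must be 0, 1 or ?: {bad}")
    return states


def _events_from_labeling(
    tree: Tree, node_states: dict[str, int], stem_gain: bool
) -> list[Event]:
    events: list[Event] = []
    if stem_gain:
        events.append(Event(STEM, tree.root.name, "gain"))
    for parent, child in tree.edges():
        ps, cs = node_states[parent.name], node_states[child.name]
        if ps == 0 and cs == 1:
            events.append(Event(parent.name, child.name, "gain"))
        elif ps == 1 and cs == 0:
            events.append(Event(parent.name, child.name, "loss"))
    return events


def sankoff_reconstruct(
    tree: Tree, leaf_states: Mapping[str, object], costs: CostModel | None = None
) -> ReconstructionResult:
    """Exact minimum-cost binary ancestral reconstruction (see module docs)."""
    costs = costs or CostModel()
    states = _validate_leaf_states(tree, leaf_states)
    INF = math.inf

    cost: dict[str, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            observed = states[node.name]
            if observed == "?":
                cost[node.name] = [0.0, 0.0]
            else:
                s = int(observed)
                cost[node.name] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            totals = [0.0, 0.0]
            for s in (0, 1):
                for child in node.children:
                    totals[s] += min(
                        costs.transition(s, t) + cost[child.name][t] for t in (0, 1)
                    )
            cost[node.name] = totals

    root = tree.root
    if costs.root_prior == "forced-0":
        root_options = {0: cost[root.name][0], 1: costs.cost_gain + cost[root.name][1]}
    else:
        root_options = {0: cost[root.name][0], 1: cost[root.name][1]}
    total = min(root_options.values())
    # tie-break at the root: prefer absent (0), delaying the gain downward
    root_state = 0 if root_options[0] <= root_options[1] else 1

    node_states: dict[str, int] = {root.name: root_state}
    order = [n for n in tree.preorder() if n.parent is not None]
    for node in order:
        ps = node_states[node.parent.name]
        options = {
            t: costs.transition(ps, t) + cost[node.name][t] for t in (0, 1)
        }
        best = min(options.values())
        # prefer keeping the parent's state on ties (delays transformations)
        if options[ps] == best:
            node_states[node.name] = ps
        else:
            node_states[node.name] = 0 if options[0] == best else 1

    stem_gain = costs.root_prior == "forced-0" and root_state == 1
    events = _events_from_labeling(tree, node_states, stem_gain)
    n_gains = sum(1 for e in events if e.kind == "gain")
    n_losses = len(events) - n_gains

    ambiguous = _gain_counts_ambiguous(tree, cost, costs, root_options, total)

    return ReconstructionResult(
        node_states=node_states,
        events=events,
        total_cost=total,
        n_gains=n_gains,
        n_losses=n_losses,
        ambiguous_counts=ambiguous,
    )


def _gain_counts_ambiguous(
    tree: Tree,
    cost: dict[str, list[float]],
    costs: CostModel,
    root_options: dict[int, float],
    total: float,
) -> bool:
    """Second DP: (gains, losses) pairs achievable by co-optimal labelings."""
    pairs: dict[str, list[set[tuple[int, int]]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            pairs[node.name] = [
                {(0, 0)} if math.isfinite(cost[node.name][s]) else set() for s in (0, 1)
            ]
            continue
        per_state: list[set[tuple[int, int]]] = []
        for s in (0, 1):
            if not math.isfinite(cost[node.name][s]):
                per_state.append(set())
                continue
            acc: set[tuple[int, int]] = {(0, 0)}
            for child in node.children:
                child_cost = {
                    t: costs.transition(s, t) + cost[child.name][t] for t in (0, 1)
                }
                best = min(child_cost.values())
                contrib: set[tuple[int, int]] = set()
                for t in (0, 1):
                    if child_cost[t] == best and pairs[child.name][t]:
                        dg = 1 if (s, t) == (0, 1) else 0
                        dl = 1 if (s, t) == (1, 0) else 0
                        contrib |= {(g + dg, l + dl) for g, l in pairs[child.name][t]}
                acc = {(g1 + g2, l1 + l2) for g1, l1 in acc for g2, l2 in contrib}
            per_state.append(acc)
        pairs[node.name] = per_state

    root = tree.root.name
    achievable: set[tuple[int, int]] = set()
    for s in (0, 1):
        if root_options[s] == total:
            stem = 1 if (s == 1 and costs.root_prior == "forced-0") else 0
            achievable |= {(g + stem, l) for g, l in pairs[root][s]}
    return len({g for g, _ in achievable}) > 1


def dollo_reconstruct(tree: Tree, leaf_states: Mapping[str, object]) -> ReconstructionResult:
    """Single-gain (Dollo) reconstruction; see module docstring for the rules."""
    states = _validate_leaf_states(tree, leaf_states)
    present = [name for name, s in states.items() if s == "1"]
    if not present:
        node_states = {n.name: 0 for n in tree.postorder()}
        return ReconstructionResult(
            node_states=node_states,
            events=[],
            total_cost=0.0,
            n_gains=0,
            n_losses=0,
        )

    gain_node = tree.lca(present)

    # earliest defensible origin: walk up while the enclosing subtree still
    # contains no definitely-absent leaf (unknowns may be resolved present)
    earliest = gain_node
    node = gain_node.parent
    while node is not None:
        leaf_values = {states[leaf.name] for leaf in tree.subtree_leaves(node)}
        if "0" in leaf_values:
            break
        earliest = node
        node = node.parent

    # inside the gain clade, a node stays absent only when its subtree holds a
    # definite absence and no definite presence; this yields the loss-minimal
    # resolution of the unknowns (one loss per maximal such subtree)
    in_clade: set[str] = {n.name for n in tree.postorder() if _is_descendant(n, gain_node)}
    has_present: dict[str, bool] = {}
    has_absent: dict[str, bool] = {}
    for n in tree.postorder():
        if n.is_leaf:
            has_present[n.name] = states[n.name] == "1"
            has_absent[n.name] = states[n.name] == "0"
        else:
            has_present[n.name] = any(has_present[c.name] for c in n.children)
            has_absent[n.name] = any(has_absent[c.name] for c in n.children)

    node_states: dict[str, int] = {}
    for n in tree.preorder():
        if n.name not in in_clade:
            node_states[n.name] = 0
        elif n.parent is not None and n.parent.name in in_clade and node_states[n.parent.name] == 0:
            node_states[n.name] = 0
        else:
            node_states[n.name] = 0 if (has_absent[n.name] and not has_present[n.name]) else 1

    stem_gain = gain_node is tree.root
    events = _events_from_labeling(tree, node_states, stem_gain)
    n_gains = sum(1 for e in events if e.kind == "gain")
    n_losses = len(events) - n_gains
    assert n_gains == 1, "Dollo reconstruction must contain exactly one gain"

    return ReconstructionResult(
        node_states=node_states,
        events=events,
        total_cost=float(n_gains + n_losses),
        n_gains=n_gains,
        n_losses=n_losses,
        gain_node_latest=gain_node.name,
        gain_node_earliest=earliest.name,
    )


def _is_descendant(node: TreeNode, ancestor: TreeNode) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def annotate_tree(tree: Tree, result: ReconstructionResult) -> tuple[str, pd.DataFrame]:
    """Project a reconstruction onto the tree as NHX state comments.

    Returns the annotated Newick string and the event table.  The annotation
    round-trips: :func:`parse_annotated_newick` recovers all node states.
    """
    tree_names = {n.name for n in tree.postorder()}
    if set(result.node_states) != tree_names:
        raise ValueError("reconstruction does not match tree: node name sets differ")
    comments = {name: f"state={state}" for name, state in result.node_states.items()}
    return tree_to_newick(tree, comments), result.event_table()


_NHX_STATE = r"\[&&NHX:state=(\d)\]"


def parse_annotated_newick(text: str) -> tuple[Tree, dict[str, int]]:
    """Parse Newick produced by :func:`annotate_tree` back into tree + states."""
    import re

    states: dict[str, int] = {}

    # strip comments while remembering which label each one followed
    pattern = re.compile(r"([^(),;\[\]]+)" + _NHX_STATE)
    for match in pattern.finditer(text):
        label = match.group(1).strip().strip("'")
        states[label] = int(match.group(2))
    cleaned = re.sub(_NHX_STATE, "", text)
    tree = parse_newick(cleaned)
    missing = {n.name for n in tree.postorder()} - states.keys()
    if missing:
        raise ValueError(f"annotated Newick lacks states for: {sorted(missing)}")
    return tree, states
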