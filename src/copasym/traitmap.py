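"""Small-parsimony mapping of discrete sexual characters on a cladogram.

Unit-cost minimum-change reconstruction (Fitch parsimony, implemented as the
Sankoff dynamic program so that polytomies and missing leaf states are handled
exactly): the minimum number of state changes needed on the tree to explain
the observed leaf states, one optimal internal labeling as a witness, and the
set of equally parsimonious root states.  An exhaustive scenario enumerator
supports gain/loss narratives on small trees, e.g. comparing independent-gain
against gain-then-loss histories of one-sided mating.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import dendropy

from .datatypes import CharacterOnTree, ParsimonyResult, ValidationError

_INF = math.inf

#: enumerate_scenarios refuses trees above this leaf count (state^internal blowup).
MAX_ENUM_LEAVES = 12


def _node_key(node: dendropy.Node, index: int) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{index}"


def _prepare(character: CharacterOnTree):
    """Assign stable keys, collect the state alphabet and per-leaf states."""
    tree = character.tree
    keys: dict[int, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[id(node)] = _node_key(node, i)
    leaf_states: dict[str, str | None] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in character.states:
            raise ValidationError(f"leaf {label!r} has no state for {character.name!r}")
        leaf_states[label] = character.states[label]
    alphabet = sorted({s for s in leaf_states.values() if s is not None})
    if not alphabet:
        raise ValidationError(f"character {character.name!r} has no determined leaf state")
    return tree, keys, leaf_states, alphabet


def fitch_min_changes(character: CharacterOnTree) -> ParsimonyResult:
    """Minimum number of unit-cost state changes for one character on the tree.

    Leaves with missing state ("nd") contribute no constraint.  Returns one
    optimal labeling (deterministic tie-break: alphabetically first state) and
    the set of root states achieving the minimum.
    """
    tree, keys, leaf_states, alphabet = _prepare(character)
    idx = {s: i for i, s in enumerate(alphabet)}
    ns = len(alphabet)

    cost: dict[int, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = leaf_states[node.taxon.label]
            if state is None:
                cost[id(node)] = [0.0] * ns
            else:
                c = [_INF] * ns
                c[idx[state]] = 0.0
                cost[id(node)] = c
        else:
            c = [0.0] * ns
            for child in node.child_nodes():
                cc = cost[id(child)]
                best = min(cc)
                for s in range(ns):
                    # stay (cc[s]) or switch from the cheapest child state (+1)
                    c[s] += min(cc[s], best + 1.0)
            cost[id(node)] = c

    root = tree.seed_node
    root_cost = cost[id(root)]
    min_changes = min(root_cost)
    root_states = frozenset(alphabet[s] for s in range(ns) if root_cost[s] == min_changes)

    # Witness labeling by deterministic top-down backtrack.
    labeling: dict[str, str] = {}
    chosen: dict[int, int] = {}
    root_choice = min(s for s in range(ns) if root_cost[s] == min_changes)
    chosen[id(root)] = root_choice
    labeling[keys[id(root)]] = alphabet[root_choice]
    for node in tree.preorder_node_iter():
        if id(node) not in chosen:
            continue
        s_parent = chosen[id(node)]
        for child in node.child_nodes():
            cc = cost[id(child)]
            best = min(
                range(ns),
                key=lambda t: (cc[t] + (0.0 if t == s_parent else 1.0), t),
            )
            chosen[id(child)] = best
            labeling[keys[id(child)]] = alphabet[best]

    return ParsimonyResult(
        character=character.name,
        min_changes=int(min_changes),
        labeling=labeling,
        root_states=root_states,
    )


def _labeling_cost(
    tree: dendropy.Tree,
    keys: Mapping[int, str],
    assignment: Mapping[str, str | None],
) -> int:
    """Number of state changes along edges whose two endpoints both have states."""
    changes = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        a = assignment[keys[id(parent)]]
        b = assignment[keys[id(node)]]
        if a is not None and b is not None and a != b:
            changes += 1
    return changes


def enumerate_scenarios(
    character: CharacterOnTree, max_extra: int = 0
) -> list[tuple[int, dict[str, str]]]:
    """All internal labelings within *max_extra* changes of the optimum.

    Exhaustive over the observed state alphabet at every internal node; only
    feasible on small trees (<= 12 leaves).  Each scenario is returned as
    (cost, full node->state map); leaves keep their observed states, missing
    leaves are omitted from the map.
    """
    tree, keys, leaf_states, alphabet = _prepare(character)
    n_leaves = len(leaf_states)
    if n_leaves > MAX_ENUM_LEAVES:
        raise ValidationError(
            f"scenario enumeration limited to {MAX_ENUM_LEAVES} leaves, got {n_leaves}"
        )
    if max_extra < 0:
        raise ValidationError("max_extra must be non-negative")
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = fitch_min_changes(character).min_changes
    budget = best + max_extra
    scenarios: list[tuple[int, dict[str, str]]] = []
    for combo in itertools.product(alphabet, repeat=len(internal)):
        assignment: dict[str, str | None] = dict(leaf_states)
        for node, state in zip(internal, combo):
            assignment[keys[id(node)]] = state
        cost = _labeling_cost(tree, keys, assignment)
        if cost <= budget:
            scenarios.append(
                (cost, {k: v for k, v in assignment.items() if v is not None})
            )
    scenarios.sort(key=lambda cs: (cs[0], sorted(cs[1].items()).__repr__()))
    return scenarios
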