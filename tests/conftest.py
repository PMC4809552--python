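"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from accelscan.phylo import (
    PhyloTree,
    SubstitutionModel,
    parse_newick,
)

# An 8-leaf tree with a monophyletic 4-leaf focal clade (f1..f4) whose stem
# edge is labeled "stem"; total tree length 2.0.
EIGHT_LEAF_NEWICK = (
    "(((f1:0.1,f2:0.12)fa:0.08,(f3:0.11,f4:0.1)fb:0.07)stem:0.15,"
    "((o1:0.25,o2:0.22)oa:0.1,(o3:0.3,o4:0.28)ob:0.12)oc:0.1)root;"
)
FOCAL = ("f1", "f2", "f3", "f4")


@pytest.fixture(scope="session")
def jc() -> SubstitutionModel:
    return SubstitutionModel.jc69()


@pytest.fixture(scope="session")
def hky() -> SubstitutionModel:
    return SubstitutionModel.hky85(kappa=4.0, pi=[0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="session")
def eight_leaf_tree() -> PhyloTree:
    return parse_newick(EIGHT_LEAF_NEWICK)


def random_tree(rng: np.random.Generator, n_leaves: int,
                max_branch: float = 0.5) -> PhyloTree:
    """Random rooted binary tree by sequential joining, random branch lengths."""
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        ta, tb = rng.uniform(0.01, max_branch, size=2)
        joined = f"({a}:{ta:.6f},{b}:{tb:.6f})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [joined]
    return parse_newick(parts[0] + ";")


def enumeration_loglik(tree: PhyloTree, model: SubstitutionModel,
                       column: dict[str, str],
                       scales: dict[str, float] | None = None) -> float:
    """Exhaustive sum over all ancestral-state assignments (pruning oracle).

    Missing leaves ('-'/'N' or absent from `column`) contribute a factor of 1.
    """
    scales = scales or {}
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    P = {}
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        t = float(tree.length[i]) * scales.get(tree.names[i], 1.0)
        P[i] = model.transition_matrix(t)
    total = 0.0
    for assignment in itertools.product(range(4), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        prob = model.pi[state[tree.root]]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            parent_state = state[int(tree.parent[i])]
            if tree.is_leaf(i):
                base = column.get(tree.names[i], "N")
                if base in "ACGT":
                    prob *= P[i][parent_state, "ACGT".index(base)]
            else:
                prob *= P[i][parent_state, state[i]]
        total += prob
    return float(np.log(total))


def canonical_form(tree: PhyloTree, node: int | None = None, ndigits: int = 10):
    """Rooted-topology + branch-length canonical form for tree comparison."""
    if node is None:
        node = tree.root
    if tree.is_leaf(node):
        return (tree.names[node], round(float(tree.length[node]), ndigits))
    kids = tuple(sorted((canonical_form(tree, c, ndigits)
                         for c in tree.children[node]), key=repr))
    ln = 0.0 if node == tree.root else float(tree.length[node])
    return (kids, round(ln, ndigits))
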