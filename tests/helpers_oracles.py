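"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning machinery: likelihoods are
computed by exhaustive enumeration over internal-node state assignments, and
parsimony by enumeration over all internal labelings.
"""

from __future__ import annotations

import itertools

import numpy as np

from clockshift.phylo_io import IUPAC_PARTIALS, CODON_INDEX, Tree
from clockshift.substitution_models import RateMatrix, transition_matrix


def enum_site_likelihood(
    tree: Tree,
    chars: dict[str, str],
    q: RateMatrix,
    category_rates: np.ndarray,
) -> float:
    """Site likelihood by summation over all internal-node states and rate
    categories (equal category weights)."""
    n_states = q.n_states
    internals = [n for n in tree.nodes() if not n.is_tip]
    total = 0.0
    for r in category_rates:
        P = {
            n.index: transition_matrix(q, (n.length or 0.0) * r)
            for n in tree.nodes()
            if n.parent is not None
        }
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            amap = {n.index: s for n, s in zip(internals, assign)}
            p = q.freqs[amap[tree.root.index]]
            for n in tree.nodes():
                if n.parent is None:
                    continue
                if n.is_tip:
                    tipv = tip_partial(chars[n.name], n_states)
                    p *= float(P[n.index][amap[n.parent.index]] @ tipv)
                else:
                    p *= P[n.index][amap[n.parent.index], amap[n.index]]
            total += p / len(category_rates)
    return total


def tip_partial(symbol: str, n_states: int) -> np.ndarray:
    if n_states == 4:
        return np.asarray(IUPAC_PARTIALS[symbol], dtype=float)
    v = np.zeros(n_states)
    idx = CODON_INDEX.get(symbol)
    if idx is None:
        v[:] = 1.0
    else:
        v[idx] = 1.0
    return v


def enum_alignment_loglik(tree, aln, q, category_rates) -> float:
    total = 0.0
    for col in aln.columns():
        chars = dict(zip(aln.taxa, col))
        total += np.log(enum_site_likelihood(tree, chars, q, category_rates))
    return float(total)


def enum_marginal_posterior(
    tree: Tree,
    chars: dict[str, str],
    q: RateMatrix,
    category_rates: np.ndarray,
    node_index: int,
) -> np.ndarray:
    """Posterior state distribution at one internal node by enumeration."""
    n_states = q.n_states
    internals = [n for n in tree.nodes() if not n.is_tip]
    joint = np.zeros(n_states)
    for r in category_rates:
        P = {
            n.index: transition_matrix(q, (n.length or 0.0) * r)
            for n in tree.nodes()
            if n.parent is not None
        }
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            amap = {n.index: s for n, s in zip(internals, assign)}
            p = q.freqs[amap[tree.root.index]]
            for n in tree.nodes():
                if n.parent is None:
                    continue
                if n.is_tip:
                    p *= float(
                        P[n.index][amap[n.parent.index]]
                        @ tip_partial(chars[n.name], n_states)
                    )
                else:
                    p *= P[n.index][amap[n.parent.index], amap[n.index]]
            joint[amap[node_index]] += p / len(category_rates)
    return joint / joint.sum()


def exhaustive_min_changes(tree: Tree, tip_states: dict[str, int]) -> int:
    """Minimum number of state changes by enumeration over all internal
    assignments (binary states)."""
    internals = [n for n in tree.nodes() if not n.is_tip]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internals)):
        amap = {n.index: s for n, s in zip(internals, assign)}
        for n in tree.nodes():
            if n.is_tip:
                amap[n.index] = tip_states[n.name]
        changes = sum(
            1
            for n in tree.nodes()
            if n.parent is not None and amap[n.index] != amap[n.parent.index]
        )
        best = changes if best is None else min(best, changes)
    return best


def random_tree(rng: np.random.Generator, n_tips: int, rooted: bool = True) -> Tree:
    """Random bifurcating topology with exponential branch lengths."""
    from clockshift.phylo_io import TreeNode

    nodes = [TreeNode(name=f"T{i}", length=float(rng.exponential(0.2)))
             for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.2)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = TreeNode()
    for n in nodes:
        root.add_child(n)
    return Tree(root, rooted=rooted)


def random_hky_params(rng: np.random.Generator, gamma: bool = False):
    from clockshift.substitution_models import HKYParams

    pi = rng.dirichlet(np.ones(4) * 5)
    pi = pi / pi.sum()
    return HKYParams(
        kappa=float(rng.uniform(0.5, 8.0)),
        pi=pi,
        gamma_shape=float(rng.uniform(0.3, 2.0)) if gamma else None,
        n_categories=int(rng.integers(2, 4)) if gamma else 5,
    )
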