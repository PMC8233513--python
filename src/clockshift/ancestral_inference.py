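"""Marginal (empirical-Bayes) ancestral sequence reconstruction and Fitch
parsimony counting of discrete-state changes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from clockshift.likelihood_engine import PruningEngine, _model_q_rates
from clockshift.phylo_io import Alignment, SitePatterns, Tree, TreeNode, compress_patterns

__all__ = [
    "AncestralPosterior",
    "ParsimonyResult",
    "marginal_reconstruction",
    "extract_sites",
    "fitch_min_changes",
    "node_label",
]

#: alphabetical order used to break MAP ties deterministically
_ALPHA_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


def node_label(node: TreeNode) -> str:
    """Stable label for a node: its name if set, else ``N<postorder index>``."""
    return node.name if node.name else f"N{node.index}"


@dataclass
class AncestralPosterior:
    """Per-node, per-column posterior state probabilities.

    ``probs[label]`` has shape (n_columns, n_states); rows sum to 1.
    ``map_states`` holds the most-probable state per column with alphabetical
    tie-breaking; tied positions are listed in ``ties``.
    """

    states: tuple[str, ...]
    node_labels: list[str]
    probs: dict[str, np.ndarray]
    map_states: dict[str, list[str]]
    map_probs: dict[str, np.ndarray]
    ties: dict[str, list[int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        first = next(iter(self.probs.values()))
        return first.shape[0]

    def map_sequence(self, label: str) -> str:
        return "".join(self.map_states[label])


def marginal_reconstruction(
    tree: Tree,
    aln: Alignment | SitePatterns,
    model,
    category_weighting: str = "posterior",
) -> AncestralPosterior:
    """Posterior state distributions at every internal node of a fitted tree.

    For each node u, site and rate category c the joint weight is
    (1/K) * P(data below u | state, c) * P(data elsewhere, state at u | c);
    normalizing over states and categories yields the marginal posterior.
    With ``category_weighting="equal"`` the per-category state posteriors are
    instead averaged with equal weights.
    """
    if category_weighting not in ("posterior", "equal"):
        raise ValueError("category_weighting must be 'posterior' or 'equal'")
    patterns = aln if isinstance(aln, SitePatterns) else compress_patterns(aln)
    engine = PruningEngine(tree, patterns)
    q, rates = _model_q_rates(model)
    t = engine.branch_length_vector()
    n_pat = patterns.n_patterns
    n_states = engine.n_states
    nodes = tree.nodes()
    internal = [n for n in nodes if not n.is_tip]

    joint = {n.index: np.zeros((n_pat, n_states)) for n in internal}
    per_cat_norm = np.zeros((len(rates), n_pat))
    per_cat_joint = {
        n.index: np.zeros((len(rates), n_pat, n_states)) for n in internal
    }

    for ci, r in enumerate(rates):
        p_all = engine._all_transition_matrices(q, t * r)
        down: dict[int, np.ndarray] = {}
        for i in engine.order:  # postorder internals
            acc = np.ones((n_pat, n_states))
            for c in engine.children[i]:
                child = engine.tip_partial.get(c, None)
                if child is None:
                    child = down[c]
                acc = acc * (child @ p_all[c].T)
            down[i] = acc
        out: dict[int, np.ndarray] = {
            engine.root_index: np.tile(q.freqs, (n_pat, 1))
        }
        for node in tree.preorder():
            if node.is_tip:
                continue
            u = node.index
            # message through each child = P_child @ down_child
            msgs = {}
            for c in engine.children[u]:
                child = engine.tip_partial.get(c, down.get(c))
                msgs[c] = child @ p_all[c].T
            for child_node in node.children:
                if child_node.is_tip:
                    continue
                v = child_node.index
                excl = out[u].copy()
                for c in engine.children[u]:
                    if c != v:
                        excl *= msgs[c]
                out[v] = excl @ p_all[v]
        for n in internal:
            j = down[n.index] * out[n.index]
            per_cat_joint[n.index][ci] = j
        per_cat_norm[ci] = (down[engine.root_index] * out[engine.root_index]).sum(axis=1)

    for n in internal:
        if category_weighting == "posterior":
            total = per_cat_joint[n.index].sum(axis=0)  # (n_pat, n_states)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                normed = per_cat_joint[n.index] / per_cat_norm[:, :, None]
            total = np.nan_to_num(normed, nan=0.0).sum(axis=0)
        denom = total.sum(axis=1, keepdims=True)
        denom = np.where(denom > 0, denom, 1.0)
        joint[n.index] = total / denom

    col_map = patterns.column_to_pattern
    labels = [node_label(n) for n in internal]
    probs: dict[str, np.ndarray] = {}
    map_states: dict[str, list[str]] = {}
    map_probs: dict[str, np.ndarray] = {}
    ties: dict[str, list[int]] = {}
    states = tuple(q.states)
    # tie-break order: alphabetical state label, then matrix order
    tie_rank = np.array(
        [(_ALPHA_ORDER.get(s[0], 99), s) for s in states], dtype=object
    )
    order_idx = sorted(range(len(states)), key=lambda i: (tie_rank[i][0], tie_rank[i][1]))
    for n, label in zip(internal, labels):
        post = joint[n.index][col_map]  # expand patterns to columns
        probs[label] = post
        best = post.max(axis=1)
        tied_cols: list[int] = []
        chosen: list[str] = []
        for col in range(post.shape[0]):
            cand = [i for i in order_idx if post[col, i] >= best[col] - 1e-12]
            if len(cand) > 1:
                tied_cols.append(col)
            chosen.append(states[cand[0]])
        map_states[label] = chosen
        map_probs[label] = best
        if tied_cols:
            ties[label] = tied_cols
    return AncestralPosterior(
        states=states,
        node_labels=labels,
        probs=probs,
        map_states=map_states,
        map_probs=map_probs,
        ties=ties,
        meta={
            "method": "marginal (empirical Bayes)",
            "category_weighting": category_weighting,
        },
    )


def extract_sites(
    post: AncestralPosterior,
    nodes: Sequence[str] | None = None,
    columns: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tidy table of MAP states and posteriors.

    ``columns`` are 1-based; ``None`` selects everything.
    """
    nodes = list(post.node_labels) if nodes is None else list(nodes)
    unknown = [n for n in nodes if n not in post.probs]
    if unknown:
        raise KeyError(f"unknown node labels: {unknown}")
    cols = list(range(1, post.n_columns + 1)) if columns is None else list(columns)
    bad = [c for c in cols if not 1 <= c <= post.n_columns]
    if bad:
        raise IndexError(f"columns out of range (1-based): {bad}")
    rows = []
    for label in nodes:
        p = post.probs[label]
        for c in cols:
            row = {
                "node": label,
                "column_1based": c,
                "map_state": post.map_states[label][c - 1],
                "prob": float(post.map_probs[label][c - 1]),
            }
            for k, s in enumerate(post.states):
                row[f"p_{s}"] = float(p[c - 1, k])
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ParsimonyResult:
    """Minimum number of state changes and one optimal assignment."""

    n_changes: int
    assignment: dict[str, Hashable]

    def to_dict(self) -> dict:
        return {"n_changes": self.n_changes, "assignment": dict(self.assignment)}


def fitch_min_changes(
    tree: Tree,
    tip_states: Mapping[str, Hashable],
    missing_as_wildcard: bool = True,
) -> ParsimonyResult:
    """Fitch parsimony count of discrete-state changes on a tree.

    Polytomies are resolved arbitrarily (with a warning) into bifurcations;
    tips absent from ``tip_states`` become wildcards when
    ``missing_as_wildcard`` is set, otherwise raise.
    """
    work = tree.copy()
    # a basal trifurcation on an unrooted tree is a representation artifact,
    # not a data polytomy: resolve it silently
    real_polytomy = any(
        len(n.children) > 2
        for n in work.postorder()
        if not (n.parent is None and not work.rooted and len(n.children) == 3)
    )
    if _resolve_polytomies(work.root):
        if real_polytomy:
            warnings.warn("polytomies resolved arbitrarily before Fitch pass")
        work = Tree(work.root, rooted=work.rooted)

    all_states = set(tip_states.values())
    if not all_states:
        raise ValueError("tip_states is empty")

    sets: dict[int, frozenset] = {}
    changes = 0
    for node in work.postorder():
        if node.is_tip:
            if node.name in tip_states:
                sets[node.index] = frozenset([tip_states[node.name]])
            elif missing_as_wildcard:
                sets[node.index] = frozenset(all_states)
            else:
                raise ValueError(f"tip {node.name!r} has no state")
        else:
            acc: frozenset | None = None
            for child in node.children:
                s = sets[child.index]
                if acc is None:
                    acc = s
                else:
                    inter = acc & s
                    if inter:
                        acc = inter
                    else:
                        acc = acc | s
                        changes += 1
            sets[node.index] = acc  # type: ignore[assignment]

    assignment: dict[str, Hashable] = {}
    order = sorted(all_states, key=repr)
    for node in work.preorder():
        s = sets[node.index]
        if node.parent is None:
            state = next(x for x in order if x in s)
        else:
            parent_state = assignment[node_label(node.parent)]
            state = parent_state if parent_state in s else next(x for x in order if x in s)
        assignment[node_label(node)] = state
    return ParsimonyResult(n_changes=changes, assignment=assignment)


def _resolve_polytomies(root: TreeNode) -> bool:
    """In-place arbitrary resolution of multifurcations; True if any found."""
    found = False
    stack = [root]
    while stack:
        node = stack.pop()
        while len(node.children) > 2:
            found = True
            a = node.children.pop()
            b = node.children.pop()
            joint = TreeNode(length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
        stack.extend(node.children)
    return found
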