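"""Trees, alignments, branch rate-class labels and site-pattern compression.

Trees are stored rooted internally; an "unrooted" tree is represented by a
basal multifurcation with the ``rooted`` flag cleared.  Branch lengths are
expected substitutions per site.  Every branch carries a small-integer rate
class (default 0) used by the local-clock machinery.

Newick extensions: ``#k`` after a node marks the single branch above it with
rate class ``k``; ``$k`` marks the branch above the node and every branch of
the clade below it.  This mirrors the de-facto convention of widely used ML
phylogenetics programs.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "Tree",
    "TreeNode",
    "Alignment",
    "SitePatterns",
    "BranchLabeling",
    "NewickParseError",
    "AlignmentError",
    "parse_newick",
    "write_newick",
    "root_on_edge",
    "read_alignment",
    "write_alignment",
    "compress_patterns",
    "NUC_STATES",
    "IUPAC_PARTIALS",
    "SENSE_CODONS",
    "CODON_INDEX",
    "STOP_CODONS",
]

NUC_STATES = "TCAG"  # order matches the usual codon-table layout

#: IUPAC nucleotide codes -> 0/1 partial-likelihood vector over NUC_STATES.
IUPAC_PARTIALS: dict[str, tuple[int, int, int, int]] = {
    "T": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "A": (0, 0, 1, 0),
    "G": (0, 0, 0, 1),
    "U": (1, 0, 0, 0),
    "Y": (1, 1, 0, 0),
    "R": (0, 0, 1, 1),
    "W": (1, 0, 1, 0),
    "S": (0, 1, 0, 1),
    "K": (1, 0, 0, 1),
    "M": (0, 1, 1, 0),
    "B": (1, 1, 0, 1),
    "D": (1, 0, 1, 1),
    "H": (1, 1, 1, 0),
    "V": (0, 1, 1, 1),
    "N": (1, 1, 1, 1),
    "X": (1, 1, 1, 1),
    "-": (1, 1, 1, 1),
    "?": (1, 1, 1, 1),
    ".": (1, 1, 1, 1),
}

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUC_STATES
    for b in NUC_STATES
    for c in NUC_STATES
    if a + b + c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


class NewickParseError(ValueError):
    """Raised on malformed Newick input; message names the offending token."""


class AlignmentError(ValueError):
    """Raised on malformed alignment input."""


class TreeNode:
    """A node in a :class:`Tree`.

    ``length`` is the length of the branch joining the node to its parent
    (``None`` for the root or when absent in the input); ``rate_class`` is the
    local-clock class of that same branch.
    """

    __slots__ = ("name", "length", "rate_class", "children", "parent", "index")

    def __init__(self, name: str | None = None, length: float | None = None,
                 rate_class: int = 0) -> None:
        self.name = name
        self.length = length
        self.rate_class = rate_class
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or self.index} {kind} len={self.length}>"


class Tree:
    """Rooted container for a phylogeny with per-branch rate classes."""

    def __init__(self, root: TreeNode, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        self._reindex()
        self._validate()

    # ------------------------------------------------------------------ admin
    def _reindex(self) -> None:
        for i, node in enumerate(self.postorder()):
            node.index = i

    def _validate(self) -> None:
        names = [t.name for t in self.tips()]
        if len(names) < 2:
            raise ValueError("tree must have at least 2 tips")
        if any(n is None for n in names):
            raise ValueError("every tip must be named")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate tip names: {sorted(dupes)}")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} above "
                    f"{node.name or 'internal node'}"
                )

    # ------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]  # type: ignore[misc]

    def nodes(self) -> list[TreeNode]:
        return list(self.postorder())

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # ----------------------------------------------------------------- query
    def find(self, name: str) -> TreeNode:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def mrca(self, names: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named tips."""
        want = set(names)
        missing = want - set(self.tip_names())
        if missing:
            raise KeyError(f"unknown tips: {sorted(missing)}")
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[node] = {node.name} & want  # type: ignore[arg-type]
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if below[node] == want:
                return node
        raise RuntimeError("unreachable: root must cover all tips")

    def clade_nodes(self, mrca: TreeNode, include_stem: bool = False) -> list[TreeNode]:
        """All nodes whose parent branch lies inside the clade under ``mrca``."""
        out: list[TreeNode] = []
        stack = list(mrca.children)
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        if include_stem and mrca.parent is not None:
            out.append(mrca)
        return out

    def resolve_branch(self, selector) -> TreeNode:
        """Resolve a branch selector to the child node of that branch.

        Accepts a node name (tip or internal label) or an iterable of tip
        names (the branch above their MRCA).
        """
        if isinstance(selector, TreeNode):
            return selector
        if isinstance(selector, str):
            node = self.find(selector)
        else:
            names = list(selector)
            node = self.find(names[0]) if len(names) == 1 else self.mrca(names)
        if node.parent is None:
            raise ValueError("selector resolves to the root, which has no branch")
        return node

    # ------------------------------------------------------------- distances
    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Tip names and the matrix of pairwise path lengths."""
        tips = self.tips()
        names = [t.name for t in tips]
        n = len(tips)
        # accumulate path to root per tip
        paths: list[dict[TreeNode, float]] = []
        for tip in tips:
            d = 0.0
            path: dict[TreeNode, float] = {tip: 0.0}
            node = tip
            while node.parent is not None:
                d += node.length or 0.0
                node = node.parent
                path[node] = d
            paths.append(path)
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            # dicts are in tip->root insertion order, so the first shared
            # node is the LCA
            node = next(k for k in paths[i] if k in paths[j])
            D[i, j] = D[j, i] = paths[i][node] + paths[j][node]
        return names, D  # type: ignore[return-value]

    def depths(self) -> dict[TreeNode, float]:
        """Distance from the root to every node."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node] = out[node.parent] + (node.length or 0.0)
        return out

    # ------------------------------------------------------------ rate class
    def rate_classes(self) -> list[int]:
        return sorted({n.rate_class for n in self.postorder() if n.parent is not None})

    def normalize_rate_classes(self) -> dict[int, int]:
        """Remap rate classes to a contiguous {0..C-1}; 0 stays 0 if present."""
        present = self.rate_classes()
        mapping = {old: new for new, old in enumerate(sorted(present))}
        if 0 in mapping and mapping[0] != 0:
            raise RuntimeError("class 0 must map to 0")
        for node in self.postorder():
            if node.parent is not None:
                node.rate_class = mapping[node.rate_class]
        return mapping

    # ------------------------------------------------------------------ misc
    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.rate_class)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root), rooted=self.rooted)

    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a basal trifurcation."""
        new = self.copy()
        root = new.root
        if len(root.children) == 2:
            a, b = root.children
            keep, fold = (a, b) if not a.is_tip else (b, a)
            if keep.is_tip:
                new.rooted = False
                return new  # 2-tip tree: nothing to collapse
            merged = (fold.length or 0.0) + (keep.length or 0.0)
            root.children = list(keep.children) + [fold]
            for c in root.children:
                c.parent = root
            fold.length = merged
            fold.rate_class = max(fold.rate_class, keep.rate_class)
            root.name = root.name or keep.name
        out = Tree(root, rooted=False)
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.n_tips} tips, rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*([(),;]|:[^,();\s#$]+|[#$]\d+|[^,();:\s#$]+)")


def parse_newick(text: str, rooted: bool | None = None) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    ``#k`` marks attach rate class ``k`` to a single branch; ``$k`` marks a
    whole clade (branch above the node plus all branches below).  Marks may
    appear before or after the ``:length`` part.

    ``rooted`` defaults to True when the basal node is bifurcating.
    """
    tokens = _TOKEN.findall(text)
    if not tokens or tokens[-1] != ";":
        raise NewickParseError("Newick string must end with ';'")
    pos = 0
    clade_marks: list[tuple[TreeNode, int]] = []

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_node() -> TreeNode:
        node = TreeNode()
        if peek() == "(":
            take()
            node.add_child(parse_node())
            while peek() == ",":
                take()
                node.add_child(parse_node())
            if peek() != ")":
                raise NewickParseError(
                    f"unbalanced parentheses near token {peek()!r}"
                )
            take()
            if peek() not in ("(", ")", ",", ";", None) and not _is_special(peek()):
                node.name = take()
        else:
            tok = peek()
            if tok is None or tok in "(),;" or _is_special(tok):
                raise NewickParseError(f"expected a tip name, got {tok!r}")
            node.name = take()
        _parse_annotations(node)
        return node

    def _is_special(tok: str | None) -> bool:
        return tok is not None and (tok.startswith(":") or tok[0] in "#$")

    def _parse_annotations(node: TreeNode) -> None:
        while _is_special(peek()):
            tok = take()
            if tok.startswith(":"):
                try:
                    node.length = float(tok[1:])
                except ValueError as exc:
                    raise NewickParseError(f"bad branch length token {tok!r}") from exc
                if node.length < 0:
                    raise NewickParseError(f"negative branch length {tok[1:]}")
            elif tok.startswith("#"):
                node.rate_class = int(tok[1:])
            else:  # $k: clade mark, resolved after the full parse
                clade_marks.append((node, int(tok[1:])))

    root = parse_node()
    if peek() != ";":
        raise NewickParseError(f"trailing tokens after tree near {peek()!r}")
    for node, k in clade_marks:
        node.rate_class = k
        stack = list(node.children)
        while stack:
            child = stack.pop()
            child.rate_class = k
            stack.extend(child.children)
    if rooted is None:
        rooted = len(root.children) <= 2
    return Tree(root, rooted=rooted)


def write_newick(tree: Tree, include_classes: bool = True,
                 precision: int = 10) -> str:
    """Serialize a :class:`Tree` to Newick, emitting ``#k`` marks for
    non-background rate classes when ``include_classes`` is set."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if include_classes and node.parent is not None and node.rate_class != 0:
            s += f"#{node.rate_class}"
        if node.length is not None:
            s += f":{node.length:.{precision}g}"
        return s

    return fmt(tree.root) + ";"


def root_on_edge(tree: Tree, edge, position: float = 0.5) -> Tree:
    """Re-root a tree on the branch identified by ``edge``.

    ``position`` is the fraction of the branch length measured from the
    *child* end at which the new root is placed.  All pairwise tip path
    lengths are preserved.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must lie in [0, 1]")
    work = tree.copy()
    child = work.resolve_branch(_reselect(edge, work, tree))
    parent = child.parent
    assert parent is not None
    length = child.length if child.length is not None else 0.0

    new_root = TreeNode()
    parent.children.remove(child)
    child.parent = None
    child.length = position * length
    new_root.add_child(child)

    # reverse the path from `parent` up to the old root
    carried_len = (1.0 - position) * length
    carried_class = child.rate_class
    node: TreeNode | None = parent
    prev = new_root
    while node is not None:
        up = node.parent
        up_len = node.length
        up_class = node.rate_class
        if up is not None:
            up.children.remove(node)
        node.parent = None
        prev.add_child(node)
        node.length = carried_len
        node.rate_class = carried_class
        carried_len = up_len if up_len is not None else 0.0
        carried_class = up_class
        prev = node
        node = up

    # the old root is now a (possibly degree-2) internal node: splice it out
    old_root = prev
    if len(old_root.children) == 1:
        only = old_root.children[0]
        grand = old_root.parent
        assert grand is not None
        grand.children.remove(old_root)
        only.parent = None
        only.length = (only.length or 0.0) + (old_root.length or 0.0)
        only.rate_class = max(only.rate_class, old_root.rate_class)
        grand.add_child(only)
    return Tree(new_root, rooted=True)


def _reselect(edge, work: Tree, original: Tree):
    """Map a selector expressed on `original` onto the copied tree."""
    if isinstance(edge, TreeNode):
        # identify by tip set below the node
        below = [n.name for n in original.clade_nodes(edge) if n.is_tip] or [edge.name]
        if edge.is_tip:
            return edge.name
        return below
    return edge


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Taxa-by-columns character matrix (nucleotide columns or codon triplets).

    ``data`` holds one uppercase string per taxon; in codon mode its length is
    three times ``n_columns``.
    """

    taxa: list[str]
    data: list[str]
    alphabet: str = "nucleotide"  # or "codon"

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.data):
            raise AlignmentError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        lens = {len(s) for s in self.data}
        if len(lens) > 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lens)}")
        self.data = [s.upper() for s in self.data]
        if self.alphabet == "codon":
            (n,) = lens or {0}
            if n % 3:
                raise AlignmentError(f"codon alignment length {n} not divisible by 3")
            self._check_stops()
        elif self.alphabet != "nucleotide":
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")

    def _check_stops(self) -> None:
        for taxon, seq in zip(self.taxa, self.data):
            for j in range(0, len(seq), 3):
                codon = seq[j : j + 3]
                if codon in STOP_CODONS:
                    raise AlignmentError(
                        f"internal stop codon {codon} in {taxon} at codon "
                        f"{j // 3 + 1} (1-based)"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        if not self.data:
            return 0
        n = len(self.data[0])
        return n // 3 if self.alphabet == "codon" else n

    def column(self, j: int) -> tuple[str, ...]:
        """Column ``j`` (0-based) as one symbol per taxon."""
        if self.alphabet == "codon":
            return tuple(s[3 * j : 3 * j + 3] for s in self.data)
        return tuple(s[j] for s in self.data)

    def columns(self) -> Iterator[tuple[str, ...]]:
        for j in range(self.n_columns):
            yield self.column(j)

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        return Alignment(list(taxa), [self.data[idx[t]] for t in taxa], self.alphabet)

    def drop_ambiguous_columns(self) -> "Alignment":
        """Strict mode: drop any column containing a non-canonical symbol."""
        keep: list[int] = []
        ok = set("ACGT") if self.alphabet == "nucleotide" else set(SENSE_CODONS)
        for j, col in enumerate(self.columns()):
            if all(c in ok for c in col):
                keep.append(j)
        w = 3 if self.alphabet == "codon" else 1
        data = ["".join(s[w * j : w * j + w] for j in keep) for s in self.data]
        return Alignment(list(self.taxa), data, self.alphabet)


@dataclass
class SitePatterns:
    """Unique alignment columns with multiplicities."""

    taxa: list[str]
    patterns: list[tuple[str, ...]]
    counts: np.ndarray
    column_to_pattern: np.ndarray
    alphabet: str = "nucleotide"

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def n_columns(self) -> int:
        return int(self.counts.sum())


def compress_patterns(aln: Alignment) -> SitePatterns:
    """Collapse an alignment to unique site patterns with counts."""
    if aln.n_columns == 0:
        raise AlignmentError("empty alignment")
    seen: dict[tuple[str, ...], int] = {}
    counts: list[int] = []
    patterns: list[tuple[str, ...]] = []
    col_map = np.empty(aln.n_columns, dtype=np.int64)
    for j, col in enumerate(aln.columns()):
        k = seen.get(col)
        if k is None:
            k = len(patterns)
            seen[col] = k
            patterns.append(col)
            counts.append(0)
        counts[k] += 1
        col_map[j] = k
    return SitePatterns(
        taxa=list(aln.taxa),
        patterns=patterns,
        counts=np.asarray(counts, dtype=np.float64),
        column_to_pattern=col_map,
        alphabet=aln.alphabet,
    )


def read_alignment(path, format: str = "fasta", alphabet: str = "nucleotide") -> Alignment:
    """Read FASTA or relaxed PHYLIP into an :class:`Alignment`.

    Unknown characters become fully-ambiguous states downstream; matching is
    case-insensitive.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif format == "phylip":
        try:
            records = list(AlignIO.read(str(path), "phylip-relaxed"))
        except Exception:
            records = list(AlignIO.read(str(path), "phylip-sequential"))
    else:
        raise AlignmentError(f"unsupported format {format!r}")
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return Alignment(
        taxa=[r.id for r in records],
        data=[str(r.seq) for r in records],
        alphabet=alphabet,
    )


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    if format == "fasta":
        with open(path, "w") as fh:
            for name, seq in zip(aln.taxa, aln.data):
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_taxa} {len(aln.data[0])}\n")
            for name, seq in zip(aln.taxa, aln.data):
                fh.write(f"{name}  {seq}\n")
    else:
        raise AlignmentError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Branch labeling
# ---------------------------------------------------------------------------

@dataclass
class BranchLabeling:
    """Declarative assignment of rate classes to branches.

    Each rule is a mapping with keys ``class`` (int), plus one of ``mrca``
    (list of tip names: the clade below their MRCA, stem controlled by
    ``include_stem``), ``branch`` (node name or list of tip names: that single
    branch), and optionally ``include_stem`` (bool, default False).
    """

    rules: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, text: str) -> "BranchLabeling":
        import yaml

        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            loaded = loaded.get("labels", [loaded])
        return cls(rules=list(loaded))

    def apply(self, tree: Tree) -> Tree:
        """Return a copy of ``tree`` with rate classes set; unselected
        branches get class 0.  Rule branch sets must be disjoint."""
        out = tree.copy()
        for node in out.postorder():
            node.rate_class = 0
        claimed: dict[int, int] = {}
        for rule in self.rules:
            k = int(rule["class"])
            include_stem = bool(rule.get("include_stem", False))
            if "mrca" in rule:
                mrca = out.mrca(list(rule["mrca"]))
                targets = out.clade_nodes(mrca, include_stem=include_stem)
            elif "branch" in rule:
                targets = [out.resolve_branch(rule["branch"])]
            else:
                raise ValueError(f"rule needs 'mrca' or 'branch': {rule!r}")
            for node in targets:
                if node.index in claimed and claimed[node.index] != k:
                    raise ValueError(
                        "labeling rules overlap: branch above "
                        f"{node.name or node.index} claimed by classes "
                        f"{claimed[node.index]} and {k}"
                    )
                claimed[node.index] = k
                node.rate_class = k
        return out
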