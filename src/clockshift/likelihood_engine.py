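"""Phylogenetic likelihood computation and maximum-likelihood fitting.

The pruning core evaluates HKY(+discrete-gamma) and M0 codon likelihoods over
compressed site patterns with per-node log-scaling.  On top of it sit three
fitters: unconstrained branch lengths, local-clock models with labeled branch
rate classes (background class 0 fixed at rate 1, overall scale carried by
node ages), and the single-ratio M0 codon model.  Standard errors come from
the observed information (central-difference Hessian of -lnL in transformed
coordinates, delta-rule back-transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from clockshift.phylo_io import (
    Alignment,
    CODON_INDEX,
    IUPAC_PARTIALS,
    SitePatterns,
    Tree,
    compress_patterns,
)
from clockshift.substitution_models import (
    HKYParams,
    M0Params,
    RateMatrix,
    f3x4_freqs,
    hky_q,
    m0_q,
)

__all__ = [
    "FreeBranchFit",
    "LocalClockFit",
    "M0Fit",
    "PruningEngine",
    "log_likelihood",
    "fit_free_branches",
    "fit_local_clock",
    "fit_m0",
    "parameter_ses",
    "hessian",
    "observed_base_freqs",
]

_TINY = 1e-300


def _tip_partial_rows(patterns: SitePatterns) -> dict[str, np.ndarray]:
    """Per-taxon (n_patterns, n_states) partial-likelihood arrays."""
    n_pat = patterns.n_patterns
    out: dict[str, np.ndarray] = {}
    if patterns.alphabet == "nucleotide":
        n_states = 4
        flat = np.ones(n_states)
        for row, taxon in enumerate(patterns.taxa):
            arr = np.empty((n_pat, n_states))
            for k, pat in enumerate(patterns.patterns):
                arr[k] = IUPAC_PARTIALS.get(pat[row], tuple(flat))
            out[taxon] = arr
    else:
        n_states = 61
        for row, taxon in enumerate(patterns.taxa):
            arr = np.zeros((n_pat, n_states))
            for k, pat in enumerate(patterns.patterns):
                idx = CODON_INDEX.get(pat[row])
                if idx is None:
                    arr[k] = 1.0  # gap/ambiguous codon: missing data
                else:
                    arr[k, idx] = 1.0
            out[taxon] = arr
    return out


class PruningEngine:
    """Cached tree structure + tip partials for repeated likelihood calls.

    ``branch_lengths`` passed to the evaluation methods are indexed by node
    postorder index (the root entry is ignored).
    """

    def __init__(self, tree: Tree, patterns: SitePatterns) -> None:
        missing = set(tree.tip_names()) - set(patterns.taxa)
        if missing:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        self.tree = tree
        self.patterns = patterns
        self.counts = patterns.counts
        nodes = tree.nodes()  # postorder
        self.n_nodes = len(nodes)
        self.root_index = tree.root.index
        self.children: list[list[int]] = [[] for _ in nodes]
        self.order: list[int] = []
        for node in nodes:
            if node.children:
                self.children[node.index] = [c.index for c in node.children]
                self.order.append(node.index)
        tip_rows = _tip_partial_rows(patterns)
        self.tip_partial: dict[int, np.ndarray] = {
            t.index: tip_rows[t.name] for t in tree.tips()
        }
        self.n_states = 4 if patterns.alphabet == "nucleotide" else 61

    def branch_length_vector(self) -> np.ndarray:
        """Current tree branch lengths as a node-indexed vector."""
        t = np.zeros(self.n_nodes)
        for node in self.tree.nodes():
            if node.parent is not None:
                if node.length is None:
                    raise ValueError("tree has unset branch lengths")
                t[node.index] = node.length
        return t

    def _all_transition_matrices(self, q: RateMatrix, t_eff: np.ndarray) -> np.ndarray:
        w, left, right = q.decomposition()
        ewt = np.exp(np.outer(t_eff, w))
        p = np.einsum("bk,ik,kj->bij", ewt, right, left, optimize=True)
        np.clip(p, 0.0, None, out=p)
        return p

    def pattern_loglikes(
        self,
        branch_lengths: np.ndarray,
        q: RateMatrix,
        category_rates: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern log-likelihoods, averaged over rate categories with
        equal prior weight.  Categories are batched through the pruning pass."""
        K = len(category_rates)
        n_pat = self.patterns.n_patterns
        # P for every (branch, category) at once: (n_nodes, K, S, S)
        t_eff = branch_lengths[:, None] * np.asarray(category_rates)[None, :]
        p_all = self._all_transition_matrices(q, t_eff.ravel()).reshape(
            self.n_nodes, K, self.n_states, self.n_states
        )
        pt_all = np.ascontiguousarray(p_all.transpose(0, 1, 3, 2))
        partial: list[np.ndarray | None] = [None] * self.n_nodes
        logscale = np.zeros((K, n_pat))
        for i in self.order:
            acc: np.ndarray | None = None
            for c in self.children[i]:
                tip = self.tip_partial.get(c)
                # (K, n_pat, S) @ (K, S, S) batched
                contrib = (tip if tip is not None else partial[c]) @ pt_all[c]
                acc = contrib if acc is None else acc * contrib
                partial[c] = None  # free memory early
            s = acc.max(axis=2)
            s = np.where(s > 0, s, 1.0)
            acc /= s[:, :, None]
            logscale += np.log(s)
            partial[i] = acc
        root = partial[self.root_index]
        site = root @ q.freqs
        per_cat = np.log(np.maximum(site, _TINY)) + logscale
        if K == 1:
            return per_cat[0]
        return logsumexp(per_cat, axis=0) - np.log(K)

    def log_likelihood(
        self,
        branch_lengths: np.ndarray,
        q: RateMatrix,
        category_rates: np.ndarray,
    ) -> float:
        return float(self.counts @ self.pattern_loglikes(branch_lengths, q, category_rates))


def _model_q_rates(model) -> tuple[RateMatrix, np.ndarray]:
    if isinstance(model, HKYParams):
        return hky_q(model), model.category_rates()
    if isinstance(model, M0Params):
        return m0_q(model), np.ones(1)
    raise TypeError(f"unsupported model {type(model).__name__}")


def log_likelihood(tree: Tree, patterns: SitePatterns | Alignment, model):
    """Total log-likelihood of the data on ``tree`` under ``model``.

    Returns ``(lnL, per_pattern_loglikes)``; multiply pattern log-likelihoods
    by ``patterns.counts`` to recover per-column contributions.
    """
    if isinstance(patterns, Alignment):
        patterns = compress_patterns(patterns)
    engine = PruningEngine(tree, patterns)
    q, rates = _model_q_rates(model)
    plp = engine.pattern_loglikes(engine.branch_length_vector(), q, rates)
    return float(engine.counts @ plp), plp


def observed_base_freqs(aln: Alignment) -> np.ndarray:
    """Observed (T, C, A, G) frequencies over unambiguous characters."""
    counts = np.zeros(4)
    index = {"T": 0, "C": 1, "A": 2, "G": 3, "U": 0}
    for seq in aln.data:
        for ch in seq:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------

@dataclass
class _FitBase:
    lnl: float = np.nan
    converged: bool = False
    message: str = ""
    n_evaluations: int = 0
    flags: list[str] = field(default_factory=list)
    param_names: list[str] = field(default_factory=list)
    x_opt: np.ndarray | None = None
    transform_derivs: np.ndarray | None = None
    _objective: Callable[[np.ndarray], float] | None = None

    def to_dict(self) -> dict:
        out = {
            "lnL": self.lnl,
            "converged": self.converged,
            "message": self.message,
            "flags": list(self.flags),
        }
        return out


@dataclass
class FreeBranchFit(_FitBase):
    """Joint ML fit of branch lengths and HKY(+gamma) parameters."""

    tree: Tree | None = None
    kappa: float = np.nan
    alpha: float | None = None
    pi: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = super().to_dict()
        out.update(
            kappa=self.kappa,
            alpha=self.alpha,
            pi=None if self.pi is None else list(self.pi),
        )
        return out


@dataclass
class LocalClockFit(_FitBase):
    """Local-clock fit: node ages plus per-class rate multipliers (r0 = 1)."""

    tree: Tree | None = None
    ages: dict[int, float] = field(default_factory=dict)
    rates: dict[int, float] = field(default_factory=dict)
    kappa: float = np.nan
    alpha: float | None = None
    pi: np.ndarray | None = None
    covariance: np.ndarray | None = None
    ses: dict[str, float] = field(default_factory=dict)

    def rate_se(self, rate_class: int) -> float:
        return self.ses.get(f"r{rate_class}", np.nan)

    def to_dict(self) -> dict:
        out = super().to_dict()
        out.update(
            rates={str(k): v for k, v in self.rates.items()},
            kappa=self.kappa,
            alpha=self.alpha,
            ses=dict(self.ses),
        )
        return out


@dataclass
class M0Fit(_FitBase):
    """M0 codon-model fit: kappa, omega (dN/dS), branch lengths."""

    tree: Tree | None = None
    kappa: float = np.nan
    omega: float = np.nan
    kappa_se: float = np.nan
    omega_se: float = np.nan
    codon_freqs: np.ndarray | None = None
    freq_mode: str = "F3x4"

    def to_dict(self) -> dict:
        out = super().to_dict()
        out.update(
            kappa=self.kappa,
            omega=self.omega,
            kappa_se=self.kappa_se,
            omega_se=self.omega_se,
            freq_mode=self.freq_mode,
        )
        return out


# ---------------------------------------------------------------------------
# Optimization helpers
# ---------------------------------------------------------------------------

_MAX_BL = 20.0


def _minimize(obj, x0, bounds=None, maxiter=500):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
    return res


def _multistart(obj, x0, bounds, rng, n_restarts=2, spread=0.5, maxiter=500):
    """Deterministic start plus seeded random restarts; keep the best."""
    best = _minimize(obj, x0, bounds, maxiter)
    nfev = best.nfev
    for _ in range(n_restarts):
        if best.success and best.fun < np.inf:
            break
        jitter = rng.normal(scale=spread, size=len(x0))
        x_try = np.asarray(x0) + jitter
        if bounds is not None:
            lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
            hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
            x_try = np.clip(x_try, lo + 1e-9, hi - 1e-9)
        res = _minimize(obj, x_try, bounds, maxiter)
        nfev += res.nfev
        if res.fun < best.fun:
            best = res
    best.nfev = nfev
    return best


# ---------------------------------------------------------------------------
# Free-branch fit
# ---------------------------------------------------------------------------

def fit_free_branches(
    tree: Tree,
    aln: Alignment,
    kappa0: float = 2.0,
    gamma_shape: float | None = 1.0,
    n_categories: int = 5,
    estimate_alpha: bool = True,
    seed: int = 0,
) -> FreeBranchFit:
    """ML fit of all branch lengths, kappa and (optionally) the gamma shape.

    Base frequencies are fixed at observed counts.  Pass
    ``gamma_shape=None`` for rate homogeneity.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 taxa")
    patterns = compress_patterns(aln)
    work = tree.copy()
    engine = PruningEngine(work, patterns)
    pi = observed_base_freqs(aln)
    n_nodes = engine.n_nodes
    root = engine.root_index
    branch_idx = [i for i in range(n_nodes) if i != root]

    t0 = np.zeros(len(branch_idx))
    for j, i in enumerate(branch_idx):
        node = work.nodes()[i]
        t0[j] = node.length if node.length is not None else 0.1
    t0 = np.clip(t0, 1e-4, _MAX_BL)

    use_gamma = gamma_shape is not None
    x0 = list(t0) + [np.log(kappa0)]
    bounds: list[tuple] = [(0.0, _MAX_BL)] * len(branch_idx) + [(None, None)]
    if use_gamma and estimate_alpha:
        x0.append(np.log(gamma_shape))
        bounds.append((np.log(1e-3), np.log(1e3)))

    def unpack(x):
        t = np.zeros(n_nodes)
        t[branch_idx] = x[: len(branch_idx)]
        kappa = np.exp(x[len(branch_idx)])
        alpha = None
        if use_gamma:
            alpha = (
                np.exp(x[len(branch_idx) + 1]) if estimate_alpha else gamma_shape
            )
        return t, kappa, alpha

    def obj(x):
        t, kappa, alpha = unpack(x)
        try:
            model = HKYParams(kappa=kappa, pi=pi, gamma_shape=alpha,
                              n_categories=n_categories)
            q, rates = _model_q_rates(model)
            return -engine.log_likelihood(t, q, rates)
        except (ValueError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    res = _multistart(obj, np.asarray(x0), bounds, rng)
    t, kappa, alpha = unpack(res.x)
    nodes = work.nodes()
    flags = []
    for i in branch_idx:
        nodes[i].length = float(t[i])
        if t[i] <= 1e-8:
            flags.append(f"branch above node {nodes[i].name or i} at 0 boundary")
    fit = FreeBranchFit(
        tree=work,
        kappa=float(kappa),
        alpha=None if alpha is None else float(alpha),
        pi=pi,
        lnl=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=int(res.nfev),
        flags=flags,
        param_names=[f"t{i}" for i in branch_idx] + ["kappa"]
        + (["alpha"] if use_gamma and estimate_alpha else []),
        x_opt=res.x.copy(),
        _objective=obj,
    )
    derivs = np.ones(len(res.x))
    derivs[len(branch_idx):] = np.exp(res.x[len(branch_idx):])
    fit.transform_derivs = derivs
    return fit


# ---------------------------------------------------------------------------
# Local-clock fit
# ---------------------------------------------------------------------------

def _initial_ages(tree: Tree) -> dict[int, float]:
    """Heuristic node ages: mean tip distance below each node (0 if the tree
    carries no lengths)."""
    ages: dict[int, float] = {}
    have_lengths = all(
        n.length is not None for n in tree.nodes() if n.parent is not None
    )
    for node in tree.postorder():
        if node.is_tip:
            ages[node.index] = 0.0
        else:
            vals = [
                ages[c.index] + ((c.length or 0.0) if have_lengths else 0.05)
                for c in node.children
            ]
            ages[node.index] = max(np.mean(vals), max(ages[c.index] for c in node.children) * 1.01 + 1e-6)
    return ages


def fit_local_clock(
    tree: Tree,
    aln: Alignment,
    labeling=None,
    kappa0: float = 2.0,
    gamma_shape: float | None = 1.0,
    n_categories: int = 5,
    estimate_alpha: bool = True,
    compute_se: bool = True,
    seed: int = 0,
) -> LocalClockFit:
    """ML local-clock fit: ultrametric node ages times per-class rate
    multipliers, with the background class 0 fixed at rate 1.

    ``labeling`` (a :class:`BranchLabeling`) is applied to a copy of the
    tree; pass ``None`` to use the classes already on the tree.  A strict
    clock (no non-background class) is permitted; a configuration whose
    non-background classes cover every branch is rejected as unidentifiable.
    """
    if not tree.rooted:
        raise ValueError("local-clock fitting requires a rooted tree")
    work = labeling.apply(tree) if labeling is not None else tree.copy()
    if 0 not in work.rate_classes():
        raise ValueError(
            "unidentifiable: non-background classes cover every branch "
            "(no class-0 branch to anchor the background rate)"
        )
    work.normalize_rate_classes()
    classes = work.rate_classes()
    free_classes = [c for c in classes if c != 0]

    patterns = compress_patterns(aln)
    engine = PruningEngine(work, patterns)
    pi = observed_base_freqs(aln)
    nodes = work.nodes()
    internal = [n for n in nodes if not n.is_tip]
    root = work.root
    non_root_internal = [n for n in internal if n.parent is not None]

    ages0 = _initial_ages(work)
    scale0 = max(ages0[root.index], 1e-3)

    # parameter vector: log(root age), logit(age proportions) for non-root
    # internal nodes, log r_c per free class, log kappa, [log alpha]
    use_gamma = gamma_shape is not None
    names = ["root_age"] + [f"p{n.index}" for n in non_root_internal]
    names += [f"r{c}" for c in free_classes] + ["kappa"]
    if use_gamma and estimate_alpha:
        names.append("alpha")

    x0 = [np.log(scale0)]
    for n in non_root_internal:
        p = ages0[n.index] / max(ages0[n.parent.index], 1e-12)
        p = min(max(p, 0.02), 0.98)
        x0.append(np.log(p / (1 - p)))
    x0 += [0.0] * len(free_classes) + [np.log(kappa0)]
    if use_gamma and estimate_alpha:
        x0.append(np.log(gamma_shape))
    x0 = np.asarray(x0)

    n_prop = len(non_root_internal)

    def unpack(x):
        ages = {root.index: np.exp(x[0])}
        for k, n in enumerate(non_root_internal):
            ages[n.index] = None  # filled below in preorder
        props = 1.0 / (1.0 + np.exp(-x[1 : 1 + n_prop]))
        prop_by_index = {n.index: props[k] for k, n in enumerate(non_root_internal)}
        for n in work.preorder():
            if n.is_tip:
                ages[n.index] = 0.0
            elif n.parent is not None:
                ages[n.index] = prop_by_index[n.index] * ages[n.parent.index]
        r = {0: 1.0}
        off = 1 + n_prop
        for k, c in enumerate(free_classes):
            r[c] = np.exp(x[off + k])
        kappa = np.exp(x[off + len(free_classes)])
        alpha = None
        if use_gamma:
            alpha = (
                np.exp(x[off + len(free_classes) + 1])
                if estimate_alpha
                else gamma_shape
            )
        return ages, r, kappa, alpha

    def branch_vector(ages, r):
        t = np.zeros(engine.n_nodes)
        for n in nodes:
            if n.parent is not None:
                t[n.index] = r[n.rate_class] * (ages[n.parent.index] - ages[n.index])
        return t

    def obj(x):
        if np.any(np.abs(x) > 60):
            return np.inf
        ages, r, kappa, alpha = unpack(x)
        t = branch_vector(ages, r)
        try:
            model = HKYParams(kappa=kappa, pi=pi, gamma_shape=alpha,
                              n_categories=n_categories)
            q, rates = _model_q_rates(model)
            return -engine.log_likelihood(t, q, rates)
        except (ValueError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    res = _multistart(obj, x0, None, rng)
    ages, r, kappa, alpha = unpack(res.x)
    t = branch_vector(ages, r)
    for n in nodes:
        if n.parent is not None:
            n.length = float(t[n.index])

    flags = []
    for c, val in r.items():
        if c != 0 and (val < 1e-4 or val > 1e3):
            flags.append(f"rate multiplier r{c} at boundary ({val:.3g})")

    fit = LocalClockFit(
        tree=work,
        ages={i: float(a) for i, a in ages.items()},
        rates={c: float(v) for c, v in r.items()},
        kappa=float(kappa),
        alpha=None if alpha is None else float(alpha),
        pi=pi,
        lnl=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=int(res.nfev),
        flags=flags,
        param_names=names,
        x_opt=res.x.copy(),
        _objective=obj,
    )
    # d(natural)/d(transformed): exp for log-params, p(1-p) for logits
    derivs = np.empty(len(res.x))
    derivs[0] = np.exp(res.x[0])
    props = 1.0 / (1.0 + np.exp(-res.x[1 : 1 + n_prop]))
    derivs[1 : 1 + n_prop] = props * (1 - props)
    derivs[1 + n_prop :] = np.exp(res.x[1 + n_prop :])
    fit.transform_derivs = derivs
    if compute_se:
        ses, cov = parameter_ses(fit)
        fit.ses = ses
        fit.covariance = cov
    return fit


# ---------------------------------------------------------------------------
# M0 codon fit
# ---------------------------------------------------------------------------

def fit_m0(
    aln: Alignment,
    tree: Tree,
    kappa0: float = 2.0,
    omega0: float = 0.2,
    freq_mode: str = "F3x4",
    compute_se: bool = True,
    seed: int = 0,
) -> M0Fit:
    """ML fit of the M0 codon model (branch lengths, kappa, omega)."""
    if aln.alphabet != "codon":
        raise ValueError("fit_m0 requires a codon alignment")
    if tree.n_tips < 3:
        raise ValueError("need at least 3 taxa")
    patterns = compress_patterns(aln)
    work = tree.copy()
    engine = PruningEngine(work, patterns)
    if freq_mode == "F3x4":
        freqs = f3x4_freqs(aln)
        freqs = np.maximum(freqs, 1e-8)
        freqs /= freqs.sum()
    elif freq_mode == "equal":
        freqs = np.full(61, 1.0 / 61.0)
    else:
        raise ValueError("freq_mode must be 'F3x4' or 'equal'")

    n_nodes = engine.n_nodes
    root = engine.root_index
    branch_idx = [i for i in range(n_nodes) if i != root]
    nodes = work.nodes()
    t0 = np.array(
        [
            nodes[i].length if nodes[i].length is not None else 0.1
            for i in branch_idx
        ]
    )
    t0 = np.clip(t0, 1e-4, _MAX_BL)
    x0 = np.concatenate([t0, [np.log(kappa0), np.log(omega0)]])
    bounds = [(0.0, _MAX_BL)] * len(branch_idx) + [
        (np.log(1e-3), np.log(1e3)),
        (np.log(1e-6), np.log(1e2)),
    ]

    def unpack(x):
        t = np.zeros(n_nodes)
        t[branch_idx] = x[: len(branch_idx)]
        return t, np.exp(x[-2]), np.exp(x[-1])

    def obj(x):
        t, kappa, omega = unpack(x)
        try:
            q = m0_q(M0Params(kappa=kappa, omega=omega, codon_freqs=freqs))
            return -engine.log_likelihood(t, q, np.ones(1))
        except (ValueError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    res = _multistart(obj, x0, bounds, rng)
    t, kappa, omega = unpack(res.x)
    flags = []
    for i in branch_idx:
        nodes[i].length = float(t[i])
    if omega <= 2e-6:
        flags.append("omega at 0 boundary")

    fit = M0Fit(
        tree=work,
        kappa=float(kappa),
        omega=float(omega),
        codon_freqs=freqs,
        freq_mode=freq_mode,
        lnl=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=int(res.nfev),
        flags=flags,
        param_names=[f"t{i}" for i in branch_idx] + ["kappa", "omega"],
        x_opt=res.x.copy(),
        _objective=obj,
    )
    derivs = np.ones(len(res.x))
    derivs[-2:] = np.exp(res.x[-2:])
    fit.transform_derivs = derivs
    if compute_se:
        ses, _ = parameter_ses(fit, which=["kappa", "omega"])
        fit.kappa_se = ses.get("kappa", np.nan)
        fit.omega_se = ses.get("omega", np.nan)
    return fit


# ---------------------------------------------------------------------------
# Curvature-based standard errors
# ---------------------------------------------------------------------------

def hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
            step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = np.full(n, step) * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def parameter_ses(
    fit,
    which: Sequence[str] | None = None,
    step: float = 1e-4,
) -> tuple[dict[str, float], np.ndarray]:
    """Standard errors and covariance of natural-scale parameters from the
    observed information at the MLE.

    The Hessian of -lnL is computed in the fit's transformed coordinates and
    back-transformed with the delta rule using the fit's stored elementwise
    transform derivatives.  A non-positive-definite Hessian triggers a
    pseudo-inverse and a flag on the fit.
    """
    if fit._objective is None or fit.x_opt is None:
        raise ValueError("fit carries no objective for curvature computation")
    H = hessian(fit._objective, fit.x_opt, step=step)
    try:
        cov_x = np.linalg.inv(H)
        if np.any(np.diag(cov_x) < 0):
            raise np.linalg.LinAlgError("negative variance")
    except np.linalg.LinAlgError:
        cov_x = np.linalg.pinv(0.5 * (H + H.T))
        fit.flags.append("observed information not positive definite; pseudo-inverse used")
    J = np.asarray(
        fit.transform_derivs
        if fit.transform_derivs is not None
        else np.ones(len(fit.x_opt))
    )
    cov = cov_x * np.outer(J, J)
    cov = 0.5 * (cov + cov.T)
    variances = np.maximum(np.diag(cov), 0.0)
    names = list(fit.param_names)
    ses = {name: float(np.sqrt(v)) for name, v in zip(names, variances)}
    if which is not None:
        ses = {k: v for k, v in ses.items() if k in set(which)}
    return ses, cov
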