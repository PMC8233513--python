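"""HKY nucleotide and M0 codon substitution processes with discrete-gamma
among-site rate variation.

All rate matrices are reversible and scaled so the mean substitution rate at
stationarity is 1, making branch lengths expected substitutions per site.
Transition probabilities use the spectral decomposition of the symmetrized
generator, with a matrix-exponential fallback for ill-conditioned cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from clockshift.phylo_io import (
    Alignment,
    AlignmentError,
    NUC_STATES,
    SENSE_CODONS,
)

__all__ = [
    "HKYParams",
    "M0Params",
    "RateMatrix",
    "hky_q",
    "m0_q",
    "transition_matrix",
    "discrete_gamma_rates",
    "f3x4_freqs",
    "GENETIC_CODE",
    "is_transition",
]

#: standard genetic code for the 61 sense codons (one-letter amino acids)
_CODE_BY_POS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {}
for _i, _a in enumerate(NUC_STATES):
    for _j, _b in enumerate(NUC_STATES):
        for _k, _c in enumerate(NUC_STATES):
            GENETIC_CODE[_a + _b + _c] = _CODE_BY_POS[16 * _i + 4 * _j + _k]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(x: str, y: str) -> bool:
    """True if the single-nucleotide change x->y is a transition."""
    return (x in _PURINES and y in _PURINES) or (
        x in _PYRIMIDINES and y in _PYRIMIDINES
    )


@dataclass
class HKYParams:
    """HKY85 parameters with optional discrete-gamma rate heterogeneity.

    ``pi`` is ordered (T, C, A, G).  ``gamma_shape`` of ``None`` means rate
    homogeneity across sites; otherwise ``n_categories`` equal-probability
    mean rates are used.
    """

    kappa: float = 2.0
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float | None = None
    n_categories: int = 5

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,):
            raise ValueError("pi must have length 4")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be non-negative and sum to 1 within 1e-12")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


@dataclass
class M0Params:
    """Single-ratio (M0) codon model parameters over the 61 sense codons."""

    kappa: float = 2.0
    omega: float = 1.0
    codon_freqs: np.ndarray = field(
        default_factory=lambda: np.full(61, 1.0 / 61.0)
    )
    freq_mode: str = "equal"  # informational: "equal" or "F3x4"

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (61,):
            raise ValueError("codon_freqs must have length 61")
        if np.any(self.codon_freqs < 0) or abs(self.codon_freqs.sum() - 1.0) > 1e-10:
            raise ValueError("codon_freqs must be non-negative and sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


@dataclass
class RateMatrix:
    """Scaled reversible generator plus cached spectral decomposition."""

    q: np.ndarray
    freqs: np.ndarray
    states: tuple[str, ...]
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def n_states(self) -> int:
        return self.q.shape[0]

    def decomposition(self):
        """Eigendecomposition of D^{1/2} Q D^{-1/2} (symmetric for
        reversible Q): returns (eigenvalues, left, right) with
        P(t) = right @ diag(exp(w t)) @ left."""
        if self._eig is None:
            pos = self.freqs > 0
            sqrtp = np.sqrt(np.where(pos, self.freqs, 1.0))
            S = self.q * (sqrtp[:, None] / sqrtp[None, :])
            S = 0.5 * (S + S.T)
            w, U = np.linalg.eigh(S)
            right = U / sqrtp[:, None]
            left = U.T * sqrtp[None, :]
            self._eig = (w, left, right)
        return self._eig


def _scale_q(q: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(freqs * np.diag(q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix: zero mean rate")
    return q / mean_rate


def hky_q(params: HKYParams) -> RateMatrix:
    """HKY85 instantaneous rate matrix, normalized to mean rate 1."""
    pi = params.pi
    q = np.tile(pi, (4, 1)).astype(float)
    for i, a in enumerate(NUC_STATES):
        for j, b in enumerate(NUC_STATES):
            if i != j and is_transition(a, b):
                q[i, j] *= params.kappa
    q = _scale_q(q, pi)
    return RateMatrix(q=q, freqs=pi.copy(), states=tuple(NUC_STATES))


def _codon_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed 61x61 structure masks: single-step, transition,
    nonsynonymous."""
    single = np.zeros((61, 61), dtype=bool)
    ts = np.zeros((61, 61), dtype=bool)
    ns = np.zeros((61, 61), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            ts[i, j] = is_transition(a, b)
            ns[i, j] = GENETIC_CODE[ci] != GENETIC_CODE[cj]
    return single, ts, ns


_SINGLE_STEP, _TS_MASK, _NS_MASK = _codon_masks()


def m0_q(params: M0Params) -> RateMatrix:
    """M0 codon generator: zero for multi-step changes, kappa on transitions,
    omega on nonsynonymous changes, target-codon frequency factor."""
    freqs = params.codon_freqs
    q = np.where(_SINGLE_STEP, np.broadcast_to(freqs, (61, 61)), 0.0).astype(float)
    q[_TS_MASK] *= params.kappa
    q[_NS_MASK] *= params.omega
    q = _scale_q(q, freqs)
    return RateMatrix(q=q, freqs=freqs.copy(), states=SENSE_CODONS)


def transition_matrix(q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to 1.  ``t`` must be non-negative."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(q.n_states)
    w, left, right = q.decomposition()
    p = (right * np.exp(w * t)) @ left
    if not np.all(np.isfinite(p)) or p.min() < -1e-8:
        p = expm(q.q * t)  # fallback for ill-conditioned decompositions
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean rates of K equal-probability classes of a Gamma(alpha, alpha)
    distribution (mean 1).  The returned rates average exactly 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones(1)
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    cuts = dist.ppf(np.arange(1, K) / K)
    # mean of X over (lo, hi] equals Gamma(alpha+1, alpha) mass ratio; use
    # the incomplete-gamma identity via the shifted distribution
    shifted = gamma_dist(a=alpha + 1.0, scale=1.0 / alpha)
    upper = np.concatenate([shifted.cdf(cuts), [1.0]])
    lower = np.concatenate([[0.0], shifted.cdf(cuts)])
    rates = (upper - lower) * K
    return rates / rates.mean()


def f3x4_freqs(aln: Alignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies
    (F3x4): product over the three codon positions, stop codons removed,
    renormalized to sum 1."""
    if aln.alphabet != "codon":
        raise AlignmentError("f3x4_freqs requires a codon alignment")
    if aln.n_columns == 0:
        raise AlignmentError("empty alignment")
    counts = np.zeros((3, 4))
    nuc_idx = {b: i for i, b in enumerate(NUC_STATES)}
    for seq in aln.data:
        for pos, base in enumerate(seq):
            i = nuc_idx.get(base)
            if i is not None:
                counts[pos % 3, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise AlignmentError("a codon position has no unambiguous nucleotides")
    pos_freqs = counts / totals
    freqs = np.array(
        [
            pos_freqs[0, nuc_idx[c[0]]]
            * pos_freqs[1, nuc_idx[c[1]]]
            * pos_freqs[2, nuc_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise AlignmentError("all sense-codon frequencies are zero")
    return freqs / total
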