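"""Seeded generators for every input the pipeline consumes: nucleotide and
codon alignments evolved along trees with branch-class rate multipliers,
binary traits with phylogenetic signal, and the two fixture trees (a
13-taxon primate tree with a focal Old-World-monkey stem branch and a slow
hominoid clade, and a 29-taxon ultrametric mammal chronogram).

Fixture branch lengths are plausible inventions for testing, not estimates
from any real data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from clockshift.phylo_io import (
    Alignment,
    NUC_STATES,
    SENSE_CODONS,
    Tree,
    TreeNode,
    write_newick,
)
from clockshift.substitution_models import (
    HKYParams,
    M0Params,
    RateMatrix,
    hky_q,
    m0_q,
    transition_matrix,
)

__all__ = [
    "SimulationSpec",
    "simulate_alignment",
    "simulate_codon_alignment",
    "simulate_binary_trait",
    "fixture_primate_tree",
    "fixture_mammal_tree",
]


@dataclass
class SimulationSpec:
    """Everything needed to regenerate one simulated alignment.

    ``class_rates`` maps branch rate classes to multipliers; branch lengths
    on the tree are durations that get multiplied by the class rate.  Class 0
    defaults to rate 1.
    """

    tree: Tree
    model: HKYParams | M0Params
    n_sites: int
    seed: int
    class_rates: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        rates = {0: 1.0, **self.class_rates}
        if any(r <= 0 for r in rates.values()):
            raise ValueError("rate multipliers must be positive")
        self.class_rates = rates
        missing = set(self.tree.rate_classes()) - set(rates)
        if missing:
            raise ValueError(f"no multiplier for rate classes {sorted(missing)}")

    def provenance(self) -> str:
        """YAML record of the spec (tree as Newick, parameters, seed)."""
        if isinstance(self.model, HKYParams):
            model = {
                "type": "HKY",
                "kappa": float(self.model.kappa),
                "pi": [float(x) for x in self.model.pi],
                "gamma_shape": self.model.gamma_shape,
                "n_categories": self.model.n_categories,
            }
        else:
            model = {
                "type": "M0",
                "kappa": float(self.model.kappa),
                "omega": float(self.model.omega),
                "freq_mode": self.model.freq_mode,
            }
        return yaml.safe_dump(
            {
                "tree": write_newick(self.tree),
                "model": model,
                "class_rates": {int(k): float(v) for k, v in self.class_rates.items()},
                "n_sites": int(self.n_sites),
                "seed": int(self.seed),
            },
            sort_keys=True,
        )


def _evolve(
    tree: Tree,
    q: RateMatrix,
    class_rates: dict[int, float],
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Draw root states from the stationary distribution and evolve them
    along each branch with P(site_rate * class_rate * duration)."""
    n_sites = len(site_rates)
    n_states = q.n_states
    states: dict[int, np.ndarray] = {}
    states[tree.root.index] = rng.choice(n_states, size=n_sites, p=q.freqs)
    unique_rates = np.unique(site_rates)
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.length is None:
            raise ValueError("tree has unset branch lengths")
        duration = node.length * class_rates[node.rate_class]
        parent_states = states[node.parent.index]
        child = np.empty(n_sites, dtype=np.int64)
        for r in unique_rates:
            mask = site_rates == r
            p = transition_matrix(q, duration * r)
            cdf = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            rows = cdf[parent_states[mask]]
            child[mask] = (rows > u[:, None]).argmax(axis=1)
        states[node.index] = child
    return states


def simulate_alignment(spec: SimulationSpec) -> Alignment:
    """Simulate a nucleotide alignment under HKY(+discrete gamma).

    Site rates are drawn from the model's K discrete gamma categories, so
    simulation and inference share the same site-rate distribution.
    """
    if not isinstance(spec.model, HKYParams):
        raise TypeError("simulate_alignment expects HKYParams")
    rng = np.random.default_rng(spec.seed)
    q = hky_q(spec.model)
    cat_rates = spec.model.category_rates()
    site_rates = rng.choice(cat_rates, size=spec.n_sites)
    states = _evolve(spec.tree, q, spec.class_rates, site_rates, rng)
    tips = spec.tree.tips()
    data = [
        "".join(NUC_STATES[s] for s in states[t.index]) for t in tips
    ]
    return Alignment([t.name for t in tips], data, alphabet="nucleotide")


def simulate_codon_alignment(spec: SimulationSpec) -> Alignment:
    """Simulate a codon alignment under M0 (no stop codons by construction)."""
    if not isinstance(spec.model, M0Params):
        raise TypeError("simulate_codon_alignment expects M0Params")
    rng = np.random.default_rng(spec.seed)
    q = m0_q(spec.model)
    site_rates = np.ones(spec.n_sites)
    states = _evolve(spec.tree, q, spec.class_rates, site_rates, rng)
    tips = spec.tree.tips()
    data = [
        "".join(SENSE_CODONS[s] for s in states[t.index]) for t in tips
    ]
    return Alignment([t.name for t in tips], data, alphabet="codon")


def simulate_binary_trait(
    tree: Tree,
    decay: float,
    beta: np.ndarray,
    X: pd.DataFrame,
    seed: int = 0,
) -> pd.Series:
    """Latent-threshold binary trait with phylogenetic signal.

    Tip liabilities are multivariate normal with unit variances, correlations
    ``exp(-decay * d_ij)`` in patristic distance, and mean ``X @ beta``;
    states are the indicator of a positive liability.
    """
    tips = tree.tip_names()
    Xv = X.loc[tips].to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite covariates")
    beta = np.asarray(beta, dtype=float)
    names, D = tree.patristic_distances()
    order = [names.index(t) for t in tips]
    D = D[np.ix_(order, order)]
    S = np.exp(-decay * D)
    np.fill_diagonal(S, 1.0)
    rng = np.random.default_rng(seed)
    w, U = np.linalg.eigh(S)
    w = np.maximum(w, 0.0)
    z = U @ (np.sqrt(w) * rng.standard_normal(len(tips)))
    liab = Xv @ beta + z
    return pd.Series((liab > 0).astype(int), index=tips, name="state")


# ---------------------------------------------------------------------------
# Fixture trees
# ---------------------------------------------------------------------------

def _ultrametric(spec, parent_age: float | None = None) -> TreeNode:
    """Build a clade from nested (age, [children]) tuples / tip-name leaves."""
    if isinstance(spec, str):
        node = TreeNode(name=spec)
        node.length = parent_age
        return node
    age, children = spec
    node = TreeNode()
    node.length = None if parent_age is None else parent_age - age
    for child in children:
        node.add_child(_ultrametric(child, age))
    return node


# ages chosen so that both labeled classes are well identified at
# promoter-like alignment lengths: a long Cercopithecidae stem (0.038) and a
# deep hominoid crown (0.040 below the 0.060 catarrhini split)
_PRIMATE_SPEC = (
    0.12,
    [
        "Mouse_lemur",
        (
            0.10,
            [
                "Tarsier",
                (
                    0.068,
                    [
                        (0.030, ["Marmoset", "Squirrel_monkey"]),
                        (
                            0.060,
                            [
                                (
                                    0.022,
                                    [
                                        (0.008, ["Rhesus_macaque", "Crab_eating_macaque"]),
                                        (0.014, ["Baboon", "Green_monkey"]),
                                    ],
                                ),
                                (
                                    0.040,
                                    [
                                        "Gibbon",
                                        (
                                            0.030,
                                            [
                                                "Orangutan",
                                                (0.018, ["Gorilla", (0.012, ["Human", "Chimpanzee"])]),
                                            ],
                                        ),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

CERCOPITHECIDAE = ("Rhesus_macaque", "Crab_eating_macaque", "Baboon", "Green_monkey")
HOMINOIDS = ("Gibbon", "Orangutan", "Gorilla", "Human", "Chimpanzee")


def fixture_primate_tree(include_hominoid_stem: bool = False) -> Tree:
    """13-taxon primate tree, rooted on the mouse-lemur branch, ultrametric
    in duration units, with rate class 1 on the Cercopithecidae stem branch
    and class 2 on the hominoid clade (stem excluded by default)."""
    tree = Tree(_ultrametric(_PRIMATE_SPEC), rooted=True)
    cerco_stem = tree.mrca(CERCOPITHECIDAE)
    cerco_stem.rate_class = 1
    hom = tree.mrca(HOMINOIDS)
    for node in tree.clade_nodes(hom, include_stem=include_hominoid_stem):
        node.rate_class = 2
    return tree


_MAMMAL_SPEC = (
    1.00,
    [
        "Platypus",
        (
            0.85,
            [
                "Opossum",
                (
                    0.55,
                    [
                        (
                            0.50,
                            [
                                (0.30, ["Elephant", "Manatee"]),
                                (0.35, ["Armadillo", "Sloth"]),
                            ],
                        ),
                        (
                            0.50,
                            [
                                (
                                    0.45,
                                    [
                                        (
                                            0.40,
                                            [
                                                (
                                                    0.38,
                                                    [
                                                        (0.35, [(0.12, ["Mouse", "Rat"]), "Guinea_pig"]),
                                                        "Squirrel",
                                                    ],
                                                ),
                                                (0.25, ["Rabbit", "Pika"]),
                                            ],
                                        ),
                                        (
                                            0.35,
                                            [
                                                "Mouse_lemur",
                                                (
                                                    0.25,
                                                    [
                                                        "Marmoset",
                                                        (0.15, ["Rhesus_macaque", (0.04, ["Human", "Chimpanzee"])]),
                                                    ],
                                                ),
                                            ],
                                        ),
                                    ],
                                ),
                                (
                                    0.48,
                                    [
                                        (0.35, ["Hedgehog", "Shrew"]),
                                        (
                                            0.45,
                                            [
                                                (0.30, ["Megabat", "Microbat"]),
                                                (
                                                    0.42,
                                                    [
                                                        (
                                                            0.30,
                                                            [
                                                                "Dog",
                                                                (0.25, ["Cat", (0.20, ["Ferret", "Panda"])]),
                                                            ],
                                                        ),
                                                        (
                                                            0.38,
                                                            [
                                                                "Horse",
                                                                (
                                                                    0.30,
                                                                    [
                                                                        "Pig",
                                                                        (0.12, ["Cow", "Sheep"]),
                                                                    ],
                                                                ),
                                                            ],
                                                        ),
                                                    ],
                                                ),
                                            ],
                                        ),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)


def fixture_mammal_tree() -> Tree:
    """29-taxon ultrametric mammal chronogram (root depth 1.0)."""
    return Tree(_ultrametric(_MAMMAL_SPEC), rooted=True)
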