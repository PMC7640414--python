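"""Synthetic alignments with the statistical structure the pipeline assumes.

The generator evolves sites independently down a guide tree under a
reversible substitution model, with three deliberate departures from the
idealised picture so every diagnostic in the package has something to
detect:

* **compositional shifts** — designated branches switch to replacement
  equilibrium frequencies that apply from that branch tipward (exchange
  rates held fixed), making the process non-stationary and producing
  Bowker-detectable asymmetry between lineages;
* **gamma rate heterogeneity** — per-site rate multipliers drawn from the
  model's discrete-gamma categories;
* **non-random missing data** — whole taxon-by-partition blocks dropped
  (transcriptome-style gene absence) plus per-cell noise, with the mask a
  first-class part of the output.

Fixtures mirror the four-cluster study design: a 59-taxon amino-acid
supermatrix with myriapod-style group sizes 16/10/1/3 over outgroups, and a
small four-cluster alignment for quartet-mapping experiments.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .phylik import SubstitutionModel
from .seqmatrix import AMINO_ACID, InputError, PartitionScheme, ResidueMatrix

__all__ = [
    "SimulationConfig",
    "simulate_alignment",
    "four_cluster_fixture",
    "myriapod_fixture",
    "quartet_tree_newick",
]


@dataclasses.dataclass
class SimulationConfig:
    """Everything the simulator needs, reproducible from ``seed``.

    ``composition_shifts`` maps a node label (leaf label or internal-node
    label in the Newick string) to replacement equilibrium frequencies; the
    shifted process applies on the branch leading to that node and
    everywhere tipward of it.  ``dropout_prob`` removes whole
    taxon-by-partition blocks; ``missing_prob`` adds per-cell noise.
    """

    tree: str | dendropy.Tree
    model: SubstitutionModel
    n_sites: int
    partitions: Sequence[int] | None = None
    composition_shifts: Mapping[str, Sequence[float]] | None = None
    missing_prob: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise InputError("n_sites must be >= 1")
        if self.partitions is not None and sum(self.partitions) != self.n_sites:
            raise InputError("partition lengths must sum to n_sites")
        for label, freqs in (self.composition_shifts or {}).items():
            f = np.asarray(freqs, dtype=float)
            if f.shape != (self.model.alphabet.size,) or abs(f.sum() - 1.0) > 1e-6 or np.any(f <= 0):
                raise InputError(f"shift frequencies for {label!r} must be a positive simplex vector")


def _sample_states(p_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical state per row of a row-stochastic matrix."""
    cum = np.cumsum(p_rows, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(p_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(np.uint8)


def simulate_alignment(config: SimulationConfig) -> ResidueMatrix:
    """Evolve sites independently down the guide tree; apply missingness last."""
    tree = config.tree
    if isinstance(tree, str):
        try:
            tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise InputError(f"invalid guide tree: {exc}") from exc
    model = config.model
    k = model.alphabet.size
    n = config.n_sites
    rng = np.random.default_rng(config.seed)

    shifts = {
        label: np.asarray(f, dtype=float)
        for label, f in (config.composition_shifts or {}).items()
    }
    # one model object per frequency regime (exchangeabilities shared)
    regime_models: dict[bytes, SubstitutionModel] = {}

    def regime(freqs: np.ndarray) -> SubstitutionModel:
        key = freqs.tobytes()
        if key not in regime_models:
            regime_models[key] = SubstitutionModel(
                model.alphabet, model.exchange, freqs, model.gamma_shape, model.n_cat
            )
        return regime_models[key]

    rates = model.category_rates
    site_rates = rates[rng.integers(0, rates.size, size=n)] if rates.size > 1 else np.ones(n)
    unique_rates = np.unique(site_rates)

    root = tree.seed_node
    root_freqs = model.freqs
    root_label = root.label or (root.taxon.label if root.taxon else None)
    if root_label and root_label in shifts:
        root_freqs = shifts[root_label]
    states = {id(root): rng.choice(k, size=n, p=root_freqs / root_freqs.sum()).astype(np.uint8)}
    freqs_at = {id(root): root_freqs}

    taxa: list[str] = []
    rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            parent = node.parent_node
            label = node.label or (node.taxon.label if node.taxon else None)
            freqs = shifts.get(label, freqs_at[id(parent)]) if label else freqs_at[id(parent)]
            freqs_at[id(node)] = freqs
            t = node.edge.length or 0.0
            parent_states = states[id(parent)]
            child = np.empty(n, dtype=np.uint8)
            if t == 0.0:
                child[:] = parent_states
            else:
                m = regime(freqs)
                for r in unique_rates:
                    idx = np.nonzero(site_rates == r)[0]
                    p = m.transition_matrix(t * r)
                    child[idx] = _sample_states(p[parent_states[idx]], rng)
            states[id(node)] = child
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            taxa.append(label)
            rows.append(states[id(node)])

    codes = np.vstack(rows)
    if config.partitions is not None:
        scheme = PartitionScheme.from_lengths(
            tuple(f"gene{i + 1}" for i in range(len(config.partitions))), list(config.partitions)
        )
    else:
        scheme = PartitionScheme.single(n)

    # non-random missingness: whole-gene dropout, then per-cell noise
    if config.dropout_prob > 0:
        for i in range(len(taxa)):
            for (a, b) in scheme.bounds:
                if rng.random() < config.dropout_prob:
                    codes[i, a:b] = k
    if config.missing_prob > 0:
        noise = rng.random(codes.shape) < config.missing_prob
        codes[noise] = k
    return ResidueMatrix(taxa, codes, model.alphabet, scheme)


# ---------------------------------------------------------------------------
# Fixtures

def quartet_tree_newick(
    quartet: Sequence[str], internal: float = 0.3, terminal: float = 0.2
) -> str:
    """Unrooted quartet tree ((q0,q1),(q2,q3)) with the given branch lengths."""
    a, b, c, d = quartet
    half = internal / 2.0
    return f"(({a}:{terminal},{b}:{terminal}):{half},({c}:{terminal},{d}:{terminal}):{half});"


def _clade(labels: Sequence[str], tip_len: float, inner_len: float, label: str = "") -> str:
    """Ladder (comb) subtree over labels; ``label`` names the stem node."""
    if len(labels) == 1:
        return f"{labels[0]}:{tip_len}"
    rest = _clade(labels[1:], tip_len, inner_len)
    return f"({labels[0]}:{tip_len},{rest}){label}:{inner_len}"


def four_cluster_fixture(
    n_per_group: int = 3,
    n_sites: int = 2000,
    internal: float = 0.3,
    terminal: float = 0.2,
    within: float = 0.05,
    groups: Sequence[str] = ("G1", "G2", "G3", "G4"),
    model: SubstitutionModel | None = None,
    composition_shifts: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> tuple[ResidueMatrix, dict[str, str], str]:
    """Four clades paired (G1,G2)|(G3,G4) — strong signal for topology T1.

    With ``internal = 0`` the group-level tree is a star and no topology is
    preferred in expectation.  Returns (alignment, group map, guide newick).
    """
    if model is None:
        model = SubstitutionModel.poisson(alphabet=AMINO_ACID)
    members = {g: [f"{g}_t{i + 1}" for i in range(n_per_group)] for g in groups}
    half = internal / 2.0
    clades = {g: _clade(members[g], terminal, within) for g in groups}
    newick = (
        f"(({clades[groups[0]]},{clades[groups[1]]}):{half},"
        f"({clades[groups[2]]},{clades[groups[3]]}):{half});"
    )
    config = SimulationConfig(
        tree=newick,
        model=model,
        n_sites=n_sites,
        composition_shifts=composition_shifts,
        seed=seed,
    )
    matrix = simulate_alignment(config)
    group_map = {t: g for g, ts in members.items() for t in ts}
    return matrix, group_map, newick


# group sizes of the study design: 16 centipedes, 10 millipedes, 1 pauropod,
# 3 symphylans, 29 non-myriapods (2 onychophorans + 9 chelicerates +
# 18 pancrustaceans) = 59 taxa in total
_GROUP_SIZES = {
    "Chilopoda": 16,
    "Diplopoda": 10,
    "Pauropoda": 1,
    "Symphyla": 3,
}


def myriapod_fixture(
    seed: int = 0,
    n_sites: int = 2000,
    n_partitions: int = 10,
    model: SubstitutionModel | None = None,
    dropout_prob: float = 0.15,
    missing_prob: float = 0.02,
) -> tuple[ResidueMatrix, dict[str, str], str]:
    """59-taxon supermatrix emulating the myriapod study design.

    Simulated on a tree whose myriapod part pairs Chilopoda+Diplopoda
    against Pauropoda+Symphyla (quartet topology A) on a mandibulate
    backbone, with ~``n_partitions`` genes, gene-wise taxon dropout, mild
    compositional shifts on two outgroup clades, and per-cell noise.
    Returns (alignment, group map, guide newick).
    """
    if model is None:
        model = SubstitutionModel.poisson(alphabet=AMINO_ACID, gamma_shape=1.0, n_cat=4)
    names = {g: [f"{g[:4]}{i + 1:02d}" for i in range(n)] for g, n in _GROUP_SIZES.items()}
    ony = [f"Onych{i + 1:02d}" for i in range(2)]
    chel = [f"Cheli{i + 1:02d}" for i in range(9)]
    panc = [f"Pancr{i + 1:02d}" for i in range(18)]

    chil = _clade(names["Chilopoda"], 0.12, 0.03)
    dipl = _clade(names["Diplopoda"], 0.12, 0.03)
    paur = f"{names['Pauropoda'][0]}:0.18"
    sym = _clade(names["Symphyla"], 0.12, 0.03)
    myriapoda = f"(({chil},{dipl}):0.05,({paur},{sym}):0.05):0.06"
    pancrustacea = _clade(panc, 0.12, 0.02, label="PANC")
    chelicerata = _clade(chel, 0.12, 0.03, label="CHEL")
    outgroup = _clade(ony, 0.12, 0.05)
    newick = f"(({outgroup},{chelicerata}):0.05,({myriapoda},{pancrustacea}):0.05);"

    # mild lineage-specific composition shifts (SRH violations) on two
    # outgroup clades, labelled PANC and CHEL on their stem branches
    k = model.alphabet.size
    base = model.freqs

    def shifted(delta_seed: int, strength: float = 0.35) -> np.ndarray:
        r = np.random.default_rng(delta_seed)
        f = base * np.exp(strength * r.standard_normal(k))
        return f / f.sum()

    shifts = {"PANC": shifted(seed * 7 + 1), "CHEL": shifted(seed * 7 + 2)}

    lengths = [n_sites // n_partitions] * n_partitions
    lengths[-1] += n_sites - sum(lengths)
    config = SimulationConfig(
        tree=newick,
        model=model,
        n_sites=n_sites,
        partitions=lengths,
        composition_shifts=shifts,
        dropout_prob=dropout_prob,
        missing_prob=missing_prob,
        seed=seed,
    )
    matrix = simulate_alignment(config)
    group_map = {t: g for g, ts in names.items() for t in ts}
    for t in ony + chel + panc:
        group_map[t] = "Outgroup"
    return matrix, group_map, newick
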