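"""Four-cluster Likelihood-Mapping (FcLM).

Given four predefined taxon clusters, every quartet drawn one-taxon-per-
cluster is scored by maximum likelihood under each of its three unrooted
topologies.  With cluster order (c1, c2, c3, c4) the topology order is fixed:

    T1 = (c1,c2) | (c3,c4)    T2 = (c1,c3) | (c2,c4)    T3 = (c1,c4) | (c2,c3)

The three log-likelihoods are turned into normalized weights
p_i = exp(lnL_i - max) / sum (likelihood weights, not posteriors), a point
on the 2-simplex.  Points are classified into seven regions, implemented as
the Voronoi partition generated by the three vertices (cells 1-3: resolved
support for T1/T2/T3), the three edge midpoints (cells 4-6: pairwise
ambiguity; 4 = T1/T2, 5 = T2/T3, 6 = T1/T3) and the centroid (cell 7:
star-like, uninformative).  Aggregating over all drawn quartets gives the
per-cell percentage report that summarises where the signal lives.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .phylik import QuartetEngine, SubstitutionModel, empirical_frequencies
from .seqmatrix import InputError, ResidueMatrix, subset_taxa

__all__ = [
    "QuartetWeights",
    "SimplexReport",
    "draw_quartets",
    "quartet_weights",
    "assign_cell",
    "fclm_report",
    "default_model",
]

# Voronoi generators in barycentric coordinates (rows: cells 1..7).
_GENERATORS = np.array(
    [
        [1.0, 0.0, 0.0],  # cell 1: T1 resolved
        [0.0, 1.0, 0.0],  # cell 2: T2 resolved
        [0.0, 0.0, 1.0],  # cell 3: T3 resolved
        [0.5, 0.5, 0.0],  # cell 4: T1/T2 ambiguous
        [0.0, 0.5, 0.5],  # cell 5: T2/T3 ambiguous
        [0.5, 0.0, 0.5],  # cell 6: T1/T3 ambiguous
        [1 / 3, 1 / 3, 1 / 3],  # cell 7: center, uninformative
    ]
)


@dataclasses.dataclass
class QuartetWeights:
    """One quartet's ML log-likelihood triple and its simplex coordinates."""

    quartet: tuple[str, str, str, str]
    loglik: tuple[float, float, float]
    weights: tuple[float, float, float]

    @property
    def cell(self) -> int:
        return assign_cell(self.weights)


@dataclasses.dataclass
class SimplexReport:
    """Aggregate FcLM result: per-cell counts/percentages over drawn quartets."""

    groups: tuple[str, str, str, str]
    counts: np.ndarray  # 7 cells
    n_drawn: int
    n_skipped: int
    quartets: list[QuartetWeights]

    @property
    def percentages(self) -> np.ndarray:
        used = self.counts.sum()
        return 100.0 * self.counts / used if used else np.zeros(7)

    @property
    def topology_labels(self) -> dict[str, int]:
        """Cluster-pairing label -> cell index for the three resolved cells."""
        c1, c2, c3, c4 = self.groups
        return {
            f"({c1},{c2})|({c3},{c4})": 1,
            f"({c1},{c3})|({c2},{c4})": 2,
            f"({c1},{c4})|({c2},{c3})": 3,
        }

    def as_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "n_drawn": self.n_drawn,
            "n_skipped": self.n_skipped,
            "counts": [int(c) for c in self.counts],
            "percentages": [round(float(p), 4) for p in self.percentages],
            "topology_cells": self.topology_labels,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# groups\t{','.join(self.groups)}\n")
            fh.write(f"# drawn\t{self.n_drawn}\n# skipped\t{self.n_skipped}\n")
            fh.write("cell\tcount\tpercent\n")
            for i in range(7):
                fh.write(f"{i + 1}\t{int(self.counts[i])}\t{self.percentages[i]:.4f}\n")


def default_model(matrix: ResidueMatrix, gamma_shape: float | None = None, n_cat: int = 0) -> SubstitutionModel:
    """Whole-matrix default: Poisson+F for amino acids, GTR-as-JC is left to callers."""
    return SubstitutionModel.poisson(
        freqs=empirical_frequencies(matrix),
        gamma_shape=gamma_shape,
        n_cat=n_cat,
        alphabet=matrix.alphabet,
    )


def draw_quartets(
    group_map: Mapping[str, str],
    groups: Sequence[str],
    cap: int | None = None,
    seed: int = 0,
) -> list[tuple[str, str, str, str]]:
    """All one-per-group quartets, or a seeded uniform subsample of size ``cap``.

    The exhaustive product is returned in deterministic (sorted-member)
    order; when it exceeds ``cap``, a uniform sample without replacement is
    drawn with the given seed and returned in product order.
    """
    if len(groups) != 4:
        raise InputError("FcLM needs exactly 4 groups")
    members = {g: sorted(t for t, gg in group_map.items() if gg == g) for g in groups}
    for g in groups:
        if not members[g]:
            raise InputError(f"group {g!r} is empty")
    total = int(np.prod([len(members[g]) for g in groups]))
    if cap is None or total <= cap:
        return list(itertools.product(*(members[g] for g in groups)))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(total, size=cap, replace=False))
    sizes = [len(members[g]) for g in groups]
    out = []
    for flat in chosen:
        idx = np.unravel_index(flat, sizes)
        out.append(tuple(members[g][i] for g, i in zip(groups, idx)))
    return out


def _quartet_newicks(q: Sequence[str]) -> list[str]:
    a, b, c, d = (f"'{t}'" if any(ch in t for ch in " (),:;") else t for t in q)
    return [
        f"(({a},{b}),{c},{d});",  # T1 = (c1,c2)|(c3,c4)
        f"(({a},{c}),{b},{d});",  # T2 = (c1,c3)|(c2,c4)
        f"(({a},{d}),{b},{c});",  # T3 = (c1,c4)|(c2,c3)
    ]


def quartet_weights(
    quartet: Sequence[str],
    matrix: ResidueMatrix,
    model: SubstitutionModel,
    tol: float = 1e-4,
    max_cycles: int = 30,
) -> QuartetWeights:
    """ML log-likelihoods of the three topologies and their normalized weights.

    The per-topology branch search stops once a full cycle improves the
    log-likelihood by less than ``tol`` (looser than the generic optimizer's
    default: topology weights depend on log-likelihood *differences* well
    above this resolution, and near-flat surfaces on signal-poor quartets
    would otherwise cycle without meaningful gain).  Raises
    :class:`InputError` when the four taxa share no jointly covered site
    (callers typically skip such quartets).
    """
    sub = subset_taxa(matrix, list(quartet))
    if not (~sub.mask).all(axis=0).any():
        raise InputError(f"quartet {tuple(quartet)} has no jointly covered site")
    logls = []
    for order in ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)):  # T1, T2, T3
        engine = QuartetEngine(sub.codes[list(order)], model)
        logls.append(engine.optimize(tol=tol, max_cycles=max_cycles).loglik)
    logls_arr = np.array(logls)
    w = np.exp(logls_arr - logls_arr.max())
    w /= w.sum()
    return QuartetWeights(quartet=tuple(quartet), loglik=tuple(logls), weights=tuple(w))


def assign_cell(weights: Sequence[float]) -> int:
    """Nearest of the 7 Voronoi generators; ties break to the lowest cell index."""
    p = np.asarray(weights, dtype=float)
    if p.shape != (3,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise InputError("weights must be a barycentric triple summing to 1")
    d2 = ((_GENERATORS - p[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2)) + 1  # argmin takes the first (lowest) index on ties


def fclm_report(
    matrix: ResidueMatrix,
    group_map: Mapping[str, str],
    groups: Sequence[str],
    model: SubstitutionModel | None = None,
    cap: int | None = None,
    seed: int = 0,
) -> SimplexReport:
    """Full FcLM pass: draw, score and classify quartets, aggregate per cell."""
    if model is None:
        model = default_model(matrix)
    quartets = draw_quartets(group_map, groups, cap=cap, seed=seed)
    counts = np.zeros(7)
    scored: list[QuartetWeights] = []
    skipped = 0
    for q in quartets:
        try:
            qw = quartet_weights(q, matrix, model)
        except InputError:
            skipped += 1
            continue
        counts[qw.cell - 1] += 1
        scored.append(qw)
    if not scored:
        raise InputError("all quartets were skipped; no jointly covered data")
    return SimplexReport(
        groups=tuple(groups),
        counts=counts,
        n_drawn=len(quartets),
        n_skipped=skipped,
        quartets=scored,
    )
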