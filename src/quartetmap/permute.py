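"""Signal-destroying alignment permutations for confounding-signal diagnosis.

Apparent quartet support can come from non-phylogenetic sources: lineage-
specific residue composition (SRH violations) and non-randomly distributed
missing data.  Each scheme destroys site-wise phylogenetic signal while
preserving a chosen confounder, so re-running FcLM on the permuted matrix
shows how much of the original support the confounder alone can generate.
The missing-data mask is never altered by any scheme.

Scheme I   - per taxon, shuffle its non-missing residues across all its
             non-missing positions matrix-wide.  Preserves per-taxon
             composition (lineage heterogeneity) and the mask.
Scheme II  - as I, but independently within each partition.  Additionally
             preserves per-taxon-per-partition composition.
Scheme III - per site column, shuffle residues among the taxa covered at
             that column.  Preserves per-site composition and the mask but
             destroys lineage-specific composition.

A support percentage that survives schemes I/II is explainable by
compositional heterogeneity; support surviving III would implicate site-
level composition rather than lineage structure.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .fclm import SimplexReport, default_model, fclm_report
from .phylik import SubstitutionModel
from .seqmatrix import InputError, ResidueMatrix

__all__ = ["SCHEMES", "permute_matrix", "fclm_with_permutations", "PermutationTable"]

SCHEMES = ("I", "II", "III")


def _child_rng(seed: int, index: int) -> np.random.Generator:
    # independent stream per taxon/column: reproducible and order-independent
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _permute_rows(codes: np.ndarray, sentinel: int, seed: int, col_slice: slice, offset: int) -> None:
    for i in range(codes.shape[0]):
        row = codes[i, col_slice]
        present = np.nonzero(row != sentinel)[0]
        if present.size > 1:
            rng = _child_rng(seed, offset + i)
            row[present] = row[present[rng.permutation(present.size)]]


def permute_matrix(matrix: ResidueMatrix, scheme: str, seed: int = 0) -> ResidueMatrix:
    """Apply permutation scheme I, II or III; the mask is preserved exactly."""
    if scheme not in SCHEMES:
        raise InputError(f"unknown permutation scheme {scheme!r}; expected one of {SCHEMES}")
    out = matrix.copy()
    sentinel = matrix.alphabet.size
    if scheme == "I":
        _permute_rows(out.codes, sentinel, seed, slice(None), offset=0)
    elif scheme == "II":
        for k, (a, b) in enumerate(matrix.partitions.bounds):
            _permute_rows(out.codes, sentinel, seed, slice(a, b), offset=k * matrix.n_taxa)
    else:  # III: per-column shuffle among covered taxa
        for j in range(matrix.n_sites):
            col = out.codes[:, j]
            present = np.nonzero(col != sentinel)[0]
            if present.size > 1:
                rng = _child_rng(seed, j)
                col[present] = col[present[rng.permutation(present.size)]]
    return out


@dataclasses.dataclass
class PermutationTable:
    """FcLM reports for the original matrix and each permutation scheme."""

    original: SimplexReport
    permuted: dict[str, SimplexReport]

    def rows(self) -> list[tuple[str, SimplexReport]]:
        return [("original", self.original)] + [
            (f"permutation {s}", self.permuted[s]) for s in self.permuted
        ]

    def explainable_by_confounding(self, cell: int, margin: float = 5.0) -> bool:
        """True when the original support for ``cell`` does not exceed the
        best permuted support by more than ``margin`` percentage points —
        i.e. confounding signal alone can account for it."""
        if not self.permuted:
            raise InputError("no permutation rows to compare against")
        best = max(rep.percentages[cell - 1] for rep in self.permuted.values())
        return self.original.percentages[cell - 1] <= best + margin

    def as_dict(self) -> dict:
        return {name: rep.as_dict() for name, rep in self.rows()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("row\t" + "\t".join(f"cell{i}" for i in range(1, 8)) + "\n")
            for name, rep in self.rows():
                fh.write(name + "\t" + "\t".join(f"{p:.4f}" for p in rep.percentages) + "\n")


def fclm_with_permutations(
    matrix: ResidueMatrix,
    group_map: Mapping[str, str],
    groups: Sequence[str],
    model: SubstitutionModel | None = None,
    schemes: Sequence[str] = SCHEMES,
    seed: int = 0,
    cap: int | None = None,
) -> PermutationTable:
    """FcLM on the original matrix and on each permuted version of it.

    The same drawn-quartet set (same cap and seed) is used for every row so
    the rows differ only by the permutation applied to the data.
    """
    if model is None:
        model = default_model(matrix)
    original = fclm_report(matrix, group_map, groups, model=model, cap=cap, seed=seed)
    permuted: dict[str, SimplexReport] = {}
    for scheme in schemes:
        pm = permute_matrix(matrix, scheme, seed=seed)
        permuted[scheme] = fclm_report(pm, group_map, groups, model=model, cap=cap, seed=seed)
    return PermutationTable(original=original, permuted=permuted)
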