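"""Pairwise Bowker tests of symmetry — diagnostics for SRH violations.

Under a stationary, (time-)reversible and homogeneous (SRH) substitution
process, the expected contingency table of aligned residue pairs between any
two sequences is symmetric.  Bowker's matched-pairs test checks exactly that:

    B = sum_{u<v} (n_uv - n_vu)^2 / (n_uv + n_vu)

over residue pairs with n_uv + n_vu > 0, chi-square distributed with one
degree of freedom per contributing pair.  Low p-values flag sequence pairs
whose evolution cannot have been SRH throughout — in practice, compositional
heterogeneity among lineages.  The scan mirrors SymTest's all-pairs heatmap
and its headline number, the percentage of pairs rejected at alpha.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
from scipy import stats

from .seqmatrix import ResidueMatrix

__all__ = ["PairSymmetryResult", "SrhSummary", "pair_counts", "bowker_test", "srh_scan"]


@dataclasses.dataclass
class PairSymmetryResult:
    taxon_i: str
    taxon_j: str
    counts: np.ndarray
    statistic: float
    df: int
    p: float
    degenerate: bool = False  # no jointly covered sites


@dataclasses.dataclass
class SrhSummary:
    taxa: list[str]
    p_matrix: np.ndarray  # symmetric, diag 1
    alpha: float

    @property
    def reject_fraction(self) -> float:
        """Percentage of unordered pairs with p < alpha."""
        n = len(self.taxa)
        iu = np.triu_indices(n, k=1)
        p = self.p_matrix[iu]
        return 100.0 * float(np.mean(p < self.alpha)) if p.size else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# alpha\t{self.alpha}\n# reject_fraction\t{self.reject_fraction:.4f}\n")
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{v:.6g}" for v in self.p_matrix[i]) + "\n")


def pair_counts(matrix: ResidueMatrix, taxon_i: str, taxon_j: str) -> np.ndarray:
    """Contingency table n_uv of residue pairs over sites covered in both taxa."""
    k = matrix.alphabet.size
    ri, rj = matrix.row(taxon_i), matrix.row(taxon_j)
    both = (ri < k) & (rj < k)
    joint = ri[both].astype(np.intp) * k + rj[both].astype(np.intp)
    return np.bincount(joint, minlength=k * k).reshape(k, k)


def bowker_test(counts: np.ndarray) -> tuple[float, int, float]:
    """Bowker statistic, degrees of freedom and upper-tail chi-square p.

    df counts the unordered off-diagonal pairs with n_uv + n_vu > 0;
    df = 0 (nothing to test) yields p = 1 by convention.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square table")
    iu = np.triu_indices(counts.shape[0], k=1)
    n_uv = counts[iu].astype(np.float64)
    n_vu = counts.T[iu].astype(np.float64)
    tot = n_uv + n_vu
    use = tot > 0
    df = int(use.sum())
    if df == 0:
        return 0.0, 0, 1.0
    b = float(np.sum((n_uv[use] - n_vu[use]) ** 2 / tot[use]))
    return b, df, float(stats.chi2.sf(b, df))


def srh_scan(matrix: ResidueMatrix, alpha: float = 0.05) -> SrhSummary:
    """Bowker's test for every unordered taxon pair; raw p-values, no correction."""
    n = matrix.n_taxa
    if n < 2:
        raise ValueError("need at least two taxa")
    k = matrix.alphabet.size
    codes = matrix.codes
    p_matrix = np.ones((n, n))
    iu = np.triu_indices(k, k=1)
    for i, j in itertools.combinations(range(n), 2):
        ri, rj = codes[i], codes[j]
        both = (ri < k) & (rj < k)
        joint = ri[both].astype(np.intp) * k + rj[both].astype(np.intp)
        counts = np.bincount(joint, minlength=k * k).reshape(k, k)
        n_uv = counts[iu].astype(np.float64)
        n_vu = counts.T[iu].astype(np.float64)
        tot = n_uv + n_vu
        use = tot > 0
        df = int(use.sum())
        if df:
            b = np.sum((n_uv[use] - n_vu[use]) ** 2 / tot[use])
            p = float(stats.chi2.sf(b, df))
        else:
            p = 1.0
        p_matrix[i, j] = p_matrix[j, i] = p
    return SrhSummary(taxa=list(matrix.taxa), p_matrix=p_matrix, alpha=alpha)


def pair_symmetry(matrix: ResidueMatrix, taxon_i: str, taxon_j: str) -> PairSymmetryResult:
    """Full Bowker result for one taxon pair, flagging zero joint coverage."""
    counts = pair_counts(matrix, taxon_i, taxon_j)
    b, df, p = bowker_test(counts)
    return PairSymmetryResult(
        taxon_i=taxon_i,
        taxon_j=taxon_j,
        counts=counts,
        statistic=b,
        df=df,
        p=p,
        degenerate=counts.sum() == 0,
    )
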