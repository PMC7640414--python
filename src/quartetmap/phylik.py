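"""Substitution models and pruning likelihoods on fixed topologies.

This is the computational substrate of quartet mapping and the AU test:
time-reversible substitution models (Poisson/empirical-exchangeability for
amino acids, JC/GTR for nucleotides) with optional discrete-gamma rate
heterogeneity, Felsenstein's pruning algorithm with per-pattern rescaling,
coordinate-wise branch-length optimization on a fixed topology, and export
of per-site log-likelihoods.

Missing residues at tips are marginalized (all-ones tip partials), the
standard convention.  Identical alignment columns are collapsed into
weighted patterns before any likelihood work.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .seqmatrix import AMINO_ACID, NUCLEOTIDE, Alphabet, InputError, ResidueMatrix

__all__ = [
    "SubstitutionModel",
    "TreeLikelihood",
    "BranchOptResult",
    "SiteLogLikelihoodMatrix",
    "NumericalError",
    "site_log_likelihoods",
    "optimize_branch_lengths",
    "slm_from_trees",
    "empirical_frequencies",
    "compress_patterns",
    "discrete_gamma_rates",
]

BRANCH_MIN = 0.0
BRANCH_MAX = 10.0
BRANCH_INIT = 0.1


class NumericalError(ArithmeticError):
    """A likelihood evaluated to zero / non-finite log-likelihood."""


def discrete_gamma_rates(shape: float, n_cat: int) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability discrete-gamma categories.

    The gamma has mean 1 (rate parameter = shape); category means are exact
    via the regularized incomplete gamma function and average to 1.
    """
    if n_cat < 2:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, n_cat) / n_cat, a=shape, scale=1.0 / shape)
    cuts = np.concatenate(([0.0], edges, [np.inf]))
    upper = np.where(np.isinf(cuts[1:]), 1.0, gammainc(shape + 1.0, shape * cuts[1:]))
    lower = gammainc(shape + 1.0, shape * cuts[:-1])
    rates = n_cat * (upper - lower)
    return rates / rates.mean()  # exact up to float noise


def empirical_frequencies(matrix: ResidueMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Observed residue frequencies (+F), Laplace-smoothed so none is zero."""
    k = matrix.alphabet.size
    counts = np.bincount(matrix.codes[matrix.codes < k], minlength=k).astype(float)
    counts += pseudocount
    return counts / counts.sum()


@dataclasses.dataclass
class SubstitutionModel:
    """Reversible substitution model with optional discrete-gamma rates.

    ``exchange`` is the symmetric exchangeability matrix S (diagonal ignored);
    the rate matrix is Q_ij = S_ij * pi_j, scaled to one expected
    substitution per unit time.  ``n_cat = 0`` disables rate heterogeneity.
    """

    alphabet: Alphabet
    exchange: np.ndarray
    freqs: np.ndarray
    gamma_shape: float | None = None
    n_cat: int = 0

    def __post_init__(self):
        k = self.alphabet.size
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (k,) or np.any(self.freqs <= 0):
            raise InputError("equilibrium frequencies must be positive and match the alphabet")
        self.freqs = self.freqs / self.freqs.sum()
        s = np.asarray(self.exchange, dtype=float)
        if s.shape != (k, k) or not np.allclose(s, s.T):
            raise InputError("exchangeability matrix must be square and symmetric")
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.sum(self.freqs * np.diag(q))
        q /= mu
        self._q = q
        # symmetric decomposition: B = D^1/2 Q D^-1/2
        d_sqrt = np.sqrt(self.freqs)
        b = d_sqrt[:, None] * q / d_sqrt[None, :]
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        self._evals = evals
        self._left = evecs / d_sqrt[:, None] * 1.0  # D^-1/2 U
        self._right = (evecs * d_sqrt[:, None]).T  # U^T D^1/2
        self._rates = (
            discrete_gamma_rates(self.gamma_shape, self.n_cat)
            if self.n_cat >= 2 and self.gamma_shape is not None
            else np.ones(1)
        )

    @property
    def rate_matrix(self) -> np.ndarray:
        return self._q.copy()

    @property
    def category_rates(self) -> np.ndarray:
        return self._rates.copy()

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetric eigendecomposition."""
        p = (self._left * np.exp(self._evals * t)) @ self._right
        return np.clip(p, 0.0, None)

    # -- constructors -------------------------------------------------------
    @classmethod
    def poisson(
        cls,
        freqs: np.ndarray | None = None,
        gamma_shape: float | None = None,
        n_cat: int = 0,
        alphabet: Alphabet = AMINO_ACID,
    ) -> "SubstitutionModel":
        """Equal exchangeabilities (Poisson when frequencies are uniform)."""
        k = alphabet.size
        if freqs is None:
            freqs = np.full(k, 1.0 / k)
        return cls(alphabet, np.ones((k, k)), freqs, gamma_shape, n_cat)

    @classmethod
    def jc(cls, gamma_shape: float | None = None, n_cat: int = 0) -> "SubstitutionModel":
        """Jukes-Cantor nucleotide model."""
        return cls.poisson(None, gamma_shape, n_cat, alphabet=NUCLEOTIDE)

    @classmethod
    def gtr(
        cls,
        rates: Sequence[float],
        freqs: np.ndarray,
        gamma_shape: float | None = None,
        n_cat: int = 0,
    ) -> "SubstitutionModel":
        """General time-reversible nucleotide model.

        ``rates`` are the six upper-triangle exchangeabilities in the order
        AC, AG, AT, CG, CT, GT.
        """
        r = np.asarray(rates, dtype=float)
        if r.shape != (6,):
            raise InputError("GTR needs 6 exchangeability rates")
        s = np.zeros((4, 4))
        s[np.triu_indices(4, k=1)] = r
        s = s + s.T
        return cls(NUCLEOTIDE, s, freqs, gamma_shape, n_cat)

    @classmethod
    def from_paml(
        cls,
        path: str | Path,
        freqs: np.ndarray | None = None,
        gamma_shape: float | None = None,
        n_cat: int = 0,
    ) -> "SubstitutionModel":
        """Load an empirical amino-acid matrix from a PAML-format .dat file.

        Expects the 19 lower-triangle exchangeability rows followed by a line
        (or lines) of 20 equilibrium frequencies; ``freqs`` overrides the
        file's frequencies (e.g. with +F empirical frequencies).
        """
        values: list[float] = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if line:
                values.extend(float(x) for x in line.split())
        if len(values) < 190 + 20:
            raise InputError("PAML matrix file must hold 190 rates and 20 frequencies")
        s = np.zeros((20, 20))
        pos = 0
        for i in range(1, 20):
            s[i, :i] = values[pos : pos + i]
            pos += i
        s = s + s.T
        file_freqs = np.asarray(values[pos : pos + 20])
        return cls(AMINO_ACID, s, freqs if freqs is not None else file_freqs, gamma_shape, n_cat)


# ---------------------------------------------------------------------------
# Pattern compression

def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (patterns, weights, site->pattern index)."""
    patterns, inverse, counts = np.unique(codes, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts.astype(float), inverse.ravel()


# ---------------------------------------------------------------------------
# Tree likelihood

@dataclasses.dataclass
class BranchOptResult:
    lengths: dict[str, float]
    loglik: float
    converged: bool
    n_cycles: int
    tree: dendropy.Tree | None = None


class TreeLikelihood:
    """Pruning likelihood of an alignment on one fixed tree.

    ``tree`` may be a dendropy Tree or a Newick string; leaf labels must be
    taxa of ``matrix``.  Branch lengths missing from the input default to
    ``BRANCH_INIT``.  The (arbitrary) pruning root is the tree's root node;
    for reversible models its placement does not change the likelihood.
    """

    def __init__(self, matrix: ResidueMatrix, tree: dendropy.Tree | str, model: SubstitutionModel):
        if model.alphabet.name != matrix.alphabet.name:
            raise InputError("model and matrix alphabets differ")
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
        self.model = model
        self._tree = tree
        nodes = list(tree.postorder_node_iter())
        self._index = {id(n): i for i, n in enumerate(nodes)}
        self._nodes = nodes
        self._children = [[self._index[id(c)] for c in n.child_nodes()] for n in nodes]
        self._root = self._index[id(tree.seed_node)]
        self.edge_names: list[str] = []
        self._edge_nodes: list[int] = []
        lengths = []
        leaf_rows = {}
        used_taxa = []
        for i, n in enumerate(nodes):
            if i != self._root:
                self._edge_nodes.append(i)
                lengths.append(n.edge.length if n.edge.length is not None else BRANCH_INIT)
                if n.is_leaf():
                    self.edge_names.append(n.taxon.label)
                else:
                    self.edge_names.append(f"edge{len(self.edge_names)}")
            if n.is_leaf():
                label = n.taxon.label
                if label not in matrix.taxa:
                    raise InputError(f"tree leaf {label!r} not in matrix")
                leaf_rows[i] = len(used_taxa)
                used_taxa.append(label)
        self._leaf_rows = leaf_rows
        self._lengths = {n: float(l) for n, l in zip(self._edge_nodes, lengths)}
        if any(l < 0 for l in self._lengths.values()):
            raise InputError("negative branch length")
        rows = [matrix.taxa.index(t) for t in used_taxa]
        self.patterns, self.weights, self._site_to_pat = compress_patterns(matrix.codes[rows])
        self.n_sites = matrix.n_sites

    # -- core evaluation ----------------------------------------------------
    def _pattern_logliks(self, lengths: dict[int, float]) -> np.ndarray:
        model = self.model
        k = model.alphabet.size
        npat = self.patterns.shape[1]
        rates = model._rates
        per_cat = np.empty((len(rates), npat))
        for ci, rate in enumerate(rates):
            pmats = {n: model.transition_matrix(lengths[n] * rate) for n in self._edge_nodes}
            partial: dict[int, np.ndarray] = {}
            logscale = np.zeros(npat)
            for i in range(len(self._nodes)):  # nodes are stored in postorder
                kids = self._children[i]
                if not kids:
                    continue
                prod = np.ones((npat, k))
                for c in kids:
                    if c in self._leaf_rows:
                        p = pmats[c]
                        ext = np.vstack([p.T, np.ones(k)])
                        contrib = ext[self.patterns[self._leaf_rows[c]]]
                    else:
                        contrib = partial.pop(c) @ pmats[c].T
                    prod *= contrib
                scale = prod.max(axis=1)
                nz = scale > 0
                prod[nz] /= scale[nz, None]
                with np.errstate(divide="ignore"):
                    logscale += np.where(nz, np.log(np.where(nz, scale, 1.0)), -np.inf)
                partial[i] = prod
            if self._root in self._leaf_rows:  # single-leaf tree (degenerate)
                root_partial = np.ones((npat, k))
            else:
                root_partial = partial[self._root]
            lik = root_partial @ model.freqs
            with np.errstate(divide="ignore"):
                per_cat[ci] = np.log(lik) + logscale
        out = logsumexp(per_cat, axis=0) - np.log(len(rates))
        return out

    def pattern_logliks(self) -> np.ndarray:
        out = self._pattern_logliks(self._lengths)
        if not np.all(np.isfinite(out)):
            bad = int(np.argmin(np.isfinite(out)))
            site = int(np.nonzero(self._site_to_pat == bad)[0][0])
            raise NumericalError(f"non-finite site log-likelihood at site {site}")
        return out

    def site_logliks(self) -> np.ndarray:
        """Per-site log-likelihoods (patterns expanded back to sites)."""
        return self.pattern_logliks()[self._site_to_pat]

    def loglik(self) -> float:
        return float(self.pattern_logliks() @ self.weights)

    @property
    def lengths(self) -> dict[str, float]:
        return {name: self._lengths[n] for name, n in zip(self.edge_names, self._edge_nodes)}

    # -- branch-length optimization -----------------------------------------
    def optimize(
        self,
        tol: float = 1e-6,
        max_cycles: int = 100,
        bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
        xatol: float = 1e-5,
    ) -> BranchOptResult:
        """Coordinate-wise bounded scalar search per branch, cycled to convergence.

        The log-likelihood never decreases across cycles: a candidate length
        is only accepted when it improves on the incumbent.  Non-convergence
        within ``max_cycles`` is flagged, not raised.
        """
        lengths = dict(self._lengths)
        w = self.weights

        def total(ls: dict[int, float]) -> float:
            return float(self._pattern_logliks(ls) @ w)

        cur = total(lengths)
        converged = False
        cycles = 0
        for cycles in range(1, max_cycles + 1):
            prev = cur
            for node in self._edge_nodes:
                incumbent = lengths[node]

                def neg(t: float, node=node) -> float:
                    trial = dict(lengths)
                    trial[node] = t
                    return -total(trial)

                res = minimize_scalar(
                    neg, bounds=bounds, method="bounded", options={"xatol": xatol}
                )
                if -res.fun > cur:
                    lengths[node] = float(res.x)
                    cur = -res.fun
                else:
                    lengths[node] = incumbent
            if cur - prev < tol:
                converged = True
                break
        self._lengths = lengths
        for n in self._edge_nodes:
            self._nodes[n].edge.length = lengths[n]
        return BranchOptResult(
            lengths=self.lengths, loglik=cur, converged=converged, n_cycles=cycles, tree=self._tree
        )


class QuartetEngine:
    """Fast ML branch lengths on a single 4-taxon unrooted topology.

    For the quartet ((a,b),(c,d)) with five branches, the per-pattern
    likelihood as a function of one branch length t factorises through the
    model's eigendecomposition as ``L(pat) = M[pat, :] @ exp(lambda * t)``
    with M precomputable from the other four branches, so each scalar
    evaluation inside the branch search is a single matrix-vector product.
    Results agree with :class:`TreeLikelihood` (same likelihood function,
    same coordinate-wise search); this path just makes quartet mapping over
    hundreds of quartets affordable.

    ``codes`` holds the four taxa's rows (alphabet codes with the missing
    sentinel) in the order (a, b, c, d) of the pairing (a,b)|(c,d).
    """

    def __init__(self, codes: np.ndarray, model: SubstitutionModel):
        if codes.shape[0] != 4:
            raise InputError("QuartetEngine needs exactly 4 sequence rows")
        self.model = model
        self.patterns, self.weights, _ = compress_patterns(codes)
        self._k = model.alphabet.size

    def _tip_ext(self, p: np.ndarray) -> np.ndarray:
        return np.vstack([p.T, np.ones(self._k)])

    def _pattern_liks(self, lengths: np.ndarray, rate: float) -> np.ndarray:
        """Per-pattern likelihood for one rate category (direct pruning)."""
        m = self.model
        pa, pb, pu, pc, pd = (m.transition_matrix(t * rate) for t in lengths)
        sa, sb, sc, sd = self.patterns
        f_u = self._tip_ext(pa)[sa] * self._tip_ext(pb)[sb]
        a_root = m.freqs * self._tip_ext(pc)[sc] * self._tip_ext(pd)[sd]
        return np.einsum("py,yx,px->p", a_root, pu, f_u, optimize=True)

    def loglik(self, lengths: np.ndarray) -> float:
        rates = self.model._rates
        liks = np.mean([self._pattern_liks(lengths, r) for r in rates], axis=0)
        return float(self.weights @ np.log(np.clip(liks, 1e-300, None)))

    def _edge_coefs(self, edge: int, lengths: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
        """(M, g0) with per-pattern likelihood M @ exp(evals * t * rate) + g0."""
        m = self.model
        left, right = m._left, m._right
        pa, pb, pu, pc, pd = (m.transition_matrix(t * rate) for t in lengths)
        sa, sb, sc, sd = self.patterns
        ea, eb, ec, ed = (self._tip_ext(p) for p in (pa, pb, pc, pd))
        npat = sa.size
        if edge == 2:  # internal branch u
            f_u = ea[sa] * eb[sb]
            a_root = m.freqs * ec[sc] * ed[sd]
            mcoef = (a_root @ left) * (f_u @ right.T)
            return mcoef, np.zeros(npat)
        if edge in (0, 1):  # tip a or b
            a_root = m.freqs * ec[sc] * ed[sd]
            out_u = a_root @ pu  # conditional above node u
            g = out_u * (eb[sb] if edge == 0 else ea[sa])
            s = sa if edge == 0 else sb
        else:  # tip c or d (root side)
            f_u = ea[sa] * eb[sb]
            through_u = f_u @ pu.T
            g = m.freqs * through_u * (ed[sd] if edge == 3 else ec[sc])
            s = sc if edge == 3 else sd
        gl = g @ left
        covered = s < self._k
        mcoef = np.where(covered[:, None], gl * right[:, np.minimum(s, self._k - 1)].T, 0.0)
        g0 = np.where(covered, 0.0, g.sum(axis=1))
        return mcoef, g0

    def optimize(
        self,
        init: float = BRANCH_INIT,
        tol: float = 1e-6,
        max_cycles: int = 100,
        bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
        xatol: float = 1e-4,
    ) -> BranchOptResult:
        """Coordinate-wise branch search; same contract as TreeLikelihood.optimize."""
        m = self.model
        rates = m._rates
        lengths = np.full(5, float(init))
        w = self.weights
        evals = m._evals
        cur = self.loglik(lengths)
        converged = False
        cycles = 0
        for cycles in range(1, max_cycles + 1):
            prev = cur
            for e in range(5):
                coefs = [self._edge_coefs(e, lengths, r) for r in rates]

                def neg(t: float) -> float:
                    liks = np.mean(
                        [mc @ np.exp(evals * (t * r)) + g0 for (mc, g0), r in zip(coefs, rates)],
                        axis=0,
                    )
                    return -float(w @ np.log(np.clip(liks, 1e-300, None)))

                res = minimize_scalar(neg, bounds=bounds, method="bounded", options={"xatol": xatol})
                if -res.fun > cur:
                    lengths[e] = float(res.x)
                    cur = -res.fun
            if cur - prev < tol:
                converged = True
                break
        names = ["a", "b", "internal", "c", "d"]
        return BranchOptResult(
            lengths=dict(zip(names, lengths)), loglik=cur, converged=converged, n_cycles=cycles
        )


def site_log_likelihoods(
    matrix: ResidueMatrix, tree: dendropy.Tree | str, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihoods of the alignment on a tree with branch lengths."""
    return TreeLikelihood(matrix, tree, model).site_logliks()


def optimize_branch_lengths(
    matrix: ResidueMatrix,
    tree: dendropy.Tree | str,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_cycles: int = 100,
) -> BranchOptResult:
    """ML branch lengths on a fixed topology (coordinate-wise bounded search)."""
    return TreeLikelihood(matrix, tree, model).optimize(tol=tol, max_cycles=max_cycles)


# ---------------------------------------------------------------------------
# Site log-likelihood matrices (AU-test substrate)

@dataclasses.dataclass
class SiteLogLikelihoodMatrix:
    """Per-tree, per-column site log-likelihoods with pattern weights.

    Columns may be raw sites (all weights 1) or collapsed patterns; the
    weighted row sums are the trees' total log-likelihoods either way.
    """

    labels: list[str]
    loglik: np.ndarray  # trees x columns
    weights: np.ndarray  # columns

    def __post_init__(self):
        self.loglik = np.atleast_2d(np.asarray(self.loglik, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.loglik.shape != (len(self.labels), self.weights.size):
            raise InputError("site log-likelihood matrix shape mismatch")

    @property
    def n_trees(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return int(round(self.weights.sum()))

    def totals(self) -> np.ndarray:
        return self.loglik @ self.weights

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site\tweight\t" + "\t".join(self.labels) + "\n")
            for j in range(self.weights.size):
                vals = "\t".join(f"{v:.10g}" for v in self.loglik[:, j])
                fh.write(f"{j}\t{self.weights[j]:g}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteLogLikelihoodMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["site", "weight"]:
                raise InputError("expected 'site\\tweight\\t<tree labels...>' header")
            labels = header[2:]
            weights, cols = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or parts == [""]:
                    continue
                weights.append(float(parts[1]))
                cols.append([float(x) for x in parts[2:]])
        return cls(labels=labels, loglik=np.array(cols).T, weights=np.array(weights))


def slm_from_trees(
    matrix: ResidueMatrix,
    trees: Sequence[dendropy.Tree | str],
    model: SubstitutionModel,
    labels: Sequence[str] | None = None,
    optimize: bool = True,
) -> SiteLogLikelihoodMatrix:
    """Site log-likelihoods for several candidate trees on one alignment."""
    if labels is None:
        labels = [f"tree{i + 1}" for i in range(len(trees))]
    rows = []
    for tree in trees:
        tl = TreeLikelihood(matrix, tree, model)
        if optimize:
            tl.optimize()
        rows.append(tl.site_logliks())
    return SiteLogLikelihoodMatrix(
        labels=list(labels), loglik=np.vstack(rows), weights=np.ones(matrix.n_sites)
    )
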