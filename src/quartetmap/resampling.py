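"""Approximately unbiased (AU) tree-selection test via multiscale RELL bootstrap.

Candidate trees enter as rows of per-site log-likelihoods.  At each scale r
the sites are resampled with replacement to round(r * n) sites (RELL: the
log-likelihoods are resampled, nothing is re-optimized), each replicate
credits the tree with the highest resampled total (ties split equally), and
the bootstrap proportion BP(r) per tree is recorded.  The probit-transformed
proportions z(r) = Phi^-1(1 - BP(r)) are fitted by weighted least squares to

    z(r) = d * sqrt(r) + c / sqrt(r)

where d estimates the signed distance to the region boundary and c its
curvature; the AU p-value is p = 1 - Phi(d - c).  Trees whose BP is 0 or 1
at every scale are degenerate (p = 0 or 1, flagged, no fit).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .phylik import SiteLogLikelihoodMatrix
from .seqmatrix import InputError

__all__ = ["AuResult", "AuTable", "rell_bootstrap", "au_test", "DEFAULT_SCALES", "dedup_slm"]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))
DEFAULT_REPLICATES = 10_000


@dataclasses.dataclass
class AuResult:
    label: str
    bp: np.ndarray  # bootstrap proportion per scale
    scales: np.ndarray
    d: float | None
    c: float | None
    p_au: float
    degenerate: bool
    fit_residual: float | None = None


@dataclasses.dataclass
class AuTable:
    results: list[AuResult]
    replicates: int
    seed: int

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, label: str) -> AuResult:
        for r in self.results:
            if r.label == label:
                return r
        raise KeyError(label)

    def p_values(self) -> dict[str, float]:
        return {r.label: r.p_au for r in self.results}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# replicates\t{self.replicates}\n# seed\t{self.seed}\n")
            fh.write("tree\tp_au\td\tc\tdegenerate\n")
            for r in self.results:
                d = "" if r.d is None else f"{r.d:.6g}"
                c = "" if r.c is None else f"{r.c:.6g}"
                fh.write(f"{r.label}\t{r.p_au:.6g}\t{d}\t{c}\t{int(r.degenerate)}\n")


def rell_bootstrap(
    slm: SiteLogLikelihoodMatrix,
    scale: float = 1.0,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-tree bootstrap proportions at one resampling scale.

    Each replicate draws round(scale * n_sites) sites with replacement
    (pattern weights act as sampling probabilities), sums the resampled
    log-likelihoods per tree and credits the argmax; exact ties are split
    equally.  Proportions sum to 1 across trees.
    """
    if scale <= 0:
        raise InputError("scale must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_sites = slm.n_sites
    m = max(1, int(round(scale * n_sites)))
    probs = slm.weights / slm.weights.sum()
    ntrees = slm.n_trees
    wins = np.zeros(ntrees)
    chunk = max(1, min(replicates, int(2e7 // max(1, probs.size))))
    done = 0
    while done < replicates:
        b = min(chunk, replicates - done)
        counts = rng.multinomial(m, probs, size=b).astype(float)
        totals = counts @ slm.loglik.T  # b x ntrees
        best = totals.max(axis=1, keepdims=True)
        is_best = np.isclose(totals, best, rtol=0.0, atol=1e-9)
        wins += (is_best / is_best.sum(axis=1, keepdims=True)).sum(axis=0)
        done += b
    return wins / replicates


def _fit_au(bp: np.ndarray, scales: np.ndarray, replicates: int) -> tuple[float, float, float, float]:
    """WLS fit of z(r) = d*sqrt(r) + c/sqrt(r); returns (d, c, p_au, rss)."""
    eps = 1.0 / (2.0 * replicates)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp_c)
    # binomial delta-method weight: Var(z) ~ BP(1-BP) / (B * phi(z)^2)
    w = replicates * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    x = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    wx = x * w[:, None]
    beta, *_ = np.linalg.lstsq(wx.T @ x, wx.T @ z, rcond=None)
    d, c = float(beta[0]), float(beta[1])
    rss = float(np.sum(w * (z - x @ beta) ** 2))
    p = float(norm.sf(d - c))
    return d, c, p, rss


def au_test(
    slm: SiteLogLikelihoodMatrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> AuTable:
    """AU p-value per candidate tree from the multiscale RELL bootstrap.

    Trees with BP identically 0 (never best) or 1 (always best) across all
    scales get p = 0 or 1 with the degenerate flag; everything else is
    fitted by the signed-distance/curvature regression.
    """
    if slm.n_trees < 2:
        raise InputError("AU test needs at least two candidate trees")
    scales_arr = np.asarray(scales, dtype=float)
    if scales_arr.size < 2:
        raise InputError("AU test needs at least two scales")
    rng = np.random.default_rng(seed)
    bp_all = np.vstack(
        [rell_bootstrap(slm, s, replicates=replicates, rng=rng) for s in scales_arr]
    ).T  # trees x scales
    results = []
    for i, label in enumerate(slm.labels):
        bp = bp_all[i]
        if np.all(bp >= 1.0):
            results.append(AuResult(label, bp, scales_arr, None, None, 1.0, True))
            continue
        if np.all(bp <= 0.0):
            results.append(AuResult(label, bp, scales_arr, None, None, 0.0, True))
            continue
        d, c, p, rss = _fit_au(bp, scales_arr, replicates)
        results.append(AuResult(label, bp, scales_arr, d, c, p, False, rss))
    return AuTable(results=results, replicates=replicates, seed=seed)


def dedup_slm(slm: SiteLogLikelihoodMatrix, atol: float = 1e-9) -> tuple[SiteLogLikelihoodMatrix, dict[str, str]]:
    """Collapse trees with (numerically) identical rows into one representative.

    Rooted variants of one unrooted topology share likelihoods, so the AU
    test cannot distinguish them; the returned mapping records which input
    label was merged into which representative.
    """
    keep: list[int] = []
    mapping: dict[str, str] = {}
    for i in range(slm.n_trees):
        for j in keep:
            if np.allclose(slm.loglik[i], slm.loglik[j], rtol=0.0, atol=atol):
                mapping[slm.labels[i]] = slm.labels[j]
                break
        else:
            keep.append(i)
            mapping[slm.labels[i]] = slm.labels[i]
    sub = SiteLogLikelihoodMatrix(
        labels=[slm.labels[i] for i in keep], loglik=slm.loglik[keep], weights=slm.weights
    )
    return sub, mapping
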