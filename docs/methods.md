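# Methods

This note documents the models and procedures `quartetmap` implements, the
defaults it commits to, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Supermatrix model and compilation rules

A supermatrix is a taxa × sites residue grid over a fixed alphabet (20
amino acids or 4 nucleotides) with an explicit missing-data mask and an
ordered, contiguous partition scheme (0-based half-open internally;
1-based inclusive in RAxML-style partition files, the convention of the
ecosystem these files come from). Every cell is either a definite residue
or masked: gaps, `?`, `X`/`N` and all partially ambiguous codes (B/Z/J for
amino acids, IUPAC degeneracies for nucleotides) are treated as missing.
This keeps mask semantics trivial; the likelihood engine would otherwise
need partial-ambiguity tip vectors for a case that is rare in practice.

The STRICT compilation rule keeps a gene partition only when **every**
taxon has at least one non-missing residue in it; the RELAXED rule keeps a
partition when every *required group* has at least one covered member.
"Covered" means ≥ 1 non-missing residue — presence/absence, not
full-length coverage; the threshold is a deliberate choice and both
filters are idempotent. Completeness diagnostics follow the AliStat
conventions: Ca (percent non-missing cells overall), Cr per taxon, and the
pairwise shared-coverage matrix.

Codon-position selection assumes the reading frame starts at position 1 of
each partition and requires partition lengths divisible by 3; no frame
inference is attempted.

## Substitution models and likelihood

Models are time-reversible: Q_ij = S_ij·π_j with symmetric exchangeability
matrix S, scaled to one expected substitution per unit time
(−Σ πᵢQᵢᵢ = 1). Built-ins are the equal-exchangeability (Poisson-class)
amino-acid model, JC and GTR for nucleotides; empirical amino-acid
matrices (LG, WAG, …) load from user-supplied PAML-format `.dat` files via
`SubstitutionModel.from_paml`. The package deliberately ships no empirical
matrix of its own: transcribing 190 published constants invites silent
error, while the PAML format is ubiquitous and trivially supplied. The
FcLM default is the Poisson model with +F frequencies estimated from the
matrix (Laplace-smoothed so no frequency is zero, which the
eigendecomposition requires); a single whole-matrix model is used rather
than per-partition models — per-partition model selection is out of scope,
and a model map can be passed explicitly where needed.

Rate heterogeneity uses Yang's discrete gamma with K equal-probability
categories (K = 4 when enabled); category means are computed exactly from
the regularized incomplete gamma function and average to 1. Site
likelihoods average the per-category likelihoods with equal weights.

Likelihoods use Felsenstein pruning with per-pattern rescaling at every
internal node; identical columns are collapsed into weighted patterns
first. Missing residues contribute all-ones tip partials
(marginalization). P(t) = exp(Qt) comes from the symmetric
eigendecomposition B = D^{1/2} Q D^{−1/2}, which also underlies the fast
4-taxon path: for a quartet, the per-pattern likelihood as a function of a
single branch length t is M·exp(λt) with M precomputable from the other
branches, so each evaluation inside the branch search is one
matrix–vector product. The fast path computes the same likelihood
function as the generic engine (tested to agree numerically).

Branch-length optimization is coordinate-wise bounded scalar search
(Brent, bounds [0, 10], initial length 0.1, `xatol` 1e−4–1e−5), cycled
until a full cycle improves log-likelihood by less than `tol`
(default 1e−6, at most 100 cycles). A candidate length is accepted only if
it improves the incumbent, so the log-likelihood is monotone by
construction; hitting the cycle limit sets a flag rather than raising.
Inside FcLM the per-quartet searches use `tol = 1e−4` and ≤ 30 cycles:
topology weights depend on log-likelihood *differences* that are orders of
magnitude larger, and on signal-poor quartets (e.g. permuted data) the
scalar search otherwise creeps by ~1e−5 per cycle indefinitely.

## FcLM conventions

With cluster order (c₁,c₂,c₃,c₄), the topology order is fixed as
T₁=(c₁,c₂)|(c₃,c₄), T₂=(c₁,c₃)|(c₂,c₄), T₃=(c₁,c₄)|(c₂,c₃). Weights are
normalized likelihoods (log-sum-exp), not posteriors with priors. The
seven simplex regions are implemented as the Voronoi partition generated
by the three vertices (cells 1–3), the three edge midpoints (cell 4 =
T₁/T₂, cell 5 = T₂/T₃, cell 6 = T₁/T₃) and the centroid (cell 7), with
ties broken toward the lowest cell index. The exact interior boundaries
used by other implementations are not published; the Voronoi construction
is this package's explicit, testable commitment (a dense grid sweep
produces exactly seven contiguous regions). Quartet drawing is exhaustive
when the group-size product is within the cap, otherwise a seeded uniform
subsample without replacement; quartets with zero jointly covered sites
are skipped and counted, never imputed.

## Permutation schemes

All schemes leave the missing-data mask untouched, so non-randomly
distributed data remains embodied in every permuted matrix. Scheme I
permutes each taxon's non-missing residues across its non-missing
positions matrix-wide (preserves lineage composition); scheme II does so
within each partition (additionally preserves per-taxon-per-partition
composition; with a single partition it coincides with scheme I);
scheme III permutes each column among the taxa covered there (preserves
per-site composition, destroys lineage composition). Seeding derives one
independent stream per taxon/column from the master seed, so results are
reproducible and order-independent. The diagnostic logic: support that
survives schemes I/II is explainable by compositional heterogeneity;
support surviving scheme III would implicate site-level composition. The
table helper flags a topology as "explainable by confounding" when its
original percentage does not exceed the best permuted percentage by more
than a stated margin (default 5 points).

## AU test

The RELL bootstrap resamples round(r·n) sites with replacement at each
scale r (default r ∈ {0.5, 0.6, …, 1.4}, 10 000 replicates per scale),
sums per-site log-likelihoods per tree and credits the argmax, splitting
exact ties equally. Bootstrap proportions are clipped to
[1/(2B), 1 − 1/(2B)] before the probit transform; the weighted
least-squares fit of z(r) = d√r + c/√r uses the binomial delta-method
weights B·φ(z)²/(BP(1−BP)). Trees with BP identically 0 or 1 across all
scales are reported as degenerate with p = 0 or 1 and no fit. RELL (no
re-optimization per replicate) is standard practice and the only
desk-scale option. Rooted variants of one unrooted topology have
identical site log-likelihoods, which likelihood cannot distinguish;
`dedup_slm` collapses such rows and reports the mapping so decisions can
be propagated back to all rooted candidates.

## Synthetic data

The simulator evolves sites independently down a guide tree: root state
from the root frequencies, branch transitions via exp(Qt), per-site
discrete-gamma rate multipliers when enabled. Non-stationarity is modelled
by switching the equilibrium frequencies at designated branches (exchange
rates held fixed) — the simplest generator of Bowker-detectable asymmetry.
Missingness combines whole taxon × partition dropout (transcriptome-style
gene absence) with per-cell noise. Identical seeds give byte-identical
output.

Two fixtures mirror the study design the package targets: a 59-taxon
amino-acid supermatrix with myriapod-style group sizes (16 Chilopoda,
10 Diplopoda, 1 Pauropoda, 3 Symphyla, 29 outgroup taxa; 480 one-per-group
quartets) simulated on a tree pairing Chilopoda+Diplopoda against
Pauropoda+Symphyla over a mandibulate-style backbone with ~10 gene
partitions, mild outgroup composition shifts and 15% gene dropout; and a
small four-cluster alignment (defaults: 3 taxa per cluster, 2000 sites,
internal branch 0.3, terminal branches 0.2, within-cluster branches 0.05)
used for quartet-mapping experiments — internal length 0 gives star-tree
data.

What the generator does **not** emulate: indels and alignment error,
codon structure and selection, among-site compositional heterogeneity,
mixture/CAT-style site profiles, data-set sizes near real supermatrices
(tests run at 10²–10⁴ sites). Passing tests therefore demonstrate that the
algorithms behave correctly under the stated generative assumptions, not
that any particular empirical data set is free of other artefacts.

## Problem sizes used in tests and the acceptance script

Calibration checks use 20-taxon, 3000-site nucleotide simulations
(190 Bowker pairs); FcLM recovery/destruction checks use the four-cluster
fixture at its defaults (81 quartets, 2000 sites); the AU decision-pattern
check uses a 2000-site quartet alignment with 10 scales; branch-length
recovery uses 10 000 sites; the pruning oracle enumerates internal states
on 100 random 4–5-taxon instances of 6 sites each. These sizes keep the
whole battery at a few minutes on one CPU while leaving wide margins on
every assertion.

## Known limitations

- Coordinate-wise branch search is robust but not Newton-fast; for trees
  much larger than quartets an analytic-derivative optimizer would be the
  next step.
- The AU fit follows the signed-distance/curvature regression; the full
  iterative maximum-likelihood refinement of the original procedure is not
  implemented (differences are far below the decision threshold in the
  regimes tested).
- Bowker's chi-square reference is asymptotic; on very sparse pairwise
  tables (short amino-acid alignments) the test is conservative.
- SRH scans are quadratic in taxa; the 59-taxon fixture (1711 pairs) runs
  in seconds, thousands of taxa would not.
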