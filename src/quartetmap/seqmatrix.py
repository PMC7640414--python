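"""Partitioned supermatrices: I/O, compilation filters, completeness diagnostics.

The central container is :class:`ResidueMatrix`, an aligned taxa x sites grid
over a fixed residue alphabet with an explicit missing-data mask and a
partition scheme recording gene boundaries.  On top of it sit the two
gene-coverage compilation rules used to build phylogenomic supermatrices —
the STRICT rule (keep a gene only if every taxon has data for it) and the
RELAXED rule (keep a gene if every required taxon group has at least one
member with data) — plus AliStat-style completeness scores (Ca overall,
Cr per taxon, pairwise shared coverage).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "AMINO_ACID",
    "NUCLEOTIDE",
    "PartitionScheme",
    "ResidueMatrix",
    "CoverageReport",
    "AlignmentError",
    "InputError",
    "read_fasta",
    "write_fasta",
    "read_group_map",
    "write_group_map",
    "read_partitions",
    "write_partitions",
    "concatenate",
    "filter_strict",
    "filter_relaxed",
    "select_codon_positions",
    "completeness",
    "subset_taxa",
]


class AlignmentError(ValueError):
    """Sequences that should be aligned are not (unequal lengths)."""


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class Alphabet:
    """Residue alphabet with a missing-data convention.

    Every symbol not in ``letters`` (after upper-casing) that appears in
    ``missing`` is masked; partially ambiguous codes (B/Z/J for amino acids,
    IUPAC degeneracies for nucleotides) are likewise treated as missing so a
    cell is always either a definite residue or masked.
    """

    def __init__(self, name: str, letters: str, missing: str, aliases: Mapping[str, str] | None = None):
        self.name = name
        self.letters = letters
        self.missing = missing
        self.aliases = dict(aliases or {})
        self.size = len(letters)
        # uint8 code per character; size == missing sentinel
        self._codes = np.full(256, 255, dtype=np.uint8)
        for i, ch in enumerate(letters):
            self._codes[ord(ch)] = i
            self._codes[ord(ch.lower())] = i
        for src, dst in self.aliases.items():
            self._codes[ord(src)] = letters.index(dst)
            self._codes[ord(src.lower())] = letters.index(dst)
        for ch in missing:
            self._codes[ord(ch)] = self.size
            self._codes[ord(ch.lower())] = self.size

    def encode(self, seq: str) -> np.ndarray:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = self._codes[arr]
        if np.any(codes == 255):
            bad = chr(arr[np.argmax(codes == 255)])
            raise InputError(f"symbol {bad!r} not in {self.name} alphabet")
        return codes

    def decode(self, codes: np.ndarray) -> str:
        table = self.letters + "-"
        return "".join(table[c] for c in codes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alphabet({self.name!r})"


AMINO_ACID = Alphabet(
    "aa",
    "ACDEFGHIKLMNPQRSTVWY",
    missing="-?XBZJ*.",
)
NUCLEOTIDE = Alphabet(
    "nt",
    "ACGT",
    missing="-?NRYSWKMBDHV.",
    aliases={"U": "T"},
)


@dataclasses.dataclass(frozen=True)
class PartitionScheme:
    """Ordered, contiguous, non-overlapping site ranges (0-based half-open)."""

    names: tuple[str, ...]
    bounds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.names) != len(self.bounds):
            raise InputError("partition names/bounds length mismatch")
        prev = 0
        for (a, b) in self.bounds:
            if a != prev or b <= a:
                raise InputError("partition ranges must be sorted, disjoint and contiguous")
            prev = b

    @classmethod
    def single(cls, n_sites: int, name: str = "all") -> "PartitionScheme":
        return cls((name,), ((0, n_sites),))

    @classmethod
    def from_lengths(cls, names: Sequence[str], lengths: Sequence[int]) -> "PartitionScheme":
        bounds, pos = [], 0
        for n in lengths:
            bounds.append((pos, pos + n))
            pos += n
        return cls(tuple(names), tuple(bounds))

    @property
    def n_sites(self) -> int:
        return self.bounds[-1][1] if self.bounds else 0

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.bounds))


@dataclasses.dataclass
class ResidueMatrix:
    """Aligned residue grid with missing-data mask and partition scheme.

    ``codes`` is a taxa x sites uint8 array; values ``0..alphabet.size-1``
    are residues and the sentinel ``alphabet.size`` marks a missing cell.
    """

    taxa: list[str]
    codes: np.ndarray
    alphabet: Alphabet
    partitions: PartitionScheme

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxon labels")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("codes shape does not match taxon list")
        if self.partitions.n_sites != self.codes.shape[1]:
            raise InputError("partition scheme does not cover all sites")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean taxa x sites array, True where the cell is missing."""
        return self.codes == self.alphabet.size

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.codes[self.taxa.index(taxon)]
        except ValueError:
            raise InputError(f"unknown taxon {taxon!r}") from None

    def sequence(self, taxon: str) -> str:
        return self.alphabet.decode(self.row(taxon))

    def copy(self) -> "ResidueMatrix":
        return ResidueMatrix(list(self.taxa), self.codes.copy(), self.alphabet, self.partitions)


@dataclasses.dataclass
class CoverageReport:
    """AliStat-style completeness summary (percent scales)."""

    ca: float
    cr: dict[str, float]
    pairwise_shared: np.ndarray
    taxa: list[str]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# Ca\t{self.ca:.4f}\n")
            fh.write("taxon\tCr\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                shared = "\t".join(f"{v:.4f}" for v in self.pairwise_shared[i])
                fh.write(f"{t}\t{self.cr[t]:.4f}\t{shared}\n")


# ---------------------------------------------------------------------------
# FASTA and sidecar formats

def read_fasta(path: str | Path, alphabet: Alphabet = AMINO_ACID) -> ResidueMatrix:
    """Read an aligned FASTA file into a :class:`ResidueMatrix`.

    Gap and ambiguity symbols are masked; residues are upper-cased on encode.
    Raises :class:`AlignmentError` for unequal sequence lengths and
    :class:`InputError` for duplicate labels or an empty file.
    """
    labels: list[str] = []
    chunks: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                labels.append(line[1:].split()[0])
                chunks.append([])
            else:
                if not labels:
                    raise InputError("FASTA data before first header")
                chunks[-1].append(line)
    if not labels:
        raise InputError(f"no sequences in {path}")
    seqs = ["".join(c) for c in chunks]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate sequence labels in {path}")
    codes = np.vstack([alphabet.encode(s) for s in seqs])
    return ResidueMatrix(labels, codes, alphabet, PartitionScheme.single(codes.shape[1]))


def write_fasta(matrix: ResidueMatrix, path: str | Path, width: int = 0) -> None:
    """Write FASTA; missing cells are written as ``-`` (canonical form)."""
    with open(path, "w") as fh:
        for i, taxon in enumerate(matrix.taxa):
            seq = matrix.alphabet.decode(matrix.codes[i])
            fh.write(f">{taxon}\n")
            if width > 0:
                for j in range(0, len(seq), width):
                    fh.write(seq[j : j + width] + "\n")
            else:
                fh.write(seq + "\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (taxon, group) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, group = line.split("\t")[:2]
            if taxon in out:
                raise InputError(f"taxon {taxon!r} mapped to more than one group")
            out[taxon] = group
    return out


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, group in group_map.items():
            fh.write(f"{taxon}\t{group}\n")


_PARTITION_RE = re.compile(r"^\s*(?:(?P<model>[\w+.]+)\s*,)?\s*(?P<name>\S+)\s*=\s*(?P<lo>\d+)\s*-\s*(?P<hi>\d+)\s*$")


def read_partitions(path: str | Path) -> PartitionScheme:
    """RAxML-style partition file ("WAG, gene1 = 1-95797"); 1-based inclusive."""
    names, bounds = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _PARTITION_RE.match(line)
            if not m:
                raise InputError(f"cannot parse partition line: {line!r}")
            names.append(m.group("name"))
            bounds.append((int(m.group("lo")) - 1, int(m.group("hi"))))
    return PartitionScheme(tuple(names), tuple(bounds))


def write_partitions(scheme: PartitionScheme, path: str | Path, model: str = "WAG") -> None:
    with open(path, "w") as fh:
        for name, (a, b) in scheme:
            fh.write(f"{model}, {name} = {a + 1}-{b}\n")


# ---------------------------------------------------------------------------
# Supermatrix compilation

def concatenate(per_gene: Sequence[ResidueMatrix], names: Sequence[str] | None = None) -> ResidueMatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    The taxon set is the union over genes (first-seen order); taxon x gene
    blocks absent from a gene are filled as missing.
    """
    if not per_gene:
        raise InputError("no gene matrices to concatenate")
    alphabet = per_gene[0].alphabet
    if any(g.alphabet.name != alphabet.name for g in per_gene):
        raise InputError("mixed alphabets in concatenation")
    taxa: list[str] = []
    for g in per_gene:
        for t in g.taxa:
            if t not in taxa:
                taxa.append(t)
    index = {t: i for i, t in enumerate(taxa)}
    lengths = [g.n_sites for g in per_gene]
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(per_gene))]
    codes = np.full((len(taxa), sum(lengths)), alphabet.size, dtype=np.uint8)
    pos = 0
    for g in per_gene:
        rows = [index[t] for t in g.taxa]
        codes[rows, pos : pos + g.n_sites] = g.codes
        pos += g.n_sites
    scheme = PartitionScheme.from_lengths(tuple(names), lengths)
    return ResidueMatrix(taxa, codes, alphabet, scheme)


def _keep_partitions(matrix: ResidueMatrix, keep: Sequence[int]) -> ResidueMatrix:
    names, lengths, blocks = [], [], []
    for k in keep:
        a, b = matrix.partitions.bounds[k]
        names.append(matrix.partitions.names[k])
        lengths.append(b - a)
        blocks.append(matrix.codes[:, a:b])
    codes = np.hstack(blocks) if blocks else np.empty((matrix.n_taxa, 0), dtype=np.uint8)
    scheme = PartitionScheme.from_lengths(tuple(names), lengths) if names else PartitionScheme((), ())
    return ResidueMatrix(list(matrix.taxa), codes, matrix.alphabet, scheme)


def filter_strict(matrix: ResidueMatrix) -> ResidueMatrix:
    """STRICT rule: keep partitions where every taxon has >=1 non-missing residue."""
    present = ~matrix.mask
    keep = []
    for k, (a, b) in enumerate(matrix.partitions.bounds):
        if present[:, a:b].any(axis=1).all():
            keep.append(k)
    return _keep_partitions(matrix, keep)


def filter_relaxed(
    matrix: ResidueMatrix,
    group_map: Mapping[str, str],
    required_groups: Iterable[str],
) -> ResidueMatrix:
    """RELAXED rule: keep partitions where each required group has >=1 covered member."""
    required = list(required_groups)
    members: dict[str, list[int]] = {g: [] for g in required}
    mapped_groups = set(group_map.values())
    for g in required:
        if g not in mapped_groups:
            raise InputError(f"required group {g!r} absent from group map")
    for i, t in enumerate(matrix.taxa):
        g = group_map.get(t)
        if g in members:
            members[g].append(i)
    for g in required:
        if not members[g]:
            raise InputError(f"required group {g!r} has no taxa in the matrix")
    present = ~matrix.mask
    keep = []
    for k, (a, b) in enumerate(matrix.partitions.bounds):
        block = present[:, a:b]
        if all(block[members[g]].any() for g in required):
            keep.append(k)
    return _keep_partitions(matrix, keep)


def select_codon_positions(matrix: ResidueMatrix, positions: Iterable[int]) -> ResidueMatrix:
    """Keep the requested within-codon positions (1, 2 and/or 3) per partition.

    The reading frame restarts at each partition boundary; every partition
    length must be divisible by 3.
    """
    if matrix.alphabet.name != "nt":
        raise InputError("codon-position selection requires a nucleotide matrix")
    pos = sorted(set(positions))
    if not pos or any(p not in (1, 2, 3) for p in pos):
        raise InputError("positions must be a nonempty subset of {1,2,3}")
    names, lengths, cols = [], [], []
    for name, (a, b) in matrix.partitions:
        if (b - a) % 3 != 0:
            raise InputError(f"partition {name!r} length {b - a} not divisible by 3")
        idx = np.concatenate([np.arange(a + p - 1, b, 3) for p in pos])
        idx.sort()
        names.append(name)
        lengths.append(idx.size)
        cols.append(idx)
    codes = matrix.codes[:, np.concatenate(cols)] if cols else matrix.codes[:, :0]
    scheme = PartitionScheme.from_lengths(tuple(names), lengths)
    return ResidueMatrix(list(matrix.taxa), codes, matrix.alphabet, scheme)


def completeness(matrix: ResidueMatrix) -> CoverageReport:
    """Ca / Cr completeness scores and the pairwise shared-coverage matrix."""
    if matrix.n_sites == 0 or matrix.n_taxa == 0:
        raise InputError("completeness undefined for an empty matrix")
    present = ~matrix.mask
    ca = 100.0 * present.mean()
    cr = {t: 100.0 * present[i].mean() for i, t in enumerate(matrix.taxa)}
    p = present.astype(np.float64)
    shared = (p @ p.T) / matrix.n_sites
    return CoverageReport(ca=ca, cr=cr, pairwise_shared=shared, taxa=list(matrix.taxa))


def subset_taxa(matrix: ResidueMatrix, taxa: Sequence[str]) -> ResidueMatrix:
    """Row-restrict to the given taxa; sites and partitions are untouched."""
    rows = []
    for t in taxa:
        if t not in matrix.taxa:
            raise InputError(f"unknown taxon {t!r}")
        rows.append(matrix.taxa.index(t))
    return ResidueMatrix(list(taxa), matrix.codes[rows].copy(), matrix.alphabet, matrix.partitions)
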