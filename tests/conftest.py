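import numpy as np
import pytest

from quartetmap import AMINO_ACID, NUCLEOTIDE, PartitionScheme, ResidueMatrix


def matrix_from(seqs: dict[str, str], alphabet=AMINO_ACID, lengths=None) -> ResidueMatrix:
    """Build a ResidueMatrix from {taxon: sequence} strings."""
    taxa = list(seqs)
    codes = np.vstack([alphabet.encode(seqs[t]) for t in taxa])
    if lengths is None:
        scheme = PartitionScheme.single(codes.shape[1])
    else:
        scheme = PartitionScheme.from_lengths(
            [f"g{i + 1}" for i in range(len(lengths))], lengths
        )
    return ResidueMatrix(taxa, codes, alphabet, scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_matrix(rng, n_taxa=6, n_sites=40, alphabet=NUCLEOTIDE, missing_prob=0.2, lengths=None):
    k = alphabet.size
    codes = rng.integers(0, k, size=(n_taxa, n_sites)).astype(np.uint8)
    codes[rng.random(codes.shape) < missing_prob] = k
    taxa = [f"t{i}" for i in range(n_taxa)]
    scheme = (
        PartitionScheme.single(n_sites)
        if lengths is None
        else PartitionScheme.from_lengths([f"g{i}" for i in range(len(lengths))], lengths)
    )
    return ResidueMatrix(taxa, codes, alphabet, scheme)
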