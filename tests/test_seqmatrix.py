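"""Supermatrix container, compilation filters and completeness diagnostics."""

import numpy as np
import pytest

from quartetmap import (
    AMINO_ACID,
    NUCLEOTIDE,
    AlignmentError,
    InputError,
    PartitionScheme,
    ResidueMatrix,
    completeness,
    concatenate,
    filter_relaxed,
    filter_strict,
    read_fasta,
    read_group_map,
    read_partitions,
    select_codon_positions,
    subset_taxa,
    write_fasta,
    write_group_map,
    write_partitions,
)
from conftest import matrix_from, random_matrix


class TestFastaIO:
    def test_mask_applied_to_gap_and_ambiguity_symbols(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nMK-\n>b\nMKX\n")
        m = read_fasta(p, AMINO_ACID)
        assert m.taxa == ["a", "b"]
        assert m.n_sites == 3
        assert m.mask.tolist() == [[False, False, True], [False, False, True]]

    def test_residues_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nmkl\n")
        assert read_fasta(p, AMINO_ACID).sequence("a") == "MKL"

    @pytest.mark.parametrize(
        "content,exc",
        [
            (">a\nMK\n>b\nMKL\n", AlignmentError),
            (">a\nMK\n>a\nML\n", InputError),
            ("", InputError),
        ],
    )
    def test_malformed_input_rejected(self, tmp_path, content, exc):
        p = tmp_path / "bad.fa"
        p.write_text(content)
        with pytest.raises(exc):
            read_fasta(p)

    def test_round_trip_byte_identical_for_canonical_input(self, tmp_path, rng):
        m = random_matrix(rng, n_taxa=5, n_sites=30, alphabet=AMINO_ACID)
        p1, p2 = tmp_path / "one.fa", tmp_path / "two.fa"
        write_fasta(m, p1)
        write_fasta(read_fasta(p1, AMINO_ACID), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPartitionScheme:
    def test_raxml_round_trip_one_based_inclusive(self, tmp_path):
        scheme = PartitionScheme.from_lengths(["g1", "g2"], [5, 3])
        p = tmp_path / "parts.txt"
        write_partitions(scheme, p)
        text = p.read_text()
        assert "g1 = 1-5" in text and "g2 = 6-8" in text
        assert read_partitions(p) == scheme

    def test_non_contiguous_ranges_rejected(self):
        with pytest.raises(InputError):
            PartitionScheme(("a", "b"), ((0, 5), (6, 8)))


class TestConcatenate:
    def test_union_of_taxa_with_missing_blocks(self):
        g1 = matrix_from({"a": "MKLLE", "b": "MKLIE"})
        g2 = matrix_from({"b": "WWC", "c": "WYC"})
        m = concatenate([g1, g2])
        assert m.taxa == ["a", "b", "c"]
        assert m.n_sites == 8
        assert m.mask[0, 5:8].all() and m.mask[2, 0:5].all()
        assert not m.mask[1].any()
        assert m.partitions.bounds == ((0, 5), (5, 8))

    def test_single_gene_is_identity_up_to_partition_name(self):
        g = matrix_from({"a": "MKL", "b": "MKI"})
        m = concatenate([g])
        assert m.taxa == g.taxa and np.array_equal(m.codes, g.codes)

    def test_conserves_total_non_missing_cells(self, rng):
        genes = [random_matrix(rng, n_taxa=rng.integers(2, 6), n_sites=rng.integers(3, 12)) for _ in range(10)]
        for i, g in enumerate(genes):
            g.taxa = [f"t{j}" for j in rng.choice(10, size=g.n_taxa, replace=False)]
        m = concatenate(genes)
        assert (~m.mask).sum() == sum((~g.mask).sum() for g in genes)


class TestCoverageFilters:
    def test_strict_drops_gene_lacking_a_taxon(self):
        g1 = matrix_from({"a": "MK", "b": "MK", "c": "MK"})
        g2 = matrix_from({"a": "WW", "b": "WY"})
        g3 = matrix_from({"a": "CC", "b": "CC", "c": "CC"})
        m = concatenate([g1, g2, g3])
        out = filter_strict(m)
        assert out.partitions.names == ("gene1", "gene3")
        assert out.n_sites == 4

    def test_strict_identity_without_missing_data(self, rng):
        m = random_matrix(rng, missing_prob=0.0, lengths=[10, 10, 20])
        out = filter_strict(m)
        assert np.array_equal(out.codes, m.codes)

    def test_strict_matches_brute_force_and_is_idempotent(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_taxa=5, n_sites=30, missing_prob=0.5, lengths=[6, 6, 6, 6, 6])
            expected = [
                name
                for name, (a, b) in m.partitions
                if all((~m.mask[i, a:b]).any() for i in range(m.n_taxa))
            ]
            out = filter_strict(m)
            assert list(out.partitions.names) == expected
            again = filter_strict(out)
            assert np.array_equal(again.codes, out.codes)

    def test_relaxed_requires_each_group_covered(self):
        gmap = {"c1": "Chil", "c2": "Chil", "c3": "Chil", "p1": "Paur"}
        gene = matrix_from({"c1": "MK", "c2": "--", "c3": "--", "p1": "--"})
        m = concatenate([gene])
        out = filter_relaxed(m, gmap, ["Chil", "Paur"])
        assert len(out.partitions) == 0  # pauropod absent -> dropped

    def test_relaxed_vacuous_requirement_keeps_everything(self, rng):
        m = random_matrix(rng, lengths=[20, 20])
        out = filter_relaxed(m, {t: "G" for t in m.taxa}, [])
        assert out.partitions.names == m.partitions.names

    def test_relaxed_unknown_group_is_configuration_error(self, rng):
        m = random_matrix(rng)
        with pytest.raises(InputError):
            filter_relaxed(m, {t: "G" for t in m.taxa}, ["Nope"])

    def test_relaxed_matches_brute_force(self, rng):
        groups = ["G1", "G2", "G3", "G4"]
        for _ in range(10):
            m = random_matrix(rng, n_taxa=8, n_sites=30, missing_prob=0.6, lengths=[10, 10, 10])
            gmap = {t: groups[i % 4] for i, t in enumerate(m.taxa)}
            out = filter_relaxed(m, gmap, groups)
            expected = []
            for name, (a, b) in m.partitions:
                ok = all(
                    any((~m.mask[i, a:b]).any() for i, t in enumerate(m.taxa) if gmap[t] == g)
                    for g in groups
                )
                if ok:
                    expected.append(name)
            assert list(out.partitions.names) == expected


class TestCodonPositions:
    def test_second_positions_of_nine_site_gene(self):
        m = matrix_from({"a": "ACGTACGTA"}, NUCLEOTIDE)
        out = select_codon_positions(m, {2})
        assert out.sequence("a") == "CAT"  # 0-based sites 1, 4, 7

    def test_all_positions_is_identity(self, rng):
        m = random_matrix(rng, n_sites=12, lengths=[6, 6])
        out = select_codon_positions(m, {1, 2, 3})
        assert np.array_equal(out.codes, m.codes)

    def test_frame_restarts_at_partition_boundary(self):
        m = matrix_from({"a": "ACGTACACGTACGTA"}, NUCLEOTIDE, lengths=[6, 9])
        out = select_codon_positions(m, {2})
        assert out.partitions.bounds == ((0, 2), (2, 5))
        assert out.sequence("a") == "CA" + "CAT"

    def test_positions_partition_the_sites_exactly(self, rng):
        m = random_matrix(rng, n_sites=18, lengths=[9, 9])
        sub = [select_codon_positions(m, {p}) for p in (1, 2, 3)]
        assert sum(s.n_sites for s in sub) == m.n_sites
        pooled = np.sort(np.concatenate([s.codes[0] for s in sub]))
        assert np.array_equal(pooled, np.sort(m.codes[0]))

    def test_frame_error_when_not_divisible_by_three(self):
        m = matrix_from({"a": "ACGTA"}, NUCLEOTIDE)
        with pytest.raises(InputError):
            select_codon_positions(m, {2})


class TestCompleteness:
    def test_full_matrix_scores_100(self):
        m = matrix_from({"a": "MKL", "b": "MKI"})
        rep = completeness(m)
        assert rep.ca == 100.0
        assert np.allclose(rep.pairwise_shared, 1.0)

    def test_half_missing_row(self):
        m = matrix_from({"a": "MKLMKLMKLM", "b": "MKLMK-----"})
        rep = completeness(m)
        assert rep.cr["b"] == 50.0
        assert rep.ca == 75.0
        assert rep.pairwise_shared[0, 1] == 0.5

    def test_matches_brute_force_counts_and_mean_identity(self, rng):
        m = random_matrix(rng, n_taxa=7, n_sites=50, missing_prob=0.3)
        rep = completeness(m)
        present = ~m.mask
        assert rep.ca == pytest.approx(100 * present.sum() / present.size)
        assert rep.ca == pytest.approx(np.mean(list(rep.cr.values())))
        i, j = 2, 5
        assert rep.pairwise_shared[i, j] == pytest.approx(
            (present[i] & present[j]).mean()
        )
        assert np.allclose(rep.pairwise_shared, rep.pairwise_shared.T)


class TestSubsetTaxa:
    def test_identity_and_row_restriction(self, rng):
        m = random_matrix(rng, n_taxa=6)
        same = subset_taxa(m, m.taxa)
        assert np.array_equal(same.codes, m.codes)
        sub = subset_taxa(m, m.taxa[:3])
        assert sub.n_taxa == 3 and sub.n_sites == m.n_sites
        assert sub.partitions == m.partitions

    def test_per_taxon_composition_unchanged(self, rng):
        m = random_matrix(rng)
        sub = subset_taxa(m, [m.taxa[4], m.taxa[1]])
        for t in sub.taxa:
            assert np.array_equal(np.sort(sub.row(t)), np.sort(m.row(t)))

    def test_unknown_taxon_rejected(self, rng):
        with pytest.raises(InputError):
            subset_taxa(random_matrix(rng), ["nope"])


def test_group_map_round_trip_and_duplicate_detection(tmp_path):
    gm = {"a": "Chilopoda", "b": "Diplopoda"}
    p = tmp_path / "groups.tsv"
    write_group_map(gm, p)
    assert read_group_map(p) == gm
    p.write_text("a\tChilopoda\na\tDiplopoda\n")
    with pytest.raises(InputError):
        read_group_map(p)
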