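"""Canonical k-mers, signatures, read counting and the reference index."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import popseq as pq
from popseq.kmer_index import decode_kmers, encode_kmer, kmer_space_size
from conftest import brute_canonical, brute_count, brute_signature, revcomp


class TestCanonicalize:
    @pytest.mark.parametrize(
        "kmer,expected", [("GT", "AC"), ("AT", "AT"), ("ACGT", "ACGT"), ("TTTT", "AAAA")]
    )
    def test_examples(self, kmer, expected):
        assert pq.canonicalize(kmer) == expected

    def test_rejects_invalid_characters(self):
        with pytest.raises(ValueError):
            pq.canonicalize("ACGN")

    def test_all_5mers_strand_invariant_and_idempotent(self):
        """Brute-force enumeration of all 4^5 5-mers."""
        for p in product("ACGT", repeat=5):
            x = "".join(p)
            c = pq.canonicalize(x)
            assert c == brute_canonical(x)
            assert c == pq.canonicalize(revcomp(x))
            assert pq.canonicalize(c) == c


class TestBuildSignature:
    def test_repeated_window(self):
        sig = pq.build_signature(pq.GenomeRecord("g", "AAAA"), k=3)
        assert sig.kmers == {"AAA"} and len(sig) == 1

    def test_vector_space_sizing(self):
        assert kmer_space_size(12) == 4**12 >= 16_000_000

    def test_short_sequence_gives_empty_signature(self, caplog):
        sig = pq.build_signature(pq.GenomeRecord("g", "ACG"), k=12)
        assert len(sig) == 0

    def test_matches_window_scan_oracle(self, small_genome):
        sig = pq.build_signature(small_genome, k=12)
        assert sig.kmers == brute_signature(small_genome.sequence, 12)

    def test_concatenation_with_spacer_is_union(self):
        """An N spacer of length k isolates the parts: signature = union."""
        a = pq.generate_genome(300, seed=1).sequence
        b = pq.generate_genome(300, seed=2).sequence
        k = 8
        union = brute_signature(a, k) | brute_signature(b, k)
        spaced = brute_signature(a + "N" * k + b, k)
        assert spaced == union
        # and the implementation agrees on the windowed-count side
        ms = pq.count_read_kmers([a, b], k=k)
        assert set(ms.counts()) == union


class TestCountReadKmers:
    def test_single_read_window_count(self):
        ms = pq.count_read_kmers(["AAAA"], k=2)
        assert ms.counts() == {"AA": (3, 3, 0)}

    def test_palindromic_read_counts_both_as_forward(self):
        ms = pq.count_read_kmers(["ACGT", "ACGT"], k=4)
        assert ms.counts() == {"ACGT": (2, 2, 0)}

    def test_orientation_tallies(self):
        # GT reads canonically as AC in reverse orientation
        ms = pq.count_read_kmers(["GT", "AC"], k=2)
        assert ms.counts() == {"AC": (2, 1, 1)}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(30)]
        ms = pq.count_read_kmers(seqs, k=5)
        assert ms.counts() == brute_count(seqs, 5)
        assert ms.n_kmers_total == sum(v[0] for v in brute_count(seqs, 5).values())

    def test_error_free_reads_stay_inside_signature(self):
        g = pq.generate_genome(3_000, seed=9, genome_id="G")
        cfg = pq.ReadSimConfig(
            read_length=80, coverage=5.0, error_rate=0.0, proportions={"G": 1.0}, seed=10
        )
        ms = pq.count_read_kmers(pq.simulate_reads([g], cfg), k=12)
        sig = pq.build_signature(g, k=12)
        assert all(code in sig for code in ms.codes)

    def test_strand_invariance(self):
        """Reverse-complementing every read preserves totals, swaps orientations."""
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(20)]
        fwd = pq.count_read_kmers(seqs, k=7)
        rev = pq.count_read_kmers([revcomp(s) for s in seqs], k=7)
        assert np.array_equal(fwd.codes, rev.codes)
        assert np.array_equal(fwd.totals, rev.totals)
        # windows that read forward in one direction read reverse in the other,
        # except palindromes which always read forward
        from popseq.kmer_index import revcomp_codes

        is_pal = fwd.codes == revcomp_codes(fwd.codes, 7)
        assert np.array_equal(fwd.as_forward[~is_pal], rev.as_reverse[~is_pal])
        assert np.array_equal(fwd.as_forward[is_pal], rev.as_forward[is_pal])

    def test_windows_with_n_are_skipped(self):
        ms = pq.count_read_kmers(["AANAA"], k=2)
        assert ms.counts() == {"AA": (2, 2, 0)}

    def test_unreadable_fastq_raises(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\nMALFORMED\nIIII\n")
        with pytest.raises(ValueError, match="FASTQ"):
            pq.count_read_kmers(str(bad), k=2)

    def test_fastq_roundtrip(self, tmp_path):
        g = pq.generate_genome(500, seed=2, genome_id="G")
        cfg = pq.ReadSimConfig(
            read_length=60, coverage=3.0, error_rate=0.01, proportions={"G": 1.0}, seed=3
        )
        reads = pq.simulate_reads([g], cfg)
        path = tmp_path / "reads.fastq"
        pq.write_fastq(reads, path)
        from_file = pq.count_read_kmers(str(path), k=9)
        in_memory = pq.count_read_kmers(reads, k=9)
        assert from_file.counts() == in_memory.counts()


class TestReferenceIndex:
    def test_singleton_inverted_map(self):
        g = pq.generate_genome(200, seed=1, genome_id="g1")
        idx = pq.build_reference_index([g], {"g1": "root;g1"}, k=8)
        for kmer, gids in idx.inverted.items():
            assert gids == {"g1"}
        assert set(idx.inverted) == pq.build_signature(g, 8).kmers

    def test_identical_genomes_share_every_kmer(self):
        g = pq.generate_genome(200, seed=1, genome_id="a")
        h = pq.GenomeRecord("b", g.sequence)
        idx = pq.build_reference_index([g, h], {"a": "r;a", "b": "r;b"}, k=8)
        assert all(v == {"a", "b"} for v in idx.inverted.values())

    def test_transpose_consistency_small_k(self):
        genomes = [pq.generate_genome(100, seed=s, genome_id=f"g{s}") for s in (1, 2)]
        idx = pq.build_reference_index(
            genomes, {"g1": "r;g1", "g2": "r;g2"}, k=4
        )
        for sig in idx.signatures:
            for kmer in sig.kmers:
                assert sig.genome_id in idx.inverted[kmer]
        for kmer, gids in idx.inverted.items():
            for gid in gids:
                assert kmer in idx.get_signature(gid).kmers

    def test_membership_oracle_on_sampled_kmers(self):
        rng = np.random.default_rng(5)
        genomes = [pq.generate_genome(10_000, seed=s, genome_id=f"g{s}") for s in (1, 2, 3)]
        idx = pq.build_reference_index(
            genomes, {f"g{s}": f"r;g{s}" for s in (1, 2, 3)}, k=12
        )
        brute = {g.genome_id: brute_signature(g.sequence, 12) for g in genomes}
        pool = sorted(set().union(*brute.values()))
        for kmer in rng.choice(pool, size=100, replace=False):
            expected = {gid for gid, sig in brute.items() if kmer in sig}
            assert idx.genomes_with(str(kmer)) == expected

    def test_missing_lineage_row_raises(self):
        g = pq.generate_genome(100, seed=1, genome_id="g1")
        with pytest.raises(KeyError, match="g1"):
            pq.build_reference_index([g], {}, k=8)

    def test_empty_genome_list_raises(self):
        with pytest.raises(ValueError):
            pq.build_reference_index([], {}, k=8)

    def test_save_load_roundtrip(self, tmp_path, trio_index):
        path = tmp_path / "index.psq"
        trio_index.save(path)
        loaded = pq.ReferenceIndex.load(path)
        assert loaded.k == trio_index.k
        assert loaded.genome_ids == trio_index.genome_ids
        for a, b in zip(loaded.signatures, trio_index.signatures):
            assert np.array_equal(a.codes, b.codes)
        assert loaded.lineages == trio_index.lineages


class TestFastaIO:
    def test_folded_fasta_roundtrip(self, tmp_path):
        genomes = [pq.generate_genome(250, seed=s, genome_id=f"g{s}") for s in (1, 2)]
        path = tmp_path / "refs.fasta"
        pq.write_fasta(genomes, path, width=60)
        loaded = pq.read_fasta(path)
        assert [(g.genome_id, g.sequence) for g in loaded] == [
            (g.genome_id, g.sequence) for g in genomes
        ]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=6, max_size=40))
def test_signature_property_matches_oracle(seq):
    sig = pq.build_signature(pq.GenomeRecord("g", seq), k=6)
    assert sig.kmers == brute_signature(seq, 6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=4, max_size=20))
def test_encode_decode_roundtrip(kmer):
    assert decode_kmers([encode_kmer(kmer)], len(kmer)) == [kmer]
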