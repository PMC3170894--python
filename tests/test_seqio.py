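"""Sequence IO, translation, frame selection, identity clustering, Newick."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haloadapt import seqio
from haloadapt.phylo import bipartitions
from .conftest import random_tree

ids = st.text(alphabet="abcdefgh123", min_size=1, max_size=8)
nt_seqs = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestFasta:
    def test_parse_and_alphabet_inference(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>p\nMKDE\n")
        records = seqio.read_fasta(p)
        assert [r.id for r in records] == ["a", "p"]
        # K/D/E force the whole file to aa
        assert all(r.alphabet == "aa" for r in records)
        p2 = tmp_path / "y.fasta"
        p2.write_text(">a\nACGT\n")
        assert seqio.read_fasta(p2)[0].alphabet == "nt"

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nACGT\n>x\nACGA\n")
        with pytest.raises(ValueError, match="x"):
            seqio.read_fasta(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            seqio.read_fasta(p)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(ids, nt_seqs), min_size=1, max_size=6,
                    unique_by=lambda t: t[0]))
    def test_roundtrip(self, tmp_path_factory, pairs):
        records = [seqio.SequenceRecord(i, s, "nt") for i, s in pairs]
        path = tmp_path_factory.mktemp("fa") / "rt.fasta"
        seqio.write_fasta(records, path)
        back = seqio.read_fasta(path, alphabet="nt")
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]

    def test_group_table_attach(self, tmp_path):
        fa = tmp_path / "g.fasta"
        fa.write_text(">s1\nACGT\n>s2\nAAAA\n")
        gt = tmp_path / "groups.tsv"
        gt.write_text("id\tgroup\tclade\tseason\ns1\ttirez\tDesulfobacteraceae\twinter\n")
        records = seqio.read_fasta(fa, group_table=gt)
        assert records[0].group == "tirez"
        assert records[0].season == "winter"
        assert records[1].group is None


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,frame,expected",
        [
            ("ATGGCC", 1, "MA"),
            ("ATGTAA", 1, "M*"),
            ("ATGGCC", -1, "GH"),  # revcomp GGCCAT
            ("ATGGCCA", 1, "MA"),  # trailing incomplete codon dropped
            ("ATGNCC", 1, "MX"),   # N-containing codon
        ],
    )
    def test_examples(self, nt, frame, expected):
        assert seqio.translate(nt, frame) == expected

    def test_bad_frame(self):
        with pytest.raises(ValueError):
            seqio.translate("ATGGCC", 4)

    def test_too_short(self):
        with pytest.raises(ValueError):
            seqio.translate("ATG", 2)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=9, max_size=50))
    def test_frames_cover_every_codon(self, nt):
        """The three frames of each strand partition that strand's codons."""
        for frames in ((1, 2, 3), (-1, -2, -3)):
            n_codons = sum(len(seqio.translate(nt, f)) for f in frames)
            assert n_codons == sum((len(nt) - off) // 3 for off in range(3))


class TestBestFrame:
    def test_clean_orf_beats_stopped_frames(self):
        # frame +1 is a clean ORF; the exhaustive six-frame oracle agrees
        clean = "ATGGAAGAAGAAGAATAG"  # M E E E E * (terminal stop not internal)
        frame, aa, stops = seqio.best_frame(clean)
        oracle = {f: seqio.translate(clean, f)[:-1].count("*") for f in seqio.FRAMES}
        assert stops == min(oracle.values())
        assert frame == next(f for f in seqio.FRAMES if oracle[f] == stops)
        assert (frame, stops) == (1, 0)

    def test_stop_free_frame_one(self):
        assert seqio.best_frame("ATGGCCGAA") == (1, "MAE", 0)

    def test_all_frames_stopped_flags_minimum(self):
        # >= 1 internal stop in every frame; check against the exhaustive oracle
        seq = "TGATACGACATGATTAGCCAATCATATTAT"
        frame, aa, stops = seqio.best_frame(seq)
        oracle = {f: seqio.translate(seq, f)[:-1].count("*") for f in seqio.FRAMES}
        best_count = min(oracle.values())
        assert best_count > 0
        assert stops == best_count
        assert frame == next(f for f in seqio.FRAMES if oracle[f] == best_count)


class TestIdentityClustering:
    def test_identical_pair_merges_at_full_identity(self):
        # mirrors redundant phylotypes collapsing at 100% identity
        records = [seqio.SequenceRecord("aps_cw1", "ACGTACGT", "nt"),
                   seqio.SequenceRecord("aps_cw16", "ACGTACGT", "nt")]
        clusters = seqio.greedy_identity_cluster(records, 1.0)
        assert len(clusters) == 1
        assert clusters[0].representative.id == "aps_cw1"

    def test_disjoint_sequences_stay_apart(self):
        records = [seqio.SequenceRecord("a", "AAAA", "nt"),
                   seqio.SequenceRecord("b", "TTTT", "nt")]
        assert len(seqio.greedy_identity_cluster(records, 0.9)) == 2

    def test_ninety_percent_identity_boundary(self):
        records = [seqio.SequenceRecord("a", "AAAAAAAAAA", "nt"),
                   seqio.SequenceRecord("b", "AAAAAAAAAT", "nt")]
        assert seqio.pairwise_identity("AAAAAAAAAA", "AAAAAAAAAT") == pytest.approx(0.9)
        assert len(seqio.greedy_identity_cluster(records, 0.9)) == 1
        assert len(seqio.greedy_identity_cluster(records, 0.95)) == 2

    @pytest.mark.parametrize("threshold", [0.0, -0.5, 1.5])
    def test_bad_threshold(self, threshold):
        with pytest.raises(ValueError):
            seqio.greedy_identity_cluster(
                [seqio.SequenceRecord("a", "ACGT", "nt")], threshold)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6),
                    min_size=1, max_size=8))
    def test_full_identity_equals_deduplication(self, seqs):
        records = [seqio.SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(seqs)]
        clusters = seqio.greedy_identity_cluster(records, 1.0)
        assert {c.representative.seq for c in clusters} == set(seqs)
        assert len(clusters) == len(set(seqs))


class TestNewick:
    def test_three_leaf_star(self, tmp_path):
        tns = dendropy.TaxonNamespace(["A", "B", "C"])
        tree = dendropy.Tree(taxon_namespace=tns)
        for lab in ["A", "B", "C"]:
            nd = dendropy.Node(taxon=tns.get_taxon(lab))
            nd.edge.length = 1.0
            tree.seed_node.add_child(nd)
        path = tmp_path / "star.nwk"
        seqio.write_newick(tree, path)
        text = path.read_text()
        assert "A:1" in text and text.strip().endswith(";")

    def test_roundtrip_preserves_bipartitions_and_lengths(self, tmp_path, rng):
        tree = random_tree(8, rng)
        path = tmp_path / "t.nwk"
        seqio.write_newick(tree, path)
        back = seqio.read_newick(path)
        assert bipartitions(back) == bipartitions(tree)
        orig = {frozenset(l.taxon.label for l in nd.leaf_iter()): nd.edge.length
                for nd in tree.preorder_node_iter() if nd.parent_node}
        after = {frozenset(l.taxon.label for l in nd.leaf_iter()): nd.edge.length
                 for nd in back.preorder_node_iter() if nd.parent_node}
        for key, ln in orig.items():
            assert after[key] == pytest.approx(ln, abs=1e-9)

    def test_support_label_written(self, tmp_path, rng):
        tree = random_tree(5, rng)
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf() and nd.parent_node is not None:
                nd.label = "87"
                break
        path = tmp_path / "s.nwk"
        seqio.write_newick(tree, path)
        assert "87" in path.read_text()
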