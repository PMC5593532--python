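"""Seed matching, cis/trans prediction and promoter motif scanning."""

import numpy as np
import pytest

from cerna_forge.errors import DataError, FormatError
from cerna_forge.model import Config, GeneAnnotation, SequenceSet
from cerna_forge.motifs import Motif, reverse_complement
from cerna_forge.simulate import simulate_sequences
from cerna_forge.targets import (
    cis_targets,
    extract_promoters,
    scan_tf_motifs,
    seed_sequence,
    seed_targets,
    trans_targets,
)

import _oracles


def _seqset(**named):
    """helper: name=(seq, role) pairs -> SequenceSet"""
    return SequenceSet({k: v[0] for k, v in named.items()},
                       {k: v[1] for k, v in named.items()})


class TestSeedTargets:
    def test_poly_t_run_matched_at_expected_offset(self):
        # seed (positions 2-8) is AAAAAAA -> site TTTTTTT
        mirnas = _seqset(mir=("UAAAAAAACGUACGUACGUACG", "mirna"))
        targets = _seqset(utr=("GGTTTTTTTGG", "three_prime_utr"))
        (hit,) = seed_targets(mirnas, targets)
        assert (hit.target_id, hit.offset, hit.match_type) == ("utr", 2, "7mer")

    def test_absent_seed_means_no_hits(self):
        mirnas = _seqset(mir=("UAAGGCACAGUACGUACGUACG", "mirna"))
        targets = _seqset(utr=("ACGATCGATCGATCGA", "three_prime_utr"))
        assert seed_targets(mirnas, targets) == []

    def test_reverse_complement_rule(self):
        # seed AAGGCAC (positions 2-8) -> DNA site GTGCCTT
        assert seed_sequence("UAAGGCACAAAAAAAAAAAAAA") == "GTGCCTT"

    def test_short_mirna_rejected(self):
        with pytest.raises(FormatError):
            seed_sequence("UAAGG")

    def test_planted_sites_recovered_exactly(self, small_spec, small_dataset):
        _, truth = small_dataset
        seqs = simulate_sequences(truth, small_spec)
        hits = {(h.mirna_id, h.target_id): h.offset for h in seed_targets(seqs, seqs)}
        for (mir, target), offset in truth.planted_seed_sites.items():
            assert hits.get((mir, target)) == offset

    def test_revcomp_involution_mirrors_offsets(self):
        mirnas = _seqset(mir=("UAAAAAAACGUACGUACGUACG", "mirna"))
        fwd_target = "GGTTTTTTTGGACGT"
        hits_fwd = seed_targets(mirnas, _seqset(u=(fwd_target, "three_prime_utr")))
        # scanning the reverse complement for the forward seed AAAAAAA
        rc = reverse_complement(fwd_target)
        pos = rc.find("AAAAAAA")
        assert pos == len(fwd_target) - hits_fwd[0].offset - 7


class TestCisTargets:
    lnc = [GeneAnnotation("l1", "chr1", 100, 200, "+", "lncRNA")]

    def _mrna(self, start, end, chrom="chr1"):
        return [GeneAnnotation("m1", chrom, start, end, "+", "mRNA")]

    def test_overlap_has_distance_zero(self):
        (pair,) = cis_targets(self.lnc, self._mrna(150, 300))
        assert pair == ("l1", "m1", 0)

    def test_gap_exactly_at_window_retained(self):
        (pair,) = cis_targets(self.lnc, self._mrna(10_200, 10_300))
        assert pair[2] == 10_000

    def test_gap_one_past_window_excluded(self):
        assert cis_targets(self.lnc, self._mrna(10_201, 10_300)) == []

    def test_other_chromosome_excluded(self):
        assert cis_targets(self.lnc, self._mrna(150, 300, chrom="chr2")) == []

    def test_distance_symmetric(self):
        a = GeneAnnotation("a", "chr1", 100, 200, "+", "lncRNA")
        b = GeneAnnotation("b", "chr1", 500, 900, "-", "mRNA")
        from cerna_forge.targets import interval_gap
        assert interval_gap(a, b) == interval_gap(b, a) == 300
        assert interval_gap(a, a) == 0


class TestTransTargets:
    def test_exact_substring_found_with_full_identity(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        utr = "".join(rng.choice(bases, size=200))
        shared = utr[80:110]  # 30 nt exact block
        lnc = "".join(rng.choice(bases, size=50)) + shared + "".join(
            rng.choice(bases, size=50))
        hits = trans_targets(_seqset(l=(lnc, "transcript")),
                             _seqset(u=(utr, "three_prime_utr")))
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(1.0)
        assert hits[0].aligned_length >= 30

    def test_no_shared_11mer_means_no_hit(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        while True:
            a = "".join(rng.choice(bases, size=200))
            b = "".join(rng.choice(bases, size=200))
            kmers_a = {a[i:i + 11] for i in range(len(a) - 10)}
            kmers_b = {b[i:i + 11] for i in range(len(b) - 10)}
            if not (kmers_a & kmers_b):
                break
        hits = trans_targets(_seqset(l=(a, "transcript")),
                             _seqset(u=(b, "three_prime_utr")))
        assert hits == []

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            trans_targets(_seqset(), _seqset(u=("ACGT" * 10, "three_prime_utr")))

    def test_score_bounded_by_aligned_length(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        config = Config(trans_min_identity=0.0, trans_min_length=11)
        for _ in range(20):
            core = "".join(rng.choice(bases, size=25))
            lnc = "".join(rng.choice(bases, size=30)) + core
            utr = core + "".join(rng.choice(bases, size=30))
            for h in trans_targets(_seqset(l=(lnc, "transcript")),
                                   _seqset(u=(utr, "three_prime_utr")), config):
                assert h.score <= h.aligned_length

    def test_matches_restricted_smith_waterman_on_small_pairs(self):
        # seeded 40/40 nt pairs sharing a guaranteed 11-mer: the best
        # ungapped local score must equal gap-free Smith-Waterman
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        config = Config(trans_min_identity=0.0, trans_min_length=11)
        agree = 0
        for _ in range(100):
            seedmer = "".join(rng.choice(bases, size=11))
            a = "".join(rng.choice(bases, size=14)) + seedmer + "".join(
                rng.choice(bases, size=15))
            b = "".join(rng.choice(bases, size=10)) + seedmer + "".join(
                rng.choice(bases, size=19))
            hits = trans_targets(_seqset(l=(a, "transcript")),
                                 _seqset(u=(b, "three_prime_utr")), config)
            sw = _oracles.ungapped_smith_waterman(a, b)
            if hits:
                assert hits[0].score == sw
                agree += 1
        assert agree == 100  # a shared 11-mer always seeds a hit


class TestMotifScan:
    def test_planted_consensus_reported_at_minus_100(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        up, down = 2000, 500
        seq = "".join(rng.choice(bases, size=up + down))
        pos = up - 100
        seq = seq[:pos] + "TGACGTCA" + seq[pos + 8:]
        promoters = _seqset(lnc1=(seq, "promoter"))
        motif = Motif.from_consensus("CREB", "TGACGTCA")
        hits = [h for h in scan_tf_motifs(promoters, [motif])
                if h.position == -100 and h.strand == "+"]
        assert len(hits) == 1

    def test_absent_motif_yields_nothing(self):
        promoters = _seqset(lnc1=("ACGT" * 100, "promoter"))
        motif = Motif.from_consensus("CREB", "TTTTTTTTTT")
        assert scan_tf_motifs(promoters, [motif]) == []

    def test_minus_strand_gene_strand_corrected_position(self):
        # genome with the motif placed 150 bp upstream of a minus-strand TSS;
        # upstream of a minus-strand gene means to the RIGHT of end-1
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        chrom = "".join(rng.choice(bases, size=10_000))
        ann = [GeneAnnotation("gm", "chr1", 3_000, 5_000, "-", "lncRNA")]
        tss = 4_999
        motif_rc = reverse_complement("TGACGTCA")  # written on + strand
        start = tss + 150 - 7  # so the motif's 5' end (gene strand) sits at TSS+150
        chrom = chrom[:start] + motif_rc + chrom[start + 8:]
        genome = _seqset(chr1=(chrom, "genome"))
        promoters, anchors = extract_promoters(genome, ann, 2000, 500)
        motif = Motif.from_consensus("CREB", "TGACGTCA")
        hits = scan_tf_motifs(promoters, [motif], tss_offset_of=anchors)
        assert any(h.position == -150 and h.strand == "+" for h in hits)

    def test_hit_count_invariant_under_coordinate_translation(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        chrom = "".join(rng.choice(bases, size=30_000))
        motif = Motif.from_consensus("OCT1", "ATGCAAAT")
        anns = [GeneAnnotation("g1", "chr1", 9_000, 12_000, "+", "lncRNA"),
                GeneAnnotation("g2", "chr1", 20_000, 21_000, "-", "lncRNA")]
        shifted = [GeneAnnotation(a.gene_id, a.chrom, a.start + 1_000,
                                  a.end + 1_000, a.strand, a.biotype) for a in anns]
        genome = _seqset(chr1=(chrom, "genome"))
        genome_shifted = _seqset(chr1=(("A" * 1_000) + chrom, "genome"))
        p1, a1 = extract_promoters(genome, anns)
        p2, a2 = extract_promoters(genome_shifted, shifted)
        h1 = scan_tf_motifs(p1, [motif], tss_offset_of=a1)
        h2 = scan_tf_motifs(p2, [motif], tss_offset_of=a2)
        assert [(h.lncrna_id, h.position, h.strand) for h in h1] == [
            (h.lncrna_id, h.position, h.strand) for h in h2]

    def test_pwm_hits_include_consensus_and_respect_threshold(self):
        pwm = np.full((4, 6), 0.04)
        consensus = "TGACGT"
        index = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, c in enumerate(consensus):
            pwm[:, j] = 0.04
            pwm[index[c], j] = 0.88
        motif = Motif("toy", pwm)
        seq = "A" * 50 + consensus + "A" * 50
        hits = scan_tf_motifs(_seqset(p=(seq, "promoter")), [motif],
                              tss_offset_of={"p": 50})
        assert any(h.position == 0 and h.strand == "+" for h in hits)

    def test_planted_motif_sites_recovered(self, small_spec, small_dataset):
        from cerna_forge.simulate import DEFAULT_MOTIF_CONSENSI, default_motifs
        _, truth = small_dataset
        seqs = simulate_sequences(truth, small_spec)
        anchors = {p: small_spec.promoter_upstream_bp
                   for p in seqs.ids_with_role("promoter")}
        hits = scan_tf_motifs(seqs, default_motifs(), tss_offset_of=anchors)
        found = {(h.motif_id, h.lncrna_id, h.position) for h in hits}
        up = small_spec.promoter_upstream_bp
        for (motif, lnc), offset in truth.planted_motif_sites.items():
            assert (motif, f"{lnc}_promoter", offset - up) in found
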