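import itertools
import math

import numpy as np
import pytest

from circscape.motifs import (
    Motif,
    background_frequencies,
    extract_circ_sequence,
    extract_interval_sequence,
    motif_enrichment,
    positional_profile,
    read_consensus_motifs,
    read_meme_motifs,
    revcomp_motif,
    revcomp_rna,
    scan_sequence,
    _int_score_matrix,
    _score_survival,
)
from circscape.intervals import GenomicInterval
from tests.conftest import make_circ, make_transcript

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def indicator_ppm(consensus):
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    ppm = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        ppm[i, idx[b]] = 1.0
    return ppm


def brute_force_ppm_hits(seq, motif, p_threshold, bg):
    """Oracle: exact p by exhaustive enumeration of all 4^L windows, using the
    same integer score discretisation as the scanner."""
    bg = np.asarray(bg)
    imat = _int_score_matrix(motif.ppm, bg)
    L = len(motif)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    # distribution over all words
    word_scores = {}
    for word in itertools.product(range(4), repeat=L):
        s = int(sum(imat[i, a] for i, a in enumerate(word)))
        prob = math.prod(bg[a] for a in word)
        word_scores[word] = (s, prob)
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if any(b not in idx for b in window):
            continue
        s_obs = int(sum(imat[i, idx[b]] for i, b in enumerate(window)))
        p = sum(prob for s, prob in word_scores.values() if s >= s_obs)
        if p <= p_threshold:
            hits.append((off, s_obs, p))
    return hits


class TestMotifType:
    def test_needs_representation(self):
        with pytest.raises(ValueError):
            Motif(name="m")

    def test_ppm_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Motif(name="m", ppm=np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            Motif(name="m", consensus="AXG")

    def test_dna_consensus_converted(self):
        assert Motif(name="m", consensus="TGT").consensus == "UGU"


class TestConsensusScan:
    def test_exact_match(self):
        hits = scan_sequence("AAUGUAAA", Motif(name="m", consensus="UGUA"))
        assert [h.offset for h in hits] == [2]

    def test_iupac_degeneracy(self):
        motif = Motif(name="m", consensus="URUA")  # R = A/G
        hits = scan_sequence("AAUGUAAUAUA", motif)
        assert [h.offset for h in hits] == [2, 7]

    def test_n_window_skipped(self):
        hits = scan_sequence("AANGUA", Motif(name="m", consensus="UGUA"))
        assert hits == []

    def test_consensus_p_is_background_probability(self):
        (hit,) = scan_sequence("AUGUA", Motif(name="m", consensus="UGUA"),
                               background=UNIFORM)
        assert hit.p == pytest.approx(0.25**4)


class TestPpmScan:
    def test_indicator_ppm_equals_consensus(self):
        consensus = "UGUAA"  # L=5: max-score p = 4^-5 < 0.001 at uniform bg
        seq = "GGUGUAACCCUGUAAGG"
        cons_hits = scan_sequence(seq, Motif(name="c", consensus=consensus),
                                  background=UNIFORM)
        ppm_hits = scan_sequence(seq, Motif(name="p", ppm=indicator_ppm(consensus)),
                                 background=UNIFORM)
        assert [h.offset for h in cons_hits] == [h.offset for h in ppm_hits] == [2, 10]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 9))
        raw = rng.dirichlet([0.6] * 4, size=L)
        motif = Motif(name="m", ppm=raw)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 200)])
        bg = rng.dirichlet([5.0] * 4)
        threshold = 0.02
        got = scan_sequence(seq, motif, p_threshold=threshold, background=bg)
        expected = brute_force_ppm_hits(seq, motif, threshold, bg)
        assert [(h.offset) for h in got] == [e[0] for e in expected]
        for h, e in zip(got, expected):
            assert h.p == pytest.approx(e[2], rel=1e-9)

    def test_survival_function_is_exact_distribution(self):
        rng = np.random.default_rng(42)
        ppm = rng.dirichlet([1.0] * 4, size=4)
        bg = np.full(4, 0.25)
        imat = _int_score_matrix(ppm, bg)
        lo, sf = _score_survival(imat, bg)
        # P(S >= min score) covers everything
        assert sf[0] == pytest.approx(1.0)
        # compare against enumeration at the median attainable score
        scores = sorted(
            int(sum(imat[i, a] for i, a in enumerate(w)))
            for w in itertools.product(range(4), repeat=4)
        )
        mid = scores[len(scores) // 2]
        brute = sum(
            math.prod(bg[a] for a in w)
            for w in itertools.product(range(4), repeat=4)
            if int(sum(imat[i, a] for i, a in enumerate(w))) >= mid
        )
        assert sf[mid - lo] == pytest.approx(brute, rel=1e-12)

    def test_strand_consistency_mirrored_offsets(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 120)])
        motif = Motif(name="m", ppm=rng.dirichlet([0.5] * 4, size=6))
        fwd = scan_sequence(seq, motif, p_threshold=0.05, background=UNIFORM)
        rev = scan_sequence(revcomp_rna(seq), revcomp_motif(motif),
                            p_threshold=0.05, background=UNIFORM)
        L = len(motif)
        mirrored = sorted(len(seq) - L - h.offset for h in rev)
        assert sorted(h.offset for h in fwd) == mirrored


class TestSequenceExtraction:
    def test_single_exon_sequence_exact(self):
        genome = {"chr1": "AAACGTACGT"}
        tx = make_transcript([(2, 8)])
        circ = make_circ(tx, 0, 0)
        assert extract_circ_sequence(circ, tx, genome) == "ACGUAC"

    def test_minus_strand_two_exons_hand_computed(self):
        # 20-base toy genome; exons at 2-6 and 10-14 on the minus strand
        genome = {"chr1": "AACGTTAAGGCTTAACCGGT"}
        tx = make_transcript([(2, 6), (10, 14)], strand="-")
        circ = make_circ(tx, 0, 1)
        # genomic concatenation: CGTT + CTTA = CGTTCTTA; revcomp = TAAGAACG -> RNA
        assert extract_circ_sequence(circ, tx, genome) == "UAAGAACG"

    def test_length_conservation_random(self, sim_bundle):
        bundle = sim_bundle
        tx_by_id = {t.transcript_id: t for t in bundle["transcripts"]}
        for circ in bundle["truth_circs"][:50]:
            tx = tx_by_id[circ.transcript_id]
            i, j = circ.bs_exon_indices
            seq = extract_circ_sequence(circ, tx, bundle["genome"])
            assert len(seq) == sum(len(e) for e in tx.exons[i : j + 1])

    def test_interval_extraction_strand_aware(self):
        genome = {"c": "AACGTT"}
        iv = GenomicInterval("c", 1, 5, "+")
        assert extract_interval_sequence(iv, genome) == "ACGU"
        assert extract_interval_sequence(iv, genome, "-") == revcomp_rna("ACGU")


class TestEnrichment:
    def make_seqs(self, n_with, n_without, motif="UGUAA"):
        seqs = {}
        for i in range(n_with):
            seqs[f"with{i}"] = "CCCC" + motif + "CCCC"
        for i in range(n_without):
            seqs[f"without{i}"] = "C" * 13
        return seqs

    def test_equal_proportions_not_enriched(self):
        # one-tailed Fisher at the expected overlap is far from significant
        # (p == 1 exactly only when the target hit count is at its minimum)
        targets = self.make_seqs(2, 2)
        background = self.make_seqs(2, 2)
        (res,) = motif_enrichment(targets, background,
                                  [Motif(name="m", consensus="UGUAA")],
                                  background_freqs=UNIFORM)
        assert res.p_fisher > 0.5

    def test_minimum_target_hits_p1(self):
        targets = self.make_seqs(0, 4)
        background = self.make_seqs(2, 2)
        (res,) = motif_enrichment(targets, background,
                                  [Motif(name="m", consensus="UGUAA")],
                                  background_freqs=UNIFORM)
        assert res.p_fisher == pytest.approx(1.0)

    def test_closed_form_fisher(self):
        targets = self.make_seqs(5, 0)
        background = self.make_seqs(0, 5)
        (res,) = motif_enrichment(targets, background,
                                  [Motif(name="m", consensus="UGUAA")],
                                  background_freqs=UNIFORM)
        assert res.p_fisher == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_hits_p1(self):
        targets = self.make_seqs(0, 3)
        background = self.make_seqs(0, 3)
        (res,) = motif_enrichment(targets, background,
                                  [Motif(name="m", consensus="UGUAA")],
                                  background_freqs=UNIFORM)
        assert res.p_fisher == 1.0

    def test_matches_exhaustive_fisher_oracle(self):
        from scipy.stats import hypergeom

        for t_with, t_total, b_with, b_total in [(3, 5, 1, 6), (4, 4, 2, 8), (2, 6, 2, 6)]:
            targets = self.make_seqs(t_with, t_total - t_with)
            background = self.make_seqs(b_with, b_total - b_with)
            (res,) = motif_enrichment(targets, background,
                                      [Motif(name="m", consensus="UGUAA")],
                                      background_freqs=UNIFORM)
            # one-tailed Fisher == hypergeometric upper tail on the margins
            N = t_total + b_total
            K = t_with + b_with
            expected = float(hypergeom.sf(t_with - 1, N, K, t_total))
            assert res.p_fisher == pytest.approx(expected, rel=1e-9)

    def test_bh_across_motifs(self):
        targets = self.make_seqs(5, 0)
        background = self.make_seqs(0, 5)
        motifs = [Motif(name="hit", consensus="UGUAA"),
                  Motif(name="absent", consensus="GGGGGGG")]
        res = motif_enrichment(targets, background, motifs, background_freqs=UNIFORM)
        by_name = {r.motif_name: r for r in res}
        assert by_name["absent"].p_fisher == 1.0
        assert by_name["hit"].padj_bh == pytest.approx(by_name["hit"].p_fisher * 2)


class TestPositionalProfile:
    def hit(self, seq_id, offset):
        from circscape.motifs import MotifHit

        return MotifHit(motif_name="m", sequence_id=seq_id, offset=offset,
                        score=1.0, p=0.001)

    def test_single_hit_frequency(self):
        info = {"c1|upstream": (1000, "upstream")}
        prof = positional_profile([self.hit("c1|upstream", 0)], info,
                                  normaliser=10)
        assert prof.frequencies[0] == pytest.approx(0.1)

    def test_distal_anchor_mirrors_downstream_intron(self):
        info = {"c1|downstream": (1000, "downstream")}
        hits = [self.hit("c1|downstream", 950)]
        five = positional_profile(hits, info, anchor="five_prime_end",
                                  bin_width=100, max_distance=999, normaliser=1)
        distal = positional_profile(hits, info, anchor="bsj_distal_splice_site",
                                    bin_width=100, max_distance=999, normaliser=1)
        assert five.counts[9] == 1
        assert distal.counts[0] == 1  # 1000-1-950 = 49 -> bin 0

    def test_upstream_intron_distal_is_five_prime(self):
        info = {"c1|upstream": (1000, "upstream")}
        hits = [self.hit("c1|upstream", 10)]
        distal = positional_profile(hits, info, anchor="bsj_distal_splice_site",
                                    bin_width=100, max_distance=999, normaliser=1)
        assert distal.counts[0] == 1

    def test_total_hits_conserved(self):
        rng = np.random.default_rng(4)
        info = {f"c{i}|upstream": (2000, "upstream") for i in range(10)}
        hits = [self.hit(f"c{int(rng.integers(0, 10))}|upstream", int(rng.integers(0, 2000)))
                for _ in range(300)]
        prof = positional_profile(hits, info, bin_width=100, max_distance=1999,
                                  normaliser=10)
        assert sum(prof.counts) == 300

    def test_hit_outside_intron_raises(self):
        info = {"c1|upstream": (100, "upstream")}
        with pytest.raises(ValueError):
            positional_profile([self.hit("c1|upstream", 150)], info, normaliser=1)

    def test_unknown_intron_raises(self):
        with pytest.raises(ValueError):
            positional_profile([self.hit("nope", 0)], {}, normaliser=1)

    def test_planted_bias_monotone_and_flat(self):
        from circscape.simulate import SynthConfig, plant_motifs
        from circscape.motifs import scan_sequences

        rng = np.random.default_rng(8)
        seqs = {
            f"c{i}|upstream": "".join(np.array(list("ACGU"))[rng.integers(0, 4, 3000)])
            for i in range(60)
        }
        consensus = "UGUGUGA"
        motif = Motif(name="m", consensus=consensus)
        info = {k: (3000, "upstream") for k in seqs}

        biased_cfg = SynthConfig(seed=8, motif_5prime_bias=0.01,
                                 motifs_per_sequence=5.0)
        planted, _ = plant_motifs(biased_cfg, seqs, consensus)
        hits = scan_sequences(planted, [motif])
        prof = positional_profile(hits, info, bin_width=500, max_distance=2999,
                                  normaliser=60)
        # geometric decay: first bin clearly dominates and beats the tail
        assert prof.counts[0] > prof.counts[1] > prof.counts[4]

        flat_cfg = SynthConfig(seed=8, motif_5prime_bias=0.0,
                               motifs_per_sequence=5.0)
        planted_flat, _ = plant_motifs(flat_cfg, seqs, consensus)
        hits_flat = scan_sequences(planted_flat, [motif])
        prof_flat = positional_profile(hits_flat, info, bin_width=500,
                                       max_distance=2999, normaliser=60)
        from scipy.stats import chisquare

        counts = np.array(prof_flat.counts, dtype=float)
        assert chisquare(counts).pvalue > 0.01


class TestMotifIo:
    def test_meme_round_trip(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 5\n\nALPHABET= ACGU\n\n"
            "MOTIF SFPQ_1\n"
            "letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
            " 0.7 0.1 0.1 0.1\n 0.1 0.7 0.1 0.1\n 0.1 0.1 0.1 0.7\n\n"
            "MOTIF TIAL1_1\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0\n"
            " 0.25 0.25 0.25 0.25\n 1.0 0.0 0.0 0.0\n"
        )
        motifs = read_meme_motifs(path)
        assert [m.name for m in motifs] == ["SFPQ_1", "TIAL1_1"]
        assert motifs[0].ppm.shape == (3, 4)
        assert motifs[1].ppm[1, 0] == 1.0

    def test_consensus_tsv(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("name\trbp\tconsensus\nm1\tSFPQ\tUGUAA\n")
        (m,) = read_consensus_motifs(path)
        assert m.consensus == "UGUAA" and m.rbp == "SFPQ"

    def test_background_frequencies(self):
        bg = background_frequencies(["AACC", "GGUU"])
        assert bg == pytest.approx([0.25, 0.25, 0.25, 0.25])
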