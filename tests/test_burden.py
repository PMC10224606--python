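import numpy as np
import pytest

from circscape.burden import (
    NoContainingTranscript,
    VariantRecord,
    burden_compare,
    classify_exons,
    classify_exons_for_catalog,
    deduplicate_exon_records,
    impact_proportions,
    missense_deleterious_fractions,
    select_longest_transcript,
    tally_variants,
)
from circscape.intervals import GenomicInterval
from tests.conftest import make_circ, make_transcript


def variant(pos, chrom="chr1", impact="low", flags=(), cohort="gnomad"):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G",
                         impact=impact, flags=frozenset(flags), cohort=cohort)


class TestSelectLongestTranscript:
    def test_containment_dominates_length(self, five_exon_tx):
        # longer transcript lacks the BSJ-end exon boundaries
        longer = make_transcript(
            [(900, 1100), (1450, 1600), (2100, 2200), (2800, 3000), (3600, 4000)],
            transcript_id="TXlong",
        )
        circ = make_circ(five_exon_tx, 1, 3)
        assert select_longest_transcript([longer, five_exon_tx], circ) is five_exon_tx

    def test_single_transcript_identity(self, five_exon_tx):
        circ = make_circ(five_exon_tx, 1, 3)
        assert select_longest_transcript([five_exon_tx], circ) is five_exon_tx

    def test_tie_breaks_lexicographically(self, five_exon_tx):
        spans = [(e.start, e.end) for e in five_exon_tx.exons]
        a = make_transcript(spans, transcript_id="TXa")
        b = make_transcript(spans, transcript_id="TXb")
        circ = make_circ(a, 1, 3)
        assert select_longest_transcript([b, a], circ).transcript_id == "TXa"

    def test_no_containing_transcript(self, five_exon_tx):
        other = make_transcript([(10, 20), (30, 40), (50, 60), (70, 80)])
        circ = make_circ(five_exon_tx, 1, 3)
        with pytest.raises(NoContainingTranscript):
            select_longest_transcript([other], circ)


class TestClassifyExons:
    def test_five_exon_scheme(self, five_exon_tx):
        # circ over exons 2-4 (1-based): boundary exons BSJ, middle nonBSJ,
        # first and last exon nonCirc
        circ = make_circ(five_exon_tx, 1, 3)
        recs = classify_exons(five_exon_tx, circ)
        assert [r.circ_class for r in recs] == ["nonCirc", "circ", "circ", "circ", "nonCirc"]
        assert [r.bsj_class for r in recs] == ["NA", "BSJ", "nonBSJ", "BSJ", "NA"]

    def test_single_exon_circ(self, five_exon_tx):
        circ = make_circ(five_exon_tx, 2, 2)
        recs = classify_exons(five_exon_tx, circ)
        assert recs[2].bsj_class == "BSJ"
        assert sum(1 for r in recs if r.circ_class == "circ") == 1

    def test_full_span_circ_no_noncirc(self, five_exon_tx):
        circ = make_circ(five_exon_tx, 0, 4)
        recs = classify_exons(five_exon_tx, circ)
        assert all(r.circ_class == "circ" for r in recs)

    def test_partition_complete(self, five_exon_tx):
        circ = make_circ(five_exon_tx, 1, 3)
        recs = classify_exons(five_exon_tx, circ)
        assert len(recs) == len(five_exon_tx.exons)
        circ_exons = {(r.exon.start, r.exon.end) for r in recs if r.circ_class == "circ"}
        bsj_union = {
            (r.exon.start, r.exon.end) for r in recs if r.bsj_class in ("BSJ", "nonBSJ")
        }
        assert circ_exons == bsj_union


class TestDeduplicate:
    def test_most_circular_label_wins(self, five_exon_tx):
        a = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        b = classify_exons(five_exon_tx, make_circ(five_exon_tx, 2, 2))
        out = deduplicate_exon_records(a + b)
        assert len(out) == len(five_exon_tx.exons)
        by_start = {r.exon.start: r for r in out}
        # exon index 2 is nonBSJ in circ A but BSJ in circ B -> BSJ wins
        assert by_start[2100].bsj_class == "BSJ"


class TestTally:
    def test_density_arithmetic(self):
        tx = make_transcript([(0, 500), (1000, 1100), (2000, 2100), (3000, 3100)])
        rec = classify_exons(tx, make_circ(tx, 1, 2))[0]
        table = tally_variants([rec], [variant(10), variant(20)])
        assert table.loc[0, "n_variants"] == 2
        assert table.loc[0, "density_per_kb"] == pytest.approx(4.0)

    def test_end_boundary_excluded(self, five_exon_tx):
        recs = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        # exon 0 spans 1000-1100 half-open: position 1100 falls outside it
        # (and inside no other exon), while 1099 is counted
        table = tally_variants(recs, [variant(1100)])
        assert table["n_variants"].sum() == 0
        table = tally_variants(recs, [variant(1099)])
        assert table.loc[0, "n_variants"] == 1

    def test_empty_variants(self, five_exon_tx):
        recs = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        table = tally_variants(recs, [])
        assert (table["density_per_kb"] == 0).all()

    def test_matches_brute_force_scan(self, five_exon_tx):
        rng = np.random.default_rng(5)
        recs = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        variants = [variant(int(p)) for p in rng.integers(0, 4000, size=300)]
        table = tally_variants(recs, variants)
        for row, rec in zip(table.itertuples(index=False), recs):
            brute = sum(1 for v in variants if rec.exon.start <= v.pos < rec.exon.end)
            assert row.n_variants == brute

    def test_group_kb_totals_exact(self, five_exon_tx):
        recs = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        table = tally_variants(recs, [])
        for group in ("circ", "nonCirc"):
            sub = table[table["circ_class"] == group]
            expect = sum(len(r.exon) for r in recs if r.circ_class == group) / 1000
            assert sub["length_kb"].sum() == pytest.approx(expect)


class TestBurdenCompare:
    def test_identical_densities_null(self, five_exon_tx):
        recs = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        res = burden_compare(recs, [], grouping="circ")
        assert res.z == 0.0 and res.p_z == 1.0

    def test_planted_density_ratio_recovered(self):
        from circscape.simulate import SynthConfig, generate_variants

        n_genes = 130  # ~5 exons each -> >= 500 exons
        records = []
        rng = np.random.default_rng(17)
        for g in range(n_genes):
            spans = []
            pos = 0
            for _ in range(5):
                length = int(rng.integers(300, 700))
                spans.append((pos, pos + length))
                pos += length + 200
            tx = make_transcript(spans, chrom=f"chr{g}", transcript_id=f"T{g}",
                                 gene_id=f"G{g}", gene_name=f"G{g}")
            records.extend(classify_exons(tx, make_circ(tx, 1, 3)))
        assert len(records) >= 500
        cfg = SynthConfig(seed=17, variant_density_ratio=2.0)
        variants = generate_variants(cfg, records)
        res = burden_compare(records, variants, grouping="circ")
        assert abs(res.pooled_ratio - 2.0) / 2.0 < 0.15
        assert res.p_z < 0.05

    def test_splice_region_filter_matches_brute_force(self, five_exon_tx):
        recs = classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
        rng = np.random.default_rng(3)
        variants = [
            variant(int(p), flags=("splice_region",) if rng.random() < 0.4 else ())
            for p in rng.integers(1000, 3700, size=200)
        ]
        res = burden_compare(recs, variants, grouping="circ", flag="splice_region")
        brute = [v for v in variants if "splice_region" in v.flags]
        brute_counts = sum(
            1 for v in brute for r in recs if r.exon.start <= v.pos < r.exon.end
        )
        assert res.n_variants_a + res.n_variants_b == brute_counts

    def test_empty_group_raises(self, five_exon_tx):
        recs = [
            r for r in classify_exons(five_exon_tx, make_circ(five_exon_tx, 1, 3))
            if r.circ_class == "circ"
        ]
        with pytest.raises(ValueError, match="nonCirc"):
            burden_compare(recs, [], grouping="circ")

    def test_null_type_one_error(self):
        # uniform placement, ratio 1: Z-test rejects at about alpha
        from circscape.simulate import SynthConfig, generate_variants

        recs = []
        for g in range(20):
            spans = [(pos, pos + 500) for pos in range(0, 6 * 700, 700)]
            tx = make_transcript(spans, chrom=f"chr{g}", transcript_id=f"T{g}",
                                 gene_id=f"G{g}", gene_name=f"G{g}")
            recs.extend(classify_exons(tx, make_circ(tx, 1, 4)))
        reps, rejections = 200, 0
        for seed in range(reps):
            cfg = SynthConfig(seed=seed, variant_density_ratio=1.0,
                              variant_density_per_kb=30.0)
            variants = generate_variants(cfg, recs)
            res = burden_compare(recs, variants, grouping="circ")
            if res.p_z < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09


class TestProportions:
    def test_impact_proportions(self):
        group = [variant(1, impact="low"), variant(2, impact="medium"),
                 variant(3, impact="high"), variant(4, impact="high")]
        table = impact_proportions({"circ": group})
        row = table.iloc[0]
        assert (row["low"], row["medium"], row["high"]) == (0.25, 0.25, 0.5)
        assert row["low"] + row["medium"] + row["high"] == pytest.approx(1.0)

    def test_single_category(self):
        table = impact_proportions({"g": [variant(1, impact="low")]})
        assert table.iloc[0]["low"] == 1.0

    def test_none_impact_excluded_and_counted(self):
        table = impact_proportions({"g": [variant(1, impact="low"),
                                          variant(2, impact="none")]})
        assert table.iloc[0]["n_unscored"] == 1
        assert table.iloc[0]["low"] == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            impact_proportions({"g": []})

    def test_missense_deleterious(self):
        vs = [variant(1, flags=("missense",)),
              variant(2, flags=("missense", "deleterious")),
              variant(3), variant(4)]
        frac_mis, frac_del = missense_deleterious_fractions(vs)
        assert frac_mis == 0.5 and frac_del == 0.5

    def test_no_missense(self):
        frac_mis, frac_del = missense_deleterious_fractions([variant(1)])
        assert frac_mis == 0.0 and frac_del is None

    def test_all_deleterious(self):
        vs = [variant(1, flags=("missense", "deleterious"))]
        assert missense_deleterious_fractions(vs) == (1.0, 1.0)


class TestCatalogClassification:
    def test_every_exon_single_circ_class(self, sim_bundle, sim_config):
        records = sim_bundle["exon_records"]
        keys = [(r.transcript_id, r.exon.start, r.exon.end) for r in records]
        assert len(keys) == len(set(keys))
        for r in records:
            assert r.circ_class in ("circ", "nonCirc")
            assert (r.bsj_class != "NA") == (r.circ_class == "circ")
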