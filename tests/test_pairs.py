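"""Pair admission, amplicon-length categories, pair coverage, specificity."""

import pytest

from conftest import make_db, random_seq
from primercover.coverage import CoverageResult, primer_coverage
from primercover.oracle import oracle_pair_truth
from primercover.pairs import (
    LengthCategory,
    PairGeometry,
    PrimerPair,
    Specificity,
    classify_specificity,
    enumerate_pairs,
    length_category,
    merge_pairs,
    not_covered_report,
    pair_coverage,
    select_candidates,
)
from primercover.positions import PositionStats
from primercover.primers import canonicalize_primer, reverse_complement

F_SEQ = "ACGGTTCACGTAGGAATT"
R_SEQ = "TGGACCGTGTCTCAGTT"
FWD = canonicalize_primer("OP_F001", "F", F_SEQ)
REV = canonicalize_primer("OP_R001", "R", R_SEQ)


def cov(pid, covered, total, domain="bacteria"):
    return CoverageResult(
        primer_id=pid, domain=domain,
        n_variants_matched=covered, n_variants_total=total,
        n_species_covered=covered, n_species_total=total,
    )


def stats(pid, first, last, n=5):
    return PositionStats(
        primer_id=pid, n_observations=n, mean_first=first, mean_last=last,
        mode_first=int(first), mode_last=int(last),
    )


class TestCandidates:
    def test_threshold_is_inclusive(self):
        results = {"OP_F001": cov("OP_F001", 3, 4)}  # SC exactly 75.00
        f, r = select_candidates(results, {"OP_F001": FWD})
        assert f == ["OP_F001"]

    def test_just_below_threshold_excluded(self):
        results = {"OP_F001": cov("OP_F001", 7499, 10000)}  # 74.99
        f, r = select_candidates(results, {"OP_F001": FWD})
        assert f == []

    def test_split_by_direction(self):
        results = {"OP_F001": cov("OP_F001", 4, 4), "OP_R001": cov("OP_R001", 4, 4)}
        f, r = select_candidates(results, {"OP_F001": FWD, "OP_R001": REV})
        assert f == ["OP_F001"] and r == ["OP_R001"]


class TestAdmission:
    def test_distance_below_minimum_rejected(self):
        pairs = enumerate_pairs(
            ["F"], ["R"],
            {"F": stats("F", 100, 117), "R": stats("R", 160, 150)},
            {"F": FWD, "R": REV}, "bacteria",
        )
        assert pairs == []

    def test_wrong_orientation_rejected(self):
        pairs = enumerate_pairs(
            ["F"], ["R"],
            {"F": stats("F", 200, 217), "R": stats("R", 110, 100)},
            {"F": FWD, "R": REV}, "bacteria",
        )
        assert pairs == []

    def test_cartesian_product_when_all_admissible(self):
        f_stats = {f"F{i}": stats(f"F{i}", 100 + i, 117 + i) for i in range(3)}
        r_stats = {f"R{j}": stats(f"R{j}", 600 + j, 580 + j) for j in range(4)}
        primers = {pid: FWD for pid in f_stats} | {pid: REV for pid in r_stats}
        pairs = enumerate_pairs(
            list(f_stats), list(r_stats), f_stats | r_stats, primers, "bacteria"
        )
        assert len(pairs) == 12

    def test_order_invariance(self):
        f_stats = {"F2": stats("F2", 101, 118), "F1": stats("F1", 100, 117)}
        r_stats = {"R1": stats("R1", 600, 580)}
        primers = {"F1": FWD, "F2": FWD, "R1": REV}
        a = enumerate_pairs(["F2", "F1"], ["R1"], f_stats | r_stats, primers, "bacteria")
        b = enumerate_pairs(["F1", "F2"], ["R1"], f_stats | r_stats, primers, "bacteria")
        assert [p.pair_id for p in a] == [p.pair_id for p in b]

    def test_undefined_positions_excluded(self):
        undefined = PositionStats(primer_id="F", n_observations=0)
        pairs = enumerate_pairs(
            ["F"], ["R"], {"F": undefined, "R": stats("R", 600, 580)},
            {"F": FWD, "R": REV}, "bacteria",
        )
        assert pairs == []


class TestLengthCategories:
    @pytest.mark.parametrize(
        "length,category",
        [
            (300, LengthCategory.cat1_100_300),
            (301, LengthCategory.cat2_301_600),
            (600, LengthCategory.cat2_301_600),
            (601, LengthCategory.cat3_gt600),
            (100, LengthCategory.cat1_100_300),
        ],
    )
    def test_boundaries(self, length, category):
        assert length_category(length) is category

    def test_mean_length_is_inclusive(self):
        geo = PairGeometry(mean_f_first=342.0, mean_r_last=529.0)
        assert geo.mean_amplicon_length == 188

    def test_categories_partition(self):
        seen = {length_category(l) for l in range(100, 1200)}
        assert seen == set(LengthCategory)


def _pair(f=FWD, r=REV):
    return PrimerPair(forward=f, reverse=r, geometry={"bacteria": PairGeometry(100, 400)})


def _implant(seq, at, insert):
    return seq[:at] + insert + seq[at + len(insert):]


class TestPairCoverage:
    def test_forward_only_variant_not_covered(self, rng):
        seq = _implant(random_seq(rng, 400), 50, F_SEQ)
        res = pair_coverage(_pair(), make_db({"SP00001": [seq]}))
        assert res.n_variants_matched == 0

    def test_reverse_site_upstream_of_forward_not_covered(self, rng):
        seq = random_seq(rng, 400)
        seq = _implant(seq, 30, reverse_complement(R_SEQ))
        seq = _implant(seq, 200, F_SEQ)
        res = pair_coverage(_pair(), make_db({"SP00001": [seq]}))
        assert res.n_variants_matched == 0

    def test_amplifiable_geometry_covered_with_product_length(self, rng):
        seq = random_seq(rng, 400)
        seq = _implant(seq, 49, F_SEQ)
        seq = _implant(seq, 300, reverse_complement(R_SEQ))
        res = pair_coverage(_pair(), make_db({"SP00001": [seq]}))
        assert res.n_variants_matched == 1
        # R primer's 3' nucleotide sits at the start of its sense footprint
        assert res.amplicon_lengths["TS000001"] == 301 - 50 + 1

    def test_six_of_ten_variants_equals_bruteforce(self, rng):
        seqs = []
        for i in range(10):
            seq = random_seq(rng, 400)
            if i < 6:
                seq = _implant(seq, 49, F_SEQ)
                seq = _implant(seq, 300, reverse_complement(R_SEQ))
            elif i < 8:
                seq = _implant(seq, 49, F_SEQ)  # F only
            seqs.append(seq)
        db = make_db({f"SP{i:05d}": [seqs[i]] for i in range(10)})
        res = pair_coverage(_pair(), db)
        assert res.vc_percent == 60.00
        oracle = oracle_pair_truth(FWD, REV, db)
        assert res.n_variants_matched == oracle["n_variants_matched"]
        assert res.n_species_covered == oracle["n_species_covered"]

    def test_pair_sc_bounded_by_single_primer_sc(self, rng):
        db_spec = {}
        for i in range(8):
            seq = random_seq(rng, 400)
            if i % 2:
                seq = _implant(seq, 49, F_SEQ)
            if i % 3:
                seq = _implant(seq, 300, reverse_complement(R_SEQ))
            db_spec[f"SP{i:05d}"] = [seq]
        db = make_db(db_spec)
        pair_res = pair_coverage(_pair(), db)
        f_res = primer_coverage(FWD, db)
        r_res = primer_coverage(REV, db)
        assert pair_res.sc_fraction <= min(f_res.sc_fraction, r_res.sc_fraction)
        assert pair_res.vc_fraction <= min(f_res.vc_fraction, r_res.vc_fraction)


class TestSpecificity:
    def test_bacteria_specific(self):
        assert classify_specificity(cov("p", 753, 769), cov("p", 0, 194, "archaea")) \
            is Specificity.bacteria_specific

    def test_archaea_specific(self):
        assert classify_specificity(cov("p", 0, 769), cov("p", 186, 194, "archaea")) \
            is Specificity.archaea_specific

    def test_non_specific(self):
        assert classify_specificity(cov("p", 735, 769), cov("p", 193, 194, "archaea")) \
            is Specificity.non_specific

    def test_dead_pair(self):
        assert classify_specificity(cov("p", 0, 769), cov("p", 0, 194, "archaea")) \
            is Specificity.dead


class TestNotCovered:
    def test_full_coverage_gives_empty_report(self, rng):
        seq = _implant(random_seq(rng, 400), 49, F_SEQ)
        seq = _implant(seq, 300, reverse_complement(R_SEQ))
        db = make_db({"SP00001": [seq]})
        assert not_covered_report(pair_coverage(_pair(), db), db) == []

    def test_species_missing_reverse_site_listed(self, rng):
        good = _implant(random_seq(rng, 400), 49, F_SEQ)
        good = _implant(good, 300, reverse_complement(R_SEQ))
        bad = _implant(random_seq(rng, 400), 49, F_SEQ)  # no R site
        db = make_db({"SP00001": [good], "SP00002": [bad]})
        report = not_covered_report(pair_coverage(_pair(), db), db)
        assert [sp for sp, _ in report] == ["SP00002"]


class TestMerge:
    def test_shared_pair_keeps_both_geometries(self):
        a = PrimerPair(FWD, REV, {"bacteria": PairGeometry(100, 400)})
        b = PrimerPair(FWD, REV, {"archaea": PairGeometry(105, 390)})
        merged = merge_pairs([a], [b])
        assert len(merged) == 1 and merged[0].admitted_in == {"bacteria", "archaea"}
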