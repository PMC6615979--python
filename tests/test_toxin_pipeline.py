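"""Proteome matching, predominant selection, copy and mechanism classification."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from venomstrat import toxin_pipeline as tp
from venomstrat.formats_io import OrthogroupTable, SimilarityHit
from venomstrat.phylostrat import FOCAL_EXCLUSIVE, NOT_APPLICABLE, UNASSIGNED

FOCAL = "Dasypogon_diadema"


def _hit(q="q1", s="g1", ev=1e-45, cov=0.95, bits=200.0):
    return SimilarityHit(q, s, ev, cov, bits)


class TestMatchProteome:
    def test_hit_within_thresholds_is_matched(self):
        out = tp.match_proteome([_hit()])
        assert out.matched == {"q1": "g1"}

    @pytest.mark.parametrize(
        "ev,cov", [(1e-39, 0.95), (1e-45, 0.89), (1e-39, 0.89)]
    )
    def test_boundary_violations_unmatched(self, ev, cov):
        out = tp.match_proteome([_hit(ev=ev, cov=cov)])
        assert out.unmatched == {"q1"}

    def test_inclusive_boundaries(self):
        out = tp.match_proteome([_hit(ev=1e-40, cov=0.90)])
        assert out.matched == {"q1": "g1"}

    def test_best_bitscore_wins(self):
        out = tp.match_proteome([_hit(s="gA", bits=120), _hit(s="gB", bits=310)])
        assert out.matched["q1"] == "gB"

    def test_tie_breaks_deterministic(self):
        # equal bitscore -> lowest evalue; equal both -> lexicographic id
        out = tp.match_proteome(
            [_hit(s="gA", bits=200, ev=1e-45), _hit(s="gB", bits=200, ev=1e-50)]
        )
        assert out.matched["q1"] == "gB"
        out2 = tp.match_proteome([_hit(s="gB"), _hit(s="gA")])
        assert out2.matched["q1"] == "gA"


def _rec(gene="g1", vg=1000.0, body=10.0, confirmed=True, housekeeping=False):
    rec = tp.ToxinRecord(
        gene_id=gene, family="famA", proteome_confirmed=confirmed,
        vg_tpm={"male": vg, "female": vg}, body_tpm={"male": body, "female": body},
        housekeeping=housekeeping,
    )
    rec.compute_folds()
    return rec


class TestPredominantFilter:
    def test_inclusive_boundaries_retained(self):
        rec = _rec(vg=500.0, body=125.0)  # fold exactly 4.0
        assert tp.predominant_filter([rec]) == [rec]

    def test_just_below_tpm_threshold_removed(self):
        rec = _rec(vg=499.9, body=10.0)
        assert tp.predominant_filter([rec]) == []

    def test_unconfirmed_removed(self):
        assert tp.predominant_filter([_rec(confirmed=False)]) == []

    def test_one_sex_suffices(self):
        rec = tp.ToxinRecord(
            gene_id="g1", family="f", proteome_confirmed=True,
            vg_tpm={"male": 600.0, "female": 5.0},
            body_tpm={"male": 10.0, "female": 100.0},
        )
        rec.compute_folds()
        assert tp.predominant_filter([rec]) == [rec]

    def test_toy_table_row_by_row(self):
        rows = [
            ("a", 2000, 10, True),   # keep
            ("b", 499, 10, True),    # tpm fail
            ("c", 600, 200, True),   # fold 3 fail
            ("d", 600, 150, True),   # fold 4 keep
            ("e", 600, 10, False),   # unconfirmed
            ("f", 0, 0, True),       # nothing
            ("g", 500, 0, True),     # inf fold keep
            ("h", 50, 1, True),      # tpm fail
        ]
        recs = [_rec(g, vg, body, conf) for g, vg, body, conf in rows]
        kept = tp.predominant_filter(recs)
        assert [r.gene_id for r in kept] == ["a", "d", "g"]

    def test_output_sorted_by_descending_vg_tpm(self):
        recs = [_rec("lo", vg=600), _rec("hi", vg=9000), _rec("mid", vg=2000)]
        assert [r.gene_id for r in tp.predominant_filter(recs)] == ["hi", "mid", "lo"]

    @given(
        tpms=st.lists(st.tuples(st.floats(0, 5000), st.floats(0, 2000)),
                      min_size=1, max_size=15),
        thresholds=st.tuples(st.floats(0, 2000), st.floats(0, 2000),
                             st.floats(0, 20), st.floats(0, 20)),
    )
    def test_raising_thresholds_never_enlarges_set(self, tpms, thresholds):
        recs = [_rec(f"g{i}", vg, body) for i, (vg, body) in enumerate(tpms)]
        t_lo, t_hi = sorted(thresholds[:2])
        f_lo, f_hi = sorted(thresholds[2:])
        loose = {r.gene_id for r in tp.predominant_filter(recs, t_lo, f_lo)}
        strict = {r.gene_id for r in tp.predominant_filter(recs, t_hi, f_hi)}
        assert strict <= loose


class TestHousekeepingExclusion:
    def test_body_dominated_flagged_gene_excluded(self):
        assert tp.housekeeping_exclusion([_rec(vg=10, body=900, housekeeping=True)]) == []

    def test_gland_enriched_flagged_gene_retained(self):
        rec = _rec(vg=2000, body=100, housekeeping=True)
        assert tp.housekeeping_exclusion([rec]) == [rec]

    def test_unflagged_records_untouched(self):
        recs = [_rec("a", 10, 900), _rec("b")]
        assert tp.housekeeping_exclusion(recs) == recs


class TestCopyClass:
    @pytest.fixture()
    def table(self):
        return OrthogroupTable(
            entries={
                "OG1": {FOCAL: ["g1"], "Bombyx_mori": ["b1"]},
                "OG2": {FOCAL: ["g2", "g3"]},
                "OG3": {FOCAL: ["g4", "g5", "g6"]},
            },
            species_list=[FOCAL, "Bombyx_mori"],
        )

    def test_single_copy(self, table):
        assert tp.copy_class("g1", table, {"g1"}, FOCAL) == tp.SINGLE_COPY

    def test_multi_copy_one_in_venom(self, table):
        assert tp.copy_class("g2", table, {"g2"}, FOCAL) == tp.MULTI_COPY_ONE_IN_VENOM

    def test_multi_copy_multi_in_venom(self, table):
        assert tp.copy_class("g4", table, {"g4", "g6"}, FOCAL) == tp.MULTI_COPY_MULTI_IN_VENOM

    def test_unclustered_gene(self, table):
        assert tp.copy_class("ghost", table, set(), FOCAL) == tp.NO_ORTHOGROUP


class TestMechanismLabel:
    def test_exhaustive_truth_table(self):
        """Every (stratum, copy class) pair agrees with the decision table."""
        strata = [1, 2, 3, 4, 5, FOCAL_EXCLUSIVE]
        for stratum, cls in itertools.product(strata, tp.COPY_CLASSES):
            if cls == tp.NO_ORTHOGROUP:
                continue
            got = tp.mechanism_label(stratum, cls, restricted_from=5)
            if stratum == FOCAL_EXCLUSIVE or stratum == 5:
                expected = tp.LINEAGE_SPECIFIC_ORPHAN
            elif cls == tp.SINGLE_COPY:
                expected = tp.CO_OPTION
            else:
                expected = tp.DUPLICATION_NEOFUNCTIONALIZATION
            assert got == expected, (stratum, cls)

    def test_no_orthogroup_is_orphan(self):
        assert (
            tp.mechanism_label(UNASSIGNED, tp.NO_ORTHOGROUP)
            == tp.LINEAGE_SPECIFIC_ORPHAN
        )

    @pytest.mark.parametrize(
        "stratum,cls",
        [
            (1, tp.NO_ORTHOGROUP),
            (UNASSIGNED, tp.SINGLE_COPY),
            (NOT_APPLICABLE, tp.SINGLE_COPY),
        ],
    )
    def test_inconsistent_pairs_rejected(self, stratum, cls):
        with pytest.raises(ValueError):
            tp.mechanism_label(stratum, cls, restricted_from=5)


class TestNaming:
    @pytest.mark.parametrize(
        "family,index,letter,expected",
        [
            ("Asilidin_3", 1, "a", "U-Asilidin_3-Dd1a"),
            ("Asilidin_2", 2, "a", "U-Asilidin_2-Dd2a"),
        ],
    )
    def test_nomenclature_pattern(self, family, index, letter, expected):
        assert tp.name_toxin("U", family, "Dd", index, letter) == expected

    def test_deterministic(self):
        a = tp.name_toxin("U", "Asilidin_3", "Dd", 1, "a")
        assert a == tp.name_toxin("U", "Asilidin_3", "Dd", 1, "a")

    @pytest.mark.parametrize(
        "kwargs", [{"gene_index": 0}, {"species_code": "Dda"}, {"family": ""}]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(activity_prefix="U", family="Asilidin_1", species_code="Dd",
                    gene_index=1, paralog_letter="a")
        base.update(kwargs)
        with pytest.raises(ValueError):
            tp.name_toxin(**base)

    def test_paralogs_share_index_with_successive_letters(self):
        recs = [
            tp.ToxinRecord("gA", "Asilidin_2", vg_tpm={"male": 900.0},
                           orthogroup_id="OG1"),
            tp.ToxinRecord("gB", "Asilidin_2", vg_tpm={"male": 500.0},
                           orthogroup_id="OG1"),
            tp.ToxinRecord("gC", "Asilidin_2", vg_tpm={"male": 100.0},
                           orthogroup_id="OG2"),
        ]
        tp.assign_names(recs)
        assert [r.name for r in recs] == [
            "U-Asilidin_2-Dd1a", "U-Asilidin_2-Dd1b", "U-Asilidin_2-Dd2a",
        ]


def test_classification_partitions_predominant_set(demo_tree, quiet_bundle):
    """Every predominant record gets exactly one copy class and mechanism."""
    from venomstrat import toxin_pipeline as tp_

    match = tp_.match_proteome(quiet_bundle.hits)
    recs = tp_.build_records(quiet_bundle.matrix, match.matched)
    pred = tp_.predominant_filter(recs)
    venom = {r.gene_id for r in recs}
    tp_.classify_records(pred, quiet_bundle.table, demo_tree, venom)
    assert all(r.copy_class in tp_.COPY_CLASSES for r in pred)
    assert all(r.mechanism in tp_.MECHANISMS for r in pred)
    from collections import Counter

    assert sum(Counter(r.copy_class for r in pred).values()) == len(pred)
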