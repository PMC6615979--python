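"""Generator determinism, noise calibration and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from venomstrat import formats_io as fio
from venomstrat import synthetic_data as sd
from venomstrat import toxin_pipeline as tp


class TestHistory:
    def test_no_loss_no_dup_one_gene_per_descendant(self, demo_tree):
        params = sd.SimulationParams(
            loss_prob=0.0, dup_prob=0.0,
            families_per_node={1: 5, 5: 5}, n_unassigned=0, n_toxins=3, n_te_toxins=1,
        )
        gene_sets, truth = sd.simulate_history(demo_tree, params, seed=1)
        for fam, birth in truth.families.items():
            members = [g for g in truth.genes.values() if g.family == fam]
            species = {g.species for g in members}
            assert len(members) == len(species)  # exactly one copy each
            if birth == 1:
                assert species == set(demo_tree.leaves)
            else:
                assert species == {sd.DEFAULT_FOCAL, "Proctacanthus_coquillettii"}

    def test_identical_seed_identical_truth(self, demo_tree):
        _, t1 = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=9)
        _, t2 = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=9)
        assert t1.to_json() == t2.to_json()

    def test_different_seed_differs(self, demo_tree):
        _, t1 = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=9)
        _, t2 = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=10)
        assert t1.to_json() != t2.to_json()

    def test_empty_focal_set_is_error(self, demo_tree):
        params = sd.SimulationParams(
            families_per_node={}, n_unassigned=0, n_toxins=0, n_te_toxins=0
        )
        with pytest.raises(ValueError, match="empty focal"):
            sd.simulate_history(demo_tree, params, seed=0)

    def test_toxins_are_surviving_focal_genes(self, quiet_bundle):
        truth = quiet_bundle.truth
        focal = set(truth.focal_gene_ids())
        assert truth.toxin_genes <= focal
        assert truth.te_genes <= truth.toxin_genes


class TestOrthogroups:
    def test_rate_zero_orthogroups_equal_families(self, demo_tree):
        _, truth = sd.simulate_history(
            demo_tree, sd.SimulationParams(loss_prob=0.0), seed=2
        )
        table = sd.simulate_orthogroups(truth)
        surviving_fams = {
            g.family for g in truth.genes.values() if not g.lost and g.family
        }
        assert table.n_orthogroups == len(surviving_fams)
        og_of = table.gene_to_orthogroup()
        for g in truth.genes.values():
            if g.family and not g.lost:
                assert g.gene_id in og_of
        for g in truth.unassigned_genes:
            assert g not in og_of

    def test_misassignment_count_within_binomial_ci(self, demo_tree):
        params = sd.SimulationParams(
            families_per_node={1: 120}, dup_prob=0.5, max_extra_copies=4,
            loss_prob=0.0, n_unassigned=0, n_toxins=5, n_te_toxins=0,
        )
        _, truth = sd.simulate_history(demo_tree, params, seed=3)
        clean = sd.simulate_orthogroups(truth)
        noisy = sd.simulate_orthogroups(truth, misassignment_rate=0.1, seed=99)
        og_clean = clean.gene_to_orthogroup()
        og_noisy = noisy.gene_to_orthogroup()
        n = len(og_clean)
        moved = sum(1 for g, og in og_clean.items() if og_noisy.get(g) != og)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.1)
        assert lo <= moved <= hi

    def test_empty_truth_is_error(self):
        truth = sd.SimulationTruth(
            families={}, genes={}, toxin_genes=set(), te_genes=set(),
            unassigned_genes=set(), params=sd.SimulationParams(), seed=0,
            focal=sd.DEFAULT_FOCAL,
        )
        with pytest.raises(ValueError):
            sd.simulate_orthogroups(truth)


class TestExpression:
    def test_enrichment_one_is_indistinguishable(self, demo_tree):
        """At enrichment 1 toxin and non-toxin venom-gland TPM come from the
        same distribution (Mann-Whitney, alpha = 0.01, ~500 genes)."""
        params = sd.SimulationParams(
            families_per_node={1: 470, 5: 30}, dup_prob=0.0, loss_prob=0.0,
            n_unassigned=0, n_toxins=100, n_te_toxins=0,
        )
        _, truth = sd.simulate_history(demo_tree, params, seed=4)
        matrix = sd.simulate_expression(truth, enrichment=1.0, seed=44)
        vg = matrix.tpm["vg_male"]
        tox = vg[[g in truth.toxin_genes for g in vg.index]]
        non = vg[[g not in truth.toxin_genes for g in vg.index]]
        p = stats.mannwhitneyu(tox, non).pvalue
        assert p > 0.01

    def test_strong_enrichment_gives_full_predominant_recall(self, demo_tree, quiet_bundle):
        match = tp.match_proteome(quiet_bundle.hits)
        recs = tp.build_records(quiet_bundle.matrix, match.matched)
        pred = {r.gene_id for r in tp.predominant_filter(recs)}
        assert pred == quiet_bundle.truth.toxin_genes

    def test_seed_reproducibility(self, demo_tree):
        _, truth = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=5)
        m1 = sd.simulate_expression(truth, seed=7)
        m2 = sd.simulate_expression(truth, seed=7)
        pd.testing.assert_frame_equal(m1.tpm, m2.tpm)

    def test_nonpositive_dispersion_rejected(self, demo_tree):
        _, truth = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=5)
        with pytest.raises(ValueError, match="dispersion"):
            sd.simulate_expression(truth, dispersion=0.0)

    def test_tpm_columns_sum_to_a_million(self, quiet_bundle):
        sums = quiet_bundle.matrix.tpm.sum(axis=0)
        assert np.allclose(sums, 1e6)


class TestProteome:
    def test_full_detection_matches_all_toxins(self, quiet_bundle):
        match = tp.match_proteome(quiet_bundle.hits)
        assert set(match.matched.values()) == quiet_bundle.truth.toxin_genes

    def test_partial_detection_within_binomial_ci(self, demo_tree):
        params = sd.SimulationParams(
            families_per_node={1: 150}, loss_prob=0.0, n_unassigned=0,
            n_toxins=100, n_te_toxins=0,
        )
        _, truth = sd.simulate_history(demo_tree, params, seed=6)
        hits = sd.simulate_proteome(truth, detection_prob=0.8, seed=66)
        lo, hi = stats.binom.ppf([0.005, 0.995], 100, 0.8)
        assert lo <= len(hits) <= hi

    def test_decoys_rejected_by_thresholds(self, demo_tree):
        _, truth = sd.simulate_history(demo_tree, sd.SimulationParams(), seed=6)
        hits = sd.simulate_proteome(truth, detection_prob=1.0, seed=66, n_decoys=20)
        match = tp.match_proteome(hits)
        assert all(q.startswith("VPdecoy") for q in match.unmatched)
        assert len(match.unmatched) == 20


class TestTEPlacement:
    def test_zero_te_budget_smaller_than_designated_is_error(self, quiet_bundle):
        with pytest.raises(ValueError):
            sd.simulate_te(quiet_bundle.truth, quiet_bundle.models, n_te=0)

    def test_exactly_designated_genes_overlap(self, quiet_bundle):
        from venomstrat import te_overlap

        hits = te_overlap.annotate_te(quiet_bundle.models, quiet_bundle.tes)
        assert {h.gene_id for h in hits} == quiet_bundle.truth.te_genes

    def test_determinism(self, quiet_bundle):
        a = sd.simulate_te(quiet_bundle.truth, quiet_bundle.models, seed=3)
        b = sd.simulate_te(quiet_bundle.truth, quiet_bundle.models, seed=3)
        assert a == b


class TestBundleRoundTrip:
    def test_all_emitted_files_reparse(self, demo_tree, bundle_dir, quiet_bundle):
        paths = bundle_dir["paths"]
        tree = fio.read_newick(paths["tree"], focal=sd.DEFAULT_FOCAL)
        assert set(tree.leaves) == set(demo_tree.leaves)

        table = fio.read_orthogroups(paths["orthogroups"])
        read_nonempty = {
            og: {sp: gs for sp, gs in m.items() if gs}
            for og, m in table.entries.items()
        }
        orig_nonempty = {
            og: {sp: list(gs) for sp, gs in m.items() if gs}
            for og, m in quiet_bundle.table.entries.items()
        }
        assert read_nonempty == orig_nonempty

        models = fio.read_gff3(paths["gff3"], species=sd.DEFAULT_FOCAL)
        assert {m.gene_id for m in models} == {m.gene_id for m in quiet_bundle.models}
        by_id = {m.gene_id: m for m in models}
        for m in quiet_bundle.models:
            assert by_id[m.gene_id].exons == m.exons

        tes = fio.read_repeat_annotations(paths["repeats"])
        assert [(t.seq_id, t.interval, t.te_class) for t in tes] == [
            (t.seq_id, t.interval, t.te_class) for t in quiet_bundle.tes
        ]

        hits = fio.read_similarity_hits(paths["hits"], quiet_bundle.query_lengths)
        assert {h.query_id for h in hits} == set(quiet_bundle.query_lengths)

    def test_write_is_deterministic(self, tmp_path, quiet_bundle):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.write_bundle(quiet_bundle, d1)
        sd.write_bundle(quiet_bundle, d2)
        for rel in ("orthogroups.tsv", "genes.gff3", "repeats.out", "truth.json"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
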