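"""PCR-error screening: clustering, the singleton rule, representative
selection and the per-individual bookkeeping table."""

import numpy as np
import pytest

from transpoly import simulate
from transpoly.screen import (
    ClusterAssignment,
    assign_clusters,
    screen_singletons,
    select_representatives,
    tabulate_forms,
)
from transpoly.seqio import Alignment, CloneRecord

from conftest import make_alignment


def clones(*items, length=60):
    """items: (barcode, clone, mutations). Builds a one-cluster
    alignment of labeled clones from a uniform backbone, so every
    listed mutation is guaranteed to differ from the backbone."""
    base = np.array(["A"] * length)
    recs = []
    for barcode, clone_no, muts in items:
        s = base.copy()
        for pos, b in muts:
            s[pos] = b
        recs.append(
            CloneRecord(
                id=f"{barcode}-{clone_no}.Gmo.Ice",
                sequence="".join(s),
                barcode=barcode,
                clone_number=clone_no,
                species="Gmo",
                locality="Ice",
            )
        )
    return Alignment(recs)


def one_cluster(aln):
    return ClusterAssignment({r.id: "C1" for r in aln.records}, "user")


class TestAssignClusters:
    def test_two_divergent_groups_split_at_threshold(self, rng):
        base = rng.choice(list("ACGT"), size=100)
        other = base.copy()
        for pos in rng.choice(100, 20, replace=False):  # 20% divergence
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        aln = make_alignment(["".join(base)] * 2 + ["".join(other)] * 2)
        cl = assign_clusters(aln, "auto", 0.10)
        assert len(cl.cluster_names) == 2
        assert cl["s0"] == cl["s1"] and cl["s2"] == cl["s3"]

    def test_identical_sequences_one_cluster(self):
        aln = make_alignment(["ACGTACGT"] * 4)
        assert len(assign_clusters(aln, "auto", 0.10).cluster_names) == 1

    def test_threshold_out_of_range_raises(self):
        aln = make_alignment(["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            assign_clusters(aln, "auto", 1.5)

    def test_recovers_simulated_paralogs_exactly(self, balancing_dataset):
        ds = balancing_dataset
        cl = assign_clusters(ds.alignment, "auto", 0.10)
        assert len(cl.cluster_names) == ds.config.n_paralogs
        # one-to-one between inferred clusters and true paralogs
        mapping = {}
        for cid in ds.alignment.ids:
            mapping.setdefault(cl[cid], set()).add(ds.paralog_of(cid))
        assert all(len(v) == 1 for v in mapping.values())


class TestScreenSingletons:
    def test_nonrecurrent_singleton_masked_to_majority(self):
        aln = clones(
            ("111111", 1, []),
            ("111111", 2, [(50, "T")]),
            ("111111", 3, []),
            ("222222", 1, []),
            ("222222", 2, []),
        )
        report, corrected = screen_singletons(aln, one_cluster(aln))
        masked = [d for d in report.decisions if d.decision == "error_masked"]
        assert len(masked) == 1
        assert masked[0].clone_id == "111111-2.Gmo.Ice" and masked[0].column == 50
        assert corrected["111111-2.Gmo.Ice"].sequence == aln[0].sequence

    def test_recurrent_singleton_retained_as_snp(self):
        aln = clones(
            ("111111", 1, []),
            ("111111", 2, [(50, "T")]),
            ("111111", 3, []),
            ("222222", 1, [(50, "T")]),
            ("222222", 2, []),
            ("222222", 3, []),
        )
        report, corrected = screen_singletons(aln, one_cluster(aln))
        assert report.n_masked == 0
        retained = {d.clone_id for d in report.decisions if d.decision == "snp_retained"}
        assert "111111-2.Gmo.Ice" in retained and "222222-1.Gmo.Ice" in retained
        ev = [d.evidence_individuals for d in report.decisions
              if d.clone_id == "111111-2.Gmo.Ice"][0]
        assert "222222" in ev
        assert corrected["111111-2.Gmo.Ice"].sequence == aln[1].sequence

    def test_identical_clones_no_decisions(self):
        aln = clones(("111111", 1, []), ("111111", 2, []), ("111111", 3, []))
        report, corrected = screen_singletons(aln, one_cluster(aln))
        assert report.decisions == []
        assert [r.sequence for r in corrected.records] == [r.sequence for r in aln.records]

    def test_single_clone_groups_never_masked(self):
        aln = clones(("111111", 1, [(10, "T")]), ("222222", 1, []))
        report, corrected = screen_singletons(aln, one_cluster(aln))
        assert report.n_masked == 0
        assert corrected[0].sequence == aln[0].sequence

    def test_gap_singleton_is_maskable_fifth_state(self):
        aln = clones(
            ("111111", 1, []),
            ("111111", 2, [(30, "-")]),
            ("111111", 3, []),
            ("222222", 1, []),
            ("222222", 2, []),
        )
        report, corrected = screen_singletons(aln, one_cluster(aln))
        assert report.n_masked == 1
        assert "-" not in corrected["111111-2.Gmo.Ice"].sequence

    def test_two_clone_disagreement_masks_cluster_minority(self):
        # I1's two clones disagree at 40; cluster majority decides
        aln = clones(
            ("111111", 1, []),
            ("111111", 2, [(40, "T")]),
            ("222222", 1, []),
            ("222222", 2, []),
        )
        report, corrected = screen_singletons(aln, one_cluster(aln))
        masked = [d for d in report.decisions if d.decision == "error_masked"]
        assert [d.clone_id for d in masked] == ["111111-2.Gmo.Ice"]
        assert corrected["111111-2.Gmo.Ice"].sequence == aln[0].sequence

    def test_masking_is_idempotent(self, balancing_dataset):
        ds = balancing_dataset
        cl = assign_clusters(ds.alignment, "auto", 0.10)
        report1, corrected1 = screen_singletons(ds.alignment, cl)
        report2, corrected2 = screen_singletons(corrected1, cl)
        assert report2.n_masked == 0
        assert [r.sequence for r in corrected2.records] == [
            r.sequence for r in corrected1.records
        ]

    def test_missing_barcode_raises(self):
        aln = make_alignment(["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="barcode"):
            screen_singletons(aln, one_cluster(aln))


class TestRepresentatives:
    def test_identical_clones_collapse_to_consensus(self):
        aln = clones(("111111", 1, []), ("111111", 2, []), ("111111", 3, []))
        report, corrected = screen_singletons(aln, one_cluster(aln))
        reps = select_representatives(corrected, report)
        assert reps.n == 1
        assert reps.records[0].id == "111111-cons.Gmo.Ice"
        assert reps.records[0].is_consensus

    def test_three_clones_three_clusters_all_kept(self):
        # the 152027-style individual: one clone in each of three paralogs
        aln = clones(("152027", 1, []), ("152027", 2, []), ("152027", 3, []))
        cl = ClusterAssignment(
            {aln[0].id: "C1", aln[1].id: "C2", aln[2].id: "C3"}, "user"
        )
        report, corrected = screen_singletons(aln, cl)
        reps = select_representatives(corrected, report)
        assert reps.n == 3
        assert sorted(report.representative_clusters.values()) == ["C1", "C2", "C3"]

    def test_error_free_pipeline_recovers_true_form_count(self):
        cfg = simulate.SimulationConfig(seed=5, error_rate=0.0, within_species_theta=False)
        ds = simulate.simulate_dataset(cfg)
        cl = assign_clusters(ds.alignment, "auto", 0.10)
        report, corrected = screen_singletons(ds.alignment, cl)
        reps = select_representatives(corrected, report)
        # with no PCR errors, distinct corrected forms per individual ==
        # distinct true clone sequences per individual
        per_ind: dict[str, set] = {}
        for r in ds.alignment.records:
            per_ind.setdefault(r.barcode, set()).add(r.sequence)
        true_forms = sum(len(v) for v in per_ind.values())
        assert reps.n == true_forms

    def test_consensus_ids_unique_across_clusters(self, neutral_dataset):
        ds = neutral_dataset
        cl = assign_clusters(ds.alignment, "auto", 0.10)
        report, corrected = screen_singletons(ds.alignment, cl)
        reps = select_representatives(corrected, report)
        assert len(set(reps.ids)) == reps.n


class TestTabulateForms:
    def test_totals_row_counts_individuals_and_clones(self):
        aln = clones(
            ("111111", 1, []), ("111111", 2, []),
            ("222222", 1, [(5, "T")]), ("222222", 2, [(5, "T")]),
        )
        report, corrected = screen_singletons(aln, one_cluster(aln))
        select_representatives(corrected, report)
        tab = tabulate_forms(report)
        total = tab.iloc[-1]
        assert total["n_clones"] == 4
        assert total["origin"] == "2 individuals"
        assert total["n_forms"] == 2

    def test_empty_input_gives_empty_table(self):
        from transpoly.screen import ScreenReport

        tab = tabulate_forms(
            ScreenReport(decisions=[], groups={}, clusters=one_cluster(make_alignment(["A"])))
        )
        assert tab.empty

    def test_simulated_truth_forms_match_rows(self):
        cfg = simulate.SimulationConfig(seed=9, error_rate=0.0, within_species_theta=False)
        ds = simulate.simulate_dataset(cfg)
        cl = assign_clusters(ds.alignment, "auto", 0.10)
        report, corrected = screen_singletons(ds.alignment, cl)
        select_representatives(corrected, report)
        tab = tabulate_forms(report).iloc[:-1]
        truth = {}
        for rec in ds.alignment.records:
            truth.setdefault(rec.barcode, set()).add(rec.sequence)
        for _, row in tab.iterrows():
            assert row["n_forms"] == len(truth[row["barcode"]])
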