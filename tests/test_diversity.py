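"""Subsampling, OTU dereplication, taxonomy, proportions, alpha diversity."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primerscope import datasets
from primerscope import diversity as div
from primerscope.seqio import SequenceRecord


def _reads(seqs, prefix="r"):
    return [SequenceRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)]


class TestSubsample:
    def test_auto_depth_is_smallest_sample(self):
        samples = {"s1": _reads(["AC"] * 30), "s2": _reads(["AC"] * 12),
                   "s3": _reads(["AC"] * 50)}
        out = div.subsample_reads(samples, "auto", seed=1)
        assert {k: len(v) for k, v in out.items()} == {"s1": 12, "s2": 12, "s3": 12}

    def test_depth_equal_to_size_is_identity_multiset(self):
        reads = _reads(["AAA", "AAT", "AAA", "CCC"])
        out = div.subsample_reads({"s": reads}, 4, seed=0)
        assert Counter(r.residues for r in out["s"]) == Counter(r.residues for r in reads)

    def test_same_seed_reproducible(self):
        samples = {"s": _reads([f"{'ACGT'[i % 4]}" * 5 for i in range(40)])}
        a = div.subsample_reads(samples, 10, seed=7)
        b = div.subsample_reads(samples, 10, seed=7)
        assert [r.id for r in a["s"]] == [r.id for r in b["s"]]

    def test_membership_preserved(self):
        reads = _reads(["AAA"] * 5 + ["TTT"] * 3)
        out = div.subsample_reads({"s": reads}, 6, seed=3)["s"]
        pool = Counter(r.residues for r in reads)
        assert not Counter(r.residues for r in out) - pool

    def test_overdeep_request_names_sample(self):
        with pytest.raises(ValueError, match="shallow"):
            div.subsample_reads({"deep": _reads(["A"] * 9), "shallow": _reads(["A"] * 3)}, 5)


class TestDereplicate:
    def test_exact_clusters(self):
        table = div.dereplicate(_reads(["AAA", "AAA", "AAT"]))
        assert table.observed_otus == 2
        assert sorted(c for _, c in table.otus.values()) == [1, 2]

    def test_all_distinct(self):
        table = div.dereplicate(_reads(["AA", "AT", "AC", "AG"]))
        assert table.observed_otus == 4
        assert all(c == 1 for _, c in table.otus.values())

    def test_representative_is_first_occurrence(self):
        table = div.dereplicate(_reads(["GGG", "AAA", "GGG"]))
        assert table.otus["OTU1"][0] == "GGG"

    @given(st.lists(st.sampled_from(["AAA", "AAT", "ATT", "TTT"]), min_size=1, max_size=40))
    def test_counts_sum_to_reads(self, seqs):
        table = div.dereplicate(_reads(seqs))
        assert table.total_reads == len(seqs)
        assert table.observed_otus == len(set(seqs))


class TestAssignTaxonomy:
    REF = [SequenceRecord("Lactobacillus_fictus", "ACGTACGTACGTACGTACGTACGTACGT",
                          "Lactobacillus fictus"),
           SequenceRecord("Weissella_ficta", "TGCATGCATGCATGCATGCATGCATGCA",
                          "Weissella ficta")]

    def test_exact_match_full_identity(self):
        table = div.dereplicate(_reads(["ACGTACGTACGTACGTACGTACGTACGT"]))
        (assignment,) = div.assign_taxonomy(table, self.REF).values()
        assert assignment.label == "Lactobacillus fictus"
        assert assignment.identity == 1.0 and not assignment.tie

    def test_below_threshold_unassigned(self):
        table = div.dereplicate(_reads(["ACCTACCTACCTACCTACCTACCTACCT"]))
        (assignment,) = div.assign_taxonomy(table, self.REF, min_identity=0.97).values()
        assert assignment.label == "unassigned"

    def test_tie_goes_to_first_reference_with_flag(self):
        ref = [SequenceRecord("A_a", "AAAAAAAACC", "Alpha alpha"),
               SequenceRecord("B_b", "CCAAAAAAAA", "Beta beta")]
        table = div.dereplicate(_reads(["AAAAAAAA"]))
        (assignment,) = div.assign_taxonomy(table, ref, min_identity=0.5).values()
        assert assignment.label == "Alpha alpha"
        assert assignment.tie

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            div.assign_taxonomy(div.dereplicate(_reads(["AAA"])), [])


def _table_from_counts(counts, sample="s"):
    reads = []
    for i, (seq, n) in enumerate(counts.items()):
        reads += [SequenceRecord(f"{sample}r{i}_{k}", seq) for k in range(n)]
    return div.dereplicate(reads, sample)


class TestTargetProportion:
    def _setup(self, target_count, other_count):
        target_seq, other_seq = "ACGT" * 6, "TGCA" * 6
        table = _table_from_counts({target_seq: target_count, other_seq: other_count})
        assignments = {}
        for oid, (rep, _) in table.otus.items():
            label = "Lactobacillus fictus" if rep == target_seq else "Escherichia coli"
            assignments[oid] = div.TaxonAssignment(label, 1.0)
        return assignments, table

    def test_survey_arithmetic(self):
        assignments, table = self._setup(356, 2551 - 356)
        tp = div.target_proportion(assignments, table, {"Lactobacillus fictus"})
        assert (tp.target_reads, tp.total_reads) == (356, 2551)
        assert tp.percent == pytest.approx(100 * 356 / 2551)
        assert tp.display == "14"

    def test_sub_percent_display(self):
        assignments, table = self._setup(60, 7696 - 60)
        tp = div.target_proportion(assignments, table, {"Lactobacillus"})  # genus match
        assert tp.display == "0.8"

    def test_zero_targets(self):
        assignments, table = self._setup(0, 100)
        tp = div.target_proportion(assignments, table, {"Lactobacillus fictus"})
        assert tp.target_reads == 0 and tp.percent == 0.0

    @pytest.mark.parametrize("value,display", [
        (73.17, "73"), (13.95, "14"), (0.78, "0.8"), (0.06, "0.1"), (1.0, "1")])
    def test_display_rounding(self, value, display):
        assert div.format_percent(value) == display


class TestAbundanceAndPresence:
    def test_proportions_consistent_with_target_proportion(self):
        target_seq, other_seq = "ACGT" * 6, "TGCA" * 6
        table = _table_from_counts({target_seq: 30, other_seq: 70})
        assignments = {oid: div.TaxonAssignment(
            "Lactobacillus fictus" if rep == target_seq else "Escherichia coli", 1.0)
            for oid, (rep, _) in table.otus.items()}
        abundance, presence, richness = div.abundance_and_presence({"c1": (assignments, table)})
        tp = div.target_proportion(assignments, table, {"Lactobacillus fictus"})
        assert abundance.loc["Lactobacillus fictus", "c1"] == pytest.approx(tp.percent)
        assert bool(presence.loc["Lactobacillus fictus", "c1"])
        assert richness["c1"] == 2

    def test_bundled_survey_richness(self):
        abundance = datasets.species_abundance()
        _, richness = div.presence_and_richness(abundance)
        assert richness["Sample 1/L5"] == 9
        assert richness["Sample 2/L5"] == 12
        assert richness["Sample 3/L5"] == 5

    def test_all_zero_column(self):
        df = pd.DataFrame({"empty": [0.0, 0.0], "full": [1.0, 2.0]},
                          index=["Taxon a", "Taxon b"])
        presence, richness = div.presence_and_richness(df)
        assert richness["empty"] == 0
        assert not presence["empty"].any()


class TestAlphaDiversity:
    def test_uniform_four_otus(self):
        table = _table_from_counts({"AAAA": 5, "CCCC": 5, "GGGG": 5, "TTTT": 5})
        result = div.alpha_diversity(table)
        assert result.observed_otus == 4
        assert result.shannon == pytest.approx(math.log(4))

    def test_single_otu_zero(self):
        result = div.alpha_diversity(_table_from_counts({"AAAA": 50}))
        assert result.shannon == 0.0

    def test_log_base_flag(self):
        table = _table_from_counts({"AAAA": 5, "CCCC": 5})
        assert div.alpha_diversity(table, base=2).shannon == pytest.approx(1.0)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            k = rng.integers(1, 8)
            counts = rng.integers(1, 50, size=k)
            s = div.shannon_index(counts)
            assert -1e-12 <= s <= math.log(k) + 1e-12

    def test_rarefaction_monotone_and_matches_closed_form(self):
        table = _table_from_counts({"AAAA": 20, "CCCC": 10, "GGGG": 2})
        result = div.alpha_diversity(table, rarefaction_depths=[2, 8, 16, 32],
                                     replicates=100, seed=4)
        means = [m for _, m, _ in result.rarefaction_curve]
        assert means == sorted(means)
        counts = list(table.counts().values())
        for depth, mean, sd in result.rarefaction_curve:
            se = sd / math.sqrt(100)
            expected = div.expected_rarefaction(counts, depth)
            assert abs(mean - expected) <= max(3 * se, 0.05)

    def test_overdeep_point_skipped(self):
        table = _table_from_counts({"AAAA": 4})
        with pytest.warns(UserWarning):
            result = div.alpha_diversity(table, rarefaction_depths=[10], replicates=3)
        assert result.rarefaction_curve == []
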