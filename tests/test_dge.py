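"""Welch testing, fold-change thresholds and the consensus call rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenonet import (DatasetEvidence, collapse_probes_to_gene,
                      cross_dataset_consensus, dataset_consensus,
                      detection_filter, linear_fold_change, per_gene_call,
                      stringency_counts, welch_test)
from phenonet.dge import (DOWN, FILTERED, NONE, UP, consensus_calls,
                          differential_table, evidence_table)

from conftest import make_dataset


class TestWelch:
    def test_identical_groups_null(self):
        res = welch_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 or abs(res.t) < 1e-12
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # means 2.5 vs 5, variances 5/3 and 20/3: t = -2.5/sqrt(25/12)
        res = welch_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.t == pytest.approx(-1.7320508, abs=1e-6)
        assert res.df == pytest.approx(4.4117647, abs=1e-6)
        assert 0 < res.p < 1

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.1], [4.0, 0.5, 2.2, 9.0]
        assert welch_test(a, b).t == pytest.approx(-welch_test(b, a).t)

    def test_zero_variance_unequal_means_warns(self):
        with pytest.warns(UserWarning):
            res = welch_test([1, 1, 1], [2, 2, 2])
        assert res.p > 0 and res.p < 1e-300

    def test_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(1, 2, size=9)
        res = welch_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestFoldChange:
    def test_identity(self):
        assert linear_fold_change([3, 3], [3, 3], "linear") == pytest.approx(1.0)

    def test_linear_means(self):
        assert linear_fold_change([30, 50], [5, 15], "linear") == pytest.approx(4.0)

    def test_log2_scale(self):
        assert linear_fold_change([3, 3], [1, 1], "log2") == pytest.approx(4.0)

    def test_reciprocal(self):
        fc = linear_fold_change([8, 10], [2, 3], "linear")
        rc = linear_fold_change([2, 3], [8, 10], "linear")
        assert fc * rc == pytest.approx(1.0)

    def test_nonpositive_linear_rejected(self):
        with pytest.raises(ValueError):
            linear_fold_change([1, -2], [1, 1], "linear")


class TestDetectionFilter:
    def _ds(self, detection):
        values = {g: [1.0] * 4 for g in detection}
        return make_dataset(values, ["case", "case", "control", "control"],
                            view="mas5-like", scale="linear", detection=detection)

    def test_requires_present_in_both_groups(self):
        ds = self._ds({
            "all_absent": list("AAAA"),
            "case_only": list("PPAA"),
            "ctrl_only": list("AAPP"),
            "one_each": list("PAAP"),
            "all_present": list("PPPP"),
        })
        assert detection_filter(ds) == {"one_each", "all_present"}

    def test_missing_detection_rejected(self):
        ds = make_dataset({"g": [1, 2, 3, 4]},
                          ["case", "case", "control", "control"])
        with pytest.raises(ValueError):
            detection_filter(ds)


class TestPerGeneCall:
    @pytest.mark.parametrize("fc,p,expected", [
        (2.0, 0.05, UP),        # both thresholds inclusive
        (0.5, 0.04, DOWN),
        (3.0, 0.2, NONE),
        (1.9, 0.01, NONE),
        (0.51, 0.01, NONE),
        (4.0, 0.001, UP),
    ])
    def test_threshold_rules(self, fc, p, expected):
        assert per_gene_call(fc, p) == expected


class TestDatasetConsensus:
    @pytest.mark.parametrize("rma,mas5,grade", [
        (UP, UP, "U2"), (UP, NONE, "U1"), (NONE, UP, "U1"),
        (DOWN, DOWN, "D2"), (DOWN, NONE, "D1"), (NONE, DOWN, "D1"),
        (NONE, NONE, "none"), (UP, DOWN, "conflict"), (DOWN, UP, "conflict"),
        (UP, FILTERED, "U1"), (NONE, FILTERED, "none"),
    ])
    def test_grade_table(self, rma, mas5, grade):
        assert dataset_consensus(rma, mas5) == grade


# --- literal brute-force interpreter of the published selection text -------

PATTERNS = [(UP, UP), (UP, NONE), (NONE, UP), (NONE, NONE),
            (DOWN, DOWN), (DOWN, NONE), (NONE, DOWN),
            (UP, DOWN), (DOWN, UP), None]  # None = unmeasured


def literal_rule(patterns):
    """Direct transcription of the cross-dataset selection rules."""
    measured = [p for p in patterns if p is not None]
    down_anywhere = any(DOWN in p for p in measured)
    up_anywhere = any(UP in p for p in measured)
    up = (not down_anywhere) and (
        (UP, UP) in measured
        or ((UP, NONE) in measured and (NONE, UP) in measured))
    down = (not up_anywhere) and (
        (DOWN, DOWN) in measured
        or ((DOWN, NONE) in measured and (NONE, DOWN) in measured))
    if up:
        return "up"
    if down:
        return "down"
    return "none"


def evidence_from_patterns(patterns):
    out = []
    for i, p in enumerate(patterns):
        if p is None:
            out.append(DatasetEvidence(f"d{i}", measured=False))
        else:
            out.append(DatasetEvidence(f"d{i}", p[0], p[1]))
    return out


class TestCrossDatasetConsensus:
    def test_single_double_support(self):
        assert cross_dataset_consensus(evidence_from_patterns(
            [(UP, UP), (NONE, NONE), (NONE, NONE)])) == "up"

    def test_split_orientation_support(self):
        assert cross_dataset_consensus(evidence_from_patterns(
            [(UP, NONE), (NONE, UP)])) == "up"

    def test_same_orientation_twice_is_not_enough(self):
        # the rule demands [+,0] in one dataset AND [0,+] in another
        assert cross_dataset_consensus(evidence_from_patterns(
            [(UP, NONE), (UP, NONE)])) == "none"

    def test_any_down_evidence_blocks_up(self):
        assert cross_dataset_consensus(evidence_from_patterns(
            [(UP, UP), (DOWN, NONE)])) == "none"

    def test_all_unmeasured_rejected(self):
        with pytest.raises(ValueError):
            cross_dataset_consensus(evidence_from_patterns([None, None]))

    @pytest.mark.parametrize("n_datasets", [1, 2, 3])
    def test_matches_literal_interpreter(self, n_datasets):
        for patterns in itertools.product(PATTERNS, repeat=n_datasets):
            if all(p is None for p in patterns):
                continue
            got = cross_dataset_consensus(evidence_from_patterns(patterns))
            assert got == literal_rule(patterns), patterns

    def test_order_invariance(self):
        pats = [(UP, UP), (NONE, UP), (DOWN, DOWN), None]
        base = cross_dataset_consensus(evidence_from_patterns(pats))
        for perm in itertools.permutations(pats):
            assert cross_dataset_consensus(
                evidence_from_patterns(list(perm))) == base

    @given(st.lists(st.sampled_from(PATTERNS[:-1]), min_size=1, max_size=5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_dilution_properties(self, patterns):
        base = cross_dataset_consensus(evidence_from_patterns(patterns))
        # appending a silent dataset never changes the final call
        widened = patterns + [(NONE, NONE)]
        assert cross_dataset_consensus(evidence_from_patterns(widened)) == base
        # appending downward evidence kills an up call
        if base == "up":
            killed = patterns + [(DOWN, NONE)]
            assert cross_dataset_consensus(
                evidence_from_patterns(killed)) != "up"


class TestCollapseProbes:
    def test_any_up_no_down(self):
        calls = {"p1": UP, "p2": NONE}
        assert collapse_probes_to_gene(calls, {"p1": "g", "p2": "g"}) == {"g": UP}

    def test_conflicting_probes_cancel(self):
        calls = {"p1": UP, "p2": DOWN}
        assert collapse_probes_to_gene(calls, {"p1": "g", "p2": "g"}) == {"g": NONE}

    def test_unmapped_probes_dropped(self):
        assert collapse_probes_to_gene({"p1": UP}, {"p1": None}) == {}

    def test_multimapped_probe_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes_to_gene({"p1": UP}, {"p1": {"g1", "g2"}})


class TestStringency:
    def _table(self):
        return {
            "g_all": [DatasetEvidence(f"d{i}", UP, UP) for i in range(3)],
            "g_two": [DatasetEvidence("d0", UP, UP), DatasetEvidence("d1", UP, UP),
                      DatasetEvidence("d2", NONE, NONE)],
            "g_combo": [DatasetEvidence("d0", UP, NONE),
                        DatasetEvidence("d1", NONE, UP),
                        DatasetEvidence("d2", NONE, NONE)],
            "g_down": [DatasetEvidence("d0", DOWN, DOWN),
                       DatasetEvidence("d1", NONE, NONE),
                       DatasetEvidence("d2", NONE, NONE)],
        }

    def test_k1_matches_base_rule(self):
        table = self._table()
        n_up, n_down = stringency_counts(table, 1)
        finals = [cross_dataset_consensus(e) for e in table.values()]
        assert n_up == finals.count("up")
        assert n_down == finals.count("down")

    def test_counts_non_increasing_in_k(self):
        table = self._table()
        counts = [stringency_counts(table, k) for k in range(1, 5)]
        for (u1, d1), (u2, d2) in zip(counts, counts[1:]):
            assert u2 <= u1 and d2 <= d1

    def test_k_beyond_datasets_gives_zero(self):
        assert stringency_counts(self._table(), 4) == (0, 0)

    def test_fully_replicated_genes_are_flat_in_k(self):
        table = {"g": [DatasetEvidence(f"d{i}", UP, UP) for i in range(3)]}
        assert all(stringency_counts(table, k) == (1, 0) for k in (1, 2, 3))


class TestStudyLevel:
    def test_differential_table_matches_scalar_path(self):
        rng = np.random.default_rng(11)
        values = {f"g{i}": rng.normal(8, 1, size=8) for i in range(5)}
        ds = make_dataset(values, ["case"] * 4 + ["control"] * 4)
        tab = differential_table(ds)
        for gene in values:
            ref = welch_test(ds.values.loc[gene, ds.case_columns],
                             ds.values.loc[gene, ds.control_columns])
            assert tab.at[gene, "t"] == pytest.approx(ref.t)
            assert tab.at[gene, "p"] == pytest.approx(ref.p)

    def test_label_swap_maps_up_to_down(self):
        from phenonet import StudyConfig, simulate_expression_studies
        cfg = StudyConfig(n_genes=200, n_datasets=2, seed=5)
        pairs, _ = simulate_expression_studies(cfg)
        flipped = []
        for rma, mas5 in pairs:
            swap = {"case": "control", "control": "case"}
            r = make_flip(rma, swap)
            m = make_flip(mas5, swap)
            flipped.append((r, m))
        base = consensus_calls(pairs)
        mirror = consensus_calls(flipped)
        up = set(base.index[base["final"] == "up"])
        down_m = set(mirror.index[mirror["final"] == "down"])
        assert up == down_m


def make_flip(ds, swap):
    import copy
    out = copy.copy(ds)
    out.groups = ds.groups.map(swap)
    return out
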