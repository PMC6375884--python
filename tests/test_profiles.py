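"""Trajectory-profile enumeration, assignment and memory categorization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memoryseq as m


def enumerate_brute_force(T, c=1):
    """Independent enumeration of non-flat step vectors."""
    return [s for s in itertools.product(range(-c, c + 1), repeat=T - 1)
            if any(x != 0 for x in s)]


class TestEnumeration:
    @pytest.mark.parametrize("T, expected", [(2, 2), (3, 8), (4, 26), (5, 80)])
    def test_counts_match_brute_force(self, T, expected):
        profs = m.enumerate_profiles(T)
        assert len(profs) == expected == len(enumerate_brute_force(T))

    def test_ids_are_a_bijection_onto_nonflat_vectors(self):
        profs = m.enumerate_profiles(4)
        assert [p.id for p in profs] == list(range(26))
        assert len({p.steps for p in profs}) == 26
        assert all(any(s != 0 for s in p.steps) for p in profs)

    def test_values_are_cumulative_steps(self):
        for p in m.enumerate_profiles(4):
            assert p.values[0] == 0
            for t in range(1, 4):
                assert p.values[t] - p.values[t - 1] == p.steps[t - 1]

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            m.enumerate_profiles(1)

    @pytest.mark.parametrize("pid, values", [
        (0, (0, -1, -2, -3)),
        (18, (0, 1, 0, 0)),
        (21, (0, 1, 1, 1)),
        (22, (0, 1, 1, 2)),
        (25, (0, 1, 2, 3)),
    ])
    def test_canonical_numbering_anchors(self, pid, values):
        by_id = {p.id: p.values for p in m.enumerate_profiles(4)}
        assert by_id[pid] == values


class TestLogRatioTransform:
    @pytest.mark.parametrize("traj, pc, expected", [
        ((10, 20, 40, 80), 0, (0, 1, 2, 3)),
        ((5, 5, 5, 5), 1, (0, 0, 0, 0)),
        ((0, 7, 0, 0), 1, (0, 3, 0, 0)),
    ])
    def test_known_values(self, traj, pc, expected):
        np.testing.assert_allclose(m.log_ratio_transform(traj, pc), expected)

    def test_rejects_negative_abundance(self):
        with pytest.raises(ValueError):
            m.log_ratio_transform([1, -2, 3])


class TestAssignment:
    def test_monotone_vectors(self):
        profs = m.enumerate_profiles(4)
        pid, corr = m.assign_profile([0, 1, 2, 3], profs)
        assert pid == 25 and corr == pytest.approx(1.0)
        pid, corr = m.assign_profile([0, -1, -2, -3], profs)
        assert pid == 0 and corr == pytest.approx(1.0)

    def test_all_zero_unassignable(self):
        pid, corr = m.assign_profile([0, 0, 0, 0], m.enumerate_profiles(4))
        assert pid is None and np.isnan(corr)

    def test_every_profile_is_its_own_best_match(self):
        profs = m.enumerate_profiles(4)
        for p in profs:
            pid, corr = m.assign_profile(np.array(p.values, float), profs)
            assert pid == p.id
            assert corr == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 100), st.floats(-5, 5), st.integers(0, 25))
    def test_positive_affine_invariance(self, scale, shift, pid):
        profs = m.enumerate_profiles(4)
        v = np.array(profs[pid].values, float)
        base = m.assign_profile(v, profs)
        scaled = m.assign_profile(scale * v + shift, profs)
        assert scaled[0] == base[0]
        assert scaled[1] == pytest.approx(base[1])


class TestCategories:
    @pytest.mark.parametrize("values, expected", [
        ((0, 1, 2, 3), "lineage"),
        ((0, 0, 1, 2), "dosage"),
        ((0, 1, 0, 0), "initial"),
        ((0, -1, 0, 0), "initial"),
        ((0, 1, 1, 1), "stable"),
        ((0, 1, 2, 2), "stable"),
        ((0, 1, 1, 2), "accumulated"),
        ((0, 1, -1, 0), "other-memory"),
    ])
    def test_shape_predicates(self, values, expected):
        assert m.categorize_values(values) == expected

    def test_paper_profile_lists_map_to_their_categories(self):
        by_id = {p.id: p.values for p in m.enumerate_profiles(4)}
        expected = {(21, 24): "stable", (22,): "accumulated", (25,): "lineage",
                    (7, 18): "initial", (9, 10, 12, 13, 15, 16): "dosage"}
        for ids, cat in expected.items():
            for pid in ids:
                assert m.categorize_values(by_id[pid]) == cat

    def test_categories_partition_memory_genes(self):
        cats = {m.categorize_values(p.values) for p in m.enumerate_profiles(4)}
        assert cats <= {"dosage", "initial", "stable", "accumulated",
                        "lineage", "other-memory"}

    def test_non_memory_and_unassigned(self):
        assert m.categorize_memory(25, False) == "non-memory"
        assert m.categorize_memory(None, True) == "other-memory"
        assert m.categorize_memory(25, True) == "lineage"


def _de_stub(status_by_contrast, genes=("g1",)):
    out = {}
    for contrast, statuses in status_by_contrast.items():
        out[contrast] = pd.DataFrame(
            {"status": list(statuses)}, index=pd.Index(genes, name="gene_id"))
    return out


class TestMemoryFlag:
    CONTRASTS = ("S1_vs_R0", "R3_vs_R0", "S4_vs_R0", "R3_vs_S1", "S4_vs_S1")

    def _flags(self, pattern, rule="any"):
        de = _de_stub(dict(zip(self.CONTRASTS, [[s] for s in pattern])))
        return m.flag_memory(de, rule=rule).iloc[0]

    def test_differs_in_one_later_contrast_is_memory(self):
        row = self._flags(["up", "unchanged", "unchanged", "unchanged", "up"])
        assert row["is_memory"]

    def test_identical_repeated_response_is_not_memory(self):
        row = self._flags(["up", "unchanged", "unchanged", "unchanged", "unchanged"])
        assert not row["is_memory"]

    def test_dosage_pattern_is_memory(self):
        # flat at the first stress, induced only after repeated cycles
        row = self._flags(["unchanged", "unchanged", "up", "unchanged", "up"])
        assert row["is_memory"]

    def test_all_rule_requires_both_later_contrasts(self):
        pattern = ["up", "unchanged", "unchanged", "unchanged", "up"]
        assert self._flags(pattern, rule="any")["is_memory"]
        assert not self._flags(pattern, rule="all")["is_memory"]

    def test_missing_contrast_raises(self):
        de = _de_stub({"S1_vs_R0": ["up"]})
        with pytest.raises(KeyError):
            m.flag_memory(de)

    def test_profile_preset_membership(self):
        flags = m.flag_memory_by_profiles([0, 2, 18, 25, -1])
        np.testing.assert_array_equal(flags, [True, False, True, True, False])
        assert len(m.PAPER_MEMORY_PROFILES) == 16


class TestClassifyGenes:
    def test_parameter_recovery_on_planted_data(self, planted_expression, planted_de):
        _, table, truth = planted_expression
        cls = m.classify_genes(table, planted_de)
        planted_memory = truth.index[truth["is_memory"]]
        assert cls.loc[planted_memory, "is_memory"].mean() >= 0.90
        nonflat = truth.index[truth["shape_id"] != m.FLAT_SHAPE]
        shape_ok = (cls.loc[nonflat, "profile_id"].to_numpy()
                    == truth.loc[nonflat, "shape_id"].to_numpy())
        assert shape_ok.mean() >= 0.85
        # planted flat genes should rarely be called memory
        flat = truth.index[truth["shape_id"] == m.FLAT_SHAPE]
        assert cls.loc[flat, "is_memory"].mean() <= 0.05

    def test_category_agreement_with_truth(self, planted_expression, planted_de):
        _, table, truth = planted_expression
        cls = m.classify_genes(table, planted_de)
        both = truth["is_memory"] & cls["is_memory"]
        agree = (cls.loc[both, "category"] == truth.loc[both, "category"]).mean()
        assert agree >= 0.85
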