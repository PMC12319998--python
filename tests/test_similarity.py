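"""Run-pair contrast tables and questionnaire averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restfc.connectivity import FCVector
from restfc.similarity import average_snycq, build_contrast_table, mad, nonoverlapping_subset


def _vec(values, subject, run):
    values = np.asarray(values, dtype=float)
    k = len(values)
    # minimal index map; content irrelevant to MAD
    idx = np.zeros((k, 2), dtype=int)
    return FCVector(values=values, index_map=idx, subject_id=subject, run_id=run)


def _snycq(rows, n_items=3):
    out = []
    for subject, run, base in rows:
        row = {"subject_id": subject, "run_id": run}
        for i in range(n_items):
            row[f"item_{i + 1:02d}"] = base + 5 * i
        out.append(row)
    return pd.DataFrame(out)


class TestMAD:
    def test_identity_is_zero(self, rng):
        v = rng.standard_normal(20)
        assert mad(v, v) == 0.0

    def test_hand_arithmetic(self):
        assert mad([0, 0], [1, 3]) == 2.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_symmetric_and_nonnegative(self, values):
        a = np.asarray(values)
        b = a[::-1].copy()
        assert mad(a, b) == mad(b, a) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mad([1, 2], [1, 2, 3])


class TestContrastTable:
    def _build(self, run_counts, min_valid_runs=3):
        fc = {}
        rows = []
        rng = np.random.default_rng(0)
        for s, (subject, k) in enumerate(run_counts.items()):
            for r in range(k):
                run = f"run{r + 1}"
                fc.setdefault(subject, {})[run] = _vec(rng.standard_normal(6), subject, run)
                rows.append((subject, run, 10.0 * s + 5 * r))
        return build_contrast_table(fc, _snycq(rows), min_valid_runs=min_valid_runs)

    @pytest.mark.parametrize("k, expected", [(4, 6), (3, 3)])
    def test_pair_counts_per_subject(self, k, expected):
        table = self._build({"s01": k})
        assert len(table) == expected

    def test_cohort_record_count(self):
        # 153 subjects with 4 runs and 11 with 3 -> 153*6 + 11*3 records
        counts = {f"s{i:03d}": 4 for i in range(153)}
        counts.update({f"t{i:02d}": 3 for i in range(11)})
        assert len(self._build(counts)) == 153 * 6 + 11 * 3

    def test_subject_below_minimum_dropped(self):
        table = self._build({"s01": 2, "s02": 4})
        assert set(table["subject_id"]) == {"s02"}

    def test_run_without_questionnaire_dropped(self):
        rng = np.random.default_rng(0)
        fc = {"s01": {f"run{r}": _vec(rng.standard_normal(4), "s01", f"run{r}") for r in (1, 2, 3, 4)}}
        snycq = _snycq([("s01", f"run{r}", 10.0) for r in (1, 2, 3)])  # run4 missing
        table = build_contrast_table(fc, snycq)
        assert len(table) == 3
        assert "run4" not in set(table["run_a"]).union(table["run_b"])

    def test_mad_fc_zero_for_duplicated_runs(self):
        v = np.array([0.1, 0.2, 0.3])
        fc = {"s01": {f"run{r}": _vec(v, "s01", f"run{r}") for r in (1, 2, 3)}}
        table = build_contrast_table(fc, _snycq([("s01", f"run{r}", 20.0) for r in (1, 2, 3)]))
        assert (table["mad_fc"] == 0).all()

    def test_run_order_shuffle_invariant(self):
        table = self._build({"s01": 4})
        pairs = set(map(tuple, table[["run_a", "run_b"]].to_numpy()))
        assert all(a < b for a, b in pairs)
        assert len(pairs) == 6


class TestNonoverlapping:
    def _table(self, runs):
        rows = []
        for i, a in enumerate(runs):
            for b in runs[i + 1 :]:
                rows.append({"subject_id": "s01", "run_a": a, "run_b": b, "mad_fc": 1.0, "mad_snycq_full": 1.0})
        return pd.DataFrame(rows)

    def test_default_scheme_keeps_two_disjoint_pairs(self):
        out = nonoverlapping_subset(self._table(["run1", "run2", "run3", "run4"]))
        assert len(out) == 2
        used = list(out["run_a"]) + list(out["run_b"])
        assert len(used) == len(set(used))

    def test_three_run_subject_contributes_first_adjacent_pair(self):
        out = nonoverlapping_subset(self._table(["run1", "run2", "run3"]))
        assert len(out) == 1
        assert tuple(out.iloc[0][["run_a", "run_b"]]) == ("run1", "run2")

    def test_alternative_scheme(self):
        scheme = {"s01": [("run1", "run3"), ("run2", "run4")]}
        out = nonoverlapping_subset(self._table(["run1", "run2", "run3", "run4"]), scheme)
        assert len(out) == 2
        assert {tuple(r) for r in out[["run_a", "run_b"]].to_numpy()} == {("run1", "run3"), ("run2", "run4")}

    def test_overlapping_scheme_rejected(self):
        scheme = {"s01": [("run1", "run2"), ("run2", "run3")]}
        with pytest.raises(ValueError):
            nonoverlapping_subset(self._table(["run1", "run2", "run3", "run4"]), scheme)


class TestAverageSNYCQ:
    def test_identical_profiles(self):
        df = _snycq([("s01", "run1", 30.0), ("s01", "run2", 30.0)])
        out = average_snycq(df)
        assert out.loc[0, "item_01"] == 30.0

    def test_arithmetic_mean(self):
        df = pd.DataFrame(
            {"subject_id": ["s01"] * 3, "run_id": ["run1", "run2", "run3"], "item_01": [10.0, 20.0, 60.0]}
        )
        assert average_snycq(df).loc[0, "item_01"] == pytest.approx(30.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            average_snycq(pd.DataFrame(columns=["subject_id", "run_id", "item_01"]))
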