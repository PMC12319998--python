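"""FC matrices, fingerprint vectors, network aggregation, run concatenation."""

import numpy as np
import pytest

from restfc.connectivity import (
    FCMatrix,
    aggregate_fnc,
    compute_fc,
    concatenate_runs,
    fnc_unique_edges,
    reassemble_fc,
    vectorize_fc,
)
from restfc.data import DataError, ParcellatedTimeseries, SchemaError
from restfc.synthetic import simulate_timeseries


def _ts(data, networks=None):
    n = data.shape[0]
    labels = [f"n{i}" for i in range(n)]
    networks = networks or {l: "net1" for l in labels}
    return ParcellatedTimeseries("s01", "run1", data, 1.4, labels, networks)


def _fc(values, networks):
    n = values.shape[0]
    return FCMatrix(values, [f"n{i}" for i in range(n)], np.asarray(networks))


class TestComputeFC:
    def test_independent_channels_near_zero(self, rng):
        ts = _ts(rng.standard_normal((2, 20000)))
        fc = compute_fc(ts)
        assert abs(fc.values[0, 1]) < 0.05

    def test_duplicated_node_clamped(self, rng):
        x = rng.standard_normal(100)
        fc = compute_fc(_ts(np.vstack([x, x])))
        assert fc.values[0, 1] == pytest.approx(np.arctanh(0.999999))

    def test_known_correlation_matches_atanh(self, rng):
        # construct channels with exact sample correlation 0.5
        n = 5000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / n  # exactly orthogonal to a
        b /= b.std()
        y = 0.5 * a + np.sqrt(0.75) * b
        fc = compute_fc(_ts(np.vstack([a, y])))
        assert fc.values[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)

    def test_zero_variance_node_rejected(self):
        data = np.vstack([np.zeros(50), np.random.default_rng(0).standard_normal(50)])
        with pytest.raises(DataError, match="n0"):
            compute_fc(_ts(data))


class TestVectorize:
    @pytest.mark.parametrize("n, expected", [(219, 23871), (5, 10)])
    def test_length(self, n, expected, rng):
        m = rng.standard_normal((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        vec = vectorize_fc(_fc(m, ["net1"] * n))
        assert len(vec) == expected == n * (n - 1) // 2

    def test_round_trip(self, rng):
        m = rng.standard_normal((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        vec = vectorize_fc(_fc(m, ["net1"] * 7))
        assert np.array_equal(reassemble_fc(vec, 7), m)

    def test_index_map_is_lower_triangle(self, rng):
        m = np.zeros((4, 4))
        vec = vectorize_fc(_fc(m, ["net1"] * 4))
        assert all(i > j for i, j in vec.index_map)


class TestAggregateFNC:
    def test_constant_edges_preserved(self):
        n = 8
        m = np.full((n, n), 0.3)
        np.fill_diagonal(m, 0)
        fnc = aggregate_fnc(_fc(m, ["netA"] * 4 + ["netB"] * 4))
        assert np.allclose(fnc.values, 0.3)

    def test_unique_entry_count_for_8_networks(self):
        assert fnc_unique_edges(8) == 36
        rng = np.random.default_rng(0)
        m = rng.standard_normal((16, 16))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        fnc = aggregate_fnc(_fc(m, [f"net{i % 8}" for i in range(16)]))
        assert fnc.values.size == 64
        assert len(fnc.unique_edges()) == 36

    def test_hand_computed_two_network_means(self):
        # nodes {0,1} in A, {2,3} in B with hand-set edges
        m = np.zeros((4, 4))
        m[1, 0] = m[0, 1] = 0.2          # within A
        m[3, 2] = m[2, 3] = 0.6          # within B
        between = {(2, 0): 0.1, (3, 0): 0.3, (2, 1): 0.5, (3, 1): 0.7}
        for (i, j), v in between.items():
            m[i, j] = m[j, i] = v
        fnc = aggregate_fnc(_fc(m, ["A", "A", "B", "B"]))
        assert fnc.values[0, 0] == pytest.approx(0.2)
        assert fnc.values[1, 1] == pytest.approx(0.6)
        assert fnc.values[0, 1] == pytest.approx(0.4)

    def test_single_node_network_flagged(self):
        m = np.zeros((3, 3))
        fnc = aggregate_fnc(_fc(m, ["A", "A", "B"]))
        assert "B" in fnc.undefined
        assert np.isnan(fnc.values[list(fnc.network_labels).index("B")] [list(fnc.network_labels).index("B")])

    def test_commutes_with_constant_shift(self, rng):
        m = rng.standard_normal((10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        nets = [f"net{i % 3}" for i in range(10)]
        base = aggregate_fnc(_fc(m, nets)).values
        shift = m + 0.7
        np.fill_diagonal(shift, 0)
        shifted = aggregate_fnc(_fc(shift, nets)).values
        assert np.allclose(shifted, base + 0.7)


class TestConcatenate:
    def test_time_dimension_sums(self, rng):
        runs = [_ts(rng.standard_normal((3, 657))) for _ in range(4)]
        for i, r in enumerate(runs):
            r.run_id = f"run{i}"
        assert concatenate_runs(runs).n_timepoints == 2628

    def test_single_run_is_zscore(self, rng):
        ts = _ts(rng.standard_normal((3, 100)) * 4 + 2)
        out = concatenate_runs([ts])
        expected = (ts.data - ts.data.mean(1, keepdims=True)) / ts.data.std(1, keepdims=True)
        assert np.allclose(out.data, expected)

    def test_node_mismatch_rejected(self, rng):
        a = _ts(rng.standard_normal((3, 50)))
        b = ParcellatedTimeseries("s01", "run2", rng.standard_normal((3, 50)), 1.4,
                                  ["x0", "x1", "x2"], {f"x{i}": "net1" for i in range(3)})
        with pytest.raises(SchemaError):
            concatenate_runs([a, b])

    def test_fnc_of_duplicated_runs_matches_single_run(self, rng):
        ts = _ts(rng.standard_normal((8, 120)), {f"n{i}": f"net{i % 2}" for i in range(8)})
        single = aggregate_fnc(compute_fc(concatenate_runs([ts]))).values
        double = aggregate_fnc(compute_fc(concatenate_runs([ts, ts.copy_with(ts.data)]))).values
        assert np.allclose(single, double, atol=1e-10)


def test_simulated_timeseries_hits_target_correlation(rng):
    # Fisher-z sampling error oracle: for r = 0.8 and n = 20000 the
    # empirical estimate lies well inside +-0.05
    target = np.eye(3)
    target[0, 1] = target[1, 0] = 0.8
    ts = simulate_timeseries(target, 20000, ar_coefficient=0.0, seed=rng)
    emp = np.corrcoef(ts.data)
    assert 0.75 < emp[0, 1] < 0.85
    assert abs(emp[0, 2]) < 0.1 and abs(emp[1, 2]) < 0.1
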