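import numpy as np
import pytest

from conftest import brute_force_signals
from t1epi.bloch import signal_arrays
from t1epi.config import GM_7T, TissueParams
from t1epi.io import ImageVolume
from t1epi.lookup import (
    FLAG_CLAMPED_HIGH,
    FLAG_CLAMPED_LOW,
    FLAG_IN_RANGE,
    FLAG_NO_SIGNAL,
    B1Map,
    T1Map,
    build_lookup_table,
    estimate_t1_map,
    histogram_peaks,
    invert_lookup,
)


@pytest.fixture(scope="module")
def table(protocol):
    return build_lookup_table(protocol)


class TestBuild:
    def test_tabulation_identity(self, protocol, table):
        i = np.where(table.b1_grid == 1.0)[0][0]
        j = 120
        t1v = table.t1_grid[j]
        s1, s2 = signal_arrays(protocol, t1v, 1.0, 1.0)
        assert table.values[i, j] == pytest.approx(float(s1 / s2), rel=1e-12)

    def test_deterministic_rebuild(self, protocol, table):
        again = build_lookup_table(protocol)
        assert np.array_equal(again.values, table.values)
        assert again.protocol_hash == table.protocol_hash

    def test_monotone_within_valid_range(self, table):
        for i in range(len(table.b1_grid)):
            lo, hi = table.valid[i]
            d = np.diff(table.values[i, lo:hi])
            assert np.all(d < 0) or np.all(d > 0)

    def test_bad_t1_range_rejected(self, protocol):
        with pytest.raises(ValueError):
            build_lookup_table(protocol, t1_min=0.0)
        with pytest.raises(ValueError):
            build_lookup_table(protocol, t1_max=20000.0)

    def test_csv_round_trippable_header(self, protocol, table, tmp_path):
        path = table.to_csv(tmp_path / "lut.csv")
        text = path.read_text()
        assert "statistic = ratio" in text
        assert "protocol_hash" in text


class TestInvert:
    def test_round_trip_at_nominal_b1(self, protocol, table):
        s1, s2 = signal_arrays(protocol, 1500.0, 1.0, 1.0)
        t1v, flag = invert_lookup(table, float(s1 / s2), 1.0)
        assert flag == FLAG_IN_RANGE
        assert t1v == pytest.approx(1500.0, abs=1.0)

    def test_out_of_range_clamped_and_flagged(self, table):
        i = np.where(table.b1_grid == 1.0)[0][0]
        lo, hi = table.valid[i]
        decreasing = table.values[i, lo] > table.values[i, hi - 1]
        big = table.values[i, lo] + (1.0 if decreasing else -1.0)
        t1v, flag = invert_lookup(table, float(big), 1.0)
        assert flag == FLAG_CLAMPED_LOW
        assert t1v == pytest.approx(table.valid_t1_range(i)[0])

    def test_nan_statistic_flagged_no_signal(self, table):
        t1v, flag = invert_lookup(table, float("nan"), 1.0)
        assert flag == FLAG_NO_SIGNAL
        assert np.isnan(t1v)

    def test_b1_outside_hull_rejected(self, table):
        with pytest.raises(ValueError, match="hull"):
            invert_lookup(table, 0.7, 2.5)

    def test_random_round_trip_oracle(self, protocol, table):
        """200 random (T1, B1) pairs: statistic from the Bloch model inverts
        back to T1 within one grid step."""
        rng = np.random.default_rng(123)
        T1s = rng.uniform(600.0, 3000.0, 200)
        b1s = rng.uniform(0.7, 1.3, 200)
        s1, s2 = signal_arrays(protocol, T1s, 1.0, b1s)
        t1v, flags = invert_lookup(table, s1 / s2, b1s)
        assert np.all(flags == FLAG_IN_RANGE)
        assert np.max(np.abs(t1v - T1s)) < 10.0

    def test_refinement_convergence(self, protocol):
        coarse = build_lookup_table(protocol, t1_step=20.0)
        fine = build_lookup_table(protocol, t1_step=10.0)
        rng = np.random.default_rng(7)
        T1s = rng.uniform(700.0, 2800.0, 50)
        s1, s2 = signal_arrays(protocol, T1s, 1.0, 1.0)
        t_coarse, _ = invert_lookup(coarse, s1 / s2, 1.0)
        t_fine, _ = invert_lookup(fine, s1 / s2, 1.0)
        assert np.max(np.abs(t_coarse - t_fine)) < 10.0


class TestEstimateT1Map:
    def _phantom_volumes(self, protocol, b1_scale=1.0):
        shape = (12, 12, 12)
        T1 = np.zeros(shape)
        T1[2:6], T1[6:10] = 1800.0, 1200.0
        support = T1 > 0
        s1, s2 = signal_arrays(protocol, np.where(support, T1, 1000.0), 1.0, b1_scale)
        s1, s2 = np.where(support, s1, 0.0), np.where(support, s2, 0.0)
        v1 = ImageVolume(s1, np.eye(4))
        v2 = ImageVolume(s2, np.eye(4))
        return T1, support, v1, v2

    def test_noiseless_round_trip(self, protocol, table):
        T1, support, v1, v2 = self._phantom_volumes(protocol)
        t1map = estimate_t1_map(v1, v2, table, B1Map(np.ones(T1.shape)))
        err = np.abs(t1map.T1[support] - T1[support])
        assert np.max(err) < 10.0

    def test_b1_mismatch_produces_bias(self, protocol, table):
        """Simulating at B1 = 0.8 but inverting at nominal B1 = 1 leaves a
        systematic T1 error — evidence the B1 correction is load-bearing."""
        T1, support, v1, v2 = self._phantom_volumes(protocol, b1_scale=0.8)
        wrong = estimate_t1_map(v1, v2, table, B1Map(np.ones(T1.shape)))
        right = estimate_t1_map(v1, v2, table, B1Map(np.full(T1.shape, 0.8)))
        bias_wrong = np.median(wrong.T1[support] - T1[support])
        bias_right = np.median(right.T1[support] - T1[support])
        assert abs(bias_wrong) > 20.0
        assert abs(bias_right) < 10.0

    def test_background_flagged_no_signal(self, protocol, table):
        T1, support, v1, v2 = self._phantom_volumes(protocol)
        t1map = estimate_t1_map(v1, v2, table, None)
        assert np.all(t1map.flags[~support] == FLAG_NO_SIGNAL)
        assert np.all(np.isnan(t1map.T1[~support]))

    def test_spatial_permutation_equivariance(self, protocol, table):
        T1, support, v1, v2 = self._phantom_volumes(protocol)
        b1 = B1Map(np.linspace(0.8, 1.2, T1.size).reshape(T1.shape))
        direct = estimate_t1_map(v1, v2, table, b1)
        flipped = estimate_t1_map(
            v1.with_data(v1.data[::-1]), v2.with_data(v2.data[::-1]),
            table, B1Map(b1.data[::-1]),
        )
        assert np.array_equal(np.nan_to_num(direct.T1[::-1]), np.nan_to_num(flipped.T1))

    def test_low_resolution_b1_resampled(self, protocol, table):
        T1, support, v1, v2 = self._phantom_volumes(protocol)
        t1map = estimate_t1_map(v1, v2, table, B1Map(np.ones((4, 4, 4))))
        assert np.max(np.abs(t1map.T1[support] - T1[support])) < 10.0

    def test_grid_mismatch_rejected(self, protocol, table):
        _, _, v1, _ = self._phantom_volumes(protocol)
        other = ImageVolume(np.ones((5, 5, 5)), np.eye(4))
        with pytest.raises(ValueError):
            estimate_t1_map(v1, other, table)


class TestHistogramPeaks:
    def _map(self, values):
        arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        return T1Map(T1=arr, flags=np.zeros(arr.shape, dtype=np.int8))

    def test_delta_distribution(self):
        t1map = self._map([1800.0] * 200)
        peaks = histogram_peaks(t1map, {"GM": np.ones((200, 1, 1), bool)})
        assert peaks["GM"] == pytest.approx(1800.0)

    def test_bimodal_returns_taller_mode(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([
            rng.normal(1200, 20, 300), rng.normal(1800, 20, 700)])
        peaks = histogram_peaks(self._map(vals), {"x": np.ones((1000, 1, 1), bool)})
        assert abs(peaks["x"] - 1800) < 60

    def test_equal_modes_tie_breaks_lower(self):
        vals = np.concatenate([np.full(500, 1200.0), np.full(500, 1800.0)])
        peaks = histogram_peaks(self._map(vals), {"x": np.ones((1000, 1, 1), bool)})
        assert abs(peaks["x"] - 1200) < 60

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="100"):
            histogram_peaks(self._map([1500.0] * 50), {"x": np.ones((50, 1, 1), bool)})
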