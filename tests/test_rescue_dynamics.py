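"""Rescue metrics: smoothing, trend-change detection, survival, final size.

The trend metrics are pinned against a brute-force oracle that scans the
first-difference sign pattern of arbitrary trajectories.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evorescue import (
    DataError,
    classify_survival,
    compute_rescue_metrics,
    detect_rescue_transfer,
    final_size_normalized,
    max_recovery_rate,
    smooth_transfers,
    summarize_rescue,
)
from evorescue.plate_io import CultureType, PlateLayout, Treatment
from conftest import traj


def oracle_rescue(od, stress_start):
    """First transfer t > stress_start with od[t] > od[t-1] (1-based)."""
    for t in range(stress_start + 1, len(od) + 1):
        if od[t - 1] > od[t - 2]:
            return t
    return None


def oracle_max_rate(od, stress_start):
    diffs = [od[t - 1] - od[t - 2] for t in range(stress_start + 1, len(od) + 1)]
    m = max(diffs)
    return m if m > 0 else None


class TestSmoothing:
    def test_constant_unchanged(self, meta):
        sm = smooth_transfers(traj([0.5] * 10, meta), window=3)
        assert np.allclose(sm.od, 0.5)

    def test_centered_shrink_edge_rule(self, meta):
        # hand computation: centered window 3 over (0.6,0.3,0.3,0.6)
        sm = smooth_transfers(traj([0.6, 0.3, 0.3, 0.6], meta, stress_start=1),
                              window=3)
        assert np.allclose(sm.od, [0.45, 0.4, 0.4, 0.45])

    def test_window_one_identity(self, meta):
        tr = traj([0.9, 0.1, 0.5, 0.7], meta, stress_start=1)
        assert np.array_equal(smooth_transfers(tr, window=1).od, tr.od)


class TestRescueDetection:
    def test_hand_traced_sign_change(self, meta):
        # post-stress sequence declining then first rise at the 0.08 entry
        od = [0.5, 0.3, 0.1, 0.05, 0.08, 0.20]
        tr = traj(od, meta, stress_start=1)
        assert detect_rescue_transfer(tr) == 5  # transfer holding 0.08

    def test_strictly_decreasing_undefined(self, meta):
        tr = traj(np.linspace(1.0, 0.1, 10), meta, stress_start=4)
        assert detect_rescue_transfer(tr) is None

    def test_rising_at_boundary_counts(self, meta):
        od = [0.9, 0.9, 0.9, 0.1, 0.2, 0.3, 0.4]
        tr = traj(od, meta, stress_start=4)
        assert detect_rescue_transfer(tr) == 5

    def test_tie_does_not_trigger(self, meta):
        od = [0.9, 0.9, 0.9, 0.5, 0.5, 0.5, 0.6]
        tr = traj(od, meta, stress_start=4)
        assert detect_rescue_transfer(tr) == 7

    def test_too_short_errors(self, meta):
        with pytest.raises(DataError):
            detect_rescue_transfer(traj([0.9, 0.5, 0.5, 0.4, 0.3], meta,
                                        stress_start=4))

    def test_exhaustive_oracle_small_alphabet(self, meta):
        # every trajectory of length 7 over ODs {0.1, 0.3, 0.5}
        for pattern in itertools.product((0.1, 0.3, 0.5), repeat=7):
            tr = traj(pattern, meta, stress_start=1)
            assert detect_rescue_transfer(tr) == oracle_rescue(pattern, 1)
            got = max_recovery_rate(tr)
            want = oracle_max_rate(pattern, 1)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


class TestMaxRecoveryRate:
    def test_max_of_positive_diffs(self, meta):
        od = [0.9, 0.9, 0.9, 0.7, 0.5, 0.4, 0.43, 0.50, 0.52]
        tr = traj(od, meta, stress_start=4)
        assert max_recovery_rate(tr) == pytest.approx(0.07)

    def test_all_negative_undefined(self, meta):
        tr = traj(np.linspace(1.0, 0.2, 9), meta, stress_start=4)
        assert max_recovery_rate(tr) is None

    def test_single_small_positive(self, meta):
        od = [0.9, 0.8, 0.7, 0.6, 0.5, 0.501, 0.4]
        tr = traj(od, meta, stress_start=4)
        assert max_recovery_rate(tr) == pytest.approx(0.001)


class TestSurvivalAndFinalSize:
    def test_survival_threshold(self, meta):
        alive = traj([0.9] * 17 + [0.3, 0.31, 0.30], meta)
        dead = traj([0.9] * 17 + [0.005, 0.004, 0.005], meta)
        assert classify_survival(alive, 0.02)
        assert not classify_survival(dead, 0.02)

    def test_exactly_at_threshold_is_extinct(self, meta):
        tr = traj([0.9] * 17 + [0.02, 0.02, 0.02], meta)
        assert not classify_survival(tr, 0.02)

    def test_final_size_normalization(self, meta, proto_meta):
        tr = traj([0.9] * 17 + [0.3, 0.35, 0.4], meta)
        refs = [traj([0.9] * 19 + [v], proto_meta) for v in (0.9, 1.0, 1.1)]
        assert final_size_normalized(tr, refs) == pytest.approx(0.35)

    def test_all_zero_tail_gives_zero(self, meta, proto_meta):
        tr = traj([0.9] * 17 + [0.0, 0.0, 0.0], meta)
        refs = [traj([0.9] * 20, proto_meta)]
        assert final_size_normalized(tr, refs) == 0.0

    def test_zero_reference_errors(self, meta, proto_meta):
        tr = traj([0.9] * 20, meta)
        refs = [traj([0.9] * 19 + [0.0], proto_meta)]
        with pytest.raises(DataError):
            final_size_normalized(tr, refs)


class TestInvariances:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_shift_and_scale_invariances(self, seed):
        meta = PlateLayout("A1", CultureType.MUTUALISM, Treatment.SALINITY)
        rng = np.random.default_rng(seed)
        od = rng.uniform(0.0, 1.0, 12)
        tr = traj(od, meta, stress_start=4)
        sm = smooth_transfers(tr, 3)
        base_rescue = detect_rescue_transfer(sm)
        base_rate = max_recovery_rate(sm)
        # adding a constant leaves the rescue transfer unchanged
        shifted = smooth_transfers(traj(od + 0.37, meta, stress_start=4), 3)
        assert detect_rescue_transfer(shifted) == base_rescue
        # scaling by c > 0 scales the max recovery rate by c
        scaled = smooth_transfers(traj(od * 2.5, meta, stress_start=4), 3)
        if base_rate is None:
            assert max_recovery_rate(scaled) is None
        else:
            assert max_recovery_rate(scaled) == pytest.approx(2.5 * base_rate)

    def test_scaling_leaves_normalized_final_size_unchanged(self, meta, proto_meta):
        od = np.array([0.9, 0.9, 0.9, 0.2, 0.1, 0.2, 0.3, 0.35, 0.4, 0.41])
        tr = traj(od, meta)
        refs = [traj(np.full(10, 0.8), proto_meta)]
        base = final_size_normalized(tr, refs)
        tr2 = traj(od * 3.0, meta)
        refs2 = [traj(np.full(10, 2.4), proto_meta)]
        assert final_size_normalized(tr2, refs2) == pytest.approx(base)

    def test_monotone_decreasing_all_undefined(self, meta):
        tr = traj(np.geomspace(0.9, 1e-4, 15), meta)
        sm = smooth_transfers(tr, 3)
        assert detect_rescue_transfer(sm) is None
        assert max_recovery_rate(sm) is None
        assert not classify_survival(tr, 0.02)


class TestPipelineAggregation:
    def _metrics(self):
        meta_s = [PlateLayout(f"S{i}", CultureType.MUTUALISM, Treatment.SALINITY)
                  for i in range(3)]
        meta_p = [PlateLayout(f"Q{i}", CultureType.MUTUALISM, Treatment.PNP)
                  for i in range(3)]
        sal = [traj([0.9, 0.9, 0.9, 0.5, 0.3, 0.1, 0.05, 0.04, 0.1, 0.3],
                    m) for m in meta_s]
        pnp = [traj([0.9, 0.9, 0.9, 0.3, 0.1, 0.2, 0.4, 0.42, 0.43, 0.44],
                    m) for m in meta_p]
        proto = {
            Treatment.SALINITY: [
                traj(np.full(10, 0.8),
                     PlateLayout("PS", CultureType.PROTOTROPH, Treatment.SALINITY))],
            Treatment.PNP: [
                traj(np.full(10, 0.8),
                     PlateLayout("PP", CultureType.PROTOTROPH, Treatment.PNP))],
        }
        return compute_rescue_metrics(sal + pnp, reference=proto)

    def test_per_treatment_medians(self):
        out = summarize_rescue(self._metrics()).set_index("treatment")
        assert out.loc["PNP", "rescue_transfer_median"] == 6
        assert out.loc["salinity", "rescue_transfer_median"] == 9
        assert out.loc["PNP", "n_survived"] == 3

    def test_survival_counts_match_classifier(self):
        metrics = self._metrics()
        out = summarize_rescue(metrics).set_index("treatment")
        for tr_name in ("salinity", "PNP"):
            n = sum(m.survived for m in metrics
                    if m.meta.treatment.value == tr_name)
            assert out.loc[tr_name, "n_survived"] == n

    def test_all_extinct_group(self):
        metas = [PlateLayout(f"E{i}", CultureType.MUTUALISM, Treatment.SALINITY)
                 for i in range(3)]
        trs = [traj(np.geomspace(0.9, 1e-4, 10), m) for m in metas]
        out = summarize_rescue(compute_rescue_metrics(trs))
        assert out.n_survived.iloc[0] == 0
        assert out.n_rescue_transfer_defined.iloc[0] == 0
        assert np.isnan(out.rescue_transfer_median.iloc[0])
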