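import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuemap import trajectory as traj
from rescuemap.io import PlateSeries
from rescuemap.trajectory import AnalysisConfig, AncestralReference


def _series(readings):
    od, yfp, cfp = (np.array(col, dtype=float) for col in zip(*readings))
    return PlateSeries("p1", "A01", np.arange(1, len(od) + 1), od, yfp, cfp)


class TestNormalize:
    def test_division(self, make_series, cfg):
        s = make_series([(0.5, 100, 50)])
        out = traj.normalize(s, cfg)
        assert out.norm_yfp[0] == pytest.approx(200.0)
        assert out.norm_cfp[0] == pytest.approx(100.0)

    def test_zeroed_below_threshold(self, make_series, cfg):
        s = make_series([(0.05, 100, 50)])
        out = traj.normalize(s, cfg)
        assert out.norm_yfp[0] == 0.0
        assert out.norm_cfp[0] == 0.0

    def test_exactly_at_threshold_not_zeroed(self, make_series, cfg):
        # "below" is a strict <, so OD exactly at the threshold is normalized
        s = make_series([(0.075, 75, 75)])
        out = traj.normalize(s, cfg)
        assert out.norm_yfp[0] == pytest.approx(1000.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 2.0, allow_nan=False),
                st.floats(0.0, 5000.0, allow_nan=False),
                st.floats(0.0, 5000.0, allow_nan=False),
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_zeroing_invariant(self, readings):
        s = _series(readings)
        out = traj.normalize(s, AnalysisConfig())
        low = s.od600 < 0.075
        assert np.all(out.norm_yfp[low] == 0.0)
        assert np.all(out.norm_cfp[low] == 0.0)


class TestAncestralReference:
    def test_mean_of_wells(self, cfg):
        ref = traj.ancestral_reference([(1.0, 90, 80), (1.0, 110, 120)], cfg)
        assert ref.mean_norm_yfp == pytest.approx(100.0)
        assert ref.mean_norm_cfp == pytest.approx(100.0)
        assert ref.n_wells == 2

    def test_single_well(self, cfg):
        ref = traj.ancestral_reference([(0.5, 100, 60)], cfg)
        assert ref.mean_norm_yfp == pytest.approx(200.0)

    def test_all_below_threshold_errors(self, cfg):
        with pytest.raises(ValueError, match="reference undefined"):
            traj.ancestral_reference([(0.01, 5, 5)], cfg)


class TestClassifyRescue:
    def test_final_above(self, make_series, cfg):
        assert traj.classify_rescue(make_series([(1.0, 0, 0), (0.5, 0, 0)]), cfg)

    def test_boundary_is_extinct(self, make_series, cfg):
        # "exceeded" is strict: final OD exactly at the threshold is extinct
        assert not traj.classify_rescue(make_series([(1.0, 0, 0), (0.075, 0, 0)]), cfg)

    def test_transient_dip_still_rescued(self, make_series, cfg):
        s = make_series([(1.0, 0, 0), (0.02, 0, 0), (0.4, 0, 0)])
        assert traj.classify_rescue(s, cfg)


class TestClassifyPhenotype:
    def test_elevated(self, make_series, ref, cfg):
        s = make_series([(1.0, 300, 100)])
        yfp, cfp = traj.classify_phenotype(traj.normalize(s, cfg), ref, cfg)
        assert yfp and not cfp

    def test_fold_exactly_at_threshold_not_elevated(self, make_series, ref, cfg):
        s = make_series([(1.0, 277, 100)])
        yfp, _ = traj.classify_phenotype(traj.normalize(s, cfg), ref, cfg)
        assert not yfp

    def test_both_channels_is_amplification_phenotype(self, make_series, ref, cfg):
        s = make_series([(1.0, 400, 400)])
        call = traj.classify_well(s, ref, cfg)
        assert call.phenotype == "YFP+CFP"

    @settings(max_examples=40, deadline=None)
    @given(
        fold=st.floats(0.1, 20, allow_nan=False),
        theta_lo=st.floats(0.5, 10),
        theta_hi=st.floats(0.5, 10),
    )
    def test_monotone_in_threshold(self, fold, theta_lo, theta_hi):
        """Raising the fold threshold never converts non-elevated to elevated."""
        ref = AncestralReference(100.0, 100.0, 95)
        lo, hi = sorted([theta_lo, theta_hi])
        s = _series([(1.0, 100 * fold, 100)])
        get = lambda th: traj.classify_phenotype(
            traj.normalize(s, AnalysisConfig(fold_threshold=th)),
            ref,
            AnalysisConfig(fold_threshold=th),
        )[0]
        if not get(lo):
            assert not get(hi)


class TestTransientElevation:
    def test_two_qualifying_days(self, make_series, ref, cfg):
        s = make_series([(0.5, 0, 200), (0.5, 0, 200), (0.01, 0, 0)])
        assert traj.detect_transient_elevation(traj.normalize(s, cfg), ref, cfg, "cfp")

    def test_od_condition_fails(self, make_series, ref, cfg):
        s = make_series([(0.25, 0, 100), (0.25, 0, 100)])
        # norm_cfp = 400 (fold 4 > 2.77) but OD <= 0.3 on both days
        assert not traj.detect_transient_elevation(traj.normalize(s, cfg), ref, cfg, "cfp")

    def test_one_day_insufficient(self, make_series, ref, cfg):
        s = make_series([(0.5, 0, 200), (0.01, 0, 0)])
        assert not traj.detect_transient_elevation(traj.normalize(s, cfg), ref, cfg, "cfp")


class TestAmplifiedForCost:
    def _call(self, rescued, cfp_elevated, transient_cfp):
        return traj.PhenotypeCall(
            plate_id="p",
            well="A01",
            rescued=rescued,
            yfp_elevated=rescued,
            cfp_elevated=cfp_elevated,
            transient_yfp=False,
            transient_cfp=transient_cfp,
            amplified_for_cost=False,
            final_ratio=1.0,
        )

    def test_extinct_transient_counted(self):
        assert traj.amplified_for_cost(self._call(False, False, True))

    def test_rescued_transient_without_final_elevation_counted(self):
        # counted for cost analysis even though the final fold fell back below
        assert traj.amplified_for_cost(self._call(True, False, True))

    def test_rescued_never_elevated_not_counted(self):
        assert not traj.amplified_for_cost(self._call(True, False, False))

    def test_implication_invariant(self):
        for rescued in (True, False):
            for cfp in (True, False):
                for trans in (True, False):
                    call = self._call(rescued, cfp, trans)
                    if traj.amplified_for_cost(call):
                        assert call.cfp_elevated or call.transient_cfp


class TestFinalRatio:
    def test_raw_units(self, make_series, cfg):
        s = make_series([(1.0, 500, 250)])
        assert traj.final_ratio(s, cfg) == pytest.approx(2.0)

    def test_zero_cfp_is_nan(self, make_series, cfg):
        s = make_series([(1.0, 500, 0)])
        assert math.isnan(traj.final_ratio(s, cfg))


class TestAmplificationTiming:
    def test_high_flat_means_amplification_second(self):
        label = traj.infer_amplification_timing([3.0, 3.1, 2.9, 3.0, 3.1], plate_median=1.0)
        assert label == "amplification_second"

    def test_intermediate_step_means_amplification_first(self):
        label = traj.infer_amplification_timing([1.0, 1.0, 1.0, 2.8, 3.0], plate_median=1.0)
        assert label == "amplification_first"

    def test_flat_low_is_indeterminate(self):
        label = traj.infer_amplification_timing([1.0, 1.05, 0.95, 1.0], plate_median=1.0)
        assert label == "indeterminate"

    def test_too_few_days_is_indeterminate(self):
        assert traj.infer_amplification_timing([3.0, 3.0, 3.0], 1.0) == "indeterminate"


class TestSpotAmplification:
    def test_default_fold_rule(self):
        flags = traj.classify_spot_amplification([61, 59], [10, 10], rule="fold")
        assert flags == [True, False]

    def test_sd_rule(self):
        # ancestor mean 10, SD 2 -> threshold 22
        anc = [8, 10, 12, 10]
        sd = np.std(anc, ddof=1)
        spot = 10 + 6 * sd + 1
        flags = traj.classify_spot_amplification([spot, 10], anc, rule="sd")
        assert flags == [True, False]

    def test_empty_ancestors_rejected(self):
        with pytest.raises(ValueError, match="empty ancestor"):
            traj.classify_spot_amplification([1.0], [])
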