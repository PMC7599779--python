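import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uadese.assays import (
    PartitionMeasurement,
    PhDiffMeasurement,
    PuritySet,
    anthocyanin_yield,
    classify_uv_spectrum,
    partition_coefficient,
    purity,
    screen_solvent_systems,
    stationary_retention,
)


def _meas(dd, **kw):
    """Measurement whose double absorbance difference is dd."""
    defaults = dict(a510_ph1=dd, a700_ph1=0.0, a510_ph45=0.0, a700_ph45=0.0)
    defaults.update(kw)
    return PhDiffMeasurement(**defaults)


class TestAnthocyaninYield:
    def test_identical_readings_give_zero(self):
        m = PhDiffMeasurement(0.5, 0.1, 0.5, 0.1)
        assert anthocyanin_yield(m) == 0.0

    def test_hand_arithmetic(self):
        """ddA 0.269, DF 1, V 0.02 L, m 1 g -> 0.269*449.2*1000*0.02/26900."""
        m = _meas(0.269, volume=0.02, mass=1.0)
        expected = 0.269 * 449.2 * 1000 * 0.02 / (26900 * 1.0 * 1.0)
        assert anthocyanin_yield(m) == pytest.approx(expected, rel=1e-12)
        assert anthocyanin_yield(m) == pytest.approx(0.0898, abs=5e-5)

    def test_dilution_linearity(self):
        y1 = anthocyanin_yield(_meas(0.3, dilution_factor=1))
        y2 = anthocyanin_yield(_meas(0.3, dilution_factor=2))
        assert y2 == pytest.approx(2 * y1)

    def test_negative_difference_warns_but_returns(self):
        m = PhDiffMeasurement(0.1, 0.0, 0.3, 0.0)
        with pytest.warns(UserWarning, match="negative"):
            y = anthocyanin_yield(m)
        assert y < 0

    @given(
        dd=st.floats(0.01, 1.0),
        df=st.floats(1.0, 10.0),
        v=st.floats(0.001, 0.1),
        m=st.floats(0.1, 10.0),
        path=st.floats(0.1, 5.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_homogeneity(self, dd, df, v, m, path):
        """Yield is degree-1 homogeneous in ddA, DF, V and degree -1 in m, L."""
        base = anthocyanin_yield(_meas(dd, dilution_factor=df, volume=v, mass=m,
                                       path_length=path))
        assert anthocyanin_yield(
            _meas(2 * dd, dilution_factor=df, volume=v, mass=m, path_length=path)
        ) == pytest.approx(2 * base, rel=1e-9)
        assert anthocyanin_yield(
            _meas(dd, dilution_factor=df, volume=2 * v, mass=m, path_length=path)
        ) == pytest.approx(2 * base, rel=1e-9)
        assert anthocyanin_yield(
            _meas(dd, dilution_factor=df, volume=v, mass=2 * m, path_length=path)
        ) == pytest.approx(base / 2, rel=1e-9)
        assert anthocyanin_yield(
            _meas(dd, dilution_factor=df, volume=v, mass=m, path_length=2 * path)
        ) == pytest.approx(base / 2, rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhDiffMeasurement(0.1, 0, 0, 0, mass=0.0)
        with pytest.raises(ValueError):
            PhDiffMeasurement(0.1, 0, 0, 0, dilution_factor=0.5)


class TestPurity:
    def test_two_component_areas(self):
        w = purity(PuritySet(areas=(92.25, 7.75)))
        assert w.tolist() == pytest.approx([92.25, 7.75])

    def test_single_component_is_pure(self):
        assert purity(PuritySet(areas=(123.4,))).tolist() == [100.0]

    def test_correction_factors(self):
        w = purity(PuritySet(areas=(1, 1, 2), factors=(2, 1, 1)))
        assert w.tolist() == pytest.approx([40.0, 20.0, 40.0])

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            PuritySet(areas=(0.0, 0.0))

    @given(
        areas=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=8),
        scale=st.floats(0.1, 100.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_sums_to_hundred_and_scale_invariant(self, areas, scale):
        w = purity(PuritySet(areas=tuple(areas)))
        assert w.sum() == pytest.approx(100.0, abs=1e-10)
        w2 = purity(PuritySet(areas=tuple(a * scale for a in areas)))
        assert np.allclose(w, w2, atol=1e-9)


class TestPartitionCoefficient:
    @pytest.mark.parametrize("up,low,expected", [(5.0, 5.0, 1.0), (3.0, 2.0, 1.5)])
    def test_ratio(self, up, low, expected):
        assert partition_coefficient(
            PartitionMeasurement("c", up, low)) == pytest.approx(expected)

    def test_scale_invariance(self):
        k1 = partition_coefficient(PartitionMeasurement("c", 3.0, 2.0))
        k2 = partition_coefficient(PartitionMeasurement("c", 300.0, 200.0))
        assert k1 == pytest.approx(k2)

    def test_zero_lower_phase_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            partition_coefficient(PartitionMeasurement("c", 1.0, 0.0))


class TestScreenSolventSystems:
    def test_all_in_window_accepted(self):
        res = screen_solvent_systems({"no1": {"I": 0.8, "II": 1.2, "III": 1.9}})
        assert res[0].accepted

    def test_washed_out_component_named(self):
        res = screen_solvent_systems({"no5": {"I": 0.1, "II": 1.0}})
        assert not res[0].accepted
        assert "I" in res[0].reason and "washed out" in res[0].reason

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            screen_solvent_systems({})
        with pytest.raises(ValueError):
            screen_solvent_systems({"s": {}})

    def test_widening_window_is_monotone(self, rng):
        """No system accepted under [k_min, k_max] is rejected by a wider window."""
        table = {
            f"s{i}": {f"c{j}": float(rng.uniform(0.05, 4.0)) for j in range(3)}
            for i in range(10)
        }
        narrow = {r.system for r in screen_solvent_systems(table, 0.5, 2.0) if r.accepted}
        wide = {r.system for r in screen_solvent_systems(table, 0.25, 3.0) if r.accepted}
        assert narrow <= wide


class TestStationaryRetention:
    def test_study_value(self):
        assert stationary_retention(0.486 * 260, 260) == pytest.approx(48.6)

    @pytest.mark.parametrize("vs,vc,expected", [(0.0, 100.0, 0.0), (100.0, 100.0, 100.0)])
    def test_edges(self, vs, vc, expected):
        assert stationary_retention(vs, vc) == expected

    def test_overfull_column_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            stationary_retention(110.0, 100.0)


class TestClassifyUvSpectrum:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([280, 520], "anthocyanin"),
            ([278, 515], "anthocyanin"),
            ([254, 365], "non-anthocyanin flavonoid"),
            ([245, 370], "non-anthocyanin flavonoid"),
            ([600], "unclassified"),
            ([280], "unclassified"),
        ],
    )
    def test_rules(self, peaks, expected):
        assert classify_uv_spectrum(peaks) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_uv_spectrum([])
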