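"""Rate conversions: the published tables' footnote formulas and the
steady-state turnover model."""

import io
import math

import pytest
from hypothesis import given, settings, strategies as st

from plastidlabel import (
    DomainError,
    ExperimentConfig,
    LabelMeasurement,
    PoolSpec,
    build_rate_table,
    c2_content,
    carbon_content,
    degradation_rate,
    dpm_to_pmol,
    growth_rate_from_doubling,
    incorporation_rate,
    rate_table_frame,
    read_measurements,
    read_pools,
    round_printed,
    specific_radioactivity_fa,
    specific_radioactivity_lipid,
    turnover_rate,
)


class TestScalarOperations:
    @pytest.mark.parametrize(
        "content,pct,expected,decimals",
        [
            (400.92, 8.80, 35.28, 2),  # galactose, intact cells
            (293.2, 3.72, 10.91, 2),  # 18:0
            (123.0, 0.0, 0.0, 2),
        ],
    )
    def test_incorporation_rate(self, content, pct, expected, decimals):
        assert round_printed(incorporation_rate(content, pct), decimals) == expected

    @pytest.mark.parametrize(
        "pct,expected",
        [(8.80, 0.092), (3.43, 0.035), (0.0, 0.0)],
    )
    def test_turnover_rate_printed(self, pct, expected):
        assert round_printed(turnover_rate(pct), 3) == expected

    def test_turnover_rejects_full_replacement(self):
        with pytest.raises(DomainError):
            turnover_rate(100.0)

    @pytest.mark.parametrize(
        "content,carbons,expected",
        [(401, 43, 17.2), (159, 40, 6.36), (0, 43, 0.0)],
    )
    def test_carbon_content(self, content, carbons, expected):
        assert carbon_content(content, carbons) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "inc,cc,expected",
        [(3.58, 17.243, 0.208), (0.60, 6.36, 0.094), (0.0, 17.2, 0.0)],
    )
    def test_specific_radioactivity_lipid(self, inc, cc, expected):
        assert round_printed(specific_radioactivity_lipid(inc, cc), 3) == expected

    @pytest.mark.parametrize(
        "content,units,expected",
        [(6.19, 7, 43.3), (1078, 8, 8624), (0, 9, 0.0)],
    )
    def test_c2_content(self, content, units, expected):
        assert c2_content(content, units) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "inc,cc,expected,decimals",
        [(0.70, 43.33, 16.2, 1), (3.68, 2637, 1.396, 3), (0.0, 100, 0.0, 3)],
    )
    def test_specific_radioactivity_fa(self, inc, cc, expected, decimals):
        assert round_printed(specific_radioactivity_fa(inc, cc), decimals) == expected

    def test_zero_denominators_rejected(self):
        with pytest.raises(DomainError):
            specific_radioactivity_lipid(1.0, 0.0)
        with pytest.raises(DomainError):
            specific_radioactivity_fa(1.0, 0.0)

    @pytest.mark.parametrize(
        "doubling,expected",
        [(12.0, 0.058), (math.log(2), 1.0), (24.0, 0.029)],
    )
    def test_growth_rate_from_doubling(self, doubling, expected):
        assert round_printed(growth_rate_from_doubling(doubling), 3) == expected

    def test_growth_rate_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            growth_rate_from_doubling(0.0)

    def test_degradation_rate(self):
        rate, flag = degradation_rate(0.092, 0.058)
        assert rate == pytest.approx(0.034)
        assert not flag
        rate, flag = degradation_rate(0.07, 0.0)
        assert rate == pytest.approx(0.07)
        rate, flag = degradation_rate(0.005, 0.058)
        assert rate == 0.0 and flag  # in vitro turnover below growth

    def test_dpm_to_pmol(self):
        assert dpm_to_pmol(130.5, 58.8) == pytest.approx(1.0, rel=1e-3)
        assert dpm_to_pmol(261.1, 58.8) == pytest.approx(
            2 * dpm_to_pmol(130.55, 58.8), rel=1e-3
        )
        with pytest.raises(DomainError):
            dpm_to_pmol(0.0, 58.8)
        with pytest.raises(DomainError):
            dpm_to_pmol(100.0, -1.0)


class TestTurnoverModel:
    @settings(max_examples=100, derandomize=True)
    @given(pct=st.floats(0.001, 99.0))
    def test_turnover_exceeds_linear_rate(self, pct):
        # -ln(1 - x) >= x, so k >= f for any labeled fraction f
        assert turnover_rate(pct) >= pct / 100.0

    @settings(max_examples=50, derandomize=True)
    @given(pct=st.floats(1e-6, 1.0))
    def test_small_fraction_limit(self, pct):
        assert turnover_rate(pct) == pytest.approx(pct / 100.0, rel=0.01)

    def test_convexity_and_monotonicity(self):
        ks = [turnover_rate(x) for x in (10.0, 30.0, 50.0, 70.0, 90.0)]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        diffs = [b - a for a, b in zip(ks, ks[1:])]
        assert all(d2 > d1 for d1, d2 in zip(diffs, diffs[1:]))

    def test_incorporation_round_trip(self):
        content, pct = 350.0, 4.2
        assert incorporation_rate(content, pct) / content * 100 == pytest.approx(pct)

    def test_turnover_inverts_labeling_model(self):
        k_true = 0.092
        f = -math.expm1(-k_true * 1.0)
        assert turnover_rate(100 * f, 1.0) == pytest.approx(k_true, abs=1e-12)

    def test_scales_with_label_time(self):
        f = -math.expm1(-0.05 * 2.0)
        assert turnover_rate(100 * f, label_time=2.0) == pytest.approx(0.05, abs=1e-12)


class TestBuildRateTable:
    def _pools(self):
        return [
            PoolSpec("galactose", 400.92),
            PoolSpec("MGDG", 401, carbon_number=43),
            PoolSpec("14:0", 6.19, c2_units=7),
        ]

    def test_mid_table_columns(self):
        config = ExperimentConfig()
        results = build_rate_table(
            self._pools(),
            [LabelMeasurement("galactose", labeled_fraction_pct=8.80)],
            config,
            "bicarbonate_mid",
        )
        r = results[0]
        assert round_printed(r.incorporation_rate, 2) == 35.28
        assert round_printed(r.turnover_rate, 3) == 0.092
        assert round_printed(r.degradation_rate, 3) == 0.034
        assert not r.below_growth

    def test_lipid_table_columns(self):
        results = build_rate_table(
            self._pools(),
            [LabelMeasurement("MGDG", incorporation_pmol=3.58)],
            ExperimentConfig(),
            "bicarbonate_lipid",
        )
        r = results[0]
        assert round_printed(r.carbon_content, 1) == 17.2
        assert round_printed(r.specific_radioactivity, 3) == 0.208

    def test_fa_table_columns(self):
        results = build_rate_table(
            self._pools(),
            [LabelMeasurement("14:0", incorporation_pmol=0.70)],
            ExperimentConfig(),
            "acetate_fa",
        )
        r = results[0]
        assert round_printed(r.c2_content, 1) == 43.3
        assert round_printed(r.specific_radioactivity, 1) == 16.2

    def test_empty_measurements(self):
        assert build_rate_table(self._pools(), [], ExperimentConfig(), "acetate_mid") == []

    def test_missing_pool_field_is_configuration_error(self):
        with pytest.raises(DomainError):
            build_rate_table(
                [PoolSpec("x", 10.0)],  # no c2_units
                [LabelMeasurement("x", incorporation_pmol=1.0)],
                ExperimentConfig(),
                "acetate_fa",
            )

    def test_unknown_pool_rejected(self):
        with pytest.raises(DomainError):
            build_rate_table(
                self._pools(),
                [LabelMeasurement("nonexistent", labeled_fraction_pct=1.0)],
                ExperimentConfig(),
                "acetate_mid",
            )

    def test_frame_has_one_row_per_measurement(self):
        results = build_rate_table(
            self._pools(),
            [
                LabelMeasurement("galactose", labeled_fraction_pct=8.80),
                LabelMeasurement("galactose", labeled_fraction_pct=3.43),
            ],
            ExperimentConfig(),
            "bicarbonate_mid",
        )
        assert len(rate_table_frame(results)) == 2


class TestConfigAndIO:
    def test_config_consistency_check(self):
        ExperimentConfig(doubling_time=12.0, specific_growth_rate=0.058)
        with pytest.raises(DomainError):
            ExperimentConfig(doubling_time=12.0, specific_growth_rate=0.2)

    def test_csv_round_trip(self):
        pools_csv = (
            "name,content_nmol_per_mg_chl,carbon_number,c2_units\n"
            "MGDG,401,43,\n"
            "14:0,6.19,,7\n"
        )
        pools = read_pools(io.StringIO(pools_csv))
        assert pools[0].carbon_number == 43 and pools[0].c2_units is None
        assert pools[1].c2_units == 7

        meas_csv = (
            "pool,labeled_fraction_pct,incorporation_pmol,label_time_h\n"
            "MGDG,,3.58,1\n"
            "14:0,2.28,,1\n"
        )
        meas = read_measurements(io.StringIO(meas_csv))
        assert meas[0].labeled_fraction_pct is None
        assert meas[1].labeled_fraction_pct == pytest.approx(2.28)

    def test_measurement_invariants(self):
        with pytest.raises(DomainError):
            LabelMeasurement("x", labeled_fraction_pct=100.0)
        with pytest.raises(DomainError):
            LabelMeasurement("x", labeled_fraction_pct=5.0, label_time=0.0)
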