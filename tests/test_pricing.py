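"""Unit behaviour of the four pricing models and their shared primitives."""

import pytest
from scipy.optimize import brentq

import omppricer as op
from omppricer.errors import NoRevenueError, OutOfRangeError, ZeroPatientsError, ZeroYearsError


class TestRdCostPpppy:
    def test_exact_amortization(self):
        assert op.rd_cost_ppppy(830e6, 0.3585, 907, 14) == pytest.approx(
            830e6 * 0.3585 / (907 * 14)
        )
        # printed granularity of the published intermediates (nearest thousand)
        assert op.report_price(op.rd_cost_ppppy(830e6, 0.3585, 907, 14), 1000) == 23_000
        assert op.report_price(op.rd_cost_ppppy(970e6, 0.3585, 604, 12), 1000) == 48_000

    def test_zero_rd_cost(self):
        assert op.rd_cost_ppppy(0, 0.3585, 907, 14) == 0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ZeroPatientsError):
            op.rd_cost_ppppy(830e6, 0.3585, 0, 14)
        with pytest.raises(ZeroYearsError):
            op.rd_cost_ppppy(830e6, 0.3585, 907, 0.5)


class TestNpv:
    def test_closed_form_two_flows(self):
        assert op.npv([-100, 110], 0.10) == pytest.approx(0.0, abs=1e-9)

    def test_zero_rate_is_plain_sum(self):
        assert op.npv([5, -3, 7.5], 0.0) == pytest.approx(9.5)

    def test_rate_bound(self):
        with pytest.raises(OutOfRangeError):
            op.npv([1.0], -1.0)


class TestNCP:
    def test_minimum_scenario_reported_price(self, config, constants):
        result = op.ncp_price(config.ncp.min, constants)
        assert result.reported_price == 87_000
        assert result.price_ppppy == pytest.approx(
            (830e6 * 0.3585 / (907 * 14) + 38e3 * 1.3) * 1.2
        )
        assert result.intermediates["eligible_patients"] == 907

    def test_no_rd_no_profit_reduces_to_drug_cost(self, config, constants):
        inputs = config.ncp.min.model_copy(update={"rd_cost_total": 0.0, "profit_margin": 0.0})
        result = op.ncp_price(inputs, constants)
        assert result.price_ppppy == pytest.approx(38e3 * 1.3)

    def test_components_sum_to_price(self, config, constants):
        result = op.ncp_price(config.ncp.max, constants)
        assert sum(result.components.values()) == pytest.approx(result.price_ppppy, rel=1e-12)
        assert sum(result.shares.values()) == pytest.approx(1.0, rel=1e-12)


class TestAIM:
    @pytest.mark.parametrize("convention", ["additive", "multiplicative"])
    def test_minimum_scenario_under_both_bonus_conventions(self, config, constants, convention):
        inputs = config.aim.min.model_copy(update={"bonus_convention": convention})
        assert op.aim_price(inputs, constants).reported_price == 33_000

    def test_no_profit_no_bonus_is_pure_cost_base(self, config, constants):
        inputs = config.aim.min.model_copy(update={"basic_profit": 0.0, "innovation_bonus": 0.0})
        result = op.aim_price(inputs, constants)
        rd = result.components["rd"]
        assert result.price_ppppy == pytest.approx(rd * 1.15 + 3000)

    def test_conventions_order(self, config, constants):
        add = op.aim_price(config.aim.max, constants).price_ppppy
        mult = op.aim_price(
            config.aim.max.model_copy(update={"bonus_convention": "multiplicative"}), constants
        ).price_ppppy
        # multiplicative applies the bonus on the profit-inclusive base
        assert mult > add


class TestDCF:
    def test_break_even_closed_form_at_zero_rate(self, constants, config):
        sched = op.constant_schedule(100.0, 10)
        inputs = config.dcf.min.model_copy(update={"cost_of_capital": 0.0})
        K = inputs.rd_lumpsum_total * constants.eu_attribution_share
        p = op.dcf_break_even_price(inputs, constants, schedule=sched)
        assert p == pytest.approx(K / (100.0 * 10 * 0.6))

    @pytest.mark.parametrize("scenario", ["min", "max"])
    def test_npv_is_zero_at_break_even(self, config, constants, scenario):
        inputs = getattr(config.dcf, scenario)
        sched = op.dcf_patient_schedule(
            op.DCFPopulationInputs(
                prevalence_per_million=inputs.prevalence_per_million,
                incidence_per_million=inputs.incidence_per_million,
                eu_population=constants.eu_population,
                response_rate=inputs.response_rate,
                failure_rate=inputs.failure_rate,
                adverse_event_rate=inputs.adverse_event_rate,
                contraindication_rate=inputs.contraindication_rate,
                restriction_prevalent=inputs.restriction_prevalent,
                restriction_incident=inputs.restriction_incident,
                population_growth=inputs.population_growth,
                uptake_cap=inputs.uptake_cap,
                uptake_ramp_years=inputs.uptake_ramp_years,
            ),
            inputs.patent_years,
        )
        K = inputs.rd_lumpsum_total * constants.eu_attribution_share
        p_star = op.dcf_break_even_price(inputs, constants)
        flows = [-K] + [
            p_star * n * (1 - inputs.drug_cost_fraction_of_revenue) for n in sched.counts
        ]
        assert op.npv(flows, inputs.cost_of_capital) == pytest.approx(0.0, abs=1e-6 * K)

    def test_break_even_agrees_with_bisection_oracle(self, config, constants):
        inputs = config.dcf.min
        K = inputs.rd_lumpsum_total * constants.eu_attribution_share
        sched = op.dcf_patient_schedule(
            op.DCFPopulationInputs(
                prevalence_per_million=inputs.prevalence_per_million,
                incidence_per_million=inputs.incidence_per_million,
                eu_population=constants.eu_population,
                restriction_prevalent=inputs.restriction_prevalent,
                restriction_incident=inputs.restriction_incident,
                uptake_cap=inputs.uptake_cap,
            ),
            inputs.patent_years,
        )

        def npv_at(price):
            flows = [-K] + [
                price * n * (1 - inputs.drug_cost_fraction_of_revenue) for n in sched.counts
            ]
            return op.npv(flows, inputs.cost_of_capital)

        root = brentq(npv_at, 1.0, 1e9, xtol=1e-6)
        assert op.dcf_break_even_price(inputs, constants) == pytest.approx(root, rel=1e-6)

    def test_premium_multiplies_break_even(self, config, constants):
        p_star = op.dcf_break_even_price(config.dcf.min, constants)
        result = op.dcf_price(config.dcf.min, constants)
        assert result.price_ppppy == pytest.approx(p_star * 1.05)
        assert result.intermediates["break_even_price"] == pytest.approx(p_star)

    def test_zero_rate_zero_premium_is_pure_cost_recovery(self, config, constants):
        inputs = config.dcf.min.model_copy(
            update={"cost_of_capital": 0.0, "innovation_premium": 0.0}
        )
        result = op.dcf_price(inputs, constants)
        assert result.components["cost_of_capital"] == pytest.approx(0.0, abs=1e-9)
        assert result.components["premium"] == 0.0
        assert result.price_ppppy == pytest.approx(result.components["rd_principal"])

    def test_eu_lumpsum_matches_published_value(self, config, constants):
        result = op.dcf_price(config.dcf.min, constants)
        assert result.intermediates["eu_rd_lumpsum"] == pytest.approx(228.3645e6)

    def test_no_revenue_raises(self, config, constants):
        sched = op.constant_schedule(0.0, 10)
        with pytest.raises(NoRevenueError):
            op.dcf_break_even_price(config.dcf.min, constants, schedule=sched)

    def test_forward_compounded_lumpsum_option(self, config, constants):
        plain = op.dcf_break_even_price(config.dcf.min, constants)
        compounded = op.dcf_break_even_price(config.dcf.min, constants, compound_rd_years=6)
        assert compounded == pytest.approx(plain * 1.09**6)


class TestROROR:
    def test_minimum_scenario_price(self, config, constants):
        result = op.roror_price(config.roror.min, constants)
        rd = 830e6 * 0.3585 / (907 * 14)
        expected = (38e3 + rd * (1.08 / 1.019) ** 6) * 1.05
        assert result.price_ppppy == pytest.approx(expected)
        assert result.price_ppppy == pytest.approx(74_775, abs=1.0)

    def test_equal_wacc_and_deflator_cancel_development_time(self, config, constants):
        base = config.roror.min.model_copy(update={"wacc": 0.05, "gdp_deflator": 0.05})
        longer = base.model_copy(update={"years_until_approval": 30.0})
        p1 = op.roror_price(base, constants).price_ppppy
        p2 = op.roror_price(longer, constants).price_ppppy
        assert p1 == pytest.approx(p2)
        rd = op.roror_price(base, constants).intermediates["rd_ppppy"]
        assert p1 == pytest.approx((38e3 + rd) * 1.05)

    def test_price_increases_with_wacc(self, config, constants):
        prices = [
            op.roror_price(
                config.roror.min.model_copy(update={"wacc": w}), constants
            ).price_ppppy
            for w in (0.02, 0.05, 0.08, 0.11, 0.14)
        ]
        assert prices == sorted(prices)
        assert len(set(prices)) == len(prices)


class TestReporting:
    @pytest.mark.parametrize(
        "price,expected",
        [(126_372.9, 126_000), (32_740.8, 33_000), (87_399.9, 87_000), (500.0, 1000), (499.9, 0)],
    )
    def test_report_price_rounds_half_up_to_thousand(self, price, expected):
        assert op.report_price(price, 1000) == expected

    def test_price_result_rejects_leaky_breakdown(self):
        with pytest.raises(ValueError):
            op.PriceResult(
                price_ppppy=100.0, reported_price=0, components={"a": 60.0, "b": 30.0}
            )
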