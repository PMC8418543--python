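"""One-at-a-time sweeps, capacity rescaling and Monte-Carlo ensembles."""

import numpy as np
import pytest

from magnetea import (
    MagneteaError,
    ScenarioEnsemble,
    SweepSpec,
    analyze,
    builtin_fixture,
    capacity_rescale,
    evaluate_ensemble,
    generate_scenario_ensemble,
    monte_carlo_summary,
    oat_sweep,
)
from magnetea.sensitivity import Perturbation, default_perturbations


def _sweep_value(table, value, column):
    return table.loc[table.value == value, column].item()


class TestOatSweep:
    def test_low_yield_raises_operating_cost_per_kg(self, base_single):
        # published sweep point: 80 mg/L pushes per-kg operating cost ~32,000
        table = oat_sweep(
            SweepSpec("fermentation.magnetite_yield_mg_l", [80.0, 150.0, 250.0]),
            base_single,
        )
        low = table.loc[table.value == 80.0]
        unit = (
            low.operating_cost_usd_year / low.annual_product_kg
        ).item()
        assert unit == pytest.approx(32_000, rel=0.08)

    def test_msc_efficiency_sweep_point(self, base_single):
        # published sensitivity: 65% capture on both columns -> ~18,000 USD/kg
        table = oat_sweep(
            SweepSpec("downstream.msc_efficiency", [0.65, 0.75, 0.85]), base_single
        )
        assert _sweep_value(table, 0.65, "unit_cost_usd_kg") == pytest.approx(
            18_000, rel=0.08
        )

    def test_base_row_flagged_and_equal_to_base(self, base_single):
        table = oat_sweep(
            SweepSpec("downstream.msc_efficiency", [0.65, 0.95]), base_single
        )
        base_rows = table[table.is_base]
        assert len(base_rows) == 1
        assert base_rows.unit_cost_usd_kg.item() == pytest.approx(
            analyze(base_single).unit_cost_usd_kg, rel=1e-12
        )

    def test_repeated_value_sweep_is_constant(self, base_single):
        table = oat_sweep(
            SweepSpec("fermentation.magnetite_yield_mg_l", [250.0, 250.0]),
            base_single,
        )
        assert table.unit_cost_usd_kg.nunique() == 1

    def test_invalid_value_recorded_not_fatal(self, base_single):
        table = oat_sweep(
            SweepSpec("downstream.msc_efficiency", [-0.5, 0.85]), base_single
        )
        bad = table.loc[table.value == -0.5]
        assert bad.error.item() != ""
        assert np.isnan(bad.unit_cost_usd_kg.item())
        good = table.loc[table.value == 0.85]
        assert good.error.item() == ""

    def test_unit_cost_strictly_decreasing_in_yield_and_efficiency(
        self, base_single
    ):
        yields = [80.0, 150.0, 250.0, 350.0]
        table = oat_sweep(
            SweepSpec("fermentation.magnetite_yield_mg_l", yields), base_single
        )
        costs = table.set_index("value").loc[yields, "unit_cost_usd_kg"].to_numpy()
        assert (np.diff(costs) < 0).all()
        effs = [0.65, 0.75, 0.85, 0.95]
        table = oat_sweep(SweepSpec("downstream.msc_efficiency", effs), base_single)
        costs = table.set_index("value").loc[effs, "unit_cost_usd_kg"].to_numpy()
        assert (np.diff(costs) < 0).all()

    def test_unresolvable_path_rejected(self, base_single):
        with pytest.raises(MagneteaError, match="does not resolve"):
            oat_sweep(SweepSpec("fermentation.nonexistent", [1.0, 2.0]), base_single)


class TestElasticities:
    def test_halving_yield_doubles_unit_cost_and_msp(self, base_single):
        base = analyze(base_single)
        table = oat_sweep(
            SweepSpec("fermentation.magnetite_yield_mg_l", [125.0, 250.0]),
            base_single,
        )
        ratio_cost = (
            _sweep_value(table, 125.0, "unit_cost_usd_kg") / base.unit_cost_usd_kg
        )
        ratio_msp = _sweep_value(table, 125.0, "msp_usd_kg") / base.msp_usd_kg
        assert 1.8 <= ratio_cost <= 2.2
        assert 1.8 <= ratio_msp <= 2.2

    def test_thirty_percent_growth_rate_cut_multiplies_costs(self, base_single):
        base = analyze(base_single)
        table = oat_sweep(SweepSpec("fermentation.mu", [0.07, 0.10]), base_single)
        ratio_cost = (
            _sweep_value(table, 0.07, "unit_cost_usd_kg") / base.unit_cost_usd_kg
        )
        ratio_msp = _sweep_value(table, 0.07, "msp_usd_kg") / base.msp_usd_kg
        assert 2.2 <= ratio_cost <= 2.8
        assert 2.2 <= ratio_msp <= 2.8

    def test_urea_price_sweep_stays_in_published_band(self, base_single):
        # 0.05-0.75 USD/kg urea (as BRL at 5.20): endpoints inside 9,700-12,000
        table = oat_sweep(
            SweepSpec("prices.entries.urea.amount", [0.26, 3.90]), base_single
        )
        for value in (0.26, 3.90):
            unit = _sweep_value(table, value, "unit_cost_usd_kg")
            assert 9_700 <= unit <= 12_000

    def test_exchange_rate_sweep_stays_in_published_band(self, base_single):
        table = oat_sweep(SweepSpec("prices.exchange_rate", [4.0, 6.5]), base_single)
        for value in (4.0, 6.5):
            unit = _sweep_value(table, value, "unit_cost_usd_kg")
            assert 9_700 <= unit <= 12_000


class TestCapacityRescale:
    def test_identity_factor(self, base_single):
        rescaled = capacity_rescale(base_single, 1.0)
        assert analyze(rescaled).unit_cost_usd_kg == pytest.approx(
            analyze(base_single).unit_cost_usd_kg, rel=1e-12
        )

    def test_doubling_capacity_cuts_unit_cost_by_about_a_quarter(self, base_single):
        base = analyze(base_single)
        double = analyze(capacity_rescale(base_single, 2.0))
        assert double.schedule.annual_product_kg == pytest.approx(1280.0, rel=1e-9)
        drop = 1 - double.unit_cost_usd_kg / base.unit_cost_usd_kg
        assert 0.15 < drop < 0.30

    def test_halving_capacity_raises_unit_cost(self, base_single):
        base = analyze(base_single)
        half = analyze(capacity_rescale(base_single, 0.5))
        assert half.unit_cost_usd_kg > 1.25 * base.unit_cost_usd_kg
        assert half.msp_usd_kg > base.msp_usd_kg

    def test_nonpositive_factor_rejected(self, base_single):
        with pytest.raises(MagneteaError, match="factor"):
            capacity_rescale(base_single, 0.0)


class TestEnsemble:
    def test_same_seed_bitwise_identical(self, base_single):
        spec = ScenarioEnsemble(base=base_single, seed=42, draws=60)
        a = evaluate_ensemble(generate_scenario_ensemble(spec)[0])
        spec2 = ScenarioEnsemble(base=base_single, seed=42, draws=60)
        b = evaluate_ensemble(generate_scenario_ensemble(spec2)[0])
        assert a.equals(b)
        sa = monte_carlo_summary(a, seed=42)
        sb = monte_carlo_summary(b, seed=42)
        assert sa.equals(sb)

    def test_different_seed_differs(self, base_single):
        a = evaluate_ensemble(
            generate_scenario_ensemble(
                ScenarioEnsemble(base=base_single, seed=1, draws=30)
            )[0]
        )
        b = evaluate_ensemble(
            generate_scenario_ensemble(
                ScenarioEnsemble(base=base_single, seed=2, draws=30)
            )[0]
        )
        assert not a.equals(b)

    def test_degenerate_distributions_reproduce_base(self, base_single):
        perturbations = {
            path: Perturbation("triangular", p.mode, p.mode, p.mode)
            for path, p in default_perturbations(base_single).items()
        }
        spec = ScenarioEnsemble(
            base=base_single, perturbations=perturbations, seed=7, draws=5
        )
        results = evaluate_ensemble(generate_scenario_ensemble(spec)[0])
        base_cost = analyze(base_single).unit_cost_usd_kg
        assert np.allclose(results.unit_cost_usd_kg, base_cost, rtol=1e-9)
        summary = monte_carlo_summary(results)
        row = summary.set_index("metric").loc["unit_cost_usd_kg"]
        assert row.p5 == row.p50 == row.p95 == pytest.approx(base_cost)

    def test_triangular_yield_mode_near_base(self, base_single):
        # 500 seeded draws over [80, 350] mg/L, mode 250: the histogram peak
        # sits in the bin containing the base value
        spec = ScenarioEnsemble(
            base=base_single,
            perturbations={
                "fermentation.magnetite_yield_mg_l": Perturbation(
                    "triangular", 80.0, 250.0, 350.0
                )
            },
            seed=42,
            draws=500,
        )
        scenarios, rejected = generate_scenario_ensemble(spec)
        draws = np.array(
            [s.fermentation.magnetite_yield_mg_l for s in scenarios]
        )
        assert rejected == 0
        counts, edges = np.histogram(draws, bins=9, range=(80, 350))
        peak_bin = np.argmax(counts)
        assert edges[peak_bin] <= 250.0 <= edges[peak_bin + 1] + 30.0

    def test_single_draw_percentiles_collapse(self, base_single):
        spec = ScenarioEnsemble(base=base_single, seed=3, draws=1)
        results = evaluate_ensemble(generate_scenario_ensemble(spec)[0])
        summary = monte_carlo_summary(results)
        row = summary.set_index("metric").loc["msp_usd_kg"]
        assert row.p5 == row.p50 == row.p95

    def test_median_brackets_base_for_symmetric_perturbation(self, base_single):
        # symmetric triangular perturbation of a monotone-response parameter:
        # the P50 of unit cost lands near the base response
        spec = ScenarioEnsemble(
            base=base_single,
            perturbations={
                "downstream.msc_efficiency": Perturbation(
                    "triangular", 0.75, 0.85, 0.95
                )
            },
            seed=11,
            draws=400,
        )
        results = evaluate_ensemble(generate_scenario_ensemble(spec)[0])
        base_cost = analyze(base_single).unit_cost_usd_kg
        p50 = np.percentile(results.unit_cost_usd_kg, 50)
        assert abs(p50 / base_cost - 1) < 0.1

    def test_unknown_family_rejected(self, base_single):
        spec = ScenarioEnsemble(
            base=base_single,
            perturbations={
                "fermentation.mu": Perturbation("gaussian", 0.07, 0.10, 0.13)
            },
            seed=1,
            draws=2,
        )
        with pytest.raises(MagneteaError, match="family"):
            generate_scenario_ensemble(spec)

    def test_empty_results_rejected(self):
        import pandas as pd

        with pytest.raises(MagneteaError, match="empty"):
            monte_carlo_summary(pd.DataFrame())
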