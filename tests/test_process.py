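"""Per-batch mass balance: inoculum train, fermentation, downstream cascade."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magnetea import (
    MagneteaError,
    batch_material_demand,
    builtin_fixture,
    lysed_fraction,
    run_downstream,
    simulate_batch,
    simulate_fed_batch,
    simulate_inoculum_train,
    simulate_semicontinuous,
)
from magnetea.process import effective_yield_factor, stream_frame
from magnetea.scenario import DownstreamParams, FermentationParams, StoichiometrySpec


class TestInoculumTrain:
    def test_three_stage_train_geometric_series(self):
        fp = FermentationParams(
            initial_volume_m3=15.0, inoculum_expansion_factor=10.0, inoculum_stages=3
        )
        assert simulate_inoculum_train(fp) == pytest.approx([0.015, 0.15, 1.5])

    def test_single_stage_is_one_division(self):
        fp = FermentationParams(
            initial_volume_m3=10.0, inoculum_expansion_factor=10.0, inoculum_stages=1
        )
        assert simulate_inoculum_train(fp) == pytest.approx([1.0])

    def test_unit_expansion_factor_rejected(self):
        fp = FermentationParams(inoculum_expansion_factor=1.0)
        with pytest.raises(MagneteaError, match="expansion factor"):
            simulate_inoculum_train(fp)


class TestFedBatch:
    def test_biomass_amplification_closed_form(self):
        # e^(mu t) with mu=0.10/h over 42 h is an amplification of ~66.69
        assert math.exp(0.10 * 42) == pytest.approx(66.69, rel=1e-3)
        # the fixture culture hits its density cap during the growth phase,
        # so final biomass is cap * volume
        fp = builtin_fixture("base_single").fermentation
        batch = simulate_fed_batch(fp, StoichiometrySpec())
        assert batch.biomass_produced_kg == pytest.approx(
            fp.target_biomass_g_l * fp.final_working_volume_m3
        )

    def test_magnetite_mass_is_titer_times_volume(self):
        fp = builtin_fixture("base_single").fermentation
        fp.final_working_volume_m3 = 26.08
        batch = simulate_fed_batch(fp, StoichiometrySpec())
        assert batch.magnetite_produced_kg == pytest.approx(6.52, rel=1e-3)

    def test_yield_factor_is_unity_at_reference_mu(self):
        fp = builtin_fixture("base_single").fermentation
        assert effective_yield_factor(fp) == pytest.approx(1.0, rel=1e-12)

    def test_slower_growth_shrinks_production_window(self):
        fp = builtin_fixture("base_single").fermentation
        fp.mu = 0.07
        assert 0 < effective_yield_factor(fp) < 1

    def test_overfilled_vessel_rejected(self):
        fp = builtin_fixture("base_single").fermentation
        fp.final_working_volume_m3 = 29.5
        with pytest.raises(MagneteaError, match="vessel"):
            simulate_fed_batch(fp, StoichiometrySpec())

    def test_nonpositive_mu_rejected(self):
        fp = builtin_fixture("base_single").fermentation
        fp.mu = 0.0
        with pytest.raises(MagneteaError, match="mu"):
            simulate_fed_batch(fp, StoichiometrySpec())

    def test_media_demand_covers_stoichiometric_floor(self):
        # the recipe supplies substrate and iron in excess of the metabolic
        # minimum implied by the growth stoichiometry
        batch = simulate_fed_batch(
            builtin_fixture("base_single").fermentation, StoichiometrySpec()
        )
        demand = batch_material_demand(batch)
        assert demand["lactic_acid"] > batch.metabolic_demands_kg["substrate"]
        assert demand["ferric_chloride"] > batch.metabolic_demands_kg["ferric_iron"]


class TestSemicontinuous:
    def test_two_harvest_mass_balance(self):
        # 0.36 kg magnetite per m3 working volume: 0.9*0.25 + 0.1*0.25 + 0.11
        fp = builtin_fixture("base_semicontinuous").fermentation
        fp.final_working_volume_m3 = 33.4
        batch = simulate_semicontinuous(fp, StoichiometrySpec())
        assert batch.magnetite_produced_kg == pytest.approx(0.36 * 33.4, rel=1e-9)
        assert batch.magnetite_produced_kg == pytest.approx(12.02, rel=1e-3)

    def test_degenerate_equals_twice_single_stage(self):
        # harvest fraction -> 1 with equal stage titers doubles the output
        fp = builtin_fixture("base_semicontinuous").fermentation
        fp.harvest_fraction = 1.0 - 1e-12
        fp.stage2_yield_mg_l = fp.magnetite_yield_mg_l
        batch = simulate_semicontinuous(fp, StoichiometrySpec())
        single = 0.250 * fp.final_working_volume_m3
        assert batch.magnetite_produced_kg == pytest.approx(2 * single, rel=1e-9)

    def test_media_demand_about_twice_single_stage(self):
        semi = simulate_batch(builtin_fixture("base_semicontinuous"))
        single = simulate_batch(builtin_fixture("base_single"))
        ratio = semi.media_volume_m3 / single.media_volume_m3
        assert 1.8 < ratio < 2.6

    def test_harvest_fraction_out_of_range_rejected(self):
        fp = builtin_fixture("base_semicontinuous").fermentation
        fp.harvest_fraction = 1.5
        with pytest.raises(MagneteaError, match="harvest"):
            simulate_semicontinuous(fp, StoichiometrySpec())


class TestDownstream:
    def test_lysis_closed_form(self):
        dp = DownstreamParams(homogenizer_passes=4, per_pass_lysis_fraction=0.70)
        assert lysed_fraction(dp) == pytest.approx(1 - 0.3**4, rel=1e-12)
        assert lysed_fraction(dp) == pytest.approx(0.9919, abs=1e-4)

    def test_cascade_recovery_factor(self):
        # separation cascade: 0.85 * 0.90 * 0.85 = 0.65025 on lysed magnetite
        batch = simulate_batch(builtin_fixture("base_single"))
        cascade = 0.85 * 0.90 * 0.85
        assert batch.magnetite_recovered_kg == pytest.approx(
            batch.magnetite_produced_kg * lysed_fraction(DownstreamParams()) * cascade,
            rel=1e-12,
        )

    def test_identity_cascade_recovers_everything(self):
        fp = builtin_fixture("base_single").fermentation
        fermented = simulate_fed_batch(fp, StoichiometrySpec())
        dp = DownstreamParams(
            per_pass_lysis_fraction=1.0, msc_efficiency=1.0, centrifuge_efficiency=1.0
        )
        batch = run_downstream(fermented, dp)
        assert batch.magnetite_recovered_kg == pytest.approx(
            batch.magnetite_produced_kg, rel=1e-12
        )

    def test_zero_efficiency_is_modelling_error(self):
        fp = builtin_fixture("base_single").fermentation
        fermented = simulate_fed_batch(fp, StoichiometrySpec())
        with pytest.raises(MagneteaError, match="msc_efficiency"):
            run_downstream(fermented, DownstreamParams(msc_efficiency=0.0))

    @given(
        e_msc=st.floats(0.05, 1.0),
        e_cfg=st.floats(0.05, 1.0),
        lysis=st.floats(0.05, 1.0),
        passes=st.integers(1, 8),
    )
    @settings(max_examples=60, deadline=None)
    def test_stagewise_conservation_and_composition(
        self, e_msc, e_cfg, lysis, passes
    ):
        """Input magnetite = captured + waste at every stage (rel 1e-9) and
        the overall recovery equals the product of stage recoveries."""
        fp = builtin_fixture("base_single").fermentation
        fermented = simulate_fed_batch(fp, StoichiometrySpec())
        dp = DownstreamParams(
            homogenizer_passes=passes,
            per_pass_lysis_fraction=lysis,
            msc_efficiency=e_msc,
            centrifuge_efficiency=e_cfg,
        )
        batch = run_downstream(fermented, dp)
        product = 1.0
        for stream in batch.stream_table:
            if "magnetite_in" not in stream.masses_kg:
                continue
            inflow = stream.masses_kg["magnetite_in"]
            outflow = (
                stream.masses_kg["magnetite_captured"]
                + stream.masses_kg["magnetite_waste"]
            )
            assert outflow == pytest.approx(inflow, rel=1e-9)
            product *= stream.masses_kg["magnetite_captured"] / inflow
        assert batch.overall_recovery == pytest.approx(product, rel=1e-9)

    @given(e_msc=st.floats(0.1, 0.99))
    @settings(max_examples=25, deadline=None)
    def test_recovery_monotone_in_efficiency(self, e_msc):
        fp = builtin_fixture("base_single").fermentation
        fermented = simulate_fed_batch(fp, StoichiometrySpec())
        lo = run_downstream(fermented, DownstreamParams(msc_efficiency=e_msc))
        hi = run_downstream(
            simulate_fed_batch(fp, StoichiometrySpec()),
            DownstreamParams(msc_efficiency=min(e_msc + 0.01, 1.0)),
        )
        assert hi.magnetite_recovered_kg >= lo.magnetite_recovered_kg

    def test_product_volume_from_colloid_concentration(self):
        batch = simulate_batch(builtin_fixture("base_single"))
        # 1 mg/mL = 1 kg/m3 colloid
        assert batch.product_volume_m3 == pytest.approx(
            batch.magnetite_recovered_kg, rel=1e-12
        )


class TestMaterialDemand:
    def test_zero_volume_means_zero_demand(self):
        fp = builtin_fixture("base_single").fermentation
        fp.media_recipe = {k: 0.0 for k in fp.media_recipe}
        batch = simulate_fed_batch(fp, StoichiometrySpec())
        demand = {
            k: v
            for k, v in batch_material_demand(batch).items()
        }
        assert all(v == 0.0 for v in demand.values())

    def test_demands_tagged_by_section(self):
        batch = simulate_batch(builtin_fixture("base_single"))
        assert set(batch.material_demand) == {
            "inoculum",
            "fermentation",
            "downstream",
        }
        assert "urea" in batch.material_demand["downstream"]
        assert "lactic_acid" in batch.material_demand["fermentation"]

    def test_stream_frame_tidy(self):
        frame = stream_frame(simulate_batch(builtin_fixture("base_single")))
        assert {"operation", "section", "component", "mass_kg", "volume_m3"} <= set(
            frame.columns
        )
        assert len(frame) > 5
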