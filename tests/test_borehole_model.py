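"""Time constants, single-segment kernels, and the chained borehole model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boreq import (
    AirflowSpec,
    BoreholeGeometry,
    Environment,
    FractionationSet,
    Species,
    SurfaceCase,
    SurfaceModelConfig,
    VaporParcel,
    VelocityConvention,
    XylemSource,
    diffusion_time,
    dry_air_inflow_correction,
    equilibrium_alpha,
    isotope_time_constants,
    ratio_to_delta,
    saturation_mole_fraction,
    segment_isotope_steady_state,
    segment_vapor_steady_state,
    segment_vapor_step,
    simulate_borehole,
    surface_composition,
    turnover_time,
    vapor_diffusivity,
    vapor_time_constant,
)

ENV_168 = Environment(T=289.95)  # 16.8 C, mean borehole T of the whole-root run
GEOM_TOP = BoreholeGeometry(r=0.005, stem_diameter=0.08)
GEOM_BOT = BoreholeGeometry(r=0.005, stem_diameter=0.099)
FLOW_80 = AirflowSpec.from_ml_per_min(80.0)


class TestGeometry:
    def test_wetted_length_default_subtracts_fittings(self):
        assert GEOM_TOP.l == pytest.approx(0.06)
        assert GEOM_BOT.l == pytest.approx(0.079)

    def test_volume_and_area(self):
        g = BoreholeGeometry(r=0.005, wetted_length=0.10)
        assert g.volume == pytest.approx(math.pi * 0.005**2 * 0.10)
        assert g.wall_area == pytest.approx(2 * math.pi * 0.005 * 0.10)
        # A/r = 2 pi l, independent of the radius
        g2 = BoreholeGeometry(r=0.002, wetted_length=0.10)
        assert g.wall_area / g.r == pytest.approx(g2.wall_area / g2.r)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BoreholeGeometry(r=-1e-3, wetted_length=0.1)
        with pytest.raises(ValueError):
            BoreholeGeometry(r=0.005, stem_diameter=0.015)  # l <= 0


class TestTimeConstants:
    def test_diffusion_time_modeling_scenario(self, env_10c):
        geom = BoreholeGeometry(r=0.005, wetted_length=0.10)
        assert diffusion_time(geom, env_10c) == pytest.approx(0.28, abs=0.005)

    def test_diffusion_time_quarter_at_half_radius(self, env_10c):
        full = diffusion_time(BoreholeGeometry(r=0.005, wetted_length=0.1), env_10c)
        half = diffusion_time(BoreholeGeometry(r=0.0025, wetted_length=0.1), env_10c)
        assert half == pytest.approx(full / 4.0)
        assert half == pytest.approx(0.069, abs=0.001)

    def test_diffusion_time_standard_conditions(self):
        geom = BoreholeGeometry(r=0.005, wetted_length=0.10)
        t_d = diffusion_time(geom, Environment(T=273.15))
        assert t_d == pytest.approx(2.5e-5 / (4 * 2.12e-5), rel=1e-12)

    def test_turnover_time_modeling_scenario(self):
        geom = BoreholeGeometry(r=0.005, wetted_length=0.10)
        t_u = turnover_time(geom, AirflowSpec.from_ml_per_min(40.0))
        assert t_u == pytest.approx(5.9, abs=0.05)

    @pytest.mark.parametrize(
        "geom, expected",
        [(GEOM_TOP, 1.77), (GEOM_BOT, 2.33)],
        ids=["top-borehole", "bottom-borehole"],
    )
    def test_turnover_time_whole_root_boreholes(self, geom, expected):
        assert turnover_time(geom, FLOW_80) == pytest.approx(expected, abs=0.005)

    def test_turnover_mean_convention_doubles(self):
        geom = BoreholeGeometry(r=0.005, wetted_length=0.10)
        assert turnover_time(
            geom, FLOW_80, VelocityConvention.MEAN
        ) == pytest.approx(2 * turnover_time(geom, FLOW_80))

    @pytest.mark.parametrize(
        "geom, expected",
        [(GEOM_TOP, 0.46), (GEOM_BOT, 0.47)],
        ids=["top-borehole", "bottom-borehole"],
    )
    def test_vapor_time_constant_whole_root(self, geom, expected):
        t_w = vapor_time_constant(geom, FLOW_80, ENV_168)
        assert t_w == pytest.approx(expected, abs=0.005)

    def test_vapor_time_constant_no_flow_limit(self, env_10c):
        geom = BoreholeGeometry(r=0.005, wetted_length=0.10)
        t_w = vapor_time_constant(
            geom, AirflowSpec(Q=1e-12), env_10c
        )
        assert t_w == pytest.approx(
            geom.r**2 / (2 * vapor_diffusivity(env_10c)), rel=1e-4
        )

    def test_isotope_constant_equals_vapor_constant_without_kinetics(self):
        alphas = FractionationSet.at_temperature(
            ENV_168.T, {Species.O18: 1.0, Species.H2: 1.0}
        )
        w_in = 0.3 * saturation_mole_fraction(ENV_168.T)
        tc = isotope_time_constants(GEOM_BOT, FLOW_80, ENV_168, w_in, alphas)
        for s in Species:
            assert tc.t_x_x[s] == pytest.approx(tc.t_w, rel=1e-12)

    def test_isotope_constant_exceeds_vapor_constant_with_kinetics(self):
        w_in = 0.3 * saturation_mole_fraction(ENV_168.T)
        tc = isotope_time_constants(GEOM_BOT, FLOW_80, ENV_168, w_in)
        for s in Species:
            assert tc.t_x_x[s] > tc.t_w

    def test_condensing_inflow_rejected(self):
        w_sat = saturation_mole_fraction(ENV_168.T)
        with pytest.raises(ValueError, match="condensation"):
            isotope_time_constants(GEOM_BOT, FLOW_80, ENV_168, 1.1 * w_sat)

    @given(
        r_mm=st.floats(1.0, 10.0),
        l_cm=st.floats(2.0, 30.0),
        q_ml=st.floats(5.0, 500.0),
        t_c=st.floats(1.0, 35.0),
        rh_in=st.floats(0.01, 1.0),
        a_k=st.floats(1.0, 1.06),
    )
    @settings(max_examples=300, derandomize=True)
    def test_isotope_constant_bound_property(self, r_mm, l_cm, q_ml, t_c,
                                             rh_in, a_k):
        """t_x_x >= t_w over random valid parameters; equality iff alpha_k=1."""
        env = Environment(T=t_c + 273.15)
        geom = BoreholeGeometry(r=r_mm * 1e-3, wetted_length=l_cm * 1e-2)
        flow = AirflowSpec.from_ml_per_min(q_ml)
        alphas = FractionationSet.at_temperature(
            env.T, {s: a_k for s in Species}
        )
        w_in = rh_in * saturation_mole_fraction(env.T)
        tc = isotope_time_constants(geom, flow, env, w_in, alphas)
        for s in Species:
            if a_k == 1.0:
                assert tc.t_x_x[s] == pytest.approx(tc.t_w, rel=1e-10)
            else:
                assert tc.t_x_x[s] > tc.t_w * (1 - 1e-12)


class TestSegmentKernels:
    def test_vapor_steady_state_is_weighted_mean(self, env_10c):
        w_sat = saturation_mole_fraction(env_10c.T)
        flow = AirflowSpec.from_ml_per_min(40.0)
        w = segment_vapor_steady_state(0.5 * w_sat, 0.01, flow, env_10c)
        assert 0.5 * w_sat < w < w_sat
        # saturated inflow is a fixed point
        assert segment_vapor_steady_state(
            w_sat, 0.01, flow, env_10c
        ) == pytest.approx(w_sat, rel=1e-14)

    def test_vapor_steady_state_diffusion_dominated_limit(self, env_10c):
        w_sat = saturation_mole_fraction(env_10c.T)
        w = segment_vapor_steady_state(0.0, 0.05, AirflowSpec(Q=1e-15), env_10c)
        assert w == pytest.approx(w_sat, rel=1e-6)

    def test_vapor_steady_state_equal_weights(self, env_10c):
        """Carrier flow equal to wall conductance averages w_in and w_sat."""
        w_sat = saturation_mole_fraction(env_10c.T)
        l_seg = 0.01
        g = 2 * math.pi * l_seg * vapor_diffusivity(env_10c)
        flow = AirflowSpec(Q=g, velocity_convention=VelocityConvention.MEAN)
        w = segment_vapor_steady_state(0.5 * w_sat, l_seg, flow, env_10c)
        assert w == pytest.approx(0.75 * w_sat, rel=1e-12)

    def test_vapor_step_relaxation(self):
        assert segment_vapor_step(0.01, 0.0, 0.02, 1.0) == 0.01
        halfway = segment_vapor_step(0.01, math.log(2.0), 0.02, 1.0)
        assert halfway == pytest.approx(0.015, rel=1e-12)

    def test_vapor_step_semigroup(self):
        """n small steps equal one combined step (exponential semigroup)."""
        w = 0.004
        for _ in range(10):
            w = segment_vapor_step(w, 0.05, 0.012, 0.47)
        w_once = segment_vapor_step(0.004, 0.5, 0.012, 0.47)
        assert w == pytest.approx(w_once, rel=1e-12)


class TestSurfaceComposition:
    def setup_method(self):
        self.env = Environment(T=283.15)
        self.alphas = FractionationSet.at_temperature(self.env.T)
        self.xylem = XylemSource.from_deltas(
            {Species.O18: -15.0, Species.H2: -110.0}
        )
        w_sat = saturation_mole_fraction(self.env.T)
        self.parcel = VaporParcel.from_deltas(
            0.5 * w_sat, {Species.O18: -20.0, Species.H2: -150.0}
        )

    def test_xylem_equilibrium_case(self):
        rs = surface_composition(
            SurfaceModelConfig(SurfaceCase.XYLEM_EQUILIBRIUM),
            self.xylem, self.parcel, self.env, self.alphas,
        )
        for s in Species:
            assert rs[s] == pytest.approx(
                self.xylem.R_x[s] / self.alphas.alpha_plus[s]
            )

    def test_mixed_endpoints(self):
        for f, case in [(1.0, SurfaceCase.XYLEM_EQUILIBRIUM),
                        (0.0, SurfaceCase.CRAIG_GORDON)]:
            mixed = surface_composition(
                SurfaceModelConfig(SurfaceCase.MIXED, f=f),
                self.xylem, self.parcel, self.env, self.alphas,
            )
            pure = surface_composition(
                SurfaceModelConfig(case),
                self.xylem, self.parcel, self.env, self.alphas,
            )
            assert mixed == pure

    def test_craig_gordon_dry_parcel_limit(self):
        """With no ambient vapor the evaporating surface sits at alpha_k R_x."""
        dry = VaporParcel.from_deltas(
            0.0, {Species.O18: -20.0, Species.H2: -150.0}
        )
        rs = surface_composition(
            SurfaceModelConfig(SurfaceCase.CRAIG_GORDON),
            self.xylem, dry, self.env, self.alphas,
        )
        for s in Species:
            assert rs[s] == pytest.approx(
                self.alphas.alpha_k[s] * self.xylem.R_x[s]
            )

    def test_craig_gordon_saturated_parcel_returns_vapor(self):
        w_sat = saturation_mole_fraction(self.env.T)
        sat = VaporParcel.from_deltas(
            w_sat, {Species.O18: -20.0, Species.H2: -150.0}
        )
        rs = surface_composition(
            SurfaceModelConfig(SurfaceCase.CRAIG_GORDON),
            self.xylem, sat, self.env, self.alphas,
        )
        for s in Species:
            assert rs[s] == pytest.approx(sat.R[s])


class TestSegmentIsotopeSteadyState:
    def test_weighted_mean_without_kinetics(self, env_10c):
        """With alpha_k = 1 the outflow ratio is the flow:wall weighted mean
        of the inflow ratio and the equilibrium vapor ratio."""
        alphas = FractionationSet.at_temperature(
            env_10c.T, {s: 1.0 for s in Species}
        )
        xylem = XylemSource.from_deltas({Species.O18: -15.0, Species.H2: -110.0})
        flow = AirflowSpec.from_ml_per_min(40.0)
        w_sat = saturation_mole_fraction(env_10c.T)
        w_in, l_seg = 0.5 * w_sat, 0.01
        w_out = segment_vapor_steady_state(w_in, l_seg, flow, env_10c)
        R_in = {Species.O18: 0.98, Species.H2: 0.85}
        R_out = segment_isotope_steady_state(
            SurfaceModelConfig(SurfaceCase.XYLEM_EQUILIBRIUM),
            w_in, R_in, w_out, xylem, l_seg, flow, env_10c, alphas,
        )
        q = flow.carrier_flow()
        g = 2 * math.pi * l_seg * vapor_diffusivity(env_10c)
        for s in Species:
            expected = (
                q * w_in * R_in[s]
                + g * w_sat * xylem.R_x[s] / alphas.alpha_plus[s]
            ) / (q * w_in + g * w_sat)
            assert R_out[s] == pytest.approx(expected, rel=1e-12)

    def test_craig_gordon_no_evaporation_passes_inflow(self, env_10c):
        xylem = XylemSource.from_deltas({Species.O18: -15.0, Species.H2: -110.0})
        flow = AirflowSpec.from_ml_per_min(40.0)
        w_sat = saturation_mole_fraction(env_10c.T)
        R_in = {Species.O18: 0.97, Species.H2: 0.83}
        R_out = segment_isotope_steady_state(
            SurfaceModelConfig(SurfaceCase.CRAIG_GORDON),
            w_sat, R_in, w_sat, xylem, 0.01, flow, env_10c,
        )
        for s in Species:
            assert R_out[s] == pytest.approx(R_in[s], rel=1e-14)

    def test_global_fixed_point(self, env_10c):
        """Inflow saturated and at equilibrium with xylem stays unchanged."""
        alphas = FractionationSet.at_temperature(env_10c.T)
        xylem = XylemSource.from_deltas({Species.O18: -15.0, Species.H2: -110.0})
        flow = AirflowSpec.from_ml_per_min(40.0)
        w_sat = saturation_mole_fraction(env_10c.T)
        R_eq = {s: xylem.R_x[s] / alphas.alpha_plus[s] for s in Species}
        R_out = segment_isotope_steady_state(
            SurfaceModelConfig(SurfaceCase.XYLEM_EQUILIBRIUM),
            w_sat, R_eq, w_sat, xylem, 0.01, flow, env_10c, alphas,
        )
        for s in Species:
            assert R_out[s] == pytest.approx(R_eq[s], rel=1e-12)


def test_dry_air_inflow_correction():
    assert dry_air_inflow_correction(1.0, 0.01, 0.01) == 1.0
    assert dry_air_inflow_correction(1.0, 0.0, 0.012) == pytest.approx(0.988)
    # monotone decreasing in the outflow mole fraction
    assert dry_air_inflow_correction(1.0, 0.0, 0.02) < dry_air_inflow_correction(
        1.0, 0.0, 0.01
    )


class TestSimulateBorehole:
    def test_outlet_approaches_equilibrium(self, modeling_config):
        """Case 3.1 outlet sits within 0.4 permil of liquid-vapor
        equilibrium with the xylem water (the published run: -25.6 vs
        -25.7 permil)."""
        res = modeling_config.run()
        eq = ratio_to_delta(
            modeling_config.xylem.R_x[Species.O18]
            / equilibrium_alpha(Species.O18, modeling_config.env.T)
        )
        assert abs(res.outlet_delta(Species.O18) - eq) < 0.4
        assert res.outlet_h > 0.99

    def test_mass_conservation(self, modeling_config):
        """Inflow vapor flux plus wall evaporation equals outlet flux."""
        for case, f in [(SurfaceCase.XYLEM_EQUILIBRIUM, 1.0),
                        (SurfaceCase.CRAIG_GORDON, 0.0),
                        (SurfaceCase.MIXED, 0.35)]:
            cfg = modeling_config.with_updates(
                surface=SurfaceModelConfig(case, f=f)
            )
            res = cfg.run()
            q_mol = cfg.flow.carrier_flow() / __import__(
                "boreq"
            ).molar_volume(cfg.env)
            influx = q_mol * cfg.inflow.w
            outflux = q_mol * res.outlet.w
            assert outflux == pytest.approx(
                influx + res.evaporation_total, rel=1e-10
            )

    def test_humidity_strictly_increasing_along_path(self, modeling_config):
        res = modeling_config.run()
        h = [seg.h for seg in res.segments]
        assert all(b > a for a, b in zip(h, h[1:]))
        assert all(0.0 < x <= 1.0 for x in h)

    def test_saturated_equilibrated_inflow_is_global_fixed_point(
        self, modeling_config
    ):
        alphas = modeling_config.fractionation()
        w_sat = saturation_mole_fraction(modeling_config.env.T)
        R_eq = {
            s: modeling_config.xylem.R_x[s] / alphas.alpha_plus[s]
            for s in Species
        }
        inflow = VaporParcel(w=w_sat, R=R_eq)
        for case, f in [(SurfaceCase.XYLEM_EQUILIBRIUM, 1.0),
                        (SurfaceCase.CRAIG_GORDON, 0.0),
                        (SurfaceCase.MIXED, 0.5)]:
            res = simulate_borehole(
                modeling_config.geom, modeling_config.flow,
                modeling_config.env, inflow, modeling_config.xylem,
                SurfaceModelConfig(case, f=f), N=37,
            )
            for s in Species:
                assert res.outlet.R[s] == pytest.approx(R_eq[s], rel=1e-12)
            assert res.outlet.w == pytest.approx(w_sat, rel=1e-12)

    def test_mixed_endpoints_bit_for_bit(self, modeling_config):
        for f, case in [(0.0, SurfaceCase.CRAIG_GORDON),
                        (1.0, SurfaceCase.XYLEM_EQUILIBRIUM)]:
            mixed = modeling_config.with_updates(
                surface=SurfaceModelConfig(SurfaceCase.MIXED, f=f)
            ).run()
            pure = modeling_config.with_updates(
                surface=SurfaceModelConfig(case)
            ).run()
            for s in Species:
                assert mixed.outlet.R[s] == pure.outlet.R[s]

    def test_grid_convergence(self, modeling_config):
        """Outlet deltas at N=400 and N=800 agree within 0.01 permil."""
        res_400 = modeling_config.with_updates(N=400).run()
        res_800 = modeling_config.with_updates(N=800).run()
        for s in Species:
            assert abs(
                res_400.outlet_delta(s) - res_800.outlet_delta(s)
            ) < 0.01

    def test_single_segment_matches_analytic_kernels(self, modeling_config):
        cfg = modeling_config.with_updates(N=1)
        res = cfg.run()
        w_out = segment_vapor_steady_state(
            cfg.inflow.w, cfg.geom.l, cfg.flow, cfg.env
        )
        R_out = segment_isotope_steady_state(
            cfg.surface, cfg.inflow.w, cfg.inflow.R, w_out, cfg.xylem,
            cfg.geom.l, cfg.flow, cfg.env, cfg.fractionation(),
        )
        assert res.outlet.w == w_out
        assert res.outlet.R == R_out

    def test_condensing_inflow_rejected(self, modeling_config):
        w_sat = saturation_mole_fraction(modeling_config.env.T)
        bad = VaporParcel.from_deltas(
            1.01 * w_sat, {Species.O18: -20.0, Species.H2: -150.0}
        )
        with pytest.raises(ValueError, match="condensation"):
            simulate_borehole(
                modeling_config.geom, modeling_config.flow,
                modeling_config.env, bad, modeling_config.xylem,
            )

    def test_craig_gordon_linear_in_inlet_humidity(self, modeling_config):
        """Outlet d18O under the Craig-Gordon closure is a straight line in
        inflow relative humidity (R^2 > 0.999)."""
        w_sat = saturation_mole_fraction(modeling_config.env.T)
        rhs = np.linspace(0.0, 0.9, 10)
        deltas = []
        for rh in rhs:
            cfg = modeling_config.with_updates(
                inflow=VaporParcel(w=rh * w_sat, R=modeling_config.inflow.R),
                surface=SurfaceModelConfig(SurfaceCase.CRAIG_GORDON),
            )
            deltas.append(cfg.run().outlet_delta(Species.O18))
        slope, intercept = np.polyfit(rhs, deltas, 1)
        fitted = slope * rhs + intercept
        ss_res = np.sum((np.array(deltas) - fitted) ** 2)
        ss_tot = np.sum((np.array(deltas) - np.mean(deltas)) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.999
        assert slope < 0  # heavier inflow humidity lowers outlet d18O

    def test_equilibrium_attractor_in_length_and_flow(self, modeling_config):
        """Outlet approaches equilibrium monotonically as the wetted length
        grows or the flow slows; deviation at l=0.05 m is below 1 permil."""
        eq = ratio_to_delta(
            modeling_config.xylem.R_x[Species.O18]
            / equilibrium_alpha(Species.O18, modeling_config.env.T)
        )
        devs_l = []
        for length in (0.02, 0.05, 0.10, 0.30):
            cfg = modeling_config.with_updates(
                geom=BoreholeGeometry(r=0.005, wetted_length=length)
            )
            devs_l.append(abs(cfg.run().outlet_delta(Species.O18) - eq))
        assert all(b < a for a, b in zip(devs_l, devs_l[1:]))
        assert devs_l[1] < 1.0  # l = 0.05 m

        devs_q = []
        for q in (400.0, 120.0, 40.0, 10.0):
            cfg = modeling_config.with_updates(
                flow=AirflowSpec.from_ml_per_min(q)
            )
            devs_q.append(abs(cfg.run().outlet_delta(Species.O18) - eq))
        assert all(b < a for a, b in zip(devs_q, devs_q[1:]))

    def test_to_frame_layout(self, modeling_config):
        df = modeling_config.with_updates(N=10).run().to_frame()
        assert len(df) == 10
        assert {"segment", "position_m", "w", "h",
                "delta_o18_permil", "delta_h2_permil"} <= set(df.columns)
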