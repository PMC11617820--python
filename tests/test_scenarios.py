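"""Scenario builders: reference wear scenarios, schedules, mouthing, configs."""

import pytest

from agderm import params
from agderm.kinetics import simulate
from agderm.scenarios import (
    IndirectContactEvent,
    MissingSupplementaryData,
    OralEvent,
    Subject,
    face_mask_scenario,
    full_body_scenario,
    glove_mouthing_scenario,
    indirect_contact_load,
    load_scenario_config,
    sport_scenario,
    wear_schedule,
)


class TestFaceMask:
    def test_builders_are_pure(self):
        assert face_mask_scenario("AgCur", "fresh") == face_mask_scenario("AgCur", "fresh")

    def test_fresh_skin_eight_hour_intake(self):
        """AgCur face mask, fresh skin: ~12 ng reaches stratum corneum in 8 h."""
        traj = simulate(face_mask_scenario("AgCur", "fresh", wear_hours=8.0), dt=0.1)
        assert traj.sc_intake == pytest.approx(11.93, abs=0.02)
        assert round(traj.sc_intake) == 12

    def test_cryopreserved_to_fresh_ratio(self):
        fresh = simulate(face_mask_scenario("AgCur", "fresh"), dt=0.5).sc_intake
        cryo = simulate(face_mask_scenario("AgCur", "cryopreserved"), dt=0.5).sc_intake
        assert round(cryo / fresh, 1) == 1.5

    def test_skin_type_ratio_follows_rate_constants(self):
        """To first order m_sc scales as k_sc: glycerolized/fresh ~ 34/1.8."""
        fresh = simulate(face_mask_scenario("AgCur", "fresh"), dt=0.5).sc_intake
        gly = simulate(face_mask_scenario("AgCur", "glycerolized"), dt=0.5).sc_intake
        assert gly / fresh == pytest.approx(34.0 / 1.8, rel=1e-2)

    def test_zero_wear_gives_zero_trajectory(self):
        scenario = face_mask_scenario("AgCur", "fresh", wear_hours=0.0, horizon_hours=8.0)
        traj = simulate(scenario, dt=1.0)
        assert traj.sc_intake == 0.0 and traj.m_skin[-1] == 0.0

    def test_unknown_family_and_skin_rejected(self):
        with pytest.raises(ValueError, match="family"):
            face_mask_scenario("AgFoo", "fresh")
        with pytest.raises(ValueError, match="skin"):
            face_mask_scenario("AgCur", "sunburnt")


class TestFullBody:
    def test_glycerolized_worst_case(self):
        traj = simulate(full_body_scenario("AgHEC6.4", "glycerolized"), dt=0.1)
        assert traj.sc_intake == pytest.approx(8.86e3, rel=1e-2)

    def test_fresh_skin(self):
        traj = simulate(full_body_scenario("AgCur", "fresh"), dt=0.1)
        assert traj.sc_intake == pytest.approx(429.0, rel=1e-2)

    def test_exact_area_ratio(self):
        face = simulate(face_mask_scenario("AgHEC", "fresh"), dt=1.0).sc_intake
        body = simulate(full_body_scenario("AgHEC", "fresh"), dt=1.0).sc_intake
        assert body / face == pytest.approx(20000.0 / 555.0, rel=1e-12)


class TestWearSchedule:
    def test_thirty_minute_wear_reduces_intake_by_one_ng(self):
        """Stopping wear at 30 min (8-h horizon, deposit kept) loses ~1 ng."""
        full = simulate(face_mask_scenario("AgCur", "fresh", wear_hours=8.0), dt=0.1)
        short = simulate(
            face_mask_scenario("AgCur", "fresh", wear_hours=0.5, horizon_hours=8.0), dt=0.1
        )
        assert round(full.sc_intake - short.sc_intake) == 1

    def test_two_hour_wear_is_equivalent_to_continuous(self):
        """2-h and 8-h wear differ by <1% because the donor empties in ~1 h."""
        full = simulate(face_mask_scenario("AgCur", "fresh", wear_hours=8.0), dt=0.1)
        two = simulate(
            face_mask_scenario("AgCur", "fresh", wear_hours=2.0, horizon_hours=8.0), dt=0.1
        )
        assert abs(full.sc_intake - two.sc_intake) / full.sc_intake < 0.01
        assert round(two.sc_intake) == 12

    def test_wear_equal_to_horizon_matches_continuous(self):
        assert wear_schedule(8.0, 8.0) == ((0.0, 480.0),)

    def test_invalid_durations(self):
        with pytest.raises(ValueError):
            wear_schedule(8.0, -1.0)
        with pytest.raises(ValueError):
            wear_schedule(2.0, 8.0)


class TestGloveMouthing:
    def test_oral_intake_with_default_transfer(self):
        """1-h glove wear then mouthing 11.5 cm2 at TF=0.1 ingests ~1.76 ug."""
        traj = simulate(glove_mouthing_scenario("AgCur", 1.0, 11.5, 0.1), dt=0.1)
        assert traj.oral_intake == pytest.approx(1.76e3, rel=0.01)

    def test_complete_transfer(self):
        traj = simulate(glove_mouthing_scenario("AgCur", 1.0, 11.5, 1.0), dt=0.1)
        assert traj.oral_intake == pytest.approx(17.6e3, rel=0.01)

    def test_zero_transfer(self):
        traj = simulate(glove_mouthing_scenario("AgCur", 1.0, 11.5, 0.0), dt=0.1)
        assert traj.oral_intake == 0.0

    def test_conservation_across_the_event(self):
        traj = simulate(glove_mouthing_scenario("AgCur", 1.0, 11.5, 0.5), dt=0.1)
        traj.validate()
        assert traj.conservation_residual() <= 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            glove_mouthing_scenario("AgCur", 1.0, 11.5, 1.5)
        with pytest.raises(ValueError):
            glove_mouthing_scenario("AgCur", 1.0, fingertip_area=1000.0)


class TestIndirectContact:
    @pytest.mark.parametrize(
        "ms, area, tf, expected",
        [(10.0, 100.0, 0.5, 500.0), (10.0, 100.0, 0.0, 0.0), (7.3, 1.0, 1.0, 7.3)],
    )
    def test_load_arithmetic(self, ms, area, tf, expected):
        assert indirect_contact_load(IndirectContactEvent(ms, area, tf)) == expected

    def test_invalid_transfer_efficiency(self):
        with pytest.raises(ValueError):
            IndirectContactEvent(10.0, 100.0, 1.2)


class TestSportScenario:
    CONFIG = {"garment_masses_kg": {"t-shirt": 0.110, "trousers": 0.0843}}

    def test_requires_supplementary_garment_masses(self):
        with pytest.raises(MissingSupplementaryData, match="Table S1"):
            sport_scenario({})

    def test_exposure_is_summed_first_order_emission(self):
        """Dermal exposure equals sum of m0*(1-exp(-60k)) over both garments."""
        import math

        scenarios = sport_scenario(self.CONFIG)
        exposure = sum(
            simulate(s, dt=0.1).m_p0 - simulate(s, dt=0.1).m_textile[-1] for s in scenarios
        )
        expected = 0.0
        for garment, (mg_per_kg, *_rest, k) in params.IMMERSION_GARMENTS.items():
            m0 = mg_per_kg * self.CONFIG["garment_masses_kg"][garment] * 1e6
            expected += m0 * (1.0 - math.exp(-k * 60.0))
        assert exposure == pytest.approx(expected, rel=1e-6)

    def test_zero_release_constants_give_zero_exposure(self):
        config = dict(self.CONFIG)
        config["release_constants_per_min"] = {"t-shirt": 0.0, "trousers": 0.0}
        for s in sport_scenario(config):
            traj = simulate(s, dt=1.0)
            assert traj.m_textile[-1] == traj.m_p0 and traj.sc_intake == 0.0


class TestYamlConfig:
    VALID = {
        "label": "test",
        "product": {"load_ng_cm2": 1530.0, "area_cm2": 555.0},
        "rates": {"kp_per_min": 0.086, "ksc_per_h": 1.8e-6},
        "schedule": {"horizon_h": 8.0, "wear_h": 8.0},
    }

    def test_valid_config_builds_scenario(self, tmp_path):
        import yaml

        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(self.VALID))
        scenario = load_scenario_config(path)
        assert scenario.product.initial_mass == pytest.approx(1530.0 * 555.0)
        assert scenario.horizon_min == 480.0

    def test_unknown_section_rejected(self):
        bad = dict(self.VALID, extra={"x": 1})
        with pytest.raises(ValueError, match="unknown config sections"):
            load_scenario_config(bad)

    def test_missing_required_key_rejected(self):
        bad = dict(self.VALID, rates={"kp_per_min": 0.086})
        with pytest.raises(ValueError, match="ksc_per_h"):
            load_scenario_config(bad)

    def test_non_numeric_value_rejected(self):
        bad = dict(self.VALID, schedule={"horizon_h": "soon", "wear_h": 8.0})
        with pytest.raises(ValueError, match="schedule.horizon_h"):
            load_scenario_config(bad)

    def test_oral_and_subject_sections(self):
        cfg = dict(
            self.VALID,
            oral={"time_h": 8.0, "area_cm2": 11.5, "tf": 0.1},
            subject={"bw_kg": 70.0, "dnel_mg_kg_day": 0.02},
        )
        scenario = load_scenario_config(cfg)
        assert scenario.oral_events[0].time_min == 480.0
        assert scenario.subject.body_weight_kg == 70.0


def test_subject_validation():
    with pytest.raises(ValueError):
        Subject(body_weight_kg=0.0)
    with pytest.raises(ValueError):
        Subject(dnel_mg_per_kg_day=-0.01)


def test_oral_event_validation():
    with pytest.raises(ValueError):
        OralEvent(10.0, 11.5, transfer_efficiency=2.0)
    with pytest.raises(ValueError):
        OralEvent(10.0, 11.5, 0.1, retention=1.5)
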