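"""Call schedules, maneuver selection, kinematic limits, collisions."""

import numpy as np
import pytest

from echoroost.arena import BatState, build_arena, spawn_bats
from echoroost.behavior import (MAX_ACCEL, ManeuverCommand, SpeciesSchedule,
                                adapt_speed_to_turn, decide_maneuver,
                                handle_collisions, integrate_kinematics,
                                next_call_params, select_phase)
from echoroost.perception import MemoryFrame, Pose, update_memory
from echoroost.receiver import Detection

PK = SpeciesSchedule("PK")
RM = SpeciesSchedule("RM")


class TestPhaseSelection:
    @pytest.mark.parametrize("dist,phase", [
        (None, "search"), (1.5, "search"), (1.2, "approach"),
        (0.8, "approach"), (0.4, "approach"), (0.3, "buzz1"),
        (0.2, "buzz1"), (0.15, "buzz2"), (0.0, "buzz2")])
    def test_breakpoints(self, dist, phase):
        assert select_phase(dist) == phase


class TestCallSchedule:
    def test_pk_approach_start_anchor(self):
        p = next_call_params("approach", 1.2, PK)
        assert p.ipi_ms == pytest.approx(70)
        assert p.duration_ms == pytest.approx(5)
        assert p.bandwidth_khz == pytest.approx(35)
        assert p.level_db == pytest.approx(120)

    def test_pk_approach_end_anchor(self):
        assert next_call_params("approach", 0.4, PK).ipi_ms == pytest.approx(35)

    def test_pk_approach_midpoint_interpolation(self):
        assert next_call_params("approach", 0.8, PK).ipi_ms \
            == pytest.approx(52.5)

    def test_pk_final_buzz(self):
        p = next_call_params("buzz2", 0.1, PK)
        assert p.ipi_ms == pytest.approx(5)
        assert p.duration_ms == pytest.approx(0.3)
        assert p.level_db == pytest.approx(80)

    def test_rm_search_call(self):
        p = next_call_params("search", None, RM)
        assert (p.ipi_ms, p.duration_ms, p.terminal_freq_khz,
                p.bandwidth_khz) == (100, 12, 26, 3)

    def test_individual_offset_shifts_terminal_frequency(self):
        p = next_call_params("search", None, PK, individual_offset_khz=1.3)
        assert p.terminal_freq_khz == pytest.approx(40.3)

    @pytest.mark.parametrize("schedule", [PK, RM])
    def test_ipi_decreases_and_duration_fits(self, schedule):
        t = schedule.table
        assert all(a >= b for a, b in zip(t["ipi_ms"], t["ipi_ms"][1:]))
        assert all(d < i for d, i in zip(t["duration_ms"], t["ipi_ms"]))


def _mem_with(points, bat_points=(), pose=None, time=0.0):
    pose = pose or Pose(position=np.array([0.0, 0.0]), heading=0.0)
    dets = []
    for p in points:
        r = float(np.linalg.norm(p))
        dets.append(Detection(reflector_ref=0, kind="own_wall_echo",
                              true_delay=2 * r / 343, detected_delay=2 * r / 343,
                              timing_error=0.0, snr=30.0, status="detected",
                              est_range=r,
                              est_doa=float(np.arctan2(p[1], p[0]))))
    for p in bat_points:
        r = float(np.linalg.norm(p))
        dets.append(Detection(reflector_ref=1, kind="own_bat_echo",
                              true_delay=2 * r / 343, detected_delay=2 * r / 343,
                              timing_error=0.0, snr=30.0, status="detected",
                              est_range=r,
                              est_doa=float(np.arctan2(p[1], p[0]))))
    return update_memory(MemoryFrame(), dets, None, pose, time)


def _bat(speed=3.0):
    return BatState(id=0, position=np.array([0.0, 0.0]), heading=0.0,
                    speed=speed, phase="approach")


class TestManeuverPriorities:
    def test_conspecific_outranks_obstacle(self, rng):
        mem = _mem_with([[1.0, 0.0]], bat_points=[[0.3, 0.1]])
        cmd = decide_maneuver(mem, _bat(), 6.0, rng, 0.05)
        assert cmd.mode == "avoid_conspecific"

    def test_empty_memory_defaults_to_random_walk(self, rng):
        cmd = decide_maneuver(MemoryFrame(), _bat(), 6.0, rng, 0.1)
        assert cmd.mode == "random_walk"
        assert cmd.max_turn_rate == pytest.approx(np.deg2rad(30))

    def test_gap_ahead_targets_its_center(self, rng):
        mem = _mem_with([[2.0, -0.7], [2.0, 0.7]])
        cmd = decide_maneuver(mem, _bat(), 6.0, rng, 0.05)
        assert cmd.mode == "gap_approach"
        assert abs(cmd.target_heading) < np.deg2rad(10)

    def test_obstacle_on_collision_course_triggers_avoidance(self, rng):
        pts = [[1.0, 0.05], [1.2, 0.05], [1.4, 0.04]]
        mem = _mem_with(pts)
        cmd = decide_maneuver(mem, _bat(), 6.0, rng, 0.05)
        assert cmd.mode == "avoid_obstacle"

    def test_priority_deterministic_given_inputs(self, rng):
        mem = _mem_with([[1.0, 0.05], [1.3, -0.6], [1.5, 0.8]])
        modes = {decide_maneuver(mem, _bat(), 6.0,
                                 np.random.default_rng(9), 0.05).mode
                 for _ in range(5)}
        assert len(modes) == 1

    def test_search_phase_cruises_at_nominal(self, rng):
        bat = _bat()
        bat.phase = "search"
        cmd = decide_maneuver(MemoryFrame(), bat, 6.0, rng, 0.1)
        assert cmd.target_speed == pytest.approx(6.0)

    def test_approach_phase_cruises_at_half_nominal(self, rng):
        mem = _mem_with([[2.0, -0.7], [2.0, 0.7]])
        cmd = decide_maneuver(mem, _bat(), 6.0, rng, 0.05)
        assert cmd.target_speed <= 3.0 + 1e-9


class TestKinematics:
    def test_straight_flight_displacement(self):
        bat = _bat(speed=3.0)
        cmd = ManeuverCommand("random_walk", target_heading=0.0,
                              target_speed=3.0)
        integrate_kinematics(bat, cmd, 0.01, 6.0, speed_tau_s=0.05)
        assert bat.position[0] == pytest.approx(0.03)
        assert bat.position[1] == pytest.approx(0.0)

    def test_speed_never_exceeds_nominal(self):
        bat = _bat(speed=5.9)
        cmd = ManeuverCommand("random_walk", 0.0, target_speed=10.0)
        for _ in range(200):
            integrate_kinematics(bat, cmd, 1e-3, 6.0, speed_tau_s=0.01)
        assert bat.speed <= 6.0 + 1e-9

    def test_linear_acceleration_clamped(self):
        bat = _bat(speed=0.0)
        cmd = ManeuverCommand("random_walk", 0.0, target_speed=6.0)
        v0 = bat.speed
        integrate_kinematics(bat, cmd, 1e-3, 6.0, speed_tau_s=1e-4)
        assert abs(bat.speed - v0) <= MAX_ACCEL * 1e-3 + 1e-12

    def test_centripetal_limit_caps_turn_rate(self):
        # commanded 180 deg turn at 6 m/s: omega <= a_max / v = 2/3 rad/s
        bat = _bat(speed=6.0)
        cmd = ManeuverCommand("avoid_obstacle", target_heading=np.pi,
                              target_speed=6.0)
        dt = 1e-3
        integrate_kinematics(bat, cmd, dt, 6.0, speed_tau_s=1.0)
        assert abs(bat.heading) <= (MAX_ACCEL / 6.0) * dt + 1e-12

    def test_random_walk_turn_rate_limit(self):
        bat = _bat(speed=1.0)
        cmd = ManeuverCommand("random_walk", target_heading=np.pi,
                              target_speed=1.0,
                              max_turn_rate=np.deg2rad(30))
        for _ in range(1000):
            integrate_kinematics(bat, cmd, 1e-3, 6.0, speed_tau_s=0.1)
        assert abs(bat.heading) <= np.deg2rad(30) + 1e-9

    def test_turn_offset_slows_target_speed(self):
        bat = _bat(speed=3.0)
        cmd = ManeuverCommand("wall_follow", target_heading=np.pi / 2,
                              target_speed=3.0)
        adapted = adapt_speed_to_turn(cmd, bat)
        assert adapted.target_speed < 1.0


class TestCollisions:
    def test_isolated_bat_unchanged(self, arena):
        bat = BatState(id=0, position=np.array([5.0, 1.25]), heading=0.3,
                       speed=3.0)
        before = bat.position.copy()
        handle_collisions(bat, arena, [], 1e-3, True)
        assert np.array_equal(bat.position, before)
        assert bat.wall_collision_events == 0

    def test_wall_contact_resets_heading_perpendicular(self, arena):
        bat = BatState(id=0, position=np.array([5.0, 0.05]),
                       heading=-np.pi / 3, speed=3.0)
        armed = handle_collisions(bat, arena, [], 1e-3, True)
        assert bat.wall_collision_events == 1
        assert bat.heading == pytest.approx(np.pi / 2)   # inward from y=0 wall
        assert not armed                                 # debounced

    def test_debounce_requires_clearance(self, arena):
        bat = BatState(id=0, position=np.array([5.0, 0.05]),
                       heading=-np.pi / 3, speed=3.0)
        armed = handle_collisions(bat, arena, [], 1e-3, True)
        bat.position = np.array([5.0, 0.1])
        armed = handle_collisions(bat, arena, [], 1e-3, armed)
        assert bat.wall_collision_events == 1            # still one event

    def test_conspecific_overlap_decelerates_and_diverges(self, arena):
        a = BatState(id=0, position=np.array([5.0, 1.2]), heading=0.0,
                     speed=3.0)
        b = BatState(id=1, position=np.array([5.3, 1.2]), heading=np.pi,
                     speed=3.0)
        sep0 = np.linalg.norm(a.position - b.position)
        for _ in range(300):
            handle_collisions(a, arena, [b], 1e-3, True)
            handle_collisions(b, arena, [a], 1e-3, True)
            a.position += a.speed * 1e-3 * np.array([np.cos(a.heading),
                                                     np.sin(a.heading)])
            b.position += b.speed * 1e-3 * np.array([np.cos(b.heading),
                                                     np.sin(b.heading)])
            if np.linalg.norm(a.position - b.position) > 0.4:
                break
        assert np.linalg.norm(a.position - b.position) > sep0
        assert a.conspecific_contact and b.conspecific_contact
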