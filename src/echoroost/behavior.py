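"""Phase-based echolocation scheduling and the flight controller.

Call design follows the stereotyped search / approach / buzz progression of
FM insectivores: outside 1.2 m the bat emits constant search calls; below
that the inter-pulse interval, duration, bandwidth and intensity are linearly
interpolated against the distance to the closest detected object between
phase anchor points (approach 1.2-0.4 m, first buzz 0.4-0.2 m, final buzz
below 0.2 m).

The movement controller picks exactly one maneuver per decision, in fixed
priority order: conspecific avoidance (< 0.4 m), obstacle avoidance (< 1.5 m
within +-60 deg of heading), flight toward a detected gap (>= 0.5 m),
wall-following toward the farthest detected obstacle ahead while holding a
0.8 m wall offset, and otherwise a correlated random walk limited to
30 deg/s. Linear and centripetal accelerations are both capped at 4 m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import (APPROACH, BAT_RADIUS, BUZZ1, BUZZ2, SEARCH, Arena,
                    BatState, point_segment_distance)
from .acoustics import CallParams
from .perception import MemoryFrame, Pose, cluster_and_reconstruct, find_gaps

MAX_ACCEL = 4.0                 # m/s^2, linear and centripetal
RANDOM_WALK_TURN_RATE = np.deg2rad(30.0)    # rad/s
OBSTACLE_AVOID_DIST = 1.5       # m
OBSTACLE_AVOID_HALF_ANGLE = np.deg2rad(60.0)
COLLISION_COURSE_MISS = 0.3     # m, projected lateral miss (bat radius + clearance)
CONSPECIFIC_AVOID_DIST = 0.4    # m
WALL_FOLLOW_OFFSET = 0.8        # m
GAP_MIN = 0.5                   # m
HEAD_ON_GATE = np.deg2rad(5.0)  # tie-break gate for dead-ahead obstacles
DISTANCE_QUANTUM = 0.05         # m, call-design distance grid

RANDOM_WALK = "random_walk"
AVOID_OBSTACLE = "avoid_obstacle"
AVOID_CONSPECIFIC = "avoid_conspecific"
WALL_FOLLOW = "wall_follow"
GAP_APPROACH = "gap_approach"

# anchor columns: search, approach start/end, buzz1 start/end, buzz2
_TABLE = {
    "PK": {
        "ipi_ms": (100.0, 70.0, 35.0, 18.0, 6.0, 5.0),
        "duration_ms": (7.0, 5.0, 2.0, 2.0, 1.0, 0.3),
        "terminal_khz": (39.0,) * 6,
        "bandwidth_khz": (8.0, 35.0, 30.0, 30.0, 20.0, 20.0),
        "level_db": (120.0, 120.0, 90.0, 90.0, 80.0, 80.0),
    },
    "RM": {
        "ipi_ms": (100.0, 80.0, 20.0, 18.0, 10.0, 9.0),
        "duration_ms": (12.0, 7.0, 2.0, 2.0, 1.5, 0.75),
        "terminal_khz": (26.0, 26.0, 26.0, 26.0, 26.0, 23.5),
        "bandwidth_khz": (3.0, 4.0, 5.0, 3.0, 3.0, 3.0),
        "level_db": (120.0,) * 2 + (90.0,) * 2 + (80.0,) * 2,
    },
}

# distance spans per interpolated phase: (far anchor col, near anchor col, d_far, d_near)
_PHASE_SPANS = {
    APPROACH: (1, 2, 1.2, 0.4),
    BUZZ1: (3, 4, 0.4, 0.2),
}


@dataclass
class SpeciesSchedule:
    """Per-phase call-parameter anchors for one species (Table anchors)."""

    species: str = "PK"

    @property
    def table(self):
        return _TABLE[self.species]

    def anchor(self, col: int) -> dict:
        t = self.table
        return {k: t[k][col] for k in t}


def select_phase(distance: float | None, schedule: SpeciesSchedule | None = None
                 ) -> str:
    """Echolocation phase from distance to the closest detected object."""
    if distance is None or distance > 1.2:
        return SEARCH
    if distance >= 0.4:
        return APPROACH
    if distance >= 0.2:
        return BUZZ1
    return BUZZ2


def next_call_params(phase: str, distance: float | None,
                     schedule: SpeciesSchedule,
                     individual_offset_khz: float = 0.0) -> CallParams:
    """Call design for the coming call, interpolated within the phase span.

    The distance is snapped to a 0.05 m grid before interpolation (pure
    numerics: lets downstream per-design filter banks be reused).
    """
    t = schedule.table
    if phase == SEARCH:
        vals = schedule.anchor(0)
    elif phase == BUZZ2:
        vals = schedule.anchor(5)
    else:
        c_far, c_near, d_far, d_near = _PHASE_SPANS[phase]
        d = np.clip(round(float(distance) / DISTANCE_QUANTUM) * DISTANCE_QUANTUM,
                    d_near, d_far)
        w = (d_far - d) / (d_far - d_near)
        vals = {k: (1 - w) * t[k][c_far] + w * t[k][c_near] for k in t}
    return CallParams(ipi_ms=vals["ipi_ms"], duration_ms=vals["duration_ms"],
                      terminal_freq_khz=vals["terminal_khz"] + individual_offset_khz,
                      bandwidth_khz=vals["bandwidth_khz"],
                      level_db=vals["level_db"], species=schedule.species)


@dataclass
class ManeuverCommand:
    mode: str
    target_heading: float
    target_speed: float
    max_turn_rate: float | None = None   # rad/s; None = acceleration-limited
    gap_center: np.ndarray | None = None  # opening currently steered for
    gap_axis: np.ndarray | None = None
    gap_width: float = 0.5


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _bearing(points: np.ndarray, pose: Pose):
    rel = np.atleast_2d(points) - pose.position
    d = np.linalg.norm(rel, axis=1)
    b = _wrap(np.arctan2(rel[:, 1], rel[:, 0]) - pose.heading)
    return d, b


def decide_maneuver(mem: MemoryFrame, state: BatState, nominal_speed: float,
                    rng: np.random.Generator, current_ipi_s: float,
                    clustering: bool = False,
                    conspecific_avoid_dist: float = CONSPECIFIC_AVOID_DIST,
                    committed_gap: tuple | None = None,
                    travel_dir: np.ndarray | None = None
                    ) -> ManeuverCommand:
    """Select one movement command from the integrated detection memory.

    Collision avoidance consumes both the integrated memory and the raw
    last-call detections (already the newest set in the guidance buffer).
    ``committed_gap`` is an opening chosen on a recent call that is still
    being flown through; while valid it outranks obstacle avoidance, since
    threading the opening is itself the avoidance maneuver and re-deciding
    each call makes its flanking detections capture the controller.
    """
    pose = Pose(position=state.position, heading=state.heading)
    walls = mem.wall_points()
    last = mem.last_call()
    # conspecific positions go stale within a call or two (neighbors move);
    # avoidance reacts to the immediate last-call detections only
    bats = last.bat_points if last is not None else np.empty((0, 2))
    cruise = nominal_speed if state.phase == SEARCH else nominal_speed / 2.0

    # priority 1: conspecific too close
    if len(bats):
        d, b = _bearing(bats, pose)
        i = int(np.argmin(d))
        if d[i] < conspecific_avoid_dist:
            away = _wrap(pose.heading + b[i] + np.pi - pose.heading)
            return ManeuverCommand(AVOID_CONSPECIFIC,
                                   target_heading=pose.heading + away,
                                   target_speed=cruise / 2.0)

    def _gap_blocked(center: np.ndarray, axis: np.ndarray | None = None,
                     width: float = 0.5) -> bool:
        # a real opening keeps its approach line clear of wall detections
        # AND leads somewhere: clearance beyond the gap is checked along the
        # opening's normal (walls converging just beyond a concave corner
        # make a false gap; a diagonal sight line through a true doorway
        # may legitimately end at a wall further on)
        if not len(walls):
            return False
        seg = center - pose.position
        L = np.linalg.norm(seg)
        if L < 1e-9:
            return False
        # center clearance: flanks sit at width/2; anything nearer is a
        # detection inside the "opening"
        if np.min(np.linalg.norm(walls - center, axis=1)) < 0.4 * width:
            return True
        checks = [(pose.position, center, 0.2)]
        if axis is not None:
            normal = np.array([-axis[1], axis[0]])
            if float(normal @ seg) < 0:
                normal = -normal
            checks.append((center, center + 0.6 * normal, 0.3))
        for a, c, lim in checks:
            v = c - a
            vv = float(v @ v)
            tproj = np.clip((walls - a) @ v / vv, 0.0, 1.0)
            closest = a + tproj[:, None] * v
            if np.min(np.linalg.norm(walls - closest, axis=1)) < lim:
                return True
        return False

    # priority 2a: keep flying through the opening already committed to,
    # re-validating it against the accumulating detections each call and
    # slowing with proximity to the nearest detection
    if committed_gap is not None:
        c_center, c_axis, c_width = committed_gap
        if not _gap_blocked(c_center, c_axis, c_width):
            dg, bg = _bearing(c_center[None], pose)
            if abs(bg[0]) <= np.deg2rad(100.0) and dg[0] > 0.25:
                slow = 1.0
                if len(walls):
                    dmin = float(np.min(np.linalg.norm(walls - pose.position,
                                                       axis=1)))
                    slow = float(np.clip(dmin / OBSTACLE_AVOID_DIST, 0.3, 1.0))
                tgt = float(np.arctan2(*(c_center - pose.position)[::-1]))
                return ManeuverCommand(GAP_APPROACH, target_heading=tgt,
                                       target_speed=cruise * 0.75 * slow,
                                       gap_center=c_center, gap_axis=c_axis,
                                       gap_width=c_width)

    # openings (used by priority 3, and to override flank-triggered avoidance)
    if clustering:
        _, openings = cluster_and_reconstruct(mem.cluster_points())
        gaps = [(o.center, o.width, o.axis) for o in openings]
    else:
        gaps = find_gaps(walls, pose, GAP_MIN, max_gap=np.inf)
    best, best_w, best_axis = None, 0.5, None
    for center, width, axis in gaps:
        _, gb = _bearing(center[None], pose)
        if abs(gb[0]) <= np.pi / 2 and not _gap_blocked(center, axis, width):
            # widest valid opening: broad passages (the corridor ahead, the
            # corner mouth) outrank narrow breaks in the detection chain
            if best is None or width > best_w:
                best, best_w, best_axis = center, width, axis

    # priority 2: obstacle ahead and too close (collision course: small
    # projected lateral miss distance, not merely inside the sensing cone)
    if len(walls):
        d, b = _bearing(walls, pose)
        near = ((d < OBSTACLE_AVOID_DIST)
                & (np.abs(b) < OBSTACLE_AVOID_HALF_ANGLE)
                & (d * np.abs(np.sin(b)) < COLLISION_COURSE_MISS))
        if near.any():
            i = int(np.argmin(np.where(near, d, np.inf)))
            side = b[i]
            # free path toward each candidate escape direction (+-60 deg):
            # nearest detection within a 30 deg cone, open = no detection
            def _free(cand):
                cone = np.abs(_wrap(b - cand)) < np.deg2rad(30.0)
                return float(d[cone].min()) if cone.any() else np.inf
            free_l = _free(np.deg2rad(60.0))
            free_r = _free(np.deg2rad(-60.0))
            if max(free_l, free_r) < 1.0:
                # cramped on both flanks (corner pocket): head for the
                # globally most open direction instead of dodging locally
                cands = np.deg2rad(np.arange(-150.0, 151.0, 30.0))
                frees = np.array([_free(c) for c in cands])
                frees = np.minimum(frees, 6.0) - 0.1 * np.abs(cands)
                k = int(np.argmax(frees))
                return ManeuverCommand(AVOID_OBSTACLE,
                                       target_heading=pose.heading + cands[k],
                                       target_speed=cruise * 0.25)
            # turn toward the freer flank, rotating just far enough to put
            # the threat abeam (90 deg) on the other side -- grazing rather
            # than reversing; slow down with proximity so the turn radius
            # shrinks faster than the gap closes
            if free_l == free_r:       # coin flip on an exact tie
                sgn = 1.0 if rng.random() < 0.5 else -1.0
            else:
                sgn = 1.0 if free_l > free_r else -1.0
            turn = side + sgn * np.pi / 2
            slow = np.clip(d[i] / OBSTACLE_AVOID_DIST, 0.25, 1.0)
            return ManeuverCommand(AVOID_OBSTACLE,
                                   target_heading=pose.heading + turn,
                                   target_speed=cruise * slow)

    # priority 3: fly through a detected opening (holding wall standoff)
    if best is not None:
        tgt = float(np.arctan2(*(best - pose.position)[::-1]))
        return ManeuverCommand(GAP_APPROACH, target_heading=tgt,
                               target_speed=cruise, gap_center=best,
                               gap_axis=best_axis, gap_width=best_w)

    # priority 4: wall-follow -- steer toward the farthest detection ahead
    # while holding the 0.8 m standoff from the nearest wall (bilateral:
    # steer away when closer, back toward the wall when drifting off)
    if len(walls):
        d, b = _bearing(walls, pose)
        # slightly wider than a half-plane: right after a wall contact the
        # heading is perpendicular to the wall and the useful continuation
        # can sit just past 90 deg; travel alignment damps backward picks
        fwd = np.abs(b) <= np.deg2rad(110.0)
        # after a wall contact the heading is reset perpendicular to the
        # wall; keep following in the direction the bat was traveling
        # rather than whichever way the reset happens to face
        score = d.copy()
        if travel_dir is not None and np.linalg.norm(travel_dir) > 1e-6:
            rel = walls - pose.position
            td = travel_dir / np.linalg.norm(travel_dir)
            align = (rel @ td) / np.maximum(d, 1e-9)
            score = d * np.maximum(align, 0.1)
        if fwd.any():
            i = int(np.argmax(np.where(fwd, score, -np.inf)))
            base = float(np.arctan2(*(walls[i] - pose.position)[::-1]))
            j = int(np.argmin(d))
            err = WALL_FOLLOW_OFFSET - d[j]    # >0: too close to nearest wall
            corr = np.clip(err / 0.45, -1.0, 1.0) * (-np.sign(b[j])) * np.deg2rad(45)
            return ManeuverCommand(WALL_FOLLOW, target_heading=base + corr,
                                   target_speed=cruise)

    # priority 5: correlated random walk
    dpsi = rng.normal(0.0, 0.5 * RANDOM_WALK_TURN_RATE * current_ipi_s)
    dpsi = float(np.clip(dpsi, -RANDOM_WALK_TURN_RATE * current_ipi_s,
                         RANDOM_WALK_TURN_RATE * current_ipi_s))
    return ManeuverCommand(RANDOM_WALK, target_heading=state.heading + dpsi,
                           target_speed=cruise,
                           max_turn_rate=RANDOM_WALK_TURN_RATE)


def adapt_speed_to_turn(cmd: ManeuverCommand, state: BatState
                        ) -> ManeuverCommand:
    """Scale the target speed down when the commanded heading is far off.

    Speed adapts to the relative direction of the steering target: a bat
    commanded to turn sharply (e.g. the right-angle corner, or a wall dead
    ahead) slows toward a quarter of the phase speed, which shrinks the
    acceleration-limited turn radius enough to complete the maneuver.
    """
    if cmd.mode == RANDOM_WALK:
        return cmd
    off = abs(_wrap(cmd.target_heading - state.heading))
    cmd.target_speed *= max(np.cos(off), 0.25)
    return cmd


def integrate_kinematics(state: BatState, cmd: ManeuverCommand, dt: float,
                         nominal_speed: float, speed_tau_s: float,
                         a_max: float = MAX_ACCEL) -> BatState:
    """Advance one bat by ``dt`` toward the command targets.

    Speed follows a first-order lag (time constant = one current IPI) toward
    the phase target, with |dv/dt| <= a_max; heading turns toward the target
    at a rate bounded by centripetal acceleration (v * omega <= a_max) and by
    the command's own turn-rate limit, if any.
    """
    dv = (cmd.target_speed - state.speed) * dt / max(speed_tau_s, dt)
    dv = float(np.clip(dv, -a_max * dt, a_max * dt))
    state.speed = float(np.clip(state.speed + dv, 0.0, nominal_speed))

    omega_max = a_max / max(state.speed, 0.5)
    if cmd.max_turn_rate is not None:
        omega_max = min(omega_max, cmd.max_turn_rate)
    err = _wrap(cmd.target_heading - state.heading)
    state.heading = _wrap(state.heading
                          + float(np.clip(err, -omega_max * dt, omega_max * dt)))
    state.position = state.position + state.speed * dt * np.array(
        [np.cos(state.heading), np.sin(state.heading)])
    return state


class SimulationIntegrityError(RuntimeError):
    """A bat left the arena through a wall or reached an invalid state."""


def handle_collisions(state: BatState, arena: Arena, others: list[BatState],
                      dt: float, wall_armed: bool,
                      conspecific_avoid_dist: float = CONSPECIFIC_AVOID_DIST,
                      a_max: float = MAX_ACCEL) -> bool:
    """Resolve wall contact and conspecific overlap for one bat, in place.

    On wall contact the heading is reset perpendicular to the contacted wall
    (into the arena) and one collision is counted per debounced contact event
    (``wall_armed``); the updated armed flag is returned. Conspecific overlap
    (< 0.4 m) decelerates the bat and rotates it away from the nearest
    neighbor each step; no collision is counted.
    """
    segs = arena.blocking_segments
    d = point_segment_distance(state.position, segs)
    i = int(np.argmin(d))
    if d[i] < BAT_RADIUS:
        a, b = segs[i]
        ab = b - a
        t = np.clip(np.dot(state.position - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        closest = a + t * ab
        normal = state.position - closest
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 1e-12 else np.array([1.0, 0.0])
        state.heading = float(np.arctan2(normal[1], normal[0]))
        state.position = closest + normal * BAT_RADIUS
        if wall_armed:
            state.wall_collision_events += 1
            wall_armed = False
    elif d[i] > 2 * BAT_RADIUS:
        wall_armed = True

    if not np.all(np.isfinite(state.position)):
        raise SimulationIntegrityError(f"bat {state.id} reached NaN state")
    xmin, ymin, xmax, ymax = arena.bounds
    m = 0.5
    if not (xmin - m <= state.position[0] <= xmax + m
            and ymin - m <= state.position[1] <= ymax + m):
        raise SimulationIntegrityError(f"bat {state.id} escaped the arena")

    if others:
        opos = np.array([o.position for o in others])
        dd = np.linalg.norm(opos - state.position, axis=1)
        j = int(np.argmin(dd))
        if dd[j] < conspecific_avoid_dist:
            state.conspecific_contact = True
            state.speed = float(max(state.speed - a_max * dt, 0.5))
            away = state.position - opos[j]
            away_hdg = float(np.arctan2(away[1], away[0]))
            omega = a_max / max(state.speed, 0.5)
            err = _wrap(away_hdg - state.heading)
            state.heading = _wrap(state.heading
                                  + float(np.clip(err, -omega * dt, omega * dt)))
    return wall_armed
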