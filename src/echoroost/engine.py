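"""Trial engine: asynchronous call scheduling, motion integration, metrics.

Each bat runs its own emit -> receive -> decide loop: it emits a call, waits
one inter-pulse interval while all bats' motion integrates in lockstep 1 ms
ticks, then processes every sound component that arrived during the window
(dual-pass detection, localization, memory update), chooses a maneuver and
the next call design, and emits again. Bats are removed from the acoustic
scene when they cross the exit segment. All randomness derives from one
master seed with independent substreams per bat.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acoustics, behavior, perception, receiver
from .acoustics import CallEvent, PropagationModel, compose_received_scene
from .arena import Arena, ArenaConfig, BatState, build_arena, spawn_bats
from .behavior import SpeciesSchedule
from .perception import MemoryFrame, Pose
from .receiver import DOAModel

TRAJECTORY_SAMPLE_S = 0.02
CALL_LOG_HORIZON_S = 0.15   # how long emitted calls stay relevant as maskers


@dataclass
class TrialConfig:
    """One simulated emergence trial."""

    n_bats: int = 1
    species: str = "PK"
    masking: bool = True
    confusion: bool = False
    clustering: bool = False
    window_calls: int = perception.DEFAULT_WINDOW_CALLS
    nominal_speed: float = 6.0          # m/s
    call_level_db: float = 120.0        # search-phase level; shifts all anchors
    wall_target_strength: float = -22.5  # dB
    conspecific_target_strength: float = -23.0  # dB
    duration: float = 15.0              # s
    seed: int = 0
    conspecific_avoid_dist: float = 0.4  # m
    fs: float = receiver.DEFAULT_FS
    dt: float = 1e-3
    occlusion: bool = True
    arena: ArenaConfig = field(default_factory=ArenaConfig)

    def __post_init__(self):
        if self.duration <= 0 or self.n_bats < 1:
            raise ValueError("duration must be positive and n_bats >= 1")


@dataclass
class TrialMetrics:
    exit_probability: float
    times_to_exit: list[float]
    wall_collision_rate: float          # events / bat / s in arena
    jamming_probability: float | None   # None if no echoes detected
    detection_prob_1m: float | None     # None if never a reflector within 1 m
    mean_nearest_neighbor: float | None
    n_bats: int
    n_calls: int
    n_echoes_free: int
    n_echoes_jammed: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mean_time_to_exit"] = (float(np.mean(self.times_to_exit))
                                  if self.times_to_exit else None)
        return d


@dataclass
class TrialResult:
    config: TrialConfig
    metrics: TrialMetrics
    bats: list[BatState]
    trajectories: pd.DataFrame
    calls: pd.DataFrame


class _BatRuntime:
    """Per-bat mutable bookkeeping that is not part of BatState."""

    def __init__(self, state: BatState, cfg: TrialConfig, rng, schedule):
        self.state = state
        self.rng = rng
        self.mem = MemoryFrame(window_calls=cfg.window_calls)
        self.schedule = schedule
        self.level_shift = cfg.call_level_db - 120.0
        self.params = self._shift(behavior.next_call_params(
            behavior.SEARCH, None, schedule, state.terminal_freq_offset))
        self.cmd = behavior.ManeuverCommand(
            behavior.RANDOM_WALK, target_heading=state.heading,
            target_speed=cfg.nominal_speed)
        self.last_event: CallEvent | None = None
        self.wall_armed = True
        self.airborne = False
        self.committed_gap: np.ndarray | None = None
        self.gap_expiry: float = 0.0
        self.travel_dir = np.zeros(2)
        self.prev_pos = state.position.copy()

    def _shift(self, p):
        return dataclasses.replace(p, level_db=p.level_db + self.level_shift)


def _segments_cross(p0, p1, a, b) -> bool:
    d = p1 - p0
    e = b - a
    denom = d[0] * e[1] - d[1] * e[0]
    if abs(denom) < 1e-14:
        return False
    ap = a - p0
    t = (ap[0] * e[1] - ap[1] * e[0]) / denom
    u = (ap[0] * d[1] - ap[1] * d[0]) / denom
    return 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0


def run_trial(cfg: TrialConfig) -> TrialResult:
    """Run one seeded trial and compute its metrics."""
    arena_cfg = dataclasses.replace(
        cfg.arena, wall_target_strength=cfg.wall_target_strength)
    arena = build_arena(arena_cfg)
    model = PropagationModel(
        bat_target_strength=cfg.conspecific_target_strength)
    doa_model = DOAModel()
    schedule = SpeciesSchedule(species=cfg.species)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_bats + 1)
    spawn_rng = np.random.default_rng(children[0])
    states = spawn_bats(cfg.n_bats, spawn_rng, arena)
    bats = [_BatRuntime(s, cfg, np.random.default_rng(children[i + 1]), schedule)
            for i, s in enumerate(states)]

    call_log: list[CallEvent] = []
    n_free = n_jam = n_calls = 0
    det1m_hits = det1m_total = 0
    nn_samples: list[float] = []
    traj_rows: list[tuple] = []
    call_rows: list[tuple] = []

    exit_a, exit_b = arena.exit_segment
    n_steps = int(round(cfg.duration / cfg.dt))
    next_sample = 0.0

    for k in range(n_steps + 1):
        t = k * cfg.dt

        for bat in bats:
            st = bat.state
            if st.exited or t < st.next_call_time:
                continue
            bat.airborne = True
            _process_decision(bat, t, cfg, arena, bats, call_log,
                              model, doa_model)
            stats = bat._last_stats
            n_free += stats["free"]
            n_jam += stats["jammed"]
            det1m_total += stats["near_total"]
            det1m_hits += stats["near_hit"]
            n_calls += 1
            call_rows.append((t, st.id, st.phase, bat.cmd.mode,
                              bat.params.ipi_ms, bat.params.duration_ms,
                              bat.params.terminal_freq_khz,
                              bat.params.bandwidth_khz, bat.params.level_db))

        if call_log and call_log[0].time < t - CALL_LOG_HORIZON_S:
            call_log[:] = [e for e in call_log
                           if e.time >= t - CALL_LOG_HORIZON_S]

        # lockstep kinematics
        active = [b for b in bats if b.airborne and not b.state.exited]
        for bat in active:
            st = bat.state
            p_old = st.position.copy()
            behavior.integrate_kinematics(st, bat.cmd, cfg.dt,
                                          cfg.nominal_speed,
                                          speed_tau_s=bat.params.ipi_s)
            if _segments_cross(p_old, st.position, exit_a, exit_b):
                st.exited = True
                st.exit_time = t
                continue
            others = [o.state for o in active
                      if o is not bat and not o.state.exited]
            bat.wall_armed = behavior.handle_collisions(
                st, arena, others, cfg.dt, bat.wall_armed,
                cfg.conspecific_avoid_dist)

        if t >= next_sample:
            next_sample += TRAJECTORY_SAMPLE_S
            flying = [b.state for b in bats if not b.state.exited]
            for st in flying:
                traj_rows.append((t, st.id, st.position[0], st.position[1],
                                  st.heading, st.speed, st.phase))
            if len(flying) >= 2:
                pos = np.array([s.position for s in flying])
                dd = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
                np.fill_diagonal(dd, np.inf)
                nn_samples.extend(dd.min(axis=1).tolist())

        if all(b.state.exited for b in bats):
            break

    in_arena_time = sum((s.exit_time if s.exited else cfg.duration)
                        - s.takeoff_time for s in states)
    collisions = sum(s.wall_collision_events for s in states)
    metrics = TrialMetrics(
        exit_probability=float(np.mean([s.exited for s in states])),
        times_to_exit=[float(s.exit_time) for s in states if s.exited],
        wall_collision_rate=collisions / in_arena_time if in_arena_time > 0 else 0.0,
        jamming_probability=(n_jam / n_free) if n_free else None,
        detection_prob_1m=(det1m_hits / det1m_total) if det1m_total else None,
        mean_nearest_neighbor=(float(np.mean(nn_samples)) if nn_samples else None),
        n_bats=cfg.n_bats, n_calls=n_calls,
        n_echoes_free=n_free, n_echoes_jammed=n_jam)

    traj = pd.DataFrame(traj_rows, columns=["t", "bat", "x", "y", "heading",
                                            "speed", "phase"])
    calls = pd.DataFrame(call_rows, columns=["t", "bat", "phase", "mode",
                                             "ipi_ms", "duration_ms",
                                             "terminal_khz", "bandwidth_khz",
                                             "level_db"])
    return TrialResult(config=cfg, metrics=metrics, bats=states,
                       trajectories=traj, calls=calls)


def _process_decision(bat: _BatRuntime, t: float, cfg: TrialConfig,
                      arena: Arena, bats: list[_BatRuntime],
                      call_log: list[CallEvent], model: PropagationModel,
                      doa_model: DOAModel) -> float | None:
    """Process the reception window of the bat's previous call, decide, emit."""
    st = bat.state
    stats = {"free": 0, "jammed": 0, "near_total": 0, "near_hit": 0}
    dist = None

    if bat.last_event is not None:
        ev = bat.last_event
        focal_snapshot = dataclasses.replace(
            st, position=ev.position, heading=ev.heading)
        others = [b.state for b in bats if not b.state.exited]
        scene = compose_received_scene(
            focal_snapshot, ev.params, ev.time, arena, others, call_log,
            model, window=ev.params.ipi_s, masking=cfg.masking,
            occlusion=cfg.occlusion)
        detections, leftovers = receiver.run_detection(
            scene, model, doa_model, bat.rng, fs=cfg.fs, masking=cfg.masking)
        pose = Pose(position=ev.position, heading=ev.heading)
        pseudo = None
        if cfg.confusion and cfg.masking:
            pseudo = perception.apply_confusion(
                scene, leftovers, pose, doa_model, bat.rng, model.c)
        perception.update_memory(bat.mem, detections, pseudo, pose, t)

        ok = [d for d in detections if d.status in (receiver.DETECTED,
                                                    receiver.TIMING_ERROR)]
        stats["free"] = len(detections)
        stats["jammed"] = sum(d.status == receiver.JAMMED for d in detections)
        # detection-at-1-m bookkeeping: nearest wall reflector ahead within 1 m
        wall_comps = [c for c in scene.components
                      if c.kind == acoustics.OWN_WALL_ECHO
                      and abs(c.true_bearing) <= np.pi / 2
                      and c.distance <= 1.0]
        if wall_comps:
            nearest = min(wall_comps, key=lambda c: c.distance)
            stats["near_total"] = 1
            stats["near_hit"] = int(any(
                d.kind == acoustics.OWN_WALL_ECHO
                and d.reflector_ref == nearest.reflector_ref for d in ok))
        if ok:
            dist = min(d.est_range for d in ok)

    if dist is None:
        pts = np.concatenate([bat.mem.wall_points(), bat.mem.bat_points()]) \
            if len(bat.mem.calls) else np.empty((0, 2))
        if len(pts):
            dist = float(np.min(np.linalg.norm(pts - st.position, axis=1)))

    st.phase = behavior.select_phase(dist)
    bat.params = bat._shift(behavior.next_call_params(
        st.phase, dist, bat.schedule, st.terminal_freq_offset))
    if bat.committed_gap is not None:
        reached = np.linalg.norm(bat.committed_gap[0] - st.position) < 0.25
        if t > bat.gap_expiry or reached:
            bat.committed_gap = None
    step = st.position - bat.prev_pos
    n = np.linalg.norm(step)
    if n > 1e-9:
        bat.travel_dir = 0.6 * bat.travel_dir + 0.4 * step / n
    bat.prev_pos = st.position.copy()
    bat.cmd = behavior.adapt_speed_to_turn(behavior.decide_maneuver(
        bat.mem, st, cfg.nominal_speed, bat.rng, bat.params.ipi_s,
        clustering=cfg.clustering,
        conspecific_avoid_dist=cfg.conspecific_avoid_dist,
        committed_gap=bat.committed_gap,
        travel_dir=bat.travel_dir), st)
    if bat.cmd.gap_center is not None:
        if bat.committed_gap is None:
            bat.gap_expiry = t + 1.0
        bat.committed_gap = (bat.cmd.gap_center, bat.cmd.gap_axis,
                             bat.cmd.gap_width)

    ev = CallEvent(time=t, bat_id=st.id, params=bat.params,
                   position=st.position.copy(), heading=st.heading)
    call_log.append(ev)
    bat.last_event = ev
    st.next_call_time = t + bat.params.ipi_s
    bat._last_stats = stats
    return dist


def compute_detection_prob_1m(n_hits: int, n_total: int) -> float | None:
    """Fraction of calls whose nearest in-front wall reflector (<= 1 m) was
    detected; None when the denominator is empty."""
    return (n_hits / n_total) if n_total else None


def run_batch(configs: list[TrialConfig], base_seed: int = 0,
              progress: bool = False) -> pd.DataFrame:
    """Run many trials and pool metrics across individual bats.

    Each config is run as-is (its own seed); means and standard errors are
    computed across all individuals within each (scenario) group, following
    the pooled-individuals convention.
    """
    rows = []
    for i, cfg in enumerate(configs):
        if progress:
            print(f"[{i + 1}/{len(configs)}] n_bats={cfg.n_bats} "
                  f"seed={cfg.seed}", flush=True)
        res = run_trial(cfg)
        m = res.metrics
        for s in res.bats:
            rows.append({
                "n_bats": cfg.n_bats, "species": cfg.species,
                "masking": cfg.masking, "confusion": cfg.confusion,
                "clustering": cfg.clustering, "window_calls": cfg.window_calls,
                "nominal_speed": cfg.nominal_speed,
                "call_level_db": cfg.call_level_db,
                "wall_ts": cfg.wall_target_strength,
                "conspecific_ts": cfg.conspecific_target_strength,
                "seed": cfg.seed, "bat": s.id,
                "exited": bool(s.exited),
                "time_to_exit": s.exit_time if s.exited else np.nan,
                "collisions": s.wall_collision_events,
                "trial_jamming_prob": m.jamming_probability,
                "trial_detection_prob_1m": m.detection_prob_1m,
            })
    return pd.DataFrame(rows)


def summarize_batch(per_bat: pd.DataFrame,
                    group_cols: list[str] | None = None) -> pd.DataFrame:
    """Scenario-level means and standard errors pooled over individuals."""
    group_cols = group_cols or ["n_bats", "species", "masking", "confusion",
                                "clustering", "window_calls", "nominal_speed",
                                "call_level_db", "wall_ts", "conspecific_ts"]
    def _agg(g):
        n = len(g)
        exited = g["exited"].astype(float)
        tte = g["time_to_exit"].dropna()
        return pd.Series({
            "n_individuals": n,
            "exit_probability": exited.mean(),
            "exit_probability_se": exited.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "time_to_exit": tte.mean() if len(tte) else np.nan,
            "time_to_exit_se": (tte.std(ddof=1) / np.sqrt(len(tte))
                                if len(tte) > 1 else np.nan),
            "collision_rate": g["collisions"].sum()
                / (g["time_to_exit"].fillna(15.0).sum()),
            "jamming_probability": g["trial_jamming_prob"].mean(),
            "detection_prob_1m": g["trial_detection_prob_1m"].mean(),
        })
    out = (per_bat.groupby(group_cols, dropna=False)
           .apply(_agg, include_groups=False).reset_index())
    return out


REPEAT_SCHEDULE = {1: 240, 2: 120, 5: 48, 10: 24, 20: 12, 40: 12, 100: 6}


def density_sweep_configs(densities=(1, 2, 5, 10, 20, 40, 100),
                          repeats: dict[int, int] | None = None,
                          base_seed: int = 0, **overrides) -> list[TrialConfig]:
    """Density-sweep scenario grid with the standard repeat schedule (published emergence-study convention)."""
    repeats = repeats or REPEAT_SCHEDULE
    cfgs = []
    for n in densities:
        for r in range(repeats.get(n, 1)):
            cfgs.append(TrialConfig(n_bats=n,
                                    seed=base_seed + 1000 * n + r, **overrides))
    return cfgs
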