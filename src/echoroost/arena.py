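"""Roost geometry: corridor arena, discretized wall reflectors, and bat spawning.

The arena is a 2D corridor with a right-angle turn. Coordinates are Cartesian
meters; the first leg runs along +x, the exit leg along +y. Headings are in
radians, counter-clockwise from +x. Walls are represented both as continuous
line segments (used for occlusion and collision tests) and as discrete point
reflectors spaced 0.2 m apart (used as acoustic targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: reflector spacing along walls [m]
REFLECTOR_SPACING = 0.2
#: wall reflector target strength [dB re incident level, 1 m reference]
WALL_TARGET_STRENGTH = -22.5
#: physical bat radius used for contact tests [m]
BAT_RADIUS = 0.15


class ConfigurationError(ValueError):
    """Raised for geometrically or numerically inconsistent configurations."""


@dataclass
class ArenaConfig:
    """Geometry of the corridor roost.

    ``total_length`` is the full path length from the far end to the exit;
    the right-angle turn sits ``turn_to_exit`` meters before the exit, so the
    first leg is ``total_length - turn_to_exit`` long. The obstacle is a thin
    transverse segment placed ``obstacle_to_exit`` meters before the exit
    opening, centered across the exit leg.
    """

    total_length: float = 14.5
    width: float = 2.5
    turn_to_exit: float = 5.5
    obstacle_width: float = 1.25
    obstacle_to_exit: float = 2.25
    #: obstacle center across the exit leg, as a fraction of the width
    #: (0 = flush with the inner wall, 0.5 = centered); the figure layout
    #: shows the barrier offset to one side, leaving a single passage
    obstacle_center_frac: float = 0.25
    spacing: float = REFLECTOR_SPACING
    wall_target_strength: float = WALL_TARGET_STRENGTH
    start_area_length: float = 2.0   # along corridor axis
    start_area_width: float = 1.5    # across corridor
    start_margin: float = 0.3        # offset of start area from the far wall


@dataclass
class Arena:
    wall_segments: np.ndarray      # (n, 2, 2) [[x1,y1],[x2,y2]] per segment
    obstacle_segments: np.ndarray  # (m, 2, 2)
    exit_segment: np.ndarray       # (2, 2)
    reflectors: np.ndarray         # (k, 2) positions
    reflector_ts: np.ndarray       # (k,) target strengths [dB]
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    config: ArenaConfig = field(default_factory=ArenaConfig)

    @property
    def blocking_segments(self) -> np.ndarray:
        """All segments that occlude sound and can be collided with."""
        return np.concatenate([self.wall_segments, self.obstacle_segments])

    def to_frame(self) -> pd.DataFrame:
        """Segments and reflectors as a tidy table (for export/plotting)."""
        rows = []
        for kind, segs in (("wall", self.wall_segments),
                           ("obstacle", self.obstacle_segments),
                           ("exit", self.exit_segment[None])):
            for s in segs:
                rows.append({"kind": kind, "x1": s[0, 0], "y1": s[0, 1],
                             "x2": s[1, 0], "y2": s[1, 1]})
        for p, ts in zip(self.reflectors, self.reflector_ts):
            rows.append({"kind": "reflector", "x1": p[0], "y1": p[1],
                         "x2": np.nan, "y2": np.nan, "target_strength": ts})
        return pd.DataFrame(rows)


def discretize_segment(p: np.ndarray, q: np.ndarray,
                       spacing: float = REFLECTOR_SPACING) -> np.ndarray:
    """Reflector positions along segment p-q at fixed spacing.

    Both endpoints are always included; interior points sit on the regular
    grid from p, so the last interval may be shorter than ``spacing``.
    A 1.0 m segment therefore carries 6 reflectors.
    """
    p, q = np.asarray(p, float), np.asarray(q, float)
    length = float(np.hypot(*(q - p)))
    n = int(np.floor(length / spacing + 1e-9))
    ts = np.arange(n + 1) * spacing / length if length > 0 else np.array([0.0])
    pts = p + ts[:, None] * (q - p)
    if length - n * spacing > 1e-6:
        pts = np.vstack([pts, q])
    return pts


def build_arena(config: ArenaConfig | None = None) -> Arena:
    """Build the corridor roost with discretized wall reflectors.

    Raises :class:`ConfigurationError` for non-positive dimensions, a turn
    offset exceeding the corridor length, or an obstacle wider than the
    corridor.
    """
    cfg = config or ArenaConfig()
    if min(cfg.total_length, cfg.width, cfg.turn_to_exit) <= 0:
        raise ConfigurationError("arena dimensions must be positive")
    if cfg.turn_to_exit >= cfg.total_length:
        raise ConfigurationError("turn offset exceeds corridor length")
    if cfg.obstacle_width >= cfg.width:
        raise ConfigurationError("obstacle must be narrower than the corridor")

    L1 = cfg.total_length - cfg.turn_to_exit   # far end to inner corner
    w = cfg.width
    x_out = L1 + w                             # outer wall of the exit leg
    y_exit = w + cfg.turn_to_exit

    walls = np.array([
        [[0.0, 0.0], [x_out, 0.0]],      # bottom of leg 1 / corner
        [[0.0, 0.0], [0.0, w]],          # far-end wall (behind start area)
        [[0.0, w], [L1, w]],             # top of leg 1, ends at inner corner
        [[x_out, 0.0], [x_out, y_exit]], # outer wall of exit leg
        [[L1, w], [L1, y_exit]],         # inner wall of exit leg
    ])
    y_obs = y_exit - cfg.obstacle_to_exit
    x_c = L1 + np.clip(cfg.obstacle_center_frac, 0.0, 1.0) * w
    x_c = float(np.clip(x_c, L1 + cfg.obstacle_width / 2 - 1e-9, x_out))
    x_c = min(x_c, x_out - cfg.obstacle_width / 2 + 1e-9)
    obstacle = np.array([
        [[x_c - cfg.obstacle_width / 2, y_obs],
         [x_c + cfg.obstacle_width / 2, y_obs]],
    ])
    exit_seg = np.array([[L1, y_exit], [x_out, y_exit]])

    pts = [discretize_segment(s[0], s[1], cfg.spacing)
           for s in np.concatenate([walls, obstacle])]
    refl = np.concatenate(pts)
    # corners share endpoints between segments: keep each point once
    _, idx = np.unique(np.round(refl / 1e-6).astype(np.int64), axis=0,
                       return_index=True)
    refl = refl[np.sort(idx)]
    ts = np.full(len(refl), cfg.wall_target_strength)

    return Arena(wall_segments=walls, obstacle_segments=obstacle,
                 exit_segment=exit_seg, reflectors=refl, reflector_ts=ts,
                 bounds=(0.0, 0.0, x_out, y_exit), config=cfg)


# ---------------------------------------------------------------------------
# line of sight

def visible(origin: np.ndarray, targets: np.ndarray,
            segments: np.ndarray) -> np.ndarray:
    """Boolean mask: which target points are visible from ``origin``.

    A target is occluded when the sight line properly crosses any blocking
    segment strictly between origin and target. A segment that merely touches
    the sight line at the target itself (the reflector's own host wall) does
    not occlude.
    """
    origin = np.asarray(origin, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    if len(segments) == 0:
        return np.ones(len(targets), bool)
    d = targets - origin                       # (n, 2)
    p = segments[:, 0]                         # (m, 2)
    e = segments[:, 1] - segments[:, 0]        # (m, 2)
    ap = p - origin                            # (m, 2)
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    cross_t = ap[None, :, 0] * e[None, :, 1] - ap[None, :, 1] * e[None, :, 0]
    cross_u = ap[None, :, 0] * d[:, None, 1] - ap[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_t / denom
        u = cross_u / denom
    blocked = ((np.abs(denom) > 1e-12)
               & (t > 1e-9) & (t < 1.0 - 1e-6)
               & (u >= -1e-9) & (u <= 1.0 + 1e-9))
    return ~blocked.any(axis=1)


def line_of_sight(a, b, arena: Arena) -> bool:
    """True iff the segment a-b crosses no wall or obstacle segment.

    The target's own host segment (touching exactly at ``b``) is excluded.
    """
    return bool(visible(np.asarray(a, float), np.asarray(b, float)[None],
                        arena.blocking_segments)[0])


# ---------------------------------------------------------------------------
# bats

SEARCH, APPROACH, BUZZ1, BUZZ2 = "search", "approach", "buzz1", "buzz2"


@dataclass
class BatState:
    id: int
    position: np.ndarray          # (2,) [m]
    heading: float                # [rad] CCW from +x
    speed: float                  # [m/s]
    phase: str = SEARCH
    next_call_time: float = 0.0   # [s]
    takeoff_time: float = 0.0     # [s]
    terminal_freq_offset: float = 0.0  # [kHz]
    exited: bool = False
    exit_time: float | None = None
    wall_collision_events: int = 0
    conspecific_contact: bool = False


def spawn_bats(n: int, seed, arena: Arena | None = None,
               heading_halfspread_deg: float = 30.0,
               takeoff_window: float = 0.1,
               tf_offset_std_khz: float = 1.0) -> list[BatState]:
    """Spawn ``n`` bats in the start area at the far end of the corridor.

    Positions are uniform in a 2 m (along corridor) x 1.5 m (across) rectangle,
    headings uniform within +-30 degrees of the exit direction (+x), takeoff
    times uniform in [0, 0.1] s, and per-bat terminal-frequency offsets are
    Normal(0, 1 kHz). Deterministic given ``seed`` (an int or a Generator).
    """
    if n < 1:
        raise ConfigurationError("need at least one bat")
    arena = arena or build_arena()
    cfg = arena.config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = cfg.start_margin
    y0 = (cfg.width - cfg.start_area_width) / 2.0
    xs = rng.uniform(x0, x0 + cfg.start_area_length, n)
    ys = rng.uniform(y0, y0 + cfg.start_area_width, n)
    hs = rng.uniform(-np.deg2rad(heading_halfspread_deg),
                     np.deg2rad(heading_halfspread_deg), n)
    t0 = rng.uniform(0.0, takeoff_window, n)
    df = rng.normal(0.0, tf_offset_std_khz, n)
    return [BatState(id=i, position=np.array([xs[i], ys[i]]), heading=float(hs[i]),
                     speed=0.0, takeoff_time=float(t0[i]),
                     next_call_time=float(t0[i]),
                     terminal_freq_offset=float(df[i]))
            for i in range(n)]


def point_segment_distance(p: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Distance from point(s) p (…,2) to each segment (m,2,2) -> (…,m)."""
    p = np.asarray(p, float)
    a = segments[:, 0]
    ab = segments[:, 1] - segments[:, 0]
    ap = p[..., None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("...ij,ij->...i", ap, ab) / np.where(denom > 0, denom, 1.0),
                0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p[..., None, :] - closest, axis=-1)
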