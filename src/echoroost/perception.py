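"""Multi-call detection memory, echo confusion, and clustering mitigation.

Detections are stored allocentrically (world-frame x-y) in two buffers: a
guidance buffer holding the detection sets of the current call plus the last
``W`` calls (the multi-call integration window), and a 1-second buffer used
by the multi-call clustering algorithm, which groups nearby detections
(single-linkage, 10 cm), discards singleton outliers, reconstructs wall
segments from clusters of two or more detections, and finds openings of
0.5-2.25 m between reconstructed wall endpoints.

The confusion model converts wall echoes generated by conspecific calls into
pseudo-detections: the bat times them against its *own* last emission, so
their inferred range is wrong while their bearing is approximately correct.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .acoustics import CONSPECIFIC_WALL_ECHO, OWN_WALL_ECHO, ReceivedScene
from .receiver import Candidate, Detection, DOAModel, MATCH_GATE_S, estimate_doa

DEFAULT_WINDOW_CALLS = 5      # W: previous calls integrated (0 = current only)
CLUSTER_BUFFER_S = 1.0
CLUSTER_LINKAGE_M = 0.10
OPENING_MIN_M = 0.5
OPENING_MAX_M = 2.25


@dataclass
class Pose:
    position: np.ndarray
    heading: float

    def to_allocentric(self, rng_m, doa_rad) -> np.ndarray:
        """Detections (range, bearing) relative to this pose -> world x-y."""
        ang = self.heading + np.asarray(doa_rad, float)
        r = np.asarray(rng_m, float)
        return self.position + np.stack([r * np.cos(ang), r * np.sin(ang)], -1)


@dataclass
class CallSet:
    """Detections of one call: world-frame points, tagged by target type."""

    time: float
    pose: Pose
    wall_points: np.ndarray       # (n, 2) walls + (under confusion) pseudo
    bat_points: np.ndarray        # (m, 2) detected conspecifics
    bat_ids: np.ndarray           # (m,)


@dataclass
class MemoryFrame:
    """Allocentric detection buffers of one bat."""

    window_calls: int = DEFAULT_WINDOW_CALLS
    calls: deque = field(default_factory=deque)
    cluster_buffer: deque = field(default_factory=deque)   # (time, point)

    def wall_points(self) -> np.ndarray:
        pts = [cs.wall_points for cs in self.calls if len(cs.wall_points)]
        return np.concatenate(pts) if pts else np.empty((0, 2))

    def bat_points(self) -> np.ndarray:
        pts = [cs.bat_points for cs in self.calls if len(cs.bat_points)]
        return np.concatenate(pts) if pts else np.empty((0, 2))

    def last_call(self) -> CallSet | None:
        return self.calls[-1] if self.calls else None

    def cluster_points(self) -> np.ndarray:
        pts = [p for _, p in self.cluster_buffer]
        return np.asarray(pts) if pts else np.empty((0, 2))


def update_memory(mem: MemoryFrame, detections: list[Detection],
                  pseudo_points: np.ndarray | None, pose: Pose,
                  time: float) -> MemoryFrame:
    """Append one call's detections (allocentric) and prune both buffers.

    ``detections`` carry est_range/est_doa relative to ``pose``;
    ``pseudo_points`` are already-allocentric confusion pseudo-detections
    (or None). Each detection is kept independently (no filtering) in the
    guidance buffer; wall-type points are also pushed to the 1 s clustering
    buffer.
    """
    walls, bats, bat_ids = [], [], []
    for d in detections:
        if d.status not in ("detected", "timing_error"):
            continue
        p = pose.to_allocentric(d.est_range, d.est_doa)
        if d.kind == OWN_WALL_ECHO:
            walls.append(p)
        else:
            bats.append(p)
            bat_ids.append(d.reflector_ref)
    wall_arr = np.asarray(walls) if walls else np.empty((0, 2))
    if pseudo_points is not None and len(pseudo_points):
        wall_arr = np.concatenate([wall_arr, pseudo_points]) if len(wall_arr) \
            else np.asarray(pseudo_points)
    cs = CallSet(time=time, pose=pose, wall_points=wall_arr,
                 bat_points=np.asarray(bats) if bats else np.empty((0, 2)),
                 bat_ids=np.asarray(bat_ids, int))
    mem.calls.append(cs)
    while len(mem.calls) > mem.window_calls + 1:
        mem.calls.popleft()
    for p in wall_arr:
        mem.cluster_buffer.append((time, p))
    while mem.cluster_buffer and mem.cluster_buffer[0][0] < time - CLUSTER_BUFFER_S:
        mem.cluster_buffer.popleft()
    return mem


def apply_confusion(scene: ReceivedScene, leftovers: list[Candidate],
                    pose: Pose, doa_model: DOAModel,
                    rng: np.random.Generator, c: float,
                    noise_floor_db: float = 0.0) -> np.ndarray:
    """Confusion-model pseudo-detections as allocentric points.

    Full-pass peaks not explained by the bat's own echoes are matched (within
    the 100 us gate) to wall echoes of conspecific calls; each match is
    treated as a self-echo: range from the delay since the bat's own last
    emission (hence mislocalized), bearing toward the physical reflector plus
    the usual SNR-dependent error.
    """
    comps = scene.by_kind(CONSPECIFIC_WALL_ECHO)
    if not comps or not leftovers:
        return np.empty((0, 2))
    arr = np.array([cc.delay for cc in comps])
    pts = []
    for cand in leftovers:
        i = int(np.argmin(np.abs(arr - cand.delay)))
        if abs(arr[i] - cand.delay) > MATCH_GATE_S:
            continue
        comp = comps[i]
        rng_est = cand.delay * c / 2.0
        snr = comp.level_db - noise_floor_db
        doa = estimate_doa(comp.true_bearing, snr, doa_model, rng)
        pts.append(pose.to_allocentric(rng_est, doa))
    return np.asarray(pts) if pts else np.empty((0, 2))


@dataclass
class WallEstimate:
    centroid: np.ndarray
    direction: np.ndarray       # unit vector
    endpoints: np.ndarray       # (2, 2)
    n_members: int


@dataclass
class Opening:
    center: np.ndarray
    width: float
    flanking_walls: tuple[int, int]
    axis: np.ndarray | None = None   # unit vector along the flank-to-flank line


def cluster_and_reconstruct(points: np.ndarray
                            ) -> tuple[list[WallEstimate], list[Opening]]:
    """Group 1 s-buffer detections into wall estimates and find openings.

    Single-linkage clustering with a 10 cm chaining distance; singleton
    clusters are discarded as outliers. Each surviving cluster yields a wall
    estimate (centroid, principal direction, extremal member projections as
    endpoints). Openings are gaps of 0.5-2.25 m between the closest endpoints
    of distinct wall estimates.
    """
    points = np.asarray(points, float)
    walls: list[WallEstimate] = []
    if len(points) >= 2:
        labels = fcluster(linkage(pdist(points), method="single"),
                          t=CLUSTER_LINKAGE_M, criterion="distance")
        for lab in np.unique(labels):
            members = points[labels == lab]
            if len(members) < 2:
                continue
            centroid = members.mean(axis=0)
            centered = members - centroid
            if len(members) == 2:
                d = members[1] - members[0]
            else:
                _, _, vt = np.linalg.svd(centered, full_matrices=False)
                d = vt[0]
            nrm = np.linalg.norm(d)
            d = d / nrm if nrm > 0 else np.array([1.0, 0.0])
            proj = centered @ d
            endpoints = np.stack([centroid + proj.min() * d,
                                  centroid + proj.max() * d])
            walls.append(WallEstimate(centroid=centroid, direction=d,
                                      endpoints=endpoints,
                                      n_members=len(members)))
    openings: list[Opening] = []
    for i in range(len(walls)):
        for j in range(i + 1, len(walls)):
            dists = np.linalg.norm(
                walls[i].endpoints[:, None, :] - walls[j].endpoints[None, :, :],
                axis=-1)
            a, b = np.unravel_index(np.argmin(dists), dists.shape)
            width = float(dists[a, b])
            if OPENING_MIN_M <= width <= OPENING_MAX_M:
                conn = walls[j].endpoints[b] - walls[i].endpoints[a]
                center = 0.5 * (walls[i].endpoints[a] + walls[j].endpoints[b])
                openings.append(Opening(center=center, width=width,
                                        flanking_walls=(i, j),
                                        axis=conn / max(width, 1e-9)))
    return walls, openings


def find_gaps(points: np.ndarray, pose: Pose,
              min_gap: float = OPENING_MIN_M,
              max_gap: float = OPENING_MAX_M,
              ) -> list[tuple[np.ndarray, float]]:
    """Basic-model openings: gaps between adjacent detections by bearing.

    Detections in the forward half-plane are sorted by bearing; a Euclidean
    gap of ``min_gap``-``max_gap`` between bearing-adjacent detections is an
    opening, returned as (gap center, gap width). Wider spacings are open
    space rather than exit candidates and are left to wall-following.
    """
    points = np.asarray(points, float)
    if len(points) < 2:
        return []
    rel = points - pose.position
    dist = np.linalg.norm(rel, axis=1)
    bearings = (np.arctan2(rel[:, 1], rel[:, 0]) - pose.heading + np.pi) \
        % (2 * np.pi) - np.pi
    fwd = np.abs(bearings) <= np.pi / 2
    pts = points[fwd]
    if len(pts) < 2:
        return []
    br = bearings[fwd]
    order = np.argsort(br)
    pts, br = pts[order], br[order]
    gaps = []
    for (a, ba), (b, bb) in zip(zip(pts[:-1], br[:-1]), zip(pts[1:], br[1:])):
        width = float(np.linalg.norm(b - a))
        # a real opening subtends a substantial angle; near-collinear pairs
        # (successive detections along a grazed wall) do not
        if min_gap <= width <= max_gap and abs(bb - ba) >= np.deg2rad(20.0):
            gaps.append((0.5 * (a + b), width, (b - a) / max(width, 1e-9)))
    return gaps
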