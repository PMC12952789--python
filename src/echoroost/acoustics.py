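"""Call synthesis and acoustic propagation.

Every sound reaching a focal bat during one reception window is described
analytically as a (kind, delay, level, bearing) component; waveforms are only
rendered later, inside the receiver. Six component classes are tracked: the
bat's own call, its echoes from walls and from conspecifics, conspecific
calls, and conspecific calls reflected off walls and off other bats.

Levels are in dB-SPL referenced 0.1 m from the emitter on axis. Echo levels
follow the sonar equation (two-way spherical spreading and absorption, piston
directivity at mouth and ear, target strength referenced at 1 m); direct
conspecific calls follow one-way Friis transmission; conspecific echoes
combine two one-way legs. Atmospheric absorption uses the ISO 9613-1 model
at 20 degC, 50% RH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import chirp
from scipy.special import j1

from .arena import Arena, BatState, visible

SPEED_OF_SOUND = 343.0  # m/s at 20 degC

OWN_CALL = "own_call"
CONSPECIFIC_CALL = "conspecific_call"
OWN_WALL_ECHO = "own_wall_echo"
OWN_BAT_ECHO = "own_bat_echo"
CONSPECIFIC_WALL_ECHO = "conspecific_wall_echo"
CONSPECIFIC_BAT_ECHO = "conspecific_bat_echo"


@dataclass(frozen=True)
class CallParams:
    """One echolocation call design (dominant harmonic only)."""

    ipi_ms: float
    duration_ms: float
    terminal_freq_khz: float
    bandwidth_khz: float
    level_db: float          # dB-SPL at 0.1 m on axis
    species: str = "PK"

    @property
    def f_low_hz(self) -> float:
        return self.terminal_freq_khz * 1e3

    @property
    def f_high_hz(self) -> float:
        return (self.terminal_freq_khz + self.bandwidth_khz) * 1e3

    @property
    def duration_s(self) -> float:
        return self.duration_ms * 1e-3

    @property
    def ipi_s(self) -> float:
        return self.ipi_ms * 1e-3


def atmospheric_absorption(f_khz: float, temperature_c: float = 20.0,
                           rel_humidity: float = 50.0,
                           pressure_kpa: float = 101.325) -> float:
    """Atmospheric absorption coefficient [dB/m], ISO 9613-1 form."""
    T = temperature_c + 273.15
    T0, T01, P0 = 293.15, 273.16, 101.325
    P = pressure_kpa
    f = f_khz * 1e3
    psat = P0 * 10.0 ** (-6.8346 * (T01 / T) ** 1.261 + 4.6151)
    h = rel_humidity * psat / P
    fr_o = (P / P0) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = (P / P0) * (T / T0) ** -0.5 * (
        9.0 + 280.0 * h * np.exp(-4.17 * ((T / T0) ** (-1.0 / 3.0) - 1.0)))
    alpha = 8.686 * f ** 2 * (
        1.84e-11 * (P0 / P) * (T / T0) ** 0.5
        + (T / T0) ** -2.5 * (
            0.01275 * np.exp(-2239.1 / T) / (fr_o + f ** 2 / fr_o)
            + 0.1068 * np.exp(-3352.0 / T) / (fr_n + f ** 2 / fr_n)))
    return float(alpha)


@lru_cache(maxsize=512)
def _alpha_cached(f_khz_rounded: float) -> float:
    return atmospheric_absorption(f_khz_rounded)


@dataclass
class PropagationModel:
    """Physical constants of the propagation medium and the bat's apertures."""

    c: float = SPEED_OF_SOUND
    mouth_radius: float = 0.003   # m, transmit piston
    ear_radius: float = 0.007     # m, receive piston
    bat_target_strength: float = -23.0   # dB re 1 m, isotropic sphere
    floor_db: float = -10.0       # components below this are dropped
    reference_distance: float = 0.1      # m, SPL reference

    def alpha(self, f_khz: float) -> float:
        """Absorption [dB/m] at the call's dominant (terminal) frequency."""
        return _alpha_cached(round(float(f_khz), 1))


def synthesize_call(params: CallParams, fs: float,
                    level_db: float | None = None) -> np.ndarray:
    """Logarithmic downward FM sweep from (terminal+bandwidth) to terminal.

    Amplitude is ``10**(level/20)`` (the configured dB-SPL at the 0.1 m
    reference); pass ``level_db=0`` for a unit-amplitude template.
    Zero bandwidth degenerates to a constant-frequency tone.
    """
    nyq_needed = 2.0 * params.f_high_hz
    if fs <= nyq_needed:
        raise ValueError(f"fs={fs} too low for call reaching {params.f_high_hz} Hz")
    n = max(int(round(params.duration_s * fs)), 2)
    t = np.arange(n) / fs
    if params.bandwidth_khz <= 0:
        wave = np.sin(2 * np.pi * params.f_low_hz * t)
    else:
        wave = chirp(t, f0=params.f_high_hz, t1=params.duration_s,
                     f1=params.f_low_hz, method="logarithmic")
    amp = 10.0 ** ((params.level_db if level_db is None else level_db) / 20.0)
    return amp * wave


def piston_gain(angle, f_khz, radius: float, c: float = SPEED_OF_SOUND):
    """Normalized circular-piston intensity directivity, gain 1 on axis.

    ``[2 J1(x)/x]**2`` with ``x = k a sin(angle)``; beyond +-90 deg the gain
    is held at its 90 deg value (no front lobe mirrored backwards).
    """
    angle = np.abs(np.asarray(angle, float))
    x = (2 * np.pi * np.asarray(f_khz, float) * 1e3 / c) * radius \
        * np.sin(np.minimum(angle, np.pi / 2))
    nz = x > 1e-12
    x_safe = np.where(nz, x, 1.0)
    out = np.where(nz, np.square(2.0 * j1(x_safe) / x_safe), 1.0)
    return out if out.ndim else float(out)


def _gain_db(angle, f_khz, radius, c):
    g = piston_gain(angle, f_khz, radius, c)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(g)


def _lambda_db(f_khz: float, c: float) -> float:
    """Sonar-equation constant 10*log10(lambda^2 / (4*pi)^3) [dB]."""
    lam = c / (f_khz * 1e3)
    return 20.0 * np.log10(lam) - 30.0 * np.log10(4.0 * np.pi)


def echo_level(Pt, D, phi_t, phi_r, f_khz, sigma_db, model: PropagationModel):
    """Received level [dB] of an echo of the bat's own call (sonar equation).

    ``Pt * Gt * Gr * lambda^2 / ((4 pi)^3 D^4) * sigma`` in dB, with two-way
    absorption applied beyond the 0.1 m reference at which ``Pt`` is defined.
    The wavelength enters at the call's dominant (terminal) frequency; the
    target strength ``sigma_db`` is referenced 1 m from the target.
    """
    D = np.asarray(D, float)
    if np.any(D < model.reference_distance):
        raise ValueError("target closer than the 0.1 m reference distance")
    a = model.alpha(f_khz)
    return (np.asarray(Pt, float)
            + _gain_db(phi_t, f_khz, model.mouth_radius, model.c)
            + _gain_db(phi_r, f_khz, model.ear_radius, model.c)
            + _lambda_db(f_khz, model.c)
            - 40.0 * np.log10(D)
            - 2.0 * a * (D - model.reference_distance)
            + sigma_db)


def masking_call_level(Pt, D, phi_t, phi_r, f_khz, model: PropagationModel):
    """Received level of a conspecific's direct call (Friis transmission).

    ``Pt * Gt * Gr * (lambda / (4 pi D))^2`` in dB with one-way absorption
    beyond the 0.1 m reference.
    """
    D = np.asarray(D, float)
    if np.any(D < model.reference_distance):
        raise ValueError("emitter closer than the 0.1 m reference distance")
    a = model.alpha(f_khz)
    lam = model.c / (f_khz * 1e3)
    return (np.asarray(Pt, float)
            + _gain_db(phi_t, f_khz, model.mouth_radius, model.c)
            + _gain_db(phi_r, f_khz, model.ear_radius, model.c)
            + 20.0 * np.log10(lam / (4.0 * np.pi * D))
            - a * (D - model.reference_distance))


def second_order_echo_level(Pt, D_tx, D_rx, phi_tx, phi_rx, f_khz, sigma_db,
                            model: PropagationModel):
    """Level of a conspecific's call reflected off a target to the focal bat.

    ``Pt * Gt * Gr * lambda^2 / ((4 pi)^3 D_tx^2 D_rx^2) * sigma`` in dB with
    one-way absorption on each leg; reduces to :func:`echo_level` when both
    legs are equal.
    """
    D_tx = np.asarray(D_tx, float)
    D_rx = np.asarray(D_rx, float)
    if np.any(D_tx < model.reference_distance) or np.any(D_rx < model.reference_distance):
        raise ValueError("path leg shorter than the 0.1 m reference distance")
    a = model.alpha(f_khz)
    return (np.asarray(Pt, float)
            + _gain_db(phi_tx, f_khz, model.mouth_radius, model.c)
            + _gain_db(phi_rx, f_khz, model.ear_radius, model.c)
            + _lambda_db(f_khz, model.c)
            - 20.0 * np.log10(D_tx) - 20.0 * np.log10(D_rx)
            - a * (D_tx + D_rx - 2 * model.reference_distance)
            + sigma_db)


@dataclass
class SoundComponent:
    kind: str
    emitter_id: int
    delay: float            # s, relative to the focal bat's own emission
    level_db: float
    source_call: CallParams
    true_bearing: float     # rad, relative to focal heading at emission
    reflector_ref: int | None = None   # reflector index or reflecting bat id
    distance: float = np.nan           # emitter->target (own echoes) [m]


@dataclass
class CallEvent:
    """One emitted call, frozen at emission (pose snapshot)."""

    time: float
    bat_id: int
    params: CallParams
    position: np.ndarray
    heading: float
    _vis_cache: np.ndarray | None = field(default=None, repr=False)

    def visible_reflectors(self, arena: Arena) -> np.ndarray:
        if self._vis_cache is None:
            self._vis_cache = visible(self.position, arena.reflectors,
                                      arena.blocking_segments)
        return self._vis_cache


@dataclass
class ReceivedScene:
    components: list[SoundComponent]
    call: CallParams          # the focal bat's own call
    emission_time: float
    window: float             # s, reception window length (one IPI)
    noise_floor_db: float = 0.0

    def by_kind(self, *kinds: str) -> list[SoundComponent]:
        return [c for c in self.components if c.kind in kinds]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"kind": c.kind, "emitter": c.emitter_id, "delay_s": c.delay,
              "level_db": c.level_db, "bearing_rad": c.true_bearing,
              "reflector": c.reflector_ref} for c in self.components])


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def compose_received_scene(focal: BatState, call: CallParams,
                           emission_time: float, arena: Arena,
                           bats: list[BatState],
                           call_log: list[CallEvent],
                           model: PropagationModel,
                           window: float | None = None,
                           masking: bool = True,
                           occlusion: bool = True) -> ReceivedScene:
    """All sound components arriving at the focal bat within one IPI.

    ``call_log`` holds recent conspecific call events (pose snapshots at their
    emission). Components below ``model.floor_db``, occluded paths (when
    ``occlusion`` is on), and own echoes arriving after the next emission are
    omitted. With ``masking=False`` only the bat's own call and its echoes
    are returned.
    """
    win = call.ipi_s if window is None else window
    pos, hdg = focal.position, focal.heading
    f = call.terminal_freq_khz
    comps: list[SoundComponent] = [SoundComponent(
        kind=OWN_CALL, emitter_id=focal.id, delay=0.0, level_db=call.level_db,
        source_call=call, true_bearing=0.0)]

    refl = arena.reflectors
    d_vec = refl - pos
    D = np.linalg.norm(d_vec, axis=1)
    bearing = _wrap(np.arctan2(d_vec[:, 1], d_vec[:, 0]) - hdg)
    Dc = np.maximum(D, model.reference_distance)

    if occlusion:
        vis_focal = visible(pos, refl, arena.blocking_segments)
    else:
        vis_focal = np.ones(len(refl), bool)

    # (3) own wall echoes
    lvl = echo_level(call.level_db, Dc, bearing, bearing, f,
                     arena.reflector_ts, model)
    delay = 2.0 * D / model.c
    keep = vis_focal & (lvl >= model.floor_db) & (delay <= win) & (D > 0.05)
    for i in np.flatnonzero(keep):
        comps.append(SoundComponent(OWN_WALL_ECHO, focal.id, float(delay[i]),
                                    float(lvl[i]), call, float(bearing[i]),
                                    reflector_ref=int(i), distance=float(D[i])))

    # (2) own echoes off conspecifics
    others = [b for b in bats if b.id != focal.id and not b.exited]
    if others:
        opos = np.array([b.position for b in others])
        ov = opos - pos
        oD = np.linalg.norm(ov, axis=1)
        ob = _wrap(np.arctan2(ov[:, 1], ov[:, 0]) - hdg)
        oDc = np.maximum(oD, model.reference_distance)
        olvl = echo_level(call.level_db, oDc, ob, ob, f,
                          model.bat_target_strength, model)
        odel = 2.0 * oD / model.c
        if occlusion:
            ovis = visible(pos, opos, arena.blocking_segments)
        else:
            ovis = np.ones(len(others), bool)
        okeep = ovis & (olvl >= model.floor_db) & (odel <= win)
        for i in np.flatnonzero(okeep):
            comps.append(SoundComponent(OWN_BAT_ECHO, focal.id, float(odel[i]),
                                        float(olvl[i]), call, float(ob[i]),
                                        reflector_ref=others[i].id,
                                        distance=float(oD[i])))

    if masking:
        bat_pos = {b.id: b.position for b in bats if not b.exited}
        others_arr = np.array([b.position for b in bats
                               if not b.exited and b.id != focal.id]) \
            if others else np.empty((0, 2))
        # only calls whose sound can still arrive inside the window matter:
        # earliest usable emission is window start minus the longest flight
        # time across the arena
        xmin, ymin, xmax, ymax = arena.bounds
        t_min = emission_time - 2.0 * np.hypot(xmax - xmin, ymax - ymin) / model.c
        t_max = emission_time + win
        for ev in call_log:
            if ev.bat_id == focal.id or not t_min <= ev.time <= t_max:
                continue
            fm = ev.params.terminal_freq_khz
            # (6) the conspecific call itself
            v = pos - ev.position
            Dm = max(float(np.hypot(*v)), model.reference_distance)
            t_arr = ev.time + Dm / model.c - emission_time
            phi_tx = _wrap(np.arctan2(v[1], v[0]) - ev.heading)
            phi_rx = _wrap(np.arctan2(-v[1], -v[0]) - hdg)
            if 0.0 <= t_arr <= win:
                lvl_m = float(masking_call_level(ev.params.level_db, Dm,
                                                 phi_tx, phi_rx, fm, model))
                if lvl_m >= model.floor_db and (
                        not occlusion
                        or visible(pos, ev.position[None],
                                   arena.blocking_segments)[0]):
                    comps.append(SoundComponent(
                        CONSPECIFIC_CALL, ev.bat_id, t_arr, lvl_m, ev.params,
                        phi_rx, distance=Dm))

            # (5) conspecific call reflected off walls
            ev_vec = refl - ev.position
            D_tx = np.maximum(np.linalg.norm(ev_vec, axis=1),
                              model.reference_distance)
            arr = ev.time + (D_tx + D) / model.c - emission_time
            in_win = (arr >= 0.0) & (arr <= win)
            if in_win.any():
                phi_t = _wrap(np.arctan2(ev_vec[:, 1], ev_vec[:, 0]) - ev.heading)
                lvl2 = second_order_echo_level(
                    ev.params.level_db, D_tx, Dc, phi_t, bearing, fm,
                    arena.reflector_ts, model)
                keep2 = in_win & (lvl2 >= model.floor_db) & vis_focal
                if occlusion and keep2.any():
                    keep2 &= ev.visible_reflectors(arena)
                for i in np.flatnonzero(keep2):
                    comps.append(SoundComponent(
                        CONSPECIFIC_WALL_ECHO, ev.bat_id, float(arr[i]),
                        float(lvl2[i]), ev.params, float(bearing[i]),
                        reflector_ref=int(i)))

            # (4) conspecific call reflected off other bats
            refl_bats = [b for b in bats
                         if not b.exited and b.id not in (ev.bat_id, focal.id)]
            if refl_bats:
                bp = np.array([b.position for b in refl_bats])
                l1 = bp - ev.position
                l2 = pos - bp
                Dt = np.maximum(np.linalg.norm(l1, axis=1),
                                model.reference_distance)
                Dr = np.maximum(np.linalg.norm(l2, axis=1),
                                model.reference_distance)
                t2 = ev.time + (Dt + Dr) / model.c - emission_time
                in_win2 = (t2 >= 0.0) & (t2 <= win)
                if in_win2.any():
                    phi_t = _wrap(np.arctan2(l1[:, 1], l1[:, 0]) - ev.heading)
                    phi_r = _wrap(np.arctan2(-l2[:, 1], -l2[:, 0]) - hdg)
                    lvlb = second_order_echo_level(
                        ev.params.level_db, Dt, Dr, phi_t, phi_r, fm,
                        model.bat_target_strength, model)
                    keepb = in_win2 & (lvlb >= model.floor_db)
                    if occlusion and keepb.any():
                        keepb &= visible(ev.position, bp,
                                         arena.blocking_segments)
                        keepb &= visible(pos, bp, arena.blocking_segments)
                    for i in np.flatnonzero(keepb):
                        comps.append(SoundComponent(
                            CONSPECIFIC_BAT_ECHO, ev.bat_id, float(t2[i]),
                            float(lvlb[i]), ev.params, float(phi_r[i]),
                            reflector_ref=refl_bats[i].id))

    return ReceivedScene(components=comps, call=call,
                         emission_time=emission_time, window=win)
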