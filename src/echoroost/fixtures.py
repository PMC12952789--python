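"""Toy acoustic scenes for receiver tests and debugging.

Scenes are plain tables (kind, delay_s, level_db, call parameters) that
round-trip through CSV and load directly into the detection pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acoustics import (OWN_WALL_ECHO, CONSPECIFIC_CALL, CallParams,
                        ReceivedScene, SoundComponent)

_CALL_COLS = ["ipi_ms", "duration_ms", "terminal_freq_khz", "bandwidth_khz",
              "level_db", "species"]


def default_call(species: str = "PK") -> CallParams:
    """A search-phase call for toy scenes."""
    if species == "RM":
        return CallParams(ipi_ms=100, duration_ms=12, terminal_freq_khz=26,
                          bandwidth_khz=3, level_db=120, species="RM")
    return CallParams(ipi_ms=100, duration_ms=7, terminal_freq_khz=39,
                      bandwidth_khz=8, level_db=120, species="PK")


def single_echo_scene(range_m: float = 1.0, level_db: float = 60.0,
                      c: float = 343.0, call: CallParams | None = None
                      ) -> ReceivedScene:
    """One clean wall echo at the given range (delay 2R/c)."""
    call = call or default_call()
    comp = SoundComponent(kind=OWN_WALL_ECHO, emitter_id=0,
                          delay=2.0 * range_m / c, level_db=level_db,
                          source_call=call, true_bearing=0.0,
                          reflector_ref=0, distance=range_m)
    return ReceivedScene(components=[comp], call=call, emission_time=0.0,
                         window=call.ipi_s)


def masked_echo_scene(range_m: float = 1.0, echo_level_db: float = 40.0,
                      masker_level_db: float = 115.0,
                      masker_offset_s: float = -1e-3, c: float = 343.0
                      ) -> ReceivedScene:
    """A wall echo overlapped by a much louder conspecific call.

    With the defaults the masker pins the 70 dB dynamic-range threshold at
    45 dB, burying the 40 dB echo, while its own de-chirped peak lands 1 ms
    away — inside the 4 ms masking window but outside the 100 us gate — so
    the echo is classified as jammed.
    """
    scene = single_echo_scene(range_m, echo_level_db, c)
    masker = SoundComponent(kind=CONSPECIFIC_CALL, emitter_id=1,
                            delay=scene.components[0].delay + masker_offset_s,
                            level_db=masker_level_db,
                            source_call=default_call(), true_bearing=0.5)
    scene.components.append(masker)
    return scene


def scene_to_frame(scene: ReceivedScene) -> pd.DataFrame:
    rows = []
    for comp in scene.components:
        row = {"kind": comp.kind, "delay_s": comp.delay,
               "level_db": comp.level_db, "bearing_rad": comp.true_bearing,
               "distance_m": comp.distance}
        for k in _CALL_COLS:
            row[f"call_{k}"] = getattr(comp.source_call,
                                       k if k != "level_db" else "level_db")
        rows.append(row)
    return pd.DataFrame(rows)


def scene_from_frame(df: pd.DataFrame, window: float | None = None
                     ) -> ReceivedScene:
    comps = []
    for _, r in df.iterrows():
        call = CallParams(ipi_ms=r["call_ipi_ms"],
                          duration_ms=r["call_duration_ms"],
                          terminal_freq_khz=r["call_terminal_freq_khz"],
                          bandwidth_khz=r["call_bandwidth_khz"],
                          level_db=r["call_level_db"],
                          species=str(r["call_species"]))
        comps.append(SoundComponent(kind=r["kind"], emitter_id=0,
                                    delay=float(r["delay_s"]),
                                    level_db=float(r["level_db"]),
                                    source_call=call,
                                    true_bearing=float(r["bearing_rad"]),
                                    reflector_ref=0,
                                    distance=float(r.get("distance_m", np.nan))))
    own = [c for c in comps if c.kind == OWN_WALL_ECHO]
    base_call = own[0].source_call if own else comps[0].source_call
    return ReceivedScene(components=comps, call=base_call, emission_time=0.0,
                         window=window or base_call.ipi_s)
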