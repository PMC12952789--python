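"""Configuration schema, file loading, and scenario presets.

Config precedence (lowest to highest): dataclass defaults < preset <
config file (YAML or JSON) < command-line flags. Presets cover the standard
parameter sweeps: bat density, species, integration window, nominal speed,
call level, masking on/off, confusion with and without multi-call
clustering, and wall/conspecific target strengths.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .engine import REPEAT_SCHEDULE, TrialConfig

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(TrialConfig)
                  if f.name != "arena"}

#: swept values per preset family; densities restricted where noted
SWEEPS = {
    "density": [1, 2, 5, 10, 20, 40, 100],
    "window": [0, 1, 3, 5, 10],
    "speed": [2.0, 4.0, 6.0, 8.0, 10.0],
    "level": [100.0, 110.0, 120.0, 130.0],
    "wall_ts": [-33.0, -23.0, -13.0, -3.0],
    "conspecific_ts": [-49.0, -43.0, -33.0, -23.0],
}


def load_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON trial-config mapping; unknown keys are an error."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config keys")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data


def make_config(preset_overrides: dict | None = None,
                file_overrides: dict | None = None,
                flag_overrides: dict | None = None) -> TrialConfig:
    """Layer overrides on the defaults in precedence order."""
    merged: dict = {}
    for layer in (preset_overrides, file_overrides, flag_overrides):
        if layer:
            merged.update({k: v for k, v in layer.items() if v is not None})
    unknown = set(merged) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return TrialConfig(**merged)


def config_to_dict(cfg: TrialConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("arena", None)
    return d


@dataclasses.dataclass
class ScenarioPreset:
    """A named batch scenario: a grid of config overrides plus repeats."""

    name: str
    grid: list[dict]                     # per-scenario overrides
    densities: list[int]
    repeats: dict[int, int] = dataclasses.field(
        default_factory=lambda: dict(REPEAT_SCHEDULE))

    def configs(self, base_seed: int = 0, repeat_scale: float = 1.0,
                file_overrides: dict | None = None,
                flag_overrides: dict | None = None) -> list[TrialConfig]:
        cfgs = []
        for gi, over in enumerate(self.grid):
            for n in self.densities:
                n_rep = max(1, int(round(self.repeats.get(n, 1) * repeat_scale)))
                for r in range(n_rep):
                    seed = base_seed + 100_000 * gi + 1000 * n + r
                    merged = dict(over, n_bats=n, seed=seed)
                    cfgs.append(make_config(merged, file_overrides,
                                            flag_overrides))
        return cfgs


def _preset(name, grid, densities=None, max_density=100) -> ScenarioPreset:
    densities = densities or [d for d in SWEEPS["density"] if d <= max_density]
    return ScenarioPreset(name=name, grid=grid, densities=densities)


PRESETS: dict[str, ScenarioPreset] = {p.name: p for p in [
    _preset("table1-density-sweep", [{}]),
    _preset("table1-species", [{"species": s} for s in ("PK", "RM")]),
    _preset("table1-window-sweep",
            [{"window_calls": w} for w in SWEEPS["window"]]),
    _preset("table1-speed-sweep",
            [{"nominal_speed": v} for v in SWEEPS["speed"]]),
    _preset("table1-level-sweep",
            [{"call_level_db": l} for l in SWEEPS["level"]]),
    _preset("table1-masking", [{"masking": m} for m in (True, False)]),
    _preset("table1-confusion",
            [{"confusion": False}, {"confusion": True},
             {"confusion": True, "clustering": True}], max_density=40),
    _preset("table1-wall-ts",
            [{"wall_target_strength": ts} for ts in SWEEPS["wall_ts"]],
            max_density=40),
    _preset("table1-conspecific-ts",
            [{"conspecific_target_strength": ts}
             for ts in SWEEPS["conspecific_ts"]], max_density=40),
]}
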