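"""Run configuration.

A run is described by a declarative YAML file (flat keys plus nested
sections) so that every model parameter — the partitioning coefficients,
the slope reclassification table, the class thresholds, and each
uncertain-parameter distribution — can be overridden without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .agb import AGBParams, SlopeReclassTable
from .stocking import DEFAULT_AU_FACTORS
from .uncertainty import ParamSpec, default_specs


@dataclass
class RunConfig:
    """Everything a pipeline run needs."""

    input_dir: str = "."
    output_dir: str = "outputs"
    years: list[int] | None = None  # None: all years present in the NPP stack
    window_years: list[int] | None = None  # None: 2008–2012 ∩ years
    n_draws: int = 1000
    rng_seed: int = 0
    class_thresholds: tuple[float, float] = (0.20, 0.65)
    agb_floor: float = 0.1  # g m⁻² yr⁻¹ display mask
    alpha: float = 0.05
    grassland_classes: tuple[int, ...] = (8, 9, 10)
    au_factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AU_FACTORS))
    agb: AGBParams = field(default_factory=AGBParams)
    param_specs: dict[str, ParamSpec] = field(default_factory=default_specs)

    def __post_init__(self) -> None:
        low, med = self.class_thresholds
        if not 0 < low < med:
            raise ValueError("class thresholds need 0 < low_max < med_max")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if self.agb_floor < 0:
            raise ValueError("agb_floor must be non-negative")


def _agb_params_from_dict(d: dict) -> AGBParams:
    kwargs = {}
    for f in fields(AGBParams):
        if f.name in d:
            kwargs[f.name] = d[f.name]
    if "slope_reclass" in kwargs:
        entries = tuple(
            (float("inf") if b in ("inf", None) else float(b), float(m))
            for b, m in kwargs["slope_reclass"]
        )
        kwargs["slope_reclass"] = SlopeReclassTable(entries)
    return AGBParams(**kwargs)


def _specs_from_dict(d: dict) -> dict[str, ParamSpec]:
    specs = default_specs()
    for name, row in d.items():
        specs[name] = ParamSpec(
            name=name,
            kind=row.get("kind", "truncated_normal"),
            lower=float(row["lower"]),
            upper=float(row["upper"]),
            mean=None if row.get("mean") is None else float(row["mean"]),
            sd=None if row.get("sd") is None else float(row["sd"]),
        )
    return specs


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unspecified keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    simple = {
        "input_dir", "output_dir", "years", "window_years", "n_draws",
        "rng_seed", "agb_floor", "alpha",
    }
    for key in simple & raw.keys():
        kwargs[key] = raw[key]
    if "class_thresholds" in raw:
        kwargs["class_thresholds"] = tuple(float(v) for v in raw["class_thresholds"])
    if "grassland_classes" in raw:
        kwargs["grassland_classes"] = tuple(int(c) for c in raw["grassland_classes"])
    if "au_factors" in raw:
        factors = dict(DEFAULT_AU_FACTORS)
        factors.update({k: float(v) for k, v in raw["au_factors"].items()})
        kwargs["au_factors"] = factors
    if "agb" in raw:
        kwargs["agb"] = _agb_params_from_dict(raw["agb"])
    if "param_specs" in raw:
        kwargs["param_specs"] = _specs_from_dict(raw["param_specs"])
    return RunConfig(**kwargs)
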