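"""Sweep orchestration: flat config files, surface generation, phase maps.

Config dialect: plain text, one ``key = value`` per line, ``#`` comments,
dotted keys for sections, e.g.::

    analysis = closed_form_doublet
    model.preset = visual_cortex_doublet
    model.a_plus = 0.02            # optional field override
    axis1.name = window_T
    axis1.start = 1
    axis1.stop = 100
    axis1.num = 50
    axis2.name = delay_d
    axis2.start = -10
    axis2.stop = 10
    axis2.num = 41
    fixed.freq_f = 5               # closed_form_triplet only
    seed = 1
    output = surface.tsv

Values parse as int, then float, then string.  Exactly two axes are swept;
for the closed-form analyses they are the synchronization window ``window_T``
and the effective delay ``delay_d``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .doublet import dw_grid
from .kernels import (
    DoubletKernelParams,
    InterpolationParams,
    PowerLawParams,
    TripletParams,
    get_preset,
)
from .pairing import NEAREST_NEIGHBOR, classify_coupling, estimate_dw_surface
from .protocols import ProtocolSpec
from .surfaces import WeightChangeSurface, save_surface
from .triplet import triplet_grid

__all__ = [
    "SweepConfig",
    "parse_config",
    "serialize_config",
    "run_sweep",
    "phase_map",
]

logger = logging.getLogger("stdpsync")

_ANALYSES = (
    "closed_form_doublet",
    "equilibrium_powerlaw",
    "equilibrium_interp",
    "closed_form_triplet",
    "monte_carlo",
)


def _parse_value(text: str):
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def parse_config(text: str) -> dict:
    """Parse the flat dotted ``key = value`` dialect into a nested dict."""
    out: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (p.strip() for p in line.split("=", 1))
        node = out
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ValueError(f"key {key!r} conflicts with a scalar entry")
        node[parts[-1]] = _parse_value(value)
    return out


def serialize_config(config: dict) -> str:
    """Flatten a nested dict back to sorted dotted ``key = value`` lines."""
    lines: list[str] = []

    def walk(prefix: str, node) -> None:
        if isinstance(node, dict):
            for key in sorted(node):
                walk(f"{prefix}.{key}" if prefix else key, node[key])
        else:
            lines.append(f"{prefix} = {node}")

    walk("", config)
    return "\n".join(lines) + "\n"


@dataclass
class SweepConfig:
    """Validated sweep description: analysis, model, two axes, fixed params."""

    analysis: str
    model_preset: str
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    model_overrides: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    output: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.analysis not in _ANALYSES:
            raise ValueError(
                f"unknown analysis {self.analysis!r}; valid: {list(_ANALYSES)}"
            )

    @classmethod
    def from_dict(cls, config: dict) -> "SweepConfig":
        model = dict(config.get("model", {}))
        preset = model.pop("preset", None)
        if preset is None:
            raise ValueError("config must set model.preset")
        axes = []
        for key in ("axis1", "axis2"):
            ax = config.get(key)
            if ax is None:
                raise ValueError(f"config must define {key} (exactly two swept axes)")
            missing = {"name", "start", "stop", "num"} - set(ax)
            if missing:
                raise ValueError(f"{key} lacks fields {sorted(missing)}")
            axes.append((ax["name"], np.linspace(ax["start"], ax["stop"], int(ax["num"]))))
        return cls(
            analysis=config.get("analysis", ""),
            model_preset=preset,
            model_overrides=model,
            axis1_name=axes[0][0], axis1_values=axes[0][1],
            axis2_name=axes[1][0], axis2_values=axes[1][1],
            fixed=dict(config.get("fixed", {})),
            output=config.get("output"),
            seed=int(config.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "SweepConfig":
        return cls.from_dict(parse_config(Path(path).read_text()))

    def resolved_model(self):
        params = get_preset(self.model_preset)
        if self.model_overrides:
            valid = {f.name for f in dataclasses.fields(params)}
            unknown = set(self.model_overrides) - valid
            if unknown:
                raise ValueError(
                    f"override(s) {sorted(unknown)} not valid for "
                    f"{type(params).__name__}; valid fields: {sorted(valid)}"
                )
            params = dataclasses.replace(
                params, **{k: float(v) for k, v in self.model_overrides.items()}
            )
        return params


_EXPECTED_MODEL = {
    "closed_form_doublet": DoubletKernelParams,
    "equilibrium_powerlaw": PowerLawParams,
    "equilibrium_interp": InterpolationParams,
    "closed_form_triplet": TripletParams,
}


def run_sweep(config: SweepConfig) -> WeightChangeSurface:
    """Dispatch a sweep to the appropriate analysis and optionally write it.

    Deterministic given the config seed; the output file header records the
    preset, package version and all generation parameters.
    """
    model = config.resolved_model()
    expected = _EXPECTED_MODEL.get(config.analysis)
    if expected is not None and not isinstance(model, expected):
        raise ValueError(
            f"analysis {config.analysis!r} requires a {expected.__name__} preset, "
            f"got {type(model).__name__} ({config.model_preset!r})"
        )
    if config.analysis != "monte_carlo" and (
        (config.axis1_name, config.axis2_name) != ("window_T", "delay_d")
    ):
        raise ValueError(
            "closed-form sweeps sweep axis1=window_T and axis2=delay_d; "
            f"got ({config.axis1_name!r}, {config.axis2_name!r})"
        )
    logger.info("running %s sweep with preset %s", config.analysis, config.model_preset)
    if config.analysis == "closed_form_triplet":
        freq_f = float(config.fixed.get("freq_f", 5.0))
        surface = triplet_grid(freq_f, config.axis1_values, config.axis2_values,
                               model, preset_name=config.model_preset)
    elif config.analysis == "monte_carlo":
        fixed = dict(config.fixed)
        repeats = int(fixed.pop("repeats", 5))
        mode = fixed.pop("mode", NEAREST_NEIGHBOR)
        template = ProtocolSpec(seed=config.seed, **fixed)
        surface = estimate_dw_surface(template, model, config.axis1_values,
                                      config.axis2_values, repeats=repeats,
                                      seed=config.seed, mode=mode)
        surface.meta["preset"] = config.model_preset
    else:
        surface = dw_grid(config.axis1_values, config.axis2_values, model,
                          preset_name=config.model_preset)
    surface.meta.update({
        "analysis": config.analysis,
        "stdpsync_version": __version__,
        "seed": config.seed,
    })
    if config.output:
        save_surface(surface, config.output)
        logger.info("surface written to %s", config.output)
    return surface


def phase_map(surface: WeightChangeSurface, policy: str = "auto") -> np.ndarray:
    """Categorical map over a surface: coupling / decoupling / indeterminate / masked.

    ``policy='sign'`` classifies by the sign of the value (closed forms),
    ``policy='stderr'`` by a 3-standard-error criterion (Monte-Carlo
    surfaces); ``'auto'`` picks 'stderr' when the surface carries standard
    errors and 'sign' otherwise.
    """
    if policy == "auto":
        policy = "stderr" if surface.stderr is not None else "sign"
    if policy not in ("sign", "stderr"):
        raise ValueError("policy must be 'auto', 'sign' or 'stderr'")
    if policy == "stderr" and surface.stderr is None:
        raise ValueError("surface has no stderr block for the stderr policy")
    out = np.empty(surface.values.shape, dtype=object)
    for i in range(surface.values.shape[0]):
        for j in range(surface.values.shape[1]):
            if (surface.mask is not None and surface.mask[i, j]) or not np.isfinite(
                surface.values[i, j]
            ):
                out[i, j] = "masked"
            elif policy == "sign":
                v = surface.values[i, j]
                out[i, j] = ("coupling" if v > 0
                             else "decoupling" if v < 0 else "indeterminate")
            else:
                out[i, j] = classify_coupling(surface.values[i, j],
                                              surface.stderr[i, j])
    return out
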