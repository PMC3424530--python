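"""Spike-timing-dependent plasticity (STDP) rules as pure weight-update functions.

Every rule is expressed as a deterministic function of spike-time lags and a
frozen parameter bundle.  Four rule families are covered:

* the linear doublet (pair-based) rule with exponential LTP/LTD branches,
* the power-law weight-dependent doublet rule,
* the doublet rule interpolating between additive and multiplicative limits,
* the nearest-neighbor triplet rule, whose potentiation/depression terms also
  depend on the previous same-side interspike interval.

Units: all times and time constants are in milliseconds; amplitudes are
dimensionless weight increments per pairing.  Unit conversion from rates
(spikes/s) happens at the protocol boundary (:mod:`stdpsync.protocols`),
never inside these kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "DoubletKernelParams",
    "PowerLawParams",
    "InterpolationParams",
    "TripletParams",
    "doublet_kernel",
    "powerlaw_amplitudes",
    "interp_amplitudes",
    "triplet_ltp",
    "triplet_ltd",
    "PRESETS",
    "get_preset",
    "save_params",
    "load_params",
]


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DoubletKernelParams:
    """Parameters of the linear doublet STDP function.

    ``a_plus``/``a_minus`` are the LTP/LTD amplitude magnitudes per pairing,
    ``tau_plus``/``tau_minus`` the corresponding exponential decay constants
    in ms.  Realistic cortical fits have ``a_plus > a_minus`` and
    ``tau_plus < tau_minus`` so that the kernel integrates to a negative
    value (depression dominates for uncorrelated firing).
    """

    a_plus: float
    a_minus: float
    tau_plus: float
    tau_minus: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class PowerLawParams:
    """Power-law weight dependence of the doublet amplitudes.

    The effective amplitudes at weight ``w`` (in units of ``w_ref``) are
    ``a_plus = eta * w_ref**(1-mu) * w**mu`` and ``a_minus = eta * alpha * w``:
    potentiation grows sub-linearly with weight, depression linearly, which
    yields a stable equilibrium weight.  ``eta`` is the learning-rate scale
    and ``alpha`` the depression/potentiation asymmetry.
    """

    mu: float
    w_ref: float
    eta: float
    alpha: float
    tau_plus: float
    tau_minus: float

    def __post_init__(self) -> None:
        if not (0 <= self.mu < 1):
            raise ValueError(f"mu must satisfy 0 <= mu < 1, got {self.mu!r}")
        for name in ("w_ref", "eta", "alpha", "tau_plus", "tau_minus"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class InterpolationParams:
    """Doublet rule interpolating between additive and multiplicative limits.

    Weights governed by this rule live in [0, 1].  The effective amplitudes
    are ``a_plus = eta * (1-w)**mu`` and ``a_minus = eta * alpha * w**mu``;
    ``mu -> 0`` approaches the additive rule, ``mu = 1`` is multiplicative.
    """

    mu: float
    eta: float
    alpha: float
    tau_plus: float
    tau_minus: float

    def __post_init__(self) -> None:
        if not (0 < self.mu <= 1):
            raise ValueError(f"mu must satisfy 0 < mu <= 1, got {self.mu!r}")
        for name in ("eta", "alpha", "tau_plus", "tau_minus"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class TripletParams:
    """Nearest-neighbor triplet STDP parameters.

    ``a2_plus``/``a2_minus`` are the pair amplitudes, ``a3_plus``/``a3_minus``
    the triplet amplitudes gating on the previous same-side interspike
    interval with decay constants ``tau_y`` (LTP) and ``tau_x`` (LTD).
    ``scale`` multiplies all four amplitudes (used to speed up slow-learning
    simulations without changing the fixed-point structure).
    """

    a2_plus: float
    a3_plus: float
    a2_minus: float
    a3_minus: float
    tau_plus: float
    tau_minus: float
    tau_x: float
    tau_y: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a2_plus", "a3_plus", "a2_minus", "a3_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_plus", "tau_minus", "tau_x", "tau_y", "scale"):
            _require_positive(name, getattr(self, name))


ParamBundle = Union[DoubletKernelParams, PowerLawParams, InterpolationParams, TripletParams]


# --------------------------------------------------------------------------
# Named presets.  Amplitudes/time constants are the published experimental
# fits these rules are routinely used with (visual cortex pair data for the
# doublet rule; hippocampus and visual-cortex minimal fits for the triplet
# rule); "lubenov_doublet" is the near-symmetric artificial parameter choice
# used in the decoupling-by-synchrony argument this package re-examines.
# --------------------------------------------------------------------------

#: Doublet fit to visual-cortex pairing data: A+=0.0147, A-=0.0073, tau+=13, tau-=34.
VISUAL_CORTEX_DOUBLET = DoubletKernelParams(0.0147, 0.0073, 13.0, 34.0)

#: Near-symmetric artificial parameters: equal time constants, A+ = 1.1 A-.
LUBENOV_DOUBLET = DoubletKernelParams(1.1 * 0.0073, 0.0073, 20.0, 20.0)

#: Power-law rule, original published parameters (tau+ = tau- = 20 ms).
POWERLAW_ORIGINAL = PowerLawParams(mu=0.4, w_ref=1.0, eta=0.1, alpha=0.11,
                                   tau_plus=20.0, tau_minus=20.0)

#: Power-law rule adapted so that at w = w_ref the effective amplitudes match
#: the visual-cortex doublet fit: eta*w_ref = 0.0147, eta*alpha*w_ref = 0.0073.
POWERLAW_ADAPTED = PowerLawParams(mu=0.4, w_ref=1.0, eta=0.0147,
                                  alpha=0.0073 / 0.0147,
                                  tau_plus=13.0, tau_minus=34.0)

#: Multiplicative interpolating rule with visual-cortex-consistent asymmetry.
INTERP_MULTIPLICATIVE = InterpolationParams(mu=1.0, eta=0.0147,
                                            alpha=0.0073 / 0.0147,
                                            tau_plus=13.0, tau_minus=34.0)

#: Almost-additive interpolating rule (mu -> 0 limit probed at mu = 0.001).
INTERP_ALMOST_ADDITIVE = InterpolationParams(mu=0.001, eta=0.0147,
                                             alpha=0.0073 / 0.0147,
                                             tau_plus=13.0, tau_minus=34.0)

#: Minimal triplet fit to hippocampal pairing/triplet data.
HIPPOCAMPUS_TRIPLET = TripletParams(a2_plus=0.0046, a3_plus=0.0091,
                                    a2_minus=0.003, a3_minus=0.0,
                                    tau_plus=16.8, tau_minus=33.7,
                                    tau_x=575.0, tau_y=48.0)

#: Minimal triplet fit to visual-cortex frequency-dependence data (A2+ = 0:
#: all potentiation is triplet-gated).
VISUAL_CORTEX_TRIPLET = TripletParams(a2_plus=0.0, a3_plus=0.05,
                                      a2_minus=0.008, a3_minus=0.0,
                                      tau_plus=16.8, tau_minus=33.7,
                                      tau_x=714.0, tau_y=40.0)

#: The visual-cortex doublet rule expressed in triplet form (A3+/- = 0); the
#: triplet time constants are inert and set to round placeholders.
DOUBLET_AS_TRIPLET = TripletParams(a2_plus=0.0147, a3_plus=0.0,
                                   a2_minus=0.0073, a3_minus=0.0,
                                   tau_plus=13.0, tau_minus=34.0,
                                   tau_x=100.0, tau_y=100.0)

PRESETS: dict[str, ParamBundle] = {
    "visual_cortex_doublet": VISUAL_CORTEX_DOUBLET,
    "lubenov_doublet": LUBENOV_DOUBLET,
    "powerlaw_original": POWERLAW_ORIGINAL,
    "powerlaw_adapted": POWERLAW_ADAPTED,
    "interp_multiplicative": INTERP_MULTIPLICATIVE,
    "interp_almost_additive": INTERP_ALMOST_ADDITIVE,
    "hippocampus_triplet": HIPPOCAMPUS_TRIPLET,
    "visual_cortex_triplet": VISUAL_CORTEX_TRIPLET,
    "doublet_as_triplet": DOUBLET_AS_TRIPLET,
}


def get_preset(name: str) -> ParamBundle:
    """Look up a named parameter preset; raises with the valid names listed."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        ) from None


# --------------------------------------------------------------------------
# Kernel functions
# --------------------------------------------------------------------------

def doublet_kernel(lag, params: DoubletKernelParams):
    """Weight change per spike pair as a function of the time lag (ms).

    Positive lags (pre before post at the synapse) potentiate with amplitude
    ``a_plus`` decaying over ``tau_plus``; negative lags depress with
    amplitude ``a_minus`` decaying over ``tau_minus``.  The value at exactly
    zero lag is defined as 0: simultaneous arrival at the synapse carries no
    causal information, and a neutral value biases neither branch.

    Accepts scalars or arrays; returns the same shape.
    """
    arr = np.asarray(lag, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("lag must be finite")
    out = np.where(
        arr > 0,
        params.a_plus * np.exp(-arr / params.tau_plus),
        np.where(arr < 0, -params.a_minus * np.exp(arr / params.tau_minus), 0.0),
    )
    if np.isscalar(lag) or arr.ndim == 0:
        return float(out)
    return out


def powerlaw_amplitudes(w: float, params: PowerLawParams) -> tuple[float, float]:
    """Effective (a_plus, a_minus) of the power-law rule at weight ``w``.

    ``w`` is measured in the same units as ``w_ref``.
    """
    if w < 0:
        raise ValueError(f"weight must be >= 0, got {w!r}")
    a_plus = params.eta * params.w_ref ** (1.0 - params.mu) * w ** params.mu
    a_minus = params.eta * params.alpha * w
    return a_plus, a_minus


def interp_amplitudes(w: float, params: InterpolationParams) -> tuple[float, float]:
    """Effective (a_plus, a_minus) of the interpolating rule at weight ``w`` in [0, 1]."""
    if not (0 <= w <= 1):
        raise ValueError(f"weight must be in [0, 1], got {w!r}")
    a_plus = params.eta * (1.0 - w) ** params.mu
    a_minus = params.eta * params.alpha * w ** params.mu
    return a_plus, a_minus


def triplet_ltp(dt1: float, dt2: float, params: TripletParams) -> float:
    """Potentiation at a postsynaptic spike under the nearest-neighbor triplet rule.

    ``dt1`` is the time (ms) since the last presynaptic spike, ``dt2`` the
    time since the previous postsynaptic spike; ``dt2`` may be ``inf`` for
    the first postsynaptic spike, in which case the triplet term vanishes
    and the pure pair amplitude remains.
    """
    if dt1 < 0 or dt2 < 0:
        raise ValueError("dt1 and dt2 must be >= 0")
    triplet = params.a3_plus * math.exp(-dt2 / params.tau_y) if math.isfinite(dt2) else 0.0
    return params.scale * math.exp(-dt1 / params.tau_plus) * (params.a2_plus + triplet)


def triplet_ltd(dt1: float, dt2: float, params: TripletParams) -> float:
    """Depression at a presynaptic spike under the nearest-neighbor triplet rule.

    ``dt1`` is the time (ms) since the last postsynaptic spike, ``dt2`` the
    time since the previous presynaptic spike (``inf`` allowed).  Returns a
    non-positive value.
    """
    if dt1 < 0 or dt2 < 0:
        raise ValueError("dt1 and dt2 must be >= 0")
    triplet = params.a3_minus * math.exp(-dt2 / params.tau_x) if math.isfinite(dt2) else 0.0
    return -params.scale * math.exp(-dt1 / params.tau_minus) * (params.a2_minus + triplet)


# --------------------------------------------------------------------------
# Flat key=value config round trip
# --------------------------------------------------------------------------

_KIND_BY_NAME = {
    "DoubletKernelParams": DoubletKernelParams,
    "PowerLawParams": PowerLawParams,
    "InterpolationParams": InterpolationParams,
    "TripletParams": TripletParams,
}


def params_to_config(params: ParamBundle) -> str:
    """Serialize a parameter bundle as flat ``name = value`` lines.

    ``repr`` of the floats is used so that the round trip is lossless.
    """
    lines = [f"kind = {type(params).__name__}"]
    for f in fields(params):
        lines.append(f"{f.name} = {getattr(params, f.name)!r}")
    return "\n".join(lines) + "\n"


def params_from_config(text: str) -> ParamBundle:
    """Parse the flat ``name = value`` format written by :func:`params_to_config`."""
    entries: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        entries[key] = value
    kind_name = entries.pop("kind", None)
    if kind_name is None or kind_name not in _KIND_BY_NAME:
        raise ValueError(f"config must declare a known 'kind', got {kind_name!r}")
    cls = _KIND_BY_NAME[kind_name]
    return cls(**{k: float(v) for k, v in entries.items()})


def save_params(params: ParamBundle, path) -> None:
    Path(path).write_text(params_to_config(params))


def load_params(path) -> ParamBundle:
    return params_from_config(Path(path).read_text())
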