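"""Event-driven application of doublet and nearest-neighbor triplet STDP to
spike-train pairs, empirical lag distributions, and Monte-Carlo estimates of
expected weight change that cross-validate the closed forms.

Pairing semantics.  Under all-to-all (AA) pairing, every presynaptic/
postsynaptic spike pair within a maximum lag contributes, so the lag
multiset is (up to the delay shift) the spike cross-correlogram.  Under
nearest-neighbor (NN) pairing, each presynaptic spike pairs only with its
nearest preceding and nearest following postsynaptic spikes.  All lags are
measured at the synaptic site: presynaptic times are shifted by the
effective delay d before comparison, so "nearest" is nearest after the
shift, matching the synapse-referenced lag convention of the closed forms.

Tie handling: a presynaptic and a postsynaptic spike landing on the same
synapse-site instant are processed post-before-pre; the doublet kernel's
zero-lag value is 0, and the triplet rule's "last" partners are strict
predecessors, so ties never create a phantom causal pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .kernels import (
    DoubletKernelParams,
    InterpolationParams,
    PowerLawParams,
    TripletParams,
    doublet_kernel,
    interp_amplitudes,
    powerlaw_amplitudes,
)
from .protocols import ProtocolSpec, SpikeTrain, generate_pair
from .surfaces import WeightChangeSurface

__all__ = [
    "ALL_TO_ALL",
    "NEAREST_NEIGHBOR",
    "WeightTrajectory",
    "Histogram",
    "collect_lags",
    "lag_histogram",
    "run_doublet",
    "run_triplet_nn",
    "estimate_dw_surface",
    "classify_coupling",
]

ALL_TO_ALL = "all_to_all"
NEAREST_NEIGHBOR = "nearest_neighbor"
_MODES = (ALL_TO_ALL, NEAREST_NEIGHBOR)

#: Default maximum lag (ms) for all-to-all collection; about six depression
#: time constants of the realistic doublet fit, beyond which kernel
#: contributions are below 0.3% of the amplitude.
DEFAULT_MAX_LAG = 200.0


@dataclass
class WeightTrajectory:
    """Weight after each plasticity update, at the update instants (ms)."""

    times: np.ndarray
    weights: np.ndarray
    w_init: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.times.size != self.weights.size:
            raise ValueError("times and weights must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("update times must be non-decreasing")

    @property
    def total_dw(self) -> float:
        """Final minus initial weight."""
        if self.weights.size == 0:
            return 0.0
        return float(self.weights[-1] - self.w_init)

    @property
    def deltas(self) -> np.ndarray:
        """Per-update weight increments."""
        return np.diff(np.concatenate([[self.w_init], self.weights]))

    def save(self, path) -> None:
        """Write the trajectory as two-column text: time_ms, weight."""
        from pathlib import Path

        lines = [f"# w_init: {self.w_init!r}", "# columns: time_ms\tweight"]
        lines.extend(f"{float(t)!r}\t{float(w)!r}" for t, w in zip(self.times, self.weights))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "WeightTrajectory":
        from pathlib import Path

        w_init = 0.0
        times, weights = [], []
        for raw in Path(path).read_text().splitlines():
            if raw.startswith("#"):
                if raw[1:].strip().startswith("w_init:"):
                    w_init = float(raw.split(":", 1)[1])
            elif raw.strip():
                t, w = raw.split("\t")
                times.append(float(t))
                weights.append(float(w))
        return cls(times=np.array(times), weights=np.array(weights), w_init=w_init)


def _collect_pairs(pre: SpikeTrain, post: SpikeTrain, delay_d: float,
                   mode: str, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (lags, update_times) of relevant pairs at the synapse site.

    The update time of a pair is the time of its later spike at the synapse.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    ps = pre.times + delay_d
    q = post.times
    if ps.size == 0 or q.size == 0:
        return np.empty(0), np.empty(0)
    if mode == ALL_TO_ALL:
        if not (max_lag > 0):
            raise ValueError("max_lag must be > 0 for all-to-all pairing")
        lo = np.searchsorted(q, ps - max_lag, side="left")
        hi = np.searchsorted(q, ps + max_lag, side="right")
        counts = hi - lo
        pre_idx = np.repeat(np.arange(ps.size), counts)
        # per-pre consecutive post indices lo[i] .. hi[i]-1
        offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
        post_idx = np.arange(counts.sum()) - np.repeat(offsets, counts) + np.repeat(lo, counts)
        lags = q[post_idx] - ps[pre_idx]
        update = np.maximum(q[post_idx], ps[pre_idx])
        return lags, update
    # nearest neighbor: per presynaptic spike, the nearest strictly preceding
    # and the nearest following (lag >= 0) postsynaptic spike
    idx = np.searchsorted(q, ps, side="left")
    lags_list, update_list = [], []
    has_prev = idx > 0
    prev = q[idx[has_prev] - 1]
    lags_list.append(prev - ps[has_prev])
    update_list.append(ps[has_prev])  # pre is the later spike
    has_next = idx < q.size
    nxt = q[idx[has_next]]
    lags_list.append(nxt - ps[has_next])
    update_list.append(nxt)  # post is the later spike (or tied)
    return np.concatenate(lags_list), np.concatenate(update_list)


def collect_lags(pre: SpikeTrain, post: SpikeTrain, delay_d: float,
                 mode: str = NEAREST_NEIGHBOR,
                 max_lag: float = DEFAULT_MAX_LAG) -> np.ndarray:
    """Multiset of synapse-site lags (post - pre - d) of the relevant pairs.

    ``max_lag`` bounds the all-to-all collection and is ignored for
    nearest-neighbor pairing.  Empty trains yield an empty array.
    """
    return _collect_pairs(pre, post, delay_d, mode, max_lag)[0]


@dataclass
class Histogram:
    """Normalized lag histogram: bin masses (or counts) and bin edges (ms)."""

    values: np.ndarray
    edges: np.ndarray
    empty: bool  # True when no lags fell in range (all-zero histogram)


def lag_histogram(lags, bin_width: float, lag_range: tuple[float, float],
                  normalize: bool = True) -> Histogram:
    """Histogram estimate of the pair-lag density G.

    Bin edges sit at integer multiples of ``bin_width``; with
    ``normalize=True`` the bin masses sum to 1 over the range (raw counts
    otherwise).  An empty lag set produces an all-zero histogram flagged
    ``empty=True``.
    """
    if not (bin_width > 0):
        raise ValueError("bin_width must be > 0")
    lo, hi = lag_range
    edges = np.arange(np.floor(lo / bin_width), np.ceil(hi / bin_width) + 1) * bin_width
    counts, _ = np.histogram(np.asarray(lags, dtype=float), bins=edges)
    total = counts.sum()
    if total == 0:
        return Histogram(values=np.zeros(edges.size - 1), edges=edges, empty=True)
    values = counts / total if normalize else counts.astype(float)
    return Histogram(values=values, edges=edges, empty=False)


def _order_pairs(lags: np.ndarray, update: np.ndarray) -> np.ndarray:
    # chronological in the later spike; ties processed post-before-pre,
    # i.e. potentiating (lag > 0) pairs first
    return np.lexsort(((lags <= 0).astype(int), update))


def run_doublet(pre: SpikeTrain, post: SpikeTrain, delay_d: float,
                kernel: Optional[DoubletKernelParams],
                mode: str = NEAREST_NEIGHBOR,
                weight_model: Union[PowerLawParams, InterpolationParams, None] = None,
                w_init: float = 0.0,
                clip_bounds: Optional[tuple[float, float]] = None,
                max_lag: float = DEFAULT_MAX_LAG) -> WeightTrajectory:
    """Apply doublet STDP to a spike-train pair.

    Kernel contributions are summed over the relevant pairs in chronological
    order of each pair's later spike.  With a ``weight_model`` the effective
    amplitudes are recomputed from the current weight before every update
    (the model's own time constants are then used; ``kernel`` may be None).
    ``clip_bounds`` clips the weight after each update; the interpolating
    model defaults to its natural domain [0, 1].
    """
    if weight_model is None and kernel is None:
        raise ValueError("either kernel or weight_model must be given")
    if isinstance(weight_model, InterpolationParams):
        if clip_bounds is None:
            clip_bounds = (0.0, 1.0)
        if not (0 <= w_init <= 1):
            raise ValueError("w_init must be in [0, 1] for the interpolating model")
    if isinstance(weight_model, PowerLawParams) and w_init < 0:
        raise ValueError("w_init must be >= 0 for the power-law model")
    lags, update = _collect_pairs(pre, post, delay_d, mode, max_lag)
    order = _order_pairs(lags, update)
    lags, update = lags[order], update[order]

    if weight_model is None and clip_bounds is None:
        # linear rule: a pure sum, evaluated vectorized
        deltas = doublet_kernel(lags, kernel) if lags.size else np.empty(0)
        weights = w_init + np.cumsum(deltas)
        return WeightTrajectory(times=update, weights=weights, w_init=w_init)

    tau_plus = weight_model.tau_plus if weight_model is not None else kernel.tau_plus
    tau_minus = weight_model.tau_minus if weight_model is not None else kernel.tau_minus
    w = w_init
    weights = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if weight_model is None:
            ap, am = kernel.a_plus, kernel.a_minus
        elif isinstance(weight_model, PowerLawParams):
            ap, am = powerlaw_amplitudes(max(w, 0.0), weight_model)
        else:
            ap, am = interp_amplitudes(min(max(w, 0.0), 1.0), weight_model)
        if lag > 0:
            w += ap * np.exp(-lag / tau_plus)
        elif lag < 0:
            w -= am * np.exp(lag / tau_minus)
        if clip_bounds is not None:
            w = min(max(w, clip_bounds[0]), clip_bounds[1])
        weights[i] = w
    return WeightTrajectory(times=update, weights=weights, w_init=w_init)


def run_triplet_nn(pre: SpikeTrain, post: SpikeTrain, delay_d: float,
                   params: TripletParams, w_init: float = 0.0,
                   clip_bounds: Optional[tuple[float, float]] = None
                   ) -> WeightTrajectory:
    """Apply nearest-neighbor triplet STDP to a spike-train pair.

    Spikes are processed in time order at the synapse site (presynaptic
    times shifted by +d).  Each postsynaptic spike potentiates as a function
    of the time since the last presynaptic spike (dt1) and the previous
    postsynaptic spike (dt2); each presynaptic spike depresses as a function
    of the time since the last postsynaptic spike (dt1) and the previous
    presynaptic spike (dt2).  "Last"/"previous" are strict predecessors; a
    spike with no presynaptic (resp. postsynaptic) partner produces no
    update, and a missing same-side predecessor only zeroes the triplet term.
    """
    ps = pre.times + delay_d
    q = post.times

    # LTP at each postsynaptic spike with a strict presynaptic predecessor
    idx = np.searchsorted(ps, q, side="left") - 1
    ltp_valid = idx >= 0
    dt1_ltp = q[ltp_valid] - ps[idx[ltp_valid]]
    post_isi = np.concatenate([[np.inf], np.diff(q)]) if q.size else np.empty(0)
    dt2_ltp = post_isi[ltp_valid]
    with np.errstate(over="ignore"):
        gate = params.a2_plus + params.a3_plus * np.where(
            np.isfinite(dt2_ltp), np.exp(-np.minimum(dt2_ltp, 1e300) / params.tau_y), 0.0
        )
    ltp = params.scale * np.exp(-dt1_ltp / params.tau_plus) * gate

    # LTD at each presynaptic spike with a strict postsynaptic predecessor
    jdx = np.searchsorted(q, ps, side="left") - 1
    ltd_valid = jdx >= 0
    dt1_ltd = ps[ltd_valid] - q[jdx[ltd_valid]]
    pre_isi = np.concatenate([[np.inf], np.diff(ps)]) if ps.size else np.empty(0)
    dt2_ltd = pre_isi[ltd_valid]
    gate_m = params.a2_minus + params.a3_minus * np.where(
        np.isfinite(dt2_ltd), np.exp(-np.minimum(dt2_ltd, 1e300) / params.tau_x), 0.0
    )
    ltd = -params.scale * np.exp(-dt1_ltd / params.tau_minus) * gate_m

    times = np.concatenate([q[ltp_valid], ps[ltd_valid]])
    deltas = np.concatenate([ltp, ltd])
    is_pre = np.concatenate([np.zeros(ltp.size, dtype=int), np.ones(ltd.size, dtype=int)])
    order = np.lexsort((is_pre, times))  # ties: post processed before pre
    times, deltas = times[order], deltas[order]

    if clip_bounds is None:
        weights = w_init + np.cumsum(deltas)
    else:
        weights = np.empty(deltas.size)
        w = w_init
        for i, dw in enumerate(deltas):
            w = min(max(w + dw, clip_bounds[0]), clip_bounds[1])
            weights[i] = w
    return WeightTrajectory(times=times, weights=weights, w_init=w_init)


def estimate_dw_surface(protocol_template: ProtocolSpec,
                        model: Union[DoubletKernelParams, TripletParams],
                        T_values, d_values, repeats: int, seed: int,
                        mode: str = NEAREST_NEIGHBOR,
                        max_lag: float = DEFAULT_MAX_LAG,
                        per_post_spike: bool = True) -> WeightChangeSurface:
    """Monte-Carlo surface of mean weight change per postsynaptic spike.

    For each (T, d) cell, ``repeats`` independent train pairs are generated
    from ``protocol_template`` (its window and delay overridden), the
    requested rule is applied, and the per-postsynaptic-spike weight change
    is averaged; the per-cell standard error of that mean is reported
    alongside.  ``per_post_spike=False`` reports the raw total weight
    change per realization instead.
    """
    T_arr = np.asarray(T_values, dtype=float)
    d_arr = np.asarray(d_values, dtype=float)
    if T_arr.size == 0 or d_arr.size == 0:
        raise ValueError("axes must be non-empty")
    values = np.empty((T_arr.size, d_arr.size))
    stderr = np.empty_like(values)
    child_seeds = (np.random.SeedSequence(seed).generate_state(
        T_arr.size * d_arr.size * repeats, dtype=np.uint32
    ) >> 1).reshape(T_arr.size, d_arr.size, repeats)
    for i, T in enumerate(T_arr):
        for j, d in enumerate(d_arr):
            per_rep = np.empty(repeats)
            for r in range(repeats):
                spec = replace(protocol_template, window_T=float(T), delay_d=float(d),
                               seed=int(child_seeds[i, j, r]))
                pre, post = generate_pair(spec)
                if isinstance(model, TripletParams):
                    traj = run_triplet_nn(pre, post, d, model)
                else:
                    traj = run_doublet(pre, post, d, model, mode=mode, max_lag=max_lag)
                n_post = max(post.n_spikes, 1) if per_post_spike else 1
                per_rep[r] = traj.total_dw / n_post
            values[i, j] = per_rep.mean()
            stderr[i, j] = per_rep.std(ddof=1) / np.sqrt(repeats) if repeats > 1 else 0.0
    return WeightChangeSurface(
        axis1_name="T_ms", axis1=T_arr, axis2_name="d_ms", axis2=d_arr,
        values=values, stderr=stderr,
        meta={"quantity": "mean_dw_per_post_spike" if per_post_spike else "mean_total_dw",
              "repeats": repeats,
              "protocol": protocol_template.kind, "seed": seed,
              "units": "ms (axes); dimensionless weight (values)"},
    )


def classify_coupling(dw: float, se: float) -> str:
    """Classify a Monte-Carlo weight change as coupling/decoupling at 3 s.e."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if dw > 3 * se:
        return "coupling"
    if dw < -3 * se:
        return "decoupling"
    return "indeterminate"
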