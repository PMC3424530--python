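"""Synthetic spike-train generation for the Poissonian stimulation protocols.

Two neurons (presynaptic and postsynaptic) share a sequence of stimulation
events of width T ms during which both fire at an elevated rate lambda_1;
outside events they fire at a background rate lambda_0 (default 1 spike/s).
Spikes are drawn independently per neuron per time step of size dt (default
0.1 ms) with probability lambda(t)*dt, so the trains are discretized
inhomogeneous Bernoulli/Poisson processes.  Three protocol kinds:

* ``oscillatory`` — events repeat regularly with frequency f (onset every
  1/f); lambda_1 is derived from the target mean rate via
  ``lambda_1 = lambda/(fT) - lambda_0 (1/(fT) - 1)``.
* ``nonoscillatory`` — an event starts at each step with probability
  lambda_e * dt (events may overlap; overlap does not stack the rate).  The
  probability that a step lies outside every event is
  ``p0 = (1 - lambda_e dt)^(T/dt)`` and
  ``lambda_1 = (lambda - p0 lambda_0)/(1 - p0)``.
* ``rate`` — homogeneous firing at the mean rate (rate coding).

The effective transmission delay d is *not* baked into stored spike trains;
trains stay soma-referenced and the delay is applied when lags are computed
(:func:`synapse_lag`).

A separate deterministic generator, :func:`generate_one_spike_per_cycle`,
produces the idealized protocol used by the closed-form triplet analysis:
postsynaptic spikes exactly at i/f, presynaptic spikes uniform in +-T/2
around them, exactly one spike per neuron per cycle.

Units: spike times and durations inside :class:`SpikeTrain` are ms; rates
are spikes/s; ``ProtocolSpec.duration`` is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "SpikeTrain",
    "ProtocolSpec",
    "lambda1_oscillatory",
    "p0_nonoscillatory",
    "lambda1_nonoscillatory",
    "generate_pair",
    "generate_one_spike_per_cycle",
    "synapse_lag",
    "save_spike_train",
    "load_spike_train",
    "save_pair",
    "load_pair",
]

_KINDS = ("oscillatory", "nonoscillatory", "rate")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one neuron over a finite recording."""

    times: np.ndarray
    duration: float  # ms

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-d array")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Empirical mean rate in spikes/s."""
        return self.n_spikes / (self.duration / 1000.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """Full description of a two-neuron stimulation protocol.

    ``window_T`` in ms, ``freq_f`` in Hz (oscillatory), ``event_rate`` in
    events/s (nonoscillatory), rates in spikes/s, ``delay_d`` in ms,
    ``dt`` in ms, ``duration`` in seconds.  The ``rate`` kind ignores
    ``window_T``/``freq_f``/``event_rate``.
    """

    kind: str
    rate_mean: float
    duration: float
    seed: int
    window_T: float = 10.0
    freq_f: Optional[float] = None
    event_rate: Optional[float] = None
    rate_bg: float = 1.0
    delay_d: float = 0.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.rate_mean < 0 or self.rate_bg < 0:
            raise ValueError("rates must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.kind == "oscillatory":
            if self.freq_f is None or self.freq_f <= 0:
                raise ValueError("oscillatory protocol requires freq_f > 0")
            if self.freq_f * self.window_T / 1000.0 > 1 + 1e-12:
                raise ValueError("oscillatory protocol requires f*T <= 1 (T in s)")
        if self.kind == "nonoscillatory":
            if self.event_rate is None or self.event_rate < 0:
                raise ValueError("nonoscillatory protocol requires event_rate >= 0")
            if self.event_rate * self.dt / 1000.0 >= 1:
                raise ValueError("event_rate * dt must be < 1")
        # derived stimulated rate must be a valid Bernoulli probability
        lam1 = self.stimulated_rate()
        if lam1 * self.dt / 1000.0 >= 1:
            raise ValueError(
                f"stimulated rate {lam1} /s gives per-step probability >= 1 at dt={self.dt} ms"
            )

    def stimulated_rate(self) -> float:
        """In-event firing rate lambda_1 (spikes/s) implied by the target mean rate."""
        if self.kind == "oscillatory":
            return lambda1_oscillatory(self.rate_mean, self.rate_bg,
                                       self.window_T, self.freq_f)
        if self.kind == "nonoscillatory":
            p0 = p0_nonoscillatory(self.event_rate, self.window_T, self.dt)
            if p0 == 1.0:  # no events ever: homogeneous background firing
                return self.rate_bg
            return lambda1_nonoscillatory(self.rate_mean, self.rate_bg, p0)
        return self.rate_mean


def lambda1_oscillatory(rate_mean: float, rate_bg: float,
                        window_T: float, freq_f: float) -> float:
    """In-event rate for the oscillatory protocol (rates /s, T ms, f Hz).

    Inverts ``lambda = fT lambda_1 + (1 - fT) lambda_0`` (with fT the duty
    cycle, T in seconds), so substituting the result back recovers the mean
    rate exactly.
    """
    fT = freq_f * window_T / 1000.0
    if fT <= 0 or fT > 1 + 1e-12:
        raise ValueError(f"duty cycle f*T must be in (0, 1], got {fT}")
    lam1 = rate_mean / fT - rate_bg * (1.0 / fT - 1.0)
    if lam1 < 0:
        raise ValueError(
            f"derived stimulated rate is negative ({lam1} /s): the target mean "
            f"rate {rate_mean} /s is below the background contribution"
        )
    return lam1


def p0_nonoscillatory(event_rate: float, window_T: float, dt: float) -> float:
    """Probability that a time step lies outside every stimulation event.

    Equals ``(1 - lambda_e dt)^(T/dt)``: no event may have started in any of
    the previous T/dt steps.
    """
    p_start = event_rate * dt / 1000.0
    if not (0 <= p_start < 1):
        raise ValueError(f"per-step event probability must be in [0, 1), got {p_start}")
    n_steps = int(round(window_T / dt))
    return (1.0 - p_start) ** n_steps


def lambda1_nonoscillatory(rate_mean: float, rate_bg: float, p0: float) -> float:
    """In-event rate for the nonoscillatory protocol given the outside-event
    probability p0; inverts ``lambda = (1-p0) lambda_1 + p0 lambda_0``."""
    if not (0 <= p0 < 1):
        raise ValueError(f"p0 must be in [0, 1) (p0 == 1 means no events), got {p0}")
    lam1 = (rate_mean - p0 * rate_bg) / (1.0 - p0)
    if lam1 < 0:
        raise ValueError(f"derived stimulated rate is negative ({lam1} /s)")
    return lam1


def _stimulation_mask(spec: ProtocolSpec, n_steps: int,
                      rng_events: np.random.Generator) -> np.ndarray | None:
    """Boolean per-step mask of stimulated steps (None for the rate kind)."""
    if spec.kind == "rate":
        return None
    if spec.kind == "oscillatory":
        t = np.arange(n_steps) * spec.dt
        period = 1000.0 / spec.freq_f
        return np.mod(t, period) < spec.window_T
    # nonoscillatory: an event starting at step j covers steps j .. j+L-1;
    # overlapping events do not stack
    p_start = spec.event_rate * spec.dt / 1000.0
    starts = rng_events.random(n_steps) < p_start
    L = max(int(round(spec.window_T / spec.dt)), 1)
    cum = np.concatenate([[0], np.cumsum(starts)])
    lo = np.maximum(np.arange(n_steps) - L + 1, 0)
    return (cum[np.arange(n_steps) + 1] - cum[lo]) > 0


def generate_pair(spec: ProtocolSpec) -> tuple[SpikeTrain, SpikeTrain]:
    """Generate a (presynaptic, postsynaptic) spike-train pair.

    Both neurons share the same stimulation-event times; the per-step
    Bernoulli spike draws are independent across neurons and steps.  The
    root seed is split into independent sub-streams for event placement and
    for each neuron, so the event sequence is unchanged by the choice of
    neuron stream.
    """
    n_steps = int(round(spec.duration * 1000.0 / spec.dt))
    ss_events, ss_pre, ss_post = np.random.SeedSequence(spec.seed).spawn(3)
    mask = _stimulation_mask(spec, n_steps, np.random.default_rng(ss_events))
    lam1 = spec.stimulated_rate()
    if mask is None:
        p = np.full(n_steps, spec.rate_mean * spec.dt / 1000.0)
    else:
        p = np.where(mask, lam1 * spec.dt / 1000.0, spec.rate_bg * spec.dt / 1000.0)
    duration_ms = n_steps * spec.dt
    trains = []
    for ss in (ss_pre, ss_post):
        rng = np.random.default_rng(ss)
        idx = np.nonzero(rng.random(n_steps) < p)[0]
        trains.append(SpikeTrain(times=idx * spec.dt, duration=duration_ms))
    return trains[0], trains[1]


def generate_one_spike_per_cycle(freq_f: float, window_T: float, n_cycles: int,
                                 seed: int) -> tuple[SpikeTrain, SpikeTrain]:
    """Idealized oscillatory protocol: exactly one spike per neuron per cycle.

    Postsynaptic spikes fall exactly at i/f (i = 1..n_cycles, in ms:
    i * 1000/f); presynaptic spikes are uniform within +-T/2 around them.
    Used as the Monte-Carlo counterpart of the closed-form triplet analysis.
    """
    period = 1000.0 / freq_f
    if window_T <= 0 or window_T > period:
        raise ValueError("window_T must be in (0, period]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    centers = (np.arange(1, n_cycles + 1)) * period
    jitter = rng.uniform(-window_T / 2.0, window_T / 2.0, size=n_cycles)
    duration = (n_cycles + 1) * period
    pre = SpikeTrain(times=centers + jitter, duration=duration)
    post = SpikeTrain(times=centers.astype(float), duration=duration)
    return pre, post


def synapse_lag(pre_time: float, post_time: float, delay_d: float) -> float:
    """Pair lag at the synaptic site: post - pre - d.

    Soma-synchronous spikes therefore register with lag -d at the synapse
    (positive effective delays push synchronous pairs into the depression
    branch of the kernel).
    """
    return post_time - pre_time - delay_d


# --------------------------------------------------------------------------
# Text I/O: one spike time (ms, 4 decimals) per line; '#' header lines.
# --------------------------------------------------------------------------

def _header_lines(duration: float, meta: dict | None) -> list[str]:
    lines = [f"# duration_ms: {duration!r}"]
    for key in sorted(meta or {}):
        lines.append(f"# {key}: {meta[key]}")
    return lines


def save_spike_train(train: SpikeTrain, path, meta: dict | None = None) -> None:
    lines = _header_lines(train.duration, meta)
    lines.extend(f"{t:.4f}" for t in train.times)
    Path(path).write_text("\n".join(lines) + "\n")


def load_spike_train(path) -> SpikeTrain:
    duration = None
    times = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            body = raw[1:].strip()
            if body.startswith("duration_ms:"):
                duration = float(body.split(":", 1)[1])
        elif raw.strip():
            times.append(float(raw))
    if duration is None:
        raise ValueError("spike-train file lacks a '# duration_ms:' header")
    return SpikeTrain(times=np.array(times), duration=duration)


def save_pair(pre: SpikeTrain, post: SpikeTrain, path,
              meta: dict | None = None) -> None:
    """Write a pair as two-column text: neuron id (0 = pre, 1 = post), time (ms)."""
    if pre.duration != post.duration:
        raise ValueError("pre and post trains must share a duration")
    lines = _header_lines(pre.duration, meta)
    lines.append("# columns: neuron_id\ttime_ms")
    for nid, train in ((0, pre), (1, post)):
        lines.extend(f"{nid}\t{t:.4f}" for t in train.times)
    Path(path).write_text("\n".join(lines) + "\n")


def load_pair(path) -> tuple[SpikeTrain, SpikeTrain]:
    duration = None
    times: dict[int, list[float]] = {0: [], 1: []}
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            body = raw[1:].strip()
            if body.startswith("duration_ms:"):
                duration = float(body.split(":", 1)[1])
        elif raw.strip():
            nid, t = raw.split("\t")
            times[int(nid)].append(float(t))
    if duration is None:
        raise ValueError("pair file lacks a '# duration_ms:' header")
    return (SpikeTrain(times=np.array(times[0]), duration=duration),
            SpikeTrain(times=np.array(times[1]), duration=duration))
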