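"""Recurrent excitatory network of adaptive leaky integrate-and-fire neurons.

The model is a population of conductance-based adaptive integrate-and-fire
(AdIF) units coupled by excitatory synapses with random connectivity and
driven by external Poisson input. Each neuron obeys

    C_m dV/dt   = g_L (E_L - V) + g_e (E_e - V) - w
    tau_w dw/dt = a (V - E_L) - w
    tau_e dg_e/dt = -g_e

with reset conditions on threshold crossing (V >= V_th):

    V -> V_r,   w -> w + b,   g_e,j -> g_e,j + w_e  for every target j.

Internally all quantities are held in pF / nS / mV / pA / ms; spike rasters
are reported in seconds. Integration is forward Euler for V and w at the
configured step, with the synaptic conductance decayed by its exact
exponential factor each step.

Two interchangeable integrator back ends are provided: a numba-compiled
production kernel (``method="fast"``) and a plain-numpy reference loop
(``method="reference"``) built from the step-level operations below. The
two share the same update order and serve as mutual cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from numba.typed import List as NumbaList

from .errors import (
    InvalidConfigError,
    NumericFailureError,
    SimulationRunawayError,
)

__all__ = [
    "NeuronParameters",
    "NetworkConfig",
    "ConnectivityGraph",
    "NetworkState",
    "SpikeRaster",
    "build_connectivity",
    "group_into_electrodes",
    "draw_external_drive",
    "integrate_step",
    "apply_resets",
    "simulate",
]


@dataclass(frozen=True)
class NeuronParameters:
    """Single-neuron constants of the AdIF model.

    Parameters
    ----------
    C_m : membrane capacitance (pF).
    g_L : leak conductance (nS).
    E_L : resting (leak reversal) potential (mV).
    E_e : excitatory reversal potential (mV).
    V_th : spike threshold (mV).
    V_r : post-spike reset potential (mV).
    tau_w : adaptation time constant (ms).
    a : subthreshold adaptation conductance (nS).
    b : spike-triggered adaptation increment (pA).
    tau_e : excitatory synaptic decay time constant (ms).
    w_e : recurrent synaptic weight — conductance increment per
        presynaptic spike (nS).
    """

    C_m: float = 80.0
    g_L: float = 4.0
    E_L: float = -65.0
    E_e: float = 0.0
    V_th: float = -50.0
    V_r: float = -60.0
    tau_w: float = 1000.0
    a: float = 4.0
    b: float = 350.0
    tau_e: float = 5.0
    w_e: float = 0.3

    def __post_init__(self):
        if not (self.C_m > 0 and self.g_L > 0 and self.tau_w > 0 and self.tau_e > 0):
            raise InvalidConfigError("C_m, g_L, tau_w, tau_e must be positive")
        if not self.V_r < self.V_th:
            raise InvalidConfigError("reset potential must lie below threshold")
        if not self.E_L < self.V_th:
            raise InvalidConfigError("resting potential must lie below threshold")
        if not self.E_e > self.V_th:
            raise InvalidConfigError("excitatory reversal must lie above threshold")
        if self.a < 0 or self.b < 0 or self.w_e < 0:
            raise InvalidConfigError("a, b and w_e must be non-negative")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m / g_L (ms)."""
        return self.C_m / self.g_L


@dataclass(frozen=True)
class NetworkConfig:
    """Network- and run-level configuration.

    ``w_ext`` is the conductance increment per external event; ``None``
    means "use the recurrent weight w_e". ``scale_recurrent_weight``
    rescales w_e by 999 / (n-1) so that the expected summed recurrent
    conductance per neuron at any given connection probability matches the
    full-size 1000-neuron network when running reduced populations; it
    compensates population size only (the connection probability remains a
    live variable, as the connectivity scans require) and is a no-op at
    full size. ``v_init_jitter`` is the SD (mV) of an optional
    Gaussian jitter on the initial membrane potential (0 = all start at
    E_L).
    """

    n_neurons: int = 1000
    connection_probability: float = 0.05
    n_ext_synapses: int = 100
    ext_rate: float = 20.0
    w_ext: float | None = None
    duration: float = 300.0
    dt: float = 0.1
    seed: int = 0
    scale_recurrent_weight: bool = True
    v_init_jitter: float = 0.0
    max_mean_rate: float = 250.0  # Hz; spike budget guarding against runaway

    REFERENCE_N = 1000  # population size the synaptic weights are stated for

    def __post_init__(self):
        if self.n_neurons < 1:
            raise InvalidConfigError("n_neurons must be >= 1")
        if not 0.0 <= self.connection_probability <= 1.0:
            raise InvalidConfigError("connection_probability must lie in [0, 1]")
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidConfigError("duration and dt must be positive")
        if self.ext_rate < 0 or self.n_ext_synapses < 0:
            raise InvalidConfigError("external drive rate/count must be >= 0")
        if self.v_init_jitter < 0:
            raise InvalidConfigError("v_init_jitter must be >= 0")

    @property
    def n_steps(self) -> int:
        """Number of integration steps; duration must be a near-integer
        multiple of dt."""
        steps = self.duration * 1000.0 / self.dt
        if abs(steps - round(steps)) > 1e-6:
            raise InvalidConfigError(
                f"duration ({self.duration} s) is not an integer multiple of "
                f"dt ({self.dt} ms)"
            )
        return int(round(steps))

    @property
    def spike_budget(self) -> int:
        """Total spikes allowed before a run is declared runaway."""
        return int(self.n_neurons * self.duration * self.max_mean_rate)

    def effective_w_e(self, params: NeuronParameters) -> float:
        if not self.scale_recurrent_weight or self.n_neurons < 2:
            return params.w_e
        return params.w_e * (self.REFERENCE_N - 1) / (self.n_neurons - 1)

    def effective_w_ext(self, params: NeuronParameters) -> float:
        return params.w_e if self.w_ext is None else self.w_ext


@dataclass(frozen=True)
class ConnectivityGraph:
    """Directed connectivity in CSR layout keyed by presynaptic index.

    ``indices[indptr[i]:indptr[i+1]]`` are the postsynaptic targets of
    neuron i. No self-edges.
    """

    n_neurons: int
    indptr: np.ndarray
    indices: np.ndarray

    def targets(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def n_edges(self) -> int:
        return int(self.indices.size)

    @property
    def out_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def mean_out_degree(self) -> float:
        return self.n_edges / self.n_neurons


@dataclass
class NetworkState:
    """Mutable per-neuron state carried between integration steps."""

    V: np.ndarray  # mV
    g_e: np.ndarray  # nS
    w: np.ndarray  # pA
    t: float = 0.0  # ms

    @classmethod
    def initial(
        cls,
        n: int,
        params: NeuronParameters,
        v_jitter: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> "NetworkState":
        V = np.full(n, params.E_L, dtype=np.float64)
        if v_jitter > 0:
            if rng is None:
                rng = np.random.default_rng()
            V = V + rng.normal(0.0, v_jitter, size=n)
            V = np.minimum(V, params.V_th - 1e-9)
        return cls(V=V, g_e=np.zeros(n), w=np.zeros(n), t=0.0)

    def copy(self) -> "NetworkState":
        return NetworkState(self.V.copy(), self.g_e.copy(), self.w.copy(), self.t)


@dataclass(frozen=True)
class SpikeRaster:
    """Per-source spike-time lists (seconds) with duration and provenance.

    ``kind`` tags whether sources are simulated neurons or MEA electrodes.
    """

    source_ids: tuple
    spike_times: tuple  # tuple of 1-D float arrays, seconds, sorted
    duration: float
    kind: str = "simulated-neuron"

    def __post_init__(self):
        if len(self.source_ids) != len(self.spike_times):
            raise InvalidConfigError("source ids and spike-time lists differ in length")
        for times in self.spike_times:
            if times.size and (times.min() < 0 or times.max() > self.duration + 1e-9):
                raise InvalidConfigError("spike times outside [0, duration]")

    @property
    def n_sources(self) -> int:
        return len(self.source_ids)

    @property
    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spike_times])

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def rates(self) -> np.ndarray:
        """Mean firing rate per source (Hz)."""
        return self.counts / self.duration

    @classmethod
    def from_events(
        cls,
        source_of_event: np.ndarray,
        time_of_event: np.ndarray,
        n_sources: int,
        duration: float,
        kind: str = "simulated-neuron",
    ) -> "SpikeRaster":
        order = np.lexsort((time_of_event, source_of_event))
        src = np.asarray(source_of_event)[order]
        tim = np.asarray(time_of_event, dtype=np.float64)[order]
        bounds = np.searchsorted(src, np.arange(n_sources + 1))
        trains = tuple(tim[bounds[k] : bounds[k + 1]] for k in range(n_sources))
        return cls(
            source_ids=tuple(range(n_sources)),
            spike_times=trains,
            duration=duration,
            kind=kind,
        )


def group_into_electrodes(
    raster: SpikeRaster, n_electrodes: int = 64, seed: int = 0
) -> SpikeRaster:
    """Merge simulated-neuron trains into multiunit electrode channels.

    Neurons are assigned to electrodes in a random balanced partition and
    their spike times merged per channel, mimicking how an extracellular
    electrode records the overlapping units around it (the model analogue
    of a 64-channel MEA well). Deterministic given seed.
    """
    if n_electrodes < 1 or n_electrodes > raster.n_sources:
        raise InvalidConfigError(
            "n_electrodes must lie in [1, number of sources]"
        )
    rng = np.random.default_rng(seed)
    assign = rng.permutation(raster.n_sources) % n_electrodes
    trains = []
    for e in range(n_electrodes):
        members = [raster.spike_times[i] for i in np.nonzero(assign == e)[0]]
        merged = (
            np.unique(np.concatenate(members)) if members else np.empty(0)
        )
        trains.append(merged)
    return SpikeRaster(
        source_ids=tuple(range(n_electrodes)),
        spike_times=tuple(trains),
        duration=raster.duration,
        kind="electrode",
    )


def build_connectivity(
    n_neurons: int, connection_probability: float, seed: int
) -> ConnectivityGraph:
    """Draw a random directed graph: each ordered pair (i, j), i != j, is an
    edge independently with the given probability. Deterministic given seed.
    """
    if not 0.0 <= connection_probability <= 1.0:
        raise InvalidConfigError("connection_probability must lie in [0, 1]")
    if n_neurons < 1:
        raise InvalidConfigError("n_neurons must be >= 1")
    rng = np.random.default_rng(seed)
    indptr = np.zeros(n_neurons + 1, dtype=np.int64)
    rows = []
    block = 256  # bound the Bernoulli matrix held at once
    for start in range(0, n_neurons, block):
        stop = min(start + block, n_neurons)
        mask = rng.random((stop - start, n_neurons)) < connection_probability
        for i in range(start, stop):
            mask[i - start, i] = False  # no self-edges
        for i in range(start, stop):
            tgt = np.nonzero(mask[i - start])[0].astype(np.int32)
            rows.append(tgt)
            indptr[i + 1] = indptr[i] + tgt.size
    indices = (
        np.concatenate(rows) if rows else np.empty(0, dtype=np.int32)
    )
    return ConnectivityGraph(n_neurons=n_neurons, indptr=indptr, indices=indices)


def draw_external_drive(
    config: NetworkConfig, rng: np.random.Generator, n_steps: int = 1
) -> np.ndarray:
    """Per-neuron external event counts for one or more steps.

    Each neuron receives ``n_ext_synapses`` independent Poisson trains at
    ``ext_rate`` Hz; per step the summed count is Poisson with mean
    n_ext_synapses * ext_rate * dt. Returns shape (n_steps, n_neurons).
    """
    lam = config.n_ext_synapses * config.ext_rate * (config.dt * 1e-3)
    return rng.poisson(lam, size=(n_steps, config.n_neurons))


def integrate_step(
    state: NetworkState, params: NeuronParameters, dt: float
) -> NetworkState:
    """One forward-Euler step of V and w plus exact exponential decay of
    g_e. Resets are NOT applied here (see ``apply_resets``)."""
    if dt <= 0:
        raise InvalidConfigError("dt must be positive")
    bad = ~(
        np.isfinite(state.V) & np.isfinite(state.g_e) & np.isfinite(state.w)
    )
    if bad.any():
        raise NumericFailureError(int(np.argmax(bad)), state.t)
    V, g_e, w = state.V, state.g_e, state.w
    dV = (params.g_L * (params.E_L - V) + g_e * (params.E_e - V) - w) / params.C_m
    dw = (params.a * (V - params.E_L) - w) / params.tau_w
    V_new = V + dt * dV
    w_new = w + dt * dw
    g_new = g_e * math.exp(-dt / params.tau_e)
    return NetworkState(V=V_new, g_e=g_new, w=w_new, t=state.t + dt)


def apply_resets(
    state: NetworkState,
    params: NeuronParameters,
    graph: ConnectivityGraph,
    w_e: float | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Detect threshold crossings and apply the reset rules in place.

    Every neuron with V >= V_th emits a spike: V -> V_r, w -> w + b, and
    each of its postsynaptic targets gains w_e of conductance (increments
    from multiple presynaptic spikers in the same step accumulate).
    Returns the (possibly new) state and the array of spiker indices.
    """
    if w_e is None:
        w_e = params.w_e
    spikers = np.nonzero(state.V >= params.V_th)[0]
    if spikers.size == 0:
        return state, spikers
    out = state.copy()
    out.V[spikers] = params.V_r
    out.w[spikers] += params.b
    if w_e > 0:
        all_targets = np.concatenate(
            [graph.targets(int(i)) for i in spikers]
        )
        np.add.at(out.g_e, all_targets, w_e)
    return out, spikers


@njit(cache=True)
def _adif_kernel(
    indptr,
    indices,
    n_neurons,
    n_steps,
    dt,
    C_m,
    g_L,
    E_L,
    E_e,
    V_th,
    V_r,
    tau_w,
    a,
    b,
    tau_e,
    w_e,
    lam_ext,
    w_ext,
    V0,
    seed,
    max_spikes,
    spike_src,
    spike_t,
):
    """Fused simulation loop. Returns -1 on success, -2 when the spike
    budget is exceeded (runaway), or the index of the first neuron whose
    state became non-finite."""
    np.random.seed(seed)
    V = V0.copy()
    g_e = np.zeros(n_neurons)
    w = np.zeros(n_neurons)
    decay = math.exp(-dt / tau_e)
    for step in range(n_steps):
        # external Poisson drive
        if lam_ext > 0.0 and w_ext > 0.0:
            for i in range(n_neurons):
                k = np.random.poisson(lam_ext)
                if k > 0:
                    g_e[i] += w_ext * k
        # forward Euler for V, w; exact decay for g_e
        for i in range(n_neurons):
            v = V[i]
            dV = (g_L * (E_L - v) + g_e[i] * (E_e - v) - w[i]) / C_m
            dw = (a * (v - E_L) - w[i]) / tau_w
            V[i] = v + dt * dV
            w[i] = w[i] + dt * dw
            g_e[i] = g_e[i] * decay
            if not (
                math.isfinite(V[i]) and math.isfinite(w[i]) and math.isfinite(g_e[i])
            ):
                return i
        # threshold crossings and resets; same-step synaptic delivery
        t_now = (step + 1) * dt
        for i in range(n_neurons):
            if V[i] >= V_th:
                V[i] = V_r
                w[i] += b
                spike_src.append(i)
                spike_t.append(t_now)
                for k in range(indptr[i], indptr[i + 1]):
                    g_e[indices[k]] += w_e
        if len(spike_t) > max_spikes:
            return -2
    return -1


def _simulate_reference(
    config: NetworkConfig,
    params: NeuronParameters,
    graph: ConnectivityGraph,
    w_e: float,
    w_ext: float,
) -> SpikeRaster:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    state = NetworkState.initial(
        config.n_neurons, params, config.v_init_jitter, rng
    )
    src: list[int] = []
    tms: list[float] = []
    lam = config.n_ext_synapses * config.ext_rate * (config.dt * 1e-3)
    drive_on = lam > 0 and w_ext > 0
    for step in range(config.n_steps):
        if drive_on:
            counts = rng.poisson(lam, size=config.n_neurons)
            state.g_e += w_ext * counts
        state = integrate_step(state, params, config.dt)
        state, spikers = apply_resets(state, params, graph, w_e=w_e)
        if spikers.size:
            t_now = state.t
            for i in spikers:
                src.append(int(i))
                tms.append(t_now)
            if len(tms) > config.spike_budget:
                raise SimulationRunawayError(len(tms), t_now)
    return SpikeRaster.from_events(
        np.array(src, dtype=np.int64),
        np.array(tms) * 1e-3,
        config.n_neurons,
        config.duration,
    )


def simulate(
    config: NetworkConfig,
    params: NeuronParameters,
    graph: ConnectivityGraph | None = None,
    method: str = "fast",
) -> SpikeRaster:
    """Run the network for ``config.duration`` seconds and return the raster.

    Deterministic (bit-reproducible) for a given (config, params, method).
    ``method="fast"`` uses the numba kernel; ``method="reference"`` loops
    the step-level operations in plain numpy (slower, independent code
    path used for cross-validation). The two back ends consume different
    random streams, so they agree statistically, not sample-for-sample.
    """
    n_steps = config.n_steps  # validates duration/dt ratio
    if graph is None:
        graph = build_connectivity(
            config.n_neurons, config.connection_probability, config.seed
        )
    w_e = config.effective_w_e(params)
    w_ext = config.effective_w_ext(params)
    if method == "reference":
        return _simulate_reference(config, params, graph, w_e, w_ext)
    if method != "fast":
        raise InvalidConfigError(f"unknown simulate method: {method!r}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    state0 = NetworkState.initial(
        config.n_neurons, params, config.v_init_jitter, rng
    )
    # typed lists for the kernel's growing spike record; seed with one
    # element then pop so numba can infer the element types
    spike_src = NumbaList()
    spike_src.append(np.int64(0))
    spike_src.pop()
    spike_t = NumbaList()
    spike_t.append(0.0)
    spike_t.pop()
    lam = config.n_ext_synapses * config.ext_rate * (config.dt * 1e-3)
    kernel_seed = int(config.seed) % (2**32 - 1)
    bad = _adif_kernel(
        graph.indptr,
        graph.indices,
        config.n_neurons,
        n_steps,
        config.dt,
        params.C_m,
        params.g_L,
        params.E_L,
        params.E_e,
        params.V_th,
        params.V_r,
        params.tau_w,
        params.a,
        params.b,
        params.tau_e,
        w_e,
        lam,
        w_ext,
        state0.V,
        kernel_seed,
        config.spike_budget,
        spike_src,
        spike_t,
    )
    if bad == -2:
        t_last = spike_t[-1] if len(spike_t) else 0.0
        raise SimulationRunawayError(len(spike_t), t_last)
    if bad >= 0:
        raise NumericFailureError(bad, float("nan"))
    src = np.array(spike_src, dtype=np.int64) if len(spike_src) else np.empty(0, np.int64)
    tms = np.array(spike_t) if len(spike_t) else np.empty(0)
    return SpikeRaster.from_events(
        src, tms * 1e-3, config.n_neurons, config.duration
    )
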