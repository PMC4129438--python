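"""Directed Erdos-Renyi networks of excitatory bursting neurons, with the
deletion and focal-stimulation protocols and the (n, p) parameter sweep.

The population is modeled as a G(n, p) directed random graph (each ordered
pair linked independently with probability p, no self-loops) whose vertices
carry group-pacemaker burster neurons (:mod:`ablatio.burster`) coupled by
excitatory synapses on the directed edges.  Integration is fixed-step RK4 at
0.25 ms.  The protocols mirror the simulated-ablation study design:

* **deletion** — a neuron is removed by zeroing its synaptic activation and
  freezing its dynamics; its spikes no longer enter rasters or histograms.
  The deletion experiment applies random deletions (uniform, without
  replacement) one every 25 s and locates the cessation tally: the tally
  after which no further network burst occurs.
* **focal stimulation** — the synaptic activation of a chosen subset is
  clamped to 0.9 for 200 ms (dynamics untouched, so excitation is transient),
  emulating glutamate un-caging; a handful of stimulated cells suffices to
  evoke a network-wide burst in a rhythmic network.
* **sweep** — n x p grid of short no-deletion runs scoring the fraction of
  rhythmic realizations and the mean cycle period, flagging cells in which
  >= 80% of realizations are respiratory-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import rhythm
from .burster import NeuronParams, draw_population, run_segment

__all__ = [
    "DirectedGraph",
    "Network",
    "SimConfig",
    "SimulationTrace",
    "er_graph",
    "build_network",
    "integrate",
    "delete_neuron",
    "focal_stimulate",
    "run_deletion_experiment",
    "sweep",
    "SweepResult",
]

HIST_BIN_MS = 10.0
DELETION_INTERVAL_S = 25.0
STIM_CLAMP = 0.9
STIM_DURATION_MS = 200.0
RESPIRATORY_PERIOD_RANGE_S = (3.0, 4.0)


@dataclass
class DirectedGraph:
    """Adjacency ``A[i, j] == 1`` iff there is a synapse from i to j."""

    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = A.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


def er_graph(n: int, p: float, seed=None) -> DirectedGraph:
    """Directed G(n, p): each ordered pair (i, j), i != j, linked
    independently with probability p.  Deterministic per seed."""
    if n < 1:
        raise ValueError("need at least one vertex")
    if not 0 <= p <= 1:
        raise ValueError("connection probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    return DirectedGraph(A)


class Network:
    """A directed graph populated with burster neurons; holds the full
    dynamical state and the alive/stimulated masks."""

    def __init__(self, graph: DirectedGraph, params: NeuronParams | None = None,
                 weight_scale: float = 1.0, seed=None):
        self.graph = graph
        self.params = params or NeuronParams()
        rng = np.random.default_rng(seed)
        n = graph.n
        pop = draw_population(n, self.params, rng)
        self.cell = pop["cell"]
        self.state = pop["state"]
        self.alive = np.ones(n, dtype=np.bool_)
        self.stim = np.zeros(n, dtype=np.bool_)
        self.last_spike_ms = np.full(n, -1e9)
        self.g_bg = np.zeros(n)          # background EPSP conductance
        self._noise_rng = np.random.default_rng(rng.integers(2**31 - 1))
        self.t_ms = 0.0

        # in-edge CSR: presynaptic indices per neuron, with per-edge weights
        A = graph.adjacency
        pre_lists = [np.flatnonzero(A[:, i]) for i in range(n)]
        counts = np.array([len(x) for x in pre_lists])
        self.pre_ptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self.pre_idx = (np.concatenate(pre_lists) if counts.sum() else
                        np.empty(0, dtype=np.int64)).astype(np.int64)
        h = self.params.hetero
        self.w = (self.params.w_syn * weight_scale
                  * rng.uniform(1 - h, 1 + h, self.pre_idx.size))

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def _draw_noise_events(self, duration_ms: float):
        """Background EPSP events for the next segment, drawn in continuous
        time (independent of the integration step) from the seeded stream."""
        rate = self.params.noise_rate_hz
        if rate <= 0:
            return None
        lam = rate * self.n * duration_ms / 1000.0
        k = self._noise_rng.poisson(lam)
        t = np.sort(self.t_ms + self._noise_rng.uniform(0, duration_ms, k))
        cells = self._noise_rng.integers(0, self.n, k)
        return t, cells.astype(np.int64)

    def advance(self, duration_ms: float, dt_ms: float = 0.25):
        """Integrate for ``duration_ms``; returns (spike_times_ms, ids) of
        alive neurons."""
        n_steps = int(round(duration_ms / dt_ms))
        if n_steps == 0:
            return np.empty(0), np.empty(0, dtype=np.int32)
        t, ids = run_segment(self.state, self.alive, self.stim, self.pre_idx,
                             self.pre_ptr, self.w, self.g_bg, self.cell,
                             self.params.scalar_vector(), dt_ms, n_steps,
                             self.t_ms, self.last_spike_ms,
                             noise_events=self._draw_noise_events(n_steps * dt_ms),
                             noise_amp_ns=self.params.noise_amp_ns)
        self.t_ms += n_steps * dt_ms
        return t, ids


def build_network(graph: DirectedGraph, params: NeuronParams | None = None,
                  weight_scale: float = 1.0, seed=None) -> Network:
    """One dynamical unit per vertex; every directed edge carries an
    excitatory synapse driven by the presynaptic activation s."""
    return Network(graph, params=params, weight_scale=weight_scale, seed=seed)


def delete_neuron(network: Network, neuron_id: int, time_s: float | None = None):
    """Remove a cell from the network: its synaptic activation is set to zero
    and its dynamics frozen; it no longer spikes nor drives its targets."""
    if not network.alive[neuron_id]:
        warnings.warn(f"neuron {neuron_id} is already deleted; no-op")
        return network
    network.alive[neuron_id] = False
    network.state[2, neuron_id] = 0.0
    network.stim[neuron_id] = False
    return network


def focal_stimulate(network: Network, ids, clamp: float = STIM_CLAMP):
    """Clamp the synaptic activation of ``ids`` (all alive) to ``clamp``.
    Call :func:`release_stimulation` (or use :func:`integrate` with
    stimulation events) to end the pulse."""
    ids = np.atleast_1d(np.asarray(ids, dtype=int))
    if ids.size == 0:
        return network
    if not network.alive[ids].all():
        raise ValueError("cannot stimulate a deleted neuron")
    network.stim[ids] = True
    network.state[2, ids] = clamp
    return network


def release_stimulation(network: Network):
    network.stim[:] = False
    return network


@dataclass
class SimConfig:
    duration_s: float = 25.0
    dt_ms: float = 0.25
    seed: int | None = None
    deletions: list = field(default_factory=list)      # (time_s, neuron_id)
    stimulations: list = field(default_factory=list)   # (onset_s, ids, duration_ms, clamp)
    keep_spikes: bool = True

    def validate(self):
        if self.dt_ms <= 0:
            raise ValueError("time step must be positive")
        if self.duration_s < 0:
            raise ValueError("duration must be non-negative")


@dataclass
class SimulationTrace:
    """Spike raster (alive-period spikes only), 10-ms spikes-per-bin
    histogram, and the event logs."""

    spike_times_s: np.ndarray
    spike_ids: np.ndarray
    histogram: np.ndarray
    bin_width_s: float
    t0_s: float
    duration_s: float
    deletion_log: list = field(default_factory=list)
    stimulation_log: list = field(default_factory=list)

    def bursts(self, **kwargs) -> rhythm.BurstSeries:
        return rhythm.detect_bursts(self.histogram, bin_width_s=self.bin_width_s,
                                    t0_s=self.t0_s, **kwargs)


def integrate(network: Network, config: SimConfig) -> SimulationTrace:
    """Run the event schedule (deletions, stimulation windows) with fixed-step
    RK4, accumulating the spike raster and the 10-ms histogram."""
    config.validate()
    t0_s = network.t_ms / 1000.0
    horizon_ms = network.t_ms + config.duration_s * 1000.0
    bin_ms = HIST_BIN_MS
    n_bins = int(np.ceil(config.duration_s * 1000.0 / bin_ms)) if config.duration_s else 0
    hist = np.zeros(n_bins)
    all_t, all_i = [], []
    del_log, stim_log = [], []

    network_t0_ms = network.t_ms

    # ordered event list: (absolute time_ms, kind, payload); event times in
    # the config are relative to the start of this call
    events = []
    for t_s, nid in config.deletions:
        events.append((network_t0_ms + t_s * 1000.0, 0, nid))
    for ev in config.stimulations:
        onset_s, ids = ev[0], ev[1]
        dur = ev[2] if len(ev) > 2 else STIM_DURATION_MS
        clamp = ev[3] if len(ev) > 3 else STIM_CLAMP
        events.append((network_t0_ms + onset_s * 1000.0, 1, (ids, clamp)))
        events.append((network_t0_ms + onset_s * 1000.0 + dur, 2, None))
    events.sort(key=lambda e: (e[0], e[1]))

    def record(times_ms, ids):
        if times_ms.size == 0:
            return
        if config.keep_spikes:
            all_t.append(times_ms)
            all_i.append(ids)
        b = ((times_ms - network_t0_ms) // bin_ms).astype(np.int64)
        np.add.at(hist, b[b < n_bins], 1)

    for t_ev, kind, payload in events:
        if t_ev > horizon_ms:
            break
        seg = t_ev - network.t_ms
        if seg > 0:
            record(*network.advance(seg, config.dt_ms))
        if kind == 0:
            delete_neuron(network, payload)
            del_log.append((network.t_ms / 1000.0, int(payload)))
        elif kind == 1:
            ids, clamp = payload
            focal_stimulate(network, ids, clamp=clamp)
            stim_log.append((network.t_ms / 1000.0, list(np.atleast_1d(ids))))
        else:
            release_stimulation(network)
    if horizon_ms > network.t_ms:
        record(*network.advance(horizon_ms - network.t_ms, config.dt_ms))

    if all_t:
        st = np.concatenate(all_t) / 1000.0
        si = np.concatenate(all_i)
    else:
        st, si = np.empty(0), np.empty(0, dtype=np.int32)
    return SimulationTrace(
        spike_times_s=st, spike_ids=si, histogram=hist,
        bin_width_s=bin_ms / 1000.0, t0_s=t0_s, duration_s=config.duration_s,
        deletion_log=del_log, stimulation_log=stim_log)


@dataclass
class DeletionExperiment:
    trace_histogram: np.ndarray
    bin_width_s: float
    deletion_log: list           # (tally, time_s, neuron_id)
    cessation_tally: int | None  # None if rhythm survived every deletion
    windows: list                # per-window (tally, n_bursts, mean_period_s)


def run_deletion_experiment(
    network: Network,
    n_deletions: int = 100,
    interval_s: float = DELETION_INTERVAL_S,
    seed=None,
    dt_ms: float = 0.25,
    lead_in_s: float | None = None,
    stop_after_quiet_windows: int | None = None,
) -> DeletionExperiment:
    """Random sequential deletions, one every ``interval_s`` (default 25 s).

    Deletion order is uniform without replacement among initially alive
    neurons.  The cessation tally is the tally after which no network burst
    occurs in any subsequent inter-deletion window through the end of the
    run.  ``stop_after_quiet_windows`` enables early stopping once that many
    consecutive windows are burst-free (the tally is already determined).
    ``lead_in_s`` (default one interval) is simulated before the first
    deletion to establish the baseline rhythm.
    """
    if n_deletions > network.n_alive:
        raise ValueError("cannot delete more neurons than are alive")
    if interval_s <= 0:
        raise ValueError("deletion interval must be positive")
    rng = np.random.default_rng(seed)
    order = rng.choice(np.flatnonzero(network.alive), size=n_deletions,
                       replace=False)
    if lead_in_s is None:
        lead_in_s = interval_s

    hists = []
    windows = []
    del_log = []
    last_bursting_tally = -1
    quiet_run = 0
    burst_threshold = None  # fixed from the baseline window (see below)

    def run_window(tally, duration_s):
        nonlocal last_bursting_tally, quiet_run, burst_threshold
        cfg = SimConfig(duration_s=duration_s, dt_ms=dt_ms, keep_spikes=False)
        tr = integrate(network, cfg)
        hists.append(tr.histogram)
        bursts = tr.bursts(threshold=burst_threshold)
        if burst_threshold is None and len(bursts) > 0:
            # anchor the burst criterion to the pre-deletion rhythm: a
            # per-window adaptive threshold would mistake the background of
            # a silent window for one long "burst"
            burst_threshold = 0.3 * float(np.median(bursts.amplitudes))
        if len(bursts) > 0:
            last_bursting_tally = tally
            quiet_run = 0
        else:
            quiet_run += 1
        mp = float(np.mean(bursts.periods)) if len(bursts) > 1 else np.nan
        windows.append((tally, len(bursts), mp))

    run_window(0, lead_in_s)
    stopped_early = False
    for k, nid in enumerate(order, start=1):
        delete_neuron(network, int(nid))
        del_log.append((k, network.t_ms / 1000.0, int(nid)))
        run_window(k, interval_s)
        if (stop_after_quiet_windows is not None
                and quiet_run >= stop_after_quiet_windows):
            stopped_early = True
            break

    # cessation tally: the tally after which no further network burst
    # occurred (0 if the network was never rhythmic); None if still bursting
    if stopped_early or last_bursting_tally < len(del_log):
        cessation = max(0, last_bursting_tally + 1)
    else:
        cessation = None
    return DeletionExperiment(
        trace_histogram=np.concatenate(hists), bin_width_s=HIST_BIN_MS / 1000.0,
        deletion_log=del_log, cessation_tally=cessation, windows=windows)


@dataclass
class SweepResult:
    n_values: np.ndarray
    p_values: np.ndarray
    rhythmic_fraction: np.ndarray   # (len(n), len(p))
    mean_period_s: np.ndarray
    asterisk: np.ndarray            # respiratory-like in >= 80% of realizations

    def records(self):
        out = []
        for i, nv in enumerate(self.n_values):
            for j, pv in enumerate(self.p_values):
                out.append({
                    "n": int(nv), "p": float(pv),
                    "rhythmic_fraction": float(self.rhythmic_fraction[i, j]),
                    "mean_period_s": float(self.mean_period_s[i, j]),
                    "asterisk": bool(self.asterisk[i, j]),
                })
        return out


def _realization_period(n, p, params, weight_scale, duration_s, dt_ms, seed):
    g = er_graph(n, p, seed=seed)
    net = build_network(g, params=params, weight_scale=weight_scale,
                        seed=seed + 1)
    tr = integrate(net, SimConfig(duration_s=duration_s, dt_ms=dt_ms,
                                  keep_spikes=False))
    bursts = tr.bursts()
    if len(bursts) < 3:
        return np.nan
    return float(np.mean(bursts.periods))


def sweep(
    n_values=range(200, 401, 10),
    p_values=np.arange(0.1, 0.2 + 1e-9, 0.0125),
    reps: int = 10,
    duration_s: float = 25.0,
    params: NeuronParams | None = None,
    weight_scale: float = 1.0,
    dt_ms: float = 0.25,
    seed=0,
    period_range_s: tuple = RESPIRATORY_PERIOD_RANGE_S,
) -> SweepResult:
    """(n, p) grid of no-deletion runs.

    Per cell: the fraction of rhythmic realizations (>= 3 bursts in
    ``duration_s``), the mean cycle period over rhythmic realizations, and an
    asterisk flag marking cells whose realizations produced respiratory-like
    periods (within ``period_range_s``) in at least 80% of cases.  The default
    grid replicates n = 200..400 step 10, p = 0.1..0.2 step 0.0125 at 10
    repetitions; tests and desk runs use reduced grids.
    """
    n_values = np.asarray(list(n_values), dtype=int)
    p_values = np.asarray(list(p_values), dtype=float)
    if n_values.size == 0 or p_values.size == 0 or reps < 1:
        raise ValueError("sweep grid must be non-empty")
    rng = np.random.default_rng(seed)
    frac = np.zeros((n_values.size, p_values.size))
    period = np.full((n_values.size, p_values.size), np.nan)
    star = np.zeros((n_values.size, p_values.size), dtype=bool)
    for i, nv in enumerate(n_values):
        for j, pv in enumerate(p_values):
            periods = [
                _realization_period(int(nv), float(pv), params, weight_scale,
                                    duration_s, dt_ms,
                                    int(rng.integers(2**31 - 2)))
                for _ in range(reps)
            ]
            periods = np.array(periods)
            rhythmic = np.isfinite(periods)
            frac[i, j] = rhythmic.mean()
            if rhythmic.any():
                period[i, j] = periods[rhythmic].mean()
            resp = (rhythmic
                    & (periods >= period_range_s[0])
                    & (periods <= period_range_s[1]))
            star[i, j] = resp.mean() >= 0.8
    return SweepResult(n_values, p_values, frac, period, star)
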