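"""Group-pacemaker burster neuron and the fixed-step RK4 network kernel.

Each vertex of the network carries a conductance-based model neuron in the
group-pacemaker tradition: rhythmic bursting is a network property, not a
cellular one.  The membrane carries

* fast spiking currents ``I_Na`` (instantaneous activation ``m_inf**3``, with
  ``1 - n`` standing in for inactivation) and ``I_K`` (``n**4``), the classic
  reduced formulation for medullary interneurons;
* an ohmic leak plus a small heterogeneous tonic excitatory conductance, so a
  minority of cells fire tonically at low rate and seed network bursts;
* a calcium-activated nonspecific cation current ``I_CAN`` gated by an
  intracellular Ca pool that is charged by synaptic drive — the synaptically
  triggered inward current that amplifies recurrent excitation into an
  all-or-none population burst;
* excitatory synapses: each directed edge transmits the presynaptic
  activation ``s`` scaled by an activity-dependent depression factor ``d``.
  ``s`` rises at spikes and decays in ~10 ms; ``d`` depletes with every spike
  and recovers over seconds, terminating bursts and setting the interburst
  recovery that paces the ~4 s network rhythm.

State per neuron: ``(V, n, s, d, ca)``.  Deleted neurons have ``s = 0`` with
all derivatives frozen (removing the cell from the network); stimulated
neurons have ``s`` clamped (default 0.9) with its own dynamics untouched, so
the excitation is transient.

Each cell additionally receives a sparse background of unitary excitatory
events (independent Poisson trains, default a few Hz per cell) standing in
for spontaneous synaptic bombardment.  Event times are drawn in continuous
time from the network's seeded generator, so a realization is fully
deterministic for a fixed seed and independent of the integration step; with
the rate set to zero the model is strictly deterministic.

Integration is classical fixed-step fourth-order Runge-Kutta (default step
0.25 ms); spikes are upward crossings of -10 mV with a 2 ms refractory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["NeuronParams", "nominal_params", "draw_population", "run_segment"]

SPIKE_THRESHOLD_MV = -10.0
REFRACTORY_MS = 2.0

# indices into the scalar-parameter vector handed to the kernel
_E_NA, _E_K, _E_SYN, _E_CAN = 0, 1, 2, 3
_TH_M, _SIG_M, _TH_N, _SIG_N, _TAU_N = 4, 5, 6, 7, 8
_CM, _TH_S, _SIG_S, _ALPHA_S, _TAU_S = 9, 10, 11, 12, 13
_K_D, _TAU_D, _K_CA, _TAU_CA, _K_CAN = 14, 15, 16, 17, 18
_N_SCALAR = 19


@dataclass
class NeuronParams:
    """Nominal parameters (conductances nS, potentials mV, times ms).

    Per-cell heterogeneity is drawn uniformly within ``hetero`` fractional
    bounds around the nominal conductances; the tonic excitatory conductance
    is uniform on [0, g_tonic_max] so only the upper tail of cells is
    spontaneously active.
    """

    c_m: float = 21.0           # pF
    g_na: float = 28.0          # nS
    e_na: float = 50.0
    theta_m: float = -34.0
    sigma_m: float = -5.0
    g_k: float = 11.2
    e_k: float = -85.0
    theta_n: float = -29.0
    sigma_n: float = -4.0
    tau_n_bar: float = 10.0     # ms
    g_leak: float = 2.8
    e_leak: float = -60.0
    e_syn: float = 0.0
    g_tonic_max: float = 1.05   # nS; uniform on [0, max] across cells
    g_can: float = 3.0          # nS
    e_can: float = 0.0
    k_can: float = 9.0          # Ca half-activation (dimensionless pool units)
    theta_s: float = -10.0      # synaptic-release gate on presynaptic V
    sigma_s: float = 2.0        # steep: release only during spikes
    alpha_s: float = 0.35       # 1/ms rise of s during a spike
    tau_s: float = 12.0         # ms decay of s
    k_d: float = 0.05           # 1/ms depression depletion while spiking
    tau_d: float = 2300.0       # ms depression recovery; paces the ~4 s rhythm
    k_ca: float = 0.1           # Ca charging per nS of synaptic drive per ms
    tau_ca: float = 200.0       # ms Ca clearance
    w_syn: float = 0.26         # nS per synapse
    hetero: float = 0.1         # fractional spread of per-cell conductances
    noise_rate_hz: float = 2.0  # unitary background EPSP events per cell
    noise_amp_ns: float = 0.2   # conductance jump per background event

    def scalar_vector(self) -> np.ndarray:
        v = np.empty(_N_SCALAR)
        v[_E_NA], v[_E_K], v[_E_SYN], v[_E_CAN] = (self.e_na, self.e_k,
                                                   self.e_syn, self.e_can)
        v[_TH_M], v[_SIG_M] = self.theta_m, self.sigma_m
        v[_TH_N], v[_SIG_N], v[_TAU_N] = self.theta_n, self.sigma_n, self.tau_n_bar
        v[_CM] = self.c_m
        v[_TH_S], v[_SIG_S] = self.theta_s, self.sigma_s
        v[_ALPHA_S], v[_TAU_S] = self.alpha_s, self.tau_s
        v[_K_D], v[_TAU_D] = self.k_d, self.tau_d
        v[_K_CA], v[_TAU_CA], v[_K_CAN] = self.k_ca, self.tau_ca, self.k_can
        return v


def nominal_params() -> NeuronParams:
    return NeuronParams()


def draw_population(n: int, params: NeuronParams, rng) -> dict:
    """Draw per-cell conductance arrays (uniform heterogeneity) and initial
    state.  Initial V is scattered below threshold; d starts partly depressed
    so the first network burst is not an artificial giant transient."""
    h = params.hetero

    def spread(x):
        return x * rng.uniform(1 - h, 1 + h, n)

    cell = {
        "g_na": spread(params.g_na),
        "g_k": spread(params.g_k),
        "g_leak": spread(params.g_leak),
        "e_leak": params.e_leak + rng.uniform(-1.5, 1.5, n),
        "g_tonic": rng.uniform(0.0, params.g_tonic_max, n),
        "g_can": spread(params.g_can),
    }
    state = np.zeros((5, n))
    state[0] = rng.uniform(-62.0, -50.0, n)   # V
    state[1] = 0.05 + 0.05 * rng.random(n)    # n
    state[2] = 0.0                            # s
    state[3] = rng.uniform(0.3, 0.6, n)       # d
    state[4] = 0.05 * rng.random(n)           # ca
    return {"cell": cell, "state": state}


@njit(cache=True, fastmath=True, error_model="numpy")
def _derivatives(Y, dY, alive, stim, pre_idx, pre_ptr, w, g_bg,
                 g_na, g_k, g_leak, e_leak, g_tonic, g_can, sp, drive,
                 release):
    n_cells = Y.shape[1]
    for j in range(n_cells):
        # glutamate un-caging bypasses presynaptic depression, so a clamped
        # cell transmits its (clamped) activation undepressed
        release[j] = Y[2, j] if stim[j] else Y[2, j] * Y[3, j]
    for i in range(n_cells):
        acc = g_bg[i]
        for e in range(pre_ptr[i], pre_ptr[i + 1]):
            acc += w[e] * release[pre_idx[e]]
        drive[i] = acc
    for i in range(n_cells):
        if not alive[i]:
            dY[0, i] = dY[1, i] = dY[2, i] = dY[3, i] = dY[4, i] = 0.0
            continue
        V = Y[0, i]
        gate_n = Y[1, i]
        s = Y[2, i]
        d = Y[3, i]
        ca = Y[4, i]

        m_inf = 1.0 / (1.0 + np.exp((V - sp[_TH_M]) / sp[_SIG_M]))
        # n_inf and tau_n share one exponential:
        # u = exp((V-th)/sig); n_inf = 1/(1+u); cosh(x/2) = (su + 1/su)/2
        u = np.exp((V - sp[_TH_N]) / sp[_SIG_N])
        n_inf = 1.0 / (1.0 + u)
        su = np.sqrt(u)
        tau_n = 2.0 * sp[_TAU_N] / (su + 1.0 / su)

        i_na = g_na[i] * m_inf**3 * (1.0 - gate_n) * (V - sp[_E_NA])
        i_k = g_k[i] * gate_n**4 * (V - sp[_E_K])
        i_leak = g_leak[i] * (V - e_leak[i])
        i_tonic = g_tonic[i] * (V - sp[_E_SYN])
        can_act = ca * ca / (ca * ca + sp[_K_CAN] * sp[_K_CAN])
        i_can = g_can[i] * can_act * (V - sp[_E_CAN])
        i_syn = drive[i] * (V - sp[_E_SYN])

        dY[0, i] = -(i_na + i_k + i_leak + i_tonic + i_can + i_syn) / sp[_CM]
        dY[1, i] = (n_inf - gate_n) / tau_n

        phi = 1.0 / (1.0 + np.exp(-(V - sp[_TH_S]) / sp[_SIG_S]))
        dY[2, i] = 0.0 if stim[i] else (sp[_ALPHA_S] * (1.0 - s) * phi
                                        - s / sp[_TAU_S])
        dY[3, i] = (1.0 - d) / sp[_TAU_D] - sp[_K_D] * phi * d
        dY[4, i] = sp[_K_CA] * drive[i] - ca / sp[_TAU_CA]


@njit(cache=True, error_model="numpy")
def _kernel(Y, alive, stim, pre_idx, pre_ptr, w, g_bg,
            ev_t, ev_cell, ev_amp,
            g_na, g_k, g_leak, e_leak, g_tonic, g_can, sp,
            dt, n_steps, t0, last_spike,
            spike_t, spike_id):
    n_cells = Y.shape[1]
    k1 = np.empty_like(Y)
    k2 = np.empty_like(Y)
    k3 = np.empty_like(Y)
    k4 = np.empty_like(Y)
    tmp = np.empty_like(Y)
    drive = np.empty(n_cells)
    release = np.empty(n_cells)
    v_prev = np.empty(n_cells)
    n_spikes = 0
    cap = spike_t.shape[0]
    bg_decay = np.exp(-dt / sp[_TAU_S])
    ev_ptr = 0
    n_ev = ev_t.shape[0]

    for step in range(n_steps):
        t = t0 + step * dt
        for i in range(n_cells):
            v_prev[i] = Y[0, i]

        # background events whose (continuous) time falls in this step
        while ev_ptr < n_ev and ev_t[ev_ptr] <= t + dt:
            c = ev_cell[ev_ptr]
            if alive[c]:
                g_bg[c] += ev_amp
            ev_ptr += 1

        _derivatives(Y, k1, alive, stim, pre_idx, pre_ptr, w, g_bg,
                     g_na, g_k, g_leak, e_leak, g_tonic, g_can, sp, drive, release)
        for a in range(5):
            for i in range(n_cells):
                tmp[a, i] = Y[a, i] + 0.5 * dt * k1[a, i]
        _derivatives(tmp, k2, alive, stim, pre_idx, pre_ptr, w, g_bg,
                     g_na, g_k, g_leak, e_leak, g_tonic, g_can, sp, drive, release)
        for a in range(5):
            for i in range(n_cells):
                tmp[a, i] = Y[a, i] + 0.5 * dt * k2[a, i]
        _derivatives(tmp, k3, alive, stim, pre_idx, pre_ptr, w, g_bg,
                     g_na, g_k, g_leak, e_leak, g_tonic, g_can, sp, drive, release)
        for a in range(5):
            for i in range(n_cells):
                tmp[a, i] = Y[a, i] + dt * k3[a, i]
        _derivatives(tmp, k4, alive, stim, pre_idx, pre_ptr, w, g_bg,
                     g_na, g_k, g_leak, e_leak, g_tonic, g_can, sp, drive, release)
        for a in range(5):
            for i in range(n_cells):
                Y[a, i] += (dt / 6.0) * (k1[a, i] + 2.0 * k2[a, i]
                                         + 2.0 * k3[a, i] + k4[a, i])
        for i in range(n_cells):
            g_bg[i] *= bg_decay

        t_new = t + dt
        for i in range(n_cells):
            if not alive[i]:
                continue
            if not np.isfinite(Y[0, i]):
                return n_spikes, -(i + 1), t_new
            if (v_prev[i] < SPIKE_THRESHOLD_MV <= Y[0, i]
                    and t_new - last_spike[i] >= REFRACTORY_MS):
                last_spike[i] = t_new
                if n_spikes < cap:
                    spike_t[n_spikes] = t_new
                    spike_id[n_spikes] = i
                    n_spikes += 1
    return n_spikes, 0, t0 + n_steps * dt


def run_segment(state, alive, stim, pre_idx, pre_ptr, w, g_bg, cell, scalars,
                dt_ms, n_steps, t0_ms, last_spike_ms,
                noise_events=None, noise_amp_ns: float = 0.0,
                expected_rate_hz: float = 60.0):
    """Advance the network ``n_steps`` RK4 steps; returns (spike_times_ms,
    spike_ids).  ``noise_events`` is an optional (times_ms, cell_ids) pair of
    pre-drawn background events within the segment.  Raises on numerical
    blow-up naming neuron and time."""
    n_cells = state.shape[1]
    cap = max(1024, int(expected_rate_hz * n_cells * n_steps * dt_ms / 1000.0))
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int32)
    if noise_events is None:
        ev_t = np.empty(0)
        ev_cell = np.empty(0, dtype=np.int64)
    else:
        ev_t, ev_cell = noise_events
    n_spk, status, t_end = _kernel(
        state, alive, stim, pre_idx, pre_ptr, w, g_bg,
        ev_t, ev_cell, noise_amp_ns,
        cell["g_na"], cell["g_k"], cell["g_leak"], cell["e_leak"],
        cell["g_tonic"], cell["g_can"], scalars,
        dt_ms, n_steps, t0_ms, last_spike_ms, spike_t, spike_id)
    if status < 0:
        raise FloatingPointError(
            f"integration blew up (non-finite V) in neuron {-status - 1} "
            f"at t = {t_end:.3f} ms")
    return spike_t[:n_spk].copy(), spike_id[:n_spk].copy()
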