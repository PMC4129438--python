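# Methods

`ablatio` is an in-silico twin of a cumulative single-cell laser-ablation
experiment in the preBötzinger complex (preBötC), the medullary network that
generates the inspiratory breathing rhythm. The package covers the full
chain: synthetic fluorescence stacks with ground truth, soma-target
detection, an excitatory spiking-network simulator with sequential-deletion
and focal-stimulation protocols, rhythm statistics, ablation-session
orchestration with the population arithmetic, and graph-topology tracking.
This note documents the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Synthetic fluorescence stacks (`synthgen`)

The generator emulates the imaging geometry of a bilateral detection domain:
two disjoint 412 × 412 µm hemi-fields imaged at 0.8 µm/pixel, focal planes
every 10 µm of depth (plane 0 at the slice surface), 12-bit intensities.
Three object classes are rendered per plane per side:

* **somata** — Gaussian-profiled discs truncated at half maximum (radius
  3.5–5.5 µm), 26–50 per plane per side under the preBötC preset;
* **dendrite shafts** — rotated rectangles with aspect ratio ≥ 5 (length
  16–30 µm), a configurable fraction of the soma count (default 25%);
* **auto-fluorescent debris** — spiky star polygons (5–8 spikes, notch radius
  0.55–0.75 of the tip radius), default 15% of the soma count.

The classes are constructed to be separable by the downstream circularity
cutoff of 0.75: rasterized somata score ≥ 0.8 at this pixel size while
shafts and stars score ≤ 0.5. Star notches deeper than ~0.5 of the tip
radius are avoided deliberately — at 0.8 µm/pixel they rasterize into round
blobs that would defeat their purpose as circularity foils.

A configurable fraction of somata (default 25%) duplicates its footprint in
the adjacent shallower plane with ≥ 50% areal overlap (center shift ≤ 0.3
radius), so the cross-plane deduplication rule is exercised. Object centers
are rejection-sampled with a clearance gap within each plane *and* against
the adjacent planes, so distinct objects never overlap in (x, y) across
neighboring planes; cross-plane overlap is reserved for deliberate two-plane
somata. Optional noise is Poisson counting noise over the clean image plus a
constant background, parameterized as a peak-signal-to-background ratio; the
default is noiseless because the detection tests quantify recall against
exact truth.

No optics (point-spread function, depth attenuation) or anatomy is
simulated; brightness and size distributions are free parameters chosen to
look like neonatal-mouse tdTomato material at low magnification. Passing
detection tests on these phantoms therefore demonstrates correctness of the
detection logic, not robustness to real microscope noise.

The **cycle-period generator** produces either stable sequences
(multiplicative log-normal jitter around a base period) or a bi-exponential
slowing drift, `T_k = a1·exp(k/τ1) + a2·exp(k/τ2)` in cycle index `k`, the
shape seen in slices during cumulative lesioning. A helper solves (a1, a2,
τ1, τ2) so the expected period runs between chosen endpoints, e.g. from
1/0.22 Hz ≈ 4.5 s up to 1/0.007 Hz ≈ 143 s.

## Target detection (`detection`)

Per focal plane, an iterative threshold-crossing particle analysis: the
threshold starts at the largest multiple of the increment below the image
maximum and drops by a fixed increment (default 16, giving 4096/16 = 256
partitions of the 12-bit range) down to zero. At each partition, 4-connected
components of supra-threshold pixels whose area lies in a window (default
20–400 µm², converted to pixels) become candidates. A component that fully
contains exactly one earlier ROI replaces it (the particle grew); one that
envelopes two or more earlier ROIs is discarded and the earlier ROIs kept,
which prevents conflating adjacent cells. Because supra-threshold sets are
nested across partitions, every earlier ROI is wholly inside exactly one
current component, so "containment" needs no partial-overlap convention.

Circularity is `C = 4πa/p²` clipped to ≤ 1, with the perimeter estimated by
corner-weighted contour length (raw pixel-edge counting biases `C` low for
small discs). ROIs pass only when `C` strictly exceeds the cutoff (default
0.75). The cutoff comparison is strict: a score of exactly 0.75 is rejected.

The **priority rule** deduplicates somata detected in more than one focal
plane: accepted ROIs in adjacent planes overlap when their masks share at
least one (x, y) pixel; overlap chains are resolved as connected components
of that graph, and within each component the ROI from the deepest plane
survives (ties broken by acquisition order). Applied to its own output the
rule is a no-op. Conventions: pixel indices are 0-based, physical
coordinates sit at pixel centers, depth is nonnegative µm below the surface,
and the area window is interpreted in µm² (the stack's pixel size converts
it). 4-connectivity is used for labeling to avoid diagonal bridges fusing
adjacent cells.

## Network model (`netmodel`, `burster`)

The population is a directed Erdős–Rényi graph G(n, p): every ordered pair
(i, j), i ≠ j, carries a synapse from i to j independently with probability
p; self-loops are excluded (autapses are biologically unintended here).
Each vertex holds a conductance-based **group-pacemaker burster**: rhythmic
bursting is a network property arising from recurrent excitation amplified
by a synaptically triggered inward current, not from intrinsically bursting
pacemaker cells. Per-neuron state is (V, n, s, d, Ca):

    C dV/dt = −I_Na − I_K − I_leak − I_tonic − I_CAN − I_syn
    I_Na   = g_Na · m∞(V)³ · (1−n) · (V − E_Na)      m∞ = σ((V−θ_m)/σ_m)
    I_K    = g_K · n⁴ · (V − E_K)
    dn/dt  = (n∞(V) − n) / τ_n(V)                    τ_n = τ̄_n / cosh((V−θ_n)/2σ_n)
    I_leak = g_leak (V − E_leak),  I_tonic = g_tonic (V − E_syn)
    I_CAN  = g_CAN · Ca²/(Ca² + K_CAN²) · (V − E_CAN)
    I_syn  = (Σ_j A_ji w_ji s_j d_j) · (V − E_syn)
    ds/dt  = α_s (1−s) φ(V) − s/τ_s                  φ = σ((V−θ_s)/σ_s)
    dd/dt  = (1−d)/τ_d − k_d φ(V) d
    dCa/dt = k_Ca · drive − Ca/τ_Ca                  drive = Σ_j A_ji w_ji s_j d_j

The spiking backbone (I_Na with instantaneous activation and 1−n standing in
for inactivation, I_K) is the classic reduced formulation for medullary
interneurons (C = 21 pF, g_Na = 28 nS, E_Na = 50 mV, θ_m = −34, σ_m = −5,
g_K = 11.2 nS, E_K = −85 mV, θ_n = −29, σ_n = −4, τ̄_n = 10 ms, g_leak =
2.8 nS, E_leak = −60 ± 1.5 mV). On top of it sit the three ingredients of
the group-pacemaker mechanism:

* a heterogeneous **tonic excitatory conductance** g_tonic ~ U(0, 1.05) nS:
  only the upper ~15% of cells fire tonically and seed network bursts;
* **I_CAN** (g_CAN = 3 nS, E_CAN = 0), gated sigmoidally by a dimensionless
  Ca pool charged by synaptic drive (k_Ca = 0.1 per nS·ms, τ_Ca = 200 ms,
  half-activation K_CAN = 9). During a burst the pool charges far past
  K_CAN and I_CAN regeneratively recruits the whole population; the tonic
  trickle between bursts keeps the pool well below K_CAN, so sustained
  low-level activity cannot hold the current on;
* **synaptic depression**: every edge transmits s_j·d_j with w = 0.26 nS
  (±10% per edge). s rises at spikes (α_s = 0.35/ms, gate θ_s = −10 mV,
  σ_s = 2 mV — steep, so release happens only during spikes) and decays with
  τ_s = 12 ms; d depletes while spiking (k_d = 0.05/ms) and recovers with
  τ_d = 2.3 s. Depression both terminates each burst and paces the rhythm:
  the network re-ignites when d has recovered to the point where a recruit
  cascade is regenerative, which yields the ~3–4 s cycle at (n, p) =
  (330, 0.125) and makes the period lengthen steeply as deletions shrink
  the recruit pool.

Each cell also receives a sparse background of unitary EPSP-like conductance
events (independent Poisson trains, 2 Hz per cell, 0.2 nS per event,
decaying with τ_s), standing in for spontaneous synaptic bombardment. The
events are drawn in continuous time from the network's seeded generator, so
a realization is exactly reproducible for a fixed seed and the event train
is independent of the integration step (halving dt does not change the
noise realization). With the rate set to zero the model is strictly
deterministic; the rate/amplitude were fixed once so that every (330,
0.125) realization is spontaneously rhythmic while a single stimulated cell
still cannot trigger a burst.

Parameter provenance: the spiking backbone values are the standard published
ones; the group-pacemaker parameters (g_tonic range, I_CAN gain and
half-activation, synaptic weight, depression rates, noise) are this
package's own calibration, set to reproduce the behavioral contract of the
modeled preparation — spontaneous ~3–4 s rhythm at (330, 0.125), evoked
network bursts within 300 ms when ≥ 5 cells are stimulated but not 1, and
rhythm slowing with cessation after a few tens of random deletions — and
frozen before the acceptance measurements.

**Integration** is classical fixed-step fourth-order Runge–Kutta, dt =
0.25 ms, in a compiled kernel. Spikes are upward crossings of −10 mV with a
2 ms refractory; the running-time histogram counts spikes of alive neurons
in 10 ms bins. A non-finite state aborts with the neuron index and time.

**Protocols.** Deletion sets the cell's synaptic activation s to zero and
freezes its dynamics; its spikes leave rasters and histograms. The deletion
experiment deletes uniformly without replacement, one cell every 25 s, after
a 25 s lead-in. Focal stimulation clamps s = 0.9 for 200 ms without touching
its ODE (the excitation is transient); a stimulated cell transmits its
clamped activation *undepressed*, because the protocol emulates glutamate
un-caging, which bypasses presynaptic release altogether. The (n, p)
**sweep** scores, per grid cell, the fraction of rhythmic realizations
(≥ 3 bursts in the run), the mean cycle period, and a flag marking cells
where ≥ 80% of realizations fall in the respiratory-like 3–4 s band.

**Cessation** is operationalized as: no network burst in any subsequent
inter-deletion window through the end of the run; the cessation tally is the
tally after which no further burst occurs. The burst criterion inside the
experiment is anchored once to the pre-deletion rhythm (30% of the median
baseline burst amplitude): a per-window adaptive threshold would mistake the
tonic background of a silent window for one long burst. An early-stopping
option ends the run after a chosen number of consecutive burst-free windows
(3 in the tests), trading the tail of the verification window for runtime.

## Rhythm statistics (`rhythm`)

Bursts are contiguous supra-threshold epochs of the histogram (default
threshold 20% of the 95th-percentile bin count, minimum separation 500 ms;
both configurable, and protocol code passes absolute thresholds anchored to
a baseline epoch as described above). The regularity score of cycle n is
RS_n = T_n / mean(T_{n−1} … T_{n−j}) with j = 10; for the first cycles the
mean runs over the available priors. RS is exactly 1 for a constant-period
rhythm, invariant under rescaling all periods, and exceeds 1 when the rhythm
slows. Cessation at a horizon time means no burst within the trailing 120 s.
Amplitude series are normalized by the mean over a baseline (pre-lesion)
epoch.

## Ablation sessions (`ablation`)

A session walks a target map in uniformly random order within each side,
alternating sides every batch (default 10), attempting each lesion as a
Bernoulli trial (default per-attempt success 0.5) up to 5 times. Confirmed
lesions increment the running tally; a target failing all 5 attempts is
dropped and never reselected. The per-attempt default makes the overall
failure rate ~3%, consistent with the >90% success regime of the emulated
rig. The session stops when targets are exhausted or the monitored rhythm
has been quiescent longer than 120 s. In coupled mode (`pipeline`), detected
image targets map to model neurons by a seeded random injection; configurable
glia/premotor fractions map to nothing, representing non-rhythmogenic
targets whose lesioning does not touch the rhythm-generating network.

Population arithmetic: the essential-core estimate is N_core =
round(N_detected (1 − f_glia − f_premotor)), e.g. 705 targets with two 10%
discounts give 564. The critical ablation fraction is 100·X̄/N_core with the
normal-theory interval 100·(X̄ ± Z·SEM)/N_core, reported in integer percent.

## Graph topology (`topology`)

Adjacency convention: A[i, j] = 1 iff a synapse runs from i to j. Global
metrics: K-core number (peeling on total degree, in-arcs and out-arcs each
counting one edge), number of strongly connected components, and mean
in/out degree (always equal). Local metrics, computed for each deleted
vertex on the graph *before* its removal: local cluster coefficient over the
out-neighborhood, counting ordered linked pairs, C_v = |{(j,k): A_jk=1}| /
(k_v(k_v−1)) with k_v the out-degree, defined 0 for k_v < 2 (the formula
divides by zero there); closeness centrality n/farness with farness the sum
of directed shortest-path lengths to reachable vertices only, 0 for a vertex
reaching nobody; and betweenness over ordered (s, t) pairs normalized by
(n−1)(n−2), requiring n ≥ 3. The out-neighbor reading of the clustering
formula (and its ordered-pair numerator) matches its (k_v(k_v−1))
denominator; both degenerate-case conventions are the common ones. Strongly
connected components and shortest paths are delegated to compiled sparse
routines and betweenness to igraph; all four local/centrality metrics are
cross-checked against brute-force oracles on random graphs in the test
suite.

## Problem sizes and runtimes

The test suite and the acceptance script are sized for a single CPU: the
spontaneous-rhythm measurement uses 10 realizations of (330, 0.125) × 25 s;
the sequential-deletion check uses three half-size networks (n = 165,
synaptic weights doubled to preserve total recurrent drive n·p·w) with
early stopping, which reproduces the full-scale cessation behavior (tallies
~40–90 at n = 330, mean ≈ 40 at the surrogate scale) in a fraction of the
time; detection tests use 2–3-plane stacks with 4–9 somata per plane per
side, with the full preset exercised once. The (n, p) sweep is exposed at
its full 21 × 9 × 10 grid but tested on reduced grids; the full grid is a
cluster-scale computation.

## Known limitations

* The phantom generator makes no attempt at realistic optics or anatomy;
  detection performance on real stacks will be bounded by noise sources the
  tests do not model.
* The neuron model is a behavioral stand-in of the group-pacemaker class:
  its parameters are calibrated to network-level behavior, not fitted to
  intracellular recordings, and model-dependent numbers (cycle period,
  cessation tally) should be read with stochastic tolerance.
* Near the rhythmic/non-rhythmic boundary the cycle period is very
  sensitive to the depression recovery constant and to realization; a small
  fraction of half-size surrogate realizations is non-rhythmic from the
  start and is screened out by protocol preconditions.
* No inhibitory synapses, no pacemaker/follower classification, no burstlet
  analysis; amplitude decline of motor output (a premotor phenomenon) is
  intentionally absent from the pure rhythmogenic model.
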