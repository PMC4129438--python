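"""End-to-end pipeline: phantom stack -> target detection -> ablation session
coupled to the network simulator -> rhythm statistics and topology report.

The coupled session is the in-silico twin of a slice experiment: detected
image targets are mapped by a seeded random injection onto model neurons
(optionally leaving configurable glia/premotor fractions mapped to nothing,
standing in for non-rhythmogenic targets), lesions are scheduled in random
bilateral batches, each confirmed lesion deletes the mapped neuron, and the
session halts when the simulated rhythm has been quiescent for longer than
120 s or the targets are exhausted.

Every artifact is written under one run directory together with a manifest of
file hashes and the per-stage seeds, so a re-run with the same config
reproduces the same hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import ablation, detection, netmodel, rhythm, synthgen, topology
from .config import RunConfig, save_config, stage_seed

__all__ = ["run_pipeline", "CoupledSession"]


class CoupledSession:
    """Couples an ablation session to a live network simulation.

    Serves as the session's rhythm monitor (advancing the simulation to the
    session clock and applying the 120-s quiescence rule) and as its lesion
    effector (deleting the model neuron mapped to each confirmed target).
    """

    def __init__(self, network, target_ids, quiescence_s=120.0,
                 f_glia=0.0, f_premotor=0.0, seed=None, dt_ms=0.25):
        self.network = network
        self.quiescence_s = quiescence_s
        self.dt_ms = dt_ms
        self.burst_times: list[float] = []
        self.histograms: list[np.ndarray] = []
        self.deleted: list[int] = []
        self._burst_threshold: float | None = None
        rng = np.random.default_rng(seed)
        ids = list(target_ids)
        rng.shuffle(ids)
        n_unmapped = int(round((f_glia + f_premotor) * len(ids)))
        mapped = ids[: len(ids) - n_unmapped]
        neurons = rng.choice(network.n, size=min(len(mapped), network.n),
                             replace=False)
        self.mapping = dict(zip(mapped, neurons.tolist()))

    def _advance_to(self, t_s: float):
        dur = t_s - self.network.t_ms / 1000.0
        if dur <= 0:
            return
        tr = netmodel.integrate(self.network, netmodel.SimConfig(
            duration_s=dur, dt_ms=self.dt_ms, keep_spikes=False))
        self.histograms.append(tr.histogram)
        # burst criterion anchored to the first rhythmic epoch so that the
        # background of a silent window is never mistaken for a burst
        bursts = tr.bursts(threshold=self._burst_threshold)
        if self._burst_threshold is None and len(bursts) > 0:
            self._burst_threshold = 0.3 * float(np.median(bursts.amplitudes))
        self.burst_times.extend(bursts.times.tolist())

    def monitor(self, t_s: float, tally: int) -> bool:
        self._advance_to(t_s)
        horizon = self.network.t_ms / 1000.0
        quiescent, _ = rhythm.detect_cessation(
            self.burst_times, horizon, self.quiescence_s)
        # never call it quiescent before one full window has elapsed
        return quiescent and horizon > self.quiescence_s

    def on_lesion(self, target_id: int, t_s: float):
        neuron = self.mapping.get(target_id)
        if neuron is not None and self.network.alive[neuron]:
            netmodel.delete_neuron(self.network, neuron, t_s)
            self.deleted.append(int(neuron))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages under ``outdir`` and return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage)
             for stage in ("synthgen", "netmodel", "ablation")}

    # --- synthetic stack
    syn_cfg = config.synthgen
    syn_cfg.seed = seeds["synthgen"]
    stack, truth = synthgen.make_stack(syn_cfg)
    synthgen.write_stack(stack, out / "stack.tiff", syn_cfg)
    synthgen.write_ground_truth(truth, out / "ground_truth.csv")

    # --- detection
    tmap = detection.detect_targets(stack, config.detection)
    detection.write_target_map(tmap, out / "targets.csv",
                               out / "detection_audit.json")

    # --- network + coupled ablation session
    net_cfg = config.netmodel
    graph = netmodel.er_graph(net_cfg.n, net_cfg.p, seed=seeds["netmodel"])
    network = netmodel.build_network(graph, weight_scale=net_cfg.weight_scale,
                                     seed=seeds["netmodel"] + 1)
    ses = config.session
    coupled = CoupledSession(network, [t.id for t in tmap.targets],
                             quiescence_s=ses.quiescence_s,
                             f_glia=ses.f_glia, f_premotor=ses.f_premotor,
                             seed=seeds["ablation"], dt_ms=net_cfg.dt_ms)
    targets = tmap.targets
    if ses.max_lesions is not None:
        targets = targets[: ses.max_lesions]
    log = ablation.run_session(
        [(t.id, t.side) for t in targets],
        monitor=coupled.monitor, on_lesion=coupled.on_lesion,
        success_probability=ses.success_probability,
        batch_size=ses.batch_size, lesion_interval_s=ses.lesion_interval_s,
        seed=seeds["ablation"])
    log.to_frame().to_csv(out / "ablation_log.csv", index=False)

    # --- rhythm statistics of the coupled run
    times = np.array(coupled.burst_times)
    rhythm_report = {"n_bursts": int(times.size)}
    if times.size >= 3:
        periods = np.diff(times)
        rs = rhythm.regularity_score(periods)
        rhythm_report.update({
            "mean_period_s": float(periods.mean()),
            "max_period_s": float(periods.max()),
            "max_rs": float(rs.rs.max()),
        })
    (out / "rhythm.json").write_text(json.dumps(rhythm_report, indent=2))

    # --- topology through the realized deletion sequence
    topo = topology.track_deletions(graph.adjacency, coupled.deleted)
    topo.to_frame().to_csv(out / "topology_deletions.csv", index=False)
    (out / "topology.json").write_text(json.dumps(topo.globals_dict(), indent=2))

    save_config(config, out / "config.yaml")
    artifacts = sorted(p for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seeds": {"master": config.seed, **seeds},
        "tally": log.tally,
        "stop_reason": log.stop_reason,
        "n_targets": len(tmap),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
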