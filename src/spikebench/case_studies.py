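"""Turn-key builders for the two benchmark experiments.

Case study 1 — PING: 5,000 LIF neurons (4,000 excitatory, 1,000 inhibitory)
plus 500 Poisson generators at 50 Hz, randomly connected by delta synapses,
simulated for 1 s at dt = 0.1 ms.  Gamma-band oscillations arise from the
excitatory-inhibitory loop (pyramidal-interneuron gamma).

Case study 2 — PIR-ING: 400 classical Hodgkin-Huxley neurons, each making
inhibitory double-exponential synapses onto 40 random peers, no external
drive, simulated for 500 ms at dt = 0.05 ms.  Rhythm emerges from
post-inhibitory rebound: neurons released from shared inhibition fire
together, re-inhibit the population, and the cycle repeats.  Each neuron
additionally integrates one silent single-exponential excitatory synapse so
that every neuron carries 7 dynamical variables (v, m, h, n, a_i, b_i, a_e).
"""

from __future__ import annotations

import time as _time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .engine import (
    HHNetwork,
    LIFNetwork,
    SimulationResult,
    min_isi,
    oscillation_frequency,
    population_rate,
    run_hh,
    run_lif,
    save_spikes,
)
from .models import HHParams, LIFParams, gating_steady_state
from .network import (
    ConnectivityConfig,
    EdgeList,
    connect_bernoulli,
    connect_fixed_outdegree,
)
from .synapses import DoubleExpParams, SingleExpParams

__all__ = [
    "CaseStudyConfig",
    "CASE1",
    "CASE2",
    "build_case_study_1",
    "build_case_study_2",
    "run_case_study_1",
    "run_case_study_2",
    "report",
]

# population id layout for case study 1
N_EXC = 4000
N_INH = 1000
N_GEN = 500


@dataclass(frozen=True)
class CaseStudyConfig:
    """Complete parameterization of one benchmark experiment."""

    kind: str  # "LIF-PING" | "HH-PIR-ING"
    duration: float  # ms
    dt: float  # ms
    solver: str
    seed: int = 0
    n_exc: int = 0
    n_inh: int = 0
    n_generators: int = 0
    generator_rate: float = 0.0  # Hz
    n_hh: int = 0
    out_degree: int = 0
    weights: dict = field(default_factory=dict)  # mV (delta) or nS
    delays: dict = field(default_factory=dict)  # ms
    probabilities: dict = field(default_factory=dict)
    neuron: dict = field(default_factory=dict)
    synapse: dict = field(default_factory=dict)
    refractory_mode: str = "clamp"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _case1_config(seed: int) -> CaseStudyConfig:
    return CaseStudyConfig(
        kind="LIF-PING",
        duration=1000.0,
        dt=0.1,
        solver="exact",
        seed=seed,
        n_exc=N_EXC,
        n_inh=N_INH,
        n_generators=N_GEN,
        generator_rate=50.0,
        probabilities={"p_ee": 0.005, "p_ei": 0.3, "p_ii": 0.3, "p_ie": 0.2,
                       "p_se": 0.15},
        weights={"g_ee": 0.009, "g_ei": 0.009, "g_ii": -0.05, "g_ie": -0.05,
                 "g_se": 0.025},
        delays={"d_ee": 0.8, "d_ei": 0.8, "d_ii": 2.1, "d_ie": 2.1,
                "d_se": 0.5},
        neuron={"tau": 10.0, "theta": 1.0, "v_reset": 0.0, "t_ref": 5.01},
    )


def _case2_config(seed: int) -> CaseStudyConfig:
    return CaseStudyConfig(
        kind="HH-PIR-ING",
        duration=500.0,
        dt=0.05,
        solver="rk4",
        seed=seed,
        n_hh=400,
        out_degree=40,
        weights={"g_i": 2.0},  # nS
        delays={"d_i": 3.0},
        # area 8e-6 cm^2 (8 pF at c = 1 uF/cm^2): small enough that the
        # 2 nS compound inhibition hyperpolarizes the cell deeply enough
        # for post-inhibitory rebound, so the rhythm self-sustains
        neuron={"g_na": 120.0, "g_k": 36.0, "g_l": 0.3, "e_na": 50.0,
                "e_k": -77.0, "e_l": -54.4, "c": 1.0, "i_inj": 0.0,
                "area": 8e-6},
        synapse={"tau_i1": 0.99, "tau_i2": 1.0, "e_i": -75.0,
                 "tau_e": 5.0, "e_e": 0.0},
    )


def build_case_study_1(seed: int) -> tuple[LIFNetwork, CaseStudyConfig]:
    """Build the PING network.

    Global ids: excitatory [0, 4000), inhibitory [4000, 5000), Poisson
    generators [5000, 5500).  Five Bernoulli projections are drawn from
    independent child seeds spawned from ``seed`` in a fixed order
    (ee, ei, ii, ie, se), so the whole connectivity is reproducible.
    """
    cfg = _case1_config(seed)
    n = N_EXC + N_INH
    w, d, pr = cfg.weights, cfg.delays, cfg.probabilities
    children = np.random.SeedSequence(seed).spawn(5)

    ee = connect_bernoulli(N_EXC, N_EXC, pr["p_ee"], np.random.default_rng(children[0]),
                           same_population=True, weight=w["g_ee"], delay=d["d_ee"])
    ei = connect_bernoulli(N_EXC, N_INH, pr["p_ei"], np.random.default_rng(children[1]),
                           weight=w["g_ei"], delay=d["d_ei"])
    ii = connect_bernoulli(N_INH, N_INH, pr["p_ii"], np.random.default_rng(children[2]),
                           same_population=True, weight=w["g_ii"], delay=d["d_ii"])
    ie = connect_bernoulli(N_INH, N_EXC, pr["p_ie"], np.random.default_rng(children[3]),
                           weight=w["g_ie"], delay=d["d_ie"])
    se = connect_bernoulli(N_GEN, N_EXC, pr["p_se"], np.random.default_rng(children[4]),
                           weight=w["g_se"], delay=d["d_se"])

    # map local ids onto the global layout and merge
    pre = np.concatenate([
        ee.pre, ei.pre, ii.pre + N_EXC, ie.pre + N_EXC, se.pre + n,
    ])
    post = np.concatenate([
        ee.post, ei.post + N_EXC, ii.post + N_EXC, ie.post, se.post,
    ])
    weight = np.concatenate([ee.weight, ei.weight, ii.weight, ie.weight, se.weight])
    delay = np.concatenate([ee.delay, ei.delay, ii.delay, ie.delay, se.delay])
    edges = EdgeList(pre=pre, post=post, weight=weight, delay=delay,
                     n_pre=n + N_GEN, n_post=n)

    net = LIFNetwork(
        params=LIFParams(**cfg.neuron),
        n_neurons=n,
        edges=edges,
        n_generators=N_GEN,
        generator_rate=cfg.generator_rate,
        v0=cfg.neuron["v_reset"],
        populations={"exc": (0, N_EXC), "inh": (N_EXC, N_INH),
                     "gen": (n, N_GEN)},
    )
    return net, cfg


def build_case_study_2(seed: int) -> tuple[HHNetwork, CaseStudyConfig]:
    """Build the PIR-ING network.

    Fixed-out-degree-40 inhibitory wiring; membrane potentials initialized
    uniformly in [-75, -55] mV with gating at the corresponding steady
    state; no injected current and no external drive.
    """
    cfg = _case2_config(seed)
    conn_seed, init_seed = np.random.SeedSequence(seed).spawn(2)
    edges = connect_fixed_outdegree(
        cfg.n_hh, cfg.out_degree, np.random.default_rng(conn_seed),
        weight=cfg.weights["g_i"], delay=cfg.delays["d_i"],
    )
    rng = np.random.default_rng(init_seed)
    v0 = rng.uniform(-75.0, -55.0, size=cfg.n_hh)
    m0, h0, n0 = gating_steady_state(v0)
    net = HHNetwork(
        params=HHParams(**cfg.neuron),
        n=cfg.n_hh,
        edges=edges,
        inh=DoubleExpParams(
            g_peak=cfg.weights["g_i"], e_rev=cfg.synapse["e_i"],
            tau_rise=cfg.synapse["tau_i1"], tau_decay=cfg.synapse["tau_i2"],
            delay=cfg.delays["d_i"],
        ),
        exc=SingleExpParams(g_peak=0.0, e_rev=cfg.synapse["e_e"],
                            tau=cfg.synapse["tau_e"]),
        v0=v0, m0=m0, h0=h0, n0=n0,
    )
    return net, cfg


def run_case_study_1(
    seed: int, duration: float | None = None, **kwargs
) -> tuple[SimulationResult, CaseStudyConfig]:
    """Build and run case study 1; build time is measured around the
    builder, simulation time around the integration loop."""
    t0 = _time.perf_counter()
    net, cfg = build_case_study_1(seed)
    build_time = _time.perf_counter() - t0
    if duration is not None:
        cfg = replace(cfg, duration=duration)
    drive_seed = np.random.SeedSequence(seed).spawn(6)[5]
    result = run_lif(
        net,
        cfg.duration,
        cfg.dt,
        seed=np.random.default_rng(drive_seed),
        refractory_mode=cfg.refractory_mode,
        **kwargs,
    )
    result.times.build_time = build_time
    return result, cfg


def run_case_study_2(
    seed: int, duration: float | None = None, solver: str | None = None, **kwargs
) -> tuple[SimulationResult, CaseStudyConfig]:
    """Build and run case study 2 (no run-time randomness: the seed fixes
    connectivity and initial conditions)."""
    t0 = _time.perf_counter()
    net, cfg = build_case_study_2(seed)
    build_time = _time.perf_counter() - t0
    if duration is not None:
        cfg = replace(cfg, duration=duration)
    result = run_hh(
        net,
        cfg.duration,
        cfg.dt,
        solver=solver or cfg.solver,
        **kwargs,
    )
    result.times.build_time = build_time
    return result, cfg


def report(result: SimulationResult, config: CaseStudyConfig, out_dir) -> dict:
    """Write raster, population-rate series, config echo and a summary.

    The summary holds spike counts, minimum ISI, oscillation frequency and
    the build/simulation wall-clock split; a silent network is flagged.
    Returns the summary dict.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    record = result.record
    duration = config.duration
    save_spikes(record, os.path.join(out_dir, "spikes.gdf"))
    config.to_yaml(os.path.join(out_dir, "config.yaml"))

    summary: dict = {
        "kind": config.kind,
        "n_spikes": int(len(record)),
        "build_time_s": float(result.times.build_time),
        "simulation_time_s": float(result.times.simulation_time),
    }
    if config.kind == "LIF-PING":
        neuron_ids = np.arange(config.n_exc + config.n_inh)
    else:
        neuron_ids = np.arange(config.n_hh)
    neuron_rec = record.select(neuron_ids)
    if len(neuron_rec) == 0:
        summary["silent_network"] = True
    else:
        summary["silent_network"] = False
        summary["min_isi_ms"] = float(min_isi(record, ids=neuron_ids))
        centers, counts = population_rate(record, 1.0, duration, ids=neuron_ids)
        with open(os.path.join(out_dir, "population_rate.tsv"), "w") as fh:
            fh.write("time_ms\tspikes_per_bin\n")
            for c, y in zip(centers, counts):
                fh.write(f"{c:.1f}\t{y:.0f}\n")
        osc = oscillation_frequency(record, duration, ids=neuron_ids)
        summary["oscillation_frequency_hz"] = osc.frequency
        summary["oscillation_significant"] = bool(osc.significant)
        summary["mean_rate_hz"] = float(
            len(neuron_rec) / len(neuron_ids) / (duration / 1000.0)
        )
    with open(os.path.join(out_dir, "summary.yaml"), "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary


CASE1 = _case1_config
CASE2 = _case2_config
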