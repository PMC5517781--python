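"""Event queue, Poisson drive, the simulation loop, and raster statistics.

The LIF loop is cross-checked against an independent scalar reference
simulator built from `lif_step` and a dict-based event queue.
"""

from collections import defaultdict

import numpy as np
import pytest

from spikebench.engine import (
    EventQueue,
    HHNetwork,
    LIFNetwork,
    SpikeRecord,
    delay_to_steps,
    load_spikes,
    min_isi,
    oscillation_frequency,
    poisson_train,
    population_rate,
    run_hh,
    run_lif,
    save_spikes,
)
from spikebench.models import (
    HHParams,
    LIFParams,
    LIFState,
    gating_steady_state,
    lif_step,
)
from spikebench.network import EdgeList, connect_bernoulli


class TestDelayGrid:
    def test_grid_delays_accepted(self):
        assert delay_to_steps(0.5, 0.1) == 5
        assert delay_to_steps(3.0, 0.05) == 60
        assert delay_to_steps(0.1, 0.1) == 1

    def test_sub_step_delay_is_causality_error(self):
        with pytest.raises(ValueError, match="causal|shorter"):
            delay_to_steps(0.05, 0.1)

    def test_off_grid_delay_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            delay_to_steps(0.55, 0.1)


class TestEventQueue:
    def test_delivery_exactly_after_delay(self):
        q = EventQueue(n_targets=3, max_delay=0.5, dt=0.1)
        q.schedule(target=1, increment=2.5, delay=0.5)
        # nothing before 5 steps, never earlier
        for _ in range(5):
            assert np.all(q.advance() == 0.0)
        due = q.advance()
        assert due[1] == 2.5 and due[0] == 0.0 and due[2] == 0.0

    def test_same_slot_events_sum(self):
        q = EventQueue(n_targets=2, max_delay=0.3, dt=0.1)
        q.schedule(0, 1.0, 0.2)
        q.schedule(0, 0.5, 0.2)
        q.advance()
        q.advance()
        assert q.advance()[0] == 1.5

    def test_delay_of_one_step_arrives_next_step(self):
        q = EventQueue(n_targets=1, max_delay=0.1, dt=0.1)
        q.schedule(0, 1.0, 0.1)
        q.advance()
        assert q.advance()[0] == 1.0


class TestPoissonTrain:
    def test_zero_rate_empty(self):
        assert len(poisson_train(0.0, 1000.0, 0.1, seed=1)) == 0

    def test_count_within_five_sigma(self):
        # 50 Hz for 100 s: Binomial(1e6, 0.005), mean 5000, sd ~ 70.5
        times = poisson_train(50.0, 100_000.0, 0.1, seed=123)
        assert abs(len(times) - 5000) < 5 * np.sqrt(5000 * 0.995)

    def test_times_on_grid(self):
        times = poisson_train(200.0, 1000.0, 0.1, seed=5)
        steps = times / 0.1
        assert np.allclose(steps, np.round(steps), atol=1e-9)
        assert times.min() >= 0.1 and times.max() <= 1000.0

    def test_determinism(self):
        a = poisson_train(50.0, 10_000.0, 0.1, seed=9)
        b = poisson_train(50.0, 10_000.0, 0.1, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            poisson_train(-1.0, 100.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            poisson_train(5000.0, 100.0, 0.1, seed=0)  # p > 0.1


def _empty_edges(n_sources, n_targets):
    return EdgeList(pre=[], post=[], weight=[], delay=[],
                    n_pre=n_sources, n_post=n_targets)


class TestRunLIF:
    def test_silent_without_drive(self):
        net = LIFNetwork(params=LIFParams(), n_neurons=10,
                         edges=_empty_edges(10, 10))
        res = run_lif(net, 50.0, 0.1, seed=0)
        assert len(res.record) == 0

    def test_suprathreshold_init_spikes_once_at_t0(self):
        net = LIFNetwork(params=LIFParams(t_ref=5.01), n_neurons=1,
                         edges=_empty_edges(1, 1), v0=1.5)
        res = run_lif(net, 20.0, 0.1, seed=0)
        assert len(res.record) == 1
        assert res.record.time[0] == 0.0

    def test_spike_propagates_with_exact_delay(self):
        # neuron 0 spikes at t=0; weight 2 mV > theta arrives at 0.5 ms
        edges = EdgeList(pre=[0], post=[1], weight=[2.0], delay=[0.5],
                         n_pre=2, n_post=2)
        net = LIFNetwork(params=LIFParams(), n_neurons=2, edges=edges,
                         v0=np.array([1.5, 0.0]))
        res = run_lif(net, 10.0, 0.1, seed=0)
        rec = {int(i): t for i, t in zip(res.record.neuron, res.record.time)}
        assert rec[0] == 0.0
        assert rec[1] == pytest.approx(0.5)

    def test_refractory_floor_in_driven_network(self):
        net = LIFNetwork(
            params=LIFParams(t_ref=5.01), n_neurons=20,
            edges=EdgeList(
                pre=np.arange(20, 25).repeat(20),
                post=np.tile(np.arange(20), 5),
                weight=np.full(100, 0.6), delay=np.full(100, 0.5),
                n_pre=25, n_post=20,
            ),
            n_generators=5, generator_rate=400.0,
        )
        res = run_lif(net, 500.0, 0.1, seed=3)
        isi = min_isi(res.record, ids=np.arange(20))
        assert isi >= 5.01

    def test_determinism_identical_records(self):
        net, res = self._random_net_and_run(seed=5)
        _, res2 = self._random_net_and_run(seed=5)
        assert np.array_equal(res.record.neuron, res2.record.neuron)
        assert np.array_equal(res.record.time, res2.record.time)

    @staticmethod
    def _random_net_and_run(seed):
        edges = connect_bernoulli(25, 20, 0.3, seed=seed, weight=0.3,
                                  delay=0.5)
        net = LIFNetwork(params=LIFParams(), n_neurons=20, edges=edges,
                         n_generators=5, generator_rate=300.0)
        return net, run_lif(net, 300.0, 0.1, seed=seed)

    @pytest.mark.parametrize("refractory_mode", ["clamp", "integrate"])
    def test_matches_scalar_reference_simulator(self, refractory_mode):
        """Dual route: the vectorized ring-buffer loop reproduces an
        independent scalar simulation built on lif_step and a dict queue."""
        params = LIFParams(tau=10.0, theta=1.0, v_reset=0.0, t_ref=5.01)
        n, n_gen = 20, 5
        rate = 300.0
        dt, duration = 0.1, 100.0
        rng = np.random.default_rng(77)
        pre, post, w, d = [], [], [], []
        for i in range(n + n_gen):
            for j in range(n):
                if i != j and rng.random() < 0.3:
                    pre.append(i)
                    post.append(j)
                    w.append(0.5 if i >= n else rng.choice([0.2, -0.3]))
                    d.append(rng.choice([0.5, 0.8, 2.1]))
        edges = EdgeList(pre=pre, post=post, weight=w, delay=d,
                         n_pre=n + n_gen, n_post=n)
        net = LIFNetwork(params=params, n_neurons=n, edges=edges,
                         n_generators=n_gen, generator_rate=rate)
        res = run_lif(net, duration, dt, seed=42,
                      refractory_mode=refractory_mode)

        # --- scalar reference ---
        adj = defaultdict(list)
        for i in range(len(edges)):
            adj[int(edges.pre[i])].append(
                (int(edges.post[i]), float(edges.weight[i]),
                 int(round(float(edges.delay[i]) / dt)))
            )
        queue: dict = defaultdict(lambda: defaultdict(float))
        states = [LIFState() for _ in range(n)]
        spikes = []
        gen_rng = np.random.default_rng(42)
        p_gen = rate * dt / 1000.0
        n_steps = int(round(duration / dt))

        def emit(src, k):
            for tgt, wt, ds in adj[src]:
                queue[k + ds][tgt] += wt

        for k in range(1, n_steps + 1):
            t = k * dt
            due = queue.pop(k, {})
            for i in range(n):
                states[i], sp = lif_step(
                    states[i], params, dt, due.get(i, 0.0), t,
                    refractory_mode=refractory_mode,
                )
                if sp:
                    spikes.append((i, t))
                    emit(i, k)
            hits = np.nonzero(gen_rng.random(n_gen) < p_gen)[0]
            for g in hits:
                spikes.append((n + int(g), t))
                emit(n + int(g), k)

        got = sorted(zip(res.record.neuron.tolist(), res.record.time.tolist()))
        want = sorted(spikes)
        assert len(got) > 50  # the comparison is not vacuous
        assert got == pytest.approx(want)


class TestRunHH:
    def test_identical_rest_no_drive_is_silent(self):
        v0 = np.full(50, -65.0)
        m0, h0, n0 = gating_steady_state(v0)
        edges = connect_bernoulli(50, 50, 0.2, seed=1, same_population=True,
                                  weight=2.0, delay=3.0)
        net = HHNetwork(params=HHParams(area=8e-6), n=50, edges=edges,
                        v0=v0, m0=m0, h0=h0, n0=n0)
        res = run_hh(net, 100.0, 0.05)
        assert len(res.record) == 0

    def test_solvers_agree_on_spike_count_scale(self):
        rng = np.random.default_rng(4)
        v0 = rng.uniform(-75, -55, 60)
        edges = connect_bernoulli(60, 60, 0.3, seed=2, same_population=True,
                                  weight=2.0, delay=3.0)
        net = HHNetwork(params=HHParams(area=8e-6), n=60, edges=edges, v0=v0)
        n_rk4 = len(run_hh(net, 100.0, 0.05, solver="rk4").record)
        n_ee = len(run_hh(net, 100.0, 0.05, solver="exp_euler").record)
        assert n_rk4 > 0 and n_ee > 0
        assert abs(n_rk4 - n_ee) <= 0.25 * max(n_rk4, n_ee)


class TestRasterStatistics:
    def test_min_isi_simple(self):
        rec = SpikeRecord([0, 0, 0], [1.0, 3.0, 8.0])
        assert min_isi(rec) == 2.0

    def test_min_isi_is_per_neuron(self):
        rec = SpikeRecord([0, 1, 0], [1.0, 1.5, 6.0])
        assert min_isi(rec) == 5.0

    def test_min_isi_empty_record_rejected(self):
        with pytest.raises(ValueError):
            min_isi(SpikeRecord([], []))

    def test_population_rate_bins(self):
        rec = SpikeRecord([0, 1, 2], [0.5, 0.7, 1.5])
        centers, counts = population_rate(rec, 1.0, 3.0)
        assert np.array_equal(counts, [2.0, 1.0, 0.0])

    def test_periodic_bursts_give_40hz_peak(self):
        # 50-spike bursts every 25 ms over 1 s -> 40 Hz +- one spectral bin
        times = np.concatenate(
            [np.full(50, t) for t in np.arange(25.0, 1000.0, 25.0)]
        )
        rec = SpikeRecord(np.zeros(len(times)), times)
        osc = oscillation_frequency(rec, 1000.0, bin=1.0, band=(20.0, 100.0))
        assert abs(osc.frequency - 40.0) <= osc.resolution
        assert osc.significant

    def test_homogeneous_poisson_flagged_non_oscillatory(self):
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(0.0, 1000.0, 5000))
        rec = SpikeRecord(np.zeros(5000), times)
        osc = oscillation_frequency(rec, 1000.0, band=(20.0, 100.0))
        assert not osc.significant

    def test_band_beyond_nyquist_rejected(self):
        rec = SpikeRecord([0], [1.0])
        with pytest.raises(ValueError, match="Nyquist"):
            oscillation_frequency(rec, 100.0, bin=10.0, band=(20.0, 100.0))

    def test_spike_file_round_trip(self, tmp_path):
        rec = SpikeRecord([3, 1, 4], [0.1, 2.5, 2.5])
        path = tmp_path / "spikes.gdf"
        save_spikes(rec, path)
        back = load_spikes(path)
        assert np.array_equal(back.neuron, rec.neuron)
        assert np.allclose(back.time, rec.time)
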