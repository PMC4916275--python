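"""Event-driven simulator: exactness, refractoriness, reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats

from wtalearn import (
    CurrentSchedule,
    NetworkSpec,
    NeuronSpec,
    PSPKernel,
    SimulationError,
    Simulator,
    SpikeRecord,
    SynapseSpec,
    simulate,
)

TAU = 0.015


def single_neuron(bias=0.0):
    net = NetworkSpec()
    net.add_neuron(NeuronSpec(bias=bias, refractory=TAU))
    return net


class TestMembranePotential:
    def test_bias_only(self):
        sim = Simulator(single_neuron(bias=-10.0), seed=0)
        assert sim.potential(0, 0.5) == -10.0

    def test_rectangular_synapse_and_clamp(self):
        net = NetworkSpec()
        net.add_neuron(NeuronSpec(bias=0.0, refractory=TAU))
        net.add_neuron(NeuronSpec(bias=-10.0, refractory=TAU))
        net.add_synapse(
            SynapseSpec(0, 1, 20.0, kernel=PSPKernel("rectangular", tau=TAU))
        )
        sim = Simulator(net, seed=0)
        sim.aff_last[1][0] = 1.0  # presynaptic spike at t=1
        sim.aff_exp[1][0] = 1.0 + TAU
        assert sim.potential(1, 1.005) == pytest.approx(10.0)
        assert sim.potential(1, 1.02) == pytest.approx(-10.0)
        sim.cur_amp[1] = 30.0
        assert sim.potential(1, 1.005) == pytest.approx(40.0)

    def test_intensity_model(self):
        sim = Simulator(single_neuron(bias=0.0), seed=0)
        assert sim.intensity(0, 0.1) == pytest.approx(1 / TAU)
        sim.refr_end[0] = 0.2
        assert sim.intensity(0, 0.19) == 0.0
        sim2 = Simulator(single_neuron(bias=-80.0), seed=0)
        assert sim2.intensity(0, 0.0) < 1e-30

    def test_nonfinite_weight_rejected(self):
        net = NetworkSpec()
        net.add_neuron(NeuronSpec())
        net.add_neuron(NeuronSpec())
        with pytest.raises(ValueError):
            net.add_synapse(SynapseSpec(0, 1, float("nan")))
        net.neurons[0].bias = float("inf")
        with pytest.raises(SimulationError):
            Simulator(net, seed=0)


class TestRenewalStatistics:
    def test_spike_count_matches_dead_time_renewal(self):
        # stationary rate of an intensity-rho process with dead time tau
        # is rho / (1 + rho * tau)
        rho = 1 / TAU  # u = 0
        expected = rho / (1 + rho * TAU)
        counts = [
            len(simulate(single_neuron(), duration=50.0, seed=s))
            for s in range(8)
        ]
        se = math.sqrt(expected * 50.0)  # binomial-ish scale
        assert abs(np.mean(counts) - expected * 50.0) < 3 * se / math.sqrt(8)

    def test_isi_distribution_is_shifted_exponential(self):
        rec = simulate(single_neuron(), duration=320.0, seed=42)
        isi = np.diff(rec.times)
        assert len(isi) >= 10000
        ks = stats.kstest(isi - TAU, "expon", args=(0, TAU))
        assert ks.pvalue > 0.001

    def test_refractoriness_exact(self):
        rec = simulate(single_neuron(bias=2.0), duration=60.0, seed=3)
        assert np.diff(rec.times).min() >= TAU

    def test_silent_under_strong_inhibition(self):
        sched = CurrentSchedule()
        sched.add(0, -80.0, 0.0, 10.0)
        rec = simulate(single_neuron(), sched, duration=10.0, seed=5)
        assert len(rec) == 0


class TestReproducibility:
    def test_same_seed_identical_records(self):
        net = single_neuron()
        r1 = simulate(net, duration=20.0, seed=9)
        r2 = simulate(net, duration=20.0, seed=9)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.neuron_ids, r2.neuron_ids)

    def test_adding_a_neuron_preserves_other_streams(self):
        net1 = single_neuron()
        rec1 = simulate(net1, duration=20.0, seed=4)
        net2 = single_neuron()
        net2.add_neuron(NeuronSpec(bias=1.0, refractory=TAU))
        rec2 = simulate(net2, duration=20.0, seed=4)
        t1 = rec1.for_neuron(0)
        t2 = rec2.for_neuron(0)
        assert np.array_equal(t1, t2)

    def test_record_file_roundtrip(self, tmp_path):
        rec = simulate(single_neuron(), duration=5.0, seed=1)
        path = tmp_path / "spikes.tsv"
        rec.dump(path)
        header = path.read_text().splitlines()[0]
        assert header == "# time_s\tneuron_id"
        back = SpikeRecord.load(path)
        assert np.allclose(back.times, np.round(rec.times, 6))
        assert np.array_equal(back.neuron_ids, rec.neuron_ids)

    def test_networkspec_roundtrip_bit_exact(self):
        net = NetworkSpec()
        net.add_neuron(NeuronSpec(bias=-10.123456789, refractory=TAU))
        net.add_neuron(NeuronSpec(bias=5.0, plastic_bias=True, name="a"))
        net.add_synapse(
            SynapseSpec(0, 1, 3.0000000001, kernel=PSPKernel("alpha"),
                        plastic=True)
        )
        back = NetworkSpec.loads(net.dumps())
        assert back.dumps() == net.dumps()
        assert back.neurons[0].bias == net.neurons[0].bias
        assert back.synapses[0].weight == net.synapses[0].weight


class TestThinningCorrectness:
    def test_alpha_driven_rate_matches_renewal_integration(self):
        """A neuron driven by near-deterministic periodic alpha EPSPs:
        the empirical rate over 100 seeds matches the numerically
        integrated expected rate of the dead-time renewal process."""
        period = 0.02
        duration = 10.0
        w = 1.5
        net = NetworkSpec()
        net.add_neuron(NeuronSpec(bias=-10.0, refractory=TAU))  # source
        net.add_neuron(NeuronSpec(bias=0.0, refractory=TAU))  # target
        kernel = PSPKernel("alpha")
        net.add_synapse(SynapseSpec(0, 1, w, kernel=kernel))
        sched = CurrentSchedule()
        n_pulses = int(duration / period)
        for k in range(n_pulses):
            sched.add(0, 40.0, k * period, k * period + 0.001)
        counts = []
        for seed in range(100):
            rec = simulate(net, sched, duration=duration, seed=seed)
            counts.append(len(rec.for_neuron(1)))
        empirical = np.mean(counts) / duration

        # independent oracle: hazard h(t) = rho(t) * P(free at t) with
        # P(free) = 1 - integral of h over the preceding dead time
        dt = 1e-4
        grid = np.arange(0.0, duration, dt)
        phase = grid % period  # source fires (essentially) at k*period
        # during refractoriness of the source every period > tau, each
        # pulse elicits exactly one source spike at the pulse onset
        # last-spike replacement: each source spike replaces the trace,
        # so only the current cycle's PSP contributes
        eps = np.array([kernel(p) for p in phase])
        u = w * eps
        rho = np.exp(u) / TAU
        dead = int(round(TAU / dt))
        h = np.zeros_like(grid)
        acc = 0.0  # running sum of h over the trailing dead window
        for k in range(len(grid)):
            h[k] = rho[k] * max(0.0, 1.0 - acc * dt)
            acc += h[k]
            if k >= dead:
                acc -= h[k - dead]
        expected = h.mean()
        assert abs(empirical - expected) / expected < 0.02
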