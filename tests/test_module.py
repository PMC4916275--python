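"""Association-module construction and training protocol."""

import numpy as np
import pytest

import wtalearn as wl
from wtalearn.module import (
    AssociationModule,
    ModuleParams,
    ModuleSpec,
    VariableSpec,
    build_module,
    presentation_schedule,
)
from wtalearn.plasticity import PlasticityConfig, Schedule


@pytest.fixture
def ex1_spec():
    return wl.example1_module().spec


class TestBuild:
    def test_example1_population_sizes(self, ex1_spec):
        net, idx = build_module(ex1_spec, seed=0)
        assert len(idx.chi) == 4  # 2 inputs x 2 values
        assert len(idx.alpha) == 4  # 2 values x J=2
        assert len(idx.zeta) == 2
        assert len(idx.inhibitory) == 5
        assert len(net) == 15

    def test_relay_weights_fixed_at_wpp(self, ex1_spec):
        net, idx = build_module(ex1_spec, seed=0)
        alpha_ids = set(idx.alpha.values())
        zeta_ids = set(idx.zeta.values())
        relays = [
            s for s in net.synapses
            if s.pre in alpha_ids and s.post in zeta_ids
        ]
        assert len(relays) == 4
        assert all(s.weight == 20.0 for s in relays)
        assert all(not s.plastic for s in relays)

    def test_lateral_inhibition_wiring(self, ex1_spec):
        net, idx = build_module(ex1_spec, seed=0)
        inh = set(idx.inhibitory)
        e2i = [s for s in net.synapses if s.post in inh]
        i2e = [s for s in net.synapses if s.pre in inh]
        assert len(e2i) == 4 * 5 and all(s.weight == 80.0 for s in e2i)
        assert len(i2e) == 5 * 4 and all(s.weight == -7.0 for s in i2e)
        assert all(s.kernel.kind == "rectangular" for s in e2i + i2e)

    def test_plastic_feedforward_all_to_all(self, ex1_spec):
        net, idx = build_module(ex1_spec, seed=0)
        plastic = [s for s in net.synapses if s.plastic]
        assert len(plastic) == 4 * 4  # every chi to every alpha
        cfg = ex1_spec.plasticity
        assert all(cfg.w_min <= s.weight <= cfg.w_max for s in plastic)

    def test_same_seed_identical_weights(self, ex1_spec):
        net1, _ = build_module(ex1_spec, seed=3)
        net2, _ = build_module(ex1_spec, seed=3)
        assert net1.dumps() == net2.dumps()
        net3, _ = build_module(ex1_spec, seed=4)
        assert net1.dumps() != net3.dumps()

    def test_initial_values_follow_gaussian_redraw(self, ex1_spec):
        # weights ~ N(3.0, 0.1) redrawn into bounds; biases ~ N(5, 0.1)
        # clipped above by b_max = 5, so all initial biases are <= 5
        net, idx = build_module(ex1_spec, seed=0)
        ws = [s.weight for s in net.synapses if s.plastic]
        assert 2.5 < np.mean(ws) < 3.5
        bs = [net.neurons[i].bias for i in idx.alpha.values()]
        assert all(b <= 5.0 for b in bs)
        assert np.mean(bs) > 4.5

    def test_cardinality_validation(self):
        with pytest.raises(ValueError):
            VariableSpec("x", 1)
        with pytest.raises(ValueError):
            ModuleSpec(inputs=[("x1", 2)], output=("z", 2), hidden=0)


class TestPresentation:
    def test_currents_for_example(self, ex1_spec):
        net, idx = build_module(ex1_spec, seed=0)
        sched = presentation_schedule(
            idx, {"x1": 1, "x2": 2, "z": 2}, t0=0.0
        )
        amps = {p.neuron: p.amplitude for p in sched}
        assert amps[idx.chi[(0, 1)]] == 30.0
        assert amps[idx.chi[(0, 2)]] == -30.0
        assert amps[idx.chi[(1, 2)]] == 30.0
        # hidden neurons outside the example's output value are gated
        assert amps[idx.alpha[(1, 1)]] == -80.0
        assert amps[idx.alpha[(1, 2)]] == -80.0
        assert idx.alpha[(2, 1)] not in amps
        assert all(p.t_end - p.t_start == pytest.approx(0.1) for p in sched)

    def test_value_out_of_range(self, ex1_spec):
        net, idx = build_module(ex1_spec, seed=0)
        with pytest.raises(ValueError):
            presentation_schedule(idx, {"x1": 3, "x2": 1, "z": 1}, 0.0)


class TestTraining:
    def test_zero_learning_rates_leave_parameters_unchanged(self):
        params = ModuleParams()
        cfg = PlasticityConfig(
            eta=Schedule.constant(0.0),
            eta_b=Schedule.constant(0.0),
            b_minus=-5.0,
        )
        mod = AssociationModule(
            [("x1", 2)], ("z", 2), hidden=1, params=params, plasticity=cfg
        )
        res = mod.fit(
            target=wl.DistributionTable(
                [("x1", [1, 2]), ("z", [1, 2])],
                [[0.25, 0.25], [0.25, 0.25]],
            ),
            duration=2.0,
            seed=0,
            checkpoint_every=1.0,
        )
        first, last = res.trajectory[0], res.trajectory[-1]
        for a, b in zip(first.weights, last.weights):
            assert np.array_equal(a, b)
        assert np.array_equal(first.biases, last.biases)

    def test_checkpoint_count_matches_interval(self, example1_target):
        res = wl.example1_module().fit(
            target=example1_target, duration=3.0, seed=0,
            checkpoint_every=1.0,
        )
        assert len(res.trajectory) == 4  # initial state + 3 checkpoints
        assert res.checkpoint_times == [0.0, 1.0, 2.0, 3.0]

    def test_deterministic_replay(self, example1_target):
        r1 = wl.example1_module().fit(
            target=example1_target, duration=2.0, seed=5,
            checkpoint_every=2.0,
        )
        r2 = wl.example1_module().fit(
            target=example1_target, duration=2.0, seed=5,
            checkpoint_every=2.0,
        )
        for c1, c2 in zip(r1.trajectory, r2.trajectory):
            assert all(
                np.array_equal(a, b) for a, b in zip(c1.weights, c2.weights)
            )
            assert np.array_equal(c1.biases, c2.biases)

    def test_learning_moves_weights_and_biases(self, example1_target):
        res = wl.example1_module().fit(
            target=example1_target, duration=5.0, seed=0,
            checkpoint_every=5.0,
        )
        first, last = res.trajectory[0], res.trajectory[-1]
        assert not np.allclose(
            np.concatenate([w.ravel() for w in first.weights]),
            np.concatenate([w.ravel() for w in last.weights]),
        )
        cfg = res.spec.plasticity
        for cp in res.trajectory:
            for w in cp.weights:
                assert np.all(w >= cfg.w_min) and np.all(w <= cfg.w_max)
            assert np.all(cp.biases >= cfg.b_min)
            assert np.all(cp.biases <= cfg.b_max)

    def test_legend_roundtrip(self, ex1_spec, tmp_path):
        net, idx = build_module(ex1_spec, seed=0)
        text = idx.legend_dumps()
        rows = [
            ln.split("\t") for ln in text.splitlines() if not ln.startswith("#")
        ]
        assert len(rows) == len(net)
        roles = {r[1] for r in rows}
        assert "chi[x1=2]" in roles and "alpha[z=2][j=1]" in roles
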