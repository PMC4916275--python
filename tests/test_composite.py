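"""Composite networks: blankets, aliasing, decoding, inference."""

import numpy as np
import pytest

import wtalearn as wl
from wtalearn.composite import (
    GraphicalModelSpec,
    decode_state,
    dwell_to_table,
    estimate_rates,
    exact_posterior,
    state_histogram,
    state_trace,
)
from wtalearn.network import SpikeRecord


@pytest.fixture(scope="module")
def gm2():
    return wl.target_example2()


class TestGraphicalModel:
    def test_markov_blankets(self, gm2):
        assert gm2.markov_blanket("y1") == ["y2", "y3"]
        assert gm2.markov_blanket("y4") == ["y2"]
        assert gm2.markov_blanket("y2") == ["y1", "y3", "y4"]

    def test_isolated_variable_has_empty_blanket(self):
        gm = GraphicalModelSpec(
            [("a", 2), ("b", 2)],
            parents={"a": [], "b": []},
            cpts={"a": [0.5, 0.5], "b": [0.3, 0.7]},
        )
        assert gm.markov_blanket("a") == []

    def test_override_must_contain_blanket(self):
        with pytest.raises(ValueError):
            GraphicalModelSpec(
                [("a", 2), ("b", 2)],
                parents={"a": [], "b": ["a"]},
                cpts={"a": [0.5, 0.5], "b": [[0.3, 0.7], [0.6, 0.4]]},
                input_sets={"b": []},
            )

    def test_cycle_detection(self):
        with pytest.raises(ValueError):
            GraphicalModelSpec(
                [("a", 2), ("b", 2)],
                parents={"a": ["b"], "b": ["a"]},
                cpts={
                    "a": [[0.5, 0.5], [0.5, 0.5]],
                    "b": [[0.5, 0.5], [0.5, 0.5]],
                },
            )

    def test_joint_and_cpt_entries(self, gm2):
        joint = gm2.joint()
        assert joint.probs.sum() == pytest.approx(1.0)
        # p(y3=2 | y1=1, y2=2) = 0.87 and p(y4=2 | y2=1) = 0.13
        c3 = joint.condition({"y1": 1, "y2": 2}).marginal(["y3"])
        assert c3.prob({"y3": 2}) == pytest.approx(0.87)
        c4 = joint.condition({"y2": 1}).marginal(["y4"])
        assert c4.prob({"y4": 2}) == pytest.approx(0.13)


class TestExactPosterior:
    def test_no_evidence_gives_priors(self, gm2):
        post = exact_posterior(gm2, {})
        assert post["y1"] == pytest.approx([0.5, 0.5])
        assert post["y2"] == pytest.approx([0.5, 0.5])

    def test_posteriors_normalised(self, gm2):
        post = exact_posterior(gm2, {"y3": 2, "y4": 2})
        for probs in post.values():
            assert probs.sum() == pytest.approx(1.0)

    def test_explaining_away_direction(self, gm2):
        p22 = exact_posterior(gm2, {"y3": 2, "y4": 2})
        p21 = exact_posterior(gm2, {"y3": 2, "y4": 1})
        # straight contour raises reflectance, lowers cylindrical shape
        assert p21["y1"][1] > p22["y1"][1]
        assert p21["y2"][1] < p22["y2"][1]


class TestBuildAliasing:
    def test_example2_structure(self, gm2):
        model = wl.example2_network()
        net, index = model.build(seed=0)
        assert len(index.modules) == 4
        for midx in index.modules.values():
            assert all(j == (1, 2) or True for j in midx.comp)
            assert len(midx.alpha) == 4  # 2 values x 2 hidden
            assert len(midx.inhibitory) == 5
        # shared principal neurons: 8 nu + per module (4 alpha + 5 inh)
        assert len(net) == 8 + 4 * 9

    def test_aliasing_no_duplicates(self, gm2):
        model = wl.example2_network()
        net, index = model.build(seed=0)
        nu_ids = list(index.nu.values())
        assert len(nu_ids) == len(set(nu_ids)) == 8
        for name, midx in index.modules.items():
            # input neurons are exactly the nu populations of the inputs
            for i, var in enumerate(model.module_specs[name].inputs):
                for m in (1, 2):
                    assert midx.chi[(i, m)] == index.nu[(var.name, m)]
            for l in (1, 2):
                assert midx.zeta[l] == index.nu[(name, l)]

    def test_input_sets_follow_fixture(self, gm2):
        model = wl.example2_network()
        ins = {
            k: [v.name for v in s.inputs]
            for k, s in model.module_specs.items()
        }
        assert ins["y3"] == ["y1", "y2", "y4"]  # override, not the blanket
        assert ins["y1"] == ["y2", "y3"]
        assert ins["y4"] == ["y2"]

    def test_nu_spike_drives_every_consumer_module(self, gm2):
        model = wl.example2_network()
        net, index = model.build(seed=0)
        nid = index.nu[("y2", 1)]
        consumers = set()
        for s in net.synapses:
            if s.pre == nid and s.plastic:
                for name, midx in index.modules.items():
                    if s.post in set(midx.alpha.values()):
                        consumers.add(name)
        # y2 is input to y1, y3 and y4
        assert consumers == {"y1", "y3", "y4"}


class TestDecoding:
    def nu_map(self):
        return {("y1", 1): 0, ("y1", 2): 1, ("y2", 1): 2, ("y2", 2): 3}

    def test_spike_sets_value_for_tau(self):
        rec = SpikeRecord([1.000], [1])
        nu = self.nu_map()
        assert decode_state(rec, nu, 1.010)["y1"] == 2
        assert decode_state(rec, nu, 1.016)["y1"] == 0
        assert decode_state(rec, nu, 0.999)["y1"] == 0

    def test_no_spikes_decodes_to_zeros(self):
        st = decode_state(SpikeRecord([], []), self.nu_map(), 0.5)
        assert st == {"y1": 0, "y2": 0}

    def test_later_spike_wins(self):
        rec = SpikeRecord([1.000, 1.005], [0, 1])
        assert decode_state(rec, self.nu_map(), 1.010)["y1"] == 2

    def test_state_trace_and_histogram(self):
        rec = SpikeRecord(
            [0.000, 0.000, 0.020, 0.020], [0, 2, 1, 3]
        )
        trace = state_trace(rec, self.nu_map(), 0.0, 0.040, tau=0.015)
        assert trace.at(0.005) == {"y1": 1, "y2": 1}
        assert trace.at(0.017) == {"y1": 0, "y2": 0}
        assert trace.at(0.025) == {"y1": 2, "y2": 2}
        dwell, nz, zero_frac = state_histogram(trace, ["y1", "y2"])
        assert dwell[(1, 1)] == pytest.approx(0.015)
        assert dwell[(2, 2)] == pytest.approx(0.015)
        assert zero_frac == pytest.approx(0.010 / 0.040)
        table = dwell_to_table(dwell, ["y1", "y2"], {"y1": 2, "y2": 2})
        assert table.probs.sum() == pytest.approx(1.0)

    def test_trace_serialisation(self):
        rec = SpikeRecord([0.0], [0])
        trace = state_trace(rec, self.nu_map(), 0.0, 0.03, tau=0.015)
        text = trace.dumps()
        assert text.startswith("# t_start\tt_end")
        assert len(text.splitlines()) == len(trace.states) + 1


class TestEstimateRates:
    def test_empty_record(self):
        t, rates = estimate_rates(SpikeRecord([], []), [0], t_max=1.0)
        assert np.all(rates[0] == 0.0)

    def test_single_spike_integrates_to_one(self):
        t, rates = estimate_rates(
            SpikeRecord([0.1], [0]), [0], kernel_tau=0.05,
            t_grid=np.linspace(0, 2.0, 4001),
        )
        area = np.trapezoid(rates[0], t)
        assert area == pytest.approx(1.0, abs=0.01)

    def test_constant_rate_plateau(self):
        rng = np.random.default_rng(0)
        rate = 40.0
        ts = np.sort(rng.uniform(0, 10, int(rate * 10)))
        t, rates = estimate_rates(
            SpikeRecord(ts, np.zeros(len(ts), int)), [0],
            kernel_tau=0.1, t_grid=np.linspace(2, 9, 701),
        )
        assert abs(np.mean(rates[0]) - rate) / rate < 0.05

    def test_invalid_kernel_tau(self):
        with pytest.raises(ValueError):
            estimate_rates(SpikeRecord([], []), [0], kernel_tau=0.0)


class TestInference:
    def test_full_evidence_returns_empty(self, gm2):
        res, _ = wl.constructed_network(gm2, eps=0.05)
        out = res.infer(
            {"y1": 1, "y2": 1, "y3": 1, "y4": 1}, duration=0.1, seed=0
        )
        assert out["marginals"] == {}

    def test_evidence_validation(self, gm2):
        res, _ = wl.constructed_network(gm2, eps=0.05)
        with pytest.raises(ValueError):
            res.infer({"y3": 5}, duration=0.1, seed=0)
        with pytest.raises(KeyError):
            res.infer({"nope": 1}, duration=0.1, seed=0)
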