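"""Static network description and spike records.

A :class:`NetworkSpec` is the complete, serialisable description of a
network of stochastic point neurons: per-neuron bias and refractory
period, synapses with their PSP kernels and plasticity flags, and a
schedule of injected currents.  The simulator consumes a NetworkSpec and
produces a :class:`SpikeRecord`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .kernels import PSPKernel

__all__ = [
    "NeuronSpec",
    "SynapseSpec",
    "CurrentPulse",
    "CurrentSchedule",
    "NetworkSpec",
    "SpikeRecord",
]


@dataclass
class NeuronSpec:
    """One stochastic point neuron.

    ``bias`` enters the membrane potential additively (log-intensity
    units); the firing intensity is ``(1/refractory) * exp(u)`` outside
    the absolute refractory period of duration ``refractory`` seconds.
    """

    bias: float = 0.0
    refractory: float = 0.015
    is_inhibitory: bool = False
    plastic_bias: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.refractory <= 0:
            raise ValueError("refractory period must be > 0")


@dataclass
class SynapseSpec:
    pre: int
    post: int
    weight: float
    kernel: PSPKernel = field(default_factory=PSPKernel)
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.pre == self.post:
            raise ValueError("self-synapses are not supported")
        if not math.isfinite(self.weight):
            raise ValueError("synaptic weight must be finite")


@dataclass
class CurrentPulse:
    neuron: int
    amplitude: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("current pulse needs t_start < t_end")


class CurrentSchedule:
    """A list of current pulses, added linearly to u(t) while active."""

    def __init__(self, pulses: list[CurrentPulse] | None = None):
        self.pulses: list[CurrentPulse] = list(pulses or [])

    def add(self, neuron: int, amplitude: float, t_start: float, t_end: float) -> None:
        self.pulses.append(CurrentPulse(neuron, amplitude, t_start, t_end))

    def __len__(self) -> int:
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)


class NetworkSpec:
    """Neurons plus synapses; the unit the simulator operates on."""

    def __init__(self) -> None:
        self.neurons: list[NeuronSpec] = []
        self.synapses: list[SynapseSpec] = []

    def add_neuron(self, neuron: NeuronSpec) -> int:
        self.neurons.append(neuron)
        return len(self.neurons) - 1

    def add_synapse(self, syn: SynapseSpec) -> int:
        n = len(self.neurons)
        if not (0 <= syn.pre < n and 0 <= syn.post < n):
            raise ValueError("synapse endpoints out of range")
        self.synapses.append(syn)
        return len(self.synapses) - 1

    def __len__(self) -> int:
        return len(self.neurons)

    # -- serialization: key-value text, round-trippable bit-exactly ------

    def dumps(self) -> str:
        out = io.StringIO()
        out.write("wtalearn-network 1\n")
        out.write(f"neurons {len(self.neurons)}\n")
        for nr in self.neurons:
            out.write(
                "neuron\t%s\t%s\t%d\t%d\t%s\n"
                % (
                    float.hex(float(nr.bias)),
                    float.hex(float(nr.refractory)),
                    int(nr.is_inhibitory),
                    int(nr.plastic_bias),
                    nr.name or "-",
                )
            )
        out.write(f"synapses {len(self.synapses)}\n")
        for sy in self.synapses:
            k = sy.kernel
            out.write(
                "synapse\t%d\t%d\t%s\t%d\t%s\t%s\t%s\t%s\n"
                % (
                    sy.pre,
                    sy.post,
                    float.hex(float(sy.weight)),
                    int(sy.plastic),
                    k.kind,
                    float.hex(float(k.tau)),
                    float.hex(float(k.eps0)),
                    float.hex(float(k.tau_alpha)),
                )
            )
        return out.getvalue()

    @classmethod
    def loads(cls, text: str) -> "NetworkSpec":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("wtalearn-network"):
            raise ValueError("not a wtalearn network file")
        net = cls()
        for ln in lines[1:]:
            parts = ln.split("\t")
            head = parts[0]
            if head == "neuron":
                net.neurons.append(
                    NeuronSpec(
                        bias=float.fromhex(parts[1]),
                        refractory=float.fromhex(parts[2]),
                        is_inhibitory=bool(int(parts[3])),
                        plastic_bias=bool(int(parts[4])),
                        name="" if parts[5] == "-" else parts[5],
                    )
                )
            elif head == "synapse":
                kern = PSPKernel(
                    kind=parts[5],
                    tau=float.fromhex(parts[6]),
                    eps0=float.fromhex(parts[7]),
                    tau_alpha=float.fromhex(parts[8]),
                )
                net.synapses.append(
                    SynapseSpec(
                        pre=int(parts[1]),
                        post=int(parts[2]),
                        weight=float.fromhex(parts[3]),
                        kernel=kern,
                        plastic=bool(int(parts[4])),
                    )
                )
        return net

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.loads(fh.read())


class SpikeRecord:
    """Time-ordered spike events, ties broken by neuron id."""

    def __init__(self, times=None, neuron_ids=None):
        self.times = np.asarray(times if times is not None else [], dtype=float)
        self.neuron_ids = np.asarray(
            neuron_ids if neuron_ids is not None else [], dtype=np.int64
        )
        if self.times.shape != self.neuron_ids.shape:
            raise ValueError("times and neuron_ids must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def for_neuron(self, neuron_id: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron_id]

    def for_neurons(self, ids) -> "SpikeRecord":
        mask = np.isin(self.neuron_ids, list(ids))
        return SpikeRecord(self.times[mask], self.neuron_ids[mask])

    def rates(self, n_neurons: int, duration: float) -> np.ndarray:
        counts = np.bincount(self.neuron_ids, minlength=n_neurons)
        return counts / duration

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# time_s\tneuron_id\n")
            for t, i in zip(self.times, self.neuron_ids):
                fh.write("%.6f\t%d\n" % (t, i))

    @classmethod
    def load(cls, path) -> "SpikeRecord":
        times, ids = [], []
        with open(path) as fh:
            for ln in fh:
                if ln.startswith("#") or not ln.strip():
                    continue
                a, b = ln.split("\t")
                times.append(float(a))
                ids.append(int(b))
        return cls(times, ids)
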