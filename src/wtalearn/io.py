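"""Configuration files, run outputs and round-trippable serialisation.

All artefacts are plain text: YAML for configuration and manifests,
JSON for parameter trajectories, tab-separated tables for
distributions, spike records and legends.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .composite import CompositeNetwork, GraphicalModelSpec, NetworkFitResults
from .genmodel import DistributionTable
from .module import Checkpoint
from .experiments import FixtureConfig

__all__ = [
    "RunConfig",
    "load_run_config",
    "gm_to_yaml",
    "gm_from_yaml",
    "save_trajectories",
    "load_trajectories",
    "save_module_results",
    "load_module_results",
    "save_network_results",
    "load_network_results",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Fully resolved description of one run."""

    fixture: str = "example1"
    duration: float = 1200.0
    seed: int = 0
    checkpoint_every: float = 60.0
    hidden: int = 2
    kernel: str = "alpha"
    burn_in: float = 20.0
    sample_duration: float = 300.0
    out: str = "runs/out"

    def fixture_config(self) -> FixtureConfig:
        return FixtureConfig(
            name=self.fixture,
            duration=self.duration,
            checkpoint_every=self.checkpoint_every,
            hidden=self.hidden,
            kernel=self.kernel,
        )

    def dumps(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def gm_to_yaml(gm: GraphicalModelSpec) -> str:
    doc = {
        "variables": [[v.name, v.cardinality] for v in gm.variables],
    }
    if gm.parents is not None:
        doc["parents"] = {k: list(v) for k, v in gm.parents.items()}
        doc["cpts"] = {k: np.asarray(v).tolist() for k, v in gm.cpts.items()}
    else:
        doc["joint"] = {
            "values": [list(v) for _, v in gm.joint().variables],
            "probs": gm.joint().probs.tolist(),
        }
    if gm.input_sets:
        doc["input_sets"] = {k: list(v) for k, v in gm.input_sets.items()}
    return yaml.safe_dump(doc, sort_keys=False)


def gm_from_yaml(text: str) -> GraphicalModelSpec:
    doc = yaml.safe_load(text)
    variables = [tuple(v) for v in doc["variables"]]
    if "joint" in doc:
        values = doc["joint"]["values"]
        probs = np.asarray(doc["joint"]["probs"], dtype=float)
        names = [n for n, _ in variables]
        table = DistributionTable(list(zip(names, values)), probs)
        return GraphicalModelSpec(
            variables, joint=table, input_sets=doc.get("input_sets")
        )
    return GraphicalModelSpec(
        variables,
        parents=doc["parents"],
        cpts={k: np.asarray(v, dtype=float) for k, v in doc["cpts"].items()},
        input_sets=doc.get("input_sets"),
    )


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------


def _checkpoint_to_doc(cp: Checkpoint) -> dict:
    return {
        "t": cp.t,
        "weights": [w.tolist() for w in cp.weights],
        "biases": cp.biases.tolist(),
    }


def _checkpoint_from_doc(doc: dict) -> Checkpoint:
    return Checkpoint(
        t=float(doc["t"]),
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        biases=np.asarray(doc["biases"], dtype=float),
    )


def save_trajectories(trajectories: dict, path) -> None:
    doc = {
        name: [_checkpoint_to_doc(cp) for cp in traj]
        for name, traj in trajectories.items()
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_trajectories(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        name: [_checkpoint_from_doc(c) for c in cps]
        for name, cps in doc.items()
    }


def save_module_results(results, out_dir, config: RunConfig | None = None):
    """Persist a module fit: trajectory, legend, summary, manifest."""
    os.makedirs(out_dir, exist_ok=True)
    save_trajectories(
        {results.spec.output.name: results.trajectory},
        os.path.join(out_dir, "trajectory.json"),
    )
    with open(os.path.join(out_dir, "legend.tsv"), "w") as fh:
        fh.write(results.index.legend_dumps())
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write(results.summary() + "\n")
    results.fitted_joint().dump(os.path.join(out_dir, "final_joint.tsv"))
    if config is not None:
        write_manifest(out_dir, config)


def load_module_results(out_dir, config: RunConfig):
    from .module import ModuleFitResults

    fixture = config.fixture_config()
    model = fixture.build()
    trajs = load_trajectories(os.path.join(out_dir, "trajectory.json"))
    (name, traj), = trajs.items()
    _, index = model.build(seed=config.seed)
    return ModuleFitResults(
        model=model,
        trajectory=traj,
        index=index,
        target=fixture.target(),
        seed=config.seed,
    )


def save_network_results(results: NetworkFitResults, out_dir,
                         config: RunConfig | None = None):
    os.makedirs(out_dir, exist_ok=True)
    save_trajectories(
        results.trajectories, os.path.join(out_dir, "trajectory.json")
    )
    with open(os.path.join(out_dir, "legend.tsv"), "w") as fh:
        fh.write(results.index.legend_dumps())
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write(results.summary() + "\n")
    if config is not None:
        write_manifest(out_dir, config)


def load_network_results(out_dir, config: RunConfig) -> NetworkFitResults:
    fixture = config.fixture_config()
    model = fixture.build()
    if not isinstance(model, CompositeNetwork):
        raise ValueError(f"fixture {config.fixture!r} is not a network")
    trajs = load_trajectories(os.path.join(out_dir, "trajectory.json"))
    _, index = model.build(seed=config.seed)
    return NetworkFitResults(
        model=model, trajectories=trajs, index=index, seed=config.seed
    )


def write_manifest(out_dir, config: RunConfig) -> None:
    """Provenance: resolved config, its hash, and package versions."""
    os.makedirs(out_dir, exist_ok=True)
    text = config.dumps()
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        fh.write(text)
    import wtalearn

    manifest = {
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": config.seed,
        "wtalearn_version": wtalearn.__version__,
        "numpy_version": np.__version__,
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        fh.write(yaml.safe_dump(manifest, sort_keys=True))
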