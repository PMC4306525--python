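"""Serialisation of network models, priors and posteriors.

Network models round-trip through plain dictionaries and YAML/JSON documents;
posteriors are written as a JSON summary (names, means, free energy, noise
hyperparameters) plus a CSV covariance matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .inversion import Posterior, PriorSpec
from .nmm import Edge, ModulationSite, NetworkModel, Source, SourceParameters

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "save_posterior",
    "load_posterior",
]


def network_to_dict(model: NetworkModel) -> dict:
    return {
        "sources": [
            {
                "name": s.name, "hemisphere": s.hemisphere, "mni": list(s.mni),
                "level": s.level, "params": vars(s.params).copy(),
            }
            for s in model.sources
        ],
        "forward": [[e.src, e.dst, e.log_scale] for e in model.forward],
        "backward": [[e.src, e.dst, e.log_scale] for e in model.backward],
        "lateral": [[e.src, e.dst, e.log_scale] for e in model.lateral],
        "input_targets": list(model.input_targets),
        "conditions": list(model.conditions),
        "design_codes": [float(c) for c in model.design_codes],
        "modulation": [[m.kind, m.target, m.beta] for m in model.modulation],
        "delay_ms": model.delay_ms,
    }


def network_from_dict(d: dict) -> NetworkModel:
    sources = [
        Source(s["name"], s["hemisphere"], tuple(s["mni"]), s["level"],
               SourceParameters(**s["params"]))
        for s in d["sources"]
    ]
    return NetworkModel(
        sources=sources,
        forward=[Edge(*e) for e in d.get("forward", [])],
        backward=[Edge(*e) for e in d.get("backward", [])],
        lateral=[Edge(*e) for e in d.get("lateral", [])],
        input_targets=list(d.get("input_targets", [])),
        conditions=list(d["conditions"]),
        design_codes=[float(c) for c in d["design_codes"]],
        modulation=[ModulationSite(*m) for m in d.get("modulation", [])],
        delay_ms=float(d.get("delay_ms", 0.0)),
    )


def save_network(model: NetworkModel, path: str | Path) -> Path:
    """Write a model spec as YAML (default) or JSON (``.json`` suffix)."""
    path = Path(path)
    d = network_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_network(path: str | Path) -> NetworkModel:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return network_from_dict(d)


def save_posterior(post: Posterior, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "posterior.json").write_text(json.dumps(post.to_dict(), indent=1))
    np.savetxt(outdir / "covariance.csv", post.cov, delimiter=",", fmt="%.17g")
    return outdir


def load_posterior(outdir: str | Path) -> Posterior:
    outdir = Path(outdir)
    d = json.loads((outdir / "posterior.json").read_text())
    cov = np.atleast_2d(np.loadtxt(outdir / "covariance.csv", delimiter=","))
    return Posterior(
        names=d["names"], mean=np.asarray(d["mean"], float), cov=cov,
        log_precision=d["log_precision"], log_precision_var=np.nan,
        free_energy=d["free_energy"], f_trace=[d["free_energy"]],
        n_data=0, converged=d["converged"], warning=d["warning"],
    )
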