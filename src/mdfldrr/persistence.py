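"""Model persistence: one archive of named arrays plus a JSON metadata block.

The archive is a NumPy ``.npz`` container holding the projections, score
matrix, relation structure and training network, with catalog, feature
names/dimensions, hyperparameters and the objective history serialized as a
JSON string alongside the arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .datamodel import DrugCatalog
from .projection import Hyperparameters, ProjectionModel
from .relation import RelationStructure

__all__ = ["save_model", "load_model"]

_FORMAT_VERSION = 1


def save_model(model: ProjectionModel, path: str | Path) -> None:
    meta = {
        "format_version": _FORMAT_VERSION,
        "catalog": list(model.catalog.ids),
        "feature_names": list(model.feature_names),
        "descriptor_counts": [int(c) for c in model.descriptor_counts],
        "hyperparameters": asdict(model.hp),
        "theta_drr": model.relation.theta_drr,
        "relation_multiplier": model.relation.multiplier,
        "relation_iterations": model.relation.iterations_run,
        "relation_history": list(map(float, model.relation.residual_history)),
        "objective_history": list(map(float, model.objective_history)),
        "converged_at": int(model.converged_at),
    }
    arrays = {
        "S": model.S,
        "Y": model.Y,
        "M": model.relation.M,
        "J": model.J,
        "meta_json": np.array(json.dumps(meta)),
    }
    for i, Z in enumerate(model.Zs):
        arrays[f"Z_{i}"] = Z
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> ProjectionModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {meta.get('format_version')}")
        hp = Hyperparameters(**meta["hyperparameters"])
        relation = RelationStructure(
            data["M"],
            meta["theta_drr"],
            meta["relation_multiplier"],
            meta["relation_iterations"],
            meta["relation_history"],
        )
        Zs = [data[f"Z_{i}"] for i in range(len(meta["feature_names"]))]
        return ProjectionModel(
            Zs=Zs,
            S=data["S"],
            Y=data["Y"],
            hp=hp,
            relation=relation,
            catalog=DrugCatalog(tuple(meta["catalog"])),
            feature_names=meta["feature_names"],
            descriptor_counts=meta["descriptor_counts"],
            J=data["J"],
            objective_history=meta["objective_history"],
            converged_at=meta["converged_at"],
        )
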