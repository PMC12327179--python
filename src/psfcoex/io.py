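"""Model configuration files (YAML or JSON) and round-trip serialization.

Schema::

    environment: soil moisture          # name of the scalar variable v
    plants:
      labels: [A, B]
      r: {A: 1.0, B: 1.0}               # optional, default 1
      c: {A: {A: -0.06, B: -0.06},      # c[i][j]: effect of j on i
          B: {A: -0.05, B: -0.075}}
    microbes:
      - label: X
        g: 1.0                          # optional, default 1
        sigma: {A: 0.002, B: 0.0}       # effect of X on each plant
        phi:   {A: 10.0,  B: 0.0}       # cultivation of X by each plant
    scaling:
      - {target: sigma.A.X, intercept: 0.002, slope: -0.00015, clamp: false}

JSON is a YAML subset, so both parse through the same loader; the output
format follows the file extension.  Re-serializing a loaded config reproduces
every numeric value bit-exactly (floats are written in ``repr`` form).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .model import MicrobeTaxon, PlantParams, PSFModel, ScalingRule

__all__ = ["load_model", "model_from_dict", "model_to_dict", "save_model"]


def _require(mapping: dict, key: str, where: str, problems: list):
    if key not in mapping:
        problems.append(f"missing {key!r} in {where}")
        return None
    return mapping[key]


def model_from_dict(doc: dict, source: str = "<config>") -> PSFModel:
    """Build and validate a model; all schema failures reported together."""
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{source}: top level must be a mapping")
    problems: list[str] = []

    plants_doc = _require(doc, "plants", source, problems) or {}
    labels = plants_doc.get("labels", ["A", "B"])
    if not (isinstance(labels, (list, tuple)) and len(labels) == 2):
        problems.append("plants.labels must list exactly two plants")
        labels = ["A", "B"]
    labels = [str(x) for x in labels]

    r_doc = plants_doc.get("r", {})
    r = tuple(float(r_doc.get(lab, 1.0)) for lab in labels)

    c = np.zeros((2, 2))
    c_doc = _require(plants_doc, "c", f"{source}:plants", problems) or {}
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            try:
                c[i, j] = float(c_doc[li][lj])
            except (KeyError, TypeError):
                problems.append(f"missing or invalid entry at c.{li}.{lj}")

    microbes = []
    for k, m_doc in enumerate(doc.get("microbes", []) or []):
        label = m_doc.get("label", f"microbe{k}")
        sigma = tuple(float(m_doc.get("sigma", {}).get(lab, 0.0))
                      for lab in labels)
        phi = tuple(float(m_doc.get("phi", {}).get(lab, 0.0))
                    for lab in labels)
        try:
            microbes.append(MicrobeTaxon(label=str(label),
                                         g=float(m_doc.get("g", 1.0)),
                                         sigma=sigma, phi=phi))
        except ConfigurationError as exc:
            problems.append(str(exc))

    scaling = []
    for s_doc in doc.get("scaling", []) or []:
        target = s_doc.get("target")
        if target is None:
            problems.append("scaling rule without a target address")
            continue
        try:
            scaling.append(ScalingRule(
                target=str(target),
                intercept=float(s_doc.get("intercept", 0.0)),
                slope=float(s_doc.get("slope", 0.0)),
                clamp_nonnegative=bool(s_doc.get("clamp", False)),
            ))
        except (TypeError, ValueError):
            problems.append(f"invalid scaling rule for {target!r}")

    if problems:
        raise ConfigurationError(f"{source}: " + "; ".join(problems))
    try:
        return PSFModel(
            plants=PlantParams(labels=tuple(labels), r=r, c=c),
            microbes=tuple(microbes),
            scaling=tuple(scaling),
            env_name=str(doc.get("environment", "v")),
            name=str(doc.get("name", "")),
        )
    except ConfigurationError as exc:
        raise ConfigurationError(f"{source}: {exc}") from None


def load_model(path: str | Path) -> PSFModel:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: parse error: {exc}") from None
    return model_from_dict(doc, source=str(path))


def model_to_dict(model: PSFModel) -> dict:
    la, lb = model.plants.labels
    doc: dict = {
        "environment": model.env_name,
        "plants": {
            "labels": [la, lb],
            "r": {la: model.plants.r[0], lb: model.plants.r[1]},
            "c": {
                la: {la: float(model.plants.c[0, 0]),
                     lb: float(model.plants.c[0, 1])},
                lb: {la: float(model.plants.c[1, 0]),
                     lb: float(model.plants.c[1, 1])},
            },
        },
        "microbes": [
            {
                "label": t.label,
                "g": t.g,
                "sigma": {la: t.sigma[0], lb: t.sigma[1]},
                "phi": {la: t.phi[0], lb: t.phi[1]},
            }
            for t in model.microbes
        ],
        "scaling": [
            {
                "target": rule.target,
                "intercept": rule.intercept,
                "slope": rule.slope,
                "clamp": rule.clamp_nonnegative,
            }
            for rule in model.scaling
        ],
    }
    if model.name:
        doc["name"] = model.name
    return doc


def save_model(model: PSFModel, path: str | Path) -> None:
    path = Path(path)
    doc = model_to_dict(model)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
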