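"""Self-describing JSON serialization of fitted models.

The file carries the covariate schema, the encoded column names and the
standardization constants alongside the model parameters, so a saved model
can score a raw patient row with no other context.
"""

from __future__ import annotations

import json

import numpy as np

from .baselines import AFTModel, CoxModel
from .cohort import CovariateDesign, schema_from_dict, schema_to_dict
from .exceptions import ValidationError
from .mtlr import MTLRModel, MTLRParams, TimeGrid

__all__ = ["save_model", "load_model"]


def _design_payload(design: CovariateDesign) -> dict:
    # the schema is order-sensitive, so it is stored as a list of entries
    schema_list = [
        {"name": name, **entry} for name, entry in schema_to_dict(design.schema).items()
    ]
    return {
        "schema": schema_list,
        "column_names": list(design.column_names),
        "center": design.center.tolist(),
        "scale": design.scale.tolist(),
        "standardize": bool(design.standardize),
    }


def _design_from_payload(d: dict) -> CovariateDesign:
    names = list(d["column_names"])
    schema_map = {e["name"]: {k: v for k, v in e.items() if k != "name"}
                  for e in d["schema"]}
    return CovariateDesign(
        schema=schema_from_dict(schema_map),
        column_names=names,
        center=np.asarray(d["center"], dtype=float),
        scale=np.asarray(d["scale"], dtype=float),
        standardize=bool(d["standardize"]),
        matrix=np.empty((0, len(names))),
    )


def save_model(path, model, design: CovariateDesign) -> None:
    if isinstance(model, MTLRModel):
        payload = {
            "kind": "mtlr",
            "tau": model.grid.tau.tolist(),
            "W": model.params.W.tolist(),
            "b": model.params.b.tolist(),
            "lam": float(model.params.lam),
        }
    elif isinstance(model, CoxModel):
        payload = {
            "kind": "cox",
            "beta": model.beta.tolist(),
            "baseline_times": model.baseline_times.tolist(),
            "baseline_surv": model.baseline_surv.tolist(),
            "penalty": list(model.penalty) if model.penalty else None,
        }
    elif isinstance(model, AFTModel):
        payload = {
            "kind": "aft",
            "mu": float(model.mu),
            "gamma": model.gamma.tolist(),
            "sigma": float(model.sigma),
        }
    else:
        raise ValidationError(f"cannot serialize model of type {type(model).__name__}")
    payload["design"] = _design_payload(design)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_model(path):
    """Load a model JSON; returns (model, design)."""
    with open(path) as fh:
        d = json.load(fh)
    design = _design_from_payload(d["design"])
    kind = d.get("kind")
    if kind == "mtlr":
        params = MTLRParams(np.asarray(d["W"], dtype=float), np.asarray(d["b"], dtype=float),
                            float(d["lam"]))
        model = MTLRModel(params=params, grid=TimeGrid(np.asarray(d["tau"], dtype=float)),
                          column_names=list(design.column_names),
                          center=design.center, scale=design.scale)
    elif kind == "cox":
        model = CoxModel(
            beta=np.asarray(d["beta"], dtype=float),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_surv=np.asarray(d["baseline_surv"], dtype=float),
            penalty=tuple(d["penalty"]) if d.get("penalty") else None,
        )
    elif kind == "aft":
        model = AFTModel(mu=float(d["mu"]), gamma=np.asarray(d["gamma"], dtype=float),
                         sigma=float(d["sigma"]))
    else:
        raise ValidationError(f"unknown model kind {kind!r}")
    return model, design
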