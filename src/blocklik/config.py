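"""JSON model configuration: the canonical structured description of a
demographic model (an events list plus rates), or a named template with
keyword arguments and optional bound overrides.

Template form::

    {"template": "m2",
     "args": {"n_a": 1400, "t": 2.5},
     "bounds": {"T": [0.1, 10.0]},
     "free_r": true}

Explicit form::

    {"populations": [{"name": "S", "initial_size": 22000, "growth_rate": 0}],
     "events": [{"kind": "split_join", "time": 2.5,
                 "participants": ["B", "S"]}],
     "reference_size": 1400,
     "mutation_rate": 2e-8,
     "recombination_rate": 2e-8}
"""

from __future__ import annotations

import json

from . import templates
from .demography import DemographicEvent, DemographicModel, ParameterMap, PopulationSpec

__all__ = ["model_to_dict", "model_from_dict", "load_model_config", "TEMPLATES"]

TEMPLATES = {
    "m1": templates.m1,
    "m2": templates.m2,
    "m3": templates.m3,
    "m4": templates.m4,
    "m5": templates.m5,
    "m6": templates.m6,
    "single_population": templates.single_population,
}


def model_to_dict(model: DemographicModel) -> dict:
    return {
        "populations": [
            {
                "name": p.name,
                "initial_size": p.initial_size,
                "growth_rate": p.growth_rate,
            }
            for p in model.populations
        ],
        "events": [
            {
                "kind": e.kind,
                "time": e.time,
                "participants": list(e.participants),
                **({"value": e.value} if e.value is not None else {}),
            }
            for e in model.events
        ],
        "reference_size": model.reference_size,
        "mutation_rate": model.mutation_rate,
        "recombination_rate": model.recombination_rate,
    }


def model_from_dict(d: dict) -> DemographicModel:
    model = DemographicModel(
        populations=[
            PopulationSpec(
                p["name"], p["initial_size"], p.get("growth_rate", 0.0)
            )
            for p in d["populations"]
        ],
        events=[
            DemographicEvent(
                e["kind"], e["time"], tuple(e["participants"]), e.get("value")
            )
            for e in d["events"]
        ],
        reference_size=d["reference_size"],
        mutation_rate=d["mutation_rate"],
        recombination_rate=d.get("recombination_rate", 0.0),
    )
    model.validate()
    return model


def load_model_config(path) -> tuple[DemographicModel, ParameterMap | None]:
    """Load a model (and, for template configs, its parameter map)."""
    with open(path) as fh:
        d = json.load(fh)
    if "template" in d:
        name = d["template"]
        if name not in TEMPLATES:
            raise ValueError(
                f"unknown template {name!r}; available: {sorted(TEMPLATES)}"
            )
        kwargs = dict(d.get("args", {}))
        if "bounds" in d:
            if name == "single_population":
                kwargs["bounds"] = tuple(d["bounds"]["N"])
            else:
                kwargs["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        if "free_r" in d and name != "single_population":
            kwargs["free_r"] = d["free_r"]
        model, pmap = TEMPLATES[name](**kwargs)
        return model, pmap
    return model_from_dict(d), None
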