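"""YAML/JSON configuration loading for PBPK models and coupling specs.

Config schema (validated on load, units fixed package-wide):

.. code-block:: yaml

    compartments: [{name: venous, volume: 3.9, sub_space: vascular}, ...]
    flows: [{source: venous, target: arterial, rate: 5.0}, ...]
    species: [{name: ammonia, mw: 17.03, partition: {liver: 1.0}}, ...]
    processes:
      - {id: production, kind: zero_order_production, compartment: rest,
         species: ammonia, parameters: {rate: 0.85}}
    doses: [{species: drug, amount: 1469.4, route: oral, times: [0, 1440]}]
    oral_dose_compartment: gut_lumen

A coupling spec lists ``indirect_links``, ``direct_links`` and ``dt`` and
is validated against both the PBPK model and the network on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .coupling import DirectLink, IndirectLink, InhibitionParams, MultiscaleModel
from .network import MetabolicNetwork, Objective
from .pbpk import (
    Compartment,
    ConfigurationError,
    DoseEvent,
    Flow,
    KineticProcess,
    PBPKModel,
    Species,
)

__all__ = [
    "model_from_dict",
    "model_to_dict",
    "load_pbpk_config",
    "save_pbpk_config",
    "load_coupling_config",
]


def _read_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def model_from_dict(cfg: dict) -> PBPKModel:
    try:
        compartments = [Compartment(**c) for c in cfg["compartments"]]
        flows = [Flow(**f) for f in cfg.get("flows", [])]
        species = [Species(**s) for s in cfg["species"]]
        processes = [
            KineticProcess(
                id=p["id"], kind=p["kind"], compartment=p["compartment"],
                species=p["species"], parameters=dict(p.get("parameters", {})),
                products=[tuple(x) for x in p.get("products", [])],
            )
            for p in cfg.get("processes", [])
        ]
        doses = [
            DoseEvent(d["species"], d["amount"], d.get("route", "oral"),
                      tuple(d.get("times", [0.0])))
            for d in cfg.get("doses", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid PBPK config: {exc}") from exc
    return PBPKModel(
        compartments, flows, species, processes, doses,
        oral_dose_compartment=cfg.get("oral_dose_compartment"),
        iv_compartment=cfg.get("iv_compartment", "venous"),
    )


def model_to_dict(model: PBPKModel) -> dict:
    return {
        "compartments": [
            {"name": c.name, "volume": c.volume, "sub_space": c.sub_space}
            for c in model.compartments
        ],
        "flows": [{"source": f.source, "target": f.target, "rate": f.rate} for f in model.flows],
        "species": [
            {"name": s.name, "mw": s.mw, "partition": dict(s.partition)} for s in model.species
        ],
        "processes": [
            {
                "id": p.id, "kind": p.kind, "compartment": p.compartment,
                "species": p.species, "parameters": dict(p.parameters),
                "products": [list(x) for x in p.products],
            }
            for p in model.processes
        ],
        "doses": [
            {"species": d.species, "amount": d.amount, "route": d.route, "times": list(d.times)}
            for d in model.doses
        ],
        "oral_dose_compartment": model.oral_dose_compartment,
        "iv_compartment": model.iv_compartment,
    }


def load_pbpk_config(path: str | Path) -> PBPKModel:
    return model_from_dict(_read_structured(path))


def save_pbpk_config(model: PBPKModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False), encoding="utf-8")


def load_coupling_config(
    path: str | Path, pbpk: PBPKModel, network: MetabolicNetwork
) -> MultiscaleModel:
    """Build a validated :class:`MultiscaleModel` from a coupling spec file."""
    cfg = _read_structured(path)
    try:
        indirect = [
            IndirectLink(
                species=l["species"], compartment=l["compartment"], reaction=l["reaction"],
                params=InhibitionParams(
                    ki=l.get("ki"), ic50=l.get("ic50"),
                    max_inhibition=l.get("max_inhibition"),
                ),
            )
            for l in cfg.get("indirect_links", [])
        ]
        direct = [
            DirectLink(
                process=l["process"], exchange_reaction=l["exchange_reaction"],
                direction=l.get("direction", "uptake"),
                volume_basis=float(l.get("volume_basis", 1.0)),
            )
            for l in cfg.get("direct_links", [])
        ]
        objective = Objective({k: float(v) for k, v in cfg["objective"].items()})
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid coupling config: {exc}") from exc
    return MultiscaleModel(
        pbpk=pbpk, network=network, objective=objective,
        indirect_links=indirect, direct_links=direct,
        dt=float(cfg.get("dt", 1.0)),
        inhibition_mode=cfg.get("inhibition_mode", "competitive"),
    )
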