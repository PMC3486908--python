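"""Objective-panel robustness scans and flux-change classification.

Liver function is probed by a panel of FBA objectives (export-maximization
tasks).  For a given inhibition state (reaction/activity → relE), each
objective is first solved unperturbed to obtain its reference optimum and
reference flux vector; every inhibited reaction is then capped at
relE·|v0| (v0 = its flux in that objective's own reference solution) and
the objective re-solved.  The relative decrease of the optimum quantifies
how robust that liver function is to the perturbation; comparing the two
parsimonious flux vectors reaction-by-reaction reveals flux rerouting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coupling import constrain_flux
from .network import FluxDistribution, MetabolicNetwork, Objective, fba

__all__ = [
    "ObjectivePanel",
    "PanelReport",
    "evaluate_panel",
    "classify_flux_changes",
]


@dataclass
class ObjectivePanel:
    """Ordered list of (name, Objective, context bound overrides)."""

    entries: list[tuple[str, Objective, dict]]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("objective names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass
class PanelReport:
    """Per-objective reference vs perturbed optima for one inhibition state."""

    rows: list[dict]
    tol: float
    label: str = ""

    @property
    def affected(self) -> list[str]:
        return [r["objective"] for r in self.rows if r["affected"]]

    @property
    def affected_count(self) -> int:
        return len(self.affected)

    def decrease(self, objective: str) -> float:
        for r in self.rows:
            if r["objective"] == objective:
                return r["decrease"]
        raise KeyError(objective)

    def max_decrease(self) -> float:
        return max((r["decrease"] for r in self.rows), default=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        return json.dumps({"label": self.label, "tol": self.tol, "rows": self.rows}, indent=2)


def _resolve(network: MetabolicNetwork, name: str) -> list[str]:
    tagged = network.reactions_with_tag(name)
    if tagged:
        return [r.id for r in tagged]
    return [network.reaction(name).id]


def evaluate_panel(
    network: MetabolicNetwork,
    panel: ObjectivePanel,
    inhibition_state: dict[str, float],
    tol: float = 1e-6,
    equality_mode: bool = False,
    label: str = "",
) -> PanelReport:
    """Reference and inhibited optimum for every panel objective.

    ``inhibition_state`` maps a reaction id or activity tag to a relE in
    [0, 1].  By default the inhibited flux is *capped* at relE·|v0|;
    ``equality_mode=True`` instead fixes it there (the literal product
    rule), which can render some objectives infeasible — those are
    recorded with a perturbed optimum of 0 and flagged.
    """
    for name, relE in inhibition_state.items():
        if not 0.0 <= relE <= 1.0:
            raise ValueError(f"relE for {name!r} must be in [0, 1]")
    rows = []
    for name, objective, context in panel.entries:
        net = network.copy()
        for rid, bnds in (context or {}).items():
            net.set_bounds(rid, *bnds)
        ref = fba(net, objective)
        if not ref.optimal:
            rows.append({"objective": name, "reference": 0.0, "perturbed": 0.0,
                         "decrease": 0.0, "affected": False, "infeasible": True})
            continue
        overrides: dict = {}
        for target, relE in inhibition_state.items():
            for rid in _resolve(net, target):
                v0 = ref.values[rid]
                if equality_mode:
                    overrides[rid] = relE * v0
                else:
                    overrides[rid] = constrain_flux(net, rid, relE, v0)[1]
        pert = fba(net, objective, overrides)
        if pert.optimal:
            pval, infeasible = pert.objective_value, False
        else:
            pval, infeasible = 0.0, True
        if abs(ref.objective_value) < 1e-12:
            decrease = 0.0
        else:
            decrease = max(0.0, 1.0 - pval / ref.objective_value)
        rows.append({
            "objective": name,
            "reference": ref.objective_value,
            "perturbed": pval,
            "decrease": decrease,
            "affected": decrease > tol,
            "infeasible": infeasible,
        })
    return PanelReport(rows, tol, label)


def classify_flux_changes(
    reference: FluxDistribution,
    perturbed: FluxDistribution,
    tol: float = 1e-6,
) -> dict:
    """Classify per-reaction flux changes between two parsimonious solutions.

    Only reactions nonzero in at least one solution are compared.  Each is
    ``equal`` (|Δv| within tol·max magnitude), ``smaller``/``larger`` (by
    magnitude, for reactions active in the reference) or ``new`` (zero in
    the reference, active after perturbation).  Returns the counts, the
    compared-set size and the fraction unchanged.
    """
    if set(reference.values) != set(perturbed.values):
        raise ValueError("flux distributions cover different reaction sets")
    counts = {"equal": 0, "smaller": 0, "larger": 0, "new": 0}
    compared = 0
    for rid, vr in reference.values.items():
        vp = perturbed.values[rid]
        if vr == 0.0 and vp == 0.0:
            continue
        compared += 1
        if abs(vp - vr) <= tol * max(abs(vr), abs(vp)):
            counts["equal"] += 1
        elif vr == 0.0:
            counts["new"] += 1
        elif abs(vp) < abs(vr):
            counts["smaller"] += 1
        else:
            counts["larger"] += 1
    frac = counts["equal"] / compared if compared else 1.0
    return {**counts, "compared": compared, "fraction_unchanged": frac, "tol": tol}
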