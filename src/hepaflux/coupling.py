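"""Coupling of whole-body PBPK models to stoichiometric networks (dFBA).

Two coupling modes connect the organism scale to the cellular scale:

*Indirect coupling* (feed-forward): the tissue concentration of a compound
sets the relative activity of a target enzyme,

    relE(t) = 1 / (1 + I(t)/IC50)        (competitive, substrate at Km)

and the flux through the corresponding reaction is capped at
relE(t)·|v0|, where v0 is the flux in the unperturbed reference FBA
solution.  The inhibitor's own concentration is unaffected.

*Direct coupling* (feed-back): each step, (1) the PBPK kinetic rates of
the linked clearance/production processes are evaluated, (2) offered as
exchange-flux bounds to the network, (3) FBA is solved, (4) the resulting
exchange fluxes replace the PBPK process rates, and (5) the whole-body
model is integrated one interval with those rates held constant.  Without
internal impairment the FBA fluxes hit their offered bounds and the
coupled model reduces exactly to the PBPK model alone.

The scheduler :func:`simulate_coupled` iterates this loop at a fixed
interval (1 min by default), holding flux distributions piecewise
constant — the cell is assumed to re-equilibrate much faster than
whole-body distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import FluxDistribution, MetabolicNetwork, NetworkLoadError, Objective, fba
from .pbpk import PBPKModel, State, Trajectory, _rk4_step

logger = logging.getLogger(__name__)

__all__ = [
    "InhibitionParams",
    "IndirectLink",
    "DirectLink",
    "Event",
    "MultiscaleModel",
    "CoupledResult",
    "relative_activity",
    "combined_relative_activity",
    "ki_from_ic50",
    "calibrate_ki_to_max_inhibition",
    "constrain_flux",
    "dfba_step",
    "simulate_coupled",
]

_BOUND_EPS = 1e-9


# ---------------------------------------------------------------------------
# inhibition kinetics


@dataclass
class InhibitionParams:
    """Inhibition constants for one compound on one enzyme activity.

    Either ``ic50`` or ``ki`` must be given.  Under the substrate-at-Km
    convention used throughout (S = Km), the two are interchangeable via
    the Cheng-Prusoff relation IC50 = 2·Ki.
    """

    ki: float | None = None
    ic50: float | None = None
    km_assumption: bool = True
    max_inhibition: float | None = None

    def __post_init__(self) -> None:
        if self.ki is None and self.ic50 is None:
            raise ValueError("need at least one of ki / ic50")
        if (self.ki is not None and self.ki <= 0) or (self.ic50 is not None and self.ic50 <= 0):
            raise ValueError("ki and ic50 must be > 0")

    @property
    def effective_ic50(self) -> float:
        return self.ic50 if self.ic50 is not None else 2.0 * self.ki


def relative_activity(I: float, params: InhibitionParams, mode: str = "competitive") -> float:
    """Relative enzyme activity relE = v(I)/v0 in [0, 1].

    Competitive inhibition with substrate at Km gives
    relE = 1/(1 + I/IC50), so relE(IC50) = 0.5 by construction.  A
    noncompetitive variant (same algebra at S = Km) is available behind
    ``mode="noncompetitive"``, where I is referenced to Ki = IC50/2.
    """
    if I < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    ic50 = params.effective_ic50
    if mode == "competitive":
        return 1.0 / (1.0 + I / ic50)
    if mode == "noncompetitive":
        return 1.0 / (1.0 + I / (ic50 / 2.0))
    raise ValueError(f"unknown inhibition mode {mode!r}")


def combined_relative_activity(
    inhibitors: list[tuple[float, InhibitionParams]], mode: str = "competitive"
) -> float:
    """relE under several inhibitors of one enzyme.

    Purine-analog pairs (e.g. a drug and its active metabolite) compete for
    the same site, so competitive terms add in the denominator:
    relE = 1/(1 + Σ Iᵢ/IC50ᵢ).  Noncompetitive contributions multiply.
    """
    if not inhibitors:
        return 1.0
    if mode == "competitive":
        s = 0.0
        for I, p in inhibitors:
            if I < 0:
                raise ValueError("inhibitor concentration must be >= 0")
            s += I / p.effective_ic50
        return 1.0 / (1.0 + s)
    out = 1.0
    for I, p in inhibitors:
        out *= relative_activity(I, p, mode)
    return out


def ki_from_ic50(ic50: float, S: float, Km: float) -> float:
    """Cheng-Prusoff relation for competitive inhibition: Ki = IC50/(1 + S/Km)."""
    if ic50 <= 0 or S < 0 or Km <= 0:
        raise ValueError("ic50 and Km must be > 0, S >= 0")
    return ic50 / (1.0 + S / Km)


def calibrate_ki_to_max_inhibition(c_max: float, max_inhibition: float) -> float:
    """Ki such that relE(c_max) = 1 − max_inhibition under the module's rate law.

    Used when no measured IC50 exists: the peak inhibitor concentration of
    the worst-case exposure is assumed to produce the literature-reported
    maximal loss of activity.  Inverting relE = 1/(1 + I/(2·Ki)):
    Ki = c_max·(1 − max_inhibition)/(2·max_inhibition).
    """
    if c_max <= 0:
        raise ValueError("c_max must be > 0")
    if not 0.0 < max_inhibition < 1.0:
        raise ValueError("max_inhibition must be strictly between 0 and 1")
    ic50 = c_max * (1.0 - max_inhibition) / max_inhibition
    return ic50 / 2.0


def constrain_flux(
    network: MetabolicNetwork, reaction: str, relE: float, v0: float
) -> tuple[str, tuple[float, float]]:
    """Bound override capping |flux| through ``reaction`` at relE·|v0|.

    The cap preserves the sign of the reference flux v0 and is applied as
    a magnitude cap (|v| ≤ relE·|v0|) intersected with the reaction's own
    bounds, rather than an equality — an equality could render unrelated
    objectives infeasible.
    """
    if not 0.0 <= relE <= 1.0:
        raise ValueError("relE must be in [0, 1]")
    r = network.reaction(reaction)  # raises for unknown ids
    cap = relE * abs(v0)
    lb = max(r.lower_bound, -cap) if v0 <= 0 else max(r.lower_bound, 0.0)
    ub = min(r.upper_bound, cap) if v0 >= 0 else min(r.upper_bound, 0.0)
    if lb > ub:  # cap conflicts with a demand bound; clamp to the cap
        lb = -cap if v0 <= 0 else 0.0
        ub = cap if v0 >= 0 else 0.0
    return r.id, (lb, ub)


# ---------------------------------------------------------------------------
# link and model types


@dataclass
class IndirectLink:
    """compound concentration (PBPK) → relE cap on one network reaction.

    ``reaction`` may name a reaction id or an activity tag shared by
    several reactions (one enzyme catalyzing consecutive steps); every
    tagged reaction is capped with the same relE against its own v0.
    """

    species: str
    compartment: str
    reaction: str
    params: InhibitionParams


@dataclass
class DirectLink:
    """PBPK clearance/production process ↔ network exchange reaction.

    ``volume_basis`` (liters) converts between the network's volumetric
    flux (µmol/L/min) and the PBPK amount rate (µmol/min).
    """

    process: str
    exchange_reaction: str
    direction: str = "uptake"  # or "secretion"
    volume_basis: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("uptake", "secretion"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.volume_basis <= 0:
            raise ValueError("volume_basis must be > 0")


@dataclass
class Event:
    """A timed modification of the runtime network/links (snaps to the grid)."""

    time: float
    apply: object  # callable(network: MetabolicNetwork) -> None
    label: str = ""


@dataclass
class MultiscaleModel:
    """A PBPK model, a metabolic network, and the links between them."""

    pbpk: PBPKModel
    network: MetabolicNetwork
    objective: Objective
    indirect_links: list[IndirectLink] = field(default_factory=list)
    direct_links: list[DirectLink] = field(default_factory=list)
    dt: float = 1.0
    inhibition_mode: str = "competitive"
    # optional time-dependent enzyme-activity schedules (disease protocols):
    # reaction id or tag -> callable(t_min) -> relE in [0, 1]
    activity_schedules: dict = field(default_factory=dict)
    reuse_slack_solutions: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for l in self.indirect_links:
            self.pbpk.get_species(l.species)
            self.pbpk.compartment(l.compartment)
            self._resolve_targets(l.reaction)
        for l in self.direct_links:
            self.pbpk.process(l.process)
            r = self.network.reaction(l.exchange_reaction)
            if not r.is_exchange:
                raise NetworkLoadError(f"direct link target {r.id!r} is not an exchange reaction")

    def _resolve_targets(self, name: str) -> list[str]:
        """Resolve a reaction id or activity tag to concrete reaction ids."""
        tagged = self.network.reactions_with_tag(name)
        if tagged:
            return [r.id for r in tagged]
        return [self.network.reaction(name).id]

    def reference_fluxes(self) -> FluxDistribution:
        """Unperturbed reference solution v(0) for the model's objective."""
        sol = fba(self.network, self.objective)
        if not sol.optimal:
            raise NetworkLoadError(f"reference FBA is {sol.status}; cannot define v0")
        return sol


@dataclass
class CoupledResult:
    """Synchronized whole-body trajectory and per-step flux distributions."""

    trajectory: Trajectory
    flux_times: np.ndarray          # start time of each coupling interval
    fluxes: np.ndarray              # (n_steps, n_reactions)
    reaction_ids: list[str]
    relE_series: dict               # target reaction -> np.ndarray per step
    events_applied: list[str] = field(default_factory=list)
    fallback_steps: int = 0

    def flux_series(self, rid: str) -> np.ndarray:
        return self.fluxes[:, self.reaction_ids.index(rid)]

    def flux_frame(self):
        """Tidy DataFrame: time_min, reaction_id, flux."""
        import pandas as pd

        n = len(self.flux_times)
        return pd.DataFrame(
            {
                "time_min": np.repeat(self.flux_times, len(self.reaction_ids)),
                "reaction_id": self.reaction_ids * n,
                "flux": self.fluxes.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# the dFBA loop


class _Runtime:
    """Mutable per-simulation context: network copy, caches, reference fluxes."""

    def __init__(self, ms: MultiscaleModel):
        self.ms = ms
        self.network = ms.network.copy()
        self.compiled = ms.pbpk.compile()
        self.v0 = ms.reference_fluxes()
        self.cache: dict = {}
        self.version = 0
        self.last_key = None
        self.last_direct: dict[str, float] = {}
        self.last_solution: FluxDistribution | None = None
        self.fallbacks = 0

    def invalidate(self) -> None:
        self.version += 1
        self.cache.clear()
        self.last_key = None
        self.last_solution = None

    # ---- per-step constraint assembly ----------------------------------
    def assemble(self, state: State, t: float):
        ms = self.ms
        comp = self.compiled
        # (1) PBPK kinetic rates -> offered exchange bounds
        direct_over: dict[str, tuple[float, float]] = {}
        offered: dict[str, float] = {}
        for link in ms.direct_links:
            rate = comp.process_rate(link.process, state.amounts)  # µmol/min
            off = max(rate / link.volume_basis, 0.0)  # µmol/L/min
            r = self.network.reaction(link.exchange_reaction)
            ub = min(off, r.upper_bound)
            lb = min(r.lower_bound, ub)
            direct_over[r.id] = (lb, ub)
            offered[r.id] = off
        # (2) indirect inhibition caps from current tissue concentrations
        groups: dict[str, list] = {}
        for link in ms.indirect_links:
            c = ms.pbpk.compartment(link.compartment)
            ci = comp.comp_index[link.compartment]
            si = comp.spec_index[link.species]
            I = state.amounts[si, ci] / c.volume
            for rid in ms._resolve_targets(link.reaction):
                groups.setdefault(rid, []).append((I, link.params))
        relE_map: dict[str, float] = {}
        for rid, inhibitors in groups.items():
            # quantized at 1e-4 so near-identical inhibition states share one
            # cached LP solution; well below every other model tolerance
            relE_map[rid] = round(combined_relative_activity(inhibitors, ms.inhibition_mode), 4)
        # (3) scheduled activities (e.g. a progressive enzyme deficiency)
        for name, sched in ms.activity_schedules.items():
            relE_t = float(np.clip(sched(t), 0.0, 1.0))
            for rid in ms._resolve_targets(name):
                relE_map[rid] = relE_map.get(rid, 1.0) * relE_t
        indirect_over: dict[str, tuple[float, float]] = {}
        for rid, relE in relE_map.items():
            _, bnds = constrain_flux(self.network, rid, relE, self.v0.values.get(rid, 0.0))
            indirect_over[rid] = bnds
        return direct_over, indirect_over, offered, relE_map

    def solve(self, direct_over, indirect_over) -> FluxDistribution:
        ms = self.ms
        q = lambda x: round(float(x), 9) if np.isfinite(x) else x
        key = (
            self.version,
            tuple(sorted((r, q(b[0]), q(b[1])) for r, b in direct_over.items())),
            tuple(sorted((r, q(b[0]), q(b[1])) for r, b in indirect_over.items())),
        )
        if key == self.last_key and self.last_solution is not None:
            return self.last_solution
        # slack-reuse: if only direct exchange bounds moved and the previous
        # solution keeps strict slack in both the old and new bound, the old
        # optimum remains optimal (tightening or relaxing a non-binding
        # availability bound cannot change the uptake-limited optimum).
        if (
            ms.reuse_slack_solutions
            and self.last_solution is not None
            and self.last_key is not None
            and key[0] == self.last_key[0]
            and key[2] == self.last_key[2]
        ):
            old_direct = dict((r, (l, u)) for r, l, u in self.last_key[1])
            ok = set(direct_over) == set(old_direct)
            if ok:
                for rid, (lb, ub) in direct_over.items():
                    olb, oub = old_direct[rid]
                    flux = self.last_solution.values.get(rid, 0.0)
                    if (q(lb), q(ub)) == (olb, oub):
                        continue
                    if lb != olb or not (flux <= ub - _BOUND_EPS and flux <= oub - _BOUND_EPS):
                        ok = False
                        break
                if ok:
                    self.last_key = key
                    return self.last_solution
        sol = self.cache.get(key)
        if sol is None:
            overrides = {**direct_over, **indirect_over}
            sol = fba(self.network, ms.objective, overrides)
            if len(self.cache) < 200_000:
                self.cache[key] = sol
        self.last_key = key
        self.last_solution = sol
        return sol


def dfba_step(
    ms: MultiscaleModel,
    state: State,
    runtime: _Runtime | None = None,
    sub_steps: int = 1,
) -> tuple[State, FluxDistribution]:
    """Advance the coupled model one interval; returns (new state, fluxes).

    Implements the five-step feedback loop: evaluate PBPK kinetic rates,
    offer them as exchange bounds, solve FBA (with inhibition caps), push
    the exchange fluxes back as constant PBPK rates, integrate one dt.
    On an infeasible FBA the linked rates fall back to zero for this step
    and the event is logged.
    """
    rt = runtime or _Runtime(ms)
    sub_steps = rt.compiled.stable_sub_steps(ms.dt, sub_steps)
    t = state.time
    direct_over, indirect_over, _offered, _relE = rt.assemble(state, t)
    sol = rt.solve(direct_over, indirect_over)
    rate_overrides: dict[str, float] = {}
    if sol.optimal:
        for link in ms.direct_links:
            flux = sol.values.get(link.exchange_reaction, 0.0)
            rate_overrides[link.process] = flux * link.volume_basis
    else:
        rt.fallbacks += 1
        logger.warning("FBA %s at t=%.1f min; linked rates set to 0 for this step", sol.status, t)
        for link in ms.direct_links:
            rate_overrides[link.process] = 0.0
    amounts = _rk4_step(rt.compiled, state.amounts.copy(), ms.dt, sub_steps, rate_overrides)
    if not np.all(np.isfinite(amounts)):
        raise RuntimeError(f"non-finite state in coupled step at t={t:.1f}")
    return State(t + ms.dt, amounts), sol


def simulate_coupled(
    ms: MultiscaleModel,
    duration: float,
    events: list[Event] | None = None,
    init: State | None = None,
    sub_steps: int = 1,
) -> CoupledResult:
    """Run the dFBA scheduler for ``duration`` minutes.

    ``events`` modify the runtime network (bounds, schedules) at their
    activation time, which snaps to the coupling grid.  Returns the
    synchronized concentration trajectory and the per-interval flux
    distributions.
    """
    events = sorted(events or [], key=lambda e: e.time)
    if any(b.time < a.time for a, b in zip(events, events[1:])):  # pragma: no cover
        raise ValueError("events must be sorted")
    rt = _Runtime(ms)
    sub_steps = rt.compiled.stable_sub_steps(ms.dt, sub_steps)
    n_steps = int(round(duration / ms.dt))
    state = init.copy() if init is not None else State(0.0, ms.pbpk.zero_state().amounts)
    comp = rt.compiled
    times = state.time + ms.dt * np.arange(n_steps + 1)
    traj = np.empty((n_steps + 1,) + state.amounts.shape)
    traj[0] = state.amounts
    rxn_ids = rt.network.reaction_ids
    fluxes = np.zeros((n_steps, len(rxn_ids)))
    relE_series: dict[str, list[float]] = {}
    applied: list[str] = []
    ev_i = 0
    for i in range(n_steps):
        t = times[i]
        while ev_i < len(events) and events[ev_i].time <= t + 0.5 * ms.dt:
            events[ev_i].apply(rt.network)
            applied.append(events[ev_i].label or f"event@{events[ev_i].time:g}")
            rt.invalidate()
            ev_i += 1
        # dose events of the PBPK model fire on the coupling grid as well
        from .pbpk import _apply_doses

        _apply_doses(ms.pbpk, comp, state.amounts, t, t + ms.dt)
        direct_over, indirect_over, _offered, relE_map = rt.assemble(state, t)
        sol = rt.solve(direct_over, indirect_over)
        for rid, val in relE_map.items():
            relE_series.setdefault(rid, [np.nan] * i).append(val)
        rate_overrides: dict[str, float] = {}
        if sol.optimal:
            for j, rid in enumerate(rxn_ids):
                fluxes[i, j] = sol.values[rid]
            for link in ms.direct_links:
                rate_overrides[link.process] = sol.values.get(link.exchange_reaction, 0.0) * link.volume_basis
        else:
            rt.fallbacks += 1
            logger.warning("FBA %s at t=%.1f min; linked rates zeroed", sol.status, t)
            for link in ms.direct_links:
                rate_overrides[link.process] = 0.0
        amounts = _rk4_step(comp, state.amounts.copy(), ms.dt, sub_steps, rate_overrides)
        if not np.all(np.isfinite(amounts)):
            raise RuntimeError(f"non-finite state in coupled run at t={t:.1f}")
        state = State(t + ms.dt, amounts)
        traj[i + 1] = amounts
    for rid, series in relE_series.items():
        if len(series) < n_steps:
            series.extend([np.nan] * (n_steps - len(series)))
    return CoupledResult(
        trajectory=Trajectory(ms.pbpk, times, traj),
        flux_times=times[:-1],
        fluxes=fluxes,
        reaction_ids=rxn_ids,
        relE_series={k: np.asarray(v) for k, v in relE_series.items()},
        events_applied=applied,
        fallback_steps=rt.fallbacks,
    )
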