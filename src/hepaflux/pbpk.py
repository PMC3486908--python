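"""Whole-body physiologically-based pharmacokinetic (PBPK) ODE engine.

A :class:`PBPKModel` is a compartmental mass-balance model: organs are
well-stirred compartments connected by blood flows, compounds distribute
between blood and tissue through dimensionless partition coefficients, and
absorption, metabolization and excretion are represented by simple kinetic
processes (first-order, Michaelis-Menten, zero-order production, first-order
oral absorption).

Units are fixed throughout the package:

* volumes in liters, flows in L/min, time in minutes
* amounts in µmol, concentrations in µM (= µmol/L)
* zero-order production rates and Michaelis-Menten Vmax in µmol/L/min,
  normalized to the volume of the compartment hosting the process
* first-order rate constants in 1/min

The integrator is a fixed-step explicit Runge-Kutta (RK4) scheme on the
reporting grid, with optional sub-stepping inside each reporting interval.
A fixed step is deliberate: the dynamic-FBA coupling layer holds cellular
exchange fluxes piecewise constant over each interval, so the outer model
must advance on the same grid.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "Compartment",
    "Flow",
    "Species",
    "KineticProcess",
    "DoseEvent",
    "PBPKModel",
    "State",
    "Trajectory",
    "SteadyStateResult",
    "CalibrationResult",
    "ConfigurationError",
    "IntegrationError",
    "simulate",
    "steady_state",
    "linear_steady_state",
    "link_metabolite",
    "calibrate",
    "local_sensitivity",
]

PROCESS_KINDS = ("first_order", "michaelis_menten", "zero_order_production", "oral_absorption")
SUB_SPACES = ("vascular", "interstitial", "intracellular", "lumen", "lumped")


class ConfigurationError(ValueError):
    """Raised when a model references unknown elements or violates invariants."""


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass
class Compartment:
    """A well-stirred space with a physical volume in liters."""

    name: str
    volume: float
    sub_space: str = "lumped"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ConfigurationError(f"compartment {self.name!r}: volume must be > 0")
        if self.sub_space not in SUB_SPACES:
            raise ConfigurationError(f"compartment {self.name!r}: unknown sub_space {self.sub_space!r}")


@dataclass
class Flow:
    """Directed convective transport between two compartments (L/min)."""

    source: str
    target: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError(f"flow {self.source}->{self.target}: rate must be >= 0")
        if self.source == self.target:
            raise ConfigurationError(f"flow {self.source}->{self.target}: source == target")


@dataclass
class Species:
    """A compound with molecular weight and per-compartment partition coefficients.

    ``partition`` maps compartment name -> K (dimensionless, > 0).  The
    effective concentration a compartment presents to its outflows is
    C/K, i.e. the classical perfusion-limited well-stirred tissue model:
    net tissue uptake is Q·(C_in/K_in − C_tissue/K_tissue).  Compartments
    absent from the map use K = 1 (blood-like).
    """

    name: str
    mw: float = 0.0
    partition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp, k in self.partition.items():
            if k <= 0:
                raise ConfigurationError(f"species {self.name!r}: partition coefficient for {comp!r} must be > 0")


@dataclass
class KineticProcess:
    """A kinetic source/sink/transfer attached to one compartment and species.

    kinds and parameters
    --------------------
    ``first_order``            elimination, ``k`` (1/min); rate = k·A
    ``michaelis_menten``       elimination, ``vmax`` (µmol/L/min), ``km`` (µM);
                               rate = Vmax·C/(Km + C)·V
    ``zero_order_production``  production, ``rate`` (µmol/L/min); rate·V
    ``oral_absorption``        transfer, ``ka`` (1/min), ``to`` (compartment);
                               moves ka·A from the lumen to ``to``

    Elimination processes may declare ``products``: a list of
    ``(species_name, yield)`` pairs formed in the same compartment at
    yield × elimination rate (metabolite chaining).
    """

    id: str
    kind: str
    compartment: str
    species: str
    parameters: dict[str, float] = field(default_factory=dict)
    products: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise ConfigurationError(f"process {self.id!r}: unknown kind {self.kind!r}")
        p = self.parameters
        if self.kind == "first_order" and p.get("k", 0.0) < 0:
            raise ConfigurationError(f"process {self.id!r}: k must be >= 0")
        if self.kind == "michaelis_menten":
            if p.get("vmax", 0.0) < 0:
                raise ConfigurationError(f"process {self.id!r}: vmax must be >= 0")
            if p.get("km", 0.0) <= 0:
                raise ConfigurationError(f"process {self.id!r}: km must be > 0")
        if self.kind == "zero_order_production" and p.get("rate", 0.0) < 0:
            raise ConfigurationError(f"process {self.id!r}: rate must be >= 0")
        if self.kind == "oral_absorption":
            if p.get("ka", 0.0) < 0:
                raise ConfigurationError(f"process {self.id!r}: ka must be >= 0")
            if "to" not in p:
                raise ConfigurationError(f"process {self.id!r}: oral_absorption needs a 'to' compartment")


@dataclass
class DoseEvent:
    """Administration of a species: oral (into the lumen) or intravenous."""

    species: str
    amount: float
    route: str = "oral"
    times: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ConfigurationError(f"dose of {self.species!r}: amount must be > 0")
        if self.route not in ("oral", "intravenous"):
            raise ConfigurationError(f"dose of {self.species!r}: unknown route {self.route!r}")
        ts = tuple(float(t) for t in self.times)
        if any(t < 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigurationError(f"dose of {self.species!r}: times must be non-negative, strictly increasing")
        self.times = ts


@dataclass
class State:
    """Time plus the full amount matrix (n_species × n_compartments), µmol."""

    time: float
    amounts: np.ndarray  # shape (n_species, n_compartments)

    def copy(self) -> "State":
        return State(self.time, self.amounts.copy())


@dataclass
class SteadyStateResult:
    state: State
    converged: bool
    time: float
    max_rel_change_per_hour: float


@dataclass
class CalibrationResult:
    parameters: dict[str, float]
    residuals: list[float]
    cost: float
    identifiable: bool


class PBPKModel:
    """The whole-body model: compartments, flows, species, processes, doses."""

    def __init__(
        self,
        compartments: list[Compartment],
        flows: list[Flow],
        species: list[Species],
        processes: list[KineticProcess],
        doses: list[DoseEvent] | None = None,
        oral_dose_compartment: str | None = None,
        iv_compartment: str = "venous",
    ) -> None:
        self.compartments = list(compartments)
        self.flows = list(flows)
        self.species = list(species)
        self.processes = list(processes)
        self.doses = list(doses or [])
        self.oral_dose_compartment = oral_dose_compartment
        self.iv_compartment = iv_compartment
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def compartment_names(self) -> list[str]:
        return [c.name for c in self.compartments]

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def total_volume(self) -> float:
        """Sum of all compartment volumes, liters."""
        return float(sum(c.volume for c in self.compartments))

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown compartment {name!r}")

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise ConfigurationError(f"unknown species {name!r}")

    def process(self, pid: str) -> KineticProcess:
        for p in self.processes:
            if p.id == pid:
                return p
        raise ConfigurationError(f"unknown process {pid!r}")

    def copy(self) -> "PBPKModel":
        return _copy.deepcopy(self)

    # -- parameter addressing (used by calibrate / sensitivity) ----------
    def get_param(self, path: str) -> float:
        """Read a scalar parameter by path ``process:<id>:<name>``."""
        kind, pid, name = path.split(":")
        if kind != "process":
            raise ConfigurationError(f"unsupported parameter path {path!r}")
        return float(self.process(pid).parameters[name])

    def set_param(self, path: str, value: float) -> None:
        kind, pid, name = path.split(":")
        if kind != "process":
            raise ConfigurationError(f"unsupported parameter path {path!r}")
        proc = self.process(pid)
        if name not in proc.parameters:
            raise ConfigurationError(f"process {pid!r} has no parameter {name!r}")
        proc.parameters[name] = float(value)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        names = self.compartment_names
        if len(set(names)) != len(names):
            raise ConfigurationError("compartment names must be unique")
        snames = self.species_names
        if len(set(snames)) != len(snames):
            raise ConfigurationError("species names must be unique")
        for f in self.flows:
            if f.source not in names or f.target not in names:
                raise ConfigurationError(f"flow {f.source}->{f.target} references unknown compartment")
        for s in self.species:
            for comp in s.partition:
                if comp not in names:
                    raise ConfigurationError(f"species {s.name!r}: partition references unknown compartment {comp!r}")
        pids = [p.id for p in self.processes]
        if len(set(pids)) != len(pids):
            raise ConfigurationError("process ids must be unique")
        for p in self.processes:
            if p.compartment not in names:
                raise ConfigurationError(f"process {p.id!r}: unknown compartment {p.compartment!r}")
            if p.species not in snames:
                raise ConfigurationError(f"process {p.id!r}: unknown species {p.species!r}")
            if p.kind == "oral_absorption" and p.parameters["to"] not in names:
                raise ConfigurationError(f"process {p.id!r}: unknown target compartment {p.parameters['to']!r}")
            for prod, _y in p.products:
                if prod not in snames:
                    raise ConfigurationError(f"process {p.id!r}: unknown product species {prod!r}")
        for d in self.doses:
            if d.species not in snames:
                raise ConfigurationError(f"dose references unknown species {d.species!r}")
            if d.route == "oral":
                comp = self.oral_dose_compartment
                if comp is None or comp not in names:
                    raise ConfigurationError("oral dose requires a valid oral_dose_compartment")
            elif self.iv_compartment not in names:
                raise ConfigurationError("intravenous dose requires a valid iv_compartment")
        if len(names) > 1 and self.flows:
            self._check_connected(names)

    def _check_connected(self, names: list[str]) -> None:
        adj: dict[str, set[str]] = {n: set() for n in names}
        for f in self.flows:
            adj[f.source].add(f.target)
            adj[f.target].add(f.source)
        for p in self.processes:  # absorption transfers connect lumen spaces
            if p.kind == "oral_absorption":
                adj[p.compartment].add(p.parameters["to"])
                adj[p.parameters["to"]].add(p.compartment)
        seen = {names[0]}
        stack = [names[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        missing = set(names) - seen
        if missing:
            raise ConfigurationError(f"flow graph not connected; unreachable: {sorted(missing)}")

    # -- compiled form ---------------------------------------------------
    def compile(self) -> "_Compiled":
        return _Compiled(self)

    def zero_state(self) -> State:
        return State(0.0, np.zeros((len(self.species), len(self.compartments))))


class _Compiled:
    """Vectorized representation used by the integrator."""

    def __init__(self, model: PBPKModel) -> None:
        self.model = model
        self.comp_index = {c.name: i for i, c in enumerate(model.compartments)}
        self.spec_index = {s.name: i for i, s in enumerate(model.species)}
        self.volumes = np.array([c.volume for c in model.compartments])
        nc, ns = len(model.compartments), len(model.species)
        # Per-species flow operator acting directly on amount vectors:
        # dA = F @ A with F[t, s] += Q / (V_s * K_s), F[s, s] -= Q / (V_s * K_s)
        self.flow_ops = np.zeros((ns, nc, nc))
        for s in model.species:
            si = self.spec_index[s.name]
            for f in model.flows:
                a, b = self.comp_index[f.source], self.comp_index[f.target]
                k = s.partition.get(f.source, 1.0)
                coef = f.rate / (self.volumes[a] * k)
                self.flow_ops[si, b, a] += coef
                self.flow_ops[si, a, a] -= coef
        # Processes as index tuples for the tight loop
        self.procs = []
        for p in model.processes:
            ci = self.comp_index[p.compartment]
            si = self.spec_index[p.species]
            prods = [(self.spec_index[ps], y) for ps, y in p.products]
            self.procs.append((p.id, p.kind, ci, si, dict(p.parameters), prods))
        # Fastest local rate constant (1/min): used to pick a stable explicit
        # sub-step automatically (RK4 stability limit ~2.8 on the real axis).
        lam = np.zeros((ns, nc))
        for si in range(ns):
            lam[si] -= np.diag(self.flow_ops[si])
        for _pid, kind, ci, si, pars, _prods in self.procs:
            if kind == "first_order" or kind == "oral_absorption":
                lam[si, ci] += pars.get("k", pars.get("ka", 0.0))
            elif kind == "michaelis_menten":
                lam[si, ci] += pars["vmax"] / pars["km"]
        self.lambda_max = float(lam.max()) if lam.size else 0.0

    def stable_sub_steps(self, dt: float, requested: int = 1) -> int:
        """Sub-steps needed so dt/sub_steps stays inside RK4 stability."""
        need = int(np.ceil(dt * self.lambda_max / 1.5)) if self.lambda_max > 0 else 1
        return max(requested, need, 1)

    def process_rate(self, pid: str, amounts: np.ndarray) -> float:
        """Evaluate one process's kinetic rate (µmol/min) at a state."""
        for id_, kind, ci, si, pars, _prods in self.procs:
            if id_ == pid:
                return self._rate(kind, ci, si, pars, amounts)
        raise ConfigurationError(f"unknown process {pid!r}")

    def _rate(self, kind: str, ci: int, si: int, pars: dict, amounts: np.ndarray) -> float:
        a = amounts[si, ci]
        v = self.volumes[ci]
        if kind == "first_order":
            return pars["k"] * a
        if kind == "michaelis_menten":
            c = a / v
            return pars["vmax"] * c / (pars["km"] + c) * v
        if kind == "zero_order_production":
            return pars["rate"] * v
        if kind == "oral_absorption":
            return pars["ka"] * a
        raise AssertionError(kind)

    def deriv(self, amounts: np.ndarray, rate_overrides: dict[str, float] | None = None) -> np.ndarray:
        dA = np.einsum("sij,sj->si", self.flow_ops, amounts)
        for pid, kind, ci, si, pars, prods in self.procs:
            if rate_overrides is not None and pid in rate_overrides:
                r = rate_overrides[pid]
            else:
                r = self._rate(kind, ci, si, pars, amounts)
            if kind == "zero_order_production":
                dA[si, ci] += r
            elif kind == "oral_absorption":
                ti = self.comp_index[pars["to"]]
                dA[si, ci] -= r
                dA[si, ti] += r
            else:  # elimination (possibly with metabolite products)
                dA[si, ci] -= r
                for psi, y in prods:
                    dA[psi, ci] += y * r
        return dA


# ---------------------------------------------------------------------------
# simulation


def _apply_doses(model: PBPKModel, comp: _Compiled, amounts: np.ndarray, t0: float, t1: float) -> None:
    """Inject dose events scheduled in [t0, t1) at the start of the step."""
    for d in model.doses:
        for td in d.times:
            if t0 <= td < t1:
                si = comp.spec_index[d.species]
                target = model.oral_dose_compartment if d.route == "oral" else model.iv_compartment
                amounts[si, comp.comp_index[target]] += d.amount


def _rk4_step(comp: _Compiled, amounts: np.ndarray, dt: float, sub_steps: int,
              rate_overrides: dict[str, float] | None = None) -> np.ndarray:
    h = dt / sub_steps
    a = amounts
    for _ in range(sub_steps):
        k1 = comp.deriv(a, rate_overrides)
        k2 = comp.deriv(a + 0.5 * h * k1, rate_overrides)
        k3 = comp.deriv(a + 0.5 * h * k2, rate_overrides)
        k4 = comp.deriv(a + h * k3, rate_overrides)
        a = a + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # discretized clearance can overshoot near zero; clip and warn
        if np.any(a < 0):
            worst = float(a.min())
            if worst < -1e-6:
                logger.warning("negative amount clipped to 0 (min %.3g µmol)", worst)
            np.clip(a, 0.0, None, out=a)
    return a


class Trajectory:
    """Time-indexed amounts for every compartment × species of one model."""

    def __init__(self, model: PBPKModel, times: np.ndarray, amounts: np.ndarray) -> None:
        self.model = model
        self.times = np.asarray(times, dtype=float)
        self.amounts = np.asarray(amounts, dtype=float)  # (nt, ns, nc)
        self._comp = {c.name: i for i, c in enumerate(model.compartments)}
        self._spec = {s.name: i for i, s in enumerate(model.species)}
        self._vol = np.array([c.volume for c in model.compartments])

    def __len__(self) -> int:
        return len(self.times)

    def conc(self, species: str, compartment: str) -> np.ndarray:
        """Concentration time course in µM."""
        return self.amounts[:, self._spec[species], self._comp[compartment]] / self._vol[self._comp[compartment]]

    def amount(self, species: str, compartment: str | None = None) -> np.ndarray:
        si = self._spec[species]
        if compartment is None:
            return self.amounts[:, si, :].sum(axis=1)
        return self.amounts[:, si, self._comp[compartment]]

    def state(self, i: int = -1) -> State:
        return State(float(self.times[i]), self.amounts[i].copy())

    def to_frame(self):
        """Tidy DataFrame with columns time_min, compartment, species, concentration_uM."""
        import pandas as pd

        rows = []
        for si, s in enumerate(self.model.species):
            for ci, c in enumerate(self.model.compartments):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_min": self.times,
                            "compartment": c.name,
                            "species": s.name,
                            "concentration_uM": self.amounts[:, si, ci] / c.volume,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def simulate(
    model: PBPKModel,
    duration: float,
    dt: float = 1.0,
    init: State | None = None,
    sub_steps: int = 1,
) -> Trajectory:
    """Integrate the whole-body model for ``duration`` minutes at step ``dt``.

    Returns ``duration/dt + 1`` states (the initial state included).  Dose
    events inject their amount at the start of the step containing their
    scheduled time.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    comp = model.compile()
    sub_steps = comp.stable_sub_steps(dt, sub_steps)
    n_steps = int(round(duration / dt))
    amounts = (init.amounts.copy() if init is not None else model.zero_state().amounts)
    t0 = init.time if init is not None else 0.0
    times = t0 + dt * np.arange(n_steps + 1)
    out = np.empty((n_steps + 1,) + amounts.shape)
    out[0] = amounts
    for i in range(n_steps):
        t = times[i]
        _apply_doses(model, comp, amounts, t, t + dt)
        amounts = _rk4_step(comp, amounts, dt, sub_steps)
        if not np.all(np.isfinite(amounts)):
            raise IntegrationError(f"non-finite state at t={t + dt:.1f} min; check rate parameters")
        out[i + 1] = amounts
    return Trajectory(model, times, out)


def steady_state(
    model: PBPKModel,
    tol: float = 1e-4,
    max_time: float = 14 * 24 * 60.0,
    dt: float = 1.0,
    init: State | None = None,
) -> SteadyStateResult:
    """Run to steady state: first state whose concentrations change by less
    than ``tol`` (relative) over a 60-minute window.

    Non-convergence within ``max_time`` returns ``converged=False`` rather
    than raising.
    """
    comp = model.compile()
    sub = comp.stable_sub_steps(dt)
    window = max(1, int(round(60.0 / dt)))
    amounts = init.amounts.copy() if init is not None else model.zero_state().amounts
    t = init.time if init is not None else 0.0
    change = math.inf
    while t < max_time:
        prev = amounts.copy()
        for _ in range(window):
            amounts = _rk4_step(comp, amounts, dt, sub)
        t += window * dt
        scale = np.maximum(np.abs(amounts), 1e-12)
        change = float(np.max(np.abs(amounts - prev) / scale))
        if change < tol:
            return SteadyStateResult(State(t, amounts), True, t, change)
    return SteadyStateResult(State(t, amounts), False, t, change)


def linear_steady_state(model: PBPKModel) -> State:
    """Exact steady state for models with purely linear kinetics.

    Valid when every process is first-order, oral absorption or zero-order
    production and there are no dose events; solves the linear balance
    M·A + b = 0 directly.  Raises :class:`ConfigurationError` otherwise.
    """
    if model.doses:
        raise ConfigurationError("linear_steady_state requires a dose-free model")
    for p in model.processes:
        if p.kind == "michaelis_menten":
            raise ConfigurationError("linear_steady_state requires linear kinetics")
    comp = model.compile()
    ns, nc = len(model.species), len(model.compartments)
    n = ns * nc
    M = np.zeros((n, n))
    b = np.zeros(n)
    eye = np.eye(n)
    b[:] = comp.deriv(np.zeros((ns, nc))).ravel()
    for j in range(n):
        M[:, j] = comp.deriv(eye[j].reshape(ns, nc)).ravel() - b
    sol, *_ = np.linalg.lstsq(M, -b, rcond=None)
    if not np.allclose(M @ sol + b, 0.0, atol=1e-9):
        raise IntegrationError("no steady state exists (unbalanced production without elimination)")
    amounts = sol.reshape(ns, nc)
    if np.any(amounts < -1e-9):
        raise IntegrationError("linear steady state has negative amounts; model is not dissipative")
    return State(0.0, np.clip(amounts, 0.0, None))


# ---------------------------------------------------------------------------
# metabolite chaining


def link_metabolite(
    parent: PBPKModel,
    metabolite: PBPKModel,
    via_process: str,
    stoichiometric_yield: float = 1.0,
) -> PBPKModel:
    """Merge a metabolite model into its parent model.

    The metabolite's formation rate is set to ``yield`` × the parent's
    clearance rate through ``via_process``, in the clearance compartment.
    Both models must share an identical compartment/flow scaffold.
    """
    proc = parent.process(via_process)
    if proc.kind not in ("first_order", "michaelis_menten"):
        raise ConfigurationError(f"process {via_process!r} is not a clearance process")
    if set(parent.species_names) & set(metabolite.species_names):
        raise ConfigurationError("parent and metabolite species must be distinct")
    pc = {(c.name, c.volume) for c in parent.compartments}
    mc = {(c.name, c.volume) for c in metabolite.compartments}
    if pc != mc:
        raise ConfigurationError("parent and metabolite must share the same compartments")
    pf = {(f.source, f.target, f.rate) for f in parent.flows}
    mf = {(f.source, f.target, f.rate) for f in metabolite.flows}
    if pf != mf:
        raise ConfigurationError("parent and metabolite must share the same flows")
    if len(metabolite.species) != 1:
        raise ConfigurationError("metabolite model must carry exactly one species")
    met_name = metabolite.species[0].name
    # formation compartment must match the clearance compartment: production
    # processes of the metabolite model in other compartments are kept, but
    # the linked formation happens where the clearance lives.
    merged = parent.copy()
    merged.species += [_copy.deepcopy(s) for s in metabolite.species]
    merged.processes += [_copy.deepcopy(p) for p in metabolite.processes]
    merged.doses += [_copy.deepcopy(d) for d in metabolite.doses]
    merged.process(via_process).products.append((met_name, float(stoichiometric_yield)))
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# calibration and sensitivity


def calibrate(
    model: PBPKModel,
    free_params: list[str],
    targets: list[tuple],
    bounds: tuple | None = None,
    x0: list[float] | None = None,
) -> CalibrationResult:
    """Fit up to 10 parameters to observable targets by local least squares.

    ``free_params`` are parameter paths (``process:<id>:<param>``);
    ``targets`` is a list of ``(observable, value)`` where each observable is
    a callable ``model -> float``.  Minimizes the sum of squared *relative*
    residuals from a fixed, documented starting point (the model's current
    values unless ``x0`` is given); deterministic, no randomness involved.
    """
    if len(free_params) > 10:
        raise ValueError("at most 10 free parameters are supported")
    work = model.copy()
    start = np.array([work.get_param(p) for p in free_params] if x0 is None else x0, dtype=float)

    def residuals(x: np.ndarray) -> np.ndarray:
        for path, val in zip(free_params, x):
            work.set_param(path, val)
        res = []
        for obs, target in targets:
            pred = obs(work)
            scale = abs(target) if target != 0 else 1.0
            res.append((pred - target) / scale)
        return np.array(res)

    lb = np.zeros_like(start) if bounds is None else np.asarray(bounds[0], dtype=float)
    ub = np.full_like(start, np.inf) if bounds is None else np.asarray(bounds[1], dtype=float)
    fit = least_squares(residuals, np.clip(start, lb + 1e-12, ub), bounds=(lb, ub),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    jac_scale = np.abs(fit.jac).max(axis=0) if fit.jac is not None and fit.jac.size else np.array([0.0])
    identifiable = bool(np.all(jac_scale > 1e-8))
    if not identifiable:
        warnings.warn(
            "calibration objective is flat in at least one parameter "
            f"(max |J| per parameter: {np.array2string(jac_scale, precision=3)})",
            stacklevel=2,
        )
    params = {p: float(v) for p, v in zip(free_params, fit.x)}
    return CalibrationResult(params, [float(r) for r in fit.fun], float(2 * fit.cost), identifiable)


def local_sensitivity(model: PBPKModel, param: str, observable, delta: float = 0.05) -> float:
    """Normalized local sensitivity (Δy/y)/(Δp/p) by central finite difference."""
    if not 0 < delta <= 0.5:
        raise ValueError("delta must be in (0, 0.5]")
    p0 = model.get_param(param)
    if p0 == 0:
        raise ValueError(f"parameter {param!r} is zero; relative sensitivity undefined")
    y0 = observable(model)
    if y0 == 0:
        raise ZeroDivisionError("observable is zero at the nominal point; sensitivity undefined")
    hi, lo = model.copy(), model.copy()
    hi.set_param(param, p0 * (1 + delta))
    lo.set_param(param, p0 * (1 - delta))
    dy = observable(hi) - observable(lo)
    return float((dy / y0) / (2 * delta))
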