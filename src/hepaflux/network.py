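"""Stoichiometric networks and flux balance analysis (FBA).

A metabolic network is a stoichiometric matrix S (m metabolites × n
reactions) with per-reaction flux bounds.  FBA solves the linear program

    maximize  f·v   subject to   S·v = 0,   lb <= v <= ub

optionally with extra bound overrides (substrate availability offered by
the whole-body model, or enzyme-inhibition caps).  Because the optimum of
such LPs is typically degenerate, :func:`fba` resolves alternate optima by
a second stage that fixes the objective at its optimal value and minimizes
the total absolute flux Σ|v| (parsimonious selection via flux splitting),
giving a reproducible flux vector for downstream flux-change
classification.

Networks load from a plain-text reaction table (TSV) or, optionally, from
SBML through :mod:`cobra`.  Reaction equations use the compact arrow
syntax ``"2 nh3[c] + co2[c] -> urea[c]"``; an equation with a single side
(``"nh3[e] ->"`` or ``"-> akg[c]"``) defines an exchange reaction across
the system boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "Objective",
    "FluxDistribution",
    "NetworkLoadError",
    "load_network",
    "parse_equation",
    "fba",
    "check_balance",
    "write_tsv",
    "read_sbml",
    "write_sbml",
]

FEASIBILITY_TOL = 1e-9
FLUX_ROUND = 1e-10  # reported fluxes rounded to suppress solver noise


class NetworkLoadError(ValueError):
    """Raised for malformed reaction tables or inconsistent networks."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""
    name: str = ""


@dataclass
class Reaction:
    """One column of S: stoichiometry (negative = consumed) plus bounds."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = np.inf
    is_exchange: bool = False
    tags: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkLoadError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkLoadError(f"reaction {self.id!r}: lower_bound > upper_bound")


@dataclass
class Objective:
    """Linear FBA objective, maximized."""

    coefficients: dict[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("objective needs at least one nonzero weight")


@dataclass
class FluxDistribution:
    values: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class MetabolicNetwork:
    """Metabolites, reactions and the stoichiometric matrix they span."""

    def __init__(self, reactions: list[Reaction], name: str = "") -> None:
        if not reactions:
            raise NetworkLoadError("a network needs at least one reaction")
        ids = [r.id for r in reactions]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise NetworkLoadError(f"duplicate reaction ids: {sorted(dup)}")
        self.name = name
        self.reactions = list(reactions)
        met_ids: list[str] = []
        for r in reactions:
            for m in r.stoichiometry:
                if m not in met_ids:
                    met_ids.append(m)
        self.metabolites = [Metabolite(m, compartment=_compartment_of(m)) for m in met_ids]
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- structure -------------------------------------------------------
    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoichiometry.items():
                S[self._met_index[m], j] = coef
        return S

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise NetworkLoadError(f"unknown reaction {rid!r}") from None

    def reactions_with_tag(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if tag in r.tags]

    def copy(self) -> "MetabolicNetwork":
        rs = [
            Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                     r.is_exchange, r.tags, r.notes)
            for r in self.reactions
        ]
        return MetabolicNetwork(rs, name=self.name)

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        r = self.reaction(rid)
        if lb > ub:
            raise NetworkLoadError(f"reaction {rid!r}: lower_bound > upper_bound")
        r.lower_bound, r.upper_bound = lb, ub

    def nitrogen_balance(self, flux: "FluxDistribution", n_atoms: dict[str, int]) -> float:
        """Net nitrogen flux across the boundary (advisory element check)."""
        net = 0.0
        for r in self.reactions:
            if not r.is_exchange:
                continue
            for m, coef in r.stoichiometry.items():
                net += coef * n_atoms.get(_bare_id(m), 0) * flux.values[r.id]
        return net


def _compartment_of(met_id: str) -> str:
    m = re.search(r"\[(\w+)\]$", met_id)
    return m.group(1) if m else ""


def _bare_id(met_id: str) -> str:
    return re.sub(r"\[\w+\]$", "", met_id)


# ---------------------------------------------------------------------------
# reaction-table parsing

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 a[c] + b[c] -> c[c]"`` into a stoichiometry map.

    Returns ``(stoichiometry, is_exchange)``; a one-sided equation is an
    exchange reaction (single-metabolite stoichiometry).
    """
    if "->" not in eq:
        raise NetworkLoadError(f"equation {eq!r}: missing '->'")
    lhs, rhs = eq.split("->", 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise NetworkLoadError(f"equation {eq!r}: malformed term {term.strip()!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise NetworkLoadError(f"equation {eq!r}: empty stoichiometry")
    is_exchange = len(stoich) == 1
    return stoich, is_exchange


def load_network(source: str | Path) -> MetabolicNetwork:
    """Load a network from a reaction-table TSV (or an SBML file by suffix).

    The TSV needs a header with columns ``reaction_id``, ``equation``,
    ``lb``, ``ub`` and optionally ``notes``; tags for inhibitable enzyme
    activities are declared in notes as ``tag=NAME`` (comma separated).
    """
    path = Path(source)
    if path.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise NetworkLoadError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    required = ["reaction_id", "equation", "lb", "ub"]
    if header[: len(required)] != required:
        raise NetworkLoadError(f"{path}: header must start with {required}, got {header}")
    has_notes = "notes" in header
    reactions: list[Reaction] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise NetworkLoadError(f"{path}:{ln}: expected at least 4 columns")
        rid, eq = parts[0].strip(), parts[1].strip()
        try:
            lb = float(parts[2]) if parts[2].strip() not in ("", "-inf") else -np.inf
            ub = float(parts[3]) if parts[3].strip() not in ("", "inf") else np.inf
        except ValueError as exc:
            raise NetworkLoadError(f"{path}:{ln}: bad bounds: {exc}") from None
        notes = parts[header.index("notes")].strip() if has_notes and len(parts) > header.index("notes") else ""
        try:
            stoich, is_exch = parse_equation(eq)
        except NetworkLoadError as exc:
            raise NetworkLoadError(f"{path}:{ln}: {exc}") from None
        tags = frozenset(
            t.split("=", 1)[1] for t in (s.strip() for s in notes.split(",")) if t.startswith("tag=")
        )
        reactions.append(Reaction(rid, stoich, lb, ub, is_exch, tags, notes))
    if not reactions:
        raise NetworkLoadError(f"{path}: no reactions found")
    return MetabolicNetwork(reactions, name=path.stem)


def write_tsv(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the network back as a reaction-table TSV (round-trip safe)."""
    lines = ["reaction_id\tequation\tlb\tub\tnotes"]
    for r in network.reactions:
        lhs = " + ".join(
            f"{-c:g} {m}" if -c != 1 else m for m, c in r.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            f"{c:g} {m}" if c != 1 else m for m, c in r.stoichiometry.items() if c > 0
        )
        eq = f"{lhs} -> {rhs}".strip()
        notes = r.notes or ",".join(f"tag={t}" for t in sorted(r.tags))
        lb = "-inf" if np.isinf(r.lower_bound) else f"{r.lower_bound:g}"
        ub = "inf" if np.isinf(r.upper_bound) else f"{r.upper_bound:g}"
        lines.append(f"{r.id}\t{eq}\t{lb}\t{ub}\t{notes}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# optional SBML path (genome-scale import, e.g. a hepatocyte reconstruction)


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Import an SBML (FBC) model through cobra, if installed."""
    import cobra

    model = cobra.io.read_sbml_model(str(path))
    reactions = []
    for rxn in model.reactions:
        stoich = {m.id: float(c) for m, c in rxn.metabolites.items()}
        reactions.append(
            Reaction(rxn.id, stoich, float(rxn.lower_bound), float(rxn.upper_bound),
                     is_exchange=len(stoich) == 1)
        )
    return MetabolicNetwork(reactions, name=model.id or Path(path).stem)


def write_sbml(network: MetabolicNetwork, path: str | Path) -> None:
    """Export through cobra, if installed."""
    import cobra

    model = cobra.Model(network.name or "hepaflux_network")
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c") for m in network.metabolites}
    for r in network.reactions:
        rxn = cobra.Reaction(r.id)
        rxn.lower_bound = -1000.0 if np.isinf(r.lower_bound) else r.lower_bound
        rxn.upper_bound = 1000.0 if np.isinf(r.upper_bound) else r.upper_bound
        model.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
    cobra.io.write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# flux balance analysis


def _resolve_bounds(network: MetabolicNetwork, extra_constraints) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    if extra_constraints:
        for rid, bnd in dict(extra_constraints).items():
            j = network._rxn_index.get(rid)
            if j is None:
                raise NetworkLoadError(f"constraint references unknown reaction {rid!r}")
            if np.isscalar(bnd):  # fixed flux
                lb[j] = ub[j] = float(bnd)
            else:
                lo, hi = bnd
                lb[j], ub[j] = float(lo), float(hi)
            if lb[j] > ub[j]:
                raise NetworkLoadError(f"constraint on {rid!r}: lb > ub")
    return lb, ub


def fba(
    network: MetabolicNetwork,
    objective: Objective,
    extra_constraints: dict | None = None,
    parsimonious: bool = True,
) -> FluxDistribution:
    """Maximize a linear objective over S·v = 0 with bounds.

    ``extra_constraints`` maps reaction id -> fixed flux (scalar) or
    ``(lb, ub)`` override.  With ``parsimonious=True`` (default) alternate
    optima are resolved to the minimum-total-absolute-flux vector by a
    second LP stage, so repeated solves return identical flux vectors.
    """
    S = network.stoichiometric_matrix
    n = S.shape[1]
    lb, ub = _resolve_bounds(network, extra_constraints)
    f = np.zeros(n)
    for rid, w in objective.coefficients.items():
        j = network._rxn_index.get(rid)
        if j is None:
            raise NetworkLoadError(f"objective references unknown reaction {rid!r}")
        f[j] = w
    res = linprog(-f, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return FluxDistribution({}, float("nan"), "infeasible")
    if res.status == 3:
        return FluxDistribution({}, float("nan"), "unbounded")
    if res.status != 0:
        return FluxDistribution({}, float("nan"), "infeasible")
    opt = float(-res.fun)
    v = res.x
    if parsimonious:
        v2 = _min_total_flux(S, f, opt, lb, ub)
        if v2 is not None:
            v = v2
    v = np.round(v / FLUX_ROUND) * FLUX_ROUND
    v[v == 0.0] = 0.0  # normalize -0.0
    values = {r.id: float(v[j]) for j, r in enumerate(network.reactions)}
    return FluxDistribution(values, opt, "optimal")


def _min_total_flux(S, f, opt, lb, ub):
    """Stage two: min Σ|v| s.t. S·v=0, f·v = opt, bounds.  Flux splitting."""
    n = S.shape[1]
    # v = vp - vn with vp, vn >= 0
    A_eq = np.hstack([S, -S])
    A_eq = np.vstack([A_eq, np.concatenate([f, -f])])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [opt]])
    bounds = [(0.0, max(u, 0.0) if np.isfinite(u) else None) for u in ub]
    bounds += [(0.0, max(-l, 0.0) if np.isfinite(l) else None) for l in lb]
    # original box constraints on v itself: lb <= vp - vn <= ub (finite only)
    rows, rhs = [], []
    eye = np.eye(n)
    for j in range(n):
        if np.isfinite(ub[j]):
            rows.append(np.concatenate([eye[j], -eye[j]]))
            rhs.append(ub[j])
        if np.isfinite(lb[j]):
            rows.append(np.concatenate([-eye[j], eye[j]]))
            rhs.append(-lb[j])
    A_ub = np.array(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    c = np.ones(2 * n)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return res.x[:n] - res.x[n:]


def check_balance(network: MetabolicNetwork, flux: FluxDistribution, tol: float = 1e-8) -> float:
    """Maximum mass-balance residual max|S·v| over internal metabolites.

    Returns the residual; compare against ``tol`` (default 1e-8 µmol/L/min)
    for a pass/fail decision.
    """
    missing = set(network.reaction_ids) - set(flux.values)
    if missing:
        raise NetworkLoadError(f"flux distribution missing reactions: {sorted(missing)}")
    v = np.array([flux.values[r.id] for r in network.reactions])
    return float(np.max(np.abs(network.stoichiometric_matrix @ v))) if len(v) else 0.0
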