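"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hepaflux.network import MetabolicNetwork, Objective, _resolve_bounds
from hepaflux.pbpk import Compartment, Flow, KineticProcess, PBPKModel, Species

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent LP oracle: exhaustive basic-solution (vertex) enumeration


def vertex_optimum(network: MetabolicNetwork, objective: Objective, overrides=None):
    """Brute-force LP optimum via enumeration of basic feasible solutions.

    Every vertex of {S v = 0, lb <= v <= ub} fixes (n - rank S) variables
    at finite bounds; enumerating all such assignments and solving for the
    rest yields every vertex, whose best objective value is the LP
    optimum (for bounded problems).  Independent of the linprog path.
    """
    S = network.stoichiometric_matrix
    lb, ub = _resolve_bounds(network, overrides)
    n = S.shape[1]
    f = np.zeros(n)
    idx_of = {r.id: j for j, r in enumerate(network.reactions)}
    for rid, w in objective.coefficients.items():
        f[idx_of[rid]] = w
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    best = None
    for fixed in combinations(range(n), k):
        opts = []
        for j in fixed:
            o = []
            if np.isfinite(lb[j]):
                o.append(lb[j])
            if np.isfinite(ub[j]) and ub[j] != lb[j]:
                o.append(ub[j])
            if not o:
                break
            opts.append(o)
        if len(opts) < k:
            continue
        free = [j for j in range(n) if j not in fixed]
        Sf = S[:, free]
        if free and np.linalg.matrix_rank(Sf) < len(free):
            continue
        for vals in product(*opts):
            v = np.zeros(n)
            v[list(fixed)] = vals
            if free:
                sol, *_ = np.linalg.lstsq(Sf, -S[:, list(fixed)] @ np.array(vals), rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                val = float(f @ v)
                if best is None or val > best:
                    best = val
    return best


@pytest.fixture(scope="session")
def lp_oracle():
    return vertex_optimum


# ---------------------------------------------------------------------------
# small PBPK building blocks


def one_compartment_model(volume=10.0, k=0.01, production=0.0, species="x") -> PBPKModel:
    processes = []
    if k > 0:
        processes.append(KineticProcess("elim", "first_order", "box", species, {"k": k}))
    if production > 0:
        processes.append(
            KineticProcess("prod", "zero_order_production", "box", species, {"rate": production})
        )
    return PBPKModel(
        compartments=[Compartment("box", volume)],
        flows=[],
        species=[Species(species)],
        processes=processes,
        iv_compartment="box",
    )


@pytest.fixture
def one_compartment():
    return one_compartment_model


def two_compartment_closed(k_a=1.0, k_b=1.0) -> PBPKModel:
    """Closed two-box flow loop with partition coefficients, no elimination."""
    return PBPKModel(
        compartments=[Compartment("a", 2.0), Compartment("b", 5.0)],
        flows=[Flow("a", "b", 1.0), Flow("b", "a", 1.0)],
        species=[Species("x", partition={"a": k_a, "b": k_b})],
        processes=[],
        iv_compartment="a",
    )


@pytest.fixture
def closed_two_compartment():
    return two_compartment_closed


# ---------------------------------------------------------------------------
# expensive, shared scenario results (session scope: computed once)


@pytest.fixture(scope="session")
def calibrated_ammonia_model():
    from hepaflux.toyliver import ammonia_model

    return ammonia_model()


@pytest.fixture(scope="session")
def ucd_result():
    """Full 21-day urea-cycle-disorder run with the default protocol."""
    from hepaflux.scenarios import run_ammonia_ucd

    return run_ammonia_ucd()


@pytest.fixture(scope="session")
def paracetamol_results():
    from hepaflux.scenarios import run_paracetamol

    return {dose: run_paracetamol(dose) for dose in (1.0, 15.0)}
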