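"""Hand-verifiable hepatocyte fixture networks and whole-body parameter sets.

These fixtures are deliberately small enough to solve by hand, yet their
stoichiometry reproduces the printed hepatic exchange rates of the three
case studies wherever the toy structure permits:

* :func:`make_ammonia_network` — hepatic ammonia detoxification.  Ammonia
  nitrogen leaves the hepatocyte as urea (2 N), glutamine (2 N: the
  glutamine amide plus the amine of its de-novo glutamate, both
  ammonia-derived via glutamate dehydrogenase) or alanine (1 N), so
  uptake = 2·urea + 2·gln + ala.
* :func:`make_purine_network` — the xanthine oxidase chain hypoxanthine →
  xanthine → uric acid, both steps carrying one shared inhibitable
  activity tag ("XO").
* :func:`make_gsh_panel` — a branched biosynthesis network with four
  inhibitable activities (THFDH, GDH, ATPS, GSH synthesis) and an export
  objective panel whose dependency structure is known by construction.

All fixtures are deterministic (no randomness) and round-trip through the
reaction-table TSV format.

The module also builds the matching whole-body parameter sets (ammonia,
allopurinol/oxypurinol/uric acid, paracetamol and metabolites) on a lumped
one-box-per-organ scaffold.  Printed volumetric rates (µmol/L/min) are
normalized to the scaffold's whole-body reference volume ``V_REF``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MetabolicNetwork, Objective, Reaction, parse_equation
from .pbpk import (
    Compartment,
    DoseEvent,
    Flow,
    KineticProcess,
    PBPKModel,
    Species,
    calibrate,
    linear_steady_state,
)
from .robustness import ObjectivePanel

__all__ = [
    "FixtureSpec",
    "make_ammonia_network",
    "make_purine_network",
    "make_gsh_panel",
    "make_fixture",
    "AMMONIA_OBJECTIVE",
    "PURINE_OBJECTIVE",
    "body_compartments",
    "body_flows",
    "V_REF",
    "ammonia_model",
    "uric_acid_model",
    "allopurinol_model",
    "paracetamol_model",
    "AMMONIA_PRODUCTION",
    "RENAL_SHARE",
    "HEPATIC_SHARE",
    "VENOUS_AMMONIA_TARGET",
    "HEPATIC_UPTAKE_BASELINE",
    "GLUTAMINE_CAP",
    "ALANINE_CAP",
    "URIC_HEALTHY_SS",
    "URIC_GOUTY_SS",
    "URATE_PRODUCTION",
    "IC50_ALLOPURINOL",
    "IC50_OXYPURINOL",
]

# ---------------------------------------------------------------------------
# printed physiological constants (µM, µmol/L/min on the V_REF basis)

AMMONIA_PRODUCTION = 0.694      # whole-body ammonia production
VENOUS_AMMONIA_TARGET = 29.0    # healthy venous plasma ammonia
HEPATIC_UPTAKE_BASELINE = 0.163  # hepatic ammonia uptake at baseline
RENAL_SHARE = 13.0 / 17.0       # renal : hepatic elimination split is 13 : 4
HEPATIC_SHARE = 4.0 / 17.0
GLUTAMINE_CAP = 0.008           # ~5 % of baseline uptake, molar
ALANINE_CAP = 0.002             # ~1 % of baseline uptake, molar

URIC_HEALTHY_SS = 302.0         # healthy male venous urate
URIC_GOUTY_SS = 476.0           # hyperuricemic steady state
URATE_HALF_LIFE_MIN = 1440.0    # plasma urate turnover ~1 day (fixture choice)

IC50_ALLOPURINOL = 13.4         # µM, xanthine oxidase
IC50_OXYPURINOL = 15.6          # µM, xanthine oxidase

MW_ALLOPURINOL = 136.11
MW_OXYPURINOL = 152.11
MW_URIC_ACID = 168.11
MW_PARACETAMOL = 151.16
MW_AMMONIA = 17.03


@dataclass
class FixtureSpec:
    """Named fixture request with optional scale overrides."""

    which: str  # ammonia_detox | purine_xo | gsh_panel
    params: dict | None = None


def _rxn(rid: str, eq: str, lb: float, ub: float, tags: tuple[str, ...] = ()) -> Reaction:
    stoich, is_exch = parse_equation(eq)
    return Reaction(rid, stoich, lb, ub, is_exch, frozenset(tags),
                    ",".join(f"tag={t}" for t in tags))


# ---------------------------------------------------------------------------
# toy networks

AMMONIA_OBJECTIVE = Objective({"EX_nh3": 1.0}, name="max_ammonia_uptake")
PURINE_OBJECTIVE = Objective({"EX_ua": 1.0}, name="max_uric_acid_production")


def make_ammonia_network(
    glutamine_cap: float = GLUTAMINE_CAP,
    alanine_cap: float = ALANINE_CAP,
    uptake_ub: float = HEPATIC_UPTAKE_BASELINE,
) -> MetabolicNetwork:
    """Toy hepatic ammonia-detoxification network.

    Glutamine and alanine exports are fixed demands at their caps
    (lb = ub): hepatic glutamine/alanine output is an obligatory,
    capacity-limited function, which is what reproduces the reported
    baseline partitioning (urea 0.0725, gln 0.008, ala 0.002 at uptake
    0.163) under the maximize-uptake objective.
    """
    if glutamine_cap < 0 or alanine_cap < 0 or uptake_ub < 0:
        raise ValueError("caps must be >= 0")
    reactions = [
        _rxn("EX_nh3", "-> nh3[c]", 0.0, uptake_ub),
        _rxn("GDH", "akg[c] + nh3[c] -> glu[c]", 0.0, np.inf),
        _rxn("GS", "glu[c] + nh3[c] -> gln[c]", 0.0, np.inf),
        _rxn("ALT", "glu[c] + pyr[c] -> ala[c] + akg[c]", 0.0, np.inf),
        _rxn("UC", "2 nh3[c] + co2[c] -> urea[c]", 0.0, np.inf, tags=("OTC",)),
        _rxn("EX_urea", "urea[c] ->", 0.0, np.inf),
        _rxn("EX_gln", "gln[c] ->", glutamine_cap, glutamine_cap),
        _rxn("EX_ala", "ala[c] ->", alanine_cap, alanine_cap),
        _rxn("EX_akg", "-> akg[c]", 0.0, np.inf),
        _rxn("EX_pyr", "-> pyr[c]", 0.0, np.inf),
        _rxn("EX_co2", "-> co2[c]", 0.0, np.inf),
    ]
    return MetabolicNetwork(reactions, name="ammonia_detox")


#: nitrogen content of the boundary metabolites of the ammonia network
AMMONIA_N_ATOMS = {"nh3": 1, "urea": 2, "gln": 2, "ala": 1, "akg": 0, "pyr": 0, "co2": 0}


def make_purine_network(supply_ub: float = 0.145) -> MetabolicNetwork:
    """Xanthine oxidase chain: hypoxanthine → xanthine → uric acid.

    Both oxidation steps share the activity tag ``XO``, so a single
    inhibitor link caps both against their own reference fluxes.
    """
    reactions = [
        _rxn("EX_hx", "-> hx[c]", 0.0, supply_ub),
        _rxn("XO1", "hx[c] -> xan[c]", 0.0, np.inf, tags=("XO",)),
        _rxn("XO2", "xan[c] -> ua[c]", 0.0, np.inf, tags=("XO",)),
        _rxn("EX_ua", "ua[c] ->", 0.0, np.inf),
    ]
    return MetabolicNetwork(reactions, name="purine_xo")


#: ground-truth activity-tag dependencies of the gsh panel objectives
GSH_PANEL_DEPENDENCIES = {
    "lactate_production": frozenset(),
    "co2_production": frozenset(),
    "pyruvate_production": frozenset(),
    "amino_acid_export": frozenset(),
    "glutathione_production": frozenset({"GSH", "ATPS"}),
    "detoxification": frozenset({"GSH", "ATPS"}),
    "protein_synthesis": frozenset({"ATPS"}),
    "nucleotide_synthesis": frozenset({"THFDH", "ATPS"}),
    "lipid_synthesis": frozenset({"ATPS"}),
    "urea_production": frozenset({"GDH"}),
    "alanine_production": frozenset({"GDH"}),
    "atp_export": frozenset({"ATPS"}),
}


def make_gsh_panel(n_objectives: int = 12) -> tuple[MetabolicNetwork, ObjectivePanel, dict]:
    """Branched biosynthesis network plus an export-objective panel.

    Returns ``(network, panel, dependencies)`` where ``dependencies`` maps
    each objective name to the set of inhibitable activity tags its
    optimum depends on (the constructed ground truth).  The first four
    objectives are independent of every tagged reaction; the remainder
    require at least one of THFDH / GDH / ATPS / GSH synthesis.
    """
    if not 1 <= n_objectives <= 12:
        raise ValueError("n_objectives must be between 1 and 12")
    reactions = [
        # bounded substrate supplies define the objective scale
        _rxn("EX_glc", "-> glc[c]", 0.0, 1.0),
        _rxn("EX_aa", "-> aa[c]", 0.0, 1.0),
        _rxn("EX_fa", "-> fa[c]", 0.0, 1.0),
        _rxn("EX_nuc", "-> nucp[c]", 0.0, 1.0),
        _rxn("EX_tox", "-> tox[c]", 0.0, 1.0),
        # inhibitable activities
        _rxn("ATPS", "glc[c] -> 2 atp[c]", 0.0, np.inf, tags=("ATPS",)),
        _rxn("THFDH", "aa[c] -> thf[c]", 0.0, np.inf, tags=("THFDH",)),
        _rxn("GDH", "aa[c] -> nh3[c]", 0.0, np.inf, tags=("GDH",)),
        _rxn("GSHS", "aa[c] + atp[c] -> gsh[c]", 0.0, np.inf, tags=("GSH",)),
        # untagged metabolism
        _rxn("GLYC", "glc[c] -> 2 lac[c]", 0.0, np.inf),
        _rxn("PYRS", "glc[c] -> 2 pyr[c]", 0.0, np.inf),
        _rxn("OX", "glc[c] -> 6 co2[c]", 0.0, np.inf),
        _rxn("PROTS", "aa[c] + atp[c] -> prot[c]", 0.0, np.inf),
        _rxn("DNAS", "nucp[c] + thf[c] + atp[c] -> dna[c]", 0.0, np.inf),
        _rxn("DETOX", "tox[c] + gsh[c] -> dtox[c]", 0.0, np.inf),
        _rxn("UREAS", "nh3[c] + co2[c] -> ureax[c]", 0.0, np.inf),
        _rxn("LIPS", "fa[c] + atp[c] -> lip[c]", 0.0, np.inf),
        _rxn("ALAS", "pyr[c] + nh3[c] -> ala2[c]", 0.0, np.inf),
        _rxn("AAT", "aa[c] -> aax[c]", 0.0, np.inf),
        # exports (objective handles)
        _rxn("EX_lac", "lac[c] ->", 0.0, np.inf),
        _rxn("EX_co2", "co2[c] ->", 0.0, np.inf),
        _rxn("EX_pyrout", "pyr[c] ->", 0.0, np.inf),
        _rxn("EX_aax", "aax[c] ->", 0.0, np.inf),
        _rxn("EX_gsh", "gsh[c] ->", 0.0, np.inf),
        _rxn("EX_dtox", "dtox[c] ->", 0.0, np.inf),
        _rxn("EX_prot", "prot[c] ->", 0.0, np.inf),
        _rxn("EX_dna", "dna[c] ->", 0.0, np.inf),
        _rxn("EX_lip", "lip[c] ->", 0.0, np.inf),
        _rxn("EX_ureax", "ureax[c] ->", 0.0, np.inf),
        _rxn("EX_ala2", "ala2[c] ->", 0.0, np.inf),
        _rxn("EX_atpout", "atp[c] ->", 0.0, np.inf),
    ]
    network = MetabolicNetwork(reactions, name="gsh_panel")
    handles = {
        "lactate_production": "EX_lac",
        "co2_production": "EX_co2",
        "pyruvate_production": "EX_pyrout",
        "amino_acid_export": "EX_aax",
        "glutathione_production": "EX_gsh",
        "detoxification": "EX_dtox",
        "protein_synthesis": "EX_prot",
        "nucleotide_synthesis": "EX_dna",
        "lipid_synthesis": "EX_lip",
        "urea_production": "EX_ureax",
        "alanine_production": "EX_ala2",
        "atp_export": "EX_atpout",
    }
    names = list(GSH_PANEL_DEPENDENCIES)[:n_objectives]
    entries = [(n, Objective({handles[n]: 1.0}, name=n), {}) for n in names]
    deps = {n: GSH_PANEL_DEPENDENCIES[n] for n in names}
    return network, ObjectivePanel(entries), deps


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its constructor."""
    params = spec.params or {}
    if spec.which == "ammonia_detox":
        return make_ammonia_network(**params)
    if spec.which == "purine_xo":
        return make_purine_network(**params)
    if spec.which == "gsh_panel":
        return make_gsh_panel(**params)
    raise ValueError(f"unknown fixture {spec.which!r}")


# ---------------------------------------------------------------------------
# whole-body scaffold (lumped one-box-per-organ)


def body_compartments(with_gut_lumen: bool = False) -> list[Compartment]:
    comps = [
        Compartment("venous", 3.9, "vascular"),
        Compartment("arterial", 1.8, "vascular"),
        Compartment("liver", 2.1),
        Compartment("kidney", 1.5),
        Compartment("rest", 35.0),
    ]
    if with_gut_lumen:
        comps.append(Compartment("gut_lumen", 1.0, "lumen"))
    return comps


def body_flows() -> list[Flow]:
    return [
        Flow("venous", "arterial", 5.0),  # lumped heart/lung
        Flow("arterial", "liver", 1.5),
        Flow("arterial", "kidney", 1.2),
        Flow("arterial", "rest", 2.3),
        Flow("liver", "venous", 1.5),
        Flow("kidney", "venous", 1.2),
        Flow("rest", "venous", 2.3),
    ]


#: whole-body reference volume (L) used to normalize printed volumetric
#: rates; the gut lumen is excluded (it is outside the body proper).
V_REF = sum(c.volume for c in body_compartments())


def _venous_ss(m: PBPKModel, species: str) -> float:
    st = linear_steady_state(m)
    comp = m.compile()
    return st.amounts[comp.spec_index[species], comp.comp_index["venous"]] / m.compartment("venous").volume


def ammonia_model(
    production: float = AMMONIA_PRODUCTION,
    venous_target: float = VENOUS_AMMONIA_TARGET,
    renal_share: float = RENAL_SHARE,
    param_overrides: dict | None = None,
) -> PBPKModel:
    """Calibrated whole-body ammonia model.

    Production (zero order, in the rest-of-body compartment) is fixed at
    the reported whole-body rate; hepatic and renal first-order clearance
    constants are calibrated so the venous steady state hits
    ``venous_target`` with the 13 : 4 renal : hepatic elimination split.
    ``param_overrides`` (path -> value) perturbs the calibrated parameters
    afterwards (virtual individuals).
    """
    comps = body_compartments()
    v_rest = next(c.volume for c in comps if c.name == "rest")
    v_liver = next(c.volume for c in comps if c.name == "liver")
    v_kidney = next(c.volume for c in comps if c.name == "kidney")
    model = PBPKModel(
        compartments=comps,
        flows=body_flows(),
        species=[Species("ammonia", MW_AMMONIA)],
        processes=[
            KineticProcess("production", "zero_order_production", "rest", "ammonia",
                           {"rate": production * V_REF / v_rest}),
            KineticProcess("liver_clearance", "first_order", "liver", "ammonia",
                           {"k": production * (1 - renal_share) * V_REF / (venous_target * v_liver)}),
            KineticProcess("kidney_clearance", "first_order", "kidney", "ammonia",
                           {"k": production * renal_share * V_REF / (venous_target * v_kidney)}),
        ],
    )

    def hepatic_share_obs(m: PBPKModel) -> float:
        st = linear_steady_state(m)
        comp = m.compile()
        liver = comp.process_rate("liver_clearance", st.amounts)
        kidney = comp.process_rate("kidney_clearance", st.amounts)
        return liver / (liver + kidney)

    fit = calibrate(
        model,
        ["process:liver_clearance:k", "process:kidney_clearance:k"],
        [(lambda m: _venous_ss(m, "ammonia"), venous_target),
         (hepatic_share_obs, 1 - renal_share)],
    )
    for path, value in fit.parameters.items():
        model.set_param(path, value)
    for path, value in (param_overrides or {}).items():
        model.set_param(path, value)
    return model


def ammonia_rates(model: PBPKModel) -> dict[str, float]:
    """Steady-state production/clearance rates on the V_REF basis (µmol/L/min)."""
    st = linear_steady_state(model)
    comp = model.compile()
    return {
        "production": comp.process_rate("production", st.amounts) / V_REF,
        "liver": comp.process_rate("liver_clearance", st.amounts) / V_REF,
        "kidney": comp.process_rate("kidney_clearance", st.amounts) / V_REF,
        "venous_uM": _venous_ss(model, "ammonia"),
    }


#: whole-body urate production on the V_REF basis, µmol/L/min: chosen so the
#: healthy steady state (302 µM) turns over with ~1 day half-life.
URATE_PRODUCTION = np.log(2) / URATE_HALF_LIFE_MIN * URIC_HEALTHY_SS


def uric_acid_model(gouty: bool = False) -> PBPKModel:
    """Uric acid whole-body model; gout = reduced renal clearance only.

    Production is identical in health and gout; the renal first-order
    constant is calibrated so the venous steady state is 302 µM (healthy)
    or 476 µM (gouty).
    """
    comps = body_compartments()
    v_liver = next(c.volume for c in comps if c.name == "liver")
    v_kidney = next(c.volume for c in comps if c.name == "kidney")
    target = URIC_GOUTY_SS if gouty else URIC_HEALTHY_SS
    model = PBPKModel(
        compartments=comps,
        flows=body_flows(),
        species=[Species("uric_acid", MW_URIC_ACID)],
        processes=[
            KineticProcess("ua_production", "zero_order_production", "liver", "uric_acid",
                           {"rate": URATE_PRODUCTION * V_REF / v_liver}),
            KineticProcess("ua_renal_clearance", "first_order", "kidney", "uric_acid",
                           {"k": URATE_PRODUCTION * V_REF / (target * v_kidney)}),
        ],
    )
    fit = calibrate(model, ["process:ua_renal_clearance:k"],
                    [(lambda m: _venous_ss(m, "uric_acid"), target)])
    model.set_param("process:ua_renal_clearance:k", fit.parameters["process:ua_renal_clearance:k"])
    return model


def allopurinol_model(
    gouty: bool = True,
    ka: float = 0.03,
    k_xo: float = 0.158,
    k_oxy_renal: float = 0.017,
    doses: list[DoseEvent] | None = None,
) -> PBPKModel:
    """Combined allopurinol + oxypurinol + uric acid whole-body model.

    Allopurinol is absorbed from the gut lumen and oxidized in the liver
    (first order, the xanthine-oxidase route) to oxypurinol with molar
    yield 1; oxypurinol undergoes slow renal elimination.  Absolute PK
    parameters are fixture choices giving literature-plausible half-lives
    (allopurinol ~1.5 h, oxypurinol ~20 h); only the printed IC50s and
    urate steady states are carried over from the study system.
    """
    comps = body_compartments(with_gut_lumen=True)
    ua = uric_acid_model(gouty=gouty)
    model = PBPKModel(
        compartments=comps,
        flows=body_flows(),
        species=[
            Species("allopurinol", MW_ALLOPURINOL),
            Species("oxypurinol", MW_OXYPURINOL),
            Species("uric_acid", MW_URIC_ACID),
        ],
        processes=[
            KineticProcess("allo_absorption", "oral_absorption", "gut_lumen", "allopurinol",
                           {"ka": ka, "to": "venous"}),
            KineticProcess("xo_clearance", "first_order", "liver", "allopurinol",
                           {"k": k_xo}, products=[("oxypurinol", 1.0)]),
            KineticProcess("oxy_renal_clearance", "first_order", "kidney", "oxypurinol",
                           {"k": k_oxy_renal}),
            ua.process("ua_production"),
            ua.process("ua_renal_clearance"),
        ],
        doses=doses or [],
        oral_dose_compartment="gut_lumen",
    )
    return model


def paracetamol_model(
    ka: float = 0.02,
    vmax_gluc: float = 38.5,
    km_gluc: float = 700.0,
    vmax_sulf: float = 6.0,
    km_sulf: float = 200.0,
    k_cyp: float = 0.010,
    k_pg_renal: float = 0.45,
    k_ps_renal: float = 0.45,
    k_napqi: float = 0.034,
    doses: list[DoseEvent] | None = None,
) -> PBPKModel:
    """Paracetamol + PG + PS + NAPQI whole-body model.

    Three hepatic clearance routes: saturable glucuronidation and
    sulfation (Michaelis-Menten, Vmax in µmol/L/min on the liver volume)
    and a linear CYP2E1 N-hydroxylation producing NAPQI.  At an overdose
    the conjugation routes saturate and the NAPQI share grows — the
    kinetic signature that drives the downstream inhibition analysis.
    Defaults give a therapeutic half-life of roughly 2.5 h.
    """
    comps = body_compartments(with_gut_lumen=True)
    model = PBPKModel(
        compartments=comps,
        flows=body_flows(),
        species=[
            Species("paracetamol", MW_PARACETAMOL),
            Species("pg", MW_PARACETAMOL + 176.12),
            Species("ps", MW_PARACETAMOL + 80.06),
            Species("napqi", 149.15),
        ],
        processes=[
            KineticProcess("apap_absorption", "oral_absorption", "gut_lumen", "paracetamol",
                           {"ka": ka, "to": "venous"}),
            KineticProcess("glucuronidation", "michaelis_menten", "liver", "paracetamol",
                           {"vmax": vmax_gluc, "km": km_gluc}, products=[("pg", 1.0)]),
            KineticProcess("sulfation", "michaelis_menten", "liver", "paracetamol",
                           {"vmax": vmax_sulf, "km": km_sulf}, products=[("ps", 1.0)]),
            KineticProcess("cyp2e1", "first_order", "liver", "paracetamol",
                           {"k": k_cyp}, products=[("napqi", 1.0)]),
            KineticProcess("pg_renal", "first_order", "kidney", "pg", {"k": k_pg_renal}),
            KineticProcess("ps_renal", "first_order", "kidney", "ps", {"k": k_ps_renal}),
            KineticProcess("napqi_conjugation", "first_order", "liver", "napqi", {"k": k_napqi}),
        ],
        doses=doses or [],
        oral_dose_compartment="gut_lumen",
    )
    return model
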