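"""The three case studies, scripted over the coupling machinery.

* :func:`run_ammonia_ucd` — pathogenesis of a urea-cycle disorder (OTC
  deficiency): the lumped urea-cycle reaction's activity ramps linearly to
  zero while glutamine/alanine output capacity is upregulated fourfold
  after a transcription/translation delay; venous ammonia rises to a new
  steady state.
* :func:`run_allopurinol` — hyperuricemia therapy: allopurinol and its
  long-lived metabolite oxypurinol competitively inhibit xanthine oxidase
  (indirect coupling), throttling hepatic uric-acid production (direct
  coupling) and lowering the venous urate steady state.
* :func:`run_paracetamol` — overdose toxication: NAPQI formed by the
  saturable clearance routes inhibits THFDH, GDH, ATP synthase and
  glutathione production; an FBA objective panel quantifies the loss of
  liver function at characteristic time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coupling import (
    DirectLink,
    Event,
    IndirectLink,
    InhibitionParams,
    MultiscaleModel,
    calibrate_ki_to_max_inhibition,
    relative_activity,
)
from .pbpk import DoseEvent, PBPKModel, State, Trajectory, linear_steady_state, simulate
from .population import CohortResult, PopulationSpec, run_cohort, sample_population
from .robustness import PanelReport, evaluate_panel
from .toyliver import (
    AMMONIA_OBJECTIVE,
    IC50_ALLOPURINOL,
    IC50_OXYPURINOL,
    MW_ALLOPURINOL,
    MW_PARACETAMOL,
    PURINE_OBJECTIVE,
    URATE_PRODUCTION,
    V_REF,
    allopurinol_model,
    ammonia_model,
    make_ammonia_network,
    make_gsh_panel,
    make_purine_network,
    paracetamol_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UCDProtocol",
    "ScenarioResult",
    "run_ammonia_ucd",
    "run_ammonia_cohort",
    "run_allopurinol",
    "run_paracetamol",
    "percent_decrease",
    "PARACETAMOL_MAX_INHIBITION",
]

MIN_PER_DAY = 1440.0


def percent_decrease(before: float, after: float) -> float:
    """Relative decrease in percent, 100·(before − after)/before."""
    if before == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (before - after) / before


@dataclass
class ScenarioResult:
    """Trajectories plus derived summaries for one scripted experiment."""

    name: str
    summaries: dict
    coupled: object = None          # CoupledResult, when the run was coupled
    trajectory: Trajectory | None = None
    panel_reports: dict | None = None
    event_log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ammonia / urea-cycle disorder


@dataclass
class UCDProtocol:
    """Timing of urea-cycle-disorder pathogenesis (minutes).

    The OTC-containing urea-cycle reaction loses activity linearly from 1
    to ``1 − depth`` over ``ramp_duration`` starting at ``onset``;
    glutamine/alanine output capacity rises ``upregulation_factor``-fold
    ``upregulation_delay`` after onset (transcription/translation delay).
    """

    onset: float = 1.0 * MIN_PER_DAY
    ramp_duration: float = 4.0 * MIN_PER_DAY
    upregulation_delay: float = 6.0 * 60.0
    upregulation_factor: float = 4.0
    total_duration: float = 21.0 * MIN_PER_DAY
    depth: float = 1.0

    def __post_init__(self) -> None:
        if min(self.onset, self.upregulation_delay, self.upregulation_factor, self.total_duration) <= 0:
            raise ValueError("protocol times and factor must be positive")
        if self.ramp_duration < 0 or not 0.0 <= self.depth <= 1.0:
            raise ValueError("ramp_duration must be >= 0 and depth in [0, 1]")
        if self.onset + self.ramp_duration > self.total_duration:
            raise ValueError("onset + ramp must fit within total_duration")

    def otc_activity(self, t: float) -> float:
        if t <= self.onset or self.depth == 0.0:
            return 1.0
        if self.ramp_duration == 0.0:
            return 1.0 - self.depth
        frac = min((t - self.onset) / self.ramp_duration, 1.0)
        return 1.0 - self.depth * frac


def _build_ammonia_multiscale(
    patient: dict | None = None,
    dt: float = 1.0,
    uptake_ub: float | None = None,
    otc_schedule=None,
) -> MultiscaleModel:
    model = ammonia_model(param_overrides=patient)
    net_kwargs = {} if uptake_ub is None else {"uptake_ub": uptake_ub}
    network = make_ammonia_network(**net_kwargs)
    schedules = {"OTC": otc_schedule} if otc_schedule is not None else {}
    return MultiscaleModel(
        pbpk=model,
        network=network,
        objective=AMMONIA_OBJECTIVE,
        direct_links=[DirectLink("liver_clearance", "EX_nh3", "uptake", volume_basis=V_REF)],
        activity_schedules=schedules,
        dt=dt,
    )


def _upregulation_event(protocol: UCDProtocol) -> Event:
    f = protocol.upregulation_factor

    def raise_caps(network) -> None:
        for rid in ("EX_gln", "EX_ala"):
            r = network.reaction(rid)
            network.set_bounds(rid, r.lower_bound * f, r.upper_bound * f)

    return Event(protocol.onset + protocol.upregulation_delay, raise_caps, "upregulate_gln_ala")


def run_ammonia_ucd(
    protocol: UCDProtocol | None = None,
    patient: dict | None = None,
    dt: float = 1.0,
) -> ScenarioResult:
    """Simulate UCD pathogenesis and report baseline/final steady states.

    The coupled model starts from the calibrated healthy steady state,
    runs undisturbed until disease onset (a consistency window used to
    verify baseline convergence), then applies the OTC activity ramp and
    the delayed capacity upregulation.
    """
    protocol = protocol or UCDProtocol()
    ms = _build_ammonia_multiscale(patient, dt, otc_schedule=protocol.otc_activity)
    init = linear_steady_state(ms.pbpk)
    events = [_upregulation_event(protocol)] if protocol.depth > 0 else []
    result = simulate_coupled_checked(ms, protocol.total_duration, events, init)
    venous = result.trajectory.conc("ammonia", "venous")
    i_onset = int(round(protocol.onset / dt))
    baseline = float(venous[i_onset])
    # baseline convergence check over the 6 h before onset
    i_back = max(0, i_onset - int(round(360 / dt)))
    if abs(venous[i_onset] - venous[i_back]) / max(baseline, 1e-12) > 1e-3:
        raise RuntimeError(
            f"baseline not converged before onset: venous moved "
            f"{venous[i_back]:.4f} -> {venous[i_onset]:.4f} µM in the last 6 h"
        )
    final = float(venous[-1])
    flux_at = lambda rid: float(result.flux_series(rid)[-1])
    summaries = {
        "baseline_venous_uM": baseline,
        "final_venous_uM": final,
        "relative_increase_pct": 100.0 * (final - baseline) / baseline,
        "final_uptake": flux_at("EX_nh3"),
        "final_urea": flux_at("EX_urea"),
        "final_gln": flux_at("EX_gln"),
        "final_ala": flux_at("EX_ala"),
        "baseline_uptake": float(result.flux_series("EX_nh3")[max(i_onset - 1, 0)]),
        "baseline_urea": float(result.flux_series("EX_urea")[max(i_onset - 1, 0)]),
        "fallback_steps": result.fallback_steps,
    }
    return ScenarioResult("ammonia_ucd", summaries, coupled=result,
                          trajectory=result.trajectory, event_log=result.events_applied)


def simulate_coupled_checked(ms, duration, events, init):
    from .coupling import simulate_coupled

    return simulate_coupled(ms, duration, events=events, init=init)


def ammonia_base_params(model: PBPKModel | None = None) -> dict[str, float]:
    """The three whole-body rate parameters a virtual population perturbs."""
    model = model or ammonia_model()
    return {
        "process:production:rate": model.get_param("process:production:rate"),
        "process:liver_clearance:k": model.get_param("process:liver_clearance:k"),
        "process:kidney_clearance:k": model.get_param("process:kidney_clearance:k"),
    }


def ucd_endpoints(params: dict[str, float], diseased_duration: float = 36.0 * 60.0,
                  dt: float = 1.0) -> tuple[float, float]:
    """Healthy and diseased steady-state venous ammonia for one individual.

    Healthy: steady state of the whole-body model (the coupled model is
    equivalent when no enzyme is impaired).  Diseased: coupled steady
    state with the urea-cycle reaction blocked and glutamine/alanine
    capacity fourfold up, run from the healthy state until equilibrated.
    """
    ms = _build_ammonia_multiscale(params, dt, otc_schedule=lambda t: 0.0)
    init = linear_steady_state(ms.pbpk)
    for rid in ("EX_gln", "EX_ala"):
        r = ms.network.reaction(rid)
        ms.network.set_bounds(rid, r.lower_bound * 4.0, r.upper_bound * 4.0)
    healthy = float(init.amounts[0, ms.pbpk.compartment_names.index("venous")]
                    / ms.pbpk.compartment("venous").volume)
    from .coupling import simulate_coupled

    res = simulate_coupled(ms, diseased_duration, init=init)
    venous = res.trajectory.conc("ammonia", "venous")
    # steady-state check: last hour must move < 0.1 %
    n_hr = int(round(60.0 / dt))
    if abs(venous[-1] - venous[-1 - n_hr]) / max(venous[-1], 1e-12) > 1e-3:
        raise RuntimeError("diseased state not converged")
    return healthy, float(venous[-1])


def run_ammonia_cohort(spec: PopulationSpec | None = None) -> CohortResult:
    """100-individual (by default) healthy-vs-UCD biomarker experiment."""
    spec = spec or PopulationSpec()
    base = ammonia_base_params()
    individuals = sample_population(spec, base)
    return run_cohort(individuals, ucd_endpoints)


# ---------------------------------------------------------------------------
# allopurinol / hyperuricemia


def run_allopurinol(
    dose_mg: float = 200.0,
    n_doses: int = 35,
    interval_min: float = MIN_PER_DAY,
    extra_duration: float = 0.0,
    gouty: bool = True,
    dt: float = 1.0,
) -> ScenarioResult:
    """Single- or multiple-dose allopurinol therapy of hyperuricemia.

    Both the parent drug and oxypurinol act as same-site competitive
    inhibitors of the xanthine oxidase activity; the network's uric-acid
    export, throttled by relE·v0, feeds back on the whole-body urate
    production (direct coupling).  Dosing is once daily by default.
    """
    dose_umol = dose_mg * 1000.0 / MW_ALLOPURINOL
    times = tuple(i * interval_min for i in range(n_doses))
    doses = [DoseEvent("allopurinol", dose_umol, "oral", times)] if n_doses > 0 else []
    model = allopurinol_model(gouty=gouty, doses=doses)
    network = make_purine_network(supply_ub=URATE_PRODUCTION)
    ms = MultiscaleModel(
        pbpk=model,
        network=network,
        objective=PURINE_OBJECTIVE,
        indirect_links=[
            IndirectLink("allopurinol", "liver", "XO", InhibitionParams(ic50=IC50_ALLOPURINOL)),
            IndirectLink("oxypurinol", "liver", "XO", InhibitionParams(ic50=IC50_OXYPURINOL)),
        ],
        direct_links=[DirectLink("ua_production", "EX_ua", "secretion", volume_basis=V_REF)],
        dt=dt,
    )
    # pre-treatment urate steady state (no drug on board)
    nodrug = model.copy()
    nodrug.doses = []
    init = linear_steady_state(nodrug)
    duration = n_doses * interval_min + extra_duration if n_doses else extra_duration
    from .coupling import simulate_coupled

    res = simulate_coupled(ms, duration, init=init)
    ua = res.trajectory.conc("uric_acid", "venous")
    allo = res.trajectory.conc("allopurinol", "venous")
    oxy = res.trajectory.conc("oxypurinol", "venous")
    baseline = float(ua[0])
    final = float(ua[-1])
    # per-interval troughs (concentration just before each next dose)
    steps_per_dose = int(round(interval_min / dt))
    trough_idx = [i * steps_per_dose for i in range(1, n_doses + 1) if i * steps_per_dose < len(allo)]
    summaries = {
        "baseline_uric_uM": baseline,
        "final_uric_uM": final,
        "min_uric_uM": float(ua.min()),
        "uric_decrease_pct": percent_decrease(baseline, final),
        "allopurinol_peak_uM": float(allo.max()),
        "allopurinol_troughs_uM": [float(allo[i]) for i in trough_idx],
        "oxypurinol_peak_uM": float(oxy.max()),
        "oxypurinol_troughs_uM": [float(oxy[i]) for i in trough_idx],
        "oxypurinol_mean_last_week_uM": float(oxy[-min(len(oxy), 7 * 1440):].mean()),
        "fallback_steps": res.fallback_steps,
    }
    return ScenarioResult("allopurinol", summaries, coupled=res, trajectory=res.trajectory)


# ---------------------------------------------------------------------------
# paracetamol / overdose robustness

#: fraction of enzyme activity lost at the lethal-dose NAPQI peak
PARACETAMOL_MAX_INHIBITION = {"THFDH": 0.25, "GDH": 0.25, "ATPS": 0.60, "GSH": 0.80}

LETHAL_DOSE_G = 15.0


def _paracetamol_dose_model(dose_g: float) -> PBPKModel:
    if dose_g == 0:
        return paracetamol_model(doses=[])
    dose_umol = dose_g * 1e6 / MW_PARACETAMOL
    return paracetamol_model(doses=[DoseEvent("paracetamol", dose_umol, "oral", (0.0,))])


def run_paracetamol(
    dose_g: float = 1.0,
    duration: float = 25.0 * 60.0,
    dt: float = 1.0,
    max_inhibition: dict | None = None,
    panel_size: int = 12,
) -> ScenarioResult:
    """Paracetamol PK plus the downstream liver-function robustness scan.

    Ki values for the four inhibited activities are calibrated so the
    NAPQI peak after the lethal reference dose (15 g) produces the
    literature maximal inhibition (THFDH/GDH 25 %, ATP synthase 60 %, GSH
    production 80 % of activity lost).  The AC conjugate is assumed to
    track the NAPQI concentration, so the liver NAPQI profile is the
    inhibitor input.  The objective panel is evaluated at t_max of
    paracetamol, t_max of NAPQI and at 24 h.
    """
    max_inh = max_inhibition or PARACETAMOL_MAX_INHIBITION
    ref_traj = simulate(_paracetamol_dose_model(LETHAL_DOSE_G), duration, dt)
    cmax_ref = float(ref_traj.conc("napqi", "liver").max())
    ki = {enz: calibrate_ki_to_max_inhibition(cmax_ref, mi) for enz, mi in max_inh.items()}
    if dose_g == LETHAL_DOSE_G:
        traj = ref_traj
    else:
        traj = simulate(_paracetamol_dose_model(dose_g), duration, dt) if dose_g > 0 else simulate(
            _paracetamol_dose_model(0.0), duration, dt)
    napqi_liver = traj.conc("napqi", "liver")
    par_venous = traj.conc("paracetamol", "venous")
    relE = {
        enz: np.array([relative_activity(c, InhibitionParams(ki=k)) for c in napqi_liver])
        for enz, k in ki.items()
    }
    i_tmax_par = int(np.argmax(par_venous)) if dose_g > 0 else 0
    i_tmax_napqi = int(np.argmax(napqi_liver)) if dose_g > 0 else 0
    i_24h = min(int(round(24 * 60 / dt)), len(traj.times) - 1)
    timepoints = {
        "t_max_paracetamol": i_tmax_par,
        "t_max_napqi": i_tmax_napqi,
        "t_24h": i_24h,
    }
    network, panel, deps = make_gsh_panel(panel_size)
    reports: dict[str, PanelReport] = {}
    for label, idx in timepoints.items():
        state = {enz: float(relE[enz][idx]) for enz in relE}
        reports[label] = evaluate_panel(network, panel, state, label=label)
    summaries = {
        "dose_g": dose_g,
        "napqi_cmax_liver_uM": float(napqi_liver.max()),
        "napqi_cmax_ref15g_uM": cmax_ref,
        "paracetamol_cmax_venous_uM": float(par_venous.max()),
        "ki_uM": ki,
        "relE_at_napqi_peak": {e: float(relE[e][i_tmax_napqi]) for e in relE},
        "relE_at_24h": {e: float(relE[e][i_24h]) for e in relE},
        "affected_counts": {lbl: rep.affected_count for lbl, rep in reports.items()},
        "timepoints_min": {lbl: float(traj.times[idx]) for lbl, idx in timepoints.items()},
        "dependencies": {k: sorted(v) for k, v in deps.items()},
    }
    return ScenarioResult("paracetamol", summaries, trajectory=traj, panel_reports=reports)
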