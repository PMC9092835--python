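"""Scripted in-silico protocols: BBB disruption, organ filling, GFR sweeps,
salivary transfer, and double-insult depletion experiments.

Every protocol is a deterministic function of its arguments; each returns a
:class:`ScenarioReport` whose summaries are recomputed from the stored
trajectories (nothing is cached).  "Operational steady state" in these
protocols means the state at a fixed readout horizon — 10 h unless noted —
because the late-time behaviour of both models is slow exponential decay
for which a relative-rate criterion is uninformative (see
:func:`s100b_pbpk.core.find_steady_state`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (ModelSpec, NoSteadyStateError, ScenarioEvent,
                   SimulationResult, find_steady_state, integrate)
from .model1 import build_model1
from .model2 import ORGANS2, BRAIN_INTERSTITIUM, build_model2

#: readout horizon used as the operational steady state, h
STEADY_STATE_HORIZON = 10.0


@dataclass
class ScenarioReport:
    scenario: str
    configuration: dict
    results: dict[str, SimulationResult]
    summaries: dict = field(default_factory=dict)


def _build(model: str, **kw) -> ModelSpec:
    if model == "model1":
        return build_model1(**kw)
    if model == "model2":
        return build_model2(**kw)
    raise ValueError(f"unknown model id {model!r}")


def _venous(res: SimulationResult) -> np.ndarray:
    return res.conc("Venous blood")


def _peak(times: np.ndarray, trace: np.ndarray) -> tuple[float, float]:
    k = int(np.argmax(trace))
    return float(trace[k]), float(times[k])


def time_to_fraction(times: np.ndarray, trace: np.ndarray,
                     fraction: float = 0.9) -> float:
    """First time the trace reaches ``fraction`` of its final value."""
    target = fraction * trace[-1]
    hit = np.nonzero(trace >= target)[0]
    return float(times[hit[0]]) if hit.size else float(times[-1])


# ---------------------------------------------------------------------------

def scenario_bbbd(model: str = "model1",
                  bbb_values: tuple[float, ...] = (0.0, 1.0),
                  trigger: str = "t0",
                  horizon: float = STEADY_STATE_HORIZON,
                  settle: float = STEADY_STATE_HORIZON,
                  dt_out: float = 0.05) -> ScenarioReport:
    """Baseline vs BBB-disrupted runs.

    ``trigger="t0"`` applies each BBB_Index from the start (kinetic display
    of organs settling toward their operational steady state);
    ``trigger="at-steady-state"`` first settles for ``settle`` hours with an
    intact barrier, then steps BBB_Index.
    """
    if trigger not in ("t0", "at-steady-state"):
        raise ValueError(f"unknown trigger {trigger!r}")
    results: dict[str, SimulationResult] = {}
    summaries: dict = {"steady_state": {}, "venous_peak": {}}
    for b in bbb_values:
        key = f"bbb={b:g}"
        spec = _build(model)
        if trigger == "t0":
            spec.params.controls.bbb_index = b
            res = integrate(spec, horizon, dt_out=dt_out)
        else:
            res = integrate(spec, settle + horizon, dt_out=dt_out,
                            events=[ScenarioEvent(settle,
                                                  "controls.bbb_index", b)])
        results[key] = res
        summaries["steady_state"][key] = {
            n: float(res.concentrations[-1, i])
            for i, n in enumerate(res.names)}
        peak, t_peak = _peak(res.times, _venous(res))
        summaries["venous_peak"][key] = {"value": peak, "time_h": t_peak}
    return ScenarioReport(
        "bbbd",
        {"model": model, "bbb_values": list(bbb_values), "trigger": trigger,
         "horizon_h": horizon, "settle_h": settle},
        results, summaries)


def steady_state_organ_ranking(horizon: float = STEADY_STATE_HORIZON
                               ) -> list[str]:
    """Model-1 organs ranked by parenchymal concentration at the
    operational steady state (intact BBB), highest first."""
    from .model1 import ORGAN_COMPARTMENTS
    res = scenario_bbbd("model1", (0.0,), horizon=horizon).results["bbb=0"]
    final = {par: float(res.conc(par)[-1])
             for par, _ in ORGAN_COMPARTMENTS.values()}
    return sorted(final, key=lambda n: -final[n])


def scenario_empty_organs(c_interstitium_brain: float = 10.0,
                          horizon: float = 100.0,
                          glymphatics: float = 8.4,
                          dt_out: float = 0.25) -> ScenarioReport:
    """'Filling' of emptied peripheral organs from the brain reservoir.

    The glymphatics-on run zeroes muscle/adipose/gut S100B and lets the
    glymphatic route load them from the brain interstitium; the control run
    additionally removes every S100B source (organs, kidney, blood, BBB,
    glymphatics, trauma), under which the venous trace must stay at zero.
    """
    results: dict[str, SimulationResult] = {}

    spec_on = build_model2(c_interstitium_brain=c_interstitium_brain)
    spec_on.params.controls.glymphatics = glymphatics
    for inter, vasc in ORGANS2.values():
        spec_on.compartments[inter].concentration = 0.0
        spec_on.compartments[vasc].concentration = 0.0
    results["glymphatics_on"] = integrate(spec_on, horizon, dt_out=dt_out)

    spec_off = build_model2(c_interstitium_brain=c_interstitium_brain)
    spec_off.params.controls.glymphatics = 0.0
    for comp in spec_off.compartments.values():
        if not comp.clamped and comp.name != BRAIN_INTERSTITIUM:
            comp.concentration = 0.0
    results["all_sources_off"] = integrate(spec_off, horizon, dt_out=dt_out)

    organ_final = {
        inter: float(results["glymphatics_on"].conc(inter)[-1])
        for inter, _ in ORGANS2.values()}
    summaries = {
        "organ_interstitium_final": organ_final,
        "venous_max_glymphatics_on":
            float(_venous(results["glymphatics_on"]).max()),
        "venous_max_all_sources_off":
            float(np.abs(_venous(results["all_sources_off"])).max()),
    }
    return ScenarioReport(
        "empty-organs",
        {"c_interstitium_brain": c_interstitium_brain, "horizon_h": horizon,
         "glymphatics_ml_h": glymphatics},
        results, summaries)


def scenario_gfr_sweep(gfr_values: tuple[float, ...] = (0.0, 10.0, 100.0),
                       bbb_values: tuple[float, ...] = (0.0, 1.0),
                       horizon: float = 25.0,
                       steady_t_max: float = 200.0,
                       dt_out: float = 0.1) -> ScenarioReport:
    """Model-2 runs across GFR x BBB_Index; flags unbounded accumulation.

    A GFR of zero removes the only major elimination route, so venous and
    organ levels keep rising over the horizon and no steady state exists
    within ``steady_t_max``; the report flags this instead of failing.
    """
    if not gfr_values:
        raise ValueError("gfr_values must be non-empty")
    if any(g < 0 for g in gfr_values):
        raise ValueError("GFR must be >= 0")
    results: dict[str, SimulationResult] = {}
    summaries: dict = {"venous_final": {}, "unbounded_growth": {},
                       "gut_interstitium_final": {},
                       "brain_interstitium_final": {}}
    for g in gfr_values:
        for b in bbb_values:
            key = f"gfr={g:g},bbb={b:g}"
            spec = build_model2()
            spec.params.renal.gfr_ml_h = g
            spec.params.controls.bbb_index = b
            res = integrate(spec, horizon, dt_out=dt_out)
            results[key] = res
            ven = _venous(res)
            half = len(ven) // 2
            rising = bool(np.all(np.diff(ven[half:]) > -1e-12)
                          and ven[-1] > ven[half])
            no_ss = False
            if rising:
                try:
                    find_steady_state(spec, t_max=steady_t_max)
                except NoSteadyStateError:
                    no_ss = True
            summaries["venous_final"][key] = float(ven[-1])
            summaries["unbounded_growth"][key] = rising and no_ss
            summaries["gut_interstitium_final"][key] = \
                float(res.conc("Interstitium gut")[-1])
            summaries["brain_interstitium_final"][key] = \
                float(res.conc(BRAIN_INTERSTITIUM)[-1])
    return ScenarioReport(
        "gfr-sweep",
        {"gfr_values": list(gfr_values), "bbb_values": list(bbb_values),
         "horizon_h": horizon},
        results, summaries)


def scenario_saliva(flows_ml_min: tuple[float, ...] = (4.0, 2.0),
                    settle: float = 50.0, horizon: float = 150.0,
                    bbb_after: float = 1.0,
                    dt_out: float = 0.1) -> ScenarioReport:
    """Salivary accumulation at different crevicular flows, with a BBBD step.

    Saliva has no outflow, so its level converges to the flow-weighted time
    integral of arterial S100B — a genuine plateau that exceeds blood levels
    at the higher flow, approached much more slowly than the venous
    transient.
    """
    if any(f < 0 for f in flows_ml_min):
        raise ValueError("salivary flow must be >= 0")
    results: dict[str, SimulationResult] = {}
    summaries: dict = {"saliva_settle": {}, "venous_peak_pre_bbbd": {},
                       "saliva_final": {}, "time_to_90pct": {}}
    for f in flows_ml_min:
        key = f"flow={f:g}ml/min"
        spec = build_model2()
        spec.params.saliva.flow_ml_h = f * 60.0
        res = integrate(spec, horizon, dt_out=dt_out,
                        events=[ScenarioEvent(settle, "controls.bbb_index",
                                              bbb_after)])
        results[key] = res
        pre = res.times <= settle
        sal, ven = res.conc("Saliva"), _venous(res)
        summaries["saliva_settle"][key] = float(sal[pre][-1])
        summaries["venous_peak_pre_bbbd"][key] = float(ven[pre].max())
        summaries["saliva_final"][key] = float(sal[-1])
        summaries["time_to_90pct"][key] = {
            "saliva": time_to_fraction(res.times[pre], sal[pre]),
            "venous": time_to_fraction(res.times[pre], ven[pre]),
        }
    return ScenarioReport(
        "saliva",
        {"flows_ml_min": list(flows_ml_min), "settle_h": settle,
         "horizon_h": horizon, "bbb_after": bbb_after},
        results, summaries)


def scenario_double_insult(first_bbb: tuple[float, ...] = (0.1, 0.3, 1.0),
                           second_bbb: float = 1.0,
                           gap: float = 10.0,
                           settle: float = STEADY_STATE_HORIZON,
                           tail: float = 10.0,
                           trauma_index: float = 0.0,
                           dt_out: float = 0.05) -> ScenarioReport:
    """Two sequential BBB-disruption episodes probing interstitial depletion.

    After a settle period the barrier opens to each ``first_bbb`` value
    (sustained), then steps to ``second_bbb`` after ``gap`` hours.  The
    venous increment of the second episode shrinks as the first episode
    depletes the brain interstitium; an active Trauma_Index replenishes the
    reservoir and restores the second response.
    """
    results: dict[str, SimulationResult] = {}
    summaries: dict = {"venous_increments": {},
                       "interstitium_at_second_event": {}}
    for b1 in first_bbb:
        key = f"first_bbb={b1:g}"
        spec = build_model2()
        spec.params.controls.trauma_index = trauma_index
        t1, t2 = settle, settle + gap
        res = integrate(spec, t2 + tail, dt_out=dt_out, events=[
            ScenarioEvent(t1, "controls.bbb_index", b1),
            ScenarioEvent(t2, "controls.bbb_index", second_bbb),
        ])
        results[key] = res
        ven = _venous(res)

        def increment(t_from: float, t_to: float) -> float:
            win = (res.times >= t_from) & (res.times <= t_to)
            base = ven[res.times == t_from][0]
            return float(ven[win].max() - base)

        summaries["venous_increments"][key] = {
            "first": increment(t1, t2), "second": increment(t2, t2 + tail)}
        summaries["interstitium_at_second_event"][key] = float(
            res.conc(BRAIN_INTERSTITIUM)[res.times == t2][0])
    return ScenarioReport(
        "double-insult",
        {"first_bbb": list(first_bbb), "second_bbb": second_bbb,
         "gap_h": gap, "settle_h": settle, "tail_h": tail,
         "trauma_index": trauma_index},
        results, summaries)
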