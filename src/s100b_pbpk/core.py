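"""Compartment-network core shared by both S100B kinetic models.

A model is a set of well-mixed compartments (organ parenchyma, vascular
fractions, blood pools, lymph, urine, saliva, glia) connected by flux terms.
Every transport process in either model — convective blood/lymph flow,
pore- or sigma-mediated transcapillary exchange, BBB leakage, trauma release
from the clamped glial reservoir, glomerular filtration — is linear in the
source compartment's concentration, so each is represented by a single
primitive:

    flux (ng/h) = coeff (ml/h) * concentration of `source` (ng/ml)

moved from `source` to `target`.  A ``target`` of ``None`` is an external
sink (e.g. urine voiding); a clamped source (the glial reservoir) acts as an
external input.  The right-hand side assembled from these terms is
``dc/dt = A c`` with clamped rows zeroed, which gives an analytic Jacobian
for the stiff integrator and makes mass accounting exact: two auxiliary
states accumulate all external inputs and outputs so that

    total mass + cumulative out - cumulative in = const

holds to integrator tolerance along any trajectory.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

logger = logging.getLogger("s100b_pbpk")

ROLES = {
    "parenchyma", "vascular_fraction", "interstitium", "vascular", "cellular",
    "arterial", "venous", "lymph", "urine", "saliva", "kidney",
}
#: roles whose compartments are treated as terminal accumulators by
#: :meth:`SimulationResult.cumulative_excreted`
TERMINAL_ROLES = {"urine", "saliva"}
FLOW_KINDS = {"blood", "lymph", "glymphatic", "salivary", "shunt"}


class ConfigurationError(ValueError):
    """Raised when a model specification or config file is inconsistent."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time and state."""


class NoSteadyStateError(RuntimeError):
    """Raised when the steady-state criterion is not met within t_max."""


@dataclass
class Compartment:
    name: str
    volume: float            # ml
    concentration: float     # ng/ml, initial value
    role: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ConfigurationError(
                f"compartment {self.name!r}: volume must be > 0, got {self.volume}")
        if self.concentration < 0:
            raise ConfigurationError(
                f"compartment {self.name!r}: negative initial concentration")
        if self.role not in ROLES:
            raise ConfigurationError(
                f"compartment {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class FluxTerm:
    """One linear transport term: coeff * c(source), moved source -> target."""
    source: str
    target: str | None
    coeff: float             # ml/h equivalent
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.coeff < 0:
            raise ConfigurationError(
                f"flux term {self.label or self.kind}: negative coefficient "
                f"{self.coeff}")
        if self.target is not None and self.source == self.target:
            raise ConfigurationError(
                f"flux term {self.label or self.kind}: source == target "
                f"({self.source!r})")


@dataclass(frozen=True)
class ScenarioEvent:
    """A timed step change of one parameter (dotted path into spec.params)."""
    time: float
    parameter: str
    value: float


@dataclass
class ModelSpec:
    """A complete compartment network plus the parameters that shape it.

    ``term_builder(params, compartments)`` regenerates the flux-term list
    from the current parameter values; it is re-invoked after every
    :class:`ScenarioEvent` so that step changes of BBB_Index, Trauma_Index,
    glymphatic flow, GFR etc. take effect.
    """
    name: str
    compartments: dict[str, Compartment]
    params: object
    term_builder: Callable[[object, dict[str, Compartment]], list[FluxTerm]]
    conversion_log: list[str] = field(default_factory=list)

    # -- convenience views -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.compartments)

    @property
    def controls(self):
        return getattr(self.params, "controls", None)

    def terms(self) -> list[FluxTerm]:
        return self.term_builder(self.params, self.compartments)

    def edges(self) -> list[FluxTerm]:
        """Volumetric transport edges (blood/lymph/glymphatic/salivary/shunt)."""
        return [t for t in self.terms() if t.kind in FLOW_KINDS]

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.compartments)}

    def volumes(self) -> np.ndarray:
        return np.array([c.volume for c in self.compartments.values()])

    def clamped_mask(self) -> np.ndarray:
        return np.array([c.clamped for c in self.compartments.values()])

    def initial_state(self) -> np.ndarray:
        return np.array([c.concentration for c in self.compartments.values()])

    def copy(self) -> "ModelSpec":
        return ModelSpec(self.name, copy.deepcopy(self.compartments),
                         copy.deepcopy(self.params), self.term_builder,
                         list(self.conversion_log))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for t in self.terms():
            if t.source not in self.compartments:
                raise ConfigurationError(
                    f"flux term {t.label or t.kind}: unknown source "
                    f"compartment {t.source!r}")
            if t.target is not None and t.target not in self.compartments:
                raise ConfigurationError(
                    f"flux term {t.label or t.kind}: unknown target "
                    f"compartment {t.target!r}")
        imb = self.flow_imbalance()
        for name, (qin, qout) in imb.items():
            if abs(qin - qout) > 1e-9 * max(qin, qout, 1.0):
                logger.warning(
                    "volumetric flow imbalance at %r: in %.6g ml/h, out %.6g "
                    "ml/h (solute mass balance is unaffected)", name, qin, qout)

    def flow_imbalance(self) -> dict[str, tuple[float, float]]:
        """Total volumetric (in, out) flow per non-terminal blood-side node.

        Only edges in FLOW_KINDS are counted; terminal sinks (urine, saliva)
        and non-flow compartments are skipped.
        """
        flows_in: dict[str, float] = {}
        flows_out: dict[str, float] = {}
        for t in self.edges():
            flows_out[t.source] = flows_out.get(t.source, 0.0) + t.coeff
            if t.target is not None:
                flows_in[t.target] = flows_in.get(t.target, 0.0) + t.coeff
        blood_roles = {"arterial", "venous", "vascular", "vascular_fraction",
                       "lymph", "kidney"}
        report = {}
        for name, comp in self.compartments.items():
            if comp.role not in blood_roles or comp.clamped:
                continue
            qin, qout = flows_in.get(name, 0.0), flows_out.get(name, 0.0)
            if qin or qout:
                report[name] = (qin, qout)
        return report


# ---------------------------------------------------------------------------
# linear-system assembly
# ---------------------------------------------------------------------------

def linear_system(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble ``dc/dt = A c`` plus the external input/output audit rows.

    Returns ``(A, e_in, e_out)`` where ``e_in @ c`` is the instantaneous
    external input rate (fluxes sourced from clamped compartments) and
    ``e_out @ c`` the external output rate (fluxes into ``None`` or into a
    clamped compartment).  Clamped rows of ``A`` are zero, so clamped
    concentrations are constant along any trajectory.
    """
    idx = spec.index()
    vol = spec.volumes()
    clamped = spec.clamped_mask()
    n = len(idx)
    A = np.zeros((n, n))
    e_in = np.zeros(n)
    e_out = np.zeros(n)
    for t in spec.terms():
        i_s = idx[t.source]
        i_t = idx[t.target] if t.target is not None else None
        src_clamped = clamped[i_s]
        tgt_external = i_t is None or clamped[i_t]
        if not src_clamped:
            A[i_s, i_s] -= t.coeff / vol[i_s]
        if i_t is not None and not clamped[i_t]:
            A[i_t, i_s] += t.coeff / vol[i_t]
        if src_clamped and not tgt_external:
            e_in[i_s] += t.coeff
        if not src_clamped and tgt_external:
            e_out[i_s] += t.coeff
    return A, e_in, e_out


def assemble_rhs(spec: ModelSpec) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return the derivative function f(t, c) -> dc/dt over concentrations.

    The function closes over the spec's *current* parameter values; rebuild
    it after mutating ``spec.params``.
    """
    spec.validate()
    A, _, _ = linear_system(spec)

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        return A @ c

    rhs.jacobian = A  # type: ignore[attr-defined]
    return rhs


def _augmented(spec: ModelSpec) -> np.ndarray:
    A, e_in, e_out = linear_system(spec)
    n = A.shape[0]
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = A
    M[n, :n] = e_in
    M[n + 1, :n] = e_out
    return M


def set_by_path(obj: object, path: str, value: float) -> None:
    """Set a dotted attribute/key path, e.g. ``controls.bbb_index``."""
    parts = path.split(".")
    for p in parts[:-1]:
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise ConfigurationError(f"unknown parameter path {path!r}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise ConfigurationError(f"unknown parameter path {path!r}")
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time grid, per-compartment trajectories and mass audit channels."""
    spec_name: str
    times: np.ndarray                       # h, strictly increasing
    names: list[str]
    concentrations: np.ndarray              # (n_times, n_compartments), ng/ml
    volumes: np.ndarray                     # ml
    clamped: np.ndarray                     # bool mask
    cum_in: np.ndarray                      # ng entered from clamped sources
    cum_out: np.ndarray                     # ng left to external sinks
    terminal: np.ndarray                    # bool mask of terminal accumulators
    events_applied: list[ScenarioEvent] = field(default_factory=list)

    def conc(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.names.index(name)]

    @property
    def amounts(self) -> np.ndarray:
        """Per-compartment mass series, ng."""
        return self.concentrations * self.volumes

    def total_mass(self) -> np.ndarray:
        """Total mass over non-clamped compartments, ng."""
        free = ~self.clamped
        return self.amounts[:, free].sum(axis=1)

    def cumulative_excreted(self) -> np.ndarray:
        """ng removed from circulation: terminal-compartment load + external sinks."""
        return self.amounts[:, self.terminal & ~self.clamped].sum(axis=1) + self.cum_out

    def mass_residual(self) -> np.ndarray:
        """|balance(t) - balance(0)| where balance = mass + out - in."""
        bal = self.total_mass() + self.cum_out - self.cum_in
        return np.abs(bal - bal[0])

    @property
    def final_state(self) -> np.ndarray:
        return self.concentrations[-1].copy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, compartment, concentration_ng_per_ml, amount_ng."""
        order = sorted(range(len(self.names)), key=lambda i: self.names[i])
        rows = []
        for i in order:
            rows.append(pd.DataFrame({
                "time_h": self.times,
                "compartment": self.names[i],
                "concentration_ng_per_ml": self.concentrations[:, i],
                "amount_ng": self.concentrations[:, i] * self.volumes[i],
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _output_grid(t0: float, t_end: float, dt_out: float,
                 event_times: Iterable[float]) -> np.ndarray:
    grid = np.arange(t0, t_end + 0.5 * dt_out, dt_out)
    pts = np.unique(np.concatenate([grid, np.asarray(list(event_times), float),
                                    [t0, t_end]]))
    return pts[(pts >= t0) & (pts <= t_end)]


def integrate(spec: ModelSpec, t_end: float,
              events: Sequence[ScenarioEvent] = (),
              dt_out: float = 0.1,
              state0: np.ndarray | None = None,
              rtol: float = 1e-8, atol: float = 1e-11,
              method: str = "BDF") -> SimulationResult:
    """Event-aware stiff integration on [0, t_end].

    Integration restarts at every event time; the output is sampled on the
    ``dt_out`` grid plus event times.  Parameter changes are applied to a
    private copy of the spec, so the caller's spec is untouched.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    events = sorted(events, key=lambda e: e.time)
    for e in events:
        if not (0.0 <= e.time <= t_end):
            raise ValueError(f"event at t={e.time} outside [0, {t_end}]")
    work = spec.copy()
    work.validate()

    grid = _output_grid(0.0, t_end, dt_out, (e.time for e in events))
    breaks = [0.0] + [e.time for e in events] + [t_end]

    n = len(work.compartments)
    z = np.zeros(n + 2)
    z[:n] = work.initial_state() if state0 is None else np.asarray(state0, float)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    applied: list[ScenarioEvent] = []
    ei = 0
    t_cur = 0.0
    first = True
    for ei, t_next in enumerate(breaks[1:]):
        if ei > 0:
            ev = events[ei - 1]
            set_by_path(work.params, ev.parameter, ev.value)
            applied.append(ev)
            logger.info("event applied at t=%g h: %s = %g",
                        ev.time, ev.parameter, ev.value)
        if t_next <= t_cur:        # coincident event times
            continue
        M = _augmented(work)
        seg = grid[(grid >= t_cur) & (grid <= t_next)]
        if seg.size == 0 or seg[0] > t_cur:
            seg = np.concatenate([[t_cur], seg])
        if seg[-1] < t_next:
            seg = np.concatenate([seg, [t_next]])
        sol = solve_ivp(lambda t, y: M @ y, (t_cur, t_next), z,
                        method=method, t_eval=seg, jac=M,
                        rtol=rtol, atol=atol)
        if not sol.success:
            t_fail = sol.t[-1] if sol.t.size else t_cur
            raise IntegrationError(
                f"integrator failed at t={t_fail:.6g} h "
                f"(segment [{t_cur:g}, {t_next:g}]): {sol.message}; "
                f"state={z[:n]}")
        keep = slice(None) if first else slice(1, None)
        times.append(sol.t[keep])
        states.append(sol.y[:, keep].T)
        z = sol.y[:, -1].copy()
        t_cur = t_next
        first = False

    t_all = np.concatenate(times)
    z_all = np.vstack(states)
    return SimulationResult(
        spec_name=work.name,
        times=t_all,
        names=work.names,
        concentrations=z_all[:, :n],
        volumes=work.volumes(),
        clamped=work.clamped_mask(),
        cum_in=z_all[:, n],
        cum_out=z_all[:, n + 1],
        terminal=np.array([c.role in TERMINAL_ROLES
                           for c in work.compartments.values()]),
        events_applied=applied,
    )


def integrate_fixed_step(spec: ModelSpec, t_end: float, dt: float,
                         dt_out: float = 0.1,
                         state0: np.ndarray | None = None) -> SimulationResult:
    """Fixed-step fourth-order reference integrator (no events).

    For the constant-coefficient linear systems built here, classical RK4
    reduces exactly to the fourth-order Taylor propagator
    ``P = I + hM + (hM)^2/2 + (hM)^3/6 + (hM)^4/24`` applied once per step,
    which is what this implements.  It serves as the cross-check for the
    adaptive path, not as the production integrator.
    """
    spec.validate()
    M = _augmented(spec)
    n = len(spec.compartments)
    z = np.zeros(n + 2)
    z[:n] = spec.initial_state() if state0 is None else np.asarray(state0, float)

    H = dt * M
    P = np.eye(M.shape[0]) + H @ (np.eye(M.shape[0]) + H @ (
        np.eye(M.shape[0]) / 2 + H @ (np.eye(M.shape[0]) / 6 + H / 24)))
    n_steps = int(round(t_end / dt))
    stride = max(1, int(round(dt_out / dt)))
    times = [0.0]
    states = [z.copy()]
    for k in range(1, n_steps + 1):
        z = P @ z
        if k % stride == 0 or k == n_steps:
            times.append(k * dt)
            states.append(z.copy())
    z_all = np.vstack(states)
    return SimulationResult(
        spec_name=spec.name,
        times=np.array(times),
        names=spec.names,
        concentrations=z_all[:, :n],
        volumes=spec.volumes(),
        clamped=spec.clamped_mask(),
        cum_in=z_all[:, n],
        cum_out=z_all[:, n + 1],
        terminal=np.array([c.role in TERMINAL_ROLES
                           for c in spec.compartments.values()]),
    )


# ---------------------------------------------------------------------------
# steady state & mass audit
# ---------------------------------------------------------------------------

def find_steady_state(spec: ModelSpec, tol: float = 1e-6,
                      t_max: float = 1000.0, floor: float = 1e-9,
                      state0: np.ndarray | None = None,
                      dt_out: float = 0.5) -> tuple[np.ndarray, float]:
    """Integrate until all non-clamped relative rates fall below ``tol``.

    The criterion is ``max_i |dc_i/dt| / max(|c_i|, floor) < tol`` over
    non-clamped compartments.  Returns ``(state, time)`` for the first grid
    time at which it holds; raises :class:`NoSteadyStateError` otherwise.
    Note that a trajectory in pure exponential decay has a scale-invariant
    relative rate and will not satisfy the criterion until it underflows the
    floor — callers simulating decaying systems should prefer a fixed
    horizon (see the scenarios module).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    work = spec.copy()
    work.validate()
    A, _, _ = linear_system(work)
    free = ~work.clamped_mask()
    state = work.initial_state() if state0 is None else np.asarray(state0, float)

    def ok(c: np.ndarray) -> bool:
        rate = A @ c
        denom = np.maximum(np.abs(c), floor)
        return bool(np.max(np.abs(rate[free]) / denom[free]) < tol)

    if ok(state):
        return state, 0.0

    t_cur = 0.0
    chunk = max(10 * dt_out, min(50.0, t_max))
    while t_cur < t_max:
        t_next = min(t_cur + chunk, t_max)
        res = integrate(work, t_next - t_cur, dt_out=dt_out, state0=state)
        for k, tk in enumerate(res.times):
            if tk == 0.0:
                continue
            if ok(res.concentrations[k]):
                return res.concentrations[k].copy(), t_cur + tk
        state = res.final_state
        t_cur = t_next
    raise NoSteadyStateError(
        f"no steady state within t_max={t_max} h (tol={tol})")


@dataclass
class MassAudit:
    frame: pd.DataFrame
    max_residual: float          # relative to the mass scale of the run
    tolerance: float
    flagged: pd.DataFrame

    @property
    def ok(self) -> bool:
        return len(self.flagged) == 0


def mass_audit(result: SimulationResult, tol: float = 1e-6) -> MassAudit:
    """Check mass + cumulative-out - cumulative-in = const along the run."""
    total = result.total_mass()
    bal = total + result.cum_out - result.cum_in
    scale = max(float(np.max(np.abs(bal))), float(np.max(total)), 1e-12)
    resid = np.abs(bal - bal[0]) / scale
    frame = pd.DataFrame({
        "time_h": result.times,
        "total_mass_ng": total,
        "cumulative_in_ng": result.cum_in,
        "cumulative_out_ng": result.cum_out,
        "relative_residual": resid,
    })
    flagged = frame[frame["relative_residual"] > tol]
    return MassAudit(frame=frame, max_residual=float(resid.max()),
                     tolerance=tol, flagged=flagged)
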