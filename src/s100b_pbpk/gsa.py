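"""Variance-based global sensitivity analysis of compartment initial levels.

Inputs are initial S100B concentrations of selected compartments, sampled
from a scrambled Sobol sequence arranged in Saltelli blocks (A, B, AB_i).
Outputs are per-compartment observables (time-integrated concentration over
the horizon, or the terminal value).  First-order indices use the
Saltelli-2010 estimator, total-order indices the Jansen estimator; the
unexplained fraction is 1 - sum of first-order indices per output.

Because every transport term is linear in concentration, the map from
initial state to any output functional is affine; ``model_evaluator`` with
``method="superposition"`` therefore reconstructs it exactly from
``n_inputs + 1`` integrations and evaluates samples by dot product.  The
generic per-sample path (``method="direct"``) integrates every sample and
is used to cross-check the fast path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .core import IntegrationError, ModelSpec, integrate

#: Model-2 sensitivity inputs in the conventional numbering (1..11)
MODEL2_GSA_INPUTS = (
    "Venous blood", "Vascular compartment brain", "Vascular space adipose",
    "Vascular space gut", "Vascular space muscle", "Interstitium adipose",
    "Interstitium brain", "Interstitium gut", "Interstitium muscle",
    "Arterial blood", "Central lymph",
)
DEFAULT_OUTPUTS = ("Venous blood", "Arterial blood", "Central lymph")


class DesignError(ValueError):
    pass


@dataclass
class GsaDesign:
    """Sampling design: inputs with bounds, outputs, horizon, sample count."""
    inputs: list[tuple[str, float, float]]   # (compartment, lower, upper)
    outputs: list[str]
    n_samples: int = 1000
    seed: int = 0
    horizon: float = 10.0                    # h
    dt_out: float = 0.1
    functional: str = "integral"             # or "terminal"

    def __post_init__(self) -> None:
        if not self.inputs:
            raise DesignError("design needs at least one input")
        if self.n_samples < 2:
            raise DesignError("n_samples must be >= 2")
        if self.functional not in ("integral", "terminal"):
            raise DesignError(f"unknown functional {self.functional!r}")
        for name, lo, hi in self.inputs:
            if not lo < hi:
                raise DesignError(
                    f"input {name!r}: degenerate bounds [{lo}, {hi}]")

    @property
    def input_names(self) -> list[str]:
        return [n for n, _, _ in self.inputs]


def default_design(spec: ModelSpec,
                   input_names: Sequence[str] = MODEL2_GSA_INPUTS,
                   outputs: Sequence[str] = DEFAULT_OUTPUTS,
                   n_samples: int = 1000, seed: int = 0,
                   horizon: float = 10.0, **kw) -> GsaDesign:
    """Bounds rule: [0, 2 x default] for nonzero initials, [0, 1] for zeros."""
    inputs = []
    for name in input_names:
        c0 = spec.compartments[name].concentration
        inputs.append((name, 0.0, 2.0 * c0 if c0 > 0 else 1.0))
    return GsaDesign(inputs=inputs, outputs=list(outputs),
                     n_samples=n_samples, seed=seed, horizon=horizon, **kw)


@dataclass
class SobolSample:
    """Saltelli blocks: A, B are (N, d); AB[i] is A with column i from B."""
    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray          # (d, N, d)

    @property
    def n_evaluations(self) -> int:
        d = self.A.shape[1]
        return self.A.shape[0] * (d + 2)

    def stacked(self) -> np.ndarray:
        return np.vstack([self.A, self.B,
                          self.AB.reshape(-1, self.A.shape[1])])


def sobol_sample(design: GsaDesign) -> SobolSample:
    """Deterministic-under-seed quasi-random Saltelli sample over the bounds."""
    d = len(design.inputs)
    lo = np.array([b[1] for b in design.inputs])
    hi = np.array([b[2] for b in design.inputs])
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=design.seed)
    with warnings.catch_warnings():
        # the published sample count (1000) is not a power of two
        warnings.simplefilter("ignore", UserWarning)
        base = sampler.random(design.n_samples)
    A = lo + (hi - lo) * base[:, :d]
    B = lo + (hi - lo) * base[:, d:]
    AB = np.repeat(A[None, :, :], d, axis=0)
    for i in range(d):
        AB[i, :, i] = B[:, i]
    return SobolSample(A=A, B=B, AB=AB)


@dataclass
class SensitivityResult:
    """First/total-order Sobol indices per (input, output)."""
    inputs: list[str]
    outputs: list[str]
    first_order: np.ndarray       # (n_inputs, n_outputs)
    total_order: np.ndarray       # (n_inputs, n_outputs)
    unexplained: np.ndarray       # (n_outputs,), 1 - sum first-order
    n_samples: int
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for j, out in enumerate(self.outputs):
            for i, inp in enumerate(self.inputs):
                rows.append({"input": inp, "output": out,
                             "first_order": self.first_order[i, j],
                             "total_order": self.total_order[i, j]})
        return pd.DataFrame(rows)

    def unexplained_frame(self):
        import pandas as pd
        return pd.DataFrame({"output": self.outputs,
                             "unexplained": self.unexplained})


def estimate_sobol(f_A: np.ndarray, f_B: np.ndarray,
                   f_AB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Saltelli-2010 first-order and Jansen total-order estimators.

    Shapes: f_A, f_B (N, m); f_AB (d, N, m).  Returns (S1, ST) of shape
    (d, m).  Outputs with (near-)zero variance get zero indices.
    """
    allf = np.concatenate([f_A, f_B], axis=0)
    V = allf.var(axis=0, ddof=1)
    scale = np.maximum(np.abs(allf).max(axis=0), 1.0) ** 2
    safe = np.where(V > 1e-14 * scale, V, np.inf)
    S1 = (f_B[None, :, :] * (f_AB - f_A[None, :, :])).mean(axis=1) / safe
    ST = 0.5 * ((f_A[None, :, :] - f_AB) ** 2).mean(axis=1) / safe
    return S1, ST


def run_gsa(evaluate: Callable[[np.ndarray], np.ndarray],
            design: GsaDesign, max_failure_fraction: float = 0.01
            ) -> SensitivityResult:
    """Evaluate the Saltelli sample and estimate Sobol indices.

    ``evaluate`` maps a sample block (k, d) to outputs (k, m).  Rows for
    which evaluation failed may be returned as NaN; the corresponding
    sample rows are excluded across all blocks, and more than
    ``max_failure_fraction`` failures is a hard error.
    """
    sample = sobol_sample(design)
    d, N = sample.AB.shape[0], sample.A.shape[0]
    f_all = np.asarray(evaluate(sample.stacked()), dtype=float)
    m = f_all.shape[1]
    f_A, f_B = f_all[:N], f_all[N:2 * N]
    f_AB = f_all[2 * N:].reshape(d, N, m)

    bad = (np.isnan(f_A).any(axis=1) | np.isnan(f_B).any(axis=1)
           | np.isnan(f_AB).any(axis=(0, 2)))
    n_bad = int(bad.sum())
    if n_bad:
        if n_bad > max_failure_fraction * N:
            raise IntegrationError(
                f"{n_bad}/{N} sample evaluations failed (> "
                f"{max_failure_fraction:.0%} allowed)")
        warnings.warn(f"{n_bad}/{N} sample evaluations failed; excluded")
        keep = ~bad
        f_A, f_B, f_AB = f_A[keep], f_B[keep], f_AB[:, keep, :]

    S1, ST = estimate_sobol(f_A, f_B, f_AB)
    return SensitivityResult(
        inputs=design.input_names, outputs=list(design.outputs),
        first_order=S1, total_order=ST,
        unexplained=1.0 - S1.sum(axis=0),
        n_samples=N - n_bad,
        metadata={"estimators": {"first_order": "Saltelli-2010",
                                 "total_order": "Jansen"},
                  "functional": design.functional,
                  "horizon_h": design.horizon,
                  "seed": design.seed,
                  "failed_samples": n_bad},
    )


# ---------------------------------------------------------------------------
# model evaluators
# ---------------------------------------------------------------------------

def _output_functional(design: GsaDesign, result) -> np.ndarray:
    cols = np.array([result.names.index(o) for o in design.outputs])
    traj = result.concentrations[:, cols]
    if design.functional == "terminal":
        return traj[-1]
    return np.trapezoid(traj, result.times, axis=0)


def model_evaluator(spec: ModelSpec, design: GsaDesign,
                    method: str = "superposition"
                    ) -> Callable[[np.ndarray], np.ndarray]:
    """Build the sample -> outputs map for a compartment model.

    Each sample row sets the initial concentrations of the design inputs;
    every other compartment keeps its spec default.  ``superposition``
    reconstructs the affine map exactly from n_inputs + 1 integrations
    (valid because the dynamics are linear time-invariant); ``direct``
    integrates every sample.
    """
    for name in list(design.input_names) + list(design.outputs):
        if name not in spec.compartments:
            raise DesignError(f"{name!r} is not a compartment of {spec.name}")
    idx = spec.index()
    in_idx = np.array([idx[n] for n in design.input_names])
    base_state = spec.initial_state()
    base_state[in_idx] = 0.0

    def run_from(c0: np.ndarray) -> np.ndarray:
        res = integrate(spec, design.horizon, dt_out=design.dt_out,
                        state0=c0)
        return _output_functional(design, res)

    if method == "superposition":
        y_base = run_from(base_state)
        W = np.empty((len(in_idx), y_base.size))
        for k, i in enumerate(in_idx):
            c0 = base_state.copy()
            c0[i] += 1.0
            W[k] = run_from(c0) - y_base

        def evaluate(X: np.ndarray) -> np.ndarray:
            return y_base[None, :] + np.asarray(X, float) @ W

        return evaluate

    if method == "direct":
        def evaluate(X: np.ndarray) -> np.ndarray:
            out = np.empty((len(X), len(design.outputs)))
            for r, x in enumerate(np.asarray(X, float)):
                c0 = base_state.copy()
                c0[in_idx] = x
                try:
                    out[r] = run_from(c0)
                except IntegrationError:
                    out[r] = np.nan
            return out

        return evaluate

    raise ValueError(f"unknown evaluator method {method!r}")


def run_model_gsa(spec: ModelSpec, design: GsaDesign,
                  method: str = "superposition") -> SensitivityResult:
    """Convenience wrapper: build the evaluator and run the analysis."""
    result = run_gsa(model_evaluator(spec, design, method=method), design)
    result.metadata["model"] = spec.name
    result.metadata["evaluator"] = method
    return result


def rank_contributors(result: SensitivityResult, output: str) -> list[str]:
    """Inputs sorted by total-order index (descending; ties lexicographic)."""
    if output not in result.outputs:
        raise KeyError(f"unknown output {output!r}")
    j = result.outputs.index(output)
    order = sorted(range(len(result.inputs)),
                   key=lambda i: (-result.total_order[i, j], result.inputs[i]))
    return [result.inputs[i] for i in order]
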