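import numpy as np
import pytest

from s100b_pbpk import build_model1, build_model2
from s100b_pbpk.core import Compartment, FluxTerm, ModelSpec


@pytest.fixture(scope="session")
def model1():
    return build_model1()


@pytest.fixture(scope="session")
def model2():
    return build_model2()


def make_spec(compartments, terms, name="toy"):
    """Build a ModelSpec from a static list of flux terms."""
    comps = {c.name: c for c in compartments}
    return ModelSpec(name, comps, params=None,
                     term_builder=lambda params, comps_: list(terms))


@pytest.fixture
def two_compartment_loop():
    """A <-> B closed loop, equal volumes, flow Q."""
    V, Q = 10.0, 4.0
    comps = [Compartment("A", V, 1.0, "vascular"),
             Compartment("B", V, 0.0, "vascular")]
    terms = [FluxTerm("A", "B", Q, "blood", "A->B"),
             FluxTerm("B", "A", Q, "blood", "B->A")]
    return make_spec(comps, terms), V, Q


@pytest.fixture
def decay_compartment():
    """Single compartment draining to a terminal sink: c(t)=c0 exp(-Qt/V)."""
    V, Q, c0 = 5.0, 2.0, 1.0
    comps = [Compartment("A", V, c0, "vascular"),
             Compartment("sink", 1.0, 0.0, "urine")]
    terms = [FluxTerm("A", "sink", Q, "blood", "drain")]
    return make_spec(comps, terms), V, Q, c0


def random_closed_spec(rng, n_comps=4):
    """Random strongly-connected conservative network (no sinks, no clamps)."""
    names = [f"C{i}" for i in range(n_comps)]
    comps = [Compartment(n, float(rng.uniform(1, 100)),
                         float(rng.uniform(0, 10)), "vascular")
             for n in names]
    terms = []
    for i in range(n_comps):
        j = (i + 1) % n_comps
        terms.append(FluxTerm(names[i], names[j],
                              float(rng.uniform(0.1, 50)), "blood",
                              f"{i}->{j}"))
    for _ in range(n_comps):
        i, j = rng.integers(0, n_comps, 2)
        if i != j:
            terms.append(FluxTerm(names[i], names[j],
                                  float(rng.uniform(0, 20)), "blood", "extra"))
    return make_spec(comps, terms)
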