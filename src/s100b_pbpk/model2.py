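"""Model 2: reduced S100B model with a three-compartment brain.

Peripheral organs (muscle, adipose, gut) are split into interstitium and
vascular space exchanging via vascular reflection coefficients (sigma);
each interstitium also drains through a sieving lymphatic into central
lymph.  The brain is vascular / interstitium / glia: the glial reservoir is
clamped at 50 ng/ml and feeds the interstitium through Trauma_Index, the
interstitium leaks into the cerebral vasculature through BBB_Index and into
central lymph through the glymphatic flow (8.4 ml/h default).  A single
kidney compartment filters into urine at
EliminationFactor * GFR / TissuePartitionKidney, and arterial blood
extravasates into saliva (no swallowing/return path, so salivary S100B
accumulates toward the converged time-integral of the arterial level).

All rate gates (BBB_Index, Trauma_Index, sigma) are first-order 1/h
coefficients scaled by the source compartment volume, making every term a
``ml/h x ng/ml`` flux as in the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Compartment, ConfigurationError, FluxTerm, ModelSpec

ORGANS2 = {
    "muscle": ("Interstitium muscle", "Vascular space muscle"),
    "adipose": ("Interstitium adipose", "Vascular space adipose"),
    "gut": ("Interstitium gut", "Vascular space gut"),
}

BRAIN_VASCULAR = "Vascular compartment brain"
BRAIN_INTERSTITIUM = "Interstitium brain"
GLIA = "Glia"


@dataclass
class SigmaExchange:
    """Reflection-coefficient exchange parameters for one organ."""
    organ: str
    sigma_iv: float          # 1/h, interstitium -> vascular
    reverse_sigma: float     # 1/h, vascular -> interstitium
    sigma_lymph: float       # dimensionless sieving coefficient in [0, 1]
    lymph_flow: float        # ml/h

    def __post_init__(self) -> None:
        if self.sigma_iv < 0 or self.reverse_sigma < 0:
            raise ConfigurationError(f"{self.organ}: sigma must be >= 0")
        if not 0.0 <= self.sigma_lymph <= 1.0:
            raise ConfigurationError(
                f"{self.organ}: sigma_lymph must be in [0, 1]")


@dataclass
class ControlsM2:
    bbb_index: float = 0.0       # 1/h gate, nominally in [0, 1]
    trauma_index: float = 0.0    # 1/h gate, nominally in [0, 1]
    glymphatics: float = 8.4     # ml/h, brain interstitium -> central lymph

    def __post_init__(self) -> None:
        if self.glymphatics < 0:
            raise ConfigurationError("glymphatics flow must be >= 0")


@dataclass
class RenalParamsM2:
    gfr_ml_h: float
    elimination_factor_per_h: float     # printed 100 /min
    tissue_partition_per_h: float       # printed 0.1 /min
    urine_kf_per_h: float               # Urine loss gate, printed dimensionless

    def __post_init__(self) -> None:
        if self.gfr_ml_h < 0:
            raise ConfigurationError("GFR must be >= 0")
        if self.tissue_partition_per_h <= 0:
            raise ConfigurationError("tissue partition must be > 0")


@dataclass
class SalivaParams:
    flow_ml_h: float                    # table prints ml/min

    def __post_init__(self) -> None:
        if self.flow_ml_h < 0:
            raise ConfigurationError("salivary blood flow must be >= 0")


@dataclass
class Model2Params:
    exchange: dict[str, SigmaExchange]
    controls: ControlsM2
    renal: RenalParamsM2
    saliva: SalivaParams
    blood_flows: dict[str, float]
    lymph_to_vein: float
    inert: dict[str, float] = field(default_factory=dict)


# -- per-compartment derivative helpers (unit-auditable forms) --------------

def brain_vascular_rhs(c_vasc: float, c_arterial: float, c_interstitium: float,
                       v_vasc: float, v_int: float, bbb_index: float,
                       q_in: float, q_out: float) -> float:
    """d(c_vasc)/dt: arterial inflow + BBB leakage - venous efflux, ng/ml/h."""
    return (q_in * c_arterial + bbb_index * c_interstitium * v_int
            - q_out * c_vasc) / v_vasc


def brain_interstitium_rhs(c_int: float, c_glia: float, v_int: float,
                           v_glia: float, trauma_index: float,
                           glymphatics: float, bbb_index: float) -> float:
    """d(c_int)/dt: trauma source - glymphatic drain - BBB leak, ng/ml/h."""
    return (trauma_index * c_glia * v_glia - glymphatics * c_int
            - bbb_index * c_int * v_int) / v_int


def sigma_exchange_fluxes(c_int: float, c_vasc: float, sx: SigmaExchange,
                          v_int: float, v_vasc: float
                          ) -> tuple[float, float, float]:
    """(interstitium->vascular, vascular->interstitium, interstitium->lymph)
    fluxes in ng/h."""
    return (sx.sigma_iv * c_int * v_int,
            sx.reverse_sigma * c_vasc * v_vasc,
            sx.sigma_lymph * sx.lymph_flow * c_int)


def kidney_rhs(c_kidney: float, c_arterial: float, rp: RenalParamsM2,
               v_kidney: float, q_in: float, q_out: float) -> float:
    """d(c_kidney)/dt with filtration, arterial inflow, venous efflux."""
    elim = (rp.elimination_factor_per_h / rp.tissue_partition_per_h
            * rp.gfr_ml_h * c_kidney)
    return (-elim + q_in * c_arterial - q_out * c_kidney) / v_kidney


def urine_rhs(c_urine: float, c_kidney: float, rp: RenalParamsM2,
              v_urine: float) -> float:
    """d(c_urine)/dt: filtration gain minus first-order voiding loss."""
    elim = (rp.elimination_factor_per_h / rp.tissue_partition_per_h
            * rp.gfr_ml_h * c_kidney)
    return (elim - rp.urine_kf_per_h * c_urine * v_urine) / v_urine


def saliva_rhs(c_saliva: float, c_arterial: float, sp: SalivaParams,
               v_saliva: float) -> float:
    """d(c_saliva)/dt: passive extravasation of arterial blood, no return."""
    return sp.flow_ml_h * c_arterial / v_saliva


def _terms(params: Model2Params,
           comps: dict[str, Compartment]) -> list[FluxTerm]:
    bf = params.blood_flows
    ctl = params.controls
    t: list[FluxTerm] = [
        FluxTerm("Venous blood", "Arterial blood",
                 bf["VenousToArterialBloodFlow"], "blood", "venous->arterial"),
        FluxTerm("Arterial blood", BRAIN_VASCULAR,
                 bf["ArterialToBrainBloodFlow"], "blood", "arterial->brain"),
        FluxTerm(BRAIN_VASCULAR, "Venous blood",
                 bf["BrainToVenousBloodFlow"], "blood", "brain->venous"),
        FluxTerm("Arterial blood", "Kidney",
                 bf["ArterialToKidneyBloodFlow"], "blood", "arterial->kidney"),
        FluxTerm("Kidney", "Venous blood",
                 bf["KidneyToVenousBloodFlow"], "blood", "kidney->venous"),
        FluxTerm("Central lymph", "Venous blood", params.lymph_to_vein,
                 "lymph", "LymphaticToVenous"),
        FluxTerm(BRAIN_INTERSTITIUM, "Central lymph", ctl.glymphatics,
                 "glymphatic", "Glymphatics"),
        FluxTerm(BRAIN_INTERSTITIUM, BRAIN_VASCULAR,
                 ctl.bbb_index * comps[BRAIN_INTERSTITIUM].volume,
                 "bbb", "BBB_Index leak"),
        FluxTerm(GLIA, BRAIN_INTERSTITIUM,
                 ctl.trauma_index * comps[GLIA].volume,
                 "trauma", "Trauma_Index release"),
        FluxTerm("Kidney", "Urine",
                 params.renal.elimination_factor_per_h
                 / params.renal.tissue_partition_per_h
                 * params.renal.gfr_ml_h, "renal", "glomerular filtration"),
        FluxTerm("Urine", None,
                 params.renal.urine_kf_per_h * comps["Urine"].volume,
                 "clearance", "urine voiding"),
        FluxTerm("Arterial blood", "Saliva", params.saliva.flow_ml_h,
                 "salivary", "SalivaryBloodFlow"),
    ]
    organ_flows = {
        "muscle": ("ArterialToMuscleBloodFlow", "MuscleToVenousBloodFlow"),
        "adipose": ("ArterialToAdiposeBloodFlow", "AdiposeToVenousBloodFlow"),
        "gut": ("ArterialToGutBloodFlow", "GutToVenousBloodFlow"),
    }
    for organ, (inter, vasc) in ORGANS2.items():
        fin, fout = organ_flows[organ]
        sx = params.exchange[organ]
        t += [
            FluxTerm("Arterial blood", vasc, bf[fin], "blood", fin),
            FluxTerm(vasc, "Venous blood", bf[fout], "blood", fout),
            FluxTerm(inter, vasc, sx.sigma_iv * comps[inter].volume,
                     "exchange", f"Sigma {organ} int->vasc"),
            FluxTerm(vasc, inter, sx.reverse_sigma * comps[vasc].volume,
                     "exchange", f"ReverseSigma {organ}"),
            FluxTerm(inter, "Central lymph", sx.sigma_lymph * sx.lymph_flow,
                     "lymph", f"{organ} lymphatic"),
        ]
    return t


_M2_FLOW_KEYS = (
    "VenousToArterialBloodFlow", "ArterialToBrainBloodFlow",
    "BrainToVenousBloodFlow", "ArterialToKidneyBloodFlow",
    "KidneyToVenousBloodFlow", "ArterialToMuscleBloodFlow",
    "MuscleToVenousBloodFlow", "ArterialToAdiposeBloodFlow",
    "AdiposeToVenousBloodFlow", "ArterialToGutBloodFlow",
    "GutToVenousBloodFlow",
)


def build_model2(quantities: dict[str, float] | None = None,
                 log: list[str] | None = None,
                 c_interstitium_brain: float | None = None) -> ModelSpec:
    """Wire the Model-2 ModelSpec from a normalized quantity table.

    ``c_interstitium_brain`` overrides the brain-interstitium initial
    concentration (comparison runs use 1 ng/ml instead of the default 10).
    """
    if quantities is None:
        from .config_io import load_config
        bundle = load_config("model2")
        spec = bundle.spec
        if c_interstitium_brain is not None:
            spec.compartments[BRAIN_INTERSTITIUM].concentration = \
                c_interstitium_brain
        return spec

    q = quantities
    log = log if log is not None else []
    comps: dict[str, Compartment] = {}

    def add(name: str, role: str, clamped: bool = False) -> None:
        if name not in q or f"{name}.S100B" not in q:
            raise ConfigurationError(f"missing quantity rows for {name!r}")
        comps[name] = Compartment(name, q[name], q[f"{name}.S100B"], role,
                                  clamped)

    add("Arterial blood", "arterial")
    add("Venous blood", "venous")
    add("Central lymph", "lymph")
    add(BRAIN_VASCULAR, "vascular")
    add(BRAIN_INTERSTITIUM, "interstitium")
    add(GLIA, "cellular", clamped=True)
    add("Urine", "urine")
    add("Kidney", "kidney")
    for inter, vasc in ORGANS2.values():
        add(inter, "interstitium")
        add(vasc, "vascular")
    add("Saliva", "saliva")
    if c_interstitium_brain is not None:
        comps[BRAIN_INTERSTITIUM].concentration = c_interstitium_brain

    scalar_keys = list(_M2_FLOW_KEYS) + [
        "BBB_index", "Trauma_index", "Glymphatics", "GFR",
        "EliminationFactor", "TissuePartitionKidney", "kf",
        "SalivaryBloodFlow", "LymphaticToVenous",
        "SigmaMuscleInterstitiumVascular", "ReverseSigmaMuscle",
        "SigmaMuscleLymphatic", "MuscleLymphFlow",
        "SigmaAdiposeInterstitiumVascular", "ReverseSigmaAdipose",
        "SigmaAdiposeLymphatic", "AdiposeLymphFlow",
        "SigmaGutInterstitiumVascular", "ReverseSigmaGut",
        "SigmaGutLymphatic", "GutLymphFlow"]
    missing = [k for k in scalar_keys if k not in q]
    if missing:
        raise ConfigurationError(f"missing quantities: {missing}")

    sigma_keys = {
        "muscle": ("SigmaMuscleInterstitiumVascular", "ReverseSigmaMuscle",
                   "SigmaMuscleLymphatic", "MuscleLymphFlow"),
        "adipose": ("SigmaAdiposeInterstitiumVascular", "ReverseSigmaAdipose",
                    "SigmaAdiposeLymphatic", "AdiposeLymphFlow"),
        "gut": ("SigmaGutInterstitiumVascular", "ReverseSigmaGut",
                "SigmaGutLymphatic", "GutLymphFlow"),
    }
    exchange = {
        organ: SigmaExchange(organ, q[k_iv], q[k_rev], q[k_ly], q[k_lf])
        for organ, (k_iv, k_rev, k_ly, k_lf) in sigma_keys.items()
    }

    inert = {k: q[k] for k in
             ("BBB", "EmptyingSaliva", "kf_1", "SigmaBrainLymphatic",
              "Brain", "Muscle", "Adipose", "Gut") if k in q}
    for k in inert:
        log.append(f"inert parameter carried unused: {k} = {inert[k]}")

    params = Model2Params(
        exchange=exchange,
        controls=ControlsM2(bbb_index=q["BBB_index"],
                            trauma_index=q["Trauma_index"],
                            glymphatics=q["Glymphatics"]),
        renal=RenalParamsM2(gfr_ml_h=q["GFR"],
                            elimination_factor_per_h=q["EliminationFactor"],
                            tissue_partition_per_h=q["TissuePartitionKidney"],
                            urine_kf_per_h=q["kf"]),
        saliva=SalivaParams(flow_ml_h=q["SalivaryBloodFlow"]),
        blood_flows={k: q[k] for k in _M2_FLOW_KEYS},
        lymph_to_vein=q["LymphaticToVenous"],
        inert=inert,
    )
    spec = ModelSpec("model2", comps, params, _terms, conversion_log=log)
    spec.validate()
    return spec
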