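"""Model 1: nine-organ whole-body S100B kinetics with two-pore exchange.

Each organ is a parenchymal compartment plus a vascular fraction (the
intra-organ blood sub-compartment).  Arterial blood perfuses the vascular
fractions, which return to venous blood; the venous pool passes through the
lung vascular fraction back to the arterial pool.  Lymphatic vessels drain
the vascular fractions of muscle, gut, heart, adipose, skin and kidney into
a central lymph pool that empties into venous blood.  Parenchyma exchanges
with its vascular fraction through a conservative antisymmetric flux derived
from two-pore theory,

    J = (kf * C_parenchyma - kr * C_vf) * interstitialFlow   [ng/h],

with kf = kr * 10,000.  The brain's exchange is additionally gated by
BBB_Index in [0, 1] (0 = intact barrier, 1 = full disruption).  Renal
elimination filters the kidney parenchyma into urine at
RenalEliminationFactor * GFR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Compartment, ConfigurationError, FluxTerm, ModelSpec

#: organ key -> (parenchyma compartment, vascular-fraction compartment)
ORGAN_COMPARTMENTS = {
    "lung": ("Lung", "Lung tissue vascular fraction"),
    "heart": ("Heart", "Heart tissue vascular fraction"),
    "bone": ("Bone", "Bone tissue vascular fraction"),
    "adipose": ("Adipose tissue", "Adipose tissue vascular fraction"),
    "skin": ("Skin", "Skin tissue vascular fraction"),
    "muscle": ("Muscle", "Muscle tissue vascular fraction"),
    "gut": ("Gut", "Gut tissue vascular fraction"),
    "kidney": ("Kidney", "Kidney tissue vascular fraction"),
    "brain": ("Brain", "Brain tissue vascular fraction"),
}

#: organs with a printed lymphatic drainage flow (vascular fraction -> lymph)
LYMPH_ORGANS = ("muscle", "gut", "heart", "adipose", "skin", "kidney")

KF_KR_RATIO = 10_000.0


@dataclass
class PoreExchange:
    """Two-pore-derived exchange constants for one organ (dimensionless)."""
    organ: str
    kf: float
    kr: float
    pore_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kr < 0:
            raise ConfigurationError(f"{self.organ}: kf/kr must be >= 0")


@dataclass
class RenalParamsM1:
    gfr_ml_h: float                  # table prints ml/min; canonical ml/h
    elimination_factor: float        # dimensionless tuning factor

    def __post_init__(self) -> None:
        if self.gfr_ml_h < 0:
            raise ConfigurationError("GFR must be >= 0")


@dataclass
class ControlsM1:
    bbb_index: float = 0.0


@dataclass
class Model1Params:
    exchange: dict[str, PoreExchange]
    renal: RenalParamsM1
    controls: ControlsM1
    interstitial_flow: float                  # ml/h
    blood_flows: dict[str, float]             # edge label -> ml/h
    lymph_flows: dict[str, float]             # organ key -> ml/h
    lymph_to_vein: float
    inert: dict[str, float] = field(default_factory=dict)


def derive_pore_rate_constants(small_pore_radius: float,
                               large_pore_radius: float,
                               pore_ratio: float) -> tuple[float, float]:
    """(kr, kf) from pore radii and the small:large pore-count ratio.

    kr = large / (small * ratio); kf = kr * 10,000.
    """
    if small_pore_radius <= 0 or large_pore_radius <= 0 or pore_ratio <= 0:
        raise ValueError("pore radii and ratio must be > 0")
    kr = large_pore_radius / (small_pore_radius * pore_ratio)
    return kr, kr * KF_KR_RATIO


def organ_exchange_flux(c_parenchyma: float, c_vascular_fraction: float,
                        px: PoreExchange, interstitial_flow: float) -> float:
    """Signed parenchyma->vascular flux, ng/h."""
    return (px.kf * c_parenchyma - px.kr * c_vascular_fraction) * interstitial_flow


def brain_release_flux(c_brain: float, c_brain_vf: float, px_brain: PoreExchange,
                       interstitial_flow: float, bbb_index: float) -> float:
    """BBB_Index-gated brain->vascular-fraction flux, ng/h."""
    return organ_exchange_flux(c_brain, c_brain_vf, px_brain,
                               interstitial_flow) * bbb_index


def renal_excretion_flux(c_kidney: float, rp: RenalParamsM1) -> float:
    """Kidney-parenchyma -> urine filtration flux, ng/h."""
    if c_kidney < 0:
        raise ValueError("kidney concentration must be >= 0")
    return rp.elimination_factor * rp.gfr_ml_h * c_kidney


def _terms(params: Model1Params,
           comps: dict[str, Compartment]) -> list[FluxTerm]:
    t: list[FluxTerm] = []
    bf = params.blood_flows
    t.append(FluxTerm("Venous blood", "Lung tissue vascular fraction",
                      bf["BloodFlowVenousToLung"], "blood", "venous->lung"))
    t.append(FluxTerm("Lung tissue vascular fraction", "Arterial blood",
                      bf["BloodFlowLungToArtery"], "blood", "lung->artery"))
    arterial_in = {
        "kidney": "BloodFlowArteryToKidney", "muscle": "BloodFlowArteryToMuscle",
        "heart": "BloodFlowArteryToHeart", "bone": "BloodFlowArterialToBone",
        "adipose": "BloodFlowArterialToAdipose", "skin": "BloodFlowArterialToSkin",
        "gut": "BloodFlowArteryToGut", "brain": "BloodFlowToBrain",
    }
    venous_out = {
        "kidney": "BloodFlowKidneyToVenous", "muscle": "BloodFlowMuscleToVenous",
        "heart": "BloodFlowHeartToVenous", "bone": "BloodFlowBoneToVenous",
        "adipose": "BloodFlowAdiposeToVenous", "skin": "BloodFlowSkinToVenous",
        "gut": "BloodFlowGutToVenous", "brain": "BloodFlowFromBrain",
    }
    for organ, (par, vf) in ORGAN_COMPARTMENTS.items():
        if organ in arterial_in:
            t.append(FluxTerm("Arterial blood", vf, bf[arterial_in[organ]],
                              "blood", arterial_in[organ]))
            t.append(FluxTerm(vf, "Venous blood", bf[venous_out[organ]],
                              "blood", venous_out[organ]))
        px = params.exchange[organ]
        kind = "bbb" if organ == "brain" else "exchange"
        gate = params.controls.bbb_index if organ == "brain" else 1.0
        t.append(FluxTerm(par, vf, px.kf * params.interstitial_flow * gate,
                          kind, f"kf_{organ}"))
        t.append(FluxTerm(vf, par, px.kr * params.interstitial_flow * gate,
                          kind, f"kr_{organ}"))
    t.append(FluxTerm("Arterial blood", "Venous blood",
                      bf["BloodFlowArteryToVenous"], "shunt",
                      "arteriovenous shunt"))
    for organ in LYMPH_ORGANS:
        _, vf = ORGAN_COMPARTMENTS[organ]
        t.append(FluxTerm(vf, "Lymph", params.lymph_flows[organ], "lymph",
                          f"LymphFlow{organ.capitalize()}"))
    t.append(FluxTerm("Lymph", "Venous blood", params.lymph_to_vein, "lymph",
                      "LymphFlowToVein"))
    t.append(FluxTerm("Kidney", "Urine",
                      params.renal.elimination_factor * params.renal.gfr_ml_h,
                      "renal", "glomerular filtration"))
    return [x for x in t if x.coeff > 0 or x.kind in ("bbb", "exchange")]


_BLOOD_FLOW_KEYS = (
    "BloodFlowVenousToLung", "BloodFlowLungToArtery", "BloodFlowArteryToKidney",
    "BloodFlowArteryToMuscle", "BloodFlowArteryToHeart", "BloodFlowHeartToVenous",
    "BloodFlowArterialToBone", "BloodFlowBoneToVenous", "BloodFlowKidneyToVenous",
    "BloodFlowAdiposeToVenous", "BloodFlowArterialToAdipose",
    "BloodFlowSkinToVenous", "BloodFlowArterialToSkin", "BloodFlowMuscleToVenous",
    "BloodFlowArteryToGut", "BloodFlowGutToVenous", "BloodFlowToBrain",
    "BloodFlowFromBrain", "BloodFlowArteryToVenous",
)

_POOL_ROLES = {"Arterial blood": "arterial", "Venous blood": "venous",
               "Lymph": "lymph", "Urine": "urine"}


def build_model1(quantities: dict[str, float] | None = None,
                 log: list[str] | None = None) -> ModelSpec:
    """Wire the full Model-1 ModelSpec from a normalized quantity table.

    ``quantities`` maps table row names to values in canonical units
    (ml, ng/ml, ml/h); ``None`` loads the packaged config.  kr constants are
    recomputed as kf / 10,000 regardless of the (rounded) printed kr rows.
    """
    if quantities is None:
        from .config_io import load_config
        bundle = load_config("model1")
        return bundle.spec

    q = quantities
    log = log if log is not None else []
    comps: dict[str, Compartment] = {}

    def add(name: str, role: str, clamped: bool = False) -> None:
        if name not in q:
            raise ConfigurationError(f"missing quantity: {name!r}")
        if f"{name}.S100B" not in q:
            raise ConfigurationError(f"missing quantity: {name!r} S100B")
        comps[name] = Compartment(name, q[name], q[f"{name}.S100B"], role,
                                  clamped)

    add("Arterial blood", "arterial")
    add("Venous blood", "venous")
    for organ, (par, vf) in ORGAN_COMPARTMENTS.items():
        add(par, "kidney" if organ == "kidney" else "parenchyma")
        add(vf, "vascular_fraction")
    add("Lymph", "lymph")
    add("Urine", "urine")

    scalar_keys = (["GFR", "RenalEliminationFactor", "BBB_Index",
                    "interstitialFlow", "LymphFlowToVein"]
                   + [f"kf_{o}" for o in ORGAN_COMPARTMENTS]
                   + [f"LymphFlow{o.capitalize()}" for o in LYMPH_ORGANS])
    missing = [k for k in scalar_keys if k not in q]
    if missing:
        raise ConfigurationError(f"missing quantities: {missing}")

    exchange = {}
    for organ in ORGAN_COMPARTMENTS:
        kf = q[f"kf_{organ}"]
        kr = kf / KF_KR_RATIO
        printed_kr = q.get(f"kr_{organ}")
        if printed_kr is not None and abs(printed_kr - kr) > 5e-3:
            log.append(f"kr_{organ}: printed {printed_kr} replaced by "
                       f"kf/10000 = {kr:.6g}")
        exchange[organ] = PoreExchange(organ, kf=kf, kr=kr,
                                       pore_ratio=q.get(f"PoreRatio{organ.capitalize()}"))

    missing = [k for k in _BLOOD_FLOW_KEYS if k not in q]
    if missing:
        raise ConfigurationError(f"missing flow quantities: {missing}")
    blood_flows = {k: q[k] for k in _BLOOD_FLOW_KEYS}
    lymph_flows = {o: q[f"LymphFlow{o.capitalize()}"] for o in LYMPH_ORGANS}

    inert = {k: q[k] for k in
             ("TissueFactor", "AdiposeTissueFactor", "Excretion", "kf_1",
              "BloodFlowArteryToSaliva", "BloodFlowLungToArterial") if k in q}
    for k in inert:
        log.append(f"inert parameter carried unused: {k} = {inert[k]}")

    params = Model1Params(
        exchange=exchange,
        renal=RenalParamsM1(gfr_ml_h=q["GFR"],
                            elimination_factor=q["RenalEliminationFactor"]),
        controls=ControlsM1(bbb_index=q["BBB_Index"]),
        interstitial_flow=q["interstitialFlow"],
        blood_flows=blood_flows,
        lymph_flows=lymph_flows,
        lymph_to_vein=q["LymphFlowToVein"],
        inert=inert,
    )
    spec = ModelSpec("model1", comps, params, _terms, conversion_log=log)
    spec.validate()
    return spec
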