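"""Whole-body PBPK model of indocyanine green (ICG).

ICG is an anionic dye that is confined to plasma (protein-bound), taken up
exclusively by the liver via OATP1B3 and excreted unchanged into the bile,
from where it reaches the feces. The whole-body model connects venous blood,
lung, arterial blood, the gastrointestinal tract (feeding the portal vein),
the liver and a pooled "rest" compartment through the systemic circulation.
Cirrhosis is represented by intrahepatic shunting (``f_shunts``) plus loss of
functional parenchyma (``f_tissue_loss``); partial hepatectomy by
``resection_rate``.

Canonical internal units: mmole, liter, minute, mM. Milligram inputs are
converted via the molar mass of ICG (774.96 g/mole).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np

__all__ = [
    "MR_ICG",
    "BodyParameters",
    "TransporterParameters",
    "ScenarioParameters",
    "ModelParameters",
    "DerivedGeometry",
    "STATE_NAMES",
    "InvalidParameterError",
    "derive_geometry",
    "uptake_rate",
    "biliary_excretion_rate",
    "feces_transport_rate",
    "rhs",
]

#: Molar mass of indocyanine green [g/mole].
MR_ICG = 774.96


class InvalidParameterError(ValueError):
    """A parameter set violates its physical or range invariants."""


def _check_positive(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not np.isfinite(v) or v <= 0:
            raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class BodyParameters:
    """Fixed anthropometric and physiological parameters (reference adult).

    Fractional tissue volumes ``FV*`` are liters of organ per kg body weight;
    fractional blood flows ``FQ*`` are fractions of cardiac output.
    """

    BW: float = 75.0            # body weight [kg]
    HEIGHT: float = 170.0       # body height [cm]
    COBW: float = 0.83          # cardiac output per body weight [ml/s/kg]
    HCT: float = 0.51           # hematocrit [-]
    Fblood: float = 0.02        # vascular fraction of organ volume [-]
    FVgi: float = 0.0171        # gastrointestinal tract [l/kg]
    FVli: float = 0.021         # liver [l/kg]
    FVlu: float = 0.0297        # lung [l/kg]
    FVve: float = 0.0587        # venous blood [l/kg]
    FVar: float = 0.0184        # arterial blood [l/kg]
    FVbi: float = 0.00071       # bile [l/kg]
    FVpo: float = 0.001         # portal vein [l/kg]
    FVhv: float = 0.001         # hepatic vein [l/kg]
    FQgi: float = 0.19          # fractional flow through the GI tract / portal vein [-]
    FQh: float = 0.255          # fractional hepatic (hepatic-vein) flow [-]
    Mr_icg: float = MR_ICG      # molar mass of ICG [g/mole]
    ti_icg: float = 5.0         # injection duration [s]
    bil_plasma: float = 0.007   # plasma bilirubin [mM]; reference range 0.005-0.015

    def __post_init__(self) -> None:
        _check_positive(self, [f.name for f in fields(self)])
        for name in ("HCT", "Fblood", "FQgi", "FQh"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.FQh < self.FQgi:
            raise InvalidParameterError(
                "FQh must be >= FQgi (hepatic-artery flow FQh - FQgi would be negative)"
            )


@dataclass(frozen=True)
class TransporterParameters:
    """Hepatic transport kinetics: sinusoidal uptake, canalicular excretion,
    bile-to-feces transit.

    ``ICGIM_*`` parametrize Michaelis-Menten uptake from liver plasma into
    hepatocytes (competitively inhibited by bilirubin via ``ki_bil``);
    ``ICGLI2CA_*`` the Michaelis-Menten excretion into the bile canaliculi;
    ``ICGLI2BI_k`` the first-order bile-to-feces transit. Vmax values are per
    liter of functional liver tissue; ``f_oatp1b3`` scales transporter amount.
    """

    ICGIM_Vmax: float = 0.037       # [mmole/min/l liver]
    ICGIM_Km: float = 0.0217        # [mM]
    ki_bil: float = 0.02            # bilirubin inhibition constant [mM]
    ICGLI2CA_Vmax: float = 0.000944  # [mmole/min/l liver]
    ICGLI2CA_Km: float = 0.0124     # [mM]
    ICGLI2BI_k: float = 0.000114    # [1/min]
    f_oatp1b3: float = 1.0          # transport-protein scaling [-]

    def __post_init__(self) -> None:
        _check_positive(self, [f.name for f in fields(self)])


@dataclass(frozen=True)
class ScenarioParameters:
    """Disease / surgery scenario knobs (all default to the healthy reference).

    Setting ``f_cirrhosis`` through :meth:`with_cirrhosis` assigns ``f_shunts``
    and ``f_tissue_loss`` in lockstep, the model's composite cirrhosis degree.
    """

    f_shunts: float = 0.0        # fraction of hepatic blood bypassing tissue [-]
    f_tissue_loss: float = 0.0   # fraction of parenchymal volume lost [-]
    resection_rate: float = 0.0  # fraction of liver volume resected [-]
    f_bloodflow: float = 1.0     # hepatic blood flow scaling [-]
    f_cardiac_output: float = 1.0  # cardiac output scaling [-]

    def __post_init__(self) -> None:
        for name in ("f_shunts", "f_tissue_loss"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1), got {v}")
        if not 0.0 <= self.resection_rate <= 0.9:
            raise InvalidParameterError(
                f"resection_rate must lie in [0, 0.9], got {self.resection_rate}"
            )
        for name in ("f_bloodflow", "f_cardiac_output"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")

    @property
    def f_cirrhosis(self) -> float:
        """Composite cirrhosis degree; defined when shunts and tissue loss agree."""
        if self.f_shunts != self.f_tissue_loss:
            raise ValueError(
                "f_cirrhosis undefined: f_shunts and f_tissue_loss differ"
            )
        return self.f_shunts

    def with_cirrhosis(self, f_cirrhosis: float) -> "ScenarioParameters":
        """Return a copy with shunts and tissue loss coupled in lockstep."""
        return replace(self, f_shunts=f_cirrhosis, f_tissue_loss=f_cirrhosis)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameterization: body + transporters + scenario."""

    body: BodyParameters = field(default_factory=BodyParameters)
    transporters: TransporterParameters = field(default_factory=TransporterParameters)
    scenario: ScenarioParameters = field(default_factory=ScenarioParameters)

    # --- flat key-value (Table-style) serialization -------------------------
    _ALIASES = {
        "LI__ICGIM_Vmax": ("transporters", "ICGIM_Vmax"),
        "LI__ICGIM_Km": ("transporters", "ICGIM_Km"),
        "LI__ICGIM_ki_bil": ("transporters", "ki_bil"),
        "LI__ICGLI2CA_Vmax": ("transporters", "ICGLI2CA_Vmax"),
        "LI__ICGLI2CA_km": ("transporters", "ICGLI2CA_Km"),
        "LI__ICGLI2CA_Km": ("transporters", "ICGLI2CA_Km"),
        "LI__ICGLI2BI_Vmax": ("transporters", "ICGLI2BI_k"),
        "LI__ICGLI2BI_k": ("transporters", "ICGLI2BI_k"),
        "LI__f_oatp1b3": ("transporters", "f_oatp1b3"),
    }

    def to_flat(self) -> dict:
        """Flat dict keyed by the canonical parameter symbols."""
        out = {f.name: getattr(self.body, f.name) for f in fields(self.body)}
        out.update(
            {
                "LI__ICGIM_Vmax": self.transporters.ICGIM_Vmax,
                "LI__ICGIM_Km": self.transporters.ICGIM_Km,
                "LI__ICGIM_ki_bil": self.transporters.ki_bil,
                "LI__ICGLI2CA_Vmax": self.transporters.ICGLI2CA_Vmax,
                "LI__ICGLI2CA_km": self.transporters.ICGLI2CA_Km,
                "LI__ICGLI2BI_Vmax": self.transporters.ICGLI2BI_k,
                "LI__f_oatp1b3": self.transporters.f_oatp1b3,
            }
        )
        out.update({f.name: getattr(self.scenario, f.name) for f in fields(self.scenario)})
        return out

    @classmethod
    def from_flat(cls, data: dict) -> "ModelParameters":
        """Build parameters from a flat key-value mapping.

        Unknown keys raise :class:`InvalidParameterError`. ``f_cirrhosis``
        assigns shunts and tissue loss in lockstep.
        """
        body_kw: dict = {}
        tp_kw: dict = {}
        sc_kw: dict = {}
        body_names = {f.name for f in fields(BodyParameters)}
        tp_names = {f.name for f in fields(TransporterParameters)}
        sc_names = {f.name for f in fields(ScenarioParameters)}
        f_cirr = None
        for key, value in data.items():
            value = float(value)
            if key == "f_cirrhosis":
                f_cirr = value
            elif key in cls._ALIASES:
                tp_kw[cls._ALIASES[key][1]] = value
            elif key in body_names:
                body_kw[key] = value
            elif key in tp_names:
                tp_kw[key] = value
            elif key in sc_names:
                sc_kw[key] = value
            else:
                raise InvalidParameterError(f"unknown parameter key: {key!r}")
        if f_cirr is not None:
            sc_kw["f_shunts"] = f_cirr
            sc_kw["f_tissue_loss"] = f_cirr
        return cls(
            body=BodyParameters(**body_kw),
            transporters=TransporterParameters(**tp_kw),
            scenario=ScenarioParameters(**sc_kw),
        )


@dataclass(frozen=True)
class DerivedGeometry:
    """Volumes [l] and blood flows [l/min] derived from the parameters.

    ``*_plasma`` volumes are the ICG distribution spaces (blood x (1-HCT),
    ICG being confined to plasma); ``Q*`` are the volumetric blood flows
    driving convective exchange between compartments.
    """

    # blood volumes [l]
    V_ve: float
    V_ar: float
    V_po: float
    V_hv: float
    V_lu_blood: float
    V_gi_blood: float
    V_re_blood: float
    V_li_blood: float
    # tissue / bile volumes [l]
    V_li_tissue: float
    V_bi: float
    # plasma volumes [l]
    V_ve_plasma: float
    V_ar_plasma: float
    V_po_plasma: float
    V_hv_plasma: float
    V_lu_plasma: float
    V_gi_plasma: float
    V_re_plasma: float
    V_li_plasma: float
    # blood flows [l/min]
    Q_CO: float
    Q_lu: float
    Q_h: float
    Q_ha: float
    Q_po: float
    Q_re: float
    Q_shunt: float
    Q_ha_shunt: float
    Q_po_shunt: float
    # functional-liver fraction applied to bile transit [-]
    f_liver_function: float


def derive_geometry(
    body: BodyParameters, scenario: ScenarioParameters
) -> DerivedGeometry:
    """Compute compartment volumes and the blood-flow network.

    Flow conservation holds by construction: ``Q_CO = Q_lu = Q_h + Q_re`` and
    ``Q_h = Q_ha + Q_po``. Hepatectomy (``resection_rate``) removes liver
    tissue and liver vascular volume; tissue loss removes parenchyma only.
    The shunted fraction ``f_shunts`` applies equally to the arterial and
    portal streams and merges directly into the hepatic vein.
    """
    b, s = body, scenario
    resected = 1.0 - s.resection_rate
    functional = (1.0 - s.f_tissue_loss) * resected

    V_ve = b.FVve * b.BW
    V_ar = b.FVar * b.BW
    V_po = b.FVpo * b.BW
    V_hv = b.FVhv * b.BW
    V_lu_blood = b.FVlu * b.BW * b.Fblood
    V_gi_blood = b.FVgi * b.BW * b.Fblood
    V_li_blood = b.FVli * b.BW * b.Fblood * resected
    V_li_tissue = b.FVli * b.BW * (1.0 - b.Fblood) * functional
    V_bi = b.FVbi * b.BW

    # rest compartment closes the volume budget (body density ~1 kg/l)
    explicit = (
        b.FVgi + b.FVli + b.FVlu + b.FVve + b.FVar + b.FVbi + b.FVpo + b.FVhv
    ) * b.BW
    V_re_blood = b.Fblood * (b.BW * 1.0 - explicit)
    if V_re_blood <= 0:
        raise InvalidParameterError("rest-compartment blood volume is non-positive")

    Q_CO = b.COBW * b.BW * 60.0 / 1000.0 * s.f_cardiac_output  # ml/s -> l/min
    Q_h = b.FQh * Q_CO * s.f_bloodflow
    Q_po = b.FQgi * Q_CO * s.f_bloodflow
    Q_ha = Q_h - Q_po
    Q_re = Q_CO - Q_h
    if Q_re < 0 or Q_ha < 0:
        raise InvalidParameterError("flow network invalid: negative Q_re or Q_ha")
    Q_lu = Q_CO
    Q_shunt = s.f_shunts * Q_h
    Q_ha_shunt = s.f_shunts * Q_ha
    Q_po_shunt = s.f_shunts * Q_po

    fp = 1.0 - b.HCT
    return DerivedGeometry(
        V_ve=V_ve,
        V_ar=V_ar,
        V_po=V_po,
        V_hv=V_hv,
        V_lu_blood=V_lu_blood,
        V_gi_blood=V_gi_blood,
        V_re_blood=V_re_blood,
        V_li_blood=V_li_blood,
        V_li_tissue=V_li_tissue,
        V_bi=V_bi,
        V_ve_plasma=V_ve * fp,
        V_ar_plasma=V_ar * fp,
        V_po_plasma=V_po * fp,
        V_hv_plasma=V_hv * fp,
        V_lu_plasma=V_lu_blood * fp,
        V_gi_plasma=V_gi_blood * fp,
        V_re_plasma=V_re_blood * fp,
        V_li_plasma=V_li_blood * fp,
        Q_CO=Q_CO,
        Q_lu=Q_lu,
        Q_h=Q_h,
        Q_ha=Q_ha,
        Q_po=Q_po,
        Q_re=Q_re,
        Q_shunt=Q_shunt,
        Q_ha_shunt=Q_ha_shunt,
        Q_po_shunt=Q_po_shunt,
        f_liver_function=functional,
    )


# ---------------------------------------------------------------------------
# Kinetic laws
# ---------------------------------------------------------------------------

def uptake_rate(
    c_liver_plasma: float,
    tp: TransporterParameters,
    v_liver_tissue: float,
    bil: float = 0.0,
) -> float:
    """Hepatic ICG uptake [mmole/min]: irreversible Michaelis-Menten kinetics
    in the liver-plasma concentration, competitively inhibited by bilirubin
    and scaled by functional liver tissue volume and transporter amount."""
    km_app = tp.ICGIM_Km * (1.0 + bil / tp.ki_bil)
    return (
        tp.f_oatp1b3
        * tp.ICGIM_Vmax
        * v_liver_tissue
        * c_liver_plasma
        / (km_app + c_liver_plasma)
    )


def biliary_excretion_rate(
    c_liver_tissue: float, tp: TransporterParameters, v_liver_tissue: float
) -> float:
    """Biliary ICG excretion [mmole/min]: irreversible Michaelis-Menten
    kinetics in the hepatocyte concentration, scaled by liver tissue volume."""
    return (
        tp.ICGLI2CA_Vmax
        * v_liver_tissue
        * c_liver_tissue
        / (tp.ICGLI2CA_Km + c_liver_tissue)
    )


def feces_transport_rate(
    bile_amount: float, tp: TransporterParameters, v_liver_tissue_fraction: float = 1.0
) -> float:
    """Bile-to-feces transit [mmole/min]: first order in the bile ICG amount,
    scaled by the functional-liver fraction."""
    return tp.ICGLI2BI_k * bile_amount * v_liver_tissue_fraction


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

#: State vector layout: ICG amounts [mmole].
STATE_NAMES = (
    "A_ve",      # venous plasma
    "A_ar",      # arterial plasma
    "A_lu",      # lung blood plasma
    "A_gi",      # GI blood plasma
    "A_po",      # portal-vein plasma
    "A_li_pl",   # liver blood plasma
    "A_hv",      # hepatic-vein plasma
    "A_re",      # rest blood plasma
    "A_li_ti",   # liver tissue (hepatocytes)
    "A_bi",      # bile
    "A_fe",      # cumulative feces
    "A_adm",     # cumulative administered
)

N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}


def rhs(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    geometry: DerivedGeometry,
    input_rate: Callable[[float], float],
) -> np.ndarray:
    """Time derivative of the ICG amount vector [mmole/min].

    Convective transport between blood compartments is irreversible: the
    flux from compartment i equals the volumetric blood flow Q_i times the
    upstream plasma concentration C_i. ICG distributes in the plasma space
    (blood volume x (1-HCT)) but each compartment's plasma is exchanged at
    the full blood flow rate, reproducing the fast venous-arterial transit
    seen clinically. Dosing enters the venous plasma. The sum of all
    derivatives except the administered-amount bookkeeping equals the input
    rate: mass balance is exact at the RHS level.
    """
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite model state")
    g = params.body
    geo = geometry
    tp = params.transporters
    sc = params.scenario

    (A_ve, A_ar, A_lu, A_gi, A_po, A_li_pl, A_hv, A_re, A_li_ti, A_bi, _A_fe,
     _A_adm) = state

    c_ve = A_ve / geo.V_ve_plasma
    c_ar = A_ar / geo.V_ar_plasma
    c_lu = A_lu / geo.V_lu_plasma
    c_gi = A_gi / geo.V_gi_plasma
    c_po = A_po / geo.V_po_plasma
    c_li_pl = A_li_pl / geo.V_li_plasma if geo.V_li_plasma > 0 else 0.0
    c_hv = A_hv / geo.V_hv_plasma
    c_re = A_re / geo.V_re_plasma
    c_li_ti = A_li_ti / geo.V_li_tissue if geo.V_li_tissue > 0 else 0.0

    keep = 1.0 - sc.f_shunts

    # convective fluxes [mmole/min]: blood flow x upstream plasma concentration
    v_ve_lu = geo.Q_lu * c_ve
    v_lu_ar = geo.Q_lu * c_lu
    v_ar_gi = geo.Q_po * c_ar          # GI perfusion feeds the portal vein
    v_gi_po = geo.Q_po * c_gi
    v_po_li = keep * geo.Q_po * c_po
    v_po_hv = geo.Q_po_shunt * c_po    # portosystemic shunt
    v_ar_li = keep * geo.Q_ha * c_ar
    v_ar_hv = geo.Q_ha_shunt * c_ar    # arteriohepatic shunt
    v_li_hv = keep * geo.Q_h * c_li_pl
    v_hv_ve = geo.Q_h * c_hv
    v_ar_re = geo.Q_re * c_ar
    v_re_ve = geo.Q_re * c_re

    v_uptake = uptake_rate(c_li_pl, tp, geo.V_li_tissue, g.bil_plasma)
    v_bile = biliary_excretion_rate(c_li_ti, tp, geo.V_li_tissue)
    v_feces = feces_transport_rate(A_bi, tp, geo.f_liver_function)

    u = input_rate(t)

    dx = np.empty(N_STATE)
    dx[IDX["A_ve"]] = u + v_re_ve + v_hv_ve - v_ve_lu
    dx[IDX["A_ar"]] = v_lu_ar - v_ar_gi - v_ar_li - v_ar_hv - v_ar_re
    dx[IDX["A_lu"]] = v_ve_lu - v_lu_ar
    dx[IDX["A_gi"]] = v_ar_gi - v_gi_po
    dx[IDX["A_po"]] = v_gi_po - v_po_li - v_po_hv
    dx[IDX["A_li_pl"]] = v_po_li + v_ar_li - v_li_hv - v_uptake
    dx[IDX["A_hv"]] = v_li_hv + v_po_hv + v_ar_hv - v_hv_ve
    dx[IDX["A_re"]] = v_ar_re - v_re_ve
    dx[IDX["A_li_ti"]] = v_uptake - v_bile
    dx[IDX["A_bi"]] = v_bile - v_feces
    dx[IDX["A_fe"]] = v_feces
    dx[IDX["A_adm"]] = u
    return dx
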