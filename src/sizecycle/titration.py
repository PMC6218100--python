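"""Titration-of-nuclear-sites cell-cycle model.

SBF occupies a fixed number of genomic binding sites (NSt); freely
diffusing SBF is neglected, so total SBF equals NSt and free active SBF
is an output of the site conservation law.  In early G1 the sites carry
Whi5-inhibited SBF to which Cln3 binds tightly and stoichiometrically.
Bound Cln3 slowly hypo-phosphorylates Whi5 (dissociating in the
process); the hypo-phosphorylated complex is either dephosphorylated or
hyper-phosphorylated by free Cln3 / Cln1,2, which liberates SBF.  Free
Cln3 only accumulates once the growing cell makes more Cln3 molecules
than the sites can absorb, so the site number sets the size threshold
for Start.  Growth, Cln1/2, Clb1/2, the APC/C, Whi5 production and the
SBF-phosphorylation bookkeeping reuse the dilution model's rate laws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np

from .gene_expression import expression_fluxes
from .params import GenomeConfig, TitrationParams

__all__ = ["TIT_VARS", "TitrationState", "rhs_titration", "titration_rates",
           "start_event_titration", "division_event_titration",
           "initial_state_titration", "whi5_total_titration", "free_sbf",
           "sbf_active_fraction_titration"]

TIT_VARS = ("Vm", "Vd", "TM", "GITM", "GDTM", "CLN3", "CLN", "CLB",
            "WHI", "WHIp", "WHIn", "WHISBF", "CLN3WHISBF", "WHIpSBF",
            "SBFp", "CDHi", "CDHa", "CDCi", "CDCa")
J = {name: k for k, name in enumerate(TIT_VARS)}

# multiplied by Vr at division; NSt and SBFp halve instead (site-linked),
# WHIn goes to the daughter in full.
_VR_SCALED = ("TM", "GITM", "GDTM", "CLN3", "CLN", "CLB",
              "WHI", "WHIp", "WHISBF", "CLN3WHISBF", "WHIpSBF",
              "CDHi", "CDHa", "CDCi", "CDCa")

_SITE_BOUND = ("WHISBF", "CLN3WHISBF", "WHIpSBF")


@dataclass
class TitrationState:
    """Dynamical state of one (mother + bud) cell in the titration model."""

    y: np.ndarray
    genome: GenomeConfig
    grm: int = 1
    grd: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.grm + self.grd != 1 or self.grm not in (0, 1):
            raise ValueError("exactly one of Grm/Grd must be 1")
        if self.genome.NSt <= 0:
            raise ValueError("titration model requires NSt > 0")

    def __getitem__(self, name: str) -> float:
        return float(self.y[J[name]])

    @property
    def Vt(self) -> float:
        return float(self.y[J["Vm"]] + self.y[J["Vd"]])

    def copy(self) -> "TitrationState":
        return TitrationState(self.y.copy(), replace(self.genome), self.grm, self.grd)


def free_sbf(y: np.ndarray, genome: GenomeConfig) -> float:
    """Free active SBF from the site conservation law.

    SBF = NSt - WHISBF - CLN3WHISBF - WHIpSBF (exact at all times).
    """
    occupied = y[J["WHISBF"]] + y[J["CLN3WHISBF"]] + y[J["WHIpSBF"]]
    return float(genome.NSt - occupied)


def sbf_active_fraction_titration(y: np.ndarray, genome: GenomeConfig) -> float:
    return max(free_sbf(y, genome), 0.0) / genome.NSt


def whi5_total_titration(state: TitrationState) -> float:
    return (state["WHI"] + state["WHIp"] + state["WHISBF"]
            + state["CLN3WHISBF"] + state["WHIpSBF"] + state["WHIn"])


def titration_rates(y: np.ndarray, genome: GenomeConfig, p: TitrationParams) -> dict:
    """Reaction rates of the titration model at one state point."""
    Vt = y[J["Vm"]] + y[J["Vd"]]
    if Vt <= 0:
        raise ValueError("total volume must be > 0")
    g = np.maximum(y, 0.0)
    CLN3, CLN, CLB = g[J["CLN3"]], g[J["CLN"]], g[J["CLB"]]
    GDTM, GITM = g[J["GDTM"]], g[J["GITM"]]
    SBFp = g[J["SBFp"]]
    SBF = max(free_sbf(g, genome), 0.0)

    gene_dose = genome.GCN / genome.GDt
    SBFt = genome.NSt
    frac_free = SBF / SBFt
    SBFu = max(SBFt - SBFp, 0.0)
    frac_unphos = SBFu / SBFt

    clb_c = CLB / Vt
    return {
        "SBF": SBF,
        "SBFu": SBFu,
        "rCln3Sy": p.kCln3Sy * GDTM * genome.GCt / genome.GDt,
        "rClnSy": p.kClnSy * GDTM * gene_dose * frac_free * frac_unphos,
        "rClbSy": (p.kClbSy + p.kClbClbSy * clb_c / (p.jClbSy + clb_c)) * GDTM * gene_dose,
        "rClbDe": p.kClbDe + p.kClbCdhDe / Vt * g[J["CDHa"]],
        "rWhiSy": p.kWhiSy * GITM * genome.GWt / genome.GIt,
        "rWhiPh": p.kWhiClnPh * CLN / Vt,
        "rWhipPh": (p.kWhipCln3Ph * CLN3 + p.kWhipClnPh * CLN) / Vt,
        "rSbfPh": p.kSbfClbPh * clb_c,
        "rCdhSy": p.kVoSy * GDTM * gene_dose,
        "rCdcSy": p.kVoSy * GDTM * gene_dose,
        "rCdhAc": p.kCdhAc * Vt + p.kCdhCdcAc * g[J["CDCa"]],
        "rCdhIn": p.kCdhClnIn * CLN + p.kCdhClbIn * CLB,
        "rCdcAc": p.kCdcClbAc * CLB,
        "rCdcIn": p.kCdcIn * Vt,
    }


def rhs_titration(state: TitrationState, p: TitrationParams) -> np.ndarray:
    """Full derivative vector of the titration model."""
    y, genome = state.y, state.genome
    Vt = y[J["Vm"]] + y[J["Vd"]]
    r = titration_rates(y, genome, p)
    g = np.maximum(y, 0.0)
    TM, GITM, GDTM = g[J["TM"]], g[J["GITM"]], g[J["GDTM"]]
    CLN3, CLN, CLB = g[J["CLN3"]], g[J["CLN"]], g[J["CLB"]]
    WHI, WHIp = g[J["WHI"]], g[J["WHIp"]]
    WHISBF, TRI, WHIpSBF = g[J["WHISBF"]], g[J["CLN3WHISBF"]], g[J["WHIpSBF"]]
    SBFp = g[J["SBFp"]]
    CDHi, CDHa, CDCi, CDCa = (g[J[n]] for n in ("CDHi", "CDHa", "CDCi", "CDCa"))
    SBF = r["SBF"]

    dTM, dGITM, dGDTM, rVoSy = expression_fluxes(TM, GITM, GDTM, Vt, genome, p)

    whi_bind = p.kWhiSbfAs / Vt * SBF * WHI          # Whi5 -> site-bound SBF
    cln3_assoc = p.kCln3WhiAs / Vt * CLN3 * WHISBF   # Cln3 -> Whi5:SBF

    def mm(r_fw, x_fw, r_bw, x_bw, j):
        fw = r_fw * (x_fw / Vt) / (j + x_fw / Vt)
        bw = r_bw * (x_bw / Vt) / (j + x_bw / Vt)
        return fw - bw

    cdh_net = mm(r["rCdhAc"], CDHi, r["rCdhIn"], CDHa, p.jCdh)
    cdc_net = mm(r["rCdcAc"], CDCi, r["rCdcIn"], CDCa, p.jCdc)

    dy = np.empty_like(y)
    dy[J["Vm"]] = state.grm * rVoSy
    dy[J["Vd"]] = state.grd * rVoSy
    dy[J["TM"]] = dTM
    dy[J["GITM"]] = dGITM
    dy[J["GDTM"]] = dGDTM
    dy[J["CLN3"]] = (r["rCln3Sy"] - cln3_assoc
                     + (p.kCln3WhiDs + p.kWhiCln3Ph) * TRI - p.kCln3De * CLN3)
    dy[J["CLN"]] = r["rClnSy"] - p.kClnDe * CLN
    dy[J["CLB"]] = r["rClbSy"] - r["rClbDe"] * CLB
    dy[J["WHI"]] = -whi_bind - r["rWhiPh"] * WHI + p.kWhiDp * WHIp
    dy[J["WHIp"]] = r["rWhiPh"] * WHI - p.kWhiDp * WHIp + r["rWhipPh"] * WHIpSBF
    dy[J["WHIn"]] = r["rWhiSy"] * state.grd
    dy[J["WHISBF"]] = (-cln3_assoc + (p.kCln3WhiDs + p.kCln3De) * TRI
                       + p.kWhiDp * WHIpSBF + whi_bind)
    dy[J["CLN3WHISBF"]] = cln3_assoc - (p.kCln3WhiDs + p.kWhiCln3Ph + p.kCln3De) * TRI
    dy[J["WHIpSBF"]] = p.kWhiCln3Ph * TRI - (r["rWhipPh"] + p.kWhiDp) * WHIpSBF
    dy[J["SBFp"]] = r["rSbfPh"] * r["SBFu"] - p.kSbfDp * SBFp
    dy[J["CDHi"]] = r["rCdhSy"] - cdh_net
    dy[J["CDHa"]] = cdh_net
    dy[J["CDCi"]] = r["rCdcSy"] - cdc_net
    dy[J["CDCa"]] = cdc_net
    return dy


def start_event_titration(state: TitrationState, p: TitrationParams) -> TitrationState:
    """Start: genome replication also doubles the nuclear sites and the
    SBF-phosphorylation bookkeeping variable (newly replicated sites
    arrive with SBF in the same phosphorylation proportions)."""
    if state.grm != 1:
        raise RuntimeError("Start fired outside G1 (event must be disarmed when budded)")
    y = state.y.copy()
    y[J["SBFp"]] = 2.0 * y[J["SBFp"]]
    return TitrationState(y, state.genome.doubled(), grm=0, grd=1)


def division_event_titration(state: TitrationState,
                             p: TitrationParams) -> tuple[TitrationState, dict]:
    """Division: sites and SBFp halve; diffusing amounts scale by Vr.

    Site-bound complexes adjust rapidly after division and are scaled by
    Vr like the freely diffusing species.  If Vr > 1/2 this could leave
    more occupied sites than the halved capacity; the occupancies are
    then renormalised proportionally (with a warning).
    """
    if state.grd != 1:
        raise RuntimeError("division fired outside the budded period")
    Vm, Vd = state["Vm"], state["Vd"]
    if Vm <= 0 or Vd <= 0:
        raise RuntimeError(f"inconsistent volumes at division: Vm={Vm}, Vd={Vd}")
    Vr = Vd / Vm
    y = state.y.copy()
    for name in _VR_SCALED:
        y[J[name]] *= Vr
    y[J["WHI"]] += state["WHIn"]
    y[J["WHIn"]] = 0.0
    y[J["SBFp"]] = state["SBFp"] / 2.0
    y[J["Vm"]] = Vd
    y[J["Vd"]] = 0.0
    genome = state.genome.halved()

    occupied = sum(y[J[n]] for n in _SITE_BOUND)
    excess_whi5 = 0.0
    if occupied > genome.NSt:
        scale = genome.NSt / occupied
        warnings.warn(
            f"occupied sites ({occupied:.3g}) exceed capacity NSt={genome.NSt:.3g} "
            f"after division (Vr={Vr:.3f}); renormalising proportionally",
            RuntimeWarning, stacklevel=2,
        )
        for name in _SITE_BOUND:
            released = y[J[name]] * (1.0 - scale)
            y[J[name]] *= scale
            excess_whi5 += released
        y[J["WHI"]] += excess_whi5  # displaced Whi5 returns to the free pool
    daughter = TitrationState(y, genome, grm=1, grd=0)
    mother_report = {"Vm": Vm, "Vd": Vd, "Vr": Vr, "Vt": Vm + Vd,
                     "renormalised_whi5": excess_whi5}
    return daughter, mother_report


def initial_state_titration(genome: GenomeConfig, p: TitrationParams,
                            V0: float = 20.0, whi5_0: float | None = None) -> TitrationState:
    """A plausible newborn G1 state: sites mostly Whi5-inhibited."""
    from .gene_expression import equilibrium_occupancy

    TMt = p.kTmSy / p.kVoSy * V0
    gi, gd = equilibrium_occupancy(genome, TMt, V0, p)
    y = np.zeros(len(TIT_VARS))
    y[J["Vm"]] = V0
    y[J["TM"]] = TMt - gi - gd
    y[J["GITM"]] = gi
    y[J["GDTM"]] = gd
    whi5 = whi5_0 if whi5_0 is not None else 1.5 * genome.NSt
    bound = min(0.95 * genome.NSt, whi5)
    y[J["WHISBF"]] = bound
    y[J["WHI"]] = whi5 - bound
    y[J["CDHa"]] = V0
    y[J["CDCi"]] = V0
    return TitrationState(y, genome, grm=1, grd=0)
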