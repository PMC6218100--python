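"""Inhibitor-dilution cell-cycle model.

Whi5, the only size-independent protein, inhibits the Start transcription
factor SBF stoichiometrically.  Growth in G1 dilutes Whi5 while SBF and
the activator Cln3 keep constant concentrations, so free SBF emerges once
the cell exceeds a threshold volume.  Positive feedback through Cln1/2
(whose synthesis requires free, unphosphorylated SBF and which in turn
phosphorylate Whi5) turns this into a bistable switch.  Two discrete
events punctuate the continuous dynamics: Start (bud emergence and genome
replication, triggered by the Cln1/2 concentration) and division
(triggered by the decay of mitotic-kinase activity).

The ODE state vector is ordered as in :data:`DIL_VARS`; the binary growth
flags Grm/Grd and the gene-copy configuration are discrete state carried
alongside in :class:`CellState`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gene_expression import expression_fluxes
from .params import DilutionParams, GenomeConfig

__all__ = ["DIL_VARS", "CellState", "rhs_dilution", "dilution_rates",
           "start_event_dilution", "division_event_dilution",
           "initial_state_dilution", "whi5_total", "sbf_active_fraction"]

DIL_VARS = ("Vm", "Vd", "TM", "GITM", "GDTM", "CLN3", "CLN", "CLB",
            "WHI", "WHIp", "WHIn", "SBF", "WHISBF", "SBFp",
            "CDHi", "CDHa", "CDCi", "CDCa")
I = {name: k for k, name in enumerate(DIL_VARS)}

# amounts multiplied by Vr = Vd/Vm at division (freely diffusing species);
# WHIn is handled separately (daughter receives all of it).
_VR_SCALED = ("TM", "GITM", "GDTM", "CLN3", "CLN", "CLB",
              "WHI", "WHIp", "SBF", "WHISBF", "SBFp",
              "CDHi", "CDHa", "CDCi", "CDCa")


@dataclass
class CellState:
    """Full dynamical state of one (mother + bud) cell."""

    y: np.ndarray
    genome: GenomeConfig
    grm: int = 1  # growth directed into the mother cell (G1)
    grd: int = 0  # growth directed into the bud (S/G2/M)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.grm + self.grd != 1 or self.grm not in (0, 1):
            raise ValueError("exactly one of Grm/Grd must be 1")

    def __getitem__(self, name: str) -> float:
        return float(self.y[I[name]])

    @property
    def Vt(self) -> float:
        return float(self.y[I["Vm"]] + self.y[I["Vd"]])

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), replace(self.genome), self.grm, self.grd)


def whi5_total(state: CellState) -> float:
    """Total Whi5 amount in all pools (free, phospho, complexed, new)."""
    return state["WHI"] + state["WHIp"] + state["WHISBF"] + state["WHIn"]


def sbf_active_fraction(y: np.ndarray, genome: GenomeConfig) -> float:
    """Fraction of SBF that is free of Whi5 (Whi5-uninhibited)."""
    sbf, whisbf = y[I["SBF"]], y[I["WHISBF"]]
    total = sbf + whisbf
    return float(sbf / total) if total > 0 else 1.0


def dilution_rates(y: np.ndarray, genome: GenomeConfig, p: DilutionParams) -> dict:
    """All reaction rates of the dilution model at one state point.

    Rate symbols follow the model's naming (rCln3Sy, rClnSy, ...).
    """
    Vt = y[I["Vm"]] + y[I["Vd"]]
    if Vt <= 0:
        raise ValueError("total volume must be > 0")
    g = np.maximum(y, 0.0)  # clip only inside rate evaluation
    CLN3, CLN, CLB = g[I["CLN3"]], g[I["CLN"]], g[I["CLB"]]
    WHI, WHIp = g[I["WHI"]], g[I["WHIp"]]
    SBF, WHISBF, SBFp = g[I["SBF"]], g[I["WHISBF"]], g[I["SBFp"]]
    CDHi, CDHa, CDCi, CDCa = (g[I[n]] for n in ("CDHi", "CDHa", "CDCi", "CDCa"))
    GDTM, GITM = g[I["GDTM"]], g[I["GITM"]]

    gene_dose = genome.GCN / genome.GDt
    SBFt = SBF + WHISBF
    frac_free = SBF / SBFt if SBFt > 0 else 1.0
    SBFu = max(SBFt - SBFp, 0.0)
    frac_unphos = SBFu / SBFt if SBFt > 0 else 1.0

    clb_c = CLB / Vt
    rates = {
        "rCln3Sy": p.kCln3Sy * GDTM * genome.GCt / genome.GDt,
        "rClnSy": p.kClnSy * GDTM * gene_dose * frac_free * frac_unphos,
        "rClbSy": (p.kClbSy + p.kClbClbSy * clb_c / (p.jClbSy + clb_c)) * GDTM * gene_dose,
        "rClbDe": p.kClbDe + p.kClbCdhDe / Vt * CDHa,
        "rWhiSy": p.kWhiSy * GITM * genome.GWt / genome.GIt,
        "rSbfSy": p.kVoSy * GDTM * gene_dose,
        "rWhiPh": (p.kWhiCln3Ph * CLN3 + p.kWhiClnPh * CLN + p.kWhiClbPh * CLB) / Vt,
        "rSbfPh": p.kSbfClbPh * clb_c,
        "rCdhSy": p.kVoSy * GDTM * gene_dose,
        "rCdcSy": p.kVoSy * GDTM * gene_dose,
        "rCdhAc": p.kCdhAc * Vt + p.kCdhCdcAc * CDCa,
        "rCdhIn": p.kCdhClnIn * CLN + p.kCdhClbIn * CLB,
        "rCdcAc": p.kCdcClbAc * CLB,
        "rCdcIn": p.kCdcIn * Vt,
        "SBFu": SBFu,
    }
    return rates


def rhs_dilution(state: CellState, p: DilutionParams) -> np.ndarray:
    """Full derivative vector of the inhibitor-dilution model."""
    y, genome = state.y, state.genome
    Vt = y[I["Vm"]] + y[I["Vd"]]
    r = dilution_rates(y, genome, p)
    g = np.maximum(y, 0.0)
    TM, GITM, GDTM = g[I["TM"]], g[I["GITM"]], g[I["GDTM"]]
    CLN3, CLN, CLB = g[I["CLN3"]], g[I["CLN"]], g[I["CLB"]]
    WHI, WHIp = g[I["WHI"]], g[I["WHIp"]]
    SBF, WHISBF, SBFp = g[I["SBF"]], g[I["WHISBF"]], g[I["SBFp"]]
    CDHi, CDHa, CDCi, CDCa = (g[I[n]] for n in ("CDHi", "CDHa", "CDCi", "CDCa"))

    dTM, dGITM, dGDTM, rVoSy = expression_fluxes(TM, GITM, GDTM, Vt, genome, p)

    bind = p.kWhiSbfAs / Vt * SBF * WHI - p.kWhiSbfDs * WHISBF

    def mm(r_fw, x_fw, r_bw, x_bw, j):
        fw = r_fw * (x_fw / Vt) / (j + x_fw / Vt)
        bw = r_bw * (x_bw / Vt) / (j + x_bw / Vt)
        return fw - bw

    cdh_net = mm(r["rCdhAc"], CDHi, r["rCdhIn"], CDHa, p.jCdh)
    cdc_net = mm(r["rCdcAc"], CDCi, r["rCdcIn"], CDCa, p.jCdc)

    dy = np.empty_like(y)
    dy[I["Vm"]] = state.grm * rVoSy
    dy[I["Vd"]] = state.grd * rVoSy
    dy[I["TM"]] = dTM
    dy[I["GITM"]] = dGITM
    dy[I["GDTM"]] = dGDTM
    dy[I["CLN3"]] = r["rCln3Sy"] - p.kCln3De * CLN3
    dy[I["CLN"]] = r["rClnSy"] - p.kClnDe * CLN
    dy[I["CLB"]] = r["rClbSy"] - r["rClbDe"] * CLB
    dy[I["WHI"]] = (-r["rWhiPh"] * WHI + p.kWhiDp * WHIp - bind)
    dy[I["WHIp"]] = r["rWhiPh"] * WHI - p.kWhiDp * WHIp + r["rWhiPh"] * WHISBF
    dy[I["WHIn"]] = r["rWhiSy"] * state.grd
    dy[I["SBF"]] = r["rSbfSy"] + r["rWhiPh"] * WHISBF - bind
    dy[I["WHISBF"]] = -r["rWhiPh"] * WHISBF + bind
    dy[I["SBFp"]] = r["rSbfPh"] * r["SBFu"] - p.kSbfDp * SBFp
    dy[I["CDHi"]] = r["rCdhSy"] - cdh_net
    dy[I["CDHa"]] = cdh_net
    dy[I["CDCi"]] = r["rCdcSy"] - cdc_net
    dy[I["CDCa"]] = cdc_net
    return dy


def start_event_dilution(state: CellState, p: DilutionParams) -> CellState:
    """Start transition: bud growth begins, the genome is replicated.

    Only the growth flags and gene counts change; every continuous
    amount is untouched.
    """
    if state.grm != 1:
        raise RuntimeError("Start fired outside G1 (event must be disarmed when budded)")
    return CellState(state.y.copy(), state.genome.doubled(), grm=0, grd=1)


def division_event_dilution(state: CellState, p: DilutionParams) -> tuple[CellState, dict]:
    """Division: follow the daughter (bud), discard the mother.

    Gene counts halve; freely diffusing amounts are multiplied by the
    mother/daughter volume ratio Vr = Vd/Vm; all newly produced Whi5 is
    directed to the daughter.  Returns the daughter state and a summary
    of the discarded mother.
    """
    if state.grd != 1:
        raise RuntimeError("division fired outside the budded period")
    Vm, Vd = state["Vm"], state["Vd"]
    if Vm <= 0 or Vd <= 0:
        raise RuntimeError(f"inconsistent volumes at division: Vm={Vm}, Vd={Vd}")
    Vr = Vd / Vm
    y = state.y.copy()
    for name in _VR_SCALED:
        y[I[name]] *= Vr
    y[I["WHI"]] += state["WHIn"]
    y[I["WHIn"]] = 0.0
    y[I["Vm"]] = Vd
    y[I["Vd"]] = 0.0
    daughter = CellState(y, state.genome.halved(), grm=1, grd=0)
    mother_report = {"Vm": Vm, "Vd": Vd, "Vr": Vr, "Vt": Vm + Vd}
    return daughter, mother_report


def initial_state_dilution(genome: GenomeConfig, p: DilutionParams,
                           V0: float = 20.0, whi5_0: float | None = None) -> CellState:
    """A plausible newborn G1 state used to seed lineage simulations.

    Gene occupancies start at binding equilibrium for the fixed-point TM
    amount; SBF, Cdh1 and Cdc20 start at 1 AU/AV; Whi5 starts entirely
    free and relaxes onto SBF within the first generations (which are
    discarded as burn-in).
    """
    from .gene_expression import equilibrium_occupancy

    TMt = p.kTmSy / p.kVoSy * V0
    gi, gd = equilibrium_occupancy(genome, TMt, V0, p)
    y = np.zeros(len(DIL_VARS))
    y[I["Vm"]] = V0
    y[I["TM"]] = TMt - gi - gd
    y[I["GITM"]] = gi
    y[I["GDTM"]] = gd
    y[I["CLN3"]] = p.kCln3Sy * gd * genome.GCt / genome.GDt / max(p.kCln3De, 1e-12)
    y[I["WHI"]] = whi5_0 if whi5_0 is not None else 3.0 * V0
    y[I["SBF"]] = V0
    y[I["CDHa"]] = V0
    y[I["CDCi"]] = V0
    return CellState(y, genome, grm=1, grd=0)
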