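"""Transcription-machinery / gene-binding core of both size-control models.

A limiting component of the transcription machinery (TM) binds genes of
two classes: size-independent genes bind tightly and are saturated in
small cells, size-dependent genes bind weakly so their occupancy grows
with the amount of TM and hence with cell volume.  TM and volume are
both synthesised in proportion to the number of transcriptionally
active size-dependent genes, which makes growth autocatalytic
(exponential) and pins the TM concentration at kTmSy/kVoSy.

State layout for the standalone expression system:

    y = (TM, GITM, GDTM, Vt, Pi, Pd)

with TM the free transcription machinery, GITM/GDTM the TM-bound
size-independent and size-dependent genes, Vt the total volume and
Pi/Pd a generic size-independent and size-dependent protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import ExpressionParams, GenomeConfig

__all__ = [
    "ExpressionState",
    "expression_rhs",
    "expression_fluxes",
    "equilibrium_occupancy",
    "specific_growth_rate",
    "simulate_expression",
    "affinity_sweep",
]

IDX = {"TM": 0, "GITM": 1, "GDTM": 2, "Vt": 3, "Pi": 4, "Pd": 5}


@dataclass
class ExpressionState:
    """Free TM and gene-occupancy state of the expression core."""

    TM: float
    GITM: float
    GDTM: float

    def validate(self, genome: GenomeConfig) -> None:
        if min(self.TM, self.GITM, self.GDTM) < 0:
            raise ValueError("negative expression-state component")
        if self.GITM > genome.GIt or self.GDTM > genome.GDt:
            raise ValueError("bound genes exceed total gene count")


def expression_fluxes(TM, GITM, GDTM, Vt, genome: GenomeConfig, p: ExpressionParams):
    """Shared TM/gene-binding derivatives and the volume-synthesis rate.

    Returns ``(dTM, dGITM, dGDTM, rVoSy)``.  Binding rates are divided by
    the total volume: a bimolecular reaction slows down in a larger cell.
    Negative excursions introduced by the integrator are clipped to zero
    inside the rate evaluation only.
    """
    TM = max(TM, 0.0)
    GI = max(genome.GIt - GITM, 0.0)
    GD = max(genome.GDt - GDTM, 0.0)
    GITM = max(GITM, 0.0)
    GDTM = max(GDTM, 0.0)

    assoc_i = p.kGiTmAs / Vt * GI * TM
    assoc_d = p.kGdTmAs / Vt * GD * TM
    dGITM = assoc_i - p.kGiTmDs * GITM
    dGDTM = assoc_d - p.kGdTmDs * GDTM
    gene_dose = genome.GCN / genome.GDt
    rTmSy = p.kTmSy * GDTM * gene_dose
    rVoSy = p.kVoSy * GDTM * gene_dose
    dTM = rTmSy + p.kGiTmDs * GITM + p.kGdTmDs * GDTM - (assoc_i + assoc_d)
    return dTM, dGITM, dGDTM, rVoSy


def expression_rhs(state: ExpressionState, genome: GenomeConfig, Vt: float,
                   params: ExpressionParams, Pi: float = 0.0, Pd: float = 0.0) -> np.ndarray:
    """Time derivatives of (TM, GITM, GDTM, Vt, Pi, Pd).

    Raises a domain error for non-positive volume or negative state.
    """
    if Vt <= 0:
        raise ValueError("volume must be > 0")
    state.validate(genome)
    if Pi < 0 or Pd < 0:
        raise ValueError("negative protein amount")
    dTM, dGITM, dGDTM, rVoSy = expression_fluxes(
        state.TM, state.GITM, state.GDTM, Vt, genome, params)
    dPi = params.kPiSy * state.GITM * genome.GCN / genome.GIt - params.kPiDe * Pi
    dPd = params.kPdSy * state.GDTM * genome.GCN / genome.GDt - params.kPdDe * Pd
    return np.array([dTM, dGITM, dGDTM, rVoSy, dPi, dPd])


def equilibrium_occupancy(genome: GenomeConfig, TMtotal: float, Vt: float,
                          params: ExpressionParams) -> tuple[float, float]:
    """Binding-equilibrium gene occupancies at a fixed total TM amount.

    Solves d(GITM)/dt = d(GDTM)/dt = 0 subject to
    TMtotal = TM + GITM + GDTM.  The occupancies are hyperbolic in the
    free-TM concentration c = TM/Vt:

        GITM = GIt * c / (c + kGiTmDs/kGiTmAs)

    and analogously for GDTM, so the conservation equation is monotone in
    the free amount and has a unique non-negative root.
    """
    if Vt <= 0:
        raise ValueError("volume must be > 0")
    if TMtotal < 0:
        raise ValueError("TMtotal must be >= 0")
    if TMtotal == 0:
        return 0.0, 0.0
    KI = params.kGiTmDs / params.kGiTmAs  # dissociation constants (AU/AV)
    KD = params.kGdTmDs / params.kGdTmAs

    def bound(free: float) -> tuple[float, float]:
        c = free / Vt
        return genome.GIt * c / (c + KI), genome.GDt * c / (c + KD)

    def residual(free: float) -> float:
        gi, gd = bound(free)
        return free + gi + gd - TMtotal

    free = brentq(residual, 0.0, TMtotal, xtol=1e-14, rtol=1e-14)
    return bound(free)


def specific_growth_rate(params: ExpressionParams, genome: GenomeConfig) -> float:
    """Closed-form specific growth rate in the unsaturated, TM-bound regime.

    With nearly all TM gene-bound and size-dependent genes far from
    saturation, GDTM tracks the total TM amount and

        mu = kVoSy * (TMt/Vt) * GCN/GDt = kTmSy * GCN / GDt.
    """
    return params.kTmSy * genome.GCN / genome.GDt


def _pack(state: ExpressionState, Vt, Pi, Pd) -> np.ndarray:
    return np.array([state.TM, state.GITM, state.GDTM, Vt, Pi, Pd])


def simulate_expression(genome: GenomeConfig, params: ExpressionParams,
                        t_span: tuple[float, float], y0: np.ndarray | None = None,
                        rtol: float = 1e-9, atol: float = 1e-10, **kw):
    """Integrate the standalone expression system.

    By default starts from equilibrated gene occupancies at Vt = 1 with
    TMt/Vt at its fixed point.  Returns the scipy solution object.
    """
    if y0 is None:
        V0 = 1.0
        TMt0 = params.kTmSy / params.kVoSy * V0
        gi, gd = equilibrium_occupancy(genome, TMt0, V0, params)
        y0 = np.array([TMt0 - gi - gd, gi, gd, V0, 0.0, 0.0])

    def rhs(t, y):
        return expression_rhs(
            ExpressionState(max(y[0], 0.0), min(max(y[1], 0.0), genome.GIt),
                            min(max(y[2], 0.0), genome.GDt)),
            genome, y[3], params, max(y[4], 0.0), max(y[5], 0.0))

    sol = solve_ivp(rhs, t_span, y0, method="LSODA", rtol=rtol, atol=atol, **kw)
    if not sol.success:
        raise RuntimeError(f"expression integration failed: {sol.message}")
    return sol


def affinity_sweep(affinity_grid, horizon: float, params: ExpressionParams | None = None,
                   genome: GenomeConfig | None = None, probe_copies: float = 1.0,
                   probe_kDs: float = 1.0, n_eval: int = 200, V0: float = 20.0):
    """Expression patterns across the TM-binding-affinity spectrum.

    ``affinity_grid`` lists equilibrium association constants kAs/kDs for
    probe genes that are added, one copy each, to the growing expression
    core.  High-affinity probes saturate early and behave like
    size-independent genes (their protein is diluted by growth); low
    affinity probes track volume and keep their protein concentration
    constant.  Probes compete for TM like any other gene.

    Returns a dict with time, volume, and per-probe occupancy, protein
    amount and protein concentration arrays.
    """
    affinity_grid = list(affinity_grid)
    if not affinity_grid:
        raise ValueError("affinity grid must not be empty")
    if params is None or genome is None:
        from .params import DilutionParams
        params = params or DilutionParams()
        genome = genome or GenomeConfig()
    n = len(affinity_grid)
    kAs = np.array([a * probe_kDs for a in affinity_grid])
    kDs = np.full(n, probe_kDs)

    TMt0 = params.kTmSy / params.kVoSy * V0
    gi, gd = equilibrium_occupancy(genome, TMt0, V0, params)
    # y = [TM, GITM, GDTM, Vt, probe occupancies..., probe proteins...]
    y0 = np.concatenate([[TMt0 - gi - gd, gi, gd, V0], np.zeros(n), np.zeros(n)])

    def rhs(t, y):
        TM, GITM, GDTM, Vt = y[0], y[1], y[2], y[3]
        occ = np.clip(y[4:4 + n], 0.0, probe_copies)
        prot = np.maximum(y[4 + n:], 0.0)
        dTM, dGITM, dGDTM, rVoSy = expression_fluxes(TM, GITM, GDTM, Vt, genome, params)
        free = np.maximum(probe_copies - occ, 0.0)
        assoc = kAs / Vt * free * max(TM, 0.0)
        docc = assoc - kDs * occ
        dTM -= assoc.sum() - (kDs * occ).sum()
        dprot = params.kPiSy * occ - params.kPiDe * prot
        return np.concatenate([[dTM, dGITM, dGDTM, rVoSy], docc, dprot])

    t_eval = np.linspace(0.0, horizon, n_eval)
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                    rtol=1e-9, atol=1e-10, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"affinity sweep integration failed: {sol.message}")
    Vt = sol.y[3]
    occ = sol.y[4:4 + n]
    prot = sol.y[4 + n:]
    return {
        "t": sol.t,
        "Vt": Vt,
        "occupancy": occ / probe_copies,
        "protein": prot,
        "concentration": prot / Vt,
        "affinity": np.asarray(affinity_grid, dtype=float),
    }
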