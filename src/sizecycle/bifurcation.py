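"""Steady-state analysis of the Start switch versus cell volume.

The Start module (Whi5, Cln3, Cln1/2 and the SBF complexes) is isolated
from the rest of the cell cycle by clamping everything outside it to its
G1 state: Clb1/2 = 0, SBFp = 0 (so the unphosphorylated fraction is 1),
the APC/C frozen, the total Whi5 amount fixed at the cell's G1 amount,
Cln3 at its quasi-steady G1 balance (dilution model), and the cell
volume treated as the bifurcation parameter (growth frozen).  Positive
feedback through Cln1/2 makes the active-SBF steady state an S-shaped
curve of volume with two fold points; the upper fold is the size
threshold for Start.

For the dilution model the clamped steady states reduce exactly to a
scalar residual in the free-SBF amount, which is scanned densely and
polished with Brent's method.  The titration model's site complexes and
Cln3 pool are mutually coupled, so its steady states are found by a
multi-start Newton solve of the vector residual.  Stability comes from
the eigenvalues of the reduced Jacobian (central differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq, fsolve

from .gene_expression import equilibrium_occupancy
from .params import GenomeConfig

__all__ = ["BranchPoint", "BifurcationBranch", "reduced_subsystem",
           "steady_states", "trace_branches", "start_threshold"]

#: reduced-state variable names per model variant
REDUCED_VARS = {
    "dilution": ("CLN", "WHIp", "WHISBF"),
    "titration": ("CLN3", "CLN", "WHIp", "WHISBF", "CLN3WHISBF", "WHIpSBF"),
}


@dataclass
class BranchPoint:
    Vt: float
    active_sbf: float      # active fraction of SBF, in [0, 1]
    stable: bool


@dataclass
class BifurcationBranch:
    """Steady-state branches of active SBF over a volume range."""

    points: list[BranchPoint]
    folds: list[float] = field(default_factory=list)  # fold volumes

    @property
    def bistable(self) -> bool:
        return len(self.folds) >= 2

    @property
    def upper_fold(self) -> float | None:
        """Largest volume at which the low-SBF (pre-Start) state exists:
        the size threshold for Start."""
        return max(self.folds) if self.folds else None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"Vt": p.Vt, "activeSBF": p.active_sbf,
              "stability": "stable" if p.stable else "unstable"}
             for p in self.points])


def _frozen_defaults(params, frozen: dict | None) -> dict:
    fr = dict(frozen or {})
    allowed = {"whi5_total", "sbf_offset", "tm_ratio", "cln3_amount"}
    unknown = set(fr) - allowed
    if unknown:
        raise ValueError(f"unknown frozen quantities: {sorted(unknown)}")
    fr.setdefault("tm_ratio", params.kTmSy / params.kVoSy)
    # SBFt(Vt) = Vt + sbf_offset in the dilution model (SBF synthesised
    # at the volume rate); ignored by the titration model (SBFt = NSt).
    fr.setdefault("sbf_offset", 0.0)
    if "whi5_total" not in fr:
        raise ValueError("frozen map must fix 'whi5_total' (the G1 Whi5 amount)")
    return fr


def _gdtm(Vt: float, genome: GenomeConfig, params, tm_ratio: float) -> float:
    """Equilibrium count of active size-dependent genes at volume Vt."""
    _, gd = equilibrium_occupancy(genome, tm_ratio * Vt, Vt, params)
    return gd


def reduced_subsystem(params, variant: Literal["dilution", "titration"],
                      frozen: dict, genome: GenomeConfig,
                      Vt: float) -> Callable[[np.ndarray], np.ndarray]:
    """Time-derivative (= steady-state residual) of the clamped Start module.

    Returns ``F(x)`` over the reduced state ``x`` ordered as
    :data:`REDUCED_VARS` for the variant, with free Whi5 and free/active
    SBF eliminated through the Whi5 and SBF conservation laws.  ``frozen``
    must fix ``whi5_total``; optional keys: ``sbf_offset`` (dilution SBF
    total is Vt + offset), ``tm_ratio`` (TM amount per unit volume),
    ``cln3_amount`` (override the quasi-steady Cln3 clamp, dilution only).
    """
    fr = _frozen_defaults(params, frozen)
    W = fr["whi5_total"]
    gdtm = _gdtm(Vt, genome, params, fr["tm_ratio"])
    gene_dose = genome.GCN / genome.GDt

    if variant == "dilution":
        SBFt = Vt + fr["sbf_offset"]
        cln3 = fr.get("cln3_amount")
        if cln3 is None:
            cln3 = params.kCln3Sy * gdtm * genome.GCt / genome.GDt / params.kCln3De

        def F(x):
            cln, whip, whisbf = x
            whi = W - whip - whisbf
            s = SBFt - whisbf
            rph = (params.kWhiCln3Ph * cln3 + params.kWhiClnPh * max(cln, 0)) / Vt
            bind = params.kWhiSbfAs / Vt * s * whi - params.kWhiSbfDs * whisbf
            dcln = params.kClnSy * gdtm * gene_dose * (s / SBFt) - params.kClnDe * cln
            dwhip = rph * (whi + whisbf) - params.kWhiDp * whip
            dwhisbf = -rph * whisbf + bind
            return np.array([dcln, dwhip, dwhisbf])

        return F

    if variant != "titration":
        raise ValueError(f"unknown variant {variant!r}")
    if genome.NSt <= 0:
        raise ValueError("titration bifurcation requires NSt > 0")
    p = params
    NSt = genome.NSt
    cln3_prod = p.kCln3Sy * gdtm * genome.GCt / genome.GDt

    def F(x):
        cln3, cln, whip, whisbf, tri, whipsbf = x
        whi = W - whip - whisbf - tri - whipsbf
        s = NSt - whisbf - tri - whipsbf
        rph = p.kWhiClnPh * max(cln, 0) / Vt
        rwhipph = (p.kWhipCln3Ph * max(cln3, 0) + p.kWhipClnPh * max(cln, 0)) / Vt
        whi_bind = p.kWhiSbfAs / Vt * s * whi
        assoc3 = p.kCln3WhiAs / Vt * cln3 * whisbf
        dcln3 = (cln3_prod - assoc3 + (p.kCln3WhiDs + p.kWhiCln3Ph) * tri
                 - p.kCln3De * cln3)
        dcln = p.kClnSy * gdtm * gene_dose * (s / NSt) - p.kClnDe * cln
        dwhip = rph * whi - p.kWhiDp * whip + rwhipph * whipsbf
        dwhisbf = (-assoc3 + (p.kCln3WhiDs + p.kCln3De) * tri
                   + p.kWhiDp * whipsbf + whi_bind)
        dtri = assoc3 - (p.kCln3WhiDs + p.kWhiCln3Ph + p.kCln3De) * tri
        dwhipsbf = p.kWhiCln3Ph * tri - (rwhipph + p.kWhiDp) * whipsbf
        return np.array([dcln3, dcln, dwhip, dwhisbf, dtri, dwhipsbf])

    return F


def _active_fraction(x, variant, genome, Vt, fr) -> float:
    if variant == "dilution":
        SBFt = Vt + fr["sbf_offset"]
        return float((SBFt - x[2]) / SBFt)
    occupied = x[3] + x[4] + x[5]
    return float((genome.NSt - occupied) / genome.NSt)


def _stable(F, x0, rel_step=1e-6):
    """Stability from eigenvalues of a central-difference Jacobian."""
    n = len(x0)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(x0[j]), 1e-8)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (F(xp) - F(xm)) / (2 * h)
    eig = np.linalg.eigvals(J)
    return bool(np.max(eig.real) < 0)


def _dilution_scalar_roots(params, genome, Vt, fr, n_scan):
    """Exact scalar reduction of the clamped dilution steady states.

    At fixed free SBF ``s`` every other species has a unique conditional
    steady state in closed form; the residual closes SBF conservation.
    """
    W = fr["whi5_total"]
    SBFt = Vt + fr["sbf_offset"]
    gdtm = _gdtm(Vt, genome, params, fr["tm_ratio"])
    gene_dose = genome.GCN / genome.GDt
    cln3 = fr.get("cln3_amount")
    if cln3 is None:
        cln3 = params.kCln3Sy * gdtm * genome.GCt / genome.GDt / params.kCln3De

    def parts(s):
        cln = params.kClnSy * gdtm * gene_dose * (s / SBFt) / params.kClnDe
        rph = (params.kWhiCln3Ph * cln3 + params.kWhiClnPh * cln) / Vt
        beta = (params.kWhiSbfAs * s / Vt) / (params.kWhiSbfDs + rph)
        whi = W / (1.0 + beta + rph * (1.0 + beta) / params.kWhiDp)
        whisbf = beta * whi
        whip = W - whi - whisbf
        return np.array([cln, whip, whisbf])

    def g(s):
        return s + parts(s)[2] - SBFt

    grid = np.unique(np.concatenate([
        np.geomspace(1e-8 * SBFt, SBFt * 0.9999, n_scan // 2),
        np.linspace(1e-8 * SBFt, SBFt * 0.9999, n_scan // 2),
    ]))
    vals = np.array([g(s) for s in grid])
    sign = np.signbit(vals)
    out = []
    for k in np.flatnonzero(sign[:-1] != sign[1:]):
        s = brentq(g, grid[k], grid[k + 1], xtol=1e-12, rtol=1e-14)
        out.append(parts(s))
    return out


def _titration_guesses(params, genome, Vt, fr, n_scan):
    """Structured initial guesses spanning OFF, intermediate and ON states."""
    W = fr["whi5_total"]
    NSt = genome.NSt
    gdtm = _gdtm(Vt, genome, params, fr["tm_ratio"])
    cln3_prod = params.kCln3Sy * gdtm * genome.GCt / genome.GDt
    A = cln3_prod / params.kCln3De
    guesses = []
    for occ_frac in np.linspace(0.02, 0.995, max(n_scan // 20, 12)):
        occupied = occ_frac * NSt
        s = NSt - occupied
        cln = params.kClnSy * gdtm * (genome.GCN / genome.GDt) \
            * (s / NSt) / params.kClnDe
        for tri_share in (0.1, 0.5, 0.9):
            tri = min(tri_share * occupied, 0.95 * A)
            whisbf = 0.8 * (occupied - tri)
            whipsbf = occupied - tri - whisbf
            cln3 = max(A - tri, 1e-9)
            diffusible = max(W - occupied, 0.0)
            whip = 0.5 * diffusible
            guesses.append(np.array([cln3, cln, whip, whisbf, tri, whipsbf]))
    return guesses


def steady_states(params, variant, genome, Vt, frozen, n_scan: int = 400):
    """All steady states of the clamped Start module at one volume.

    Returns ``(active_fraction, stable)`` pairs sorted by activity.
    """
    fr = _frozen_defaults(params, frozen)
    F = reduced_subsystem(params, variant, frozen, genome, Vt)

    if variant == "dilution":
        roots = _dilution_scalar_roots(params, genome, Vt, fr, n_scan)
    else:
        scale = max(genome.NSt, fr["whi5_total"])
        roots = []
        for x0 in _titration_guesses(params, genome, Vt, fr, n_scan):
            x, info, ier, _ = fsolve(F, x0, full_output=True, xtol=1e-12)
            if ier != 1:
                continue
            if np.max(np.abs(F(x))) > 1e-8 * scale:
                continue
            whi = fr["whi5_total"] - x[2] - x[3] - x[4] - x[5]
            s = genome.NSt - x[3] - x[4] - x[5]
            if np.min(x) < -1e-8 * scale or whi < -1e-8 * scale or s < -1e-8 * scale:
                continue
            roots.append(x)

    out = []
    for x in roots:
        frac = _active_fraction(x, variant, genome, Vt, fr)
        out.append((min(max(frac, 0.0), 1.0), _stable(F, x)))
    out.sort()
    dedup = []
    for frac, st in out:
        if not dedup or abs(frac - dedup[-1][0]) > 1e-6:
            dedup.append((frac, st))
    return dedup


def trace_branches(params, variant, genome, V_range, frozen,
                   n_scan: int = 400) -> BifurcationBranch:
    """Trace stable/unstable steady-state branches over a volume grid.

    ``V_range`` is an iterable of volumes or a ``(lo, hi, n)`` tuple.
    Fold volumes (where the number of coexisting states changes) are
    refined by bisection on the state count.
    """
    if isinstance(V_range, tuple) and len(V_range) == 3:
        volumes = np.linspace(*V_range)
    else:
        volumes = np.asarray(list(V_range), dtype=float)
    if len(volumes) < 2:
        raise ValueError("V_range must contain at least two volumes")

    cache: dict[float, list] = {}

    def states_at(Vt):
        key = float(Vt)
        if key not in cache:
            cache[key] = steady_states(params, variant, genome, key,
                                       frozen, n_scan)
        return cache[key]

    points: list[BranchPoint] = []
    for Vt in volumes:
        for frac, st in states_at(Vt):
            points.append(BranchPoint(float(Vt), float(frac), st))

    # a narrow bistable window can hide between grid points: wherever the
    # (apparently unique) branch jumps discontinuously, bisect for a
    # volume with coexisting states before giving up
    volumes = list(volumes)
    refined = list(volumes)
    for k in range(len(volumes) - 1):
        a, b = volumes[k], volumes[k + 1]
        sa, sb = states_at(a), states_at(b)
        if len(sa) == 1 and len(sb) == 1 and abs(sa[0][0] - sb[0][0]) > 0.05:
            lo, hi = a, b
            for _ in range(18):
                mid = 0.5 * (lo + hi)
                sm = states_at(mid)
                refined.append(mid)
                if len(sm) > 1:
                    break
                # follow the discontinuity
                if abs(sm[0][0] - states_at(lo)[0][0]) > \
                        abs(sm[0][0] - states_at(hi)[0][0]):
                    hi = mid
                else:
                    lo = mid
    refined = sorted(set(refined))
    for Vt in refined:
        if Vt not in volumes:
            for frac, st in states_at(Vt):
                points.append(BranchPoint(float(Vt), float(frac), st))
    points.sort(key=lambda p: (p.Vt, p.active_sbf))

    folds = []
    for k in range(len(refined) - 1):
        n_a = len(states_at(refined[k]))
        n_b = len(states_at(refined[k + 1]))
        if n_a != n_b:
            lo, hi = refined[k], refined[k + 1]
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if len(states_at(mid)) == n_a:
                    lo = mid
                else:
                    hi = mid
            folds.append(0.5 * (lo + hi))
    return BifurcationBranch(points=points, folds=folds)


def start_threshold(params, variant, genome, frozen, V_range=None,
                    n_grid: int = 40) -> float | None:
    """Upper-fold volume: the size threshold for the Start transition."""
    if V_range is None:
        W = frozen["whi5_total"]
        V_hi = 2.0 * W if variant == "dilution" else 8.0 * W
        V_range = (max(0.05 * V_hi, 1e-3), V_hi, n_grid)
    branch = trace_branches(params, variant, genome, V_range, frozen)
    return branch.upper_fold
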