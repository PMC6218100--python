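"""Hybrid ODE/event integrator and multi-generation lineage driver.

A cell cycle is integrated in two phases.  In G1 only the Start event is
armed (upward crossing of the Cln1/2 concentration through StartThr); in
the budded period only the division event is armed (downward crossing of
the combined Cln1/2 + Clb1/2 concentration through MitosisThr).  This
state machine makes double triggering impossible.  Lineages follow the
daughter cell after every division; the specific growth rate can be held
fixed (deterministic mode) or resampled at each division with the AR(1)
inheritance rule

    mu_{n+1} = 0.5 mu_n + 0.5 mu_bar (1 + eps),   eps ~ N(0, variance 0.04),

applied by scaling kVoSy and kTmSy by mu_{n+1}/mu_bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import dilution, titration
from .params import DilutionParams, GenomeConfig, TitrationParams, scale_growth
from .gene_expression import specific_growth_rate

__all__ = [
    "G1ArrestError", "MitoticArrestError", "CycleRecord", "LineageConfig",
    "integrate_cycle", "sample_growth_rate", "simulate_lineage",
    "records_to_frame", "trajectory_frame", "new_cell",
]


class G1ArrestError(RuntimeError):
    """No Start transition within the integration horizon."""


class MitoticArrestError(RuntimeError):
    """No division within the integration horizon."""


@dataclass
class CycleRecord:
    """Per-generation summary of one cell cycle (daughter lineage)."""

    generation: int
    V_birth: float
    V_start: float
    V_division: float
    T_G1: float
    T_SGM: float
    WHI_birth: float
    WHIn_produced: float
    growth_factor: float = 1.0

    def validate(self) -> None:
        if not (self.V_birth < self.V_start < self.V_division):
            raise ValueError("cycle volumes must satisfy V_birth < V_start < V_division")
        if self.T_G1 <= 0 or self.T_SGM <= 0:
            raise ValueError("phase durations must be > 0")


@dataclass
class LineageConfig:
    """Configuration of a multi-generation lineage simulation."""

    variant: Literal["dilution", "titration"] = "titration"
    n_generations: int = 30
    seed: int | None = None
    stochastic_growth: bool = False
    growth_factor: float = 1.0        # fixed factor f in deterministic mode
    inheritance_weight: float = 0.5
    noise_variance: float = 0.04
    burn_in: int = 10                 # generations discarded before statistics
    V0: float = 20.0
    fix_birth_whi5: float | None = None  # overwrite total Whi5 at each birth
    max_phase_time: float = 5000.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


_MODEL = {
    "dilution": dict(
        rhs=dilution.rhs_dilution,
        start=dilution.start_event_dilution,
        divide=dilution.division_event_dilution,
        idx=dilution.I,
        whi5_total=dilution.whi5_total,
        whi5_pools=("WHI", "WHIp", "WHISBF"),
        init=dilution.initial_state_dilution,
        vars=dilution.DIL_VARS,
    ),
    "titration": dict(
        rhs=titration.rhs_titration,
        start=titration.start_event_titration,
        divide=titration.division_event_titration,
        idx=titration.J,
        whi5_total=titration.whi5_total_titration,
        whi5_pools=("WHI", "WHIp", "WHISBF", "CLN3WHISBF", "WHIpSBF"),
        init=titration.initial_state_titration,
        vars=titration.TIT_VARS,
    ),
}


def new_cell(variant: str, genome: GenomeConfig, params, V0: float = 20.0,
             whi5_0: float | None = None):
    """Construct a newborn G1 cell state for either model variant."""
    return _MODEL[variant]["init"](genome, params, V0=V0, whi5_0=whi5_0)


def _check_nonnegative(y: np.ndarray, where: str) -> None:
    floor = -1e-9 * max(1.0, float(np.max(np.abs(y))))
    if float(np.min(y)) < floor:
        k = int(np.argmin(y))
        raise RuntimeError(f"state went negative during {where}: y[{k}] = {y[k]:.3e}")


def _integrate_phase(state, params, rhs, event_fn, direction: int,
                     t0: float, max_time: float, rtol: float, atol: float):
    """Integrate one phase until the armed event fires; returns (sol, t_event)."""

    def f(t, y):
        s = state.copy()
        s.y = y
        return rhs(s, params)

    def ev(t, y):
        return event_fn(y)

    ev.terminal = True
    ev.direction = direction
    sol = solve_ivp(f, (t0, t0 + max_time), state.y, method="LSODA",
                    rtol=rtol, atol=atol, events=ev, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    fired = len(sol.t_events[0]) > 0
    t_event = float(sol.t_events[0][0]) if fired else None
    y_end = sol.y_events[0][0] if fired else sol.y[:, -1]
    _check_nonnegative(y_end, "phase integration")
    return sol, t_event, y_end


def integrate_cycle(state, params, variant: str, t0: float = 0.0,
                    max_phase_time: float = 5000.0, rtol: float = 1e-8,
                    atol: float = 1e-10, generation: int = 0,
                    growth_factor: float = 1.0, collect_trajectory: bool = False):
    """Integrate one full cell cycle from a newborn G1 state.

    Fires Start exactly once, then division exactly once.  Returns
    ``(trajectory, record, daughter_state)`` where ``trajectory`` is a
    dict of phase solutions (or None) and ``record`` a CycleRecord.

    Raises :class:`G1ArrestError` / :class:`MitoticArrestError` when the
    respective event does not occur within ``max_phase_time``.
    """
    m = _MODEL[variant]
    idx = m["idx"]
    iVm, iVd, iCLN, iCLB = idx["Vm"], idx["Vd"], idx["CLN"], idx["CLB"]

    V_birth = state.y[iVm] + state.y[iVd]
    WHI_birth = m["whi5_total"](state)

    def start_fn(y):
        return y[iCLN] / (y[iVm] + y[iVd]) - params.StartThr

    sol1, t_start, y_start = _integrate_phase(
        state, params, m["rhs"], start_fn, +1, t0, max_phase_time, rtol, atol)
    if t_start is None:
        raise G1ArrestError(
            f"generation {generation}: no Start within {max_phase_time} time units")
    g1_state = state.copy()
    g1_state.y = y_start
    V_start = y_start[iVm] + y_start[iVd]
    budded = m["start"](g1_state, params)

    def division_fn(y):
        return (y[iCLN] + y[iCLB]) / (y[iVm] + y[iVd]) - params.MitosisThr

    sol2, t_div, y_div = _integrate_phase(
        budded, params, m["rhs"], division_fn, -1, t_start, max_phase_time, rtol, atol)
    if t_div is None:
        raise MitoticArrestError(
            f"generation {generation}: no division within {max_phase_time} time units")
    end_state = budded.copy()
    end_state.y = y_div
    V_division = y_div[iVm] + y_div[iVd]
    WHIn_produced = y_div[idx["WHIn"]]
    daughter, _ = m["divide"](end_state, params)

    record = CycleRecord(
        generation=generation,
        V_birth=float(V_birth),
        V_start=float(V_start),
        V_division=float(V_division),
        T_G1=float(t_start - t0),
        T_SGM=float(t_div - t_start),
        WHI_birth=float(WHI_birth),
        WHIn_produced=float(WHIn_produced),
        growth_factor=float(growth_factor),
    )
    record.validate()
    trajectory = None
    if collect_trajectory:
        trajectory = {"G1": sol1, "SGM": sol2, "t_start": t_start, "t_division": t_div}
    return trajectory, record, daughter


def sample_growth_rate(mu_prev: float, mu_bar: float, rng: np.random.Generator,
                       inheritance_weight: float = 0.5,
                       noise_variance: float = 0.04) -> float:
    """Growth rate of the next generation under the inheritance rule.

    mu_next = w*mu_prev + (1-w)*mu_bar*(1+eps), eps ~ N(0, noise_variance).
    A draw that would make the rate non-positive is rejected and redrawn
    (vanishingly rare at the default variance).
    """
    if mu_prev <= 0 or mu_bar <= 0:
        raise ValueError("growth rates must be > 0")
    sigma = np.sqrt(noise_variance)
    w = inheritance_weight
    for _ in range(100):
        eps = rng.normal(0.0, sigma)
        mu_next = w * mu_prev + (1.0 - w) * mu_bar * (1.0 + eps)
        if mu_next > 0:
            return float(mu_next)
    raise RuntimeError("failed to draw a positive growth rate")


def _rescale_whi5(state, variant: str, target: float):
    """Overwrite the total Whi5 amount with ``target`` at birth.

    The free pool absorbs the adjustment; only if the deficit exceeds the
    free + phosphorylated pools are the remaining (complexed) pools scaled
    down, which keeps site conservation intact in the titration model.
    """
    m = _MODEL[variant]
    idx = m["idx"]
    total = m["whi5_total"](state)
    if total <= 0:
        raise RuntimeError("cannot rescale zero Whi5")
    delta = target - total
    if delta >= 0:
        state.y[idx["WHI"]] += delta
        return state
    for name in ("WHI", "WHIp"):  # drain diffusible pools first
        take = min(state.y[idx[name]], -delta)
        state.y[idx[name]] -= take
        delta += take
        if delta >= 0:
            return state
    bound = [n for n in m["whi5_pools"] if n not in ("WHI", "WHIp")]
    bound_total = sum(state.y[idx[n]] for n in bound)
    scale = max(1.0 + delta / bound_total, 0.0) if bound_total > 0 else 0.0
    for name in bound:
        state.y[idx[name]] *= scale
    return state


def simulate_lineage(config: LineageConfig, params, genome: GenomeConfig,
                     collect_trajectories: bool = False,
                     initial_state=None):
    """Chain cell cycles across generations, following daughters.

    Returns ``(records, trajectories)``; ``records`` contains only the
    post-burn-in generations.  Growth-rate resampling (stochastic mode)
    happens at each division.  Arrest errors propagate, annotated with
    the generation index.
    """
    variant = config.variant
    rng = np.random.default_rng(config.seed)
    mu_bar = specific_growth_rate(params, genome)
    mu = mu_bar
    factor = config.growth_factor

    state = initial_state if initial_state is not None else new_cell(
        variant, genome, params, V0=config.V0)
    if config.fix_birth_whi5 is not None:
        _rescale_whi5(state, variant, config.fix_birth_whi5)

    records: list[CycleRecord] = []
    trajectories = [] if collect_trajectories else None
    t = 0.0
    total = config.burn_in + config.n_generations
    for gen in range(total):
        if config.stochastic_growth:
            factor = mu / mu_bar
        p_gen = scale_growth(params, factor) if factor != 1.0 else params
        traj, record, state = integrate_cycle(
            state, p_gen, variant, t0=t,
            max_phase_time=config.max_phase_time,
            rtol=config.rtol, atol=config.atol,
            generation=gen, growth_factor=factor,
            collect_trajectory=collect_trajectories)
        t += record.T_G1 + record.T_SGM
        if gen >= config.burn_in:
            records.append(record)
            if collect_trajectories:
                trajectories.append(traj)
        if config.stochastic_growth:
            mu = sample_growth_rate(mu, mu_bar, rng,
                                    config.inheritance_weight,
                                    config.noise_variance)
        if config.fix_birth_whi5 is not None:
            _rescale_whi5(state, variant, config.fix_birth_whi5)
    return records, trajectories


def records_to_frame(records: list[CycleRecord]) -> pd.DataFrame:
    """Per-generation summaries as a tidy DataFrame."""
    return pd.DataFrame([vars(r) for r in records])


def trajectory_frame(trajectory: dict, variant: str) -> pd.DataFrame:
    """Tidy (time, variable, value) long-format frame of one cycle."""
    names = _MODEL[variant]["vars"]
    rows = []
    for phase in ("G1", "SGM"):
        sol = trajectory[phase]
        for k, name in enumerate(names):
            rows.append(pd.DataFrame(
                {"time": sol.t, "variable": name, "value": sol.y[k], "phase": phase}))
    return pd.concat(rows, ignore_index=True)
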