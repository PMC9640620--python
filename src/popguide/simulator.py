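"""Batch-fermentation integration and in-silico experiment designs.

Wraps the consortium vector field in an adaptive stiff-capable integrator
and provides the experiment layouts used throughout: ampicillin dose
scans, inoculum-size scans, and exogenous 3-HP × ampicillin growth
matrices (ΔOD600 over a fixed horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    ConsortiumParams,
    CultureState,
    STATE_FIELDS,
    rhs,
)

__all__ = [
    "SimulationConfig",
    "TimeCourse",
    "IntegrationError",
    "simulate",
    "scan_amp",
    "scan_inoculum",
    "growth_matrix",
    "compare_strategies",
    "DEFAULT_INIT",
    "CONSTITUTIVE_GRID",
]

#: Standard co-culture inoculum: producer OD 0.5, consumer OD 2, on
#: 20 g/L alginate.
DEFAULT_INIT = CultureState(x_v=0.5, x_e=2.0, s=20.0)

#: CSV column names for a serialized time course.
TIMECOURSE_COLUMNS = (
    "time_h", "X_V", "X_E", "S_gL", "A_gL", "P_mgL", "C_ugmL", "OD", "ratio_E")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid time t={t_last:.4g} h)")
        self.t_last = t_last


@dataclass(frozen=True)
class SimulationConfig:
    """Integration horizon, output grid and solver tolerances.

    ``output_times=None`` means a 6-h sampling grid over ``[0, t_end]``,
    the cadence at which batch fermentations are typically sampled.
    """

    t_end: float = 48.0
    output_times: Sequence[float] | None = None
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            if t.ndim != 1 or len(t) == 0:
                raise ValueError("output_times must be a non-empty 1-d grid")
            if np.any(t < 0) or np.any(t > self.t_end + 1e-12):
                raise ValueError("output_times must lie within [0, t_end]")
            if np.any(np.diff(t) <= 0):
                raise ValueError("output_times must be strictly increasing")

    def grid(self) -> np.ndarray:
        if self.output_times is not None:
            return np.asarray(self.output_times, dtype=float)
        return np.arange(0.0, self.t_end + 1e-9, 6.0)


@dataclass(frozen=True)
class TimeCourse:
    """Simulated trajectory on the output grid plus the dense solver steps.

    ``states`` has one row per output time in :data:`STATE_FIELDS` order.
    ``dense_times``/``dense_states`` are the solver's own accepted steps,
    used for extrema (e.g. peak acetate) that a coarse 6-h grid misses.
    """

    times: np.ndarray
    states: np.ndarray
    dense_times: np.ndarray = field(repr=False, default=None)
    dense_states: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (len(self.times), 6):
            raise ValueError("states must be (n_times, 6)")

    @property
    def od_total(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    @property
    def ratio_e(self) -> np.ndarray:
        """Consumer fraction per time point; NaN where the culture is empty."""
        od = self.od_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(od > 0, self.states[:, 1] / od, np.nan)

    def state_at(self, t: float) -> CultureState:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if len(idx) == 0:
            raise ValueError(f"t={t} not on the output grid")
        return CultureState.from_array(self.states[idx[0]])

    def final_state(self) -> CultureState:
        return CultureState.from_array(self.states[-1])

    def channel(self, name: str) -> np.ndarray:
        """One state channel by field name (``x_v``, ``s``, ...)."""
        return self.states[:, STATE_FIELDS.index(name)]

    def peak_acetate(self) -> float:
        """Maximum acetate over the dense solver steps."""
        src = self.dense_states if self.dense_states is not None else self.states
        return float(np.max(src[:, 3]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=["X_V", "X_E", "S_gL",
                                                "A_gL", "P_mgL", "C_ugmL"])
        df.insert(0, "time_h", self.times)
        df["OD"] = self.od_total
        df["ratio_E"] = self.ratio_e
        return df[list(TIMECOURSE_COLUMNS)]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    params: ConsortiumParams,
    init: CultureState = DEFAULT_INIT,
    config: SimulationConfig = SimulationConfig(),
    stop_when: Callable[[float, np.ndarray], float] | None = None,
) -> TimeCourse:
    """Integrate the consortium model over a batch fermentation.

    Uses LSODA (adaptive, stiff-capable).  Output states are clipped at
    zero to absorb solver-tolerance-sized negative excursions.  The run is
    deterministic: identical inputs give identical output.

    ``stop_when`` is an optional terminal event function ``f(t, y)`` whose
    sign change stops the integration early (e.g. substrate depletion);
    the event time is appended to the output grid.
    """
    grid = config.grid()
    y0 = init.as_array()

    events = None
    if stop_when is not None:
        stop_when.terminal = True  # type: ignore[attr-defined]
        events = [stop_when]

    sol = solve_ivp(
        lambda t, y: rhs(y, params),
        (0.0, config.t_end),
        y0,
        method="LSODA",
        t_eval=None,
        dense_output=True,
        events=events,
        rtol=config.rel_tol,
        atol=config.abs_tol,
        max_step=config.max_step,
    )
    if not sol.success:
        raise IntegrationError(sol.message, t_last=float(sol.t[-1]))

    t_stop = float(sol.t[-1])
    out_t = grid[grid <= t_stop + 1e-12]
    if len(out_t) == 0 or not np.isclose(out_t[0], 0.0):
        out_t = np.concatenate([[0.0], out_t])
    if t_stop < config.t_end - 1e-9 and not np.isclose(out_t[-1], t_stop):
        out_t = np.concatenate([out_t, [t_stop]])  # stopped early at event

    out_y = sol.sol(out_t).T
    dense_y = sol.y.T
    return TimeCourse(
        times=out_t,
        states=np.clip(out_y, 0.0, None),
        dense_times=sol.t.copy(),
        dense_states=np.clip(dense_y, 0.0, None),
    )


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------


def _summary_row(tc: TimeCourse) -> dict[str, float]:
    end = tc.final_state()
    return {
        "final_P_mgL": end.p,
        "peak_A_gL": tc.peak_acetate(),
        "final_OD": end.od_total,
        "final_ratio_E": end.ratio_e,
        "consumed_S_gL": tc.channel("s")[0] - end.s,
    }


def scan_amp(
    params: ConsortiumParams,
    amp_levels: Sequence[float],
    init: CultureState = DEFAULT_INIT,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[dict[float, TimeCourse], pd.DataFrame]:
    """One batch simulation per initial ampicillin dose.

    Returns the per-level trajectories and a summary table (48-h titre,
    peak acetate, final OD, final consumer fraction).  A level whose
    integration fails is reported with NaNs and the rest continue.
    """
    if any(a < 0 for a in amp_levels):
        raise ValueError("ampicillin levels must be >= 0")
    courses: dict[float, TimeCourse] = {}
    rows = []
    for amp in amp_levels:
        ic = replace(init, c=float(amp))
        row: dict[str, float] = {"amp_ugmL": float(amp)}
        try:
            tc = simulate(params, ic, config)
            courses[float(amp)] = tc
            row.update(_summary_row(tc))
        except IntegrationError as err:
            row.update({k: np.nan for k in ("final_P_mgL", "peak_A_gL",
                                            "final_OD", "final_ratio_E",
                                            "consumed_S_gL")})
            row["error_t_last"] = err.t_last
        rows.append(row)
    return courses, pd.DataFrame(rows)


def scan_inoculum(
    params: ConsortiumParams,
    inocula: Sequence[tuple[float, float]],
    init: CultureState = DEFAULT_INIT,
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Final-titre summary across (producer, consumer) inoculum sizes.

    Everything but the two biomass components is taken from ``init``.
    """
    rows = []
    for x_v0, x_e0 in inocula:
        if x_v0 < 0 or x_e0 < 0 or (x_v0 == 0 and x_e0 == 0):
            raise ValueError("inocula must be non-negative and not both zero")
        ic = replace(init, x_v=float(x_v0), x_e=float(x_e0))
        row = {"X_V0": float(x_v0), "X_E0": float(x_e0)}
        try:
            tc = simulate(params, ic, config)
            row.update(_summary_row(tc))
        except IntegrationError as err:
            row["error_t_last"] = err.t_last
        rows.append(row)
    return pd.DataFrame(rows)


#: Constitutive expression strengths for strategy comparisons, spanning
#: three orders of magnitude like a weak-to-strong promoter ladder.
CONSTITUTIVE_GRID = (0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0)


def compare_strategies(
    params: ConsortiumParams,
    dose: float,
    beta_0_grid: Sequence[float] = CONSTITUTIVE_GRID,
    init: CultureState = DEFAULT_INIT,
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Final-titre comparison of circuit strategies at one ampicillin dose.

    Runs the commensal baseline (no *bla*), one constitutive variant per
    expression strength in ``beta_0_grid``, and the product-inducible
    guider, all from the same inoculum with ``C(0) = dose``.  Everything
    but the circuit is shared, so differences isolate the expression
    strategy.
    """
    import dataclasses as _dc

    rows = []
    variants: list[tuple[str, float, ConsortiumParams]] = [
        ("none", 0.0, params.with_circuit(
            _dc.replace(params.circuit, mode="none"))),
        ("guider", np.nan, params.with_circuit(
            _dc.replace(params.circuit, mode="guider"))),
    ]
    for b0 in beta_0_grid:
        circ = _dc.replace(params.circuit, mode="constitutive",
                           beta_0=float(b0),
                           beta_1=max(float(b0), params.circuit.beta_1))
        variants.append(("constitutive", float(b0), params.with_circuit(circ)))
    for strategy, b0, p in variants:
        ic = replace(init, c=float(dose))
        tc = simulate(p, ic, config)
        row = {"strategy": strategy, "beta_0": b0, "amp_ugmL": float(dose)}
        row.update(_summary_row(tc))
        rows.append(row)
    return pd.DataFrame(rows)


def growth_matrix(
    params: ConsortiumParams,
    hp_levels: Sequence[float],
    amp_levels: Sequence[float],
    init: CultureState = DEFAULT_INIT,
    horizon: float = 24.0,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """ΔOD600 over ``horizon`` hours for each exogenous 3-HP × ampicillin pair.

    Emulates a growth-control assay with a *non-producing* consumer: the
    product yield is zeroed so the only 3-HP present is the exogenously
    added dose (``hp_levels``, g/L), which drives the circuit.  Returns a
    DataFrame indexed by 3-HP level with one column per ampicillin level.
    """
    if config is None:
        config = SimulationConfig(t_end=horizon,
                                  output_times=(0.0, horizon))
    prod_off = replace(params.production, y_pa=0.0)
    p = params.replace(production=prod_off)
    data = {}
    for amp in amp_levels:
        col = []
        for hp in hp_levels:
            ic = replace(init, p=float(hp) * 1000.0, c=float(amp))
            tc = simulate(p, ic, config)
            col.append(tc.od_total[-1] - tc.od_total[0])
        data[float(amp)] = col
    df = pd.DataFrame(data, index=[float(h) for h in hp_levels])
    df.index.name = "hp_gL"
    df.columns.name = "amp_ugmL"
    return df
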