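"""Parameter estimation from multi-condition fermentation time courses.

An :class:`ObservationSet` holds tidy measured channels (OD, alginate,
acetate, 3-HP, population ratio) for one or more culture conditions; the
fitting layer wraps a channel-weighted least-squares objective in a
seeded multi-start bounded optimizer, with residual-resampling bootstrap
intervals on top.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import (
    ConsortiumParams,
    CultureState,
    params_from_dict,
    params_to_dict,
)
from .simulator import IntegrationError, SimulationConfig, TimeCourse, simulate

__all__ = [
    "CHANNELS",
    "Condition",
    "ObservationSet",
    "FitResult",
    "loss",
    "fit",
    "bootstrap",
]

#: Measured channels and the TimeCourse quantity each one observes.
CHANNELS = ("OD", "S_gL", "A_gL", "P_mgL", "ratio_E")

#: Penalty residual used when an integration fails inside the optimizer.
_FAIL_RESIDUAL = 1e3


@dataclass(frozen=True)
class Condition:
    """One culture condition: initial state and circuit mode."""

    condition_id: str
    init: CultureState
    circuit_mode: str = "guider"


def _channel_values(tc: TimeCourse, channel: str, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(tc.times, times)
    if not np.allclose(tc.times[idx], times, atol=1e-9):
        raise ValueError("requested times missing from simulated grid")
    if channel == "OD":
        return tc.od_total[idx]
    if channel == "ratio_E":
        return tc.ratio_e[idx]
    key = {"S_gL": "s", "A_gL": "a", "P_mgL": "p"}[channel]
    return tc.channel(key)[idx]


@dataclass
class ObservationSet:
    """Tidy measured time courses for a set of culture conditions.

    ``data`` columns: ``condition_id``, ``channel``, ``time_h``,
    ``value``; missing measurements are NaN.  ``noise_scales`` gives the
    per-channel measurement scale used to weight residuals; channels
    without an entry fall back to their own maximum observed value.
    ``truth`` optionally carries the generating parameters of a
    synthetic set, for recovery experiments.
    """

    data: pd.DataFrame
    conditions: dict[str, Condition]
    noise_scales: dict[str, float] = field(default_factory=dict)
    provenance: str = "user"
    truth: ConsortiumParams | None = None

    def __post_init__(self) -> None:
        required = {"condition_id", "channel", "time_h", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if len(self.data) == 0:
            raise ValueError("observation set is empty")
        t = self.data["time_h"].to_numpy(float)
        if np.any(t < 0) or np.any(t > 48 + 1e-9):
            raise ValueError("observation times must lie within [0, 48] h")
        vals = self.data["value"].to_numpy(float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("measured values must be >= 0 or missing")
        unknown = set(self.data["condition_id"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"conditions missing definitions: {sorted(unknown)}")
        if self.provenance not in ("synthetic", "user"):
            raise ValueError("provenance must be 'synthetic' or 'user'")

    def channel_scale(self, channel: str) -> float:
        if channel in self.noise_scales and self.noise_scales[channel] > 0:
            return float(self.noise_scales[channel])
        vals = self.data.loc[self.data["channel"] == channel, "value"]
        m = np.nanmax(vals.to_numpy(float)) if len(vals) else np.nan
        return float(m) if np.isfinite(m) and m > 0 else 1.0

    # -- serialization ------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the tidy measurement table (floats at full precision)."""
        self.data.to_csv(path, index=False, float_format="%.17g")

    def save(self, base) -> None:
        """Write ``<base>.csv`` (data) and ``<base>.meta.yaml`` (design)."""
        base = str(base)
        self.to_csv(base + ".csv")
        meta = {
            "provenance": self.provenance,
            "noise_scales": {k: float(v) for k, v in self.noise_scales.items()},
            "conditions": {
                cid: {"init": {f: getattr(c.init, f) for f in
                               ("x_v", "x_e", "s", "a", "p", "c")},
                      "circuit_mode": c.circuit_mode}
                for cid, c in self.conditions.items()},
        }
        if self.truth is not None:
            meta["truth"] = params_to_dict(self.truth)
        with open(base + ".meta.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def load(cls, base) -> "ObservationSet":
        base = str(base)
        data = pd.read_csv(base + ".csv", float_precision="round_trip")
        data["time_h"] = data["time_h"].astype(float)
        data["value"] = data["value"].astype(float)
        with open(base + ".meta.yaml", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
        conditions = {
            cid: Condition(cid, CultureState(**d["init"]), d["circuit_mode"])
            for cid, d in meta["conditions"].items()}
        truth = params_from_dict(meta["truth"]) if "truth" in meta else None
        return cls(data=data, conditions=conditions,
                   noise_scales=meta.get("noise_scales", {}),
                   provenance=meta.get("provenance", "user"), truth=truth)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start fit."""

    params: ConsortiumParams
    loss: float
    free_names: tuple[str, ...]
    estimates: dict[str, float]
    per_start_losses: tuple[float, ...]
    fixed_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    seed: int
    n_starts: int
    intervals: dict[str, tuple[float, float]] | None = None

    def save(self, base) -> None:
        """Write ``<base>.yaml`` (parameters) and ``<base>.json`` (diagnostics)."""
        base = str(base)
        with open(base + ".yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(params_to_dict(self.params), fh, sort_keys=True)
        diag = {
            "loss": self.loss,
            "free_names": list(self.free_names),
            "estimates": self.estimates,
            "per_start_losses": list(self.per_start_losses),
            "fixed_names": list(self.fixed_names),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "n_starts": self.n_starts,
            "intervals": ({k: list(v) for k, v in self.intervals.items()}
                          if self.intervals else None),
        }
        with open(base + ".json", "w", encoding="utf-8") as fh:
            json.dump(diag, fh, indent=2)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

#: Solver settings used inside the objective — looser than presentation
#: runs, for speed; the final reported fit is re-evaluated at the same
#: settings so losses are comparable.
_FIT_CONFIG = dict(rel_tol=1e-6, abs_tol=1e-8)


def _condition_params(params: ConsortiumParams, cond: Condition) -> ConsortiumParams:
    if cond.circuit_mode == params.circuit.mode:
        return params
    circ = dataclasses.replace(params.circuit, mode=cond.circuit_mode)
    return params.with_circuit(circ)


def residual_vector(params: ConsortiumParams, obs: ObservationSet,
                    weights: Mapping[str, float] | None = None) -> np.ndarray:
    """Stacked scaled residuals (simulated − observed)/scale.

    Missing observations are skipped.  An integration failure yields a
    constant penalty residual per data point, keeping optimizers away
    from infeasible parameter regions without raising.
    """
    out: list[np.ndarray] = []
    for cid, grp in obs.data.groupby("condition_id", sort=True):
        cond = obs.conditions[cid]
        times = np.unique(grp["time_h"].to_numpy(float))
        t_end = max(times[-1], 1e-6)
        cfg = SimulationConfig(t_end=t_end, output_times=times, **_FIT_CONFIG)
        try:
            tc = simulate(_condition_params(params, cond), cond.init, cfg)
        except IntegrationError:
            n = int(grp["value"].notna().sum())
            out.append(np.full(n, _FAIL_RESIDUAL))
            continue
        for channel, sub in grp.groupby("channel", sort=True):
            vals = sub["value"].to_numpy(float)
            mask = np.isfinite(vals)
            if not mask.any():
                continue
            sim = _channel_values(tc, channel, sub["time_h"].to_numpy(float)[mask])
            scale = obs.channel_scale(channel)
            w = (weights or {}).get(channel, 1.0)
            r = (np.nan_to_num(sim, nan=0.0) - vals[mask]) / scale
            out.append(np.sqrt(w) * r)
    if not out:
        warnings.warn("all observations missing; loss is 0", stacklevel=2)
        return np.zeros(0)
    return np.concatenate(out)


def loss(params: ConsortiumParams, obs: ObservationSet,
         weights: Mapping[str, float] | None = None) -> float:
    """Channel-weighted sum of squared scaled residuals.

    Returns ``inf`` when every condition fails to integrate."""
    r = residual_vector(params, obs, weights)
    val = float(np.sum(r ** 2))
    if len(r) and np.all(r == _FAIL_RESIDUAL):
        return float("inf")
    return val


# ---------------------------------------------------------------------------
# Multi-start fitting
# ---------------------------------------------------------------------------

#: Size of the Latin-hypercube start pool; taking the first ``n_starts``
#: points of one seeded pool makes start sets nested in ``n_starts``.
_LHS_POOL = 256


def _start_points(bounds: Sequence[tuple[float, float]], n: int,
                  seed: int) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(_LHS_POOL)[:n]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + unit * (hi - lo)


def fit(
    obs: ObservationSet,
    bounds: Mapping[str, tuple[float, float]],
    base_params: ConsortiumParams | None = None,
    fixed_mask: Iterable[str] = (),
    n_starts: int = 20,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
) -> FitResult:
    """Multi-start bounded least squares over named flat parameters.

    ``bounds`` maps flat parameter keys (``producer.mu_max_primary``,
    ...) to finite ``(lo, hi)`` boxes; names listed in ``fixed_mask`` are
    held at their ``base_params`` values (so a fully masked fit evaluates
    a hand-parameterized model).  The first start is the ``base_params``
    point (clipped into the box); the remaining ``n_starts - 1`` are the
    leading points of a seeded Latin-hypercube pool over the free box,
    which makes start sets nested in ``n_starts``.  Deterministic for
    fixed ``(obs, bounds, seed)``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if n_starts > _LHS_POOL:
        raise ValueError(f"n_starts must be <= {_LHS_POOL}")
    base = base_params if base_params is not None else (
        obs.truth if obs.truth is not None else None)
    if base is None:
        raise ValueError("base_params required when the observation set "
                         "carries no generating parameters")
    base_flat = params_to_dict(base)

    fixed = tuple(sorted(set(fixed_mask)))
    free = tuple(sorted(k for k in bounds if k not in fixed))
    for name in free:
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
        if name not in base_flat:
            raise ValueError(f"unknown parameter {name!r}")

    def build(x: np.ndarray) -> ConsortiumParams:
        flat = dict(base_flat)
        for name, v in zip(free, x):
            flat[name] = float(v)
        return params_from_dict(flat)

    def resid(x: np.ndarray) -> np.ndarray:
        try:
            return residual_vector(build(x), obs, weights)
        except ValueError:
            return np.full(max(len(obs.data), 1), _FAIL_RESIDUAL)

    if not free:
        val = loss(base, obs, weights)
        return FitResult(params=base, loss=val, free_names=(), estimates={},
                         per_start_losses=(val,), fixed_names=fixed,
                         bounds=dict(bounds), seed=seed, n_starts=1)

    box = [bounds[name] for name in free]
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    x_base = np.clip([base_flat[name] for name in free], lo, hi)
    starts = np.vstack([x_base, _start_points(box, n_starts - 1, seed)]) \
        if n_starts > 1 else x_base[None, :]

    per_start: list[float] = []
    best_x, best_loss = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi),
                                xtol=1e-8, ftol=1e-8, diff_step=1e-3)
            l = float(np.sum(sol.fun ** 2))
            per_start.append(l)
            if l < best_loss:
                best_loss, best_x = l, sol.x
        except Exception:
            per_start.append(np.inf)
    if best_x is None or not np.isfinite(best_loss):
        raise RuntimeError(
            f"all {n_starts} starts failed; per-start losses: {per_start}")

    params_hat = build(best_x)
    return FitResult(
        params=params_hat,
        loss=best_loss,
        free_names=free,
        estimates={name: float(v) for name, v in zip(free, best_x)},
        per_start_losses=tuple(per_start),
        fixed_names=fixed,
        bounds=dict(bounds),
        seed=seed,
        n_starts=n_starts,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap(
    obs: ObservationSet,
    fit_result: FitResult,
    n_boot: int = 20,
    seed: int = 0,
    level: float = 0.90,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling percentile intervals for the free parameters.

    Residuals are resampled on the *relative* scale — measurement noise
    in fermentation channels is multiplicative, so relative residuals
    (observed/fitted − 1) are the exchangeable quantity — pooled within
    each channel and re-applied multiplicatively to the fitted
    trajectories; fitted values near zero are left unperturbed, as
    multiplicative noise cannot move them.  A channel with fewer than
    five informative (non-zero-fitted) points cannot characterize its
    own residual distribution and draws from the pool of all channels
    instead.  Each replicate is refit from the point estimate (single
    start).  The point estimate is included among the replicate values,
    so intervals always contain it.  Failed refits are dropped and
    counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not fit_result.free_names:
        raise ValueError("fit has no free parameters to bootstrap")
    rng = np.random.default_rng(seed)

    fitted = obs.data.copy()
    sim_vals = np.full(len(fitted), np.nan)
    for cid, grp in fitted.groupby("condition_id", sort=True):
        cond = obs.conditions[cid]
        times = np.unique(grp["time_h"].to_numpy(float))
        cfg = SimulationConfig(t_end=max(times[-1], 1e-6),
                               output_times=times, **_FIT_CONFIG)
        tc = simulate(_condition_params(fit_result.params, cond), cond.init, cfg)
        for channel, sub in grp.groupby("channel", sort=True):
            sim = _channel_values(tc, channel, sub["time_h"].to_numpy(float))
            sim_vals[sub.index.to_numpy()] = sim
    obs_vals = fitted["value"].to_numpy(float)
    channels = fitted["channel"].to_numpy()
    # points where the fit is effectively zero carry no relative residual
    floors = {ch: 1e-3 * obs.channel_scale(ch)
              for ch in np.unique(channels)}
    floor_arr = np.array([floors[ch] for ch in channels])
    informative = np.isfinite(obs_vals) & (sim_vals > floor_arr)
    rel_resid = np.where(informative, obs_vals / np.where(sim_vals > 0,
                                                          sim_vals, 1.0) - 1.0,
                         np.nan)

    global_pool = rel_resid[informative]
    if len(global_pool) == 0:
        raise RuntimeError("no informative observations to resample")

    draws: dict[str, list[float]] = {n: [fit_result.estimates[n]]
                                     for n in fit_result.free_names}
    n_ok = 0
    for _ in range(n_boot):
        new_vals = sim_vals.copy()
        for channel in np.unique(channels):
            idx = np.flatnonzero((channels == channel) & informative)
            if len(idx) == 0:
                continue
            pool = rel_resid[idx] if len(idx) >= 5 else global_pool
            new_vals[idx] = sim_vals[idx] * (
                1.0 + rng.choice(pool, size=len(idx)))
        rep = obs.data.copy()
        rep["value"] = np.clip(new_vals, 0.0, None)
        rep_obs = dataclasses.replace(obs, data=rep)
        base_flat = params_to_dict(fit_result.params)
        free = fit_result.free_names
        box = [fit_result.bounds[n] for n in free]

        def build(x):
            flat = dict(base_flat)
            for n, v in zip(free, x):
                flat[n] = float(v)
            return params_from_dict(flat)

        x0 = np.array([fit_result.estimates[n] for n in free])
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        try:
            sol = least_squares(
                lambda x: residual_vector(build(x), rep_obs),
                np.clip(x0, lo, hi), bounds=(lo, hi),
                xtol=1e-8, ftol=1e-8, diff_step=1e-3)
        except Exception:
            continue
        n_ok += 1
        for n, v in zip(free, sol.x):
            draws[n].append(float(v))
    if n_ok == 0:
        raise RuntimeError(f"all {n_boot} bootstrap refits failed")

    alpha = (1.0 - level) / 2.0
    intervals = {}
    for n, vals in draws.items():
        lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
        est = fit_result.estimates[n]
        intervals[n] = (float(min(lo, est)), float(max(hi, est)))
    intervals["_n_success"] = (float(n_ok), float(n_boot))  # type: ignore
    return intervals
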