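"""Synthetic observation sets with the statistical structure of real assays.

Emulates the measurement layer of a batch co-culture study: 6-hourly
sampling of OD600 and metabolite concentrations over 0–48 h with
multiplicative lognormal noise and additive detection floors, a linear
carbazole standard curve for alginate (calibrated over 0–2 g/L), and
flow-cytometry population-ratio estimation from ≥100,000 gated cell
counts with a linear ratio calibration and a small gate-misclassification
rate.  Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibration import CHANNELS, Condition, ObservationSet, _condition_params
from .model_core import ConsortiumParams, CultureState
from .simulator import DEFAULT_INIT, SimulationConfig, TimeCourse, simulate

__all__ = [
    "NoiseModel",
    "StandardCurve",
    "CytometryCalib",
    "sample_timecourse",
    "carbazole_readout",
    "invert_absorbance",
    "cytometry_counts",
    "estimate_ratio",
    "four_dose_design",
    "make_study",
    "DEFAULT_SAMPLE_TIMES",
]

#: Default sampling grid: every 6 h over a 48-h fermentation (9 points).
DEFAULT_SAMPLE_TIMES = tuple(float(t) for t in range(0, 49, 6))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for sampled time courses.

    ``od_cv`` applies multiplicatively to OD (and, clipped to [0, 1], to
    the population ratio); ``conc_cv`` to the concentration channels
    (alginate, acetate, 3-HP).  ``floor_sd`` adds per-channel Gaussian
    noise on the measurement's own scale, emulating detection limits.
    Defaults reflect typical triplicate flask-culture scatter (~5 % CV).
    """

    od_cv: float = 0.05
    conc_cv: float = 0.05
    floor_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.od_cv <= 0.5 and 0.0 <= self.conc_cv <= 0.5):
            raise ValueError("noise CVs must lie in [0, 0.5]")
        for k, v in self.floor_sd.items():
            if k not in CHANNELS:
                raise ValueError(f"unknown channel {k!r}")
            if v < 0:
                raise ValueError("floor_sd values must be >= 0")

    def cv_for(self, channel: str) -> float:
        return self.od_cv if channel in ("OD", "ratio_E") else self.conc_cv


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance standard curve: abs = slope·conc + intercept."""

    slope: float = 0.45
    intercept: float = 0.02
    residual_sd: float = 0.005
    conc_range: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.conc_range[0] < 0 or self.conc_range[1] <= self.conc_range[0]:
            raise ValueError("conc_range must be a non-empty [lo, hi] with lo >= 0")


@dataclass(frozen=True)
class CytometryCalib:
    """Linear mapping from true to observed population ratio, plus gating error.

    ``slope``/``intercept`` describe the instrument's standard curve
    (identity by default); ``epsilon`` is the probability that a cell is
    counted in the wrong fluorescence gate.
    """

    slope: float = 1.0
    intercept: float = 0.0
    epsilon: float = 0.005

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0.0 <= self.epsilon <= 0.05:
            raise ValueError("epsilon must lie in [0, 0.05]")
        for r in (0.0, 1.0):
            m = self.slope * r + self.intercept
            if not 0.0 <= m <= 1.0:
                raise ValueError("calibrated ratio must stay within [0, 1]")


# ---------------------------------------------------------------------------
# Time-course sampling
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    # mean-one lognormal so the noise is unbiased on the original scale
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def sample_timecourse(
    tc: TimeCourse,
    sample_times: Sequence[float],
    noise: NoiseModel,
    condition: Condition | None = None,
) -> ObservationSet:
    """Noisy sampled measurements of a simulated trajectory.

    Each channel value is multiplied by a mean-one lognormal factor with
    the channel's CV, then perturbed by the additive floor and truncated
    at zero (the ratio channel is clipped to [0, 1]).  Seeded and
    reproducible through ``noise.seed``.
    """
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("sample_times must be a non-empty 1-d sequence")
    if np.any(times < tc.times[0] - 1e-9) or np.any(times > tc.times[-1] + 1e-9):
        raise ValueError("sample_times must lie within the simulated span")

    if condition is None:
        condition = Condition("c0", CultureState.from_array(tc.states[0]))
    rng = np.random.default_rng(noise.seed)

    idx = np.searchsorted(tc.times, times)
    rows = []
    for channel in CHANNELS:
        if channel == "OD":
            true = tc.od_total[idx]
        elif channel == "ratio_E":
            true = tc.ratio_e[idx]
        else:
            key = {"S_gL": "s", "A_gL": "a", "P_mgL": "p"}[channel]
            true = tc.channel(key)[idx]
        vals = true * _lognormal_factor(rng, noise.cv_for(channel), len(times))
        sd = noise.floor_sd.get(channel, 0.0)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=len(times))
        vals = np.clip(vals, 0.0, 1.0 if channel == "ratio_E" else None)
        for t, v in zip(times, vals):
            rows.append((condition.condition_id, channel, float(t), float(v)))

    data = pd.DataFrame(rows, columns=["condition_id", "channel",
                                       "time_h", "value"])
    scales = {ch: noise.cv_for(ch) *
              max(float(np.nanmax(data.loc[data.channel == ch, "value"])), 1e-9)
              for ch in CHANNELS}
    return ObservationSet(data=data,
                          conditions={condition.condition_id: condition},
                          noise_scales=scales, provenance="synthetic")


# ---------------------------------------------------------------------------
# Carbazole alginate assay
# ---------------------------------------------------------------------------


class InvertedConc(NamedTuple):
    """Back-calculated concentration and a dilution flag."""

    conc_gL: float
    out_of_range: bool


def carbazole_readout(conc_gL: float, curve: StandardCurve = StandardCurve(),
                      seed: int = 0) -> float:
    """Simulated 530-nm absorbance of an alginate sample."""
    if conc_gL < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    return float(curve.slope * conc_gL + curve.intercept
                 + rng.normal(0.0, curve.residual_sd))


def invert_absorbance(absorbance: float,
                      curve: StandardCurve = StandardCurve()) -> InvertedConc:
    """Back-calculate concentration; flag estimates beyond the calibrated range.

    A flagged value signals that the sample should be diluted and
    re-measured, as the linear curve is only validated on ``conc_range``.
    """
    conc = max((absorbance - curve.intercept) / curve.slope, 0.0)
    return InvertedConc(conc, conc > curve.conc_range[1] + 1e-12)


# ---------------------------------------------------------------------------
# Flow-cytometry ratio estimation
# ---------------------------------------------------------------------------


def cytometry_counts(true_ratio_e: float, n_cells: int,
                     calib: CytometryCalib = CytometryCalib(),
                     seed: int = 0) -> tuple[int, int]:
    """Gated cell counts (consumer-gate, producer-gate) for one sample.

    The expected consumer-gate probability is the calibration-mapped
    true ratio perturbed by symmetric gate misclassification; the counts
    are one binomial draw over ``n_cells`` total cells.
    """
    if not 0.0 <= true_ratio_e <= 1.0:
        raise ValueError("true_ratio_e must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells < 10_000:
        warnings.warn(f"n_cells={n_cells} below the 10^4 counting floor; "
                      "ratio estimates will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    mapped = np.clip(calib.slope * true_ratio_e + calib.intercept, 0.0, 1.0)
    p_eff = mapped * (1 - calib.epsilon) + (1 - mapped) * calib.epsilon
    gfp = int(rng.binomial(n_cells, p_eff))
    return gfp, n_cells - gfp


def estimate_ratio(counts: tuple[int, int],
                   calib: CytometryCalib = CytometryCalib()) -> float:
    """Invert gated counts back to an estimated consumer fraction.

    Undoes the misclassification mixing and the linear calibration, then
    clips to [0, 1].
    """
    gfp, mch = counts
    total = gfp + mch
    if total < 1:
        raise ValueError("counts must contain at least one cell")
    raw = gfp / total
    if calib.epsilon < 0.5:
        raw = (raw - calib.epsilon) / (1.0 - 2.0 * calib.epsilon)
    return float(np.clip((raw - calib.intercept) / calib.slope, 0.0, 1.0))


# ---------------------------------------------------------------------------
# One-call study generator
# ---------------------------------------------------------------------------


def four_dose_design(amp_levels: Sequence[float] = (0.0, 5.0, 10.0, 20.0),
                     init: CultureState = DEFAULT_INIT,
                     circuit_mode: str = "guider") -> list[Condition]:
    """The standard dose-series design: one condition per ampicillin level."""
    return [Condition(f"amp{level:g}", replace(init, c=float(level)),
                      circuit_mode)
            for level in amp_levels]


def make_study(
    params: ConsortiumParams,
    design: Sequence[Condition],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    config: SimulationConfig | None = None,
) -> ObservationSet:
    """Simulate and sample every condition of a study design.

    Returns one tidy :class:`ObservationSet` carrying the generating
    parameters (``truth``) so the set can drive parameter-recovery
    experiments.  Per-condition noise streams are split from ``seed``.
    """
    if len(design) == 0:
        raise ValueError("design must contain at least one condition")
    if config is None:
        config = SimulationConfig(t_end=max(sample_times),
                                  output_times=np.unique(sample_times))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(design))
    frames, conditions, scales = [], {}, {}
    for cond, s in zip(design, child_seeds):
        tc = simulate(_condition_params(params, cond), cond.init, config)
        sub = sample_timecourse(
            tc, sample_times, replace(noise, seed=int(s % (2 ** 31 - 1))),
            condition=cond)
        frames.append(sub.data)
        conditions[cond.condition_id] = cond
        for ch, sc in sub.noise_scales.items():
            scales[ch] = max(scales.get(ch, 0.0), sc)
    data = pd.concat(frames, ignore_index=True)
    return ObservationSet(data=data, conditions=conditions,
                          noise_scales=scales, provenance="synthetic",
                          truth=params)
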