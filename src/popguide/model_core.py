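"""Core state, parameters and vector field of the consortium model.

The model describes a two-member batch co-culture converting alginate to
3-hydroxypropionic acid (3-HP):

* a **producer** strain (an alginate-assimilating *Vibrio*) grows on
  alginate ``S`` and secretes acetate ``A`` as overflow;
* a **consumer** strain (an engineered *E. coli*) grows on that acetate and
  couples growth to 3-HP ``P`` formation;
* ampicillin ``C`` inhibits both strains in proportion to their growth
  rate; a plasmid-borne circuit in the consumer expresses β-lactamase —
  either constitutively or under 3-HP induction (the "population guider") —
  and detoxifies the shared medium.

Growth follows Monod kinetics; induction follows a Hill law; ampicillin
removal is first-order in ampicillin and proportional to consumer biomass
and β-lactamase activity.  Biomass is carried in OD600-equivalent units
throughout, so yields are OD units per g/L of substrate consumed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "CultureState",
    "StrainParams",
    "ProductionParams",
    "CircuitSpec",
    "ConsortiumParams",
    "monod",
    "bla_activity",
    "kill_rate",
    "rhs",
    "default_params",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

#: State-vector component order used everywhere arrays appear.
STATE_FIELDS = ("x_v", "x_e", "s", "a", "p", "c")

CIRCUIT_MODES = ("none", "constitutive", "guider")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CultureState:
    """Instantaneous state of the batch culture.

    Attributes
    ----------
    x_v : float
        Producer-strain biomass (OD600-equivalent units).
    x_e : float
        Consumer-strain biomass (OD600-equivalent units).
    s : float
        Alginate concentration (g/L).
    a : float
        Acetate concentration (g/L).
    p : float
        3-HP concentration (mg/L).
    c : float
        Ampicillin concentration (µg/mL).
    """

    x_v: float = 0.0
    x_e: float = 0.0
    s: float = 0.0
    a: float = 0.0
    p: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            v = getattr(self, name)
            _require(math.isfinite(v), f"{name} must be finite, got {v!r}")
            _require(v >= 0.0, f"{name} must be non-negative, got {v!r}")

    @property
    def od_total(self) -> float:
        """Total biomass, the quantity an OD600 reading reports."""
        return self.x_v + self.x_e

    @property
    def ratio_e(self) -> float:
        """Consumer fraction of total biomass; NaN for an empty culture."""
        od = self.od_total
        return self.x_e / od if od > 0.0 else math.nan

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "CultureState":
        vals = [max(float(v), 0.0) for v in arr]
        return cls(*vals)


@dataclass(frozen=True)
class StrainParams:
    """Growth, yield, secretion and antibiotic-susceptibility constants.

    ``mu_max_primary`` / ``k_primary`` parameterize Monod growth on the
    strain's primary substrate (alginate for the producer, acetate for the
    consumer).  ``phi_a`` is the overflow stoichiometry: grams of acetate
    secreted per gram of alginate consumed (producer only).  The producer
    may additionally re-assimilate acetate (``mu_max_ac``/``k_ac``) once
    alginate runs low; the diauxic gate is ``k_rep/(k_rep + S)``.

    The ampicillin kill term is ``alpha_kill * mu * C/(k_kill + C)`` —
    proportional to the instantaneous growth rate, as β-lactams act on
    growing cells.  Set ``growth_linked_kill=False`` for a growth-rate
    independent form ``alpha_kill * mu_max_primary * C/(k_kill + C)``.
    """

    mu_max_primary: float
    k_primary: float
    y_x: float
    phi_a: float = 0.0
    mu_max_ac: float = 0.0
    k_ac: float = 1.0
    k_rep: float = 0.5
    alpha_kill: float = 0.0
    k_kill: float = 1.0
    growth_linked_kill: bool = True

    def __post_init__(self) -> None:
        for name in ("mu_max_primary", "k_primary", "y_x", "phi_a",
                     "mu_max_ac", "k_ac", "k_rep", "alpha_kill", "k_kill"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0.0,
                     f"{name} must be finite and >= 0, got {v!r}")
        _require(self.y_x > 0.0, "y_x must be > 0")
        _require(self.k_primary > 0.0, "k_primary must be > 0")
        _require(0.0 <= self.phi_a <= 1.2, "phi_a must lie in [0, 1.2]")


@dataclass(frozen=True)
class ProductionParams:
    """Product-formation and product-loss constants.

    ``y_pa`` is the 3-HP yield on acetate consumed by the consumer
    (mg product per g acetate).  ``k_pdeg`` is a second-order loss rate
    (L/(OD·h)) for 3-HP consumption by either strain after the alginate is
    gone; it is gated by ``s_gate/(s_gate + S)`` so the loss only opens as
    the primary substrate depletes.  ``k_pdeg = 0`` disables the term.
    """

    y_pa: float
    k_pdeg: float = 0.0
    s_gate: float = 0.5

    def __post_init__(self) -> None:
        _require(self.y_pa >= 0.0, "y_pa must be >= 0")
        _require(self.k_pdeg >= 0.0, "k_pdeg must be >= 0")
        _require(self.s_gate > 0.0, "s_gate must be > 0")


@dataclass(frozen=True)
class CircuitSpec:
    """β-lactamase expression law carried by the consumer strain.

    mode
        ``"none"`` — no *bla* gene, activity ≡ 0 (commensal baseline);
        ``"constitutive"`` — static expression, activity ≡ ``beta_0``;
        ``"guider"`` — 3-HP-inducible Hill activation between ``beta_0``
        (basal leak) and ``beta_1`` (full induction) with half-induction
        ``k_p`` (mg/L) and Hill coefficient ``n_hill``.

    ``k_cat`` converts activity × consumer biomass into a first-order
    ampicillin removal rate: dC/dt = -k_cat · activity · X_E · C, in
    1/h per AU per OD unit.
    """

    mode: str = "none"
    beta_0: float = 0.0
    beta_1: float = 0.0
    k_p: float = 1.0
    n_hill: float = 2.0
    k_cat: float = 0.0

    def __post_init__(self) -> None:
        _require(self.mode in CIRCUIT_MODES,
                 f"mode must be one of {CIRCUIT_MODES}, got {self.mode!r}")
        _require(self.beta_0 >= 0.0, "beta_0 must be >= 0")
        _require(self.beta_1 >= self.beta_0 or self.mode != "guider",
                 "beta_1 must be >= beta_0 for the guider mode")
        _require(self.k_p > 0.0, "k_p must be > 0")
        _require(self.n_hill >= 1.0, "n_hill must be >= 1")
        _require(self.k_cat >= 0.0, "k_cat must be >= 0")


@dataclass(frozen=True)
class ConsortiumParams:
    """Full parameter set: producer, consumer, production and circuit."""

    producer: StrainParams
    consumer: StrainParams
    production: ProductionParams
    circuit: CircuitSpec = field(default_factory=CircuitSpec)

    def __post_init__(self) -> None:
        _require(self.consumer.phi_a == 0.0,
                 "consumer.phi_a must be 0 (the consumer secretes no acetate)")
        _require(self.consumer.mu_max_ac == 0.0,
                 "consumer.mu_max_ac must be 0 (acetate is already its "
                 "primary substrate)")

    def replace(self, **sections) -> "ConsortiumParams":
        """Return a copy with whole sections swapped out."""
        return dataclasses.replace(self, **sections)

    def with_circuit(self, circuit: CircuitSpec) -> "ConsortiumParams":
        return dataclasses.replace(self, circuit=circuit)


# ---------------------------------------------------------------------------
# Kinetic laws
# ---------------------------------------------------------------------------


def monod(s: float, mu_max: float, k: float) -> float:
    """Monod saturation kinetics ``mu_max * s / (k + s)``.

    Parameters are the substrate concentration, the maximal specific
    growth rate (1/h) and the half-saturation constant (same units as
    ``s``).  Monotone non-decreasing in ``s`` and bounded by ``mu_max``.
    """
    _require(s >= 0.0, f"substrate concentration must be >= 0, got {s!r}")
    _require(mu_max >= 0.0, "mu_max must be >= 0")
    _require(k > 0.0, "half-saturation constant must be > 0")
    return mu_max * s / (k + s)


def bla_activity(p: float, circuit: CircuitSpec) -> float:
    """β-lactamase activity (AU) at 3-HP concentration ``p`` (mg/L).

    ``none`` → 0; ``constitutive`` → ``beta_0``; ``guider`` → Hill
    activation ``beta_0 + (beta_1 - beta_0) * p**n / (k_p**n + p**n)``.
    Continuous and non-decreasing in ``p``.
    """
    _require(p >= 0.0, f"3-HP concentration must be >= 0, got {p!r}")
    if circuit.mode == "none":
        return 0.0
    if circuit.mode == "constitutive":
        return circuit.beta_0
    pn = (p / circuit.k_p) ** circuit.n_hill
    return circuit.beta_0 + (circuit.beta_1 - circuit.beta_0) * pn / (1.0 + pn)


def kill_rate(c: float, mu: float, sp: StrainParams) -> float:
    """Ampicillin-induced death rate (1/h) at concentration ``c`` (µg/mL).

    Growth-linked form (default): ``alpha_kill * mu * c/(k_kill + c)`` —
    zero for non-growing cells, saturating in ``c``.  With
    ``growth_linked_kill=False`` the strain's ``mu_max_primary`` replaces
    the instantaneous rate ``mu``.
    """
    _require(c >= 0.0, f"ampicillin concentration must be >= 0, got {c!r}")
    _require(mu >= 0.0, f"growth rate must be >= 0, got {mu!r}")
    base = mu if sp.growth_linked_kill else sp.mu_max_primary
    return sp.alpha_kill * base * c / (sp.k_kill + c)


def rhs(state, params: ConsortiumParams) -> np.ndarray:
    """Time derivatives of the six-component culture state.

    ``state`` may be a :class:`CultureState` or an array in
    :data:`STATE_FIELDS` order.  Negative excursions handed in by an
    adaptive solver are treated as zero, so no component's outflow can
    drive it below zero.
    """
    if isinstance(state, CultureState):
        arr = state.as_array()
    else:
        arr = np.asarray(state, dtype=float)
        _require(arr.shape == (6,), "state must have six components")
        _require(bool(np.all(np.isfinite(arr))), "state must be finite")
    x_v, x_e, s, a, p, c = np.maximum(arr, 0.0)

    prod = params.producer
    cons = params.consumer
    prn = params.production

    # diauxic gate: opens (→1) as alginate depletes
    g_s = prod.k_rep / (prod.k_rep + s)
    g_deg = prn.s_gate / (prn.s_gate + s)

    mu_s = monod(s, prod.mu_max_primary, prod.k_primary)
    mu_reuse = g_s * monod(a, prod.mu_max_ac, prod.k_ac)
    mu_v = mu_s + mu_reuse
    mu_e = monod(a, cons.mu_max_primary, cons.k_primary)

    q_s = mu_s * x_v / prod.y_x                 # alginate uptake, g/(L·h)
    q_a_cons = mu_e * x_e / cons.y_x            # consumer acetate uptake
    q_a_reuse = mu_reuse * x_v / prod.y_x       # producer acetate re-uptake

    d_xv = (mu_v - kill_rate(c, mu_v, prod)) * x_v
    d_xe = (mu_e - kill_rate(c, mu_e, cons)) * x_e
    d_s = -q_s
    d_a = prod.phi_a * q_s - q_a_cons - q_a_reuse
    d_p = prn.y_pa * q_a_cons - prn.k_pdeg * g_deg * (x_v + x_e) * p
    d_c = -params.circuit.k_cat * bla_activity(p, params.circuit) * x_e * c

    return np.array([d_xv, d_xe, d_s, d_a, d_p, d_c])


# ---------------------------------------------------------------------------
# Shipped default parameter set
# ---------------------------------------------------------------------------

# Maximum specific growth rates 0.83 1/h (producer on alginate) and
# 0.16 1/h (consumer on acetate) are measured monoculture values; the
# product yield 27.282 mg 3-HP per g acetate reproduces the consumer
# monoculture batch outcome (272.82 mg/L from 10 g/L acetate).  All other
# constants were calibrated against the 48-h co-culture endpoints of the
# ampicillin dose series (titres 68.35/125.40/293.55/199.40 mg/L and
# consumer fractions 18.50/29.15/40.4 % at 0/5/10/20 µg/mL); see
# scripts/calibrate_defaults.py for the procedure.
_DEFAULTS: dict[str, float | str | bool] = {
    "producer.mu_max_primary": 0.83,
    "producer.k_primary": 1.2,
    "producer.y_x": 0.5444,
    "producer.phi_a": 0.4769,
    "producer.mu_max_ac": 0.2787,
    "producer.k_ac": 1.0,
    "producer.k_rep": 0.50,
    "producer.alpha_kill": 4.5,
    "producer.k_kill": 25.0,
    "producer.growth_linked_kill": True,
    "consumer.mu_max_primary": 0.16,
    "consumer.k_primary": 0.30,
    "consumer.y_x": 0.271,
    "consumer.phi_a": 0.0,
    "consumer.mu_max_ac": 0.0,
    "consumer.k_ac": 1.0,
    "consumer.k_rep": 0.5,
    "consumer.alpha_kill": 2.0,
    "consumer.k_kill": 6.0,
    "consumer.growth_linked_kill": True,
    "production.y_pa": 27.282,
    "production.k_pdeg": 0.0013,
    "production.s_gate": 0.50,
    "circuit.mode": "guider",
    "circuit.beta_0": 0.02,
    "circuit.beta_1": 0.30,
    "circuit.k_p": 50.0,
    "circuit.n_hill": 2.0,
    "circuit.k_cat": 0.08,
}


def params_from_dict(flat: Mapping[str, object]) -> ConsortiumParams:
    """Build :class:`ConsortiumParams` from flat ``section.key`` mapping."""
    sections: dict[str, dict[str, object]] = {
        "producer": {}, "consumer": {}, "production": {}, "circuit": {}}
    for key, value in flat.items():
        section, _, name = key.partition(".")
        if section not in sections or not name:
            raise ValueError(f"unrecognized parameter key {key!r}")
        sections[section][name] = value
    return ConsortiumParams(
        producer=StrainParams(**sections["producer"]),
        consumer=StrainParams(**sections["consumer"]),
        production=ProductionParams(**sections["production"]),
        circuit=CircuitSpec(**sections["circuit"]),
    )


def params_to_dict(params: ConsortiumParams) -> dict[str, object]:
    """Flatten :class:`ConsortiumParams` to ``section.key`` mapping."""
    flat: dict[str, object] = {}
    for section in ("producer", "consumer", "production", "circuit"):
        obj = getattr(params, section)
        for f in dataclasses.fields(obj):
            flat[f"{section}.{f.name}"] = getattr(obj, f.name)
    return flat


def default_params(circuit_mode: str = "guider") -> ConsortiumParams:
    """Shipped calibrated defaults; ``circuit_mode`` selects the circuit.

    ``"none"`` gives the commensal baseline (no *bla*), ``"constitutive"``
    static expression at the guider's fully induced level, ``"guider"``
    the 3-HP-inducible circuit.
    """
    flat = dict(_DEFAULTS)
    flat["circuit.mode"] = circuit_mode
    if circuit_mode == "none":
        flat["circuit.beta_0"] = 0.0
        flat["circuit.beta_1"] = 0.0
    elif circuit_mode == "constitutive":
        flat["circuit.beta_0"] = flat["circuit.beta_1"]
    return params_from_dict(flat)


def save_params(params: ConsortiumParams, path) -> None:
    """Write parameters as a flat key-value YAML file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)


def load_params(path) -> ConsortiumParams:
    """Read parameters from a flat key-value YAML file."""
    with open(path, encoding="utf-8") as fh:
        flat = yaml.safe_load(fh)
    if not isinstance(flat, Mapping):
        raise ValueError(f"{path}: expected a mapping of parameter keys")
    return params_from_dict(flat)
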