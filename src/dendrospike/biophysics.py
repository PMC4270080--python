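"""Membrane biophysics: passive properties, spine correction, channel kinetics,
and distance-dependent conductance-density rules.

The model carries four active conductances — a fast Na+ conductance (G_Na), a
delayed-rectifier K+ conductance (G_Kdr), an A-type K+ conductance (G_KA), and
a hyperpolarization-activated cation conductance (G_h) — on top of a passive
membrane (Rm = 40,000 Ω·cm², Cm = 0.75 µF/cm², Ri = 150 Ω·cm).  Dendritic
spines are not modelled explicitly; instead Cm of dendritic compartments is
multiplied by a spine scale factor and Rm divided by the same factor, which
leaves the membrane time constant τ_m = Rm·Cm = 30 ms unchanged everywhere.

Density distributions along the somato-dendritic axis:

* G_Na (0.022 S/cm²) and G_Kdr (0.035 S/cm²): uniform in both cell classes.
* G_KA: 0.035 S/cm² at the soma, rising linearly sixfold with path distance.
* G_h: sevenfold linear increase in the CA1 class; uniform in the CA2 class
  (its somatic density is an open parameter calibrated against voltage sag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "PassiveProperties",
    "SpineCorrectionRule",
    "DensityRule",
    "GateSpec",
    "ChannelSpec",
    "CellBiophysics",
    "corrected_passive",
    "channel_density",
    "gate_dynamics",
    "ionic_current_density",
    "load_kinetics",
    "ca1_biophysics",
    "ca2_biophysics",
]

GATE_KINDS = ("activation", "inactivation", "hyperpolarization_activated")


@dataclass(frozen=True)
class PassiveProperties:
    """Specific passive membrane constants."""

    Rm: float = 40_000.0  # Ω·cm²
    Cm: float = 0.75  # µF/cm²
    Ri: float = 150.0  # Ω·cm
    E_leak: float = -70.0  # mV (overridden by per-compartment leak calibration)

    def __post_init__(self):
        if min(self.Rm, self.Cm, self.Ri) <= 0:
            raise ValueError("Rm, Cm and Ri must all be > 0")


@dataclass(frozen=True)
class SpineCorrectionRule:
    """Spine scale factor as a step function of path distance from the soma.

    Cm is multiplied and Rm divided by ``factor_proximal`` below ``boundary``
    and by ``factor_distal`` at or beyond it; the soma itself is uncorrected.
    """

    boundary: float = 150.0  # µm
    factor_proximal: float = 1.0
    factor_distal: float = 2.0

    def __post_init__(self):
        if self.boundary <= 0:
            raise ValueError("boundary must be > 0")
        if self.factor_proximal < 1 or self.factor_distal < 1:
            raise ValueError("spine scale factors must be >= 1")

    def factor(self, distance: float) -> float:
        return self.factor_proximal if distance < self.boundary else self.factor_distal


def corrected_passive(
    props: PassiveProperties, rule: SpineCorrectionRule, distance: float
) -> tuple[float, float]:
    """Effective (Rm, Cm) at a path distance after spine correction.

    The product Rm_eff · Cm_eff (hence τ_m) is invariant under the factor.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    f = rule.factor(distance)
    return props.Rm / f, props.Cm * f


@dataclass(frozen=True)
class DensityRule:
    """Conductance density (S/cm²) as a function of path distance.

    ``uniform``: density == base everywhere.
    ``linear_fold``: base at the soma, rising linearly to fold × base at
    ``span`` µm and constant beyond (continuous, non-decreasing).
    """

    kind: str = "uniform"  # {"uniform", "linear_fold"}
    base: float = 0.0
    fold: float = 1.0
    span: float = 350.0  # µm

    def __post_init__(self):
        if self.kind not in ("uniform", "linear_fold"):
            raise ValueError(f"unknown density rule kind {self.kind!r}")
        if self.base < 0:
            raise ValueError("base density must be >= 0")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.kind == "linear_fold" and self.span <= 0:
            raise ValueError("span must be > 0 for linear_fold rules")


def channel_density(rule: DensityRule, distance) -> float:
    """Evaluate a density rule at a path distance (scalar or array, µm)."""
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be >= 0")
    if rule.kind == "uniform":
        out = np.full_like(distance, rule.base)
    else:
        out = rule.base * (1.0 + (rule.fold - 1.0) * np.minimum(distance, rule.span) / rule.span)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating variable.

    Steady state is a Boltzmann of voltage; the time constant is a bounded
    sigmoid.  ``kind`` declares the monotone direction of the steady state:
    activation gates rise with V; inactivation and hyperpolarization-activated
    gates fall with V.
    """

    symbol: str
    exponent: int
    kind: str
    vhalf: float
    k: float
    tau_min: float
    tau_amp: float
    tau_vhalf: float
    tau_k: float

    def __post_init__(self):
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.exponent < 0 or int(self.exponent) != self.exponent:
            raise ValueError("gate exponent must be a non-negative integer")
        if self.k <= 0 or self.tau_min <= 0 or self.tau_amp < 0:
            raise ValueError("k and tau_min must be > 0, tau_amp >= 0")

    @property
    def increasing(self) -> bool:
        return self.kind == "activation"

    def steady_state(self, V):
        V = np.asarray(V, dtype=float)
        sign = -1.0 if self.increasing else 1.0
        out = 1.0 / (1.0 + np.exp(sign * (V - self.vhalf) / self.k))
        return float(out) if out.ndim == 0 else out

    def time_constant(self, V):
        V = np.asarray(V, dtype=float)
        out = self.tau_min + self.tau_amp / (1.0 + np.exp((V - self.tau_vhalf) / self.tau_k))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance: its gates, reversal potential, and density rule."""

    name: str
    gates: tuple[GateSpec, ...]
    E_rev: float
    density_rule: DensityRule

    def gate(self, symbol: str) -> GateSpec:
        for g in self.gates:
            if g.symbol == symbol:
                return g
        raise KeyError(f"channel {self.name}: no gate {symbol!r}")


def gate_dynamics(spec: ChannelSpec, gate: str, V: float) -> tuple[float, float]:
    """(steady_state, time_constant in ms) of one gate at voltage V (mV)."""
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    g = spec.gate(gate)
    return g.steady_state(V), g.time_constant(V)


def ionic_current_density(
    spec: ChannelSpec, state: dict[str, float], V: float, density: float
) -> float:
    """Ohmic channel current density i = ḡ·∏gateᵉ·(V − E_rev), in mA/cm².

    ``density`` in S/cm² and voltages in mV give mA/cm² directly.  Outward
    current is positive.  A zeroed density (e.g. a TTX mask) or any fully
    closed gate gives zero current.
    """
    open_frac = 1.0
    for g in spec.gates:
        x = state[g.symbol]
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gate {g.symbol} state {x} outside [0, 1]")
        open_frac *= x ** g.exponent
    return density * open_frac * (V - spec.E_rev)


def load_kinetics(path=None) -> dict[str, dict]:
    """Load the channel-kinetics parameter file (default: packaged YAML)."""
    if path is None:
        src = resources.files("dendrospike").joinpath("data/kinetics_default.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return raw["channels"]


def _build_channel(name: str, kin: dict, rule: DensityRule, e_rev=None) -> ChannelSpec:
    gates = tuple(
        GateSpec(
            symbol=sym,
            exponent=int(g["exponent"]),
            kind=g["kind"],
            vhalf=float(g["vhalf"]),
            k=float(g["k"]),
            tau_min=float(g["tau_min"]),
            tau_amp=float(g["tau_amp"]),
            tau_vhalf=float(g["tau_vhalf"]),
            tau_k=float(g["tau_k"]),
        )
        for sym, g in kin["gates"].items()
    )
    return ChannelSpec(
        name=name,
        gates=gates,
        E_rev=float(kin["e_rev"]) if e_rev is None else e_rev,
        density_rule=rule,
    )


# printed conductance densities (S/cm²)
GNA_DEFAULT = 0.022
GKDR_DEFAULT = 0.035
GKA_SOMA_DEFAULT = 0.035
# somatic G_h is not printed; calibrated so the CA1 class shows a visibly
# larger somatic sag than the CA2 class under identical hyperpolarizing steps
GH_SOMA_DEFAULT = 5e-4
DENSITY_SPAN_DEFAULT = 350.0  # µm ramp for linear_fold rules


@dataclass(frozen=True)
class CellBiophysics:
    """Complete biophysical description of one cell class."""

    cell_class: str
    passive: PassiveProperties
    spine_rule: SpineCorrectionRule
    channels: tuple[ChannelSpec, ...]

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel {name!r}")


def _common_channels(kin, gh_rule: DensityRule, gna: float, span: float):
    return (
        _build_channel("Na", kin["Na"], DensityRule(kind="uniform", base=gna)),
        _build_channel("Kdr", kin["Kdr"], DensityRule(kind="uniform", base=GKDR_DEFAULT)),
        _build_channel(
            "KA",
            kin["KA"],
            DensityRule(kind="linear_fold", base=GKA_SOMA_DEFAULT, fold=6.0, span=span),
        ),
        _build_channel("H", kin["H"], gh_rule),
    )


def ca1_biophysics(
    gna: float = GNA_DEFAULT,
    gh_soma: float = GH_SOMA_DEFAULT,
    span: float = DENSITY_SPAN_DEFAULT,
    kinetics_path=None,
) -> CellBiophysics:
    """CA1-class membrane: spine factor 1/2 around 150 µm, sevenfold G_h ramp."""
    kin = load_kinetics(kinetics_path)
    gh_rule = DensityRule(kind="linear_fold", base=gh_soma, fold=7.0, span=span)
    return CellBiophysics(
        cell_class="ca1",
        passive=PassiveProperties(),
        spine_rule=SpineCorrectionRule(boundary=150.0, factor_proximal=1.0, factor_distal=2.0),
        channels=_common_channels(kin, gh_rule, gna, span),
    )


def ca2_biophysics(
    gna: float = GNA_DEFAULT,
    gh_soma: float = GH_SOMA_DEFAULT,
    span: float = DENSITY_SPAN_DEFAULT,
    kinetics_path=None,
) -> CellBiophysics:
    """CA2-class membrane: spine factors 2/3 around 150 µm, uniform G_h."""
    kin = load_kinetics(kinetics_path)
    gh_rule = DensityRule(kind="uniform", base=gh_soma)
    return CellBiophysics(
        cell_class="ca2",
        passive=PassiveProperties(),
        spine_rule=SpineCorrectionRule(boundary=150.0, factor_proximal=2.0, factor_distal=3.0),
        channels=_common_channels(kin, gh_rule, gna, span),
    )


def passive_only(cell_class: str = "ca2") -> CellBiophysics:
    """Biophysics with all active densities zero (for calibration checks)."""
    full = ca2_biophysics() if cell_class == "ca2" else ca1_biophysics()
    channels = tuple(
        replace(c, density_rule=DensityRule(kind="uniform", base=0.0)) for c in full.channels
    )
    return CellBiophysics(
        cell_class=full.cell_class,
        passive=full.passive,
        spine_rule=full.spine_rule,
        channels=channels,
    )
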