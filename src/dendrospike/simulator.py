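"""Compartmental electrical model: discretization, stimulation, integration.

A :class:`~dendrospike.morphology.Morphology` plus a
:class:`~dendrospike.biophysics.CellBiophysics` is discretized into short
compartments (default ≤ 10 µm).  Channel densities are evaluated from the
distance-dependent density rules at each compartment's path-distance midpoint;
spine correction scales Rm/Cm of dendritic compartments.  The branched cable
equation is integrated with backward Euler and a linear-time tree (Hines)
solve; see :mod:`dendrospike._core`.

Resting potential: all simulations run from −70 mV.  Rather than holding the
cell with a bias current, the leak reversal of every compartment is calibrated
so that its net membrane current vanishes at −70 mV with gates at steady
state, which makes −70 mV an exact fixed point of the full system.

Local TTX application is emulated by zeroing the Na conductance density within
a path-distance radius of a mask centre (:func:`apply_ttx`).
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _core
from .biophysics import CellBiophysics, channel_density, corrected_passive
from .morphology import Morphology, path_distance

__all__ = [
    "Compartment",
    "CompartmentalModel",
    "Synapse",
    "CurrentStimulus",
    "SimulationConfig",
    "TraceSet",
    "SimulationError",
    "discretize",
    "place_synapses",
    "initialize",
    "run",
    "apply_ttx",
]

CHANNEL_ORDER = ("Na", "Kdr", "KA", "H")


class SimulationError(RuntimeError):
    pass


@dataclass
class Compartment:
    """One node of the discretized tree (view onto the model arrays)."""

    index: int
    section: str
    fraction: float  # midpoint fraction along the section
    length: float  # µm
    diameter: float  # µm (mean)
    area: float  # cm²
    path_dist: float  # µm, to soma centre (midpoint)
    parent: int  # -1 for the soma


class CompartmentalModel:
    """Discretized electrical tree with per-compartment densities.

    Attributes are flat numpy arrays indexed by compartment, topologically
    ordered (``parent[i] < i``; compartment 0 is the soma).
    """

    def __init__(self, morph, biophys, parent, section_ids, fracs, lengths, diams,
                 areas, path_dists, g_ax, cm_nF, g_leak_uS, gbar_uS, e_rev):
        self.morphology = morph
        self.biophysics = biophys
        self.parent = parent
        self.section_ids = section_ids
        self.fracs = fracs
        self.lengths = lengths
        self.diams = diams
        self.areas = areas
        self.path_dists = path_dists
        self.g_ax = g_ax  # µS, coupling to parent
        self.cm = cm_nF  # nF
        self.g_leak = g_leak_uS  # µS
        self.gbar = gbar_uS  # (4, N) µS, CHANNEL_ORDER
        self.e_rev = e_rev  # (4,)
        self.e_leak = np.full(self.n, biophys.passive.E_leak)
        self.initialized_at: Optional[float] = None
        self._gates: Optional[np.ndarray] = None  # (6, N) steady states

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def soma_index(self) -> int:
        return 0

    def compartment(self, index: int) -> Compartment:
        return Compartment(
            index=index,
            section=self.section_ids[index],
            fraction=self.fracs[index],
            length=self.lengths[index],
            diameter=self.diams[index],
            area=self.areas[index],
            path_dist=self.path_dists[index],
            parent=int(self.parent[index]),
        )

    def locate(self, location: tuple[str, float]) -> int:
        """Compartment index containing (section id, fraction)."""
        sec_id, frac = location
        idx = [i for i in range(self.n) if self.section_ids[i] == sec_id]
        if not idx:
            raise KeyError(f"unknown section {sec_id!r}")
        best = min(idx, key=lambda i: abs(self.fracs[i] - frac))
        return best

    def tree_distance(self, i: int, j: int) -> float:
        """Path distance (µm) between the midpoints of two compartments.

        Since ``path_dists`` measure arc length from the soma along the tree,
        the distance is d_i + d_j - 2·d_lca for the lowest common ancestor.
        """
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = int(self.parent[a])
        b = j
        while b not in anc:
            b = int(self.parent[b])
        return float(
            self.path_dists[i] + self.path_dists[j] - 2.0 * self.path_dists[b]
        )

    def copy(self) -> "CompartmentalModel":
        new = copy.copy(self)
        new.gbar = self.gbar.copy()
        new.e_leak = self.e_leak.copy()
        if self._gates is not None:
            new._gates = self._gates.copy()
        return new

    def total_area(self) -> float:
        return float(self.areas.sum())


def _gate_param_arrays(biophys: CellBiophysics):
    """(6, 6) gate-constant array in the core's fixed gate order."""
    order = [("Na", "m"), ("Na", "h"), ("Kdr", "n"), ("KA", "a"), ("KA", "b"), ("H", "l")]
    gp = np.zeros((6, 6))
    sign = np.zeros(6)
    for gi, (cname, sym) in enumerate(order):
        g = biophys.channel(cname).gate(sym)
        gp[gi] = [g.vhalf, g.k, g.tau_min, g.tau_amp, g.tau_vhalf, g.tau_k]
        sign[gi] = 1.0 if g.increasing else -1.0
    return gp, sign


def discretize(
    morph: Morphology, biophys: CellBiophysics, max_seg_len: float = 10.0
) -> CompartmentalModel:
    """Spatially discretize a morphology into compartments of ≤ max_seg_len µm.

    The soma becomes a single isopotential compartment.  Each dendritic
    section is split into equal segments; membrane area uses the frustum
    (mean-diameter) rule, which conserves total area under refinement for the
    piecewise-linear tapers produced by the generator.
    """
    if max_seg_len <= 0:
        raise ValueError("max_seg_len must be > 0")
    morph.validate()
    Ri = biophys.passive.Ri

    parent, section_ids, fracs, lengths, diams, areas, dists = [], [], [], [], [], [], []

    soma = morph.sections[morph.root]
    d_soma = float(np.mean([p.diameter for p in soma.points]))
    l_soma = max(soma.length, d_soma)  # point somata: sphere-equivalent cylinder
    parent.append(-1)
    section_ids.append(soma.id)
    fracs.append(0.5)
    lengths.append(l_soma)
    diams.append(d_soma)
    areas.append(math.pi * d_soma * l_soma * 1e-8)  # µm² -> cm²
    dists.append(0.0)

    # (section id -> list of compartment indices, in order along the section)
    sec_comps: dict[str, list[int]] = {soma.id: [0]}

    for sec in morph.ordered_sections():
        if sec.id == morph.root:
            continue
        L = sec.length
        if L <= 0:
            raise SimulationError(f"section {sec.id} has zero length")
        n_seg = max(1, math.ceil(L / max_seg_len))
        seg_len = L / n_seg
        pid, pfrac = sec.parent
        start_dist = path_distance(morph, (sec.id, 0.0))
        comp_ids = []
        for k in range(n_seg):
            f0, f1 = k / n_seg, (k + 1) / n_seg
            d0 = sec.point_at(f0).diameter
            d1 = sec.point_at(f1).diameter
            dm = 0.5 * (d0 + d1)
            if k == 0:
                if pid == morph.root:
                    par = 0
                else:
                    pcomps = sec_comps[pid]
                    par = pcomps[min(int(pfrac * len(pcomps)), len(pcomps) - 1)]
            else:
                par = comp_ids[-1]
            idx = len(parent)
            parent.append(par)
            section_ids.append(sec.id)
            fracs.append((f0 + f1) / 2)
            lengths.append(seg_len)
            diams.append(dm)
            areas.append(math.pi * dm * seg_len * 1e-8)
            dists.append(start_dist + (f0 + f1) / 2 * L)
            comp_ids.append(idx)
        sec_comps[sec.id] = comp_ids

    n = len(parent)
    parent = np.asarray(parent, dtype=np.int64)
    lengths = np.asarray(lengths)
    diams = np.asarray(diams)
    areas = np.asarray(areas)
    dists = np.asarray(dists)

    # axial conductances: half-cylinder resistances on each side of the joint
    def half_res(i: int) -> float:  # Ω
        L_cm = lengths[i] * 1e-4 / 2.0
        A_cm2 = math.pi * (diams[i] * 1e-4 / 2.0) ** 2
        return Ri * L_cm / A_cm2

    g_ax = np.zeros(n)
    for i in range(1, n):
        R = half_res(i) + half_res(int(parent[i]))
        g_ax[i] = 1e6 / R  # µS

    # passive + channel densities (spine correction skips the soma)
    cm_nF = np.empty(n)
    g_leak = np.empty(n)
    gbar = np.zeros((4, n))
    for i in range(n):
        if i == 0:
            rm_eff, cm_eff = biophys.passive.Rm, biophys.passive.Cm
        else:
            rm_eff, cm_eff = corrected_passive(
                biophys.passive, biophys.spine_rule, dists[i]
            )
        cm_nF[i] = cm_eff * areas[i] * 1e3  # µF/cm² · cm² -> µF -> nF
        g_leak[i] = areas[i] / rm_eff * 1e6  # S -> µS
    e_rev = np.empty(4)
    for ci, cname in enumerate(CHANNEL_ORDER):
        ch = biophys.channel(cname)
        e_rev[ci] = ch.E_rev
        dens = channel_density(ch.density_rule, dists)  # S/cm²
        gbar[ci] = dens * areas * 1e6  # µS

    return CompartmentalModel(
        morph, biophys, parent, section_ids, np.asarray(fracs), lengths, diams,
        areas, dists, g_ax, cm_nF, g_leak, gbar, e_rev,
    )


@dataclass
class Synapse:
    """Double-exponential conductance synapse (peak-normalized to g_max)."""

    compartment: int
    g_max: float = 0.0002  # µS
    tau_rise: float = 0.2  # ms
    tau_decay: float = 2.0  # ms
    e_rev: float = 0.0  # mV
    times: tuple[float, ...] = ()  # activation times, ms

    def __post_init__(self):
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass
class CurrentStimulus:
    """Injected current at one compartment.

    kind 'step': amplitude from onset for duration; 'epsc_like': double-
    exponential kernel (peak-normalized to amplitude) from onset; 'hold':
    constant amplitude for the whole run.
    """

    compartment: int
    kind: str = "step"  # {"step", "epsc_like", "hold"}
    amplitude: float = 0.0  # nA
    onset: float = 0.0  # ms
    duration: float = 0.0  # ms (step)
    tau_rise: float = 0.2
    tau_decay: float = 2.0

    def waveform(self, t: np.ndarray) -> np.ndarray:
        if not math.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.kind == "hold":
            return np.full_like(t, self.amplitude)
        if self.kind == "step":
            return np.where(
                (t >= self.onset) & (t < self.onset + self.duration), self.amplitude, 0.0
            )
        if self.kind == "epsc_like":
            s = np.maximum(t - self.onset, 0.0)
            kern = np.exp(-s / self.tau_decay) - np.exp(-s / self.tau_rise)
            kern[t < self.onset] = 0.0
            peak = _biexp_peak(self.tau_rise, self.tau_decay)
            return self.amplitude * kern / peak
        raise ValueError(f"unknown stimulus kind {self.kind!r}")


def _biexp_peak(tau_rise: float, tau_decay: float) -> float:
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)


@dataclass
class SimulationConfig:
    dt: float = 0.025  # ms
    duration: float = 100.0  # ms
    v_init: float = -70.0  # mV
    settle: float = 50.0  # ms of stimulus-free integration before recording
    seed: int = 0
    record_sites: tuple[tuple[str, float], ...] = (("soma", 0.5),)
    ttx_center: Optional[tuple[str, float]] = None
    ttx_radius: float = 0.0  # µm
    snapshot_times: tuple[float, ...] = ()  # per-compartment V export (ms)

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")


@dataclass
class TraceSet:
    """Uniformly sampled voltage records at named sites."""

    time: np.ndarray  # ms
    voltages: dict[str, np.ndarray]  # site label -> mV
    config_hash: str = ""
    seed: int = 0
    snapshots: Optional[pd.DataFrame] = None  # per-compartment V at times

    def __post_init__(self):
        for k, v in self.voltages.items():
            if len(v) != len(self.time):
                raise ValueError(f"trace {k!r} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, v in self.voltages.items():
            rows.append(pd.DataFrame({"time": self.time, "site": site, "voltage": v}))
        return pd.concat(rows, ignore_index=True)

    def metadata_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.config_hash.encode())
        h.update(np.int64(self.seed).tobytes())
        for site in sorted(self.voltages):
            h.update(site.encode())
            h.update(np.ascontiguousarray(self.voltages[site]).tobytes())
        return h.hexdigest()


def place_synapses(
    model: CompartmentalModel,
    eligibility: Callable[[float], bool],
    n: int,
    seed: int,
    g_max: float = 0.0002,
) -> list[Synapse]:
    """Place n synapses uniformly per unit eligible cable length.

    ``eligibility`` is a predicate on path distance (µm), e.g.
    ``lambda d: d > 400`` for the distal apical territory.  Deterministic
    given ``seed``; raises if no dendritic cable is eligible.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    elig = np.array(
        [
            i != model.soma_index and eligibility(model.path_dists[i])
            for i in range(model.n)
        ]
    )
    total = model.lengths[elig].sum()
    if n > 0 and total <= 0:
        raise SimulationError("no eligible cable for synapse placement")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    p = np.where(elig, model.lengths, 0.0)
    p = p / p.sum()
    comps = rng.choice(model.n, size=n, replace=True, p=p)
    return [Synapse(compartment=int(c), g_max=g_max) for c in comps]


def _steady_gates(model: CompartmentalModel, V: np.ndarray) -> np.ndarray:
    gp, sign = _gate_param_arrays(model.biophysics)
    xinf, _ = _core.gate_inf_tau(gp, sign, np.asarray(V, dtype=float))
    return xinf


def initialize(model: CompartmentalModel, config: SimulationConfig) -> CompartmentalModel:
    """Calibrate the leak reversal so v_init is a fixed point; verify settling.

    Gates are set to steady state at ``v_init`` and each compartment's leak
    reversal chosen so its net membrane current vanishes there.  A stimulus-
    free integration of ``config.settle`` ms then verifies that the somatic
    drift stays below 0.5 mV.
    """
    model = model.copy()
    v0 = np.full(model.n, config.v_init)
    X = _steady_gates(model, v0)
    i_active = np.zeros(model.n)
    opens = _open_fractions(X)
    for ci in range(4):
        g = model.gbar[ci] * opens[ci]
        i_active += g * (config.v_init - model.e_rev[ci])
    model.e_leak = config.v_init + i_active / model.g_leak
    model._gates = X
    model.initialized_at = config.v_init

    if config.settle > 0:
        ts = run(
            model,
            synapses=(),
            currents=(),
            config=replace(config, duration=config.settle, settle=0.0,
                           record_sites=(("soma", 0.5),), ttx_center=None),
            _skip_init_check=True,
        )
        drift = abs(ts.voltages["soma[0.5]"][-1] - config.v_init)
        if drift >= 0.5:
            raise SimulationError(
                f"initialization failed: somatic drift {drift:.3f} mV after "
                f"{config.settle} ms settle"
            )
    return model


def _open_fractions(X: np.ndarray) -> np.ndarray:
    opens = np.empty((4, X.shape[1]))
    opens[0] = X[0] ** 3 * X[1]
    opens[1] = X[2]
    opens[2] = X[3] * X[4]
    opens[3] = X[5]
    return opens


def apply_ttx(
    model: CompartmentalModel, center: tuple[str, float], radius: float
) -> CompartmentalModel:
    """Zero the Na conductance within a path-distance radius of a location.

    Returns a modified copy; all other densities are untouched.  Emulates
    local tetrodotoxin application.
    """
    new = model.copy()
    ci = new.locate(center)
    for i in range(new.n):
        if new.tree_distance(ci, i) <= radius:
            new.gbar[0, i] = 0.0
    return new


def run(
    model: CompartmentalModel,
    synapses: Sequence[Synapse],
    currents: Sequence[CurrentStimulus],
    config: SimulationConfig,
    _skip_init_check: bool = False,
) -> TraceSet:
    """Integrate the model and return voltage traces at the recording sites.

    The model must have been passed through :func:`initialize` (its gate
    states and calibrated leak are carried on the model).  A TTX mask in the
    config is applied to a copy before integration.  Deterministic given the
    config and model.
    """
    if model._gates is None and not _skip_init_check:
        raise SimulationError("model not initialized; call initialize() first")
    if config.ttx_center is not None:
        model = apply_ttx(model, config.ttx_center, config.ttx_radius)

    n_steps = int(round(config.duration / config.dt))
    V = np.full(model.n, config.v_init if model.initialized_at is None
                else model.initialized_at, dtype=float)
    if model._gates is not None:
        X = model._gates.copy()
    else:
        X = _steady_gates(model, V)

    # synapse events -> flat arrays (all synapses share the kernel taus)
    taus = {(s.tau_rise, s.tau_decay, s.e_rev) for s in synapses}
    if len(taus) > 1:
        raise SimulationError("all synapses in one run must share kernel taus and e_rev")
    tau_r, tau_d, e_syn = (0.2, 2.0, 0.0) if not taus else next(iter(taus))
    peak = _biexp_peak(tau_r, tau_d)
    events = []
    for s in synapses:
        for t in s.times:
            if 0 <= t <= config.duration:
                events.append((int(round(t / config.dt)), s.compartment, s.g_max / peak))
    events.sort()
    if events:
        ev_step = np.array([e[0] for e in events], dtype=np.int64)
        ev_comp = np.array([e[1] for e in events], dtype=np.int64)
        ev_w = np.array([e[2] for e in events], dtype=float)
    else:
        ev_step = np.zeros(0, dtype=np.int64)
        ev_comp = np.zeros(0, dtype=np.int64)
        ev_w = np.zeros(0)

    t_grid = np.arange(1, n_steps + 1) * config.dt  # implicit scheme: end of step
    if currents:
        stim_comp = np.array([c.compartment for c in currents], dtype=np.int64)
        stim_I = np.stack([c.waveform(t_grid) for c in currents])
    else:
        stim_comp = np.zeros(0, dtype=np.int64)
        stim_I = np.zeros((0, n_steps))

    rec_labels = [f"{sec}[{frac:g}]" for sec, frac in config.record_sites]
    rec_idx = np.array([model.locate(site) for site in config.record_sites], dtype=np.int64)
    v_out = np.empty((len(rec_idx), n_steps + 1))

    gp, sign = _gate_param_arrays(model.biophysics)
    syn_A = np.zeros(model.n)
    syn_B = np.zeros(model.n)
    snap_step = np.array(
        [int(round(t / config.dt)) - 1 for t in config.snapshot_times], dtype=np.int64
    )
    v_snap = np.empty((len(snap_step), model.n))
    status = _core.integrate(
        n_steps, config.dt, model.parent, model.g_ax, model.cm / config.dt,
        model.g_leak, model.e_leak, model.gbar, model.e_rev, gp, sign,
        V, X, syn_A, syn_B,
        math.exp(-config.dt / tau_r), math.exp(-config.dt / tau_d), e_syn,
        ev_step, ev_comp, ev_w, stim_comp, stim_I, rec_idx, v_out,
        snap_step, v_snap,
    )
    if status >= 0:
        raise SimulationError(f"numerical divergence at step {status}")

    snapshots = None
    if len(snap_step):
        frames = []
        for s, t_snap in enumerate(config.snapshot_times):
            frames.append(pd.DataFrame({
                "time": t_snap,
                "compartment": np.arange(model.n),
                "section": model.section_ids,
                "path_distance": model.path_dists,
                "voltage": v_snap[s],
            }))
        snapshots = pd.concat(frames, ignore_index=True)

    cfg_repr = json.dumps(
        {
            "dt": config.dt, "duration": config.duration, "v_init": config.v_init,
            "seed": config.seed, "sites": rec_labels,
            "ttx": [config.ttx_center, config.ttx_radius],
            "n_syn": len(synapses), "n_stim": len(currents),
        },
        default=str,
    )
    time = np.arange(n_steps + 1) * config.dt
    voltages = {lab: v_out[i] for i, lab in enumerate(rec_labels)}
    return TraceSet(
        time=time,
        voltages=voltages,
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest(),
        seed=config.seed,
        snapshots=snapshots,
    )
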