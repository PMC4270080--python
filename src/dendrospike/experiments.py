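"""End-to-end in-silico experiments on the CA1/CA2 model pair.

Protocols
---------
* ``run_weak_strong``: distal synaptic stimulation (weak ≈ 75 synapses,
  strong ≈ 1000, placed randomly > 400 µm from the soma) on both cell
  classes, across replicate seeds.  Reports, per condition, the fraction of
  replicates with a local tuft spike, a primary-branch-point spike, and a
  somatic AP, plus the branch-point → soma latency where both spike.
* ``branch_recruitment_search``: activates k of the ~12 CA2 secondary
  branches (≈ 150 synapses each, in a band around 300 µm path distance) and
  returns the minimal k that fires a somatic AP in the majority of seeded
  branch-subset draws.
* ``ttx_experiment``: regional Na-conductance block emulating local TTX —
  a dendritic (stratum-radiatum) mask that should abolish the somatic AP
  while leaving the subthreshold EPSP nearly unchanged, or a somatic mask
  that converts the AP into a spikelet.
* ``characterize_cell``: calibration dashboard (R_input, τ_m, sag ratio,
  somatic AP threshold, dendritic spike threshold current).

Event criteria (documented operational definitions):
a *somatic AP* is a dV/dt ≥ 10 V/s crossing whose voltage peak exceeds 0 mV;
a *dendritic spike* at a dendritic site is a local depolarization whose peak
exceeds −20 mV (regenerative range, far above what the synaptic conductances
can sustain passively at these sites once the driving force collapses).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biophysics import CellBiophysics, ca1_biophysics, ca2_biophysics
from .morphology import Morphology, MorphogenParams, branches_at_distance, generate_morphology
from .simulator import (
    CompartmentalModel,
    CurrentStimulus,
    SimulationConfig,
    Synapse,
    discretize,
    initialize,
    place_synapses,
    run,
)
from .trace_analysis import (Trace, ap_threshold, detect_spikelet, dvdt,
                             epsp_amplitude, passive_constants, sag_ratio)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "build_cell",
    "run_weak_strong",
    "branch_recruitment_search",
    "ttx_experiment",
    "characterize_cell",
]

DENDRITIC_SPIKE_PEAK = -20.0  # mV
WEAK_N = 75
STRONG_N = 1000
SYN_PER_BRANCH = 150


@dataclass
class ExperimentConfig:
    """Shared settings for the in-silico protocols."""

    cell_class: str = "ca2"
    morph_seed: int = 1
    morph_overrides: dict = field(default_factory=dict)
    n_weak: int = WEAK_N
    n_strong: int = STRONG_N
    syn_per_branch: int = SYN_PER_BRANCH
    branch_band: float = 300.0  # µm, centre of the per-branch activation band
    branch_band_halfwidth: float = 50.0  # µm
    eligibility_distance: float = 400.0  # µm, distal synaptic territory
    replicate_seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_subset_draws: int = 7  # branch subsets per k in the recruitment search
    stim_time: float = 10.0  # ms after recording onset
    jitter_sigma: float = 0.0  # ms, Gaussian jitter of activation times (off)
    dt: float = 0.025
    duration: float = 60.0
    max_seg_len: float = 10.0
    g_max: float = 0.0002  # µS per synapse
    ttx_somatic_radius: float = 30.0  # µm
    ttx_dendritic_center: float = 150.0  # µm up the apical axis
    ttx_dendritic_radius: float = 75.0  # µm

    def morphogen_params(self) -> MorphogenParams:
        kwargs = dict(cell_class=self.cell_class, seed=self.morph_seed)
        kwargs.update(self.morph_overrides)
        return MorphogenParams(**kwargs)


@dataclass
class ExperimentResult:
    """Per-replicate event table plus condition-level summary."""

    events: pd.DataFrame
    summary: pd.DataFrame

    def table_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.events.to_csv(index=False).encode())
        h.update(self.summary.to_csv(index=False).encode())
        return h.hexdigest()


def build_cell(
    config: ExperimentConfig, cell_class: Optional[str] = None
) -> tuple[Morphology, CompartmentalModel]:
    """Generate the class morphology, discretize, and initialize at −70 mV."""
    cls = cell_class or config.cell_class
    params = replace(config.morphogen_params(), cell_class=cls)
    morph = generate_morphology(params)
    biophys = ca2_biophysics() if cls == "ca2" else ca1_biophysics()
    model = discretize(morph, biophys, max_seg_len=config.max_seg_len)
    model = initialize(model, SimulationConfig(dt=config.dt, settle=50.0))
    return morph, model


def _recording_sites(morph: Morphology) -> list[tuple[str, float]]:
    """Soma, primary branch point (distal trunk end), and every tuft midpoint."""
    sites = [("soma", 0.5), ("apical_trunk", 1.0)]
    tufts = sorted(s for s in morph.sections if s.startswith("apical_tuft"))
    sites.extend((t, 0.5) for t in tufts)
    return sites


def _activation_times(n: int, config: ExperimentConfig, seed: int) -> list[tuple[float, ...]]:
    if config.jitter_sigma > 0:
        rng = np.random.default_rng(seed + 10_000)
        return [
            (float(max(config.stim_time + rng.normal(0.0, config.jitter_sigma), 0.0)),)
            for _ in range(n)
        ]
    return [(config.stim_time,)] * n


def _run_distal(
    morph: Morphology,
    model: CompartmentalModel,
    config: ExperimentConfig,
    n_syn: int,
    seed: int,
    ttx_center=None,
    ttx_radius=0.0,
) -> dict[str, Trace]:
    syns = place_synapses(
        model, lambda d: d > config.eligibility_distance, n_syn, seed, g_max=config.g_max
    )
    times = _activation_times(len(syns), config, seed)
    syns = [replace(s, times=t) for s, t in zip(syns, times)]
    sim = SimulationConfig(
        dt=config.dt,
        duration=config.duration,
        settle=0.0,
        seed=seed,
        record_sites=tuple(_recording_sites(morph)),
        ttx_center=ttx_center,
        ttx_radius=ttx_radius,
    )
    ts = run(model, syns, (), sim)
    return {site: Trace(time=ts.time, samples=v) for site, v in ts.voltages.items()}


def _event_row(traces: dict[str, Trace], stim_time: float) -> dict:
    soma = traces["soma[0.5]"]
    bp = traces["apical_trunk[1]"]
    tuft_keys = [k for k in traces if k.startswith("apical_tuft")]
    tuft_peaks = {k: float(traces[k].samples.max()) for k in tuft_keys}
    tuft_spike = any(v > DENDRITIC_SPIKE_PEAK for v in tuft_peaks.values())
    bp_spike = float(bp.samples.max()) > DENDRITIC_SPIKE_PEAK
    ap = ap_threshold(soma, criterion=10.0, stimulus_time=stim_time)
    soma_ap = ap is not None

    latency = np.nan
    if bp_spike and soma_ap:
        d_bp = dvdt(bp).samples
        d_soma = dvdt(soma).samples
        i_bp = np.flatnonzero(d_bp >= 10.0)
        i_soma = np.flatnonzero(d_soma >= 10.0)
        if i_bp.size and i_soma.size:
            latency = float(soma.time[i_soma[0]] - bp.time[i_bp[0]])

    return {
        "tuft_spike": tuft_spike,
        "bp_spike": bp_spike,
        "soma_ap": soma_ap,
        "soma_peak_mV": float(soma.samples.max()),
        "bp_peak_mV": float(bp.samples.max()),
        "max_tuft_peak_mV": max(tuft_peaks.values()) if tuft_peaks else np.nan,
        "bp_to_soma_latency_ms": latency,
    }


def run_weak_strong(config: ExperimentConfig) -> ExperimentResult:
    """Weak (~75 syn) and strong (~1000 syn) distal input on both classes."""
    rows = []
    for cls in ("ca1", "ca2"):
        morph, model = build_cell(config, cls)
        for intensity, n_syn in (("weak", config.n_weak), ("strong", config.n_strong)):
            for seed in config.replicate_seeds:
                traces = _run_distal(morph, model, config, n_syn, seed)
                row = {"cell_class": cls, "intensity": intensity, "seed": seed,
                       "n_synapses": n_syn}
                row.update(_event_row(traces, config.stim_time))
                rows.append(row)
    events = pd.DataFrame(rows)
    summary = (
        events.groupby(["cell_class", "intensity"])
        .agg(
            tuft_spike_fraction=("tuft_spike", "mean"),
            bp_spike_fraction=("bp_spike", "mean"),
            soma_ap_fraction=("soma_ap", "mean"),
            median_latency_ms=("bp_to_soma_latency_ms", "median"),
        )
        .reset_index()
    )
    return ExperimentResult(events=events, summary=summary)


def _branch_synapses(
    model: CompartmentalModel,
    branch_sections: Sequence[str],
    config: ExperimentConfig,
    seed: int,
) -> list[Synapse]:
    """~150 synapses per selected branch, within the ~300 µm band on that route."""
    lo = config.branch_band - config.branch_band_halfwidth
    hi = config.branch_band + config.branch_band_halfwidth
    syns = []
    for j, sec in enumerate(branch_sections):
        idx = [
            i
            for i in range(model.n)
            if model.section_ids[i] == sec and lo <= model.path_dists[i] <= hi
        ]
        if not idx:
            raise ValueError(f"branch {sec!r} has no cable in the activation band")
        rng = np.random.default_rng(seed * 1000 + j)
        p = np.array([model.lengths[i] for i in idx], dtype=float)
        p /= p.sum()
        comps = rng.choice(idx, size=config.syn_per_branch, replace=True, p=p)
        syns.extend(
            Synapse(compartment=int(c), g_max=config.g_max, times=(config.stim_time,))
            for c in comps
        )
    return syns


def branch_recruitment_search(config: ExperimentConfig) -> dict:
    """Minimal number of co-active CA2 branches that triggers a somatic AP.

    For k = 1..n_branches, ``n_subset_draws`` seeded random subsets of k
    branches are each activated with ~150 synapses; k qualifies when the
    majority of draws fires a somatic AP.  The smallest qualifying k is
    verified against k+1 (monotone recruitment).  Returns a dict with
    ``min_k`` (None when no k fires), the per-k AP fraction, and the maximal
    somatic depolarization observed.
    """
    cfg = replace(config, cell_class="ca2")
    morph, model = build_cell(cfg)
    branch_locs = branches_at_distance(morph, cfg.branch_band)
    branch_secs = [sec for sec, _ in branch_locs]
    n_branches = len(branch_secs)
    if n_branches == 0:
        raise ValueError("no branches at the activation band")

    sim_sites = tuple(_recording_sites(morph))
    per_k: dict[int, float] = {}
    max_depol = [-np.inf]

    def ap_fraction(k: int) -> float:
        if k in per_k:
            return per_k[k]
        fired = 0
        for draw in range(cfg.n_subset_draws):
            rng = np.random.default_rng(1_000_000 + 97 * k + draw)
            subset = list(rng.choice(n_branches, size=k, replace=False))
            syns = _branch_synapses(model, [branch_secs[j] for j in subset], cfg,
                                    seed=97 * k + draw)
            sim = SimulationConfig(
                dt=cfg.dt, duration=cfg.duration, settle=0.0, seed=draw,
                record_sites=sim_sites,
            )
            ts = run(model, syns, (), sim)
            soma = Trace(time=ts.time, samples=ts.voltages["soma[0.5]"])
            max_depol[0] = max(max_depol[0], float(soma.samples.max()))
            if ap_threshold(soma, criterion=10.0, stimulus_time=cfg.stim_time):
                fired += 1
        per_k[k] = fired / cfg.n_subset_draws
        return per_k[k]

    # smallest k with a majority of AP-firing draws, verified at k+1
    min_k = None
    k = 1
    while k <= n_branches:
        if ap_fraction(k) > 0.5:
            if k == n_branches or ap_fraction(k + 1) > 0.5:
                min_k = k
                break
            k += 2  # isolated majority: not a stable recruitment point
        else:
            k += 1
    max_depol = max_depol[0]
    return {
        "min_k": min_k,
        "n_branches": n_branches,
        "ap_fraction_per_k": per_k,
        "max_soma_depolarization_mV": float(max_depol),
    }


def ttx_experiment(config: ExperimentConfig, variant: str = "dendritic") -> dict:
    """Regional Na block analogs of local TTX application.

    ``dendritic``: Na zeroed in a band around 150 µm along every apical
    route (stratum radiatum); strong distal input should no longer evoke a
    somatic AP while the weak-input subthreshold somatic EPSP should change
    by < 10%.  ``somatic``: Na zeroed within 30 µm of the soma; strong input
    should evoke a spikelet (dV/dt ≥ 10 V/s, peak < 0 mV) but no AP.
    ``whole``: Na zeroed everywhere.
    """
    if variant not in ("dendritic", "somatic", "whole"):
        raise ValueError(f"unknown TTX variant {variant!r}")
    morph, model = build_cell(config)
    seed = config.replicate_seeds[0]

    from .simulator import apply_ttx

    if variant == "dendritic":
        blocked = model
        for sec, frac in branches_at_distance(morph, config.ttx_dendritic_center):
            blocked = apply_ttx(blocked, (sec, frac), config.ttx_dendritic_radius)
    elif variant == "somatic":
        blocked = apply_ttx(model, ("soma", 0.5), config.ttx_somatic_radius)
    else:
        blocked = apply_ttx(model, ("soma", 0.5), 10 * morph.total_length)

    out = {"variant": variant}
    strong = _run_distal(morph, blocked, config, config.n_strong, seed)
    soma_strong = strong["soma[0.5]"]
    ap = ap_threshold(soma_strong, criterion=10.0, stimulus_time=config.stim_time)
    out["soma_ap"] = ap is not None
    out["soma_peak_mV"] = float(soma_strong.samples.max())
    spikelets = detect_spikelet(soma_strong)
    out["n_spikelets"] = len(spikelets)
    out["max_spikelet_dvdt"] = max((s.peak_dvdt for s in spikelets), default=0.0)

    if variant == "dendritic":
        weak_ctl = _run_distal(morph, model, config, config.n_weak, seed)
        weak_ttx = _run_distal(morph, blocked, config, config.n_weak, seed)
        a_ctl = epsp_amplitude(weak_ctl["soma[0.5]"], config.stim_time)
        a_ttx = epsp_amplitude(weak_ttx["soma[0.5]"], config.stim_time)
        out["weak_epsp_control_mV"] = a_ctl
        out["weak_epsp_ttx_mV"] = a_ttx
        out["weak_epsp_change_fraction"] = abs(a_ttx - a_ctl) / a_ctl
    if variant == "whole":
        peaks = {k: float(tr.samples.max()) for k, tr in strong.items()}
        out["any_site_spike"] = any(v > DENDRITIC_SPIKE_PEAK for v in peaks.values())
    return out


def characterize_cell(config: ExperimentConfig) -> pd.DataFrame:
    """Calibration dashboard: passive constants, sag, and spike thresholds."""
    morph, model = build_cell(config)
    rows = []

    def somatic_step(amp_nA: float, duration: float = 300.0) -> Trace:
        sim = SimulationConfig(dt=config.dt, duration=duration + 100.0, settle=0.0,
                               record_sites=(("soma", 0.5),))
        stim = CurrentStimulus(compartment=model.soma_index, kind="step",
                               amplitude=amp_nA, onset=10.0, duration=duration)
        ts = run(model, (), (stim,), sim)
        return Trace(time=ts.time, samples=ts.voltages["soma[0.5]"])

    small = somatic_step(-0.05)
    r_in, tau_m = passive_constants(small, 10.0, 310.0, -0.05)
    rows.append({"metric": "R_input_MOhm", "value": r_in})
    rows.append({"metric": "tau_m_ms", "value": tau_m})

    sag_tr = somatic_step(-0.1)
    rows.append({"metric": "sag_ratio", "value": sag_ratio(sag_tr, 10.0, 310.0)})

    # somatic AP threshold: smallest step (25 pA grid) that fires, criterion 50 V/s
    thr_v = np.nan
    for amp in np.arange(0.05, 1.51, 0.025):
        tr = somatic_step(float(amp), duration=100.0)
        ev = ap_threshold(tr, criterion=50.0, stimulus_time=10.0)
        if ev is not None:
            thr_v = ev.threshold_voltage
            rows.append({"metric": "rheobase_nA", "value": float(amp)})
            break
    rows.append({"metric": "ap_threshold_50Vps_mV", "value": thr_v})

    # dendritic spike threshold: brief pulse at a mid-apical site
    dend_site = branches_at_distance(morph, min(250.0, morph.total_length / 4))
    if dend_site:
        sec, frac = dend_site[0]
        comp = model.locate((sec, frac))
        dthr = np.nan
        for amp in np.arange(0.1, 3.01, 0.1):
            sim = SimulationConfig(dt=config.dt, duration=40.0, settle=0.0,
                                   record_sites=((sec, frac),))
            stim = CurrentStimulus(compartment=comp, kind="step",
                                   amplitude=float(amp), onset=10.0, duration=5.0)
            ts = run(model, (), (stim,), sim)
            v = ts.voltages[f"{sec}[{frac:g}]"]
            if v.max() > DENDRITIC_SPIKE_PEAK:
                dthr = float(amp)
                break
        rows.append({"metric": "dendritic_spike_threshold_nA", "value": dthr})

    df = pd.DataFrame(rows)
    df.insert(0, "cell_class", config.cell_class)
    return df
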