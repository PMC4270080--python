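"""Operational measurements on membrane-potential traces.

These mirror the quantities extracted from current-clamp recordings in the
hippocampal dendritic-spike literature: time derivative and phase-plane
representations, action-potential threshold at fixed dV/dt criteria (10 or
50 V/s), spikelet detection (fast depolarizations whose voltage peak stays
below 0 mV — the somatic signature of an attenuated dendritic spike), a
dendritic-spike-aware EPSP amplitude, 20-80% rise time, paired-pulse ratio,
sag ratio, passive constants, and inter-site event latency.

All functions accept a :class:`Trace` (uniform time base, samples in mV).
Because mV/ms ≡ V/s, derivative values are numerically in V/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Trace",
    "APEvent",
    "SpikeletEvent",
    "IOCurve",
    "dvdt",
    "phase_plane",
    "ap_threshold",
    "detect_spikelet",
    "epsp_amplitude",
    "rise_time_20_80",
    "ppr",
    "sag_ratio",
    "passive_constants",
    "latency_difference",
]

AP_PEAK_CUT = 0.0  # mV: voltage peaks above this are full APs, below, spikelets
SPIKELET_FLOOR = 10.0  # V/s: detection floor, the lower AP-threshold criterion
DSPIKE_WINDOW = 5.0  # ms: dendritic-spike latency window after the stimulus
BASELINE_WINDOW = 5.0  # ms preceding the stimulus used as baseline


class MeasurementError(RuntimeError):
    pass


@dataclass
class Trace:
    """A uniformly sampled membrane-potential record."""

    time: np.ndarray  # ms
    samples: np.ndarray  # mV

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.time.size != self.samples.size or self.time.size < 2:
            raise ValueError("trace needs >= 2 samples with matching time base")
        steps = np.diff(self.time)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12) or steps[0] <= 0:
            raise ValueError("time base must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def index_at(self, t: float) -> int:
        return int(round((t - self.time[0]) / self.dt))


@dataclass
class APEvent:
    threshold_voltage: float  # mV
    threshold_time: float  # ms
    peak_voltage: float  # mV
    amplitude: float  # mV, from baseline
    criterion: float  # V/s

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("AP amplitude must be > 0")


@dataclass
class SpikeletEvent:
    onset_time: float  # ms
    peak_dvdt: float  # V/s
    amplitude: float  # mV above the concurrent slow depolarization
    pre_ap: bool = False  # spikelet immediately preceding a full AP upstroke


@dataclass
class IOCurve:
    intensities: np.ndarray
    responses: np.ndarray
    kind: str = "epsp_mV"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.intensities.size != self.responses.size:
            raise ValueError("length mismatch")
        if np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")


def dvdt(trace: Trace) -> Trace:
    """Time derivative in V/s: central differences, one-sided at endpoints."""
    if trace.samples.size < 3:
        raise MeasurementError("need >= 3 samples for a derivative")
    d = np.gradient(trace.samples, trace.time)
    return Trace(time=trace.time.copy(), samples=d)


def phase_plane(trace: Trace) -> np.ndarray:
    """(V, dV/dt) pairs in sampling order, shape (n, 2)."""
    d = dvdt(trace)
    return np.column_stack([trace.samples, d.samples])


def _baseline(trace: Trace, stimulus_time: Optional[float]) -> float:
    if stimulus_time is None:
        return float(trace.samples[0])
    i1 = max(trace.index_at(stimulus_time), 1)
    i0 = max(trace.index_at(stimulus_time - BASELINE_WINDOW), 0)
    return float(trace.samples[i0:i1].mean())


def ap_threshold(
    trace: Trace, criterion: float = 50.0, stimulus_time: Optional[float] = None
) -> Optional[APEvent]:
    """Voltage at which dV/dt first exceeds the criterion before a full AP.

    Returns None if the derivative never crosses the criterion or if no
    subsequent voltage peak qualifies as an action potential (peak > 0 mV).
    """
    d = dvdt(trace).samples
    v = trace.samples
    above = np.flatnonzero(d >= criterion)
    if above.size == 0:
        return None
    peak_i = int(above[0]) + int(np.argmax(v[above[0]:]))
    peak_v = float(v[peak_i])
    if peak_v <= AP_PEAK_CUT:
        return None
    # threshold: start of the contiguous dV/dt >= criterion run carrying the
    # upstroke into the peak (a brief stimulus-onset transient that decays
    # below the criterion before the AP does not count)
    before = above[above <= peak_i]
    i = int(before[-1]) if before.size else int(above[0])
    while i > 0 and d[i - 1] >= criterion:
        i -= 1
    base = _baseline(trace, stimulus_time)
    return APEvent(
        threshold_voltage=float(trace.samples[i]),
        threshold_time=float(trace.time[i]),
        peak_voltage=peak_v,
        amplitude=peak_v - base,
        criterion=criterion,
    )


def detect_spikelet(
    trace: Trace,
    floor: float = SPIKELET_FLOOR,
    ap_peak_cut: float = AP_PEAK_CUT,
    smooth_window_ms: float = 0.5,
) -> list[SpikeletEvent]:
    """Detect spikelets: fast depolarizations that do not become full APs.

    A local maximum of dV/dt at or above ``floor`` is a spikelet if the next
    voltage peak stays below ``ap_peak_cut``; a qualifying dV/dt maximum that
    is followed by a full AP upstroke is reported as a pre-AP spikelet (the
    phase-plane double-inflection signature of a dendritic spike driving the
    AP).  Traces are lightly box-smoothed before differentiation so that
    recording noise does not fragment events.
    """
    w = max(1, int(round(smooth_window_ms / trace.dt)))
    if w > 1:
        kernel = np.ones(w) / w
        padded = np.pad(trace.samples, (w // 2, w - 1 - w // 2), mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")
    else:
        sm = trace.samples
    smooth = Trace(time=trace.time, samples=sm)
    d = dvdt(smooth).samples
    v = trace.samples
    n = d.size

    # local maxima of dV/dt above the floor
    cand = [
        i
        for i in range(1, n - 1)
        if d[i] >= floor and d[i] >= d[i - 1] and d[i] > d[i + 1]
    ]
    events: list[SpikeletEvent] = []
    last_end = -1
    for i in cand:
        if i <= last_end:
            continue
        # find the voltage peak that terminates this upstroke
        j = i
        while j < n - 1 and v[j + 1] >= v[j]:
            j += 1
        peak_v = v[j]
        # concurrent slow depolarization: voltage where the fast rise began
        k = i
        while k > 0 and d[k - 1] > floor / 2:
            k -= 1
        amp = float(peak_v - v[k])
        if peak_v > ap_peak_cut:
            # full AP: report only if a distinct sub-threshold dV/dt hump
            # precedes the main upstroke (local minimum between i and the
            # global acceleration into the AP)
            seg = d[i:j + 1]
            mins = [
                m
                for m in range(1, seg.size - 1)
                if seg[m] < seg[m - 1] and seg[m] <= seg[m + 1]
            ]
            if mins and v[i + mins[0]] < ap_peak_cut:
                events.append(
                    SpikeletEvent(
                        onset_time=float(trace.time[i]),
                        peak_dvdt=float(d[i]),
                        amplitude=amp,
                        pre_ap=True,
                    )
                )
        else:
            events.append(
                SpikeletEvent(
                    onset_time=float(trace.time[i]),
                    peak_dvdt=float(d[i]),
                    amplitude=max(amp, 0.0),
                )
            )
        last_end = j
    return events


def epsp_amplitude(
    trace: Trace,
    stimulus_time: float,
    dspike_aware: bool = False,
    dspike_window: float = DSPIKE_WINDOW,
) -> float:
    """Peak depolarization from baseline after a stimulus.

    With ``dspike_aware``, the peak search starts ``dspike_window`` ms after
    the stimulus, excluding the early window in which a dendritic-spike
    transient would ride on the EPSP (the EPSP itself peaks later).
    """
    if not trace.time[0] <= stimulus_time <= trace.time[-1]:
        raise MeasurementError("stimulus time outside trace")
    base = _baseline(trace, stimulus_time)
    start = stimulus_time + (dspike_window if dspike_aware else 0.0)
    i0 = min(max(trace.index_at(start), 0), trace.samples.size - 1)
    return float(trace.samples[i0:].max() - base)


def rise_time_20_80(trace: Trace, stimulus_time: float) -> float:
    """Time between the 20% and 80% crossings of the baseline-to-peak rise."""
    base = _baseline(trace, stimulus_time)
    i0 = max(trace.index_at(stimulus_time), 0)
    seg = trace.samples[i0:]
    tseg = trace.time[i0:]
    pk = int(np.argmax(seg))
    peak = seg[pk]
    if peak <= base:
        raise MeasurementError("no identifiable peak after stimulus")
    lo, hi = base + 0.2 * (peak - base), base + 0.8 * (peak - base)

    def crossing(level: float) -> float:
        idx = np.flatnonzero(seg[: pk + 1] >= level)
        if idx.size == 0:
            raise MeasurementError(f"rise never crosses {level:.3f} mV")
        i = int(idx[0])
        if i == 0:
            return float(tseg[0])
        # linear interpolation between samples
        t0, t1 = tseg[i - 1], tseg[i]
        v0, v1 = seg[i - 1], seg[i]
        return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))

    return crossing(hi) - crossing(lo)


def ppr(trace: Trace, t1: float, t2: Optional[float] = None) -> float:
    """Paired-pulse ratio: second/first EPSP amplitude, 50 ms apart by default.

    The second amplitude is measured from the voltage just before the second
    stimulus, correcting for residual decay of the first response.
    """
    if t2 is None:
        t2 = t1 + 50.0
    if not (trace.time[0] <= t1 < t2 <= trace.time[-1]):
        raise MeasurementError("stimulus times outside trace")
    base1 = _baseline(trace, t1)
    i1, i2 = trace.index_at(t1), trace.index_at(t2)
    a1 = float(trace.samples[i1:i2].max() - base1)
    if a1 <= 0:
        raise MeasurementError("first response amplitude <= 0: PPR undefined")
    base2 = float(trace.samples[max(i2 - 1, 0)])
    a2 = float(trace.samples[i2:].max() - base2)
    return a2 / a1


def sag_ratio(trace: Trace, step_onset: float, step_end: float) -> float:
    """Sag ratio of a hyperpolarizing step: (peak − steady state)/peak.

    Both deflections are measured from the pre-step baseline; the steady
    state is the mean over the last 10% of the step.  Sag — the slow
    depolarizing relaxation after the initial peak hyperpolarization — is the
    signature of the h-current.
    """
    base = _baseline(trace, step_onset)
    i0, i1 = trace.index_at(step_onset), trace.index_at(step_end)
    seg = trace.samples[i0:i1]
    peak_defl = base - seg.min()
    if peak_defl <= 0:
        raise MeasurementError("step is not hyperpolarizing")
    tail = seg[int(0.9 * seg.size):]
    ss_defl = base - tail.mean()
    return float((peak_defl - ss_defl) / peak_defl)


def passive_constants(
    trace: Trace, step_onset: float, step_end: float, current_nA: float
) -> tuple[float, float]:
    """(R_input in MΩ, τ_m in ms) from a small hyperpolarizing current step.

    R_input = ΔV_ss / I; τ_m from a single-exponential fit to the late
    charging phase (after the first 5% of the step, avoiding fast
    equalization components).
    """
    if current_nA == 0:
        raise MeasurementError("zero step current")
    base = _baseline(trace, step_onset)
    i0, i1 = trace.index_at(step_onset), trace.index_at(step_end)
    seg = trace.samples[i0:i1]
    tseg = trace.time[i0:i1] - trace.time[i0]
    ss = seg[int(0.9 * seg.size):].mean()
    r_input = abs((ss - base) / current_nA)  # mV/nA = MΩ

    j0 = max(int(0.05 * seg.size), 1)
    y = seg[j0:]
    t = tseg[j0:]

    def model(t, tau, a):
        return ss + a * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[20.0, seg[0] - ss], maxfev=10000
        )
    except RuntimeError as e:
        raise MeasurementError(f"charging-phase fit failed: {e}") from None
    tau = float(abs(popt[0]))
    return float(r_input), tau


def latency_difference(
    traces: dict[str, Trace], site_a: str, site_b: str, criterion: float = 10.0
) -> float:
    """Threshold-crossing time at site B minus site A (positive: A leads).

    The event time at each site is the first crossing of dV/dt ≥ criterion.
    """
    times = {}
    for key in (site_a, site_b):
        tr = traces[key]
        d = dvdt(tr).samples
        above = np.flatnonzero(d >= criterion)
        if above.size == 0:
            raise MeasurementError(f"no dV/dt >= {criterion} V/s event at {key!r}")
        times[key] = float(tr.time[int(above[0])])
    return times[site_b] - times[site_a]
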