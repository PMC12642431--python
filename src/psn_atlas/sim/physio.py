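"""Synthetic respiratory-physiology recordings.

Three simulators with shared scenario presets:

- :func:`simulate_flow` — whole-body-plethysmography-style airflow traces,
  breath by breath: half-sine inspiration (positive by convention) and a
  volume-balancing half-sine expiration, per-breath lognormal jitter, and
  interleaved irregular "sniffing" bouts for the eupnea selector to reject;
- :func:`simulate_emg` — diaphragm EMG burst trains under a mechanical
  ventilation protocol with sustained inflation/deflation holds; hold
  pressure scales burst duration (the operational inspiratory time) through
  a preset-specific curve and reduces burst rate;
- :func:`simulate_calcium` — ΔF/F traces of vagal sensory neurons under the
  hold protocol, with class-specific response shapes (slowly adapting type
  I/II, rapidly adapting, inflation-suppressed, non-responding).

Scenario presets encode the cell-ablation experiments: the PSN6 preset
lengthens inspiratory time by 11% (tidal volume follows, peak flow does
not), the PSN7 preset raises peak inspiratory flow by 13% with a small Ti
component so tidal volume rises ~15%. Every simulated breath's ground truth
is attached for recovery tests.

Absolute tidal-volume and flow magnitudes are conventional mouse-scale
placeholders (0.2 mL eupneic TV); the analyses consume relative changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import ConfigurationError, InputError

__all__ = [
    "BreathModel",
    "ScenarioPreset",
    "VentilationProtocol",
    "CalciumProfile",
    "FlowTrace",
    "EMGTrace",
    "CalciumTrace",
    "PRESETS",
    "default_calcium_cohort",
    "simulate_flow",
    "simulate_emg",
    "simulate_calcium",
]


@dataclass
class BreathModel:
    """Eupneic breath template.

    Implied tidal volume is (2/π)·PIF·Ti (the half-sine integral); rate is
    60/(Ti+Te) breaths per minute. Defaults give 150/min and TV = 0.2 mL.
    """

    ti: float = 0.133
    te: float = 0.267
    pif: float = 0.2 * np.pi / (2 * 0.133)  # mL/s, chosen so TV = 0.2 mL
    jitter_ti: float = 0.05  # lognormal sigma per breath
    jitter_te: float = 0.05
    jitter_pif: float = 0.08
    irregular_frac: float = 0.2  # fraction of record in sniffing bouts
    irregular_rate_range: tuple[float, float] = (2.0, 4.0)
    irregular_amplitude: float = 0.5
    noise_sd: float = 0.02  # additive Gaussian on flow, mL/s
    #: breaths flanking a sniffing bout are transitions, not quiet breathing;
    #: the truth table does not label them eupneic
    transition_guard: int = 4

    def validate(self) -> None:
        if min(self.ti, self.te, self.pif) <= 0:
            raise ConfigurationError("Ti, Te and PIF must be positive")


@dataclass
class ScenarioPreset:
    """Named multiplier set applied on top of a breath model."""

    name: str
    ti_multiplier: float = 1.0
    pif_multiplier: float = 1.0
    te_multiplier: float = 1.0
    #: hold pressure (cmH2O) -> multiplicative burst-duration (Ti) factor;
    #: a factor of 0 means apnea during the hold.
    emg_ti_curve: dict[float, float] = field(default_factory=dict)

    def validate(self) -> None:
        if min(self.ti_multiplier, self.pif_multiplier, self.te_multiplier) <= 0:
            raise ConfigurationError("preset multipliers must be positive")


# Control EMG curve: inspiratory holds shorten bursts progressively with
# pressure and abolish them at 20 cmH2O (apnea). The PSN6-ablation curve is
# flattened at the two low pressures (6 and 8 cmH2O) only.
_CONTROL_CURVE = {2.0: 1.0, 6.0: 0.85, 8.0: 0.72, 10.0: 0.55, 20.0: 0.0}
_PSN6_CURVE = {2.0: 1.0, 6.0: 1.0, 8.0: 1.0, 10.0: 0.55, 20.0: 0.0}

PRESETS: dict[str, ScenarioPreset] = {
    "control": ScenarioPreset("control", emg_ti_curve=dict(_CONTROL_CURVE)),
    "psn6_ablation": ScenarioPreset(
        "psn6_ablation", ti_multiplier=1.11, emg_ti_curve=dict(_PSN6_CURVE)
    ),
    "psn7_ablation": ScenarioPreset(
        "psn7_ablation",
        pif_multiplier=1.13,
        ti_multiplier=1.018,
        emg_ti_curve=dict(_CONTROL_CURVE),
    ),
}


@dataclass
class VentilationProtocol:
    """Mechanical-ventilation protocol with static holds."""

    rate: float = 150.0  # breaths/min
    target_pressure: float = 11.0  # cmH2O
    ie_ratio: float = 0.5  # I:E = 1:2
    #: (type, pressure cmH2O, duration s)
    hold_schedule: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("inflation", 20.0, 5.0),
            ("inflation", 10.0, 5.0),
            ("deflation", 2.0, 5.0),
        ]
    )
    inter_hold_gap: float = 10.0  # s of normal ventilation between holds

    def validate(self) -> None:
        for kind, p, dur in self.hold_schedule:
            if kind not in ("inflation", "deflation"):
                raise ConfigurationError(f"unknown hold type {kind!r}")
            if p <= 0 or dur <= 0:
                raise ConfigurationError("hold pressures and durations must be positive")


@dataclass
class CalciumProfile:
    """Response profile of one imaged neuron."""

    cell_id: str
    cls: str  # typeI_slow | typeII_slow | rapid_adapt | inflation_suppressed | nonresponder
    baseline_f: float = 1.0
    amplitude: float = 1.0  # peak ΔF/F of the response
    tau_adapt: float = 0.5  # s; decay constant for rapidly adapting cells
    noise_sd: float = 0.02
    soma_diameter_um: float = 25.0

    def validate(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.cls not in (
            "typeI_slow",
            "typeII_slow",
            "rapid_adapt",
            "inflation_suppressed",
            "nonresponder",
        ):
            raise ConfigurationError(f"unknown calcium class {self.cls!r}")


@dataclass
class FlowTrace:
    t: np.ndarray
    flow: np.ndarray
    fs: float
    truth: pd.DataFrame  # per-breath ground truth incl. eupnea mask
    meta: dict


@dataclass
class EMGTrace:
    t: np.ndarray
    emg: np.ndarray
    fs: float
    hold_windows: list[dict]
    truth: pd.DataFrame  # per-burst ground truth
    meta: dict


@dataclass
class CalciumTrace:
    cell_id: str
    t: np.ndarray
    dff: np.ndarray
    fs: float
    hold_windows: list[dict]
    truth_class: str
    soma_diameter_um: float


def _halfsine_breath(ti: float, te: float, pif: float, fs: float):
    """Sampled flow of one breath; expiration balances inspired volume."""
    n_i = max(2, int(round(ti * fs)))
    n_e = max(2, int(round(te * fs)))
    tv = 2.0 / np.pi * pif * ti
    pef = tv * np.pi / (2.0 * te)
    insp = pif * np.sin(np.pi * np.arange(n_i) / n_i)
    exp = -pef * np.sin(np.pi * np.arange(n_e) / n_e)
    return np.concatenate([insp, exp]), tv, pef


def simulate_flow(
    model: BreathModel | None = None,
    preset: ScenarioPreset | str = "control",
    duration: float = 60.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> FlowTrace:
    """Simulate an airflow trace (inspiration positive).

    Eupneic epochs alternate with irregular sniffing bouts (faster, smaller,
    noisier breaths) occupying ``model.irregular_frac`` of the record on
    average. The attached truth table lists each breath's realized onset,
    Ti, Te, PIF, PEF, TV, rate, and eupnea flag.
    """
    model = model or BreathModel()
    model.validate()
    if isinstance(preset, str):
        preset = PRESETS[preset]
    preset.validate()
    if fs < 200:
        raise ConfigurationError("sampling rate must be >= 200 Hz")
    ti0 = model.ti * preset.ti_multiplier
    if fs * ti0 < 5:
        raise ConfigurationError("sampling rate too low to resolve inspiratory time")
    if duration <= 10 * (ti0 + model.te * preset.te_multiplier):
        raise ConfigurationError("duration must cover more than 10 breaths")

    rng = np.random.default_rng(seed)
    te0 = model.te * preset.te_multiplier
    pif0 = model.pif * preset.pif_multiplier

    segs: list[np.ndarray] = []
    rows: list[dict] = []
    t_cursor = 0.0
    # epoch schedule: eupneic stretches broken by sniffing bouts
    f = model.irregular_frac
    in_bout = False
    seg_end = rng.uniform(5.0, 15.0) if f > 0 else np.inf
    while t_cursor < duration:
        if t_cursor >= seg_end:
            in_bout = not in_bout
            if in_bout:
                seg_end = t_cursor + rng.uniform(1.5, 3.5) * (f / 0.2 if f > 0 else 1.0)
            else:
                seg_end = t_cursor + rng.uniform(5.0, 15.0)
        if in_bout:
            speed = rng.uniform(*model.irregular_rate_range)
            ti = ti0 / speed * np.exp(rng.normal(0, 3 * model.jitter_ti))
            te = te0 / speed * np.exp(rng.normal(0, 3 * model.jitter_te))
            pif = pif0 * model.irregular_amplitude * np.exp(rng.normal(0, 3 * model.jitter_pif))
        else:
            ti = ti0 * np.exp(rng.normal(0, model.jitter_ti))
            te = te0 * np.exp(rng.normal(0, model.jitter_te))
            pif = pif0 * np.exp(rng.normal(0, model.jitter_pif))
        wave, tv, pef = _halfsine_breath(ti, te, pif, fs)
        segs.append(wave)
        n = len(wave)
        rows.append(
            {
                "onset": t_cursor,
                "ti": ti,
                "te": te,
                "pif": pif,
                "pef": pef,
                "tv": tv,
                "f": 60.0 / (ti + te),
                "is_eupneic": not in_bout,
            }
        )
        t_cursor += n / fs
    flow = np.concatenate(segs)
    if model.noise_sd > 0:
        flow = flow + rng.normal(0, model.noise_sd, size=len(flow))
    t = np.arange(len(flow)) / fs
    truth = pd.DataFrame(rows)
    # transition guard: quiet breaths adjacent to a bout are not eupneic truth
    if model.transition_guard > 0 and (~truth["is_eupneic"]).any():
        irr = (~truth["is_eupneic"]).to_numpy()
        guard = irr.copy()
        for k in range(1, model.transition_guard + 1):
            guard[k:] |= irr[:-k]
            guard[:-k] |= irr[k:]
        truth["is_eupneic"] = ~guard
    return FlowTrace(
        t=t,
        flow=flow,
        fs=fs,
        truth=truth,
        meta={"preset": preset.name, "seed": seed, "duration": duration},
    )


def _rate_factor(pressure: float) -> float:
    """Burst-rate reduction with inflation-hold pressure (linear in the
    anchor table; apnea at 20 cmH2O)."""
    anchors = {2.0: 1.0, 6.0: 0.9, 8.0: 0.8, 10.0: 0.6, 20.0: 0.0}
    ps = sorted(anchors)
    return float(np.interp(pressure, ps, [anchors[p] for p in ps]))


def simulate_emg(
    protocol: VentilationProtocol | None = None,
    preset: ScenarioPreset | str = "control",
    seed: int = 0,
    fs: float = 2000.0,
) -> EMGTrace:
    """Simulate a diaphragm EMG trace under a ventilation-hold protocol.

    Bursts are half-sine envelopes multiplying broadband carrier noise.
    During an inflation hold at pressure p the burst duration is scaled by
    the preset's ``emg_ti_curve[p]`` (0 ⇒ apnea) and the burst rate by a
    pressure-dependent factor; deflation holds leave bursts at baseline.
    """
    protocol = protocol or VentilationProtocol()
    protocol.validate()
    if isinstance(preset, str):
        preset = PRESETS[preset]
    for kind, p, _ in protocol.hold_schedule:
        if kind == "inflation" and p not in preset.emg_ti_curve:
            raise ConfigurationError(f"no emg_ti_curve entry for pressure {p}")

    rng = np.random.default_rng(seed)
    base_period = 60.0 / protocol.rate
    base_ti = base_period * protocol.ie_ratio / (1 + protocol.ie_ratio)

    segments: list[tuple[str, float, float]] = [("baseline", np.nan, protocol.inter_hold_gap)]
    for kind, p, dur in protocol.hold_schedule:
        segments.append((kind, p, dur))
        segments.append(("baseline", np.nan, protocol.inter_hold_gap))

    total = sum(s[2] for s in segments)
    n_total = int(round(total * fs))
    env = np.zeros(n_total)
    rows: list[dict] = []
    hold_windows: list[dict] = []
    t0 = 0.0
    for kind, p, dur in segments:
        if kind == "baseline" or kind == "deflation":
            dur_factor, rate_factor = 1.0, 1.0
        else:
            dur_factor = preset.emg_ti_curve[p]
            rate_factor = _rate_factor(p)
        if kind != "baseline":
            hold_windows.append({"type": kind, "pressure": p, "start": t0, "end": t0 + dur})
        if dur_factor > 0 and rate_factor > 0:
            period = base_period / rate_factor
            tb = t0 + 0.05
            while tb + base_ti * dur_factor < t0 + dur:
                d = base_ti * dur_factor * np.exp(rng.normal(0, 0.03))
                amp = 1.0 * np.exp(rng.normal(0, 0.05))
                i0 = int(round(tb * fs))
                n = max(2, int(round(d * fs)))
                env[i0 : i0 + n] = np.maximum(
                    env[i0 : i0 + n], amp * np.sin(np.pi * np.arange(min(n, n_total - i0)) / n)
                )
                rows.append(
                    {"onset": tb, "duration": d, "amplitude": amp, "segment": kind, "pressure": p}
                )
                tb += period * np.exp(rng.normal(0, 0.02))
        t0 += dur
    carrier = rng.normal(0, 1.0, size=n_total)
    emg = env * carrier + rng.normal(0, 0.02, size=n_total)
    t = np.arange(n_total) / fs
    return EMGTrace(
        t=t,
        emg=emg,
        fs=fs,
        hold_windows=hold_windows,
        truth=pd.DataFrame(rows),
        meta={"preset": preset.name, "seed": seed},
    )


def default_calcium_cohort(seed: int = 0) -> list[CalciumProfile]:
    """Default 29-cell imaging cohort: 11 inflation responders (7 slowly
    adapting type I, 4 type II) and 18 non-responders, with type I cells
    drawn from the large-soma population."""
    rng = np.random.default_rng(seed)
    cohort: list[CalciumProfile] = []
    k = 0
    for _ in range(7):
        cohort.append(
            CalciumProfile(f"cell{k:02d}", "typeI_slow", soma_diameter_um=float(rng.normal(34, 2)))
        )
        k += 1
    for _ in range(4):
        cohort.append(
            CalciumProfile(f"cell{k:02d}", "typeII_slow", soma_diameter_um=float(rng.normal(27, 2)))
        )
        k += 1
    for _ in range(18):
        cohort.append(
            CalciumProfile(
                f"cell{k:02d}", "nonresponder", soma_diameter_um=float(rng.normal(20, 3))
            )
        )
        k += 1
    return cohort


def _class_response(cls: str, amplitude: float, tau: float, kind: str, pressure: float, tt: np.ndarray):
    """Mean ΔF/F during one hold, as a function of time-in-hold tt."""
    rise = 1.0 - np.exp(-tt / 0.3)
    if cls == "typeI_slow":
        if kind == "inflation":
            return amplitude * (1.0 if pressure >= 20 else 0.7) * rise
        return -0.5 * amplitude * rise  # deflation: drops below baseline
    if cls == "typeII_slow":
        if kind == "inflation" and pressure >= 20:
            return amplitude * rise
        return np.zeros_like(tt)
    if cls == "rapid_adapt":
        if kind == "inflation" and pressure >= 20:
            return amplitude * np.exp(-tt / tau)
        return np.zeros_like(tt)
    if cls == "inflation_suppressed":
        if kind == "inflation":
            return -amplitude * rise
        return np.zeros_like(tt)
    return np.zeros_like(tt)


def simulate_calcium(
    profiles: list[CalciumProfile],
    protocol: VentilationProtocol | None = None,
    seed: int = 0,
    fs: float = 20.0,
) -> list[CalciumTrace]:
    """Simulate ΔF/F traces for a cohort of neurons under the hold protocol.

    The protocol must include inflation holds at 20 and 10 cmH2O and a
    deflation hold at 2 cmH2O (the classification assay).
    """
    if not profiles:
        raise InputError("empty profile list")
    protocol = protocol or VentilationProtocol()
    protocol.validate()
    have = {(k, p) for k, p, _ in protocol.hold_schedule}
    for req in [("inflation", 20.0), ("inflation", 10.0), ("deflation", 2.0)]:
        if req not in have:
            raise InputError(f"protocol must include a {req[0]} hold at {req[1]} cmH2O")
    rng = np.random.default_rng(seed)

    segments: list[tuple[str, float, float]] = [("baseline", np.nan, protocol.inter_hold_gap)]
    for kind, p, dur in protocol.hold_schedule:
        segments.append((kind, p, dur))
        segments.append(("baseline", np.nan, protocol.inter_hold_gap))
    total = sum(s[2] for s in segments)
    n_total = int(round(total * fs))
    t = np.arange(n_total) / fs

    traces = []
    for prof in profiles:
        prof.validate()
        dff = np.zeros(n_total)
        hold_windows = []
        t0 = 0.0
        for kind, p, dur in segments:
            if kind != "baseline":
                i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
                tt = np.arange(i1 - i0) / fs
                dff[i0:i1] = _class_response(prof.cls, prof.amplitude, prof.tau_adapt, kind, p, tt)
                hold_windows.append({"type": kind, "pressure": p, "start": t0, "end": t0 + dur})
            t0 += dur
        if prof.noise_sd > 0:
            dff = dff + rng.normal(0, prof.noise_sd, size=n_total)
        traces.append(
            CalciumTrace(
                cell_id=prof.cell_id,
                t=t,
                dff=dff,
                fs=fs,
                hold_windows=hold_windows,
                truth_class=prof.cls,
                soma_diameter_um=prof.soma_diameter_um,
            )
        )
    return traces
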