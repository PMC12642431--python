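"""Breath segmentation, eupnea selection, and KDE-peak effect estimation.

A whole-body-plethysmography airflow trace (inspiration positive) is
low-pass filtered and segmented at positive-going zero crossings with a
hysteresis band; per-breath parameters (Ti, Te, TV, PIF, PEF, rate, minute
ventilation) are computed, eupneic breaths are selected by a windowed
coefficient-of-variation regularity rule, and per-animal effects of an
intervention are summarized as the percentage shift of the kernel-density
peak of a parameter's eupneic distribution, compared across groups with the
Mann-Whitney U test.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import ConfigurationError, InputError
from .sim.physio import FlowTrace

__all__ = [
    "BreathTable",
    "EffectEstimate",
    "segment_breaths",
    "select_eupnea",
    "kde_peak",
    "effect_estimate",
    "group_compare",
]

PARAMETERS = ("tv", "ti", "te", "pif", "pef", "f", "mv")


@dataclass
class BreathTable:
    breaths: pd.DataFrame  # onset, ti, te, tv, pif, pef, f, mv
    eupnea_mask: np.ndarray | None = None
    selection_params: dict | None = None

    def __len__(self) -> int:
        return len(self.breaths)

    def eupneic(self) -> pd.DataFrame:
        if self.eupnea_mask is None:
            raise InputError("eupnea selection has not been run")
        return self.breaths[self.eupnea_mask]


@dataclass
class EffectEstimate:
    parameter: str
    pre_peak: float
    post_peak: float
    delta_pct: float
    animal_id: str | None = None


def segment_breaths(
    trace: FlowTrace | tuple[np.ndarray, float],
    lowpass_hz: float = 20.0,
    hysteresis_frac: float = 0.02,
) -> BreathTable:
    """Delimit breaths at positive-going zero crossings of filtered flow.

    The flow is filtered with a zero-phase 4th-order Butterworth low-pass
    (default 20 Hz); crossings use a hysteresis band of ±``hysteresis_frac``
    times the trace SD. Tidal volume is the trapezoidal integral of
    inspiratory flow; PIF/PEF are the filtered extrema of each phase; the
    rate comes from the full cycle period and MV = TV × f.

    Accepts a :class:`FlowTrace` or a ``(flow, fs)`` tuple. A trace with no
    zero crossings yields an empty table with a warning.
    """
    if isinstance(trace, FlowTrace):
        flow, fs = trace.flow, trace.fs
    else:
        flow, fs = np.asarray(trace[0], dtype=float), float(trace[1])
    if len(flow) < 10:
        raise InputError("trace too short")
    sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, flow)
    h = hysteresis_frac * filt.std()
    state = np.where(filt > h, 1, np.where(filt < -h, -1, 0))
    # propagate last nonzero state through the dead band
    nz = state != 0
    idx = np.where(nz, np.arange(len(state)), 0)
    np.maximum.accumulate(idx, out=idx)
    state = state[idx]
    trans = np.diff(state)
    onsets = np.where((trans == 2) | ((trans == 1) & (state[1:] == 1)))[0] + 1
    # keep only true -1 -> +1 transitions
    onsets = np.array([i for i in onsets if state[i] == 1 and state[i - 1] == -1])
    if len(onsets) < 2 or h == 0:
        _warnings.warn("no breaths detected", stacklevel=2)
        return BreathTable(
            breaths=pd.DataFrame(columns=["onset", "ti", "te", "tv", "pif", "pef", "f", "mv"])
        )
    rows = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = state[a:b]
        downs = np.where((seg[:-1] == 1) & (seg[1:] == -1))[0]
        if len(downs) == 0:
            continue
        mid = a + downs[0] + 1
        ti = (mid - a) / fs
        te = (b - mid) / fs
        insp = filt[a:mid]
        tv = float(np.trapezoid(insp, dx=1.0 / fs))
        if ti <= 0 or te <= 0 or tv <= 0:
            continue
        period = (b - a) / fs
        f_bpm = 60.0 / period
        rows.append(
            {
                "onset": a / fs,
                "ti": ti,
                "te": te,
                "tv": tv,
                "pif": float(insp.max()),
                "pef": float(-filt[mid:b].min()),
                "f": f_bpm,
                "mv": tv * f_bpm,
            }
        )
    return BreathTable(breaths=pd.DataFrame(rows))


def select_eupnea(table: BreathTable, window: int = 9, cv_max: float = 0.15) -> BreathTable:
    """Mark breaths as eupneic by local regularity.

    A breath is eupneic iff, within its centered window of ``window``
    breaths, the coefficient of variation of both the cycle period and the
    tidal volume is at most ``cv_max`` and no parameter is missing. Breaths
    whose window falls off either end of the record are not eupneic.
    """
    if window % 2 == 0:
        raise ConfigurationError("window must be odd (centered)")
    df = table.breaths
    n = len(df)
    mask = np.zeros(n, dtype=bool)
    if n < window:
        _warnings.warn("record shorter than the eupnea window; no breaths selected", stacklevel=2)
        return BreathTable(df, mask, {"window": window, "cv_max": cv_max})
    period = (df["ti"] + df["te"]).to_numpy()
    tv = df["tv"].to_numpy()
    ok = np.isfinite(period) & np.isfinite(tv)
    half = window // 2
    for i in range(half, n - half):
        sl = slice(i - half, i + half + 1)
        if not ok[sl].all():
            continue
        p, v = period[sl], tv[sl]
        if p.std() / p.mean() <= cv_max and v.std() / v.mean() <= cv_max:
            mask[i] = True
    return BreathTable(df, mask, {"window": window, "cv_max": cv_max})


def kde_peak(values: np.ndarray, bw_method: str = "silverman") -> float:
    """Location of the maximum of a Gaussian kernel density estimate.

    Silverman bandwidth by default, evaluated on a 512-point grid spanning
    [min − 3h, max + 3h]. Requires >= 10 values; identical values return
    their common value directly.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise InputError("need at least 10 values for a KDE peak")
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    h = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 512)
    return float(grid[np.argmax(kde(grid))])


def effect_estimate(
    pre: BreathTable, post: BreathTable, parameter: str, animal_id: str | None = None
) -> EffectEstimate:
    """Percentage change of the eupneic KDE peak of one breath parameter."""
    parameter = parameter.lower()
    if parameter not in PARAMETERS:
        raise InputError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")
    vals = []
    for tbl in (pre, post):
        eup = tbl.eupneic()
        if len(eup) < 10:
            raise InputError("need >= 10 eupneic breaths in each condition")
        vals.append(eup[parameter].to_numpy())
    pre_peak = kde_peak(vals[0])
    post_peak = kde_peak(vals[1])
    if pre_peak <= 0:
        raise InputError("pre-condition peak must be positive")
    return EffectEstimate(
        parameter=parameter,
        pre_peak=pre_peak,
        post_peak=post_peak,
        delta_pct=(post_peak - pre_peak) / pre_peak * 100.0,
        animal_id=animal_id,
    )


def group_compare(
    control: list[EffectEstimate] | np.ndarray, treated: list[EffectEstimate] | np.ndarray
) -> dict:
    """Two-sided Mann-Whitney U comparison of per-animal effect estimates.

    Exact null distribution when both groups have <= 8 animals and there are
    no ties; otherwise the tie-corrected normal approximation. Reports the U
    statistic (number of (treated, control) pairs with treated > control,
    counting ties as half), group means and standard errors.
    """

    def _vals(group):
        if len(group) == 0:
            raise InputError("empty group")
        if isinstance(group[0], EffectEstimate):
            return np.array([e.delta_pct for e in group], dtype=float)
        return np.asarray(group, dtype=float)

    x, y = _vals(treated), _vals(control)
    if np.ptp(np.concatenate([x, y])) == 0:  # degenerate: everything tied
        from types import SimpleNamespace

        res = SimpleNamespace(statistic=len(x) * len(y) / 2.0, pvalue=1.0)
        method = "degenerate"
    else:
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_value": float(min(1.0, res.pvalue)),
        "method": method,
        "mean_treated": float(x.mean()),
        "sem_treated": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
        "mean_control": float(y.mean()),
        "sem_control": float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else np.nan,
        "n_treated": len(x),
        "n_control": len(y),
    }
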