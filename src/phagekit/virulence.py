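"""Kill-curve virulence indexing.

Local virulence at one multiplicity of infection (MOI) compares growth
with and without phage over a fixed window ending at the onset of
stationary phase in the uninfected control:

    v = 1 - AUC_phage / AUC_control

where AUC is the trapezoidal area under the OD600 curve.  The global
virulence index (GVI) is the area under the local-virulence-versus-
log10(MOI) curve normalized by the log-MOI range, so it runs from 0 (no
measurable virulence) to 1 (complete suppression of growth at every MOI
tested).  For decade-spaced MOIs the normalizing divisor equals
(number of MOIs - 1), e.g. 6 for log MOI -3..3.  GVI values are only
comparable between experiments that used the same MOI ladder.

Local virulence is deliberately not clamped at zero: values below zero
flag conditions where the infected culture outgrew the control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .io_tables import GrowthCurve, KillCurvePanel

__all__ = [
    "OnsetResult",
    "VirulenceProfile",
    "detect_stationary_onset",
    "auc",
    "local_virulence",
    "global_virulence_index",
    "virulence_profile",
]


class OnsetResult(NamedTuple):
    time: float
    flagged: bool  # True when no plateau was found and the last time was returned


@dataclass
class VirulenceProfile:
    entries: list[tuple[float, float]]  # (log10 MOI, local virulence), sorted
    gvi: float
    window: tuple[float, float]
    temperature: str = ""

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[0])


def detect_stationary_onset(
    control: GrowthCurve, frac: float = 0.05, window: int = 3
) -> OnsetResult:
    """Detect the onset of stationary phase in a control growth curve.

    The curve is smoothed with a centered moving average of ``window``
    points; the onset is the earliest time after the point of maximum
    slope at which the slope stays below ``frac`` times the maximum slope
    for ``window`` consecutive intervals.  If the slope never settles the
    last time point is returned with ``flagged=True``.
    """
    if len(control) < 2 * window:
        raise ValueError(f"control curve needs at least {2 * window} points")
    t, od = control.times, control.od
    half = window // 2
    smooth = np.array(
        [od[max(0, i - half) : i + half + 1].mean() for i in range(od.size)]
    )
    slopes = np.diff(smooth) / np.diff(t)
    i_max = int(np.argmax(slopes))
    max_slope = slopes[i_max]
    if max_slope <= 0:
        return OnsetResult(float(t[-1]), True)
    below = slopes < frac * max_slope
    for j in range(i_max + 1, slopes.size - window + 1):
        if below[j : j + window].all():
            return OnsetResult(float(t[j]), False)
    return OnsetResult(float(t[-1]), True)


def _snap(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def auc(
    curve: GrowthCurve, t0: float, t1: float, baseline: str = "none"
) -> float:
    """Trapezoidal area under the OD curve over [t0, t1] (OD600 * h).

    t0 and t1 are snapped to the nearest grid points.  With
    ``baseline="subtract_t0"`` the OD at t0 is subtracted first and
    negative values floored at zero.
    """
    if t0 >= t1:
        raise ValueError("t0 must be less than t1")
    eps = 1e-9
    if t0 < curve.times[0] - eps or t1 > curve.times[-1] + eps:
        raise ValueError(
            f"window [{t0}, {t1}] outside curve grid "
            f"[{curve.times[0]}, {curve.times[-1]}]"
        )
    i0, i1 = _snap(curve.times, t0), _snap(curve.times, t1)
    if i0 >= i1:
        raise ValueError("window snaps to fewer than two grid points")
    od = curve.od[i0 : i1 + 1]
    if baseline == "subtract_t0":
        od = np.maximum(od - od[0], 0.0)
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(od, curve.times[i0 : i1 + 1]))


def local_virulence(
    phage: GrowthCurve, control: GrowthCurve, t0: float, t1: float,
    baseline: str = "none",
) -> float:
    """Local virulence v = 1 - AUC_phage / AUC_control over [t0, t1].

    Not clamped: v < 0 means the infected culture accumulated more
    biomass than the control over the window.
    """
    if not np.array_equal(phage.times, control.times):
        raise ValueError("phage and control curves must share a time grid")
    denom = auc(control, t0, t1, baseline=baseline)
    if denom <= 0:
        raise ValueError("control AUC must be positive")
    return 1.0 - auc(phage, t0, t1, baseline=baseline) / denom


def global_virulence_index(entries: Sequence[tuple[float, float]]) -> float:
    """Normalized area under local virulence vs log10(MOI).

    The divisor is the log-MOI range, which equals (count - 1) for
    decade-spaced MOIs; this keeps the index in [0, 1] whenever every
    local virulence is in [0, 1], for any MOI spacing.
    """
    if len(entries) < 2:
        raise ValueError("need at least two (log_moi, v) entries")
    entries = sorted(entries, key=lambda e: e[0])
    x = np.array([e[0] for e in entries], dtype=float)
    v = np.array([e[1] for e in entries], dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("log MOI values must be distinct")
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def virulence_profile(
    panel: KillCurvePanel,
    onset: float | str = "auto",
    t_start: float = 0.0,
    baseline: str = "none",
) -> VirulenceProfile:
    """Local virulence per MOI plus the global virulence index for a panel.

    ``onset`` is either ``"auto"`` (detect stationary onset in the
    control) or an explicit window end in hours, mirroring analyses that
    fix the window by inspection of the control curve.
    """
    if onset == "auto":
        t1 = detect_stationary_onset(panel.control).time
    else:
        t1 = float(onset)
    entries = [
        (float(np.log10(moi)), local_virulence(curve, panel.control, t_start, t1, baseline))
        for moi, curve in panel.phage_curves
    ]
    gvi = global_virulence_index(entries)
    return VirulenceProfile(
        entries=entries, gvi=gvi, window=(t_start, t1), temperature=panel.temperature
    )
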