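"""Titer arithmetic, growth-rate estimation, one-step growth analysis and
adsorption-assay normalization."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_tables import TiterSeries

__all__ = [
    "OneStepResult",
    "GrowthRateResult",
    "titer_from_spot",
    "growth_rate",
    "one_step_analysis",
    "adsorption_remaining",
]


@dataclass
class OneStepResult:
    """Summary of a one-step growth curve.

    burst_size = P / I, where P (``p_max``) is the maximum titer after
    lysis and I (``initial``) is the phage initially added.
    """

    latent_period: float  # h
    burst_size: float     # virions per infected cell
    p_max: float          # PFU/mL
    initial: float        # PFU/mL
    baseline: float       # PFU/mL, pre-rise plateau


@dataclass
class GrowthRateResult:
    """Exponential growth rate mu (per hour) over a window.

    From log10(N) - log10(N0) = (mu / 2.303) * (t - t0).
    """

    mu: float
    window: tuple[float, float]
    n0: float
    n1: float


def titer_from_spot(count: int, dilution_exponent: int, volume_ul: float) -> float:
    """PFU/mL from a plaque count on a spotted serial dilution."""
    if count < 0:
        raise ValueError("plaque count must be non-negative")
    if volume_ul <= 0:
        raise ValueError("spot volume must be positive")
    return count * 10.0**dilution_exponent / (volume_ul / 1000.0)


def growth_rate(n0: float, n1: float, t0: float, t1: float) -> GrowthRateResult:
    """Growth rate mu = 2.303 * (log10 n1 - log10 n0) / (t1 - t0)."""
    if n0 <= 0 or n1 <= 0:
        raise ValueError("abundances must be positive")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    mu = 2.303 * (math.log10(n1) - math.log10(n0)) / (t1 - t0)
    return GrowthRateResult(mu=mu, window=(t0, t1), n0=n0, n1=n1)


def one_step_analysis(
    series: TiterSeries, rise_factor: float = 2.0, baseline_points: int = 2
) -> OneStepResult:
    """Latent period and burst size from a one-step titer series.

    The baseline is the mean of the first ``baseline_points`` titers; the
    latent period is the last sampled time before the titer first exceeds
    ``rise_factor`` times the baseline (a conservative, sampling-
    resolution-limited estimate); P is the maximum titer at or after that
    crossing, and the burst size is P divided by the phage initially added
    (the baseline when ``initial_phage`` was not recorded).
    """
    if len(series) < baseline_points + 2:
        raise ValueError(f"series needs at least {baseline_points + 2} points")
    pfu = series.pfu_per_ml
    baseline = float(pfu[:baseline_points].mean())
    if baseline <= 0:
        raise ValueError("baseline titer is zero")
    above = np.nonzero(pfu > rise_factor * baseline)[0]
    if above.size == 0:
        raise ValueError("no burst detected: titer never exceeds "
                         f"{rise_factor:g} x baseline")
    idx = int(above[0])
    latent = float(series.times[idx - 1]) if idx > 0 else float(series.times[0])
    p_max = float(pfu[idx:].max())
    initial = series.initial_phage if series.initial_phage is not None else baseline
    return OneStepResult(
        latent_period=latent,
        burst_size=p_max / initial,
        p_max=p_max,
        initial=float(initial),
        baseline=baseline,
    )


def adsorption_remaining(treated_supernatant_titer: float, control_titer: float) -> float:
    """Percentage of free phage remaining relative to the no-cell control.

    The control supernatant defines 100%; values above 100% are reported
    as-is (they indicate assay noise, not adsorption).
    """
    if control_titer <= 0:
        raise ValueError("control titer must be positive")
    if treated_supernatant_titer < 0:
        raise ValueError("titers must be non-negative")
    return 100.0 * treated_supernatant_titer / control_titer
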