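"""Tabular screening computations: virion-association filtering of
mass-spectrometry hits, LD50 estimation from larval dose-response data,
and serum-survival normalization."""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_tables import MassSpecRecord, SurvivalRecord

__all__ = ["filter_virion_associated", "ld50", "nhs_percent_survival"]


def filter_virion_associated(
    records: Sequence[MassSpecRecord], min_unique: int = 2
) -> tuple[list[MassSpecRecord], list[MassSpecRecord]]:
    """Partition proteins into virion-associated and unconfirmed.

    A protein counts as virion-associated when identified by at least
    ``min_unique`` unique medium-to-high-quality peptides; the rest are
    returned flagged ``unconfirmed`` rather than dropped, since a single
    peptide suggests but cannot confirm association.
    """
    passed, flagged = [], []
    for rec in records:
        if rec.unique_peptides >= min_unique:
            passed.append(replace(rec, status="confirmed"))
        else:
            flagged.append(replace(rec, status="unconfirmed"))
    return passed, flagged


def _fractions(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = sorted(records, key=lambda r: r.dose)
    doses = np.array([r.dose for r in recs], dtype=float)
    fracs = np.array([r.deaths / r.n for r in recs], dtype=float)
    return doses, fracs


def ld50(records: Sequence[SurvivalRecord], method: str = "interpolate") -> float:
    """Dose killing half the cohort, in the dose units of the records.

    ``interpolate`` (default) draws a straight line in death fraction vs
    log10(dose) between the two consecutive doses bracketing 0.5 —
    parameter-free and robust for sparse decade-spaced dose ladders.
    ``logistic`` fits a two-parameter log-logistic model
    p(dose) = 1 / (1 + (ld50/dose)^hill) by least squares and returns its
    midpoint.
    """
    if not records:
        raise ValueError("no survival records")
    doses, fracs = _fractions(records)

    exact = np.nonzero(np.abs(fracs - 0.5) < 1e-12)[0]
    if method == "interpolate":
        if exact.size:
            return float(doses[exact[0]])
        if len(records) < 2:
            raise ValueError("need at least two doses to interpolate")
        for i in range(doses.size - 1):
            lo, hi = fracs[i], fracs[i + 1]
            if (lo - 0.5) * (hi - 0.5) < 0:
                x0, x1 = math.log10(doses[i]), math.log10(doses[i + 1])
                x = x0 + (0.5 - lo) * (x1 - x0) / (hi - lo)
                return float(10.0**x)
        raise ValueError("death fractions never bracket 0.5; cannot interpolate")

    if method == "logistic":
        if len(records) < 2:
            raise ValueError("need at least two doses for a logistic fit")

        def model(logd, log_ld50, hill):
            return 1.0 / (1.0 + 10.0 ** (-hill * (logd - log_ld50)))

        logd = np.log10(doses)
        p0 = (float(np.median(logd)), 1.0)
        popt, _ = curve_fit(model, logd, fracs, p0=p0, maxfev=10000)
        return float(10.0 ** popt[0])

    raise ValueError(f"unknown method {method!r}")


def nhs_percent_survival(cfu_at_conc: float, cfu_at_zero: float) -> float:
    """Bacterial survival in serum as a percentage of the serum-free control."""
    if cfu_at_zero <= 0:
        raise ValueError("zero-serum control count must be positive")
    if cfu_at_conc < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * cfu_at_conc / cfu_at_zero
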