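"""Host-range scoring: efficiency of plating and qualitative clearing."""

from __future__ import annotations

from typing import NamedTuple, Sequence

from .io_tables import HostRangeRecord

__all__ = [
    "HostRangeSummary",
    "compute_eop",
    "format_eop",
    "qualitative_score",
    "summarize_host_range",
]

# lowest titer (PFU/mL) still producing confluent clearing -> score;
# lower clearing titer means higher sensitivity, hence more '+'
_QUAL_BY_TITER = {1e10: "+", 1e9: "++", 1e8: "+++"}


class HostRangeSummary(NamedTuple):
    total: int
    any_activity: int     # plaques or clearing at some titer
    plaque_forming: int   # numeric EOP available


def compute_eop(pfu_test: float, pfu_host: float) -> float:
    """Efficiency of plating: titer on the test strain over titer on the
    reference host.  Only meaningful for strains on which plaques formed.
    """
    if pfu_host <= 0:
        raise ValueError("reference host titer must be positive")
    if pfu_test < 0:
        raise ValueError("test titer must be non-negative")
    return pfu_test / pfu_host


def format_eop(eop: float) -> str:
    """Render an EOP with two significant figures (table style)."""
    if eop == 0:
        return "0"
    return f"{eop:.2g}"


def qualitative_score(lowest_clearing_titer: float | None) -> str:
    """Map the lowest spotted titer still clearing to a '+' score.

    10^10 -> '+', 10^9 -> '++', 10^8 -> '+++', None -> 'ND'.  Titers off
    this three-decade scale are rejected rather than extrapolated.
    """
    if lowest_clearing_titer is None:
        return "ND"
    for titer, score in _QUAL_BY_TITER.items():
        if abs(lowest_clearing_titer / titer - 1.0) < 1e-6:
            return score
    raise ValueError(
        f"clearing titer {lowest_clearing_titer:g} outside the scored scale "
        "(1e8, 1e9, 1e10 PFU/mL)"
    )


def summarize_host_range(records: Sequence[HostRangeRecord]) -> HostRangeSummary:
    """Panel totals: strains tested, strains with any lytic activity, and
    strains supporting plaque formation (numeric EOP)."""
    total = len(records)
    any_activity = sum(1 for r in records if r.eop is not None or r.qual is not None)
    plaque_forming = sum(1 for r in records if r.eop is not None)
    return HostRangeSummary(total, any_activity, plaque_forming)
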