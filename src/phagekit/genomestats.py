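"""Genome-level summary statistics and integration-site analyses.

Coordinates follow the printed annotation dialect (1-based inclusive,
minus strand written start > end); att-overlap hits are reported 0-based
half-open.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from Bio.Seq import Seq

from .io_tables import AnnotatedGenome

__all__ = [
    "trim_terminal_repeat",
    "coding_density",
    "gc_content",
    "boundary_codon_usage",
    "AttOverlap",
    "find_att_overlap",
    "FrameCheck",
    "frame_preservation_check",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trim_terminal_repeat(
    sequence: str, max_repeat: int = 50, min_repeat: int = 4
) -> tuple[str, int]:
    """Remove one copy of a direct terminal repeat from a contig.

    Headful-packaged, circularly permuted genomes assemble with the same
    sequence duplicated at both contig ends; the true genome length drops
    the trailing copy.  Finds the longest exact repeat of length in
    [``min_repeat``, ``max_repeat``] shared by the prefix and the suffix
    and trims it from the end; returns (trimmed sequence, repeat length),
    with repeat length 0 when no repeat is present.  ``min_repeat``
    screens out 1-3 bp coincidences that any sequence ends with.
    """
    if len(sequence) <= 2 * max_repeat:
        raise ValueError("sequence must be longer than twice max_repeat")
    for k in range(max_repeat, min_repeat - 1, -1):
        if sequence[:k] == sequence[-k:]:
            return sequence[:-k], k
    return sequence, 0


def coding_density(genome: AnnotatedGenome) -> float:
    """Percentage of the genome covered by at least one annotated gene.

    Both strands are pooled and overlapping genes (nested lysis genes,
    overlapping start/stop codons) are counted once via interval union.
    """
    if not genome.genes:
        raise ValueError("genome has no genes")
    intervals = sorted(g.interval() for g in genome.genes)
    covered = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi + 1:
            covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo + 1
    return 100.0 * covered / genome.length


def gc_content(sequence: str) -> float:
    """G+C percentage of a nucleotide sequence.

    Ambiguity codes are excluded from numerator and denominator; a
    sequence with no unambiguous bases is rejected.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def ambiguous_base_count(sequence: str) -> int:
    """Number of non-ACGT characters (excluded from GC computations)."""
    s = sequence.upper()
    return len(s) - sum(s.count(b) for b in "ACGT")


def boundary_codon_usage(genome: AnnotatedGenome) -> tuple[dict, dict]:
    """Tallies of start and stop codons across all annotated genes.

    For plus-strand genes the start codon is bases [start, start+2]; for
    minus-strand genes (printed start > end) it is the reverse complement
    of bases [start-2, start], and stop codons sit at the opposite gene
    end.  Returns ({ATG, GTG, TTG, other}, {TAA, TAG, TGA, other}).
    """
    if genome.sequence is None:
        raise ValueError("codon usage requires the genome sequence")
    seq = genome.sequence
    start_counts = {"ATG": 0, "GTG": 0, "TTG": 0, "other": 0}
    stop_counts = {"TAA": 0, "TAG": 0, "TGA": 0, "other": 0}
    for g in genome.genes:
        if g.strand == "+":
            start_codon = seq[g.start - 1 : g.start + 2]
            stop_codon = seq[g.end - 3 : g.end]
        else:
            start_codon = _revcomp(seq[g.start - 3 : g.start])
            stop_codon = _revcomp(seq[g.end - 1 : g.end + 2])
        if len(start_codon) != 3 or len(stop_codon) != 3:
            raise ValueError(f"gene {g.gene_id}: codon extraction outside sequence")
        start_counts[start_codon if start_codon in start_counts else "other"] += 1
        stop_counts[stop_codon if stop_codon in stop_counts else "other"] += 1
    return start_counts, stop_counts


class AttOverlap(NamedTuple):
    """A shared (near-)identical segment between two sequences.

    Offsets are 0-based half-open: the segment is
    ``a[offset_a : offset_a + length]`` vs ``b[offset_b : offset_b + length]``.
    """

    offset_a: int
    offset_b: int
    length: int
    mismatches: int


def find_att_overlap(
    seq_a: str, seq_b: str, min_len: int = 12, max_mismatch: int = 1
) -> AttOverlap | None:
    """Longest common segment of two sequences with bounded mismatches.

    Scans every alignment diagonal with a sliding window, returning the
    longest pair of equal-length substrings differing at no more than
    ``max_mismatch`` positions and at least ``min_len`` long.  Ties are
    broken by fewer mismatches, then smaller ``offset_a``, then smaller
    ``offset_b``.  Returns None when no qualifying segment exists — e.g.
    between unrelated sequences, where attachment-site detection should
    come up empty.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    na, nb = a.size, b.size
    best: AttOverlap | None = None

    def better(cand: AttOverlap) -> bool:
        if best is None:
            return True
        return (-cand.length, cand.mismatches, cand.offset_a, cand.offset_b) < (
            -best.length, best.mismatches, best.offset_a, best.offset_b,
        )

    for d in range(-(nb - 1), na):  # d = offset_a - offset_b
        i0 = max(0, d)
        j0 = i0 - d
        span = min(na - i0, nb - j0)
        if span < min_len:
            continue
        mism = (a[i0 : i0 + span] != b[j0 : j0 + span]).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(mism)))
        left = 0
        for right in range(span):
            while csum[right + 1] - csum[left] > max_mismatch:
                left += 1
            length = right - left + 1
            if length < min_len:
                continue
            cand = AttOverlap(
                offset_a=i0 + left,
                offset_b=j0 + left,
                length=length,
                mismatches=int(csum[right + 1] - csum[left]),
            )
            if better(cand):
                best = cand
    return best


class FrameCheck(NamedTuple):
    in_frame: bool
    alt_start_offset: int | None  # bp from alternative ATG to the junction
    aa_changes: int | None        # differing residues over the compared codons


def frame_preservation_check(
    hybrid_5prime: str,
    reference_cds: str,
    upstream_window: int = 30,
    n_compare: int = 10,
) -> FrameCheck:
    """Test whether a sequence junction preserves a gene's reading frame.

    Models prophage integration into the 5' end of a gene: the hybrid
    sequence carries foreign (phage-derived) sequence up to a junction,
    followed by the downstream remainder of the reference CDS.  The
    junction is located as the longest suffix of ``hybrid_5prime``
    occurring verbatim in ``reference_cds``; the window of
    ``upstream_window`` bases before the junction is then scanned for the
    ATG nearest the junction that is in frame with the downstream
    reference remainder.  When one exists, the first ``n_compare`` codons
    of the rescued hybrid gene are translated (bacterial code) against the
    reference start and differing residues counted.
    """
    hybrid = hybrid_5prime.upper()
    ref = reference_cds.upper()
    if ref[:3] not in ("ATG", "GTG", "TTG"):
        raise ValueError("reference CDS must begin with a start codon")
    ref_offset = None
    for j0 in range(len(hybrid)):
        pos = ref.find(hybrid[j0:])
        if pos != -1:
            junction, ref_offset = j0, pos
            break
    if ref_offset is None:
        raise ValueError("hybrid shares no suffix with the reference CDS")

    alt_start = None
    for p in range(junction, max(-1, junction - upstream_window - 1), -1):
        if hybrid[p : p + 3] == "ATG" and (junction - p) % 3 == ref_offset % 3:
            alt_start = p
            break
    if alt_start is None:
        return FrameCheck(False, None, None)

    n_nt = 3 * n_compare
    hyb_pep = str(Seq(hybrid[alt_start : alt_start + n_nt]).translate(table=11))
    ref_pep = str(Seq(ref[:n_nt]).translate(table=11))
    n = min(len(hyb_pep), len(ref_pep))
    changes = sum(1 for x, y in zip(hyb_pep[:n], ref_pep[:n]) if x != y)
    return FrameCheck(True, junction - alt_start, changes)
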