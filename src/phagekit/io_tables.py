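"""Domain containers and tabular/sequence I/O.

All downstream analyses operate on a small set of validated containers:
plate-reader growth curves and kill-curve panels, phage titer series,
genome annotation records, host-range records, mass-spectrometry protein
records and larval dose-response records.

Coordinate dialect for gene annotations: 1-based inclusive positions as
printed in phage annotation tables, with minus-strand genes written as
``start > end``.  :func:`GeneRecord.interval` normalizes this to a
``(low, high)`` pair.

Packaged reference tables (under ``phagekit/data``) are verbatim
transcriptions of the published characterization of *Burkholderia*
phage JC1: the 85-strain host-range panel (``table1``), the 76-gene
genome annotation (``table3``) and the virion proteomics table
(``table6``); load them with :func:`load_fixture`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GrowthCurve",
    "KillCurvePanel",
    "TiterSeries",
    "GeneRecord",
    "AnnotatedGenome",
    "HostRangeRecord",
    "MassSpecRecord",
    "SurvivalRecord",
    "read_growth_panel",
    "write_growth_panel",
    "read_titer_series",
    "write_titer_series",
    "read_survival_table",
    "write_survival_table",
    "read_mass_spec",
    "read_host_range",
    "read_annotations",
    "read_fasta",
    "write_fasta",
    "load_fixture",
]

QUAL_SCORES = ("+", "++", "+++")


# ---------------------------------------------------------------------------
# containers


@dataclass
class GrowthCurve:
    """A time-ordered OD600 series for one culture condition."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("growth curve needs at least two time points")
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times must be strictly increasing ({self.label!r})")
        if np.any(self.od < 0):
            raise ValueError(f"negative OD values in curve {self.label!r}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class KillCurvePanel:
    """An uninfected control curve plus phage-challenged curves keyed by MOI.

    All curves share one time grid; MOIs are unique and positive.
    """

    control: GrowthCurve
    phage_curves: list[tuple[float, GrowthCurve]]
    temperature: str = ""

    def __post_init__(self) -> None:
        mois = [m for m, _ in self.phage_curves]
        if any(m <= 0 for m in mois):
            raise ValueError("MOIs must be positive")
        if len(set(mois)) != len(mois):
            raise ValueError("duplicate MOIs in panel")
        for moi, curve in self.phage_curves:
            if not np.array_equal(curve.times, self.control.times):
                raise ValueError(
                    f"curve for MOI {moi:g} is not on the control time grid"
                )
        self.phage_curves = sorted(self.phage_curves, key=lambda mc: mc[0])

    @property
    def mois(self) -> list[float]:
        return [m for m, _ in self.phage_curves]


@dataclass
class TiterSeries:
    """Free-phage titer (PFU/mL) against time; the one-step growth object."""

    times: np.ndarray
    pfu_per_ml: np.ndarray
    initial_phage: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pfu_per_ml = np.asarray(self.pfu_per_ml, dtype=float)
        if self.times.size != self.pfu_per_ml.size:
            raise ValueError("times and pfu_per_ml must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pfu_per_ml < 0):
            raise ValueError("negative titers")
        if self.initial_phage is not None and self.initial_phage <= 0:
            raise ValueError("initial_phage must be positive when supplied")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class GeneRecord:
    """One annotated protein-coding gene in the printed coordinate dialect."""

    gene_id: int
    start: int
    end: int
    strand: str
    aa_length: int
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start == self.end:
            raise ValueError(f"gene {self.gene_id}: zero-length gene")
        if (self.strand == "-") != (self.start > self.end):
            raise ValueError(
                f"gene {self.gene_id}: strand {self.strand} inconsistent with "
                f"coordinates {self.start}..{self.end} (minus strand is "
                "written start > end)"
            )
        if self.span % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: span {self.span} not divisible by 3")

    @property
    def span(self) -> int:
        """Gene length in bp, including the stop codon."""
        return abs(self.end - self.start) + 1

    def interval(self) -> tuple[int, int]:
        """Normalized (low, high) 1-based inclusive interval."""
        return (min(self.start, self.end), max(self.start, self.end))


@dataclass
class AnnotatedGenome:
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared {self.length}"
                )
        for g in self.genes:
            low, high = g.interval()
            if low < 1 or high > self.length:
                raise ValueError(
                    f"gene {g.gene_id} interval {low}..{high} outside genome "
                    f"of length {self.length}"
                )


@dataclass
class HostRangeRecord:
    """Outcome of spotting a phage dilution series on one bacterial strain.

    Exactly one of ``eop``/``qual`` may be set; a strain with neither and
    ``detected=False`` showed no lysis at any titer tested.
    """

    strain: str
    species: str = ""
    eop: float | None = None
    qual: str | None = None
    detected: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if self.eop is not None and self.qual is not None:
            raise ValueError(f"{self.strain}: eop and qual are mutually exclusive")
        if self.qual is not None and self.qual not in QUAL_SCORES:
            raise ValueError(f"{self.strain}: invalid qualitative score {self.qual!r}")
        if not self.detected and (self.eop is not None or self.qual is not None):
            raise ValueError(f"{self.strain}: undetected strains carry no score")
        if self.eop is not None and self.eop < 0:
            raise ValueError(f"{self.strain}: negative EOP")


@dataclass
class MassSpecRecord:
    protein: str
    score: float
    coverage: float
    unique_peptides: int
    putative_function: str = ""
    status: str = ""

    def __post_init__(self) -> None:
        if self.unique_peptides < 0:
            raise ValueError(f"{self.protein}: negative unique peptide count")
        if not 0 <= self.coverage <= 100:
            raise ValueError(f"{self.protein}: coverage {self.coverage} outside [0, 100]")


@dataclass
class SurvivalRecord:
    """One dose group in a larval lethality assay."""

    dose: float
    n: int
    deaths: int
    horizon: float = 96.0

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 <= self.deaths <= self.n:
            raise ValueError(f"deaths {self.deaths} outside [0, n={self.n}]")


# ---------------------------------------------------------------------------
# growth panels


def read_growth_panel(
    path: str | Path, average_replicates: bool = True, temperature: str = ""
) -> KillCurvePanel:
    """Read a kill-curve panel from CSV.

    Expected columns: ``time_h``, ``condition``, ``replicate``, ``od600``;
    ``condition`` is the string ``control`` or a numeric MOI.  Replicates
    are averaged per time point unless ``average_replicates`` is False, in
    which case replicate 0 of each condition is kept.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"time_h", "condition", "replicate", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth panel missing columns: {sorted(missing)}")
    df["condition"] = df["condition"].astype(str)

    conditions = list(dict.fromkeys(df["condition"]))
    if "control" not in conditions:
        raise ValueError("growth panel has no 'control' condition")

    def build(cond: str) -> GrowthCurve:
        sub = df[df["condition"] == cond]
        if average_replicates:
            grouped = sub.groupby("time_h", sort=True)["od600"].mean()
            times, od = grouped.index.to_numpy(), grouped.to_numpy()
        else:
            rep0 = sorted(sub["replicate"].unique())[0]
            sub = sub[sub["replicate"] == rep0].sort_values("time_h")
            times, od = sub["time_h"].to_numpy(), sub["od600"].to_numpy()
        return GrowthCurve(times, od, label=cond)

    control = build("control")
    curves: list[tuple[float, GrowthCurve]] = []
    for cond in conditions:
        if cond == "control":
            continue
        curve = build(cond)
        if not np.array_equal(curve.times, control.times):
            raise ValueError(
                f"condition {cond!r} is not sampled on the control time grid"
            )
        curves.append((float(cond), curve))
    return KillCurvePanel(control=control, phage_curves=curves, temperature=temperature)


def write_growth_panel(panel: KillCurvePanel, path: str | Path) -> None:
    """Write a panel back to the ``read_growth_panel`` CSV dialect."""
    rows = []
    for cond, curve in [("control", panel.control)] + [
        (f"{moi:g}", c) for moi, c in panel.phage_curves
    ]:
        for t, od in zip(curve.times, curve.od):
            rows.append(
                {"time_h": t, "condition": cond, "replicate": curve.replicate, "od600": od}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# titer, survival, mass-spec and host-range tables


def read_titer_series(path: str | Path, initial_phage: float | None = None) -> TiterSeries:
    df = pd.read_csv(path, comment="#", float_precision="round_trip").sort_values("time_h")
    return TiterSeries(
        df["time_h"].to_numpy(), df["pfu_per_ml"].to_numpy(), initial_phage=initial_phage
    )


def write_titer_series(series: TiterSeries, path: str | Path) -> None:
    pd.DataFrame({"time_h": series.times, "pfu_per_ml": series.pfu_per_ml}).to_csv(
        path, index=False
    )


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, comment="#")
    horizon = df["horizon"] if "horizon" in df.columns else [96.0] * len(df)
    return [
        SurvivalRecord(dose=float(d), n=int(n), deaths=int(k), horizon=float(h))
        for d, n, k, h in zip(df["dose"], df["n"], df["deaths"], horizon)
    ]


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "dose": [r.dose for r in records],
            "n": [r.n for r in records],
            "deaths": [r.deaths for r in records],
            "horizon": [r.horizon for r in records],
        }
    ).to_csv(path, index=False)


def read_mass_spec(path: str | Path) -> list[MassSpecRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MassSpecRecord(
            protein=str(r.protein),
            score=float(r.score),
            coverage=float(r.coverage),
            unique_peptides=int(r.unique_peptides),
            putative_function=str(r.putative_function),
        )
        for r in df.itertuples()
    ]


def _parse_host_range_score(score: str) -> dict:
    score = score.strip()
    if score == "ND":
        return {"eop": None, "qual": None, "detected": False}
    if score in QUAL_SCORES:
        return {"eop": None, "qual": score, "detected": True}
    return {"eop": float(score), "qual": None, "detected": True}


def read_host_range(path: str | Path) -> list[HostRangeRecord]:
    """Read a host-range table (TSV: species, strain, score, source).

    ``score`` is a numeric EOP (scientific notation accepted), one of
    ``+``/``++``/``+++`` for lysis without plaques, or ``ND``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = []
    for r in df.itertuples():
        records.append(
            HostRangeRecord(
                strain=r.strain,
                species=r.species,
                source=getattr(r, "source", ""),
                **_parse_host_range_score(r.score),
            )
        )
    return records


# ---------------------------------------------------------------------------
# annotations and sequences


def _gene_from_printed(gene_id, start, end, strand, product="") -> GeneRecord:
    span = abs(int(end) - int(start)) + 1
    return GeneRecord(
        gene_id=int(gene_id),
        start=int(start),
        end=int(end),
        strand=strand,
        aa_length=span // 3 - 1,
        product=product,
    )


def read_annotations(
    path: str | Path,
    format: str = "tsv",
    length: int | None = None,
    circular: bool = False,
) -> AnnotatedGenome:
    """Read a genome annotation as an :class:`AnnotatedGenome`.

    ``tsv`` expects columns gene/start/end/strand and optionally
    length_aa/product, in the printed dialect.  ``genbank`` reads CDS
    features and converts them to the printed dialect (minus strand stored
    as start > end); the record sequence is attached when present.
    """
    if format == "tsv":
        if length is None:
            raise ValueError("genome length is required for TSV annotations")
        df = pd.read_csv(path, sep="\t", comment="#")
        genes = []
        for r in df.itertuples():
            rec = _gene_from_printed(
                r.gene, r.start, r.end, str(r.strand), product=str(getattr(r, "product", ""))
            )
            if hasattr(r, "length_aa") and int(r.length_aa) != rec.aa_length:
                raise ValueError(
                    f"gene {rec.gene_id}: declared aa length {r.length_aa} "
                    f"inconsistent with span {rec.span}"
                )
            genes.append(rec)
        return AnnotatedGenome(length=length, genes=genes, circular=circular)

    if format == "genbank":
        record = SeqIO.read(str(path), "genbank")
        genes = []
        n = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            n += 1
            lo = int(feat.location.start) + 1  # to 1-based inclusive
            hi = int(feat.location.end)
            if feat.location.strand == -1:
                start, end, strand = hi, lo, "-"
            else:
                start, end, strand = lo, hi, "+"
            product = "; ".join(feat.qualifiers.get("product", []))
            genes.append(_gene_from_printed(n, start, end, strand, product=product))
        seq = str(record.seq) if len(record.seq) else None
        return AnnotatedGenome(
            length=len(record), genes=genes, sequence=seq,
            circular=record.annotations.get("topology") == "circular" or circular,
        )

    raise ValueError(f"unknown annotation format {format!r}")


def read_fasta(path: str | Path) -> str:
    """Read the single sequence of a FASTA file as an uppercase string."""
    record = SeqIO.read(str(path), "fasta")
    return str(record.seq).upper()


def write_fasta(sequence: str, path: str | Path, name: str = "sequence") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(filename: str) -> Path:
    return Path(str(importlib.resources.files("phagekit").joinpath("data", filename)))


def load_fixture(name: str):
    """Load a packaged reference table.

    ``table1`` -> 85 :class:`HostRangeRecord`, ``table3`` -> 76
    :class:`GeneRecord`, ``table6`` -> 16 :class:`MassSpecRecord`.
    """
    if name == "table1":
        return read_host_range(_data_path("table1.tsv"))
    if name == "table3":
        df = pd.read_csv(_data_path("table3.tsv"), sep="\t", comment="#")
        genes = []
        for r in df.itertuples():
            rec = _gene_from_printed(r.gene, r.start, r.end, str(r.strand), str(r.product))
            if rec.aa_length != int(r.length_aa):
                raise ValueError(f"fixture gene {r.gene}: inconsistent aa length")
            genes.append(rec)
        return genes
    if name == "table6":
        return read_mass_spec(_data_path("table6.tsv"))
    raise ValueError(f"unknown fixture {name!r} (expected table1, table3 or table6)")
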