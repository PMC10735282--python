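"""Domain model for cassette-exon regulation data.

Exons are identified across datasets by their genomic coordinates
(chrom, start, end, strand); gene symbols and exon numbers are carried as
annotation labels only.  Internally all intervals are 0-based half-open.
The tab-separated exon tables exchanged with users are 1-based inclusive
(the convention of the annotation database the tables derive from) and are
converted at the readers/writers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

DELTA_PSI_THRESHOLD = 10.0   # percent; |dPSI| >= this
PVALUE_THRESHOLD = 0.05      # adjusted p-value <= this

#: identity key used for cross-dataset matching
ExonKey = tuple[str, int, int, str]


class ExonTableError(ValueError):
    """Malformed exon/annotation table (carries file and line context)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> ExonKey:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class ExonRecord:
    """One cassette exon, optionally with knockdown regulation statistics.

    ``delta_psi`` is the change in percent-spliced-in between knockdown and
    control, on a -100..100 percent scale (positive = more included upon
    knockdown).  ``delta_psi`` and ``adj_pvalue`` are either both present
    (statistics mode) or both absent (coordinates-only mode).
    """

    gene_symbol: str
    exon_number: int
    interval: GenomicInterval
    delta_psi: Optional[float] = None
    adj_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.delta_psi is None) != (self.adj_pvalue is None):
            raise ValueError(
                "delta_psi and adj_pvalue must both be present or both absent"
            )
        if self.exon_number < 1:
            raise ValueError("exon_number must be a positive integer")
        if self.delta_psi is not None and not -100.0 <= self.delta_psi <= 100.0:
            raise ValueError(f"delta_psi {self.delta_psi} outside [-100, 100]")
        if self.adj_pvalue is not None and not 0.0 <= self.adj_pvalue <= 1.0:
            raise ValueError(f"adj_pvalue {self.adj_pvalue} outside [0, 1]")

    @property
    def key(self) -> ExonKey:
        return self.interval.key

    @property
    def has_stats(self) -> bool:
        return self.delta_psi is not None

    def is_significant(
        self,
        delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
        pvalue_threshold: float = PVALUE_THRESHOLD,
    ) -> bool:
        if not self.has_stats:
            raise ValueError("significance undefined without delta_psi")
        return (
            abs(self.delta_psi) >= delta_psi_threshold
            and self.adj_pvalue <= pvalue_threshold
        )


def significant_subset(
    records: Iterable[ExonRecord],
    delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
    pvalue_threshold: float = PVALUE_THRESHOLD,
) -> list[ExonRecord]:
    """Exons passing ``|dPSI| >= delta_psi_threshold and adj_p <= pvalue_threshold``.

    Both comparisons are inclusive.  Raises if any record lacks statistics.
    """
    return [
        r for r in records if r.is_significant(delta_psi_threshold, pvalue_threshold)
    ]


@dataclass
class SFDataset:
    """Differentially included exons from one splicing-factor knockdown.

    Stored records all pass the significance filter; exon identity keys are
    unique within a dataset.
    """

    sf_name: str
    cell_line: str = ""
    perturbation: str = ""
    build: str = ""
    dataset_id: str = ""
    exons: dict[ExonKey, ExonRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dataset_id:
            self.dataset_id = (
                f"{self.sf_name}_{self.cell_line}" if self.cell_line else self.sf_name
            )

    @classmethod
    def from_records(
        cls,
        sf_name: str,
        records: Iterable[ExonRecord],
        cell_line: str = "",
        perturbation: str = "",
        build: str = "",
        dataset_id: str = "",
        delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
        pvalue_threshold: float = PVALUE_THRESHOLD,
        apply_filter: bool = True,
    ) -> "SFDataset":
        exons: dict[ExonKey, ExonRecord] = {}
        for rec in records:
            if apply_filter and not rec.is_significant(
                delta_psi_threshold, pvalue_threshold
            ):
                continue
            if rec.key in exons:
                raise ValueError(
                    f"duplicate exon identity {rec.key} in dataset {sf_name}"
                )
            exons[rec.key] = rec
        return cls(
            sf_name=sf_name,
            cell_line=cell_line,
            perturbation=perturbation,
            build=build,
            dataset_id=dataset_id,
            exons=exons,
        )

    def __len__(self) -> int:
        return len(self.exons)

    def __contains__(self, key: ExonKey) -> bool:
        return key in self.exons

    @property
    def keys(self) -> set[ExonKey]:
        return set(self.exons)

    def records(self) -> list[ExonRecord]:
        return [self.exons[k] for k in sorted(self.exons)]


@dataclass
class AnnotationTable:
    """Exon annotation: (gene_symbol, exon_number) <-> genomic interval."""

    entries: dict[tuple[str, int], GenomicInterval] = field(default_factory=dict)
    by_coords: dict[ExonKey, tuple[str, int]] = field(default_factory=dict)

    def add(self, gene_symbol: str, exon_number: int, interval: GenomicInterval) -> None:
        ident = (gene_symbol, exon_number)
        if ident in self.entries:
            raise ValueError(f"duplicate annotation identity {ident}")
        self.entries[ident] = interval
        self.by_coords[interval.key] = ident

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_identity(self, key: ExonKey) -> Optional[tuple[str, int]]:
        return self.by_coords.get(key)

    def records(self) -> list[ExonRecord]:
        """All annotated exons as coordinate-only records (sorted by interval)."""
        out = [
            ExonRecord(gene_symbol=g, exon_number=n, interval=iv)
            for (g, n), iv in self.entries.items()
        ]
        out.sort(key=lambda r: r.key)
        return out

    def chrom_lengths(self, margin: int = 0) -> dict[str, int]:
        """Rightmost annotated coordinate per chromosome, plus a margin."""
        lengths: dict[str, int] = {}
        for iv in self.entries.values():
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end + margin)
        return lengths


@dataclass
class ValidationReport:
    """Partition of query records into recognized / corrected / unknown."""

    recognized: list[ExonRecord] = field(default_factory=list)
    corrected: list[tuple[ExonRecord, tuple[str, int]]] = field(default_factory=list)
    unknown: list[ExonRecord] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.recognized) + len(self.corrected) + len(self.unknown)


def validate_against_annotation(
    records: Sequence[ExonRecord], annotation: AnnotationTable
) -> ValidationReport:
    """Classify query records by coordinate lookup in the annotation.

    Coordinates are authoritative: a record whose interval matches an
    annotated exon but whose labels disagree goes to ``corrected`` together
    with the annotation's (gene_symbol, exon_number) as the proposal.
    Records whose coordinates match nothing go to ``unknown``.
    """
    report = ValidationReport()
    for rec in records:
        ident = annotation.lookup_identity(rec.key)
        if ident is None:
            report.unknown.append(rec)
        elif ident == (rec.gene_symbol, rec.exon_number):
            report.recognized.append(rec)
        else:
            report.corrected.append((rec, ident))
    return report


# ---------------------------------------------------------------------------
# TSV input/output.  Exon tables are tab-separated with '#'-prefixed header
# or comment lines; coordinates on disk are 1-based inclusive.
# ---------------------------------------------------------------------------

EXON_TABLE_COLUMNS = (
    "gene_symbol",
    "exon_number",
    "chrom",
    "start",
    "end",
    "strand",
    "delta_psi",
    "adj_pvalue",
)


def _parse_row(
    fields: list[str], mode: str, path: os.PathLike, lineno: int
) -> ExonRecord:
    def fail(what: str) -> ExonTableError:
        return ExonTableError(f"{path}:{lineno}: {what}")

    n_expected = 8 if mode == "with_stats" else 6
    if len(fields) < n_expected:
        raise fail(
            f"expected {n_expected} columns for mode {mode!r}, got {len(fields)}"
        )
    gene, exno_s, chrom, start_s, end_s, strand = fields[:6]
    try:
        exon_number = int(exno_s)
    except ValueError:
        raise fail(f"bad exon_number {exno_s!r}") from None
    try:
        start1 = int(start_s)
        end1 = int(end_s)
    except ValueError:
        raise fail(f"bad coordinates {start_s!r}/{end_s!r}") from None
    try:
        # 1-based inclusive on disk -> 0-based half-open internally
        interval = GenomicInterval(chrom, start1 - 1, end1, strand)
    except ValueError as exc:
        raise fail(str(exc)) from None

    delta_psi = adj_p = None
    if mode == "with_stats":
        try:
            delta_psi = float(fields[6])
            adj_p = float(fields[7])
        except ValueError:
            raise fail(
                f"bad delta_psi/adj_pvalue {fields[6]!r}/{fields[7]!r}"
            ) from None
    try:
        return ExonRecord(
            gene_symbol=gene,
            exon_number=exon_number,
            interval=interval,
            delta_psi=delta_psi,
            adj_pvalue=adj_p,
        )
    except ValueError as exc:
        raise fail(str(exc)) from None


def read_exon_table(path: os.PathLike, mode: str = "with_stats") -> list[ExonRecord]:
    """Read a tab-separated exon table.

    ``mode`` is ``"with_stats"`` (8 columns, ΔPSI and adjusted p-value
    required) or ``"coords_only"`` (6 columns).  Lines starting with ``#``
    and blank lines are skipped.  Malformed rows raise :class:`ExonTableError`
    naming the file, line number and offending field.
    """
    if mode not in ("with_stats", "coords_only"):
        raise ValueError(f"unknown mode {mode!r}")
    records: list[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            records.append(_parse_row(line.split("\t"), mode, path, lineno))
    return records


def write_exon_table(
    records: Sequence[ExonRecord], path: os.PathLike, header: bool = True
) -> None:
    """Write records as a tab-separated table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        if header:
            fh.write("#" + "\t".join(EXON_TABLE_COLUMNS) + "\n")
        for rec in records:
            iv = rec.interval
            fields = [
                rec.gene_symbol,
                str(rec.exon_number),
                iv.chrom,
                str(iv.start + 1),
                str(iv.end),
                iv.strand,
            ]
            if rec.has_stats:
                # repr gives the shortest string that round-trips the float
                fields += [repr(rec.delta_psi), repr(rec.adj_pvalue)]
            fh.write("\t".join(fields) + "\n")


def read_annotation(path: os.PathLike) -> AnnotationTable:
    """Read a 6-column annotation TSV (1-based inclusive coordinates)."""
    table = AnnotationTable()
    for rec in read_exon_table(path, mode="coords_only"):
        table.add(rec.gene_symbol, rec.exon_number, rec.interval)
    return table


def write_annotation(table: AnnotationTable, path: os.PathLike) -> None:
    write_exon_table(table.records(), path)


# ---------------------------------------------------------------------------
# Registry: a directory of dataset TSVs plus a manifest.
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("sf_name", "cell_line", "perturbation", "build", "path")
MANIFEST_NAME = "manifest.tsv"
ANNOTATION_NAME = "annotation.tsv"


def load_registry(directory: os.PathLike) -> list[SFDataset]:
    """Load all datasets listed in ``directory/manifest.tsv``.

    Dataset files are read in statistics mode and records are re-filtered
    with the default significance thresholds, so a registry on disk can
    never violate the dataset invariants.
    """
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.is_file():
        raise FileNotFoundError(f"registry manifest not found: {manifest}")
    datasets: list[SFDataset] = []
    seen_ids: set[str] = set()
    with open(manifest) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(MANIFEST_COLUMNS):
                raise ExonTableError(
                    f"{manifest}:{lineno}: expected {len(MANIFEST_COLUMNS)} columns"
                )
            sf_name, cell_line, perturbation, build, rel_path = fields[:5]
            records = read_exon_table(directory / rel_path, mode="with_stats")
            ds = SFDataset.from_records(
                sf_name,
                records,
                cell_line=cell_line,
                perturbation=perturbation,
                build=build,
            )
            if ds.dataset_id in seen_ids:
                raise ExonTableError(
                    f"{manifest}:{lineno}: duplicate dataset id {ds.dataset_id}"
                )
            seen_ids.add(ds.dataset_id)
            datasets.append(ds)
    return datasets


def load_registry_annotation(directory: os.PathLike) -> Optional[AnnotationTable]:
    """Load ``annotation.tsv`` from a registry directory if present."""
    path = Path(directory) / ANNOTATION_NAME
    return read_annotation(path) if path.is_file() else None


def registry_universe(datasets: Iterable[SFDataset]) -> set[ExonKey]:
    """Union of exon identities across datasets (the default sampling frame)."""
    universe: set[ExonKey] = set()
    for ds in datasets:
        universe |= ds.keys
    return universe


def check_same_build(query_build: str, datasets: Iterable[SFDataset]) -> None:
    """Refuse comparison across genome builds (no liftOver is performed)."""
    if not query_build:
        return
    for ds in datasets:
        if ds.build and ds.build != query_build:
            raise ValueError(
                f"genome build mismatch: query is {query_build!r} but dataset "
                f"{ds.dataset_id} is {ds.build!r}; convert coordinates first"
            )
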