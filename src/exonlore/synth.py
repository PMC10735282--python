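"""Synthetic fixture generator.

Produces every input the other modules consume — annotation tables,
SF-knockdown dataset registries with controlled pairwise exon sharing and
ΔPSI correlation, coordinate-only query lists, CLIP peak sets with planted
class-specific overlap rates, and random genomes with planted motif
occurrences — all deterministically from a seed, together with
ground-truth records of the realized quantities.

The generated registries emulate the statistical structure of real
knockdown experiments: every stored exon passes the significance filter
(|ΔPSI| >= 10, adjusted p <= 0.05), ΔPSI magnitudes fall in a
configurable range, and exons sit on synthetic chromosomes with realistic
exon lengths (50-300 nt) and inter-exon gaps wide enough (>= 700 nt) that
flanking analysis windows of neighbouring exons never collide.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .clip import PeakSet, RegulatedExonClasses, merge_intervals, region_windows
from .model import (
    ANNOTATION_NAME,
    MANIFEST_NAME,
    AnnotationTable,
    ExonKey,
    ExonRecord,
    GenomicInterval,
    SFDataset,
    write_annotation,
    write_exon_table,
)
from .motifs import MotifModel, reverse_complement

EXON_LENGTH_RANGE = (50, 300)
GAP_MIN = 700
DPSI_RANGE_DEFAULT = (10.0, 60.0)


@dataclass
class RegistrySpec:
    """Target structure of a synthetic registry.

    ``overlap`` and ``correlation`` may be scalars (applied to every
    off-diagonal pair) or full symmetric matrices with unit diagonal.
    """

    n_sf: int = 3
    exons_per_dataset: int = 200
    universe_size: int = 2000
    overlap: float | np.ndarray = 0.1
    correlation: float | np.ndarray = 0.5
    sign_up_fraction: float = 0.5
    dpsi_range: tuple[float, float] = DPSI_RANGE_DEFAULT
    seed: int = 0

    def overlap_matrix(self) -> np.ndarray:
        return _expand_matrix(self.overlap, self.n_sf, "overlap")

    def correlation_matrix(self) -> np.ndarray:
        return _expand_matrix(self.correlation, self.n_sf, "correlation")

    def validate(self) -> None:
        if self.n_sf < 1 or self.exons_per_dataset < 1:
            raise ValueError("n_sf and exons_per_dataset must be positive")
        if self.exons_per_dataset > self.universe_size:
            raise ValueError("dataset size exceeds universe size")
        ov = self.overlap_matrix()
        if np.any((ov < 0) | (ov > 1)):
            raise ValueError("overlap fractions must lie in [0, 1]")
        corr = self.correlation_matrix()
        if np.any((corr < -1) | (corr > 1)):
            raise ValueError("correlations must lie in [-1, 1]")
        lo, hi = self.dpsi_range
        if not (10.0 <= lo <= hi <= 100.0):
            raise ValueError("dpsi_range must lie within [10, 100]")
        # each dataset must fit its planted overlaps plus fresh exons
        total_needed = self.n_sf * self.exons_per_dataset
        shared = sum(
            ov[i, j] * self.exons_per_dataset
            for i in range(self.n_sf)
            for j in range(i)
        )
        if total_needed - shared > self.universe_size:
            raise ValueError(
                "universe too small for the requested overlap structure"
            )


def _expand_matrix(value, n: int, label: str) -> np.ndarray:
    if np.isscalar(value):
        mat = np.full((n, n), float(value))
        np.fill_diagonal(mat, 1.0)
    else:
        mat = np.asarray(value, dtype=float)
        if mat.shape != (n, n):
            raise ValueError(f"{label} matrix must be {n}x{n}")
        if not np.allclose(mat, mat.T):
            raise ValueError(f"{label} matrix must be symmetric")
        if not np.allclose(np.diag(mat), 1.0):
            raise ValueError(f"{label} matrix must have unit diagonal")
    return mat


def generate_annotation(
    n_exons: int,
    rng: np.random.Generator,
    exons_per_chrom: int = 250,
    exons_per_gene: int = 8,
    exon_length_range: tuple[int, int] = EXON_LENGTH_RANGE,
    gap_min: int = GAP_MIN,
) -> AnnotationTable:
    """Non-overlapping exons laid out on synthetic chromosomes."""
    table = AnnotationTable()
    gene_index = 0
    for start_idx in range(0, n_exons, exons_per_chrom):
        chrom = f"chrS{start_idx // exons_per_chrom + 1}"
        pos = int(rng.integers(gap_min, 2 * gap_min))
        n_here = min(exons_per_chrom, n_exons - start_idx)
        for j in range(n_here):
            length = int(rng.integers(*exon_length_range, endpoint=True))
            strand = "+" if rng.random() < 0.5 else "-"
            if j % exons_per_gene == 0:
                gene_index += 1
            table.add(
                f"GENE{gene_index:05d}",
                j % exons_per_gene + 1,
                GenomicInterval(chrom, pos, pos + length, strand),
            )
            pos += length + gap_min + int(rng.integers(0, gap_min))
    return table


def _draw_dpsi(
    n: int,
    rng: np.random.Generator,
    sign_up_fraction: float,
    dpsi_range: tuple[float, float],
) -> np.ndarray:
    signs = np.where(rng.random(n) < sign_up_fraction, 1.0, -1.0)
    return signs * rng.uniform(dpsi_range[0], dpsi_range[1], size=n)


def _clip_dpsi(values: np.ndarray, dpsi_min: float = 10.0) -> np.ndarray:
    """Force values into the significant range [-100, -min] u [min, 100]."""
    out = np.clip(values, -100.0, 100.0)
    small = np.abs(out) < dpsi_min
    signs = np.where(out[small] >= 0, 1.0, -1.0)
    out[small] = signs * dpsi_min
    return out


def correlated_dpsi(
    base: np.ndarray,
    r_target: float,
    rng: np.random.Generator,
    dpsi_min: float = 10.0,
) -> np.ndarray:
    """ΔPSI values correlated with ``base`` at approximately ``r_target``.

    Additive Gaussian noise with its scale calibrated by bisection so that
    the correlation *after* clipping back into the significant range hits
    the target (clipping otherwise biases the realized r; documented
    tolerance ±0.05 at moderate targets and sample sizes).
    """
    if not -1.0 <= r_target <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    if r_target == 0.0:
        return _clip_dpsi(
            _draw_dpsi(len(base), rng, 0.5, (dpsi_min, 60.0)), dpsi_min
        )
    sd = float(np.std(base))
    if sd == 0.0:
        sd = 1.0
    noise = rng.normal(0.0, 1.0, size=len(base))
    signed = np.sign(r_target) * base

    def realized(sigma: float) -> np.ndarray:
        return _clip_dpsi(signed + sigma * noise, dpsi_min)

    if abs(r_target) == 1.0 or len(base) < 3:
        return realized(0.0)

    def corr(sigma: float) -> float:
        out = realized(sigma)
        if np.std(out) == 0.0:
            return 1.0
        return float(np.corrcoef(base, out)[0, 1])

    # realized correlation decreases monotonically in sigma; bisect
    lo, hi = 0.0, sd * math.sqrt(1.0 / r_target**2 - 1.0) + sd
    target = abs(r_target)
    while abs(corr(hi)) > target and hi < 100 * sd:
        hi *= 2.0
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if abs(corr(mid)) > target:
            lo = mid
        else:
            hi = mid
    return realized((lo + hi) / 2.0)


def generate_registry(
    spec: RegistrySpec,
) -> tuple[AnnotationTable, list[SFDataset], dict]:
    """Registry of SF datasets with planted overlap/correlation structure.

    Returns the annotation (the exon universe), the datasets, and a ground
    truth record with the realized pairwise shared fractions and Pearson
    correlations.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ann = generate_annotation(spec.universe_size, rng)
    universe_keys = sorted(ann.by_coords)
    overlap = spec.overlap_matrix()
    corr = spec.correlation_matrix()
    size = spec.exons_per_dataset

    chosen: list[list[ExonKey]] = []
    dpsi: list[dict[ExonKey, float]] = []
    used: set[ExonKey] = set()
    for i in range(spec.n_sf):
        keys: list[ExonKey] = []
        key_set: set[ExonKey] = set()
        values: dict[ExonKey, float] = {}
        for j in range(i):
            n_share = round(overlap[i, j] * size)
            # prefer exons exclusive to dataset j so planting the (i, j)
            # overlap does not inflate the overlap with other datasets
            others = set().union(*(chosen[t] for t in range(i) if t != j)) if i > 1 else set()
            pool = [k for k in chosen[j] if k not in key_set and k not in others]
            if len(pool) < n_share:
                pool = [k for k in chosen[j] if k not in key_set]
            n_share = min(n_share, len(pool), size - len(keys))
            if n_share == 0:
                continue
            picked_idx = rng.choice(len(pool), size=n_share, replace=False)
            picked = [pool[t] for t in sorted(picked_idx)]
            base = np.array([dpsi[j][k] for k in picked])
            vals = correlated_dpsi(base, corr[i, j], rng)
            for k, v in zip(picked, vals):
                keys.append(k)
                key_set.add(k)
                values[k] = float(v)
        n_fresh = size - len(keys)
        if n_fresh:
            fresh_pool = [k for k in universe_keys if k not in used and k not in key_set]
            if len(fresh_pool) < n_fresh:
                fresh_pool = [k for k in universe_keys if k not in key_set]
            idx = rng.choice(len(fresh_pool), size=n_fresh, replace=False)
            fresh = [fresh_pool[t] for t in sorted(idx)]
            vals = _draw_dpsi(n_fresh, rng, spec.sign_up_fraction, spec.dpsi_range)
            for k, v in zip(fresh, vals):
                keys.append(k)
                key_set.add(k)
                values[k] = float(v)
        chosen.append(keys)
        dpsi.append(values)
        used |= key_set

    datasets: list[SFDataset] = []
    for i, (keys, values) in enumerate(zip(chosen, dpsi)):
        records = []
        for key in sorted(keys):
            chrom, start, end, strand = key
            ident = ann.lookup_identity(key)
            records.append(
                ExonRecord(
                    gene_symbol=ident[0],
                    exon_number=ident[1],
                    interval=GenomicInterval(chrom, start, end, strand),
                    delta_psi=values[key],
                    adj_pvalue=float(rng.uniform(1e-6, 0.05)),
                )
            )
        datasets.append(
            SFDataset.from_records(
                f"SF{i + 1:03d}",
                records,
                cell_line="SYN",
                perturbation="siRNA",
                build="syn1",
            )
        )

    truth: dict = {"realized_overlap": {}, "realized_correlation": {}}
    for i in range(spec.n_sf):
        for j in range(i):
            shared = set(chosen[i]) & set(chosen[j])
            frac = len(shared) / size
            truth["realized_overlap"][f"{i},{j}"] = frac
            if len(shared) >= 3:
                a = np.array([dpsi[i][k] for k in sorted(shared)])
                b = np.array([dpsi[j][k] for k in sorted(shared)])
                if np.std(a) > 0 and np.std(b) > 0:
                    truth["realized_correlation"][f"{i},{j}"] = float(
                        np.corrcoef(a, b)[0, 1]
                    )
    return ann, datasets, truth


def generate_query_from_dataset(
    dataset: SFDataset,
    annotation: AnnotationTable,
    overlap_fraction: float,
    r_target: float,
    n_query: int,
    rng: np.random.Generator,
) -> list[ExonRecord]:
    """Query list sharing a planted fraction of exons with one dataset.

    Shared exons get ΔPSI correlated with the dataset at ``r_target``;
    filler exons are drawn from the annotation outside the dataset.
    """
    ds_keys = sorted(dataset.keys)
    n_shared = min(round(overlap_fraction * n_query), len(ds_keys))
    idx = rng.choice(len(ds_keys), size=n_shared, replace=False)
    shared = [ds_keys[t] for t in sorted(idx)]
    base = np.array([dataset.exons[k].delta_psi for k in shared])
    shared_vals = correlated_dpsi(base, r_target, rng) if n_shared else np.empty(0)
    filler_pool = [k for k in sorted(annotation.by_coords) if k not in dataset.keys]
    n_filler = n_query - n_shared
    if n_filler > len(filler_pool):
        raise ValueError("annotation too small for the requested query size")
    idx = rng.choice(len(filler_pool), size=n_filler, replace=False)
    filler = [filler_pool[t] for t in sorted(idx)]
    filler_vals = _draw_dpsi(n_filler, rng, 0.5, DPSI_RANGE_DEFAULT)
    records = []
    for keys, vals in ((shared, shared_vals), (filler, filler_vals)):
        for key, v in zip(keys, vals):
            chrom, start, end, strand = key
            ident = annotation.lookup_identity(key)
            records.append(
                ExonRecord(
                    gene_symbol=ident[0],
                    exon_number=ident[1],
                    interval=GenomicInterval(chrom, start, end, strand),
                    delta_psi=float(v),
                    adj_pvalue=float(rng.uniform(1e-6, 0.05)),
                )
            )
    records.sort(key=lambda r: r.key)
    return records


def generate_clip_fixture(
    classes: RegulatedExonClasses,
    p_overlap_reg: float,
    p_overlap_ctrl: float,
    seed: int | np.random.Generator | None = None,
    regions: Sequence[str] = ("exon_body",),
    peak_width: int = 40,
) -> PeakSet:
    """Peaks planted with class-specific probabilities.

    Each regulated (up or down) exon independently receives a peak inside
    each listed region with probability ``p_overlap_reg``; control exons
    with ``p_overlap_ctrl``.
    """
    for p in (p_overlap_reg, p_overlap_ctrl):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    intervals: list[tuple[str, int, int]] = []

    def plant(keys: Iterable[ExonKey], prob: float) -> None:
        for key in sorted(keys):
            chrom, start, end, strand = key
            windows = region_windows(GenomicInterval(chrom, start, end, strand))
            for region in regions:
                if rng.random() >= prob:
                    continue
                win = windows[region]
                if win is None:
                    continue
                width = min(peak_width, win.length)
                offset = int(rng.integers(0, win.length - width + 1))
                intervals.append((chrom, win.start + offset, win.start + offset + width))

    plant(classes.up_exons | classes.down_exons, p_overlap_reg)
    plant(classes.control_exons, p_overlap_ctrl)
    return merge_intervals(intervals, sf_name=classes.sf_name)


def generate_genome(
    annotation: AnnotationTable,
    rng: np.random.Generator,
    margin: int = 500,
) -> dict[str, str]:
    """Random uniform-ACGT genome covering every annotated exon plus margin."""
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, str] = {}
    for chrom, length in sorted(annotation.chrom_lengths(margin).items()):
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        genome[chrom] = bytes(base_bytes[codes]).decode()
    return genome


def plant_motif(
    genome: dict[str, str],
    exons: Iterable[ExonKey],
    motif: MotifModel,
    rate: float,
    rng: np.random.Generator,
    flank: int = 200,
) -> list[tuple[ExonKey, int]]:
    """Insert the motif consensus inside the extended region of exons.

    Each exon receives one planted occurrence with probability ``rate`` at a
    uniform position within [start - flank, end + flank); minus-strand exons
    get the reverse complement so the oriented sequence contains the motif.
    Returns the planted (exon, genomic position) pairs; mutates ``genome``.
    """
    site = motif.consensus
    if any(c not in "ACGT" for c in site):
        raise ValueError("planting requires an unambiguous consensus")
    planted: list[tuple[ExonKey, int]] = []
    buffers = {c: bytearray(s.encode()) for c, s in genome.items()}
    for key in sorted(exons):
        if rng.random() >= rate:
            continue
        chrom, start, end, strand = key
        lo = max(start - flank, 0)
        hi = min(end + flank, len(genome[chrom])) - len(site)
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        insert = site if strand == "+" else reverse_complement(site)
        buffers[chrom][pos : pos + len(site)] = insert.encode()
        planted.append((key, pos))
    for chrom in buffers:
        genome[chrom] = buffers[chrom].decode()
    return planted


def generate_motif_fixture(
    classes: RegulatedExonClasses,
    annotation: AnnotationTable,
    motif: MotifModel,
    plant_rate_reg: float,
    plant_rate_ctrl: float,
    seed: int | np.random.Generator | None = None,
    flank: int = 200,
    target_class: str = "both",
) -> tuple[dict[str, str], dict]:
    """Random genome with the motif planted at class-specific rates.

    ``target_class`` selects which regulated class receives the high rate:
    "up", "down" or "both".  Returns the genome and a ground-truth record
    of planted positions.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genome = generate_genome(annotation, rng, margin=flank + 300)
    reg: set[ExonKey] = set()
    if target_class in ("up", "both"):
        reg |= classes.up_exons
    if target_class in ("down", "both"):
        reg |= classes.down_exons
    truth = {
        "regulated": plant_motif(genome, reg, motif, plant_rate_reg, rng, flank),
        "control": plant_motif(
            genome, classes.control_exons, motif, plant_rate_ctrl, rng, flank
        ),
    }
    return genome, truth


def write_fasta(genome: Mapping[str, str], path: os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_registry(
    directory: os.PathLike,
    annotation: AnnotationTable,
    datasets: Sequence[SFDataset],
    truth: Optional[dict] = None,
) -> None:
    """Write a registry directory: manifest, annotation, dataset TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_annotation(annotation, directory / ANNOTATION_NAME)
    with open(directory / MANIFEST_NAME, "w") as fh:
        fh.write("#sf_name\tcell_line\tperturbation\tbuild\tpath\n")
        for ds in datasets:
            rel = f"{ds.dataset_id}.tsv"
            write_exon_table(ds.records(), directory / rel)
            fh.write(
                "\t".join(
                    [ds.sf_name, ds.cell_line, ds.perturbation, ds.build, rel]
                )
                + "\n"
            )
    if truth is not None:
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
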