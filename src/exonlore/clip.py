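"""CLIP-peak enrichment at regulated exons and their flanking windows.

For each splicing factor with CLIP data, peaks from all experiments are
merged into one interval set.  Exons significantly more included (up) or
more skipped (down) upon knockdown of the factor are compared with control
exons (all other detected exons) for peak overlap in the exon body and in
three consecutive 100-nt windows on each side.  The effect size is

    R = log2((P_reg + 0.01) / (P_ctrl + 0.01))

with P_reg and P_ctrl the overlap proportions; significance comes from a
logistic regression of the overlap indicator on the exon class (two-sided
Wald test), with a Fisher exact fallback when a contingency cell is empty,
and Benjamini-Hochberg correction across all cells of a run.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import fisher_exact

from .model import ExonKey, ExonTableError, GenomicInterval, SFDataset
from .overlap import bh_adjust

PSEUDOCOUNT = 0.01
WINDOW_SIZE_DEFAULT = 100
MIN_CLASS_SIZE_DEFAULT = 100

#: region identifiers, ordered 5' -> 3' on the exon's strand
REGIONS = ("up3", "up2", "up1", "exon_body", "down1", "down2", "down3")


@dataclass
class PeakSet:
    """Merged, sorted, non-overlapping peak intervals for one SF."""

    sf_name: str
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return sum(len(s) for s, _ in self.by_chrom.values())

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.by_chrom):
            starts, ends = self.by_chrom[chrom]
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any-basepair overlap of [start, end) with a peak."""
        if start >= end or chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends[i - 1] > start


def read_bed(path: os.PathLike) -> list[tuple[str, int, int]]:
    """Read intervals from a BED file (0-based half-open; first 3 columns)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExonTableError(f"{path}:{lineno}: BED line has < 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ExonTableError(
                    f"{path}:{lineno}: bad BED coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            if not chrom or start < 0 or end <= start:
                raise ExonTableError(f"{path}:{lineno}: invalid BED interval")
            intervals.append((chrom, start, end))
    return intervals


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]], sf_name: str = ""
) -> PeakSet:
    """Coalesce overlapping and abutting intervals into a PeakSet."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        per_chrom.setdefault(chrom, []).append((start, end))
    peaks = PeakSet(sf_name=sf_name)
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for start, end in ivs:
            if merged and start <= merged[-1][1]:  # abutting intervals merge too
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        peaks.by_chrom[chrom] = (
            np.array([m[0] for m in merged], dtype=np.int64),
            np.array([m[1] for m in merged], dtype=np.int64),
        )
    return peaks


def merge_peaks(bed_paths: Sequence[os.PathLike], sf_name: str = "") -> PeakSet:
    """Merge peaks from any number of BED files into one set."""
    intervals: list[tuple[str, int, int]] = []
    for path in bed_paths:
        intervals.extend(read_bed(path))
    return merge_intervals(intervals, sf_name=sf_name)


def region_windows(
    exon: GenomicInterval,
    window_size: int = WINDOW_SIZE_DEFAULT,
    chrom_length: Optional[int] = None,
) -> dict[str, Optional[GenomicInterval]]:
    """Exon body plus three windows on each side, oriented by strand.

    "up" regions are 5' of the exon on its strand (genomic left for +,
    genomic right for -), with up1/down1 adjacent to the exon.  Windows are
    truncated at position 0 and at ``chrom_length``; a window truncated to
    nothing is returned as None.
    """

    def clip(start: int, end: int) -> Optional[GenomicInterval]:
        start = max(start, 0)
        if chrom_length is not None:
            end = min(end, chrom_length)
        if start >= end:
            return None
        return GenomicInterval(exon.chrom, start, end, exon.strand)

    left = [
        clip(exon.start - i * window_size, exon.start - (i - 1) * window_size)
        for i in (1, 2, 3)
    ]
    right = [
        clip(exon.end + (i - 1) * window_size, exon.end + i * window_size)
        for i in (1, 2, 3)
    ]
    if exon.strand == "+":
        up, down = left, right
    else:
        up, down = right, left
    return {
        "exon_body": exon,
        "up1": up[0],
        "up2": up[1],
        "up3": up[2],
        "down1": down[0],
        "down2": down[1],
        "down3": down[2],
    }


@dataclass
class RegulatedExonClasses:
    """Up/down/control exon identity sets for one SF, conflicts removed."""

    sf_name: str
    up_exons: set[ExonKey]
    down_exons: set[ExonKey]
    control_exons: set[ExonKey]
    n_conflicted: int
    usable: bool


def build_regulated_classes(
    datasets_for_sf: Sequence[SFDataset],
    all_detected: Iterable[ExonKey],
    min_class_size: int = MIN_CLASS_SIZE_DEFAULT,
) -> RegulatedExonClasses:
    """Union regulated exons across samples of one SF; drop conflicts.

    An exon significantly regulated in opposite directions in different
    samples of the same SF is excluded from every class.  The factor is
    flagged unusable unless both the up and the down class reach
    ``min_class_size``.
    """
    if not datasets_for_sf:
        raise ValueError("at least one dataset is required")
    sf_name = datasets_for_sf[0].sf_name
    up: set[ExonKey] = set()
    down: set[ExonKey] = set()
    for ds in datasets_for_sf:
        if ds.sf_name != sf_name:
            raise ValueError("all datasets must belong to the same SF")
        for key, rec in ds.exons.items():
            if rec.delta_psi > 0:
                up.add(key)
            elif rec.delta_psi < 0:
                down.add(key)
    conflicted = up & down
    up -= conflicted
    down -= conflicted
    control = set(all_detected) - up - down - conflicted
    return RegulatedExonClasses(
        sf_name=sf_name,
        up_exons=up,
        down_exons=down,
        control_exons=control,
        n_conflicted=len(conflicted),
        usable=len(up) >= min_class_size and len(down) >= min_class_size,
    )


def overlap_proportion(
    exon_keys: Iterable[ExonKey],
    peaks: PeakSet,
    region: str,
    window_size: int = WINDOW_SIZE_DEFAULT,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[int, int]:
    """(n_overlapping, n_with_window) for one region over a set of exons.

    Exons whose window is fully truncated away contribute to neither count.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    n_hit = n_tot = 0
    for chrom, start, end, strand in exon_keys:
        exon = GenomicInterval(chrom, start, end, strand)
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        window = region_windows(exon, window_size, clen)[region]
        if window is None:
            continue
        n_tot += 1
        if peaks.overlaps(window.chrom, window.start, window.end):
            n_hit += 1
    return n_hit, n_tot


def proportion_test(
    n_reg_hit: int, n_reg: int, n_ctrl_hit: int, n_ctrl: int
) -> float:
    """Two-sided p-value for P_reg != P_ctrl.

    Logistic regression (binomial GLM on the aggregated 2x2 table) with a
    Wald test on the class coefficient; falls back to Fisher's exact test
    when any contingency cell is zero (separation).
    """
    if n_reg == 0 or n_ctrl == 0:
        raise ValueError("empty class in proportion test")
    table = np.array(
        [[n_reg_hit, n_reg - n_reg_hit], [n_ctrl_hit, n_ctrl - n_ctrl_hit]]
    )
    if np.any(table == 0):
        return float(fisher_exact(table, alternative="two-sided")[1])
    endog = table.astype(float)
    exog = sm.add_constant(np.array([1.0, 0.0]))
    import warnings

    with warnings.catch_warnings():
        # the two-row aggregated model is saturated (df_resid = 0); the
        # Binomial family fixes scale = 1, so the Wald test is unaffected
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        return float(fit.pvalues[1])


def r_ratio(p_reg: float, p_ctrl: float) -> float:
    """Pseudocounted log2 enrichment ratio of two overlap proportions."""
    return math.log2((p_reg + PSEUDOCOUNT) / (p_ctrl + PSEUDOCOUNT))


@dataclass
class EnrichmentCell:
    sf_name: str
    exon_class: str  # up | down
    region: str
    n_reg: int
    n_ctrl: int
    p_reg: float
    p_ctrl: float
    r_value: float
    pvalue: float
    computable: bool = True
    q_bh: Optional[float] = None
    significant: Optional[bool] = None


def enrichment_cell(
    reg_exons: Iterable[ExonKey],
    ctrl_exons: Iterable[ExonKey],
    peaks: PeakSet,
    region: str,
    sf_name: str = "",
    exon_class: str = "",
    window_size: int = WINDOW_SIZE_DEFAULT,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> EnrichmentCell:
    """One (SF, class, region) enrichment cell: R value and test p-value."""
    reg_hit, reg_tot = overlap_proportion(
        reg_exons, peaks, region, window_size, chrom_lengths
    )
    ctrl_hit, ctrl_tot = overlap_proportion(
        ctrl_exons, peaks, region, window_size, chrom_lengths
    )
    if reg_tot == 0 or ctrl_tot == 0:
        return EnrichmentCell(
            sf_name=sf_name,
            exon_class=exon_class,
            region=region,
            n_reg=reg_tot,
            n_ctrl=ctrl_tot,
            p_reg=float("nan"),
            p_ctrl=float("nan"),
            r_value=float("nan"),
            pvalue=float("nan"),
            computable=False,
        )
    p_reg = reg_hit / reg_tot
    p_ctrl = ctrl_hit / ctrl_tot
    return EnrichmentCell(
        sf_name=sf_name,
        exon_class=exon_class,
        region=region,
        n_reg=reg_tot,
        n_ctrl=ctrl_tot,
        p_reg=p_reg,
        p_ctrl=p_ctrl,
        r_value=r_ratio(p_reg, p_ctrl),
        pvalue=proportion_test(reg_hit, reg_tot, ctrl_hit, ctrl_tot),
    )


def run_clip_panel(
    datasets: Sequence[SFDataset],
    peaks_by_sf: Mapping[str, PeakSet],
    all_detected: Iterable[ExonKey],
    min_class_size: int = MIN_CLASS_SIZE_DEFAULT,
    window_size: int = WINDOW_SIZE_DEFAULT,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    alpha: float = 0.05,
) -> list[EnrichmentCell]:
    """All enrichment cells for SFs with peaks, BH-corrected as one family.

    SFs with fewer than ``min_class_size`` exons in either regulated class
    are discarded.  The BH family is every computable cell of the run.
    """
    all_detected = set(all_detected)
    by_sf: dict[str, list[SFDataset]] = {}
    for ds in datasets:
        by_sf.setdefault(ds.sf_name, []).append(ds)
    cells: list[EnrichmentCell] = []
    for sf_name in sorted(set(by_sf) & set(peaks_by_sf)):
        classes = build_regulated_classes(
            by_sf[sf_name], all_detected, min_class_size
        )
        if not classes.usable:
            continue
        for exon_class, keys in (
            ("up", classes.up_exons),
            ("down", classes.down_exons),
        ):
            for region in REGIONS:
                cells.append(
                    enrichment_cell(
                        keys,
                        classes.control_exons,
                        peaks_by_sf[sf_name],
                        region,
                        sf_name=sf_name,
                        exon_class=exon_class,
                        window_size=window_size,
                        chrom_lengths=chrom_lengths,
                    )
                )
    computable = [c for c in cells if c.computable]
    if computable:
        adjusted = bh_adjust([c.pvalue for c in computable])
        for cell, q in zip(computable, adjusted):
            cell.q_bh = float(q)
            cell.significant = bool(q < alpha)
    return cells
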