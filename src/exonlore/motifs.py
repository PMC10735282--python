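"""Motif enrichment/depletion at regulated exon sequences.

Sequences of regulated exons, extended by a flank (default 200 nt) on both
sides, are tested for presence of an SF's binding motif against control
sequences.  Enrichment and impoverishment p-values P_e and P_i come from a
sequence-level Fisher exact test on the contains/does-not-contain 2x2
table (the impoverishment test simply swaps the roles of the two sets).
The two one-sided p-values are combined into a signed V statistic:

    as_printed:  V = min(1 - P_e, 1 - P_i) * s
    consistent:  V = (1 - min(P_e, P_i)) * s
    with s = -1 if P_i < P_e, s = +1 if P_i > P_e

The ``consistent`` variant is the default: with one-sided p-values the two
tests are near-complementary (P_e small forces P_i near 1), which makes
the printed min-of-complements collapse towards 0 exactly when the
evidence is strongest; taking the complement of the smaller p-value keeps
|V| -> 1 for strong enrichment or depletion, matching the 0.95 display
threshold.  Cells with |V| > 0.95 display red/blue, others grey, and SFs
with fewer than 100 regulated exons in a class display white.

Motifs are IUPAC consensus strings or position probability matrices
(MEME minimal format); RNA alphabets are mapped to DNA at read time.
Matching is either exact-consensus (regex over IUPAC codes) or PWM
log-odds against a 0-order background with a threshold calibrated on the
control sequences.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from scipy.stats import fisher_exact

from .model import ExonKey, GenomicInterval, SFDataset

FLANK_DEFAULT = 200
MIN_CLASS_SIZE_DEFAULT = 100
DISPLAY_THRESHOLD = 0.95
PWM_HIT_RATE_DEFAULT = 0.001  # expected background hits per nt

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """An RBP binding motif: IUPAC consensus and/or probability matrix."""

    name: str
    consensus: Optional[str] = None
    pwm: Optional[np.ndarray] = None  # shape (L, 4), columns A C G T
    source: str = ""

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError("motif needs a consensus or a matrix")
        if self.consensus is not None:
            self.consensus = self.consensus.upper().replace("U", "T")
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("matrix must have shape (length, 4)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("matrix rows must each sum to 1")
            if self.consensus is None:
                self.consensus = "".join(
                    _BASES[i] for i in np.argmax(self.pwm, axis=1)
                )

    @property
    def length(self) -> int:
        return len(self.consensus) if self.pwm is None else self.pwm.shape[0]

    @classmethod
    def from_consensus(cls, name: str, consensus: str) -> "MotifModel":
        return cls(name=name, consensus=consensus)


def read_meme(path: os.PathLike) -> list[MotifModel]:
    """Parse motifs from a MEME (minimal) motif file."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        letters = "ACGU" if "U" in m.alphabet else "ACGT"  # U maps onto the T column
        counts = np.array(
            [[m.counts[base][i] for base in letters] for i in range(m.length)],
            dtype=float,
        )
        rows = counts.sum(axis=1, keepdims=True)
        out.append(
            MotifModel(name=m.name or m.base_id or "motif", pwm=counts / rows,
                       source=str(path))
        )
    return out


def consensus_regex(consensus: str) -> re.Pattern:
    return re.compile("".join(IUPAC[c] for c in consensus.upper().replace("U", "T")))


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT become 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate(_BASES):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def pwm_window_scores(seq: str, pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of the sequence (strand as given).

    Windows containing non-ACGT characters score -inf.
    """
    length = pwm.shape[0]
    codes = _encode(seq)
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0)
    logodds = np.log2(np.maximum(pwm, 1e-9) / background[None, :])
    padded = np.vstack([logodds.T, np.full((1, length), -np.inf)])  # code 4 -> -inf
    idx = np.add.outer(np.arange(n), np.arange(length))
    return padded[codes[idx], np.arange(length)[None, :]].sum(axis=1)


def background_frequencies(seqs: Iterable[str]) -> np.ndarray:
    """0-order A/C/G/T frequencies over a set of sequences."""
    counts = np.zeros(4)
    for seq in seqs:
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def pwm_threshold(
    pwm: np.ndarray,
    control_seqs: Sequence[str],
    hit_rate: float = PWM_HIT_RATE_DEFAULT,
    max_nt: int = 200_000,
) -> float:
    """Score threshold giving an expected ``hit_rate`` hits per background nt.

    Calibrated on the pooled control-sequence windows (capped at ``max_nt``
    positions for speed).
    """
    background = background_frequencies(control_seqs)
    scores: list[np.ndarray] = []
    total = 0
    for seq in control_seqs:
        s = pwm_window_scores(seq, pwm, background)
        scores.append(s[np.isfinite(s)])
        total += len(s)
        if total >= max_nt:
            break
    pool = np.concatenate(scores) if scores else np.empty(0)
    if pool.size == 0:
        return float("inf")
    return float(np.quantile(pool, 1.0 - hit_rate))


def contains_motif(
    seq: str,
    motif: MotifModel,
    mode: str = "consensus",
    threshold: Optional[float] = None,
    background: Optional[np.ndarray] = None,
) -> bool:
    """Whether the sequence carries at least one motif match."""
    if motif.length > len(seq):
        return False
    if mode == "consensus":
        return consensus_regex(motif.consensus).search(seq.upper()) is not None
    if mode == "pwm":
        if motif.pwm is None:
            raise ValueError("PWM mode requires a probability matrix")
        if threshold is None:
            raise ValueError("PWM mode requires a calibrated threshold")
        bg = background if background is not None else np.full(4, 0.25)
        scores = pwm_window_scores(seq, motif.pwm, bg)
        return bool(scores.size and np.max(scores) >= threshold)
    raise ValueError(f"unknown match mode {mode!r}")


@dataclass
class SequenceSet:
    """Extended exon sequences with a role label."""

    records: list[tuple[ExonKey, str]]
    role: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [s for _, s in self.records]


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract [start, end) from a pyfaidx Fasta or a plain dict of strings."""
    if isinstance(genome, Mapping):
        seq = genome[chrom]
        return seq[start:end]
    return genome[chrom][start:end].seq  # pyfaidx-style indexed FASTA


def extract_extended_sequences(
    exons: Iterable[ExonKey],
    genome,
    flank: int = FLANK_DEFAULT,
    role: str = "",
) -> SequenceSet:
    """Exon sequences extended by ``flank`` nt on both sides, strand-oriented.

    Minus-strand exons are reverse-complemented.  Coordinates are truncated
    at chromosome bounds.  A chromosome missing from the genome raises an
    error listing the affected exons.
    """
    records: list[tuple[ExonKey, str]] = []
    missing: list[ExonKey] = []
    for key in sorted(exons):
        chrom, start, end, strand = key
        try:
            if isinstance(genome, Mapping):
                clen = len(genome[chrom])
            else:
                clen = len(genome[chrom])
        except KeyError:
            missing.append(key)
            continue
        lo = max(start - flank, 0)
        hi = min(end + flank, clen)
        seq = str(_fetch(genome, chrom, lo, hi)).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        records.append((key, seq))
    if missing:
        raise KeyError(f"chromosomes missing from genome for exons: {missing[:5]}")
    return SequenceSet(records=records, role=role)


def motif_enrichment_pvalue(
    primary: SequenceSet,
    control: SequenceSet,
    motif: MotifModel,
    mode: str = "consensus",
    threshold: Optional[float] = None,
    background: Optional[np.ndarray] = None,
) -> float:
    """One-sided p-value that motif-containing sequences are over-represented
    in the primary set relative to the control set (Fisher exact, greater).
    """
    if len(primary) == 0 or len(control) == 0:
        raise ValueError("both sequence sets must be non-empty")
    short = [len(s) for s in primary.sequences() + control.sequences()
             if len(s) < motif.length]
    if short:
        import warnings
        warnings.warn(
            f"{len(short)} sequence(s) shorter than the motif count as non-matching"
        )
    n_prim = sum(
        contains_motif(s, motif, mode, threshold, background)
        for s in primary.sequences()
    )
    n_ctrl = sum(
        contains_motif(s, motif, mode, threshold, background)
        for s in control.sequences()
    )
    table = [
        [n_prim, len(primary) - n_prim],
        [n_ctrl, len(control) - n_ctrl],
    ]
    return float(fisher_exact(table, alternative="greater")[1])


def v_statistic(
    p_e: float, p_i: float, variant: str = "consistent"
) -> tuple[float, int, bool]:
    """Signed V value from enrichment (P_e) and impoverishment (P_i) p-values.

    Returns ``(v, s, ambiguous)``; ``ambiguous`` is True at the tie
    P_e == P_i, where the sign defaults to +1.
    """
    for p in (p_e, p_i):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    ambiguous = p_e == p_i
    s = -1 if p_i < p_e else 1
    if variant == "as_printed":
        v = min(1.0 - p_e, 1.0 - p_i) * s
    elif variant == "consistent":
        v = (1.0 - min(p_e, p_i)) * s
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return v, s, ambiguous


@dataclass
class VResult:
    sf_name: str
    exon_class: str  # up | down
    n_class: int
    p_e: float = float("nan")
    p_i: float = float("nan")
    s: int = 0
    v: float = float("nan")
    display: str = "white"  # red | blue | grey | white
    ambiguous: bool = False


def _display(v: float) -> str:
    if v > DISPLAY_THRESHOLD:
        return "red"
    if v < -DISPLAY_THRESHOLD:
        return "blue"
    return "grey"


def run_motif_panel(
    datasets: Sequence[SFDataset],
    genome,
    motifs_by_sf: Mapping[str, MotifModel],
    all_detected: Iterable[ExonKey],
    min_class_size: int = MIN_CLASS_SIZE_DEFAULT,
    flank: int = FLANK_DEFAULT,
    variant: str = "consistent",
    mode: str = "consensus",
    hit_rate: float = PWM_HIT_RATE_DEFAULT,
) -> list[VResult]:
    """One V value per (SF, up/down class) for SFs with a known motif.

    Control sequences for an SF are all detected exons minus that SF's
    regulated exons.  Classes smaller than ``min_class_size`` render white
    (no test performed).  SFs without a motif are skipped with a warning.
    """
    from .clip import build_regulated_classes  # class construction is shared

    all_detected = set(all_detected)
    by_sf: dict[str, list[SFDataset]] = {}
    for ds in datasets:
        by_sf.setdefault(ds.sf_name, []).append(ds)
    results: list[VResult] = []
    for sf_name in sorted(by_sf):
        motif = motifs_by_sf.get(sf_name)
        if motif is None:
            import warnings
            warnings.warn(f"no motif for SF {sf_name}; skipped")
            continue
        classes = build_regulated_classes(by_sf[sf_name], all_detected,
                                          min_class_size)
        ctrl_seqs = extract_extended_sequences(
            classes.control_exons, genome, flank, role="control"
        )
        threshold = background = None
        if mode == "pwm":
            background = background_frequencies(ctrl_seqs.sequences())
            threshold = pwm_threshold(motif.pwm, ctrl_seqs.sequences(), hit_rate)
        for exon_class, keys in (
            ("up", classes.up_exons),
            ("down", classes.down_exons),
        ):
            if len(keys) < min_class_size:
                results.append(
                    VResult(sf_name=sf_name, exon_class=exon_class,
                            n_class=len(keys), display="white")
                )
                continue
            reg_seqs = extract_extended_sequences(
                keys, genome, flank, role=f"regulated_{exon_class}"
            )
            p_e = motif_enrichment_pvalue(
                reg_seqs, ctrl_seqs, motif, mode, threshold, background
            )
            p_i = motif_enrichment_pvalue(
                ctrl_seqs, reg_seqs, motif, mode, threshold, background
            )
            v, s, ambiguous = v_statistic(p_e, p_i, variant)
            results.append(
                VResult(
                    sf_name=sf_name,
                    exon_class=exon_class,
                    n_class=len(keys),
                    p_e=p_e,
                    p_i=p_i,
                    s=s,
                    v=v,
                    display=_display(v),
                    ambiguous=ambiguous,
                )
            )
    return results
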