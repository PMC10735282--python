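"""Query mode 1: ΔPSI correlation of a query exon list against SF datasets.

For each dataset the query is matched by exon identity, the Pearson
correlation of ΔPSI over the shared exons is computed, and one-sided
empirical p-values are obtained from a permutation null that randomly
re-pairs the query ΔPSI values with the dataset ΔPSI values (both marginal
distributions are preserved).  A composite confidence Score combines the
empirical p-value with the two overlap fractions:

    Score = mean(1 - p, percent.sig.input/100, percent.sig.SF/100)

and ranges between 0 and 1.  Positive and negative correlation each get
their own p-value and Score; rankings use the larger of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    DELTA_PSI_THRESHOLD,
    PVALUE_THRESHOLD,
    ExonKey,
    ExonRecord,
    SFDataset,
    check_same_build,
    significant_subset,
)

N_PERMUTATIONS_DEFAULT = 10_000
MIN_SHARED_DEFAULT = 10


class NotComputableError(ValueError):
    """Raised when a correlation statistic is undefined for the input."""


@dataclass
class SharedExonPairs:
    """ΔPSI pairs over the exon identities present in both inputs.

    Pairs are ordered by genomic coordinate so downstream permutation tests
    are deterministic given a seed.
    """

    keys: list[ExonKey]
    query_dpsi: np.ndarray
    dataset_dpsi: np.ndarray

    @property
    def n_shared(self) -> int:
        return len(self.keys)


def shared_pairs(query: Sequence[ExonRecord], dataset: SFDataset) -> SharedExonPairs:
    by_key = {r.key: r for r in query}
    common = sorted(set(by_key) & dataset.keys)
    q = np.array([by_key[k].delta_psi for k in common], dtype=float)
    d = np.array([dataset.exons[k].delta_psi for k in common], dtype=float)
    if common and (np.any(np.isnan(q)) or np.any(np.isnan(d))):
        raise ValueError("shared_pairs requires ΔPSI on both sides")
    return SharedExonPairs(keys=common, query_dpsi=q, dataset_dpsi=d)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise NotComputableError("zero variance in ΔPSI values")
    return float(np.dot(xc, yc) / (nx * ny))


def pearson_delta_psi(
    pairs: SharedExonPairs, min_shared: int = MIN_SHARED_DEFAULT
) -> float:
    """Pearson product-moment correlation of the shared ΔPSI pairs."""
    if pairs.n_shared < min_shared:
        raise NotComputableError(
            f"only {pairs.n_shared} shared exons (minimum {min_shared})"
        )
    return _pearson(pairs.query_dpsi, pairs.dataset_dpsi)


def empirical_pvalues(
    pairs: SharedExonPairs,
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int | np.random.Generator | None = None,
    min_shared: int = MIN_SHARED_DEFAULT,
) -> tuple[float, float]:
    """One-sided empirical p-values for positive and negative correlation.

    The null re-pairs query and dataset ΔPSI values by shuffling one side;
    the tail probability is read off the empirical distribution of the
    permuted correlations, with ties counted as extreme (``>=`` / ``<=``)
    and a floor of ``1/n_permutations`` (the resolution of the test).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    r_obs = pearson_delta_psi(pairs, min_shared=min_shared)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = pairs.query_dpsi - pairs.query_dpsi.mean()
    y = pairs.dataset_dpsi - pairs.dataset_dpsi.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    # Permuting y leaves its centred norm unchanged, so each permuted
    # correlation is a single dot product.
    perms = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1)
    r_perm = perms @ x / (nx * ny)
    p_pos = max(int(np.sum(r_perm >= r_obs)), 1) / n_permutations
    p_neg = max(int(np.sum(r_perm <= r_obs)), 1) / n_permutations
    return p_pos, p_neg


@dataclass
class OverlapFractions:
    percent_sig_input: float
    percent_sig_sf: float
    percent_common_query: float
    percent_common_sf: float
    warnings: list[str] = field(default_factory=list)


def overlap_fractions(
    query: Sequence[ExonRecord],
    dataset: SFDataset,
    delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
    pvalue_threshold: float = PVALUE_THRESHOLD,
) -> OverlapFractions:
    """Overlap percentages between the query list and a dataset.

    ``percent_sig_input`` is the fraction of the query's *significant* exons
    that appear in the dataset; ``percent_sig_sf`` is the fraction of the
    dataset's exons (all significant by construction) found in the query.
    The ``percent_common`` pair uses all listed exons on the query side.
    Empty denominators yield 0 with a warning flag.
    """
    warnings: list[str] = []
    query_keys = {r.key for r in query}
    ds_keys = dataset.keys
    common = query_keys & ds_keys

    if query and query[0].has_stats:
        sig_keys = {
            r.key
            for r in significant_subset(query, delta_psi_threshold, pvalue_threshold)
        }
    else:
        sig_keys = set(query_keys)
        if query:
            warnings.append("query lacks statistics; treating all exons as significant")

    def pct(num: int, den: int, label: str) -> float:
        if den == 0:
            warnings.append(f"empty denominator for {label}")
            return 0.0
        return 100.0 * num / den

    return OverlapFractions(
        percent_sig_input=pct(len(sig_keys & ds_keys), len(sig_keys), "percent.sig.input"),
        percent_sig_sf=pct(len(ds_keys & query_keys), len(ds_keys), "percent.sig.SF"),
        percent_common_query=pct(len(common), len(query_keys), "percent.common.query"),
        percent_common_sf=pct(len(common), len(ds_keys), "percent.common.SF"),
        warnings=warnings,
    )


def score(p_value: float, percent_sig_input: float, percent_sig_sf: float) -> float:
    """Composite confidence score in [0, 1]."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p_value outside [0, 1]")
    if not 0.0 <= percent_sig_input <= 100.0 or not 0.0 <= percent_sig_sf <= 100.0:
        raise ValueError("percentages outside [0, 100]")
    return (1.0 - p_value + percent_sig_input / 100.0 + percent_sig_sf / 100.0) / 3.0


@dataclass
class UpDownBreakdown:
    """Direction-aware breakdown of shared exons.

    "Up" means ΔPSI > 0 upon knockdown (more included), "down" means
    ΔPSI < 0.  Shared exons with ΔPSI exactly 0 on either side are excluded
    and counted in ``n_zero_excluded``.  Percentages are relative to the
    query's full up/down subset sizes.
    """

    n_query_up: int = 0
    n_query_down: int = 0
    n_query_up_in_sf_up: int = 0
    n_query_up_in_sf_down: int = 0
    n_query_down_in_sf_up: int = 0
    n_query_down_in_sf_down: int = 0
    n_zero_excluded: int = 0

    def _pct(self, n: int, den: int) -> float:
        return 100.0 * n / den if den else 0.0

    @property
    def pct_query_up_in_sf_up(self) -> float:
        return self._pct(self.n_query_up_in_sf_up, self.n_query_up)

    @property
    def pct_query_up_in_sf_down(self) -> float:
        return self._pct(self.n_query_up_in_sf_down, self.n_query_up)

    @property
    def pct_query_down_in_sf_up(self) -> float:
        return self._pct(self.n_query_down_in_sf_up, self.n_query_down)

    @property
    def pct_query_down_in_sf_down(self) -> float:
        return self._pct(self.n_query_down_in_sf_down, self.n_query_down)


def updown_breakdown(
    query: Sequence[ExonRecord], dataset: SFDataset
) -> UpDownBreakdown:
    out = UpDownBreakdown()
    by_key = {r.key: r for r in query}
    for rec in by_key.values():
        if rec.delta_psi is None:
            raise ValueError("up/down breakdown requires ΔPSI on the query")
        if rec.delta_psi > 0:
            out.n_query_up += 1
        elif rec.delta_psi < 0:
            out.n_query_down += 1
    for key in set(by_key) & dataset.keys:
        q = by_key[key].delta_psi
        d = dataset.exons[key].delta_psi
        if q == 0 or d == 0:
            out.n_zero_excluded += 1
            continue
        if q > 0 and d > 0:
            out.n_query_up_in_sf_up += 1
        elif q > 0 and d < 0:
            out.n_query_up_in_sf_down += 1
        elif q < 0 and d > 0:
            out.n_query_down_in_sf_up += 1
        else:
            out.n_query_down_in_sf_down += 1
    return out


@dataclass
class ComparisonResult:
    """All query-mode-1 outputs for one dataset."""

    dataset_id: str
    sf_name: str
    cell_line: str
    n_dataset_exons: int
    n_shared: int
    computable: bool
    reason: str = ""
    pearson_r: Optional[float] = None
    p_pos: Optional[float] = None
    p_neg: Optional[float] = None
    score_pos: Optional[float] = None
    score_neg: Optional[float] = None
    percent_sig_input: float = 0.0
    percent_sig_sf: float = 0.0
    percent_common_query: float = 0.0
    percent_common_sf: float = 0.0
    warnings: list[str] = field(default_factory=list)
    updown: Optional[UpDownBreakdown] = None
    pairs: Optional[SharedExonPairs] = None

    @property
    def best_score(self) -> float:
        if not self.computable:
            return float("-inf")
        return max(self.score_pos, self.score_neg)


def compare_to_dataset(
    query: Sequence[ExonRecord],
    dataset: SFDataset,
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int | np.random.Generator | None = None,
    min_shared: int = MIN_SHARED_DEFAULT,
    delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
    pvalue_threshold: float = PVALUE_THRESHOLD,
    keep_pairs: bool = False,
) -> ComparisonResult:
    """Full mode-1 comparison of a query list against one dataset."""
    fractions = overlap_fractions(query, dataset, delta_psi_threshold, pvalue_threshold)
    pairs = shared_pairs(query, dataset)
    result = ComparisonResult(
        dataset_id=dataset.dataset_id,
        sf_name=dataset.sf_name,
        cell_line=dataset.cell_line,
        n_dataset_exons=len(dataset),
        n_shared=pairs.n_shared,
        computable=True,
        percent_sig_input=fractions.percent_sig_input,
        percent_sig_sf=fractions.percent_sig_sf,
        percent_common_query=fractions.percent_common_query,
        percent_common_sf=fractions.percent_common_sf,
        warnings=list(fractions.warnings),
        updown=updown_breakdown(query, dataset),
        pairs=pairs if keep_pairs else None,
    )
    try:
        result.pearson_r = pearson_delta_psi(pairs, min_shared=min_shared)
        result.p_pos, result.p_neg = empirical_pvalues(
            pairs, n_permutations=n_permutations, seed=seed, min_shared=min_shared
        )
    except NotComputableError as exc:
        result.computable = False
        result.reason = str(exc)
        return result
    result.score_pos = score(
        result.p_pos, result.percent_sig_input, result.percent_sig_sf
    )
    result.score_neg = score(
        result.p_neg, result.percent_sig_input, result.percent_sig_sf
    )
    return result


def run_query_mode1(
    query: Sequence[ExonRecord],
    registry: Iterable[SFDataset],
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int | None = None,
    min_shared: int = MIN_SHARED_DEFAULT,
    delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
    pvalue_threshold: float = PVALUE_THRESHOLD,
    query_build: str = "",
    keep_pairs: bool = False,
) -> list[ComparisonResult]:
    """Compare a query against every dataset; sort by best Score descending.

    Datasets with too few shared exons (or degenerate ΔPSI) are reported
    with ``computable=False`` and sort last; ties break on dataset id.  Each
    dataset gets an independent RNG stream derived from ``seed``, so results
    do not depend on registry order and are bit-reproducible given a seed.
    """
    datasets = sorted(registry, key=lambda d: d.dataset_id)
    if not datasets:
        raise ValueError("registry is empty")
    check_same_build(query_build, datasets)
    streams = np.random.SeedSequence(seed).spawn(len(datasets))
    results = [
        compare_to_dataset(
            query,
            ds,
            n_permutations=n_permutations,
            seed=np.random.default_rng(stream),
            min_shared=min_shared,
            delta_psi_threshold=delta_psi_threshold,
            pvalue_threshold=pvalue_threshold,
            keep_pairs=keep_pairs,
        )
        for ds, stream in zip(datasets, streams)
    ]
    results.sort(key=lambda r: (-r.best_score, r.dataset_id))
    return results
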