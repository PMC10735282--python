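"""Query mode 2: coordinate-only overlap randomization test.

For a query exon list E and each SF dataset S, the observed count N of
query exons regulated by S is compared with counts obtained for random
control sets of the same size drawn uniformly without replacement from a
universe of exon identities (by default the union over all registry
datasets).  The empirical p-value is the two-sided minimum-tail form

    P_emp = (min(k, l) + 1) / (n_control_sets + 1)

where k is the number of control sets with count >= N and l the number
with count <= N (both inclusive, so k + l >= n_control_sets).  P-values
are Benjamini-Hochberg corrected across all datasets of the query.

Because control sets are uniform without-replacement draws, the count of
regulated exons in one control set is exactly hypergeometric; the control
counts are therefore sampled directly from that distribution, which is
equivalent to materializing each control set and counting.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .model import ExonKey, ExonRecord, SFDataset, check_same_build, registry_universe

N_CONTROL_SETS_DEFAULT = 10_000


def count_regulated(input_exons: Sequence[ExonRecord], dataset: SFDataset) -> int:
    """Number of input exons whose identity appears in the dataset."""
    return len({r.key for r in input_exons} & dataset.keys)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OverlapTestResult:
    sf_id: str
    sf_name: str
    cell_line: str
    n_input: int
    n_observed: int
    expected: float
    k: int
    l: int
    p_emp: float
    direction: str  # enriched | depleted | none
    q_bh: Optional[float] = None
    n_dropped: int = 0


def randomization_test(
    input_exons: Sequence[ExonRecord],
    dataset: SFDataset,
    universe: Iterable[ExonKey],
    n_control_sets: int = N_CONTROL_SETS_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> OverlapTestResult:
    """Two-sided overlap randomization test for one dataset.

    Query exons whose identity is absent from the universe are dropped with
    a warning.  The direction label compares N with the control median:
    ``enriched`` above, ``depleted`` below, ``none`` at the median.
    """
    universe_set = set(universe)
    input_keys = {r.key for r in input_exons}
    if len(universe_set) < len(input_keys):
        raise ValueError(
            f"universe of {len(universe_set)} exons cannot support input "
            f"of size {len(input_keys)}"
        )
    retained = input_keys & universe_set
    n_dropped = len(input_keys) - len(retained)
    if n_dropped:
        _warnings.warn(
            f"{n_dropped} query exon(s) outside the sampling universe were dropped"
        )
    n = len(retained)
    if len(universe_set) < n or n == 0:
        raise ValueError(
            f"universe of {len(universe_set)} exons cannot support input of size {n}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_regulated = len(dataset.keys & universe_set)
    n_observed = len(retained & dataset.keys)
    # count in a uniform without-replacement control set ~ Hypergeometric
    counts = rng.hypergeometric(
        n_regulated, len(universe_set) - n_regulated, n, size=n_control_sets
    )
    k = int(np.sum(counts >= n_observed))
    l = int(np.sum(counts <= n_observed))
    p_emp = (min(k, l) + 1) / (n_control_sets + 1)
    median = float(np.median(counts))
    if n_observed > median:
        direction = "enriched"
    elif n_observed < median:
        direction = "depleted"
    else:
        direction = "none"
    return OverlapTestResult(
        sf_id=dataset.dataset_id,
        sf_name=dataset.sf_name,
        cell_line=dataset.cell_line,
        n_input=n,
        n_observed=n_observed,
        expected=float(counts.mean()),
        k=k,
        l=l,
        p_emp=p_emp,
        direction=direction,
        n_dropped=n_dropped,
    )


def run_query_mode2(
    query: Sequence[ExonRecord],
    registry: Iterable[SFDataset],
    universe: Iterable[ExonKey] | None = None,
    n_control_sets: int = N_CONTROL_SETS_DEFAULT,
    seed: int | None = None,
    query_build: str = "",
    sf_union: bool = False,
) -> list[OverlapTestResult]:
    """Overlap test of a coordinate-only query against every dataset.

    ``universe`` defaults to the union of exon identities over the registry.
    With ``sf_union=True``, datasets of the same SF are pooled (identity
    union) and tested once per SF instead of once per dataset.  BH
    correction is applied across all tests of the run.
    """
    datasets = sorted(registry, key=lambda d: d.dataset_id)
    if not datasets:
        raise ValueError("registry is empty")
    check_same_build(query_build, datasets)
    if sf_union:
        pooled: dict[str, SFDataset] = {}
        for ds in datasets:
            agg = pooled.get(ds.sf_name)
            if agg is None:
                pooled[ds.sf_name] = SFDataset(
                    sf_name=ds.sf_name,
                    cell_line="(union)",
                    build=ds.build,
                    dataset_id=ds.sf_name,
                    exons=dict(ds.exons),
                )
            else:
                for key, rec in ds.exons.items():
                    agg.exons.setdefault(key, rec)
        datasets = [pooled[name] for name in sorted(pooled)]
    if universe is None:
        universe = registry_universe(datasets)
    universe = set(universe)
    streams = np.random.SeedSequence(seed).spawn(len(datasets))
    results = [
        randomization_test(
            query,
            ds,
            universe,
            n_control_sets=n_control_sets,
            seed=np.random.default_rng(stream),
        )
        for ds, stream in zip(datasets, streams)
    ]
    adjusted = bh_adjust([r.p_emp for r in results])
    for res, q in zip(results, adjusted):
        res.q_bh = float(q)
    results.sort(key=lambda r: (r.p_emp, r.sf_id))
    return results
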