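import numpy as np
import pytest

from exonlore.model import ExonRecord, GenomicInterval, SFDataset
from exonlore.synth import RegistrySpec, generate_registry


def make_record(
    chrom="chr1",
    start=1000,
    end=1200,
    strand="+",
    dpsi=None,
    pval=None,
    gene="GENE1",
    exno=1,
):
    return ExonRecord(
        gene_symbol=gene,
        exon_number=exno,
        interval=GenomicInterval(chrom, start, end, strand),
        delta_psi=dpsi,
        adj_pvalue=pval,
    )


def make_dataset(records, sf_name="SF001", **kwargs):
    return SFDataset.from_records(sf_name, records, **kwargs)


def random_records(rng, n, chrom="chrR", with_stats=True, start0=0, spacing=2000):
    """n non-overlapping records with random (not necessarily significant) stats."""
    records = []
    for i in range(n):
        start = start0 + i * spacing
        dpsi = pval = None
        if with_stats:
            dpsi = float(rng.uniform(-60, 60))
            pval = float(rng.uniform(0, 1))
        records.append(
            make_record(
                chrom,
                start,
                start + int(rng.integers(50, 300)),
                "+" if rng.random() < 0.5 else "-",
                dpsi,
                pval,
                gene=f"G{i:05d}",
                exno=1,
            )
        )
    return records


@pytest.fixture(scope="session")
def small_registry():
    """3 SF datasets of 100 exons, 50% pairwise sharing, r = 0.8."""
    spec = RegistrySpec(
        n_sf=3,
        exons_per_dataset=100,
        universe_size=1000,
        overlap=0.5,
        correlation=0.8,
        seed=7,
    )
    return generate_registry(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
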