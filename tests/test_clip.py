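"""Peak merging, flanking windows, regulated classes, and R enrichment."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from exonlore.clip import (
    EnrichmentCell,
    GenomicInterval,
    PSEUDOCOUNT,
    build_regulated_classes,
    enrichment_cell,
    merge_intervals,
    merge_peaks,
    proportion_test,
    r_ratio,
    read_bed,
    region_windows,
    run_clip_panel,
)
from exonlore.model import ExonTableError
from exonlore.synth import RegistrySpec, generate_clip_fixture, generate_registry

from conftest import make_dataset, make_record


class TestMergePeaks:
    def test_overlapping_and_abutting_intervals_coalesce(self):
        peaks = merge_intervals([("chr1", 10, 20), ("chr1", 15, 30)])
        assert peaks.intervals() == [("chr1", 10, 30)]
        peaks = merge_intervals([("chr1", 10, 20), ("chr1", 20, 25)])
        assert peaks.intervals() == [("chr1", 10, 25)]

    def test_matches_quadratic_pairwise_merge_oracle(self, rng):
        intervals = [
            ("chr1", int(s), int(s + rng.integers(1, 200)))
            for s in rng.integers(0, 5000, 500)
        ]
        fast = merge_intervals(intervals).intervals()
        # O(n^2) oracle: repeatedly merge any touching pair until fixpoint
        pool = [list(iv) for iv in intervals]
        changed = True
        while changed:
            changed = False
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    a, b = pool[i], pool[j]
                    if a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]:
                        a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                        del pool[j]
                        changed = True
                        break
                if changed:
                    break
        oracle = sorted((c, s, e) for c, s, e in pool)
        assert fast == oracle

    def test_bed_reading_and_error_location(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t100\t200\tpeak1\t0\t+\nchr1\t150\t250\n")
        assert merge_peaks([bed]).intervals() == [("chr1", 100, 250)]
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\t200\nchr1\tx\t300\n")
        with pytest.raises(ExonTableError, match=r":2:"):
            read_bed(bad)

    def test_point_overlap_queries(self):
        peaks = merge_intervals([("chr1", 100, 200), ("chr1", 500, 600)])
        assert peaks.overlaps("chr1", 150, 160)
        assert peaks.overlaps("chr1", 199, 510)
        assert not peaks.overlaps("chr1", 200, 500)  # gap between peaks
        assert not peaks.overlaps("chr2", 150, 160)


class TestRegionWindows:
    def test_plus_strand_window_arithmetic(self):
        w = region_windows(GenomicInterval("chr1", 1000, 1200, "+"))
        assert (w["up1"].start, w["up1"].end) == (900, 1000)
        assert (w["up2"].start, w["up2"].end) == (800, 900)
        assert (w["up3"].start, w["up3"].end) == (700, 800)
        assert (w["down1"].start, w["down1"].end) == (1200, 1300)
        assert (w["down3"].start, w["down3"].end) == (1400, 1500)
        assert w["exon_body"].start == 1000

    def test_minus_strand_windows_mirror(self):
        w = region_windows(GenomicInterval("chr1", 1000, 1200, "-"))
        assert (w["up1"].start, w["up1"].end) == (1200, 1300)  # 5' is genomic right
        assert (w["down1"].start, w["down1"].end) == (900, 1000)

    def test_truncation_at_chromosome_bounds(self):
        w = region_windows(GenomicInterval("chr1", 50, 150, "+"))
        assert (w["up1"].start, w["up1"].end) == (0, 50)
        assert w["up2"] is None and w["up3"] is None
        w = region_windows(GenomicInterval("chr1", 1000, 1200, "+"), chrom_length=1250)
        assert (w["down1"].start, w["down1"].end) == (1200, 1250)
        assert w["down2"] is None


class TestRegulatedClasses:
    def _ds(self, ups, downs, sf="SF1", cell="A"):
        records = [
            make_record(start=k * 1000, end=k * 1000 + 100, dpsi=20.0, pval=0.01,
                        gene=f"U{k}")
            for k in ups
        ] + [
            make_record(start=k * 1000, end=k * 1000 + 100, dpsi=-20.0, pval=0.01,
                        gene=f"D{k}")
            for k in downs
        ]
        return make_dataset(records, sf_name=sf, cell_line=cell)

    def test_single_dataset_sign_partition(self):
        ds = self._ds(range(5), range(10, 15))
        all_detected = {r.key for r in ds.records()} | {("chrX", 1, 2, "+")}
        classes = build_regulated_classes([ds], all_detected, min_class_size=3)
        assert len(classes.up_exons) == 5 and len(classes.down_exons) == 5
        assert classes.control_exons == {("chrX", 1, 2, "+")}
        assert classes.usable

    def test_opposite_regulation_across_samples_excluded_everywhere(self):
        a = self._ds([1, 2, 3], [10], cell="A")
        b = self._ds([10], [4], cell="B")  # exon 10 up in B but down in A
        detected = {r.key for ds in (a, b) for r in ds.records()}
        classes = build_regulated_classes([a, b], detected, min_class_size=1)
        conflicted_key = ("chr1", 10_000, 10_100, "+")
        assert conflicted_key not in classes.up_exons
        assert conflicted_key not in classes.down_exons
        assert conflicted_key not in classes.control_exons
        assert classes.n_conflicted == 1

    def test_class_of_99_is_not_usable(self):
        ds = self._ds(range(99), range(100, 250))
        classes = build_regulated_classes([ds], {r.key for r in ds.records()})
        assert len(classes.up_exons) == 99
        assert not classes.usable


class TestRRatio:
    def test_equal_proportions_give_zero(self, rng):
        for p in rng.uniform(0, 1, 20):
            assert r_ratio(p, p) == 0.0

    def test_pseudocount_arithmetic(self):
        assert r_ratio(0.99, 0.0) == pytest.approx(math.log2(1.0 / 0.01))

    def test_antisymmetry_and_bound(self, rng):
        for _ in range(200):
            a, b = rng.uniform(0, 1, 2)
            assert r_ratio(a, b) == pytest.approx(-r_ratio(b, a), abs=1e-12)
            assert abs(r_ratio(a, b)) <= math.log2(1.01 / PSEUDOCOUNT) + 1e-12


class TestProportionTest:
    def test_wald_direction_agrees_with_fisher(self, rng):
        agree = 0
        n_cells = 1000
        for _ in range(n_cells):
            n_reg = int(rng.integers(50, 400))
            n_ctrl = int(rng.integers(50, 400))
            p1, p2 = rng.uniform(0.05, 0.95, 2)
            h_reg = int(rng.binomial(n_reg, p1))
            h_ctrl = int(rng.binomial(n_ctrl, p2))
            p_wald = proportion_test(h_reg, n_reg, h_ctrl, n_ctrl)
            p_fish = fisher_exact(
                [[h_reg, n_reg - h_reg], [h_ctrl, n_ctrl - h_ctrl]]
            )[1]
            # same side of 0.5 counts as directional agreement
            if (p_wald - 0.5) * (p_fish - 0.5) >= 0:
                agree += 1
        assert agree / n_cells >= 0.99

    def test_zero_cell_falls_back_to_fisher(self):
        p = proportion_test(0, 100, 30, 100)
        assert p == pytest.approx(
            fisher_exact([[0, 100], [30, 70]])[1]
        )


@pytest.fixture(scope="module")
def planted():
    ann, datasets, _ = generate_registry(
        RegistrySpec(n_sf=1, exons_per_dataset=1000, universe_size=2000, seed=11)
    )
    detected = set(ann.by_coords)
    classes = build_regulated_classes([datasets[0]], detected)
    peaks = generate_clip_fixture(classes, 0.6, 0.2, seed=13)
    return classes, peaks


class TestEnrichmentRecovery:
    def test_planted_rates_recovered_within_binomial_error(self, planted):
        classes, peaks = planted
        reg = classes.up_exons | classes.down_exons
        cell = enrichment_cell(reg, classes.control_exons, peaks, "exon_body")
        sd_reg = math.sqrt(0.6 * 0.4 / cell.n_reg)
        sd_ctrl = math.sqrt(0.2 * 0.8 / cell.n_ctrl)
        assert abs(cell.p_reg - 0.6) < 3 * sd_reg
        assert abs(cell.p_ctrl - 0.2) < 3 * sd_ctrl
        expected_r = math.log2(0.61 / 0.21)
        sd_r = (sd_reg / 0.61 + sd_ctrl / 0.21) / math.log(2)
        assert abs(cell.r_value - expected_r) < 3 * sd_r
        assert cell.pvalue < 1e-10

    def test_flank_windows_without_peaks_show_no_enrichment(self, planted):
        classes, peaks = planted  # peaks planted on exon bodies only
        reg = classes.up_exons | classes.down_exons
        cell = enrichment_cell(reg, classes.control_exons, peaks, "up2")
        assert cell.p_reg <= 0.05 and abs(cell.r_value) < 0.5


class TestNullCalibration:
    def test_bh_significant_fraction_bounded_under_null(self):
        ann, datasets, _ = generate_registry(
            RegistrySpec(n_sf=1, exons_per_dataset=300, universe_size=900, seed=5)
        )
        detected = set(ann.by_coords)
        classes = build_regulated_classes([datasets[0]], detected)
        n_sig = n_cells = 0
        root = np.random.default_rng(2024)
        for rep in range(200):
            peaks = generate_clip_fixture(
                classes,
                0.3,
                0.3,  # identical overlap probability in both classes
                seed=root,
                regions=("exon_body", "up1", "down1"),
            )
            cells = run_clip_panel(
                [datasets[0]], {datasets[0].sf_name: peaks}, detected
            )
            for c in cells:
                if c.region in ("exon_body", "up1", "down1") and c.computable:
                    n_cells += 1
                    n_sig += bool(c.significant)
        assert n_cells > 0
        assert n_sig / n_cells <= 0.05


class TestRunClipPanel:
    def test_panel_shape_and_bh_family(self, small_registry):
        ann, datasets, _ = small_registry
        detected = set(ann.by_coords)
        classes = build_regulated_classes(
            [datasets[0]], detected, min_class_size=10
        )
        peaks = generate_clip_fixture(classes, 0.7, 0.1, seed=3)
        cells = run_clip_panel(
            [datasets[0]],
            {datasets[0].sf_name: peaks},
            detected,
            min_class_size=10,
        )
        assert len(cells) == 14  # 2 classes x 7 regions
        body = [c for c in cells if c.region == "exon_body"]
        assert all(c.significant for c in body)
        assert all(c.q_bh is not None for c in cells if c.computable)

    def test_unusable_sf_discarded(self, small_registry):
        ann, datasets, _ = small_registry
        detected = set(ann.by_coords)
        cells = run_clip_panel(
            [datasets[0]],
            {datasets[0].sf_name: merge_intervals([("chrS1", 0, 10)])},
            detected,
            min_class_size=100,  # ~50 per class only
        )
        assert cells == []
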