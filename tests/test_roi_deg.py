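import numpy as np
import pandas as pd
import pytest
from scipy import stats

import saspatial as sa
from saspatial import errors
from saspatial.moran_local import LocalMoranField


def make_field(barcodes, co_types, gene="g"):
    """Construct a LocalMoranField directly from CO labels."""
    n = len(barcodes)
    z = np.zeros(n)
    return LocalMoranField(
        gene=gene, barcodes=pd.Index(barcodes), Ii=z, expected_Ii=z, variance_Ii=z,
        z=z, p=np.ones(n), co_type=np.asarray(co_types, dtype=object), lag=z,
        s_i_sq=np.ones(n), alpha=0.05, fdr=False,
    )


class TestResolveRoi:
    def test_polygon_covers_4_of_9_spots(self):
        spots = sa.gen_lattice(3, 3, "square")
        roi = sa.RoiDefinition(
            name="sq", mode="polygon", polygon=((-0.5, -0.5), (1.0, -0.5), (1.0, 1.0), (-0.5, 1.0))
        )
        resolved = sa.resolve_roi(roi, spots)
        # boundary counts as inside: spots at (0,0),(1,0),(0,1),(1,1)
        assert resolved == {"S1-r0c0", "S1-r0c1", "S1-r1c0", "S1-r1c1"}

    def test_barcode_list_passthrough(self):
        spots = sa.gen_lattice(3, 3, "square")
        wanted = {"S1-r0c0", "S1-r2c2", "S1-r1c1"}
        roi = sa.RoiDefinition(name="l", barcodes=tuple(wanted))
        assert sa.resolve_roi(roi, spots) == wanted

    def test_off_lattice_polygon_is_empty_roi_error(self):
        spots = sa.gen_lattice(3, 3, "square")
        roi = sa.RoiDefinition(
            name="far", mode="polygon", polygon=((10, 10), (11, 10), (11, 11))
        )
        with pytest.raises(errors.EmptyRoiError):
            sa.resolve_roi(roi, spots)

    def test_unknown_barcode_named(self):
        spots = sa.gen_lattice(3, 3, "square")
        roi = sa.RoiDefinition(name="bad", barcodes=("S1-r0c0", "phantom"))
        with pytest.raises(errors.UnknownBarcodeError, match="phantom"):
            sa.resolve_roi(roi, spots)


class TestChiSquared:
    def test_matches_direct_pearson_formula(self):
        """chi2 on [[30,70],[10,90]] equals the textbook 2x2 formula
        N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
        barcodes = [f"s{i}" for i in range(200)]
        co = ["HH"] * 30 + ["NS"] * 70 + ["HH"] * 10 + ["NS"] * 90
        field = make_field(barcodes, co)
        roi = set(barcodes[:100])
        ref = set(barcodes[100:])
        res = sa.deg_chi2(field, roi, ref, "up")
        a, b, c, d = 30, 70, 10, 90
        n = a + b + c + d
        chi2_direct = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p_direct = stats.chi2.sf(chi2_direct, 1)
        assert res.chi2 == pytest.approx(chi2_direct, abs=1e-10)
        assert res.p == pytest.approx(p_direct, abs=1e-10)
        assert res.rate_difference == pytest.approx(0.2)

    def test_identical_rates_give_zero_statistic(self):
        barcodes = [f"s{i}" for i in range(200)]
        co = (["HH"] * 20 + ["NS"] * 80) * 2
        field = make_field(barcodes, co)
        res = sa.deg_chi2(field, set(barcodes[:100]), set(barcodes[100:]), "up")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_target_everywhere_flagged_untestable(self):
        barcodes = [f"s{i}" for i in range(20)]
        field = make_field(barcodes, ["NS"] * 20)
        res = sa.deg_chi2(field, set(barcodes[:10]), set(barcodes[10:]), "up")
        assert "untestable_zero_target" in res.flags
        assert res.p == 1.0

    def test_down_direction_counts_ll(self):
        barcodes = [f"s{i}" for i in range(40)]
        co = ["LL"] * 10 + ["NS"] * 10 + ["NS"] * 20
        field = make_field(barcodes, co)
        res = sa.deg_chi2(field, set(barcodes[:20]), set(barcodes[20:]), "down")
        assert res.table[0, 0] == 10 and res.table[1, 0] == 0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        barcodes = [f"s{i}" for i in range(120)]
        co = rng.choice(["HH", "NS", "LL"], size=120, p=[0.3, 0.5, 0.2])
        field = make_field(barcodes, co)
        roi, ref = set(barcodes[:50]), set(barcodes[50:])
        ab = sa.deg_chi2(field, roi, ref, "up")
        ba = sa.deg_chi2(field, ref, roi, "up")
        assert ab.chi2 == pytest.approx(ba.chi2, abs=1e-12)
        assert ab.p == pytest.approx(ba.p, abs=1e-12)
        assert ab.rate_difference == pytest.approx(-ba.rate_difference, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        barcodes = [f"s{i}" for i in range(10)]
        field = make_field(barcodes, ["HH"] * 10)
        with pytest.raises(ValueError, match="overlap"):
            sa.deg_chi2(field, set(barcodes[:6]), set(barcodes[4:]), "up")

    def test_type_one_error_calibrated_on_null_fields(self):
        """Null CO fields (iid H-H labels, same rate in ROI and reference)
        reject at alpha=0.05 within binomial 99% bounds over 500 genes."""
        rng = np.random.default_rng(99)
        barcodes = [f"s{i}" for i in range(400)]
        roi, ref = set(barcodes[:80]), set(barcodes[80:])
        rejections = 0
        n_genes = 500
        for _ in range(n_genes):
            co = np.where(rng.random(400) < 0.15, "HH", "NS").astype(object)
            res = sa.deg_chi2(make_field(barcodes, co), roi, ref, "up")
            rejections += res.p < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], n_genes, 0.05)
        assert lo <= rejections <= hi


def test_power_grows_with_planted_effect_size():
    """Detection probability for an ROI-enriched gene increases with the
    effect size and saturates near 1 for strong effects."""
    spots = sa.gen_lattice(10, 10, "square")
    wm = sa.row_standardize(sa.build_weights(spots, "rook"))
    roi_mask = (spots.table["array_row"].between(3, 6) & spots.table["array_col"].between(3, 6))
    roi = set(spots.barcodes[roi_mask.to_numpy()])
    ref = set(spots.barcodes) - roi

    def power(effect, n_sim=10):
        hits = 0
        for seed in range(n_sim):
            x = sa.gen_pattern(
                spots,
                sa.PatternSpec(
                    "roi_enriched",
                    {"baseline": 1.0, "effect": effect, "barcodes": list(roi), "noise_sd": 0.5},
                    seed=seed,
                ),
            ).values[0]
            field = sa.local_moran(sa.GeneVector("g", x), wm, null="analytic",
                                   barcodes=spots.barcodes)
            hits += sa.deg_chi2(field, roi, ref, "up").p < 0.05
        return hits / n_sim

    p0, p1, p2 = power(0.0), power(1.0), power(4.0)
    assert p2 >= 0.9
    assert p2 >= p1 >= p0
    assert p0 <= 0.2


class TestRankingAndMetrics:
    def _result(self, gene, p, rate_diff):
        return sa.DegTestResult(
            gene=gene, direction="up", table=np.array([[1, 1], [1, 1]]), chi2=0.0,
            p=p, rate_roi=0.0, rate_ref=0.0, rate_difference=rate_diff,
        )

    def test_rank_filters_and_orders_by_p(self):
        results = [self._result("a", 0.01, 0.1), self._result("b", 0.001, 0.1),
                   self._result("c", 0.2, 0.9)]
        assert sa.rank_degs(results) == ["b", "a"]

    def test_tie_broken_by_rate_difference_then_name(self):
        results = [self._result("a", 0.01, 0.2), self._result("b", 0.01, 0.4),
                   self._result("d", 0.01, 0.2)]
        assert sa.rank_degs(results) == ["b", "a", "d"]

    def test_top_n_truncation(self):
        results = [self._result(f"g{i}", 0.001 * (i + 1), 0.1) for i in range(5)]
        assert sa.rank_degs(results, top_n=1) == ["g0"]

    def test_roi_ratio_quotient(self):
        barcodes = [f"s{i}" for i in range(100)]
        co = ["HH"] * 5 + ["NS"] * 95
        field = make_field(barcodes, co)
        assert sa.roi_ratio(field, set(barcodes[:10])) == pytest.approx(0.05)
        assert sa.roi_ratio(make_field(barcodes, ["NS"] * 100), set(barcodes)) == 0.0
        assert sa.roi_ratio(make_field(barcodes, ["HH"] * 100), set(barcodes)) == 1.0

    def test_region_specificity_shares(self):
        barcodes = [f"s{i}" for i in range(20)]
        co = ["HH"] * 8 + ["NS"] * 2 + ["HH"] * 2 + ["NS"] * 8
        field = make_field(barcodes, co)
        regions = {"A": set(barcodes[:10]), "B": set(barcodes[10:])}
        table = sa.region_specificity(field, regions).set_index("region")
        assert table.loc["A", "share"] == pytest.approx(0.8)
        assert table.loc["B", "share"] == pytest.approx(0.2)
        assert table["share"].sum() == pytest.approx(1.0)
        assert bool(table.loc["A", "specific"]) and not bool(table.loc["B", "specific"])

    def test_region_specificity_no_hh_flagged(self):
        barcodes = [f"s{i}" for i in range(10)]
        field = make_field(barcodes, ["NS"] * 10)
        table = sa.region_specificity(field, {"A": set(barcodes[:5]), "B": set(barcodes[5:])})
        assert table["share"].isna().all()
        assert not table["specific"].any()

    def test_bh_adjustment_matches_sort_and_cummin_oracle(self):
        rng = np.random.default_rng(31)
        pvals = rng.random(15)
        results = [self._result(f"g{i}", p, 0.1) for i, p in enumerate(pvals)]
        adjusted = sa.multiple_testing_adjust(results)
        # independent BH: sort ascending, p*m/rank, cumulative min from the top
        m = len(pvals)
        order = np.argsort(pvals)
        scaled = pvals[order] * m / np.arange(1, m + 1)
        cummin = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(cummin, 1.0)
        np.testing.assert_allclose([r.p_adjusted for r in adjusted], expected, atol=1e-12)

    def test_bh_single_and_identical(self):
        single = sa.multiple_testing_adjust([self._result("a", 0.03, 0.1)])
        assert single[0].p_adjusted == pytest.approx(0.03)
        same = sa.multiple_testing_adjust([self._result(g, 0.04, 0.1) for g in "abc"])
        assert all(r.p_adjusted == pytest.approx(0.04) for r in same)
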