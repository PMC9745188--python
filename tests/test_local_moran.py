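import numpy as np
import pytest

import saspatial as sa
from saspatial import errors

from conftest import brute_force_local_moran


class TestLocalMoranStatistic:
    def test_checkerboard_every_spot_minus_one(self, checkerboard6):
        """On a checkerboard each spot's lag is the negated own deviation
        and S_i^2 equals the squared deviation, so every I_i = -1."""
        _, wm, gv = checkerboard6
        field = sa.local_moran(gv, wm, null="analytic")
        np.testing.assert_allclose(field.Ii, -1.0, atol=1e-12)

    def test_matches_brute_force_per_spot_loop(self, random25):
        _, wm_raw, wm_std, gv = random25
        for wm in (wm_raw, wm_std):
            for mode in ("local", "global"):
                expected = brute_force_local_moran(gv.x, wm.weights.toarray(), si_mode=mode)
                field = sa.local_moran(gv, wm, null="analytic", si_mode=mode)
                np.testing.assert_allclose(field.Ii, expected, atol=1e-12)

    def test_global_denominator_variant_sums_to_s0_times_global(self, random25):
        """With S_i^2 = sum(Z^2)/n the local statistics aggregate exactly:
        sum_i I_i = S0 * I."""
        _, wm_raw, wm_std, gv = random25
        for wm in (wm_raw, wm_std):
            field = sa.local_moran(gv, wm, null="analytic", si_mode="global")
            stat = sa.global_moran(gv, wm)
            assert field.Ii.sum() == pytest.approx(wm.S0 * stat.I, abs=1e-9)

    def test_expected_local_index(self, random25):
        _, _, wm, gv = random25
        field = sa.local_moran(gv, wm, null="analytic")
        wi = np.asarray(wm.weights.sum(axis=1)).ravel()
        np.testing.assert_allclose(field.expected_Ii, -wi / 24, atol=1e-15)

    def test_constant_gene_rejected(self, square6):
        _, wm = square6
        with pytest.raises(errors.ZeroVarianceError):
            sa.local_moran(sa.GeneVector("flat", np.zeros(36)), wm)

    def test_too_few_permutations_rejected(self, random25):
        _, _, wm, gv = random25
        with pytest.raises(ValueError, match="99"):
            sa.local_moran(gv, wm, n_perm=50)


class TestSignificanceNulls:
    def test_analytic_variance_tracks_permutation_null(self):
        """The closed-form total-randomization variance of I_i agrees with
        the empirical variance over full relabelings (global scaling)."""
        spots = sa.gen_lattice(5, 5, "square")
        wm = sa.row_standardize(sa.build_weights(spots, "rook"))
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        gv = sa.GeneVector("g", x)
        field = sa.local_moran(gv, wm, null="analytic", si_mode="global")
        z = gv.deviations
        m2 = (z**2).mean()
        W = wm.weights.toarray()
        sims = np.empty((20_000, 25))
        for s in range(sims.shape[0]):
            zp = z[rng.permutation(25)]
            sims[s] = zp / m2 * (W @ zp)
        emp = sims.var(axis=0, ddof=1)
        se = emp * np.sqrt(2 / (sims.shape[0] - 1))
        assert (np.abs(field.variance_Ii - emp) < 5 * se).mean() > 0.9

    def test_conditional_p_insensitive_to_nonneighbor_relabeling(self):
        """Shuffling values among non-neighbors of a spot leaves its
        conditional pseudo-p close on average (sanity over seeds)."""
        spots = sa.gen_lattice(5, 5, "square")
        wm = sa.row_standardize(sa.build_weights(spots, "rook"))
        rng = np.random.default_rng(17)
        x = rng.normal(size=25)
        i = spots.barcodes.get_loc("S1-r2c2")
        neigh = set(wm.weights[i].indices) | {i}
        far = np.array([j for j in range(25) if j not in neigh])
        p_orig, p_shuf = [], []
        for seed in range(8):
            x2 = x.copy()
            x2[far] = x2[rng.permutation(far)]
            p_orig.append(sa.local_moran(sa.GeneVector("g", x), wm, seed=seed).p[i])
            p_shuf.append(sa.local_moran(sa.GeneVector("g", x2), wm, seed=seed).p[i])
        assert abs(np.mean(p_orig) - np.mean(p_shuf)) < 0.2

    def test_fdr_typing_is_subset_of_unadjusted(self):
        spots = sa.gen_lattice(8, 8, "square")
        wm = sa.row_standardize(sa.build_weights(spots, "rook"))
        bump = sa.gen_pattern(
            spots, sa.PatternSpec("gaussian_bump", {"sigma": 2.0, "amplitude": 4.0})
        ).values[0]
        x = bump + np.random.default_rng(2).normal(0, 0.3, 64)
        gv = sa.GeneVector("g", x)
        raw = sa.local_moran(gv, wm, seed=9, fdr=False)
        adj = sa.local_moran(gv, wm, seed=9, fdr=True)
        sig_raw = set(np.flatnonzero(raw.co_type != "NS"))
        sig_adj = set(np.flatnonzero(adj.co_type != "NS"))
        assert sig_adj <= sig_raw


class TestCoTyping:
    @pytest.mark.parametrize(
        "dev,lag,sig,expected",
        [
            (1.0, 1.0, True, "HH"),
            (-1.0, -1.0, True, "LL"),
            (1.0, -1.0, True, "HL"),
            (-1.0, 1.0, True, "LH"),
            (1.0, 1.0, False, "NS"),
            (0.0, 1.0, True, "NS"),  # tie on deviation
        ],
    )
    def test_five_categories(self, dev, lag, sig, expected):
        assert sa.classify_co_type(dev, lag, sig) == expected

    def test_hh_spots_concentrate_at_bump(self):
        """On a Gaussian bump, H-H spots sit near the peak and L-L spots in
        the far field."""
        spots = sa.gen_lattice(12, 12, "square")
        wm = sa.row_standardize(sa.build_weights(spots, "rook"))
        bump = sa.gen_pattern(
            spots, sa.PatternSpec("gaussian_bump", {"sigma": 2.0, "amplitude": 3.0})
        ).values[0]
        x = bump + np.random.default_rng(4).normal(0, 0.15, spots.n)
        field = sa.local_moran(sa.GeneVector("g", x), wm, seed=13, n_perm=499)
        center = spots.pixel_coords.mean(axis=0)
        d = np.linalg.norm(spots.pixel_coords - center, axis=1)
        hh, ll = field.co_type == "HH", field.co_type == "LL"
        assert hh.sum() > 0 and ll.sum() > 0
        assert d[hh].mean() < d[ll].mean()

    def test_counts_tally_and_subset(self):
        spots = sa.gen_lattice(12, 12, "square")
        wm = sa.row_standardize(sa.build_weights(spots, "rook"))
        bump = sa.gen_pattern(
            spots, sa.PatternSpec("gaussian_bump", {"sigma": 2.0, "amplitude": 3.0})
        ).values[0]
        field = sa.local_moran(
            sa.GeneVector("g", bump), wm, seed=3, n_perm=199, barcodes=spots.barcodes
        )
        counts = sa.co_type_counts(field)
        assert sum(counts.values()) == field.n
        assert sa.co_type_counts(field, set()) == {t: 0 for t in sa.moran_local.CO_TYPES}
        hh_barcodes = set(field.barcodes[field.co_type == "HH"][:3])
        assert len(hh_barcodes) == 3
        assert sa.co_type_counts(field, hh_barcodes)["HH"] == 3

    def test_unknown_barcode_in_subset_named(self):
        spots = sa.gen_lattice(4, 4, "square")
        wm = sa.row_standardize(sa.build_weights(spots, "rook"))
        field = sa.local_moran(
            sa.GeneVector("g", np.arange(16.0)), wm, null="analytic", barcodes=spots.barcodes
        )
        with pytest.raises(errors.UnknownBarcodeError, match="ghost"):
            sa.co_type_counts(field, {"ghost"})
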