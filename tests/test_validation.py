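"""Data edits, cross-validation design, and the weighted validation statistics."""

import numpy as np
import pandas as pd
import pytest

import crossblup as cb
from crossblup.validation import round_half_away


class TestOutlierFilter:
    def test_constant_group_untouched(self):
        df = pd.DataFrame({"y": [5.0] * 20, "group": 1})
        assert len(cb.outlier_filter(df, "y", "group")) == 20

    def test_extreme_record_removed(self, rng):
        y = np.r_[rng.normal(0, 1, 100), [10.0 * 1.0]]
        y[-1] = 10 * y[:-1].std() + y[:-1].mean()
        df = pd.DataFrame({"y": y, "group": 1})
        out = cb.outlier_filter(df, "y", "group")
        assert len(out) == 100
        assert y[-1] not in out["y"].to_numpy()

    def test_boundary_kept(self):
        # a record at exactly the threshold survives (strict inequality)
        base = np.array([-1.0, 1.0] * 8)
        sd = np.r_[base, [0.0]].std(ddof=1)
        df = pd.DataFrame({"y": np.r_[base, [0.0]], "group": 1})
        df.loc[len(df)] = [3.5 * sd * 0.999, 1]
        out = cb.outlier_filter(df, "y", "group")
        assert len(out) == len(df)

    def test_singleton_group_warned(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 99.0], "group": [1, 1, 1, 2]})
        with pytest.warns(UserWarning, match="size 1"):
            out = cb.outlier_filter(df, "y", "group")
        assert 99.0 in out["y"].to_numpy()


class TestSnpQC:
    def test_low_maf_removed(self):
        dos = np.ones((1000, 2))
        dos[:, 0] = 0.0
        dos[:4, 0] = 1.0   # MAF 0.002 < 0.005
        dos[:, 1] = np.tile([0, 1, 2, 1], 250)
        keep = cb.snp_qc(dos, pairs=np.array([[0, 1]]))
        assert not keep[0] and keep[1]

    def test_mendelian_inconsistency_removed(self, rng):
        n_pairs = 100
        dos = rng.integers(0, 3, (2 * n_pairs, 2)).astype(float)
        pairs = np.column_stack([np.arange(n_pairs), n_pairs + np.arange(n_pairs)])
        dos[:, 0] = 1.0
        # SNP 0: make 2% of pairs opposing homozygotes
        dos[pairs[:2, 0], 0] = 0.0
        dos[pairs[:2, 1], 0] = 2.0
        dos[:, 1] = np.tile([0, 1, 2, 1], 50)
        keep = cb.snp_qc(dos, pairs)
        assert not keep[0] and keep[1]

    def test_clean_data_fully_retained(self, tiny_dataset):
        ds = tiny_dataset
        ped = ds.ped
        g = ds.crossbred_labels
        dos = ds.dosages_for(g)
        # genotyped parent-offspring pairs: none among crossbreds-only rows
        with pytest.warns(UserWarning, match="Mendelian filter skipped"):
            keep = cb.snp_qc(dos, pairs=None, maf_min=0.0)
        assert keep.all()

    def test_call_rate_filter_only_with_missing(self, rng):
        dos = np.ones((100, 2))        # heterozygote-coded, Mendelian-safe
        dos[:20, 0] = np.nan           # call rate 0.8 < 0.95
        keep = cb.snp_qc(dos, pairs=np.array([[0, 1]]), maf_min=0.0)
        assert not keep[0] and keep[1]


class TestFoldsAndSchemes:
    def test_161_sires_give_paper_fold_sizes(self):
        folds = cb.make_folds(range(1, 162), k=5, seed=0)
        assert sorted(len(f) for f in folds) == [32, 32, 32, 32, 33]
        assert sorted(np.concatenate(folds).tolist()) == list(range(1, 162))

    def test_even_split(self):
        folds = cb.make_folds(range(10), k=5, seed=1)
        assert [len(f) for f in folds] == [2] * 5

    def test_fold_determinism(self):
        a = cb.make_folds(range(50), 5, seed=42)
        b = cb.make_folds(range(50), 5, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            cb.make_folds(range(3), k=5)

    def test_full_rate_selects_everyone(self):
        sel = cb.apply_genotyping_scheme(range(1, 21), 1.0, "RND", seed=0)
        assert np.array_equal(sel, np.arange(1, 21))

    def test_top_selection_is_rank_based(self):
        sel = cb.apply_genotyping_scheme(np.arange(1, 11), 0.5, "TOP",
                                         phenotypes=np.arange(1.0, 11.0), seed=0)
        assert np.array_equal(sel, np.arange(6, 11))

    def test_top_differs_between_traits(self, rng):
        animals = np.arange(1, 101)
        t1 = rng.normal(size=100)
        t2 = rng.normal(size=100)
        s1 = cb.apply_genotyping_scheme(animals, 0.5, "TOP", t1, seed=3)
        s2 = cb.apply_genotyping_scheme(animals, 0.5, "TOP", t2, seed=3)
        assert not np.array_equal(s1, s2)

    def test_rate_menu_enforced(self):
        with pytest.raises(ValueError, match="menu"):
            cb.apply_genotyping_scheme(range(10), 0.6, "RND")


class TestCameronReliability:
    @pytest.mark.parametrize("n,h2,expected", [
        (2, 0.26, 0.12), (430, 0.26, 0.97), (404, 0.25, 0.96)])
    def test_printed_endpoints(self, n, h2, expected):
        assert round_half_away(cb.cameron_reliability(n, h2), 2) == expected

    def test_single_offspring_closed_form(self):
        assert cb.cameron_reliability(1, 0.3) == pytest.approx(0.3 / 4)

    def test_monotone_and_saturating(self):
        n = np.arange(1, 2000)
        r = cb.cameron_reliability(n, 0.26)
        assert (np.diff(r) > 0).all()
        assert r[-1] < 1.0 and r[-1] > 0.99
        assert cb.cameron_reliability(50, 0.4) > cb.cameron_reliability(50, 0.2)


class TestSireProgenyMeans:
    def test_no_fixed_variation_gives_raw_means(self):
        df = pd.DataFrame({"y": [1.0, 3.0, 2.0, 6.0], "fixed": 0,
                           "sire": [1, 1, 2, 2]})
        rec = cb.sire_progeny_means(df, h2=0.25)
        centred = rec["progeny_mean"].to_numpy()
        raw = np.array([2.0, 4.0])
        # a common intercept is absorbed; sire contrasts survive exactly
        assert np.allclose(np.diff(centred), np.diff(raw))

    def test_balanced_fixed_shifts_cancel(self, rng):
        sires = np.repeat(np.arange(10), 8)
        pens = np.tile([0, 1], 40)   # each sire balanced across both pens
        base = rng.normal(size=80)
        for delta in (0.0, 7.0):
            y = base + delta * (pens == 1)
            df = pd.DataFrame({"y": y, "fixed": pens, "sire": sires})
            rec = cb.sire_progeny_means(df, 0.26)
            if delta == 0.0:
                ref = rec["progeny_mean"].to_numpy()
        assert np.allclose(rec["progeny_mean"].to_numpy(), ref, atol=1e-8)

    def test_small_families_excluded_with_warning(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "fixed": 0, "sire": [1, 1, 2]})
        with pytest.warns(UserWarning, match="< 2 offspring"):
            rec = cb.sire_progeny_means(df, 0.26)
        assert rec["sire"].tolist() == [1]

    def test_reliability_attached(self):
        df = pd.DataFrame({"y": np.arange(8.0), "fixed": 0,
                           "sire": np.repeat([1, 2], 4)})
        rec = cb.sire_progeny_means(df, 0.26)
        assert rec["reliability"].to_numpy() == pytest.approx(
            cb.cameron_reliability(np.array([4, 4]), 0.26))


class TestWeightedStatistics:
    def test_equal_weights_reduce_to_pearson(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        w = np.full(40, 0.37)
        assert cb.weighted_accuracy(x, y, w) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_proportional_vectors_give_unit_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert cb.weighted_accuracy(x, 3 * x, [0.2, 0.5, 0.9, 0.4]) == pytest.approx(1.0)

    def test_weighted_moments_against_explicit_arithmetic(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = np.array([0.5, 1.9, 4.2, 7.0])
        w = np.array([0.1, 0.4, 0.3, 0.2])
        sw = w.sum()
        mx, my = (w * x).sum() / sw, (w * y).sum() / sw
        cxy = (w * (x - mx) * (y - my)).sum() / sw
        vx = (w * (x - mx) ** 2).sum() / sw
        vy = (w * (y - my) ** 2).sum() / sw
        assert cb.weighted_accuracy(x, y, w) == pytest.approx(cxy / np.sqrt(vx * vy))
        assert cb.dispersion_slope(x, y, w) == pytest.approx(2 * cxy / vx)

    def test_dispersion_doubling(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.ones(4)
        assert cb.dispersion_slope(g, 0.5 * g, w) == pytest.approx(1.0)
        assert cb.dispersion_slope(g, g, w) == pytest.approx(2.0)

    def test_degenerate_variance_reported_missing(self):
        assert np.isnan(cb.weighted_accuracy([1, 1, 1], [1, 2, 3], [1, 1, 1]))

    def test_too_few_sires_rejected(self):
        with pytest.raises(ValueError, match="3 sires"):
            cb.weighted_accuracy([1, 2], [1, 2], [1, 1])

    def test_report_rounding_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(0.124, 2) == 0.12


class TestScenarioGrid:
    def test_grid_shape_and_determinism(self, tiny_dataset):
        cfg = cb.GridConfig(n_folds=3, replicates=1, max_folds_per_replicate=1,
                            seed=5)
        d1 = cb.scenario_grid(tiny_dataset, cfg)
        d2 = cb.scenario_grid(tiny_dataset, cfg)
        pd.testing.assert_frame_equal(d1, d2)
        # 4 J-methods x 4 rates = 16 scenario cells per trait
        assert d1.groupby(["j_method", "rate"]).ngroups == 16
        # the degenerate cells carry a note
        none100 = d1[(d1.rate == 1.0) & (d1.j_method == "NONE")]
        assert none100["note"].str.contains("identical to ONE").all()
        top100 = d1[(d1.rate == 1.0) & (d1.scheme == "TOP")]
        assert top100["note"].str.contains("duplicate of RND").all()

    def test_restricted_grid_single_cell(self, tiny_dataset):
        cfg = cb.GridConfig(j_methods=("ONE",), rates=(1.0,), schemes=("RND",),
                            n_folds=3, replicates=1, max_folds_per_replicate=1,
                            seed=5)
        d = cb.scenario_grid(tiny_dataset, cfg)
        assert len(d) == 1

    def test_bad_grid_values_rejected(self):
        with pytest.raises(ValueError, match="menu"):
            cb.GridConfig(rates=(0.9,))
        with pytest.raises(ValueError, match="J method"):
            cb.GridConfig(j_methods=("SOME",))
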