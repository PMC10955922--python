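import numpy as np
import pytest
from scipy import stats

from specblend import (
    CLASS_MASKS,
    MIXTURE_CLASSES,
    PerturbationConfig,
    apply_perturbations,
    generate_dataset,
    kfold,
    sample_concentrations,
    split_holdout,
)
from specblend.dataset import default_allocation


class TestSampleConcentrations:
    def test_single_gas_classes(self, rng):
        lab = sample_concentrations("M", rng)
        assert lab.ci == (1, 0, 0)
        assert 0 <= lab.cr[0] <= 50 and lab.cr[1] == 0 and lab.cr[2] == 0

        lab = sample_concentrations("W", rng)
        assert lab.ci == (0, 0, 1)
        assert 1000 <= lab.cr[2] <= 2000

    def test_absent_gas_exactly_zero_for_every_class(self, rng):
        for cls, mask in CLASS_MASKS.items():
            lab = sample_concentrations(cls, rng)
            assert lab.ci == mask
            for g, c in zip(mask, lab.cr):
                if g == 0:
                    assert c == 0.0
                else:
                    assert c >= 0.0

    def test_uniform_distribution_not_rejected(self):
        rng = np.random.default_rng(77)
        draws = np.array([sample_concentrations("MAW", rng).cr for _ in range(10_000)])
        for i, (lo, hi) in enumerate([(0, 50), (0, 50), (1000, 2000)]):
            assert draws[:, i].min() >= lo and draws[:, i].max() <= hi
            p = stats.kstest(draws[:, i], stats.uniform(lo, hi - lo).cdf).pvalue
            assert p > 0.01

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_concentrations("XYZ", rng)


class TestPerturbations:
    def test_all_disabled_is_exact_identity(self, rng):
        x = rng.normal(0.2, 0.05, 500)
        cfg = PerturbationConfig(
            enable_power_fluct=False,
            enable_unknown_bands=False,
            enable_noise=False,
            enable_baseline=False,
        )
        out = apply_perturbations(x, cfg, rng)
        assert np.array_equal(out, x)

    def test_noise_only_folded_normal_mean(self):
        rng = np.random.default_rng(5)
        sigma = 0.02
        cfg = PerturbationConfig(
            enable_power_fluct=False,
            enable_unknown_bands=False,
            enable_baseline=False,
            noise_sigma=sigma,
        )
        x = np.zeros(100_000)
        out = apply_perturbations(x, cfg, rng)
        assert np.mean(np.abs(out)) == pytest.approx(
            sigma * np.sqrt(2 / np.pi), rel=0.02
        )

    def test_unknown_bands_additive_and_local(self):
        rng = np.random.default_rng(8)
        wn = np.linspace(2950, 3150, 3321)
        cfg = PerturbationConfig(
            enable_power_fluct=False,
            enable_noise=False,
            enable_baseline=False,
            unknown_band_count_range=(1, 3),
            unknown_band_width_range=(1.0, 5.0),
        )
        x = np.zeros_like(wn)
        out = apply_perturbations(x, cfg, rng, wavenumbers=wn)
        delta = out - x
        assert np.all(delta >= 0)
        assert np.any(delta > 0)
        # bands are truncated: most of the window stays exactly zero
        assert np.mean(delta == 0) > 0.5

    def test_power_fluctuation_is_multiplicative_in_transmittance(self):
        rng = np.random.default_rng(3)
        cfg = PerturbationConfig(
            enable_unknown_bands=False, enable_noise=False, enable_baseline=False,
            power_fluct_amplitude=0.02,
        )
        x = np.full(1000, 0.7)
        out = apply_perturbations(x, cfg, rng)
        # alpha' = alpha - ln(g) with |g - 1| <= 2%
        gain = np.exp(x - out)
        assert np.all(np.abs(gain - 1.0) <= 0.021)


class TestGenerateDataset:
    def test_one_sample_per_class(self, small_grid, demo_units):
        alloc = {c: 1 for c in MIXTURE_CLASSES}
        ds = generate_dataset(7, small_grid, demo_units, class_allocation=alloc, seed=1)
        patterns = {tuple(row) for row in ds.Y[:, :3].astype(int)}
        assert patterns == set(CLASS_MASKS.values())

    def test_deterministic_given_seed(self, small_grid, demo_units):
        a = generate_dataset(21, small_grid, demo_units, seed=9)
        b = generate_dataset(21, small_grid, demo_units, seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)
        assert np.array_equal(a.classes, b.classes)

    def test_allocation_counts_exact(self, small_grid, demo_units):
        alloc = default_allocation(700)
        ds = generate_dataset(700, small_grid, demo_units, class_allocation=alloc, seed=2)
        counts = np.bincount(ds.classes, minlength=7)
        assert all(counts[i] == alloc[c] for i, c in enumerate(MIXTURE_CLASSES))

    def test_allocation_mismatch_rejected(self, small_grid, demo_units):
        with pytest.raises(ValueError, match="allocation"):
            generate_dataset(
                10, small_grid, demo_units, class_allocation={"M": 3}, seed=0
            )

    def test_label_consistency(self, small_grid, demo_units):
        ds = generate_dataset(70, small_grid, demo_units, seed=4)
        ci, cr = ds.Y[:, :3], ds.Y[:, 3:]
        assert np.all(cr[ci == 0] == 0)
        assert np.all(cr[ci == 1] > 0)
        # clean spectra contain no contribution from absent gases: a class-W
        # clean sample is exactly water-unit times its concentration
        w_idx = MIXTURE_CLASSES.index("W")
        rows = np.where(ds.classes == w_idx)[0]
        assert rows.size > 0
        j = rows[0]
        assert np.allclose(ds.X_clean[j], ds.Y[j, 5] * demo_units[2].values)


class TestSplits:
    def test_holdout_9_to_1(self):
        split = split_holdout(100, 0.1, seed=0)
        assert split.train.size == 90 and split.test.size == 10
        assert np.intersect1d(split.train, split.test).size == 0
        assert np.array_equal(
            np.sort(np.concatenate([split.train, split.test])), np.arange(100)
        )

    def test_kfold_ten_folds_of_nine(self):
        folds = kfold(np.arange(90), 10, seed=1)
        assert len(folds) == 10
        assert all(val.size == 9 for _, val in folds)

    @pytest.mark.parametrize("n,k", [(37, 5), (100, 7), (12, 12)])
    def test_folds_disjoint_and_covering(self, n, k):
        idx = np.arange(1000, 1000 + n)
        folds = kfold(idx, k, seed=3)
        all_val = np.concatenate([val for _, val in folds])
        assert np.array_equal(np.sort(all_val), idx)
        for train, val in folds:
            assert np.intersect1d(train, val).size == 0
            assert np.array_equal(np.sort(np.concatenate([train, val])), idx)
        sizes = sorted(val.size for _, val in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            split_holdout(10, 1.5, seed=0)
        with pytest.raises(ValueError):
            kfold(np.arange(5), 6, seed=0)
        with pytest.raises(ValueError):
            kfold(np.arange(5), 1, seed=0)
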