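"""Correlation, GC-Ka tables, PCA regression, ridge selection, feature tests."""

import numpy as np
import pandas as pd
import pytest

from gcaa import (
    AA_ORDER,
    AAFeatureTable,
    GeneFamilyMatrix,
    correlate,
    feature_table_tests,
    gene_gc_ka_table,
    pca_regression,
    ridge_fit,
)


def _family(name, X, gc, ka):
    data = pd.DataFrame({f"f_{aa}": X[:, i] for i, aa in enumerate(AA_ORDER)})
    data["gc_percent"] = gc
    data["ka"] = ka
    return GeneFamilyMatrix(name, data)


def _random_compositions(rng, n, latent=None, load=None):
    """Dirichlet compositions, optionally tilted by a latent variable."""
    X = rng.dirichlet(np.full(20, 8.0), size=n)
    if latent is not None:
        X = X * np.exp(np.outer(latent, load))
        X = X / X.sum(axis=1, keepdims=True)
    return X


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2, 3, 4, 5]
        r, p = correlate(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r_xy, _ = correlate(x, y)
        r_yx, _ = correlate(y, x)
        r_affine, _ = correlate(3.0 * x + 7.0, y)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert r_xy == pytest.approx(r_affine, abs=1e-10)

    def test_independent_data_rarely_correlates(self, rng):
        big = 0
        for _ in range(100):
            x = rng.normal(size=20)
            y = rng.permutation(x)
            r, _ = correlate(x, y)
            big += abs(r) >= 0.6
        assert big <= 5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1, 1, 1], [1, 2, 3])

    def test_p_values_never_exactly_zero(self):
        x = np.linspace(0, 1, 50)
        _, p = correlate(x, 2 * x + 1e-6 * np.sin(x))
        assert 0 < p <= 1


class TestGeneGcKaTable:
    def test_exact_linear_family_gives_r_one(self, rng):
        gc = np.linspace(30, 70, 12)
        fam = _family("fam", _random_compositions(rng, 12), gc, 0.01 * gc + 0.1)
        table = gene_gc_ka_table([fam])
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert "q" in table.columns

    def test_antithetic_family_gives_negative_r(self, rng):
        gc = np.linspace(30, 70, 20)
        ka = -0.01 * gc + 1.0 + rng.normal(0, 0.01, size=20)
        fam = _family("fam", _random_compositions(rng, 20), gc, ka)
        assert gene_gc_ka_table([fam])["r"].iloc[0] < 0

    def test_small_families_skipped_with_warning(self, rng):
        gc = np.linspace(30, 70, 7)
        fam = _family("tiny", _random_compositions(rng, 7), gc, gc * 0.01)
        with pytest.warns(UserWarning, match="tiny"):
            table = gene_gc_ka_table([fam])
        assert len(table) == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gene_gc_ka_table([])


class TestPcaRegression:
    def test_constructed_linear_response_is_recovered(self, rng):
        # response is a linear function of composition acting through the
        # dominant axes of variation, the case PCR is designed to capture
        X = _random_compositions(rng, 60)
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        beta = vt[:4].T @ np.array([3.0, -2.0, 1.5, 1.0])
        ka = X @ beta + rng.normal(0, 1e-4, size=60)
        fam = _family("fam", X, rng.uniform(30, 70, 60), ka)
        res = pca_regression(fam, n_components=6)
        assert res.r_squared > 0.95

    def test_full_rank_matches_ols(self, rng):
        X = _random_compositions(rng, 40)
        ka = X @ rng.normal(size=20) + rng.normal(0, 0.05, size=40)
        fam = _family("fam", X, rng.uniform(30, 70, 40), ka)
        with pytest.warns(UserWarning, match="rank"):
            res = pca_regression(fam, n_components=20)  # compositions have rank 19
        Xc = X - X.mean(axis=0)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(40), Xc]), ka, rcond=None)
        fitted = np.column_stack([np.ones(40), Xc]) @ coef
        ss_res = np.sum((ka - fitted) ** 2)
        ss_tot = np.sum((ka - ka.mean()) ** 2)
        assert res.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)

    def test_r_squared_monotone_in_components(self, rng):
        X = _random_compositions(rng, 50)
        ka = X @ rng.normal(size=20) + rng.normal(0, 0.1, size=50)
        fam = _family("fam", X, rng.uniform(30, 70, 50), ka)
        r2 = [pca_regression(fam, n_components=k).r_squared for k in (1, 2, 4, 6, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_pc1_tracks_gc_when_gc_drives_composition(self, rng, feature_table):
        latent = rng.uniform(-1, 1, size=60)
        load = 0.8 * (np.array(feature_table.vector("gc_class")) - 1.0)
        X = _random_compositions(rng, 60, latent=latent, load=load)
        gc = 50 + 20 * latent + rng.normal(0, 1, 60)
        fam = _family("fam", X, gc, rng.uniform(0, 1, 60))
        res = pca_regression(fam)
        assert abs(res.pc1_gc_correlation) > 0.8

    def test_too_few_rows_rejected(self, rng):
        fam = _family("fam", _random_compositions(rng, 6), np.arange(6), np.arange(6) * 0.1)
        with pytest.raises(ValueError, match="rows"):
            pca_regression(fam, n_components=6)


class TestRidgeFit:
    def test_constructed_signal_selected(self, rng):
        X = _random_compositions(rng, 80)
        a_idx, d_idx = AA_ORDER.index("A"), AA_ORDER.index("D")
        ka = 5.0 * X[:, a_idx] - 5.0 * X[:, d_idx] + rng.normal(0, 0.02, size=80)
        fam = _family("fam", X, rng.uniform(30, 70, 80), ka)
        res = ridge_fit(fam, n_perm=300, seed=1)
        assert "A" in res.selected_positive
        assert "D" in res.selected_negative

    def test_noise_rarely_selected(self, rng):
        empty = 0
        for seed in range(10):
            X = _random_compositions(rng, 60)
            fam = _family("fam", X, rng.uniform(30, 70, 60), rng.normal(size=60))
            res = ridge_fit(fam, n_perm=300, seed=seed)
            empty += not (res.selected_positive | res.selected_negative)
        assert empty >= 9

    def test_coefficients_shrink_with_penalty(self, rng):
        from sklearn.linear_model import Ridge

        X = _random_compositions(rng, 50)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        y = rng.normal(size=50)
        norms = [
            np.linalg.norm(Ridge(alpha=a).fit(Xs, y).coef_) for a in (0.01, 1, 100, 1e4)
        ]
        assert norms == sorted(norms, reverse=True)

    def test_too_few_rows_rejected(self, rng):
        fam = _family("fam", _random_compositions(rng, 8), np.arange(8), np.arange(8.0))
        with pytest.raises(ValueError, match="10"):
            ridge_fit(fam)


class TestFeatureTableTests:
    def test_six_pairwise_correlations(self, feature_table):
        res = feature_table_tests(feature_table)
        assert len(res.correlations) == 6
        assert ((res.correlations["p"] > 0) & (res.correlations["p"] <= 1)).all()

    def test_identical_features_correlate_perfectly(self, feature_table):
        frame = feature_table.frame.reset_index().copy()
        frame["mol_weight"] = frame["cost"]
        res = feature_table_tests(AAFeatureTable(frame))
        row = res.correlations.query("feature_a == 'cost' and feature_b == 'mol_weight'")
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_gc_rich_amino_acids_are_cheaper(self, feature_table):
        res = feature_table_tests(feature_table)
        assert res.mean_cost_gc_rich < res.mean_cost_at_rich
        assert res.cost_contrast_p < 0.05
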