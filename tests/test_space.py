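import numpy as np
import pandas as pd
import pytest

import phenospace as ph
from phenospace.space import (EncodedMatrix, compute_mpdi, drop_linear_combinations,
                              encode_traits, famd, hypervolume_log_ratio,
                              pillai_trace, species_disjunction)


def _em(df, forms=None):
    forms = pd.Series(forms if forms is not None else ["wild"] * len(df),
                      index=df.index)
    return EncodedMatrix(df, [(c, c, None) for c in df.columns], forms)


class TestEncoding:
    def test_z_score_hand_example(self):
        df = pd.DataFrame({
            "species_id": "s", "accession_id": list("abc"),
            "form": ["wild", "wild", "domestic"], "x": [1.0, 2.0, 3.0]})
        t = ph.TraitTable(df, [ph.TraitMeta("x", "continuous")])
        em = encode_traits(t)
        np.testing.assert_allclose(em.matrix["x"], [-1.0, 0.0, 1.0])

    def test_five_level_trait_becomes_five_binaries(self):
        df = pd.DataFrame({
            "species_id": "s", "accession_id": [f"a{i}" for i in range(10)],
            "form": ["wild"] * 5 + ["domestic"] * 5,
            "q": list("ABCDE") * 2})
        t = ph.TraitTable(df, [ph.TraitMeta("q", "qualitative")])
        em = encode_traits(t)
        assert em.matrix.shape[1] == 5
        assert set(np.unique(em.matrix.to_numpy())) == {0.0, 1.0}
        np.testing.assert_allclose(em.matrix.sum(axis=1), 1.0)

    def test_standardization_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"species_id": "s",
                           "accession_id": [f"a{i}" for i in range(20)],
                           "form": ["wild"] * 10 + ["domestic"] * 10, "x": x})
        em = encode_traits(ph.TraitTable(df, [ph.TraitMeta("x", "continuous")]))
        np.testing.assert_allclose(em.matrix["x"], x, atol=1e-12)

    def test_zero_variance_trait_dropped_with_warning(self):
        df = pd.DataFrame({"species_id": "s", "accession_id": list("abcd"),
                           "form": ["wild", "wild", "domestic", "domestic"],
                           "x": [1.0, 2.0, 3.0, 4.0], "z": [5.0] * 4})
        t = ph.TraitTable(df, [ph.TraitMeta("x", "continuous"),
                               ph.TraitMeta("z", "continuous")])
        with pytest.warns(UserWarning, match="z"):
            em = encode_traits(t)
        assert list(em.matrix.columns) == ["x"]

    def test_all_constant_fatal(self):
        df = pd.DataFrame({"species_id": "s", "accession_id": list("ab"),
                           "form": ["wild", "domestic"], "z": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                encode_traits(ph.TraitTable(df, [ph.TraitMeta("z", "continuous")]))


class TestLinearCombinationRemoval:
    def test_sum_column_dropped(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        df = pd.DataFrame({"a": a, "b": b, "c": a + b})
        red = drop_linear_combinations(df)
        assert list(red.columns) == ["a", "b"]
        assert np.linalg.matrix_rank(df.to_numpy() - df.to_numpy().mean(0)) == 2

    def test_full_rank_unchanged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        pd.testing.assert_frame_equal(drop_linear_combinations(df), df)

    def test_one_hot_block_loses_one_column(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(0, 4, size=40)
        onehot = pd.get_dummies(levels).astype(float)
        red = drop_linear_combinations(onehot)
        assert red.shape[1] == 3  # centered one-hot block of k levels has rank k-1

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=15)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=15)})
        once = drop_linear_combinations(df)
        pd.testing.assert_frame_equal(drop_linear_combinations(once), once)


class TestHypervolume:
    def test_identical_forms_zero(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(25, 4)))
        s = hypervolume_log_ratio(_em(X), _em(X.copy(), ["domestic"] * 25))
        assert s.log_ratio == pytest.approx(0.0, abs=1e-12)
        assert s.r == 4

    def test_uniform_scaling_closed_form(self):
        """dom = c * wild with p = r gives log_ratio = (2p/r) ln c = 2 ln c."""
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        for c in (2.0, 0.5):
            s = hypervolume_log_ratio(_em(X), _em(X * c, ["domestic"] * 30))
            assert s.log_ratio == pytest.approx(2 * np.log(c), abs=1e-8)

    def test_antisymmetric_under_form_swap(self):
        rng = np.random.default_rng(7)
        W = pd.DataFrame(rng.normal(size=(25, 3)))
        D = pd.DataFrame(rng.normal(scale=1.7, size=(22, 3)))
        a = hypervolume_log_ratio(_em(W), _em(D, ["domestic"] * 22))
        b = hypervolume_log_ratio(_em(D, ["domestic"] * 22), _em(W))
        assert a.log_ratio == pytest.approx(-b.log_ratio, abs=1e-10)

    def test_degenerate_form_fatal(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        flat = pd.DataFrame(np.ones((10, 3)), columns=X.columns)  # no variation at all
        with pytest.raises(ValueError, match="domestic"):
            hypervolume_log_ratio(_em(X), _em(flat, ["domestic"] * 10))

    def test_reduction_caps_dimension_below_row_count(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(4, 5)))  # more traits than rows
        s = hypervolume_log_ratio(_em(X), _em(X.copy(), ["domestic"] * 4))
        assert s.dim_wild <= 3 and s.dim_dom <= 3  # centered rank <= n - 1


class TestFamd:
    @staticmethod
    def _mixed_table(n=30, seed=9):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "species_id": "s", "accession_id": [f"a{i}" for i in range(n)],
            "form": ["wild"] * (n // 2) + ["domestic"] * (n - n // 2),
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "q": rng.choice(list("ABC"), size=n),
        })
        meta = [ph.TraitMeta("x1", "continuous"), ph.TraitMeta("x2", "continuous"),
                ph.TraitMeta("q", "qualitative")]
        return ph.TraitTable(df, meta)

    def test_all_quantitative_equals_standardized_pca(self):
        rng = np.random.default_rng(10)
        n = 25
        df = pd.DataFrame({"species_id": "s",
                           "accession_id": [f"a{i}" for i in range(n)],
                           "form": ["wild"] * 12 + ["domestic"] * 13})
        for j in range(4):
            df[f"x{j}"] = rng.normal(size=n)
        meta = [ph.TraitMeta(f"x{j}", "continuous") for j in range(4)]
        scores, eig = famd(ph.TraitTable(df, meta))
        X = df[[f"x{j}" for j in range(4)]].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=0)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        pca_scores = Z @ Vt.T
        for j in range(scores.shape[1]):
            r = abs(np.corrcoef(scores.iloc[:, j], pca_scores[:, j])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(np.sort(eig)[::-1], (s ** 2) / n, atol=1e-8)

    def test_all_qualitative_matches_mca_subspace(self):
        """On purely qualitative data the FAMD axes span the correspondence-
        analysis (MCA) axes of the indicator matrix, up to sign/scale."""
        rng = np.random.default_rng(11)
        n = 40
        df = pd.DataFrame({"species_id": "s",
                           "accession_id": [f"a{i}" for i in range(n)],
                           "form": ["wild"] * 20 + ["domestic"] * 20,
                           "q1": rng.choice(list("AB"), size=n),
                           "q2": rng.choice(list("XYZ"), size=n)})
        meta = [ph.TraitMeta("q1", "qualitative"), ph.TraitMeta("q2", "qualitative")]
        scores, _ = famd(ph.TraitTable(df, meta))
        # brute-force MCA: SVD of the centered, 1/sqrt(p)-scaled indicators
        Z = pd.get_dummies(df[["q1", "q2"]]).to_numpy(dtype=float)
        p = Z.mean(0)
        M = (Z - p) / np.sqrt(p)
        U, s, Vt = np.linalg.svd(M / np.sqrt(n), full_matrices=False)
        mca_scores = M @ Vt.T
        for j in range(min(2, scores.shape[1])):
            r = abs(np.corrcoef(scores.iloc[:, j], mca_scores[:, j])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_individuals_identical_scores(self):
        t = self._mixed_table()
        df2 = pd.concat([t.data, t.data.iloc[[0]].assign(accession_id="dup")],
                        ignore_index=True)
        scores, _ = famd(ph.TraitTable(df2, t.traits))
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[-1], atol=1e-10)

    def test_single_individual_fatal(self):
        df = pd.DataFrame({"species_id": "s", "accession_id": ["a"],
                           "form": ["wild"], "x": [1.0]})
        with pytest.raises(ValueError):
            famd(ph.TraitTable(df, [ph.TraitMeta("x", "continuous")]))


class TestPillai:
    def test_univariate_anova_identity(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        f = ["wild", "wild", "domestic", "domestic"]
        assert pillai_trace(x, f) == pytest.approx(100 / 101, abs=1e-12)

    def test_identical_group_means_zero(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        f = ["wild", "wild", "domestic", "domestic"]
        assert pillai_trace(x, f) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_eigen_solution(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 3))
        X[10:] += [1.0, -0.5, 0.3]
        f = np.array(["wild"] * 10 + ["domestic"] * 10)
        # explicit H and E cross-product construction
        grand = X.mean(0)
        H = np.zeros((3, 3)); E = np.zeros((3, 3))
        for g in ("wild", "domestic"):
            sub = X[f == g]
            m = sub.mean(0)
            H += len(sub) * np.outer(m - grand, m - grand)
            E += (sub - m).T @ (sub - m)
        expected = np.trace(H @ np.linalg.inv(H + E))
        assert pillai_trace(X, f) == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_invertible_linear_map(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(24, 4))
        X[12:] += 0.8
        f = ["wild"] * 12 + ["domestic"] * 12
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        assert pillai_trace(X @ A, f) == pytest.approx(pillai_trace(X, f), abs=1e-8)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 3))
        X[15:] += [0.5, 1.0, -0.2]
        f = np.array(["wild"] * 15 + ["domestic"] * 15)
        mv = MANOVA(X, pd.get_dummies(f, dtype=float).to_numpy())
        # statsmodels: test joint group-mean structure via contrast on the
        # difference of the two group-mean parameters
        res = mv.mv_test(hypotheses=[("form", np.array([[1.0, -1.0]]))])
        stat = res.results["form"]["stat"]
        sm_pillai = float(stat.loc["Pillai's trace", "Value"])
        assert pillai_trace(X, f) == pytest.approx(sm_pillai, abs=1e-10)


class TestMpdi:
    def test_arithmetic(self):
        d = compute_mpdi(0.9, 0.1)
        assert d.mpdi == pytest.approx(0.8)
        assert d.mpdi_per_baseline == pytest.approx(8.0)

    def test_equal_components_zero(self):
        assert compute_mpdi(0.4, 0.4).mpdi == pytest.approx(0.0)

    def test_zero_baseline_flagged(self):
        d = compute_mpdi(0.6, 0.0)
        assert d.mpdi == pytest.approx(0.6)
        assert d.baseline_undefined and np.isnan(d.mpdi_per_baseline)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            compute_mpdi(1.2, 0.0)


class TestSpeciesDisjunction:
    def test_individual_mismatch_fatal(self, small_params):
        t = ph.simulate_species_traits(small_params, "sp01")
        leaf = pd.DataFrame({"LNIRS1": [0.0], "LNIRS2": [0.0]}, index=["nope"])
        with pytest.raises(ValueError, match="missing"):
            species_disjunction(t, leaf)

    def test_matched_drift_gives_near_zero_mpdi(self):
        """When the control axes carry divergence as strong as the traits
        themselves (the apple-like sampling artifact), mPDI collapses to ~0."""
        params = ph.SimParams(n_leaf_wavelengths=300, seed_form_shift=2.0, rng_seed=21)
        inds = [(f"w{i}", "wild") for i in range(12)] + [(f"d{i}", "domestic") for i in range(12)]
        spectra = ph.simulate_spectra(params, "seed", inds)  # strong form signal
        pre = ph.preprocess_spectra(spectra)
        res = ph.pcoa(pre)
        axes = ph.spectra_to_traits(res, "LNIRS")
        df = pd.DataFrame({
            "species_id": "apple_like",
            "accession_id": axes.index,
            "form": ["wild"] * 12 + ["domestic"] * 12,
            "t1": axes["LNIRS1"].to_numpy(),
            "t2": axes["LNIRS2"].to_numpy(),
        })
        t = ph.TraitTable(df, [ph.TraitMeta("t1", "continuous"),
                               ph.TraitMeta("t2", "continuous")])
        d = species_disjunction(t, axes)
        assert d.pillai_all > 0.4  # forms genuinely disjoint on the traits
        assert abs(d.mpdi) < 0.05  # but no divergence beyond the baseline

    def test_permuted_forms_center_near_zero(self, small_params):
        rng = np.random.default_rng(22)
        t = ph.simulate_species_traits(small_params, "sp01")
        leaf = ph.simulate_spectra(small_params, "leaf",
                                   list(zip(t.individual_ids(), t.data["form"])),
                                   rng=np.random.default_rng(5))
        traits, _ = ph.nirs_control_traits(leaf, prefix="LNIRS")
        mpdis = []
        for _ in range(10):
            df = t.data.copy()
            perm = rng.permutation(len(df))
            df["form"] = df["form"].to_numpy()[perm]
            # keep accession labels consistent with permuted forms
            tt = ph.TraitTable(df, t.traits)
            mpdis.append(species_disjunction(tt, traits).mpdi)
        assert abs(float(np.mean(mpdis))) < 0.25
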