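"""SIMCA class models: PCA fit, residual statistics, F-test, distances."""

import numpy as np
import pytest
from scipy import integrate, special

from gcmsannot import simca, synth
from gcmsannot.simca import (
    ClassModel,
    DegenerateModelError,
    TrainingSet,
    choose_components_cv,
    classify,
    cross_validate_models,
    f_test_membership,
    fit_class_model,
    important_mz,
    interclass_distance,
    project_and_residual,
    residual_sd_training,
    rsd_from_residual_matrix,
)


def rank_k_training(rng, m=10, p=20, k=1, noise=0.0, name="toy"):
    """Rows = positive offset + k-dimensional latent structure + noise."""
    basis = np.linalg.qr(rng.normal(size=(p, k)))[0]
    X = 50.0 + rng.normal(0, 10, (m, k)) @ basis.T + rng.normal(0, noise, (m, p))
    return TrainingSet(name, np.abs(X), tuple(f"c{i}" for i in range(m)))


class TestFitClassModel:
    def test_noiseless_rank1_has_zero_s0(self, rng):
        train = rank_k_training(rng, k=1)
        model = fit_class_model(train, r=1)
        assert model.s0 == pytest.approx(0.0, abs=1e-9)

    def test_rank1_loading_recovers_direction_up_to_sign(self, rng):
        basis = np.linalg.qr(rng.normal(size=(20, 1)))[0][:, 0]
        X = 50.0 + rng.normal(0, 10, (8, 1)) * basis
        train = TrainingSet("toy", np.abs(X), tuple(f"c{i}" for i in range(8)))
        model = fit_class_model(train, r=1)
        assert abs(float(model.loadings[:, 0] @ basis)) == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_error_equals_discarded_singular_values(self, rng):
        """SVD identity: residual sum of squares after keeping r components
        equals the sum of the discarded squared singular values."""
        train = rank_k_training(rng, m=10, p=20, k=9, noise=3.0)
        model = fit_class_model(train, r=2)
        Xc = train.X - model.mean
        E = Xc - (Xc @ model.loadings) @ model.loadings.T
        discarded = np.linalg.svd(Xc, compute_uv=False)[2:] ** 2
        assert np.sum(E * E) == pytest.approx(np.sum(discarded), rel=1e-10)

    def test_m_too_small_for_r(self, rng):
        train = rank_k_training(rng, m=4, k=1)
        with pytest.raises(ValueError, match="m >= r \\+ 2"):
            fit_class_model(train, r=3)

    def test_loadings_orthonormal(self, rng):
        model = fit_class_model(rank_k_training(rng, m=12, p=30, k=6, noise=2.0), r=3)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(3), atol=1e-9)


class TestEckartYoung:
    @pytest.mark.parametrize("r", [1, 2, 4])
    def test_fitted_error_is_the_rank_r_minimum(self, rng, r):
        """Brute-force check of optimality: no random rank-r basis beats the
        fitted reconstruction error (Eckart-Young)."""
        train = rank_k_training(rng, m=15, p=25, k=14, noise=4.0)
        model = fit_class_model(train, r=r)
        Xc = train.X - model.mean
        E = Xc - (Xc @ model.loadings) @ model.loadings.T
        best = np.sum(E * E)
        svals = np.linalg.svd(Xc, compute_uv=False)
        assert best == pytest.approx(np.sum(svals[r:] ** 2), rel=1e-8)
        for _ in range(25):
            V = np.linalg.qr(rng.normal(size=(25, r)))[0]
            E_rand = Xc - (Xc @ V) @ V.T
            assert np.sum(E_rand * E_rand) >= best - 1e-8


class TestChooseComponents:
    def test_noiseless_rank1_selects_one(self, rng):
        assert choose_components_cv(rank_k_training(rng, k=1), r_max=5) == 1

    def test_rank2_with_high_snr_selects_two(self, rng):
        train = rank_k_training(rng, m=14, p=400, k=2, noise=0.3)
        assert choose_components_cv(train, r_max=5) == 2

    def test_pure_iid_noise_selects_parsimony_floor(self, rng):
        X = np.abs(50.0 + rng.normal(0, 1.0, (12, 400)))
        train = TrainingSet("noise", X, tuple(f"c{i}" for i in range(12)))
        assert choose_components_cv(train, r_max=5) == 1


class TestResidualSD:
    def test_formula_on_unit_residuals(self):
        # m=5, p=3, r=1: sqrt(15 / ((5-1-1)(3-1))) = sqrt(2.5)
        E = np.ones((5, 3))
        assert rsd_from_residual_matrix(E, m=5, r=1) == pytest.approx(np.sqrt(2.5))

    def test_noiseless_rank_r_gives_zero(self, rng):
        train = rank_k_training(rng, k=2)
        model = fit_class_model(train, r=2)
        assert residual_sd_training(train, model) == pytest.approx(0.0, abs=1e-9)

    def test_homogeneity_under_intensity_doubling(self, rng):
        train = rank_k_training(rng, m=10, p=20, k=9, noise=2.0)
        doubled = TrainingSet("x2", 2.0 * train.X, train.compound_names)
        m1 = fit_class_model(train, r=1)
        m2 = fit_class_model(doubled, r=1)
        assert m2.s0 == pytest.approx(2.0 * m1.s0, rel=1e-9)


class TestProjection:
    @pytest.fixture
    def model(self, rng):
        return fit_class_model(rank_k_training(rng, m=10, p=20, k=9, noise=2.0), r=2)

    def test_model_mean_projects_to_zero(self, model):
        scores, resid, s_j = project_and_residual(model.mean, model)
        assert np.allclose(scores, 0.0)
        assert s_j == pytest.approx(0.0, abs=1e-12)

    def test_in_space_object_has_zero_residual(self, model):
        x = model.mean + model.loadings @ np.array([3.0, -7.0])
        _, _, s_j = project_and_residual(x, model)
        assert s_j == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_unit_norm_per_dof_gives_sj_one(self, model, rng):
        u = rng.normal(size=model.p)
        u -= model.loadings @ (model.loadings.T @ u)
        u *= np.sqrt(model.p - model.r) / np.linalg.norm(u)
        _, _, s_j = project_and_residual(model.mean + u, model)
        assert s_j == pytest.approx(1.0, abs=1e-9)


def f_sf_by_quadrature(x, d1, d2):
    """Upper tail of the F distribution by numerical integration of its
    density (independent of scipy.stats.f)."""
    lognorm = (
        special.gammaln((d1 + d2) / 2)
        - special.gammaln(d1 / 2)
        - special.gammaln(d2 / 2)
        + (d1 / 2) * np.log(d1 / d2)
    )

    def pdf(t):
        return np.exp(
            lognorm + (d1 / 2 - 1) * np.log(t) - ((d1 + d2) / 2) * np.log(1 + d1 * t / d2)
        )

    val, _ = integrate.quad(pdf, x, np.inf, limit=200)
    return val


class TestFTest:
    def test_equal_residuals_are_members(self):
        F, p, member = f_test_membership(2.0, 2.0, m=12, r=1, alpha=0.05)
        assert F == pytest.approx(1.0)
        assert member

    def test_zero_object_residual(self):
        F, p, member = f_test_membership(0.0, 1.5, m=12, r=1, alpha=0.05)
        assert F == 0.0
        assert p == pytest.approx(1.0)
        assert member

    def test_large_ratio_rejected_with_quadrature_oracle(self):
        # organic-acid-sized class (m = 12), residual ratio 10
        F, p, member = f_test_membership(10.0, 1.0, m=12, r=1, alpha=0.05)
        assert F == pytest.approx(100.0)
        assert not member
        assert p == pytest.approx(f_sf_by_quadrature(100.0, 10, 100), rel=1e-6)

    def test_classical_convention_df(self):
        F, p, _ = f_test_membership(
            2.0, 1.0, m=12, r=1, alpha=0.05, p=416, df_convention="classical"
        )
        assert p == pytest.approx(f_sf_by_quadrature(4.0, 415, 415 * 10), rel=1e-6)

    def test_degenerate_model_raises(self):
        with pytest.raises(DegenerateModelError):
            f_test_membership(1.0, 0.0, m=12, r=1, alpha=0.05)


class TestClassify:
    def test_class_mean_is_assigned_to_its_class(self, training_sets, class_models):
        model = class_models[0]
        report = classify(model.mean, class_models, alpha=0.05)
        assert report.final_label == model.class_name
        assert not report.multi_class

    def test_distant_orthogonal_object_is_unknown(self, class_models, rng):
        x = np.abs(rng.normal(0, 300.0, class_models[0].p))
        report = classify(x, class_models, alpha=0.05)
        assert report.final_label == "unknown"
        assert all(not cs.member for cs in report.per_class.values())

    def test_two_accepting_classes_resolved_by_largest_p(self, rng):
        """Two overlapping classes both accept a shared object; the final
        label follows the larger p-value and the multi-class flag is set."""
        base = rank_k_training(rng, m=12, p=50, k=1, noise=1.0, name="one")
        X2 = base.X + rng.normal(0, 1.0, base.X.shape)
        twin = TrainingSet("two", X2, base.compound_names)
        models = [fit_class_model(base, r=1), fit_class_model(twin, r=1)]
        x = base.X.mean(axis=0) + rng.normal(0, 1.0, 50)
        report = classify(x, models, alpha=0.05)
        assert all(cs.member for cs in report.per_class.values())
        assert report.multi_class
        best = max(report.per_class, key=lambda k: report.per_class[k].p_value)
        assert report.final_label == best

    def test_permutation_invariant_in_model_order(self, class_models, training_sets):
        x = training_sets[2].X[0]
        fwd = classify(x, class_models, alpha=0.05)
        rev = classify(x, list(reversed(class_models)), alpha=0.05)
        assert fwd.final_label == rev.final_label
        assert fwd.per_class == rev.per_class

    def test_dimension_mismatch_names_model(self, class_models, rng):
        bad = fit_class_model(rank_k_training(rng, m=10, p=20, k=9, noise=1.0, name="bad20"), r=1)
        with pytest.raises(ValueError, match="bad20"):
            classify(np.zeros(416), class_models + [bad], alpha=0.05)


class TestInterclassDistance:
    def test_model_against_itself_is_exactly_zero(self, training_sets, class_models):
        for t, m in zip(training_sets, class_models):
            assert interclass_distance(m, m, t, t) == 0.0

    def test_symmetric(self, training_sets, class_models):
        d12 = interclass_distance(class_models[0], class_models[1], training_sets[0], training_sets[1])
        d21 = interclass_distance(class_models[1], class_models[0], training_sets[1], training_sets[0])
        assert d12 == pytest.approx(d21, rel=1e-12)

    def test_separated_synthetic_classes_exceed_one(self, training_sets, class_models):
        """Classes built on disjoint diagnostic fragments at 5% noise are
        'really different': D > 1 for every pair."""
        n = len(class_models)
        for i in range(n):
            for j in range(i + 1, n):
                d = interclass_distance(
                    class_models[i], class_models[j], training_sets[i], training_sets[j]
                )
                assert d > 1.0

    def test_monotone_in_mean_shift(self, rng):
        """D grows with the separation between two otherwise identical
        classes (three increasing shifts)."""
        base = rank_k_training(rng, m=10, p=60, k=1, noise=1.0, name="a")
        direction = np.zeros(60)
        direction[:6] = 1.0
        dists = []
        for shift in (2.0, 8.0, 32.0):
            X2 = base.X + shift * direction
            other = TrainingSet("b", X2, base.compound_names)
            m1 = fit_class_model(base, r=1)
            m2 = fit_class_model(other, r=1)
            dists.append(interclass_distance(m1, m2, base, other))
        assert dists[0] < dists[1] < dists[2]


class TestImportantMz:
    def test_variance_concentrated_bin_ranks_first(self, rng):
        X = np.full((10, 416), 10.0)
        X[:, 299 - 85] += rng.normal(0, 20.0, 10)
        X += rng.normal(0, 0.01, X.shape)
        train = TrainingSet("t", np.abs(X), tuple(f"c{i}" for i in range(10)))
        model = fit_class_model(train, r=1)
        assert important_mz(model, train, k=1)[0] == 299

    def test_constant_offset_leaves_ranking_unchanged(self, training_sets, class_models):
        t, m = training_sets[0], class_models[0]
        shifted = TrainingSet(t.class_name, t.X + 5.0, t.compound_names)
        m2 = fit_class_model(shifted, r=m.r)
        assert important_mz(m, t, k=10) == important_mz(m2, shifted, k=10)

    def test_amine_diagnostic_masses_in_top_ranks(self):
        """An amine-like class whose compound-to-compound variation lives on
        the diagnostic fragments m/z 86 and 174 ranks both in the top-4.
        The base peak (m/z 100 here) is the normalization reference, carries
        no variance, and so is never 'important'."""
        amine_like = synth.ClassTemplate(
            class_name="amine_like",
            diagnostic_masses=(86, 100, 174),
            background_masses=(95, 130, 210, 305, 390),
            diagnostic_intensities=(80.0, 100.0, 75.0),
            background_intensities=(8.0, 5.0, 12.0, 6.0, 9.0),
            intensity_sd_rel=0.05,
        )
        train = synth.make_training_set(amine_like, m=13, seed=77, baseline_sd=0.5)
        model = fit_class_model(train, r="auto")
        top4 = important_mz(model, train, k=4)
        assert 86 in top4
        assert 174 in top4


class TestCrossValidation:
    def test_five_class_benchmark_is_diagonal(self, training_sets):
        cm = cross_validate_models(training_sets, alpha=0.05)
        arr = cm.to_numpy()
        sizes = [t.m for t in training_sets]
        assert list(np.diag(arr[:, : len(training_sets)])) == sizes
        assert arr.sum() == sum(sizes)

    def test_duplicated_class_is_confusable(self, rng):
        base = rank_k_training(rng, m=10, p=60, k=1, noise=1.0, name="one")
        twin = TrainingSet("two", base.X + rng.normal(0, 1.0, base.X.shape), base.compound_names)
        cm = cross_validate_models([base, twin], alpha=0.05)
        arr = cm.to_numpy()
        off_diag = arr[0, 1] + arr[1, 0]
        diag = arr[0, 0] + arr[1, 1]
        # indistinguishable classes: assignments follow the largest p-value,
        # so a substantial share lands in the twin class
        assert off_diag >= 5 or diag < 15

    def test_single_class_rejected(self, training_sets):
        with pytest.raises(ValueError):
            cross_validate_models(training_sets[:1])


class TestSerialization:
    def test_json_round_trip(self, class_models, tmp_path):
        path = tmp_path / "models.json"
        simca.save_models(class_models, path)
        back = simca.load_models(path)
        for a, b in zip(class_models, back):
            assert a.class_name == b.class_name
            assert a.r == b.r and a.m == b.m and a.p == b.p
            assert a.s0 == pytest.approx(b.s0, rel=1e-12)
            assert np.allclose(a.mean, b.mean)
            assert np.allclose(a.loadings, b.loadings)


class TestTrainingCSV:
    def test_round_trip(self, training_sets, tmp_path):
        path = tmp_path / "training.csv"
        simca.write_training_csv(training_sets, path)
        back = simca.load_training_csv(path)
        assert [t.class_name for t in back] == [t.class_name for t in training_sets]
        for a, b in zip(training_sets, back):
            assert a.compound_names == b.compound_names
            assert np.allclose(a.X, b.X, atol=1e-9)
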