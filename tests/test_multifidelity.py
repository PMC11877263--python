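"""Sub-model bookkeeping, nested sampling, and the four model families."""

import numpy as np
import pytest

from mflearn.krr import MaternKernelRidge
from mflearn.multifidelity import (
    DeltaKRR,
    MultiFidelityKRR,
    SubModelIndex,
    build_submodel_set,
    draw_nested_training,
    optimize_beta,
)


class TestSubmodelSet:
    def test_enumeration_four_levels(self):
        got = build_submodel_set(F=4, eta_F=1, fb=2)
        pos = {s for s, b in got if b == +1}
        neg = {s for s, b in got if b == -1}
        assert pos == {SubModelIndex(4, 1), SubModelIndex(3, 2), SubModelIndex(2, 3)}
        assert neg == {SubModelIndex(3, 1), SubModelIndex(2, 2)}

    def test_enumeration_two_levels(self):
        got = build_submodel_set(F=2, eta_F=0, fb=1)
        assert {(s, b) for s, b in got} == {
            (SubModelIndex(2, 0), 1.0), (SubModelIndex(1, 1), 1.0), (SubModelIndex(1, 0), -1.0)}

    def test_degenerate_fb_equals_F(self):
        assert build_submodel_set(3, 2, 3) == [(SubModelIndex(3, 2), 1.0)]

    @pytest.mark.parametrize("F,eta,fb", [(4, 0, 1), (4, 3, 2), (2, 5, 1), (5, 0, 5)])
    def test_beta_rule_and_telescoping_sum(self, F, eta, fb):
        got = build_submodel_set(F, eta, fb)
        for s, b in got:
            assert b == (1.0 if s.f + s.eta == F + eta else -1.0)
        assert sum(b for _, b in got) == 1.0
        assert len(got) == 2 * (F - fb) + 1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_submodel_set(3, 0, 4)
        with pytest.raises(ValueError):
            build_submodel_set(3, -1, 1)


class TestNestedTraining:
    def test_prefix_nesting_sizes(self):
        labels = np.ones((8, 2))
        s = draw_nested_training(labels, F=2, eta_F=1, fb=1, seed=0)
        assert s.n_train(1) == 4 and s.n_train(2) == 2
        assert set(s.nested_indices[2]) <= set(s.nested_indices[1])
        assert np.array_equal(s.nested_indices[2], s.nested_indices[1][:2])

    def test_seeded_determinism(self):
        labels = np.ones((32, 3))
        a = draw_nested_training(labels, 3, 2, 1, seed=11)
        b = draw_nested_training(labels, 3, 2, 1, seed=11)
        for f in a.nested_indices:
            assert np.array_equal(a.nested_indices[f], b.nested_indices[f])

    def test_insufficient_pool_names_fidelity(self):
        labels = np.ones((8, 2))
        with pytest.raises(ValueError, match="cheap"):
            draw_nested_training(labels, 2, 3, 1, seed=0, fidelity_names=["cheap", "dear"])

    def test_partial_top_coverage_prefers_fully_labeled(self):
        labels = np.ones((12, 2))
        labels[6:, 1] = np.nan  # only 6 molecules labeled at the top
        s = draw_nested_training(labels, F=2, eta_F=2, fb=1, seed=3)
        assert set(s.nested_indices[2]) <= set(range(6))
        assert s.n_train(1) == 8  # draws into the cheap-only tier

    def test_exclusion(self):
        labels = np.ones((16, 2))
        s = draw_nested_training(labels, 2, 1, 1, seed=0, exclude=range(8))
        assert set(s.nested_indices[1]).isdisjoint(range(8))


def _toy_multifidelity(n=40, seed=0, gap=1.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2, 2, size=(n, 2))
    base = np.sin(X[:, 0]) + 0.3 * X[:, 1] ** 2
    Y = np.column_stack([base + gap * np.cos(X[:, 1]), base])
    return X, Y


class TestDeltaKRR:
    def test_identical_fidelities_alpha_zero(self):
        X, _ = _toy_multifidelity()
        Y = np.column_stack([np.ones(40), np.ones(40)])
        m = DeltaKRR(n_train=8).fit(X, Y)
        assert np.all(m.krr_.alpha_ == 0.0)
        pred = m.predict(X[:5], y_baseline=np.arange(5.0))
        assert np.array_equal(pred, np.arange(5.0))

    def test_single_point_closed_form(self):
        X = np.array([[0.0, 0.0], [9.0, 9.0]])
        Y = np.array([[1.0, 4.0], [0.0, 0.0]])
        m = DeltaKRR(n_train=1, sigma=1.0, lam=0.5, random_state=0).fit(X, Y)
        dy = Y[m.train_indices_[0], 1] - Y[m.train_indices_[0], 0]
        assert m.krr_.alpha_[0] == pytest.approx(dy / 1.5, abs=1e-14)

    def test_interpolation_recovers_target_at_training_point(self):
        X, Y = _toy_multifidelity()
        m = DeltaKRR(sigma=1.0, lam=0.0, random_state=1).fit(X, Y)
        i = m.train_indices_[0]
        pred = m.predict(X[[i]], y_baseline=Y[i, 0])
        assert pred[0] == pytest.approx(Y[i, 1], abs=1e-8)

    def test_linearity_in_baseline(self):
        X, Y = _toy_multifidelity()
        m = DeltaKRR(n_train=16, random_state=2).fit(X, Y)
        p0 = m.predict(X[:4], y_baseline=np.zeros(4))
        p1 = m.predict(X[:4], y_baseline=np.full(4, 7.0))
        assert np.allclose(p1 - p0, 7.0)

    def test_requires_baseline_and_enough_data(self):
        X, Y = _toy_multifidelity()
        m = DeltaKRR(n_train=4).fit(X, Y)
        with pytest.raises(ValueError, match="baseline"):
            m.predict(X[:2])
        with pytest.raises(ValueError, match="insufficient"):
            DeltaKRR(n_train=100).fit(X, Y)

    def test_seeded_determinism(self):
        X, Y = _toy_multifidelity()
        a = DeltaKRR(n_train=8, random_state=5).fit(X, Y)
        b = DeltaKRR(n_train=8, random_state=5).fit(X, Y)
        assert np.array_equal(a.train_indices_, b.train_indices_)
        assert np.array_equal(a.krr_.alpha_, b.krr_.alpha_)


class TestMultiFidelityKRR:
    def test_fb_equals_F_is_plain_krr(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=3, fb=2, target_fidelity=2, random_state=0).fit(X, Y)
        idx = m.structure_.nested_indices[2]
        k = MaternKernelRidge(sigma=m.sigma_).fit(X[idx], Y[idx, 1])
        assert np.allclose(m.predict(X[:10]), k.predict(X[:10]), atol=1e-12)

    def test_telescoping_collapse_on_toy_data(self):
        X, Y0 = _toy_multifidelity()
        Y = np.column_stack([Y0[:, 1]] * 2)  # identical labels at both fidelities
        m = MultiFidelityKRR(eta_target=2, fb=1, random_state=4).fit(X, Y)
        idx = m.structure_.nested_indices[1]
        k = MaternKernelRidge(sigma=m.sigma_).fit(X[idx], Y[idx, 1])
        assert np.max(np.abs(m.predict(X[:10]) - k.predict(X[:10]))) <= 1e-8

    def test_mfdelta_all_equal_to_lowest_returns_baseline(self):
        X, _ = _toy_multifidelity()
        base = np.cos(X[:, 0])
        Y = np.column_stack([base, base])
        m = MultiFidelityKRR(eta_target=2, fb=1, variant="mfdelta", random_state=0).fit(X, Y)
        q = np.linspace(-1, 1, 6)
        assert np.array_equal(m.predict(X[:6], y_baseline=q), q)

    def test_mfdelta_requires_baseline_and_mfml_rejects_it(self):
        X, Y = _toy_multifidelity()
        md = MultiFidelityKRR(eta_target=1, fb=1, variant="mfdelta", random_state=0).fit(X, Y)
        with pytest.raises(ValueError, match="lowest-fidelity"):
            md.predict(X[:2])
        mm = MultiFidelityKRR(eta_target=1, fb=1, variant="mfml", random_state=0).fit(X, Y)
        with pytest.raises(ValueError, match="y_baseline"):
            mm.predict(X[:2], y_baseline=np.zeros(2))

    def test_beta_values_match_rule(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=2, fb=1, random_state=0).fit(X, Y)
        for s, beta in m.beta_.items():
            assert beta == (1.0 if s.f + s.eta == 2 + 2 else -1.0)
        assert sum(m.beta_.values()) == 1.0

    def test_seeded_determinism_bit_identical(self):
        X, Y = _toy_multifidelity()
        a = MultiFidelityKRR(eta_target=3, fb=1, random_state=9).fit(X, Y)
        b = MultiFidelityKRR(eta_target=3, fb=1, random_state=9).fit(X, Y)
        assert np.array_equal(a.predict(X[:7]), b.predict(X[:7]))

    def test_unknown_variant_rejected(self):
        X, Y = _toy_multifidelity()
        with pytest.raises(ValueError, match="variant"):
            MultiFidelityKRR(variant="bogus").fit(X, Y)


class TestOptimizeBeta:
    def test_single_submodel_closed_form(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=3, fb=2, target_fidelity=2, random_state=0).fit(X, Y)
        Xv, yv = X[20:], Y[20:, 1]
        o = optimize_beta(m, Xv, yv)
        P = m.submodel_predictions(Xv)[:, 0]
        expected = float(np.dot(yv, P) / np.dot(P, P))
        assert list(o.beta_.values())[0] == pytest.approx(expected, abs=1e-10)

    def test_never_worse_than_fixed_beta(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=2, fb=1, random_state=1).fit(X, Y, exclude=range(30, 40))
        Xv, yv = X[30:], Y[30:, 1]
        o = optimize_beta(m, Xv, yv)
        assert o.validation_error(Xv, yv, p=2) <= m.validation_error(Xv, yv, p=2) + 1e-9
        assert o.variant == "omfml" and m.variant == "mfml"  # original untouched

    def test_feasible_exact_fit_reaches_zero_error(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=2, fb=1, random_state=2).fit(X, Y)
        Xv = X[25:]
        yv = m.predict(Xv)  # labels equal the fixed-beta predictions
        o = optimize_beta(m, Xv, yv)
        assert o.validation_error(Xv, yv, p=2) <= 1e-16

    def test_p1_objective_never_worse(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=1, fb=1, random_state=3).fit(X, Y)
        Xv, yv = X[25:], Y[25:, 1]
        o = optimize_beta(m, Xv, yv, p=1.0)
        assert o.validation_error(Xv, yv, p=1.0) <= m.validation_error(Xv, yv, p=1.0) + 1e-9

    def test_requires_fitted_mfml_and_nonempty_validation(self):
        X, Y = _toy_multifidelity()
        md = MultiFidelityKRR(eta_target=1, fb=1, variant="mfdelta", random_state=0).fit(X, Y)
        with pytest.raises(ValueError, match="mfml"):
            optimize_beta(md, X[:5], Y[:5, 1])
        m = MultiFidelityKRR(eta_target=1, fb=1, random_state=0).fit(X, Y)
        with pytest.raises(ValueError, match="empty"):
            optimize_beta(m, X[:0], Y[:0, 1])

    def test_underdetermined_validation_warns(self):
        X, Y = _toy_multifidelity()
        m = MultiFidelityKRR(eta_target=2, fb=1, random_state=1).fit(X, Y)
        with pytest.warns(UserWarning, match="validation"):
            optimize_beta(m, X[:2], Y[:2, 1])


def test_mf_persistence_roundtrip(tmp_path):
    from mflearn.persist import load_model, save_model

    X, Y = _toy_multifidelity()
    for variant, kwargs in [("mfml", {}), ("mfdelta", {"y_baseline": Y[:5, 0]})]:
        m = MultiFidelityKRR(eta_target=2, fb=1, variant=variant, random_state=1).fit(X, Y)
        path = tmp_path / f"{variant}.npz"
        save_model(m, path)
        m2 = load_model(path)
        assert np.array_equal(m.predict(X[:5], **kwargs), m2.predict(X[:5], **kwargs))
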