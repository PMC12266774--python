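import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from salamech.errors import (
    EvaluationError,
    GridMismatchError,
    InvalidFoldsError,
    NonConvergenceError,
    UndefinedCBIError,
)
from salamech.synthetic import OccurrenceSet, sample_occurrences
from salamech.sdm import (
    SuitabilitySurface,
    ensemble,
    evaluate_auc,
    evaluate_cbi,
    evaluate_tss,
    fit_envelope,
    fit_logistic,
    kfold_cv,
    threshold_suitable,
)
from .conftest import make_grid, single_var_stack


def occ_at_cells(grid, rows, cols, species="sp"):
    x, y = grid.cell_center(np.asarray(rows), np.asarray(cols))
    return OccurrenceSet(np.column_stack([x, y]), species)


def surface_from(values, cell_size=3.0):
    return SuitabilitySurface(make_grid(values, cell_size))


class TestEnvelope:
    def fit_on_values(self, presence_values):
        """Envelope on one variable whose presence values are given."""
        n = len(presence_values)
        side = int(np.ceil(np.sqrt(n)))
        vals = np.zeros(side * side)
        vals[:n] = presence_values
        grid_vals = vals.reshape(side, side)
        stack = single_var_stack(grid_vals)
        rows, cols = np.unravel_index(np.arange(n), (side, side))
        occ = occ_at_cells(stack.grid, rows, cols)
        return fit_envelope(occ, stack), stack

    def test_score_one_inside_envelope(self):
        model, _ = self.fit_on_values(np.linspace(0, 100, 101))
        assert model.score_matrix(np.array([[50.0]]), ["BIO1"])[0] == pytest.approx(1.0)

    def test_score_zero_far_outside(self):
        model, _ = self.fit_on_values(np.linspace(0, 100, 101))
        assert model.score_matrix(np.array([[1e4]]), ["BIO1"])[0] == 0.0
        assert model.score_matrix(np.array([[-1e4]]), ["BIO1"])[0] == 0.0

    def test_boundary_percentile_inclusive(self):
        vals = np.linspace(0, 100, 101)
        model, _ = self.fit_on_values(vals)
        p5 = np.percentile(vals, 5)
        assert model.score_matrix(np.array([[p5]]), ["BIO1"])[0] == pytest.approx(1.0)

    def test_linear_decay_outside_box(self):
        model, _ = self.fit_on_values(np.linspace(0, 100, 101))
        s_mid = model.score_matrix(np.array([[-12.5]]), ["BIO1"])[0]
        assert 0.0 < s_mid < 1.0

    def test_constant_predictor_dropped_with_warning(self):
        grid_vals = np.full((4, 4), 7.0)
        stack = single_var_stack(grid_vals)
        stack.variables["BIO2"] = stack.grid.like(np.arange(16.0).reshape(4, 4))
        occ = occ_at_cells(stack.grid, np.arange(4).repeat(4) % 4, np.tile(np.arange(4), 4))
        with pytest.warns(UserWarning, match="constant predictor"):
            model = fit_envelope(occ, stack)
        assert model.variables == ["BIO2"]


class TestLogistic:
    def elevationish_stack(self, seed=0):
        rng = np.random.default_rng(seed)
        elev = np.linspace(300, 2000, 400).reshape(20, 20)
        bio1 = 25 - 0.006 * elev + rng.normal(0, 0.3, (20, 20))
        return single_var_stack(bio1)

    def test_sign_recovery_on_high_elevation_presences(self):
        stack = self.elevationish_stack()
        grid = stack.grid
        # presences in the coolest (high-elevation) rows, background everywhere
        occ = occ_at_cells(grid, np.repeat(np.arange(15, 20), 10), np.tile(np.arange(10), 5))
        rng = np.random.default_rng(1)
        bg = occ_at_cells(grid, rng.integers(0, 20, 200), rng.integers(0, 20, 200))
        model = fit_logistic(occ, bg, stack, l2=0.01)
        assert model.coef[0] < 0  # warmer = lower elevation = less suitable

    def test_strong_ridge_shrinks_slopes_to_class_balance(self):
        stack = self.elevationish_stack()
        grid = stack.grid
        occ = occ_at_cells(grid, np.repeat(np.arange(15, 20), 10), np.tile(np.arange(10), 5))
        rng = np.random.default_rng(1)
        bg = occ_at_cells(grid, rng.integers(0, 20, 150), rng.integers(0, 20, 150))
        model = fit_logistic(occ, bg, stack, l2=1e6)
        assert abs(model.coef[0]) < 1e-3
        assert model.intercept == pytest.approx(np.log(50 / 150), abs=1e-2)

    def test_uniform_duplication_invariance(self):
        stack = self.elevationish_stack()
        grid = stack.grid
        occ = occ_at_cells(grid, np.repeat(np.arange(15, 20), 4), np.tile(np.arange(4), 5))
        rng = np.random.default_rng(2)
        bg = occ_at_cells(grid, rng.integers(0, 20, 100), rng.integers(0, 20, 100))
        m1 = fit_logistic(occ, bg, stack, l2=0.5)
        occ2 = OccurrenceSet(np.vstack([occ.points, occ.points]))
        bg2 = OccurrenceSet(np.vstack([bg.points, bg.points]))
        m2 = fit_logistic(occ2, bg2, stack, l2=0.5)
        np.testing.assert_allclose(m2.coef, m1.coef, atol=1e-5)
        assert m2.intercept == pytest.approx(m1.intercept, abs=1e-5)

    def test_perfect_separation_without_penalty_reported(self):
        vals = np.linspace(0, 1, 100).reshape(10, 10)
        stack = single_var_stack(vals)
        grid = stack.grid
        occ = occ_at_cells(grid, np.full(10, 9), np.arange(10))
        bg = occ_at_cells(grid, np.zeros(10, int), np.arange(10))
        with pytest.raises(NonConvergenceError, match="l2 > 0"):
            fit_logistic(occ, bg, stack, l2=0.0)

    def test_empty_class_rejected(self):
        stack = self.elevationish_stack()
        occ = occ_at_cells(stack.grid, [0], [0])
        with pytest.raises(EvaluationError):
            fit_logistic(occ, OccurrenceSet(np.empty((0, 2))), stack)


class TestEnsemble:
    def test_idempotent_on_identical_members(self):
        s = surface_from(np.random.default_rng(0).random((4, 4)))
        out = ensemble([s, s, s])
        np.testing.assert_allclose(out.prob.values, s.prob.values)

    def test_equal_weight_mean(self):
        out = ensemble([surface_from(np.full((3, 3), 0.2)), surface_from(np.full((3, 3), 0.8))])
        np.testing.assert_allclose(out.prob.values, 0.5)

    def test_degenerate_weight_returns_member(self):
        a, b = surface_from(np.full((3, 3), 0.3)), surface_from(np.full((3, 3), 0.9))
        out = ensemble([a, b], [1.0, 0.0])
        np.testing.assert_allclose(out.prob.values, a.prob.values)

    def test_bounded_by_members(self):
        rng = np.random.default_rng(3)
        members = [surface_from(rng.random((5, 5))) for _ in range(3)]
        out = ensemble(members, [0.2, 0.5, 0.3])
        lo = np.min([m.prob.values for m in members], axis=0)
        hi = np.max([m.prob.values for m in members], axis=0)
        assert np.all(out.prob.values >= lo - 1e-12) and np.all(out.prob.values <= hi + 1e-12)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            ensemble([surface_from(np.zeros((3, 3))),
                      surface_from(np.zeros((3, 3)), cell_size=5.0)])


class TestAUC:
    def scores_surface(self, pres_scores, bg_scores):
        vals = np.array(list(pres_scores) + list(bg_scores), float)
        side = len(vals)
        grid = make_grid(vals.reshape(1, side), cell_size=1.0)
        surf = SuitabilitySurface(grid)
        pres = occ_at_cells(grid, np.zeros(len(pres_scores), int), np.arange(len(pres_scores)))
        bg = occ_at_cells(grid, np.zeros(len(bg_scores), int),
                          len(pres_scores) + np.arange(len(bg_scores)))
        return surf, pres, bg

    def test_perfect_separation(self):
        surf, p, b = self.scores_surface([0.9, 0.8], [0.1, 0.2])
        assert evaluate_auc(surf, p, b) == 1.0

    def test_all_ties(self):
        surf, p, b = self.scores_surface([0.5, 0.5], [0.5, 0.5])
        assert evaluate_auc(surf, p, b) == 0.5

    def test_pairwise_brute_force_example(self):
        # pairs: 0.9>0.7, 0.9>0.85, 0.8>0.7, 0.8<0.85 -> 3/4
        surf, p, b = self.scores_surface([0.9, 0.8], [0.7, 0.85])
        assert evaluate_auc(surf, p, b) == pytest.approx(0.75)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        surf, p, b = self.scores_surface(rng.random(8), rng.random(12))
        auc1 = evaluate_auc(surf, p, b)
        transformed = SuitabilitySurface(
            surf.prob.like(1.0 / (1.0 + np.exp(-5.0 * surf.prob.values))))
        assert evaluate_auc(transformed, p, b) == pytest.approx(auc1, abs=1e-12)


class TestTSS:
    def test_perfect_classifier(self):
        surf, p, b = TestAUC().scores_surface([0.9, 0.8], [0.1, 0.2])
        assert evaluate_tss(surf, p, b, threshold=0.5) == pytest.approx(1.0)

    def test_class_blind_constant(self):
        surf, p, b = TestAUC().scores_surface([0.5] * 4, [0.5] * 4)
        assert evaluate_tss(surf, p, b, threshold=0.5) == pytest.approx(0.0)

    def test_definitional_contingency(self):
        # sensitivity 0.8, specificity 0.7 -> TSS 0.5
        pres = [0.8] * 8 + [0.2] * 2
        bg = [0.2] * 7 + [0.8] * 3
        surf, p, b = TestAUC().scores_surface(pres, bg)
        assert evaluate_tss(surf, p, b, threshold=0.5) == pytest.approx(0.5)

    def test_default_threshold_maximizes(self):
        surf, p, b = TestAUC().scores_surface([0.9, 0.8, 0.6], [0.1, 0.2, 0.7])
        best = evaluate_tss(surf, p, b)
        grid = np.arange(0, 1.0001, 0.01)
        assert best == pytest.approx(max(evaluate_tss(surf, p, b, t) for t in grid))


class TestCBI:
    def make_surface(self, seed=0):
        rng = np.random.default_rng(seed)
        return SuitabilitySurface(make_grid(rng.random((50, 50))))

    def test_proportional_presences_score_high(self):
        surf = self.make_surface()
        occ = sample_occurrences(surf.prob, 3000, seed=11)
        assert evaluate_cbi(surf, occ) >= 0.9

    def test_reversed_presences_score_low(self):
        surf = self.make_surface()
        inv = surf.prob.like(1.0 - surf.prob.values)
        occ = sample_occurrences(inv, 3000, seed=12)
        assert evaluate_cbi(surf, occ) <= -0.9

    def test_uniform_presences_near_zero(self):
        surf = self.make_surface()
        uni = surf.prob.like(np.ones(surf.prob.shape))
        occ = sample_occurrences(uni, 5000, seed=13)
        assert abs(evaluate_cbi(surf, occ)) <= 0.3

    def test_constant_surface_undefined(self):
        surf = SuitabilitySurface(make_grid(np.full((30, 30), 0.4)))
        occ = sample_occurrences(surf.prob, 50, seed=14)
        with pytest.raises(UndefinedCBIError):
            evaluate_cbi(surf, occ)

    def test_requires_enough_presences(self):
        surf = self.make_surface()
        occ = sample_occurrences(surf.prob, 10, seed=15)
        with pytest.raises(EvaluationError):
            evaluate_cbi(surf, occ)


class TestKFold:
    def setup_method(self):
        rng = np.random.default_rng(4)
        elev = np.linspace(300, 2000, 900).reshape(30, 30)
        self.stack = single_var_stack(25 - 0.006 * elev + rng.normal(0, 0.3, (30, 30)))
        grid = self.stack.grid
        self.occ = occ_at_cells(grid, rng.integers(20, 30, 40), rng.integers(0, 30, 40))
        self.bg = occ_at_cells(grid, rng.integers(0, 30, 200), rng.integers(0, 30, 200))
        self.fit = lambda o, b, p: fit_logistic(o, b, p, l2=0.01)

    def test_leave_one_out_partition(self):
        rep = kfold_cv(self.fit, self.occ, self.bg, self.stack, k=len(self.occ), seed=0)
        assert len(rep.fold_auc) == len(self.occ)

    def test_deterministic_partition(self):
        r1 = kfold_cv(self.fit, self.occ, self.bg, self.stack, k=4, seed=3)
        r2 = kfold_cv(self.fit, self.occ, self.bg, self.stack, k=4, seed=3)
        assert r1.fold_auc == r2.fold_auc

    def test_mean_equals_fold_mean(self):
        rep = kfold_cv(self.fit, self.occ, self.bg, self.stack, k=5, seed=1)
        assert rep.auc == pytest.approx(np.mean(rep.fold_auc))
        assert rep.tss == pytest.approx(np.mean(rep.fold_tss))

    def test_bad_fold_counts_rejected(self):
        with pytest.raises(InvalidFoldsError):
            kfold_cv(self.fit, self.occ, self.bg, self.stack, k=len(self.occ) + 1)
        with pytest.raises(InvalidFoldsError):
            kfold_cv(self.fit, self.occ, self.bg, self.stack, k=1)


class TestThreshold:
    def test_inclusive_at_cutoff(self):
        surf = surface_from(np.array([[0.7, 0.69], [0.71, 0.2]]))
        mask = threshold_suitable(surf, 0.7)
        assert mask.values.tolist() == [[True, False], [True, False]]

    def test_extreme_cutoffs(self):
        surf = surface_from(np.random.default_rng(0).random((4, 4)) * 0.99)
        assert np.all(threshold_suitable(surf, 0.0).values)
        assert not np.any(threshold_suitable(surf, 1.0).values)

    def test_nodata_propagates(self):
        grid = make_grid(np.full((3, 3), 0.9), nodata=np.eye(3, dtype=bool))
        mask = threshold_suitable(SuitabilitySurface(grid), 0.7)
        assert not mask.values[0, 0]
        assert mask.nodata_mask[0, 0]
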