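"""Presence-background Gibbs model: constraint satisfaction (KKT), parameter
recovery, logistic projection, cross-validation and model selection."""
import numpy as np
import pytest

from condorcircuit.maxent import (MaxentSettings, ModelEvaluation,
                                  crossvalidate, fit_maxent,
                                  percent_contribution, predict_logistic,
                                  select_model)
from condorcircuit.raster import CovariateStack, Raster


def _grid_stack(cov: np.ndarray, name: str = "c") -> CovariateStack:
    return CovariateStack({name: Raster(cov, 1_000.0)})


def _cell_points(raster: Raster, idx: np.ndarray) -> np.ndarray:
    rows, cols = np.unravel_index(idx, raster.shape)
    x, y = raster.centre_of(rows, cols)
    return np.column_stack([x, y])


def _gibbs_sample(rng, cov, lam, n):
    w = np.exp(lam * cov.ravel())
    return rng.choice(cov.size, size=n, p=w / w.sum())


@pytest.fixture(scope="module")
def single_feature_fit():
    rng = np.random.default_rng(0)
    cov = rng.uniform(0, 1, (40, 40))
    stack = _grid_stack(cov)
    grid = stack.grid
    pres = _cell_points(grid, _gibbs_sample(rng, cov, 2.0, 1_500))
    bg = _cell_points(grid, np.arange(cov.size))
    model = fit_maxent(pres, bg, stack, MaxentSettings(features="l"))
    return stack, model, pres, bg


def test_constant_covariates_give_uniform_distribution():
    stack = _grid_stack(np.full((16, 16), 3.0))
    grid = stack.grid
    bg = _cell_points(grid, np.arange(256))
    pres = bg[:50]
    model = fit_maxent(pres, bg, stack)
    raw = model.raw(stack.values_at(bg[:, 0], bg[:, 1]))
    np.testing.assert_allclose(raw, 1.0 / 256, atol=1e-12)


def test_background_raw_probabilities_sum_to_one(single_feature_fit):
    stack, model, _, bg = single_feature_fit
    raw = model.raw(stack.values_at(bg[:, 0], bg[:, 1]))
    assert abs(raw.sum() - 1.0) < 1e-8


def test_lambda_recovery_within_tolerance():
    """Truth lambda = 2.0 on a uniform [0,1] feature, n = 2,000 presences."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        cov = rng.uniform(0, 1, (64, 64))
        stack = _grid_stack(cov)
        pres = _cell_points(stack.grid, _gibbs_sample(rng, cov, 2.0, 2_000))
        bg = _cell_points(stack.grid, np.arange(cov.size))
        model = fit_maxent(pres, bg, stack, MaxentSettings(features="l"))
        span = model.mapper.lin_hi[0] - model.mapper.lin_lo[0]
        if abs(model.lambdas[0] / span - 2.0) <= 0.3:
            hits += 1
    assert hits >= 8


def test_kkt_box_conditions(single_feature_fit):
    """At the optimum, |E_model[f] - presence mean| <= beta for every
    feature (equality with the matching sign when lambda is nonzero)."""
    stack, model, pres, bg = single_feature_fit
    P = model.mapper.transform(stack.values_at(pres[:, 0], pres[:, 1]))
    B = model.mapper.transform(stack.values_at(bg[:, 0], bg[:, 1]), clamp=False)
    p_bg = model.raw(stack.values_at(bg[:, 0], bg[:, 1]))
    resid = P.mean(axis=0) - p_bg @ B
    for j in range(len(model.lambdas)):
        if model.lambdas[j] == 0:
            assert abs(resid[j]) <= model.beta[j] + 1e-6
        else:
            assert resid[j] == pytest.approx(np.sign(model.lambdas[j]) * model.beta[j], abs=1e-6)


def test_gain_nonnegative_and_nondecreasing(single_feature_fit):
    _, model, _, _ = single_feature_fit
    gains = [g for _, g in model.trace]
    assert model.gain >= 0
    assert all(b >= a - 1e-10 for a, b in zip(gains, gains[1:]))


def test_monotone_link_and_clamping(single_feature_fit):
    stack, model, _, _ = single_feature_fit
    x = np.linspace(0, 1, 50)[:, None]
    pred = model.logistic(x)
    assert np.all(np.diff(pred) >= -1e-12)  # positive lambda -> non-decreasing
    # clamped extrapolation equals the boundary prediction
    lo, hi = model.mapper.clamp_lo[0], model.mapper.clamp_hi[0]
    assert model.logistic(np.array([[hi + 5.0]]))[0] == pytest.approx(
        model.logistic(np.array([[hi]]))[0], abs=1e-12)
    assert model.logistic(np.array([[lo - 5.0]]))[0] == pytest.approx(
        model.logistic(np.array([[lo]]))[0], abs=1e-12)


def test_projection_mean_logistic_near_half(single_feature_fit):
    stack, model, _, bg = single_feature_fit
    surface = predict_logistic(model, stack)
    assert np.all((surface.data > 0) & (surface.data < 1))
    assert abs(np.nanmean(surface.data) - 0.5) < 0.2
    with pytest.raises(ValueError):
        predict_logistic(model, CovariateStack({"other": stack.grid}))


def test_json_roundtrip_preserves_predictions(tmp_path, single_feature_fit):
    stack, model, _, bg = single_feature_fit
    model.to_json(tmp_path / "m.json")
    from condorcircuit.maxent import MaxentModel
    back = MaxentModel.from_json(tmp_path / "m.json")
    X = stack.values_at(bg[:200, 0], bg[:200, 1])
    np.testing.assert_allclose(back.logistic(X), model.logistic(X), rtol=1e-12)


@pytest.fixture(scope="module")
def cv_data():
    rng = np.random.default_rng(3)
    cov = rng.uniform(0, 1, (32, 32))
    stack = _grid_stack(cov)
    pres = _cell_points(stack.grid, _gibbs_sample(rng, cov, 2.0, 300))
    bg = _cell_points(stack.grid, np.arange(cov.size))
    return stack, pres, bg


class TestCrossvalidation:
    def test_folds_partition_the_presences(self, cv_data):
        stack, pres, bg = cv_data
        ev = crossvalidate(pres, bg, stack, k=5, seed=1)
        assert len(ev.fold_auc) == 5 and len(ev.fold_aic) == 5
        assert all(0 <= a <= 1 for a in ev.fold_auc)

    def test_auc_matches_mann_whitney_count(self, cv_data):
        stack, pres, bg = cv_data
        settings = MaxentSettings(features="l")
        model = fit_maxent(pres, bg, stack, settings)
        sub_p = model.eta(stack.values_at(pres[:50, 0], pres[:50, 1]))
        sub_b = model.eta(stack.values_at(bg[:50, 0], bg[:50, 1]))
        wins = sum((p > b) + 0.5 * (p == b) for p in sub_p for b in sub_b)
        oracle = wins / (len(sub_p) * len(sub_b))
        from sklearn.metrics import roc_auc_score
        y = np.r_[np.ones(50), np.zeros(50)]
        assert roc_auc_score(y, np.r_[sub_p, sub_b]) == pytest.approx(oracle, abs=1e-12)

    def test_separable_data_has_high_auc(self):
        rng = np.random.default_rng(5)
        cov = rng.uniform(0, 1, (32, 32))
        stack = _grid_stack(cov)
        top = np.nonzero(cov.ravel() > 0.95)[0]  # presences confined to the top tail
        pres = _cell_points(stack.grid, rng.choice(top, size=200))
        bg = _cell_points(stack.grid, np.arange(32 * 32))
        ev = crossvalidate(pres, bg, stack, k=5, seed=2)
        assert ev.mean_auc > 0.95

    def test_too_few_presences_rejected(self, cv_data):
        stack, pres, bg = cv_data
        with pytest.raises(ValueError):
            crossvalidate(pres[:3], bg, stack, k=5)


class TestModelSelection:
    def test_single_and_lowest_aic(self):
        evs = [
            ModelEvaluation("m1", ["a"], [0], [0.5], [10.0], {}),
            ModelEvaluation("m2", ["a", "b"], [0], [0.5], [5.0], {}),
            ModelEvaluation("m3", ["a"], [0], [0.5], [7.0], {}),
        ]
        assert select_model(evs[:1]) == "m1"
        assert select_model(evs) == "m2"

    def test_tie_broken_by_fewer_covariates(self):
        evs = [
            ModelEvaluation("big", ["a", "b", "c"], [0], [0.5], [5.0], {}),
            ModelEvaluation("small", ["a"], [0], [0.5], [5.0], {}),
        ]
        assert select_model(evs) == "small"

    def test_informative_covariate_set_wins_aic(self):
        """The candidate containing the generating covariate should win in
        most seeded replicates."""
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            good = rng.uniform(0, 1, (24, 24))
            noise = rng.uniform(0, 1, (24, 24))
            stack = CovariateStack({"good": Raster(good, 1_000.0),
                                    "noise": Raster(noise, 1_000.0)})
            pres = _cell_points(stack.grid, _gibbs_sample(rng, good, 3.0, 250))
            bg = _cell_points(stack.grid, np.arange(good.size))
            evs = [
                crossvalidate(pres, bg, stack, k=5, seed=seed,
                              covariates=["good"], model_id="good"),
                crossvalidate(pres, bg, stack, k=5, seed=seed,
                              covariates=["noise"], model_id="noise"),
            ]
            if select_model(evs) == "good":
                wins += 1
        assert wins >= 5


class TestPercentContribution:
    def test_single_covariate_gets_everything(self, single_feature_fit):
        _, model, _, _ = single_feature_fit
        contrib = percent_contribution(model)
        assert contrib == {"c": pytest.approx(100.0)}

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(8)
        stack = CovariateStack({
            "a": Raster(rng.uniform(0, 1, (24, 24)), 1_000.0),
            "b": Raster(rng.uniform(0, 1, (24, 24)), 1_000.0),
        })
        w = np.exp(2.5 * stack.layers["a"].data.ravel())
        pres = _cell_points(stack.grid, rng.choice(576, size=300, p=w / w.sum()))
        bg = _cell_points(stack.grid, np.arange(576))
        model = fit_maxent(pres, bg, stack)
        contrib = percent_contribution(model)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)
        assert max(contrib, key=contrib.get) == "a"  # dominant covariate

    def test_dominant_covariate_leads_across_seeds(self):
        leads = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            stack = CovariateStack({
                "a": Raster(rng.uniform(0, 1, (20, 20)), 1_000.0),
                "b": Raster(rng.uniform(0, 1, (20, 20)), 1_000.0),
            })
            w = np.exp(3.0 * stack.layers["a"].data.ravel())
            pres = _cell_points(stack.grid, rng.choice(400, size=200, p=w / w.sum()))
            bg = _cell_points(stack.grid, np.arange(400))
            contrib = percent_contribution(fit_maxent(pres, bg, stack))
            if contrib["a"] > contrib["b"]:
                leads += 1
        assert leads >= 9
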