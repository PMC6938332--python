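"""Maximum-entropy presence-background model with linear + quadratic features.

The model is the Gibbs distribution over background cells

    p(x) = exp(sum_j lambda_j f_j(x)) / Z

that maximises the L1-regularised average log-likelihood of the presence
points.  Features are the covariates and their squares, each rescaled to
[0, 1] over the background sample; projection clamps raw covariates to their
training range so extrapolated predictions equal boundary predictions.  The
logistic output c*p / (1 + c*p) with c = exp(H) (H the entropy of the fitted
background distribution) maps relative suitability to (0, 1) and is used as
the landscape conductance surface.

Fitting is sequential coordinate descent: one exact 1-D minimisation per
feature per pass, gain increments attributed to the updated feature (the
basis of the percent-contribution report), capped at ``max_iterations``
single-feature updates (default 5,000).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .raster import CovariateStack, Raster


@dataclass
class MaxentSettings:
    features: str = "lq"  # "l" linear only, "lq" linear + quadratic
    beta_multiplier: float = 1.0
    max_iterations: int = 5_000
    convergence_tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.features not in ("l", "lq"):
            raise ValueError("features must be 'l' or 'lq'")


@dataclass
class _FeatureMapper:
    """Background-derived clamp bounds and [0, 1] feature scalings."""

    covariates: list[str]
    quadratic: bool
    clamp_lo: np.ndarray
    clamp_hi: np.ndarray
    lin_lo: np.ndarray
    lin_hi: np.ndarray
    quad_lo: np.ndarray
    quad_hi: np.ndarray

    @classmethod
    def fit(cls, X_bg: np.ndarray, covariates: list[str], quadratic: bool) -> "_FeatureMapper":
        lo, hi = X_bg.min(axis=0), X_bg.max(axis=0)
        sq = X_bg**2
        return cls(covariates, quadratic, lo, hi, lo, hi, sq.min(axis=0), sq.max(axis=0))

    @property
    def feature_names(self) -> list[str]:
        names = [f"{c}" for c in self.covariates]
        if self.quadratic:
            names += [f"{c}^2" for c in self.covariates]
        return names

    def feature_covariate(self) -> list[str]:
        """Parent covariate of each feature column."""
        out = list(self.covariates)
        if self.quadratic:
            out += list(self.covariates)
        return out

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values")
        if clamp:
            X = np.clip(X, self.clamp_lo, self.clamp_hi)
        span = np.where(self.lin_hi > self.lin_lo, self.lin_hi - self.lin_lo, 1.0)
        feats = [(X - self.lin_lo) / span]
        if self.quadratic:
            qspan = np.where(self.quad_hi > self.quad_lo, self.quad_hi - self.quad_lo, 1.0)
            feats.append((X**2 - self.quad_lo) / qspan)
        return np.concatenate(feats, axis=1)


@dataclass
class MaxentModel:
    covariates: list[str]
    mapper: _FeatureMapper
    lambdas: np.ndarray
    beta: np.ndarray
    normalizer: float  # log partition over the background
    entropy: float  # entropy of the fitted background distribution
    settings: MaxentSettings
    gain: float
    trace: list[tuple[int, float]] = field(default_factory=list)  # (feature, gain after)
    converged: bool = True
    n_iterations: int = 0

    # -- scoring ----------------------------------------------------------
    def eta(self, X_raw: np.ndarray, clamp: bool = True) -> np.ndarray:
        return self.mapper.transform(X_raw, clamp=clamp) @ self.lambdas

    def raw(self, X_raw: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Raw (background-normalised Gibbs) probability of each row."""
        return np.exp(self.eta(X_raw, clamp=clamp) - self.normalizer)

    def logistic(self, X_raw: np.ndarray, clamp: bool = True) -> np.ndarray:
        c = np.exp(self.entropy)
        r = self.raw(X_raw, clamp=clamp)
        return c * r / (1.0 + c * r)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "covariates": self.covariates,
            "features": self.settings.features,
            "lambdas": self.lambdas.tolist(),
            "beta": self.beta.tolist(),
            "normalizer": self.normalizer,
            "entropy": self.entropy,
            "gain": self.gain,
            "clamp_lo": self.mapper.clamp_lo.tolist(),
            "clamp_hi": self.mapper.clamp_hi.tolist(),
            "quad_lo": self.mapper.quad_lo.tolist(),
            "quad_hi": self.mapper.quad_hi.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        settings = MaxentSettings(features=d["features"])
        lo = np.array(d["clamp_lo"]); hi = np.array(d["clamp_hi"])
        mapper = _FeatureMapper(
            d["covariates"], d["features"] == "lq", lo, hi, lo, hi,
            np.array(d["quad_lo"]), np.array(d["quad_hi"]),
        )
        return cls(
            covariates=d["covariates"], mapper=mapper,
            lambdas=np.array(d["lambdas"]), beta=np.array(d["beta"]),
            normalizer=d["normalizer"], entropy=d["entropy"], settings=settings,
            gain=d["gain"], converged=d["converged"], n_iterations=d["n_iterations"],
        )


def _extract(stack: CovariateStack, xy: np.ndarray, covariates: list[str]) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    X = stack.values_at(xy[:, 0], xy[:, 1], names=covariates)
    if not np.all(np.isfinite(X)):
        raise ValueError("points fall on nodata or outside the grid")
    return X


def fit_maxent(
    presence_xy: np.ndarray,
    background_xy: np.ndarray,
    stack: CovariateStack,
    settings: MaxentSettings | None = None,
    covariates: list[str] | None = None,
) -> MaxentModel:
    """Fit the regularised Gibbs model to presence vs background points.

    Duplicate presence records are retained.  The regularisation weight per
    feature is ``beta_multiplier * sd(feature at presences) / sqrt(m)``.
    """
    settings = settings or MaxentSettings()
    covariates = covariates or stack.names
    presence_xy = np.asarray(presence_xy, dtype=float)
    background_xy = np.asarray(background_xy, dtype=float)
    if len(presence_xy) < 10:
        raise ValueError("need at least 10 presence points")
    if len(background_xy) < len(presence_xy):
        raise ValueError("background must be at least as large as presence")

    X_pres = _extract(stack, presence_xy, covariates)
    X_bg = _extract(stack, background_xy, covariates)
    mapper = _FeatureMapper.fit(X_bg, list(covariates), settings.features == "lq")
    P = mapper.transform(X_pres, clamp=True)
    B = mapper.transform(X_bg, clamp=False)
    return _fit_features(P, B, mapper, settings, list(covariates))


def _fit_features(
    P: np.ndarray,
    B: np.ndarray,
    mapper: _FeatureMapper,
    settings: MaxentSettings,
    covariates: list[str],
) -> MaxentModel:
    m, F = P.shape
    n_bg = B.shape[0]
    pbar = P.mean(axis=0)
    beta = settings.beta_multiplier * P.std(axis=0, ddof=0) / np.sqrt(m)
    beta = np.maximum(beta, 1e-6)

    lam = np.zeros(F)
    eta = np.zeros(n_bg)
    log_n = np.log(n_bg)

    def regularized_gain(lam_vec: np.ndarray, eta_vec: np.ndarray) -> float:
        return float(pbar @ lam_vec - logsumexp(eta_vec) + log_n - beta @ np.abs(lam_vec))

    gain = regularized_gain(lam, eta)
    trace: list[tuple[int, float]] = []
    it = 0
    converged = False
    while it < settings.max_iterations and not converged:
        pass_start = gain
        for j in range(F):
            if it >= settings.max_iterations:
                break
            bj = B[:, j]
            lj = lam[j]

            def neg_obj(delta: float) -> float:
                new = lj + delta
                pen = beta @ np.abs(lam) - beta[j] * abs(lj) + beta[j] * abs(new)
                return float(logsumexp(eta + delta * bj) - pbar @ lam - pbar[j] * delta + pen)

            span = abs(lj) + 8.0
            res = minimize_scalar(
                neg_obj, bounds=(-span, span), method="bounded",
                options={"xatol": 1e-10},
            )
            delta = float(res.x)
            # prefer an exact zero when it is at least as good (L1 kink)
            if neg_obj(-lj) <= res.fun + 1e-12:
                delta = -lj
            if delta != 0.0:
                lam[j] = lj + delta
                if abs(lam[j]) < 1e-12:
                    lam[j] = 0.0
                eta = eta + (lam[j] - lj) * bj
            gain = regularized_gain(lam, eta)
            trace.append((j, gain))
            it += 1
        if gain - pass_start < settings.convergence_tol:
            converged = True

    logZ = float(logsumexp(eta))
    p_bg = np.exp(eta - logZ)
    entropy = float(-np.sum(p_bg * np.log(np.maximum(p_bg, 1e-300))))
    return MaxentModel(
        covariates=covariates, mapper=mapper, lambdas=lam, beta=beta,
        normalizer=logZ, entropy=entropy, settings=settings, gain=gain,
        trace=trace, converged=converged, n_iterations=it,
    )


def predict_logistic(model: MaxentModel, stack: CovariateStack, clamp: bool = True) -> Raster:
    """Project the model's logistic output over the stack's grid."""
    missing = [c for c in model.covariates if c not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing model covariates: {missing}")
    arr = stack.as_array(model.covariates)
    flat = arr.reshape(len(model.covariates), -1).T
    valid = np.all(np.isfinite(flat), axis=1)
    out = np.full(flat.shape[0], np.nan)
    out[valid] = model.logistic(flat[valid], clamp=clamp)
    return stack.grid.like(out.reshape(stack.grid.shape))


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Share of the positive gain increments attributable to each covariate."""
    parents = model.mapper.feature_covariate()
    totals = {c: 0.0 for c in model.covariates}
    prev = 0.0
    for j, g in model.trace:
        inc = g - prev
        prev = g
        if inc > 0:
            totals[parents[j]] += inc
    s = sum(totals.values())
    if s <= 0:
        return {c: 0.0 for c in model.covariates}
    return {c: 100.0 * v / s for c, v in totals.items()}


@dataclass
class ModelEvaluation:
    """5-fold cross-validation summary for one candidate covariate set."""

    model_id: str
    covariates: list[str]
    fold_gain: list[float]
    fold_auc: list[float]
    fold_aic: list[float]
    contribution: dict[str, float]

    @property
    def mean_gain(self) -> float:
        return float(np.mean(self.fold_gain))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aic(self) -> float:
        return float(np.mean(self.fold_aic))


def crossvalidate(
    presence_xy: np.ndarray,
    background_xy: np.ndarray,
    stack: CovariateStack,
    k: int = 5,
    settings: MaxentSettings | None = None,
    seed: int = 0,
    covariates: list[str] | None = None,
    model_id: str = "model",
) -> ModelEvaluation:
    """Random k-fold CV: per fold, regularised training gain, test AUC
    (withheld presences vs background), and AIC = 2K - 2 lnL with K the
    number of nonzero lambdas and lnL the log raw likelihood of *all*
    presences under the fold's renormalised model."""
    settings = settings or MaxentSettings()
    covariates = covariates or stack.names
    presence_xy = np.asarray(presence_xy, dtype=float)
    background_xy = np.asarray(background_xy, dtype=float)
    m = len(presence_xy)
    if m < k:
        raise ValueError("fewer presences than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)

    X_all = _extract(stack, presence_xy, list(covariates))
    X_bg = _extract(stack, background_xy, list(covariates))

    gains, aucs, aics = [], [], []
    contribs = []
    for f in range(k):
        test_idx = folds[f]
        train_idx = np.concatenate([folds[g] for g in range(k) if g != f])
        if len(train_idx) < 1 or len(test_idx) < 1:
            raise ValueError("fold with no presences")
        model = fit_maxent(
            presence_xy[train_idx], background_xy, stack,
            settings=settings, covariates=list(covariates),
        )
        gains.append(model.gain)
        scores_pres = model.eta(X_all[test_idx])
        scores_bg = model.eta(X_bg)
        y = np.r_[np.ones(len(test_idx)), np.zeros(len(X_bg))]
        aucs.append(float(roc_auc_score(y, np.r_[scores_pres, scores_bg])))
        K = int(np.sum(np.abs(model.lambdas) > 1e-8))
        lnL = float(np.sum(model.eta(X_all) - model.normalizer))
        aics.append(2 * K - 2 * lnL)
        contribs.append(percent_contribution(model))

    contribution = {
        c: float(np.mean([d[c] for d in contribs])) for c in covariates
    }
    return ModelEvaluation(
        model_id=model_id, covariates=list(covariates),
        fold_gain=gains, fold_auc=aucs, fold_aic=aics, contribution=contribution,
    )


def select_model(evaluations: list[ModelEvaluation]) -> str:
    """Lowest mean AIC wins; ties go to the candidate with fewer covariates."""
    if not evaluations:
        raise ValueError("no candidate models")
    best = min(evaluations, key=lambda e: (e.mean_aic, len(e.covariates)))
    return best.model_id
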