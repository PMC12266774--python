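"""Presence-background suitability models on bioclim predictors.

Two simple in-repo learners fill the ensemble slots: a percentile envelope
(rectilinear climate envelope with linear decay outside the inner
percentile box) and an L2-penalized logistic regression of presence versus
background.  The ensemble machinery, the ``>= 0.7`` highly-suitable
threshold, and the three evaluation statistics (AUC, TSS, Continuous Boyce
Index) follow the standard presence-background conventions exactly.

The logistic penalty is scaled so that the optimized objective is
mean log-loss + (l2/2)*||w||^2; uniform duplication of the training rows
therefore leaves the coefficients unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .errors import (
    EvaluationError,
    GridMismatchError,
    InvalidFoldsError,
    NonConvergenceError,
    UndefinedCBIError,
)
from .raster import RasterGrid, require_same_grid
from .bioclim import BioclimStack
from .synthetic import OccurrenceSet


@dataclass
class SuitabilitySurface:
    """Probability-of-suitable-habitat raster, p in [0, 1]."""

    prob: RasterGrid
    species: str = "synthetic"
    period_label: str = "2010"
    provenance: str = "ensemble"


@dataclass
class EvaluationReport:
    auc: float
    tss: float
    cbi: float
    k: int
    fold_auc: list[float] = field(default_factory=list)
    fold_tss: list[float] = field(default_factory=list)
    fold_cbi: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------


@dataclass
class EnvelopeModel:
    """Percentile envelope: per-variable trapezoid score, min across variables.

    Score is 1 inside the [p_lo, p_hi] percentile interval of presence
    values (boundaries inclusive), decays linearly to 0 at the presence
    min/max extended by one interquartile range, and is 0 beyond.
    """

    kind: str = "envelope"
    variables: list[str] = field(default_factory=list)
    nodes: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def score_matrix(self, X: np.ndarray, codes: list[str]) -> np.ndarray:
        score = np.ones(len(X))
        for name in self.variables:
            j = codes.index(name)
            z_lo, p_lo, p_hi, z_hi = self.nodes[name]
            v = X[:, j]
            s = np.interp(v, [z_lo, p_lo, p_hi, z_hi], [0.0, 1.0, 1.0, 0.0])
            score = np.minimum(score, s)
        return score

    def predict_surface(self, predictors: BioclimStack, species="synthetic") -> SuitabilitySurface:
        X, valid = predictors.matrix()
        codes = list(predictors.codes)
        p = np.zeros(len(X))
        p[valid] = self.score_matrix(X[valid], codes)
        grid = predictors.grid
        prob = grid.like(p.reshape(grid.shape), ~valid.reshape(grid.shape))
        return SuitabilitySurface(prob, species, predictors.period_label, "envelope")


@dataclass
class LogisticModel:
    """Penalized logistic regression on standardized predictors."""

    kind: str = "logistic"
    variables: list[str] = field(default_factory=list)
    coef: np.ndarray | None = None
    intercept: float = 0.0
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    l2: float = 1.0

    def score_matrix(self, X: np.ndarray, codes: list[str]) -> np.ndarray:
        idx = [codes.index(v) for v in self.variables]
        Z = (X[:, idx] - self.mean) / self.sd
        eta = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_surface(self, predictors: BioclimStack, species="synthetic") -> SuitabilitySurface:
        X, valid = predictors.matrix()
        codes = list(predictors.codes)
        p = np.zeros(len(X))
        p[valid] = self.score_matrix(X[valid], codes)
        grid = predictors.grid
        prob = grid.like(p.reshape(grid.shape), ~valid.reshape(grid.shape))
        return SuitabilitySurface(prob, species, predictors.period_label, "logistic")


def _presence_matrix(occ: OccurrenceSet, predictors: BioclimStack) -> np.ndarray:
    X, ok = predictors.values_at(occ.points)
    if not np.any(ok):
        raise EvaluationError("no occurrence points fall on valid predictor cells")
    return X[ok]


def fit_envelope(occ: OccurrenceSet, predictors: BioclimStack,
                 pct: tuple[float, float] = (5.0, 95.0)) -> EnvelopeModel:
    """Fit the percentile envelope on presence predictor values.

    Variables with zero spread at the presences carry no envelope
    information and are dropped with a warning.
    """
    if len(occ) < 10:
        raise EvaluationError("envelope fitting needs >= 10 presences")
    X = _presence_matrix(occ, predictors)
    model = EnvelopeModel()
    for j, name in enumerate(predictors.codes):
        v = X[:, j]
        if np.ptp(v) == 0:
            warnings.warn(f"envelope: constant predictor {name} dropped", stacklevel=2)
            continue
        p_lo, p_hi = np.percentile(v, pct)
        q1, q3 = np.percentile(v, [25.0, 75.0])
        iqr = q3 - q1
        z_lo = v.min() - iqr
        z_hi = v.max() + iqr
        # keep interpolation nodes strictly increasing
        eps = 1e-9 * max(1.0, abs(p_hi - p_lo), iqr)
        z_lo = min(z_lo, p_lo - eps)
        z_hi = max(z_hi, p_hi + eps)
        if p_hi <= p_lo:
            p_hi = p_lo + eps
        model.variables.append(name)
        model.nodes[name] = (float(z_lo), float(p_lo), float(p_hi), float(z_hi))
    if not model.variables:
        raise EvaluationError("all predictors constant at presences")
    return model


def fit_logistic(occ: OccurrenceSet, background: OccurrenceSet,
                 predictors: BioclimStack, l2: float = 0.01,
                 balanced: bool = False) -> LogisticModel:
    """Penalized maximum-likelihood presence-vs-background fit.

    Predictors are standardized internally; the penalty scales as mean
    log-loss + (l2/2)*||w||^2.  With ``balanced=True`` the two classes get
    equal total weight regardless of the background:presence ratio, so the
    output probability follows the prevalence-0.5 convention of standard
    presence-background suitability outputs (used by the ensemble).  With
    ``l2 == 0`` and perfectly separable classes the likelihood is unbounded;
    the non-convergence is reported with advice to set ``l2 > 0``.
    """
    if len(occ) == 0 or len(background) == 0:
        raise EvaluationError("both presence and background sets must be non-empty")
    if l2 < 0:
        raise ValueError("l2 must be >= 0")
    Xp = _presence_matrix(occ, predictors)
    Xb = _presence_matrix(background, predictors)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    variables = [v for v, k in zip(predictors.codes, keep) if k]
    if not variables:
        raise EvaluationError("all predictors constant across training data")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    n = len(Z)
    cw = "balanced" if balanced else None
    if l2 == 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500,
                                 tol=1e-8, class_weight=cw)
    else:
        clf = LogisticRegression(C=1.0 / (l2 * n), solver="lbfgs", max_iter=500,
                                 tol=1e-8, class_weight=cw)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Z, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        if l2 == 0:
            raise NonConvergenceError(
                "logistic fit did not converge (likely perfect separation); set l2 > 0"
            )
        raise NonConvergenceError("logistic fit did not converge within 500 iterations")
    if l2 == 0:
        # with separable classes the unpenalized MLE does not exist; the
        # fitted direction separating the classes is the telltale
        eta = Z @ clf.coef_[0] + clf.intercept_[0]
        if eta[y == 1].min() > eta[y == 0].max():
            raise NonConvergenceError(
                "perfect separation: unpenalized likelihood is unbounded; set l2 > 0"
            )
    return LogisticModel(
        variables=variables,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        mean=mean[keep],
        sd=sd[keep],
        l2=float(l2),
    )


# ---------------------------------------------------------------------------
# Ensemble and thresholding
# ---------------------------------------------------------------------------


def ensemble(predictions: list[SuitabilitySurface], weights=None,
             species: str | None = None) -> SuitabilitySurface:
    """Cellwise weighted mean of member surfaces (weights normalized)."""
    if not predictions:
        raise ValueError("no member predictions")
    grids = [p.prob for p in predictions]
    require_same_grid(*grids)
    if weights is None:
        weights = np.ones(len(predictions))
    w = np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 and not all zero")
    w = w / w.sum()
    vals = sum(wi * g.values for wi, g in zip(w, grids))
    mask = grids[0].nodata_mask.copy()
    for g in grids[1:]:
        mask |= g.nodata_mask
    label = predictions[0].period_label
    sp = species if species is not None else predictions[0].species
    prov = "ensemble(" + "+".join(p.provenance for p in predictions) + ")"
    return SuitabilitySurface(grids[0].like(vals, mask), sp, label, prov)


def threshold_suitable(surface: SuitabilitySurface, cutoff: float = 0.7) -> RasterGrid:
    """Boolean highly-suitable mask: p >= cutoff (inclusive), nodata kept."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    g = surface.prob
    vals = (g.values >= cutoff) & g.valid
    return g.like(vals, g.nodata_mask.copy())


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------


def _scores_at(surface: SuitabilitySurface, occ: OccurrenceSet) -> np.ndarray:
    v, ok = surface.prob.values_at(occ.points)
    return v[ok]


def _auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Mann-Whitney AUC: P(presence > background) + P(tie)/2."""
    if len(scores_presence) == 0 or len(scores_background) == 0:
        raise EvaluationError("AUC needs non-empty presence and background scores")
    combined = np.concatenate([scores_presence, scores_background])
    ranks = stats.rankdata(combined)
    n1, n2 = len(scores_presence), len(scores_background)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def evaluate_auc(surface: SuitabilitySurface, presences: OccurrenceSet,
                 background: OccurrenceSet) -> float:
    return _auc(_scores_at(surface, presences), _scores_at(surface, background))


def _tss(scores_presence, scores_background, threshold):
    sens = float(np.mean(scores_presence >= threshold))
    spec = float(np.mean(scores_background < threshold))
    return sens + spec - 1.0


def evaluate_tss(surface: SuitabilitySurface, presences: OccurrenceSet,
                 background: OccurrenceSet, threshold: float | None = None) -> float:
    """TSS = sensitivity + specificity - 1.

    With no threshold given, the value maximized over a 0.01-step grid on
    [0, 1] is returned (max-TSS convention).
    """
    sp = _scores_at(surface, presences)
    sb = _scores_at(surface, background)
    if len(sp) == 0 or len(sb) == 0:
        raise EvaluationError("TSS needs non-empty presence and background scores")
    if threshold is not None:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        return _tss(sp, sb, threshold)
    grid = np.arange(0.0, 1.0001, 0.01)
    return max(_tss(sp, sb, t) for t in grid)


def _cbi(scores_presence: np.ndarray, landscape_scores: np.ndarray,
         n_windows: int = 100) -> float:
    lo = float(landscape_scores.min())
    hi = float(landscape_scores.max())
    if hi <= lo:
        raise UndefinedCBIError("constant suitability surface: CBI undefined")
    width = (hi - lo) / 10.0
    centers = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    pe, kept_centers = [], []
    for c in centers:
        a, b = c - width / 2.0, c + width / 2.0
        e = np.mean((landscape_scores >= a) & (landscape_scores <= b))
        if e == 0:
            continue
        p = np.mean((scores_presence >= a) & (scores_presence <= b))
        pe.append(p / e)
        kept_centers.append(c)
    if len(pe) < 3:
        raise UndefinedCBIError("fewer than 3 windows with nonzero expected fraction")
    rho = stats.spearmanr(kept_centers, pe).statistic
    if not np.isfinite(rho):
        raise UndefinedCBIError("P/E ratios have zero rank variance")
    return float(rho)


def evaluate_cbi(surface: SuitabilitySurface, presences: OccurrenceSet,
                 n_windows: int = 100) -> float:
    """Continuous Boyce Index with a 100-window Spearman moving-window scheme.

    Windows have width range/10 with centers evenly spaced across the
    landscape score range; windows with zero expected (landscape) fraction
    are dropped; CBI is the Spearman correlation of window center against
    the presence-to-expected ratio P/E.
    """
    sp = _scores_at(surface, presences)
    if len(sp) < 20:
        raise EvaluationError("CBI needs >= 20 presences")
    return _cbi(sp, surface.prob.masked_values(), n_windows)


# ---------------------------------------------------------------------------
# Cross-validation and the full ensemble fit
# ---------------------------------------------------------------------------


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def kfold_cv(fit_fn, occ: OccurrenceSet, background: OccurrenceSet,
             predictors: BioclimStack, k: int = 5, seed: int = 0,
             species: str = "synthetic") -> EvaluationReport:
    """k-fold cross-validation of a presence-background fit procedure.

    ``fit_fn(occ_train, background_train, predictors)`` must return a model
    exposing ``predict_surface``.  Presences and backgrounds are partitioned
    independently; the partition is deterministic given the seed.  Held-out
    AUC and max-TSS are always reported; CBI is reported when a test fold
    holds at least 20 presences (NaN otherwise).
    """
    n = len(occ)
    if k < 2:
        raise InvalidFoldsError("k must be >= 2")
    if k > n:
        raise InvalidFoldsError(f"k={k} exceeds the {n} presences")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 31])
    pres_folds = _fold_indices(n, k, rng)
    bg_folds = _fold_indices(len(background), k, rng)
    fold_auc, fold_tss, fold_cbi = [], [], []
    for pf, bf in zip(pres_folds, bg_folds):
        p_test = np.zeros(n, bool)
        p_test[pf] = True
        b_test = np.zeros(len(background), bool)
        b_test[bf] = True
        occ_tr = OccurrenceSet(occ.points[~p_test], occ.species)
        bg_tr = OccurrenceSet(background.points[~b_test], background.species)
        occ_te = OccurrenceSet(occ.points[p_test], occ.species)
        bg_te = OccurrenceSet(background.points[b_test], background.species)
        model = fit_fn(occ_tr, bg_tr, predictors)
        surf = model.predict_surface(predictors, species)
        fold_auc.append(evaluate_auc(surf, occ_te, bg_te))
        fold_tss.append(evaluate_tss(surf, occ_te, bg_te))
        if len(occ_te) >= 20:
            try:
                fold_cbi.append(evaluate_cbi(surf, occ_te))
            except UndefinedCBIError:
                fold_cbi.append(float("nan"))
        else:
            fold_cbi.append(float("nan"))
    cbi_vals = [c for c in fold_cbi if np.isfinite(c)]
    return EvaluationReport(
        auc=float(np.mean(fold_auc)),
        tss=float(np.mean(fold_tss)),
        cbi=float(np.mean(cbi_vals)) if cbi_vals else float("nan"),
        k=k,
        fold_auc=fold_auc,
        fold_tss=fold_tss,
        fold_cbi=fold_cbi,
    )


@dataclass
class _EnsembleFit:
    members: list
    weights: np.ndarray

    def predict_surface(self, predictors: BioclimStack, species="synthetic") -> SuitabilitySurface:
        surfs = [m.predict_surface(predictors, species) for m in self.members]
        return ensemble(surfs, self.weights, species)


def make_ensemble_fitter(l2: float = 0.01, pct: tuple[float, float] = (5.0, 95.0),
                         weights=(1.0, 1.0)):
    """A fit procedure (for :func:`kfold_cv`) that fits both learners on the
    training fold and combines them with fixed weights."""

    def fit(occ, background, predictors):
        env = fit_envelope(occ, predictors, pct)
        logi = fit_logistic(occ, background, predictors, l2, balanced=True)
        return _EnsembleFit([env, logi], np.asarray(weights, float))

    return fit


def fit_ensemble(occ: OccurrenceSet, background: OccurrenceSet,
                 predictors: BioclimStack, l2: float = 0.01,
                 pct: tuple[float, float] = (5.0, 95.0), k: int = 5, seed: int = 0,
                 weighting: str = "auc", species: str = "synthetic"):
    """Fit both learners, weight them by cross-validated AUC, and ensemble.

    Member weights default to max(AUC_cv - 0.5, 0); ``weighting='equal'``
    gives the unweighted mean.  Returns ``(surface, models, reports)`` where
    ``models`` maps learner name to fitted model and ``reports`` maps
    learner name to its cross-validation report.
    """

    def fit_env(o, b, p):
        return fit_envelope(o, p, pct)

    def fit_log(o, b, p):
        return fit_logistic(o, b, p, l2, balanced=True)

    fitters = {"envelope": fit_env, "logistic": fit_log}
    reports = {
        name: kfold_cv(fn, occ, background, predictors, k=k, seed=seed, species=species)
        for name, fn in fitters.items()
    }
    models = {name: fn(occ, background, predictors) for name, fn in fitters.items()}
    members = [models[name].predict_surface(predictors, species) for name in fitters]
    if weighting == "equal":
        weights = np.ones(len(members))
    else:
        weights = np.array([max(reports[name].auc - 0.5, 0.0) for name in fitters])
        if weights.sum() <= 0:
            weights = np.ones(len(members))
    surface = ensemble(members, weights, species)
    return surface, models, reports
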