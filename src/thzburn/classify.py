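"""Burn-severity labelling, cross-validated classifiers, ROC analysis.

Severity grades follow the Day-4 histology convention: superficial
partial-thickness (SPT) below 40% dermal burn depth, deep partial-thickness
(DPT) between 40% and 80%, full-thickness (FT) above 80%.

Six classifier families (linear/polynomial/Gaussian-kernel SVM, Gaussian
naive Bayes, LDA, AdaBoosted LDA) are evaluated as three independent
one-vs-all binary problems under stratified fivefold cross-validation.
Hyperparameters are chosen per training split by Bayesian optimization (a
Gaussian-process surrogate maximizing expected improvement of the inner-CV
classification accuracy), and the whole protocol is repeated over independently re-drawn
ROI configurations, reporting AUC mean +/- sd over iterations together
with sensitivity/specificity/accuracy at the classifiers' native decision
boundary (score threshold 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .features import BandSpec, observation_features, sample_rois, build_observations

logger = logging.getLogger(__name__)

SEVERITY_LABELS = ("SPT", "DPT", "FT")
FAMILIES = (
    "svm_linear",
    "svm_poly",
    "svm_gaussian",
    "naive_bayes",
    "lda",
    "adaboost_lda",
)


def assign_severity_label(d: float) -> str:
    """Severity grade from the dermal burn percentage.

    SPT for d < 40, DPT for 40 <= d <= 80 (boundary values, which cannot
    arise from continuous draws, are assigned to DPT), FT for d > 80.
    """
    if not (0.0 <= d <= 100.0):
        raise ValueError("dermal burn percentage must lie in [0, 100]")
    if d < 40.0:
        return "SPT"
    if d <= 80.0:
        return "DPT"
    return "FT"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve (threshold sweep over unique scores) and its area.

    The area equals the Mann-Whitney concordance probability with
    half-credit for tied scores.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both positive and negative observations")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of a binary prediction."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.size == 0:
        raise ValueError("empty prediction")
    if truth.all() or not truth.any():
        raise ValueError("both truth classes must be present")
    tp = np.sum(predicted & truth)
    fn = np.sum(~predicted & truth)
    tn = np.sum(~predicted & ~truth)
    fp = np.sum(predicted & ~truth)
    return (
        float(tp / (tp + fn)),
        float(tn / (tn + fp)),
        float((tp + tn) / truth.size),
    )


# ---------------------------------------------------------------------------
# classifier families and their search spaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dim:
    """One hyperparameter search dimension."""

    name: str
    kind: str  # "log" | "linear" | "int"
    lo: float
    hi: float

    def from_unit(self, u: float):
        if self.kind == "log":
            return float(np.exp(np.log(self.lo) + u * (np.log(self.hi) - np.log(self.lo))))
        if self.kind == "linear":
            return float(self.lo + u * (self.hi - self.lo))
        if self.kind == "int":
            return int(np.clip(round(self.lo + u * (self.hi - self.lo)), self.lo, self.hi))
        raise ValueError(f"unknown dimension kind {self.kind!r}")


SEARCH_SPACES: dict[str, tuple[Dim, ...]] = {
    "svm_linear": (Dim("C", "log", 1e-3, 1e3),),
    "svm_poly": (
        Dim("C", "log", 1e-3, 1e3),
        Dim("kernel_scale", "log", 1e-2, 1e2),
        Dim("degree", "int", 2, 4),
    ),
    "svm_gaussian": (
        Dim("C", "log", 1e-3, 1e3),
        Dim("kernel_scale", "log", 1e-2, 1e2),
    ),
    "naive_bayes": (Dim("var_smoothing", "log", 1e-12, 1e-3),),
    "lda": (Dim("shrinkage", "linear", 0.0, 1.0),),
    "adaboost_lda": (
        Dim("n_estimators", "int", 10, 200),
        Dim("learning_rate", "log", 0.01, 1.0),
    ),
}


class _WeightedLDA(BaseEstimator, ClassifierMixin):
    """Binary LDA weak learner with exact ``sample_weight`` support.

    scikit-learn's LDA does not accept sample weights, which AdaBoost
    requires; this implementation fits weighted class means and a weighted
    pooled covariance, shrunk toward its spherical part for stability
    (weak learners with ill-conditioned covariances otherwise amplify
    noise directions), and exposes the log-posterior-odds decision
    function.
    """

    def __init__(self, shrinkage: float = 0.05):
        self.shrinkage = shrinkage

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("weak learner expects a binary problem")
        w = (
            np.ones(len(y))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        w = np.clip(w, 0.0, None)
        wsum = w.sum()
        if wsum <= 0:
            w = np.ones(len(y))
            wsum = float(len(y))
        means, priors = [], []
        d = X.shape[1]
        cov = np.zeros((d, d))
        for cls in self.classes_:
            sel = y == cls
            wk = w[sel]
            if wk.sum() <= 0:  # a class lost all its weight mass
                wk = np.ones(sel.sum())
            mu = np.average(X[sel], axis=0, weights=wk)
            means.append(mu)
            priors.append(max(wk.sum() / wsum, 1e-12))
            xc = X[sel] - mu
            cov += (xc * wk[:, None]).T @ xc
        cov /= wsum
        a = self.shrinkage
        cov = (1 - a) * cov + np.eye(d) * (a * np.trace(cov) / d + 1e-12)
        m0, m1 = means
        coef = np.linalg.solve(cov, m1 - m0)
        self.coef_ = coef
        self.intercept_ = float(
            -0.5 * (m0 + m1) @ coef + np.log(priors[1] / priors[0])
        )
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class _BoostedLDA(AdaBoostClassifier):
    """AdaBoosted LDA that degrades gracefully on degenerate folds.

    AdaBoost refuses to fit when the first weak learner is no better than
    random on the training set (possible on tiny or label-permuted folds);
    this variant falls back to the single unboosted weak learner instead
    of aborting the evaluation.
    """

    def fit(self, X, y, sample_weight=None):
        self._fallback = None
        try:
            return super().fit(X, y, sample_weight)
        except ValueError:
            self._fallback = _WeightedLDA().fit(X, y)
            self.classes_ = self._fallback.classes_
            return self

    def decision_function(self, X):
        if getattr(self, "_fallback", None) is not None:
            return self._fallback.decision_function(X)
        return super().decision_function(X)

    def predict(self, X):
        if getattr(self, "_fallback", None) is not None:
            return self._fallback.predict(X)
        return super().predict(X)


def make_estimator(family: str, params: dict, random_state: int = 0) -> Pipeline:
    """Standardizing pipeline around the requested classifier family."""
    # solver iterations are capped: extreme search-space corners (huge C or
    # tiny kernel scale) can otherwise stall libsvm indefinitely
    max_iter = 200_000
    if family == "svm_linear":
        clf = SVC(
            kernel="linear", C=params["C"], max_iter=max_iter, random_state=random_state
        )
    elif family == "svm_poly":
        clf = SVC(
            kernel="poly",
            C=params["C"],
            gamma=1.0 / params["kernel_scale"] ** 2,
            degree=params["degree"],
            coef0=1.0,  # inhomogeneous polynomial kernel (1 + <x, x'>)^d
            max_iter=max_iter,
            random_state=random_state,
        )
    elif family == "svm_gaussian":
        # searched as a kernel scale sigma; K = exp(-||x-x'||^2 / sigma^2)
        clf = SVC(
            kernel="rbf",
            C=params["C"],
            gamma=1.0 / params["kernel_scale"] ** 2,
            max_iter=max_iter,
            random_state=random_state,
        )
    elif family == "naive_bayes":
        clf = GaussianNB(var_smoothing=params["var_smoothing"])
    elif family == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=params["shrinkage"])
    elif family == "adaboost_lda":
        clf = _BoostedLDA(
            estimator=_WeightedLDA(),
            n_estimators=params["n_estimators"],
            learning_rate=params["learning_rate"],
            random_state=random_state,
        )
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Real-valued scores with the decision boundary at 0."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    p = model.predict_proba(X)
    return np.log(p[:, 1] + 1e-300) - np.log(p[:, 0] + 1e-300)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization (GP surrogate, expected improvement)
# ---------------------------------------------------------------------------


#: Orderings used to break ties between equally-scoring hyperparameter
#: settings: (+1 prefers larger values, -1 smaller).  Inner-CV AUC surfaces
#: plateau on small samples; among ties the SVMs prefer the large-box-
#: constraint (max-margin) solution, whose decision values are margin
#: calibrated (+-1 at the support vectors) and therefore commensurable when
#: test scores are pooled across folds, then the smoothest kernel; the other
#: families prefer the most regularized member.
TIE_PREFERENCES: dict[str, tuple[tuple[str, int], ...]] = {
    "svm_linear": (("C", +1),),
    "svm_poly": (("C", +1), ("kernel_scale", +1), ("degree", -1)),
    "svm_gaussian": (("C", +1), ("kernel_scale", +1)),
    "naive_bayes": (("var_smoothing", +1),),
    "lda": (("shrinkage", +1),),
    "adaboost_lda": (("n_estimators", -1), ("learning_rate", -1)),
}


def bayes_optimize(
    objective,
    space: tuple[Dim, ...],
    n_evals: int,
    rng: np.random.Generator,
    n_candidates: int = 128,
    prefer: tuple[tuple[str, int], ...] = (),
    tie_tol: float = 5e-3,
) -> dict:
    """Maximize ``objective(params)`` over the search space.

    Random initialization followed by GP-surrogate expected-improvement
    proposals on the unit cube; deterministic for a given generator state.
    In the spirit of the one-standard-error rule, evaluations within
    ``tie_tol`` of the best objective (default half an AUC percent, below
    the resolution of a small inner CV) are treated as ties and broken by
    the ``prefer`` ordering: the simplest/smoothest model wins.
    """
    d = len(space)
    n_init = min(max(4, d + 1), n_evals)
    U: list[np.ndarray] = []
    y: list[float] = []

    def run(u: np.ndarray) -> None:
        params = {dim.name: dim.from_unit(float(v)) for dim, v in zip(space, u)}
        U.append(u)
        y.append(float(objective(params)))

    for _ in range(n_init):
        run(rng.random(d))
    while len(y) < n_evals:
        Ua, ya = np.array(U), np.array(y)
        if np.ptp(ya) < 1e-12:
            run(rng.random(d))
            continue
        # fixed kernel hyperparameters: with <= a few dozen evaluations a
        # marginal-likelihood fit is noise; EI over a fixed Matern works
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(d, 0.3))
            + WhiteKernel(noise_level=1e-4),
            optimizer=None,
            normalize_y=True,
            random_state=0,
        )
        gp.fit(Ua, ya)
        cand = rng.random((n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        best = ya.max()
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = sd * (z * stats.norm.cdf(z) + stats.norm.pdf(z))
        run(cand[int(np.argmax(ei))])
    ya = np.array(y)
    tied = np.nonzero(ya >= ya.max() - tie_tol)[0]
    all_params = [
        {dim.name: dim.from_unit(float(v)) for dim, v in zip(space, u)} for u in U
    ]
    best = int(tied[0])
    for i in tied[1:]:
        a, b = all_params[int(i)], all_params[best]
        for name, direction in prefer:
            if a[name] == b[name]:
                continue
            if direction * (a[name] - b[name]) > 0:
                best = int(i)
            break
    return all_params[best]


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierSpec:
    """Evaluation protocol of one classifier family."""

    family: str
    n_search_evals: int = 30
    cv_folds: int = 5
    n_iterations: int = 10
    group_by_burn: bool = False  # leakage-safe alternative: whole burns per fold

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CVResult:
    """Pooled-over-folds result of one cross-validated run."""

    roc: RocCurve
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    scores: np.ndarray
    y_true: np.ndarray


def _inner_cv_score(family, params, X, y, n_folds, seed, groups=None) -> float:
    """Inner stratified-CV classification accuracy (the search objective,
    i.e. one minus the CV loss).

    When burn-grouped folds are in force the inner CV is grouped too, so
    the search cannot reward hyperparameters that only memorize burns.
    """
    if groups is not None:
        skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = skf.split(X, y, groups=groups)
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = skf.split(X, y)
    scores = []
    for tr, te in split_iter:
        if y[tr].all() or not y[tr].any():
            continue
        model = make_estimator(family, params, random_state=seed)
        model.fit(X[tr], y[tr])
        scores.append(float(np.mean(model.predict(X[te]) == y[te])))
    return float(np.mean(scores)) if scores else 0.5


def crossval_evaluate(
    obs: pd.DataFrame,
    spec: ClassifierSpec,
    target_class: str,
    rng: np.random.Generator | int | None = None,
) -> CVResult:
    """One-vs-all cross-validation of one iteration's observation table.

    Hyperparameters are tuned on the training folds only (inner stratified
    CV as the Bayesian-search objective); the test-fold scores are pooled
    across the outer folds before the ROC is built, and the binary metrics
    are taken at score threshold 0.
    """
    if target_class not in SEVERITY_LABELS:
        raise ValueError(f"unknown severity class {target_class!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = observation_features(obs)
    y = (obs["label"].to_numpy() == target_class).astype(bool)
    counts = (int((~y).sum()), int(y.sum()))
    if min(counts) < 2:
        raise ValueError(f"need >= 2 observations per class, got {counts}")
    if min(counts) < spec.cv_folds:
        raise ValueError(
            f"stratification failure: class counts {counts} below cv_folds="
            f"{spec.cv_folds}"
        )
    seed = int(rng.integers(2**31 - 1))
    groups = obs["burn_id"].to_numpy() if spec.group_by_burn else None
    if spec.group_by_burn:
        splitter = StratifiedGroupKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)

    scores = np.empty(len(y))
    for tr, te in splits:
        if y[tr].all() or not y[tr].any():
            raise ValueError("stratification failure: a class is absent from a training fold")
        g_tr = groups[tr] if groups is not None else None
        if g_tr is not None:
            n_pos_groups = len(np.unique(g_tr[y[tr]]))
            n_neg_groups = len(np.unique(g_tr[~y[tr]]))
            inner = int(min(3, n_pos_groups, n_neg_groups))
        else:
            inner = int(min(3, y[tr].sum(), (~y[tr]).sum()))
        fold_seed = int(rng.integers(2**31 - 1))
        if inner >= 2 and spec.n_search_evals > 0:
            params = bayes_optimize(
                lambda p: _inner_cv_score(
                    spec.family, p, X[tr], y[tr], inner, fold_seed, groups=g_tr
                ),
                SEARCH_SPACES[spec.family],
                spec.n_search_evals,
                rng,
                prefer=TIE_PREFERENCES.get(spec.family, ()),
            )
        else:
            params = {d.name: d.from_unit(0.5) for d in SEARCH_SPACES[spec.family]}
        model = make_estimator(spec.family, params, random_state=fold_seed)
        model.fit(X[tr], y[tr])
        scores[te] = decision_scores(model, X[te])

    roc = roc_auc(scores, y)
    sens, spc, acc = confusion_metrics(scores > 0, y)
    return CVResult(
        roc=roc,
        auc=roc.auc,
        sensitivity=sens,
        specificity=spc,
        accuracy=acc,
        scores=scores,
        y_true=y,
    )


# ---------------------------------------------------------------------------
# full evaluation suite over ROI randomizations
# ---------------------------------------------------------------------------


@dataclass
class PreprocessedBurn:
    """What the classifier stage needs from one burn's scan."""

    burn_id: int
    spectra: object  # SpectraCube
    mask: np.ndarray  # biopsy mask to exclude from ROI sampling
    d: float


@dataclass
class EvalReport:
    """Long-format metrics plus per-iteration ROC curves and a summary."""

    results: pd.DataFrame  # family, class, iteration, metric, value
    curves: dict  # (family, class) -> list[RocCurve] per iteration
    observations: list  # per-iteration observation tables

    def summary(self) -> pd.DataFrame:
        g = (
            self.results.groupby(["family", "class", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )
        g["std"] = g["std"].fillna(0.0)
        return g

    def mean_auc(self, family: str, target_class: str) -> float:
        sel = self.results[
            (self.results["family"] == family)
            & (self.results["class"] == target_class)
            & (self.results["metric"] == "auc")
        ]
        return float(sel["value"].mean())


def evaluate_suite(
    burns: list[PreprocessedBurn],
    families=FAMILIES,
    band: BandSpec = BandSpec(),
    k_rois: int = 15,
    roi_size: int = 4,
    n_iterations: int = 10,
    cv_folds: int = 5,
    n_search_evals: int = 30,
    group_by_burn: bool = False,
    permute_labels: bool = False,
    seed: int | None = 0,
) -> EvalReport:
    """The full protocol: for each iteration draw fresh ROIs per burn, build
    the observation table, and cross-validate every family on every
    one-vs-all severity target.

    ``permute_labels`` re-permutes the label/d columns (rows shuffled as a
    block, seeded per iteration) before training — the null-calibration
    mode.  With ``n_iterations=1`` the reported sd fields are zero.
    """
    if n_iterations == 1:
        logger.warning("n_iterations=1: reported standard deviations are zero")
    master = np.random.SeedSequence(seed)
    rows = []
    curves: dict[tuple[str, str], list[RocCurve]] = {}
    tables = []
    for it in range(n_iterations):
        it_ss = master.spawn(1)[0]
        roi_rng, perm_rng, cv_ss = (
            np.random.default_rng(it_ss.spawn(1)[0]),
            np.random.default_rng(it_ss.spawn(1)[0]),
            it_ss.spawn(1)[0],
        )
        spectra_by_burn = {b.burn_id: b.spectra for b in burns}
        d_by_burn = {b.burn_id: b.d for b in burns}
        roisets = {
            b.burn_id: sample_rois(b.mask, k=k_rois, size=roi_size, rng=roi_rng, iteration_id=it)
            for b in burns
        }
        obs = build_observations(spectra_by_burn, roisets, band, d_by_burn, iteration_id=it)
        if permute_labels:
            perm = perm_rng.permutation(len(obs))
            obs[["label", "d"]] = obs[["label", "d"]].to_numpy()[perm]
        tables.append(obs)
        for family in families:
            spec = ClassifierSpec(
                family=family,
                n_search_evals=n_search_evals,
                cv_folds=cv_folds,
                n_iterations=n_iterations,
                group_by_burn=group_by_burn,
            )
            for target in SEVERITY_LABELS:
                res = crossval_evaluate(
                    obs, spec, target, rng=np.random.default_rng(cv_ss.spawn(1)[0])
                )
                curves.setdefault((family, target), []).append(res.roc)
                for metric, value in (
                    ("auc", res.auc),
                    ("sensitivity", res.sensitivity),
                    ("specificity", res.specificity),
                    ("accuracy", res.accuracy),
                ):
                    rows.append(
                        dict(family=family, **{"class": target}, iteration=it, metric=metric, value=value)
                    )
    results = pd.DataFrame(rows, columns=["family", "class", "iteration", "metric", "value"])
    return EvalReport(results=results, curves=curves, observations=tables)


# ---------------------------------------------------------------------------
# ANOVA on the scalar band areas
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise_p: dict  # frozenset pair -> Tukey-Kramer adjusted p
    alpha: float = 0.05


def anova_band_area(obs: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of the band areas across the three severity groups,
    with Tukey-Kramer pairwise comparisons."""
    groups = [obs.loc[obs["label"] == lab, "band_area"].to_numpy() for lab in SEVERITY_LABELS]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each severity group needs >= 2 observations")
    pairs = [("SPT", "DPT"), ("SPT", "FT"), ("DPT", "FT")]
    if np.ptp(np.concatenate(groups)) == 0:  # degenerate: identical values
        f_stat, p = 0.0, 1.0
        pairwise = {frozenset(pr): 1.0 for pr in pairs}
    else:
        f_stat, p = stats.f_oneway(*groups)
        tk = pairwise_tukeyhsd(
            obs["band_area"].to_numpy(), obs["label"].to_numpy(), alpha=alpha
        )
        pairwise = {}
        data = np.asarray(tk.summary().data[1:], dtype=object)
        for row in data:
            pairwise[frozenset((str(row[0]), str(row[1])))] = float(row[3])
    return AnovaResult(
        f_statistic=float(f_stat), p_value=float(p), pairwise_p=pairwise, alpha=alpha
    )
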