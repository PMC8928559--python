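"""Calibration method: modeling trait presence from site environment.

Evaluated accessions (0-100 disease severity ratings, DSr) are binarized —
resistant means DSr strictly below the first decile of the empirical
distribution — and the resulting presence/absence response is modeled from
the site's ecogeographic variables by a suite of nine algorithm families:

GLM, GAM, GBM, CTA (classification tree), ANN, FDA, MARS, RF, and SRE
(surface range envelope, a Bioclim-style quantile box on the presences).

Each algorithm is fitted over ``n_runs`` stratified 75/25 train/test splits
with presences and absences given equal total weight; performance is the
True Skill Statistic, TSS = sensitivity + specificity - 1, computed on the
held-out 25% at the training-set TSS-maximizing cutoff.  Mean TSS per
algorithm is binned into Fail/Poor/Fair/Good/Excellent.  The best run of
the chosen algorithm is projected onto unevaluated populations as a 0-1000
suitability; populations above the cutoff are labelled resistant, and the
top-N by suitability form the screening subset.  If every algorithm's mean
TSS falls below 0.2 the trait is declared unmodelable and nothing is
projected.

Variable importance of a fitted run is permutation-based: one minus the
Pearson correlation between predictions on intact data and predictions
after shuffling one variable, averaged over permutations and clipped to
[0, 1] (0 = no influence, 1 = total influence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .types import DomainError, ValidationError

ALGORITHMS = ("GLM", "GAM", "GBM", "CTA", "ANN", "FDA", "MARS", "RF", "SRE")

PERFORMANCE_CLASSES = ("Fail", "Poor", "Fair", "Good", "Excellent")
_PERFORMANCE_EDGES = (0.2, 0.4, 0.6, 0.8)

#: Mean TSS below which an algorithm is considered uninformative; a trait
#: where every algorithm falls below this is declared unmodelable.
UNMODELABLE_TSS = 0.2


# ---------------------------------------------------------------------------
# Elementary statistics


def binarize_dsr(records: pd.DataFrame, quantile: float = 0.10) -> pd.DataFrame:
    """Label accessions resistant iff DSr is strictly below the given quantile.

    The threshold is the empirical quantile (linear-interpolation, type-7
    estimator) of the ``dsr`` column; strict inequality excludes boundary
    ties, keeping the resistant set within the decile.  Adds ``resistant``
    and stores the threshold and class counts in ``df.attrs``.
    """
    dsr = records["dsr"].dropna().to_numpy(dtype=float)
    if len(dsr) < 10:
        raise ValidationError("need at least 10 DSr values to binarize")
    if np.ptp(dsr) == 0:
        raise DomainError("degenerate DSr distribution: all values identical")
    threshold = float(np.quantile(dsr, quantile))
    out = records.copy()
    out["resistant"] = out["dsr"] < threshold
    out.attrs["dsr_threshold"] = threshold
    out.attrs["n_resistant"] = int(out["resistant"].sum())
    out.attrs["n_sensitive"] = int((~out["resistant"]).sum())
    return out


def tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True Skill Statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if tp + fn == 0 or tn + fp == 0:
        raise DomainError("TSS undefined when a true class is empty")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def classify_performance(mean_tss: float) -> str:
    """Fail [<0.2) / Poor / Fair / Good / Excellent [0.8, 1] bins of mean TSS."""
    if mean_tss < _PERFORMANCE_EDGES[0]:
        return "Fail"
    idx = int(np.searchsorted(_PERFORMANCE_EDGES, mean_tss, side="right"))
    return PERFORMANCE_CLASSES[min(idx, len(PERFORMANCE_CLASSES) - 1)]


def _tss_from_scores(y: np.ndarray, scores: np.ndarray, cutoff: float) -> float:
    pred = scores > cutoff
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tss(tp, fn, tn, fp)


def best_cutoff(y: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Threshold on the score maximizing TSS (strict >), with its TSS.

    Candidate cutoffs are midpoints between consecutive distinct scores plus
    a just-below-minimum value (predict-all-positive).
    """
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0]) if len(uniq) > 1 else np.array([uniq[0] - 1.0])
    best_c, best_t = candidates[0], -np.inf
    for c in candidates:
        t = _tss_from_scores(y, scores, c)
        if t > best_t:
            best_c, best_t = c, t
    return float(best_c), float(best_t)


# ---------------------------------------------------------------------------
# Algorithm suite


class SurfaceRangeEnvelope(BaseEstimator, ClassifierMixin):
    """Bioclim-style envelope: per-variable quantile box on the presences.

    Suitability of a point is the fraction of variables lying inside the
    [q_low, q_high] training-presence envelope (1 = inside every envelope).
    """

    def __init__(self, quantile_pair: tuple[float, float] = (0.025, 0.975)):
        self.quantile_pair = quantile_pair

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pres = X[y == 1]
        if len(pres) < 2:
            raise DomainError("surface range envelope needs at least 2 presences")
        lo, hi = self.quantile_pair
        self.lower_ = np.quantile(pres, lo, axis=0)
        self.upper_ = np.quantile(pres, hi, axis=0)
        self.classes_ = np.array([0, 1])
        return self

    def suitability(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lower_) & (X <= self.upper_)
        return inside.mean(axis=1)

    def predict_proba(self, X):
        s = self.suitability(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X):
        return (self.suitability(X) == 1.0).astype(int)


def _hinge_basis(n_knots: int = 3):
    """Paired hinge (max(0, x-k), max(0, k-x)) features at quantile knots."""

    class HingeTransformer(BaseEstimator):
        def __init__(self, n_knots=n_knots):
            self.n_knots = n_knots

        def fit(self, X, y=None):
            X = np.asarray(X, dtype=float)
            qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
            self.knots_ = np.quantile(X, qs, axis=0)
            return self

        def transform(self, X):
            X = np.asarray(X, dtype=float)
            feats = [X]
            for k in self.knots_:
                feats.append(np.maximum(0.0, X - k))
                feats.append(np.maximum(0.0, k - X))
            return np.hstack(feats)

    return HingeTransformer()


def make_algorithm(name: str, seed: int = 0):
    """Construct an unfitted estimator for one algorithm family.

    Hyperparameters live here, in one auditable place; presences and
    absences always receive equal total weight (balanced class weights or
    the estimator-specific equivalent).
    """
    if name == "GLM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("glm", LogisticRegression(penalty=None, max_iter=1000, class_weight="balanced")),
            ]
        )
    if name == "GAM":
        return Pipeline(
            [
                ("spline", SplineTransformer(n_knots=5, degree=3)),
                ("glm", LogisticRegression(C=1.0, max_iter=1000, class_weight="balanced")),
            ]
        )
    if name == "GBM":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed
        )
    if name == "CTA":
        return DecisionTreeClassifier(
            min_samples_leaf=5, class_weight="balanced", random_state=seed
        )
    if name == "ANN":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(8,),
                        max_iter=500,
                        random_state=seed,
                        tol=1e-3,
                    ),
                ),
            ]
        )
    if name == "FDA":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("hinge", _hinge_basis(3)),
                ("lda", LinearDiscriminantAnalysis(priors=[0.5, 0.5])),
            ]
        )
    if name == "MARS":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("hinge", _hinge_basis(3)),
                ("glm", LogisticRegression(C=1.0, max_iter=1000, class_weight="balanced")),
            ]
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=100, class_weight="balanced", random_state=seed, n_jobs=1
        )
    if name == "SRE":
        return SurfaceRangeEnvelope()
    raise ValidationError(f"unknown algorithm {name!r}")


def _suitability_raw(model, X: np.ndarray) -> np.ndarray:
    """Model score in [0, 1] (probability of the resistant class)."""
    if isinstance(model, SurfaceRangeEnvelope):
        return model.suitability(X)
    proba = model.predict_proba(X)
    cls = list(getattr(model, "classes_", [0, 1]))
    return proba[:, cls.index(1)]


# ---------------------------------------------------------------------------
# Runs


@dataclass
class ModelRun:
    """One fitted train/test split of one algorithm."""

    algorithm: str
    run: int
    seed: int
    tss: float  # on the held-out 25%
    cutoff: float  # suitability cutoff (0-1000 scale), chosen on training data
    train_index: np.ndarray = field(repr=False, default=None)
    test_index: np.ndarray = field(repr=False, default=None)
    model: object = field(repr=False, default=None)  # retained for best runs only
    failed: bool = False


@dataclass
class AlgorithmSummary:
    algorithm: str
    mean_tss: float
    performance: str
    n_runs: int
    n_failed: int
    best_run: ModelRun | None


@dataclass
class CalibrationResult:
    """Suite outcome: summaries, chosen model, projections, and subset."""

    trait: str
    summaries: dict[str, AlgorithmSummary]
    ranked_algorithms: list[str]
    chosen_algorithm: str | None
    best_run: ModelRun | None
    unmodelable: bool
    importance: dict[str, dict[str, float]] = field(default_factory=dict)
    projections: pd.DataFrame | None = None
    top_subset: pd.DataFrame | None = None
    cutoff: float | None = None

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": s.algorithm,
                "mean_tss": s.mean_tss,
                "performance": s.performance,
                "n_runs": s.n_runs,
                "n_failed": s.n_failed,
                "best_tss": s.best_run.tss if s.best_run else np.nan,
            }
            for s in self.summaries.values()
        ]
        return pd.DataFrame(rows).sort_values("mean_tss", ascending=False).reset_index(drop=True)


def train_suite(
    records: pd.DataFrame,
    predictors: Sequence[str],
    algorithms: Sequence[str] = ALGORITHMS,
    n_runs: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[ModelRun], dict[str, AlgorithmSummary]]:
    """Fit every algorithm over ``n_runs`` random 75/25 splits.

    ``records`` must carry boolean ``resistant`` labels and the predictor
    columns.  Within each run the split is stratified by class (unless
    ``stratify=False``), the cutoff is the training TSS-maximizing
    suitability threshold, and TSS is evaluated on the held-out quarter at
    that cutoff.  Runs that fail to fit (e.g. a degenerate envelope) are
    recorded as failed and excluded from the mean, never silently dropped.
    """
    if "resistant" not in records.columns:
        raise ValidationError("records must be binarized first (no 'resistant' column)")
    data = records.dropna(subset=list(predictors))
    y = data["resistant"].to_numpy(dtype=int)
    X = data[list(predictors)].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    if X.shape[1] < 2:
        raise ValidationError("need at least two predictors")

    master = np.random.SeedSequence(entropy=seed % (2**31))
    split_seeds = master.generate_state(n_runs) % (2**31)

    runs: list[ModelRun] = []
    summaries: dict[str, AlgorithmSummary] = {}
    for algo in algorithms:
        algo_runs: list[ModelRun] = []
        best: ModelRun | None = None
        n_failed = 0
        template = make_algorithm(algo, seed=seed)
        for r in range(n_runs):
            rs = int(split_seeds[r])
            idx = np.arange(len(y))
            train_idx, test_idx = train_test_split(
                idx,
                train_size=train_frac,
                random_state=rs,
                stratify=y if stratify else None,
            )
            run = ModelRun(
                algorithm=algo, run=r, seed=rs, tss=np.nan, cutoff=np.nan,
                train_index=train_idx, test_index=test_idx,
            )
            try:
                model = clone(template)
                if hasattr(model, "random_state"):
                    model.random_state = rs
                elif isinstance(model, Pipeline):
                    for _, step in model.steps:
                        if hasattr(step, "random_state"):
                            step.random_state = rs
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if algo == "GBM":
                        # boosting takes equal class weight via sample weights
                        w = _balanced_weights(y[train_idx])
                        model.fit(X[train_idx], y[train_idx], sample_weight=w)
                    elif algo == "ANN":
                        # the perceptron accepts no weights; balance by
                        # seeded oversampling of the rare class
                        Xb, yb = _oversample(X[train_idx], y[train_idx], rs)
                        model.fit(Xb, yb)
                    else:
                        model.fit(X[train_idx], y[train_idx])
                train_scores = _suitability_raw(model, X[train_idx])
                cutoff01, _ = best_cutoff(y[train_idx], train_scores)
                test_scores = _suitability_raw(model, X[test_idx])
                run.tss = _tss_from_scores(y[test_idx], test_scores, cutoff01)
                run.cutoff = 1000.0 * cutoff01
            except Exception:
                run.failed = True
                n_failed += 1
            else:
                if best is None or run.tss > best.tss:
                    run.model = model
                    if best is not None:
                        best.model = None
                    best = run
            algo_runs.append(run)
        ok = [r.tss for r in algo_runs if not r.failed]
        mean_tss = float(np.mean(ok)) if ok else np.nan
        summaries[algo] = AlgorithmSummary(
            algorithm=algo,
            mean_tss=mean_tss,
            performance=classify_performance(mean_tss) if ok else "Fail",
            n_runs=n_runs,
            n_failed=n_failed,
            best_run=best,
        )
        runs.extend(algo_runs)
    return runs, summaries


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    w = np.ones(len(y), dtype=float)
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if n1 and n0:
        w[y == 1] = len(y) / (2.0 * n1)
        w[y == 0] = len(y) / (2.0 * n0)
    return w


def _oversample(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if n1 == 0 or n0 == 0 or n1 == n0:
        return X, y
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    pool = np.nonzero(y == minority)[0]
    extra = rng.choice(pool, size=need, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def permutation_importance(
    run: ModelRun,
    X: np.ndarray,
    variable_names: Sequence[str],
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """0-1 influence of each variable on a fitted run's predictions.

    For each variable: mean over ``n_perm`` shuffles of
    1 - corr(predictions intact, predictions with that variable shuffled),
    clipped to [0, 1].  A variable the model ignores scores exactly 0;
    constant predictions score 0 everywhere.
    """
    if run.model is None:
        raise ValidationError("run does not retain a fitted model")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    base = _suitability_raw(run.model, X)
    out: dict[str, float] = {}
    if np.ptp(base) == 0:
        return {name: 0.0 for name in variable_names}
    for j, name in enumerate(variable_names):
        vals = np.empty(n_perm)
        for p in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            shuffled = _suitability_raw(run.model, Xp)
            if np.ptp(shuffled) == 0:
                vals[p] = 1.0
            else:
                vals[p] = 1.0 - np.corrcoef(base, shuffled)[0, 1]
        out[name] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return out


def select_and_project(
    summaries: dict[str, AlgorithmSummary],
    populations: pd.DataFrame,
    predictors: Sequence[str],
    eval_X: np.ndarray,
    trait: str = "rust",
    top_n: int = 30,
    choose: str | None = None,
    n_perm: int = 100,
    seed: int = 0,
    n_compare: int = 3,
) -> CalibrationResult:
    """Pick the algorithm, project its best run, and emit the top-N subset.

    Algorithms are ranked by mean TSS; permutation-importance tables are
    computed for the top ``n_compare`` so a dominated model (e.g. one driven
    almost entirely by a single positional variable) can be excluded by the
    caller via ``choose`` — that judgment is reported, not automated.  If
    every algorithm's mean TSS is below 0.2 the trait is unmodelable: no
    projection is produced.

    ``eval_X`` is the predictor matrix the suite was trained on (used for
    importance); ``populations`` provides the unevaluated targets.
    """
    valid = {a: s for a, s in summaries.items() if np.isfinite(s.mean_tss)}
    if not valid:
        raise ValidationError("no successful runs in any algorithm")
    ranked = sorted(valid, key=lambda a: (-valid[a].mean_tss, a))

    if all(valid[a].mean_tss < UNMODELABLE_TSS for a in ranked):
        return CalibrationResult(
            trait=trait,
            summaries=summaries,
            ranked_algorithms=ranked,
            chosen_algorithm=None,
            best_run=None,
            unmodelable=True,
        )

    importance: dict[str, dict[str, float]] = {}
    for a in ranked[:n_compare]:
        best = valid[a].best_run
        if best is not None and best.model is not None:
            importance[a] = permutation_importance(best, eval_X, predictors, n_perm=n_perm, seed=seed)

    chosen = choose if choose is not None else ranked[0]
    if chosen not in valid:
        raise ValidationError(f"chosen algorithm {chosen!r} has no successful runs")
    best = valid[chosen].best_run

    pop = populations.dropna(subset=list(predictors)).copy()
    Xp = pop[list(predictors)].to_numpy(dtype=float)
    suit = 1000.0 * _suitability_raw(best.model, Xp) if len(pop) else np.empty(0)
    pop["suitability"] = suit
    pop["label"] = np.where(suit > best.cutoff, "resistant", "sensitive")

    resistant = pop[pop["label"] == "resistant"].sort_values(
        ["suitability", "pop_id"] if "pop_id" in pop.columns else ["suitability"],
        ascending=[False, True] if "pop_id" in pop.columns else False,
    )
    top = resistant.head(top_n).reset_index(drop=True)

    return CalibrationResult(
        trait=trait,
        summaries=summaries,
        ranked_algorithms=ranked,
        chosen_algorithm=chosen,
        best_run=best,
        unmodelable=False,
        importance=importance,
        projections=pop.reset_index(drop=True),
        top_subset=top,
        cutoff=best.cutoff,
    )


def sre_envelope(
    presences: np.ndarray, quantile_pair: tuple[float, float] = (0.025, 0.975)
) -> SurfaceRangeEnvelope:
    """Fit a surface range envelope directly from presence vectors."""
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    if presences.shape[0] < 2:
        raise DomainError("surface range envelope needs at least 2 presences")
    model = SurfaceRangeEnvelope(quantile_pair=quantile_pair)
    X = presences
    y = np.ones(len(X), dtype=int)
    # fit() only uses presences; append nothing
    model.fit(X, y)
    return model
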