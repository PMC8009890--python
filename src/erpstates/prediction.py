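"""Outcome prediction from microstate features.

Two complementary analyses:

* **Categorical outcome** (ASD diagnosis within the family-history group):
  binary-mask feature selection by a genetic algorithm whose fitness is the
  ROC AUC of a 10-fold cross-validated, class-weighted SVM; evaluation on a
  stratified 30% holdout with repeated refits; significance by label-shuffle
  permutation test.
* **Dimensional outcome** (VABS Socialization standard score): elastic-net
  regression with leave-one-out outer cross-validation and nested repeated
  10-fold inner cross-validation minimising RMSE; uncertainty by subject
  bootstrap and shuffle test.

All standardisation, tuning and selection statistics are computed strictly
inside training partitions — no leakage into test or holdout data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedKFold, StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

NON_FEATURE_COLUMNS = (
    "subject_id", "group", "sex", "asd_outcome", "vabs_socialization",
)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All numeric predictor columns (everything but ids, group and outcomes)."""
    drop = set(NON_FEATURE_COLUMNS)
    return [c for c in table.columns if c not in drop and not c.startswith("trials_")]


def build_feature_table(
    subjects: pd.DataFrame,
    ms_features: pd.DataFrame | None = None,
    retained_maps: Sequence[int] = (1, 2, 4),
    conditions: Sequence[str] = ("FD", "FA", "Noise"),
) -> pd.DataFrame:
    """Assemble the modelling table: covariates + per-map x condition features.

    ``subjects`` must carry subject_id, sex, age_days, msel_composite and the
    outcome columns. ``ms_features`` (optional) is a tidy per subject x
    condition x map table with duration_ms / mean_gfp columns; when omitted,
    the duration/GFP columns are taken from ``subjects`` itself (the planted
    ground-truth layout). Sex is binary-coded (F=1); missing mean GFP for an
    absent map is imputed as 0.
    """
    out = subjects.copy()
    if ms_features is not None:
        # pivot (not pivot_table): a map absent everywhere must keep its
        # all-NaN mean-GFP column for imputation rather than vanish
        wide = ms_features.pivot(
            index="subject_id", columns=["map", "condition"],
            values=["duration_ms", "mean_gfp"],
        )
        cols = {}
        for (val, m, cond) in wide.columns:
            stem = "dur" if val == "duration_ms" else "gfp"
            cols[(val, m, cond)] = f"{stem}_M{m}_{cond}"
        wide.columns = [cols[c] for c in wide.columns]
        out = out.merge(wide.reset_index(), on="subject_id", how="inner")
    keep = ["subject_id", "group", "sex", "age_days", "msel_composite",
            "asd_outcome", "vabs_socialization"]
    feat_cols = []
    for m in retained_maps:
        for cond in conditions:
            for stem in ("dur", "gfp"):
                col = f"{stem}_M{m}_{cond}"
                if col in out.columns:
                    feat_cols.append(col)
    table = out[[c for c in keep if c in out.columns] + feat_cols].copy()
    table["sex_F"] = (table["sex"] == "F").astype(float)
    for col in feat_cols:
        table[col] = table[col].fillna(0.0)
    return table


def _xy(table: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table[outcome].to_numpy()
    if outcome == "asd_outcome":
        y = y.astype(int)
    return X, y, cols


# ---------------------------------------------------------------------------
# Splitting and the SVM fitness
# ---------------------------------------------------------------------------


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    outcome: str = "asd_outcome",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/holdout split preserving class proportions.

    The training size is ``round(train_fraction * n)`` so that 91 subjects at
    0.7 give the 64/27 partition.
    """
    y = table[outcome].to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if np.any(counts < 2):
        raise ValueError("each class needs at least 2 members")
    n = len(table)
    n_train = int(round(train_fraction * n))
    if n_train >= n or n_train < 2:
        raise ValueError("degenerate split: empty train or holdout")
    sss = StratifiedShuffleSplit(n_splits=1, train_size=n_train, random_state=seed)
    tr, ho = next(sss.split(np.zeros(n), y))
    return table.iloc[np.sort(tr)].copy(), table.iloc[np.sort(ho)].copy()


def _fit_svm(Xtr: np.ndarray, ytr: np.ndarray, kernel: str, seed: int) -> tuple[SVC, np.ndarray, np.ndarray]:
    """Standardise on the training rows and fit a class-weighted SVM."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel=kernel, class_weight="balanced", random_state=seed)
    clf.fit((Xtr - mu) / sd, ytr)
    return clf, mu, sd


def svm_cv_auc(
    train: pd.DataFrame,
    feature_mask: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    outcome: str = "asd_outcome",
    kernel: str = "linear",
) -> float:
    """ROC AUC of pooled out-of-fold SVM decision scores.

    Stratified k-fold; per fold, features are standardised with training-fold
    statistics only and a class-weighted SVM (misclassification cost inversely
    proportional to class frequency) is fit; decision scores for all test
    folds are pooled into one ROC curve.
    """
    X, y, _ = _xy(train, outcome)
    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        if feature_mask.sum() < 1:
            raise ValueError("feature mask selects no features")
        X = X[:, feature_mask]
    return _svm_cv_auc_arrays(X, y, folds, seed, kernel)


def _svm_cv_auc_arrays(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, kernel: str = "linear"
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:  # cannot happen with stratified folds
            raise RuntimeError("training fold with a single class")
        clf, mu, sd = _fit_svm(X[tr], y[tr], kernel, seed)
        scores[te] = clf.decision_function((X[te] - mu) / sd)
    return float(roc_auc_score(y, scores))


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection
# ---------------------------------------------------------------------------


@dataclass
class GaParams:
    """Genetic-algorithm settings for binary-mask feature selection."""

    population_size: int = 50
    n_generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # default 1/n_features
    elitism_count: int = 2
    n_evolutions: int = 20
    auc_threshold: float = 0.75
    incidence_threshold: float = 0.80
    cv_folds: int = 10
    patience: int = 20  # stop an evolution when the best mask stalls this long
    tournament_size: int = 3
    kernel: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.auc_threshold, self.incidence_threshold):
            if not 0 < p <= 1:
                raise ValueError("probabilities/thresholds must be in (0, 1]")


@dataclass
class GaResult:
    optimal_set: list[str]
    optimal_fitness: float
    incidence: dict[str, float]
    high_incidence_set: list[str]
    best_per_evolution: list[tuple[list[str], float]]
    warnings: tuple[str, ...] = ()


def ga_select(train: pd.DataFrame, params: GaParams | None = None,
              outcome: str = "asd_outcome") -> GaResult:
    """Evolve binary feature masks with cross-validated SVM AUC as fitness.

    Runs ``n_evolutions`` independent evolutions. The *optimal set* is the
    best-fitness mask over all evolutions; *incidence* of a feature is the
    fraction of qualifying evolutions (best fitness above ``auc_threshold``)
    whose best mask contains it; the *high-incidence set* collects features
    with incidence above ``incidence_threshold``. If no evolution qualifies,
    incidence falls back to all best-per-evolution masks with a warning.
    """
    params = params or GaParams()
    X, y, cols = _xy(train, outcome)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 candidate features")
    mut = params.mutation_prob if params.mutation_prob is not None else 1.0 / p
    rng = np.random.default_rng(params.seed)
    cache: dict[bytes, float] = {}

    # the folds and fold-wise standardisation are mask-independent, so they
    # are computed once; slicing standardised columns equals standardising
    # the sliced matrix
    skf = StratifiedKFold(n_splits=params.cv_folds, shuffle=True, random_state=params.seed)
    folds = []
    for tr, te in skf.split(X, y):
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        folds.append(((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, te))

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            scores = np.zeros(len(y))
            for Xtr, ytr, Xte, te in folds:
                clf = SVC(kernel=params.kernel, class_weight="balanced",
                          random_state=params.seed)
                clf.fit(Xtr[:, mask], ytr)
                scores[te] = clf.decision_function(Xte[:, mask])
            cache[key] = float(roc_auc_score(y, scores))
        return cache[key]

    def ensure_nonempty(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(p)] = True
        return mask

    best_masks: list[np.ndarray] = []
    best_fits: list[float] = []
    for _ in range(params.n_evolutions):
        pop = rng.random((params.population_size, p)) < 0.5
        pop = np.array([ensure_nonempty(m) for m in pop])
        fits = np.array([fitness(m) for m in pop])
        stall = 0
        best = float(fits.max())
        for _gen in range(params.n_generations):
            order = np.argsort(-fits, kind="stable")
            elite = pop[order[: params.elitism_count]]
            children = [m.copy() for m in elite]
            while len(children) < params.population_size:
                # tournament selection of two parents
                pa = pop[order[np.min(rng.integers(len(pop), size=params.tournament_size))]]
                pb = pop[order[np.min(rng.integers(len(pop), size=params.tournament_size))]]
                child = pa.copy()
                if rng.random() < params.crossover_prob:  # uniform crossover
                    take = rng.random(p) < 0.5
                    child[take] = pb[take]
                flip = rng.random(p) < mut
                child[flip] = ~child[flip]
                children.append(ensure_nonempty(child))
            pop = np.array(children)
            fits = np.array([fitness(m) for m in pop])
            top = float(fits.max())
            if top > best + 1e-12:
                best = top
                stall = 0
            else:
                stall += 1
                if stall >= params.patience:
                    break
        i = int(np.argmax(fits))
        best_masks.append(pop[i].copy())
        best_fits.append(float(fits[i]))

    best_fits_arr = np.array(best_fits)
    i_opt = int(np.argmax(best_fits_arr))
    qualifying = [m for m, f in zip(best_masks, best_fits) if f > params.auc_threshold]
    warns: tuple[str, ...] = ()
    if not qualifying:
        warns = (
            f"no evolution exceeded the AUC threshold {params.auc_threshold}; "
            "incidence computed over best-per-evolution sets",
        )
        logger.warning(warns[0])
        qualifying = best_masks
    inc = np.mean(np.array(qualifying), axis=0)
    incidence = {c: float(v) for c, v in zip(cols, inc)}
    return GaResult(
        optimal_set=[c for c, m in zip(cols, best_masks[i_opt]) if m],
        optimal_fitness=float(best_fits_arr[i_opt]),
        incidence=incidence,
        high_incidence_set=[c for c in cols if incidence[c] > params.incidence_threshold],
        best_per_evolution=[
            ([c for c, b in zip(cols, m) if b], f) for m, f in zip(best_masks, best_fits)
        ],
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Classifier evaluation
# ---------------------------------------------------------------------------


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent.

    Ratios with a zero denominator are NaN (recorded as missing upstream).
    """
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, tp + fn + tn + fp),
    }


def _wilson_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0 or not np.isfinite(p_hat):
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(0.5 + level / 2)
    denom = 1 + z**2 / n
    centre = (p_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def _auc_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil confidence interval for an ROC AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2))
        / (n_pos * n_neg)
    )
    z = stats.norm.ppf(0.5 + level / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


@dataclass
class ClassifierReport:
    """Holdout metrics (percent scale) as mean +- SD with averaged 95% CIs."""

    metrics: dict[str, dict[str, float]]  # name -> {mean, sd, ci_low, ci_high, n_missing}
    confusion_matrices: list[tuple[int, int, int, int]]  # (tp, fn, tn, fp) per rep
    feature_set: list[str]
    n_repetitions: int
    seed: int
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "confusion_matrices": [list(c) for c in self.confusion_matrices],
            "feature_set": self.feature_set,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "p_value": self.p_value,
        }


def evaluate_classifier(
    train: pd.DataFrame,
    holdout: pd.DataFrame,
    feature_set: Sequence[str],
    n_repetitions: int = 1000,
    seed: int = 0,
    outcome: str = "asd_outcome",
    kernel: str = "linear",
) -> ClassifierReport:
    """Repeatedly refit a class-weighted SVM and score the fixed holdout.

    Each repetition draws a stratified bootstrap resample of the training
    rows, standardises with the resample's statistics, fits, and thresholds
    holdout decision scores at the decision boundary (0). Metrics with an
    undefined ratio in a repetition are excluded from that metric's mean,
    with the exclusion counted. Percent scale throughout.
    """
    feature_set = list(feature_set)
    if not feature_set:
        raise ValueError("feature_set must be non-empty")
    ytr_all = train[outcome].to_numpy().astype(int)
    yho = holdout[outcome].to_numpy().astype(int)
    if len(np.unique(yho)) < 2:
        raise ValueError("holdout must contain both classes")
    Xtr_all = train[feature_set].to_numpy(dtype=float)
    Xho = holdout[feature_set].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    pos = np.nonzero(ytr_all == 1)[0]
    neg = np.nonzero(ytr_all == 0)[0]

    names = ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy")
    vals: dict[str, list[float]] = {n: [] for n in names}
    cis: dict[str, list[tuple[float, float]]] = {n: [] for n in names}
    missing = {n: 0 for n in names}
    cms: list[tuple[int, int, int, int]] = []
    for _ in range(n_repetitions):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        clf, mu, sd = _fit_svm(Xtr_all[idx], ytr_all[idx], kernel, seed)
        scores = clf.decision_function((Xho - mu) / sd)
        pred = (scores > 0).astype(int)
        tp = int(np.sum((pred == 1) & (yho == 1)))
        fn = int(np.sum((pred == 0) & (yho == 1)))
        tn = int(np.sum((pred == 0) & (yho == 0)))
        fp = int(np.sum((pred == 1) & (yho == 0)))
        cms.append((tp, fn, tn, fp))
        mets = confusion_metrics(tp, fn, tn, fp)
        mets["auc"] = 100.0 * roc_auc_score(yho, scores)
        denoms = {
            "sensitivity": tp + fn, "specificity": tn + fp,
            "ppv": tp + fp, "npv": tn + fn, "accuracy": len(yho),
        }
        for n in names:
            v = mets[n]
            if np.isnan(v):
                missing[n] += 1
                continue
            vals[n].append(v)
            if n == "auc":
                lo, hi = _auc_ci(v / 100.0, int(np.sum(yho == 1)), int(np.sum(yho == 0)))
            else:
                lo, hi = _wilson_ci(v / 100.0, denoms[n])
            cis[n].append((100.0 * lo, 100.0 * hi))

    metrics = {}
    for n in names:
        arr = np.array(vals[n])
        ci = np.array(cis[n]) if cis[n] else np.full((1, 2), np.nan)
        metrics[n] = {
            "mean": float(arr.mean()) if arr.size else float("nan"),
            "sd": float(arr.std(ddof=0)) if arr.size else float("nan"),
            "ci_low": float(ci[:, 0].mean()),
            "ci_high": float(ci[:, 1].mean()),
            "n_missing": missing[n],
        }
    return ClassifierReport(
        metrics=metrics, confusion_matrices=cms, feature_set=feature_set,
        n_repetitions=n_repetitions, seed=seed,
    )


def shuffle_test(
    observed_metric: float,
    refit: Callable[[pd.DataFrame], float],
    table: pd.DataFrame,
    n_shuffles: int = 999,
    seed: int = 0,
    outcome: str = "asd_outcome",
) -> float:
    """One-sided permutation p-value with add-one correction.

    Outcome labels are permuted ``n_shuffles`` times; ``refit`` recomputes
    the metric on each permuted table; p = (1 + #{null >= observed}) /
    (n_shuffles + 1).
    """
    if n_shuffles < 99:
        raise ValueError("use at least 99 shuffles")
    rng = np.random.default_rng(seed)
    y = table[outcome].to_numpy()
    count = 0
    for _ in range(n_shuffles):
        shuffled = table.copy()
        shuffled[outcome] = y[rng.permutation(len(y))]
        if refit(shuffled) >= observed_metric:
            count += 1
    return (1 + count) / (n_shuffles + 1)


# ---------------------------------------------------------------------------
# Elastic-net regression with nested cross-validation
# ---------------------------------------------------------------------------

L1_RATIO_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
ALPHA_GRID = tuple(np.logspace(-8, 1, 10))


@dataclass
class RegressionReport:
    rmse: float
    relative_error: float  # percent of outcome range
    rmse_ci: tuple[float, float] | None
    p_value: float | None
    coefficients: pd.DataFrame  # feature, mean, sd, always_selected
    predictions: pd.DataFrame  # subject_id, y_true, y_pred
    seed: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "relative_error_pct": self.relative_error,
            "rmse_ci": list(self.rmse_ci) if self.rmse_ci else None,
            "p_value": self.p_value,
            "coefficients": self.coefficients.to_dict(orient="list"),
            "seed": self.seed,
        }


def _inner_grid_rmse(
    X: np.ndarray, y: np.ndarray, splits, tol: float, alphas: tuple[float, ...]
) -> np.ndarray:
    alphas_desc = np.array(sorted(alphas, reverse=True))
    rmse = np.zeros((len(L1_RATIO_GRID), len(alphas)))
    for tr, te in splits:
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = np.asfortranarray((X[tr] - mu) / sd, dtype=np.float64)
        Xte = (X[te] - mu) / sd
        ym = y[tr].mean()
        ytr = np.ascontiguousarray(y[tr] - ym, dtype=np.float64)
        for i, l1 in enumerate(L1_RATIO_GRID):
            # inputs are standardised/centred here, so the path solver
            # can skip its own input validation
            _, coefs, _ = enet_path(
                Xtr, ytr, l1_ratio=l1, alphas=alphas_desc, max_iter=20000,
                tol=tol, check_input=False,
            )
            preds = Xte @ coefs + ym  # (n_te, n_alphas)
            err = np.sqrt(np.mean((preds - y[te][:, None]) ** 2, axis=0))
            # alphas_desc maps back onto ascending ALPHA_GRID
            rmse[i] += err[::-1]
    return rmse / len(splits)


def _inner_select(
    X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int
) -> tuple[float, float, float]:
    """Pick (l1_ratio, alpha) minimising mean inner-CV RMSE; ties -> sparser.

    The whole penalty path per mixing value is computed in one coordinate-
    descent call, which keeps the 10-fold x 10-repeat grid tractable. A
    first pass searches the practical penalty range (alpha >= 1e-3) at the
    solver's standard tolerance; only when the best achievable error is far
    below the outcome scale (a near-noiseless fit, where the optimum sits in
    the near-OLS limit and solver error would distort the ranking among tiny
    penalties) is the full grid re-evaluated at tight tolerance.
    """
    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X))
    coarse = tuple(a for a in ALPHA_GRID if a >= 1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        alphas = coarse
        rmse = _inner_grid_rmse(X, y, splits, tol=1e-4, alphas=alphas)
        if rmse.min() < 1e-2 * np.std(y):
            alphas = ALPHA_GRID
            rmse = _inner_grid_rmse(X, y, splits, tol=1e-8, alphas=alphas)
    # sparser on ties: prefer larger alpha, then larger l1_ratio
    best = np.inf
    pick = (L1_RATIO_GRID[0], alphas[0])
    for j in range(len(alphas) - 1, -1, -1):
        for i in range(len(L1_RATIO_GRID) - 1, -1, -1):
            if rmse[i, j] < best - 1e-12:
                best = rmse[i, j]
                pick = (L1_RATIO_GRID[i], alphas[j])
    return pick[0], pick[1], float(best)


def elasticnet_nested(
    table: pd.DataFrame,
    outcome: str = "vabs_socialization",
    inner_folds: int = 10,
    inner_repeats: int = 10,
    seed: int = 0,
    compute_ci: bool = True,
    n_boot: int = 1000,
) -> RegressionReport:
    """Leave-one-out elastic net with nested hyperparameter tuning.

    The outer loop leaves one subject out; the inner loop tunes the mixing
    parameter and penalty strength on the outer-training subjects by
    minimising repeated 10-fold cross-validated RMSE (features standardised
    with inner-training statistics). Outer predictions are pooled into one
    RMSE; relative error is RMSE divided by the outcome range, in percent.
    Coefficients are recorded per outer fold (on the standardised scale);
    a feature is *always selected* if its coefficient is nonzero in every
    fold. The RMSE CI is a percentile bootstrap over pooled prediction pairs.
    """
    X, y, cols = _xy(table, outcome)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 subjects")
    if np.std(y) == 0:
        raise ValueError("constant outcome")
    if n - 1 < inner_folds:
        raise ValueError("too few subjects for the inner folds")
    preds = np.zeros(n)
    coefs = np.zeros((n, len(cols)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            l1, a, inner_rmse = _inner_select(X[tr], y[tr], inner_folds, inner_repeats, seed)
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            # adaptive tolerance: a (near-)noiseless fit must be solved to
            # numerical precision for the near-OLS limit to be exact, while
            # a noisy fit gains nothing from sub-noise precision
            tol = float(np.clip(1e-3 * inner_rmse**2 / max(np.var(y[tr]), 1e-300),
                                1e-12, 1e-4))
            model = ElasticNet(alpha=a, l1_ratio=l1, max_iter=50_000, tol=tol)
            model.fit((X[tr] - mu) / sd, y[tr])
            preds[i] = model.predict(((X[i] - mu) / sd)[None, :])[0]
            coefs[i] = model.coef_
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    rng_span = float(np.ptp(y))
    rel = 100.0 * rmse / rng_span
    pred_df = pd.DataFrame(
        {"subject_id": table.get("subject_id", pd.RangeIndex(n)),
         "y_true": y, "y_pred": preds}
    )
    ci = None
    if compute_ci:
        ci = bootstrap_ci(
            lambda t: float(np.sqrt(np.mean((t["y_pred"] - t["y_true"]) ** 2))),
            pred_df, n_boot=n_boot, seed=seed,
        )
    coef_df = pd.DataFrame(
        {
            "feature": cols,
            "mean": coefs.mean(axis=0),
            "sd": coefs.std(axis=0, ddof=0),
            "always_selected": (coefs != 0).all(axis=0),
        }
    )
    return RegressionReport(
        rmse=rmse, relative_error=rel, rmse_ci=ci, p_value=None,
        coefficients=coef_df, predictions=pred_df, seed=seed,
    )


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    table: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI over subject-level resamples with replacement."""
    if len(table) < 10:
        raise ValueError("need at least 10 subjects for a bootstrap CI")
    rng = np.random.default_rng(seed)
    n = len(table)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        reps[b] = statistic(table.iloc[idx])
    lo = (1 - level) / 2
    return (float(np.quantile(reps, lo)), float(np.quantile(reps, 1 - lo)))
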