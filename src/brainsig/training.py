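"""Signature training: LASSO-PCR, stratified splits, and cross-validation.

The estimator is a principal-components regression with L1 selection:

1. center voxel features (no variance scaling — voxel units are homogeneous);
2. PCA to ``n_components`` (default: min(n_obs - 1, n_voxels));
3. LASSO on the component scores (penalty chosen by inner 5-fold CV on a
   penalty path, or fixed);
4. OLS refit on the components with nonzero LASSO coefficients, undoing the
   shrinkage on the survivors;
5. back-projection of the component coefficients to a voxel weight map plus
   intercept, so that X @ w + b reproduces the component-space predictions
   exactly.

Cross-validation is leave-one-subject-out at the subject level (fold models
never see the held-out subject's rows), and the train/test split is at
subject granularity, stratified on each subject's average rating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso, LassoCV

from .core import BetaImageSet, BrainMask, WeightMap

__all__ = [
    "TrainedModel",
    "CrossValidationResult",
    "stratified_split",
    "fit_lasso_pcr",
    "predict",
    "loso_cross_validate",
    "fit_within_subject",
    "retrain_excluding",
]


@dataclass
class TrainedModel:
    """A fitted LASSO-PCR signature."""

    weight_map: WeightMap
    n_components: int
    selected_components: np.ndarray  # indices of PCs surviving the LASSO
    component_coef: np.ndarray       # OLS coefficients of the survivors
    penalty: float                   # LASSO alpha actually used
    metadata: dict = field(default_factory=dict)

    def predict(self, images: BetaImageSet | np.ndarray) -> np.ndarray:
        X = images.data if isinstance(images, BetaImageSet) else np.asarray(images)
        return X @ self.weight_map.weights + self.weight_map.intercept


@dataclass
class CrossValidationResult:
    """Per-observation predictions from subject-level cross-validation."""

    predictions: pd.DataFrame  # subject, fold, actual, predicted
    per_subject: pd.DataFrame  # subject, r, rmse, n (r is NaN when undefined)
    pooled_r: float
    pooled_rmse: float

    @property
    def mean_within_subject_r(self) -> float:
        return float(self.per_subject["r"].mean(skipna=True))

    @property
    def mean_within_subject_rmse(self) -> float:
        return float(self.per_subject["rmse"].mean())


def stratified_split(
    image_set: BetaImageSet,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    max_tries: int = 200,
    balance_tol: float = 0.1,
) -> tuple[BetaImageSet, BetaImageSet]:
    """Split at subject granularity, stratified on subject-average rating.

    Training size is ``round(fraction * n_subjects)``.  Subjects are sorted
    by their average rating and allocated proportionally within consecutive
    strata, so the two groups have near-equal mean ratings; for n >= 30
    subjects the group means must agree within ``balance_tol`` rating units
    (resampling with a fresh sub-seed otherwise, up to ``max_tries``).
    """
    subjects = image_set.subjects
    n = len(subjects)
    if n < 3:
        raise ValueError("stratified split needs at least 3 subjects")
    ratings = image_set.rating
    avg = pd.Series(ratings).groupby(pd.Series(image_set.subject_id)).mean()
    order = avg.loc[subjects].sort_values(kind="mergesort").index.to_numpy()
    n_train = int(round(fraction * n))
    if not 0 < n_train < n:
        raise ValueError(f"fraction {fraction} leaves an empty split for n={n}")

    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        # systematic proportional allocation along the sorted list, with the
        # within-position choice randomized: walk the sorted subjects and
        # assign to train until its quota along the walk is exhausted
        assign = np.zeros(n, dtype=bool)
        quota = np.full(n, fraction)
        # randomized rounding that hits n_train exactly
        picks = rng.permutation(n)
        frac_target = np.cumsum(quota)
        taken = 0
        for i in range(n):
            want = int(round(frac_target[i])) - taken
            if want > 0:
                assign[i] = True
                taken += 1
        # correct count drift from rounding
        while taken > n_train:
            on = np.nonzero(assign)[0]
            assign[rng.choice(on)] = False
            taken -= 1
        while taken < n_train:
            off = np.nonzero(~assign)[0]
            assign[rng.choice(off)] = True
            taken += 1
        # random swap within adjacent pairs to de-pattern the systematic walk
        for i in range(0, n - 1, 2):
            if rng.random() < 0.5:
                assign[i], assign[i + 1] = assign[i + 1], assign[i]
        if assign.sum() != n_train:
            continue
        train_subj = order[assign]
        test_subj = order[~assign]
        diff = abs(avg.loc[train_subj].mean() - avg.loc[test_subj].mean())
        if n < 30 or diff < balance_tol:
            train = image_set.subset_subjects(train_subj)
            test = image_set.subset_subjects(test_subj)
            train.split, test.split = "train", "test"
            return train, test
    raise RuntimeError(
        f"could not balance split to {balance_tol} rating units in {max_tries} tries"
    )


def _fit_core(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None,
    penalty,
    seed: int,
) -> tuple[np.ndarray, float, dict]:
    """LASSO-PCR in feature space; returns (weights, intercept, info)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_obs, n_feat = X.shape
    if n_obs < 2:
        raise ValueError("need at least 2 observations")
    k_max = min(n_obs - 1, n_feat)
    k = k_max if n_components is None else min(n_components, k_max)
    if k < 1:
        raise ValueError("n_components must be >= 1")

    mu = X.mean(axis=0)
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    Z = pca.fit_transform(X)  # (n_obs, k), uses centered X internally

    if penalty == "cv":
        cv_model = LassoCV(cv=min(5, n_obs), random_state=seed, max_iter=50000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_model.fit(Z, y)
        alpha = float(cv_model.alpha_)
        coef = cv_model.coef_
    else:
        alpha = float(penalty)
        lasso = Lasso(alpha=alpha, max_iter=50000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso.fit(Z, y)
        coef = lasso.coef_

    selected = np.nonzero(coef)[0]
    if selected.size == 0:
        warnings.warn(
            "LASSO shrank all components to zero; falling back to an "
            "intercept-only model", RuntimeWarning, stacklevel=3,
        )
        w = np.zeros(n_feat)
        b = float(y.mean())
        info = dict(n_components=k, selected=selected, beta=np.empty(0), alpha=alpha)
        return w, b, info

    # OLS refit on the surviving components (lstsq: exact, no shrinkage)
    Zs = Z[:, selected]
    A = np.column_stack([np.ones(n_obs), Zs])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    b0, beta = sol[0], sol[1:]

    # back-project: yhat = (X - mu) @ V_sel.T @ beta + b0 = X @ w + b
    V_sel = pca.components_[selected]          # (m, n_feat)
    w = V_sel.T @ beta
    b = float(b0 - mu @ w)
    info = dict(n_components=k, selected=selected, beta=beta, alpha=alpha)
    return w, b, info


def fit_lasso_pcr(
    train: BetaImageSet,
    ratings: np.ndarray | None = None,
    n_components: int | None = None,
    penalty="cv",
    seed: int = 0,
    provenance: str = "lasso-pcr",
) -> TrainedModel:
    """Fit the LASSO-PCR signature on a training image set.

    ``penalty`` is ``"cv"`` (inner 5-fold cross-validated path, default) or
    a fixed nonnegative float.  If all coefficients are shrunk to zero the
    model falls back to intercept-only with a warning.
    """
    y = train.rating if ratings is None else np.asarray(ratings, dtype=float)
    w, b, info = _fit_core(train.data, y, n_components, penalty, seed)
    wmap = WeightMap(w, b, train.mask, provenance=provenance)
    return TrainedModel(
        weight_map=wmap,
        n_components=info["n_components"],
        selected_components=info["selected"],
        component_coef=info["beta"],
        penalty=info["alpha"],
        metadata={"algorithm": "lasso-pcr", "penalty": penalty, "seed": seed},
    )


def predict(model: TrainedModel, images: BetaImageSet) -> np.ndarray:
    if not model.weight_map.mask.same_grid(images.mask):
        raise ValueError("model and images are on different grids")
    return model.predict(images)


def _subject_metrics(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, g in df.groupby("subject", sort=True):
        resid = g["predicted"] - g["actual"]
        rmse = float(np.sqrt(np.mean(resid**2)))
        if len(g) >= 2 and g["actual"].nunique() > 1 and g["predicted"].nunique() > 1:
            r = float(np.corrcoef(g["predicted"], g["actual"])[0, 1])
        else:
            r = np.nan  # undefined: single observation or constant vector
        rows.append({"subject": sid, "r": r, "rmse": rmse, "n": len(g)})
    return pd.DataFrame(rows)


def loso_cross_validate(
    image_set: BetaImageSet,
    ratings: np.ndarray | None = None,
    n_components: int | None = None,
    penalty="cv",
    seed: int = 0,
) -> CrossValidationResult:
    """Leave-one-subject-out cross-validation (one fold per subject)."""
    subjects = image_set.subjects
    if len(subjects) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    y = image_set.rating if ratings is None else np.asarray(ratings, dtype=float)
    recs = []
    for fold, sid in enumerate(sorted(subjects)):
        test_rows = np.nonzero(image_set.subject_id == sid)[0]
        train_rows = np.nonzero(image_set.subject_id != sid)[0]
        w, b, _ = _fit_core(
            image_set.data[train_rows], y[train_rows], n_components, penalty, seed
        )
        pred = image_set.data[test_rows] @ w + b
        for i, row in enumerate(test_rows):
            recs.append(
                {"subject": sid, "fold": fold, "actual": y[row], "predicted": pred[i]}
            )
    df = pd.DataFrame(recs)
    per_subject = _subject_metrics(df)
    pooled_r = float(np.corrcoef(df["predicted"], df["actual"])[0, 1])
    pooled_rmse = float(np.sqrt(np.mean((df["predicted"] - df["actual"]) ** 2)))
    return CrossValidationResult(df, per_subject, pooled_r, pooled_rmse)


def fit_within_subject(
    trials: BetaImageSet,
    ratings: np.ndarray | None = None,
    k_folds: int = 5,
    n_components: int | None = None,
    penalty="cv",
    seed: int = 0,
) -> tuple[TrainedModel, float]:
    """Per-subject model on trial-level data with k-fold cross-validation.

    Returns the model trained on all trials plus the cross-validated
    trial-level prediction correlation (NaN when ratings are constant).
    Group-level weight consistency across subjects is then testable with a
    one-sample t-test on the stacked per-subject weight maps.
    """
    if len(trials.subjects) != 1:
        raise ValueError("fit_within_subject expects a single subject's trials")
    n = trials.n_observations
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} trials, got {n}")
    y = trials.rating if ratings is None else np.asarray(ratings, dtype=float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    pred = np.empty(n)
    for f in folds:
        train_rows = np.setdiff1d(order, f)
        w, b, _ = _fit_core(trials.data[train_rows], y[train_rows],
                            n_components, penalty, seed)
        pred[f] = trials.data[f] @ w + b

    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        cv_r = float("nan")  # constant ratings or predictions: r undefined
    else:
        cv_r = float(np.corrcoef(pred, y)[0, 1])
    model = fit_lasso_pcr(trials, y, n_components, penalty, seed,
                          provenance="within-subject lasso-pcr")
    return model, cv_r


def retrain_excluding(
    image_set: BetaImageSet,
    exclusion: BrainMask,
    ratings: np.ndarray | None = None,
    n_components: int | None = None,
    penalty="cv",
    seed: int = 0,
) -> TrainedModel:
    """Refit the signature with an anatomical exclusion zone zeroed out.

    The exclusion mask must live on the same grid; excluded voxels are
    removed from the feature set and get zero weight in the returned map.
    """
    if exclusion.grid_shape != image_set.mask.grid_shape:
        raise ValueError(
            f"exclusion grid {exclusion.grid_shape} does not match image grid "
            f"{image_set.mask.grid_shape}"
        )
    keep = ~image_set.mask.vectorize(exclusion.inclusion)
    if not keep.any():
        raise ValueError("exclusion removes every in-mask voxel")
    y = image_set.rating if ratings is None else np.asarray(ratings, dtype=float)
    w_red, b, info = _fit_core(
        image_set.data[:, keep], y, n_components, penalty, seed
    )
    w = np.zeros(image_set.mask.n_voxels)
    w[keep] = w_red
    wmap = WeightMap(w, b, image_set.mask,
                     provenance="lasso-pcr (with exclusion mask)")
    return TrainedModel(
        weight_map=wmap,
        n_components=info["n_components"],
        selected_components=info["selected"],
        component_coef=info["beta"],
        penalty=info["alpha"],
        metadata={"algorithm": "lasso-pcr", "excluded_voxels": int((~keep).sum())},
    )
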