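"""Applying signatures to images: pattern responses, map comparisons,
ROI averages, peristimulus chronometry, and item analyses.

The canonical pattern response is the dot product of a signature weight map
with a vectorized activation image plus the intercept (rating units when
the signature was trained on ratings).  Scale-free alternatives (Pearson /
Spearman spatial correlations, point-biserial for binary masks) ignore the
intercept and are bounded in [-1, 1], which makes responses comparable
across datasets with different units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaImageSet, BrainMask, WeightMap

__all__ = [
    "MapComparison",
    "pattern_response",
    "pattern_responses",
    "response_table",
    "compare_maps",
    "roi_response",
    "timeseries_response",
    "item_analysis",
]

_CORR_METHODS = ("pearson", "spearman", "pointbiserial")


@dataclass
class MapComparison:
    pattern_a: str
    pattern_b: str
    statistic: str
    value: float
    scope: str = "whole-mask"


def _one_response(w: np.ndarray, intercept: float, beta: np.ndarray,
                  method: str) -> float:
    if method == "dot":
        return float(w @ beta + intercept)
    if method == "pearson":
        return float(stats.pearsonr(w, beta).statistic)
    if method == "spearman":
        return float(stats.spearmanr(w, beta).statistic)
    if method == "pointbiserial":
        return float(stats.pointbiserialr(w.astype(bool).astype(float), beta).statistic)
    raise ValueError(f"unknown response method {method!r}")


def pattern_response(
    wmap: WeightMap, image: np.ndarray | BetaImageSet, method: str = "dot"
):
    """Signature expression in one image (or each row of an image set).

    ``dot`` returns w.beta + intercept; correlation methods return values
    in [-1, 1] and ignore the intercept.
    """
    if isinstance(image, BetaImageSet):
        if not wmap.mask.same_grid(image.mask) or wmap.mask.n_voxels != image.mask.n_voxels:
            raise ValueError("weight map and images are on different masks")
        return pattern_responses(wmap, image.data, method)
    beta = np.asarray(image, dtype=float).ravel()
    if beta.shape[0] != wmap.mask.n_voxels:
        raise ValueError(
            f"image has {beta.shape[0]} voxels, mask has {wmap.mask.n_voxels}"
        )
    return _one_response(wmap.weights, wmap.intercept, beta, method)


def pattern_responses(wmap: WeightMap, data: np.ndarray, method: str = "dot"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if method == "dot":
        return data @ wmap.weights + wmap.intercept
    return np.array(
        [_one_response(wmap.weights, wmap.intercept, row, method) for row in data]
    )


def response_table(
    patterns: dict[str, WeightMap],
    images: BetaImageSet,
    method: str = "dot",
) -> pd.DataFrame:
    """Long-format table of responses: one row per (observation, pattern)."""
    recs = []
    for name, wmap in patterns.items():
        resp = pattern_response(wmap, images, method)
        for i in range(images.n_observations):
            recs.append(
                {
                    "subject": images.subject_id[i],
                    "condition": images.condition_label[i],
                    "trial": None if images.trial_id is None else images.trial_id[i],
                    "pattern": name,
                    "response": resp[i],
                    "method": method,
                }
            )
    return pd.DataFrame(recs)


def _robust_ranked_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation of ranks estimated by a Huber-weighted straight-line fit,
    reported on the correlation scale (slope of standardized ranks)."""
    import statsmodels.api as sm

    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = (ra - ra.mean()) / ra.std()
    rb = (rb - rb.mean()) / rb.std()
    fit = sm.RLM(rb, sm.add_constant(ra), M=sm.robust.norms.HuberT()).fit()
    return float(np.clip(fit.params[1], -1.0, 1.0))


def compare_maps(
    a: WeightMap,
    b: WeightMap | BrainMask,
    statistic: str = "spearman",
    scope: np.ndarray | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> MapComparison:
    """Spatial similarity of two maps over the shared mask (or a scope ROI).

    ``statistic``: ``pearson``, ``spearman`` (the ranked statistic, default
    for map-to-map comparisons), ``ranked_robust`` (Huber-weighted fit on
    ranks), or ``pointbiserial`` (binary second map).
    """
    va = a.weights
    if isinstance(b, BrainMask):
        vb = a.mask.vectorize(b.inclusion).astype(float)
    else:
        if b.mask.n_voxels != a.mask.n_voxels:
            raise ValueError("maps are on different masks")
        vb = b.weights
    if scope is not None:
        scope = np.asarray(scope, dtype=bool)
        va, vb = va[scope], vb[scope]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero-variance map: comparison undefined")
    if statistic == "pearson":
        value = float(stats.pearsonr(va, vb).statistic)
    elif statistic == "spearman":
        value = float(stats.spearmanr(va, vb).statistic)
    elif statistic == "ranked_robust":
        value = _robust_ranked_corr(va, vb)
    elif statistic == "pointbiserial":
        value = float(stats.pointbiserialr(vb.astype(bool).astype(float), va).statistic)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return MapComparison(names[0], names[1], statistic, value,
                         scope="roi" if scope is not None else "whole-mask")


def roi_response(
    images: BetaImageSet,
    roi: BrainMask | np.ndarray,
    calibrate: tuple[BetaImageSet, np.ndarray] | None = None,
) -> np.ndarray:
    """Mean activation over an ROI per observation.

    With ``calibrate=(train_set, train_ratings)`` the ROI means are mapped
    to predicted ratings through a univariate linear model estimated on the
    training split, for RMSE / correlation benchmarking against signatures.
    """
    if isinstance(roi, BrainMask):
        sel = images.mask.vectorize(roi.inclusion)
    else:
        sel = np.asarray(roi, dtype=bool)
    if sel.shape[0] != images.mask.n_voxels:
        raise ValueError("ROI is not on the image mask")
    if not sel.any():
        raise ValueError("empty ROI")
    means = images.data[:, sel].mean(axis=1)
    if calibrate is None:
        return means
    train_set, train_y = calibrate
    train_means = train_set.data[:, sel].mean(axis=1)
    slope, intercept, *_ = stats.linregress(train_means, np.asarray(train_y, float))
    return slope * means + intercept


def timeseries_response(
    wmap: WeightMap,
    series: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    window: float = 20.0,
) -> pd.DataFrame:
    """Event-locked (peristimulus) pattern-response curves.

    ``series`` is a grid x time array on the map's grid.  The signature is
    applied to every volume, then responses are extracted per event from
    onset over ``window`` seconds and averaged by the event's ``rating``
    condition.  Returns a tidy frame (time_s, condition, response, n).
    """
    if series.shape[:3] != wmap.mask.grid_shape:
        raise ValueError("series is not on the weight map grid")
    vecs = wmap.mask.vectorize(series)  # (n_voxels, n_volumes)
    pr = vecs.T @ wmap.weights + wmap.intercept
    n_vol = pr.shape[0]
    n_steps = int(np.floor(window / tr)) + 1
    recs = []
    for _, ev in events.iterrows():
        start = int(np.round(ev["onset"] / tr))
        for step in range(n_steps):
            t = start + step
            if t >= n_vol:
                import warnings

                warnings.warn("window truncated at end of series", stacklevel=2)
                break
            recs.append(
                {"condition": ev["rating"], "time_s": step * tr, "response": pr[t]}
            )
    df = pd.DataFrame(recs)
    return (
        df.groupby(["condition", "time_s"], sort=True)["response"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "response", "count": "n"})
        .reset_index()
    )


def item_analysis(
    trial_responses: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
) -> dict:
    """Item-level agreement between signature expression and ratings.

    ``trial_responses`` needs ``item``, ``subject``, ``response`` and —
    unless a separate ``ratings`` table (item, subject, rating) is given —
    a ``rating`` column.  Items are averaged across subjects; the result is
    the Pearson r between item-mean response and item-mean rating with a
    two-sided t test on n_items - 2 degrees of freedom.
    """
    df = trial_responses.copy()
    if ratings is not None:
        df = df.merge(ratings[["item", "subject", "rating"]],
                      on=["item", "subject"], how="inner")
    for col in ("item", "response", "rating"):
        if col not in df.columns:
            raise ValueError(f"trial responses are missing column {col!r}")
    per_item = (
        df.groupby("item", sort=True)
        .agg(mean_response=("response", "mean"), mean_rating=("rating", "mean"),
             n_subjects=("subject", "nunique"))
        .reset_index()
    )
    thin = per_item.loc[per_item["n_subjects"] < 2, "item"].tolist()
    n_items = len(per_item)
    if n_items < 3:
        raise ValueError("item analysis needs at least 3 items")
    r = float(stats.pearsonr(per_item["mean_response"], per_item["mean_rating"]).statistic)
    dof = n_items - 2
    t = r * np.sqrt(dof / max(1e-300, 1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return {
        "per_item": per_item,
        "r": r,
        "t": float(t),
        "dof": dof,
        "p": p,
        "items_with_single_subject": thin,
    }
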