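"""Classification and accuracy statistics for signature responses.

Two classification schemes are provided:

* forced choice — within-subject comparison of responses to two
  conditions; the larger response designates the predicted higher-intensity
  condition.  Threshold free, invariant to any strictly increasing
  transform of the responses, and sensitivity = specificity = accuracy.

* single interval — each observation is labeled by comparing its response
  to a fixed cutpoint.  The cutpoint is chosen by brute-force scan over the
  midpoints between adjacent sorted responses to minimize the
  signal-detection response bias c = -(Phi^-1(TPR) + Phi^-1(FPR)) / 2
  (rates clamped to [1/(2n), 1 - 1/(2n)] per class before the probit), and
  accuracy is reported as balanced accuracy b = (TPR + TNR) / 2.  Ties in
  |c| break toward higher balanced accuracy, then toward the lower
  threshold.

Accuracies are compared with McNemar's test (dependent designs, matched
units) or a two-proportion z test (independent designs); significance
against chance uses exact binomial tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassificationResult",
    "forced_choice",
    "single_interval",
    "balanced_accuracy",
    "prediction_metrics",
    "compare_accuracies",
    "trend_test",
    "orthogonal_polynomial_contrasts",
]


@dataclass
class ClassificationResult:
    accuracy: float
    sensitivity: float
    specificity: float
    se: float
    n: int
    p_value: float
    test_name: str
    threshold: float | None = None
    correct: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        for v in (self.accuracy, self.sensitivity, self.specificity):
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError("classification rates must lie in [0, 1]")


def forced_choice(
    high: np.ndarray, low: np.ndarray
) -> ClassificationResult:
    """Paired within-subject comparison: fraction of pairs where the
    designated higher-intensity condition got the larger response.

    Ties are credited 0.5.  Pairs with a missing side must be excluded by
    the caller (NaN on either side drops the pair here).  The p-value is a
    two-tailed exact binomial test against 0.5 on the non-tied pairs.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if high.shape != low.shape:
        raise ValueError("forced choice needs paired response vectors")
    ok = np.isfinite(high) & np.isfinite(low)
    high, low = high[ok], low[ok]
    n = len(high)
    if n == 0:
        raise ValueError("no complete pairs for forced-choice test")
    wins = np.sum(high > low)
    ties = np.sum(high == low)
    acc = float((wins + 0.5 * ties) / n)
    n_eff = n - ties
    p = (
        float(stats.binomtest(int(wins), int(n_eff), 0.5).pvalue)
        if n_eff > 0
        else 1.0
    )
    se = float(np.sqrt(acc * (1 - acc) / n))
    correct = (high > low).astype(float) + 0.5 * (high == low)
    return ClassificationResult(
        accuracy=acc, sensitivity=acc, specificity=acc, se=se, n=n,
        p_value=p, test_name="forced-choice binomial", threshold=None,
        correct=correct,
    )


def _rates(responses, labels, threshold):
    pred = responses > threshold
    pos, neg = labels, ~labels
    tp = np.sum(pred & pos)
    fn = np.sum(~pred & pos)
    tn = np.sum(~pred & neg)
    fp = np.sum(pred & neg)
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return tpr, tnr, int(tp + tn)


def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    """b = (TP/(TP+FN) + TN/(FP+TN)) / 2."""
    return 0.5 * (tp / (tp + fn) + tn / (fp + tn))


def single_interval(
    responses: np.ndarray, labels: np.ndarray
) -> ClassificationResult:
    """Single-interval classification at the bias-minimizing threshold.

    ``labels`` are boolean (True = positive / higher-intensity class).
    See the module docstring for the threshold rule.
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if responses.shape != labels.shape:
        raise ValueError("responses and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.sort(np.unique(responses))
    if len(order) == 1:
        candidates = np.array([order[0]])
    else:
        candidates = (order[:-1] + order[1:]) / 2.0

    clamp_pos = 1.0 / (2.0 * n_pos)
    clamp_neg = 1.0 / (2.0 * n_neg)
    best = None
    for thr in candidates:
        tpr, tnr, n_correct = _rates(responses, labels, thr)
        fpr = 1.0 - tnr
        tpr_c = np.clip(tpr, clamp_pos, 1.0 - clamp_pos)
        fpr_c = np.clip(fpr, clamp_neg, 1.0 - clamp_neg)
        c = -(stats.norm.ppf(tpr_c) + stats.norm.ppf(fpr_c)) / 2.0
        b = 0.5 * (tpr + tnr)
        key = (abs(c), -b, thr)  # |bias| min, then max b, then low threshold
        if best is None or key < best[0]:
            best = (key, thr, tpr, tnr, b, n_correct)

    _, thr, tpr, tnr, b, n_correct = best
    n = n_pos + n_neg
    se = float(
        0.5 * np.sqrt(tpr * (1 - tpr) / n_pos + tnr * (1 - tnr) / n_neg)
    )
    p = float(stats.binomtest(n_correct, n, 0.5).pvalue)
    pred = responses > thr
    return ClassificationResult(
        accuracy=float(b), sensitivity=float(tpr), specificity=float(tnr),
        se=se, n=n, p_value=p, threshold=float(thr),
        test_name="single-interval binomial",
        correct=(pred == labels).astype(float),
    )


def prediction_metrics(
    predicted: np.ndarray,
    actual: np.ndarray,
    subject: np.ndarray | None = None,
) -> dict:
    """RMSE and Pearson r, within subject when a grouping is given.

    With ``subject``, metrics are computed per subject and averaged across
    subjects with standard errors; subjects with constant vectors get an
    undefined (NaN) r and are listed under ``r_undefined``.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if subject is None:
        rmse = float(np.sqrt(np.mean((predicted - actual) ** 2)))
        if np.ptp(predicted) == 0 or np.ptp(actual) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(predicted, actual).statistic)
        return {"rmse": rmse, "r": r, "n": len(actual)}
    df = pd.DataFrame({"subject": subject, "predicted": predicted, "actual": actual})
    rows, undef = [], []
    for sid, g in df.groupby("subject", sort=True):
        rmse = float(np.sqrt(np.mean((g["predicted"] - g["actual"]) ** 2)))
        if len(g) >= 2 and g["actual"].nunique() > 1 and g["predicted"].nunique() > 1:
            r = float(stats.pearsonr(g["predicted"], g["actual"]).statistic)
        else:
            r = float("nan")
            undef.append(sid)
        rows.append({"subject": sid, "r": r, "rmse": rmse})
    per = pd.DataFrame(rows)
    r_vals = per["r"].dropna()
    return {
        "per_subject": per,
        "mean_r": float(r_vals.mean()),
        "se_r": float(r_vals.std(ddof=1) / np.sqrt(len(r_vals))) if len(r_vals) > 1 else float("nan"),
        "mean_rmse": float(per["rmse"].mean()),
        "se_rmse": float(per["rmse"].std(ddof=1) / np.sqrt(len(per))) if len(per) > 1 else float("nan"),
        "r_undefined": undef,
        "n_subjects": len(per),
    }


def compare_accuracies(
    correct_a: np.ndarray,
    correct_b: np.ndarray | None = None,
    design: str = "dependent",
    n_a: int | None = None,
    n_b: int | None = None,
    p_a: float | None = None,
    p_b: float | None = None,
) -> dict:
    """Test whether two classifiers differ in accuracy.

    dependent: McNemar's chi-square on the discordant pairs of two
    per-unit correctness vectors (matched units).  independent: two-sample
    two-tailed z test for proportions, from correctness vectors or from
    (p_a, n_a, p_b, n_b) summaries.
    """
    if design == "dependent":
        a = np.asarray(correct_a) >= 0.5
        b = np.asarray(correct_b) >= 0.5
        if a.shape != b.shape:
            raise ValueError("dependent design needs matched correctness vectors")
        n01 = int(np.sum(a & ~b))
        n10 = int(np.sum(~a & b))
        if n01 + n10 == 0:
            return {"statistic": 0.0, "p_value": 1.0, "test": "mcnemar",
                    "note": "no discordant pairs"}
        chi2 = (n01 - n10) ** 2 / (n01 + n10)
        p = float(stats.chi2.sf(chi2, df=1))
        return {"statistic": float(chi2), "p_value": p, "test": "mcnemar",
                "discordant": (n01, n10)}
    if design == "independent":
        if correct_a is not None and correct_b is not None and p_a is None:
            a = np.asarray(correct_a, dtype=float)
            b = np.asarray(correct_b, dtype=float)
            p_a, n_a = float(a.mean()), len(a)
            p_b, n_b = float(b.mean()), len(b)
        pool = (p_a * n_a + p_b * n_b) / (n_a + n_b)
        denom = np.sqrt(pool * (1 - pool) * (1 / n_a + 1 / n_b))
        z = 0.0 if denom == 0 else (p_a - p_b) / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
        return {"statistic": float(z), "p_value": p, "test": "two-proportion z"}
    raise ValueError(f"unknown design {design!r}")


def orthogonal_polynomial_contrasts(n_levels: int, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial contrast matrix (degree x n_levels) for
    equally spaced levels, built by QR on the Vandermonde basis."""
    if n_levels < degree + 1:
        raise ValueError(f"{n_levels} levels support at most degree {n_levels - 1}")
    x = np.arange(n_levels, dtype=float)
    V = np.vander(x, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1 : degree + 1].T
    # fix sign: linear contrast increases with level, quadratic is U-shaped
    for d in range(C.shape[0]):
        ref = x ** (d + 1)
        if C[d] @ (ref - ref.mean()) < 0:
            C[d] = -C[d]
    return C


def trend_test(
    responses: pd.DataFrame,
    value: str = "response",
    level: str = "condition",
    subject: str = "subject",
) -> pd.DataFrame:
    """Within-subject linear and quadratic trends across ordinal levels.

    Each subject's level means are projected on orthonormal polynomial
    contrasts; the contrast estimates are then tested against zero across
    subjects with one-sample t tests.  Needs >= 3 levels for the quadratic
    term.  Returns a frame with contrast, estimate, se, t, dof, p.
    """
    levels = np.sort(responses[level].unique())
    n_levels = len(levels)
    if n_levels < 3:
        raise ValueError("trend test needs at least 3 levels")
    C = orthogonal_polynomial_contrasts(n_levels, degree=2)
    names = ["linear", "quadratic"]
    per_subject = []
    for sid, g in responses.groupby(subject, sort=True):
        means = g.groupby(level)[value].mean().reindex(levels)
        if means.isna().any():
            continue  # subject missing a level: no full contrast
        per_subject.append(C @ means.to_numpy())
    est = np.array(per_subject)
    if len(est) < 2:
        raise ValueError("need at least 2 subjects with all levels")
    rows = []
    for i, name in enumerate(names):
        t, p = stats.ttest_1samp(est[:, i], 0.0)
        rows.append(
            {
                "contrast": name,
                "estimate": float(est[:, i].mean()),
                "se": float(est[:, i].std(ddof=1) / np.sqrt(len(est))),
                "t": float(t),
                "dof": len(est) - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
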