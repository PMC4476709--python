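"""Sensitivity/specificity comparison grid for signatures, ROIs, and
network masks on emotion and pain test sets.

Each candidate pattern is scored on every rating-level observation of both
test sets — dot-product responses for weight maps, point-biserial spatial
correlations for binary network masks, mean activation for anatomical ROIs
— then five cells are computed per pattern:

* emotion high-vs-low (rating 5 vs 1) single-interval balanced accuracy,
* pain high-vs-low single-interval balanced accuracy,
* emotion-vs-pain (highest emotion level vs highest pain level)
  single-interval balanced accuracy,
* emotion correlation: per-subject Pearson r of response vs rating level,
  averaged across subjects (+/- SE),
* pain correlation: same for pain levels.

Accuracies are signed: values above 50% mean the higher-intensity (or
emotion) condition drew the larger response, values below 50% the reverse.
Observations from subjects lacking a required extreme level simply
contribute no row to that cell.  Each cell also carries a chance test and,
when a reference pattern is named, a McNemar comparison against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaImageSet, BrainMask, WeightMap
from .evaluate import (
    ClassificationResult,
    compare_accuracies,
    forced_choice,
    prediction_metrics,
    single_interval,
)
from .expression import pattern_response, roi_response

__all__ = ["BenchmarkGrid", "run_benchmark", "published_table_metrics"]

ACCURACY_CELLS = ("emotion_high_vs_low", "pain_high_vs_low", "emotion_vs_pain")


@dataclass
class BenchmarkGrid:
    table: pd.DataFrame            # one row per pattern, cells as columns
    details: dict                  # pattern -> cell -> ClassificationResult/dict

    def cell(self, pattern: str, name: str):
        return self.details[pattern][name]


def _pattern_scores(pattern, images: BetaImageSet) -> np.ndarray:
    if isinstance(pattern, WeightMap):
        return pattern_response(pattern, images, method="dot")
    if isinstance(pattern, BrainMask):  # binary network mask
        sel = images.mask.vectorize(pattern.inclusion).astype(float)
        wmap = WeightMap(sel, 0.0, images.mask)
        return pattern_response(wmap, images, method="pointbiserial")
    if isinstance(pattern, tuple) and pattern[0] == "roi":
        return roi_response(images, pattern[1])
    raise ValueError(f"pattern type not recognized: {type(pattern).__name__}")


def _paired(values, subjects, labels, level_a, level_b):
    """Per-subject (level_a, level_b) response pairs, NaN when missing."""
    df = pd.DataFrame({"subject": subjects, "label": labels, "value": values})
    wide = df.pivot_table(index="subject", columns="label", values="value",
                          aggfunc="mean")
    a = wide[level_a] if level_a in wide else pd.Series(dtype=float)
    b = wide[level_b] if level_b in wide else pd.Series(dtype=float)
    both = pd.concat([a, b], axis=1).dropna()
    return both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy()


def _high_low_cell(values, images: BetaImageSet, high, low,
                   scheme: str) -> ClassificationResult:
    lab = images.condition_label
    keep = (lab == high) | (lab == low)
    if scheme == "forced":
        hi, lo = _paired(values, images.subject_id, lab, high, low)
        return forced_choice(hi, lo)
    return single_interval(values[keep], lab[keep] == high)


def run_benchmark(
    patterns: dict[str, object],
    emotion: BetaImageSet,
    pain: BetaImageSet,
    scheme: str = "single_interval",
    reference: str | None = None,
) -> BenchmarkGrid:
    """Evaluate each pattern on the emotion and pain test sets.

    ``patterns`` maps a display name to a :class:`WeightMap`, a binary
    :class:`BrainMask` (network mask), or ``("roi", BrainMask)`` for an
    anatomical ROI scored by mean activation.  ``scheme`` selects
    single-interval (default) or forced-choice accuracy cells.
    ``reference`` names the pattern against which McNemar comparisons are
    annotated.
    """
    emo_levels = np.sort(np.unique(emotion.rating))
    pain_levels = np.sort(np.unique(pain.rating))
    emo_hi = emotion.condition_label[np.argmax(emotion.rating)]
    emo_lo = emotion.condition_label[np.argmin(emotion.rating)]
    pain_hi = pain.condition_label[np.argmax(pain.rating)]
    pain_lo = pain.condition_label[np.argmin(pain.rating)]

    details: dict[str, dict] = {}
    rows = []
    for name, pattern in patterns.items():
        emo_scores = _pattern_scores(pattern, emotion)
        pain_scores = _pattern_scores(pattern, pain)
        cells: dict[str, object] = {}

        cells["emotion_high_vs_low"] = _high_low_cell(
            emo_scores, emotion, emo_hi, emo_lo, scheme
        )
        cells["pain_high_vs_low"] = _high_low_cell(
            pain_scores, pain, pain_hi, pain_lo, scheme
        )
        # emotion (positive class) at its top level vs pain at its top level
        ev = emo_scores[emotion.condition_label == emo_hi]
        pv = pain_scores[pain.condition_label == pain_hi]
        pooled = np.concatenate([ev, pv])
        labels = np.concatenate([np.ones(len(ev), bool), np.zeros(len(pv), bool)])
        cells["emotion_vs_pain"] = single_interval(pooled, labels)

        cells["emotion_correlation"] = prediction_metrics(
            emo_scores, emotion.rating, emotion.subject_id
        )
        cells["pain_correlation"] = prediction_metrics(
            pain_scores, pain.rating, pain.subject_id
        )
        details[name] = cells
        rows.append(
            {
                "pattern": name,
                **{
                    c: 100.0 * cells[c].accuracy for c in ACCURACY_CELLS
                },
                "emotion_correlation": cells["emotion_correlation"]["mean_r"],
                "pain_correlation": cells["pain_correlation"]["mean_r"],
            }
        )

    if reference is not None and reference in details:
        for name in details:
            if name == reference:
                continue
            for cell in ("emotion_high_vs_low", "emotion_vs_pain"):
                ref_res = details[reference][cell]
                res = details[name][cell]
                if ref_res.correct is not None and res.correct is not None \
                        and len(ref_res.correct) == len(res.correct):
                    details[name][f"{cell}_vs_{reference}"] = compare_accuracies(
                        res.correct, ref_res.correct, design="dependent"
                    )
                else:
                    details[name][f"{cell}_vs_{reference}"] = compare_accuracies(
                        None, None, design="independent",
                        p_a=res.accuracy, n_a=res.n,
                        p_b=ref_res.accuracy, n_b=ref_res.n,
                    )
    return BenchmarkGrid(table=pd.DataFrame(rows), details=details)


# ---------------------------------------------------------------------------
# Recomputation from published rating/trial-level response tables
# ---------------------------------------------------------------------------

def published_table_metrics(
    rating_level: pd.DataFrame,
    trial_level: pd.DataFrame | None = None,
) -> dict:
    """Recompute headline evaluation numbers from released response tables.

    ``rating_level`` must carry one row per (subject, condition) with
    columns ``subject``, ``modality`` ("emotion" | "pain"), ``condition``
    (rating 1-5 or low/medium/high), ``split`` ("train" | "test"), a
    ``rating`` column with the observed self-report, and one response
    column per pattern (``pines``, ``nps``, ``amygdala``, ...; matched
    case-insensitively).  ``trial_level`` needs ``subject``, ``item``,
    ``rating``, ``pines`` for the item and trial-level analyses.

    Returns a dict of quantities on the percentage / correlation scales.
    """
    df = rating_level.copy()
    df.columns = [c.lower() for c in df.columns]
    need = {"subject", "modality", "condition", "split", "pines"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"rating-level table missing columns: {sorted(missing)}")
    emo = df[df["modality"] == "emotion"]
    pain = df[df["modality"] == "pain"]
    emo_test = emo[emo["split"] == "test"]
    out: dict[str, float] = {}

    def fc(frame, col, a, b):
        hi, lo = _paired(
            frame[col].to_numpy(), frame["subject"].to_numpy(),
            frame["condition"].astype(str).to_numpy(), str(a), str(b),
        )
        return 100.0 * forced_choice(hi, lo).accuracy

    def si(frame_pos, frame_neg, col):
        pooled = np.concatenate([frame_pos[col].to_numpy(),
                                 frame_neg[col].to_numpy()])
        labels = np.concatenate(
            [np.ones(len(frame_pos), bool), np.zeros(len(frame_neg), bool)]
        )
        return 100.0 * single_interval(pooled, labels).accuracy

    cond = emo_test["condition"].astype(str)
    out["fc_emotion_5v1_pct"] = fc(emo, "pines", 5, 1)  # cv + test subjects
    out["fc_emotion_5v3_test_pct"] = fc(emo_test, "pines", 5, 3)
    out["si_emotion_5v1_pines_pct"] = si(
        emo_test[cond == "5"], emo_test[cond == "1"], "pines"
    )
    pain_cond = pain["condition"].astype(str)
    out["si_pain_high_low_pines_pct"] = si(
        pain[pain_cond == "high"], pain[pain_cond == "low"], "pines"
    )
    out["si_emotion_vs_pain_pines_pct"] = si(
        emo_test[cond == "5"], pain[pain_cond == "high"], "pines"
    )
    if "nps" in df.columns:
        out["si_pain_vs_emotion_nps_pct"] = si(
            pain[pain_cond == "high"], emo_test[cond == "5"], "nps"
        )
        out["si_pain_high_low_nps_pct"] = si(
            pain[pain_cond == "high"], pain[pain_cond == "low"], "nps"
        )
    if "amygdala" in df.columns:
        out["si_emotion_5v1_amygdala_pct"] = si(
            emo_test[cond == "5"], emo_test[cond == "1"], "amygdala"
        )
    if "rating" in df.columns:
        pm = prediction_metrics(
            emo_test["pines"].to_numpy(), emo_test["rating"].to_numpy(),
            emo_test["subject"].to_numpy(),
        )
        out["mean_within_subject_r_test"] = pm["mean_r"]

    if trial_level is not None:
        tl = trial_level.copy()
        tl.columns = [c.lower() for c in tl.columns]
        from .expression import item_analysis

        ia = item_analysis(tl.rename(columns={"pines": "response"}))
        out["item_analysis_r"] = ia["r"]
        pm = prediction_metrics(
            tl["pines"].to_numpy(), tl["rating"].to_numpy(),
            tl["subject"].to_numpy(),
        )
        out["mean_trial_pines_r"] = pm["mean_r"]
    return out
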