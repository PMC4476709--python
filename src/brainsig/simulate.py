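"""Synthetic multi-subject beta-map datasets with known ground truth.

The generator emulates the statistical structure the signature pipeline
assumes: each subject contributes one condition-level beta map per ordinal
rating level, and the map is the rating times a subject-specific gain times
a spatially structured ground-truth pattern, plus spatially smoothed
Gaussian noise:

    beta(s, r) = r * (effect_size + delta_s) * truth + noise,
    delta_s ~ Normal(0, subject_sd),  noise = smooth(white) * noise_sd.

Smoothed noise is renormalized to unit voxel variance before scaling, so
``noise_sd`` is the marginal voxel SD regardless of the smoothing kernel
(smoothing uses wrap-around boundaries to keep the field stationary).

A second modality ("pain", levels low/medium/high) can be driven by a
dissociable truth pattern with disjoint support, giving a controlled
double-dissociation test bed.  Rating availability per subject mimics real
self-report: extreme levels are present for only a subset of subjects.

Default sample sizes mirror the study conditions the pipeline targets
(182 emotion subjects with 5 rating levels, 28 pain subjects with 3 levels,
30 trials per subject) on a scaled-down ellipsoidal brain grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import BetaImageSet, BrainMask, WeightMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_mask",
    "make_ground_truth_pattern",
    "simulate_dataset",
    "simulate_trials",
    "simulate_timeseries",
    "double_gamma_hrf",
    "emotion_config",
    "pain_config",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Fraction of subjects reporting each rating level 1..5 (training-sample
# usage rates of the 5-point scale; extremes are the rarest).
RATING_USE_PROB = {1: 0.98, 2: 0.88, 3: 0.98, 4: 0.88, 5: 0.80}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic beta-map dataset.

    effect_size is the mean signal amplitude per rating unit (activation
    units per rating); subject_sd the between-subject SD of that gain;
    noise_sd the marginal voxel noise SD; smooth_fwhm the noise smoothing
    kernel in voxel units.
    """

    grid_shape: tuple[int, int, int] = (18, 22, 18)
    n_subjects: int = 182
    levels: tuple = (1, 2, 3, 4, 5)
    effect_size: float = 1.0
    subject_sd: float = 0.2
    noise_sd: float = 1.0
    smooth_fwhm: float = 3.0
    n_true_regions: int = 6
    region_size: int = 60
    modality: str = "emotion"
    seed: int = 0

    def __post_init__(self):
        for name in ("effect_size", "subject_sd", "noise_sd", "smooth_fwhm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


def emotion_config(**overrides) -> SimulationConfig:
    """Study-sized emotion dataset: 182 subjects, ratings 1-5."""
    return replace(SimulationConfig(), **overrides)


def pain_config(**overrides) -> SimulationConfig:
    """Study-sized pain dataset: 28 subjects, levels low/medium/high."""
    base = SimulationConfig(
        n_subjects=28, levels=("low", "medium", "high"), modality="pain",
        n_true_regions=4,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Everything needed to regenerate / score a simulated dataset."""

    true_weights: WeightMap
    subject_gain: pd.Series  # per-subject amplitude multiplier (effect+delta)
    config: SimulationConfig


def default_mask(grid_shape=(18, 22, 18), affine_mm: float = 2.0) -> BrainMask:
    """Ellipsoidal 'brain' inclusion mask on an isotropic grid."""
    idx = np.indices(grid_shape, dtype=float)
    center = (np.array(grid_shape) - 1) / 2.0
    semi = np.array(grid_shape) / 2.0 - 0.5
    dist = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    affine = np.diag([affine_mm] * 3 + [1.0])
    return BrainMask(inclusion=dist <= 1.0, affine=affine)


def _smooth_unit_noise(rng, shape, fwhm):
    """Smoothed white noise rescaled to unit marginal variance."""
    white = rng.standard_normal(shape)
    if fwhm <= 0:
        return white
    sigma = fwhm * _FWHM_TO_SIGMA
    sm = gaussian_filter(white, sigma=sigma, mode="wrap")
    # wrap keeps the field stationary, so sum(kernel^2) is the exact
    # variance shrinkage at every voxel
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    k2 = float((gaussian_filter(impulse, sigma=sigma, mode="wrap") ** 2).sum())
    return sm / np.sqrt(k2)


def make_ground_truth_pattern(
    config: SimulationConfig,
    mask: BrainMask | None = None,
    avoid: WeightMap | None = None,
) -> WeightMap:
    """Sparse signed pattern of contiguous smoothed blobs.

    Each blob starts as a sphere of the requested size, is smoothed, and
    thresholded back to the requested voxel count, giving contiguous
    regions with soft edges.  Signs alternate across blobs.  ``avoid``
    excludes another pattern's support so two modalities can be driven by
    orthogonal truths.
    """
    if mask is None:
        mask = default_mask(config.grid_shape)
    rng = np.random.default_rng(config.seed)
    shape = mask.grid_shape
    vol = np.zeros(shape)
    if config.n_true_regions == 0:
        return WeightMap(mask.vectorize(vol), 0.0, mask, provenance="ground truth")

    radius = (3.0 * config.region_size / (4.0 * np.pi)) ** (1.0 / 3.0)
    margin = int(np.ceil(radius)) + 1
    if any(2 * margin >= s for s in shape):
        raise ValueError(
            f"regions of size {config.region_size} do not fit in grid {shape}"
        )
    forbidden = np.zeros(shape, dtype=bool)
    if avoid is not None:
        forbidden |= avoid.to_volume() != 0
    candidates = np.argwhere(mask.inclusion & ~forbidden)
    candidates = candidates[
        np.all((candidates >= margin) & (candidates < np.array(shape) - margin), axis=1)
    ]
    if len(candidates) == 0:
        raise ValueError("no admissible blob centers inside the mask")

    idx = np.indices(shape, dtype=float)
    taken = forbidden.copy()
    placed = 0
    for attempt in range(200 * config.n_true_regions):
        if placed == config.n_true_regions:
            break
        center = candidates[rng.integers(len(candidates))]
        dist2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        sphere = (dist2 <= radius**2).astype(float)
        blob = gaussian_filter(sphere, sigma=1.0)
        # keep exactly the requested number of strongest voxels
        flat = np.argsort(blob, axis=None)[::-1][: config.region_size]
        support = np.zeros(shape, dtype=bool)
        support[np.unravel_index(flat, shape)] = True
        if (support & taken).any() or (support & ~mask.inclusion).any():
            continue
        sign = 1.0 if placed % 2 == 0 else -1.0
        vol += sign * np.where(support, blob, 0.0)
        taken |= support
        placed += 1
    if placed < config.n_true_regions:
        raise ValueError(
            f"could only place {placed}/{config.n_true_regions} regions in grid"
        )
    vol /= np.abs(vol).max()
    return WeightMap(mask.vectorize(vol), 0.0, mask, provenance="ground truth")


def _subject_levels(rng, levels, modality):
    """Which condition levels a subject reports (extremes may be absent)."""
    if modality != "emotion" or len(levels) != 5:
        return list(levels)
    out = [lv for lv in levels if rng.random() < RATING_USE_PROB[int(lv)]]
    if len(out) < 2:  # degenerate subject: keep the middle of the scale
        out = [levels[0], levels[len(levels) // 2]]
    return out


def simulate_dataset(
    config: SimulationConfig,
    truth: WeightMap | None = None,
    mask: BrainMask | None = None,
) -> tuple[BetaImageSet, pd.DataFrame, GroundTruth]:
    """Generate rating-level beta maps for ``config.n_subjects`` subjects.

    Returns the image set, a rating table (subject, condition, rating), and
    the :class:`GroundTruth`.  Fully determined by ``config.seed``.
    """
    if mask is None:
        mask = default_mask(config.grid_shape) if truth is None else truth.mask
    if truth is None:
        truth = make_ground_truth_pattern(config, mask)
    rng = np.random.default_rng(config.seed + 1)
    truth_vec = truth.weights

    rows, subj, cond = [], [], []
    gains = {}
    numeric = {lv: BetaImageSet.PAIN_LEVELS.get(lv, None) or _num(lv) for lv in config.levels}
    for s in range(config.n_subjects):
        sid = f"{config.modality[:3]}{s:03d}"
        gains[sid] = config.effect_size + rng.normal(0.0, config.subject_sd)
        for lv in _subject_levels(rng, config.levels, config.modality):
            noise = _smooth_unit_noise(rng, mask.grid_shape, config.smooth_fwhm)
            vol = numeric[lv] * gains[sid] * truth.to_volume() + config.noise_sd * noise
            rows.append(mask.vectorize(vol))
            subj.append(sid)
            cond.append(lv)

    image_set = BetaImageSet(
        data=np.vstack(rows),
        subject_id=np.array(subj),
        condition_label=np.array(cond),
        mask=mask,
        modality=config.modality,
    )
    ratings = pd.DataFrame(
        {"subject": subj, "condition": cond, "rating": [numeric[c] for c in cond]}
    )
    gt = GroundTruth(truth, pd.Series(gains), config)
    return image_set, ratings, gt


def _num(level) -> float:
    return float(level)


def simulate_trials(
    config: SimulationConfig,
    truth: WeightMap,
    n_trials: int = 30,
    seed: int | None = None,
) -> tuple[BetaImageSet, pd.DataFrame]:
    """Trial-level maps: each subject sees ``n_trials`` items with fixed
    item intensities; trial rating = item intensity, map = rating-scaled
    truth + noise.  Items are shared across subjects (for item analyses)."""
    mask = truth.mask
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    lo, hi = float(min(_coerce(config.levels))), float(max(_coerce(config.levels)))
    item_intensity = np.round(np.linspace(lo, hi, n_trials), 3)
    rows, subj, cond, trial = [], [], [], []
    for s in range(config.n_subjects):
        sid = f"{config.modality[:3]}{s:03d}"
        gain = config.effect_size + rng.normal(0.0, config.subject_sd)
        for t in range(n_trials):
            r = item_intensity[t]
            noise = _smooth_unit_noise(rng, mask.grid_shape, config.smooth_fwhm)
            vol = r * gain * truth.to_volume() + config.noise_sd * noise
            rows.append(mask.vectorize(vol))
            subj.append(sid)
            cond.append(r)
            trial.append(t)
    image_set = BetaImageSet(
        data=np.vstack(rows),
        subject_id=np.array(subj),
        condition_label=np.array(cond),
        mask=mask,
        modality=config.modality,
        trial_id=np.array(trial),
    )
    ratings = pd.DataFrame(
        {"subject": subj, "trial": trial, "item": trial, "rating": cond}
    )
    return image_set, ratings


def _coerce(levels):
    return [BetaImageSet.PAIN_LEVELS.get(lv, None) or _num(lv) for lv in levels]


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot
    16 s, undershoot amplitude 1/6), normalized to unit maximum."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, peak, scale=1.0)
    neg = gamma_dist.pdf(t, undershoot, scale=1.0)
    h = pos - ratio * neg
    return h / h.max()


def simulate_timeseries(
    config: SimulationConfig,
    truth: WeightMap,
    events: pd.DataFrame,
    tr: float = 2.0,
    n_volumes: int = 150,
) -> tuple[np.ndarray, pd.DataFrame]:
    """4-D timeseries whose voxel signal is a rating-scaled truth pattern
    times a boxcar convolved with the canonical HRF, plus smoothed noise.

    ``events`` needs ``onset``, ``duration``, ``rating`` columns (seconds).
    Overlapping events add.  Returns (grid x time array, events).
    """
    required = {"onset", "duration", "rating"}
    if not required <= set(events.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    duration_s = n_volumes * tr
    if len(events) and (events["onset"] + events["duration"]).max() > duration_s:
        raise ValueError("events extend past the end of the scan")
    rng = np.random.default_rng(config.seed + 3)
    mask = truth.mask

    dt = 0.1  # oversampled regressor grid, seconds
    n_fine = int(np.ceil(duration_s / dt))
    stick = np.zeros(n_fine)
    for _, ev in events.iterrows():
        a = int(round(ev["onset"] / dt))
        b = int(round((ev["onset"] + ev["duration"]) / dt))
        stick[a:b] += float(ev["rating"])
    hrf = double_gamma_hrf(np.arange(0, 32, dt))
    reg = np.convolve(stick, hrf)[:n_fine]
    vol_times = np.arange(n_volumes) * tr
    reg_tr = np.interp(vol_times, np.arange(n_fine) * dt, reg)

    series = np.empty(mask.grid_shape + (n_volumes,))
    truth_vol = truth.to_volume()
    for t in range(n_volumes):
        noise = _smooth_unit_noise(rng, mask.grid_shape, config.smooth_fwhm)
        series[..., t] = reg_tr[t] * config.effect_size * truth_vol \
            + config.noise_sd * noise
    return series, events
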