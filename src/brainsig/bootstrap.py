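"""Bootstrap inference on voxel weights and map thresholding.

The training sample is resampled with replacement (subject-level by
default, so each resample keeps whole within-subject row blocks; row-level
optional) and the full LASSO-PCR fit is repeated per resample with the
penalty fixed at the full-data value.  The per-voxel bootstrap distribution
is summarized as z = mean / SD with a two-tailed p from the standard normal
reference; degenerate voxels (zero bootstrap SD) get z = 0, p = 1 when the
mean is also zero, and a near-zero p sentinel otherwise.

Thresholding keeps voxels passing an uncorrected p cutoff or
Benjamini-Hochberg FDR over in-mask voxels, then removes connected
components smaller than an extent minimum k (26-connectivity by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import BetaImageSet, WeightMap
from .training import _fit_core, fit_lasso_pcr

__all__ = [
    "BootstrapResult",
    "ThresholdedMap",
    "Region",
    "bootstrap_weights",
    "threshold_map",
    "extract_regions",
    "CONNECTIVITY",
]

P_SENTINEL = 1e-300  # degenerate: SD = 0 with nonzero mean

CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class BootstrapResult:
    mean: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_resamples: int
    unit: str
    degenerate: np.ndarray  # True where SD = 0 with nonzero mean
    samples: np.ndarray | None = None  # (B, n_voxels) when save_samples


@dataclass
class Region:
    voxel_index: np.ndarray  # indices into the mask's vector order
    size: int
    sign: float              # sign of the mean weight in the region
    peak_index: int          # voxel with the largest |weight|


@dataclass
class ThresholdedMap:
    """Signed weights retained at surviving voxels (zero elsewhere)."""

    weights: WeightMap
    survivors: np.ndarray    # boolean over mask voxels
    rule: str
    extent_k: int
    connectivity: int

    @property
    def n_voxels(self) -> int:
        return int(self.survivors.sum())


def bootstrap_weights(
    train: BetaImageSet,
    ratings: np.ndarray | None = None,
    n_resamples: int = 5000,
    unit: str = "subject",
    n_components: int | None = None,
    penalty="cv",
    seed: int = 0,
    save_samples: bool = False,
) -> BootstrapResult:
    """Bootstrap the LASSO-PCR voxel weights.

    Per-resample fits reuse the penalty selected on the full data, so the
    only stochasticity is the resampling itself.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if unit not in ("subject", "row"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    y = train.rating if ratings is None else np.asarray(ratings, dtype=float)

    full = fit_lasso_pcr(train, y, n_components, penalty, seed)
    alpha = full.penalty
    rng = np.random.default_rng(seed)
    n_vox = train.mask.n_voxels

    units = sorted(train.subjects) if unit == "subject" else np.arange(len(y))
    if len(units) < 2:
        raise ValueError("need at least 2 resampling units")
    row_blocks = (
        {u: np.nonzero(train.subject_id == u)[0] for u in units}
        if unit == "subject"
        else None
    )

    count = 0
    mean = np.zeros(n_vox)
    m2 = np.zeros(n_vox)
    saved = np.empty((n_resamples, n_vox)) if save_samples else None
    for b in range(n_resamples):
        draw = rng.choice(len(units), size=len(units), replace=True)
        if unit == "subject":
            rows = np.concatenate([row_blocks[units[i]] for i in draw])
        else:
            rows = draw
        if np.ptp(y[rows]) == 0:  # degenerate resample: refuse, redraw
            continue
        w, _, _ = _fit_core(train.data[rows], y[rows], n_components, alpha, seed)
        count += 1
        delta = w - mean
        mean += delta / count
        m2 += delta * (w - mean)
        if save_samples:
            saved[count - 1] = w
    if count < 2:
        raise RuntimeError("all bootstrap resamples were degenerate")
    sd = np.sqrt(m2 / (count - 1))
    z, p, degenerate = _zp_from_moments(mean, sd)
    return BootstrapResult(
        mean=mean, sd=sd, z=z, p=p, n_resamples=count, unit=unit,
        degenerate=degenerate,
        samples=saved[:count] if save_samples else None,
    )


def _zp_from_moments(mean, sd):
    """z = mean/SD with two-tailed normal p; degenerate-voxel handling."""
    n_vox = len(mean)
    z = np.zeros(n_vox)
    p = np.ones(n_vox)
    ok = sd > 0
    z[ok] = mean[ok] / sd[ok]
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    np.clip(p, P_SENTINEL, 1.0, out=p)
    degenerate = (~ok) & (mean != 0)
    p[degenerate] = P_SENTINEL
    z[degenerate] = np.inf
    return z, p, degenerate


def summarize_samples(samples: np.ndarray, unit: str = "row") -> BootstrapResult:
    """Summarize an explicit (B, n_voxels) bootstrap weight matrix into a
    :class:`BootstrapResult` (same z/p rules as :func:`bootstrap_weights`)."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a (B >= 2, n_voxels) sample matrix")
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    z, p, degenerate = _zp_from_moments(mean, sd)
    return BootstrapResult(
        mean=mean, sd=sd, z=z, p=p, n_resamples=samples.shape[0], unit=unit,
        degenerate=degenerate, samples=samples,
    )


def _parse_rule(rule: str) -> tuple[str, float]:
    kind, _, value = rule.partition(":")
    if kind not in ("p", "fdr") or not value:
        raise ValueError(
            f"unknown threshold rule {rule!r}; expected 'p:<alpha>' or 'fdr:<q>'"
        )
    return kind, float(value)


def threshold_map(
    result: BootstrapResult,
    weights: WeightMap,
    rule: str = "p:0.001",
    extent_k: int = 10,
    connectivity: int = 26,
) -> ThresholdedMap:
    """Apply a p-value rule plus a cluster-extent minimum to a weight map.

    ``rule`` is ``"p:<alpha>"`` (uncorrected) or ``"fdr:<q>"``
    (Benjamini-Hochberg over in-mask voxels).  Surviving voxels keep their
    original signed weights; connected components smaller than ``extent_k``
    voxels are removed.
    """
    if len(result.p) != weights.mask.n_voxels:
        raise ValueError("bootstrap result and weight map are on different masks")
    kind, value = _parse_rule(rule)
    if kind == "p":
        pass_p = result.p < value
    else:
        pass_p = multipletests(result.p, alpha=value, method="fdr_bh")[0]

    mask = weights.mask
    surv_vol = mask.devectorize(pass_p.astype(float)) > 0
    structure = CONNECTIVITY[connectivity]
    labels, n_lab = ndimage.label(surv_vol, structure=structure)
    if n_lab:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_lab + 1))
        small = np.isin(labels, np.nonzero(sizes < extent_k)[0] + 1)
        surv_vol &= ~small
    survivors = mask.vectorize(surv_vol)
    thresholded = WeightMap(
        np.where(survivors, weights.weights, 0.0),
        weights.intercept,
        mask,
        provenance=f"{weights.provenance} [{rule}, k={extent_k}]",
    )
    return ThresholdedMap(thresholded, survivors, rule, extent_k, connectivity)


def extract_regions(tmap: ThresholdedMap) -> list[Region]:
    """Contiguous surviving regions, ordered by size (desc) then by the
    lexicographically smallest voxel coordinate — a deterministic order."""
    mask = tmap.weights.mask
    surv_vol = mask.devectorize(tmap.survivors.astype(float)) > 0
    labels, n_lab = ndimage.label(surv_vol, structure=CONNECTIVITY[tmap.connectivity])
    if n_lab == 0:
        return []
    label_vec = mask.vectorize(labels)
    regions = []
    for lab in range(1, n_lab + 1):
        idx = np.nonzero(label_vec == lab)[0]
        w = tmap.weights.weights[idx]
        regions.append(
            Region(
                voxel_index=idx,
                size=len(idx),
                sign=float(np.sign(w.mean())) if w.size else 0.0,
                peak_index=int(idx[np.argmax(np.abs(w))]),
            )
        )
    coords = mask.voxel_coordinates()
    regions.sort(key=lambda r: (-r.size, tuple(coords[r.voxel_index].min(axis=0))))
    return regions
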