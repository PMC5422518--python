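"""Multi-threshold, edge-assisted tissue segmentation.

Hard tissues attenuate X-rays differently, so each tissue occupies its
own grayscale band.  Thresholds between bands are estimated by
multi-level Otsu (between-class-variance maximization) on the intensity
histogram; voxels with high gradient magnitude — partial-volume voxels
sitting on tissue interfaces — are excluded from the histogram first, so
the class means are estimated from interior voxels only (the
edge-assisted mean-grayscale estimate).

Class labels are assigned by threshold interval; optional morphological
cleanup removes speckle components and single-layer holes, a
deterministic stand-in for the manual correction an operator would do.
A voxel exactly equal to a cut point is assigned to the lower class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from mandifem.phantom import INTENSITY_ORDER, LabelVolume, VoxelVolume

#: class index (by increasing intensity) -> tissue code, for the default
#: eight-class phantom attenuation ordering.
DEFAULT_CLASS_MAP: Tuple[int, ...] = INTENSITY_ORDER


class DegenerateVolumeError(ValueError):
    """The volume has too little intensity structure to threshold."""


@dataclass(frozen=True)
class ThresholdSet:
    """k-1 strictly increasing grayscale cut points partitioning
    intensities into k classes, plus the class -> tissue-code mapping."""

    cuts: Tuple[float, ...]
    class_map: Tuple[int, ...]

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        if len(self.class_map) != len(cuts) + 1:
            raise ValueError(
                f"class_map must name {len(cuts) + 1} classes, got {len(self.class_map)}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.cuts) + 1


def gradient_magnitude(volume: VoxelVolume) -> np.ndarray:
    """Central-difference gradient magnitude in intensity units per mm."""
    grads = np.gradient(volume.values, *volume.spacing)
    return np.sqrt(sum(g * g for g in grads))


def multi_otsu(
    values: np.ndarray, k: int, nbins: int = 256, weighting: str = "raw"
) -> np.ndarray:
    """Exact multi-level Otsu thresholds by dynamic programming.

    Maximizing the between-class variance of a k-way histogram partition
    is equivalent to minimizing the within-class weighted sum of squares,
    which decomposes over contiguous bin runs; the optimum is found in
    O(k * nbins^2).  Returns k-1 increasing cut points (bin edges).
    Unlike the combinatorial search in common implementations, the cost
    is polynomial in both k and nbins, which matters at eight tissue
    classes.

    ``weighting="log"`` replaces raw bin counts by ``log1p(count)``.
    Tissue compartments differ in volume by orders of magnitude (pulp
    versus background), and count-weighted Otsu then prefers splitting
    the dominant mode over separating small ones; log weighting keeps
    every populated mode competitive while preserving valley positions.
    """
    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if weighting == "log":
        w = np.log1p(counts.astype(float))
    elif weighting == "raw":
        w = counts.astype(float)
    else:
        raise ValueError("weighting must be 'raw' or 'log'")
    # prefix sums for O(1) within-class SSE of any bin run [i, j)
    W = np.concatenate([[0.0], np.cumsum(w)])
    S = np.concatenate([[0.0], np.cumsum(w * centers)])
    Q = np.concatenate([[0.0], np.cumsum(w * centers**2)])
    i = np.arange(nbins + 1)
    Wij = W[None, :] - W[:, None]  # (i, j) lower-triangular invalid
    Sij = S[None, :] - S[:, None]
    Qij = Q[None, :] - Q[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = Qij - np.where(Wij > 0, Sij**2 / np.where(Wij > 0, Wij, 1.0), 0.0)
    sse[Wij <= 0] = 0.0
    sse = np.triu(sse)

    big = np.inf
    D = np.full((k + 1, nbins + 1), big)
    arg = np.zeros((k + 1, nbins + 1), np.int64)
    D[0, 0] = 0.0
    for c in range(1, k + 1):
        # D[c, j] = min_i D[c-1, i] + sse[i, j]
        tot = D[c - 1][:, None] + sse  # (i, j)
        arg[c] = np.nanargmin(np.where(np.isfinite(tot), tot, big), axis=0)
        D[c] = tot[arg[c], np.arange(nbins + 1)]
    cuts_bins = []
    j = nbins
    for c in range(k, 0, -1):
        j = int(arg[c, j])
        cuts_bins.append(j)
    cuts_bins = cuts_bins[::-1][1:]  # drop the leading 0
    cuts = edges[cuts_bins]
    if len(np.unique(cuts)) != k - 1:
        raise DegenerateVolumeError(
            "histogram has too few populated bins for the requested class count"
        )
    return np.asarray(cuts, float)


def _background_suppressed_otsu(sample: np.ndarray, k: int, nbins: int) -> np.ndarray:
    """Multi-level Otsu with explicit handling of a dominant dark mode.

    In micro-CT the air/background mode outweighs the smallest tissue
    compartments by orders of magnitude and sits next to them on the
    intensity axis, so any count-based partition criterion prefers
    splitting the background mode over isolating a faint neighbour.
    When the histogram's dominant mode lies in the dark fifth of the
    range, it is treated as background: its spread is estimated by a
    median-absolute-deviation fit to the dark flank, the first cut is
    placed at the mode plus two estimated standard deviations (a ~97.7%
    background quantile), and the remaining k-1 classes are partitioned
    above that cut by log-weighted between-class-variance maximization.
    Otherwise a single log-weighted k-class pass is used.
    """
    counts, edges = np.histogram(sample, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[np.argmax(counts)]
    rng_lo, rng_hi = sample.min(), sample.max()
    if mode > rng_lo + 0.2 * (rng_hi - rng_lo):
        return multi_otsu(sample, k=k, nbins=nbins, weighting="log")
    dark = sample[sample <= mode]
    sigma = 1.4826 * np.median(np.abs(dark - mode)) if len(dark) else 0.0
    bin_w = (rng_hi - rng_lo) / nbins
    cut0 = mode + max(2.0 * sigma, 0.5 * bin_w)
    upper = sample[sample > cut0]
    if len(np.unique(upper)) < k - 1:
        return multi_otsu(sample, k=k, nbins=nbins, weighting="log")
    rest = multi_otsu(upper, k=k - 1, nbins=nbins, weighting="log")
    return np.concatenate([[cut0], rest])


def estimate_thresholds(
    volume: VoxelVolume,
    k: int,
    class_map: Sequence[int] | None = None,
    edge_percentile: float = 90.0,
    nbins: int = 256,
) -> ThresholdSet:
    """Estimate a k-class ThresholdSet from the intensity histogram.

    Voxels whose gradient magnitude falls in the top
    ``100 - edge_percentile`` percent are treated as interface voxels and
    excluded before the between-class-variance maximization.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    values = volume.values
    if np.ptp(values) == 0:
        raise DegenerateVolumeError("constant volume cannot be thresholded")
    n_distinct = len(np.unique(values)) if values.size < 2**22 else nbins + 1
    if n_distinct < k:
        raise DegenerateVolumeError(
            f"volume has only {n_distinct} distinct intensities for k={k} classes"
        )
    if not 0 < edge_percentile <= 100:
        raise ValueError("edge_percentile must lie in (0, 100]")

    gmag = gradient_magnitude(volume)
    thresh = np.percentile(gmag, edge_percentile)
    if thresh <= 0 and (gmag > 0).any():
        # piecewise-constant volume: grade only among true interface voxels,
        # otherwise thin layers (one interface thick) vanish from the sample
        thresh = np.percentile(gmag[gmag > 0], edge_percentile)
    keep = gmag <= thresh
    sample = values[keep]
    if np.ptp(sample) == 0:  # pathological mask; fall back to all voxels
        sample = values.ravel()
    cuts = _background_suppressed_otsu(sample, k=k, nbins=nbins)

    if class_map is None:
        if k == len(DEFAULT_CLASS_MAP):
            class_map = DEFAULT_CLASS_MAP
        else:
            class_map = tuple(range(k))
    if len(set(class_map)) != k:
        raise ValueError("class_map must cover all k classes")
    return ThresholdSet(tuple(float(c) for c in cuts), tuple(int(c) for c in class_map))


def _classify(values: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    cuts = np.asarray(thresholds.cuts, float)
    # side='left': a value exactly equal to a cut point joins the lower class
    cls = np.searchsorted(cuts, values, side="left")
    lut = np.asarray(thresholds.class_map, dtype=np.uint8)
    return lut[cls]


_STRUCT26 = np.ones((3, 3, 3), bool)
_OFFSETS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _cleanup(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Deterministic morphological cleanup.

    Voxels belonging to connected components smaller than ``min_size``
    (26-connectivity) and single-layer internal holes are reassigned to
    the majority class among their 26-neighbours, counting only
    non-suspect neighbours and their pre-cleanup labels.  A voxel is
    therefore never moved to a class absent from its original
    neighbourhood; suspects with no trustworthy neighbour keep their
    label (deep cavities are filled one layer only).
    """
    pre = labels
    suspect = np.zeros(pre.shape, bool)
    for code in np.unique(pre):
        mask = pre == code
        comp, n = ndimage.label(mask, structure=_STRUCT26)
        if n:
            sizes = np.bincount(comp.ravel())
            small = sizes < min_size
            small[0] = False
            suspect |= small[comp]
        # fill only *small* enclosed cavities: large enclosed regions are
        # legitimate anatomy (pulp inside dentin, tissues inside the shell)
        holes = ndimage.binary_fill_holes(mask) & ~mask
        if holes.any():
            hcomp, hn = ndimage.label(holes, structure=_STRUCT26)
            hsizes = np.bincount(hcomp.ravel())
            hsmall = hsizes < min_size
            hsmall[0] = False
            suspect |= hsmall[hcomp]

    coords = np.argwhere(suspect)
    if len(coords) == 0:
        return pre.copy()
    shape = np.array(pre.shape)
    n_codes = int(pre.max()) + 1
    votes = np.zeros((len(coords), n_codes), np.int32)
    valid_any = np.zeros(len(coords), bool)
    for off in _OFFSETS26:
        nb = coords + off
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        idx = tuple(nb[ok].T)
        trusted = ~suspect[idx]
        rows = np.flatnonzero(ok)[trusted]
        votes[rows, pre[idx][trusted]] += 1
        valid_any[rows] = True

    out = pre.copy()
    # argmax breaks ties toward the lowest code
    new = votes.argmax(axis=1).astype(pre.dtype)
    sel = tuple(coords[valid_any].T)
    out[sel] = new[valid_any]
    return out


def segment(
    volume: VoxelVolume,
    thresholds: ThresholdSet,
    cleanup: bool = True,
    min_component: int = 20,
) -> LabelVolume:
    """Assign per-voxel tissue classes by threshold interval, with
    optional morphological cleanup (see :func:`_cleanup`)."""
    labels = _classify(volume.values, thresholds)
    if cleanup:
        labels = _cleanup(labels, min_component)
    return LabelVolume(volume.origin, volume.spacing, labels)


def render_class_means(labels: LabelVolume, intensity_means) -> VoxelVolume:
    """Map a label volume back to grayscale at the class means (used for
    idempotence checks and visual comparison)."""
    lut = np.zeros(int(labels.labels.max()) + 1, float)
    for code, mean in intensity_means.items():
        if code <= labels.labels.max():
            lut[code] = mean
    return VoxelVolume(labels.origin, labels.spacing, lut[labels.labels])


def dice(a: np.ndarray, b: np.ndarray, code: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of one tissue class between two
    label grids (1.0 if the class is absent from both)."""
    ma, mb = a == code, b == code
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(ma, mb).sum() / denom


def dice_per_class(pred: LabelVolume, truth: LabelVolume) -> dict:
    codes = np.union1d(np.unique(pred.labels), np.unique(truth.labels))
    return {int(c): dice(pred.labels, truth.labels, int(c)) for c in codes}
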