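"""Fluorescence colocalization and recruitment-kinetics statistics.

Covers the light-microscopy side of tag validation: overlap fractions
between tag and target segmentations, punctum segmentation, per-grid
intensity normalization, nonparametric comparison of timepoint groups
against a baseline (Kruskal–Wallis followed by Dunn's test), and rank
correlation between expression level and targeting specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .errors import ConfigError, GeometryError, InputError, NormalizationError

__all__ = [
    "GroupComparison",
    "overlap_fractions",
    "segment_puncta",
    "puncta_on_target_fraction",
    "per_grid_normalize",
    "compare_to_baseline",
    "rank_correlation",
]


def overlap_fractions(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float | None, float | None]:
    """Pixel overlap fractions ``(|A∩B|/|A|, |A∩B|/|B|)``.

    An empty mask makes its own fraction undefined; that direction is
    returned as ``None`` (missing), never silently zero.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    return (inter / na if na else None, inter / nb if nb else None)


def segment_puncta(image: np.ndarray, threshold: float | None = None,
                   min_area: int = 4) -> np.ndarray:
    """Global-threshold segmentation of punctate labels.

    Otsu's threshold by default; connected components smaller than
    ``min_area`` pixels are removed. Deterministic.
    """
    img = np.asarray(image, dtype=float)
    if np.any(img < 0):
        raise InputError("image must be nonnegative")
    if np.ptp(img) == 0:
        raise InputError("constant image: no threshold separates foreground")
    thr = threshold_otsu(img) if threshold is None else threshold
    binary = img > thr
    labels = sk_label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def puncta_on_target_fraction(image: np.ndarray, target_mask: np.ndarray,
                              threshold: float | None = None,
                              min_area: int = 4) -> tuple[float, int, int]:
    """Fraction of segmented puncta whose centroid lies inside the target mask."""
    puncta = segment_puncta(image, threshold=threshold, min_area=min_area)
    labels, n = ndimage.label(puncta, structure=np.ones((3, 3), bool))
    if n == 0:
        raise InputError("no puncta segmented")
    centroids = ndimage.center_of_mass(puncta, labels, range(1, n + 1))
    tgt = np.asarray(target_mask, dtype=bool)
    on = sum(
        bool(tgt[int(round(cy)), int(round(cx))]) for cy, cx in centroids
    )
    return on / n, on, n


def per_grid_normalize(measurements: pd.DataFrame, intensity_col: str = "gem_intensity",
                       grid_col: str = "grid_id",
                       correction_factor: dict | float | None = None) -> pd.DataFrame:
    """Normalize per-cell intensities against the mean of cells on the same grid.

    An optional multiplicative ``correction_factor`` (scalar, or a mapping
    from a ``batch`` column value) is applied after normalization.
    """
    df = measurements.copy()
    means = df.groupby(grid_col)[intensity_col].transform("mean")
    if np.any(means == 0):
        raise NormalizationError("a grid has zero mean intensity")
    df["normalized_intensity"] = df[intensity_col] / means
    if correction_factor is not None:
        if np.isscalar(correction_factor):
            df["normalized_intensity"] *= correction_factor
        else:
            df["normalized_intensity"] *= df["batch"].map(correction_factor)
    return df


@dataclass
class GroupComparison:
    """Kruskal–Wallis H plus Dunn's comparisons against the baseline group."""

    h_statistic: float
    kw_pvalue: float
    baseline: object
    comparisons: pd.DataFrame  # group, n, mean_rank, z, p_unadjusted, p_adjusted
    group_ns: dict


def compare_to_baseline(groups: dict, baseline=None) -> GroupComparison:
    """Kruskal–Wallis test, then Dunn's test of each group against a baseline.

    Dunn z-statistics use pooled ranks with the standard tie correction; the
    two-sided p-values are Bonferroni-adjusted by the number of baseline
    comparisons (k − 1), capped at 1 — the baseline-only family, matching
    "compared to 0 min" usage. With all observations identical the test is
    degenerate: H = 0, all p = 1.
    """
    keys = list(groups.keys())
    if len(keys) < 2:
        raise InputError("need at least two groups")
    samples = {k: np.asarray(groups[k], dtype=float).ravel() for k in keys}
    if any(len(v) < 2 for v in samples.values()):
        raise InputError("every group needs n >= 2")
    if baseline is None:
        baseline = keys[0]
    if baseline not in samples:
        raise InputError(f"baseline {baseline!r} not among groups")

    pooled = np.concatenate([samples[k] for k in keys])
    n_total = len(pooled)
    others = [k for k in keys if k != baseline]

    if np.ptp(pooled) == 0:
        comp = pd.DataFrame(
            {"group": others, "n": [len(samples[k]) for k in others],
             "mean_rank": (n_total + 1) / 2, "z": 0.0,
             "p_unadjusted": 1.0, "p_adjusted": 1.0}
        )
        return GroupComparison(0.0, 1.0, baseline, comp,
                               {k: len(v) for k, v in samples.items()})

    h_stat, kw_p = stats.kruskal(*[samples[k] for k in keys])

    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(samples[k]) for k in keys])
    mean_ranks = {
        k: ranks[bounds[i]:bounds[i + 1]].mean() for i, k in enumerate(keys)
    }
    # tie correction: sum over tied groups of (t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    n_comp = len(others)
    rows = []
    for k in others:
        se = np.sqrt(base_var * (1.0 / len(samples[k]) + 1.0 / len(samples[baseline])))
        z = (mean_ranks[k] - mean_ranks[baseline]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {"group": k, "n": len(samples[k]), "mean_rank": mean_ranks[k], "z": z,
             "p_unadjusted": p, "p_adjusted": min(1.0, p * n_comp)}
        )
    return GroupComparison(float(h_stat), float(kw_p), baseline, pd.DataFrame(rows),
                           {k: len(v) for k, v in samples.items()})


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman rank correlation (default) or Pearson, with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be paired 1D vectors")
    if len(x) < 3:
        raise InputError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ConfigError(f"unknown correlation method {method!r}")
    return float(rho), float(p)
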