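"""Quantitative image-quality metrics for difference SPECT.

All metrics are computed over volumes of interest (VOIs): spherical tumor
masks and an eroded healthy-liver background mask.

- ARC, the activity recovery coefficient: mean reconstructed activity in a
  VOI over its true mean, in percent.  100% is ideal.
- Noise: sample standard deviation over the background divided by the
  background mean (normalized, unitless).
- Contrast: (tumor mean - background mean) / background mean.
- CNR: contrast / noise (the Rose criterion places reliable detectability
  at CNR above about 5).
- T/N ratio: tumor mean over background mean.

The optimal iteration of an OSEM reconstruction is defined as the first
iteration at which the ARC of every VOI changes by less than 1 percentage
point from the previous iteration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "arc",
    "noise",
    "contrast_cnr",
    "tn_ratio",
    "optimal_iteration",
    "paired_test",
    "true_voi_means",
    "trace_metrics",
    "StabilizationWarning",
    "DegenerateTestWarning",
]


class StabilizationWarning(UserWarning):
    """ARC curves never stabilized within the available iterations."""


class DegenerateTestWarning(UserWarning):
    """Paired differences have zero variance; the t statistic is undefined."""


def _mean(img: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("mask is empty")
    return float(img[mask].mean())


def arc(img: np.ndarray, mask: np.ndarray, true_mean: float) -> float:
    """Activity recovery coefficient in percent: 100 * mean(img|mask) / true_mean.

    For a VOI whose difference uptake equals the background (a depleted
    tumor), ``true_mean`` is its — nonzero — true mean in the difference
    volume, not zero.
    """
    if true_mean <= 0:
        raise ValueError("true_mean must be positive")
    return 100.0 * _mean(img, mask) / true_mean


def noise(img: np.ndarray, bg_mask: np.ndarray) -> float:
    """Normalized background standard deviation (N-1 denominator)."""
    vals = img[bg_mask]
    if vals.size < 2:
        raise ValueError("background mask needs at least two voxels")
    m = vals.mean()
    if m == 0:
        raise ValueError("background mean is zero; noise is undefined")
    return float(vals.std(ddof=1) / abs(m))


def contrast_cnr(
    img: np.ndarray, tumor_mask: np.ndarray, bg_mask: np.ndarray
) -> tuple[float, float]:
    """Tumor contrast against the background, and contrast over noise."""
    bg_mean = _mean(img, bg_mask)
    if bg_mean == 0:
        raise ValueError("background mean is zero; contrast is undefined")
    contrast = (_mean(img, tumor_mask) - bg_mean) / bg_mean
    n = noise(img, bg_mask)
    if n == 0:
        if contrast == 0:
            return 0.0, 0.0
        raise ValueError("noise is zero; CNR is undefined for noiseless input")
    return float(contrast), float(contrast / n)


def tn_ratio(img: np.ndarray, tumor_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Tumor-to-nontumor ratio of mean activities."""
    bg_mean = _mean(img, bg_mask)
    if bg_mean == 0:
        raise ValueError("background mean is zero; T/N is undefined")
    return float(_mean(img, tumor_mask) / bg_mean)


def optimal_iteration(arc_curves: np.ndarray | pd.DataFrame, threshold: float = 1.0) -> int:
    """First iteration at which every VOI's ARC has stabilized.

    Parameters
    ----------
    arc_curves : array-like, shape (n_iterations, n_vois)
        Per-iteration ARC values (percent) for each VOI, iteration 1 first.
    threshold : float
        Stabilization threshold in ARC percentage points; the absolute
        change from the previous iteration must fall below it for every
        VOI simultaneously.

    Returns
    -------
    int
        1-based iteration index.  If the curves never stabilize the last
        available iteration is returned and a :class:`StabilizationWarning`
        is emitted.
    """
    curves = np.atleast_2d(np.asarray(arc_curves, dtype=np.float64))
    if curves.shape[0] < 2:
        raise ValueError("need ARC values for at least two iterations")
    deltas = np.abs(np.diff(curves, axis=0))  # deltas[k] = change at iteration k+2
    stable = (deltas < threshold).all(axis=1)
    hits = np.nonzero(stable)[0]
    if hits.size == 0:
        warnings.warn(
            "ARC did not stabilize within the available iterations",
            StabilizationWarning,
            stacklevel=2,
        )
        return curves.shape[0]
    return int(hits[0]) + 2


def paired_test(metric_a, metric_b) -> float:
    """Two-sided paired t-test over per-realization metric values.

    Degenerate cases: identical vectors give p = 1.0; a nonzero constant
    shift has an undefined t statistic and is reported as p = 0.0 with a
    :class:`DegenerateTestWarning`.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two paired realizations")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 1.0
        warnings.warn(
            "paired differences are a nonzero constant; t statistic undefined",
            DegenerateTestWarning,
            stacklevel=2,
        )
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# --------------------------------------------------------------------------
# trace evaluation helpers


def true_voi_means(true_diff, masks) -> dict[str, float]:
    """True mean activity per VOI from the ground-truth difference volume.

    Keys are ``tumor_1``, ``tumor_2``, ... and ``background``.  A depleted
    tumor (difference T/N of 1) gets its actual — background-level — true
    mean, keeping its ARC finite.
    """
    values = true_diff.values if hasattr(true_diff, "values") else np.asarray(true_diff)
    out = {}
    for i, m in enumerate(masks.tumor_masks):
        out[f"tumor_{i + 1}"] = float(values[m].mean())
    out["background"] = float(values[masks.background_mask].mean())
    return out


def volume_metrics(img: np.ndarray, masks, truths: dict[str, float]) -> list[dict]:
    """Metric rows for one volume: one row per VOI (wide format)."""
    bg = masks.background_mask
    bg_mean = float(img[bg].mean())
    rows = []
    nz = noise(img, bg) if bg_mean != 0 else np.nan
    for i, m in enumerate(masks.tumor_masks):
        name = f"tumor_{i + 1}"
        row = {"voi": name, "arc": arc(img, m, truths[name])}
        if bg_mean != 0:
            contrast = (float(img[m].mean()) - bg_mean) / bg_mean
            row["contrast"] = contrast
            row["cnr"] = contrast / nz if nz not in (0.0, np.nan) else np.nan
            row["tn_ratio"] = float(img[m].mean()) / bg_mean
        rows.append(row)
    rows.append(
        {"voi": "background", "arc": arc(img, bg, truths["background"]), "noise": nz}
    )
    return rows


def trace_metrics(trace, masks, truths: dict[str, float]) -> pd.DataFrame:
    """Per-iteration, per-VOI metrics of a reconstruction trace.

    Columns: iteration (1-based), voi, arc, noise, contrast, cnr, tn_ratio
    (NaN where a metric does not apply to the VOI).
    """
    rows = []
    for it, vol in enumerate(trace.volumes, start=1):
        for row in volume_metrics(vol, masks, truths):
            rows.append({"iteration": it, **row})
    df = pd.DataFrame(rows)
    for col in ("arc", "noise", "contrast", "cnr", "tn_ratio"):
        if col not in df:
            df[col] = np.nan
    return df[["iteration", "voi", "arc", "noise", "contrast", "cnr", "tn_ratio"]]
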