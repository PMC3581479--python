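"""Shared statistical inference utilities.

One- and two-sample t-tests with Cohen's d, Benjamini-Hochberg FDR
adjustment, Monte-Carlo cluster-extent thresholds for smoothed statistic
maps, effect-size conversions between t and d, and group-mean imputation
of missing physiological covariates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps


@dataclass
class TestResult:
    """Result of a t-test with effect size.

    Attributes
    ----------
    statistic : float
        t statistic.
    df : float
        Degrees of freedom.
    p : float
        Two-sided p-value.
    d : float
        Cohen's d (mean difference over pooled SD).
    q : float or None
        FDR-adjusted p-value, set when tests are batch-adjusted.
    """

    statistic: float
    df: float
    p: float
    d: float
    q: float | None = None


def t_tests(a, b=None) -> TestResult:
    """One-sample (vs 0) or pooled-variance two-sample t-test.

    Parameters
    ----------
    a, b : array-like
        Samples. With ``b`` absent a one-sample test against zero is run.

    Returns
    -------
    TestResult
        t, df, two-sided p and Cohen's d (pooled SD for two samples).
    """
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if b is None:
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance sample")
        n = a.size
        t = a.mean() / (sd / math.sqrt(n))
        df = n - 1
        d = a.mean() / sd
    else:
        b = np.asarray(b, dtype=float)
        if b.size < 2:
            raise ValueError("need at least 2 observations per sample")
        n1, n2 = a.size, b.size
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        d = (a.mean() - b.mean()) / math.sqrt(sp2)
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), d=float(d))


def d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d from a two-sample t statistic: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    return float(t) * math.sqrt(1.0 / n1 + 1.0 / n2)


def d_from_t_df(t: float, df: float) -> float:
    """Cohen's d from t and degrees of freedom: d = 2 t / sqrt(df).

    Convention used for pairwise functional-connectivity comparisons where
    only the t statistic and its df are reported.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    return 2.0 * float(t) / math.sqrt(df)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Empty input returns an empty array; q is monotone in the rank of p and
    never smaller than p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce step-up monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cluster_mc_threshold(
    grid_shape,
    voxel_size,
    fwhm: float,
    voxel_p: float,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int | None = None,
):
    """Monte-Carlo minimum cluster extent controlling family-wise error.

    Gaussian white-noise volumes are smoothed to the stated FWHM,
    re-standardized, thresholded at the one-sided ``voxel_p`` quantile, and
    the maximum suprathreshold cluster size is recorded per iteration. The
    returned threshold is the (1 - alpha) quantile of that null maximum.

    Parameters
    ----------
    grid_shape : tuple of int
        Volume dimensions in voxels.
    voxel_size : float or sequence of float
        Voxel edge length(s) in mm.
    fwhm : float
        Smoothing kernel full width at half maximum in mm (0 disables).
    voxel_p : float
        Per-voxel one-sided threshold probability.
    alpha : float
        Cluster-level family-wise error rate.
    n_iter : int
        Number of simulated noise volumes (>= 100).
    seed : int, optional
        Reproducibility seed.

    Returns
    -------
    dict
        ``{"voxels": int, "mm3": float, "max_sizes": ndarray}`` — the
        minimum significant cluster size in voxels and mm^3, and the null
        distribution of maximum cluster sizes.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    grid_shape = tuple(int(s) for s in grid_shape)
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (len(grid_shape),))
    voxel_vol = float(np.prod(vs))
    sigma_vox = (fwhm / 2.3548) / vs  # FWHM = sigma * 2 sqrt(2 ln 2)
    zthr = sps.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)
    structure = ndimage.generate_binary_structure(len(grid_shape), 1)
    max_sizes = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        vol = rng.standard_normal(grid_shape)
        if fwhm > 0:
            vol = ndimage.gaussian_filter(vol, sigma_vox)
            vol = (vol - vol.mean()) / vol.std()
        mask = vol > zthr
        if not mask.any():
            max_sizes[i] = 0
            continue
        labels, n_lab = ndimage.label(mask, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        max_sizes[i] = sizes.max()
    thr_vox = int(np.quantile(max_sizes, 1 - alpha, method="higher"))
    return {"voxels": thr_vox, "mm3": thr_vox * voxel_vol, "max_sizes": max_sizes}


def impute_group_mean(covariate_table: pd.DataFrame, group_labels) -> pd.DataFrame:
    """Replace missing covariate values by their within-group means.

    Observed entries are untouched; a group with a fully-missing covariate
    is an error because no mean exists to impute from.
    """
    table = covariate_table.copy()
    groups = pd.Series(np.asarray(group_labels), index=table.index)
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        for g, idx in table.groupby(groups).groups.items():
            vals = table.loc[idx, col]
            if vals.isna().all():
                raise ValueError(
                    f"group {g!r} has no observed values for covariate {col!r}"
                )
            table.loc[idx, col] = vals.fillna(vals.mean())
    return table
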