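"""Cohort-level statistics: paired hemisphere comparisons, FDR-corrected
clinical correlations, and cross-algorithm agreement.

Paired hemisphere contrasts report both the paired t-test and the Wilcoxon
signed-rank test (two-sided).  Clinical correlations are Spearman rank
coefficients with Benjamini-Hochberg adjustment across an explicitly
declared family of (feature, variable) pairs; cross-algorithm agreement is
Pearson.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import HemisphericPair, ValidationError

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "paired_compare",
    "spearman_fdr",
    "cross_algorithm_agreement",
    "hemispheric_difference_table",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedTestResult:
    statistic_t: float
    df: int
    p_t: float
    statistic_wilcoxon: float
    p_wilcoxon: float
    mean_ipsi: float
    sd_ipsi: float
    mean_contra: float
    sd_contra: float
    n: int


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    rho: float
    n: int
    p_raw: float
    p_fdr: float
    method: str  # spearman | pearson


def paired_compare(values_ipsi, values_contra) -> PairedTestResult:
    """Two-sided paired t and Wilcoxon signed-rank on aligned subject vectors.

    Wilcoxon drops zero differences and uses the exact null distribution for
    n <= 25 untied nonzero differences, otherwise the normal approximation
    with tie and continuity correction.  All-zero differences leave the
    Wilcoxon undefined (NaN) and report t = 0, p = 1; zero-variance nonzero
    shifts are flagged with an infinite t and p -> 0.
    """
    ipsi = np.asarray(values_ipsi, dtype=float)
    contra = np.asarray(values_contra, dtype=float)
    if ipsi.shape != contra.shape or ipsi.ndim != 1:
        raise ValidationError("ipsi/contra vectors must be aligned 1-d arrays")
    n = len(ipsi)
    if n < 3:
        raise ValidationError(f"need n >= 3 paired observations, got {n}")
    diff = contra - ipsi
    desc = dict(
        mean_ipsi=float(ipsi.mean()),
        sd_ipsi=float(ipsi.std(ddof=1)),
        mean_contra=float(contra.mean()),
        sd_contra=float(contra.std(ddof=1)),
        n=n,
    )
    if np.all(diff == 0):
        return PairedTestResult(0.0, n - 1, 1.0, float("nan"), float("nan"), **desc)
    if diff.std(ddof=1) == 0:  # constant nonzero shift: degenerate t
        t_stat = math.inf if diff[0] > 0 else -math.inf
        w_stat, w_p = _wilcoxon(diff)
        return PairedTestResult(t_stat, n - 1, 0.0, w_stat, w_p, **desc)
    t_res = sps.ttest_rel(contra, ipsi)
    w_stat, w_p = _wilcoxon(diff)
    return PairedTestResult(
        float(t_res.statistic), n - 1, float(t_res.pvalue), w_stat, w_p, **desc
    )


def _wilcoxon(diff: np.ndarray) -> tuple[float, float]:
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        return float("nan"), float("nan")
    if len(nonzero) <= 25:
        res = sps.wilcoxon(diff, zero_method="wilcox", method="exact")
    else:
        res = sps.wilcoxon(diff, zero_method="wilcox", method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def _spearman_permutation_p(xs: np.ndarray, ys: np.ndarray, rho: float,
                            n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p for Spearman rho with mid-rank ties.

    Exact exchangeability-based inference; unlike the n-2 df t
    approximation it stays valid in the far tail for heavily tied ordinal
    scales (muscle grades, tumor grades), which is what the
    family-wise-controlled FDR families here require.
    """
    rx = sps.rankdata(xs) - (len(xs) + 1) / 2.0
    ry = sps.rankdata(ys) - (len(ys) + 1) / 2.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 1.0
    perms = rng.permuted(np.tile(rx, (n_perm, 1)), axis=1)
    rho_null = perms @ ry / denom
    exceed = int(np.sum(np.abs(rho_null) >= abs(rho) - 1e-12))
    return (1.0 + exceed) / (n_perm + 1.0)


def spearman_fdr(
    feature_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    family: list[tuple[str, str]],
    p_method: str = "permutation",
    n_perm: int = 999,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Spearman correlations with BH adjustment across the declared family.

    Both tables are subject-aligned (same row order).  Missing values are
    pairwise-dropped; pairs with fewer than 4 complete observations or a
    constant vector are excluded from the family with a warning, shrinking
    it accordingly.  Results are sorted by adjusted p.

    ``p_method`` is "permutation" (default: seeded two-sided permutation p,
    valid under heavy ties) or "t" (the classical n-2 df approximation).
    """
    if p_method not in ("permutation", "t"):
        raise ValidationError(f"unknown p_method {p_method!r}")
    if len(feature_table) != len(clinical_table):
        raise ValidationError("feature and clinical tables are not subject-aligned")
    rng = np.random.default_rng(seed)
    kept: list[tuple[str, str, float, float, int]] = []
    for feat, var in family:
        x = feature_table[feat].to_numpy(dtype=float)
        y = clinical_table[var].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 4:
            logger.warning("dropping (%s, %s): fewer than 4 complete pairs", feat, var)
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            logger.warning("dropping (%s, %s): constant vector", feat, var)
            continue
        rho, p = sps.spearmanr(xs, ys)
        if p_method == "permutation":
            p = _spearman_permutation_p(xs, ys, float(rho), n_perm, rng)
        kept.append((feat, var, float(rho), float(p), int(ok.sum())))
    if not kept:
        return []
    p_raw = [k[3] for k in kept]
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    results = [
        CorrelationResult(feat, var, rho, n, p, float(q), "spearman")
        for (feat, var, rho, p, n), q in zip(kept, p_adj)
    ]
    results.sort(key=lambda r: (r.p_fdr, r.p_raw, r.variable_x, r.variable_y))
    return results


def cross_algorithm_agreement(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    group_columns: list[str] | None = None,
) -> list[CorrelationResult]:
    """Pearson agreement between two algorithms' metric tables.

    Tables are row-aligned (e.g. one row per subject x hemisphere; pooling
    hemispheres doubles n as in rs(72) reporting).  With ``group_columns``,
    correlations are computed within each group of those columns.  Constant
    columns are reported with NaN.
    """
    if metrics_a.shape[0] != metrics_b.shape[0]:
        raise ValidationError("metric tables are not aligned")
    group_columns = group_columns or []
    numeric = [
        c
        for c in metrics_a.columns
        if c not in group_columns and np.issubdtype(metrics_a[c].dtype, np.number)
    ]
    if group_columns:
        groups = list(metrics_a.groupby(group_columns, sort=True).groups.items())
    else:
        groups = [((), metrics_a.index)]
    results = []
    for key, idx in groups:
        tag = "" if key == () else f"[{key if isinstance(key, str) else '/'.join(map(str, np.atleast_1d(key)))}] "
        for col in numeric:
            x = metrics_a.loc[idx, col].to_numpy(dtype=float)
            y = metrics_b.loc[idx, col].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            xs, ys = x[ok], y[ok]
            if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
                results.append(
                    CorrelationResult(f"{tag}{col}", col, float("nan"), int(len(xs)), float("nan"), float("nan"), "pearson")
                )
                continue
            r, p = sps.pearsonr(xs, ys)
            results.append(
                CorrelationResult(f"{tag}{col}", col, float(r), int(len(xs)), float(p), float(p), "pearson")
            )
    return results


def hemispheric_difference_table(
    pairs: list[HemisphericPair],
    metric_rows_ipsi: list[dict[str, float]] | None = None,
    metric_rows_contra: list[dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Subjects x features table of (contra - ipsi) values.

    Features are the homolog-aligned edge weights (columns ``edge:a|b`` over
    the upper triangle) plus, when metric rows are supplied, each scalar
    topology metric.  Feeds :func:`spearman_fdr`.
    """
    if not pairs:
        raise ValidationError("no hemispheric pairs supplied")
    regions = pairs[0].region_labels
    n = len(regions)
    iu, ju = np.triu_indices(n, k=1)
    cols = [f"edge:{regions[i]}|{regions[j]}" for i, j in zip(iu, ju)]
    data = np.asarray([(p.contra.weights - p.ipsi.weights)[iu, ju] for p in pairs])
    frame = pd.DataFrame(data, columns=cols)
    if metric_rows_ipsi is not None or metric_rows_contra is not None:
        if metric_rows_ipsi is None or metric_rows_contra is None or len(
            metric_rows_ipsi
        ) != len(pairs) or len(metric_rows_contra) != len(pairs):
            raise ValidationError("metric rows misaligned with subjects")
        mi = pd.DataFrame(metric_rows_ipsi)
        mc = pd.DataFrame(metric_rows_contra)
        for col in mi.columns:
            frame[f"metric:{col}"] = mc[col].to_numpy() - mi[col].to_numpy()
    return frame
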