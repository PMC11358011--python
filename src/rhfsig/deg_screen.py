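"""Differential-expression screening for the banding models and human cohort.

Counts are normalized to reads per million (RPM).  Differential expression is
tested with a negative-binomial Wald test: median-of-ratios size factors,
per-gene method-of-moments dispersion shrunk 50/50 toward a fitted
``alpha(mu) = a0 + a1/mu`` trend, and a Wald z-statistic on the log2 ratio of
size-factor-adjusted group means.  The screen applies the three-part rodent
filter (two-fold change, disease-mean RPM above 50, p <= 0.01) and composes
ventricle-specific Venn partitions per banding model; a separate filter
implements the human contrast criteria (average count > 5, BH-adjusted
p < 0.05, |log2FC| > 0.585).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: floor applied to method-of-moments dispersion estimates
DISPERSION_FLOOR = 1e-4
#: pseudocount (RPM units) used when forming reported log2 fold changes
LFC_PSEUDOCOUNT = 0.5


# ------------------------------------------------------------- normalization

def normalize_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to reads per million.

    Parameters
    ----------
    counts
        Gene-by-sample matrix of non-negative integer counts.

    Returns
    -------
    DataFrame of the same shape whose columns each sum to 1e6.

    Raises
    ------
    ValueError
        If any sample has zero total counts (the sample is named).
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return counts / totals * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        # degenerate matrix: fall back to library-size factors
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.where(totals > 0, totals, 1.0))))
        return pd.Series(sf, index=counts.columns)
    logc = np.log(arr[positive])
    log_gm = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns)


# -------------------------------------------------------------- NB Wald test

def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha = a0 + a1/mu to binned trimmed means of per-gene estimates.

    Raw method-of-moments dispersions are extremely noisy at small replicate
    numbers with a heavy right tail; fitting the trend to 10%-trimmed means
    within mean-expression quantile bins keeps the fit from being dragged by
    outliers (an unbinned least-squares fit badly overestimates the
    intercept, which in turn makes the Wald test conservative).
    """
    ok = (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        return 0.05, 5.0
    mu_ok, al_ok = mu[ok], alpha_mom[ok]
    n_bins = min(20, max(2, ok.sum() // 50))
    order = np.argsort(mu_ok)
    bins = np.array_split(order, n_bins)
    x = np.array([1.0 / mu_ok[b].mean() for b in bins])
    y = np.array([stats.trim_mean(al_ok[b], 0.1) for b in bins])
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0 = float(max(coef[0], DISPERSION_FLOOR))
    a1 = float(max(coef[1], 0.0))
    return a0, a1


def nb_wald_test(counts: pd.DataFrame,
                 group_a: Sequence[str],
                 group_b: Sequence[str]) -> pd.DataFrame:
    """Negative-binomial Wald test of group A (disease) vs group B (control).

    Returns a table with one row per gene: ``log2fc`` (from mean RPM with a
    0.5 pseudocount), ``mean_rpm_disease``, ``mean_rpm_control``,
    ``mean_count`` (mean size-factor-normalized count over both groups),
    ``stat`` (signed Wald z), ``p_value`` and ``padj`` (Benjamini-Hochberg).
    All-zero genes get ``p_value = 1`` and ``log2fc = 0``.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in group_a + group_b if s not in counts.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")

    sub = counts[group_a + group_b]
    sf = size_factors(sub)
    norm = sub / sf

    qa = norm[group_a].to_numpy(dtype=float)
    qb = norm[group_b].to_numpy(dtype=float)
    na, nb = qa.shape[1], qb.shape[1]
    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    mu = (qa.sum(axis=1) + qb.sum(axis=1)) / (na + nb)

    # pooled within-group method-of-moments dispersion
    var_within = (qa.var(axis=1, ddof=1) * (na - 1)
                  + qb.var(axis=1, ddof=1) * (nb - 1)) / (na + nb - 2)
    mu_pos = np.where(mu > 0, mu, np.nan)
    alpha_mom = (var_within - mu_pos) / mu_pos**2
    a0, a1 = _fit_dispersion_trend(mu_pos, alpha_mom)
    alpha_trend = a0 + a1 / np.where(mu_pos > 0, mu_pos, 1.0)
    alpha = 0.5 * np.clip(np.nan_to_num(alpha_mom, nan=DISPERSION_FLOOR),
                          DISPERSION_FLOOR, None) + 0.5 * alpha_trend

    # Wald z on the log2 ratio of adjusted means (delta method under
    # Var(q) = mu + alpha mu^2 per sample)
    eps = 1e-8
    mu_a_s = np.maximum(mu_a, eps)
    mu_b_s = np.maximum(mu_b, eps)
    log2_ratio = np.log2(mu_a_s / mu_b_s)
    se = np.sqrt((1.0 / mu_a_s + alpha) / na
                 + (1.0 / mu_b_s + alpha) / nb) / np.log(2)
    z = log2_ratio / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    allzero = (mu_a == 0) & (mu_b == 0)
    z[allzero] = 0.0
    p[allzero] = 1.0

    rpm = normalize_rpm(sub)
    rpm_a = rpm[group_a].to_numpy().mean(axis=1)
    rpm_b = rpm[group_b].to_numpy().mean(axis=1)
    log2fc = np.log2((rpm_a + LFC_PSEUDOCOUNT) / (rpm_b + LFC_PSEUDOCOUNT))
    log2fc[allzero] = 0.0

    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_rpm_disease": rpm_a,
            "mean_rpm_control": rpm_b,
            "mean_count": mu,
            "stat": z,
            "p_value": p,
            "padj": padj,
        },
        index=counts.index,
    )


# -------------------------------------------------------------- filter rules

def apply_deg_filter(table: pd.DataFrame,
                     fc_threshold: float = 2.0,
                     min_mean_disease: float = 50.0,
                     alpha: float = 0.01,
                     adjusted: bool = False) -> set[str]:
    """Three-part rodent DEG filter.

    A gene passes iff |log2fc| >= log2(fc_threshold) (inclusive two-fold),
    mean disease RPM strictly above ``min_mean_disease``, and p <= ``alpha``
    (inclusive).  ``adjusted=True`` applies the criteria to BH-adjusted p.
    """
    if fc_threshold <= 0 or min_mean_disease < 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    p = table["padj"] if adjusted else table["p_value"]
    passing = (
        (table["log2fc"].abs() >= np.log2(fc_threshold))
        & (table["mean_rpm_disease"] > min_mean_disease)
        & (p <= alpha)
    )
    return set(table.index[passing])


def human_de_filter(table: pd.DataFrame,
                    min_avg_count: float = 5.0,
                    alpha_adj: float = 0.05,
                    lfc: float = 0.585) -> set[str]:
    """Human contrast filter: avg count > 5, adjusted p < 0.05, |log2fc| > 0.585.

    All three boundaries are strict, matching the stated criteria.
    """
    if "padj" not in table.columns:
        raise ValueError("table must carry BH-adjusted p-values in 'padj'")
    if table.empty:
        return set()
    passing = (
        (table["mean_count"] > min_avg_count)
        & (table["padj"] < alpha_adj)
        & (table["log2fc"].abs() > lfc)
    )
    return set(table.index[passing])


# ---------------------------------------------------------------- Venn logic

@dataclass
class BandingGeneSets:
    """Ventricle-specific DEG partition for one banding model.

    ``compensated_specific`` holds genes differentially expressed in the
    affected ventricle at the compensated stage but not in the contralateral
    ventricle; ``decompensated`` holds affected-ventricle DEGs at the failing
    stage; ``shared`` and ``union`` follow by set algebra.
    """

    model: str
    compensated_specific: set[str]
    decompensated: set[str]
    shared: set[str] = field(init=False)
    union: set[str] = field(init=False)

    def __post_init__(self):
        self.compensated_specific = set(self.compensated_specific)
        self.decompensated = set(self.decompensated)
        self.shared = self.compensated_specific & self.decompensated
        self.union = self.compensated_specific | self.decompensated

    def sizes(self) -> dict[str, int]:
        return {
            "compensated_specific": len(self.compensated_specific),
            "decompensated": len(self.decompensated),
            "shared": len(self.shared),
            "union": len(self.union),
        }


#: affected ventricle per banding model
AFFECTED_VENTRICLE = {"PAB": "RV", "AOB": "LV"}
CONTRALATERAL = {"RV": "LV", "LV": "RV"}


def ventricle_specific_sets(
        deg_by_condition: Mapping[tuple[str, str, str], set[str]],
        model: str) -> BandingGeneSets:
    """Compose the banding-model partition from per-condition DEG sets.

    ``deg_by_condition`` maps (model, state, ventricle) -> DEG set, with
    states "compensated" and "decompensated".  The compensated-specific set
    excludes genes that also reach full DEG status in the contralateral
    ventricle at the compensated stage; decompensated DEGs are taken from the
    affected ventricle without contralateral exclusion.
    """
    affected = AFFECTED_VENTRICLE[model]
    contra = CONTRALATERAL[affected]
    needed = [(model, "compensated", affected),
              (model, "compensated", contra),
              (model, "decompensated", affected)]
    for key in needed:
        if key not in deg_by_condition:
            raise KeyError(f"missing DEG set for condition {key}")
    comp_specific = (set(deg_by_condition[(model, "compensated", affected)])
                     - set(deg_by_condition[(model, "compensated", contra)]))
    decomp = set(deg_by_condition[(model, "decompensated", affected)])
    return BandingGeneSets(model=model,
                           compensated_specific=comp_specific,
                           decompensated=decomp)
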