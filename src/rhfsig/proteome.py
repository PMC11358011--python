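"""Proteome preprocessing, valid-value filtering, DEP calling and
mRNA-protein correlation.

Scaled protein abundances are log2 transformed and width normalized: each
sample column is centered on its median and scaled so its interquartile
range matches the median interquartile range across samples (a documented
location-scale proxy for the named desktop procedure; a raw passthrough is
available).  Proteins are retained when at least 75% of replicates in at
least one group carry valid (non-missing) values — six of eight at the
default group size.  Differentially expressed proteins are called by a
two-sided two-sample t-test at -log10 p >= 1.3 (inclusive), and global
mRNA-protein concordance is summarized by Pearson r, r^2, least-squares
slope and the F-test p for zero slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: -log10 p cutoff for DEP calling; p <= 10**-1.3 (~0.0501) is significant
DEP_NEG_LOG10_P = 1.3


def _group_columns(groups: Mapping[str, list[str]], columns) -> None:
    for name, cols in groups.items():
        if not cols:
            raise ValueError(f"empty replicate group {name!r}")
        missing = [c for c in cols if c not in columns]
        if missing:
            raise ValueError(f"group {name!r} references unknown samples {missing}")


def preprocess_proteome(m: pd.DataFrame, width_normalize: bool = True) -> pd.DataFrame:
    """log2 transform and width-normalize a protein-by-sample matrix.

    Missing values stay missing.  With a single sample (or
    ``width_normalize=False``) only the log2 transform is applied.
    """
    if (m <= 0).any().any():
        bad = m.columns[(m <= 0).any(axis=0)]
        raise ValueError(f"non-positive abundances in sample(s): {list(bad)}")
    logm = np.log2(m)
    if not width_normalize or m.shape[1] < 2:
        return logm
    med = logm.median(axis=0)
    iqr = logm.quantile(0.75, axis=0) - logm.quantile(0.25, axis=0)
    iqr = iqr.replace(0, 1.0)
    target = float(iqr.median())
    return (logm - med) / iqr * target


def filter_valid_values(m: pd.DataFrame, groups: Mapping[str, list[str]],
                        min_fraction: float = 0.75) -> pd.DataFrame:
    """Keep proteins with enough valid values in at least one group.

    A protein passes if some group has at least
    ``ceil(min_fraction * group_size)`` non-missing values (six of eight at
    the defaults).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    _group_columns(groups, m.columns)
    keep = pd.Series(False, index=m.index)
    for cols in groups.values():
        required = math.ceil(min_fraction * len(cols))
        keep |= m[cols].notna().sum(axis=1) >= required
    return m[keep]


def call_deps(m: pd.DataFrame, group_a: list[str], group_b: list[str],
              neg_log10_p: float = DEP_NEG_LOG10_P) -> dict:
    """Two-sample t-test DEP calling between two replicate groups.

    Proteins with fewer than 2 valid values in either group are skipped and
    reported.  Returns up/down protein sets (direction by mean difference,
    A relative to B) and the per-protein statistics table.
    """
    _group_columns({"a": group_a, "b": group_b}, m.columns)
    a = m[group_a].to_numpy(dtype=float)
    b = m[group_b].to_numpy(dtype=float)
    valid_a = (~np.isnan(a)).sum(axis=1)
    valid_b = (~np.isnan(b)).sum(axis=1)
    testable = (valid_a >= 2) & (valid_b >= 2)

    res = stats.ttest_ind(a[testable], b[testable], axis=1, nan_policy="omit")
    diff = np.nanmean(a[testable], axis=1) - np.nanmean(b[testable], axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero-variance ties: no evidence of change
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    p_cut = 10.0 ** (-neg_log10_p)
    sig = pvals <= p_cut

    idx = m.index[testable]
    table = pd.DataFrame({"mean_diff": diff, "p": pvals,
                          "neg_log10_p": -np.log10(np.maximum(pvals, 1e-300)),
                          "significant": sig}, index=idx)
    return {
        "up": set(idx[sig & (diff > 0)]),
        "down": set(idx[sig & (diff < 0)]),
        "table": table,
        "skipped": list(m.index[~testable]),
    }


@dataclass
class MrnaProteinCorrelation:
    r: float
    r2: float
    slope: float
    intercept: float
    p: float
    n: int
    highlighted: pd.DataFrame | None = None


def correlate_mrna_protein(mrna_changes: Mapping[str, float] | pd.Series,
                           protein_changes: Mapping[str, float] | pd.Series,
                           mapping: Mapping[str, str] | None = None,
                           highlight: set[str] | None = None) -> MrnaProteinCorrelation:
    """Pearson correlation of paired mRNA and protein log2 fold changes.

    ``mapping`` translates mRNA ids to protein ids (identity when omitted).
    The F-test p for zero overall slope of the least-squares fit equals the
    two-sided t-test p of simple linear regression.  A ``highlight`` subset
    (e.g. signature genes) is reported separately.
    """
    mrna = pd.Series(mrna_changes, dtype=float)
    prot = pd.Series(protein_changes, dtype=float)
    if mapping is not None:
        mrna = mrna.rename(index=dict(mapping))
    common = mrna.index.intersection(prot.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 mapped pairs, got {len(common)}")
    x = mrna.loc[common].to_numpy()
    y = prot.loc[common].to_numpy()
    fit = stats.linregress(x, y)
    highlighted = None
    if highlight is not None:
        sub = [g for g in common if g in highlight]
        highlighted = pd.DataFrame({"mrna_log2fc": mrna.loc[sub],
                                    "protein_log2fc": prot.loc[sub]})
    return MrnaProteinCorrelation(r=float(fit.rvalue), r2=float(fit.rvalue**2),
                                  slope=float(fit.slope),
                                  intercept=float(fit.intercept),
                                  p=float(fit.pvalue), n=len(common),
                                  highlighted=highlighted)
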