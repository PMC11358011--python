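"""Clinical risk stratification, severity ranking and rank-correlation screen.

Patients with chronic thromboembolic pulmonary hypertension are classified
into 1-year-mortality risk groups from three hemodynamic/biomarker
parameters (cardiac index, NT-proBNP, TAPSE/sPAP) with a 2-of-3 band rule,
ranked for disease severity by equally weighting per-parameter midranks
(higher composite rank = lower mortality risk), and genes are screened for
Pearson correlation of expression with the composite rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REQUIRED_PARAMS = ("CI", "NTproBNP", "TAPSE_sPAP")


@dataclass
class RiskThresholds:
    """Band cutoffs for 1-year mortality risk.

    Low risk (<5%): CI >= 2.0 L/min/m2 (inclusive), NT-proBNP < 300 ng/L,
    TAPSE/sPAP > 0.32 mm/mmHg.  High risk (>20%): CI < 2.0, NT-proBNP
    > 1,100, TAPSE/sPAP < 0.19.  Values between the bands are intermediate.
    """

    ci_low: float = 2.0
    ntprobnp_low: float = 300.0
    tapse_spap_low: float = 0.32
    ci_high: float = 2.0
    ntprobnp_high: float = 1100.0
    tapse_spap_high: float = 0.19


def _check_record(record) -> tuple[float, float, float]:
    vals = []
    for name in REQUIRED_PARAMS:
        v = record[name] if isinstance(record, (dict, pd.Series)) else getattr(record, name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing clinical parameter {name}")
        vals.append(float(v))
    return tuple(vals)


def classify_risk(record, thresholds: RiskThresholds | None = None) -> str:
    """Assign 'low', 'intermediate' or 'high' risk by the 2-of-3 band rule.

    A patient is low (or high) risk if at least two of the three parameters
    satisfy the corresponding band; otherwise intermediate.  All three
    parameters must be present; there is no imputation.
    """
    th = thresholds or RiskThresholds()
    ci, bnp, ts = _check_record(record)
    low_hits = (ci >= th.ci_low) + (bnp < th.ntprobnp_low) + (ts > th.tapse_spap_low)
    high_hits = (ci < th.ci_high) + (bnp > th.ntprobnp_high) + (ts < th.tapse_spap_high)
    if low_hits >= 2 and high_hits >= 2:
        # cannot happen with disjoint bands on 3 parameters, but guard anyway
        raise ValueError("ambiguous risk classification")
    if low_hits >= 2:
        return "low"
    if high_hits >= 2:
        return "high"
    return "intermediate"


@dataclass
class SeverityRanking:
    """Composite severity ranking; higher rank = lower mortality risk."""

    composite: pd.Series                    # patient -> final midrank
    per_parameter: pd.DataFrame = field(repr=False)

    @property
    def patients(self) -> list:
        return list(self.composite.index)


def severity_rank(table: pd.DataFrame) -> SeverityRanking:
    """Equal-weight severity ranking of a clinical table.

    Each parameter is midranked with the healthier direction receiving the
    higher rank (CI and TAPSE/sPAP ascending, NT-proBNP descending); the
    composite score is the unweighted mean of the three ranks and is itself
    midranked to give the final rank.  Being rank-based, the result is
    invariant under strictly monotone transforms of any raw parameter.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 patients to rank")
    for name in REQUIRED_PARAMS:
        if name not in table.columns:
            raise ValueError(f"missing clinical parameter column {name}")
        if table[name].isna().any():
            raise ValueError(f"missing values in clinical parameter {name}")
    ranks = pd.DataFrame(index=table.index)
    ranks["CI"] = stats.rankdata(table["CI"])
    ranks["TAPSE_sPAP"] = stats.rankdata(table["TAPSE_sPAP"])
    ranks["NTproBNP"] = stats.rankdata(-table["NTproBNP"].to_numpy())
    composite_score = ranks.mean(axis=1)
    final = pd.Series(stats.rankdata(composite_score), index=table.index,
                      name="esc_rank")
    return SeverityRanking(composite=final, per_parameter=ranks)


def correlation_screen(expr: pd.DataFrame, ranking: SeverityRanking,
                       r_threshold: float = 0.3, alpha: float = 0.01,
                       adjusted: bool = False) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with the composite rank.

    ``expr`` is gene-by-patient; its columns must match the ranked patients
    1:1.  Selection requires |r| strictly above ``r_threshold`` and a
    two-sided t-distribution p (n-2 df) at or below ``alpha``.  Constant
    genes have undefined r; they are flagged and never selected.  Negative r
    means higher expression with more severe disease (lower rank).
    """
    patients = ranking.patients
    if set(expr.columns) != set(patients) or len(expr.columns) != len(patients):
        raise ValueError("expression samples must match ranked patients 1:1")
    x = ranking.composite.reindex(expr.columns).to_numpy(dtype=float)
    n = len(x)
    y = expr.to_numpy(dtype=float)

    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    sx = np.sqrt((xc**2).sum())
    constant = sy == 0
    denom = np.where(constant, 1.0, sy * sx)
    r = (yc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    r[constant] = np.nan
    p[constant] = np.nan
    padj = np.full_like(p, np.nan)
    if (~constant).any():
        padj[~constant] = multipletests(p[~constant], method="fdr_bh")[1]
    crit_p = padj if adjusted else p
    selected = (~constant) & (np.abs(r) > r_threshold) & (crit_p <= alpha)
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "padj": padj,
            "selected": selected,
            "sign": np.sign(np.nan_to_num(r)).astype(int),
            "constant": constant,
        },
        index=expr.index,
    )


def postpea_compare(expr_pre: pd.DataFrame, expr_post: pd.DataFrame,
                    paired_ids: list[str] | None = None) -> pd.DataFrame:
    """Pre- vs post-intervention per-gene comparison.

    Unpaired: group means and two-sided Mann-Whitney rank-sum p per gene.
    Paired: per-patient deltas (post - pre) summarized for the paired subset.
    """
    if expr_pre.shape[1] < 3 or expr_post.shape[1] < 3:
        raise ValueError("need at least 3 samples per timepoint")
    genes = expr_pre.index.intersection(expr_post.index)
    pre = expr_pre.loc[genes].to_numpy(dtype=float)
    post = expr_post.loc[genes].to_numpy(dtype=float)
    res = stats.mannwhitneyu(pre, post, axis=1, alternative="two-sided",
                             method="asymptotic")
    # fully tied rows have zero rank variance; report the maximal p there
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame(
        {
            "mean_pre": pre.mean(axis=1),
            "mean_post": post.mean(axis=1),
            "mw_p": pvals,
        },
        index=genes,
    )
    if paired_ids is not None:
        missing = [p for p in paired_ids
                   if p not in expr_pre.columns or p not in expr_post.columns]
        if missing or not paired_ids:
            raise ValueError(f"paired ids absent from a timepoint: {missing}")
        delta = (expr_post.loc[genes, paired_ids].to_numpy()
                 - expr_pre.loc[genes, paired_ids].to_numpy())
        out["paired_mean_delta"] = delta.mean(axis=1)
        out["paired_n"] = len(paired_ids)
    return out
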