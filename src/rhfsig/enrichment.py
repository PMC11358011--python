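"""Over-representation analysis and permutation GSEA.

ORA tests a query gene set against every set of a collection with the
hypergeometric upper tail, after restricting sets to the universe and
excluding those outside the configured size bounds (defaults 5-2000); p
values are Benjamini-Hochberg adjusted across tested terms.  A second filter
reproduces the common term-collection rule (p < 0.01, overlap count >= 3,
enrichment factor > 1.5).

GSEA is the weighted Kolmogorov-Smirnov running-sum statistic: genes sorted
by decreasing statistic, hit increments proportional to |stat|^weight
(normalized), uniform miss decrements, enrichment score at the running-sum
extremum.  The null is gene-label permutation at fixed set size; NES divides
ES by the mean |null ES| of the matching sign and the permutation p is the
one-sided exceedance among same-sign null scores with the +1 correction
(the convention of the fgsea/clusterProfiler family, which keeps the test
calibrated at its nominal level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ----------------------------------------------------------------------- ORA

def ora(query: set[str], collection: Mapping[str, set[str]], universe: set[str],
        min_size: int = 5, max_size: int = 2000) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    Sets are intersected with the universe first; sets whose restricted size
    falls outside [min_size, max_size] are excluded from testing.  Returns a
    table with overlap counts, enrichment factor (observed/expected) and
    BH-adjusted p values, sorted by p.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_u = len(universe)
    n_q = len(query)
    rows = []
    for name, members in collection.items():
        in_universe = set(members) & universe
        size = len(in_universe)
        if size < min_size or size > max_size:
            continue
        k = len(query & in_universe)
        expected = n_q * size / n_u
        p = float(stats.hypergeom.sf(k - 1, n_u, size, n_q))
        rows.append({
            "term": name, "overlap": k, "set_size": size,
            "query_size": n_q, "universe_size": n_u,
            "enrichment_factor": (k / expected) if expected > 0 else 0.0,
            "p": min(p, 1.0),
        })
    if not rows:
        return pd.DataFrame(columns=["term", "overlap", "set_size", "query_size",
                                     "universe_size", "enrichment_factor",
                                     "p", "fdr"]).set_index("term")
    out = pd.DataFrame(rows).set_index("term")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set_size"], kind="stable")


def filter_terms_metascape(records: pd.DataFrame, alpha: float = 0.01,
                           min_count: int = 3, min_ef: float = 1.5) -> pd.DataFrame:
    """Term-collection rule: p < alpha, overlap >= min_count, EF > min_ef.

    The p and enrichment-factor cuts are strict, the count cut inclusive.
    """
    keep = (
        (records["p"] < alpha)
        & (records["overlap"] >= min_count)
        & (records["enrichment_factor"] > min_ef)
    )
    return records[keep]


def merge_best_p(*record_tables: pd.DataFrame) -> pd.DataFrame:
    """Merge several ORA runs, keeping the best (smallest) p per term."""
    merged = pd.concat(record_tables)
    return (merged.sort_values("p", kind="stable")
                  .groupby(level=0).head(1).sort_values("p", kind="stable"))


# ---------------------------------------------------------------------- GSEA

@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str]
    n_perm: int
    seed: int
    n_hits: int
    missing: list[str] = field(default_factory=list)


def _running_extremum(positions: np.ndarray, weights: np.ndarray,
                      n_total: int) -> tuple[float, int, bool]:
    """Signed extremum of the KS running sum given sorted hit positions.

    ``weights`` are the normalized hit increments aligned with ``positions``
    (0-based indices into the sorted gene list).  The extremum of the running
    sum is attained immediately after a hit (candidate maxima) or immediately
    before a hit (candidate minima), so only O(n_hits) points are evaluated.
    Returns (ES, index of extremal hit, is_max).
    """
    m = len(positions)
    miss = 1.0 / (n_total - m)
    cumw = np.cumsum(weights)
    i = np.arange(m)
    after = cumw - (positions + 1 - (i + 1)) * miss      # value just after hit i
    before = np.concatenate(([0.0], cumw[:-1])) - (positions - i) * miss
    hi_idx = int(np.argmax(after))
    lo_idx = int(np.argmin(before))
    hi, lo = after[hi_idx], before[lo_idx]
    if hi >= -lo:
        return float(hi), hi_idx, True
    return float(lo), lo_idx, False


def gsea(ranked_stats: pd.Series, gene_set: set[str], weight: float = 1.0,
         n_perm: int = 1000, seed: int = 0,
         set_name: str = "gene_set") -> GseaResult:
    """Weighted-KS gene set enrichment with a gene-label permutation null.

    ``ranked_stats`` maps gene id to a real-valued statistic (e.g. a Wald z);
    genes are sorted by decreasing statistic with ties broken by gene id so
    runs are reproducible.  Set members absent from the ranking are reported
    in ``missing``.  Requires at least 2 scored members and ``n_perm`` >= 100.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    order = ranked_stats.sort_index(kind="stable")
    order = order.sort_values(ascending=False, kind="stable")
    genes = order.index.to_numpy()
    statv = order.to_numpy(dtype=float)
    n = len(genes)

    members = set(gene_set)
    missing = sorted(members - set(genes))
    hit_mask = np.isin(genes, list(members & set(genes)))
    m = int(hit_mask.sum())
    if m < 2:
        raise ValueError("fewer than 2 set members present in the ranking")
    if m >= n:
        raise ValueError("gene set covers the whole ranking")

    wstat = np.abs(statv) ** weight

    def es_for(positions: np.ndarray) -> tuple[float, int, bool]:
        w = wstat[positions]
        total = w.sum()
        w = w / total if total > 0 else np.full(len(positions), 1.0 / len(positions))
        return _running_extremum(positions, w, n)

    hit_pos = np.flatnonzero(hit_mask)
    es, ext_idx, is_max = es_for(hit_pos)
    if is_max:
        leading = genes[hit_pos[: ext_idx + 1]].tolist()
    else:
        leading = genes[hit_pos[ext_idx:]].tolist()

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=m, replace=False))
        null_es[b], _, _ = es_for(pos)

    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if len(same_sign) == 0:
        same_sign = null_es
    nes = es / np.mean(np.abs(same_sign)) if np.mean(np.abs(same_sign)) > 0 else 0.0
    p_perm = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + len(same_sign))

    return GseaResult(set_name=set_name, es=float(es), nes=float(nes),
                      p_perm=float(p_perm), leading_edge=leading,
                      n_perm=n_perm, seed=seed, n_hits=m, missing=missing)


def gsea_collection(ranked_stats: pd.Series,
                    collection: Mapping[str, set[str]], weight: float = 1.0,
                    n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Run :func:`gsea` for every set of a collection; BH-adjust p across sets."""
    rows = []
    for i, (name, members) in enumerate(sorted(collection.items())):
        res = gsea(ranked_stats, members, weight=weight, n_perm=n_perm,
                   seed=seed + i, set_name=name)
        rows.append({"set": name, "es": res.es, "nes": res.nes,
                     "p_perm": res.p_perm, "n_hits": res.n_hits})
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    return out
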