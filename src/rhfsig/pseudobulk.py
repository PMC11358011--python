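"""Pseudo-bulk aggregation of cell-level counts and downstream ranking.

Cell-level counts are summed per (sample, cell type) to yield bulk-style
profiles that can be differentially tested with the NB Wald engine; lowly
expressed genes (mean raw pseudo-bulk count below 5 across the contrast
samples) are removed before ranking.  A dot-plot summary reports, per
(cell type, condition, gene), the fraction of expressing cells and the mean
normalized expression (counts per 10k, log1p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deg_screen import nb_wald_test, size_factors

META_COLUMNS = ("sample", "cell_type", "condition")


def _check_meta(cells: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"cell metadata lacks column {col!r}")
    missing = cells.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"cells without metadata: {list(missing[:5])}"
                         f"{'...' if len(missing) > 5 else ''}")
    return meta.loc[cells.index]


def aggregate_pseudobulk(cells: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Sum cell-by-gene counts into (sample, cell_type)-by-gene profiles.

    ``cells`` is cell-by-gene; ``meta`` is indexed by cell id with columns
    sample, cell_type, condition.  The output carries a MultiIndex
    (sample, cell_type) plus per-group cell counts in ``attrs['n_cells']``.
    """
    meta = _check_meta(cells, meta)
    grouped = cells.groupby([meta["sample"], meta["cell_type"]], observed=True).sum()
    grouped.index.names = ["sample", "cell_type"]
    n_cells = (meta.groupby(["sample", "cell_type"], observed=True)
                   .size().reindex(grouped.index))
    grouped.attrs["n_cells"] = n_cells.to_dict()
    return grouped


def pseudobulk_conditions(pb: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Condition label per pseudo-bulk sample, derived from cell metadata."""
    cond = (meta.groupby(["sample", "cell_type"], observed=True)["condition"]
                .agg(lambda s: s.iloc[0]))
    return cond.reindex(pb.index)


def basemean_filter(pb: pd.DataFrame, contrast_samples: list,
                    min_mean: float = 5.0, size_adjusted: bool = False) -> list[str]:
    """Genes retained after the base-mean cut.

    The base mean is the plain mean of raw pseudo-bulk counts across the
    contrast samples; genes with mean strictly below ``min_mean`` are
    removed (mean exactly 5 is retained).  ``size_adjusted=True`` averages
    size-factor-normalized counts instead.
    """
    sub = pb.loc[contrast_samples]
    if size_adjusted:
        sf = size_factors(sub.T)
        sub = sub.div(sf, axis=0)
    means = sub.mean(axis=0)
    return list(means.index[means >= min_mean])


def rank_for_gsea(pb: pd.DataFrame, samples_a: list, samples_b: list,
                  min_mean: float = 5.0) -> pd.Series:
    """Signed Wald z per retained gene for condition A vs condition B.

    Applies :func:`basemean_filter` over both sample groups, then the NB
    Wald test on the transposed (gene-by-pseudo-bulk-sample) matrix.
    """
    contrast = list(samples_a) + list(samples_b)
    keep = basemean_filter(pb, contrast, min_mean=min_mean)
    mat = pb.loc[contrast, keep].T
    mat.columns = [f"pb{i}" for i in range(len(contrast))]
    a_cols = mat.columns[: len(samples_a)]
    b_cols = mat.columns[len(samples_a):]
    table = nb_wald_test(mat.round().astype(int), list(a_cols), list(b_cols))
    return table["stat"].rename("wald_z")


def dotplot_stats(cells: pd.DataFrame, meta: pd.DataFrame,
                  genes: list[str], target: float = 1e4) -> pd.DataFrame:
    """Fraction of expressing cells and mean normalized expression per group.

    Per (cell_type, condition, gene): fraction of cells with count > 0 and
    the mean of log1p(count / cell_total * target) over all group cells.
    """
    unknown = [g for g in genes if g not in cells.columns]
    if unknown:
        raise ValueError(f"unknown gene(s): {unknown}")
    meta = _check_meta(cells, meta)
    totals = cells.sum(axis=1).to_numpy(dtype=float)
    totals = np.where(totals > 0, totals, 1.0)
    norm = np.log1p(cells[genes].to_numpy(dtype=float) / totals[:, None] * target)
    norm = pd.DataFrame(norm, index=cells.index, columns=genes)
    keys = [meta["cell_type"], meta["condition"]]
    frac = (cells[genes] > 0).groupby(keys, observed=True).mean()
    mean_expr = norm.groupby(keys, observed=True).mean()
    out = pd.concat({"fraction": frac, "mean_expr": mean_expr}, axis=1)
    out.index.names = ["cell_type", "condition"]
    return out
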