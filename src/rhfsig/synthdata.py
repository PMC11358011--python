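"""Synthetic cohorts, annotation resources, proteome and cell-level counts.

Every downstream stage of the pipeline is testable without any external
download: this module generates rat banding cohorts (negative-binomial
counts with planted group-by-ventricle expression templates), a human
pressure-overload cohort (clinical triplets monotone in a latent severity,
with genes planted to correlate with the severity rank), gene-set/ortholog/
edge annotation stand-ins, a proteome with missing-completely-at-random
values, and cell-level counts with cell-type- and condition-specific
programs.  Each simulator returns the ground truth of what was planted.

Counts follow the mean-dispersion NB parameterization Var = mu + alpha*mu^2
with dispersion trend alpha(mu) = a0 + a1/mu; library sizes are drawn
log-normally around their expectation (CV 0.2) so per-million normalization
is non-trivial.  One global seed fans out to per-simulator child seeds by
fixed offsets, keeping sub-simulations independently reproducible.

The study's deposited data give no distributional description beyond
platform counts; all distributional defaults here are documented stand-ins
(see docs/methods.md), while design constants (six animals per group and
ventricle, 71 patients, eight proteome replicates per group, gene universes
of 17,341 rat and 16,354 human genes) mirror the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RAT_GROUPS = ("Sham-H", "Sham-F", "PAB-H", "PAB-F", "AOB-H", "AOB-F")
VENTRICLES = ("RV", "LV")
GROUP_WEEKS = {"Sham-H": 14, "PAB-H": 14, "AOB-H": 14,
               "PAB-F": 29, "Sham-F": 33, "AOB-F": 33}

#: fixed child-seed offsets per simulator
SEED_OFFSETS = {"rat": 101, "human": 202, "annotation": 303,
                "proteome": 404, "singlecell": 505}


def child_seed(seed: int, simulator: str) -> int:
    return (int(seed) + SEED_OFFSETS[simulator]) % (2**31 - 1)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB draw; degenerates to Poisson as alpha -> 0."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha <= 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        a = alpha[~tiny]
        lam = rng.gamma(shape=1.0 / a, scale=mean[~tiny] * a)
        out[~tiny] = rng.poisson(lam)
    return out


# ------------------------------------------------------------ rat simulator

def default_rat_templates(n_per_template: int = 40,
                          log2fc: float = 2.0) -> list[tuple[dict, int]]:
    """Planted expression templates over (group, ventricle) cells.

    Four patterns echoing banding-model biology: an RV-specific
    pressure-overload program (induced in both PAB stages), a
    decompensation-only RV program, a downregulated RV program, and an
    LV-specific program under aortic banding.  Cells not named carry
    effect 0.
    """
    return [
        ({("PAB-H", "RV"): log2fc, ("PAB-F", "RV"): log2fc}, n_per_template),
        ({("PAB-F", "RV"): log2fc}, n_per_template),
        ({("PAB-H", "RV"): -log2fc, ("PAB-F", "RV"): -log2fc}, n_per_template),
        ({("AOB-H", "LV"): log2fc, ("AOB-F", "LV"): log2fc}, n_per_template),
    ]


@dataclass
class RatSimConfig:
    """Conditions of the rat banding cohort simulation.

    Defaults mirror the study design: six groups (sham/banded at
    compensated and decompensated stages for both models) times two
    ventricles, six animals per group, a 17,341-gene universe and 25e6
    expected reads per sample.
    """

    n_genes: int = 17341
    n_per_group: int = 6
    groups: tuple = RAT_GROUPS
    ventricles: tuple = VENTRICLES
    baseline_logmean_loc: float = 0.0
    baseline_logmean_scale: float = 1.8
    dispersion_a0: float = 0.05
    dispersion_a1: float = 5.0
    planted_clusters: list = field(default_factory=default_rat_templates)
    library_size: float = 25e6
    library_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.library_size <= 0:
            raise ValueError("n_genes and library_size must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        cells = {(g, v) for g in self.groups for v in self.ventricles}
        for template, count in self.planted_clusters:
            if count < 0:
                raise ValueError("negative planted gene count")
            unknown = set(template) - cells
            if unknown:
                raise ValueError(f"template names unknown cells: {unknown}")


def simulate_rat_cohort(config: RatSimConfig):
    """Simulate the rat cohort; returns (counts, sample sheet, truth table).

    Counts are NB draws around gene baselines scaled by 2**(template
    effect) and a log-normal library factor; the sample sheet has one row
    per (animal, ventricle); the truth table lists planted genes with their
    template id and log2 effect.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    weights = np.exp(rng.normal(config.baseline_logmean_loc,
                                config.baseline_logmean_scale, config.n_genes))
    weights /= weights.sum()

    n_planted = sum(c for _, c in config.planted_clusters)
    if n_planted > config.n_genes:
        raise ValueError("more planted genes than genes")
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)

    # per-gene log2 effect per (group, ventricle)
    effects: dict[tuple[str, str], np.ndarray] = {
        (g, v): np.zeros(config.n_genes)
        for g in config.groups for v in config.ventricles
    }
    truth_rows = []
    cursor = 0
    for tid, (template, count) in enumerate(config.planted_clusters):
        idx = planted_idx[cursor: cursor + count]
        cursor += count
        for cell, fc in template.items():
            effects[cell][idx] += fc
        peak = max(template.values(), key=abs) if template else 0.0
        for i in idx:
            truth_rows.append({"gene": genes[i], "role": "planted-DE",
                               "effect": float(peak), "cluster": tid})

    samples, sheet_rows, columns = [], [], []
    sexes = ["M", "F"]
    for group in config.groups:
        for vent in config.ventricles:
            eff = effects[(group, vent)]
            mu_rel = weights * np.exp2(eff)
            for a in range(config.n_per_group):
                sid = f"{group}_{vent}_{a}"
                lib = config.library_size * rng.lognormal(
                    -0.5 * np.log1p(config.library_cv**2),
                    np.sqrt(np.log1p(config.library_cv**2)))
                mu = mu_rel / mu_rel.sum() * lib
                alpha = config.dispersion_a0 + config.dispersion_a1 / np.maximum(mu, 1e-8)
                samples.append(_nb_draw(rng, mu, alpha))
                columns.append(sid)
                sheet_rows.append({"sample_id": sid, "species": "rat",
                                   "ventricle": vent, "group": group,
                                   "sex": sexes[a % 2],
                                   "timepoint": GROUP_WEEKS.get(group, 14)})

    counts = pd.DataFrame(np.column_stack(samples), index=genes, columns=columns)
    sheet = pd.DataFrame(sheet_rows)
    truth = _truth_frame(truth_rows, genes)
    return counts, sheet, truth


def _truth_frame(planted_rows: list[dict], genes: list[str]) -> pd.DataFrame:
    planted = {r["gene"]: r for r in planted_rows}
    rows = [planted.get(g, {"gene": g, "role": "null", "effect": 0.0,
                            "cluster": pd.NA}) for g in genes]
    truth = pd.DataFrame(rows, columns=["gene", "role", "effect", "cluster"])
    return truth.set_index("gene").sort_index()


# ---------------------------------------------------------- human simulator

@dataclass
class HumanSimConfig:
    """Conditions of the human pressure-overload cohort simulation.

    71 patients (the baseline cohort size) over a 16,354-gene expressed
    universe.  Clinical triplets are monotone in a latent severity on
    [0, 1]: cardiac index and TAPSE/sPAP decrease with severity, NT-proBNP
    increases (log-normally).  Planted genes respond linearly to the
    severity rank; the default slope and baseline give a population |r|
    around 0.6.
    """

    n_patients: int = 71
    n_genes: int = 16354
    n_planted_pos: int = 60
    n_planted_neg: int = 140
    effect_slope: float = 3.0           # counts per rank unit
    planted_baseline: tuple = (150.0, 400.0)
    baseline_logmean_loc: float = 3.0   # log counts
    baseline_logmean_scale: float = 1.6
    dispersion_a0: float = 0.05
    dispersion_a1: float = 5.0
    ci_intercept: float = 3.2
    ci_slope: float = 1.6
    ci_noise: float = 0.2
    ntprobnp_range: tuple = (100.0, 3000.0)
    ntprobnp_lognoise: float = 0.4
    tapse_spap_intercept: float = 0.42
    tapse_spap_slope: float = 0.30
    tapse_spap_noise: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients (correlation undefined)")
        if self.n_planted_pos + self.n_planted_neg > self.n_genes:
            raise ValueError("more planted genes than genes")


def simulate_human_cohort(config: HumanSimConfig):
    """Simulate the patient cohort; returns (counts, clinical table, truth).

    The severity rank used for planting is oriented so that higher rank
    means healthier (lower mortality risk); negatively planted genes
    therefore rise with disease severity, as most signature genes do.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    severity = rng.uniform(0, 1, n)
    # higher rank = lower severity = healthier
    rank = stats.rankdata(-severity)

    ci = config.ci_intercept - config.ci_slope * severity \
        + rng.normal(0, config.ci_noise, n)
    ci = np.maximum(ci, 0.5)
    lo, hi = config.ntprobnp_range
    bnp = np.exp(np.log(lo) + severity * np.log(hi / lo)
                 + rng.normal(0, config.ntprobnp_lognoise, n))
    ts = config.tapse_spap_intercept - config.tapse_spap_slope * severity \
        + rng.normal(0, config.tapse_spap_noise, n)
    ts = np.maximum(ts, 0.02)

    clinical = pd.DataFrame({
        "patient_id": [f"p{i:03d}" for i in range(n)],
        "CI": ci, "NTproBNP": bnp, "TAPSE_sPAP": ts,
        "timepoint": "prePEA",
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "latent_severity": severity,
    }).set_index("patient_id")

    genes = [f"h{i:05d}" for i in range(config.n_genes)]
    base = np.exp(rng.normal(config.baseline_logmean_loc,
                             config.baseline_logmean_scale, config.n_genes))
    n_planted = config.n_planted_pos + config.n_planted_neg
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    slopes = np.zeros(config.n_genes)
    slopes[planted_idx[: config.n_planted_pos]] = config.effect_slope
    slopes[planted_idx[config.n_planted_pos:]] = -config.effect_slope
    lo_b, hi_b = config.planted_baseline
    base[planted_idx] = rng.uniform(lo_b, hi_b, n_planted)

    centered = rank - (n + 1) / 2.0
    mu = np.maximum(base[:, None] + slopes[:, None] * centered[None, :], 0.5)
    alpha = config.dispersion_a0 + config.dispersion_a1 / mu
    counts = pd.DataFrame(_nb_draw(rng, mu, alpha), index=genes,
                          columns=clinical.index)

    truth_rows = [
        {"gene": genes[i], "role": "planted-pos-corr" if slopes[i] > 0
         else "planted-neg-corr", "effect": float(slopes[i]), "cluster": pd.NA}
        for i in planted_idx
    ]
    truth = _truth_frame(truth_rows, genes)
    return counts, clinical, truth


# ----------------------------------------------------- annotation resources

def simulate_annotation_resources(n_genes: int, seed: int,
                                  ortholog_fraction: float = 0.9,
                                  n_edges: int = 2000):
    """Gene-set collection, ortholog map and scored edge table.

    Stands in for secretome/TF/pathway/ECM collections, a rat-human
    ortholog map and a confidence-scored interaction table.  Set sizes span
    below, within and (gene count permitting) above the 5-2000 ORA bounds.
    Rat genes are lower-case ids; their human orthologs are the upper-case
    counterparts over a configurable fraction of genes.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])

    sizes = [3, 4] + [s for s in (8, 20, 50, 120, 300, 800) if s <= n_genes // 2]
    if n_genes > 2 * 2001:
        sizes.append(2001)
    collection = {
        f"SET_{i:02d}_{size}": set(rng.choice(genes, size=size, replace=False))
        for i, size in enumerate(sizes)
    }
    secretome = set(rng.choice(genes, size=max(5, n_genes // 10), replace=False))
    ecm = set(rng.choice(genes, size=max(5, n_genes // 12), replace=False))
    collection["SECRETOME"] = secretome
    collection["ECM_MATRISOME"] = ecm

    n_mapped = int(round(ortholog_fraction * n_genes))
    mapped = rng.choice(genes, size=n_mapped, replace=False)
    orthologs = pd.DataFrame({"rat_gene": sorted(mapped)})
    orthologs["human_gene"] = orthologs["rat_gene"].str.upper()

    a = rng.integers(0, n_genes, size=n_edges)
    b = rng.integers(0, n_genes, size=n_edges)
    keep = a != b
    edges = pd.DataFrame({
        "gene_a": genes[a[keep]],
        "gene_b": genes[b[keep]],
        "score": rng.uniform(0, 1, keep.sum()),
    })
    return collection, orthologs, edges


# --------------------------------------------------------- proteome cohort

def simulate_proteome(n_proteins: int, n_per_group: int = 8,
                      groups: tuple = ("Sham", "PAB", "AOB"),
                      missing_rate: float = 0.1, seed: int = 0,
                      n_planted: int = 20, planted_shift: float = 1.0,
                      noise_sd: float = 0.3):
    """Log-normal protein abundances with planted group shifts and MCAR holes.

    Eight replicates per group by default.  Returns (abundance matrix with
    NaN for missing, group->columns map, truth table).  Planted proteins
    carry a ``planted_shift`` log2-unit increase in the second group.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    base_log2 = rng.normal(20.0, 2.0, n_proteins)

    shift_group = groups[1] if len(groups) > 1 else groups[0]
    planted = rng.choice(n_proteins, size=min(n_planted, n_proteins), replace=False)

    cols, data = [], []
    group_map: dict[str, list[str]] = {}
    for g in groups:
        group_map[g] = []
        for r in range(n_per_group):
            col = f"{g}_{r}"
            group_map[g].append(col)
            cols.append(col)
            log2_abund = base_log2 + rng.normal(0, noise_sd, n_proteins)
            if g == shift_group:
                log2_abund[planted] += planted_shift
            data.append(np.exp2(log2_abund))
    m = pd.DataFrame(np.column_stack(data), index=proteins, columns=cols)
    mask = rng.random(m.shape) < missing_rate
    m = m.mask(mask)

    truth_rows = [{"gene": proteins[i], "role": "planted-DE",
                   "effect": planted_shift, "cluster": pd.NA} for i in planted]
    truth = _truth_frame(truth_rows, proteins)
    return m, group_map, truth


# -------------------------------------------------------- cell-level counts

def simulate_singlecell(n_cells: int, celltypes: list[str], n_samples: int,
                        conditions: list[str], seed: int = 0,
                        n_genes: int = 500, program_size: int = 30,
                        program_log2fc: float = 2.0,
                        program_celltype: str | None = None,
                        mean_counts_per_cell: float = 5000.0):
    """Per-cell NB counts with a condition-linked program in one cell type.

    Samples are assigned to conditions round-robin; cells are spread evenly
    over (sample, cell type) so every sample holds every requested cell
    type.  A disease program (``program_size`` genes, ``program_log2fc``)
    is planted in ``program_celltype`` (first cell type by default) for
    samples of the last condition.  Returns (cell-by-gene counts, metadata,
    truth table).
    """
    if not celltypes:
        raise ValueError("empty cell-type list")
    if n_cells < n_samples * len(celltypes):
        raise ValueError("need at least one cell per (sample, cell type)")
    rng = np.random.default_rng(seed)
    program_celltype = program_celltype or celltypes[0]
    disease = conditions[-1]
    genes = [f"g{i:04d}" for i in range(n_genes)]

    weights = np.exp(rng.normal(0, 1.2, n_genes))
    weights /= weights.sum()
    program = rng.choice(n_genes, size=program_size, replace=False)
    # mild constitutive cell-type programs so types are distinguishable
    ct_shift = {ct: rng.normal(0, 0.3, n_genes) for ct in celltypes}

    sample_condition = {f"s{i}": conditions[i % len(conditions)]
                        for i in range(n_samples)}
    slots = [(s, ct) for s in sample_condition for ct in celltypes]
    assignment = [slots[i % len(slots)] for i in range(n_cells)]

    rows, meta_rows = [], []
    for i, (sample, ct) in enumerate(assignment):
        eff = ct_shift[ct].copy()
        if ct == program_celltype and sample_condition[sample] == disease:
            eff[program] += program_log2fc
        mu_rel = weights * np.exp2(eff)
        lib = rng.lognormal(np.log(mean_counts_per_cell), 0.25)
        mu = mu_rel / mu_rel.sum() * lib
        alpha = 0.1 + 2.0 / np.maximum(mu, 1e-8)
        rows.append(_nb_draw(rng, mu, alpha))
        meta_rows.append({"cell_id": f"c{i:05d}", "sample": sample,
                          "cell_type": ct,
                          "condition": sample_condition[sample]})

    cells = pd.DataFrame(np.vstack(rows),
                         index=[r["cell_id"] for r in meta_rows], columns=genes)
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    truth_rows = [{"gene": genes[i], "role": "planted-DE",
                   "effect": program_log2fc, "cluster": pd.NA}
                  for i in program]
    truth = _truth_frame(truth_rows, genes)
    return cells, meta, truth
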