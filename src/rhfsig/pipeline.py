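"""End-to-end driver chaining the analysis stages.

``run_full_pipeline`` executes simulate -> DEG screen -> pattern clusters ->
clinical ranking/correlation screen -> cross-species signature -> ORA/GSEA
-> proteome integration on synthetic cohorts, writing every intermediate
table as plain text under a run directory together with a manifest (seeds,
parameters, per-stage row counts and content hashes).  Reruns with the same
configuration and seed are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import deg_screen, enrichment, esc_rank, io, pattern_clusters
from . import proteome as proteome_mod
from . import signature as signature_mod
from . import synthdata

log = logging.getLogger("rhfsig")


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-data pipeline run."""

    out_dir: str = "rhfsig_run"
    seed: int = 0
    # scaled-down cohort sizes for a desk-scale demonstration run
    n_genes_rat: int = 4000
    n_genes_human: int = 4000
    n_per_group: int = 6
    n_patients: int = 71
    library_size: float = 2e6
    kmeans_k: int = 5
    fc_threshold: float = 2.0
    min_mean_disease: float = 50.0
    alpha: float = 0.01
    r_threshold: float = 0.3
    n_perm: int = 500
    n_proteins: int = 1000
    verbosity: str = "INFO"
    # optional pre-existing rat inputs; simulated when left unset
    counts_path: str | None = None
    samples_path: str | None = None

    def rat_config(self) -> synthdata.RatSimConfig:
        return synthdata.RatSimConfig(
            n_genes=self.n_genes_rat, n_per_group=self.n_per_group,
            library_size=self.library_size,
            seed=synthdata.child_seed(self.seed, "rat"))

    def human_config(self) -> synthdata.HumanSimConfig:
        return synthdata.HumanSimConfig(
            n_genes=self.n_genes_human, n_patients=self.n_patients,
            seed=synthdata.child_seed(self.seed, "human"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _deg_condition_sets(counts, sheet, cfg: PipelineConfig):
    """Per-(model, state, ventricle) DEG sets from the rat cohort."""
    sets = {}
    tables = {}
    by = sheet.set_index("sample_id")
    for model, sham in (("PAB", ("Sham-H", "Sham-F")), ("AOB", ("Sham-H", "Sham-F"))):
        for state, dis_group, sham_group in (
                ("compensated", f"{model}-H", sham[0]),
                ("decompensated", f"{model}-F", sham[1])):
            for vent in ("RV", "LV"):
                dis = by[(by["group"] == dis_group) & (by["ventricle"] == vent)].index
                ctl = by[(by["group"] == sham_group) & (by["ventricle"] == vent)].index
                table = deg_screen.nb_wald_test(counts, list(dis), list(ctl))
                tables[(model, state, vent)] = table
                sets[(model, state, vent)] = deg_screen.apply_deg_filter(
                    table, cfg.fc_threshold, cfg.min_mean_disease, cfg.alpha)
    return sets, tables


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory containing the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    manifest: dict = {"seed": config.seed, "parameters": vars(config).copy(),
                      "stages": {}, "files": {}}

    try:
        # ---- simulate or load
        log.info("simulate: seed=%s", config.seed)
        if config.counts_path is not None:
            for p in (config.counts_path, config.samples_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")
            counts = io.read_counts_tsv(config.counts_path)
            sheet = io.read_table_csv(config.samples_path)
            rat_truth = None
        else:
            counts, sheet, rat_truth = synthdata.simulate_rat_cohort(config.rat_config())
        hcounts, clinical, human_truth = synthdata.simulate_human_cohort(
            config.human_config())
        collection, orthologs, edges = synthdata.simulate_annotation_resources(
            config.n_genes_rat, synthdata.child_seed(config.seed, "annotation"))
        prot, prot_groups, prot_truth = synthdata.simulate_proteome(
            config.n_proteins, seed=synthdata.child_seed(config.seed, "proteome"))
        io.write_counts_tsv(counts, out / "rat_counts.tsv")
        io.write_table_csv(sheet, out / "rat_samples.csv")
        io.write_counts_tsv(hcounts, out / "human_counts.tsv")
        io.write_table_csv(clinical.reset_index(), out / "human_clinical.csv")
        io.write_gmt(collection, out / "gene_sets.gmt")
        manifest["stages"]["simulate"] = {
            "rat_genes": int(counts.shape[0]), "rat_samples": int(counts.shape[1]),
            "human_genes": int(hcounts.shape[0]), "patients": int(hcounts.shape[1]),
        }

        # ---- DEG screen + Venn partitions
        log.info("deg: NB Wald screens per condition")
        deg_sets, deg_tables = _deg_condition_sets(counts, sheet, config)
        banding = {m: deg_screen.ventricle_specific_sets(deg_sets, m)
                   for m in ("PAB", "AOB")}
        for (model, state, vent), table in deg_tables.items():
            io.write_table_tsv(table.reset_index(names="gene"),
                               out / f"deg_{model}_{state}_{vent}.tsv")
        io.write_json({m: {k: sorted(v) for k, v in
                           {"compensated_specific": b.compensated_specific,
                            "decompensated": b.decompensated,
                            "shared": b.shared, "union": b.union}.items()}
                       for m, b in banding.items()}, out / "banding_sets.json")
        manifest["stages"]["deg"] = {m: banding[m].sizes() for m in banding}

        # ---- pattern clusters on the PAB union
        pab_union = sorted(banding["PAB"].union)
        cluster_info = {"n_genes": len(pab_union)}
        if len(pab_union) >= config.kmeans_k:
            rpm = deg_screen.normalize_rpm(counts)
            key = sheet.set_index("sample_id")[["group", "ventricle"]].agg("|".join, axis=1)
            means = rpm.loc[pab_union].T.groupby(key).mean().T
            zmat = pattern_clusters.zscore_rows(means)
            assign = pattern_clusters.kmeans_patterns(
                zmat, k=config.kmeans_k, seed=config.seed)
            profile = pattern_clusters.cluster_profile_table(assign, zmat)
            secreted = pattern_clusters.tag_secreted(
                set(pab_union), collection["SECRETOME"], assign.labels)
            io.write_table_tsv(assign.labels.rename("cluster").rename_axis("gene").reset_index(),
                               out / "clusters.tsv")
            io.write_table_tsv(profile.reset_index(), out / "cluster_profiles.tsv")
            cluster_info.update(k=assign.k, inertia=assign.inertia,
                                n_secreted=len(secreted["secreted"]))
        manifest["stages"]["cluster"] = cluster_info

        # ---- clinical ranking and correlation screen
        log.info("escrank: %d patients", len(clinical))
        risk = clinical.apply(esc_rank.classify_risk, axis=1)
        ranking = esc_rank.severity_rank(clinical)
        hexpr = deg_screen.normalize_rpm(hcounts)
        screen = esc_rank.correlation_screen(hexpr, ranking,
                                             r_threshold=config.r_threshold,
                                             alpha=config.alpha)
        io.write_table_csv(pd.DataFrame({"risk": risk,
                                         "esc_rank": ranking.composite}),
                           out / "esc_risk_rank.csv", index=True)
        io.write_table_tsv(screen.reset_index(names="gene"),
                           out / "correlation_screen.tsv")
        manifest["stages"]["escrank"] = {
            "risk_counts": risk.value_counts().to_dict(),
            "selected_genes": int(screen["selected"].sum()),
        }

        # ---- cross-species signature
        hselected = set(screen.index[screen["selected"]])
        # synthetic "LHF" list: stand-in built from the human screen at a
        # relaxed threshold, in the human namespace
        relaxed = esc_rank.correlation_screen(hexpr, ranking,
                                              r_threshold=0.2, alpha=0.05)
        hlhf = set(relaxed.index[relaxed["selected"]])
        # translate rat ids into the human cohort namespace (index-aligned)
        rat_to_human = {r: f"h{int(r[1:]):05d}" for r in pab_union
                        if int(r[1:]) < config.n_genes_human}
        report = signature_mod.build_core_signature(
            pab_union, hselected, hlhf, rat_to_human,
            universe_size=hexpr.shape[0])
        io.write_json({"sizes": report.sizes(),
                       "fisher": {k: v.as_dict() for k, v in report.fisher.items()}},
                      out / "signature_report.json")
        manifest["stages"]["signature"] = report.sizes()

        # ---- enrichment (ORA on the rat union; GSEA on the human ranking)
        universe = set(counts.index)
        if pab_union:
            records = enrichment.ora(set(pab_union), collection, universe)
            io.write_table_tsv(records.reset_index(), out / "ora.tsv")
            manifest["stages"]["ora"] = {"tested_terms": int(len(records))}
        ranked = screen["r"].dropna()
        gsea_set = set(ranked.sample(min(50, len(ranked)),
                                     random_state=config.seed).index)
        gres = enrichment.gsea(ranked, gsea_set, n_perm=config.n_perm,
                               seed=config.seed)
        manifest["stages"]["gsea"] = {"es": gres.es, "p_perm": gres.p_perm}

        # ---- proteome
        log.info("proteome: %d proteins", prot.shape[0])
        filtered = proteome_mod.filter_valid_values(prot, prot_groups)
        pre = proteome_mod.preprocess_proteome(filtered)
        deps = proteome_mod.call_deps(pre, prot_groups["PAB"], prot_groups["Sham"])
        io.write_table_tsv(deps["table"].reset_index(names="protein"),
                           out / "deps.tsv")
        manifest["stages"]["proteome"] = {
            "identified": int(prot.shape[0]), "valid": int(filtered.shape[0]),
            "up": len(deps["up"]), "down": len(deps["down"]),
        }

        for path in sorted(out.glob("*")):
            if path.is_file() and path.name not in ("manifest.json", "run.log"):
                manifest["files"][path.name] = _sha256(path)
        io.write_json(manifest, out / "manifest.json")
        return out
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"pipeline input missing: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
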