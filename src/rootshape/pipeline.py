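"""End-to-end orchestration of the synthetic root-shape study.

Stages run in dependency order, each writing its artifacts into the output
directory and a summary into the run report:

    simulate -> phenotype -> model -> structure -> gwas -> predict
    -> annotate

A run is fully determined by (config, seed); the report carries a manifest
with SHA-256 checksums so reruns can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import gwas as gwas_mod
from . import popgen, predict, shapes, simulate, traitmodel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "model", "structure", "gwas",
          "predict", "annotate")

TRAITS = ("digital_biomass_mm2", "length_mm", "max_width_mm",
          "lw_ratio_log", "tip_angle_deg", "contour_pc")


DEFAULT_SYNTHETIC = {
    "n_accessions": 120,
    "n_markers": 600,
    "k_pops": 3,
    "fst": 0.25,
    "admixture_alpha": 0.05,
    "n_chromosomes": 5,
    "design": {"n_environments": 2, "n_blocks": 2, "roots_per_plot": 2},
    "n_qtl_length": 3,
    "n_qtl_width": 3,
    "qtl_effect": 0.25,
    "biomass_extra_noise": 0.45,
    "pixel_scale": 1.0,
}

DEFAULT_PARAMS = {
    "outlier_sd": 3.0,
    "ld_window_kb": 50.0,
    "ld_step_kb": 5.0,
    "ld_r2_cutoff": 0.02,
    "admixture_k_range": [1, 2, 3, 4, 5],
    "admixture_folds": 3,
    "admixture_restarts": 2,
    "gwas_models": ["K", "K-LOCO"],
    "gwas_n_pcs": 0,
    "alpha": 0.05,
    "merge_radius_bp": 100_000,
    "subset_fraction": 0.5,
    "cv_split": 0.8,
    "cv_reps": 20,
    "candidate_window_bp": 500_000,
    "ld_decay_max_bp": 2_000_000,
    "ld_decay_bin_bp": 50_000,
    "ld_decay_r2_target": 0.1,
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one data source is supported per run: the built-in synthetic
    study (``synthetic`` block) or pre-existing input paths (``paths``
    block with phenotype CSV / VCF / GFF3 / GO map).
    """

    seed: int = 0
    output_dir: str = "rootshape_run"
    stages: dict = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES})
    synthetic: dict | None = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SYNTHETIC))
    paths: dict | None = None
    params: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self):
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError(
                "exactly one of 'synthetic' or 'paths' must be configured")
        syn = dict(DEFAULT_SYNTHETIC)
        if self.synthetic is not None:
            syn.update(self.synthetic)
            self.synthetic = syn
        par = dict(DEFAULT_PARAMS)
        par.update(self.params or {})
        self.params = par
        st = {s: True for s in STAGES}
        st.update(self.stages or {})
        unknown = set(st) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = st
        if self.paths is not None:
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{key}: {p}")
        if not 0 < self.params["alpha"] < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.params["cv_split"] < 1:
            raise ValueError("cv_split must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RunReport:
    config: dict
    version: str
    stages: dict = dataclasses.field(default_factory=dict)
    manifest: dict = dataclasses.field(default_factory=dict)
    skipped: list = dataclasses.field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the pipeline stages."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        from . import __version__
        self.report = RunReport(config=config.to_dict(),
                                version=__version__)
        self.state: dict = {}

    def artifact(self, name: str) -> Path:
        return self.out / name

    def record(self, stage: str, summary: dict, files) -> None:
        summary = dict(summary)
        summary["wall_time_s"] = round(summary.get("wall_time_s", 0.0), 3)
        self.report.stages[stage] = summary
        for f in files:
            self.report.manifest[str(Path(f).relative_to(self.out))] = \
                _sha256(Path(f))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(run: _Run):
    cfg = run.cfg
    if cfg.paths is not None:
        return _load_real_inputs(run)
    syn = cfg.synthetic
    rng = np.random.default_rng(cfg.seed)
    geno, truth = simulate.generate_population(
        syn["n_accessions"], syn["n_markers"], syn["k_pops"], syn["fst"],
        syn["admixture_alpha"], n_chromosomes=syn["n_chromosomes"],
        seed=cfg.seed)
    # causal markers: spread across chromosomes, away from each other
    m = geno.n_markers
    picks = rng.choice(m, size=syn["n_qtl_length"] + syn["n_qtl_width"],
                       replace=False)
    eff = syn["qtl_effect"]
    qtl_len = [(geno.chrom[j], int(geno.pos[j]), eff)
               for j in picks[:syn["n_qtl_length"]]]
    qtl_wid = [(geno.chrom[j], int(geno.pos[j]), eff)
               for j in picks[syn["n_qtl_length"]:]]
    masks, meta, truth2 = simulate.simulate_shape_study(
        geno, qtl_length=qtl_len, qtl_width=qtl_wid,
        design=syn["design"], seed=cfg.seed + 1,
        biomass_extra_noise=syn["biomass_extra_noise"],
        pixel_scale=syn["pixel_scale"])
    truth2.q_true = truth.q_true
    truth2.f_true = truth.f_true

    vcf = run.artifact("genotypes.vcf")
    geno.to_vcf(vcf)
    meta_path = run.artifact("observations.csv")
    meta.to_csv(meta_path, index=False)
    truth_path = run.artifact("truth.json")
    truth2.to_json(truth_path)
    mask_paths = []
    for i, mask in enumerate(masks[:4]):     # sample silhouettes
        p = run.artifact(f"mask_example_{i}.png")
        mask.to_png(p)
        mask_paths.append(p)
    run.state.update(geno=geno, masks=masks, meta=meta, truth=truth2)
    return ({"n_accessions": geno.n_accessions,
             "n_markers": geno.n_markers,
             "n_masks": len(masks)},
            [vcf, meta_path, truth_path] + mask_paths)


def _load_real_inputs(run: _Run):
    """Load pre-existing inputs (VCF genotypes; long phenotype CSV or a
    mask directory with a metadata CSV) instead of simulating."""
    from .genotypes import GenotypeMatrix

    cfg = run.cfg
    paths = cfg.paths
    geno = GenotypeMatrix.from_vcf(paths["vcf"])
    summary = {"n_accessions": geno.n_accessions,
               "n_markers": geno.n_markers, "source": "paths"}
    run.state["geno"] = geno
    if "phenotypes" in paths:
        records = pd.read_csv(paths["phenotypes"])
        required = {"accession", "env", "block", "plot", "trait", "value"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"phenotype CSV missing columns {missing}")
        run.state["records"] = records
        summary["n_phenotype_rows"] = len(records)
    if "masks_dir" in paths:
        meta = pd.read_csv(Path(paths["masks_dir"]) / "masks.csv")
        pixel_scale = float(meta["pixel_scale"].iloc[0])
        masks = [shapes.RootMask.from_png(
            Path(paths["masks_dir"]) / f, pixel_scale)
            for f in meta["file"]]
        run.state.update(masks=masks, meta=meta.drop(
            columns=["file", "pixel_scale"]))
        summary["n_masks"] = len(masks)
    return summary, []


def _stage_phenotype(run: _Run):
    masks, meta = run.state["masks"], run.state["meta"]
    wide, loadings = shapes.traits_table(masks)
    wide = wide.reset_index(drop=True)
    table = pd.concat([meta.reset_index(drop=True), wide], axis=1)
    if "biomass_noise" in table:
        # synthetic biomass carries its extra non-genetic noise factor
        table["digital_biomass_mm2"] *= table.pop("biomass_noise")
    drop = [c for c in ("log_length", "log_width") if c in table]
    table = table.drop(columns=drop)
    long = table.melt(
        id_vars=["accession", "env", "block", "plot", "root"],
        value_vars=[t for t in TRAITS if t in table],
        var_name="trait", value_name="value")
    long["units"] = long["trait"].map({
        "digital_biomass_mm2": "mm2", "length_mm": "mm",
        "max_width_mm": "mm", "lw_ratio_log": "ln(mm/mm)",
        "tip_angle_deg": "deg", "contour_pc": "score"})
    filtered, removed = shapes.outlier_filter(
        long, sd_threshold=run.cfg.params["outlier_sd"])
    traits_path = run.artifact("traits_long.csv")
    filtered.to_csv(traits_path, index=False)
    removed_path = run.artifact("outliers_removed.csv")
    removed.to_csv(removed_path, index=False)
    loadings_path = run.artifact("contour_loadings.json")
    shapes.save_loadings(loadings, loadings_path)
    run.state["records"] = filtered
    return ({"n_obs": len(long), "n_removed": len(removed),
             "n_traits": len(TRAITS)},
            [traits_path, removed_path, loadings_path])


def _stage_model(run: _Run):
    records = run.state["records"]
    traits = [t for t in records["trait"].unique()]
    blues, h2, varrows = {}, {}, []
    for trait in traits:
        fix = traitmodel.fit_trait_model(records, trait, "fixed")
        ran = traitmodel.fit_trait_model(records, trait, "random")
        blues[trait] = fix.blues
        h2[trait] = ran.cullis_h2()
        row = {"trait": trait, **ran.varcomp, "h2": h2[trait],
               "converged": ran.converged}
        varrows.append(row)
    blue_df = pd.DataFrame(blues)
    blue_path = run.artifact("blues.csv")
    blue_df.to_csv(blue_path)
    var_df = pd.DataFrame(varrows)
    var_path = run.artifact("variance_components.csv")
    var_df.to_csv(var_path, index=False)
    h2_path = run.artifact("heritability.csv")
    pd.Series(h2, name="cullis_h2").to_csv(h2_path)

    fw_trait = "lw_ratio_log" if "lw_ratio_log" in traits else traits[0]
    per_env = traitmodel.per_env_blues(records, fw_trait)
    fw = traitmodel.fw_regression(per_env)
    fw_path = run.artifact(f"finlay_wilkinson_{fw_trait}.csv")
    fw.table.to_csv(fw_path)
    corr_path = run.artifact("trait_correlations.csv")
    traitmodel.trait_correlations(blue_df).to_csv(corr_path)
    run.state.update(blues=blue_df, h2=h2)
    return ({"traits": len(traits),
             "h2": {k: round(v, 3) for k, v in h2.items()}},
            [blue_path, var_path, h2_path, fw_path, corr_path])


def _stage_structure(run: _Run):
    cfg, geno = run.cfg, run.state["geno"]
    par = cfg.params
    kept = popgen.ld_prune(geno, par["ld_window_kb"], par["ld_step_kb"],
                           par["ld_r2_cutoff"])
    pruned = geno.take_markers(kept)
    prune_path = run.artifact("pruned_markers.csv")
    pd.DataFrame({"chrom": pruned.chrom, "pos": pruned.pos}).to_csv(
        prune_path, index=False)

    scores, pct = popgen.pca_genotypes(pruned)
    pca_path = run.artifact("pca_scores.csv")
    scores.to_csv(pca_path)

    cv_table, k_best = popgen.admixture_cv(
        pruned, par["admixture_k_range"],
        n_folds=par["admixture_folds"], seed=cfg.seed,
        n_restarts=par["admixture_restarts"])
    fit = popgen.AdmixtureModel(pruned, k_best).fit(
        seed=cfg.seed, n_restarts=par["admixture_restarts"])
    q_path = run.artifact("admixture_q.csv")
    fit.q_frame(pruned.accessions).to_csv(q_path)
    cv_path = run.artifact("admixture_cv.csv")
    cv_table.to_csv(cv_path, index=False)

    # group accessions by modal ancestry for distances / Fst
    assign = {a: f"pop{int(np.argmax(fit.q[i])) + 1}"
              for i, a in enumerate(pruned.accessions)}
    pruned.groups = assign
    nei, labels = popgen.nei_distance(pruned, unit="accession")
    nei_path = run.artifact("nei_distance.csv")
    nei.to_csv(nei_path)
    newick = popgen.nj_tree(nei)
    tree_path = run.artifact("nj_tree.nwk")
    tree_path.write_text(newick + "\n")
    if len(set(assign.values())) >= 2:
        fst = popgen.pairwise_fst(pruned)
        fst_path = run.artifact("fst_populations.csv")
        fst.to_csv(fst_path)
        fst_files = [fst_path]
    else:
        fst_files = []
    run.state.update(admixture=fit, k_selected=k_best,
                     pop_assignment=assign)
    return ({"markers_pruned_in": geno.n_markers,
             "markers_retained": len(kept), "k_selected": k_best,
             "pc1_pct": round(float(pct[0]), 2)},
            [prune_path, pca_path, q_path, cv_path, nei_path, tree_path]
            + fst_files)


def _subset_accessions(run: _Run):
    """The label-filtered second GWAS panel (largest assigned population)."""
    assign = run.state.get("pop_assignment")
    geno = run.state["geno"]
    if assign is None:
        return None
    counts = pd.Series(assign).value_counts()
    label = counts.index[0]
    members = [a for a, g in assign.items() if g == label]
    if len(members) < 30:
        return None
    idx = [geno.accessions.index(a) for a in members]
    return geno.take_accessions(idx)


def _stage_gwas(run: _Run):
    cfg, geno = run.cfg, run.state["geno"]
    par = cfg.params
    blues = run.state["blues"]
    panels = {"full": geno}
    subset = _subset_accessions(run)
    if subset is not None:
        panels["subset"] = subset
    thresholds = {name: gwas_mod.bonferroni_threshold(
        g.n_markers, par["alpha"]) for name, g in panels.items()}

    results, files, lam_rows = [], [], []
    traits = list(blues.columns)
    for panel, pgeno in panels.items():
        for trait in traits:
            for model in par["gwas_models"]:
                scan = gwas_mod.MixedLMScan(
                    blues[trait], pgeno, kinship_mode=model,
                    n_pcs=par["gwas_n_pcs"], panel=panel, trait=trait)
                res = scan.fit()
                results.append(res)
                lam_rows.append({"panel": panel, "trait": trait,
                                 "model": model,
                                 "lambda": res.inflation()})
                path = run.artifact(f"gwas_{panel}_{trait}_{model}.csv")
                res.table.to_csv(path, index=False)
                files.append(path)
    lam_path = run.artifact("inflation_lambda.csv")
    pd.DataFrame(lam_rows).to_csv(lam_path, index=False)
    files.append(lam_path)

    # PVE on the union of significant markers, per panel/trait
    pve = {}
    for res in results:
        pgeno = panels[res.panel]
        thr = thresholds[res.panel]
        sig = res.table[res.table["score"] >= thr]
        d = pgeno.imputed()
        y = blues[res.trait].reindex(pgeno.accessions).to_numpy()
        ids = {(c, p): j for j, (c, p) in enumerate(
            zip(pgeno.chrom.astype(str), pgeno.pos))}
        for _, row in sig.iterrows():
            key = (str(row["chrom"]), int(row["pos"]))
            if key not in pve:
                pve[key] = gwas_mod.marker_pve(d[:, ids[key]], y)

    calls = gwas_mod.consensus_qtl(results, thresholds,
                                   merge_radius_bp=par["merge_radius_bp"],
                                   pve_by_marker=pve)
    qtl_path = run.artifact("consensus_qtl.csv")
    gwas_mod.qtl_table(calls).to_csv(qtl_path, index=False)
    files.append(qtl_path)

    from . import plot
    first = results[0]
    man_path = run.artifact("manhattan_example.png")
    plot.manhattan(first.table, thresholds[first.panel], path=man_path)
    qq_path = run.artifact("qq_example.png")
    plot.qq(first.table["p"].dropna(), path=qq_path)
    files += [man_path, qq_path]

    decay, crossing = gwas_mod.ld_decay(
        geno, max_dist_bp=par["ld_decay_max_bp"],
        bin_width_bp=par["ld_decay_bin_bp"],
        r2_target=par["ld_decay_r2_target"])
    decay_path = run.artifact("ld_decay.csv")
    decay.to_csv(decay_path, index=False)
    files.append(decay_path)

    run.state.update(gwas_results=results, qtl_calls=calls,
                     thresholds=thresholds)
    return ({"panels": list(panels), "models": par["gwas_models"],
             "thresholds": {k: round(v, 2) for k, v in thresholds.items()},
             "n_qtl": len(calls),
             "ld_r2_crossing_bp": None if np.isnan(crossing)
             else int(crossing)}, files)


def _stage_predict(run: _Run):
    cfg, geno = run.cfg, run.state["geno"]
    par = cfg.params
    blues = run.state["blues"]
    rows = []
    gebvs = {}
    for trait in blues.columns:
        fit = predict.rrblup_fit(blues[trait], geno)
        gebvs[trait] = fit.gebv
        cv = predict.cv_accuracy(blues[trait], geno,
                                 split=par["cv_split"],
                                 n_reps=par["cv_reps"], seed=cfg.seed)
        rows.append({"trait": trait, "accuracy_r": cv.accuracy_r,
                     "r2": cv.r2, "se_r": cv.se_r,
                     "n_reps": cv.n_reps})
    gebv_path = run.artifact("gebv.csv")
    pd.DataFrame(gebvs).to_csv(gebv_path)
    cv_df = pd.DataFrame(rows)
    cv_path = run.artifact("cv_accuracy.csv")
    cv_df.to_csv(cv_path, index=False)
    run.state["cv_accuracy"] = cv_df.set_index("trait")["accuracy_r"]
    return ({"accuracy_r": {r["trait"]: round(r["accuracy_r"], 3)
                            for r in rows}}, [gebv_path, cv_path])


def synthetic_annotation(geno, seed: int = 0, gene_every_bp: int = 150_000,
                         n_terms: int = 12):
    """A synthetic gene annotation and gene->GO map spanning the genome.

    Purely structural stand-in for a real annotation: genes tile each
    chromosome at regular spacing with 2-4 random GO terms each, so the
    candidate-window and enrichment machinery has realistic input shapes.
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    rows, gene2go = [], {}
    for c in pd.unique(geno.chrom.astype(str)):
        top = int(geno.pos[geno.chrom.astype(str) == c].max())
        for i, start in enumerate(range(10_000, top, gene_every_bp)):
            gid = f"{c}.g{i:04d}"
            length = int(rng.integers(1_000, 8_000))
            rows.append({"gene_id": gid, "chrom": c, "start": start,
                         "end": start + length,
                         "strand": rng.choice(["+", "-"]),
                         "label": ""})
            k = int(rng.integers(2, 5))
            gene2go[gid] = set(rng.choice(terms, size=k, replace=False))
    return pd.DataFrame(rows), gene2go


def _stage_annotate(run: _Run):
    cfg = run.cfg
    calls = run.state.get("qtl_calls")
    if not calls:
        run.report.skipped.append(
            "annotate: no consensus QTL available")
        return {"skipped": "no QTL"}, []
    if cfg.paths and "gff3" in cfg.paths:
        ann = annotate_mod.load_gff3_genes(cfg.paths["gff3"])
        gene2go = annotate_mod.load_gene2go(cfg.paths["go_map"])
    else:
        ann, gene2go = synthetic_annotation(run.state["geno"],
                                            seed=cfg.seed)
    cand = annotate_mod.candidate_genes(
        calls, ann, window_bp=cfg.params["candidate_window_bp"])
    cand_path = run.artifact("candidate_genes.csv")
    cand.to_csv(cand_path, index=False)
    files = [cand_path]
    summary = {"n_candidates": int(cand["gene_id"].nunique())
               if len(cand) else 0}
    if len(cand):
        in_window = set(cand["gene_id"])
        flags = {g: int(g in in_window) for g in ann["gene_id"]}
        enr = annotate_mod.go_enrichment(flags, gene2go)
        enr_path = run.artifact("go_enrichment.csv")
        enr.to_csv(enr_path, index=False)
        files.append(enr_path)
        summary["top_go_p"] = float(enr["p"].iloc[0]) if len(enr) else None
    return summary, files


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "phenotype": _stage_phenotype,
    "model": _stage_model,
    "structure": _stage_structure,
    "gwas": _stage_gwas,
    "predict": _stage_predict,
    "annotate": _stage_annotate,
}

_REQUIRES = {
    "phenotype": ("masks",),
    "model": ("records",),
    "structure": ("geno",),
    "gwas": ("geno", "blues"),
    "predict": ("geno", "blues"),
    "annotate": ("qtl_calls",),
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the configured stages in order and write the run report.

    A stage whose inputs are missing (because an upstream stage was
    disabled) is skipped with a notice rather than failing the run.
    """
    run = _Run(config)
    for stage in STAGES:
        if not config.stages.get(stage, True):
            run.report.skipped.append(f"{stage}: disabled in config")
            logger.info("stage %s disabled", stage)
            continue
        missing = [k for k in _REQUIRES.get(stage, ())
                   if k not in run.state]
        if missing:
            run.report.skipped.append(
                f"{stage}: missing upstream inputs {missing}")
            logger.warning("stage %s skipped (needs %s)", stage, missing)
            continue
        t0 = time.time()
        logger.info("stage %s ...", stage)
        summary, files = _STAGE_FUNCS[stage](run)
        summary["wall_time_s"] = time.time() - t0
        run.record(stage, summary, files)
    report_path = run.out / "report.json"
    run.report.to_json(report_path)
    return run.report
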