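"""End-to-end orchestration of the synthetic-study analysis.

Runs simulate -> morphometrics -> growth -> SNP filtering -> PCA ->
sex-linkage -> divergence/diversity -> within-lake structure -> PERMANOVA
in dependency order, writing each stage's artifacts plus a manifest
(parameters, seeds, content hashes) and a terminal report JSON with the
headline results.  A stage failure halts downstream stages but preserves
the partial manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genomatrix, growth, morphometrics, permanova, popstats, sexlink, simdata, structure

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    sim: simdata.SimConfig | None = None
    filter: genomatrix.SNPFilterConfig = field(default_factory=genomatrix.SNPFilterConfig)
    stages: tuple = (
        "simulate", "morphometrics", "growth", "filter",
        "popstats", "sexlink", "structure", "permanova",
    )
    k_max_morph: int = 5
    k_range_structure: tuple = (1, 2, 3)
    n_perm: int = 999
    n_boot_fst: int = 100
    structure_lakes: tuple = ("Fog3", "LTER348")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the report dict.

    Every stochastic operation derives its seed from ``cfg.seed``, so a rerun
    with the same config reproduces the report byte-for-byte.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}
    simcfg = cfg.sim or simdata.default_config(seed=cfg.seed)

    def save_manifest():
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=_json_default)

    study = None
    try:
        if "simulate" in cfg.stages:
            study = simdata.simulate_study(simcfg, seed=cfg.seed)
            simdata.write_study(study, cfg.outdir)
            manifest["stages"]["simulate"] = {
                "seed": simcfg.seed, "n_fish": len(study.fish),
                "n_loci": study.genotypes.n_loci,
            }
            report["stages"]["simulate"] = {
                "n_fish": len(study.fish), "n_loci": study.genotypes.n_loci,
            }
        if study is None:
            raise ValueError("downstream stages require the simulate stage")

        fish = study.fish
        if "morphometrics" in cfg.stages:
            traits = fish[[f"{t}_mm" for t in morphometrics.TRAIT_NAMES]]
            lengths = fish["total_length_mm"].to_numpy()
            allom = morphometrics.fit_allometric_slope(traits, lengths)
            adjusted = morphometrics.size_adjust_frame(traits, lengths, allom)
            raw_model = morphometrics.gmm_cluster(
                traits.to_numpy(), k_max=cfg.k_max_morph, seed=cfg.seed
            )
            adj_model = morphometrics.gmm_cluster(
                adjusted.to_numpy(), k_max=cfg.k_max_morph, seed=cfg.seed
            )
            fish = morphometrics.assign_size_classes(raw_model, fish)
            fish.to_csv(os.path.join(cfg.outdir, "fish_classified.tsv"), sep="\t", index=False)
            raw_model.bic_table.to_csv(
                os.path.join(cfg.outdir, "bic_raw.tsv"), sep="\t", index=False
            )
            adj_model.bic_table.to_csv(
                os.path.join(cfg.outdir, "bic_adjusted.tsv"), sep="\t", index=False
            )
            report["stages"]["morphometrics"] = {
                "k_raw": raw_model.k, "k_size_adjusted": adj_model.k,
                "delta_bic_raw": raw_model.delta_bic,
                "delta_bic_adjusted": adj_model.delta_bic,
                "reference_length_mm": allom.reference_length,
                "slopes": allom.slopes.to_dict(),
            }
            manifest["stages"]["morphometrics"] = {"k_max": cfg.k_max_morph}

        if "growth" in cfg.stages:
            L0, O0, diag = growth.estimate_biological_intercept(study.otoliths)
            curves = {
                r.fish_id: growth.back_calculate(r, L0, O0) for r in study.otoliths
            }
            grouping = dict(zip(fish["id"], fish["group"]))
            summary = growth.growth_summary(curves, grouping)
            summary.table.to_csv(
                os.path.join(cfg.outdir, "growth_summary.tsv"), sep="\t", index=False
            )
            report["stages"]["growth"] = {
                "hatch_length_mm": L0, "hatch_radius": O0,
                "n_fish": len(curves),
            }
            manifest["stages"]["growth"] = {"n_youngest": 5}

        g = study.genotypes
        if "filter" in cfg.stages:
            g, filt_report = genomatrix.filter_genotypes(g, cfg.filter)
            report["stages"]["filter"] = filt_report.to_dict()
            manifest["stages"]["filter"] = cfg.filter.__dict__.copy()

        pca_res = genomatrix.pca(genomatrix.genotype_covariance(g))

        if "sexlink" in cfg.stages:
            known = fish.loc[fish["known_sex"], ["id", "sex"]]
            putative, axis = sexlink.infer_sex_groups(
                pca_res, pd.Series(known["sex"].values, index=known["id"].values),
                seed=cfg.seed,
            )
            sex_report = sexlink.detect_sex_linked(
                g, putative, pca_result=pca_res, seed=cfg.seed
            )
            sex_report.candidates.to_csv(
                os.path.join(cfg.outdir, "sex_candidates.tsv"), sep="\t", index=False
            )
            g, drop_manifest = sexlink.drop_sex_chromosomes(g, sex_report)
            pca_res = genomatrix.pca(genomatrix.genotype_covariance(g))
            report["stages"]["sexlink"] = {
                "sex_axis": axis + 1,
                "n_candidates": len(sex_report.candidates),
                "patterns": sex_report.candidates["pattern"].value_counts().to_dict(),
                "flagged_chromosomes": sex_report.flagged_chromosomes,
                "fst_between_sexes": sex_report.fst_between_sexes,
                **drop_manifest,
            }
            manifest["stages"]["sexlink"] = {"loading_quantile": 0.999}

        if "popstats" in cfg.stages:
            inds = g.individuals
            pairs = []
            groups = list(dict.fromkeys(inds["group"]))
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1 :]:
                    res = popstats.fst_from_matrix(
                        g, (inds["group"] == g1).to_numpy(),
                        (inds["group"] == g2).to_numpy(), (g1, g2),
                    )
                    res = popstats.fst_bootstrap_ci(res, cfg.n_boot_fst, seed=cfg.seed)
                    pairs.append(res)
            lakes = list(dict.fromkeys(inds["lake"]))
            lake_pairs = []
            for i, l1 in enumerate(lakes):
                for l2 in lakes[i + 1 :]:
                    res = popstats.fst_from_matrix(
                        g, (inds["lake"] == l1).to_numpy(),
                        (inds["lake"] == l2).to_numpy(), (l1, l2),
                    )
                    lake_pairs.append(res)
            fst_rows = [
                {"pop1": r.pop1, "pop2": r.pop2, "fst": r.estimate,
                 "ci_low": r.ci_low, "ci_high": r.ci_high}
                for r in pairs + lake_pairs
            ]
            pd.DataFrame(fst_rows).to_csv(
                os.path.join(cfg.outdir, "fst.tsv"), sep="\t", index=False
            )
            div_rows = []
            for lake in lakes:
                s = popstats.het_fis(g, (inds["lake"] == lake).to_numpy(), lake)
                div_rows.append(s.__dict__)
            pd.DataFrame(div_rows).to_csv(
                os.path.join(cfg.outdir, "diversity.tsv"), sep="\t", index=False
            )
            within = [
                r.estimate for r in lake_pairs
                if inds.loc[inds["lake"] == r.pop1, "group"].iloc[0]
                == inds.loc[inds["lake"] == r.pop2, "group"].iloc[0]
            ]
            report["stages"]["popstats"] = {
                "group_fst": {f"{r.pop1}-{r.pop2}": r.estimate for r in pairs},
                "group_fst_ci": {
                    f"{r.pop1}-{r.pop2}": [r.ci_low, r.ci_high] for r in pairs
                },
                "mean_within_group_lake_fst": float(np.mean(within)) if within else None,
                "diversity": {d["unit"]: d["theta_w"] for d in div_rows},
            }
            manifest["stages"]["popstats"] = {"n_boot": cfg.n_boot_fst}

        if "structure" in cfg.stages:
            struct = {}
            for lake in cfg.structure_lakes:
                mask = (g.individuals["lake"] == lake).to_numpy()
                if mask.sum() < 10:
                    continue
                sub = g.take_individuals(np.flatnonzero(mask))
                sub, _ = genomatrix.filter_genotypes(sub, cfg.filter)
                k_best, curve = structure.choose_k_cv(
                    sub, k_range=range(cfg.k_range_structure[0],
                                       cfg.k_range_structure[-1] + 1),
                    seed=cfg.seed,
                )
                size_class = fish.set_index("id").loc[
                    sub.individuals["id"], "size_class"
                ].to_numpy() if "size_class" in fish.columns else None
                stock = structure.stock_mixture_em(
                    sub, K=2, n_boot=cfg.n_boot_fst, seed=cfg.seed,
                    size_class=size_class,
                )
                curve.to_csv(
                    os.path.join(cfg.outdir, f"cv_curve_{lake}.tsv"),
                    sep="\t", index=False,
                )
                struct[lake] = {
                    "selected_k": k_best,
                    "fisher_p_stock_vs_size": stock.fisher_p,
                    "mean_bootstrap_support": (
                        float(np.mean(stock.bootstrap_support))
                        if stock.bootstrap_support is not None else None
                    ),
                }
            report["stages"]["structure"] = struct
            manifest["stages"]["structure"] = {"k_range": list(cfg.k_range_structure)}

        if "permanova" in cfg.stages:
            lake_tab = study.lakes.set_index("lake")
            comp = (
                fish.groupby("lake")["size_class"]
                .value_counts(normalize=True)
                .unstack(fill_value=0.0)
                if "size_class" in fish.columns
                else fish.groupby("lake")["total_length_mm"].mean().to_frame()
            )
            comp = comp.loc[[l for l in lake_tab.index if l in comp.index]]
            preds = lake_tab.loc[comp.index, ["group", "secchi_depth_m", "density_fish_ha"]]
            preds = preds.rename(columns={"group": "lake_group"})
            res = permanova.permanova_test(
                comp.to_numpy(), preds.reset_index(drop=True),
                n_perm=cfg.n_perm, seed=cfg.seed,
            )
            res.table.to_csv(
                os.path.join(cfg.outdir, "permanova.tsv"), sep="\t", index=False
            )
            report["stages"]["permanova"] = {
                "terms": res.table.to_dict(orient="records"),
                "residual_ss": res.residual_ss,
                "residual_df": res.residual_df,
            }
            manifest["stages"]["permanova"] = {"n_perm": cfg.n_perm}
    finally:
        for name in sorted(os.listdir(cfg.outdir)):
            path = os.path.join(cfg.outdir, name)
            if os.path.isfile(path) and name != "manifest.json":
                manifest["artifacts"][name] = _hash_file(path)
        save_manifest()

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default, sort_keys=True)
    return report
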