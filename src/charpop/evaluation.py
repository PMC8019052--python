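"""Replicated evaluation experiments for the analysis pipeline.

Each function regenerates synthetic data under the study conditions, runs
the relevant stage, and measures a recovery or calibration statistic.  They
are used by the acceptance script and the acceptance test suite; sizes
default to the evaluation conditions described in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genomatrix, growth, morphometrics, permanova, popstats, sexlink, simdata, structure
from .lakes import LAKE_TABLE

__all__ = [
    "table1_densities",
    "fst_closed_forms",
    "fst_recovery_sweep",
    "permanova_calibration",
    "morpho_contrast_sweep",
    "sexlink_sweep",
    "structure_negative_control",
    "structure_positive_control",
    "growth_checks",
    "diversity_closed_forms",
]


def table1_densities() -> dict:
    """Char density (fish/ha) for each study lake from abundance and area."""
    return {
        row["lake"]: permanova.char_density(row["abundance"], row["surface_area_ha"])
        for _, row in LAKE_TABLE.iterrows()
    }


def fst_closed_forms() -> dict:
    """Worked examples of the Reich-Patterson estimator."""
    hand = popstats.fst_reich_patterson(([4], [10]), ([1], [10])).estimate
    fixed = popstats.fst_reich_patterson(([10], [10]), ([0], [10])).estimate
    return {"hand_example": hand, "fixed_difference": fixed}


def _two_deme(seed: int, n_loci: int, n: int, fst: float) -> simdata.SimConfig:
    return simdata.default_config(
        seed=seed, n_loci=n_loci, fst_between_groups=fst, fst_within_group=0.0,
        missing_rate=0.0, n_sex_loci_xy=0, n_sex_loci_female_only=0,
        lakes=(
            simdata.LakeSpec("A", "G1", n, ((300, 30, 1.0),)),
            simdata.LakeSpec("B", "G2", n, ((300, 30, 1.0),)),
        ),
    )


def fst_recovery_sweep(
    seed: int = 0, n_reps: int = 100, n_loci: int = 5000, n: int = 50,
    fst: float = 0.2, n_boot: int = 100,
) -> dict:
    """Divergence recovery: simulate two demes at F, check the bootstrap CI.

    Returns the fraction of replicates whose 95% CI covers the planted F and
    the mean point estimate.
    """
    covered = 0
    estimates = []
    for rep in range(n_reps):
        g, _ = simdata.simulate_genotypes(_two_deme(seed + rep, n_loci, n, fst))
        res = popstats.fst_from_matrix(
            g, (g.individuals["group"] == "G1").to_numpy(),
            (g.individuals["group"] == "G2").to_numpy(),
        )
        res = popstats.fst_bootstrap_ci(res, n_boot=n_boot, seed=seed + rep)
        covered += res.ci_low <= fst <= res.ci_high
        estimates.append(res.estimate)
    return {
        "coverage": covered / n_reps,
        "mean_estimate": float(np.mean(estimates)),
        "n_reps": n_reps,
    }


def permanova_calibration(
    seed: int = 0, n_datasets: int = 500, n_perm: int = 999, n: int = 21,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the permutation test under the null."""
    rej = 0
    for i in range(n_datasets):
        rng = np.random.default_rng(seed * 100_000 + i)
        y = rng.normal(size=(n, 3))
        x = rng.normal(size=n)
        res = permanova.permanova_test(
            y, pd.DataFrame({"x": x}), n_perm=n_perm, seed=seed * 100_000 + i
        )
        rej += res.table["p"].iloc[0] < alpha
    return {"rejection_rate": rej / n_datasets, "n_datasets": n_datasets}


def morpho_contrast_sweep(seed: int = 0, n_reps: int = 20, n_fish: int = 400) -> dict:
    """Plasticity-only lakes: raw traits cluster at the planted K, adjusted
    traits collapse to K = 1.  Returns per-outcome replicate fractions."""
    raw_ok = adj_ok = joint = 0
    for rep in range(n_reps):
        cfg = simdata.default_config(
            seed=seed + rep,
            lakes=(
                simdata.LakeSpec("L", "G", n_fish, ((160, 15, 0.5), (350, 40, 0.5))),
            ),
        )
        fish = simdata.simulate_phenotypes(cfg)
        traits = fish[[f"{t}_mm" for t in morphometrics.TRAIT_NAMES]]
        lengths = fish["total_length_mm"].to_numpy()
        raw = morphometrics.gmm_cluster(traits.to_numpy(), k_max=4, seed=seed + rep)
        model = morphometrics.fit_allometric_slope(traits, lengths)
        adjusted = morphometrics.size_adjust_frame(traits, lengths, model)
        adj = morphometrics.gmm_cluster(adjusted.to_numpy(), k_max=4, seed=seed + rep)
        raw_ok += raw.k == 2
        adj_ok += adj.k == 1
        joint += (raw.k == 2) and (adj.k == 1)
    return {
        "frac_raw_k_planted": raw_ok / n_reps,
        "frac_adjusted_k1": adj_ok / n_reps,
        "frac_joint": joint / n_reps,
        "n_reps": n_reps,
    }


def sexlink_sweep(seed: int = 0, n_reps: int = 20, n_loci: int = 5000) -> dict:
    """Recovery of the 5 planted sex loci with no false positives, and loss
    of the sex axis after removing the flagged chromosomes."""
    full_recovery = 0
    false_positives = 0
    axis_gone = 0
    for rep in range(n_reps):
        cfg = simdata.default_config(seed=seed + rep, n_loci=n_loci)
        study = simdata.simulate_study(cfg)
        g, _ = genomatrix.filter_genotypes(study.genotypes)
        pca_res = genomatrix.pca(genomatrix.genotype_covariance(g))
        known = study.fish.loc[study.fish["known_sex"], ["id", "sex"]]
        known = pd.Series(known["sex"].values, index=known["id"].values)
        putative, _ = sexlink.infer_sex_groups(pca_res, known, seed=seed + rep)
        report = sexlink.detect_sex_linked(
            g, putative, pca_result=pca_res, seed=seed + rep
        )
        classified = report.candidates[report.candidates["pattern"] != "ambiguous"]
        roles = g.loci["role"].to_numpy()
        planted = {int(j) for j in np.flatnonzero(np.isin(roles, ["xy", "female_only"]))}
        found = set(classified["locus_index"].astype(int))
        full_recovery += found >= planted
        false_positives += len(found - planted)
        g2, _ = sexlink.drop_sex_chromosomes(g, report)
        pca2 = genomatrix.pca(genomatrix.genotype_covariance(g2))
        try:
            sexlink.infer_sex_groups(pca2, known, seed=seed + rep)
        except ValueError:
            axis_gone += 1
    return {
        "sensitivity": full_recovery / n_reps,
        "false_positive_count": false_positives,
        "frac_no_axis_after_removal": axis_gone / n_reps,
        "n_reps": n_reps,
    }


def _panmictic_bimodal(seed: int, n: int = 60, n_loci: int = 300) -> tuple:
    cfg = simdata.default_config(
        seed=seed, n_loci=n_loci, fst_between_groups=0.0, fst_within_group=0.0,
        n_sex_loci_xy=0, n_sex_loci_female_only=0,
        lakes=(simdata.LakeSpec("L", "G", n, ((160, 15, 0.5), (350, 40, 0.5))),),
    )
    return simdata.simulate_genotypes(cfg)


def structure_negative_control(seed: int = 0, n_reps: int = 50) -> dict:
    """Plasticity-only lakes (bimodal lengths, panmictic genotypes): CV picks
    K = 1 and stock-vs-size-class association is nonsignificant."""
    joint = k1 = nonsig = 0
    for rep in range(n_reps):
        g, truth = _panmictic_bimodal(seed + rep)
        k, _ = structure.choose_k_cv(g, k_range=range(1, 4), seed=seed + rep)
        comp = np.array([truth["size_class_component"][i] for i in g.individuals["id"]])
        stock = structure.stock_mixture_em(
            g, K=2, n_boot=0, seed=seed + rep, size_class=comp
        )
        k1 += k == 1
        nonsig += stock.fisher_p >= 0.05
        joint += (k == 1) and (stock.fisher_p >= 0.05)
    return {
        "frac_k1_and_nonsignificant": joint / n_reps,
        "frac_k1": k1 / n_reps,
        "frac_fisher_nonsignificant": nonsig / n_reps,
        "n_reps": n_reps,
    }


def structure_positive_control(
    seed: int = 0, n: int = 30, n_loci: int = 500, fst: float = 0.2
) -> dict:
    """Planted genetic ecotypes aligned with size class: the pipeline must
    find them (K = 2, assignment accuracy > 95%)."""
    cfg = _two_deme(seed, n_loci, n, fst)
    g, _ = simdata.simulate_genotypes(cfg)
    # ecotypes: deme membership and size class coincide
    size_class = np.where(
        (g.individuals["group"] == "G1").to_numpy(), "small", "large"
    )
    k, _ = structure.choose_k_cv(g, k_range=range(1, 4), seed=seed)
    stock = structure.stock_mixture_em(g, K=2, n_boot=0, seed=seed, size_class=size_class)
    accuracy = structure.assignment_accuracy(stock.responsibilities, size_class)
    return {"selected_k": k, "assignment_accuracy_pct": accuracy, "fisher_p": stock.fisher_p}


def growth_checks(seed: int = 0, n_fish: int = 40) -> dict:
    """Back-calculation worked example and the zero-noise round trip."""
    rec = growth.OtolithRecord(
        fish_id="hand", capture_length=300.0, capture_radius=2.0,
        annulus_radii=np.array([1.0]),
    )
    hand = float(growth.back_calculate(rec, 17.0, 0.2)[0])
    cfg = simdata.default_config(
        seed=seed, otolith=simdata.OtolithSpec(noise_sd=0.0)
    )
    fish = simdata.simulate_phenotypes(cfg)
    recs, truth = simdata.simulate_otoliths(cfg, fish.head(n_fish))
    L0, O0, _ = growth.estimate_biological_intercept(recs)
    max_rel = 0.0
    for r in recs:
        la = growth.back_calculate(r, L0, O0)
        t = truth["lengths_at_age"][r.fish_id]
        max_rel = max(max_rel, float(np.max(np.abs(la - t) / t)))
    return {
        "hand_example_mm": hand,
        "roundtrip_max_rel_error": max_rel,
        "hatch_radius_estimate": O0,
        "hatch_radius_true": truth["hatch_radius"],
    }


def _plain_matrix(values: np.ndarray) -> genomatrix.GenotypeMatrix:
    n, L = values.shape
    loci = pd.DataFrame(
        {"chrom": ["chr01"] * L, "pos": np.arange(1, L + 1) * 1000,
         "ref": ["A"] * L, "alt": ["T"] * L, "counted_allele": ["T"] * L}
    )
    inds = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
    return genomatrix.GenotypeMatrix(values, loci, inds)


def diversity_closed_forms() -> dict:
    """Watterson's theta harmonic-number example and the all-heterozygote
    inbreeding coefficient."""
    # 5 diploids (n = 10 alleles), 5 of 1,000 sites segregating
    values = np.zeros((5, 1000))
    values[0, :5] = 1.0
    theta = popstats.watterson_theta(_plain_matrix(values))
    # every fish heterozygous at every site: maximal heterozygote excess
    fis = popstats.het_fis(_plain_matrix(np.ones((6, 10)))).fis
    return {"theta_w_example": theta, "fis_all_heterozygous": fis}
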