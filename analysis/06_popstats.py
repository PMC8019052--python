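#!/usr/bin/env python
"""Divergence and diversity after sex-chromosome removal.

Reich-Patterson F_ST (ratio of sums, 100-replicate locus bootstrap) between
lake groups and between lakes, Watterson's theta / heterozygosity / F_IS per
lake, and the within-lake relatedness distributions with their
unimodal-vs-bimodal verdicts (panmixia check).
"""

import os

import numpy as np
import pandas as pd

from charpop import genomatrix as gm
from charpop import popstats as ps

SEXLINK = "results/sexlink"
STUDY = "results/study"
OUT = "results/popstats"
SEED = 1


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    g = gm.read_vcf(f"{SEXLINK}/no_sex_chromosomes.vcf")
    fish = pd.read_csv(f"{STUDY}/fish.tsv", sep="\t").set_index("id")
    inds = g.individuals
    for col in ("lake", "group"):
        inds[col] = fish.loc[inds["id"], col].values

    rows = []
    units = [("group", u) for u in inds["group"].unique()]
    units += [("lake", u) for u in inds["lake"].unique()]
    pair_list = []
    for kind in ("group", "lake"):
        names = [u for k, u in units if k == kind]
        for i, u1 in enumerate(names):
            for u2 in names[i + 1 :]:
                res = ps.fst_from_matrix(
                    g, (inds[kind] == u1).to_numpy(), (inds[kind] == u2).to_numpy(),
                    (u1, u2),
                )
                res = ps.fst_bootstrap_ci(res, n_boot=100, seed=SEED)
                pair_list.append((kind, res))
                rows.append(
                    {"kind": kind, "pop1": u1, "pop2": u2, "fst": res.estimate,
                     "ci_low": res.ci_low, "ci_high": res.ci_high}
                )
    fst = pd.DataFrame(rows)
    fst.to_csv(f"{OUT}/fst.tsv", sep="\t", index=False)
    print(fst.round(4).to_string(index=False))

    div_rows = []
    for lake in inds["lake"].unique():
        s = ps.het_fis(g, (inds["lake"] == lake).to_numpy(), lake)
        div_rows.append(
            {"lake": lake, "theta_w": s.theta_w, "Ho": s.ho, "He": s.he,
             "He_corrected": s.he_corrected, "Fis": s.fis, "n": s.n_individuals}
        )
    div = pd.DataFrame(div_rows)
    div.to_csv(f"{OUT}/diversity.tsv", sep="\t", index=False)
    print(div.round(4).to_string(index=False))

    verdicts = []
    for lake in ("Fog3", "LTER348"):
        grm = ps.relatedness_grm(g, (inds["lake"] == lake).to_numpy())
        verdict, delta = ps.relatedness_modality(grm.offdiag(), seed=SEED)
        verdicts.append({"lake": lake, "verdict": verdict, "delta_bic": delta,
                         "mean_relatedness": float(np.mean(grm.offdiag()))})
        np.savetxt(f"{OUT}/relatedness_{lake}.tsv", grm.values, delimiter="\t")
    print(pd.DataFrame(verdicts).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
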