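#!/usr/bin/env python
"""Ecological predictors of char size structure (PERMANOVA).

Uses the study lakes' measured covariates (area, volume, depths, Secchi
depth, abundance, density) against the per-lake size-class composition from
the morphometric clustering.  Each candidate is tested singly, then the
additive model search looks for the combination with all terms significant
and the smallest residual sum of squares — the study found Secchi depth +
char density (+ lake group).
"""

import os

import pandas as pd

from charpop import permanova as pm
from charpop.lakes import LAKE_TABLE

MORPHO = "results/morphometrics"
OUT = "results/permanova"
SEED = 1
N_PERM = 9999


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    fish = pd.read_csv(f"{MORPHO}/fish_classified.tsv", sep="\t")
    comp = (
        fish.groupby("lake")["size_class"].value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    lakes = LAKE_TABLE.set_index("lake").loc[comp.index]
    lakes["density_by_volume"] = lakes["abundance"] / lakes["volume_1e5_m3"]

    candidates = {
        "lake_group": lakes["group"],
        "abundance": lakes["abundance"],
        "density_area": lakes["density_fish_ha"],
        "density_volume": lakes["density_by_volume"],
        "secchi_depth": lakes["secchi_depth_m"],
        "max_depth": lakes["max_depth_m"],
        "mean_depth": lakes["mean_depth_m"],
        "surface_area": lakes["surface_area_ha"],
        "prop_area_lt3m": lakes["prop_area_lt3m"],
        "prop_vol_lt3m": lakes["prop_vol_lt3m"],
        "volume": lakes["volume_1e5_m3"],
    }
    preds = pd.DataFrame(candidates).reset_index(drop=True)
    y = comp.to_numpy()

    single_rows = []
    for term in preds.columns:
        res = pm.permanova_test(y, preds, terms=[term], n_perm=N_PERM, seed=SEED)
        r = res.table.iloc[0]
        single_rows.append(
            {"term": term, "df": r["df"], "ss": r["ss"], "F": r["pseudo_f"], "p": r["p"]}
        )
    singles = pd.DataFrame(single_rows)
    singles.to_csv(f"{OUT}/single_term_tests.tsv", sep="\t", index=False)
    print("single-term tests:")
    print(singles.round(3).to_string(index=False))

    best, table = pm.model_search(
        y, preds[["lake_group", "secchi_depth", "density_area", "abundance"]],
        max_terms=3, n_perm=999, seed=SEED,
    )
    table.to_csv(f"{OUT}/model_search.tsv", sep="\t", index=False)
    if best is None:
        print("\nno additive model had all terms significant at alpha = 0.05")
        print(table.head(5).round(3).to_string(index=False))
    else:
        print(f"\nbest additive model: {best.formula}")
        print(best.table.round(3).to_string(index=False))
        print(f"residual SS = {best.residual_ss:.3f} (df = {best.residual_df})")


if __name__ == "__main__":
    main()
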