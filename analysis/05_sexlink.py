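#!/usr/bin/env python
"""Sex-linked SNP detection and chromosome exclusion.

Scans PCA axes for the one that splits the fish of known sex, runs DAPC
between the putative sexes, classifies high-loading SNPs by their
heterozygosity/call-rate patterns (males heterogametic), and removes the
implicated chromosomes, writing the cleaned VCF used by later stages.
"""

import os

import pandas as pd

from charpop import genomatrix as gm
from charpop import sexlink

GENOMICS = "results/genomics"
STUDY = "results/study"
OUT = "results/sexlink"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    g = gm.read_vcf(f"{GENOMICS}/filtered.vcf")
    fish = pd.read_csv(f"{STUDY}/fish.tsv", sep="\t").set_index("id")
    for col in ("lake", "group", "sex", "known_sex"):
        g.individuals[col] = fish.loc[g.individuals["id"], col].values

    pca = gm.pca(gm.genotype_covariance(g))
    known = fish.loc[fish["known_sex"], "sex"]
    putative, axis = sexlink.infer_sex_groups(pca, known)
    truth = fish["sex"]
    agree = (putative.reindex(truth.index) == truth).mean()
    print(f"sex axis: PC{axis + 1}; putative-sex agreement with truth {agree:.1%}")

    report = sexlink.detect_sex_linked(g, putative, pca_result=pca)
    report.candidates.to_csv(f"{OUT}/candidates.tsv", sep="\t", index=False)
    classified = report.candidates[report.candidates["pattern"] != "ambiguous"]
    print(classified[["chrom", "pos", "pattern", "loading_rank"]].to_string(index=False))
    print(
        f"flagged chromosomes: {report.flagged_chromosomes}; "
        f"F_ST between putative sexes = {report.fst_between_sexes:.4f}"
    )

    cleaned, manifest = sexlink.drop_sex_chromosomes(g, report)
    gm.write_vcf(cleaned, f"{OUT}/no_sex_chromosomes.vcf")
    print(
        f"removed {manifest['n_loci_removed']} loci on "
        f"{len(manifest['dropped_chromosomes'])} chromosomes; "
        f"{manifest['n_loci_retained']} retained"
    )


if __name__ == "__main__":
    main()
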