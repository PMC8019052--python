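"""Sex-linked SNP detection and chromosome exclusion.

In salmonids the sex-determining region is small and males are the
heterogametic sex, so sex-linked SNPs show up as loci that are heterozygous
in (nearly) every male and monomorphic in females -- or as loci genotyped in
only one sex.  The workflow here mirrors the PCA-first approach: find the
principal component axis that splits individuals into two clusters matching
the fish of known sex, assign putative sex from that split, run a
discriminant analysis of principal components (DAPC) between the putative
sexes, and inspect the SNPs with the highest discriminant loadings for the
diagnostic heterozygosity / call-rate patterns.  Chromosomes carrying any
classified SNP are then removed from further population analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture

from .genomatrix import GenotypeMatrix, PCAResult, genotype_covariance, pca

__all__ = [
    "DAPCResult",
    "SexLinkReport",
    "infer_sex_groups",
    "dapc",
    "detect_sex_linked",
    "drop_sex_chromosomes",
]


@dataclass
class DAPCResult:
    n_pc: int
    ind_scores: np.ndarray  # individuals x discriminant axes
    posteriors: np.ndarray  # individuals x groups
    groups: np.ndarray  # group label per column of posteriors
    assignments: np.ndarray
    cv_table: pd.DataFrame | None  # n_pc candidates vs RMSE
    lda: LinearDiscriminantAnalysis = field(repr=False, default=None)


@dataclass
class SexLinkReport:
    candidates: pd.DataFrame
    # columns: locus_index, chrom, pos, loading, loading_rank, het_male,
    # het_female, call_rate_male, call_rate_female, pattern
    flagged_chromosomes: list
    n_pc: int
    cv_error: float | None
    loading_threshold: float
    fst_between_sexes: float | None = None


def infer_sex_groups(
    pca_result: PCAResult,
    known_sex: pd.Series,
    n_axes: int = 10,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Find the PC axis whose two-cluster split separates the known sexes.

    ``known_sex`` maps individual id -> 'male'/'female' for the fish of known
    sex.  Each of the first ``n_axes`` axes is split by a 1-D two-component
    Gaussian mixture; an axis qualifies only if (a) the two-component fit
    beats the one-component fit by dBIC >= 3 (a unimodal noise axis can
    split a handful of known fish correctly by chance), (b) every known male
    falls in one cluster with every known female in the other, and (c) when
    individual metadata carries a ``lake`` column, both clusters occur
    within every well-sampled lake -- sexes are interleaved within lakes,
    whereas a population-structure axis splits along them and can match a
    few known fish coincidentally.  Returns (putative sex per individual,
    0-based axis index); raises if no axis separates them.
    """
    ids = pca_result.individuals["id"].astype(str)
    known = {str(k): v for k, v in known_sex.items()}
    known_idx = np.flatnonzero(ids.isin(known.keys()).values)
    ksex = np.array([known[ids.iloc[i]] for i in known_idx])
    if (ksex == "male").sum() < 2 or (ksex == "female").sum() < 2:
        raise ValueError("need at least 2 known-sex individuals of each sex")
    n_axes = min(n_axes, pca_result.scores.shape[1])
    for ax in range(n_axes):
        s = pca_result.scores[:, ax : ax + 1]
        if np.ptp(s) == 0:
            continue
        gm = GaussianMixture(n_components=2, n_init=5, random_state=seed).fit(s)
        gm1 = GaussianMixture(n_components=1, random_state=seed).fit(s)
        if gm1.bic(s) - gm.bic(s) < 3.0:  # not meaningfully bimodal
            continue
        lab = gm.predict(s)
        klab = lab[known_idx]
        male_lab = set(klab[ksex == "male"])
        female_lab = set(klab[ksex == "female"])
        if len(male_lab) == 1 and len(female_lab) == 1 and male_lab != female_lab:
            if "lake" in pca_result.individuals.columns:
                lakes = pca_result.individuals["lake"].to_numpy()
                interleaved = True
                for lk in np.unique(lakes):
                    sub = lab[lakes == lk]
                    # ~1:1 sex ratios make a pure-cluster lake of 20+ fish
                    # essentially impossible on a true sex axis
                    if len(sub) >= 20 and min(
                        (sub == 0).mean(), (sub == 1).mean()
                    ) < 0.1:
                        interleaved = False
                        break
                if not interleaved:
                    continue
            male_cluster = male_lab.pop()
            putative = pd.Series(
                np.where(lab == male_cluster, "male", "female"),
                index=ids.values,
                name="putative_sex",
            )
            return putative, ax
    raise ValueError(
        f"no axis among the first {n_axes} separates the known-sex individuals"
    )


def dapc(
    scores: np.ndarray,
    groups: np.ndarray,
    n_pc: int | None = None,
    n_reps: int = 30,
    holdout_frac: float = 0.1,
    seed: int = 0,
) -> DAPCResult:
    """Discriminant analysis on the leading PC scores.

    If ``n_pc`` is not given it is chosen by stratified repeated holdout
    (``n_reps`` repetitions of a 90/10 split), keeping the candidate with the
    lowest root mean squared assignment error.  ``n_pc`` values at or above
    n_individuals - n_groups are reduced with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels, y = np.unique(groups, return_inverse=True)
    if len(labels) < 2 or np.min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    n = scores.shape[0]
    cap = n - len(labels)
    cv_table = None
    if n_pc is None:
        candidates = [c for c in (1, 2, 3, 5, 8, 10, 15, 20, 30, 50) if c <= min(cap, scores.shape[1])]
        rng = np.random.default_rng(seed)
        rows = []
        for c in candidates:
            errs = []
            for _ in range(n_reps):
                test_idx = _stratified_holdout(y, holdout_frac, rng)
                train = np.setdiff1d(np.arange(n), test_idx)
                if len(np.unique(y[train])) < len(labels):
                    continue
                lda = LinearDiscriminantAnalysis().fit(scores[train, :c], y[train])
                pred = lda.predict(scores[test_idx, :c])
                errs.append(np.mean(pred != y[test_idx]))
            rows.append({"n_pc": c, "rmse": float(np.sqrt(np.mean(np.square(errs))))})
        cv_table = pd.DataFrame(rows)
        n_pc = int(cv_table.loc[cv_table["rmse"].idxmin(), "n_pc"])
    if n_pc >= n - len(labels) + 1:
        warnings.warn(f"n_pc={n_pc} too large; reduced to {cap}")
        n_pc = cap
    n_pc = min(n_pc, scores.shape[1])
    lda = LinearDiscriminantAnalysis().fit(scores[:, :n_pc], y)
    post = lda.predict_proba(scores[:, :n_pc])
    return DAPCResult(
        n_pc=n_pc,
        ind_scores=lda.transform(scores[:, :n_pc]),
        posteriors=post,
        groups=labels,
        assignments=labels[post.argmax(axis=1)],
        cv_table=cv_table,
        lda=lda,
    )


def _stratified_holdout(y: np.ndarray, frac: float, rng) -> np.ndarray:
    idx = []
    for g in np.unique(y):
        members = np.flatnonzero(y == g)
        k = max(1, int(round(frac * len(members))))
        idx.append(rng.choice(members, size=k, replace=False))
    return np.concatenate(idx)


def snp_loadings(g: GenotypeMatrix, axis: np.ndarray) -> np.ndarray:
    """Absolute per-SNP loading on an individual-space axis.

    Centres each locus over nonmissing calls (missing -> 0) and projects it
    onto the axis; equivalent to mapping discriminant coefficients back
    through the PC loadings of the genotype covariance decomposition.
    """
    v = g.values
    called = ~np.isnan(v)
    mean = np.nanmean(np.where(called, v, np.nan), axis=0)
    w = np.where(called, v - mean, 0.0)
    axis = np.asarray(axis, dtype=float).ravel()
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("zero discriminant axis")
    return np.abs(w.T @ (axis / norm))


def detect_sex_linked(
    g: GenotypeMatrix,
    putative_sex: pd.Series,
    loading_quantile: float = 0.999,
    min_candidates: int = 3,
    pca_result: PCAResult | None = None,
    seed: int = 0,
) -> SexLinkReport:
    """Classify high-loading SNPs into sex-linkage patterns.

    SNPs above the ``loading_quantile`` of DAPC loadings (at least
    ``min_candidates`` inspected) are classified:

    * XY-like -- heterozygosity strictly > 0.95 in one sex, < 0.05 in the
      other with a single dominant homozygote class there;
    * female-only-genotyped -- call rate < 0.05 in males and > 0.5 in
      females (or the symmetric male-only pattern);
    * ambiguous otherwise.

    Chromosomes with any classified (non-ambiguous) SNP are flagged.
    """
    ids = g.individuals["id"].astype(str).values
    sex = putative_sex.reindex(ids).values
    is_male = sex == "male"
    is_female = sex == "female"
    if is_male.sum() == 0 or is_female.sum() == 0:
        raise ValueError("both putative sexes must be nonempty")

    if pca_result is None or pca_result.scores.shape[1] == 0:
        pca_result = pca(genotype_covariance(g))
    d = dapc(pca_result.scores, np.where(is_male, "male", "female"), seed=seed)
    loadings = snp_loadings(g, d.ind_scores[:, 0])
    threshold = float(np.quantile(loadings, loading_quantile))
    cand = np.flatnonzero(loadings >= threshold)
    if len(cand) < min_candidates:
        cand = np.argsort(loadings)[::-1][:min_candidates]
    if len(cand) == 0:
        raise ValueError("no SNPs above the loading quantile")
    # loci genotyped in essentially one sex carry their signal in the call
    # pattern, not the genotype values, so loadings cannot rank them; screen
    # call rates directly and add matches to the candidate set
    called = ~np.isnan(g.values)
    cr_m = called[is_male].mean(axis=0)
    cr_f = called[is_female].mean(axis=0)
    one_sex = ((cr_m < 0.05) & (cr_f > 0.5)) | ((cr_f < 0.05) & (cr_m > 0.5))
    cand = np.union1d(cand, np.flatnonzero(one_sex))

    rank_of = {j: r + 1 for r, j in enumerate(np.argsort(loadings)[::-1])}
    rows = []
    for j in cand:
        col = g.values[:, j]
        row = {"locus_index": int(j), "chrom": g.loci["chrom"].iloc[j],
               "pos": int(g.loci["pos"].iloc[j]), "loading": float(loadings[j]),
               "loading_rank": rank_of[int(j)]}
        stats = {}
        for name, mask in (("male", is_male), ("female", is_female)):
            sub = col[mask]
            called = ~np.isnan(sub)
            stats[f"call_rate_{name}"] = float(called.mean()) if len(sub) else np.nan
            if called.sum() > 0:
                stats[f"het_{name}"] = float((sub[called] == 1).mean())
                counts = np.bincount(sub[called].astype(int), minlength=3)
                hom = counts[0] + counts[2]
                stats[f"dominant_hom_{name}"] = (
                    float(max(counts[0], counts[2]) / hom) if hom > 0 else np.nan
                )
            else:
                stats[f"het_{name}"] = np.nan
                stats[f"dominant_hom_{name}"] = np.nan
        row.update(stats)
        row["pattern"] = _classify(stats)
        rows.append(row)
    candidates = pd.DataFrame(rows).sort_values("loading_rank").reset_index(drop=True)
    classified = candidates[candidates["pattern"] != "ambiguous"]
    flagged = sorted(classified["chrom"].unique().tolist())

    from .popstats import fst_from_matrix

    fst_sex = fst_from_matrix(g, is_male, is_female, ("male", "female")).estimate
    return SexLinkReport(
        candidates=candidates,
        flagged_chromosomes=flagged,
        n_pc=d.n_pc,
        cv_error=(
            float(d.cv_table["rmse"].min()) if d.cv_table is not None else None
        ),
        loading_threshold=threshold,
        fst_between_sexes=fst_sex,
    )


def _classify(s: dict) -> str:
    def xy(hi: str, lo: str) -> bool:
        return (
            not np.isnan(s[f"het_{hi}"])
            and s[f"het_{hi}"] > 0.95
            and not np.isnan(s[f"het_{lo}"])
            and s[f"het_{lo}"] < 0.05
            and not np.isnan(s[f"dominant_hom_{lo}"])
            and s[f"dominant_hom_{lo}"] > 0.95
        )

    def only(present: str, absent: str) -> bool:
        return s[f"call_rate_{absent}"] < 0.05 and s[f"call_rate_{present}"] > 0.5

    if xy("male", "female") or xy("female", "male"):
        return "XY-like"
    if only("female", "male"):
        return "female-only-genotyped"
    if only("male", "female"):
        return "male-only-genotyped"
    return "ambiguous"


def drop_sex_chromosomes(
    g: GenotypeMatrix, report: SexLinkReport | list
) -> tuple[GenotypeMatrix, dict]:
    """Remove every locus on the flagged chromosomes.

    Accepts a report or a plain chromosome list.  Flagging every chromosome
    is an error; names absent from the matrix warn and no-op.
    """
    chroms = report.flagged_chromosomes if isinstance(report, SexLinkReport) else list(report)
    present = set(g.loci["chrom"].unique())
    absent = [c for c in chroms if c not in present]
    if absent:
        warnings.warn(f"chromosomes not in matrix, ignored: {absent}")
    to_drop = set(chroms) & present
    if to_drop == present and present:
        raise ValueError("refusing to drop every chromosome")
    keep = ~g.loci["chrom"].isin(to_drop).values
    manifest = {
        "dropped_chromosomes": sorted(to_drop),
        "n_loci_removed": int((~keep).sum()),
        "n_loci_retained": int(keep.sum()),
    }
    return g.take_loci(np.flatnonzero(keep)), manifest
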