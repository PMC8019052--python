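"""Divergence and diversity statistics from called genotypes.

Implements the Reich-Patterson (Hudson-family) F_ST estimator with a
locus-bootstrap confidence interval, the folded site frequency spectrum and
Watterson's theta, observed/expected heterozygosity and F_IS, and the
additive (VanRaden/Endelman-style) genomic relationship matrix with a
mixture-based check for bimodality of pairwise relatedness.

All estimators work from the 0/1/2 minor-allele-count matrix; sites with
fewer than two called allele copies in a unit are excluded per statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomatrix import GenotypeMatrix

__all__ = [
    "FstResult",
    "DiversitySummary",
    "RelatednessMatrix",
    "fst_reich_patterson",
    "fst_from_matrix",
    "fst_bootstrap_ci",
    "folded_sfs",
    "watterson_theta",
    "het_fis",
    "relatedness_grm",
    "relatedness_modality",
]


@dataclass
class FstResult:
    pop1: str
    pop2: str
    estimate: float
    numerators: np.ndarray  # per-locus N
    denominators: np.ndarray  # per-locus D
    n_loci: int
    n_excluded: int
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    undefined: bool = False


@dataclass
class DiversitySummary:
    unit: str
    theta_w: float
    ho: float
    he: float  # uncorrected 2pq, site-averaged
    he_corrected: float  # with the n/(n-1) small-sample factor
    fis: float
    n_individuals: int
    n_sites: int
    undefined_fis: bool = False


@dataclass
class RelatednessMatrix:
    values: np.ndarray
    normalization: float
    n_imputed: int
    individuals: pd.DataFrame
    modality: str | None = None
    modality_delta_bic: float | None = None

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Reich-Patterson F_ST


def fst_reich_patterson(
    counts1: tuple[np.ndarray, np.ndarray],
    counts2: tuple[np.ndarray, np.ndarray],
    labels: tuple[str, str] = ("pop1", "pop2"),
) -> FstResult:
    """Ratio-of-sums Reich-Patterson F_ST from per-locus allele counts.

    ``counts1``/``counts2`` are (allele count a, total called copies n) per
    locus.  Per locus, with h = a(n-a)/(n(n-1)),

        N = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2,   D = N + h1 + h2

    and the estimate is sum(N)/sum(D) -- unbiased for small, unequal sample
    sizes.  Loci with n < 2 in either population are excluded (counted).
    """
    a1, n1 = (np.asarray(x, dtype=float) for x in counts1)
    a2, n2 = (np.asarray(x, dtype=float) for x in counts2)
    ok = (n1 >= 2) & (n2 >= 2)
    n_excluded = int((~ok).sum())
    a1, n1, a2, n2 = a1[ok], n1[ok], a2[ok], n2[ok]
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
    N = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    D = N + h1 + h2
    sD = D.sum()
    undefined = bool(sD == 0)
    est = np.nan if undefined else float(N.sum() / sD)
    if undefined:
        warnings.warn("all loci monomorphic in both populations; F_ST undefined")
    return FstResult(
        pop1=labels[0],
        pop2=labels[1],
        estimate=est,
        numerators=N,
        denominators=D,
        n_loci=int(ok.sum()),
        n_excluded=n_excluded,
        undefined=undefined,
    )


def fst_from_matrix(
    g: GenotypeMatrix, mask1: np.ndarray, mask2: np.ndarray,
    labels: tuple[str, str] = ("pop1", "pop2"),
) -> FstResult:
    """Reich-Patterson F_ST between two individual subsets of a matrix."""
    a1, n1 = g.allele_counts(np.flatnonzero(np.asarray(mask1)))
    a2, n2 = g.allele_counts(np.flatnonzero(np.asarray(mask2)))
    return fst_reich_patterson((a1, n1), (a2, n2), labels)


def fst_bootstrap_ci(
    result: FstResult, n_boot: int = 100, seed: int | None = None
) -> FstResult:
    """Percentile 95% CI by resampling loci with replacement.

    Replicates with a zero denominator sum are redrawn (count warned).
    Returns a copy of ``result`` with ci_low/ci_high/n_bootstrap filled in.
    """
    if result.n_loci < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    if n_boot == 1:
        warnings.warn("n_boot = 1: CI is a single replicate value")
    rng = np.random.default_rng(seed)
    N, D = result.numerators, result.denominators
    L = len(N)
    reps = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, L, size=L)
            sD = D[idx].sum()
            if sD != 0:
                break
            n_redrawn += 1
        reps[b] = N[idx].sum() / sD
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap replicates")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    out = FstResult(**{**result.__dict__})
    out.ci_low, out.ci_high, out.n_bootstrap = float(lo), float(hi), n_boot
    return out


# ---------------------------------------------------------------------------
# Diversity


def folded_sfs(
    g: GenotypeMatrix, unit: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Folded site frequency spectrum over a subset of individuals.

    Per site the minor-allele count over nonmissing calls is tallied into
    bins 0..floor(max allele total / 2).  Returns (spectrum, per-site allele
    totals); sites with < 2 called copies get total 0 and are not tallied.
    """
    rows = None if unit is None else np.flatnonzero(np.asarray(unit))
    a, n = g.allele_counts(rows)
    valid = n >= 2
    minor = np.minimum(a, n - a).astype(int)
    max_bin = int(np.max(n[valid]) // 2) if valid.any() else 0
    spectrum = np.zeros(max_bin + 1, dtype=int)
    np.add.at(spectrum, np.minimum(minor[valid], max_bin), 1)
    n_out = np.where(valid, n, 0).astype(int)
    return spectrum, n_out


def watterson_theta(g: GenotypeMatrix, unit: np.ndarray | None = None) -> float:
    """Watterson's theta per site from segregating-site counts.

    theta_w = sum_sites [ segregating / a(n_site) ] / L with
    a(n) = sum_{i=1..n-1} 1/i, n_site the called allele copies at the site,
    and L the number of sites with n_site >= 2.
    """
    rows = None if unit is None else np.flatnonzero(np.asarray(unit))
    a, n = g.allele_counts(rows)
    valid = n >= 2
    if not valid.any():
        raise ValueError("no sites with >= 2 called allele copies")
    a, n = a[valid], n[valid]
    seg = (a > 0) & (a < n)
    nmax = int(n.max())
    harm = np.concatenate([[np.nan, np.nan], np.cumsum(1.0 / np.arange(1, nmax))])
    # harm[k] = a(k) = sum_{i=1}^{k-1} 1/i for k >= 2
    L = int(valid.sum())
    return float(np.sum(seg / harm[n.astype(int)]) / L)


def het_fis(
    g: GenotypeMatrix, unit: np.ndarray | None = None, label: str = "all"
) -> DiversitySummary:
    """Observed/expected heterozygosity and F_IS for one unit.

    Ho is the fraction heterozygous among called genotypes per site; He is
    2*p*(1-p) (reported also with the n/(n-1) small-sample factor, n = called
    individuals).  F_IS = 1 - mean(Ho)/mean(He) uses the uncorrected He, so a
    site where every fish is heterozygous at p = 0.5 gives exactly -1.
    """
    rows = None if unit is None else np.flatnonzero(np.asarray(unit))
    v = g.values if rows is None else g.values[rows]
    called = ~np.isnan(v)
    n_ind = called.sum(axis=0)
    valid = n_ind >= 2
    if not valid.any():
        raise ValueError("no sites with >= 2 called individuals")
    vv = v[:, valid]
    cc = called[:, valid]
    nn = n_ind[valid].astype(float)
    ho = np.where(cc, vv == 1, False).sum(axis=0) / nn
    p = np.nansum(vv, axis=0) / (2.0 * nn)
    he = 2.0 * p * (1.0 - p)
    hec = he * nn / (nn - 1.0)
    mean_ho, mean_he, mean_hec = float(ho.mean()), float(he.mean()), float(hec.mean())
    undefined = mean_he == 0
    fis = np.nan if undefined else 1.0 - mean_ho / mean_he
    if undefined:
        warnings.warn("mean expected heterozygosity is 0; F_IS undefined")
    return DiversitySummary(
        unit=label,
        theta_w=watterson_theta(g, unit),
        ho=mean_ho,
        he=mean_he,
        he_corrected=mean_hec,
        fis=float(fis),
        n_individuals=int(v.shape[0]),
        n_sites=int(valid.sum()),
        undefined_fis=undefined,
    )


# ---------------------------------------------------------------------------
# Relatedness


def relatedness_grm(
    g: GenotypeMatrix, unit: np.ndarray | None = None
) -> RelatednessMatrix:
    """Additive genomic relationship matrix G = W W' / (2 sum p(1-p)).

    W centres genotypes by twice the allele frequency; missing entries are
    mean-imputed (centred value 0, count reported).  Monomorphic loci (p = 0
    or 1) and loci with no calls are excluded from both W and the
    normalization constant.
    """
    rows = None if unit is None else np.flatnonzero(np.asarray(unit))
    v = g.values if rows is None else g.values[rows]
    inds = g.individuals if rows is None else g.individuals.iloc[rows].reset_index(drop=True)
    called = ~np.isnan(v)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(v, axis=0) / (2.0 * np.where(n_called > 0, n_called, 1))
    keep = (n_called > 0) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("normalization constant is 0: no polymorphic loci")
    vv = v[:, keep]
    pp = p[keep]
    n_imputed = int(np.isnan(vv).sum())
    W = np.where(np.isnan(vv), 0.0, vv - 2.0 * pp)
    const = 2.0 * float(np.sum(pp * (1.0 - pp)))
    G = (W @ W.T) / const
    return RelatednessMatrix(
        values=G, normalization=const, n_imputed=n_imputed, individuals=inds
    )


def relatedness_modality(
    values: np.ndarray, delta_threshold: float = 3.0, seed: int | None = 0
) -> tuple[str, float]:
    """Unimodal-vs-bimodal verdict on pairwise relatedness values.

    Fits 1- and 2-component Gaussian mixtures; bimodal iff the 2-component
    BIC (higher-is-better convention) exceeds the 1-component BIC by at
    least ``delta_threshold``.  A panmictic population is expected unimodal.
    """
    from .morphometrics import gmm_cluster

    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 10:
        raise ValueError("need at least 10 relatedness values")
    if np.ptp(values) == 0:
        warnings.warn("constant relatedness values; degenerate, called unimodal")
        return "unimodal", 0.0
    model = gmm_cluster(values[:, None], k_max=2, seed=seed, families=("full",))
    tab = model.bic_table
    bic1 = tab.loc[tab["k"] == 1, "bic"].max()
    bic2 = tab.loc[tab["k"] == 2, "bic"].max()
    delta = float(bic2 - bic1)
    return ("bimodal" if delta >= delta_threshold else "unimodal"), delta
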