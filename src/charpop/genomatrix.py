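"""Genotype container, SNP filtering, pairwise-complete covariance and PCA.

Genotypes are held as an individuals x loci matrix of minor-allele counts
(0/1/2) with ``NaN`` marking missing calls.  The covariance between two
individuals is computed over the loci both were genotyped at ("shared loci"),
so PCA tolerates the patchy missingness typical of genotyping-by-sequencing
data without imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "SNPFilterConfig",
    "FilterReport",
    "PCAResult",
    "read_vcf",
    "write_vcf",
    "filter_genotypes",
    "genotype_covariance",
    "pca",
    "pc_length_association",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, entries counting the minor allele.

    ``values`` is float with NaN for missing calls.  ``loci`` carries one row
    per locus (chrom, pos, ref, alt, counted allele); ``individuals`` one row
    per fish (id plus whatever phenotype columns the caller attaches).
    """

    values: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x loci)")
        n, m = self.values.shape
        if len(self.individuals) != n or len(self.loci) != m:
            raise ValueError("metadata dimensions do not match genotype matrix")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (counted-allele copies, total nonmissing allele copies)."""
        v = self.values if rows is None else self.values[rows]
        called = ~np.isnan(v)
        a = np.nansum(v, axis=0)
        n = 2.0 * called.sum(axis=0)
        return a, n

    def maf(self) -> np.ndarray:
        """Minor allele frequency over nonmissing calls (NaN if no calls)."""
        a, n = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, a / np.where(n > 0, n, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def site_missing_frac(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def individual_missing_frac(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            self.loci.iloc[idx].reset_index(drop=True),
            self.individuals.copy(),
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            self.loci.copy(),
            self.individuals.iloc[idx].reset_index(drop=True),
        )

    def subset_by_ids(self, ids) -> "GenotypeMatrix":
        pos = self.individuals.reset_index(drop=True)
        lookup = pd.Series(pos.index.values, index=pos["id"].values)
        return self.take_individuals(lookup.loc[list(ids)].values)


@dataclass(frozen=True)
class SNPFilterConfig:
    """Thresholds of the SNP filtering recipe.

    Defaults follow the study pipeline: sites with more than 50% missing
    calls removed, minor allele frequency strictly greater than 0.01, one
    site per 90 bp (GBS-locus thinning), then individuals with more than 80%
    missing cells dropped.  ``max_missing_frac=0.3`` gives the stringent
    variant used as a robustness check.
    """

    max_missing_frac: float = 0.5
    min_maf: float = 0.01
    thin_bp: int = 90
    max_ind_missing_frac: float = 0.8

    def __post_init__(self) -> None:
        for name in ("max_missing_frac", "min_maf", "max_ind_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.thin_bp < 0:
            raise ValueError("thin_bp must be >= 0")


@dataclass
class FilterReport:
    n_input_loci: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_thin: int = 0
    n_retained_loci: int = 0
    n_input_individuals: int = 0
    n_removed_individuals: int = 0
    empty: bool = False
    config: SNPFilterConfig | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["config"] = None if self.config is None else self.config.__dict__.copy()
        return d


@dataclass
class PCAResult:
    covariance: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    proportion_variance: np.ndarray
    individuals: pd.DataFrame
    shared_loci: np.ndarray | None = None
    n_zero_shared_pairs: int = 0


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic diploid SNPs from a VCF into a GenotypeMatrix.

    Multiallelic sites are dropped with a warning; haploid genotype records
    raise.  Genotypes are recoded to count the minor allele, determined per
    locus over nonmissing calls (ties count the ALT allele).
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes
        alt_counts = np.full(len(samples), np.nan)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS} sample {samples[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                continue
            alt_counts[i] = alleles[0] + alleles[1]
        rows.append(alt_counts)
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_multi:
        warnings.warn(f"dropped {n_multi} multiallelic sites")
    if not rows:
        raise ValueError("no biallelic SNPs found in VCF")
    values = np.vstack(rows).T  # individuals x loci
    loci = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])

    # recode to minor-allele counts
    called = ~np.isnan(values)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(values, axis=0) / (2.0 * np.where(n_called > 0, n_called, 1))
    flip = (alt_freq > 0.5) & (n_called > 0)
    values[:, flip] = 2.0 - values[:, flip]
    loci["counted_allele"] = np.where(flip, loci["ref"], loci["alt"])
    loci["maf_defined"] = n_called > 0
    individuals = pd.DataFrame({"id": samples})
    return GenotypeMatrix(values, loci, individuals)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as VCF 4.2 with GT only (./. for missing)."""
    counted_is_alt = g.loci.get("counted_allele")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        ids = "\t".join(str(s) for s in g.individuals["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(g.n_loci):
            row = g.loci.iloc[j]
            ref = row.get("ref", "A")
            alt = row.get("alt", "T")
            col = g.values[:, j]
            # values count the minor allele; emit ALT counts
            if counted_is_alt is not None and row["counted_allele"] == ref:
                col = 2.0 - col
            gts = "\t".join("./." if np.isnan(x) else gt_codes[float(x)] for x in col)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering


def filter_genotypes(
    g: GenotypeMatrix, cfg: SNPFilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP filters in order: site missingness, MAF, positional
    thinning, then individual missingness over the retained sites."""
    cfg = cfg or SNPFilterConfig()
    report = FilterReport(
        n_input_loci=g.n_loci, n_input_individuals=g.n_individuals, config=cfg
    )

    keep = g.site_missing_frac() <= cfg.max_missing_frac
    report.n_removed_missing = int((~keep).sum())
    g2 = g.take_loci(np.flatnonzero(keep))

    if g2.n_loci == 0:
        report.empty = True
        report.n_retained_loci = 0
        return g2, report

    maf = g2.maf()
    keep = np.nan_to_num(maf, nan=0.0) > cfg.min_maf
    report.n_removed_maf = int((~keep).sum())
    g2 = g2.take_loci(np.flatnonzero(keep))
    if g2.n_loci == 0:
        report.empty = True
        return g2, report

    if cfg.thin_bp > 0:
        keep_idx = _thin_positions(g2.loci["chrom"].values, g2.loci["pos"].values, cfg.thin_bp)
        report.n_removed_thin = g2.n_loci - len(keep_idx)
        g2 = g2.take_loci(keep_idx)
    report.n_retained_loci = g2.n_loci
    if g2.n_loci == 0:
        report.empty = True
        return g2, report

    ind_keep = g2.individual_missing_frac() <= cfg.max_ind_missing_frac
    report.n_removed_individuals = int((~ind_keep).sum())
    g2 = g2.take_individuals(np.flatnonzero(ind_keep))
    if g2.n_individuals == 0:
        report.empty = True
    return g2, report


def _thin_positions(chrom: np.ndarray, pos: np.ndarray, thin_bp: int) -> np.ndarray:
    """Keep the first site of each run: a site survives only if it is at
    least ``thin_bp`` from the last *kept* site on the same chromosome."""
    keep: list[int] = []
    last_chrom = None
    last_pos = -np.inf
    for i in range(len(pos)):
        if chrom[i] != last_chrom or pos[i] - last_pos >= thin_bp:
            keep.append(i)
            last_chrom = chrom[i]
            last_pos = pos[i]
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# Covariance / PCA


def genotype_covariance(g: GenotypeMatrix) -> PCAResult:
    """Pairwise-complete genotype covariance among individuals.

    Loci are centred by their mean genotype over nonmissing calls; the (i, j)
    entry is the mean product of centred genotypes over loci where both i and
    j have calls.  Pairs sharing zero loci are flagged and set to 0.
    """
    if g.n_individuals < 2 or g.n_loci < 2:
        raise ValueError("need at least 2 individuals and 2 loci")
    v = g.values
    called = ~np.isnan(v)
    mean = np.nanmean(np.where(called, v, np.nan), axis=0)
    w = np.where(called, v - mean, 0.0)
    shared = called.astype(float) @ called.T.astype(float)
    prod = w @ w.T
    n_zero = int((shared == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} individual pairs share no loci; covariance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(shared > 0, prod / np.where(shared > 0, shared, 1), 0.0)
    cov = 0.5 * (cov + cov.T)
    return PCAResult(
        covariance=cov,
        eigenvalues=np.array([]),
        scores=np.empty((g.n_individuals, 0)),
        proportion_variance=np.array([]),
        individuals=g.individuals.copy(),
        shared_loci=shared,
        n_zero_shared_pairs=n_zero,
    )


def pca(cov: PCAResult | np.ndarray, individuals: pd.DataFrame | None = None) -> PCAResult:
    """Eigendecomposition of the genotype covariance matrix.

    Scores are eigenvectors scaled by sqrt(eigenvalue); axes are ordered by
    descending eigenvalue with the sign fixed so the largest-magnitude
    coordinate on each axis is positive.  Negative eigenvalues (possible with
    pairwise-complete covariance) are reported, not clipped; their scores use
    sqrt of the clipped value.
    """
    if isinstance(cov, PCAResult):
        base = cov
        c = cov.covariance
        individuals = cov.individuals
    else:
        c = np.asarray(cov, dtype=float)
        if individuals is None:
            individuals = pd.DataFrame({"id": np.arange(c.shape[0])})
        base = None
    if not np.all(np.isfinite(c)):
        raise ValueError("covariance contains non-finite entries")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    flip = np.abs(vecs).argmax(axis=0)
    sign = np.sign(vecs[flip, np.arange(vecs.shape[1])])
    sign[sign == 0] = 1.0
    vecs = vecs * sign
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))
    total = vals.sum()
    prop = vals / total if total != 0 else np.zeros_like(vals)
    return PCAResult(
        covariance=c,
        eigenvalues=vals,
        scores=scores,
        proportion_variance=prop,
        individuals=individuals.copy(),
        shared_loci=None if base is None else base.shared_loci,
        n_zero_shared_pairs=0 if base is None else base.n_zero_shared_pairs,
    )


def pc_length_association(
    pca_result: PCAResult,
    lengths: np.ndarray,
    axes: int = 2,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation of the leading PC scores with fish length.

    Returns one row per axis with r and the two-sided t-test p; if ``n_perm``
    is positive a permutation p-value is added.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape[0] != pca_result.scores.shape[0]:
        raise ValueError("lengths must align with individuals")
    if np.std(lengths) == 0:
        raise ValueError("lengths have zero variance")
    rng = np.random.default_rng(seed)
    out = []
    for ax in range(min(axes, pca_result.scores.shape[1])):
        s = pca_result.scores[:, ax]
        if np.std(s) == 0:
            out.append({"axis": ax + 1, "r": np.nan, "p": np.nan, "p_perm": np.nan})
            continue
        r, p = stats.pearsonr(s, lengths)
        row = {"axis": ax + 1, "r": r, "p": p}
        if n_perm > 0:
            robs = abs(r)
            count = 0
            for _ in range(n_perm):
                rp = stats.pearsonr(s, rng.permutation(lengths))[0]
                count += abs(rp) >= robs
            row["p_perm"] = (count + 1) / (n_perm + 1)
        out.append(row)
    return pd.DataFrame(out)
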