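"""Synthetic study generator: fish phenotypes, genotypes, otoliths, lakes.

Emulates the study design the analysis pipeline assumes: 263 genotyped char
across seven lakes in two groups (closed "Fog" vs leaky "LTER"), with

* two-level Balding-Nichols genotypes -- ancestral allele frequencies drawn
  from a Beta distribution, group frequencies diverged at F ~ 0.2 around
  them, lake frequencies weakly diverged (F ~ 0.02) within groups, diploid
  binomial genotypes with uniform missingness;
* planted sex-linked loci on three dedicated chromosomes: XY-like loci
  heterozygous in (heterogametic) males and homozygous-reference in females,
  plus a female-only-genotyped locus missing in every male;
* total lengths drawn from per-lake Gaussian mixtures (two lakes bimodal),
  with the nine linear traits generated by a shared power-law allometry
  M = a * L^b * exp(eps) -- so any apparent morph structure is size, not
  shape ("plasticity-only" truth);
* otoliths growing proportionally to body length from a 17 mm hatch length,
  with per-fish growth following a saturating curve whose annual increments
  decline log-linearly with age.

Ground truth (size-class component, sex, sex-locus indices, deme allele
frequencies, lengths-at-age) is returned alongside the data so every
downstream stage has an objective recovery target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomatrix import GenotypeMatrix
from .growth import HATCH_LENGTH_MM, OtolithRecord
from .morphometrics import TRAIT_NAMES

__all__ = [
    "LakeSpec",
    "AllometrySpec",
    "OtolithSpec",
    "SimConfig",
    "SyntheticStudy",
    "default_config",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_otoliths",
    "simulate_study",
    "balding_nichols",
]


@dataclass(frozen=True)
class LakeSpec:
    name: str
    group: str
    n_fish: int
    length_mixture: tuple  # ((mean mm, sd mm, weight), ...)

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.length_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"lake {self.name}: mixture weights sum to {w}, not 1")


@dataclass(frozen=True)
class AllometrySpec:
    """Per-trait power law M = a * L^b * exp(eps), eps ~ N(0, sigma^2)."""

    a: dict
    b: dict
    sigma: dict

    def __post_init__(self) -> None:
        for t in TRAIT_NAMES:
            if self.a[t] <= 0 or self.sigma[t] < 0:
                raise ValueError(f"trait {t}: a must be > 0 and sigma >= 0")


@dataclass(frozen=True)
class OtolithSpec:
    hatch_length: float = HATCH_LENGTH_MM
    hatch_radius: float = 0.05  # otolith units (true O0 planted)
    radius_per_mm_mean: float = 0.004
    radius_per_mm_sd: float = 0.0003
    noise_sd: float = 0.05  # lognormal sd on annual increments
    age_range: tuple = (5, 10)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    lakes: tuple = ()
    n_loci: int = 15000
    n_chromosomes: int = 12
    fst_between_groups: float = 0.2
    fst_within_group: float = 0.02
    maf_beta: tuple = (0.8, 0.8)
    missing_rate: float = 0.15
    n_sex_loci_xy: int = 4
    n_sex_loci_female_only: int = 1
    n_sex_background: int | None = None  # default: 2% of n_loci
    sex_error_rate: float = 0.0
    allometry: AllometrySpec | None = None
    otolith: OtolithSpec = field(default_factory=OtolithSpec)
    n_known_sex: int = 6

    def __post_init__(self) -> None:
        for name in ("fst_between_groups", "fst_within_group", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 or (name == "missing_rate" and v > 1.0):
                raise ValueError(f"{name} out of range: {v}")
        n_bg = self.sex_background_count()
        if self.n_loci < self.n_sex_loci_xy + self.n_sex_loci_female_only + n_bg:
            raise ValueError("n_loci must cover the planted sex loci")
        if self.sex_error_rate > 0.01:
            raise ValueError("sex-locus error rate capped at 1%")
        if self.n_chromosomes < 10:
            raise ValueError("need >= 10 chromosomes (3 are reserved for sex loci)")

    def sex_background_count(self) -> int:
        """Partially sex-linked loci planted around the diagnostic ones.

        Sex chromosomes carry a differentiated region, not just a handful of
        diagnostic SNPs; without this background the sex axis cannot rise
        above the noise eigenvalue bulk of the genotype covariance.  Default
        is 2% of n_loci (0 if no diagnostic sex loci are planted).
        """
        if self.n_sex_loci_xy + self.n_sex_loci_female_only == 0:
            return 0
        if self.n_sex_background is not None:
            return self.n_sex_background
        return int(round(0.02 * self.n_loci))


@dataclass
class SyntheticStudy:
    fish: pd.DataFrame
    genotypes: GenotypeMatrix
    lakes: pd.DataFrame
    otoliths: list
    truth: dict


# Default per-trait allometry: intercepts sized so traits are realistic
# fractions of total length at b = 1; mild positive/negative allometry.
_DEFAULT_A = {
    "sl": 0.055, "ew": 0.030, "ml": 0.085, "hd": 0.120, "hl": 0.200,
    "bdp": 0.140, "bda": 0.170, "ppf": 0.110, "cp": 0.065,
}
_DEFAULT_B = {
    "sl": 1.05, "ew": 0.90, "ml": 1.10, "hd": 1.00, "hl": 0.97,
    "bdp": 1.08, "bda": 1.06, "ppf": 1.02, "cp": 0.95,
}


def default_allometry(sigma: float = 0.05) -> AllometrySpec:
    return AllometrySpec(
        a=dict(_DEFAULT_A), b=dict(_DEFAULT_B), sigma={t: sigma for t in TRAIT_NAMES}
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale defaults: 263 fish in 7 lakes, 2 groups, 15,000 loci.

    Per-lake sample sizes follow the study's genotyped counts; Fog3 and
    LTER348 get bimodal length mixtures, the rest unimodal.
    """
    lakes = (
        LakeSpec("Fog1", "Fog", 19, ((344, 45, 1.0),)),
        LakeSpec("Fog2", "Fog", 9, ((254, 80, 1.0),)),
        LakeSpec("Fog3", "Fog", 79, ((160, 15, 0.57), (350, 40, 0.43))),
        LakeSpec("Fog5", "Fog", 18, ((351, 60, 1.0),)),
        LakeSpec("LTER345", "LTER", 29, ((485, 60, 1.0),)),
        LakeSpec("LTER347", "LTER", 24, ((447, 70, 1.0),)),
        LakeSpec("LTER348", "LTER", 85, ((388, 45, 0.75), (565, 20, 0.25))),
    )
    cfg = SimConfig(seed=seed, lakes=lakes, allometry=default_allometry())
    return replace(cfg, **overrides) if overrides else cfg


def balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Deme frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); F = 0 copies p."""
    p = np.asarray(p, dtype=float)
    if F == 0:
        return p.copy()
    scale = (1.0 - F) / F
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def simulate_phenotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fish table: lengths from per-lake mixtures, traits by power law.

    Columns: id, lake, group, total_length_mm, the nine *_mm traits, sex,
    known_sex, true_component (mixture component index = true size class).
    Negative simulated lengths are redrawn.
    """
    if cfg.allometry is None:
        raise ValueError("config has no allometry spec")
    rng = rng or np.random.default_rng(cfg.seed)
    rows = []
    fish_counter = 0
    for lake in cfg.lakes:
        comps = lake.length_mixture
        weights = np.array([c[2] for c in comps])
        comp_idx = rng.choice(len(comps), size=lake.n_fish, p=weights)
        for ci in comp_idx:
            mean, sd, _ = comps[ci]
            L = rng.normal(mean, sd)
            while L <= 0:
                L = rng.normal(mean, sd)
            fish_counter += 1
            row = {
                "id": f"F{fish_counter:04d}",
                "lake": lake.name,
                "group": lake.group,
                "total_length_mm": L,
                "true_component": int(ci),
            }
            for t in TRAIT_NAMES:
                eps = rng.normal(0.0, cfg.allometry.sigma[t])
                row[f"{t}_mm"] = cfg.allometry.a[t] * L ** cfg.allometry.b[t] * np.exp(eps)
            rows.append(row)
    fish = pd.DataFrame(rows)
    n = len(fish)
    # random 1:1 assignment; females take the extra fish when n is odd so a
    # locus genotyped only in females keeps site missingness at or below 50%
    sexes = np.array(["female", "male"])[np.argsort(rng.random(n)) % 2]
    fish["sex"] = sexes
    fish["known_sex"] = False
    # known-sex subset split as evenly as possible between the sexes
    n_known = min(cfg.n_known_sex, n)
    males = np.flatnonzero(sexes == "male")
    females = np.flatnonzero(sexes == "female")
    half = n_known // 2
    chosen = np.concatenate(
        [
            rng.choice(males, size=min(half, len(males)), replace=False),
            rng.choice(females, size=min(n_known - half, len(females)), replace=False),
        ]
    )
    fish.loc[fish.index[chosen], "known_sex"] = True
    return fish


def _locus_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign loci to chromosomes with strictly increasing positions.

    The last three chromosomes are reserved for the sex-linked region (XY
    diagnostic loci and background on the first two, the one-sex-genotyped
    locus on the third).  Autosomal spacing is drawn from 40-400 bp so
    distance thinning at 90 bp removes some sites; sex-region loci sit on
    distinct GBS loci kilobases apart and are never thinned away.
    """
    n_auto_chrom = cfg.n_chromosomes - 3
    n_bg = cfg.sex_background_count()
    n_diag = cfg.n_sex_loci_xy + cfg.n_sex_loci_female_only
    n_neutral = cfg.n_loci - n_diag - n_bg
    chrom_of = np.repeat(np.arange(n_auto_chrom), int(np.ceil(n_neutral / n_auto_chrom)))[
        :n_neutral
    ]
    roles = ["neutral"] * n_neutral
    sex_chroms: list[int] = []
    for i in range(cfg.n_sex_loci_xy):
        sex_chroms.append(n_auto_chrom + (i % 2))
        roles.append("xy")
    sex_chroms += [n_auto_chrom + 2] * cfg.n_sex_loci_female_only
    roles += ["female_only"] * cfg.n_sex_loci_female_only
    for i in range(n_bg):
        sex_chroms.append(n_auto_chrom + (i % 2))
        roles.append("sex_background")
    chrom_idx = np.concatenate([chrom_of, np.array(sex_chroms, dtype=int)])
    names = np.array([f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)])
    loci = pd.DataFrame({"chrom": names[chrom_idx], "role": roles})
    pos = np.empty(len(loci), dtype=int)
    for c in np.unique(chrom_idx):
        mask = chrom_idx == c
        lo, hi = (2000, 20000) if c >= n_auto_chrom else (40, 400)
        pos[mask] = np.cumsum(rng.integers(lo, hi, size=mask.sum()))
    loci["pos"] = pos
    loci["ref"] = "A"
    loci["alt"] = "T"
    loci["is_sex_locus"] = loci["role"].isin(["xy", "female_only"])
    order = np.lexsort((loci["pos"].values, loci["chrom"].values))
    return loci.iloc[order].reset_index(drop=True)


def simulate_genotypes(
    cfg: SimConfig,
    fish: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Two-level Balding-Nichols genotypes with planted sex loci.

    Ancestral frequencies come from Beta(*cfg.maf_beta*); group frequencies
    diverge at ``fst_between_groups`` and lake frequencies at
    ``fst_within_group`` around their group.  Diploid genotypes are binomial
    draws from the lake frequency; missing calls are planted uniformly.  XY
    loci are then overwritten (males heterozygous, females homozygous
    reference, flipped at ``sex_error_rate``) and female-only loci are set
    missing in every male.  Returns (matrix, truth dict).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if fish is None:
        fish = simulate_phenotypes(cfg, np.random.default_rng(cfg.seed))
    loci = _locus_map(cfg, rng)
    L = len(loci)
    xy_idx = np.flatnonzero((loci["role"] == "xy").values)
    fo_idx = np.flatnonzero((loci["role"] == "female_only").values)
    bg_idx = np.flatnonzero((loci["role"] == "sex_background").values)
    sex_idx = np.sort(np.concatenate([xy_idx, fo_idx]))

    p_anc = rng.beta(cfg.maf_beta[0], cfg.maf_beta[1], size=L)
    p_anc = np.clip(p_anc, 0.01, 0.99)
    groups = list(dict.fromkeys(s.group for s in cfg.lakes))
    p_group = {g: balding_nichols(p_anc, cfg.fst_between_groups, rng) for g in groups}
    p_lake = {
        s.name: balding_nichols(p_group[s.group], cfg.fst_within_group, rng)
        for s in cfg.lakes
    }

    n = len(fish)
    values = np.empty((n, L))
    for s in cfg.lakes:
        mask = (fish["lake"] == s.name).to_numpy()
        values[mask] = rng.binomial(2, p_lake[s.name][None, :], size=(mask.sum(), L))
    if cfg.missing_rate > 0:
        values[rng.random((n, L)) < cfg.missing_rate] = np.nan

    is_male = (fish["sex"] == "male").to_numpy()
    for j in xy_idx:
        col = np.where(is_male, 1.0, 0.0)
        if cfg.sex_error_rate > 0:
            flips = rng.random(n) < cfg.sex_error_rate
            col[flips] = np.where(col[flips] == 1.0, 0.0, 1.0)
        values[:, j] = col
    for j in fo_idx:
        # genotyped only in females (W-region-like); females are fully called
        # so site missingness stays at the male fraction (<= 50%)
        col = rng.binomial(2, 0.4, size=n).astype(float)
        col[is_male] = np.nan
        values[:, j] = col
    for j in bg_idx:
        # partially degenerate XY region: males carry a fixed Y-haplotype
        # allele plus an X copy, females two X copies
        p_x = rng.uniform(0.05, 0.3)
        col = rng.binomial(2, p_x, size=n).astype(float)
        col[is_male] = 1.0 + rng.binomial(1, p_x, size=int(is_male.sum()))
        if cfg.missing_rate > 0:
            col[rng.random(n) < cfg.missing_rate] = np.nan
        values[:, j] = col

    individuals = fish[["id", "lake", "group", "sex", "known_sex", "total_length_mm"]].copy()
    loci_meta = loci.copy()
    loci_meta["counted_allele"] = loci_meta["alt"]
    g = GenotypeMatrix(values, loci_meta, individuals)
    truth = {
        "sex": dict(zip(fish["id"], fish["sex"])),
        "size_class_component": dict(zip(fish["id"], fish["true_component"])),
        "sex_locus_indices": sex_idx.tolist(),
        "xy_locus_indices": xy_idx.tolist(),
        "female_only_locus_indices": fo_idx.tolist(),
        "sex_background_indices": bg_idx.tolist(),
        "sex_chromosomes": sorted(loci.loc[sex_idx, "chrom"].unique().tolist()),
        "p_ancestral": p_anc,
        "p_group": p_group,
        "p_lake": p_lake,
    }
    return g, truth


def simulate_otoliths(
    cfg: SimConfig, fish: pd.DataFrame, rng: np.random.Generator | None = None
) -> tuple[list, dict]:
    """Otolith radii proportional to body length from the hatch point.

    Each fish gets an integer age, a saturating length-at-age trajectory
    ending at its capture length (annual increments decline exponentially
    with age, so log increment is linear in age), and annulus radii
    O_a = O0 + c_fish * (L_a - L0).  Multiplicative lognormal noise with sd
    ``otolith.noise_sd`` perturbs annual radius increments, preserving
    monotonicity.  Returns (records, truth lengths-at-age per fish).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    spec = cfg.otolith
    L0 = spec.hatch_length
    records = []
    truth_lengths = {}
    for _, row in fish.iterrows():
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        k = rng.uniform(0.15, 0.35)
        frac_extra = rng.uniform(0.05, 0.45)  # capture part-way into the next year
        Lc = float(row["total_length_mm"])
        ages = np.arange(1, age + 1, dtype=float)
        capture_age = age + frac_extra
        scale = (Lc - L0) / (1.0 - np.exp(-k * capture_age))
        La = L0 + scale * (1.0 - np.exp(-k * ages))
        c = rng.normal(spec.radius_per_mm_mean, spec.radius_per_mm_sd)
        while c <= 0:
            c = rng.normal(spec.radius_per_mm_mean, spec.radius_per_mm_sd)
        Oa = spec.hatch_radius + c * (La - L0)
        Oc = spec.hatch_radius + c * (Lc - L0)
        if spec.noise_sd > 0:
            incr = np.diff(np.concatenate([[spec.hatch_radius], Oa, [Oc]]))
            incr = incr * np.exp(rng.normal(0.0, spec.noise_sd, size=len(incr)))
            radii = spec.hatch_radius + np.cumsum(incr)
            Oa, Oc = radii[:-1], radii[-1]
        records.append(
            OtolithRecord(
                fish_id=str(row["id"]),
                capture_length=Lc,
                capture_radius=float(Oc),
                annulus_radii=Oa,
            )
        )
        truth_lengths[str(row["id"])] = La
    return records, {"lengths_at_age": truth_lengths, "hatch_radius": spec.hatch_radius}


def lake_metadata() -> pd.DataFrame:
    """The study lakes' morphometry and community table (inputs, not simulated)."""
    from .lakes import LAKE_TABLE

    return LAKE_TABLE.copy()


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate the full synthetic study (phenotypes, genotypes, otoliths).

    All randomness derives from ``cfg.seed`` (or ``seed`` if given); repeated
    calls with the same seed are bit-reproducible.
    """
    cfg = cfg or default_config()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    fish = simulate_phenotypes(cfg, np.random.default_rng(cfg.seed))
    genotypes, gtruth = simulate_genotypes(cfg, fish, np.random.default_rng(cfg.seed + 1))
    otoliths, otruth = simulate_otoliths(cfg, fish, np.random.default_rng(cfg.seed + 2))
    truth = {**gtruth, **otruth}
    return SyntheticStudy(
        fish=fish,
        genotypes=genotypes,
        lakes=lake_metadata(),
        otoliths=otoliths,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str) -> None:
    """Write fish/lakes/otoliths as TSV, genotypes as VCF, truth as JSON."""
    import os

    from .genomatrix import write_vcf
    from .growth import otoliths_to_frame

    os.makedirs(outdir, exist_ok=True)
    study.fish.to_csv(os.path.join(outdir, "fish.tsv"), sep="\t", index=False)
    study.lakes.to_csv(os.path.join(outdir, "lakes.tsv"), sep="\t", index=False)
    otoliths_to_frame(study.otoliths).to_csv(
        os.path.join(outdir, "otoliths.tsv"), sep="\t", index=False
    )
    write_vcf(study.genotypes, os.path.join(outdir, "genotypes.vcf"))
    truth = {
        k: v
        for k, v in study.truth.items()
        if k in ("sex", "size_class_component", "sex_locus_indices",
                 "xy_locus_indices", "female_only_locus_indices", "sex_chromosomes")
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
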