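"""Allometric size adjustment and model-based size-class clustering.

Linear trait measurements scale with body size; a trait M measured on a fish
of total length L is rescaled to a common reference length Lm through the
power-law allometry M = a * L^b, giving the size-adjusted value

    log10 Y = log10 M + b * (log10 Lm - log10 L)

with b the OLS slope of log10 M on log10 L.  Size classes are then found by
Gaussian-mixture clustering with BIC model selection (higher is better,
BIC = 2*logL - m*log n) and a dBIC > 3 rule against the runner-up K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

TRAIT_NAMES = ("sl", "ew", "ml", "hd", "hl", "bdp", "bda", "ppf", "cp")
"""The nine linear measurements: snout length, eye width, maxilla length,
head depth, head length, body depth posterior/anterior, postpelvic fin
length, caudal peduncle depth (all mm)."""

COVARIANCE_FAMILIES = ("spherical", "diag", "tied", "full")

__all__ = [
    "TRAIT_NAMES",
    "FishRecord",
    "AllometryModel",
    "SizeClassModel",
    "fit_allometric_slope",
    "size_adjust",
    "size_adjust_frame",
    "gmm_cluster",
    "assign_size_classes",
]


@dataclass
class FishRecord:
    id: str
    lake: str
    group: str
    total_length: float
    traits: dict
    sex: str = "unknown"
    known_sex: bool = False
    size_class: str | None = None

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        bad = set(self.traits) - set(TRAIT_NAMES)
        if bad:
            raise ValueError(f"unknown trait names: {sorted(bad)}")
        for k, v in self.traits.items():
            if v is not None and not np.isnan(v) and v <= 0:
                raise ValueError(f"trait {k} must be positive")


@dataclass
class AllometryModel:
    """Per-trait log10-scale OLS fits and the reference length Lm (mm)."""

    slopes: pd.Series
    reference_length: float
    intercepts: pd.Series
    residual_sd: pd.Series
    n_fit: pd.Series

    def __post_init__(self) -> None:
        if self.reference_length <= 0:
            raise ValueError("reference length must be positive")
        if not np.all(np.isfinite(self.slopes.values)):
            raise ValueError("non-finite allometric slope")


@dataclass
class SizeClassModel:
    k: int
    family: str
    bic_table: pd.DataFrame  # columns: k, family, bic
    delta_bic: float
    ambiguous: bool
    labels: np.ndarray
    responsibilities: np.ndarray
    means: np.ndarray
    ids: np.ndarray | None = None
    n_dropped_missing: int = 0
    mixture: GaussianMixture | None = field(default=None, repr=False)


def fit_allometric_slope(traits: pd.DataFrame, lengths: np.ndarray) -> AllometryModel:
    """OLS slope of log10(trait) on log10(total length) for each trait.

    The reference length Lm is the arithmetic mean of the lengths in the
    fitting set (pass all fish for across-lake analyses, the lake's fish for
    within-lake analyses).  Rows missing a trait are dropped for that trait.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    slopes, intercepts, rsd, nfit = {}, {}, {}, {}
    for trait in traits.columns:
        m = traits[trait].to_numpy(dtype=float)
        ok = ~np.isnan(m) & ~np.isnan(lengths)
        if np.any(m[ok] <= 0):
            raise ValueError(f"trait {trait} has nonpositive values")
        if ok.sum() < 3:
            raise ValueError(f"trait {trait}: need >= 3 fish with trait and length")
        x = np.log10(lengths[ok])
        y = np.log10(m[ok])
        if np.ptp(x) == 0:
            raise ValueError(f"trait {trait}: zero variance in length, slope undefined")
        b, a = np.polyfit(x, y, 1)
        resid = y - (a + b * x)
        slopes[trait] = b
        intercepts[trait] = a
        rsd[trait] = float(np.sqrt(np.mean(resid**2)))
        nfit[trait] = int(ok.sum())
    return AllometryModel(
        slopes=pd.Series(slopes),
        reference_length=float(np.mean(lengths[~np.isnan(lengths)])),
        intercepts=pd.Series(intercepts),
        residual_sd=pd.Series(rsd),
        n_fit=pd.Series(nfit),
    )


def size_adjust(M, L, b: float, Lm: float):
    """Size-adjusted trait Y = M * (Lm / L)^b (identity at L = Lm or b = 0)."""
    M = np.asarray(M, dtype=float)
    L = np.asarray(L, dtype=float)
    if Lm <= 0:
        raise ValueError("reference length must be positive")
    if np.any(M[~np.isnan(M)] <= 0) or np.any(L[~np.isnan(L)] <= 0):
        raise ValueError("trait and length values must be positive")
    return 10.0 ** (np.log10(M) + b * (np.log10(Lm) - np.log10(L)))


def size_adjust_frame(
    traits: pd.DataFrame, lengths: np.ndarray, model: AllometryModel
) -> pd.DataFrame:
    """Apply :func:`size_adjust` column-wise using a fitted allometry."""
    out = {}
    for trait in traits.columns:
        out[trait] = size_adjust(
            traits[trait].to_numpy(dtype=float),
            np.asarray(lengths, dtype=float),
            float(model.slopes[trait]),
            model.reference_length,
        )
    return pd.DataFrame(out, index=traits.index)


def gmm_cluster(
    X,
    k_max: int = 5,
    delta_threshold: float = 3.0,
    seed: int | None = None,
    n_init: int = 10,
    families: tuple[str, ...] = COVARIANCE_FAMILIES,
) -> SizeClassModel:
    """Gaussian-mixture clustering with BIC selection over K and covariance
    family.

    BIC here is 2*logL - m*log n (higher is better); the selected model
    maximizes it.  If the gap to the best model with a *different* K is below
    ``delta_threshold`` the selection is flagged ambiguous and the smaller of
    the two K values is reported.  Rows with any missing value are dropped
    (count reported).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = ~np.isnan(X).any(axis=1)
    n_dropped = int((~ok).sum())
    Xc = X[ok]
    n = Xc.shape[0]
    if n <= k_max:
        raise ValueError(f"need more rows ({n}) than k_max ({k_max})")

    fits = []
    rows = []
    for k in range(1, k_max + 1):
        for fam in families:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=fam,
                n_init=n_init if k > 1 else 1,
                init_params="k-means++",
                reg_covar=1e-6,
                random_state=seed,
                max_iter=300,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(Xc)
            bic = -gm.bic(Xc)  # sklearn reports lower-is-better
            fits.append((k, fam, bic, gm))
            rows.append({"k": k, "family": fam, "bic": bic})
    bic_table = pd.DataFrame(rows)

    fits.sort(key=lambda t: t[2], reverse=True)
    best_k, best_fam, best_bic, best_gm = fits[0]
    other = next((f for f in fits if f[0] != best_k), None)
    ambiguous = False
    if other is not None:
        delta = best_bic - other[2]
        if delta < delta_threshold and other[0] < best_k:
            # conservative: fall back to the more parsimonious K
            best_k, best_fam, best_bic, best_gm = other
            other2 = next((f for f in fits if f[0] != best_k), None)
            delta = best_bic - other2[2] if other2 else np.inf
            ambiguous = True
        elif delta < delta_threshold:
            ambiguous = True
    else:
        delta = np.inf

    resp_c = best_gm.predict_proba(Xc)
    labels = np.full(X.shape[0], -1, dtype=int)
    labels[ok] = resp_c.argmax(axis=1)
    resp = np.full((X.shape[0], best_k), np.nan)
    resp[ok] = resp_c
    return SizeClassModel(
        k=best_k,
        family=best_fam,
        bic_table=bic_table,
        delta_bic=float(delta),
        ambiguous=ambiguous,
        labels=labels,
        responsibilities=resp,
        means=best_gm.means_,
        n_dropped_missing=n_dropped,
        mixture=best_gm,
    )


_SIZE_NAMES = {1: ["all"], 2: ["small", "large"], 3: ["small", "medium", "large"]}


def assign_size_classes(model: SizeClassModel, fish: pd.DataFrame) -> pd.DataFrame:
    """Name clusters by increasing mean total length and write labels.

    With K = 3 the names are small/medium/large (K = 2: small/large; K = 1:
    all; otherwise class-1..K).  Ties in mean length break by cluster index
    and are flagged with a warning.
    """
    if len(fish) != len(model.labels):
        raise ValueError("fish table does not align with the fitted model")
    lengths = fish["total_length_mm"].to_numpy(dtype=float)
    means = np.array(
        [
            lengths[model.labels == c].mean() if np.any(model.labels == c) else np.inf
            for c in range(model.k)
        ]
    )
    finite = means[np.isfinite(means)]
    if len(np.unique(finite)) < len(finite):
        warnings.warn("clusters with equal mean length; tie broken by cluster index")
    order = np.argsort(means, kind="stable")
    names = _SIZE_NAMES.get(model.k, [f"class-{i + 1}" for i in range(model.k)])
    name_of = {int(c): names[rank] for rank, c in enumerate(order)}
    out = fish.copy()
    out["size_class"] = [
        name_of[int(c)] if c >= 0 else None for c in model.labels
    ]
    return out
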