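"""PERMANOVA on Euclidean distances with marginal (Type-II) tests.

Relates char size structure to lake-level predictors.  The machinery is the
McArdle-Anderson trace formulation: with D the Euclidean distance matrix,
G = -1/2 * J * D^2 * J (J the centring matrix), the sum of squares explained
by a model matrix X is tr(H G) with H the hat matrix of X.  Each term is
tested marginally -- its SS is the drop from the full model to the model
without it -- and significance comes from free permutation of the response
rows (optionally within strata), with

    p = (number of permuted pseudo-F >= observed + 1) / (n_perm + 1).

For a univariate response this pseudo-F equals the classical ANOVA F.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermanovaResult",
    "char_density",
    "permanova_test",
    "model_search",
]


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, ss, pseudo_f, p, n_perm
    residual_df: int
    residual_ss: float
    total_ss: float
    formula: str
    n_permutations: int
    seed: int | None
    dropped_terms: list


def char_density(abundance: float, area_ha: float) -> int:
    """Arctic char density (fish per hectare), truncated toward zero.

    Matches the study table's convention: e.g. 448 fish in 3.5 ha -> 128,
    331 fish in 5.7 ha -> 58.
    """
    if area_ha <= 0:
        raise ValueError("lake area must be positive")
    if abundance < 0:
        raise ValueError("abundance must be nonnegative")
    return math.trunc(abundance / area_ha)


def _gower_center(response: np.ndarray) -> np.ndarray:
    """G = -1/2 J D^2 J for the Euclidean distance on the response rows."""
    sq = (response**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * response @ response.T
    np.clip(d2, 0.0, None, out=d2)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _model_matrix(predictors: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept plus columns per term; factors are dummy-coded (drop first)."""
    n = len(predictors)
    cols = [np.ones((n, 1))]
    for t in terms:
        s = predictors[t]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
            cols.append(d)
        else:
            cols.append(s.to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of X and its rank."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    rank = int((diag > 1e-10 * max(diag.max(), 1.0)).sum())
    Qr = Q[:, :rank] if rank < Q.shape[1] else Q
    # recompute with column pivoting via SVD for rank-deficient X
    if rank < X.shape[1]:
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        rank = int((s > 1e-10 * s.max()).sum())
        Qr = U[:, :rank]
    return Qr @ Qr.T, rank


def permanova_test(
    response,
    predictors: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 9999,
    seed: int | None = 0,
    standardize: bool = False,
    strata: np.ndarray | None = None,
) -> PermanovaResult:
    """Marginal permutation tests of each predictor on the response distances.

    ``response`` is an observations x variables numeric array (no missing
    rows); ``predictors`` a DataFrame with one column per candidate term
    (numeric, or categorical for factors).  Collinear terms (zero marginal
    df) are dropped with a warning.  ``strata`` restricts permutations to
    within-group shuffles.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(Y).any():
        raise ValueError("response contains missing values")
    if len(predictors) != Y.shape[0]:
        raise ValueError("predictors must align with response rows")
    if np.all(np.ptp(Y, axis=0) == 0):
        raise ValueError("constant response")
    if standardize:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = (Y - Y.mean(axis=0)) / sd
    terms = list(terms if terms is not None else predictors.columns)
    n = Y.shape[0]
    G = _gower_center(Y)
    total_ss = float(np.trace(G))

    X_full = _model_matrix(predictors, terms)
    H_full, rank_full = _hat(X_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    R_full = np.eye(n) - H_full

    dropped = []
    kept = []
    hats_reduced = {}
    for t in terms:
        others = [u for u in terms if u != t]
        H_red, rank_red = _hat(_model_matrix(predictors, others))
        df_t = rank_full - rank_red
        if df_t == 0:
            warnings.warn(f"term {t} is collinear with the others; dropped")
            dropped.append(t)
            continue
        kept.append((t, df_t, H_red))
        hats_reduced[t] = H_red

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=int)
    base = np.arange(n)
    if strata is None:
        for i in range(n_perm):
            perms[i] = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        for i in range(n_perm):
            p = base.copy()
            for gset in (np.flatnonzero(strata == s) for s in np.unique(strata)):
                p[gset] = gset[rng.permutation(len(gset))]
            perms[i] = p

    rows = []
    ss_resid = float(np.sum(R_full * G))
    for t, df_t, H_red in kept:
        Hdiff = H_full - H_red
        ss_t = float(np.sum(Hdiff * G))
        f_obs = (ss_t / df_t) / (ss_resid / df_resid)
        count = 0
        for i in range(n_perm):
            p = perms[i]
            Gp = G[np.ix_(p, p)]
            ss_tp = np.sum(Hdiff * Gp)
            ss_rp = np.sum(R_full * Gp)
            fp = (ss_tp / df_t) / (ss_rp / df_resid) if ss_rp > 0 else np.inf
            count += fp >= f_obs - 1e-12
        pval = (count + 1) / (n_perm + 1)
        rows.append(
            {"term": t, "df": df_t, "ss": ss_t, "pseudo_f": f_obs,
             "p": pval, "n_perm": n_perm}
        )
    return PermanovaResult(
        table=pd.DataFrame(rows),
        residual_df=df_resid,
        residual_ss=ss_resid,
        total_ss=total_ss,
        formula=" + ".join(t for t, _, _ in kept),
        n_permutations=n_perm,
        seed=seed,
        dropped_terms=dropped,
    )


def model_search(
    response,
    predictors: pd.DataFrame,
    max_terms: int = 3,
    n_perm: int = 999,
    seed: int | None = 0,
    alpha: float = 0.05,
    **kwargs,
) -> tuple[PermanovaResult | None, pd.DataFrame]:
    """Additive model search: all subsets up to ``max_terms`` predictors.

    A model qualifies when every term is significant at ``alpha``; qualifying
    models are ranked by smallest residual SS.  Returns (best model result or
    None, full ranking table).
    """
    candidates = list(predictors.columns)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    rows = []
    results = {}
    for size in range(1, max_terms + 1):
        for combo in itertools.combinations(candidates, size):
            try:
                res = permanova_test(
                    response, predictors, terms=list(combo),
                    n_perm=n_perm, seed=seed, **kwargs,
                )
            except ValueError:
                continue
            if res.table.empty:
                continue
            all_sig = bool((res.table["p"] < alpha).all()) and not res.dropped_terms
            rows.append(
                {"model": " + ".join(combo), "n_terms": size,
                 "residual_ss": res.residual_ss, "all_significant": all_sig,
                 "max_p": float(res.table["p"].max())}
            )
            results[" + ".join(combo)] = res
    table = pd.DataFrame(rows).sort_values(
        ["all_significant", "residual_ss"], ascending=[False, True]
    ).reset_index(drop=True)
    sig = table[table["all_significant"]]
    best = results[sig.iloc[0]["model"]] if len(sig) else None
    return best, table
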