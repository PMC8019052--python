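"""Model-based genetic clustering: admixture EM, K selection, stock mixtures.

The admixture model treats each individual's genotype at locus l as a
Binomial(2, sum_k q_ik p_lk) draw, with Q the individuals x K ancestry
proportions and P the loci x K cluster allele frequencies; it is maximized
by block EM from multiple random starts.  K is chosen by 10-fold
cross-validation that masks genotype cells and scores the squared error of
their predicted dosage.  The stock mixture model instead assigns each
individual wholly to one of K stocks with stock-specific frequencies, and a
locus bootstrap measures per-individual assignment support.  Fisher's exact
test checks independence of stock assignment and morphological size class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, logsumexp

from .genomatrix import GenotypeMatrix, PCAResult

__all__ = [
    "AncestryResult",
    "StockAssignment",
    "admixture_em",
    "choose_k_cv",
    "stock_mixture_em",
    "fisher_exact",
    "find_clusters_bic",
    "assignment_accuracy",
]

_EPS = 1e-9


@dataclass
class AncestryResult:
    k: int
    Q: np.ndarray
    P: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray


@dataclass
class StockAssignment:
    k: int
    assignments: np.ndarray  # hard stock label per individual (0..K-1)
    responsibilities: np.ndarray
    bootstrap_support: np.ndarray | None
    P: np.ndarray
    proportions: np.ndarray
    log_likelihood: float
    contingency: pd.DataFrame | None = None
    fisher_p: float | None = None
    n_restarts: int = 0


def _binom_const(x: np.ndarray) -> float:
    """Sum of log C(2, x) over nonmissing genotypes."""
    ok = ~np.isnan(x)
    return float(np.sum(np.where(ok & (x == 1), np.log(2.0), 0.0)))


def admixture_em(
    g: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-3,
    n_starts: int = 10,
    warn_nonconverged: bool = True,
) -> AncestryResult:
    """Maximum-likelihood admixture proportions by block EM.

    Missing genotypes are skipped in the likelihood.  The best of
    ``n_starts`` random initializations is returned; K = 1 has the closed
    form Q = 1, P = observed allele frequencies.
    """
    x = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    n, L = x.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    called = ~np.isnan(x)
    a = np.where(called, x, 0.0)  # minor-allele copies
    b = np.where(called, 2.0 - x, 0.0)
    const = _binom_const(x)

    if K == 1:
        tot = called.sum(axis=0) * 2.0
        p = np.where(tot > 0, a.sum(axis=0) / np.where(tot > 0, tot, 1), 0.5)
        pc = np.clip(p, _EPS, 1 - _EPS)
        ll = const + float(np.sum(a * np.log(pc)[None, :] + b * np.log1p(-pc)[None, :]))
        return AncestryResult(
            k=1, Q=np.ones((n, 1)), P=p[:, None], log_likelihood=ll,
            converged=True, n_iter=0, loglik_trace=np.array([ll]),
        )

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(rng.uniform(0.05, 0.95, size=(L, K)), _EPS, 1 - _EPS)
        trace = []
        converged = False
        prev = -np.inf
        for it in range(max_iter):
            f = np.clip(Q @ P.T, _EPS, 1 - _EPS)  # n x L expected freq
            ll = const + float(np.sum(a * np.log(f) + b * np.log1p(-f)))
            trace.append(ll)
            if ll - prev < tol and it > 0:
                converged = True
                break
            prev = ll
            # E-step responsibilities, per cluster
            num_q = np.empty((n, K))
            num_p = np.empty((L, K))
            den_p = np.empty((L, K))
            for k in range(K):
                r1 = Q[:, k : k + 1] * P[None, :, k] / f  # n x L
                r0 = Q[:, k : k + 1] * (1.0 - P[None, :, k]) / (1.0 - f)
                ar1 = a * r1
                br0 = b * r0
                num_q[:, k] = ar1.sum(axis=1) + br0.sum(axis=1)
                num_p[:, k] = ar1.sum(axis=0)
                den_p[:, k] = ar1.sum(axis=0) + br0.sum(axis=0)
            copies = 2.0 * called.sum(axis=1, keepdims=True)
            Q = num_q / np.maximum(copies, 1.0)
            Q = np.clip(Q, _EPS, None)
            Q /= Q.sum(axis=1, keepdims=True)
            P = np.clip(num_p / np.maximum(den_p, _EPS), _EPS, 1 - _EPS)
        if not converged and warn_nonconverged:
            warnings.warn(f"admixture EM did not converge in {max_iter} iterations")
        res = AncestryResult(
            k=K, Q=Q, P=P, log_likelihood=trace[-1], converged=converged,
            n_iter=len(trace), loglik_trace=np.asarray(trace),
        )
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    return best


def choose_k_cv(
    g: GenotypeMatrix | np.ndarray,
    k_range=range(1, 6),
    n_folds: int = 10,
    seed: int = 0,
    n_starts: int = 2,
    max_iter: int = 150,
) -> tuple[int, pd.DataFrame]:
    """Select K by masking genotype cells and scoring predicted dosages.

    Nonmissing cells are split into ``n_folds`` folds; each fold is masked,
    the admixture model refit, and the fold scored by mean squared error
    between the held-out genotype and its expected dosage 2 * sum_k q p.
    The K with the lowest mean error wins (ties to the smaller K).
    """
    x = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    rng = np.random.default_rng(seed)
    cells = np.argwhere(~np.isnan(x))
    if len(cells) < n_folds:
        raise ValueError("not enough nonmissing genotype cells to mask")
    perm = rng.permutation(len(cells))
    folds = np.array_split(perm, n_folds)
    rows = []
    for K in k_range:
        errs = []
        for fi, fold in enumerate(folds):
            if len(fold) == 0:
                raise ValueError("fold with no masked cells")
            xm = x.copy()
            rr, cc = cells[fold, 0], cells[fold, 1]
            xm[rr, cc] = np.nan
            fit = admixture_em(
                xm, K, seed=seed + 1000 * fi + K, n_starts=n_starts,
                max_iter=max_iter, warn_nonconverged=False,
            )
            pred = 2.0 * (fit.Q @ fit.P.T)[rr, cc]
            errs.append(float(np.mean((x[rr, cc] - pred) ** 2)))
        rows.append({"k": int(K), "cv_error": float(np.mean(errs)),
                     "cv_se": float(np.std(errs, ddof=1) / np.sqrt(len(errs)))})
    table = pd.DataFrame(rows)
    best = int(table.sort_values(["cv_error", "k"]).iloc[0]["k"])
    return best, table


# ---------------------------------------------------------------------------
# Stock mixture (whole-individual membership)


def _stock_em_once(
    a: np.ndarray, b: np.ndarray, K: int, rng, max_iter: int, tol: float,
    z_init: np.ndarray | None = None,
):
    n = a.shape[0]
    if z_init is None:
        z = rng.dirichlet(np.ones(K), size=n)
    else:
        z = z_init
    prev = -np.inf
    for _ in range(max_iter):
        zsum = z.sum(axis=0)
        if np.any(zsum < 1e-6):
            return None  # responsibility collapse; caller restarts
        pi = zsum / n
        P = np.clip((z.T @ a) / np.maximum(z.T @ (a + b), _EPS), _EPS, 1 - _EPS).T
        logf = a @ np.log(P) + b @ np.log1p(-P) + np.log(pi)[None, :]
        ll = float(logsumexp(logf, axis=1).sum())
        z = np.exp(logf - logsumexp(logf, axis=1, keepdims=True))
        if ll - prev < tol:
            break
        prev = ll
    return z, P, pi, ll


def stock_mixture_em(
    g: GenotypeMatrix | np.ndarray,
    K: int = 2,
    n_boot: int = 100,
    seed: int = 0,
    size_class: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_starts: int = 5,
) -> StockAssignment:
    """Finite-mixture stock model with a locus bootstrap on assignments.

    Each individual belongs wholly to one of K stocks with stock-specific
    allele frequencies; EM computes membership responsibilities.  Bootstrap
    replicates resample loci, refit from the point estimate, and per-fish
    support is the fraction of replicates agreeing with the full-data hard
    assignment (labels matched by maximum overlap).  If ``size_class`` labels
    are given, a contingency table and Fisher's exact p are attached.
    """
    x = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    n, L = x.shape
    if K < 2:
        raise ValueError("stock mixture needs K >= 2")
    if K >= n:
        raise ValueError("K must be smaller than the number of individuals")
    called = ~np.isnan(x)
    a = np.where(called, x, 0.0)
    b = np.where(called, 2.0 - x, 0.0)
    rng = np.random.default_rng(seed)

    best = None
    n_restarts = 0
    for _ in range(n_starts):
        out = _stock_em_once(a, b, K, rng, max_iter, tol)
        while out is None:
            n_restarts += 1
            if n_restarts > 20:
                raise RuntimeError("stock EM kept collapsing to an empty stock")
            out = _stock_em_once(a, b, K, rng, max_iter, tol)
        z, P, pi, ll = out
        if best is None or ll > best[3]:
            best = (z, P, pi, ll)
    z, P, pi, ll = best
    hard = z.argmax(axis=1)

    support = None
    if n_boot > 0:
        agree = np.zeros(n)
        for _ in range(n_boot):
            idx = rng.integers(0, L, size=L)
            out = _stock_em_once(
                a[:, idx], b[:, idx], K, rng, max_iter=50, tol=tol, z_init=z
            )
            if out is None:
                continue
            zb = out[0]
            hb = zb.argmax(axis=1)
            # match replicate labels to the full-fit labels by overlap
            overlap = np.zeros((K, K))
            for k1 in range(K):
                for k2 in range(K):
                    overlap[k1, k2] = np.sum((hard == k1) & (hb == k2))
            ri, ci = linear_sum_assignment(-overlap)
            remap = dict(zip(ci, ri))
            agree += np.array([remap[h] for h in hb]) == hard
        support = agree / n_boot

    contingency = None
    fisher_p = None
    if size_class is not None:
        contingency = pd.crosstab(
            pd.Series(hard, name="stock"), pd.Series(np.asarray(size_class), name="size_class")
        )
        fisher_p = fisher_exact(contingency.values, seed=seed)
    return StockAssignment(
        k=K, assignments=hard, responsibilities=z, bootstrap_support=support,
        P=P, proportions=pi, log_likelihood=ll, contingency=contingency,
        fisher_p=fisher_p, n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact(table: np.ndarray, seed: int = 0, n_mc: int = 100_000) -> float:
    """Two-sided Fisher's exact p for an r x c count table.

    2x2 tables are computed exactly by summing hypergeometric probabilities
    no larger than the observed table's.  Larger tables with total n <= 200
    are enumerated over the 2xC network when feasible, otherwise (and for
    any r x c with r > 2) a Monte-Carlo permutation of labels with ``n_mc``
    draws is used.  Degenerate margins give p = 1.
    """
    t = np.asarray(table)
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.round(t).astype(int)
        if np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        warnings.warn("degenerate margin in contingency table; p = 1")
        t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
        if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
            return 1.0
    if t.shape == (2, 2):
        return _fisher_2x2(t)
    return _fisher_mc(t, seed, n_mc)


def _fisher_2x2(t: np.ndarray) -> float:
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    rv = sstats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def _log_table_prob(t: np.ndarray) -> float:
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(t + 1).sum()
    )


def _fisher_mc(t: np.ndarray, seed: int, n_mc: int) -> float:
    rng = np.random.default_rng(seed)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    lp_obs = _log_table_prob(t)
    labels = np.repeat(np.arange(len(cols)), cols)
    row_id = np.repeat(np.arange(len(rows)), rows)
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(labels)
        tp = np.zeros_like(t)
        np.add.at(tp, (row_id, perm), 1)
        if _log_table_prob(tp) <= lp_obs + 1e-9:
            count += 1
    return (count + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# k-means group finding and assignment accuracy


def find_clusters_bic(
    pca_result: PCAResult | np.ndarray,
    k_range=range(1, 6),
    seed: int = 0,
    n_pcs: int | None = None,
    k_select: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """k-means over retained PCs with a BIC curve (lower is better).

    BIC_K = n * log(WSS_K / n) + K * log(n), the criterion used by the
    find.clusters approach.  Returns (assignment at ``k_select`` or at the
    BIC minimizer, curve).  Identical points make K > 1 degenerate (warned).
    """
    from sklearn.cluster import KMeans

    S = pca_result.scores if isinstance(pca_result, PCAResult) else np.asarray(pca_result)
    if n_pcs is not None:
        S = S[:, :n_pcs]
    n = S.shape[0]
    if max(k_range) > n:
        raise ValueError("K exceeds the number of individuals")
    if np.all(np.ptp(S, axis=0) == 0):
        warnings.warn("identical points: clustering degenerate for K > 1")
    rows = []
    assignments = {}
    for K in k_range:
        km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(S)
        wss = float(km.inertia_)
        bic = n * np.log(max(wss, 1e-12) / n) + K * np.log(n)
        rows.append({"k": int(K), "wss": wss, "bic": float(bic)})
        assignments[int(K)] = km.labels_
    curve = pd.DataFrame(rows)
    chosen = k_select or int(curve.loc[curve["bic"].idxmin(), "k"])
    return assignments[chosen], curve


def assignment_accuracy(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Percent of max-posterior assignments matching labels, best permutation.

    Label-to-cluster matching is solved by the Hungarian algorithm on the
    contingency table, so the statistic is invariant to label switching.  If
    the cluster and label counts differ, matching is on the smaller set
    (flagged with a warning).
    """
    posteriors = np.asarray(posteriors, dtype=float)
    labels = np.asarray(labels)
    if posteriors.shape[0] != len(labels):
        raise ValueError("labels must align with posteriors")
    hard = posteriors.argmax(axis=1)
    uniq, y = np.unique(labels, return_inverse=True)
    kc, kl = posteriors.shape[1], len(uniq)
    if kc != kl:
        warnings.warn(f"{kc} clusters vs {kl} labels; matching on the smaller")
    table = np.zeros((kc, kl))
    np.add.at(table, (hard, y), 1)
    ri, ci = linear_sum_assignment(-table)
    return float(table[ri, ci].sum() / len(labels) * 100.0)
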