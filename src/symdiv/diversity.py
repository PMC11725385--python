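"""Community diversity statistics for collapsed symbiont count tables.

Alpha diversity is the Shannon index per sample, mapped to Pielou evenness
on (0, 1) so that group effects can be modelled by beta regression with a
logit mean link. Beta diversity uses Bray-Curtis dissimilarities, ordinated
by non-metric multidimensional scaling (NMDS, Kruskal stress-1) and tested
by label-permutation statistics: PERMANOVA pseudo-F, ANOSIM R, and a
multivariate dispersion test (distance to group centroid in a principal
coordinate embedding).

All permutation p-values use the +1 convention,
p = (#{permuted statistic >= observed} + 1) / (n_perm + 1),
and are reproducible under an explicit seed. Small designs can be tested by
exhaustive enumeration of label permutations instead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "BetaRegressionFit",
    "OrdinationResult",
    "PermutationTestResult",
    "shannon_index",
    "shannon_per_sample",
    "squeeze_to_unit_interval",
    "fit_beta_regression",
    "pairwise_group_tests",
    "bray_curtis",
    "nmds",
    "permanova",
    "anosim",
    "betadisper",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(m).all() or (m < -1e-12).any():
            raise ValueError("distances must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))


def shannon_index(values) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), zero entries excluded."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: pd.DataFrame) -> pd.Series:
    """Shannon index for each row of a samples x taxa abundance table."""
    return pd.Series(
        {sid: shannon_index(table.loc[sid].to_numpy()) for sid in table.index},
        name="shannon",
    )


def squeeze_to_unit_interval(
    values, mode: str = "evenness", s_total: int | None = None
) -> np.ndarray:
    """Map diversity values into the open unit interval for beta regression.

    ``evenness``: divide Shannon H by ln(S_total) (Pielou evenness over the
    dataset-wide richness ``s_total``) and then squeeze. ``squeeze``: apply
    the boundary transform (y * (n - 1) + 0.5) / n to values already in
    [0, 1], which moves exact 0/1 strictly inside the interval.
    """
    y = np.asarray(values, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite values")
    n = y.size
    if mode == "evenness":
        if s_total is None or s_total < 2:
            raise ValueError("evenness mode requires richness s_total >= 2")
        y = y / np.log(s_total)
    elif mode != "squeeze":
        raise ValueError(f"unknown mode {mode!r}")
    if (y < -1e-9).any() or (y > 1 + 1e-9).any():
        raise ValueError("values must lie in [0, 1] before squeezing")
    y = np.clip(y, 0.0, 1.0)
    return (y * (n - 1) + 0.5) / n


@dataclass(frozen=True)
class BetaRegressionFit:
    """Beta regression with logit mean link and a single precision phi.

    ``coef`` are mean-model coefficients on the logit scale (treatment
    coding against the first group level in sorted order). The response
    and design are kept so that pairwise contrasts can be calibrated by
    label permutation.
    """

    coef: pd.Series
    se: pd.Series
    phi: float
    loglik: float
    converged: bool
    levels: tuple[str, ...]
    cov: np.ndarray = field(repr=False)
    n: int = 0
    endog: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def fitted_mean(self, level: str) -> float:
        eta = self.coef.iloc[0]
        if level != self.levels[0]:
            eta = eta + self.coef[f"group[{level}]"]
        return float(1.0 / (1.0 + np.exp(-eta)))


def _design_matrix(groups) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    labels = pd.Series(list(groups), dtype="object")
    levels = tuple(sorted(labels.unique()))
    cols = ["Intercept"] + [f"group[{lv}]" for lv in levels[1:]]
    X = np.zeros((len(labels), len(cols)))
    X[:, 0] = 1.0
    for j, lv in enumerate(levels[1:], start=1):
        X[:, j] = (labels == lv).to_numpy(dtype=float)
    return X, cols, levels


def fit_beta_regression(y, groups) -> BetaRegressionFit:
    """ML beta regression of a (0,1) response on group membership.

    The response is beta distributed with shape (mu*phi, (1-mu)*phi) and
    mu = logistic(x'beta). The likelihood is maximised by quasi-Newton
    (BFGS) from the model's method-of-moments start values; standard errors
    come from the inverse observed information. Boundary responses are a
    support violation and rejected.
    """
    yv = np.asarray(y, dtype=float)
    if ((yv <= 0) | (yv >= 1)).any():
        raise ValueError("responses must lie strictly inside (0, 1)")
    X, cols, levels = _design_matrix(groups)
    if len(yv) <= len(levels):
        raise ValueError("need more observations than groups")
    model = BetaModel(yv, X, exog_precision=np.ones((len(yv), 1)))
    res = model.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    k = len(cols)
    params = res.params
    cov = np.asarray(res.cov_params())[:k, :k]
    phi = float(np.exp(params[k]))  # precision uses a log link
    return BetaRegressionFit(
        coef=pd.Series(params[:k], index=cols),
        se=pd.Series(np.sqrt(np.diag(cov)), index=cols),
        phi=phi,
        loglik=float(res.llf),
        converged=converged,
        levels=levels,
        cov=cov,
        n=len(yv),
        endog=yv,
        labels=np.asarray(list(groups), dtype=object),
    )


def _wald_contrasts(fit: BetaRegressionFit, params: np.ndarray, cov: np.ndarray):
    """Estimates, SEs and z for all pairwise group contrasts (logit scale)."""
    levels = fit.levels
    idx = list(fit.coef.index)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = np.zeros(len(idx))
        if a != levels[0]:
            c[idx.index(f"group[{a}]")] = 1.0
        if b != levels[0]:
            c[idx.index(f"group[{b}]")] = -1.0
        est = float(c @ params)
        var = float(c @ cov @ c)
        if var <= 0:
            raise ValueError(f"singular contrast {a} - {b}")
        rows.append((a, b, est, np.sqrt(var), est / np.sqrt(var)))
    return rows


def _refit_z(yv: np.ndarray, labels: np.ndarray, start: np.ndarray):
    """Warm-started refit returning mean coefficients and their covariance."""
    X, cols, _levels = _design_matrix(labels)
    k = len(cols)
    model = BetaModel(yv, X, exog_precision=np.ones((len(yv), 1)))
    res = model.fit(start_params=start, method="bfgs", maxiter=200, disp=False)
    params = res.params[:k]
    cov = np.asarray(res.cov_params())[:k, :k]
    if not (np.isfinite(params).all() and np.isfinite(cov).all()):
        res = model.fit(method="bfgs", maxiter=500, disp=False)  # cold restart
        params = res.params[:k]
        cov = np.asarray(res.cov_params())[:k, :k]
    if not (np.isfinite(params).all() and np.isfinite(cov).all()):
        raise FloatingPointError("beta regression refit did not converge")
    return params, cov


def pairwise_group_tests(
    fit: BetaRegressionFit,
    p_mode: str = "permutation",
    n_perm: int = 199,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise group contrasts from a beta-regression fit, Holm-adjusted.

    Contrasts are differences of group means on the logit scale with Wald
    z statistics. Their null reference is, by default, a label-permutation
    distribution (the model is refit under each permutation and the
    permuted |z| compared with the observed one, +1 convention): at the
    study's group sizes the asymptotic normal reference is anticonservative
    for these boundary-adjacent evenness values, while the permutation
    reference is exact under group exchangeability. ``p_mode="wald"``
    selects the plain normal reference. Holm adjustment controls the
    family-wise error rate over all pairwise comparisons.
    """
    if len(fit.levels) < 2:
        raise ValueError("need at least 2 groups")
    observed = _wald_contrasts(fit, fit.coef.to_numpy(), fit.cov)
    if p_mode == "wald":
        pvals = [2 * stats.norm.sf(abs(z)) for *_x, z in observed]
    elif p_mode == "permutation":
        if fit.endog is None or fit.labels is None:
            raise ValueError("fit lacks data; refit with fit_beta_regression")
        rng = np.random.default_rng(seed)
        # start from the observed solution (mean coefs + log phi)
        start = np.append(fit.coef.to_numpy(), np.log(fit.phi))
        obs_abs = np.array([abs(z) for *_x, z in observed])
        exceed = np.zeros(len(observed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(n_perm):
                labels_p = rng.permutation(fit.labels)
                try:
                    params_p, cov_p = _refit_z(fit.endog, labels_p, start)
                    perm = _wald_contrasts(fit, params_p, cov_p)
                    perm_abs = np.array([abs(z) for *_x, z in perm])
                    exceed += perm_abs >= obs_abs - 1e-12
                except Exception:
                    exceed += 1  # failed refit counted as exceeding
        pvals = ((exceed + 1) / (n_perm + 1)).tolist()
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    out = pd.DataFrame(
        observed, columns=["group1", "group2", "estimate", "se", "z"]
    )
    out["p"] = pvals
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    return out


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = table.to_numpy(dtype=float)
    if (X.sum(axis=1) <= 0).any():
        bad = table.index[X.sum(axis=1) <= 0].tolist()
        raise ValueError(f"zero-total samples: {bad}")
    m = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(ids=tuple(str(i) for i in table.index), matrix=m)


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS embedding with Kruskal stress-1 for the best restart."""

    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    stress_history: tuple[float, ...] = field(repr=False, default=())


def _pcoa_embedding(D: np.ndarray, k: int, lingoes: bool = False):
    """Classical scaling of a distance matrix; optionally Lingoes-corrected.

    Returns (coords over positive eigenvalues, eigenvalues). The Lingoes
    correction adds twice the magnitude of the most negative eigenvalue to
    every off-diagonal squared distance, which makes the corrected Gower
    matrix positive semi-definite while preserving the original distance
    ordering.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = (G + G.T) / 2
    evals, evecs = np.linalg.eigh(G)
    if lingoes and evals.min() < -1e-8 * max(1.0, abs(evals).max()):
        c = -evals.min()
        D2c = D**2 + 2 * c * (1 - np.eye(n))
        G = -0.5 * J @ D2c @ J
        G = (G + G.T) / 2
        evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals).max())
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if k is not None:
        if coords.shape[1] < k:
            coords = np.hstack(
                [coords, np.zeros((n, k - coords.shape[1]))]
            )
        coords = coords[:, :k]
    return coords, evals


def _stress1(d_cond: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d_cond**2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d_cond - dhat) ** 2).sum() / denom))


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Alternates monotone (pool-adjacent-violators, ties averaged) regression
    of the configuration distances on the input dissimilarities with a
    Guttman-transform update of the coordinates. One restart is seeded from
    the classical (principal coordinate) embedding, the rest from random
    Gaussian configurations; the lowest-stress restart is returned.
    Deterministic under ``seed``.
    """
    n = D.n
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    diss = D.condensed()
    if not np.isfinite(diss).all():
        raise ValueError("non-finite distances")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def run(X0: np.ndarray):
        X = X0.copy()
        d = pdist(X)
        dhat = iso.fit(diss, d).predict(diss)
        stress = _stress1(d, dhat)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform with the current disparities
            Dsq = squareform(d, checks=False)
            ratio = np.zeros_like(Dsq)
            nz = Dsq > 1e-12
            Dhat_sq = squareform(dhat, checks=False)
            ratio[nz] = Dhat_sq[nz] / Dsq[nz]
            B = -ratio
            np.fill_diagonal(B, -B.sum(axis=1))
            Xn = B @ X / n
            dn = pdist(Xn)
            dhn = iso.fit(diss, dn).predict(diss)
            sn = _stress1(dn, dhn)
            if sn > stress + 1e-12:
                converged = True  # majorization exhausted at this precision
                break
            X, d, dhat = Xn, dn, dhn
            delta = stress - sn
            stress = sn
            history.append(stress)
            if delta < tol:
                converged = True
                break
        return X, stress, history, converged

    inits = [_pcoa_embedding(D.matrix, k)[0]]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.standard_normal((n, k)))
    best = None
    for X0 in inits:
        X, stress, history, conv = run(X0)
        if best is None or stress < best[1]:
            best = (X, stress, history, conv)
    X, stress, history, conv = best
    return OrdinationResult(
        coordinates=X,
        stress=stress,
        n_restarts=len(inits),
        converged=conv,
        stress_history=tuple(history),
    )


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None
    method: str
    parametric_p: float | None = None
    extras: dict = field(default_factory=dict, repr=False)


def _check_groups(D: DistanceMatrix, groups) -> np.ndarray:
    labels = np.asarray(list(groups), dtype=object)
    if len(labels) != D.n:
        raise ValueError("group labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    return labels


def _permanova_f(D2: np.ndarray, labels: np.ndarray) -> float:
    n = D2.shape[0]
    uniq = np.unique(labels)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.where(labels == g)[0]
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    k = len(uniq)
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def _distinct_labelings(labels: np.ndarray):
    """All distinct orderings of a label multiset (exhaustive enumeration)."""
    seen = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm, dtype=object)


def _perm_pvalue_batch(
    stat_fn, labels: np.ndarray, n_perm, seed, observed: float
) -> tuple[float, int]:
    """Permutation p with the +1 convention, or exact enumeration."""
    if n_perm == "exhaustive":
        stats_all = [stat_fn(lab) for lab in _distinct_labelings(labels)]
        count = sum(1 for s in stats_all if s >= observed - 1e-12)
        return count / len(stats_all), len(stats_all)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        s = stat_fn(rng.permutation(labels))
        if s >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1), n_perm


def permanova(
    D: DistanceMatrix, groups, n_perm: int | str = 999, seed: int | None = None
) -> PermutationTestResult:
    """One-factor PERMANOVA pseudo-F with a label-permutation p-value.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums the analogous
    quantity per group; pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)).
    ``n_perm="exhaustive"`` enumerates every distinct labeling and reports
    the exact tail proportion (the identity labeling included).
    """
    labels = _check_groups(D, groups)
    D2 = D.matrix**2

    observed = _permanova_f(D2, labels)
    p, np_used = _perm_pvalue_batch(
        lambda lab: _permanova_f(D2, lab), labels, n_perm, seed, observed
    )
    return PermutationTestResult(
        statistic=float(observed), p_value=float(p), n_perm=np_used, seed=seed,
        method="permanova",
    )


def _anosim_r(rank_sq: np.ndarray, labels: np.ndarray) -> float:
    n = rank_sq.shape[0]
    iu = np.triu_indices(n, 1)
    same = (labels[iu[0]] == labels[iu[1]])
    ranks = rank_sq[iu]
    r_within = ranks[same].mean()
    r_between = ranks[~same].mean()
    return (r_between - r_within) / (n * (n - 1) / 4)


def anosim(
    D: DistanceMatrix, groups, n_perm: int | str = 999, seed: int | None = None
) -> PermutationTestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).

    Ranks are over all n(n-1)/2 dissimilarities, ties averaged; tested by
    label permutation with the +1 convention (or exhaustively).
    """
    labels = _check_groups(D, groups)
    cond = D.condensed()
    rank_sq = squareform(stats.rankdata(cond), checks=False)

    observed = _anosim_r(rank_sq, labels)
    p, np_used = _perm_pvalue_batch(
        lambda lab: _anosim_r(rank_sq, lab), labels, n_perm, seed, observed
    )
    return PermutationTestResult(
        statistic=float(observed), p_value=float(p), n_perm=np_used, seed=seed,
        method="anosim",
    )


def betadisper(
    D: DistanceMatrix, groups, n_perm: int | str = 0, seed: int | None = None
) -> PermutationTestResult:
    """Multivariate dispersion test (distance to group centroid).

    The distance matrix is embedded by principal coordinates with a
    Lingoes-style additive correction when negative eigenvalues arise, each
    sample's Euclidean distance to its group centroid (mean) is computed in
    the embedding, and group differences in those distances are tested by a
    one-way ANOVA F (parametric p) and, optionally, by permuting group
    labels. Per-sample centroid distances are returned in ``extras``.
    """
    labels = _check_groups(D, groups)
    coords, _ = _pcoa_embedding(D.matrix, k=None, lingoes=True)

    def disp_f(lab: np.ndarray) -> tuple[float, np.ndarray]:
        dists = np.empty(len(lab))
        for g in np.unique(lab):
            idx = np.where(lab == g)[0]
            centroid = coords[idx].mean(axis=0)
            dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
        grand = dists.mean()
        ss_between = ss_within = 0.0
        k_groups = 0
        for g in np.unique(lab):
            gd = dists[lab == g]
            ss_between += len(gd) * (gd.mean() - grand) ** 2
            ss_within += ((gd - gd.mean()) ** 2).sum()
            k_groups += 1
        nn = len(lab)
        scale = (dists**2).sum() + 1e-300  # relative zero guard
        if ss_between <= 1e-12 * scale and ss_within <= 1e-12 * scale:
            return 0.0, dists
        if ss_within <= 1e-12 * scale:
            return np.inf, dists
        return float(
            (ss_between / (k_groups - 1)) / (ss_within / (nn - k_groups))
        ), dists

    observed, centroid_dists = disp_f(labels)
    k = len(np.unique(labels))
    n = len(labels)
    parametric_p = float(stats.f.sf(observed, k - 1, n - k))
    if n_perm:
        p, np_used = _perm_pvalue_batch(
            lambda lab: disp_f(lab)[0], labels, n_perm, seed, observed
        )
    else:
        p, np_used = parametric_p, 0
    return PermutationTestResult(
        statistic=float(observed),
        p_value=float(p),
        n_perm=np_used,
        seed=seed,
        method="betadisper",
        parametric_p=parametric_p,
        extras={"centroid_distances": centroid_dists},
    )
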