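"""Phylogenetic generalized least squares and phylogenetic signal.

Species-level quantities (here: per-pair mimetic-accuracy distances keyed by
the mimic species) are not independent — close relatives resemble each other.
Under Brownian-motion trait evolution the expected among-species covariance is
proportional to shared branch length: C_ij = depth of the most recent common
ancestor of tips i and j.  This module builds that matrix from a Newick tree
and fits linear models whose error covariance is

- Brownian: V = C,
- Pagel: V(λ) = λ·C off-diagonal, diagonal unchanged (λ = 0: star phylogeny,
  λ = 1: Brownian; λ may go below 0 as far as positive-definiteness allows),
- Martins (Ornstein–Uhlenbeck): correlation exp(−α·d_ij) in patristic
  distance d.

λ is estimated by profile maximum likelihood; covariance structures are
compared by AIC on the same ML likelihood; term significance uses drop-one
Wald-type F tests with residual denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

STRUCTURES = ("pagel", "brownian", "martins")


# ---------------------------------------------------------------------------
# tree -> covariance


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    s = str(tree)
    if s.lstrip().startswith("("):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


@dataclass
class PhyloCovariance:
    """Among-species covariance C_ij = shared root-to-MRCA path length."""

    matrix: np.ndarray
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.tip_labels)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape must match tip labels")

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.tip_labels.index(l) for l in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))


def tree_to_vcv(tree: dendropy.Tree | str) -> PhyloCovariance:
    """Phylogenetic variance–covariance matrix from a rooted tree.

    C_ij is the depth (root-to-node path length) of the MRCA of tips i and j;
    the diagonal holds root-to-tip distances.
    """
    t = _as_tree(tree)
    tips = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    n = len(tips)
    index = {lab: i for i, lab in enumerate(tips)}
    C = np.zeros((n, n))
    # depth of every node; missing edge lengths are an error (root edge may be None)
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node._depth = node.edge.length or 0.0
        else:
            if node.edge.length is None:
                raise ValueError("tree has missing branch lengths")
            node._depth = node.parent_node._depth + node.edge.length
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            node._tipset = [i]
            C[i, i] = node._depth
        else:
            kids = [ch._tipset for ch in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = node._depth
            node._tipset = [i for k in kids for i in k]
    return PhyloCovariance(C, tips)


def _lambda_bounds(C: np.ndarray, margin: float = 0.05) -> tuple[float, float]:
    """Search range of λ keeping V(λ) = D + λ(C − D) well conditioned (D = diag C).

    The exact positive-definiteness limits are −1/μ_max and 1/(−μ_min) for the
    extreme eigenvalues μ of the off-diagonal correlation part.  Within ~1e-3
    of the exact limit the profile likelihood develops a spurious spike (a
    near-zero eigenvalue acts as an almost-deterministic constraint the data
    happen to satisfy), so the bounds keep the smallest correlation eigenvalue
    at least ``margin``; λ = 1 is always admitted since C itself is PD.
    """
    d = np.sqrt(np.diag(C))
    B = (C - np.diag(np.diag(C))) / np.outer(d, d)
    mu = np.linalg.eigvalsh(B)
    lo = -(1.0 - margin) / mu[-1] if mu[-1] > 0 else -np.inf
    hi = (1.0 - margin) / (-mu[0]) if mu[0] < 0 else np.inf
    return lo, max(hi, 1.0)


def apply_lambda(C: PhyloCovariance | np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: multiply off-diagonal covariances by λ."""
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    V = lam * M
    np.fill_diagonal(V, np.diag(M))
    # positive (semi-)definiteness check with a tolerance for discretization
    w_min = float(np.linalg.eigvalsh(V)[0])
    if w_min < -1e-9 * float(np.max(np.diag(M))):
        lo, hi = _lambda_bounds(M)
        raise ValueError(f"lambda={lam:g} outside positive-definite range [{lo:.4f}, {hi:.4f}]")
    return V


def martins_correlation(tree: dendropy.Tree | str, alpha: float) -> PhyloCovariance:
    """Ornstein–Uhlenbeck correlation exp(−α·d_ij) in patristic distance."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        import logging

        logging.getLogger(__name__).warning(
            "martins_correlation with alpha=0 is the all-ones matrix (singular)"
        )
    t = _as_tree(tree)
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    n = len(taxa)
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            R[i, j] = R[j, i] = np.exp(-alpha * d)
    return PhyloCovariance(R, labels)


# ---------------------------------------------------------------------------
# GLS core


@dataclass
class GLSFit:
    """A generalized least-squares fit under a fixed error covariance."""

    coef: np.ndarray
    se: np.ndarray
    sigma2: float  # ML residual variance scale
    loglik: float
    loglik_reml: float
    n_params: int  # parameters counted in AIC (mean + scale + structure)
    nobs: int
    names: list[str] = field(default_factory=list)
    structure: str = "fixed"
    structure_param: float | None = None
    cov_unscaled: np.ndarray | None = None  # (X' V^-1 X)^-1
    rss_gls: float = np.nan  # (y-Xb)' V^-1 (y-Xb)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.coef)

    def f_test(self, terms: list[int] | int) -> tuple[float, int, int, float]:
        """Drop-one Wald-type F test for the given coefficient indices.

        Returns (F, df_num, df_den, p).  The denominator uses residual df and
        the unbiased residual variance, matching classical GLS ANOVA output.
        """
        if np.isscalar(terms):
            terms = [int(terms)]
        q = len(terms)
        b = self.coef[terms]
        s2_unbiased = self.rss_gls / self.df_resid
        cov = s2_unbiased * self.cov_unscaled[np.ix_(terms, terms)]
        F = float(b @ np.linalg.solve(cov, b) / q)
        p = float(stats.f.sf(F, q, self.df_resid))
        return F, q, self.df_resid, p


def gls_fit(
    X: np.ndarray,
    y: np.ndarray,
    V: np.ndarray,
    names: list[str] | None = None,
    extra_params: int = 0,
    structure: str = "fixed",
    structure_param: float | None = None,
) -> GLSFit:
    """Fit y = Xβ + ε, ε ~ N(0, σ²V), by ML.

    β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹y; σ̂² = RSS_V / n (ML); the log-likelihood is the
    multivariate-normal density at the optimum.  ``extra_params`` counts
    estimated covariance-structure parameters (λ or α) into the AIC.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y disagree in length")
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError("covariance matrix is not positive definite") from e
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    cov_unscaled = np.linalg.inv(XtX)
    beta = cov_unscaled @ Xw.T @ yw
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
    p = X.shape[1]
    s2_reml = rss / (n - p)
    _, logdetXtX = np.linalg.slogdet(XtX)
    loglik_reml = -0.5 * ((n - p) * np.log(2 * np.pi * s2_reml) + logdetV + logdetXtX + (n - p))
    se = np.sqrt(np.diag(cov_unscaled) * rss / (n - p))
    return GLSFit(
        coef=beta,
        se=se,
        sigma2=sigma2,
        loglik=loglik,
        loglik_reml=loglik_reml,
        n_params=p + 1 + extra_params,
        nobs=n,
        names=names or [f"b{i}" for i in range(p)],
        structure=structure,
        structure_param=structure_param,
        cov_unscaled=cov_unscaled,
        rss_gls=rss,
    )


# ---------------------------------------------------------------------------
# Pagel's lambda


@dataclass
class SignalEstimate:
    lam: float
    loglik: float
    bounds: tuple[float, float]
    fit: GLSFit


def estimate_lambda(
    X: np.ndarray,
    y: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    lam_max: float = 1.0,
    method: str = "reml",
) -> SignalEstimate:
    """Profile estimate of Pagel's λ for y = Xβ + ε, ε ~ N(0, σ²C(λ)).

    The search interval is [λ_min, λ_max] where λ_min is the smallest λ
    keeping C(λ) positive definite and well conditioned (this permits
    negative estimates) and λ_max defaults to 1.  The profile objective is
    the restricted likelihood by default: plain ML is noticeably biased
    toward 0 at intermediate λ on trees of the study's size, while REML
    recovers λ essentially unbiasedly; pass ``method="ml"`` where ML
    likelihoods are needed (e.g. AIC comparison across mean structures).
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    y = np.asarray(y, float).ravel()
    if len(y) < 4:
        raise ValueError("need at least 4 observations to profile lambda")
    lo, hi = _lambda_bounds(M)
    lo = max(lo, -lam_max)  # keep the search on a sane range even for star-like C
    hi = min(hi, lam_max)

    def nll(lam: float) -> float:
        V = lam * M
        np.fill_diagonal(V, np.diag(M))
        try:
            f = gls_fit(X, y, V)
            return -(f.loglik_reml if method == "reml" else f.loglik)
        except ValueError:
            return np.inf

    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    lam = float(res.x)
    # guard against an interior optimizer missing a boundary optimum
    for cand in (lo, hi):
        if nll(cand) < res.fun:
            lam = cand
            res.fun = nll(cand)
    V = apply_lambda(M, lam)
    fit = gls_fit(X, y, V, extra_params=1, structure="pagel", structure_param=lam)
    return SignalEstimate(lam=lam, loglik=fit.loglik, bounds=(lo, hi), fit=fit)


def lambda_signal(
    values: np.ndarray, C: PhyloCovariance | np.ndarray, method: str = "reml"
) -> SignalEstimate:
    """Phylogenetic signal of one variable: intercept-only profile λ."""
    y = np.asarray(values, float).ravel()
    X = np.ones((len(y), 1))
    return estimate_lambda(X, y, C, method=method)


# ---------------------------------------------------------------------------
# PGLS regression / ANCOVA


def _ancova_design(
    x: np.ndarray, taxon: np.ndarray
) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(set(taxon))
    x = np.asarray(x, float).ravel()
    if len(levels) == 1:
        return np.column_stack([np.ones_like(x), x]), ["intercept", "slope"], levels
    if len(levels) != 2:
        raise ValueError("taxon factor must have 1 or 2 levels")
    ind = (np.asarray(taxon) == levels[1]).astype(float)
    X = np.column_stack([np.ones_like(x), x, ind, x * ind])
    names = ["intercept", "slope", f"{levels[1]}", f"slope:{levels[1]}"]
    return X, names, levels


@dataclass
class AncovaFit:
    fit: GLSFit
    lam: float
    levels: list[str]
    slopes: dict[str, float]
    interaction_F: tuple[float, int, int, float] | None  # F, df1, df2, p
    slope_F: tuple[float, int, int, float]


def pgls_ancova(
    y: np.ndarray,
    x: np.ndarray,
    taxon: np.ndarray,
    C: PhyloCovariance | np.ndarray,
) -> AncovaFit:
    """ANCOVA y ~ x × taxon under a Pagel covariance with jointly ML-fit λ.

    With a single-level factor this reduces to simple PGLS regression.
    Per-level slopes are the reference slope and slope + interaction.
    """
    taxon = np.asarray(taxon)
    for lev in set(taxon):
        if int(np.sum(taxon == lev)) < 3:
            raise ValueError(f"taxon level {lev!r} has fewer than 3 tips")
    X, names, levels = _ancova_design(x, taxon)
    est = estimate_lambda(X, np.asarray(y, float), C)
    fit = est.fit
    fit.names = names
    if len(levels) == 2:
        slopes = {levels[0]: float(fit.coef[1]), levels[1]: float(fit.coef[1] + fit.coef[3])}
        interaction = fit.f_test(3)
    else:
        slopes = {levels[0]: float(fit.coef[1])}
        interaction = None
    return AncovaFit(
        fit=fit,
        lam=est.lam,
        levels=levels,
        slopes=slopes,
        interaction_F=interaction,
        slope_F=fit.f_test(1),
    )


def phylo_correlation(
    d1: np.ndarray, d2: np.ndarray, C: PhyloCovariance | np.ndarray | None = None
) -> float:
    """Pearson correlation of two species variables under a phylogenetic GLS.

    Both variables are centred by a GLS intercept fit under the structure V
    (Pagel with a jointly profiled λ when a phylogenetic covariance is given;
    the identity otherwise) and the residuals are whitened by the inverse
    Cholesky factor of V before the ordinary correlation is taken.  With
    V = I this is exactly the ordinary Pearson correlation.
    """
    d1 = np.asarray(d1, float).ravel()
    d2 = np.asarray(d2, float).ravel()
    if d1.shape != d2.shape:
        raise ValueError("variables must share the tip set")
    n = len(d1)
    if np.std(d1) == 0 or np.std(d2) == 0:
        raise ValueError("zero variance variable")
    if C is None:
        V = np.eye(n)
    else:
        M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
        X = np.ones((n, 1))
        # one λ for the pair: maximize the summed profile likelihoods
        lo, hi = _lambda_bounds(M)
        lo, hi = max(lo, -1.0), min(hi, 1.0)

        def nll(lam: float) -> float:
            Vl = lam * M
            np.fill_diagonal(Vl, np.diag(M))
            try:
                return -(gls_fit(X, d1, Vl).loglik + gls_fit(X, d2, Vl).loglik)
            except ValueError:
                return np.inf

        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        V = apply_lambda(M, float(res.x))
    L = linalg.cholesky(V, lower=True)
    X = np.ones((n, 1))
    e = []
    for d in (d1, d2):
        f = gls_fit(X, d, V)
        e.append(linalg.solve_triangular(L, d - X @ f.coef, lower=True))
    num = float(e[0] @ e[1])
    den = float(np.linalg.norm(e[0]) * np.linalg.norm(e[1]))
    if den == 0:
        raise ValueError("zero variance after whitening")
    return num / den


def select_structure(fits: dict[str, GLSFit]) -> str:
    """Pick the covariance structure with minimal AIC; ties favour fewer params."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted structures to compare")
    return min(fits.items(), key=lambda kv: (kv[1].aic, kv[1].n_params))[0]


def bonferroni(p_values: np.ndarray | list[float], m: int | None = None, alpha: float = 0.05):
    """Bonferroni decisions: significant iff p < alpha/m."""
    p = np.asarray(p_values, float)
    m = m if m is not None else len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m
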