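"""Nested random-intercept mixed models for trait comparisons.

Each trait is compared among the three mimetic types (ant, control, mimic)
with a linear mixed model whose random intercepts reflect the sampling
design: mimic–ant–control triplets are nested inside eight taxonomic groups.
Variance components are reported as percentages of the total (group, triplet,
residual).  Per-pair distances are compared between pair types (mimic–ant vs
mimic–control) with the mimetic pair as random intercept, and the four
scaled category accuracies are compared with the pair as random intercept.

Estimation is REML via statsmodels ``MixedLM``; fixed factors are tested with
Wald-type F statistics on residual denominator df.  Square-root and angular
(arcsin-sqrt) transforms are provided for traits and proportions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "sqrt", "angular")


def transform(values: np.ndarray, kind: str) -> np.ndarray:
    """Variance-stabilizing transform: sqrt for counts/ratios, arcsin-sqrt for proportions."""
    x = np.asarray(values, dtype=float)
    if kind == "none":
        return x
    if kind == "sqrt":
        if np.any(x < 0):
            raise ValueError("sqrt transform requires values >= 0")
        return np.sqrt(x)
    if kind == "angular":
        if np.any((x < 0) | (x > 1)):
            raise ValueError("angular transform requires proportions in [0, 1]")
        return np.arcsin(np.sqrt(x))
    raise ValueError(f"unknown transform {kind!r}; expected one of {TRANSFORMS}")


@dataclass
class VarianceComponents:
    group: float
    triplet: float
    residual: float

    @property
    def total(self) -> float:
        return self.group + self.triplet + self.residual

    @property
    def percents(self) -> tuple[float, float, float]:
        t = self.total
        return (100 * self.group / t, 100 * self.triplet / t, 100 * self.residual / t)


@dataclass
class LMEFit:
    """Fixed-effect summary of one REML mixed-model fit."""

    terms: list[str]
    estimates: np.ndarray  # estimated level means (or effects, see context)
    ci_low: np.ndarray
    ci_high: np.ndarray
    F: float
    df_num: int
    df_den: int
    p_value: float
    varcomp: VarianceComponents | None
    loglik: float  # REML
    nobs: int


def _fit_mixedlm(model: MixedLM) -> "MixedLMResults":
    """REML fit with a fallback optimizer chain for hard likelihoods."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=True, method=method, maxiter=200)
                if res.converged:
                    # polish: lbfgs stops ~1e-4 from the REML optimum, which is
                    # visible against closed-form estimators on balanced designs
                    try:
                        best = res
                        for _ in range(2):
                            res2 = model.fit(
                                reml=True, method="cg", start_params=best.params_object,
                                maxiter=5000, gtol=1e-14,
                            )
                            # cg rarely sets its convergence flag; judge by the
                            # restricted likelihood it reaches
                            if np.isfinite(res2.llf) and res2.llf >= best.llf - 1e-8:
                                best = res2
                        return best
                    except Exception:  # noqa: BLE001 - keep the unpolished fit
                        return res
            except Exception:  # noqa: BLE001 - try the next optimizer
                continue
    raise RuntimeError("mixed model failed to converge with lbfgs/bfgs/powell")


def _wald_F(res, idx: list[int], df_den: int) -> tuple[float, float]:
    """Wald F for a block of fixed-effect coefficients; returns (F, p)."""
    b = np.asarray(res.fe_params)[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    q = len(idx)
    if float(b @ b) < 1e-24:
        return 0.0, 1.0
    F = float(b @ np.linalg.solve(cov, b) / q)
    return F, float(stats.f.sf(F, q, df_den))


def _level_means_ci(res, levels: list[str], df_den: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimated marginal mean and 95% t CI per factor level (treatment coding)."""
    k = len(levels)
    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: k, : k]
    tcrit = stats.t.ppf(0.975, df_den)
    means, lo, hi = np.empty(k), np.empty(k), np.empty(k)
    for i in range(k):
        c = np.zeros(k)
        c[0] = 1.0
        if i > 0:
            c[i] = 1.0
        m = float(c @ fe[:k])
        s = float(np.sqrt(c @ cov @ c))
        means[i], lo[i], hi[i] = m, m - tcrit * s, m + tcrit * s
    return means, lo, hi


def fit_nested_lme(
    data: pd.DataFrame,
    response: str = "value",
    fixed: str = "mimetic_type",
    group: str = "group",
    triplet: str = "triplet_id",
    transform_kind: str = "none",
) -> LMEFit:
    """Trait ~ mimetic type with triplet-in-group nested random intercepts.

    ``data`` is tidy with one row per specimen measurement.  The response is
    transformed per ``transform_kind`` before fitting.  Variance components
    are reported for group, triplet (within group) and residual, as
    percentages of their sum.
    """
    df = data.dropna(subset=[response]).copy()
    if df[group].nunique() < 2:
        raise ValueError("need at least 2 taxonomic groups")
    df["_y"] = transform(df[response].to_numpy(), transform_kind)
    levels = sorted(df[fixed].unique())
    X = pd.get_dummies(df[fixed], drop_first=True, dtype=float)
    exog = np.column_stack([np.ones(len(df)), X.to_numpy()])
    vcf = {"triplet": f"0 + C({triplet})"}
    model = MixedLM.from_formula(
        f"_y ~ C({fixed})", groups=group, vc_formula=vcf, re_formula="1", data=df
    )
    res = _fit_mixedlm(model)
    var_group = float(np.asarray(res.cov_re)[0, 0])
    var_triplet = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    vc = VarianceComponents(var_group, var_triplet, float(res.scale))
    n = len(df)
    p = exog.shape[1]
    df_den = n - p
    idx = list(range(1, len(levels)))
    F, pval = _wald_F(res, idx, df_den)
    means, lo, hi = _level_means_ci(res, levels, df_den)
    return LMEFit(
        terms=[str(l) for l in levels],
        estimates=means,
        ci_low=lo,
        ci_high=hi,
        F=F,
        df_num=len(idx),
        df_den=df_den,
        p_value=pval,
        varcomp=vc,
        loglik=float(res.llf),
        nobs=n,
    )


def fit_pairtype_lme(
    data: pd.DataFrame,
    response: str = "distance",
    pair_type: str = "pair_type",
    pair: str = "pair_id",
) -> LMEFit:
    """Distance ~ pair type (mimic–ant vs mimic–control), pair as random intercept.

    Pairs observed under a single type carry no within-pair contrast and are
    dropped with a warning.
    """
    df = data.dropna(subset=[response]).copy()
    counts = df.groupby(pair)[pair_type].nunique()
    keep = counts[counts == 2].index
    dropped = counts.index.difference(keep)
    if len(dropped):
        logger.warning("dropping %d pairs observed under one type only", len(dropped))
        df = df[df[pair].isin(keep)]
    levels = sorted(df[pair_type].unique())
    if len(levels) != 2:
        raise ValueError("pair_type must have exactly 2 levels")
    model = MixedLM.from_formula(
        f"{response} ~ C({pair_type})", groups=pair, re_formula="1", data=df
    )
    res = _fit_mixedlm(model)
    n = len(df)
    df_den = n - 2
    F, pval = _wald_F(res, [1], df_den)
    means, lo, hi = _level_means_ci(res, levels, df_den)
    vc = VarianceComponents(0.0, float(np.asarray(res.cov_re)[0, 0]), float(res.scale))
    return LMEFit(
        terms=[str(l) for l in levels],
        estimates=means,
        ci_low=lo,
        ci_high=hi,
        F=F,
        df_num=1,
        df_den=df_den,
        p_value=pval,
        varcomp=vc,
        loglik=float(res.llf),
        nobs=n,
    )


def compare_categories_lme(
    data: pd.DataFrame,
    response: str = "scaled",
    category: str = "category",
    pair: str = "pair_id",
) -> LMEFit:
    """Scaled category accuracy ~ category (4 levels), pair as random intercept."""
    df = data.dropna(subset=[response]).copy()
    levels = sorted(df[category].unique())
    expected = {"color", "movement", "shape", "size"}
    missing = expected - set(levels)
    if missing:
        raise ValueError(f"categories entirely missing from data: {sorted(missing)}")
    model = MixedLM.from_formula(
        f"{response} ~ C({category})", groups=pair, re_formula="1", data=df
    )
    res = _fit_mixedlm(model)
    n = len(df)
    k = len(levels)
    df_den = n - k
    F, pval = _wald_F(res, list(range(1, k)), df_den)
    means, lo, hi = _level_means_ci(res, levels, df_den)
    vc = VarianceComponents(0.0, float(np.asarray(res.cov_re)[0, 0]), float(res.scale))
    return LMEFit(
        terms=[str(l) for l in levels],
        estimates=means,
        ci_low=lo,
        ci_high=hi,
        F=F,
        df_num=k - 1,
        df_den=df_den,
        p_value=pval,
        varcomp=vc,
        loglik=float(res.llf),
        nobs=n,
    )
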