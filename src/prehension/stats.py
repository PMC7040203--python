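"""The statistical battery for feature tables and ordinal ratings.

Four analyses, mirroring how prehension studies of this design are usually
reported:

* :func:`rm_anova` — repeated-measures ANOVA on subject-by-cell means for a
  fully within-subject factorial, with generalized eta squared effect sizes
  (native balanced sums-of-squares decomposition; every effect is tested
  against its interaction with subjects).
* :func:`lmm_fit` — linear mixed model with a per-participant random
  intercept (statsmodels ``MixedLM``); each fixed term is tested by a
  likelihood-ratio chi-square of ML-fitted nested models, matching the
  "b, SE, chi2(1), p" reporting style.
* :func:`clmm_fit` — cumulative-link (proportional-odds, logit) mixed model
  with a participant random intercept, fitted natively by maximising an
  adaptive Gauss-Hermite approximation of the marginal likelihood (mixed
  ordinal models have no canonical implementation in the scientific Python
  stack).
* :func:`kruskal_wallis` — rank-based H test across blocks, tie-corrected
  (scipy).

No multiple-testing correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ModelResult",
    "rm_anova",
    "lmm_fit",
    "clmm_fit",
    "kruskal_wallis",
    "format_term",
]


@dataclass
class ModelResult:
    """Tidy container for one fitted model.

    ``terms`` holds one dict per tested term; keys depend on the test
    family (``estimate``/``std_error``/``chi_square`` for regression-style
    models, ``F``/``df1``/``df2`` for the ANOVA) but always include
    ``name`` and ``p``.
    """

    model: str
    dv: str
    terms: list[dict]
    effect_sizes: dict = field(default_factory=dict)
    loglik: float | None = None
    n_obs: int = 0
    n_groups: int = 0
    converged: bool = True
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            row = {"model": self.model, "dv": self.dv, **t}
            if t["name"] in self.effect_sizes:
                row["eta2_g"] = self.effect_sizes[t["name"]]
            rows.append(row)
        return pd.DataFrame(rows)


def format_term(t: dict) -> str:
    """Human-readable one-liner in the conventional reporting style."""
    p = t.get("p")
    ptxt = "p = n.s." if p is None or np.isnan(p) else (
        "p < 0.001" if p < 0.001 else ("p < 0.01" if p < 0.01 else (
            "p < 0.05" if p < 0.05 else f"p = {p:.2f}"))
    )
    if "chi_square" in t:
        est = t.get("estimate")
        lead = f"b = {est:.2f}, SE = {t.get('std_error', float('nan')):.2f}, " if est is not None else ""
        return f"{t['name']}: {lead}chi2({t['df']}) = {t['chi_square']:.2f}, {ptxt}"
    if "F" in t:
        return f"{t['name']}: F({t['df1']},{t['df2']}) = {t['F']:.2f}, {ptxt}"
    if "H" in t:
        return f"{t['name']}: H({t['df']}) = {t['H']:.2f}, {ptxt}"
    return f"{t['name']}: {ptxt}"


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with generalized eta squared
# ---------------------------------------------------------------------------

def _balanced_cell_means(
    features: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list[list], list[str]]:
    keys = [subject, *within]
    g = features.groupby(keys, sort=True, observed=True)[dv].mean()
    levels = [sorted(features[k].unique()) for k in keys]
    expected = int(np.prod([len(lv) for lv in levels]))
    if len(g) != expected:
        missing = expected - len(g)
        raise ValueError(
            f"design is incomplete: {missing} empty subject-by-cell combinations; "
            "every subject needs at least one observation per cell"
        )
    idx = pd.MultiIndex.from_product(levels, names=keys)
    y = g.reindex(idx).to_numpy().reshape([len(lv) for lv in levels])
    return y, levels, keys


def rm_anova(
    features: pd.DataFrame,
    dv: str,
    within_factors: Sequence[str],
    subject: str = "participant_id",
) -> ModelResult:
    """Fully within-subject factorial ANOVA on subject-by-cell means.

    Each within-subject effect is tested against its subject interaction
    (no sphericity correction, as is conventional for 2-level factors).
    Generalized eta squared treats all factors as manipulated:
    ``SS_effect / (SS_effect + sum of all subject-involving SS)``.
    """
    within = list(within_factors)
    y, levels, keys = _balanced_cell_means(features, dv, within, subject)
    if np.allclose(y, y.flat[0]):
        return ModelResult(
            model="rm_anova", dv=dv, degenerate=True, n_obs=y.size,
            n_groups=y.shape[0],
            terms=[{"name": w, "F": np.nan, "df1": np.nan, "df2": np.nan, "p": np.nan}
                   for w in within],
        )
    axes_all = tuple(range(y.ndim))
    shape = y.shape
    grand = float(y.mean())

    effects: dict[frozenset, np.ndarray] = {}

    def effect(T: frozenset) -> np.ndarray:
        if T in effects:
            return effects[T]
        other = tuple(a for a in axes_all if a not in T)
        marg = y.mean(axis=other, keepdims=True) - grand
        for k in range(1, len(T)):
            for U in combinations(sorted(T), k):
                marg = marg - effect(frozenset(U))
        effects[T] = marg
        return marg

    ss: dict[frozenset, float] = {}
    df: dict[frozenset, int] = {}
    for k in range(1, len(axes_all) + 1):
        for T in combinations(axes_all, k):
            Tf = frozenset(T)
            e = effect(Tf)
            mult = int(np.prod([shape[a] for a in axes_all if a not in Tf]))
            ss[Tf] = float(mult * np.sum(e**2))
            df[Tf] = int(np.prod([shape[a] - 1 for a in Tf]))

    subject_ax = 0
    ss_subject_all = sum(v for T, v in ss.items() if subject_ax in T)

    terms = []
    effect_sizes = {}
    for k in range(1, len(within) + 1):
        for combo in combinations(range(1, len(keys)), k):
            E = frozenset(combo)
            Err = frozenset({subject_ax, *combo})
            name = ":".join(keys[a] for a in sorted(combo))
            F = (ss[E] / df[E]) / (ss[Err] / df[Err]) if ss[Err] > 0 else np.nan
            p = float(sps.f.sf(F, df[E], df[Err])) if np.isfinite(F) else np.nan
            terms.append(
                {"name": name, "F": float(F), "df1": df[E], "df2": df[Err], "p": p,
                 "ss": ss[E]}
            )
            effect_sizes[name] = ss[E] / (ss[E] + ss_subject_all)
    return ModelResult(
        model="rm_anova", dv=dv, terms=terms, effect_sizes=effect_sizes,
        n_obs=int(y.size), n_groups=int(shape[0]),
    )


# ---------------------------------------------------------------------------
# Linear mixed model with random intercept
# ---------------------------------------------------------------------------

def lmm_fit(
    features: pd.DataFrame,
    dv: str,
    fixed_terms: Sequence[str],
    subject: str = "participant_id",
    lrt: bool = True,
) -> ModelResult:
    """Random-intercept LMM; per-term likelihood-ratio tests of ML fits.

    Categorical predictors are treatment-coded in level-sorted order (e.g.
    content: empty is the reference, so a positive estimate means larger
    values for filled cups).  With ``lrt=False`` only the full model is
    fitted and Wald z p-values are reported (used in bulk simulations).
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    data = features.dropna(subset=[dv]).copy()
    if data[subject].nunique() < 2:
        raise ValueError("need at least 2 subjects for a random intercept")
    fixed_terms = list(fixed_terms)
    formula = f"{dv} ~ " + " + ".join(fixed_terms)

    def fit(f):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            m = smf.mixedlm(f, data, groups=data[subject])
            return m.fit(reml=False)

    full = fit(formula)
    singular = bool(np.asarray(full.cov_re).min() <= 1e-10)
    if singular:
        warnings.warn(
            f"random-intercept variance for {dv} is at the boundary (~0); "
            "fixed effects reduce to OLS", UserWarning, stacklevel=2,
        )

    terms = []
    for term in fixed_terms:
        # coefficient(s) whose design column belongs to this term
        names = [n for n in full.params.index
                 if n == term or n.startswith(f"{term}[")]
        est = float(full.params[names[0]]) if len(names) == 1 else None
        se = float(full.bse[names[0]]) if len(names) == 1 else None
        if lrt:
            rest = [t for t in fixed_terms if t != term]
            reduced = fit(f"{dv} ~ " + (" + ".join(rest) if rest else "1"))
            chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
            dof = max(1, len(names))
            p = float(sps.chi2.sf(chi2, dof))
        else:
            chi2, dof = np.nan, max(1, len(names))
            z = est / se if (est is not None and se) else np.nan
            p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        terms.append(
            {"name": term, "estimate": est, "std_error": se,
             "chi_square": chi2, "df": dof, "p": p}
        )
    return ModelResult(
        model="lmm", dv=dv, terms=terms, loglik=float(full.llf),
        n_obs=int(full.nobs), n_groups=int(data[subject].nunique()),
        converged=bool(full.converged),
        extra={"singular": singular,
               "random_intercept_var": float(np.asarray(full.cov_re)[0, 0])},
    )


# ---------------------------------------------------------------------------
# Cumulative-link mixed model (native, adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------

def _clmm_loglik(
    params: np.ndarray,
    X: np.ndarray,  # (J, n_max, p), zero-padded
    y: np.ndarray,  # (J, n_max), -1 on padding
    n_cat: int,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Negative marginal log-likelihood, adaptive Gauss-Hermite quadrature.

    Vectorised over subjects; padded observations get (lower, upper) =
    (-inf, +inf), hence probability 1 and zero contribution.
    """
    n_th = n_cat - 1
    p = X.shape[2]
    th = np.empty(n_th)
    th[0] = params[0]
    th[1:] = params[0] + np.cumsum(np.exp(params[1:n_th]))
    beta = params[n_th : n_th + p]
    sigma = np.exp(params[n_th + p])

    eta = X @ beta  # (J, n)
    pad = y < 0
    yc = np.clip(y, 0, n_cat - 1)
    upper = np.where((yc == n_cat - 1) | pad, np.inf, th[np.minimum(yc, n_th - 1)]) - eta
    lower = np.where((yc == 0) | pad, -np.inf, th[np.maximum(yc - 1, 0)]) - eta

    def derivs(z):  # z: (J,)
        u = upper - sigma * z[:, None]
        v = lower - sigma * z[:, None]
        Fu, Fv = expit(u), expit(v)
        pr = np.clip(Fu - Fv, 1e-300, None)
        fu = Fu * (1 - Fu)
        fv = Fv * (1 - Fv)
        r = (fu - fv) / pr
        d1 = -sigma * r
        d2 = sigma**2 * ((fu * (1 - 2 * Fu) - fv * (1 - 2 * Fv)) / pr - r**2)
        return d1.sum(axis=1), d2.sum(axis=1)

    # Newton search for the per-subject mode of h(z) = sum log p - z^2/2
    z = np.zeros(X.shape[0])
    for _ in range(8):
        g1, g2 = derivs(z)
        h2 = np.minimum(g2 - 1.0, -1e-8)
        z = z + np.clip(-(g1 - z) / h2, -3.0, 3.0)
    _, g2 = derivs(z)
    s = 1.0 / np.sqrt(np.clip(-(g2 - 1.0), 1e-8, None))  # (J,)

    zs = z[:, None] + np.sqrt(2.0) * s[:, None] * nodes[None, :]  # (J, Q)
    U = upper[:, None, :] - sigma * zs[:, :, None]
    V = lower[:, None, :] - sigma * zs[:, :, None]
    logpr = np.log(np.clip(expit(U) - expit(V), 1e-300, None)).sum(axis=2)  # (J, Q)
    lse = logpr - 0.5 * zs**2 + nodes[None, :] ** 2 + np.log(weights)[None, :]
    m = lse.max(axis=1)
    ll = m + np.log(np.exp(lse - m[:, None]).sum(axis=1)) \
        + np.log(np.sqrt(2.0) * s) - 0.5 * np.log(2 * np.pi)
    return -float(ll.sum())


def clmm_fit(
    ratings: pd.DataFrame,
    fixed_terms: Sequence[str],
    dv: str = "value",
    subject: str = "participant_id",
    n_quad_nodes: int = 21,
    lrt: bool = True,
    fix_sigma: float | None = None,
) -> ModelResult:
    """Proportional-odds logit model with a participant random intercept.

    The marginal likelihood integrates the standard-normal random intercept
    (scaled by sigma) by adaptive Gauss-Hermite quadrature: for each
    participant the integrand's mode and curvature are located by Newton
    steps and the nodes are recentred and rescaled there.  Thresholds are
    kept strictly increasing through a log-difference parameterization.
    ``fix_sigma`` holds the random-intercept SD at a given value (0 gives
    the fixed-effects cumulative-link limit), as when profiling a variance
    component.
    """
    from patsy import dmatrix

    data = ratings.dropna(subset=[dv]).copy()
    cats = np.sort(data[dv].unique())
    if len(cats) < 2:
        raise ValueError("ordinal response needs at least 2 observed categories")
    ymap = {c: i for i, c in enumerate(cats)}
    yall = data[dv].map(ymap).to_numpy()
    design = dmatrix(" + ".join(fixed_terms), data, return_type="dataframe")
    design = design.drop(columns=[c for c in design.columns if c == "Intercept"])
    colnames = list(design.columns)
    Xall = design.to_numpy(dtype=float)
    groups = data[subject].to_numpy()

    uniq = pd.unique(groups)
    n_max = max(int((groups == g).sum()) for g in uniq)
    Xpad = np.zeros((len(uniq), n_max, Xall.shape[1]))
    ypad = np.full((len(uniq), n_max), -1, dtype=int)
    for j, g in enumerate(uniq):
        sel = groups == g
        k = int(sel.sum())
        Xpad[j, :k] = Xall[sel]
        ypad[j, :k] = yall[sel]

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad_nodes)
    n_cat = len(cats)
    n_th = n_cat - 1
    p = Xall.shape[1]

    def fit_subset(cols: list[int]) -> tuple[np.ndarray, float, bool]:
        Xb = Xpad[:, :, cols]
        pk = len(cols)
        x0 = np.zeros(n_th + pk + 1)
        x0[1:n_th] = np.log(1.0)
        x0[-1] = 0.0
        try:  # warm start from the fixed-effects cumulative-link fit
            from statsmodels.miscmodels.ordinal_model import OrderedModel

            om = OrderedModel(yall, Xall[:, cols], distr="logit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                of = om.fit(method="bfgs", disp=0)
            x0[n_th : n_th + pk] = of.params[:pk]
            x0[0] = of.params[pk]
            x0[1:n_th] = np.clip(of.params[pk + 1 :], -7.0, 7.0)
            x0[-1] = np.log(0.5)
        except Exception:
            x0[0] = -1.0
        obj = lambda q: _clmm_loglik(q, Xb, ypad, n_cat, nodes, weights)
        if fix_sigma is None:
            sig_bounds = (-7.0, 3.0)
        else:
            log_fix = float(np.log(max(fix_sigma, 1e-7)))
            sig_bounds = (log_fix, log_fix)
            x0[-1] = log_fix
        bounds = [(None, None)] * (n_th + pk) + [sig_bounds]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 500, "ftol": 1e-11})
        return res.x, -res.fun, bool(res.success)

    all_cols = list(range(p))
    params, llf, ok = fit_subset(all_cols)
    beta = params[n_th : n_th + p]
    th = np.empty(n_th)
    th[0] = params[0]
    th[1:] = params[0] + np.cumsum(np.exp(params[1:n_th]))
    sigma = float(np.exp(params[-1]))

    # Wald SEs from the numerical Hessian at the optimum
    try:
        from statsmodels.tools.numdiff import approx_hess1

        H = approx_hess1(
            params,
            lambda q: _clmm_loglik(q, Xpad, ypad, n_cat, nodes, weights),
        )
        cov = np.linalg.pinv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_beta = se_all[n_th : n_th + p]
    except Exception:
        se_beta = np.full(p, np.nan)

    # map design columns to requested terms
    term_cols: dict[str, list[int]] = {}
    for term in fixed_terms:
        term_cols[term] = [
            i for i, c in enumerate(colnames)
            if c == term or c.startswith(f"{term}[") or c.startswith(f"C({term})")
        ]
    terms = []
    for term in fixed_terms:
        cols = term_cols[term]
        est = float(beta[cols[0]]) if len(cols) == 1 else None
        se = float(se_beta[cols[0]]) if len(cols) == 1 else None
        if lrt:
            keep = [i for i in all_cols if i not in cols]
            _, llf_red, _ = fit_subset(keep)
            chi2 = max(0.0, 2.0 * (llf - llf_red))
            dof = max(1, len(cols))
            pval = float(sps.chi2.sf(chi2, dof))
        else:
            chi2, dof = np.nan, max(1, len(cols))
            z = est / se if (est is not None and se) else np.nan
            pval = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        terms.append(
            {"name": term, "estimate": est, "std_error": se,
             "chi_square": chi2, "df": dof, "p": pval}
        )
    return ModelResult(
        model="clmm", dv=dv, terms=terms, loglik=float(llf),
        n_obs=len(data), n_groups=len(uniq), converged=ok,
        extra={"thresholds": th.tolist(), "sigma": sigma,
               "beta": dict(zip(colnames, beta.tolist())),
               "n_quad_nodes": n_quad_nodes},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(
    features: pd.DataFrame, dv: str, group: str = "block"
) -> dict:
    """Tie-corrected Kruskal-Wallis H across the levels of ``group``."""
    groups = [g[dv].dropna().to_numpy() for _, g in features.groupby(group)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return {"H": np.nan, "df": len(groups) - 1, "p": np.nan, "degenerate": True}
    H, p = sps.kruskal(*groups)
    return {"H": float(H), "df": len(groups) - 1, "p": float(p), "degenerate": False}
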