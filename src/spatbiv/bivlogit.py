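"""Bivariate binary logistic regression with a Plackett-Dale association.

The model couples two marginal logistic regressions — one per outcome
(ANC attendance and facility delivery) — through a constant dependency odds
ratio psi. Given marginal success probabilities p1 = logistic(eta1) and
p2 = logistic(eta2), the joint cell p11 is the admissible root of the
Plackett quadratic

    p11 (1 - p1 - p2 + p11) / ((p1 - p11)(p2 - p11)) = psi,

lying in the Frechet interval (max(0, p1+p2-1), min(p1, p2)); the remaining
cells follow by margin subtraction. Each woman contributes her observed cell's
log probability to a multinomial log-likelihood, maximized jointly over
(beta1, beta2, log psi) by quasi-Newton iteration.

Spatial dependence enters autologistically: each outcome's linear predictor
may carry rho * S_i, where S_i is the neighbor-average of that outcome's
observed zone prevalence (the autocovariate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from statsmodels.tools import numdiff

from .core_io import Dataset, SpatialWeights, ValidationError
from .spatial_stats import autocovariate

_CLAMP = 1e-12


class SeparationError(RuntimeError):
    """Perfect separation or rank deficiency makes the logistic MLE undefined."""


# ---------------------------------------------------------------------------
# Plackett cells
# ---------------------------------------------------------------------------

def plackett_p11(p1, p2, psi):
    """Joint probability p11 given the two marginals and the dependency odds ratio.

    Vectorized; psi = 1 returns the independence product p1*p2 exactly. The
    root taken is the one inside the Frechet bounds, which is unique for any
    psi > 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    psi_arr = np.asarray(psi, dtype=float)
    if np.any(psi_arr <= 0):
        raise ValidationError("psi must be > 0")
    if np.any((p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)):
        raise ValidationError("marginal probabilities must lie in (0,1)")
    p1, p2, psi_arr = np.broadcast_arrays(p1, p2, psi_arr)
    a = psi_arr - 1.0
    s = 1.0 + (p1 + p2) * a
    root = np.sqrt(np.maximum(s * s - 4.0 * psi_arr * a * p1 * p2, 0.0))
    # conjugate form avoids cancellation near psi = 1 (and is exact at psi = 1);
    # the direct form is the stable one on the rare s < 0 branch (tiny psi, large margins)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0, 2.0 * psi_arr * p1 * p2 / (s + root), (s - root) / (2.0 * a))
    # numerical safety: pin to the open Frechet interval
    lo = np.maximum(0.0, p1 + p2 - 1.0)
    hi = np.minimum(p1, p2)
    out = np.clip(out, lo + _CLAMP, hi - _CLAMP)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CellProbs:
    """Per-observation joint cell probabilities of the outcome pair."""

    p11: np.ndarray
    p10: np.ndarray
    p01: np.ndarray
    p00: np.ndarray

    def stacked(self) -> np.ndarray:
        """(n, 4) array in the order (1,1), (1,0), (0,1), (0,0)."""
        return np.stack([self.p11, self.p10, self.p01, self.p00], axis=-1)


def cell_probabilities(eta1, eta2, log_psi: float) -> CellProbs:
    """Joint cells from the two linear predictors and the log dependency OR."""
    eta1 = np.atleast_1d(np.asarray(eta1, dtype=float))
    eta2 = np.atleast_1d(np.asarray(eta2, dtype=float))
    with np.errstate(over="ignore"):
        p1 = 1.0 / (1.0 + np.exp(-eta1))
        p2 = 1.0 / (1.0 + np.exp(-eta2))
    p1 = np.clip(p1, _CLAMP, 1 - _CLAMP)
    p2 = np.clip(p2, _CLAMP, 1 - _CLAMP)
    p11 = np.atleast_1d(plackett_p11(p1, p2, np.exp(log_psi)))
    p10 = np.maximum(p1 - p11, _CLAMP)
    p01 = np.maximum(p2 - p11, _CLAMP)
    p00 = np.maximum(1.0 - p1 - p2 + p11, _CLAMP)
    return CellProbs(p11, p10, p01, p00)


# ---------------------------------------------------------------------------
# model specification / design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Terms per outcome; categorical terms expand against their first (reference) label.

    ``covariates1``/``covariates2`` name schema covariates, ``"year"``, or
    numeric columns already present in the data (e.g. the autocovariate
    columns added by :func:`add_spatial_autocovariate`). ``include_spatial``
    appends each outcome's own autocovariate term.
    """

    covariates1: tuple[str, ...] = ()
    covariates2: tuple[str, ...] = ()
    include_spatial: bool = False

    def __init__(self, covariates1=(), covariates2=(), include_spatial=False):
        object.__setattr__(self, "covariates1", tuple(covariates1))
        object.__setattr__(self, "covariates2", tuple(covariates2))
        object.__setattr__(self, "include_spatial", bool(include_spatial))


def build_design(data: Dataset, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix: dummy expansion for categoricals, pass-through numerics."""
    df = data.df
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for term in terms:
        if term in data.schema:
            labels = data.schema[term]
        elif term == "year":
            labels = data.years
        elif term in df.columns:
            vals = pd.to_numeric(df[term], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"term {term!r} is neither categorical nor numeric")
            cols.append(vals.to_numpy(float))
            names.append(term)
            continue
        else:
            raise ValidationError(f"unknown model term {term!r}")
        col = df[term].astype(str)
        for lab in labels[1:]:  # first label is the reference
            cols.append((col == lab).to_numpy(float))
            names.append(f"{term}[{lab}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# univariate fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariateFit:
    outcome: int
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float

    def or_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "odds_ratio": np.exp(self.coef),
                "ci_low": np.exp(self.coef - 1.96 * self.se),
                "ci_high": np.exp(self.coef + 1.96 * self.se),
            }
        )


def fit_univariate_logit(
    data: Dataset, outcome: int, spec: ModelSpec, use_weights: bool = True
) -> UnivariateFit:
    """Maximum-likelihood logistic regression for one of the two outcomes.

    Weights enter as frequency weights; standard errors come from the inverse
    observed information (model-based, no survey design correction).
    """
    if outcome not in (1, 2):
        raise ValidationError("outcome must be 1 (anc) or 2 (dc)")
    terms = spec.covariates1 if outcome == 1 else spec.covariates2
    y = data.df["anc" if outcome == 1 else "dc"].to_numpy(int)
    x, names = build_design(data, terms)
    if y.min() == y.max():
        raise SeparationError("all outcomes identical: perfect separation")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise SeparationError(
            f"design matrix rank {rank} < {x.shape[1]} columns: drop an aliased term"
        )
    w = data.df["weight"].to_numpy(float) if use_weights else None
    model = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w)
    try:
        res = model.fit(maxiter=200, tol=1e-12)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(str(exc)) from exc
    mu = res.predict(x)
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        fitted_extreme = names[int(np.argmax(np.abs(res.params)))]
        raise SeparationError(f"fitted probabilities at the boundary (term {fitted_extreme!r})")
    cov = np.asarray(res.cov_params())
    return UnivariateFit(
        outcome=outcome,
        names=names,
        coef=np.asarray(res.params, float),
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        loglik=float(res.llf),
    )


# ---------------------------------------------------------------------------
# spatial autocovariate columns
# ---------------------------------------------------------------------------

def add_spatial_autocovariate(
    data: Dataset, W: SpatialWeights, per_year: bool = True, use_weights: bool = True
) -> Dataset:
    """Attach per-record autocovariate columns ``Si1`` and ``Si2``.

    For each outcome the zone's (weighted) observed prevalence is computed —
    per survey year by default — and S_i at a zone is the mean of its
    neighboring zones' prevalences; every record in the zone inherits that
    value. Island zones fall back to the global prevalence.
    """
    df = data.df
    missing = set(df["zone"]) - set(W.zone_order)
    if missing:
        raise ValidationError(f"zones absent from the weights registry: {sorted(missing)}")
    out = df.copy()
    out["Si1"] = np.nan
    out["Si2"] = np.nan
    groups = df.groupby("year").groups.items() if per_year else [(None, df.index)]
    for _, idx in groups:
        sub = df.loc[idx]
        w = sub["weight"].to_numpy() if use_weights else np.ones(len(sub))
        for k, col in ((1, "anc"), (2, "dc")):
            num = pd.Series(w * sub[col].to_numpy(), index=sub.index).groupby(sub["zone"]).sum()
            den = pd.Series(w, index=sub.index).groupby(sub["zone"]).sum()
            prev = (num / den).reindex(W.zone_order)
            # zones unobserved in this stratum carry the overall prevalence
            prev = prev.fillna(float(num.sum() / den.sum()))
            si = autocovariate(prev.to_numpy(), W)
            si_map = dict(zip(W.zone_order, si))
            out.loc[idx, f"Si{k}"] = sub["zone"].map(si_map).to_numpy()
    return Dataset(out, schema=dict(data.schema), drop_report=dict(data.drop_report))


# ---------------------------------------------------------------------------
# joint likelihood + fit
# ---------------------------------------------------------------------------

def _aggregate(data: Dataset, x1: np.ndarray, x2: np.ndarray, use_weights: bool):
    """Collapse records to unique (design-row-pair) patterns with weighted cell counts."""
    key = np.column_stack([x1, x2])
    _, pattern_idx, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    u1, u2 = x1[pattern_idx], x2[pattern_idx]
    y1 = data.df["anc"].to_numpy(int)
    y2 = data.df["dc"].to_numpy(int)
    cell = (1 - y1) * 2 + (1 - y2)  # 0:(1,1) 1:(1,0) 2:(0,1) 3:(0,0)
    w = data.df["weight"].to_numpy(float) if use_weights else np.ones(len(y1))
    counts = np.zeros((len(pattern_idx), 4))
    np.add.at(counts, (inverse, cell), w)
    return u1, u2, counts


def _loglik_core(params, u1, u2, counts, p1_dim, fixed_log_psi):
    beta1 = params[:p1_dim]
    if fixed_log_psi is None:
        beta2 = params[p1_dim:-1]
        log_psi = params[-1]
    else:
        beta2 = params[p1_dim:]
        log_psi = fixed_log_psi
    cells = cell_probabilities(u1 @ beta1, u2 @ beta2, log_psi).stacked()
    ll = float((counts * np.log(np.maximum(cells, _CLAMP))).sum())
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite log-likelihood at params {params}")
    return ll


def bivariate_loglik(
    params: np.ndarray,
    data: Dataset,
    spec: ModelSpec,
    use_weights: bool = True,
    fixed_log_psi: float | None = None,
) -> float:
    """Weighted multinomial log-likelihood of the Plackett-coupled model.

    ``params`` is (beta1, beta2, log_psi) unless ``fixed_log_psi`` pins the
    association, in which case it is (beta1, beta2).
    """
    terms1, terms2 = _spatial_terms(spec)
    x1, _ = build_design(data, terms1)
    x2, _ = build_design(data, terms2)
    u1, u2, counts = _aggregate(data, x1, x2, use_weights)
    params = np.asarray(params, dtype=float)
    expected = x1.shape[1] + x2.shape[1] + (0 if fixed_log_psi is not None else 1)
    if params.size != expected:
        raise ValidationError(f"expected {expected} parameters, got {params.size}")
    return _loglik_core(params, u1, u2, counts, x1.shape[1], fixed_log_psi)


def _spatial_terms(spec: ModelSpec) -> tuple[tuple[str, ...], tuple[str, ...]]:
    t1, t2 = spec.covariates1, spec.covariates2
    if spec.include_spatial:
        t1 = t1 + ("Si1",)
        t2 = t2 + ("Si2",)
    return t1, t2


@dataclass(frozen=True)
class BivariateLogitFit:
    names1: list[str]
    names2: list[str]
    beta1: np.ndarray
    beta2: np.ndarray
    log_psi: float
    se1: np.ndarray | None
    se2: np.ndarray | None
    se_log_psi: float | None
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    spatial: bool
    psi_fixed: bool = False
    se_available: bool = True

    @property
    def dependency_or(self) -> float:
        """The fitted measure of dependency, exp(log psi)."""
        return float(np.exp(self.log_psi))

    def fitted_cells(self, data: Dataset, spec: ModelSpec, use_weights: bool = True) -> CellProbs:
        terms1, terms2 = _spatial_terms(spec)
        x1, _ = build_design(data, terms1)
        x2, _ = build_design(data, terms2)
        return cell_probabilities(x1 @ self.beta1, x2 @ self.beta2, self.log_psi)


def fit_bivariate_logit(
    data: Dataset,
    spec: ModelSpec,
    W: SpatialWeights | None = None,
    use_weights: bool = True,
    fix_log_psi: float | None = None,
    max_iter: int = 500,
) -> BivariateLogitFit:
    """Maximize the Plackett-coupled multinomial likelihood by quasi-Newton iteration.

    The optimizer warm-starts at the two univariate logistic MLEs with log psi
    initialized at the log of the empirical 2x2 odds ratio. The covariance of
    the estimates comes from the inverse numerical Hessian; when that Hessian
    is not positive definite the fit is returned with SEs flagged unavailable.
    """
    if spec.include_spatial:
        if W is None:
            raise ValidationError("spec.include_spatial requires a SpatialWeights argument")
        data = add_spatial_autocovariate(data, W, use_weights=use_weights)
    terms1, terms2 = _spatial_terms(spec)
    x1, names1 = build_design(data, terms1)
    x2, names2 = build_design(data, terms2)
    p1_dim, p2_dim = x1.shape[1], x2.shape[1]
    if spec.include_spatial:
        # the univariate warm starts must carry the Si columns too
        coef1, _ = _glm_fit(data, "anc", x1, use_weights)
        coef2, _ = _glm_fit(data, "dc", x2, use_weights)
    else:
        coef1 = fit_univariate_logit(data, 1, spec, use_weights).coef
        coef2 = fit_univariate_logit(data, 2, spec, use_weights).coef
    from .descriptive import build_2x2, odds_ratio_2x2  # local import avoids a cycle

    emp_or = odds_ratio_2x2(build_2x2(data, use_weights=use_weights), continuity=True)
    start_psi = float(np.clip(np.log(emp_or), -8, 8))
    if fix_log_psi is None:
        x0 = np.concatenate([coef1, coef2, [start_psi]])
    else:
        x0 = np.concatenate([coef1, coef2])
    u1, u2, counts = _aggregate(data, x1, x2, use_weights)

    def nll(p):
        return -_loglik_core(p, u1, u2, counts, p1_dim, fix_log_psi)

    res = optimize.minimize(
        nll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": max_iter}
    )
    if not res.success and res.status != 2:
        # status 2 = precision loss, common near flat optima; anything else aborts
        raise RuntimeError(f"bivariate fit did not converge: {res.message}")
    params = res.x
    hess = numdiff.approx_hess(params, nll)
    se_ok = True
    cov = None
    try:
        cov = np.linalg.inv(hess)
        if np.any(np.diag(cov) <= 0):
            se_ok = False
    except np.linalg.LinAlgError:
        se_ok = False
    beta1 = params[:p1_dim]
    beta2 = params[p1_dim : p1_dim + p2_dim]
    log_psi = float(params[-1]) if fix_log_psi is None else float(fix_log_psi)
    if se_ok and cov is not None:
        d = np.sqrt(np.diag(cov))
        se1, se2 = d[:p1_dim], d[p1_dim : p1_dim + p2_dim]
        se_psi = float(d[-1]) if fix_log_psi is None else None
    else:
        se1 = se2 = None
        se_psi = None
    return BivariateLogitFit(
        names1=names1,
        names2=names2,
        beta1=beta1,
        beta2=beta2,
        log_psi=log_psi,
        se1=se1,
        se2=se2,
        se_log_psi=se_psi,
        cov=cov if se_ok else None,
        loglik=float(-res.fun),
        converged=bool(res.success or res.status == 2),
        n_iter=int(res.nit),
        n_obs=data.n,
        spatial=spec.include_spatial,
        psi_fixed=fix_log_psi is not None,
        se_available=se_ok,
    )


def _glm_fit(data: Dataset, col: str, x: np.ndarray, use_weights: bool):
    y = data.df[col].to_numpy(int)
    w = data.df["weight"].to_numpy(float) if use_weights else None
    res = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w).fit(
        maxiter=200, tol=1e-12
    )
    return np.asarray(res.params, float), res


def summarize_fit(fit: BivariateLogitFit) -> pd.DataFrame:
    """Per-coefficient estimate, SE, OR and 95% CI, with the dependency OR appended."""
    rows = []
    for outcome, names, beta, se in (
        ("anc", fit.names1, fit.beta1, fit.se1),
        ("dc", fit.names2, fit.beta2, fit.se2),
    ):
        for j, name in enumerate(names):
            est = float(beta[j])
            s = float(se[j]) if se is not None else np.nan
            rows.append(
                {
                    "outcome": outcome,
                    "term": name,
                    "estimate": est,
                    "se": s,
                    "odds_ratio": float(np.exp(est)),
                    "ci_low": float(np.exp(est - 1.96 * s)),
                    "ci_high": float(np.exp(est + 1.96 * s)),
                }
            )
    s = float(fit.se_log_psi) if fit.se_log_psi is not None else np.nan
    rows.append(
        {
            "outcome": "dependency",
            "term": "log_psi",
            "estimate": fit.log_psi,
            "se": s,
            "odds_ratio": fit.dependency_or,
            "ci_low": float(np.exp(fit.log_psi - 1.96 * s)),
            "ci_high": float(np.exp(fit.log_psi + 1.96 * s)),
        }
    )
    return pd.DataFrame(rows)
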