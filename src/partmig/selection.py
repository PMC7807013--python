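"""Information-criterion model selection and post-hoc contrasts.

Implements the multimodel-inference layer used for every fitness analysis:
family-specific fits (Gaussian GLM/GLMM, Poisson, CMP, binomial,
quasibinomial), small-sample AICc / QAICc, all-subsets ranking under
marginality, the "fewest parameters within the Delta-2 subset" final-model
rule, and single-step multiple-comparison contrasts for the
strategy-by-area interaction.

Parameter counting convention (held fixed across a candidate set): one per
fixed-effect coefficient, plus one per variance component (residual
variance, random intercept), plus one for the CMP dispersion nu, plus one
for the overdispersion estimate c-hat under QAICc.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices, dmatrix
from scipy import stats

from .cmp import fit_cmp_regression

__all__ = [
    "ModelSpec",
    "FittedModel",
    "SelectionTable",
    "PosthocResult",
    "aicc",
    "qaicc",
    "fit_model",
    "rank_subsets",
    "apply_delta2_rule",
    "admissible_subsets",
    "estimate_chat",
    "posthoc_contrasts",
    "zscore",
]

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "poisson-log", "cmp-log", "binomial-logit", "quasibinomial-logit")


def zscore(s: pd.Series) -> pd.Series:
    """Centre and scale to unit SD (population-wide z transform)."""
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return s - s.mean()
    return (s - s.mean()) / sd


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate (or global) model."""

    response: str
    family: str
    terms: tuple[str, ...]
    group: str | None = None          # random-intercept grouping column
    weights: str | None = None        # var weights (clutch size), (quasi)binomial only
    scale_terms: tuple[str, ...] = () # continuous covariates to z-score before fitting

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.weights is not None and "binomial" not in self.family:
            raise ValueError("weights are only supported for (quasi)binomial families")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def with_terms(self, terms: tuple[str, ...]) -> "ModelSpec":
        return ModelSpec(self.response, self.family, terms, self.group,
                         self.weights, self.scale_terms)


@dataclass
class FittedModel:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    nobs: int
    k: int                 # parameter count per the package convention
    criterion: float       # AICc, or QAICc when chat is set
    converged: bool
    chat: float | None = None
    result: Any = None     # underlying statsmodels / CMP result

    @property
    def term_label(self) -> str:
        return " + ".join(self.spec.terms) if self.spec.terms else "(null)"


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def qaicc(llf: float, chat: float, k: int, n: int) -> float:
    """Quasi-AICc: the quasi-likelihood -2l/chat, with one extra parameter for chat."""
    if chat <= 0:
        raise ValueError("chat must be positive")
    kq = k + 1
    if n <= kq + 1:
        raise ValueError(f"QAICc undefined for n={n} <= k+2={kq + 1}")
    return -2.0 * llf / chat + 2.0 * kq + 2.0 * kq * (kq + 1) / (n - kq - 1)


def estimate_chat(result) -> float:
    """Overdispersion c-hat = Pearson chi-square / residual df of a binomial fit."""
    df = result.df_resid
    if df <= 0:
        raise ValueError("zero residual degrees of freedom; c-hat undefined")
    return float(result.pearson_chi2 / df)


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = data.copy()
    for col in spec.scale_terms:
        if col in df.columns:
            df[col] = zscore(df[col].astype(float))
    return df


def fit_model(spec: ModelSpec, data: pd.DataFrame, chat: float | None = None,
              _prescaled: bool = False) -> FittedModel:
    """Fit a single model and compute its information criterion.

    ``chat`` (floored at 1) switches the criterion to QAICc and is only
    meaningful for the quasibinomial family. Non-convergence is recorded on
    the returned object rather than raised.
    """
    df = data if _prescaled else _prepare(data, spec)
    n = len(df)
    fam = spec.family
    if fam == "gaussian" and spec.group is not None:
        # ML (not REML) so criteria are comparable across fixed structures
        md = smf.mixedlm(spec.formula, df, groups=df[spec.group])
        import warnings as _w

        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = md.fit(reml=False)
            converged = bool(res.converged)
        except Exception:
            try:
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    res = md.fit(reml=False, method="lbfgs")
                converged = bool(res.converged)
            except Exception as exc:  # pragma: no cover - singular fits
                logger.warning("mixed model failed: %s", exc)
                return FittedModel(spec, pd.Series(dtype=float), pd.Series(dtype=float),
                                   np.nan, n, 0, np.inf, False)
        k = len(res.fe_params) + 2  # random-intercept var + residual var
        fm = FittedModel(spec, res.fe_params, res.bse_fe, float(res.llf), n, k,
                         aicc(res.llf, k, n), converged, result=res)
        return fm
    if fam == "gaussian":
        res = smf.ols(spec.formula, df).fit()
        k = len(res.params) + 1  # + residual variance
        return FittedModel(spec, res.params, res.bse, float(res.llf), n, k,
                           aicc(res.llf, k, n), True, result=res)
    if fam == "poisson-log":
        res = smf.glm(spec.formula, df, family=sm.families.Poisson()).fit()
        k = len(res.params)
        return FittedModel(spec, res.params, res.bse, float(res.llf), n, k,
                           aicc(res.llf, k, n), bool(res.converged), result=res)
    if fam == "binomial-logit":
        res = smf.glm(spec.formula, df, family=sm.families.Binomial()).fit()
        k = len(res.params)
        return FittedModel(spec, res.params, res.bse, float(res.llf), n, k,
                           aicc(res.llf, k, n), bool(res.converged), result=res)
    if fam == "quasibinomial-logit":
        vw = df[spec.weights].astype(float) if spec.weights else None
        res = smf.glm(spec.formula, df, family=sm.families.Binomial(),
                      var_weights=vw).fit()
        k = len(res.params)
        ch = 1.0 if chat is None else max(1.0, chat)
        crit = qaicc(float(res.llf), ch, k, n)
        return FittedModel(spec, res.params, res.bse, float(res.llf), n, k + 1,
                           crit, bool(res.converged), chat=ch, result=res)
    if fam == "cmp-log":
        rhs = " + ".join(spec.terms) if spec.terms else "1"
        x = dmatrix(rhs, df, return_type="dataframe")
        y = df[spec.response].to_numpy()
        res = fit_cmp_regression(y, x.to_numpy(), exog_names=list(x.columns))
        params = pd.Series(res.params, index=x.columns)
        bse = pd.Series(res.bse, index=x.columns)
        return FittedModel(spec, params, bse, res.llf, n, res.k,
                           aicc(res.llf, res.k, n), res.converged, result=res)
    raise AssertionError(fam)


def _interaction_parts(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


def admissible_subsets(terms: tuple[str, ...]) -> list[tuple[str, ...]]:
    """All term subsets respecting marginality (interactions need their mains)."""
    subsets = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            ok = all(
                all(p in combo for p in _interaction_parts(t))
                for t in combo
            )
            if ok:
                subsets.append(combo)
    return subsets


@dataclass
class SelectionTable:
    """Ranked candidate set with the Delta-2 / fewest-parameters rule applied."""

    models: list[FittedModel]          # sorted by criterion, ascending
    delta: np.ndarray
    delta2_mask: np.ndarray
    final_index: int
    dropped: list[tuple[ModelSpec, str]] = field(default_factory=list)
    note: str = "model averaging not performed (interaction terms in candidate set)"

    @property
    def final(self) -> FittedModel:
        return self.models[self.final_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.models):
            rows.append({
                "terms": m.term_label,
                "k": m.k,
                "criterion": m.criterion,
                "delta": self.delta[i],
                "in_delta2": bool(self.delta2_mask[i]),
                "final": i == self.final_index,
            })
        return pd.DataFrame(rows)


def rank_subsets(global_spec: ModelSpec, data: pd.DataFrame) -> SelectionTable:
    """Fit all admissible reductions of a global model and rank them.

    Candidates within 2 criterion units of the best form the Delta-2
    subset; the final model is its fewest-parameter member (ties broken by
    the better criterion value). For the quasibinomial family, c-hat is
    estimated from the global model's Pearson statistic and applied to
    every candidate's QAICc.
    """
    df = _prepare(data, global_spec).dropna(
        subset=[c for c in _columns_used(global_spec) if c in data.columns]
    )
    chat = None
    if global_spec.family == "quasibinomial-logit":
        gfit = fit_model(global_spec, df, chat=1.0, _prescaled=True)
        chat = max(1.0, estimate_chat(gfit.result))
    fitted: list[FittedModel] = []
    dropped: list[tuple[ModelSpec, str]] = []
    for terms in admissible_subsets(global_spec.terms):
        spec = global_spec.with_terms(terms)
        try:
            fm = fit_model(spec, df, chat=chat, _prescaled=True)
        except Exception as exc:
            dropped.append((spec, str(exc)))
            logger.warning("candidate %s dropped: %s", spec.formula, exc)
            continue
        if not fm.converged or not np.isfinite(fm.criterion):
            dropped.append((spec, "non-convergence"))
            logger.warning("candidate %s dropped: non-convergence", spec.formula)
            continue
        fitted.append(fm)
    if not fitted:
        raise RuntimeError("no candidate model converged")
    table = apply_delta2_rule(fitted)
    table.dropped = dropped
    return table


def apply_delta2_rule(fitted: list[FittedModel]) -> SelectionTable:
    """Rank candidates and pick the fewest-parameter Delta-2 member.

    Ties on parameter count break to the better criterion value. Invariant
    under any constant shift of all log-likelihoods (criteria shift
    together, deltas are unchanged).
    """
    order = np.argsort([m.criterion for m in fitted], kind="stable")
    fitted = [fitted[i] for i in order]
    crit = np.array([m.criterion for m in fitted])
    delta = crit - crit[0]
    mask = delta <= 2.0
    idx = [i for i in range(len(fitted)) if mask[i]]
    final_index = min(idx, key=lambda i: (fitted[i].k, fitted[i].criterion))
    return SelectionTable(fitted, delta, mask, final_index)


def _columns_used(spec: ModelSpec) -> list[str]:
    cols = [spec.response]
    for t in spec.terms:
        cols.extend(t.split(":"))
    if spec.group:
        cols.append(spec.group)
    if spec.weights:
        cols.append(spec.weights)
    return list(dict.fromkeys(cols))


@dataclass
class PosthocResult:
    labels: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    z_values: np.ndarray
    p_unadjusted: np.ndarray
    p_adjusted: np.ndarray
    method: str = "single-step max-|z| (joint multivariate normal)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contrast": self.labels,
            "estimate": self.estimates,
            "se": self.std_errors,
            "z": self.z_values,
            "p_raw": self.p_unadjusted,
            "p_adj": self.p_adjusted,
        })


def _design_row(res, row: pd.DataFrame) -> np.ndarray:
    di = res.model.data.design_info
    return np.asarray(build_design_matrices([di], row)[0])[0]


def posthoc_contrasts(
    fm: FittedModel,
    data: pd.DataFrame,
    strategy_col: str = "strategy",
    area_col: str = "area",
    seed: int | None = 0,
) -> PosthocResult:
    """Strategy-within-area (and between-area) contrasts on a final model.

    Requires the strategy-by-area interaction in the final model. Adjusted
    p-values use the single-step method: each contrast's p is the
    probability that the maximum absolute standardized contrast exceeds its
    observed |z| under the joint normal distribution of the contrasts.
    """
    inter = f"{strategy_col}:{area_col}"
    inter_rev = f"{area_col}:{strategy_col}"
    if inter not in fm.spec.terms and inter_rev not in fm.spec.terms:
        raise ValueError(
            "post-hoc contrasts require the strategy-by-area interaction in the final model"
        )
    res = fm.result
    df = _prepare(data, fm.spec)
    strategies = sorted(df[strategy_col].dropna().unique())
    areas = sorted(df[area_col].dropna().unique())
    if len(strategies) != 2 or len(areas) != 2:
        raise ValueError("expected exactly two strategies and two areas")

    # reference rows: covariates at their mean (numeric) or mode (other)
    def ref_row(strategy, area) -> pd.DataFrame:
        row = {}
        for col in df.columns:
            if col == strategy_col:
                row[col] = strategy
            elif col == area_col:
                row[col] = area
            elif pd.api.types.is_numeric_dtype(df[col]):
                row[col] = df[col].mean()
            else:
                row[col] = df[col].mode().iloc[0]
        return pd.DataFrame([row])

    rows = {(s, a): _design_row(res, ref_row(s, a)) for s in strategies for a in areas}
    s0, s1 = strategies
    a0, a1 = areas
    contrasts = {
        f"{s1} - {s0} | {a0}": rows[(s1, a0)] - rows[(s0, a0)],
        f"{s1} - {s0} | {a1}": rows[(s1, a1)] - rows[(s0, a1)],
        f"{a1} - {a0} | mean strategy": (
            (rows[(s0, a1)] + rows[(s1, a1)]) - (rows[(s0, a0)] + rows[(s1, a0)])
        ) / 2.0,
    }
    L = np.vstack(list(contrasts.values()))
    beta = np.asarray(fm.params)
    V = np.asarray(res.cov_params())
    if V.shape[0] > len(beta):  # mixed models append covariance parameters
        V = V[: len(beta), : len(beta)]
    est = L @ beta
    cov = L @ V @ L.T
    se = np.sqrt(np.diag(cov))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    corr = cov / np.outer(se, se)
    corr = (corr + corr.T) / 2.0 + 1e-10 * np.eye(len(se))
    p_adj = np.empty_like(p_raw)
    if seed is not None:  # the mvn box probability uses randomized quadrature
        np.random.seed(seed)
    for i, zi in enumerate(np.abs(z)):
        box = stats.multivariate_normal.cdf(
            np.full(len(se), zi), mean=np.zeros(len(se)), cov=corr,
            lower_limit=np.full(len(se), -zi),
        )
        p_adj[i] = 1.0 - box
    p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)
    return PosthocResult(list(contrasts), est, se, z, p_raw, p_adj)
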