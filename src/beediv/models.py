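"""Gaussian linear mixed models of diversity on land use and pressures.

Each facet's effective number of species (natural-log transformed for the
species facet) is modelled on land-use class (reference: semi-natural),
centred log1p human population density, centred log1p distance to roads
and subregion, with the two-way interactions of land use with the
continuous pressures, and random intercepts for study and block (plus an
optional within-study random slope). The workflow mirrors standard mixed-
model practice in community ecology:

* random structure chosen by AIC among REML fits sharing the full fixed
  structure;
* fixed structure simplified backwards with likelihood-ratio tests on ML
  fits, respecting marginality;
* Type II analysis-of-deviance tables, parametric-bootstrap confidence
  intervals, marginal R² (fixed-effect variance over total variance),
  generalized variance-inflation factors and a Moran's I residual check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .rasters import LAND_USE_LEVELS

__all__ = [
    "ModelSpec",
    "ModelFit",
    "prepare_model_frame",
    "fit_lmm",
    "select_random_effects",
    "backward_select_fixed",
    "type2_anova",
    "bootstrap_ci",
    "marginal_r2",
    "gvif",
    "morans_i",
    "predict_fixed",
]

DEFAULT_FIXED = [
    "land_use",
    "hpd_c",
    "roads_c",
    "subregion",
    "land_use:hpd_c",
    "land_use:roads_c",
]


@dataclass(frozen=True)
class ModelSpec:
    """Formula-level description of one mixed model."""

    response: str
    fixed: tuple[str, ...] = tuple(DEFAULT_FIXED)
    re_formula: str = "~1"  # study-level random effects
    include_block: bool = True
    groups: str = "study_id"

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def drop_term(self, term: str) -> "ModelSpec":
        return ModelSpec(
            self.response,
            tuple(t for t in self.fixed if t != term),
            self.re_formula,
            self.include_block,
            self.groups,
        )


@dataclass
class ModelFit:
    """Fitted-model summary detached from the statsmodels internals."""

    spec: ModelSpec
    params: pd.Series  # fixed effects
    bse: pd.Series
    cov_params: pd.DataFrame
    vcomp: dict[str, float]  # named variance components (+ residual)
    llf: float
    aic: float
    criterion: str  # 'ML' | 'REML'
    converged: bool
    singular: bool
    centring: dict[str, float] = field(default_factory=dict)
    categories: dict[str, list[str]] = field(default_factory=dict)
    result: object | None = None  # live statsmodels result (not serialized)

    @property
    def n_params(self) -> int:
        return len(self.params) + len(self.vcomp)

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula(),
            "re_formula": self.spec.re_formula,
            "include_block": self.spec.include_block,
            "coefficients": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "vcov": {
                r: {c: float(self.cov_params.loc[r, c]) for c in self.cov_params.columns}
                for r in self.cov_params.index
            },
            "variance_components": self.vcomp,
            "logLik": self.llf,
            "AIC": self.aic,
            "criterion": self.criterion,
            "converged": self.converged,
            "singular": self.singular,
            "centring": self.centring,
            "categories": self.categories,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def prepare_model_frame(sites: pd.DataFrame, div: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Merge site covariates with diversity results and add transformed
    responses/covariates: ln_E_sd; hpd_c and roads_c are log1p-transformed
    and centred (centring constants returned for reuse in projection)."""
    df = sites.merge(div, on="site_id", how="inner").copy()
    df["ln_E_sd"] = np.log(df["E_sd"])
    hpd_log = np.log1p(df["hpd"])
    roads_log = np.log1p(df["dist_roads"])
    centring = {"hpd_log_mean": float(hpd_log.mean()), "roads_log_mean": float(roads_log.mean())}
    df["hpd_c"] = hpd_log - centring["hpd_log_mean"]
    df["roads_c"] = roads_log - centring["roads_log_mean"]
    df["land_use"] = pd.Categorical(
        df["land_use"], categories=[l for l in LAND_USE_LEVELS if l in set(df["land_use"])]
    )
    df["subregion"] = pd.Categorical(df["subregion"], categories=sorted(df["subregion"].unique()))
    return df, centring


def _vc_formula(spec: ModelSpec):
    return {"block": "0 + C(block_id)"} if spec.include_block else None


def fit_lmm(
    data: pd.DataFrame, spec: ModelSpec, criterion: str = "REML", centring: dict | None = None
) -> ModelFit:
    """Fit one Gaussian mixed model; singular variance components are
    flagged (not silently accepted) and convergence status is recorded."""
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    if data[spec.groups].nunique() < 2:
        raise ValueError("need at least 2 studies to fit study-level random effects")
    y = data[spec.response]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    model = MixedLM.from_formula(
        spec.formula(),
        data,
        groups=data[spec.groups],
        re_formula=spec.re_formula,
        vc_formula=_vc_formula(spec),
    )
    X = np.asarray(model.exog)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient fixed-effect design for {spec.formula()!r}; "
            "a land-use or subregion level is too sparse for the requested terms"
        )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = None
        for method in (["lbfgs"], ["bfgs"], ["cg"], "powell"):
            try:
                res = model.fit(reml=(criterion == "REML"), method=method, maxiter=300)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is None:
            raise RuntimeError(f"mixed-model fit failed to converge for {spec.formula()!r}")
        converged = bool(getattr(res, "converged", True))
        fe = res.fe_params
        bse_fe = res.bse_fe  # may touch a near-singular Hessian; keep quiet
        cov_all = np.asarray(res.cov_params())
    vcomp: dict[str, float] = {}
    re_names = list(model.data.exog_re_names) if model.exog_re is not None else []
    cov_re = np.atleast_2d(np.asarray(res.cov_re)) if len(re_names) else np.zeros((0, 0))
    for i, name in enumerate(re_names):
        key = "study" if name in ("Group", "Intercept", "Group Var") else f"study_slope[{name}]"
        vcomp[key] = float(cov_re[i, i])
    for name, v in zip(model.exog_vc.names if model.exog_vc is not None else [], res.vcomp):
        vcomp[name] = float(v)
    vcomp["residual"] = float(res.scale)
    singular = any(
        v < 1e-8 * max(vcomp["residual"], 1e-12) for k, v in vcomp.items() if k != "residual"
    )
    # statsmodels reports NaN AIC under REML; compute it directly so REML
    # random-structure comparisons (identical fixed parts) are possible
    q = cov_re.shape[0]
    n_par = len(fe) + q * (q + 1) // 2 + (len(vcomp) - 1 - q) + 1
    aic = float(-2.0 * res.llf + 2.0 * n_par)
    k_fe = len(fe)
    cov_fe = pd.DataFrame(cov_all[:k_fe, :k_fe], index=fe.index, columns=fe.index)
    categories = {
        c: list(data[c].cat.categories)
        for c in data.columns
        if isinstance(data[c].dtype, pd.CategoricalDtype)
    }
    return ModelFit(
        spec=spec,
        params=fe,
        bse=bse_fe,
        cov_params=cov_fe,
        vcomp=vcomp,
        llf=float(res.llf),
        aic=aic,
        criterion=criterion,
        converged=converged,
        singular=singular,
        centring=centring or {},
        categories=categories,
        result=res,
    )


# ---------------------------------------------------------------------------
# model selection


def candidate_random_structures(include_slope: bool = True) -> list[dict]:
    """{study intercept} x {± block intercept} x {± HPD slope within study}."""
    cands = []
    slopes = ["~1", "~1 + hpd_c"] if include_slope else ["~1"]
    for re in slopes:
        for block in (False, True):
            cands.append({"re_formula": re, "include_block": block})
    return cands


def select_random_effects(
    data: pd.DataFrame,
    spec: ModelSpec,
    candidates: list[dict] | None = None,
    centring: dict | None = None,
) -> tuple[ModelSpec, ModelFit]:
    """Among REML fits sharing the fixed structure, keep the random
    structure with minimum AIC; ties go to the fit with fewer parameters."""
    if candidates is None:
        candidates = candidate_random_structures()
    fits = []
    for cand in candidates:
        s = ModelSpec(spec.response, spec.fixed, cand["re_formula"], cand["include_block"], spec.groups)
        try:
            fits.append((s, fit_lmm(data, s, "REML", centring)))
        except Exception:
            continue
    if not fits:
        raise RuntimeError("no candidate random structure could be fitted")
    usable = [(s, f) for s, f in fits if not f.singular] or fits
    best = min(usable, key=lambda sf: (round(sf[1].aic, 6), sf[1].n_params))
    return best


def _component_vars(term: str) -> set[str]:
    return set(term.split(":"))


def droppable_terms(fixed: tuple[str, ...]) -> list[str]:
    """Terms removable without violating marginality: a main effect is
    protected while any retained interaction contains it."""
    out = []
    for t in fixed:
        if ":" in t:
            out.append(t)
        else:
            in_interaction = any(":" in u and t in _component_vars(u) for u in fixed)
            if not in_interaction:
                out.append(t)
    return out


def lrt(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested ML fits."""
    chi2 = max(2.0 * (full.llf - reduced.llf), 0.0)
    df = len(full.params) - len(reduced.params)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def backward_select_fixed(
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    centring: dict | None = None,
) -> tuple[ModelFit, list[dict]]:
    """Backwards stepwise simplification with likelihood-ratio tests (ML
    fits): repeatedly drop the least significant droppable term while its
    deletion p-value exceeds ``alpha``; interactions go before their main
    effects. Returns the minimum adequate ML fit and the drop log."""
    current = spec
    fit = fit_lmm(data, current, "ML", centring)
    log: list[dict] = []
    while current.fixed:
        tests = []
        for term in droppable_terms(current.fixed):
            reduced_fit = fit_lmm(data, current.drop_term(term), "ML", centring)
            chi2, df, p = lrt(fit, reduced_fit)
            tests.append((p, term, chi2, df, reduced_fit))
        if not tests:
            break
        p, term, chi2, df, reduced_fit = max(tests, key=lambda t: t[0])
        if p > alpha:
            log.append({"dropped": term, "chi2": chi2, "df": df, "p": p})
            current = current.drop_term(term)
            fit = reduced_fit
        else:
            break
    return fit, log


def type2_anova(data: pd.DataFrame, spec: ModelSpec, centring: dict | None = None) -> pd.DataFrame:
    """Type II analysis-of-deviance table: each term is tested by a
    likelihood-ratio test against a model containing every term that does
    not include it (so main effects are tested excluding their own
    interactions)."""
    rows = []
    for term in spec.fixed:
        others = tuple(
            t for t in spec.fixed if t != term and not (_component_vars(term) <= _component_vars(t))
        )
        with_spec = ModelSpec(spec.response, others + (term,), spec.re_formula, spec.include_block, spec.groups)
        without_spec = ModelSpec(spec.response, others, spec.re_formula, spec.include_block, spec.groups)
        f1 = fit_lmm(data, with_spec, "ML", centring)
        f0 = fit_lmm(data, without_spec, "ML", centring)
        chi2, df, p = lrt(f1, f0)
        rows.append({"term": term, "chi2": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inference & diagnostics


def _simulate_response(fit: ModelFit, data: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Parametric simulation from the fitted model: fixed-effect mean plus
    study (intercept/slope), block and residual draws."""
    res = fit.result
    X = np.asarray(res.model.exog)
    mu = X @ fit.params.to_numpy()
    spec = fit.spec
    groups = data[spec.groups].to_numpy()
    studies = pd.unique(groups)
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    k_re = cov_re.shape[0] if res.model.exog_re is not None else 0
    y = mu.copy()
    if k_re > 0:
        draws = rng.multivariate_normal(np.zeros(k_re), cov_re, size=len(studies))
        z = np.asarray(res.model.exog_re)
        lookup = {g: i for i, g in enumerate(studies)}
        idx = np.array([lookup[g] for g in groups])
        y += np.einsum("ij,ij->i", z, draws[idx])
    if spec.include_block:
        var_block = fit.vcomp.get("block", 0.0)
        blocks = data["block_id"].to_numpy()
        ub = dict(zip(pd.unique(blocks), rng.normal(0, np.sqrt(max(var_block, 0.0)), pd.unique(blocks).size)))
        y += np.array([ub[b] for b in blocks])
    y += rng.normal(0, np.sqrt(fit.vcomp["residual"]), len(y))
    return y


def bootstrap_ci(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    centring: dict | None = None,
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for the fixed effects.

    Responses are simulated from the fitted (REML) model — respecting the
    nested study/block random-effect structure — and the model is refitted
    to each simulated dataset. A coefficient is flagged significant when
    its interval excludes zero. Aborts if more than ``max_failure_rate`` of
    the refits fail."""
    rng = np.random.default_rng(seed)
    fit = fit_lmm(data, spec, "REML", centring)
    draws = []
    failures = 0
    sim_data = data.copy()
    for _ in range(n_boot):
        sim_data[spec.response] = _simulate_response(fit, data, rng)
        try:
            bfit = fit_lmm(sim_data, spec, "REML", centring)
            if not np.all(np.isfinite(bfit.params.to_numpy())):
                raise FloatingPointError
            draws.append(bfit.params)
        except Exception:
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"bootstrap refits failed for {failures}/{n_boot} samples; "
            "model too fragile for interval estimation"
        )
    boot = pd.DataFrame(draws)
    a = (1 - level) / 2
    lo, hi = boot.quantile(a), boot.quantile(1 - a)
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "lower": lo,
            "upper": hi,
            "significant": (lo > 0) | (hi < 0),
        }
    )


def marginal_r2(fit: ModelFit) -> float:
    """Variance explained by the fixed effects relative to total variance
    (fixed + random + residual)."""
    res = fit.result
    X = np.asarray(res.model.exog)
    var_f = float(np.var(X @ fit.params.to_numpy()))
    var_r = 0.0
    if res.model.exog_re is not None:
        z = np.asarray(res.model.exog_re)
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        var_r += float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    var_r += sum(v for k, v in fit.vcomp.items() if k not in ("residual",) and not k.startswith("study"))
    denom = var_f + var_r + fit.vcomp["residual"]
    return var_f / denom if denom > 0 else 0.0


def gvif(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Generalized variance-inflation factors of the fixed-effect terms
    (determinant ratio of the predictor correlation matrix; multi-column
    terms handled jointly). Reports GVIF and GVIF^(1/(2·df))."""
    X = patsy.dmatrix(" + ".join(spec.fixed) if spec.fixed else "1", data, return_type="dataframe")
    di = X.design_info
    cols = X.to_numpy()
    keep = [t for t in di.term_names if t != "Intercept"]
    idx = {t: list(range(*di.term_name_slices[t].indices(cols.shape[1]))) for t in keep}
    centred = cols - cols.mean(axis=0)
    sd = centred.std(axis=0)
    use = sd > 0
    R = np.corrcoef(centred[:, use], rowvar=False)
    colmap = {old: new for new, old in enumerate(np.where(use)[0])}
    rows = []
    det = np.linalg.det
    detR = det(R)
    for term in keep:
        ti = [colmap[i] for i in idx[term] if i in colmap]
        if not ti:
            continue
        oi = [i for i in range(R.shape[0]) if i not in ti]
        if detR <= 0:
            g = np.inf
        else:
            g = det(R[np.ix_(ti, ti)]) * det(R[np.ix_(oi, oi)]) / detR
            if not np.isfinite(g) or g < 0:
                g = np.inf
        rows.append({"term": term, "df": len(ti), "gvif": g, "gvif_scaled": g ** (1 / (2 * len(ti))) if np.isfinite(g) else np.inf})
    return pd.DataFrame(rows)


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Moran's I with inverse-distance weights and a permutation p-value
    (alternative: positive spatial autocorrelation)."""
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 sites")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if not np.any(np.isfinite(d) & (d > 0)):
        raise ValueError("all coordinates coincide")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    w[np.isinf(w)] = 0.0
    s0 = w.sum()
    zc = z - z.mean()

    def stat(v):
        return (n / s0) * (v @ w @ v) / (v @ v)

    i_obs = stat(zc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(zc)) >= i_obs:
            count += 1
    return {
        "I": float(i_obs),
        "expected": -1.0 / (n - 1),
        "p": (count + 1) / (n_perm + 1),
    }


# ---------------------------------------------------------------------------
# prediction from serialized coefficients


def predict_fixed(fit: ModelFit | dict, newdata: pd.DataFrame) -> np.ndarray:
    """Population-level (fixed-effects-only) prediction for new covariate
    rows, rebuilding the design matrix from the stored formula and
    categorical level sets."""
    if isinstance(fit, ModelFit):
        formula = fit.spec.formula()
        params = fit.params
        categories = fit.categories
    else:
        formula = fit["formula"]
        params = pd.Series(fit["coefficients"])
        categories = fit.get("categories", {})
    rhs = formula.split("~", 1)[1]
    df = newdata.copy()
    for col, levels in categories.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=levels)
    X = patsy.dmatrix(rhs, df, return_type="dataframe")
    missing = [c for c in params.index if c not in X.columns]
    if missing:
        raise ValueError(f"design lacks model columns: {missing}")
    return X[list(params.index)].to_numpy() @ params.to_numpy()
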