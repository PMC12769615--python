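"""Longitudinal mixed models of formant values and modulation metrics.

Each metric (formant values, CV, modulation depth, spectral entropy) is
modelled as a Gaussian linear mixed model of vocal type and training day
(plus formant, where the metric pools formants), with a random intercept
per vocalization or per session. Responses are first passed through an
ordered-quantile (rank-based inverse normal) transform; full models are
compared against a random-intercept-only null with a likelihood-ratio
test, non-significant highest-order interactions are dropped, and per
vocal type day slopes with a Wald contrast are extracted from the fitted
coefficients (the estimated-marginal-trends construction: design-matrix
derivatives averaged over the remaining factor levels).

The mixed-model likelihood optimization is delegated to
``statsmodels.MixedLM``; the transform, model specification, LRT,
interaction-retention rule and slope algebra live here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "ModelSpec",
    "OrderNormTransform",
    "fit_model",
    "group_slopes",
    "ordernorm_apply",
    "ordernorm_fit",
]


@dataclass(frozen=True)
class OrderNormTransform:
    """Ordered-quantile normalizing transform.

    Maps the i-th order statistic of the training sample to the normal
    score ``Phi^-1((i - 0.5) / n)``; new values are transformed by linear
    interpolation between stored (value, score) pairs, with linear
    extrapolation beyond the training range. Monotone by construction.
    """

    x: np.ndarray  # sorted unique training values
    score: np.ndarray  # matching normal scores

    def apply(self, values: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(values, dtype=float)
        out = np.interp(v, self.x, self.score)
        # linear extrapolation on the tails
        if self.x.size >= 2:
            lo_slope = (self.score[1] - self.score[0]) / (self.x[1] - self.x[0])
            hi_slope = (self.score[-1] - self.score[-2]) / (self.x[-1] - self.x[-2])
            below = v < self.x[0]
            above = v > self.x[-1]
            out = np.where(below, self.score[0] + (v - self.x[0]) * lo_slope, out)
            out = np.where(above, self.score[-1] + (v - self.x[-1]) * hi_slope, out)
        return float(out) if np.isscalar(values) else out

    def inverse(self, scores: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(scores, dtype=float)
        out = np.interp(s, self.score, self.x)
        return float(out) if np.isscalar(scores) else out


def ordernorm_fit(values: np.ndarray) -> OrderNormTransform:
    """Fit the ordered-quantile transform on a training sample (n >= 10)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("ordernorm_fit needs at least 10 finite values")
    if np.all(v == v[0]):
        raise ValueError("ordernorm undefined on a constant sample")
    n = v.size
    order = np.sort(v)
    scores = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    # collapse ties to their average score so the map is a function
    xs, inverse = np.unique(order, return_inverse=True)
    avg = np.zeros(xs.size)
    counts = np.bincount(inverse)
    np.add.at(avg, inverse, scores)
    avg /= counts
    return OrderNormTransform(x=xs, score=avg)


def ordernorm_apply(transform: OrderNormTransform, values: np.ndarray) -> np.ndarray:
    return transform.apply(values)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one longitudinal mixed model.

    ``fixed`` is a formula right-hand side over {formant, vocal_type, day}
    (e.g. ``"formant * vocal_type * day"``); ``random`` names the grouping
    column for the random intercept, with an optional ``fallback_random``
    used when the first grouping gives a singular fit (the session-level
    fallback used for metrics with one value per vocalization).
    """

    response: str
    fixed: str
    random: str
    fallback_random: str | None = None
    transform: str = "ordernorm"  # or "none"
    drop_nonsig_interactions: bool = True
    alpha: float = 0.05


@dataclass
class ModelResult:
    spec: ModelSpec
    formula: str
    coefficients: pd.DataFrame  # estimate, se, z, p per fixed term
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    random_group: str
    singular: bool
    transform: OrderNormTransform | None
    design_info: object = field(repr=False, default=None)
    cov_params: np.ndarray = field(repr=False, default=None)
    data_columns: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "random_group": self.random_group,
            "singular": self.singular,
            "lrt": {"chi2": self.lrt_chi2, "df": self.lrt_df, "p": self.lrt_p},
            "coefficients": self.coefficients.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
        }


def _interaction_order(term: str) -> int:
    return term.count(":") + 1


def _fit_mixedlm(formula: str, data: pd.DataFrame, group: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[group])
        res = None
        for method in ("bfgs", "powell", "lbfgs"):
            res = model.fit(reml=False, method=method)
            cov = np.asarray(res.cov_params())
            if np.isfinite(res.llf) and np.isfinite(np.diag(cov)).all():
                break
        return model, res


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """Fit the specified mixed model and test it against its null.

    Steps: transform the response (ordered-quantile by default), fit the
    full fixed-effect structure with a random intercept, drop the
    highest-order interaction block when jointly non-significant (Wald,
    alpha = 0.05) and refit, then compare against a random-intercept-only
    null by likelihood ratio (both fits by maximum likelihood). A singular
    random-effect variance triggers the fallback grouping when configured.
    """
    df = data.dropna(subset=[spec.response]).copy()
    if "vocal_type" in df.columns and df["vocal_type"].nunique() < 2:
        raise ValueError("need both vocal types in the data")
    transform = None
    y = df[spec.response].to_numpy(dtype=float)
    if spec.transform == "ordernorm":
        transform = ordernorm_fit(y)
        df["_y"] = transform.apply(y)
    elif spec.transform == "none":
        df["_y"] = y
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")

    group = spec.random
    fixed = spec.fixed
    model, res = _fit_mixedlm(f"_y ~ {fixed}", df, group)
    singular = _is_singular(res)
    if singular and spec.fallback_random:
        group = spec.fallback_random
        model, res = _fit_mixedlm(f"_y ~ {fixed}", df, group)
        singular = _is_singular(res)

    if spec.drop_nonsig_interactions:
        while True:
            fe_names = list(model.exog_names)
            max_order = max(_interaction_order(t) for t in fe_names if t != "Intercept")
            if max_order < 2:
                break
            top = [t for t in fe_names if _interaction_order(t) == max_order]
            # constraint columns span all params (fixed + variance components)
            contrast = np.zeros((len(top), len(res.params)))
            for i, t in enumerate(top):
                contrast[i, fe_names.index(t)] = 1.0
            wald = res.wald_test(contrast, scalar=True)
            if float(wald.pvalue) < spec.alpha:
                break
            fixed = _drop_order(fixed, max_order)
            model, res = _fit_mixedlm(f"_y ~ {fixed}", df, group)

    null_model, null_res = _fit_mixedlm("_y ~ 1", df, group)
    chi2 = max(0.0, 2.0 * (res.llf - null_res.llf))
    dfree = len(model.exog_names) - len(null_model.exog_names)
    p = float(sps.chi2.sf(chi2, dfree)) if dfree > 0 else 1.0

    fe = res.fe_params
    k = len(fe)
    cov = np.asarray(res.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov))
    z = fe.to_numpy() / se
    coef = pd.DataFrame(
        {
            "estimate": fe.to_numpy(),
            "se": se,
            "z": z,
            "p": 2.0 * sps.norm.sf(np.abs(z)),
        },
        index=list(fe.index),
    )
    levels = {
        c: sorted(df[c].unique())
        for c in ("vocal_type", "formant")
        if c in df.columns and c in fixed
    }
    return ModelResult(
        spec=spec,
        formula=f"_y ~ {fixed}",
        coefficients=coef,
        lrt_chi2=chi2,
        lrt_df=dfree,
        lrt_p=p,
        random_group=group,
        singular=singular,
        transform=transform,
        design_info=model.data.design_info,
        cov_params=cov,
        data_columns=levels,
    )


def _is_singular(res, tol: float = 1e-6) -> bool:
    """Degenerate random-effect structure: variance on the zero boundary,
    or an uninformative grouping (all groups singletons, so the intercept
    variance is unidentifiable — the situation that forces the session-level
    fallback for one-value-per-vocalization metrics)."""
    try:
        re_var = float(np.asarray(res.cov_re).ravel()[0])
    except Exception:
        return False
    if re_var < tol * max(res.scale, 1e-12):
        return True
    sizes = [len(idx) for idx in res.model.row_indices.values()]
    return max(sizes) < 2


def _drop_order(fixed: str, order: int) -> str:
    """Rewrite a `a * b * c`-style RHS without its order-``order`` terms."""
    factors = [f.strip() for f in re.split(r"[*+:]", fixed) if f.strip()]
    factors = list(dict.fromkeys(factors))
    from itertools import combinations

    terms = []
    for r in range(1, min(order - 1, len(factors)) + 1):
        for combo in combinations(factors, r):
            terms.append(":".join(combo))
    return " + ".join(terms)


def group_slopes(
    result: ModelResult, data: pd.DataFrame, by: str = "vocal_type", over: str = "day"
) -> tuple[pd.DataFrame, dict]:
    """Per-group day slopes and their pairwise contrast.

    For each level of ``by``, the slope is the change in linear predictor
    per unit of ``over``, averaged over the levels of any other factors in
    the model (the estimated-marginal-trends construction; exact for a
    model linear in ``over``). Standard errors come from the fixed-effect
    covariance by the delta method; the two-group contrast is a Wald z test
    (equivalent to a Tukey comparison with two groups).
    """
    if over not in result.formula:
        raise ValueError(f"model has no {over!r} term")
    di = result.design_info
    by_levels = result.data_columns.get(by) or sorted(data[by].unique())
    other_factors = {
        c: lv for c, lv in result.data_columns.items() if c != by and c in result.formula
    }
    d0 = float(data[over].mean())
    rows = []
    lvecs = {}
    for level in by_levels:
        grids = []
        import itertools as it

        other_names = list(other_factors)
        combos = list(it.product(*[other_factors[c] for c in other_names])) or [()]
        for combo in combos:
            base = {by: level, over: d0}
            base.update(dict(zip(other_names, combo)))
            grids.append(base)
        g = pd.DataFrame(grids)
        g1 = g.copy()
        g1[over] = d0 + 1.0
        X0 = np.asarray(build_design_matrices([di], g)[0])
        X1 = np.asarray(build_design_matrices([di], g1)[0])
        L = (X1 - X0).mean(axis=0)
        lvecs[level] = L
        beta = result.coefficients["estimate"].to_numpy()
        slope = float(L @ beta)
        se = float(np.sqrt(L @ result.cov_params @ L))
        rows.append(
            {
                by: level,
                "slope": slope,
                "se": se,
                "ci_lo": slope - 1.96 * se,
                "ci_hi": slope + 1.96 * se,
            }
        )
    slopes = pd.DataFrame(rows)
    contrast: dict = {}
    if len(by_levels) == 2:
        Ld = lvecs[by_levels[1]] - lvecs[by_levels[0]]
        beta = result.coefficients["estimate"].to_numpy()
        est = float(Ld @ beta)
        se = float(np.sqrt(Ld @ result.cov_params @ Ld))
        z = est / se if se > 0 else np.inf * np.sign(est)
        contrast = {
            "comparison": f"{by_levels[1]} - {by_levels[0]}",
            "estimate": est,
            "se": se,
            "z": z,
            "p": float(2.0 * sps.norm.sf(abs(z))),
        }
    return slopes, contrast
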