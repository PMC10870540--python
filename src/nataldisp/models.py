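"""Fitted models of the dispersal analysis.

Three models are exposed:

* a binomial GLM of recruitment within the study area on the distance from
  the natal nest to the nearest foreign border or coastline (km, unscaled),
  whose predicted probabilities are used as case weights in the distance
  model to adjust for border-proximity emigration losses;
* a linear mixed model of log natal dispersal distance (natural log of
  metres) on sex, scaled natal-area breeder density (30 km) and scaled
  expected recruitment year, with crossed random intercepts for natal
  territory and recruitment year and the recruitment-probability weights;
* a linear mixed model of the breeding-minus-natal 10 km density difference
  on scaled natal density, scaled year and the scaled expected density
  difference (control), unweighted, same crossed random intercepts.

First-order interactions are fitted in an initial distance model and removed
when not significant (Wald, alpha = 0.05), after which the model is refit
with main effects only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import CrossedLMMResult, fit_crossed_lmm

__all__ = [
    "ModelFit",
    "fit_recruitment_glm",
    "predict_weights",
    "fit_lmm_distance",
    "fit_lmm_density_diff",
    "vif",
]


@dataclass
class ModelFit:
    """Uniform container for GLM/LMM outputs (fixed effects + variance components)."""

    formula: str
    coef: pd.DataFrame                 # term, estimate, se, chi2, df, p
    varcomp: pd.DataFrame              # group, variance, sd, n
    n_obs: int
    converged: bool
    loglik: float
    kind: str = "lmm"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "kind": self.kind,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "loglik": self.loglik,
            "coefficients": self.coef.to_dict(orient="records"),
            "variance_components": self.varcomp.to_dict(orient="records"),
            "extra": self.extra,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def format_table(self) -> str:
        """Plain-text table: fixed effects block, then random effects block."""
        lines = [self.formula, "", "Fixed effects:"]
        hdr = f"{'term':<28}{'estimate':>10}{'SE':>9}{'chi2':>10}{'df':>9}{'p':>12}"
        lines.append(hdr)
        for _, r in self.coef.iterrows():
            lines.append(f"{r['term']:<28}{r['estimate']:>10.3f}{r['se']:>9.3f}"
                         f"{r['chi2']:>10.2f}{r['df']:>9.2f}{r['p']:>12.4g}")
        if not self.varcomp.empty:
            lines += ["", "Random effects:",
                      f"{'group':<28}{'variance':>10}{'SD':>9}{'n':>7}"]
            for _, r in self.varcomp.iterrows():
                lines.append(f"{r['group']:<28}{r['variance']:>10.3f}"
                             f"{r['sd']:>9.3f}{int(r['n']):>7}")
        lines.append(f"\nn = {self.n_obs}, REML loglik = {self.loglik:.3f}"
                     if self.kind == "lmm" else f"\nn = {self.n_obs}")
        return "\n".join(lines)


def _from_lmm(res: CrossedLMMResult, formula: str, extra=None) -> ModelFit:
    return ModelFit(
        formula=formula,
        coef=res.coef_table(),
        varcomp=res.varcomp_table(),
        n_obs=res.n_obs,
        converged=res.converged,
        loglik=res.loglik,
        kind="lmm",
        extra={"singular": res.singular, "df_method": res.df_method,
               **(extra or {})},
    )


# ---------------------------------------------------------------------------
# recruitment GLM and weights


def fit_recruitment_glm(nestlings: pd.DataFrame,
                        response: str = "recruited",
                        distance: str = "border_km") -> ModelFit:
    """Binomial GLM: recruitment (0/1) ~ distance to border/coastline (km).

    Distance is deliberately left on its natural km scale so the slope reads
    as change in log-odds of recruitment per km.
    """
    y = nestlings[response].astype(float).to_numpy()
    d = nestlings[distance].astype(float).to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("recruitment outcome has a single class; GLM is undefined")
    if np.unique(d).size < 2:
        raise ValueError("need at least two distinct border distances")
    X = sm.add_constant(pd.DataFrame({distance: d}))
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    fitted = res.fittedvalues.to_numpy()
    if np.any(fitted > 1 - 1e-10) or np.any(fitted < 1e-10):
        raise ValueError("complete (quasi-)separation: fitted probabilities at 0/1; "
                         "check the border-distance covariate")
    z = res.params / res.bse
    coef = pd.DataFrame({
        "term": ["Intercept", distance],
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "chi2": (z ** 2).to_numpy(),
        "df": [1.0, 1.0],
        "p": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
    })
    return ModelFit(
        formula=f"{response} ~ {distance}  (binomial, logit link)",
        coef=coef,
        varcomp=pd.DataFrame(columns=["group", "variance", "sd", "n"]),
        n_obs=int(res.nobs),
        converged=bool(res.converged),
        loglik=float(res.llf),
        kind="glm",
        extra={"params": {"Intercept": float(res.params.iloc[0]),
                          distance: float(res.params.iloc[1])}},
    )


def predict_weights(fit: ModelFit, nestlings: pd.DataFrame,
                    distance: str = "border_km",
                    id_col: str = "individual_id") -> pd.Series:
    """Predicted recruitment probability per individual, indexed by id.

    Used directly as case weights in the distance model (weighting by the
    predicted probability, as opposed to its inverse, downweights the
    individuals least likely to have been observable — an
    ``inverse=True`` option gives conventional inverse-probability weights).
    """
    if not fit.converged:
        raise ValueError("recruitment GLM did not converge")
    b0 = fit.extra["params"]["Intercept"]
    b1 = fit.extra["params"][distance]
    eta = b0 + b1 * nestlings[distance].astype(float).to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(p, index=nestlings[id_col].astype(str), name="weight")


# ---------------------------------------------------------------------------
# mixed models


def _design(rows: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(rows))]
    names = ["Intercept"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(_column(rows, a) * _column(rows, b))
        else:
            cols.append(_column(rows, t))
        names.append(t)
    return np.column_stack(cols), names


def _column(rows: pd.DataFrame, term: str) -> np.ndarray:
    if term == "sex_male":
        return (rows["sex"] == "M").astype(float).to_numpy()
    return rows[term].astype(float).to_numpy()


def fit_lmm_distance(rows: pd.DataFrame, weights: pd.Series | np.ndarray | None = None,
                     include_interactions: bool = True, alpha: float = 0.05,
                     compute_df: bool = True) -> ModelFit:
    """Distance model: log_distance ~ sex + density30_z + year_z, crossed
    random intercepts for natal territory and recruitment year, case weights.

    With ``include_interactions`` the three first-order interactions are
    fitted first and those not significant at ``alpha`` (Wald) are removed
    before the reported refit.
    """
    w = _align_weights(rows, weights)
    groups = {"Natal territory": rows["natal_territory"].to_numpy(),
              "Recruitment year": rows["recruit_year"].to_numpy()}
    main = ["sex_male", "density30_z", "year_z"]
    dropped = []
    terms = list(main)
    if include_interactions:
        inter = ["sex_male:density30_z", "sex_male:year_z", "density30_z:year_z"]
        X0, names0 = _design(rows, main + inter)
        fit0 = fit_crossed_lmm(rows["log_distance"].to_numpy(), X0, names0,
                               groups, weights=w, compute_df=False)
        tab0 = fit0.coef_table().set_index("term")
        keep = [t for t in inter if tab0.loc[t, "p"] < alpha]
        dropped = [t for t in inter if t not in keep]
        terms = main + keep
    X, names = _design(rows, terms)
    res = fit_crossed_lmm(rows["log_distance"].to_numpy(), X, names, groups,
                          weights=w, compute_df=compute_df)
    formula = ("log_distance ~ " + " + ".join(terms)
               + " + (1 | natal_territory) + (1 | recruit_year)"
               + ("" if w is None else ", weights = recruitment probability"))
    return _from_lmm(res, formula, extra={"dropped_interactions": dropped})


def fit_lmm_density_diff(rows: pd.DataFrame, compute_df: bool = True) -> ModelFit:
    """Density-difference model: density_diff ~ density10_natal_z + year_z +
    expected_diff_z, unweighted, same crossed random intercepts.

    Variance components estimated at the zero boundary are legitimate and
    reported as 0."""
    use = rows.dropna(subset=["expected_diff_z"])
    groups = {"Natal territory": use["natal_territory"].to_numpy(),
              "Recruitment year": use["recruit_year"].to_numpy()}
    terms = ["density10_natal_z", "year_z", "expected_diff_z"]
    X, names = _design(use, terms)
    res = fit_crossed_lmm(use["density_diff"].astype(float).to_numpy(), X, names,
                          groups, weights=None, compute_df=compute_df)
    formula = ("density_diff ~ " + " + ".join(terms)
               + " + (1 | natal_territory) + (1 | recruit_year)")
    return _from_lmm(res, formula)


def _align_weights(rows: pd.DataFrame, weights) -> np.ndarray | None:
    if weights is None:
        return None
    if isinstance(weights, pd.Series):
        w = weights.reindex(rows["individual_id"].astype(str)).to_numpy()
        if np.any(~np.isfinite(w)):
            missing = rows.loc[~np.isfinite(w), "individual_id"].tolist()
            raise KeyError(f"no weight for individuals {missing[:5]}")
        return w
    w = np.asarray(weights, float)
    if w.shape[0] != len(rows):
        raise ValueError("weight vector length mismatch")
    return w


# ---------------------------------------------------------------------------
# multicollinearity


def vif(rows: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R_j^2) from regressing
    predictor j on the remaining predictors (with intercept)."""
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    M = np.column_stack([_column(rows, t) for t in predictors])
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(rows)), M]))
    if rank < len(predictors) + 1:
        raise ValueError(f"design is rank deficient; collinear set within {predictors}")
    out = {}
    for j, name in enumerate(predictors):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(len(rows)), np.delete(M, j, axis=1)])
        bhat, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ bhat
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out, name="VIF")
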