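"""Poisson regression with robust variance for prevalence ratios.

Prevalence contrasts between areas are estimated on aggregated (age band,
sex, area) strata with a log-link Poisson model offset by log population;
exponentiated coefficients are prevalence ratios.  Standard errors use the
HC0 sandwich A^-1 B A^-1 (A the Fisher information, B the outer product of
scores), which stays valid when the Poisson variance assumption fails;
an HC1 small-sample scaling is available by flag.  For a log-link model
with offsets the aggregated-cell fit is identical to the person-level fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm


@dataclass
class GlmFit:
    params: pd.Series
    robust_cov: pd.DataFrame
    model_cov: pd.DataFrame
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov)),
                         index=self.params.index)


def fit_poisson(counts, design: pd.DataFrame, offset_log_pop,
                cov: str = "HC0") -> GlmFit:
    """Poisson ML with log link, offset, and sandwich covariance.

    ``design`` must include the intercept column.  Raises on a
    rank-deficient design, naming the dependent columns.
    """
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    X = design.astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns whose removal restores full column rank
        bad = []
        for col in X.columns:
            rest = X.drop(columns=[col])
            if np.linalg.matrix_rank(rest.to_numpy()) == rank:
                bad.append(col)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    offset = np.asarray(offset_log_pop, dtype=float)
    if not np.isfinite(offset).all():
        raise ValueError("offsets must be finite")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=100, tol=1e-8, cov_type=cov)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {res.fit_history['iteration']} steps"
        )
    base = model.fit(maxiter=100, tol=1e-8)
    return GlmFit(
        params=pd.Series(res.params, index=X.columns),
        robust_cov=pd.DataFrame(res.cov_params(), index=X.columns,
                                columns=X.columns),
        model_cov=pd.DataFrame(base.cov_params(), index=X.columns,
                               columns=X.columns),
        converged=bool(res.converged),
        n_iter=int(res.fit_history["iteration"]),
        n_obs=len(y),
    )


def prevalence_ratio_table(fit: GlmFit, terms: list[str] | None = None,
                           level: float = 0.95) -> pd.DataFrame:
    """Exponentiated coefficients with robust Wald CIs and p-values."""
    z = float(norm.ppf(1 - (1 - level) / 2))
    terms = list(fit.params.index) if terms is None else terms
    rows = []
    for t in terms:
        b = float(fit.params[t])
        se = float(fit.robust_se[t])
        zval = b / se if se > 0 else np.inf * np.sign(b)
        rows.append(
            {
                "term": t,
                "pr": np.exp(b),
                "ci_low": np.exp(b - z * se),
                "ci_high": np.exp(b + z * se),
                "p": 2 * float(norm.sf(abs(zval))),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def fit_prevalence_model(strata: pd.DataFrame, factor: str = "province",
                         reference: str = "Napoli",
                         adjust: tuple[str, ...] = ("age_band", "sex"),
                         level: float = 0.95) -> tuple[GlmFit, pd.DataFrame]:
    """Prevalence ratios for the levels of ``factor`` adjusted for age and
    sex, on a stratum table with columns cases / population / factor /
    adjusters.  The reference level has PR fixed at 1."""
    if reference not in set(strata[factor]):
        raise ValueError(f"reference level {reference!r} not in {factor}")
    # an adjuster level with zero cases overall is fitted exactly at zero
    # (coefficient at the -inf boundary) and carries no information about
    # the factor contrasts; drop its strata to keep the fit interior
    strata = strata.copy()
    for adj in adjust:
        totals = strata.groupby(adj)["cases"].sum()
        dead = set(totals.index[totals <= 0])
        if dead:
            strata = strata.loc[~strata[adj].isin(dead)]
    strata = strata.reset_index(drop=True)
    X = pd.DataFrame({"const": np.ones(len(strata))}, index=strata.index)
    fac = pd.Categorical(
        strata[factor],
        categories=[reference] + sorted(set(strata[factor]) - {reference}),
    )
    for lev in fac.categories[1:]:
        X[f"{factor}[{lev}]"] = (fac == lev).astype(float)
    for adj in adjust:
        levels = sorted(set(strata[adj]))
        for lev in levels[1:]:
            X[f"{adj}[{lev}]"] = (strata[adj] == lev).astype(float)
    pop = strata["population"].to_numpy(dtype=float)
    keep = pop > 0
    fit = fit_poisson(
        strata.loc[keep, "cases"], X.loc[keep],
        np.log(pop[keep]),
    )
    factor_terms = [c for c in X.columns if c.startswith(f"{factor}[")]
    table = prevalence_ratio_table(fit, factor_terms, level)
    table.index = [t[len(factor) + 1:-1] for t in table.index]
    ref_row = pd.DataFrame(
        {"pr": [1.0], "ci_low": [1.0], "ci_high": [1.0], "p": [np.nan]},
        index=[reference],
    )
    return fit, pd.concat([ref_row, table])
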