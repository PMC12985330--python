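"""Association stage: Mantel screening, per-colour GLMs, inequality GLMM.

Spatial autocorrelation in each response is screened with a Mantel
permutation test between the response-distance matrix and the geographic
distance matrix; longitude and latitude then enter the models as fixed
covariates.  Each colour percentage is modelled with a gaussian-identity
GLM on habitat (treatment-coded), LUR, WEDGE, species richness, longitude
and latitude.  Colour inequality (Gini) is modelled the same way with PSV
added, and again as a linear mixed model with a habitat random intercept
(REML), reporting marginal and conditional pseudo-R².  Results are
condensed into a sign table: the sign of each estimate where p < alpha,
blank otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import (
    CollinearityError,
    DegenerateGroupingError,
    InvalidInputError,
    InvalidParameterError,
)

#: Default fixed predictors for the per-colour models.
COLOUR_PREDICTORS = ("lur", "wedge", "richness", "lon", "lat")
#: Fixed predictors for the colour-inequality models (PSV added).
INEQUALITY_PREDICTORS = ("lur", "wedge", "richness", "psv", "lon", "lat")


@dataclass
class ModelSpec:
    """Specification of one association model."""

    response: str
    predictors: tuple = COLOUR_PREDICTORS
    habitat: str | None = "habitat"
    reference: str | None = None  # None: most frequent observed level
    family: str = "gaussian"  # or "gaussian_logit" for a logit link
    random_intercept: bool = False

    def __post_init__(self):
        if len(set(self.predictors)) != len(self.predictors):
            raise InvalidParameterError("duplicate predictors")


@dataclass
class AssociationResult:
    """Fitted coefficients, standard errors and p-values of one model."""

    response: str
    terms: pd.DataFrame  # index: term; columns: estimate, se, p
    loglik: float
    family: str
    reference: str | None = None
    variance_components: dict = field(default_factory=dict)
    r_squared: dict = field(default_factory=dict)


def mantel_test(
    d_var: np.ndarray,
    d_geo: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the corresponding off-diagonal
    entries; p is the one-sided (greater) Monte-Carlo p-value
    (1 + #{permuted r >= observed}) / (n_perm + 1) under simultaneous
    row/column permutation of one matrix.
    """
    a = np.asarray(d_var, dtype=float)
    b = np.asarray(d_geo, dtype=float)
    for name, m in (("d_var", a), ("d_geo", b)):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError(f"{name} is not square")
        if not np.allclose(m, m.T):
            raise InvalidInputError(f"{name} is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise InvalidInputError(f"{name} has a nonzero diagonal")
    if a.shape != b.shape:
        raise InvalidInputError("distance matrices differ in dimension")
    n = a.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 sites")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    y = b[iu]
    xc = x - x.mean()
    yn = y - y.mean()
    xnorm = np.sqrt((xc**2).sum())
    ynorm = np.sqrt((yn**2).sum())
    if xnorm == 0 or ynorm == 0:
        raise InvalidInputError("degenerate (constant) distance matrix")
    r_obs = float(xc @ yn / (xnorm * ynorm))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = a[np.ix_(perm, perm)][iu]
        xpc = xp - xp.mean()
        r_p = xpc @ yn / (np.sqrt((xpc**2).sum()) * ynorm)
        if r_p >= r_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return r_obs, p


def mantel_screen(
    data: pd.DataFrame,
    responses: list[str],
    lon: str = "lon",
    lat: str = "lat",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel test of each response's distance matrix vs geographic distance."""
    xy = data[[lon, lat]].to_numpy(dtype=float)
    d_geo = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    rows = []
    for i, resp in enumerate(responses):
        v = data[resp].to_numpy(dtype=float)
        d_var = np.abs(v[:, None] - v[None, :])
        r, p = mantel_test(d_var, d_geo, n_perm=n_perm, seed=seed + i)
        rows.append({"response": resp, "mantel_r": r, "p": p})
    return pd.DataFrame(rows).set_index("response")


def _resolve_reference(data: pd.DataFrame, spec: ModelSpec) -> str | None:
    if spec.habitat is None:
        return None
    levels = data[spec.habitat].astype(str)
    if spec.reference is not None:
        if spec.reference not in set(levels):
            raise InvalidInputError(
                f"reference level {spec.reference!r} not observed"
            )
        return spec.reference
    return levels.value_counts().idxmax()


def _formula(spec: ModelSpec, reference: str | None) -> str:
    terms = []
    if spec.habitat is not None and not spec.random_intercept:
        terms.append(f"C({spec.habitat}, Treatment(reference={reference!r}))")
    terms.extend(spec.predictors)
    return f"Q({spec.response!r}) ~ " + " + ".join(terms)


_HABITAT_TERM = re.compile(r"^C\([^,]+,.*\)\[T\.(.+)\]$")


def _clean_term(name: str, habitat: str | None) -> str:
    m = _HABITAT_TERM.match(name)
    if m:
        return f"{habitat}[{m.group(1)}]"
    return name


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # scale columns to unit norm so the rank test is insensitive to units
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        raise CollinearityError([names[i] for i in np.flatnonzero(norms == 0)])
    Xs = X / norms
    rank = np.linalg.matrix_rank(Xs)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(Xs)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise CollinearityError(bad or names)


def _transform_response(y: pd.Series, family: str) -> pd.Series:
    if family == "gaussian":
        return y
    if family == "gaussian_logit":
        # percentages squeezed off the boundary before the logit
        p = np.clip(y / 100.0, 1e-6, 1 - 1e-6)
        return pd.Series(np.log(p / (1 - p)), index=y.index)
    raise InvalidParameterError(f"unknown family: {family!r}")


def fit_colour_glm(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Gaussian-identity GLM of one response on habitat + landscape terms.

    Habitat is treatment-coded against the reference level (default: the
    most frequent observed label); per-term Wald tests are reported.
    """
    if data.isna().any().any():
        raise InvalidInputError("data contains missing values")
    reference = _resolve_reference(data, spec)
    work = data.copy()
    work[spec.response] = _transform_response(work[spec.response], spec.family)
    formula = _formula(spec, reference)
    y, X = patsy.dmatrices(formula, work, return_type="dataframe")
    if X.shape[0] <= X.shape[1]:
        raise InvalidInputError("more coefficients than observations")
    _check_full_rank(X.to_numpy(), list(X.columns))
    model = sm.GLM(y, X, family=sm.families.Gaussian())
    res = model.fit()
    terms = pd.DataFrame(
        {
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "p": res.pvalues.to_numpy(),
        },
        index=[_clean_term(t, spec.habitat) for t in X.columns],
    )
    return AssociationResult(
        response=spec.response,
        terms=terms,
        loglik=float(res.llf),
        family=spec.family,
        reference=reference,
    )


def fit_inequality_mixed(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Linear mixed model with a habitat random intercept, fit by REML.

    Reports fixed-effect estimates/SE/p, variance components, and the
    marginal / conditional pseudo-R²:

        marginal    = s2_fixed / (s2_fixed + s2_group + s2_resid)
        conditional = (s2_fixed + s2_group) / (s2_fixed + s2_group + s2_resid)

    where s2_fixed is the variance of the fixed-effect linear predictor.
    """
    if data.isna().any().any():
        raise InvalidInputError("data contains missing values")
    if spec.habitat is None:
        raise InvalidParameterError("mixed model requires a grouping column")
    groups = data[spec.habitat].astype(str)
    if groups.nunique() < 2:
        raise DegenerateGroupingError(
            f"need >= 2 habitat groups, got {groups.nunique()}"
        )
    work = data.copy()
    work[spec.response] = _transform_response(work[spec.response], spec.family)
    # fit on z-scored predictors for numerical stability, then map the
    # estimates back to the original scale (p-values are invariant)
    centres = {p: float(work[p].mean()) for p in spec.predictors}
    scales = {p: float(work[p].std(ddof=0)) or 1.0 for p in spec.predictors}
    for p in spec.predictors:
        work[p] = (work[p] - centres[p]) / scales[p]
    formula = f"Q({spec.response!r}) ~ " + " + ".join(spec.predictors)
    model = smf.mixedlm(formula, work, groups=groups)
    try:
        res = model.fit(reml=True, method="lbfgs")
    except np.linalg.LinAlgError:
        # gradient evaluation can hit a singular profile when the group
        # variance collapses; retry derivative-free
        res = model.fit(reml=True, method="powell")
    fe_names = list(model.exog_names)
    beta = res.fe_params.to_numpy()
    var_fixed = float(np.var(model.exog @ beta))
    var_group = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    var_resid = float(res.scale)
    denom = var_fixed + var_group + var_resid
    terms = pd.DataFrame(
        {
            "estimate": [res.params[t] for t in fe_names],
            "se": [res.bse[t] for t in fe_names],
            "p": [res.pvalues[t] for t in fe_names],
        },
        index=fe_names,
    )
    for p in spec.predictors:
        terms.loc[p, ["estimate", "se"]] /= scales[p]
        terms.loc["Intercept", "estimate"] -= (
            terms.loc[p, "estimate"] * centres[p]
        )
    return AssociationResult(
        response=spec.response,
        terms=terms,
        loglik=float(res.llf),
        family=spec.family,
        variance_components={
            "group": var_group,
            "residual": var_resid,
            "fixed": var_fixed,
        },
        r_squared={
            "marginal": var_fixed / denom,
            "conditional": (var_fixed + var_group) / denom,
        },
    )


def sign_table(
    results: list[AssociationResult],
    alpha: float = 0.05,
    habitat: str = "habitat",
) -> pd.DataFrame:
    """Condense fitted models into a predictor x response table of signs.

    Each cell holds "+" or "-" when the term's p-value is below ``alpha``
    and is blank otherwise.  Rows are ordered habitat contrasts first,
    then LUR, WEDGE, richness, PSV, latitude, longitude.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    cells: dict[str, dict[str, str]] = {}
    row_order: list[str] = []
    for res in results:
        col = {}
        for term, row in res.terms.iterrows():
            if term == "Intercept":
                continue
            col[term] = (
                ("+" if row["estimate"] > 0 else "-") if row["p"] < alpha else ""
            )
            if term not in row_order:
                row_order.append(term)
        cells[res.response] = col
    habitat_rows = sorted(t for t in row_order if t.startswith(f"{habitat}["))
    tail = [t for t in ("lur", "wedge", "richness", "psv", "lat", "lon") if t in row_order]
    other = [t for t in row_order if t not in habitat_rows and t not in tail]
    ordered = habitat_rows + other + tail
    table = pd.DataFrame(index=ordered, columns=[r.response for r in results], data="")
    for res in results:
        for term, sign in cells[res.response].items():
            table.loc[term, res.response] = sign
    table.index.name = "predictor"
    return table
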