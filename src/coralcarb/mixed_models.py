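"""Random-intercept linear mixed models for annual-band density.

Skeletal density measured on successive annual growth bands of the same core
is not independent: colonies differ in baseline density and bands within a
colony share that baseline.  The model is

    density ~ status + band_age (+ status:band_age) + extension_cm

with REML-estimated random intercepts for colony identity nested in reef zone
(statsmodels ``MixedLM``).  Extension rate enters as a fixed continuous
covariate: a continuous covariate cannot be a random intercept, so this is the
closest expressible design (flagged in the fit metadata).  Fixed terms are
tested with Type II Wald chi-square statistics; designs with three status
levels (living / dead 1 yr / dead 2 yr) additionally get all pairwise
contrasts of estimated marginal means with a Tukey-style adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMMFit",
    "WaldTestResult",
    "ContrastResult",
    "ConvergenceError",
    "fit_density_lmm",
    "wald_type2",
    "pairwise_status_contrasts",
]


class ConvergenceError(RuntimeError):
    """Raised when no optimizer produces a converged, non-singular fit."""


@dataclass
class LMMFit:
    """A converged REML mixed-model fit of band density.

    Holds the fixed-effect estimates/covariance plus enough context (the data
    and model options) to construct marginality-respecting Type II tests and
    marginal-mean contrasts.
    """

    params: pd.Series
    cov: pd.DataFrame
    term_columns: dict[str, list[str]]
    random_variances: dict[str, float]
    resid_variance: float
    converged: bool
    n_obs: int
    df_resid: int
    status_levels: list[str]
    method: str = "REML"
    metadata: dict = field(default_factory=dict)
    # context for type-II companions and contrasts (not part of the public repr)
    _data: pd.DataFrame | None = field(default=None, repr=False)
    _design_info: object | None = field(default=None, repr=False)
    _options: dict = field(default_factory=dict, repr=False)
    _companion: "LMMFit | None" = field(default=None, repr=False)

    @property
    def include_interaction(self) -> bool:
        return bool(self._options.get("include_interaction", False))


@dataclass(frozen=True)
class WaldTestResult:
    """Type II Wald chi-square test of one fixed term."""

    term: str
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContrastResult:
    """Pairwise difference of estimated marginal means between status levels."""

    level_a: str
    level_b: str
    estimate: float
    se: float
    z: float
    p_value: float
    adjustment: str


def _formula(include_interaction: bool, include_extension: bool) -> str:
    rhs = "C(status, Treatment('living')) + band_age"
    if include_interaction:
        rhs += " + C(status, Treatment('living')):band_age"
    if include_extension:
        rhs += " + extension_cm"
    return "density ~ " + rhs


def fit_density_lmm(
    data: pd.DataFrame,
    include_interaction: bool = False,
    include_extension: bool = True,
    zone_re: bool = True,
) -> LMMFit:
    """Fit the random-intercept density model by REML.

    ``data`` needs columns colony, status, zone, band_age, extension_cm,
    density; each colony must carry a single status, with at least two colonies
    per status and no missing densities.  Raises :class:`ConvergenceError`
    rather than returning a silently non-converged fit.
    """
    required = {"colony", "status", "zone", "band_age", "extension_cm", "density"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"band observations missing columns: {sorted(missing)}")
    if data["density"].isna().any():
        raise ValueError("missing densities are not allowed")
    if (data["density"] <= 0).any():
        raise ValueError("densities must be positive")
    if (data["band_age"] < 1).any():
        raise ValueError("band_age counts years from the surface, starting at 1")
    per_colony = data.groupby("colony")["status"].nunique()
    if (per_colony > 1).any():
        raise ValueError("each colony must have a single status")
    levels = sorted(data["status"].unique(), key=lambda s: (s != "living", s))
    if len(levels) < 2:
        raise ValueError("single-status data: the status term is inestimable")
    colonies_per_status = data.groupby("status")["colony"].nunique()
    if (colonies_per_status < 2).any():
        raise ValueError("need at least two colonies per status level")

    formula = _formula(include_interaction, include_extension)
    use_zone = zone_re and data["zone"].nunique() > 1
    if use_zone:
        model = MixedLM.from_formula(
            formula,
            data,
            groups="zone",
            re_formula="1",
            vc_formula={"colony": "0 + C(colony)"},
        )
    else:
        model = MixedLM.from_formula(formula, data, groups="colony", re_formula="1")

    result = None
    errors: list[str] = []
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=True, method=method, maxiter=200)
        except (np.linalg.LinAlgError, ValueError) as exc:  # singular fits
            errors.append(f"{method}: {exc}")
            continue
        if cand.converged:
            result = cand
            break
        errors.append(f"{method}: optimizer did not converge")
    if result is None:
        raise ConvergenceError(
            "mixed-model fit failed to converge; optimizer diagnostics: " + "; ".join(errors)
        )

    fe = result.fe_params
    cov = result.cov_params().loc[fe.index, fe.index]
    di = result.model.data.design_info
    term_cols = {
        name: list(fe.index[sl]) for name, sl in di.term_name_slices.items()
    }
    scale = float(result.scale)
    rand = {}
    if use_zone:
        rand["zone"] = float(np.asarray(result.cov_re)[0, 0])
        rand["colony"] = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    else:
        rand["colony"] = float(np.asarray(result.cov_re)[0, 0])
    return LMMFit(
        params=fe,
        cov=cov,
        term_columns=term_cols,
        random_variances=rand,
        resid_variance=scale,
        converged=bool(result.converged),
        n_obs=int(result.nobs),
        df_resid=int(result.nobs - len(fe)),
        status_levels=levels,
        metadata={
            "formula": formula,
            "zone_random_intercept": use_zone,
            "extension_as_fixed_covariate": include_extension,
        },
        _data=data,
        _design_info=di,
        _options={
            "include_interaction": include_interaction,
            "include_extension": include_extension,
            "zone_re": zone_re,
        },
    )


def _subvector_wald(fit: LMMFit, term: str) -> WaldTestResult:
    cols = fit.term_columns[term]
    beta = fit.params[cols].to_numpy()
    V = fit.cov.loc[cols, cols].to_numpy()
    if np.linalg.matrix_rank(V) < len(cols):
        raise np.linalg.LinAlgError(
            f"rank-deficient covariance submatrix for term {term!r}"
        )
    stat = float(beta @ np.linalg.solve(V, beta))
    df = len(cols)
    return WaldTestResult(term=term, statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def _companion_fit(fit: LMMFit) -> LMMFit:
    """Fit without the interaction, for type-II tests of its main effects."""
    if fit._companion is None:
        opts = dict(fit._options)
        opts["include_interaction"] = False
        fit._companion = fit_density_lmm(fit._data, **opts)
    return fit._companion


def wald_type2(fit: LMMFit) -> list[WaldTestResult]:
    """Type II Wald chi-square test for every non-intercept fixed term.

    Each term is tested after all other terms except its own higher-order
    interactions: with the status x band_age interaction in the model, the
    status and band_age main effects are tested on the companion fit that
    excludes the interaction; the interaction itself (and any term with no
    higher-order relatives) is a subvector Wald test on the given fit.
    """
    if not fit.converged:
        raise ValueError("refusing to test a non-converged fit")
    results = []
    interaction = [t for t in fit.term_columns if ":" in t]
    for term in fit.term_columns:
        if term == "Intercept":
            continue
        is_main_of_interaction = any(
            term != inter and set(term.split(":")) < set(inter.split(":"))
            for inter in interaction
        )
        source = _companion_fit(fit) if is_main_of_interaction else fit
        results.append(_subvector_wald(source, term))
    return results


def _emm_rows(fit: LMMFit) -> dict[str, np.ndarray]:
    """Fixed-effect design row of the estimated marginal mean per status level."""
    data = fit._data
    ref = pd.DataFrame(
        {
            "status": pd.Series(fit.status_levels),
            "band_age": float(data["band_age"].mean()),
            "extension_cm": float(data["extension_cm"].mean()),
        }
    )
    (mat,) = patsy.build_design_matrices([fit._design_info], ref)
    arr = np.asarray(mat)
    return {lvl: arr[i] for i, lvl in enumerate(fit.status_levels)}


def pairwise_status_contrasts(fit: LMMFit, adjustment: str = "tukey") -> list[ContrastResult]:
    """All pairwise status contrasts of estimated marginal means.

    Marginal means are evaluated at the mean band age (and mean extension).
    ``adjustment``: 'tukey' (studentized-range over the 3 means, default),
    'bonferroni', or 'none'."""
    if len(fit.status_levels) != 3:
        raise ValueError(
            "pairwise contrasts are for 3-level status designs; "
            "use wald_type2 for 2-level status"
        )
    if adjustment not in ("tukey", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment: {adjustment!r}")
    rows = _emm_rows(fit)
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    out = []
    pairs = list(itertools.combinations(fit.status_levels, 2))
    for a, b in pairs:
        L = rows[a] - rows[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        z = est / se if se > 0 else 0.0
        p = 2.0 * float(stats.norm.sf(abs(z)))
        if adjustment == "tukey":
            p_adj = float(
                stats.studentized_range.sf(abs(z) * np.sqrt(2.0), 3, max(fit.df_resid, 2))
            )
        elif adjustment == "bonferroni":
            p_adj = min(1.0, p * len(pairs))
        else:
            p_adj = p
        out.append(
            ContrastResult(
                level_a=a, level_b=b, estimate=est, se=se, z=z,
                p_value=min(1.0, p_adj), adjustment=adjustment,
            )
        )
    return out
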