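"""Nested mixed-model comparisons of encoder metrics against human norms.

Linear mixed models with a single random intercept for the anaphoric
expression relate each response variable (surprisal, cosine distance, or
mean human similarity) to fixed effects drawn from {condition, surprisal,
cosine distance}.  Models are fitted by maximum likelihood (not REML —
REML likelihoods are not comparable across fixed-effect structures), and
nested pairs are compared with likelihood-ratio tests

    chi2 = 2 (ll_full - ll_reduced),  df = extra fixed-effect parameters,

with the 4-level condition factor contributing 3 parameters under
treatment coding (alphabetically first level as reference).  p values are
Bonferroni-adjusted over the family of encoder metrics tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

_ALLOWED_RESPONSES = {"surprisal", "cosine_distance", "mean_similarity"}
_ALLOWED_EFFECTS = {"condition", "surprisal", "cosine_distance"}

#: Delta-loglik below which optimizer noise is floored to chi2 = 0.
CHI2_TOL = 1e-6


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A linear mixed model: response ~ fixed effects + (1 | group)."""

    response: str
    fixed_effects: tuple[str, ...]
    random_intercept: str = "anaphor"

    def __post_init__(self) -> None:
        if self.response not in _ALLOWED_RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        bad = set(self.fixed_effects) - _ALLOWED_EFFECTS
        if bad:
            raise ValueError(f"unknown fixed effects {sorted(bad)}")
        if self.response in self.fixed_effects:
            raise ValueError("response cannot also be a fixed effect")

    @property
    def formula(self) -> str:
        terms = [
            "C(condition)" if fe == "condition" else fe for fe in self.fixed_effects
        ]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.response == other.response
            and self.random_intercept == other.random_intercept
            and set(self.fixed_effects) < set(other.fixed_effects)
        )


@dataclass(frozen=True)
class FittedModel:
    spec: ModelSpec
    params: pd.Series
    loglik: float
    n_fixed_params: int
    converged: bool
    singular: bool  # random-intercept variance estimated at (near) zero
    n_obs: int
    group_var: float


def fit_mixed_model(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit the mixed model by maximum likelihood.

    Rows with missing values in any used variable are dropped (complete
    cases).  The condition factor is treatment-coded with the
    alphabetically first level as reference, so the intercept estimates
    that level's adjusted mean.  A singular fit (zero random-intercept
    variance) is retained with a warning; failure to converge raises
    :class:`ConvergenceError`.
    """
    cols = [spec.response, spec.random_intercept] + [
        fe for fe in spec.fixed_effects
    ]
    df = data[cols].dropna().reset_index(drop=True)
    if df[spec.random_intercept].nunique() < 2:
        raise ValueError("random-intercept grouping factor needs >= 2 levels")

    if np.ptp(df[spec.response].to_numpy()) == 0.0:
        # constant response: the Gaussian ML likelihood degenerates, so the
        # fit is returned in closed form (every coefficient absorbs nothing)
        import patsy

        warnings.warn(f"response {spec.response!r} is constant", stacklevel=2)
        design = patsy.dmatrix(spec.formula.split("~", 1)[1], df)
        names = design.design_info.column_names
        const = float(df[spec.response].iloc[0])
        params = pd.Series(
            [const if n == "Intercept" else 0.0 for n in names], index=names
        )
        return FittedModel(
            spec=spec, params=params, loglik=0.0, n_fixed_params=len(params),
            converged=True, singular=True, n_obs=len(df), group_var=0.0,
        )

    # Powell first: near the variance boundary (common with a weak grouping
    # factor) gradient-based optimizers here can fail outright or report a
    # non-finite likelihood.
    res = None
    failures = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, df, groups=df[spec.random_intercept])
        for method in ("powell", "lbfgs", "cg"):
            try:
                cand = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as err:
                failures.append(f"{method}: {err}")
                continue
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
            failures.append(f"{method}: converged={cand.converged}, llf={cand.llf}")
    if res is None:
        raise ConvergenceError(
            f"ML fit failed for {spec.formula!r} "
            f"(n={len(df)}, groups={df[spec.random_intercept].nunique()}): "
            + "; ".join(failures)
        )
    group_var = float(np.atleast_2d(res.cov_re)[0, 0])
    singular = group_var < 1e-8
    if singular:
        warnings.warn(
            f"singular fit: zero random-intercept variance for {spec.formula!r}",
            stacklevel=2,
        )
    return FittedModel(
        spec=spec,
        params=res.fe_params,
        loglik=float(res.llf),
        n_fixed_params=len(res.fe_params),
        converged=bool(res.converged),
        singular=singular,
        n_obs=len(df),
        group_var=group_var,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Likelihood-ratio test between nested mixed models."""

    full: ModelSpec
    reduced: ModelSpec
    loglik_full: float
    loglik_reduced: float
    chi2: float
    df: int
    p_raw: float
    p_adjusted: float = field(default=float("nan"))


def likelihood_ratio_test(full: FittedModel, reduced: FittedModel) -> ComparisonResult:
    """chi2 = 2*delta-loglik against a chi-square with df = extra parameters.

    Requires the reduced model's fixed effects to be a strict subset of the
    full model's, fitted on the same rows with the same random structure.
    Small negative delta-logliks from optimizer noise are floored at zero.
    """
    identical = (
        reduced.spec.response == full.spec.response
        and reduced.spec.random_intercept == full.spec.random_intercept
        and set(reduced.spec.fixed_effects) == set(full.spec.fixed_effects)
    )
    if not identical and not reduced.spec.is_nested_in(full.spec):
        raise ValueError(
            f"{reduced.spec.formula!r} is not nested in {full.spec.formula!r}"
        )
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted on different numbers of rows")
    delta = full.loglik - reduced.loglik
    if delta < -CHI2_TOL:
        warnings.warn(
            f"full model loglik below reduced by {-delta:.3g}; flooring chi2 at 0",
            stacklevel=2,
        )
    chi2 = max(0.0, 2.0 * delta)
    df = full.n_fixed_params - reduced.n_fixed_params
    if identical:
        # degenerate self-comparison: no extra parameters, nothing to test
        chi2, df, p = 0.0, 0, 1.0
    else:
        if df < 1:
            raise ValueError("nested comparison needs >= 1 extra parameter")
        p = float(stats.chi2.sf(chi2, df))
    return ComparisonResult(
        full=full.spec,
        reduced=reduced.spec,
        loglik_full=full.loglik,
        loglik_reduced=reduced.loglik,
        chi2=chi2,
        df=df,
        p_raw=p,
    )


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """min(1, m*p) for each p; m defaults to the family size len(p_values)."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("family size must be >= 1")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p value outside [0, 1]: {p}")
    return [min(1.0, m * p) for p in ps]


def compare_metrics(
    data: pd.DataFrame, family_size: int = 2
) -> list[ComparisonResult]:
    """The study's nested comparisons over both encoder metrics.

    For each metric in {surprisal, final-layer cosine_distance}: (a) does
    condition explain variance in the metric, and (b) does the metric
    explain variance in mean human similarity beyond condition?  Each
    family of ``family_size`` metric tests is Bonferroni-adjusted together.
    ``data`` columns: item, condition, anaphor, mean_similarity, surprisal,
    cosine_distance (final layer).
    """
    results: list[ComparisonResult] = []

    def lrt(full_spec: ModelSpec, reduced_spec: ModelSpec) -> ComparisonResult:
        return likelihood_ratio_test(
            fit_mixed_model(full_spec, data), fit_mixed_model(reduced_spec, data)
        )

    # (a) metric ~ condition vs metric ~ 1
    family_a = [
        lrt(
            ModelSpec(metric, ("condition",)),
            ModelSpec(metric, ()),
        )
        for metric in ("surprisal", "cosine_distance")
    ]
    # (b) similarity ~ condition + metric vs similarity ~ condition
    family_b = [
        lrt(
            ModelSpec("mean_similarity", ("condition", metric)),
            ModelSpec("mean_similarity", ("condition",)),
        )
        for metric in ("surprisal", "cosine_distance")
    ]
    for family in (family_a, family_b):
        adjusted = bonferroni_adjust([r.p_raw for r in family], m=family_size)
        for r, p_adj in zip(family, adjusted):
            results.append(
                ComparisonResult(
                    **{**vars(r), "p_adjusted": p_adj}
                )
            )
    return results
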