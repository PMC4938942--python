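"""Binary-outcome index models with robust inference.

Probit (default), logit, or linear-probability models for the ELCS/EMCS
indicators, estimated by maximum likelihood (OLS for the linear case) with
Huber-White (HC1) sandwich covariance — the "robust standard errors" of the
applied literature.  Average marginal effects use the discrete 0->1 change
for binary/dummy regressors and the density-weighted slope for continuous
ones, averaged over the estimation sample, with delta-method standard
errors from the robust covariance.

Estimation is delegated to statsmodels; separation, collinearity and
convergence diagnostics are checked here so failures name the offending
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import GROUP_COLUMN, Cohort
from .design import INTERCEPT, PRIVATE, DesignInfo, build_design
from .exceptions import (CollinearityError, ConfigError, DataError,
                         EstimationError, SeparationError)
from .links import get_link

_LL_CLIP = 1e-10

__all__ = [
    "ModelSpec",
    "FitResult",
    "MarginalEffectsTable",
    "fit",
    "predict_probability",
    "average_marginal_effects",
    "pseudo_r2",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Stars at the 0.01 / 0.05 / 0.10 levels."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass(frozen=True)
class ModelSpec:
    """One binary-outcome model.

    ``terms`` are cohort covariate names (categoricals expand against
    ``reference_levels``, defaulting to the first declared level).  With
    ``include_private`` and no terms this is the unadjusted "private only"
    specification.  ``exclude_if_positive`` drops rows positive in another
    outcome before estimation — the convention that the elective-CS model
    excludes emergency deliveries and vice versa.
    """

    outcome: str
    terms: tuple[str, ...] = ()
    link: str = "probit"
    include_private: bool = True
    reference_levels: Mapping[str, str] | None = None
    term_kinds: Mapping[str, str] | None = None
    exclude_if_positive: tuple[str, ...] = ()

    def validate(self) -> None:
        get_link(self.link)
        # no terms + no group indicator = intercept-only model; allowed
        # (used for null log-likelihoods and degenerate checks)

    def without_terms(self, drop: Sequence[str]) -> "ModelSpec":
        drop = set(drop)
        unknown = drop - set(self.terms)
        if unknown:
            raise ConfigError(f"cannot drop unknown terms {sorted(unknown)}")
        kept = tuple(t for t in self.terms if t not in drop)
        if not kept and not self.include_private:
            raise ConfigError("dropping all covariates leaves an empty model")
        return replace(self, terms=kept)


@dataclass
class FitResult:
    """Estimates, robust covariance and estimation-sample metadata."""

    params: pd.Series
    robust_cov: pd.DataFrame
    link: str
    n_used: int
    loglik: float
    converged: bool
    design: DesignInfo
    model_spec: ModelSpec
    sample_index: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)

    @property
    def coefficients(self) -> pd.Series:
        return self.params

    def beta(self) -> np.ndarray:
        return self.params.to_numpy()


@dataclass
class MarginalEffectsTable:
    """Per-column AME with robust SE, z, p and significance stars."""

    table: pd.DataFrame
    outcome: str
    n_used: int
    pseudo_r2: float | None = None

    def to_csv(self, path) -> None:
        """Export in published-table layout (estimate, SE, stars) plus
        full-precision columns."""
        out = self.table.copy()
        out.insert(0, "display", [
            f"{row.ame:.3f} ({row.se:.3f}){row.stars}"
            for row in out.itertuples()
        ])
        out.to_csv(path, index_label="term")


def _estimation_frame(cohort: Cohort, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply outcome exclusions and listwise deletion; return (frame, index)."""
    df = cohort.data
    if spec.outcome not in df.columns:
        raise ConfigError(f"outcome {spec.outcome!r} not in cohort")
    keep = np.ones(len(df), dtype=bool)
    for other in spec.exclude_if_positive:
        if other not in df.columns:
            raise ConfigError(f"exclusion outcome {other!r} not in cohort")
        keep &= ~(pd.to_numeric(df[other], errors="coerce") == 1).to_numpy()
    work = df.loc[keep].copy()
    info = build_design(cohort, spec.terms, include_private=spec.include_private,
                        reference_levels=spec.reference_levels,
                        term_kinds=spec.term_kinds)
    needed = [spec.outcome, *info.source_columns]
    for col in needed:
        if col == GROUP_COLUMN:
            continue
        if work[col].dtype == object and info.kinds.get(col) != "categorical":
            # columns read under a missing-value sentinel arrive as strings
            coerced = pd.to_numeric(work[col], errors="coerce")
            if coerced.notna().sum() > 0 and work[col].notna().sum() > 0:
                non_numeric = coerced.isna() & work[col].notna()
                if not non_numeric.any():
                    work[col] = coerced
    complete = work[needed].notna().all(axis=1)
    work = work.loc[complete]
    if len(work) == 0:
        raise DataError("no complete observations after listwise deletion")
    index = np.flatnonzero(keep)[complete.to_numpy()]
    return work, index


def _check_separation(y: np.ndarray, X: np.ndarray, info: DesignInfo) -> None:
    for j, col in enumerate(info.columns):
        if info.kinds[col] != "binary":
            continue
        x = X[:, j]
        if x.min() == x.max():
            continue
        y1, y0 = y[x == 1], y[x == 0]
        if y1.size and y0.size and y1.min() == y1.max() and y0.min() == y0.max() \
                and y1[0] != y0[0]:
            raise SeparationError(
                f"column {col!r} perfectly partitions outcome "
                f"{np.round(float(y1[0]))!r} vs {np.round(float(y0[0]))!r}"
            )


def _check_rank(X: np.ndarray, info: DesignInfo) -> None:
    from scipy import linalg
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        collinear = sorted(info.columns[j] for j in piv[r:])
        raise CollinearityError(f"rank-deficient design; collinear columns {collinear}")


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _LL_CLIP, 1 - _LL_CLIP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def fit(cohort: Cohort, spec: ModelSpec) -> FitResult:
    """Fit the model by ML (Newton, gradient tolerance 1e-8, <=100 iters)."""
    spec.validate()
    work, index = _estimation_frame(cohort, spec)
    y = pd.to_numeric(work[spec.outcome]).to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DataError(f"outcome {spec.outcome!r} is not binary 0/1")
    if np.unique(y).size < 2:
        raise DataError(f"outcome {spec.outcome!r} has a single class in sample")
    info = build_design(cohort, spec.terms, include_private=spec.include_private,
                        reference_levels=spec.reference_levels,
                        term_kinds=spec.term_kinds)
    X = info.matrix(work)
    _check_rank(X, info)
    _check_separation(y, X, info)

    if spec.link == "identity":
        res = sm.OLS(y, X).fit(cov_type="HC1")
        params = res.params
        cov = res.cov_params()
        llf = _bernoulli_loglik(y, X @ params)
        converged = True
    else:
        model = sm.Probit(y, X) if spec.link == "probit" else sm.Logit(y, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="newton", maxiter=100, tol=1e-8,
                                disp=0, cov_type="HC1", warn_convergence=False)
                converged = bool(res.mle_retvals.get("converged", True))
                if not converged:
                    # Newton oscillates under quasi-separation (rare binary
                    # indicators with a one-sided outcome); L-BFGS settles on
                    # the likelihood plateau.  Accept only if the score has
                    # genuinely vanished.
                    res = model.fit(method="lbfgs", maxiter=5000, disp=0,
                                    pgtol=1e-9, factr=10.0, maxfun=20000,
                                    cov_type="HC1", warn_convergence=False)
                    score = model.score(np.asarray(res.params))
                    converged = float(np.max(np.abs(score))) < 1e-4 * len(y)
            except (np.linalg.LinAlgError,
                    sm.tools.sm_exceptions.PerfectSeparationError) as exc:
                raise EstimationError(f"estimation failed: {exc}") from exc
        if not converged:
            raise EstimationError(
                "maximisation did not converge (Newton 100 iterations, then "
                f"L-BFGS): loglik {res.llf:.6g}, "
                f"max |score| {float(np.max(np.abs(model.score(np.asarray(res.params))))):.3g}"
            )
        params = res.params
        cov = res.cov_params()
        llf = float(res.llf)

    params = pd.Series(np.asarray(params), index=info.columns)
    cov = pd.DataFrame(np.asarray(cov), index=info.columns, columns=info.columns)
    return FitResult(params=params, robust_cov=cov, link=spec.link,
                     n_used=len(work), loglik=llf, converged=converged,
                     design=info, model_spec=spec, sample_index=index,
                     y=y.astype(np.int64), X=X)


def predict_probability(fit_result: FitResult, covariate_rows) -> np.ndarray:
    """Predicted P(y=1) for new rows (DataFrame or Cohort).

    Identity-link predictions are returned unclipped; values outside [0, 1]
    raise a ``UserWarning``.
    """
    df = covariate_rows.data if isinstance(covariate_rows, Cohort) else covariate_rows
    X = fit_result.design.matrix(df)
    p = get_link(fit_result.link).cdf(X @ fit_result.beta())
    if fit_result.link == "identity" and ((p < 0) | (p > 1)).any():
        warnings.warn("identity-link predictions outside [0, 1] returned unclipped",
                      UserWarning, stacklevel=2)
    return p


def _ame_and_gradient(beta: np.ndarray, X: np.ndarray, j: int, kind: str, link):
    """AME for column j and its gradient wrt beta (for the delta method)."""
    if kind == "binary":
        X1, X0 = X.copy(), X.copy()
        X1[:, j], X0[:, j] = 1.0, 0.0
        z1, z0 = X1 @ beta, X0 @ beta
        ame = float(np.mean(link.cdf(z1) - link.cdf(z0)))
        grad = (link.pdf(z1)[:, None] * X1 - link.pdf(z0)[:, None] * X0).mean(axis=0)
    else:
        z = X @ beta
        f = link.pdf(z)
        ame = float(np.mean(f) * beta[j])
        grad = (link.dpdf(z)[:, None] * X).mean(axis=0) * beta[j]
        grad[j] += float(np.mean(f))
    return ame, grad


def average_marginal_effects(fit_result: FitResult,
                             cohort: Cohort | None = None) -> MarginalEffectsTable:
    """AMEs over the estimation sample (or over ``cohort`` if given)."""
    if not fit_result.converged:
        raise EstimationError("marginal effects require a converged fit")
    if cohort is None:
        X = fit_result.X
    else:
        X = fit_result.design.matrix(cohort.data)
    link = get_link(fit_result.link)
    beta = fit_result.beta()
    V = fit_result.robust_cov.to_numpy()
    rows = []
    from scipy import stats
    for j, col in enumerate(fit_result.design.columns):
        if col == INTERCEPT:
            continue
        ame, grad = _ame_and_gradient(beta, X, j, fit_result.design.kinds[col], link)
        se = float(np.sqrt(grad @ V @ grad))
        z = ame / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append((col, ame, se, z, p, significance_stars(p) if np.isfinite(z) else ""))
    table = pd.DataFrame(rows, columns=["term", "ame", "se", "z", "p", "stars"])
    table = table.set_index("term")
    return MarginalEffectsTable(table=table, outcome=fit_result.model_spec.outcome,
                                n_used=fit_result.n_used)


def pseudo_r2(fit_result: FitResult, cohort: Cohort | None = None) -> float:
    """McFadden pseudo-R2: 1 - loglik(model)/loglik(intercept-only)."""
    if not fit_result.converged:
        raise EstimationError("pseudo-R2 requires a converged fit")
    y = fit_result.y
    pbar = float(y.mean())
    if pbar in (0.0, 1.0):
        raise EstimationError("degenerate outcome: all 0 or all 1")
    ll0 = _bernoulli_loglik(y.astype(float), np.full(y.shape, pbar))
    return 1.0 - fit_result.loglik / ll0
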