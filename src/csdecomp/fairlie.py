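"""Non-linear Oaxaca-Blinder decomposition of a binary-outcome group gap.

The public-private gap in mean outcome is split into an *explained* part —
what the gap would be if only the distribution of observed characteristics
differed between groups, evaluated at a reference coefficient vector — and
an *unexplained* remainder:

    gap       = mean(Y | public) - mean(Y | private)
    explained = mean F(X_pub b_ref) - mean F(X_pri b_ref)
    unexplained = gap - explained            (exact, by construction)

Per-covariate detailed contributions follow the Fairlie procedure for
non-linear models: each replication draws a random subsample of the larger
group equal in size to the smaller, pairs observations across groups by the
rank of their predicted probabilities, then switches covariates one block
at a time from the larger-group value to the smaller-group value in a
random order, recording the change in the mean predicted probability at
each step.  The per-block changes telescope to the matched sample's
explained gap; averaging over replications integrates out both the
subsample and the switching order (path dependence).

Reference coefficients may come from the public-sample fit, the
private-sample fit, or a pooled fit (with or without a group dummy whose
coefficient is then zeroed for the counterfactual predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .design import INTERCEPT, PRIVATE
from .exceptions import ConfigError, DataError, EstimationError
from .links import get_link
from .model import FitResult, ModelSpec, _estimation_frame, fit, significance_stars

REFERENCES = ("public", "private", "pooled")

__all__ = [
    "DecompositionSpec",
    "AggregateDecomposition",
    "DetailedContributionTable",
    "aggregate_decomposition",
    "draw_subsample",
    "match_by_rank",
    "sequential_contributions",
    "detailed_decomposition",
    "sensitivity_rerun",
    "reference_fit",
]

_TIE_SCALE = 1e-12


@dataclass(frozen=True)
class DecompositionSpec:
    """How the gap is decomposed.

    ``covariate_blocks`` optionally groups design columns (or whole model
    terms, which expand to their dummy columns) so they are switched
    jointly; by default every design column is its own block, so each dummy
    level of a categorical family is listed separately.
    """

    reference: str = "public"
    replications: int = 1000
    randomize_order: bool = True
    fixed_order: tuple[str, ...] | None = None
    pooled_includes_group_dummy: bool = False
    seed: int = 0
    covariate_blocks: Mapping[str, Sequence[str]] | None = None
    se_method: str = "replication"  # or "delta"

    def validate(self) -> None:
        if self.reference not in REFERENCES:
            raise ConfigError(f"unknown reference {self.reference!r}")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")
        if not self.randomize_order and self.fixed_order is None:
            raise ConfigError("randomize_order=False requires a fixed_order")
        if self.se_method not in ("replication", "delta"):
            raise ConfigError(f"unknown se_method {self.se_method!r}")


@dataclass
class AggregateDecomposition:
    """Raw gap and its explained/unexplained split, in probability units."""

    outcome: str
    reference: str
    gap: float
    explained: float
    unexplained: float
    n_public: int
    n_private: int

    @property
    def explained_share(self) -> float:
        """Explained component as % of the gap."""
        return 100.0 * self.explained / self.gap


@dataclass
class DetailedContributionTable:
    """Per-block contributions averaged over replications.

    ``table`` has one row per covariate block plus a ``(residual)`` row
    (aggregate explained minus the sum of listed contributions, i.e. the
    Monte-Carlo subsampling remainder); columns: contribution (probability
    units), pct_of_gap, se, z, p, stars.
    """

    table: pd.DataFrame
    aggregate: AggregateDecomposition
    spec: DecompositionSpec
    replications_used: int
    failed_replications: int = 0
    dropped_terms: tuple[str, ...] = ()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="block")


# ---------------------------------------------------------------------------
# reference coefficients


def _subcohort(cohort: Cohort, frame: pd.DataFrame) -> Cohort:
    return Cohort(data=frame, outcome_names=cohort.outcome_names,
                  covariates=cohort.covariates, provenance=None)


def reference_fit(cohort: Cohort, model_spec: ModelSpec,
                  decomp_spec: DecompositionSpec) -> FitResult:
    """Fit the reference coefficient vector on the appropriate sample."""
    if decomp_spec.reference == "pooled":
        spec = replace(model_spec,
                       include_private=decomp_spec.pooled_includes_group_dummy)
        return fit(cohort, spec)
    spec = replace(model_spec, include_private=False)
    mask = cohort.data["group"] == decomp_spec.reference
    if not mask.any():
        raise DataError(f"no rows in reference group {decomp_spec.reference!r}")
    return fit(_subcohort(cohort, cohort.data.loc[mask]), spec)


def _decomposition_beta(fit_ref: FitResult) -> np.ndarray:
    """Reference beta with the group-dummy coefficient (if any) zeroed."""
    beta = fit_ref.beta().copy()
    if PRIVATE in fit_ref.design.columns:
        beta[fit_ref.design.index_of(PRIVATE)] = 0.0
    return beta


# ---------------------------------------------------------------------------
# aggregate decomposition


def aggregate_decomposition(fit_ref: FitResult, cohort: Cohort,
                            outcome: str) -> AggregateDecomposition:
    """Explained/unexplained split of the gap using ``fit_ref``'s coefficients.

    The analysis sample applies the reference model's exclusion and
    listwise-deletion rules to the full two-group cohort; additivity
    (explained + unexplained = gap) is exact.
    """
    spec = replace(fit_ref.model_spec, outcome=outcome)
    work, _ = _estimation_frame(cohort, spec)
    pub = (work["group"] == "public").to_numpy()
    pri = (work["group"] == "private").to_numpy()
    if not pub.any() or not pri.any():
        raise DataError("both groups must be present in the analysis sample")
    y = pd.to_numeric(work[outcome]).to_numpy(dtype=float)
    gap = float(y[pub].mean() - y[pri].mean())
    beta = _decomposition_beta(fit_ref)
    p = get_link(fit_ref.link).cdf(fit_ref.design.matrix(work) @ beta)
    explained = float(p[pub].mean() - p[pri].mean())
    return AggregateDecomposition(
        outcome=outcome, reference=None, gap=gap, explained=explained,
        unexplained=gap - explained,
        n_public=int(pub.sum()), n_private=int(pri.sum()),
    )


# ---------------------------------------------------------------------------
# Fairlie machinery


def draw_subsample(larger_group: np.ndarray, target_size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Simple random sample without replacement from an index array."""
    larger_group = np.asarray(larger_group)
    if target_size > larger_group.size:
        raise ValueError(
            f"target_size {target_size} exceeds group size {larger_group.size}"
        )
    return rng.choice(larger_group, size=target_size, replace=False)


def match_by_rank(p_a: np.ndarray, p_b: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Pair the i-th smallest of ``p_a`` with the i-th smallest of ``p_b``.

    Ties are broken by a seeded uniform perturbation of magnitude 1e-12
    before ranking, so the pairing is deterministic given the RNG substream
    and unbiased across ties.
    """
    p_a, p_b = np.asarray(p_a, dtype=float), np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError(f"length mismatch: {p_a.size} vs {p_b.size}")
    order_a = np.argsort(p_a + _TIE_SCALE * rng.random(p_a.size))
    order_b = np.argsort(p_b + _TIE_SCALE * rng.random(p_b.size))
    return order_a, order_b


def sequential_contributions(pairing: tuple[np.ndarray, np.ndarray],
                             X_a: np.ndarray, X_b: np.ndarray,
                             beta_ref: np.ndarray,
                             ordering: Sequence[int],
                             blocks: Sequence[Sequence[int]],
                             link_name: str = "probit") -> np.ndarray:
    """Per-block contributions for one matched replication.

    Starting from every pair at its group-a covariates, blocks are switched
    to the group-b values in ``ordering``; the contribution of a block is
    the drop in mean predicted probability when it switches.  Contributions
    are returned in block order (not switching order) and sum exactly to
    mean F(X_a b) - mean F(X_b b) on the matched sample.
    """
    idx_a, idx_b = pairing
    if len(idx_a) != len(idx_b):
        raise ValueError("pairing must be a bijection between equal-size samples")
    if sorted(ordering) != list(range(len(blocks))):
        raise ValueError("ordering must be a permutation of the blocks")
    link = get_link(link_name)
    Xa = X_a[idx_a]
    Xb = X_b[idx_b]
    lp = Xa @ beta_ref
    contributions = np.empty(len(blocks))
    mean_before = float(link.cdf(lp).mean())
    for k in ordering:
        cols = list(blocks[k])
        delta = (Xb[:, cols] - Xa[:, cols]) @ beta_ref[cols]
        lp = lp + delta
        mean_after = float(link.cdf(lp).mean())
        contributions[k] = mean_before - mean_after
        mean_before = mean_after
    return contributions


def _sequential_gradients(pairing, X_a, X_b, beta_ref, ordering, blocks,
                          link_name):
    """Per-block gradients of the contributions wrt beta (delta method)."""
    idx_a, idx_b = pairing
    link = get_link(link_name)
    Xa = X_a[idx_a].copy()
    Xb = X_b[idx_b]
    grads = np.empty((len(blocks), beta_ref.size))
    Z = Xa.copy()
    lp = Z @ beta_ref
    f_before = link.pdf(lp)
    Z_before = Z.copy()
    for k in ordering:
        cols = list(blocks[k])
        Z[:, cols] = Xb[:, cols]
        lp = Z @ beta_ref
        f_after = link.pdf(lp)
        grads[k] = (f_before[:, None] * Z_before - f_after[:, None] * Z).mean(axis=0)
        f_before = f_after
        Z_before = Z.copy()
    return grads


def _resolve_blocks(design, decomp_spec) -> tuple[list[str], list[list[int]]]:
    """Blocks of design-column indices; intercept and group dummy excluded."""
    switchable = [c for c in design.columns if c not in (INTERCEPT, PRIVATE)]
    col_index = {c: j for j, c in enumerate(design.columns)}
    if decomp_spec.covariate_blocks is None:
        return switchable, [[col_index[c]] for c in switchable]
    names, blocks, used = [], [], set()
    for name, members in decomp_spec.covariate_blocks.items():
        cols: list[str] = []
        for m in members:
            if m in col_index and m not in (INTERCEPT, PRIVATE):
                cols.append(m)
            else:  # a term name: expand to its design columns
                expanded = [c for c in switchable if design.term_of[c] == m]
                if not expanded:
                    raise ConfigError(f"block {name!r}: unknown member {m!r}")
                cols.extend(expanded)
        overlap = used & set(cols)
        if overlap:
            raise ConfigError(f"block {name!r}: columns {sorted(overlap)} reused")
        used |= set(cols)
        names.append(name)
        blocks.append([col_index[c] for c in cols])
    missing = [c for c in switchable if c not in used]
    for c in missing:  # unblocked columns become singleton blocks
        names.append(c)
        blocks.append([col_index[c]])
    return names, blocks


def detailed_decomposition(cohort: Cohort, outcome: str, model_spec: ModelSpec,
                           decomp_spec: DecompositionSpec) -> DetailedContributionTable:
    """Full Fairlie decomposition: aggregate split plus per-block table.

    Reproducible given ``decomp_spec.seed``: replication ``r`` uses an
    independent RNG substream keyed by ``r``, so results do not depend on
    execution order.  Replications that fail are skipped and counted; more
    than 1% failures aborts.
    """
    decomp_spec.validate()
    model_spec = replace(model_spec, outcome=outcome)
    fit_ref = reference_fit(cohort, model_spec, decomp_spec)
    aggregate = aggregate_decomposition(fit_ref, cohort, outcome)
    aggregate.reference = decomp_spec.reference

    work, _ = _estimation_frame(cohort, replace(fit_ref.model_spec, outcome=outcome))
    pub_mask = (work["group"] == "public").to_numpy()
    X = fit_ref.design.matrix(work)
    beta = _decomposition_beta(fit_ref)
    p_hat = get_link(fit_ref.link).cdf(X @ beta)

    X_pub, X_pri = X[pub_mask], X[~pub_mask]
    p_pub, p_pri = p_hat[pub_mask], p_hat[~pub_mask]

    block_names, blocks = _resolve_blocks(fit_ref.design, decomp_spec)
    K = len(blocks)
    if K == 0:
        raise ConfigError("no switchable covariates: the model has no terms")
    if decomp_spec.fixed_order is not None:
        name_pos = {n: i for i, n in enumerate(block_names)}
        unknown = [n for n in decomp_spec.fixed_order if n not in name_pos]
        if unknown:
            raise ConfigError(f"fixed_order names unknown blocks {unknown}")
        if len(decomp_spec.fixed_order) != K:
            raise ConfigError("fixed_order must list every block exactly once")
        fixed = [name_pos[n] for n in decomp_spec.fixed_order]

    # the larger group is subsampled down to the smaller group's size
    pub_larger = X_pub.shape[0] >= X_pri.shape[0]
    X_large, p_large = (X_pub, p_pub) if pub_larger else (X_pri, p_pri)
    X_small, p_small = (X_pri, p_pri) if pub_larger else (X_pub, p_pub)
    n_small = X_small.shape[0]
    large_indices = np.arange(X_large.shape[0])

    R = decomp_spec.replications
    contribs = np.full((R, K), np.nan)
    grads = np.zeros((K, beta.size)) if decomp_spec.se_method == "delta" else None
    failed = 0
    for r in range(R):
        rng = np.random.default_rng(
            np.random.SeedSequence(decomp_spec.seed, spawn_key=(r,)))
        try:
            sub = draw_subsample(large_indices, n_small, rng)
            pairing = match_by_rank(p_large[sub], p_small, rng)
            ordering = (rng.permutation(K) if decomp_spec.randomize_order
                        else np.asarray(fixed))
            # orient switching public -> private so signs follow the gap
            if pub_larger:
                args = (pairing, X_large[sub], X_small, beta, ordering, blocks)
            else:
                args = ((pairing[1], pairing[0]), X_small, X_large[sub], beta,
                        ordering, blocks)
            contribs[r] = sequential_contributions(*args, link_name=fit_ref.link)
            if grads is not None:
                grads += _sequential_gradients(*args, link_name=fit_ref.link)
        except Exception:  # degenerate subsample etc.: skip and count
            failed += 1
    used = R - failed
    if used == 0:
        raise EstimationError("all replications failed")
    if failed > 0.01 * R:
        raise EstimationError(f"{failed}/{R} replications failed (> 1%)")
    contribs = contribs[~np.isnan(contribs[:, 0])]

    mean_c = contribs.mean(axis=0)
    if decomp_spec.se_method == "delta":
        V = fit_ref.robust_cov.to_numpy()
        G = grads / used
        se = np.sqrt(np.einsum("kp,pq,kq->k", G, V, G))
    elif used > 1:
        se = contribs.std(axis=0, ddof=1) / np.sqrt(used)
    else:
        se = np.full(K, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean_c / se
    p_val = 2 * stats.norm.sf(np.abs(z))

    gap = aggregate.gap
    rows = []
    for k, name in enumerate(block_names):
        pct = 100.0 * mean_c[k] / gap if gap != 0 else np.nan
        star = significance_stars(p_val[k]) if np.isfinite(p_val[k]) else ""
        rows.append((name, mean_c[k], pct, se[k], z[k], p_val[k], star))
    residual = aggregate.explained - mean_c.sum()
    pct_res = 100.0 * residual / gap if gap != 0 else np.nan
    rows.append(("(residual)", residual, pct_res, np.nan, np.nan, np.nan, ""))
    table = pd.DataFrame(
        rows, columns=["block", "contribution", "pct_of_gap", "se", "z", "p", "stars"]
    ).set_index("block")
    return DetailedContributionTable(
        table=table, aggregate=aggregate, spec=decomp_spec,
        replications_used=used, failed_replications=failed,
    )


def sensitivity_rerun(cohort: Cohort, outcome: str, model_spec: ModelSpec,
                      decomp_spec: DecompositionSpec,
                      drop: Sequence[str]) -> DetailedContributionTable:
    """Refit and re-decompose with ``drop`` covariate terms removed."""
    drop = tuple(drop)
    reduced = model_spec.without_terms(drop) if drop else model_spec
    result = detailed_decomposition(cohort, outcome, reduced, decomp_spec)
    result.dropped_terms = tuple(sorted(drop))
    return result
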