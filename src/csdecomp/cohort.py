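"""Synthetic delivery-level cohorts with a two-group (public/private) structure.

The generator emulates the statistical skeleton the decomposition analysis
assumes: two groups of unequal size, group-specific covariate mixes, and
binary caesarean-section outcomes drawn from probit (or logit/linear) index
models.  ``default_spec()`` calibrates the covariate marginals and group
sizes to the published 2009 Irish nulliparous-singleton descriptive table;
its outcome coefficients are illustrative, because published average
marginal effects cannot be inverted into index coefficients without the
record-level data.

Covariates are drawn independently within group by default (only marginal
prevalences are published).  An optional Gaussian-copula correlation hook
couples selected covariates.  A single root seed is expanded into one
substream per covariate and per outcome, so adding a column never perturbs
the values of existing columns.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration as calib
from .exceptions import ConfigError, DataError
from .links import VALID_LINKS, get_link

GROUPS = ("public", "private")
GROUP_COLUMN = "group"

__all__ = [
    "CovariateSpec",
    "OutcomeSpec",
    "CohortSpec",
    "Cohort",
    "CohortSchema",
    "default_spec",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution of one covariate, parameterised per group.

    kind:
        ``binary``       group_params[g] is the prevalence in [0, 1]
        ``categorical``  group_params[g] maps level -> probability (sums to 1)
        ``continuous``   group_params[g] is (mean, sd), sd > 0
        ``banded``       like categorical over bands, but additionally emits a
                         continuous column drawn uniformly within the band's
                         (low, high) range; the band label goes to
                         ``<name>_band``.  Used for age (years), birthweight
                         (kg) and gestation (weeks), which are published in
                         bands but modelled continuously.
    """

    name: str
    kind: str
    group_params: Mapping[str, object]
    bands: Mapping[str, tuple[float, float]] | None = None

    def validate(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous", "banded"):
            raise ConfigError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        for g in GROUPS:
            if g not in self.group_params:
                raise ConfigError(f"covariate {self.name!r}: missing group {g!r}")
        if self.kind == "binary":
            for g in GROUPS:
                p = float(self.group_params[g])
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"covariate {self.name!r}: prevalence {p} outside [0, 1]"
                    )
        elif self.kind in ("categorical", "banded"):
            levels = None
            for g in GROUPS:
                probs = dict(self.group_params[g])
                if levels is None:
                    levels = list(probs)
                elif list(probs) != levels:
                    raise ConfigError(
                        f"covariate {self.name!r}: level sets differ between groups"
                    )
                vec = np.array(list(probs.values()), dtype=float)
                if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-12:
                    raise ConfigError(
                        f"covariate {self.name!r}: probabilities for group {g!r} "
                        f"must be non-negative and sum to 1 (got sum {vec.sum()!r})"
                    )
            if self.kind == "banded":
                if self.bands is None or list(self.bands) != levels:
                    raise ConfigError(
                        f"covariate {self.name!r}: banded kind requires bands "
                        "matching the probability levels"
                    )
        elif self.kind == "continuous":
            for g in GROUPS:
                mean, sd = self.group_params[g]
                if not sd > 0:
                    raise ConfigError(
                        f"covariate {self.name!r}: standard deviation must be > 0"
                    )

    @property
    def levels(self) -> list[str] | None:
        if self.kind in ("categorical", "banded"):
            return list(self.group_params[GROUPS[0]])
        return None

    def columns(self) -> list[str]:
        """Column names this covariate contributes to the cohort table."""
        if self.kind == "banded":
            return [self.name, f"{self.name}_band"]
        return [self.name]


@dataclass(frozen=True)
class OutcomeSpec:
    """Binary outcome drawn from an index model y ~ Bernoulli(F(x'b)).

    ``coefficients`` maps design-column names (including ``intercept``) to
    values; categorical levels are addressed as ``name[level]``.
    ``group_effect`` is an extra coefficient on the private-group indicator.
    """

    name: str
    coefficients: Mapping[str, float]
    group_effect: float = 0.0
    link: str = "probit"

    def validate(self, available_columns: set[str]) -> None:
        if self.link not in VALID_LINKS:
            raise ConfigError(f"outcome {self.name!r}: unknown link {self.link!r}")
        unknown = [c for c in self.coefficients if c not in available_columns]
        if unknown:
            raise ConfigError(
                f"outcome {self.name!r}: coefficient columns {unknown} not "
                "produced by the declared covariates"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic two-group cohort."""

    n_public: int
    n_private: int
    covariates: tuple[CovariateSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    seed: int = 0
    # optional Gaussian-copula correlation: [(name_a, name_b, rho), ...]
    correlations: tuple[tuple[str, str, float], ...] = ()

    def validate(self) -> None:
        if self.n_public < 1 or self.n_private < 1:
            raise ConfigError("both groups must be non-empty")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("covariate names must be unique")
        for cov in self.covariates:
            cov.validate()
        available = self.design_columns()
        for out in self.outcomes:
            out.validate(available)
        for a, b, rho in self.correlations:
            if a not in names or b not in names:
                raise ConfigError(f"correlation references unknown covariate ({a}, {b})")
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"correlation rho {rho} outside (-1, 1)")

    def design_columns(self) -> set[str]:
        """Column names an OutcomeSpec may reference."""
        cols = {"intercept", "private"}
        for cov in self.covariates:
            if cov.kind in ("binary", "continuous"):
                cols.add(cov.name)
            elif cov.kind == "banded":
                cols.add(cov.name)
                cols.update(f"{cov.name}_band[{lv}]" for lv in cov.levels)
            else:
                cols.update(f"{cov.name}[{lv}]" for lv in cov.levels)
        return cols

    @property
    def covariate_map(self) -> dict[str, CovariateSpec]:
        return {c.name: c for c in self.covariates}


@dataclass
class Cohort:
    """Delivery-level table: one row per birth.

    ``data`` holds a ``group`` column (public/private), one column per
    covariate (two for banded kinds) and one strictly-0/1 column per
    outcome.  ``provenance`` records the generating spec, or ``None`` for
    externally loaded data (which, unlike generated cohorts, may contain
    missing values).
    """

    data: pd.DataFrame
    outcome_names: tuple[str, ...]
    covariates: tuple[CovariateSpec, ...] | None = None
    provenance: CohortSpec | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return (self.data[GROUP_COLUMN] == group).to_numpy()

    def group_sizes(self) -> dict[str, int]:
        return {g: int(self.group_mask(g).sum()) for g in GROUPS}


# ---------------------------------------------------------------------------
# default calibrated spec


def _pct_pair(pair):
    return {"public": pair[0] / 100.0, "private": pair[1] / 100.0}


def _pct_table(table):
    """Renormalise printed percentage columns into exact probability vectors."""
    out = {}
    for gi, g in enumerate(GROUPS):
        vec = np.array([v[gi] for v in table.values()], dtype=float)
        vec = vec / vec.sum()
        out[g] = dict(zip(table.keys(), vec))
    return out


# Illustrative index coefficients for the default outcomes.  These are NOT
# estimates from the study (its record-level data are not public); they are
# fixed, clinically plausible values: risks rise with maternal age and
# birthweight, obstetric risk factors raise both outcomes, and the private
# model of care carries a larger residual effect for elective than for
# emergency sections.
_ELCS_COEFFICIENTS = {
    "intercept": -4.2,
    "age": 0.06,
    "birthweight": 0.10,
    "breech": 1.9,
    "malpresentation": 1.4,
    "placenta_praevia_abruption": 1.1,
    "diabetes_preexisting": 0.8,
    "gestational_diabetes": 0.55,
    "eclampsia_preeclampsia": 0.45,
    "poor_fetal_growth": 0.55,
    "hypertensive_disorders": 0.05,
    "previous_miscarriage": 0.10,
    "teaching_hospital": -0.02,
}
_EMCS_COEFFICIENTS = {
    "intercept": -3.52,
    "age": 0.045,
    "birthweight": 0.35,
    "breech": 0.8,
    "malpresentation": 0.9,
    "placenta_praevia_abruption": 1.3,
    "diabetes_preexisting": 1.2,
    "gestational_diabetes": 0.5,
    "eclampsia_preeclampsia": 0.8,
    "hypertensive_disorders": 0.35,
    "poor_fetal_growth": 0.5,
    "induction": 0.30,
    "previous_miscarriage": 0.08,
    "married": -0.05,
    "teaching_hospital": -0.10,
}


def default_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec calibrated to the published 2009 descriptive table.

    Group sizes (22,059 public / 7,811 private) and every covariate's
    per-group marginal distribution follow the published prevalences; see
    :mod:`csdecomp.calibration`.  Outcome coefficients are illustrative
    defaults, documented as such — they are not study estimates.
    """
    covariates = [
        CovariateSpec("age", "banded", _pct_table(calib.AGE_PREVALENCE),
                      bands=dict(calib.AGE_BANDS)),
        CovariateSpec("social_class", "categorical",
                      _pct_table(calib.SOCIAL_CLASS_PREVALENCE)),
        CovariateSpec("married", "binary", _pct_pair(calib.MARRIED_PREVALENCE)),
        CovariateSpec("country_of_birth", "categorical",
                      _pct_table(calib.COUNTRY_OF_BIRTH_PREVALENCE)),
        CovariateSpec("previous_miscarriage", "binary",
                      _pct_pair(calib.PREVIOUS_MISCARRIAGE_PREVALENCE)),
        CovariateSpec("gestation", "banded", _pct_table(calib.GESTATION_PREVALENCE),
                      bands=dict(calib.GESTATION_BANDS)),
        CovariateSpec("birthweight", "banded",
                      _pct_table(calib.BIRTHWEIGHT_PREVALENCE),
                      bands=dict(calib.BIRTHWEIGHT_BANDS)),
    ]
    covariates += [
        CovariateSpec(name, "binary", _pct_pair(pair))
        for name, pair in calib.CLINICAL_RISK_PREVALENCE.items()
    ]
    covariates.append(
        CovariateSpec("teaching_hospital", "binary",
                      _pct_pair(calib.TEACHING_HOSPITAL_PREVALENCE))
    )
    outcomes = (
        OutcomeSpec("elcs", _ELCS_COEFFICIENTS, group_effect=0.16, link="probit"),
        OutcomeSpec("emcs", _EMCS_COEFFICIENTS, group_effect=0.03, link="probit"),
    )
    spec = CohortSpec(
        n_public=calib.STUDY_2009_COUNTS["public"]["n"],
        n_private=calib.STUDY_2009_COUNTS["private"]["n"],
        covariates=tuple(covariates),
        outcomes=outcomes,
        seed=seed,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# generation


def _substream(seed: int, kind: int, name: str) -> np.random.Generator:
    """Independent RNG stream keyed by (root seed, kind, column name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(kind, key)))


def _inverse_transform(cov: CovariateSpec, group: str, u: np.ndarray,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Map uniforms u ~ U(0,1) through the covariate's inverse CDF."""
    params = cov.group_params[group]
    if cov.kind == "binary":
        return {cov.name: (u < float(params)).astype(np.int64)}
    if cov.kind == "continuous":
        from scipy import stats
        mean, sd = params
        return {cov.name: mean + sd * stats.norm.ppf(u)}
    probs = np.array(list(params.values()), dtype=float)
    levels = np.array(list(params.keys()), dtype=object)
    idx = np.searchsorted(np.cumsum(probs), u, side="right")
    idx = np.minimum(idx, len(levels) - 1)
    if cov.kind == "categorical":
        return {cov.name: levels[idx]}
    # banded: band label plus a continuous value uniform within the band
    lows = np.array([cov.bands[lv][0] for lv in params], dtype=float)
    highs = np.array([cov.bands[lv][1] for lv in params], dtype=float)
    within = rng.random(u.shape[0])
    value = lows[idx] + within * (highs[idx] - lows[idx])
    return {cov.name: value, f"{cov.name}_band": levels[idx]}


def _copula_uniforms(spec: CohortSpec, corr_names: list[str], n: int,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Correlated U(0,1) draws for the covariates named in spec.correlations."""
    from scipy import stats
    k = len(corr_names)
    R = np.eye(k)
    pos = {name: i for i, name in enumerate(corr_names)}
    for a, b, rho in spec.correlations:
        R[pos[a], pos[b]] = R[pos[b], pos[a]] = rho
    # nudge to positive definite if needed
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(k), R, size=n, method="cholesky")
    return {name: stats.norm.cdf(z[:, i]) for name, i in pos.items()}


def design_column(df: pd.DataFrame, name: str) -> np.ndarray:
    """Fetch a design column; ``name[level]`` denotes a categorical dummy."""
    if name == "intercept":
        return np.ones(len(df))
    if name == "private":
        return (df[GROUP_COLUMN] == "private").to_numpy(dtype=float)
    if name.endswith("]") and "[" in name:
        base, level = name[:-1].split("[", 1)
        if base not in df.columns:
            raise DataError(f"design column {name!r}: no column {base!r}")
        return (df[base].astype(str) == level).to_numpy(dtype=float)
    if name not in df.columns:
        raise DataError(f"missing design column {name!r}")
    return df[name].to_numpy(dtype=float)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from ``spec``; a pure function of (spec, seed)."""
    spec.validate()
    sizes = {"public": spec.n_public, "private": spec.n_private}
    n_total = spec.n_public + spec.n_private
    group_values = np.repeat(list(GROUPS), [sizes[g] for g in GROUPS])
    columns: dict[str, np.ndarray] = {GROUP_COLUMN: group_values}

    corr_names: list[str] = []
    for a, b, _ in spec.correlations:
        for name in (a, b):
            if name not in corr_names:
                corr_names.append(name)
    copula_u: dict[str, np.ndarray] = {}
    if corr_names:
        copula_u = _copula_uniforms(
            spec, corr_names, n_total, _substream(spec.seed, 2, "copula")
        )

    for cov in spec.covariates:
        rng = _substream(spec.seed, 0, cov.name)
        u_all = copula_u.get(cov.name)
        if u_all is None:
            u_all = rng.random(n_total)
        else:
            rng.random(n_total)  # keep stream alignment for banded draws
        parts: dict[str, list[np.ndarray]] = {}
        offset = 0
        for g in GROUPS:
            n_g = sizes[g]
            vals = _inverse_transform(cov, g, u_all[offset:offset + n_g], rng)
            for col, arr in vals.items():
                parts.setdefault(col, []).append(arr)
            offset += n_g
        for col, arrs in parts.items():
            columns[col] = np.concatenate(arrs)

    df = pd.DataFrame(columns)

    for out in spec.outcomes:
        lp = np.zeros(n_total)
        for col, coef in out.coefficients.items():
            lp += coef * design_column(df, col)
        lp += out.group_effect * design_column(df, "private")
        link = get_link(out.link)
        p = link.cdf(lp)
        if out.link == "identity":
            bad = np.flatnonzero((p < 0) | (p > 1))
            if bad.size:
                i = int(bad[0])
                raise ConfigError(
                    f"outcome {out.name!r}: identity link gives probability "
                    f"{p[i]:.6f} (linear predictor {lp[i]:.6f}) at row {i}"
                )
        rng = _substream(spec.seed, 1, out.name)
        df[out.name] = (rng.random(n_total) < p).astype(np.int64)

    return Cohort(
        data=df,
        outcome_names=tuple(out.name for out in spec.outcomes),
        covariates=spec.covariates,
        provenance=spec,
    )


# ---------------------------------------------------------------------------
# spec serialization (dict form; YAML/JSON handled by callers)


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_public": spec.n_public,
        "n_private": spec.n_private,
        "seed": spec.seed,
        "covariates": [
            {
                "name": c.name,
                "kind": c.kind,
                "group_params": {g: c.group_params[g] for g in GROUPS},
                **({"bands": {k: list(v) for k, v in c.bands.items()}}
                   if c.bands else {}),
            }
            for c in spec.covariates
        ],
        "outcomes": [
            {
                "name": o.name,
                "coefficients": dict(o.coefficients),
                "group_effect": o.group_effect,
                "link": o.link,
            }
            for o in spec.outcomes
        ],
        "correlations": [list(c) for c in spec.correlations],
    }


def cohort_spec_from_dict(d: Mapping) -> CohortSpec:
    try:
        covariates = tuple(
            CovariateSpec(
                name=c["name"], kind=c["kind"], group_params=c["group_params"],
                bands={k: tuple(v) for k, v in c["bands"].items()}
                if c.get("bands") else None,
            )
            for c in d["covariates"]
        )
        outcomes = tuple(
            OutcomeSpec(name=o["name"], coefficients=o["coefficients"],
                        group_effect=float(o.get("group_effect", 0.0)),
                        link=o.get("link", "probit"))
            for o in d["outcomes"]
        )
        spec = CohortSpec(
            n_public=int(d["n_public"]), n_private=int(d["n_private"]),
            covariates=covariates, outcomes=outcomes,
            seed=int(d.get("seed", 0)),
            correlations=tuple(tuple(c) for c in d.get("correlations", ())),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed cohort spec: {exc}") from exc
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# CSV I/O


@dataclass(frozen=True)
class CohortSchema:
    """Column roles for reading a cohort CSV.

    ``covariates=None`` accepts every non-group, non-outcome column as a
    covariate; otherwise unknown columns are an error.
    """

    outcomes: tuple[str, ...] = ("elcs", "emcs")
    group_column: str = GROUP_COLUMN
    covariates: tuple[str, ...] | None = None
    missing_sentinel: str | None = None


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort to CSV (UTF-8, header, no index)."""
    cohort.data.to_csv(path, index=False)


def read_cohort(path, schema: CohortSchema = CohortSchema()) -> Cohort:
    """Read a cohort CSV; round-trips ``write_cohort`` output exactly."""
    try:
        df = pd.read_csv(
            path,
            na_values=[schema.missing_sentinel] if schema.missing_sentinel else [],
            keep_default_na=False,
        )
    except (OSError, UnicodeDecodeError) as exc:
        raise DataError(f"unreadable cohort file {path!r}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataError("empty cohort") from exc
    if len(df) == 0:
        raise DataError("empty cohort")
    if schema.group_column not in df.columns:
        raise DataError(f"missing group column {schema.group_column!r}")
    bad_groups = set(df[schema.group_column].unique()) - set(GROUPS)
    if bad_groups:
        raise DataError(f"group column contains unknown labels {sorted(bad_groups)}")
    outcomes = [o for o in schema.outcomes if o in df.columns]
    if not outcomes:
        raise DataError(f"no outcome column among {schema.outcomes} present")
    if schema.covariates is not None:
        known = {schema.group_column, *schema.outcomes, *schema.covariates}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise DataError(f"unknown columns {unknown}")
    for col in outcomes:
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0, 1, "0", "1"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"outcome column {col!r} has non-binary value {vals.iloc[row]!r} "
                f"at row {row}"
            )
        if not vals.isna().any():
            df[col] = vals.astype(np.int64)
    # numeric covariates read as strings (e.g. under a sentinel) stay as read;
    # listwise deletion downstream handles flagged missing values
    return Cohort(data=df, outcome_names=tuple(outcomes), covariates=None,
                  provenance=None)
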