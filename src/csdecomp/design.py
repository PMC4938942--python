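"""Design-matrix construction shared by the model and decomposition layers.

Terms name cohort covariates; categorical terms expand into dummy columns
against a declared reference level (``name[level]``), banded covariates
enter through their continuous column, and the group indicator enters as a
``private`` dummy.  Column kinds (binary vs continuous) are carried along
explicitly because average marginal effects treat them differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import GROUP_COLUMN, Cohort, design_column
from .exceptions import ConfigError, DataError

INTERCEPT = "intercept"
PRIVATE = "private"


@dataclass(frozen=True)
class DesignInfo:
    """Ordered design columns with their kinds and source data columns."""

    columns: tuple[str, ...]
    kinds: Mapping[str, str]          # column -> intercept|binary|continuous
    source_columns: tuple[str, ...]   # raw data columns the design reads
    term_of: Mapping[str, str]        # design column -> term name

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(df), len(self.columns)))
        for j, col in enumerate(self.columns):
            X[:, j] = design_column(df, col)
        return X

    def index_of(self, column: str) -> int:
        return self.columns.index(column)


def _term_kind(cohort: Cohort, term: str,
               declared: Mapping[str, str] | None) -> tuple[str, list[str] | None]:
    """Resolve a term to (kind, levels); levels only for categoricals."""
    if cohort.covariates is not None:
        for cov in cohort.covariates:
            if cov.name == term:
                if cov.kind == "banded":
                    return "continuous", None
                if cov.kind == "categorical":
                    return "categorical", cov.levels
                return cov.kind, None
    if declared and term in declared:
        kind = declared[term]
        if kind == "categorical":
            levels = sorted(cohort.data[term].dropna().astype(str).unique())
            return kind, levels
        return kind, None
    if term not in cohort.data.columns:
        raise ConfigError(f"model term {term!r} not found in cohort")
    col = cohort.data[term]
    if col.dtype == object:
        return "categorical", sorted(col.dropna().astype(str).unique())
    vals = pd.unique(col.dropna())
    if set(np.asarray(vals).tolist()) <= {0, 1}:
        return "binary", None
    return "continuous", None


def build_design(cohort: Cohort, terms: Sequence[str], *,
                 include_private: bool = False,
                 reference_levels: Mapping[str, str] | None = None,
                 term_kinds: Mapping[str, str] | None = None) -> DesignInfo:
    columns: list[str] = [INTERCEPT]
    kinds: dict[str, str] = {INTERCEPT: "intercept"}
    term_of: dict[str, str] = {INTERCEPT: INTERCEPT}
    sources: list[str] = []
    if include_private:
        columns.append(PRIVATE)
        kinds[PRIVATE] = "binary"
        term_of[PRIVATE] = PRIVATE
        sources.append(GROUP_COLUMN)
    for term in terms:
        kind, levels = _term_kind(cohort, term, term_kinds)
        if kind == "categorical":
            ref = (reference_levels or {}).get(term, levels[0])
            if ref not in levels:
                raise ConfigError(
                    f"reference level {ref!r} not a level of {term!r} ({levels})"
                )
            for lv in levels:
                if lv == ref:
                    continue
                col = f"{term}[{lv}]"
                columns.append(col)
                kinds[col] = "binary"
                term_of[col] = term
            sources.append(term)
        else:
            columns.append(term)
            kinds[term] = kind
            term_of[term] = term
            sources.append(term)
    dupes = {c for c in columns if columns.count(c) > 1}
    if dupes:
        raise ConfigError(f"duplicate design columns {sorted(dupes)}")
    return DesignInfo(tuple(columns), kinds, tuple(sources), term_of)
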