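"""Descriptive tables and end-to-end analysis orchestration.

``descriptive_table`` reproduces the shape of the published prevalence /
unadjusted-rate table: per characteristic and level, the percentage
prevalence in each group, the unadjusted elective and emergency CS rates
(as a proportion of total deliveries in the cell), and a Pearson chi-square
test of the group-by-level contingency table.

``run_analysis`` drives the whole pipeline from one config: cohort
(loaded or simulated), descriptive table, the two model specifications per
outcome (group indicator only; fully adjusted), the Fairlie decomposition
per outcome and reference scheme, sensitivity reruns, and a machine-readable
manifest.  The same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .calibration import STUDY_2009_COUNTS
from .cohort import (Cohort, CohortSchema, CohortSpec, GROUPS, default_spec,
                     cohort_spec_from_dict, generate_cohort, read_cohort,
                     write_cohort)
from .exceptions import ConfigError, CsdecompError, DataError
from .fairlie import DecompositionSpec, detailed_decomposition, sensitivity_rerun
from .model import (ModelSpec, average_marginal_effects, fit, pseudo_r2,
                    significance_stars)

logger = logging.getLogger("csdecomp")

__all__ = [
    "DescriptiveTable",
    "OverallRates",
    "AnalysisConfig",
    "descriptive_table",
    "overall_rates",
    "rates_from_counts",
    "run_analysis",
    "default_analysis_config",
    "DEFAULT_ELCS_TERMS",
    "DEFAULT_EMCS_TERMS",
    "CLINICAL_TERMS",
]


@dataclass
class DescriptiveTable:
    """Prevalence and unadjusted CS rates per characteristic level."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _chi_square(levels: pd.Series, group: pd.Series) -> tuple[float, float, float | None]:
    """Pearson chi-square of level x group; returns (stat, p, corrected_stat).

    No continuity correction (tables usually exceed 2x2); for 2x2 tables the
    Yates-corrected statistic is additionally reported.
    """
    table = pd.crosstab(levels, group)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, np.nan, None
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    corrected = None
    if table.shape == (2, 2):
        corrected = stats.chi2_contingency(table.to_numpy(), correction=True)[0]
    return float(stat), float(p), corrected


def _characteristics(cohort: Cohort) -> list[tuple[str, pd.Series]]:
    """(name, level series) pairs; banded covariates report their bands."""
    df = cohort.data
    out = []
    if cohort.covariates is not None:
        for cov in cohort.covariates:
            if cov.kind == "binary":
                out.append((cov.name, df[cov.name].map({1: "yes", 0: "no"})))
            elif cov.kind == "categorical":
                out.append((cov.name, df[cov.name]))
            elif cov.kind == "banded":
                out.append((cov.name, df[f"{cov.name}_band"]))
            # pure continuous covariates have no levels to tabulate
        return out
    skip = {"group", *cohort.outcome_names}
    for col in df.columns:
        if col in skip:
            continue
        series = df[col]
        if series.dtype == object:
            out.append((col, series))
        elif set(pd.unique(series.dropna())).issubset({0, 1}):
            out.append((col, series.map({1: "yes", 0: "no"})))
    return out


def descriptive_table(cohort: Cohort) -> DescriptiveTable:
    """Per-level prevalence, unadjusted CS rates and chi-square stars.

    Missing values are excluded from prevalence denominators; CS rates are
    calculated as a proportion of total deliveries in the cell.  A
    characteristic with a single observed level gets no p-value.
    """
    df = cohort.data
    masks = {g: (df["group"] == g).to_numpy() for g in GROUPS}
    if not all(m.any() for m in masks.values()):
        raise DataError("both groups must be present")
    outcome_vals = {
        o: pd.to_numeric(df[o], errors="coerce").to_numpy(dtype=float)
        for o in cohort.outcome_names
    }
    rows = []
    for name, levels in _characteristics(cohort):
        levels = levels.astype("object")
        observed = levels.notna().to_numpy()
        stat, p, corrected = _chi_square(levels[observed],
                                         df["group"].to_numpy()[observed])
        stars = significance_stars(p) if np.isfinite(p) else ""
        uniq = [lv for lv in pd.unique(levels.dropna())]
        if set(uniq) == {"yes", "no"}:
            uniq = ["yes"]  # binary rows report the positive level only
        for i, lv in enumerate(uniq):
            in_level = (levels == lv).to_numpy()
            row = {"characteristic": name, "level": lv}
            for g in GROUPS:
                denom = (masks[g] & observed).sum()
                row[f"prevalence_{g}"] = 100.0 * (in_level & masks[g]).sum() / denom
            for o in cohort.outcome_names:
                for g in GROUPS:
                    cell = in_level & masks[g]
                    n_cell = cell.sum()
                    row[f"{o}_rate_{g}"] = (
                        100.0 * np.nansum(outcome_vals[o][cell]) / n_cell
                        if n_cell else np.nan
                    )
            row["chi2"] = stat if i == 0 else np.nan
            row["p_value"] = p if i == 0 else np.nan
            row["stars"] = stars if i == 0 else ""
            row["chi2_corrected"] = corrected if i == 0 and corrected is not None else np.nan
            rows.append(row)
    return DescriptiveTable(pd.DataFrame(rows))


def rates_from_counts(total: int, count: int) -> tuple[float, float]:
    """(raw percentage, display-rounded to 1 decimal)."""
    if total <= 0:
        raise DataError("empty cohort")
    raw = 100.0 * count / total
    return raw, round(raw, 1)


@dataclass
class OverallRates:
    """Births, CS counts and percentage rates, per group and overall."""

    summary: pd.DataFrame  # rows: public, private, total

    def display(self) -> pd.DataFrame:
        out = self.summary.copy()
        for col in out.columns:
            if col.endswith("_rate"):
                out[col] = out[col].round(1)
        return out


def overall_rates(cohort: Cohort) -> OverallRates:
    """Total births, CS counts and ELCS/EMCS split per group.

    A delivery counts as CS if any outcome indicator is 1.  Rates are
    percentages of total deliveries; unrounded values are retained, with
    rounding to one decimal applied only in :meth:`OverallRates.display`.
    """
    df = cohort.data
    if len(df) == 0:
        raise DataError("empty cohort")
    rows = {}
    for label in (*GROUPS, "total"):
        sub = df if label == "total" else df[df["group"] == label]
        n = len(sub)
        row = {"n": n}
        any_cs = np.zeros(n, dtype=bool)
        for o in cohort.outcome_names:
            vals = pd.to_numeric(sub[o], errors="coerce").to_numpy(dtype=float)
            count = int(np.nansum(vals))
            row[f"{o}_n"] = count
            row[f"{o}_rate"] = 100.0 * count / n if n else np.nan
            any_cs |= vals == 1
        row["cs_n"] = int(any_cs.sum())
        row["cs_rate"] = 100.0 * any_cs.sum() / n if n else np.nan
        rows[label] = row
    return OverallRates(pd.DataFrame(rows).T.convert_dtypes())


# ---------------------------------------------------------------------------
# orchestration

# Fully adjusted model covariates; induction of labour enters the emergency
# model only, and fetal distress / dystocia are never generated or modelled.
DEFAULT_ELCS_TERMS = (
    "age", "social_class", "married", "country_of_birth",
    "previous_miscarriage", "birthweight", "breech", "diabetes_preexisting",
    "gestational_diabetes", "eclampsia_preeclampsia", "hypertensive_disorders",
    "malpresentation", "placenta_praevia_abruption", "poor_fetal_growth",
    "teaching_hospital",
)
DEFAULT_EMCS_TERMS = DEFAULT_ELCS_TERMS[:-1] + ("induction", "teaching_hospital")

CLINICAL_TERMS = (
    "breech", "diabetes_preexisting", "gestational_diabetes",
    "eclampsia_preeclampsia", "hypertensive_disorders", "malpresentation",
    "placenta_praevia_abruption", "poor_fetal_growth", "induction",
)


def default_analysis_config(output_dir, seed: int = 0, replications: int = 1000,
                            references: Sequence[str] = ("public", "private",
                                                         "pooled")) -> AnalysisConfig:
    """The standard workflow on the calibrated synthetic cohort.

    Both outcomes with mutual exclusion (the elective model drops emergency
    deliveries and vice versa), the fully adjusted covariate lists, all
    requested reference schemes, and the two emergency-model sensitivity
    reruns (excluding the clinical block; excluding age).
    """
    return AnalysisConfig(
        output_dir=Path(output_dir),
        cohort_spec=None,  # calibrated default
        seed=seed,
        outcomes={"elcs": DEFAULT_ELCS_TERMS, "emcs": DEFAULT_EMCS_TERMS},
        exclusions={"elcs": ("emcs",), "emcs": ("elcs",)},
        references=tuple(references),
        replications=replications,
        sensitivity={"emcs": {
            "no_clinical": tuple(t for t in CLINICAL_TERMS
                                 if t in DEFAULT_EMCS_TERMS),
            "no_age": ("age",),
        }},
        published_counts=STUDY_2009_COUNTS,
    )


@dataclass
class AnalysisConfig:
    """Everything one full run needs; see ``AnalysisConfig.from_dict``."""

    output_dir: Path
    cohort_path: Path | None = None
    cohort_spec: CohortSpec | None = None
    seed: int = 0
    outcomes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    exclusions: Mapping[str, Sequence[str]] = field(default_factory=dict)
    link: str = "probit"
    references: Sequence[str] = ("public",)
    replications: int = 1000
    decomposition_seed: int | None = None
    sensitivity: Mapping[str, Mapping[str, Sequence[str]]] = field(default_factory=dict)
    published_counts: Mapping[str, Mapping[str, int]] | None = None

    @classmethod
    def from_dict(cls, d: Mapping, base_dir: Path | None = None) -> "AnalysisConfig":
        base = Path(base_dir) if base_dir else Path(".")
        try:
            cohort_cfg = d.get("cohort", {}) or {}
            spec = None
            path = None
            if "path" in cohort_cfg:
                path = base / cohort_cfg["path"]
            elif "spec" in cohort_cfg:
                spec = cohort_spec_from_dict(cohort_cfg["spec"])
            decomp = d.get("decomposition", {}) or {}
            return cls(
                output_dir=base / d["output_dir"],
                cohort_path=path,
                cohort_spec=spec,
                seed=int(cohort_cfg.get("seed", d.get("seed", 0))),
                outcomes={k: tuple(v) for k, v in (d.get("outcomes") or {}).items()},
                exclusions={k: tuple(v) for k, v in (d.get("exclusions") or {}).items()},
                link=d.get("link", "probit"),
                references=tuple(decomp.get("references", ["public"])),
                replications=int(decomp.get("replications", 1000)),
                decomposition_seed=decomp.get("seed"),
                sensitivity={
                    o: {label: tuple(terms) for label, terms in runs.items()}
                    for o, runs in (d.get("sensitivity") or {}).items()
                },
                published_counts=d.get("published_counts"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed analysis config: {exc}") from exc


def _load_cohort(config: AnalysisConfig) -> Cohort:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    spec = config.cohort_spec or default_spec()
    if spec.seed != config.seed:
        from dataclasses import replace
        spec = replace(spec, seed=config.seed)
    return generate_cohort(spec)


def _config_hash(config: AnalysisConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, CohortSpec):
            from .cohort import cohort_spec_to_dict
            return cohort_spec_to_dict(o)
        return repr(o)

    payload = {k: v for k, v in config.__dict__.items() if k != "output_dir"}
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Any stage failure aborts with the stage name; files already written for
    the failed run are removed.
    """
    written: list[Path] = []
    stage = "config"
    try:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

        stage = "data"
        cohort = _load_cohort(config)
        missing = [o for o in config.outcomes if o not in cohort.data.columns]
        if missing:
            raise ConfigError(f"outcomes {missing} not present in cohort")

        manifest: dict = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_rows": cohort.n,
            "group_sizes": cohort.group_sizes(),
            "models": {},
            "decompositions": {},
            "sensitivity": {},
        }

        def save(name: str, writer) -> None:
            path = outdir / name
            writer(path)
            written.append(path)

        stage = "descriptive"
        save("descriptive.csv", descriptive_table(cohort).to_csv)
        rates = overall_rates(cohort)
        save("overall_rates.csv", lambda p: rates.summary.to_csv(p, index_label="group"))
        manifest["overall_rates"] = json.loads(
            rates.summary.to_json(orient="index"))

        if config.published_counts:
            # recompute published aggregate rates; surfaces e.g. the
            # EMCS-share-of-CS figure implied by the printed counts
            checks = {}
            counts = config.published_counts
            tot_n = sum(c["n"] for c in counts.values())
            tot_cs = sum(c.get("elcs", 0) + c.get("emcs", 0) for c in counts.values())
            checks["cs_rate_overall_pct"] = rates_from_counts(tot_n, tot_cs)[1]
            tot_emcs = sum(c.get("emcs", 0) for c in counts.values())
            checks["emcs_share_of_cs_pct"] = rates_from_counts(tot_cs, tot_emcs)[1]
            for g, c in counts.items():
                checks[f"cs_rate_{g}_pct"] = rates_from_counts(
                    c["n"], c.get("elcs", 0) + c.get("emcs", 0))[1]
            manifest["published_count_checks"] = checks

        stage = "models"
        model_specs: dict[str, ModelSpec] = {}
        for outcome, terms in config.outcomes.items():
            exclude = tuple(config.exclusions.get(outcome, ()))
            for label, spec in {
                "private_only": ModelSpec(outcome, (), link=config.link,
                                          exclude_if_positive=exclude),
                "adjusted": ModelSpec(outcome, tuple(terms), link=config.link,
                                      exclude_if_positive=exclude),
            }.items():
                res = fit(cohort, spec)
                ame = average_marginal_effects(res)
                save(f"model_{outcome}_{label}.csv", ame.to_csv)
                manifest["models"][f"{outcome}_{label}"] = {
                    "n_used": res.n_used,
                    "loglik": res.loglik,
                    "pseudo_r2": pseudo_r2(res),
                }
                if label == "adjusted":
                    model_specs[outcome] = spec

        stage = "decomposition"
        decomp_seed = (config.decomposition_seed
                       if config.decomposition_seed is not None else config.seed)
        for outcome, mspec in model_specs.items():
            for ref in config.references:
                dspec = DecompositionSpec(reference=ref,
                                          replications=config.replications,
                                          seed=decomp_seed)
                result = detailed_decomposition(cohort, outcome, mspec, dspec)
                save(f"decomposition_{outcome}_{ref}.csv", result.to_csv)
                agg = result.aggregate
                manifest["decompositions"][f"{outcome}_{ref}"] = {
                    "gap": agg.gap,
                    "explained": agg.explained,
                    "unexplained": agg.unexplained,
                    "explained_share_pct": agg.explained_share,
                    "replications": result.replications_used,
                    "failed_replications": result.failed_replications,
                    "spec": {
                        "reference": dspec.reference,
                        "replications": dspec.replications,
                        "randomize_order": dspec.randomize_order,
                        "pooled_includes_group_dummy": dspec.pooled_includes_group_dummy,
                        "se_method": dspec.se_method,
                        "seed": dspec.seed,
                    },
                }

        stage = "sensitivity"
        for outcome, runs in config.sensitivity.items():
            if outcome not in model_specs:
                raise ConfigError(f"sensitivity outcome {outcome!r} has no model")
            for label, drop in runs.items():
                dspec = DecompositionSpec(reference=config.references[0],
                                          replications=config.replications,
                                          seed=decomp_seed)
                result = sensitivity_rerun(cohort, outcome, model_specs[outcome],
                                           dspec, drop)
                save(f"sensitivity_{outcome}_{label}.csv", result.to_csv)
                manifest["sensitivity"][f"{outcome}_{label}"] = {
                    "dropped": list(result.dropped_terms),
                    "gap": result.aggregate.gap,
                    "explained_share_pct": result.aggregate.explained_share,
                }

        stage = "manifest"
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
        logger.info("analysis complete: %d files in %s", len(written), outdir)
        return manifest
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, CsdecompError):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise CsdecompError(f"stage {stage!r} failed: {exc}") from exc
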