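"""Sensitivity of the emergency-CS decomposition to covariate blocks.

Re-runs the emergency-CS decomposition without the clinical risk factors
and without maternal age, mirroring the usual robustness exercise: if age
carries most of the compositional gap, dropping it should collapse the
explained share, while dropping other blocks moves it far less.
"""

from csdecomp import (CLINICAL_TERMS, DEFAULT_EMCS_TERMS, DecompositionSpec,
                      ModelSpec, default_spec, detailed_decomposition,
                      generate_cohort, sensitivity_rerun)

cohort = generate_cohort(default_spec(seed=1))
mspec = ModelSpec("emcs", DEFAULT_EMCS_TERMS, exclude_if_positive=("elcs",))
dspec = DecompositionSpec(reference="public", replications=200, seed=1)

full = detailed_decomposition(cohort, "emcs", mspec, dspec)
print(f"full model:        explained {full.aggregate.explained_share:.1f}% "
      f"of a {100*full.aggregate.gap:+.2f} pp gap")

drop_clinical = tuple(t for t in CLINICAL_TERMS if t in DEFAULT_EMCS_TERMS)
for label, drop in [("without clinical", drop_clinical), ("without age", ("age",))]:
    rerun = sensitivity_rerun(cohort, "emcs", mspec, dspec, drop)
    print(f"{label + ':':<19}explained {rerun.aggregate.explained_share:.1f}%"
          f"  (dropped: {', '.join(rerun.dropped_terms)})")

print("\nIn this synthetic cohort the age distributions differ sharply "
      "between groups,\nso removing age wipes out most of the explained "
      "component; the clinical block\nmatters far less for the gap even "
      "though it strongly predicts the outcome.")
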