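"""Fairlie decomposition of the public-private elective-CS gap.

Splits the raw gap into the part explained by different covariate mixes
and the unexplained remainder, then lists the largest per-covariate
contributions (200 replications, random switching order, public-sample
reference coefficients).
"""

from csdecomp import (DEFAULT_ELCS_TERMS, DecompositionSpec, ModelSpec,
                      default_spec, detailed_decomposition, generate_cohort)

cohort = generate_cohort(default_spec(seed=1))
mspec = ModelSpec("elcs", DEFAULT_ELCS_TERMS, exclude_if_positive=("emcs",))

for reference in ("public", "private", "pooled"):
    dspec = DecompositionSpec(reference=reference, replications=200, seed=1)
    result = detailed_decomposition(cohort, "elcs", mspec, dspec)
    agg = result.aggregate
    print(f"\nreference={reference}: gap {100*agg.gap:+.2f} pp, "
          f"explained {agg.explained_share:.1f}%, "
          f"unexplained {100 - agg.explained_share:.1f}%")
    if reference == "public":
        top = result.table.drop("(residual)").reindex(
            result.table["contribution"].abs().sort_values(ascending=False).index
        ).head(5)
        print("largest contributions (probability units; % of gap):")
        print(top[["contribution", "pct_of_gap", "z", "stars"]]
              .round(4).to_string())

print("\nA negative gap means the private rate is higher.  A contribution "
      "with positive\n'% of gap' moves the rates apart (private-ward "
      "characteristics raise the rate);\nthe three references differ only in "
      "whose coefficients price the covariate\ndifferences — the raw gap is "
      "identical.")
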