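"""Chain-length trend directions and anion ordering vs the Hofmeister series.

For each cation family the screen's capacities are correlated with the
alkyl chain length per anion (Spearman sign -> decreasing / increasing /
non-monotone), and the family's mean-capacity anion ordering is compared
with the Hofmeister reference by Kendall tau over the shared anions.
"""

from collections import Counter

from ilscreen import (
    HOFMEISTER_ANION_ORDER,
    RunConfig,
    anion_concordance,
    run_screening_pipeline,
)

bundle = run_screening_pipeline(RunConfig(output_dir="screen-out"))

for family, report in bundle.trends.items():
    directions = Counter(report.per_anion_direction.values())
    tau = report.concordance_with_reference
    print(f"{family:<14} {dict(directions)}  Hofmeister tau = "
          f"{'n/a' if tau is None else f'{tau:+.2f}'}")

# the capacity ordering reported for the shared anions, vs the reference
observed = ["[SO4]-", "[Cl]-", "[Br]-", "[NO3]-"]
tau = anion_concordance(observed, list(HOFMEISTER_ANION_ORDER))
print(f"reported capacity order {observed} vs Hofmeister: tau = {tau:+.3f}")
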