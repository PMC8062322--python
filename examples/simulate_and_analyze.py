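"""Simulate a two-group cohort and export the tidy analysis tables.

Ten alternation-biased ("control") and ten repetition-biased ("impaired")
agents explore hour-long sessions; zone-entry logs go through the full
pipeline and the per-subject summaries separate the groups on
alternation percentage without any group label leaking into the analysis."""

from fmpy import (
    AgentSpec,
    DEFAULT_GEOMETRY,
    SessionSpec,
    analyze_subject,
    cohort_table,
    simulate_cohort,
    summary_frame,
)

specs, labels = [], []
for grp, p_alt, seeds in [("control", 0.75, range(10)), ("impaired", 0.45, range(10, 20))]:
    for s in seeds:
        specs.append(
            (AgentSpec("markov1", p_alternate=p_alt, seed=s),
             SessionSpec(3600.0, 3.6, n_entries_target=1001, subject_id=f"{grp}{s:02d}"))
        )
        labels.append(grp)

logs = simulate_cohort(specs, DEFAULT_GEOMETRY)
summaries = [analyze_subject(log, DEFAULT_GEOMETRY) for log in logs]

wide = summary_frame(summaries)
wide["group"] = labels
print(wide.groupby("group")[["alternation_pct", "repetition_pct", "L4",
                             "n_significant_lags"]].mean().round(2))
print("\nControl agents sit far above the 12.5% chance share of alternations;")
print("impaired agents fall toward chance and carry close to one full bit of")
print("residual choice uncertainty (L4 -> 1 = memoryless).")

long = cohort_table(summaries, labels)
print(f"\ntidy long table: {len(long)} rows, e.g.\n{long.head(4).to_string(index=False)}")
print("Feed this table to external mixed-model software with total_turns as")
print("the locomotor covariate.")
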