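"""Literature footprint of a single highly cited trial.

Uses the exemplar single-trial network (21 articles, 60 systematic
reviews, 16 guidelines) and shows the per-path classification: which of
the guideline connections run through included citations at every step.
"""

from collections import Counter

from guideline_impact import enumerate_paths, exemplar_fixture, export_transitions, trial_impact

network = exemplar_fixture()
trial_id = next(iter(network.trials))

payload = export_transitions(network, trial_id)
layers = Counter(n["layer"] for n in payload["nodes"])
print(f"trial {trial_id}: {layers['article']} articles, {layers['sr']} SRs, "
      f"{layers['cpg']} guidelines")

paths = enumerate_paths(network, trial_id)
cases = Counter(p.case_number for p in paths)
print(f"{len(paths)} trial->guideline paths by case number:", dict(sorted(cases.items())))

ti = trial_impact(network, trial_id)
print(f"associated guidelines: {ti.associated_cpgs}  "
      f"impacted: {ti.impacted_cpgs}  impact-on-CPGs: {ti.impact_on_cpgs}")

# impacted counts each guideline once; impact-on-CPGs sums the main-text
# mention counts of the terminal references of impactful paths.
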