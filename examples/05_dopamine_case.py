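"""The dopamine case study: deficiencies, treatments, grade tables.

Loads the packaged presynaptic dopamine network (a synthetic stand-in with
the published dimensions, species identities and healthy-state
concentrations), runs the VMAT2-deficiency series, and evaluates two
clinical treatment presets under the 50% deficiency.
"""

from fmdd import solve_fixed_targets, solve_steady_state
from fmdd.dopamine import (
    DRUG_PRESETS,
    load_dopamine_model,
    make_problem,
    run_scenario_table,
    scenario_perturbation,
)

net = load_dopamine_model()
healthy = solve_steady_state(net)
i = net.species_index("DA-e")
print(f"healthy extracellular dopamine: {healthy.x[i]:.1f} (relative units)")

print("\nVMAT2 deficiency series (DA-e fold vs healthy):")
for name in ["VM50", "VM70", "VM90", "VM95"]:
    st = solve_steady_state(net, scenario_perturbation(net, name))
    print(f"  {name}: {st.x[i] / healthy.x[i]:.3f}")

print("\ntreatments under VM50 (therapeutic + adverse objectives):")
problem = make_problem(net, "VM50", include_variation=False)
for preset in ["maoi", "levodopa"]:
    dp = solve_fixed_targets(problem, tuple(DRUG_PRESETS[preset]),
                             n_starts=4, seed=0)
    print(f"  {preset:10s} T={dp.report.T:.3f} A={dp.report.A:.3f} "
          f"lambda={dp.lam:.3f}")

print("\nuntreated VM50 fold/grade table (reported species):")
table = run_scenario_table(net, ["VM50"])
sub = table[table.treatment == "untreated"][["species", "basal", "fold",
                                             "grade", "status"]]
print(sub.to_string(index=False))
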